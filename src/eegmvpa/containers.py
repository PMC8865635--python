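"""Core in-memory containers for epoched and continuous EEG data.

The package works on two array-backed containers:

* :class:`ContinuousRecording` — channels x samples, with a stimulus event
  list, as produced by an acquisition system or the synthetic session
  generator.
* :class:`EpochedDataset` — trials x channels x samples, cut around stimulus
  onsets, carrying stimulus identities and animate/non-animal class labels.

Both keep a ``provenance`` list that processing stages append to, so a
finished dataset records every transformation (with parameters and seeds)
that produced it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

ANIMATE = "animate"
INANIMATE = "inanimate"

#: Scalp montage used by the default study design: 63 recording electrodes
#: plus the reference electrode ("REF") inserted as channel 33 (index 32),
#: mirroring a 64-channel cap where channel 33 is the reference.
SCALP_CHANNELS_63 = [
    # frontal pole / anterior frontal
    "Fp1", "Fpz", "Fp2", "AF7", "AF3", "AFz", "AF4", "AF8",
    # frontal
    "F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8",
    # fronto-central / fronto-temporal
    "FT7", "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6", "FT8",
    # central / temporal
    "T7", "C5", "C3", "C1", "Cz", "C2",  # REF sits after C2 (index 32)
    "C4", "C6", "T8",
    # centro-parietal / temporo-parietal
    "TP7", "TP9", "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6", "TP8", "TP10",
    # parietal
    "P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8",
    # parieto-occipital / occipital
    "PO7", "PO3", "POz", "PO4", "PO8", "O1", "Oz", "O2",
]

REFERENCE_CHANNEL = "REF"
REFERENCE_INDEX = 32
EOG_CHANNELS = ["EOG1", "EOG2", "EOG3"]


def default_channel_names(include_reference: bool = True,
                          include_eog: bool = True) -> list[str]:
    """Channel-name list of the default montage, in recording order.

    With both flags set this is the full 67-channel acquisition layout:
    63 scalp electrodes, the reference as channel 33 (index 32), and three
    EOG channels at the end.
    """
    names = list(SCALP_CHANNELS_63)
    if include_reference:
        names.insert(REFERENCE_INDEX, REFERENCE_CHANNEL)
    if include_eog:
        names.extend(EOG_CHANNELS)
    return names


#: The 23 named scalp regions used for region-level ERP and decoding
#: summaries, mapped to electrode names of the default montage.
DEFAULT_REGIONS: dict[str, list[str]] = {
    "Fp": ["Fp1", "Fpz", "Fp2"],
    "AFL": ["AF7", "AF3"],
    "AFR": ["AF4", "AF8"],
    "FL": ["F7", "F5", "F3"],
    "Fz": ["AFz", "F1", "Fz", "F2"],
    "FR": ["F4", "F6", "F8"],
    "FCL": ["FC5", "FC3", "FC1"],
    "FCR": ["FC2", "FC4", "FC6"],
    "TL": ["FT7", "T7"],
    "CL": ["C5", "C3", "C1"],
    "Cz": ["FCz", "Cz", "CPz"],
    "CR": ["C2", "C4", "C6"],
    "TR": ["FT8", "T8"],
    "TPL": ["TP7", "TP9"],
    "CPL": ["CP5", "CP3", "CP1"],
    "CPR": ["CP2", "CP4", "CP6"],
    "TPR": ["TP8", "TP10"],
    "PL": ["P7", "P5", "P3"],
    "PR": ["P4", "P6", "P8"],
    "Pz": ["P1", "Pz", "P2"],
    "POL": ["PO7", "PO3"],
    "POR": ["PO4", "PO8"],
    "O": ["POz", "O1", "Oz", "O2"],
}


class ChannelGroupMap:
    """Named scalp regions mapped to channel index sets.

    Parameters
    ----------
    groups
        Mapping of region name to channel indices (into the channel axis of
        the dataset the map will be used with).
    """

    def __init__(self, groups: Mapping[str, Sequence[int]]):
        if not groups:
            raise ValueError("channel-group map must contain at least one group")
        seen: set[int] = set()
        self.groups: dict[str, np.ndarray] = {}
        for name, idx in groups.items():
            arr = np.asarray(list(idx), dtype=int)
            if arr.size == 0:
                raise ValueError(f"channel group {name!r} is empty")
            self.groups[name] = arr
            seen.update(arr.tolist())
        self._max_index = max(seen)

    @classmethod
    def from_names(cls, channel_names: Sequence[str],
                   regions: Mapping[str, Sequence[str]] | None = None) -> "ChannelGroupMap":
        """Build an index map from electrode names.

        Regions default to :data:`DEFAULT_REGIONS`; electrodes absent from
        ``channel_names`` raise, so a map never silently references missing
        channels.
        """
        regions = DEFAULT_REGIONS if regions is None else regions
        lookup = {name: i for i, name in enumerate(channel_names)}
        groups = {}
        for region, electrodes in regions.items():
            try:
                groups[region] = [lookup[e] for e in electrodes]
            except KeyError as err:
                raise KeyError(f"region {region!r} references unknown channel {err}") from err
        return cls(groups)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.groups[name]

    def __contains__(self, name: str) -> bool:
        return name in self.groups

    def __iter__(self):
        return iter(self.groups)

    def __len__(self) -> int:
        return len(self.groups)

    def names(self) -> list[str]:
        return list(self.groups)

    def validate_against(self, n_channels: int) -> None:
        if self._max_index >= n_channels:
            raise IndexError(
                f"channel-group map references index {self._max_index} but the "
                f"dataset has only {n_channels} channels")


@dataclass
class ContinuousRecording:
    """A continuous multichannel recording with stimulus events.

    ``events`` is a structured list of ``(sample, stimulus_id, class_label)``
    tuples; sample indices refer to the ``data`` time axis.
    """

    data: np.ndarray                       # channels x samples
    sfreq: float
    channel_names: list[str]
    events: list[tuple[int, int, str]] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)
    provenance: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValueError("continuous data must be channels x samples")
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError("channel_names length must match data rows")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def eog_indices(self) -> list[int]:
        """Indices of EOG channels, identified by name prefix."""
        return [i for i, n in enumerate(self.channel_names)
                if n.upper().startswith("EOG")]

    def copy(self) -> "ContinuousRecording":
        return ContinuousRecording(
            data=self.data.copy(), sfreq=self.sfreq,
            channel_names=list(self.channel_names),
            events=list(self.events), metadata=dict(self.metadata),
            provenance=[dict(p) for p in self.provenance])

    def log_stage(self, stage: str, **params) -> None:
        self.provenance.append({"stage": stage, **params})


@dataclass
class EpochedDataset:
    """Epoched EEG: trials x channels x samples around stimulus onset.

    The time axis is uniform at ``1/sfreq`` and uses the half-open epoch
    convention ``[start, end)`` with the ``t = 0`` sample counted on the
    post-stimulus side.
    """

    data: np.ndarray                       # trials x channels x samples
    times_ms: np.ndarray                   # per-sample timestamps, ms
    sfreq: float
    channel_names: list[str]
    stimulus_ids: np.ndarray               # per-trial stimulus identity
    class_labels: np.ndarray               # per-trial "animate"/"inanimate"
    metadata: dict = field(default_factory=dict)
    provenance: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.times_ms = np.asarray(self.times_ms, dtype=float)
        self.stimulus_ids = np.asarray(self.stimulus_ids)
        self.class_labels = np.asarray(self.class_labels)
        if self.data.ndim != 3:
            raise ValueError("epoched data must be trials x channels x samples")
        n_trials, n_ch, n_t = self.data.shape
        if len(self.channel_names) != n_ch:
            raise ValueError("channel_names length must match channel axis")
        if self.times_ms.shape != (n_t,):
            raise ValueError("times_ms length must match time axis")
        if self.stimulus_ids.shape != (n_trials,):
            raise ValueError("stimulus_ids length must match trial axis")
        if self.class_labels.shape != (n_trials,):
            raise ValueError("class_labels length must match trial axis")
        if n_t > 1:
            steps = np.diff(self.times_ms)
            if np.any(steps <= 0):
                raise ValueError("time axis must be strictly increasing")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_times(self) -> int:
        return self.data.shape[2]

    def time_index(self, time_ms: float) -> int:
        """Index of the sample closest to ``time_ms``."""
        return int(np.argmin(np.abs(self.times_ms - time_ms)))

    def baseline_mask(self) -> np.ndarray:
        """Boolean mask of pre-stimulus (t < 0) samples."""
        return self.times_ms < 0.0

    def unique_stimuli(self) -> np.ndarray:
        return np.unique(self.stimulus_ids)

    def trials_for_stimulus(self, stimulus_id) -> np.ndarray:
        return np.flatnonzero(self.stimulus_ids == stimulus_id)

    def class_of_stimulus(self, stimulus_id) -> str:
        labels = self.class_labels[self.stimulus_ids == stimulus_id]
        return str(labels[0])

    def select_channels(self, indices: Iterable[int]) -> "EpochedDataset":
        idx = np.asarray(list(indices), dtype=int)
        if idx.size == 0:
            raise ValueError("channel selection is empty")
        out = self.copy()
        out.data = self.data[:, idx, :]
        out.channel_names = [self.channel_names[i] for i in idx]
        return out

    def copy(self) -> "EpochedDataset":
        return EpochedDataset(
            data=self.data.copy(), times_ms=self.times_ms.copy(),
            sfreq=self.sfreq, channel_names=list(self.channel_names),
            stimulus_ids=self.stimulus_ids.copy(),
            class_labels=self.class_labels.copy(),
            metadata=dict(self.metadata),
            provenance=[dict(p) for p in self.provenance])

    def log_stage(self, stage: str, **params) -> None:
        self.provenance.append({"stage": stage, **params})
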