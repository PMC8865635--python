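"""On-disk containers, standard-format import, and run configuration.

Epoched datasets round-trip through a two-file container: a ``.npz`` array
store (data, time axis, stimulus ids, class labels) plus a ``.json``
sidecar holding channel names, metadata, the provenance log and the array
shape for validation. Continuous recordings can be imported from EDF or
BrainVision files via mne. Channel-group maps travel as two-column TSV
(channel_name, group_name); cohort manifests as CSV.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .containers import ChannelGroupMap, ContinuousRecording, EpochedDataset

__all__ = [
    "SCHEMA_VERSION", "RunConfig", "write_epochs", "read_epochs",
    "import_continuous", "write_channel_groups", "read_channel_groups",
    "write_cohort_manifest", "read_cohort_manifest",
]

SCHEMA_VERSION = 1


@dataclass
class RunConfig:
    """Serializable bundle of every pipeline parameter.

    Defaults reproduce the study constants: 13 runs x 32 stimuli, 1200 Hz
    acquisition, (-100, 800) ms epochs, 50 Hz low-pass, 1000 Hz resampling,
    linear SVM with C = 1, bin sizes {2, 3, 4} and 10,000 repetitions /
    resamples.
    """

    n_runs: int = 13
    n_animate: int = 16
    n_inanimate: int = 16
    sfreq_acquisition: float = 1200.0
    epoch_window_ms: tuple[float, float] = (-100.0, 800.0)
    lowpass_hz: float = 50.0
    resample_hz: float = 1000.0
    svm_c: float = 1.0
    bin_sizes: tuple[int, ...] = (2, 3, 4)
    n_repetitions: int = 10_000
    n_bootstrap: int = 10_000
    n_permutations: int = 10_000
    fdr_alpha: float = 0.05
    seed: int = 0
    extra: dict = field(default_factory=dict)

    def to_yaml(self, path) -> None:
        payload = asdict(self)
        payload["epoch_window_ms"] = list(payload["epoch_window_ms"])
        payload["bin_sizes"] = list(payload["bin_sizes"])
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text())
        payload["epoch_window_ms"] = tuple(payload["epoch_window_ms"])
        payload["bin_sizes"] = tuple(payload["bin_sizes"])
        return cls(**payload)


def _paths(path) -> tuple[Path, Path]:
    base = Path(path)
    if base.suffix == ".npz":
        base = base.with_suffix("")
    return base.with_suffix(".npz"), base.with_suffix(".json")


def write_epochs(dataset: EpochedDataset, path) -> None:
    """Write an epoched dataset as ``<path>.npz`` + ``<path>.json``."""
    npz_path, json_path = _paths(path)
    np.savez_compressed(
        npz_path, data=dataset.data, times_ms=dataset.times_ms,
        stimulus_ids=dataset.stimulus_ids,
        class_labels=dataset.class_labels.astype(str))
    sidecar = {
        "schema_version": SCHEMA_VERSION,
        "shape": list(dataset.data.shape),
        "sfreq": dataset.sfreq,
        "channel_names": list(dataset.channel_names),
        "metadata": _jsonable(dataset.metadata),
        "provenance": _jsonable(dataset.provenance),
    }
    json_path.write_text(json.dumps(sidecar, indent=1))


def read_epochs(path) -> EpochedDataset:
    """Read a dataset written by :func:`write_epochs`, validating the sidecar."""
    npz_path, json_path = _paths(path)
    sidecar = json.loads(json_path.read_text())
    version = sidecar.get("schema_version")
    if version != SCHEMA_VERSION:
        raise ValueError(f"unknown epochs schema version {version!r}")
    with np.load(npz_path, allow_pickle=False) as store:
        data = store["data"]
        times_ms = store["times_ms"]
        stimulus_ids = store["stimulus_ids"]
        class_labels = store["class_labels"]
    if list(data.shape) != sidecar["shape"]:
        raise ValueError("array shape does not match sidecar")
    if len(sidecar["channel_names"]) != data.shape[1]:
        raise ValueError("channel_names do not match array")
    return EpochedDataset(
        data=data, times_ms=times_ms, sfreq=float(sidecar["sfreq"]),
        channel_names=list(sidecar["channel_names"]),
        stimulus_ids=stimulus_ids,
        class_labels=class_labels.astype(object),
        metadata=sidecar.get("metadata", {}),
        provenance=sidecar.get("provenance", []))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def import_continuous(path, fmt: str | None = None) -> ContinuousRecording:
    """Import a continuous recording from EDF or BrainVision via mne.

    Stimulus events come from annotations whose description parses as
    ``"<stimulus_id>/<class_label>"``; other annotations are ignored.
    An empty annotation set yields an empty event list with a warning.
    """
    import warnings

    import mne

    path = Path(path)
    fmt = fmt or {".edf": "edf", ".vhdr": "brainvision"}.get(path.suffix.lower())
    if fmt == "edf":
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    elif fmt == "brainvision":
        raw = mne.io.read_raw_brainvision(path, preload=True, verbose="error")
    else:
        raise ValueError(f"unsupported continuous format for {path.name!r}")

    data = raw.get_data()
    events = []
    for onset, desc in zip(raw.annotations.onset, raw.annotations.description):
        # accept "<id>/<class>" with an optional marker-type prefix that
        # readers such as the BrainVision one prepend ("Stimulus/<id>/<class>")
        parts = str(desc).split("/")
        if len(parts) >= 2 and parts[-2].lstrip("-").isdigit():
            sample = int(round((onset - raw.first_time) * raw.info["sfreq"]))
            events.append((sample, int(parts[-2]), parts[-1]))
    if not events:
        warnings.warn(f"no parseable stimulus annotations in {path.name}")
    rec = ContinuousRecording(
        data=data, sfreq=float(raw.info["sfreq"]),
        channel_names=list(raw.ch_names), events=events,
        metadata={"source": str(path), "format": fmt})
    rec.log_stage("import_continuous", path=str(path), format=fmt)
    return rec


def write_channel_groups(group_map: ChannelGroupMap, channel_names, path) -> None:
    """Write a channel-group map as two-column TSV (channel_name, group_name)."""
    rows = []
    for region in group_map:
        for idx in group_map[region]:
            rows.append({"channel_name": channel_names[idx],
                         "group_name": region})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_channel_groups(path, channel_names) -> ChannelGroupMap:
    """Read a two-column TSV into a :class:`ChannelGroupMap`."""
    table = pd.read_csv(path, sep="\t")
    regions: dict[str, list[str]] = {}
    for _, row in table.iterrows():
        regions.setdefault(str(row["group_name"]), []).append(str(row["channel_name"]))
    return ChannelGroupMap.from_names(channel_names, regions)


def write_cohort_manifest(records, path) -> None:
    """Cohort manifest: one row per subject (id, group, seed, n_runs)."""
    rows = [{"subject_id": r.subject_id, "group": r.group, "seed": r.seed,
             "n_runs": r.dataset.metadata.get("n_runs")}
            for r in records]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_cohort_manifest(path) -> pd.DataFrame:
    return pd.read_csv(path)
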