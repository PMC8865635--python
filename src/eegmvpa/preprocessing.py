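"""Preprocessing stages for continuous and epoched EEG.

The full chain applies six stages in a fixed order: average re-referencing
(dropping the reference channel), ICA-based removal of the single component
most correlated with the EOG channels, epoching around stimulus onsets,
baseline z-normalization, 50 Hz low-pass smoothing, and resampling to
1000 Hz. Note that normalization deliberately precedes filtering.

Each stage appends to the container's provenance log, works on a copy, and
is usable standalone; :func:`preprocess_pipeline` composes them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal as spsig
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning

from .containers import ContinuousRecording, EpochedDataset, REFERENCE_CHANNEL

__all__ = [
    "PreprocessConfig", "rereference_average", "remove_eog_component",
    "epoch", "baseline_normalize", "lowpass", "resample",
    "preprocess_pipeline", "preprocess_epochs", "drop_eog_channels",
]


@dataclass
class PreprocessConfig:
    """Parameters of the preprocessing chain.

    ``lowpass_hz`` / ``resample_hz`` may be None to skip the stage (useful
    for scaled-down simulations whose sampling rate is already below the
    cutoff). ``zero_phase`` selects forward-backward filtering; a causal
    forward-only filter is available for sensitivity checks.
    """

    reference_channel: str = REFERENCE_CHANNEL
    run_ica: bool = True
    ica_seed: int = 0
    ica_max_components: int = 20
    epoch_window_ms: tuple[float, float] = (-100.0, 800.0)
    lowpass_hz: float | None = 50.0
    filter_order: int = 4
    zero_phase: bool = True
    resample_hz: float | None = 1000.0


def _channel_axis_view(obj):
    """(data, channel_axis) for either container type."""
    if isinstance(obj, ContinuousRecording):
        return obj.data, 0
    if isinstance(obj, EpochedDataset):
        return obj.data, 1
    raise TypeError(f"unsupported container {type(obj).__name__}")


def _scalp_mask(channel_names) -> np.ndarray:
    return np.array([not n.upper().startswith("EOG") for n in channel_names])


def rereference_average(raw, reference_channel: str = REFERENCE_CHANNEL):
    """Re-reference scalp channels to their common average and drop the
    reference channel.

    The across-scalp-channel mean (EOG channels excluded) is subtracted from
    every scalp channel at each sample, after which the scalp channels sum
    to zero; the now-redundant reference channel is removed. Works on both
    continuous and epoched containers.
    """
    if reference_channel not in raw.channel_names:
        raise ValueError(f"reference channel {reference_channel!r} not present")
    out = raw.copy()
    data, ch_axis = _channel_axis_view(out)
    scalp = _scalp_mask(out.channel_names)
    scalp[out.channel_names.index(reference_channel)] = False
    idx = np.flatnonzero(scalp)
    scalp_data = np.take(data, idx, axis=ch_axis)
    mean = scalp_data.mean(axis=ch_axis, keepdims=True)
    scalp_data = scalp_data - mean
    for pos, i in enumerate(idx):
        sl = [slice(None)] * data.ndim
        sl[ch_axis] = i
        data[tuple(sl)] = np.take(scalp_data, pos, axis=ch_axis)
    keep = [i for i, n in enumerate(out.channel_names) if n != reference_channel]
    out.data = np.take(data, keep, axis=ch_axis)
    out.channel_names = [out.channel_names[i] for i in keep]
    out.log_stage("rereference_average", reference_channel=reference_channel)
    return out


def drop_eog_channels(obj):
    """Remove EOG channels (needed only for artifact correction)."""
    out = obj.copy()
    data, ch_axis = _channel_axis_view(out)
    keep = np.flatnonzero(_scalp_mask(out.channel_names))
    out.data = np.take(data, keep, axis=ch_axis)
    out.channel_names = [out.channel_names[i] for i in keep]
    out.log_stage("drop_eog")
    return out


def remove_eog_component(raw: ContinuousRecording,
                         eog_channels: list[int] | None = None,
                         max_components: int = 20,
                         seed: int = 0) -> ContinuousRecording:
    """Neutralize eye blinks: zero the single independent component most
    correlated with any EOG channel and reconstruct the scalp data.

    The decomposition runs on the scalp channels only (EOG excluded).
    If the ICA fails to converge the input is returned unchanged with a
    warning, so a difficult recording degrades rather than aborts.
    """
    if not isinstance(raw, ContinuousRecording):
        raise TypeError("EOG component removal operates on continuous data")
    eog_idx = raw.eog_indices() if eog_channels is None else list(eog_channels)
    if not eog_idx:
        raise ValueError("no EOG channels available")
    eog = raw.data[eog_idx]
    if np.all(np.std(eog, axis=1) == 0):
        warnings.warn("EOG channels have zero variance; skipping component removal")
        out = raw.copy()
        out.log_stage("remove_eog_component", skipped="zero-variance EOG")
        return out

    scalp_idx = [i for i in range(raw.n_channels) if i not in eog_idx]
    X = raw.data[scalp_idx].T  # samples x channels
    n_comp = min(len(scalp_idx), max_components)
    ica = FastICA(n_components=n_comp, random_state=seed, max_iter=500,
                  whiten="unit-variance")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            sources = ica.fit_transform(X)  # samples x components
    except Exception as err:  # pragma: no cover - sklearn internal failure
        warnings.warn(f"ICA failed ({err}); returning data unchanged")
        out = raw.copy()
        out.log_stage("remove_eog_component", skipped=str(err))
        return out

    # pick the component with the largest |Pearson r| against any EOG trace
    src = sources - sources.mean(axis=0)
    src_sd = src.std(axis=0)
    src_sd[src_sd == 0] = 1.0
    eogc = eog.T - eog.T.mean(axis=0)
    eog_sd = eogc.std(axis=0)
    eog_sd[eog_sd == 0] = 1.0
    corr = (src.T @ eogc) / (len(src) * np.outer(src_sd, eog_sd))
    worst = int(np.argmax(np.max(np.abs(corr), axis=1)))

    # subtract only that component's contribution, leaving both the other
    # components and the unmodeled subspace untouched
    contribution = np.outer(sources[:, worst], ica.mixing_[:, worst])
    out = raw.copy()
    out.data[scalp_idx] = (X - contribution).T
    out.log_stage("remove_eog_component", component=worst,
                  max_abs_corr=float(np.max(np.abs(corr))), seed=seed)
    return out


def epoch(raw: ContinuousRecording, events=None,
          window_ms: tuple[float, float] = (-100.0, 800.0)) -> EpochedDataset:
    """Cut epochs around stimulus onsets.

    The window is half-open, ``[start, end)``, with the ``t = 0`` sample on
    the post-stimulus side; at 1200 Hz the default (-100, 800) ms window
    yields 1080 samples. Events whose window leaves the recording are
    dropped with a warning.
    """
    events = raw.events if events is None else events
    start_ms, end_ms = window_ms
    if not start_ms < end_ms:
        raise ValueError("window start must precede end")
    n_samp = int(round((end_ms - start_ms) / 1000.0 * raw.sfreq))
    offset = int(round(start_ms / 1000.0 * raw.sfreq))
    times = start_ms + np.arange(n_samp) * 1000.0 / raw.sfreq

    epochs, stims, labels, dropped = [], [], [], 0
    for sample, stim, label in events:
        lo = sample + offset
        hi = lo + n_samp
        if lo < 0 or hi > raw.n_samples:
            dropped += 1
            continue
        epochs.append(raw.data[:, lo:hi])
        stims.append(stim)
        labels.append(label)
    if dropped:
        warnings.warn(f"dropped {dropped} events whose epoch window left the recording")
    data = (np.stack(epochs) if epochs
            else np.empty((0, raw.n_channels, n_samp)))
    ds = EpochedDataset(
        data=data, times_ms=times, sfreq=raw.sfreq,
        channel_names=list(raw.channel_names),
        stimulus_ids=np.asarray(stims, dtype=int),
        class_labels=np.asarray(labels, dtype=object) if labels else np.empty(0, dtype=object),
        metadata=dict(raw.metadata),
        provenance=[dict(p) for p in raw.provenance])
    ds.log_stage("epoch", window_ms=window_ms, n_epochs=len(epochs),
                 n_dropped=dropped)
    return ds


def baseline_normalize(epochs: EpochedDataset) -> EpochedDataset:
    """Z-normalize each trial and channel by its pre-stimulus baseline.

    After this stage the baseline samples of every trial/channel have mean 0
    and SD 1 (zero-variance baselines divide by 1 with a warning), which also
    makes the operation idempotent.
    """
    mask = epochs.baseline_mask()
    if not np.any(mask):
        raise ValueError("epoch has no pre-stimulus baseline samples")
    out = epochs.copy()
    base = out.data[:, :, mask]
    mean = base.mean(axis=2, keepdims=True)
    sd = base.std(axis=2, ddof=0, keepdims=True)
    n_degenerate = int(np.sum(sd == 0))
    if n_degenerate:
        warnings.warn(f"{n_degenerate} trial-channel baselines have zero SD; "
                      "dividing by 1 instead")
        sd = np.where(sd == 0, 1.0, sd)
    out.data = (out.data - mean) / sd
    out.log_stage("baseline_normalize", n_zero_sd=n_degenerate)
    return out


def lowpass(epochs: EpochedDataset, cutoff_hz: float = 50.0,
            order: int = 4, zero_phase: bool = True) -> EpochedDataset:
    """Butterworth low-pass along the time axis (zero-phase by default)."""
    nyq = epochs.sfreq / 2.0
    if cutoff_hz >= nyq:
        raise ValueError(f"cutoff {cutoff_hz} Hz must be below Nyquist {nyq} Hz")
    sos = spsig.butter(order, cutoff_hz, btype="low", fs=epochs.sfreq,
                       output="sos")
    out = epochs.copy()
    if zero_phase:
        out.data = spsig.sosfiltfilt(sos, out.data, axis=2)
    else:
        out.data = spsig.sosfilt(sos, out.data, axis=2)
    out.log_stage("lowpass", cutoff_hz=cutoff_hz, order=order,
                  zero_phase=zero_phase)
    return out


def resample(epochs: EpochedDataset, target_hz: float = 1000.0) -> EpochedDataset:
    """Polyphase resampling to ``target_hz`` over the same epoch window.

    Upsampling is rejected; anti-aliasing beyond the polyphase filter is
    assumed to be handled by the preceding low-pass stage.
    """
    if target_hz > epochs.sfreq:
        raise ValueError("upsampling not supported")
    if target_hz == epochs.sfreq:
        out = epochs.copy()
        out.log_stage("resample", target_hz=target_hz, identity=True)
        return out
    frac = Fraction(target_hz / epochs.sfreq).limit_denominator(1000)
    out = epochs.copy()
    out.data = spsig.resample_poly(out.data, frac.numerator,
                                   frac.denominator, axis=2)
    n_new = out.data.shape[2]
    out.times_ms = epochs.times_ms[0] + np.arange(n_new) * 1000.0 / target_hz
    out.sfreq = float(target_hz)
    out.log_stage("resample", target_hz=target_hz)
    return out


def preprocess_pipeline(raw: ContinuousRecording, events=None,
                        config: PreprocessConfig | None = None) -> EpochedDataset:
    """Run the full six-stage chain on a continuous recording.

    Order: average re-reference, EOG component removal, epoching, baseline
    normalization, low-pass smoothing, resampling. EOG channels are dropped
    right after the artifact-correction stage; the output carries only the
    analysis scalp channels and a provenance entry per stage.
    """
    config = config or PreprocessConfig()
    rec = rereference_average(raw, config.reference_channel)
    if config.run_ica:
        rec = remove_eog_component(rec, seed=config.ica_seed,
                                   max_components=config.ica_max_components)
    rec = drop_eog_channels(rec)
    ds = epoch(rec, events=events, window_ms=config.epoch_window_ms)
    ds = baseline_normalize(ds)
    if config.lowpass_hz is not None:
        ds = lowpass(ds, config.lowpass_hz, order=config.filter_order,
                     zero_phase=config.zero_phase)
    if config.resample_hz is not None and config.resample_hz != ds.sfreq:
        ds = resample(ds, config.resample_hz)
    return ds


def preprocess_epochs(epochs: EpochedDataset,
                      config: PreprocessConfig | None = None) -> EpochedDataset:
    """Preprocess already-epoched data (e.g. simulated subjects).

    Applies the epoched-domain stages — average re-reference, EOG channel
    removal, baseline normalization, optional low-pass and resampling — and
    returns the analysis-ready scalp-only dataset.
    """
    config = config or PreprocessConfig()
    ds = rereference_average(epochs, config.reference_channel)
    ds = drop_eog_channels(ds)
    ds = baseline_normalize(ds)
    if config.lowpass_hz is not None and config.lowpass_hz < ds.sfreq / 2.0:
        ds = lowpass(ds, config.lowpass_hz, order=config.filter_order,
                     zero_phase=config.zero_phase)
    if config.resample_hz is not None and config.resample_hz < ds.sfreq:
        ds = resample(ds, config.resample_hz)
    return ds
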