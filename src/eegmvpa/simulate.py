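"""Synthetic epoched-EEG cohorts with controllable group effects.

The generator emulates a rapid animal / non-animal categorization study:
each subject sees ``n_animate + n_inanimate`` stimuli once per run over
``n_runs`` runs (the default design: 13 runs x 32 stimuli, 63 scalp
channels plus a reference and three EOG channels, 1200 Hz, epochs from
-100 ms to +800 ms around stimulus onset).

The evoked model for a trial of stimulus ``s`` (class ``c``) in group ``g`` is

    x(ch, t) = A_g * k_g(t) * w_{g,c}[ch]
             + A_stim * k_g(t) * u_s[ch] + noise(ch, t)

where ``k_g`` is a half-cosine temporal kernel rising at the group's onset
latency and peaking at its peak latency, ``w_{g,c}`` are unit-norm spatial
patterns built from a shared topography plus/minus half a class-contrast
vector, and ``u_s`` is a small stimulus-identity pattern (what makes
individual stimuli pairwise discriminable).

Group differences are injected through onset/peak latencies, amplitudes,
and ``pattern_divergence``, which rotates the MCI class-contrast vector
away from the HC one and mixes the MCI stimulus-identity patterns toward an
independent set by the same angle, all inside the subspace orthogonal to
the all-ones channel vector and with every stimulus-pattern set centered —
so response *patterns* can differ between groups while channel-wise *mean*
responses stay identical (``mean_matched``).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .containers import (ANIMATE, INANIMATE, ContinuousRecording,
                         EpochedDataset, default_channel_names)

__all__ = [
    "SyntheticDesign", "GroupEffectSpec", "SubjectRecord",
    "generate_subject", "generate_cohort", "generate_continuous_session",
    "evoked_signal", "class_contrast_vectors",
]

GROUPS = ("HC", "MCI")


@dataclass(frozen=True)
class SyntheticDesign:
    """Structural constants of the study design."""

    n_runs: int = 13
    n_animate: int = 16
    n_inanimate: int = 16
    sfreq_acquisition: float = 1200.0
    epoch_window_ms: tuple[float, float] = (-100.0, 800.0)
    n_scalp_channels: int = 63
    n_eog: int = 3
    reference_channel_index: int = 32

    def __post_init__(self) -> None:
        if self.n_runs < 1:
            raise ValueError("need at least one run")
        if self.n_animate + self.n_inanimate < 2:
            raise ValueError("need at least two stimuli")
        start, end = self.epoch_window_ms
        if not (start < 0.0 < end):
            raise ValueError("epoch window must straddle stimulus onset")
        if not 0 <= self.reference_channel_index <= self.n_scalp_channels:
            raise ValueError("reference index outside channel range")

    @property
    def n_stimuli(self) -> int:
        return self.n_animate + self.n_inanimate

    @property
    def n_trials(self) -> int:
        return self.n_runs * self.n_stimuli

    def n_epoch_samples(self, sfreq: float | None = None) -> int:
        """Samples per epoch under the half-open [start, end) convention."""
        sfreq = self.sfreq_acquisition if sfreq is None else sfreq
        start, end = self.epoch_window_ms
        return int(round((end - start) / 1000.0 * sfreq))

    def epoch_times_ms(self, sfreq: float | None = None) -> np.ndarray:
        sfreq = self.sfreq_acquisition if sfreq is None else sfreq
        n = self.n_epoch_samples(sfreq)
        return self.epoch_window_ms[0] + np.arange(n) * 1000.0 / sfreq

    def channel_names(self) -> list[str]:
        """Full acquisition channel list (scalp + reference + EOG)."""
        if (self.n_scalp_channels == 63 and self.n_eog == 3
                and self.reference_channel_index == 32):
            return default_channel_names()
        names = [f"CH{i + 1:02d}" for i in range(self.n_scalp_channels)]
        names.insert(self.reference_channel_index, "REF")
        names += [f"EOG{i + 1}" for i in range(self.n_eog)]
        return names

    def scalp_indices(self) -> np.ndarray:
        """Indices of the recording scalp channels (reference excluded)."""
        total = self.n_scalp_channels + 1
        return np.array([i for i in range(total)
                         if i != self.reference_channel_index])


@dataclass
class GroupEffectSpec:
    """Controllable group effects of the simulated cohort.

    Latencies and amplitudes are per-group dicts; amplitudes are in
    baseline-SD units (the noise SD defaults to 1, so an amplitude of 1
    means the evoked peak matches the single-trial noise floor).
    ``pattern_divergence`` in [0, 1] rotates the MCI class-contrast vector
    by ``pattern_divergence * 90`` degrees away from the HC one and
    interpolates the MCI per-stimulus directions and gains toward an
    independent draw by the same fraction; ``stimulus_gain_spread`` sets
    how unequal stimuli are in discriminability (gains uniform on
    ``1 +/- spread``), which bounds how far the groups' RDMs can diverge.
    ``mean_matched`` forces equal amplitudes/latencies across groups and
    disables between-subject jitter, so the noise-free mean evoked response
    of the two groups is identical by construction.
    """

    onset_latency_ms: Mapping[str, float] = field(
        default_factory=lambda: {"HC": 100.0, "MCI": 139.0})
    peak_latency_ms: Mapping[str, float] = field(
        default_factory=lambda: {"HC": 200.0, "MCI": 239.0})
    signal_amplitude: Mapping[str, float] = field(
        default_factory=lambda: {"HC": 1.0, "MCI": 0.9})
    stimulus_amplitude: float = 0.5
    stimulus_gain_spread: float = 0.5
    pattern_divergence: float = 0.3
    mean_matched: bool = False
    noise_sd: float = 1.0
    latency_jitter_ms: float = 10.0
    amplitude_jitter_sd: float = 0.1
    ar_coeff: float = 0.0
    spatial_patterns: Mapping[str, Mapping[str, np.ndarray]] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if not 0.0 <= self.pattern_divergence <= 1.0:
            raise ValueError("pattern_divergence must lie in [0, 1]")
        if not 0.0 <= self.stimulus_gain_spread < 1.0:
            raise ValueError("stimulus_gain_spread must lie in [0, 1)")
        if not 0.0 <= self.ar_coeff < 1.0:
            raise ValueError("ar_coeff must lie in [0, 1)")
        for g in GROUPS:
            if not self.onset_latency_ms[g] < self.peak_latency_ms[g]:
                raise ValueError(f"{g}: onset must precede peak")

    def resolved(self) -> "GroupEffectSpec":
        """Effects with the mean-matching constraint applied."""
        if not self.mean_matched:
            return self
        return replace(
            self,
            onset_latency_ms={g: self.onset_latency_ms["HC"] for g in GROUPS},
            peak_latency_ms={g: self.peak_latency_ms["HC"] for g in GROUPS},
            signal_amplitude={g: self.signal_amplitude["HC"] for g in GROUPS},
            latency_jitter_ms=0.0, amplitude_jitter_sd=0.0)


@dataclass
class SubjectRecord:
    """One simulated participant: identity, group, data and its seed."""

    subject_id: str
    group: str
    dataset: EpochedDataset
    seed: int


# ---------------------------------------------------------------------------
# spatial patterns

def _orthogonalize(v: np.ndarray, basis: list[np.ndarray]) -> np.ndarray:
    for b in basis:
        v = v - np.dot(v, b) * b
    norm = np.linalg.norm(v)
    if norm < 1e-12:
        raise RuntimeError("degenerate random vector during orthogonalization")
    return v / norm


def _pattern_bank(design: SyntheticDesign, effects: GroupEffectSpec):
    """Shared topography, per-group class contrasts, stimulus patterns.

    All vectors live in the subspace orthogonal to the all-ones channel
    vector, so average re-referencing leaves them untouched.
    """
    n_ch = design.n_scalp_channels
    rng = np.random.default_rng(effects.seed)
    ones = np.ones(n_ch) / np.sqrt(n_ch)
    p_common = _orthogonalize(rng.standard_normal(n_ch), [ones])
    d_hc = _orthogonalize(rng.standard_normal(n_ch), [ones, p_common])
    v = _orthogonalize(rng.standard_normal(n_ch), [ones, p_common, d_hc])
    theta = effects.pattern_divergence * np.pi / 2.0
    d_mci = np.cos(theta) * d_hc + np.sin(theta) * v
    contrasts = {"HC": d_hc, "MCI": d_mci}

    # stimulus-identity patterns: the MCI directions are mixed toward an
    # independent set by the divergence angle, and each stimulus carries a
    # per-group gain whose MCI values interpolate toward an independent
    # draw. The gains are what make the realized pairwise geometry (hence
    # the RDMs) differ between groups — in high channel dimension, mixed
    # unit directions alone have concentrated pairwise distances. Both
    # final sets are centered across stimuli, so they contribute nothing
    # to the across-stimulus mean response and mean-matching is exact.
    u_hc = np.empty((design.n_stimuli, n_ch))
    u_alt = np.empty((design.n_stimuli, n_ch))
    for s in range(design.n_stimuli):
        u_hc[s] = _orthogonalize(rng.standard_normal(n_ch), [ones])
        u_alt[s] = _orthogonalize(rng.standard_normal(n_ch), [ones])
    u_mci = np.cos(theta) * u_hc + np.sin(theta) * u_alt
    frac = effects.pattern_divergence
    lo = 1.0 - effects.stimulus_gain_spread
    hi = 1.0 + effects.stimulus_gain_spread
    gain_base = rng.uniform(lo, hi, size=design.n_stimuli)
    gain_alt = rng.uniform(lo, hi, size=design.n_stimuli)
    gain_mci = (1.0 - frac) * gain_base + frac * gain_alt
    u_hc = gain_base[:, None] * u_hc
    u_mci = gain_mci[:, None] * u_mci
    u_hc = u_hc - u_hc.mean(axis=0, keepdims=True)
    u_mci = u_mci - u_mci.mean(axis=0, keepdims=True)
    return p_common, contrasts, {"HC": u_hc, "MCI": u_mci}


def class_contrast_vectors(design: SyntheticDesign,
                           effects: GroupEffectSpec) -> dict[str, np.ndarray]:
    """Per-group class-contrast spatial vectors (animate minus inanimate).

    The angle between the two groups' vectors equals
    ``pattern_divergence * 90`` degrees, which is what the pattern-divergence
    parameter controls.
    """
    _, contrasts, _ = _pattern_bank(design, effects.resolved())
    return contrasts


def _class_patterns(design: SyntheticDesign, effects: GroupEffectSpec):
    """Unit-norm spatial pattern per group per class."""
    if effects.spatial_patterns is not None:
        out = {}
        for g in GROUPS:
            out[g] = {}
            for c in (ANIMATE, INANIMATE):
                w = np.asarray(effects.spatial_patterns[g][c], dtype=float)
                if w.shape != (design.n_scalp_channels,):
                    raise ValueError("spatial pattern has wrong length")
                out[g][c] = w / np.linalg.norm(w)
        return out
    p_common, contrasts, _ = _pattern_bank(design, effects)
    norm = np.sqrt(1.0 + 0.25)  # ||p_common +/- d/2|| with orthogonal parts
    return {g: {ANIMATE: (p_common + 0.5 * contrasts[g]) / norm,
                INANIMATE: (p_common - 0.5 * contrasts[g]) / norm}
            for g in GROUPS}


# ---------------------------------------------------------------------------
# temporal kernel

def temporal_kernel(times_ms: np.ndarray, onset_ms: float,
                    peak_ms: float) -> np.ndarray:
    """Half-cosine ramp from onset to peak, then symmetric decay to zero."""
    k = np.zeros_like(times_ms, dtype=float)
    half = peak_ms - onset_ms
    rise = (times_ms >= onset_ms) & (times_ms <= peak_ms)
    k[rise] = 0.5 * (1.0 - np.cos(np.pi * (times_ms[rise] - onset_ms) / half))
    fall = (times_ms > peak_ms) & (times_ms <= peak_ms + half)
    k[fall] = 0.5 * (1.0 + np.cos(np.pi * (times_ms[fall] - peak_ms) / half))
    return k


def _check_latencies(design: SyntheticDesign, effects: GroupEffectSpec,
                     group: str) -> None:
    start, end = design.epoch_window_ms
    onset = effects.onset_latency_ms[group]
    peak = effects.peak_latency_ms[group]
    if not (start <= onset < end and start < peak <= end):
        raise ValueError(f"{group} latencies ({onset}, {peak}) outside "
                         f"epoch window {design.epoch_window_ms}")


def _noise(rng: np.random.Generator, shape: tuple, sd: float,
           ar: float) -> np.ndarray:
    eps = rng.standard_normal(shape) * sd
    if ar > 0.0:
        # AR(1) along the last (time) axis, scaled back to marginal SD `sd`
        out = np.empty_like(eps)
        out[..., 0] = eps[..., 0]
        innov = np.sqrt(1.0 - ar ** 2)
        for t in range(1, shape[-1]):
            out[..., t] = ar * out[..., t - 1] + innov * eps[..., t]
        return out
    return eps


# ---------------------------------------------------------------------------
# subject / cohort generation

def _stimulus_table(design: SyntheticDesign):
    stim_ids = np.arange(design.n_stimuli)
    classes = np.array([ANIMATE] * design.n_animate
                       + [INANIMATE] * design.n_inanimate)
    return stim_ids, classes


def evoked_signal(design: SyntheticDesign, effects: GroupEffectSpec,
                  group: str, sfreq: float | None = None) -> np.ndarray:
    """Noise-free mean evoked response (scalp channels x samples).

    This is the closed form of the generator's trial-average over all
    stimuli: the stimulus-identity patterns are centered and the class
    contrast cancels between the two equally-sized classes, so only the
    shared topography survives.
    """
    effects = effects.resolved()
    _check_latencies(design, effects, group)
    times = design.epoch_times_ms(sfreq)
    patterns = _class_patterns(design, effects)
    k = temporal_kernel(times, effects.onset_latency_ms[group],
                        effects.peak_latency_ms[group])
    w_mean = (design.n_animate * patterns[group][ANIMATE]
              + design.n_inanimate * patterns[group][INANIMATE]) / design.n_stimuli
    return effects.signal_amplitude[group] * np.outer(w_mean, k)


def generate_subject(design: SyntheticDesign, effects: GroupEffectSpec,
                     group: str, seed: int,
                     sfreq: float | None = None,
                     n_runs: int | None = None) -> SubjectRecord:
    """Simulate one participant's epoched session.

    Returns epochs with the full acquisition layout (scalp channels, the
    all-zero reference channel, EOG channels); run :mod:`eegmvpa.preprocessing`
    to obtain the 63-channel analysis-ready dataset. ``sfreq`` may lower the
    simulated sampling rate for scaled-down analyses; ``n_runs`` overrides
    the design's run count (run-dropout subjects).
    """
    if group not in GROUPS:
        raise ValueError(f"unknown group {group!r}")
    effects = effects.resolved()
    _check_latencies(design, effects, group)
    sfreq = design.sfreq_acquisition if sfreq is None else float(sfreq)
    n_runs = design.n_runs if n_runs is None else int(n_runs)
    times = design.epoch_times_ms(sfreq)
    n_t = times.size
    rng = np.random.default_rng(seed)

    # per-subject physiology: latency shift and amplitude scaling
    lat_shift = rng.normal(0.0, effects.latency_jitter_ms) if effects.latency_jitter_ms else 0.0
    amp_scale = max(0.1, 1.0 + (rng.normal(0.0, effects.amplitude_jitter_sd)
                                if effects.amplitude_jitter_sd else 0.0))
    onset = effects.onset_latency_ms[group] + lat_shift
    peak = effects.peak_latency_ms[group] + lat_shift
    onset = float(np.clip(onset, design.epoch_window_ms[0], design.epoch_window_ms[1] - 1.0))
    peak = float(np.clip(peak, onset + 1.0, design.epoch_window_ms[1]))
    k = temporal_kernel(times, onset, peak)

    patterns = _class_patterns(design, effects)
    u_stim = _pattern_bank(design, effects)[2][group]
    amp = effects.signal_amplitude[group] * amp_scale

    stim_ids, classes = _stimulus_table(design)
    order = np.concatenate([rng.permutation(design.n_stimuli)
                            for _ in range(n_runs)])
    trial_stim = stim_ids[order]
    trial_class = classes[order]

    n_trials = n_runs * design.n_stimuli
    n_scalp = design.n_scalp_channels
    n_total = n_scalp + 1 + design.n_eog

    signal = np.empty((n_trials, n_scalp, n_t))
    for i, (s, c) in enumerate(zip(trial_stim, trial_class)):
        w = amp * patterns[group][c] + effects.stimulus_amplitude * u_stim[s]
        signal[i] = np.outer(w, k)

    data = np.zeros((n_trials, n_total, n_t))
    scalp_idx = design.scalp_indices()
    data[:, scalp_idx, :] = signal + _noise(
        rng, (n_trials, n_scalp, n_t), effects.noise_sd, effects.ar_coeff)
    eog_idx = np.arange(n_scalp + 1, n_total)
    data[:, eog_idx, :] = _noise(rng, (n_trials, design.n_eog, n_t),
                                 effects.noise_sd, effects.ar_coeff)
    # the reference channel records zero by definition

    ds = EpochedDataset(
        data=data, times_ms=times, sfreq=sfreq,
        channel_names=design.channel_names(),
        stimulus_ids=trial_stim, class_labels=trial_class,
        metadata={"group": group, "seed": seed, "n_runs": n_runs,
                  "onset_ms": onset, "peak_ms": peak, "amplitude": amp})
    ds.log_stage("simulate", group=group, seed=seed, sfreq=sfreq, n_runs=n_runs)
    return SubjectRecord(subject_id=f"{group}{seed}", group=group,
                         dataset=ds, seed=seed)


def generate_cohort(design: SyntheticDesign, effects: GroupEffectSpec,
                    n_hc: int, n_mci: int, seed: int,
                    sfreq: float | None = None,
                    run_dropout: bool = False) -> list[SubjectRecord]:
    """Simulate a two-group cohort with reproducible per-subject seeds.

    With ``run_dropout`` a small fraction of subjects completes 10 or 12
    runs instead of the full count, mirroring real attrition.
    """
    if n_hc < 2 or n_mci < 2:
        raise ValueError("need at least 2 subjects per group")
    master = np.random.default_rng(seed)
    records = []
    for group, n_sub in (("HC", n_hc), ("MCI", n_mci)):
        for i in range(n_sub):
            sub_seed = int(master.integers(0, 2 ** 31 - 1))
            n_runs = None
            if run_dropout and master.random() < 0.1:
                n_runs = int(master.choice([10, 12]))
            rec = generate_subject(design, effects, group, sub_seed,
                                   sfreq=sfreq, n_runs=n_runs)
            rec.subject_id = f"{group}{i + 1:02d}"
            records.append(rec)
    return records


# ---------------------------------------------------------------------------
# continuous sessions (input to the full preprocessing chain)

BLINK_DURATION_MS = 300.0
BLINK_AMPLITUDE = 25.0
#: projection of a blink onto EOG channels and frontal scalp electrodes
_BLINK_EOG_WEIGHTS = (1.0, 0.9, 0.8)
_BLINK_SCALP_PREFIX_WEIGHTS = {"Fp": 0.5, "AF": 0.3, "F": 0.15}


def _blink_scalp_weights(channel_names: list[str]) -> np.ndarray:
    w = np.zeros(len(channel_names))
    for i, name in enumerate(channel_names):
        for prefix, weight in _BLINK_SCALP_PREFIX_WEIGHTS.items():
            if name.startswith(prefix) and not name.startswith("FT"):
                w[i] = weight
                break
    return w


def generate_continuous_session(design: SyntheticDesign,
                                effects: GroupEffectSpec, group: str,
                                blink_rate: float, seed: int,
                                soa_ms: float = 1870.0,
                                inter_run_gap_s: float = 2.0) -> ContinuousRecording:
    """Simulate a continuous multichannel session with stimulus events.

    Stimuli are presented once per run in random order at a fixed stimulus
    onset asynchrony; blink transients occur as a Poisson process at
    ``blink_rate`` events per minute, projected onto the EOG channels and
    frontal scalp electrodes. Epoching the output at its event list
    reproduces the trial structure of :func:`generate_subject`.
    """
    if blink_rate < 0:
        raise ValueError("blink_rate must be non-negative")
    if group not in GROUPS:
        raise ValueError(f"unknown group {group!r}")
    effects = effects.resolved()
    _check_latencies(design, effects, group)
    sfreq = design.sfreq_acquisition
    rng = np.random.default_rng(seed)

    lead_s = 1.0
    run_span = design.n_stimuli * soa_ms / 1000.0 + lead_s
    total_s = design.n_runs * run_span + (design.n_runs - 1) * inter_run_gap_s + lead_s
    n_samples = int(round(total_s * sfreq))

    names = design.channel_names()
    n_total = len(names)
    scalp_idx = design.scalp_indices()
    eog_idx = np.arange(design.n_scalp_channels + 1, n_total)

    data = np.zeros((n_total, n_samples))
    data[scalp_idx] = _noise(rng, (len(scalp_idx), n_samples),
                             effects.noise_sd, effects.ar_coeff)
    data[eog_idx] = _noise(rng, (len(eog_idx), n_samples),
                           effects.noise_sd, effects.ar_coeff)

    patterns = _class_patterns(design, effects)
    u_stim = _pattern_bank(design, effects)[2][group]
    amp = effects.signal_amplitude[group]
    onset_ms = effects.onset_latency_ms[group]
    peak_ms = effects.peak_latency_ms[group]
    resp_len = design.n_epoch_samples(sfreq)
    resp_times = design.epoch_times_ms(sfreq)
    k = temporal_kernel(resp_times, onset_ms, peak_ms)
    pre_samples = int(round(-design.epoch_window_ms[0] / 1000.0 * sfreq))

    stim_ids, classes = _stimulus_table(design)
    events: list[tuple[int, int, str]] = []
    for run in range(design.n_runs):
        run_start = lead_s + run * (run_span + inter_run_gap_s)
        order = rng.permutation(design.n_stimuli)
        for j, s in enumerate(order):
            onset_sample = int(round((run_start + j * soa_ms / 1000.0) * sfreq))
            c = classes[s]
            w = amp * patterns[group][c] + effects.stimulus_amplitude * u_stim[s]
            seg = slice(onset_sample - pre_samples,
                        onset_sample - pre_samples + resp_len)
            if seg.start < 0 or seg.stop > n_samples:
                continue
            data[np.ix_(scalp_idx, np.arange(seg.start, seg.stop))] += np.outer(w, k)
            events.append((onset_sample, int(stim_ids[s]), str(c)))

    # blink transients: raised-cosine bumps on EOG + frontal scalp channels
    n_blinks = rng.poisson(blink_rate * total_s / 60.0)
    blink_len = int(round(BLINK_DURATION_MS / 1000.0 * sfreq))
    bump = BLINK_AMPLITUDE * 0.5 * (1.0 - np.cos(
        2.0 * np.pi * np.arange(blink_len) / blink_len))
    scalp_w = _blink_scalp_weights(names)
    for start in rng.integers(0, max(1, n_samples - blink_len), size=n_blinks):
        seg = np.arange(start, start + blink_len)
        for ei, ew in zip(eog_idx, _BLINK_EOG_WEIGHTS[:len(eog_idx)]):
            data[ei, seg] += ew * bump
        data[:, seg] += np.outer(scalp_w, bump)

    rec = ContinuousRecording(
        data=data, sfreq=sfreq, channel_names=names, events=events,
        metadata={"group": group, "seed": seed, "blink_rate": blink_rate,
                  "n_blinks": int(n_blinks)})
    rec.log_stage("simulate_continuous", group=group, seed=seed,
                  blink_rate=blink_rate)
    return rec
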