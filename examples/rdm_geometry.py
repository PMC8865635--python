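"""Pairwise-decoding RDMs, group RDM distance, and MDS geometry.

Builds per-subject RDMs at a pre-stimulus and an evoked time point for a
mean-matched, pattern-divergent cohort — the groups' channel-wise mean
responses are identical by construction, but their class-contrast patterns
differ — and shows that the RDM distance between groups peaks in the evoked
window with a significant permutation test, the signature that response
patterns carry information beyond mean responses.
"""

import numpy as np

import eegmvpa as em

design = em.SyntheticDesign(n_animate=6, n_inanimate=6, sfreq_acquisition=100)
effects = em.GroupEffectSpec(mean_matched=True, pattern_divergence=1.0,
                             stimulus_amplitude=1.0, stimulus_gain_spread=0.8,
                             signal_amplitude={"HC": 1.5, "MCI": 1.5})

cohort = em.generate_cohort(design, effects, n_hc=6, n_mci=6, seed=11)
pcfg = em.PreprocessConfig(lowpass_hz=None, resample_hz=None)
pre = [em.preprocess_epochs(r.dataset, pcfg) for r in cohort]

times = [-50.0, 200.0]
rdms = np.stack([em.compute_rdm_series(ds, times) for ds in pre])
groups = np.array([r.group for r in cohort])
hc_rdms, mci_rdms = rdms[groups == "HC"], rdms[groups == "MCI"]

res = em.rdm_distance_timecourse(hc_rdms, mci_rdms, times, n_perm=500,
                                 rng=0, test_time_ms=200.0)
for t, d in zip(res.times_ms, res.distance):
    print(f"t = {t:+.0f} ms: raw RDM distance {d:.2f}")
print(f"maximum at {res.max_time_ms:.0f} ms; permutation test at 200 ms: "
      f"p = {res.p_value:.3f}")

flags, _ = em.rdm_cellwise_comparison(hc_rdms[:, 1], mci_rdms[:, 1])
print(f"{flags.sum() // 2} individual stimulus pairs flagged "
      "(rank-sum, FDR 0.05 over cells; cell-level power needs larger groups)")

coords, stress = em.mds_embed(rdms[:, 1].mean(axis=0), dims=2, seed=0)
print(f"2-D MDS of the evoked-window mean RDM: stress {stress:.2f}; "
      f"animate/inanimate centroid separation "
      f"{np.linalg.norm(coords[:6].mean(0) - coords[6:].mean(0)):.2f}")
# distances near chance pre-stimulus and a significant evoked-window peak
# reproduce the pattern-level group difference without any ERP difference
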