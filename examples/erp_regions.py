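"""Region-level ERPs and a univariate HC-vs-MCI comparison.

Computes per-subject ERPs over the 23 named scalp regions, then tests the
group difference in one region per time point (rank-sum, FDR-corrected
across time) for a cohort in which the MCI evoked amplitude is reduced.
"""

import numpy as np

import eegmvpa as em

design = em.SyntheticDesign(n_animate=8, n_inanimate=8, sfreq_acquisition=100)
effects = em.GroupEffectSpec(signal_amplitude={"HC": 2.0, "MCI": 0.5},
                             latency_jitter_ms=0.0)

cohort = em.generate_cohort(design, effects, n_hc=10, n_mci=10, seed=5)
pcfg = em.PreprocessConfig(lowpass_hz=None, resample_hz=None)
pre = [em.preprocess_epochs(r.dataset, pcfg) for r in cohort]
gmap = em.ChannelGroupMap.from_names(pre[0].channel_names)

erps = [em.compute_erp(ds, gmap) for ds in pre]
hc = [e for e, r in zip(erps, cohort) if r.group == "HC"]
mci = [e for e, r in zip(erps, cohort) if r.group == "MCI"]

# the random evoked topography projects more strongly onto some regions
# than others, so scan all 23 and summarize the most differentiated one
times = pre[0].times_ms
results = {r: em.erp_group_difference(em.cohort_erp(hc, r),
                                      em.cohort_erp(mci, r),
                                      n_boot=500, rng=0)
           for r in gmap.names()}
flagged = {r: res for r, res in results.items() if res.flags.any()}
print(f"{len(flagged)} of {len(results)} regions show a significant "
      "HC-MCI ERP difference (rank-sum, FDR 0.05 across time)")

best = max(results, key=lambda r: np.max(np.abs(results[r].difference)))
res = results[best]
sig = times[res.flags]
peak = int(np.argmax(np.abs(res.difference)))
print(f"strongest region {best}: largest difference "
      f"{res.difference[peak]:+.2f} baseline-SD units at {times[peak]:.0f} ms "
      f"(95% CI [{res.ci_low[peak]:.2f}, {res.ci_high[peak]:.2f}])")
if sig.size:
    print(f"significant window in {best}: {sig.min():.0f} to {sig.max():.0f} ms")
# flagged windows bracket the simulated evoked response; with equal group
# amplitudes the same script reports no significant regions
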