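"""Time-resolved animal vs. non-animal decoding and peak-latency comparison.

Simulates a small two-group cohort in which the MCI group's evoked response
is delayed by 40 ms, decodes animacy over time per subject with the
bin-sub-averaging SVM scheme, and compares the groups' median decoding-peak
latencies with a one-sided bootstrap test. The printed median delay should
sit near the injected 40 ms, with the add-one bootstrap p-value small when
the delay is real.
"""

import numpy as np

import eegmvpa as em

design = em.SyntheticDesign(sfreq_acquisition=100)   # full stimulus set
effects = em.GroupEffectSpec(
    onset_latency_ms={"HC": 100.0, "MCI": 140.0},
    peak_latency_ms={"HC": 200.0, "MCI": 240.0},
    signal_amplitude={"HC": 2.0, "MCI": 2.0},
)

cohort = em.generate_cohort(design, effects, n_hc=6, n_mci=6, seed=3)
pcfg = em.PreprocessConfig(lowpass_hz=None, resample_hz=None)
decoder = em.DecoderConfig(n_repetitions=15, seed=0)  # study scale: 10,000
times = np.arange(0.0, 401.0, 20.0)

courses = {"HC": [], "MCI": []}
rng = np.random.default_rng(0)
for rec in cohort:
    pre = em.preprocess_epochs(rec.dataset, pcfg)
    course = em.decode_timecourse(pre, decoder, times_ms=times, rng=rng)
    courses[rec.group].append(course)
    print(f"{rec.subject_id}: peak {course.peak_accuracy:.2f} "
          f"at {course.peak_time_ms:.0f} ms")

res = em.compare_peak_latency(courses["HC"], courses["MCI"],
                              n_boot=1000, rng=1)
lo, hi = res.extras["ci95"]
print(f"\nmedian MCI-minus-HC peak delay: {res.statistic:.0f} ms "
      f"(95% CI [{lo:.0f}, {hi:.0f}], SE {res.extras['se']:.0f} ms, "
      f"one-sided bootstrap p = {res.p_value:.4f})")
# the delay estimate tracks the injected 40 ms latency shift; chance-level
# decoding away from the evoked window keeps pre-stimulus peaks rare
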