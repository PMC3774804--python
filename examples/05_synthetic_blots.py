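"""Generate a blot-like densitometry series with known ground truth.

A log-normal pulse with the OVA-like shape (peak time 2 min, width 3.9
min) is sampled on a typical immunoblot grid, both channels are corrupted
by multiplicative lognormal measurement noise, and the phospho/total
fold-change normalization plus peak summarization recover the shape.
Printed: the noisy series and the recovered vs true statistics.
"""

import itkmaxent as im
from itkmaxent.experiment import DEFAULT_BLOT_GRID
from itkmaxent.synthetic import PulseSpec

pulse = PulseSpec.from_width(A=4.0, tau_p=2.0, tau_w=3.9)
series, truth = im.generate_blot_series(
    pulse, noise_sigma=0.10, time_grid=DEFAULT_BLOT_GRID, seed=7
)

print("t [min]  phospho [au]  total [au]  fold change")
for t, p, tot, f in zip(series.times, series.phospho, series.total,
                        series.fold_change):
    print(f"{t:6.0f} {p:12.1f} {tot:11.1f} {f:12.2f}")

measured = im.summarize_experiment(series)
print(f"\nrecovered: A={measured.A:.2f}, tau_p={measured.tau_p:.2f}, "
      f"tau_w={measured.tau_w:.2f}, R={measured.R:.2f}")
print(f"truth:     A={truth.A:.2f}, tau_p={truth.tau_p:.2f}, "
      f"tau_w={truth.tau_w:.2f}, R={truth.R:.2f}")
print("(coarse blot sampling and noise shift the recovered width; a dense "
      "noiseless grid recovers the truth exactly)")
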