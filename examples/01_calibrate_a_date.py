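"""Calibrate a single radiocarbon date and summarise its calendar posterior.

Builds a synthetic wiggly calibration curve, calibrates a charcoal date of
7600 +/- 40 14C BP against it, and prints the point summaries and the 95.4%
highest-posterior-density interval.
"""

import phasecal as pc

curve = pc.simulate_calibration_curve((11000, 5000), wiggle_amplitude=20,
                                      wiggle_period=500, sigma=8, seed=1)
det = pc.Determination("EX-001", 7600.0, 40.0)
grid = pc.CalendarGrid(9500.0, 7500.0, 1.0)
dens = pc.calibrate_terrestrial(det, curve, grid)

mean, median, mode = pc.point_summaries(dens)
hpd = pc.hpd_intervals(dens, 0.954)
print(f"mean {mean:.0f} cal BP, median {median:.0f}, mode {mode:.0f}")
for older, younger in hpd.intervals:
    print(f"95.4% HPD: {older:.0f} - {younger:.0f} cal BP")
print("The HPD interval is the smallest calendar range holding 95.4% of the")
print("posterior; wiggles in the curve can split it into several pieces.")
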