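"""Calibrate a single radiocarbon determination and report its intervals.

Builds a synthetic calibration curve (identity trend plus decadal wiggles),
calibrates a 12,100 +/- 60 BP charcoal date, and prints the median and the
highest-posterior-density intervals rounded to 10 years.  A marine shell
date shows the Delta-R reservoir correction: a positive Delta-R (locally
older water) is subtracted from the measured age before calibration.
"""

from calphase import (
    Determination,
    calibrate,
    gen_calibration_curve,
    hpd_interval,
    round_interval,
)

curve = gen_calibration_curve((20000, 8000), knot_step=20, wiggle_sd=20,
                              error_level=15, seed=11, label="example-sh")

charcoal = Determination("Beta-0001", cra=12100, sigma=60, material="charcoal")
pdf = calibrate(charcoal, curve)
print(f"{charcoal.lab_id}: {charcoal.cra} +/- {charcoal.sigma:.0f} BP")
print(f"  median {pdf.median():.0f} cal BP")
for level, tag in ((0.954, "95.4%"), (0.682, "68.2%")):
    spans = [round_interval(iv) for iv in hpd_interval(pdf, level)]
    print(f"  {tag}: " + "; ".join(f"{o:.0f}-{y:.0f}" for o, y in spans) + " cal BP")

marine_curve = gen_calibration_curve((20000, 8000), knot_step=20, wiggle_sd=20,
                                     error_level=20, seed=12, offset=400,
                                     label="example-marine", hemisphere="marine")
shell = Determination("AA-0002", cra=12500, sigma=70, material="marine shell",
                      reservoir="marine", delta_r=(150, 40))
pdf_m = calibrate(shell, marine_curve)
print(f"{shell.lab_id}: marine, Delta-R 150 +/- 40 -> median {pdf_m.median():.0f} cal BP")
# The shell's effective age is (12500 - 150) BP with error sqrt(70^2 + 40^2),
# calibrated on the marine curve.
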