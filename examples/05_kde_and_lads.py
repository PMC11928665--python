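"""Summarise an event set with the MCMC kernel-density model and compare
faunal last-appearance dates with an exploitation start estimate.

The KDE model treats the true age behind each input PDF as latent, samples
them jointly with a bandwidth shrinkage factor s ~ U(0,1) applied to
Silverman's rule, and reports the snapshot-mean density — which keeps
multi-modal structure a fixed-bandwidth KDE would smooth away.  The LAD
comparison is descriptive only: a last-appearance date records one
individual's death, not the extinction, so the gap distributions carry no
causal reading.
"""

import numpy as np

from calphase import CalendarPDF, gen_calibration_curve, kde_model, lad_comparison

rng = np.random.default_rng(3)


def sharp_pdf(age, sd=40.0):
    grid = np.arange(np.floor((age - 6 * sd) / 5) * 5, age + 6 * sd, 5.0)
    mass = np.exp(-0.5 * ((grid - age) / sd) ** 2)
    return CalendarPDF(grid, mass / mass.sum(), 5.0)


# two occupation pulses -> bimodal summary
ages = np.concatenate([rng.normal(14200, 150, 25), rng.normal(12300, 200, 35)])
result = kde_model([sharp_pdf(a) for a in ages], seed=3)
print(f"KDE model over {result.n_events} events: mean {result.mean:.0f}, "
      f"median {result.median:.0f} cal BP")
print(f"bandwidth posterior mean {result.bandwidth_posterior.mean():.0f} yr "
      "(shrunk below Silverman's rule to keep both pulses visible)")

lads = {
    "Equus": 12200.0,
    "Hippidion": 11900.0,
    "Mylodon": 12400.0,
    "Megatherium": 12700.0,
    "Smilodon": 11600.0,
}
start = sharp_pdf(17600, sd=500.0)  # an exploitation-start posterior
report = lad_comparison(lads, start)
print(f"LAD KDE mean {report['mean']:.0f}, median {report['median']:.0f} cal BP")
for genus, gap in report["per_genus"].items():
    print(f"  {genus:12s} gap to exploitation start {gap['gap_mean']:+.0f} yr, "
          f"P(LAD older) = {gap['p_lad_older_than_start']:.3f}")
print(report["note"])
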