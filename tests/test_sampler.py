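"""Posterior correctness, constraints, convergence and determinism."""

import math

import numpy as np
import pytest

from calphase import (
    Determination,
    OutlierSpec,
    SamplerSettings,
    Trace,
    boundary,
    check_convergence,
    event,
    phase,
    posterior_pdf,
    sample_posterior,
    sequence,
)
from calphase.sampler import _half_chain_overlap


def _phase_model(dets, outlier=None):
    events = [
        event(f"e{i}", determination=d,
              outlier=OutlierSpec(outlier) if outlier else None)
        for i, d in enumerate(dets)
    ]
    return sequence("m", boundary("start"), phase("p", *events), boundary("end"))


class TestSingleEvent:
    def test_bare_event_reproduces_calibration(self, identity_curve):
        root = sequence("m", event("e", determination=Determination("e", 10000, 50)))
        trace = sample_posterior(
            root, {"default": identity_curve},
            SamplerSettings(initial_iterations=20000, burn_in=2000, seed=3),
        )
        col = trace.column("e")
        assert col.mean() == pytest.approx(10000, abs=2)
        assert col.std() == pytest.approx(50, abs=2)

    def test_unregistered_curve_raises(self, identity_curve):
        root = sequence("m", event("e", determination=Determination("e", 10000, 50, curve_key="missing")))
        with pytest.raises(KeyError):
            sample_posterior(root, {"default": identity_curve})


class TestConstraints:
    def test_sequence_order_holds_in_every_sample(self, identity_curve):
        d = Determination("a", 12000, 60)
        root = sequence(
            "m",
            boundary("b0"),
            phase("p1", event("older", determination=d)),
            boundary("b1"),
            phase("p2", event("younger", determination=Determination("b", 12000, 60))),
            boundary("b2"),
        )
        trace = sample_posterior(
            root, {"default": identity_curve},
            SamplerSettings(initial_iterations=8000, burn_in=1500, seed=5),
        )
        older = trace.column("older")
        younger = trace.column("younger")
        mid = trace.column("b1")
        assert np.all(older >= mid)
        assert np.all(mid >= younger)
        assert np.all(older >= younger)

    def test_boundary_contains_phase_events(self, wiggly_curve):
        dets = [Determination(f"d{i}", 11800 + 60 * i, 45) for i in range(6)]
        trace = sample_posterior(
            _phase_model(dets, outlier="general"), {"default": wiggly_curve},
            SamplerSettings(initial_iterations=6000, burn_in=1500, seed=9),
        )
        start = trace.column("start")
        end = trace.column("end")
        events = trace.samples[:, trace.n_boundaries:]
        assert np.all(start[:, None] >= events)
        assert np.all(events >= end[:, None])


class TestPriorLimit:
    def test_no_data_start_boundary_matches_analytic_prior(self, identity_curve):
        # one undated event between two boundaries: (a, b, t) is uniform on
        # the wedge {lo <= b <= t <= a <= hi} (the n=1 standard span prior
        # is flat), so the start-boundary marginal CDF is cubic in (a - lo)
        root = sequence("m", boundary("a"), phase("p", event("undated")), boundary("b"))
        settings = SamplerSettings(
            initial_iterations=100000, burn_in=5000, seed=11, thinning=1,
            range_padding=5000.0,
        )
        trace = sample_posterior(root, {"default": identity_curve}, settings)
        a = np.sort(trace.column("a"))
        lo, hi = -5000.0, 15000.0  # default anchor 0..10000 plus the padding
        floor = settings.grid_resolution
        ref = ((a - lo - floor) / (hi - lo - floor)) ** 3
        emp = (np.arange(a.size) + 0.5) / a.size
        assert np.abs(emp - ref).max() < 0.02


class TestExchangeability:
    def test_event_declaration_order_irrelevant(self, wiggly_curve):
        dets = [Determination(f"d{i}", 12000 + 80 * i, 50) for i in range(5)]
        settings = SamplerSettings(initial_iterations=12000, burn_in=2000, seed=21)
        t1 = sample_posterior(_phase_model(dets), {"default": wiggly_curve}, settings)
        t2 = sample_posterior(_phase_model(dets[::-1]), {"default": wiggly_curve}, settings)
        s1 = posterior_pdf(t1, "start")
        s2 = posterior_pdf(t2, "start")
        mc_se = t1.column("start").std() / math.sqrt(200)
        assert abs(s1.mean() - s2.mean()) < 4 * mc_se


class TestConvergence:
    def test_unimodal_model_converges_within_initial_run(self, identity_curve):
        root = _phase_model([Determination("d", 11000, 50), Determination("e", 11100, 50)])
        trace, report = check_convergence(
            root, {"default": identity_curve},
            SamplerSettings(initial_iterations=30000, burn_in=3000, seed=2),
        )
        assert report.converged
        assert report.overall > 0.95
        assert report.passes_run == 0

    def test_frozen_chain_flagged(self):
        assert _half_chain_overlap(np.full(1000, 12000.0)) == 0.0
        assert _half_chain_overlap(np.random.default_rng(0).normal(size=4000)) > 0.9

    def test_protocol_doubles_pass_interval(self, identity_curve):
        # a tiny initial run forces at least one extension pass
        root = _phase_model([Determination("d", 11000, 50) for _ in range(3)])
        trace, report = check_convergence(
            root, {"default": identity_curve},
            SamplerSettings(initial_iterations=200, burn_in=200, pass_length=200,
                            convergence_threshold=0.97, seed=4),
        )
        assert report.iterations > 400
        assert trace.samples.shape[0] > 200


class TestDeterminism:
    def test_same_seed_bit_identical(self, wiggly_curve):
        dets = [Determination(f"d{i}", 12500 + 70 * i, 45) for i in range(4)]
        settings = SamplerSettings(initial_iterations=3000, burn_in=500, seed=13)
        t1 = sample_posterior(_phase_model(dets, "general"), {"default": wiggly_curve}, settings)
        t2 = sample_posterior(_phase_model(dets, "general"), {"default": wiggly_curve}, settings)
        assert np.array_equal(t1.samples, t2.samples)
        assert np.array_equal(t1.z_samples, t2.z_samples)

    def test_different_seeds_agree_within_monte_carlo_error(self, wiggly_curve):
        dets = [Determination(f"d{i}", 12500 + 70 * i, 45) for i in range(4)]
        means = []
        for seed in (1, 2):
            t = sample_posterior(
                _phase_model(dets), {"default": wiggly_curve},
                SamplerSettings(initial_iterations=20000, burn_in=2000, seed=seed),
            )
            means.append(t.column("start").mean())
            sd = t.column("start").std()
        mc_se = sd / math.sqrt(300)  # conservative effective sample size
        assert abs(means[0] - means[1]) < 2 * mc_se * 2


class TestPosteriorPdf:
    def _trace_from(self, samples, label="x"):
        return Trace(
            names=[label], samples=np.asarray(samples, float)[:, None],
            n_boundaries=0, z_names=[], z_samples=np.empty((len(samples), 0), np.int8),
            delta_samples=np.empty((len(samples), 0)), m_names=[],
            m_samples=np.empty((len(samples), 0)), query_map={}, seed=0,
            settings=SamplerSettings(),
        )

    def test_constant_samples_give_point_mass(self):
        pdf = posterior_pdf(self._trace_from(np.full(500, 12000.0)), "x")
        assert pdf.mass.max() == pytest.approx(1.0)
        assert pdf.grid[np.argmax(pdf.mass)] == 12000.0

    def test_normal_samples_recover_mean(self):
        samples = np.random.default_rng(7).normal(12000, 100, 100000)
        pdf = posterior_pdf(self._trace_from(samples), "x")
        assert pdf.mean() == pytest.approx(12000, abs=2)
        assert pdf.mass.sum() == pytest.approx(1.0, abs=1e-9)

    def test_resolution_change_shifts_mean_below_cell(self):
        samples = np.random.default_rng(8).normal(12000, 80, 20000)
        m5 = posterior_pdf(self._trace_from(samples), "x", resolution=5.0).mean()
        m10 = posterior_pdf(self._trace_from(samples), "x", resolution=10.0).mean()
        assert abs(m5 - m10) < 5

    def test_unknown_label_raises(self):
        with pytest.raises(KeyError):
            posterior_pdf(self._trace_from(np.zeros(10)), "nope")


class TestOutlierModel:
    def test_clean_data_activation_stays_near_prior(self, wiggly_curve):
        rng = np.random.default_rng(17)
        dets = []
        for i in range(8):
            age = rng.uniform(13000, 14000)
            mu, sc = (float(v) for v in wiggly_curve.lookup(age))
            dets.append(Determination(f"d{i}", round(mu + rng.standard_normal() * 40), 40))
        trace = sample_posterior(
            _phase_model(dets, "general"), {"default": wiggly_curve},
            SamplerSettings(initial_iterations=15000, burn_in=2000, seed=19),
        )
        acts = list(trace.outlier_activation().values())
        assert max(acts) < 0.25
        assert abs(np.mean(acts) - 0.05) < 0.05

    def test_trace_exports_manifest_and_csv(self, identity_curve, tmp_path):
        import json

        trace = sample_posterior(
            _phase_model([Determination("d", 11000, 50), Determination("e", 11050, 50)]),
            {"default": identity_curve},
            SamplerSettings(initial_iterations=500, burn_in=200, seed=1),
        )
        man = trace.manifest()
        assert man["seed"] == 1 and man["n_retained"] == 500
        json.dumps(man)  # serialisable
        with open(tmp_path / "trace.csv", "w") as fh:
            trace.export_csv(fh)
        header = (tmp_path / "trace.csv").read_text().splitlines()[0]
        assert header == "iteration,parameter,value"
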