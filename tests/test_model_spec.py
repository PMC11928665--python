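"""Model trees, replicate pooling, and automatic site-model construction."""

import itertools

import numpy as np
import pytest
from scipy import stats

from calphase import (
    Determination,
    OutlierSpec,
    SiteComponent,
    SiteRecord,
    SiteSkipped,
    boundary,
    date_query,
    event,
    gen_site,
    model_from_text,
    model_to_text,
    phase,
    r_combine,
    sequence,
    site_model_from_record,
    validate_model,
)


def _dets(*pairs):
    return [Determination(f"d{i}", c, s) for i, (c, s) in enumerate(pairs)]


class TestRCombine:
    def test_identical_pair(self):
        out = r_combine(_dets((10000, 50), (10000, 50)))
        assert out.cra == pytest.approx(10000)
        assert out.sigma == pytest.approx(50 / np.sqrt(2))
        assert out.t_stat == 0
        assert out.passed

    def test_consistent_pair_t_statistic(self):
        out = r_combine(_dets((10000, 50), (10100, 50)))
        assert out.cra == pytest.approx(10050)
        assert out.sigma == pytest.approx(35.3553, abs=1e-3)
        assert out.t_stat == pytest.approx(2.0)
        assert out.passed  # chi2(1, 5%) = 3.84

    def test_inconsistent_pair_fails(self):
        out = r_combine(_dets((10000, 30), (10500, 30)))
        assert out.t_stat == pytest.approx(500**2 / 2 / 30**2, rel=1e-6)
        assert out.t_stat > stats.chi2.ppf(0.95, 1)
        assert not out.passed

    def test_permutation_invariant(self):
        dets = _dets((9000, 40), (9100, 60), (9050, 35))
        ref = r_combine(dets)
        for perm in itertools.permutations(dets):
            out = r_combine(list(perm))
            assert out.cra == pytest.approx(ref.cra)
            assert out.sigma == pytest.approx(ref.sigma)
            assert out.t_stat == pytest.approx(ref.t_stat)

    @pytest.mark.parametrize("k", [2, 4, 9])
    def test_k_identical_scale_as_inverse_sqrt_k(self, k):
        out = r_combine(_dets(*[(8000, 45)] * k))
        assert out.sigma == pytest.approx(45 / np.sqrt(k))

    def test_requires_common_curve_assignment(self):
        a = Determination("a", 9000, 40, curve_key="sh")
        b = Determination("b", 9050, 40, curve_key="nh")
        with pytest.raises(ValueError):
            r_combine([a, b])

    def test_requires_two(self):
        with pytest.raises(ValueError):
            r_combine(_dets((9000, 40)))


class TestValidateModel:
    def test_canonical_uniform_phase_is_valid(self, det):
        root = sequence(
            "s",
            boundary("a"),
            phase("p", *(event(f"e{i}", determination=det(10000 + i)) for i in range(3))),
            boundary("b"),
        )
        assert validate_model(root) == []

    def test_phase_without_boundaries_flagged(self, det):
        root = sequence("s", phase("naked", event("e", determination=det(10000))))
        violations = validate_model(root)
        assert any("naked" in v for v in violations)

    def test_duplicate_event_label_flagged(self, det):
        root = sequence(
            "s",
            boundary("a"),
            phase("p", event("e", determination=det(10000)),
                  event("e", determination=det(10100))),
            boundary("b"),
        )
        assert any("twice" in v for v in validate_model(root))

    def test_outlier_on_undated_event_flagged(self):
        root = sequence(
            "s", boundary("a"),
            phase("p", event("e", outlier=OutlierSpec("general"))),
            boundary("b"),
        )
        assert any("undated" in v for v in validate_model(root))

    def test_generator_output_always_valid(self, wiggly_curve):
        for seed in range(100):
            rng = np.random.default_rng(seed)
            n_layers = int(rng.integers(1, 4))
            layers = []
            a = 16000.0
            for _ in range(n_layers):
                span = float(rng.uniform(300, 900))
                layers.append((a, a - span, int(rng.integers(2, 6))))
                a -= span + 50
            site, _ = gen_site(layers, wiggly_curve, seed=seed, name=f"s{seed}")
            spec = site_model_from_record(site)
            if spec.root is not None:
                assert validate_model(spec.root) == []


class TestOutlierSpec:
    def test_prior_prob_bounds(self):
        with pytest.raises(ValueError):
            OutlierSpec("general", prior_prob=0.0)

    def test_unknown_preset(self):
        with pytest.raises(ValueError):
            OutlierSpec("charcoal")


def _component(cid, layer, idx, n, base, sample_prefix=None):
    comp = SiteComponent(component_id=cid, layer=layer, layer_index=idx)
    for j in range(n):
        comp.determinations.append(Determination(f"{cid}-{j}", base + 30 * j, 50))
        comp.sample_ids.append(f"{sample_prefix}-{j}" if sample_prefix else "")
    return comp


class TestSiteRules:
    def test_rule1_three_ordered_layers(self):
        site = SiteRecord(
            "S",
            [
                _component("c0", "L0", 3, 2, 14800),
                _component("c1", "L1", 2, 2, 14200),
                _component("c2", "L2", 1, 2, 13600),
            ],
        )
        spec = site_model_from_record(site)
        assert spec.rule == 1
        kinds = [c.kind for c in spec.root.children]
        assert kinds.count("boundary") == 4
        assert kinds.count("phase") == 3
        # oldest layer comes first in the sequence
        first_phase = next(c for c in spec.root.children if c.kind == "phase")
        assert "L0" in first_phase.label
        assert validate_model(spec.root) == []

    def test_rule2_no_layer_info(self):
        site = SiteRecord("S", [_component("c0", "", None, 4, 14000)])
        spec = site_model_from_record(site)
        assert spec.rule == 2
        kinds = [c.kind for c in spec.root.children]
        assert kinds == ["boundary", "phase", "boundary"]

    def test_rule2_when_partial_stratigraphy(self):
        site = SiteRecord(
            "S",
            [
                _component("c0", "L0", 2, 2, 14500),
                _component("c1", "L1", None, 2, 14000),  # floating layer
            ],
        )
        spec = site_model_from_record(site)
        assert spec.rule == 2
        assert any("stratigraph" in n for n in spec.notes)

    def test_rule3_single_measurement(self):
        site = SiteRecord("S", [_component("c0", "", None, 1, 14000)])
        spec = site_model_from_record(site)
        assert spec.rule == 3
        assert spec.root is None
        assert spec.passthrough.cra == 14000

    def test_zero_usable_dates_skipped(self):
        sed = SiteComponent("c0", cultural=False,
                            determinations=[Determination("d", 15000, 80)])
        with pytest.raises(SiteSkipped):
            site_model_from_record(SiteRecord("S", [sed]))

    def test_rules_exhaustive_and_deterministic(self):
        site = SiteRecord("S", [_component("c0", "", None, 3, 14000)])
        assert site_model_from_record(site).rule == site_model_from_record(site).rule

    def test_replicates_pooled_with_ssimple(self):
        comp = _component("c0", "", None, 3, 14000, sample_prefix="same")
        comp.sample_ids = ["s1", "s1", "s2"]  # first two replicate one sample
        site = SiteRecord("S", [comp, _component("c1", "", None, 1, 13800)])
        spec = site_model_from_record(site)
        events = [n for n in spec.root.walk() if n.kind == "event"]
        assert len(events) == 3  # 2 pooled into 1, plus 1 solo, plus c1's
        pooled = [e for e in events if e.outlier.preset == "ssimple"]
        assert len(pooled) == 1
        assert pooled[0].determination.sigma == pytest.approx(50 / np.sqrt(2))

    def test_sediment_enters_as_non_cultural_event(self):
        cult = _component("c0", "", None, 2, 14000)
        sed = SiteComponent("geo", cultural=False,
                            determinations=[Determination("g", 15000, 100)],
                            sample_ids=[""])
        spec = site_model_from_record(SiteRecord("S", [cult, sed]))
        events = [n for n in spec.root.walk() if n.kind == "event"]
        assert sum(1 for e in events if not e.cultural) == 1
        queries = [n for n in spec.root.walk() if n.kind == "date_query"]
        assert all("geo" not in q.label for q in queries)


class TestSerialisation:
    def test_round_trip_preserves_structure(self, normal_pdf):
        root = sequence(
            "site",
            boundary("start"),
            phase(
                "L0",
                event("e0", determination=Determination("e0", 12000, 45),
                      outlier=OutlierSpec("general", 0.05)),
                event("e1", prior_pdf=normal_pdf(12100, 60)),
                event("geo", determination=Determination("geo", 12500, 80),
                      cultural=False),
                date_query("c0"),
            ),
            boundary("end"),
        )
        text = model_to_text(root)
        back = model_from_text(text)
        assert model_to_text(back) == text
        orig = [(n.kind, n.label, n.cultural) for n in root.walk()]
        rt = [(n.kind, n.label, n.cultural) for n in back.walk()]
        assert orig == rt
        ev = next(n for n in back.walk() if n.label == "e1")
        assert np.allclose(ev.prior_pdf.mass,
                           next(n for n in root.walk() if n.label == "e1").prior_pdf.mass,
                           atol=1e-9)
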