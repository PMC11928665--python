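"""End-to-end multi-site timeline analysis.

The pipeline ingests a component table (one row per chronometric
measurement, grouped into cultural components at archaeological sites),
assigns calibration curves by latitude policy, models every site under the
three construction rules, collects one posterior calendar PDF per cultural
component whose age range intersects the interval of interest, integrates
those PDFs into single-phase category models (geographic province, lithic
technology, high altitude, megafauna exploitation) whose start boundaries
estimate the onset of each activity, and compares the start estimates with
fixed climatic intervals (ACR, YD).  Database-completeness statistics and a
descriptive comparison with faunal last-appearance dates round it out.
"""

from __future__ import annotations

import logging
import math
import zlib
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .calcurve import (
    DEFAULT_RESOLUTION,
    CalendarPDF,
    CalibrationCurve,
    Determination,
    calibrate,
    hpd_interval,
    mix_calibration,
    round_interval,
)
from .density import ACR, YD, difference, kde_model, kde_plot, overlap_probability
from .model_spec import (
    SiteComponent,
    SiteRecord,
    SiteSkipped,
    boundary,
    event,
    phase,
    sequence,
    site_model_from_record,
)
from .sampler import SamplerSettings, posterior_pdf, sample_posterior

logger = logging.getLogger("calphase.pipeline")

__all__ = [
    "AgeRecord",
    "ComponentRecord",
    "LoadResult",
    "PipelineConfig",
    "CategoryModelResult",
    "DatabaseSummary",
    "load_database",
    "assign_curves",
    "run_site_stage",
    "integrate_category",
    "southern_andes_subset",
    "sensitivity_run",
    "summarize_database",
    "lad_comparison",
    "build_category_sets",
    "run_timeline",
    "PROVINCES",
]

PROVINCES = [
    "Patagonian Plateau",
    "Northern Andes",
    "Central Andes",
    "Southern Andes",
    "Paraguay-Parana Lowlands",
    "Brazilian Highlands",
    "Amazonian Lowlands",
    "Orinoco Lowlands",
    "Guiana Highlands",
]

MANDATORY_COLUMNS = [
    "site",
    "province",
    "component",
    "lab_id",
    "cra",
    "error",
]


@dataclass
class AgeRecord:
    """One measurement row with its quality metadata."""

    lab_id: str
    cra: float
    error: float
    age_type: str = "14C"  # {14C, calendar}
    material: str = ""
    species: str = ""
    pretreatment: str = ""
    d13c: float | None = None
    cn_ratio: float | None = None
    reservoir: str = ""  # {"", marine}
    delta_r: float | None = None
    delta_r_sd: float | None = None
    sample_id: str = ""
    curve_key: str = ""  # filled by assign_curves

    def to_determination(self) -> Determination:
        reservoir = "atmospheric"
        delta_r = None
        if self.reservoir == "marine":
            reservoir = "marine"
            delta_r = (self.delta_r or 0.0, self.delta_r_sd or 0.0)
        elif "+" in self.curve_key:
            reservoir = "mixed_hemispheric"
        return Determination(
            lab_id=self.lab_id,
            cra=self.cra,
            sigma=self.error,
            material=self.material,
            reservoir=reservoir,
            delta_r=delta_r,
            curve_key=self.curve_key,
        )


@dataclass
class ComponentRecord:
    """One cultural component (or sediment constraint) with category labels."""

    site: str
    component_id: str
    province: str
    country: str = ""
    latitude: float | None = None
    longitude: float | None = None
    altitude: float = 0.0
    layer: str = ""
    layer_index: int | None = None
    cultural: bool = True
    lithic: list[str] = field(default_factory=list)
    megafauna: bool = False
    ages: list[AgeRecord] = field(default_factory=list)
    extra: dict = field(default_factory=dict)


@dataclass
class LoadResult:
    records: list[ComponentRecord]
    rejects: pd.DataFrame  # row number, reason

    @property
    def n_components(self) -> int:
        return len(self.records)


@dataclass
class PipelineConfig:
    seed: int = 1
    grid_resolution: float = DEFAULT_RESOLUTION
    mixing_band: tuple[float, float] = (-25.0, 15.0)  # latitudes using a mixed curve
    default_curve: str = "sh"
    north_curve: str = "nh"
    marine_curve: str = "marine"
    high_altitude_cutoff: float = 2500.0
    poleward_cutoff: float = 40.0  # degrees south
    inclusion_window: tuple[float, float] = (14500.0, 11700.0)  # older, younger
    inclusion_level: float = 0.954
    cn_range: tuple[float, float] = (2.9, 3.6)
    outlier_prior: float = 0.05
    min_category_size: int = 2
    low_n_threshold: int = 5
    sampler: SamplerSettings = field(default_factory=SamplerSettings)
    curve_overrides: dict = field(default_factory=dict)  # site -> curve key


@dataclass
class CategoryModelResult:
    category: str
    n_components: int
    start_pdf: CalendarPDF
    ci_954: list[tuple[float, float]]  # rounded to 10 yr, older first
    ci_682: list[tuple[float, float]]
    acr_yd: dict  # interval label -> (p_before, p_within, p_after)
    manifest: dict = field(default_factory=dict)
    notes: list[str] = field(default_factory=list)

    @property
    def headline_954(self) -> tuple[float, float]:
        """Envelope of the 95.4% HPD region (older, younger)."""
        return (self.ci_954[0][0], self.ci_954[-1][1])


@dataclass
class DatabaseSummary:
    n_sites: int
    n_ages: int
    pct_radiocarbon: float
    pct_charcoal: float
    pct_charcoal_species_unreported: float
    pct_cn_reported: float
    n_cn_reported: int
    n_cn_in_range: int
    per_country: dict[str, int]
    per_province: dict[str, int]


# ---------------------------------------------------------------------------
# loading


def _opt_float(value) -> float | None:
    if value is None or (isinstance(value, float) and math.isnan(value)) or value == "":
        return None
    return float(value)


def load_database(source, schema_version: int = 1) -> LoadResult:
    """Load a component CSV without filtering ("without exclusion").

    One :class:`ComponentRecord` per (site, component); malformed rows go
    into the rejects report with their row number and reason, never
    silently dropped.
    """
    df = pd.read_csv(source, dtype=str, keep_default_na=False)
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"component table lacks mandatory columns: {missing}")
    known = set(MANDATORY_COLUMNS) | {
        "country", "latitude", "longitude", "altitude", "layer", "layer_index",
        "cultural", "sample_id", "age_type", "material", "species", "pretreatment",
        "d13c", "cn_ratio", "lithic", "megafauna", "reservoir", "delta_r", "delta_r_sd",
    }
    extra_cols = [c for c in df.columns if c not in known]

    components: dict[tuple[str, str], ComponentRecord] = {}
    rejects: list[dict] = []
    for idx, row in df.iterrows():
        rowno = int(idx) + 2  # header is line 1
        try:
            cra = float(row["cra"])
            error = float(row["error"])
            if error <= 0:
                raise ValueError("error must be positive")
            province = row["province"]
            if province not in PROVINCES:
                raise ValueError(f"unknown province {province!r}")
            key = (row["site"], row["component"])
            if key not in components:
                lithic = [t for t in str(row.get("lithic", "")).split(";") if t]
                components[key] = ComponentRecord(
                    site=row["site"],
                    component_id=row["component"],
                    province=province,
                    country=row.get("country", ""),
                    latitude=_opt_float(row.get("latitude", "")),
                    longitude=_opt_float(row.get("longitude", "")),
                    altitude=_opt_float(row.get("altitude", "")) or 0.0,
                    layer=row.get("layer", ""),
                    layer_index=(
                        int(float(row["layer_index"]))
                        if str(row.get("layer_index", "")).strip() != ""
                        else None
                    ),
                    cultural=str(row.get("cultural", "1")).strip() not in ("0", "false", "False"),
                    lithic=lithic,
                    megafauna=str(row.get("megafauna", "0")).strip() in ("1", "true", "True"),
                    extra={c: row[c] for c in extra_cols},
                )
            rec = components[key]
            rec.ages.append(
                AgeRecord(
                    lab_id=row["lab_id"],
                    cra=cra,
                    error=error,
                    age_type=row.get("age_type", "14C") or "14C",
                    material=row.get("material", ""),
                    species=row.get("species", ""),
                    pretreatment=row.get("pretreatment", ""),
                    d13c=_opt_float(row.get("d13c", "")),
                    cn_ratio=_opt_float(row.get("cn_ratio", "")),
                    reservoir=row.get("reservoir", ""),
                    delta_r=_opt_float(row.get("delta_r", "")),
                    delta_r_sd=_opt_float(row.get("delta_r_sd", "")),
                    sample_id=row.get("sample_id", ""),
                )
            )
        except (ValueError, KeyError) as exc:
            rejects.append({"row": rowno, "reason": str(exc)})
    return LoadResult(
        records=list(components.values()),
        rejects=pd.DataFrame(rejects, columns=["row", "reason"]),
    )


# ---------------------------------------------------------------------------
# curve assignment


def assign_curves(
    records: list[ComponentRecord], config: PipelineConfig
) -> list[ComponentRecord]:
    """Assign a calibration curve key to every measurement.

    Southern-hemisphere atmospheric curve by default; a uniform
    north+south mixture inside the configured latitude band; the marine
    curve (with the record's Delta-R) where the row says so.  Per-site
    overrides in the config win.  Sites with neither coordinates nor an
    override raise.
    """
    mixed_key = f"{config.north_curve}+{config.default_curve}"
    for rec in records:
        override = config.curve_overrides.get(rec.site)
        for age in rec.ages:
            if age.age_type != "14C":
                age.curve_key = ""
                continue
            if age.reservoir == "marine":
                age.curve_key = config.marine_curve
            elif override is not None:
                age.curve_key = override
            elif rec.latitude is None:
                raise ValueError(
                    f"site {rec.site!r}: no coordinates and no curve override"
                )
            elif config.mixing_band[0] <= rec.latitude <= config.mixing_band[1]:
                age.curve_key = mixed_key
            else:
                age.curve_key = config.default_curve
    return records


# ---------------------------------------------------------------------------
# site stage


def _site_seed(master: int, site: str) -> int:
    return (master * 1000003 + zlib.crc32(site.encode())) % (2**31 - 1)


def _calendar_pdf_for_age(age: AgeRecord, resolution: float) -> CalendarPDF:
    """Normal calendar-scale likelihood for non-radiocarbon ages."""
    lo = math.floor((age.cra - 5 * age.error) / resolution) * resolution
    hi = math.ceil((age.cra + 5 * age.error) / resolution) * resolution
    grid = np.arange(lo, hi + 0.5 * resolution, resolution)
    dens = np.exp(-0.5 * ((grid - age.cra) / age.error) ** 2)
    return CalendarPDF(grid, dens / dens.sum(), resolution=resolution, label=age.lab_id)


def _site_record(records: list[ComponentRecord], resolution: float) -> SiteRecord:
    site = records[0].site
    comps = []
    for rec in records:
        comp = SiteComponent(
            component_id=rec.component_id,
            layer=rec.layer,
            layer_index=rec.layer_index,
            cultural=rec.cultural,
        )
        for age in rec.ages:
            if age.age_type == "14C":
                comp.determinations.append(age.to_determination())
                comp.sample_ids.append(age.sample_id)
            else:
                # calendar-scale age: normal prior entered directly
                comp.determinations.append(
                    Determination(age.lab_id, age.cra, age.error, material=age.material)
                )
                comp.sample_ids.append(age.sample_id or age.lab_id)
        comps.append(comp)
    return SiteRecord(name=site, components=comps)


def _calibrate_age(age: AgeRecord, curves: dict[str, CalibrationCurve], resolution: float) -> CalendarPDF:
    if age.age_type != "14C":
        return _calendar_pdf_for_age(age, resolution)
    det = age.to_determination()
    if det.reservoir == "mixed_hemispheric":
        ka, kb = det.curve_key.split("+")
        return mix_calibration(det, curves[ka], curves[kb], resolution)
    return calibrate(det, curves[det.curve_key], resolution)


@dataclass
class SiteStageResult:
    component_pdfs: dict[str, CalendarPDF]  # "site/component" -> PDF
    rules: dict[str, int]  # site -> rule used (0 = skipped)
    skipped: dict[str, str]  # site -> reason
    manifests: dict[str, dict]


def run_site_stage(
    records: list[ComponentRecord],
    curves: dict[str, CalibrationCurve],
    config: PipelineConfig,
) -> SiteStageResult:
    """Model every site and emit one posterior PDF per cultural component.

    Rules 1-2 components are represented by the Date query posterior of
    their phase; rule-3 components by the calibrated measurement itself.
    """
    by_site: dict[str, list[ComponentRecord]] = {}
    for rec in records:
        by_site.setdefault(rec.site, []).append(rec)

    # calendar-scale ages must enter the model as PDF events, so swap the
    # placeholder determinations for prior PDFs after model construction
    component_pdfs: dict[str, CalendarPDF] = {}
    rules: dict[str, int] = {}
    skipped: dict[str, str] = {}
    manifests: dict[str, dict] = {}
    res = config.grid_resolution
    for site, recs in sorted(by_site.items()):
        cal_types = {
            age.lab_id: age for rec in recs for age in rec.ages if age.age_type != "14C"
        }
        try:
            spec = site_model_from_record(_site_record(recs, res), config.outlier_prior)
        except SiteSkipped as exc:
            skipped[site] = str(exc)
            rules[site] = 0
            logger.info("skipping %s: %s", site, exc)
            continue
        rules[site] = spec.rule
        if spec.rule == 3:
            rec = next(r for r in recs if r.cultural and r.ages)
            age = rec.ages[0]
            component_pdfs[f"{site}/{rec.component_id}"] = _calibrate_age(age, curves, res)
            manifests[site] = {"rule": 3}
            continue
        for node in spec.root.walk():
            if node.kind == "event" and node.determination is not None:
                if node.determination.lab_id in cal_types:
                    age = cal_types[node.determination.lab_id]
                    node.prior_pdf = _calendar_pdf_for_age(age, res)
                    node.determination = None
        settings = replace(
            config.sampler,
            seed=_site_seed(config.seed, site),
            grid_resolution=res,
        )
        try:
            trace = sample_posterior(spec.root, curves, settings)
        except Exception as exc:  # sampling failure: log, continue
            skipped[site] = f"sampling failed: {exc}"
            rules[site] = 0
            logger.warning("site %s sampling failed: %s", site, exc)
            continue
        for label in trace.query_map:
            component_pdfs[label] = posterior_pdf(trace, label)
        manifests[site] = trace.manifest()
    return SiteStageResult(component_pdfs, rules, skipped, manifests)


# ---------------------------------------------------------------------------
# category integration


def in_window(pdf: CalendarPDF, config: PipelineConfig) -> bool:
    """A component is interval-aged when its 95.4% range intersects the
    configured window (older, younger)."""
    older, younger = config.inclusion_window
    spans = hpd_interval(pdf, config.inclusion_level)
    return any(a >= younger and b <= older for a, b in spans)


def build_category_sets(
    records: list[ComponentRecord],
    pdfs: dict[str, CalendarPDF],
    config: PipelineConfig,
) -> dict[str, dict[str, list[CalendarPDF]]]:
    """Group interval-aged component PDFs into the four category facets.

    A component carrying several lithic labels enters each corresponding
    category once.  Returns facet -> category -> PDFs.
    """
    sets: dict[str, dict[str, list[CalendarPDF]]] = {
        "province": {},
        "lithic": {},
        "altitude": {},
        "megafauna": {},
    }
    for rec in records:
        if not rec.cultural:
            continue
        key = f"{rec.site}/{rec.component_id}"
        pdf = pdfs.get(key)
        if pdf is None or not in_window(pdf, config):
            continue
        sets["province"].setdefault(rec.province, []).append(pdf)
        for lab in rec.lithic:
            sets["lithic"].setdefault(lab, []).append(pdf)
        if rec.altitude >= config.high_altitude_cutoff:
            sets["altitude"].setdefault(
                f">={config.high_altitude_cutoff:.0f} m", []
            ).append(pdf)
        if rec.megafauna:
            sets["megafauna"].setdefault("megafauna exploitation", []).append(pdf)
    return sets


def integrate_category(
    pdfs: Sequence[CalendarPDF],
    category: str,
    config: PipelineConfig,
    settings: SamplerSettings | None = None,
) -> CategoryModelResult:
    """Fit a single uniform phase whose events carry the component PDFs as
    likelihoods; the start-boundary posterior estimates the category onset."""
    if len(pdfs) < config.min_category_size:
        raise ValueError(
            f"category {category!r}: need >= {config.min_category_size} PDFs, got {len(pdfs)}"
        )
    ph = phase(f"{category}/phase")
    for i, p in enumerate(pdfs):
        ph.children.append(event(f"{category}/ev{i}", prior_pdf=p))
    root = sequence(
        category, boundary(f"{category}/start"), ph, boundary(f"{category}/end")
    )
    if settings is None:
        settings = replace(
            config.sampler,
            seed=_site_seed(config.seed, f"category:{category}"),
            grid_resolution=config.grid_resolution,
        )
    trace = sample_posterior(root, {}, settings)
    start_pdf = posterior_pdf(trace, f"{category}/start")
    ci954 = [round_interval(iv) for iv in hpd_interval(start_pdf, 0.954)]
    ci682 = [round_interval(iv) for iv in hpd_interval(start_pdf, 0.682)]
    overlaps = {
        iv.label: overlap_probability(start_pdf, iv) for iv in (ACR, YD)
    }
    notes = []
    if len(pdfs) <= config.low_n_threshold:
        notes.append(
            f"low sample size (n = {len(pdfs)}): start estimate carries widened uncertainty"
        )
    return CategoryModelResult(
        category=category,
        n_components=len(pdfs),
        start_pdf=start_pdf,
        ci_954=ci954,
        ci_682=ci682,
        acr_yd=overlaps,
        manifest=trace.manifest(),
        notes=notes,
    )


def southern_andes_subset(
    records: list[ComponentRecord],
    pdfs: dict[str, CalendarPDF],
    config: PipelineConfig,
    cutoff: float | None = None,
) -> CategoryModelResult:
    """Start estimate using only components poleward of the cutoff
    latitude (strictly south of 40 degrees S by default)."""
    cut = -(cutoff if cutoff is not None else config.poleward_cutoff)
    selected = [
        pdfs[f"{rec.site}/{rec.component_id}"]
        for rec in records
        if rec.cultural
        and rec.province == "Southern Andes"
        and rec.latitude is not None
        and rec.latitude < cut
        and f"{rec.site}/{rec.component_id}" in pdfs
        and in_window(pdfs[f"{rec.site}/{rec.component_id}"], config)
    ]
    if not selected:
        raise ValueError("no components poleward of the cutoff")
    return integrate_category(selected, f"Southern Andes poleward {abs(cut):.0f}S", config)


def sensitivity_run(
    pdf_sets: dict[str, list[CalendarPDF]],
    config: PipelineConfig,
    variants: dict[str, dict],
) -> pd.DataFrame:
    """Re-fit named category models under prior/settings overrides.

    ``variants`` maps a variant name to SamplerSettings field overrides
    (e.g. {"span_prior": "naive"}).  Returns a table of 95.4% start CIs per
    variant with the endpoint shifts against the base fit.
    """
    rows = []
    base_results = {}
    for cat, pdfs in pdf_sets.items():
        base_results[cat] = integrate_category(pdfs, cat, config)
    for name, overrides in [("base", {})] + list(variants.items()):
        for cat, pdfs in pdf_sets.items():
            settings = replace(
                config.sampler,
                seed=_site_seed(config.seed, f"category:{cat}"),
                grid_resolution=config.grid_resolution,
                **overrides,
            )
            res = (
                base_results[cat]
                if name == "base"
                else integrate_category(pdfs, cat, config, settings=settings)
            )
            old, young = res.headline_954
            b_old, b_young = base_results[cat].headline_954
            rows.append(
                {
                    "variant": name,
                    "category": cat,
                    "ci954_older": old,
                    "ci954_younger": young,
                    "shift_older": old - b_old,
                    "shift_younger": young - b_young,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# database summary


def summarize_database(
    records: list[ComponentRecord], cn_range: tuple[float, float] = (2.9, 3.6)
) -> DatabaseSummary:
    """Completeness statistics over all measurements (no exclusions)."""
    ages = [(rec, age) for rec in records for age in rec.ages]
    n_ages = len(ages)
    rc = [a for _, a in ages if a.age_type == "14C"]
    charcoal = [a for a in rc if "charcoal" in a.material.lower()]
    bone = [a for a in rc if "bone" in a.material.lower() or "collagen" in a.material.lower()]
    cn_rep = [a for a in bone if a.cn_ratio is not None]
    cn_in = [a for a in cn_rep if cn_range[0] <= a.cn_ratio <= cn_range[1]]
    per_country: dict[str, int] = {}
    per_province: dict[str, int] = {}
    for rec, _ in ages:
        if rec.country:
            per_country[rec.country] = per_country.get(rec.country, 0) + 1
        per_province[rec.province] = per_province.get(rec.province, 0) + 1

    def pct(num: int, den: int) -> float:
        return 100.0 * num / den if den else 0.0

    return DatabaseSummary(
        n_sites=len({rec.site for rec in records}),
        n_ages=n_ages,
        pct_radiocarbon=pct(len(rc), n_ages),
        pct_charcoal=pct(len(charcoal), len(rc)),
        pct_charcoal_species_unreported=pct(
            sum(1 for a in charcoal if not a.species), len(charcoal)
        ),
        pct_cn_reported=pct(len(cn_rep), len(bone)),
        n_cn_reported=len(cn_rep),
        n_cn_in_range=len(cn_in),
        per_country=per_country,
        per_province=per_province,
    )


# ---------------------------------------------------------------------------
# LAD comparison


def lad_comparison(
    lads: dict[str, CalendarPDF | float],
    exploitation_start: CalendarPDF,
    resolution: float = DEFAULT_RESOLUTION,
) -> dict:
    """Descriptive comparison of faunal last-appearance dates with the
    estimated start of human exploitation.

    LADs are terminus post quem ages for extinction while the start
    estimate is a modelled onset of activity; the gap distributions are
    reported descriptively, not as a causal test.
    """
    if len(lads) < 2:
        raise ValueError("need at least 2 last-appearance dates")
    values = []
    pdf_map: dict[str, CalendarPDF] = {}
    for genus, lad in lads.items():
        if isinstance(lad, CalendarPDF):
            pdf_map[genus] = lad
            values.append(lad.median())
        else:
            v = float(lad)
            g = math.floor(v / resolution) * resolution
            pdf_map[genus] = CalendarPDF(
                np.array([g]), np.array([1.0]), resolution=resolution, label=genus
            )
            values.append(v)
    kde = kde_plot(values, resolution=resolution)
    gaps = {}
    for genus, pdf in pdf_map.items():
        diff, p_pos = difference(pdf, exploitation_start)
        gaps[genus] = {
            "gap_mean": diff.mean(),
            "p_lad_older_than_start": p_pos,
        }
    return {
        "kde": kde,
        "mean": kde.mean(),
        "median": kde.median(),
        "per_genus": gaps,
        "note": "descriptive comparison: LADs and modelled start estimates are different temporal markers",
    }


# ---------------------------------------------------------------------------
# orchestration


@dataclass
class TimelineResult:
    site_stage: SiteStageResult
    categories: dict[str, dict[str, CategoryModelResult]]
    summary_kde: object | None  # KDEResult over all interval-aged components
    db_summary: DatabaseSummary
    n_components_included: int
    skipped_categories: list[str] = field(default_factory=list)


def run_timeline(
    records: list[ComponentRecord],
    curves: dict[str, CalibrationCurve],
    config: PipelineConfig,
    with_kde: bool = True,
) -> TimelineResult:
    """Full analysis: curves, site models, category starts, KDE summary."""
    assign_curves(records, config)
    stage = run_site_stage(records, curves, config)
    sets = build_category_sets(records, stage.component_pdfs, config)
    included = {
        key for key in stage.component_pdfs
        if in_window(stage.component_pdfs[key], config)
    }
    categories: dict[str, dict[str, CategoryModelResult]] = {}
    skipped_cats: list[str] = []
    for facet, groups in sets.items():
        categories[facet] = {}
        for cat, pdfs in sorted(groups.items()):
            if len(pdfs) < config.min_category_size:
                skipped_cats.append(f"{facet}:{cat} (n={len(pdfs)})")
                logger.info("category %s/%s skipped: n=%d", facet, cat, len(pdfs))
                continue
            categories[facet][cat] = integrate_category(pdfs, cat, config)
    summary_kde = None
    if with_kde and len(included) >= 2:
        pdfs = [stage.component_pdfs[k] for k in sorted(included)]
        summary_kde = kde_model(
            pdfs,
            seed=_site_seed(config.seed, "summary-kde"),
            resolution=config.grid_resolution,
        )
    db_summary = summarize_database(records, cn_range=config.cn_range)
    return TimelineResult(
        site_stage=stage,
        categories=categories,
        summary_kde=summary_kde,
        db_summary=db_summary,
        n_components_included=len(included),
        skipped_categories=skipped_cats,
    )
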