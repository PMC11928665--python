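"""Chronological model trees: sequences, phases, boundaries, events, outliers.

A site chronology is a tree whose leaves are dated events and whose
structure encodes prior knowledge: a Phase groups events that are
exchangeable (uniform between a start and end Boundary), a Sequence orders
its children oldest to youngest.  A Boundary-Boundary pair around a Phase
yields the uniform-phase model in which all events are equally likely
between the boundaries, and the boundaries themselves estimate the start
and end of the activity they bracket.

Automatic model construction for a site follows three rules:

1. several stratigraphic levels, each dated, with a known ordering ->
   multi-phase sequence (one phase per level, boundaries shared between
   consecutive levels), every date carrying a General outlier term and
   replicate measurements pooled first;
2. at least two dates but no usable stratigraphy -> a single uniform phase;
3. exactly one dated cultural event -> no model, the calibrated
   measurement itself stands for the component.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace
from typing import Iterator

import numpy as np
from scipy import stats

from .calcurve import CalendarPDF, Determination

__all__ = [
    "ModelNode",
    "ModelSpec",
    "OutlierSpec",
    "CombinedDetermination",
    "SiteComponent",
    "SiteRecord",
    "SiteSkipped",
    "r_combine",
    "validate_model",
    "site_model_from_record",
    "sequence",
    "phase",
    "boundary",
    "event",
    "date_query",
    "model_to_text",
    "model_from_text",
]

DEFAULT_OUTLIER_PRIOR = 0.05


class SiteSkipped(RuntimeError):
    """Raised when a site has no usable dated event; carries the reason."""


@dataclass(frozen=True)
class OutlierSpec:
    """Outlier mixture term attached to one dated event.

    ``general`` shifts the event on the calendar scale with a Student-t
    (5 df) shift whose scale is 10^u years, u ~ U(0, 4); ``ssimple`` shifts
    the measurement by a N(0,1) multiple of its own sigma.  ``prior_prob``
    is the prior probability that the shift is active.
    """

    preset: str = "general"  # {general, ssimple}
    prior_prob: float = DEFAULT_OUTLIER_PRIOR
    scale_log10_range: tuple[float, float] = (0.0, 4.0)

    def __post_init__(self) -> None:
        if self.preset not in ("general", "ssimple"):
            raise ValueError(f"unknown outlier preset {self.preset!r}")
        if not 0.0 < self.prior_prob < 1.0:
            raise ValueError("outlier prior_prob must be in (0, 1)")


@dataclass
class ModelNode:
    kind: str  # {sequence, phase, boundary, event, date_query}
    label: str = ""
    children: list["ModelNode"] = field(default_factory=list)
    determination: Determination | None = None
    prior_pdf: CalendarPDF | None = None
    outlier: OutlierSpec | None = None
    cultural: bool = True  # False for sediment/geological terminus events

    def walk(self) -> Iterator["ModelNode"]:
        yield self
        for c in self.children:
            yield from c.walk()


def sequence(label: str, *children: ModelNode) -> ModelNode:
    return ModelNode("sequence", label, list(children))


def phase(label: str, *children: ModelNode) -> ModelNode:
    return ModelNode("phase", label, list(children))


def boundary(label: str) -> ModelNode:
    return ModelNode("boundary", label)


def event(
    label: str,
    determination: Determination | None = None,
    prior_pdf: CalendarPDF | None = None,
    outlier: OutlierSpec | None = None,
    cultural: bool = True,
) -> ModelNode:
    if determination is not None and prior_pdf is not None:
        raise ValueError(f"event {label!r}: at most one likelihood source")
    return ModelNode(
        "event",
        label,
        determination=determination,
        prior_pdf=prior_pdf,
        outlier=outlier,
        cultural=cultural,
    )


def date_query(label: str) -> ModelNode:
    """Undated age query for a cultural unit: the posterior of a generic
    event uniform within the enclosing phase (no feedback on the model)."""
    return ModelNode("date_query", label)


@dataclass
class ModelSpec:
    """A site or category model plus bookkeeping for the pipeline."""

    site: str
    rule: int  # 1, 2 for modelled sites; 3 for single-date passthrough
    root: ModelNode | None
    passthrough: Determination | None = None  # rule 3
    notes: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# replicate combination


@dataclass(frozen=True)
class CombinedDetermination:
    """Inverse-variance pool of replicate measurements with a chi-square
    consistency test (5% criterion on the T statistic, n-1 df)."""

    cra: float
    sigma: float
    t_stat: float
    df: int
    passed: bool
    lab_ids: tuple[str, ...] = ()

    def as_determination(self, template: Determination, label: str = "") -> Determination:
        return replace(
            template,
            lab_id=label or "+".join(self.lab_ids),
            cra=self.cra,
            sigma=self.sigma,
        )


def r_combine(dets: list[Determination]) -> CombinedDetermination:
    """Pool replicate measurements of one sample.

    cra is the inverse-variance weighted mean, sigma the pooled error
    (sum sigma_i^-2)^-1/2, and T = sum (x_i - cra)^2 / sigma_i^2 is compared
    with the upper 5% chi-square quantile at n-1 degrees of freedom.
    """
    if len(dets) < 2:
        raise ValueError("r_combine needs at least 2 determinations")
    keys = {(d.curve_key, d.reservoir) for d in dets}
    if len(keys) > 1:
        raise ValueError("r_combine requires a common curve/reservoir assignment")
    w = np.array([1.0 / d.sigma**2 for d in dets])
    x = np.array([d.cra for d in dets])
    cra = float(np.dot(w, x) / w.sum())
    sigma = float(1.0 / math.sqrt(w.sum()))
    t_stat = float(np.dot(w, (x - cra) ** 2))
    df = len(dets) - 1
    crit = float(stats.chi2.ppf(0.95, df))
    return CombinedDetermination(
        cra=cra,
        sigma=sigma,
        t_stat=t_stat,
        df=df,
        passed=t_stat <= crit,
        lab_ids=tuple(d.lab_id for d in dets),
    )


# ---------------------------------------------------------------------------
# validation


def validate_model(root: ModelNode) -> list[str]:
    """Structural checks; returns human-readable violations (empty = valid)."""
    violations: list[str] = []
    seen_events: set[str] = set()

    def visit(node: ModelNode, parent: ModelNode | None) -> None:
        if node.kind == "sequence":
            if not node.children:
                violations.append(f"sequence {node.label!r} is empty")
            kinds = [c.kind for c in node.children]
            for i, child in enumerate(node.children):
                if child.kind == "phase":
                    if "boundary" not in kinds[:i] or "boundary" not in kinds[i + 1 :]:
                        violations.append(
                            f"phase {child.label!r} is not boundary-delimited in sequence {node.label!r}"
                        )
        elif node.kind == "phase":
            if parent is None or parent.kind != "sequence":
                violations.append(f"phase {node.label!r} has no enclosing sequence")
            for child in node.children:
                if child.kind not in ("event", "date_query"):
                    violations.append(
                        f"phase {node.label!r} contains a {child.kind!r} node"
                    )
        elif node.kind == "event":
            if node.determination is not None and node.prior_pdf is not None:
                violations.append(f"event {node.label!r} has two likelihood sources")
            if node.label in seen_events:
                violations.append(f"event label {node.label!r} appears twice")
            seen_events.add(node.label)
            if node.outlier is not None and node.determination is None and node.prior_pdf is None:
                violations.append(
                    f"outlier attached to undated event {node.label!r}"
                )
        elif node.kind == "boundary":
            if parent is None or parent.kind != "sequence":
                violations.append(f"boundary {node.label!r} outside a sequence")
        for child in node.children:
            visit(child, node)

    visit(root, None)
    return violations


# ---------------------------------------------------------------------------
# site records and automatic model construction


@dataclass
class SiteComponent:
    """One dated unit (cultural component or sediment constraint) at a site."""

    component_id: str
    layer: str = ""
    layer_index: int | None = None  # stratigraphic rank; larger = older
    cultural: bool = True
    determinations: list[Determination] = field(default_factory=list)
    sample_ids: list[str] = field(default_factory=list)  # replicate grouping


@dataclass
class SiteRecord:
    name: str
    components: list[SiteComponent] = field(default_factory=list)


def _pool_replicates(comp: SiteComponent) -> list[tuple[Determination, OutlierSpec]]:
    """Combine determinations sharing a sample id; attach outlier terms.

    Pooled replicates keep an SSimple outlier term (shift in measurement
    units); singleton dates get the General calendar-scale term.
    """
    groups: dict[str, list[Determination]] = {}
    order: list[str] = []
    for i, det in enumerate(comp.determinations):
        sid = comp.sample_ids[i] if i < len(comp.sample_ids) and comp.sample_ids[i] else f"__solo_{i}"
        if sid not in groups:
            groups[sid] = []
            order.append(sid)
        groups[sid].append(det)
    out: list[tuple[Determination, OutlierSpec]] = []
    for sid in order:
        dets = groups[sid]
        if len(dets) == 1:
            out.append((dets[0], OutlierSpec("general")))
        else:
            comb = r_combine(dets)
            pooled = comb.as_determination(dets[0])
            out.append((pooled, OutlierSpec("ssimple")))
    return out


def site_model_from_record(site: SiteRecord, outlier_prior: float = DEFAULT_OUTLIER_PRIOR) -> ModelSpec:
    """Build the site model under the three construction rules.

    Raises :class:`SiteSkipped` when the site carries no usable
    (non-sediment) determination.
    """
    cultural = [c for c in site.components if c.cultural and c.determinations]
    sediment = [c for c in site.components if not c.cultural and c.determinations]
    if not cultural:
        raise SiteSkipped(f"{site.name}: no cultural determination")

    def events_for(comp: SiteComponent) -> list[ModelNode]:
        nodes = []
        for i, (det, ospec) in enumerate(_pool_replicates(comp)):
            ospec = replace(ospec, prior_prob=outlier_prior)
            nodes.append(
                event(f"{comp.component_id}:{det.lab_id or i}", determination=det,
                      outlier=ospec, cultural=comp.cultural)
            )
        return nodes

    dated = cultural + sediment
    n_dates = sum(len(c.determinations) for c in cultural)
    layers = {c.layer for c in dated if c.layer}
    ordered = (
        len(layers) >= 2
        and all(c.layer and c.layer_index is not None for c in dated)
        and len({c.layer_index for c in dated if c.layer}) >= 2
    )

    if ordered:
        # rule 1: one phase per stratigraphic level, oldest level first
        by_layer: dict[tuple[int, str], list[SiteComponent]] = {}
        for c in dated:
            by_layer.setdefault((-c.layer_index, c.layer), []).append(c)
        children: list[ModelNode] = [boundary(f"{site.name}/start")]
        last_key = None
        for j, (key, comps) in enumerate(sorted(by_layer.items())):
            layer_label = key[1]
            ph = phase(f"{site.name}/{layer_label}")
            for c in comps:
                ph.children.extend(events_for(c))
                if c.cultural:
                    ph.children.append(date_query(f"{site.name}/{c.component_id}"))
            children.append(ph)
            children.append(boundary(f"{site.name}/after_{layer_label}"))
            last_key = key
        children[-1].label = f"{site.name}/end"
        return ModelSpec(site.name, 1, sequence(site.name, *children))

    if n_dates >= 2:
        # rule 2: a single uniform phase over every date
        ph = phase(f"{site.name}/all")
        for c in dated:
            ph.children.extend(events_for(c))
            if c.cultural:
                ph.children.append(date_query(f"{site.name}/{c.component_id}"))
        root = sequence(
            site.name, boundary(f"{site.name}/start"), ph, boundary(f"{site.name}/end")
        )
        notes = []
        if len(layers) >= 2:
            notes.append("partial stratigraphy ignored: no total layer order")
        return ModelSpec(site.name, 2, root, notes=notes)

    # rule 3: single measurement, no site model
    comp = cultural[0]
    pooled = _pool_replicates(comp)
    det = pooled[0][0]
    return ModelSpec(site.name, 3, None, passthrough=det)


# ---------------------------------------------------------------------------
# text serialisation (CQL-flavoured, not byte-compatible)


def _emit(node: ModelNode, lines: list[str], indent: int) -> None:
    pad = "  " * indent
    if node.kind == "sequence":
        lines.append(f'{pad}Sequence("{node.label}") {{')
        for c in node.children:
            _emit(c, lines, indent + 1)
        lines.append(f"{pad}}}")
    elif node.kind == "phase":
        lines.append(f'{pad}Phase("{node.label}") {{')
        for c in node.children:
            _emit(c, lines, indent + 1)
        lines.append(f"{pad}}}")
    elif node.kind == "boundary":
        lines.append(f'{pad}Boundary("{node.label}")')
    elif node.kind == "date_query":
        lines.append(f'{pad}Date("{node.label}")')
    elif node.kind == "event":
        parts = []
        if node.determination is not None:
            d = node.determination
            parts.append(f'R_Date("{node.label}", {d.cra:g}, {d.sigma:g})')
        elif node.prior_pdf is not None:
            p = node.prior_pdf
            vals = " ".join(f"{v:.10g}" for v in p.mass)
            parts.append(
                f'P_Date("{node.label}", {p.grid[0]:g}, {p.resolution:g}, [{vals}])'
            )
        else:
            parts.append(f'Event("{node.label}")')
        if node.outlier is not None:
            o = node.outlier
            parts.append(f'Outlier("{o.preset}", {o.prior_prob:g})')
        if not node.cultural:
            parts.append("NonCultural()")
        lines.append(pad + " ".join(parts))


def model_to_text(root: ModelNode) -> str:
    lines: list[str] = []
    _emit(root, lines, 0)
    return "\n".join(lines) + "\n"


_LINE_RE = re.compile(r'^(\w+)\("([^"]*)"(?:,\s*([^)]*))?\)')


def model_from_text(text: str) -> ModelNode:
    """Parse the serialisation produced by :func:`model_to_text`."""
    stack: list[ModelNode] = []
    root: ModelNode | None = None
    for raw in text.splitlines():
        line = raw.strip()
        if not line:
            continue
        if line == "}":
            node = stack.pop()
            if not stack:
                root = node
            continue
        m = _LINE_RE.match(line)
        if not m:
            raise ValueError(f"cannot parse model line: {line!r}")
        cmd, label, args = m.group(1), m.group(2), m.group(3)
        if cmd in ("Sequence", "Phase"):
            node = ModelNode(cmd.lower(), label)
            if stack:
                stack[-1].children.append(node)
            stack.append(node)
            continue
        if cmd == "Boundary":
            node = boundary(label)
        elif cmd == "Date":
            node = date_query(label)
        elif cmd == "R_Date":
            cra, sig = (float(a) for a in args.split(","))
            node = event(label, determination=Determination(label, cra, sig))
        elif cmd == "P_Date":
            start_s, res_s, rest = args.split(",", 2)
            vals = np.array([float(v) for v in rest.strip(" []").split()])
            res = float(res_s)
            grid = float(start_s) + res * np.arange(vals.size)
            node = event(label, prior_pdf=CalendarPDF(grid, vals / vals.sum(), resolution=res, label=label))
        elif cmd == "Event":
            node = event(label)
        else:
            raise ValueError(f"unknown model command {cmd!r}")
        # trailing modifiers on the same line
        om = re.search(r'Outlier\("(\w+)",\s*([0-9.eE+-]+)\)', line)
        if om:
            node.outlier = OutlierSpec(om.group(1), float(om.group(2)))
        if "NonCultural()" in line:
            node.cultural = False
        if stack:
            stack[-1].children.append(node)
        else:
            root = node
    if root is None:
        raise ValueError("empty model text")
    return root
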