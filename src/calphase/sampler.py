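"""Metropolis-within-Gibbs sampling of uniform-phase chronological models.

The posterior over boundary ages a_k, event ages t_i, outlier shifts
delta_i (with activation indicators z_i) and per-determination curve-mixing
fractions m_i is

    p ~ prod_i L_i(x_i | t_i, z_i, delta_i, m_i)
        * prod_phases (a - b)^-(n - s) * 1[order constraints]
        * prod_i p_out(z_i, delta_i) * 1[boundaries within the model range]

where n is the number of sampled events in a phase and s = 1 under the
standard uniform-span construction (events i.i.d. uniform between their
boundaries with the group span itself uniform a priori) or s = 0 under the
naive variant.  All updates are single-parameter moves: symmetric
random-walk Metropolis for continuous parameters, exact prior redraws for
outlier shifts while inactive, and indicator flips for activation.

Ages are cal BP throughout (larger = older); within a sequence, boundary
ages decrease from the start boundary to the end boundary and every phase
event lies between its two delimiting boundaries in every retained sample.
"""

from __future__ import annotations

import json
import math
import zlib
from bisect import bisect_right
from dataclasses import dataclass
from typing import TextIO

import numpy as np

from .calcurve import (
    DEFAULT_RESOLUTION,
    CalendarPDF,
    CalibrationCurve,
    calibrate,
    mix_calibration,
)
from .model_spec import ModelNode, validate_model

__all__ = [
    "SamplerSettings",
    "Trace",
    "ConvergenceReport",
    "InitialisationError",
    "sample_posterior",
    "check_convergence",
    "posterior_pdf",
]

_NEG_INF = float("-inf")
_LOG10 = math.log(10.0)
# standard Student-t log-density constant for 5 degrees of freedom
_T5_CONST = math.lgamma(3.0) - math.lgamma(2.5) - 0.5 * math.log(5.0 * math.pi)
HARD_CAP = 2**20


class InitialisationError(RuntimeError):
    """Raised when no valid starting state exists (empty constraint support)."""


@dataclass
class SamplerSettings:
    """MCMC protocol settings.

    ``initial_iterations`` retained iterations are run first (default
    30,000), convergence is then checked every ``pass_length`` iterations
    (default 3,000) with the pass interval doubling until the overlap
    criterion exceeds ``convergence_threshold``.  ``burn_in`` iterations of
    proposal-scale adaptation are run before retention begins and
    discarded; scales are frozen afterwards.
    """

    initial_iterations: int = 30000
    pass_length: int = 3000
    pass_interval_growth: float = 2.0
    convergence_threshold: float = 0.95
    seed: int = 1
    thinning: int = 1
    burn_in: int = 3000
    span_prior: str = "standard"  # {standard, naive}
    range_padding: float | None = None  # cal BP; default scales with data span
    grid_resolution: float = DEFAULT_RESOLUTION

    def __post_init__(self) -> None:
        for name in ("initial_iterations", "pass_length", "thinning", "burn_in"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 < self.convergence_threshold < 1.0:
            raise ValueError("convergence_threshold must be in (0, 1)")
        if self.span_prior not in ("standard", "naive"):
            raise ValueError("span_prior must be 'standard' or 'naive'")


@dataclass
class ConvergenceReport:
    per_parameter: dict[str, float]
    overall: float
    passes_run: int
    converged: bool
    iterations: int


@dataclass
class Trace:
    """Posterior samples plus the bookkeeping needed for queries."""

    names: list[str]  # boundary labels then event labels
    samples: np.ndarray  # (n_retained, n_boundaries + n_events), cal BP
    n_boundaries: int
    z_names: list[str]
    z_samples: np.ndarray  # (n_retained, n_outlier_events) {0,1}
    delta_samples: np.ndarray  # outlier shifts (yr or sigma units)
    m_names: list[str]
    m_samples: np.ndarray  # mixing fractions in [0,1]
    query_map: dict[str, tuple[int, int]]  # date-query label -> boundary cols
    seed: int
    settings: SamplerSettings
    convergence: ConvergenceReport | None = None

    def column(self, label: str) -> np.ndarray:
        return self.samples[:, self.names.index(label)]

    def outlier_activation(self) -> dict[str, float]:
        return {
            name: float(self.z_samples[:, j].mean())
            for j, name in enumerate(self.z_names)
        }

    def query_samples(self, label: str) -> np.ndarray:
        """Posterior draws for a Date query: a generic event uniform within
        its phase, drawn per retained iteration (deterministic per seed)."""
        hi_col, lo_col = self.query_map[label]
        hi = self.samples[:, hi_col]
        lo = self.samples[:, lo_col]
        rng = np.random.default_rng([self.seed, 0x5EED, zlib.crc32(label.encode())])
        return lo + (hi - lo) * rng.random(hi.size)

    def export_csv(self, stream: TextIO) -> None:
        stream.write("iteration,parameter,value\n")
        for j, name in enumerate(self.names):
            col = self.samples[:, j]
            for it, v in enumerate(col):
                stream.write(f"{it},{name},{v:.6f}\n")

    def manifest(self) -> dict:
        conv = None
        if self.convergence is not None:
            conv = {
                "overall": self.convergence.overall,
                "passes_run": self.convergence.passes_run,
                "converged": self.convergence.converged,
                "iterations": self.convergence.iterations,
            }
        return {
            "seed": self.seed,
            "n_retained": int(self.samples.shape[0]),
            "parameters": self.names,
            "settings": {
                "initial_iterations": self.settings.initial_iterations,
                "pass_length": self.settings.pass_length,
                "span_prior": self.settings.span_prior,
                "burn_in": self.settings.burn_in,
            },
            "convergence": conv,
        }


class _RngBuf:
    """Buffered scalar draws from one numpy Generator (deterministic order)."""

    def __init__(self, rng: np.random.Generator, block: int = 8192) -> None:
        self.rng = rng
        self.block = block
        self._n: list[float] = []
        self._u: list[float] = []
        self._t: list[float] = []
        self._ni = self._ui = self._ti = 0

    def normal(self) -> float:
        if self._ni == len(self._n):
            self._n = self.rng.standard_normal(self.block).tolist()
            self._ni = 0
        v = self._n[self._ni]
        self._ni += 1
        return v

    def uniform(self) -> float:
        if self._ui == len(self._u):
            self._u = self.rng.random(self.block).tolist()
            self._ui = 0
        v = self._u[self._ui]
        self._ui += 1
        return v

    def t5(self) -> float:
        if self._ti == len(self._t):
            self._t = self.rng.standard_t(5, self.block).tolist()
            self._ti = 0
        v = self._t[self._ti]
        self._ti += 1
        return v


def _t5_logpdf(x: float) -> float:
    return _T5_CONST - 3.0 * math.log1p(x * x / 5.0)


class _Compiled:
    """Flattened model state and update machinery."""

    def __init__(
        self,
        root: ModelNode,
        curves: dict[str, CalibrationCurve],
        settings: SamplerSettings,
    ) -> None:
        violations = validate_model(root)
        if violations:
            raise ValueError("invalid model: " + "; ".join(violations))
        if root.kind != "sequence":
            raise ValueError("top-level node must be a sequence")
        self.settings = settings
        self.res = settings.grid_resolution
        self.span_floor = self.res
        self.span_corr = 1.0 if settings.span_prior == "standard" else 0.0

        self.b_labels: list[str] = []
        self.e_labels: list[str] = []
        self.etype: list[int] = []  # 0 none, 1 det, 2 det-mixed, 3 pdf
        self.x: list[float] = []
        self.sig: list[float] = []
        self.curve_a: list[CalibrationCurve | None] = []
        self.curve_b: list[CalibrationCurve | None] = []
        self.pdfdata: list[tuple[list[float], list[float]] | None] = []
        self.otype: list[int] = []  # 0 none, 1 general, 2 ssimple
        self.oprior: list[float] = []
        self.e_phase: list[int] = []
        self.phase_hi: list[int] = []  # boundary index (older side) per phase
        self.phase_lo: list[int] = []
        self.phase_events: list[list[int]] = []
        self.queries: list[tuple[str, int]] = []  # (label, phase index)
        self.init_med: list[float] = []
        self.init_sd: list[float] = []

        pending_phase_nodes: list[tuple[ModelNode, int]] = []
        loose_events: list[ModelNode] = []
        for child in root.children:
            if child.kind == "boundary":
                self.b_labels.append(child.label)
            elif child.kind == "phase":
                hi = len(self.b_labels) - 1
                if hi < 0:
                    raise ValueError(f"phase {child.label!r} lacks a start boundary")
                pidx = len(self.phase_hi)
                self.phase_hi.append(hi)
                self.phase_lo.append(hi + 1)  # next boundary to come
                self.phase_events.append([])
                pending_phase_nodes.append((child, pidx))
            elif child.kind == "event":
                loose_events.append(child)  # unconstrained, likelihood only
            else:
                raise ValueError(f"unsupported top-level node kind {child.kind!r}")
        for pidx, lo in enumerate(self.phase_lo):
            if lo >= len(self.b_labels):
                raise ValueError("phase lacks a closing boundary")

        leaves: list[tuple[ModelNode, int]] = [(lf, -1) for lf in loose_events]
        for node, pidx in pending_phase_nodes:
            for leaf in node.children:
                if leaf.kind == "date_query":
                    self.queries.append((leaf.label, pidx))
                    continue
                leaves.append((leaf, pidx))
        for leaf, pidx in leaves:
            eidx = len(self.e_labels)
            self.e_labels.append(leaf.label)
            self.e_phase.append(pidx)
            if pidx >= 0:
                self.phase_events[pidx].append(eidx)
            if leaf.determination is not None:
                det = leaf.determination
                if det.reservoir == "mixed_hemispheric":
                    try:
                        ka, kb = det.curve_key.split("+")
                        ca, cb = curves[ka], curves[kb]
                    except (ValueError, KeyError):
                        raise KeyError(
                            f"mixed determination {det.lab_id!r} needs curve_key 'a+b' "
                            f"with both registered"
                        ) from None
                    self.etype.append(2)
                    self.curve_a.append(ca)
                    self.curve_b.append(cb)
                    self.pdfdata.append(None)
                    med_pdf = mix_calibration(det, ca, cb, self.res, n_quad=21)
                else:
                    key = det.curve_key or "default"
                    if key not in curves:
                        raise KeyError(f"curve {key!r} not registered for {det.lab_id!r}")
                    cv = curves[key]
                    self.etype.append(1)
                    self.curve_a.append(cv)
                    self.curve_b.append(None)
                    self.pdfdata.append(None)
                    med_pdf = calibrate(det, cv, self.res)
                self.x.append(float(det.cra))
                self.sig.append(float(det.sigma))
                self.init_med.append(med_pdf.median())
                self.init_sd.append(max(med_pdf.sd(), self.res))
            elif leaf.prior_pdf is not None:
                p = leaf.prior_pdf
                self.etype.append(3)
                self.curve_a.append(None)
                self.curve_b.append(None)
                with np.errstate(divide="ignore"):
                    logm = np.log(p.mass)
                logm = np.maximum(logm, -745.0)
                self.pdfdata.append((p.grid.tolist(), logm.tolist()))
                self.x.append(0.0)
                self.sig.append(1.0)
                self.init_med.append(p.median())
                self.init_sd.append(max(p.sd(), self.res))
            else:
                self.etype.append(0)
                self.curve_a.append(None)
                self.curve_b.append(None)
                self.pdfdata.append(None)
                self.x.append(0.0)
                self.sig.append(1.0)
                self.init_med.append(math.nan)
                self.init_sd.append(self.res * 10)
            if leaf.outlier is not None:
                self.otype.append(
                    1 if leaf.outlier.preset == "general" else 2
                )
                self.oprior.append(leaf.outlier.prior_prob)
            else:
                self.otype.append(0)
                self.oprior.append(0.0)

        self.nb = len(self.b_labels)
        self.ne = len(self.e_labels)
        self.np_ = len(self.phase_hi)
        if self.np_ > 0 and self.nb < 2:
            raise ValueError("phased models need at least a start and an end boundary")
        self.phase_exponent = [
            max(len(ev) - self.span_corr, 0.0) for ev in self.phase_events
        ]
        self.out_events = [i for i in range(self.ne) if self.otype[i] != 0]
        self.mixed_events = [i for i in range(self.ne) if self.etype[i] == 2]
        # boundary adjacency: phase above (boundary is its lower edge) and
        # phase below (boundary is its upper edge)
        self.b_phase_above: list[int | None] = [None] * self.nb
        self.b_phase_below: list[int | None] = [None] * self.nb
        for p in range(self.np_):
            self.b_phase_below[self.phase_hi[p]] = p
            self.b_phase_above[self.phase_lo[p]] = p

        self._init_state()
        self._init_scales()

    # -- state initialisation ---------------------------------------------
    def _init_state(self) -> None:
        meds = self.init_med
        finite = [m for m in meds if not math.isnan(m)]
        if not finite:
            lo_d, hi_d = 0.0, 10000.0
        else:
            lo_d, hi_d = min(finite), max(finite)
        pad = self.settings.range_padding
        if pad is None:
            pad = max(1000.0, 0.5 * (hi_d - lo_d))
        self.range_lo = lo_d - pad
        self.range_hi = hi_d + pad

        # per-phase median windows (fall back to neighbours for undated phases)
        ph_hi = [None] * self.np_
        ph_lo = [None] * self.np_
        for p in range(self.np_):
            ms = [meds[i] for i in self.phase_events[p] if not math.isnan(meds[i])]
            if ms:
                ph_hi[p], ph_lo[p] = max(ms), min(ms)
        span_guess = max((hi_d - lo_d) / max(self.np_, 1), 10 * self.res)
        cursor = hi_d
        for p in range(self.np_):
            if ph_hi[p] is None:
                ph_hi[p], ph_lo[p] = cursor, cursor - span_guess
            cursor = ph_lo[p] - span_guess
        # boundary positions: start above the oldest, then descending
        eps = max(self.span_floor, self.res)
        B = [0.0] * self.nb
        if self.nb:
            anchor = ph_hi[0] if ph_hi else hi_d
            B[0] = min(anchor + eps, self.range_hi)
        for k in range(1, self.nb):
            above = self.b_phase_above[k]
            below = self.b_phase_below[k]
            cands = []
            if above is not None:
                cands.append(ph_lo[above] - eps)
            if below is not None:
                cands.append(ph_hi[below] + eps)
            val = sum(cands) / len(cands) if cands else B[k - 1] - eps
            B[k] = min(val, B[k - 1] - eps)
        if self.nb:
            if B[-1] < self.range_lo:
                self.range_lo = B[-1] - eps
            if B[0] > self.range_hi:
                self.range_hi = B[0] + eps
        self.B = B
        # events clipped strictly inside their phase window
        t = [0.0] * self.ne
        for i in range(self.ne):
            p = self.e_phase[i]
            if p < 0:  # unconstrained event
                m0 = meds[i]
                t[i] = 0.5 * (hi_d + lo_d) if math.isnan(m0) else m0
                continue
            hi = self.B[self.phase_hi[p]]
            lo = self.B[self.phase_lo[p]]
            if hi - lo < self.span_floor:
                raise InitialisationError(
                    f"phase {p} has empty support between boundaries "
                    f"{self.b_labels[self.phase_hi[p]]!r} and {self.b_labels[self.phase_lo[p]]!r}"
                )
            margin = 0.25 * (hi - lo)
            m0 = meds[i]
            if math.isnan(m0):
                m0 = 0.5 * (hi + lo)
            t[i] = min(max(m0, lo + min(margin, eps)), hi - min(margin, eps))
        self.t = t
        self.z = [0] * self.ne
        self.delta = [0.0] * self.ne
        self.u = [1.0] * self.ne  # log10 outlier scale (general preset)
        self.m = [0.5] * self.ne  # mixing fraction (mixed-curve events)
        self.cur_ll = [0.0] * self.ne
        for i in range(self.ne):
            ll = self._ll(i, self.t[i], self.z[i], self.delta[i], self.m[i])
            if ll == _NEG_INF:
                # nudge onto the nearest supported age
                tgt = meds[i]
                if not math.isnan(tgt):
                    self.t[i] = tgt
                    ll = self._ll(i, tgt, self.z[i], self.delta[i], self.m[i])
            if ll == _NEG_INF:
                raise InitialisationError(
                    f"event {self.e_labels[i]!r} has no support inside its phase"
                )
            self.cur_ll[i] = ll

    def _init_scales(self) -> None:
        self.e_scale = [max(s, self.res) for s in self.init_sd]
        span = max((self.range_hi - self.range_lo) / 20.0, self.res)
        self.b_scale = [
            max(min(span, 4.0 * max(self.init_sd + [self.res])), self.res)
            for _ in range(self.nb)
        ]
        self.d_scale = [1.0] * self.ne  # multiplies the active outlier scale
        self.m_scale = 0.2
        self.u_scale = 0.4
        self.jump_scale = max(4.0 * self.res, 20.0)  # exp proposal scale (yr)
        self._acc = {}
        self._prop = {}

    # -- likelihood ---------------------------------------------------------
    def _ll(self, i: int, t: float, z: int, d: float, m: float) -> float:
        et = self.etype[i]
        if et == 0:
            return 0.0
        ot = self.otype[i]
        if et == 3:
            if z and ot == 1:
                t = t + d
            grid, logm = self.pdfdata[i]
            if t < grid[0] or t > grid[-1]:
                return _NEG_INF
            if len(grid) == 1:
                return logm[0]
            j = bisect_right(grid, t)
            if j == len(grid):
                j -= 1
            g0, g1 = grid[j - 1], grid[j]
            w = (t - g0) / (g1 - g0)
            return logm[j - 1] + w * (logm[j] - logm[j - 1])
        x = self.x[i]
        sig = self.sig[i]
        if z:
            if ot == 1:
                t = t + d
            elif ot == 2:
                x = x - d * sig
        if et == 1:
            r = self.curve_a[i].lookup_scalar(t)
            if r is None:
                return _NEG_INF
            mu, sc = r
        else:
            ra = self.curve_a[i].lookup_scalar(t)
            rb = self.curve_b[i].lookup_scalar(t)
            if ra is None or rb is None:
                return _NEG_INF
            mu = m * ra[0] + (1.0 - m) * rb[0]
            sc = m * ra[1] + (1.0 - m) * rb[1]
        v = sig * sig + sc * sc
        dx = x - mu
        return -0.5 * dx * dx / v - 0.5 * math.log(v)

    def _boundary_move_dlp(self, k: int, v: float, exclude: int = -1) -> float | None:
        """Span-prior log-density change for moving boundary k to v, or None
        when v violates a constraint (optionally ignoring one event)."""
        B = self.B
        t = self.t
        hi = B[k - 1] if k > 0 else self.range_hi
        lo = B[k + 1] if k < self.nb - 1 else self.range_lo
        pa = self.b_phase_above[k]
        pb = self.b_phase_below[k]
        if pa is not None:
            for e in self.phase_events[pa]:
                if e != exclude and t[e] < hi:
                    hi = t[e]
        if pb is not None:
            for e in self.phase_events[pb]:
                if e != exclude and t[e] > lo:
                    lo = t[e]
        if v < lo or v > hi:
            return None
        dlp = 0.0
        floor = self.span_floor
        if pa is not None:
            old_span = B[self.phase_hi[pa]] - B[k]
            new_span = B[self.phase_hi[pa]] - v
            if new_span < floor:
                return None
            dlp -= self.phase_exponent[pa] * (math.log(new_span) - math.log(old_span))
        if pb is not None:
            old_span = B[k] - B[self.phase_lo[pb]]
            new_span = v - B[self.phase_lo[pb]]
            if new_span < floor:
                return None
            dlp -= self.phase_exponent[pb] * (math.log(new_span) - math.log(old_span))
        return dlp

    def _jump_move(self, i: int, buf: _RngBuf) -> None:
        """Joint boundary/outlier mode jump for a general-preset event.

        Deactivate & widen: an active shift whose effective age tau falls
        outside the phase is turned off by moving the offending boundary
        just past tau.  Activate & shrink (the exact reverse): an inactive
        event pinning the phase edge is flagged and the boundary pulled back
        to the remaining events.  Both preserve the likelihood, so the
        Hastings ratio involves only priors and proposal densities.
        """
        p = self.e_phase[i]
        if p < 0 or len(self.phase_events[p]) < 2:
            return
        B = self.B
        t = self.t
        pi = self.oprior[i]
        lam = self.jump_scale
        k_hi = self.phase_hi[p]
        k_lo = self.phase_lo[p]
        a = B[k_hi]
        b = B[k_lo]
        others = [t[e] for e in self.phase_events[p] if e != i]
        if self.z[i] == 1:
            tau = t[i] + self.delta[i]
            s = 10.0 ** self.u[i]
            if tau > a:
                a_new = tau + lam * (-math.log(buf.uniform()))
                dlp_span = self._boundary_move_dlp(k_hi, a_new, exclude=i)
                if dlp_span is None:
                    return
                m_hi = max(others)
                log_r = (
                    math.log((1.0 - pi) / pi)
                    + dlp_span
                    - math.log(a - b)
                    - (_t5_logpdf(self.delta[i] / s) - math.log(s))
                    + (a_new - tau) / lam
                    - (a - m_hi) / lam
                )
                if log_r >= 0.0 or (log_r > -700 and buf.uniform() < math.exp(log_r)):
                    B[k_hi] = a_new
                    t[i] = tau
                    self.z[i] = 0
                    u_d = 4.0 * buf.uniform()
                    self.u[i] = u_d
                    self.delta[i] = (10.0**u_d) * buf.t5()  # dormant
            elif tau < b:
                b_new = tau - lam * (-math.log(buf.uniform()))
                dlp_span = self._boundary_move_dlp(k_lo, b_new, exclude=i)
                if dlp_span is None:
                    return
                m_lo = min(others)
                log_r = (
                    math.log((1.0 - pi) / pi)
                    + dlp_span
                    - math.log(a - b)
                    - (_t5_logpdf(self.delta[i] / s) - math.log(s))
                    + (tau - b_new) / lam
                    - (m_lo - b) / lam
                )
                if log_r >= 0.0 or (log_r > -700 and buf.uniform() < math.exp(log_r)):
                    B[k_lo] = b_new
                    t[i] = tau
                    self.z[i] = 0
                    u_d = 4.0 * buf.uniform()
                    self.u[i] = u_d
                    self.delta[i] = (10.0**u_d) * buf.t5()  # dormant
            return
        # z == 0: activate & shrink when this event pins an edge
        tau = t[i]
        m_hi = max(others)
        m_lo = min(others)
        if tau > m_hi:
            a_new = m_hi + lam * (-math.log(buf.uniform()))
            if a_new >= tau:
                return
            dlp_span = self._boundary_move_dlp(k_hi, a_new, exclude=i)
            if dlp_span is None:
                return
            u_new = 4.0 * buf.uniform()
            s_new = 10.0**u_new
            t_new = b + (a_new - b) * buf.uniform()
            d_new = tau - t_new
            log_r = (
                math.log(pi / (1.0 - pi))
                + dlp_span
                + (_t5_logpdf(d_new / s_new) - u_new * _LOG10)
                + math.log(a_new - b)
                - (a - tau) / lam
                + (a_new - m_hi) / lam
            )
            if log_r >= 0.0 or (log_r > -700 and buf.uniform() < math.exp(log_r)):
                B[k_hi] = a_new
                t[i] = t_new
                self.z[i] = 1
                self.delta[i] = d_new
                self.u[i] = u_new
        elif tau < m_lo:
            b_new = m_lo - lam * (-math.log(buf.uniform()))
            if b_new <= tau:
                return
            dlp_span = self._boundary_move_dlp(k_lo, b_new, exclude=i)
            if dlp_span is None:
                return
            u_new = 4.0 * buf.uniform()
            s_new = 10.0**u_new
            t_new = b_new + (a - b_new) * buf.uniform()
            d_new = tau - t_new
            log_r = (
                math.log(pi / (1.0 - pi))
                + dlp_span
                + (_t5_logpdf(d_new / s_new) - u_new * _LOG10)
                + math.log(a - b_new)
                - (tau - b) / lam
                + (m_lo - b_new) / lam
            )
            if log_r >= 0.0 or (log_r > -700 and buf.uniform() < math.exp(log_r)):
                B[k_lo] = b_new
                t[i] = t_new
                self.z[i] = 1
                self.delta[i] = d_new
                self.u[i] = u_new

    # -- one full sweep ------------------------------------------------------
    def sweep(self, buf: _RngBuf, adapt: bool) -> None:
        B = self.B
        t = self.t
        floor = self.span_floor
        # boundaries
        for k in range(self.nb):
            hi = B[k - 1] if k > 0 else self.range_hi
            lo = B[k + 1] if k < self.nb - 1 else self.range_lo
            pa = self.b_phase_above[k]
            pb = self.b_phase_below[k]
            if pa is not None and self.phase_events[pa]:
                ea = min(t[i] for i in self.phase_events[pa])
                if ea < hi:
                    hi = ea
            if pb is not None and self.phase_events[pb]:
                eb = max(t[i] for i in self.phase_events[pb])
                if eb > lo:
                    lo = eb
            prop = B[k] + self.b_scale[k] * buf.normal()
            if adapt:
                self._prop[("b", k)] = self._prop.get(("b", k), 0) + 1
            if prop < lo or prop > hi:
                continue
            dlp = 0.0
            ok = True
            if pa is not None:
                old_span = B[self.phase_hi[pa]] - B[k]
                new_span = B[self.phase_hi[pa]] - prop
                if new_span < floor:
                    ok = False
                else:
                    dlp -= self.phase_exponent[pa] * (
                        math.log(new_span) - math.log(old_span)
                    )
            if ok and pb is not None:
                old_span = B[k] - B[self.phase_lo[pb]]
                new_span = prop - B[self.phase_lo[pb]]
                if new_span < floor:
                    ok = False
                else:
                    dlp -= self.phase_exponent[pb] * (
                        math.log(new_span) - math.log(old_span)
                    )
            if not ok:
                continue
            if dlp >= 0.0 or buf.uniform() < math.exp(dlp):
                B[k] = prop
                if adapt:
                    self._acc[("b", k)] = self._acc.get(("b", k), 0) + 1
        # events
        for i in range(self.ne):
            p = self.e_phase[i]
            if p >= 0:
                hi = B[self.phase_hi[p]]
                lo = B[self.phase_lo[p]]
            else:
                hi, lo = math.inf, -math.inf
            if self.etype[i] == 0 and p >= 0:
                # undated event: conditional is exactly uniform on the phase
                t[i] = lo + (hi - lo) * buf.uniform()
                continue
            prop = t[i] + self.e_scale[i] * buf.normal()
            if adapt:
                self._prop[("e", i)] = self._prop.get(("e", i), 0) + 1
            if prop < lo or prop > hi:
                continue
            new_ll = self._ll(i, prop, self.z[i], self.delta[i], self.m[i])
            dlp = new_ll - self.cur_ll[i]
            if dlp >= 0.0 or (dlp > -700 and buf.uniform() < math.exp(dlp)):
                t[i] = prop
                self.cur_ll[i] = new_ll
                if adapt:
                    self._acc[("e", i)] = self._acc.get(("e", i), 0) + 1
        # outlier indicators and shifts
        for i in self.out_events:
            pi = self.oprior[i]
            general = self.otype[i] == 1
            p = self.e_phase[i]
            if general and p >= 0:
                self._jump_move(i, buf)
            zi = self.z[i]
            if general and p >= 0:
                # swap move: flip z while preserving the effective age
                # t + z*delta, so the likelihood cancels and the ratio is
                # prior odds x shift prior x phase width; repeated attempts
                # with a freshly drawn scale exponent improve mode mixing
                hi = B[self.phase_hi[p]]
                lo = B[self.phase_lo[p]]
                width = hi - lo
                log_w = math.log(width)
                for _attempt in range(3):
                    if self.z[i] == 0:
                        u_new = 4.0 * buf.uniform()
                        s = 10.0**u_new
                        t_new = lo + width * buf.uniform()
                        d_new = t[i] - t_new
                        dlp = (
                            math.log(pi / (1.0 - pi))
                            + _t5_logpdf(d_new / s)
                            - u_new * _LOG10
                            + log_w
                        )
                        if dlp >= 0.0 or (dlp > -700 and buf.uniform() < math.exp(dlp)):
                            self.z[i] = 1
                            t[i] = t_new
                            self.delta[i] = d_new
                            self.u[i] = u_new
                    else:
                        tau = t[i] + self.delta[i]
                        if lo <= tau <= hi:
                            s = 10.0 ** self.u[i]
                            dlp = (
                                math.log((1.0 - pi) / pi)
                                - _t5_logpdf(self.delta[i] / s)
                                + self.u[i] * _LOG10
                                - log_w
                            )
                            if dlp >= 0.0 or (
                                dlp > -700 and buf.uniform() < math.exp(dlp)
                            ):
                                self.z[i] = 0
                                t[i] = tau
                                u_d = 4.0 * buf.uniform()
                                self.u[i] = u_d
                                self.delta[i] = (10.0**u_d) * buf.t5()  # dormant
            else:
                new_ll = self._ll(i, t[i], 1 - zi, self.delta[i], self.m[i])
                dlp = new_ll - self.cur_ll[i] + (
                    math.log(pi / (1.0 - pi)) if zi == 0 else math.log((1.0 - pi) / pi)
                )
                if dlp >= 0.0 or (dlp > -700 and buf.uniform() < math.exp(dlp)):
                    self.z[i] = 1 - zi
                    self.cur_ll[i] = new_ll
            zi = self.z[i]
            if zi == 0:
                # exact conditional redraw from the prior
                if general:
                    self.u[i] = 4.0 * buf.uniform()
                    self.delta[i] = (10.0 ** self.u[i]) * buf.t5()
                else:
                    self.delta[i] = buf.normal()
                continue
            scale = 10.0 ** self.u[i] if general else 1.0
            d_new = self.delta[i] + self.d_scale[i] * scale * buf.normal()
            new_ll = self._ll(i, t[i], zi, d_new, self.m[i])
            if general:
                dpr = _t5_logpdf(d_new / scale) - _t5_logpdf(self.delta[i] / scale)
            else:
                dpr = 0.5 * (self.delta[i] ** 2 - d_new**2)
            dlp = new_ll - self.cur_ll[i] + dpr
            if adapt:
                self._prop[("d", i)] = self._prop.get(("d", i), 0) + 1
            if dlp >= 0.0 or (dlp > -700 and buf.uniform() < math.exp(dlp)):
                self.delta[i] = d_new
                self.cur_ll[i] = new_ll
                if adapt:
                    self._acc[("d", i)] = self._acc.get(("d", i), 0) + 1
            if general:
                u_new = self.u[i] + self.u_scale * buf.normal()
                if 0.0 <= u_new <= 4.0:
                    s_new = 10.0**u_new
                    dlp = (
                        _t5_logpdf(self.delta[i] / s_new)
                        - u_new * _LOG10
                        - _t5_logpdf(self.delta[i] / scale)
                        + self.u[i] * _LOG10
                    )
                    if dlp >= 0.0 or (dlp > -700 and buf.uniform() < math.exp(dlp)):
                        self.u[i] = u_new
        # mixing fractions
        for i in self.mixed_events:
            m_new = self.m[i] + self.m_scale * buf.normal()
            if m_new < 0.0 or m_new > 1.0:
                continue
            new_ll = self._ll(i, t[i], self.z[i], self.delta[i], m_new)
            dlp = new_ll - self.cur_ll[i]
            if dlp >= 0.0 or (dlp > -700 and buf.uniform() < math.exp(dlp)):
                self.m[i] = m_new
                self.cur_ll[i] = new_ll

    def adapt_scales(self) -> None:
        for key, nprop in self._prop.items():
            if nprop < 20:
                continue
            acc = self._acc.get(key, 0) / nprop
            kind, idx = key
            if kind == "b":
                arr = self.b_scale
            elif kind == "e":
                arr = self.e_scale
            else:
                arr = self.d_scale
            if acc < 0.2:
                arr[idx] = max(arr[idx] * 0.7, 1e-3)
            elif acc > 0.5:
                arr[idx] *= 1.4
        self._acc = {}
        self._prop = {}


def _half_chain_overlap(col: np.ndarray, bins: int = 40) -> float:
    """Overlap integral between density estimates from the two interleaved
    half-chains; 1.0 means indistinguishable halves."""
    a, b = col[0::2], col[1::2]
    lo = min(a.min(), b.min())
    hi = max(a.max(), b.max())
    if hi - lo < 1e-9:
        # a frozen chain cannot demonstrate convergence
        return 0.0
    edges = np.linspace(lo, hi, bins + 1)
    pa, _ = np.histogram(a, bins=edges)
    pb, _ = np.histogram(b, bins=edges)
    pa = pa / pa.sum()
    pb = pb / pb.sum()
    return float(np.minimum(pa, pb).sum())


def _run(
    model: ModelNode,
    curves: dict[str, CalibrationCurve],
    settings: SamplerSettings,
    with_protocol: bool,
) -> tuple[Trace, ConvergenceReport]:
    comp = _Compiled(model, curves, settings)
    rng = np.random.default_rng(np.random.SeedSequence(entropy=settings.seed))
    buf = _RngBuf(rng)

    # adaptation (discarded)
    for it in range(settings.burn_in):
        comp.sweep(buf, adapt=True)
        if (it + 1) % 100 == 0:
            comp.adapt_scales()

    nb, ne = comp.nb, comp.ne
    n_out = len(comp.out_events)
    n_mix = len(comp.mixed_events)
    chunks: list[np.ndarray] = []
    z_chunks: list[np.ndarray] = []
    d_chunks: list[np.ndarray] = []
    m_chunks: list[np.ndarray] = []

    def run_block(n_iter: int) -> None:
        keep = n_iter // settings.thinning
        block = np.empty((keep, nb + ne))
        zb = np.empty((keep, n_out), dtype=np.int8)
        db = np.empty((keep, n_out))
        mb = np.empty((keep, n_mix))
        row = 0
        for it in range(n_iter):
            comp.sweep(buf, adapt=False)
            if (it + 1) % settings.thinning == 0 and row < keep:
                block[row, :nb] = comp.B
                block[row, nb:] = comp.t
                for j, ei in enumerate(comp.out_events):
                    zb[row, j] = comp.z[ei]
                    db[row, j] = comp.delta[ei]
                for j, ei in enumerate(comp.mixed_events):
                    mb[row, j] = comp.m[ei]
                row += 1
        chunks.append(block[:row])
        z_chunks.append(zb[:row])
        d_chunks.append(db[:row])
        m_chunks.append(mb[:row])

    run_block(settings.initial_iterations)
    total_iters = settings.burn_in + settings.initial_iterations
    passes = 0
    pass_len = settings.pass_length

    def report() -> ConvergenceReport:
        samples = np.concatenate(chunks, axis=0)
        names = comp.b_labels + comp.e_labels
        per = {}
        for j, name in enumerate(names):
            per[name] = _half_chain_overlap(samples[:, j])
        overall = min(per.values()) if per else 1.0
        return ConvergenceReport(
            per_parameter=per,
            overall=overall,
            passes_run=passes,
            converged=overall > settings.convergence_threshold,
            iterations=total_iters,
        )

    rep = report()
    if with_protocol:
        while not rep.converged and total_iters + pass_len <= HARD_CAP:
            run_block(pass_len)
            total_iters += pass_len
            passes += 1
            pass_len = int(pass_len * settings.pass_interval_growth)
            rep = report()

    samples = np.concatenate(chunks, axis=0)
    query_map = {
        label: (comp.phase_hi[p], comp.phase_lo[p]) for label, p in comp.queries
    }
    trace = Trace(
        names=comp.b_labels + comp.e_labels,
        samples=samples,
        n_boundaries=nb,
        z_names=[comp.e_labels[i] for i in comp.out_events],
        z_samples=np.concatenate(z_chunks, axis=0),
        delta_samples=np.concatenate(d_chunks, axis=0),
        m_names=[comp.e_labels[i] for i in comp.mixed_events],
        m_samples=np.concatenate(m_chunks, axis=0),
        query_map=query_map,
        seed=settings.seed,
        settings=settings,
        convergence=rep,
    )
    return trace, rep


def sample_posterior(
    model: ModelNode,
    curves: dict[str, CalibrationCurve],
    settings: SamplerSettings | None = None,
) -> Trace:
    """Draw posterior samples without the convergence-pass protocol."""
    settings = settings or SamplerSettings()
    trace, _ = _run(model, curves, settings, with_protocol=False)
    return trace


def check_convergence(
    model: ModelNode,
    curves: dict[str, CalibrationCurve],
    settings: SamplerSettings | None = None,
) -> tuple[Trace, ConvergenceReport]:
    """Sample with convergence checked per pass, doubling the pass interval
    until the half-chain overlap criterion is met or the hard cap is hit."""
    settings = settings or SamplerSettings()
    return _run(model, curves, settings, with_protocol=True)


def posterior_pdf(
    trace: Trace,
    label: str,
    resolution: float | None = None,
) -> CalendarPDF:
    """Marginal posterior of a named parameter or Date query as a gridded PDF."""
    if label in trace.query_map:
        samples = trace.query_samples(label)
    elif label in trace.names:
        samples = trace.column(label)
    else:
        raise KeyError(f"unknown parameter or query {label!r}")
    res = resolution if resolution is not None else trace.settings.grid_resolution
    lo = math.floor(samples.min() / res) * res
    hi = math.ceil(samples.max() / res) * res + res
    edges = np.arange(lo - 0.5 * res, hi + 0.5 * res + 1e-9, res)
    counts, _ = np.histogram(samples, bins=edges)
    grid = 0.5 * (edges[:-1] + edges[1:])
    # snap cell centres onto the lattice
    grid = np.round(grid / res) * res
    mass = counts / counts.sum()
    if np.count_nonzero(mass) > 2:
        # mild fixed-width smoothing (sd = 1.5 cells) keeps HPD sets
        # contiguous under per-cell Monte-Carlo noise; pad first so the
        # kernel is never truncated at the support edges
        pad = 6
        grid = np.concatenate(
            [grid[0] + res * np.arange(-pad, 0), grid, grid[-1] + res * np.arange(1, pad + 1)]
        )
        mass = np.concatenate([np.zeros(pad), mass, np.zeros(pad)])
        k = np.exp(-0.5 * (np.arange(-5, 6) / 1.5) ** 2)
        mass = np.convolve(mass, k / k.sum(), mode="same")
        mass = mass / mass.sum()
    keep = mass > 0
    first, last = np.argmax(keep), len(keep) - np.argmax(keep[::-1])
    grid, mass = grid[first:last], mass[first:last]
    return CalendarPDF(grid, mass / mass.sum(), resolution=res, label=label)


def write_manifest(trace: Trace, stream: TextIO) -> None:
    json.dump(trace.manifest(), stream, indent=2)
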