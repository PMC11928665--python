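"""Radiocarbon calibration curves and single-determination calibration.

A calibration curve maps calendar age theta (cal BP, years before AD 1950,
larger = older) to the expected conventional radiocarbon age (CRA) mu(theta)
with 1-sigma curve uncertainty sigma_curve(theta).  Both are linearly
interpolated between knots.  Calibrating a laboratory determination
x +/- sigma onto a calendar grid uses the error-in-variables likelihood

    p(theta) ~ exp(-(x - mu(theta))^2 / (2 (sigma^2 + sigma_c(theta)^2)))
               / sqrt(sigma^2 + sigma_c(theta)^2)

normalised over the grid.  Marine determinations first receive a local
reservoir correction Delta-R (positive = locally older water): the mean is
subtracted from the CRA and its uncertainty added in quadrature.  Samples
that may have drawn carbon from either hemisphere's atmosphere are
calibrated against a uniform mixture of the two hemispheric curves.
"""

from __future__ import annotations

import io
import math
from bisect import bisect_right
from dataclasses import dataclass, replace
from typing import Iterable, Sequence, TextIO

import numpy as np

__all__ = [
    "CalibrationCurve",
    "Determination",
    "CalendarPDF",
    "CurveFormatError",
    "CalibrationError",
    "read_calibration_curve",
    "write_calibration_curve",
    "curve_lookup",
    "apply_reservoir_offset",
    "calibrate",
    "mix_calibration",
    "hpd_interval",
    "round_interval",
    "write_pdf_csv",
    "read_pdf_csv",
    "DEFAULT_RESOLUTION",
]

DEFAULT_RESOLUTION = 5.0  # years per grid cell; reporting is rounded to 10 yr

_TAIL_EPS = 1e-12  # per-side cumulative mass below which the grid is trimmed


class CurveFormatError(ValueError):
    """Raised for malformed `.14c` calibration-curve input."""


class CalibrationError(ValueError):
    """Raised when a determination cannot be calibrated on a curve."""


@dataclass(frozen=True)
class CalibrationCurve:
    """Piecewise-linear calibration curve theta -> (mu, sigma_curve)."""

    theta: np.ndarray  # cal BP, strictly ascending
    mu: np.ndarray  # 14C yr BP
    sigma: np.ndarray  # 14C yr, 1 sigma, > 0
    label: str = "curve"
    hemisphere: str = "synthetic"  # {north, south, marine, synthetic}

    def __post_init__(self) -> None:
        theta = np.asarray(self.theta, dtype=float)
        mu = np.asarray(self.mu, dtype=float)
        sigma = np.asarray(self.sigma, dtype=float)
        if theta.ndim != 1 or theta.size < 2:
            raise CurveFormatError("curve needs at least 2 knots")
        if not (np.diff(theta) > 0).all():
            raise CurveFormatError("curve knots must be strictly ascending in theta")
        if not (sigma > 0).all():
            raise CurveFormatError("curve sigma must be positive at every knot")
        object.__setattr__(self, "theta", theta)
        object.__setattr__(self, "mu", mu)
        object.__setattr__(self, "sigma", sigma)
        # plain-float knot copies for the scalar fast path used by the sampler
        object.__setattr__(self, "_theta_list", theta.tolist())
        object.__setattr__(self, "_mu_list", mu.tolist())
        object.__setattr__(self, "_sigma_list", sigma.tolist())

    @property
    def theta_min(self) -> float:
        return float(self.theta[0])

    @property
    def theta_max(self) -> float:
        return float(self.theta[-1])

    def lookup(self, theta: float | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Interpolate (mu, sigma_curve); out-of-range theta is an error."""
        t = np.asarray(theta, dtype=float)
        if np.any(t < self.theta[0]) or np.any(t > self.theta[-1]):
            raise CalibrationError(
                f"theta outside curve range [{self.theta[0]}, {self.theta[-1]}]"
            )
        return np.interp(t, self.theta, self.mu), np.interp(t, self.theta, self.sigma)

    def lookup_scalar(self, theta: float) -> tuple[float, float] | None:
        """Scalar fast path: (mu, sigma_curve) or None when out of range."""
        ts = self._theta_list
        if theta < ts[0] or theta > ts[-1]:
            return None
        i = bisect_right(ts, theta)
        if i == len(ts):
            i -= 1
        t0, t1 = ts[i - 1], ts[i]
        w = (theta - t0) / (t1 - t0)
        return (
            self._mu_list[i - 1] + w * (self._mu_list[i] - self._mu_list[i - 1]),
            self._sigma_list[i - 1] + w * (self._sigma_list[i] - self._sigma_list[i - 1]),
        )


@dataclass(frozen=True)
class Determination:
    """One laboratory radiocarbon measurement (CRA +/- 1 sigma)."""

    lab_id: str
    cra: float
    sigma: float
    material: str = ""
    reservoir: str = "atmospheric"  # {atmospheric, marine, mixed_hemispheric}
    delta_r: tuple[float, float] | None = None  # (mean, sd), 14C yr
    curve_key: str = ""

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError(f"{self.lab_id}: sigma must be positive")
        if (self.reservoir == "marine") != (self.delta_r is not None):
            raise ValueError(
                f"{self.lab_id}: delta_r must be given iff reservoir is marine"
            )


@dataclass(frozen=True)
class CalendarPDF:
    """Discrete probability distribution over a regular cal BP grid.

    ``grid`` holds ascending cell-centre ages at constant resolution; grid
    points sit on the global lattice of integer multiples of the resolution
    so PDFs from different calls can be combined cell-wise.
    """

    grid: np.ndarray
    mass: np.ndarray
    resolution: float = DEFAULT_RESOLUTION
    label: str = ""

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid, dtype=float)
        mass = np.asarray(self.mass, dtype=float)
        if grid.shape != mass.shape or grid.ndim != 1 or grid.size == 0:
            raise ValueError("grid and mass must be equal-length 1-d arrays")
        if grid.size > 1:
            steps = np.diff(grid)
            if not np.allclose(steps, self.resolution, atol=1e-6):
                raise ValueError("grid must be regular at the stated resolution")
        if (mass < -1e-15).any():
            raise ValueError("mass must be non-negative")
        total = mass.sum()
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError(f"mass must sum to 1 (got {total!r})")
        object.__setattr__(self, "grid", grid)
        object.__setattr__(self, "mass", np.clip(mass, 0.0, None))

    # -- summaries ---------------------------------------------------------
    def mean(self) -> float:
        return float(np.dot(self.grid, self.mass))

    def median(self) -> float:
        cum = np.cumsum(self.mass)
        return float(self.grid[int(np.searchsorted(cum, 0.5))])

    def mode(self) -> float:
        return float(self.grid[int(np.argmax(self.mass))])

    def sd(self) -> float:
        m = self.mean()
        return float(math.sqrt(max(np.dot((self.grid - m) ** 2, self.mass), 0.0)))

    def hpd(self, level: float = 0.954) -> list[tuple[float, float]]:
        return hpd_interval(self, level)

    def log_density_interp(self) -> tuple[list[float], list[float]]:
        """(grid, log-mass) as plain lists for scalar interpolation."""
        with np.errstate(divide="ignore"):
            logm = np.log(self.mass)
        return self.grid.tolist(), logm.tolist()


# ---------------------------------------------------------------------------
# curve I/O


def read_calibration_curve(
    source: TextIO | str | Iterable[str],
    dialect: str | None = None,
    label: str = "curve",
    hemisphere: str = "synthetic",
) -> CalibrationCurve:
    """Read a `.14c`-style curve (columns: cal BP, 14C age BP, 1 sigma).

    Comma and tab/whitespace separation are both accepted; lines starting
    with ``#`` (or ``##``) are comments.  ``dialect`` may force ``"comma"``
    or ``"tab"``.
    """
    if isinstance(source, str):
        source = io.StringIO(source)
    rows: list[tuple[float, float, float]] = []
    for lineno, raw in enumerate(source, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if dialect == "comma":
            parts = line.split(",")
        elif dialect == "tab":
            parts = line.split()
        else:
            parts = line.split(",") if "," in line else line.split()
        if len(parts) < 3:
            raise CurveFormatError(f"line {lineno}: expected 3 columns, got {len(parts)}")
        try:
            theta, mu, sig = (float(p) for p in parts[:3])
        except ValueError as exc:
            raise CurveFormatError(f"line {lineno}: {exc}") from None
        rows.append((theta, mu, sig))
    if len(rows) < 2:
        raise CurveFormatError("curve file has fewer than 2 knots")
    rows.sort(key=lambda r: r[0])
    thetas = [r[0] for r in rows]
    for a, b in zip(thetas, thetas[1:]):
        if a == b:
            raise CurveFormatError(f"duplicate knot theta={a}")
    arr = np.array(rows, dtype=float)
    return CalibrationCurve(arr[:, 0], arr[:, 1], arr[:, 2], label=label, hemisphere=hemisphere)


def write_calibration_curve(curve: CalibrationCurve, stream: TextIO, dialect: str = "comma") -> None:
    sep = "," if dialect == "comma" else "\t"
    stream.write(f"# {curve.label} (cal BP, 14C age BP, 1 sigma)\n")
    for t, m, s in zip(curve.theta, curve.mu, curve.sigma):
        stream.write(f"{t:.9g}{sep}{m:.9g}{sep}{s:.9g}\n")


def curve_lookup(curve: CalibrationCurve, theta: float) -> tuple[float, float]:
    """(mu, sigma_curve) at calendar age theta by linear interpolation."""
    mu, sig = curve.lookup(theta)
    return float(mu), float(sig)


# ---------------------------------------------------------------------------
# calibration


def apply_reservoir_offset(det: Determination, delta_r: tuple[float, float] | None = None) -> Determination:
    """Apply a marine Delta-R correction, returning a corrected copy.

    Positive Delta-R means locally older water: its mean is subtracted from
    the CRA and its sd folded into the measurement error in quadrature.
    """
    if det.reservoir != "marine":
        raise ValueError(f"{det.lab_id}: reservoir correction applies to marine determinations only")
    dr = delta_r if delta_r is not None else det.delta_r
    if dr is None:
        raise ValueError(f"{det.lab_id}: no delta_r available")
    mean, sd = dr
    return replace(
        det,
        cra=det.cra - mean,
        sigma=math.hypot(det.sigma, sd),
        reservoir="atmospheric",
        delta_r=None,
    )


def _lattice_grid(lo: float, hi: float, resolution: float) -> np.ndarray:
    """Ascending grid of lattice points (multiples of resolution) in [lo, hi]."""
    i0 = math.ceil(lo / resolution - 1e-9)
    i1 = math.floor(hi / resolution + 1e-9)
    if i1 < i0:
        raise CalibrationError("curve range narrower than one grid cell")
    return np.arange(i0, i1 + 1, dtype=float) * resolution


def _trim_and_normalise(grid: np.ndarray, dens: np.ndarray, resolution: float, label: str) -> CalendarPDF:
    total = dens.sum()
    if not np.isfinite(total) or total <= 0:
        raise CalibrationError("zero total mass: determination lies outside the curve")
    mass = dens / total
    cum = np.cumsum(mass)
    lo = int(np.searchsorted(cum, _TAIL_EPS))
    hi = int(np.searchsorted(cum, 1.0 - _TAIL_EPS)) + 1
    lo, hi = max(lo, 0), min(hi, mass.size)
    grid, mass = grid[lo:hi], mass[lo:hi]
    mass = mass / mass.sum()
    return CalendarPDF(grid, mass, resolution=resolution, label=label)


def _calib_density(x: float, sigma: float, mu: np.ndarray, sig_c: np.ndarray) -> np.ndarray:
    var = sigma * sigma + sig_c * sig_c
    return np.exp(-0.5 * (x - mu) ** 2 / var) / np.sqrt(var)


def _cell_subpoints(grid: np.ndarray, resolution: float) -> tuple[np.ndarray, int]:
    """Midpoint sub-grid (strips <= 0.25 yr) for integrating cell masses,
    rather than evaluating the density at cell centres only."""
    k = max(1, math.ceil(resolution / 0.25))
    offsets = (np.arange(k) + 0.5) / k * resolution - 0.5 * resolution
    return (grid[:, None] + offsets[None, :]).ravel(), k


def calibrate(
    det: Determination,
    curve: CalibrationCurve,
    grid_resolution: float = DEFAULT_RESOLUTION,
) -> CalendarPDF:
    """Calibrate one determination onto the calendar grid spanned by the curve."""
    if det.reservoir == "marine":
        det = apply_reservoir_offset(det)
    grid = _lattice_grid(curve.theta_min, curve.theta_max, grid_resolution)
    sub, k = _cell_subpoints(grid, grid_resolution)
    inside = (sub >= curve.theta_min) & (sub <= curve.theta_max)
    mu = np.empty_like(sub)
    sig_c = np.empty_like(sub)
    mu[inside], sig_c[inside] = curve.lookup(sub[inside])
    dens_sub = np.zeros_like(sub)
    dens_sub[inside] = _calib_density(det.cra, det.sigma, mu[inside], sig_c[inside])
    n_in = inside.reshape(grid.size, k).sum(axis=1)
    dens = np.where(
        n_in > 0, dens_sub.reshape(grid.size, k).sum(axis=1) / np.maximum(n_in, 1), 0.0
    )
    return _trim_and_normalise(grid, dens, grid_resolution, label=det.lab_id)


def mix_calibration(
    det: Determination,
    curve_n: CalibrationCurve,
    curve_s: CalibrationCurve,
    grid_resolution: float = DEFAULT_RESOLUTION,
    n_quad: int = 64,
) -> CalendarPDF:
    """Calibrate against a uniform mixture of two hemispheric curves.

    The mixing fraction m ~ U(0,1) is marginalised by Gauss-Legendre
    quadrature over the effective curve mu_m = m mu_n + (1-m) mu_s (sigma
    interpolated the same way).  Inside an MCMC model m is a latent
    variable instead (see :mod:`calphase.sampler`).
    """
    if n_quad < 21:
        raise ValueError("n_quad must be >= 21")
    lo = max(curve_n.theta_min, curve_s.theta_min)
    hi = min(curve_n.theta_max, curve_s.theta_max)
    grid = _lattice_grid(lo, hi, grid_resolution)
    sub, k = _cell_subpoints(grid, grid_resolution)
    inside = (sub >= lo) & (sub <= hi)
    mu_n = np.zeros_like(sub)
    sig_n = np.zeros_like(sub)
    mu_s = np.zeros_like(sub)
    sig_s = np.zeros_like(sub)
    mu_n[inside], sig_n[inside] = curve_n.lookup(sub[inside])
    mu_s[inside], sig_s[inside] = curve_s.lookup(sub[inside])
    nodes, weights = np.polynomial.legendre.leggauss(n_quad)
    ms = 0.5 * (nodes + 1.0)  # map to (0, 1)
    dens_sub = np.zeros_like(sub)
    for m, w in zip(ms, weights):
        mu_m = m * mu_n[inside] + (1.0 - m) * mu_s[inside]
        sig_m = m * sig_n[inside] + (1.0 - m) * sig_s[inside]
        dens_sub[inside] += 0.5 * w * _calib_density(det.cra, det.sigma, mu_m, sig_m)
    n_in = inside.reshape(grid.size, k).sum(axis=1)
    dens = np.where(
        n_in > 0, dens_sub.reshape(grid.size, k).sum(axis=1) / np.maximum(n_in, 1), 0.0
    )
    return _trim_and_normalise(grid, dens, grid_resolution, label=det.lab_id)


# ---------------------------------------------------------------------------
# interval queries


def hpd_interval(pdf: CalendarPDF, level: float = 0.954) -> list[tuple[float, float]]:
    """Highest-posterior-density region as disjoint (older, younger) intervals.

    Grid cells are accumulated in descending mass order until the target
    level is reached (ties broken toward older ages); contiguous runs are
    merged and each interval reported as (older, younger) cal BP spanning
    the included cells' outer edges rounded to cell centres.
    """
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    mass = pdf.mass
    # stable sort on (-mass, -grid): equal masses favour the older (larger) age
    order = np.lexsort((-pdf.grid, -mass))
    cum = np.cumsum(mass[order])
    k = int(np.searchsorted(cum, level - 1e-12)) + 1
    chosen = np.sort(order[:k])
    intervals: list[tuple[float, float]] = []
    start = prev = chosen[0]
    for idx in chosen[1:]:
        if idx == prev + 1:
            prev = idx
            continue
        intervals.append((float(pdf.grid[prev]), float(pdf.grid[start])))
        start = prev = idx
    intervals.append((float(pdf.grid[prev]), float(pdf.grid[start])))
    # each run spans grid[start]..grid[prev] ascending, so (older, younger) =
    # (grid[prev], grid[start]); report the oldest interval first
    return sorted(intervals, reverse=True)


def round_interval(interval: tuple[float, float], step: float = 10.0) -> tuple[float, float]:
    """Round an (older, younger) interval to multiples of ``step``.

    Half-way cases round outward (away from the interval centre) so the
    rounded interval never loses the tie cell: (12345, 12335) -> (12350, 12330).
    """
    older, younger = interval
    if older < younger:
        raise ValueError("interval must be (older, younger) with older >= younger")
    r_old = math.floor(older / step + 0.5) * step
    r_young = math.ceil(younger / step - 0.5) * step
    return (r_old, r_young)


# ---------------------------------------------------------------------------
# PDF I/O


def write_pdf_csv(pdf: CalendarPDF, stream: TextIO) -> None:
    """Two-column CSV (cal BP, probability mass) with a metadata header."""
    stream.write(f"# label={pdf.label} resolution={pdf.resolution:g}\n")
    stream.write("cal_bp,probability\n")
    for t, m in zip(pdf.grid, pdf.mass):
        stream.write(f"{t:.6g},{m:.12g}\n")


def read_pdf_csv(stream: TextIO | str) -> CalendarPDF:
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    label, resolution = "", DEFAULT_RESOLUTION
    grid: list[float] = []
    mass: list[float] = []
    for raw in stream:
        line = raw.strip()
        if line.startswith("#"):
            for tok in line[1:].split():
                if tok.startswith("label="):
                    label = tok[6:]
                elif tok.startswith("resolution="):
                    resolution = float(tok[11:])
            continue
        if not line or line.startswith("cal_bp"):
            continue
        a, b = line.split(",")
        grid.append(float(a))
        mass.append(float(b))
    arr_g, arr_m = np.array(grid), np.array(mass)
    arr_m = arr_m / arr_m.sum()
    return CalendarPDF(arr_g, arr_m, resolution=resolution, label=label)


def align_pdfs(pdfs: Sequence[CalendarPDF]) -> tuple[np.ndarray, np.ndarray]:
    """Stack PDFs onto a common lattice grid (union of supports), zero-padded."""
    if not pdfs:
        raise ValueError("need at least one PDF")
    res = pdfs[0].resolution
    for p in pdfs:
        if not math.isclose(p.resolution, res):
            raise ValueError("PDFs must share one grid resolution")
    lo = min(p.grid[0] for p in pdfs)
    hi = max(p.grid[-1] for p in pdfs)
    grid = _lattice_grid(lo, hi, res)
    out = np.zeros((len(pdfs), grid.size))
    for i, p in enumerate(pdfs):
        j = int(round((p.grid[0] - grid[0]) / res))
        out[i, j : j + p.grid.size] = p.mass
    return grid, out
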