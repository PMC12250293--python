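"""High-resolution melting (HRM) analysis.

Melt curves are normalized between linear baselines fitted in pre- and
post-melt temperature windows, differentiated with a Savitzky-Golay filter
(negative first derivative; peaks mark melting temperatures), and
quantified by temperature-wise calibration: for every temperature on a
calibration grid (default 79.6-81.6 degC), the unique cubic through the
four standard points (normalized fluorescence at 0/25/50/75% methylation)
maps a sample's normalized fluorescence to a methylation percentage; the
per-temperature estimates are aggregated (median by default).

A seeded logistic melt simulator stands in for instrument output, and a
GC-content-based attribution assigns observed melt peaks to candidate
amplicon species (higher GC melts higher).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.signal import savgol_filter

from .errors import CalibrationError

_TOL = 1e-9


@dataclass(frozen=True)
class MeltCurve:
    """Fluorescence versus temperature for one sample."""

    temperatures: tuple[float, ...]
    fluorescence: tuple[float, ...]
    sample_id: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.temperatures, dtype=float)
        f = np.asarray(self.fluorescence, dtype=float)
        if t.size != f.size:
            raise CalibrationError("temperature and fluorescence lengths differ")
        if t.size < 20:
            raise CalibrationError("melt curve needs at least 20 points")
        if np.any(np.diff(t) <= 0):
            raise CalibrationError("temperature grid must be strictly increasing")

    @classmethod
    def from_arrays(cls, temperatures, fluorescence, sample_id: str = "") -> "MeltCurve":
        return cls(tuple(float(x) for x in temperatures),
                   tuple(float(x) for x in fluorescence), sample_id)

    @property
    def t(self) -> np.ndarray:
        return np.asarray(self.temperatures, dtype=float)

    @property
    def f(self) -> np.ndarray:
        return np.asarray(self.fluorescence, dtype=float)


@dataclass(frozen=True)
class HrmParams:
    """Analysis settings for HRM normalization, derivative and calibration.

    ``pre_melt_window``/``post_melt_window`` are (low, high) degC intervals
    for baseline fitting; when ``None`` they default to 1.0 degC windows at
    the ends of the curve. ``sg_window`` is the odd Savitzky-Golay point
    count (11 points at 0.1 degC spacing by default) and ``sg_degree`` the
    polynomial degree (3). Calibration uses standards at 0/25/50/75%
    methylation over 79.6-81.6 degC.
    """

    pre_melt_window: tuple[float, float] | None = None
    post_melt_window: tuple[float, float] | None = None
    sg_degree: int = 3
    sg_window: int = 11
    calibration_window: tuple[float, float] = (79.6, 81.6)
    calibration_levels: tuple[float, ...] = (0.0, 25.0, 50.0, 75.0)
    aggregate: str = "median"  # median | mean

    def __post_init__(self) -> None:
        if self.sg_window % 2 == 0 or self.sg_window <= self.sg_degree:
            raise CalibrationError("sg_window must be odd and exceed sg_degree")
        if self.aggregate not in ("median", "mean"):
            raise CalibrationError(f"unknown aggregate {self.aggregate!r}")

    def windows_for(self, curve: MeltCurve) -> tuple[tuple[float, float],
                                                     tuple[float, float]]:
        t = curve.t
        pre = self.pre_melt_window or (float(t[0]), float(t[0]) + 1.0)
        post = self.post_melt_window or (float(t[-1]) - 1.0, float(t[-1]))
        return pre, post


@dataclass(frozen=True)
class MeltSpecies:
    """One amplicon species with its melting temperature and GC content."""

    label: str
    tm: float
    gc_percent: float | None = None
    weight: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.weight <= 1.0:
            raise CalibrationError(f"species weight out of [0, 1]: {self.weight}")


def _fit_baseline(t: np.ndarray, f: np.ndarray,
                  window: tuple[float, float]) -> np.ndarray:
    mask = (t >= window[0] - _TOL) & (t <= window[1] + _TOL)
    if mask.sum() < 2:
        raise CalibrationError(
            f"baseline window {window} contains fewer than 2 points"
        )
    coeff = np.polyfit(t[mask], f[mask], 1)
    return np.polyval(coeff, t)


def normalize_curve(raw: MeltCurve, params: HrmParams | None = None) -> MeltCurve:
    """Normalize fluorescence to [0, 1] between fitted linear baselines.

    The upper baseline is fitted in the pre-melt window, the lower in the
    post-melt window; normalized F(T) = (F - lower)/(upper - lower), clipped
    to [0, 1]. Invariant under affine transforms of the raw fluorescence.
    """
    params = params or HrmParams()
    pre, post = params.windows_for(raw)
    t, f = raw.t, raw.f
    upper = _fit_baseline(t, f, pre)
    lower = _fit_baseline(t, f, post)
    span = upper - lower
    if np.min(span) <= _TOL * max(1.0, float(np.max(np.abs(f)))):
        raise CalibrationError(
            "degenerate normalization: upper and lower baselines coincide"
        )
    norm = np.clip((f - lower) / span, 0.0, 1.0)
    return MeltCurve.from_arrays(t, norm, raw.sample_id)


def neg_derivative(curve: MeltCurve, params: HrmParams | None = None) -> MeltCurve:
    """Negative first derivative -dF/dT via Savitzky-Golay smoothing.

    Length matches the input; edges are handled by the filter's polynomial
    extrapolation. Peaks of the result mark melting temperatures.
    """
    params = params or HrmParams()
    t, f = curve.t, curve.f
    if params.sg_window > t.size:
        raise CalibrationError(
            f"sg_window {params.sg_window} exceeds curve length {t.size}"
        )
    delta = float(np.mean(np.diff(t)))
    d = savgol_filter(f, params.sg_window, params.sg_degree, deriv=1,
                      delta=delta, mode="interp")
    return MeltCurve.from_arrays(t, -d, f"{curve.sample_id}|-dF/dT")


@dataclass(frozen=True)
class CalibrationModel:
    """Per-temperature cubics mapping normalized fluorescence to percent
    methylation, fitted on the standard levels."""

    temperatures: tuple[float, ...]
    coefficients: tuple[tuple[float, float, float, float], ...]  # np.polyval order
    levels: tuple[float, ...]
    excluded_temperatures: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if len(self.temperatures) != len(self.coefficients):
            raise CalibrationError("one cubic per grid temperature required")

    def predict_fluorescence(self, norm_f: Sequence[float]) -> np.ndarray:
        """Evaluate each per-temperature cubic at the matching normalized
        fluorescence value (one per grid temperature)."""
        norm_f = np.asarray(norm_f, dtype=float)
        if norm_f.size != len(self.temperatures):
            raise CalibrationError("need one fluorescence value per grid point")
        return np.array([np.polyval(c, x)
                         for c, x in zip(self.coefficients, norm_f)])

    def to_json(self) -> str:
        return json.dumps({
            "temperatures": list(self.temperatures),
            "coefficients": [list(c) for c in self.coefficients],
            "levels": list(self.levels),
            "excluded_temperatures": list(self.excluded_temperatures),
        }, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "CalibrationModel":
        d = json.loads(text)
        return cls(
            temperatures=tuple(d["temperatures"]),
            coefficients=tuple(tuple(c) for c in d["coefficients"]),
            levels=tuple(d["levels"]),
            excluded_temperatures=tuple(d.get("excluded_temperatures", ())),
        )


def _window_grid(curve: MeltCurve, window: tuple[float, float]) -> np.ndarray:
    t = curve.t
    mask = (t >= window[0] - _TOL) & (t <= window[1] + _TOL)
    if mask.sum() < 2:
        raise CalibrationError(
            f"curve does not cover the calibration window {window}"
        )
    return t[mask]


def fit_calibration(standards: Mapping[float, MeltCurve],
                    params: HrmParams | None = None) -> CalibrationModel:
    """Fit the temperature-wise cubic calibration from methylation standards.

    Exactly the four configured standard levels (0/25/50/75% by default)
    must be present: four points determine the degree-3 polynomial exactly,
    so each interpolant passes through the standards at machine precision.
    Temperatures at which two standards share the same normalized
    fluorescence (non-invertible) are excluded; if every temperature is
    excluded, calibration fails.
    """
    params = params or HrmParams()
    want = tuple(sorted(params.calibration_levels))
    got = tuple(sorted(float(k) for k in standards))
    if got != want:
        raise CalibrationError(
            f"calibration needs exactly levels {want}, got {got}"
        )
    levels = [float(k) for k in want]
    norm = {lvl: normalize_curve(standards[lvl], params) for lvl in levels}
    grid = _window_grid(norm[levels[0]], params.calibration_window)

    # sample every normalized standard on the shared grid
    fmat = np.vstack([
        np.interp(grid, norm[lvl].t, norm[lvl].f) for lvl in levels
    ])  # shape (4, n_grid)

    coeffs: list[tuple[float, ...]] = []
    kept: list[float] = []
    excluded: list[float] = []
    for k, temp in enumerate(grid):
        x = fmat[:, k]
        if np.min(np.abs(np.subtract.outer(x, x))[~np.eye(len(x), dtype=bool)]) < 1e-12:
            excluded.append(float(temp))
            continue
        c = np.polyfit(x, levels, 3)
        coeffs.append(tuple(float(v) for v in c))
        kept.append(float(temp))
    if not kept:
        raise CalibrationError(
            "all calibration temperatures excluded (standards not separable)"
        )
    return CalibrationModel(temperatures=tuple(kept),
                            coefficients=tuple(coeffs),
                            levels=tuple(levels),
                            excluded_temperatures=tuple(excluded))


def quantify_sample(curve: MeltCurve, model: CalibrationModel,
                    params: HrmParams | None = None) -> tuple[float, np.ndarray]:
    """Methylation percent of a sample from its melt curve.

    The sample curve is normalized, sampled at the model's grid
    temperatures, pushed through each per-temperature cubic, and aggregated
    (median by default), clipped to [0, 100]. Returns
    ``(aggregate, per_temperature_estimates)``.
    """
    params = params or HrmParams()
    norm = normalize_curve(curve, params)
    grid = np.asarray(model.temperatures)
    if grid[0] < norm.t[0] - _TOL or grid[-1] > norm.t[-1] + _TOL:
        raise CalibrationError("sample curve does not cover the calibration window")
    fx = np.interp(grid, norm.t, norm.f)
    est = model.predict_fluorescence(fx)
    agg = float(np.median(est) if params.aggregate == "median" else np.mean(est))
    return min(100.0, max(0.0, agg)), est


class HrmCalibrator:
    """Estimator-style wrapper: fit on standards, predict samples.

    ``fit`` takes melt curves and their nominal methylation levels;
    ``predict`` returns one methylation percentage per curve. Thin wrapper
    over :func:`fit_calibration` / :func:`quantify_sample`.
    """

    def __init__(self, params: HrmParams | None = None):
        self.params = params or HrmParams()

    def get_params(self, deep: bool = True) -> dict:
        return {"params": self.params}

    def set_params(self, **kw) -> "HrmCalibrator":
        for k, v in kw.items():
            setattr(self, k, v)
        return self

    def fit(self, curves: Sequence[MeltCurve], levels: Sequence[float]) -> "HrmCalibrator":
        if len(curves) != len(levels):
            raise CalibrationError("one level per standard curve required")
        self.model_ = fit_calibration(dict(zip([float(l) for l in levels], curves)),
                                      self.params)
        return self

    def predict(self, curves: Sequence[MeltCurve]) -> np.ndarray:
        if not hasattr(self, "model_"):
            raise CalibrationError("HrmCalibrator is not fitted")
        return np.array([quantify_sample(c, self.model_, self.params)[0]
                         for c in curves])


def simulate_melt(species: Sequence[MeltSpecies],
                  baseline: tuple[float, float] = (0.0, 0.0),
                  noise_sd: float = 0.0, seed: int | None = None,
                  grid: tuple[float, float, float] = (65.0, 95.0, 0.1),
                  width: float = 0.35,
                  sample_id: str = "") -> MeltCurve:
    """Simulate a melt curve as a weighted sum of two-state logistic melts.

    F(T) = sum_s w_s * logistic((tm_s - T)/width) + b0 + b1*(T - T_min),
    plus seeded Gaussian noise. Each species contributes half its weight at
    its melting temperature. Species weights must sum to 1.
    """
    w = sum(s.weight for s in species)
    if abs(w - 1.0) > 1e-9:
        raise CalibrationError(f"species weights must sum to 1, got {w}")
    lo, hi, step = grid
    t = lo + step * np.arange(int(round((hi - lo) / step)) + 1)
    f = np.zeros_like(t)
    for s in species:
        f += s.weight / (1.0 + np.exp(-(s.tm - t) / width))
    b0, b1 = baseline
    f = f + b0 + b1 * (t - t[0])
    if noise_sd:
        rng = np.random.default_rng(seed)
        f = f + rng.normal(0.0, noise_sd, size=t.size)
    return MeltCurve.from_arrays(t, f, sample_id)


@dataclass(frozen=True)
class SpeciesAssignment:
    observed_tm: float
    species: MeltSpecies | None
    status: str  # assigned | unresolved
    note: str = ""


@dataclass(frozen=True)
class AttributionResult:
    assignments: tuple[SpeciesAssignment, ...]
    gc_order_consistent: bool
    warnings: tuple[str, ...] = ()


def attribute_species(observed_tms: Sequence[float],
                      candidates: Sequence[MeltSpecies],
                      excluded_labels: Sequence[str] = ()) -> AttributionResult:
    """Assign observed melt peaks to candidate amplicon species.

    Candidates whose expected products are known to be absent are excluded
    first (``excluded_labels``), then each observed melting temperature is
    assigned to the nearest remaining candidate Tm. An exact tie between
    two candidates yields an unresolved assignment rather than a guess.
    Because GC-richer amplicons melt higher, the result carries a
    consistency check that candidate GC ordering matches Tm ordering.
    """
    pool = [c for c in candidates if c.label not in set(excluded_labels)]
    if not pool:
        raise CalibrationError("no candidate species remain after exclusion")

    warnings: list[str] = []
    with_gc = [c for c in pool if c.gc_percent is not None]
    consistent = True
    if len(with_gc) >= 2:
        by_gc = sorted(with_gc, key=lambda c: c.gc_percent)
        tms = [c.tm for c in by_gc]
        consistent = all(a <= b for a, b in zip(tms, tms[1:]))
        if not consistent:
            warnings.append(
                "candidate GC ordering contradicts Tm ordering "
                "(higher GC should melt higher)"
            )

    assignments: list[SpeciesAssignment] = []
    for tm in observed_tms:
        dists = sorted(((abs(tm - c.tm), i) for i, c in enumerate(pool)),
                       key=lambda d: d[0])
        if len(dists) >= 2 and abs(dists[0][0] - dists[1][0]) < 1e-9:
            assignments.append(SpeciesAssignment(
                observed_tm=float(tm), species=None, status="unresolved",
                note=f"equidistant between {pool[dists[0][1]].label} and "
                     f"{pool[dists[1][1]].label}"))
        else:
            assignments.append(SpeciesAssignment(
                observed_tm=float(tm), species=pool[dists[0][1]],
                status="assigned"))
    return AttributionResult(assignments=tuple(assignments),
                             gc_order_consistent=consistent,
                             warnings=tuple(warnings))


def find_melt_peaks(derivative: MeltCurve, min_height: float = 0.05) -> list[float]:
    """Temperatures of local maxima of a negative-derivative curve."""
    f, t = derivative.f, derivative.t
    peaks = []
    for i in range(1, f.size - 1):
        if f[i] >= f[i - 1] and f[i] > f[i + 1] and f[i] >= min_height:
            peaks.append(float(t[i]))
    return peaks
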