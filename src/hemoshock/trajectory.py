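"""Phase-plane analytics for simulated patient trajectories.

A trajectory is a pair of uniformly sampled vitals series (e.g. blood volume
vs. lactate).  The pipeline is: smooth both axes with a centered moving
average (a normalized ones-kernel convolution; raw curvature otherwise locks
onto cardiac/respiratory oscillation), compute the planar curvature

    k = |x′y″ − y′x″| / (x′² + y′²)^{3/2}

with central finite differences in sample index, and extract the global
maximum-curvature point — the turning point where deterioration gives way to
recovery.  Max-curvature points pooled over a cohort are covered by their
convex hull (one hull per hemorrhage severity), and a four-parameter
logistic severity curve

    f(BV) = a / (1 + exp(b·(BV − c))) + d

is fitted to (blood volume lost, lactate) by nonlinear least squares, with
delta-method parameter uncertainty and normal-theory prediction intervals.
The fit layer follows the Model → fit() → Results convention: build a
:class:`LogisticSeverityModel` from data, call ``fit()``, and query the
returned :class:`LogisticSeverityResults` for parameters, covariance,
intervals and a summary table.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit
from scipy.spatial import ConvexHull, QhullError
from scipy.stats import norm

__all__ = [
    "Trajectory",
    "CurvaturePoint",
    "HullRegion",
    "DegenerateHullError",
    "smooth_series",
    "curvature",
    "max_curvature_point",
    "hull_region",
    "LogisticSeverityModel",
    "LogisticSeverityResults",
    "fit_logistic",
    "prediction_interval",
    "invert_logistic",
    "logistic4",
]


class DegenerateHullError(ValueError):
    """Fewer than three non-collinear points: no planar hull exists."""


@dataclass
class Trajectory:
    """Uniformly sampled phase-plane trajectory r(t) = (x(t), y(t))."""

    x: np.ndarray
    y: np.ndarray
    sample_interval: float = 1.0  # s
    x_scale: float | None = None  # axis pre-scaling recorded with results
    y_scale: float | None = None

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.y.shape or self.x.ndim != 1:
            raise ValueError("x and y must be 1-D arrays of equal length")
        if len(self.x) < 3:
            raise ValueError("trajectory needs at least 3 samples")

    def __len__(self) -> int:
        return len(self.x)

    def scaled(self) -> "Trajectory":
        """Rescale both axes to unit range (recorded for back-transformation)."""
        xs = float(np.ptp(self.x)) or 1.0
        ys = float(np.ptp(self.y)) or 1.0
        return Trajectory(self.x / xs, self.y / ys,
                          sample_interval=self.sample_interval,
                          x_scale=xs, y_scale=ys)


@dataclass
class CurvaturePoint:
    """The phase-plane turning point of one trajectory."""

    index: int
    x: float
    y: float
    k: float  # curvature, 1/length in the (possibly scaled) plane


@dataclass
class HullRegion:
    """Convex hull over a cohort's max-curvature points."""

    vertices: np.ndarray   # (m, 2) counterclockwise
    area: float

    def contains(self, point: tuple[float, float], tol: float = 1e-9) -> bool:
        """Point-in-convex-polygon test via signed edge cross-products."""
        v = self.vertices
        p = np.asarray(point, dtype=float)
        for i in range(len(v)):
            a, b = v[i], v[(i + 1) % len(v)]
            cross = (b[0] - a[0]) * (p[1] - a[1]) - (b[1] - a[1]) * (p[0] - a[0])
            if cross < -tol * (1.0 + np.abs(v).max()):
                return False
        return True


def smooth_series(x: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with a normalized ones kernel.

    Output length equals input length; near the edges the window shrinks
    symmetrically so the average stays centered and mean-preserving.
    """
    x = np.asarray(x, dtype=float)
    if window < 1 or window % 2 == 0:
        raise ValueError(f"window must be odd and >= 1, got {window}")
    if window > len(x):
        raise ValueError(f"window {window} exceeds series length {len(x)}")
    if window == 1:
        return x.copy()
    half = window // 2
    csum = np.concatenate(([0.0], np.cumsum(x)))
    out = np.empty_like(x)
    n = len(x)
    for i in range(n):
        h = min(half, i, n - 1 - i)
        out[i] = (csum[i + h + 1] - csum[i - h]) / (2 * h + 1)
    return out


def curvature(traj: Trajectory) -> np.ndarray:
    """Pointwise curvature via central differences in sample index.

    Degenerate points (x′ = y′ = 0) get k = 0 with a warning.  The formula
    is parameterization-dependent, so axes should be pre-scaled to
    comparable ranges (see :meth:`Trajectory.scaled`).
    """
    if len(traj) < 5:
        raise ValueError("curvature needs at least 5 samples")
    x, y = traj.x, traj.y
    dx = np.gradient(x)
    dy = np.gradient(y)
    ddx = np.gradient(dx)
    ddy = np.gradient(dy)
    speed_sq = dx * dx + dy * dy
    num = np.abs(dx * ddy - dy * ddx)
    k = np.zeros_like(x)
    ok = speed_sq > 0.0
    if not np.all(ok):
        warnings.warn("degenerate trajectory point(s): curvature set to 0",
                      RuntimeWarning, stacklevel=2)
    k[ok] = num[ok] / speed_sq[ok] ** 1.5
    return k


def max_curvature_point(traj: Trajectory, window: int = 31,
                        presmoothed: bool = False) -> CurvaturePoint:
    """Global maximum of the smoothed-trajectory curvature.

    The trajectory is smoothed first (window must be odd); a margin of one
    window at each end is excluded so edge effects cannot win; ties break to
    the earliest index (the first deterioration→recovery crossing).
    """
    if presmoothed:
        sm = traj
    else:
        sm = Trajectory(smooth_series(traj.x, window),
                        smooth_series(traj.y, window),
                        sample_interval=traj.sample_interval,
                        x_scale=traj.x_scale, y_scale=traj.y_scale)
    k = curvature(sm)
    margin = min(window, (len(k) - 1) // 2)
    interior = k[margin:len(k) - margin]
    if interior.size == 0 or np.all(interior == 0.0):
        raise ValueError("no turning point: curvature vanishes on the interior")
    idx = int(np.argmax(interior)) + margin
    return CurvaturePoint(index=idx, x=float(sm.x[idx]), y=float(sm.y[idx]),
                          k=float(k[idx]))


def hull_region(points: np.ndarray) -> HullRegion:
    """Convex hull of ≥3 non-collinear planar points (counterclockwise)."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 3:
        raise DegenerateHullError(
            f"need >= 3 planar points, got shape {pts.shape}")
    try:
        hull = ConvexHull(pts)
    except QhullError as exc:
        raise DegenerateHullError(f"degenerate (collinear) point set: {exc}") from exc
    return HullRegion(vertices=pts[hull.vertices], area=float(hull.volume))


# --- logistic severity curve -------------------------------------------------

def logistic4(bv, a, b, c, d):
    """Four-parameter logistic f(BV) = a/(1 + exp(b(BV − c))) + d."""
    z = np.clip(b * (np.asarray(bv, dtype=float) - c), -700.0, 700.0)
    return a / (1.0 + np.exp(z)) + d


def _logistic4_grad(bv: np.ndarray, a: float, b: float, c: float,
                    d: float) -> np.ndarray:
    """Parameter gradient of the logistic, rows = points, cols = (a,b,c,d)."""
    bv = np.atleast_1d(np.asarray(bv, dtype=float))
    z = np.clip(b * (bv - c), -700.0, 700.0)
    e = np.exp(z)
    denom = (1.0 + e) ** 2
    g = np.empty((len(bv), 4))
    g[:, 0] = 1.0 / (1.0 + e)
    g[:, 1] = -a * (bv - c) * e / denom
    g[:, 2] = a * b * e / denom
    g[:, 3] = 1.0
    return g


@dataclass
class LogisticSeverityResults:
    """Fitted severity curve: estimates, covariance, intervals, summary."""

    params: np.ndarray           # (a, b, c, d)
    covariance: np.ndarray       # 4×4, residual-variance scaled
    residual_sd: float
    n: int
    bv: np.ndarray = field(repr=False)
    y: np.ndarray = field(repr=False)

    param_names = ("a", "b", "c", "d")

    @property
    def bse(self) -> np.ndarray:
        return np.sqrt(np.clip(np.diag(self.covariance), 0.0, None))

    @property
    def asymptotes(self) -> tuple[float, float]:
        """(upper, lower) plateaus: d and a + d for b < 0 orientation."""
        a, _, _, d = self.params
        return float(d), float(a + d)

    def predict(self, bv) -> np.ndarray:
        return logistic4(bv, *self.params)

    def prediction_interval(self, bv, level: float = 0.95
                            ) -> tuple[np.ndarray, np.ndarray]:
        return prediction_interval(self, bv, level)

    def confidence_interval(self, bv, level: float = 0.95
                            ) -> tuple[np.ndarray, np.ndarray]:
        """Delta-method confidence band for the mean curve (no residual term)."""
        if not (0.0 < level < 1.0):
            raise ValueError("level must be in (0, 1)")
        g = _logistic4_grad(bv, *self.params)
        var = np.einsum("ij,jk,ik->i", g, self.covariance, g)
        half = norm.ppf(0.5 + level / 2.0) * np.sqrt(np.clip(var, 0.0, None))
        mean = self.predict(bv)
        return mean - half, mean + half

    def invert(self, lactate: float) -> float:
        return invert_logistic(self, lactate)

    def summary(self) -> str:
        lines = [
            "Logistic severity curve  f(BV) = a/(1 + exp(b(BV - c))) + d",
            f"n = {self.n}    residual sd = {self.residual_sd:.4f}",
            f"{'param':>6} {'estimate':>12} {'std err':>12}",
        ]
        for name, est, se in zip(self.param_names, self.params, self.bse):
            lines.append(f"{name:>6} {est:>12.5g} {se:>12.4g}")
        up, lo = self.asymptotes
        lines.append(f"asymptotes: {up:.4g} (low BV) -> {lo:.4g} (high BV); "
                     f"midpoint f(c) = {self.predict(self.params[2]):.4g}")
        return "\n".join(lines)


class LogisticSeverityModel:
    """Nonlinear least-squares model of lactate vs. maximal blood volume lost.

    Parameters
    ----------
    bv : array-like
        Maximum blood volume lost per patient (axis units are the caller's;
        they are recorded on the results, not rescaled).
    lactate : array-like
        Lactate at the max-curvature (turning) point, mmol/L.
    """

    def __init__(self, bv, lactate):
        self.bv = np.asarray(bv, dtype=float)
        self.y = np.asarray(lactate, dtype=float)
        if self.bv.shape != self.y.shape or self.bv.ndim != 1:
            raise ValueError("bv and lactate must be 1-D arrays of equal length")
        if len(self.bv) < 8:
            raise ValueError("need at least 8 points to fit 4 parameters")
        if np.ptp(self.bv) == 0.0:
            raise ValueError("bv values have no spread")

    @classmethod
    def from_dataframe(cls, df, bv_col: str = "blood_volume_lost",
                       lactate_col: str = "lactate") -> "LogisticSeverityModel":
        return cls(df[bv_col].to_numpy(), df[lactate_col].to_numpy())

    def _start(self) -> np.ndarray:
        y, x = self.y, self.bv
        d0 = float(np.max(y))
        a0 = float(np.min(y) - np.max(y))
        c0 = float(np.median(x))
        trend = np.polyfit(x, y, 1)[0]
        # y rising in x with a < 0 needs b < 0 (and vice versa)
        b0 = -0.5 if trend * a0 > 0 else 0.5
        return np.array([a0, b0, c0, d0])

    def fit(self, p0=None, maxfev: int = 20000) -> LogisticSeverityResults:
        start = np.asarray(p0, dtype=float) if p0 is not None else self._start()
        bounds = ([-np.inf, -10.0, -np.inf, -np.inf],
                  [np.inf, 10.0, np.inf, np.inf])
        try:
            popt, pcov = curve_fit(logistic4, self.bv, self.y, p0=start,
                                   jac=lambda x, *p: _logistic4_grad(x, *p),
                                   bounds=bounds, maxfev=maxfev)
        except RuntimeError as exc:
            raise RuntimeError(f"logistic fit did not converge from {start}: "
                               f"{exc}") from exc
        resid = self.y - logistic4(self.bv, *popt)
        dof = max(len(self.y) - 4, 1)
        residual_sd = float(np.sqrt(resid @ resid / dof))
        return LogisticSeverityResults(params=popt, covariance=pcov,
                                       residual_sd=residual_sd, n=len(self.y),
                                       bv=self.bv, y=self.y)


def fit_logistic(bv, lactate, p0=None) -> LogisticSeverityResults:
    """Fit the four-parameter logistic severity curve (functional wrapper)."""
    return LogisticSeverityModel(bv, lactate).fit(p0=p0)


def prediction_interval(fit: LogisticSeverityResults, bv, level: float = 0.95
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Two-sided normal prediction interval at ``level``.

    Variance is the delta-method curve variance g(bv)ᵀ·Cov·g(bv) plus the
    residual variance (new-observation noise).
    """
    if not (0.0 < level < 1.0):
        raise ValueError(f"level must be in (0, 1), got {level}")
    g = _logistic4_grad(bv, *fit.params)
    var = np.einsum("ij,jk,ik->i", g, fit.covariance, g) + fit.residual_sd ** 2
    half = norm.ppf(0.5 + level / 2.0) * np.sqrt(var)
    mean = logistic4(np.atleast_1d(bv), *fit.params)
    lo, hi = mean - half, mean + half
    if np.ndim(bv) == 0:
        return float(lo[0]), float(hi[0])
    return lo, hi


def invert_logistic(fit: LogisticSeverityResults, lactate: float) -> float:
    """Closed-form inverse: the BV at which the fitted curve equals lactate.

    Valid strictly between the asymptotes d and a + d; used clinically to
    read blood volume lost off a measured serum lactate.
    """
    a, b, c, d = fit.params
    lo, hi = sorted((d, a + d))
    if not (lo < lactate < hi):
        raise ValueError(
            f"lactate {lactate} outside the open range of the curve ({lo:.4g}, "
            f"{hi:.4g})")
    return float(c + math.log(a / (lactate - d) - 1.0) / b)
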