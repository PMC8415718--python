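"""Empirical ROC, binormal smoothing, radial confidence bands, bootstrap CIs.

The binormal model assumes the classifier scores of cases and controls are
each normally distributed, y1 ~ N(mu1, sigma1^2) and y0 ~ N(mu0, sigma0^2).
With a = (mu1 - mu0)/sigma1 and b = sigma0/sigma1 the smoothed curve is
TPR = Phi(a + b Phi^-1(FPR)) and its area is AUC = Phi(a / sqrt(1 + b^2)).
(a, b) are estimated by ordinary least squares of probit(TPR) on probit(FPR)
over the interior empirical ROC vertices (vertices at 0 or 1 have infinite
probits and are dropped).

Confidence bands use a radial sweep: the curve is re-expressed in polar
coordinates about the point (FPR=1, TPR=0), the radius r(theta) is solved on
a theta grid in steps of 0.01 over [0, pi/2], and per-theta percentile bounds
are taken over case-resampling bootstrap refits.  AUC confidence intervals
are percentile intervals over the same bootstrap replicates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "ROCCurve",
    "BinormalFit",
    "RadialBand",
    "InsufficientDataError",
    "empirical_roc",
    "binormal_fit",
    "smoothed_auc",
    "radial_band",
    "auc_ci",
    "THETA_STEP",
]

THETA_STEP = 0.01


class InsufficientDataError(ValueError):
    pass


@dataclass
class ROCCurve:
    thresholds: np.ndarray  # descending; one per distinct score
    fpr: np.ndarray  # starts 0, ends 1, non-decreasing
    tpr: np.ndarray

    @property
    def empirical_auc(self) -> float:
        return float(np.trapezoid(self.tpr, self.fpr))


@dataclass
class BinormalFit:
    a: float
    b: float
    n_points: int

    @property
    def auc(self) -> float:
        return float(stats.norm.cdf(self.a / np.sqrt(1.0 + self.b**2)))

    def tpr_at(self, fpr: np.ndarray) -> np.ndarray:
        """Smoothed curve TPR = Phi(a + b Phi^-1(FPR))."""
        return stats.norm.cdf(self.a + self.b * stats.norm.ppf(fpr))


@dataclass
class RadialBand:
    theta: np.ndarray
    r: np.ndarray
    r_lower: np.ndarray
    r_upper: np.ndarray
    replicates: int
    redraws: int  # single-class / failed bootstrap replicates that were redrawn

    def to_cartesian(self):
        """(FPR, TPR) of the point-estimate curve from the polar form."""
        return 1.0 - self.r * np.cos(self.theta), self.r * np.sin(self.theta)


def _validate_two_class(scores, labels):
    scores = np.asarray(scores, dtype=float).ravel()
    labels = np.asarray(labels).ravel()
    if not set(np.unique(labels)) <= {0, 1}:
        raise ValueError("labels must be binary 0/1")
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must align")
    if labels.sum() == 0 or labels.sum() == len(labels):
        raise ValueError("need at least one observation of each class")
    return scores, labels.astype(int)


def empirical_roc(scores, labels) -> ROCCurve:
    """Empirical ROC with one vertex per distinct score (ties grouped).

    The trapezoidal area under the returned polyline equals the Mann-Whitney
    rank statistic U/(n1*n0) with the usual 1/2 credit for ties.
    """
    scores, labels = _validate_two_class(scores, labels)
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    y = labels[order]
    distinct = np.r_[np.flatnonzero(np.diff(s) != 0), len(s) - 1]
    tps = np.cumsum(y)[distinct]
    fps = (distinct + 1) - tps
    n1 = labels.sum()
    n0 = len(labels) - n1
    return ROCCurve(
        thresholds=s[distinct],
        fpr=np.r_[0.0, fps / n0],
        tpr=np.r_[0.0, tps / n1],
    )


def binormal_fit(roc: ROCCurve) -> BinormalFit:
    """OLS of probit(TPR) on probit(FPR) over interior vertices."""
    mask = (roc.fpr > 0) & (roc.fpr < 1) & (roc.tpr > 0) & (roc.tpr < 1)
    if mask.sum() < 3:
        raise InsufficientDataError(
            f"need >= 3 interior ROC vertices for the probit regression, got {int(mask.sum())}"
        )
    x = stats.norm.ppf(roc.fpr[mask])
    z = stats.norm.ppf(roc.tpr[mask])
    b, a = np.polyfit(x, z, 1)
    if b <= 0:
        raise InsufficientDataError("degenerate probit regression (slope <= 0)")
    return BinormalFit(a=float(a), b=float(b), n_points=int(mask.sum()))


def _theta_grid() -> np.ndarray:
    n = int(np.floor((np.pi / 2) / THETA_STEP)) + 1  # 158 values: 0.00 .. 1.57
    return np.arange(n) * THETA_STEP


def _solve_radii(fit: BinormalFit, theta: np.ndarray) -> np.ndarray:
    """Solve r sin(theta) = Phi(a + b Phi^-1(1 - r cos(theta))) per theta.

    Vectorized bisection; the boundary rays theta = 0 (along the FPR axis) and
    cos(theta) ~ 0 (vertical) are clipped to the axis intersections at r = 1.
    """
    sin_t, cos_t = np.sin(theta), np.cos(theta)
    interior = (sin_t > 1e-9) & (cos_t > 1e-9)
    r = np.ones_like(theta)

    st, ct = sin_t[interior], cos_t[interior]
    r_max = np.minimum(1.0 / ct, 1.0 / st)
    lo = np.full_like(st, 1e-12)
    hi = r_max * (1.0 - 1e-12)

    def g(rr):
        fpr = np.clip(1.0 - rr * ct, 1e-15, 1.0 - 1e-15)
        return rr * st - stats.norm.cdf(fit.a + fit.b * stats.norm.ppf(fpr))

    # g(lo) < 0 (curve is above the ray near the center), g(hi) >= 0
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        neg = g(mid) < 0
        lo = np.where(neg, mid, lo)
        hi = np.where(neg, hi, mid)
    r[interior] = 0.5 * (lo + hi)
    return r


def _bootstrap_fits(scores, labels, replicates, rng, max_redraw_factor=10):
    """Case-resampling bootstrap binormal fits; redraws degenerate replicates."""
    n = len(scores)
    fits = []
    redraws = 0
    budget = max_redraw_factor * replicates
    while len(fits) < replicates:
        idx = rng.integers(0, n, size=n)
        lab = labels[idx]
        if lab.sum() == 0 or lab.sum() == n:
            redraws += 1
        else:
            try:
                fits.append(binormal_fit(empirical_roc(scores[idx], lab)))
            except InsufficientDataError:
                redraws += 1
        if redraws > budget:
            raise RuntimeError("bootstrap kept producing degenerate replicates")
    return fits, redraws


def radial_band(scores, labels, replicates: int = 10_000, seed: int | None = None) -> RadialBand:
    """95% radial confidence band of the binormally smoothed ROC curve."""
    scores, labels = _validate_two_class(scores, labels)
    fit = binormal_fit(empirical_roc(scores, labels))
    theta = _theta_grid()
    r_point = _solve_radii(fit, theta)

    rng = np.random.default_rng(seed)
    fits, redraws = _bootstrap_fits(scores, labels, replicates, rng)
    boot_r = np.empty((replicates, len(theta)))
    for i, f in enumerate(fits):
        boot_r[i] = _solve_radii(f, theta)
    lower = np.percentile(boot_r, 2.5, axis=0)
    upper = np.percentile(boot_r, 97.5, axis=0)
    # sanity clamp: the band must contain the point estimate
    lower = np.minimum(lower, r_point)
    upper = np.maximum(upper, r_point)
    return RadialBand(
        theta=theta,
        r=r_point,
        r_lower=lower,
        r_upper=upper,
        replicates=replicates,
        redraws=redraws,
    )


def smoothed_auc(scores, labels) -> float:
    """Binormally smoothed AUC, falling back to the empirical AUC when the
    probit regression is infeasible (e.g. perfect separation leaves no
    interior vertices, where the smoothed and empirical areas coincide)."""
    roc = empirical_roc(scores, labels)
    try:
        return binormal_fit(roc).auc
    except InsufficientDataError:
        return roc.empirical_auc


def auc_ci(
    scores, labels, replicates: int = 10_000, seed: int | None = None
) -> tuple[float, float, float]:
    """Binormally smoothed AUC with a percentile 95% bootstrap CI."""
    scores, labels = _validate_two_class(scores, labels)
    point = smoothed_auc(scores, labels)
    rng = np.random.default_rng(seed)
    n = len(scores)
    aucs = np.empty(replicates)
    done = 0
    redraws = 0
    while done < replicates:
        idx = rng.integers(0, n, size=n)
        lab = labels[idx]
        if lab.sum() == 0 or lab.sum() == n:
            redraws += 1
            if redraws > 10 * replicates:
                raise RuntimeError("bootstrap kept producing single-class replicates")
            continue
        aucs[done] = smoothed_auc(scores[idx], lab)
        done += 1
    lower, upper = np.percentile(aucs, [2.5, 97.5])
    return point, float(min(lower, point)), float(max(upper, point))
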