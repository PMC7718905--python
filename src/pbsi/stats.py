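"""Non-parametric group-comparison toolkit for PBSI analyses.

Sign conventions, fixed and documented once:

* ``mann_whitney(x, y)`` returns the U statistic of the first sample
  (number of (x, y) pairs with x > y, counting ties as 1/2).  Z is its
  tie-corrected normal deviate with continuity correction: negative Z means
  the first sample is stochastically smaller.
* ``cliffs_delta(x, y)`` is positive when the first sample is
  stochastically larger; ``cliffs_delta(x, y) == -cliffs_delta(y, x)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import scipy.stats as ss
from scipy.stats import rankdata

from pbsi.core import PBSIResult, spearman_rho


def _clean(v, name: str, min_n: int = 1) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    if v.ndim != 1:
        raise ValueError(f"{name} must be 1-D")
    if v.size < min_n:
        raise ValueError(f"{name} needs n >= {min_n}, got {v.size}")
    if not np.isfinite(v).all():
        raise ValueError(f"{name} contains non-finite values")
    return v


class MannWhitneyResult(NamedTuple):
    U: float
    Z: float
    p: float
    n_x: int
    n_y: int


def mann_whitney(x: Sequence[float], y: Sequence[float]) -> MannWhitneyResult:
    """Mann-Whitney U with tie-corrected normal approximation.

    U is computed from pooled midranks.  Z uses the tie-corrected variance
    and a 0.5 continuity correction toward the mean.  The two-sided p-value
    comes from exact enumeration when ``n_x * n_y <= 400`` and the pooled
    data is tie-free, otherwise from the normal approximation.
    """
    x = _clean(x, "x")
    y = _clean(y, "y")
    nx, ny = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    u_x = float(ranks[:nx].sum() - nx * (nx + 1) / 2.0)

    n = nx + ny
    _, counts = np.unique(pooled, return_counts=True)
    has_ties = bool((counts > 1).any())
    tie_term = float(((counts**3 - counts).sum()) / (n * (n - 1))) if n > 1 else 0.0
    sigma2 = nx * ny / 12.0 * ((n + 1) - tie_term)
    mu = nx * ny / 2.0

    if sigma2 <= 0.0:  # every pooled value identical
        return MannWhitneyResult(U=u_x, Z=0.0, p=1.0, n_x=nx, n_y=ny)
    diff = u_x - mu
    cc = 0.5 * np.sign(diff)
    z = (diff - cc) / np.sqrt(sigma2) if diff != 0.0 else 0.0

    if nx * ny <= 400 and not has_ties:
        p = float(ss.mannwhitneyu(x, y, alternative="two-sided", method="exact").pvalue)
    else:
        p = float(min(1.0, 2.0 * ss.norm.sf(abs(z))))
    return MannWhitneyResult(U=u_x, Z=float(z), p=p, n_x=nx, n_y=ny)


def cliffs_delta(x: Sequence[float], y: Sequence[float]) -> float:
    """Cliff's delta: P(X > Y) - P(X < Y) over all cross-group pairs.

    Computed in O(n log n) via binary search on the sorted second sample;
    the result equals the all-pairs definition exactly.
    """
    x = _clean(x, "x")
    y = _clean(y, "y")
    ys = np.sort(y)
    greater = np.searchsorted(ys, x, side="left").sum()   # pairs with x > y
    not_less = np.searchsorted(ys, x, side="right").sum()
    less = x.size * y.size - not_less                      # pairs with x < y
    return float((int(greater) - int(less)) / (x.size * y.size))


def ks_normality(x: Sequence[float]) -> tuple[float, float]:
    """One-sample Kolmogorov-Smirnov statistic against a fitted normal.

    Screens distributions to route group comparisons to a parametric or
    non-parametric test; because mean and sd are estimated from the data
    the p-value is approximate (anti-conservative), which is acceptable
    for routing.
    """
    x = _clean(x, "x", min_n=5)
    sd = float(x.std(ddof=1))
    if sd == 0.0:
        return 1.0, 0.0
    stat, p = ss.kstest(x, "norm", args=(float(x.mean()), sd))
    return float(stat), float(p)


def spearman_assoc(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rho with a t-approximation p-value on n - 2 df."""
    x = _clean(x, "x", min_n=5)
    y = _clean(y, "y", min_n=5)
    if x.size != y.size:
        raise ValueError("length mismatch")
    rho = spearman_rho(x, y)
    if np.isnan(rho):
        return rho, float("nan")
    n = x.size
    if abs(rho) >= 1.0:
        return rho, 0.0
    t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = float(2.0 * ss.t.sf(abs(t), df=n - 2))
    return float(rho), min(1.0, p)


def fdr_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    ``q_(i) = min_{j >= i} p_(j) * m / j`` on the ascending sort, clipped
    at 1.  Output is pointwise >= input.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p must be a non-empty 1-D vector")
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out


@dataclass(frozen=True)
class CVTestResult:
    """Asymptotic (Feltz-Miller) test for equality of coefficients of variation."""

    statistic: float
    df: int
    p_value: float
    cvs: tuple[float, ...]
    n: tuple[int, ...]


def cv_equality_test(samples: Sequence[Sequence[float]]) -> CVTestResult:
    """Feltz-Miller asymptotic chi-square test that k groups share one CV.

    With ``c_i = s_i / mean_i`` (sd with n-1 denominator), weights
    ``m_i = n_i - 1`` and pooled ``c = sum(m_i c_i) / sum(m_i)``, the
    statistic ``sum(m_i (c_i - c)^2) / (c^2 (0.5 + c^2))`` is referred to a
    chi-square distribution with k - 1 degrees of freedom.  The statistic
    is invariant to rescaling all samples by a common positive constant.
    """
    if len(samples) < 2:
        raise ValueError("need >= 2 groups")
    cvs, weights, ns = [], [], []
    for i, sample in enumerate(samples):
        v = _clean(sample, f"samples[{i}]", min_n=2)
        mean = float(v.mean())
        if mean <= 0.0:
            raise ValueError(f"samples[{i}] has non-positive mean; CV undefined")
        cvs.append(float(v.std(ddof=1)) / mean)
        weights.append(v.size - 1)
        ns.append(v.size)
    cvs_arr = np.asarray(cvs)
    m = np.asarray(weights, dtype=float)
    pooled = float((m * cvs_arr).sum() / m.sum())
    df = len(samples) - 1
    if pooled == 0.0 or np.ptp(cvs_arr) == 0.0:  # no dispersion, or all CVs identical
        return CVTestResult(0.0, df, 1.0, tuple(cvs), tuple(ns))
    stat = float((m * (cvs_arr - pooled) ** 2).sum() / (pooled**2 * (0.5 + pooled**2)))
    p = float(ss.chi2.sf(stat, df))
    return CVTestResult(stat, df, p, tuple(cvs), tuple(ns))


def tukey_inlier_mask(values: Sequence[float], k: float = 1.5) -> np.ndarray:
    """Boolean mask of points inside the Tukey fences (quartiles +/- k*IQR)."""
    v = np.asarray(values, dtype=float)
    q25, q75 = np.percentile(v, [25, 75])
    iqr = q75 - q25
    return (v >= q25 - k * iqr) & (v <= q75 + k * iqr)


@dataclass
class GroupComparison:
    """Two-group contrast of PBSI scores with and without outlier trimming.

    Orientation: negative Z / negative d mean group A is stochastically
    smaller than group B.  ``p_adj`` is NaN until the caller applies FDR
    across its declared family of contrasts.
    """

    contrast: tuple[str, str, str]  # (label A, label B, variable)
    U: float
    Z: float
    p_raw: float
    cliffs_d: float
    n_A: int
    n_B: int
    p_adj: float = float("nan")
    trimmed: dict = field(default_factory=dict)

    def to_row(self) -> dict:
        a, b, variable = self.contrast
        row = {
            "group_a": a, "group_b": b, "variable": variable,
            "U": self.U, "Z": self.Z, "p_raw": self.p_raw, "p_adj": self.p_adj,
            "cliffs_d": self.cliffs_d, "n_a": self.n_A, "n_b": self.n_B,
        }
        row.update({f"{k}_trimmed": v for k, v in self.trimmed.items()})
        return row


def compare_samples(
    x: Sequence[float],
    y: Sequence[float],
    contrast: tuple[str, str, str],
    outlier_k: float | None = 1.5,
) -> GroupComparison:
    """Mann-Whitney + Cliff's delta on two score vectors.

    Reported twice: on all subjects, and after removing per-group Tukey-fence
    outliers (``outlier_k`` times the IQR; ``None`` disables trimming).
    """
    x = _clean(x, "x")
    y = _clean(y, "y")
    mw = mann_whitney(x, y)
    d = cliffs_delta(x, y)
    comparison = GroupComparison(
        contrast=contrast, U=mw.U, Z=mw.Z, p_raw=mw.p,
        cliffs_d=d, n_A=mw.n_x, n_B=mw.n_y,
    )
    if outlier_k is not None:
        xt = x[tukey_inlier_mask(x, outlier_k)]
        yt = y[tukey_inlier_mask(y, outlier_k)]
        if xt.size >= 1 and yt.size >= 1:
            mwt = mann_whitney(xt, yt)
            comparison.trimmed = {
                "U": mwt.U, "Z": mwt.Z, "p_raw": mwt.p,
                "cliffs_d": cliffs_delta(xt, yt),
                "n_a": int(xt.size), "n_b": int(yt.size),
            }
    return comparison


def compare_pbsi(
    result_a: PBSIResult,
    result_b: PBSIResult,
    outlier_k: float | None = 1.5,
    cross_site: bool = False,
) -> GroupComparison:
    """Contrast the PBSI scores of two cells sharing modality (and site).

    Comparing cells from different sites requires ``cross_site=True``;
    different modalities are never comparable.
    """
    group_a, site_a, mod_a = result_a.cell
    group_b, site_b, mod_b = result_b.cell
    if mod_a != mod_b:
        raise ValueError(f"cannot compare modalities {mod_a} vs {mod_b}")
    if site_a != site_b and not cross_site:
        raise ValueError(
            f"cells come from different sites ({site_a} vs {site_b}); "
            "pass cross_site=True to override"
        )
    x = result_a.scores.dropna().to_numpy()
    y = result_b.scores.dropna().to_numpy()
    label_a = group_a if site_a == site_b else f"{group_a}@{site_a}"
    label_b = group_b if site_a == site_b else f"{group_b}@{site_b}"
    return compare_samples(x, y, (label_a, label_b, f"pbsi_{mod_a}"), outlier_k=outlier_k)
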