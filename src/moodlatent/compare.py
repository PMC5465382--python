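"""Cohort comparison of component scores: kernel density estimates,
two-sample Kolmogorov-Smirnov tests and symmetric Kullback-Leibler
divergence.

Component-score distributions in clinical cohorts are typically
non-Gaussian (mixtures of mood states), so effect sizes are a poor summary
of cohort separation.  Instead the scores of each cohort are turned into a
Gaussian-kernel density estimate and pairs of cohorts are compared with

* the two-sample KS statistic ``D = sup |ECDF_a - ECDF_b|`` with its
  two-sided p-value (a distribution-free test of "same underlying
  continuous distribution"), and
* the symmetric Kullback-Leibler divergence
  ``KL(p||q) + KL(q||p)`` evaluated by trapezoid quadrature on a shared
  grid (a ``"mean"`` variant halves the sum).

Medians and interquartile ranges summarize each cohort's score location
and spread (linear-interpolation quantile convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DegenerateSampleError, ValidationError

__all__ = [
    "DensityEstimate",
    "DivergenceReport",
    "project",
    "kde",
    "ks_two_sample",
    "symmetric_kl",
    "summarize",
    "divergence_report",
]

GRID_POINTS = 512
GRID_PAD_BANDWIDTHS = 3.0
DENSITY_FLOOR = 1e-12


@dataclass
class DensityEstimate:
    """A Gaussian-kernel density on a regular grid.

    ``grid`` is strictly increasing; ``density`` is nonnegative and
    trapezoid-integrates to 1 within 1e-6; ``bandwidth`` is the kernel
    standard deviation; ``n`` the sample count.  ``point_mass`` flags the
    degenerate fallback (zero-variance sample) where no smooth density
    exists.
    """

    grid: np.ndarray
    density: np.ndarray
    bandwidth: float
    n: int
    point_mass: bool = False


def project(X, w: np.ndarray) -> np.ndarray:
    """Component scores: the linear combination of item columns by a
    loading vector, one score per sample row."""
    from .latent import _as_array

    A = _as_array(X)
    w = np.asarray(w, dtype=float)
    if w.shape != (A.shape[1],):
        raise ValidationError(
            f"loading length {w.shape[0] if w.ndim == 1 else w.shape} "
            f"does not match {A.shape[1]} items"
        )
    return A @ w


def kde(
    sample,
    bandwidth_rule: str | float = "silverman",
    *,
    grid_points: int = GRID_POINTS,
    allow_degenerate: bool = False,
) -> DensityEstimate:
    """Gaussian kernel density estimate of a 1-D sample.

    The grid spans ``[min - 3h, max + 3h]`` with 512 points (h = kernel
    bandwidth, Silverman's rule by default) and the evaluated density is
    renormalized so its trapezoid integral is exactly 1.

    A sample with fewer than 2 points or zero variance has no smooth
    density; by default this raises :class:`DegenerateSampleError`, or with
    ``allow_degenerate=True`` returns a ``point_mass`` estimate
    concentrated at the sample value.
    """
    x = np.asarray(sample, dtype=float).ravel()
    if x.size and not np.all(np.isfinite(x)):
        raise ValidationError("sample contains non-finite values")
    if x.size < 2 or np.std(x) == 0:
        if not allow_degenerate:
            raise DegenerateSampleError(
                f"sample of size {x.size} with zero spread has no density"
            )
        loc = float(x[0]) if x.size else 0.0
        grid = np.linspace(loc - 1.0, loc + 1.0, grid_points)
        density = np.zeros(grid_points)
        density[grid_points // 2] = 1.0
        density /= np.trapezoid(density, grid)
        return DensityEstimate(grid=grid, density=density, bandwidth=0.0,
                               n=int(x.size), point_mass=True)

    k = stats.gaussian_kde(x, bw_method=bandwidth_rule)
    h = float(np.sqrt(k.covariance[0, 0]))
    grid = np.linspace(
        x.min() - GRID_PAD_BANDWIDTHS * h,
        x.max() + GRID_PAD_BANDWIDTHS * h,
        grid_points,
    )
    density = k(grid)
    density = np.maximum(density, 0.0)
    density /= np.trapezoid(density, grid)
    return DensityEstimate(grid=grid, density=density, bandwidth=h, n=x.size)


def ks_two_sample(a, b, *, exact_below: int = 25) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test.

    Uses the asymptotic Kolmogorov distribution for the p-value (sample
    sizes in this application are in the thousands); switches to the exact
    small-sample distribution when both samples are below ``exact_below``.
    Returns ``(D, p)``.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size < 2 or b.size < 2:
        raise ValidationError("both samples need n >= 2")
    method = "exact" if (a.size < exact_below and b.size < exact_below) else "asymp"
    res = stats.ks_2samp(a, b, method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def _reevaluate(d: DensityEstimate, grid: np.ndarray) -> np.ndarray:
    p = np.interp(grid, d.grid, d.density, left=0.0, right=0.0)
    p = np.maximum(p, DENSITY_FLOOR)
    return p / np.trapezoid(p, grid)


def symmetric_kl(
    da: DensityEstimate,
    db: DensityEstimate,
    variant: str = "sum",
    *,
    grid_points: int = GRID_POINTS,
) -> float:
    """Symmetric Kullback-Leibler divergence between two density estimates.

    Both densities are re-evaluated (linear interpolation, zero outside
    their own grid) on a shared grid spanning the union of the two
    supports, floored at 1e-12 and renormalized; the two directed
    divergences are computed by trapezoid quadrature.  ``variant="sum"``
    returns ``KL(p||q) + KL(q||p)``; ``variant="mean"`` halves it.
    """
    if variant not in ("sum", "mean"):
        raise ValidationError(f"variant must be 'sum' or 'mean', got {variant!r}")
    lo = min(da.grid[0], db.grid[0])
    hi = max(da.grid[-1], db.grid[-1])
    grid = np.linspace(lo, hi, grid_points)
    p = _reevaluate(da, grid)
    q = _reevaluate(db, grid)
    kl_pq = float(np.trapezoid(p * np.log(p / q), grid))
    kl_qp = float(np.trapezoid(q * np.log(q / p), grid))
    total = max(kl_pq + kl_qp, 0.0)
    return 0.5 * total if variant == "mean" else total


def summarize(sample) -> tuple[float, float]:
    """Median and interquartile range (Q3 - Q1, linear-interpolation
    quantiles) of a sample."""
    x = np.asarray(sample, dtype=float).ravel()
    if x.size < 1:
        raise ValidationError("sample must be non-empty")
    q1, med, q3 = np.percentile(x, [25, 50, 75], method="linear")
    return float(med), float(q3 - q1)


@dataclass
class DivergenceReport:
    """Per-component cohort comparison.

    ``summaries``: rows (component, cohort, median, iqr, n).
    ``pairwise``: rows (component, cohort_a, cohort_b, ks_statistic,
    ks_p_value, symmetric_kl).
    """

    summaries: pd.DataFrame
    pairwise: pd.DataFrame
    kl_variant: str = "sum"
    bandwidth_rule: str | float = "silverman"

    def to_table(self) -> pd.DataFrame:
        """Wide summary table: one row per component, per-cohort
        'median (IQR)' columns followed by the pairwise divergences."""
        rows = {}
        for comp, group in self.summaries.groupby("component", sort=False):
            row = {
                f"{r.cohort} median (IQR)": f"{r.median:.2f} ({r.iqr:.2f})"
                for r in group.itertuples()
            }
            rows[comp] = row
        for r in self.pairwise.itertuples():
            rows.setdefault(r.component, {})[
                f"{r.cohort_a} vs {r.cohort_b} (divergence)"
            ] = round(r.symmetric_kl, 2)
        return pd.DataFrame.from_dict(rows, orient="index")


def divergence_report(
    scores_by_cohort: dict[str, dict[str, np.ndarray]],
    *,
    kl_variant: str = "sum",
    bandwidth_rule: str | float = "silverman",
) -> DivergenceReport:
    """Build a :class:`DivergenceReport` from per-component, per-cohort
    score samples.

    Parameters
    ----------
    scores_by_cohort : mapping component label -> {cohort -> score sample}

    Degenerate (zero-variance) cohort samples are summarized but excluded
    from KDE-based divergences (the KS test, which needs no density, is
    still reported).
    """
    summary_rows, pair_rows = [], []
    for comp, cohorts in scores_by_cohort.items():
        names = list(cohorts)
        densities: dict[str, DensityEstimate | None] = {}
        for name in names:
            s = np.asarray(cohorts[name], dtype=float)
            med, iqr = summarize(s)
            summary_rows.append(
                {"component": comp, "cohort": name, "median": med,
                 "iqr": iqr, "n": s.size}
            )
            try:
                densities[name] = kde(s, bandwidth_rule)
            except DegenerateSampleError:
                densities[name] = None
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                a, b = names[i], names[j]
                d_stat, p = ks_two_sample(cohorts[a], cohorts[b])
                if densities[a] is not None and densities[b] is not None:
                    skl = symmetric_kl(densities[a], densities[b], kl_variant)
                else:
                    skl = float("nan")
                pair_rows.append(
                    {"component": comp, "cohort_a": a, "cohort_b": b,
                     "ks_statistic": d_stat, "ks_p_value": p,
                     "symmetric_kl": skl}
                )
    return DivergenceReport(
        summaries=pd.DataFrame(summary_rows),
        pairwise=pd.DataFrame(pair_rows),
        kl_variant=kl_variant,
        bandwidth_rule=bandwidth_rule,
    )
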