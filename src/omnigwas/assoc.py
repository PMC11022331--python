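"""Statistical core: omnibus multi-trait test, trans-ancestry extension,
fixed-effect meta-analysis z, sample-size downscaling, genomic inflation.

The omnibus test asks whether a SNP is associated with *any* linear
combination of k traits. With z the SNP's vector of per-trait z-scores
and Omega the residual covariance of z under the null (phenotype
correlation plus sample overlap),

    T = z' Omega^{-1} z   ~   chi2(k)   under the null.

Because cohorts of different ancestries are independent, per-ancestry
omnibus statistics add, and the sum follows chi2(sum of per-ancestry k)
— the trans-ancestry omnibus. A fixed-effect univariate counterpart
combines per-ancestry z with sqrt(sample-size) weights.

All p-values are carried as -log10(p) computed in log space, so
p < 1e-300 stays representable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.linalg import cho_factor, cho_solve

from .containers import ZPanel
from .nullcov import NullCovariance

__all__ = [
    "TestResult",
    "omnibus_test",
    "omnibus_scan",
    "trans_omnibus",
    "trans_scan",
    "meta_z",
    "scale_z",
    "min_univariate_p",
    "univariate_log10p",
    "genomic_inflation",
]

LN10 = np.log(10.0)


@dataclass
class TestResult:
    """A chi-square test outcome with a tail-safe -log10 p."""

    statistic: float
    df: int
    p: float
    log10p: float


def _chi2_log10p(statistic: np.ndarray | float, df: np.ndarray | int) -> np.ndarray | float:
    """-log10 of the chi-square upper tail, computed in log space."""
    return -stats.chi2.logsf(statistic, df) / LN10


def _finish(statistic: float, df: int) -> TestResult:
    log10p = float(_chi2_log10p(statistic, df))
    return TestResult(statistic=float(statistic), df=int(df),
                      p=float(stats.chi2.sf(statistic, df)), log10p=log10p)


def _omega_matrix(cov: NullCovariance | np.ndarray) -> np.ndarray:
    return cov.omega if isinstance(cov, NullCovariance) else np.asarray(cov, dtype=float)


def omnibus_test(z: np.ndarray, cov: NullCovariance | np.ndarray) -> TestResult:
    """Joint chi-square test of one SNP across k traits: T = z' Omega^-1 z.

    The quadratic form is evaluated through a Cholesky solve, never an
    explicit inverse. A singular Omega raises with a pointer to the
    conditioning diagnostics.
    """
    z = np.asarray(z, dtype=float)
    if not np.isfinite(z).all():
        raise ValueError("z contains non-finite values; drop masked traits first")
    omega = _omega_matrix(cov)
    try:
        factor = cho_factor(omega)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            "omega is singular or not positive definite; run check_condition / "
            "regularize before testing"
        ) from err
    statistic = float(z @ cho_solve(factor, z))
    return _finish(statistic, len(z))


def omnibus_scan(
    panel: ZPanel | np.ndarray,
    cov: NullCovariance | np.ndarray,
    mask: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized omnibus test over every SNP of a panel.

    SNPs with masked (missing) traits are tested on the sub-vector and
    sub-matrix of present traits, so the degrees of freedom adapt per
    SNP rather than padding zeros (zeros would deflate the statistic).

    Returns ``(statistic, df, log10p)`` arrays of length n_snps.
    """
    if isinstance(panel, ZPanel):
        z = panel.z
        mask = panel.mask if mask is None else mask
    else:
        z = np.asarray(panel, dtype=float)
        if mask is None:
            mask = np.isfinite(z)
    omega = _omega_matrix(cov)
    n, k = z.shape
    statistic = np.full(n, np.nan)
    df = np.zeros(n, dtype=int)

    # group SNPs by missingness pattern: one factorization per pattern
    pattern_codes = mask @ (1 << np.arange(k, dtype=object))
    for code in np.unique(pattern_codes):
        rows = np.flatnonzero(pattern_codes == code)
        cols = np.flatnonzero(mask[rows[0]])
        if cols.size == 0:
            continue
        sub = omega[np.ix_(cols, cols)]
        factor = cho_factor(sub)
        zz = z[np.ix_(rows, cols)]
        statistic[rows] = np.einsum("ij,ij->i", zz, cho_solve(factor, zz.T).T)
        df[rows] = cols.size

    log10p = np.full(n, np.nan)
    ok = df > 0
    log10p[ok] = _chi2_log10p(statistic[ok], df[ok])
    return statistic, df, log10p


def trans_omnibus(
    per_ancestry: list[tuple[np.ndarray, NullCovariance | np.ndarray]],
) -> TestResult:
    """Trans-ancestry omnibus: sum of independent per-ancestry statistics.

    Ancestry cohorts are assumed sample-independent (the caller's
    responsibility), so the sum of the per-ancestry quadratic forms
    follows chi-square with the summed degrees of freedom; trait counts
    may differ between ancestries.
    """
    if not per_ancestry:
        raise ValueError("at least one ancestry required")
    total, df = 0.0, 0
    for z, cov in per_ancestry:
        res = omnibus_test(z, cov)
        total += res.statistic
        df += res.df
    return _finish(total, df)


def trans_scan(
    panels: list[tuple[np.ndarray, NullCovariance | np.ndarray, np.ndarray | None]],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized trans-ancestry omnibus over aligned SNP rows.

    ``panels`` is a list of ``(z, omega, mask)`` per ancestry, all with
    the same number of rows (align SNPs beforehand; use an all-False
    mask row for SNPs absent from an ancestry). Returns
    ``(statistic, df, log10p)``.
    """
    total = None
    df_total = None
    for z, cov, mask in panels:
        statistic, df, _ = omnibus_scan(np.asarray(z, dtype=float), cov, mask=mask)
        statistic = np.nan_to_num(statistic, nan=0.0)
        total = statistic if total is None else total + statistic
        df_total = df if df_total is None else df_total + df
    log10p = np.full(total.shape, np.nan)
    ok = df_total > 0
    log10p[ok] = _chi2_log10p(total[ok], df_total[ok])
    return total, df_total, log10p


def meta_z(z_a: np.ndarray, n_a: np.ndarray) -> float | np.ndarray:
    """Sample-size-weighted fixed-effect meta-analysis z across ancestries.

        Z_meta = sum_a sqrt(N_a) z_a / sqrt(sum_a N_a)

    ``z_a`` may be 1-D (one SNP) or 2-D (SNP rows x ancestry columns);
    NaN entries mark SNPs absent from an ancestry and contribute
    nothing — the weights renormalize over present ancestries.
    """
    z_a = np.asarray(z_a, dtype=float)
    n_a = np.asarray(n_a, dtype=float)
    present = np.isfinite(z_a)
    if not present.any():
        raise ValueError("SNP missing from every ancestry")
    w = np.sqrt(n_a) * present
    num = np.nansum(w * np.where(present, z_a, 0.0), axis=-1)
    den = np.sqrt(np.sum(n_a * present, axis=-1))
    if np.ndim(den) > 0 and (den == 0).any():
        raise ValueError("SNP missing from every ancestry")
    return num / den


def scale_z(z: np.ndarray | float, n_total: float, n_simulated: float) -> np.ndarray | float:
    """Rescale z-scores to a smaller simulated sample size.

        Z_sim = Z / sqrt(N_total) * sqrt(N_sim)

    Used to ask how a strongly-powered cohort would look at the sample
    size of a smaller one; downstream p-values are recomputed from the
    scaled z.
    """
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not 0 <= n_simulated <= n_total:
        raise ValueError("n_simulated must lie in [0, n_total]")
    return np.asarray(z, dtype=float) * np.sqrt(n_simulated / n_total) if np.ndim(z) \
        else float(z) * np.sqrt(n_simulated / n_total)


def univariate_log10p(z: np.ndarray) -> np.ndarray:
    """Two-sided normal -log10 p for each z, tail-safe."""
    z = np.asarray(z, dtype=float)
    return -(np.log(2.0) + stats.norm.logsf(np.abs(z))) / LN10


def min_univariate_p(z_row: np.ndarray, traits: list[str] | None = None,
                     mask: np.ndarray | None = None) -> tuple[float, float, str | int]:
    """Minimum two-sided univariate p across traits, uncorrected.

    Returns ``(p, log10p, trait)`` where ``trait`` is the label (or
    column index) attaining the minimum. No multiple-testing correction
    is applied — the convention used when contrasting joint-only
    discoveries with everything any univariate analysis would report.
    """
    z_row = np.asarray(z_row, dtype=float)
    if mask is None:
        mask = np.isfinite(z_row)
    if not mask.any():
        raise ValueError("all traits masked at this SNP")
    idx = np.flatnonzero(mask)
    logs = univariate_log10p(z_row[idx])
    best = idx[int(np.argmax(logs))]
    log10p = float(np.max(logs))
    label = traits[best] if traits is not None else int(best)
    return float(10.0 ** (-log10p)), log10p, label


def genomic_inflation(statistics: np.ndarray, df: int) -> float:
    """Genomic inflation factor: median observed over median expected chi2.

    lambda ~ 1 indicates calibrated type-I error; substantially above 1
    signals confounding or a misspecified null covariance.
    """
    statistics = np.asarray(statistics, dtype=float)
    statistics = statistics[np.isfinite(statistics)]
    if statistics.size < 1000:
        raise ValueError("need at least 1000 statistics for a stable median")
    return float(np.median(statistics) / stats.chi2.median(df))
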