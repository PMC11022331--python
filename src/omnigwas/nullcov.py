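"""Residual z-score covariance under the null: the omnibus test's key input.

At null SNPs the cross-trait covariance of GWAS z-scores is not the
identity: correlated phenotypes measured on overlapping samples induce

    Omega_ij = rho_ij * n_s / sqrt(n_i * n_j)

where rho_ij is the total phenotypic covariance of traits i and j, n_s
the number of samples the two studies share, and n_i, n_j the study
sample sizes. When every sample is shared, Omega reduces to the Pearson
correlation matrix of the phenotypes.

Overlap counts are rarely public, so Omega is routinely estimated from
the summary statistics themselves by cross-trait LD-score regression:
regressing z_i * z_j on the per-SNP LD score, the intercept isolates
the overlap/confounding term from polygenic signal (which scales with
the LD score).

An ill-conditioned Omega — nearly collinear traits measured on heavily
overlapping samples — makes the quadratic form unstable and can inflate
the test; `check_condition` flags that situation and `regularize`
offers an explicit, logged shrinkage remedy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm

from .containers import ZPanel

__all__ = [
    "OverlapModel",
    "NullCovariance",
    "ConditionReport",
    "omega_from_overlap",
    "estimate_omega_ldsc",
    "check_condition",
    "regularize",
]

logger = logging.getLogger(__name__)


@dataclass
class OverlapModel:
    """Phenotypic covariance plus the sample-overlap bookkeeping.

    ``rho`` is the k x k total phenotypic covariance (correlation matrix
    for standardized traits), ``n_s`` the pairwise shared-sample counts
    and ``n`` the per-study sample sizes.
    """

    rho: np.ndarray
    n_s: np.ndarray
    n: np.ndarray

    def __post_init__(self) -> None:
        self.rho = np.asarray(self.rho, dtype=float)
        self.n_s = np.asarray(self.n_s, dtype=float)
        self.n = np.asarray(self.n, dtype=float)
        k = len(self.n)
        if self.rho.shape != (k, k) or self.n_s.shape != (k, k):
            raise ValueError("rho and n_s must be k x k for k sample sizes")
        if not np.allclose(self.rho, self.rho.T, atol=1e-10):
            raise ValueError("rho must be symmetric")
        if (self.n <= 0).any():
            raise ValueError("sample sizes must be positive")
        upper = np.minimum.outer(self.n, self.n)
        if (self.n_s < 0).any() or (self.n_s > upper + 1e-9).any():
            raise ValueError("shared counts must satisfy 0 <= n_s <= min(n_i, n_j)")


@dataclass
class NullCovariance:
    """A k x k residual z-score covariance with provenance.

    ``provenance`` records how the matrix was obtained: ``formula``
    (overlap model), ``ldsc-intercept`` (estimated from summary stats)
    or ``direct`` (supplied). ``se`` carries entrywise jackknife
    standard errors when available.
    """

    omega: np.ndarray
    traits: list[str]
    provenance: str = "direct"
    condition_number: float = field(default=np.nan)
    se: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.omega = np.asarray(self.omega, dtype=float)
        k = self.omega.shape[0]
        if self.omega.shape != (k, k):
            raise ValueError("omega must be square")
        if not np.allclose(self.omega, self.omega.T, atol=1e-8):
            raise ValueError("omega must be symmetric")
        self.omega = (self.omega + self.omega.T) / 2.0
        if len(self.traits) != k:
            raise ValueError("trait labels do not match omega dimension")
        diag = np.diag(self.omega)
        if (diag < 0.5).any() or (diag > 2.0).any():
            logger.warning(
                "omega diagonal outside [0.5, 2] (range %.3f-%.3f); residual "
                "variance estimates look implausible", diag.min(), diag.max()
            )
        if np.isnan(self.condition_number):
            eig = np.linalg.eigvalsh(self.omega)
            self.condition_number = float(eig[-1] / eig[0]) if eig[0] > 0 else np.inf

    @property
    def k(self) -> int:
        return self.omega.shape[0]

    def subset(self, trait_idx: np.ndarray) -> "NullCovariance":
        trait_idx = np.asarray(trait_idx)
        return NullCovariance(
            omega=self.omega[np.ix_(trait_idx, trait_idx)],
            traits=[self.traits[i] for i in trait_idx],
            provenance=self.provenance,
        )


def omega_from_overlap(model: OverlapModel) -> NullCovariance:
    """Closed-form null covariance from phenotype covariance and overlap.

    Omega_ij = rho_ij * n_s(i, j) / sqrt(n_i * n_j); with full overlap
    and standardized traits this is exactly the Pearson correlation
    matrix of the phenotypes.
    """
    scale = model.n_s / np.sqrt(np.outer(model.n, model.n))
    omega = model.rho * scale
    k = len(model.n)
    return NullCovariance(
        omega=omega,
        traits=[f"trait_{i + 1}" for i in range(k)],
        provenance="formula",
    )


def _wls_fit(x: np.ndarray, y: np.ndarray, weights: np.ndarray) -> tuple[float, float]:
    design = sm.add_constant(x)
    res = sm.WLS(y, design, weights=weights).fit()
    return float(res.params[0]), float(res.params[1])


def _jackknife_intercept_se(
    x: np.ndarray, y: np.ndarray, w: np.ndarray, n_blocks: int
) -> float:
    """Delete-one block jackknife SE of the WLS intercept over contiguous blocks."""
    n = len(x)
    design = np.column_stack([np.ones(n), x])
    wd = design * w[:, None]
    xtx_total = design.T @ wd
    xty_total = wd.T @ y
    edges = np.linspace(0, n, n_blocks + 1).astype(int)
    intercepts = []
    for b in range(n_blocks):
        sl = slice(edges[b], edges[b + 1])
        if sl.start == sl.stop:
            continue
        xtx = xtx_total - design[sl].T @ wd[sl]
        xty = xty_total - wd[sl].T @ y[sl]
        try:
            params = np.linalg.solve(xtx, xty)
        except np.linalg.LinAlgError:
            continue
        intercepts.append(params[0])
    intercepts = np.asarray(intercepts)
    m = len(intercepts)
    if m < 2:
        return np.nan
    return float(np.sqrt((m - 1) / m * np.sum((intercepts - intercepts.mean()) ** 2)))


def estimate_omega_ldsc(
    panel: ZPanel,
    scores: np.ndarray,
    n_jackknife_blocks: int = 200,
    force_unit_diagonal: bool = False,
    chisq_max: float = 80.0,
) -> NullCovariance:
    """Estimate Omega as the intercepts of cross-trait LD-score regressions.

    For every trait pair (i, j), z_i * z_j is regressed on the per-SNP
    LD score by weighted least squares; the intercept estimates
    Omega_ij, while polygenic signal loads on the slope. Diagonal
    entries come from the same regression on z_i**2, so residual
    inflation is absorbed into Omega rather than the statistic (pass
    ``force_unit_diagonal=True`` for strict unit-variance semantics).

    Weights follow standard LD-score-regression practice: a first
    unweighted pass predicts the variance of the product regressand,
    var(z_i z_j) ~ (a_i + b_i l)(a_j + b_j l) + (a_ij + b_ij l)^2, and
    a second pass reweights by its inverse times the 1/l overcounting
    correction (SNPs in strong LD carry redundant information).
    Following standard practice, SNPs with z^2 above ``chisq_max``
    (outliers a polygenic regression cannot absorb — strong single
    loci) are excluded trait-wise from the fit. Standard errors come
    from a delete-one block jackknife over contiguous SNP blocks.
    """
    scores = np.asarray(scores, dtype=float)
    if panel.n_snps < 2000:
        raise ValueError("need at least 2000 scored SNPs for a stable intercept")
    if scores.shape[0] != panel.n_snps:
        raise ValueError("scores length must match panel SNPs")
    if np.ptp(scores) == 0:
        raise ValueError("degenerate regression: LD scores are constant")

    k = panel.n_traits
    z = panel.z
    with np.errstate(invalid="ignore"):
        mask = panel.mask & ~(z**2 > chisq_max)
    omega = np.eye(k)
    se = np.full((k, k), np.nan)

    overcount = 1.0 / np.clip(scores, 1.0, None)

    # univariate pass: per-trait intercept/slope for the variance model
    uni: list[tuple[float, float]] = []
    for i in range(k):
        rows = mask[:, i]
        y = z[rows, i] ** 2
        x = scores[rows]
        a0, b0 = _wls_fit(x, y, np.ones_like(x))
        v = np.clip(a0 + b0 * x, 0.05, None)
        w = overcount[rows] / (2.0 * v**2)
        a, b = _wls_fit(x, y, w)
        uni.append((a, b))
        omega[i, i] = a
        se[i, i] = _jackknife_intercept_se(x, y, w, n_jackknife_blocks)

    for i in range(k):
        for j in range(i + 1, k):
            rows = mask[:, i] & mask[:, j]
            if rows.sum() < 2000:
                raise ValueError(
                    f"fewer than 2000 SNPs shared by traits {i} and {j}"
                )
            x = scores[rows]
            y = z[rows, i] * z[rows, j]
            a0, b0 = _wls_fit(x, y, np.ones_like(x))
            vi = np.clip(uni[i][0] + uni[i][1] * x, 0.05, None)
            vj = np.clip(uni[j][0] + uni[j][1] * x, 0.05, None)
            var = vi * vj + (a0 + b0 * x) ** 2
            w = overcount[rows] / var
            a, _ = _wls_fit(x, y, w)
            omega[i, j] = omega[j, i] = a
            se[i, j] = se[j, i] = _jackknife_intercept_se(x, y, w,
                                                          n_jackknife_blocks)

    if force_unit_diagonal:
        np.fill_diagonal(omega, 1.0)
    return NullCovariance(omega=omega, traits=list(panel.traits),
                          provenance="ldsc-intercept", se=se)


@dataclass
class ConditionReport:
    """Conditioning diagnostic for a null covariance."""

    condition_number: float
    eigen_min: float
    eigen_max: float
    threshold: float
    flagged: bool

    def to_dict(self) -> dict:
        return {
            "condition_number": self.condition_number,
            "eigen_min": self.eigen_min,
            "eigen_max": self.eigen_max,
            "threshold": self.threshold,
            "flagged": self.flagged,
        }


def check_condition(cov: NullCovariance, threshold: float = 1e4) -> ConditionReport:
    """Diagnose near-collinearity of the null covariance.

    A condition number (ratio of extreme eigenvalues) above the
    threshold marks a null that lacks robustness: small errors in Omega
    are amplified by the quadratic form and can masquerade as genome-
    wide signal. Flagged matrices should be regularized explicitly or
    the analysis abandoned for that trait set.
    """
    eig = np.linalg.eigvalsh(cov.omega)
    cond = float(eig[-1] / eig[0]) if eig[0] > 0 else np.inf
    flagged = not np.isfinite(cond) or cond > threshold
    if flagged:
        logger.warning(
            "omega condition number %.3g exceeds %.3g: omnibus statistics on "
            "this matrix are unreliable", cond, threshold
        )
    return ConditionReport(condition_number=cond, eigen_min=float(eig[0]),
                           eigen_max=float(eig[-1]), threshold=threshold,
                           flagged=flagged)


def regularize(cov: NullCovariance, lam: float) -> NullCovariance:
    """Shrink Omega toward the identity: Omega' = (1 - lambda) Omega + lambda I.

    Opt-in remedy for an ill-conditioned matrix; the provenance string
    records the shrinkage so downstream reports show it was applied.
    """
    if not 0.0 <= lam <= 1.0:
        raise ValueError("lambda must lie in [0, 1]")
    omega = (1.0 - lam) * cov.omega + lam * np.eye(cov.k)
    out = NullCovariance(omega=omega, traits=list(cov.traits),
                         provenance=f"{cov.provenance}+ridge({lam:g})")
    logger.info("regularized omega with lambda=%g: condition %.3g -> %.3g",
                lam, cov.condition_number, out.condition_number)
    return out
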