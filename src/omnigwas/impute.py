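"""LD-based z-score imputation for untyped SNPs (RAISS-style).

Under the null (and to first order under sparse signal), the z-scores
of SNPs in a region are jointly multivariate normal with covariance
equal to the LD correlation matrix. The conditional expectation of an
untyped SNP u given typed neighbors t is therefore

    z_hat_u = Sigma_ut @ Sigma_tt^+ @ z_t

with imputation quality (the fraction of the variance of z_u the typed
set explains)

    r2_u = Sigma_ut @ Sigma_tt^+ @ Sigma_tu.

``Sigma_tt^+`` is an eigenvalue-truncated pseudo-inverse: eigenvalues
below ``eigen_threshold`` times the largest are discarded, guarding
against noise amplification from near-singular LD. SNPs whose quality
falls below ``r2_threshold``, or with fewer than ``minimum_ld``
informative typed neighbors (|r| > 0.2), are left missing rather than
imputed badly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import eigh
from scipy import stats

from .containers import LDBlock, ZPanel

__all__ = ["ImputeParams", "ImputeResult", "impute_block", "impute_panel",
           "mask_and_assess"]

NEIGHBOR_R = 0.2  # |r| above which a typed SNP counts as informative


@dataclass
class ImputeParams:
    """Accuracy-control knobs of the imputation.

    ``r2_threshold`` — minimum imputation quality to keep an imputed z
    (default 0.6). ``minimum_ld`` — minimum count of typed neighbors
    with |r| > 0.2 (default 5). ``eigen_threshold`` — eigenvalues of
    the typed-typed LD matrix below this fraction of the largest are
    truncated from the pseudo-inverse (default 0.05).
    """

    r2_threshold: float = 0.6
    minimum_ld: int = 5
    eigen_threshold: float = 0.05

    def __post_init__(self) -> None:
        if not 0.0 <= self.r2_threshold <= 1.0:
            raise ValueError("r2_threshold must lie in [0, 1]")
        if self.minimum_ld < 0 or self.eigen_threshold < 0:
            raise ValueError("minimum_ld and eigen_threshold must be nonnegative")


@dataclass
class ImputeResult:
    """Imputation output for one block.

    ``z`` has one entry per block SNP: typed values pass through,
    untyped SNPs carry their imputed value or NaN when filtered.
    ``quality`` is r2_u for untyped SNPs (NaN for typed); ``kept``
    marks untyped SNPs that passed both filters.
    """

    z: np.ndarray
    quality: np.ndarray
    kept: np.ndarray
    n_neighbors: np.ndarray


def _truncated_pinv(sigma_tt: np.ndarray, eigen_threshold: float) -> np.ndarray:
    vals, vecs = eigh(sigma_tt)
    keep = vals >= eigen_threshold * vals[-1]
    if not keep.any():  # degenerate; keep the top eigenpair
        keep[-1] = True
    return (vecs[:, keep] / vals[keep]) @ vecs[:, keep].T


def impute_block(
    z_typed: np.ndarray,
    ld: LDBlock | np.ndarray,
    typed_index: np.ndarray,
    params: ImputeParams = ImputeParams(),
) -> ImputeResult:
    """Impute untyped SNPs of one LD block from its typed SNPs.

    Parameters
    ----------
    z_typed
        z-scores of the typed SNPs, ordered as ``typed_index``.
    ld
        The block's full correlation matrix (typed and untyped SNPs).
    typed_index
        Row indices of the typed SNPs within the block; must be a
        non-empty strict subset or the full block.
    """
    corr = ld.corr if isinstance(ld, LDBlock) else np.asarray(ld, dtype=float)
    if not np.allclose(corr, corr.T, atol=1e-10):
        raise ValueError("LD matrix must be symmetric")
    n = corr.shape[0]
    typed_index = np.asarray(typed_index, dtype=int)
    if typed_index.size == 0:
        raise ValueError("typed set is empty")
    z_typed = np.asarray(z_typed, dtype=float)
    if z_typed.shape[0] != typed_index.shape[0]:
        raise ValueError("z_typed length must match typed_index")

    typed_mask = np.zeros(n, dtype=bool)
    typed_mask[typed_index] = True
    untyped = np.flatnonzero(~typed_mask)

    z = np.full(n, np.nan)
    z[typed_index] = z_typed
    quality = np.full(n, np.nan)
    kept = np.zeros(n, dtype=bool)
    n_neighbors = np.zeros(n, dtype=int)
    if untyped.size == 0:
        return ImputeResult(z=z, quality=quality, kept=kept, n_neighbors=n_neighbors)

    sigma_tt = corr[np.ix_(typed_index, typed_index)]
    sigma_ut = corr[np.ix_(untyped, typed_index)]
    pinv = _truncated_pinv(sigma_tt, params.eigen_threshold)

    z_hat = sigma_ut @ pinv @ z_typed
    r2 = np.clip(np.einsum("ij,jk,ik->i", sigma_ut, pinv, sigma_ut), 0.0, 1.0)
    neighbors = (np.abs(sigma_ut) > NEIGHBOR_R).sum(axis=1)

    ok = (r2 >= params.r2_threshold) & (neighbors >= params.minimum_ld)
    z[untyped[ok]] = z_hat[ok]
    quality[untyped] = r2
    kept[untyped[ok]] = True
    n_neighbors[untyped] = neighbors
    return ImputeResult(z=z, quality=quality, kept=kept, n_neighbors=n_neighbors)


def impute_panel(
    panel: ZPanel,
    ld: list[LDBlock],
    params: ImputeParams = ImputeParams(),
) -> ZPanel:
    """Impute every masked entry of a panel, block by block and per trait.

    Entries that pass the quality filters are filled in and flagged in
    the returned panel's ``imputed`` matrix; the rest stay masked.
    """
    z = panel.z.copy()
    mask = panel.mask.copy()
    imputed = np.zeros_like(mask)
    for block in ld:
        sl = slice(block.start, block.stop)
        for t in range(panel.n_traits):
            typed = np.flatnonzero(panel.mask[sl, t])
            if typed.size == 0 or typed.size == block.n_snps:
                continue
            res = impute_block(panel.z[sl, t][typed], block, typed, params)
            newly = res.kept
            z[sl, t] = np.where(newly, res.z, z[sl, t])
            mask[sl, t] |= newly
            imputed[sl, t] = newly
    return ZPanel(snps=panel.snps, z=z, traits=list(panel.traits),
                  n_per_trait=panel.n_per_trait, mask=mask,
                  n_matrix=panel.n_matrix, imputed=imputed)


def mask_and_assess(
    panel: ZPanel,
    ld: list[LDBlock],
    mask_fraction: float,
    params: ImputeParams = ImputeParams(),
    seed: int = 0,
) -> "pd.DataFrame":
    """Hold-out assessment of imputation accuracy.

    Randomly masks a fraction of typed SNPs, re-imputes them from the
    survivors, and reports the Pearson correlation between held-out and
    imputed z per trait, plus the fraction of masked SNPs that passed
    the quality filters (retention). Traits where nothing passed the
    filters are reported with NaN correlation rather than dropped.
    """
    import pandas as pd

    if not 0.0 < mask_fraction < 1.0:
        if mask_fraction == 0.0:
            return pd.DataFrame(columns=["trait", "n_masked", "n_imputed",
                                         "retention", "correlation"])
        raise ValueError("mask_fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    n = panel.n_snps
    holdout = rng.random(n) < mask_fraction
    rows = []
    for t, trait in enumerate(panel.traits):
        true_z = np.full(n, np.nan)
        imput_z = np.full(n, np.nan)
        n_masked = 0
        for block in ld:
            sl = slice(block.start, block.stop)
            block_mask = panel.mask[sl, t] & ~holdout[sl]
            held = panel.mask[sl, t] & holdout[sl]
            n_masked += int(held.sum())
            typed = np.flatnonzero(block_mask)
            if typed.size == 0:
                continue
            res = impute_block(panel.z[sl, t][typed], block, typed, params)
            idx = np.flatnonzero(held)
            true_z[block.start + idx] = panel.z[sl, t][idx]
            imput_z[block.start + idx] = res.z[idx]
        both = np.isfinite(true_z) & np.isfinite(imput_z)
        corr = np.nan
        if both.sum() >= 3:
            corr = float(stats.pearsonr(true_z[both], imput_z[both])[0])
        rows.append((trait, n_masked, int(both.sum()),
                     both.sum() / n_masked if n_masked else np.nan, corr))
    return pd.DataFrame(rows, columns=["trait", "n_masked", "n_imputed",
                                       "retention", "correlation"])
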