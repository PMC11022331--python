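"""Synthetic multi-ancestry, multi-trait summary statistics with known truth.

The generative model works directly on the z-score scale. For one
ancestry with LD correlation matrix ``R`` (block diagonal), standardized
effect matrix ``Gamma`` (SNP x trait, per-SD units such that ``sqrt(N) *
gamma`` is the expected z at a causal SNP under no LD), per-trait sample
sizes ``N`` and residual cross-trait covariance ``Omega``:

    Z = R @ Gamma @ diag(sqrt(N)) + L_R @ E @ L_Omega.T

where ``E`` is an iid standard-normal matrix and ``L_R``, ``L_Omega``
are Cholesky factors, so the noise has the matrix-normal distribution
with row covariance ``R`` (LD) and column covariance ``Omega``
(phenotype correlation plus sample overlap), i.e. ``Cov(vec(Z)) =
Omega (x) R``. Under the global null (``Gamma = 0``) each SNP's
trait-vector is multivariate normal with covariance ``Omega`` — exactly
the null the downstream omnibus chi-square test assumes.

Ancestry divergence is emulated by per-ancestry availability masks
(variants rare or absent in one population are dropped from its panel)
and optional per-ancestry perturbation of the effect vectors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cholesky

from .containers import LDBlock, ZPanel

__all__ = [
    "LDSpec",
    "StudyTruth",
    "AncestryDesign",
    "StudyResult",
    "make_ld_matrix",
    "heterogeneous_ld_blocks",
    "simulate_z_panel",
    "simulate_study",
    "default_hematological_study",
    "exchangeable_omega",
    "banded_omega",
]

logger = logging.getLogger(__name__)

# Per-trait GWAS sample sizes of the four-ancestry hematological design
# the generator emulates by default (EUR/EAS/AMR/AFR blood-trait panels;
# the EAS panel lacks two of the fifteen traits).
DEFAULT_SAMPLE_SIZES = {"EUR": 563_946, "EAS": 151_807, "AFR": 15_171, "AMR": 9_368}
DEFAULT_N_TRAITS = 15


@dataclass
class LDSpec:
    """Recipe for a block-diagonal AR(1) LD structure.

    ``within_block_decay`` is the correlation between adjacent SNPs of a
    block; the correlation between SNPs ``i`` and ``j`` of the same
    block is ``decay ** |i - j|``, which is positive definite for any
    decay in [0, 1).
    """

    n_snps: int
    block_sizes: list[int]
    within_block_decay: float = 0.8
    seed: int = 0
    chrom: str = "1"
    pos_spacing: int = 1000  # bp between adjacent simulated SNPs
    block_decays: list[float] | None = None  # per-block override of the decay

    def __post_init__(self) -> None:
        if sum(self.block_sizes) != self.n_snps:
            raise ValueError(
                f"block sizes sum to {sum(self.block_sizes)}, expected {self.n_snps}"
            )
        decays = (self.block_decays if self.block_decays is not None
                  else [self.within_block_decay])
        if self.block_decays is not None and \
                len(self.block_decays) != len(self.block_sizes):
            raise ValueError("block_decays must match block_sizes in length")
        if any(not 0.0 <= d < 1.0 for d in decays):
            raise ValueError(
                "decay must be in [0, 1) for a positive definite LD matrix"
            )

    @property
    def decays(self) -> list[float]:
        if self.block_decays is not None:
            return list(self.block_decays)
        return [self.within_block_decay] * len(self.block_sizes)


@dataclass
class StudyTruth:
    """Ground truth for one simulated study.

    ``gamma`` holds standardized per-allele effects (per-SD units), so
    the expected z-score of causal SNP ``m`` on trait ``t`` in the
    absence of LD is ``sqrt(N_t) * gamma[m, t]``. ``omega_true`` is the
    residual z-score covariance under the null; ``ancestry_masks`` maps
    ancestry labels to boolean SNP-availability vectors emulating
    variants below the 1% frequency floor in some populations.
    """

    gamma: np.ndarray
    omega_true: np.ndarray
    sample_sizes: np.ndarray
    ancestry_masks: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.gamma = np.atleast_2d(np.asarray(self.gamma, dtype=float))
        self.omega_true = np.asarray(self.omega_true, dtype=float)
        self.sample_sizes = np.asarray(self.sample_sizes, dtype=float)
        k = self.omega_true.shape[0]
        if self.omega_true.shape != (k, k):
            raise ValueError("omega_true must be square")
        if not np.allclose(self.omega_true, self.omega_true.T, atol=1e-10):
            raise ValueError("omega_true must be symmetric")
        if self.gamma.shape[1] != k or len(self.sample_sizes) != k:
            raise ValueError("gamma / sample_sizes dimensions disagree with omega")
        eigvals = np.linalg.eigvalsh(self.omega_true)
        if eigvals[0] <= 0:
            raise ValueError(
                f"omega_true is not positive definite (smallest eigenvalue {eigvals[0]:.3e})"
            )

    @property
    def n_traits(self) -> int:
        return self.omega_true.shape[0]

    @property
    def causal_index(self) -> np.ndarray:
        """Row indices of SNPs with a nonzero effect on any trait."""
        return np.flatnonzero(np.any(self.gamma != 0.0, axis=1))


def exchangeable_omega(k: int, rho: float) -> np.ndarray:
    """Unit-diagonal covariance with constant off-diagonal ``rho``."""
    if not -1.0 / (k - 1) < rho < 1.0:
        raise ValueError("rho outside the positive definite range")
    return (1.0 - rho) * np.eye(k) + rho * np.ones((k, k))


def banded_omega(k: int, max_rho: float = 0.6, seed: int = 0) -> np.ndarray:
    """Random unit-diagonal correlation matrix with |off-diagonals| <= max_rho.

    Draws a random correlation structure and rescales its off-diagonal
    part so the largest absolute entry equals ``max_rho``, then verifies
    positive definiteness (shrinking toward identity if needed).
    """
    rng = np.random.default_rng(seed)
    a = rng.standard_normal((k, k + 5))
    c = np.corrcoef(a)
    off = c - np.eye(k)
    peak = np.abs(off).max()
    if peak > 0:
        off *= max_rho / peak
    omega = np.eye(k) + off
    # shrink until positive definite (rarely needed at max_rho <= 0.6)
    lam = 0.0
    while np.linalg.eigvalsh(omega)[0] <= 1e-8:
        lam += 0.05
        omega = (1 - lam) * (np.eye(k) + off) + lam * np.eye(k)
    return omega


def make_ld_matrix(spec: LDSpec) -> list[LDBlock]:
    """Build the block-diagonal AR(1) LD structure described by ``spec``.

    Each block is symmetric, unit diagonal and positive definite, with
    entry ``(i, j)`` equal to ``decay ** |i - j|``.
    """
    blocks: list[LDBlock] = []
    offset = 0
    for size, decay in zip(spec.block_sizes, spec.decays):
        idx = np.arange(size)
        corr = decay ** np.abs(idx[:, None] - idx[None, :])
        positions = (offset + idx + 1) * spec.pos_spacing
        blocks.append(LDBlock(corr=corr, start=offset, positions=positions,
                              chrom=spec.chrom))
        offset += size
    return blocks


def heterogeneous_ld_blocks(
    n_snps: int,
    block_size: int = 50,
    decay_range: tuple[float, float] = (0.2, 0.95),
    seed: int = 0,
    chrom: str = "1",
    pos_spacing: int = 1000,
) -> list[LDBlock]:
    """AR(1) LD blocks with a different decay per block.

    Real genomes mix recombination deserts with hotspots, so per-SNP LD
    scores span more than an order of magnitude; a single uniform decay
    collapses that spread and leaves LD-score regression barely
    identified (intercept and slope become collinear). Drawing each
    block's decay from ``decay_range`` restores a realistic LD-score
    distribution.
    """
    lo, hi = decay_range
    if not 0.0 <= lo <= hi < 1.0:
        raise ValueError("decay_range must satisfy 0 <= lo <= hi < 1")
    rng = np.random.default_rng(seed)
    sizes = [block_size] * (n_snps // block_size)
    if n_snps % block_size:
        sizes.append(n_snps % block_size)
    blocks, offset = [], 0
    for size, decay in zip(sizes, rng.uniform(lo, hi, size=len(sizes))):
        idx = np.arange(size)
        corr = decay ** np.abs(idx[:, None] - idx[None, :])
        positions = (offset + idx + 1) * pos_spacing
        blocks.append(LDBlock(corr=corr, start=offset, positions=positions,
                              chrom=chrom))
        offset += size
    return blocks


def _snp_table(blocks: list[LDBlock], prefix: str = "rs") -> pd.DataFrame:
    rows = []
    for block in blocks:
        for i in range(block.n_snps):
            j = block.start + i
            rows.append((f"{prefix}{j + 1}", block.chrom, int(block.positions[i]), "A", "G"))
    table = pd.DataFrame(rows, columns=["rsid", "chrom", "pos", "ref", "alt"])
    return table.set_index("rsid")


def simulate_z_panel(
    ld: list[LDBlock],
    truth: StudyTruth,
    seed: int,
    traits: list[str] | None = None,
) -> ZPanel:
    """Draw one SNP x trait z-score panel from the matrix-normal model.

    The mean is ``R @ Gamma @ diag(sqrt(N))`` (causal effects convolved
    through LD); the noise is matrix-normal with row covariance ``R``
    and column covariance ``Omega``, sampled through the Cholesky
    factors of both. One seed gives bit-identical panels.
    """
    n_snps = sum(b.n_snps for b in ld)
    k = truth.n_traits
    if truth.gamma.shape[0] != n_snps:
        raise ValueError(
            f"gamma has {truth.gamma.shape[0]} SNPs but LD describes {n_snps}"
        )
    eigvals = np.linalg.eigvalsh(truth.omega_true)
    if eigvals[0] <= 0:
        raise ValueError(
            f"omega is not positive definite (smallest eigenvalue {eigvals[0]:.3e})"
        )
    rng = np.random.default_rng(seed)
    l_omega = cholesky(truth.omega_true, lower=True)
    sqrt_n = np.sqrt(truth.sample_sizes)

    z = np.empty((n_snps, k))
    for block in ld:
        sl = slice(block.start, block.stop)
        mean = block.corr @ (truth.gamma[sl] * sqrt_n[None, :])
        l_r = cholesky(block.corr, lower=True)
        noise = l_r @ rng.standard_normal((block.n_snps, k)) @ l_omega.T
        z[sl] = mean + noise

    if traits is None:
        traits = [f"trait_{t + 1}" for t in range(k)]
    return ZPanel(
        snps=_snp_table(ld),
        z=z,
        traits=list(traits),
        n_per_trait=truth.sample_sizes.copy(),
        mask=np.ones_like(z, dtype=bool),
    )


@dataclass
class AncestryDesign:
    """One ancestry's slice of a simulated study."""

    name: str
    ld_spec: LDSpec
    truth: StudyTruth
    traits: list[str] | None = None


@dataclass
class StudyResult:
    """Simulated study: per-ancestry panels plus the truth that made them."""

    panels: dict[str, ZPanel]
    ld: dict[str, list[LDBlock]]
    truths: dict[str, StudyTruth]

    def causal_positions(self, ancestry: str) -> np.ndarray:
        """Base-pair positions of causal SNPs present in an ancestry's panel."""
        truth = self.truths[ancestry]
        panel = self.panels[ancestry]
        blocks = self.ld[ancestry]
        all_pos = np.concatenate([b.positions for b in blocks])
        causal_pos = all_pos[truth.causal_index]
        present = np.isin(causal_pos, panel.snps["pos"].to_numpy())
        return causal_pos[present]


def _check_masks(truth: StudyTruth, spec: LDSpec, ancestry: str) -> np.ndarray:
    mask = truth.ancestry_masks.get(ancestry)
    if mask is None:
        return np.ones(spec.n_snps, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape[0] != spec.n_snps:
        raise ValueError(f"ancestry mask for {ancestry} has wrong length")
    offset = 0
    for size in spec.block_sizes:
        if not mask[offset:offset + size].any():
            raise ValueError(
                f"ancestry mask for {ancestry} empties a whole LD block"
            )
        offset += size
    return mask


def simulate_study(designs: list[AncestryDesign], seed: int) -> StudyResult:
    """Simulate a multi-ancestry study with per-ancestry LD, effects and masks.

    Masked SNPs are removed from that ancestry's panel entirely (they
    are absent from its reference, as variants below the frequency floor
    are). Trait sets may differ between ancestries.
    """
    if not designs:
        raise ValueError("at least one ancestry required")
    rng = np.random.default_rng(seed)
    panels: dict[str, ZPanel] = {}
    ld: dict[str, list[LDBlock]] = {}
    truths: dict[str, StudyTruth] = {}
    for design in designs:
        if design.truth.n_traits == 0:
            raise ValueError(f"empty trait set for ancestry {design.name}")
        blocks = make_ld_matrix(design.ld_spec)
        sub_seed = int(rng.integers(0, 2**31 - 1))
        panel = simulate_z_panel(blocks, design.truth, seed=sub_seed,
                                 traits=design.traits)
        avail = _check_masks(design.truth, design.ld_spec, design.name)
        if not avail.all():
            panel = panel.subset_snps(np.flatnonzero(avail))
        panels[design.name] = panel
        ld[design.name] = blocks
        truths[design.name] = design.truth
    return StudyResult(panels=panels, ld=ld, truths=truths)


def default_hematological_study(
    n_snps: int = 5000,
    block_size: int = 50,
    decay_range: tuple[float, float] = (0.2, 0.95),
    causal_fraction: float = 0.01,
    effect_sd: float | None = None,
    omega_max_rho: float = 0.6,
    missing_fraction: float = 0.1,
    effect_divergence: float = 0.0,
    seed: int = 0,
) -> list[AncestryDesign]:
    """Build the default four-ancestry, fifteen-trait study design.

    Emulates the blood-trait design the pipeline targets: four ancestry
    panels (EUR, EAS, AFR, AMR) with realistic relative sample sizes,
    the EAS panel missing two traits, sparse pleiotropic effects shared
    across ancestries, per-ancestry availability masks, and a residual
    covariance with off-diagonals up to ``omega_max_rho``. Each
    ancestry's LD blocks draw their decay from ``decay_range``
    independently — LD is heterogeneous along the genome and differs
    between populations.

    ``effect_sd`` defaults to a scale at which causal SNPs in the
    largest panel are comfortably genome-wide significant while the
    small panels are underpowered — the regime that makes multi-trait
    testing worthwhile. ``effect_divergence`` adds independent
    per-ancestry noise to the shared effect vectors (0 = identical
    pleiotropy everywhere).
    """
    rng = np.random.default_rng(seed)
    k = DEFAULT_N_TRAITS
    omega = banded_omega(k, max_rho=omega_max_rho, seed=seed)
    n_causal = max(1, int(round(causal_fraction * n_snps)))
    causal = rng.choice(n_snps, size=n_causal, replace=False)
    if effect_sd is None:
        # ~ |z| around 8 at the EUR sample size for a typical causal SNP
        effect_sd = 8.0 / np.sqrt(max(DEFAULT_SAMPLE_SIZES.values()))
    base_gamma = np.zeros((n_snps, k))
    # each causal SNP hits a random subset of traits (pleiotropy)
    for m in causal:
        hit = rng.random(k) < 0.5
        if not hit.any():
            hit[rng.integers(k)] = True
        base_gamma[m, hit] = rng.normal(0.0, effect_sd, size=int(hit.sum()))

    sizes = [block_size] * (n_snps // block_size)
    if n_snps % block_size:
        sizes.append(n_snps % block_size)

    designs = []
    for name, n_total in DEFAULT_SAMPLE_SIZES.items():
        traits = [f"trait_{t + 1}" for t in range(k)]
        omega_a = omega
        gamma_a = base_gamma.copy()
        if effect_divergence > 0:
            jitter = rng.normal(0.0, effect_divergence * effect_sd, size=gamma_a.shape)
            gamma_a[causal] += jitter[causal]
        if name == "EAS":  # this panel lacks two of the fifteen traits
            keep = np.arange(k - 2)
            traits = [traits[t] for t in keep]
            omega_a = omega[np.ix_(keep, keep)]
            gamma_a = gamma_a[:, keep]
        k_a = len(traits)
        mask = np.ones(n_snps, dtype=bool)
        if name != "EUR" and missing_fraction > 0:
            # rare/absent variants in this population, never a whole block
            drop = rng.random(n_snps) < missing_fraction
            offset = 0
            for size in sizes:
                if drop[offset:offset + size].all():
                    drop[offset] = False
                offset += size
            mask = ~drop
        truth = StudyTruth(
            gamma=gamma_a,
            omega_true=omega_a,
            sample_sizes=np.full(k_a, float(n_total)),
            ancestry_masks={name: mask},
        )
        decays = list(rng.uniform(decay_range[0], decay_range[1],
                                  size=len(sizes)))
        spec = LDSpec(n_snps=n_snps, block_sizes=sizes, seed=seed, chrom="1",
                      block_decays=decays)
        designs.append(AncestryDesign(name=name, ld_spec=spec, truth=truth,
                                      traits=traits))
    return designs
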