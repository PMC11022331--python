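"""From per-SNP statistics to independent lead associations and novelty calls.

Discovery proceeds region by region: quasi-independent LD regions whose
minimum joint p passes genome-wide significance are clumped (greedy,
PLINK-style: smallest-p SNP leads, LD-correlated significant SNPs join
its clump), isolated leads — clumps containing nothing but their lead —
are filtered out as poor-quality signals, and each surviving lead is
classified. A lead is a *new* association when the joint (omnibus) test
is genome-wide significant while the minimum univariate p across traits
is not; the minimum univariate p is deliberately left uncorrected so
that anything any single-trait analysis would have reported is counted
as known.

All thresholds are compared in -log10 space.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ldtools import RegionSet

__all__ = [
    "ClumpParams",
    "Clump",
    "GENOME_WIDE_LOG10P",
    "region_scan",
    "clump",
    "filter_isolated",
    "classify_new",
    "bonferroni_variant",
    "trans_lead_selection",
]

logger = logging.getLogger(__name__)

GENOME_WIDE_P = 5e-8
GENOME_WIDE_LOG10P = -np.log10(GENOME_WIDE_P)  # 7.30103
BIN_BP = 1_000_000


@dataclass
class ClumpParams:
    """PLINK-style clumping thresholds.

    ``p1`` — significance required of a lead; ``p2`` — significance
    required of other members; ``r2`` — squared correlation above which
    a SNP joins a lead's clump.
    """

    p1: float = GENOME_WIDE_P
    p2: float = 5e-4
    r2: float = 0.2

    def __post_init__(self) -> None:
        if self.p1 > self.p2:
            raise ValueError("p1 must be at most p2")
        if not 0.0 < self.r2 < 1.0:
            raise ValueError("r2 must lie in (0, 1)")

    @property
    def log10_p1(self) -> float:
        return -np.log10(self.p1)

    @property
    def log10_p2(self) -> float:
        return -np.log10(self.p2)


@dataclass
class Clump:
    """A lead SNP with the member SNPs assigned to it."""

    lead: int  # positional index into the results table passed to clump()
    members: list[int] = field(default_factory=list)  # excludes the lead

    @property
    def size(self) -> int:
        return 1 + len(self.members)


def region_scan(results: pd.DataFrame, regions: RegionSet) -> pd.DataFrame:
    """Per-region minima of the joint and univariate -log10 p.

    ``results`` must carry ``snp_index`` (row position on the region
    index), ``log10p_joint`` and ``log10p_univ``. SNPs outside every
    region are logged and excluded. Regions whose joint minimum passes
    genome-wide significance are flagged ``candidate`` for clumping.
    """
    region_id = regions.region_of(results["snp_index"].to_numpy())
    outside = region_id < 0
    if outside.any():
        logger.warning("%d SNPs fall outside every region; excluded",
                       int(outside.sum()))
    inside = results.loc[~outside].copy()
    inside["region"] = region_id[~outside]
    grouped = inside.groupby("region").agg(
        min_log10p_joint=("log10p_joint", "max"),
        min_log10p_univ=("log10p_univ", "max"),
        n_snps=("log10p_joint", "size"),
    ).reset_index()
    grouped["candidate"] = grouped["min_log10p_joint"] >= GENOME_WIDE_LOG10P
    return grouped


def clump(
    results: pd.DataFrame,
    ld: np.ndarray,
    params: ClumpParams = ClumpParams(),
    p_column: str = "log10p_joint",
) -> list[Clump]:
    """Greedy PLINK-style clumping of one region's results.

    Repeatedly takes the smallest-p unassigned SNP with p <= p1 as a
    lead and assigns every unassigned SNP with p <= p2 and r2 >= the
    threshold to its clump (single assignment). Ties in p are broken by
    leftmost position.
    """
    log10p = results[p_column].to_numpy(dtype=float)
    pos = results["pos"].to_numpy()
    n = len(results)
    if ld.shape != (n, n):
        raise ValueError("LD matrix does not match the results table")
    r2 = np.asarray(ld, dtype=float) ** 2

    unassigned = np.ones(n, dtype=bool)
    clumps: list[Clump] = []
    # sort by decreasing -log10 p, then position (leftmost wins ties)
    order = np.lexsort((pos, -log10p))
    for i in order:
        if not unassigned[i] or log10p[i] < params.log10_p1 or not np.isfinite(log10p[i]):
            continue
        unassigned[i] = False
        members = np.flatnonzero(
            unassigned & (log10p >= params.log10_p2) & (r2[i] >= params.r2)
        )
        unassigned[members] = False
        clumps.append(Clump(lead=int(i), members=[int(m) for m in members]))
    return clumps


def filter_isolated(clumps: list[Clump]) -> list[Clump]:
    """Drop clumps whose only member is the lead itself.

    Isolated leads — significant SNPs that no LD-correlated neighbor
    supports — are a hallmark of unstable or poorly-imputed signals.
    """
    kept = [c for c in clumps if c.size > 1]
    n_dropped = len(clumps) - len(kept)
    if n_dropped:
        logger.info("filtered %d isolated lead(s)", n_dropped)
    return kept


def classify_new(associations: pd.DataFrame,
                 log10_threshold: float = GENOME_WIDE_LOG10P) -> pd.DataFrame:
    """Flag joint-only associations as new.

    An association is *new* when the joint test is significant at the
    threshold while the minimum univariate p across traits is not. Both
    comparisons are done on the -log10 scale.
    """
    out = associations.copy()
    joint_sig = out["log10p_joint"] >= log10_threshold
    univ_sig = out["log10p_univ"] >= log10_threshold
    out["new"] = joint_sig & ~univ_sig
    return out


def bonferroni_variant(associations: pd.DataFrame, n_analyses: int) -> pd.DataFrame:
    """Stricter novelty call correcting for the number of multi-trait scans.

    Recomputes significance and novelty at 5e-8 / n_analyses; leads no
    longer significant at the corrected threshold are dropped.
    """
    if n_analyses < 1:
        raise ValueError("n_analyses must be >= 1")
    threshold = GENOME_WIDE_LOG10P + np.log10(n_analyses)
    out = associations[associations["log10p_joint"] >= threshold].copy()
    return classify_new(out, log10_threshold=threshold)


def trans_lead_selection(results: pd.DataFrame,
                         log10_threshold: float = GENOME_WIDE_LOG10P) -> pd.DataFrame:
    """One lead per fixed 1 Mbp bin for trans-ancestry results.

    LD regions cannot be defined across ancestries, so the genome is
    tiled with fixed-origin 1 Mbp bins (``bin = floor((pos - 1) / 1e6)``)
    and the minimum-p SNP of each bin is reported when it passes the
    significance threshold. Ties break to the leftmost position.
    """
    out = results.copy()
    out["bin"] = (out["pos"].astype(np.int64) - 1) // BIN_BP
    out = out.sort_values(["chrom", "bin", "log10p_joint", "pos"],
                          ascending=[True, True, False, True], kind="stable")
    leads = out.drop_duplicates(["chrom", "bin"], keep="first")
    return leads[leads["log10p_joint"] >= log10_threshold].reset_index(drop=True)
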