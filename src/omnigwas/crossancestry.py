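"""Comparing association landscapes across ancestries.

Three complementary views:

* **Locus overlap** — the genome is tiled into fixed 1 Mbp bins; a bin
  counts as detected in an ancestry when it contains at least one
  significant association (joint or univariate). UpSet-style exclusive
  intersection counts summarize sharing.
* **Signal similarity** — at loci shared by two ancestries, the squared
  Pearson correlation (R^2) of the two lead SNPs' z-vectors across the
  traits both panels measure. Identical pleiotropic architecture gives
  R^2 near 1; population-specific biology (e.g. selection at a locus)
  shows up as an outlier. Computed on z rather than per-allele effects:
  the sample-size scale cancels in a correlation.
* **Downsampling specificity** — how much of the largest cohort's
  apparent exclusivity is just statistical power: its lead z-scores are
  shrunk to a simulated smaller sample size and the fraction of its
  detected loci that no other ancestry detects is traced as the
  fraction sweeps 0..100%.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .assoc import omnibus_test, scale_z, univariate_log10p
from .containers import ZPanel
from .discovery import BIN_BP, GENOME_WIDE_LOG10P
from .nullcov import NullCovariance

__all__ = ["OverlapTable", "SimilarityRecord", "bin_of", "bin_loci",
           "signal_similarity", "downsample_specificity"]

logger = logging.getLogger(__name__)


def bin_of(chrom: pd.Series | np.ndarray, pos: pd.Series | np.ndarray) -> list[tuple]:
    """Fixed-origin 1 Mbp bin labels: (chrom, floor((pos - 1) / 1e6))."""
    pos = np.asarray(pos, dtype=np.int64)
    return list(zip(np.asarray(chrom).astype(str), (pos - 1) // BIN_BP))


@dataclass
class OverlapTable:
    """Per-ancestry occupied 1 Mbp bins and their exclusive intersections.

    ``table`` has one boolean column per ancestry (the subset mask),
    an exclusive ``count`` (bins in exactly that subset) and a
    ``has_new`` flag (some contributing association was joint-only).
    """

    ancestries: list[str]
    bins: dict[str, set]
    table: pd.DataFrame

    @property
    def union_size(self) -> int:
        return len(set().union(*self.bins.values())) if self.bins else 0


def bin_loci(associations: dict[str, pd.DataFrame]) -> OverlapTable:
    """Build the UpSet-style locus-overlap table across ancestries.

    Each ancestry's associations (columns ``chrom``, ``pos`` and
    optionally ``new``) occupy the 1 Mbp bins of their positions;
    exclusive intersection counts are reported for every non-empty
    ancestry subset, with a flag marking subsets containing at least
    one bin with a joint-only (new) association.
    """
    ancestries = list(associations)
    bins: dict[str, set] = {}
    new_bins: dict[str, set] = {}
    for anc, df in associations.items():
        occupied = set(bin_of(df["chrom"], df["pos"]))
        bins[anc] = occupied
        if "new" in df.columns:
            flag = df["new"].to_numpy(dtype=bool)
            new_bins[anc] = set(
                b for b, is_new in zip(bin_of(df["chrom"], df["pos"]), flag)
                if is_new
            )
        else:
            new_bins[anc] = set()

    rows = []
    for r in range(1, len(ancestries) + 1):
        for subset in itertools.combinations(ancestries, r):
            inside = set.intersection(*[bins[a] for a in subset])
            outside = set().union(*[bins[a] for a in ancestries
                                    if a not in subset]) if r < len(ancestries) else set()
            exclusive = inside - outside
            has_new = any(exclusive & new_bins[a] for a in subset)
            mask = {a: a in subset for a in ancestries}
            rows.append({**mask, "count": len(exclusive), "has_new": has_new})
    table = pd.DataFrame(rows)
    return OverlapTable(ancestries=ancestries, bins=bins, table=table)


@dataclass
class SimilarityRecord:
    """Cross-ancestry multi-trait signal similarity at one shared locus."""

    bin: tuple
    rsid_a: str
    rsid_b: str
    r2: float
    n_traits: int
    same_snp: bool


def _lead_in_bin(leads: pd.DataFrame, target_bin: tuple) -> pd.DataFrame:
    b = bin_of(leads["chrom"], leads["pos"])
    hit = [i for i, bb in enumerate(b) if bb == target_bin]
    return leads.iloc[hit]


def signal_similarity(
    panel_a: ZPanel,
    panel_b: ZPanel,
    leads_a: pd.DataFrame,
    leads_b: pd.DataFrame,
    prefer_same_snp: bool = True,
) -> pd.DataFrame:
    """R^2 of multi-trait z-vectors at loci shared by two ancestries.

    For every 1 Mbp bin occupied by leads of both ancestries, the two
    z-vectors (over the traits both panels measure and both SNPs have)
    are correlated; the squared Pearson correlation is reported. By
    default the same variant is used in both ancestries when it leads
    in both; otherwise each ancestry contributes its own smallest-p
    lead in the bin. Correlation is sign-insensitive, so a globally
    flipped signal still scores 1.
    """
    shared_traits = [t for t in panel_a.traits if t in set(panel_b.traits)]
    if len(shared_traits) < 3:
        raise ValueError("need at least 3 shared traits for a meaningful R^2")
    col_a = [panel_a.traits.index(t) for t in shared_traits]
    col_b = [panel_b.traits.index(t) for t in shared_traits]

    bins_a = set(bin_of(leads_a["chrom"], leads_a["pos"]))
    bins_b = set(bin_of(leads_b["chrom"], leads_b["pos"]))
    records: list[SimilarityRecord] = []
    for target in sorted(bins_a & bins_b):
        in_a = _lead_in_bin(leads_a, target).sort_values("log10p_joint",
                                                         ascending=False)
        in_b = _lead_in_bin(leads_b, target).sort_values("log10p_joint",
                                                         ascending=False)
        rsid_a, rsid_b, same = in_a["rsid"].iloc[0], in_b["rsid"].iloc[0], False
        if prefer_same_snp:
            common = set(in_a["rsid"]) & set(in_b["rsid"])
            if common:
                # best joint p in ancestry A among variants leading in both
                ranked = [r for r in in_a["rsid"] if r in common]
                rsid_a = rsid_b = ranked[0]
                same = True
        if rsid_a not in panel_a.snps.index or rsid_b not in panel_b.snps.index:
            continue
        ia = panel_a.snps.index.get_loc(rsid_a)
        ib = panel_b.snps.index.get_loc(rsid_b)
        za = panel_a.z[ia, col_a]
        zb = panel_b.z[ib, col_b]
        ok = panel_a.mask[ia, col_a] & panel_b.mask[ib, col_b]
        if ok.sum() < 3:
            continue
        r = stats.pearsonr(za[ok], zb[ok])[0]
        records.append(SimilarityRecord(bin=target, rsid_a=rsid_a,
                                        rsid_b=rsid_b, r2=float(r**2),
                                        n_traits=int(ok.sum()), same_snp=same))
    return pd.DataFrame([r.__dict__ for r in records])


def downsample_specificity(
    leads: pd.DataFrame,
    panel: ZPanel,
    omega: NullCovariance,
    other_bins: set,
    fractions: np.ndarray | None = None,
    log10_threshold: float = GENOME_WIDE_LOG10P,
) -> pd.DataFrame:
    """Trace lead-locus specificity as the focal cohort's N is shrunk.

    For each sample-size fraction f, every lead's z-vector is scaled by
    sqrt(f) (the z-scale equivalent of re-running the GWAS at f x N),
    joint and minimum-univariate p are recomputed, and the fraction of
    still-detected 1 Mbp bins that no other ancestry detects is
    reported. At f = 1 this is the observed specificity; at f = 0 no
    lead survives and specificity is 0 by convention.
    """
    if fractions is None:
        fractions = np.arange(0.0, 1.0 + 1e-9, 0.01)
    lead_rows = []
    for rsid in leads["rsid"]:
        i = panel.snps.index.get_loc(rsid)
        present = panel.mask[i]
        lead_rows.append((panel.z[i, present], np.flatnonzero(present)))
    lead_bins = bin_of(leads["chrom"], leads["pos"])

    rows = []
    prev_detected = -1
    for f in np.sort(fractions):
        detected: set = set()
        for (z_row, cols), b in zip(lead_rows, lead_bins):
            if f == 0.0:
                continue
            z_scaled = scale_z(z_row, 1.0, f)
            sub = omega.subset(cols)
            joint = omnibus_test(z_scaled, sub).log10p
            univ = float(np.max(univariate_log10p(z_scaled)))
            if max(joint, univ) >= log10_threshold:
                detected.add(b)
        exclusive = detected - other_bins
        specificity = len(exclusive) / len(detected) if detected else 0.0
        rows.append((float(f), len(detected), len(exclusive), specificity))
        if len(detected) < prev_detected:
            logger.warning("detected-locus count decreased at fraction %.2f; "
                           "curve is not monotone", f)
        prev_detected = max(prev_detected, len(detected))
    return pd.DataFrame(rows, columns=["fraction", "n_detected",
                                       "n_exclusive", "specificity"])
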