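"""Reading and harmonizing GWAS summary statistics against a reference panel.

Public summary statistics come in many delimited dialects and many
allele orientations. Harmonization maps every per-trait file onto one
reference panel of common variants (MAF > 1%), aligning alleles — a
record whose effect/other alleles are swapped relative to the panel has
its z-score sign flipped — and dropping strand-ambiguous (A/T, C/G) and
allele-mismatched records. The surviving per-trait columns are
assembled into a single SNP x trait :class:`~omnigwas.containers.ZPanel`
with a missingness mask.

A second pass harmonizes sample sizes within each trait: SNPs genotyped
on a much smaller subsample than the rest of the study behave like a
different study and are masked.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .containers import ZPanel

__all__ = ["read_sumstats", "read_reference_panel", "harmonize",
           "harmonize_sample_size", "DEFAULT_DIALECT"]

logger = logging.getLogger(__name__)

# Column mapping: canonical name -> accepted file column names, first hit wins.
DEFAULT_DIALECT: dict[str, list[str]] = {
    "rsid": ["rsid", "rs_id", "snp", "variant_id", "ID"],
    "chrom": ["chrom", "chr", "chromosome"],
    "pos": ["pos", "position", "base_pair_location", "bp"],
    "effect_allele": ["effect_allele", "a1", "alt", "ea"],
    "other_allele": ["other_allele", "a2", "ref", "oa", "nea"],
    "z": ["z", "zscore", "z_score"],
    "beta": ["beta", "b", "effect"],
    "se": ["se", "standard_error", "stderr"],
    "n": ["n", "sample_size", "n_total"],
    "maf": ["maf", "eaf", "effect_allele_frequency", "freq"],
}

_AMBIGUOUS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}
_VALID = {"A", "C", "G", "T"}


def _resolve_columns(columns: list[str], dialect: dict[str, list[str]]) -> dict[str, str]:
    lower = {c.lower(): c for c in columns}
    resolved = {}
    for canonical, candidates in dialect.items():
        for cand in candidates:
            if cand.lower() in lower:
                resolved[canonical] = lower[cand.lower()]
                break
    return resolved


def read_sumstats(path: str, dialect: dict[str, list[str]] | None = None,
                  sep: str = "\t") -> pd.DataFrame:
    """Read one trait's summary statistics into a canonical table.

    The dialect maps canonical column names to the names a file may
    use. ``z`` is computed as ``beta / se`` when absent; when both are
    present the z column wins and discrepancies above 1e-6 are logged.
    Malformed rows (bad alleles, se <= 0, missing key fields) are
    counted, logged and dropped.
    """
    dialect = {**DEFAULT_DIALECT, **(dialect or {})}
    raw = pd.read_csv(path, sep=sep)
    cols = _resolve_columns(list(raw.columns), dialect)
    mandatory = ["rsid", "chrom", "pos", "effect_allele", "other_allele"]
    missing = [c for c in mandatory if c not in cols]
    if missing:
        raise ValueError(f"missing mandatory columns: {missing}")
    if "z" not in cols and not {"beta", "se"} <= cols.keys():
        raise ValueError("need either a z column or beta and se columns")

    df = pd.DataFrame({canon: raw[src] for canon, src in cols.items()})
    df["effect_allele"] = df["effect_allele"].astype(str).str.upper()
    df["other_allele"] = df["other_allele"].astype(str).str.upper()

    n_in = len(df)
    ok = (
        df["effect_allele"].isin(_VALID)
        & df["other_allele"].isin(_VALID)
        & (df["effect_allele"] != df["other_allele"])
        & df["rsid"].notna()
    )
    if "se" in df:
        has_se = df["se"].notna()
        bad_se = has_se & (df["se"] <= 0)
        if bad_se.any():
            logger.warning("%d rows with non-positive se rejected", bad_se.sum())
        ok &= ~bad_se
    df = df[ok].copy()

    if "z" in df.columns and df["z"].notna().any():
        if {"beta", "se"} <= set(df.columns):
            both = df["z"].notna() & df["beta"].notna() & df["se"].notna()
            implied = df.loc[both, "beta"] / df.loc[both, "se"]
            n_disc = int((np.abs(df.loc[both, "z"] - implied) > 1e-6).sum())
            if n_disc:
                logger.warning(
                    "%d rows where z and beta/se disagree by >1e-6; z column wins",
                    n_disc,
                )
        filled = df["z"]
        if {"beta", "se"} <= set(df.columns):
            filled = filled.fillna(df["beta"] / df["se"])
        df["z"] = filled
    else:
        df["z"] = df["beta"] / df["se"]
    df = df[df["z"].notna() & np.isfinite(df["z"])]

    n_bad = n_in - len(df)
    if n_bad:
        logger.info("rejected %d malformed rows of %d", n_bad, n_in)
    keep = ["rsid", "chrom", "pos", "effect_allele", "other_allele", "z"]
    for extra in ("n", "maf"):
        if extra in df.columns:
            keep.append(extra)
    return df[keep].reset_index(drop=True)


def read_reference_panel(path: str, sep: str = "\t") -> pd.DataFrame:
    """Read a reference-panel index: rsid, chrom, pos, ref, alt, maf."""
    panel = pd.read_csv(path, sep=sep)
    required = {"rsid", "chrom", "pos", "ref", "alt", "maf"}
    if not required <= set(panel.columns):
        raise ValueError(f"reference panel must have columns {sorted(required)}")
    panel = panel.set_index("rsid")
    panel["ref"] = panel["ref"].astype(str).str.upper()
    panel["alt"] = panel["alt"].astype(str).str.upper()
    return panel


def _align_to_panel(records: pd.DataFrame, panel: pd.DataFrame) -> pd.DataFrame:
    """Restrict to panel SNPs, orient z to the panel's reference allele."""
    merged = records.join(panel[["chrom", "pos", "ref", "alt", "maf"]],
                          on="rsid", how="inner", rsuffix="_panel")
    if merged.empty:
        return merged

    pair = list(zip(merged["effect_allele"], merged["other_allele"]))
    ambiguous = np.array([p in _AMBIGUOUS for p in pair])
    same = (merged["effect_allele"] == merged["ref"]) & \
           (merged["other_allele"] == merged["alt"])
    swapped = (merged["effect_allele"] == merged["alt"]) & \
              (merged["other_allele"] == merged["ref"])
    n_amb = int(ambiguous.sum())
    n_mismatch = int((~ambiguous & ~same & ~swapped).sum())
    if n_amb:
        logger.info("dropped %d strand-ambiguous (A/T, C/G) SNPs", n_amb)
    if n_mismatch:
        logger.info("dropped %d allele-mismatched SNPs", n_mismatch)

    keep = ~ambiguous & (same | swapped)
    merged = merged[keep].copy()
    flip = swapped[keep]
    merged.loc[flip, "z"] = -merged.loc[flip, "z"]
    return merged


def _dedup_rsids(records: pd.DataFrame) -> pd.DataFrame:
    if not records["rsid"].duplicated().any():
        return records
    if "n" in records.columns:
        records = records.sort_values("n", ascending=False, kind="stable")
    n_dup = int(records["rsid"].duplicated().sum())
    logger.info("dropped %d duplicated rsid records (kept largest n)", n_dup)
    return records.drop_duplicates("rsid", keep="first")


def harmonize(
    records_per_trait: dict[str, pd.DataFrame],
    panel: pd.DataFrame,
    maf_floor: float = 0.01,
) -> ZPanel:
    """Assemble per-trait summary statistics into one harmonized panel.

    Records are restricted to reference-panel SNPs with MAF above the
    floor, allele-aligned to the panel orientation (sign flips on
    swapped alleles, strand-ambiguous and mismatched records dropped),
    and stacked on the union of surviving SNPs with a per-trait
    missingness mask.
    """
    common = panel[panel["maf"] > maf_floor]
    aligned: dict[str, pd.DataFrame] = {}
    for trait, records in records_per_trait.items():
        rec = _dedup_rsids(records)
        rec = _align_to_panel(rec, common)
        aligned[trait] = rec.set_index("rsid")

    union = sorted(set().union(*[set(a.index) for a in aligned.values()]))
    if not union:
        raise ValueError("no summary-statistic SNP matched the reference panel")
    snps = common.loc[union, ["chrom", "pos", "ref", "alt"]].copy()
    snps = snps.sort_values(["chrom", "pos"])
    order = snps.index

    traits = list(aligned)
    n_snps, k = len(order), len(traits)
    z = np.full((n_snps, k), np.nan)
    mask = np.zeros((n_snps, k), dtype=bool)
    n_matrix = np.full((n_snps, k), np.nan)
    n_per_trait = np.zeros(k)
    for t, trait in enumerate(traits):
        rec = aligned[trait].reindex(order)
        present = rec["z"].notna().to_numpy()
        z[present, t] = rec.loc[present, "z"]
        mask[:, t] = present
        if "n" in rec.columns:
            n_matrix[:, t] = rec["n"].to_numpy()
            n_per_trait[t] = np.nanmedian(rec["n"].to_numpy())
    return ZPanel(snps=snps, z=z, traits=traits, n_per_trait=n_per_trait,
                  mask=mask, n_matrix=n_matrix)


def harmonize_sample_size(panel: ZPanel, min_fraction: float = 0.7) -> ZPanel:
    """Mask SNPs genotyped on an atypically small subsample.

    Within each trait, SNPs whose per-SNP n falls below ``min_fraction``
    of that trait's 90th-percentile n are masked (they effectively come
    from a different, smaller study). The trait's scalar N becomes the
    median n of the retained SNPs. ``min_fraction = 0`` disables the
    filter (N is still refreshed).
    """
    if panel.n_matrix is None or not np.isfinite(panel.n_matrix).any():
        logger.info("no per-SNP sample sizes available; nothing to harmonize")
        return panel
    z = panel.z.copy()
    mask = panel.mask.copy()
    n_per_trait = panel.n_per_trait.copy()
    for t, trait in enumerate(panel.traits):
        n_col = panel.n_matrix[:, t]
        present = mask[:, t] & np.isfinite(n_col)
        if not present.any():
            continue
        ref_n = np.percentile(n_col[present], 90)
        low = present & (n_col < min_fraction * ref_n)
        mask[low, t] = False
        z[low, t] = np.nan
        retained = mask[:, t] & np.isfinite(n_col)
        if not retained.any():
            raise ValueError(
                f"sample-size harmonization masked every SNP of trait {trait!r}"
            )
        n_per_trait[t] = float(np.median(n_col[retained]))
        if low.any():
            logger.info("trait %s: masked %d SNPs with n < %.0f%% of the "
                        "90th-percentile n", trait, int(low.sum()),
                        100 * min_fraction)
    return ZPanel(snps=panel.snps, z=z, traits=list(panel.traits),
                  n_per_trait=n_per_trait, mask=mask, n_matrix=panel.n_matrix,
                  imputed=panel.imputed)
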