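"""Shared data containers: harmonized z-score panels and LD blocks.

A :class:`ZPanel` is the central in-memory object of the pipeline: a
SNP x trait matrix of association z-scores harmonized against a single
reference panel, together with per-trait sample sizes and a missingness
mask (a SNP can be present for some traits and absent for others).

An :class:`LDBlock` is a contiguous run of SNPs with its dense
correlation matrix; a chromosome is represented as an ordered list of
blocks (the correlation between SNPs of different blocks is treated as
zero).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ZPanel", "LDBlock", "save_panel", "load_panel"]


@dataclass
class LDBlock:
    """Contiguous SNP interval with its dense LD correlation matrix.

    Parameters
    ----------
    corr
        Symmetric correlation matrix, unit diagonal, one row per SNP.
    start
        Row offset of the first SNP of the block in the enclosing panel.
    positions
        1-based base-pair positions, one per SNP, strictly increasing.
    chrom
        Chromosome label shared by all SNPs of the block.
    """

    corr: np.ndarray
    start: int = 0
    positions: np.ndarray | None = None
    chrom: str = "1"

    def __post_init__(self) -> None:
        self.corr = np.asarray(self.corr, dtype=float)
        if self.corr.ndim != 2 or self.corr.shape[0] != self.corr.shape[1]:
            raise ValueError("LD matrix must be square")
        if not np.allclose(self.corr, self.corr.T, atol=1e-10):
            raise ValueError("LD matrix must be symmetric")
        if self.positions is not None:
            self.positions = np.asarray(self.positions, dtype=np.int64)
            if self.positions.shape[0] != self.corr.shape[0]:
                raise ValueError("positions length must match matrix size")

    @property
    def n_snps(self) -> int:
        return self.corr.shape[0]

    @property
    def stop(self) -> int:
        """Half-open end offset in the enclosing panel."""
        return self.start + self.n_snps


@dataclass
class ZPanel:
    """Harmonized SNP x trait z-score matrix for one ancestry.

    Attributes
    ----------
    snps
        Index table with columns ``chrom``, ``pos``, ``ref``, ``alt``,
        indexed by rsid; one row per SNP, no duplicates.
    z
        Array of shape ``(n_snps, n_traits)``; entries where ``mask`` is
        False are undefined (conventionally NaN).
    traits
        Trait labels, one per column of ``z``.
    n_per_trait
        Scalar effective sample size per trait.
    mask
        Boolean availability matrix, True where a z-score is present.
    n_matrix
        Optional per-SNP, per-trait sample sizes (pre-harmonization).
    imputed
        Optional boolean matrix flagging imputed entries.
    """

    snps: pd.DataFrame
    z: np.ndarray
    traits: list[str]
    n_per_trait: np.ndarray
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]
    n_matrix: np.ndarray | None = None
    imputed: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        self.n_per_trait = np.asarray(self.n_per_trait, dtype=float)
        if self.mask is None:
            self.mask = np.isfinite(self.z)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.z.shape != self.mask.shape:
            raise ValueError("z and mask shapes differ")
        if self.z.shape[1] != len(self.traits):
            raise ValueError("number of traits does not match z columns")
        if len(self.n_per_trait) != len(self.traits):
            raise ValueError("n_per_trait length does not match traits")
        if self.snps.index.has_duplicates:
            raise ValueError("duplicated rsid in panel index")
        if not np.isfinite(self.z[self.mask]).all():
            raise ValueError("non-finite z where mask marks presence")

    @property
    def n_snps(self) -> int:
        return self.z.shape[0]

    @property
    def n_traits(self) -> int:
        return self.z.shape[1]

    def subset_snps(self, row_indices: np.ndarray) -> "ZPanel":
        """Return a new panel restricted to the given SNP rows."""
        row_indices = np.asarray(row_indices)
        return ZPanel(
            snps=self.snps.iloc[row_indices].copy(),
            z=self.z[row_indices].copy(),
            traits=list(self.traits),
            n_per_trait=self.n_per_trait.copy(),
            mask=self.mask[row_indices].copy(),
            n_matrix=None if self.n_matrix is None else self.n_matrix[row_indices].copy(),
            imputed=None if self.imputed is None else self.imputed[row_indices].copy(),
        )


def save_panel(panel: ZPanel, prefix: str) -> None:
    """Persist a panel as ``<prefix>.npz`` (arrays) + ``<prefix>.index.tsv``."""
    arrays = {
        "z": panel.z,
        "mask": panel.mask,
        "n_per_trait": panel.n_per_trait,
    }
    if panel.n_matrix is not None:
        arrays["n_matrix"] = panel.n_matrix
    if panel.imputed is not None:
        arrays["imputed"] = panel.imputed
    arrays["traits"] = np.asarray(panel.traits, dtype=object)
    np.savez(prefix + ".npz", **arrays)
    panel.snps.to_csv(prefix + ".index.tsv", sep="\t", index_label="rsid")


def load_panel(prefix: str) -> ZPanel:
    """Load a panel saved by :func:`save_panel`."""
    with np.load(prefix + ".npz", allow_pickle=True) as data:
        z = data["z"]
        mask = data["mask"]
        n_per_trait = data["n_per_trait"]
        traits = [str(t) for t in data["traits"]]
        n_matrix = data["n_matrix"] if "n_matrix" in data else None
        imputed = data["imputed"] if "imputed" in data else None
    snps = pd.read_csv(prefix + ".index.tsv", sep="\t", index_col="rsid")
    return ZPanel(snps=snps, z=z, traits=traits, n_per_trait=n_per_trait,
                  mask=mask, n_matrix=n_matrix, imputed=imputed)
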