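"""Core domain types: genotype-probability matrices, variant tables, cohorts.

The universal genotype representation is the per-individual, per-SNP triplet
``(p0, p1, p2)`` of posterior probabilities for carrying 0, 1 or 2 copies of
the alternative allele.  Downstream analyses collapse the triplet either into
the *dosage* (expected alternative-allele count, ``p1 + 2*p2``) or into the
*best guess* (the genotype with the highest posterior probability).  Dosage
preserves imputation uncertainty; best guess discards it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "GPMatrix",
    "VariantTable",
    "CohortStudy",
    "gp_to_dosage",
    "gp_to_best_guess",
]

_SUM_TOL = 1e-6


class GPMatrix:
    """N-individuals x M-SNPs matrix of genotype-probability triplets.

    Parameters
    ----------
    probs : ndarray, shape (N, M, 3)
        ``probs[i, j]`` is the probability triplet for individual ``i`` at
        SNP ``j``.  Triplets must be non-negative and sum to 1 within 1e-6.
        A triplet of all-NaN marks a masked (deleted, not yet imputed) entry;
        such entries are only meaningful inside the simulation pipeline.
    """

    def __init__(self, probs: np.ndarray):
        probs = np.asarray(probs, dtype=float)
        if probs.ndim != 3 or probs.shape[2] != 3:
            raise ValueError(f"probs must have shape (N, M, 3), got {probs.shape}")
        if probs.shape[0] < 1 or probs.shape[1] < 1:
            raise ValueError("GPMatrix needs at least one individual and one SNP")
        finite = ~np.isnan(probs).any(axis=2)
        vals = probs[finite]
        if vals.size:
            if (vals < -_SUM_TOL).any():
                raise ValueError("genotype probabilities must be non-negative")
            sums = vals.sum(axis=1)
            if (np.abs(sums - 1.0) > _SUM_TOL).any():
                bad = np.abs(sums - 1.0).max()
                raise ValueError(
                    f"genotype-probability triplets must sum to 1 (max deviation {bad:.2e})"
                )
        self.probs = probs

    # ------------------------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return self.probs.shape[0]

    @property
    def n_snps(self) -> int:
        return self.probs.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.probs.shape[:2]

    def missing_mask(self) -> np.ndarray:
        """Boolean (N, M) mask of masked/deleted entries."""
        return np.isnan(self.probs).any(axis=2)

    # ------------------------------------------------------------------
    def dosage(self) -> np.ndarray:
        """Expected alternative-allele count, shape (N, M); values in [0, 2]."""
        return self.probs[:, :, 1] + 2.0 * self.probs[:, :, 2]

    def best_guess(self) -> np.ndarray:
        """Hard genotype with the highest probability, shape (N, M).

        Ties break towards the lowest genotype index (``argmax`` convention),
        so a fully uniform triplet yields genotype 0.  Masked entries give -1.
        """
        miss = self.missing_mask()
        filled = np.where(np.isnan(self.probs), -np.inf, self.probs)
        bg = np.argmax(filled, axis=2).astype(np.int8)
        bg[miss] = -1
        return bg

    def __eq__(self, other) -> bool:  # pragma: no cover - convenience
        return isinstance(other, GPMatrix) and np.array_equal(
            self.probs, other.probs, equal_nan=True
        )

    def __repr__(self) -> str:  # pragma: no cover
        return f"GPMatrix(n_individuals={self.n_individuals}, n_snps={self.n_snps})"


def gp_to_dosage(gp: GPMatrix, snp_index: int) -> np.ndarray:
    """Dosage vector ``e_i = p_i1 + 2 p_i2`` for one SNP column."""
    col = gp.probs[:, snp_index, :]
    return col[:, 1] + 2.0 * col[:, 2]


def gp_to_best_guess(gp: GPMatrix, snp_index: int) -> np.ndarray:
    """Best-guess genotype vector for one SNP column (ties -> lowest index)."""
    # slice first so an out-of-range index raises like any array indexing
    _ = gp.probs[:, snp_index, :]
    return gp.best_guess()[:, snp_index]


class VariantTable:
    """Per-SNP metadata: chromosome, position, alleles, typed/imputed status.

    Positions are 1-based base-pair coordinates (VCF convention) and must be
    strictly increasing within each chromosome.  ``typed`` marks SNPs that
    were directly genotyped on the array scaffold, as opposed to imputed.
    """

    REQUIRED = ("chrom", "pos", "ref", "alt", "typed")

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise ValueError(f"VariantTable missing columns: {missing}")
        df = df.reset_index(drop=True).copy()
        df["chrom"] = df["chrom"].astype(str)
        df["pos"] = df["pos"].astype(np.int64)
        df["typed"] = df["typed"].astype(bool)
        for chrom, sub in df.groupby("chrom", sort=False):
            if not (np.diff(sub["pos"].to_numpy()) > 0).all():
                raise ValueError(
                    f"positions must be strictly increasing within chromosome {chrom}"
                )
        self.df = df

    @classmethod
    def from_arrays(cls, chrom, pos, ref=None, alt=None, typed=None) -> "VariantTable":
        pos = np.asarray(pos)
        n = len(pos)
        chrom = np.broadcast_to(np.asarray(chrom, dtype=object), (n,))
        return cls(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "pos": pos,
                    "ref": ref if ref is not None else ["A"] * n,
                    "alt": alt if alt is not None else ["G"] * n,
                    "typed": typed if typed is not None else np.ones(n, dtype=bool),
                }
            )
        )

    def __len__(self) -> int:
        return len(self.df)

    @property
    def chrom(self) -> np.ndarray:
        return self.df["chrom"].to_numpy()

    @property
    def pos(self) -> np.ndarray:
        return self.df["pos"].to_numpy()

    @property
    def typed(self) -> np.ndarray:
        return self.df["typed"].to_numpy()

    def with_typed(self, typed: np.ndarray) -> "VariantTable":
        df = self.df.copy()
        df["typed"] = np.asarray(typed, dtype=bool)
        return VariantTable(df)

    def __repr__(self) -> str:  # pragma: no cover
        return f"VariantTable(n_snps={len(self)})"


@dataclass
class CohortStudy:
    """A case-control cohort: two GP matrices over one shared variant table.

    ``covariates``, when present, stacks cases first then controls and must
    have one row per individual (numeric columns only, e.g. sex, age, PCs).
    """

    cases: GPMatrix
    controls: GPMatrix
    variants: VariantTable
    covariates: Optional[pd.DataFrame] = None

    def __post_init__(self):
        if self.cases.n_snps != len(self.variants) or self.controls.n_snps != len(
            self.variants
        ):
            raise ValueError(
                "cases and controls must share the VariantTable "
                f"({self.cases.n_snps}/{self.controls.n_snps} SNPs vs "
                f"{len(self.variants)} variants)"
            )
        if self.covariates is not None and len(self.covariates) != self.n_individuals:
            raise ValueError(
                f"covariates have {len(self.covariates)} rows, expected "
                f"{self.n_individuals}"
            )

    @property
    def n_cases(self) -> int:
        return self.cases.n_individuals

    @property
    def n_controls(self) -> int:
        return self.controls.n_individuals

    @property
    def n_individuals(self) -> int:
        return self.n_cases + self.n_controls

    @property
    def n_snps(self) -> int:
        return len(self.variants)

    def phenotype(self) -> np.ndarray:
        """Binary status vector: 1 for cases, 0 for controls (cases first)."""
        return np.r_[np.ones(self.n_cases), np.zeros(self.n_controls)]

    def combined_gp(self) -> GPMatrix:
        """GP matrix stacking cases on top of controls."""
        return GPMatrix(np.concatenate([self.cases.probs, self.controls.probs], axis=0))
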