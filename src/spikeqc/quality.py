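"""Per-SNP imputation-quality measures computed from genotype probabilities.

Implements the three classical post-imputation quality scores — the IMPUTE
info score, MaCH R² and a Beagle-style dosage R² — plus surrogate versions of
the Iam (``iam_chance``, ``iam_hwe``, and their combination) and hiQ accuracy
measures.  All are functions of the per-SNP column of genotype-probability
triplets alone; none look at true genotypes.

In a case-control setting the scores are computed separately per group and
combined across groups, by default taking the minimum: poor imputation in
even one group undermines the downstream association test.

Notes on the Iam/hiQ surrogates
-------------------------------
The published Iam hiQ measures are characterised here by their qualitative
behaviour: ``iam_chance`` is low when per-individual triplets are near
uniform (imputation by chance), ``iam_hwe`` is low when triplets follow the
Hardy-Weinberg triplet implied by the allele frequency (imputation by allele
frequency alone), ``iam_hwe`` never exceeds ``iam_chance``, and

    ``iam_combined = iam_hwe - iam_chance + 1``   (in [0, 1]).

The surrogates implement these properties with normalised total-variation
distances; they are not numerically interchangeable with the original
published scores, so published Iam thresholds do not transfer.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .core import CohortStudy, GPMatrix

__all__ = [
    "impute_info",
    "mach_r2",
    "beagle_dr2",
    "iam_scores",
    "hiq",
    "quality_table",
    "MEASURES",
]

log = logging.getLogger(__name__)

MEASURES = (
    "impute_info",
    "mach_r2",
    "beagle_dr2",
    "iam_chance",
    "iam_hwe",
    "iam_combined",
    "hiq",
)

_THETA_EPS = 1e-12


def _as_columns(gp) -> np.ndarray:
    """Accept a (N, 3) column or (N, M, 3) stack; return (N, M, 3)."""
    arr = np.asarray(gp, dtype=float)
    if arr.ndim == 2:
        arr = arr[:, None, :]
    if arr.ndim != 3 or arr.shape[-1] != 3 or arr.shape[0] < 1:
        raise ValueError("expected an (N, 3) GP column or (N, M, 3) stack")
    return arr


def _theta(arr: np.ndarray) -> np.ndarray:
    e = arr[:, :, 1] + 2.0 * arr[:, :, 2]
    return e.mean(axis=0) / 2.0


def impute_info(gp) -> np.ndarray | float:
    """IMPUTE info score: ratio of observed to expected statistical
    information about the allele frequency.

    With ``e_i = p_i1 + 2 p_i2``, ``f_i = p_i1 + 4 p_i2`` and
    ``theta = sum(e_i) / 2N``::

        info = 1 - sum(f_i - e_i^2) / (2N * theta * (1 - theta))

    Monomorphic columns (theta of 0 or 1) score 1 by convention.  The raw
    value can dip below 0 for badly calibrated triplets; it is clipped to
    [0, 1] with a log notice.
    """
    arr = _as_columns(gp)
    scalar = np.asarray(gp).ndim == 2
    n = arr.shape[0]
    e = arr[:, :, 1] + 2.0 * arr[:, :, 2]
    f = arr[:, :, 1] + 4.0 * arr[:, :, 2]
    theta = e.mean(axis=0) / 2.0
    denom = 2.0 * n * theta * (1.0 - theta)
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = 1.0 - (f - e**2).sum(axis=0) / denom
    mono = (theta < _THETA_EPS) | (theta > 1.0 - _THETA_EPS)
    raw = np.where(mono, 1.0, raw)
    if (raw < -1e-9).any():
        log.info("impute_info: %d negative raw values clipped to 0", int((raw < 0).sum()))
    out = np.clip(raw, 0.0, 1.0)
    return float(out[0]) if scalar else out


def mach_r2(gp) -> np.ndarray | float:
    """MaCH R²: population variance of the dosage over its binomial
    expectation ``2 theta (1 - theta)``.  0 for monomorphic columns; may
    exceed 1 by sampling variation."""
    arr = _as_columns(gp)
    scalar = np.asarray(gp).ndim == 2
    e = arr[:, :, 1] + 2.0 * arr[:, :, 2]
    theta = e.mean(axis=0) / 2.0
    denom = 2.0 * theta * (1.0 - theta)
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = e.var(axis=0) / denom
    mono = (theta < _THETA_EPS) | (theta > 1.0 - _THETA_EPS)
    out = np.where(mono, 0.0, raw)
    return float(out[0]) if scalar else out


def beagle_dr2(gp) -> np.ndarray | float:
    """Beagle-style dosage R²: squared Pearson correlation between the
    expected dosage and the best-guess dosage.  0 when either vector is
    constant.  Needs at least 2 individuals."""
    arr = _as_columns(gp)
    scalar = np.asarray(gp).ndim == 2
    n = arr.shape[0]
    if n < 2:
        raise ValueError("beagle_dr2 needs at least 2 individuals")
    e = arr[:, :, 1] + 2.0 * arr[:, :, 2]
    g = np.argmax(arr, axis=2).astype(float)
    ec = e - e.mean(axis=0)
    gc = g - g.mean(axis=0)
    se = (ec**2).sum(axis=0)
    sg = (gc**2).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = (ec * gc).sum(axis=0) ** 2 / (se * sg)
    out = np.where((se < _THETA_EPS) | (sg < _THETA_EPS), 0.0, r2)
    return float(out[0]) if scalar else out


_UNIF = np.array([1.0, 1.0, 1.0]) / 3.0
_MAX_TV_UNIF = 2.0 / 3.0  # TV distance from uniform to any simplex vertex


def iam_scores(gp) -> tuple:
    """Surrogate Iam accuracy scores ``(iam_chance, iam_hwe, iam_combined)``.

    ``iam_chance``: mean total-variation distance of each individual's
    triplet from the uniform triplet, normalised to [0, 1].  Low means the
    imputation was mostly random guessing.

    ``iam_hwe``: mean normalised total-variation distance from the
    Hardy-Weinberg triplet ``((1-theta)^2, 2 theta (1-theta), theta^2)``,
    clamped so it never exceeds ``iam_chance``.  Low means the triplets were
    driven by allele frequency alone, not individual information.

    ``iam_combined = iam_hwe - iam_chance + 1``, in [0, 1].
    """
    arr = _as_columns(gp)
    scalar = np.asarray(gp).ndim == 2
    chance = (0.5 * np.abs(arr - _UNIF).sum(axis=2)).mean(axis=0) / _MAX_TV_UNIF
    theta = _theta(arr)
    hwe = np.stack(
        [(1 - theta) ** 2, 2 * theta * (1 - theta), theta**2], axis=-1
    )  # (M, 3)
    max_tv = 1.0 - hwe.min(axis=-1)  # worst case: all mass on the rarest genotype
    tv = 0.5 * np.abs(arr - hwe[None, :, :]).sum(axis=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        raw_hwe = np.where(max_tv > _THETA_EPS, tv.mean(axis=0) / max_tv, 0.0)
    iam_hwe = np.minimum(raw_hwe, chance)
    combined = iam_hwe - chance + 1.0
    if scalar:
        return float(chance[0]), float(iam_hwe[0]), float(combined[0])
    return chance, iam_hwe, combined


def hiq(gp) -> np.ndarray | float:
    """Surrogate hiQ: heterogeneity of genotype probabilities between
    individuals.  With ``m_j`` the mean of ``p_ij`` over individuals::

        hiq = (1 - sum_j m_j^2) / (2/3)

    0 for monomorphic imputation (all mass on one genotype for everyone),
    1 when the mean triplet is uniform."""
    arr = _as_columns(gp)
    scalar = np.asarray(gp).ndim == 2
    m = arr.mean(axis=0)
    out = (1.0 - (m**2).sum(axis=-1)) / (2.0 / 3.0)
    return float(out[0]) if scalar else out


def _group_scores(probs: np.ndarray) -> dict[str, np.ndarray]:
    chance, ihwe, comb = iam_scores(probs)
    return {
        "impute_info": impute_info(probs),
        "mach_r2": mach_r2(probs),
        "beagle_dr2": beagle_dr2(probs),
        "iam_chance": chance,
        "iam_hwe": ihwe,
        "iam_combined": comb,
        "hiq": hiq(probs),
    }


_COMBINERS = {"min": np.minimum, "max": np.maximum, "mean": lambda a, b: (a + b) / 2.0}


def quality_table(study: CohortStudy, group_combine: str = "min") -> pd.DataFrame:
    """Per-SNP quality table with per-group and combined columns.

    Every measure is computed separately for cases and controls (columns
    ``<measure>_cases`` / ``<measure>_controls``) and combined across groups
    under ``group_combine`` in {"min" (default), "mean", "max"} into
    ``<measure>``, which is the column the Midrange Filter consumes.  The
    estimated alternative-allele frequency per group is included as
    ``theta_cases`` / ``theta_controls``.
    """
    if group_combine not in _COMBINERS:
        raise ValueError(f"group_combine must be one of {sorted(_COMBINERS)}")
    if study.n_cases == 0 or study.n_controls == 0:
        raise ValueError("both groups must contain at least one individual")
    combine = _COMBINERS[group_combine]
    out = pd.DataFrame(
        {
            "chrom": study.variants.chrom,
            "pos": study.variants.pos,
            "typed": study.variants.typed,
        }
    )
    ca = _group_scores(study.cases.probs)
    co = _group_scores(study.controls.probs)
    for m in MEASURES:
        out[f"{m}_cases"] = ca[m]
        out[f"{m}_controls"] = co[m]
        out[m] = combine(ca[m], co[m])
    out["theta_cases"] = _theta(study.cases.probs)
    out["theta_controls"] = _theta(study.controls.probs)
    return out
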