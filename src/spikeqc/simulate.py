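"""Desk-scale synthetic case-control cohorts with imputation uncertainty.

This module emulates, at laptop scale, the structure of a genotype-array
GWAS with post-imputation artefacts:

* a haplotype pool with linkage disequilibrium from a first-order copying
  process (each allele is carried over from the previous SNP with
  probability ``1 - ld_decay``, resampled from the population frequency
  otherwise), optionally with two diverged subpopulations;
* case-control sampling under a logistic disease model with configurable
  per-locus odds ratios and dominance coding, with the intercept solved for
  a target population prevalence;
* deletion of SNPs down to an array-like scaffold (quasi-regular,
  frequency-biased) or by uniform random deletion;
* a surrogate imputer that fills deleted SNPs with genotype-probability
  triplets by weighting reference haplotype pairs by their agreement with
  the individual's typed genotypes over a window of nearby scaffold SNPs —
  cases and controls are imputed independently against disjoint panels;
* gold-standard truth labels from an association scan of the complete
  (pre-deletion) data.

The generator preserves the statistical features the Midrange Filter needs
(LD spikes, an imputation-quality gradient driven by scaffold density and
panel size/match, separately imputed groups); it makes no claim to
population-genetic realism beyond that.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .association import assoc_scan
from .core import CohortStudy, GPMatrix, VariantTable

log = logging.getLogger(__name__)

__all__ = [
    "DiseaseLocus",
    "DeletionConfig",
    "SimConfig",
    "HaplotypePool",
    "simulate_haplotype_pool",
    "sample_case_control",
    "apply_deletion_mask",
    "surrogate_impute",
    "make_truth",
    "TruthLabels",
    "simulate_cohort",
]

MAX_POOL_RETRIES = 5
MAX_SAMPLING_BATCHES = 500


@dataclass(frozen=True)
class DiseaseLocus:
    """A causal SNP: ``index`` into the variant table (None = pick randomly
    among SNPs whose pool MAF lies in the configured range), odds ratio per
    risk unit, and dominance coding."""

    index: Optional[int] = None
    odds_ratio: float = 3.0
    model: str = "additive"  # additive | dominant | recessive

    def risk_code(self, genotypes: np.ndarray) -> np.ndarray:
        if self.model == "additive":
            return genotypes.astype(float)
        if self.model == "dominant":
            return (genotypes >= 1).astype(float)
        if self.model == "recessive":
            return (genotypes == 2).astype(float)
        raise ValueError(f"unknown dominance model {self.model!r}")


@dataclass(frozen=True)
class DeletionConfig:
    """SNP deletion down to the typed scaffold.

    ``mode='scaffold'``: keep a quasi-regular, frequency-biased subset of
    fraction ``fraction`` (array emulation).  ``mode='uniform'``: delete
    each SNP independently with probability ``fraction`` (the classical
    80% random-deletion design uses fraction 0.8).
    """

    mode: str = "scaffold"
    fraction: float = 0.14

    def __post_init__(self):
        if self.mode not in ("scaffold", "uniform"):
            raise ValueError("deletion mode must be 'scaffold' or 'uniform'")
        hi = 1.0 if self.mode == "scaffold" else 1.0 - 1e-12
        if not 0.0 < self.fraction <= hi:
            raise ValueError("deletion fraction out of range for mode")


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated case-control cohort.

    Defaults mirror a small clinical GWAS: 1,000 cases and 1,000 controls,
    reference panels of 10,000 individuals per group, disease-locus minor
    allele frequencies in [0.05, 0.4], odds ratios from {1.5, 3} with
    optional dominance, an array-like scaffold, and population prevalence
    0.1.  ``panel_size`` is per group; cases and controls are imputed
    against disjoint panels.  ``ld_decay`` is the per-adjacent-SNP copying
    switch probability; ``mismatch`` holds one subpopulation out of the
    reference pool so panels are mildly mismatched to the cohort.
    """

    n_snps: int = 2000
    n_cases: int = 1000
    n_controls: int = 1000
    panel_size: int = 10000
    maf_range: tuple[float, float] = (0.05, 0.4)
    disease_loci: tuple[DiseaseLocus, ...] = (DiseaseLocus(None, 3.0, "additive"),)
    deletion: DeletionConfig = DeletionConfig()
    mismatch: bool = False
    ld_decay: float = 0.1
    prevalence: float = 0.1
    spacing_bp: int = 5000
    k_window: int = 8
    match_alpha: float = 0.3
    seed: int = 0

    def __post_init__(self):
        for name in ("n_snps", "n_cases", "n_controls", "panel_size"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.ld_decay <= 1.0:
            raise ValueError("ld_decay must be in [0, 1]")
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError("prevalence must be in (0, 1)")
        lo, hi = self.maf_range
        if not 0.0 < lo < hi <= 0.5:
            raise ValueError("maf_range must satisfy 0 < lo < hi <= 0.5")

    # -- plain-text round trip -----------------------------------------
    def to_file(self, path) -> None:
        lines = [
            f"n_snps={self.n_snps}",
            f"n_cases={self.n_cases}",
            f"n_controls={self.n_controls}",
            f"panel_size={self.panel_size}",
            f"maf_range={self.maf_range[0]},{self.maf_range[1]}",
            "disease_loci="
            + ";".join(
                f"{'auto' if d.index is None else d.index},{d.odds_ratio},{d.model}"
                for d in self.disease_loci
            ),
            f"deletion={self.deletion.mode},{self.deletion.fraction}",
            f"mismatch={int(self.mismatch)}",
            f"ld_decay={self.ld_decay}",
            f"prevalence={self.prevalence}",
            f"spacing_bp={self.spacing_bp}",
            f"k_window={self.k_window}",
            f"match_alpha={self.match_alpha}",
            f"seed={self.seed}",
        ]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path) -> "SimConfig":
        kv = {}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            k, _, v = line.partition("=")
            kv[k.strip()] = v.strip()
        loci = []
        if kv.get("disease_loci"):
            for part in kv["disease_loci"].split(";"):
                idx, or_, model = part.split(",")
                loci.append(
                    DiseaseLocus(
                        None if idx == "auto" else int(idx), float(or_), model
                    )
                )
        mode, frac = kv["deletion"].split(",")
        lo, hi = kv["maf_range"].split(",")
        return cls(
            n_snps=int(kv["n_snps"]),
            n_cases=int(kv["n_cases"]),
            n_controls=int(kv["n_controls"]),
            panel_size=int(kv["panel_size"]),
            maf_range=(float(lo), float(hi)),
            disease_loci=tuple(loci),
            deletion=DeletionConfig(mode, float(frac)),
            mismatch=bool(int(kv["mismatch"])),
            ld_decay=float(kv["ld_decay"]),
            prevalence=float(kv["prevalence"]),
            spacing_bp=int(kv["spacing_bp"]),
            k_window=int(kv["k_window"]),
            match_alpha=float(kv["match_alpha"]),
            seed=int(kv["seed"]),
        )


@dataclass
class HaplotypePool:
    """Haplotypes for the study + reference pools, with resolved loci."""

    haplotypes: np.ndarray  # (n_hap, n_snps) int8
    subpop: np.ndarray  # (n_hap,) int8
    freqs: np.ndarray  # (n_subpops, n_snps) generating frequencies
    variants: VariantTable
    disease_loci: tuple[DiseaseLocus, ...]  # indices resolved

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]

    def allele_freq(self) -> np.ndarray:
        return self.haplotypes.mean(axis=0)


def _gen_haplotypes(
    freqs: np.ndarray, subpop: np.ndarray, ld_decay: float, rng: np.random.Generator
) -> np.ndarray:
    n_hap = subpop.size
    n_snps = freqs.shape[1]
    H = np.empty((n_hap, n_snps), dtype=np.int8)
    f = freqs[subpop, :]  # (n_hap, n_snps)
    H[:, 0] = rng.random(n_hap) < f[:, 0]
    for j in range(1, n_snps):
        fresh = rng.random(n_hap) < f[:, j]
        if ld_decay >= 1.0:
            H[:, j] = fresh
        elif ld_decay <= 0.0:
            H[:, j] = H[:, j - 1]
        else:
            switch = rng.random(n_hap) < ld_decay
            H[:, j] = np.where(switch, fresh, H[:, j - 1])
    return H


def simulate_haplotype_pool(config: SimConfig) -> HaplotypePool:
    """Generate the haplotype pool: ``2*(panel_size + n_cases + n_controls)``
    haplotypes over ``n_snps`` SNPs with copying-process LD and two mildly
    diverged subpopulations.

    Disease loci with ``index=None`` are resolved to random SNPs whose pool
    minor allele frequency lies in ``maf_range``; a pool in which any
    resolved locus falls outside the range (or is monomorphic) is
    regenerated with a logged retry, up to a cap.
    """
    rng = np.random.default_rng(config.seed)
    n_hap = 2 * (config.panel_size + config.n_cases + config.n_controls)
    pos = config.spacing_bp * np.arange(1, config.n_snps + 1) + rng.integers(
        0, max(config.spacing_bp // 2, 2), size=config.n_snps
    )
    pos = np.sort(pos)
    pos = pos + np.arange(config.n_snps)  # guarantee strictly increasing
    variants = VariantTable.from_arrays(
        chrom="1", pos=pos, typed=np.ones(config.n_snps, dtype=bool)
    )

    lo, hi = config.maf_range
    for attempt in range(1, MAX_POOL_RETRIES + 1):
        base = rng.uniform(0.05, 0.95, size=config.n_snps)
        delta = rng.normal(0.0, 0.04, size=config.n_snps)
        freqs = np.clip(np.stack([base - delta, base + delta]), 0.02, 0.98)
        subpop = (np.arange(n_hap) % 2).astype(np.int8)
        rng.shuffle(subpop)
        H = _gen_haplotypes(freqs, subpop, config.ld_decay, rng)
        pool_freq = H.mean(axis=0)
        maf = np.minimum(pool_freq, 1.0 - pool_freq)
        eligible = np.flatnonzero((maf >= lo) & (maf <= hi))
        loci: list[DiseaseLocus] = []
        ok = True
        if len(eligible) < len(config.disease_loci):
            ok = False
        else:
            chosen = rng.choice(eligible, size=len(config.disease_loci), replace=False)
            for d, c in zip(config.disease_loci, chosen):
                idx = d.index if d.index is not None else int(c)
                if not (lo <= maf[idx] <= hi):
                    ok = False
                    break
                loci.append(replace(d, index=idx))
        if ok:
            return HaplotypePool(
                haplotypes=H,
                subpop=subpop,
                freqs=freqs,
                variants=variants,
                disease_loci=tuple(loci),
            )
        log.warning(
            "pool attempt %d: disease locus MAF outside %s; regenerating", attempt,
            config.maf_range,
        )
    raise RuntimeError(
        f"could not place disease loci with MAF in {config.maf_range} after "
        f"{MAX_POOL_RETRIES} pool regenerations"
    )


def _solve_intercept(score: np.ndarray, prevalence: float) -> float:
    lo, hi = -30.0, 10.0
    return brentq(lambda b0: expit(b0 + score).mean() - prevalence, lo, hi)


def sample_case_control(
    pool: HaplotypePool, config: SimConfig
) -> tuple[CohortStudy, dict[str, np.ndarray]]:
    """Draw the complete-data cohort and the per-group reference panels.

    The pool is split into disjoint halves; study individuals are formed by
    pairing haplotypes resampled from the study half and assigned case or
    control status under the logistic disease model (intercept solved so
    the population prevalence matches the configured value).  Reference
    panels are two disjoint haplotype sets from the reference half (cases
    and controls are later imputed against their own panel).  With
    ``mismatch``, the reference half is restricted to subpopulation 0 while
    the cohort draws from both.

    Complete-data GP triplets are degenerate (probability 1 on the true
    genotype).  Raises if the configured prevalence makes the case count
    unattainable in a bounded number of sampling batches.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    n_hap = pool.n_haplotypes
    perm = rng.permutation(n_hap)
    study_idx = perm[: n_hap // 2]
    ref_idx = perm[n_hap // 2 :]
    if config.mismatch:
        ref_idx = ref_idx[pool.subpop[ref_idx] == 0]
        if ref_idx.size < 4:
            raise RuntimeError("mismatch setting left too few reference haplotypes")

    H = pool.haplotypes
    loci = pool.disease_loci
    beta = np.array([np.log(d.odds_ratio) for d in loci])

    def risk_score(geno_cols: np.ndarray) -> np.ndarray:
        s = np.zeros(geno_cols.shape[0])
        for k, d in enumerate(loci):
            s += beta[k] * d.risk_code(geno_cols[:, k])
        return s

    locus_cols = np.array([d.index for d in loci], dtype=int)

    # intercept from a large candidate draw off the study half
    cal = rng.choice(study_idx, size=(4000, 2), replace=True)
    g_cal = (H[cal[:, 0]][:, locus_cols] + H[cal[:, 1]][:, locus_cols]).astype(np.int8)
    b0 = _solve_intercept(risk_score(g_cal), config.prevalence)

    need_cases, need_controls = config.n_cases, config.n_controls
    case_rows: list[np.ndarray] = []
    ctrl_rows: list[np.ndarray] = []
    batch = max(2000, (need_cases + need_controls) * 2)
    for _ in range(MAX_SAMPLING_BATCHES):
        if len(case_rows) >= need_cases and len(ctrl_rows) >= need_controls:
            break
        pairs = rng.choice(study_idx, size=(batch, 2), replace=True)
        g_loc = (H[pairs[:, 0]][:, locus_cols] + H[pairs[:, 1]][:, locus_cols]).astype(
            np.int8
        )
        p = expit(b0 + risk_score(g_loc))
        is_case = rng.random(batch) < p
        for row, case in zip(pairs, is_case):
            if case and len(case_rows) < need_cases:
                case_rows.append(row)
            elif not case and len(ctrl_rows) < need_controls:
                ctrl_rows.append(row)
    if len(case_rows) < need_cases or len(ctrl_rows) < need_controls:
        raise RuntimeError(
            "could not reach the requested case/control counts; the disease-model "
            "prevalence is too extreme — adjust the intercept via config.prevalence"
        )

    def genotypes(rows: list[np.ndarray]) -> np.ndarray:
        idx = np.asarray(rows)
        return (H[idx[:, 0]] + H[idx[:, 1]]).astype(np.int8)

    def degenerate_gp(G: np.ndarray) -> GPMatrix:
        n, m = G.shape
        probs = np.zeros((n, m, 3))
        ii, jj = np.indices(G.shape)
        probs[ii, jj, G] = 1.0
        return GPMatrix(probs)

    study = CohortStudy(
        cases=degenerate_gp(genotypes(case_rows)),
        controls=degenerate_gp(genotypes(ctrl_rows)),
        variants=pool.variants,
    )
    half = ref_idx.size // 2
    panel_hap = 2 * config.panel_size
    panels = {
        "cases": H[ref_idx[: min(half, panel_hap)]],
        "controls": H[ref_idx[half : half + min(half, panel_hap)]],
    }
    return study, panels


def apply_deletion_mask(study: CohortStudy, config: SimConfig) -> CohortStudy:
    """Delete SNPs down to the typed scaffold.

    Scaffold mode keeps a quasi-regular, frequency-biased subset (within
    each window of ``1/fraction`` consecutive SNPs the most common SNP is
    kept — array manifests favour common variants).  Uniform mode deletes
    each SNP independently with the configured probability.  Deleted
    entries become NaN triplets; the variant table keeps every SNP with the
    typed flag updated.  Disease loci get no protection.  Raises if fewer
    than 2 typed SNPs remain.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    m = study.n_snps
    dosage = np.concatenate(
        [study.cases.dosage(), study.controls.dosage()], axis=0
    )
    freq = dosage.mean(axis=0) / 2.0
    maf = np.minimum(freq, 1.0 - freq)
    if config.deletion.mode == "uniform":
        typed = rng.random(m) >= config.deletion.fraction
    else:
        n_keep = max(2, int(round(m * config.deletion.fraction)))
        edges = np.linspace(0, m, n_keep + 1).astype(int)
        typed = np.zeros(m, dtype=bool)
        for a, b in zip(edges[:-1], edges[1:]):
            if b > a:
                typed[a + int(np.argmax(maf[a:b]))] = True
    if typed.sum() < 2:
        raise ValueError("deletion mask leaves fewer than 2 typed SNPs")

    def masked(gp: GPMatrix) -> GPMatrix:
        probs = gp.probs.copy()
        probs[:, ~typed, :] = np.nan
        return GPMatrix(probs)

    return CohortStudy(
        cases=masked(study.cases),
        controls=masked(study.controls),
        variants=study.variants.with_typed(typed),
        covariates=study.covariates,
    )


def _impute_group(
    gp: GPMatrix,
    variants: VariantTable,
    panel: np.ndarray,
    k_window: int,
    alpha: float,
) -> tuple[np.ndarray, int]:
    typed = variants.typed
    pos = variants.pos
    typed_idx = np.flatnonzero(typed)
    untyped_idx = np.flatnonzero(~typed)
    probs = gp.probs.copy()
    if untyped_idx.size == 0:
        return probs, 0
    # reference individuals: pair consecutive haplotypes
    n_ref = panel.shape[0] // 2
    R = (panel[0 : 2 * n_ref : 2] + panel[1 : 2 * n_ref : 2]).astype(np.int8)
    G_typed = np.rint(gp.dosage()[:, typed_idx]).astype(np.int8)  # degenerate
    n_empty = 0

    # window of the k nearest typed SNPs for each untyped SNP; untyped SNPs
    # sharing a window are imputed in one matrix product
    windows: dict[tuple, list[int]] = {}
    tp = pos[typed_idx]
    for j in untyped_idx:
        if typed_idx.size == 0:
            windows.setdefault((), []).append(j)
            continue
        k = min(k_window, typed_idx.size)
        ins = np.searchsorted(tp, pos[j])
        lo = max(0, ins - k)
        hi = min(typed_idx.size, ins + k)
        cand = np.arange(lo, hi)
        order = np.argsort(np.abs(tp[cand] - pos[j]), kind="stable")
        win = tuple(sorted(cand[order[:k]].tolist()))
        windows.setdefault(win, []).append(j)

    log_alpha = np.log(alpha)
    for win, js in windows.items():
        js = np.asarray(js)
        if not win:
            probs[:, js, :] = 1.0 / 3.0
            n_empty += len(js)
            continue
        wcols = typed_idx[list(win)]
        D = np.zeros((G_typed.shape[0], n_ref), dtype=np.int16)
        Gw = G_typed[:, list(win)]
        Rw = R[:, wcols]
        for c in range(Gw.shape[1]):
            D += Gw[:, c][:, None] != Rw[:, c][None, :]
        W = np.exp(D * log_alpha)
        W /= W.sum(axis=1, keepdims=True)
        Rj = R[:, js]  # (n_ref, m)
        for g in (0, 1, 2):
            probs[:, js, g] = W @ (Rj == g)
    # numerical guard: renormalise
    sub = probs[:, untyped_idx, :]
    probs[:, untyped_idx, :] = sub / sub.sum(axis=2, keepdims=True)
    return probs, n_empty


def surrogate_impute(
    masked_study: CohortStudy,
    panels: dict[str, np.ndarray],
    k_window: int | None = None,
    alpha: float | None = None,
    config: SimConfig | None = None,
) -> CohortStudy:
    """Fill deleted SNPs with genotype-probability triplets.

    For each individual and untyped SNP, every reference individual (a
    haplotype pair from that group's panel) is weighted by
    ``alpha ** mismatches`` against the individual's typed genotypes over
    the ``k_window`` nearest scaffold SNPs; the GP triplet is the
    weight-normalised distribution of reference genotypes at the SNP.
    Cases and controls are imputed independently against their own panels.
    Typed SNPs keep their degenerate triplets.  An untyped SNP with no
    scaffold SNP in reach receives the uniform triplet (counted and
    logged).
    """
    if config is not None:
        k_window = config.k_window if k_window is None else k_window
        alpha = config.match_alpha if alpha is None else alpha
    k_window = 8 if k_window is None else k_window
    alpha = 0.3 if alpha is None else alpha

    out = {}
    total_empty = 0
    for group, gp in (("cases", masked_study.cases), ("controls", masked_study.controls)):
        probs, n_empty = _impute_group(
            gp, masked_study.variants, panels[group], k_window, alpha
        )
        total_empty += n_empty
        out[group] = GPMatrix(probs)
    if total_empty:
        log.warning("surrogate_impute: %d SNP columns had empty windows (uniform GP)",
                    total_empty)
    return CohortStudy(
        cases=out["cases"],
        controls=out["controls"],
        variants=masked_study.variants,
        covariates=masked_study.covariates,
    )


@dataclass
class TruthLabels:
    """Gold-standard labels from the complete (pre-deletion) data."""

    table: pd.DataFrame  # chrom, pos, p_gold, sig_gold
    significance: float

    def snp_truth(self) -> pd.Series:
        return self.table.set_index(["chrom", "pos"])["sig_gold"]

    def spike_is_true(self, spike) -> bool:
        """A spike is a true signal iff it contains at least one SNP that is
        significant in the gold standard (spikes mixing false-positive and
        false-negative members therefore count as true)."""
        sub = self.table[self.table["chrom"].astype(str) == str(spike.chrom)]
        sub = sub[sub["pos"].isin(np.asarray(spike.positions))]
        return bool(sub["sig_gold"].any())

    def label_spikes(self, spikes: list) -> list:
        for sp in spikes:
            sp.truth = self.spike_is_true(sp)
        return spikes


def make_truth(
    complete_study: CohortStudy,
    gold_assoc: pd.DataFrame | None = None,
    significance: float = 5e-8,
) -> TruthLabels:
    """Truth labels: a SNP is truly associated iff it is significant in the
    complete data.  With degenerate complete-data GP the dosage and
    best-guess scans coincide, so one gold scan covers both formats."""
    if gold_assoc is None:
        gold_assoc = assoc_scan(complete_study, fmt="dosage")
    p = gold_assoc["p"].to_numpy(dtype=float)
    table = pd.DataFrame(
        {
            "chrom": gold_assoc["chrom"].astype(str),
            "pos": gold_assoc["pos"].astype(int),
            "p_gold": p,
            "sig_gold": p < significance,
        }
    )
    return TruthLabels(table=table, significance=significance)


def simulate_cohort(config: SimConfig) -> dict:
    """Full generation pipeline: pool -> cohort + panels -> deletion ->
    surrogate imputation -> truth labels.

    Returns a dict with keys ``pool, complete, masked, imputed, panels,
    truth``.  Deterministic for a given config (all randomness flows from
    ``config.seed``)."""
    pool = simulate_haplotype_pool(config)
    complete, panels = sample_case_control(pool, config)
    masked = apply_deletion_mask(complete, config)
    imputed = surrogate_impute(masked, panels, config=config)
    truth = make_truth(complete)
    return {
        "pool": pool,
        "complete": complete,
        "masked": masked,
        "imputed": imputed,
        "panels": panels,
        "truth": truth,
    }
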