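"""The Midrange Filter: spike-level post-imputation quality control.

Per-SNP filtering at a single imputation-quality threshold faces a dilemma
in the *midrange* of quality (IMPUTE info between the established 0.3 and
0.8 thresholds): a high threshold discards true associations, a low one
keeps false ones, and within the midrange the two classes are not separable
SNP by SNP.  The Midrange Filter instead decides whole spikes, using both
thresholds and the dosage/best-guess format dichotomy:

1. A spike containing a significant directly-typed SNP is kept (the typed
   anchor secures the signal).
2. Any spike whose minimum member imputation quality fails the lower
   threshold is discarded.
3. A spike specific to the best-guess format must additionally show at
   least one member passing the upper threshold, because dosage has more
   power: a signal visible only after flattening the genotype
   probabilities needs high-confidence imputation to be credible.
4. Everything else is kept.

"Fails a threshold" means strictly below; a quality exactly at the
threshold passes.  The quality fed to the rules is a per-SNP measure
combined across the separately-imputed case and control groups (minimum by
default — poor imputation in even one group undermines the test).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .association import assoc_scan, significant_set
from .core import CohortStudy
from .quality import MEASURES, quality_table
from .spikes import GAP_LIMIT, Spike, aggregate, annotate_spikes, complete_spikes

__all__ = [
    "FilterConfig",
    "FilterDecision",
    "classify_spike",
    "run_filter",
    "MidrangeFilter",
    "MidrangeFilterResults",
]

KEEP = "keep"
DISCARD = "discard"


@dataclass(frozen=True)
class FilterConfig:
    """Tuning knobs of the Midrange Filter.

    lower_threshold / upper_threshold
        The minimum-acceptable and high-confidence imputation-quality
        thresholds (defaults 0.3 and 0.8, the established IMPUTE info
        values, which also delimit the midrange).
    quality_measure
        Which per-SNP measure the rules read: impute_info (default),
        mach_r2 or beagle_dr2.
    group_combine
        How case/control scores merge into one per-SNP value: min
        (default), mean or max.
    significance / suggestive
        Genome-wide significance (5e-8) and the spike-building suggestive
        threshold (5e-7).
    presence_threshold
        P-value threshold for calling a format present in a spike;
        defaults to ``suggestive``.
    gap_limit
        Chaining distance for spikes, in base pairs (default 2 Mb).
    initial_format
        Format of the initial quality-restricted association scan.
    """

    lower_threshold: float = 0.3
    upper_threshold: float = 0.8
    quality_measure: str = "impute_info"
    group_combine: str = "min"
    significance: float = 5e-8
    suggestive: float = 5e-7
    presence_threshold: Optional[float] = None
    gap_limit: int = GAP_LIMIT
    initial_format: str = "dosage"

    def __post_init__(self):
        if not (0.0 <= self.lower_threshold < self.upper_threshold <= 1.0):
            raise ValueError("need 0 <= lower_threshold < upper_threshold <= 1")
        if self.quality_measure not in MEASURES:
            raise ValueError(f"unknown quality measure {self.quality_measure!r}")
        if self.group_combine not in ("min", "mean", "max"):
            raise ValueError("group_combine must be min, mean or max")
        if self.initial_format not in ("dosage", "best_guess"):
            raise ValueError("initial_format must be dosage or best_guess")

    @property
    def presence(self) -> float:
        return self.presence_threshold if self.presence_threshold is not None else self.suggestive


@dataclass(frozen=True)
class FilterDecision:
    spike_id: str
    verdict: str  # keep | discard
    reason: str  # typed_anchor | q_min_below_lower | bg_specific_q_max_below_upper | passed
    case: str  # typed | dosage_detectable | bestguess_only
    q_min: float
    q_max: float
    n_members: int


def classify_spike(spike: Spike, config: FilterConfig) -> FilterDecision:
    """Apply the Midrange Filter decision rules to one annotated spike.

    Rule order: typed anchor -> minimum-quality rule -> best-guess-specific
    maximum-quality rule -> keep.
    """
    if not spike.formats_present and not spike.has_typed_significant:
        raise ValueError(
            f"spike {spike.spike_id} is unannotated (no formats_present); run "
            "annotate_spikes first"
        )
    if spike.has_typed_significant:
        case = "typed"
    elif "dosage" in spike.formats_present:
        case = "dosage_detectable"
    else:
        case = "bestguess_only"

    if case == "typed":
        verdict, reason = KEEP, "typed_anchor"
    elif spike.q_min < config.lower_threshold:  # NaN compares False -> falls through
        verdict, reason = DISCARD, "q_min_below_lower"
    elif case == "bestguess_only" and spike.q_max < config.upper_threshold:
        verdict, reason = DISCARD, "bg_specific_q_max_below_upper"
    else:
        verdict, reason = KEEP, "passed"
    return FilterDecision(
        spike_id=spike.spike_id,
        verdict=verdict,
        reason=reason,
        case=case,
        q_min=spike.q_min,
        q_max=spike.q_max,
        n_members=spike.n_members,
    )


def _decisions_frame(spikes: list[Spike], decisions: list[FilterDecision]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "spike_id": [d.spike_id for d in decisions],
            "chrom": [s.chrom for s in spikes],
            "start": [s.start for s in spikes],
            "end": [s.end for s in spikes],
            "n_members": [d.n_members for d in decisions],
            "case": [d.case for d in decisions],
            "verdict": [d.verdict for d in decisions],
            "reason": [d.reason for d in decisions],
            "q_min": [d.q_min for d in decisions],
            "q_max": [d.q_max for d in decisions],
            "truth": [s.truth for s in spikes],
        }
    )


def _classify_all(
    spikes: list[Spike], snp_table: pd.DataFrame, config: FilterConfig
) -> "MidrangeFilterResults":
    spikes = annotate_spikes(
        spikes,
        snp_table,
        presence_threshold=config.presence,
        significance=config.significance,
    )
    decisions = [classify_spike(sp, config) for sp in spikes]
    ddf = _decisions_frame(spikes, decisions)
    kept_pos = {
        (s.chrom, int(p))
        for s, d in zip(spikes, decisions)
        if d.verdict == KEEP
        for p in s.positions
    }
    member_pos = {(s.chrom, int(p)) for s in spikes for p in s.positions}
    keys = list(zip(snp_table["chrom"].astype(str), snp_table["pos"].astype(int)))
    in_kept = np.array([k in kept_pos for k in keys])
    in_spike = np.array([k in member_pos for k in keys])
    filtered = snp_table[in_kept].reset_index(drop=True)
    report = {
        "n_spikes": len(spikes),
        "n_kept": int(sum(d.verdict == KEEP for d in decisions)),
        "n_discarded": int(sum(d.verdict == DISCARD for d in decisions)),
        "n_member_snps": int(in_spike.sum()),
        "n_kept_snps": int(in_kept.sum()),
    }
    return MidrangeFilterResults(
        config=config,
        spikes=spikes,
        decisions=decisions,
        decision_table=ddf,
        snp_table=snp_table.reset_index(drop=True),
        filtered_snps=filtered,
        report=report,
    )


def run_filter(study: CohortStudy, config: FilterConfig = FilterConfig()):
    """End-to-end Midrange Filter pipeline on a cohort with GP data.

    quality table -> quality-restricted initial scan (both formats) ->
    significance check -> follow-up association around spikes for SNPs the
    restriction skipped -> chaining + annotation -> per-spike verdicts.

    Returns ``(decisions, filtered_snps, report)`` where ``decisions`` is a
    per-spike DataFrame, ``filtered_snps`` keeps every member SNP of kept
    spikes, and ``report`` carries stage counts.  See
    :class:`MidrangeFilter` for the object-style interface.
    """
    res = MidrangeFilter(study=study, config=config).fit()
    return res.decision_table, res.filtered_snps, res.report


class MidrangeFilter:
    """Midrange Filter model, statsmodels-style.

    Construct either from a :class:`~spikeqc.core.CohortStudy` carrying
    genotype probabilities (the full pipeline: quality, association,
    aggregation, classification) or from a precomputed per-SNP table via
    :meth:`from_snp_table` (summary-statistic input: one row per SNP with
    ``chrom, pos, typed, p_dosage, p_best_guess, quality``).  ``fit()``
    returns a :class:`MidrangeFilterResults`.
    """

    def __init__(
        self,
        study: Optional[CohortStudy] = None,
        config: FilterConfig = FilterConfig(),
        snp_table: Optional[pd.DataFrame] = None,
    ):
        if (study is None) == (snp_table is None):
            raise ValueError("provide exactly one of study or snp_table")
        self.study = study
        self.snp_table = snp_table
        self.config = config

    @classmethod
    def from_snp_table(
        cls, snp_table: pd.DataFrame, config: FilterConfig = FilterConfig()
    ) -> "MidrangeFilter":
        required = {"chrom", "pos", "typed", "p_dosage", "p_best_guess", "quality"}
        missing = required - set(snp_table.columns)
        if missing:
            raise ValueError(f"snp_table missing columns: {sorted(missing)}")
        return cls(snp_table=snp_table, config=config)

    # ------------------------------------------------------------------
    def fit(self) -> "MidrangeFilterResults":
        if self.snp_table is not None:
            return self._fit_from_table()
        return self._fit_from_study()

    def _fit_from_table(self) -> "MidrangeFilterResults":
        cfg = self.config
        t = self.snp_table.copy()
        t["chrom"] = t["chrom"].astype(str)
        pmin = np.fmin(t["p_dosage"].to_numpy(float), t["p_best_guess"].to_numpy(float))
        sel = t[pmin < cfg.presence]
        pos_by_chrom = {
            c: sub["pos"].to_numpy() for c, sub in sel.groupby("chrom", sort=False)
        }
        spikes = aggregate(pos_by_chrom, gap_limit=cfg.gap_limit)
        return _classify_all(spikes, t, cfg)

    def _fit_from_study(self) -> "MidrangeFilterResults":
        cfg = self.config
        study = self.study
        qt = quality_table(study, group_combine=cfg.group_combine)
        q = qt[cfg.quality_measure].to_numpy(float)
        typed = study.variants.typed
        # typed SNPs carry real genotypes; the quality restriction is about
        # imputed SNPs only
        mask = typed | (q >= cfg.lower_threshold)

        scans = {
            fmt: assoc_scan(study, fmt=fmt, snp_mask=mask)
            for fmt in ("dosage", "best_guess")
        }
        snp_table = pd.DataFrame(
            {
                "chrom": study.variants.chrom.astype(str),
                "pos": study.variants.pos,
                "typed": typed,
                "p_dosage": scans["dosage"]["p"].to_numpy(),
                "p_best_guess": scans["best_guess"]["p"].to_numpy(),
                "quality": np.where(typed, np.nan, q),
                "tested": mask,
            }
        )
        n_sig = int(
            (np.fmin(snp_table["p_dosage"], snp_table["p_best_guess"]) < cfg.significance).sum()
        )
        if n_sig == 0:
            empty = snp_table.iloc[0:0]
            return MidrangeFilterResults(
                config=cfg,
                spikes=[],
                decisions=[],
                decision_table=_decisions_frame([], []),
                snp_table=snp_table,
                filtered_snps=empty,
                report={
                    "n_spikes": 0,
                    "n_kept": 0,
                    "n_discarded": 0,
                    "n_member_snps": 0,
                    "n_kept_snps": 0,
                },
            )
        pmin = np.fmin(snp_table["p_dosage"].to_numpy(), snp_table["p_best_guess"].to_numpy())
        sel = snp_table[pmin < cfg.suggestive]
        pos_by_chrom = {
            c: sub["pos"].to_numpy() for c, sub in sel.groupby("chrom", sort=False)
        }
        spikes = aggregate(pos_by_chrom, gap_limit=cfg.gap_limit)
        # only spikes that actually reach genome-wide significance are signals
        sig = snp_table[pmin < cfg.significance]
        sig_keys = set(zip(sig["chrom"], sig["pos"].astype(int)))
        spikes = [
            sp
            for sp in spikes
            if any((sp.chrom, int(p)) in sig_keys for p in sp.positions)
        ]

        def followup(indices: np.ndarray) -> np.ndarray:
            m = np.zeros(study.n_snps, dtype=bool)
            m[indices] = True
            res = assoc_scan(study, fmt="dosage", snp_mask=m)
            return res["p"].to_numpy()[indices]

        spikes, snp_table = complete_spikes(
            spikes,
            snp_table,
            assoc_fn=followup,
            suggestive=cfg.suggestive,
            gap_limit=cfg.gap_limit,
        )
        # follow-up SNPs now have quality-bearing membership; restore their
        # quality values (they were computed for all SNPs already)
        snp_table["quality"] = np.where(typed, np.nan, q)
        return _classify_all(spikes, snp_table, cfg)


@dataclass
class MidrangeFilterResults:
    """Fitted Midrange Filter: per-spike verdicts plus the filtered SNP set."""

    config: FilterConfig
    spikes: list[Spike]
    decisions: list[FilterDecision]
    decision_table: pd.DataFrame
    snp_table: pd.DataFrame
    filtered_snps: pd.DataFrame
    report: dict

    @property
    def n_kept(self) -> int:
        return self.report["n_kept"]

    @property
    def n_discarded(self) -> int:
        return self.report["n_discarded"]

    def decision_for(self, chrom, pos: int) -> Optional[FilterDecision]:
        """Decision of the spike containing the given SNP, if any."""
        for sp, d in zip(self.spikes, self.decisions):
            if sp.chrom == str(chrom) and int(pos) in set(int(p) for p in sp.positions):
                return d
        return None

    def summary(self) -> str:
        cfg = self.config
        lines = [
            "Midrange Filter results",
            "=======================",
            f"quality measure: {cfg.quality_measure} (group combine: {cfg.group_combine})",
            f"thresholds: lower {cfg.lower_threshold}, upper {cfg.upper_threshold}",
            f"significance {cfg.significance:g}, suggestive {cfg.suggestive:g}, "
            f"presence {cfg.presence:g}, gap {cfg.gap_limit} bp",
            "",
            f"spikes: {self.report['n_spikes']}  kept: {self.n_kept}  "
            f"discarded: {self.n_discarded}",
            f"member SNPs: {self.report['n_member_snps']}  "
            f"kept SNPs: {self.report['n_kept_snps']}",
            "",
        ]
        if len(self.decision_table):
            lines.append(
                self.decision_table[
                    ["spike_id", "n_members", "case", "verdict", "reason", "q_min", "q_max"]
                ].to_string(index=False)
            )
        return "\n".join(lines)
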