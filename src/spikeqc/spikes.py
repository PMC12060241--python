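"""Aggregation of suggestive SNPs into spikes by physical proximity.

An association signal backed by linkage disequilibrium shows up in a
Manhattan plot not as a lone significant SNP but as a spike of low P-values
in close physical distance.  Spikes are built by single-linkage chaining of
SNP positions: two SNPs belong to the same spike if they are fewer than
``gap_limit`` (default 2 Mb) apart, or connected by a chain of SNPs with
each consecutive pair fewer than ``gap_limit`` apart.  Only positions enter
the algorithm; P-values play no role beyond selecting the suggestive set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

GAP_LIMIT = 2_000_000

__all__ = ["Spike", "aggregate", "annotate_spikes", "complete_spikes", "GAP_LIMIT"]


@dataclass
class Spike:
    """A chained set of suggestive SNPs on one chromosome."""

    chrom: str
    positions: np.ndarray  # sorted member positions

    # annotation (filled by annotate_spikes)
    formats_present: frozenset = frozenset()
    has_typed_significant: bool = False
    q_min: float = np.nan
    q_max: float = np.nan
    truth: Optional[bool] = None

    @property
    def start(self) -> int:
        return int(self.positions[0])

    @property
    def end(self) -> int:
        return int(self.positions[-1])

    @property
    def n_members(self) -> int:
        return len(self.positions)

    @property
    def spike_id(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


def _chrom_sort_key(c: str):
    return (0, int(c)) if str(c).isdigit() else (1, str(c))


def aggregate(
    positions_by_chrom: Mapping[str, Iterable[int]],
    gap_limit: int = GAP_LIMIT,
) -> list[Spike]:
    """Chain positions into spikes per chromosome (gap < gap_limit merges).

    Input positions are deduplicated and sorted; the strict inequality means
    two SNPs exactly ``gap_limit`` apart start separate spikes.  Output order
    is deterministic by (chromosome, start).
    """
    spikes: list[Spike] = []
    for chrom in sorted(positions_by_chrom, key=_chrom_sort_key):
        pos = np.unique(np.asarray(list(positions_by_chrom[chrom]), dtype=np.int64))
        if pos.size == 0:
            continue
        breaks = np.flatnonzero(np.diff(pos) >= gap_limit)
        for seg in np.split(pos, breaks + 1):
            spikes.append(Spike(chrom=str(chrom), positions=seg))
    return spikes


def _snp_lookup(snp_table: pd.DataFrame, chrom: str, positions: np.ndarray) -> pd.DataFrame:
    sub = snp_table[snp_table["chrom"].astype(str) == str(chrom)]
    sub = sub[sub["pos"].isin(positions)]
    missing = set(positions.tolist()) - set(sub["pos"].tolist())
    if missing:
        raise KeyError(
            f"SNP(s) {sorted(missing)} on chromosome {chrom} missing from the "
            "per-SNP table (quality/association not available)"
        )
    return sub


def annotate_spikes(
    spikes: list[Spike],
    snp_table: pd.DataFrame,
    presence_threshold: float = 5e-7,
    significance: float = 5e-8,
    member_threshold: float | None = None,
) -> list[Spike]:
    """Annotate spikes with format presence, typed anchors and quality extremes.

    ``snp_table`` needs one row per SNP with columns ``chrom, pos, typed,
    p_dosage, p_best_guess, quality`` (the combined quality column the filter
    uses).  A format is *present* in a spike iff at least one member SNP has
    P below ``presence_threshold`` in that format.  ``has_typed_significant``
    is true iff a typed member reaches ``significance`` in either format.

    Quality extremes (q_min/q_max) are taken over the members below
    ``member_threshold`` (defaults to ``presence_threshold``) in any present
    format, skipping typed members, whose quality is not an imputation
    quality.
    """
    if member_threshold is None:
        member_threshold = presence_threshold
    out = []
    for sp in spikes:
        sub = _snp_lookup(snp_table, sp.chrom, sp.positions)
        pd_ = sub["p_dosage"].to_numpy(dtype=float)
        pb_ = sub["p_best_guess"].to_numpy(dtype=float)
        typed = sub["typed"].to_numpy(dtype=bool)
        q = sub["quality"].to_numpy(dtype=float)

        formats = set()
        if np.nanmin(pd_, initial=np.inf) < presence_threshold:
            formats.add("dosage")
        if np.nanmin(pb_, initial=np.inf) < presence_threshold:
            formats.add("best_guess")
        has_typed = bool(
            (typed & ((pd_ < significance) | (pb_ < significance))).any()
        )
        member = np.zeros(len(sub), dtype=bool)
        if "dosage" in formats:
            member |= pd_ < member_threshold
        if "best_guess" in formats:
            member |= pb_ < member_threshold
        member = member & ~typed & ~np.isnan(q)
        if member.any():
            q_min = float(np.min(q[member]))
            q_max = float(np.max(q[member]))
        else:
            q_min = q_max = np.nan
        out.append(
            Spike(
                chrom=sp.chrom,
                positions=sp.positions,
                formats_present=frozenset(formats),
                has_typed_significant=has_typed,
                q_min=q_min,
                q_max=q_max,
                truth=sp.truth,
            )
        )
    return out


def complete_spikes(
    spikes: list[Spike],
    snp_table: pd.DataFrame,
    assoc_fn,
    suggestive: float = 5e-7,
    gap_limit: int = GAP_LIMIT,
) -> tuple[list[Spike], pd.DataFrame]:
    """Follow-up association around spikes for SNPs skipped by the initial
    quality restriction, then re-chain membership.

    ``snp_table`` must carry a boolean ``tested`` column marking SNPs covered
    by the initial scan.  ``assoc_fn(indices) -> p-values`` runs the dosage
    follow-up association on the untested SNP rows (indices into
    ``snp_table``).  New suggestive SNPs within ``gap_limit`` of an existing
    spike join the membership; members are never removed, and the merged
    positions are re-aggregated so neighbouring spikes may fuse.

    Returns the updated spikes (unannotated) and the updated snp_table with
    follow-up P-values filled into ``p_dosage``.
    """
    snp_table = snp_table.copy()
    if not spikes:
        return spikes, snp_table
    untested = ~snp_table["tested"].to_numpy(dtype=bool)
    near = np.zeros(len(snp_table), dtype=bool)
    chroms = snp_table["chrom"].astype(str).to_numpy()
    pos = snp_table["pos"].to_numpy()
    for sp in spikes:
        on = chroms == str(sp.chrom)
        d = np.minimum(np.abs(pos - sp.start), np.abs(pos - sp.end))
        inside = (pos >= sp.start) & (pos <= sp.end)
        near |= on & (inside | (d < gap_limit))
    todo = np.flatnonzero(untested & near)
    if todo.size:
        p_new = np.asarray(assoc_fn(todo), dtype=float)
        snp_table.loc[snp_table.index[todo], "p_dosage"] = p_new
        snp_table.loc[snp_table.index[todo], "tested"] = True
    # re-chain: original members plus any newly suggestive follow-up SNP
    pos_by_chrom: dict[str, set] = {}
    for sp in spikes:
        pos_by_chrom.setdefault(str(sp.chrom), set()).update(sp.positions.tolist())
    if todo.size:
        newly = snp_table.iloc[todo]
        hit = newly[newly["p_dosage"] < suggestive]
        for c, p in zip(hit["chrom"].astype(str), hit["pos"]):
            pos_by_chrom.setdefault(c, set()).add(int(p))
    merged = aggregate(pos_by_chrom, gap_limit=gap_limit)
    # keep only spikes that contain at least one original member (follow-up
    # must not conjure spikes out of previously untested regions alone)
    orig = {
        (str(sp.chrom), int(p)) for sp in spikes for p in sp.positions
    }
    merged = [
        m
        for m in merged
        if any((m.chrom, int(p)) in orig for p in m.positions)
    ]
    return merged, snp_table
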