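"""VCF and TSV input/output for cohorts (pysam-backed).

Cohorts are written as a single VCF 4.2 file with all samples (cases first,
named ``case_<i>``, then ``control_<i>``), FORMAT fields GT/DS/GP, and an
INFO flag marking directly typed SNPs.  GP values are written with 4 decimals,
so a write/read round trip preserves them to 1e-4.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .core import CohortStudy, GPMatrix, VariantTable

__all__ = ["FormatError", "read_vcf", "read_cohort_vcf", "write_vcf", "write_tsv", "read_tsv"]

log = logging.getLogger(__name__)


class FormatError(ValueError):
    """Raised when a VCF lacks the FORMAT fields needed to build GP triplets."""


def _triplet_from_dosage(ds: np.ndarray) -> np.ndarray:
    """Reconstruct GP triplets from dosages by splitting mass between the two
    nearest integer genotypes (e.g. 1.6 -> (0, 0.4, 0.6)).  Lossy: any triplet
    with the same expectation maps to the same dosage."""
    ds = np.clip(np.asarray(ds, dtype=float), 0.0, 2.0)
    lo = np.floor(ds).astype(int)
    frac = ds - lo
    # dosage exactly 2 -> lo=2; shift down so lo/lo+1 are valid genotype slots
    shift = lo == 2
    lo[shift] = 1
    frac[shift] = 1.0
    out = np.zeros(ds.shape + (3,))
    idx = np.indices(ds.shape)
    out[(*idx, lo)] = 1.0 - frac
    out[(*idx, lo + 1)] = frac
    return out


def read_vcf(
    path, typed_key: str = "TYPED"
) -> tuple[GPMatrix, VariantTable, list[str]]:
    """Read a VCF with GP (preferred) or DS FORMAT fields.

    Returns the GP matrix (samples x biallelic SNPs), the variant table with
    the typed flag taken from INFO key ``typed_key``, and the sample names.
    Non-biallelic records are skipped with a warning.  A VCF carrying neither
    GP nor DS raises :class:`FormatError`.
    """
    path = str(path)
    with pysam.VariantFile(path) as vf:
        samples = list(vf.header.samples)
        fmts = set(vf.header.formats.keys())
        if "GP" not in fmts and "DS" not in fmts:
            raise FormatError(
                "VCF has neither GP nor DS FORMAT fields; cannot build genotype "
                "probabilities (found: " + ", ".join(sorted(fmts)) + ")"
            )
        use_gp = "GP" in fmts
        rows = []
        meta = []
        for rec in vf.fetch() if vf.index is not None else vf:
            if rec.alts is None or len(rec.alts) != 1:
                log.warning(
                    "skipping non-biallelic record %s:%s", rec.chrom, rec.pos
                )
                continue
            if use_gp and all("GP" in rec.samples[s] and rec.samples[s]["GP"] is not None
                              and rec.samples[s]["GP"][0] is not None for s in samples):
                trip = np.array([rec.samples[s]["GP"] for s in samples], dtype=float)
            elif "DS" in fmts:
                ds = np.array([rec.samples[s]["DS"] for s in samples], dtype=float).ravel()
                trip = _triplet_from_dosage(ds)
            else:  # pragma: no cover - defensive
                raise FormatError(f"record {rec.chrom}:{rec.pos} has no usable GP/DS")
            # renormalise away 4-decimal rounding
            trip = trip / trip.sum(axis=1, keepdims=True)
            rows.append(trip)
            meta.append(
                (rec.chrom, rec.pos, rec.ref, rec.alts[0], typed_key in rec.info)
            )
    if not rows:
        raise FormatError(f"no biallelic SNP records in {path}")
    probs = np.stack(rows, axis=1)  # (N, M, 3)
    variants = VariantTable(
        pd.DataFrame(meta, columns=["chrom", "pos", "ref", "alt", "typed"])
    )
    return GPMatrix(probs), variants, samples


def read_cohort_vcf(path, typed_key: str = "TYPED") -> CohortStudy:
    """Read a VCF written by :func:`write_vcf` back into a CohortStudy,
    splitting samples on the ``case_``/``control_`` name prefixes."""
    gp, variants, samples = read_vcf(path, typed_key=typed_key)
    case_idx = [i for i, s in enumerate(samples) if s.startswith("case_")]
    ctrl_idx = [i for i, s in enumerate(samples) if s.startswith("control_")]
    if not case_idx or not ctrl_idx:
        raise FormatError(
            "cohort VCF must contain samples named case_<i> and control_<i>"
        )
    return CohortStudy(
        cases=GPMatrix(gp.probs[case_idx]),
        controls=GPMatrix(gp.probs[ctrl_idx]),
        variants=variants,
    )


def write_vcf(study: CohortStudy, path, typed_key: str = "TYPED") -> None:
    """Write a cohort to VCF 4.2 with GT/DS/GP FORMAT fields (GP to 4 dp)."""
    path = str(path)
    header = pysam.VariantHeader()
    for chrom in pd.unique(study.variants.chrom):
        header.contigs.add(str(chrom))
    header.info.add(typed_key, 0, "Flag", "Directly genotyped (not imputed)")
    header.formats.add("GT", 1, "String", "Best-guess genotype")
    header.formats.add("DS", 1, "Float", "Expected alternative allele dosage")
    header.formats.add("GP", "G", "Float", "Genotype posterior probabilities")
    samples = [f"case_{i}" for i in range(study.n_cases)] + [
        f"control_{i}" for i in range(study.n_controls)
    ]
    for s in samples:
        header.add_sample(s)

    gp = study.combined_gp()
    probs = np.round(gp.probs, 4)
    dosage = gp.dosage()
    bg = gp.best_guess()
    gts = {0: (0, 0), 1: (0, 1), 2: (1, 1)}

    with pysam.VariantFile(path, "w", header=header) as out:
        vdf = study.variants.df
        for j, row in enumerate(vdf.itertuples(index=False)):
            rec = out.new_record(
                contig=str(row.chrom),
                start=int(row.pos) - 1,
                stop=int(row.pos),
                alleles=(row.ref, row.alt),
            )
            if row.typed:
                rec.info[typed_key] = True
            for i, s in enumerate(samples):
                rec.samples[s]["GT"] = gts[int(bg[i, j])]
                rec.samples[s]["DS"] = float(dosage[i, j])
                rec.samples[s]["GP"] = tuple(float(x) for x in probs[i, j])
            out.write(rec)


def write_tsv(table: pd.DataFrame, path, float_format: str = "%.6g") -> None:
    """Write a report table as TSV with a deterministic column order."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, sep="\t", index=False, float_format=float_format)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
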