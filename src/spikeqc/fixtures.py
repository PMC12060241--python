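"""Packaged application fixture: suggestive SNPs from the PsyCourse GWAS.

The fixture lists the 80 SNPs reaching P < 5e-6 in either genotype format
in a published psychiatric case-control GWAS (the PsyCourse study; cases
and controls imputed jointly, imputation quality afterwards recalculated
separately per diagnostic group).  Columns: chromosome, position, P-values
in dosage and best-guess format on the 1e-6 scale exactly as printed, the
imputation quality read straight from the imputed files (``initial``), the
minimum of the per-diagnosis-group recalculated Beagle dosage R²
(``min``), and the typed flag.  Three SNPs are directly genotyped; their
quality columns are NA.

A best-guess P-value printed as a censored ``>100`` is parsed as +inf (it
can never fall below a significance threshold).
"""

from __future__ import annotations

import hashlib
from importlib import resources

import numpy as np
import pandas as pd

__all__ = ["load_psycourse_hits", "psycourse_snp_table", "PRESENCE_THRESHOLD"]

_FILENAME = "psycourse_suggestive_snps.tsv"
_SHA256 = "a492af8e5988c9b78d7b662da5f9f73bf25aa725c3bf254f351ab98a72e80368"

#: Reporting threshold of the application: the published hit list collects
#: SNPs with P < 5e-6 in at least one format.
PRESENCE_THRESHOLD = 5e-6


def _parse_p(col: pd.Series) -> np.ndarray:
    """P-values stored x 1e-6; censored entries like '>100' become +inf."""
    out = np.empty(len(col))
    for i, v in enumerate(col):
        s = str(v).strip()
        out[i] = np.inf if s.startswith(">") else float(s) * 1e-6
    return out


def load_psycourse_hits() -> pd.DataFrame:
    """Load and validate the packaged hit list.

    Returns a DataFrame with columns ``chrom, pos, p_dosage, p_best_guess,
    quality_initial, quality_min, typed`` (P-values on the natural scale).
    Raises if the packaged file's checksum or invariants do not hold.
    """
    ref = resources.files("spikeqc.data").joinpath(_FILENAME)
    raw = ref.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _SHA256:
        raise ValueError(
            f"packaged fixture {_FILENAME} is corrupted (sha256 {digest[:12]}..., "
            f"expected {_SHA256[:12]}...)"
        )
    df = pd.read_csv(ref.open("r"), sep="\t", dtype={"chrom": str}, na_values=["NA"])
    out = pd.DataFrame(
        {
            "chrom": df["chrom"].astype(str),
            "pos": df["pos"].astype(int),
            "p_dosage": _parse_p(df["p_dosage_e6"]),
            "p_best_guess": _parse_p(df["p_best_guess_e6"]),
            "quality_initial": df["quality_initial"].astype(float),
            "quality_min": df["quality_min"].astype(float),
            "typed": df["typed"].astype(bool),
        }
    )
    # invariants of the published list
    if len(out) != 80:
        raise ValueError(f"fixture must have 80 rows, found {len(out)}")
    if int(out["typed"].sum()) != 3:
        raise ValueError("fixture must contain exactly 3 typed SNPs")
    pmin = np.fmin(out["p_dosage"], out["p_best_guess"])
    if not (pmin < PRESENCE_THRESHOLD).all():
        raise ValueError("every fixture row must reach P < 5e-6 in some format")
    return out


def psycourse_snp_table(quality: str = "min") -> pd.DataFrame:
    """Fixture reshaped for the Midrange Filter (``quality`` column from the
    per-group-minimum recalculated scores by default, or ``initial``)."""
    hits = load_psycourse_hits()
    if quality not in ("min", "initial"):
        raise ValueError("quality must be 'min' or 'initial'")
    return pd.DataFrame(
        {
            "chrom": hits["chrom"],
            "pos": hits["pos"],
            "typed": hits["typed"],
            "p_dosage": hits["p_dosage"],
            "p_best_guess": hits["p_best_guess"],
            "quality": hits[f"quality_{quality}"],
            "tested": True,
        }
    )
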