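"""Per-SNP case-control association by logistic regression.

Each SNP is tested with a maximum-likelihood logistic regression of the
binary status on its genotype (dosage or best guess) plus optional
covariates::

    logit P(Y = 1) = b0 + b1 * SNP + b2 * cov_1 + ...

The Wald P-value on ``b1`` is reported.  Fitting is Newton-Raphson (IRLS)
with at most 100 iterations and score tolerance 1e-8; complete or
quasi-complete separation is detected as a diverging coefficient
(|b1| > 15) and flagged rather than reported as a spurious P-value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import CohortStudy

__all__ = ["logistic_fit", "assoc_scan", "significant_set"]

MAX_ITER = 100
TOL = 1e-8
BETA_CAP = 15.0


@dataclass
class LogisticFit:
    beta: np.ndarray
    se: np.ndarray
    converged: bool
    separated: bool
    n_iter: int


def logistic_fit(y: np.ndarray, X: np.ndarray) -> LogisticFit:
    """Newton-Raphson ML fit of a logistic regression.

    Returns coefficient vector, standard errors from the inverse observed
    information, and convergence/separation flags.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    beta = np.zeros(p)
    # separation is judged on the per-SD scale so that legitimate large
    # coefficients on tiny-variance dosage columns are not misflagged
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    converged = False
    separated = False
    it = 0
    for it in range(1, MAX_ITER + 1):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -30, 30)))
        w = mu * (1.0 - mu)
        score = X.T @ (y - mu)
        info = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            separated = True
            break
        beta = beta + step
        if (np.abs(beta[1:]) * sd[1:]).max(initial=0.0) > BETA_CAP:
            separated = True
            break
        if np.abs(score).max() < TOL or np.abs(step).max() < TOL:
            converged = True
            break
    eta = X @ beta
    mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -30, 30)))
    w = mu * (1.0 - mu)
    info = (X * w[:, None]).T @ X
    try:
        cov = np.linalg.inv(info)
        se = np.sqrt(np.clip(np.diag(cov), 0, np.inf))
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)
        separated = True
    return LogisticFit(beta=beta, se=se, converged=converged and not separated,
                       separated=separated, n_iter=it)


def assoc_scan(
    study: CohortStudy,
    fmt: str = "dosage",
    covariates: pd.DataFrame | None = None,
    snp_mask: np.ndarray | None = None,
) -> pd.DataFrame:
    """Scan every SNP (or the masked subset) for association with status.

    Parameters
    ----------
    fmt : {"dosage", "best_guess"}
        Genotype encoding handed to the regression.
    covariates : DataFrame, optional
        Overrides ``study.covariates``; one numeric row per individual,
        cases first.
    snp_mask : boolean array over SNPs, optional
        SNPs outside the mask get a row with NaN P (``tested`` False); this
        is how quality-restricted initial scans are expressed.

    Returns a DataFrame with one row per SNP: chrom, pos, format, beta, se,
    p, converged, tested, note.  Constant genotypes are flagged untestable;
    separated fits are flagged with no P-value.
    """
    if fmt not in ("dosage", "best_guess"):
        raise ValueError("fmt must be 'dosage' or 'best_guess'")
    gp = study.combined_gp()
    G = gp.dosage() if fmt == "dosage" else gp.best_guess().astype(float)
    y = study.phenotype()
    cov = covariates if covariates is not None else study.covariates
    if cov is not None:
        C = np.asarray(cov, dtype=float)
        if C.shape[0] != len(y):
            raise ValueError("covariate rows must match total individual count")
    else:
        C = np.empty((len(y), 0))
    n_snps = study.n_snps
    if snp_mask is None:
        snp_mask = np.ones(n_snps, dtype=bool)

    beta = np.full(n_snps, np.nan)
    se = np.full(n_snps, np.nan)
    pval = np.full(n_snps, np.nan)
    conv = np.zeros(n_snps, dtype=bool)
    note = np.array([""] * n_snps, dtype=object)

    base = np.column_stack([np.ones(len(y)), np.zeros(len(y)), C])
    for j in np.flatnonzero(snp_mask):
        g = G[:, j]
        if np.isnan(g).any():
            note[j] = "missing_genotypes"
            continue
        if np.ptp(g) == 0:
            note[j] = "constant_genotype"
            continue
        base[:, 1] = g
        fit = logistic_fit(y, base)
        if fit.separated:
            note[j] = "separation"
            continue
        if not fit.converged:
            note[j] = "not_converged"
            continue
        beta[j] = fit.beta[1]
        se[j] = fit.se[1]
        z = fit.beta[1] / fit.se[1] if fit.se[1] > 0 else np.nan
        pval[j] = 2.0 * stats.norm.sf(abs(z))
        conv[j] = True

    return pd.DataFrame(
        {
            "chrom": study.variants.chrom,
            "pos": study.variants.pos,
            "format": fmt,
            "beta": beta,
            "se": se,
            "p": pval,
            "converged": conv,
            "tested": snp_mask,
            "note": note,
        }
    )


def significant_set(
    table: pd.DataFrame,
    significance: float = 5e-8,
    suggestive: float = 5e-7,
) -> dict[str, pd.DataFrame]:
    """Split an association table into the nested significant and suggestive
    SNP sets (``P < significance`` is a subset of ``P < suggestive``)."""
    if suggestive < significance:
        raise ValueError("suggestive threshold must be >= significance threshold")
    p = table["p"]
    return {
        "significant": table[p < significance],
        "suggestive": table[p < suggestive],
    }
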