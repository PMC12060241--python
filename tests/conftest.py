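import numpy as np
import pytest
from hypothesis import settings

import spikeqc as sq
from spikeqc.simulate import DeletionConfig, DiseaseLocus, SimConfig, simulate_cohort

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


def degenerate_gp(genotypes: np.ndarray) -> np.ndarray:
    """One-hot GP triplets from an integer genotype matrix."""
    probs = np.zeros(genotypes.shape + (3,))
    ii, jj = np.indices(genotypes.shape)
    probs[ii, jj, genotypes] = 1.0
    return probs


def hwe_genotypes(rng, n, m, freq):
    return rng.binomial(1, freq, (n, m)) + rng.binomial(1, freq, (n, m))


@pytest.fixture(scope="session")
def small_sim():
    """One seeded midrange-regime cohort shared across tests."""
    cfg = SimConfig(
        n_snps=400,
        n_cases=150,
        n_controls=150,
        panel_size=150,
        spacing_bp=25000,
        disease_loci=(DiseaseLocus(None, 3.0, "additive"),),
        deletion=DeletionConfig("scaffold", 0.18),
        ld_decay=0.03,
        seed=42,
    )
    return simulate_cohort(cfg)


def build_planted_cohort(seed: int = 11) -> sq.CohortStudy:
    """Hand-built cohort: one high-quality true spike (positions 1.00-1.10 Mb),
    one false spike driven by frequency-style imputation (8.00 Mb at
    midrange quality, 8.04 Mb at quality ~0), and typed null background."""
    rng = np.random.default_rng(seed)
    n = 500
    pos = np.array(
        [1_000_000, 1_050_000, 1_100_000, 8_000_000, 8_040_000,
         14_000_000, 14_500_000, 15_000_000, 15_500_000, 16_000_000,
         16_500_000, 17_000_000]
    )
    m = len(pos)
    cases = np.zeros((n, m, 3))
    ctrls = np.zeros((n, m, 3))
    bg_idx = list(range(5, m))
    cases[:, bg_idx, :] = degenerate_gp(hwe_genotypes(rng, n, len(bg_idx), 0.3))
    ctrls[:, bg_idx, :] = degenerate_gp(hwe_genotypes(rng, n, len(bg_idx), 0.3))
    # true spike: high-confidence triplets, real frequency difference
    for j in range(3):
        for arr, f in ((cases, 0.45), (ctrls, 0.20)):
            g = hwe_genotypes(rng, n, 1, f).ravel()
            p = degenerate_gp(g[:, None])[:, 0, :] * 0.94 + 0.02
            arr[:, j, :] = p / p.sum(1, keepdims=True)
    # false spike, midrange member: half-informative triplets, shifted groups
    for arr, f in ((cases, 0.32), (ctrls, 0.18)):
        g = hwe_genotypes(rng, n, 1, f).ravel()
        freq_trip = np.array([(1 - f) ** 2, 2 * f * (1 - f), f**2])
        p = 0.62 * degenerate_gp(g[:, None])[:, 0, :] + 0.38 * freq_trip
        arr[:, 3, :] = p / p.sum(1, keepdims=True)
    # false spike, frequency-imputed member: quality ~0, spurious dosage shift
    for arr, base in (
        (cases, np.array([0.50, 0.40, 0.10])),
        (ctrls, np.array([0.545, 0.375, 0.08])),
    ):
        p = np.abs(base + rng.normal(0, 0.03, (n, 3)))
        arr[:, 4, :] = p / p.sum(1, keepdims=True)
    variants = sq.VariantTable.from_arrays(
        "1", pos, typed=[False] * 5 + [True] * (m - 5)
    )
    return sq.CohortStudy(
        cases=sq.GPMatrix(cases), controls=sq.GPMatrix(ctrls), variants=variants
    )


@pytest.fixture(scope="session")
def planted_cohort():
    return build_planted_cohort()
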