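"""Shared fixtures and independent statistical oracles for the suite."""
from __future__ import annotations

import numpy as np
import pytest
from scipy import special

from surfprofiler import (
    GeneId,
    SyntheticCohortSpec,
    generate,
    normalize_log2,
    build_lineage_cohort,
)
from surfprofiler.synthdata import PlantedLineageEffect, PlantedMutationEffect


def pooled_t_oracle(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Textbook pooled-variance two-sample t-test, coded from the formula.

    The two-sided p-value comes from the regularised incomplete beta
    function form of the t CDF, independent of scipy.stats.ttest_ind.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = len(x), len(y)
    sp2 = ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2)
    t = (x.mean() - y.mean()) / np.sqrt(sp2 * (1.0 / nx + 1.0 / ny))
    df = nx + ny - 2
    p = float(special.betainc(df / 2.0, 0.5, df / (df + t * t)))
    return float(t), p


def welch_t_oracle(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Textbook Welch t-test with Welch-Satterthwaite degrees of freedom."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = len(x), len(y)
    vx, vy = x.var(ddof=1) / nx, y.var(ddof=1) / ny
    t = (x.mean() - y.mean()) / np.sqrt(vx + vy)
    df = (vx + vy) ** 2 / (vx**2 / (nx - 1) + vy**2 / (ny - 1))
    p = float(special.betainc(df / 2.0, 0.5, df / (df + t * t)))
    return float(t), p


@pytest.fixture(scope="session")
def small_spec() -> SyntheticCohortSpec:
    """One LUAD-like lineage, 15 pairs, planted lineage + mutation effects."""
    return SyntheticCohortSpec(
        lineages=[("LUAD", 15)],
        n_genes=60,
        n_surface=20,
        noise_sd=0.7,
        planted_lineage_effects=[PlantedLineageEffect(0, "LUAD", 2.5)],
        planted_mutation_effects=[PlantedMutationEffect(1, "STK11", "LUAD", 6, 3.0)],
        seed=11,
    )


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    expr, samples, muts, surface = generate(small_spec)
    log2 = normalize_log2(expr)
    cohort = build_lineage_cohort(log2, samples, "LUAD")
    return cohort, samples, muts, surface, log2


@pytest.fixture(scope="session")
def three_lineage_inputs():
    """Three lineages, one below the 10-pair floor, one planted
    lineage-specific surface gene in LUAD only."""
    spec = SyntheticCohortSpec(
        lineages=[("LUAD", 12), ("BRCA", 11), ("KIRP", 4)],
        n_genes=40,
        n_surface=15,
        noise_sd=0.6,
        planted_lineage_effects=[PlantedLineageEffect(0, "LUAD", 2.5)],
        seed=7,
    )
    expr, samples, muts, surface = generate(spec)
    return normalize_log2(expr), samples, muts, surface


def planted_gene() -> GeneId:
    return GeneId(symbol="GENE00000", entrez=100000)
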