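"""Per-gene differential expression: log2Delta effect sizes, t-test
p-values and hit selection.

The effect-size statistic is log2Delta, the difference of group mean
log2-scale expression between the two arms of a contrast (tumor - normal,
or mutant - wild-type tumor). Significance comes from a two-sided
two-sample Student's t-test (pooled variance by default, Welch and paired
variants available). A hit is a gene with log2Delta > 1.0 and p < 0.01
(strict inequalities) that belongs to the cell-surface gene set.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .cohort import (
    CohortError,
    LineageCohort,
    MutationStatus,
    build_lineage_cohort,
    DEFAULT_MIN_PAIRS,
)
from .io import ExpressionMatrix, GeneId, GeneSet, SampleTable, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "HitCriteria",
    "ProfileResult",
    "MutantCountError",
    "lineage_profile",
    "mutation_profile",
    "select_hits",
    "profile_all_lineages",
]

#: Sentinel p-value for zero pooled variance with unequal means: the
#: smallest positive double, so the gene sorts as maximally significant
#: without producing -log10(p) = inf downstream (plots cap it).
P_SENTINEL = float(np.nextafter(0.0, 1.0))


class MutantCountError(CohortError):
    """Too few mutant samples to run the mutant/wild-type t-test."""


@dataclass(frozen=True)
class HitCriteria:
    """Hit-selection thresholds (strict inequalities).

    Defaults reproduce the tool's standard rule: log2Delta > 1.0 and
    p-value < 0.01, restricted to cell-surface genes.
    """

    min_log2_delta: float = 1.0
    max_p: float = 0.01
    surface_only: bool = True
    absolute: bool = False  # apply the delta threshold to |log2Delta|

    def __post_init__(self) -> None:
        if self.min_log2_delta < 0:
            raise ValidationError("min_log2_delta must be >= 0")
        if not (0.0 < self.max_p <= 1.0):
            raise ValidationError("max_p must lie in (0, 1]")


@dataclass
class ProfileResult:
    """Per-gene log2Delta + p-value table for one contrast.

    ``rows`` columns: gene (GeneId), log2_delta, p_value (NaN when
    undefined), n_group1, n_group2, is_surface, is_hit, zero_variance,
    and optionally fdr_bh.
    """

    contrast: str  # "lineage_tumor_vs_normal" | "mutant_vs_wildtype"
    lineage: str
    rows: pd.DataFrame
    mutated_gene: Optional[GeneId] = None

    def __len__(self) -> int:
        return len(self.rows)

    def row_for(self, gene) -> pd.Series:
        if isinstance(gene, str):
            gene = GeneId(symbol=gene)
        sym = self.rows["gene"].map(lambda g: g.symbol)
        match = self.rows[sym == gene.symbol] if gene.symbol else self.rows[0:0]
        if match.empty and gene.entrez is not None:
            ent = self.rows["gene"].map(lambda g: g.entrez)
            match = self.rows[ent == gene.entrez]
        if match.empty:
            raise KeyError(f"gene {gene.label} not profiled")
        return match.iloc[0]


def _two_sample_test(
    x: np.ndarray, y: np.ndarray, welch: bool
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised two-sided two-sample t-test per gene (rows).

    Returns (p_values, zero_variance_flags). Genes where both groups have
    zero variance get NaN when the means agree and the smallest-positive-
    double sentinel when they differ.
    """
    res = stats.ttest_ind(x, y, axis=1, equal_var=not welch)
    p = np.asarray(res.pvalue, dtype=float)
    var_x = x.var(axis=1, ddof=1)
    var_y = y.var(axis=1, ddof=1)
    degenerate = (var_x == 0.0) & (var_y == 0.0)
    if degenerate.any():
        diff = x.mean(axis=1) - y.mean(axis=1)
        p[degenerate & (diff == 0.0)] = np.nan
        p[degenerate & (diff != 0.0)] = P_SENTINEL
    return p, degenerate


def _paired_test(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    d = x - y
    res = stats.ttest_rel(x, y, axis=1)
    p = np.asarray(res.pvalue, dtype=float)
    degenerate = d.var(axis=1, ddof=1) == 0.0
    if degenerate.any():
        mean_d = d.mean(axis=1)
        p[degenerate & (mean_d == 0.0)] = np.nan
        p[degenerate & (mean_d != 0.0)] = P_SENTINEL
    return p, degenerate


def _build_rows(
    matrix: ExpressionMatrix,
    group1: list[str],
    group2: list[str],
    surface: GeneSet,
    welch: bool,
    paired: bool,
    fdr: Optional[str],
) -> pd.DataFrame:
    idx1 = [matrix.samples.index(s) for s in group1]
    idx2 = [matrix.samples.index(s) for s in group2]
    x = matrix.values[:, idx1]
    y = matrix.values[:, idx2]
    delta = x.mean(axis=1) - y.mean(axis=1)
    if paired:
        p, degenerate = _paired_test(x, y)
    else:
        p, degenerate = _two_sample_test(x, y, welch=welch)
    rows = pd.DataFrame({
        "gene": matrix.genes,
        "log2_delta": delta,
        "p_value": p,
        "n_group1": len(group1),
        "n_group2": len(group2),
        "is_surface": [g in surface for g in matrix.genes],
        "is_hit": False,
        "zero_variance": degenerate,
    })
    if fdr == "bh":
        defined = rows["p_value"].notna().to_numpy()
        adj = np.full(len(rows), np.nan)
        if defined.any():
            adj[defined] = multipletests(
                rows.loc[defined, "p_value"].to_numpy(), method="fdr_bh")[1]
        rows["fdr_bh"] = adj
    return rows


def lineage_profile(
    cohort: LineageCohort,
    surface: GeneSet,
    welch: bool = False,
    paired: bool = False,
    fdr: Optional[str] = None,
) -> ProfileResult:
    """Tumor-vs-matched-normal contrast for every gene in the matrix.

    log2Delta(g) = mean log2 expression over the cohort's paired tumor
    samples minus the mean over the paired normals. All genes are
    profiled, not only surface genes, so the volcano shows the full
    transcriptome backdrop. ``paired=True`` tests per-patient differences
    instead of the two pooled groups.
    """
    if cohort.expression is None or cohort.expression.scale_tag != "log2":
        raise ValidationError("cohort carries no log2 expression matrix")
    if cohort.n_pairs < 2:
        raise CohortError(
            f"lineage {cohort.lineage}: {cohort.n_pairs} pairs, need >= 2 for a t-test")
    rows = _build_rows(
        cohort.expression, cohort.tumor_samples, cohort.normal_samples,
        surface, welch=welch, paired=paired, fdr=fdr)
    return ProfileResult(
        contrast="lineage_tumor_vs_normal", lineage=cohort.lineage, rows=rows)


def mutation_profile(
    cohort: LineageCohort,
    status: MutationStatus,
    surface: GeneSet,
    welch: bool = False,
    fdr: Optional[str] = None,
) -> ProfileResult:
    """Mutant-vs-wild-type contrast over the cohort's tumor samples.

    Normal samples are not used. Refuses to run when the mutant arm is
    below the status' mutant threshold or the wild-type arm has fewer
    than two samples.
    """
    if status.lineage != cohort.lineage:
        raise ValidationError(
            f"mutation status is for {status.lineage}, cohort is {cohort.lineage}")
    if status.below_threshold or status.n_mutant < 2:
        raise MutantCountError(
            f"{cohort.lineage}: {status.n_mutant} {status.mutated_gene.label}-mutant "
            f"sample(s) — too few for a mutant/wild-type t-test (plotting is still possible)")
    if status.n_wildtype < 2:
        raise MutantCountError(
            f"{cohort.lineage}: only {status.n_wildtype} wild-type sample(s)")
    rows = _build_rows(
        cohort.expression,
        sorted(status.mutant_samples), sorted(status.wildtype_samples),
        surface, welch=welch, paired=False, fdr=fdr)
    return ProfileResult(
        contrast="mutant_vs_wildtype", lineage=cohort.lineage,
        rows=rows, mutated_gene=status.mutated_gene)


def hit_mask(rows: pd.DataFrame, criteria: HitCriteria) -> np.ndarray:
    """Boolean hit mask under strict-inequality criteria; undefined p never hits."""
    delta = rows["log2_delta"].to_numpy()
    effect = np.abs(delta) if criteria.absolute else delta
    p = rows["p_value"].to_numpy()
    mask = (effect > criteria.min_log2_delta) & (p < criteria.max_p) & ~np.isnan(p)
    if criteria.surface_only:
        mask &= rows["is_surface"].to_numpy()
    return mask


def select_hits(result: ProfileResult, criteria: HitCriteria = HitCriteria()) -> ProfileResult:
    """Return the hit-flagged subset, sorted by descending log2Delta.

    A hit satisfies log2Delta > min_log2_delta AND p < max_p (strict), and
    surface membership when ``surface_only``. Pure filter: applying twice
    equals applying once.
    """
    mask = hit_mask(result.rows, criteria)
    hits = result.rows[mask].copy()
    hits["is_hit"] = True
    hits = hits.assign(_sym=[g.label for g in hits["gene"]]).sort_values(
        ["log2_delta", "_sym"], ascending=[False, True], kind="mergesort"
    ).drop(columns="_sym").reset_index(drop=True)
    return ProfileResult(
        contrast=result.contrast, lineage=result.lineage,
        rows=hits, mutated_gene=result.mutated_gene)


def flag_hits(result: ProfileResult, criteria: HitCriteria = HitCriteria()) -> ProfileResult:
    """Return the full table with ``is_hit`` set under the criteria."""
    rows = result.rows.copy()
    rows["is_hit"] = hit_mask(rows, criteria)
    return ProfileResult(
        contrast=result.contrast, lineage=result.lineage,
        rows=rows, mutated_gene=result.mutated_gene)


@dataclass
class AllLineagesResult:
    profiles: dict[str, ProfileResult]
    skipped: dict[str, str] = field(default_factory=dict)
    #: surface-gene x lineage matrix of log2Delta values, for external
    #: clustering/heatmap tools
    delta_matrix: Optional[pd.DataFrame] = None


def profile_all_lineages(
    matrix: ExpressionMatrix,
    samples: SampleTable,
    surface: GeneSet,
    criteria: HitCriteria = HitCriteria(),
    min_pairs: int = DEFAULT_MIN_PAIRS,
    exclude_metastatic: bool = True,
    welch: bool = False,
    paired: bool = False,
    fdr: Optional[str] = None,
) -> AllLineagesResult:
    """Run the tumor-vs-normal profile for every qualifying lineage.

    Lineages failing the cohort rules are skipped with a logged reason.
    Also assembles a surface-gene x lineage log2Delta matrix suitable for
    external clustering tools.
    """
    profiles: dict[str, ProfileResult] = {}
    skipped: dict[str, str] = {}
    for lineage in samples.lineages:
        try:
            cohort = build_lineage_cohort(
                matrix, samples, lineage,
                min_pairs=min_pairs, exclude_metastatic=exclude_metastatic)
            result = lineage_profile(
                cohort, surface, welch=welch, paired=paired, fdr=fdr)
        except CohortError as exc:
            logger.info("skipping lineage %s: %s", lineage, exc)
            skipped[lineage] = str(exc)
            continue
        profiles[lineage] = flag_hits(result, criteria)

    delta_matrix = None
    if profiles:
        surface_idx = [i for i, g in enumerate(matrix.genes) if g in surface]
        delta_matrix = pd.DataFrame(
            {lin: prof.rows["log2_delta"].to_numpy()[surface_idx]
             for lin, prof in profiles.items()},
            index=[matrix.genes[i].label for i in surface_idx],
        )
    return AllLineagesResult(profiles=profiles, skipped=skipped, delta_matrix=delta_matrix)
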