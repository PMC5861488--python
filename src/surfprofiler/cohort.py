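"""Cohort construction: log2 normalisation, tumor/normal pairing and
mutant/wild-type labelling.

A lineage cohort pairs each patient's primary tumor sample with their
matched normal sample, drops metastatic samples, and enforces a minimum
pair count before any statistics are run. Mutant/wild-type status of the
tumor samples is derived from a mutation table that has already passed the
non-synonymous consequence filter (SIFT < 0.05 or PolyPhen-2 > 0.85, plus
truncating variants).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np

from .io import (
    ExpressionMatrix,
    GeneId,
    MutationTable,
    SampleTable,
    SampleType,
    ValidationError,
    VariantClass,
)

logger = logging.getLogger(__name__)

__all__ = [
    "CohortError",
    "CohortTooSmallError",
    "LineageCohort",
    "MutationStatus",
    "normalize_log2",
    "build_lineage_cohort",
    "filter_nonsynonymous",
    "mutation_status",
]

#: Consequence-filter thresholds for deleterious missense variants.
SIFT_MAX = 0.05
POLYPHEN_MIN = 0.85

DEFAULT_MIN_PAIRS = 10
DEFAULT_MIN_MUTANTS = 2
DEFAULT_PSEUDOCOUNT = 1.0


class CohortError(ValueError):
    """A cohort rule (pairing, size) is violated."""


class CohortTooSmallError(CohortError):
    def __init__(self, lineage: str, n_pairs: int, min_pairs: int):
        self.lineage, self.n_pairs, self.min_pairs = lineage, n_pairs, min_pairs
        super().__init__(
            f"lineage {lineage}: {n_pairs} complete tumor/normal pairs, "
            f"need at least {min_pairs}"
        )


@dataclass
class LineageCohort:
    """One lineage's analyzable samples.

    ``pairs`` holds (tumor, normal) sample IDs matched within a patient;
    ``tumor_only`` holds primary tumor samples without a matched normal,
    which take part in the mutant/wild-type contrast but not the
    tumor-vs-normal contrast. ``expression`` is log2-scale and restricted
    to the cohort's samples.
    """

    lineage: str
    pairs: list[tuple[str, str]]
    tumor_only: list[str] = field(default_factory=list)
    expression: Optional[ExpressionMatrix] = None

    @property
    def tumor_samples(self) -> list[str]:
        return [t for t, _ in self.pairs]

    @property
    def normal_samples(self) -> list[str]:
        return [n for _, n in self.pairs]

    @property
    def all_tumor_samples(self) -> list[str]:
        return self.tumor_samples + self.tumor_only

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)


@dataclass
class MutationStatus:
    """Mutant/wild-type partition of a cohort's tumor samples for one gene."""

    lineage: str
    mutated_gene: GeneId
    mutant_samples: frozenset[str]
    wildtype_samples: frozenset[str]
    below_threshold: bool = False

    def __post_init__(self) -> None:
        if self.mutant_samples & self.wildtype_samples:
            raise ValidationError("mutant and wild-type sample sets overlap")

    @property
    def n_mutant(self) -> int:
        return len(self.mutant_samples)

    @property
    def n_wildtype(self) -> int:
        return len(self.wildtype_samples)


def normalize_log2(matrix: ExpressionMatrix, pseudocount: float = DEFAULT_PSEUDOCOUNT) -> ExpressionMatrix:
    """log2-transform a raw-scale matrix: v -> log2(v + pseudocount).

    RSEM-style estimates are non-negative; any negative value is a hard
    error. The default pseudocount of 1 maps 0 to 0.
    """
    if matrix.scale_tag != "raw_counts":
        raise ValidationError(f"expected raw_counts matrix, got scale_tag={matrix.scale_tag!r}")
    if pseudocount <= 0:
        raise ValidationError("pseudocount must be positive")
    if (matrix.values < 0).any():
        i, j = np.argwhere(matrix.values < 0)[0]
        raise ValidationError(
            f"negative expression value {matrix.values[i, j]} at gene "
            f"{matrix.genes[i].label}, sample {matrix.samples[j]}"
        )
    return ExpressionMatrix(
        genes=list(matrix.genes),
        samples=list(matrix.samples),
        values=np.log2(matrix.values + pseudocount),
        scale_tag="log2",
    )


def build_lineage_cohort(
    matrix: ExpressionMatrix,
    samples: SampleTable,
    lineage: str,
    min_pairs: int = DEFAULT_MIN_PAIRS,
    exclude_metastatic: bool = True,
) -> LineageCohort:
    """Pair tumor and normal samples by patient within one lineage.

    A pair requires exactly one primary tumor and one normal sample from
    the same patient; metastatic samples are dropped when
    ``exclude_metastatic`` is set. A patient with several primary tumors
    keeps the lexicographically smallest sample ID (warning logged).
    Raises :class:`CohortTooSmallError` below ``min_pairs`` pairs.
    """
    if matrix.scale_tag != "log2":
        raise ValidationError("cohort expression must be log2-scale; run normalize_log2 first")
    recs = samples.in_lineage(lineage)
    if not recs:
        raise CohortError(f"lineage {lineage!r} absent from sample table")
    in_matrix = set(matrix.samples)
    missing = [r.sample_id for r in recs if r.sample_id not in in_matrix]
    if missing:
        raise ValidationError(
            f"lineage {lineage}: samples absent from expression matrix: "
            + ", ".join(sorted(missing)[:5])
        )

    by_patient: dict[str, dict[str, list[str]]] = {}
    for r in recs:
        if r.sample_type is SampleType.tumor_metastatic:
            if exclude_metastatic:
                logger.info("excluding metastatic sample %s", r.sample_id)
                continue
            kind = "tumor"
        elif r.sample_type is SampleType.tumor_primary:
            kind = "tumor"
        else:
            kind = "normal"
        by_patient.setdefault(r.patient_id, {"tumor": [], "normal": []})[kind].append(r.sample_id)

    pairs: list[tuple[str, str]] = []
    tumor_only: list[str] = []
    # patient order is irrelevant to the result: sorting makes it canonical
    for patient in sorted(by_patient):
        groups = by_patient[patient]
        tumors = sorted(groups["tumor"])
        normals = sorted(groups["normal"])
        if len(tumors) > 1:
            logger.warning(
                "patient %s has %d primary tumor samples in %s; keeping %s",
                patient, len(tumors), lineage, tumors[0])
        if len(normals) > 1:
            logger.warning(
                "patient %s has %d normal samples in %s; keeping %s",
                patient, len(normals), lineage, normals[0])
        if tumors and normals:
            pairs.append((tumors[0], normals[0]))
        elif tumors:
            tumor_only.append(tumors[0])
    if len(pairs) < min_pairs:
        raise CohortTooSmallError(lineage, len(pairs), min_pairs)

    ordered = [s for pair in pairs for s in pair] + tumor_only
    return LineageCohort(
        lineage=lineage,
        pairs=pairs,
        tumor_only=tumor_only,
        expression=matrix.subset_samples(ordered),
    )


def _qualifies(rec) -> bool:
    if rec.variant_class is VariantClass.truncating:
        return True
    if rec.variant_class is not VariantClass.missense:
        return False
    if rec.sift_score is not None and rec.sift_score < SIFT_MAX:
        return True
    if rec.polyphen_score is not None and rec.polyphen_score > POLYPHEN_MIN:
        return True
    return False


def filter_nonsynonymous(mutations: MutationTable) -> MutationTable:
    """Keep non-synonymous variants: truncating always, and missense with
    SIFT < 0.05 or PolyPhen-2 > 0.85 (strict inequalities; a missing score
    never qualifies). Synonymous, 'other' and score-failing missense
    records are dropped. Idempotent pure filter.
    """
    return MutationTable([r for r in mutations if _qualifies(r)])


def mutation_status(
    cohort: LineageCohort,
    mutations: MutationTable,
    mutated_gene: Union[GeneId, str],
    min_mutants: int = DEFAULT_MIN_MUTANTS,
) -> MutationStatus:
    """Split the cohort's tumor samples into mutant and wild-type for a gene.

    ``mutations`` must already have passed :func:`filter_nonsynonymous`.
    A tumor sample is mutant when it carries at least one retained variant
    in ``mutated_gene``. Below ``min_mutants`` mutants the status is
    flagged (plot data may still be built; the t-test downstream refuses).
    """
    if isinstance(mutated_gene, str):
        mutated_gene = GeneId(symbol=mutated_gene)
    tumors = set(cohort.all_tumor_samples)
    hits = {r.sample_id for r in mutations.for_gene(mutated_gene)}
    mutant = frozenset(hits & tumors)
    if not mutant:
        logger.warning(
            "no retained %s mutations among %s tumor samples",
            mutated_gene.label, cohort.lineage)
    below = len(mutant) < min_mutants
    if mutant and below:
        logger.warning(
            "%s: only %d %s-mutant sample(s), below min_mutants=%d — "
            "plotting allowed, testing refused",
            cohort.lineage, len(mutant), mutated_gene.label, min_mutants)
    return MutationStatus(
        lineage=cohort.lineage,
        mutated_gene=mutated_gene,
        mutant_samples=mutant,
        wildtype_samples=frozenset(tumors - mutant),
        below_threshold=below,
    )
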