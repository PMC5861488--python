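"""Seeded synthetic cohorts with the statistical structure the profiler
assumes: paired tumor/normal log2-scale expression with lineage effects,
sparse mutation annotations with SIFT/PolyPhen-2 consequence scores, and a
surface gene set.

The generative model is Gaussian on the log2 scale — each gene's normal-
sample expression is Normal(baseline_mean, noise_sd) bits, tumor samples
add planted lineage deltas, and mutant tumor samples add planted
mutation-effect deltas on marker genes — because the downstream statistics
are t-tests on log2 RSEM-style estimates, not count models. Values are
inverse-transformed to the raw scale so the normal pipeline entry point
(read -> log2-normalise) round-trips.

Mutation records are built so the consequence filter's outcome is known by
construction: qualifying missense variants draw SIFT ~ U(0, 0.05), decoy
records draw SIFT ~ U(0.05, 1) with PolyPhen-2 ~ U(0, 0.85) (or are
synonymous), and truncating variants carry no scores.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Union

import numpy as np
import yaml

from .io import (
    ExpressionMatrix,
    GeneId,
    GeneSet,
    MutationRecord,
    MutationTable,
    SampleRecord,
    SampleTable,
    SampleType,
    ValidationError,
    VariantClass,
)

logger = logging.getLogger(__name__)

__all__ = [
    "PlantedLineageEffect",
    "PlantedMutationEffect",
    "MutationScoreModel",
    "SyntheticCohortSpec",
    "default_spec",
    "generate",
    "write_fixture_bundle",
]


@dataclass(frozen=True)
class PlantedLineageEffect:
    """Additive tumor-over-normal shift on one gene in one lineage."""

    gene_index: int
    lineage: str
    delta: float  # bits


@dataclass(frozen=True)
class PlantedMutationEffect:
    """Additive mutant-over-wildtype shift on a marker gene.

    ``n_mutant`` tumor samples of ``lineage`` carry a qualifying variant
    in ``mutated_gene`` and have ``delta`` bits added to the marker gene.
    """

    marker_gene_index: int
    mutated_gene: str
    lineage: str
    n_mutant: int
    delta: float  # bits


@dataclass(frozen=True)
class MutationScoreModel:
    """Score-sampling parameters guaranteeing deterministic filter outcomes."""

    truncating_fraction: float = 0.3  # of qualifying variants
    decoy_fraction: float = 0.2       # of wild-type tumors receiving a decoy
    decoy_synonymous_fraction: float = 0.5  # of decoys that are synonymous


@dataclass
class SyntheticCohortSpec:
    """Parameters of one synthetic multi-lineage cohort.

    Defaults mirror a bulk tumor/normal RNA-seq cohort on the log2 scale:
    a baseline of 8 bits with 1 bit of per-sample noise is typical of
    moderately expressed genes in RSEM-quantified TCGA data.
    """

    lineages: list[tuple[str, int]] = field(default_factory=lambda: [("LUAD", 15)])
    n_genes: int = 500
    n_surface: int = 50
    baseline_mean: float = 8.0  # bits
    noise_sd: float = 1.0       # bits
    planted_lineage_effects: list[PlantedLineageEffect] = field(default_factory=list)
    planted_mutation_effects: list[PlantedMutationEffect] = field(default_factory=list)
    score_model: MutationScoreModel = field(default_factory=MutationScoreModel)
    seed: int = 0

    def validate(self) -> None:
        problems = []
        names = [name for name, _ in self.lineages]
        pair_counts = dict(self.lineages)
        if len(set(names)) != len(names):
            problems.append("duplicate lineage names")
        if any(n < 1 for _, n in self.lineages):
            problems.append("every lineage needs n_pairs >= 1")
        if self.n_surface > self.n_genes:
            problems.append("n_surface exceeds n_genes")
        if self.noise_sd <= 0:
            problems.append("noise_sd must be > 0")
        for eff in self.planted_lineage_effects:
            if not (0 <= eff.gene_index < self.n_genes):
                problems.append(f"lineage-effect gene index {eff.gene_index} out of range")
            if eff.lineage not in pair_counts:
                problems.append(f"lineage-effect lineage {eff.lineage!r} not in spec")
        for eff in self.planted_mutation_effects:
            if not (0 <= eff.marker_gene_index < self.n_genes):
                problems.append(f"mutation-effect marker index {eff.marker_gene_index} out of range")
            if eff.lineage not in pair_counts:
                problems.append(f"mutation-effect lineage {eff.lineage!r} not in spec")
            elif eff.n_mutant > pair_counts[eff.lineage]:
                problems.append(
                    f"n_mutant={eff.n_mutant} exceeds n_pairs={pair_counts[eff.lineage]} "
                    f"for {eff.lineage}")
        if problems:
            raise ValidationError("invalid synthetic spec: " + "; ".join(problems))

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "SyntheticCohortSpec":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        raw["lineages"] = [tuple(x) for x in raw.get("lineages", [("LUAD", 15)])]
        raw["planted_lineage_effects"] = [
            PlantedLineageEffect(**e) for e in raw.get("planted_lineage_effects", [])]
        raw["planted_mutation_effects"] = [
            PlantedMutationEffect(**e) for e in raw.get("planted_mutation_effects", [])]
        if "score_model" in raw:
            raw["score_model"] = MutationScoreModel(**raw["score_model"])
        return cls(**raw)

    def to_yaml(self, path: Union[str, Path]) -> None:
        Path(path).write_text(
            yaml.safe_dump(asdict(self), sort_keys=False), encoding="utf-8")


def default_spec(seed: int = 0) -> SyntheticCohortSpec:
    """The packaged study-scale scenario: three lineages with one planted
    lineage-specific surface gene each, plus an STK11-style mutation
    signature in LUAD (6 mutant tumors; marker deltas 2.76, 4.74 and 1.55
    bits, the magnitudes typical of strong mutation-linked surface
    markers)."""
    return SyntheticCohortSpec(
        lineages=[("LUAD", 29), ("BRCA", 20), ("KIRC", 15)],
        n_genes=1200,
        n_surface=100,
        baseline_mean=8.0,
        noise_sd=1.0,
        planted_lineage_effects=[
            PlantedLineageEffect(gene_index=0, lineage="LUAD", delta=2.0),
            PlantedLineageEffect(gene_index=1, lineage="BRCA", delta=2.0),
            PlantedLineageEffect(gene_index=2, lineage="KIRC", delta=2.0),
        ],
        planted_mutation_effects=[
            PlantedMutationEffect(3, "STK11", "LUAD", 6, 2.76),
            PlantedMutationEffect(4, "STK11", "LUAD", 6, 4.74),
            PlantedMutationEffect(5, "STK11", "LUAD", 6, 1.55),
        ],
        seed=seed,
    )


def _sample_ids(lineage: str, n_pairs: int) -> list[tuple[str, str, str]]:
    # (patient, tumor sample, normal sample)
    return [
        (f"{lineage}-P{i:03d}", f"{lineage}-P{i:03d}-T", f"{lineage}-P{i:03d}-N")
        for i in range(1, n_pairs + 1)
    ]


def generate(spec: SyntheticCohortSpec) -> tuple[ExpressionMatrix, SampleTable, MutationTable, GeneSet]:
    """Generate (raw-scale expression, samples, mutations, surface set).

    Fully deterministic given ``spec.seed``. The raw matrix is
    ``2**log2 - 1``, the exact inverse of the pipeline's
    log2(v+1) normalisation.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    genes = [GeneId(symbol=f"GENE{i:05d}", entrez=100000 + i) for i in range(spec.n_genes)]
    surface = GeneSet(
        name="synthetic cell surface",
        members=frozenset(genes[: spec.n_surface]))

    sample_records: list[SampleRecord] = []
    tumor_cols: dict[str, list[int]] = {}
    col_of: dict[str, int] = {}
    for lineage, n_pairs in spec.lineages:
        tumor_cols[lineage] = []
        for patient, t_id, n_id in _sample_ids(lineage, n_pairs):
            for sid, stype in ((t_id, SampleType.tumor_primary), (n_id, SampleType.normal)):
                col_of[sid] = len(sample_records)
                sample_records.append(SampleRecord(
                    sample_id=sid, patient_id=patient,
                    lineage=lineage, sample_type=stype))
            tumor_cols[lineage].append(col_of[t_id])
    samples = SampleTable(sample_records)
    n_samples = len(sample_records)

    log2 = rng.normal(spec.baseline_mean, spec.noise_sd, size=(spec.n_genes, n_samples))
    for eff in spec.planted_lineage_effects:
        log2[eff.gene_index, tumor_cols[eff.lineage]] += eff.delta

    # assign mutant tumors per (lineage, mutated_gene); effects sharing both
    # share the same mutant sample set so markers co-occur as in real data
    mutant_sets: dict[tuple[str, str], list[str]] = {}
    for eff in spec.planted_mutation_effects:
        key = (eff.lineage, eff.mutated_gene)
        if key not in mutant_sets:
            cols = tumor_cols[eff.lineage]
            chosen = rng.choice(len(cols), size=eff.n_mutant, replace=False)
            mutant_sets[key] = sorted(
                sample_records[cols[i]].sample_id for i in chosen)
        elif len(mutant_sets[key]) != eff.n_mutant:
            raise ValidationError(
                f"conflicting n_mutant for {key}: {len(mutant_sets[key])} vs {eff.n_mutant}")
        for sid in mutant_sets[key]:
            log2[eff.marker_gene_index, col_of[sid]] += eff.delta

    log2 = np.maximum(log2, 0.0)  # raw scale must be non-negative
    raw = np.exp2(log2) - 1.0

    expression = ExpressionMatrix(
        genes=genes,
        samples=[r.sample_id for r in sample_records],
        values=raw,
        scale_tag="raw_counts",
    )

    mutations = _generate_mutations(spec, rng, mutant_sets, tumor_cols, sample_records)
    return expression, samples, MutationTable(mutations), surface


def _generate_mutations(spec, rng, mutant_sets, tumor_cols, sample_records) -> list[MutationRecord]:
    sm = spec.score_model
    records: list[MutationRecord] = []
    for (lineage, mut_gene), mutant_ids in sorted(mutant_sets.items()):
        gid = GeneId(symbol=mut_gene)
        for sid in mutant_ids:
            if rng.random() < sm.truncating_fraction:
                records.append(MutationRecord(
                    gene=gid, sample_id=sid,
                    variant_class=VariantClass.truncating))
            else:
                records.append(MutationRecord(
                    gene=gid, sample_id=sid,
                    variant_class=VariantClass.missense,
                    sift_score=float(rng.uniform(0.0, 0.05)),
                    polyphen_score=float(rng.uniform(0.0, 1.0))))
        # decoys on wild-type tumors: fail the consequence filter by construction
        wildtype = sorted(
            sample_records[c].sample_id for c in tumor_cols[lineage]
            if sample_records[c].sample_id not in set(mutant_ids))
        for sid in wildtype:
            if rng.random() >= sm.decoy_fraction:
                continue
            if rng.random() < sm.decoy_synonymous_fraction:
                records.append(MutationRecord(
                    gene=gid, sample_id=sid,
                    variant_class=VariantClass.synonymous))
            else:
                records.append(MutationRecord(
                    gene=gid, sample_id=sid,
                    variant_class=VariantClass.missense,
                    sift_score=float(rng.uniform(0.05, 1.0)),
                    polyphen_score=float(rng.uniform(0.0, 0.85))))
    return records


def _fmt(x: float) -> str:
    return repr(float(x))


def write_fixture_bundle(
    outputs: tuple[ExpressionMatrix, SampleTable, MutationTable, GeneSet],
    directory: Union[str, Path],
) -> dict[str, Path]:
    """Write the four generated objects in the on-disk input formats.

    Files: expression.tsv, samples.tsv, mutations.tsv, surface_genes.list.
    Byte-identical across re-runs of the same spec/seed.
    """
    expression, samples, mutations, surface = outputs
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {k: directory / f for k, f in (
        ("expression", "expression.tsv"), ("samples", "samples.tsv"),
        ("mutations", "mutations.tsv"), ("gene_set", "surface_genes.list"))}

    with open(paths["expression"], "w", encoding="utf-8", newline="\n") as fh:
        fh.write("gene_id\t" + "\t".join(expression.samples) + "\n")
        for gene, row in zip(expression.genes, expression.values):
            fh.write(gene.label + "\t" + "\t".join(_fmt(v) for v in row) + "\n")

    with open(paths["samples"], "w", encoding="utf-8", newline="\n") as fh:
        fh.write("sample_id\tpatient_id\tlineage\tsample_type\n")
        for r in samples:
            fh.write(f"{r.sample_id}\t{r.patient_id}\t{r.lineage}\t{r.sample_type.value}\n")

    with open(paths["mutations"], "w", encoding="utf-8", newline="\n") as fh:
        fh.write("gene\tsample_id\tvariant_class\tsift_score\tpolyphen_score\n")
        for m in mutations:
            sift = "NA" if m.sift_score is None else _fmt(m.sift_score)
            poly = "NA" if m.polyphen_score is None else _fmt(m.polyphen_score)
            fh.write(f"{m.gene.label}\t{m.sample_id}\t{m.variant_class.value}\t{sift}\t{poly}\n")

    ordered = sorted(surface.members, key=lambda g: (g.symbol or "", g.entrez or -1))
    with open(paths["gene_set"], "w", encoding="utf-8", newline="\n") as fh:
        for g in ordered:
            fh.write((g.symbol or g.label) + "\n")
    return paths
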