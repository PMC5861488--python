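"""Readers and writers for the tabular formats the profiler consumes and emits.

Supported inputs are a gene x sample expression TSV (TCGA RNASeqV2 dialect
with ``SYMBOL|ENTREZ`` row IDs, or a plain-symbol dialect), a sample
annotation TSV, a MAF-like somatic mutation TSV carrying SIFT and
PolyPhen-2 consequence scores, and gene sets in GMT or one-symbol-per-line
form. The single output format is the per-gene profile TSV.

All readers are strict: malformed cells, duplicate identifiers and
out-of-range scores raise :class:`ValidationError` with coordinates rather
than being silently coerced.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ValidationError",
    "SampleType",
    "VariantClass",
    "GeneId",
    "ExpressionMatrix",
    "SampleRecord",
    "SampleTable",
    "MutationRecord",
    "MutationTable",
    "GeneSet",
    "read_expression",
    "read_samples",
    "read_mutations",
    "read_gene_set",
    "write_profile",
    "load_packaged_surface_genes",
]


class ValidationError(ValueError):
    """An input file or record violates the format contract."""


class SampleType(str, Enum):
    tumor_primary = "tumor_primary"
    tumor_metastatic = "tumor_metastatic"
    normal = "normal"


#: TCGA barcode sample-type codes accepted in the ``sample_type`` column.
#: 01 = primary solid tumor, 06 = metastatic, 11 = solid tissue normal.
TCGA_SAMPLE_TYPE_CODES = {
    "01": SampleType.tumor_primary,
    "06": SampleType.tumor_metastatic,
    "11": SampleType.normal,
}


class VariantClass(str, Enum):
    missense = "missense"
    truncating = "truncating"
    synonymous = "synonymous"
    other = "other"


# Common MAF Variant_Classification spellings, normalised case-insensitively.
_VARIANT_CLASS_ALIASES = {
    "missense": VariantClass.missense,
    "missense_mutation": VariantClass.missense,
    "truncating": VariantClass.truncating,
    "nonsense_mutation": VariantClass.truncating,
    "frame_shift_del": VariantClass.truncating,
    "frame_shift_ins": VariantClass.truncating,
    "splice_site": VariantClass.truncating,
    "nonstop_mutation": VariantClass.truncating,
    "synonymous": VariantClass.synonymous,
    "silent": VariantClass.synonymous,
    "other": VariantClass.other,
}


@dataclass(frozen=True)
class GeneId:
    """A gene identifier: HGNC-style symbol, Entrez id, or both.

    TCGA RNASeqV2 rows are labelled ``SYMBOL|ENTREZ``; rows with no symbol
    use ``?`` in the symbol slot and are represented here with
    ``symbol=None``.
    """

    symbol: Optional[str] = None
    entrez: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.symbol and self.entrez is None:
            raise ValidationError("GeneId needs a symbol or an Entrez id")

    @classmethod
    def parse(cls, text: str, dialect: str = "tcga_rnaseqv2") -> "GeneId":
        text = text.strip()
        if dialect == "tcga_rnaseqv2" and "|" in text:
            sym, _, ent = text.partition("|")
            sym = sym.strip()
            try:
                entrez = int(ent)
            except ValueError as exc:
                raise ValidationError(f"bad Entrez id in gene row {text!r}") from exc
            return cls(symbol=None if sym in ("", "?") else sym, entrez=entrez)
        if dialect not in ("tcga_rnaseqv2", "plain"):
            raise ValidationError(f"unknown expression dialect {dialect!r}")
        if not text or text == "?":
            raise ValidationError("gene row has neither symbol nor Entrez id")
        return cls(symbol=text)

    @property
    def label(self) -> str:
        """Round-trippable text form (``SYMBOL|ENTREZ`` when both known)."""
        if self.symbol is not None and self.entrez is not None:
            return f"{self.symbol}|{self.entrez}"
        if self.symbol is not None:
            return self.symbol
        return f"?|{self.entrez}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.label


@dataclass
class ExpressionMatrix:
    """Gene x sample expression values, tagged with their scale.

    ``scale_tag`` is ``"raw_counts"`` for RSEM-style estimates as read from
    disk and ``"log2"`` after :func:`surfprofiler.cohort.normalize_log2`.
    """

    genes: list[GeneId]
    samples: list[str]
    values: np.ndarray
    scale_tag: str = "raw_counts"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.genes), len(self.samples)):
            raise ValidationError(
                f"value matrix shape {self.values.shape} does not match "
                f"{len(self.genes)} genes x {len(self.samples)} samples"
            )
        labels = [g.label for g in self.genes]
        dup = _first_duplicate(labels)
        if dup is not None:
            raise ValidationError(f"duplicate gene row: {dup}")
        dup = _first_duplicate(self.samples)
        if dup is not None:
            raise ValidationError(f"duplicate sample column: {dup}")
        if self.scale_tag == "log2" and not np.isfinite(self.values).all():
            raise ValidationError("log2 matrix contains non-finite values")
        self._sample_index = {s: j for j, s in enumerate(self.samples)}
        self._gene_index: dict[Union[str, int], int] = {}
        for i, g in enumerate(self.genes):
            if g.symbol is not None:
                self._gene_index.setdefault(g.symbol, i)
            if g.entrez is not None:
                self._gene_index.setdefault(g.entrez, i)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def gene_row(self, gene: Union[GeneId, str, int]) -> int:
        """Row index of a gene, matching by symbol first, Entrez fallback."""
        if isinstance(gene, GeneId):
            if gene.symbol is not None and gene.symbol in self._gene_index:
                return self._gene_index[gene.symbol]
            if gene.entrez is not None and gene.entrez in self._gene_index:
                return self._gene_index[gene.entrez]
            raise KeyError(f"gene {gene.label} not in matrix")
        if gene in self._gene_index:
            return self._gene_index[gene]
        raise KeyError(f"gene {gene!r} not in matrix")

    def __contains__(self, gene: Union[GeneId, str, int]) -> bool:
        try:
            self.gene_row(gene)
            return True
        except KeyError:
            return False

    def expression_of(self, gene: Union[GeneId, str, int], samples: Sequence[str]) -> np.ndarray:
        row = self.gene_row(gene)
        cols = [self._sample_index[s] for s in samples]
        return self.values[row, cols]

    def subset_samples(self, samples: Sequence[str]) -> "ExpressionMatrix":
        cols = [self._sample_index[s] for s in samples]
        return ExpressionMatrix(
            genes=list(self.genes),
            samples=list(samples),
            values=self.values[:, cols].copy(),
            scale_tag=self.scale_tag,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=[g.label for g in self.genes], columns=self.samples
        )


@dataclass(frozen=True)
class SampleRecord:
    sample_id: str
    patient_id: str
    lineage: str
    sample_type: SampleType

    def __post_init__(self) -> None:
        if not self.lineage:
            raise ValidationError(f"sample {self.sample_id}: empty lineage")


@dataclass
class SampleTable:
    records: list[SampleRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        dup = _first_duplicate([r.sample_id for r in self.records])
        if dup is not None:
            raise ValidationError(f"duplicate sample_id: {dup}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def lineages(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.records:
            seen.setdefault(r.lineage, None)
        return list(seen)

    def in_lineage(self, lineage: str) -> list[SampleRecord]:
        return [r for r in self.records if r.lineage == lineage]


@dataclass(frozen=True)
class MutationRecord:
    gene: GeneId
    sample_id: str
    variant_class: VariantClass
    sift_score: Optional[float] = None
    polyphen_score: Optional[float] = None

    def __post_init__(self) -> None:
        for name, score in (("sift_score", self.sift_score), ("polyphen_score", self.polyphen_score)):
            if score is not None and not (0.0 <= score <= 1.0):
                raise ValidationError(
                    f"{name}={score} outside [0, 1] for {self.gene.label} in {self.sample_id}"
                )


@dataclass
class MutationTable:
    records: list[MutationRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def for_gene(self, gene: Union[GeneId, str]) -> list[MutationRecord]:
        """Records for one gene, matched by symbol first, Entrez fallback."""
        if isinstance(gene, str):
            gene = GeneId(symbol=gene)
        by_symbol = [
            r for r in self.records
            if gene.symbol is not None and r.gene.symbol == gene.symbol
        ]
        if by_symbol:
            return by_symbol
        if gene.entrez is not None:
            return [r for r in self.records if r.gene.entrez == gene.entrez]
        return []


@dataclass
class GeneSet:
    """A named set of genes, e.g. the GO:0009986 'cell surface' membership."""

    name: str
    members: frozenset[GeneId]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValidationError(f"gene set {self.name!r} is empty")
        object.__setattr__(self, "_symbols", frozenset(
            g.symbol for g in self.members if g.symbol is not None))
        object.__setattr__(self, "_entrez", frozenset(
            g.entrez for g in self.members if g.entrez is not None))

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, gene: Union[GeneId, str]) -> bool:
        if isinstance(gene, str):
            return gene in self._symbols
        if gene.symbol is not None and gene.symbol in self._symbols:
            return True
        return gene.entrez is not None and gene.entrez in self._entrez

    @property
    def symbols(self) -> frozenset[str]:
        return self._symbols


def _first_duplicate(items: Iterable) -> Optional[object]:
    seen = set()
    for x in items:
        if x in seen:
            return x
        seen.add(x)
    return None


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_expression(path: Union[str, Path], dialect: str = "tcga_rnaseqv2") -> ExpressionMatrix:
    """Read a gene x sample expression TSV into a raw-scale matrix.

    The header row holds sample IDs; the first column holds gene IDs
    (``SYMBOL|ENTREZ`` under the ``tcga_rnaseqv2`` dialect, bare symbols
    under ``plain``). Non-numeric cells and duplicate gene rows are hard
    errors with coordinates.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, index_col=0)
    df.index = df.index.astype(str)
    genes = [GeneId.parse(t, dialect=dialect) for t in df.index]
    samples = [str(c) for c in df.columns]
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise ValidationError(
            f"non-numeric expression value {df.iat[i, j]!r} at gene "
            f"{df.index[i]!r}, sample {samples[j]!r}"
        )
    if numeric.isna().to_numpy().any():
        i, j = np.argwhere(numeric.isna().to_numpy())[0]
        raise ValidationError(
            f"missing expression value at gene {df.index[i]!r}, sample {samples[j]!r}"
        )
    return ExpressionMatrix(
        genes=genes, samples=samples,
        values=numeric.to_numpy(dtype=float), scale_tag="raw_counts",
    )


def read_samples(path: Union[str, Path]) -> SampleTable:
    """Read the sample annotation TSV (sample_id, patient_id, lineage, sample_type).

    ``sample_type`` accepts either the explicit enum names or TCGA barcode
    sample-type codes (01 tumor, 06 metastatic, 11 normal). An empty file
    yields an empty table with a logged warning.
    """
    path = Path(path)
    required = ["sample_id", "patient_id", "lineage", "sample_type"]
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        logger.warning("sample table %s is empty", path)
        return SampleTable([])
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"sample table missing required columns: {', '.join(missing)}")
    records = []
    for row in df.itertuples(index=False):
        raw_type = str(row.sample_type).strip()
        if raw_type in TCGA_SAMPLE_TYPE_CODES:
            stype = TCGA_SAMPLE_TYPE_CODES[raw_type]
        else:
            try:
                stype = SampleType(raw_type.lower())
            except ValueError:
                raise ValidationError(
                    f"unknown sample_type {raw_type!r} for sample {row.sample_id!r}"
                ) from None
        records.append(SampleRecord(
            sample_id=str(row.sample_id), patient_id=str(row.patient_id),
            lineage=str(row.lineage), sample_type=stype,
        ))
    return SampleTable(records)


_NA_TOKENS = {"", "na", "nan", "n/a", "none", "null", "."}


def _parse_score(raw, what: str, where: str) -> Optional[float]:
    if raw is None or (isinstance(raw, float) and math.isnan(raw)):
        return None
    text = str(raw).strip()
    if text.lower() in _NA_TOKENS:
        return None
    try:
        return float(text)
    except ValueError:
        raise ValidationError(f"non-numeric {what} {text!r} in {where}") from None


def read_mutations(path: Union[str, Path]) -> MutationTable:
    """Read a MAF-like mutation TSV (gene, sample_id, variant_class, sift_score, polyphen_score).

    NA score cells become absent scores; variant classes are normalised
    case-insensitively (common MAF spellings are accepted, anything
    unrecognised maps to ``other`` with a warning).
    """
    path = Path(path)
    required = ["gene", "sample_id", "variant_class", "sift_score", "polyphen_score"]
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        logger.warning("mutation table %s is empty", path)
        return MutationTable([])
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"mutation table missing required columns: {', '.join(missing)}")
    records = []
    unknown_classes: set[str] = set()
    for row in df.itertuples(index=False):
        key = str(row.variant_class).strip().lower()
        vclass = _VARIANT_CLASS_ALIASES.get(key)
        if vclass is None:
            unknown_classes.add(str(row.variant_class))
            vclass = VariantClass.other
        where = f"mutation row ({row.gene}, {row.sample_id})"
        records.append(MutationRecord(
            gene=GeneId.parse(str(row.gene), dialect="tcga_rnaseqv2"),
            sample_id=str(row.sample_id),
            variant_class=vclass,
            sift_score=_parse_score(row.sift_score, "SIFT score", where),
            polyphen_score=_parse_score(row.polyphen_score, "PolyPhen-2 score", where),
        ))
    if unknown_classes:
        logger.warning(
            "unrecognised variant_class values mapped to 'other': %s",
            ", ".join(sorted(unknown_classes)))
    return MutationTable(records)


def read_gene_set(path: Union[str, Path], format: Optional[str] = None) -> GeneSet:
    """Read a gene set from a GMT line or a one-symbol-per-line list file.

    When ``format`` is omitted it is guessed from the ``.gmt`` suffix.
    Duplicate members are collapsed with a logged count; an empty member
    list is a hard error.
    """
    path = Path(path)
    if format is None:
        format = "gmt" if path.suffix.lower() == ".gmt" else "list"
    if format not in ("gmt", "list"):
        raise ValidationError(f"unknown gene-set format {format!r}")
    text = path.read_text(encoding="utf-8")
    lines = [ln.strip() for ln in text.replace("\r\n", "\n").split("\n")]
    if format == "gmt":
        content = [ln for ln in lines if ln]
        if not content:
            raise ValidationError(f"gene-set file {path} is empty")
        fields = content[0].split("\t")
        if len(fields) < 3:
            raise ValidationError(f"GMT line in {path} has no members")
        name, symbols = fields[0], [s for s in fields[2:] if s]
    else:
        name = path.stem
        symbols = [ln for ln in lines if ln and not ln.startswith("#")]
    if not symbols:
        raise ValidationError(f"gene set {name!r} has no members")
    unique = list(dict.fromkeys(symbols))
    n_dup = len(symbols) - len(unique)
    if n_dup:
        logger.warning("gene set %s: collapsed %d duplicate members", name, n_dup)
    return GeneSet(name=name, members=frozenset(GeneId(symbol=s) for s in unique))


def load_packaged_surface_genes() -> GeneSet:
    """Load the packaged cell-surface gene list (GO:0009986 stand-in).

    The packaged file is a synthetic stand-in for the 519-gene
    Gene Ontology 'cell surface' (GO:0009986) membership: it carries the
    surface/ADC-target symbols discussed in the literature plus generated
    placeholder symbols to reach the same size, and exists so the full
    pipeline runs without any external download.
    """
    ref = resources.files("surfprofiler").joinpath(
        "data/surface_genes_go0009986_synthetic.list")
    with resources.as_file(ref) as p:
        gs = read_gene_set(p, format="list")
    return replace(gs, name="GO:0009986 cell surface (synthetic stand-in)")


# ---------------------------------------------------------------------------
# writer
# ---------------------------------------------------------------------------

def _fmt(x: float) -> str:
    # repr round-trips doubles exactly and is locale-independent
    return repr(float(x))


def write_profile(result, path: Union[str, Path]) -> None:
    """Write a profile result as a TSV with deterministic row order.

    Columns: gene, log2_delta, p_value, n_group1, n_group2, is_surface,
    is_hit (plus fdr_bh when present). Rows are ordered by descending
    \\|log2_delta\\|, ties broken by gene label; undefined p-values are
    written as ``NA``. Re-running on identical input produces an identical
    file.
    """
    rows = result.rows
    order = rows.assign(
        _mag=rows["log2_delta"].abs(), _sym=[g.label for g in rows["gene"]]
    ).sort_values(["_mag", "_sym"], ascending=[False, True], kind="mergesort")
    has_fdr = "fdr_bh" in rows.columns
    cols = ["gene", "log2_delta", "p_value", "n_group1", "n_group2", "is_surface", "is_hit"]
    if has_fdr:
        cols.append("fdr_bh")
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(cols) + "\n")
        for row in order.itertuples(index=False):
            p = "NA" if pd.isna(row.p_value) else _fmt(row.p_value)
            out = [row.gene.label, _fmt(row.log2_delta), p,
                   str(int(row.n_group1)), str(int(row.n_group2)),
                   str(bool(row.is_surface)), str(bool(row.is_hit))]
            if has_fdr:
                out.append("NA" if pd.isna(row.fdr_bh) else _fmt(row.fdr_bh))
            fh.write("\t".join(out) + "\n")
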