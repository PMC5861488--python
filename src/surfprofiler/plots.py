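"""Deterministic plot-data builders and renderers: volcano, box,
waterfall and cross-lineage comparison views.

Every builder is a pure function returning a tabular object that can be
exported as TSV (for headless use) or rendered to SVG/PNG. SVG output is
byte-deterministic for fixed data and style.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .cohort import LineageCohort, MutationStatus
from .io import ExpressionMatrix, GeneId, GeneSet, SampleTable, SampleType, ValidationError
from .profiling import HitCriteria, ProfileResult, hit_mask

logger = logging.getLogger(__name__)

__all__ = [
    "VolcanoData",
    "BoxplotData",
    "WaterfallData",
    "ComparisonData",
    "DEFAULT_STYLE",
    "volcano_data",
    "gene_boxplot_data",
    "waterfall_data",
    "comparison_data",
    "render",
    "export_table",
]

#: -log10(p) display cap: keeps sentinel-small p-values finite on the plot.
NEGLOG10_CAP = 300.0

#: Style defaults: grey = all genes, yellow = surface genes, red = hits;
#: red/blue = mutant vs wild-type/normal in sample-level views.
DEFAULT_STYLE = {
    "all_color": "#b0b0b0",
    "surface_color": "#e6c800",
    "hit_color": "#d62728",
    "mutant_color": "#d62728",
    "wildtype_color": "#1f77b4",
    "normal_color": "#1f77b4",
    "tumor_color": "#d62728",
    "highlight_color": "#d62728",
    "other_color": "#b0b0b0",
    "figsize": (6.0, 5.0),
    "dpi": 100,
    "svg_hashsalt": "surfprofiler",
}


@dataclass
class VolcanoData:
    """Per-gene (x = log2Delta, y = -log10 p) with display layers.

    Layer precedence is hit > surface > all; genes with undefined p are
    excluded from the rows and counted in ``n_undefined``.
    """

    rows: pd.DataFrame  # columns: gene, x, y, layer
    n_undefined: int
    lineage: str
    kind: str = "volcano"

    def layer_counts(self) -> dict[str, int]:
        return self.rows["layer"].value_counts().to_dict()


@dataclass
class BoxplotData:
    """Grouped expression values for one gene + five-number summaries.

    Quantiles use linear interpolation between order statistics
    (numpy's default convention).
    """

    gene: GeneId
    lineage: str
    groups: dict[str, np.ndarray]
    summaries: pd.DataFrame  # index group, columns min/q1/median/q3/max/n
    warning: Optional[str] = None
    kind: str = "box"

    @property
    def rows(self) -> pd.DataFrame:
        recs = [
            {"group": g, "value": float(v)}
            for g, vals in self.groups.items() for v in vals
        ]
        return pd.DataFrame(recs, columns=["group", "value"])


@dataclass
class WaterfallData:
    """All samples ranked by one gene's expression (descending; ties by
    sample_id), with group and highlight-lineage annotations."""

    gene: GeneId
    highlight_lineage: str
    rows: pd.DataFrame  # columns: sample_id, lineage, group, value, highlighted
    kind: str = "waterfall"


@dataclass
class ComparisonData:
    """One gene's per-lineage effect sizes across all profiled lineages."""

    gene: GeneId
    rows: pd.DataFrame  # columns: lineage, log2_delta, p_value, n_group1, n_group2, present
    kind: str = "comparison"


def volcano_data(
    result: ProfileResult,
    surface: GeneSet,
    criteria: HitCriteria = HitCriteria(),
) -> VolcanoData:
    """Assign every profiled gene to exactly one volcano layer.

    Layers partition the defined-p genes: hits (criteria satisfied),
    remaining surface genes, remaining genes.
    """
    rows = result.rows
    defined = rows["p_value"].notna().to_numpy()
    hits = hit_mask(rows, criteria)
    is_surface = rows["is_surface"].to_numpy()
    layer = np.where(hits, "hit", np.where(is_surface, "surface", "all"))
    y = -np.log10(rows["p_value"].to_numpy()[defined])
    out = pd.DataFrame({
        "gene": rows["gene"].to_numpy()[defined],
        "x": rows["log2_delta"].to_numpy()[defined],
        "y": np.minimum(y, NEGLOG10_CAP),
        "layer": layer[defined],
    })
    return VolcanoData(
        rows=out, n_undefined=int((~defined).sum()), lineage=result.lineage)


def _five_numbers(values: np.ndarray) -> dict[str, float]:
    q1, med, q3 = np.quantile(values, [0.25, 0.5, 0.75])  # linear interpolation
    return {
        "min": float(values.min()), "q1": float(q1), "median": float(med),
        "q3": float(q3), "max": float(values.max()), "n": int(values.size),
    }


def gene_boxplot_data(
    cohort: LineageCohort,
    status: Optional[MutationStatus],
    gene: Union[GeneId, str],
) -> BoxplotData:
    """Grouped log2 expression of one gene.

    Lineage mode (``status=None``): tumor vs normal groups. Mutation mode:
    mutant / wildtype / normal, still produced (with a warning) when the
    mutant count is below the testing threshold — plotting is allowed
    where testing is not.
    """
    matrix = cohort.expression
    if matrix is None or gene not in matrix:
        label = gene.label if isinstance(gene, GeneId) else str(gene)
        raise KeyError(f"gene {label} not in cohort expression matrix")
    warning = None
    if status is None:
        groups = {
            "tumor": matrix.expression_of(gene, cohort.tumor_samples),
            "normal": matrix.expression_of(gene, cohort.normal_samples),
        }
    else:
        groups = {
            "mutant": matrix.expression_of(gene, sorted(status.mutant_samples)),
            "wildtype": matrix.expression_of(gene, sorted(status.wildtype_samples)),
            "normal": matrix.expression_of(gene, cohort.normal_samples),
        }
        if status.below_threshold:
            warning = (
                f"{status.n_mutant} mutant sample(s): below the testing "
                "threshold; plot data only")
    summaries = pd.DataFrame(
        {g: _five_numbers(v) for g, v in groups.items() if v.size > 0}
    ).T[["min", "q1", "median", "q3", "max", "n"]]
    gid = gene if isinstance(gene, GeneId) else GeneId(symbol=gene)
    return BoxplotData(
        gene=gid, lineage=cohort.lineage, groups=groups,
        summaries=summaries, warning=warning)


def waterfall_data(
    matrix: ExpressionMatrix,
    samples: SampleTable,
    gene: Union[GeneId, str],
    highlight_lineage: str,
) -> WaterfallData:
    """Rank every annotated sample (tumor and normal) by one gene's
    expression, descending, ties broken by sample_id."""
    if gene not in matrix:
        label = gene.label if isinstance(gene, GeneId) else str(gene)
        raise KeyError(f"gene {label} not in expression matrix")
    recs = [r for r in samples if r.sample_id in set(matrix.samples)]
    ids = [r.sample_id for r in recs]
    values = matrix.expression_of(gene, ids)
    rows = pd.DataFrame({
        "sample_id": ids,
        "lineage": [r.lineage for r in recs],
        "group": ["normal" if r.sample_type is SampleType.normal else "tumor" for r in recs],
        "value": values,
    })
    rows = rows.sort_values(
        ["value", "sample_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    rows["highlighted"] = rows["lineage"] == highlight_lineage
    gid = gene if isinstance(gene, GeneId) else GeneId(symbol=gene)
    return WaterfallData(gene=gid, highlight_lineage=highlight_lineage, rows=rows)


def comparison_data(
    results: dict[str, ProfileResult],
    gene: Union[GeneId, str],
) -> ComparisonData:
    """Collect one gene's (log2Delta, p, n) across all lineage profiles.

    Lineages where the gene was not profiled get a row marked absent.
    A gene profiled in no lineage is a hard error.
    """
    gid = gene if isinstance(gene, GeneId) else GeneId(symbol=gene)
    recs = []
    n_present = 0
    for lineage, result in results.items():
        try:
            row = result.row_for(gid)
        except KeyError:
            recs.append({
                "lineage": lineage, "log2_delta": np.nan, "p_value": np.nan,
                "n_group1": 0, "n_group2": 0, "present": False})
            continue
        n_present += 1
        recs.append({
            "lineage": lineage,
            "log2_delta": float(row["log2_delta"]),
            "p_value": float(row["p_value"]) if pd.notna(row["p_value"]) else np.nan,
            "n_group1": int(row["n_group1"]), "n_group2": int(row["n_group2"]),
            "present": True})
    if n_present == 0:
        raise KeyError(f"gene {gid.label} profiled in no lineage")
    return ComparisonData(gene=gid, rows=pd.DataFrame(recs))


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _style(overrides: Optional[dict]) -> dict:
    s = dict(DEFAULT_STYLE)
    if overrides:
        s.update(overrides)
    return s


def _new_figure(style: dict):
    fig, ax = plt.subplots(figsize=style["figsize"], dpi=style["dpi"])
    return fig, ax


def _draw_volcano(data: VolcanoData, ax, style: dict) -> None:
    for layer, color, size in (
        ("all", style["all_color"], 6),
        ("surface", style["surface_color"], 10),
        ("hit", style["hit_color"], 14),
    ):
        sub = data.rows[data.rows["layer"] == layer]
        ax.scatter(sub["x"], sub["y"], s=size, c=color, label=layer, linewidths=0)
    ax.set_xlabel("log2Delta (bits)")
    ax.set_ylabel("-log10 p-value")
    ax.set_title(f"{data.lineage}: tumor vs normal")
    ax.legend(frameon=False)


def _draw_box(data: BoxplotData, ax, style: dict) -> None:
    names = [g for g, v in data.groups.items() if v.size > 0]
    colors = {
        "tumor": style["tumor_color"], "mutant": style["mutant_color"],
        "wildtype": style["wildtype_color"], "normal": style["normal_color"],
    }
    bp = ax.boxplot([data.groups[g] for g in names], tick_labels=names,
                    patch_artist=True, whis=(0, 100))
    for patch, name in zip(bp["boxes"], names):
        patch.set_facecolor(colors.get(name, style["other_color"]))
    ax.set_ylabel("log2 expression")
    title = f"{data.gene.label} in {data.lineage}"
    if data.warning:
        title += " (!)"
    ax.set_title(title)


def _draw_waterfall(data: WaterfallData, ax, style: dict) -> None:
    colors = np.where(
        data.rows["highlighted"], style["highlight_color"], style["other_color"])
    ax.bar(np.arange(len(data.rows)), data.rows["value"], width=1.0,
           color=colors, linewidth=0)
    ax.set_xlabel("samples (ranked)")
    ax.set_ylabel("log2 expression")
    ax.set_title(f"{data.gene.label} — {data.highlight_lineage} highlighted")


def _draw_comparison(data: ComparisonData, ax, style: dict) -> None:
    present = data.rows[data.rows["present"]]
    ax.bar(present["lineage"], present["log2_delta"], color=style["surface_color"])
    ax.axhline(0.0, color="black", linewidth=0.8)
    ax.set_ylabel("log2Delta (bits)")
    ax.set_title(f"{data.gene.label} across lineages")
    ax.tick_params(axis="x", rotation=60)


_DRAWERS = {
    "volcano": _draw_volcano,
    "box": _draw_box,
    "waterfall": _draw_waterfall,
    "comparison": _draw_comparison,
}


def render(data, path: Union[str, Path], format: str = "svg",
           style: Optional[dict] = None) -> None:
    """Render plot data to SVG or PNG.

    SVG output is byte-deterministic for fixed data and style (the SVG
    hash salt is pinned and no timestamp metadata is written). Empty data
    is refused.
    """
    if format not in ("svg", "png"):
        raise ValidationError(f"unknown render format {format!r}")
    rows = getattr(data, "rows", None)
    if rows is None or len(rows) == 0:
        raise ValidationError("refusing to render empty plot data")
    drawer = _DRAWERS.get(getattr(data, "kind", None))
    if drawer is None:
        raise ValidationError(f"unknown plot data kind {getattr(data, 'kind', None)!r}")
    s = _style(style)
    with matplotlib.rc_context({"svg.hashsalt": s["svg_hashsalt"]}):
        fig, ax = _new_figure(s)
        try:
            drawer(data, ax, s)
            fig.tight_layout()
            if format == "svg":
                fig.savefig(path, format="svg", metadata={"Date": None})
            else:
                fig.savefig(path, format="png")
        finally:
            plt.close(fig)


def export_table(data, path: Union[str, Path]) -> None:
    """Write a plot's underlying table as TSV (deterministic float text)."""
    rows = getattr(data, "rows", None)
    if rows is None:
        raise ValidationError("plot data has no table")
    out = rows.copy()
    if "gene" in out.columns:
        out["gene"] = [g.label for g in out["gene"]]
    for col in out.columns:
        if out[col].dtype.kind == "f":
            out[col] = out[col].map(lambda v: "NA" if pd.isna(v) else repr(float(v)))
    out.to_csv(path, sep="\t", index=False, lineterminator="\n")
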