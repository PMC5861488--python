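"""Statistical core: log2Delta, t-test p-values, hit selection."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from conftest import pooled_t_oracle, welch_t_oracle, planted_gene

from surfprofiler import (
    ExpressionMatrix,
    GeneId,
    HitCriteria,
    MutantCountError,
    MutationTable,
    ValidationError,
    build_lineage_cohort,
    filter_nonsynonymous,
    lineage_profile,
    mutation_profile,
    mutation_status,
    profile_all_lineages,
    select_hits,
)
from surfprofiler.cohort import LineageCohort
from surfprofiler.profiling import P_SENTINEL, ProfileResult, flag_hits


def _cohort_from_arrays(tumor: np.ndarray, normal: np.ndarray) -> LineageCohort:
    """Build a cohort directly from (genes x n) tumor and normal arrays."""
    n = tumor.shape[1]
    t_ids = [f"T{i:02d}" for i in range(n)]
    n_ids = [f"N{i:02d}" for i in range(normal.shape[1])]
    matrix = ExpressionMatrix(
        genes=[GeneId(symbol=f"G{i}") for i in range(tumor.shape[0])],
        samples=t_ids + n_ids,
        values=np.hstack([tumor, normal]),
        scale_tag="log2")
    return LineageCohort(
        lineage="LUAD", pairs=list(zip(t_ids, n_ids)), expression=matrix)


def _surface(symbols):
    from surfprofiler.io import GeneSet
    return GeneSet(name="s", members=frozenset(GeneId(symbol=s) for s in symbols))


class TestLineageProfile:
    def test_identical_groups_zero_delta(self):
        vals = np.random.default_rng(0).normal(8, 1, size=(5, 6))
        cohort = _cohort_from_arrays(vals, vals.copy())
        res = lineage_profile(cohort, _surface(["G0"]))
        np.testing.assert_array_equal(res.rows["log2_delta"], 0.0)

    def test_constant_shift_recovered_exactly(self):
        rng = np.random.default_rng(1)
        normal = rng.normal(8, 1, size=(4, 8))
        cohort = _cohort_from_arrays(normal + 1.0, normal)
        res = lineage_profile(cohort, _surface(["G0"]))
        np.testing.assert_allclose(res.rows["log2_delta"], 1.0, rtol=0, atol=1e-12)

    def test_p_matches_textbook_pooled_t_oracle(self):
        rng = np.random.default_rng(2)
        tumor = rng.normal(8.5, 1, size=(20, 10))
        normal = rng.normal(8.0, 1, size=(20, 10))
        cohort = _cohort_from_arrays(tumor, normal)
        res = lineage_profile(cohort, _surface(["G0"]))
        for i in range(20):
            _, p = pooled_t_oracle(tumor[i], normal[i])
            assert res.rows["p_value"][i] == pytest.approx(p, abs=1e-12)

    def test_welch_matches_welch_oracle(self):
        rng = np.random.default_rng(3)
        tumor = rng.normal(8.5, 2, size=(10, 9))
        normal = rng.normal(8.0, 0.5, size=(10, 9))
        cohort = _cohort_from_arrays(tumor, normal)
        res = lineage_profile(cohort, _surface(["G0"]), welch=True)
        for i in range(10):
            _, p = welch_t_oracle(tumor[i], normal[i])
            assert res.rows["p_value"][i] == pytest.approx(p, abs=1e-12)

    def test_antisymmetry_swapping_groups(self):
        rng = np.random.default_rng(4)
        tumor = rng.normal(9, 1, size=(8, 7))
        normal = rng.normal(8, 1, size=(8, 7))
        fwd = lineage_profile(_cohort_from_arrays(tumor, normal), _surface(["G0"]))
        rev = lineage_profile(_cohort_from_arrays(normal, tumor), _surface(["G0"]))
        np.testing.assert_allclose(
            fwd.rows["log2_delta"], -rev.rows["log2_delta"], atol=1e-12)
        np.testing.assert_allclose(
            fwd.rows["p_value"], rev.rows["p_value"], atol=1e-12)

    def test_constant_added_to_group1_shifts_delta_exactly(self):
        rng = np.random.default_rng(5)
        tumor = rng.normal(8, 1, size=(6, 5))
        normal = rng.normal(8, 1, size=(6, 5))
        base = lineage_profile(_cohort_from_arrays(tumor, normal), _surface(["G0"]))
        shifted = lineage_profile(
            _cohort_from_arrays(tumor + 2.5, normal), _surface(["G0"]))
        np.testing.assert_allclose(
            shifted.rows["log2_delta"] - base.rows["log2_delta"], 2.5, atol=1e-12)

    def test_degenerate_variance_equal_means_undefined(self):
        tumor = np.full((1, 5), 3.0)
        res = lineage_profile(
            _cohort_from_arrays(tumor, tumor.copy()), _surface(["G0"]))
        assert np.isnan(res.rows["p_value"][0])
        assert res.rows["zero_variance"][0]

    def test_degenerate_variance_unequal_means_sentinel(self):
        res = lineage_profile(
            _cohort_from_arrays(np.full((1, 5), 4.0), np.full((1, 5), 3.0)),
            _surface(["G0"]))
        assert res.rows["p_value"][0] == P_SENTINEL

    def test_paired_flag_uses_per_patient_differences(self):
        rng = np.random.default_rng(6)
        normal = rng.normal(8, 1, size=(3, 10))
        tumor = normal + 1.0 + rng.normal(0, 0.01, size=(3, 10))
        paired = lineage_profile(_cohort_from_arrays(tumor, normal),
                                 _surface(["G0"]), paired=True)
        unpaired = lineage_profile(_cohort_from_arrays(tumor, normal),
                                   _surface(["G0"]))
        # shared per-patient baseline: pairing is far more sensitive
        assert (paired.rows["p_value"] < unpaired.rows["p_value"]).all()

    def test_fdr_column_added_without_changing_hits(self):
        rng = np.random.default_rng(7)
        tumor = rng.normal(9, 1, size=(20, 10))
        normal = rng.normal(8, 1, size=(20, 10))
        cohort = _cohort_from_arrays(tumor, normal)
        plain = lineage_profile(cohort, _surface(["G0"]))
        with_fdr = lineage_profile(cohort, _surface(["G0"]), fdr="bh")
        assert "fdr_bh" in with_fdr.rows.columns
        assert (with_fdr.rows["fdr_bh"] >= with_fdr.rows["p_value"] - 1e-15).all()
        crit = HitCriteria(surface_only=False)
        assert select_hits(plain, crit).rows["log2_delta"].tolist() == \
            select_hits(with_fdr, crit).rows["log2_delta"].tolist()


class TestMutationProfile:
    def test_planted_effect_recovered(self, small_cohort):
        cohort, samples, muts, surface, _ = small_cohort
        status = mutation_status(cohort, filter_nonsynonymous(muts), "STK11")
        res = mutation_profile(cohort, status, surface)
        row = res.row_for("GENE00001")
        se = 0.7 * np.sqrt(1 / status.n_mutant + 1 / status.n_wildtype)
        assert abs(row["log2_delta"] - 3.0) < 3 * se
        assert row["p_value"] < 0.01
        assert res.contrast == "mutant_vs_wildtype"

    def test_single_mutant_refused(self, small_cohort):
        cohort, _, _, surface, _ = small_cohort
        muts = filter_nonsynonymous(MutationTable([]))
        from surfprofiler.io import MutationRecord, VariantClass
        one = MutationTable([MutationRecord(
            gene=GeneId(symbol="STK11"),
            sample_id=cohort.tumor_samples[0],
            variant_class=VariantClass.truncating)])
        status = mutation_status(cohort, one, "STK11")
        with pytest.raises(MutantCountError, match="1"):
            mutation_profile(cohort, status, surface)

    def test_normal_samples_unused(self, small_cohort):
        """Perturbing normal-sample expression must not change the result."""
        cohort, samples, muts, surface, _ = small_cohort
        status = mutation_status(cohort, filter_nonsynonymous(muts), "STK11")
        res_a = mutation_profile(cohort, status, surface)
        perturbed = cohort.expression.values.copy()
        normal_cols = [cohort.expression.samples.index(s) for s in cohort.normal_samples]
        perturbed[:, normal_cols] += 100.0
        noisy_cohort = LineageCohort(
            lineage=cohort.lineage, pairs=cohort.pairs,
            tumor_only=cohort.tumor_only,
            expression=ExpressionMatrix(
                genes=cohort.expression.genes, samples=cohort.expression.samples,
                values=perturbed, scale_tag="log2"))
        res_b = mutation_profile(noisy_cohort, status, surface)
        np.testing.assert_array_equal(res_a.rows["log2_delta"], res_b.rows["log2_delta"])


def _toy_rows(entries):
    return ProfileResult(
        contrast="lineage_tumor_vs_normal", lineage="LUAD",
        rows=pd.DataFrame({
            "gene": [GeneId(symbol=s) for s, *_ in entries],
            "log2_delta": [e[1] for e in entries],
            "p_value": [e[2] for e in entries],
            "n_group1": 10, "n_group2": 10,
            "is_surface": [e[3] for e in entries],
            "is_hit": False, "zero_variance": False,
        }))


class TestSelectHits:
    @pytest.mark.parametrize("delta,p,surface,expected", [
        (2.76, 0.002, True, True),    # strong over-expression, significant
        (1.0, 0.005, True, False),    # boundary delta: strict inequality
        (1.06, 0.03, True, False),    # significant delta, weak p
        (2.0, 0.01, True, False),     # boundary p: strict inequality
        (2.0, 0.001, False, False),   # not a surface gene
        (-2.5, 0.0001, True, False),  # under-expression: signed rule
    ])
    def test_default_criteria(self, delta, p, surface, expected):
        res = _toy_rows([("G", delta, p, surface)])
        hits = select_hits(res, HitCriteria())
        assert (len(hits) == 1) is expected

    def test_absolute_flag_captures_downregulation(self):
        res = _toy_rows([("G", -2.5, 0.0001, True)])
        assert len(select_hits(res, HitCriteria(absolute=True))) == 1

    def test_undefined_p_never_hit(self):
        res = _toy_rows([("G", 5.0, np.nan, True)])
        assert len(select_hits(res, HitCriteria())) == 0

    def test_pure_filter_and_idempotent(self):
        res = _toy_rows([
            ("A", 2.0, 0.001, True), ("B", 3.0, 0.0001, True),
            ("C", 0.5, 0.5, True)])
        once = select_hits(res, HitCriteria())
        twice = select_hits(once, HitCriteria())
        assert [g.symbol for g in once.rows["gene"]] == ["B", "A"]
        assert once.rows["log2_delta"].tolist() == twice.rows["log2_delta"].tolist()

    def test_invalid_criteria_rejected(self):
        with pytest.raises(ValidationError):
            HitCriteria(min_log2_delta=-1)
        with pytest.raises(ValidationError):
            HitCriteria(max_p=0.0)


class TestProfileAllLineages:
    def test_undersized_lineage_skipped_not_fatal(self, three_lineage_inputs):
        log2, samples, _, surface = three_lineage_inputs
        out = profile_all_lineages(log2, samples, surface)
        assert set(out.profiles) == {"LUAD", "BRCA"}
        assert set(out.skipped) == {"KIRP"}
        assert "pairs" in out.skipped["KIRP"]

    def test_delta_matrix_shape(self, three_lineage_inputs):
        log2, samples, _, surface = three_lineage_inputs
        out = profile_all_lineages(log2, samples, surface)
        assert out.delta_matrix.shape == (len(surface), 2)

    def test_planted_gene_hit_only_in_its_lineage(self, three_lineage_inputs):
        log2, samples, _, surface = three_lineage_inputs
        out = profile_all_lineages(log2, samples, surface)
        gene = planted_gene()
        luad_hits = [g.symbol for g in select_hits(out.profiles["LUAD"]).rows["gene"]]
        brca_hits = [g.symbol for g in select_hits(out.profiles["BRCA"]).rows["gene"]]
        assert gene.symbol in luad_hits
        assert gene.symbol not in brca_hits
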