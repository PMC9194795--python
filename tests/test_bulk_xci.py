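"""Bulk pipeline: filtering, size factors, rank-sum tests, end-to-end run."""

import numpy as np
import pandas as pd
import pytest

from xkin import (
    GeneAnnotation,
    InsufficientDataError,
    ValidationError,
    compare_category_expression,
    escapee_share_percent,
    filter_expressed_genes,
    generate_bulk,
    run_bulk_xci,
    size_factors_median_of_ratios,
    PipelineConfig,
)


def _annotation(genes, chromosome="chrX", patch=None):
    patch = patch or set()
    table = pd.DataFrame(
        {
            "chromosome": chromosome,
            "start": np.arange(len(genes)) * 1000,
            "end": np.arange(len(genes)) * 1000 + 500,
            "is_patch": [g in patch for g in genes],
        },
        index=pd.Index(genes, name="gene_id"),
    )
    return GeneAnnotation(table=table)


class TestFilterExpressedGenes:
    def test_strictly_above_mean_cutoff(self):
        counts = pd.DataFrame(
            {"s1": [10, 11, 100], "s2": [10, 10, 100], "s3": [10, 10, 100]},
            index=pd.Index(["at_cutoff", "above", "patchy"], name="gene_id"),
        )
        ann = _annotation(list(counts.index), patch={"patchy"})
        kept = filter_expressed_genes(counts, ann, mean_cutoff=10)
        assert list(kept) == ["above"]  # mean 10.0 removed, patch removed

    def test_no_samples_is_error(self):
        counts = pd.DataFrame(index=pd.Index(["g1"], name="gene_id"))
        with pytest.raises(ValidationError):
            filter_expressed_genes(counts, _annotation(["g1"]))


class TestSizeFactors:
    def test_identical_samples_give_unit_factors(self):
        counts = pd.DataFrame({"s1": [10, 20, 5], "s2": [10, 20, 5]})
        assert np.allclose(size_factors_median_of_ratios(counts), 1.0)

    def test_global_scaling_recovered(self):
        rng = np.random.default_rng(0)
        base = rng.integers(1, 200, 50)
        counts = pd.DataFrame({"A": base, "B": 2 * base})
        factors = size_factors_median_of_ratios(counts)
        assert factors["B"] / factors["A"] == pytest.approx(2.0)

    def test_gene_with_zero_excluded_from_reference(self):
        # the zero-containing gene would otherwise drag sample ratios down
        counts = pd.DataFrame({"s1": [100, 0], "s2": [100, 50]})
        factors = size_factors_median_of_ratios(counts)
        assert np.allclose(factors, [1.0, 1.0])

    def test_matches_deseq2_reference_implementation(self):
        pydeseq2 = pytest.importorskip("pydeseq2.preprocessing")
        rng = np.random.default_rng(5)
        counts = pd.DataFrame(
            rng.negative_binomial(5, 0.05, size=(200, 6)),
            columns=[f"s{i}" for i in range(6)],
        )
        ours = size_factors_median_of_ratios(counts)
        _, theirs = pydeseq2.deseq2_norm(counts.T.to_numpy())
        assert np.allclose(ours.to_numpy(), theirs, rtol=1e-10)

    def test_all_zero_reference_is_error(self):
        counts = pd.DataFrame({"s1": [0, 5], "s2": [5, 0]})
        with pytest.raises(InsufficientDataError):
            size_factors_median_of_ratios(counts)


class TestCompareCategoryExpression:
    def test_identical_multisets_give_p_one(self):
        expr = pd.Series([1.0, 2, 3, 1, 2, 3], index=list("abcdef"))
        cats = pd.Series(["x"] * 3 + ["y"] * 3, index=list("abcdef"))
        result = compare_category_expression(expr, cats)
        assert result["p_value"].iloc[0] == pytest.approx(1.0)

    def test_disjoint_small_groups_exact_p(self):
        expr = pd.Series([1.0, 2, 3, 4, 5, 6], index=list("abcdef"))
        cats = pd.Series(["lo"] * 3 + ["hi"] * 3, index=list("abcdef"))
        result = compare_category_expression(expr, cats)
        # exact enumeration: U = 0, two-sided p = 2 / C(6,3)
        assert result["method"].iloc[0] == "exact"
        assert result["p_value"].iloc[0] == pytest.approx(0.1)

    def test_large_shifted_groups_significant(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 1, 50)
        b = rng.normal(2, 1, 50)
        expr = pd.Series(np.concatenate([a, b]))
        cats = pd.Series(["a"] * 50 + ["b"] * 50)
        result = compare_category_expression(expr, cats)
        assert result["method"].iloc[0] == "asymptotic"
        assert result["p_value"].iloc[0] < 1e-3

    def test_small_category_skipped_with_warning(self):
        expr = pd.Series([1.0, 2, 3, 4, 5, 6, 7, 8], index=list("abcdefgh"))
        cats = pd.Series(["x"] * 4 + ["y"] * 2 + ["z"] * 2, index=list("abcdefgh"))
        with pytest.warns(UserWarning, match="skipped"):
            with pytest.raises(InsufficientDataError):
                compare_category_expression(expr, cats, min_genes=3)


class TestEscapeeShare:
    @pytest.mark.parametrize(
        "counts,expected", [((1, 1, 1), 33), ((1, 0, 1), 50), ((0, 3, 1), 25)]
    )
    def test_round_half_up(self, counts, expected):
        assert escapee_share_percent(*counts) == expected


@pytest.fixture(scope="module")
def planted_run():
    matrix, annotation, truth = generate_bulk(
        n_per_category={"earlyXCI": 10, "lateXCI": 20, "escapee": 15},
        n_decoys=5,
        n_autosomal_controls=10,
        depth_mean=5000,
        bb_overdispersion=0.0,
        seed=3,
    )
    config = PipelineConfig()
    result = run_bulk_xci(matrix, annotation, config, matrix.unit_meta["stage"])
    return matrix, annotation, truth, config, result


class TestRunBulkXci:
    def test_recovers_planted_categories_exactly(self, planted_run):
        *_, result = planted_run
        assert result.summary == {
            "earlyXCI": 10,
            "lateXCI": 20,
            "escapee": 15,
            "excluded_nonbiallelic": 5,
            "undetected": 0,
        }

    def test_autosomal_controls_never_inactive(self, planted_run):
        *_, result = planted_run
        assert result.control_summary["escapee"] == 10
        assert result.control_summary["earlyXCI"] == 0
        assert result.control_summary["lateXCI"] == 0

    def test_escapee_overlap_set_arithmetic(self, planted_run):
        matrix, annotation, truth, config, result = planted_run
        escapees = list(result.escapees)
        external = set(escapees[:2]) | {"made_up_gene"}
        rerun = run_bulk_xci(
            matrix, annotation, config, matrix.unit_meta["stage"],
            external_escapee_set=external,
        )
        assert rerun.escapee_overlap == (len(escapees) - 2, 1, 2)

    def test_xist_excluded_from_overlap(self, planted_run):
        matrix, annotation, truth, config, result = planted_run
        n_esc = len(result.escapees)
        rerun = run_bulk_xci(
            matrix, annotation, config, matrix.unit_meta["stage"],
            external_escapee_set={"Xist"},
        )
        assert rerun.escapee_overlap == (n_esc, 0, 0)

    def test_sample_order_permutation_invariance(self, planted_run):
        matrix, annotation, truth, config, result = planted_run
        rng = np.random.default_rng(0)
        shuffled = matrix.subset_units(rng.permutation(matrix.unit_ids))
        rerun = run_bulk_xci(shuffled, annotation, config, matrix.unit_meta["stage"])
        pd.testing.assert_series_equal(rerun.classification, result.classification)

    def test_missing_required_stage_is_error(self, planted_run):
        matrix, annotation, truth, config, _ = planted_run
        bad_stages = matrix.unit_meta["stage"].replace({"EpiLC": "ESC"})
        with pytest.raises(ValidationError, match="EpiLC"):
            run_bulk_xci(matrix, annotation, config, bad_stages)

    def test_threshold_monotonicity_in_inactive_calls(self, planted_run):
        matrix, annotation, truth, config, _ = planted_run
        inactive_sets = []
        for threshold in (0.05, 0.135, 0.30):
            cfg = PipelineConfig(xci_threshold=threshold)
            res = run_bulk_xci(matrix, annotation, cfg, matrix.unit_meta["stage"])
            inactive = set(
                res.classification.index[
                    res.classification.isin(["earlyXCI", "lateXCI"])
                ]
            )
            inactive_sets.append(inactive)
        assert inactive_sets[0] <= inactive_sets[1] <= inactive_sets[2]
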