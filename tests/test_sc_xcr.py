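"""Single-cell QC gates, normalisation, profiling and the full chain."""

import numpy as np
import pandas as pd
import pytest

from xkin import (
    PipelineConfig,
    ValidationError,
    ParameterError,
    allelic_cell_qc,
    classify_cell_xstatus,
    generate_e65,
    generate_sc,
    informative_genes,
    lognormalize,
    nonallelic_cell_qc,
    per_cell_avg_ratio,
    pluripotency_score,
    run_e65,
    run_sc_xcr,
    subset_by_markers,
)
from xkin.sc_xcr import cell_allelic_stats, cell_nonallelic_stats


def _stats(rows, columns):
    return pd.DataFrame(rows, columns=columns, index=[f"c{i}" for i in range(len(rows))])


class TestNonallelicQC:
    @pytest.mark.parametrize(
        "genes,molecules,mito,keep",
        [
            (3999, 20000, 0.01, False),  # one gene short
            (4000, 10000, 0.05, True),   # every boundary kept
            (8000, 9999, 0.01, False),
            (8000, 50000, 0.051, False),
            (8000, 50000, 0.05, True),
        ],
    )
    def test_invitro_boundaries(self, genes, molecules, mito, keep):
        stats = _stats(
            [[genes, molecules, mito]],
            ["n_genes_detected", "n_molecules", "mito_fraction"],
        )
        assert nonallelic_cell_qc(stats, "invitro_sc").iloc[0] == keep

    def test_invivo_profile_uses_relaxed_gates(self):
        stats = _stats(
            [[2000, 2000, 0.01]],
            ["n_genes_detected", "n_molecules", "mito_fraction"],
        )
        assert not nonallelic_cell_qc(stats, "invitro_sc").iloc[0]
        assert nonallelic_cell_qc(stats, "invivo_germ").iloc[0]


class TestLognormalize:
    def test_counts_per_scale_arithmetic(self):
        counts = pd.DataFrame({"c1": [1, 9999]}, index=["g1", "g2"])
        norm = lognormalize(counts, scale=10_000)
        assert norm.loc["g1", "c1"] == pytest.approx(1.0)  # log2(1 + 1)
        assert lognormalize(pd.DataFrame({"c": [0, 5]})).iloc[0, 0] == 0.0

    def test_depth_invariance(self):
        counts = pd.DataFrame({"c1": [3, 7], "c2": [6, 14]}, index=["g1", "g2"])
        norm = lognormalize(counts)
        assert np.allclose(norm["c1"], norm["c2"])

    def test_zero_total_cell_is_error(self):
        with pytest.raises(ValidationError, match="zero total"):
            lognormalize(pd.DataFrame({"c1": [0, 0]}))


class TestMarkerSubsetting:
    def _norm(self, dazl, gata4=0.0):
        return pd.DataFrame({"cell": [dazl, gata4]}, index=["Dazl", "Gata4"])

    def test_include_is_strictly_greater(self):
        assert len(subset_by_markers(self._norm(1.0), include={"Dazl": 1})) == 0
        assert len(subset_by_markers(self._norm(1.2), include={"Dazl": 1})) == 1

    def test_exclude_is_strictly_less(self):
        kept = subset_by_markers(
            self._norm(2.0, 0.5), include={"Dazl": 1}, exclude={"Gata4": 0.5}
        )
        assert len(kept) == 0

    def test_absent_marker_names_gene(self):
        with pytest.raises(ValidationError, match="Nr5a1"):
            subset_by_markers(self._norm(2.0), include={"Nr5a1": 0.5})


class TestAllelicCellQC:
    @pytest.mark.parametrize(
        "reads,genes,minor,keep",
        [
            (3500, 30, 0.10, False),  # "more than 3,500" is strict
            (3600, 25, 0.03, True),   # "a minimum of" is inclusive
            (3600, 24, 0.10, False),
            (3600, 30, 0.029, False),
        ],
    )
    def test_invitro_boundaries(self, reads, genes, minor, keep):
        stats = _stats(
            [[reads, genes, minor]],
            ["total_allelic_reads", "n_allelic_genes", "minor_genotype_fraction"],
        )
        assert allelic_cell_qc(stats, "invitro_sc").iloc[0] == keep

    @pytest.mark.parametrize(
        "reads,genes,keep", [(400, 25, False), (401, 25, True), (401, 24, False)]
    )
    def test_e65_profile_has_no_genotype_gate(self, reads, genes, keep):
        stats = _stats(
            [[reads, genes, 0.0]],  # zero minor fraction must not drop e65 cells
            ["total_allelic_reads", "n_allelic_genes", "minor_genotype_fraction"],
        )
        assert allelic_cell_qc(stats, "e65_sc").iloc[0] == keep

    def test_unknown_profile_is_error(self):
        stats = _stats(
            [[5000, 30, 0.1]],
            ["total_allelic_reads", "n_allelic_genes", "minor_genotype_fraction"],
        )
        with pytest.raises(ParameterError, match="unknown QC profile"):
            allelic_cell_qc(stats, "bogus")


class TestInformativeGenes:
    def _layers(self, totals_per_gene, detected_cells, n_cells=4):
        genes = [f"g{i}" for i in range(len(totals_per_gene))]
        a1 = pd.DataFrame(0, index=genes, columns=[f"c{i}" for i in range(n_cells)])
        for g, total, k in zip(genes, totals_per_gene, detected_cells):
            per_cell = [total // k] * k
            per_cell[0] += total - sum(per_cell)
            a1.loc[g, a1.columns[:k]] = per_cell
        a2 = a1 * 0
        return a1, a2

    def test_read_sum_strictly_above_ten(self):
        a1, a2 = self._layers([10, 11], [4, 4])
        kept = informative_genes(a1, a2, "invitro_sc")
        assert list(kept) == ["g1"]

    def test_detection_fraction_inclusive(self):
        a1, a2 = self._layers([100, 100], [1, 2], n_cells=8)
        # 1/8 cells < 25%; 2/8 cells = 25% exactly
        kept = informative_genes(a1, a2, "invitro_sc")
        assert list(kept) == ["g1"]
        kept_e65 = informative_genes(a1, a2, "e65_sc")  # 20% gate: 2/8 passes too
        assert list(kept_e65) == ["g1"]

    def test_empty_cell_set_is_error(self):
        a1 = pd.DataFrame(index=["g1"], columns=[], dtype=int)
        with pytest.raises(ValidationError):
            informative_genes(a1, a1, "invitro_sc")


class TestPerCellAvgRatio:
    def _layers(self, pairs):
        genes = [f"g{i}" for i in range(len(pairs))]
        a1 = pd.DataFrame({"cell": [p[0] for p in pairs]}, index=genes)
        a2 = pd.DataFrame({"cell": [p[1] for p in pairs]}, index=genes)
        return a1, a2, genes

    def test_single_gene(self):
        a1, a2, genes = self._layers([(6, 4)])
        assert per_cell_avg_ratio(a1, a2, genes)["cell"] == pytest.approx(0.6)

    def test_unweighted_mean_of_gene_ratios(self):
        a1, a2, genes = self._layers([(2, 8), (6, 4)])
        assert per_cell_avg_ratio(a1, a2, genes)["cell"] == pytest.approx(0.4)

    def test_unweighted_differs_from_pooled(self):
        a1, a2, genes = self._layers([(1, 9), (90, 10)])
        unweighted = per_cell_avg_ratio(a1, a2, genes)["cell"]
        pooled = per_cell_avg_ratio(a1, a2, genes, weighted=True)["cell"]
        assert unweighted == pytest.approx(0.5)
        assert pooled == pytest.approx(91 / 110)

    def test_undetected_cell_is_nan(self):
        a1, a2, genes = self._layers([(0, 0)])
        assert np.isnan(per_cell_avg_ratio(a1, a2, genes)["cell"])


class TestCellXStatus:
    @pytest.mark.parametrize(
        "ratio,status",
        [
            (0.50, "XaXa"),
            (0.65, "XiXa"),
            (0.35, "XaXi"),
            (0.40, "XaXa"),  # closed window
            (0.60, "XaXa"),
            (np.nan, "NA"),
        ],
    )
    def test_windows(self, ratio, status):
        assert classify_cell_xstatus(ratio) == status

    def test_mirror_swaps_inactive_states(self):
        for r in (0.1, 0.35, 0.45, 0.5, 0.62, 0.9):
            direct = classify_cell_xstatus(r)
            mirrored = classify_cell_xstatus(1 - r)
            swap = {"XaXi": "XiXa", "XiXa": "XaXi", "XaXa": "XaXa"}
            assert mirrored == swap[direct]


class TestPluripotencyScore:
    GENES = ("Pou5f1", "Sox2")

    def test_constant_genes_score_zero(self):
        norm = pd.DataFrame(1.0, index=list(self.GENES), columns=["c1", "c2"])
        assert np.allclose(pluripotency_score(norm, self.GENES), 0.0)

    def test_one_sd_above_mean_scores_one(self):
        norm = pd.DataFrame(
            {"c1": [0.0, 0.0], "c2": [2.0, 2.0]}, index=list(self.GENES)
        )
        scores = pluripotency_score(norm, self.GENES)
        assert scores["c2"] == pytest.approx(1.0)
        assert scores["c1"] == pytest.approx(-1.0)

    def test_gene_order_invariance_and_missing_warn(self):
        norm = pd.DataFrame(
            {"c1": [0.0, 1.0], "c2": [2.0, 3.0]}, index=list(self.GENES)
        )
        s1 = pluripotency_score(norm, self.GENES)
        s2 = pluripotency_score(norm, self.GENES[::-1])
        pd.testing.assert_series_equal(s1, s2)
        with pytest.warns(UserWarning, match="skipped"):
            pluripotency_score(norm, self.GENES + ("Nanog",))
        with pytest.raises(ValidationError):
            pluripotency_score(norm, ("Nanog",))


@pytest.fixture(scope="module")
def sc_run():
    matrix, annotation, truth = generate_sc(
        n_cells_per_cluster={c: 30 for c in
                             ["Mitotic1", "Mitotic2", "PreMeiotic1",
                              "PreMeiotic2", "Meiotic"]},
        n_per_xcr_category={"escapee": 20, "earlyXCR": 10, "lateXCR": 6, "noXCR": 4},
        frac_qc_fail=0.2,
        n_somatic=5,
        seed=21,
    )
    config = PipelineConfig(qc_profile="invitro_sc")
    result = run_sc_xcr(
        matrix, annotation, config, matrix.unit_meta["cluster"],
        truth.bulk_reference_ratios,
        macro_groups={**{c: "mitotic" for c in ["Mitotic1", "Mitotic2"]},
                      **{c: "premeiotic" for c in ["PreMeiotic1", "PreMeiotic2"]},
                      "Meiotic": "meiotic", "Somatic": "mitotic"},
    )
    return matrix, truth, result


class TestFullChain:
    def test_every_cell_lands_in_exactly_one_bin(self, sc_run):
        matrix, truth, result = sc_run
        assert set(result.qc_bin.index) == set(matrix.unit_ids)
        assert set(result.qc_bin.unique()) <= {
            "nonallelic_qc_fail", "marker_fail", "allelic_qc_fail", "profiled"
        }
        profiled = result.qc_bin.index[result.qc_bin == "profiled"]
        assert set(profiled) == set(result.cell_profiles.index)

    def test_somatic_contaminants_removed_at_marker_gate(self, sc_run):
        matrix, truth, result = sc_run
        somatic = truth.cell_truth.index[truth.cell_truth["is_somatic"]]
        assert (result.qc_bin.loc[somatic] == "marker_fail").all()

    def test_planted_qc_failures_are_exactly_the_dropped_cells(self, sc_run):
        matrix, truth, result = sc_run
        planted = set(truth.cell_truth.index[truth.cell_truth["qc_should_fail"]])
        dropped = set(result.qc_bin.index[result.qc_bin == "allelic_qc_fail"])
        assert planted == dropped

    def test_category_recovery(self, sc_run):
        _, truth, result = sc_run
        assert result.summary == {
            "escapee": 20, "earlyXCR": 10, "lateXCR": 6, "noXCR": 4, "unclassified": 0
        }

    def test_cluster_fractions_sum_to_one(self, sc_run):
        *_, result = sc_run
        sums = result.cluster_summary[
            ["xaxa_fraction", "xaxi_fraction", "xixa_fraction"]
        ].sum(axis=1)
        assert np.allclose(sums, 1.0)

    def test_cell_order_permutation_invariance(self, sc_run):
        matrix, truth, result = sc_run
        rng = np.random.default_rng(2)
        shuffled = matrix.subset_units(rng.permutation(matrix.unit_ids))
        rerun = run_sc_xcr(
            shuffled, *_sc_args(truth),
        )
        pd.testing.assert_series_equal(
            rerun.classification.sort_index(), result.classification.sort_index()
        )
        pd.testing.assert_frame_equal(
            rerun.cell_profiles.sort_index(), result.cell_profiles.sort_index()
        )


def _sc_args(truth):
    # helper re-creating the fixed arguments of the class fixture above
    from xkin.synthetic_data import generate_sc as _  # noqa: F401

    matrix, annotation, truth2 = generate_sc(
        n_cells_per_cluster={c: 30 for c in
                             ["Mitotic1", "Mitotic2", "PreMeiotic1",
                              "PreMeiotic2", "Meiotic"]},
        n_per_xcr_category={"escapee": 20, "earlyXCR": 10, "lateXCR": 6, "noXCR": 4},
        frac_qc_fail=0.2,
        n_somatic=5,
        seed=21,
    )
    config = PipelineConfig(qc_profile="invitro_sc")
    return (
        annotation, config, matrix.unit_meta["cluster"], truth2.bulk_reference_ratios,
        {**{c: "mitotic" for c in ["Mitotic1", "Mitotic2"]},
         **{c: "premeiotic" for c in ["PreMeiotic1", "PreMeiotic2"]},
         "Meiotic": "meiotic", "Somatic": "mitotic"},
    )


class TestE65Mode:
    def test_imprinted_cluster_fully_xaxi_at_zero_overdispersion(self):
        matrix, annotation, truth = generate_e65(
            n_cells_per_cluster={"aVE": 40, "proxEpi": 40},
            escapee_fraction_xaxi=0.05,
            bb_overdispersion=0.0,
            seed=4,
        )
        config = PipelineConfig(qc_profile="e65_sc")
        result = run_e65(matrix, annotation, config, matrix.unit_meta["cluster"])
        assert result.cluster_summary.loc["aVE", "xixa_fraction"] == 0.0
        assert result.cluster_summary.loc["aVE", "xaxa_fraction"] == 0.0
        assert result.cluster_summary.loc["aVE", "xaxi_fraction"] == 1.0

    def test_bad_fraction_rejected(self):
        with pytest.raises(ParameterError, match="fraction"):
            generate_e65(epiblast_xaxa_fraction=1.5)
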