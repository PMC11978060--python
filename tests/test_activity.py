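"""Size factors, activity transforms, and promoter classification."""

import numpy as np
import pandas as pd
import pytest

from promdyn import (
    ActivityNormalizer,
    build_promoters,
    classify_promoters,
    compute_activity,
    flag_internal,
    multi_active_genes,
    size_factors,
    top_variance_promoters,
)
from promdyn.activity import absolute_activity, gene_expression, relative_activity

from conftest import tm


def counts_df(data, samples=None):
    df = pd.DataFrame(data).T if isinstance(data, dict) else pd.DataFrame(data)
    if samples is not None:
        df.columns = samples
    return df.astype(float)


class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self):
        counts = counts_df({"p1": [10, 10], "p2": [50, 50]}, ["a", "b"])
        np.testing.assert_allclose(size_factors(counts), [1.0, 1.0])

    def test_doubled_column_hand_computed(self):
        # column b = 2a elementwise: reference = a*sqrt(2),
        # ratios a/(a*sqrt 2) = 1/sqrt2 and 2a/(a*sqrt2) = sqrt2
        counts = counts_df({"p1": [10, 20], "p2": [7, 14], "p3": [100, 200]}, ["a", "b"])
        np.testing.assert_allclose(
            size_factors(counts), [1 / np.sqrt(2), np.sqrt(2)], rtol=1e-12
        )

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError, match="at least 2 samples"):
            size_factors(counts_df({"p1": [10]}, ["a"]))

    def test_no_all_positive_promoter_rejected(self):
        counts = counts_df({"p1": [0, 5], "p2": [5, 0]}, ["a", "b"])
        with pytest.raises(ValueError, match="pseudo-reference"):
            size_factors(counts)

    def test_matches_pydeseq2_median_of_ratios(self):
        """Independent oracle: DESeq2's size factors as implemented in pydeseq2."""
        pydeseq2 = pytest.importorskip("pydeseq2.preprocessing")
        rng = np.random.default_rng(5)
        mat = rng.poisson(rng.uniform(20, 200, size=(60, 1)), size=(60, 8)).astype(float)
        mat *= rng.uniform(0.5, 2.0, size=8)  # planted depth differences
        counts = pd.DataFrame(mat, columns=[f"s{i}" for i in range(8)])
        ours = size_factors(counts).to_numpy()
        # pydeseq2 expects samples x genes
        _, theirs = pydeseq2.deseq2_norm(counts.T)
        np.testing.assert_allclose(ours, np.asarray(theirs, dtype=float), rtol=1e-10)

    def test_scale_invariance_of_activity(self):
        """Scaling one sample's counts by c scales its factor by c relative
        to every other sample; with many samples the self-referential shift
        of the geometric-mean reference is negligible and that sample's
        activities are stable within 1% (counts >= 100)."""
        rng = np.random.default_rng(0)
        cols = [f"s{i}" for i in range(16)]
        counts = pd.DataFrame(
            rng.poisson(500, size=(40, 16)).astype(float) + 100, columns=cols
        )
        scaled = counts.copy()
        scaled["s1"] *= 2.0
        f0, f1 = size_factors(counts), size_factors(scaled)
        rel_change = (f1 / f0)["s1"] / (f1 / f0)["s0"]
        np.testing.assert_allclose(rel_change, 2.0, rtol=1e-9)
        a0 = absolute_activity(counts, f0)
        a1 = absolute_activity(scaled, f1)
        np.testing.assert_allclose(a0["s1"], a1["s1"], rtol=0.01)


class TestNormalizerEstimatorApi:
    def test_get_set_params_and_clone(self):
        from sklearn.base import clone

        norm = ActivityNormalizer(pseudocount=2.0)
        assert clone(norm).get_params()["pseudocount"] == 2.0
        norm.set_params(pseudocount=1.0)
        assert norm.pseudocount == 1.0

    def test_fit_transform_pipeline(self):
        counts = counts_df({"p1": [10, 20], "p2": [50, 100]}, ["a", "b"])
        norm = ActivityNormalizer(gene_map=pd.Series({"p1": "g", "p2": "g"}))
        act = norm.fit_transform(counts)
        assert hasattr(norm, "size_factors_")
        np.testing.assert_allclose(
            act.to_numpy(), absolute_activity(counts, norm.size_factors_).to_numpy()
        )
        rel = norm.relative(counts)
        np.testing.assert_allclose(rel.sum(axis=0), 1.0)

    def test_unfitted_transform_raises(self):
        with pytest.raises(RuntimeError, match="not fitted"):
            ActivityNormalizer().transform(counts_df({"p": [1]}, ["a"]))

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            ActivityNormalizer().fit(counts_df({"p": [-1, 2]}, ["a", "b"]))


class TestAbsoluteActivity:
    def test_pseudocount_rule(self):
        counts = counts_df({"p": [15, 0, 31]}, ["a", "b", "c"])
        f = pd.Series([1.0, 1.0, 2.0], index=["a", "b", "c"])
        act = absolute_activity(counts, f)
        assert act.loc["p", "a"] == pytest.approx(4.0)
        assert act.loc["p", "b"] == 0.0
        assert act.loc["p", "c"] == pytest.approx(np.log2(16.5))

    def test_missing_counts_stay_missing(self):
        counts = counts_df({"p": [np.nan, 4]}, ["a", "b"])
        act = absolute_activity(counts, pd.Series([1.0, 1.0], index=["a", "b"]))
        assert np.isnan(act.loc["p", "a"]) and act.loc["p", "b"] == pytest.approx(np.log2(5))

    def test_strictly_increasing_in_count(self):
        f = pd.Series([1.0], index=["a"])
        vals = [
            absolute_activity(counts_df({"p": [c]}, ["a"]), f).iloc[0, 0]
            for c in range(0, 50)
        ]
        assert all(b > a for a, b in zip(vals, vals[1:]))


class TestGeneAndRelative:
    gene_map = pd.Series({"p1": "g", "p2": "g"})

    def test_gene_expression_sums_linear_counts(self):
        counts = counts_df({"p1": [15], "p2": [16]}, ["a"])
        f = pd.Series([1.0], index=["a"])
        ge = gene_expression(counts, f, self.gene_map)
        assert ge.loc["g", "a"] == pytest.approx(5.0)  # log2(15+16+1)

    def test_single_promoter_gene_equals_promoter_activity(self):
        gm = pd.Series({"p1": "g"})
        counts = counts_df({"p1": [15]}, ["a"])
        f = pd.Series([1.0], index=["a"])
        assert gene_expression(counts, f, gm).loc["g", "a"] == pytest.approx(
            absolute_activity(counts, f).loc["p1", "a"]
        )

    def test_all_zero_gene_is_zero_expression_missing_fractions(self):
        counts = counts_df({"p1": [0], "p2": [0]}, ["a"])
        f = pd.Series([1.0], index=["a"])
        assert gene_expression(counts, f, self.gene_map).loc["g", "a"] == 0.0
        rel = relative_activity(counts, f, self.gene_map)
        assert rel["a"].isna().all()

    def test_relative_fractions(self):
        counts = counts_df({"p1": [30], "p2": [10]}, ["a"])
        f = pd.Series([1.0], index=["a"])
        rel = relative_activity(counts, f, self.gene_map)
        assert rel.loc["p1", "a"] == pytest.approx(0.75)
        assert rel.loc["p2", "a"] == pytest.approx(0.25)

    def test_relative_sums_to_one_on_simulation(self, sim_pipeline):
        am = sim_pipeline.am
        gm = sim_pipeline.catalog.gene_map()
        sums = am.relative.groupby(gm.reindex(am.relative.index)).sum(min_count=1)
        expressed = sums.stack().dropna()
        np.testing.assert_allclose(expressed.to_numpy(), 1.0, atol=1e-9)


@pytest.fixture(scope="module")
def sim_pipeline(sim_data):
    """Activity matrix over the default synthetic study."""
    from promdyn import assign_junctions, count_promoter_reads
    from promdyn.quantification import JunctionRecord
    from promdyn.annotation import JunctionKey
    from conftest import sj_lines_frame

    ann, sj_lines, truth = sim_data
    index = assign_junctions(ann.catalog)
    records = {
        s: [
            JunctionRecord(
                JunctionKey(r["chrom"], r["start"], r["end"], r["strand"]), r["unique"]
            )
            for _, r in sj_lines_frame(lines).iterrows()
        ]
        for s, lines in sj_lines.items()
    }
    table = count_promoter_reads(records, index)
    am = compute_activity(table.counts, ann.catalog.gene_map())
    from types import SimpleNamespace
    return SimpleNamespace(am=am, catalog=ann.catalog, truth=truth, counts=table)


def three_promoter_catalog(means_irrelevant=None):
    return flag_internal(
        build_promoters(
            [
                tm("t1", "g", "+", [(100, 200), (5000, 5100)]),
                tm("t2", "g", "+", [(1000, 1100), (5000, 5100)]),
                tm("t3", "g", "+", [(2000, 2100), (5000, 5100)]),
            ]
        )
    )


def activity_with_means(means, n=8):
    """Constant activity rows with the requested per-promoter means."""
    return pd.DataFrame(
        {f"s{i}": means for i in range(n)},
        index=[f"g:p{k+1}" for k in range(len(means))],
    ).astype(float)


class TestClassification:
    def test_major_minor_inactive(self):
        cat = three_promoter_catalog()
        labels = classify_promoters(activity_with_means([5.0, 1.0, 0.1]), cat)
        assert labels.loc["g:p1", "label"] == "major"
        assert labels.loc["g:p2", "label"] == "minor"
        assert labels.loc["g:p3", "label"] == "inactive"

    def test_all_below_threshold_no_major(self):
        cat = three_promoter_catalog()
        labels = classify_promoters(activity_with_means([0.2, 0.1, 0.05]), cat)
        assert (labels["label"] == "inactive").all()

    def test_boundary_mean_exactly_at_threshold_is_not_inactive(self):
        cat = three_promoter_catalog()
        labels = classify_promoters(activity_with_means([5.0, 0.25, 0.1]), cat)
        assert labels.loc["g:p2", "label"] == "minor"

    def test_tie_breaks_to_five_prime_most(self):
        cat = three_promoter_catalog()
        labels = classify_promoters(activity_with_means([3.0, 3.0, 0.0]), cat)
        assert labels.loc["g:p1", "label"] == "major"
        assert labels.loc["g:p2", "label"] == "minor"

    def test_exactly_one_major_per_expressed_gene(self, sim_pipeline):
        am = sim_pipeline.am
        labels = classify_promoters(am.absolute, sim_pipeline.catalog)
        per_gene = labels[labels["label"] == "major"].groupby("gene_id").size()
        expressed = labels.groupby("gene_id")["mean_activity"].max() >= 0.25
        assert set(per_gene.index) == set(expressed[expressed].index)
        assert (per_gene == 1).all()

    def test_planted_major_recovered(self, sim_pipeline):
        """Generator truth consistency: the highest-baseline promoter is
        classified major for nearly all quantifiable multi-promoter genes."""
        am = sim_pipeline.am
        truth = sim_pipeline.truth
        labels = classify_promoters(am.absolute, sim_pipeline.catalog)
        planted = truth.promoters[
            truth.promoters["is_major_planted"] & ~truth.promoters["internal"]
        ]
        planted = planted[planted.index.isin(labels.index)]
        got = labels.reindex(planted.index)["label"]
        assert (got == "major").mean() >= 0.95


class TestMultiActive:
    labels = pd.DataFrame(
        {
            "gene_id": ["g", "g"],
            "label": ["major", "minor"],
        },
        index=["g:p1", "g:p2"],
    )

    def rel(self, f1, f2):
        return pd.DataFrame({"s0": [f1, f2], "s1": [f1, f2]}, index=["g:p1", "g:p2"])

    def test_both_contributing_qualifies(self):
        assert multi_active_genes(self.labels, self.rel(0.85, 0.15)) == {"g"}

    def test_small_contribution_excluded(self):
        assert multi_active_genes(self.labels, self.rel(0.95, 0.05)) == set()

    def test_single_promoter_gene_excluded(self):
        labels = self.labels.iloc[:1]
        assert multi_active_genes(labels, self.rel(1.0, np.nan).iloc[:1]) == set()


class TestTopVariance:
    def test_matches_bruteforce_sort(self):
        rng = np.random.default_rng(3)
        act = pd.DataFrame(
            rng.normal(size=(100, 6)), index=[f"p{i}" for i in range(100)]
        )
        got = top_variance_promoters(act, 10)
        expect = list(act.var(axis=1).sort_values(ascending=False).index[:10])
        assert got == expect

    def test_constant_promoter_ranks_last(self):
        act = pd.DataFrame(
            [[1.0, 1.0, 1.0], [0.0, 5.0, 1.0]], index=["flat", "var"]
        )
        assert top_variance_promoters(act, 2) == ["var", "flat"]

    def test_n_zero_and_overflow(self):
        act = pd.DataFrame([[1.0, 2.0]], index=["p"])
        assert top_variance_promoters(act, 0) == []
        with pytest.warns(UserWarning, match="only 1"):
            assert top_variance_promoters(act, 5) == ["p"]
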