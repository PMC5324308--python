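"""RPKM, differential expression, clustering/PCA plumbing, repeat expression."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from epirepeat import (
    ExpressionMatrix,
    Genome,
    GenomicInterval,
    ReadTrack,
    RepeatAnnotation,
    TimeCourseDesign,
    ValidationError,
    compute_rpkm,
    detect_de_genes,
    filter_expressed_repeats,
    generate_expression_timecourse,
    kmeans_time_course,
    pca_time_course,
    repeat_expression,
    repeat_subfamily_fold_change,
)


def small_matrix(counts, lengths, samples=None):
    samples = samples or [f"s{i}" for i in range(np.asarray(counts).shape[1])]
    idx = pd.Index([f"g{i}" for i in range(len(lengths))], name="gene_id")
    return ExpressionMatrix(
        counts=pd.DataFrame(counts, index=idx, columns=samples),
        lengths=pd.Series(lengths, index=idx),
    )


class TestRpkm:
    def test_formula(self):
        m = small_matrix([[100], [999_900]], [2000, 1000])
        rpkm = compute_rpkm(m)
        assert rpkm.iloc[0, 0] == pytest.approx(50.0)

    def test_zero_counts_zero_rpkm(self):
        m = small_matrix([[0], [10]], [1000, 1000])
        assert compute_rpkm(m).iloc[0, 0] == 0.0

    def test_hand_computed_3x2(self):
        counts = np.array([[10, 40], [20, 10], [70, 50]])
        lengths = np.array([500, 2000, 1000])
        m = small_matrix(counts, lengths)
        rpkm = compute_rpkm(m)
        libs = counts.sum(axis=0)
        for i in range(3):
            for j in range(2):
                expect = counts[i, j] / (lengths[i] / 1000) / (libs[j] / 1e6)
                assert rpkm.iloc[i, j] == pytest.approx(expect, rel=1e-12)

    def test_zero_library_is_error(self):
        m = small_matrix([[0], [0]], [1000, 1000])
        with pytest.raises(ValidationError):
            compute_rpkm(m)


class TestDetectDe:
    def test_low_expression_gene_excluded_from_testing(self):
        # gene g0 at RPKM ~1 in both conditions is excluded; g1 carries depth
        counts = np.array([[1, 1], [999_999, 999_999]])
        m = small_matrix(counts, [1000, 1000], ["a", "b"])
        de = detect_de_genes(m, ["a"], ["b"])
        assert not de.loc["g0", "tested"]
        assert np.isnan(de.loc["g0", "p_value"])

    def test_fourfold_gene_matches_exact_binomial(self):
        counts = np.array([[400, 100], [99_600, 99_900]])
        m = small_matrix(counts, [1000, 5000], ["a", "b"])
        de = detect_de_genes(m, ["a"], ["b"])
        assert de.loc["g0", "log2_fold_change"] == pytest.approx(-2.0, abs=0.05)
        expect_p = min(1.0, 2 * min(stats.binom.cdf(400, 500, 0.5),
                                    stats.binom.sf(399, 500, 0.5)))
        assert de.loc["g0", "p_value"] == pytest.approx(expect_p, rel=1e-9)
        assert de.loc["g0", "is_de"]

    def test_equal_counts_not_de(self):
        counts = np.array([[500, 500], [10_000, 10_000]])
        m = small_matrix(counts, [1000, 1000], ["a", "b"])
        de = detect_de_genes(m, ["a"], ["b"])
        assert not de["is_de"].any()

    def test_empty_group_is_error(self):
        m = small_matrix([[1, 1]], [1000], ["a", "b"])
        with pytest.raises(ValidationError):
            detect_de_genes(m, [], ["b"])

    def test_type_one_error_control_under_mild_overdispersion(self):
        """With no planted effects and near-Poisson noise, the pooled
        binomial test calls essentially no DE genes at FDR 0.001."""
        hits = 0
        for seed in range(10):
            matrix, design, _ = generate_expression_timecourse(
                n_genes=5000, de_fraction=0.0, accel_fraction=0.0,
                dispersion=0.01, seed=seed,
            )
            de = detect_de_genes(
                matrix,
                design.samples(genotype="control", stage="ESC"),
                design.samples(genotype="knockdown", stage="ESC"),
            )
            if de["is_de"].sum() <= 5:
                hits += 1
        assert hits >= 9

    def test_planted_fourfold_recovery(self, default_dataset):
        """Planted 4-fold genes at healthy expression are recovered at the
        ES-cell comparison with sensitivity >= 0.9."""
        ds = default_dataset
        de = detect_de_genes(
            ds.expression,
            ds.design.samples(genotype="control", stage="ESC"),
            ds.design.samples(genotype="knockdown", stage="ESC"),
        )
        called = set(de.index[de["is_de"]])
        planted = [
            g for g in ds.truth.de_gene_ids
            if max(de.loc[g, "rpkm_a"], de.loc[g, "rpkm_b"]) >= 10
        ]
        sens = np.mean([g in called for g in planted])
        assert sens >= 0.9


class TestClusteringPca:
    def test_two_planted_patterns_recovered_exactly(self):
        rng = np.random.default_rng(0)
        up = 2.0 ** np.arange(5) * 10
        down = up[::-1]
        rows = [up * rng.lognormal(0, 0.05, 5) for _ in range(40)]
        rows += [down * rng.lognormal(0, 0.05, 5) for _ in range(40)]
        rpkm = pd.DataFrame(rows, index=[f"g{i}" for i in range(80)])
        labels, _ = kmeans_time_course(rpkm, k=2, seed=0)
        truth = [0] * 40 + [1] * 40
        assert adjusted_rand_score(truth, labels) == pytest.approx(1.0)

    def test_k1_single_cluster_and_determinism(self):
        rng = np.random.default_rng(1)
        rpkm = pd.DataFrame(rng.lognormal(2, 1, (30, 4)))
        l1, _ = kmeans_time_course(rpkm, k=1, seed=0)
        assert set(l1) == {0}
        a, _ = kmeans_time_course(rpkm, k=3, seed=5)
        b, _ = kmeans_time_course(rpkm, k=3, seed=5)
        assert (a == b).all()
        with pytest.raises(ValidationError):
            kmeans_time_course(rpkm, k=0)

    def make_design(self, samples):
        table = pd.DataFrame(
            dict(genotype=["control"] * len(samples), stage=["ESC"] * len(samples)),
            index=pd.Index(samples, name="sample_id"),
        )
        return TimeCourseDesign(table, ["ESC"])

    def test_duplicated_samples_identical_coordinates(self):
        rng = np.random.default_rng(2)
        x = rng.lognormal(2, 1, (50, 1))
        rpkm = pd.DataFrame(np.hstack([x, x, x + rng.lognormal(0, 1, (50, 1))]),
                            columns=["a", "b", "c"])
        coords = pca_time_course(rpkm, self.make_design(["a", "b", "c"]))
        np.testing.assert_allclose(coords.loc["a"], coords.loc["b"], atol=1e-9)

    def test_pc1_separates_two_sample_types(self):
        rng = np.random.default_rng(3)
        base = rng.lognormal(3, 1, 100)
        type_a = [base * rng.lognormal(0, 0.05, 100) for _ in range(3)]
        type_b = [base * rng.lognormal(2, 0.05, 100) * rng.lognormal(0, 0.05, 100)
                  for _ in range(3)]
        rpkm = pd.DataFrame(np.column_stack(type_a + type_b),
                            columns=[f"s{i}" for i in range(6)])
        coords = pca_time_course(rpkm, self.make_design(list(rpkm.columns)))
        pc1 = coords["PC1"]
        assert (pc1.iloc[:3].max() < pc1.iloc[3:].min()) or (
            pc1.iloc[:3].min() > pc1.iloc[3:].max()
        )

    def test_two_components_reconstruct_rank_two_input(self):
        rng = np.random.default_rng(4)
        u = rng.normal(size=(40, 2))
        v = rng.normal(size=(2, 6))
        x = u @ v  # log-space rank-2 signal
        x -= x.min()
        rpkm = pd.DataFrame(2.0**x - 1.0)  # so log2(rpkm + 1) == x exactly
        from sklearn.decomposition import PCA

        logx = np.log2(rpkm.to_numpy() + 1.0).T
        pca = PCA(n_components=2, svd_solver="full").fit(logx)
        recon = pca.inverse_transform(pca.transform(logx))
        np.testing.assert_allclose(recon, logx, atol=1e-8)

    def test_constant_matrix_is_error(self):
        rpkm = pd.DataFrame(np.ones((10, 4)), columns=list("abcd"))
        with pytest.raises(ValidationError):
            pca_time_course(rpkm, self.make_design(list("abcd")))


@pytest.fixture()
def repeat_setup():
    genome = Genome([("chr1", 100_000)])
    rows = []
    for i in range(10):
        rows.append(dict(chrom="chr1", start=i * 5000, end=i * 5000 + 1000,
                         element_id=f"L1|{i}", strand="+", repeat_class="LINE",
                         repeat_family="L1", repeat_name="L1Md_T"))
    for i in range(10):
        rows.append(dict(chrom="chr1", start=60_000 + i * 2000, end=60_000 + i * 2000 + 1000,
                         element_id=f"IAP|{i}", strand="+", repeat_class="LTR",
                         repeat_family="ERVK", repeat_name="IAPEz-int"))
    return genome, RepeatAnnotation(pd.DataFrame(rows), genome=genome)


class TestRepeatExpression:
    def test_no_reads_all_zero(self, repeat_setup):
        genome, ann = repeat_setup
        track = ReadTrack({}, genome, library_size=1000)
        per_element, agg = repeat_expression(track, ann)
        assert (per_element == 0).all()
        assert (agg["rpbm"] == 0).all()

    def test_uniform_reads_give_equal_label_densities(self, repeat_setup):
        genome, ann = repeat_setup
        track = ReadTrack({"chr1": np.arange(0, 100_000, 3)}, genome, read_length=1)
        _, agg = repeat_expression(track, ann)
        classes = agg[agg["level"] == "class"].set_index("key")["rpbm"]
        assert abs(classes["LINE"] / classes["LTR"] - 1) < 0.2

    def test_aggregate_matches_brute_force_count(self, repeat_setup):
        genome, ann = repeat_setup
        rng = np.random.default_rng(7)
        pos = np.sort(rng.integers(0, 99_000, 5000))
        rl = 36
        track = ReadTrack({"chr1": pos}, genome, read_length=rl)
        _, agg = repeat_expression(track, ann)
        row = agg[(agg["level"] == "name") & (agg["key"] == "L1Md_T")].iloc[0]
        naive = 0
        for r in ann.table.itertuples():
            if r.repeat_name != "L1Md_T":
                continue
            naive += sum(1 for p in pos if p < r.end and p + rl > r.start)
        assert row["reads"] == naive

    def test_filter_is_strictly_greater(self, repeat_setup):
        genome, ann = repeat_setup
        ids = ann.table["element_id"]
        rpbm = pd.Series(0.003, index=ids)
        rpbm.iloc[0] = 0.0031
        kept = filter_expressed_repeats(rpbm, ann, threshold=0.003)
        assert len(kept) == 1 and kept[0].name == ids.iloc[0]
        assert len(filter_expressed_repeats(pd.Series(0.0, index=ids), ann)) == 0
        with_read = pd.Series(0.001, index=ids)
        assert len(filter_expressed_repeats(with_read, ann, threshold=0.0)) == len(ids)

    def test_fold_change_identity_and_reciprocity(self, repeat_setup):
        genome, ann = repeat_setup
        rng = np.random.default_rng(8)
        a = ReadTrack({"chr1": np.sort(rng.integers(0, 99_000, 4000))}, genome)
        b = ReadTrack({"chr1": np.sort(rng.integers(0, 99_000, 4000))}, genome)
        same = repeat_subfamily_fold_change(a, a, ann)
        np.testing.assert_allclose(same["fold_change"], 1.0, atol=1e-12)
        fwd = repeat_subfamily_fold_change(a, b, ann)["fold_change"]
        rev = repeat_subfamily_fold_change(b, a, ann)["fold_change"]
        np.testing.assert_allclose((fwd * rev).to_numpy(), 1.0, rtol=0.02)

    def test_single_planted_fifty_fold_measured(self):
        """One subfamily de-repressed 50x is measured near 50 when the
        library is dominated by non-repeat reads."""
        from epirepeat import generate_genome, generate_repeat_annotation, \
            generate_rna_repeat_reads
        from epirepeat.simulate import SubfamilyConfig

        genome = generate_genome()
        config = [
            SubfamilyConfig("MMETn-int", "ERVK", "LTR", 80, 2000),
            SubfamilyConfig("B1_Mm", "Alu", "SINE", 200, 150),
        ]
        ann = generate_repeat_annotation(genome, config, seed=1)
        ctrl, kd = generate_rna_repeat_reads(
            genome, ann, {"MMETn-int": 50.0}, seed=1
        )
        fc = repeat_subfamily_fold_change(ctrl, kd, ann)
        assert 35 <= fc.loc["MMETn-int", "fold_change"] <= 65
        assert fc.index[0] == "MMETn-int"
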