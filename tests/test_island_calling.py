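"""Island calling, RPBM density, differential islands, profiles, ECDFs."""
import numpy as np
import pytest
from scipy import stats

from epirepeat import (
    Genome,
    GenomicInterval,
    IntervalSet,
    ReadTrack,
    ValidationError,
    average_profile,
    call_islands,
    compute_rpbm,
    differential_islands,
    fold_change_ecdf,
    generate_chip_tracks,
    generate_genome,
    plant_islands,
)


@pytest.fixture(scope="module")
def mb_genome():
    return Genome([("chr1", 1_000_000)])


def jaccard(a, b):
    inter = max(0, min(a.end, b.end) - max(a.start, b.start))
    return inter / (a.length + b.length - inter)


class TestRpbm:
    def test_formula(self, mb_genome):
        track = ReadTrack(
            {"chr1": np.arange(1000, 1010)}, mb_genome, read_length=1, library_size=10**6
        )
        iv = GenomicInterval("chr1", 1000, 1100)
        assert compute_rpbm(track, iv) == pytest.approx(0.1)

    def test_empty_track_is_zero(self, mb_genome):
        track = ReadTrack({}, mb_genome, library_size=1000)
        assert compute_rpbm(track, GenomicInterval("chr1", 0, 100)) == 0.0

    def test_doubling_library_halves_density(self, mb_genome):
        pos = {"chr1": np.arange(0, 5000, 13)}
        iv = GenomicInterval("chr1", 100, 2000)
        t1 = ReadTrack(pos, mb_genome, library_size=10_000)
        t2 = ReadTrack(pos, mb_genome, library_size=20_000)
        assert compute_rpbm(t1, iv) == pytest.approx(2 * compute_rpbm(t2, iv))

    def test_matches_linear_scan_oracle(self, mb_genome):
        rng = np.random.default_rng(0)
        for _ in range(30):
            pos = np.sort(rng.integers(0, 999_000, size=500))
            rl = int(rng.integers(1, 100))
            track = ReadTrack({"chr1": pos}, mb_genome, read_length=rl)
            s = int(rng.integers(0, 990_000))
            iv = GenomicInterval("chr1", s, s + int(rng.integers(50, 5000)))
            naive = sum(1 for p in pos if p < iv.end and p + rl > iv.start)
            expect = naive / iv.length / (track.library_size / 1e6)
            assert compute_rpbm(track, iv) == pytest.approx(expect, abs=1e-15)


class TestCallIslands:
    def test_empty_chip_gives_no_islands(self, mb_genome):
        chip = ReadTrack({}, mb_genome)
        inp = ReadTrack({"chr1": np.arange(0, 10_000, 7)}, mb_genome)
        assert call_islands(chip, inp) == []

    def test_invalid_parameters(self, mb_genome):
        t = ReadTrack({"chr1": np.array([10])}, mb_genome)
        with pytest.raises(ValidationError):
            call_islands(t, t, window_bp=0)
        with pytest.raises(ValidationError):
            call_islands(t, t, gap_bp=-1)

    def test_null_background_yields_at_most_two_islands(self, mb_genome):
        """ChIP identical in distribution to scaled Input (0.25 reads per
        200 bp window) should produce essentially no islands at FDR 0.001."""
        rng = np.random.default_rng(12)
        def track():
            n = rng.poisson(1250)
            return ReadTrack({"chr1": rng.integers(0, 999_964, n)}, mb_genome)
        assert len(call_islands(track(), track())) <= 2

    def test_single_planted_island_recovered(self, mb_genome):
        """A lone 1 kb region at 10x background density is called as exactly
        one island that overlaps the planted region well."""
        planted = IntervalSet(
            [GenomicInterval("chr1", 500_000, 501_000, name="planted")], genome=mb_genome
        )
        ctrl, _, inp = generate_chip_tracks(
            mb_genome, planted, enrichment_fold=10, background_rate=0.00125, seed=0
        )
        calls = call_islands(ctrl, inp)
        assert len(calls) == 1
        assert jaccard(calls[0].interval, planted[0]) >= 0.5

    def test_qvalues_dominate_pvalues(self, mb_genome):
        planted, _ = plant_islands(mb_genome, n_islands=5, island_length=1000, seed=3)
        ctrl, _, inp = generate_chip_tracks(
            mb_genome, planted, enrichment_fold=10, background_rate=0.005, seed=3
        )
        calls = call_islands(ctrl, inp)
        assert calls
        for c in calls:
            assert c.q_value >= c.p_value
            assert c.chip_count >= 0 and c.input_count >= 0


class TestDifferentialIslands:
    def make_tracks(self, mb_genome, count_a, count_b, lib=100_000):
        islands = IntervalSet([GenomicInterval("chr1", 1000, 2000)], genome=mb_genome)
        a = ReadTrack({"chr1": np.linspace(1000, 1999, count_a).astype(int)},
                      mb_genome, library_size=lib)
        b = ReadTrack({"chr1": np.linspace(1000, 1999, count_b).astype(int)},
                      mb_genome, library_size=lib)
        return islands, a, b

    def test_twofold_drop_matches_exact_binomial(self, mb_genome):
        islands, a, b = self.make_tracks(mb_genome, 100, 50)
        (d,) = differential_islands(islands, a, b)
        expect_p = 2 * stats.binom.sf(99, 150, 0.5)
        assert d.p_value == pytest.approx(expect_p, rel=1e-12)
        assert d.q_value < 0.001
        assert d.log2_fold_change == pytest.approx(1.0, abs=0.02)  # pseudocount-negligible
        assert d.call == "decreased"

    def test_equal_counts_unaltered(self, mb_genome):
        islands, a, b = self.make_tracks(mb_genome, 80, 80)
        (d,) = differential_islands(islands, a, b)
        assert d.log2_fold_change == pytest.approx(0.0)
        assert d.call == "unaltered"

    def test_swap_antisymmetry(self, mb_genome):
        islands, a, b = self.make_tracks(mb_genome, 200, 60)
        (d1,) = differential_islands(islands, a, b)
        (d2,) = differential_islands(islands, b, a)
        assert d1.p_value == pytest.approx(d2.p_value)
        assert d1.log2_fold_change == pytest.approx(-d2.log2_fold_change)
        assert (d1.call, d2.call) == ("decreased", "increased")

    def test_empty_islands_is_error(self, mb_genome):
        _, a, b = self.make_tracks(mb_genome, 10, 10)
        with pytest.raises(ValidationError):
            differential_islands(IntervalSet(genome=mb_genome), a, b)


class TestAverageProfile:
    def test_uniform_track_is_flat(self, mb_genome):
        track = ReadTrack({"chr1": np.arange(0, 1_000_000)}, mb_genome, read_length=1)
        anchors = IntervalSet([GenomicInterval("chr1", 400_000, 402_000)], genome=mb_genome)
        profile = average_profile(track, anchors, flank_bp=5000, n_bins=20)
        assert np.ptp(profile) < 1e-12

    def test_point_mass_lands_in_center_bin(self, mb_genome):
        track = ReadTrack({"chr1": np.full(50, 500_000)}, mb_genome, read_length=1)
        anchors = IntervalSet([GenomicInterval("chr1", 499_990, 500_010)], genome=mb_genome)
        profile = average_profile(track, anchors, flank_bp=1000, n_bins=5)
        assert profile[2] > 0
        assert profile[[0, 1, 3, 4]].sum() == 0

    def test_matches_naive_binning_oracle(self, mb_genome):
        rng = np.random.default_rng(5)
        pos = np.sort(rng.integers(0, 999_000, 2000))
        rl = 36
        track = ReadTrack({"chr1": pos}, mb_genome, read_length=rl)
        anchors = IntervalSet(
            [GenomicInterval("chr1", int(s), int(s) + 100) for s in rng.integers(50_000, 900_000, 8)],
            genome=mb_genome,
        )
        flank, nb = 3000, 12
        got = average_profile(track, anchors, flank, nb)
        width = 2 * flank / nb
        expect = np.zeros(nb)
        for iv in anchors:
            mid = (iv.start + iv.end) // 2
            edges = (mid - flank) + np.round(np.arange(nb + 1) * width).astype(int)
            for k in range(nb):
                n = sum(1 for p in pos if p < edges[k + 1] and p + rl > edges[k])
                expect[k] += n / (edges[k + 1] - edges[k]) / (track.library_size / 1e6)
        expect /= len(anchors)
        np.testing.assert_allclose(got, expect, atol=1e-12)

    def test_all_anchors_truncated_is_error(self, mb_genome):
        track = ReadTrack({"chr1": np.array([100])}, mb_genome)
        anchors = IntervalSet([GenomicInterval("chr1", 0, 10)], genome=mb_genome)
        with pytest.raises(ValidationError):
            average_profile(track, anchors, flank_bp=5000, n_bins=10)


class TestFoldChangeEcdf:
    def test_identical_tracks_step_at_zero(self, mb_genome):
        pos = {"chr1": np.sort(np.random.default_rng(1).integers(0, 999_000, 5000))}
        track = ReadTrack(pos, mb_genome)
        islands = IntervalSet(
            [GenomicInterval("chr1", s, s + 2000) for s in range(0, 100_000, 10_000)],
            genome=mb_genome,
        )
        ecdf = fold_change_ecdf(islands, track, track)
        assert np.all(ecdf.values == 0.0)

    def test_ecdf_axioms(self, mb_genome):
        rng = np.random.default_rng(2)
        a = ReadTrack({"chr1": np.sort(rng.integers(0, 999_000, 3000))}, mb_genome)
        b = ReadTrack({"chr1": np.sort(rng.integers(0, 999_000, 3000))}, mb_genome)
        islands = IntervalSet(
            [GenomicInterval("chr1", s, s + 1000) for s in range(0, 500_000, 5000)],
            genome=mb_genome,
        )
        ecdf = fold_change_ecdf(islands, a, b)
        assert np.all(np.diff(ecdf.fractions) >= 0)
        assert ecdf.fractions[-1] == pytest.approx(1.0)
        assert np.all(np.diff(ecdf.values) >= 0)

    def test_half_thinned_track_shifts_left_one_unit(self, mb_genome):
        """Keeping every second read halves densities: the median log2
        fold-change sits near -1."""
        rng = np.random.default_rng(3)
        pos = np.sort(rng.integers(0, 999_000, 60_000))
        full = ReadTrack({"chr1": pos}, mb_genome, library_size=60_000)
        thin = ReadTrack({"chr1": pos[::2]}, mb_genome, library_size=60_000)
        islands = IntervalSet(
            [GenomicInterval("chr1", s, s + 2000) for s in range(0, 900_000, 9000)],
            genome=mb_genome,
        )
        ecdf = fold_change_ecdf(islands, full, thin)
        median = np.median(ecdf.values)
        assert median == pytest.approx(-1.0, abs=0.2)
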