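"""Windowed estimators against brute-force oracles and known identities."""

import itertools
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import divscape as d
from divscape.window_stats import allele_counts

from conftest import small_matrix


# ---------------------------------------------------------------------------
# Brute-force oracles (exact rational arithmetic where possible)
# ---------------------------------------------------------------------------


def alleles_of(dosage_col):
    """Expand diploid dosages into a list of 0/1 alleles (called only)."""
    out = []
    for g in dosage_col:
        if g != d.MISSING:
            out.extend([1] * int(g) + [0] * (2 - int(g)))
    return out


def brute_pi_site(dosages):
    """Mean pairwise difference over all C(n,2) allele pairs at one site."""
    a = alleles_of(dosages)
    pairs = list(itertools.combinations(a, 2))
    if not pairs:
        return None
    return Fraction(sum(x != y for x, y in pairs), len(pairs))


def brute_dxy_site(dos_a, dos_b):
    """Mean difference over all cross-population allele pairs at one site."""
    aa, bb = alleles_of(dos_a), alleles_of(dos_b)
    if not aa or not bb:
        return None
    return Fraction(sum(x != y for x in aa for y in bb), len(aa) * len(bb))


def brute_hudson_site(dos_a, dos_b):
    """Hudson per-site (num, den) from exact allele frequencies."""
    aa, bb = alleles_of(dos_a), alleles_of(dos_b)
    na, nb = len(aa), len(bb)
    if na < 2 or nb < 2:
        return None
    pa, pb = Fraction(sum(aa), na), Fraction(sum(bb), nb)
    num = ((pa - pb) ** 2 - pa * (1 - pa) / (na - 1)
           - pb * (1 - pb) / (nb - 1))
    den = pa * (1 - pb) + pb * (1 - pa)
    return num, den


# ---------------------------------------------------------------------------
# Windows
# ---------------------------------------------------------------------------


class TestMakeWindows:
    def test_exact_tiling(self):
        w = d.make_windows({"c": 100_000}, 20_000)
        assert len(w) == 5
        assert (w[0].start, w[0].end) == (0, 20_000)
        assert (w[-1].start, w[-1].end) == (80_000, 100_000)

    def test_truncated_trailing_window(self):
        w = d.make_windows({"c": 55_000}, 50_000)
        assert [(x.start, x.end) for x in w] == [(0, 50_000), (50_000, 55_000)]

    def test_sliding_window_count(self):
        w = d.make_windows({"c": 100_000}, 20_000, step=5_000)
        assert len(w) == int(np.ceil((100_000 - 20_000) / 5_000)) + 1
        assert w[-1].end == 100_000

    def test_invalid_size_rejected(self):
        with pytest.raises(ValueError):
            d.make_windows({"c": 1000}, 0)

    @given(length=st.integers(1, 500_000), size=st.integers(1, 100_000))
    @settings(max_examples=50, deadline=None)
    def test_tiling_covers_contig_without_overlap(self, length, size):
        w = d.make_windows({"c": length}, size)
        assert w[0].start == 0 and w[-1].end == length
        for a, b in zip(w, w[1:]):
            assert a.end == b.start


# ---------------------------------------------------------------------------
# pi / D_xy / F_ST
# ---------------------------------------------------------------------------


class TestPiWindow:
    def test_single_snp_brute_force_value(self):
        # 2 diploids, 2 ref + 2 alt alleles: 4 of 6 allele pairs differ
        gm = small_matrix([[1, 1]], positions=[5000])
        w = d.Window("chr1", 0, 10_000)
        expect = brute_pi_site([1, 1]) / 10_000
        assert expect == Fraction(2, 3) / 10_000
        assert d.pi_window(gm, ["s1", "s2"], w) == pytest.approx(
            float(expect), abs=1e-15)

    def test_monomorphic_window_is_zero(self):
        gm = small_matrix([[0, 0, 0]], positions=[100])
        assert d.pi_window(gm, ["s1", "s2", "s3"],
                           d.Window("chr1", 0, 1000)) == 0.0

    def test_denominator_scaling(self):
        gm = small_matrix([[1, 1]], positions=[500])
        short = d.pi_window(gm, ["s1", "s2"], d.Window("chr1", 0, 1000))
        long = d.pi_window(gm, ["s1", "s2"], d.Window("chr1", 0, 2000))
        assert short == pytest.approx(2 * long)

    def test_matches_brute_force_on_random_matrices(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            dos = rng.choice([0, 1, 2, d.MISSING], size=(6, 6),
                             p=[0.3, 0.3, 0.3, 0.1])
            gm = small_matrix(dos, positions=np.arange(1, 7) * 10)
            w = d.Window("chr1", 0, 100)
            expect = sum((f for f in map(brute_pi_site, dos) if f is not None),
                         Fraction(0)) / 100
            got = d.pi_window(gm, [f"s{i}" for i in range(1, 7)], w)
            assert got == pytest.approx(float(expect), abs=1e-12)


class TestDxyWindow:
    A = ["s1", "s2"]
    B = ["s3", "s4"]

    def test_reciprocally_fixed_snp(self):
        gm = small_matrix([[2, 2, 0, 0]], positions=[100])
        w = d.Window("chr1", 0, 20_000)
        assert d.dxy_window(gm, self.A, self.B, w) == pytest.approx(5e-5)

    def test_equal_intermediate_frequencies(self):
        gm = small_matrix([[1, 1, 1, 1]], positions=[100])
        w = d.Window("chr1", 0, 20_000)
        assert d.dxy_window(gm, self.A, self.B, w) == pytest.approx(2.5e-5)

    def test_shared_monomorphism_is_zero(self):
        gm = small_matrix([[0, 0, 0, 0]], positions=[100])
        assert d.dxy_window(gm, self.A, self.B,
                            d.Window("chr1", 0, 1000)) == 0.0

    def test_matches_brute_force_on_random_matrices(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            dos = rng.choice([0, 1, 2, d.MISSING], size=(5, 6),
                             p=[0.3, 0.3, 0.3, 0.1])
            gm = small_matrix(dos, positions=np.arange(1, 6) * 10)
            w = d.Window("chr1", 0, 64)
            expect = Fraction(0)
            for row in dos:
                v = brute_dxy_site(row[:3], row[3:])
                if v is not None:
                    expect += v
            got = d.dxy_window(gm, ["s1", "s2", "s3"], ["s4", "s5", "s6"], w)
            assert got == pytest.approx(float(expect / 64), abs=1e-12)

    def test_invariant_to_within_species_relabelling(self, default_sim):
        gm, pm = default_sim.gm, default_sim.popmap
        w = d.Window("chr1", 0, 200_000)
        base = d.dxy_window(gm, pm.samples_of("OT"), pm.samples_of("OK"), w)
        rng = np.random.default_rng(3)
        shuffled = list(rng.permutation(pm.samples_of("OT")))
        assert d.dxy_window(gm, shuffled, pm.samples_of("OK"), w) == \
            pytest.approx(base, abs=1e-15)


class TestHudsonFst:
    def test_reciprocally_fixed_site_is_one(self):
        gm = small_matrix([[2] * 10 + [0] * 10], positions=[100])
        comp = d.hudson_components(gm, np.arange(10), np.arange(10, 20))
        assert comp.num[0] == pytest.approx(1.0)
        assert comp.den[0] == pytest.approx(1.0)
        assert comp.ratio() == pytest.approx(1.0)

    def test_identical_frequencies_give_negative_estimate(self):
        # p = 0.5 in both, n = 10 alleles each: num = -2 * 0.25/9
        gm = small_matrix([[1] * 10], positions=[100])
        comp = d.hudson_components(gm, np.arange(5), np.arange(5, 10))
        assert comp.num[0] == pytest.approx(-2 * 0.25 / 9)
        assert comp.ratio() < 0

    def test_window_value_is_ratio_of_sums_not_mean_of_ratios(self):
        gm = small_matrix([[2] * 5 + [0] * 5, [1] * 10],
                          positions=[100, 200])
        comp = d.hudson_components(gm, np.arange(5), np.arange(5, 10))
        per_site = comp.num / comp.den
        ratio_of_sums = comp.num.sum() / comp.den.sum()
        assert comp.ratio() == pytest.approx(ratio_of_sums)
        assert comp.ratio() != pytest.approx(per_site.mean())

    def test_matches_brute_force_on_random_matrices(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            dos = rng.choice([0, 1, 2, d.MISSING], size=(6, 6),
                             p=[0.35, 0.3, 0.3, 0.05])
            gm = small_matrix(dos, positions=np.arange(1, 7) * 10)
            comp = d.hudson_components(gm, np.arange(3), np.arange(3, 6))
            num = den = Fraction(0)
            any_site = False
            for row in dos:
                v = brute_hudson_site(row[:3], row[3:])
                if v is not None:
                    num, den = num + v[0], den + v[1]
                    any_site = True
            if not any_site or den == 0:
                assert np.isnan(comp.ratio())
            else:
                assert comp.ratio() == pytest.approx(float(num / den),
                                                     abs=1e-12)

    def test_split_half_panmictic_fst_near_zero(self):
        cfg = d.SimConfig(contigs=[("chr1", 4_000_000)],
                          f_ot=1e-4, f_anc=1e-4, f_ok=1e-4, f_oi=1e-4,
                          migration={}, divergent_site_rate=0.0, seed=9)
        sim = d.simulate_dataset(cfg)
        ot = sim.popmap.samples_of("OT")
        cols_a = sim.gm.sample_indices(ot[:9])
        cols_b = sim.gm.sample_indices(ot[9:])
        comp = d.hudson_components(sim.gm, cols_a, cols_b)
        table = d.window_fst_table(
            comp, d.make_windows({"chr1": 4_000_000}, 20_000))
        assert abs(np.nanmean(table["fst"])) <= 0.05

    def test_mean_fst_increases_with_drift(self):
        means = []
        for f in (0.05, 0.2, 0.5):
            cfg = d.SimConfig(contigs=[("chr1", 1_000_000)],
                              f_ot=f, f_anc=0.05, f_ok=f, f_oi=f,
                              migration={}, divergent_site_rate=0.0, seed=4)
            sim = d.simulate_dataset(cfg)
            w = d.make_windows({"chr1": 1_000_000}, 20_000)
            s = d.windowed_statistics(sim.gm, sim.popmap, w, with_tajd=False)
            means.append(s["fst_OT_OK"].mean())
        assert means[0] < means[1] < means[2]

    def test_weir_cockerham_agrees_on_balanced_fixed_site(self):
        gm = small_matrix([[2] * 8 + [0] * 8], positions=[100])
        comp = d.weir_cockerham_components(gm, np.arange(8), np.arange(8, 16))
        assert comp.ratio() == pytest.approx(1.0)


class TestTajimasD:
    def test_singleton_four_alleles(self):
        # n=4 alleles, S=1 singleton: D = (0.5 - 6/11)/sqrt(e1) ~ -0.612
        gm = small_matrix([[1, 0]], positions=[100])
        got = d.tajimas_d_window(gm, ["s1", "s2"], d.Window("chr1", 0, 1000))
        assert got == pytest.approx(-0.612, abs=1e-3)

    def test_no_segregating_sites_undefined(self):
        gm = small_matrix([[0, 0], [2, 2]], positions=[10, 20])
        assert np.isnan(d.tajimas_d_window(gm, ["s1", "s2"],
                                           d.Window("chr1", 0, 100)))

    def test_intermediate_frequencies_give_positive_d(self):
        # every site at frequency 0.5 maximises pi relative to theta_W
        gm = small_matrix([[1, 1, 2, 0]] * 6, positions=np.arange(1, 7) * 10)
        got = d.tajimas_d_window(gm, ["s1", "s2", "s3", "s4"],
                                 d.Window("chr1", 0, 100))
        assert got > 0

    def test_small_sample_undefined(self):
        gm = small_matrix([[1]], positions=[10])
        assert np.isnan(d.tajimas_d_window(gm, ["s1"],
                                           d.Window("chr1", 0, 100)))


class TestLdDecay:
    def test_identical_vectors_r2_one(self):
        gm = small_matrix([[0, 1, 2, 1], [0, 1, 2, 1]], positions=[10, 20])
        out = d.ld_decay(gm, ["s1", "s2", "s3", "s4"], max_dist=100,
                         bin_width=100)
        assert out.loc[0, "mean_r2"] == pytest.approx(1.0)

    def test_uncorrelated_vectors_r2_zero(self):
        gm = small_matrix([[0, 0, 2, 2], [0, 2, 0, 2]], positions=[10, 20])
        out = d.ld_decay(gm, ["s1", "s2", "s3", "s4"], max_dist=100,
                         bin_width=100)
        assert out.loc[0, "mean_r2"] == pytest.approx(0.0, abs=1e-12)

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(5)
        dos = rng.choice([0, 1, 2], size=(5, 8))
        gm = small_matrix(dos, positions=[10, 200, 1500, 2200, 4100])
        out = d.ld_decay(gm, [f"s{i}" for i in range(1, 9)],
                         max_dist=5000, bin_width=1000)
        sums = np.zeros(5)
        counts = np.zeros(5, dtype=int)
        for i, j in itertools.combinations(range(5), 2):
            dist = gm.pos[j] - gm.pos[i]
            if dist > 5000:
                continue
            r = np.corrcoef(dos[i], dos[j])[0, 1]
            if np.isnan(r):
                continue
            b = (dist - 1) // 1000
            sums[b] += r ** 2
            counts[b] += 1
        for b in range(5):
            if counts[b]:
                assert out.loc[b, "mean_r2"] == pytest.approx(
                    sums[b] / counts[b], abs=1e-12)
                assert out.loc[b, "n_pairs"] == counts[b]

    def test_planted_ld_blocks_elevate_short_range_r2(self):
        cfg = d.SimConfig(contigs=[("chr1", 500_000)], seed=6,
                          ld_blocks=[("chr1", 100_000, 110_000)],
                          missing_rate=0.0)
        sim = d.simulate_dataset(cfg)
        ot = sim.popmap.samples_of("OT")
        pos0 = sim.gm.pos - 1
        in_block = (pos0 >= 100_000) & (pos0 < 110_000)
        block = sim.gm.take_sites(in_block)
        rest = sim.gm.take_sites(~in_block)
        r2_block = d.ld_decay(block, ot, max_dist=10_000,
                              bin_width=10_000).loc[0, "mean_r2"]
        r2_rest = d.ld_decay(rest, ot, max_dist=10_000,
                             bin_width=10_000).loc[0, "mean_r2"]
        assert r2_block > r2_rest + 0.3


def test_windowed_statistics_agrees_with_per_window_ops(default_sim):
    gm, pm = default_sim.gm, default_sim.popmap
    windows = d.make_windows(gm.contig_lengths(), 100_000)[:5]
    table = d.windowed_statistics(gm, pm, windows)
    for i, w in enumerate(windows):
        assert table.loc[i, "pi_OT"] == pytest.approx(
            d.pi_window(gm, pm.samples_of("OT"), w), abs=1e-12)
        assert table.loc[i, "dxy_OT_OK"] == pytest.approx(
            d.dxy_window(gm, pm.samples_of("OT"), pm.samples_of("OK"), w),
            abs=1e-12)
        comp = d.hudson_components(
            gm, pm.indices_of("OT", gm), pm.indices_of("OK", gm))
        assert table.loc[i, "fst_OT_OK"] == pytest.approx(
            d.hudson_fst_window(comp, gm, w), abs=1e-12, nan_ok=True)


def test_allele_counts_on_missing_data():
    gm = small_matrix([[0, 1, 2, d.MISSING]])
    an, ac = allele_counts(gm, np.arange(4))
    assert an[0] == 6 and ac[0] == 3
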