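import logging
import math

import numpy as np
import pytest
from scipy import stats as sps
from scipy.spatial.transform import Rotation

from wolclock.divergence import from_records
from wolclock.exceptions import DomainError, InputError, WolclockError
from wolclock.structdnds import (
    Residue,
    StructureModel,
    bca_interval,
    global_omega,
    group_compare,
    kabsch_tm,
    label_residues,
    median_profile,
    pairwise_site_counts,
    read_structure,
    spearman,
    spherical_windows,
    tm_d0,
    tm_score_from_transform,
    window_omega,
)
from wolclock.structdnds.stats import _adjusted_percentiles, _p_adjust
from wolclock.synthetic_data import sim_codon_pair_omega, sim_helix

import oracles
from conftest import make_pdb


class TestReadStructure:
    def test_toy_coordinates_exact(self, tmp_path):
        coords = [[1.0, 2.0, 3.0], [4.0, 5.0, 6.0], [7.0, 8.0, 9.5]]
        path = make_pdb(tmp_path / "s.pdb", coords, bfactors=[80.0, 85.5, 90.0])
        model = read_structure(path, chain="A")
        assert len(model) == 3
        np.testing.assert_allclose(model.coords, coords)
        assert model.residues[1].confidence == 85.5
        assert model.residues[0].aa == "A"

    def test_missing_chain(self, tmp_path):
        path = make_pdb(tmp_path / "s.pdb", [[0, 0, 0], [1, 1, 1]])
        with pytest.raises(InputError):
            read_structure(path, chain="B")

    def test_altloc_first_kept(self, tmp_path, caplog):
        coords = [[1.0, 1.0, 1.0], [5.0, 5.0, 5.0], [9.0, 9.0, 9.0]]
        path = make_pdb(tmp_path / "s.pdb", coords, altlocs={2: ["A", "B"]})
        with caplog.at_level(logging.WARNING, logger="wolclock.structdnds.structure"):
            model = read_structure(path, chain="A")
        np.testing.assert_allclose(model.coords[1], [5.0, 5.0, 5.0])
        assert any("altloc" in rec.message for rec in caplog.records)


class TestSphericalWindows:
    def test_tiny_radius_self_only(self):
        helix = sim_helix(20)
        windows = spherical_windows(helix, radius=0.1)
        for i, members in windows.items():
            assert members == (i,)

    def test_huge_radius_everything(self):
        helix = sim_helix(20)
        windows = spherical_windows(helix, radius=1e6)
        for members in windows.values():
            assert len(members) == 20

    def test_helix_brute_force(self):
        helix = sim_helix(40)
        radius = 6.0
        windows = spherical_windows(helix, radius=radius)
        coords = helix.coords
        for row, i in enumerate(helix.indices):
            expected = tuple(
                helix.indices[col]
                for col in range(len(coords))
                if math.dist(coords[row], coords[col]) <= radius
            )
            assert windows[i] == expected

    def test_bad_radius(self):
        with pytest.raises(DomainError):
            spherical_windows(sim_helix(5), radius=0.0)


class TestPairwiseSiteCounts:
    def test_identical_no_diffs(self):
        aln = from_records([("r", "ATGGCTAAA"), ("o", "ATGGCTAAA")])
        counts = pairwise_site_counts(aln, "r", "o")
        assert np.nansum(counts.s_diff) == 0
        assert np.nansum(counts.n_diff) == 0
        np.testing.assert_allclose(counts.s_sites + counts.n_sites, 3.0)

    def test_single_synonymous_change_at_codon_5(self):
        ref = "GGG" * 4 + "TTT" + "GGG" * 3
        oth = "GGG" * 4 + "TTC" + "GGG" * 3
        aln = from_records([("r", ref), ("o", oth)])
        counts = pairwise_site_counts(aln, "r", "o")
        assert counts.s_diff[4] == 1.0
        assert np.nansum(counts.s_diff) == 1.0
        assert np.nansum(counts.n_diff) == 0.0

    def test_reference_gap_column_dropped(self):
        aln = from_records([("r", "GGG---AAA"), ("o", "GGGCCCAAA")])
        counts = pairwise_site_counts(aln, "r", "o")
        assert list(counts.indices) == [1, 2]
        assert len(counts) == 2

    def test_other_gap_is_nan_row(self):
        aln = from_records([("r", "GGGAAATTT"), ("o", "GGG--ATTT")])
        counts = pairwise_site_counts(aln, "r", "o")
        assert np.isnan(counts.s_sites[1])
        assert not np.isnan(counts.s_sites[0])


class TestWindowOmega:
    def _counts(self, n=60, seed=5, profile=None, t=0.3):
        aln = sim_codon_pair_omega(profile or [(n, 0.5)], t, seed=seed)
        return pairwise_site_counts(aln, "a", "b")

    def test_infinite_radius_equals_global(self):
        counts = self._counts()
        helix = sim_helix(len(counts))
        windows = spherical_windows(helix, radius=1e9)
        om = window_omega(counts, windows)
        g = global_omega(counts)
        ok = ~np.isnan(om)
        assert ok.any()
        np.testing.assert_allclose(om[ok], g, rtol=1e-12)

    def test_ds_zero_is_nan(self):
        # single-codon windows; AAA->AGA is purely nonsynonymous
        aln = from_records([("r", "AAA"), ("o", "AGA")])
        counts = pairwise_site_counts(aln, "r", "o")
        om = window_omega(counts, {1: (1,)})
        assert np.isnan(om[0])

    def test_dn_zero_gives_zero(self):
        # one synonymous change pooled over 10 codons: dN = 0, dS > 0
        aln = from_records([("r", "GGG" * 9 + "TTT"), ("o", "GGG" * 9 + "TTC")])
        counts = pairwise_site_counts(aln, "r", "o")
        members = tuple(range(1, 11))
        om = window_omega(counts, {i: members for i in members})
        assert om[0] == 0.0


class TestMedianProfile:
    def test_single_comparison(self):
        p = np.array([0.1, 0.2, np.nan])
        prof = median_profile([p], np.arange(1, 4))
        np.testing.assert_array_equal(prof.median[:2], [0.1, 0.2])
        assert np.isnan(prof.median[2])

    def test_na_aware_median(self):
        a = np.array([0.2])
        b = np.array([0.4])
        c = np.array([np.nan])
        prof = median_profile([a, b, c], np.array([1]))
        assert prof.median[0] == pytest.approx(0.3)

    def test_order_invariance(self):
        rng = np.random.default_rng(0)
        ps = [rng.uniform(size=10) for _ in range(5)]
        m1 = median_profile(ps, np.arange(1, 11)).median
        m2 = median_profile(ps[::-1], np.arange(1, 11)).median
        np.testing.assert_allclose(m1, m2)

    def test_length_mismatch(self):
        with pytest.raises(InputError):
            median_profile([np.zeros(3), np.zeros(4)], np.arange(1, 4))

    def test_label_residues(self):
        labels = label_residues(6, domains={"nuc": [(5, 6)]}, binding=[(2, 5)])
        assert labels == ["none", "binding", "binding", "binding", "domain:nuc", "domain:nuc"]


class TestBca:
    def test_all_equal_zero_width(self):
        lo, hi = bca_interval(np.ones(10), np.mean, n_boot=200, seed=0)
        assert lo == hi == 1.0

    def test_reduces_to_percentile(self, rng):
        boot = rng.normal(size=5000)
        lo, hi = _adjusted_percentiles(boot, 0.0, 0.0, 0.95)
        assert lo == pytest.approx(np.percentile(boot, 2.5))
        assert hi == pytest.approx(np.percentile(boot, 97.5))

    def test_preconditions(self):
        with pytest.raises(DomainError):
            bca_interval([1.0], np.mean)
        with pytest.raises(DomainError):
            bca_interval([1.0, 2.0], np.mean, n_boot=50)

    def test_median_interval_contains_point(self, rng):
        vals = rng.normal(size=40)
        lo, hi = bca_interval(vals, np.median, n_boot=500, seed=1)
        assert lo <= np.median(vals) <= hi


class TestGroupCompare:
    def test_identical_full_ties_p_one(self):
        res = group_compare([1.0] * 6, ["a"] * 3 + ["b"] * 3)
        assert res.p_value == 1.0
        assert res.letters["a"] == res.letters["b"]

    def test_enumerated_mwu(self):
        res = group_compare([1, 2, 3, 10, 11, 12], ["x"] * 3 + ["y"] * 3)
        assert res.test == "mann-whitney"
        assert res.p_value == pytest.approx(0.1)  # two-sided 1/10

    def test_three_identical_groups_one_letter(self):
        vals = [1.0, 1.0] * 3
        labels = ["a", "a", "b", "b", "c", "c"]
        res = group_compare(vals, labels)
        assert len(set(res.letters.values())) == 1

    def test_three_separated_groups(self):
        rng = np.random.default_rng(4)
        vals = np.concatenate([rng.normal(0, 0.1, 15),
                               rng.normal(5, 0.1, 15),
                               rng.normal(10, 0.1, 15)])
        labels = ["a"] * 15 + ["b"] * 15 + ["c"] * 15
        res = group_compare(vals, labels)
        assert res.test == "kruskal-wallis"
        assert res.p_value < 0.001
        assert len({res.letters["a"], res.letters["b"], res.letters["c"]}) == 3

    def test_small_group_excluded(self, caplog):
        with caplog.at_level(logging.WARNING):
            res = group_compare([1, 2, 3, 4, 9], ["a", "a", "b", "b", "c"])
        assert "c" not in res.letters

    def test_too_few_groups(self):
        with pytest.raises(InputError):
            group_compare([1, 2, 3], ["a", "a", "a"])

    def test_nan_dropped(self):
        res = group_compare([1, 2, np.nan, 10, 11, np.nan],
                            ["a", "a", "a", "b", "b", "b"])
        assert res.group_sizes == {"a": 2, "b": 2}

    def test_holm_adjustment(self):
        p = np.array([0.01, 0.04, 0.03])
        adj = _p_adjust(p, "holm")
        np.testing.assert_allclose(adj, [0.03, 0.06, 0.06])


class TestKabschTm:
    def test_self_perfect(self):
        h = sim_helix(30)
        res = kabsch_tm(h, h)
        assert res.score == pytest.approx(1.0, abs=1e-9)
        assert res.rmsd == pytest.approx(0.0, abs=1e-9)

    def test_rigid_motion_invariance(self):
        h = sim_helix(25)
        rot = Rotation.random(random_state=7).as_matrix()
        shift = np.array([12.0, -3.0, 8.0])
        moved = StructureModel(
            tuple(
                Residue(r.index, r.aa, rot @ r.coord + shift, r.confidence)
                for r in h.residues
            )
        )
        assert kabsch_tm(h, moved).score == pytest.approx(1.0, abs=1e-9)

    def test_too_few_pairs(self):
        h = sim_helix(5)
        with pytest.raises(InputError):
            kabsch_tm(h, h, correspondence=[(1, 1), (2, 2)])

    def test_collinear_degenerate(self):
        line = StructureModel(
            tuple(
                Residue(i + 1, "A", np.array([float(i), 0.0, 0.0]), 90.0)
                for i in range(5)
            )
        )
        with pytest.raises(WolclockError):
            kabsch_tm(line, line)

    def test_transform_reproduces_score(self):
        h = sim_helix(30)
        target = StructureModel(
            tuple(
                Residue(
                    r.index, r.aa,
                    r.coord + (np.array([20.0, 0, 0]) if r.index == 10 else 0),
                    r.confidence,
                )
                for r in h.residues
            )
        )
        res = kabsch_tm(h, target)
        pairs = [(i, i) for i in h.indices]
        ref_xyz = h.coords
        tgt_xyz = target.coords
        replayed = tm_score_from_transform(
            ref_xyz, tgt_xyz, res.rotation, res.translation, res.norm_length
        )
        assert replayed == pytest.approx(res.score, abs=1e-9)

    def test_displaced_residue_matches_refinement_oracle(self):
        h = sim_helix(30)
        target = StructureModel(
            tuple(
                Residue(
                    r.index, r.aa,
                    r.coord + (np.array([20.0, 0, 0]) if r.index == 10 else 0),
                    r.confidence,
                )
                for r in h.residues
            )
        )
        res = kabsch_tm(h, target)
        d0 = tm_d0(30)
        expected = oracles.tm_refine_oracle(
            h.coords, target.coords, 30, d0, cutoff=max(d0, 1.0)
        )
        assert res.score == pytest.approx(expected, abs=1e-6)
        assert res.score < 1.0

    def test_asymmetric_when_lengths_differ(self):
        short = sim_helix(30)
        long = sim_helix(45)
        pairs = [(i, i) for i in range(1, 31)]
        fwd = kabsch_tm(short, long, correspondence=pairs)
        rev = kabsch_tm(long, short, correspondence=pairs)
        assert fwd.norm_length == 45
        assert rev.norm_length == 30
        assert fwd.score != pytest.approx(rev.score, abs=1e-6)


class TestSpearman:
    def test_monotone_increasing(self):
        rho, p = spearman([1, 2, 3, 4, 5], [2, 4, 9, 16, 30])
        assert rho == pytest.approx(1.0)

    def test_monotone_decreasing(self):
        rho, _ = spearman([1, 2, 3, 4, 5], [10, 8, 5, 4, 0])
        assert rho == pytest.approx(-1.0)

    def test_tie_matches_permutation_oracle(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        y = [2.0, 2.0, 3.0, 5.0, 4.0]  # one tie in y
        rho, p = spearman(x, y)
        rho_expect, p_expect = oracles.spearman_perm_oracle(x, y)
        assert rho == pytest.approx(rho_expect)
        assert p == pytest.approx(p_expect)

    def test_zero_variance_nan(self):
        rho, p = spearman([1, 2, 3], [5, 5, 5])
        assert math.isnan(rho) and math.isnan(p)

    def test_large_n_t_approximation(self, rng):
        x = rng.normal(size=40)
        y = x + rng.normal(size=40)
        rho, p = spearman(x, y)
        ref = sps.spearmanr(x, y)
        assert rho == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue, rel=1e-6)

    def test_bad_lengths(self):
        with pytest.raises(InputError):
            spearman([1, 2], [1, 2])
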