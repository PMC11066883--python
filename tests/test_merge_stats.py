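import numpy as np
import pandas as pd
import pytest

from dsmap.grid_symmetry import MillerGrid, UnitCell, pack_voxels
from dsmap.merge_stats import (
    ShellScheme,
    cc_by_shell,
    cc_rep,
    halo_partition,
    make_shells,
    shell_statistics,
    split_observations,
)
from dsmap.scaling import merge_scaled


def _obs_with_multiplicity(counts, seed=0):
    """Observation table with given per-voxel observation counts."""
    rng = np.random.default_rng(seed)
    rows = []
    for vox_id, mult in enumerate(counts):
        for _ in range(mult):
            rows.append(
                {
                    "asu_key": 1000 + vox_id,
                    "friedel": bool(rng.integers(2)),
                    "I": rng.normal(10, 1),
                    "sigma": 1.0,
                    "s": 0.1 + 0.01 * vox_id,
                    "batch": int(rng.integers(2)),
                }
            )
    return pd.DataFrame(rows)


class TestSplits:
    def test_even_multiplicity_splits_evenly(self):
        obs = _obs_with_multiplicity([4, 4, 6])
        h1, h2 = split_observations(obs, "randomHalf", seed=1)
        for key in obs.asu_key.unique():
            assert (h1.asu_key == key).sum() == (h2.asu_key == key).sum()

    def test_odd_multiplicity_imbalance_at_most_one(self):
        obs = _obs_with_multiplicity([5, 3, 7, 1])
        h1, h2 = split_observations(obs, "randomHalf", seed=2)
        for key in obs.asu_key.unique():
            n1 = (h1.asu_key == key).sum()
            n2 = (h2.asu_key == key).sum()
            assert abs(n1 - n2) <= 1

    def test_halves_partition_the_input(self):
        obs = _obs_with_multiplicity([3, 2, 5, 4])
        h1, h2 = split_observations(obs, "randomHalf", seed=3)
        assert len(h1) + len(h2) == len(obs)
        assert set(h1.index).isdisjoint(h2.index)
        assert set(h1.index) | set(h2.index) == set(obs.index)

    def test_friedel_split_follows_flag(self):
        obs = _obs_with_multiplicity([4, 4])
        h1, h2 = split_observations(obs, "Friedel", seed=0)
        assert not h1.friedel.any()
        assert h2.friedel.all()

    def test_coin_balances_odd_voxels_across_seeds(self):
        """With many odd-multiplicity voxels, the extra observation lands in
        either half about equally often."""
        obs = _obs_with_multiplicity([3] * 200)
        h1, _ = split_observations(obs, "randomHalf", seed=4)
        extra_in_h1 = sum(
            (h1.asu_key == k).sum() == 2 for k in obs.asu_key.unique()
        )
        assert 60 < extra_in_h1 < 140  # fair coin over 200 voxels

    def test_unknown_mode(self):
        with pytest.raises(ValueError):
            split_observations(_obs_with_multiplicity([2]), "bogus")


class TestShellScheme:
    def test_edges_must_increase(self):
        with pytest.raises(ValueError):
            ShellScheme(np.array([0.1, 0.1, 0.2]))

    def test_assignment_is_half_open_with_inclusive_top(self):
        scheme = ShellScheme(np.array([0.0, 1.0, 2.0]))
        np.testing.assert_array_equal(
            scheme.assign([0.0, 0.5, 1.0, 2.0, 2.5]), [0, 0, 1, 1, -1]
        )

    def test_equal_count_shells_balance_membership(self):
        rng = np.random.default_rng(0)
        s = rng.power(3.0, 2000)
        scheme = make_shells(s, 10, mode="equal_count")
        counts = np.bincount(scheme.assign(s), minlength=scheme.n_shells)
        assert counts.min() > 150 and counts.max() < 250


class TestCorrelations:
    def _merged(self, I, seed=0):
        n = len(I)
        rng = np.random.default_rng(seed)
        return pd.DataFrame(
            {
                "asu_key": np.arange(n),
                "s": np.sort(rng.uniform(0.1, 0.7, n)),
                "I": I,
                "sigma": np.ones(n),
            }
        )

    def test_identical_halves_correlate_perfectly(self):
        rng = np.random.default_rng(1)
        m = self._merged(rng.normal(5, 2, 400))
        shells = make_shells(m.s, 5)
        cc = cc_by_shell(m, m.copy(), shells)
        np.testing.assert_allclose(cc.cc.dropna(), 1.0, atol=1e-12)

    def test_anticorrelated_halves(self):
        rng = np.random.default_rng(2)
        m1 = self._merged(rng.normal(0, 2, 400))
        m2 = m1.assign(I=-m1.I)
        shells = make_shells(m1.s, 4)
        cc = cc_by_shell(m1, m2, shells)
        np.testing.assert_allclose(cc.cc.dropna(), -1.0, atol=1e-12)

    def test_pure_noise_halves_decorrelate(self):
        rng = np.random.default_rng(3)
        m1 = self._merged(rng.normal(0, 1, 3000), seed=4)
        m2 = m1.assign(I=rng.normal(0, 1, 3000))
        shells = make_shells(m1.s, 3)  # ~1000 voxels per shell
        cc = cc_by_shell(m1, m2, shells)
        assert np.nanmax(np.abs(cc.cc)) < 0.1

    def test_affine_rescaling_invariance(self):
        rng = np.random.default_rng(5)
        m1 = self._merged(rng.normal(5, 2, 500))
        m2 = m1.assign(I=m1.I + rng.normal(0, 1, 500))
        shells = make_shells(m1.s, 4)
        base = cc_by_shell(m1, m2, shells).cc
        scaled = cc_by_shell(
            m1.assign(I=2.5 * m1.I - 3), m2.assign(I=0.1 * m2.I + 7), shells
        ).cc
        np.testing.assert_allclose(base, scaled, rtol=1e-9)

    def test_sparse_shells_marked_undefined(self):
        m = self._merged(np.arange(4.0))
        shells = ShellScheme(np.array([0.0, 0.05, 2.0]))
        cc = cc_by_shell(m, m.copy(), shells)
        assert np.isnan(cc.cc.iloc[0])  # fewer than 3 common voxels


class TestCcRep:
    def test_overlapping_groups_rejected(self, small_experiment):
        _, obs, _ = small_experiment
        shells = make_shells(obs.s, 5)
        with pytest.raises(ValueError, match="overlap"):
            cc_rep(obs, {0}, {0, 1}, shells)

    def test_shared_truth_gives_high_correlation(self, small_experiment):
        """Two sweeps measure the same intensities through different
        artifact fields; independently merged, they still correlate."""
        _, obs, _ = small_experiment
        shells = make_shells(obs.s, 5, mode="equal_count")
        table = cc_rep(obs, {0}, {1}, shells)
        assert np.nanmin(table.cc) > 0.8

    def test_uncorrelated_truths_decorrelate(self):
        rng = np.random.default_rng(6)
        n = 4000
        obs = pd.DataFrame(
            {
                "asu_key": np.tile(np.arange(n // 2), 2),
                "batch": np.repeat([0, 1], n // 2),
                "I": rng.normal(0, 1, n),
                "sigma": np.ones(n),
                "s": np.tile(np.sort(rng.uniform(0.1, 0.7, n // 2)), 2),
            }
        )
        shells = make_shells(obs.s, 2)
        table = cc_rep(obs, {0}, {1}, shells, refine_fn=False)
        assert np.nanmax(np.abs(table.cc)) < 0.1


class TestHaloPartition:
    @pytest.fixture()
    def grid(self):
        return MillerGrid.from_preset(UnitCell.cubic(79.48), 3, "I", "m-3")

    def test_partition_rules(self, grid):
        merged = pd.DataFrame(
            {
                "i": [0, 3, 1, 6],
                "j": [0, 3, 0, 0],
                "k": [0, 3, 0, 0],
                "asu_key": [1, 2, 3, 4],
            }
        )
        halo = halo_partition(merged, grid)
        # (0,0,0): allowed node; (1,1,1): violates h+k+l=2n; (1/3,0,0):
        # fractional; (2,0,0): allowed node
        assert list(halo) == [True, False, False, True]


class TestShellStatistics:
    def _merged_with_halo(self, grid, n=2000, halo_boost=0.0, seed=0):
        rng = np.random.default_rng(seed)
        vox = rng.integers(-30, 30, size=(n, 3))
        merged = pd.DataFrame(
            {
                "i": vox[:, 0],
                "j": vox[:, 1],
                "k": vox[:, 2],
                "asu_key": np.arange(n),
                "s": np.linalg.norm(vox / 3.0, axis=1) / 79.48,
                "I": rng.normal(10.0, 1.0, n),
            }
        )
        halo = halo_partition(merged, grid)
        merged.loc[halo, "I"] += rng.normal(0, halo_boost, int(halo.sum()))
        return merged, halo

    def test_constant_intensity_normalizes_to_one(self):
        grid = MillerGrid.from_preset(UnitCell.cubic(79.48), 3, "I", "m-3")
        merged, halo = self._merged_with_halo(grid)
        merged["I"] = 7.0
        shells = make_shells(merged.s, 5)
        stats = shell_statistics(merged, shells, halo)
        non = stats[stats.partition == "non-halo"].dropna(subset=["mean"])
        np.testing.assert_allclose(non["mean"], 1.0, rtol=1e-12)
        np.testing.assert_allclose(non["sd"].dropna(), 0.0, atol=1e-12)

    def test_normalization_constant_is_nonhalo_maximum(self, small_experiment):
        _, obs, _ = small_experiment
        grid = MillerGrid.from_preset(UnitCell.cubic(79.48), 3, "I", "m-3")
        merged = merge_scaled(obs)
        halo = halo_partition(merged, grid)
        shells = make_shells(merged.s, 10)
        stats = shell_statistics(merged, shells, halo)
        non = stats[stats.partition == "non-halo"]
        assert np.nanmax(non["mean"].to_numpy()) == pytest.approx(1.0, rel=1e-12)

    def test_halo_to_nonhalo_sd_ratio_tracks_signal(self):
        """Halo voxels given ~5x the variational amplitude show ~5x the
        per-shell standard deviation."""
        grid = MillerGrid.from_preset(UnitCell.cubic(79.48), 3, "I", "m-3")
        merged, halo = self._merged_with_halo(grid, n=20_000, halo_boost=np.sqrt(24))
        shells = ShellScheme(np.array([0.0, 0.1, 0.2, 0.3]))
        stats = shell_statistics(merged, shells, halo)
        piv = stats.pivot(index="shell", columns="partition", values="sd").dropna()
        ratio = piv["halo"] / piv["non-halo"]
        np.testing.assert_allclose(ratio, 5.0, rtol=0.35)


class TestHalfMergeConsistency:
    def test_recombined_halves_reproduce_full_merge(self, small_experiment):
        _, obs, _ = small_experiment
        usable = obs[obs.sigma > 0]
        h1, h2 = split_observations(usable, "randomHalf", seed=9)
        m1 = merge_scaled(h1).set_index("asu_key")
        m2 = merge_scaled(h2).set_index("asu_key")
        full = merge_scaled(usable).set_index("asu_key")
        keys = full.index
        w1 = 1.0 / m1.reindex(keys).sigma ** 2
        w2 = 1.0 / m2.reindex(keys).sigma ** 2
        num = (w1 * m1.reindex(keys).I).fillna(0) + (w2 * m2.reindex(keys).I).fillna(0)
        den = w1.fillna(0) + w2.fillna(0)
        np.testing.assert_allclose(num / den, full.I, rtol=1e-10)
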