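"""Double-PETH construction, PCA embedding against an independent SVD
oracle, and the lab/region comparison tests."""

import numpy as np
import pandas as pd
import pytest

from reprophys import (
    REGIONS,
    SynthConfig,
    UnitRecord,
    build_peth_matrix,
    distance_permutation_test,
    fisher_combine,
    gen_multilab_population,
    ks_target_test,
    ks_test_grid,
    pca_embed,
    subsampled_ks_fisher,
)

from conftest import make_bare_session


def _session_with_unit(spikes, n_trials=40, rt=None):
    s = make_bare_session(n_trials=n_trials)
    if rt is not None:
        t = s.trial_table
        t["reaction_time"] = rt
        t["first_move"] = t["stim_on"] + rt
        t["feedback_time"] = t["first_move"] + 0.1
    # Alternate fast/slow reaction times so both PETH halves exist; the
    # half-period offset keeps a metronomic train off the bin edges.
    t = s.trial_table
    fast = np.arange(len(t)) % 2 == 0
    t.loc[fast, "reaction_time"] = 0.085
    t.loc[~fast, "reaction_time"] = 0.405
    t["first_move"] = t["stim_on"] + t["reaction_time"]
    t["feedback_time"] = t["first_move"] + 0.1
    s.units = [
        UnitRecord(0, spikes, np.full(len(spikes), 100.0), np.zeros(3), 0.5, "LP")
    ]
    s.duration = float(t["feedback_time"].iloc[-1] + 2)
    return s


class TestBuildPethMatrix:
    def test_constant_rate_cell_is_near_zero(self):
        s = _session_with_unit(np.arange(0.0, 200.0, 0.01))  # exact 100 Hz
        pm = build_peth_matrix([s])
        assert pm.Y.shape == (1, 200)
        assert np.isfinite(pm.Y).all()
        assert np.abs(pm.Y).max() < 1e-9

    def test_silent_baseline_active_post_move(self):
        # A cell firing only within 0.2 s after movement at rate r has
        # baseline b = 0, so post-movement bins sit near r / epsilon.
        s = make_bare_session(n_trials=60)
        t = s.trial_table
        fast = np.arange(len(t)) % 2 == 0
        t.loc[fast, "reaction_time"] = 0.08
        t.loc[~fast, "reaction_time"] = 0.4
        t["first_move"] = t["stim_on"] + t["reaction_time"]
        t["feedback_time"] = t["first_move"] + 0.3
        r = 50.0  # spikes/s inside the response window
        # One spike per 20 ms bin, offset to sit mid-bin rather than on edges.
        spikes = np.sort(
            np.concatenate(
                [m + 0.005 + np.arange(0.0, 0.2, 1 / r) for m in t["first_move"]]
            )
        )
        s.units = [
            UnitRecord(0, spikes, np.full(len(spikes), 100.0), np.zeros(3), 0.5, "LP")
        ]
        s.duration = float(t["feedback_time"].iloc[-1] + 2)
        pm = build_peth_matrix([s], epsilon=0.5)
        fast_half = pm.Y[0, : len(pm.bin_centers)]
        post = fast_half[(pm.bin_centers >= 0.02) & (pm.bin_centers < 0.18)]
        assert np.allclose(post, r / 0.5, rtol=0.15)

    def test_all_cells_excluded_when_split_degenerate(self):
        s = _session_with_unit(np.arange(0.0, 200.0, 0.05))
        # Threshold below every reaction time: no fast trials anywhere.
        pm = build_peth_matrix([s], rt_threshold=0.01)
        assert pm.Y.shape[0] == 0 and pm.n_excluded == 1


class TestPcaEmbed:
    def test_exact_low_rank_r2_one(self, rng):
        u = rng.normal(size=(30, 1))
        v = rng.normal(size=(1, 40))
        emb = pca_embed(u @ v, k=1)
        np.testing.assert_allclose(emb.r2_per_cell, 1.0, atol=1e-10)

    def test_full_rank_perfect_reconstruction(self, rng):
        Y = rng.normal(size=(10, 6))
        emb = pca_embed(Y, k=6)
        np.testing.assert_allclose(emb.r2_per_cell, 1.0, atol=1e-10)

    def test_oracle_svd_agreement(self, rng):
        # Independent oracle: eigen-decomposition of the covariance gives
        # the principal axes; compare the rank-2 reconstruction.
        Y = rng.normal(size=(50, 3)) @ rng.normal(size=(3, 80)) + 0.01 * rng.normal(
            size=(50, 80)
        )
        emb = pca_embed(Y, k=2)
        Yc = Y - Y.mean(axis=0)
        evals, evecs = np.linalg.eigh(Yc.T @ Yc)
        V_oracle = evecs[:, ::-1][:, :2].T
        recon_oracle = Yc @ V_oracle.T @ V_oracle
        recon = emb.U @ emb.V
        np.testing.assert_allclose(recon, recon_oracle, atol=1e-8)
        # Principal angles between spans are ~0.
        cross = emb.V @ V_oracle.T
        sv = np.linalg.svd(cross, compute_uv=False)
        np.testing.assert_allclose(sv, 1.0, atol=1e-8)

    def test_r2_non_decreasing_in_k(self, rng):
        Y = rng.normal(size=(40, 30))
        r = [pca_embed(Y, k=k).r2_per_cell for k in (1, 2, 3)]
        assert np.all(r[1] >= r[0] - 1e-12) and np.all(r[2] >= r[1] - 1e-12)

    def test_row_permutation_equivariance(self, rng):
        Y = rng.normal(size=(20, 15))
        perm = rng.permutation(20)
        a = pca_embed(Y, k=2)
        b = pca_embed(Y[perm], k=2)
        # Components are sign-ambiguous; compare reconstructions.
        np.testing.assert_allclose((a.U @ a.V)[perm], b.U @ b.V, atol=1e-10)

    def test_too_few_rows(self):
        with pytest.raises(ValueError):
            pca_embed(np.zeros((1, 5)), k=2)


class TestKsTargetTest:
    def test_disjoint_supports(self, rng):
        pc1 = np.concatenate([rng.uniform(0, 1, 30), rng.uniform(5, 6, 30)])
        mask = np.arange(60) < 30
        stat, p = ks_target_test(pc1, mask)
        assert stat == 1.0 and p < 1e-6

    def test_all_cells_target_invalid(self, rng):
        with pytest.raises(ValueError):
            ks_target_test(rng.normal(size=10), np.ones(10, dtype=bool))

    def test_null_calibration(self, rng):
        hits = 0
        n_rep = 300
        for _ in range(n_rep):
            pc1 = rng.normal(size=80)
            mask = np.zeros(80, dtype=bool)
            mask[rng.choice(80, 40, replace=False)] = True
            hits += ks_target_test(pc1, mask)[1] < 0.05
        assert hits / n_rep < 0.05 + 3 * np.sqrt(0.05 * 0.95 / n_rep)


class TestDistancePermutation:
    def test_null_groups_not_significant(self, rng):
        U = rng.normal(size=(120, 2))
        labels = np.repeat(list("abcd"), 30)
        res = distance_permutation_test(U, labels, n_perm=500, seed=0)
        assert (res["p_value"] > 0.01).all()

    def test_displaced_group_detected(self, rng):
        U = rng.normal(size=(80, 2))
        labels = np.repeat(list("ab"), 40)
        U[labels == "a"] += 5.0
        res = distance_permutation_test(U, labels, n_perm=500, seed=0)
        assert res.loc["a", "p_value"] <= 1 / 501 + 1e-12

    def test_zero_permutations_invalid(self, rng):
        with pytest.raises(ValueError):
            distance_permutation_test(rng.normal(size=(10, 2)), ["a"] * 5 + ["b"] * 5, 0)


class TestFisher:
    def test_boundary_all_ones(self):
        X, p = fisher_combine([1.0, 1.0])
        assert X == 0.0 and p == 1.0

    def test_two_p05_example(self):
        X, p = fisher_combine([0.05, 0.05])
        assert X == pytest.approx(11.9829, abs=1e-3)
        assert p == pytest.approx(0.017479, abs=1e-6)

    def test_subsampled_identical_groups(self):
        pc1 = np.full(40, 2.0)
        mask = np.arange(40) < 15
        res = subsampled_ks_fisher(pc1, mask, n_samplings=10, seed=0)
        assert res.chi2 == 0.0 and res.p_value == 1.0

    def test_subsampled_undetermined(self):
        res = subsampled_ks_fisher(np.arange(5.0), np.array([True] + [False] * 4), 10)
        assert np.isnan(res.p_value)

    def test_subsampled_separated_groups_significant(self, rng):
        pc1 = np.concatenate([rng.normal(0, 1, 50), rng.normal(6, 1, 50)])
        mask = np.arange(100) < 50
        res = subsampled_ks_fisher(pc1, mask, n_samplings=20, seed=1)
        assert res.p_value < 1e-10


def test_region_separation_lab_homogeneity():
    """Distinct region response templates separate in the embedding while
    balanced labs do not: the qualitative cross-lab headline."""
    cfg = SynthConfig(
        seed=77,
        n_labs=6,
        mice_per_lab=1,
        units_per_region={r: 5 for r in REGIONS},
        n_trials=100,
        n_channels=16,
    )
    pop = gen_multilab_population(cfg)
    pm = build_peth_matrix(pop)
    emb = pca_embed(pm.Y, k=2)
    grid = ks_test_grid(
        emb.U[:, 0],
        pm.cell_meta["lab"].to_numpy(),
        pm.cell_meta["region"].to_numpy(),
    )
    region_p = grid.loc["all", list(REGIONS)]
    lab_p = grid.loc[[f"lab_{i:02d}" for i in range(6)], "all"]
    assert (region_p < 0.01).all()
    assert (lab_p < 0.01).sum() <= 1
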