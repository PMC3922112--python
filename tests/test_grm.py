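"""GRM estimation, relatedness pruning, and the interaction mask."""

import itertools

import numpy as np
import pandas as pd
import pytest

from gxeherit import (
    EnvFactor,
    GenotypeMatrix,
    GRMatrix,
    SimConfig,
    compute_grm,
    gxe_grm,
    prune_related,
    read_grm,
    simulate_genotypes,
    spike_relatives,
    write_grm,
)


def _single_snp(dosages):
    snps = pd.DataFrame(
        {"chrom": "1", "snp_id": ["v1"], "cm": 0.0, "pos": [1], "a1": "A", "a2": "B"}
    )
    ids = [f"s{i}" for i in range(len(dosages))]
    return GenotypeMatrix(np.array(dosages, dtype=float)[:, None], ids, snps)


def _grm_from(values, ids=None):
    values = np.asarray(values, dtype=float)
    ids = ids or [f"s{i}" for i in range(len(values))]
    return GRMatrix(values, ids, np.full(values.shape, 100))


class TestComputeGrm:
    def test_hand_computed_entries_single_snp(self):
        # dosages 2,0,1,1 -> sample p = 0.5; hand-evaluate the estimator
        G = _single_snp([2, 0, 1, 1])
        A = compute_grm(G)
        # (2-1)(0-1)/(2*0.5*0.5) = -2 for the (hom, hom) pair
        assert A.values[0, 1] == pytest.approx(-2.0)
        # centered het dosage is zero
        assert A.values[2, 3] == pytest.approx(0.0)
        # diagonal uses the same formula: (2-1)^2/0.5 = 2
        assert A.values[0, 0] == pytest.approx(2.0)

    def test_unrelated_cohort_diagonal_near_one(self):
        n = 500
        G = simulate_genotypes(SimConfig(n_individuals=n, n_snps=5000, seed=7))
        A = compute_grm(G)
        diag = A.values.diagonal()
        assert abs(diag.mean() - 1.0) < 0.02
        # sample-frequency centering forces the off-diagonal mean to
        # -mean(diag)/(n-1); deviations beyond that are sampling noise
        off = A.values[np.triu_indices(n, k=1)]
        expected = -diag.mean() / (n - 1)
        assert abs(off.mean() - expected) < 3.0 / np.sqrt(len(off) * 5000)

    def test_invariant_to_snp_order(self, small_cohort):
        _, G, _, _, _ = small_cohort
        A1 = compute_grm(G)
        perm = np.random.default_rng(0).permutation(G.n_snps)
        G2 = GenotypeMatrix(
            G.dosages[:, perm], list(G.sample_ids),
            G.snps.iloc[perm].reset_index(drop=True),
        )
        A2 = compute_grm(G2)
        np.testing.assert_allclose(A1.values, A2.values, atol=1e-10)

    def test_equivariant_to_sample_permutation(self, small_cohort):
        _, G, _, _, _ = small_cohort
        A1 = compute_grm(G)
        perm = np.random.default_rng(1).permutation(G.n_samples)
        G2 = GenotypeMatrix(
            G.dosages[perm], [G.sample_ids[i] for i in perm], G.snps
        )
        A2 = compute_grm(G2)
        np.testing.assert_allclose(A2.values, A1.values[np.ix_(perm, perm)], atol=1e-10)

    def test_monomorphic_snp_excluded_with_warning(self):
        dos = np.column_stack([[0, 1, 2, 1], [0, 0, 0, 0]]).astype(float)
        snps = pd.DataFrame(
            {"chrom": "1", "snp_id": ["a", "b"], "cm": 0.0, "pos": [1, 2],
             "a1": "A", "a2": "B"}
        )
        G = GenotypeMatrix(dos, ["s1", "s2", "s3", "s4"], snps)
        with pytest.warns(UserWarning, match="monomorphic"):
            A = compute_grm(G)
        assert (A.n_snps_used == 1).all()

    def test_all_monomorphic_raises(self):
        G = _single_snp([2, 2, 2])
        with pytest.raises(ValueError, match="polymorphic"):
            compute_grm(G)

    def test_missing_handled_by_pairwise_counts(self):
        rng = np.random.default_rng(5)
        cfg = SimConfig(n_individuals=200, n_snps=500, missing_rate=0.1, seed=9)
        G = simulate_genotypes(cfg)
        A = compute_grm(G)
        assert (A.n_snps_used < 500).any()
        assert abs(A.values.diagonal().mean() - 1.0) < 0.05


class TestSpikedRelatives:
    @pytest.mark.parametrize("c", [0.5, 0.0])
    def test_grm_entry_matches_copy_fraction(self, c):
        G = simulate_genotypes(SimConfig(n_individuals=100, n_snps=5000, seed=13))
        G2 = spike_relatives(G, n_pairs=5, copy_fraction=c, seed=13)
        A = compute_grm(G2)
        entries = [A.values[2 * t, 2 * t + 1] for t in range(5)]
        assert np.mean(entries) == pytest.approx(c, abs=0.05)

    def test_clone_matches_diagonal(self):
        G = simulate_genotypes(SimConfig(n_individuals=20, n_snps=2000, seed=21))
        G2 = spike_relatives(G, n_pairs=1, copy_fraction=1.0, seed=21)
        A = compute_grm(G2)
        assert A.values[0, 1] == pytest.approx(A.values[0, 0], abs=1e-9)

    def test_invalid_fraction_rejected(self, small_cohort):
        _, G, _, _, _ = small_cohort
        with pytest.raises(ValueError):
            spike_relatives(G, 1, 1.5, 0)


class TestPruneRelated:
    def test_pair_drops_second_member(self):
        # related pair plus an unrelated bystander: the later-indexed
        # member of the pair is the one removed
        vals = np.array([[1.0, 0.03, 0.0], [0.03, 1.0, 0.0], [0.0, 0.0, 1.0]])
        assert prune_related(_grm_from(vals)) == ["s0", "s2"]

    def test_isolated_pair_cannot_prune_below_two(self):
        A = _grm_from([[1.0, 0.03], [0.03, 1.0]])
        with pytest.raises(ValueError, match="fewer than 2"):
            prune_related(A)

    def test_no_pairs_above_cutoff_noop(self):
        A = _grm_from([[1.0, 0.01, 0.0], [0.01, 1.0, 0.02], [0.0, 0.02, 1.0]])
        assert prune_related(A) == ["s0", "s1", "s2"]

    def test_hub_removed_first_matches_exhaustive_search(self):
        vals = np.eye(3)
        vals[0, 1] = vals[1, 0] = 0.05
        vals[0, 2] = vals[2, 0] = 0.05
        vals[1, 2] = vals[2, 1] = 0.01
        A = _grm_from(vals)
        retained = prune_related(A)
        assert retained == ["s1", "s2"]
        # brute force: the maximum retained set with no above-cutoff pair
        best = max(
            (
                s
                for r in range(1, 4)
                for s in itertools.combinations(range(3), r)
                if all(vals[i, j] <= 0.025 for i, j in itertools.combinations(s, 2))
            ),
            key=len,
        )
        assert [f"s{i}" for i in best] == retained

    def test_output_never_contains_above_cutoff_pair(self):
        rng = np.random.default_rng(17)
        n = 40
        vals = np.eye(n)
        for _ in range(60):
            i, j = rng.integers(0, n, 2)
            if i != j:
                vals[i, j] = vals[j, i] = rng.uniform(0, 0.08)
        A = _grm_from(vals)
        retained = prune_related(A, 0.025)
        idx = [A.sample_ids.index(s) for s in retained]
        sub = vals[np.ix_(idx, idx)]
        np.fill_diagonal(sub, 0.0)
        assert sub.max() <= 0.025

    def test_too_aggressive_cutoff_raises(self):
        A = _grm_from(np.full((3, 3), 0.9) + 0.1 * np.eye(3))
        with pytest.raises(ValueError, match="fewer than 2"):
            prune_related(A, 0.025)


class TestGxeMask:
    def test_single_environment_is_identity_mask(self, small_grm):
        env = EnvFactor("area", np.array(["1"] * small_grm.n, dtype=object))
        M = gxe_grm(small_grm, env)
        np.testing.assert_array_equal(M.values, small_grm.values)

    def test_cross_environment_entries_zero(self, small_grm, small_cohort):
        _, _, env, _, _ = small_cohort
        M = gxe_grm(small_grm, env)
        diff = env.levels[:, None] != env.levels[None, :]
        assert np.all(M.values[diff] == 0.0)
        same = ~diff
        np.testing.assert_array_equal(M.values[same], small_grm.values[same])

    def test_idempotent_and_complement_zero(self, small_grm, small_cohort):
        _, _, env, _, _ = small_cohort
        M = gxe_grm(small_grm, env)
        M2 = gxe_grm(M, env)
        np.testing.assert_array_equal(M.values, M2.values)
        diff = env.levels[:, None] != env.levels[None, :]
        assert np.all(M.values * diff == 0.0)

    def test_commutes_with_permutation(self, small_grm, small_cohort):
        _, _, env, _, _ = small_cohort
        perm = np.random.default_rng(3).permutation(small_grm.n)
        A_p = GRMatrix(
            small_grm.values[np.ix_(perm, perm)],
            [small_grm.sample_ids[i] for i in perm],
            small_grm.n_snps_used[np.ix_(perm, perm)],
        )
        env_p = EnvFactor(env.name, env.levels[perm])
        M_then_perm = gxe_grm(small_grm, env).values[np.ix_(perm, perm)]
        perm_then_M = gxe_grm(A_p, env_p).values
        np.testing.assert_array_equal(M_then_perm, perm_then_M)


class TestGrmIO:
    def test_text_round_trip(self, tmp_path, small_grm):
        write_grm(small_grm, tmp_path / "g")
        B = read_grm(tmp_path / "g")
        np.testing.assert_allclose(B.values, small_grm.values, atol=1e-9)
        assert B.sample_ids == small_grm.sample_ids
        np.testing.assert_array_equal(B.n_snps_used, small_grm.n_snps_used)
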