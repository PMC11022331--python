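"""Generator correctness: LD construction, the matrix-normal z model, masks."""

import numpy as np
import pytest

from omnigwas import (
    AncestryDesign,
    LDSpec,
    StudyTruth,
    default_hematological_study,
    exchangeable_omega,
    heterogeneous_ld_blocks,
    make_ld_matrix,
    simulate_study,
    simulate_z_panel,
)
from omnigwas.ldtools import dense_from_blocks


class TestMakeLdMatrix:
    def test_zero_decay_gives_identity_blocks(self):
        blocks = make_ld_matrix(LDSpec(n_snps=10, block_sizes=[4, 6],
                                       within_block_decay=0.0))
        for b in blocks:
            np.testing.assert_array_equal(b.corr, np.eye(b.n_snps))

    def test_ar1_closed_form_entry(self):
        (block,) = make_ld_matrix(LDSpec(n_snps=3, block_sizes=[3],
                                         within_block_decay=0.9))
        assert block.corr[0, 2] == pytest.approx(0.81)
        assert np.allclose(np.diag(block.corr), 1.0)

    def test_large_block_positive_definite(self):
        (block,) = make_ld_matrix(LDSpec(n_snps=50, block_sizes=[50],
                                         within_block_decay=0.5))
        eigvals = np.linalg.eigvalsh(block.corr)
        assert eigvals[0] > 0

    def test_decay_of_one_rejected(self):
        with pytest.raises(ValueError, match="positive definite"):
            LDSpec(n_snps=4, block_sizes=[4], within_block_decay=1.0)

    def test_block_sizes_must_sum(self):
        with pytest.raises(ValueError, match="sum"):
            LDSpec(n_snps=5, block_sizes=[2, 2])

    def test_heterogeneous_blocks_widen_ld_score_spread(self):
        from omnigwas import ld_scores

        blocks = heterogeneous_ld_blocks(2000, block_size=50,
                                         decay_range=(0.2, 0.95), seed=1)
        scores = ld_scores(blocks)
        assert scores.min() >= 1.0
        assert scores.max() / scores.min() > 3.0


def _null_truth(n_snps, omega, n=1e4):
    k = omega.shape[0]
    return StudyTruth(gamma=np.zeros((n_snps, k)), omega_true=omega,
                      sample_sizes=np.full(k, n))


class TestSimulateZPanel:
    def test_null_marginal_variance_near_one(self):
        # gamma=0, omega=I, R=I: marginal z is standard normal
        n = 100_000
        blocks = make_ld_matrix(LDSpec(n_snps=n, block_sizes=[1000] * 100,
                                       within_block_decay=0.0))
        panel = simulate_z_panel(blocks, _null_truth(n, np.eye(2)), seed=11)
        assert panel.z.var(axis=0) == pytest.approx(1.0, abs=0.03)
        assert panel.z.mean(axis=0) == pytest.approx(0.0, abs=0.02)

    def test_cross_trait_correlation_matches_omega(self):
        n = 100_000
        omega = exchangeable_omega(2, 0.5)
        blocks = make_ld_matrix(LDSpec(n_snps=n, block_sizes=[1000] * 100,
                                       within_block_decay=0.0))
        panel = simulate_z_panel(blocks, _null_truth(n, omega), seed=12)
        r = np.corrcoef(panel.z.T)[0, 1]
        assert r == pytest.approx(0.5, abs=0.02)

    def test_causal_snp_mean_is_sqrt_n_gamma(self):
        # R=I, one causal SNP replicated 10^4 times: mean z = sqrt(N) gamma
        n_reps, gamma_val, n_samp = 10_000, 0.05, 1e4
        blocks = make_ld_matrix(LDSpec(n_snps=n_reps, block_sizes=[500] * 20,
                                       within_block_decay=0.0))
        gamma = np.full((n_reps, 1), gamma_val)
        truth = StudyTruth(gamma=gamma, omega_true=np.eye(1),
                           sample_sizes=np.array([n_samp]))
        panel = simulate_z_panel(blocks, truth, seed=13)
        expected = np.sqrt(n_samp) * gamma_val
        assert panel.z.mean() == pytest.approx(expected, abs=3.0 / np.sqrt(n_reps) * 10)

    def test_ld_convolves_the_mean(self):
        # a causal SNP leaks signal into its LD neighbors through R @ Gamma
        blocks = make_ld_matrix(LDSpec(n_snps=5, block_sizes=[5],
                                       within_block_decay=0.9))
        gamma = np.zeros((5, 1))
        gamma[2, 0] = 0.1
        truth = StudyTruth(gamma=gamma, omega_true=np.eye(1),
                           sample_sizes=np.array([1e4]))
        reps = np.stack([
            simulate_z_panel(blocks, truth, seed=s).z[:, 0] for s in range(3000)
        ])
        mean = reps.mean(axis=0)
        expected = blocks[0].corr @ (gamma[:, 0] * 100.0)
        np.testing.assert_allclose(mean, expected, atol=0.15)

    def test_kronecker_covariance_structure(self):
        # empirical covariance of vec(Z) matches Omega (x) R entrywise
        n_snps, k, n_reps = 10, 3, 10_000
        omega = np.array([[1.0, 0.5, 0.2], [0.5, 1.0, 0.3], [0.2, 0.3, 1.0]])
        blocks = make_ld_matrix(LDSpec(n_snps=n_snps, block_sizes=[n_snps],
                                       within_block_decay=0.6))
        truth = _null_truth(n_snps, omega)
        draws = np.stack([
            simulate_z_panel(blocks, truth, seed=s).z.ravel(order="F")
            for s in range(n_reps)
        ])
        empirical = np.cov(draws.T)
        expected = np.kron(omega, blocks[0].corr)
        assert np.abs(empirical - expected).max() < 0.06

    def test_seed_reproducibility(self):
        blocks = make_ld_matrix(LDSpec(n_snps=20, block_sizes=[20],
                                       within_block_decay=0.5))
        truth = _null_truth(20, np.eye(2))
        z1 = simulate_z_panel(blocks, truth, seed=5).z
        z2 = simulate_z_panel(blocks, truth, seed=5).z
        np.testing.assert_array_equal(z1, z2)

    def test_non_positive_definite_omega_names_eigenvalue(self):
        bad = np.array([[1.0, 1.1], [1.1, 1.0]])
        with pytest.raises(ValueError, match="eigenvalue"):
            StudyTruth(gamma=np.zeros((4, 2)), omega_true=bad,
                       sample_sizes=np.array([100.0, 100.0]))


class TestSimulateStudy:
    def test_mask_removes_snp_from_one_ancestry_only(self):
        spec = LDSpec(n_snps=6, block_sizes=[3, 3], within_block_decay=0.5)
        mask_a = np.array([True, False, True, True, True, True])
        truth_a = StudyTruth(gamma=np.zeros((6, 2)), omega_true=np.eye(2),
                             sample_sizes=np.array([1e3, 1e3]),
                             ancestry_masks={"A": mask_a})
        truth_b = StudyTruth(gamma=np.zeros((6, 2)), omega_true=np.eye(2),
                             sample_sizes=np.array([1e3, 1e3]))
        study = simulate_study(
            [AncestryDesign("A", spec, truth_a), AncestryDesign("B", spec, truth_b)],
            seed=3,
        )
        assert study.panels["A"].n_snps == 5
        assert study.panels["B"].n_snps == 6
        assert "rs2" not in study.panels["A"].snps.index
        assert "rs2" in study.panels["B"].snps.index

    def test_mask_emptying_a_block_rejected(self):
        spec = LDSpec(n_snps=4, block_sizes=[2, 2], within_block_decay=0.5)
        mask = np.array([True, True, False, False])
        truth = StudyTruth(gamma=np.zeros((4, 1)), omega_true=np.eye(1),
                           sample_sizes=np.array([1e3]),
                           ancestry_masks={"A": mask})
        with pytest.raises(ValueError, match="block"):
            simulate_study([AncestryDesign("A", spec, truth)], seed=1)

    def test_shared_causal_snp_correlates_across_ancestries(self):
        # SNP-varying shared effects induce cross-ancestry z correlation
        spec = LDSpec(n_snps=200, block_sizes=[10] * 20, within_block_decay=0.0)
        rng = np.random.default_rng(99)
        gamma = np.zeros((200, 1))
        gamma[::10, 0] = rng.normal(0.0, 0.05, size=20)  # sd(sqrt(N) gamma) = 5
        z_a, z_b = [], []
        for s in range(200):
            truth = StudyTruth(gamma=gamma, omega_true=np.eye(1),
                               sample_sizes=np.array([1e4]))
            study = simulate_study(
                [AncestryDesign("A", spec, truth), AncestryDesign("B", spec, truth)],
                seed=s,
            )
            z_a.append(study.panels["A"].z[::10, 0])
            z_b.append(study.panels["B"].z[::10, 0])
        r = np.corrcoef(np.concatenate(z_a), np.concatenate(z_b))[0, 1]
        # shared-mean variance 25 against unit noise: rho = 25/26
        assert r > 0.9

    def test_empty_design_rejected(self):
        with pytest.raises(ValueError, match="ancestry"):
            simulate_study([], seed=0)

    def test_default_study_shape(self):
        designs = default_hematological_study(n_snps=300, block_size=30, seed=1)
        study = simulate_study(designs, seed=1)
        assert set(study.panels) == {"EUR", "EAS", "AFR", "AMR"}
        assert study.panels["EUR"].n_traits == 15
        assert study.panels["EAS"].n_traits == 13  # two traits missing
        assert study.panels["AFR"].n_snps < 300  # availability mask applied
        assert study.panels["EUR"].n_snps == 300
        assert len(study.causal_positions("EUR")) >= 1
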