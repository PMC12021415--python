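"""RDM construction, alignment, model regression, human-network comparison."""

import numpy as np
import pandas as pd
import pytest

from flexwm import rsa, task_design as td
from flexwm.rsa import RDM


class TestNeuralRdm:
    def test_rdm_basic_properties(self, rdm_dataset):
        rdm = rsa.neural_rdm(rdm_dataset, [11, 12], "maintenance")
        m = rdm.matrix
        assert m.shape == (30, 30)
        assert np.allclose(m, m.T)
        assert np.allclose(np.diag(m), 0.0)
        assert np.all(m >= -1e-9) and np.all(m <= 2 + 1e-9)

    def test_identical_and_anticorrelated_patterns(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=12)
        pat = np.stack([base, base, -base, -base])
        m, conds = rsa.pairwise_condition_rdm(pat, np.array([10, 10, 40, 40]))
        assert m[0, 1] == pytest.approx(2.0)  # anti-correlated conditions
        assert conds.tolist() == [10, 40]

    def test_missing_orientation_rejected(self, rdm_dataset, noiseless_dataset):
        with pytest.raises(rsa.RdmError):
            rsa.neural_rdm(rdm_dataset, [12], "nonexistent-task")
        # single trial per orientation is not enough for trial-pair averaging
        with pytest.raises(rsa.RdmError):
            rsa.neural_rdm(noiseless_dataset, [12], "maintenance")

    def test_graded_structure_increases_with_distance(self, rdm_dataset):
        rdm = rsa.neural_rdm(rdm_dataset, [12], "maintenance")
        ori = rdm.orientations
        from flexwm import circ

        d = circ.distance(ori[None, :], ori[:, None])
        iu = np.triu_indices(30, 1)
        r = np.corrcoef(d[iu], rdm.matrix[iu])[0, 1]
        assert r > 0.7  # tuning makes dissimilarity grow with orientation distance


class TestAlignment:
    def test_category_alignment_order_rule_a(self, rdm_dataset):
        rdm = rsa.neural_rdm(rdm_dataset, [12], "categorization", rule="A")
        aligned = rsa.align_rdm(rdm, "category", td.RULE_A)
        assert aligned.orientations[0] == 22 and aligned.orientations[14] == 106
        assert aligned.orientations[15] == 112 and aligned.orientations[-1] == 16
        labels = td.category_labels(aligned.orientations, td.RULE_A)
        assert set(labels[:15]) == {1} and set(labels[15:]) == {2}

    def test_alignment_idempotent_and_permutation(self, rdm_dataset):
        rdm = rsa.neural_rdm(rdm_dataset, [12], "categorization", rule="A")
        a1 = rsa.align_rdm(rdm, "category", td.RULE_A)
        a2 = rsa.align_rdm(a1, "category", td.RULE_A)
        assert np.array_equal(a1.matrix, a2.matrix)
        assert np.allclose(np.sort(a1.offdiag()), np.sort(rdm.offdiag()))

    def test_stimulus_alignment_of_sorted_rdm_is_identity(self):
        rng = np.random.default_rng(1)
        m = rng.random((5, 5))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0)
        rdm = RDM(m, np.array([10.0, 30, 50, 70, 90]))
        out = rsa.align_rdm(rdm, "stimulus")
        assert np.array_equal(out.matrix, rdm.matrix)


class TestModelRdms:
    def test_category_model_cells(self, grid30):
        models = rsa.model_rdms(td.RULE_A, grid30)
        cat = models["abstract_category"]
        i22 = np.where(cat.orientations == 22)[0][0]
        i106 = np.where(cat.orientations == 106)[0][0]
        i112 = np.where(cat.orientations == 112)[0][0]
        assert cat.matrix[i22, i106] == 0.0
        assert cat.matrix[i22, i112] == 1.0

    def test_graded_and_discrete_forms(self, grid30):
        models = rsa.model_rdms(td.RULE_A, grid30)
        g, d = models["graded_stimulus"], models["discrete_stimulus"]
        assert np.all(np.diag(g.matrix) == 0)
        assert g.matrix.max() <= 1.0
        assert np.array_equal(d.matrix, 1.0 - np.eye(30))
        # graded increases with circular distance
        from flexwm import circ

        dist = circ.distance(g.orientations[None, :], g.orientations[:, None])
        assert np.allclose(g.matrix, dist / 90.0)


def _synthetic_subject_rdms(n_subjects, coefs, noise_sd, grid, seed=0):
    """RDMs built as known mixtures of the model RDMs plus symmetric noise."""
    rng = np.random.default_rng(seed)
    models = rsa.model_rdms(td.RULE_A, grid)
    names = list(models)
    out = []
    for s in range(n_subjects):
        m = sum(c * models[n].matrix for c, n in zip(coefs, names))
        noise = rng.normal(0, noise_sd, size=m.shape)
        noise = (noise + noise.T) / 2
        np.fill_diagonal(noise, 0)
        m = m + noise + rng.normal(0, 0.05)  # subject-level offset
        out.append(RDM((m + m.T) / 2, models[names[0]].orientations))
    return out, models


class TestLmem:
    def test_parameter_recovery(self, grid30):
        rdms, models = _synthetic_subject_rdms(12, (2.0, 0.0, 1.0), 0.1, grid30, seed=3)
        fit = rsa.fit_lmem(rdms, models)
        coefs = fit.set_index("model")["coef"]
        assert abs(coefs["graded_stimulus"] - 2.0) < 0.2
        assert abs(coefs["discrete_stimulus"]) < 0.2
        assert abs(coefs["abstract_category"] - 1.0) < 0.2

    def test_selectivity_on_single_model_data(self, grid30):
        rdms, models = _synthetic_subject_rdms(10, (0.0, 0.0, 1.5), 0.1, grid30, seed=4)
        fit = rsa.fit_lmem(rdms, models).set_index("model")
        assert fit.loc["abstract_category", "p_value"] < 1e-4
        assert abs(fit.loc["graded_stimulus", "coef"]) < 0.15

    def test_too_few_subjects_rejected(self, grid30):
        rdms, models = _synthetic_subject_rdms(2, (1, 0, 0), 0.1, grid30)
        with pytest.raises(rsa.RdmError):
            rsa.fit_lmem(rdms, models)


class TestComparison:
    def test_identical_matrices_tau_one(self, grid30):
        rdms, models = _synthetic_subject_rdms(5, (1.0, 0.2, 0.5), 0.0, grid30)
        taus, p = rsa.rdm_similarity(rdms, rdms[0])
        assert np.allclose(taus, 1.0)
        assert p < 0.05

    def test_independent_matrices_tau_near_zero(self, grid30):
        rng = np.random.default_rng(9)
        subj = []
        for s in range(8):
            m = rng.random((30, 30))
            m = (m + m.T) / 2
            np.fill_diagonal(m, 0)
            subj.append(RDM(m, np.sort(grid30.values)))
        m = rng.random((30, 30))
        ref = RDM((m + m.T) / 2 - np.diag(np.diag(m)), np.sort(grid30.values))
        taus, p = rsa.rdm_similarity(subj, ref)
        assert abs(np.mean(taus)) < 0.1
        assert p > 0.05

    def test_mean_rdm_reference_positive_tau(self, grid30):
        rdms, _ = _synthetic_subject_rdms(8, (1.5, 0.0, 0.8), 0.15, grid30, seed=6)
        ref = rsa.average_rdms(rdms)
        taus, p = rsa.rdm_similarity(rdms, ref)
        assert np.all(taus > 0)
        assert p < 0.01

    def test_network_contrast_sign_flip(self, grid30):
        rdms, models = _synthetic_subject_rdms(10, (2.0, 0.0, 0.0), 0.2, grid30, seed=8)
        good = rsa.average_rdms(rdms)
        rng = np.random.default_rng(3)
        m = rng.random((30, 30))
        bad = RDM((m + m.T) / 2 - np.diag(np.diag(m)), good.orientations)
        out = rsa.compare_rdms(rdms, good, other_network_rdm=bad, n_iter=1000, seed=0)
        assert out["mean_tau"] > 0.3
        assert out["contrast"]["mean_z_diff"] > 0
        assert out["contrast"]["p_value"] < 0.05


class TestConditionMatching:
    def test_mixed_grids_pair_within_tolerance(self):
        rng = np.random.default_rng(2)
        human = np.sort(np.arange(4.0, 180, 6))     # 30 conditions
        network = np.arange(0.0, 180, 9)            # 20 conditions
        def rand_rdm(ori):
            m = rng.random((len(ori), len(ori)))
            m = (m + m.T) / 2
            np.fill_diagonal(m, 0)
            return RDM(m, ori)
        ra, rb = rsa.match_conditions(rand_rdm(human), rand_rdm(network))
        assert len(ra.orientations) == len(rb.orientations) > 0
        from flexwm import circ
        assert np.all(circ.distance(ra.orientations, rb.orientations) <= 4.5)
        # matched sub-RDMs are comparable
        taus, _ = rsa.rdm_similarity([ra], rb)
        assert -1 <= taus[0] <= 1

    def test_identical_grids_match_fully(self):
        ori = np.arange(0.0, 180, 9)
        m = np.zeros((20, 20))
        rdm = RDM(m, ori)
        ra, rb = rsa.match_conditions(rdm, rdm)
        assert np.array_equal(ra.orientations, rb.orientations)
        assert len(ra.orientations) == 20

    def test_disjoint_grids_raise(self):
        a = RDM(np.zeros((3, 3)), np.array([0.0, 60.0, 120.0]))
        b = RDM(np.zeros((3, 3)), np.array([30.0, 90.0, 150.0]))
        with pytest.raises(rsa.RdmError):
            rsa.match_conditions(a, b, tol=5.0)
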