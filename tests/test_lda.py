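"""Fisher LDA over PC scores, class densities, contact-space back-mapping."""

import numpy as np
import pytest
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from contactmodes import lda as cl
from contactmodes import pca as cp
from contactmodes.pca import PCABasis, ScoreMatrix
from oracles import gaussian_overlap


def labeling_two(n_a, n_b, names=("A", "B")):
    return cl.ClassLabeling(condition="cond", classes=list(names),
                            assignment=np.array([0] * n_a + [1] * n_b))


class TestFit:
    def test_axis_aligned_two_clouds(self, rng):
        x = np.concatenate([rng.normal(-1, 0.2, 50), rng.normal(1, 0.2, 50)])
        model = cl.fit_lda(ScoreMatrix(scores=x[:, None]), labeling_two(50, 50))
        assert model.n_discriminants == 1
        np.testing.assert_allclose(np.abs(model.C), [[1.0]])
        assert model.class_means_on_LD[0, 0] < model.class_means_on_LD[1, 0]

    def test_shift_on_single_pc_dominates_coefficients(self, rng):
        S = rng.normal(size=(400, 8))
        S[200:, 2] += 5.0  # classes differ only along PC3
        model = cl.fit_lda(ScoreMatrix(scores=S), labeling_two(200, 200))
        c = np.abs(model.C[0])
        assert np.argmax(c) == 2 and c[2] > 2 * np.delete(c, 2).max()

    def test_three_classes_give_two_discriminants(self, rng):
        S = rng.normal(size=(150, 4))
        S[:50, 0] += 3
        S[100:, 1] += 3
        lab = cl.ClassLabeling("cond", ["a", "b", "c"],
                               np.repeat([0, 1, 2], 50))
        model = cl.fit_lda(ScoreMatrix(scores=S), lab)
        assert model.n_discriminants == 2

    def test_matches_sklearn_eigen_solver_direction(self, rng):
        """Independent cross-check: LD1 collinear with sklearn's scaling."""
        S = rng.normal(size=(300, 5))
        S[150:] += rng.normal(1.0, 0.1, size=5)
        lab = labeling_two(150, 150)
        model = cl.fit_lda(ScoreMatrix(scores=S), lab)
        sk = LinearDiscriminantAnalysis(solver="eigen").fit(S, lab.assignment)
        w = sk.scalings_[:, 0]
        cos = abs(model.C[0] @ w) / np.linalg.norm(w)
        assert cos == pytest.approx(1.0, abs=1e-6)

    def test_too_many_classes_rejected(self, rng):
        S = rng.normal(size=(40, 2))
        lab = cl.ClassLabeling("cond", ["a", "b", "c", "d"],
                               np.repeat([0, 1, 2, 3], 10))
        with pytest.raises(ValueError):
            cl.fit_lda(ScoreMatrix(scores=S), lab)

    def test_rotation_invariance_of_ld_scores(self, rng):
        """LD scores unchanged (up to sign) under joint orthogonal rotation."""
        S = rng.normal(size=(200, 4))
        S[100:, 0] += 3.0
        lab = labeling_two(100, 100)
        Q, _ = np.linalg.qr(rng.normal(size=(4, 4)))
        m1 = cl.fit_lda(ScoreMatrix(scores=S), lab)
        m2 = cl.fit_lda(ScoreMatrix(scores=S @ Q), lab)
        ld1 = cl.lda_scores(m1, ScoreMatrix(scores=S))
        ld2 = cl.lda_scores(m2, ScoreMatrix(scores=S @ Q))
        np.testing.assert_allclose(np.abs(ld1), np.abs(ld2), atol=1e-8)

    def test_uninformative_extra_pc_barely_changes_separation(self, rng):
        S = rng.normal(size=(2000, 8))
        S[1000:, 0] += 4.0
        lab = labeling_two(1000, 1000)

        def separation(scores):
            m = cl.fit_lda(ScoreMatrix(scores=scores), lab)
            ld = cl.lda_scores(m, ScoreMatrix(scores=scores))[:, 0]
            a, b = ld[:1000], ld[1000:]
            pooled = np.sqrt((a.var(ddof=1) + b.var(ddof=1)) / 2)
            return abs(a.mean() - b.mean()) / pooled

        s8 = separation(S)
        s9 = separation(np.column_stack([S, rng.normal(size=2000)]))
        assert abs(s9 - s8) / s8 < 0.05


class TestScores:
    def test_linearity_zero_row(self, rng):
        S = rng.normal(size=(50, 3))
        S[25:] += 2
        model = cl.fit_lda(ScoreMatrix(scores=S), labeling_two(25, 25))
        assert cl.lda_scores(model, ScoreMatrix(scores=np.zeros((1, 3))))[0, 0] == 0

    def test_identity_coefficients_reproduce_pc_scores(self, rng):
        S = rng.normal(size=(10, 3))
        model = cl.LDAModel(C=np.eye(3), n_discriminants=3,
                            class_means_on_LD=np.zeros((2, 3)),
                            condition="c", classes=["a", "b"])
        np.testing.assert_allclose(cl.lda_scores(model, ScoreMatrix(scores=S)), S)

    def test_dimension_mismatch_rejected(self, rng):
        S = rng.normal(size=(50, 3))
        S[25:] += 2
        model = cl.fit_lda(ScoreMatrix(scores=S), labeling_two(25, 25))
        with pytest.raises(ValueError):
            cl.lda_scores(model, ScoreMatrix(scores=S[:, :2]))


class TestBackMap:
    def _basis(self, D):
        return PCABasis(mean_vector=np.zeros(D), loadings=np.eye(D),
                        eigenvalues=np.linspace(2, 1, D), D=D, n_frames_fit=10)

    def test_unit_coefficient_reproduces_pc_map(self):
        pairs = [(0, 1), (0, 2), (1, 2)]
        model = cl.LDAModel(C=np.array([[1.0, 0.0, 0.0]]), n_discriminants=1,
                            class_means_on_LD=np.zeros((2, 1)),
                            condition="c", classes=["a", "b"])
        m = cl.ld_loading_in_contact_space(model, self._basis(3), pairs, 3, 1)
        pc1 = cp.loading_to_contact_map(self._basis(3).loadings[:, 0], pairs, 3)
        np.testing.assert_allclose(m.matrix, pc1.matrix)

    def test_orthonormal_combination_has_unit_norm(self):
        pairs = [(0, 1), (0, 2), (1, 2)]
        model = cl.LDAModel(C=np.array([[0.6, 0.8, 0.0]]), n_discriminants=1,
                            class_means_on_LD=np.zeros((2, 1)),
                            condition="c", classes=["a", "b"])
        m = cl.ld_loading_in_contact_space(model, self._basis(3), pairs, 3, 1)
        vec = cp.contact_map_to_vector(m, pairs)
        assert np.linalg.norm(vec) == pytest.approx(1.0)

    def test_pc_count_mismatch_rejected(self):
        model = cl.LDAModel(C=np.ones((1, 5)), n_discriminants=1,
                            class_means_on_LD=np.zeros((2, 1)),
                            condition="c", classes=["a", "b"])
        with pytest.raises(ValueError):
            cl.ld_loading_in_contact_space(model, self._basis(3),
                                           [(0, 1)] * 3, 3, 1)


class TestDensities:
    def test_identical_classes_overlap_one(self, rng):
        x = rng.normal(size=200)
        scores = np.concatenate([x, x])
        dens = cl.class_score_density(scores, labeling_two(200, 200))
        assert cl.overlap_coefficient(dens, "A", "B") == pytest.approx(1.0, abs=1e-9)

    def test_each_class_integrates_to_one(self, rng):
        scores = np.concatenate([rng.normal(0, 1, 300), rng.normal(4, 2, 300)])
        dens = cl.class_score_density(scores, labeling_two(300, 300))
        for f in dens.densities.values():
            assert np.trapezoid(f, dens.grid) == pytest.approx(1.0, abs=1e-6)

    def test_distant_classes_barely_overlap(self, rng):
        scores = np.concatenate([rng.normal(0, 1, 500), rng.normal(10, 1, 500)])
        dens = cl.class_score_density(scores, labeling_two(500, 500))
        assert cl.overlap_coefficient(dens, "A", "B") < 0.01

    def test_gaussian_overlap_closed_form(self, rng):
        """KDE overlap of N(0,1) vs N(2,1) approaches 2*Phi(-1)."""
        n = 50000  # Silverman bandwidth ~0.1 here; KDE smoothing bias ~0.003
        scores = np.concatenate([rng.normal(0, 1, n), rng.normal(2, 1, n)])
        dens = cl.class_score_density(scores, labeling_two(n, n))
        want = gaussian_overlap(0, 1, 2, 1)  # = 0.3173...
        assert cl.overlap_coefficient(dens, "A", "B") == pytest.approx(want, abs=0.01)

    def test_degenerate_class_warns(self):
        scores = np.concatenate([np.zeros(10), np.ones(10)])
        with pytest.warns(UserWarning, match="degenerate"):
            cl.class_score_density(scores, labeling_two(10, 10))

    def test_labeling_validation(self):
        with pytest.raises(ValueError):
            # a class with fewer than 2 frames is unusable
            cl.ClassLabeling("c", ["a", "b"], np.array([0, 0, 0, 1]))
        with pytest.raises(ValueError, match="2 classes"):
            # single-class labeling is valid metadata but not fittable
            lab = cl.ClassLabeling("c", ["only"], np.zeros(4, dtype=int))
            cl.fit_lda(ScoreMatrix(scores=np.zeros((4, 2))), lab)
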