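import numpy as np
import pytest

from mcri.factor_models import (
    FactorModel,
    cfa_fit,
    parallel_analysis,
    principal_axis,
    promax,
    prune_items,
    varimax,
    vss_criterion,
)
from mcri.synthetic import TABLE_LOADINGS


def align_columns(est: np.ndarray, truth: np.ndarray) -> np.ndarray:
    """Resolve the column permutation/sign indeterminacy of a factor solution."""
    k = truth.shape[1]
    cong = np.zeros((k, k))
    for a in range(k):
        for b in range(k):
            cong[a, b] = est[:, a] @ truth[:, b] / np.sqrt(
                (est[:, a] @ est[:, a]) * (truth[:, b] @ truth[:, b])
            )
    order = np.argmax(np.abs(cong), axis=0)
    assert len(set(order)) == k, "columns could not be matched one-to-one"
    signs = np.sign(cong[order, np.arange(k)])
    return est[:, order] * signs


def table_population_R() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    L = np.array(list(TABLE_LOADINGS.values()))
    Phi = np.array([[1.0, 0.54], [0.54, 1.0]])
    R = L @ Phi @ L.T
    np.fill_diagonal(R, 1.0)
    return R, L, Phi


class TestPrincipalAxis:
    def test_single_factor_exact_structure_recovered(self):
        lam = np.array([0.8, 0.7, 0.6, 0.5])
        R = np.outer(lam, lam)
        np.fill_diagonal(R, 1.0)
        L, h2 = principal_axis(R, 1, tol=1e-9)
        assert np.abs(np.abs(L[:, 0]) - lam).max() < 1e-6
        assert h2 == pytest.approx(lam**2, abs=1e-6)

    def test_identity_matrix_degenerate(self):
        with pytest.warns(UserWarning, match="degenerate"):
            L, h2 = principal_axis(np.eye(6), 1)
        assert h2.max() < 1e-3

    def test_two_factor_exact_structure_congruence(self):
        truth = np.array(
            [[0.8, 0.0], [0.7, 0.0], [0.6, 0.0], [0.0, 0.75], [0.0, 0.65], [0.0, 0.55]]
        )
        R = truth @ truth.T
        np.fill_diagonal(R, 1.0)
        L, _ = principal_axis(R, 2)
        aligned = align_columns(L, truth)
        for j in range(2):
            c = aligned[:, j] @ truth[:, j] / np.sqrt(
                (aligned[:, j] @ aligned[:, j]) * (truth[:, j] @ truth[:, j])
            )
            assert c > 0.9999

    def test_offdiagonal_reproduction_on_exact_input(self):
        R, L_true, Phi = table_population_R()
        L, _ = principal_axis(R, 2)
        fitted = L @ L.T
        off = ~np.eye(R.shape[0], dtype=bool)
        assert np.abs((R - fitted)[off]).max() < 1e-4

    def test_bad_k_rejected(self):
        with pytest.raises(ValueError):
            principal_axis(np.eye(4), 4)


class TestRotationOracle:
    """Frozen values from R 4.3.3 stats::varimax / stats::promax(m=4) on a
    fixed 8 x 2 unrotated loading matrix (phi = inv(U) inv(U)')."""

    A = np.array(
        [
            [0.72, 0.10], [0.65, -0.04], [0.58, 0.21], [0.44, 0.32],
            [0.12, 0.68], [-0.05, 0.61], [0.20, 0.55], [0.31, 0.47],
        ]
    )
    R_VARIMAX = np.array(
        [
            [0.71919282, 0.10564888], [0.65029397, -0.03489631],
            [0.57833364, 0.21454649], [0.43747446, 0.32344411],
            [0.11465834, 0.68092104], [-0.05478692, 0.60958871],
            [0.19567637, 0.55155304], [0.30630098, 0.47241900],
        ]
    )
    R_PROMAX = np.array(
        [
            [0.75226463, -0.06095335], [0.71565620, -0.19757006],
            [0.56969620, 0.09252963], [0.38712776, 0.24601262],
            [-0.06061371, 0.71562370], [-0.22522483, 0.67925931],
            [0.06253721, 0.55445515], [0.20418133, 0.44089516],
        ]
    )
    R_PHI12 = 0.4494509

    def test_varimax_matches_reference(self):
        z, _ = varimax(self.A)
        assert np.abs(align_columns(z, self.R_VARIMAX) - self.R_VARIMAX).max() < 1e-4

    def test_promax_matches_reference(self):
        pat, phi = promax(self.A)
        assert np.abs(align_columns(pat, self.R_PROMAX) - self.R_PROMAX).max() < 1e-4
        assert phi[0, 1] == pytest.approx(self.R_PHI12, abs=1e-4)


class TestPromaxProperties:
    def test_perfect_simple_structure_fixed_point(self):
        truth = np.array(
            [[0.8, 0.0], [0.7, 0.0], [0.6, 0.0], [0.0, 0.75], [0.0, 0.65], [0.0, 0.55]]
        )
        pat, phi = promax(truth)
        aligned = align_columns(pat, truth)
        assert np.abs(aligned - truth).max() < 1e-6
        assert abs(phi[0, 1]) < 1e-6

    def test_phi_valid_and_communalities_rotation_invariant(self):
        R, _, _ = table_population_R()
        L, h2 = principal_axis(R, 2)
        pat, phi = promax(L)
        assert np.allclose(phi, phi.T) and np.allclose(np.diag(phi), 1.0)
        assert np.linalg.eigvalsh(phi).min() > 0
        h2_rotated = np.einsum("ij,jk,ik->i", pat, phi, pat)
        assert np.abs(h2_rotated - h2).max() < 1e-6

    def test_structure_pattern_consistency(self):
        R, _, _ = table_population_R()
        L, _ = principal_axis(R, 2)
        pat, phi = promax(L)
        model = FactorModel(tuple(TABLE_LOADINGS), pat, phi)
        assert np.allclose(model.structure, pat @ phi, atol=1e-12)

    def test_single_factor_rejected(self):
        with pytest.raises(ValueError):
            promax(np.array([[0.5], [0.6]]))


class TestParallelAnalysis:
    def test_pure_noise_suggests_zero_factors(self):
        # quantile comparator: ~5% false-positive rate on the top eigenvalue
        rng = np.random.default_rng(41)
        zeros = 0
        for _ in range(5):
            X = rng.standard_normal((500, 23))
            ev = np.sort(np.linalg.eigvalsh(np.corrcoef(X, rowvar=False)))[::-1]
            k = parallel_analysis(500, 23, ev, reps=60, seed=rng, quantile=0.95)
            zeros += k == 0
        assert zeros >= 4

    def test_dominant_eigenvalues_select_everything(self):
        assert parallel_analysis(200, 5, [50, 40, 30, 20, 10], reps=60, seed=1) == 5

    def test_too_few_reps_rejected(self):
        with pytest.raises(ValueError):
            parallel_analysis(100, 5, [2, 1, 1, 0.5, 0.5], reps=10, seed=0)


class TestVSS:
    def test_one_factor_exact_structure_peaks_at_one(self):
        lam = np.array([0.8, 0.7, 0.6, 0.5, 0.65])
        R = np.outer(lam, lam)
        np.fill_diagonal(R, 1.0)
        curve, argmax = vss_criterion(R, 3)
        assert argmax == 1

    def test_values_within_unit_interval(self):
        R, _, _ = table_population_R()
        for c in (1, 2):
            curve, _ = vss_criterion(R, 4, complexity=c)
            assert np.all((curve >= 0) & (curve <= 1))

    def test_complexity_two_supports_two_factors_on_population_structure(self):
        R, _, _ = table_population_R()
        _, argmax = vss_criterion(R, 4, complexity=2)
        assert argmax == 2


class TestPruning:
    def _model(self, loadings):
        ids = tuple(f"I{i}" for i in range(len(loadings)))
        return FactorModel(ids, np.asarray(loadings), np.array([[1.0, 0.4], [0.4, 1.0]]))

    def test_all_salient_identity_subset_no_refit(self):
        m = self._model([[0.5, 0.1], [0.6, 0.0], [0.1, 0.5], [0.0, 0.6]])
        subset, refit = prune_items(m)
        assert subset.item_ids == m.item_ids and not refit

    def test_planted_low_loading_item_dropped(self):
        m = self._model([[0.5, 0.1], [0.6, 0.0], [0.25, 0.2], [0.1, 0.5], [0.0, 0.6]])
        subset, refit = prune_items(m)
        assert refit and subset.removed("low-loading") == ("I2",)

    def test_loading_exactly_at_threshold_retained(self):
        m = self._model([[0.5, 0.1], [0.30, 0.0], [0.1, 0.5], [0.0, 0.6]])
        subset, refit = prune_items(m)
        assert "I1" in subset.item_ids and not refit

    def test_emptying_a_factor_errors(self):
        m = self._model([[0.5, 0.1], [0.6, 0.0], [0.1, 0.2], [0.0, 0.25]])
        with pytest.raises(ValueError, match="no salient item"):
            prune_items(m)


def simple_structure_pattern():
    """CFA layout: disability-type block (4 items) and distress block (4)."""
    lam = np.zeros((8, 2))
    lam[:4, 0] = [1.0, 0.9, 0.8, 0.7]
    lam[4:, 1] = [1.0, 0.85, 0.75, 0.65]
    phi = np.array([[0.5, 0.2], [0.2, 0.6]])
    psi = np.full(8, 0.5)
    sigma = lam @ phi @ lam.T + np.diag(psi)
    pattern = [[0, 1, 2, 3], [4, 5, 6, 7]]
    return sigma, pattern, lam, phi, psi


class TestCFA:
    def test_exact_model_covariance_perfect_fit(self):
        sigma, pattern, *_ = simple_structure_pattern()
        fit, est = cfa_fit(sigma, pattern, n=400)
        assert fit.chi2 == pytest.approx(0.0, abs=1e-4)
        assert fit.rmsea == 0.0 and fit.cfi == 1.0
        assert fit.rmsea_ci[0] == 0.0

    def test_parameter_recovery_on_exact_input(self):
        sigma, pattern, lam, phi, psi = simple_structure_pattern()
        _, est = cfa_fit(sigma, pattern, n=400)
        assert np.abs(est["loadings"] - lam).max() < 1e-3
        assert np.abs(est["phi"] - phi).max() < 1e-3
        assert np.abs(est["uniquenesses"] - psi).max() < 1e-3

    def test_anchor_choice_does_not_change_fit(self):
        sigma, pattern, *_ = simple_structure_pattern()
        # perturb so the model does not fit exactly
        rng = np.random.default_rng(3)
        E = 0.02 * rng.standard_normal(sigma.shape)
        S = sigma + (E + E.T) / 2
        np.fill_diagonal(S, np.diag(sigma))
        fit_a, _ = cfa_fit(S, [[0, 1, 2, 3], [4, 5, 6, 7]], n=400)
        fit_b, _ = cfa_fit(S, [[2, 1, 0, 3], [6, 5, 4, 7]], n=400)
        assert fit_a.chi2 == pytest.approx(fit_b.chi2, abs=1e-4)

    def test_merged_factor_misspecification_lowers_cfi(self):
        sigma, pattern, *_ = simple_structure_pattern()
        good, _ = cfa_fit(sigma, pattern, n=400)
        merged, _ = cfa_fit(sigma, [[0, 1, 2, 3, 4, 5], [6, 7]], n=400)
        assert merged.cfi < good.cfi

    def test_non_pd_sample_matrix_rejected(self):
        S = np.ones((4, 4))
        with pytest.raises(ValueError, match="positive definite"):
            cfa_fit(S, [[0, 1], [2, 3]], n=100)
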