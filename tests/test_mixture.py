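"""Gaussian mixture EM, bootstrap component selection, density crossings
and cut-off derivation, against closed forms and grid-scan oracles."""

import math

import numpy as np
import pytest

from evb.mixture import (
    CutoffDerivationError,
    MixtureModel,
    boot_comp,
    density_crossings,
    derive_cutoffs,
    em_fit,
)


def make_model(weights, means, sds):
    w = np.asarray(weights, float)
    return MixtureModel(len(w), w / w.sum(), np.asarray(means, float), np.asarray(sds, float), 0.0, 100, True, 1)


def crossing_grid_oracle(model, i, j, weighted=True, lo=None, hi=None, step=1e-5):
    """Sign-change scan of the log-density difference on a fine grid."""
    if lo is None:
        lo = float(min(model.means)) - 6 * float(max(model.sds))
    if hi is None:
        hi = float(max(model.means)) + 6 * float(max(model.sds))
    x = np.arange(lo, hi, step)
    wi = np.log(model.weights[i]) if weighted else 0.0
    wj = np.log(model.weights[j]) if weighted else 0.0
    di = wi - np.log(model.sds[i]) - 0.5 * ((x - model.means[i]) / model.sds[i]) ** 2
    dj = wj - np.log(model.sds[j]) - 0.5 * ((x - model.means[j]) / model.sds[j]) ** 2
    diff = di - dj
    idx = np.flatnonzero(np.sign(diff[:-1]) * np.sign(diff[1:]) < 0)
    # linear interpolation within the bracketing step
    return [float(x[k] - diff[k] * step / (diff[k + 1] - diff[k])) for k in idx]


def crossing_oracle_piecewise(model, i, j, weighted, candidates, step=1e-5):
    """Grid oracle over the data region plus a local window around every
    candidate root (near-equal sds put one crossing arbitrarily far out, so
    a single contiguous grid would be enormous)."""
    sd_max = float(max(model.sds))
    windows = [(float(min(model.means)) - 6 * sd_max, float(max(model.means)) + 6 * sd_max)]
    windows += [(r - 0.5, r + 0.5) for r in candidates]
    roots: list[float] = []
    for lo, hi in windows:
        for r in crossing_grid_oracle(model, i, j, weighted=weighted, lo=lo, hi=hi, step=step):
            if not any(abs(r - seen) < 1e-4 for seen in roots):
                roots.append(r)
    return sorted(roots)


class TestEMFit:
    def test_constant_data_single_component(self):
        m = em_fit(np.full(20, 3.5), k=1)
        assert m.means[0] == pytest.approx(3.5)
        assert m.weights[0] == 1.0

    def test_constant_data_rejects_two_components(self):
        with pytest.raises(ValueError):
            em_fit(np.full(20, 1.0), k=2)

    def test_insufficient_data_rejected(self):
        with pytest.raises(ValueError):
            em_fit(np.arange(9.0), k=2)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            em_fit(np.array([1.0, np.nan, 2.0] * 5), k=1)

    def test_two_component_parameter_recovery(self, rng):
        x = np.concatenate([rng.normal(-5, 0.5, 500), rng.normal(5, 0.5, 500)])
        m = em_fit(x, k=2, seed=0)
        assert m.means[0] == pytest.approx(-5.0, abs=0.15)
        assert m.means[1] == pytest.approx(5.0, abs=0.15)
        assert m.weights[0] == pytest.approx(0.5, abs=0.05)
        assert m.converged

    def test_loglik_improves_with_k_on_bimodal_data(self, rng):
        x = np.concatenate([rng.normal(0, 1, 300), rng.normal(8, 1, 300)])
        assert em_fit(x, 2, seed=1).loglik > em_fit(x, 1, seed=1).loglik

    def test_components_sorted_by_mean_regardless_of_seed(self, rng):
        x = np.concatenate([rng.normal(0, 0.3, 200), rng.normal(2, 0.3, 200), rng.normal(5, 0.5, 200)])
        for seed in range(5):
            m = em_fit(x, 3, seed=seed)
            assert np.all(np.diff(m.means) > 0)

    def test_bvftd_marker_is_detectably_bimodal(self, describe_cohort):
        """The generated bvFTD tau-ratio mixture separates into two fitted
        components whose means straddle the published subgroup summaries."""
        x = describe_cohort.loc[
            (describe_cohort["diagnosis"] == "bvFTD") & (describe_cohort["pathology"] == "unknown"),
            "tau_ratio",
        ].to_numpy()
        m = em_fit(x, 2, seed=0)
        assert m.means[0] < 1.1 < m.means[1]
        assert 0.25 < m.weights[0] < 0.75


class TestBootComp:
    def test_kmax_one_short_circuits(self, rng):
        assert boot_comp(rng.normal(size=100), k_max=1) == 1

    def test_single_gaussian_selects_one(self, rng):
        x = rng.normal(size=1000)
        assert boot_comp(x, k_max=3, n_boot=50, alpha=0.05, seed=42) == 1

    def test_three_separated_components_selected(self, rng):
        x = np.concatenate(
            [rng.normal(0.4, 0.08, 200), rng.normal(1.0, 0.1, 200), rng.normal(2.5, 0.4, 200)]
        )
        assert boot_comp(x, k_max=3, n_boot=50, alpha=0.05, seed=7) == 3

    def test_deterministic_under_fixed_seed(self, rng):
        x = np.concatenate([rng.normal(0, 1, 150), rng.normal(4, 1, 150)])
        assert boot_comp(x, k_max=3, n_boot=20, seed=5) == boot_comp(x, k_max=3, n_boot=20, seed=5)

    def test_small_bootstrap_rejected(self, rng):
        with pytest.raises(ValueError):
            boot_comp(rng.normal(size=50), k_max=2, n_boot=5)


class TestDensityCrossings:
    def test_symmetric_equal_sds(self):
        m = make_model([0.5, 0.5], [0.0, 2.0], [1.0, 1.0])
        assert density_crossings(m, 0, 1) == pytest.approx([1.0])

    def test_weighted_linear_closed_form(self):
        m = make_model([0.75, 0.25], [0.0, 3.0], [1.0, 1.0])
        expected = (9.0 + 2.0 * math.log(3.0)) / 6.0  # 1.86620
        assert density_crossings(m, 0, 1, weighted=True) == pytest.approx([expected], abs=1e-10)
        # unweighted falls back to the midpoint
        assert density_crossings(m, 0, 1, weighted=False) == pytest.approx([1.5])

    def test_equal_means_different_sds(self):
        m = make_model([0.5, 0.5], [0.0, 0.0], [1.0, 2.0])
        expected = math.sqrt(8.0 / 3.0 * math.log(2.0))  # 1.35956
        assert density_crossings(m, 0, 1) == pytest.approx([-expected, expected], abs=1e-9)

    def test_identical_components_flagged(self):
        m = make_model([0.5, 0.5], [1.0, 1.0], [0.5, 0.5])
        with pytest.raises(ValueError):
            density_crossings(m, 0, 1)

    def test_same_index_rejected(self):
        m = make_model([0.5, 0.5], [0.0, 1.0], [1.0, 1.0])
        with pytest.raises(ValueError):
            density_crossings(m, 0, 0)

    def test_matches_grid_oracle_on_random_pairs(self, rng):
        for _ in range(200):
            means = np.sort(rng.uniform(0, 3, size=2))
            sds = rng.uniform(0.1, 1.0, size=2)
            w = rng.dirichlet([3.0, 3.0])
            m = make_model(w, means, sds)
            weighted = bool(rng.integers(0, 2))
            got = density_crossings(m, 0, 1, weighted=weighted)
            oracle = crossing_oracle_piecewise(m, 0, 1, weighted, got)
            assert len(got) == len(oracle)
            for g, o in zip(sorted(got), sorted(oracle)):
                assert g == pytest.approx(o, abs=1e-6)


class TestDeriveCutoffs:
    def test_symmetric_model(self):
        m = make_model([1, 1, 1], [-2.0, 0.0, 2.0], [0.7, 0.7, 0.7])
        cut = derive_cutoffs(m)
        assert cut.lower == pytest.approx(-1.0, abs=1e-9)
        assert cut.upper == pytest.approx(1.0, abs=1e-9)

    def test_matches_grid_oracle_on_marker_like_model(self):
        m = make_model([1, 1, 1], [0.45, 1.00, 2.30], [0.10, 0.15, 0.60])
        cut = derive_cutoffs(m)
        lo_oracle = [r for r in crossing_grid_oracle(m, 0, 1) if 0.45 < r < 1.0]
        hi_oracle = [r for r in crossing_grid_oracle(m, 1, 2) if 1.0 < r < 2.3]
        assert cut.lower == pytest.approx(lo_oracle[0], abs=1e-6)
        assert cut.upper == pytest.approx(hi_oracle[0], abs=1e-6)

    def test_requires_three_components(self):
        m = make_model([0.5, 0.5], [0.0, 1.0], [0.3, 0.3])
        with pytest.raises(CutoffDerivationError):
            derive_cutoffs(m)

    def test_no_admissible_crossing_raises_with_diagnostics(self):
        # diffuse middle component never overtakes its neighbours inside
        # (mu1, mu2): the crossing lies far outside the admissible interval
        m = make_model([0.495, 0.01, 0.495], [0.0, 0.1, 0.2], [1.0, 100.0, 1.0])
        with pytest.raises(CutoffDerivationError, match="no crossing"):
            derive_cutoffs(m)

    def test_label_switch_safety(self, rng):
        """Cut-offs are invariant to EM initialisation order: every seeded
        restart yields the same sorted model and the same cut-offs."""
        x = np.concatenate(
            [rng.normal(0.4, 0.08, 200), rng.normal(1.0, 0.1, 200), rng.normal(2.5, 0.4, 200)]
        )
        cuts = [derive_cutoffs(em_fit(x, 3, seed=s, n_starts=4)) for s in range(4)]
        lowers = {round(c.lower, 6) for c in cuts}
        uppers = {round(c.upper, 6) for c in cuts}
        assert len(lowers) == 1 and len(uppers) == 1

    def test_recovery_from_known_model_tightens_with_n(self, rng):
        true = make_model([1, 1, 1], [0.4, 1.0, 2.5], [0.08, 0.1, 0.4])
        truth = derive_cutoffs(true)
        errors = []
        for n in (300, 3000):
            x = true.sample(n, np.random.default_rng(17))
            cut = derive_cutoffs(em_fit(x, 3, seed=3))
            errors.append(abs(cut.lower - truth.lower) + abs(cut.upper - truth.upper))
        assert errors[-1] < 0.1
        assert errors[-1] <= errors[0] + 0.02
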