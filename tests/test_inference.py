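import math
from dataclasses import replace

import numpy as np
import pytest

from refugia.engine import SampleConfig, derive_seeds, simulate_snp_masks
from refugia.inference import (
    OptConfig,
    ParamTransform,
    _Objective,
    composite_loglik,
    joint_sfs_from_masks,
    optimize_model,
    parametric_bootstrap,
)
from refugia.models import DemographicModel, EvolutionaryConstants, build_catalog
from refugia.sfs import JointSFS
from refugia.synthetic import null_preset

CONST = EvolutionaryConstants()


def toy_sfs(counts):
    arr = np.zeros((2, 2, 2))
    arr[1, 0, 0], arr[0, 1, 0], arr[0, 0, 1] = counts
    return JointSFS(sizes=(1, 1, 1), counts=arr, n_input_sites=sum(counts))


class TestCompositeLoglik:
    def test_point_mass_is_zero(self):
        obs = toy_sfs([5, 0, 0])
        probs = np.zeros((2, 2, 2))
        probs[1, 0, 0] = 1.0
        assert composite_loglik(obs, probs) == pytest.approx(0.0)

    def test_three_cell_toy_matches_product_oracle(self):
        # per-site product oracle: 0.5^5 * 0.3^3 * 0.2^2
        obs = toy_sfs([5, 3, 2])
        probs = np.zeros((2, 2, 2))
        probs[1, 0, 0], probs[0, 1, 0], probs[0, 0, 1] = 0.5, 0.3, 0.2
        oracle = math.log(0.5 ** 5 * 0.3 ** 3 * 0.2 ** 2)
        assert composite_loglik(obs, probs) == pytest.approx(oracle)

    def test_empirical_frequencies_maximise(self):
        obs = toy_sfs([5, 3, 2])
        mle = np.zeros((2, 2, 2))
        mle[1, 0, 0], mle[0, 1, 0], mle[0, 0, 1] = 0.5, 0.3, 0.2
        best = composite_loglik(obs, mle)
        rng = np.random.default_rng(0)
        for _ in range(50):
            probs = np.zeros((2, 2, 2))
            p = rng.dirichlet([1, 1, 1])
            probs[1, 0, 0], probs[0, 1, 0], probs[0, 0, 1] = p
            assert composite_loglik(obs, probs) <= best + 1e-12

    def test_zero_probability_cells_floored_with_warning(self):
        obs = toy_sfs([5, 3, 2])
        probs = np.zeros((2, 2, 2))
        probs[1, 0, 0] = 1.0
        with pytest.warns(UserWarning, match="zero expected mass"):
            ll = composite_loglik(obs, probs)
        # five observations in the point-mass cell contribute log(1) = 0;
        # the other five land on floored cells
        assert ll == pytest.approx(5 * math.log(1e-30), abs=1e-6)

    def test_shape_mismatch_rejected(self):
        obs = toy_sfs([1, 1, 1])
        with pytest.raises(ValueError, match="mismatch"):
            composite_loglik(obs, np.ones((3, 3, 3)) / 27)


class TestParamTransform:
    def test_round_trip_encoding(self, catalog):
        tr = ParamTransform(catalog["VI"])
        params = {"Ne_A": 1e5, "Ne_B": 2e5, "Ne_C": 4e5,
                  "tdiv_AB": 0.4e6, "tdiv_ABC": 0.8e6,
                  "tmig_A_B": 0.1e6, "p_A_B": 0.1,
                  "tmig_B_A": 0.2e6, "p_B_A": 0.2,
                  "tmig_AB_C": 0.5e6, "p_AB_C": 0.3,
                  "tmig_C_AB": 0.3e6, "p_C_AB": 0.4}
        back = tr.decode(tr.encode(params))
        for k, v in params.items():
            assert back[k] == pytest.approx(v, rel=1e-9)

    def test_every_box_point_decodes_to_valid_orderings(self, catalog, rng):
        from refugia.models import validate_model

        tr = ParamTransform(catalog["XII"])
        for _ in range(100):
            params = tr.decode(tr.sample_start(rng))
            assert validate_model(catalog["XII"], params) == []

    def test_anchor_is_exact_invariance_direction(self, catalog):
        tr = ParamTransform(catalog["X"])
        params = {"Ne_A": 1e5, "Ne_B": 3e5, "Ne_C": 2e5,
                  "tdiv_AB": 0.4e6, "tdiv_ABC": 0.8e6,
                  "tmig_A_B": 0.1e6, "p_A_B": 0.1,
                  "tmig_B_A": 0.2e6, "p_B_A": 0.2,
                  "tmig_AB_C": 0.5e6, "p_AB_C": 0.3,
                  "tmig_C_AB": 0.3e6, "p_C_AB": 0.4,
                  "growth_C": 1e-5}
        anchored = tr.anchor(params, 2e5)
        gm = (anchored["Ne_A"] * anchored["Ne_B"] * anchored["Ne_C"]) ** (1 / 3)
        assert gm == pytest.approx(2e5, rel=1e-9)
        # ratios preserved
        assert anchored["tdiv_ABC"] / anchored["Ne_C"] == pytest.approx(
            params["tdiv_ABC"] / params["Ne_C"], rel=1e-9)
        assert anchored["growth_C"] * anchored["Ne_C"] == pytest.approx(
            params["growth_C"] * params["Ne_C"], rel=1e-9)
        assert anchored["p_A_B"] == params["p_A_B"]


@pytest.fixture(scope="module")
def null_data(catalog, null_params):
    sc = SampleConfig(12, 12, 12)
    masks = simulate_snp_masks(catalog["I"], null_params, 2000, sc, 640)
    return joint_sfs_from_masks(masks, sc)


class TestOptimizer:
    def test_deterministic_under_seed(self, catalog, null_data):
        cfg = OptConfig(n_starts=2, mc_reps=48, final_mc_reps=256, seed=5,
                        max_evals=120)
        f1 = optimize_model(catalog["I"], null_data, cfg)
        f2 = optimize_model(catalog["I"], null_data, cfg)
        assert f1.loglik == f2.loglik
        assert f1.params == f2.params

    def test_more_starts_never_worse(self, catalog, null_data):
        base = dict(mc_reps=48, final_mc_reps=512, max_evals=150, seed=5)
        ll1 = optimize_model(catalog["I"], null_data,
                             OptConfig(n_starts=1, **base)).loglik
        ll8 = optimize_model(catalog["I"], null_data,
                             OptConfig(n_starts=8, **base)).loglik
        assert ll8 >= ll1 - 1e-9

    def test_null_model_parameter_recovery(self, catalog):
        # data simulated from the null scenario, refit with the null model
        pre = null_preset()
        sc = SampleConfig(12, 12, 12)
        errs = {s: [] for s in ("Ne_A", "Ne_B", "Ne_C")}
        for rep in range(5):
            masks = simulate_snp_masks(catalog["I"], pre.true_params, 2000,
                                       sc, 300 + rep)
            obs = joint_sfs_from_masks(masks, sc)
            fit = optimize_model(catalog["I"], obs,
                                 OptConfig(n_starts=8, seed=rep))
            for s in errs:
                errs[s].append(abs(fit.params[s] / pre.true_params[s] - 1))
        for s, es in errs.items():
            assert np.median(es) < 0.25, f"{s}: {es}"

    def test_nested_model_never_fits_worse(self, catalog, null_data):
        # model III (pulses) nests model I; shared CRN seeds
        cfg = OptConfig(n_starts=4, seed=11, final_mc_reps=1024)
        f1 = optimize_model(catalog["I"], null_data, cfg)
        f3 = optimize_model(catalog["III"], null_data, cfg,
                            warm_starts=[{**f1.params, "tmig_A_B": 1e5,
                                          "p_A_B": 1e-4, "tmig_B_A": 1e5,
                                          "p_B_A": 1e-4}])
        assert f3.loglik >= f1.loglik - 3.0  # small MC tolerance

    def test_zero_parameter_model(self, null_data):
        frozen = build_catalog({"models": ["I"]})[0]
        frozen.bounds = {s: (2e5, 2e5) if s.startswith("Ne") else b
                         for s, b in frozen.bounds.items()}
        frozen.bounds["tdiv_AB"] = (3e6, 3e6)
        frozen.bounds["tdiv_ABC"] = (3.5e6, 3.5e6)
        fit = optimize_model(frozen, null_data, OptConfig(seed=1))
        assert fit.k == 0
        assert np.isfinite(fit.loglik)

    def test_empty_sfs_rejected(self, catalog):
        empty = JointSFS(sizes=(2, 2, 2), counts=np.zeros((3, 3, 3)))
        with pytest.raises(ValueError, match="empty"):
            optimize_model(catalog["I"], empty, OptConfig(seed=0))

    def test_fixed_zero_pulse_changes_nothing_exactly(self, catalog,
                                                      null_data, null_params):
        # shared CRN: adding a pulse whose fraction is fixed at zero leaves
        # the objective value exactly unchanged
        seeds = derive_seeds(77, 128)
        p3 = {**null_params, "tmig_A_B": 1e5, "p_A_B": 0.0,
              "tmig_B_A": 2e5, "p_B_A": 0.0}
        lls = []
        for name, params in (("I", null_params), ("III", p3)):
            tr = ParamTransform(catalog[name])
            obj = _Objective(catalog[name], null_data, CONST, tr, seeds,
                             None, 1e-30)
            lls.append(obj.loglik(tr.encode(params)))
        assert lls[0] == lls[1]


class TestBootstrap:
    def test_degenerate_model_zero_width_ci(self, null_params):
        frozen = build_catalog({"models": ["I"]})[0]
        frozen.bounds = {s: (null_params[s], null_params[s])
                         for s in frozen.bounds}
        res = parametric_bootstrap(frozen, null_params, 200, 4,
                                   OptConfig(n_starts=1, seed=2),
                                   sample_config=SampleConfig(8, 8, 8))
        assert res.ci == {}
        assert res.n_failed == 0

    def test_percentiles_match_sort_oracle(self, catalog, null_params):
        cfg = OptConfig(n_starts=1, mc_reps=48, final_mc_reps=128,
                        max_evals=100, seed=3)
        res = parametric_bootstrap(catalog["I"], null_params, 400, 8, cfg,
                                   sample_config=SampleConfig(8, 8, 8))
        for sym, reps in res.replicates.items():
            lo, hi = res.ci[sym]
            assert lo == pytest.approx(np.percentile(reps, 2.5))
            assert hi == pytest.approx(np.percentile(reps, 97.5))
            assert lo <= hi
        assert all(len(r) == 8 for r in res.replicates.values())
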