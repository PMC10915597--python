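"""Desk-scale evaluation protocols.

Self-contained routines that exercise the whole pipeline at sizes a
workstation handles in minutes: information-theoretic ranking arithmetic on
published empirical inputs, the analytic single-population spectrum check,
divergence-time recovery and bootstrap coverage under a study-shaped truth,
barrier-vs-migration model discrimination, the shared-divergence comparison
and neutrality-statistic calibration.  Both the test suite and
``scripts/acceptance.py`` run these, so the numbers they report are produced
by one code path.

Problem sizes (2000 loci, 8 diploids per cluster, 20 optimiser starts,
12-16 bootstrap replicates, 20 replicate datasets per question) are the
package's desk-scale defaults; the methods note discusses them.
"""

from __future__ import annotations

import numpy as np

from .engine import SampleConfig, expected_sfs_mc, simulate_site_matrix, simulate_snp_dataset
from .inference import OptConfig, optimize_model, parametric_bootstrap, joint_sfs_from_masks
from .engine import simulate_snp_masks
from .models import build_catalog
from .selection import rank_models, test_shared_divergence
from .sfs import build_joint_sfs
from .stats import tajimas_d
from .synthetic import barrier_preset, get_preset

__all__ = [
    "RANKING_INPUTS_MENTALIS",
    "RANKING_INPUTS_RUFICAPILLUS",
    "ranking_arithmetic",
    "single_population_spectrum_error",
    "tdiv_recovery_and_coverage",
    "barrier_discrimination",
    "zero_pulse_loglik_shift",
    "codivergence_calibration",
    "neutrality_calibration",
]

# Published per-model (lnL, k) inputs for the two empirical SNP matrices
# whose printed rankings are internally consistent (best model first).
RANKING_INPUTS_MENTALIS = [
    ("X", "Divergences, migrations, and expansions", -5262.392335, 14),
    ("III", "Divergences and migrations", -5261.258098, 16),
    ("IX", "Divergences, migrations, and expansions", -5262.817181, 16),
    ("II", "Divergences and migrations", -5275.603138, 12),
    ("XII", "Divergences, migrations, expansions, and bottleneck",
     -5279.918669, 16),
    ("I", "Divergences", -5309.276383, 8),
    ("IV", "Divergences and migrations", -5480.279081, 18),
]
RANKING_INPUTS_RUFICAPILLUS = [
    ("VI", "Migrations and divergence", -6273.820533, 13),
    ("VII", "Migrations, divergence, and expansion", -6274.55217, 15),
    ("III", "Migrations and divergence", -6274.999944, 16),
    ("V", "Migrations and divergence", -6277.374519, 15),
    ("II", "Migrations and divergence", -6282.69762, 15),
    ("IV", "Migrations and divergence", -6288.002384, 14),
    ("I", "Migrations and divergence", -6374.94489, 5),
]


def ranking_arithmetic() -> dict:
    """Recompute dAIC and relative likelihoods from the published
    (lnL, k) inputs of the two internally consistent empirical rankings."""
    out = {}
    for label, rows in (("mentalis", RANKING_INPUTS_MENTALIS),
                        ("ruficapillus", RANKING_INPUTS_RUFICAPILLUS)):
        table = rank_models([(n, t, ll, k) for n, t, ll, k in rows])
        frame = table.frame.set_index("Model_number")
        for name in frame.index:
            out[f"{label}_{name}_dAIC"] = float(frame.loc[name, "dAIC"])
            out[f"{label}_{name}_omega"] = float(frame.loc[name, "omega_i"])
    return out


def single_population_spectrum_error(seed: int, n: int = 10,
                                     n_reps: int = 100_000) -> dict:
    """Maximum relative error of the Monte-Carlo expected spectrum against
    the analytic 1/i law for a constant-size single population."""
    model = build_catalog({"models": ["I"]})[0]
    params = {"Ne_A": 2e5, "Ne_B": 2e5, "Ne_C": 2e5,
              "tdiv_AB": 5e6, "tdiv_ABC": 6e6}
    sc = SampleConfig(n, 0, 0)
    esfs = expected_sfs_mc(model, params, sc, n_reps, seed)
    probs = esfs.probs[1:n, 0, 0]
    expect = 1.0 / np.arange(1, n)
    expect /= expect.sum()
    rel = np.abs(probs - expect) / expect
    return {"max_rel_err": float(rel.max()), "n_reps": n_reps}


def _fit_preset_dataset(preset, data_seed: int, opt_seed: int, n_loci: int,
                        n_starts: int):
    table = simulate_snp_dataset(preset.model, preset.true_params, n_loci,
                                 preset.sample_config, preset.missing_rate,
                                 data_seed)
    observed = build_joint_sfs(table)
    cfg = OptConfig(n_starts=n_starts, final_mc_reps=4096, seed=opt_seed)
    fit = optimize_model(preset.model, observed, cfg)
    return observed, fit


def tdiv_recovery_and_coverage(seed: int, n_recovery: int = 10,
                               n_coverage: int = 20, n_loci: int = 2000,
                               n_starts: int = 20, n_boot: int = 12,
                               progress=None) -> dict:
    """Simulate study-shaped datasets under the four-pulse divergence truth,
    refit the generating model, and measure (a) how often the root
    divergence time is recovered within a factor of two (full-strength
    fits) and (b) how often the parametric-bootstrap 95% interval covers
    the truth.

    The coverage replicates use one reduced-budget estimator for both the
    observed-data fit and every bootstrap refit (fresh random multistart,
    no warm start): percentile intervals are calibrated exactly when the
    refit estimator is distributed like the one that produced the
    observed-data estimate, so both sides must run the same protocol.
    """
    preset = get_preset("caerulescens-like")
    truth = preset.true_params["tdiv_ABC"]

    ratios = []
    for rep in range(n_recovery):
        _, fit = _fit_preset_dataset(
            preset, seed + 1000 + rep, seed + rep, n_loci, n_starts)
        ratios.append(fit.params["tdiv_ABC"] / truth)
        if progress:
            progress(f"recovery replicate {rep + 1}")

    covered = 0
    for rep in range(n_coverage):
        cfg = OptConfig(n_starts=2, mc_reps=64, stage_a_reps=48,
                        final_mc_reps=1024, max_evals=300,
                        seed=seed + 50 + rep)
        table = simulate_snp_dataset(
            preset.model, preset.true_params, n_loci, preset.sample_config,
            preset.missing_rate, seed + 2000 + rep)
        observed = build_joint_sfs(table)
        fit = optimize_model(preset.model, observed, cfg)
        boot = parametric_bootstrap(
            preset.model, fit.params, n_loci, n_boot, cfg,
            sample_config=SampleConfig(*observed.sizes),
            data_sample_config=preset.sample_config,
            missing_rate=preset.missing_rate,
            warm_start=False)
        lo, hi = boot.ci["tdiv_ABC"]
        covered += int(lo <= truth <= hi)
        if progress:
            progress(f"coverage replicate {rep + 1}")

    n_ok = sum(1 for r in ratios if 0.5 <= r <= 2.0)
    return {
        "recovered_within_factor2": n_ok,
        "n_recovery": n_recovery,
        "recovery_fraction": n_ok / n_recovery,
        "median_tdiv_ratio": float(np.median(ratios)),
        "ci_covered": covered,
        "n_coverage": n_coverage,
        "coverage_fraction": covered / n_coverage,
    }


def barrier_discrimination(seed: int, n_reps: int = 20,
                           n_loci: int = 2000, n_starts: int = 4,
                           progress=None) -> dict:
    """Data simulated under the no-migration barrier scenario: how often
    does the barrier model out-rank the pulse-migration alternative?"""
    cat = {m.name: m for m in build_catalog({"models": ["II", "III"]})}
    preset = barrier_preset()
    sc = SampleConfig(12, 12, 12)
    wins = 0
    for rep in range(n_reps):
        masks = simulate_snp_masks(cat["II"], preset.true_params, n_loci,
                                   sc, seed + 500 + rep)
        observed = joint_sfs_from_masks(masks, sc)
        fits = []
        for name in ("II", "III"):
            cfg = OptConfig(n_starts=n_starts, seed=seed + rep,
                            final_mc_reps=2048)
            f = optimize_model(cat[name], observed, cfg)
            fits.append({"name": name, "model_type": cat[name].model_type,
                         "loglik": f.loglik, "k": f.k})
        table = rank_models(fits)
        wins += int(table.best["Model_number"] == "II")
        if progress:
            progress(f"discrimination replicate {rep + 1}")
    return {"barrier_wins": wins, "n_reps": n_reps,
            "win_fraction": wins / n_reps}


def zero_pulse_loglik_shift(seed: int) -> dict:
    """Adding a pulse with fraction fixed at zero must leave the composite
    likelihood exactly unchanged under shared common random numbers."""
    from .inference import ParamTransform, _Objective
    from .models import EvolutionaryConstants
    from .engine import derive_seeds

    cat = {m.name: m for m in build_catalog({"models": ["I", "III"]})}
    params = {"Ne_A": 2e5, "Ne_B": 2e5, "Ne_C": 2e5,
              "tdiv_AB": 3e6, "tdiv_ABC": 3.5e6}
    params3 = {**params, "tmig_A_B": 1e5, "p_A_B": 0.0,
               "tmig_B_A": 2e5, "p_B_A": 0.0}
    sc = SampleConfig(12, 12, 12)
    masks = simulate_snp_masks(cat["I"], params, 500, sc, seed + 3)
    observed = joint_sfs_from_masks(masks, sc)
    const = EvolutionaryConstants()
    seeds = derive_seeds(seed + 4, 256)
    lls = []
    for name, p in (("I", params), ("III", params3)):
        tr = ParamTransform(cat[name])
        obj = _Objective(cat[name], observed, const, tr, seeds, None, 1e-30)
        lls.append(obj.loglik(tr.encode(p)))
    return {"loglik_shift": float(lls[1] - lls[0])}


def codivergence_calibration(seed: int, n_reps: int = 20,
                             n_loci: int = 1000, progress=None) -> dict:
    """Two-taxon shared-divergence comparison: preference frequencies when
    the true split times are identical and when they differ four-fold."""
    model = build_catalog({"models": ["I"]})[0]
    sc = SampleConfig(12, 12, 12)
    base = {"Ne_A": 2e5, "Ne_B": 2e5, "Ne_C": 2e5}
    out = {}
    for label, t2 in (("same", 0.5e6), ("fourfold", 2.0e6)):
        shared_pref = 0
        for rep in range(n_reps):
            p1 = {**base, "tdiv_AB": 0.5e6, "tdiv_ABC": 1.5e6}
            p2 = {**base, "tdiv_AB": t2, "tdiv_ABC": 2.8e6}
            d1 = joint_sfs_from_masks(
                simulate_snp_masks(model, p1, n_loci, sc,
                                   seed + 10 * rep + 1), sc)
            d2 = joint_sfs_from_masks(
                simulate_snp_masks(model, p2, n_loci, sc,
                                   seed + 10 * rep + 2), sc)
            cfg = OptConfig(n_starts=3, mc_reps=64, seed=seed + rep,
                            final_mc_reps=4096)
            cmp = test_shared_divergence({"t1": d1, "t2": d2}, "AB", cfg)
            shared_pref += int(cmp.preferred == "shared")
            if progress:
                progress(f"codivergence {label} replicate {rep + 1}")
        out[f"{label}_shared_preferred"] = shared_pref
        out[f"{label}_n_reps"] = n_reps
        out[f"{label}_shared_fraction"] = shared_pref / n_reps
    return out


def neutrality_calibration(seed: int, n_reps: int = 500, n: int = 20,
                           theta: float = 6.0) -> dict:
    """Mean Tajima's D under neutral constant size (expected near zero) and
    under strong recent exponential growth (expected negative)."""
    ne = 1e5
    mut = theta / (4 * ne)
    out = {}
    for label, growth, reps in (("neutral", 0.0, n_reps),
                                ("expansion", 5e-4, max(n_reps // 2, 100))):
        ds = []
        for rep in range(reps):
            mat = simulate_site_matrix(ne, n, mut, seed + 7919 * rep + 11,
                                       growth=growth, min_s=1)
            d = tajimas_d(mat)
            if d is not None:
                ds.append(d)
        out[f"mean_tajima_d_{label}"] = float(np.mean(ds))
        out[f"n_{label}"] = len(ds)
    return out
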