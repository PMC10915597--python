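"""Composite-likelihood fitting of demographic models to joint SFS data.

The likelihood is multinomial over unlinked SNPs conditioned on
polymorphism: ``lnL = sum_c n_c log pi_c`` where ``n_c`` are observed cell
counts of the joint SFS and ``pi_c`` the model's expected (normalised)
spectrum, evaluated by Monte Carlo with *common random numbers* — a fixed
set of genealogy seeds per optimisation — so the objective is a
deterministic function of the parameters and can be optimised by a bounded
Nelder-Mead search in transformed parameter space (log scale for sizes,
times and rates; linear for admixture fractions; event times expressed as
fractions of their bounding divergence so orderings hold by construction).

A likelihood of this form is invariant to jointly rescaling every size and
time (and inversely every growth rate); only coalescent-scaled ratios are
identified.  Absolute values are therefore *anchored*: the geometric mean of
the three contemporary effective sizes is pinned to a reference ``anchor_ne``
(default 2e5 diploids) inside the objective, and all reported sizes and
times are on that anchor's scale.  See the methods note for discussion.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import minimize

from .engine import (
    SampleConfig,
    derive_seeds,
    expected_sfs_mc,
    kernel_args,
    sfs_kernel_probs,
    simulate_snp_masks,
)
from .models import (
    Bottleneck,
    DemographicModel,
    EvolutionaryConstants,
    Growth,
    ParameterSet,
    Pulse,
    SizeChange,
    Split,
    count_free_parameters,
)
from .sfs import JointSFS

__all__ = [
    "OptConfig",
    "FitResult",
    "BootstrapResult",
    "composite_loglik",
    "optimize_model",
    "parametric_bootstrap",
    "joint_sfs_from_masks",
    "ParamTransform",
]

logger = logging.getLogger("refugia")

DEFAULT_ANCHOR_NE = 2.0e5
_PROB_FLOOR_DEFAULT = 1e-30


# ---------------------------------------------------------------------------
# Configuration and results
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OptConfig:
    """Optimiser settings.

    ``n_starts`` independent searches (log-uniform initial points), each
    with a fresh common-random-number seed.  Every start first fits the
    divergence backbone (sizes and split times) with migration/size-change
    intensities held at neutral values (``stage_a_reps`` MC replicates per
    call); the most promising fraction (``keep_frac``) then receives a full
    Nelder-Mead search with ``mc_reps`` replicates, and all survivors are
    re-scored with ``final_mc_reps`` replicates under one shared seed so
    their likelihoods are commensurable.

    ``smoothing`` shrinks the Monte-Carlo spectrum toward uniform
    (``pi' = (pi + a/K) / (1 + a)`` over the K polymorphic cells) so that
    observed cells the finite simulation happens to miss are penalised
    smoothly instead of through the hard ``prob_floor``.
    """

    n_starts: int = 100
    mc_reps: int = 96
    stage_a_reps: int = 48
    final_mc_reps: int = 2048
    max_evals: int | None = None
    keep_frac: float = 0.25
    seed: int = 0
    anchor_ne: float | None = DEFAULT_ANCHOR_NE
    smoothing: float = 0.01
    prob_floor: float = _PROB_FLOOR_DEFAULT

    def evals_for(self, k: int) -> int:
        return self.max_evals if self.max_evals else max(200, 60 * k)


@dataclass
class StartRecord:
    start_params: dict
    loglik_search: float
    loglik_final: float
    n_evals: int
    success: bool


@dataclass
class FitResult:
    """Best parameter set and per-start diagnostics for one model fit."""

    model_name: str
    params: dict
    loglik: float
    k: int
    starts: list[StartRecord]
    seed: int
    bound_hits: list[str] = field(default_factory=list)

    def aic(self) -> float:
        return 2.0 * self.k - 2.0 * self.loglik


@dataclass
class BootstrapResult:
    """Percentile confidence intervals from a parametric bootstrap."""

    ci: dict
    replicates: dict
    n_boot: int
    n_failed: int
    level: float = 0.95


# ---------------------------------------------------------------------------
# Composite likelihood
# ---------------------------------------------------------------------------

def composite_loglik(observed: JointSFS, expected, floor: float = _PROB_FLOOR_DEFAULT,
                     warn_on_floor: bool = True) -> float:
    """``sum_c n_c log pi_c`` over polymorphic cells.

    ``expected`` is an :class:`~refugia.engine.ExpectedSFS` or a dense
    probability array of matching shape.  Observed cells with positive count
    but zero expected mass are floored at ``floor`` (with a warning): under
    finite Monte Carlo a structural zero cannot be distinguished from an
    unsampled cell.
    """
    probs = getattr(expected, "probs", expected)
    if probs.shape != tuple(m + 1 for m in observed.sizes):
        raise ValueError(
            f"projected sizes mismatch: observed {observed.sizes}, "
            f"expected shape {probs.shape}")
    idx, counts = observed.cells()
    p = probs[tuple(idx.T)]
    n_floored = int(np.sum(p <= 0))
    if n_floored and warn_on_floor:
        warnings.warn(f"{n_floored} observed cells have zero expected mass; "
                      f"flooring at {floor:g}")
    return float(np.sum(counts * np.log(np.maximum(p, floor))))


# ---------------------------------------------------------------------------
# Parameter transform
# ---------------------------------------------------------------------------

def _classify_symbols(model: DemographicModel):
    """Partition symbols by dimensional role (time / size / rate / unitless)
    and map event-time symbols to the split that bounds them."""
    t_ab_ref, t_abc_ref = model.split_time_symbols()
    time_syms: set[str] = set()
    frac_windows: dict[str, str] = {}
    size_syms: set[str] = set()
    rate_syms: set[str] = set()
    pulse_fracs: set[str] = set()
    strengths: set[str] = set()
    for s in (t_ab_ref, t_abc_ref):
        if isinstance(s, str):
            time_syms.add(s)
    for s in model.bounds:
        if s.startswith("Ne_"):
            size_syms.add(s)
    for ev in model.events:
        if isinstance(ev, Pulse):
            if isinstance(ev.time, str):
                time_syms.add(ev.time)
                window = t_ab_ref if {ev.source, ev.dest} <= {"A", "B"} \
                    else t_abc_ref
                if isinstance(window, str):
                    frac_windows[ev.time] = window
            if isinstance(ev.fraction, str):
                pulse_fracs.add(ev.fraction)
        elif isinstance(ev, (Bottleneck, SizeChange)):
            if isinstance(ev.time, str):
                time_syms.add(ev.time)
                window = t_ab_ref if ev.pop in ("A", "B") else t_abc_ref
                if isinstance(window, str):
                    frac_windows[ev.time] = window
            if isinstance(ev, SizeChange) and isinstance(ev.new_ne, str):
                size_syms.add(ev.new_ne)
            if isinstance(ev, Bottleneck) and isinstance(ev.strength, str):
                strengths.add(ev.strength)
        elif isinstance(ev, Growth):
            if isinstance(ev.rate, str):
                rate_syms.add(ev.rate)
    return time_syms, frac_windows, size_syms, rate_syms, pulse_fracs, strengths


class ParamTransform:
    """Bijection between a model's free parameters and the optimiser's box.

    Positive scale parameters are optimised in log space; pulse fractions
    and bottleneck strengths linearly; bounded event times as fractions of
    the divergence time that must postdate them (so every point in the box
    decodes to a valid event ordering).
    """

    def __init__(self, model: DemographicModel):
        self.model = model
        times, fracs, sizes, rates, pfracs, strengths = _classify_symbols(model)
        self.time_syms = times
        self.frac_windows = fracs
        self.size_syms = sizes
        self.rate_syms = rates
        self.pulse_frac_syms = pfracs
        self.strength_syms = strengths
        split_syms = {s for s in model.split_time_symbols()
                      if isinstance(s, str)}
        self.backbone_syms = ({"Ne_A", "Ne_B", "Ne_C", "Ne_AB", "Ne_ABC"}
                              & set(model.bounds)) | split_syms
        self.free = [s for s, _ in model.free_params]
        self.fixed = {s: lo for s, (lo, hi) in model.bounds.items() if lo == hi}
        self.kinds: list[str] = []
        self.lo = np.empty(len(self.free))
        self.hi = np.empty(len(self.free))
        for i, s in enumerate(self.free):
            lo, hi = model.bounds[s]
            if s in fracs:
                self.kinds.append("frac")
                self.lo[i], self.hi[i] = 0.005, 0.995
            elif lo > 0:
                self.kinds.append("log")
                self.lo[i], self.hi[i] = np.log(lo), np.log(hi)
            else:
                self.kinds.append("linear")
                self.lo[i], self.hi[i] = lo, hi

    @property
    def n_dim(self) -> int:
        return len(self.free)

    def sample_start(self, rng: np.random.Generator) -> np.ndarray:
        return rng.uniform(self.lo, self.hi)

    def decode(self, x: np.ndarray) -> dict:
        params = dict(self.fixed)
        frac_vals = {}
        for s, kind, v in zip(self.free, self.kinds, x):
            if kind == "log":
                params[s] = float(np.exp(v))
            elif kind == "frac":
                frac_vals[s] = float(v)
            else:
                params[s] = float(v)
        # mirror fold: an inverted pair of split times maps onto the
        # ordered one, keeping the search surface continuous
        t_ab, t_abc = self.model.split_time_symbols()
        if (isinstance(t_ab, str) and isinstance(t_abc, str)
                and t_ab in params and t_abc in params
                and params[t_ab] > params[t_abc]):
            params[t_ab], params[t_abc] = params[t_abc], params[t_ab]
        for s, f in frac_vals.items():
            window = self.frac_windows[s]
            params[s] = f * params[window]
        return params

    def encode(self, params: ParameterSet) -> np.ndarray:
        x = np.empty(self.n_dim)
        for i, (s, kind) in enumerate(zip(self.free, self.kinds)):
            v = float(params[s])
            if kind == "log":
                x[i] = np.log(v)
            elif kind == "frac":
                window = float(params[self.frac_windows[s]])
                x[i] = v / window if window > 0 else 0.5
            else:
                x[i] = v
            x[i] = min(max(x[i], self.lo[i]), self.hi[i])
        return x

    @property
    def backbone_idx(self) -> list[int]:
        """Indices of the divergence backbone (sizes and split times)."""
        return [i for i, s in enumerate(self.free) if s in self.backbone_syms]

    def neutralize(self, x: np.ndarray) -> np.ndarray:
        """Move event-intensity coordinates to neutral values (tiny pulses,
        no growth, no bottleneck, mid-window times) — the starting point of
        the incremental search schedule."""
        out = x.copy()
        for i, (s, kind) in enumerate(zip(self.free, self.kinds)):
            if s in self.pulse_frac_syms:
                out[i] = min(max(0.02, self.lo[i]), self.hi[i])
            elif s in self.strength_syms:
                out[i] = self.hi[i]
            elif s in self.rate_syms:
                out[i] = self.lo[i]
            elif kind == "frac":
                out[i] = 0.5
        return out

    def anchor(self, params: dict, anchor_ne: float) -> dict:
        """Rescale along the likelihood's exact scale-invariance so that the
        geometric mean of the contemporary Ne equals ``anchor_ne``."""
        nes = [params[s] for s in ("Ne_A", "Ne_B", "Ne_C") if s in params]
        if not nes:
            return params
        c = anchor_ne / float(np.exp(np.mean(np.log(nes))))
        out = dict(params)
        for s in self.size_syms:
            if s in out:
                out[s] *= c
        for s in self.time_syms:
            if s in out:
                out[s] *= c
        for s in self.rate_syms:
            if s in out:
                out[s] /= c
        return out


# ---------------------------------------------------------------------------
# Objective
# ---------------------------------------------------------------------------

class _Objective:
    """Deterministic Monte-Carlo composite-likelihood objective (CRN)."""

    def __init__(self, model, observed: JointSFS, constants, transform,
                 seeds: np.ndarray, anchor_ne, prob_floor,
                 smoothing: float = 0.0):
        self.model = model
        self.observed = observed
        self.constants = constants
        self.transform = transform
        self.seeds = seeds
        self.anchor_ne = anchor_ne
        self.prob_floor = prob_floor
        self.smoothing = smoothing
        self.sample_config = SampleConfig(*observed.sizes)
        idx, counts = observed.cells()
        self._idx = tuple(idx.T)
        self._counts = counts
        self.n_evals = 0

    def params_at(self, x: np.ndarray) -> dict:
        params = self.transform.decode(x)
        if self.anchor_ne:
            params = self.transform.anchor(params, self.anchor_ne)
        return params

    def loglik(self, x: np.ndarray, seeds: np.ndarray | None = None) -> float:
        params = self.params_at(x)
        try:
            args = kernel_args(self.model, params, self.constants,
                               self.sample_config)
        except ValueError:
            return -np.inf
        probs = sfs_kernel_probs(args, seeds if seeds is not None else self.seeds,
                                 self.sample_config)
        p = probs[self._idx]
        if self.smoothing > 0:
            ncells = probs.size - 2  # polymorphic configurations
            p = (p + self.smoothing / ncells) / (1.0 + self.smoothing)
            return float(np.sum(self._counts * np.log(p)))
        return float(np.sum(self._counts *
                            np.log(np.maximum(p, self.prob_floor))))

    def __call__(self, x: np.ndarray) -> float:
        self.n_evals += 1
        ll = self.loglik(x)
        return -ll if np.isfinite(ll) else 1e12


# ---------------------------------------------------------------------------
# Optimisation
# ---------------------------------------------------------------------------

def _nm(fun, x0, lo, hi, maxfev):
    return minimize(fun, x0, method="Nelder-Mead",
                    bounds=list(zip(lo, hi)),
                    options={"maxfev": maxfev, "adaptive": True,
                             "xatol": 1e-3, "fatol": 1e-3})


def optimize_model(model: DemographicModel, observed: JointSFS,
                   opt_config: OptConfig = OptConfig(),
                   constants: EvolutionaryConstants = EvolutionaryConstants(),
                   warm_starts: Sequence[ParameterSet] = (),
                   ) -> FitResult:
    """Multi-start bounded Nelder-Mead maximisation of the composite lnL.

    Each start draws its initial point log-uniformly within bounds (warm
    starts, if given, replace the first starts) and is optimised in two
    stages under its own fixed CRN seed: first the divergence backbone
    (sizes and split times) with all event intensities at neutral values,
    then — for the best ``keep_frac`` of starts — the full parameter vector
    with a restart.  All survivors are re-scored with ``final_mc_reps``
    replicates under a single shared seed and the best point (ties broken
    by smaller transformed-parameter norm) is returned.
    """
    if observed.total <= 0:
        raise ValueError("observed SFS is empty")
    transform = ParamTransform(model)
    k = count_free_parameters(model)
    start_seeds = derive_seeds(opt_config.seed, max(opt_config.n_starts, 1))
    # the final-comparison seed set depends only on the config seed, so fits
    # with different n_starts stay commensurable
    final_seeds = derive_seeds(opt_config.seed + 24251, opt_config.final_mc_reps)
    rng = np.random.default_rng(np.random.SeedSequence(opt_config.seed).spawn(1)[0])

    def make_obj(seeds):
        return _Objective(model, observed, constants, transform, seeds,
                          opt_config.anchor_ne, opt_config.prob_floor,
                          opt_config.smoothing)

    if k == 0:
        obj = make_obj(final_seeds)
        x = np.empty(0)
        ll = obj.loglik(x)
        params = obj.params_at(x)
        rec = StartRecord(dict(params), ll, ll, 1, True)
        return FitResult(model.name, params, ll, 0, [rec], opt_config.seed)

    maxfev = opt_config.evals_for(k)
    backbone = transform.backbone_idx
    obj_final = make_obj(final_seeds)

    # stage A: backbone-only search from every start
    stage_a = []
    for s in range(opt_config.n_starts):
        seeds_a = derive_seeds(int(start_seeds[s]), opt_config.stage_a_reps)
        obj_a = make_obj(seeds_a)
        warm = s < len(warm_starts)
        if warm:
            x1 = transform.encode(warm_starts[s])
            x0_params = dict(warm_starts[s])
        else:
            x0 = transform.neutralize(transform.sample_start(rng))
            x0_params = transform.decode(x0)
            if backbone:  # full-dimensional when nothing but backbone is free
                def f_bb(xb, x0=x0, obj_a=obj_a):
                    xx = x0.copy()
                    xx[backbone] = xb
                    obj_a.n_evals += 1
                    ll = obj_a.loglik(xx)
                    return -ll if np.isfinite(ll) else 1e12
                res = _nm(f_bb, x0[backbone], transform.lo[backbone],
                          transform.hi[backbone], min(300, maxfev))
                x1 = x0.copy()
                x1[backbone] = res.x
            else:
                x1 = x0
        stage_a.append({"x": x1, "seed": int(start_seeds[s]),
                        "x0_params": x0_params, "warm": warm,
                        "ll_a": obj_final.loglik(x1), "n_evals": 0})

    # stage B: full-dimension search for the most promising starts
    n_keep = max(2, int(np.ceil(opt_config.keep_frac * opt_config.n_starts)))
    n_keep = min(n_keep, opt_config.n_starts)
    order = sorted(range(len(stage_a)),
                   key=lambda i: -stage_a[i]["ll_a"])
    survivors = sorted(order[:n_keep])
    scored = []
    for i, rec in enumerate(stage_a):
        if i not in survivors:
            scored.append((rec["x"], rec["ll_a"], rec["ll_a"], rec["n_evals"],
                           False, rec["x0_params"]))
            continue
        seeds_b = derive_seeds(rec["seed"], opt_config.mc_reps)
        obj_b = make_obj(seeds_b)
        res = _nm(obj_b, rec["x"], transform.lo, transform.hi, maxfev)
        res = _nm(obj_b, res.x, transform.lo, transform.hi, max(maxfev // 2, 100))
        ll_fin = obj_final.loglik(res.x)
        if rec["ll_a"] > ll_fin:
            # the full search wandered off on its noisier surface: keep the
            # stage-A point, which already scores better under final seeds
            scored.append((rec["x"], rec["ll_a"], rec["ll_a"],
                           obj_b.n_evals, True, rec["x0_params"]))
        else:
            scored.append((res.x, -res.fun, ll_fin, obj_b.n_evals, True,
                           rec["x0_params"]))
    if not any(np.isfinite(r[2]) for r in scored):
        raise RuntimeError("objective non-finite at all starts")
    best = max(scored,
               key=lambda r: (r[2] if np.isfinite(r[2]) else -np.inf,
                              -float(np.linalg.norm(r[0]))))
    best_params = obj_final.params_at(best[0])

    bound_hits = []
    for i, s in enumerate(transform.free):
        span = transform.hi[i] - transform.lo[i]
        if (best[0][i] - transform.lo[i] < 1e-3 * span
                or transform.hi[i] - best[0][i] < 1e-3 * span):
            bound_hits.append(s)
    if bound_hits:
        logger.info("fit of %s: parameters at bounds: %s",
                    model.name, bound_hits)

    starts = [StartRecord(p0, lls, llf, nev, ok)
              for _, lls, llf, nev, ok, p0 in scored]
    return FitResult(model.name, best_params, best[2], k, starts,
                     opt_config.seed, bound_hits)


# ---------------------------------------------------------------------------
# Parametric bootstrap
# ---------------------------------------------------------------------------

def joint_sfs_from_masks(masks: np.ndarray, sample_config: SampleConfig,
                         ) -> JointSFS:
    """Direct tabulation of simulated derived-allele masks into a JointSFS."""
    mA, mB, mC = sample_config.pop_masks()
    iA = np.bitwise_count(masks & mA).astype(np.int64)
    iB = np.bitwise_count(masks & mB).astype(np.int64)
    iC = np.bitwise_count(masks & mC).astype(np.int64)
    sizes = sample_config.sizes
    counts = np.zeros(tuple(m + 1 for m in sizes))
    np.add.at(counts, (iA, iB, iC), 1.0)
    counts[0, 0, 0] = 0.0
    counts[sizes[0], sizes[1], sizes[2]] = 0.0
    return JointSFS(sizes=sizes, counts=counts,
                    n_input_sites=float(masks.size))


def parametric_bootstrap(model: DemographicModel, fitted_params: ParameterSet,
                         n_loci: int, n_boot: int,
                         opt_config: OptConfig = OptConfig(n_starts=2),
                         constants: EvolutionaryConstants = EvolutionaryConstants(),
                         sample_config: SampleConfig | None = None,
                         data_sample_config: SampleConfig | None = None,
                         missing_rate: float = 0.0,
                         warm_start: bool = True,
                         level: float = 0.95) -> BootstrapResult:
    """Percentile bootstrap: re-simulate ``n_loci`` conditioned SNPs under
    the fitted parameters, refit the same model, and return per-parameter
    percentile intervals.

    ``sample_config`` gives the haploid sizes of the *analysed* spectrum.
    When ``data_sample_config`` is provided, each replicate emulates the
    full observation process — diploid genotypes at those (larger) sample
    sizes, genotype masking at ``missing_rate``, then expected hypergeometric
    projection down to ``sample_config`` — so replicate spectra are
    distributed like the observed one.  Otherwise sites are tabulated
    directly at ``sample_config``.

    With ``warm_start`` each refit starts at the fitted parameters (fast,
    good for well-converged fits); without it refits re-run the same
    random multi-start schedule as a fresh fit, which keeps the refit
    estimator distributionally identical to the one that produced the
    observed-data estimate — the condition percentile intervals rely on.
    """
    from .sfs import build_joint_sfs

    if sample_config is None:
        sample_config = SampleConfig(12, 12, 12)
    transform = ParamTransform(model)
    boot_seeds = derive_seeds(opt_config.seed + 101, n_boot)
    estimates: dict[str, list] = {s: [] for s in transform.free}
    n_failed = 0
    for b in range(n_boot):
        if data_sample_config is not None:
            from .engine import simulate_snp_dataset

            table = simulate_snp_dataset(model, fitted_params, n_loci,
                                         data_sample_config, missing_rate,
                                         int(boot_seeds[b]), constants)
            sfs_b = build_joint_sfs(table,
                                    projection_sizes=sample_config.sizes)
        else:
            masks = simulate_snp_masks(model, fitted_params, n_loci,
                                       sample_config, int(boot_seeds[b]),
                                       constants)
            sfs_b = joint_sfs_from_masks(masks, sample_config)
        cfg_b = replace(opt_config, seed=int(boot_seeds[b]))
        warm = [fitted_params] if warm_start else []
        try:
            fit_b = optimize_model(model, sfs_b, cfg_b, constants,
                                   warm_starts=warm)
        except RuntimeError as exc:
            logger.warning("bootstrap replicate %d failed: %s", b, exc)
            n_failed += 1
            continue
        for s in transform.free:
            estimates[s].append(fit_b.params[s])
    alpha = (1.0 - level) / 2.0
    reps = {s: np.asarray(v) for s, v in estimates.items()}
    ci = {}
    for s, v in reps.items():
        if v.size == 0:
            ci[s] = (np.nan, np.nan)
        else:
            ci[s] = (float(np.percentile(v, 100 * alpha)),
                     float(np.percentile(v, 100 * (1 - alpha))))
    return BootstrapResult(ci=ci, replicates=reps,
                           n_boot=n_boot, n_failed=n_failed, level=level)
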