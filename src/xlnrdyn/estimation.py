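"""Least-squares fitting of the regulon kinetics to time-course data.

Each gene is fitted on its own, jointly to the 1 mM and 50 mM induction
time courses: the combined goal is J_comb = J_1 + J_50 with
J_c = sum_j (y_cj - yhat_cj)^2, the plain sum of squared differences
between measured and model-predicted transcript levels.

The study's sequential protocol is reproduced by
:func:`two_stage_protocol`:

* stage 1a — full per-gene fits on the wild type;
* stage 1b — the least-sensitive shared block
  theta1 = (K_on, K_off, k1, k2) is averaged across genes, fixed, and the
  gene-specific block theta2 = (k_is, K_i1, K_i2, k_id) re-estimated;
* stage 2  — for the CreA mutant, theta1-bar and the gene's (K_i1, k_id)
  are held at their wild-type values and only (k_is_Mt, K_i2_Mt) are
  estimated (a config variant additionally frees k_id).

Optimization runs in log-parameter space (positivity by construction)
with a bounded trust-region least-squares solver and seeded multi-start.
Inside the optimizer the model is evaluated by an exact-propagator
predictor: the (X, x_CreA) subsystem is linear and solved in closed form
for constant/exponential xylose inputs, and the transcript equation is
advanced with an integrating-factor trapezoidal update on a fine grid.
The reference solve_ivp integrator in :mod:`xlnrdyn.kinetics` is the
oracle this predictor is checked against.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.signal import lfilter
from scipy.stats import f as f_dist

from .data import TimeCourse, group_by_gene
from .kinetics import (
    InputSignal,
    IntegrationError,
    KineticParameters,
    LegacyParameters,
    psi_crea,
    psi_xyl,
    simulate,
)

__all__ = [
    "FitOptions",
    "ProtocolConfig",
    "FitResult",
    "ProtocolResult",
    "RepressionComparison",
    "ProtocolError",
    "predict_timecourse",
    "residuals",
    "goal_value",
    "fit_gene",
    "two_stage_protocol",
    "fold_change",
    "compare_repression_models",
    "sensitivity_ranking",
    "default_input",
]

THETA1_NAMES = ("K_on", "K_off", "k1", "k2")
THETA2_NAMES = ("k_is", "K_i1", "K_i2", "k_id")
FULL_NAMES = THETA1_NAMES + THETA2_NAMES


class ProtocolError(ValueError):
    """Raised when the two-stage protocol preconditions are violated."""


def default_input(condition_mM: float) -> InputSignal:
    # local import: synthetic hosts the calibrated depletion profiles
    from .synthetic import xylose_profile

    return xylose_profile(condition_mM)


def _resolve(names: Sequence[str], strain: str) -> tuple[str, ...]:
    """Map generic parameter names to strain-specific dataclass fields."""
    out = []
    for n in names:
        if n in ("k_is", "K_i2"):
            out.append(f"{n}_{strain}")
        else:
            out.append(n)
    return tuple(out)


# ---------------------------------------------------------------------------
# Fast trajectory prediction
# ---------------------------------------------------------------------------

def _first_order_response(t: np.ndarray, amp: float, rho: float, k: float,
                          x0: float = 0.0) -> np.ndarray:
    """Closed-form solution of x' = amp*exp(-rho*t) - k*x, x(0) = x0."""
    if abs(k - rho) > 1e-10 * max(k, rho, 1.0):
        forced = amp * (np.exp(-rho * t) - np.exp(-k * t)) / (k - rho)
    else:  # resonant limit k == rho
        forced = amp * t * np.exp(-k * t)
    return x0 * np.exp(-k * t) + forced


def _xi_exponential_trapezoid(a: np.ndarray, dt: float, k_id: float,
                              x0: float) -> np.ndarray:
    """Advance x' = a(t) - k_id*x on a uniform grid with the exact propagator.

    x_{n+1} = E x_n + (dt/2) (E a_n + a_{n+1}),  E = exp(-k_id dt);
    second-order in dt, unconditionally stable for any k_id > 0.
    """
    E = math.exp(-k_id * dt)
    forcing = 0.5 * dt * (E * a[:-1] + a[1:])
    y, _ = lfilter([1.0], [1.0, -E], forcing, zi=np.array([E * x0]))
    return np.concatenate(([x0], y))


#: end of the refined early segment of the prediction grid (h); covers the
#: fast equilibration of X (1/K_off) and CreA (1/k2) after the xylose pulse
_EARLY_SEGMENT = 0.25


def _prediction_grid(t_end: float, n_fine: int) -> tuple[np.ndarray, np.ndarray]:
    """Two uniform segments, dense over the initial transient."""
    if t_end <= 2 * _EARLY_SEGMENT:
        return np.linspace(0.0, t_end, n_fine + 1), np.array([], dtype=float)
    n1 = n_fine // 2
    seg1 = np.linspace(0.0, _EARLY_SEGMENT, n1 + 1)
    seg2 = np.linspace(_EARLY_SEGMENT, t_end, n_fine - n1 + 1)
    return seg1, seg2[1:]


def predict_timecourse(
    params,
    u: InputSignal,
    times: np.ndarray,
    model: str = "new",
    strain: str = "Wt",
    use_repression: bool = True,
    x_i0: float = 0.0,
    n_fine: int = 3000,
    fast: bool = True,
) -> np.ndarray:
    """Model-predicted transcript level x_i at the observation times.

    The fast path requires a constant or exponential-decay input; other
    input kinds fall back to the reference integrator.
    """
    times = np.asarray(times, dtype=float)
    if not fast or u.kind == "interp":
        init = [0.0, 0.0, x_i0] if model == "new" else [0.0, x_i0]
        grid = times if times[0] == 0 else np.concatenate(([0.0], times))
        traj = simulate(params, u, grid, init=init, model=model, strain=strain,
                        knockout=(model == "new" and not use_repression))
        return np.interp(times, traj["time_h"].to_numpy(), traj["x_i"].to_numpy())

    rho = u.decay_rate if u.kind == "exp" else 0.0
    seg1, seg2 = _prediction_grid(float(times[-1]), n_fine)
    t_f = np.concatenate([seg1, seg2])
    if model == "new":
        X = _first_order_response(t_f, params.K_on * params.x_xlnR_const * u.u0,
                                  rho, params.K_off)
        k_is, K_i2 = params.for_strain(strain)
        act = psi_xyl(X, params.K_i1, params.h1)
        if use_repression:
            crea = _first_order_response(t_f, params.k1 * u.u0, rho, params.k2)
            rep = psi_crea(crea, K_i2, params.h2)
        else:
            rep = 1.0
        a = k_is * act * rep
        k_id = params.k_id
    elif model == "legacy":
        x_xlnr = _first_order_response(t_f, params.b * u.u0, rho, params.k_d)
        num = (params.k_i1 * x_xlnr) ** params.h1
        act = num / (1.0 + num)
        rep = 1.0 / (1.0 + (params.k_i2 * u(t_f)) ** params.h2)
        a = params.k_is * act * rep
        k_id = params.k_id
    else:
        raise ValueError(f"unknown model {model!r}")
    n1 = seg1.size
    x1 = _xi_exponential_trapezoid(a[:n1], seg1[1] - seg1[0], k_id, x_i0)
    if seg2.size:
        a2 = a[n1 - 1:]  # boundary point opens the second segment
        x2 = _xi_exponential_trapezoid(a2, seg2[0] - seg1[-1], k_id, x1[-1])
        x_fine = np.concatenate([x1, x2[1:]])
    else:
        x_fine = x1
    return np.interp(times, t_f, x_fine)


# ---------------------------------------------------------------------------
# Residuals and goal function
# ---------------------------------------------------------------------------

def residuals(
    tc: TimeCourse,
    params,
    u: InputSignal,
    model: str = "new",
    strain: str | None = None,
    use_repression: bool = True,
    weighted: bool = False,
    x_i0: float | None = None,
    n_fine: int = 3000,
    fast: bool = True,
) -> np.ndarray:
    """Vector of y_ij - yhat_ij for one gene and one induction condition.

    ``x_i0`` defaults to the first measured value (cultures were pregrown
    on sorbitol, a non-inducing carbon source, so the trajectory starts at
    the observed baseline).
    """
    strain = strain or tc.strain
    x0 = float(tc.mean[0]) if x_i0 is None else x_i0
    yhat = predict_timecourse(params, u, tc.times, model=model, strain=strain,
                              use_repression=use_repression, x_i0=x0,
                              n_fine=n_fine, fast=fast)
    r = tc.mean - yhat
    if weighted:
        w = np.where(tc.sd > 0, tc.sd, np.nanmax(tc.sd) or 1.0)
        r = r / w
    return r


def goal_value(*residual_vectors: np.ndarray) -> float:
    """Sum of squared residuals across the given condition blocks."""
    return float(sum(np.dot(r, r) for r in residual_vectors))


# ---------------------------------------------------------------------------
# Per-gene fitting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FitOptions:
    """Optimizer settings for one per-gene fit.

    ``bounds_scale`` multiplies each free parameter's initialization to
    give box bounds; multi-start draws are log-uniform within the box.
    ``accept_frac`` delimits the near-optimal ensemble used for the
    coefficient of variation: local optima whose goal is within that
    fraction of the best are treated as replicate estimates.
    """

    n_restarts: int = 20
    bounds_scale: tuple[float, float] = (1e-3, 1e3)
    bounds_scale_overrides: Mapping[str, tuple[float, float]] | None = None
    weighted: bool = False
    model: str = "new"
    use_repression: bool = True
    n_fine: int = 3000
    accept_frac: float = 0.01
    ftol: float = 1e-10
    xtol: float = 1e-10
    max_nfev: int | None = None


@dataclass
class FitResult:
    """Estimates and diagnostics for one gene in one strain."""

    gene: str
    strain: str
    theta_hat: KineticParameters
    free: tuple[str, ...]
    fixed_mask: dict[str, bool]
    J1: float
    J50: float
    residuals: dict[float, np.ndarray]
    cv: dict[str, float]
    converged: bool
    n_restarts_used: int
    ensemble: list[tuple[float, dict[str, float]]] = field(default_factory=list)

    @property
    def J_comb(self) -> float:
        return self.J1 + self.J50

    def estimates(self) -> dict[str, float]:
        d = self.theta_hat.to_dict()
        return {k: d[k] for k in self.free}


def _make_params(init: KineticParameters, free: Sequence[str],
                 values: np.ndarray) -> KineticParameters:
    return init.replace(**{n: float(v) for n, v in zip(free, values)})


def fit_gene(
    tc_1mM: TimeCourse,
    tc_50mM: TimeCourse,
    init: KineticParameters,
    free: Sequence[str] = THETA2_NAMES,
    u_1mM: InputSignal | None = None,
    u_50mM: InputSignal | None = None,
    options: FitOptions = FitOptions(),
    seed: int | np.random.SeedSequence = 0,
    extra_starts: Sequence[Mapping[str, float]] = (),
) -> FitResult:
    """Minimize J_comb = J_1 + J_50 over the free parameters of one gene.

    Multi-start bounded least squares in log-parameter space; start 0 is
    the supplied initialization, the rest are seeded log-uniform draws
    within the bounds (plus any ``extra_starts``). Ties on the goal are
    broken by the smaller log-parameter norm. Failure of every start
    yields a flagged non-convergent result, not an exception.
    """
    if tc_1mM.gene != tc_50mM.gene or tc_1mM.strain != tc_50mM.strain:
        raise ValueError("both conditions must belong to the same gene and strain")
    strain = tc_1mM.strain
    free = _resolve(free, strain)
    u1 = u_1mM or default_input(tc_1mM.condition)
    u50 = u_50mM or default_input(tc_50mM.condition)

    z0 = np.log([getattr(init, n) for n in free])
    over = options.bounds_scale_overrides or {}
    scales = [over.get(n, options.bounds_scale) for n in free]
    lo = z0 + np.log([s[0] for s in scales])
    hi = z0 + np.log([s[1] for s in scales])

    def residual_fun(z):
        p = _make_params(init, free, np.exp(z))
        r1 = residuals(tc_1mM, p, u1, model=options.model, strain=strain,
                       use_repression=options.use_repression,
                       weighted=options.weighted, n_fine=options.n_fine)
        r50 = residuals(tc_50mM, p, u50, model=options.model, strain=strain,
                        use_repression=options.use_repression,
                        weighted=options.weighted, n_fine=options.n_fine)
        return np.concatenate([r1, r50])

    rng = np.random.default_rng(seed)
    starts = [z0]
    for s in extra_starts:
        starts.append(np.clip(np.log([s[n] for n in free]), lo, hi))
    for _ in range(max(options.n_restarts - 1, 0)):
        starts.append(rng.uniform(lo, hi))

    solutions = []
    for z_start in starts:
        try:
            res = least_squares(
                residual_fun, z_start, bounds=(lo, hi), method="trf",
                ftol=options.ftol, xtol=options.xtol, gtol=1e-12,
                max_nfev=options.max_nfev,
            )
        except (IntegrationError, FloatingPointError, OverflowError):
            continue
        J = float(np.dot(res.fun, res.fun))
        if math.isfinite(J):
            solutions.append((J, float(np.linalg.norm(res.x)), res.x))

    n_used = len(starts)
    if not solutions:
        fixed_mask = {n: n not in free for n in init.to_dict()}
        return FitResult(tc_1mM.gene, strain, init, free, fixed_mask,
                         math.inf, math.inf, {}, {n: math.nan for n in free},
                         converged=False, n_restarts_used=n_used)

    solutions.sort(key=lambda s: (s[0], s[1]))
    J_best, _, z_best = solutions[0]
    theta_hat = _make_params(init, free, np.exp(z_best))

    r1 = residuals(tc_1mM, theta_hat, u1, model=options.model, strain=strain,
                   use_repression=options.use_repression,
                   weighted=options.weighted, n_fine=options.n_fine)
    r50 = residuals(tc_50mM, theta_hat, u50, model=options.model, strain=strain,
                    use_repression=options.use_repression,
                    weighted=options.weighted, n_fine=options.n_fine)

    cutoff = J_best * (1.0 + options.accept_frac) + 1e-300
    accepted = [np.exp(z) for J, _, z in solutions if J <= cutoff]
    ensemble = [
        (J, {n: float(v) for n, v in zip(free, np.exp(z))})
        for J, _, z in solutions if J <= cutoff
    ]
    est = np.exp(z_best)
    spread = np.std(np.array(accepted), axis=0) if len(accepted) > 1 else np.zeros_like(est)
    cv = {n: float(s / e) for n, s, e in zip(free, spread, est)}

    fixed_mask = {n: n not in free for n in init.to_dict()}
    return FitResult(tc_1mM.gene, strain, theta_hat, free, fixed_mask,
                     goal_value(r1), goal_value(r50),
                     {tc_1mM.condition: r1, tc_50mM.condition: r50},
                     cv, converged=True, n_restarts_used=n_used,
                     ensemble=ensemble)


# ---------------------------------------------------------------------------
# Two-stage protocol
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProtocolConfig:
    """Configuration of the sequential wild-type -> mutant protocol.

    Stage 1a defaults to a single local fit from the supplied
    initialization rather than a multi-start search: the shared block is
    weakly identifiable (X and CreA equilibrate much faster than the
    sampling interval, so essentially only the ratios K_on/K_off and
    k1/k2 are constrained), and global restarts merely return arbitrary
    points on that ridge. Its only role is to seed the cross-gene
    average that is then fixed. The well-conditioned theta2 stages keep
    full multi-start.
    """

    init: KineticParameters = KineticParameters()
    options: FitOptions = FitOptions()
    n_restarts_stage1a: int | None = 1
    #: stage-1a refinement window for the shared block, as (lower, upper)
    #: factors around its initialization. The block carries two exact
    #: scale degeneracies — rescaling K_on together with every K_i1, or
    #: k1 with every K_i2, changes no trajectory — and the only other
    #: signal (the sub-sampling-interval equilibration transients of X
    #: and CreA) is far below realistic noise floors. Per-gene
    #: "refinement" of such directions just chases noise to the window
    #: edges, so the default anchors the block exactly at its
    #: initialization (stage 1a then estimates the gene-specific block
    #: against the fixed convention); widen the window to let unusually
    #: informative data (e.g. dense early sampling) move it.
    theta1_bounds_scale: tuple[float, float] = (1.0, 1.0)
    free_kid_in_mt: bool = False
    seed: int = 0


@dataclass
class ProtocolResult:
    stage1a: dict[str, FitResult]
    theta1_bar: dict[str, float]
    wt: dict[str, FitResult]
    mt: dict[str, FitResult]
    fold_changes: dict[str, float]
    config: ProtocolConfig

    def params_frame(self) -> pd.DataFrame:
        """One row per (gene, strain) with estimates, goals and CVs."""
        rows = []
        for stage, results in (("Wt", self.wt), ("Mt", self.mt)):
            for gene, fr in sorted(results.items()):
                row = {"gene": gene, "strain": stage}
                row.update(fr.theta_hat.to_dict())
                row.update({"J1": fr.J1, "J50": fr.J50, "J_comb": fr.J_comb,
                            "converged": fr.converged})
                for n, v in fr.cv.items():
                    row[f"cv_{n}"] = v
                if stage == "Mt" and gene in self.fold_changes:
                    row["lambda"] = self.fold_changes[gene]
                rows.append(row)
        return pd.DataFrame(rows)


def two_stage_protocol(
    wt_data: Sequence[TimeCourse],
    mt_data: Sequence[TimeCourse] = (),
    config: ProtocolConfig = ProtocolConfig(),
) -> ProtocolResult:
    """Run the sequential wild-type -> mutant estimation protocol.

    Every mutant gene must have a wild-type counterpart, because stage 2
    reuses that gene's wild-type (K_i1, k_id).
    """
    wt = group_by_gene(wt_data)
    mt = group_by_gene(mt_data)
    missing = sorted(set(mt) - set(wt))
    if missing:
        raise ProtocolError(
            f"Mt genes without a Wt counterpart: {missing}; stage 2 needs "
            "the wild-type K_i1 and k_id for every mutant gene"
        )

    def pair(d, gene):
        conds = sorted(d[gene])
        if len(conds) != 2:
            raise ProtocolError(
                f"{gene}: need exactly two induction conditions, got {conds}"
            )
        return d[gene][conds[0]], d[gene][conds[1]]

    genes_wt = sorted(wt)
    genes_mt = sorted(mt)
    ss = np.random.SeedSequence(config.seed)
    seeds = ss.spawn(2 * len(genes_wt) + len(genes_mt))
    opts = config.options
    opts_1a = opts if config.n_restarts_stage1a is None else replace(
        opts, n_restarts=config.n_restarts_stage1a)
    opts_1a = replace(
        opts_1a,
        bounds_scale_overrides={
            **(opts_1a.bounds_scale_overrides or {}),
            **{n: config.theta1_bounds_scale for n in THETA1_NAMES},
        },
    )

    # stage 1a: per-gene wild-type fits. With the default exactly-anchored
    # shared block only theta2 is free here; with a widened window the
    # full vector is refined, warm-started from a theta2-only prefit so
    # the trust-region solver is not kicked along the shared block's flat
    # directions while the gene-specific misfit is still large.
    anchored = config.theta1_bounds_scale == (1.0, 1.0)
    stage1a = {}
    for i, gene in enumerate(genes_wt):
        lo_tc, hi_tc = pair(wt, gene)
        if anchored:
            stage1a[gene] = fit_gene(lo_tc, hi_tc, config.init, THETA2_NAMES,
                                     options=opts, seed=seeds[i])
            continue
        pre = fit_gene(lo_tc, hi_tc, config.init, THETA2_NAMES,
                       options=opts, seed=seeds[i])
        start = pre.theta_hat if pre.converged else config.init
        stage1a[gene] = fit_gene(lo_tc, hi_tc, start, FULL_NAMES,
                                 options=opts_1a, seed=seeds[i])

    # stage 1b: consolidate the insensitive shared block across genes, fix
    # it, and re-estimate theta2. Rate constants are positive and their
    # per-gene estimates scatter multiplicatively (along the scale
    # degeneracies), so the geometric mean is the appropriate average: it
    # is unbiased in log space and commutes with the identifiable ratios
    # K_on/K_off and k1/k2.
    converged = [fr for fr in stage1a.values() if fr.converged]
    if not converged:
        raise ProtocolError("no wild-type gene converged in stage 1a")
    def geomean(values: list[float]) -> float:
        if len(values) == 1:  # mean of one is exact, no log round-trip
            return values[0]
        return float(np.exp(np.mean(np.log(values))))

    theta1_bar = {
        n: geomean([getattr(fr.theta_hat, n) for fr in converged])
        for n in THETA1_NAMES
    }
    wt_results = {}
    for i, gene in enumerate(genes_wt):
        lo_tc, hi_tc = pair(wt, gene)
        init = config.init.replace(**theta1_bar)
        warm = stage1a[gene]
        extra = [
            {n: getattr(warm.theta_hat, n) for n in _resolve(THETA2_NAMES, "Wt")}
        ] if warm.converged else []
        init = init.replace(**(extra[0] if extra else {}))
        wt_results[gene] = fit_gene(lo_tc, hi_tc, init, THETA2_NAMES,
                                    options=opts, seed=seeds[len(genes_wt) + i])

    # stage 2: mutant fits with theta1-bar and wild-type (K_i1, k_id) fixed
    mt_results = {}
    fold = {}
    mt_free = ("k_is", "K_i2", "k_id") if config.free_kid_in_mt else ("k_is", "K_i2")
    for i, gene in enumerate(genes_mt):
        lo_tc, hi_tc = pair(mt, gene)
        wt_fr = wt_results[gene]
        init = config.init.replace(
            **theta1_bar,
            K_i1=wt_fr.theta_hat.K_i1,
            k_id=wt_fr.theta_hat.k_id,
            k_is_Mt=wt_fr.theta_hat.k_is_Wt,
            K_i2_Mt=wt_fr.theta_hat.K_i2_Wt,
        )
        mt_results[gene] = fit_gene(lo_tc, hi_tc, init, mt_free,
                                    options=opts,
                                    seed=seeds[2 * len(genes_wt) + i])
        if wt_fr.converged and mt_results[gene].converged:
            fold[gene] = fold_change(wt_fr, mt_results[gene])

    return ProtocolResult(stage1a, theta1_bar, wt_results, mt_results, fold, config)


def fold_change(fit_wt: FitResult, fit_mt: FitResult) -> float:
    """De-repression fold-change lambda = k_is_Mt / k_is_Wt for one gene."""
    if fit_wt.gene != fit_mt.gene:
        raise ValueError("fold change requires the same gene in both strains")
    if not (fit_wt.converged and fit_mt.converged):
        raise ValueError("fold change requires two converged fits")
    k_wt = fit_wt.theta_hat.k_is_Wt
    if k_wt == 0:
        raise ZeroDivisionError("k_is_Wt is zero")
    return fit_mt.theta_hat.k_is_Mt / k_wt


# ---------------------------------------------------------------------------
# Nested hypothesis test: is CreA repression needed?
# ---------------------------------------------------------------------------

@dataclass
class RepressionComparison:
    """Extra-sum-of-squares comparison of the full model vs psi_CreA == 1."""

    gene: str
    J_full: float
    J_reduced: float
    n_params_full: int
    n_params_reduced: int
    n_obs: int
    f_statistic: float
    p_value: float
    alpha: float

    @property
    def repression_significant(self) -> bool:
        return self.p_value < self.alpha


def compare_repression_models(
    tc_1mM: TimeCourse,
    tc_50mM: TimeCourse,
    init: KineticParameters,
    free_full: Sequence[str] = THETA2_NAMES,
    options: FitOptions = FitOptions(),
    seed: int | np.random.SeedSequence = 0,
    alpha: float = 0.05,
) -> RepressionComparison:
    """Test whether CreA repression significantly improves the fit.

    The reduced model clamps the repression factor to 1 (no functional
    CreA); it is nested in the full model, which is additionally started
    from the reduced optimum with K_i2 at its upper bound so the nested
    inequality J_full <= J_reduced holds numerically. Significance is the
    classical extra-sum-of-squares F test.
    """
    free_full = tuple(free_full)
    strain = tc_1mM.strain
    k_i2_name = f"K_i2_{strain}"
    free_reduced = tuple(n for n in free_full if n not in ("K_i2", k_i2_name))
    if free_reduced == free_full:
        raise ValueError("free_full must include the repression threshold K_i2")

    ss = np.random.SeedSequence(seed) if isinstance(seed, int) else seed
    s_red, s_full = ss.spawn(2)
    red_opts = replace(options, use_repression=False)
    fit_red = fit_gene(tc_1mM, tc_50mM, init, free_reduced, options=red_opts,
                       seed=s_red)

    # warm start at the reduced optimum, repression effectively off
    hi = options.bounds_scale[1]
    warm = {n: getattr(fit_red.theta_hat, n) for n in _resolve(free_reduced, strain)}
    warm[k_i2_name] = getattr(init, k_i2_name) * hi
    fit_full = fit_gene(tc_1mM, tc_50mM, init, free_full, options=options,
                        seed=s_full, extra_starts=[warm])

    n_obs = len(tc_1mM) + len(tc_50mM)
    p_full, p_red = len(free_full), len(free_reduced)
    J_full = min(fit_full.J_comb, fit_red.J_comb)  # nested by construction
    J_red = fit_red.J_comb
    df1, df2 = p_full - p_red, n_obs - p_full
    if df2 <= 0:
        raise ValueError("not enough observations for the nested F test")
    if J_full <= 0:
        f_stat, p_value = math.inf, 0.0
    else:
        f_stat = ((J_red - J_full) / df1) / (J_full / df2)
        p_value = float(f_dist.sf(f_stat, df1, df2))
    return RepressionComparison(tc_1mM.gene, J_full, J_red, p_full, p_red,
                                n_obs, f_stat, p_value, alpha)


# ---------------------------------------------------------------------------
# Sensitivity ranking (audit of the theta1/theta2 split)
# ---------------------------------------------------------------------------

def sensitivity_ranking(
    params: KineticParameters,
    times: np.ndarray,
    conditions: Sequence[float] = (1.0, 50.0),
    strain: str = "Wt",
    names: Sequence[str] = FULL_NAMES,
    rel_step: float = 0.05,
) -> pd.Series:
    """Finite-difference output sensitivity of each parameter, ranked.

    For each parameter the L2 norm of the change in the predicted
    trajectory under a +-5 % log-perturbation, summed over conditions, is
    reported (descending), making the shared/gene-specific split
    auditable. Note that one-at-a-time perturbations understate how
    poorly the shared block is determined: its real weakness is
    directional (K_on trades exactly against K_i1, and k1 against K_i2),
    which shows up as parameter correlations, not as small single-
    parameter sensitivities.
    """
    names = _resolve(names, strain)
    out = {}
    for n in names:
        v = getattr(params, n)
        up = params.replace(**{n: v * (1 + rel_step)})
        dn = params.replace(**{n: v * (1 - rel_step)})
        s = 0.0
        for cond in conditions:
            u = default_input(cond)
            y_up = predict_timecourse(up, u, times, strain=strain)
            y_dn = predict_timecourse(dn, u, times, strain=strain)
            s += float(np.linalg.norm(y_up - y_dn) / (2 * rel_step))
        out[n] = s
    return pd.Series(out).sort_values(ascending=False)
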