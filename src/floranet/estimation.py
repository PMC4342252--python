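"""Two-stage parameter estimation for the flowering-time network.

Stage 1 (decoupling): each of the six equations is fitted on its own.  The
trajectories of a gene's regulators are taken from the *data* (interpolated
replicate means), so each equation reduces to a scalar linear ODE in its own
state,

    dx/dt = P(t; theta) - d * x,

whose solution is computed exactly by an integrating-factor quadrature on a
dense uniform grid (exponential-trapezoid rule, a stable linear recurrence).
That makes a single objective evaluation a handful of vectorised array
operations, so a generous multistart is cheap.  The FT transport delay enters
stage 1 through the SOC1 equation, where the leaf-FT data interpolant is
evaluated at ``t - delta`` with ``delta`` free; the AP1 equation then reuses
that estimate, giving the delay a single stage-1 value.

Stage 2 (refinement): the per-equation estimates are concatenated and used as
the starting point of a bounded least-squares fit of the fully coupled
simulation against all six time courses simultaneously.

Goodness of fit is reported as NRMSE = RMSE / (x_max - x_min) per gene, with
residuals taken at the observation days against the replicate means.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
from scipy.optimize import least_squares
from scipy.signal import lfilter

from .data import InputProfiles, TimeCourse, interpolate_timecourse
from .model import IDX, SPECIES, ParameterSet, Trajectory, Variant, simulate

_PENALTY = 1e6  # residual magnitude substituted when a trial integration fails


@dataclass
class FitProblem:
    """Data, inputs and configuration for one estimation run.

    data maps each modelled gene (FT, AGL24, SOC1, LFY, AP1, FD) to its
    observed time course; inputs carries the FLC/SVP forcings.  ``fixed``
    freezes non-fitted quantities: the Hill coefficient ``n`` always, and
    optionally ``delta``.  ``bounds`` overrides the default box per parameter
    class (keys among ``beta``, ``K``, ``d``, ``delta``).
    """

    data: Mapping[str, TimeCourse]
    inputs: InputProfiles
    variant: Variant = "independent"
    fixed: Mapping[str, float] = field(default_factory=lambda: {"n": 3})
    bounds: Mapping[str, tuple[float, float]] | None = None
    interp_scheme: str = "piecewise_cubic"
    interp_degree: int = 5
    weight_by_sd: bool = False
    grid_points: int = 401

    def __post_init__(self) -> None:
        missing = [g for g in SPECIES if g not in self.data]
        if missing:
            raise ValueError(f"fit problem is missing time courses for {missing}")

    @property
    def n(self) -> int:
        return int(self.fixed.get("n", 3))

    def max_abundance(self) -> float:
        return max(float(tc.mean_abundance.max()) for tc in self.data.values())

    def class_bounds(self) -> dict[str, tuple[float, float]]:
        """Default parameter box, scaled to the data's abundance ceiling."""
        a = self.max_abundance()
        box = {
            "beta": (0.0, 10.0 * a),
            "K": (1e-3, 10.0 * a),
            "d": (1e-3, 10.0),
            "delta": (0.0, 5.0),
        }
        if self.bounds:
            box.update({k: tuple(v) for k, v in self.bounds.items()})
        for kind, (lo, hi) in box.items():
            if not (np.isfinite(lo) and np.isfinite(hi)) or hi < lo:
                raise ValueError(f"invalid bounds for {kind}: {(lo, hi)}")
        return box


@dataclass
class FitDiagnostics:
    """Per-gene goodness of fit and optimiser metadata for one stage."""

    stage: str
    per_gene_rmse: dict[str, float]
    per_gene_nrmse: dict[str, float]
    objective: float
    multistart_count: int = 0
    seed: int | None = None
    converged: bool = True
    per_equation_cost: dict[str, float] | None = None


def compute_nrmse(observed: TimeCourse, predicted) -> float:
    """NRMSE of a prediction against one observed time course.

    ``predicted`` is a Trajectory (interpolated at the observation days) or an
    array already aligned with ``observed.days``.  Normalisation is by the
    observed range; a constant series has no defined NRMSE and raises.
    """
    x_obs = observed.mean_abundance
    x_rng = float(x_obs.max() - x_obs.min())
    if x_rng <= 0:
        raise ValueError(
            f"NRMSE undefined for constant observed series ({observed.gene})"
        )
    if isinstance(predicted, Trajectory):
        x_pred = predicted.at(observed.gene, observed.days)
    else:
        x_pred = np.asarray(predicted, dtype=float)
        if x_pred.shape != x_obs.shape:
            raise ValueError("prediction and observation lengths differ")
    rmse = float(np.sqrt(np.mean((x_obs - x_pred) ** 2)))
    return rmse / x_rng


def _solve_linear_ode(grid: np.ndarray, production: np.ndarray, d: float, x0: float) -> np.ndarray:
    """Exact integrating-factor solution of dx/dt = P(t) - d*x on a uniform grid.

    Uses the exponential-trapezoid step x_{k+1} = a*x_k + (h/2)(a*P_k + P_{k+1})
    with a = exp(-d*h); the recurrence is evaluated as an IIR filter.
    """
    h = grid[1] - grid[0]
    a = float(np.exp(-d * h))
    b = 0.5 * h * (production[:-1] * a + production[1:])
    out = lfilter([1.0], [1.0, -a], b)
    x = np.empty(grid.size)
    x[0] = x0
    x[1:] = out + np.power(a, np.arange(1, grid.size)) * x0
    return x


def _hill_act(x: np.ndarray, K: float, n: float = 1.0) -> np.ndarray:
    if n == 1:
        return x / (K + x)
    r = (x / K) ** n
    return r / (1.0 + r)


def _hill_rep(x: np.ndarray, K: float) -> np.ndarray:
    return K / (K + x)


@dataclass
class _Equation:
    gene: str
    param_names: list[str]          # e.g. ["beta1", "K1", "K2", "d1"]
    production: Callable            # theta (without d) -> P on grid
    d_name: str


def _build_equations(
    problem: FitProblem,
    grid: np.ndarray,
    delta_mode: str,
    delta_value: float | None = None,
) -> list[_Equation]:
    """Assemble the six decoupled equations with regulators frozen to data.

    ``delta_mode`` is "free" (delta fitted inside the SOC1 equation) or
    "fixed" (``delta_value`` used everywhere).
    """
    interp = {
        g: interpolate_timecourse(
            problem.data[g], scheme=problem.interp_scheme, degree=problem.interp_degree
        )
        for g in SPECIES
    }
    reg = {g: interp[g](grid) for g in SPECIES}
    svp_l = np.asarray(problem.inputs.svp_leaf(grid), dtype=float)
    flc_l = np.asarray(problem.inputs.flc_leaf(grid), dtype=float)
    svp_m = np.asarray(problem.inputs.svp_meristem(grid), dtype=float)
    flc_m = np.asarray(problem.inputs.flc_meristem(grid), dtype=float)
    ft_call = interp["FT"]  # leaf FT, evaluated lagged inside SOC1/AP1 terms
    n_hill = problem.n

    def ft_lagged(delta: float) -> np.ndarray:
        return ft_call(grid - delta)  # interpolant clamps to the first data day

    eqs: list[_Equation] = []

    eqs.append(
        _Equation(
            gene="FT",
            param_names=["beta1", "K1", "K2", "d1"],
            production=lambda th: th[0] * _hill_rep(svp_l, th[1]) * _hill_rep(flc_l, th[2]),
            d_name="d1",
        )
    )
    eqs.append(
        _Equation(
            gene="AGL24",
            param_names=["beta2", "K3", "d2"],
            production=lambda th: th[0] * _hill_act(reg["SOC1"], th[1]),
            d_name="d2",
        )
    )

    soc1_names = ["beta3", "beta4", "beta5", "K4", "K5", "K6", "K7", "K8", "K9", "d3"]
    if delta_mode == "free":
        soc1_names.append("delta")

        def soc1_production(th):
            return (
                th[0] * _hill_act(reg["AGL24"], th[3])
                + th[1] * _hill_act(reg["SOC1"], th[4])
                + th[2] * _hill_act(ft_lagged(th[10]), th[5]) * _hill_act(reg["FD"], th[6])
            ) * _hill_rep(svp_m, th[7]) * _hill_rep(flc_m, th[8])

    else:

        def soc1_production(th):
            return (
                th[0] * _hill_act(reg["AGL24"], th[3])
                + th[1] * _hill_act(reg["SOC1"], th[4])
                + th[2] * _hill_act(ft_lagged(delta_value), th[5]) * _hill_act(reg["FD"], th[6])
            ) * _hill_rep(svp_m, th[7]) * _hill_rep(flc_m, th[8])

    eqs.append(
        _Equation(gene="SOC1", param_names=soc1_names, production=soc1_production, d_name="d3")
    )

    if problem.variant == "independent":
        eqs.append(
            _Equation(
                gene="LFY",
                param_names=["beta6", "beta7", "beta8", "K10", "K11", "K12", "d4"],
                production=lambda th: (
                    th[0] * _hill_act(reg["AGL24"], th[3])
                    + th[1] * _hill_act(reg["SOC1"], th[4])
                    + th[2] * _hill_act(reg["AP1"], th[5])
                ),
                d_name="d4",
            )
        )
    else:  # dimer_only: one shared strength for the AGL24-SOC1 heterodimer
        eqs.append(
            _Equation(
                gene="LFY",
                param_names=["beta7", "beta8", "K10", "K11", "K12", "d4"],
                production=lambda th: (
                    th[0] * _hill_act(reg["AGL24"], th[2]) * _hill_act(reg["SOC1"], th[3])
                    + th[1] * _hill_act(reg["AP1"], th[4])
                ),
                d_name="d4",
            )
        )

    # AP1 reuses the stage-1 delay estimate; production is built lazily so the
    # SOC1 fit can run first.
    def ap1_production_factory(delta: float):
        ft_lag = ft_lagged(delta)

        def production(th):
            return (
                th[0] * _hill_act(reg["LFY"], th[3], n_hill)
                + th[1] * _hill_act(ft_lag, th[4])
                + th[2] * _hill_act(reg["FD"], th[5])
            )

        return production

    eqs.append(
        _Equation(
            gene="AP1",
            param_names=["beta9", "beta10", "beta11", "K13", "K14", "K15", "d5"],
            production=ap1_production_factory,  # resolved in fit_decoupled
            d_name="d5",
        )
    )
    eqs.append(
        _Equation(
            gene="FD",
            param_names=["beta12", "K16", "d6"],
            production=lambda th: th[0] * _hill_act(reg["LFY"], th[1]),
            d_name="d6",
        )
    )
    return eqs


def _param_kind(name: str) -> str:
    if name.startswith("beta"):
        return "beta"
    if name.startswith("K"):
        return "K"
    if name.startswith("d") and name != "delta":
        return "d"
    return "delta"


def _sample_start(rng: np.random.Generator, names: Sequence[str], box) -> np.ndarray:
    """One random multistart point: uniform beta/delta, log-uniform K and d."""
    theta = np.empty(len(names))
    for i, name in enumerate(names):
        lo, hi = box[_param_kind(name)]
        if _param_kind(name) in ("K", "d"):
            theta[i] = np.exp(rng.uniform(np.log(max(lo, 1e-6)), np.log(hi)))
        else:
            theta[i] = rng.uniform(lo, hi)
    return theta


def _fit_single_equation(
    eq: _Equation,
    grid: np.ndarray,
    tc: TimeCourse,
    box,
    starts: int,
    rng: np.random.Generator,
    weights: np.ndarray | None,
    max_nfev: int | None = None,
) -> tuple[dict[str, float], float, bool]:
    d_pos = eq.param_names.index(eq.d_name)
    lo = np.array([box[_param_kind(p)][0] for p in eq.param_names])
    hi = np.array([box[_param_kind(p)][1] for p in eq.param_names])
    # strictly positive K/d floors keep Hill terms defined
    lo = np.where([_param_kind(p) in ("K", "d") for p in eq.param_names], np.maximum(lo, 1e-6), lo)
    x0_state = tc.first_point()
    y = tc.mean_abundance
    days = tc.days

    def residuals(theta):
        production = eq.production(theta)
        x = _solve_linear_ode(grid, production, theta[d_pos], x0_state)
        pred = np.interp(days, grid, x)
        r = pred - y
        return r * weights if weights is not None else r

    best_cost = np.inf
    best_theta = None
    any_success = False
    for _ in range(starts):
        start = _sample_start(rng, eq.param_names, box)
        try:
            res = least_squares(
                residuals, start, bounds=(lo, hi), method="trf", max_nfev=max_nfev
            )
        except Exception:
            continue
        any_success = True
        if res.cost < best_cost:
            best_cost = res.cost
            best_theta = res.x
    if best_theta is None:
        raise RuntimeError(
            f"all {starts} multistart fits failed for the {eq.gene} equation"
        )
    return dict(zip(eq.param_names, best_theta)), float(best_cost), any_success


_NAME_TO_SLOT = {f"beta{i+1}": ("beta", i) for i in range(12)}
_NAME_TO_SLOT.update({f"K{i+1}": ("K", i) for i in range(16)})
_NAME_TO_SLOT.update({f"d{i+1}": ("d", i) for i in range(6)})


def _assemble(named: Mapping[str, float], delta: float, n: int) -> ParameterSet:
    beta = np.zeros(12)
    K = np.full(16, 1.0)
    d = np.full(6, 0.1)
    for name, value in named.items():
        if name == "delta":
            continue
        kind, i = _NAME_TO_SLOT[name]
        if kind == "beta":
            beta[i] = value
        elif kind == "K":
            K[i] = value
        else:
            d[i] = value
    return ParameterSet(beta=beta, K=K, d=d, delta=delta, n=n)


def fit_decoupled(
    problem: FitProblem,
    starts: int = 100,
    seed: int = 0,
    max_nfev: int | None = None,
) -> tuple[ParameterSet, FitDiagnostics]:
    """Stage 1: fit the six equations independently with regulators from data.

    Each equation is minimised by bounded least squares from ``starts`` random
    initial points drawn from ``seed`` (the best local optimum is kept).
    Returns the concatenated parameter set and per-gene diagnostics of the
    decoupled predictions.
    """
    if starts < 1:
        raise ValueError("starts must be >= 1")
    t0 = min(tc.span[0] for tc in problem.data.values())
    t1 = max(tc.span[1] for tc in problem.data.values())
    grid = np.linspace(t0, t1, problem.grid_points)
    box = problem.class_bounds()
    delta_fixed = problem.fixed.get("delta")
    eqs = _build_equations(
        problem,
        grid,
        delta_mode="fixed" if delta_fixed is not None else "free",
        delta_value=delta_fixed,
    )
    rng = np.random.default_rng(seed)
    eq_seeds = {eq.gene: int(rng.integers(2**31)) for eq in eqs}

    named: dict[str, float] = {}
    costs: dict[str, float] = {}
    rmse: dict[str, float] = {}
    nrmse: dict[str, float] = {}
    delta_hat = float(delta_fixed) if delta_fixed is not None else 0.0

    for eq in eqs:
        tc = problem.data[eq.gene]
        weights = None
        if problem.weight_by_sd and tc.sd_abundance is not None:
            sd = np.where(np.isnan(tc.sd_abundance), 1.0, tc.sd_abundance)
            weights = 1.0 / np.maximum(sd, 1e-3)
        if eq.gene == "AP1":
            # bind the delay estimated in the SOC1 fit (or the fixed value)
            eq = replace(eq, production=eq.production(delta_hat))
        theta, cost, _ = _fit_single_equation(
            eq, grid, tc, box, starts, np.random.default_rng(eq_seeds[eq.gene]),
            weights, max_nfev,
        )
        theta_vec = np.array([theta[p] for p in eq.param_names])
        if "delta" in theta:
            delta_hat = theta.pop("delta")
        named.update(theta)
        costs[eq.gene] = cost
        # decoupled prediction for diagnostics
        x = _solve_linear_ode(grid, eq.production(theta_vec), theta[eq.d_name], tc.first_point())
        pred = np.interp(tc.days, grid, x)
        rmse[eq.gene] = float(np.sqrt(np.mean((pred - tc.mean_abundance) ** 2)))
        # a constant observed series has no defined NRMSE; keep RMSE, mark NaN
        rng_obs = tc.mean_abundance.max() - tc.mean_abundance.min()
        nrmse[eq.gene] = rmse[eq.gene] / rng_obs if rng_obs > 0 else float("nan")

    if problem.variant == "dimer_only":
        named["beta6"] = 0.0
    params = _assemble(named, delta=delta_hat, n=problem.n)
    diagnostics = FitDiagnostics(
        stage="decoupled",
        per_gene_rmse=rmse,
        per_gene_nrmse=nrmse,
        objective=float(sum(costs.values())),
        multistart_count=starts,
        seed=seed,
        converged=True,
        per_equation_cost=costs,
    )
    return params, diagnostics


_PACK_ORDER = (
    [f"beta{i+1}" for i in range(12)]
    + [f"K{i+1}" for i in range(16)]
    + [f"d{i+1}" for i in range(6)]
    + ["delta"]
)


def _pack(params: ParameterSet) -> np.ndarray:
    return np.concatenate([params.beta, params.K, params.d, [params.delta]])


def _unpack(vector: np.ndarray, n: int) -> ParameterSet:
    return ParameterSet(
        beta=vector[:12], K=vector[12:28], d=vector[28:34], delta=vector[34], n=n
    )


def _coupled_residuals(problem: FitProblem, params: ParameterSet) -> np.ndarray:
    """Residuals of the fully coupled simulation at every observation day."""
    x0 = {g: problem.data[g].first_point() for g in SPECIES}
    t0 = min(tc.span[0] for tc in problem.data.values())
    t1 = max(tc.span[1] for tc in problem.data.values())
    all_days = np.unique(np.concatenate([problem.data[g].days for g in SPECIES]))
    try:
        traj = simulate(
            params,
            problem.inputs,
            x0,
            horizon=(t0, t1),
            variant=problem.variant,
            grid_step=0.2,
            extra_days=all_days,
        )
    except (RuntimeError, ValueError):
        n_resid = sum(problem.data[g].days.size for g in SPECIES)
        return np.full(n_resid, _PENALTY)
    chunks = []
    for g in SPECIES:
        tc = problem.data[g]
        r = traj.at(g, tc.days) - tc.mean_abundance
        if problem.weight_by_sd and tc.sd_abundance is not None:
            sd = np.where(np.isnan(tc.sd_abundance), 1.0, tc.sd_abundance)
            r = r / np.maximum(sd, 1e-3)
        chunks.append(r)
    return np.concatenate(chunks)


def refine_full_system(
    problem: FitProblem,
    init: ParameterSet,
    max_nfev: int | None = 300,
    xtol: float = 1e-8,
) -> tuple[ParameterSet, FitDiagnostics]:
    """Stage 2: refine a parameter set against the fully coupled simulation.

    Bounded least squares started at ``init``; a trial point whose integration
    fails contributes a large penalty residual.  The returned set never has a
    larger coupled objective than ``init`` (non-improvement is reported via
    diagnostics, not an error).  Parameters whose bounds collapse to a point
    (including beta6 under the dimer-only variant and a fixed delta) are held.
    """
    box = problem.class_bounds()
    lo = np.array([box[_param_kind(p)][0] for p in _PACK_ORDER])
    hi = np.array([box[_param_kind(p)][1] for p in _PACK_ORDER])
    is_kd = np.array([_param_kind(p) in ("K", "d") for p in _PACK_ORDER])
    lo = np.where(is_kd, np.maximum(lo, 1e-6), lo)
    if problem.variant == "dimer_only":
        lo[_PACK_ORDER.index("beta6")] = hi[_PACK_ORDER.index("beta6")] = 0.0
    if "delta" in problem.fixed:
        i = _PACK_ORDER.index("delta")
        lo[i] = hi[i] = float(problem.fixed["delta"])

    x_init = np.clip(_pack(init), lo, hi)
    free = hi > lo
    n_hill = problem.n

    def to_params(theta_free: np.ndarray) -> ParameterSet:
        full = x_init.copy()
        full[free] = theta_free
        return _unpack(full, n_hill)

    init_resid = _coupled_residuals(problem, _unpack(x_init, n_hill))
    init_cost = 0.5 * float(init_resid @ init_resid)

    if not np.any(free):
        refined, cost, converged = _unpack(x_init, n_hill), init_cost, True
    else:
        res = least_squares(
            lambda th: _coupled_residuals(problem, to_params(th)),
            x_init[free],
            bounds=(lo[free], hi[free]),
            method="trf",
            max_nfev=max_nfev,
            xtol=xtol,
        )
        if res.cost <= init_cost:
            refined, cost = to_params(res.x), float(res.cost)
        else:  # keep the better starting point; report non-improvement
            refined, cost = _unpack(x_init, n_hill), init_cost
        converged = bool(res.success)

    rmse, nrmse = coupled_fit_quality(problem, refined)
    diagnostics = FitDiagnostics(
        stage="full_system",
        per_gene_rmse=rmse,
        per_gene_nrmse=nrmse,
        objective=cost,
        multistart_count=1,
        seed=None,
        converged=converged,
    )
    return refined, diagnostics


def coupled_fit_quality(
    problem: FitProblem, params: ParameterSet
) -> tuple[dict[str, float], dict[str, float]]:
    """Per-gene RMSE and NRMSE of the coupled simulation against the data."""
    x0 = {g: problem.data[g].first_point() for g in SPECIES}
    t0 = min(tc.span[0] for tc in problem.data.values())
    t1 = max(tc.span[1] for tc in problem.data.values())
    traj = simulate(params, problem.inputs, x0, horizon=(t0, t1),
                    variant=problem.variant)
    rmse, nrmse = {}, {}
    for g in SPECIES:
        tc = problem.data[g]
        pred = traj.at(g, tc.days)
        rmse[g] = float(np.sqrt(np.mean((pred - tc.mean_abundance) ** 2)))
        rng_obs = tc.mean_abundance.max() - tc.mean_abundance.min()
        nrmse[g] = rmse[g] / rng_obs if rng_obs > 0 else float("nan")
    return rmse, nrmse


def coupled_objective(problem: FitProblem, params: ParameterSet) -> float:
    """Half the summed squared residuals of the coupled simulation."""
    r = _coupled_residuals(problem, params)
    return 0.5 * float(r @ r)


@dataclass
class HillSelection:
    best_n: int
    ap1_nrmse: dict[int, float]
    diagnostics: dict[int, FitDiagnostics]


def select_hill_coefficient(
    problem: FitProblem,
    candidates: Iterable[int] = (1, 2, 3, 4, 5),
    starts: int = 20,
    seed: int = 0,
    refine: bool = True,
    refine_max_nfev: int | None = 100,
) -> HillSelection:
    """Choose the LFY->AP1 Hill coefficient by goodness of fit.

    Runs the two-stage fit for each candidate ``n`` (only the LFY->AP1 term is
    cooperative) and returns the candidate with the lowest AP1 NRMSE, along
    with the full NRMSE-versus-n table.  A candidate whose fit fails is
    excluded with a warning.
    """
    candidates = sorted(set(int(c) for c in candidates))
    if not candidates or any(c < 1 or c > 5 for c in candidates):
        raise ValueError("candidates must be a non-empty subset of {1..5}")
    table: dict[int, float] = {}
    diags: dict[int, FitDiagnostics] = {}
    for n in candidates:
        trial = replace(problem, fixed={**dict(problem.fixed), "n": n})
        try:
            params, diag = fit_decoupled(trial, starts=starts, seed=seed)
            if refine:
                params, diag = refine_full_system(trial, params, max_nfev=refine_max_nfev)
        except RuntimeError as exc:
            warnings.warn(f"fit failed for Hill coefficient n={n}: {exc}")
            continue
        table[n] = diag.per_gene_nrmse["AP1"]
        diags[n] = diag
    if not table:
        raise RuntimeError("every candidate Hill coefficient failed to fit")
    best = min(table, key=table.get)
    return HillSelection(best_n=best, ap1_nrmse=table, diagnostics=diags)
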