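"""Six-species delayed-ODE model of the flowering-time integration network.

The modelled species are FT (in the leaf), AGL24, SOC1, LFY, AP1 and FD (in
the shoot apical meristem).  FLC and SVP are not modelled; their measured
trajectories enter as external forcing functions (:class:`~floranet.data.InputProfiles`).
All regulation is Hill-type:

* activation  x**n / (K**n + x**n)
* repression  K / (K + x)

FT is produced in leaves and acts in the meristem after a transport delay
``delta``: wherever meristem equations need FT they read the leaf value at
``t - delta``.  Because the leaf FT equation depends only on the external
inputs — never on the five meristem species — the system is triangular in the
delayed variable.  :func:`simulate` exploits this: it first integrates leaf FT
over the whole horizon, then integrates the meristem subsystem against the
lagged FT interpolant (pre-horizon history is the constant initial FT value).
This closes the method-of-steps recursion in a single pass and is exact for
this wiring.

The LFY equation has two structural variants.  In the default ``independent``
form AGL24 and SOC1 each activate LFY through their own saturating term; in
the ``dimer_only`` form they act solely as an AGL24-SOC1 heterodimer,
represented by a single product of the two Hill terms with one shared
activation strength (beta7; beta6 is structurally absent and pinned at 0).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Literal, Mapping

import numpy as np
from scipy.integrate import solve_ivp

from .data import InputProfiles

SPECIES = ("FT", "AGL24", "SOC1", "LFY", "AP1", "FD")
INPUT_GENES = ("FLC", "SVP")
NETWORK_GENES = SPECIES + INPUT_GENES

IDX = {name: i for i, name in enumerate(SPECIES)}

Variant = Literal["independent", "dimer_only"]

#: Number of free kinetic parameters: 12 beta + 16 K + 6 d + delta.
N_FREE_PARAMETERS = 35


@dataclass
class ParameterSet:
    """The 35 free kinetic parameters plus the fixed Hill coefficient ``n``.

    beta : ndarray, shape (12,)
        Maximum transcription rates beta1..beta12 (nM/day).
    K : ndarray, shape (16,)
        Half-maximum abundances K1..K16 (nM).
    d : ndarray, shape (6,)
        Degradation rates d1..d6 (1/day), one per modelled species.
    delta : float
        FT leaf-to-meristem transport delay (days).
    n : int
        Hill coefficient of the LFY -> AP1 activation term; all other
        interactions are non-cooperative (exponent 1).
    """

    beta: np.ndarray
    K: np.ndarray
    d: np.ndarray
    delta: float
    n: int = 3

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        self.K = np.asarray(self.K, dtype=float)
        self.d = np.asarray(self.d, dtype=float)
        self.delta = float(self.delta)
        self.n = int(self.n)
        if self.beta.shape != (12,):
            raise ValueError("beta must have 12 entries (beta1..beta12)")
        if self.K.shape != (16,):
            raise ValueError("K must have 16 entries (K1..K16)")
        if self.d.shape != (6,):
            raise ValueError("d must have 6 entries (d1..d6)")
        if np.any(self.beta < 0) or np.any(self.K < 0) or np.any(self.d < 0):
            raise ValueError("beta, K and d must be non-negative")
        if self.delta < 0:
            raise ValueError("delta must be non-negative")
        if self.n < 1:
            raise ValueError("Hill coefficient n must be >= 1")

    @property
    def n_free(self) -> int:
        """Count of free parameters (n is fixed by configuration)."""
        return self.beta.size + self.K.size + self.d.size + 1

    def to_dict(self) -> dict:
        return {
            "beta": self.beta.tolist(),
            "K": self.K.tolist(),
            "d": self.d.tolist(),
            "delta": self.delta,
            "n": self.n,
        }

    @classmethod
    def from_dict(cls, payload: Mapping) -> "ParameterSet":
        return cls(
            beta=np.asarray(payload["beta"], dtype=float),
            K=np.asarray(payload["K"], dtype=float),
            d=np.asarray(payload["d"], dtype=float),
            delta=float(payload["delta"]),
            n=int(payload.get("n", 3)),
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "ParameterSet":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def digest(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]

    def replace(self, **changes) -> "ParameterSet":
        payload = self.to_dict()
        payload.update({k: v for k, v in changes.items()})
        return ParameterSet.from_dict(payload)


def hill_activation(x, K, n: float = 1.0):
    """Saturating activation x**n / (K**n + x**n) in [0, 1)."""
    if np.any(np.asarray(K) <= 0):
        raise ValueError("half-maximum K must be positive")
    x = np.maximum(np.asarray(x, dtype=float), 0.0)
    if n == 1:
        return x / (K + x)
    # (x/K)**n form avoids overflow for large x and n
    r = (x / K) ** n
    return r / (1.0 + r)


def hill_repression(x, K):
    """Saturating repression K / (K + x) in (0, 1]."""
    if np.any(np.asarray(K) <= 0):
        raise ValueError("half-maximum K must be positive")
    x = np.maximum(np.asarray(x, dtype=float), 0.0)
    return K / (K + x)


@dataclass
class Trajectory:
    """Simulated abundances on a day grid; column order follows SPECIES."""

    days: np.ndarray
    values: np.ndarray  # shape (len(days), 6)
    species: tuple = SPECIES
    params_digest: str = ""
    variant: Variant = "independent"
    clamps: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.days = np.asarray(self.days, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.days.size, len(self.species)):
            raise ValueError("values must be (n_days, n_species)")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("trajectory contains non-finite values")

    def column(self, gene: str) -> np.ndarray:
        return self.values[:, self.species.index(gene)]

    def at(self, gene: str, t) -> np.ndarray:
        """Linear interpolation of one species at arbitrary days."""
        return np.interp(np.asarray(t, dtype=float), self.days, self.column(gene))


def evaluate_rhs(
    t: float,
    state: np.ndarray,
    params: ParameterSet,
    inputs: InputProfiles,
    ft_delayed: float | None = None,
    variant: Variant = "independent",
    clamped: Mapping[str, float] | None = None,
) -> np.ndarray:
    """Right-hand side of the six equations at time ``t`` (nM/day).

    ``ft_delayed`` is the leaf FT abundance at ``t - delta``; when omitted the
    current FT value is used (the delta = 0 reduction).  Clamped species get
    derivative 0.
    """
    x = np.asarray(state, dtype=float)
    if x.shape != (6,):
        raise ValueError("state must hold the six modelled species")
    if np.any(x < -1e-6):
        raise ValueError(f"negative state at t={t}: {x}")
    b, K, d, n = params.beta, params.K, params.d, params.n
    ft, agl24, soc1, lfy, ap1, fd = np.maximum(x, 0.0)
    ft_del = ft if ft_delayed is None else max(float(ft_delayed), 0.0)

    svp_l = float(inputs.svp_leaf(t))
    flc_l = float(inputs.flc_leaf(t))
    svp_m = float(inputs.svp_meristem(t))
    flc_m = float(inputs.flc_meristem(t))
    for name, value in (("SVP leaf", svp_l), ("FLC leaf", flc_l),
                        ("SVP meristem", svp_m), ("FLC meristem", flc_m)):
        if not np.isfinite(value):
            raise ValueError(f"input profile {name} undefined at t={t}")

    dft = b[0] * hill_repression(svp_l, K[0]) * hill_repression(flc_l, K[1]) - d[0] * ft

    dagl24 = b[1] * hill_activation(soc1, K[2]) - d[1] * agl24

    dsoc1 = (
        b[2] * hill_activation(agl24, K[3])
        + b[3] * hill_activation(soc1, K[4])
        + b[4] * hill_activation(ft_del, K[5]) * hill_activation(fd, K[6])
    ) * hill_repression(svp_m, K[7]) * hill_repression(flc_m, K[8]) - d[2] * soc1

    if variant == "independent":
        lfy_activation = (
            b[5] * hill_activation(agl24, K[9])
            + b[6] * hill_activation(soc1, K[10])
        )
    elif variant == "dimer_only":
        lfy_activation = b[6] * hill_activation(agl24, K[9]) * hill_activation(soc1, K[10])
    else:
        raise ValueError(f"unknown model variant: {variant!r}")
    dlfy = lfy_activation + b[7] * hill_activation(ap1, K[11]) - d[3] * lfy

    dap1 = (
        b[8] * hill_activation(lfy, K[12], n)
        + b[9] * hill_activation(ft_del, K[13])
        + b[10] * hill_activation(fd, K[14])
    ) - d[4] * ap1

    dfd = b[11] * hill_activation(lfy, K[15]) - d[5] * fd

    deriv = np.array([dft, dagl24, dsoc1, dlfy, dap1, dfd])
    if clamped:
        for gene in clamped:
            if gene in IDX:
                deriv[IDX[gene]] = 0.0
    return deriv


def _ft_production(t, params: ParameterSet, inputs: InputProfiles):
    return (
        params.beta[0]
        * hill_repression(np.asarray(inputs.svp_leaf(t), dtype=float), params.K[0])
        * hill_repression(np.asarray(inputs.flc_leaf(t), dtype=float), params.K[1])
    )


def simulate(
    params: ParameterSet,
    inputs: InputProfiles,
    x0: Mapping[str, float] | np.ndarray,
    horizon: tuple[float, float] = (0.0, 20.0),
    variant: Variant = "independent",
    clamps: Mapping[str, float] | None = None,
    grid_step: float = 0.05,
    extra_days: np.ndarray | None = None,
    rtol: float = 1e-6,
    atol: float = 1e-9,
) -> Trajectory:
    """Integrate the delayed system over ``horizon`` and sample a dense grid.

    ``x0`` is either a length-6 array ordered like :data:`SPECIES` or a mapping
    by species name.  ``clamps`` maps modelled species to the constant value
    they are held at (mutant simulation); FLC/SVP overrides belong in
    ``inputs``, not here.  The output grid is a uniform ``grid_step`` lattice
    over the horizon, unioned with ``extra_days`` (e.g. the observation days).

    Raises if the delay exceeds the horizon length or the stiff integrator
    fails, naming the failing stage and time.
    """
    t0, t1 = float(horizon[0]), float(horizon[1])
    if t1 <= t0:
        raise ValueError("horizon must be an increasing interval")
    if inputs.span[0] > t0 or inputs.span[1] < t1:
        raise ValueError(
            f"input profiles span {inputs.span} does not cover horizon {horizon}"
        )
    if params.delta > (t1 - t0):
        raise ValueError("FT transport delay exceeds the simulation horizon")
    clamps = dict(clamps or {})
    unknown = set(clamps) - set(SPECIES)
    if unknown:
        raise ValueError(f"clamps reference unknown species: {sorted(unknown)}")

    if isinstance(x0, Mapping):
        x0_arr = np.array([float(x0[s]) for s in SPECIES])
    else:
        x0_arr = np.asarray(x0, dtype=float).copy()
    if x0_arr.shape != (6,):
        raise ValueError("x0 must provide the six modelled species")
    if np.any(x0_arr < 0):
        raise ValueError("initial abundances must be non-negative")
    for gene, value in clamps.items():
        x0_arr[IDX[gene]] = float(value)

    days = np.arange(t0, t1 + 0.5 * grid_step, grid_step)
    days[-1] = min(days[-1], t1)
    if extra_days is not None:
        days = np.union1d(days, np.asarray(extra_days, dtype=float))
        days = days[(days >= t0) & (days <= t1)]

    # Stage 1: leaf FT (autonomous given the inputs).
    if "FT" in clamps:
        ft_value = float(clamps["FT"])
        ft_on_grid = np.full(days.size, ft_value)

        def ft_at(t):
            return np.full_like(np.asarray(t, dtype=float), ft_value)
    else:
        ft_sol = solve_ivp(
            lambda t, y: _ft_production(t, params, inputs) - params.d[0] * y,
            (t0, t1),
            [x0_arr[IDX["FT"]]],
            method="LSODA",
            dense_output=True,
            rtol=rtol,
            atol=atol,
        )
        if not ft_sol.success:
            raise RuntimeError(f"FT integration failed: {ft_sol.message}")

        def ft_at(t):
            t = np.clip(np.asarray(t, dtype=float), t0, t1)
            return np.clip(ft_sol.sol(t)[0], 0.0, None)

        ft_on_grid = ft_at(days)

    delta = params.delta
    ft0 = x0_arr[IDX["FT"]] if "FT" not in clamps else float(clamps["FT"])

    def ft_lagged(t: float) -> float:
        # constant pre-horizon history: FT held at its initial value
        tq = t - delta
        if tq <= t0:
            return float(ft0)
        return float(ft_at(tq))

    # Stage 2: the five meristem species against the lagged FT.
    rest = [s for s in SPECIES if s != "FT"]
    rest_idx = [IDX[s] for s in rest]
    clamped_rest = {g: v for g, v in clamps.items() if g != "FT"}
    full = np.empty(6)

    def rhs(t, y):
        full[IDX["FT"]] = float(ft_at(t)) if "FT" not in clamps else float(clamps["FT"])
        full[rest_idx] = y
        deriv = evaluate_rhs(
            t,
            np.maximum(full, 0.0),
            params,
            inputs,
            ft_delayed=ft_lagged(t),
            variant=variant,
            clamped=clamped_rest,
        )
        return deriv[rest_idx]

    sol = solve_ivp(
        rhs,
        (t0, t1),
        x0_arr[rest_idx],
        method="LSODA",
        t_eval=days,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        t_fail = sol.t[-1] if sol.t.size else t0
        raise RuntimeError(
            f"meristem subsystem integration failed near t={t_fail:.3f}: {sol.message}"
        )

    values = np.empty((days.size, 6))
    values[:, IDX["FT"]] = ft_on_grid
    for j, idx in enumerate(rest_idx):
        values[:, idx] = sol.y[j]
    for gene, value in clamps.items():
        values[:, IDX[gene]] = float(value)
    # LSODA can undershoot 0 by ~atol; abundances are non-negative by definition
    values = np.clip(values, 0.0, None)

    return Trajectory(
        days=days,
        values=values,
        params_digest=params.digest(),
        variant=variant,
        clamps=clamps,
    )
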