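"""In-silico mutants, network-wide expression changes and significance tests.

A mutant clamps one or more genes to a constant abundance k_mut for the whole
simulation: 0 for a knockout null allele, a small fraction of the wild-type
first time point for a knockdown, and five times the 500 nM abundance ceiling
(2500 nM) for a constitutive overexpressor.  FLC and SVP are external inputs,
so their mutants rewrite the input profiles (both leaf and meristem) rather
than clamping a model state.  An FT clamp applies both in the leaf equation
and in every delayed meristem occurrence: a null allele has no transcript
anywhere.

The network-wide effect of a mutation is summarised by the change of each
gene's integrated expression over days 0-20 relative to wild type
(trapezoid-rule integrals), the same scale used to compare against expression
profiling of mutant backgrounds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .data import InputProfiles, _constant_profile
from .flowering import FloweringCalibration, predict_flowering
from .model import (
    INPUT_GENES,
    NETWORK_GENES,
    SPECIES,
    ParameterSet,
    Trajectory,
    Variant,
    simulate,
)

OVEREXPRESSION_LEVEL = 2500.0  # nM: 5 x the 500 nM abundance ceiling
DEFAULT_KNOCKDOWN_FRACTION = 0.1

MutantKind = str  # {"knockout", "knockdown", "overexpression"}


@dataclass
class MutantSpec:
    """Named set of clamped genes with their clamp values and classes."""

    name: str
    clamps: dict[str, float] = field(default_factory=dict)
    kinds: dict[str, MutantKind] = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = set(self.clamps) - set(NETWORK_GENES)
        if unknown:
            raise ValueError(f"unknown genes in mutant spec: {sorted(unknown)}")

    def merge(self, other: "MutantSpec", name: str | None = None) -> "MutantSpec":
        """Combine with another spec (double/triple mutants)."""
        overlap = set(self.clamps) & set(other.clamps)
        if overlap:
            raise ValueError(f"genes clamped twice: {sorted(overlap)}")
        return MutantSpec(
            name=name or f"{self.name} {other.name}",
            clamps={**self.clamps, **other.clamps},
            kinds={**self.kinds, **other.kinds},
        )


def make_mutant(
    gene: str,
    kind: MutantKind,
    wt_first_point: float | None = None,
    fraction: float = DEFAULT_KNOCKDOWN_FRACTION,
    overexpression_level: float = OVEREXPRESSION_LEVEL,
    name: str | None = None,
) -> MutantSpec:
    """Build a single-gene mutant.

    knockout -> clamp 0; overexpression -> ``overexpression_level`` (2500 nM
    default); knockdown -> ``fraction`` of the wild-type abundance at the
    first time point (``wt_first_point``), with the fraction required inside
    (0, 1).
    """
    if gene not in NETWORK_GENES:
        raise ValueError(f"unknown gene {gene!r}; expected one of {NETWORK_GENES}")
    if kind == "knockout":
        value = 0.0
    elif kind == "overexpression":
        value = float(overexpression_level)
    elif kind == "knockdown":
        if not (0.0 < fraction < 1.0):
            raise ValueError(f"knockdown fraction must be in (0, 1), got {fraction}")
        if wt_first_point is None:
            raise ValueError("knockdown needs the wild-type first-time-point value")
        value = fraction * float(wt_first_point)
    else:
        raise ValueError(f"unknown mutant kind {kind!r}")
    return MutantSpec(name=name or f"{gene.lower()} {kind}", clamps={gene: value},
                      kinds={gene: kind})


def _override_inputs(inputs: InputProfiles, clamps: Mapping[str, float]) -> InputProfiles:
    """Replace FLC/SVP profiles by constants for input-gene mutants.

    Both the leaf and the meristem profile of a mutated input gene are
    overridden: the allele is the same in every tissue.
    """
    overrides = {}
    if "FLC" in clamps:
        c = _constant_profile(clamps["FLC"])
        overrides["flc_leaf"] = overrides["flc_meristem"] = c
    if "SVP" in clamps:
        c = _constant_profile(clamps["SVP"])
        overrides["svp_leaf"] = overrides["svp_meristem"] = c
    return inputs.replace(**overrides) if overrides else inputs


def simulate_mutant(
    params: ParameterSet,
    inputs: InputProfiles,
    mutant: MutantSpec,
    x0: Mapping[str, float] | np.ndarray,
    horizon: tuple[float, float] = (0.0, 20.0),
    variant: Variant = "independent",
    **simulate_kwargs,
) -> Trajectory:
    """Simulate a mutant background: clamp modelled species, rewrite inputs."""
    state_clamps = {g: v for g, v in mutant.clamps.items() if g in SPECIES}
    eff_inputs = _override_inputs(inputs, mutant.clamps)
    return simulate(
        params,
        eff_inputs,
        x0,
        horizon=horizon,
        variant=variant,
        clamps=state_clamps,
        **simulate_kwargs,
    )


@dataclass
class ExpressionChange:
    """Mutant-versus-wild-type change of a gene's integrated expression."""

    gene: str
    integral_wt: float
    integral_mut: float

    @property
    def relative_change(self) -> float:
        return (self.integral_mut - self.integral_wt) / self.integral_wt

    @property
    def abs_relative_change(self) -> float:
        return abs(self.relative_change)


def expression_change(wt: Trajectory, mut: Trajectory, gene: str) -> ExpressionChange:
    """Relative change of the day-0-to-20 expression integral (trapezoid rule)."""
    if abs(wt.days[0] - mut.days[0]) > 1e-9 or abs(wt.days[-1] - mut.days[-1]) > 1e-9:
        raise ValueError("wild-type and mutant trajectories must share the horizon")
    integral_wt = float(np.trapezoid(wt.column(gene), wt.days))
    integral_mut = float(np.trapezoid(mut.column(gene), mut.days))
    if integral_wt == 0:
        raise ValueError(f"wild-type integral of {gene} is zero; change undefined")
    return ExpressionChange(gene=gene, integral_wt=integral_wt, integral_mut=integral_mut)


def correlation_with_permutation_null(
    predicted: Sequence[float],
    observed: Sequence[float],
    permutations: int = 999,
    seed: int = 0,
) -> tuple[float, float]:
    """Pearson correlation with a permutation p-value.

    The observed vector is permuted ``permutations`` times (seeded); the
    two-sided p-value is (1 + #{|r*| >= |r|}) / (1 + permutations).
    """
    x = np.asarray(predicted, dtype=float)
    y = np.asarray(observed, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("need two equal-length vectors with at least 3 entries")
    if permutations < 99:
        raise ValueError("use at least 99 permutations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero-variance vector; correlation undefined")
    r = float(stats.pearsonr(x, y).statistic)
    rng = np.random.default_rng(seed)
    xc = (x - x.mean()) / (x.std() * np.sqrt(x.size))
    perms = rng.permuted(np.tile(y, (permutations, 1)), axis=1)
    perms = (perms - perms.mean(axis=1, keepdims=True))
    perms /= perms.std(axis=1, keepdims=True) * np.sqrt(x.size)
    r_null = perms @ xc
    p = (1.0 + np.count_nonzero(np.abs(r_null) >= abs(r) - 1e-12)) / (1.0 + permutations)
    return r, float(p)


def beta_sensitivity_sweep(
    params: ParameterSet,
    inputs: InputProfiles,
    x0: Mapping[str, float] | np.ndarray,
    calibration: FloweringCalibration,
    beta6_values: Iterable[float],
    beta7_values: Iterable[float],
    horizon: tuple[float, float] = (0.0, 20.0),
    variant: Variant = "independent",
    as_rl: bool = True,
) -> np.ndarray:
    """Predicted flowering time over a (beta6, beta7) lattice.

    beta6 and beta7 are the strengths with which AGL24 and SOC1 activate LFY.
    Returns a matrix of shape (len(beta6_values), len(beta7_values)) holding
    rosette leaves (or days when ``as_rl=False``); cells whose AP1 never
    crosses the calibrated threshold hold the no-flowering sentinel (inf).
    """
    b6 = np.asarray(list(beta6_values), dtype=float)
    b7 = np.asarray(list(beta7_values), dtype=float)
    if np.any(b6 < 0) or np.any(b7 < 0):
        raise ValueError("activation strengths must be non-negative")
    out = np.empty((b6.size, b7.size))
    for i, v6 in enumerate(b6):
        for j, v7 in enumerate(b7):
            beta = params.beta.copy()
            beta[5], beta[6] = v6, v7
            trial = params.replace(beta=beta.tolist())
            traj = simulate(trial, inputs, x0, horizon=horizon, variant=variant)
            pred = predict_flowering(traj, calibration)
            out[i, j] = pred.rosette_leaves if as_rl else pred.transition_day
    return out
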