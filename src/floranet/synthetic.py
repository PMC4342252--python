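"""Synthetic ground-truth datasets for exercising the whole pipeline.

The generator emulates the structure of the wild-type expression study the
model is designed for: 13 near-daily qRT-PCR sampling points over days 0-20
after germination, duplicate replicates with multiplicative (qPCR-like,
scale-proportional) noise, abundances normalised so the dataset maximum is
500 nM, and smoothly declining FLC/SVP repressor profiles in leaf and
meristem.  Every dataset carries its generating parameter set, so parameter-
and trajectory-recovery of the estimation stages can be tested end to end
without any external data.

:func:`reference_parameters` is a fixed, hand-chosen kinetic parameter set
that reproduces the qualitative wild-type behaviour of the network: FT rising
in the leaf as its repressors decline, a gradual build-up of SOC1/AGL24/LFY
in the meristem, and a sharp, cooperativity-driven (n = 3) AP1 switch shortly
after day 12.  It also encodes the regulatory asymmetry reported for LFY
activation - SOC1 a much stronger activator than AGL24 (beta7 >> beta6) with
similar DNA-binding efficiencies (K10 ~ K11).  It is the default truth for
examples and qualitative tests; :func:`sample_parameters` draws random truths
in a realistic neighbourhood of it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Literal, Mapping

import numpy as np
import pandas as pd

from .data import InputProfiles, TimeCourse, build_input_profiles, summarize_replicates
from .estimation import FitProblem
from .model import SPECIES, ParameterSet, Trajectory, simulate
from .flowering import first_up_crossing

InputShape = Literal["declining", "constant", "sigmoid"]


@dataclass
class SynthConfig:
    """Study-design knobs for one synthetic dataset.

    Defaults mirror the real study design: 13 time points, duplicates, 10%
    multiplicative noise, 500 nM ceiling, horizon 0-20 days.
    """

    seed: int = 0
    n_timepoints: int = 13
    horizon: tuple[float, float] = (0.0, 20.0)
    noise_cv: float = 0.1
    replicates: int = 2
    abundance_ceiling: float = 500.0
    input_shape: InputShape = "declining"
    input_constant: float = 100.0
    noise_model: Literal["lognormal", "additive"] = "lognormal"
    n: int = 3
    rescale_to_ceiling: bool = True

    def __post_init__(self) -> None:
        if self.n_timepoints < 4:
            raise ValueError("need at least 4 time points")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be non-negative")
        if self.replicates < 1:
            raise ValueError("need at least one replicate")


#: Wild-type initial abundances (nM), playing the role of the first observed
#: time point of each modelled species.
REFERENCE_X0: dict[str, float] = {
    "FT": 5.0,
    "AGL24": 10.0,
    "SOC1": 15.0,
    "LFY": 10.0,
    "AP1": 1.0,
    "FD": 10.0,
}


def reference_parameters(n: int = 3) -> ParameterSet:
    """Fixed realistic kinetic parameters (see module docstring)."""
    return ParameterSet(
        #        b1    b2    b3     b4     b5    b6    b7    b8     b9   b10  b11   b12
        beta=[75.0, 55.0, 80.0, 170.0, 170.0, 6.0, 60.0, 40.0, 170.0, 9.0, 7.0, 30.0],
        #      K1     K2     K3    K4    K5    K6    K7     K8
        K=[110.0, 100.0, 100.0, 35.0, 80.0, 70.0, 50.0, 130.0,
           #  K9   K10   K11    K12   K13    K14    K15   K16
           120.0, 70.0, 90.0, 140.0, 95.0, 150.0, 100.0, 80.0],
        #      d1    d2    d3    d4    d5    d6
        d=[0.30, 0.40, 0.45, 0.42, 0.50, 0.35],
        delta=1.0,
        n=n,
    )


def _declining_profile(amp: float, base: float, t_mid: float, width: float) -> Callable:
    def profile(t):
        t = np.asarray(t, dtype=float)
        return base + amp / (1.0 + np.exp((t - t_mid) / width))

    return profile


def _rising_profile(amp: float, base: float, t_mid: float, width: float) -> Callable:
    def profile(t):
        t = np.asarray(t, dtype=float)
        return base + amp / (1.0 + np.exp(-(t - t_mid) / width))

    return profile


_INPUT_BASELINES = {
    # amp, base, t_mid (day), width (day) for the four repressor inputs
    "flc_leaf": (180.0, 8.0, 4.5, 1.8),
    "flc_meristem": (150.0, 6.0, 5.0, 1.8),
    "svp_leaf": (470.0, 12.0, 6.0, 2.0),
    "svp_meristem": (320.0, 10.0, 6.0, 2.0),
}


def generate_inputs(config: SynthConfig) -> InputProfiles:
    """Seeded FLC/SVP forcing profiles for leaf and meristem.

    The default "declining" family emulates floral repressors waning over the
    vegetative phase: smooth sigmoids dropping from a high early plateau to a
    small baseline, with mild seeded variation of amplitude, midpoint and
    steepness.  "constant" holds every input at ``config.input_constant`` and
    "sigmoid" produces rising profiles (useful for stress-testing only).
    """
    span = config.horizon
    if config.input_shape == "constant":
        return InputProfiles.constant(
            flc=config.input_constant, svp=config.input_constant, span=span
        )
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 101]))
    family = _declining_profile if config.input_shape == "declining" else _rising_profile
    profiles = {}
    for name, (amp, base, t_mid, width) in _INPUT_BASELINES.items():
        profiles[name] = family(
            amp * rng.lognormal(0.0, 0.08),
            base * rng.lognormal(0.0, 0.1),
            t_mid + rng.uniform(-1.0, 1.0),
            width * rng.lognormal(0.0, 0.1),
        )
    return InputProfiles(span=span, **profiles)


def _ap1_first_crossing(traj: Trajectory) -> float:
    """Day at which AP1 first reaches halfway between its start and its peak."""
    ap1 = traj.column("AP1")
    swing = ap1.max() - ap1[0]
    if swing < 20.0:  # no meaningful up-swing
        return np.inf
    return first_up_crossing(traj.days, ap1, ap1[0] + 0.5 * swing)


def sample_parameters(
    config: SynthConfig,
    max_draws: int = 1000,
    jitter_sd: float = 0.25,
) -> ParameterSet:
    """Draw a random ground-truth parameter set with a realistic AP1 switch.

    Parameters are sampled log-normally around :func:`reference_parameters`
    (sd ``jitter_sd`` on the log scale; the delay uniform within +/-50% of the
    reference).  Draws are rejected until the wild-type simulation shows an
    AP1 up-swing whose half-rise falls within days 5-19 of the horizon.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 202]))
    ref = reference_parameters(n=config.n)
    inputs = generate_inputs(config)
    for _ in range(max_draws):
        candidate = ParameterSet(
            beta=ref.beta * rng.lognormal(0.0, jitter_sd, 12),
            K=ref.K * rng.lognormal(0.0, jitter_sd, 16),
            d=ref.d * rng.lognormal(0.0, jitter_sd, 6),
            delta=ref.delta * rng.uniform(0.5, 1.5),
            n=config.n,
        )
        try:
            traj = simulate(candidate, inputs, REFERENCE_X0, horizon=config.horizon)
        except RuntimeError:
            continue
        crossing = _ap1_first_crossing(traj)
        if 5.0 <= crossing <= 19.0:
            return candidate
    raise RuntimeError(
        f"no acceptable parameter set in {max_draws} draws; widen the sampling ranges"
    )


def sampling_days(config: SynthConfig) -> np.ndarray:
    """Near-daily sampling grid: n_timepoints integer days spread over the horizon."""
    t0, t1 = config.horizon
    days = np.unique(np.round(np.linspace(t0, t1, config.n_timepoints)))
    return days.astype(float)


@dataclass
class SyntheticDataset:
    """A generated study: truth, forcings, clean and noisy observations."""

    truth: ParameterSet
    inputs: InputProfiles
    clean: dict[tuple[str, str], TimeCourse]  # keyed by (gene, tissue)
    table: pd.DataFrame  # abundance-bearing qPCR-style table
    config: SynthConfig
    scale: float = 1.0  # factor applied in the ceiling normalisation

    def fit_problem(self, **overrides) -> FitProblem:
        """Build a FitProblem from the noisy table, exactly as for real data."""
        courses = {(tc.gene, tc.tissue): tc for tc in summarize_replicates(self.table)}
        data = {g: courses[(g, "leaf" if g == "FT" else "meristem")] for g in SPECIES}
        inputs = build_input_profiles(
            flc_leaf=courses[("FLC", "leaf")],
            flc_meristem=courses[("FLC", "meristem")],
            svp_leaf=courses[("SVP", "leaf")],
            svp_meristem=courses[("SVP", "meristem")],
            horizon=self.config.horizon,
        )
        kwargs = dict(data=data, inputs=inputs, fixed={"n": self.config.n})
        kwargs.update(overrides)
        return FitProblem(**kwargs)


def _noise_factors(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Mean-one multiplicative log-normal factors with coefficient of variation cv."""
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv**2))
    return rng.lognormal(-0.5 * sigma**2, sigma, size)


def generate_dataset(
    config: SynthConfig,
    params: ParameterSet | None = None,
    x0: Mapping[str, float] | None = None,
) -> SyntheticDataset:
    """Simulate a ground truth and wrap it as a noisy qPCR-style dataset.

    ``params`` defaults to a fresh :func:`sample_parameters` draw; pass
    :func:`reference_parameters` for the fixed realistic truth.  Noise is
    multiplicative log-normal per replicate (additive Gaussian by config
    flag); the finished table is rescaled so its maximum abundance equals the
    configured ceiling, exactly as the real normalisation contract demands.
    """
    params = params if params is not None else sample_parameters(config)
    x0 = dict(x0) if x0 is not None else dict(REFERENCE_X0)
    inputs = generate_inputs(config)
    days = sampling_days(config)
    traj = simulate(params, inputs, x0, horizon=config.horizon, extra_days=days)

    series: dict[tuple[str, str], np.ndarray] = {}
    for gene in SPECIES:
        tissue = "leaf" if gene == "FT" else "meristem"
        series[(gene, tissue)] = traj.at(gene, days)
    series[("FLC", "leaf")] = np.asarray(inputs.flc_leaf(days), dtype=float)
    series[("FLC", "meristem")] = np.asarray(inputs.flc_meristem(days), dtype=float)
    series[("SVP", "leaf")] = np.asarray(inputs.svp_leaf(days), dtype=float)
    series[("SVP", "meristem")] = np.asarray(inputs.svp_meristem(days), dtype=float)

    clean = {
        key: TimeCourse(gene=key[0], tissue=key[1], days=days, mean_abundance=values)
        for key, values in series.items()
    }

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 303]))
    rows = []
    for (gene, tissue), values in series.items():
        for rep in range(1, config.replicates + 1):
            if config.noise_model == "lognormal":
                noisy = values * _noise_factors(rng, config.noise_cv, values.size)
            else:  # additive Gaussian scaled to the series amplitude
                sd = config.noise_cv * max(values.max(), 1e-12)
                noisy = np.clip(values + rng.normal(0.0, sd, values.size), 0.0, None)
            for day, value in zip(days, noisy):
                rows.append((gene, tissue, day, rep, value))
    table = pd.DataFrame(rows, columns=["gene", "tissue", "day", "replicate", "abundance"])

    scale = 1.0
    if config.rescale_to_ceiling:
        peak = table["abundance"].max()
        if peak <= 0:
            raise RuntimeError("degenerate dataset: all abundances are zero")
        scale = config.abundance_ceiling / peak
        table["abundance"] *= scale

    return SyntheticDataset(
        truth=params, inputs=inputs, clean=clean, table=table, config=config, scale=scale
    )


def empirical_replicate_cv(table: pd.DataFrame) -> float:
    """Pooled replicate coefficient of variation: RMS of per-point sd/mean."""
    ratios = []
    for _, group in table.groupby(["gene", "tissue", "day"]):
        v = group["abundance"].to_numpy(float)
        if v.size > 1 and v.mean() > 0:
            ratios.append(v.std(ddof=1) / v.mean())
    if not ratios:
        raise ValueError("no replicated observations in table")
    return float(np.sqrt(np.mean(np.square(ratios))))
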