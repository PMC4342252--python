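"""Expression time-course handling.

qRT-PCR tables are carried as pandas DataFrames with one row per measured
replicate.  Two dialects are accepted:

* Ct-bearing: columns ``gene, tissue, day, replicate, ct_target, ct_reference``
* abundance-bearing: columns ``gene, tissue, day, replicate, abundance`` (nM)

:func:`normalize_qpcr` converts the first into the second; downstream code
(fitting, simulation inputs) only ever sees abundance-bearing tables or the
:class:`TimeCourse` summaries built from them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

CT_COLUMNS = ["gene", "tissue", "day", "replicate", "ct_target", "ct_reference"]
ABUNDANCE_COLUMNS = ["gene", "tissue", "day", "replicate", "abundance"]

SignConvention = Literal["as_printed", "conventional"]
Extrapolation = Literal["clamp", "error"]


@dataclass
class TimeCourse:
    """Replicate-averaged abundance trajectory for one gene in one tissue.

    Attributes
    ----------
    gene, tissue : str
        Identifiers; tissue is ``"leaf"`` or ``"meristem"``.
    days : ndarray
        Strictly increasing sampling days (days after germination).
    mean_abundance : ndarray
        Replicate mean abundance in nM, same length as ``days``.
    sd_abundance : ndarray or None
        Replicate sample standard deviation; ``None`` where every day has a
        single replicate.
    """

    gene: str
    tissue: str
    days: np.ndarray
    mean_abundance: np.ndarray
    sd_abundance: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.days = np.asarray(self.days, dtype=float)
        self.mean_abundance = np.asarray(self.mean_abundance, dtype=float)
        if self.days.shape != self.mean_abundance.shape:
            raise ValueError("days and mean_abundance must have the same length")
        if self.days.size and np.any(np.diff(self.days) <= 0):
            raise ValueError(f"days must be strictly increasing for {self.gene}")
        if np.any(self.mean_abundance < 0):
            raise ValueError(f"negative abundance in time course for {self.gene}")
        if self.sd_abundance is not None:
            self.sd_abundance = np.asarray(self.sd_abundance, dtype=float)

    @property
    def span(self) -> tuple[float, float]:
        return float(self.days[0]), float(self.days[-1])

    def first_point(self) -> float:
        """Abundance at the earliest sampled day (used as initial condition)."""
        return float(self.mean_abundance[0])


@dataclass
class InputProfiles:
    """FLC and SVP trajectories supplied to the model as external forcings.

    The four callables map day -> nM and are defined on ``span``; behaviour
    outside the span follows ``extrapolation`` ("clamp" holds the endpoint
    value, "error" raises).
    """

    flc_leaf: Callable[[np.ndarray], np.ndarray]
    flc_meristem: Callable[[np.ndarray], np.ndarray]
    svp_leaf: Callable[[np.ndarray], np.ndarray]
    svp_meristem: Callable[[np.ndarray], np.ndarray]
    span: tuple[float, float] = (0.0, 20.0)

    def replace(self, **profiles) -> "InputProfiles":
        """Return a copy with some profiles substituted (mutant overrides)."""
        kwargs = dict(
            flc_leaf=self.flc_leaf,
            flc_meristem=self.flc_meristem,
            svp_leaf=self.svp_leaf,
            svp_meristem=self.svp_meristem,
            span=self.span,
        )
        kwargs.update(profiles)
        return InputProfiles(**kwargs)

    @classmethod
    def constant(
        cls,
        flc: float = 0.0,
        svp: float = 0.0,
        span: tuple[float, float] = (0.0, 20.0),
    ) -> "InputProfiles":
        """Profiles constant in time (useful for steady-state analysis)."""
        f = _constant_profile(flc)
        s = _constant_profile(svp)
        return cls(flc_leaf=f, flc_meristem=f, svp_leaf=s, svp_meristem=s, span=span)


def _constant_profile(value: float) -> Callable[[np.ndarray], np.ndarray]:
    value = float(value)

    def profile(t):
        return np.full_like(np.asarray(t, dtype=float), value)

    profile.constant_value = value  # type: ignore[attr-defined]
    return profile


def _require_columns(table: pd.DataFrame, columns: Sequence[str]) -> None:
    missing = [c for c in columns if c not in table.columns]
    if missing:
        raise ValueError(f"table is missing required columns: {missing}")


def normalize_qpcr(
    table: pd.DataFrame,
    max_abundance: float = 500.0,
    sign_convention: SignConvention = "as_printed",
) -> pd.DataFrame:
    """Convert a Ct-bearing qPCR table to absolute abundances in nM.

    Relative expression per record is ``E = 2**(dCt)`` with
    ``dCt = ct_target - ct_reference`` under ``sign_convention="as_printed"``,
    or ``E = 2**(-dCt)`` under ``"conventional"``.  A single global scaling
    factor ``s = max_abundance / max(E)`` then maps relative expression to
    abundance, so the largest abundance across *all* records equals
    ``max_abundance`` (default 500 nM, an average cellular protein abundance).
    """
    _require_columns(table, CT_COLUMNS)
    if max_abundance <= 0:
        raise ValueError("max_abundance must be positive")
    if table["ct_reference"].isna().any():
        bad = table[table["ct_reference"].isna()].iloc[0]
        raise ValueError(
            "missing reference Ct for record "
            f"gene={bad['gene']} tissue={bad['tissue']} day={bad['day']} "
            f"replicate={bad['replicate']}"
        )
    dct = table["ct_target"].to_numpy(float) - table["ct_reference"].to_numpy(float)
    if sign_convention == "as_printed":
        e = np.exp2(dct)
    elif sign_convention == "conventional":
        e = np.exp2(-dct)
    else:
        raise ValueError(f"unknown sign_convention: {sign_convention!r}")
    e_max = e.max() if e.size else 0.0
    if e_max <= 0:
        raise ValueError("all relative expression values are zero; cannot scale")
    out = table[["gene", "tissue", "day", "replicate"]].copy()
    out["abundance"] = e * (max_abundance / e_max)
    return out


def summarize_replicates(table: pd.DataFrame, ddof: int = 1) -> list[TimeCourse]:
    """Collapse replicates to per-day mean and sample sd, one TimeCourse per
    (gene, tissue).

    Days with a single replicate get sd = NaN (absent), never 0.
    """
    _require_columns(table, ABUNDANCE_COLUMNS)
    courses: list[TimeCourse] = []
    for (gene, tissue), group in table.groupby(["gene", "tissue"], sort=True):
        stats = (
            group.groupby("day")["abundance"]
            .agg(mean="mean", sd=lambda v: v.std(ddof=ddof) if len(v) > 1 else np.nan)
            .sort_index()
        )
        sd = stats["sd"].to_numpy(float)
        courses.append(
            TimeCourse(
                gene=str(gene),
                tissue=str(tissue),
                days=stats.index.to_numpy(float),
                mean_abundance=stats["mean"].to_numpy(float),
                sd_abundance=None if np.all(np.isnan(sd)) else sd,
            )
        )
    return courses


def interpolate_timecourse(
    tc: TimeCourse,
    scheme: Literal["polynomial", "piecewise_cubic"] = "piecewise_cubic",
    degree: int = 5,
    extrapolation: Extrapolation = "clamp",
) -> Callable[[np.ndarray], np.ndarray]:
    """Build a day -> nM callable from a time course.

    ``piecewise_cubic`` passes through the replicate means (natural cubic
    spline); ``polynomial`` least-squares fits a single polynomial of
    ``degree``.  Interpolated values are clipped at 0: abundances are
    non-negative by definition and a spline may undershoot between knots.
    """
    t0, t1 = tc.span
    if scheme == "piecewise_cubic":
        spline = CubicSpline(tc.days, tc.mean_abundance, bc_type="natural")
        raw = spline
    elif scheme == "polynomial":
        if tc.days.size < degree + 1:
            raise ValueError(
                f"polynomial degree {degree} needs at least {degree + 1} points, "
                f"got {tc.days.size}"
            )
        coeffs = np.polynomial.Polynomial.fit(tc.days, tc.mean_abundance, degree)
        raw = coeffs
    else:
        raise ValueError(f"unknown interpolation scheme: {scheme!r}")

    def interpolant(t):
        t = np.asarray(t, dtype=float)
        if extrapolation == "error":
            if np.any(t < t0) or np.any(t > t1):
                raise ValueError(
                    f"evaluation outside [{t0}, {t1}] for {tc.gene} ({tc.tissue})"
                )
            tq = t
        else:
            tq = np.clip(t, t0, t1)
        return np.clip(raw(tq), 0.0, None)

    interpolant.span = (t0, t1)  # type: ignore[attr-defined]
    return interpolant


def build_input_profiles(
    flc_leaf: TimeCourse,
    flc_meristem: TimeCourse,
    svp_leaf: TimeCourse,
    svp_meristem: TimeCourse,
    horizon: tuple[float, float] = (0.0, 20.0),
    scheme: Literal["polynomial", "piecewise_cubic"] = "piecewise_cubic",
    degree: int = 5,
    extrapolation: Extrapolation = "clamp",
) -> InputProfiles:
    """Interpolate the four FLC/SVP time courses into model input profiles."""
    courses = {
        "flc_leaf": flc_leaf,
        "flc_meristem": flc_meristem,
        "svp_leaf": svp_leaf,
        "svp_meristem": svp_meristem,
    }
    short = [
        name
        for name, tc in courses.items()
        if tc.span[0] > horizon[0] or tc.span[1] < horizon[1]
    ]
    if short:
        raise ValueError(
            f"input profiles {short} do not span the requested horizon {horizon}"
        )
    profiles = {
        name: interpolate_timecourse(tc, scheme=scheme, degree=degree, extrapolation=extrapolation)
        for name, tc in courses.items()
    }
    return InputProfiles(span=horizon, **profiles)
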