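"""Probabilistic lifetime-cancer-risk propagation.

Each trial draws the inhalation dose inputs (concentration c, inhalation
rate IR, body weight BW, exposure frequency EF, exposure duration ED) from
configurable independent distributions, computes the lifetime average daily
dose and multiplies by the cancer slope factor.  The default configuration
randomizes only the concentration — a lognormal moment-matched to the
observed section mean and SD — and keeps the exposure factors at their
point values, so the simulation mean coincides with the deterministic
point-estimate LTCR up to Monte-Carlo error.

Summaries report the mean, SD, the 15/25/50/75/90th percentiles (linear
interpolation between order statistics, numpy's default), the ratio of
each percentile to the 10⁻⁶ acceptable-risk baseline, and the fraction of
trials exceeding that baseline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import ConfigurationError, InvalidInputError, SamplingError
from .exposure import ExposureFactors

RISK_BASELINE = 1e-6
DEFAULT_PERCENTILES = (15, 25, 50, 75, 90)
DEFAULT_N_TRIALS = 100_000

_VARIABLES = ("c", "ir", "bw", "ef", "ed")
_FAMILIES = ("point", "normal", "lognormal", "triangular", "uniform")


@dataclass(frozen=True)
class DistributionSpec:
    """A named parametric distribution for one Monte-Carlo input.

    Families and their ``params``:

    - ``point``: (value,)
    - ``normal``: (mean, sd) — truncated at 0 by default
    - ``lognormal``: (mu, sigma) on the log scale
    - ``triangular``: (left, mode, right)
    - ``uniform``: (low, high)
    """

    variable: str
    family: str
    params: tuple[float, ...]
    truncation: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.variable not in _VARIABLES:
            raise ConfigurationError(f"unknown variable {self.variable!r}")
        if self.family not in _FAMILIES:
            raise ConfigurationError(f"unknown family {self.family!r}")
        p = tuple(float(v) for v in self.params)
        object.__setattr__(self, "params", p)
        n_expected = {"point": 1, "normal": 2, "lognormal": 2, "triangular": 3, "uniform": 2}
        if len(p) != n_expected[self.family]:
            raise ConfigurationError(
                f"{self.family} needs {n_expected[self.family]} params, got {len(p)}"
            )
        if self.family == "normal" and p[1] < 0:
            raise ConfigurationError("normal sd must be >= 0")
        if self.family == "lognormal" and p[1] < 0:
            raise ConfigurationError("lognormal sigma must be >= 0")
        if self.family == "triangular" and not (p[0] <= p[1] <= p[2]):
            raise ConfigurationError("triangular needs left <= mode <= right")
        if self.family == "uniform" and p[0] > p[1]:
            raise ConfigurationError("uniform needs low <= high")
        if self.truncation is not None:
            lo, hi = self.truncation
            if lo > hi:
                raise ConfigurationError("truncation bounds out of order")

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        if self.family == "point":
            draws = np.full(size, self.params[0])
        elif self.family == "normal":
            mean, sd = self.params
            trunc = self.truncation if self.truncation is not None else (0.0, math.inf)
            draws = _truncated_normal(rng, mean, sd, trunc, size)
            return draws
        elif self.family == "lognormal":
            draws = rng.lognormal(self.params[0], self.params[1], size)
        elif self.family == "triangular":
            left, mode, right = self.params
            draws = rng.triangular(left, mode, right, size)
        else:  # uniform
            draws = rng.uniform(self.params[0], self.params[1], size)
        if self.truncation is not None:
            draws = _rejection_truncate(lambda n: self.sample_raw(rng, n), draws, self.truncation)
        return draws

    def sample_raw(self, rng: np.random.Generator, size: int) -> np.ndarray:
        """Draw without truncation (rejection-resampling helper)."""
        spec = DistributionSpec(self.variable, self.family, self.params, None)
        return spec.sample(rng, size)


def _truncated_normal(
    rng: np.random.Generator,
    mean: float,
    sd: float,
    bounds: tuple[float, float],
    size: int,
) -> np.ndarray:
    if sd == 0:
        draws = np.full(size, mean)
        if not (bounds[0] <= mean <= bounds[1]):
            raise SamplingError("point normal lies outside truncation bounds")
        return draws
    return _rejection_truncate(lambda n: rng.normal(mean, sd, n), rng.normal(mean, sd, size), bounds)


def _rejection_truncate(draw, initial: np.ndarray, bounds: tuple[float, float]) -> np.ndarray:
    lo, hi = bounds
    out = initial
    for _ in range(1000):
        bad = (out < lo) | (out > hi)
        n_bad = int(bad.sum())
        if n_bad == 0:
            return out
        out = out.copy()
        out[bad] = draw(n_bad)
    raise SamplingError("truncation bounds leave (almost) no support")


@dataclass(frozen=True)
class SimulationResult:
    """Summaries of one LTCR simulation run."""

    n_trials: int
    draws: np.ndarray
    mean: float
    sd: float
    percentiles: dict[int, float]
    baseline_ratios: dict[int, float]
    exceedance_prob: float
    seed: int
    baseline: float = RISK_BASELINE


def fit_lognormal_moments(mean: float, sd: float) -> DistributionSpec:
    """Lognormal concentration spec whose analytic mean/SD match the targets.

    Moment matching: μ = ln(mean²/√(mean²+sd²)), σ = √(ln(1+sd²/mean²)).
    ``sd = 0`` degenerates to a point mass at the mean.
    """
    if mean <= 0:
        raise InvalidInputError("lognormal moment matching needs mean > 0")
    if sd < 0:
        raise InvalidInputError("sd must be >= 0")
    if sd == 0:
        return DistributionSpec("c", "point", (mean,))
    sigma2 = math.log1p((sd / mean) ** 2)
    mu = math.log(mean**2 / math.sqrt(mean**2 + sd**2))
    return DistributionSpec("c", "lognormal", (mu, math.sqrt(sigma2)))


def point_specs_from_factors(ef: ExposureFactors) -> dict[str, DistributionSpec]:
    """Point distributions for IR/BW/EF/ED at a gender's default factors."""
    return {
        "ir": DistributionSpec("ir", "point", (ef.ir,)),
        "bw": DistributionSpec("bw", "point", (ef.bw,)),
        "ef": DistributionSpec("ef", "point", (ef.ef,)),
        "ed": DistributionSpec("ed", "point", (ef.ed,)),
    }


def simulate_ltcr(
    specs: Mapping[str, DistributionSpec] | Iterable[DistributionSpec],
    sf: float,
    ef_defaults: ExposureFactors,
    n_trials: int = DEFAULT_N_TRIALS,
    seed: int = 0,
    percentiles: Sequence[int] = DEFAULT_PERCENTILES,
    baseline: float = RISK_BASELINE,
) -> SimulationResult:
    """Propagate input distributions through LADD × SF.

    Any dose variable without an explicit spec falls back to a point mass at
    the ``ef_defaults`` value; a concentration spec is mandatory.  Trials
    draw all variables independently.  Fixed seed + specs give a
    bit-identical result.
    """
    if n_trials < 1:
        raise InvalidInputError("n_trials must be >= 1")
    if sf < 0:
        raise InvalidInputError("slope factor must be >= 0")
    if isinstance(specs, Mapping):
        spec_map = dict(specs)
    else:
        spec_map = {s.variable: s for s in specs}
    merged = point_specs_from_factors(ef_defaults)
    merged.update(spec_map)
    if "c" not in merged:
        raise ConfigurationError("no distribution for the concentration 'c'")
    unknown = set(merged) - set(_VARIABLES)
    if unknown:
        raise ConfigurationError(f"unresolvable variables {sorted(unknown)}")

    rng = np.random.default_rng(seed)
    draws_by_var = {v: merged[v].sample(rng, n_trials) for v in ("c", "ir", "bw", "ef", "ed")}
    ladd = (
        draws_by_var["c"]
        * draws_by_var["ir"]
        * draws_by_var["ef"]
        * draws_by_var["ed"]
        * ef_defaults.cf
        / (draws_by_var["bw"] * ef_defaults.at_cancer)
    )
    ltcr = ladd * sf

    pct = {int(q): float(np.percentile(ltcr, q)) for q in percentiles}
    if np.all(ltcr == ltcr[0]):
        # degenerate (all-point) run: report the exact common value, not a
        # pairwise-summation mean that can differ in the last ulp
        mean, sd = float(ltcr[0]), 0.0
    else:
        mean, sd = float(ltcr.mean()), float(ltcr.std(ddof=1)) if n_trials > 1 else 0.0
    return SimulationResult(
        n_trials=n_trials,
        draws=ltcr,
        mean=mean,
        sd=sd,
        percentiles=pct,
        baseline_ratios={q: v / baseline for q, v in pct.items()},
        exceedance_prob=float((ltcr > baseline).mean()),
        seed=seed,
        baseline=baseline,
    )


def baseline_ratio_report(result: SimulationResult, baseline: float = RISK_BASELINE) -> dict:
    """Percentile-to-baseline multipliers and the baseline exceedance fraction."""
    if baseline <= 0:
        raise InvalidInputError("baseline must be > 0")
    return {
        "baseline": baseline,
        "ratios": {q: v / baseline for q, v in sorted(result.percentiles.items())},
        "exceedance_prob": float((result.draws > baseline).mean()),
    }
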