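"""Synthetic per-sample concentration tables.

The raw monitoring data behind the study's summary tables are not public,
so this module generates per-sample tables carrying the same statistical
structure: right-skewed lognormal marginals with the published mean/SD per
compound and section, and the published pairwise rank correlations between
compounds, imposed through a Gaussian copula.

Two generation paths exist on purpose:

- :func:`generate_samples` — the stochastic emulator.  Standard normals are
  correlated with the (Pearson-converted) target rank-correlation matrix,
  pushed through the standard-normal CDF and the per-compound
  moment-matched lognormal quantile functions, and optionally clipped to
  the published min/max envelope.  Sample moments fluctuate around the
  targets as real resampling would.
- :func:`moment_match_exact` — the fixture path.  A generated draw is
  affinely rescaled per compound so its sample mean and SD hit the targets
  to 10⁻⁹ exactly; the rescale is strictly increasing, so rank correlations
  are preserved.  Clipping is never applied here — it would break the
  exact-moment guarantee.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .config import MomentTargets
from .errors import FixtureError, GenerationError
from .exposure import ConcentrationSample
from .montecarlo import fit_lognormal_moments

#: Eigenvalues above this (negative) floor count as positive semidefinite.
_PSD_TOL = -1e-8


@dataclass(frozen=True)
class GeneratorSpec:
    """Targets for one section's synthetic concentration table."""

    section: str
    n_samples: int
    targets: dict[str, MomentTargets]  # compound -> moments
    rank_correlations: tuple[tuple[str, str, float], ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise GenerationError("need at least 2 samples")
        for comp, t in self.targets.items():
            if t.mean <= 0:
                raise GenerationError(f"{comp}: target mean must be > 0")
            if t.sd < 0:
                raise GenerationError(f"{comp}: target sd must be >= 0")

    @property
    def compounds(self) -> tuple[str, ...]:
        return tuple(self.targets)

    def correlation_matrix(self) -> np.ndarray:
        """Target Spearman matrix; unspecified pairs default to 0."""
        comps = self.compounds
        idx = {c: i for i, c in enumerate(comps)}
        mat = np.eye(len(comps))
        for a, b, r in self.rank_correlations:
            if a in idx and b in idx:
                mat[idx[a], idx[b]] = mat[idx[b], idx[a]] = r
        return mat


def spearman_to_pearson(rho_s: float) -> float:
    """Gaussian-copula mapping: normal-score correlation r with rank
    correlation ρ_S satisfies ρ_S = (6/π)·arcsin(r/2); invert it."""
    return 2.0 * math.sin(math.pi * rho_s / 6.0)


def nearest_psd(mat: np.ndarray) -> np.ndarray:
    """Repair a symmetric matrix to the nearest positive semidefinite one
    by clipping negative eigenvalues, then restore the unit diagonal."""
    sym = (mat + mat.T) / 2.0
    vals, vecs = np.linalg.eigh(sym)
    if vals.min() >= _PSD_TOL:
        return sym
    vals = np.clip(vals, 0.0, None)
    repaired = vecs @ np.diag(vals) @ vecs.T
    d = np.sqrt(np.diag(repaired))
    if np.any(d <= 0):
        raise GenerationError("correlation matrix not repairable to PSD")
    repaired = repaired / np.outer(d, d)
    np.fill_diagonal(repaired, 1.0)
    return repaired


def _copula_matrix(spec: GeneratorSpec) -> np.ndarray:
    rank_mat = spec.correlation_matrix()
    pearson = np.vectorize(spearman_to_pearson)(rank_mat)
    np.fill_diagonal(pearson, 1.0)
    pearson = nearest_psd(pearson)
    vals = np.linalg.eigvalsh(pearson)
    if vals.min() < _PSD_TOL:
        raise GenerationError("correlation matrix infeasible after PSD repair")
    return pearson


def _draw_matrix(spec: GeneratorSpec, rng: np.random.Generator, clip: bool) -> np.ndarray:
    """n_samples × n_compounds concentrations via the Gaussian copula."""
    comps = spec.compounds
    cov = _copula_matrix(spec)
    chol = np.linalg.cholesky(cov + 1e-12 * np.eye(len(comps)))
    z = rng.standard_normal((spec.n_samples, len(comps))) @ chol.T
    u = sps.norm.cdf(z)
    out = np.empty_like(u)
    for j, comp in enumerate(comps):
        t = spec.targets[comp]
        ln = fit_lognormal_moments(t.mean, t.sd)
        if ln.family == "point":
            out[:, j] = t.mean
        else:
            mu, sigma = ln.params
            out[:, j] = np.exp(mu + sigma * sps.norm.ppf(u[:, j]))
        if clip and (t.min is not None or t.max is not None):
            lo = t.min if t.min is not None else -np.inf
            hi = t.max if t.max is not None else np.inf
            out[:, j] = np.clip(out[:, j], lo, hi)
    return out


def _to_samples(spec: GeneratorSpec, mat: np.ndarray) -> list[ConcentrationSample]:
    prefix = spec.section[:3]
    return [
        ConcentrationSample(
            sample_id=f"{prefix}-{i + 1:02d}",
            section=spec.section,
            compound=comp,
            concentration=float(mat[i, j]),
        )
        for i in range(spec.n_samples)
        for j, comp in enumerate(spec.compounds)
    ]


def generate_samples(spec: GeneratorSpec) -> list[ConcentrationSample]:
    """Draw a synthetic section table; deterministic under a fixed seed."""
    rng = np.random.default_rng(spec.seed)
    mat = _draw_matrix(spec, rng, clip=True)
    return _to_samples(spec, mat)


def moment_match_exact(spec: GeneratorSpec, max_attempts: int = 100) -> list[ConcentrationSample]:
    """Generate, then affinely rescale so sample mean/SD equal the targets.

    The positive-slope affine map preserves rank order (hence Spearman
    correlations).  Rescaling a right-skewed draw can in principle push its
    minimum below zero; such draws are rejected and redrawn from a
    deterministically derived sub-seed, so the output is still a pure
    function of the spec.
    """
    for attempt in range(max_attempts):
        rng = np.random.default_rng(spec.seed + 1_000_003 * attempt)
        mat = _draw_matrix(spec, rng, clip=False)
        rescaled = np.empty_like(mat)
        ok = True
        for j, comp in enumerate(spec.compounds):
            t = spec.targets[comp]
            col = mat[:, j]
            m, s = col.mean(), col.std(ddof=1)
            if t.sd > 0 and s == 0:
                raise FixtureError(f"{comp}: degenerate generated sample (zero variance)")
            if t.sd == 0:
                rescaled[:, j] = t.mean
            else:
                rescaled[:, j] = t.mean + (col - m) * (t.sd / s)
            if rescaled[:, j].min() < 0:
                ok = False
                break
        if ok:
            return _to_samples(spec, rescaled)
    raise FixtureError(
        f"could not produce a nonnegative moment-matched table in {max_attempts} attempts"
    )


def study_specs(
    targets: dict[str, dict[str, MomentTargets]],
    section_sizes: dict[str, int],
    rank_correlations: list[tuple[str, str, float]],
    seed: int = 0,
) -> list[GeneratorSpec]:
    """One GeneratorSpec per configured section, with decorrelated seeds."""
    specs = []
    for k, (section, comp_targets) in enumerate(targets.items()):
        specs.append(
            GeneratorSpec(
                section=section,
                n_samples=section_sizes[section],
                targets=dict(comp_targets),
                rank_correlations=tuple(rank_correlations),
                seed=seed + 7919 * k,
            )
        )
    return specs
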