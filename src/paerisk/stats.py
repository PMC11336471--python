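"""Descriptive statistics and Spearman rank-correlation source analysis.

``summarize`` reduces a long-format sample table to per-(compound, section)
summary rows — mean, median, sample SD (n−1), min, max, range — plus a
ΣPAEs pseudo-compound formed by summing the measured compounds within each
sample before summarizing.

``spearman_matrix`` computes average-rank Spearman correlations for every
compound pair with a two-tailed p-value: exact by permutation enumeration
for small tie-free columns (n ≤ 9), otherwise the usual t-distribution
approximation.  Significance is flagged at the 0.05 and 0.01 levels.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations, permutations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .config import TOTAL_LABEL
from .errors import InvalidInputError
from .exposure import ConcentrationSample

logger = logging.getLogger(__name__)

#: Largest n for which the exact permutation null of Spearman's rho is used.
EXACT_PERMUTATION_MAX_N = 9


@dataclass(frozen=True)
class CompoundSummary:
    """Summary statistics (μg/m³) for one compound within one section."""

    compound: str
    section: str
    n: int
    mean: float
    median: float
    sd: float
    min: float
    max: float

    @property
    def range(self) -> float:
        return self.max - self.min


@dataclass(frozen=True)
class CorrelationCell:
    """One Spearman correlation between two compounds."""

    compound_a: str
    compound_b: str
    rho: float
    p_two_tailed: float
    n: int

    @property
    def significant_05(self) -> bool:
        return self.p_two_tailed < 0.05

    @property
    def significant_01(self) -> bool:
        return self.p_two_tailed < 0.01


def samples_to_frame(samples: Iterable[ConcentrationSample]) -> pd.DataFrame:
    """Long-format DataFrame (sample_id, section, compound, concentration_ug_m3)."""
    return pd.DataFrame(
        [
            {
                "sample_id": s.sample_id,
                "section": s.section,
                "compound": s.compound,
                "concentration_ug_m3": s.concentration,
            }
            for s in samples
        ]
    )


def frame_to_samples(frame: pd.DataFrame) -> list[ConcentrationSample]:
    """Parse a long-format table back into samples, naming bad rows."""
    required = {"sample_id", "section", "compound", "concentration_ug_m3"}
    missing = required - set(frame.columns)
    if missing:
        raise InvalidInputError(f"sample table missing columns {sorted(missing)}")
    out = []
    for idx, row in frame.iterrows():
        try:
            out.append(
                ConcentrationSample(
                    sample_id=str(row["sample_id"]),
                    section=str(row["section"]),
                    compound=str(row["compound"]),
                    concentration=float(row["concentration_ug_m3"]),
                )
            )
        except (TypeError, ValueError) as exc:
            raise InvalidInputError(f"bad sample row {idx}: {exc}") from exc
    return out


def _summary_from_values(compound: str, section: str, values: np.ndarray) -> CompoundSummary:
    n = len(values)
    if n == 1:
        logger.warning(
            "single sample for %s/%s: SD undefined, reported as 0", compound, section
        )
        sd = 0.0
    else:
        sd = float(np.std(values, ddof=1))
    return CompoundSummary(
        compound=compound,
        section=section,
        n=n,
        mean=float(np.mean(values)),
        median=float(np.median(values)),
        sd=sd,
        min=float(np.min(values)),
        max=float(np.max(values)),
    )


def summarize(
    samples: Iterable[ConcentrationSample], total_label: str = TOTAL_LABEL
) -> list[CompoundSummary]:
    """Per-(compound, section) summaries plus the within-sample ΣPAEs total.

    The total row sums every compound measured in a sample before
    summarizing, so its mean equals the sum of the compound means exactly
    (linearity) whenever every sample carries the full compound panel.
    Empty cells are omitted with a logged warning.
    """
    frame = samples_to_frame(list(samples))
    if frame.empty:
        logger.warning("no samples to summarize")
        return []

    out: list[CompoundSummary] = []
    for section, sec_frame in frame.groupby("section", sort=False):
        for compound, cell in sec_frame.groupby("compound", sort=False):
            values = cell["concentration_ug_m3"].to_numpy(dtype=float)
            if values.size == 0:  # pragma: no cover - groupby never yields empties
                logger.warning("empty cell %s/%s omitted", compound, section)
                continue
            out.append(_summary_from_values(str(compound), str(section), values))
        totals = (
            sec_frame.groupby("sample_id", sort=False)["concentration_ug_m3"]
            .sum()
            .to_numpy(dtype=float)
        )
        out.append(_summary_from_values(total_label, str(section), totals))
    return out


def summary_frame(summaries: Iterable[CompoundSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "compound": s.compound,
                "section": s.section,
                "n": s.n,
                "mean": s.mean,
                "median": s.median,
                "sd": s.sd,
                "min": s.min,
                "max": s.max,
                "range": s.range,
            }
            for s in summaries
        ]
    )


def wide_table(samples: Iterable[ConcentrationSample], section: str | None = None) -> pd.DataFrame:
    """Pivot to one row per sample, one column per compound."""
    frame = samples_to_frame(list(samples))
    if section is not None:
        frame = frame[frame["section"] == section]
    return frame.pivot_table(
        index="sample_id", columns="compound", values="concentration_ug_m3", sort=False
    )


def _exact_spearman_pvalue(x: np.ndarray, y: np.ndarray, rho_obs: float) -> float:
    """Two-tailed p by full enumeration of rank permutations (tie-free input)."""
    n = len(x)
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rx = (rx - rx.mean()) / rx.std()
    denom = ry.std() * n
    count = 0
    total = 0
    tol = 1e-12
    for perm in permutations(range(n)):
        rho = float(np.dot(rx[list(perm)], ry - ry.mean())) / denom
        if abs(rho) >= abs(rho_obs) - tol:
            count += 1
        total += 1
    return count / total


def spearman_pair(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Average-rank Spearman rho and a two-tailed p-value for one pair.

    Exact permutation null for n ≤ 9 without ties in either column; the
    t-approximation otherwise.  A constant column yields (nan, nan).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise InvalidInputError("Spearman needs >= 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        logger.warning("constant column: Spearman rho undefined")
        return math.nan, math.nan
    res = sps.spearmanr(x, y)
    rho = float(res.statistic)
    n = len(x)
    tie_free = len(np.unique(x)) == n and len(np.unique(y)) == n
    if n <= EXACT_PERMUTATION_MAX_N and tie_free:
        p = _exact_spearman_pvalue(x, y, rho)
    else:
        p = float(res.pvalue)
    return rho, p


def spearman_matrix(wide: pd.DataFrame) -> list[CorrelationCell]:
    """All pairwise Spearman correlations of a samples × compounds table.

    Rows with any missing value are dropped pairwise; ties are handled by
    average ranks.
    """
    cells: list[CorrelationCell] = []
    for a, b in combinations(wide.columns, 2):
        pair = wide[[a, b]].dropna()
        if len(pair) < 3:
            logger.warning("pair (%s, %s): fewer than 3 complete rows, skipped", a, b)
            continue
        rho, p = spearman_pair(pair[a].to_numpy(), pair[b].to_numpy())
        cells.append(CorrelationCell(str(a), str(b), rho, p, len(pair)))
    return cells


def correlation_frame(cells: Iterable[CorrelationCell]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "compound_a": c.compound_a,
                "compound_b": c.compound_b,
                "rho": c.rho,
                "p_two_tailed": c.p_two_tailed,
                "n": c.n,
                "significant_0.05": c.significant_05,
                "significant_0.01": c.significant_01,
            }
            for c in cells
        ]
    )
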