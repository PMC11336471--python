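"""Configuration loading: exposure factors, toxicity, generator targets.

The package ships a default YAML configuration (``data/defaults.yaml``)
holding the adult male/female occupational exposure-factor blocks, the four
phthalates' inhalation reference concentrations and the DEHP slope factor,
and the per-compound concentration summary targets the synthetic generator
reproduces.  Users may supply their own YAML file with the same layout.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Any, Mapping

import yaml

from .errors import ConfigurationError
from .exposure import ExposureFactors, ToxicityProfile

COMPOUNDS = ("DMP", "DEP", "DBP", "DEHP")
SECTIONS = ("industrial", "administrative")
TOTAL_LABEL = "sum_PAEs"


@dataclass(frozen=True)
class MomentTargets:
    """Target summary moments (μg/m³) for one compound in one section."""

    mean: float
    sd: float
    median: float | None = None
    min: float | None = None
    max: float | None = None


@dataclass(frozen=True)
class StudyConfig:
    """Parsed configuration bundle for the whole pipeline."""

    exposure_factors: dict[str, ExposureFactors]
    toxicity: dict[str, ToxicityProfile]
    concentration_targets: dict[str, dict[str, MomentTargets]]  # section -> compound
    section_sizes: dict[str, int]
    rank_correlations: list[tuple[str, str, float]]
    monte_carlo: dict[str, Any]

    def factors(self, gender: str) -> ExposureFactors:
        try:
            return self.exposure_factors[gender]
        except KeyError:
            raise ConfigurationError(f"no exposure factors for gender {gender!r}") from None


def _parse_factors(gender: str, block: Mapping[str, Any]) -> ExposureFactors:
    try:
        return ExposureFactors(
            gender=gender,
            ir=float(block["ir"]),
            bw=float(block["bw"]),
            ef=float(block["ef"]),
            ed=float(block["ed"]),
            at_noncancer=float(block["at_noncancer"]),
            at_cancer=float(block["at_cancer"]),
            cf=float(block.get("cf", 1e-3)),
        )
    except KeyError as exc:
        raise ConfigurationError(f"exposure factors for {gender!r} missing key {exc}") from None


def _parse_toxicity(compound: str, block: Mapping[str, Any]) -> ToxicityProfile:
    sf = block.get("slope_factor")
    return ToxicityProfile(
        compound=compound,
        rfc_air=float(block["rfc_air"]),
        carcinogenic=bool(block.get("carcinogenic", False)),
        slope_factor=None if sf is None else float(sf),
    )


def parse_config(raw: Mapping[str, Any]) -> StudyConfig:
    """Build a :class:`StudyConfig` from a parsed YAML mapping."""
    try:
        factors = {g: _parse_factors(g, b) for g, b in raw["exposure_factors"].items()}
        toxicity = {c: _parse_toxicity(c, b) for c, b in raw["toxicity"].items()}
    except KeyError as exc:
        raise ConfigurationError(f"configuration missing section {exc}") from None

    targets: dict[str, dict[str, MomentTargets]] = {}
    sizes: dict[str, int] = {}
    for section, block in raw.get("concentration_targets", {}).items():
        sizes[section] = int(block["n_samples"])
        targets[section] = {
            comp: MomentTargets(
                mean=float(m["mean"]),
                sd=float(m["sd"]),
                median=m.get("median"),
                min=m.get("min"),
                max=m.get("max"),
            )
            for comp, m in block["compounds"].items()
        }

    corrs = [(str(a), str(b), float(r)) for a, b, r in raw.get("rank_correlations", [])]
    return StudyConfig(
        exposure_factors=factors,
        toxicity=toxicity,
        concentration_targets=targets,
        section_sizes=sizes,
        rank_correlations=corrs,
        monte_carlo=dict(raw.get("monte_carlo", {})),
    )


def load_config(path: str | Path | None = None) -> StudyConfig:
    """Load a YAML configuration; ``None`` loads the shipped defaults."""
    if path is None:
        text = resources.files("paerisk.data").joinpath("defaults.yaml").read_text()
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)
    if not isinstance(raw, Mapping):
        raise ConfigurationError("configuration root must be a mapping")
    return parse_config(raw)


def default_config() -> StudyConfig:
    """The shipped study defaults (adult workers, four phthalates)."""
    return load_config(None)
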