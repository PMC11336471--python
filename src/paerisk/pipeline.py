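"""End-to-end pipeline: generate/load samples, summarize, correlate,
compute the deterministic risk tables and the Monte-Carlo LTCR summary,
and write a reproducible report bundle with a run manifest."""

from __future__ import annotations

import hashlib
import json
import logging
import platform
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy

from . import __version__
from .config import StudyConfig, TOTAL_LABEL, load_config
from .errors import ConfigurationError, InvalidInputError
from .exposure import (
    average_daily_dose,
    classify_cancer_risk,
    lifetime_cancer_risk,
    risk_frame,
    risk_table,
)
from .montecarlo import (
    DEFAULT_N_TRIALS,
    RISK_BASELINE,
    baseline_ratio_report,
    fit_lognormal_moments,
    simulate_ltcr,
)
from .stats import (
    correlation_frame,
    frame_to_samples,
    samples_to_frame,
    spearman_matrix,
    summarize,
    summary_frame,
    wide_table,
)
from .synthetic import generate_samples, study_specs

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Where inputs come from and where the bundle goes."""

    output_dir: Path
    input_csv: Path | None = None  # long-format sample table; None → generate
    study_config: Path | None = None  # None → shipped defaults
    seed: int = 0
    n_trials: int | None = None  # None → study config / default
    dry_run: bool = False

    def __post_init__(self) -> None:
        self.output_dir = Path(self.output_dir)
        if self.input_csv is not None:
            self.input_csv = Path(self.input_csv)


def _load_samples(pc: PipelineConfig, cfg: StudyConfig):
    if pc.input_csv is not None:
        try:
            frame = pd.read_csv(pc.input_csv)
        except Exception as exc:
            raise InvalidInputError(f"cannot parse {pc.input_csv}: {exc}") from exc
        return frame_to_samples(frame)
    specs = study_specs(
        cfg.concentration_targets, cfg.section_sizes, cfg.rank_correlations, seed=pc.seed
    )
    samples = []
    for spec in specs:
        samples.extend(generate_samples(spec))
    return samples


def _deterministic_ltcr_frame(cfg: StudyConfig, summaries) -> pd.DataFrame:
    """Point-estimate LTCR per carcinogen × section × gender from mean c."""
    rows = []
    means = {(s.compound, s.section): s.mean for s in summaries if s.compound != TOTAL_LABEL}
    for (compound, section), c in means.items():
        tox = cfg.toxicity.get(compound)
        if tox is None or not tox.carcinogenic:
            continue
        for gender, ef in cfg.exposure_factors.items():
            ladd = average_daily_dose(c, ef, "cancer")
            ltcr = lifetime_cancer_risk(ladd, tox.slope_factor)
            rows.append(
                {
                    "compound": compound,
                    "section": section,
                    "gender": gender,
                    "mean_c_ug_m3": c,
                    "ladd_mg_kg_day": ladd,
                    "ltcr": ltcr,
                    "classification": classify_cancer_risk(ltcr),
                }
            )
    return pd.DataFrame(rows)


def _monte_carlo_summaries(cfg: StudyConfig, summaries, seed: int, n_trials: int) -> dict:
    """Lognormal-c Monte-Carlo LTCR per carcinogen × section × gender."""
    out: dict[str, dict] = {}
    mc_cfg = cfg.monte_carlo
    baseline = float(mc_cfg.get("baseline", RISK_BASELINE))
    percentiles = tuple(mc_cfg.get("percentiles", (15, 25, 50, 75, 90)))
    stream = np.random.SeedSequence(seed).spawn(64)
    k = 0
    for s in summaries:
        tox = cfg.toxicity.get(s.compound)
        if tox is None or not tox.carcinogenic:
            continue
        for gender, ef in cfg.exposure_factors.items():
            sub_seed = int(stream[k].generate_state(1)[0] % (2**31))
            k += 1
            res = simulate_ltcr(
                {"c": fit_lognormal_moments(s.mean, s.sd)},
                sf=tox.slope_factor,
                ef_defaults=ef,
                n_trials=n_trials,
                seed=sub_seed,
                percentiles=percentiles,
                baseline=baseline,
            )
            report = baseline_ratio_report(res, baseline)
            out[f"{s.compound}/{s.section}/{gender}"] = {
                "n_trials": res.n_trials,
                "seed": res.seed,
                "mean": res.mean,
                "sd": res.sd,
                "percentiles": {str(q): v for q, v in sorted(res.percentiles.items())},
                "baseline_ratios": {str(q): v for q, v in sorted(report["ratios"].items())},
                "exceedance_prob": report["exceedance_prob"],
                "baseline": baseline,
            }
    return out


def run_pipeline(pc: PipelineConfig) -> dict[str, Path]:
    """Run every stage and write the report bundle; returns written paths.

    Bundle: samples.csv, summary.csv, correlations.csv, risk.csv,
    ltcr_deterministic.csv, monte_carlo.json, manifest.json.
    """
    cfg = load_config(pc.study_config)
    samples = _load_samples(pc, cfg)
    summaries = summarize(samples)
    compound_summaries = [s for s in summaries if s.compound != TOTAL_LABEL]

    missing = {s.compound for s in compound_summaries} - set(cfg.toxicity)
    if missing:
        raise ConfigurationError(f"no toxicity profile for {sorted(missing)}")

    cells = []
    for section in sorted({s.section for s in compound_summaries}):
        wide = wide_table(samples, section=section)
        for cell in spearman_matrix(wide):
            cells.append((section, cell))

    means = {(s.compound, s.section): s.mean for s in compound_summaries}
    risks = risk_table(means, cfg.exposure_factors.values(), cfg.toxicity)

    n_trials = pc.n_trials or int(cfg.monte_carlo.get("n_trials", DEFAULT_N_TRIALS))
    mc = _monte_carlo_summaries(cfg, compound_summaries, pc.seed, n_trials)

    if pc.dry_run:
        logger.info("dry run: configuration valid, nothing written")
        return {}

    pc.output_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    def write_csv(name: str, frame: pd.DataFrame) -> None:
        path = pc.output_dir / name
        frame.to_csv(path, index=False)
        paths[name] = path

    write_csv("samples.csv", samples_to_frame(samples))
    write_csv("summary.csv", summary_frame(summaries))
    corr = correlation_frame([c for _, c in cells])
    corr.insert(0, "section", [sec for sec, _ in cells])
    write_csv("correlations.csv", corr)
    write_csv("risk.csv", risk_frame(risks))
    write_csv("ltcr_deterministic.csv", _deterministic_ltcr_frame(cfg, compound_summaries))

    mc_path = pc.output_dir / "monte_carlo.json"
    mc_path.write_text(json.dumps(mc, indent=2, sort_keys=True))
    paths["monte_carlo.json"] = mc_path

    manifest = {
        "seed": pc.seed,
        "n_trials": n_trials,
        "input": str(pc.input_csv) if pc.input_csv else "synthetic",
        "config": str(pc.study_config) if pc.study_config else "defaults",
        "config_sha256": _config_hash(pc.study_config),
        "versions": {
            "paerisk": __version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
        },
        "outputs": sorted(paths),
    }
    man_path = pc.output_dir / "manifest.json"
    man_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    paths["manifest.json"] = man_path
    return paths


def _config_hash(path: Path | None) -> str:
    if path is None:
        from importlib import resources

        text = resources.files("paerisk.data").joinpath("defaults.yaml").read_text()
    else:
        text = Path(path).read_text()
    return hashlib.sha256(text.encode()).hexdigest()
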