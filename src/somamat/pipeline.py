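"""End-to-end orchestration: simulate or ingest → estimate → infer → report.

A :class:`RunConfig` fully determines a run; the single top-level seed is
fanned out into named substreams per stage, so identical config + seed give
byte-identical outputs.  Every output is delimited text or JSON and
re-parses under the package's own readers; a manifest records the seed, a
hash of the configuration and the provenance label of the growth reference
used.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from . import __version__
from .cohort_io import read_cohort, summarise_cohort, write_cohort
from .growth_reference import (
    GrowthReferenceTable,
    load_reference,
    synthetic_default_reference,
)
from .inference import (
    category_distribution,
    cohort_frame,
    crosstab_success,
    fit_selection_model,
    likelihood_ratio_test,
    nhl_spec,
    predicted_probabilities,
    team16_spec,
    univariable_spec,
)
from .maturity import (
    ClassificationConfig,
    UnresolvableAdultHeightError,
    estimate_maturity,
    estimates_frame,
)
from .synthetic_cohort import SyntheticCohortConfig, simulate_cohort

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "stage_rng", "estimate_cohort"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """A named, reproducible substream of the top-level seed."""
    return np.random.default_rng(np.random.SeedSequence([seed, zlib.crc32(stage.encode())]))


@dataclass
class RunConfig:
    """Everything a pipeline run depends on."""

    mode: str = "synthetic"  # 'synthetic' | 'files'
    out_dir: str = "somamat_out"
    seed: int = 0
    measurements_path: Optional[str] = None
    roster_path: Optional[str] = None
    reference_path: Optional[str] = None  # None -> synthetic default reference
    synthetic: SyntheticCohortConfig = field(default_factory=SyntheticCohortConfig)
    classification: ClassificationConfig = field(default_factory=ClassificationConfig)
    cohort_default_age: float = 16.2
    maturity_term: str = "z_pah"  # 'z_pah' | 'pah' (raw-scale option)
    log_level: str = "INFO"

    def __post_init__(self):
        if self.mode not in {"synthetic", "files"}:
            raise ValueError("mode must be 'synthetic' or 'files'")
        if isinstance(self.synthetic, dict):
            self.synthetic = SyntheticCohortConfig(**self.synthetic)
        if isinstance(self.classification, dict):
            self.classification = ClassificationConfig(**self.classification)
        if self.mode == "files":
            for name in ("measurements_path", "roster_path"):
                p = getattr(self, name)
                if p is None or not Path(p).exists():
                    raise ValueError(f"{name} missing or does not exist: {p!r}")
        if self.reference_path is not None and not Path(self.reference_path).exists():
            raise ValueError(f"reference_path does not exist: {self.reference_path!r}")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()


def _load_ref(cfg: RunConfig) -> GrowthReferenceTable:
    if cfg.reference_path is None:
        return synthetic_default_reference()
    return load_reference(cfg.reference_path, provenance_label=str(cfg.reference_path))


def estimate_cohort(records, ref, classification=ClassificationConfig(), cohort_default_age=16.2):
    """Maturity estimates for every player with a resolvable adult height."""
    estimates = []
    for rec in records:
        try:
            estimates.append(
                estimate_maturity(rec, ref, classification, cohort_default_age)
            )
        except UnresolvableAdultHeightError:
            continue  # lost to follow-up; counted by summarise_cohort
    return estimates


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full pipeline and write all report tables to ``cfg.out_dir``.

    Returns a run report (paths, summary numbers).  Any stage error removes
    partial outputs and raises :class:`PipelineError` naming the stage.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _write_df(df, name, index=False):
        p = out / name
        df.to_csv(p, index=index)
        written.append(p)
        return p

    def _write_json(obj, name):
        p = out / name
        p.write_text(json.dumps(obj, indent=2, sort_keys=True, default=str) + "\n")
        written.append(p)
        return p

    stage = "load_reference"
    try:
        ref = _load_ref(cfg)

        stage = "ingest"
        if cfg.mode == "synthetic":
            sim_cfg = dataclasses.replace(cfg.synthetic, seed=cfg.seed)
            records, truth = simulate_cohort(sim_cfg, ref, rng=stage_rng(cfg.seed, "simulate"))
            _write_df(truth.reset_index(), "truth.csv")
            write_cohort(records, out / "measurements.csv", out / "roster.csv")
            written += [out / "measurements.csv", out / "roster.csv"]
        else:
            records = read_cohort(cfg.measurements_path, cfg.roster_path)

        stage = "estimate"
        estimates = estimate_cohort(records, ref, cfg.classification, cfg.cohort_default_age)
        est_df = estimates_frame(estimates)
        _write_df(est_df, "estimates.csv")

        stage = "summarise"
        summary = summarise_cohort(records, estimates)
        _write_json(summary.to_dict(), "cohort_summary.json")
        _write_df(crosstab_success(records), "crosstab_success.csv")
        frame = cohort_frame(records, estimates)
        for by in ("category_z", "category_offset"):
            _write_df(category_distribution(frame, by=by), f"distribution_{by}.csv", index=True)

        stage = "fit"
        fits, model_summaries = {}, {}
        for name, spec in (("team16", team16_spec(cfg.maturity_term)),
                           ("nhl", nhl_spec(cfg.maturity_term))):
            fit = fit_selection_model(frame, spec)
            fits[name] = fit
            _write_df(fit.summary_frame(), f"model_{name}_coefficients.csv")
            null = fit_selection_model(frame, univariable_spec(name, cfg.maturity_term))
            lrt = likelihood_ratio_test(fit, null)
            model_summaries[name] = {
                "aic": fit.aic,
                "log_likelihood": fit.log_likelihood,
                "n_obs": fit.n_obs,
                "converged": fit.converged,
                "random_intercept_sd": fit.random_intercept_sd,
                "lrt_vs_univariable": {"statistic": lrt.statistic, "df": lrt.df, "p": lrt.p},
            }
            if fit.converged:
                frame[f"p_{name}"] = predicted_probabilities(fit, frame)
        _write_df(
            frame[["player_id"] + [c for c in ("p_team16", "p_nhl") if c in frame]],
            "predicted_probabilities.csv",
        )
        _write_json(model_summaries, "model_summaries.json")

        stage = "manifest"
        manifest = {
            "package_version": __version__,
            "seed": cfg.seed,
            "config_hash": cfg.config_hash(),
            "reference_provenance": ref.provenance_label,
            "mode": cfg.mode,
            "n_players": summary.n_players,
            "outputs": sorted(p.name for p in written),
        }
        _write_json(manifest, "manifest.json")
    except Exception as exc:
        for p in written:
            p.unlink(missing_ok=True)
        raise PipelineError(stage, exc) from exc

    return {
        "out_dir": str(out),
        "summary": summary.to_dict(),
        "models": model_summaries,
        "manifest": manifest,
    }
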