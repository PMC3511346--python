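"""Table input, report output and the three-stage analysis pipeline.

The pipeline mirrors the study design: (1) direction statistics with a
paired bootstrap for each requested method, (2) assumption diagnostics
for the kernel-MI-chosen direction, (3) an optional sensitivity grid on
a generative model fitted to the input pair. All machine outputs are
delimited text with raw numeric p-values; "<.001"-style flooring is a
display concern only.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .causality import METHODS, PairedSample, compute_statistic
from .exceptions import InputError
from .model_check import assumption_report
from .resampling import bootstrap_causality
from .simulation import fit_data_model, run_experiment_grid

log = logging.getLogger("paircause")

__all__ = ["AnalysisConfig", "read_pair_table", "write_pair_table", "run_analysis"]


@dataclass(frozen=True)
class AnalysisConfig:
    """Configuration of one pipeline run."""

    input: str
    x_col: str
    y_col: str
    methods: tuple[str, ...] = ("lingam", "skew", "tanh")
    B: int = 2000
    level: float = 0.95
    standardize: bool = True
    jitter: bool = False
    jitter_sd: float = np.sqrt(0.1)
    seed: int = 0
    outdir: str = "paircause_out"
    run_simulation: bool = False
    simulation_reps: int = 1000
    lingam_B: int | None = 200

    def __post_init__(self):
        if self.B < 100:
            raise InputError("B must be >= 100")
        unknown = set(self.methods) - set(METHODS)
        if unknown:
            raise InputError(f"unknown methods {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "methods" in raw:
            raw["methods"] = tuple(raw["methods"])
        return cls(**raw)

    def digest(self) -> str:
        """Hash of the analysis-relevant settings (output location excluded)."""
        payload = asdict(self)
        payload.pop("outdir")
        payload = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _sniff_sep(path) -> str:
    with open(path) as fh:
        header = fh.readline()
    return "\t" if header.count("\t") >= header.count(",") else ","


def read_pair_table(path, x_col: str, y_col: str) -> PairedSample:
    """Read a two-column paired sample from a delimited text file.

    Rows with a missing value in either column are dropped (complete-case
    inclusion) with a logged count.
    """
    sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    for col in (x_col, y_col):
        if col not in df.columns:
            raise InputError(
                f"column {col!r} not found; available: {list(df.columns)}")
    sub = df[[x_col, y_col]].apply(pd.to_numeric, errors="coerce")
    complete = sub.dropna()
    dropped = len(sub) - len(complete)
    if dropped:
        log.info("dropped %d incomplete rows of %d", dropped, len(sub))
    if len(complete) < 20:
        raise InputError(f"only {len(complete)} complete rows; need >= 20")
    return PairedSample(complete[x_col].to_numpy(), complete[y_col].to_numpy(),
                        x_label=x_col, y_label=y_col)


def write_pair_table(sample: PairedSample, path, sep: str = ",") -> None:
    pd.DataFrame({sample.x_label: sample.x, sample.y_label: sample.y}) \
        .to_csv(path, sep=sep, index=False)


def _apply_jitter(sample: PairedSample, sd: float, seed) -> PairedSample:
    rng = np.random.default_rng(seed)
    return PairedSample(sample.x + rng.normal(0, sd, sample.n),
                        sample.y + rng.normal(0, sd, sample.n),
                        sample.x_label, sample.y_label)


def run_analysis(config: AnalysisConfig) -> dict[str, Path]:
    """Execute the full three-stage pipeline and write report files.

    Returns a mapping from report name to the written path. Outputs are
    deterministic given the config (including its master seed); the run
    manifest records the config, its hash, the seed and the package
    version so a run can be reproduced bit for bit.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    sample = read_pair_table(config.input, config.x_col, config.y_col)
    if config.jitter:
        sample = _apply_jitter(sample, config.jitter_sd,
                               np.random.SeedSequence([1, config.seed]))

    manifest = {
        "config": asdict(config),
        "config_hash": config.digest(),
        "seed": config.seed,
        "paircause_version": __version__,
        "n": sample.n,
        "stages": [],
    }

    stage = "direction_bootstrap"
    try:
        rows = []
        for i, method in enumerate(config.methods):
            B = config.lingam_B if (method == "lingam" and config.lingam_B) \
                else config.B
            kwargs = {"standardize_first": config.standardize} \
                if method == "lingam" else {}
            point = compute_statistic(sample, method, **kwargs)
            boot = bootstrap_causality(
                sample, method, B=B, level=config.level,
                seed=np.random.SeedSequence([10 + i, config.seed]), **kwargs)
            rows.append({
                "x": sample.x_label, "y": sample.y_label, "method": method,
                "B": B, "statistic": point.value, "direction": point.direction,
                "pct_first_cause": boot.pct_first,
                "pct_second_cause": boot.pct_second,
                "pct_tie": boot.pct_tie,
                "median_statistic": boot.median_value,
                "ci_low": boot.ci_low, "ci_high": boot.ci_high,
                "level": config.level, "seed": config.seed,
                "config_hash": config.digest(),
            })
        direction_df = pd.DataFrame(rows)
        path = outdir / "direction_bootstrap.tsv"
        direction_df.to_csv(path, sep="\t", index=False)
        written["direction_bootstrap"] = path
        manifest["stages"].append(stage)

        stage = "assumption_checks"
        anchor = "lingam" if "lingam" in config.methods else config.methods[0]
        chosen = direction_df.loc[direction_df.method == anchor, "direction"].iloc[0]
        if chosen == "tie":
            log.warning("anchor statistic is exactly 0; skipping assumption "
                        "checks (no estimated direction)")
        else:
            report = assumption_report(sample, chosen, seed=config.seed)
            path = outdir / "assumption_checks.tsv"
            pd.DataFrame([{**report.as_dict(), "seed": config.seed,
                           "config_hash": config.digest()}]) \
                .to_csv(path, sep="\t", index=False)
            written["assumption_checks"] = path
        manifest["stages"].append(stage)

        if config.run_simulation:
            stage = "sensitivity_grid"
            model = fit_data_model(sample, seed=config.seed)
            grid = run_experiment_grid(
                model, methods=[m for m in config.methods if m != "lingam"],
                reps=config.simulation_reps, seed=config.seed)
            grid["seed"] = config.seed
            grid["config_hash"] = config.digest()
            path = outdir / "sensitivity_grid.tsv"
            grid.to_csv(path, sep="\t", index=False)
            written["sensitivity_grid"] = path
            manifest["stages"].append(stage)
    except Exception:
        manifest["failed_stage"] = stage
        (outdir / "run_manifest.json").write_text(json.dumps(manifest, indent=2))
        log.error("pipeline failed in stage %r; partial outputs kept in %s",
                  stage, outdir)
        raise

    path = outdir / "run_manifest.json"
    path.write_text(json.dumps(manifest, indent=2))
    written["run_manifest"] = path
    return written


def configure_logging(verbosity: int = 0) -> None:
    level = logging.WARNING - 10 * verbosity
    logging.basicConfig(stream=sys.stderr, level=max(level, logging.DEBUG),
                        format="%(levelname)s %(name)s: %(message)s")
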