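"""Trial-table I/O, run configuration and pipeline orchestration.

The canonical on-disk trial table is comma-separated UTF-8 text with a
'.' decimal separator, times in seconds and signed float coherences.
Files written by this module embed the run seed and a configuration hash
in '#'-prefixed header lines, which the reader ignores.
"""

from __future__ import annotations

import hashlib
import io
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "SchemaError",
    "PipelineError",
    "read_trial_table",
    "write_trial_table",
    "run_pipeline",
    "FIGSHARE_RENAME_MAP",
]


class SchemaError(ValueError):
    """A trial table violates the preset's schema."""


class PipelineError(RuntimeError):
    """A pipeline stage failed; .stage names the stage."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


#: required columns per task preset
SCHEMAS: dict[str, tuple[str, ...]] = {
    "exp1_eye": ("subject", "task", "s_m", "s_c", "R_m", "R_c", "rt"),
    "exp1_uni": ("subject", "task", "s_m", "s_c", "R_m", "R_c", "rt"),
    "exp2_short": ("subject", "task", "s_m", "s_c", "R_m", "R_c", "rt", "t_dur"),
    "exp3_duration": ("subject", "task", "s_m", "s_c", "R_m", "R_c", "t_dur"),
    "exp4_bimanual": (
        "subject", "task", "s_m", "s_c", "R_m", "R_c",
        "rt_first", "rt_second", "first_dim",
    ),
    "exp5_samediff": ("subject", "task", "s_left", "s_right", "R_sd", "rt"),
}

#: rename map from a deposited-data style export (synthetic mimic of the
#: public archive's column names) onto the canonical schema
FIGSHARE_RENAME_MAP: dict[str, str] = {
    "subj": "subject",
    "taskType": "task",
    "cohM": "s_m",
    "cohC": "s_c",
    "chM": "R_m",
    "chC": "R_c",
    "RT": "rt",
    "RT1": "rt_first",
    "RT2": "rt_second",
    "dim1st": "first_dim",
    "Tdur": "t_dur",
}


def _validate(df: pd.DataFrame, preset: str | None) -> None:
    if preset is not None:
        if preset not in SCHEMAS:
            raise SchemaError(f"unknown preset {preset!r}")
        missing = [c for c in SCHEMAS[preset] if c not in df.columns]
        if missing:
            raise SchemaError(f"preset {preset!r}: missing required columns {missing}")
    for col in ("rt", "rt_first", "rt_second"):
        if col in df.columns:
            vals = df[col].to_numpy(dtype=float)
            bad = np.where(np.isfinite(vals) & (vals <= 0))[0]
            if len(bad):
                raise SchemaError(
                    f"{col} must be > 0; first violation at data row {bad[0] + 1}"
                )
    if "rt_first" in df.columns and "rt_second" in df.columns:
        a = df["rt_first"].to_numpy(dtype=float)
        b = df["rt_second"].to_numpy(dtype=float)
        bad = np.where(np.isfinite(a) & np.isfinite(b) & (a > b + 1e-12))[0]
        if len(bad):
            raise SchemaError(
                f"rt_first > rt_second at data row {bad[0] + 1}"
            )
    for col in ("s_m", "s_c", "s_left", "s_right"):
        if col in df.columns:
            vals = df[col].to_numpy(dtype=float)
            bad = np.where(np.abs(vals) > 1)[0]
            if len(bad):
                raise SchemaError(
                    f"|{col}| must be <= 1; first violation at data row {bad[0] + 1}"
                )


def write_trial_table(
    df: pd.DataFrame,
    path: str | Path,
    seed: int | None = None,
    config_hash: str | None = None,
) -> Path:
    """Write a trial table as commented CSV; returns the path."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    seed = seed if seed is not None else df.attrs.get("seed")
    buf = io.StringIO()
    buf.write("# multidec trial table\n")
    if seed is not None:
        buf.write(f"# seed={seed}\n")
    if config_hash is not None:
        buf.write(f"# config_hash={config_hash}\n")
    df.to_csv(buf, index=False)
    path.write_text(buf.getvalue(), encoding="utf-8")
    return path


def read_trial_table(
    path: str | Path,
    preset: str | None = None,
    rename_map: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Read a trial table; optionally validate against a preset schema.

    rename_map (e.g. FIGSHARE_RENAME_MAP) translates foreign column
    names before validation.
    """
    df = pd.read_csv(path, comment="#")
    if rename_map:
        df = df.rename(columns=rename_map)
    _validate(df, preset)
    # recover embedded metadata
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if "seed=" in line:
                df.attrs["seed"] = int(line.split("seed=")[1])
            if "config_hash=" in line:
                df.attrs["config_hash"] = line.split("config_hash=")[1].strip()
    return df


@dataclass
class RunConfig:
    """Configuration of an end-to-end simulate/fit/compare run."""

    preset: str = "exp1_eye"
    architecture: str = "serial"
    params: dict = field(default_factory=dict)
    n_per_cell: int = 16
    seed: int = 0
    split: str = "strongest"  # or "none"
    outdir: str = "multidec_out"
    log_level: str = "INFO"
    fit_options: dict = field(default_factory=lambda: {"n_starts": 2, "maxfev": 200})

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha1(blob).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


def _default_generating_params(overrides: dict) -> dict:
    from .combine import NonDecisionSpec
    from .ddm_core import BoundSpec, DDMParams

    base = {
        "kappa_m": 11.0, "s0_m": 0.0, "u_m": 0.9, "a_m": 1.2, "d_m": 1.5,
        "kappa_c": 9.0, "s0_c": 0.0, "u_c": 0.8, "a_c": 1.0, "d_c": 1.4,
        "mu_nd": 0.32, "sigma_nd": 0.06,
    }
    base.update(overrides or {})
    return {
        "motion": DDMParams(
            base["kappa_m"], base["s0_m"],
            BoundSpec(form="logistic", u=base["u_m"], a=base["a_m"], d=base["d_m"]),
            "motion",
        ),
        "color": DDMParams(
            base["kappa_c"], base["s0_c"],
            BoundSpec(form="logistic", u=base["u_c"], a=base["a_c"], d=base["d_c"]),
            "color",
        ),
        "nd": NonDecisionSpec(base["mu_nd"], base["sigma_nd"]),
    }


def run_pipeline(config: RunConfig) -> dict:
    """Simulate (or load), fit serial and parallel, compare, and write a
    result bundle.  Fully reproducible from config + seed.

    Returns {"trials": ..., "fit_serial": ..., "fit_parallel": ...,
    "log10_bf": ..., "paths": {...}}.
    """
    from . import fit_compare, synthetic_data

    logging.basicConfig(level=getattr(logging, config.log_level.upper(), 20))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    paths: dict[str, Path] = {}

    try:
        design = synthetic_data.EXP_DESIGNS[config.preset]
    except KeyError as exc:
        raise PipelineError("design", f"no design preset {config.preset!r}") from exc

    try:
        gen = _default_generating_params(config.params)
        trials = synthetic_data.simulate_trials(
            config.architecture, gen, design, n=config.n_per_cell, seed=config.seed
        )
        paths["trials"] = write_trial_table(
            trials, outdir / "trials.csv", seed=config.seed, config_hash=chash
        )
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("simulate", str(exc)) from exc

    fits = {}
    for rule in ("serial", "parallel"):
        try:
            if config.split == "strongest":
                fits[rule] = fit_compare.split_fit_predict(
                    trials, rule, seed=config.seed, **config.fit_options
                )
            else:
                logger.info("split disabled: fitting rule %s on all conditions", rule)
                fits[rule] = fit_compare.fit_mle(
                    trials, rule, seed=config.seed, **config.fit_options
                )
        except Exception as exc:
            raise PipelineError(f"fit-{rule}", str(exc)) from exc

    try:
        bf = fit_compare.log10_bayes_factor(fits["serial"], fits["parallel"])
        report = {
            "config_hash": chash,
            "seed": config.seed,
            "preset": config.preset,
            "architecture": config.architecture,
            "n_trials": int(len(trials)),
            "nll_serial": fits["serial"].nll,
            "nll_parallel": fits["parallel"].nll,
            "holdout_nll_serial": fits["serial"].holdout_nll,
            "holdout_nll_parallel": fits["parallel"].holdout_nll,
            "log10_bayes_factor_serial_over_parallel": bf,
            "params_serial": dict(zip(fit_compare.PARAM_NAMES, fits["serial"].vector.tolist())),
            "params_parallel": dict(zip(fit_compare.PARAM_NAMES, fits["parallel"].vector.tolist())),
        }
        paths["report"] = outdir / "report.json"
        paths["report"].write_text(json.dumps(report, indent=2), encoding="utf-8")
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("compare", str(exc)) from exc

    return {
        "trials": trials,
        "fit_serial": fits["serial"],
        "fit_parallel": fits["parallel"],
        "log10_bf": bf,
        "paths": paths,
        "config_hash": chash,
    }
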