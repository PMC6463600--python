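"""End-to-end pipeline: simulate or ingest a cohort, produce the cohort
summary, univariate table, full/stepwise/BBO models, the model-comparison
report and per-covariate Kaplan-Meier curve data with log-rank p-values.

All artifacts are plain CSV/JSON; every file is stamped with the seed, the
package version and a hash of the generating configuration, and a fixed
seed makes the whole bundle byte-identical across runs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import io
import json
import logging
import time as _time
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .bbo import BBOParams, BBORun, run_bbo
from .comparison import (
    STEPWISE_ALPHAS,
    compare_models,
    stepwise_select,
    univariate_table,
)
from .simulate import GeneratorConfig, generate_cohort, table_one
from .survival import covariate_columns, km_curve, logrank_test

__all__ = ["PipelineConfig", "run_pipeline", "export_tables",
           "round_half_up", "load_cohort_csv", "write_cohort_csv"]

logger = logging.getLogger("bbocox")


def round_half_up(x: float, ndigits: int) -> float:
    """Decimal half-up rounding (0.4935 -> 0.494 at 3 digits), the style of
    the published tables, as opposed to float banker's rounding."""
    x = float(x)
    if not np.isfinite(x):
        return x
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def load_cohort_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    for col in ("time", "event"):
        if col not in df.columns:
            raise ValueError(f"cohort CSV lacks required column {col!r}")
    return df


def write_cohort_csv(cohort: pd.DataFrame, path: str | Path,
                     header_comment: str | None = None) -> None:
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        cohort.to_csv(fh, index=False)


@dataclass
class PipelineConfig:
    cohort_source: str | GeneratorConfig | None = None  # CSV path or generator
    seed: int = 0
    bbo: BBOParams = field(default_factory=BBOParams)
    stepwise_alphas: tuple[float, ...] = STEPWISE_ALPHAS
    output_dir: str | Path | None = None
    km_covariates: str | tuple[str, ...] = "bbo-selected"

    def __post_init__(self):
        for a in self.stepwise_alphas:
            if not 0.0 < a < 1.0:
                raise ValueError("stepwise alphas must be in (0, 1)")

    def config_hash(self) -> str:
        """Hash of the analysis-relevant configuration (output location
        excluded, so relocating a run does not change its identity)."""

        def enc(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {f.name: enc(getattr(obj, f.name))
                        for f in dataclasses.fields(obj)
                        if f.name != "output_dir"}
            if isinstance(obj, np.ndarray):
                return obj.tolist()
            if isinstance(obj, (list, tuple)):
                return [enc(o) for o in obj]
            if isinstance(obj, Path):
                return str(obj)
            return obj

        blob = json.dumps(enc(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _stage(name: str):
    logger.info("stage %s started", name)
    return _time.perf_counter()


def _stage_done(name: str, t0: float):
    logger.info("stage %s done in %.2fs", name, _time.perf_counter() - t0)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every analysis stage; returns the artifact bundle and, when
    ``output_dir`` is set, writes the CSV/JSON artifacts there."""
    bundle: dict = {
        "meta": {
            "seed": config.seed,
            "version": __version__,
            "config_hash": config.config_hash(),
        }
    }
    try:
        t0 = _stage("cohort")
        source = config.cohort_source
        if source is None:
            source = GeneratorConfig(seed=config.seed)
        if isinstance(source, GeneratorConfig):
            cohort = generate_cohort(source, seed=config.seed)
        else:
            cohort = load_cohort_csv(source)
        bundle["cohort"] = cohort
        _stage_done("cohort", t0)

        t0 = _stage("table_one")
        bundle["table1"] = table_one(cohort)
        _stage_done("table_one", t0)

        t0 = _stage("univariate")
        bundle["univariate"] = univariate_table(cohort)
        _stage_done("univariate", t0)

        t0 = _stage("bbo")
        bbo_params = dataclasses.replace(config.bbo, seed=config.seed)
        bbo_run = run_bbo(cohort, bbo_params)
        bundle["bbo_run"] = bbo_run
        _stage_done("bbo", t0)

        t0 = _stage("comparison")
        bundle["comparison"] = compare_models(
            cohort, bbo_run, alphas=config.stepwise_alphas)
        _stage_done("comparison", t0)

        t0 = _stage("km")
        if config.km_covariates == "bbo-selected":
            km_names = list(bbo_run.best_subset)
        else:
            km_names = list(config.km_covariates)
        km_tables: dict[str, pd.DataFrame] = {}
        time_arr = cohort["time"].to_numpy()
        event_arr = cohort["event"].to_numpy()
        for name in km_names:
            x = cohort[name].to_numpy()
            frames = []
            for lvl in (0, 1):
                mask = x == lvl
                if mask.sum() == 0:
                    continue
                curve = km_curve(time_arr[mask], event_arr[mask])
                frames.append(pd.DataFrame({
                    "stratum": lvl,
                    "time": curve.times,
                    "survival": curve.survival,
                    "at_risk": curve.at_risk,
                    "n_events": curve.n_events,
                }))
            tab = (pd.concat(frames, ignore_index=True) if frames
                   else pd.DataFrame(columns=["stratum", "time", "survival",
                                              "at_risk", "n_events"]))
            try:
                p = logrank_test(time_arr, event_arr, x).p
            except ValueError:
                p = float("nan")
            tab.attrs["logrank_p"] = p
            km_tables[name] = tab
        bundle["km"] = km_tables
        _stage_done("km", t0)
    except Exception:
        logger.exception("pipeline aborted; partial bundle retained")
        if config.output_dir is not None:
            export_tables(bundle, config.output_dir)
        raise

    if config.output_dir is not None:
        export_tables(bundle, config.output_dir)
    return bundle


def _stamp(bundle: dict, extra: str = "") -> str:
    meta = bundle["meta"]
    tail = f" {extra}" if extra else ""
    return (f"bbocox v{meta['version']} seed={meta['seed']} "
            f"config_sha256={meta['config_hash']}{tail}")


def _write_csv(df: pd.DataFrame, path: Path, stamp: str) -> None:
    buf = io.StringIO()
    df.to_csv(buf, index=False)
    path.write_text(f"# {stamp}\n" + buf.getvalue())


_DISPLAY_RULES = {  # column-name substring -> digits (percent-style: 2, ratio-style: 3)
    "pct": 2, "hr": 3, "ci": 3, "p": 3, "beta": 3, "se": 3, "c": 3,
    "hsi": 3, "survival": 3,
}


def _display_round(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    for col in out.columns:
        if out[col].dtype.kind != "f":
            continue
        digits = next((d for key, d in _DISPLAY_RULES.items()
                       if key in col.lower()), None)
        if digits is not None:
            out[col] = out[col].map(lambda v: round_half_up(v, digits))
    return out


def export_tables(bundle: dict, output_dir: str | Path) -> list[Path]:
    """Write the bundle's tables as stamped CSV/JSON files (full precision,
    plus a ``*_display.csv`` half-up-rounded variant of each table)."""
    outdir = Path(output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    stamp = _stamp(bundle)
    written: list[Path] = []

    def emit(df: pd.DataFrame, name: str, extra: str = ""):
        p = outdir / f"{name}.csv"
        _write_csv(df, p, stamp + (f" {extra}" if extra else ""))
        written.append(p)
        pd_disp = _display_round(df)
        pdisp = outdir / f"{name}_display.csv"
        _write_csv(pd_disp, pdisp, stamp + (f" {extra}" if extra else ""))
        written.append(pdisp)

    if "cohort" in bundle:
        p = outdir / "cohort.csv"
        write_cohort_csv(bundle["cohort"], p, stamp)
        written.append(p)
    if "table1" in bundle:
        emit(bundle["table1"], "table1")
    if "univariate" in bundle:
        emit(bundle["univariate"], "table2_univariate")
    if "comparison" in bundle:
        emit(bundle["comparison"].to_frame(), "table3_comparison")
        p = outdir / "comparison.json"
        p.write_text(bundle["comparison"].to_json())
        written.append(p)
    if "bbo_run" in bundle:
        run: BBORun = bundle["bbo_run"]
        emit(run.history, "bbo_history")
        p = outdir / "bbo_run.json"
        p.write_text(json.dumps({
            "stamp": stamp,
            "best_subset": list(run.best_subset),
            "best_hsi": run.best.hsi,
            "evaluations": run.evaluations,
            "seed": run.params.seed,
        }, indent=2))
        written.append(p)
    for name, tab in bundle.get("km", {}).items():
        emit(tab, f"km_{name}", extra=f"logrank_p={tab.attrs['logrank_p']!r}")
    return written
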