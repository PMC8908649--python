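"""End-to-end orchestration: simulate -> preprocess -> connect -> metrics -> stats.

A :class:`RunConfig` (YAML/JSON-serializable mapping) drives every stage;
equal config + seed reproduces every table byte-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from wmhnet import io as wio
from wmhnet.cohort import CohortParams, SubjectRecord, generate_cohort, write_cohort
from wmhnet.connectivity import ConnectivityMatrix, SparsityGrid, fisher_z, pearson_matrix
from wmhnet.inference import run_group_analysis
from wmhnet.metrics import GLOBAL_METRICS, NullEnsembleParams, metric_profiles
from wmhnet.preprocess import ConfoundSet, preprocess_timeseries

__all__ = ["RunConfig", "ReportBundle", "run_pipeline", "load_config"]

STAGES = ("simulate", "preprocess", "connect", "metrics", "stats")

_PREPROC_KEYS = {"discard_n", "detrend", "band_low_hz", "band_high_hz", "confound_columns"}
_STATS_KEYS = {"alpha", "summary_method"}


@dataclass
class RunConfig:
    """Validated pipeline configuration."""

    cohort: CohortParams = field(default_factory=CohortParams)
    stages: tuple[str, ...] = STAGES
    preprocess: dict = field(default_factory=lambda: {"discard_n": 10, "detrend": True, "band_low_hz": 0.01, "band_high_hz": 0.08})
    sparsity_grid: SparsityGrid = field(default_factory=SparsityGrid)
    null_ensemble: NullEnsembleParams = field(default_factory=NullEnsembleParams)
    stats: dict = field(default_factory=lambda: {"alpha": 0.05, "summary_method": "mean"})
    out_dir: str = "wmhnet_run"
    seed: int = 0
    input_dir: str | None = None

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)} (choose from {STAGES})")
        bad = set(self.preprocess) - _PREPROC_KEYS
        if bad:
            raise ValueError(f"unknown preprocess keys: {sorted(bad)}")
        bad = set(self.stats) - _STATS_KEYS
        if bad:
            raise ValueError(f"unknown stats keys: {sorted(bad)}")

    def to_dict(self) -> dict:
        return {
            "cohort": dataclasses.asdict(self.cohort),
            "stages": list(self.stages),
            "preprocess": dict(self.preprocess),
            "sparsity_grid": list(self.sparsity_grid.thresholds),
            "null_ensemble": dataclasses.asdict(self.null_ensemble),
            "stats": dict(self.stats),
            "out_dir": self.out_dir,
            "seed": self.seed,
            "input_dir": self.input_dir,
        }

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs: dict = {}
        if "cohort" in raw:
            cohort_raw = dict(raw.pop("cohort"))
            bad = set(cohort_raw) - {f.name for f in dataclasses.fields(CohortParams)}
            if bad:
                raise ValueError(f"unknown cohort keys: {sorted(bad)}")
            kwargs["cohort"] = CohortParams(**cohort_raw)
        if "stages" in raw:
            kwargs["stages"] = tuple(raw.pop("stages"))
        if "sparsity_grid" in raw:
            kwargs["sparsity_grid"] = SparsityGrid(tuple(raw.pop("sparsity_grid")))
        if "null_ensemble" in raw:
            kwargs["null_ensemble"] = NullEnsembleParams(**raw.pop("null_ensemble"))
        kwargs.update(raw)
        return cls(**kwargs)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return RunConfig.from_dict(raw)


@dataclass(frozen=True)
class ReportBundle:
    """Paths to every artifact a run produced, plus run metadata."""

    out_dir: Path
    tables: dict[str, Path]
    config_hash: str
    log_path: Path


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _write_df(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, index=index, lineterminator="\n")


def _load_confounds(cfg: RunConfig, subject_id: str) -> ConfoundSet | None:
    """Confound CSVs are optional external inputs named confounds_<id>.csv."""
    cols = cfg.preprocess.get("confound_columns")
    if not cols or cfg.input_dir is None:
        return None
    path = Path(cfg.input_dir) / f"confounds_{subject_id}.csv"
    if not path.exists():
        return None
    df = pd.read_csv(path)
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"confound file {path} missing columns: {missing}")
    return ConfoundSet(df[list(cols)].to_numpy(dtype=float), tuple(cols))


def run_pipeline(config: RunConfig) -> ReportBundle:
    """Execute the enabled stages in order, writing artifacts under the
    configured output directory.  Any stage failure aborts with the stage
    name and underlying cause.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.config_hash()
    (out / "config.yaml").write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))
    log: dict = {"config_hash": cfg_hash, "stages": {}, "seed": config.seed}
    tables: dict[str, Path] = {}
    enabled = [s for s in STAGES if s in config.stages]

    cohort: list[SubjectRecord] | None = None
    cleaned: dict[str, object] | None = None
    matrices: dict[str, ConnectivityMatrix] | None = None
    summaries = nodal_e = nodal_eloc = None

    def _require_cohort() -> list[SubjectRecord]:
        nonlocal cohort
        if cohort is None:
            if config.input_dir is None:
                raise FileNotFoundError(
                    "simulate disabled and no input_dir with an existing cohort was given"
                )
            cohort = wio.read_cohort(config.input_dir, config.cohort.tr_seconds)
        return cohort

    for stage in enabled:
        t0 = time.perf_counter()
        try:
            if stage == "simulate":
                params = dataclasses.replace(config.cohort, seed=config.seed)
                cohort = generate_cohort(params)
                cohort_dir = out / "cohort"
                write_cohort(cohort, cohort_dir)
                tables["subjects"] = cohort_dir / "subjects.csv"
            elif stage == "preprocess":
                cleaned = {
                    s.subject_id: preprocess_timeseries(
                        s.timeseries,
                        discard_n=int(config.preprocess.get("discard_n", 10)),
                        detrend=bool(config.preprocess.get("detrend", True)),
                        band_low_hz=config.preprocess.get("band_low_hz", 0.01),
                        band_high_hz=config.preprocess.get("band_high_hz", 0.08),
                        confounds=_load_confounds(config, s.subject_id),
                    )
                    for s in _require_cohort()
                }
            elif stage == "connect":
                source = cleaned or {s.subject_id: s.timeseries for s in _require_cohort()}
                matrices = {sid: fisher_z(pearson_matrix(ts)) for sid, ts in source.items()}
                conn_dir = out / "connectivity"
                conn_dir.mkdir(exist_ok=True)
                for sid, z in matrices.items():
                    df = pd.DataFrame(z.values, columns=list(z.node_labels))
                    _write_df(df.round(10), conn_dir / f"z_{sid}.csv")
            elif stage == "metrics":
                if matrices is None:
                    raise RuntimeError("metrics stage requires the connect stage")
                metrics_dir = out / "metrics"
                metrics_dir.mkdir(exist_ok=True)
                summary_rows = {}
                nodal_e_rows = {}
                nodal_eloc_rows = {}
                base_seed = config.null_ensemble.seed or config.seed
                for k, (sid, z) in enumerate(sorted(matrices.items())):
                    nulls = NullEnsembleParams(
                        config.null_ensemble.n_random,
                        config.null_ensemble.swaps_per_edge,
                        int(np.random.SeedSequence([base_seed, k]).generate_state(1)[0]),
                    )
                    gp, np_ = metric_profiles(
                        z, config.sparsity_grid, nulls, config.stats.get("summary_method", "mean")
                    )
                    _write_df(gp.rows.round(10), metrics_dir / f"global_{sid}.csv")
                    nodal_out = pd.concat(
                        {"nodal_e": np_.nodal_e.round(10), "nodal_eloc": np_.nodal_eloc.round(10)}, axis=1
                    )
                    _write_df(nodal_out, metrics_dir / f"nodal_{sid}.csv", index=True)
                    summary_rows[sid] = gp.summary
                    nodal_e_rows[sid] = np_.nodal_e_mean
                    nodal_eloc_rows[sid] = np_.nodal_eloc_mean
                summaries = pd.DataFrame(summary_rows).T[list(GLOBAL_METRICS)]
                nodal_e = pd.DataFrame(nodal_e_rows).T
                nodal_eloc = pd.DataFrame(nodal_eloc_rows).T
                for name, df in (
                    ("global_summaries", summaries),
                    ("nodal_e_means", nodal_e),
                    ("nodal_eloc_means", nodal_eloc),
                ):
                    path = metrics_dir / f"{name}.csv"
                    _write_df(df.round(10).rename_axis("subject_id"), path, index=True)
                    tables[name] = path
            elif stage == "stats":
                if summaries is None:
                    raise RuntimeError("stats stage requires the metrics stage")
                assert cohort is not None
                subj_df = pd.DataFrame(
                    {
                        "subject_id": [s.subject_id for s in cohort],
                        "group": [s.group for s in cohort],
                        "wmh_volume_ml": [s.wmh_volume for s in cohort],
                        "age": [s.age for s in cohort],
                        "sex": [s.sex for s in cohort],
                        "education_years": [s.education for s in cohort],
                        "moca": [s.moca for s in cohort],
                        "mmse": [s.mmse for s in cohort],
                    }
                ).set_index("subject_id")
                results = run_group_analysis(
                    subj_df, summaries, nodal_e, nodal_eloc, alpha=float(config.stats.get("alpha", 0.05))
                )
                stats_dir = out / "stats"
                stats_dir.mkdir(exist_ok=True)
                for key, fname in (
                    ("global", "global_comparisons.csv"),
                    ("nodal", "nodal_comparisons.csv"),
                    ("volume", "volume_correlations.csv"),
                    ("cognition", "cognition_correlations.csv"),
                ):
                    path = stats_dir / fname
                    _write_df(results[key].round(10), path)
                    tables[key] = path
        except Exception as exc:  # noqa: BLE001 - rewrap with stage context
            raise StageError(stage, exc) from exc
        log["stages"][stage] = {"seconds": round(time.perf_counter() - t0, 3)}

    log_path = out / "run_log.json"
    log_path.write_text(json.dumps(log, indent=2, sort_keys=True) + "\n")
    return ReportBundle(out, tables, cfg_hash, log_path)
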