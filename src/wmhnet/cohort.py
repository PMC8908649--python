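"""Seeded synthetic cohorts with the statistical structure the pipeline assumes.

Two severity groups defined by summed white-matter lesion grades; regional
time series drawn from a modular (block) covariance whose within-module
coupling is attenuated in the high-severity group; cognition scores
optionally coupled to a designated node's connectivity strength.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from wmhnet.labels import default_labels
from wmhnet.preprocess import RoiTimeSeries

__all__ = [
    "CohortParams",
    "SubjectRecord",
    "fazekas_group",
    "generate_cohort",
    "write_cohort",
    "module_assignment",
    "SUBJECTS_HEADER",
]

SUBJECTS_HEADER = [
    "subject_id",
    "pvh",
    "dwmh",
    "fazekas_total",
    "group",
    "wmh_volume_ml",
    "age",
    "sex",
    "education_years",
    "moca",
    "mmse",
    "timeseries_file",
]

#: node whose connectivity strength drives the simulated MoCA score
DESIGNATED_NODE = 0

# group medians for the lognormal lesion-volume model (mL)
_WMH_MEDIAN = {"A": 1.31, "B": 7.84}
_WMH_LOG_SD = 0.8
_AGE_MEAN = {"A": 65.0, "B": 69.0}
_AGE_SD = {"A": 5.0, "B": 6.0}
_FEMALE_PROB = 0.69
_MOCA_BASELINE = 24.0
_MMSE_BASELINE = 29.0


def fazekas_group(pvh_grade: int, dwmh_grade: int) -> tuple[int, str | None]:
    """Sum periventricular and deep lesion grades and map to a severity group.

    Totals 1-2 -> group "A", 3-6 -> group "B"; a total of 0 (no lesions)
    returns ``None`` as an explicit ungrouped marker.
    """
    for name, g in (("pvh_grade", pvh_grade), ("dwmh_grade", dwmh_grade)):
        if not isinstance(g, (int, np.integer)) or not 0 <= g <= 3:
            raise ValueError(f"{name} must be an integer in 0..3, got {g!r}")
    total = int(pvh_grade) + int(dwmh_grade)
    if total == 0:
        return 0, None
    return total, "A" if total <= 2 else "B"


@dataclass(frozen=True)
class CohortParams:
    """Generation parameters for a two-group synthetic cohort."""

    n_group_a: int = 64
    n_group_b: int = 46
    n_regions: int = 90
    n_timepoints: int = 200
    tr_seconds: float = 2.0
    n_modules: int = 6
    within_module_r: float = 0.6
    between_module_r: float = 0.1
    group_b_attenuation: float = 0.3
    cognition_effect: float = 0.0
    noise_sd: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_group_a, self.n_group_b) < 0:
            raise ValueError("group sizes must be nonnegative")
        if self.n_regions < 2 or self.n_modules < 1 or self.n_modules > self.n_regions:
            raise ValueError(
                f"invalid n_regions={self.n_regions} / n_modules={self.n_modules}"
            )
        if self.n_timepoints < 3:
            raise ValueError("n_timepoints must be >= 3")
        if self.tr_seconds <= 0 or self.noise_sd <= 0:
            raise ValueError("tr_seconds and noise_sd must be positive")
        if not 0.0 < self.within_module_r < 1.0:
            raise ValueError(f"within_module_r must lie in (0, 1), got {self.within_module_r}")
        if not 0.0 <= self.between_module_r < self.within_module_r:
            raise ValueError(
                "need 0 <= between_module_r < within_module_r, got "
                f"({self.between_module_r}, {self.within_module_r})"
            )
        if not 0.0 <= self.group_b_attenuation < 1.0:
            raise ValueError(f"group_b_attenuation must lie in [0, 1), got {self.group_b_attenuation}")
        attenuated = self.within_module_r * (1.0 - self.group_b_attenuation)
        if attenuated <= self.between_module_r:
            raise ValueError(
                f"attenuated within-module coupling {attenuated:.3f} does not exceed "
                f"between_module_r={self.between_module_r} "
                f"(within_module_r={self.within_module_r}, "
                f"group_b_attenuation={self.group_b_attenuation})"
            )


@dataclass(frozen=True)
class SubjectRecord:
    """One participant: lesion grades, demographics, cognition, time series."""

    subject_id: str
    pvh_grade: int
    dwmh_grade: int
    fazekas_total: int
    group: str
    wmh_volume: float
    age: int
    sex: str
    education: int
    moca: int
    mmse: int
    timeseries: RoiTimeSeries

    def __post_init__(self) -> None:
        total, group = fazekas_group(self.pvh_grade, self.dwmh_grade)
        if total != self.fazekas_total:
            raise ValueError(
                f"fazekas_total={self.fazekas_total} != pvh+dwmh={total} for {self.subject_id}"
            )
        if group != self.group:
            raise ValueError(
                f"group {self.group!r} inconsistent with total {total} for {self.subject_id}"
            )
        if self.wmh_volume <= 0:
            raise ValueError(f"wmh_volume must be positive for {self.subject_id}")
        for name, score in (("moca", self.moca), ("mmse", self.mmse)):
            if not 0 <= score <= 30:
                raise ValueError(f"{name}={score} outside 0..30 for {self.subject_id}")


def module_assignment(n_regions: int, n_modules: int) -> np.ndarray:
    """Near-equal-size module index for each region."""
    return np.concatenate(
        [np.full(len(chunk), m) for m, chunk in enumerate(np.array_split(np.arange(n_regions), n_modules))]
    )


def _block_correlation(params: CohortParams, attenuation: float) -> np.ndarray:
    modules = module_assignment(params.n_regions, params.n_modules)
    same = modules[:, None] == modules[None, :]
    within = params.within_module_r * (1.0 - attenuation)
    corr = np.where(same, within, params.between_module_r)
    np.fill_diagonal(corr, 1.0)
    eigmin = float(np.linalg.eigvalsh(corr).min())
    if eigmin < -1e-10:
        raise ValueError(
            "implied covariance is not positive semi-definite "
            f"(min eigenvalue {eigmin:.3e}; within_module_r={params.within_module_r}, "
            f"between_module_r={params.between_module_r}, attenuation={attenuation})"
        )
    return corr


def _sample_grades(rng: np.random.Generator, group: str) -> tuple[int, int]:
    totals = (1, 2) if group == "A" else (3, 4, 5, 6)
    total = int(rng.choice(totals))
    splits = [(p, total - p) for p in range(4) if 0 <= total - p <= 3]
    return splits[rng.integers(len(splits))]


def _int_score(value: float, upper: int = 30) -> int:
    return int(np.clip(np.round(value), 0, upper))


def generate_cohort(params: CohortParams) -> list[SubjectRecord]:
    """Draw a full cohort; identical parameters and seed give identical output.

    Each subject's time series is zero-mean multivariate normal with the
    group's block correlation.  The simulated MoCA is
    ``baseline + cognition_effect * strength + noise`` where ``strength`` is
    the subject's realized mean correlation between the designated node and
    its module partners (a monotone proxy for that node's efficiency).
    """
    corr = {
        "A": _block_correlation(params, 0.0),
        "B": _block_correlation(params, params.group_b_attenuation),
    }
    chol = {g: np.linalg.cholesky(c + 1e-12 * np.eye(params.n_regions)) for g, c in corr.items()}
    labels = default_labels(params.n_regions)
    modules = module_assignment(params.n_regions, params.n_modules)
    partners = np.nonzero((modules == modules[DESIGNATED_NODE]) & (np.arange(params.n_regions) != DESIGNATED_NODE))[0]

    master = np.random.SeedSequence(params.seed)
    n_total = params.n_group_a + params.n_group_b
    streams = master.spawn(n_total)
    subjects = []
    for idx in range(n_total):
        group = "A" if idx < params.n_group_a else "B"
        rng = np.random.default_rng(streams[idx])
        data = rng.standard_normal((params.n_timepoints, params.n_regions)) @ chol[group].T
        ts = RoiTimeSeries(data, params.tr_seconds, tuple(labels))

        pvh, dwmh = _sample_grades(rng, group)
        total, _ = fazekas_group(pvh, dwmh)
        wmh = float(rng.lognormal(np.log(_WMH_MEDIAN[group]), _WMH_LOG_SD))
        age = int(np.clip(np.round(rng.normal(_AGE_MEAN[group], _AGE_SD[group])), 55, 90))
        sex = "F" if rng.random() < _FEMALE_PROB else "M"
        education = int(np.clip(np.round(rng.normal(9.0, 3.0)), 0, 22))

        if partners.size:
            node = data[:, DESIGNATED_NODE]
            strength = float(
                np.mean(
                    [np.corrcoef(node, data[:, j])[0, 1] for j in partners]
                )
            )
        else:
            strength = 0.0
        moca = _int_score(
            _MOCA_BASELINE + params.cognition_effect * strength + rng.normal(0.0, params.noise_sd)
        )
        mmse = _int_score(_MMSE_BASELINE + rng.normal(0.0, params.noise_sd / 2.0))

        subjects.append(
            SubjectRecord(
                subject_id=f"sub-{idx + 1:03d}",
                pvh_grade=pvh,
                dwmh_grade=dwmh,
                fazekas_total=total,
                group=group,
                wmh_volume=wmh,
                age=age,
                sex=sex,
                education=education,
                moca=moca,
                mmse=mmse,
                timeseries=ts,
            )
        )
    return subjects


def write_cohort(cohort: list[SubjectRecord], directory: str | Path) -> dict[str, Path]:
    """Write one time-series CSV per subject plus a subjects table and the
    node-label list; round-trips losslessly through the pipeline readers.
    """
    directory = Path(directory)
    try:
        directory.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create cohort directory {directory}: {exc}") from exc
    paths: dict[str, Path] = {}
    table_path = directory / "subjects.csv"
    with open(table_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(SUBJECTS_HEADER)
        for s in cohort:
            ts_name = f"ts_{s.subject_id}.csv"
            writer.writerow(
                [
                    s.subject_id,
                    s.pvh_grade,
                    s.dwmh_grade,
                    s.fazekas_total,
                    s.group,
                    repr(s.wmh_volume),
                    s.age,
                    s.sex,
                    s.education,
                    s.moca,
                    s.mmse,
                    ts_name,
                ]
            )
            ts_path = directory / ts_name
            _write_timeseries(s.timeseries, ts_path)
            paths[s.subject_id] = ts_path
    if cohort:
        label_path = directory / "node_labels.txt"
        label_path.write_text("\n".join(cohort[0].timeseries.node_labels) + "\n")
        paths["node_labels"] = label_path
    paths["subjects"] = table_path
    return paths


def _write_timeseries(ts: RoiTimeSeries, path: Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(ts.node_labels)
        for row in ts.data:
            writer.writerow([repr(float(v)) for v in row])
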