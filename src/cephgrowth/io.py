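"""CSV readers/writers, pipeline configuration and the end-to-end pipeline.

File formats (plain text, versioned):

* landmark CSV — ``subject_id, age, landmark, x, y, frame`` with
  ``frame`` ∈ {raw_px, norm_mm}; one row per landmark per present age.
* measurement CSV — ``subject_id, age, measurement, value, kind`` with
  ``kind`` ∈ {coord_x, coord_y, linear, angular}.

Every file written here starts with ``#`` comment lines carrying the
format version, the config hash and the seeds, so any artifact can be
traced back to the exact run that produced it. Readers skip ``#`` lines.
"""

from __future__ import annotations

import csv
import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cephalometrics import MEASUREMENT_COLUMNS, compute_measurement_table
from .errors import ConfigurationError, DataError
from .evaluation import EvaluationReport, age_window_experiment, cross_validate
from .geometry import NORM_MM, RAW_PX, SubjectSeries, interpolate_missing, normalize_coordinates
from .landmarks import INPUT_AGES, LANDMARK_INDEX, LANDMARKS
from .synthetic import AcquisitionConfig, SyntheticConfig, generate_population

logger = logging.getLogger("cephgrowth")

LANDMARK_HEADER = ["subject_id", "age", "landmark", "x", "y", "frame"]
FORMAT_VERSION = 1


def _header_comment(config_hash: str, seeds: dict[str, int]) -> list[str]:
    seed_str = " ".join(f"{k}={v}" for k, v in seeds.items())
    return [
        f"# cephgrowth landmark/measurement file v{FORMAT_VERSION}",
        f"# config_hash={config_hash} {seed_str}",
    ]


def config_hash(obj) -> str:
    """Short stable hash of a config-like object (dataclass or dict).

    The output directory is excluded: it changes where results land, not
    what they are.
    """
    if hasattr(obj, "__dataclass_fields__"):
        obj = asdict(obj)
    obj = {k: v for k, v in obj.items() if k != "out_dir"}
    return hashlib.sha256(json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()[:12]


# ---------------------------------------------------------------------------
# landmark CSV

def write_landmark_csv(
    series_list: list[SubjectSeries],
    path: str | Path,
    *,
    config_hash_value: str = "unspecified",
    seeds: dict[str, int] | None = None,
) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        for line in _header_comment(config_hash_value, seeds or {}):
            fh.write(line + "\n")
        writer = csv.writer(fh)
        writer.writerow(LANDMARK_HEADER)
        for series in series_list:
            for age in series.ages:
                arr = series.observations[age]
                for name in LANDMARKS:
                    x, y = arr[LANDMARK_INDEX[name]]
                    writer.writerow([series.subject_id, age, name, repr(float(x)), repr(float(y)), series.frame])


def read_landmark_csv(path: str | Path) -> list[SubjectSeries]:
    """Read and validate a landmark CSV into subject series.

    Enforces: known landmark names, numeric fields (errors cite the line
    number), no duplicate (subject, age, landmark) rows, exactly 26
    landmarks per present age, and one coordinate frame per subject.
    Interior ages absent from the file become ``missing_ages``.
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"landmark file not found: {path}")
    cells: dict[str, dict[int, dict[str, tuple[float, float]]]] = {}
    frames: dict[str, str] = {}
    with path.open() as fh:
        lineno = 0
        header_seen = False
        for raw in fh:
            lineno += 1
            if raw.startswith("#") or not raw.strip():
                continue
            row = next(csv.reader([raw]))
            if not header_seen:
                if [c.strip() for c in row] != LANDMARK_HEADER:
                    raise DataError(
                        f"{path}:{lineno}: expected header {LANDMARK_HEADER}, got {row}"
                    )
                header_seen = True
                continue
            if len(row) != 6:
                raise DataError(f"{path}:{lineno}: expected 6 fields, got {len(row)}")
            sid, age_s, landmark, x_s, y_s, frame = [c.strip() for c in row]
            if landmark not in LANDMARK_INDEX:
                raise DataError(
                    f"{path}:{lineno}: unknown landmark {landmark!r}; valid names: {list(LANDMARKS)}"
                )
            try:
                age = int(age_s)
                x, y = float(x_s), float(y_s)
            except ValueError:
                raise DataError(f"{path}:{lineno}: malformed numeric field in row {row}") from None
            if frame not in (RAW_PX, NORM_MM):
                raise DataError(f"{path}:{lineno}: unknown frame {frame!r}")
            if sid in frames and frames[sid] != frame:
                raise DataError(
                    f"{path}:{lineno}: subject {sid} mixes frames {frames[sid]!r} and {frame!r}"
                )
            frames[sid] = frame
            by_age = cells.setdefault(sid, {})
            lm = by_age.setdefault(age, {})
            if landmark in lm:
                raise DataError(f"{path}:{lineno}: duplicate row for ({sid}, {age}, {landmark})")
            lm[landmark] = (x, y)
    if not header_seen:
        raise DataError(f"{path}: empty landmark file")

    series_list = []
    for sid, by_age in cells.items():
        obs: dict[int, np.ndarray] = {}
        for age, lm in by_age.items():
            missing_names = [n for n in LANDMARKS if n not in lm]
            if missing_names:
                raise DataError(
                    f"subject {sid}, age {age}: incomplete landmark set; missing {missing_names}"
                )
            obs[age] = np.array([lm[n] for n in LANDMARKS], dtype=float)
        ages = sorted(obs)
        gaps = frozenset(range(ages[0], ages[-1] + 1)) - frozenset(ages)
        series_list.append(
            SubjectSeries(subject_id=sid, observations=obs, frame=frames[sid], missing_ages=gaps)
        )
    return sorted(series_list, key=lambda s: s.subject_id)


# ---------------------------------------------------------------------------
# measurement CSV

def write_measurement_csv(
    measurements: pd.DataFrame,
    path: str | Path,
    *,
    config_hash_value: str = "unspecified",
    seeds: dict[str, int] | None = None,
) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for line in _header_comment(config_hash_value, seeds or {}):
            fh.write(line + "\n")
        measurements.to_csv(fh, index=False)


def read_measurement_csv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise DataError(f"measurement file not found: {path}")
    df = pd.read_csv(path, comment="#")
    if list(df.columns) != list(MEASUREMENT_COLUMNS):
        raise DataError(
            f"{path}: expected columns {list(MEASUREMENT_COLUMNS)}, got {list(df.columns)}"
        )
    return df


# ---------------------------------------------------------------------------
# pipeline configuration

@dataclass
class PipelineConfig:
    """Configuration of a full generate → normalize → measure → evaluate run.

    All randomness flows from three named seeds: ``data_seed`` (synthetic
    cohort), ``fold_seed`` (cross-validation partition) and ``train_seed``
    (model training / tuning). No wall-clock entropy anywhere.
    """

    out_dir: str = "cephgrowth_out"
    landmark_csv: str | None = None  # input data; None -> generate synthetically
    px_per_mm: float = 10.0
    layout: str = "separate"
    method: str = "LASSO"
    model_options: dict = field(default_factory=dict)
    folds: int = 10
    data_seed: int = 0
    fold_seed: int = 0
    train_seed: int = 0
    age_window: tuple[int, ...] = INPUT_AGES
    families: tuple[str, ...] = ("coord", "linear", "angular")
    include_ns: bool = True
    pooled: bool = False
    clinical_convexity: bool = False
    interpolate: str = "after_normalize"  # or "before_normalize"
    synthetic: dict = field(default_factory=dict)  # SyntheticConfig overrides

    def __post_init__(self) -> None:
        if self.interpolate not in ("after_normalize", "before_normalize"):
            raise ConfigurationError(
                f"interpolate must be 'after_normalize' or 'before_normalize', got {self.interpolate!r}"
            )
        if self.folds < 1:
            raise ConfigurationError("folds must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ConfigurationError(f"{path}: config must be a mapping")
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"{path}: unknown config keys {sorted(unknown)}")
        if "age_window" in raw:
            raw["age_window"] = tuple(raw["age_window"])
        if "families" in raw:
            raw["families"] = tuple(raw["families"])
        return cls(**raw)

    def synthetic_config(self) -> SyntheticConfig:
        overrides = dict(self.synthetic)
        known = {f.name for f in fields(SyntheticConfig)}
        unknown = set(overrides) - known
        if unknown:
            raise ConfigurationError(f"unknown synthetic config keys {sorted(unknown)}")
        if "acquisition" in overrides:
            overrides["acquisition"] = AcquisitionConfig(**overrides["acquisition"])
        if "ages" in overrides:
            overrides["ages"] = tuple(overrides["ages"])
        overrides.setdefault("seed", self.data_seed)
        overrides.setdefault(
            "acquisition", AcquisitionConfig(px_per_mm=self.px_per_mm)
        )
        return SyntheticConfig(**overrides)


def prepare_measurements(
    series_list: list[SubjectSeries], config: PipelineConfig
) -> pd.DataFrame:
    """Normalize, interpolate (in the configured order) and measure."""
    out = []
    for series in series_list:
        if config.interpolate == "before_normalize":
            series = interpolate_missing(series)
        if series.frame == RAW_PX:
            series = normalize_coordinates(series, px_per_mm=config.px_per_mm)
        if series.missing_ages:
            series = interpolate_missing(series)
        out.append(series)
    return compute_measurement_table(out, clinical_convexity=config.clinical_convexity)


def run_pipeline(config: PipelineConfig) -> EvaluationReport:
    """End-to-end run; writes artifacts under ``config.out_dir``.

    Stages: load-or-generate landmarks → normalize + interpolate → measure
    → cross-validated evaluation. Outputs (landmark, measurement and
    report CSVs) carry the config hash and seeds; two runs with the same
    config are byte-identical.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    chash = config_hash(config)
    seeds = {
        "data_seed": config.data_seed,
        "fold_seed": config.fold_seed,
        "train_seed": config.train_seed,
    }

    stage = "generate/load"
    try:
        if config.landmark_csv is None:
            population = generate_population(config.synthetic_config())
            write_landmark_csv(
                population, out_dir / "landmarks_raw.csv",
                config_hash_value=chash, seeds=seeds,
            )
        else:
            population = read_landmark_csv(config.landmark_csv)
        logger.info("stage %s: %d subjects", stage, len(population))

        stage = "normalize/measure"
        measurements = prepare_measurements(population, config)
        write_measurement_csv(
            measurements, out_dir / "measurements.csv", config_hash_value=chash, seeds=seeds
        )
        logger.info("stage %s: %d rows", stage, len(measurements))

        stage = "evaluate"
        report = cross_validate(
            measurements, config.method,
            age_window=config.age_window, k=config.folds,
            seed=config.fold_seed, train_seed=config.train_seed,
            families=config.families, include_ns=config.include_ns,
            pooled=config.pooled, model_options=config.model_options,
            layout=config.layout,
        )
        header = _header_comment(chash, seeds)
        for name, df in (
            ("report_per_fold", report.per_fold),
            ("report_per_target", report.per_target),
            ("report_family_summary", report.family_summary),
        ):
            with (out_dir / f"{name}.csv").open("w") as fh:
                fh.write("\n".join(header) + "\n")
                df.to_csv(fh, index=False)
        logger.info("stage %s: method=%s families=%s", stage, config.method, config.families)
        return report
    except Exception as exc:
        raise type(exc)(f"pipeline stage {stage!r} failed: {exc}") from exc


def run_age_windows(config: PipelineConfig) -> pd.DataFrame:
    """The age-window experiment under a pipeline config; writes a CSV."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if config.landmark_csv is None:
        population = generate_population(config.synthetic_config())
    else:
        population = read_landmark_csv(config.landmark_csv)
    measurements = prepare_measurements(population, config)
    curve = age_window_experiment(
        measurements, config.method, seed=config.fold_seed,
        k=config.folds, train_seed=config.train_seed,
        model_options=config.model_options,
    )
    header = _header_comment(config_hash(config), {"fold_seed": config.fold_seed})
    with (out_dir / "age_window_curve.csv").open("w") as fh:
        fh.write("\n".join(header) + "\n")
        curve.to_csv(fh, index=False)
    return curve
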