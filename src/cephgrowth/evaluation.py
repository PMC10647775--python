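"""Cross-validated evaluation: k-fold RMSE, accuracy and the age-window study.

The evaluation design mirrors the study: subjects are partitioned into k
(default 10) near-equal random folds; each fold is held out in turn while
the model — with all of its tuning nested inside the training subjects —
is fit on the rest and predicts the held-out subjects' target-age values.
Per-target RMSE is computed per fold and averaged across folds (a pooled
mode that aggregates all residuals first is available).

For a landmark target the squared error of one subject is the squared
Euclidean distance between predicted and actual 2-D points, giving one
mm-valued error per landmark. Family averages are arithmetic means of the
member targets' fold-averaged RMSEs. Accuracy = 100·(1 − RMSE/mean-actual)
is reported for the linear and angular families, whose values are positive
by construction; signed landmark coordinates admit no such relative error
and get none.

The sella is excluded from landmark-error reporting (it is the origin of
the normalized frame by construction).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from collections.abc import Callable, Sequence

import numpy as np
import pandas as pd

from . import models as _models
from .datasets import FAMILIES, SupervisedDataset, build_supervised_dataset, feature_name
from .errors import ConfigurationError, DataError
from .landmarks import INPUT_AGES, LANDMARKS, TARGET_AGE

METHODS = ("MRA", "LASSO", "RBFN", "MLP", "GBDT", "MEAN")


def make_folds(subject_ids: Sequence[str], k: int = 10, seed: int = 0) -> list[list[str]]:
    """Random partition of subjects into k folds with sizes differing by ≤ 1.

    59 subjects at k=10 give nine folds of 6 and one of 5. Deterministic
    given the seed.
    """
    ids = list(subject_ids)
    if k < 1 or k > len(ids):
        raise ConfigurationError(f"k must be in [1, {len(ids)}], got {k}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    return [[ids[i] for i in chunk] for chunk in np.array_split(perm, k)]


def rmse(predicted: np.ndarray, actual: np.ndarray, target_kind: str = "scalar") -> float:
    """Root-mean-square error; for ``target_kind="point"`` the per-subject
    squared difference is the squared Euclidean distance between paired
    2-D points."""
    predicted = np.asarray(predicted, dtype=float)
    actual = np.asarray(actual, dtype=float)
    if predicted.shape != actual.shape:
        raise DataError(f"shape mismatch: {predicted.shape} vs {actual.shape}")
    if predicted.size == 0:
        raise DataError("rmse of empty input is undefined")
    diff = predicted - actual
    if target_kind == "point":
        if diff.ndim != 2 or diff.shape[1] != 2:
            raise DataError("point targets require (n, 2) arrays")
        return float(np.sqrt((diff**2).sum(axis=1).mean()))
    if target_kind != "scalar":
        raise ConfigurationError(f"target_kind must be 'scalar' or 'point', got {target_kind!r}")
    return float(np.sqrt((diff**2).mean()))


def accuracy(average_rmse: float, mean_actual: float) -> float:
    """Relative-error summary: 100 × (1 − RMSE / mean of actual values)."""
    if not mean_actual > 0:
        raise DataError(f"accuracy denominator must be positive, got {mean_actual}")
    return 100.0 * (1.0 - average_rmse / mean_actual)


@dataclass
class EvaluationReport:
    """Cross-validation results for one method and one age window."""

    method: str
    age_window: tuple[int, ...]
    fold_seed: int
    fold_sizes: list[int]
    per_fold: pd.DataFrame  # family, target, fold, rmse
    per_target: pd.DataFrame  # family, target, rmse, accuracy
    family_summary: pd.DataFrame  # family, avg_rmse, accuracy
    constant_targets: list[tuple[int, str]] = field(default_factory=list)

    def family_average(self, family: str) -> float:
        row = self.family_summary[self.family_summary["family"] == family]
        if row.empty:
            raise DataError(f"family {family!r} not in report")
        return float(row["avg_rmse"].iloc[0])

    def family_accuracy(self, family: str) -> float:
        row = self.family_summary[self.family_summary["family"] == family]
        if row.empty:
            raise DataError(f"family {family!r} not in report")
        return float(row["accuracy"].iloc[0])


def _scalar_targets(dataset: SupervisedDataset, families: Sequence[str]) -> list[tuple[str, str, str]]:
    """(scalar target column name, family, report target) triples.

    Coordinate columns of the sella are dropped (constant origin).
    """
    out = []
    for name in dataset.target_names:
        head, _age = name.rsplit("@", 1)
        measurement, kind = head.rsplit("|", 1)
        family = {"coord_x": "coord", "coord_y": "coord", "linear": "linear", "angular": "angular"}[kind]
        if family not in families:
            continue
        if family == "coord" and measurement == "sella":
            continue
        out.append((name, family, measurement))
    return out


def _fit_and_predict(
    method: str,
    train: SupervisedDataset,
    test: SupervisedDataset,
    scalar_names: list[str],
    train_seed: int,
    options: dict,
) -> np.ndarray:
    """Predictions (n_test × len(scalar_names)) for one fold."""
    cols = {t: j for j, t in enumerate(train.target_names)}
    pred = np.empty((test.n, len(scalar_names)))
    if method == "MEAN":
        for j, t in enumerate(scalar_names):
            pred[:, j] = train.Y[:, cols[t]].mean()
    elif method in ("MRA", "LASSO", "GBDT"):
        for j, t in enumerate(scalar_names):
            if method == "MRA":
                model = _models.fit_mra_stepwise(train, t, **options)
            elif method == "LASSO":
                model = _models.fit_lasso(train, t, seed=train_seed, **options)
            else:
                model = _models.fit_gbdt(train, t, seed=train_seed, **options)
            pred[:, j] = model.predict(test.X)
    elif method in ("RBFN", "MLP"):
        fit = _models.fit_rbfn if method == "RBFN" else _models.fit_mlp
        model = fit(train, targets=scalar_names, seed=train_seed, **options)
        pred[:] = model.predict(test.X)
    else:
        raise ConfigurationError(f"unknown method {method!r}; valid: {METHODS}")
    return pred


def cross_validate(
    measurements: pd.DataFrame,
    method: str,
    *,
    age_window: Sequence[int] = INPUT_AGES,
    k: int = 10,
    seed: int = 0,
    train_seed: int = 0,
    families: Sequence[str] = FAMILIES,
    include_ns: bool = True,
    pooled: bool = False,
    model_options: dict | None = None,
    layout: str = "separate",
    fit_hook: Callable[[int, list[str], list[str]], None] | None = None,
) -> EvaluationReport:
    """k-fold cross-validation of one method over the chosen target families.

    All model tuning (λ search, hyperparameter search) happens inside each
    fold's training subjects only; held-out target-age values never enter
    fitting. ``fit_hook(fold, train_ids, test_ids)`` is called before each
    fold's fit (instrumentation for leak tests). ``include_ns=False`` drops
    the N–S distance from the linear report (12-row mode).
    """
    if method not in METHODS:
        raise ConfigurationError(f"unknown method {method!r}; valid: {METHODS}")
    options = dict(model_options or {})
    dataset = build_supervised_dataset(
        measurements, age_window=age_window, target_age=TARGET_AGE,
        families=families, layout=layout,
    )
    scalar = _scalar_targets(dataset, families)
    if not include_ns:
        scalar = [s for s in scalar if not (s[1] == "linear" and s[2] == "N-S")]
    scalar_names = [s[0] for s in scalar]
    col_of = {t: j for j, t in enumerate(dataset.target_names)}

    folds = make_folds(dataset.subject_ids, k=k, seed=seed)
    row_of = {sid: i for i, sid in enumerate(dataset.subject_ids)}

    # report targets: landmarks pool their x and y columns into one entry
    report_targets: list[tuple[str, str]] = []  # (family, report name)
    for _, family, meas in scalar:
        if (family, meas) not in report_targets:
            report_targets.append((family, meas))

    per_fold_rows = []
    residuals: dict[tuple[str, str], list[np.ndarray]] = {t: [] for t in report_targets}
    constant_targets: list[tuple[int, str]] = []

    for f, test_ids in enumerate(folds):
        test_idx = [row_of[s] for s in test_ids]
        train_idx = [i for i in range(dataset.n) if dataset.subject_ids[i] not in set(test_ids)]
        train = dataset.subset_subjects(train_idx)
        test = dataset.subset_subjects(test_idx)
        if fit_hook is not None:
            fit_hook(f, list(train.subject_ids), list(test_ids))
        for t in scalar_names:
            if _models._is_constant(train.Y[:, col_of[t]]):
                constant_targets.append((f, t))
        pred = _fit_and_predict(method, train, test, scalar_names, train_seed, options)
        j_of = {t: j for j, t in enumerate(scalar_names)}
        for family, meas in report_targets:
            if family == "coord":
                px = pred[:, j_of[feature_name(meas, "coord_x", TARGET_AGE)]]
                py = pred[:, j_of[feature_name(meas, "coord_y", TARGET_AGE)]]
                ax = test.Y[:, col_of[feature_name(meas, "coord_x", TARGET_AGE)]]
                ay = test.Y[:, col_of[feature_name(meas, "coord_y", TARGET_AGE)]]
                err = rmse(np.column_stack([px, py]), np.column_stack([ax, ay]), "point")
                sq = (px - ax) ** 2 + (py - ay) ** 2
            else:
                kind = "linear" if family == "linear" else "angular"
                t = feature_name(meas, kind, TARGET_AGE)
                err = rmse(pred[:, j_of[t]], test.Y[:, col_of[t]])
                sq = (pred[:, j_of[t]] - test.Y[:, col_of[t]]) ** 2
            residuals[(family, meas)].append(sq)
            per_fold_rows.append((family, meas, f, err))

    per_fold = pd.DataFrame(per_fold_rows, columns=["family", "target", "fold", "rmse"])

    # fold-averaged (default) or pooled per-target RMSE
    rows = []
    for family, meas in report_targets:
        if pooled:
            all_sq = np.concatenate(residuals[(family, meas)])
            avg = float(np.sqrt(all_sq.mean()))
        else:
            sub = per_fold[(per_fold["family"] == family) & (per_fold["target"] == meas)]
            avg = float(sub["rmse"].mean())
        rows.append((family, meas, avg))
    per_target = pd.DataFrame(rows, columns=["family", "target", "rmse"])

    # per-target accuracy where the actual mean is positive
    acc_col = []
    for family, meas, avg in per_target.itertuples(index=False):
        if family in ("linear", "angular"):
            kind = "linear" if family == "linear" else "angular"
            actual = dataset.Y[:, col_of[feature_name(meas, kind, TARGET_AGE)]]
            acc_col.append(accuracy(avg, float(actual.mean())) if actual.mean() > 0 else np.nan)
        else:
            acc_col.append(np.nan)
    per_target["accuracy"] = acc_col

    fam_rows = []
    for family in [f for f in FAMILIES if f in set(per_target["family"])]:
        sub = per_target[per_target["family"] == family]
        avg = float(sub["rmse"].mean())
        if family in ("linear", "angular"):
            kind = "linear" if family == "linear" else "angular"
            names = sub["target"].tolist()
            actual = np.concatenate(
                [dataset.Y[:, col_of[feature_name(m, kind, TARGET_AGE)]] for m in names]
            )
            fam_acc = accuracy(avg, float(actual.mean()))
        else:
            fam_acc = np.nan
        fam_rows.append((family, avg, fam_acc))
    family_summary = pd.DataFrame(fam_rows, columns=["family", "avg_rmse", "accuracy"])

    return EvaluationReport(
        method=method,
        age_window=tuple(age_window),
        fold_seed=seed,
        fold_sizes=[len(fold) for fold in folds],
        per_fold=per_fold,
        per_target=per_target,
        family_summary=family_summary,
        constant_targets=constant_targets,
    )


def age_window_experiment(
    measurements: pd.DataFrame,
    method: str = "LASSO",
    seed: int = 0,
    *,
    k: int = 10,
    train_seed: int = 0,
    families: Sequence[str] = ("coord",),
    model_options: dict | None = None,
    windows: Sequence[int] = (6, 7, 8, 9, 10, 11, 12),
) -> pd.DataFrame:
    """Prediction error as the input age window widens: {6}, {6–7}, …, {6–12}.

    Runs the cross-validation once per window (same fold seed throughout)
    and reports the overall average landmark error per window, ordered by
    window end age. The widest window reproduces a direct
    :func:`cross_validate` call exactly.
    """
    rows = []
    for end in windows:
        report = cross_validate(
            measurements, method,
            age_window=tuple(range(6, end + 1)), k=k, seed=seed, train_seed=train_seed,
            families=families, model_options=model_options,
        )
        rows.append(
            {"window_start": 6, "window_end": end,
             "avg_rmse": report.family_average(families[0])}
        )
    return pd.DataFrame(rows).sort_values("window_end", ignore_index=True)
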