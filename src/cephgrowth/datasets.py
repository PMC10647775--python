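"""Assembly of supervised design matrices from measurement tables.

Features are the measurement items observed over the input age window
(default ages 6–12); targets are the same items at the target age
(default 13). Feature/target names carry (item, kind, age) provenance as
``"<measurement>|<kind>@<age>"``, e.g. ``"nasion|coord_x@9"`` or
``"SNA|angular@13"``.

Two item-accounting layouts exist for the coordinate block. ``"separate"``
counts x and y as distinct items (26×2 + 13 + 17 = 82 per age);
``"compact56"`` counts each landmark point once (26 + 13 + 17 = 56 per
age). A 2-D point can only enter a regression through its two coordinates,
so both layouts produce the *same* design matrix — the flag changes item
bookkeeping and report granularity only.
"""

from __future__ import annotations

from dataclasses import dataclass
from collections.abc import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError
from .landmarks import INPUT_AGES, TARGET_AGE

FAMILIES = ("coord", "linear", "angular")
_KIND_TO_FAMILY = {"coord_x": "coord", "coord_y": "coord", "linear": "linear", "angular": "angular"}


@dataclass
class SupervisedDataset:
    """Design matrix of age-window features and target-age outcomes.

    ``X`` is (subjects × features), ``Y`` (subjects × targets), both in
    natural units (mm / degrees); rows are aligned with ``subject_ids``.
    """

    X: np.ndarray
    Y: np.ndarray
    feature_names: list[str]
    target_names: list[str]
    subject_ids: list[str]
    age_window: tuple[int, ...]
    layout: str = "separate"

    @property
    def n(self) -> int:
        return self.X.shape[0]

    def target_column(self, name: str) -> np.ndarray:
        try:
            return self.Y[:, self.target_names.index(name)]
        except ValueError:
            raise DataError(f"unknown target {name!r}") from None

    def subset_subjects(self, idx: Sequence[int]) -> "SupervisedDataset":
        idx = np.asarray(idx)
        return SupervisedDataset(
            X=self.X[idx],
            Y=self.Y[idx],
            feature_names=self.feature_names,
            target_names=self.target_names,
            subject_ids=[self.subject_ids[i] for i in idx],
            age_window=self.age_window,
            layout=self.layout,
        )


def feature_name(measurement: str, kind: str, age: int) -> str:
    return f"{measurement}|{kind}@{age}"


def parse_feature_name(name: str) -> tuple[str, str, int]:
    head, age = name.rsplit("@", 1)
    measurement, kind = head.rsplit("|", 1)
    return measurement, kind, int(age)


def build_supervised_dataset(
    measurements: pd.DataFrame,
    *,
    age_window: Sequence[int] = INPUT_AGES,
    target_age: int = TARGET_AGE,
    families: Sequence[str] = FAMILIES,
    layout: str = "separate",
) -> SupervisedDataset:
    """Pivot a tidy measurement table into an (X, Y) supervised dataset.

    ``families`` selects which measurement kinds appear as *targets*;
    features always use every measurement item over the window (the study
    design feeds all items to every model). Raises on missing cells —
    interpolation must precede assembly.
    """
    if layout not in ("separate", "compact56"):
        raise ConfigurationError(f"layout must be 'separate' or 'compact56', got {layout!r}")
    ages = tuple(int(a) for a in age_window)
    bad = [f for f in families if f not in FAMILIES]
    if bad:
        raise ConfigurationError(f"unknown families {bad}; valid: {FAMILIES}")
    df = measurements.copy()
    df["family"] = df["kind"].map(_KIND_TO_FAMILY)
    if df["family"].isna().any():
        raise DataError(f"unknown measurement kind in table: {sorted(df[df.family.isna()]['kind'].unique())}")
    df["column"] = [
        feature_name(m, k, a) for m, k, a in zip(df["measurement"], df["kind"], df["age"])
    ]

    wide = df.pivot_table(index="subject_id", columns="column", values="value", aggfunc="first")
    present_ages = sorted(df["age"].unique())
    for a in (*ages, target_age):
        if a not in present_ages:
            raise DataError(f"age {a} absent from measurement table")
    # column order: by age, then by first appearance in the table
    order = df.drop_duplicates("column")[["measurement", "kind", "age", "column", "family"]]

    feat_cols = order[order["age"].isin(ages)].sort_values("age", kind="stable")["column"].tolist()
    targ = order[(order["age"] == target_age) & order["family"].isin(families)]
    targ_cols = targ["column"].tolist()

    sub = wide.loc[:, feat_cols + [c for c in targ_cols if c not in feat_cols]]
    if sub.isna().any().any():
        missing = sub.columns[sub.isna().any()][:3].tolist()
        raise DataError(f"measurement table has missing cells (e.g. {missing}); interpolate first")

    return SupervisedDataset(
        X=wide[feat_cols].to_numpy(dtype=float),
        Y=wide[targ_cols].to_numpy(dtype=float),
        feature_names=feat_cols,
        target_names=targ_cols,
        subject_ids=list(wide.index),
        age_window=ages,
        layout=layout,
    )
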