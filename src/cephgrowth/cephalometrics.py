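"""Linear and angular cephalometric parameters and the per-age measurement table.

A linear parameter is the Euclidean distance (mm) between two named
landmarks; an angular parameter is the unsigned angle in [0, 180] degrees
between the direction vectors of two landmark-defined segments, taken in
the listed landmark order via the arccosine of their normalized dot
product. No sign convention is applied: an angle such as ANB therefore
equals |SNA − SNB| only when the A and B points lie on the same side of
the S–N line. ``clinical_convexity=True`` switches Convexity and A–B plane
to the clinical 180°-complement reading.

The measurement table is tidy/long: one row per (subject, age, measurement)
with ``kind`` in {coord_x, coord_y, linear, angular} — 26 coordinate pairs
+ 13 linear + 17 angular items per subject-age.
"""

from __future__ import annotations

import math
from collections.abc import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import DataError, DegenerateGeometryError
from .geometry import NORM_MM, SubjectSeries
from .landmarks import ANGULAR_PARAMS, LANDMARKS, LINEAR_PARAMS

MEASUREMENT_COLUMNS = ("subject_id", "age", "measurement", "value", "kind")


def _get(landmarks: Mapping[str, np.ndarray], name: str) -> np.ndarray:
    try:
        p = np.asarray(landmarks[name], dtype=float)
    except KeyError:
        raise DataError(f"landmark {name!r} missing from landmark map") from None
    if p.shape != (2,) or not np.all(np.isfinite(p)):
        raise DataError(f"landmark {name!r} is not a finite 2-D point: {p}")
    return p


def linear_parameter(landmarks: Mapping[str, np.ndarray], name: str) -> float:
    """Distance in mm between the two landmarks defining ``name``."""
    try:
        a, b = LINEAR_PARAMS[name]
    except KeyError:
        raise DataError(
            f"unknown linear parameter {name!r}; valid: {sorted(LINEAR_PARAMS)}"
        ) from None
    pa, pb = _get(landmarks, a), _get(landmarks, b)
    return float(np.hypot(*(pa - pb)))


def angular_parameter(
    landmarks: Mapping[str, np.ndarray], name: str, *, clinical_convexity: bool = False
) -> float:
    """Unsigned angle in degrees between the two segments defining ``name``."""
    try:
        (a1, a2), (b1, b2) = ANGULAR_PARAMS[name]
    except KeyError:
        raise DataError(
            f"unknown angular parameter {name!r}; valid: {sorted(ANGULAR_PARAMS)}"
        ) from None
    u = _get(landmarks, a2) - _get(landmarks, a1)
    v = _get(landmarks, b2) - _get(landmarks, b1)
    nu, nv = np.hypot(*u), np.hypot(*v)
    if nu == 0.0 or nv == 0.0:
        raise DegenerateGeometryError(
            f"angular parameter {name!r}: zero-length segment "
            f"({a1}->{a2} if nu==0 else {b1}->{b2})"
        )
    cos = float(np.dot(u, v) / (nu * nv))
    angle = math.degrees(math.acos(min(1.0, max(-1.0, cos))))
    if clinical_convexity and name in ("Convexity", "A-B_plane"):
        angle = 180.0 - angle
    return angle


def compute_measurement_table(
    series_list: SubjectSeries | Iterable[SubjectSeries],
    *,
    clinical_convexity: bool = False,
) -> pd.DataFrame:
    """All measurements for every subject and age, as a tidy DataFrame.

    Requires normalized (``norm_mm``), gap-free series (interpolate first).
    Errors from individual measurements propagate with subject/age context.
    """
    if isinstance(series_list, SubjectSeries):
        series_list = [series_list]
    rows: list[tuple] = []
    for series in series_list:
        if series.frame != NORM_MM:
            raise DataError(
                f"subject {series.subject_id}: measurement table requires normalized "
                f"coordinates (frame=norm_mm), got {series.frame!r}"
            )
        if series.missing_ages:
            raise DataError(
                f"subject {series.subject_id}: ages {sorted(series.missing_ages)} missing; "
                "interpolate before measuring"
            )
        for age in series.ages:
            lm = series.landmarks_at(age)
            for name in LANDMARKS:
                x, y = lm[name]
                rows.append((series.subject_id, age, name, float(x), "coord_x"))
                rows.append((series.subject_id, age, name, float(y), "coord_y"))
            try:
                for name in LINEAR_PARAMS:
                    rows.append((series.subject_id, age, name, linear_parameter(lm, name), "linear"))
                for name in ANGULAR_PARAMS:
                    rows.append(
                        (
                            series.subject_id,
                            age,
                            name,
                            angular_parameter(lm, name, clinical_convexity=clinical_convexity),
                            "angular",
                        )
                    )
            except (DataError, DegenerateGeometryError) as exc:
                raise type(exc)(
                    f"subject {series.subject_id}, age {age}: {exc}"
                ) from exc
    return pd.DataFrame(rows, columns=MEASUREMENT_COLUMNS)
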