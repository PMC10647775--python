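"""Series container, missing-year interpolation and coordinate normalization.

Serial films of one subject are digitized per image, so raw landmark
coordinates differ in position, inclination and pixel scale from film to
film. Normalization places every film in a common anatomical frame:

1. translate so the sella is the origin (0, 0);
2. rotate about the origin so the nasion lies on the positive x-axis,
   i.e. the S–N line (anterior cranial base) becomes the x-axis;
3. divide by the dataset-wide pixels-per-millimetre constant.

Each age is normalized independently from its own sella→nasion vector.
The frame is right-handed with superior = positive y; inputs are assumed
mirror-consistent (no reflection detection — scanned films share chirality).

Occasional missing interior years are filled per landmark per coordinate by
linear interpolation in age between the nearest observed years on either
side, matching the annual sampling of the series.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ConfigurationError, DataError, DegenerateGeometryError
from .landmarks import LANDMARK_INDEX, LANDMARKS, REQUIRED_AGES

RAW_PX = "raw_px"
NORM_MM = "norm_mm"
_S = LANDMARK_INDEX["sella"]
_N = LANDMARK_INDEX["nasion"]


@dataclass
class SubjectSeries:
    """One subject's longitudinal landmark record.

    ``observations`` maps age (integer years) to a (26, 2) float array in the
    canonical :data:`~cephgrowth.landmarks.LANDMARKS` order. ``frame`` is
    ``"raw_px"`` (per-film pixel coordinates) or ``"norm_mm"`` (sella-origin,
    S–N-aligned millimetres). ``missing_ages`` records ages absent from the
    record; ``interpolated_ages`` records ages filled by interpolation.
    """

    subject_id: str
    observations: dict[int, np.ndarray]
    frame: str = RAW_PX
    missing_ages: frozenset[int] = frozenset()
    interpolated_ages: frozenset[int] = frozenset()

    def __post_init__(self) -> None:
        if self.frame not in (RAW_PX, NORM_MM):
            raise ConfigurationError(f"frame must be raw_px or norm_mm, got {self.frame!r}")
        if self.missing_ages & REQUIRED_AGES:
            raise DataError(
                f"subject {self.subject_id}: ages {sorted(self.missing_ages & REQUIRED_AGES)} "
                "are required and cannot be missing"
            )
        for age, pts in self.observations.items():
            arr = np.asarray(pts, dtype=float)
            if arr.shape != (len(LANDMARKS), 2):
                raise DataError(
                    f"subject {self.subject_id}, age {age}: expected "
                    f"({len(LANDMARKS)}, 2) coordinates, got {arr.shape}"
                )
            if not np.all(np.isfinite(arr)):
                raise DataError(f"subject {self.subject_id}, age {age}: non-finite coordinate")
            self.observations[age] = arr

    @property
    def ages(self) -> list[int]:
        return sorted(self.observations)

    def point(self, age: int, landmark: str) -> np.ndarray:
        """Coordinates of one landmark at one age, shape (2,)."""
        return self.observations[age][LANDMARK_INDEX[landmark]]

    def landmarks_at(self, age: int) -> dict[str, np.ndarray]:
        arr = self.observations[age]
        return {name: arr[i] for name, i in LANDMARK_INDEX.items()}


def interpolate_missing(series: SubjectSeries) -> SubjectSeries:
    """Fill missing interior ages by per-coordinate linear interpolation.

    Each missing age is filled, landmark by landmark and coordinate by
    coordinate, by evaluating the line through the nearest observed ages
    below and above. Originally observed ages are copied bit-exactly.
    Filled ages are recorded in ``interpolated_ages``.
    """
    if not series.missing_ages:
        return replace(
            series,
            observations={a: v.copy() for a, v in series.observations.items()},
        )
    present = series.ages
    filled: dict[int, np.ndarray] = {a: v.copy() for a, v in series.observations.items()}
    for age in sorted(series.missing_ages):
        lower = [a for a in present if a < age]
        upper = [a for a in present if a > age]
        if not lower or not upper:
            raise DataError(
                f"subject {series.subject_id}: missing age {age} has no observed "
                "age on one side; cannot interpolate"
            )
        a0, a1 = max(lower), min(upper)
        w = (age - a0) / (a1 - a0)
        filled[age] = (1.0 - w) * series.observations[a0] + w * series.observations[a1]
    return replace(
        series,
        observations=filled,
        missing_ages=frozenset(),
        interpolated_ages=series.interpolated_ages | series.missing_ages,
    )


def normalize_coordinates(series: SubjectSeries, px_per_mm: float = 1.0) -> SubjectSeries:
    """Normalize raw pixel coordinates into the sella-origin S–N-aligned mm frame.

    Per age: translate so sella = (0, 0); rotate about the origin so the
    nasion lands on the positive x-axis; divide by ``px_per_mm``. All
    pairwise inter-landmark distances are preserved up to the scale factor.
    The same conversion constant applies to every film.
    """
    if series.frame != RAW_PX:
        raise ConfigurationError(
            f"normalize_coordinates expects frame=raw_px, got {series.frame!r}"
        )
    if not px_per_mm > 0:
        raise ConfigurationError(f"px_per_mm must be positive, got {px_per_mm}")
    out: dict[int, np.ndarray] = {}
    for age, pts in series.observations.items():
        centered = pts - pts[_S]
        v = centered[_N]
        norm = math.hypot(v[0], v[1])
        if norm == 0.0:
            raise DegenerateGeometryError(
                f"subject {series.subject_id}, age {age}: sella and nasion coincide"
            )
        c, s = v[0] / norm, v[1] / norm
        # rotation by -angle(v): aligns sella->nasion with +x
        rot = np.array([[c, s], [-s, c]])
        out[age] = (centered @ rot.T) / px_per_mm
    return replace(series, observations=out, frame=NORM_MM)
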