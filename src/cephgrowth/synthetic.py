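"""Synthetic longitudinal cephalometric populations and regression benchmarks.

The study cohort this package is built for — annual lateral cephalograms of
59 untreated children, ages 6 through 13 — is not publicly deposited, so
this module generates populations with the same statistical structure:

* a shared 26-landmark facial template with per-landmark mean annual
  growth displacements;
* subject-level variation as a random growth-rate multiplier (random
  slopes around the population mean trajectory), optionally with a
  quadratic-in-age term;
* landmark-placement noise (the dominant measurement error when tracing
  films by hand);
* a per-film rigid acquisition transform (rotation + translation) plus
  the dataset-wide pixel scale, which the geometry module's normalization
  is designed to undo;
* occasional missing interior years (ages 7–11 only; every subject has
  films at 6, 12 and 13).

True millimetre positions follow the linear random-slope model

    p(subject, age) = template + age * growth * multiplier[subject] + noise,

with ``template`` the age-0 intercept of the model. A quadratic term
(``quadratic`` config field, off by default) adds
``quadratic * age**2 * growth * multiplier``.

RNG discipline: four independent seeded streams are derived from the config
seed — ``[seed, 0]`` subject multipliers, ``[seed, 1]`` placement noise,
``[seed, 2]`` acquisition transforms, ``[seed, 3]`` missingness Bernoulli
draws (a ``(n_subjects, n_interior_ages)`` uniform matrix compared to
``missing_rate``). Everything is reproducible bitwise from the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ConfigurationError
from .geometry import RAW_PX, SubjectSeries
from .landmarks import AGES, LANDMARK_INDEX, LANDMARKS, REQUIRED_AGES

# Hand-built, anatomically plausible template (mm): intercept of the linear
# growth model, sella at origin, nasion anterior on +x, superior = +y.
LANDMARK_TEMPLATE: dict[str, tuple[float, float]] = {
    "sella": (0.0, 0.0),
    "porion": (-38.0, -8.0),
    "basion": (-28.0, -32.0),
    "nasion": (62.0, 0.0),
    "orbitale": (45.0, -14.0),
    "A_point": (55.0, -47.0),
    "pogonion": (48.0, -84.0),
    "B_point": (49.0, -72.0),
    "PNS": (12.0, -37.0),
    "ANS": (57.0, -40.0),
    "R1": (-5.0, -52.0),
    "R3": (-15.0, -38.0),
    "articulare": (-25.0, -35.0),
    "menton": (41.0, -91.0),
    "mx1_incisor_superius": (50.0, -62.0),
    "mx1_root": (52.0, -48.0),
    "md1_incisor_inferius": (48.0, -64.0),
    "md1_root": (46.0, -76.0),
    "occlusal_plane": (30.0, -60.0),
    "mx6_distal": (25.0, -55.0),
    "mx6_root": (27.0, -47.0),
    "md6_distal": (24.0, -62.0),
    "md6_root": (25.0, -70.0),
    "gnathion": (45.0, -89.0),
    "gonion": (-15.0, -70.0),
    "condylion": (-27.0, -28.0),
}

# Mean annual displacement (mm/yr): anterior cranial base lengthens along
# S-N; maxillary and mandibular structures drift downward and forward, the
# ramus/condyle region backward, giving the familiar down-and-forward
# facial growth pattern.
GROWTH_VECTORS: dict[str, tuple[float, float]] = {
    "sella": (0.0, 0.0),
    "porion": (-0.3, -0.2),
    "basion": (-0.4, -0.5),
    "nasion": (0.8, 0.0),
    "orbitale": (0.5, -0.3),
    "A_point": (0.6, -0.9),
    "pogonion": (0.6, -1.6),
    "B_point": (0.5, -1.4),
    "PNS": (0.2, -0.6),
    "ANS": (0.7, -0.7),
    "R1": (0.0, -0.9),
    "R3": (-0.2, -0.7),
    "articulare": (-0.4, -0.6),
    "menton": (0.4, -1.7),
    "mx1_incisor_superius": (0.5, -1.1),
    "mx1_root": (0.5, -0.9),
    "md1_incisor_inferius": (0.5, -1.2),
    "md1_root": (0.5, -1.3),
    "occlusal_plane": (0.4, -1.1),
    "mx6_distal": (0.5, -1.0),
    "mx6_root": (0.5, -0.9),
    "md6_distal": (0.5, -1.2),
    "md6_root": (0.5, -1.3),
    "gnathion": (0.5, -1.7),
    "gonion": (-0.3, -1.3),
    "condylion": (-0.4, -0.5),
}

INTERIOR_AGES: tuple[int, ...] = tuple(a for a in AGES if a not in REQUIRED_AGES)


@dataclass(frozen=True)
class AcquisitionConfig:
    """Per-film digitization transform ranges.

    Each film gets rotation ~ U(−rotation_deg, rotation_deg) and translation
    ~ U(−translation_px, translation_px) per axis; ``px_per_mm`` is a single
    dataset-wide scale (all films scanned at the same resolution), so
    normalization with the same constant recovers millimetres exactly.
    """

    rotation_deg: float = 5.0
    translation_px: float = 200.0
    px_per_mm: float = 10.0

    def validate(self) -> None:
        if self.rotation_deg < 0:
            raise ConfigurationError("acquisition.rotation_deg must be >= 0")
        if self.translation_px < 0:
            raise ConfigurationError("acquisition.translation_px must be >= 0")
        if not self.px_per_mm > 0:
            raise ConfigurationError("acquisition.px_per_mm must be > 0")


def _as_array(table: dict[str, tuple[float, float]], what: str) -> np.ndarray:
    if set(table) != set(LANDMARKS):
        missing = sorted(set(LANDMARKS) - set(table))
        extra = sorted(set(table) - set(LANDMARKS))
        raise ConfigurationError(
            f"{what} must contain exactly the 26 landmark names; "
            f"missing={missing}, unexpected={extra}"
        )
    return np.array([table[name] for name in LANDMARKS], dtype=float)


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-condition parameters of the synthetic cohort.

    Defaults mirror the study design: 59 subjects, annual films at ages
    6–13, and a missing-film rate matching roughly four missing interior
    films out of 59 × 5 subject-age cells.
    """

    n_subjects: int = 59
    ages: tuple[int, ...] = AGES
    landmark_template: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(LANDMARK_TEMPLATE)
    )
    growth_vectors: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(GROWTH_VECTORS)
    )
    subject_sd: float = 0.1
    noise_sd: float = 0.5
    acquisition: AcquisitionConfig = AcquisitionConfig()
    missing_rate: float = 4.0 / (59 * 5)
    quadratic: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise ConfigurationError("n_subjects must be >= 1")
        ages = tuple(self.ages)
        if list(ages) != list(range(min(ages), max(ages) + 1)):
            raise ConfigurationError("ages must be contiguous integer years")
        if not REQUIRED_AGES <= set(ages):
            raise ConfigurationError("ages must include 6, 12 and 13")
        if self.subject_sd < 0:
            raise ConfigurationError("subject_sd must be >= 0")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if not 0 <= self.missing_rate < 1:
            raise ConfigurationError("missing_rate must be in [0, 1)")
        self.acquisition.validate()
        _as_array(self.landmark_template, "landmark_template")
        _as_array(self.growth_vectors, "growth_vectors")


def proportional_growth(rate: float = 0.02) -> dict[str, tuple[float, float]]:
    """Growth vectors proportional to the template (uniform facial scaling).

    With these vectors every landmark moves along its ray from the sella at
    a shared relative rate, so the whole face scales by ``1 + age*rate*m``:
    coordinates and distances are exactly affine in any single age's value
    and all angles are constant over age and across subjects. This is the
    idealized fully-linear growth regime used for exact-recoverability
    checks; the default per-landmark vectors are the realistic setting.
    """
    return {
        name: (rate * x, rate * y) for name, (x, y) in LANDMARK_TEMPLATE.items()
    }


def true_positions(config: SyntheticConfig, multipliers: np.ndarray) -> dict[int, np.ndarray]:
    """Noise-free mm positions per age: arrays of shape (n_subjects, 26, 2)."""
    template = _as_array(config.landmark_template, "landmark_template")
    growth = _as_array(config.growth_vectors, "growth_vectors")
    out = {}
    for age in config.ages:
        coeff = age + config.quadratic * age * age
        out[age] = template[None] + coeff * multipliers[:, None, None] * growth[None]
    return out


def missingness_draws(config: SyntheticConfig) -> np.ndarray:
    """Boolean (n_subjects, len(INTERIOR_AGES)) missing-film indicator.

    Drawn from the dedicated ``[seed, 3]`` stream so callers can reproduce
    the exact Bernoulli draws independently of the rest of the simulation.
    """
    interior = [a for a in config.ages if a not in REQUIRED_AGES]
    rng = np.random.default_rng([config.seed, 3])
    return rng.random((config.n_subjects, len(interior))) < config.missing_rate


def subject_multipliers(config: SyntheticConfig) -> np.ndarray:
    """Per-subject growth-rate multipliers, mean 1, SD ``subject_sd``."""
    rng = np.random.default_rng([config.seed, 0])
    return 1.0 + config.subject_sd * rng.standard_normal(config.n_subjects)


def generate_population(
    config: SyntheticConfig, *, return_truth: bool = False
) -> list[SubjectSeries] | tuple[list[SubjectSeries], dict]:
    """Simulate a cohort of raw-pixel longitudinal landmark series.

    For each subject and each non-missing age, the true mm positions are
    template + age·growth·multiplier (+ optional quadratic term), perturbed
    by iid Gaussian placement noise, then pushed through the per-film
    acquisition transform (rotation, pixel scale, translation). Ages 6, 12
    and 13 are never missing. Deterministic given ``config.seed``.

    With ``return_truth=True`` also returns a dict with the noise-free mm
    positions (``truth[age][i]``), the subject multipliers and the missing
    mask, for ground-truth comparisons in tests.
    """
    config.validate()
    interior = [a for a in config.ages if a not in REQUIRED_AGES]
    mult = subject_multipliers(config)
    truth = true_positions(config, mult)
    missing = missingness_draws(config)
    rng_noise = np.random.default_rng([config.seed, 1])
    rng_acq = np.random.default_rng([config.seed, 2])
    acq = config.acquisition

    population: list[SubjectSeries] = []
    for i in range(config.n_subjects):
        miss = {age for j, age in enumerate(interior) if missing[i, j]}
        obs: dict[int, np.ndarray] = {}
        for age in config.ages:
            # draw the full RNG stream even for skipped films so the stream
            # layout does not depend on the missingness pattern
            noise = rng_noise.normal(0.0, config.noise_sd or 0.0, size=(len(LANDMARKS), 2))
            theta = math.radians(rng_acq.uniform(-acq.rotation_deg, acq.rotation_deg))
            shift = rng_acq.uniform(-acq.translation_px, acq.translation_px, size=2)
            if age in miss:
                continue
            mm = truth[age][i] + (noise if config.noise_sd > 0 else 0.0)
            c, s = math.cos(theta), math.sin(theta)
            rot = np.array([[c, -s], [s, c]])
            obs[age] = (mm * acq.px_per_mm) @ rot.T + shift
        population.append(
            SubjectSeries(
                subject_id=f"S{i:03d}",
                observations=obs,
                frame=RAW_PX,
                missing_ages=frozenset(miss),
            )
        )
    if return_truth:
        return population, {"positions": truth, "multipliers": mult, "missing": missing}
    return population


@dataclass(frozen=True)
class SparseLinearBenchmark:
    """A sparse linear-regression instance for selector-recovery tests.

    ``y = X @ true_coefficients + noise`` with iid standard-normal design
    and at most p/4 nonzero coefficients; reproducible from the seed.
    """

    X: np.ndarray
    y: np.ndarray
    true_coefficients: np.ndarray
    noise_sd: float
    seed: int

    @property
    def support(self) -> np.ndarray:
        return np.flatnonzero(self.true_coefficients)

    def draw(self, n: int, seed: int) -> tuple[np.ndarray, np.ndarray]:
        """An independent sample of n rows from the same linear model."""
        rng = np.random.default_rng([seed, 1])
        X = rng.standard_normal((n, self.X.shape[1]))
        y = X @ self.true_coefficients + rng.normal(0.0, self.noise_sd, size=n)
        return X, y


def make_sparse_linear_benchmark(
    n: int, p: int, k_nonzero: int, noise_sd: float, seed: int
) -> SparseLinearBenchmark:
    """Standard-normal X, exactly ``k_nonzero`` nonzero coefficients.

    Nonzero coefficients have magnitude in [1, 3] with random sign, placed
    at the first ``k_nonzero`` positions of a seeded permutation.
    """
    if n < 3:
        raise ConfigurationError("n must be >= 3")
    if not 0 <= k_nonzero <= p:
        raise ConfigurationError(f"k_nonzero must be in [0, p]; got {k_nonzero} > p={p}")
    if p > 10_000:
        raise ConfigurationError("p capped at 10000")
    rng = np.random.default_rng([seed, 0])
    beta = np.zeros(p)
    idx = rng.permutation(p)[:k_nonzero]
    beta[idx] = rng.uniform(1.0, 3.0, size=k_nonzero) * rng.choice([-1.0, 1.0], size=k_nonzero)
    X = rng.standard_normal((n, p))
    y = X @ beta + (rng.normal(0.0, noise_sd, size=n) if noise_sd > 0 else 0.0)
    return SparseLinearBenchmark(X=X, y=y, true_coefficients=beta, noise_sd=noise_sd, seed=seed)
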