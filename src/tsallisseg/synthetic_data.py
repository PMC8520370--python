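"""Seeded synthetic phantoms and ADC cohorts for end-to-end testing.

Real lesion images for this clinical setting are not publicly deposited, so
every downstream module is exercised on synthetic substrates that carry the
structure the method assumes:

* piecewise-constant lesion-on-background rasters in the four lesion
  morphologies of the reference cohort's vocabulary (round, irregular,
  nodular, patchy), under additive Gaussian or Rician (MRI magnitude) noise,
  with the noiseless lesion support as ground truth;
* per-patient ADC samples drawn from two normal distributions parameterized
  by the reference cohort's group means and SDs (tumor 0.62 +/- 0.095,
  contralateral 0.73 +/- 0.038, in 1e-3 mm^2/s, n = 10 per group);
* randomized cohort tables honoring a specification of marginal counts.

Every generator is a pure function of its spec including the seed: the same
spec yields bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cohort import (
    ENHANCEMENTS,
    LOCATIONS,
    REFERENCE_ADC_GROUPS,
    T1_SIGNALS,
    T2_SIGNALS,
    DWI_SIGNALS,
    HISTOLOGIES,
    MRS_LIP,
    SEXES,
    LesionRecord,
    PatientRecord,
)
from .errors import SpecError
from .image_model import BinaryMask

__all__ = [
    "LesionSpec",
    "PhantomSpec",
    "ADCSimSpec",
    "REFERENCE_MARGINALS",
    "generate_phantom",
    "simulate_adc_cohort",
    "generate_cohort_table",
]

MORPHOLOGIES = ("round", "irregular", "nodular", "patchy")


@dataclass
class LesionSpec:
    """One synthetic lesion: morphology, center, radius/extent, and contrast."""

    morphology: str = "round"
    center: tuple = (64, 64)
    size: float = 20.0
    contrast: float = 80.0

    def __post_init__(self) -> None:
        if self.morphology not in MORPHOLOGIES:
            raise SpecError(f"unknown morphology {self.morphology!r}")
        if self.contrast == 0:
            raise SpecError("lesion contrast must be nonzero")
        if self.size <= 0:
            raise SpecError("lesion size must be positive")


@dataclass
class PhantomSpec:
    """Piecewise-constant phantom: background + lesions + noise."""

    shape: tuple = (128, 128)
    background_level: float = 60.0
    lesions: list = field(default_factory=lambda: [LesionSpec()])
    noise_model: str = "gaussian"
    sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_model not in ("gaussian", "rician"):
            raise SpecError(f"unknown noise model {self.noise_model!r}")
        if self.sigma < 0:
            raise SpecError("sigma must be >= 0")
        for les in self.lesions:
            if len(les.center) != len(self.shape):
                raise SpecError("lesion center rank must match phantom shape")
            for c, n in zip(les.center, self.shape):
                if c - les.size < 0 or c + les.size > n - 1:
                    raise SpecError(f"lesion at {les.center} (size {les.size}) exceeds bounds")


@dataclass
class ADCSimSpec:
    """Two-group normal ADC simulation, defaulting to the reference cohort's parameters."""

    n_tumor: int = REFERENCE_ADC_GROUPS["tumor"]["n"]
    n_contralateral: int = REFERENCE_ADC_GROUPS["contralateral"]["n"]
    mean_tumor: float = REFERENCE_ADC_GROUPS["tumor"]["mean"]
    sd_tumor: float = REFERENCE_ADC_GROUPS["tumor"]["sd"]
    mean_contralateral: float = REFERENCE_ADC_GROUPS["contralateral"]["mean"]
    sd_contralateral: float = REFERENCE_ADC_GROUPS["contralateral"]["sd"]
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tumor < 1 or self.n_contralateral < 1:
            raise SpecError("sample sizes must be >= 1")
        if self.sd_tumor <= 0 or self.sd_contralateral <= 0:
            raise SpecError("SDs must be positive")


# ---------------------------------------------------------------------------
# Phantoms


def _radial_support(shape, center, radius_fn) -> np.ndarray:
    """Voxels whose distance from center is below a direction-dependent radius."""
    grids = np.meshgrid(*[np.arange(n, dtype=np.float64) for n in shape], indexing="ij")
    deltas = [g - c for g, c in zip(grids, center)]
    r = np.sqrt(sum(d**2 for d in deltas))
    return r <= radius_fn(deltas, r)


def _ball(shape, center, radius) -> np.ndarray:
    return _radial_support(shape, center, lambda deltas, r: radius)


def _irregular(shape, center, radius, rng) -> np.ndarray:
    """Ball deformed by a smooth seeded radial perturbation (Fourier modes in angle)."""
    amps = rng.uniform(0.05, 0.18, size=3)
    phases = rng.uniform(0, 2 * np.pi, size=3)
    modes = rng.integers(2, 6, size=3)

    def radius_fn(deltas, r):
        theta = np.arctan2(deltas[-1], deltas[-2])
        pert = sum(a * np.cos(m * theta + ph) for a, ph, m in zip(amps, phases, modes))
        if len(deltas) == 3:
            phi = np.arctan2(np.hypot(deltas[1], deltas[2]), deltas[0])
            pert = pert + amps[0] * np.cos(2 * phi + phases[0])
        return radius * (1.0 + pert)

    return _radial_support(shape, center, radius_fn)


def _nodular(shape, center, radius, rng) -> np.ndarray:
    """Cluster of 2-4 small balls scattered around the center."""
    n_nodes = int(rng.integers(2, 5))
    support = np.zeros(shape, dtype=bool)
    for _ in range(n_nodes):
        offset = rng.uniform(-0.5 * radius, 0.5 * radius, size=len(shape))
        sub_r = rng.uniform(0.35, 0.55) * radius
        c = tuple(np.clip(np.asarray(center) + offset, sub_r, np.asarray(shape) - 1 - sub_r))
        support |= _ball(shape, c, sub_r)
    return support


def _patchy(shape, center, radius, rng) -> np.ndarray:
    """Ragged patch: union of several overlapping anisotropic blobs."""
    n_blobs = int(rng.integers(4, 8))
    support = np.zeros(shape, dtype=bool)
    for _ in range(n_blobs):
        offset = rng.uniform(-0.6 * radius, 0.6 * radius, size=len(shape))
        c = np.asarray(center) + offset
        semi = rng.uniform(0.25, 0.5, size=len(shape)) * radius
        c = np.clip(c, semi, np.asarray(shape) - 1 - semi)
        grids = np.meshgrid(*[np.arange(n, dtype=np.float64) for n in shape], indexing="ij")
        d2 = sum(((g - ci) / si) ** 2 for g, ci, si in zip(grids, c, semi))
        support |= d2 <= 1.0
    return support


def generate_phantom(spec: PhantomSpec) -> tuple[np.ndarray, BinaryMask]:
    """Render a phantom image and its noiseless ground-truth lesion mask.

    The image is the background level plus each lesion's contrast over its
    support, then noise: additive Gaussian, or Rician as the magnitude of
    the signal plus a complex Gaussian — the correct MRI magnitude-noise
    model, which biases dark regions upward.
    """
    rng = np.random.default_rng(spec.seed)
    image = np.full(spec.shape, spec.background_level, dtype=np.float64)
    truth = np.zeros(spec.shape, dtype=bool)
    for les in spec.lesions:
        if les.morphology == "round":
            support = _ball(spec.shape, les.center, les.size)
        elif les.morphology == "irregular":
            support = _irregular(spec.shape, les.center, les.size, rng)
        elif les.morphology == "nodular":
            support = _nodular(spec.shape, les.center, les.size, rng)
        else:
            support = _patchy(spec.shape, les.center, les.size, rng)
        image[support] += les.contrast
        truth |= support
    if spec.sigma > 0:
        if spec.noise_model == "gaussian":
            image = image + rng.normal(0.0, spec.sigma, size=spec.shape)
        else:
            re = image + rng.normal(0.0, spec.sigma, size=spec.shape)
            im = rng.normal(0.0, spec.sigma, size=spec.shape)
            image = np.hypot(re, im)
    return image, BinaryMask(truth.astype(np.uint8))


# ---------------------------------------------------------------------------
# ADC cohort simulation


def simulate_adc_cohort(spec: ADCSimSpec) -> tuple[np.ndarray, np.ndarray]:
    """Draw (tumor, contralateral) ADC samples from the two group normals.

    Draws are truncated at zero by redrawing — negligible at the default
    parameters but avoids a point mass that clipping would create.
    """
    rng = np.random.default_rng(spec.seed)

    def draw(n, mean, sd):
        out = rng.normal(mean, sd, size=n)
        while np.any(out <= 0):
            bad = out <= 0
            out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        return out

    tumor = draw(spec.n_tumor, spec.mean_tumor, spec.sd_tumor)
    contra = draw(spec.n_contralateral, spec.mean_contralateral, spec.sd_contralateral)
    return tumor, contra


# ---------------------------------------------------------------------------
# Randomized cohort tables

#: Marginal counts of the packaged reference cohort, usable as a template
#: specification for :func:`generate_cohort_table`.
REFERENCE_MARGINALS = {
    "n_patients": 15,
    "n_lesions": 25,
    "multiplicity": {"single": 10, "multiple": 5},
    "sex": {"M": 11, "F": 4},
    "histology": {"DLBCL": 12, "Burkitt": 3},
    "dwi_signal": {"homogeneous_high": 5, "uneven_high": 2, "intermediate": 3, "not_done": 5},
    "mrs_lip_peak": {"present": 2, "absent": 2, "not_done": 11},
    "location": {
        "cerebellar_hemisphere": 13,
        "cerebellar_vermis": 2,
        "midbrain": 2,
        "fourth_ventricle": 1,
        "cerebellopontine_angle": 2,
        "supratentorial": 5,
    },
    "t1_signal": {"low": 12, "slightly_low": 10, "intermediate": 3},
    "t2_signal": {"slightly_high": 20, "intermediate": 3, "mixed_slightly_high": 2},
    "enhancement": {"mass_nodular": 17, "striped": 4, "patchy": 3, "ring": 1},
    "composition": {"solid": 24, "cystic": 1},
    "n_with_signs": 8,
    "n_with_edema": 12,
}

_PATIENT_CATS = {
    "multiplicity": ("single", "multiple"),
    "sex": SEXES,
    "histology": HISTOLOGIES,
    "dwi_signal": DWI_SIGNALS,
    "mrs_lip_peak": MRS_LIP,
}
_LESION_CATS = {
    "location": LOCATIONS,
    "t1_signal": T1_SIGNALS,
    "t2_signal": T2_SIGNALS,
    "enhancement": ENHANCEMENTS,
    "composition": ("solid", "cystic"),
}


def _expand(counts: dict, total: int, name: str, rng) -> list:
    if sum(counts.values()) != total:
        raise SpecError(f"{name} counts sum to {sum(counts.values())}, expected {total}")
    values = [v for v, c in counts.items() for _ in range(c)]
    rng.shuffle(values)
    return values


def generate_cohort_table(
    n_patients: int, marginals: dict, seed: int = 0
) -> tuple[list[PatientRecord], list[LesionRecord]]:
    """Build a randomized cohort whose marginal counts match ``marginals`` exactly.

    The specification maps each categorical field to its per-category
    counts (see :data:`REFERENCE_MARGINALS`).  Attribute-to-record
    assignment is shuffled by the seed; only the marginals are guaranteed.
    Single-lesion patients get exactly one lesion and every multiple-lesion
    patient at least two, so the specification must satisfy
    ``n_lesions >= n_single + 2 * n_multiple``.
    """
    rng = np.random.default_rng(seed)
    if n_patients != marginals.get("n_patients", n_patients):
        raise SpecError("n_patients disagrees with marginals")
    n_lesions = marginals["n_lesions"]
    if n_patients == 0:
        if n_lesions != 0:
            raise SpecError("lesions require patients")
        return [], []

    patient_vals = {
        key: _expand(marginals[key], n_patients, key, rng) for key in _PATIENT_CATS
    }
    lesion_vals = {key: _expand(marginals[key], n_lesions, key, rng) for key in _LESION_CATS}

    n_single = marginals["multiplicity"]["single"]
    n_multiple = marginals["multiplicity"]["multiple"]
    if n_lesions < n_single + 2 * n_multiple:
        raise SpecError("n_lesions too small for the requested multiplicity split")
    if n_multiple == 0 and n_lesions != n_single:
        raise SpecError("without multiple-lesion patients, n_lesions must equal n_single")

    patients = [
        PatientRecord(
            patient_id=f"S{i + 1:03d}",
            age=float(rng.integers(6, 79)),
            sex=patient_vals["sex"][i],
            multiplicity=patient_vals["multiplicity"][i],
            dwi_signal=patient_vals["dwi_signal"][i],
            mrs_lip_peak=patient_vals["mrs_lip_peak"][i],
            histology=patient_vals["histology"][i],
        )
        for i in range(n_patients)
    ]

    singles = [p.patient_id for p in patients if p.multiplicity == "single"]
    multiples = [p.patient_id for p in patients if p.multiplicity == "multiple"]
    lesion_counts = {pid: 1 for pid in singles}
    lesion_counts.update({pid: 2 for pid in multiples})
    spare = n_lesions - sum(lesion_counts.values())
    for _ in range(spare):
        if not multiples:
            raise SpecError("leftover lesions but no multiple-lesion patients")
        lesion_counts[multiples[int(rng.integers(len(multiples)))]] += 1
    owners = [pid for pid, c in lesion_counts.items() for _ in range(c)]

    sign_flags = np.zeros(n_lesions, dtype=bool)
    sign_flags[: marginals["n_with_signs"]] = True
    rng.shuffle(sign_flags)
    edema_flags = np.zeros(n_lesions, dtype=bool)
    edema_flags[: marginals["n_with_edema"]] = True
    rng.shuffle(edema_flags)

    lesions = [
        LesionRecord(
            patient_id=owners[k],
            location=lesion_vals["location"][k],
            t1_signal=lesion_vals["t1_signal"][k],
            t2_signal=lesion_vals["t2_signal"][k],
            enhancement=lesion_vals["enhancement"][k],
            composition=lesion_vals["composition"][k],
            signs=frozenset(("sharp_angle", "umbilical")) if sign_flags[k] else frozenset(),
            peritumoral_edema=bool(edema_flags[k]),
        )
        for k in range(n_lesions)
    ]
    return patients, lesions
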