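"""Cohort records, ADC computation, and the Mann-Whitney group comparison.

This module carries the clinical quantification layer around the segmentation
core: per-patient / per-lesion annotation records for a posterior-fossa PCNSL
(primary central nervous system lymphoma) case series, summary tabulations
over those records, ADC (apparent diffusion coefficient) maps from paired
diffusion-weighted acquisitions, and an exact Mann-Whitney U test comparing
tumor against contralateral-parenchyma ADC values.

ADC is reported throughout in units of 1e-3 mm^2/s, the conventional clinical
scale on which restricted diffusion in densely cellular lymphoma reads as a
low value (around 0.6) against normal parenchyma (around 0.7-0.8).
"""

from __future__ import annotations

import itertools
import json
import math
from collections import Counter
from dataclasses import asdict, dataclass, field
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ContractError, StatisticsError, ValidationError
from .image_model import BinaryMask

__all__ = [
    "LOCATIONS",
    "ENHANCEMENTS",
    "REFERENCE_ADC_GROUPS",
    "LesionRecord",
    "PatientRecord",
    "CohortSummary",
    "MannWhitneyResult",
    "compute_adc",
    "roi_statistics",
    "mann_whitney_u",
    "reference_cohort",
    "summarize",
    "adc_group_test",
    "read_cohort_tsv",
    "write_cohort_tsv",
]

LOCATIONS = (
    "cerebellar_hemisphere",
    "cerebellar_vermis",
    "midbrain",
    "fourth_ventricle",
    "cerebellopontine_angle",
    "supratentorial",
)
T1_SIGNALS = ("low", "slightly_low", "intermediate")
T2_SIGNALS = ("slightly_high", "intermediate", "mixed_slightly_high")
ENHANCEMENTS = ("mass_nodular", "striped", "patchy", "ring")
COMPOSITIONS = ("solid", "cystic")
SIGNS = ("sharp_angle", "umbilical")
SEXES = ("M", "F")
MULTIPLICITIES = ("single", "multiple")
DWI_SIGNALS = ("homogeneous_high", "uneven_high", "intermediate", "not_done")
MRS_LIP = ("present", "absent", "not_done")
HISTOLOGIES = ("DLBCL", "Burkitt")

#: Group-level ADC summaries (n, mean, sd) in 1e-3 mm^2/s for the reference
#: posterior-fossa PCNSL cohort: solid tumor vs contralateral parenchyma.
REFERENCE_ADC_GROUPS = {
    "tumor": {"n": 10, "mean": 0.62, "sd": 0.095},
    "contralateral": {"n": 10, "mean": 0.73, "sd": 0.038},
}


def _check_enum(value, allowed, name: str) -> None:
    if value not in allowed:
        raise ValidationError(f"{name}={value!r} not in {allowed}")


@dataclass
class LesionRecord:
    """One lesion's imaging annotations."""

    patient_id: str
    location: str
    t1_signal: str
    t2_signal: str
    enhancement: str
    composition: str
    signs: frozenset = field(default_factory=frozenset)
    peritumoral_edema: bool = False

    def __post_init__(self) -> None:
        if not self.patient_id:
            raise ValidationError("patient_id must be non-empty")
        _check_enum(self.location, LOCATIONS, "location")
        _check_enum(self.t1_signal, T1_SIGNALS, "t1_signal")
        _check_enum(self.t2_signal, T2_SIGNALS, "t2_signal")
        _check_enum(self.enhancement, ENHANCEMENTS, "enhancement")
        _check_enum(self.composition, COMPOSITIONS, "composition")
        self.signs = frozenset(self.signs)
        for s in self.signs:
            _check_enum(s, SIGNS, "sign")


@dataclass
class PatientRecord:
    """One patient's demographics, DWI/MRS findings, and optional ADC values."""

    patient_id: str
    age: float
    sex: str
    multiplicity: str
    dwi_signal: str = "not_done"
    adc_tumor: float | None = None
    adc_contralateral: float | None = None
    mrs_lip_peak: str = "not_done"
    histology: str = "DLBCL"

    def __post_init__(self) -> None:
        if not self.patient_id:
            raise ValidationError("patient_id must be non-empty")
        _check_enum(self.sex, SEXES, "sex")
        _check_enum(self.multiplicity, MULTIPLICITIES, "multiplicity")
        _check_enum(self.dwi_signal, DWI_SIGNALS, "dwi_signal")
        _check_enum(self.mrs_lip_peak, MRS_LIP, "mrs_lip_peak")
        _check_enum(self.histology, HISTOLOGIES, "histology")
        for attr in ("adc_tumor", "adc_contralateral"):
            v = getattr(self, attr)
            if v is not None and not v > 0:
                raise ValidationError(f"{attr} must be positive when present, got {v}")


@dataclass
class CohortSummary:
    """Marginal counts over a cohort plus per-group ADC summaries."""

    n_patients: int
    n_lesions: int
    multiplicity: dict
    location: dict
    enhancement: dict
    composition: dict
    t1_signal: dict
    t2_signal: dict
    n_with_signs: int
    n_with_edema: int
    dwi_signal: dict
    mrs_lip_peak: dict
    histology: dict
    sex: dict
    adc: dict

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(asdict(self), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


@dataclass
class MannWhitneyResult:
    """Mann-Whitney U statistic (for the first sample) and two-sided p-value."""

    U: float
    p_two_sided: float
    method: str
    n1: int
    n2: int

    def __post_init__(self) -> None:
        if not 0 <= self.U <= self.n1 * self.n2:
            raise ContractError("U outside [0, n1*n2]")
        if not 0 < self.p_two_sided <= 1:
            raise ContractError("p must lie in (0, 1]")

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(asdict(self), indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


# ---------------------------------------------------------------------------
# ADC computation


def compute_adc(b_low_img, b_high_img, b_low: float = 0.0, b_high: float = 1000.0) -> np.ndarray:
    """Two-point mono-exponential ADC map in 1e-3 mm^2/s.

    ADC = ln(S_low / S_high) / (b_high - b_low), the standard clinical
    estimate from a paired acquisition (conventionally b = 0 and
    1000 s/mm^2).  Voxels with non-positive signal in either input are
    invalid and returned as NaN so that ROI statistics exclude them;
    negative ADC values (S_high > S_low, e.g. from noise) are physically
    suspect but returned as computed.
    """
    s_low = np.asarray(getattr(b_low_img, "data", b_low_img), dtype=np.float64)
    s_high = np.asarray(getattr(b_high_img, "data", b_high_img), dtype=np.float64)
    if s_low.shape != s_high.shape:
        raise ContractError(f"shapes differ: {s_low.shape} vs {s_high.shape}")
    if not b_high > b_low >= 0:
        raise ContractError(f"need b_high > b_low >= 0, got {b_low}, {b_high}")
    valid = (s_low > 0) & (s_high > 0)
    adc = np.full(s_low.shape, np.nan)
    adc[valid] = np.log(s_low[valid] / s_high[valid]) / (b_high - b_low) * 1e3
    return adc


def roi_statistics(adc_map: np.ndarray, mask: BinaryMask) -> tuple[int, float, float]:
    """(n, mean, sample SD) of valid ADC voxels inside the mask.

    NaN voxels (invalid signal) are excluded; SD uses the n-1 denominator
    and is 0 for a single voxel.
    """
    adc_map = np.asarray(adc_map, dtype=np.float64)
    if adc_map.shape != mask.shape:
        raise ContractError(f"shapes differ: {adc_map.shape} vs {mask.shape}")
    vals = adc_map[mask.data.astype(bool)]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise StatisticsError("ROI contains no valid voxels")
    sd = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
    return int(vals.size), float(vals.mean()), sd


# ---------------------------------------------------------------------------
# Mann-Whitney U


@lru_cache(maxsize=64)
def _u_null_counts(n1: int, n2: int) -> np.ndarray:
    """Exact null frequencies of U over all C(n1+n2, n1) tie-free labelings.

    Classic dynamic program: counts[u] = number of ways to choose n1 of the
    ranks 1..n1+n2 so that the rank sum yields statistic u.
    """
    n = n1 + n2
    max_u = n1 * n2
    # ways[k][s]: choose k ranks from those processed so far with rank sum s
    ways = np.zeros((n1 + 1, n1 * n + 1), dtype=np.float64)
    ways[0, 0] = 1.0
    for r in range(1, n + 1):
        for k in range(min(r, n1), 0, -1):
            ways[k, r:] += ways[k - 1, :-r] if r > 0 else ways[k - 1, :]
    sums = ways[n1]
    counts = np.zeros(max_u + 1)
    offset = n1 * (n1 + 1) // 2
    for s in range(offset, offset + max_u + 1):
        counts[s - offset] = sums[s]
    return counts


def _exact_p_no_ties(u: float, n1: int, n2: int) -> float:
    counts = _u_null_counts(n1, n2)
    mu = n1 * n2 / 2.0
    dev = abs(u - mu)
    us = np.arange(n1 * n2 + 1)
    hit = np.abs(us - mu) >= dev - 1e-9
    return float(counts[hit].sum() / counts.sum())


def _exact_p_enumerate(ranks: np.ndarray, n1: int) -> tuple[float, float]:
    """Permutation p by full enumeration; handles midranks (ties)."""
    n = len(ranks)
    mu = n1 * (n - n1) / 2.0
    offset = n1 * (n1 + 1) / 2.0
    obs_u = None
    devs = []
    idx = np.arange(n)
    obs_u = ranks[:n1].sum() - offset
    obs_dev = abs(obs_u - mu)
    total = 0
    hits = 0
    for combo in itertools.combinations(idx, n1):
        u = ranks[list(combo)].sum() - offset
        total += 1
        if abs(u - mu) >= obs_dev - 1e-9:
            hits += 1
    return obs_u, hits / total


def mann_whitney_u(x, y, method: str = "auto") -> MannWhitneyResult:
    """Two-sided Mann-Whitney U test with midranks for ties.

    ``method="exact"`` evaluates the permutation p-value over all
    C(n1+n2, n1) group labelings — the proportion whose U deviates from the
    null mean n1*n2/2 at least as far as observed.  For tie-free data this
    distribution is computed by a dynamic program; with ties the labelings
    are enumerated directly (requires n1+n2 <= 20).
    ``method="normal_approx"`` uses the tie-corrected normal approximation
    with continuity correction.  ``"auto"`` picks exact when n1+n2 <= 20.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    n1, n2 = len(x), len(y)
    if n1 < 1 or n2 < 1:
        raise ContractError("both samples must be non-empty")
    if method not in ("auto", "exact", "normal_approx"):
        raise ContractError(f"unknown method {method!r}")
    if method == "auto":
        method = "exact" if n1 + n2 <= 20 else "normal_approx"
    if method == "exact" and n1 + n2 > 20:
        raise ContractError("exact method limited to n1+n2 <= 20")

    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    u1 = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)
    mu = n1 * n2 / 2.0

    if np.all(pooled == pooled[0]):
        return MannWhitneyResult(U=mu, p_two_sided=1.0, method=method, n1=n1, n2=n2)

    has_ties = len(np.unique(pooled)) < n1 + n2
    if method == "exact":
        if has_ties:
            u1, p = _exact_p_enumerate(ranks, n1)
        else:
            p = _exact_p_no_ties(u1, n1, n2)
    else:
        n = n1 + n2
        _, tie_counts = np.unique(pooled, return_counts=True)
        tie_term = (tie_counts**3 - tie_counts).sum() / (n * (n - 1))
        var = n1 * n2 / 12.0 * (n + 1 - tie_term)
        if var <= 0:
            p = 1.0
        else:
            z = (abs(u1 - mu) - 0.5) / math.sqrt(var)
            p = float(min(1.0, 2.0 * stats.norm.sf(max(z, 0.0))))
    p = min(1.0, max(p, np.finfo(float).tiny))
    return MannWhitneyResult(U=u1, p_two_sided=p, method=method, n1=n1, n2=n2)


# ---------------------------------------------------------------------------
# Reference cohort fixture

_SIGN_SET = frozenset(SIGNS)


def reference_cohort() -> tuple[list[PatientRecord], list[LesionRecord]]:
    """The packaged 15-patient posterior-fossa PCNSL reference cohort.

    Encodes the published case series this package quantifies: 15 patients
    (11 M / 4 F; 12 DLBCL / 3 Burkitt; 10 single- and 5 multiple-lesion)
    carrying 25 lesions in total.  Marginal counts (locations, enhancement
    patterns, signal characteristics, signs, edema, DWI/MRS findings) are
    contractual; the assignment of attributes to individual records is a
    deterministic choice wherever the source tabulations do not
    cross-tabulate them.  Per-patient ADC values are not part of the record
    set — only the group summaries in :data:`REFERENCE_ADC_GROUPS` are
    reported at the source — so ``adc_*`` fields are left absent.
    """
    ages = [52, 58, 47, 63, 55, 71, 38, 66, 6, 45, 60, 49, 9, 78, 29]
    females = {"P04", "P08", "P12", "P15"}
    burkitt = {"P09", "P13", "P15"}
    dwi = dict.fromkeys(["P01", "P02", "P03", "P04", "P05"], "homogeneous_high")
    dwi.update(dict.fromkeys(["P06", "P07"], "uneven_high"))
    dwi.update(dict.fromkeys(["P08", "P09", "P10"], "intermediate"))
    mrs = {"P01": "present", "P02": "present", "P03": "absent", "P04": "absent"}

    patients = []
    for i in range(15):
        pid = f"P{i + 1:02d}"
        patients.append(
            PatientRecord(
                patient_id=pid,
                age=ages[i],
                sex="F" if pid in females else "M",
                multiplicity="single" if i < 10 else "multiple",
                dwi_signal=dwi.get(pid, "not_done"),
                mrs_lip_peak=mrs.get(pid, "not_done"),
                histology="Burkitt" if pid in burkitt else "DLBCL",
            )
        )

    # (patient, location) for each of the 25 lesions; totals per location:
    # hemisphere+vermis 15, midbrain 2, CPA 2, fourth ventricle 1, supratentorial 5
    placements = [
        *[(f"P{i + 1:02d}", "cerebellar_hemisphere") for i in range(8)],
        ("P09", "fourth_ventricle"),
        ("P10", "cerebellopontine_angle"),
        ("P11", "supratentorial"),
        ("P11", "supratentorial"),
        ("P11", "cerebellar_hemisphere"),
        ("P11", "cerebellar_hemisphere"),
        ("P12", "supratentorial"),
        ("P12", "midbrain"),
        ("P12", "cerebellar_vermis"),
        ("P13", "supratentorial"),
        ("P13", "cerebellar_hemisphere"),
        ("P13", "cerebellopontine_angle"),
        ("P14", "supratentorial"),
        ("P14", "cerebellar_hemisphere"),
        ("P15", "midbrain"),
        ("P15", "cerebellar_hemisphere"),
        ("P15", "cerebellar_vermis"),
    ]
    enhancement = ["mass_nodular"] * 17 + ["striped"] * 4 + ["patchy"] * 3 + ["ring"]
    t1 = ["low"] * 12 + ["slightly_low"] * 10 + ["intermediate"] * 3
    t2 = ["slightly_high"] * 20 + ["intermediate"] * 3 + ["mixed_slightly_high"] * 2
    lesions = []
    for k, (pid, loc) in enumerate(placements):
        lesions.append(
            LesionRecord(
                patient_id=pid,
                location=loc,
                t1_signal=t1[k],
                t2_signal=t2[k],
                enhancement=enhancement[k],
                composition="cystic" if k == 24 else "solid",
                signs=_SIGN_SET if k < 8 else frozenset(),
                peritumoral_edema=k < 12,
            )
        )
    return patients, lesions


# ---------------------------------------------------------------------------
# Summaries and the group test


def _count(values, categories) -> dict:
    c = Counter(values)
    return {cat: int(c.get(cat, 0)) for cat in categories}


def summarize(patients: list[PatientRecord], lesions: list[LesionRecord]) -> CohortSummary:
    """Tabulate marginal counts and per-group ADC summaries over a cohort.

    Validates that every lesion's patient exists and that each patient's
    stated multiplicity matches their lesion count (1 vs > 1); patients
    with no lesion rows are tolerated only for an empty lesion table.
    """
    by_patient = Counter(les.patient_id for les in lesions)
    known = {p.patient_id for p in patients}
    orphans = sorted(set(by_patient) - known)
    if orphans:
        raise ValidationError(f"lesions reference unknown patients: {orphans}")
    if lesions:
        bad = [
            p.patient_id
            for p in patients
            if (p.multiplicity == "single") != (by_patient.get(p.patient_id, 0) == 1)
        ]
        if bad:
            raise ValidationError(f"multiplicity inconsistent with lesion counts for: {bad}")

    def group_stats(vals):
        vals = [v for v in vals if v is not None]
        if not vals:
            return {"n": 0, "mean": None, "sd": None}
        arr = np.asarray(vals, dtype=np.float64)
        sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
        return {"n": int(arr.size), "mean": float(arr.mean()), "sd": sd}

    return CohortSummary(
        n_patients=len(patients),
        n_lesions=len(lesions),
        multiplicity=_count((p.multiplicity for p in patients), MULTIPLICITIES),
        location=_count((l.location for l in lesions), LOCATIONS),
        enhancement=_count((l.enhancement for l in lesions), ENHANCEMENTS),
        composition=_count((l.composition for l in lesions), COMPOSITIONS),
        t1_signal=_count((l.t1_signal for l in lesions), T1_SIGNALS),
        t2_signal=_count((l.t2_signal for l in lesions), T2_SIGNALS),
        n_with_signs=sum(1 for l in lesions if l.signs),
        n_with_edema=sum(1 for l in lesions if l.peritumoral_edema),
        dwi_signal=_count((p.dwi_signal for p in patients), DWI_SIGNALS),
        mrs_lip_peak=_count((p.mrs_lip_peak for p in patients), MRS_LIP),
        histology=_count((p.histology for p in patients), HISTOLOGIES),
        sex=_count((p.sex for p in patients), SEXES),
        adc={
            "tumor": group_stats(p.adc_tumor for p in patients),
            "contralateral": group_stats(p.adc_contralateral for p in patients),
        },
    )


def adc_group_test(patients: list[PatientRecord], method: str = "auto") -> MannWhitneyResult:
    """Mann-Whitney comparison of tumor vs contralateral ADC across patients.

    Uses all patients with the respective value present; the exact
    permutation method applies whenever the combined sample size is <= 20.
    """
    tumor = [p.adc_tumor for p in patients if p.adc_tumor is not None]
    contra = [p.adc_contralateral for p in patients if p.adc_contralateral is not None]
    if len(tumor) < 2 or len(contra) < 2:
        raise StatisticsError("need at least two ADC values per group")
    return mann_whitney_u(tumor, contra, method=method)


# ---------------------------------------------------------------------------
# TSV input/output


def write_cohort_tsv(
    patients: list[PatientRecord], lesions: list[LesionRecord], patients_path, lesions_path
) -> None:
    """Write patient and lesion tables as UTF-8 TSV with header rows."""
    pdf = pd.DataFrame([asdict(p) for p in patients])
    ldf = pd.DataFrame(
        [{**asdict(l), "signs": ",".join(sorted(l.signs))} for l in lesions]
    )
    pdf.to_csv(patients_path, sep="\t", index=False)
    ldf.to_csv(lesions_path, sep="\t", index=False)


def read_cohort_tsv(patients_path, lesions_path) -> tuple[list[PatientRecord], list[LesionRecord]]:
    """Read tables written by :func:`write_cohort_tsv`, re-validating every record."""
    pdf = pd.read_csv(patients_path, sep="\t", dtype={"patient_id": str})
    ldf = pd.read_csv(lesions_path, sep="\t", dtype={"patient_id": str})
    patients = []
    for i, row in pdf.iterrows():
        try:
            patients.append(
                PatientRecord(
                    patient_id=row["patient_id"],
                    age=float(row["age"]),
                    sex=row["sex"],
                    multiplicity=row["multiplicity"],
                    dwi_signal=row["dwi_signal"],
                    adc_tumor=None if pd.isna(row["adc_tumor"]) else float(row["adc_tumor"]),
                    adc_contralateral=(
                        None
                        if pd.isna(row["adc_contralateral"])
                        else float(row["adc_contralateral"])
                    ),
                    mrs_lip_peak=row["mrs_lip_peak"],
                    histology=row["histology"],
                )
            )
        except (ValidationError, KeyError) as exc:
            raise ValidationError(f"patient table row {i}: {exc}") from exc
    lesions = []
    for i, row in ldf.iterrows():
        signs = row.get("signs")
        signs = frozenset() if pd.isna(signs) or not signs else frozenset(str(signs).split(","))
        try:
            lesions.append(
                LesionRecord(
                    patient_id=row["patient_id"],
                    location=row["location"],
                    t1_signal=row["t1_signal"],
                    t2_signal=row["t2_signal"],
                    enhancement=row["enhancement"],
                    composition=row["composition"],
                    signs=signs,
                    peritumoral_edema=bool(row["peritumoral_edema"]),
                )
            )
        except (ValidationError, KeyError) as exc:
            raise ValidationError(f"lesion table row {i}: {exc}") from exc
    return patients, lesions
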