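"""Synthetic screening cohorts: phantom images or direct feature tables.

Emulates the statistical structure of a nested case-control screening
study: two screens about a year apart, a 2:1 control:case frequency-matched
design, three nodule size classes by baseline longest diameter, case
nodules that grow and change texture between the screens while control
nodules stay stable, and measurement noise calibrated so a test/retest
stability filter on the two screens is meaningful.

Default arm sizes and size-class mixes follow the screening study the
pipeline is modelled on: 83 cases / 172 controls in the training cohort,
77 cases / 135 controls in the test cohort, with cases concentrated in the
intermediate (6-16 mm) class.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .images import ContextMap, ImageVolume, NoduleMask, save_nifti
from .phantoms import PhantomSpec, generate_nodule_phantom
from .radiomics import extract_all_features

SIZE_CLASS_RANGES = {"small": (3.0, 6.0), "intermediate": (6.0, 16.0), "large": (16.0, 25.0)}

#: training-cohort size-class counts (cases 14/53/16, controls 40/125/7)
DEFAULT_CASE_MIX = (14 / 83, 53 / 83, 16 / 83)
DEFAULT_CONTROL_MIX = (40 / 172, 125 / 172, 7 / 172)


@dataclass
class CohortDesignParams:
    """Arm sizes, size-class mixes and longitudinal change parameters.

    ``case_growth_factor`` multiplies the nodule diameter between T0 and T1
    for cases (default 1.26, i.e. one volume doubling over the inter-scan
    year); controls keep their size (factor 1.0).  ``case_texture_shift``
    is added to the case nodules' HU texture SD at T1.  The inter-scan
    interval is treated as constant, so no per-subject time is generated.
    """

    n_cases_train: int = 83
    n_controls_train: int = 172
    n_cases_test: int = 77
    n_controls_test: int = 135
    case_size_mix: tuple[float, float, float] = DEFAULT_CASE_MIX
    control_size_mix: tuple[float, float, float] = DEFAULT_CONTROL_MIX
    case_growth_factor: float = 1.26
    control_growth_factor: float = 1.0
    case_texture_shift: float = 15.0
    measurement_noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        for n in (self.n_cases_train, self.n_controls_train, self.n_cases_test, self.n_controls_test):
            if n < 0:
                raise ValueError("arm sizes must be non-negative")
        for mix in (self.case_size_mix, self.control_size_mix):
            if any(not (0.0 <= p <= 1.0) for p in mix) or abs(sum(mix) - 1.0) > 1e-9:
                raise ValueError("size-class mixes must be proportions summing to 1")
        if self.case_growth_factor < 1.0:
            raise ValueError("case_growth_factor must be >= 1")
        if self.measurement_noise_sd < 0:
            raise ValueError("measurement_noise_sd must be non-negative")


def _allocate(n: int, mix: tuple[float, ...]) -> list[int]:
    """Largest-remainder allocation of n subjects to size classes."""
    raw = [n * p for p in mix]
    counts = [int(np.floor(r)) for r in raw]
    rem = n - sum(counts)
    order = sorted(range(len(mix)), key=lambda i: raw[i] - counts[i], reverse=True)
    for i in order[:rem]:
        counts[i] += 1
    return counts


@dataclass
class SubjectRecord:
    subject_id: str
    label: str  # case | control
    cohort: str  # train | test
    size_class: str
    ld_mm: float  # T0 longest diameter
    t0_spec: PhantomSpec | None = None
    t1_spec: PhantomSpec | None = None
    t0_seed: int = 0
    t1_seed: int = 0
    shape_seed: int = 0  # shared across timepoints: same nodule, rescaled


@dataclass
class CohortBundle:
    """All subjects of a simulated cohort, with image and feature views.

    Volumes are rendered on demand (``images_for``) so the statistical
    stages can run on the fast table path without paying the voxel cost.
    """

    params: CohortDesignParams
    subjects: list[SubjectRecord] = field(default_factory=list)

    def design_frame(self) -> pd.DataFrame:
        rows = [
            {
                "subject_id": s.subject_id,
                "label": s.label,
                "cohort": s.cohort,
                "size_class": s.size_class,
                "ld_mm": s.ld_mm,
            }
            for s in self.subjects
        ]
        return pd.DataFrame(rows).set_index("subject_id")

    def images_for(
        self, subject_id: str, timepoint: str
    ) -> tuple[ImageVolume, NoduleMask, ContextMap]:
        rec = next(s for s in self.subjects if s.subject_id == subject_id)
        spec = rec.t0_spec if timepoint == "T0" else rec.t1_spec
        seed = rec.t0_seed if timepoint == "T0" else rec.t1_seed
        if spec is None:
            raise ValueError("bundle was generated without phantom specs")
        return generate_nodule_phantom(spec, seed, shape_seed=rec.shape_seed)

    def extract_features(self, timepoint: str) -> pd.DataFrame:
        """Voxel-path feature table for one timepoint (slow for large cohorts)."""
        rows = {}
        for rec in self.subjects:
            img, mask, ctx = self.images_for(rec.subject_id, timepoint)
            rows[rec.subject_id] = extract_all_features(img, mask, ctx)
        return pd.DataFrame.from_dict(rows, orient="index")

    def write_nifti(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for rec in self.subjects:
            for tp in ("T0", "T1"):
                img, mask, ctx = self.images_for(rec.subject_id, tp)
                stem = f"{rec.subject_id}_{tp}"
                save_nifti(img, out / f"{stem}_image.nii.gz")
                save_nifti(mask, out / f"{stem}_mask.nii.gz")
                save_nifti(ctx, out / f"{stem}_context.nii.gz")


def _arm_subjects(
    label: str,
    cohort: str,
    n: int,
    mix: tuple[float, float, float],
    params: CohortDesignParams,
    rng: np.random.Generator,
    start_idx: int,
    strict: bool,
) -> list[SubjectRecord]:
    counts = _allocate(n, mix)
    if strict and n > 0 and any(c == 0 for c in counts):
        raise ValueError(f"stratum with zero subjects in arm {label}/{cohort} under strict mode")
    recs = []
    idx = start_idx
    for cls, count in zip(("small", "intermediate", "large"), counts):
        lo, hi = SIZE_CLASS_RANGES[cls]
        for _ in range(count):
            ld = float(rng.uniform(lo, hi))
            growth = params.case_growth_factor if label == "case" else params.control_growth_factor
            jitter = 1.0 + params.measurement_noise_sd * float(rng.standard_normal())
            ld_t1 = max(ld * growth * jitter, 1.0)
            sd_hu = float(rng.uniform(40.0, 100.0))
            common = dict(
                shape_eccentricity=float(rng.uniform(0.0, 0.6)),
                spiculation_count=int(rng.integers(0, 4)),
                mean_hu=float(rng.normal(-40.0, 20.0)),
                pleural_attached=bool(rng.uniform() < 0.2),
                voxel_mm=0.7,
            )
            t0_spec = PhantomSpec(diameter_mm=ld, sd_hu=sd_hu, **common)
            t1_sd = sd_hu + (params.case_texture_shift if label == "case" else 0.0)
            t1_spec = PhantomSpec(diameter_mm=ld_t1, sd_hu=t1_sd, **common)
            recs.append(
                SubjectRecord(
                    subject_id=f"s{idx:04d}",
                    label=label,
                    cohort=cohort,
                    size_class=cls,
                    ld_mm=ld,
                    t0_spec=t0_spec,
                    t1_spec=t1_spec,
                    t0_seed=int(rng.integers(2**31)),
                    t1_seed=int(rng.integers(2**31)),
                    shape_seed=int(rng.integers(2**31)),
                )
            )
            idx += 1
    return recs


def simulate_screening_cohort(params: CohortDesignParams, strict: bool = False) -> CohortBundle:
    """Simulate the two-timepoint image-mode cohort.

    Cases grow isotropically by ``case_growth_factor`` and gain texture SD
    between T0 and T1; controls stay stable up to re-scan jitter.
    Deterministic for fixed params (including the seed).
    """
    rng = np.random.default_rng(params.seed)
    subjects: list[SubjectRecord] = []
    arms = [
        ("case", "train", params.n_cases_train, params.case_size_mix),
        ("control", "train", params.n_controls_train, params.control_size_mix),
        ("case", "test", params.n_cases_test, params.case_size_mix),
        ("control", "test", params.n_controls_test, params.control_size_mix),
    ]
    for label, cohort, n, mix in arms:
        subjects.extend(
            _arm_subjects(label, cohort, n, mix, params, rng, len(subjects), strict)
        )
    return CohortBundle(params=params, subjects=subjects)


def simulate_feature_table(
    n_features: int,
    n_informative_baseline: int,
    n_informative_delta: int,
    effect_size: float,
    retest_ccc_target: float,
    params: CohortDesignParams,
    delta_effect_size: float | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Fast path: draw T0/T1 feature tables directly with known structure.

    Features are standardised latent traits.  Informative *baseline*
    features shift the case mean by ``effect_size`` SD at both timepoints;
    informative *delta* features shift only the case T1 values (by
    ``delta_effect_size``, default ``effect_size``), so their signal lives
    purely in the change.  Independent measurement noise at each timepoint
    is calibrated so that a stable feature's T0/T1 concordance over control
    subjects is approximately ``retest_ccc_target``.

    Returns (table_t0, table_t1, design) with subjects as index.
    """
    if not (0.0 < retest_ccc_target <= 1.0):
        raise ValueError("retest_ccc_target must lie in (0, 1]")
    if n_informative_baseline + n_informative_delta > n_features:
        raise ValueError("more informative features than features")
    if delta_effect_size is None:
        delta_effect_size = effect_size

    bundle = simulate_screening_cohort(params)
    design = bundle.design_frame()
    n = len(design)
    rng = np.random.default_rng(np.random.SeedSequence([params.seed, 7]))

    latent = rng.standard_normal((n, n_features))
    is_case = (design["label"] == "case").to_numpy()
    ib = slice(0, n_informative_baseline)
    idl = slice(n_informative_baseline, n_informative_baseline + n_informative_delta)
    latent_t1 = latent.copy()
    latent[is_case, ib] += effect_size
    latent_t1[is_case, ib] += effect_size
    latent_t1[is_case, idl] += delta_effect_size

    noise_sd = float(np.sqrt(1.0 / retest_ccc_target - 1.0))
    t0 = latent + noise_sd * rng.standard_normal(latent.shape)
    t1 = latent_t1 + noise_sd * rng.standard_normal(latent.shape)

    names = [f"feat_{j:03d}" for j in range(n_features)]
    table_t0 = pd.DataFrame(t0, index=design.index, columns=names)
    table_t1 = pd.DataFrame(t1, index=design.index, columns=names)
    return table_t0, table_t1, design
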