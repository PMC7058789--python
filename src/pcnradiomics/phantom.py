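"""Synthetic cohorts of tumor volumes, masks and clinical covariates.

The images of the cohort this pipeline was designed around are not publicly
deposited, so every downstream stage is exercised on phantoms with the same
statistical structure the analysis assumes: three tumor classes (SCA, MCN,
IPMN) that differ in intensity-histogram shape (entropy, skewness,
uniformity, kurtosis) and in spatial texture scale, joined to clinical
covariates in which serum CA 19-9, serum CEA, sex and age carry class
information while the remaining fields are class-independent nuisance.

A tumor is an axis-aligned ellipsoid ROI (radii jittered +/-20%) filled with
a stationary Gaussian random field — white noise convolved with an isotropic
Gaussian kernel whose width sets the spatial correlation length — that is
then rank-transformed through a skewed quantile map to the target histogram
skewness and snapped to a configurable number of effective intensity levels
(which controls entropy and uniformity).  Texture scale and histogram shape
are therefore controlled independently.

Everything is a pure function of (spec, seed): per-case substreams are
derived from the master seed with counter-based keys (see ``rng``), so the
cohort is bit-identical across runs and independent of generation order.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .errors import InvalidArgumentError
from .rng import stream_seed, substream
from .volume_io import ImageVolume, RoiMask, write_case

__all__ = [
    "ClassSpec",
    "ClinicalRecord",
    "Case",
    "SyntheticCohort",
    "default_class_specs",
    "generate_tumor",
    "generate_clinical",
    "generate_cohort",
    "clinical_table",
    "write_cohort",
    "LABELS",
    "DEFAULT_CLASS_SIZES",
]

LABELS = ("SCA", "MCN", "IPMN")
#: cohort composition emulated by default: 76 SCA, 40 MCN, 48 IPMN
DEFAULT_CLASS_SIZES = (76, 40, 48)

DEFAULT_SHAPE_MM = (40.0, 40.0, 60.0)
DEFAULT_SPACING = (1.0, 1.0, 5.0)


@dataclass(frozen=True)
class ClassSpec:
    """Generative parameters of one tumor subtype."""

    label: str
    texture_corr_length: float  # mm, spatial correlation of the intensity field
    hist_skew: float            # target skewness of ROI intensities
    hist_levels_active: int     # effective intensity levels (entropy control)
    mean_hu: float
    sd_hu: float
    ca199_log_mean: float       # log U/mL
    ca199_log_sd: float
    cea_log_mean: float         # log ng/mL
    cea_log_sd: float
    age_mean: float             # years
    age_sd: float
    female_prob: float

    def __post_init__(self):
        if self.label not in LABELS:
            raise InvalidArgumentError(f"label must be one of {LABELS}")
        if not 0.0 <= self.female_prob <= 1.0:
            raise InvalidArgumentError("female_prob must lie in [0, 1]")
        if self.texture_corr_length <= 0:
            raise InvalidArgumentError("texture_corr_length must be > 0")
        if self.sd_hu <= 0 or self.age_sd <= 0:
            raise InvalidArgumentError("sd values must be > 0")
        if self.ca199_log_sd < 0 or self.cea_log_sd < 0:
            raise InvalidArgumentError("log-sd values must be >= 0")
        if self.hist_levels_active < 1:
            raise InvalidArgumentError("hist_levels_active must be >= 1")


def default_class_specs() -> dict[str, ClassSpec]:
    """The three subtype specifications used as the package's study conditions.

    SCA phantoms are fine-textured, right-skewed and intensity-poor (low
    histogram entropy); IPMN phantoms are coarse, left-skewed and
    intensity-rich; MCN sits between.  Clinically, IPMN patients are older,
    more often male and carry higher CA 19-9 / CEA, MCN patients are
    predominantly female — the four informative covariates.  The remaining
    fields are drawn identically across classes.
    """
    return {
        "SCA": ClassSpec(
            label="SCA", texture_corr_length=3.0, hist_skew=1.1,
            hist_levels_active=10, mean_hu=30.0, sd_hu=12.0,
            ca199_log_mean=float(np.log(8.0)), ca199_log_sd=0.8,
            cea_log_mean=float(np.log(1.5)), cea_log_sd=0.5,
            age_mean=52.0, age_sd=12.0, female_prob=0.70,
        ),
        "MCN": ClassSpec(
            label="MCN", texture_corr_length=6.0, hist_skew=0.3,
            hist_levels_active=24, mean_hu=45.0, sd_hu=14.0,
            ca199_log_mean=float(np.log(20.0)), ca199_log_sd=1.0,
            cea_log_mean=float(np.log(2.5)), cea_log_sd=0.6,
            age_mean=45.0, age_sd=12.0, female_prob=0.95,
        ),
        "IPMN": ClassSpec(
            label="IPMN", texture_corr_length=10.0, hist_skew=-0.8,
            hist_levels_active=48, mean_hu=60.0, sd_hu=16.0,
            ca199_log_mean=float(np.log(60.0)), ca199_log_sd=1.2,
            cea_log_mean=float(np.log(4.5)), cea_log_sd=0.7,
            age_mean=66.0, age_sd=9.0, female_prob=0.30,
        ),
    }


@dataclass
class ClinicalRecord:
    """One patient's covariates (units follow routine laboratory reporting)."""

    age: float                 # years
    sex: str                   # {M, F}
    location: str              # {head-neck, body-tail, both}
    max_diameter: float        # cm
    ca199: float               # U/mL
    cea: float                 # ng/mL
    alt: float                 # U/L
    ast: float                 # U/L
    fbg: float                 # mmol/L
    platelet: float            # 10^9/L
    alb: float                 # g/L
    afp: float                 # ng/mL
    sf: float                  # ng/mL
    calcification: bool
    abdominal_symptom: bool
    smoking: bool
    alcohol: bool
    obesity: bool              # BMI >= 25
    chronic_pancreatitis: bool
    family_history: bool
    blood_type: str            # {A, B, AB, O}

    def __post_init__(self):
        for name in ("age", "max_diameter", "ca199", "cea", "alt", "ast",
                     "fbg", "platelet", "alb", "afp", "sf"):
            if getattr(self, name) <= 0:
                raise InvalidArgumentError(f"{name} must be positive")
        if self.sex not in ("M", "F"):
            raise InvalidArgumentError("sex must be M or F")
        if self.location not in ("head-neck", "body-tail", "both"):
            raise InvalidArgumentError(f"bad location {self.location!r}")
        if self.blood_type not in ("A", "B", "AB", "O"):
            raise InvalidArgumentError(f"bad blood type {self.blood_type!r}")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class Case:
    patient_id: str
    volume: ImageVolume
    mask: RoiMask
    clinical: ClinicalRecord
    label: str


@dataclass
class SyntheticCohort:
    cases: list[Case]
    seed: int
    class_specs: dict[str, ClassSpec]

    def labels(self) -> list[str]:
        return [c.label for c in self.cases]

    def __len__(self) -> int:
        return len(self.cases)


# ---------------------------------------------------------------------------
# skewed quantile map


def _skew_ppf(u: np.ndarray, target_skew: float) -> np.ndarray:
    """Quantiles of a unit-scale distribution with the requested skewness.

    Moderate targets use a skew-normal (solving its shape parameter for the
    target third standardized moment); targets beyond the skew-normal's
    attainable range (|skew| ~< 0.995) fall back to a lognormal whose
    log-scale is solved from the lognormal skewness identity, mirrored for
    negative targets.
    """
    s = float(target_skew)
    if abs(s) < 1e-12:
        return stats.norm.ppf(u)
    sign = 1.0 if s > 0 else -1.0
    mag = abs(s)
    if mag <= 0.9:
        def skewnorm_skew(a):
            d = a / np.sqrt(1.0 + a * a)
            num = (4.0 - np.pi) / 2.0 * (d * np.sqrt(2.0 / np.pi)) ** 3
            den = (1.0 - 2.0 * d * d / np.pi) ** 1.5
            return num / den

        from scipy.optimize import brentq

        a = brentq(lambda x: skewnorm_skew(x) - mag, 1e-9, 80.0)
        q = stats.skewnorm.ppf(u, a)
    else:
        def logn_skew(sig):
            e = np.exp(sig * sig)
            return (e + 2.0) * np.sqrt(e - 1.0)

        from scipy.optimize import brentq

        sig = brentq(lambda x: logn_skew(x) - mag, 1e-9, 5.0)
        q = stats.lognorm.ppf(u, sig)
    return sign * q


def generate_tumor(
    spec: ClassSpec,
    shape_mm: tuple[float, float, float] = DEFAULT_SHAPE_MM,
    spacing: tuple[float, float, float] = DEFAULT_SPACING,
    seed: int = 0,
) -> tuple[ImageVolume, RoiMask]:
    """Generate one phantom tumor volume and its ellipsoidal ROI mask."""
    spacing = tuple(float(s) for s in spacing)
    shape_mm = tuple(float(s) for s in shape_mm)
    if any(s <= 0 for s in spacing) or any(s <= 0 for s in shape_mm):
        raise InvalidArgumentError("spacing and extents must be positive")
    grid_shape = tuple(max(1, round(e / s)) for e, s in zip(shape_mm, spacing))

    rng = substream(seed, "tumor")
    # per-case biological variability: patients within a class are not
    # parameter-identical; this spread is what makes between-patient variance
    # dominate segmentation-perturbation noise (histogram features then agree
    # across perturbed masks, i.e. are ICC-robust, as they should be)
    skew = spec.hist_skew + rng.uniform(-0.25, 0.25)
    mean_hu = spec.mean_hu + rng.uniform(-4.0, 4.0)
    sd_hu = spec.sd_hu * (1.0 + rng.uniform(-0.15, 0.15))
    corr = spec.texture_corr_length * (1.0 + rng.uniform(-0.15, 0.15))
    if spec.hist_levels_active > 1:
        k_active = max(2, int(round(spec.hist_levels_active
                                    * (1.0 + rng.uniform(-0.15, 0.15)))))
    else:
        k_active = 1
    # ellipsoid with per-axis +/-20% radius jitter
    radii_vox = []
    for e, s in zip(shape_mm, spacing):
        base = 0.28 * e / s
        radii_vox.append(base * (1.0 + 0.2 * rng.uniform(-1.0, 1.0)))
    center = [(n - 1) / 2.0 + rng.uniform(-0.5, 0.5) for n in grid_shape]
    ax = [np.arange(n) for n in grid_shape]
    xs, ys, zs = np.meshgrid(*ax, indexing="ij")
    ell = (((xs - center[0]) / radii_vox[0]) ** 2
           + ((ys - center[1]) / radii_vox[1]) ** 2
           + ((zs - center[2]) / radii_vox[2]) ** 2)
    mask = (ell <= 1.0).astype(np.uint8)
    if mask.sum() < 100:
        raise InvalidArgumentError(
            f"extents {shape_mm} at spacing {spacing} give an ROI of "
            f"{int(mask.sum())} voxels; >= 100 required"
        )

    # correlated field: white noise smoothed at the case's correlation length
    sigma_vox = [corr / s for s in spacing]
    white = rng.standard_normal(grid_shape)
    fieldv = ndimage.gaussian_filter(white, sigma=sigma_vox, mode="nearest")

    fg = mask > 0
    vals = fieldv[fg]
    grid = np.empty(grid_shape)
    if k_active == 1:
        grid[:] = rng.normal(mean_hu, sd_hu, size=grid_shape)
        grid[fg] = mean_hu
    else:
        # rank -> uniform -> skewed quantile map (monotone warp of the field)
        order = np.argsort(vals, kind="stable")
        ranks = np.empty_like(order)
        ranks[order] = np.arange(vals.size)
        u = (ranks + 0.5) / vals.size
        warped = _skew_ppf(u, skew)
        # snap to the active number of effective levels (equal-width bins)
        lo, hi = warped.min(), warped.max()

        def snap(w):
            idx = np.minimum(k_active - 1,
                             np.floor(k_active * (w - lo) / (hi - lo)))
            return lo + (hi - lo) * (np.clip(idx, 0, k_active - 1) + 0.5) / k_active

        centers = snap(warped)
        mu_c, sd_c = centers.mean(), centers.std()
        scale = sd_hu / sd_c if sd_c > 0 else 0.0
        grid[fg] = mean_hu + scale * (centers - mu_c)
        # background: spatially WHITE noise pushed through the same marginal
        # distribution (skew-warped, level-snapped) — the isointense-margin
        # case in which manual delineation is genuinely uncertain.  Boundary
        # perturbations then change spatial texture, not histogram shape,
        # mirroring how first-order features survive segmentation jitter on
        # real lesions while texture features do not.
        bg = ~fg
        u_bg = rng.random(int(bg.sum()))
        bg_centers = snap(_skew_ppf(np.clip(u_bg, u.min(), u.max()), skew))
        grid[bg] = mean_hu + scale * (bg_centers - mu_c)
    return ImageVolume(grid, spacing), RoiMask(mask, spacing)


# ---------------------------------------------------------------------------
# clinical covariates

#: class-independent nuisance distributions (medians chosen to resemble a
#: routine pre-surgical panel); log-normal for strictly positive analytes.
_NUISANCE = {
    "max_diameter": (np.log(3.5), 0.5),
    "alt": (np.log(16.0), 0.5),
    "ast": (np.log(19.0), 0.4),
    "fbg": (np.log(5.0), 0.15),
    "platelet": (np.log(200.0), 0.3),
    "alb": (np.log(44.0), 0.08),
    "afp": (np.log(2.3), 0.6),
    "sf": (np.log(130.0), 0.9),
}
_BOOL_P = {
    "calcification": 0.06,
    "abdominal_symptom": 0.45,
    "smoking": 0.13,
    "alcohol": 0.16,
    "obesity": 0.22,
    "chronic_pancreatitis": 0.01,
    "family_history": 0.005,
}
_LOCATION = (("head-neck", 0.40), ("body-tail", 0.53), ("both", 0.07))
_BLOOD = (("A", 0.30), ("B", 0.17), ("AB", 0.09), ("O", 0.44))


def generate_clinical(spec: ClassSpec, seed: int = 0) -> ClinicalRecord:
    """Draw one clinical record: informative fields from the class spec,
    nuisance fields from class-independent defaults."""
    rng = substream(seed, "clinical")
    a, b = (18.0 - spec.age_mean) / spec.age_sd, (90.0 - spec.age_mean) / spec.age_sd
    age = float(stats.truncnorm.ppf(rng.random(), a, b,
                                    loc=spec.age_mean, scale=spec.age_sd))
    sex = "F" if rng.random() < spec.female_prob else "M"
    ca199 = float(np.exp(spec.ca199_log_mean + spec.ca199_log_sd * rng.standard_normal()))
    cea = float(np.exp(spec.cea_log_mean + spec.cea_log_sd * rng.standard_normal()))

    cont = {k: float(np.exp(m + s * rng.standard_normal()))
            for k, (m, s) in _NUISANCE.items()}
    flags = {k: bool(rng.random() < p) for k, p in _BOOL_P.items()}

    def pick(table):
        r, acc = rng.random(), 0.0
        for name, p in table:
            acc += p
            if r < acc:
                return name
        return table[-1][0]

    return ClinicalRecord(age=age, sex=sex, location=pick(_LOCATION),
                          ca199=ca199, cea=cea, **cont, **flags,
                          blood_type=pick(_BLOOD))


def generate_cohort(
    class_sizes: tuple[int, int, int] = DEFAULT_CLASS_SIZES,
    specs: dict[str, ClassSpec] | None = None,
    seed: int = 0,
    shape_mm: tuple[float, float, float] = DEFAULT_SHAPE_MM,
    spacing: tuple[float, float, float] = DEFAULT_SPACING,
) -> SyntheticCohort:
    """Generate a labelled cohort; sizes map to (SCA, MCN, IPMN)."""
    if specs is None:
        specs = default_class_specs()
    if len(class_sizes) != 3 or any(n < 1 for n in class_sizes):
        raise InvalidArgumentError("class_sizes must be three integers >= 1")
    cases: list[Case] = []
    for label, n in zip(LABELS, class_sizes):
        spec = specs[label]
        for i in range(n):
            case_seed = stream_seed(seed, label, i)
            vol, mask = generate_tumor(spec, shape_mm, spacing, seed=case_seed)
            clin = generate_clinical(spec, seed=case_seed)
            cases.append(Case(f"{label}-{i + 1:03d}", vol, mask, clin, label))
    return SyntheticCohort(cases, int(seed), dict(specs))


def clinical_table(cohort: SyntheticCohort) -> pd.DataFrame:
    """Cohort covariates as a DataFrame indexed by patient_id, with label."""
    rows = []
    for c in cohort.cases:
        row = {"patient_id": c.patient_id, **c.clinical.to_dict(),
               "label": c.label}
        rows.append(row)
    return pd.DataFrame(rows).set_index("patient_id")


def write_cohort(cohort: SyntheticCohort, outdir) -> Path:
    """Write volumes/masks as NIfTI, covariates as CSV and a JSON manifest."""
    outdir = Path(outdir)
    (outdir / "images").mkdir(parents=True, exist_ok=True)
    entries = []
    for c in cohort.cases:
        vpath = outdir / "images" / f"{c.patient_id}_vol.nii.gz"
        mpath = outdir / "images" / f"{c.patient_id}_mask.nii.gz"
        write_case(c.volume, c.mask, vpath, mpath)
        entries.append({"patient_id": c.patient_id, "label": c.label,
                        "volume": str(vpath.relative_to(outdir)),
                        "mask": str(mpath.relative_to(outdir))})
    clinical_table(cohort).to_csv(outdir / "clinical.csv")
    manifest = {"seed": cohort.seed, "n_cases": len(cohort),
                "class_specs": {k: asdict(v) for k, v in cohort.class_specs.items()},
                "cases": entries}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return outdir
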