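"""Virtual BA / non-BA cohorts and multi-b DWI phantom volumes.

The generator emulates the study design this pipeline targets: a 10-b-value
free-breathing liver DWI protocol (b = 0..800 s/mm^2, matrix 128x128, slice
thickness 3 mm), 12 biliary-atresia (BA) and 5 non-BA infants, two axial
ROI measurements per patient, and group-separated diffusion parameters and
laboratory values.  Ground-truth diffusion parameters are drawn per patient
from log-normal distributions (logit-normal for the heterogeneity index
alpha) centred on the published group values; magnitude images carry Rician
noise, the noise model of magnitude MR reconstruction.

Geometry is deliberately schematic — an elliptical liver slab with a few
circular "vessels" per slice — because the downstream analysis consumes ROI
statistics, not anatomy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .signal_models import (
    STUDY_B_VALUES,
    BiExpParams,
    BValueScheme,
    StretchedExpParams,
    bem_signal,
    sem_signal,
)
from .fitting import SignalCurve

__all__ = [
    "LogNormalSpec",
    "LogitNormalSpec",
    "GroupParameterProfile",
    "BA_PROFILE",
    "NONBA_PROFILE",
    "VirtualPatient",
    "CohortConfig",
    "sample_patient",
    "add_rician_noise",
    "synthesize_dwi_volume",
    "simulate_roi_curves",
    "sample_cohort",
    "generate_cohort",
]

_Z95 = 1.959963984540054   # two-sided 95% normal quantile
_Z50 = 0.6744897501960817  # quartile normal quantile


def _logit(p: float) -> float:
    return math.log(p / (1.0 - p))


def _expit(x: np.ndarray | float):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


@dataclass(frozen=True)
class LogNormalSpec:
    """Log-normal distribution given by its median and log-scale sigma."""

    median: float
    sigma_log: float

    def __post_init__(self) -> None:
        if self.median <= 0:
            raise ValueError("median must be positive")
        if self.sigma_log < 0:
            raise ValueError("dispersion must be >= 0")

    @classmethod
    def from_interval(cls, median: float, lo: float, hi: float,
                      z: float = _Z95) -> "LogNormalSpec":
        """Spec whose central interval at +-z matches (lo, hi)."""
        return cls(median, math.log(hi / lo) / (2 * z))

    @classmethod
    def from_iqr(cls, median: float, q1: float, q3: float) -> "LogNormalSpec":
        return cls.from_interval(median, q1, q3, z=_Z50)

    def sample(self, rng: np.random.Generator, size=None):
        return self.median * np.exp(self.sigma_log * rng.standard_normal(size))


@dataclass(frozen=True)
class LogitNormalSpec:
    """Logit-normal distribution for quantities constrained to (0, 1)."""

    median: float
    sigma_logit: float

    def __post_init__(self) -> None:
        if not 0 < self.median < 1:
            raise ValueError("median must be in (0, 1)")
        if self.sigma_logit < 0:
            raise ValueError("dispersion must be >= 0")

    @classmethod
    def from_interval(cls, median: float, lo: float, hi: float,
                      z: float = _Z95) -> "LogitNormalSpec":
        return cls(median, (_logit(hi) - _logit(lo)) / (2 * z))

    def sample(self, rng: np.random.Generator, size=None):
        return _expit(_logit(self.median) + self.sigma_logit * rng.standard_normal(size))


@dataclass(frozen=True)
class GroupParameterProfile:
    """Per-group ground-truth distributions for diffusion parameters and labs.

    Diffusion coefficients are in mm^2/s, the perfusion fraction f and
    heterogeneity index alpha dimensionless, labs in their clinical units
    (IU/L; bilirubins mg/dl).  Defaults encode the published BA and non-BA
    group summaries: diffusion locations from the group estimates, lab
    locations/dispersion from the group medians and IQRs.
    """

    group: str
    d: LogNormalSpec
    dstar: LogNormalSpec
    f: LogitNormalSpec
    ddc: LogNormalSpec
    alpha: LogitNormalSpec
    age_weeks: LogNormalSpec
    p_male: float
    labs: dict[str, LogNormalSpec]

    def __post_init__(self) -> None:
        if not 0 <= self.p_male <= 1:
            raise ValueError("p_male must be in [0, 1]")


BA_PROFILE = GroupParameterProfile(
    group="BA",
    d=LogNormalSpec.from_interval(0.835e-3, 0.703e-3, 0.966e-3),
    dstar=LogNormalSpec.from_interval(33.2e-3, 23.1e-3, 43.3e-3),
    f=LogitNormalSpec.from_interval(0.134, 0.101, 0.166),
    ddc=LogNormalSpec.from_interval(0.889e-3, 0.721e-3, 1.057e-3),
    alpha=LogitNormalSpec.from_interval(0.699, 0.634, 0.765),
    age_weeks=LogNormalSpec.from_iqr(8, 6, 12),
    p_male=4 / 12,
    labs={
        "AST": LogNormalSpec.from_iqr(168.5, 112.8, 374.3),
        "ALT": LogNormalSpec.from_iqr(101.5, 53.8, 173.5),
        "total_bilirubin": LogNormalSpec.from_iqr(8.0, 5.7, 9.1),
        "direct_bilirubin": LogNormalSpec.from_iqr(6.0, 4.6, 6.9),
        "ALP": LogNormalSpec.from_iqr(649.5, 465.8, 795.3),
        "GGT": LogNormalSpec.from_iqr(368.0, 185.8, 545.0),
    },
)

NONBA_PROFILE = GroupParameterProfile(
    group="non-BA",
    d=LogNormalSpec.from_interval(1.025e-3, 0.821e-3, 1.228e-3),
    dstar=LogNormalSpec.from_interval(55.3e-3, 39.7e-3, 71.0e-3),
    f=LogitNormalSpec.from_interval(0.221, 0.171, 0.272),
    ddc=LogNormalSpec.from_interval(1.323e-3, 1.062e-3, 1.584e-3),
    alpha=LogitNormalSpec.from_interval(0.556, 0.454, 0.658),
    age_weeks=LogNormalSpec.from_iqr(8, 5, 11),
    p_male=4 / 5,
    labs={
        "AST": LogNormalSpec.from_iqr(72.5, 35.0, 148.3),
        "ALT": LogNormalSpec.from_iqr(27.5, 15.8, 103.0),
        "total_bilirubin": LogNormalSpec.from_iqr(5.75, 3.8, 11.4),
        "direct_bilirubin": LogNormalSpec.from_iqr(3.20, 3.0, 7.8),
        "ALP": LogNormalSpec.from_iqr(616.5, 354.5, 1006.0),
        "GGT": LogNormalSpec.from_iqr(93.5, 86.5, 136.5),
    },
)

DEFAULT_PROFILES = {"BA": BA_PROFILE, "non-BA": NONBA_PROFILE}


@dataclass(frozen=True)
class VirtualPatient:
    """One simulated subject with ground-truth tissue parameters and labs."""

    patient_id: str
    group: str
    age_weeks: float
    sex: str  # "M" | "F"
    bem: BiExpParams
    sem: StretchedExpParams
    labs: dict[str, float]

    def __post_init__(self) -> None:
        if self.group not in ("BA", "non-BA"):
            raise ValueError(f"group must be BA or non-BA, got {self.group}")
        if any(v <= 0 for v in self.labs.values()):
            raise ValueError("lab values must be positive")


@dataclass(frozen=True)
class CohortConfig:
    """Cohort size, acquisition geometry and noise level.

    ``snr_b0`` is the signal-to-noise ratio of liver parenchyma on the b = 0
    image (sigma = S0 / snr_b0).  The geometry defaults reproduce the target
    acquisition (128x128 matrix, 3 mm slices); ``fov_mm`` = 256 gives 2 mm
    in-plane pixels, so the default ROI radius of 10 px covers ~1257 mm^2,
    in line with reported freehand liver ROI areas.
    """

    n_ba: int = 12
    n_nonba: int = 5
    snr_b0: float = 50.0
    matrix: int = 128
    n_slices: int = 8
    slice_thickness_mm: float = 3.0
    fov_mm: float = 256.0
    rois_per_patient: int = 2
    roi_radius_px: float = 10.0
    s0: float = 100.0
    signal_model: str = "bem"  # liver attenuation model: "bem" | "sem"
    b_values: tuple[float, ...] = STUDY_B_VALUES
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_ba < 1 or self.n_nonba < 1:
            raise ValueError("need at least one patient per group")
        if self.snr_b0 <= 0:
            raise ValueError("snr_b0 must be positive")
        if self.signal_model not in ("bem", "sem"):
            raise ValueError("signal_model must be 'bem' or 'sem'")
        if self.rois_per_patient < 1:
            raise ValueError("rois_per_patient must be >= 1")
        if self.rois_per_patient > self.n_slices:
            raise ValueError("cannot place more single-slice ROIs than slices")

    @property
    def scheme(self) -> BValueScheme:
        return BValueScheme(self.b_values)

    @property
    def pixdim_mm(self) -> float:
        return self.fov_mm / self.matrix

    @property
    def noise_sigma(self) -> float:
        return self.s0 / self.snr_b0

    def patient_rng(self, patient_index: int) -> np.random.Generator:
        """Stable per-patient stream derived from (master seed, index)."""
        return np.random.default_rng(np.random.SeedSequence((self.seed, patient_index)))


def sample_patient(profile: GroupParameterProfile, patient_id: str,
                   rng: np.random.Generator, s0: float = 100.0) -> VirtualPatient:
    """Draw one patient's ground truth from a group profile.

    Deterministic given the generator state.  Draws are rejected and redrawn
    (bounded) until the bi-exponential invariant D < D* holds — essentially
    never triggered with the default profiles, whose scales differ 30-fold.
    """
    for _ in range(100):
        d = float(profile.d.sample(rng))
        dstar = float(profile.dstar.sample(rng))
        if d < dstar:
            break
    else:
        raise RuntimeError("could not draw D < Dstar from this profile")
    f = float(profile.f.sample(rng))
    ddc = float(profile.ddc.sample(rng))
    alpha = float(profile.alpha.sample(rng))
    labs = {k: float(spec.sample(rng)) for k, spec in profile.labs.items()}
    age = float(profile.age_weeks.sample(rng))
    sex = "M" if rng.random() < profile.p_male else "F"
    return VirtualPatient(
        patient_id=patient_id,
        group=profile.group,
        age_weeks=age,
        sex=sex,
        bem=BiExpParams(S0=s0, D=d, Dstar=dstar, f=f),
        sem=StretchedExpParams(S0=s0, DDC=ddc, alpha=alpha),
        labs=labs,
    )


def add_rician_noise(signal, sigma: float, rng: np.random.Generator):
    """Rician-corrupted magnitude: sqrt((S + e1)^2 + e2^2), e ~ N(0, sigma).

    sigma = 0 returns the input unchanged.  Models the magnitude of a complex
    image whose real channel holds the true signal and both channels carry
    independent Gaussian noise; biases low-SNR values upward (Rayleigh floor
    sigma*sqrt(pi/2) at S = 0).
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    s = np.asarray(signal, dtype=float)
    if sigma == 0:
        return s if s.ndim else float(s)
    e1 = rng.normal(0.0, sigma, s.shape)
    e2 = rng.normal(0.0, sigma, s.shape)
    out = np.sqrt((s + e1) ** 2 + e2 ** 2)
    return out if s.ndim else float(out)


# Fixed high-pseudo-diffusion profile for vessel voxels: bright, strongly
# perfusion-dominated decay so ROI contamination would be visible.
_VESSEL = dict(f=0.8, dstar=80e-3, d=1.5e-3, brightness=1.6)


def _liver_ellipse(matrix: int, z_frac: float) -> tuple[float, float, float, float]:
    """Centre and semi-axes of the liver ellipse for one slice.

    The slab tapers slightly toward the end slices so slices differ.
    """
    taper = 1.0 - 0.25 * abs(z_frac - 0.5) * 2
    cx, cy = matrix * 0.5, matrix * 0.45
    return cx, cy, matrix * 0.36 * taper, matrix * 0.24 * taper


def _noiseless_liver_curve(patient: VirtualPatient, cfg: CohortConfig) -> np.ndarray:
    b = cfg.scheme.as_array()
    if cfg.signal_model == "bem":
        return np.asarray(bem_signal(patient.bem, b))
    return np.asarray(sem_signal(patient.sem, b))


def synthesize_dwi_volume(patient: VirtualPatient, cfg: CohortConfig,
                          rng: np.random.Generator,
                          max_roi_retries: int = 200):
    """Build one patient's 4D DWI phantom plus masks.

    Returns ``(dwi, liver_mask, vessel_mask, roi_masks)`` where ``dwi`` has
    shape (matrix, matrix, n_slices, n_b) and ``roi_masks`` is a list of
    ``cfg.rois_per_patient`` boolean volumes, each confined to one distinct
    slice and guaranteed vessel-free.  Liver voxels decay with the patient's
    ground-truth model, vessel voxels with a fixed high-pseudo-diffusion
    profile, background is zero; Rician noise is applied last, per voxel per
    b-image.
    """
    m, nz = cfg.matrix, cfg.n_slices
    b = cfg.scheme.as_array()
    nb = len(b)
    yy, xx = np.meshgrid(np.arange(m), np.arange(m), indexing="ij")

    liver = np.zeros((m, m, nz), dtype=bool)
    for z in range(nz):
        cx, cy, ax, ay = _liver_ellipse(m, z / max(nz - 1, 1))
        liver[..., z] = ((xx - cx) / ax) ** 2 + ((yy - cy) / ay) ** 2 <= 1.0

    # 2-4 roughly vertical cylindrical vessels inside the liver
    vessel = np.zeros_like(liver)
    n_vessels = int(rng.integers(2, 5))
    cx0, cy0, ax0, ay0 = _liver_ellipse(m, 0.5)
    for _ in range(n_vessels):
        r = rng.uniform(1.5, 3.5)
        vx = cx0 + rng.uniform(-0.6, 0.6) * ax0
        vy = cy0 + rng.uniform(-0.6, 0.6) * ay0
        disk = (xx - vx) ** 2 + (yy - vy) ** 2 <= r ** 2
        vessel |= disk[..., None] & liver
    liver_par = liver & ~vessel  # parenchyma

    liver_curve = _noiseless_liver_curve(patient, cfg)
    vp = _VESSEL
    vessel_curve = cfg.s0 * vp["brightness"] * (
        vp["f"] * np.exp(-b * vp["dstar"]) + (1 - vp["f"]) * np.exp(-b * vp["d"])
    )

    dwi = np.zeros((m, m, nz, nb), dtype=float)
    dwi[liver_par] = liver_curve
    dwi[vessel] = vessel_curve
    dwi = add_rician_noise(dwi, cfg.noise_sigma, rng)

    # ROIs: one circle per distinct slice, inside parenchyma, vessel-free
    roi_slices = rng.choice(nz, size=cfg.rois_per_patient, replace=False)
    roi_masks = []
    for z in sorted(int(z) for z in roi_slices):
        cx, cy, ax, ay = _liver_ellipse(m, z / max(nz - 1, 1))
        placed = False
        radius = cfg.roi_radius_px
        for attempt in range(max_roi_retries):
            if attempt and attempt % 50 == 0:
                radius *= 0.8  # shrink if the liver is too vessel-crowded
            ox = cx + rng.uniform(-0.4, 0.4) * ax
            oy = cy + rng.uniform(-0.4, 0.4) * ay
            disk = (xx - ox) ** 2 + (yy - oy) ** 2 <= radius ** 2
            if disk.any() and np.all(liver_par[..., z][disk]):
                roi = np.zeros_like(liver)
                roi[..., z] = disk
                roi_masks.append(roi)
                placed = True
                break
        if not placed:
            raise RuntimeError(
                f"could not place a vessel-free ROI on slice {z} "
                f"after {max_roi_retries} attempts"
            )
    return dwi, liver_par, vessel, roi_masks


def simulate_roi_curves(patient: VirtualPatient, cfg: CohortConfig,
                        rng: np.random.Generator,
                        voxels_per_roi: int = 49) -> list[SignalCurve]:
    """ROI-mean signal curves without synthesizing a full volume.

    For each of the patient's ROIs, draws ``voxels_per_roi`` independent
    Rician-noised copies of the patient's noiseless liver curve and averages
    them — statistically what an ROI mean over homogeneous parenchyma is.
    This is the fast path used for cohort-scale simulation studies.
    """
    clean = _noiseless_liver_curve(patient, cfg)
    curves = []
    for _ in range(cfg.rois_per_patient):
        vox = add_rician_noise(np.tile(clean, (voxels_per_roi, 1)),
                               cfg.noise_sigma, rng)
        curves.append(SignalCurve(cfg.scheme, tuple(vox.mean(axis=0))))
    return curves


def sample_cohort(cfg: CohortConfig,
                  profiles: dict[str, GroupParameterProfile] | None = None
                  ) -> list[VirtualPatient]:
    """Draw the full virtual cohort (n_ba BA then n_nonba non-BA patients)."""
    profiles = profiles or DEFAULT_PROFILES
    patients = []
    for i in range(cfg.n_ba + cfg.n_nonba):
        group = "BA" if i < cfg.n_ba else "non-BA"
        rng = cfg.patient_rng(i)
        patients.append(
            sample_patient(profiles[group], f"P{i + 1:03d}", rng, s0=cfg.s0)
        )
    return patients


def _clinical_frame(patients: list[VirtualPatient]) -> pd.DataFrame:
    rows = []
    for p in patients:
        row = {"patient_id": p.patient_id, "group": p.group,
               "age_weeks": round(p.age_weeks, 1), "sex": p.sex}
        row.update({k: round(v, 1) for k, v in p.labs.items()})
        rows.append(row)
    return pd.DataFrame(rows)


def _ground_truth_frame(patients: list[VirtualPatient]) -> pd.DataFrame:
    return pd.DataFrame([
        {"patient_id": p.patient_id, "group": p.group, "S0": p.bem.S0,
         "D": p.bem.D, "Dstar": p.bem.Dstar, "f": p.bem.f,
         "DDC": p.sem.DDC, "alpha": p.sem.alpha}
        for p in patients
    ])


def generate_cohort(cfg: CohortConfig, out_dir: str | Path,
                    profiles: dict[str, GroupParameterProfile] | None = None
                    ) -> list[VirtualPatient]:
    """Write a full synthetic cohort to disk and return the patients.

    Layout: ``<out>/<patient_id>/{dwi.nii.gz,dwi.bval,liver_mask.nii.gz,
    roi_slice1.nii.gz,roi_slice2.nii.gz,...}`` plus ``<out>/clinical.csv``
    and ``<out>/ground_truth.csv``.  NIfTI volumes use a diagonal RAS affine
    with the configured pixel size and slice thickness; masks are uint8 0/1.
    Fully reproducible from ``cfg.seed``.
    """
    import nibabel as nib

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    patients = sample_cohort(cfg, profiles)
    affine = np.diag([cfg.pixdim_mm, cfg.pixdim_mm, cfg.slice_thickness_mm, 1.0])

    for i, patient in enumerate(patients):
        rng = cfg.patient_rng(10_000 + i)  # volume stream separate from draws
        dwi, liver, vessel, rois = synthesize_dwi_volume(patient, cfg, rng)
        pdir = out / patient.patient_id
        pdir.mkdir(exist_ok=True)
        nib.save(nib.Nifti1Image(dwi.astype(np.float32), affine), pdir / "dwi.nii.gz")
        (pdir / "dwi.bval").write_text(
            " ".join(str(int(b)) for b in cfg.b_values) + "\n")
        nib.save(nib.Nifti1Image(liver.astype(np.uint8), affine),
                 pdir / "liver_mask.nii.gz")
        nib.save(nib.Nifti1Image(vessel.astype(np.uint8), affine),
                 pdir / "vessel_mask.nii.gz")
        for j, roi in enumerate(rois, start=1):
            nib.save(nib.Nifti1Image(roi.astype(np.uint8), affine),
                     pdir / f"roi_slice{j}.nii.gz")

    _clinical_frame(patients).to_csv(out / "clinical.csv", index=False)
    _ground_truth_frame(patients).to_csv(out / "ground_truth.csv", index=False)
    return patients
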