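"""Synthetic multi-channel phantom cohorts with ground-truth lesion masks.

The generator stands in for multiparametric prostate MRI: each slice has
three co-registered channels (a T2W-like anatomy channel, an ADC-like channel
where lesions are dark, a high-b-value-DWI-like channel where lesions are
bright). A gland-shaped elliptical region with smooth texture forms the
background; lesions are randomly deformed blobs spanning one to four
contiguous slices so that lesion-level 3D metrics are meaningful.

The ``difficulty`` knob scales lesion contrast-to-noise down linearly
(contrast multiplied by ``1 - difficulty``), so per-patient difficulty drawn
across [0, 1] yields cohorts whose coarse-segmentation quality spans the
full Dice range — exactly the heterogeneity a quality-regression gate must
learn to rank.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import nibabel as nib
import numpy as np
from scipy import ndimage

from .errors import ConfigurationError
from .preprocessing_io import BinaryMask, MultiModalSlice

__all__ = [
    "PhantomSpec", "PhantomPatient", "PhantomCohort",
    "generate_phantom", "generate_cohort", "write_patient_nifti",
    "write_cohort_nifti", "SLICE_THICKNESS_MM",
]

SLICE_THICKNESS_MM = 3.0
SPLITS = ("train", "val", "test")


@dataclass(frozen=True)
class PhantomSpec:
    """Stated world of the phantom generator.

    ``contrast_per_channel`` holds signed lesion intensity offsets: the first
    channel is mildly variable, the second negative (lesions dark, ADC-like),
    the third positive (lesions bright, DWI-like). Effective lesion contrast
    is ``contrast * (1 - difficulty)``.
    """

    image_size: int = 128
    lesion_count_range: tuple[int, int] = (0, 3)
    lesion_radius_range: tuple[float, float] | None = None
    contrast_per_channel: tuple[float, float, float] = (0.20, -0.40, 0.50)
    noise_sd: float = 0.08
    difficulty: float = 0.0
    spacing_mm: tuple[float, float] = (0.5, 0.5)
    seed: int = 0

    def __post_init__(self):
        if self.image_size < 32:
            raise ConfigurationError("image_size must be >= 32")
        lo, hi = self.lesion_count_range
        if not (0 <= lo <= hi):
            raise ConfigurationError("lesion_count_range must be a non-negative interval")
        if self.lesion_radius_range is None:
            object.__setattr__(self, "lesion_radius_range",
                               (max(2.0, 0.03 * self.image_size), 0.065 * self.image_size))
        rlo, rhi = self.lesion_radius_range
        if not (0 < rlo <= rhi):
            raise ConfigurationError("lesion_radius_range must be a positive interval")
        if rhi >= self.image_size / 4:
            raise ConfigurationError("lesion_radius_range upper end must be < image_size/4")
        if self.noise_sd <= 0:
            raise ConfigurationError("noise_sd must be > 0")
        if not 0.0 <= self.difficulty <= 1.0:
            raise ConfigurationError("difficulty must lie in [0, 1]")
        if self.contrast_per_channel[1] >= 0:
            raise ConfigurationError("contrast_per_channel[1] must be negative (dark lesions)")
        if self.contrast_per_channel[2] <= 0:
            raise ConfigurationError("contrast_per_channel[2] must be positive (bright lesions)")


@dataclass
class PhantomPatient:
    patient_id: str
    difficulty: float
    split: str
    slices: list[tuple[MultiModalSlice, BinaryMask]] = field(default_factory=list)

    def gt_volume(self) -> np.ndarray:
        """(S, H, W) boolean stack of ground-truth masks."""
        return np.stack([m.pixels for _, m in self.slices])


@dataclass
class PhantomCohort:
    spec: PhantomSpec
    patients: list[PhantomPatient] = field(default_factory=list)

    def normalized(self) -> "PhantomCohort":
        """Copy with per-patient channel normalisation applied (model input)."""
        from .preprocessing_io import normalize_patient
        out = []
        for p in self.patients:
            out.append(PhantomPatient(patient_id=p.patient_id,
                                      difficulty=p.difficulty, split=p.split,
                                      slices=normalize_patient(p.slices)))
        return PhantomCohort(spec=self.spec, patients=out)

    def split(self, name: str) -> list[PhantomPatient]:
        if name not in SPLITS:
            raise ValueError(f"unknown split {name!r}")
        return [p for p in self.patients if p.split == name]

    def slices(self, split_name: str) -> list[tuple[MultiModalSlice, BinaryMask]]:
        return [pair for p in self.split(split_name) for pair in p.slices]


# -- geometry helpers ------------------------------------------------------

def _gland_params(spec: PhantomSpec, rng: np.random.Generator) -> dict:
    n = spec.image_size
    return {
        "center": n / 2 + rng.uniform(-0.04, 0.04, size=2) * n,
        "semiaxes": rng.uniform(0.32, 0.40, size=2) * n,
        "angle": rng.uniform(0, np.pi),
        "texture_seed": int(rng.integers(0, 2**31 - 1)),
    }


def _gland_mask(spec: PhantomSpec, g: dict) -> np.ndarray:
    n = spec.image_size
    rr, cc = np.mgrid[0:n, 0:n].astype(np.float64)
    dr, dc = rr - g["center"][0], cc - g["center"][1]
    ca, sa = np.cos(g["angle"]), np.sin(g["angle"])
    u = ca * dr + sa * dc
    v = -sa * dr + ca * dc
    return (u / g["semiaxes"][0]) ** 2 + (v / g["semiaxes"][1]) ** 2 <= 1.0


def _blob_mask(n: int, center: np.ndarray, radius: float,
               amps: np.ndarray, phases: np.ndarray) -> np.ndarray:
    """Ellipse-like blob: radius modulated by low-frequency harmonics."""
    rr, cc = np.mgrid[0:n, 0:n].astype(np.float64)
    dr, dc = rr - center[0], cc - center[1]
    dist = np.hypot(dr, dc)
    theta = np.arctan2(dr, dc)
    mod = 1.0
    for k, (a, ph) in enumerate(zip(amps, phases), start=2):
        mod = mod + a * np.cos(k * theta + ph)
    return dist <= radius * mod


def _lesion_geometry(spec: PhantomSpec, rng: np.random.Generator, g: dict) -> dict:
    n = spec.image_size
    rlo, rhi = spec.lesion_radius_range
    # keep lesion centres inside the gland interior
    for _ in range(50):
        offs = rng.uniform(-0.6, 0.6, size=2)
        center = g["center"] + offs * g["semiaxes"]
        if np.all(center > 2) and np.all(center < n - 2):
            break
    return {
        "center": center,
        "radius": float(rng.uniform(rlo, rhi)),
        "amps": rng.uniform(0.0, 0.25, size=2),
        "phases": rng.uniform(0, 2 * np.pi, size=2),
    }


def _render_slice(spec: PhantomSpec, g: dict, lesion_mask: np.ndarray,
                  noise_rng: np.random.Generator, difficulty: float,
                  patient_id: str = "", slice_index: int = 0
                  ) -> tuple[MultiModalSlice, BinaryMask]:
    n = spec.image_size
    gland = _gland_mask(spec, g)
    lesion_mask = lesion_mask & gland
    tex_rng = np.random.default_rng(g["texture_seed"])
    channels = np.empty((n, n, 3), dtype=np.float64)
    scale = 1.0 - difficulty
    for c in range(3):
        base = np.where(gland, 0.55, 0.15).astype(np.float64)
        texture = ndimage.gaussian_filter(tex_rng.normal(0, 1.0, (n, n)), sigma=n / 16)
        base += 0.05 * texture * gland
        base[lesion_mask] += spec.contrast_per_channel[c] * scale
        base += noise_rng.normal(0.0, spec.noise_sd, (n, n))
        channels[:, :, c] = base
    sl = MultiModalSlice(pixels=channels.astype(np.float32),
                         spacing_mm=spec.spacing_mm,
                         patient_id=patient_id, slice_index=slice_index)
    return sl, BinaryMask(pixels=lesion_mask, spacing_mm=spec.spacing_mm)


# -- public generators -----------------------------------------------------

def generate_phantom(spec: PhantomSpec,
                     rng: np.random.Generator | None = None
                     ) -> tuple[MultiModalSlice, BinaryMask]:
    """One phantom slice with its ground-truth mask.

    All geometry and noise derive from ``rng`` (defaulting to
    ``default_rng(spec.seed)``); ``spec.difficulty`` only scales contrast, so
    two specs differing only in difficulty share identical geometry and noise
    under the same seed.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    g = _gland_params(spec, rng)
    lo, hi = spec.lesion_count_range
    count = int(rng.integers(lo, hi + 1))
    lesion = np.zeros((spec.image_size, spec.image_size), dtype=bool)
    for _ in range(count):
        geo = _lesion_geometry(spec, rng, g)
        lesion |= _blob_mask(spec.image_size, geo["center"], geo["radius"],
                             geo["amps"], geo["phases"])
    return _render_slice(spec, g, lesion, rng, spec.difficulty)


def _split_sizes(n: int, fractions: tuple[float, float, float]) -> list[int]:
    raw = [f * n for f in fractions]
    sizes = [int(np.floor(r)) for r in raw]
    remainder = n - sum(sizes)
    order = np.argsort([s - r for s, r in zip(sizes, raw)])  # largest deficit first
    for i in range(remainder):
        sizes[order[i % 3]] += 1
    return sizes


def generate_cohort(spec: PhantomSpec, n_patients: int,
                    slices_per_patient: int = 8,
                    split_fractions: tuple[float, float, float] = (0.6, 0.1, 0.3),
                    difficulty_range: tuple[float, float] = (0.02, 0.98),
                    ) -> PhantomCohort:
    """Seeded phantom cohort with patient-level splits and 3D lesions.

    Per-patient difficulty is a shuffled even grid over ``difficulty_range``
    (default almost the full [0, 1]), so a default cohort spans easy to
    near-impossible cases. Each lesion extends over 1-4 contiguous slices
    with an ellipsoid-like radius profile. Splits are disjoint on a patient
    basis with sizes matching the fractions to within rounding.
    """
    if n_patients < 3:
        raise ConfigurationError("n_patients must be >= 3 to form three splits")
    if abs(sum(split_fractions) - 1.0) > 1e-9:
        raise ConfigurationError("split_fractions must sum to 1")
    if slices_per_patient < 1:
        raise ConfigurationError("slices_per_patient must be >= 1")

    rng = np.random.default_rng(spec.seed)
    lo, hi = difficulty_range
    if not 0.0 <= lo <= hi <= 1.0:
        raise ConfigurationError("difficulty_range must be ordered within [0, 1]")
    difficulties = rng.permutation(np.linspace(lo, hi, n_patients))
    sizes = _split_sizes(n_patients, split_fractions)
    split_labels = np.repeat(SPLITS, sizes)
    split_labels = split_labels[rng.permutation(n_patients)]

    patients = []
    for i in range(n_patients):
        pid = f"phantom{i:03d}"
        prng = np.random.default_rng([spec.seed, i])
        g = _gland_params(spec, prng)
        lo, hi = spec.lesion_count_range
        count = int(prng.integers(lo, hi + 1))
        lesions = []
        for _ in range(count):
            geo = _lesion_geometry(spec, prng, g)
            extent = int(prng.integers(1, min(4, slices_per_patient) + 1))
            start = int(prng.integers(0, slices_per_patient - extent + 1))
            lesions.append((geo, start, extent))
        slices = []
        for s in range(slices_per_patient):
            lesion = np.zeros((spec.image_size, spec.image_size), dtype=bool)
            for geo, start, extent in lesions:
                if not start <= s < start + extent:
                    continue
                p = (s - start + 1) / (extent + 1) * 2.0 - 1.0  # in (-1, 1)
                r = geo["radius"] * np.sqrt(max(1.0 - p * p, 0.0))
                if r < 1.0:
                    continue
                lesion |= _blob_mask(spec.image_size, geo["center"], r,
                                     geo["amps"], geo["phases"])
            sl, mask = _render_slice(spec, g, lesion, prng,
                                     difficulty=float(difficulties[i]),
                                     patient_id=pid, slice_index=s)
            slices.append((sl, mask))
        patients.append(PhantomPatient(patient_id=pid,
                                       difficulty=float(difficulties[i]),
                                       split=str(split_labels[i]), slices=slices))
    return PhantomCohort(spec=spec, patients=patients)


# -- NIfTI writer (shared loader path with real data) ----------------------

def write_patient_nifti(patient: PhantomPatient, out_dir: str) -> dict[str, str]:
    """Write per-modality volumes plus a label volume; returns the paths."""
    os.makedirs(out_dir, exist_ok=True)
    first_slice = patient.slices[0][0]
    sr, sc = first_slice.spacing_mm
    affine = np.diag([sr, sc, SLICE_THICKNESS_MM, 1.0])
    stack = np.stack([sl.pixels for sl, _ in patient.slices], axis=2)  # (H, W, S, 3)
    labels = np.stack([m.pixels for _, m in patient.slices], axis=2).astype(np.uint8)
    paths = {}
    for c, name in enumerate(("t2w", "adc", "dwi_hb")):
        path = os.path.join(out_dir, f"{patient.patient_id}_{name}.nii.gz")
        nib.save(nib.Nifti1Image(stack[:, :, :, c].astype(np.float32), affine), path)
        paths[name] = path
    label_path = os.path.join(out_dir, f"{patient.patient_id}_label.nii.gz")
    nib.save(nib.Nifti1Image(labels, affine), label_path)
    paths["label"] = label_path
    return paths


def write_cohort_nifti(cohort: PhantomCohort, out_dir: str) -> dict[str, dict[str, str]]:
    return {p.patient_id: write_patient_nifti(p, out_dir) for p in cohort.patients}
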