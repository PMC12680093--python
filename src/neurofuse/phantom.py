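"""Synthetic multimodal brain-MRI phantom cohorts.

Emulates a paired DWI (three b-values: b0, b500, b1000) + T2 acquisition:
a smooth ellipsoidal "brain" with additive Gaussian noise, into which benign
or malignant lesions are rendered with class-dependent morphology and
modality-dependent contrast:

* benign — smooth ellipsoidal lesion, bright on T2, mild b1000 contrast;
* malignant — boundary perturbed by low-order spherical harmonics, strongly
  hyperintense on b1000 (the diffusion-restriction analogue), milder on T2.

Intensities are arbitrary units in [0, 1] before noise.  The T2 grid is
acquired at twice the DWI in-plane resolution with the same slice count, so
a factor-2 space-to-depth downsampling aligns the two modalities exactly.

With ``noise_sigma=0`` the cohort is separable by construction: lesion
presence distinguishes normal from tumor, and the mean b1000 contrast inside
the lesion separates benign from malignant.  Training sanity checks rely on
this guarantee.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

LABELS = {"normal": 0, "benign": 1, "malignant": 2}
LABEL_NAMES = {v: k for k, v in LABELS.items()}

# class-conditional lesion contrast (arbitrary units; jittered ±20% per patient)
_BENIGN_T2, _BENIGN_B1000 = 0.30, 0.10
_MALIGNANT_T2, _MALIGNANT_B1000 = 0.15, 0.35
# baseline tissue intensity per channel inside the brain ellipsoid
_BASE = {"b0": 0.80, "b500": 0.55, "b1000": 0.35, "t2": 0.60}


class PhantomError(ValueError):
    """Raised for invalid phantom configurations or unplaceable lesions."""


@dataclass(frozen=True)
class PhantomConfig:
    """Cohort geometry and composition.

    Defaults mirror the study cohort this generator stands in for:
    70 patients (20 normal, 22 benign, 28 malignant), DWI 18x256x256,
    T2 18x512x512.
    """

    n_normal: int = 20
    n_benign: int = 22
    n_malignant: int = 28
    dwi_shape: tuple[int, int, int] = (18, 256, 256)
    t2_shape: tuple[int, int, int] = (18, 512, 512)
    noise_sigma: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if min(self.n_normal, self.n_benign, self.n_malignant) < 0:
            raise PhantomError("class counts must be non-negative")
        d, h, w = self.dwi_shape
        td, th, tw = self.t2_shape
        if td != d:
            raise PhantomError(f"modalities must share depth: DWI {d}, T2 {td}")
        if (th, tw) != (2 * h, 2 * w):
            raise PhantomError(
                f"T2 in-plane size must be 2x DWI: DWI {(h, w)}, T2 {(th, tw)}")

    @property
    def n_total(self) -> int:
        return self.n_normal + self.n_benign + self.n_malignant


def tiny_config(n_normal=4, n_benign=4, n_malignant=4, noise_sigma=0.0,
                seed=0) -> PhantomConfig:
    """Reduced-resolution preset for CPU-scale tests: DWI 8x64x64, T2 8x128x128."""
    return PhantomConfig(n_normal, n_benign, n_malignant,
                         dwi_shape=(8, 64, 64), t2_shape=(8, 128, 128),
                         noise_sigma=noise_sigma, seed=seed)


@dataclass(frozen=True)
class LesionSpec:
    """One lesion, in DWI voxel coordinates."""

    center: tuple[float, float, float]  # (z, y, x)
    radius: float                       # in-plane semi-axis, voxels
    radius_z: float                     # through-plane semi-axis, voxels
    boundary_irregularity: float        # in [0, 1]
    contrast_t2: float
    contrast_b1000: float
    harmonic_coeffs: tuple[float, ...] = field(default=())

    def __post_init__(self):
        if self.radius <= 0 or self.radius_z <= 0:
            raise PhantomError("lesion radius must be positive")
        if not 0.0 <= self.boundary_irregularity <= 1.0:
            raise PhantomError("boundary_irregularity must lie in [0, 1]")


@dataclass
class PatientSample:
    """One patient's paired volumes: DWI (3, D, H, W) and T2 (1, D, 2H, 2W)."""

    patient_id: str
    dwi: np.ndarray
    t2: np.ndarray
    label: int
    lesion_mask: np.ndarray  # boolean (D, H, W) on the DWI grid; all-False if normal
    lesion: LesionSpec | None = None


# ----------------------------------------------------------------- geometry
def _brain_mask_and_profile(shape, scale_hw=1.0):
    """Ellipsoidal brain support and a smooth radial intensity falloff.

    scale_hw: in-plane voxels per DWI voxel (2 for the T2 grid), so the brain
    occupies the same physical region on both grids.
    """
    D, H, W = shape
    z, y, x = np.ogrid[:D, :H, :W]
    cz, cy, cx = (D - 1) / 2, (H - 1) / 2, (W - 1) / 2
    az, ay, ax = 0.45 * D, 0.42 * H, 0.42 * W
    rho2 = (((z - cz) / az) ** 2 + ((y - cy) / ay) ** 2 + ((x - cx) / ax) ** 2)
    mask = rho2 <= 1.0
    profile = np.clip(1.0 - 0.25 * rho2, 0.0, None)
    return mask, profile


_HARMONICS = 6  # number of real l=2 spherical-harmonic terms + one l=1 term


def _angular_perturbation(ux, uy, uz, coeffs):
    """Smooth function on the unit sphere from low-order real harmonics."""
    basis = (
        ux * uy, uy * uz, uz * ux,
        ux * ux - uy * uy, 3 * uz * uz - 1.0,
        ux,  # l=1 term breaks the inversion symmetry
    )
    out = np.zeros_like(ux)
    for c, b in zip(coeffs, basis):
        out += c * b
    return out


def _lesion_mask(shape, lesion: LesionSpec, scale_hw=1.0):
    """Boolean mask of the lesion on a grid with the given in-plane scale."""
    D, H, W = shape
    cz, cy, cx = lesion.center
    cy, cx = cy * scale_hw, cx * scale_hw
    r, rz = lesion.radius * scale_hw, lesion.radius_z
    z, y, x = np.ogrid[:D, :H, :W]
    dz, dy, dx = (z - cz) / rz, (y - cy) / r, (x - cx) / r
    rho = np.sqrt(dz * dz + dy * dy + dx * dx)
    with np.errstate(invalid="ignore", divide="ignore"):
        ux, uy, uz = (np.broadcast_to(a / np.maximum(rho, 1e-9), (D, H, W))
                      for a in (dx, dy, dz))
    pert = _angular_perturbation(ux, uy, uz, lesion.harmonic_coeffs)
    local = 1.0 + lesion.boundary_irregularity * pert
    return rho <= np.clip(local, 0.3, 2.0)


def _sample_lesion(rng: np.random.Generator, label: int,
                   config: PhantomConfig) -> LesionSpec:
    D, H, W = config.dwi_shape
    radius = rng.uniform(0.08, 0.14) * min(H, W)
    # through-plane extent capped so even a maximally perturbed boundary can
    # sit inside the brain ellipsoid (semi-axis 0.45*D) on thin volumes
    radius_z = min(max(1.25, radius * 2.0 * D / min(H, W)), 0.2 * D)
    if label == LABELS["benign"]:
        irregularity = rng.uniform(0.0, 0.2)
        c_t2 = _BENIGN_T2 * rng.uniform(0.8, 1.2)
        c_b1000 = _BENIGN_B1000 * rng.uniform(0.8, 1.2)
    else:
        irregularity = rng.uniform(0.5, 0.8)
        c_t2 = _MALIGNANT_T2 * rng.uniform(0.8, 1.2)
        c_b1000 = _MALIGNANT_B1000 * rng.uniform(0.8, 1.2)
    coeffs = tuple(rng.normal(0, 0.35, _HARMONICS))

    cz, cy, cx = (D - 1) / 2, (H - 1) / 2, (W - 1) / 2
    az, ay, ax = 0.45 * D, 0.42 * H, 0.42 * W
    for _ in range(64):
        # candidate center inside the brain, margin for the full lesion extent
        f = rng.uniform(-0.45, 0.45, size=3)
        center = (cz + f[0] * az, cy + f[1] * ay, cx + f[2] * ax)
        ext = 1.0 + irregularity  # worst-case radial stretch
        ok = (abs(center[0] - cz) + radius_z * ext <= 0.95 * az
              and abs(center[1] - cy) + radius * ext <= 0.95 * ay
              and abs(center[2] - cx) + radius * ext <= 0.95 * ax)
        if ok:
            return LesionSpec(center, radius, radius_z, irregularity,
                              c_t2, c_b1000, coeffs)
    raise PhantomError(
        f"lesion of radius {radius:.1f} cannot be placed inside the brain "
        f"ellipsoid for shape {config.dwi_shape}")


# ---------------------------------------------------------------- generation
def generate_patient(label: int, config: PhantomConfig, seed: int) -> PatientSample:
    """Render one patient; deterministic for fixed (label, config, seed)."""
    if label not in (0, 1, 2):
        raise PhantomError(f"label must be 0, 1 or 2, got {label!r}")
    rng = np.random.default_rng(seed)

    dwi_mask, dwi_prof = _brain_mask_and_profile(config.dwi_shape)
    t2_mask, t2_prof = _brain_mask_and_profile(config.t2_shape, scale_hw=2.0)

    dwi = np.stack([
        np.clip(_BASE[ch] * dwi_prof, 0, 1) * dwi_mask
        for ch in ("b0", "b500", "b1000")
    ]).astype(np.float32)
    t2 = (np.clip(_BASE["t2"] * t2_prof, 0, 1) * t2_mask)[None].astype(np.float32)

    lesion = None
    lesion_mask = np.zeros(config.dwi_shape, dtype=bool)
    if label != LABELS["normal"]:
        lesion = _sample_lesion(rng, label, config)
        lesion_mask = _lesion_mask(config.dwi_shape, lesion)
        t2_lesion = _lesion_mask(config.t2_shape, lesion, scale_hw=2.0)
        # diffusion restriction grows with b-value; b0 barely affected
        dwi[0][lesion_mask] += 0.10 * lesion.contrast_b1000
        dwi[1][lesion_mask] += 0.50 * lesion.contrast_b1000
        dwi[2][lesion_mask] += lesion.contrast_b1000
        t2[0][t2_lesion] += lesion.contrast_t2

    if config.noise_sigma > 0:
        dwi += rng.normal(0, config.noise_sigma, dwi.shape).astype(np.float32)
        t2 += rng.normal(0, config.noise_sigma, t2.shape).astype(np.float32)

    return PatientSample(patient_id=f"sub-{seed:08d}", dwi=dwi, t2=t2,
                         label=label, lesion_mask=lesion_mask, lesion=lesion)


def generate_cohort(config: PhantomConfig) -> list[PatientSample]:
    """Generate the full cohort; per-patient seeds derive from config.seed."""
    labels = ([LABELS["normal"]] * config.n_normal
              + [LABELS["benign"]] * config.n_benign
              + [LABELS["malignant"]] * config.n_malignant)
    seeds = np.random.SeedSequence(config.seed).generate_state(
        max(1, len(labels)), dtype=np.uint32) >> 1
    samples = []
    for i, label in enumerate(labels):
        s = generate_patient(label, config, int(seeds[i]))
        s.patient_id = f"sub-{i + 1:03d}"
        samples.append(s)
    return samples
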