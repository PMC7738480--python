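"""Synthetic folded-shell phantoms.

Each phantom is a two-hemisphere volume on an isotropic grid (0.75 mm by
default): a smooth "inner" ellipsoidal body per hemisphere surrounded by a
thin corrugated shell that plays the role of the cortical plate. The outer
and inner boundaries are radially perturbed ellipsoids,

    rho(direction) <= 1 + (A / r(direction)) * sin(f * theta) * sin(f * phi)

where rho is the ellipsoid-normalized radius, r(direction) the local radius
in mm, A the fold amplitude in mm and f the angular fold frequency. Both
surfaces share the corrugation phase, so shell thickness stays close to
`shell_thickness_mm` while the folded surface area grows with amplitude.
A scalar `complexity` in [0, 1] drives amplitude and frequency together and
stands in for gestational age.

The intensity channel is the label-wise mean image (background, inner,
shell) blurred to a partial-volume FWHM and corrupted with i.i.d. Gaussian
noise. Labels follow the 5-label scheme: 0 background, 1/2 left/right inner
volume of the cortical plate, 3/4 left/right cortical plate. The left
hemisphere occupies the low-x half-space; a voxel exactly on the
mid-sagittal plane counts as left.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

BG, IN_L, IN_R, CP_L, CP_R = 0, 1, 2, 3, 4
FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))  # 0.42466


@dataclass(frozen=True)
class PhantomSpec:
    """Parametric description of one synthetic two-hemisphere volume."""

    grid_shape: tuple = (96, 96, 96)
    voxel_mm: float = 0.75
    hemisphere_centers: tuple = ((19.44, 36.0, 36.0), (52.56, 36.0, 36.0))
    hemisphere_radii: tuple = ((12.0, 16.0, 14.0), (12.0, 16.0, 14.0))
    shell_thickness_mm: float = 2.0
    fold_amplitude_mm: float = 1.0
    fold_frequency: float = 5.0
    intensity_means: tuple = (0.05, 1.0, 0.55)  # background, inner, shell
    noise_sd: float = 0.08
    blur_fwhm_mm: float = 1.0
    seed: int = 0

    def validate(self) -> "PhantomSpec":
        if self.shell_thickness_mm <= 0:
            raise ValueError("shell_thickness_mm must be > 0")
        if self.voxel_mm <= 0:
            raise ValueError("voxel_mm must be > 0")
        for radii in self.hemisphere_radii:
            if min(radii) <= self.shell_thickness_mm:
                raise ValueError("hemisphere radii must exceed shell_thickness_mm")
            if self.fold_amplitude_mm >= min(radii) - self.shell_thickness_mm:
                raise ValueError("fold amplitude must be smaller than the inner radius")
        if self.fold_amplitude_mm < 0:
            raise ValueError("fold_amplitude_mm must be >= 0")
        # hemispheres must stay inside their half-spaces (and hence disjoint)
        mid_mm = 0.5 * (self.grid_shape[0] - 1) * self.voxel_mm
        (c0, c1), (r0, r1) = self.hemisphere_centers, self.hemisphere_radii
        a = self.fold_amplitude_mm
        if c0[0] + r0[0] + a > mid_mm or c1[0] - r1[0] - a < mid_mm:
            raise ValueError("hemispheres overlap the mid-sagittal plane")
        return self

    @classmethod
    def default(cls, grid: int = 96, voxel_mm: float = 0.75, **overrides) -> "PhantomSpec":
        """Scale the default geometry to a cubic grid of `grid` voxels."""
        extent = grid * voxel_mm
        s = extent / 72.0  # reference geometry sized for 96 voxels at 0.75 mm
        radii = tuple(round(v * s, 3) for v in (12.0, 16.0, 14.0))
        spec = cls(
            grid_shape=(grid, grid, grid),
            voxel_mm=voxel_mm,
            hemisphere_centers=(
                (round(0.27 * extent, 3), extent / 2, extent / 2),
                (round(0.73 * extent, 3), extent / 2, extent / 2),
            ),
            hemisphere_radii=(radii, radii),
        )
        return replace(spec, **overrides) if overrides else spec

    def scalars(self) -> dict:
        """Flat scalar summary for cohort metadata tables."""
        d = {
            "voxel_mm": self.voxel_mm,
            "shell_thickness_mm": self.shell_thickness_mm,
            "fold_amplitude_mm": self.fold_amplitude_mm,
            "fold_frequency": self.fold_frequency,
            "noise_sd": self.noise_sd,
            "blur_fwhm_mm": self.blur_fwhm_mm,
            "seed": self.seed,
        }
        for h, radii in enumerate(self.hemisphere_radii):
            for ax, v in zip("xyz", radii):
                d[f"radius_{h}{ax}"] = v
        return d


@dataclass
class PhantomCase:
    """A generated phantom: intensity volume, label volume and provenance."""

    intensity: np.ndarray
    labels: np.ndarray
    complexity: float
    spec: PhantomSpec
    case_id: str = "case"

    @property
    def voxel_mm(self) -> float:
        return self.spec.voxel_mm

    def brain_mask(self, dilate_voxels: int = 2) -> np.ndarray:
        """Binary brain mask: the labeled region dilated a little."""
        mask = self.labels > 0
        if dilate_voxels > 0:
            mask = ndimage.binary_dilation(mask, iterations=dilate_voxels)
        return mask.astype(np.uint8)


def _corrugated_interior(coords_mm, center, radii, amplitude_mm, frequency):
    """Boolean mask of the corrugated-ellipsoid interior."""
    d = [coords_mm[ax] - center[ax] for ax in range(3)]
    u = [d[ax] / radii[ax] for ax in range(3)]
    rho = np.sqrt(u[0] ** 2 + u[1] ** 2 + u[2] ** 2)
    if amplitude_mm == 0:
        return rho <= 1.0
    dist_mm = np.sqrt(d[0] ** 2 + d[1] ** 2 + d[2] ** 2)
    safe_rho = np.maximum(rho, 1e-9)
    r_dir = np.maximum(dist_mm / safe_rho, 1e-9)  # local mm radius along the ray
    theta = np.arctan2(u[1], u[0])
    phi = np.arccos(np.clip(u[2] / safe_rho, -1.0, 1.0))
    wave = np.sin(frequency * theta) * np.sin(frequency * phi)
    return rho <= 1.0 + (amplitude_mm / r_dir) * wave


def generate_phantom(spec: PhantomSpec, complexity: float = float("nan")) -> PhantomCase:
    """Build one phantom volume deterministically from its spec."""
    spec.validate()
    nx, ny, nz = spec.grid_shape
    idx = np.indices(spec.grid_shape, dtype=np.float32)
    coords_mm = idx * spec.voxel_mm

    labels = np.zeros(spec.grid_shape, dtype=np.uint8)
    t = spec.shell_thickness_mm
    for h, (center, radii) in enumerate(zip(spec.hemisphere_centers, spec.hemisphere_radii)):
        outer = _corrugated_interior(
            coords_mm, center, radii, spec.fold_amplitude_mm, spec.fold_frequency
        )
        inner = _corrugated_interior(
            coords_mm,
            center,
            tuple(r - t for r in radii),
            spec.fold_amplitude_mm,
            spec.fold_frequency,
        )
        labels[inner] = IN_L + h
        labels[outer & ~inner] = CP_L + h

    means = np.asarray(spec.intensity_means, dtype=np.float32)
    tissue = np.zeros(spec.grid_shape, dtype=np.uint8)  # 0 bg, 1 inner, 2 shell
    tissue[(labels == IN_L) | (labels == IN_R)] = 1
    tissue[(labels == CP_L) | (labels == CP_R)] = 2
    intensity = means[tissue]
    if spec.blur_fwhm_mm > 0:
        sigma_vox = spec.blur_fwhm_mm * FWHM_TO_SIGMA / spec.voxel_mm
        intensity = ndimage.gaussian_filter(intensity, sigma=sigma_vox)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        intensity = intensity + rng.normal(0.0, spec.noise_sd, size=intensity.shape).astype(
            np.float32
        )
    return PhantomCase(
        intensity=intensity.astype(np.float32),
        labels=labels,
        complexity=float(complexity),
        spec=spec,
    )


#: default sampling intervals for cohort generation (per-field (lo, hi))
DEFAULT_RANGES: dict = {
    "complexity": (0.1, 0.9),
    "shell_thickness_mm": (1.6, 2.4),
    "radius_scale": (0.92, 1.08),
    "noise_sd": (0.06, 0.10),
    "blur_fwhm_mm": (0.8, 1.2),
}

#: complexity -> folding parameters (gestational-age surrogate mapping)
FOLD_AMPLITUDE_SPAN = (0.3, 1.8)  # mm
FOLD_FREQUENCY_SPAN = (3.0, 8.0)


def complexity_to_folds(complexity: float, scale: float = 1.0) -> tuple[float, float]:
    """Map the gestational-age surrogate to fold amplitude (mm) and frequency.

    `scale` shrinks the amplitude with the overall brain size so small
    phantoms keep geometrically valid (non-self-intersecting) folds.
    """
    a0, a1 = FOLD_AMPLITUDE_SPAN
    f0, f1 = FOLD_FREQUENCY_SPAN
    return scale * (a0 + complexity * (a1 - a0)), f0 + complexity * (f1 - f0)


def generate_cohort(
    n: int,
    ranges: dict | None = None,
    seed: int = 0,
    grid: int = 96,
    voxel_mm: float = 0.75,
) -> tuple[list[PhantomCase], pd.DataFrame]:
    """Sample `n` phantom cases from per-field intervals with one master seed.

    Returns the cases plus a metadata table (case id, seed, complexity and
    the sampled spec scalars) used downstream for stratified fold
    assignment.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    ranges = {**DEFAULT_RANGES, **(ranges or {})}
    for key, (lo, hi) in ranges.items():
        if hi < lo:
            raise ValueError(f"empty range for {key!r}: ({lo}, {hi})")
    rng = np.random.default_rng(seed)
    base = PhantomSpec.default(grid=grid, voxel_mm=voxel_mm)

    def draw(key):
        lo, hi = ranges[key]
        return float(lo if hi == lo else rng.uniform(lo, hi))

    scale = grid * voxel_mm / 72.0
    cases, rows = [], []
    for i in range(n):
        complexity = draw("complexity")
        amplitude, frequency = complexity_to_folds(complexity, scale=scale)
        rscale = draw("radius_scale")
        spec = replace(
            base,
            hemisphere_radii=tuple(
                tuple(r * rscale for r in radii) for radii in base.hemisphere_radii
            ),
            shell_thickness_mm=draw("shell_thickness_mm"),
            fold_amplitude_mm=amplitude,
            fold_frequency=frequency,
            noise_sd=draw("noise_sd"),
            blur_fwhm_mm=draw("blur_fwhm_mm"),
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        case = generate_phantom(spec, complexity=complexity)
        case.case_id = f"case{i:03d}"
        cases.append(case)
        rows.append({"case_id": case.case_id, "complexity": complexity, **spec.scalars()})
    return cases, pd.DataFrame(rows)


def ellipsoid_shell_volume_mm3(radii, thickness: float) -> float:
    """Analytic volume of the shell between two nested ellipsoids."""
    a, b, c = radii
    t = thickness
    return 4.0 / 3.0 * np.pi * (a * b * c - (a - t) * (b - t) * (c - t))


# -- NIfTI / CSV interfaces ----------------------------------------------------


def write_case(case: PhantomCase, out_dir: str | Path) -> tuple[Path, Path]:
    """Write the intensity/label pair as NIfTI with voxel spacing in the header."""
    import nibabel as nib

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    affine = np.diag([case.voxel_mm] * 3 + [1.0])
    ipath = out_dir / f"{case.case_id}_intensity.nii"
    lpath = out_dir / f"{case.case_id}_labels.nii"
    nib.save(nib.Nifti1Image(case.intensity.astype(np.float32), affine), ipath)
    nib.save(nib.Nifti1Image(case.labels.astype(np.uint8), affine), lpath)
    return ipath, lpath


def read_case(intensity_path: str | Path, labels_path: str | Path) -> PhantomCase:
    import nibabel as nib

    img = nib.load(str(intensity_path))
    lab = nib.load(str(labels_path))
    voxel = float(img.header.get_zooms()[0])
    spec = PhantomSpec.default(grid=img.shape[0], voxel_mm=voxel)
    return PhantomCase(
        intensity=np.asarray(img.dataobj, dtype=np.float32),
        labels=np.asarray(lab.dataobj, dtype=np.uint8),
        complexity=float("nan"),
        spec=spec,
        case_id=Path(intensity_path).stem.replace("_intensity", ""),
    )
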