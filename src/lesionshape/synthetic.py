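"""Synthetic paired lesion cohorts: ground truth + resolution degradation.

Real glioma T2-hyperintense areas are irregular, densely folded bodies
with tendril-like extensions along white-matter tracts, occasionally
spreading through the corpus callosum to the opposite hemisphere as a
thin bridge. The generator emulates this at the *segmentation* level (no
MR signal physics):

* a star-convex core — a lobulated ball whose surface is carved by
  narrow, deep fissure arcs (``spike_amplitude`` scales the relief; the
  fissures carry most of the surface complexity at little volume cost);
* capsule-shaped tendrils roughly aligned with a random "tract" axis,
  plus optionally a thin bridge capsule ending in a distal blob
  (cross-midline spread). These extensions are infiltrative tissue with
  lower T2 contrast than the core.

Observation at a given scanner resolution is simulated as blur-then-
threshold of the contrast image: convolution with the acquisition's
point-spread function, sampling onto the (possibly anisotropic) scan
grid at a random sub-voxel offset, and thresholding. Narrow fissures are
filled in and low-contrast extensions drop below threshold at coarse
resolution — the partial-volume and contrast mechanisms by which
clinical scans underestimate lesion extent and complexity.

Everything is a pure function of its spec and seed; paired cohorts are
fully reproducible from a single master seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import EmptyMaskError, SyntheticSpecError
from .mask import STRUCT_26, LesionMask, ensure_margin, write_mask

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


# -- specifications ---------------------------------------------------------


#: Internal geometry of the star-convex core. Lobes are broad positive
#: radius bumps (lobulated outline); fissures are narrow negative grooves
#: carved along random great-circle arcs (deep folds: large surface area,
#: little volume — the structures a coarse acquisition fills in).
_LOBE_COUNT = 6
_LOBE_WIDTH_RANGE = (0.30, 0.60)      # radians
_LOBE_GAIN = 0.35                     # lobes grow slower than fissures cut
_FISSURE_ARC_RANGE = (1.2, 2.6)       # radians of arc length
_FISSURE_DEPTH_RANGE = (0.5, 1.0)     # fraction of amp * base_radius
_FISSURE_CAP = 1.3                    # cap on summed fissure depth
_CORE_FLOOR = 0.12                    # min radius as fraction of base


@dataclass(frozen=True)
class SyntheticLesionSpec:
    """Parameters of one ground-truth lesion.

    ``spike_amplitude`` is the complexity dial: 0 gives a plain ball;
    larger values deepen narrow surface fissures and grow broad lobes,
    scaled by ``base_radius``. ``spike_count`` is the number of fissure
    arcs. Tendrils and the optional bridge are capsules (line segments
    with a radius); all lengths are mm.

    Tendrils, bridge and the bridge's distal blob are *extensions*:
    infiltrative tissue whose T2 contrast is lower than the lesion core
    (``extension_intensity`` on a core-normalised scale). A high-quality
    acquisition still detects them; under a coarse point-spread function
    their blurred intensity drops below the segmentation threshold and
    they vanish — the mechanism by which clinical scans underestimate
    tract-aligned tumour extension.
    """

    base_radius: float = 15.0
    spike_amplitude: float = 0.4
    spike_count: int = 12
    tendril_count: int = 2
    tendril_length: float = 12.0
    tendril_radius: float = 2.0
    bridge: bool = False
    bridge_radius: float = 1.0
    bridge_length: float = 25.0
    extension_intensity: float = 0.7
    fissure_width_mm: tuple[float, float] = (0.8, 1.8)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.base_radius <= 0:
            raise SyntheticSpecError("base_radius must be positive")
        if not 0.0 <= self.spike_amplitude <= 1.0:
            raise SyntheticSpecError("spike_amplitude must lie in [0, 1]")
        if self.tendril_radius >= self.base_radius:
            raise SyntheticSpecError("tendril_radius must be < base_radius")
        if min(self.spike_count, self.tendril_count,
               self.tendril_length, self.tendril_radius,
               self.bridge_radius, self.bridge_length) < 0:
            raise SyntheticSpecError("negative geometry parameter")
        if not 0.0 < self.extension_intensity <= 1.0:
            raise SyntheticSpecError(
                "extension_intensity must lie in (0, 1]"
            )
        if self.fissure_width_mm[0] <= 0 \
                or self.fissure_width_mm[1] < self.fissure_width_mm[0]:
            raise SyntheticSpecError("invalid fissure_width_mm range")


@dataclass(frozen=True)
class AcquisitionSpec:
    """Parameters of the resolution-degradation simulator.

    ``spacing`` is the acquisition voxel size (mm per axis),
    ``psf_fwhm`` the Gaussian point-spread full width at half maximum per
    axis (partial-volume blur; slice-direction FWHM is typically larger
    than the slice spacing). The sampling grid is shifted by a random
    sub-voxel offset drawn from ``seed``, emulating arbitrary scan
    positioning.
    """

    spacing: tuple[float, float, float]
    psf_fwhm: tuple[float, float, float]
    segmentation_threshold: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.spacing) <= 0:
            raise SyntheticSpecError("spacing must be positive")
        if min(self.psf_fwhm) < 0:
            raise SyntheticSpecError("psf_fwhm must be non-negative")
        if not 0.0 < self.segmentation_threshold < 1.0:
            raise SyntheticSpecError(
                "segmentation_threshold must lie in (0, 1)"
            )


# -- elementary shapes ------------------------------------------------------


def ball_mask(radius_mm: float, spacing_mm: float,
              label: str = "ball") -> LesionMask:
    """A digital ball centred on the grid: the convex reference phantom."""
    if radius_mm <= 0 or spacing_mm <= 0:
        raise SyntheticSpecError("radius and spacing must be positive")
    n = int(np.ceil(radius_mm / spacing_mm)) + 2
    ax = (np.arange(-n, n + 1) * spacing_mm).astype(np.float32)
    x, y, z = np.meshgrid(ax, ax, ax, indexing="ij", sparse=True)
    grid = (x * x + y * y + z * z) <= radius_mm ** 2
    affine = np.diag([spacing_mm] * 3 + [1.0])
    affine[:3, 3] = -n * spacing_mm
    return ensure_margin(LesionMask(grid=grid, affine=affine, label=label))


def _unit_vectors(rng: np.random.Generator, n: int) -> np.ndarray:
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def _capsule_fill(grid: np.ndarray, origin: np.ndarray, h: float,
                  p0: np.ndarray, p1: np.ndarray, radius: float) -> None:
    """Set voxels within ``radius`` of segment p0-p1 (world mm, in place)."""
    lo_w = np.minimum(p0, p1) - radius - h
    hi_w = np.maximum(p0, p1) + radius + h
    lo = np.maximum(np.floor((lo_w - origin) / h).astype(int), 0)
    hi = np.minimum(np.ceil((hi_w - origin) / h).astype(int) + 1,
                    np.array(grid.shape))
    if np.any(lo >= hi):
        return
    axes = [origin[i] + h * np.arange(lo[i], hi[i]) for i in range(3)]
    x, y, z = np.meshgrid(*axes, indexing="ij", sparse=True)
    seg = p1 - p0
    seg_len2 = float(seg @ seg)
    px, py, pz = x - p0[0], y - p0[1], z - p0[2]
    if seg_len2 > 0:
        tpar = (px * seg[0] + py * seg[1] + pz * seg[2]) / seg_len2
        tpar = np.clip(tpar, 0.0, 1.0)
    else:
        tpar = 0.0
    dx = px - tpar * seg[0]
    dy = py - tpar * seg[1]
    dz = pz - tpar * seg[2]
    inside = (dx * dx + dy * dy + dz * dz) <= radius ** 2
    sub = grid[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    np.logical_or(sub, inside, out=sub)


def _radius_table(rng: np.random.Generator, spec: SyntheticLesionSpec,
                  n_theta: int = 180, n_phi: int = 360) -> np.ndarray:
    """Angular radius field r(theta, phi) of the star-convex core, mm.

    r = R * (1 + amp * (lobe_gain * L - F)) with L a sum of broad
    positive bumps and F a sum of narrow grooves along great-circle
    arcs, floored at a small core radius so the body stays star-convex
    (hence one connected component).
    """
    R, amp = spec.base_radius, spec.spike_amplitude
    lobe_dirs = _unit_vectors(rng, _LOBE_COUNT)
    lobe_widths = rng.uniform(*_LOBE_WIDTH_RANGE, size=_LOBE_COUNT)
    lobe_amps = rng.uniform(0.3, 1.0, size=_LOBE_COUNT)
    n_fis = max(spec.spike_count, 0)
    fis_frames = _unit_vectors(rng, 2 * max(n_fis, 1))
    # Groove widths are physical (mm): their visibility depends on the
    # acquisition PSF, not on lesion size.
    fis_widths = rng.uniform(*spec.fissure_width_mm,
                             size=max(n_fis, 1)) / R
    fis_lengths = rng.uniform(*_FISSURE_ARC_RANGE, size=max(n_fis, 1))
    fis_depths = rng.uniform(*_FISSURE_DEPTH_RANGE, size=max(n_fis, 1))

    theta = np.linspace(0.0, np.pi, n_theta)
    phi = np.linspace(-np.pi, np.pi, n_phi)
    tg, pg = np.meshgrid(theta, phi, indexing="ij")
    dirs = np.stack(
        [np.sin(tg) * np.cos(pg), np.sin(tg) * np.sin(pg), np.cos(tg)],
        axis=-1,
    ).reshape(-1, 3).astype(np.float32)

    field = np.zeros(dirs.shape[0], dtype=np.float32)
    if amp > 0:
        lobe = np.zeros_like(field)
        for u, w, a in zip(lobe_dirs, lobe_widths, lobe_amps):
            ang = np.arccos(np.clip(dirs @ u.astype(np.float32), -1, 1))
            lobe += a * np.exp(-0.5 * (ang / w) ** 2)
        fis = np.zeros_like(field)
        for j in range(n_fis):
            e1 = fis_frames[2 * j]
            e2 = fis_frames[2 * j + 1] - (fis_frames[2 * j + 1] @ e1) * e1
            e2 /= np.linalg.norm(e2)
            ts = np.arange(0.0, fis_lengths[j], 0.04)
            arc = (np.cos(ts)[:, None] * e1
                   + np.sin(ts)[:, None] * e2).astype(np.float32)
            cos_d = np.clip(dirs @ arc.T, -1, 1).max(axis=1)
            ang = np.arccos(cos_d)
            fis += fis_depths[j] * np.exp(-0.5 * (ang / fis_widths[j]) ** 2)
        np.minimum(fis, _FISSURE_CAP, out=fis)
        field = _LOBE_GAIN * lobe - fis
    r = R * (1.0 + amp * field)
    np.maximum(r, _CORE_FLOOR * R, out=r)
    return r.reshape(n_theta, n_phi)


def _voxelize(spec: SyntheticLesionSpec,
              grid_spacing: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(core grid, extension grid, affine): the two tissue classes.

    The core is the star-convex fissured body; extensions are the
    tendril/bridge/blob capsules (lower-contrast infiltrative tissue).
    """
    if grid_spacing <= 0:
        raise SyntheticSpecError("grid_spacing must be positive")
    if grid_spacing > spec.base_radius / 10.0:
        raise SyntheticSpecError(
            f"grid_spacing {grid_spacing} too coarse for base_radius "
            f"{spec.base_radius} (need <= base_radius/10 for fidelity)"
        )
    rng = np.random.default_rng(spec.seed)
    R = spec.base_radius
    h = float(grid_spacing)

    r_table = _radius_table(rng, spec)
    tract_axis = _unit_vectors(rng, 1)[0]
    t_n = max(spec.tendril_count, 1)
    tendril_jitter = rng.normal(scale=0.35, size=(t_n, 3))
    tendril_signs = np.where(np.arange(t_n) % 2 == 0, 1.0, -1.0)

    r_min = float(r_table.min())
    r_max = float(r_table.max())
    reach = r_max
    if spec.tendril_count > 0:
        reach = max(reach, R + spec.tendril_length + spec.tendril_radius)
    blob_radius = 0.25 * R
    if spec.bridge:
        reach = max(reach, R + spec.bridge_length + blob_radius)
    n = int(np.ceil((reach + 2 * h) / h))
    ax = (np.arange(-n, n + 1) * h).astype(np.float32)
    x, y, z = np.meshgrid(ax, ax, ax, indexing="ij", sparse=True)
    rho2 = x * x + y * y + z * z
    core = rho2 <= r_min ** 2

    if r_max > r_min:
        # Only the shell r_min < rho <= r_max needs the angular lookup.
        shell = (rho2 > r_min ** 2) & (rho2 <= r_max ** 2)
        idx = np.argwhere(shell)
        if idx.size:
            pts = (idx - n) * h
            rho = np.linalg.norm(pts, axis=1)
            theta = np.arccos(np.clip(pts[:, 2] / rho, -1.0, 1.0))
            phi = np.arctan2(pts[:, 1], pts[:, 0])
            coords = np.stack([
                theta / np.pi * (r_table.shape[0] - 1),
                (phi + np.pi) / (2 * np.pi) * (r_table.shape[1] - 1),
            ])
            r_local = ndimage.map_coordinates(
                r_table, coords, order=1, mode="nearest")
            core[tuple(idx[rho <= r_local].T)] = True

    origin = np.full(3, -n * h)
    centre = np.zeros(3)
    ext = np.zeros_like(core)
    if spec.tendril_count > 0:
        for i in range(spec.tendril_count):
            d = tendril_signs[i] * tract_axis + tendril_jitter[i]
            d = d / np.linalg.norm(d)
            # Rooted at the centre so the union is always connected.
            p1 = centre + (R + spec.tendril_length) * d
            _capsule_fill(ext, origin, h, centre.copy(), p1,
                          spec.tendril_radius)
    if spec.bridge:
        p1 = centre + (R + spec.bridge_length) * tract_axis
        _capsule_fill(ext, origin, h, centre.copy(), p1, spec.bridge_radius)
        _capsule_fill(ext, origin, h, p1, p1, blob_radius)
    ext &= ~core

    affine = np.diag([h, h, h, 1.0])
    affine[:3, 3] = origin
    return core, ext, affine


def generate_lesion(spec: SyntheticLesionSpec,
                    grid_spacing: float) -> LesionMask:
    """Voxelize one ground-truth lesion at isotropic ``grid_spacing`` mm.

    Deterministic given ``spec`` (including its seed); the result is a
    single 26-connected component centred at world origin.
    """
    mask, _ = generate_lesion_image(spec, grid_spacing)
    return mask


def generate_lesion_image(
    spec: SyntheticLesionSpec, grid_spacing: float
) -> tuple[LesionMask, np.ndarray]:
    """Ground-truth mask plus its core-normalised contrast image.

    The image is 1 inside the lesion core, ``extension_intensity`` inside
    tendril/bridge extensions and 0 outside; it is what the acquisition
    simulator blurs and thresholds, so low-contrast extensions can drop
    below threshold at coarse resolution while the binary truth keeps
    them.
    """
    core, ext, affine = _voxelize(spec, grid_spacing)
    union = core | ext
    labels, n_comp = ndimage.label(union, structure=STRUCT_26)
    if n_comp != 1:
        # Steep radius fields can leave sub-voxel walls that voxelize as
        # stray one-to-few-voxel islets. Those are discretization dust and
        # are dropped; anything larger means the spec itself is degenerate.
        counts = np.bincount(labels.ravel())[1:]
        main = int(np.argmax(counts)) + 1
        if counts.sum() - counts[main - 1] > 0.01 * counts.sum():
            raise SyntheticSpecError(
                f"generated lesion fragmented into {n_comp} substantial "
                "components; increase tendril/bridge radius relative to "
                "grid_spacing"
            )
        keep = labels == main
        core &= keep
        ext &= keep
        union = core | ext
    mask = LesionMask(grid=union, affine=affine,
                      label=f"synthetic(seed={spec.seed})")
    intensity = core.astype(np.float32)
    np.maximum(intensity, spec.extension_intensity * ext, out=intensity)
    return mask, intensity


# -- acquisition degradation ------------------------------------------------


def degrade_acquisition(truth: LesionMask,
                        acq: AcquisitionSpec,
                        intensity: np.ndarray | None = None) -> LesionMask:
    """Observe a ground-truth mask at a coarser scanner resolution.

    Gaussian PSF blur of the contrast field (the binary mask, or the
    graded ``intensity`` image from :func:`generate_lesion_image`),
    sampling at the acquisition grid's voxel centres (randomly offset
    within one voxel), threshold at ``segmentation_threshold``. Thin or
    low-contrast structures (diameter below roughly the slice thickness)
    fall under a 0.5 threshold and disappear.
    """
    spacing = np.asarray(acq.spacing, dtype=float)
    truth_spacing = truth.spacing
    if np.any(spacing < truth_spacing - 1e-9):
        raise SyntheticSpecError(
            f"acquisition spacing {tuple(spacing)} finer than truth grid "
            f"{tuple(truth_spacing)}"
        )
    sigma_vox = (np.asarray(acq.psf_fwhm, dtype=float) * _FWHM_TO_SIGMA
                 / truth_spacing)
    if intensity is not None:
        if intensity.shape != truth.grid.shape:
            raise SyntheticSpecError(
                "intensity image must match the truth grid shape"
            )
        field = np.asarray(intensity, dtype=np.float32)
    else:
        field = truth.grid.astype(np.float32)
    if np.any(sigma_vox > 0):
        field = ndimage.gaussian_filter(field, sigma=sigma_vox)

    rng = np.random.default_rng(acq.seed)
    offset_frac = rng.uniform(0.0, 1.0, size=3)

    # World-space extent of the truth grid.
    shape = np.array(truth.grid.shape, dtype=float)
    corners = np.array([[0, 0, 0], shape - 1], dtype=float)
    cc = np.array([[corners[b & 1, 0], corners[(b >> 1) & 1, 1],
                    corners[(b >> 2) & 1, 2]] for b in range(8)])
    world = truth.world_coordinates(cc)
    wmin, wmax = world.min(axis=0), world.max(axis=0)
    start = wmin - spacing + offset_frac * spacing
    count = np.ceil((wmax - start) / spacing).astype(int) + 2

    inv = np.linalg.inv(truth.affine)
    matrix = inv[:3, :3] * spacing
    offset = inv[:3, :3] @ start + inv[:3, 3]
    sampled = ndimage.affine_transform(
        field, matrix=matrix, offset=offset,
        output_shape=tuple(count), order=1,
        mode="constant", cval=0.0, prefilter=False,
    )
    grid = sampled >= acq.segmentation_threshold
    if not grid.any():
        raise EmptyMaskError(
            "lesion fell entirely below threshold at this resolution"
        )
    affine = np.eye(4)
    affine[:3, :3] = np.diag(spacing)
    affine[:3, 3] = start
    return ensure_margin(LesionMask(grid=grid, affine=affine,
                                    label=truth.label))


# -- cohort scenarios -------------------------------------------------------


@dataclass(frozen=True)
class CohortScenario:
    """Distributions that one paired cohort is drawn from.

    Per subject, the lesion spec is sampled from uniform ranges; the same
    ground truth is then observed under ``highquality`` and ``clinical``
    acquisitions. ``truth_spacing`` is the isotropic voxelization grid of
    the ground truth and bounds voxelization error below both observation
    resolutions.
    """

    name: str
    truth_spacing: float
    base_radius_range: tuple[float, float]
    spike_amplitude_range: tuple[float, float]
    spike_count: int
    tendril_count_range: tuple[int, int]
    #: tendril length as a fraction of the drawn base radius, so small
    #: lesions are not dominated by their extensions
    tendril_length_rel_range: tuple[float, float]
    tendril_radius_range: tuple[float, float]
    bridge_probability: float
    bridge_radius: float
    bridge_length: float
    fissure_width_mm: tuple[float, float]
    highquality: AcquisitionSpec
    clinical: AcquisitionSpec
    analysis_spacing: float | None = None

    def draw_lesion_spec(self, rng: np.random.Generator,
                         seed: int) -> SyntheticLesionSpec:
        lo, hi = self.tendril_count_range
        base_radius = float(rng.uniform(*self.base_radius_range))
        return SyntheticLesionSpec(
            base_radius=base_radius,
            spike_amplitude=float(
                rng.uniform(*self.spike_amplitude_range)),
            spike_count=self.spike_count,
            tendril_count=int(rng.integers(lo, hi + 1)),
            tendril_length=base_radius * float(
                rng.uniform(*self.tendril_length_rel_range)),
            tendril_radius=float(rng.uniform(*self.tendril_radius_range)),
            bridge=bool(rng.random() < self.bridge_probability),
            bridge_radius=self.bridge_radius,
            bridge_length=self.bridge_length,
            fissure_width_mm=self.fissure_width_mm,
            seed=seed,
        )


#: The study conditions: 7T-like 0.75 mm isotropic observation versus a
#: clinical-like thick-slice acquisition of the same lesions.
#: The study conditions. The high-quality arm mimics a 7 T 3D T2 scan
#: (0.75 mm isotropic, ~1 mm effective PSF); the clinical arm a 1.5/3 T
#: multislice T2/FLAIR (fine in-plane recon grid but 5 mm slices). PSFs
#: model the segmentation-effective resolution — acquisition blur plus
#: the detail a rater can actually trace at that field strength — which
#: for clinical scans is far coarser than the recon voxel.
DEFAULT_SCENARIO = CohortScenario(
    name="default",
    truth_spacing=0.4,
    base_radius_range=(13.0, 25.0),
    spike_amplitude_range=(0.4, 0.8),
    spike_count=24,
    tendril_count_range=(1, 4),
    tendril_length_rel_range=(0.5, 0.8),
    tendril_radius_range=(2.0, 3.0),
    bridge_probability=0.3,
    bridge_radius=1.5,
    bridge_length=25.0,
    fissure_width_mm=(0.8, 1.8),
    highquality=AcquisitionSpec((0.75, 0.75, 0.75), (1.0, 1.0, 1.0)),
    clinical=AcquisitionSpec((0.4, 0.4, 5.0), (2.8, 2.8, 6.0)),
)

#: Zero-complexity control: plain balls observed twice with the SAME
#: acquisition geometry (independent grid offsets only), so the two arms
#: are exchangeable and the paired test's type-I error is well defined.
NULL_SCENARIO = dataclasses.replace(
    DEFAULT_SCENARIO,
    name="null",
    spike_amplitude_range=(0.0, 0.0),
    tendril_count_range=(0, 0),
    bridge_probability=0.0,
    clinical=DEFAULT_SCENARIO.highquality,
)

#: Scaled-down variant of the default conditions for replicate studies:
#: the same morphology and partial-volume mechanism on the smallest
#: lesions (13-15 mm radius) for which the fractal-dimension contrast
#: between the two acquisitions remains resolvable, with a coarser truth
#: grid and a 0.75 mm analysis grid to keep hundreds of replicate
#: cohorts affordable.
FAST_SCENARIO = CohortScenario(
    name="fast",
    truth_spacing=0.5,
    base_radius_range=(13.0, 15.0),
    spike_amplitude_range=(0.4, 0.8),
    spike_count=24,
    tendril_count_range=(1, 4),
    tendril_length_rel_range=(0.4, 0.6),
    tendril_radius_range=(2.0, 3.0),
    bridge_probability=0.3,
    bridge_radius=1.5,
    bridge_length=8.0,
    fissure_width_mm=(0.8, 1.8),
    highquality=AcquisitionSpec((0.75, 0.75, 0.75), (1.0, 1.0, 1.0)),
    clinical=AcquisitionSpec((0.75, 0.75, 5.0), (2.8, 2.8, 6.0)),
    analysis_spacing=0.5,
)

#: Zero-complexity balls observed twice with the same acquisition: the
#: type-I-error control scenario, sized for cheap mass replication.
FAST_NULL_SCENARIO = dataclasses.replace(
    FAST_SCENARIO,
    name="fast-null",
    base_radius_range=(8.0, 10.0),
    spike_amplitude_range=(0.0, 0.0),
    tendril_count_range=(0, 0),
    bridge_probability=0.0,
    clinical=FAST_SCENARIO.highquality,
    # plain balls need no sub-observation analysis grid; 0.75 mm keeps
    # hundreds of replicate cohorts cheap
    analysis_spacing=0.75,
)

SCENARIOS: dict[str, CohortScenario] = {
    s.name: s for s in (DEFAULT_SCENARIO, NULL_SCENARIO,
                        FAST_SCENARIO, FAST_NULL_SCENARIO)
}


# -- paired cohorts ---------------------------------------------------------


def _subject_seeds(master_seed: int, n_subjects: int) -> list[list[int]]:
    """Four child seeds (params, lesion, highquality, clinical) per subject."""
    ss = np.random.SeedSequence(master_seed)
    children = ss.spawn(n_subjects)
    return [
        [int(s) for s in child.generate_state(4) % (2 ** 31)]
        for child in children
    ]


def simulate_subject(
    scenario: CohortScenario, seeds: Sequence[int]
) -> tuple[LesionMask, LesionMask, LesionMask]:
    """(truth, highquality observation, clinical observation) for one subject."""
    param_seed, lesion_seed, hq_seed, cl_seed = seeds
    rng = np.random.default_rng(param_seed)
    spec = scenario.draw_lesion_spec(rng, seed=lesion_seed)
    truth, intensity = generate_lesion_image(spec, scenario.truth_spacing)
    hq = degrade_acquisition(
        truth, dataclasses.replace(scenario.highquality, seed=hq_seed),
        intensity=intensity)
    cl = degrade_acquisition(
        truth, dataclasses.replace(scenario.clinical, seed=cl_seed),
        intensity=intensity)
    return truth, hq, cl


def make_paired_cohort(
    n_subjects: int,
    scenario: CohortScenario | str,
    master_seed: int,
    out_dir: str | Path,
) -> Path:
    """Write a paired synthetic cohort to disk and return the manifest path.

    One NIfTI per subject per condition plus ``manifest.csv`` with columns
    ``subject_id,highquality_path,clinical_path``. Fully reproducible from
    ``master_seed``; the scenario parameters are recorded next to the
    manifest for provenance.
    """
    if isinstance(scenario, str):
        scenario = SCENARIOS[scenario]
    if n_subjects < 5:
        raise SyntheticSpecError("a paired cohort needs >= 5 subjects")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, seeds in enumerate(_subject_seeds(master_seed, n_subjects)):
        sid = f"sub{i + 1:03d}"
        _, hq, cl = simulate_subject(scenario, seeds)
        hq_path = out_dir / f"{sid}_highquality.nii"
        cl_path = out_dir / f"{sid}_clinical.nii"
        hq.label = f"{sid}/highquality"
        cl.label = f"{sid}/clinical"
        write_mask(hq, hq_path)
        write_mask(cl, cl_path)
        rows.append((sid, hq_path.name, cl_path.name))
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(
        rows, columns=["subject_id", "highquality_path", "clinical_path"]
    ).to_csv(manifest, index=False)
    params = out_dir / "scenario.txt"
    with open(params, "w") as fh:
        fh.write(f"scenario={scenario.name}\n")
        fh.write(f"master_seed={master_seed}\n")
        fh.write(f"n_subjects={n_subjects}\n")
        for f in dataclasses.fields(scenario):
            fh.write(f"{f.name}={getattr(scenario, f.name)}\n")
    return manifest


def replicate_rejection_rates(
    scenario: CohortScenario | str,
    n_subjects: int,
    n_replicates: int,
    master_seed: int,
    alpha: float = 0.05,
    markers: Sequence[str] | None = None,
    include: Sequence[str] = ("hull", "fractal"),
) -> pd.DataFrame:
    """Wilcoxon rejection rates over independent replicate cohorts.

    Simulates ``n_replicates`` paired cohorts (each with fresh seeds
    derived from ``master_seed``), runs the full marker + comparison
    pipeline on each, and tabulates how often each marker's two-sided
    test rejects at ``alpha``, split by the direction of the median
    difference. Under a null scenario the rate estimates the pipeline's
    type-I error; under an effect scenario, its power.
    """
    from .stats import compare_cohort

    if isinstance(scenario, str):
        scenario = SCENARIOS[scenario]
    seeds = np.random.SeedSequence(master_seed).generate_state(
        n_replicates, dtype=np.uint64) % (2 ** 31)
    counts: dict[str, dict[str, int]] = {}
    for seed in seeds:
        table = cohort_marker_table(n_subjects, scenario, int(seed),
                                    include=include)
        report = compare_cohort(table, alpha=alpha, markers=markers)
        for _, row in report.table.iterrows():
            rec = counts.setdefault(row["marker"], {
                "n_reject": 0, "n_reject_highquality_higher": 0,
                "n_reject_clinical_higher": 0})
            if row["significant"]:
                rec["n_reject"] += 1
                if row["median_highquality"] > row["median_clinical"]:
                    rec["n_reject_highquality_higher"] += 1
                else:
                    rec["n_reject_clinical_higher"] += 1
    rows = []
    for marker, rec in counts.items():
        rows.append({
            "marker": marker,
            "n_replicates": n_replicates,
            "rejection_rate": rec["n_reject"] / n_replicates,
            "rejection_rate_highquality_higher":
                rec["n_reject_highquality_higher"] / n_replicates,
            "rejection_rate_clinical_higher":
                rec["n_reject_clinical_higher"] / n_replicates,
        })
    return pd.DataFrame(rows)


def cohort_marker_table(
    n_subjects: int,
    scenario: CohortScenario | str,
    master_seed: int,
    include: Sequence[str] = ("hull", "fractal"),
) -> pd.DataFrame:
    """In-memory paired marker table for one simulated cohort.

    Skips all file I/O: each subject's pair of observations is fed
    straight into the marker pipeline. ``include`` restricts the marker
    groups (see :func:`lesionshape.markers.compute_markers`), which the
    replicate studies use to keep large simulations tractable.
    """
    from .markers import compute_markers, default_analysis_spacing
    from .stats import paired_table_from_markers

    if isinstance(scenario, str):
        scenario = SCENARIOS[scenario]
    if n_subjects < 5:
        raise SyntheticSpecError("a paired cohort needs >= 5 subjects")
    rows = []
    for i, seeds in enumerate(_subject_seeds(master_seed, n_subjects)):
        sid = f"sub{i + 1:03d}"
        _, hq, cl = simulate_subject(scenario, seeds)
        t = scenario.analysis_spacing or default_analysis_spacing(hq, cl)
        for condition, m in (("highquality", hq), ("clinical", cl)):
            ms = compute_markers(m, target_spacing=t, include=include)
            rows.append({"subject_id": sid, "condition": condition,
                         **ms.as_dict()})
    markers = pd.DataFrame(rows)
    return paired_table_from_markers(markers)
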