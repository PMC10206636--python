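"""Digital dual-modality lung phantom.

A ground-truth ventilation field on a fine isotropic grid — two ellipsoidal
"lungs" with spatially smooth gamma-law ventilation and ellipsoidal defects of
a known total cavity fraction — observed through two forward models:

* **SPECT-like**: optional axial Gaussian smear (a surrogate for the averaging
  over 15 min of tidal breathing), isotropic Gaussian PSF (default 12 mm
  FWHM, the reconstruction filter width), optional focal hot-spots (aerosol
  aggregation proximal to severe obstruction), volume-average resampling to a
  coarse isotropic grid (default 4.42 mm, 128x128 in-plane), count scaling and
  Poisson noise.
* **MRI-like**: volume-average resampling to an anisotropic grid (default
  3.125 x 3.125 x 15 mm, 128x128x16), a smooth multiplicative coil-bias field,
  and Rician noise (magnitude of a complex Gaussian) at a given SNR.

The truth grid (default 2 mm isotropic) is finer than both output grids, so
resampling is a genuinely degrading step. Every operation is a pure function
of its inputs and seed: the master seed spawns per-stage child streams by
fixed offsets, so the SPECT and MRI observations of one phantom are
reproducible independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage

from .io import CavityMask, VolumeGrid

FWHM_TO_SIGMA = 1.0 / 2.3548  # Gaussian sigma per unit FWHM

# fixed per-stage offsets for child seed streams
_STAGE_TRUTH = 1
_STAGE_SPECT = 2
_STAGE_MRI = 3


def _rng(seed: int, stage: int) -> np.random.Generator:
    return np.random.default_rng([int(seed) % (2**31), stage])


@dataclass
class PhantomSpec:
    """Geometry and intensity law of the ground-truth phantom.

    Lengths in mm. ``defect_contrast`` is the defect intensity as a fraction
    of the local ventilated intensity (0.05 means defects retain 5% of the
    signal they replace). Ventilated intensity is an i.i.d. gamma field,
    Gaussian-smoothed over ``smoothing_length_mm`` so that ventilation varies
    smoothly at the centimeter scale, as it does across real lung.
    """

    grid_shape: tuple[int, int, int] = (128, 128, 64)
    truth_spacing: float = 2.0  # mm, isotropic
    lung_semiaxes: tuple[float, float, float] = (45.0, 80.0, 55.0)  # mm per lung
    lung_gap: float = 30.0  # mm between lung centers' inner edges
    defect_fraction_target: float = 0.15
    defect_count: int = 4
    defect_contrast: float = 0.05
    gamma_shape: float = 16.0
    gamma_scale: float = 1.0 / 16.0  # mean ventilated intensity ~ 1
    smoothing_length_mm: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.defect_fraction_target <= 0.9):
            raise ValueError(
                f"defect_fraction_target must be in [0, 0.9], got {self.defect_fraction_target}"
            )
        if self.truth_spacing <= 0 or any(a <= 0 for a in self.lung_semiaxes):
            raise ValueError("all lengths must be > 0")
        if self.defect_count < 1:
            raise ValueError("defect_count must be >= 1")
        if not (0.0 <= self.defect_contrast < 1.0):
            raise ValueError("defect_contrast must be in [0, 1)")


@dataclass
class PhantomTruth:
    """Ground-truth ventilation field, cavity, defect mask, and true fraction."""

    truth_volume: VolumeGrid
    cavity: CavityMask
    defect_mask_true: np.ndarray
    true_defect_fraction: float

    def __post_init__(self) -> None:
        self.defect_mask_true = np.asarray(self.defect_mask_true).astype(bool)
        if np.any(self.defect_mask_true & ~self.cavity.mask):
            raise ValueError("true defect voxel outside cavity")


@dataclass
class SpectModel:
    """SPECT-like observation model parameters."""

    psf_fwhm: float = 12.0  # mm
    out_spacing: float = 4.42  # mm isotropic
    out_matrix: tuple[int, int] = (128, 128)  # in-plane; slices cover the truth extent
    out_slices: Optional[int] = None  # None -> computed from truth z extent
    mean_counts: float = 50.0  # target cavity mean, counts/voxel
    breathing_smear_sigma: float = 4.0  # mm, axial
    hotspot_count: int = 0
    hotspot_amplitude: float = 10.0  # local intensity multiplier at the focus
    hotspot_sigma_mm: float = 4.0  # spatial extent of a focus (~1 cm diameter)
    poisson: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.psf_fwhm < 0:
            raise ValueError("psf_fwhm must be >= 0")
        if self.poisson and self.mean_counts <= 0:
            raise ValueError("mean_counts must be > 0 when Poisson noise is enabled")


@dataclass
class MriModel:
    """MRI-like observation model parameters."""

    out_spacing: tuple[float, float, float] = (3.125, 3.125, 15.0)  # mm
    out_matrix: tuple[int, int, int] = (128, 128, 16)
    snr: float = 20.0
    bias_field_amplitude: float = 0.2  # peak fractional deviation of the bias field
    bias_field_length: float = 80.0  # mm correlation length
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.snr > 0:
            raise ValueError("snr must be > 0")
        if not (0.0 <= self.bias_field_amplitude <= 0.5):
            raise ValueError("bias_field_amplitude must be in [0, 0.5]")


# ---------------------------------------------------------------------------
# truth generation


def _ellipsoid_mask(shape, spacing, center_mm, semiaxes_mm) -> np.ndarray:
    coords = [
        (np.arange(n) + 0.5) * spacing - c
        for n, c in zip(shape, center_mm)
    ]
    gx, gy, gz = np.meshgrid(*coords, indexing="ij")
    a, b, c = semiaxes_mm
    return (gx / a) ** 2 + (gy / b) ** 2 + (gz / c) ** 2 <= 1.0


def _lung_cavity(spec: PhantomSpec) -> np.ndarray:
    """Two ellipsoidal lungs, mirrored about the midsagittal plane."""
    shape = spec.grid_shape
    sp = spec.truth_spacing
    fov = np.array(shape) * sp
    cx, cy, cz = fov / 2.0
    ax = spec.lung_semiaxes[0]
    offset = ax + spec.lung_gap / 2.0
    left = _ellipsoid_mask(shape, sp, (cx - offset, cy, cz), spec.lung_semiaxes)
    right = _ellipsoid_mask(shape, sp, (cx + offset, cy, cz), spec.lung_semiaxes)
    return left | right


def _ventilated_field(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Smooth positive ventilation intensity over the whole grid.

    An i.i.d. gamma field smoothed with a Gaussian kernel to set the spatial
    correlation length, then re-scaled so the marginal keeps the gamma law's
    mean and coefficient of variation (shape 16 -> CoV 0.25, the moderate
    heterogeneity of ventilated lung). Without the re-scale the smoothing
    would also flatten the marginal, leaving an unrealistically homogeneous
    ventilated compartment.
    """
    raw = rng.gamma(spec.gamma_shape, spec.gamma_scale, size=spec.grid_shape)
    sigma_vox = spec.smoothing_length_mm / spec.truth_spacing
    smooth = ndimage.gaussian_filter(raw, sigma=sigma_vox, mode="nearest")
    mu = spec.gamma_shape * spec.gamma_scale
    sd_target = np.sqrt(spec.gamma_shape) * spec.gamma_scale
    sd_now = smooth.std()
    if sd_now > 0:
        smooth = mu + (smooth - smooth.mean()) * (sd_target / sd_now)
    return np.clip(smooth, mu * 0.05, None)


def _defect_union(cavity: np.ndarray, centers_vox: np.ndarray,
                  semiaxes_vox: np.ndarray, scale: float) -> np.ndarray:
    shape = cavity.shape
    out = np.zeros(shape, dtype=bool)
    idx = [np.arange(n, dtype=float) for n in shape]
    gx, gy, gz = np.meshgrid(*idx, indexing="ij")
    for c, ax in zip(centers_vox, semiaxes_vox):
        a, b, cc = ax * scale
        out |= ((gx - c[0]) / a) ** 2 + ((gy - c[1]) / b) ** 2 + ((gz - c[2]) / cc) ** 2 <= 1.0
    return out & cavity


def make_phantom(spec: PhantomSpec) -> PhantomTruth:
    """Generate a ground-truth phantom with a known defect fraction.

    Defects are random non-overlapping-centered ellipsoids inside the cavity,
    with a single global size scale found by bisection so the realized
    defect fraction of the cavity is within 0.01 of the target. Deterministic
    for a fixed spec (including its seed).
    """
    rng = _rng(spec.seed, _STAGE_TRUTH)
    cavity_mask = _lung_cavity(spec)
    n_cavity = int(cavity_mask.sum())
    if n_cavity == 0:
        raise ValueError("phantom lungs do not fit the grid: empty cavity")

    vent = _ventilated_field(spec, rng)

    target = spec.defect_fraction_target
    tol = 0.01
    defect = np.zeros(spec.grid_shape, dtype=bool)
    frac = 0.0
    if target > 0:
        cav_idx = np.argwhere(cavity_mask)
        achieved = False
        for _attempt in range(20):
            centers = cav_idx[rng.choice(len(cav_idx), size=spec.defect_count, replace=False)]
            # anisotropic semi-axes, in voxels; base size scaled by bisection
            base = (target * n_cavity / spec.defect_count * 3.0 / (4.0 * np.pi)) ** (1 / 3.0)
            ratios = rng.uniform(0.6, 1.6, size=(spec.defect_count, 3))
            semiaxes = base * ratios
            lo_s, hi_s = 0.0, 1.0
            # grow hi until fraction exceeds target (or give up this attempt)
            for _ in range(30):
                frac = _defect_union(cavity_mask, centers, semiaxes, hi_s).sum() / n_cavity
                if frac >= target:
                    break
                hi_s *= 1.5
            if frac < target:
                continue
            for _ in range(60):
                mid = 0.5 * (lo_s + hi_s)
                d = _defect_union(cavity_mask, centers, semiaxes, mid)
                frac = d.sum() / n_cavity
                if abs(frac - target) <= tol * 0.5:
                    defect = d
                    achieved = True
                    break
                if frac > target:
                    hi_s = mid
                else:
                    lo_s = mid
            if achieved:
                break
        if not achieved:
            raise RuntimeError(
                f"could not place defects reaching fraction {target} with "
                f"defect_count={spec.defect_count} (voxelization too coarse)"
            )
        frac = defect.sum() / n_cavity

    field_vals = vent.copy()
    field_vals[~cavity_mask] = 0.0
    field_vals[defect] = spec.defect_contrast * vent[defect]

    truth = VolumeGrid(
        intensities=field_vals,
        voxel_spacing=(spec.truth_spacing,) * 3,
        modality="TRUTH",
        subject_id="phantom",
    )
    cav = CavityMask(mask=cavity_mask, voxel_spacing=(spec.truth_spacing,) * 3)
    out = PhantomTruth(
        truth_volume=truth,
        cavity=cav,
        defect_mask_true=defect,
        true_defect_fraction=float(frac),
    )
    if abs(out.true_defect_fraction - target) > tol:
        raise RuntimeError(
            f"realized defect fraction {out.true_defect_fraction:.4f} misses "
            f"target {target} beyond voxelization tolerance {tol}"
        )
    return out


# ---------------------------------------------------------------------------
# volume-average resampling (separable, exact overlap weights)


def _overlap_matrix(n_in: int, sp_in: float, n_out: int, sp_out: float) -> np.ndarray:
    """Row-stochastic (n_out, n_in) matrix averaging input cells into output cells.

    Input and output grids are centered on the same physical extent midpoint.
    Weights are exact 1-D cell-overlap lengths normalized by the covered
    length, so a constant field resamples to the same constant wherever the
    output cell is at least partly covered.
    """
    len_in = n_in * sp_in
    len_out = n_out * sp_out
    off = (len_in - len_out) / 2.0  # output origin in input coordinates (mm)
    edges_in = np.arange(n_in + 1) * sp_in
    edges_out = off + np.arange(n_out + 1) * sp_out
    lo = np.maximum(edges_out[:-1, None], edges_in[None, :-1])
    hi = np.minimum(edges_out[1:, None], edges_in[None, 1:])
    w = np.clip(hi - lo, 0.0, None)
    cover = w.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        w = np.where(cover > 0, w / cover, 0.0)
    return w


def resample_volume_average(data: np.ndarray, in_spacing, out_shape, out_spacing) -> np.ndarray:
    """Volume-average (box-integrate) a 3-D field onto a new grid."""
    in_spacing = np.broadcast_to(np.asarray(in_spacing, dtype=float), (3,))
    out_spacing = np.broadcast_to(np.asarray(out_spacing, dtype=float), (3,))
    out = np.asarray(data, dtype=float)
    for axis in range(3):
        m = _overlap_matrix(data.shape[axis], in_spacing[axis],
                            out_shape[axis], out_spacing[axis])
        out = np.moveaxis(np.tensordot(m, np.moveaxis(out, axis, 0), axes=(1, 0)), 0, axis)
    return out


def _resample_mask(mask: np.ndarray, in_spacing, out_shape, out_spacing) -> np.ndarray:
    """Majority-vote mask resampling: output voxel inside if > 50% covered."""
    frac = resample_volume_average(mask.astype(float), in_spacing, out_shape, out_spacing)
    return frac > 0.5


def _spect_out_shape(truth: PhantomTruth, model: SpectModel) -> tuple[int, int, int]:
    nx, ny = model.out_matrix
    if model.out_slices is not None:
        nz = model.out_slices
    else:
        z_extent = truth.truth_volume.shape[2] * truth.truth_volume.voxel_spacing[2]
        nz = max(1, int(np.ceil(z_extent / model.out_spacing)))
    return (nx, ny, nz)


def simulate_spect(truth: PhantomTruth, model: SpectModel) -> tuple[VolumeGrid, CavityMask]:
    """SPECT-like observation of a phantom.

    Pipeline: axial breathing smear -> Gaussian PSF -> hot-spot insertion ->
    volume-average resample -> scale cavity mean to ``mean_counts`` ->
    Poisson sampling (optional). The cavity mask is resampled by majority vote.
    """
    sp_in = truth.truth_volume.voxel_spacing
    if model.out_spacing < min(sp_in):
        raise ValueError("output grid must be coarser than the truth grid")
    rng = _rng(model.seed, _STAGE_SPECT)
    img = truth.truth_volume.intensities.copy()

    if model.breathing_smear_sigma > 0:
        img = ndimage.gaussian_filter1d(
            img, sigma=model.breathing_smear_sigma / sp_in[2], axis=2, mode="nearest"
        )
    if model.psf_fwhm > 0:
        sigma_mm = model.psf_fwhm * FWHM_TO_SIGMA
        img = ndimage.gaussian_filter(
            img, sigma=[sigma_mm / s for s in sp_in], mode="nearest"
        )
    if model.hotspot_count > 0:
        img = _insert_hotspots(img, truth.cavity.mask, sp_in, model, rng)

    out_shape = _spect_out_shape(truth, model)
    out_spacing = (model.out_spacing,) * 3
    coarse = resample_volume_average(img, sp_in, out_shape, out_spacing)
    cav_mask = _resample_mask(truth.cavity.mask, sp_in, out_shape, out_spacing)
    if not cav_mask.any():
        raise ValueError("output grid too coarse: resampled cavity is empty")

    cavity_mean = coarse[cav_mask].mean()
    if cavity_mean <= 0:
        raise ValueError("degenerate simulation: non-positive cavity mean")
    coarse *= model.mean_counts / cavity_mean
    if model.poisson:
        coarse = rng.poisson(np.clip(coarse, 0.0, None)).astype(float)

    vol = VolumeGrid(
        intensities=coarse,
        voxel_spacing=out_spacing,
        modality="SPECT",
        subject_id=truth.truth_volume.subject_id,
    )
    return vol, CavityMask(mask=cav_mask, voxel_spacing=out_spacing)


def _insert_hotspots(img: np.ndarray, cavity: np.ndarray, spacing,
                     model: SpectModel, rng: np.random.Generator) -> np.ndarray:
    """Add focal aerosol-aggregation spikes at random intra-cavity sites."""
    cav_idx = np.argwhere(cavity)
    picks = cav_idx[rng.choice(len(cav_idx), size=model.hotspot_count, replace=False)]
    bump = np.zeros_like(img)
    for p in picks:
        bump[tuple(p)] = 1.0
    sigma_vox = [model.hotspot_sigma_mm / s for s in spacing]
    bump = ndimage.gaussian_filter(bump, sigma=sigma_vox, mode="nearest")
    if bump.max() > 0:
        bump /= bump.max()
    # a focus dwarfs the brightest normal ventilation signal: amplitude is a
    # multiplier of the bright (99th percentile) cavity intensity
    anchor = np.percentile(img[cavity], 99)
    return img + model.hotspot_amplitude * anchor * bump


def _bias_field(shape, spacing, amplitude: float, length_mm: float,
                cavity: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Smooth multiplicative field: cavity mean 1, peak cavity deviation = amplitude."""
    if amplitude == 0:
        return np.ones(shape)
    noise = rng.standard_normal(shape)
    sigma_vox = [length_mm / s for s in spacing]
    smooth = ndimage.gaussian_filter(noise, sigma=sigma_vox, mode="nearest")
    dev = smooth - smooth[cavity].mean()
    peak = np.abs(dev[cavity]).max()
    if peak == 0:
        return np.ones(shape)
    fld = 1.0 + amplitude * dev / peak
    return fld / fld[cavity].mean()


def simulate_mri(truth: PhantomTruth, model: MriModel) -> tuple[VolumeGrid, CavityMask]:
    """MRI-like observation: resample -> multiplicative bias -> Rician noise."""
    sp_in = truth.truth_volume.voxel_spacing
    if min(model.out_spacing) < min(sp_in):
        raise ValueError("output grid must be coarser than the truth grid")
    rng = _rng(model.seed, _STAGE_MRI)

    out_shape = tuple(model.out_matrix)
    out_spacing = tuple(model.out_spacing)
    coarse = resample_volume_average(
        truth.truth_volume.intensities, sp_in, out_shape, out_spacing
    )
    cav_mask = _resample_mask(truth.cavity.mask, sp_in, out_shape, out_spacing)
    if not cav_mask.any():
        raise ValueError("output grid too coarse: resampled cavity is empty")

    bias = _bias_field(out_shape, out_spacing, model.bias_field_amplitude,
                       model.bias_field_length, cav_mask, rng)
    signal = coarse * bias

    sigma = signal[cav_mask].mean() / model.snr if np.isfinite(model.snr) else 0.0
    if sigma > 0:
        n1 = rng.normal(0.0, sigma, size=out_shape)
        n2 = rng.normal(0.0, sigma, size=out_shape)
        signal = np.sqrt((signal + n1) ** 2 + n2 ** 2)

    vol = VolumeGrid(
        intensities=signal,
        voxel_spacing=out_spacing,
        modality="MRI",
        subject_id=truth.truth_volume.subject_id,
    )
    return vol, CavityMask(mask=cav_mask, voxel_spacing=out_spacing)
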