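"""B0 and B1+ field mapping.

B0 comes from the phase difference of a dual-echo GRE; it feeds a native
1-D pixel-shift EPI distortion correction and the through-slice dephasing
model of the 2D double-angle-method (DAM) B1+ map.  The 2D DAM uses
GRE-EPI images at nominal 65°/130° and corrects the signal ratio for the
selective excitation's slice profile and for through-slice B0 gradients;
the 3D DAM (long-TR, non-selective) needs neither correction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.restoration import unwrap_phase

from .sequence_models import RFPulse, make_pulse, slice_profile

log = logging.getLogger(__name__)


@dataclass
class B0Map:
    """Per-voxel off-resonance (Hz) with validity mask."""

    offres_hz: np.ndarray
    mask: np.ndarray
    delta_te_ms: float


@dataclass
class B1Map:
    """Per-voxel ratio of achieved to nominal flip angle.

    NaN outside the mask.  ``source`` records the estimation route
    ('2D-corrected' or '3D-GS').
    """

    b1_factor: np.ndarray
    mask: np.ndarray
    source: str = "3D-GS"

    @property
    def n_masked_out(self) -> int:
        return int((~self.mask).sum())


def _noise_mask(magnitude, threshold_factor=5.0, background_sd=None):
    """Voxels with magnitude above threshold_factor × background noise SD.

    The background SD is estimated from the lowest-decile voxels unless
    given explicitly.
    """
    mag = np.abs(magnitude)
    if background_sd is None:
        low = np.quantile(mag, 0.1)
        background_sd = max(np.std(mag[mag <= low]), 1e-3 * mag.max(), 1e-30)
    return mag > threshold_factor * background_sd


def compute_b0(echo1, echo2, delta_te_ms, mask=None, threshold_factor=5.0,
               background_sd=None) -> B0Map:
    """Off-resonance map from two complex echoes.

    offres = angle(echo2 · conj(echo1)) / (2π ΔTE), phase-unwrapped in 2D
    slice by slice inside the mask.  Echo arrays are (nx, ny[, nz]) complex
    with identical geometry; ΔTE in ms (the in-vivo protocol uses
    7.17 − 4.78 = 2.39 ms).
    """
    echo1 = np.asarray(echo1)
    echo2 = np.asarray(echo2)
    if echo1.shape != echo2.shape:
        raise ValueError("echoes must share geometry")
    if delta_te_ms <= 0:
        raise ValueError("delta_te must be positive")
    if mask is None:
        mask = (_noise_mask(echo1, threshold_factor, background_sd)
                & _noise_mask(echo2, threshold_factor, background_sd))
    phase = np.angle(echo2 * np.conj(echo1))
    vol = phase if phase.ndim == 3 else phase[..., None]
    mvol = mask if mask.ndim == 3 else mask[..., None]
    unwrapped = np.zeros_like(vol)
    for k in range(vol.shape[2]):
        sl = np.ma.array(vol[:, :, k], mask=~mvol[:, :, k])
        if mvol[:, :, k].any():
            u = unwrap_phase(sl)
            unwrapped[:, :, k] = np.ma.filled(u, 0.0)
    unwrapped = unwrapped.reshape(phase.shape)
    offres = unwrapped / (2 * np.pi * delta_te_ms * 1e-3)
    offres[~mask] = np.nan
    n_out = int((~mask).sum())
    if n_out:
        log.info("compute_b0: %d voxels masked out", n_out)
    return B0Map(offres_hz=offres, mask=mask, delta_te_ms=delta_te_ms)


def unwarp_epi(epi, b0: B0Map, echo_spacing_ms, pe_axis=1, n_pe_lines=None,
               max_shift_fraction=0.25):
    """Native 1-D EPI distortion correction along the phase-encode axis.

    The voxel displacement of an EPI image is offres × (effective echo
    spacing × number of PE lines) along the PE axis; the unwarped image is
    the input resampled at the displaced positions (linear interpolation).
    Voxels whose shift exceeds ``max_shift_fraction`` of the PE FOV are
    flagged (returned as second output).
    """
    epi = np.asarray(epi, float)
    off = np.where(b0.mask, b0.offres_hz, 0.0)
    if off.shape != epi.shape:
        raise ValueError("B0 map must be resampled to the EPI grid first")
    n_pe = epi.shape[pe_axis] if n_pe_lines is None else n_pe_lines
    shift_vox = off * echo_spacing_ms * 1e-3 * n_pe
    flagged = np.abs(shift_vox) > max_shift_fraction * epi.shape[pe_axis]
    if flagged.any():
        log.warning("unwarp_epi: %d voxels exceed shift limit", int(flagged.sum()))
    moved = np.ascontiguousarray(np.moveaxis(epi, pe_axis, 0))
    sh = np.ascontiguousarray(np.moveaxis(shift_vox, pe_axis, 0))
    idx = np.arange(moved.shape[0], dtype=float)
    flat = moved.reshape(moved.shape[0], -1)
    shf = sh.reshape(moved.shape[0], -1)
    outf = np.empty_like(flat)
    for j in range(flat.shape[1]):
        outf[:, j] = np.interp(idx + shf[:, j], idx, flat[:, j])
    out = outf.reshape(moved.shape)
    return np.moveaxis(out, 0, pe_axis).copy(), flagged


def dam_b1_3d(img_alpha, img_2alpha, nominal_alpha_deg, mask=None,
              threshold_factor=5.0, background_sd=None) -> B1Map:
    """3D long-TR double-angle B1+ map.

    Under full relaxation S(α) ∝ sin(α_true), so
    b1 = arccos(S(2α) / (2 S(α))) / α_nominal.  Voxels where S(α) is below
    the noise threshold or the half-ratio leaves [−1, 1] are masked.
    """
    s1 = np.asarray(img_alpha, float)
    s2 = np.asarray(img_2alpha, float)
    if s1.shape != s2.shape:
        raise ValueError("DAM images must share geometry")
    if mask is None:
        mask = _noise_mask(s1, threshold_factor, background_sd)
    with np.errstate(divide="ignore", invalid="ignore"):
        half_ratio = s2 / (2.0 * s1)
    valid = mask & np.isfinite(half_ratio) & (np.abs(half_ratio) <= 1.0) & (s1 > 0)
    b1 = np.full(s1.shape, np.nan)
    b1[valid] = np.rad2deg(np.arccos(half_ratio[valid])) / nominal_alpha_deg
    n_rejected = int((mask & ~valid).sum())
    if n_rejected:
        log.info("dam_b1_3d: %d in-mask voxels outside arccos domain", n_rejected)
    return B1Map(b1_factor=b1, mask=valid, source="3D-GS")


class DamLookup:
    """Monotone lookup R(b1; Gz) for slice-profile-corrected 2D DAM.

    For each candidate b1 the achieved flip profiles α1(z), α2(z) of the
    selective 65°/130° excitations are Bloch-simulated, and the through-
    slice-integrated EPI signal ratio

        R(b1; Gz) = |∫ sin(α2(z)) w(z) dz| / |∫ sin(α1(z)) w(z) dz|,
        w(z) = exp(i 2π Gz z TE)

    is tabulated, where Gz is the through-slice B0 gradient (Hz/mm) and TE
    the EPI echo time.  R is strictly decreasing in b1 (asserted at build),
    so measured ratios invert uniquely.
    """

    def __init__(self, nominal_angles=(65.0, 130.0), pulse: RFPulse | None = None,
                 slice_thickness_mm=8.0, te_ms=11.0,
                 b1_grid=None, gz_grid=None, n_z=129):
        self.nominal_angles = nominal_angles
        self.pulse = pulse if pulse is not None else make_pulse("hann_sinc")
        self.slice_thickness_mm = slice_thickness_mm
        self.te_ms = te_ms
        self.b1_grid = (np.arange(0.05, 1.4001, 0.01) if b1_grid is None
                        else np.asarray(b1_grid, float))
        self.gz_grid = (np.linspace(-6.0, 6.0, 25) if gz_grid is None
                        else np.asarray(gz_grid, float))
        a1, a2 = nominal_angles
        sig = np.empty((2, self.b1_grid.size, self.gz_grid.size))
        for i, b1 in enumerate(self.b1_grid):
            z, p1 = slice_profile(self.pulse, a1, b1, slice_thickness_mm, n_z=n_z)
            _, p2 = slice_profile(self.pulse, a2, b1, slice_thickness_mm, n_z=n_z)
            s1 = np.sin(np.deg2rad(p1))
            s2 = np.sin(np.deg2rad(p2))
            w = np.exp(2j * np.pi * np.outer(self.gz_grid, z) * te_ms * 1e-3)
            sig[0, i] = np.abs(w @ s1)
            sig[1, i] = np.abs(w @ s2)
        with np.errstate(divide="ignore", invalid="ignore"):
            self.ratio = sig[1] / sig[0]          # (n_b1, n_gz)
        # R(b1) turns around once 2α crosses 180 deg; keep the maximal
        # strictly-decreasing prefix of the grid
        dec = np.all(np.diff(self.ratio, axis=0) < 0, axis=1)
        n_keep = int(np.argmin(dec)) + 1 if not dec.all() else self.b1_grid.size
        if self.b1_grid[n_keep - 1] < 1.3:
            raise RuntimeError("DAM lookup R(b1) loses monotonicity below "
                               f"b1={self.b1_grid[n_keep - 1]:.2f}; check pulse "
                               "descriptor / nominal angles")
        self.b1_grid = self.b1_grid[:n_keep]
        self.ratio = self.ratio[:n_keep]

    def invert(self, measured_ratio, gz_hz_per_mm=0.0):
        """b1 for a measured S(2α)/S(α) ratio; NaN outside the lookup range.

        Linear interpolation along b1 within each Gz column, then linear
        blending between the two neighbouring Gz columns.
        """
        r = np.asarray(measured_ratio, float)
        g = np.broadcast_to(np.asarray(gz_hz_per_mm, float), r.shape).ravel()
        rf = r.ravel()
        gi = np.clip(np.searchsorted(self.gz_grid, g) - 1, 0, self.gz_grid.size - 2)
        frac = np.clip((g - self.gz_grid[gi])
                       / (self.gz_grid[gi + 1] - self.gz_grid[gi]), 0, 1)
        b1cols = np.empty((2, rf.size))
        for d in (0, 1):
            cols = self.ratio[:, gi + d]              # (n_b1, n_pts)
            vals = np.empty(rf.size)
            for j in range(rf.size):
                dec = cols[:, j][::-1]               # increasing
                vals[j] = np.interp(rf[j], dec, self.b1_grid[::-1],
                                    left=np.nan, right=np.nan)
            b1cols[d] = vals
        out = (1 - frac) * b1cols[0] + frac * b1cols[1]
        return out.reshape(r.shape)


def through_slice_gradient(b0: B0Map, slice_spacing_mm, slice_axis=2):
    """Through-slice B0 gradient (Hz/mm) by central finite differences
    across neighbouring slices, constant within each slice."""
    off = np.where(b0.mask, b0.offres_hz, np.nan)
    grad = np.gradient(off, slice_spacing_mm, axis=slice_axis)
    return np.nan_to_num(grad, nan=0.0)


def dam_b1_2d_corrected(epi_alpha, epi_2alpha, b0: B0Map | None = None,
                        nominal_angles=(65.0, 130.0),
                        slice_thickness_mm=8.0, slice_spacing_mm=10.0,
                        te_ms=11.0, pulse: RFPulse | None = None,
                        lookup: DamLookup | None = None, mask=None,
                        threshold_factor=5.0, background_sd=None) -> B1Map:
    """Slice-profile and through-slice-B0 corrected 2D DAM B1+ map.

    Per voxel, the measured S(2α)/S(α) ratio is inverted through the
    precomputed monotone lookup R(b1; Gz), with Gz estimated from
    inter-slice finite differences of the B0 map.  With a hard pulse and
    no B0 gradient this reduces to the closed-form 3D DAM.
    """
    s1 = np.asarray(epi_alpha, float)
    s2 = np.asarray(epi_2alpha, float)
    if s1.shape != s2.shape:
        raise ValueError("DAM images must share geometry")
    if lookup is None:
        lookup = DamLookup(nominal_angles=nominal_angles, pulse=pulse,
                           slice_thickness_mm=slice_thickness_mm, te_ms=te_ms)
    if mask is None:
        mask = _noise_mask(s1, threshold_factor, background_sd)
    if b0 is not None and s1.ndim == 3 and s1.shape[2] >= 2:
        gz = through_slice_gradient(b0, slice_spacing_mm)
    else:
        gz = np.zeros_like(s1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = s2 / s1
    b1 = np.full(s1.shape, np.nan)
    sel = mask & np.isfinite(ratio)
    b1[sel] = lookup.invert(ratio[sel], gz[sel])
    valid = sel & np.isfinite(b1)
    b1[~valid] = np.nan
    n_rej = int((mask & ~valid).sum())
    if n_rej:
        log.info("dam_b1_2d_corrected: %d in-mask voxels outside lookup range",
                 n_rej)
    return B1Map(b1_factor=b1, mask=valid, source="2D-corrected")


def resample_b1_to_spgr(b1: B1Map, source_affine, target_affine, target_shape,
                        ) -> B1Map:
    """Trilinear resampling of a B1+ map onto the SPGR grid.

    Interpolation happens in physical coordinates via the NIfTI affines
    (0-based voxel indices).  The mask propagates conservatively: a target
    voxel is valid only if every contributing source voxel was valid.
    """
    src = np.nan_to_num(b1.b1_factor, nan=0.0)
    inv = np.linalg.inv(source_affine) @ target_affine
    ii, jj, kk = np.meshgrid(*[np.arange(n) for n in target_shape], indexing="ij")
    vox = np.stack([ii.ravel(), jj.ravel(), kk.ravel(), np.ones(ii.size)])
    src_coords = (inv @ vox)[:3]
    vals = ndimage.map_coordinates(src, src_coords, order=1, mode="constant",
                                   cval=np.nan)
    mvals = ndimage.map_coordinates(b1.mask.astype(float), src_coords, order=1,
                                    mode="constant", cval=0.0)
    out = vals.reshape(target_shape)
    out_mask = (mvals.reshape(target_shape) > 1.0 - 1e-9) & np.isfinite(out)
    out[~out_mask] = np.nan
    n_out = int((~out_mask).sum())
    if n_out:
        log.info("resample_b1_to_spgr: %d target voxels outside coverage", n_out)
    return B1Map(b1_factor=out, mask=out_mask, source=b1.source)
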