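"""Digital phantoms emulating every acquisition the pipeline consumes.

Two layouts:

* ``vials`` — a 14-vial T1 calibration phantom (T1 367–1699 ms in ~100 ms
  steps, T2 45 ms, no fat), the synthetic counterpart of an agar/NiCl2
  phantom scanned overnight against gold-standard methods.
* ``abdomen`` — an abdomen-like ellipse with smooth B1+ depression (down
  to ~0.6 in one corner), a smooth B0 field with optional through-slice
  gradient, and a uniform fat fraction.

Signals are generated through the same physics used for fitting
(optionally EPG-realistic spoiling for the VFA water signal), slice-
profile-integrated for the 2D EPI acquisitions, with seeded Rician noise
on magnitude data.  Ground-truth maps ride along with every acquisition.

Default geometry is deliberately small (64×64×6) so closed-loop tests run
in seconds; the full acquisition matrix of the real protocol is available
by overriding ``shape``.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np

from .epg import epg_spgr_steady_state
from .sequence_models import (FatModel, TissueParams, fat_water_signal,
                              ir_signal, make_pulse, slice_profile, spgr_signal)

DEFAULT_VIAL_T1S = tuple(np.linspace(367.0, 1699.0, 14))  # ~100 ms steps


@dataclass
class PhantomSpec:
    """Geometry, tissue and field parameters of a digital phantom."""

    layout: str = "vials"                    # vials | abdomen
    shape: tuple[int, int, int] = (64, 64, 6)
    voxel_mm: tuple[float, float, float] = (3.0, 3.0, 3.0)
    vial_t1s: tuple[float, ...] = DEFAULT_VIAL_T1S
    t2: float = 45.0
    t1_abdomen: float = 950.0
    b1_range: tuple[float, float] = (1.0, 1.0)   # (corner minimum, bulk)
    b0_amplitude_hz: float = 0.0                  # smooth in-plane variation
    b0_gradient_hz_per_mm: float = 0.0            # through-slice
    pdff: float = 0.0
    noise_sigma: float = 0.0                      # Rician, absolute units
    seed: int = 0

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), default=list, indent=1)

    @classmethod
    def from_json(cls, s: str) -> "PhantomSpec":
        d = json.loads(s)
        for k in ("shape", "voxel_mm", "vial_t1s", "b1_range"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


@dataclass
class GroundTruth:
    t1_ms: np.ndarray
    b1_factor: np.ndarray
    b0_hz: np.ndarray
    pdff: np.ndarray
    tissue_mask: np.ndarray


def _vial_layout(spec: PhantomSpec):
    """14 vials on a 4×4 grid (two corners empty); returns (t1 map, mask)."""
    nx, ny, nz = spec.shape
    t1 = np.zeros((nx, ny, nz))
    mask = np.zeros((nx, ny, nz), bool)
    grid = 4
    r = max(2.0, 0.45 * min(nx, ny) / grid)
    xs = np.linspace(0.15 * nx, 0.85 * nx, grid)
    ys = np.linspace(0.15 * ny, 0.85 * ny, grid)
    ii, jj = np.ogrid[:nx, :ny]
    v = 0
    for xc in xs:
        for yc in ys:
            if v >= len(spec.vial_t1s):
                break
            disk = (ii - xc) ** 2 + (jj - yc) ** 2 <= r ** 2
            for k in range(nz):
                t1[:, :, k][disk] = spec.vial_t1s[v]
                mask[:, :, k][disk] = True
            v += 1
    return t1, mask


def _abdomen_layout(spec: PhantomSpec):
    nx, ny, nz = spec.shape
    ii, jj = np.ogrid[:nx, :ny]
    ell = (((ii - nx / 2) / (0.42 * nx)) ** 2
           + ((jj - ny / 2) / (0.42 * ny)) ** 2) <= 1.0
    mask = np.repeat(ell[:, :, None], nz, axis=2)
    t1 = np.where(mask, spec.t1_abdomen, 0.0)
    return t1, mask


def _b1_field(spec: PhantomSpec):
    """Smooth 2D Gaussian depression reaching the stated minimum in one
    corner of the tissue region (replicated across slices)."""
    nx, ny, nz = spec.shape
    lo, hi = spec.b1_range
    ii, jj = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    # depression centered beyond the lower-left corner for a smooth ramp
    d2 = ((ii - 0.15 * nx) / (0.6 * nx)) ** 2 + ((jj - 0.15 * ny) / (0.6 * ny)) ** 2
    f2d = hi - (hi - lo) * np.exp(-d2)
    return np.repeat(f2d[:, :, None], nz, axis=2)


def _b0_field(spec: PhantomSpec):
    nx, ny, nz = spec.shape
    ii, jj, kk = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz),
                             indexing="ij")
    inplane = spec.b0_amplitude_hz * np.sin(np.pi * ii / nx) \
        * np.cos(np.pi * jj / ny)
    thru = spec.b0_gradient_hz_per_mm * (kk - nz / 2) * spec.voxel_mm[2]
    return inplane + thru


def rician(rng, signal, sigma):
    """Rician-distributed magnitude: |signal + complex Gaussian noise|."""
    if sigma == 0:
        return np.abs(signal)
    noise = rng.normal(0, sigma, signal.shape) + 1j * rng.normal(0, sigma,
                                                                 signal.shape)
    return np.abs(signal + noise)


def affine(spec: PhantomSpec) -> np.ndarray:
    a = np.diag(list(spec.voxel_mm) + [1.0])
    return a


class DigitalPhantom:
    """Generator of the full acquisition set for one phantom spec."""

    def __init__(self, spec: PhantomSpec, fat: FatModel | None = None):
        self.spec = spec
        self.fat = fat or FatModel()
        if spec.layout == "vials":
            self.t1_map, self.tissue = _vial_layout(spec)
        elif spec.layout == "abdomen":
            self.t1_map, self.tissue = _abdomen_layout(spec)
        else:
            raise ValueError(f"unknown layout {spec.layout!r}")
        self.b1 = _b1_field(spec)
        self.b0 = _b0_field(spec)
        self.pdff_map = np.where(self.tissue, spec.pdff, 0.0)
        self.rng = np.random.default_rng(spec.seed)

    # -- ground truth -----------------------------------------------------
    def ground_truth(self) -> GroundTruth:
        return GroundTruth(t1_ms=self.t1_map.copy(), b1_factor=self.b1.copy(),
                           b0_hz=self.b0.copy(), pdff=self.pdff_map.copy(),
                           tissue_mask=self.tissue.copy())

    def _unique_t1s(self):
        return np.unique(self.t1_map[self.tissue])

    # -- acquisitions -----------------------------------------------------
    def vfa_dixon(self, fas=(2.0, 2.0, 15.0, 15.0), tr=4.1,
                  tes=(1.23, 2.46), epg_spoiling=True,
                  rf_spoil_increment=50.0, noise=True):
        """Dual-echo VFA SPGR volumes: complex arrays (n_fa, n_te, *shape)
        plus a sidecar dict.  Water amplitude per voxel from EPG-realistic
        spoiling (or the ideal Ernst model)."""
        spec = self.spec
        out = np.zeros((len(fas), len(tes)) + spec.shape, complex)
        t1s = self._unique_t1s()
        for i, fa in enumerate(fas):
            fa_true = self.b1 * fa
            if epg_spoiling:
                # EPG per unique (T1, quantized flip): quantize flip to 0.02°
                water_amp = np.zeros(spec.shape)
                faq = np.round(fa_true / 0.02) * 0.02
                for t1v in t1s:
                    sel = self.tissue & (self.t1_map == t1v)
                    if not sel.any():
                        continue
                    angles = np.unique(faq[sel])
                    sig = np.abs(epg_spgr_steady_state(
                        np.full(angles.size, t1v), spec.t2, angles, tr,
                        rf_spoil_increment))
                    lut = dict(zip(angles, sig))
                    water_amp[sel] = np.vectorize(lut.get)(faq[sel])
            else:
                water_amp = np.where(self.tissue,
                                     spgr_signal(np.where(self.tissue,
                                                          self.t1_map, 1000.0),
                                                 fa_true, tr), 0.0)
                water_amp[~self.tissue] = 0.0
            for j, te in enumerate(tes):
                vol = np.zeros(spec.shape, complex)
                tis_mask = self.tissue
                if spec.pdff > 0:
                    fat_amp = spgr_signal(self.fat.t1, fa_true, tr)
                    phasor = sum(a * np.exp(2j * np.pi * (df + self.b0) * te * 1e-3)
                                 for df, a in zip(self.fat.freqs_hz,
                                                  self.fat.amps))
                    vol[tis_mask] = ((1 - spec.pdff) * water_amp[tis_mask]
                                     * np.exp(2j * np.pi * self.b0[tis_mask]
                                              * te * 1e-3)
                                     + spec.pdff * fat_amp[tis_mask]
                                     * phasor[tis_mask])
                else:
                    vol[tis_mask] = water_amp[tis_mask] * np.exp(
                        2j * np.pi * self.b0[tis_mask] * te * 1e-3)
                if noise and spec.noise_sigma > 0:
                    vol = (vol + self.rng.normal(0, spec.noise_sigma, vol.shape)
                           + 1j * self.rng.normal(0, spec.noise_sigma, vol.shape))
                out[i, j] = vol
        sidecar = {"tr": tr, "te": list(tes), "nominal_fa": list(fas),
                   "rf_spoil_increment": rf_spoil_increment,
                   "epg_spoiling": epg_spoiling}
        return out, sidecar

    def b0_gre(self, tes=(4.78, 7.17), noise=True):
        """Dual-echo GRE for B0 mapping: two complex volumes + sidecar."""
        spec = self.spec
        mag = np.where(self.tissue, 1.0, 0.0)
        echoes = []
        for te in tes:
            vol = mag * np.exp(2j * np.pi * self.b0 * te * 1e-3)
            if noise and spec.noise_sigma > 0:
                vol = (vol + self.rng.normal(0, spec.noise_sigma, vol.shape)
                       + 1j * self.rng.normal(0, spec.noise_sigma, vol.shape))
            echoes.append(vol)
        return echoes, {"te": list(tes), "delta_te": tes[1] - tes[0]}

    def dam_3d(self, nominal=65.0, noise=True):
        """Long-TR non-selective DAM pair (full relaxation, sin law)."""
        spec = self.spec
        s1 = np.where(self.tissue, np.sin(np.deg2rad(self.b1 * nominal)), 0.0)
        s2 = np.where(self.tissue, np.sin(np.deg2rad(self.b1 * 2 * nominal)), 0.0)
        if noise and spec.noise_sigma > 0:
            s1 = rician(self.rng, s1, spec.noise_sigma)
            s2 = rician(self.rng, s2, spec.noise_sigma)
        return (s1, s2), {"nominal_alpha": nominal, "tr": 10000.0}

    def dam_epi(self, nominal=(65.0, 130.0), slice_thickness=8.0,
                te_ms=11.0, pulse=None, n_z=65, noise=True, distort=True,
                echo_spacing=0.3, pe_axis=1):
        """2D multi-slice GRE-EPI DAM pair with slice-profile integration
        and through-slice B0-gradient dephasing (fat-saturated, long TR).

        ``distort`` applies the forward EPI displacement along the PE axis
        that the pipeline's unwarp step removes."""
        spec = self.spec
        pulse = pulse or make_pulse("hann_sinc")
        gz = np.gradient(self.b0, spec.voxel_mm[2], axis=2)
        # quantize b1 and gz to keep the signal integral count tractable
        b1q = np.round(self.b1 / 0.002) * 0.002
        gzq = np.round(gz / 0.1) * 0.1
        vols = []
        for nom in nominal:
            vol = np.zeros(spec.shape)
            for b1v in np.unique(b1q[self.tissue]):
                z, prof = slice_profile(pulse, nom, b1v, slice_thickness, n_z=n_z)
                s = np.sin(np.deg2rad(prof))
                sel0 = self.tissue & (b1q == b1v)
                for gzv in np.unique(gzq[sel0]):
                    w = np.exp(2j * np.pi * gzv * z * te_ms * 1e-3)
                    val = np.abs(np.trapezoid(s * w, z)) / (z[-1] - z[0])
                    vol[sel0 & (gzq == gzv)] = val
            if distort:
                vol = self._epi_distort(vol, echo_spacing, pe_axis)
            if noise and spec.noise_sigma > 0:
                vol = rician(self.rng, vol, spec.noise_sigma)
            vols.append(vol)
        sidecar = {"nominal_angles": list(nominal),
                   "slice_thickness": slice_thickness, "te": te_ms,
                   "echo_spacing": echo_spacing}
        return tuple(vols), sidecar

    def _epi_distort(self, vol, echo_spacing_ms, pe_axis):
        """Forward EPI displacement: the inverse of the pixel-shift unwarp."""
        n_pe = vol.shape[pe_axis]
        shift = self.b0 * echo_spacing_ms * 1e-3 * n_pe
        moved = np.ascontiguousarray(np.moveaxis(vol, pe_axis, 0))
        sh = np.ascontiguousarray(np.moveaxis(shift, pe_axis, 0))
        idx = np.arange(n_pe, dtype=float)
        flat = moved.reshape(n_pe, -1)
        shf = sh.reshape(n_pe, -1)
        outf = np.empty_like(flat)
        for j in range(flat.shape[1]):
            outf[:, j] = np.interp(idx - shf[:, j], idx, flat[:, j])
        return np.moveaxis(outf.reshape(moved.shape), 0, pe_axis).copy()

    def ir_se(self, tis=None, noise=True):
        """Slice-selective IR-SE volumes at log-spaced TIs (gold standard)."""
        spec = self.spec
        if tis is None:
            tis = np.geomspace(25.0, 5000.0, 10)
        tis = np.asarray(tis, float)
        vols = np.zeros((tis.size,) + spec.shape)
        t1safe = np.where(self.tissue, self.t1_map, 1000.0)
        for i, ti in enumerate(tis):
            v = np.where(self.tissue, ir_signal(ti, 1.0, 2.0, t1safe), 0.0)
            vols[i] = rician(self.rng, v, spec.noise_sigma) if (
                noise and spec.noise_sigma > 0) else np.abs(v)
        return vols, {"tis": tis.tolist()}

    def generate_acquisitions(self, which):
        """Dispatch: which in {vfa_dixon, dam_epi, b0_gre, dam_3d, ir_se}."""
        gen = {"vfa_dixon": self.vfa_dixon, "dam_epi": self.dam_epi,
               "b0_gre": self.b0_gre, "dam_3d": self.dam_3d,
               "ir_se": self.ir_se}
        if which not in gen:
            raise ValueError(f"unknown acquisition {which!r}")
        return gen[which]()
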