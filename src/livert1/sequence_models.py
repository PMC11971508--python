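"""Closed-form and Bloch-simulated MR signal models.

Conventions: relaxation times in ms, frequencies in Hz, flip angles in
degrees at every public API boundary (radians are used internally only).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

GAMMA_HZ_PER_T = 42.5774688e6  # proton gyromagnetic ratio / 2π


@dataclass(frozen=True)
class TissueParams:
    """Relaxation and composition parameters of a single voxel/compartment.

    t1, t2, t2star are in ms; m0 is the equilibrium magnetization in
    arbitrary units; pdff is the proton-density fat fraction in [0, 1].
    """

    t1: float
    t2: float | None = None
    t2star: float | None = None
    m0: float = 1.0
    pdff: float = 0.0

    def __post_init__(self):
        if self.t1 <= 0:
            raise ValueError(f"t1 must be positive, got {self.t1}")
        if self.t2 is not None:
            if self.t2 <= 0:
                raise ValueError(f"t2 must be positive, got {self.t2}")
            if self.t2 > self.t1:
                raise ValueError(f"t2 ({self.t2}) must not exceed t1 ({self.t1})")
        if self.t2star is not None and self.t2 is not None and self.t2star > self.t2:
            raise ValueError(f"t2star ({self.t2star}) must not exceed t2 ({self.t2})")
        if not 0.0 <= self.pdff <= 1.0:
            raise ValueError(f"pdff must be in [0, 1], got {self.pdff}")


@dataclass(frozen=True)
class SequenceParams:
    """Acquisition constants of one sequence (times ms, angles degrees)."""

    tr: float
    te: tuple[float, ...] = ()
    nominal_fa: tuple[float, ...] = ()
    rf_spoil_increment: float = 50.0
    slice_thickness: float | None = None
    pulse_descriptor: str = "hann_sinc"

    def __post_init__(self):
        if self.te and not self.tr > max(self.te) > 0:
            raise ValueError("require tr > max(te) > 0")
        for fa in self.nominal_fa:
            if not 0.0 < fa <= 180.0:
                raise ValueError(f"flip angle {fa} outside (0, 180]")


# Six-peak liver fat spectrum (Hamilton-type amplitudes), chemical shifts in
# ppm relative to water (water at 4.70 ppm).
SIX_PEAK_LIVER_FAT = (
    (-3.80, 0.087),
    (-3.40, 0.694),
    (-2.60, 0.128),
    (-1.94, 0.004),
    (-0.39, 0.039),
    (0.60, 0.048),
)
SINGLE_PEAK_FAT = ((-3.40, 1.0),)


@dataclass(frozen=True)
class FatModel:
    """Fat spectral model: (shift ppm relative to water, relative amplitude).

    Amplitudes must sum to 1.  ``t1`` is the fat T1 (ms) used when a fat
    SPGR amplitude is needed; liver triglyceride T1 at 3 T is ~350 ms.
    """

    peaks: tuple[tuple[float, float], ...] = SIX_PEAK_LIVER_FAT
    field_strength: float = 3.0
    t1: float = 350.0

    def __post_init__(self):
        total = sum(a for _, a in self.peaks)
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"fat peak amplitudes must sum to 1, got {total}")

    @property
    def freqs_hz(self) -> np.ndarray:
        """Peak frequencies in Hz relative to water (negative = lower)."""
        ppm = np.array([p for p, _ in self.peaks])
        return ppm * 1e-6 * GAMMA_HZ_PER_T * self.field_strength

    @property
    def amps(self) -> np.ndarray:
        return np.array([a for _, a in self.peaks])

    @classmethod
    def single_peak(cls, field_strength: float = 3.0, t1: float = 350.0) -> "FatModel":
        return cls(peaks=SINGLE_PEAK_FAT, field_strength=field_strength, t1=t1)

    @classmethod
    def from_dict(cls, d: dict) -> "FatModel":
        if d.get("model") == "single_peak":
            return cls.single_peak(
                field_strength=d.get("field_strength", 3.0), t1=d.get("t1", 350.0)
            )
        peaks = tuple((float(p), float(a)) for p, a in d.get("peaks", SIX_PEAK_LIVER_FAT))
        return cls(
            peaks=peaks,
            field_strength=d.get("field_strength", 3.0),
            t1=d.get("t1", 350.0),
        )


def spgr_signal(t1, fa_deg, tr, m0=1.0):
    """Ideal-spoiling steady-state SPGR (Ernst) signal.

    S = M0 sin(α) (1 − E1) / (1 − E1 cos α),  E1 = exp(−TR/T1).

    Accepts scalars or broadcastable arrays.  t1 and tr in ms, fa in
    degrees.
    """
    t1 = np.asarray(t1, dtype=float)
    tr = np.asarray(tr, dtype=float)
    if np.any(t1 <= 0) or np.any(tr <= 0):
        raise ValueError("t1 and tr must be positive")
    fa_deg = np.asarray(fa_deg, dtype=float)
    if np.any(fa_deg < 0) or np.any(fa_deg > 180):
        raise ValueError("flip angle must lie in [0, 180] degrees")
    a = np.deg2rad(fa_deg)
    e1 = np.exp(-tr / t1)
    return m0 * np.sin(a) * (1.0 - e1) / (1.0 - e1 * np.cos(a))


def ernst_angle(t1, tr):
    """Flip angle (degrees) maximizing the SPGR signal: arccos(exp(−TR/T1))."""
    return np.rad2deg(np.arccos(np.exp(-np.asarray(tr, float) / np.asarray(t1, float))))


def spgr_bloch_recursion(t1, fa_deg, tr, m0=1.0, tol=1e-14, max_iter=2_000_000):
    """Steady-state SPGR signal by iterating the longitudinal recursion.

    Mz(n+1) = Mz(n) cosα E1 + M0 (1 − E1); S = Mz_ss sinα.  Independent
    oracle for :func:`spgr_signal` (assumes perfect spoiling).
    """
    a = np.deg2rad(float(fa_deg))
    e1 = np.exp(-float(tr) / float(t1))
    mz = float(m0)
    for _ in range(max_iter):
        mz_new = mz * np.cos(a) * e1 + m0 * (1.0 - e1)
        if abs(mz_new - mz) <= tol * max(abs(mz_new), 1e-300):
            mz = mz_new
            break
        mz = mz_new
    return mz * np.sin(a)


def ir_signal(ti, a, b, t1):
    """Three-parameter inversion-recovery model S(TI) = A − B exp(−TI/T1).

    Perfect inversion corresponds to B = 2A.  ti in ms; may be an array.
    """
    ti = np.asarray(ti, dtype=float)
    if np.any(ti < 0):
        raise ValueError("ti must be non-negative")
    if np.any(np.asarray(t1) <= 0):
        raise ValueError("t1 must be positive")
    return a - b * np.exp(-ti / t1)


# ---------------------------------------------------------------------------
# Shaped RF pulses and slice profiles
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RFPulse:
    """Sampled RF envelope with its slice-select context.

    ``samples`` is the (real) B1 envelope on a uniform time grid spanning
    ``duration_ms``; the absolute scale is irrelevant (it is calibrated to
    the requested on-resonance flip angle).  ``tbw`` is the time-bandwidth
    product used to set the slice-select gradient.
    """

    name: str
    duration_ms: float
    tbw: float
    samples: tuple[float, ...] = field(repr=False, default=())

    @property
    def is_hard(self) -> bool:
        return self.name == "hard"


def make_pulse(descriptor: str = "hann_sinc", duration_ms: float = 2.0,
               tbw: float = 8.0, n_samples: int = 256) -> RFPulse:
    """Build a named excitation pulse.

    Supported descriptors: ``hard`` (non-selective) and ``hann_sinc``
    (Hanning-windowed sinc, default time-bandwidth 8).
    """
    if descriptor == "hard":
        return RFPulse("hard", duration_ms, 0.0, (1.0,))
    if descriptor == "hann_sinc":
        t = np.linspace(-0.5, 0.5, n_samples)  # normalized time
        env = np.sinc(tbw * t) * (0.5 + 0.5 * np.cos(2 * np.pi * t))
        return RFPulse("hann_sinc", duration_ms, tbw, tuple(env))
    raise ValueError(f"unknown pulse descriptor {descriptor!r}")


def slice_profile(pulse: RFPulse, nominal_fa, b1_factor=1.0,
                  slice_thickness_mm: float = 8.0, n_z: int = 257,
                  z_span_factor: float = 4.0):
    """Achieved flip angle α(z) across the slice by Bloch simulation.

    The pulse amplitude is calibrated so the on-resonance flip is
    b1_factor × nominal_fa, then the shaped pulse is integrated with the
    slice-select gradient (amplitude from the time-bandwidth product and
    slice thickness) followed by the standard half-area refocusing lobe.

    Returns ``(z_mm, alpha_deg)`` with z symmetric about the slice center
    spanning ``z_span_factor`` slice thicknesses.  α(z) = atan2(|Mxy|, Mz),
    valid through 180°.  Relaxation during the pulse is neglected.
    """
    nominal_fa = float(nominal_fa)
    b1 = float(b1_factor)
    if b1 < 0:
        raise ValueError("b1_factor must be non-negative")
    half = 0.5 * z_span_factor * slice_thickness_mm
    z = np.linspace(-half, half, n_z)
    if pulse.is_hard or b1 == 0.0:
        return z, np.full_like(z, b1 * nominal_fa)

    env = np.asarray(pulse.samples, dtype=float)
    n = env.size
    dt_s = pulse.duration_ms * 1e-3 / n
    # calibrate: sum(omega1) * dt = flip (rad)
    flip_rad = np.deg2rad(b1 * nominal_fa)
    scale = flip_rad / (env.sum() * dt_s)
    omega1 = env * scale  # rad/s, about +x

    # gradient: pulse bandwidth (Hz) maps onto the slice thickness
    bw_hz = pulse.tbw / (pulse.duration_ms * 1e-3)
    g_hz_per_mm = bw_hz / slice_thickness_mm
    omega_z = 2 * np.pi * g_hz_per_mm * z  # rad/s per position

    mx = np.zeros_like(z)
    my = np.zeros_like(z)
    mz = np.ones_like(z)
    for w1 in omega1:
        # rotation about axis (w1, 0, wz) for dt
        weff = np.sqrt(w1 * w1 + omega_z * omega_z)
        phi = weff * dt_s
        with np.errstate(invalid="ignore", divide="ignore"):
            nx = np.where(weff > 0, w1 / np.where(weff > 0, weff, 1.0), 1.0)
            nz = np.where(weff > 0, omega_z / np.where(weff > 0, weff, 1.0), 0.0)
        c, s = np.cos(phi), np.sin(phi)
        onemc = 1.0 - c
        # Rodrigues rotation about the unit axis (nx, 0, nz)
        r00 = c + nx * nx * onemc
        r01 = nz * s
        r02 = nx * nz * onemc
        r10 = -nz * s
        r11 = c
        r12 = nx * s
        r20 = nx * nz * onemc
        r21 = -nx * s
        r22 = c + nz * nz * onemc
        mx2 = r00 * mx + r01 * my + r02 * mz
        my2 = r10 * mx + r11 * my + r12 * mz
        mz2 = r20 * mx + r21 * my + r22 * mz
        mx, my, mz = mx2, my2, mz2

    # half-area refocus lobe: undo half the through-slice precession,
    # using the same rotation convention as the in-pulse steps
    phi_ref = -omega_z * (pulse.duration_ms * 1e-3) / 2.0
    c, s = np.cos(phi_ref), np.sin(phi_ref)
    mx, my = c * mx + s * my, -s * mx + c * my

    alpha = np.rad2deg(np.arctan2(np.hypot(mx, my), mz))
    return z, alpha


def small_tip_profile(pulse: RFPulse, nominal_fa, b1_factor=1.0,
                      slice_thickness_mm: float = 8.0, n_z: int = 257,
                      z_span_factor: float = 4.0):
    """Small-tip-angle slice profile: scaled Fourier transform of the envelope.

    Independent cross-check of :func:`slice_profile` at small flips.
    """
    half = 0.5 * z_span_factor * slice_thickness_mm
    z = np.linspace(-half, half, n_z)
    if pulse.is_hard:
        return z, np.full_like(z, b1_factor * nominal_fa)
    env = np.asarray(pulse.samples, dtype=float)
    n = env.size
    t = (np.arange(n) - (n - 1) / 2) * pulse.duration_ms * 1e-3 / n
    bw_hz = pulse.tbw / (pulse.duration_ms * 1e-3)
    f = (bw_hz / slice_thickness_mm) * z  # off-resonance at z, Hz
    # on-resonance refocused FT (envelope symmetric, result real)
    ft = np.array([(env * np.cos(2 * np.pi * fi * t)).sum() for fi in f])
    alpha = b1_factor * nominal_fa * ft / env.sum()
    return z, alpha


def fat_water_signal(tissue: TissueParams, fat: FatModel, fa_deg, tr, te,
                     b0_hz=0.0, epg_water_signal=None):
    """Complex SPGR signal of a water+fat voxel at echo time ``te``.

    Water contributes (1−pdff)·S_SPGR(T1w) and each fat peak
    pdff·a_p·S_SPGR(T1fat), dephased by exp(i2π(Δf_p + b0)TE − TE/T2*);
    the water term is dephased by the B0 term alone.  ``epg_water_signal``
    optionally replaces the ideal-spoiling water amplitude (e.g. with an
    EPG-simulated one).  te may be an array.
    """
    te = np.asarray(te, dtype=float)
    w_amp = spgr_signal(tissue.t1, fa_deg, tr, tissue.m0) if epg_water_signal is None \
        else epg_water_signal
    f_amp = spgr_signal(fat.t1, fa_deg, tr, tissue.m0)
    r2s = 0.0 if tissue.t2star is None else 1.0 / tissue.t2star
    decay = np.exp(-te * r2s)
    water = (1.0 - tissue.pdff) * w_amp * np.exp(2j * np.pi * b0_hz * te * 1e-3)
    fat_sum = 0.0
    for df, amp in zip(fat.freqs_hz, fat.amps):
        fat_sum = fat_sum + amp * np.exp(2j * np.pi * (df + b0_hz) * te * 1e-3)
    return decay * (water + tissue.pdff * f_amp * fat_sum)
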