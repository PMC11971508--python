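"""Two-echo Dixon water/fat separation and T1 fitting.

The VFA T1 fit minimizes, per voxel,

    sum_j ( S_j - c(alpha_j, T1) * S_SPGR(T1, M0, alpha_j = b1 * alpha_nom_j) )^2

over (T1, M0), where c is the EPG incomplete-spoiling correction.  Because
M0 enters linearly it is projected out (variable projection), leaving a 1-D
minimization in T1 solved by a coarse log-grid search plus golden-section
refinement — equivalent to the usual Levenberg–Marquardt solution of this
separable problem, but trivially vectorized over voxels.

The inversion-recovery spin-echo fit (gold standard for the phantom) uses
the same variable-projection idea with the linear pair (A, B) of
S(TI) = A − B exp(−TI/T1), fitting magnitude data with polarity
restoration (both candidate sign patterns around the null are tried and
the lower-residual one kept).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .epg import SpoilingCorrection
from .sequence_models import spgr_signal

log = logging.getLogger(__name__)

_GOLD = (np.sqrt(5.0) - 1.0) / 2.0


@dataclass
class T1Map:
    """Per-voxel T1 (ms) with fit diagnostics."""

    t1_ms: np.ndarray
    m0: np.ndarray
    resnorm: np.ndarray
    converged: np.ndarray
    mask: np.ndarray


# ---------------------------------------------------------------------------
# Dixon separation
# ---------------------------------------------------------------------------


def dixon_separate(echo_op, echo_ip, b0=None, te_op_ms=1.23, te_ip_ms=2.46):
    """Two-echo Dixon water/fat separation (3 T: TEs 1.23/2.46 ms).

    Complex inputs: after removal of the B0 phase accrued at each TE,
    W = |S_ip + S_op|/2 and F = |S_ip − S_op|/2.  Magnitude inputs (real
    arrays): W = (|S_ip|+|S_op|)/2, F = (|S_ip|−|S_op|)/2 under the
    water-dominant assumption.  Returns (water, fat, swap_flags) where
    swap_flags marks voxels with F > W (fat-dominant ambiguity).
    """
    op = np.asarray(echo_op)
    ip = np.asarray(echo_ip)
    if op.shape != ip.shape:
        raise ValueError("Dixon echoes must share geometry")
    if np.iscomplexobj(op) or np.iscomplexobj(ip):
        if b0 is not None:
            off = np.where(np.isfinite(b0), b0, 0.0)
            op = op * np.exp(-2j * np.pi * off * te_op_ms * 1e-3)
            ip = ip * np.exp(-2j * np.pi * off * te_ip_ms * 1e-3)
        # align the water phase of both echoes using the in-phase echo
        phase = np.exp(-1j * np.angle(ip))
        op = op * phase
        ip = ip * phase
        water = 0.5 * np.abs(ip + op)
        fat = 0.5 * np.abs(ip - op)
    else:
        water = 0.5 * (np.abs(ip) + np.abs(op))
        fat = 0.5 * (np.abs(ip) - np.abs(op))
    swap = fat > water
    if swap.any():
        log.info("dixon_separate: %d voxels with F > W (possible fat-dominant)",
                 int(swap.sum()))
    return water, fat, swap


# ---------------------------------------------------------------------------
# VFA T1 fit
# ---------------------------------------------------------------------------


def _vfa_ssr(t1, signals, alphas_eff, tr, correction):
    """Residual sum of squares at T1 with M0 projected out.

    t1: (nvox,), signals: (nfa, nvox), alphas_eff: (nfa, nvox) degrees.
    Returns (ssr, m0) each (nvox,).
    """
    f = spgr_signal(t1[None, :], alphas_eff, tr)
    if correction is not None:
        f = f * correction(alphas_eff, np.broadcast_to(t1[None, :], alphas_eff.shape))
    denom = np.einsum("fv,fv->v", f, f)
    num = np.einsum("fv,fv->v", signals, f)
    with np.errstate(invalid="ignore", divide="ignore"):
        m0 = num / denom
    ssr = np.einsum("fv,fv->v", signals, signals) - m0 * num
    return ssr, m0


def despot1_init(signals, alphas_eff_deg, tr):
    """Linearized two-point DESPOT1 estimate (initializer / fallback).

    Ordinary least squares on S/sinα = E1 · S/tanα + M0(1−E1) across the
    available flip angles.  Returns T1 (ms) per voxel (NaN where the slope
    leaves (0, 1))."""
    a = np.deg2rad(alphas_eff_deg)
    y = signals / np.sin(a)
    x = signals / np.tan(a)
    xm = x.mean(axis=0)
    ym = y.mean(axis=0)
    sxx = ((x - xm) ** 2).sum(axis=0)
    sxy = ((x - xm) * (y - ym)).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        e1 = sxy / sxx
        t1 = np.where((e1 > 0) & (e1 < 1), -tr / np.log(e1), np.nan)
    return t1


def fit_vfa_t1(signals, fa_nominal_deg, tr, b1=None,
               correction: SpoilingCorrection | None = None,
               mask=None, bounds=(100.0, 5000.0), n_grid=96, tol=1e-8,
               chunk=20000) -> T1Map:
    """B1+-corrected, spoiling-corrected NLLS VFA T1 fit.

    signals: array (n_fa, ...spatial) of water magnitudes — repeated flip
    angles enter as separate observations; fa_nominal_deg: nominal flip
    angles (degrees); b1: per-voxel B1+ factor (None → 1, i.e. no
    correction); correction: EPG incomplete-spoiling table (None → ideal
    spoiling).  T1 is found by variable projection (see module docstring)
    within ``bounds``; tolerance is relative on T1.
    """
    signals = np.asarray(signals, float)
    fa_nom = np.asarray(fa_nominal_deg, float)
    nfa = fa_nom.size
    if signals.shape[0] != nfa:
        raise ValueError("first axis of signals must match the flip angles")
    if len(np.unique(fa_nom)) < 2:
        raise ValueError("need at least two distinct flip angles")
    spatial = signals.shape[1:]
    sig = signals.reshape(nfa, -1)
    nv = sig.shape[1]
    if b1 is None:
        b1f = np.ones(nv)
    else:
        b1f = np.asarray(b1, float).reshape(nv)
    if mask is None:
        maskf = np.ones(nv, bool)
    else:
        maskf = np.asarray(mask, bool).reshape(nv)
    maskf = maskf & np.isfinite(b1f) & (b1f > 0) & np.isfinite(sig).all(axis=0)

    t1_out = np.full(nv, np.nan)
    m0_out = np.full(nv, np.nan)
    res_out = np.full(nv, np.nan)
    conv_out = np.zeros(nv, bool)

    lo, hi = bounds
    t1_grid = np.geomspace(lo, hi, n_grid)
    idx_all = np.flatnonzero(maskf)
    for start in range(0, idx_all.size, chunk):
        idx = idx_all[start:start + chunk]
        s = sig[:, idx]
        a_eff = fa_nom[:, None] * b1f[None, idx]
        # coarse grid
        best_ssr = np.full(idx.size, np.inf)
        best_t1 = np.full(idx.size, t1_grid[0])
        for t1v in t1_grid:
            ssr, _ = _vfa_ssr(np.full(idx.size, t1v), s, a_eff, tr, correction)
            better = ssr < best_ssr
            best_ssr = np.where(better, ssr, best_ssr)
            best_t1 = np.where(better, t1v, best_t1)
        # golden-section refinement in log T1 around the best grid node
        gi = np.searchsorted(t1_grid, best_t1)
        a_lo = np.log(t1_grid[np.maximum(gi - 1, 0)])
        a_hi = np.log(t1_grid[np.minimum(gi + 1, n_grid - 1)])
        for _ in range(60):
            x1 = a_hi - _GOLD * (a_hi - a_lo)
            x2 = a_lo + _GOLD * (a_hi - a_lo)
            f1, _ = _vfa_ssr(np.exp(x1), s, a_eff, tr, correction)
            f2, _ = _vfa_ssr(np.exp(x2), s, a_eff, tr, correction)
            pick1 = f1 < f2
            a_hi = np.where(pick1, x2, a_hi)
            a_lo = np.where(pick1, a_lo, x1)
            if np.max(a_hi - a_lo) < tol:
                break
        t1_fit = np.exp(0.5 * (a_lo + a_hi))
        ssr, m0 = _vfa_ssr(t1_fit, s, a_eff, tr, correction)
        t1_out[idx] = t1_fit
        m0_out[idx] = m0
        res_out[idx] = ssr
        conv_out[idx] = (a_hi - a_lo) < 10 * tol
    # mark boundary hits as non-converged
    on_edge = (np.abs(t1_out - lo) < 1e-6 * lo) | (np.abs(t1_out - hi) < 1e-6 * hi)
    conv_out &= ~on_edge
    n_bad = int((maskf & ~conv_out).sum())
    if n_bad:
        log.info("fit_vfa_t1: %d voxels flagged non-converged/at-bounds", n_bad)
    return T1Map(t1_ms=t1_out.reshape(spatial), m0=m0_out.reshape(spatial),
                 resnorm=res_out.reshape(spatial),
                 converged=conv_out.reshape(spatial),
                 mask=(maskf & conv_out).reshape(spatial))


# ---------------------------------------------------------------------------
# IR-SE T1 fit (gold standard)
# ---------------------------------------------------------------------------


def paper_ti_schedule(n=10, lo=25.0, hi=5000.0):
    """Logarithmically increasing inversion times, 25 to 5000 ms."""
    return np.geomspace(lo, hi, n)


def _ir_ssr(t1, signed, tis):
    """VARPRO residual for S = A − B exp(−TI/T1): solve (A, B) linearly.

    t1: (nvox,), signed: (nti, nvox).  Returns (ssr, a, b)."""
    e = np.exp(-tis[:, None] / t1[None, :])       # (nti, nvox)
    nti = tis.size
    # normal equations for design [1, -e]
    s1 = float(nti)
    se = e.sum(axis=0)
    see = (e * e).sum(axis=0)
    sy = signed.sum(axis=0)
    sey = (e * signed).sum(axis=0)
    det = s1 * see - se * se
    with np.errstate(invalid="ignore", divide="ignore"):
        a = (see * sy - se * sey) / det
        b = (se * sy - s1 * sey) / det  # coefficient of -e
    pred = a[None, :] - b[None, :] * e
    ssr = ((signed - pred) ** 2).sum(axis=0)
    return ssr, a, b


def fit_ir_t1(signals, tis_ms, mask=None, bounds=(25.0, 8000.0), n_grid=120,
              tol=1e-8) -> T1Map:
    """Three-parameter magnitude IR fit with polarity restoration.

    signals: (n_ti, ...spatial) magnitudes; tis_ms strictly increasing
    (>=4 values).  For each voxel the minimum-magnitude TI locates the
    null; both sign patterns (flip strictly-before vs through the minimum)
    are fitted and the lower residual kept.  (A, B) are solved linearly at
    each T1 candidate; T1 by grid + golden refinement as in the VFA fit.
    """
    signals = np.asarray(signals, float)
    tis = np.asarray(tis_ms, float)
    if tis.size < 4:
        raise ValueError("need at least 4 inversion times")
    if np.any(np.diff(tis) <= 0):
        raise ValueError("inversion times must be strictly increasing")
    spatial = signals.shape[1:]
    sig = signals.reshape(tis.size, -1)
    nv = sig.shape[1]
    maskf = (np.ones(nv, bool) if mask is None
             else np.asarray(mask, bool).reshape(nv))
    maskf = maskf & np.isfinite(sig).all(axis=0)

    kmin = np.argmin(sig, axis=0)
    best = {"ssr": np.full(nv, np.inf), "t1": np.full(nv, np.nan),
            "a": np.full(nv, np.nan), "b": np.full(nv, np.nan)}
    lo, hi = bounds
    t1_grid = np.geomspace(lo, hi, n_grid)
    for flip_through_min in (False, True):
        cut = kmin + (1 if flip_through_min else 0)
        signed = np.where(np.arange(tis.size)[:, None] < cut[None, :], -sig, sig)
        ssr_best = np.full(nv, np.inf)
        t1_best = np.full(nv, t1_grid[0])
        for t1v in t1_grid:
            ssr, _, _ = _ir_ssr(np.full(nv, t1v), signed, tis)
            better = ssr < ssr_best
            ssr_best = np.where(better, ssr, ssr_best)
            t1_best = np.where(better, t1v, t1_best)
        gi = np.searchsorted(t1_grid, t1_best)
        a_lo = np.log(t1_grid[np.maximum(gi - 1, 0)])
        a_hi = np.log(t1_grid[np.minimum(gi + 1, n_grid - 1)])
        for _ in range(60):
            x1 = a_hi - _GOLD * (a_hi - a_lo)
            x2 = a_lo + _GOLD * (a_hi - a_lo)
            f1, _, _ = _ir_ssr(np.exp(x1), signed, tis)
            f2, _, _ = _ir_ssr(np.exp(x2), signed, tis)
            pick1 = f1 < f2
            a_hi = np.where(pick1, x2, a_hi)
            a_lo = np.where(pick1, a_lo, x1)
            if np.max(a_hi - a_lo) < tol:
                break
        t1_fit = np.exp(0.5 * (a_lo + a_hi))
        ssr, a, b = _ir_ssr(t1_fit, signed, tis)
        better = ssr < best["ssr"]
        best["ssr"] = np.where(better, ssr, best["ssr"])
        best["t1"] = np.where(better, t1_fit, best["t1"])
        best["a"] = np.where(better, a, best["a"])
        best["b"] = np.where(better, b, best["b"])

    ok = maskf & np.isfinite(best["t1"]) & (best["a"] > 0)
    t1_out = np.where(ok, best["t1"], np.nan)
    n_bad = int((maskf & ~ok).sum())
    if n_bad:
        log.info("fit_ir_t1: %d voxels failed", n_bad)
    return T1Map(t1_ms=t1_out.reshape(spatial), m0=best["a"].reshape(spatial),
                 resnorm=best["ssr"].reshape(spatial),
                 converged=ok.reshape(spatial), mask=ok.reshape(spatial))
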