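"""ROI-level and subject-level T1 statistics.

Implements the weighted subject summaries, the inaccuracy metric against a
reference method, the B1+-sensitivity regression with its confidence
interval, the one-way-ANOVA repeatability coefficient, the paired
mean-difference CI, and the Bland–Altman / correlation agreement metrics.

Weighted summaries use per-ROI weights w_{s,r} = N_pixels / σ²  (the
inverse squared standard error of the ROI mean).  The subject mean and SD
are pixel-level sums with those ROI weights and denominator Σ N·w; the
ROI-level homogeneity SD uses ROI means with denominator Σ w.  Both forms
are implemented exactly as defined.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)


@dataclass
class RoiSample:
    """Pixel values of one ROI on one slice of one acquisition."""

    subject: str
    run: str
    slice_id: int
    roi_id: int
    pixel_t1s: np.ndarray
    pixel_b1s: np.ndarray | None = None

    def __post_init__(self):
        self.pixel_t1s = np.asarray(self.pixel_t1s, float)
        if self.pixel_t1s.size < 1:
            raise ValueError("ROI must contain at least one pixel")
        if self.pixel_b1s is not None:
            self.pixel_b1s = np.asarray(self.pixel_b1s, float)

    @property
    def n_pixels(self) -> int:
        return self.pixel_t1s.size

    @property
    def mean(self) -> float:
        return float(self.pixel_t1s.mean())

    @property
    def sd(self) -> float:
        return float(self.pixel_t1s.std(ddof=1)) if self.n_pixels > 1 else 0.0


def _weights(samples, cap_quantile=0.99):
    """Per-ROI weights N/σ²; zero-σ ROIs capped at the 99th percentile of
    the finite weights (possible on noiseless synthetic data)."""
    w = np.array([s.n_pixels / s.sd ** 2 if s.sd > 0 else np.inf for s in samples])
    bad = ~np.isfinite(w)
    if bad.any():
        finite = w[~bad]
        if finite.size == 0:
            # every ROI noiseless: weights cancel, fall back to equal weights
            warnings.warn("all ROI weights undefined (zero SD); using equal "
                          "weights")
            return np.ones(w.size)
        cap = np.quantile(finite, cap_quantile)
        warnings.warn(f"{bad.sum()} ROI(s) with zero SD; weight capped at {cap:.3g}")
        w[bad] = cap
    return w


def weighted_subject_summary(samples: list[RoiSample]) -> tuple[float, float]:
    """Weighted mean and SD of T1 over all ROIs of a subject/acquisition.

    wμ = ΣΣΣ w_{s,r} T1_{s,r,p} / ΣΣ N_{s,r} w_{s,r};
    wσ = sqrt( ΣΣΣ w_{s,r} (T1_{s,r,p} − wμ)² / ΣΣ N_{s,r} w_{s,r} ).
    """
    if not samples:
        raise ValueError("no ROI samples")
    w = _weights(samples)
    denom = sum(wi * s.n_pixels for wi, s in zip(w, samples))
    num = sum(wi * s.pixel_t1s.sum() for wi, s in zip(w, samples))
    mu = num / denom
    var = sum(wi * ((s.pixel_t1s - mu) ** 2).sum() for wi, s in zip(w, samples))
    return float(mu), float(np.sqrt(var / denom))


def roi_level_homogeneity(samples: list[RoiSample]) -> float:
    """Dispersion of per-ROI mean T1s around the weighted subject mean.

    wσ_ROI = sqrt( ΣΣ w_{s,r} (μT1_{s,r} − wμ)² / ΣΣ w_{s,r} ), with the
    subject mean from :func:`weighted_subject_summary`.  Requires ≥2 ROIs.
    """
    if len(samples) < 2:
        raise ValueError("ROI-level homogeneity needs at least two ROIs")
    w = _weights(samples)
    mu, _ = weighted_subject_summary(samples)
    means = np.array([s.mean for s in samples])
    return float(np.sqrt(np.sum(w * (means - mu) ** 2) / np.sum(w)))


def inaccuracy(vfa_t1, reference_t1) -> float:
    """Mean signed relative difference between the VFA T1 and a reference.

    Inputs are aligned arrays (or dicts keyed by (volunteer, run));
    missing reference entries (NaN) are skipped with a log message.
    """
    if isinstance(vfa_t1, dict):
        keys = sorted(vfa_t1)
        missing = [k for k in keys if k not in reference_t1
                   or not np.isfinite(reference_t1[k])]
        if missing:
            log.info("inaccuracy: skipping %d unpaired entries: %s",
                     len(missing), missing)
        pairs = [(vfa_t1[k], reference_t1[k]) for k in keys if k not in missing]
        v = np.array([p[0] for p in pairs])
        r = np.array([p[1] for p in pairs])
    else:
        v = np.asarray(vfa_t1, float)
        r = np.asarray(reference_t1, float)
        keep = np.isfinite(v) & np.isfinite(r)
        if (~keep).any():
            log.info("inaccuracy: skipping %d unpaired entries", int((~keep).sum()))
        v, r = v[keep], r[keep]
    if v.size == 0:
        raise ValueError("no paired measurements")
    return float(np.mean((v - r) / r))


@dataclass
class RegressionResult:
    """T1-vs-B1+ linear fit and the derived B1+-related T1 variation."""

    intercept: float
    slope: float
    slope_se: float
    delta_b1: float
    delta_t1_b1: float          # slope × ΔB1+
    ci95: tuple[float, float]   # CI of ΔT1_B1
    p_value: float              # correlation t-test, n−2 d.o.f.
    n: int


def b1_sensitivity(t1_means, b1_means, b1_range=None, dof=None) -> RegressionResult:
    """Residual T1-vs-B1+ regression μT1 = a + b μB1+ and ΔT1 = b ΔB1+.

    The 95% CI of ΔT1_B1 is b ΔB1 ± t(0.975, dof) ΔB1 √(s²/Σ(μB1−mean)²)
    with s² the residual variance of the fit; ``dof`` defaults to N−2 (a
    printed variant quoting 2 d.o.f. can be forced via the argument).  The
    no-relationship null hypothesis is tested via the correlation
    t-statistic with N−2 d.o.f.
    """
    t1 = np.asarray(t1_means, float)
    b1 = np.asarray(b1_means, float)
    if t1.size < 3 or t1.size != b1.size:
        raise ValueError("need >=3 paired (T1, B1) ROI means")
    if np.allclose(b1, b1[0]):
        raise ValueError("zero B1+ variance: slope undefined")
    n = t1.size
    res = stats.linregress(b1, t1)
    delta_b1 = float(np.ptp(b1)) if b1_range is None else float(b1_range)
    dof = n - 2 if dof is None else int(dof)
    sxx = np.sum((b1 - b1.mean()) ** 2)
    resid = t1 - (res.intercept + res.slope * b1)
    s2 = np.sum(resid ** 2) / (n - 2)
    half = stats.t.ppf(0.975, dof) * delta_b1 * np.sqrt(s2 / sxx)
    dt1 = res.slope * delta_b1
    # correlation t-test (equivalent to the slope test), n−2 d.o.f.
    r = res.rvalue
    if np.isnan(r):            # zero T1 variance: no relationship
        p = 1.0
    elif abs(r) >= 1.0:
        p = 0.0
    else:
        tstat = r * np.sqrt((n - 2) / (1 - r ** 2))
        p = 2 * stats.t.sf(abs(tstat), n - 2)
    return RegressionResult(intercept=float(res.intercept), slope=float(res.slope),
                            slope_se=float(res.stderr), delta_b1=delta_b1,
                            delta_t1_b1=float(dt1), ci95=(float(dt1 - half),
                                                          float(dt1 + half)),
                            p_value=float(p), n=n)


@dataclass
class RepeatabilityResult:
    """Scan–rescan agreement metrics for paired subject means."""

    sigma_within: float
    rc: float                   # 1.96 √2 σ_within
    mean_diff: float
    mean_diff_ci95: tuple[float, float]
    mean_diff_p: float
    pearson_r: float
    regression_slope: float
    regression_slope_se: float
    bland_altman_bias: float
    bland_altman_loa: float     # half-width 1.96 SD(differences)
    n_subjects: int


def repeatability(run_a, run_b) -> RepeatabilityResult:
    """Repeatability of paired runs across subjects.

    σ_within is the square root of the residual mean square of a one-way
    ANOVA with subjects as groups (= √(mean((a−b)²)/2) for two runs);
    RC = 1.96 √2 σ_within.  The paired mean difference gets a 95% CI with
    t(0.975, N−1).  Pearson r, the run-b-on-run-a regression slope ± SE,
    and Bland–Altman bias ± 1.96 SD limits of agreement are also returned.
    """
    a = np.asarray(run_a, float)
    b = np.asarray(run_b, float)
    if a.size != b.size:
        raise ValueError("runs must cover the same subjects")
    if a.size < 3:
        raise ValueError("need at least 3 subjects")
    n = a.size
    # one-way ANOVA residual MS, subjects as groups, two observations each
    grp_mean = (a + b) / 2
    ss_within = np.sum((a - grp_mean) ** 2 + (b - grp_mean) ** 2)
    sigma_within = np.sqrt(ss_within / n)      # d.o.f. = N(k−1), k=2
    rc = 1.96 * np.sqrt(2.0) * sigma_within

    d = a - b
    md = d.mean()
    sd_d = d.std(ddof=1)
    half = stats.t.ppf(0.975, n - 1) * sd_d / np.sqrt(n)
    tstat, p = stats.ttest_rel(a, b)

    if np.allclose(a, a[0]) or np.allclose(b, b[0]):
        r, slope, slope_se = np.nan, np.nan, np.nan
    else:
        r = stats.pearsonr(a, b).statistic
        reg = stats.linregress(a, b)
        slope, slope_se = reg.slope, reg.stderr

    return RepeatabilityResult(
        sigma_within=float(sigma_within), rc=float(rc), mean_diff=float(md),
        mean_diff_ci95=(float(md - half), float(md + half)),
        mean_diff_p=float(p) if np.isfinite(p) else 1.0,
        pearson_r=float(r), regression_slope=float(slope),
        regression_slope_se=float(slope_se),
        bland_altman_bias=float(md), bland_altman_loa=float(1.96 * sd_d),
        n_subjects=n)


# ---------------------------------------------------------------------------
# ROI extraction and tabular I/O
# ---------------------------------------------------------------------------


def circular_roi_pixels(map_2d, center, radius, valid_mask=None):
    """Values of a map inside a circular ROI (center (row, col), radius in
    pixels), excluding NaNs and optionally invalid voxels."""
    arr = np.asarray(map_2d, float)
    rr, cc = np.ogrid[:arr.shape[0], :arr.shape[1]]
    sel = (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius ** 2
    if valid_mask is not None:
        sel &= np.asarray(valid_mask, bool)
    vals = arr[sel]
    return vals[np.isfinite(vals)]


def extract_rois(t1_volume, centers, radius, b1_volume=None, valid_mask=None,
                 subject="s1", run="r1") -> list[RoiSample]:
    """Circular-ROI extraction from a (nx, ny, nz) map.

    ``centers`` is a list of (slice_index, row, col); same-slice entries
    get consecutive roi ids.  The in-vivo protocol uses 3 ROIs/slice with
    radius 4 px on the VFA maps (2 px SASHA, 5 px MOLLI).
    """
    vol = np.asarray(t1_volume, float)
    samples = []
    per_slice_count: dict[int, int] = {}
    for (k, r0, c0) in centers:
        mask2d = None if valid_mask is None else np.asarray(valid_mask)[:, :, k]
        vals = circular_roi_pixels(vol[:, :, k], (r0, c0), radius, mask2d)
        if vals.size == 0:
            log.info("extract_rois: empty ROI at slice %d (%d,%d)", k, r0, c0)
            continue
        rid = per_slice_count.get(k, 0)
        per_slice_count[k] = rid + 1
        b1s = None
        if b1_volume is not None:
            b1s = circular_roi_pixels(np.asarray(b1_volume)[:, :, k],
                                      (r0, c0), radius, mask2d)
        samples.append(RoiSample(subject=subject, run=run, slice_id=k,
                                 roi_id=rid, pixel_t1s=vals, pixel_b1s=b1s))
    return samples


def samples_to_frame(samples: list[RoiSample]) -> pd.DataFrame:
    """Long-format table: one row per pixel (subject, run, slice, roi, t1, b1)."""
    rows = []
    for s in samples:
        b1s = (s.pixel_b1s if s.pixel_b1s is not None and
               s.pixel_b1s.size == s.n_pixels else [np.nan] * s.n_pixels)
        for t1, b1 in zip(s.pixel_t1s, b1s):
            rows.append((s.subject, s.run, s.slice_id, s.roi_id, t1, b1))
    return pd.DataFrame(rows, columns=["subject", "run", "slice", "roi",
                                       "t1_ms", "b1_factor"])


def frame_to_samples(df: pd.DataFrame) -> list[RoiSample]:
    samples = []
    for (subj, run, sl, roi), g in df.groupby(["subject", "run", "slice", "roi"],
                                              sort=True):
        b1 = g["b1_factor"].to_numpy() if "b1_factor" in g else None
        if b1 is not None and np.all(np.isnan(b1)):
            b1 = None
        samples.append(RoiSample(subject=str(subj), run=str(run),
                                 slice_id=int(sl), roi_id=int(roi),
                                 pixel_t1s=g["t1_ms"].to_numpy(),
                                 pixel_b1s=b1))
    return samples
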