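"""NIfTI / sidecar I/O, pipeline configuration and the pipeline driver.

Voxel indices are 0-based and half-open; physical coordinates come from
the NIfTI affine.  Every map written carries its affine; sidecar
parameters travel as JSON next to the image files.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from . import field_maps as fm
from .dixon_vfa import T1Map, dixon_separate, fit_vfa_t1
from .epg import SpoilingCorrection, build_spoiling_correction
from .sequence_models import make_pulse

log = logging.getLogger(__name__)


@dataclass
class ImageVolume:
    """Voxel array + geometry (affine in mm, optional PE axis)."""

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    pe_axis: int = 1

    @property
    def voxel_mm(self) -> tuple:
        return tuple(np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0)))


def load_volume(path) -> ImageVolume:
    img = nib.load(str(path))
    return ImageVolume(data=np.asanyarray(img.dataobj), affine=img.affine)


def save_volume(vol: ImageVolume | np.ndarray, path, affine=None):
    if isinstance(vol, ImageVolume):
        data, aff = vol.data, vol.affine
    else:
        data, aff = vol, (np.eye(4) if affine is None else affine)
    if np.iscomplexobj(data):
        raise ValueError("save magnitude and phase separately for complex data")
    nib.save(nib.Nifti1Image(np.asarray(data), aff), str(path))


def save_complex(data, prefix, affine=None):
    """Complex volume as <prefix>_mag.nii.gz / <prefix>_phase.nii.gz."""
    aff = np.eye(4) if affine is None else affine
    save_volume(np.abs(data), f"{prefix}_mag.nii.gz", aff)
    save_volume(np.angle(data), f"{prefix}_phase.nii.gz", aff)


def load_complex(prefix) -> np.ndarray:
    mag = load_volume(f"{prefix}_mag.nii.gz")
    ph = load_volume(f"{prefix}_phase.nii.gz")
    return mag.data * np.exp(1j * ph.data)


class PipelineError(RuntimeError):
    def __init__(self, stage, message):
        super().__init__(f"[stage {stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Validated configuration of the full T1-mapping pipeline."""

    input_dir: str = "."
    output_dir: str = "out"
    tr: float = 4.1
    tes: tuple[float, float] = (1.23, 2.46)
    nominal_fas: tuple[float, ...] = (2.0, 2.0, 15.0, 15.0)
    dam_nominal: tuple[float, float] = (65.0, 130.0)
    b0_delta_te: float = 2.39
    epi_echo_spacing: float = 0.3
    slice_thickness: float = 8.0
    slice_spacing: float = 10.0
    epi_te: float = 11.0
    rf_spoil_increment: float = 50.0
    spoiling_t2: float = 34.0
    mask_threshold_factor: float = 5.0
    fit_bounds: tuple[float, float] = (100.0, 5000.0)
    pulse_descriptor: str = "hann_sinc"
    apply_spoiling_correction: bool = True
    seed: int = 0

    def validate(self):
        if not self.tr > max(self.tes) > 0:
            raise ValueError("require tr > max(te) > 0")
        if len(self.nominal_fas) < 2:
            raise ValueError("need at least two flip-angle acquisitions")
        if self.fit_bounds[0] <= 0 or self.fit_bounds[1] <= self.fit_bounds[0]:
            raise ValueError("invalid fit bounds")
        return self

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        text = Path(path).read_text()
        d = yaml.safe_load(text)
        for k in ("tes", "nominal_fas", "dam_nominal", "fit_bounds"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d).validate()

    def to_dict(self):
        return dataclasses.asdict(self)


@dataclass
class PipelineResult:
    t1: T1Map
    b0: fm.B0Map
    b1: fm.B1Map
    water: np.ndarray
    fat: np.ndarray
    report: dict


def run_pipeline_arrays(cfg: PipelineConfig, vfa_complex, b0_echoes,
                        dam_pair, affines=None,
                        correction: SpoilingCorrection | None = None,
                        background_sd=None) -> PipelineResult:
    """Full in-memory pipeline on pre-loaded arrays.

    Stage order: B0 map → EPI unwarp → corrected 2D DAM B1+ → resample →
    per-FA Dixon separation → spoiling-corrected NLLS fit.  ``vfa_complex``
    is (n_fa, 2, *shape) complex; ``b0_echoes`` two complex volumes;
    ``dam_pair`` the 65°/130° EPI magnitudes.  ``affines`` maps
    {'vfa','b0','dam'} to 4×4 affines (identity → all grids match).
    Deterministic given config + inputs.
    """
    cfg.validate()
    affines = affines or {}
    report: dict = {"config": cfg.to_dict(), "stages": {}}

    try:
        b0 = fm.compute_b0(b0_echoes[0], b0_echoes[1], cfg.b0_delta_te,
                           threshold_factor=cfg.mask_threshold_factor,
                           background_sd=background_sd)
    except Exception as e:  # noqa: BLE001
        raise PipelineError("b0map", str(e)) from e
    report["stages"]["b0map"] = {"masked_out": int((~b0.mask).sum())}

    if dam_pair is None:
        raise PipelineError("b1map", "missing DAM acquisition")
    try:
        epi1, _ = fm.unwarp_epi(dam_pair[0], b0, cfg.epi_echo_spacing)
        epi2, _ = fm.unwarp_epi(dam_pair[1], b0, cfg.epi_echo_spacing)
        b1 = fm.dam_b1_2d_corrected(
            epi1, epi2, b0=b0, nominal_angles=cfg.dam_nominal,
            slice_thickness_mm=cfg.slice_thickness,
            slice_spacing_mm=cfg.slice_spacing, te_ms=cfg.epi_te,
            pulse=make_pulse(cfg.pulse_descriptor),
            threshold_factor=cfg.mask_threshold_factor,
            background_sd=background_sd)
    except PipelineError:
        raise
    except Exception as e:  # noqa: BLE001
        raise PipelineError("b1map", str(e)) from e
    report["stages"]["b1map"] = {"masked_out": b1.n_masked_out}

    vfa_shape = vfa_complex.shape[2:]
    if b1.b1_factor.shape != vfa_shape or ("dam" in affines
                                           or "vfa" in affines):
        try:
            b1 = fm.resample_b1_to_spgr(
                b1, affines.get("dam", np.eye(4)), affines.get("vfa", np.eye(4)),
                vfa_shape)
        except Exception as e:  # noqa: BLE001
            raise PipelineError("resample", str(e)) from e
    report["stages"]["resample"] = {"masked_out": b1.n_masked_out}

    try:
        b0_vfa = b0.offres_hz if b0.offres_hz.shape == vfa_shape else None
        n_fa = vfa_complex.shape[0]
        water = np.zeros((n_fa,) + vfa_shape)
        fat = np.zeros_like(water)
        n_swap = 0
        for i in range(n_fa):
            w, f, swap = dixon_separate(vfa_complex[i, 0], vfa_complex[i, 1],
                                        b0=b0_vfa, te_op_ms=cfg.tes[0],
                                        te_ip_ms=cfg.tes[1])
            water[i], fat[i] = w, f
            n_swap += int(swap.sum())
    except Exception as e:  # noqa: BLE001
        raise PipelineError("dixon", str(e)) from e
    report["stages"]["dixon"] = {"fat_dominant_flags": n_swap}

    try:
        if correction is None and cfg.apply_spoiling_correction:
            correction = build_spoiling_correction(
                tr=cfg.tr, t2=cfg.spoiling_t2,
                rf_spoil_increment=cfg.rf_spoil_increment)
        t1 = fit_vfa_t1(water, np.asarray(cfg.nominal_fas), cfg.tr,
                        b1=b1.b1_factor, mask=b1.mask,
                        correction=correction if cfg.apply_spoiling_correction
                        else None,
                        bounds=cfg.fit_bounds)
    except Exception as e:  # noqa: BLE001
        raise PipelineError("fit-t1", str(e)) from e
    report["stages"]["fit-t1"] = {
        "fitted": int(t1.mask.sum()),
        "non_converged": int((~t1.converged & b1.mask).sum())}

    return PipelineResult(t1=t1, b0=b0, b1=b1, water=water, fat=fat,
                          report=report)


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    """Disk-based pipeline driver.

    Expects under ``cfg.input_dir`` the phantom-writer layout:
    vfa_fa<i>_e<j>_{mag,phase}.nii.gz, b0_e{1,2}_{mag,phase}.nii.gz,
    dam_{65,130}.nii.gz.  Writes T1/B0/B1 maps and a JSON report to
    ``cfg.output_dir``.
    """
    ind = Path(cfg.input_dir)
    n_fa = len(cfg.nominal_fas)
    try:
        vfa = np.stack([np.stack([load_complex(ind / f"vfa_fa{i}_e{j}")
                                  for j in range(2)])
                        for i in range(n_fa)])
        aff = nib.load(str(ind / "vfa_fa0_e0_mag.nii.gz")).affine
    except FileNotFoundError as e:
        raise PipelineError("load-vfa", str(e)) from e
    try:
        b0_echoes = [load_complex(ind / f"b0_e{j}") for j in (1, 2)]
    except FileNotFoundError as e:
        raise PipelineError("b0map", f"missing B0 input: {e}") from e
    try:
        dam = [load_volume(ind / f"dam_{int(a)}.nii.gz").data
               for a in cfg.dam_nominal]
    except FileNotFoundError as e:
        raise PipelineError("b1map", f"missing DAM input: {e}") from e

    res = run_pipeline_arrays(cfg, vfa, b0_echoes, dam)

    outd = Path(cfg.output_dir)
    outd.mkdir(parents=True, exist_ok=True)
    save_volume(np.nan_to_num(res.t1.t1_ms), outd / "t1_map.nii.gz", aff)
    save_volume(np.nan_to_num(res.b1.b1_factor), outd / "b1_map.nii.gz", aff)
    save_volume(np.nan_to_num(res.b0.offres_hz), outd / "b0_map.nii.gz", aff)
    (outd / "report.json").write_text(json.dumps(res.report, indent=1))
    return res


def write_phantom_acquisitions(phantom, out_dir, include=("vfa_dixon",
                                                          "b0_gre", "dam_epi")):
    """Emit a digital phantom's acquisitions + ground truth in the layout
    :func:`run_pipeline` consumes."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    aff = np.diag(list(phantom.spec.voxel_mm) + [1.0])
    sidecars = {}
    if "vfa_dixon" in include:
        vfa, sc = phantom.vfa_dixon()
        sidecars["vfa_dixon"] = sc
        for i in range(vfa.shape[0]):
            for j in range(vfa.shape[1]):
                save_complex(vfa[i, j], out / f"vfa_fa{i}_e{j}", aff)
    if "b0_gre" in include:
        echoes, sc = phantom.b0_gre()
        sidecars["b0_gre"] = sc
        for j, e in enumerate(echoes, start=1):
            save_complex(e, out / f"b0_e{j}", aff)
    if "dam_epi" in include:
        (d1, d2), sc = phantom.dam_epi()
        sidecars["dam_epi"] = sc
        save_volume(d1, out / f"dam_{int(sc['nominal_angles'][0])}.nii.gz", aff)
        save_volume(d2, out / f"dam_{int(sc['nominal_angles'][1])}.nii.gz", aff)
    if "dam_3d" in include:
        (d1, d2), sc = phantom.dam_3d()
        sidecars["dam_3d"] = sc
        save_volume(d1, out / "dam3d_65.nii.gz", aff)
        save_volume(d2, out / "dam3d_130.nii.gz", aff)
    if "ir_se" in include:
        vols, sc = phantom.ir_se()
        sidecars["ir_se"] = sc
        for i in range(vols.shape[0]):
            save_volume(vols[i], out / f"ir_ti{i}.nii.gz", aff)
    gt = phantom.ground_truth()
    for name in ("t1_ms", "b1_factor", "b0_hz", "pdff"):
        save_volume(getattr(gt, name), out / f"truth_{name}.nii.gz", aff)
    save_volume(gt.tissue_mask.astype(np.uint8), out / "truth_mask.nii.gz", aff)
    (out / "sidecars.json").write_text(json.dumps(sidecars, indent=1))
    (out / "phantom_spec.json").write_text(phantom.spec.to_json())
    return sidecars
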