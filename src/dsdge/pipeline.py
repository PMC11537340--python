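"""Dynamic glucose enhanced post-processing of Z-spectral image series.

Input is a 4D dynamic Z-spectral acquisition: for every dynamic, one image
per saturation offset, with the +/-10 ppm offsets acquired twice for
normalization.  The pipeline normalizes each voxel's spectra, fits a
Lorentzian per voxel per dynamic to obtain linewidth (LW) maps in Hz,
averages the pre-infusion dynamics into a baseline LWbase with +/-2 SD
outlier rejection, and derives

    dLW(t) [%]  = 100 * (LW(t) - LWbase) / LWbase
    AUC    [%]  = mean of dLW over a post-infusion-start window

as voxelwise maps, plus region-of-interest time curves with 3-point
moving-average smoothing.

Images travel as NIfTI (4th axis = offset-within-dynamic, fastest, times
dynamics) with a JSON sidecar carrying the offset schedule and timing.
Rigid motion correction is an external concern: the pipeline consumes
already-corrected series and records whether a correction hook ran.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .lineshape import DEFAULT_LARMOR_MHZ, fit_lorentzian
from .bm_core import ZSpectrum

logger = logging.getLogger(__name__)

__all__ = [
    "SCHEDULE_32PT",
    "INFUSION_DOSE_G",
    "INFUSION_RATE_G_PER_MIN",
    "DynamicSeries",
    "DGEResult",
    "normalize_dynamic",
    "compute_lw_maps",
    "baseline_lw",
    "delta_lw",
    "auc_maps",
    "roi_timecurve",
    "infusion_block_dynamics",
    "run_pipeline",
]

#: Acquisition offset schedule: +/-10 ppm twice (second pair normalizes),
#: then 14 offset magnitudes alternating around water -> 32 acquisitions.
_SCHED_HALF = (5.0, 2.5, 2.0, 1.5, 1.2, 1.0, 0.80, 0.70, 0.60, 0.50, 0.40,
               0.30, 0.20, 0.10)
SCHEDULE_32PT: tuple[float, ...] = (10.0, 10.0, -10.0, -10.0) + tuple(
    x for m in _SCHED_HALF for x in (m, -m)
)

#: D-glucose infusion: 35 g at 6.25 g/min.
INFUSION_DOSE_G = 35.0
INFUSION_RATE_G_PER_MIN = 6.25

#: LWbase below this floor (Hz) is masked to avoid dLW blow-up.
LW_BASE_FLOOR_HZ = 5.0


def infusion_block_dynamics(dynamic_duration_s: float,
                            dose_g: float = INFUSION_DOSE_G,
                            rate_g_per_min: float = INFUSION_RATE_G_PER_MIN) -> int:
    """Number of dynamics covering the infusion itself, rounded up."""
    infusion_s = 60.0 * dose_g / rate_g_per_min
    return int(np.ceil(infusion_s / dynamic_duration_s))


@dataclass
class DynamicSeries:
    """A dynamic Z-spectral image series.

    ``data`` has shape ``(nx, ny, nz, n_dynamics, n_offsets)``; the offset
    schedule is identical across dynamics.  ``mask`` selects voxels to
    process.  ``normalized`` records whether intensities are already Z
    values (S/S0).
    """

    data: np.ndarray
    offset_schedule_ppm: np.ndarray
    dynamic_duration_s: float
    infusion_start_dynamic: int
    mask: np.ndarray | None = None
    larmor_MHz: float = DEFAULT_LARMOR_MHZ
    normalized: bool = False
    motion_corrected: bool = False
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.offset_schedule_ppm = np.asarray(self.offset_schedule_ppm, dtype=float)
        if self.data.ndim != 5:
            raise ValueError("data must be 5D (x, y, z, dynamic, offset)")
        if self.data.shape[-1] != self.offset_schedule_ppm.size:
            raise ValueError("last data axis must match the offset schedule")
        if not 0 <= self.infusion_start_dynamic < self.n_dynamics:
            raise ValueError("infusion_start_dynamic out of range")
        if self.mask is None:
            self.mask = np.ones(self.data.shape[:3], dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.data.shape[:3]:
                raise ValueError("mask shape must match the spatial grid")

    @property
    def n_dynamics(self) -> int:
        return self.data.shape[3]

    @property
    def n_offsets(self) -> int:
        return self.data.shape[4]

    @property
    def times_s(self) -> np.ndarray:
        """Mid-dynamic acquisition times."""
        return (np.arange(self.n_dynamics) + 0.5) * self.dynamic_duration_s

    # -- IO -----------------------------------------------------------------

    def to_nifti(self, stem) -> tuple[Path, Path]:
        """Write ``<stem>.nii`` (4D, offsets fastest) + ``<stem>.json``."""
        import nibabel as nib

        stem = Path(stem)
        nx, ny, nz, nd, no = self.data.shape
        vol = self.data.reshape(nx, ny, nz, nd * no)
        img = nib.Nifti1Image(vol.astype(np.float32), affine=np.eye(4))
        nii_path = stem.with_suffix(".nii")
        nib.save(img, nii_path)
        sidecar = {
            "offset_schedule_ppm": self.offset_schedule_ppm.tolist(),
            "dynamic_duration_s": self.dynamic_duration_s,
            "n_dynamics": nd,
            "infusion_start_dynamic": self.infusion_start_dynamic,
            "larmor_MHz": self.larmor_MHz,
            "normalized": self.normalized,
            "motion_corrected": self.motion_corrected,
            "metadata": self.metadata,
        }
        json_path = stem.with_suffix(".json")
        json_path.write_text(json.dumps(sidecar, indent=2))
        if self.mask is not None and not self.mask.all():
            nib.save(
                nib.Nifti1Image(self.mask.astype(np.uint8), affine=np.eye(4)),
                stem.parent / (stem.name + "_mask.nii"),
            )
        return nii_path, json_path

    @classmethod
    def from_nifti(cls, stem) -> "DynamicSeries":
        import nibabel as nib

        stem = Path(stem)
        sidecar = json.loads(stem.with_suffix(".json").read_text())
        vol = np.asarray(nib.load(stem.with_suffix(".nii")).dataobj, dtype=float)
        schedule = np.asarray(sidecar["offset_schedule_ppm"], dtype=float)
        nd = int(sidecar["n_dynamics"])
        no = schedule.size
        data = vol.reshape(vol.shape[0], vol.shape[1], vol.shape[2], nd, no)
        mask_path = stem.parent / (stem.name + "_mask.nii")
        mask = None
        if mask_path.exists():
            mask = np.asarray(nib.load(mask_path).dataobj).astype(bool)
        return cls(
            data=data,
            offset_schedule_ppm=schedule,
            dynamic_duration_s=float(sidecar["dynamic_duration_s"]),
            infusion_start_dynamic=int(sidecar["infusion_start_dynamic"]),
            mask=mask,
            larmor_MHz=float(sidecar.get("larmor_MHz", DEFAULT_LARMOR_MHZ)),
            normalized=bool(sidecar.get("normalized", False)),
            motion_corrected=bool(sidecar.get("motion_corrected", False)),
            metadata=sidecar.get("metadata", {}),
        )


@dataclass
class DGEResult:
    """Voxelwise outputs of the DS-DGE pipeline."""

    lw_maps_hz: np.ndarray          # (x, y, z, dynamic)
    lw_base_hz: np.ndarray          # (x, y, z)
    delta_lw_percent: np.ndarray    # (x, y, z, dynamic)
    auc_full_percent: np.ndarray    # (x, y, z)
    auc_infusion_block_percent: np.ndarray  # (x, y, z)
    rejected_baseline_count: np.ndarray     # (x, y, z), int
    mask: np.ndarray                # final processed-voxel mask
    infusion_start_dynamic: int
    failed_fit_fraction: float

    def save(self, out_dir) -> None:
        import nibabel as nib

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        eye = np.eye(4)
        for name, arr in [
            ("lw_maps_hz", self.lw_maps_hz),
            ("lw_base_hz", self.lw_base_hz),
            ("delta_lw_percent", self.delta_lw_percent),
            ("auc_full_percent", self.auc_full_percent),
            ("auc_infusion_block_percent", self.auc_infusion_block_percent),
            ("rejected_baseline_count", self.rejected_baseline_count),
            ("mask", self.mask.astype(np.uint8)),
        ]:
            nib.save(nib.Nifti1Image(np.asarray(arr, dtype=np.float32), eye),
                     out / f"{name}.nii")


# ---------------------------------------------------------------------------
# Pipeline stages


def _norm_indices(schedule: np.ndarray) -> tuple[int, int]:
    """Indices of the *second* +10 and second -10 ppm acquisitions."""
    pos = np.flatnonzero(np.isclose(schedule, 10.0))
    neg = np.flatnonzero(np.isclose(schedule, -10.0))
    if pos.size < 2 or neg.size < 2:
        raise ValueError(
            "offset schedule must contain +10 and -10 ppm twice each "
            "for normalization"
        )
    return int(pos[1]), int(neg[1])


def normalize_dynamic(raw: DynamicSeries) -> DynamicSeries:
    """Normalize per voxel per dynamic by the second +/-10 ppm pair.

    S0 is the mean of the second +10 ppm and second -10 ppm acquisitions;
    voxels with non-positive S0 in any dynamic are masked out.
    """
    if raw.normalized:
        return raw
    ip, im = _norm_indices(raw.offset_schedule_ppm)
    s0 = 0.5 * (raw.data[..., ip] + raw.data[..., im])  # (x,y,z,dyn)
    good = np.all(s0 > 0, axis=-1)
    mask = raw.mask & good
    with np.errstate(divide="ignore", invalid="ignore"):
        z = raw.data / s0[..., None]
    z[~np.isfinite(z)] = 0.0
    return DynamicSeries(
        data=z,
        offset_schedule_ppm=raw.offset_schedule_ppm.copy(),
        dynamic_duration_s=raw.dynamic_duration_s,
        infusion_start_dynamic=raw.infusion_start_dynamic,
        mask=mask,
        larmor_MHz=raw.larmor_MHz,
        normalized=True,
        motion_corrected=raw.motion_corrected,
        metadata=dict(raw.metadata),
    )


def compute_lw_maps(series: DynamicSeries,
                    fit_window_ppm: float = 5.0) -> np.ndarray:
    """Per-voxel, per-dynamic Lorentzian linewidth maps (Hz).

    Non-converged fits become NaN.  Identical voxel spectra (e.g. uniform
    noiseless phantom regions) are fitted once and cached.
    """
    if not series.normalized:
        raise ValueError("series must be normalized first (normalize_dynamic)")
    nx, ny, nz, nd, _ = series.data.shape
    lw = np.full((nx, ny, nz, nd), np.nan)
    offsets = series.offset_schedule_ppm
    cache: dict[bytes, float] = {}
    n_fit = n_fail = 0
    voxels = np.argwhere(series.mask)
    for (i, j, k) in voxels:
        for d in range(nd):
            z = series.data[i, j, k, d]
            key = z.tobytes()
            if key in cache:
                lw[i, j, k, d] = cache[key]
                continue
            n_fit += 1
            res = fit_lorentzian(
                ZSpectrum(offsets, z), series.larmor_MHz, fit_window_ppm
            )
            val = res.fwhm_hz if res.converged else np.nan
            if not res.converged:
                n_fail += 1
            cache[key] = val
            lw[i, j, k, d] = val
    frac_failed = n_fail / n_fit if n_fit else 0.0
    if n_fit and frac_failed > 0.5:
        warnings.warn(
            f"{100 * frac_failed:.0f}% of in-mask Lorentzian fits failed",
            RuntimeWarning,
        )
    logger.info("fitted %d spectra (%d failed)", n_fit, n_fail)
    return lw


def baseline_lw(lw_maps_hz: np.ndarray,
                infusion_start: int) -> tuple[np.ndarray, np.ndarray]:
    """Baseline linewidth with +/-2 SD outlier rejection.

    Per voxel, pre-infusion LW values outside mean +/- 2 SD are discarded
    (single pass) and the survivors averaged.  Returns ``(lw_base,
    rejected_count)``; voxels where everything was rejected or missing are
    NaN.
    """
    if infusion_start < 3:
        raise ValueError("need at least 3 pre-infusion dynamics")
    base = lw_maps_hz[..., :infusion_start]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(base, axis=-1, keepdims=True)
        sd = np.nanstd(base, axis=-1, keepdims=True)
        keep = np.abs(base - mean) <= 2.0 * sd
        keep &= np.isfinite(base)
        n_pre = np.isfinite(base).sum(axis=-1)
        rejected = (n_pre - keep.sum(axis=-1)).astype(int)
        masked = np.where(keep, base, np.nan)
        lw_base = np.nanmean(masked, axis=-1)
    lw_base[keep.sum(axis=-1) == 0] = np.nan
    return lw_base, rejected


def delta_lw(lw_maps_hz: np.ndarray, lw_base_hz: np.ndarray) -> np.ndarray:
    """Percent linewidth change relative to baseline, per voxel per dynamic."""
    base = lw_base_hz[..., None]
    with np.errstate(divide="ignore", invalid="ignore"):
        d = 100.0 * (lw_maps_hz - base) / base
    d[..., :][~np.isfinite(d)] = np.nan
    d[np.broadcast_to(~(lw_base_hz > LW_BASE_FLOOR_HZ)[..., None], d.shape)] = np.nan
    return d


def auc_maps(delta_lw_percent: np.ndarray, infusion_start: int,
             window: str = "full_post_start",
             dynamic_duration_s: float | None = None) -> np.ndarray:
    """Time-averaged dLW over a post-infusion-start window (%).

    ``window="full_post_start"`` averages from infusion start through the
    end of the scan; ``"infusion_block_only"`` restricts to the dynamics
    covering the infusion itself (requires ``dynamic_duration_s``).
    Missing dynamics are excluded from the mean.
    """
    nd = delta_lw_percent.shape[-1]
    if window == "full_post_start":
        stop = nd
    elif window == "infusion_block_only":
        if dynamic_duration_s is None:
            raise ValueError("infusion_block_only window needs dynamic_duration_s")
        stop = min(nd, infusion_start + infusion_block_dynamics(dynamic_duration_s))
    else:
        raise ValueError(f"unknown window {window!r}")
    if stop <= infusion_start:
        raise ValueError("empty AUC window")
    sel = delta_lw_percent[..., infusion_start:stop]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanmean(sel, axis=-1)


def roi_timecurve(delta_lw_percent: np.ndarray, roi_mask: np.ndarray,
                  dynamic_duration_s: float,
                  smoothing_window: int = 3) -> dict[str, np.ndarray]:
    """ROI-mean dLW(t) with centered moving-average smoothing.

    Returns ``{"time_s", "raw_percent", "smoothed_percent"}``.  Smoothing
    replicates edge values to keep the curve length.
    """
    roi_mask = np.asarray(roi_mask, dtype=bool)
    if not roi_mask.any():
        raise ValueError("empty ROI")
    nd = delta_lw_percent.shape[-1]
    vals = delta_lw_percent[roi_mask]  # (n_voxels, nd)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        raw = np.nanmean(vals, axis=0)
    if smoothing_window < 1 or smoothing_window % 2 == 0:
        raise ValueError("smoothing_window must be odd and >= 1")
    half = smoothing_window // 2
    padded = np.concatenate([np.repeat(raw[:1], half), raw,
                             np.repeat(raw[-1:], half)])
    kernel = np.ones(smoothing_window) / smoothing_window
    smoothed = np.convolve(padded, kernel, mode="valid")
    time_s = (np.arange(nd) + 0.5) * dynamic_duration_s
    return {"time_s": time_s, "raw_percent": raw, "smoothed_percent": smoothed}


def run_pipeline(raw: DynamicSeries, fit_window_ppm: float = 5.0) -> DGEResult:
    """Full DS-DGE processing: normalize, fit, baseline, dLW, AUC."""
    series = normalize_dynamic(raw)
    lw = compute_lw_maps(series, fit_window_ppm)
    n_fit = series.mask.sum() * series.n_dynamics
    failed = float(np.isnan(lw[series.mask]).sum() / n_fit) if n_fit else 0.0
    lw_base, rejected = baseline_lw(lw, series.infusion_start_dynamic)
    dlw = delta_lw(lw, lw_base)
    auc_full = auc_maps(dlw, series.infusion_start_dynamic, "full_post_start")
    auc_block = auc_maps(dlw, series.infusion_start_dynamic,
                         "infusion_block_only", series.dynamic_duration_s)
    final_mask = series.mask & np.isfinite(lw_base) & (lw_base > LW_BASE_FLOOR_HZ)
    return DGEResult(
        lw_maps_hz=lw,
        lw_base_hz=lw_base,
        delta_lw_percent=dlw,
        auc_full_percent=auc_full,
        auc_infusion_block_percent=auc_block,
        rejected_baseline_count=rejected,
        mask=final_mask,
        infusion_start_dynamic=series.infusion_start_dynamic,
        failed_fit_fraction=failed,
    )
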