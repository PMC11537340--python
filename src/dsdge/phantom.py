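"""Digital head phantom: seeded synthetic dynamic Z-spectral series.

Builds a deterministic geometric label map (WM core, GM rim, CSF
ventricles, spherical tumor, cylindrical vessel), gives each region a
tissue model and a glucose uptake time course, simulates the region
Z-spectra with the compartmental Bloch-McConnell machinery, resamples them
onto the experimental 32-offset schedule, broadcasts them to voxels and
adds per-voxel Rician noise.  The output is a
:class:`~dsdge.pipeline.DynamicSeries` plus ground truth, so the full
DS-DGE pipeline is testable end to end without any acquired data.

Regions are internally homogeneous (one spectrum per region per dynamic;
noise varies per voxel).  Uptake is an exponential approach from the
normoglycemic toward the hyperglycemic concentrations of each tissue's
compartments — a stand-in for measured uptake curves, which this phantom
does not attempt to model mechanistically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from . import tissue as ts
from .bm_core import PulseTrain, SimProtocol, ValidationError, ZSpectrum
from .pipeline import SCHEDULE_32PT, DynamicSeries

__all__ = [
    "RegionSpec",
    "PhantomSpec",
    "build_label_map",
    "uptake_curve",
    "generate_dynamic_series",
    "REGION_LABELS",
]

REGION_LABELS = {
    "background": 0,
    "WM": 1,
    "GM": 2,
    "CSF": 3,
    "TUMOR": 4,
    "vessel": 5,
}


@dataclass(frozen=True)
class RegionSpec:
    """Per-region tissue reference and uptake curve parameters."""

    tissue: str                  # key into the tissue table
    onset_dynamic: int = 8       # first dynamic with glucose arriving
    rise_time_dynamics: float = 4.0  # exponential time constant, in dynamics
    uptake_fraction: float = 1.0     # plateau, as fraction of ngl->hgl span

    def __post_init__(self) -> None:
        if self.rise_time_dynamics <= 0:
            raise ValidationError("rise_time_dynamics must be positive")
        if not 0.0 <= self.uptake_fraction <= 1.0:
            raise ValidationError("uptake_fraction must be in [0, 1]")


def _default_regions() -> dict[str, RegionSpec]:
    return {
        "WM": RegionSpec("WM"),
        "GM": RegionSpec("GM"),
        "CSF": RegionSpec("CSF", rise_time_dynamics=6.0),
        "TUMOR": RegionSpec("TUMOR", rise_time_dynamics=3.0),
        "vessel": RegionSpec("blood", rise_time_dynamics=1.0),
    }


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, dynamics, noise and seed of a synthetic acquisition."""

    grid_shape: tuple[int, int, int] = (24, 24, 16)
    n_dynamics: int = 40
    infusion_start_dynamic: int = 8
    dynamic_duration_s: float = 38.4   # 32 offsets x 1.2 s (scanner prints 38.2)
    noise_sigma_fraction: float = 0.02
    seed: int = 0
    tumor_radius_vox: float = 3.5
    vessel_radius_vox: float = 1.5
    regions: Mapping[str, RegionSpec] = field(default_factory=_default_regions)

    def __post_init__(self) -> None:
        if min(self.grid_shape) < 8 or max(self.grid_shape) < 16:
            raise ValidationError("grid must be at least 16 voxels across")
        if not 0 <= self.infusion_start_dynamic < self.n_dynamics:
            raise ValidationError("infusion_start_dynamic out of range")
        for name, reg in self.regions.items():
            if reg.onset_dynamic < self.infusion_start_dynamic:
                raise ValidationError(
                    f"region {name!r}: uptake onset precedes infusion start"
                )
        if self.tumor_radius_vox < 0 or self.vessel_radius_vox < 0:
            raise ValidationError("radii must be non-negative")


def build_label_map(spec: PhantomSpec) -> np.ndarray:
    """Deterministic geometric label image for the phantom.

    Concentric head geometry: an ellipsoidal GM rim around a WM core, two
    box-like CSF ventricles, a spherical tumor in one hemisphere and a
    straight cylindrical vessel along z.
    """
    nx, ny, nz = spec.grid_shape
    cx, cy, cz = (nx - 1) / 2, (ny - 1) / 2, (nz - 1) / 2
    x, y, z = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz),
                          indexing="ij")
    # normalized ellipsoidal radius of the head
    rx, ry, rz = 0.45 * nx, 0.45 * ny, 0.48 * nz
    r = np.sqrt(((x - cx) / rx) ** 2 + ((y - cy) / ry) ** 2
                + ((z - cz) / rz) ** 2)
    labels = np.zeros(spec.grid_shape, dtype=np.uint8)
    labels[r <= 1.0] = REGION_LABELS["GM"]
    labels[r <= 0.78] = REGION_LABELS["WM"]

    # two ventricles flanking the midline
    vx = max(1, int(round(0.08 * nx)))
    vy = max(1, int(round(0.14 * ny)))
    vz = max(1, int(round(0.2 * nz)))
    for side in (-1, 1):
        x0 = int(round(cx + side * 0.14 * nx))
        sl = (slice(x0 - vx // 2, x0 + (vx + 1) // 2),
              slice(int(cy) - vy // 2, int(cy) + (vy + 1) // 2),
              slice(int(cz) - vz // 2, int(cz) + (vz + 1) // 2))
        region = labels[sl]
        region[region == REGION_LABELS["WM"]] = REGION_LABELS["CSF"]

    # spherical tumor in the posterior WM
    if spec.tumor_radius_vox > 0:
        tx, ty, tz = cx + 0.22 * nx, cy - 0.2 * ny, cz
        if spec.tumor_radius_vox > min(nx, ny, nz) / 2:
            raise ValidationError("tumor radius exceeds the grid")
        rt = np.sqrt((x - tx) ** 2 + (y - ty) ** 2 + (z - tz) ** 2)
        inside = (rt <= spec.tumor_radius_vox) & (labels != 0)
        labels[inside] = REGION_LABELS["TUMOR"]

    # vessel: cylinder along z in the anterior left quadrant
    if spec.vessel_radius_vox > 0:
        wx, wy = cx - 0.25 * nx, cy + 0.22 * ny
        rv = np.sqrt((x - wx) ** 2 + (y - wy) ** 2)
        inside = (rv <= spec.vessel_radius_vox) & (labels != 0)
        labels[inside] = REGION_LABELS["vessel"]
    return labels


def uptake_curve(baseline_mM: float, increment_mM: float, onset_dynamic: int,
                 rise_time_dynamics: float, n_dynamics: int) -> np.ndarray:
    """Per-dynamic glucose concentration (mM).

    Constant at ``baseline_mM`` before onset, then an exponential approach
    ``baseline + increment * (1 - exp(-(t - onset)/tau))``.
    """
    if rise_time_dynamics <= 0:
        raise ValidationError("rise_time_dynamics must be positive")
    if increment_mM < 0:
        raise ValidationError("increment must be non-negative")
    t = np.arange(n_dynamics, dtype=float)
    c = np.full(n_dynamics, float(baseline_mM))
    after = t >= onset_dynamic
    c[after] += increment_mM * (1.0 - np.exp(-(t[after] - onset_dynamic)
                                             / rise_time_dynamics))
    return c


def _uptake_fraction_curve(reg: RegionSpec, n_dynamics: int) -> np.ndarray:
    """Fraction of the ngl->hgl concentration span reached per dynamic."""
    return uptake_curve(0.0, reg.uptake_fraction, reg.onset_dynamic,
                        reg.rise_time_dynamics, n_dynamics)


def generate_dynamic_series(
    spec: PhantomSpec,
    protocol: SimProtocol | None = None,
    train: PulseTrain | None = None,
    table: ts.TissueTable | None = None,
) -> tuple[DynamicSeries, pd.DataFrame]:
    """Simulate the phantom acquisition.

    Returns the (noisy, unnormalized-Z) dynamic series and a ground-truth
    table with one row per region per dynamic: the uptake fraction and the
    noiseless region spectrum's provenance.  The series' intensities are Z
    values with the +/-10 ppm normalization pair embedded, so the full
    pipeline (including its normalization stage) applies.
    """
    table = table or ts.load_tissue_table()
    protocol = protocol or ts.default_protocol()
    train = train or ts.default_train()
    labels = build_label_map(spec)
    rng = np.random.default_rng(spec.seed)
    schedule = np.asarray(SCHEDULE_32PT)

    nd = spec.n_dynamics
    data = np.zeros(spec.grid_shape + (nd, schedule.size))
    truth_rows = []
    cache: dict = {}
    for name, reg in spec.regions.items():
        lbl = REGION_LABELS[name]
        vox = labels == lbl
        if not vox.any():
            continue
        tis = table.tissue(reg.tissue)
        frac = _uptake_fraction_curve(reg, nd)
        for d in range(nd):
            g = float(frac[d])
            scale = {k: g for k in tis.compartments()}
            spec_d = ts.tissue_zspectrum(
                tis, ts.NORMOGLYCEMIA, train, protocol, table.hydroxyl,
                concentration_scale=scale, _cache=cache,
            )
            resampled = ts.resample_offsets(spec_d, schedule)
            data[vox, d, :] = resampled.intensities
            truth_rows.append(
                {"region": name, "tissue": reg.tissue, "dynamic": d,
                 "uptake_fraction": g}
            )
    simulated = [REGION_LABELS[name] for name in spec.regions]
    mask = np.isin(labels, simulated)
    if spec.noise_sigma_fraction > 0:
        sigma = spec.noise_sigma_fraction
        n1 = rng.normal(0.0, sigma, size=data.shape)
        n2 = rng.normal(0.0, sigma, size=data.shape)
        data = np.sqrt((data + n1) ** 2 + n2 ** 2)
    series = DynamicSeries(
        data=data,
        offset_schedule_ppm=schedule,
        dynamic_duration_s=spec.dynamic_duration_s,
        infusion_start_dynamic=spec.infusion_start_dynamic,
        mask=mask,
        larmor_MHz=protocol.larmor_frequency_MHz,
        normalized=False,
        metadata={
            "phantom_seed": spec.seed,
            "noise_sigma_fraction": spec.noise_sigma_fraction,
            "scanner_dynamic_duration_s": 38.2,
            "labels": {k: int(v) for k, v in REGION_LABELS.items()},
        },
    )
    truth = pd.DataFrame(truth_rows)
    return series, truth


def region_masks(spec: PhantomSpec) -> dict[str, np.ndarray]:
    """Boolean mask per named region of the phantom geometry."""
    labels = build_label_map(spec)
    return {name: labels == lbl for name, lbl in REGION_LABELS.items()
            if lbl != 0}
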