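"""Compartmental glucose tissue models for DS Z-spectrum simulation.

Builds Bloch-McConnell pool systems for brain-tissue water compartments
(arterial/venous blood, extravascular-extracellular space, cell), converts
D-glucose concentrations into hydroxyl proton-pool fractions, mixes
compartment Z-spectra into tissue Z-spectra with water-density-corrected
volume weights, adds Rician noise, and resamples onto experimental offset
grids.

The shipped parameter table (``data/tissue_table.json``) holds per-
compartment relaxation times, water densities and glucose concentrations
for the normoglycemic and hyperglycemic state, plus the tissue volume
fractions.  User overrides merge by key.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
from scipy.interpolate import CubicSpline

from .bm_core import (
    Pool,
    PulseTrain,
    SimProtocol,
    ValidationError,
    ZSpectrum,
    simulate_zspectrum,
    water_pool,
)

__all__ = [
    "GlycemicState",
    "Compartment",
    "TissueModel",
    "load_tissue_table",
    "glucose_pools",
    "compartment_zspectrum",
    "mix_tissue_zspectrum",
    "tissue_zspectrum",
    "add_rician_noise",
    "resample_offsets",
    "OFFSETS_41PT",
    "OFFSETS_28PT",
    "default_protocol",
    "default_train",
]

NORMOGLYCEMIA = "normoglycemia"
HYPERGLYCEMIA = "hyperglycemia"
GlycemicState = str

#: Simulation offset grid: 41 offsets from -10 to +10 ppm, dense near water.
_HALF_41 = (10.0, 5.0, 4.0, 3.0, 2.5, 2.0, 1.75, 1.5, 1.25, 1.0, 0.80, 0.65,
            0.55, 0.48, 0.40, 0.33, 0.26, 0.18, 0.11, 0.036)
OFFSETS_41PT: tuple[float, ...] = tuple(
    sorted([-x for x in _HALF_41] + [0.0] + list(_HALF_41))
)

#: Experimental resampling grid: 28 offsets from -5 to +5 ppm.
_HALF_28 = (5.0, 2.5, 2.0, 1.5, 1.2, 1.0, 0.80, 0.70, 0.60, 0.50, 0.40,
            0.30, 0.20, 0.10)
OFFSETS_28PT: tuple[float, ...] = tuple(
    sorted([-x for x in _HALF_28] + list(_HALF_28))
)


def default_protocol(**overrides) -> SimProtocol:
    """41-offset, 3 T, TR 1.2 s protocol with the sideband-free
    steady-state saturation model (see :class:`SimProtocol`)."""
    kwargs = dict(offsets_ppm=OFFSETS_41PT, field_strength_T=3.0, TR_s=1.2,
                  initial_state="cycled_steady_state",
                  saturation_model="cw_steady_state")
    kwargs.update(overrides)
    return SimProtocol(**kwargs)


def default_train(**overrides) -> PulseTrain:
    """Ten consecutive 50-ms sinc-Gauss pulses at 0.5 uT peak (tsat 0.5 s)."""
    kwargs = dict(shape="sinc_gauss", n_pulses=10, pulse_duration_s=0.050,
                  b1_peak_uT=0.5, interpulse_delay_s=0.0)
    kwargs.update(overrides)
    return PulseTrain(**kwargs)


@dataclass(frozen=True)
class Compartment:
    """One water environment with its own relaxation and glucose content."""

    id: str
    T1_water_s: float
    T2_water_s: float
    water_density: float  # mL water / mL compartment
    glucose_mM: Mapping[GlycemicState, float]
    pH_regime: str = "normal"

    def __post_init__(self) -> None:
        if self.T1_water_s is None or self.T2_water_s is None:
            raise ValidationError(f"compartment {self.id!r}: missing relaxation time")
        if not 0.0 < self.water_density <= 1.0:
            raise ValidationError(f"compartment {self.id!r}: water_density not in (0,1]")
        for state, c in self.glucose_mM.items():
            if c < 0:
                raise ValidationError(
                    f"compartment {self.id!r}: negative glucose at {state}"
                )
        if (HYPERGLYCEMIA in self.glucose_mM and NORMOGLYCEMIA in self.glucose_mM
                and self.glucose_mM[HYPERGLYCEMIA] < self.glucose_mM[NORMOGLYCEMIA]):
            raise ValidationError(
                f"compartment {self.id!r}: hyperglycemic concentration below baseline"
            )

    def concentration(self, state: GlycemicState) -> float:
        return float(self.glucose_mM[state])

    def with_concentration(self, state: GlycemicState, value: float) -> "Compartment":
        g = dict(self.glucose_mM)
        g[state] = float(value)
        return replace(self, glucose_mM=g)


@dataclass(frozen=True)
class TissueModel:
    """Named mixture of blood / EES / cell compartments.

    Volume fractions are mL compartment per mL tissue; the blood fraction is
    split into arterial and venous sub-fractions (mL per mL blood).
    """

    name: str
    blood_fraction: float
    EES_fraction: float
    cell_fraction: float
    arterial_subfraction: float
    venous_subfraction: float
    tissue_water_density: float
    arterial: Compartment | None = None
    venous: Compartment | None = None
    EES: Compartment | None = None
    cell: Compartment | None = None

    def __post_init__(self) -> None:
        fs = (self.blood_fraction, self.EES_fraction, self.cell_fraction,
              self.arterial_subfraction, self.venous_subfraction)
        if any(f < 0 or f > 1 for f in fs):
            raise ValidationError(f"tissue {self.name!r}: fractions must be in [0,1]")
        if abs(self.blood_fraction + self.EES_fraction + self.cell_fraction - 1.0) > 1e-9:
            raise ValidationError(
                f"tissue {self.name!r}: blood+EES+cell fractions must sum to 1"
            )
        if abs(self.arterial_subfraction + self.venous_subfraction - 1.0) > 1e-9:
            raise ValidationError(
                f"tissue {self.name!r}: arterial+venous sub-fractions must sum to 1"
            )

    def compartments(self) -> dict[str, Compartment]:
        """Compartments with non-zero weight in this tissue."""
        out: dict[str, Compartment] = {}
        if self.blood_fraction > 0:
            if self.arterial_subfraction > 0:
                out["arterial"] = self.arterial
            if self.venous_subfraction > 0:
                out["venous"] = self.venous
        if self.EES_fraction > 0:
            out["EES"] = self.EES
        if self.cell_fraction > 0:
            out["cell"] = self.cell
        missing = [k for k, v in out.items() if v is None]
        if missing:
            raise ValidationError(
                f"tissue {self.name!r}: missing compartment definitions {missing}"
            )
        return out


@dataclass(frozen=True)
class HydroxylConfig:
    """Glucose hydroxyl pool constants: shifts, multiplicities, exchange."""

    shifts_ppm: tuple[float, ...]
    protons_per_glucose: tuple[float, ...]
    exchange_rates_hz: Mapping[str, tuple[float, ...]]
    T1_s: float
    T2_s: float
    water_proton_concentration_mM: float = 111000.0


class TissueTable:
    """The shipped compartment/tissue parameter resource."""

    def __init__(self, raw: dict):
        self.raw = raw
        hp = raw["hydroxyl_pools"]
        self.hydroxyl = HydroxylConfig(
            shifts_ppm=tuple(hp["shifts_ppm"]),
            protons_per_glucose=tuple(hp["protons_per_glucose"]),
            exchange_rates_hz={k: tuple(v) for k, v in hp["exchange_rates_hz"].items()},
            T1_s=hp["T1_s"],
            T2_s=hp["T2_s"],
            water_proton_concentration_mM=raw["water_proton_concentration_mM"],
        )
        self.compartments: dict[str, Compartment] = {
            cid: Compartment(
                id=cid,
                T1_water_s=c["T1_s"],
                T2_water_s=c["T2_s"],
                water_density=c["water_density"],
                glucose_mM=dict(c["glucose_mM"]),
                pH_regime=c["pH_regime"],
            )
            for cid, c in raw["compartments"].items()
        }
        self.tissues: dict[str, TissueModel] = {}
        for name, t in raw["tissues"].items():
            self.tissues[name] = TissueModel(
                name=name,
                blood_fraction=t["blood_fraction"],
                EES_fraction=t["EES_fraction"],
                cell_fraction=t["cell_fraction"],
                arterial_subfraction=t["arterial_subfraction"],
                venous_subfraction=t["venous_subfraction"],
                tissue_water_density=t["tissue_water_density"],
                arterial=self.compartments.get("arterial"),
                venous=self.compartments.get("venous"),
                EES=self.compartments.get(t["EES_compartment"])
                if t["EES_compartment"] else None,
                cell=self.compartments.get(t["cell_compartment"])
                if t["cell_compartment"] else None,
            )
        self.reference_results = raw.get("reference_simulation_results", {})

    def tissue(self, name: str) -> TissueModel:
        return self.tissues[name]


def _deep_merge(base: dict, override: Mapping) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, Mapping) and isinstance(out.get(k), dict):
            out[k] = _deep_merge(out[k], v)
        else:
            out[k] = v
    return out


def load_tissue_table(overrides: Mapping | None = None,
                      path=None) -> TissueTable:
    """Load the packaged tissue table, optionally merged with overrides."""
    if path is not None:
        raw = json.loads(open(path).read())
    else:
        raw = json.loads(
            resources.files("dsdge.data").joinpath("tissue_table.json").read_text()
        )
    if overrides:
        raw = _deep_merge(raw, overrides)
    return TissueTable(raw)


# ---------------------------------------------------------------------------
# Pools from glucose concentration


def glucose_pools(
    concentration_mM: float,
    pH_regime: str = "normal",
    config: HydroxylConfig | None = None,
) -> list[Pool]:
    """Hydroxyl proton pools for a D-glucose concentration.

    Each of the four hydroxyl resonances carries its proton multiplicity
    (1 : 3 : 0.36 : 0.64 for the 0.66 / 1.28 / 2.08 / 2.88 ppm pools, the
    anomeric OH split 36:64 between the alpha and beta anomer).  The pool
    proton fraction is ``multiplicity * C / (2 * 55,500 mM)`` relative to
    water protons.
    """
    if concentration_mM < 0:
        raise ValidationError("glucose concentration must be non-negative")
    cfg = config or load_tissue_table().hydroxyl
    if pH_regime not in cfg.exchange_rates_hz:
        raise ValidationError(f"unknown pH regime {pH_regime!r}")
    rates = cfg.exchange_rates_hz[pH_regime]
    pools = []
    for shift, mult, k in zip(cfg.shifts_ppm, cfg.protons_per_glucose, rates):
        frac = mult * concentration_mM / cfg.water_proton_concentration_mM
        pools.append(
            Pool(
                label=f"OH_{shift:g}ppm",
                chemical_shift_ppm=shift,
                T1_s=cfg.T1_s,
                T2_s=cfg.T2_s,
                exchange_rate_hz=k,
                proton_fraction=frac,
            )
        )
    return pools


def compartment_zspectrum(
    comp: Compartment,
    state: GlycemicState,
    train: PulseTrain,
    protocol: SimProtocol,
    hydroxyl: HydroxylConfig | None = None,
    concentration_mM: float | None = None,
) -> ZSpectrum:
    """Simulate the Z-spectrum of one compartment at a glycemic state.

    ``concentration_mM`` overrides the tabulated concentration (used for
    continuous uptake curves).
    """
    c = comp.concentration(state) if concentration_mM is None else concentration_mM
    pools = [water_pool(comp.T1_water_s, comp.T2_water_s)]
    pools += glucose_pools(c, comp.pH_regime, hydroxyl)
    spec = simulate_zspectrum(pools, train, protocol)
    spec.metadata.update(
        {"compartment": comp.id, "state": state, "glucose_mM": c}
    )
    return spec


def mix_tissue_zspectrum(
    tissue: TissueModel,
    compartment_spectra: Mapping[str, ZSpectrum],
) -> ZSpectrum:
    """Mix normalized compartment spectra into a tissue Z-spectrum.

    The mixed intensity at each offset is

        [ fb*rho_b*(fa*Za + fv*Zv) + fe*rho_e*Ze + fc*rho_c*Zc ] / rho_tis

    where the rho are water densities (mL water per mL compartment or
    tissue) and the f are volume fractions.  Compartments are combined at
    the signal level; water exchange between compartments is not modelled.
    """
    needed = tissue.compartments()
    grids = []
    for key in needed:
        if key not in compartment_spectra:
            raise ValidationError(f"missing compartment spectrum {key!r}")
        grids.append(np.asarray(compartment_spectra[key].offsets_ppm))
    for g in grids[1:]:
        if g.shape != grids[0].shape or not np.allclose(g, grids[0], atol=1e-12):
            raise ValidationError("compartment spectra are on different offset grids")

    offsets = grids[0]
    total = np.zeros_like(offsets, dtype=float)
    if tissue.blood_fraction > 0:
        blood = np.zeros_like(total)
        rho_b = None
        if tissue.arterial_subfraction > 0:
            blood += tissue.arterial_subfraction * compartment_spectra["arterial"].intensities
            rho_b = needed["arterial"].water_density
        if tissue.venous_subfraction > 0:
            blood += tissue.venous_subfraction * compartment_spectra["venous"].intensities
            rho_b = needed["venous"].water_density
        total += tissue.blood_fraction * rho_b * blood
    if tissue.EES_fraction > 0:
        total += (tissue.EES_fraction * needed["EES"].water_density
                  * compartment_spectra["EES"].intensities)
    if tissue.cell_fraction > 0:
        total += (tissue.cell_fraction * needed["cell"].water_density
                  * compartment_spectra["cell"].intensities)
    mixed = total / tissue.tissue_water_density
    meta = {"tissue": tissue.name}
    src = next(iter(compartment_spectra.values()))
    meta.update({k: v for k, v in src.metadata.items() if k in ("state",)})
    return ZSpectrum(offsets.copy(), mixed, meta)


def tissue_zspectrum(
    tissue: TissueModel,
    state: GlycemicState,
    train: PulseTrain,
    protocol: SimProtocol,
    hydroxyl: HydroxylConfig | None = None,
    concentration_scale: Mapping[str, float] | None = None,
    _cache: dict | None = None,
) -> ZSpectrum:
    """Simulate and mix all compartments of a tissue at one glycemic state.

    ``concentration_scale`` optionally maps compartment keys to a factor in
    [0, 1] interpolating each compartment's concentration between its
    normoglycemic (0) and hyperglycemic (1) value, for dynamic uptake
    modelling; when given, ``state`` only labels the output.
    ``_cache`` (dict) memoizes compartment simulations across calls.
    """
    spectra: dict[str, ZSpectrum] = {}
    for key, comp in tissue.compartments().items():
        conc = None
        if concentration_scale is not None:
            g = float(concentration_scale.get(key, 0.0))
            c0 = comp.concentration(NORMOGLYCEMIA)
            c1 = comp.concentration(HYPERGLYCEMIA)
            conc = c0 + g * (c1 - c0)
        if _cache is not None:
            cache_key = (comp.id, state if conc is None else round(conc, 9))
            if cache_key in _cache:
                spectra[key] = _cache[cache_key]
                continue
        spec = compartment_zspectrum(
            comp, state, train, protocol, hydroxyl, concentration_mM=conc
        )
        if _cache is not None:
            _cache[cache_key] = spec
        spectra[key] = spec
    mixed = mix_tissue_zspectrum(tissue, spectra)
    mixed.metadata["state"] = state
    return mixed


# ---------------------------------------------------------------------------
# Noise and resampling


def add_rician_noise(
    spec: ZSpectrum,
    sigma_fraction: float,
    rng: np.random.Generator | int | None = None,
    s0: float = 1.0,
) -> ZSpectrum:
    """Replace each intensity S by ``sqrt((S+n1)^2 + n2^2)`` (Rician noise).

    ``n1, n2 ~ Normal(0, sigma_fraction * s0)``.  ``sigma_fraction = 0`` is
    the identity.  ``rng`` may be a Generator or a seed.
    """
    if sigma_fraction < 0:
        raise ValidationError("sigma_fraction must be non-negative")
    if sigma_fraction == 0:
        return ZSpectrum(spec.offsets_ppm.copy(), spec.intensities.copy(),
                         dict(spec.metadata))
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    sigma = sigma_fraction * s0
    n1 = gen.normal(0.0, sigma, size=spec.intensities.shape)
    n2 = gen.normal(0.0, sigma, size=spec.intensities.shape)
    noisy = np.sqrt((spec.intensities + n1) ** 2 + n2 ** 2)
    meta = dict(spec.metadata)
    meta["rician_sigma_fraction"] = sigma_fraction
    return ZSpectrum(spec.offsets_ppm.copy(), noisy, meta)


def resample_offsets(
    spec: ZSpectrum, target_offsets_ppm: Sequence[float] | None = None
) -> ZSpectrum:
    """Cubic-spline resampling onto a target offset grid (no extrapolation).

    The default target is the 28-point experimental grid from -5 to +5 ppm.
    """
    target = np.asarray(
        OFFSETS_28PT if target_offsets_ppm is None else target_offsets_ppm,
        dtype=float,
    )
    src = spec.sorted()
    lo, hi = src.offsets_ppm[0], src.offsets_ppm[-1]
    if target.min() < lo - 1e-12 or target.max() > hi + 1e-12:
        raise ValidationError(
            f"target offsets [{target.min():g}, {target.max():g}] ppm extend "
            f"beyond the simulated range [{lo:g}, {hi:g}] ppm"
        )
    if src.offsets_ppm.shape == target.shape and np.allclose(src.offsets_ppm, target):
        return ZSpectrum(target.copy(), src.intensities.copy(), dict(src.metadata))
    spline = CubicSpline(src.offsets_ppm, src.intensities)
    meta = dict(src.metadata)
    meta["resampled_from_n"] = int(src.offsets_ppm.size)
    return ZSpectrum(target, spline(target), meta)
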