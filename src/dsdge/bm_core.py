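"""Bloch-McConnell propagation of pulsed saturation for multi-pool Z-spectra.

The water resonance and any number of exchanging solute proton pools are
propagated through a train of shaped RF saturation pulses.  Each pool
contributes three magnetization components (Mx, My, Mz); exchange between a
solute pool and water obeys detailed balance (the water->pool rate is the
pool->water rate scaled by the pool's proton fraction).  Propagation is
piecewise-constant: the RF envelope is sampled, and the affine
Bloch-McConnell generator is exponentiated per sample.

Conventions
-----------
* Offsets are in ppm, positive downfield of water; the Larmor frequency
  converts ppm to Hz (42.577 MHz/T).
* ``b1`` amplitudes are in microtesla; the on-resonance nutation rate is
  ``omega1 = GAMMA_RAD_PER_S_PER_UT * b1`` in rad/s.
* Z-spectral intensities are water Mz at the end of saturation, normalized
  by the same propagation with the RF turned off, so a noiseless spectrum
  lies in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.linalg import expm

__all__ = [
    "GAMMA_MHZ_PER_T",
    "GAMMA_RAD_PER_S_PER_UT",
    "Pool",
    "PulseTrain",
    "SimProtocol",
    "ZSpectrum",
    "sample_pulse_envelope",
    "build_bm_generator",
    "propagate",
    "simulate_zspectrum",
]

#: Proton gyromagnetic ratio, MHz per tesla (gamma-bar).
GAMMA_MHZ_PER_T = 42.577

#: Proton gyromagnetic ratio, rad/s per microtesla.
GAMMA_RAD_PER_S_PER_UT = 2.0 * np.pi * GAMMA_MHZ_PER_T

_MAX_STEADY_STATE_CYCLES = 200
_STEADY_STATE_TOL = 1e-6


class ValidationError(ValueError):
    """Raised when a physical parameter violates its constraints."""


class ConvergenceError(RuntimeError):
    """Raised when steady-state cycling fails to converge."""


@dataclass(frozen=True)
class Pool:
    """One proton species: water or an exchanging solute pool.

    Parameters
    ----------
    label : str
        Identifier; the pool named ``"water"`` is the detected pool.
    chemical_shift_ppm : float
        Resonance offset relative to water.
    T1_s, T2_s : float
        Longitudinal / transverse relaxation times in seconds.
    exchange_rate_hz : float
        Pool-to-water exchange rate (s^-1).  Zero for water itself.
    proton_fraction : float
        Pool proton concentration relative to water protons.  Fixed at 1
        for water.
    """

    label: str
    chemical_shift_ppm: float
    T1_s: float
    T2_s: float
    exchange_rate_hz: float = 0.0
    proton_fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.T1_s <= 0 or self.T2_s <= 0:
            raise ValidationError(
                f"pool {self.label!r}: relaxation times must be positive"
            )
        if self.exchange_rate_hz < 0:
            raise ValidationError(
                f"pool {self.label!r}: exchange rate must be non-negative"
            )
        if self.is_water:
            if self.proton_fraction != 1.0:
                raise ValidationError("water pool must have proton_fraction 1")
            if self.chemical_shift_ppm != 0.0:
                raise ValidationError("water pool must resonate at 0 ppm")
        elif not 0.0 <= self.proton_fraction < 1.0:
            raise ValidationError(
                f"pool {self.label!r}: proton_fraction must be in [0, 1)"
            )

    @property
    def is_water(self) -> bool:
        return self.label == "water"


def water_pool(T1_s: float, T2_s: float) -> Pool:
    """Convenience constructor for the detected water pool."""
    return Pool("water", 0.0, T1_s, T2_s, exchange_rate_hz=0.0, proton_fraction=1.0)


@dataclass(frozen=True)
class PulseTrain:
    """A train of identical saturation pulses.

    ``shape`` is ``"sinc_gauss"`` (Gaussian-apodized single-lobe sinc) or
    ``"block"`` (constant amplitude, i.e. CW when ``n_pulses == 1``).
    Total saturation time is
    ``n_pulses * pulse_duration_s + (n_pulses - 1) * interpulse_delay_s``.
    """

    shape: str = "sinc_gauss"
    n_pulses: int = 10
    pulse_duration_s: float = 0.050
    b1_peak_uT: float = 0.5
    interpulse_delay_s: float = 0.0
    samples_per_pulse: int = 32
    #: Gaussian apodization width as a fraction of the pulse duration.
    gauss_sigma_fraction: float = 0.25
    #: sinc time-bandwidth product; 2 gives a single lobe spanning the
    #: pulse, larger values add side lobes and lower the average B1.
    sinc_tbw: float = 2.6

    def __post_init__(self) -> None:
        if self.shape not in ("sinc_gauss", "block"):
            raise ValidationError(f"unknown pulse shape {self.shape!r}")
        if self.n_pulses < 1:
            raise ValidationError("n_pulses must be >= 1")
        if self.pulse_duration_s <= 0:
            raise ValidationError("pulse_duration_s must be positive")
        if self.samples_per_pulse < 8:
            raise ValidationError("samples_per_pulse must be >= 8")
        if self.interpulse_delay_s < 0:
            raise ValidationError("interpulse_delay_s must be non-negative")
        if self.b1_peak_uT < 0:
            raise ValidationError("b1_peak_uT must be non-negative")

    @property
    def total_saturation_time_s(self) -> float:
        return (
            self.n_pulses * self.pulse_duration_s
            + (self.n_pulses - 1) * self.interpulse_delay_s
        )

    @property
    def b1_average_uT(self) -> float:
        """Amplitude average of the train over the saturation window.

        For slowly precessing spins the shaped low-B1 train coherently
        averages to this equivalent continuous-wave amplitude.
        """
        env, _ = sample_pulse_envelope(self)
        duty = (self.n_pulses * self.pulse_duration_s) / self.total_saturation_time_s
        return float(np.mean(env)) * duty


@dataclass(frozen=True)
class SimProtocol:
    """Acquisition protocol for a simulated Z-spectrum.

    ``saturation_model`` selects how the saturation response is computed:

    ``"pulse_train"``
        Piecewise-constant propagation through the sampled RF envelope.
        ``initial_state`` then selects the magnetization at the start of
        saturation: ``"thermal"`` starts every offset from equilibrium,
        while ``"cycled_steady_state"`` repeats {saturation, relaxation to
        TR} cycles until the end-of-saturation water Mz is stationary.
    ``"cw_steady_state"``
        The exact steady state of the Bloch-McConnell system under
        continuous-wave irradiation at the train's amplitude average
        (``PulseTrain.b1_average_uT``).  This is the sideband-free
        effective description of low-B1 shaped-pulse saturation: a single
        isochromat propagated through the literal train shows coherent
        nutation sidebands at harmonics of the pulse rate that intra-voxel
        frequency dispersion suppresses in measured spectra.
    """

    offsets_ppm: tuple[float, ...]
    field_strength_T: float = 3.0
    TR_s: float = 1.2
    initial_state: str = "cycled_steady_state"
    saturation_model: str = "pulse_train"

    def __post_init__(self) -> None:
        offsets = tuple(float(x) for x in self.offsets_ppm)
        if len(offsets) == 0:
            raise ValidationError("offsets_ppm must be non-empty")
        if not np.all(np.isfinite(offsets)):
            raise ValidationError("offsets must be finite")
        object.__setattr__(self, "offsets_ppm", offsets)
        if self.initial_state not in ("thermal", "cycled_steady_state"):
            raise ValidationError(f"unknown initial_state {self.initial_state!r}")
        if self.saturation_model not in ("pulse_train", "cw_steady_state"):
            raise ValidationError(
                f"unknown saturation_model {self.saturation_model!r}"
            )
        if self.field_strength_T <= 0:
            raise ValidationError("field_strength_T must be positive")

    @property
    def larmor_frequency_MHz(self) -> float:
        return self.field_strength_T * GAMMA_MHZ_PER_T


@dataclass
class ZSpectrum:
    """Normalized saturation intensities S(dw)/S0 versus offset (ppm)."""

    offsets_ppm: np.ndarray
    intensities: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.offsets_ppm = np.asarray(self.offsets_ppm, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.offsets_ppm.shape != self.intensities.shape:
            raise ValidationError("offsets and intensities must have equal length")

    def sorted(self) -> "ZSpectrum":
        order = np.argsort(self.offsets_ppm)
        return ZSpectrum(
            self.offsets_ppm[order], self.intensities[order], dict(self.metadata)
        )

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(
            {"offset_ppm": self.offsets_ppm, "z": self.intensities}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ZSpectrum":
        import pandas as pd

        df = pd.read_csv(path)
        return cls(df["offset_ppm"].to_numpy(), df["z"].to_numpy())


# ---------------------------------------------------------------------------
# Pulse envelope


def sample_pulse_envelope(train: PulseTrain) -> tuple[np.ndarray, float]:
    """Sample one pulse of the train as a piecewise-constant B1 waveform.

    Returns ``(amplitudes_uT, dt_s)`` with one amplitude per sample (the
    envelope evaluated at the sample midpoint) and the time step per sample.

    The sinc-Gauss envelope is a single-lobe sinc whose first zero crossings
    sit at the pulse edges, apodized by a Gaussian window of width
    ``gauss_sigma_fraction * pulse_duration``, and peak-normalized to
    ``b1_peak_uT``.
    """
    n = train.samples_per_pulse
    dt = train.pulse_duration_s / n
    t_mid = (np.arange(n) + 0.5) * dt
    return _envelope_at(train, t_mid), dt


def _envelope_at(train: PulseTrain, t: np.ndarray) -> np.ndarray:
    """Evaluate the closed-form pulse envelope (uT) at times ``t`` in [0, T]."""
    if train.shape == "block":
        return np.full_like(np.asarray(t, dtype=float), train.b1_peak_uT)
    T = train.pulse_duration_s
    tc = T / 2.0
    # np.sinc(x) = sin(pi x)/(pi x): zero crossings at integer x
    sinc = np.sinc(train.sinc_tbw * (np.asarray(t, dtype=float) - tc) / T)
    sigma = train.gauss_sigma_fraction * T
    gauss = np.exp(-0.5 * ((t - tc) / sigma) ** 2)
    env = sinc * gauss
    return train.b1_peak_uT * env / np.max(np.abs(env))


# ---------------------------------------------------------------------------
# Generator assembly


def _check_pools(pools: Sequence[Pool]) -> list[Pool]:
    pools = list(pools)
    n_water = sum(p.is_water for p in pools)
    if n_water != 1:
        raise ValidationError(f"exactly one water pool required, got {n_water}")
    # water first, stable order otherwise
    pools.sort(key=lambda p: not p.is_water)
    return pools


def build_bm_generator(
    pools: Sequence[Pool],
    offset_ppm: float,
    b1_uT: float,
    protocol: SimProtocol,
) -> np.ndarray:
    """Affine Bloch-McConnell generator for one offset and B1 amplitude.

    Returns the homogeneous ``(3n+1, 3n+1)`` matrix ``G`` such that the
    augmented state ``[Mx1, My1, Mz1, ..., 1]`` evolves as ``dM/dt = G M``.
    Pool ordering puts water first.
    """
    pools = _check_pools(pools)
    return _generator(pools, float(offset_ppm), float(b1_uT),
                      protocol.larmor_frequency_MHz)


def _generator(
    pools: list[Pool], offset_ppm: float, b1_uT: float, f0_MHz: float
) -> np.ndarray:
    n = len(pools)
    dim = 3 * n + 1
    G = np.zeros((dim, dim))
    w1 = GAMMA_RAD_PER_S_PER_UT * b1_uT
    for i, p in enumerate(pools):
        ix, iy, iz = 3 * i, 3 * i + 1, 3 * i + 2
        # rotating-frame precession of pool i relative to the RF carrier
        delta = 2.0 * np.pi * (p.chemical_shift_ppm - offset_ppm) * f0_MHz
        r1, r2 = 1.0 / p.T1_s, 1.0 / p.T2_s
        G[ix, ix] -= r2
        G[iy, iy] -= r2
        G[iz, iz] -= r1
        G[ix, iy] += delta
        G[iy, ix] -= delta
        G[iy, iz] += w1
        G[iz, iy] -= w1
        G[iz, -1] += r1 * p.proton_fraction  # relaxation drive toward M0_i
    # exchange: solute pool s <-> water (index 0), detailed balance
    for s, p in enumerate(pools):
        if p.is_water or p.exchange_rate_hz == 0.0:
            continue
        k_sw = p.exchange_rate_hz
        k_ws = p.proton_fraction * k_sw
        for c in range(3):
            w, sidx = c, 3 * s + c
            G[w, w] -= k_ws
            G[w, sidx] += k_sw
            G[sidx, w] += k_ws
            G[sidx, sidx] -= k_sw
    return G


def equilibrium_state(pools: Sequence[Pool]) -> np.ndarray:
    """Thermal-equilibrium augmented state vector (water first)."""
    pools = _check_pools(pools)
    m = np.zeros(3 * len(pools) + 1)
    for i, p in enumerate(pools):
        m[3 * i + 2] = p.proton_fraction
    m[-1] = 1.0
    return m


# ---------------------------------------------------------------------------
# Propagation


def _train_propagators(
    pools: list[Pool],
    train: PulseTrain,
    offsets_ppm: np.ndarray,
    protocol: SimProtocol,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-offset propagators over (a) the full pulse train and (b) the
    post-saturation relaxation interval to TR.

    Returns arrays of shape ``(n_offsets, dim, dim)``.
    """
    f0 = protocol.larmor_frequency_MHz
    n_off = len(offsets_ppm)
    env, dt = sample_pulse_envelope(train)
    # batch generators: (n_off, n_samples, dim, dim)
    gens = np.stack(
        [
            np.stack([_generator(pools, off, b1, f0) for b1 in env])
            for off in offsets_ppm
        ]
    )
    steps = expm(gens * dt)  # scipy expm broadcasts over leading axes
    dim = steps.shape[-1]
    pulse_prop = np.empty((n_off, dim, dim))
    for i in range(n_off):
        P = steps[i, 0]
        for k in range(1, train.samples_per_pulse):
            P = steps[i, k] @ P
        pulse_prop[i] = P

    free = np.stack([_generator(pools, off, 0.0, f0) for off in offsets_ppm])
    if train.interpulse_delay_s > 0 and train.n_pulses > 1:
        delay_prop = expm(free * train.interpulse_delay_s)
    else:
        delay_prop = np.broadcast_to(np.eye(dim), (n_off, dim, dim))

    train_prop = pulse_prop.copy()
    for _ in range(train.n_pulses - 1):
        train_prop = pulse_prop @ delay_prop @ train_prop

    t_rest = protocol.TR_s - train.total_saturation_time_s
    if t_rest < -1e-12:
        raise ValidationError("TR is shorter than the total saturation time")
    rest_prop = expm(free * max(t_rest, 0.0))
    return train_prop, rest_prop


def _steady_state_batch(
    pools: list[Pool],
    b1_uT: float,
    offsets_ppm: np.ndarray,
    protocol: SimProtocol,
) -> np.ndarray:
    """Water Mz of the exact CW steady state at each offset."""
    f0 = protocol.larmor_frequency_MHz
    out = np.empty(len(offsets_ppm))
    for i, off in enumerate(offsets_ppm):
        G = _generator(pools, float(off), b1_uT, f0)
        mss = np.linalg.solve(G[:-1, :-1], -G[:-1, -1])
        out[i] = mss[2]
    return out


def _propagate_batch(
    pools: list[Pool],
    train: PulseTrain,
    offsets_ppm: np.ndarray,
    protocol: SimProtocol,
) -> np.ndarray:
    """End-of-saturation water Mz for each offset (fraction of M0)."""
    if protocol.saturation_model == "cw_steady_state":
        return _steady_state_batch(pools, train.b1_average_uT, offsets_ppm, protocol)
    train_prop, rest_prop = _train_propagators(pools, train, offsets_ppm, protocol)
    m0 = equilibrium_state(pools)
    m_start = np.broadcast_to(m0, (len(offsets_ppm), m0.size)).copy()

    m_sat = np.einsum("oij,oj->oi", train_prop, m_start)
    if protocol.initial_state == "thermal":
        return m_sat[:, 2]

    mz_prev = m_sat[:, 2].copy()
    for _ in range(_MAX_STEADY_STATE_CYCLES):
        m_start = np.einsum("oij,oj->oi", rest_prop, m_sat)
        m_sat = np.einsum("oij,oj->oi", train_prop, m_start)
        mz = m_sat[:, 2]
        if np.max(np.abs(mz - mz_prev)) < _STEADY_STATE_TOL:
            return mz
        mz_prev = mz.copy()
    worst = offsets_ppm[int(np.argmax(np.abs(mz - mz_prev)))]
    raise ConvergenceError(
        f"steady-state cycling did not converge within "
        f"{_MAX_STEADY_STATE_CYCLES} cycles (worst offset {worst:+.3f} ppm, "
        f"residual {np.max(np.abs(mz - mz_prev)):.2e})"
    )


def propagate(
    pools: Sequence[Pool],
    train: PulseTrain,
    offset_ppm: float,
    protocol: SimProtocol,
) -> float:
    """Water Mz (fraction of M0) at the end of the saturation train."""
    pools = _check_pools(pools)
    return float(
        _propagate_batch(pools, train, np.array([float(offset_ppm)]), protocol)[0]
    )


def simulate_zspectrum(
    pools: Sequence[Pool],
    train: PulseTrain,
    protocol: SimProtocol,
) -> ZSpectrum:
    """Simulate a Z-spectrum over the protocol's offsets.

    Intensities are normalized so an unsaturated (B1 = 0) acquisition of the
    same protocol equals 1.
    """
    pools = _check_pools(pools)
    offsets = np.asarray(protocol.offsets_ppm, dtype=float)
    try:
        mz = _propagate_batch(pools, train, offsets, protocol)
    except ConvergenceError:
        # retry offset-by-offset to name the offending offset
        mz = np.empty_like(offsets)
        for i, off in enumerate(offsets):
            try:
                mz[i] = _propagate_batch(pools, train, np.array([off]), protocol)[0]
            except ConvergenceError as err:
                raise ConvergenceError(
                    f"propagation failed at offset {off:+.3f} ppm: {err}"
                ) from err
    from dataclasses import replace as _replace

    ref_train = _replace(train, b1_peak_uT=0.0)
    s0 = _propagate_batch(pools, ref_train, np.array([0.0]), protocol)[0]
    spec = ZSpectrum(
        offsets,
        mz / s0,
        metadata={
            "b1_peak_uT": train.b1_peak_uT,
            "n_pulses": train.n_pulses,
            "pulse_duration_s": train.pulse_duration_s,
            "tsat_s": train.total_saturation_time_s,
            "TR_s": protocol.TR_s,
            "field_strength_T": protocol.field_strength_T,
            "initial_state": protocol.initial_state,
        },
    )
    return spec.sorted()
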