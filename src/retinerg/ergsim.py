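"""Synthetic full-field ERG waveform generator with known ground truth.

The generator composes the components that flash ERG analysis decomposes a
recording into:

* **P3 (a-wave)** — the photoreceptoral response, modelled with the
  delayed-Gaussian saturation function of Hood & Birch / Lamb & Pugh::

      P3(i, t) = -RmP3 * (1 - exp(-i * S * (t - td)^2))   for t > td, else 0

  with ``i`` the flash energy in linear cd·s/m², ``RmP3`` the saturated
  amplitude (µV), ``S`` a sensitivity scaling ((cd·s·m⁻²)⁻¹·s⁻²) and ``td``
  a short transduction delay (s).
* **P2 (b-wave)** — ON-bipolar-cell driven. Only its peak amplitude is
  analysed downstream, so any smooth positive kernel suffices; a gamma
  kernel ``g(t) ∝ (t/4τ)^4 exp(4 - t/τ)`` (unit peak at ``t = 4τ``) is
  scaled by the Naka–Rushton intensity-response value
  ``Vmax · iⁿ / (iⁿ + Kⁿ)``.
* **Oscillatory potentials** — a windowed oscillation riding the rising
  b-wave, scaled with the same Naka–Rushton fraction so it vanishes at dim
  flashes.
* **pSTR** — the positive scotopic threshold response, a small positive
  Gaussian bump (default peak ~110 ms) present only at the dimmest flashes.

Acquisition is emulated by a zero-phase band-pass with net -3 dB corners at
0.3 and 1000 Hz and additive white Gaussian noise. Every stochastic call
takes an explicit seed; there is no global random state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from . import filters
from .errors import ConfigurationError, InvalidParameterError, ProtocolError

DARK = "dark"
LIGHT = "light"

#: Dark-adapted flash energies, log10 cd·s/m². Spans -5.01 … 2.07 and includes
#: the pSTR pair (-5.01, -4.90) and the rod P3 pair (1.55, 2.07).
DEFAULT_DARK_ENERGIES: tuple[float, ...] = (
    -5.01, -4.90, -3.81, -2.89, -2.21, -1.51, -0.81, -0.21, 0.48, 1.22, 1.55, 2.07,
)
#: Light-adapted energies, log10 cd·s/m². Spans 0.3 … 2.72 and includes the
#: cone P3 pair (2.20, 2.72).
DEFAULT_LIGHT_ENERGIES: tuple[float, ...] = (0.30, 0.72, 1.22, 1.72, 2.20, 2.72)


def _require_finite(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not math.isfinite(value):
            raise InvalidParameterError(f"{name} must be finite, got {value!r}")


@dataclass(frozen=True)
class Timebase:
    """Uniform sampling grid for one recording.

    Defaults follow the acquisition protocol: 4000 samples/s over 640 ms,
    with the flash delivered 20 ms into the sweep so a pre-stimulus baseline
    exists.
    """

    sampling_rate: float = 4000.0
    duration: float = 0.640
    onset_index: int = 80

    def __post_init__(self) -> None:
        _require_finite(sampling_rate=self.sampling_rate, duration=self.duration)
        if self.sampling_rate <= 0 or self.duration <= 0:
            raise InvalidParameterError("sampling_rate and duration must be > 0")
        if not 0 <= self.onset_index < self.n_samples:
            raise InvalidParameterError(
                f"onset_index {self.onset_index} outside [0, {self.n_samples})")

    @property
    def n_samples(self) -> int:
        return int(round(self.sampling_rate * self.duration))

    @property
    def onset_time(self) -> float:
        return self.onset_index / self.sampling_rate

    def times(self) -> np.ndarray:
        """Sample times in seconds from sweep start."""
        return np.arange(self.n_samples) / self.sampling_rate

    def times_from_onset(self) -> np.ndarray:
        """Sample times in seconds relative to flash onset (negative before)."""
        return self.times() - self.onset_time


@dataclass(frozen=True)
class FlashStimulus:
    """One calibrated flash: log10 luminous energy and adaptation state."""

    log_energy: float
    adaptation: str = DARK

    def __post_init__(self) -> None:
        _require_finite(log_energy=self.log_energy)
        if self.adaptation not in (DARK, LIGHT):
            raise InvalidParameterError(
                f"adaptation must be '{DARK}' or '{LIGHT}', got {self.adaptation!r}")

    @property
    def energy(self) -> float:
        """Linear luminous energy, cd·s/m²."""
        return 10.0 ** self.log_energy


@dataclass(frozen=True)
class P3Params:
    """Delayed-Gaussian photoreceptor model parameters."""

    rm_p3: float  # saturated amplitude, µV (reported positive)
    s: float      # sensitivity, (cd·s·m⁻²)⁻¹·s⁻²
    td: float     # delay, s

    def __post_init__(self) -> None:
        _require_finite(rm_p3=self.rm_p3, s=self.s, td=self.td)
        if self.rm_p3 < 0 or self.s <= 0 or self.td < 0:
            raise InvalidParameterError(
                f"require rm_p3 >= 0, s > 0, td >= 0; got {self}")


@dataclass(frozen=True)
class P2Params:
    """Naka–Rushton amplitude law plus b-wave kernel time constant."""

    vmax: float           # saturated b-wave amplitude, µV
    k: float              # semi-saturation energy, cd·s/m²
    n: float = 1.0        # Naka–Rushton exponent
    shape_tau: float = 0.018  # gamma-kernel tau, s (peak at 4*tau)

    def __post_init__(self) -> None:
        _require_finite(vmax=self.vmax, k=self.k, n=self.n, shape_tau=self.shape_tau)
        if self.vmax < 0 or self.k <= 0 or self.n <= 0 or self.shape_tau <= 0:
            raise InvalidParameterError(
                f"require vmax >= 0, k > 0, n > 0, shape_tau > 0; got {self}")

    def naka_rushton(self, energy: float | np.ndarray) -> float | np.ndarray:
        i_n = np.asarray(energy, dtype=float) ** self.n
        return self.vmax * i_n / (i_n + self.k ** self.n)


@dataclass(frozen=True)
class AccessoryParams:
    """Everything that is not P3 or P2: OPs, pSTR, noise, acquisition band."""

    op_amplitude: float = 25.0                    # µV, peak of OP envelope
    op_band: tuple[float, float] = (90.0, 180.0)  # Hz; oscillation at band centre
    op_center_time: float = 0.035                 # s after onset
    op_envelope_sd: float = 0.008                 # s, Gaussian envelope width
    str_amplitude: float = 12.0                   # µV, pSTR bump peak
    str_peak_time: float = 0.110                  # s after onset
    str_width: float = 0.025                      # s, Gaussian sd
    noise_sd: float = 0.0                         # µV, white Gaussian
    acquisition_band: tuple[float, float] | None = (0.3, 1000.0)  # Hz, net -3 dB

    def __post_init__(self) -> None:
        _require_finite(op_amplitude=self.op_amplitude,
                        str_amplitude=self.str_amplitude,
                        noise_sd=self.noise_sd)
        if self.op_band[0] <= 0 or self.op_band[0] >= self.op_band[1]:
            raise InvalidParameterError(f"invalid op_band {self.op_band}")


@dataclass(frozen=True)
class ERGWaveform:
    """A single uniformly sampled voltage trace (µV) for one flash."""

    timebase: Timebase
    stimulus: FlashStimulus
    samples: np.ndarray

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if samples.shape != (self.timebase.n_samples,):
            raise InvalidParameterError(
                f"samples shape {samples.shape} != ({self.timebase.n_samples},)")
        if not np.all(np.isfinite(samples)):
            raise InvalidParameterError("samples must be finite")

    @property
    def key(self) -> tuple[str, float]:
        return (self.stimulus.adaptation, self.stimulus.log_energy)


class WaveformFamily:
    """Ordered collection of waveforms sharing a timebase.

    Within each adaptation state, flashes are kept sorted by increasing log
    energy; duplicate (adaptation, log_energy) keys are rejected.
    """

    def __init__(self, waveforms: Iterable[ERGWaveform]):
        waveforms = list(waveforms)
        if not waveforms:
            raise ProtocolError("a waveform family cannot be empty")
        tb = waveforms[0].timebase
        if any(w.timebase != tb for w in waveforms):
            raise ProtocolError("all waveforms must share one timebase")
        keys = [w.key for w in waveforms]
        if len(set(keys)) != len(keys):
            raise ProtocolError("duplicate (adaptation, log_energy) keys")
        order = {DARK: 0, LIGHT: 1}
        self._waveforms = sorted(
            waveforms, key=lambda w: (order[w.stimulus.adaptation], w.stimulus.log_energy))
        self.timebase = tb

    def __iter__(self):
        return iter(self._waveforms)

    def __len__(self) -> int:
        return len(self._waveforms)

    def energies(self, adaptation: str) -> tuple[float, ...]:
        return tuple(w.stimulus.log_energy for w in self._waveforms
                     if w.stimulus.adaptation == adaptation)

    def get(self, adaptation: str, log_energy: float,
            atol: float = 1e-9) -> ERGWaveform:
        for w in self._waveforms:
            if (w.stimulus.adaptation == adaptation
                    and abs(w.stimulus.log_energy - log_energy) <= atol):
                return w
        raise ProtocolError(
            f"no flash at ({adaptation}, {log_energy}) in family")

    def has(self, adaptation: str, log_energy: float, atol: float = 1e-9) -> bool:
        try:
            self.get(adaptation, log_energy, atol)
            return True
        except ProtocolError:
            return False

    def subset(self, adaptation: str) -> "WaveformFamily":
        kept = [w for w in self._waveforms if w.stimulus.adaptation == adaptation]
        return WaveformFamily(kept)


# ---------------------------------------------------------------------------
# component models
# ---------------------------------------------------------------------------

def p3_model(p: P3Params, energy: float, t_from_onset: np.ndarray) -> np.ndarray:
    """Evaluate the delayed-Gaussian P3 (µV, non-positive) on a time grid."""
    t = np.asarray(t_from_onset, dtype=float)
    out = np.zeros_like(t)
    late = t > p.td
    arg = energy * p.s * (t[late] - p.td) ** 2
    out[late] = -p.rm_p3 * (1.0 - np.exp(-arg))
    return out


def generate_p3(p: P3Params, stim: FlashStimulus, tb: Timebase) -> ERGWaveform:
    """Noiseless, unfiltered P3 component for one flash."""
    samples = p3_model(p, stim.energy, tb.times_from_onset())
    return ERGWaveform(tb, stim, samples)


def p2_kernel(tb: Timebase, tau: float) -> np.ndarray:
    """Unit-peak gamma kernel ``(t/4τ)^4 exp(4 - t/τ)``; zero before onset."""
    t = tb.times_from_onset()
    out = np.zeros_like(t)
    pos = t > 0
    out[pos] = (t[pos] / (4.0 * tau)) ** 4 * np.exp(4.0 - t[pos] / tau)
    return out


def _op_component(acc: AccessoryParams, tb: Timebase) -> np.ndarray:
    t = tb.times_from_onset()
    f_c = 0.5 * (acc.op_band[0] + acc.op_band[1])
    envelope = np.exp(-0.5 * ((t - acc.op_center_time) / acc.op_envelope_sd) ** 2)
    envelope[t <= 0] = 0.0
    return acc.op_amplitude * envelope * np.sin(2.0 * np.pi * f_c * t)


def _str_component(acc: AccessoryParams, tb: Timebase) -> np.ndarray:
    t = tb.times_from_onset()
    bump = acc.str_amplitude * np.exp(
        -0.5 * ((t - acc.str_peak_time) / acc.str_width) ** 2)
    bump[t <= 0] = 0.0
    return bump


def generate_erg(p3: P3Params, p2: P2Params, acc: AccessoryParams,
                 stim: FlashStimulus, tb: Timebase,
                 seed: int | np.random.Generator) -> ERGWaveform:
    """Compose one flash response: P3 + P2 + OPs + pSTR, noise, acquisition band.

    ``seed`` is mandatory (an int or an existing Generator); the same seed
    reproduces the trace bit-for-bit. Setting ``acc.acquisition_band = None``
    disables the acquisition filter, which makes the composition exactly the
    sum of its analytic components.
    """
    nyq = tb.sampling_rate / 2.0
    if acc.op_band[1] >= nyq:
        raise ConfigurationError(
            f"op_band upper edge {acc.op_band[1]} Hz >= Nyquist {nyq} Hz")
    rng = np.random.default_rng(seed)
    nr = float(p2.naka_rushton(stim.energy))
    signal = p3_model(p3, stim.energy, tb.times_from_onset())
    signal = signal + nr * p2_kernel(tb, p2.shape_tau)
    if acc.op_amplitude and p2.vmax > 0:
        signal = signal + (nr / p2.vmax) * _op_component(acc, tb)
    if acc.str_amplitude:
        signal = signal + _str_component(acc, tb)
    if acc.noise_sd:
        signal = signal + rng.normal(0.0, acc.noise_sd, size=signal.shape)
    if acc.acquisition_band is not None:
        sos = filters.bandpass_net3db(acc.acquisition_band[0],
                                      acc.acquisition_band[1], tb.sampling_rate)
        signal = filters.zero_phase(sos, signal)
    return ERGWaveform(tb, stim, signal)


def default_protocol(dark: Sequence[float] = DEFAULT_DARK_ENERGIES,
                     light: Sequence[float] = DEFAULT_LIGHT_ENERGIES,
                     ) -> list[FlashStimulus]:
    """The full dark- plus light-adapted flash sequence."""
    return ([FlashStimulus(e, DARK) for e in dark]
            + [FlashStimulus(e, LIGHT) for e in light])


#: Default generator parameters for a healthy (wildtype-like) eye.
DEFAULT_ROD_P3 = P3Params(rm_p3=450.0, s=900.0, td=0.0035)
DEFAULT_ROD_P2 = P2Params(vmax=600.0, k=0.05, n=1.0, shape_tau=0.022)
DEFAULT_CONE_P3 = P3Params(rm_p3=120.0, s=600.0, td=0.003)
DEFAULT_CONE_P2 = P2Params(vmax=150.0, k=25.0, n=1.0, shape_tau=0.015)
DEFAULT_ACCESSORY = AccessoryParams()

#: Number of dimmest dark flashes that carry the pSTR bump.
N_STR_FLASHES = 2


def generate_family(protocol: Sequence[FlashStimulus],
                    rod_p3: P3Params = DEFAULT_ROD_P3,
                    rod_p2: P2Params = DEFAULT_ROD_P2,
                    cone_p3: P3Params = DEFAULT_CONE_P3,
                    cone_p2: P2Params = DEFAULT_CONE_P2,
                    acc: AccessoryParams = DEFAULT_ACCESSORY,
                    tb: Timebase = Timebase(),
                    seed: int | np.random.Generator = 0) -> WaveformFamily:
    """Generate a full multi-flash family.

    Dark-adapted flashes use the rod parameter set, light-adapted the cone
    set. The pSTR bump is injected only at the ``N_STR_FLASHES`` dimmest
    dark-adapted energies (at brighter flashes the ganglion-cell response is
    swamped and is not a measurement target).
    """
    if not protocol:
        raise ProtocolError("protocol must contain at least one flash")
    keys = [(s.adaptation, s.log_energy) for s in protocol]
    if len(set(keys)) != len(keys):
        raise ProtocolError("duplicate flash energies within an adaptation state")
    dark_energies = sorted(s.log_energy for s in protocol if s.adaptation == DARK)
    str_energies = set(dark_energies[:N_STR_FLASHES])
    rng = np.random.default_rng(seed)
    waves = []
    for stim in protocol:
        if stim.adaptation == DARK:
            p3, p2 = rod_p3, rod_p2
            flash_acc = acc if stim.log_energy in str_energies else replace(
                acc, str_amplitude=0.0)
        else:
            p3, p2 = cone_p3, cone_p2
            flash_acc = replace(acc, str_amplitude=0.0)
        waves.append(generate_erg(p3, p2, flash_acc, stim, tb, rng))
    return WaveformFamily(waves)
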