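"""Decompose ERG waveform families into photoreceptoral, bipolar-cell and
ganglion-cell endpoints.

The pipeline mirrors standard flash-ERG practice:

1. **P3 (a-wave)**: the delayed-Gaussian model is fit jointly (one shared
   ``RmP3, S, td`` triple) to the leading edges of the two brightest flashes
   of the pathway; the fit window runs from flash onset to the per-flash
   a-wave trough located on a low-pass-smoothed copy.
2. **P3 subtraction** isolates the P2–OP complex.
3. **P2 (b-wave)**: the residual is low-pass filtered (net -3 dB at 46.9 Hz,
   zero phase) to strip the oscillatory potentials; the baseline-corrected
   positive peak after onset is the per-flash P2 amplitude.
4. **Naka–Rushton** ``V(i) = Vmax·iⁿ/(iⁿ+Kⁿ)`` is fit across all flash
   energies to yield ``Vmax`` (exponent fixed at 1 by default: a saturated
   hyperbola).
5. **pSTR**: the mean of the baseline-corrected positive peaks at the two
   dimmest energies (default -5.01 and -4.90 log cd·s/m², searched 60–200 ms
   after onset).

Implicit-time/timing endpoints are deliberately not produced; the
acquisition band-pass makes them unreliable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.optimize import curve_fit, least_squares

from . import filters
from .ergsim import DARK, LIGHT, ERGWaveform, P3Params, WaveformFamily, p3_model
from .errors import (ConfigurationError, DegenerateFitError, FitError,
                     ProtocolError, StageError)

#: Default energy pairs (log10 cd·s/m²) per pathway.
ROD_P3_ENERGIES = (1.55, 2.07)
CONE_P3_ENERGIES = (2.20, 2.72)
PSTR_ENERGIES = (-5.01, -4.90)

#: b-wave extraction filter: corner (Hz, net -3 dB after zero-phase pass) and
#: single-pass Butterworth order.
P2_FILTER_CORNER_HZ = 46.9
P2_FILTER_ORDER = 4


@dataclass(frozen=True)
class P3Fit:
    """Result of the joint two-flash photoreceptor fit."""

    params: P3Params
    fit_window: tuple[tuple[float, float], ...]  # (start_s, end_s) per flash
    energies_used: tuple[float, float]
    residual_rms: float
    adaptation: str = DARK


@dataclass(frozen=True)
class P2Result:
    amplitudes: Mapping[float, float]  # log_energy -> peak µV
    vmax: float
    k: float
    n: float
    filter_spec: tuple[float, int]  # (corner Hz, order)
    degenerate: bool = False


@dataclass(frozen=True)
class PSTRResult:
    amplitude: float
    energies_used: tuple[float, float]
    search_window: tuple[float, float]
    per_flash_peaks: tuple[float, ...] = ()


@dataclass(frozen=True)
class DecompositionConfig:
    rod_p3_energies: tuple[float, float] = ROD_P3_ENERGIES
    cone_p3_energies: tuple[float, float] = CONE_P3_ENERGIES
    pstr_energies: tuple[float, float] = PSTR_ENERGIES
    pstr_window: tuple[float, float] = (0.060, 0.200)  # s after onset
    p2_filter: tuple[float, int] = (P2_FILTER_CORNER_HZ, P2_FILTER_ORDER)
    fix_n: bool = True
    min_deflection_uv: float = 1.0  # smallest a-wave depth accepted as real


@dataclass(frozen=True)
class DecompositionResult:
    rod_p3: P3Fit | None = None
    cone_p3: P3Fit | None = None
    rod_p2: P2Result | None = None
    cone_p2: P2Result | None = None
    pstr: PSTRResult | None = None


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _p2_sos(fs: float, corner_hz: float = P2_FILTER_CORNER_HZ,
            order: int = P2_FILTER_ORDER) -> np.ndarray:
    return filters.design_net3db(corner_hz, fs, order=order, btype="low")


def baseline(wave: ERGWaveform) -> float:
    """Mean of the pre-stimulus samples (0 if the flash starts the sweep)."""
    onset = wave.timebase.onset_index
    if onset == 0:
        return 0.0
    return float(np.mean(wave.samples[:onset]))


def _trough_index(wave: ERGWaveform, sos: np.ndarray,
                  min_deflection_uv: float = 1.0) -> int:
    """a-wave trough: first local minimum of the smoothed trace after onset
    that dips below ``-min_deflection_uv``.

    The b-wave turns the trace upward right after the trough, so the first
    qualifying local minimum is the a-wave trough even when later parts of
    the sweep are more negative (an unfiltered saturating P3 returns to
    -RmP3 once the b-wave decays). Falls back to the global minimum for
    monotone traces (e.g. an isolated P3).
    """
    smoothed = filters.zero_phase(sos, wave.samples)
    onset = wave.timebase.onset_index
    seg = smoothed[onset:] - np.mean(smoothed[:onset]) if onset else smoothed
    d = np.diff(seg)
    candidates = np.nonzero(
        (seg[1:-1] < -min_deflection_uv) & (d[:-1] < 0) & (d[1:] >= 0))[0]
    if candidates.size:
        return onset + int(candidates[0]) + 1
    return onset + int(np.argmin(seg))


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

#: Fraction of model saturation at which the refined fit window is capped.
#: Past ~90% saturation the a-wave limb is flat and the window samples are
#: increasingly contaminated by the rising b-wave, which biases RmP3 downward.
SATURATION_CAP = 0.90


def _solve_p3(seg_t: list[np.ndarray], seg_v: list[np.ndarray],
              i_lin: list[float]):
    depth = max(-float(np.min(v)) for v in seg_v)
    t_max = max(float(t.max()) for t in seg_t)

    def residuals(theta: np.ndarray) -> np.ndarray:
        rm, s, td = theta
        p = P3Params(max(rm, 0.0), max(s, 1e-12), max(td, 0.0))
        out = [p3_model(p, i, t) - v for i, t, v in zip(i_lin, seg_t, seg_v)]
        return np.concatenate(out)

    # coarse grid over S and td for the starting point (the objective has
    # shallow valleys in log S)
    best = None
    for s0 in np.geomspace(1e-2, 1e6, 17):
        for td0 in (0.0, 0.002, 0.004, 0.008):
            theta = np.array([depth, s0, td0])
            sse = float(np.sum(residuals(theta) ** 2))
            if best is None or sse < best[0]:
                best = (sse, theta)
    assert best is not None
    sol = least_squares(
        residuals, best[1],
        bounds=([0.0, 1e-12, 0.0], [np.inf, np.inf, max(t_max, 0.05)]),
        x_scale=[max(depth, 1.0), max(best[1][1], 1.0), 0.005],
        max_nfev=5000)
    if not sol.success:
        raise FitError(f"P3 fit did not converge: {sol.message}")
    return sol


def fit_p3(family: WaveformFamily,
           energies: tuple[float, float] = ROD_P3_ENERGIES,
           adaptation: str = DARK,
           window: tuple[float, float] | None = None,
           min_deflection_uv: float = 1.0) -> P3Fit:
    """Jointly fit one (RmP3, S, td) triple to the a-wave leading edges of two
    flashes.

    The default window runs from flash onset to the per-flash a-wave trough
    (located on a 46.9 Hz-smoothed copy), then is refined: after an initial
    fit, each flash's window is capped at the time the model reaches
    ``SATURATION_CAP`` of its saturated amplitude and the fit is repeated.
    The cap keeps the flat, b-wave-contaminated part of the limb out of the
    fit while the curvature of the retained edge still pins ``RmP3``.

    Parameters
    ----------
    family : WaveformFamily
    energies : two log10 energies present in ``family`` (brightest pair of the
        pathway by default).
    adaptation : which adaptation state the energies refer to.
    window : optional explicit fit window (seconds from flash onset) applied
        to both flashes; when given, the saturation refinement is skipped.
    min_deflection_uv : a trace whose smoothed minimum within the window is
        shallower than this raises :class:`DegenerateFitError`.
    """
    if len(energies) != 2:
        raise ProtocolError("fit_p3 expects exactly two energies")
    waves = [family.get(adaptation, e) for e in energies]
    tb = family.timebase
    fs = tb.sampling_rate
    sos = _p2_sos(fs)
    t_rel = tb.times_from_onset()
    i_lin = [10.0 ** e for e in energies]

    starts, ends = [], []
    for wave in waves:
        if window is None:
            i0 = tb.onset_index
            i1 = _trough_index(wave, sos, min_deflection_uv)
        else:
            i0 = tb.onset_index + int(round(window[0] * fs))
            i1 = tb.onset_index + int(round(window[1] * fs))
        if i1 <= i0 + 2:
            raise DegenerateFitError("fit window too short for a 3-parameter fit")
        smoothed = filters.zero_phase(sos, wave.samples - baseline(wave))
        if np.min(smoothed[i0:i1 + 1]) > -min_deflection_uv:
            raise DegenerateFitError(
                f"no negative deflection deeper than {min_deflection_uv} µV in "
                f"window for flash {wave.stimulus.log_energy}")
        starts.append(i0)
        ends.append(i1)

    def segments(end_idx: list[int]):
        seg_t = [t_rel[i0:i1 + 1] for i0, i1 in zip(starts, end_idx)]
        seg_v = [w.samples[i0:i1 + 1] - baseline(w)
                 for w, i0, i1 in zip(waves, starts, end_idx)]
        return seg_t, seg_v

    seg_t, seg_v = segments(ends)
    sol = _solve_p3(seg_t, seg_v, i_lin)
    if window is None:
        for _ in range(2):  # saturation-capped refinement
            _, s, td = sol.x
            capped = []
            for i0, i1, i in zip(starts, ends, i_lin):
                t_cap = td + np.sqrt(-np.log(1.0 - SATURATION_CAP) / (i * s))
                i_cap = tb.onset_index + int(np.ceil(t_cap * fs))
                capped.append(int(np.clip(i_cap, i0 + 3, i1)))
            seg_t, seg_v = segments(capped)
            sol = _solve_p3(seg_t, seg_v, i_lin)
            ends = capped
    rm, s, td = sol.x
    rms = float(np.sqrt(np.mean(sol.fun ** 2)))
    windows = tuple((float(t_rel[i0]), float(t_rel[i1]))
                    for i0, i1 in zip(starts, ends))
    return P3Fit(params=P3Params(rm, s, td), fit_window=windows,
                 energies_used=(float(energies[0]), float(energies[1])),
                 residual_rms=rms, adaptation=adaptation)


def subtract_p3(family: WaveformFamily, fit: P3Fit) -> WaveformFamily:
    """Subtract the fitted P3 model (evaluated at each flash's own energy)
    from every waveform of the fit's adaptation state; other states pass
    through untouched."""
    out = []
    t_rel = family.timebase.times_from_onset()
    for wave in family:
        if wave.stimulus.adaptation == fit.adaptation:
            model = p3_model(fit.params, wave.stimulus.energy, t_rel)
            out.append(ERGWaveform(wave.timebase, wave.stimulus,
                                   wave.samples - model))
        else:
            out.append(wave)
    return WaveformFamily(out)


def extract_p2(residual: ERGWaveform,
               filter_spec: tuple[float, int] = (P2_FILTER_CORNER_HZ,
                                                 P2_FILTER_ORDER),
               ) -> tuple[ERGWaveform, float]:
    """Low-pass the P2–OP complex and measure the b-wave peak.

    Returns the filtered waveform and the baseline-corrected positive peak
    after flash onset (µV; 0 if no positive deflection exists).
    """
    corner, order = filter_spec
    fs = residual.timebase.sampling_rate
    if corner >= fs / 2:
        raise ConfigurationError(f"corner {corner} Hz >= Nyquist {fs / 2} Hz")
    sos = filters.design_net3db(corner, fs, order=order, btype="low")
    filtered = filters.zero_phase(sos, residual.samples)
    fwave = ERGWaveform(residual.timebase, residual.stimulus, filtered)
    onset = residual.timebase.onset_index
    peak = float(np.max(filtered[onset:]) - baseline(fwave))
    return fwave, max(peak, 0.0)


def _naka_rushton(i: np.ndarray, vmax: float, k: float, n: float) -> np.ndarray:
    return vmax * i ** n / (i ** n + k ** n)


def fit_naka_rushton(amplitudes: Mapping[float, float],
                     fix_n: bool = True) -> tuple[float, float, float]:
    """Fit ``V(i) = Vmax·iⁿ/(iⁿ+Kⁿ)`` to a log-energy → amplitude map.

    Returns ``(vmax, k, n)``. With ``fix_n=True`` (default) the exponent is
    pinned at 1 — the saturated hyperbola. Negative amplitudes are clipped to
    zero with a warning; an all-zero map returns ``(0, nan, n)``.
    """
    log_e = np.array(sorted(amplitudes))
    v = np.array([amplitudes[e] for e in log_e], dtype=float)
    if np.any(v < 0):
        warnings.warn("negative P2 amplitudes clipped to 0 for Naka-Rushton fit")
        v = np.clip(v, 0.0, None)
    if np.all(v == 0):
        return 0.0, float("nan"), 1.0
    i = 10.0 ** log_e
    if len(i) < 3:
        warnings.warn("fewer than 3 energies: Naka-Rushton fit poorly identified")
    vmax0 = float(v.max())
    k0 = float(i[np.argmin(np.abs(v - vmax0 / 2))])
    try:
        if fix_n:
            popt, _ = curve_fit(lambda ii, vm, kk: _naka_rushton(ii, vm, kk, 1.0),
                                i, v, p0=[vmax0, k0],
                                bounds=([0, 1e-30], [np.inf, np.inf]),
                                maxfev=20000)
            return float(popt[0]), float(popt[1]), 1.0
        popt, _ = curve_fit(_naka_rushton, i, v, p0=[vmax0, k0, 1.0],
                            bounds=([0, 1e-30, 0.1], [np.inf, np.inf, 10.0]),
                            maxfev=20000)
        return float(popt[0]), float(popt[1]), float(popt[2])
    except RuntimeError as exc:  # pragma: no cover - pathological inputs
        raise FitError(f"Naka-Rushton fit failed: {exc}") from exc


def measure_pstr(family: WaveformFamily,
                 energies: tuple[float, float] = PSTR_ENERGIES,
                 window: tuple[float, float] = (0.060, 0.200),
                 smooth: bool = True) -> PSTRResult:
    """Mean positive peak amplitude at the two threshold-level flashes.

    With ``smooth=True`` (default) the trace is low-passed with the same
    46.9 Hz zero-phase filter used for b-wave extraction before the peak is
    read off. The pSTR bump is far slower than the corner so it passes
    unchanged, while wideband noise — whose running maximum would otherwise
    bias the peak upward — is suppressed.
    """
    tb = family.timebase
    fs = tb.sampling_rate
    sos = _p2_sos(fs) if smooth else None
    i0 = tb.onset_index + int(round(window[0] * fs))
    i1 = tb.onset_index + int(round(window[1] * fs))
    peaks = []
    for e in energies:
        wave = family.get(DARK, e)
        samples = (filters.zero_phase(sos, wave.samples) if smooth
                   else wave.samples)
        wave = ERGWaveform(tb, wave.stimulus, samples)
        seg = wave.samples[i0:i1 + 1] - baseline(wave)
        peaks.append(max(float(np.max(seg)), 0.0))
    return PSTRResult(amplitude=float(np.mean(peaks)),
                      energies_used=(float(energies[0]), float(energies[1])),
                      search_window=window, per_flash_peaks=tuple(peaks))


def _p2_branch(family: WaveformFamily, p3fit: P3Fit, adaptation: str,
               cfg: DecompositionConfig) -> P2Result:
    residuals = subtract_p3(family, p3fit)
    amps: dict[float, float] = {}
    for wave in residuals:
        if wave.stimulus.adaptation != adaptation:
            continue
        _, peak = extract_p2(wave, cfg.p2_filter)
        amps[wave.stimulus.log_energy] = peak
    vmax, k, n = fit_naka_rushton(amps, fix_n=cfg.fix_n)
    return P2Result(amplitudes=amps, vmax=vmax, k=k, n=n,
                    filter_spec=cfg.p2_filter,
                    degenerate=not np.isfinite(k))


def decompose(family: WaveformFamily,
              config: DecompositionConfig = DecompositionConfig(),
              ) -> DecompositionResult:
    """Run the full decomposition on whichever pathways the family covers.

    Rod P3/P2 and pSTR need dark-adapted flashes at the configured energies;
    cone P3/P2 need the light-adapted pair. Pathways whose energies are
    absent are left as ``None`` rather than raising.
    """
    out: dict[str, object] = {}
    if all(family.has(DARK, e) for e in config.rod_p3_energies):
        try:
            rod_fit = fit_p3(family, config.rod_p3_energies, DARK,
                             min_deflection_uv=config.min_deflection_uv)
            out["rod_p3"] = rod_fit
            out["rod_p2"] = _p2_branch(family, rod_fit, DARK, config)
        except (DegenerateFitError, FitError) as exc:
            raise StageError("rod", exc) from exc
    if all(family.has(LIGHT, e) for e in config.cone_p3_energies):
        try:
            cone_fit = fit_p3(family, config.cone_p3_energies, LIGHT,
                              min_deflection_uv=config.min_deflection_uv)
            out["cone_p3"] = cone_fit
            out["cone_p2"] = _p2_branch(family, cone_fit, LIGHT, config)
        except (DegenerateFitError, FitError) as exc:
            raise StageError("cone", exc) from exc
    if all(family.has(DARK, e) for e in config.pstr_energies):
        try:
            out["pstr"] = measure_pstr(family, config.pstr_energies,
                                       config.pstr_window)
        except ProtocolError as exc:
            raise StageError("pstr", exc) from exc
    return DecompositionResult(**out)
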