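"""Whole-cell voltage-clamp analysis equations.

Small, self-contained implementations of the standard analysis steps for
step-depolarization recordings of slowly activating K+ channels:

* leak subtraction against a control (non-transfected) recording,
* peak current densities (pA/pF),
* normalized conductance G/Gmax from steady-state peak currents and a
  supplied reversal potential,
* Boltzmann activation fit  G/Gmax = 1 / (1 + exp((V_half - V) / k)),
* mono-exponential activation time constant,
* current-decay ratio I(10 s) / I_peak under voltage-sensitive-phosphatase
  activation (an index of PIP2-depletion sensitivity).

All are testable by parameter recovery on synthetic traces; the package does
no acquisition and no binary file parsing. Trace I/O is a plain tab-separated
time series (``time_ms`` plus one column per voltage).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import FitError, ProtocolError


def boltzmann(v: np.ndarray, v_half: float, k: float) -> np.ndarray:
    """Activation Boltzmann: 1 / (1 + exp((v_half - v) / k))."""
    return 1.0 / (1.0 + np.exp((v_half - np.asarray(v, dtype=float)) / k))


@dataclass(frozen=True)
class StepRecording:
    """One step-protocol recording: per-voltage current time series.

    ``currents`` has shape (n_voltages, n_samples) in pA; ``time_ms`` is the
    shared time base; ``capacitance_pF`` scales current densities.
    """

    voltages: np.ndarray
    time_ms: np.ndarray
    currents: np.ndarray
    capacitance_pF: float = 1.0
    reversal_potential_mV: Optional[float] = None

    def __post_init__(self) -> None:
        v = np.asarray(self.voltages, dtype=float)
        t = np.asarray(self.time_ms, dtype=float)
        i = np.asarray(self.currents, dtype=float)
        if i.shape != (v.size, t.size):
            raise ProtocolError(
                f"currents shape {i.shape} does not match "
                f"({v.size} voltages, {t.size} samples)"
            )
        if self.capacitance_pF <= 0:
            raise ProtocolError("capacitance must be positive")
        object.__setattr__(self, "voltages", v)
        object.__setattr__(self, "time_ms", t)
        object.__setattr__(self, "currents", i)

    def trace(self, voltage: float) -> np.ndarray:
        match = np.flatnonzero(np.isclose(self.voltages, voltage))
        if match.size == 0:
            raise ProtocolError(f"no trace recorded at {voltage} mV")
        return self.currents[match[0]]

    def peak_currents(self) -> np.ndarray:
        """Per-voltage peak current in pA, signed at the maximal amplitude
        (steps below the reversal potential carry inward, negative current)."""
        idx = np.argmax(np.abs(self.currents), axis=1)
        return self.currents[np.arange(self.currents.shape[0]), idx]

    def peak_current_densities(self) -> np.ndarray:
        """Per-voltage peak current density in pA/pF."""
        return self.peak_currents() / self.capacitance_pF

    @classmethod
    def from_tsv(
        cls, path: Union[str, Path], capacitance_pF: float = 1.0,
        reversal_potential_mV: Optional[float] = None,
    ) -> "StepRecording":
        df = pd.read_csv(path, sep="\t")
        if "time_ms" not in df.columns:
            raise ProtocolError(f"{path}: missing 'time_ms' column")
        volt_cols = [c for c in df.columns if c != "time_ms"]
        voltages = np.array([float(c) for c in volt_cols])
        return cls(
            voltages=voltages,
            time_ms=df["time_ms"].to_numpy(),
            currents=df[volt_cols].to_numpy().T,
            capacitance_pF=capacitance_pF,
            reversal_potential_mV=reversal_potential_mV,
        )

    def to_tsv(self, path: Union[str, Path]) -> None:
        df = pd.DataFrame({"time_ms": self.time_ms})
        for v, trace in zip(self.voltages, self.currents):
            df[f"{v:g}"] = trace
        df.to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class BoltzmannFit:
    """Half-activation voltage (mV), slope factor (mV), residual norm."""

    v_half: float
    k: float
    residual_norm: float

    def predict(self, v: np.ndarray) -> np.ndarray:
        return boltzmann(v, self.v_half, self.k)


@dataclass(frozen=True)
class VSPDecayResult:
    """Per-voltage I(10 s)/I_peak ratio and percent decay."""

    voltages: np.ndarray
    ratio: np.ndarray

    @property
    def decay_percent(self) -> np.ndarray:
        return (1.0 - self.ratio) * 100.0

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "voltage_mV": self.voltages,
                "ratio_10s_over_peak": self.ratio,
                "decay_percent": self.decay_percent,
            }
        )


def leak_subtract(recording: StepRecording, control: StepRecording) -> StepRecording:
    """Subtract the control (leak) current pointwise in time, per voltage.

    The control is typically the mean recording from cells expressing no
    channel; voltage protocols must match exactly.
    """
    if not np.array_equal(recording.voltages, control.voltages):
        raise ProtocolError("recording and control voltage protocols differ")
    if recording.time_ms.size != control.time_ms.size or not np.allclose(
        recording.time_ms, control.time_ms
    ):
        raise ProtocolError("recording and control time bases differ")
    return replace(recording, currents=recording.currents - control.currents)


def conductance_curve(
    recording: StepRecording, reversal_potential_mV: Optional[float] = None
) -> tuple[np.ndarray, np.ndarray]:
    """Normalized conductance G/Gmax from steady-state peak currents.

    G(V) = I_peak(V) / (V - V_rev), normalized by the maximum over steps.
    Steps at V == V_rev are excluded with a warning (zero driving force).
    Returns (voltages, g_over_gmax).
    """
    v_rev = (
        reversal_potential_mV
        if reversal_potential_mV is not None
        else recording.reversal_potential_mV
    )
    if v_rev is None:
        raise ProtocolError("a reversal potential is required")
    v = recording.voltages
    peaks = recording.peak_currents()
    usable = ~np.isclose(v, v_rev)
    if not usable.all():
        warnings.warn(
            f"excluding step(s) at the reversal potential {v_rev} mV",
            stacklevel=2,
        )
    v, peaks = v[usable], peaks[usable]
    g = peaks / (v - v_rev)
    gmax = g.max()
    if gmax <= 0:
        raise FitError("non-positive maximal conductance; check polarity")
    return v, g / gmax


def fit_boltzmann(
    voltages: Sequence[float], g_over_gmax: Sequence[float]
) -> BoltzmannFit:
    """Least-squares Boltzmann fit of normalized conductance.

    Requires at least 4 points spanning the transition. Initial values: the
    voltage nearest half-activation for V_half, and a slope estimated from
    the 25-75% rise for k.
    """
    v = np.asarray(voltages, dtype=float)
    g = np.asarray(g_over_gmax, dtype=float)
    if v.size != g.size or v.size < 4:
        raise FitError("need >= 4 (V, G/Gmax) points")
    v0 = float(v[np.argmin(np.abs(g - 0.5))])
    span = v.max() - v.min()
    k0 = max(span / 10.0, 1.0)
    try:
        popt, _ = curve_fit(
            boltzmann, v, g, p0=[v0, k0], maxfev=10_000
        )
    except RuntimeError as exc:
        raise FitError(f"Boltzmann fit did not converge: {exc}") from exc
    v_half, k = float(popt[0]), float(popt[1])
    if k == 0:
        raise FitError("degenerate slope factor k = 0")
    resid = g - boltzmann(v, v_half, k)
    return BoltzmannFit(
        v_half=v_half, k=k, residual_norm=float(np.linalg.norm(resid))
    )


def fit_activation_tau(
    time_ms: Sequence[float],
    current: Sequence[float],
    window_ms: Optional[tuple[float, float]] = None,
) -> float:
    """Mono-exponential activation time constant (ms).

    Fits I(t) = A * (1 - exp(-t/tau)) + C over the window from stimulus
    onset to the peak (or an explicit ``window_ms``). Raises
    :class:`FitError` on flat or non-activating traces.
    """
    t = np.asarray(time_ms, dtype=float)
    i = np.asarray(current, dtype=float)
    if window_ms is not None:
        mask = (t >= window_ms[0]) & (t <= window_ms[1])
        t, i = t[mask], i[mask]
    else:
        peak = int(np.argmax(i))
        t, i = t[: peak + 1], i[: peak + 1]
    if t.size < 4:
        raise FitError("too few samples in the activation window")
    amplitude = i.max() - i[0]
    if amplitude <= 0 or amplitude < 1e-12 * max(1.0, abs(i.max())):
        raise FitError("trace does not activate (no rise above baseline)")
    t0 = t - t[0]

    def model(tt, A, tau, C):
        return A * (1.0 - np.exp(-tt / tau)) + C

    # crude tau init: time to 63% of the rise
    level = i[0] + 0.632 * amplitude
    above = np.flatnonzero(i >= level)
    tau0 = float(t0[above[0]]) if above.size else float(t0[-1] / 3)
    tau0 = max(tau0, (t0[1] - t0[0]) if t0.size > 1 else 1.0)
    try:
        popt, _ = curve_fit(
            model, t0, i, p0=[amplitude, tau0, i[0]], maxfev=10_000
        )
    except RuntimeError as exc:
        raise FitError(f"activation fit did not converge: {exc}") from exc
    tau = float(popt[1])
    if tau <= 0:
        raise FitError(f"non-physical time constant {tau}")
    return tau


def vsp_decay(
    recording: StepRecording, at_time_ms: float = 10_000.0
) -> VSPDecayResult:
    """Current-decay ratio I(t = 10 s) / I_peak per voltage step.

    The trace must span the 10 s step. Ratios are clipped to [0, 1] only by
    validation: a non-positive peak raises an error rather than producing an
    undefined ratio.
    """
    if recording.time_ms[-1] < at_time_ms:
        raise ProtocolError(
            f"trace ends at {recording.time_ms[-1]} ms, before {at_time_ms} ms"
        )
    idx_end = int(np.argmin(np.abs(recording.time_ms - at_time_ms)))
    peaks = recording.currents.max(axis=1)
    if np.any(peaks <= 0):
        bad = recording.voltages[peaks <= 0]
        raise FitError(f"non-positive peak current at {bad.tolist()} mV")
    ratio = recording.currents[:, idx_end] / peaks
    return VSPDecayResult(voltages=recording.voltages.copy(), ratio=ratio)


def synthesize_step_recording(
    voltages: Sequence[float] = tuple(range(-100, 30, 10)),
    v_half: float = -26.8,
    k: float = 9.0,
    gmax_nS: float = 8.0,
    reversal_potential_mV: float = -78.0,
    tau_ms: float = 120.0,
    duration_ms: float = 1_500.0,
    dt_ms: float = 5.0,
    leak_conductance_nS: float = 0.0,
    noise_sd_pA: float = 0.0,
    capacitance_pF: float = 10.0,
    rng: Optional[np.random.Generator] = None,
) -> StepRecording:
    """Synthetic step-protocol recording for validation and examples.

    Currents follow I(V, t) = Gmax * Po(V) * (V - Vrev) * (1 - exp(-t/tau))
    with Boltzmann open probability Po, optional ohmic leak, and optional
    additive Gaussian noise. Purely a test-harness construct: real recordings
    contain capacitive transients, series-resistance error and rundown that
    this generator does not emulate.
    """
    v = np.asarray(voltages, dtype=float)
    t = np.arange(0.0, duration_ms + dt_ms / 2, dt_ms)
    po = boltzmann(v, v_half, k)
    drive = v - reversal_potential_mV
    activation = 1.0 - np.exp(-t / tau_ms)
    currents = (gmax_nS * po * drive)[:, None] * activation[None, :]
    currents += (leak_conductance_nS * drive)[:, None] * np.ones_like(t)[None, :]
    if noise_sd_pA > 0:
        if rng is None:
            rng = np.random.default_rng()
        currents = currents + rng.normal(0.0, noise_sd_pA, size=currents.shape)
    return StepRecording(
        voltages=v,
        time_ms=t,
        currents=currents,
        capacitance_pF=capacitance_pF,
        reversal_potential_mV=reversal_potential_mV,
    )
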