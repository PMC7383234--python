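"""Voltage-clamp and current-clamp analysis of K_V channel recordings.

Covers the standard offline chain for delayed-rectifier potassium currents:
linear leak subtraction, tail-current activation curves, Boltzmann fits of
voltage dependence (single for activation, single or double for steady-state
inactivation), isolation of the stromatoxin-1 (ScTx)-sensitive current by
pre/post subtraction, single-exponential recovery from inactivation, and
action-potential threshold extraction from ramp and step current injections.

All voltages are mV, times ms, currents pA internally (nA accepted on input
by the table readers and converted).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize

__all__ = [
    "Sweep",
    "SweepSeries",
    "BoltzmannParams",
    "DoubleBoltzmannParams",
    "RecoveryFit",
    "FitFailure",
    "boltzmann",
    "double_boltzmann",
    "leak_subtract",
    "tail_activation_curve",
    "fit_boltzmann",
    "fit_double_boltzmann",
    "sctx_subtract",
    "fractional_reduction",
    "fit_recovery",
    "detect_spikes",
    "ap_threshold_ramp",
    "ap_threshold_step",
    "capsaicin_responder",
]

PROTOCOLS = ("activation", "inactivation", "recovery", "ramp", "step")


class FitFailure(RuntimeError):
    """Nonlinear fit failed to converge; carries diagnostics."""


@dataclass
class Sweep:
    """One sweep: a command level and a uniformly sampled trace."""

    command: float  # step/ramp amplitude: mV (voltage clamp) or pA (current clamp)
    time: np.ndarray  # ms
    value: np.ndarray  # pA (voltage clamp) or mV (current clamp)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.value = np.asarray(self.value, dtype=float)
        if self.time.shape != self.value.shape or self.time.ndim != 1:
            raise ValueError("time and value must be matching 1-D arrays")
        if self.time.size >= 3:
            dt = np.diff(self.time)
            if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
                raise ValueError("sweep sampling must be uniform")

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0])


@dataclass
class SweepSeries:
    """A protocol's family of sweeps plus holding potential and metadata.

    ``metadata`` carries protocol annotations, e.g. ``tail_start_ms`` and
    ``tail_voltage`` for activation protocols, ``ramp`` = (i0_pA, i1_pA,
    duration_ms) for ramps, or ``sctx_sensitive`` after subtraction.
    """

    protocol: str
    sweeps: list[Sweep]
    holding: float = -90.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.protocol not in PROTOCOLS:
            raise ValueError(f"unknown protocol {self.protocol!r}")

    @property
    def commands(self) -> np.ndarray:
        return np.array([s.command for s in self.sweeps])

    def copy(self) -> "SweepSeries":
        return SweepSeries(
            protocol=self.protocol,
            sweeps=[Sweep(s.command, s.time.copy(), s.value.copy()) for s in self.sweeps],
            holding=self.holding,
            metadata=dict(self.metadata),
        )


@dataclass(frozen=True)
class BoltzmannParams:
    """y = top / (1 + exp((v_half - E) / slope)); slope > 0 (mV)."""

    top: float
    v_half: float
    slope: float


@dataclass(frozen=True)
class DoubleBoltzmannParams:
    """Sum of two Boltzmann components.

    y = top * [F / (1 + exp((v_half_1 - E)/slope_1))
               + (1 - F) / (1 + exp((v_half_2 - E)/slope_2))]

    Components are ordered so ``v_half_1 >= v_half_2`` (component 1 is the
    more depolarized); ``degenerate`` flags near-coincident midpoints
    (|v_half_1 - v_half_2| < 2 mV), where F is unidentifiable.
    """

    top: float
    fraction: float
    v_half_1: float
    slope_1: float
    v_half_2: float
    slope_2: float
    degenerate: bool = False


@dataclass(frozen=True)
class RecoveryFit:
    """y(dt) = 1 - amplitude * exp(-dt / tau); tau in ms."""

    amplitude: float
    tau: float


def boltzmann(v, top: float, v_half: float, slope: float):
    v = np.asarray(v, dtype=float)
    with np.errstate(over="ignore"):  # saturated exp -> y = 0 is correct
        return top / (1.0 + np.exp((v_half - v) / slope))


def double_boltzmann(
    v, top: float, fraction: float, v1: float, k1: float, v2: float, k2: float
):
    v = np.asarray(v, dtype=float)
    with np.errstate(over="ignore"):
        return top * (
            fraction / (1.0 + np.exp((v1 - v) / k1))
            + (1.0 - fraction) / (1.0 + np.exp((v2 - v) / k2))
        )


# ---------------------------------------------------------------------------
# voltage-clamp pre-processing


def _steady_state(sweep: Sweep, frac: float = 0.1, end_ms: float | None = None) -> float:
    """Mean current over the last ``frac`` of the step segment."""
    if end_ms is None:
        values = sweep.value
    else:
        values = sweep.value[sweep.time < end_ms]
    n = max(int(len(values) * frac), 1)
    return float(values[-n:].mean())


def leak_subtract(series: SweepSeries, leak_window: tuple[float, float]) -> SweepSeries:
    """Fit and remove the linear (ohmic) leak component.

    Steady-state currents of sweeps whose command voltage lies inside
    ``leak_window`` (where channels stay closed) are fit to
    ``I = g (V - V_rev)`` by least squares; ``g (V - V_rev)`` is then
    subtracted from every sweep, using the tail command voltage over the
    annotated tail segment when present.
    """
    lo, hi = leak_window
    end = series.metadata.get("tail_start_ms")
    leak = [s for s in series.sweeps if lo <= s.command <= hi]
    if len(leak) < 2:
        raise ValueError("need >= 2 sweeps inside the leak window")
    v = np.array([s.command for s in leak])
    i = np.array([_steady_state(s, end_ms=end) for s in leak])
    g, intercept = np.polyfit(v, i, 1)  # I = g*V + b, V_rev = -b/g
    out = series.copy()
    tail_v = series.metadata.get("tail_voltage")
    for s in out.sweeps:
        pred = g * s.command + intercept
        if end is not None and tail_v is not None:
            correction = np.where(s.time < end, pred, g * tail_v + intercept)
        else:
            correction = pred
        s.value = s.value - correction
    out.metadata["leak_conductance_nS"] = float(g)  # pA/mV == nS
    out.metadata["leak_reversal_mV"] = float(-intercept / g) if g != 0 else float("nan")
    return out


def tail_activation_curve(
    series: SweepSeries,
    peak_window_ms: float = 10.0,
    baseline_frac: float = 0.2,
) -> np.ndarray:
    """Normalized tail amplitudes vs step voltage from an activation series.

    The tail amplitude is the peak absolute deviation from the late-tail
    baseline within the first ``peak_window_ms`` of the tail segment; the
    curve is normalized to its maximum.  Returns an array of rows
    ``(step_voltage_mV, normalized_amplitude)`` sorted by voltage.
    """
    start = series.metadata.get("tail_start_ms")
    if start is None:
        raise ValueError("activation series lacks tail_start_ms annotation")
    pts = []
    for s in series.sweeps:
        tail = s.value[s.time >= start]
        t = s.time[s.time >= start]
        if tail.size < 4:
            raise ValueError("tail segment too short")
        n_base = max(int(tail.size * baseline_frac), 1)
        base = tail[-n_base:].mean()
        early = tail[t < start + peak_window_ms]
        amp = float(np.abs(early - base).max())
        pts.append((s.command, amp))
    pts = np.array(sorted(pts))
    peak = pts[:, 1].max()
    if peak > 0:
        pts[:, 1] = pts[:, 1] / peak
    return pts


# ---------------------------------------------------------------------------
# curve fits


def _rms(resid: np.ndarray) -> float:
    return float(np.sqrt(np.mean(resid**2)))


def _default_boltzmann_init(v: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    top = float(y.max())
    half = top / 2.0
    order = np.argsort(v)
    vs, ys = v[order], y[order]
    v_half = float(np.interp(half, ys, vs)) if np.any(np.diff(ys) != 0) else float(vs.mean())
    v10 = float(np.interp(0.1 * top, ys, vs))
    v90 = float(np.interp(0.9 * top, ys, vs))
    k = max(abs(v90 - v10) / 4.39, 0.5)
    return top, v_half, k


def fit_boltzmann(
    points,
    init: tuple[float, float, float] | None = None,
    fix_top: float | None = None,
    max_restarts: int = 5,
    seed: int = 0,
) -> tuple[BoltzmannParams, float]:
    """Least-squares single-Boltzmann fit of (voltage, response) points.

    Default initialisation: top = max response, v_half by linear
    interpolation of the half-max crossing, slope = (V90 - V10)/4.39.  The
    slope is constrained positive; ``fix_top`` freezes the top (e.g. at 1
    for pre-normalized curves).  Raises :class:`FitFailure` after bounded
    jittered restarts.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 4:
        raise ValueError("need >= 4 (voltage, response) points")
    v, y = pts[:, 0], pts[:, 1]
    p0 = np.array(init if init is not None else _default_boltzmann_init(v, y))
    rng = np.random.default_rng(seed)
    span = v.max() - v.min()
    if fix_top is None:
        def f(vv, top, vh, k):
            return boltzmann(vv, top, vh, k)
        full0 = p0
        lb = [0.0, v.min() - span, 1e-3]
        ub = [np.inf, v.max() + span, np.inf]
    else:
        def f(vv, vh, k):
            return boltzmann(vv, fix_top, vh, k)
        full0 = p0[1:]
        lb = [v.min() - span, 1e-3]
        ub = [v.max() + span, np.inf]
    last_err: Exception | None = None
    for attempt in range(max_restarts + 1):
        start = full0 if attempt == 0 else full0 * (1 + 0.2 * rng.standard_normal(len(full0)))
        start = np.clip(start, lb, ub)
        try:
            popt, _ = optimize.curve_fit(f, v, y, p0=start, bounds=(lb, ub), maxfev=10000)
        except (RuntimeError, ValueError) as err:  # pragma: no cover - rare
            last_err = err
            continue
        if fix_top is None:
            params = BoltzmannParams(top=float(popt[0]), v_half=float(popt[1]), slope=float(popt[2]))
        else:
            params = BoltzmannParams(top=float(fix_top), v_half=float(popt[0]), slope=float(popt[1]))
        resid = y - boltzmann(v, params.top, params.v_half, params.slope)
        return params, _rms(resid)
    raise FitFailure(f"single-Boltzmann fit failed after {max_restarts} restarts: {last_err}")


def fit_double_boltzmann(
    points,
    n_starts: int = 5,
    seed: int = 0,
) -> tuple[DoubleBoltzmannParams, float]:
    """Least-squares double-Boltzmann fit with multistart.

    F is bounded to [0, 1] and both slopes positive.  ``n_starts`` seeded
    initialisations spread the two midpoints over the sampled span to
    escape local minima; components are relabelled after the fit so that
    component 1 is the more depolarized (larger F breaks exact ties).
    Near-coincident midpoints (|dV50| < 2 mV) set ``degenerate``.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 8:
        raise ValueError("need >= 8 (voltage, response) points")
    v, y = pts[:, 0], pts[:, 1]
    rng = np.random.default_rng(seed)
    span = v.max() - v.min()
    top0, vh0, k0 = _default_boltzmann_init(v, y)
    lb = [0.0, 0.0, v.min() - span, 1e-3, v.min() - span, 1e-3]
    ub = [np.inf, 1.0, v.max() + span, np.inf, v.max() + span, np.inf]
    best: tuple[float, np.ndarray] | None = None
    for attempt in range(n_starts):
        if attempt == 0:
            start = [top0, 0.5, vh0 + span / 4, k0, vh0 - span / 4, k0]
        else:
            start = [
                top0 * (1 + 0.1 * rng.standard_normal()),
                rng.uniform(0.2, 0.8),
                rng.uniform(vh0, v.max()),
                k0 * rng.uniform(0.5, 2.0),
                rng.uniform(v.min(), vh0),
                k0 * rng.uniform(0.5, 2.0),
            ]
        start = np.clip(start, lb, ub)
        try:
            popt, _ = optimize.curve_fit(
                double_boltzmann, v, y, p0=start, bounds=(lb, ub), maxfev=20000
            )
        except (RuntimeError, ValueError):
            continue
        rms = _rms(y - double_boltzmann(v, *popt))
        if best is None or rms < best[0]:
            best = (rms, popt)
    if best is None:
        raise FitFailure(f"double-Boltzmann fit failed in all {n_starts} starts")
    rms, (top, frac, v1, k1, v2, k2) = best
    if (v1, frac) < (v2, 1 - frac):  # order: depolarized first, larger F on ties
        v1, k1, v2, k2, frac = v2, k2, v1, k1, 1 - frac
    params = DoubleBoltzmannParams(
        top=float(top),
        fraction=float(frac),
        v_half_1=float(v1),
        slope_1=float(k1),
        v_half_2=float(v2),
        slope_2=float(k2),
        degenerate=bool(abs(v1 - v2) < 2.0),
    )
    return params, rms


def sctx_subtract(pre_series: SweepSeries, post_series: SweepSeries) -> SweepSeries:
    """Toxin-sensitive current: pre-ScTx minus post-ScTx, sweep by sweep."""
    if len(pre_series.sweeps) != len(post_series.sweeps):
        raise ValueError("pre and post series have different sweep counts")
    out = pre_series.copy()
    for s_out, s_pre, s_post in zip(out.sweeps, pre_series.sweeps, post_series.sweeps):
        if s_pre.command != s_post.command:
            raise ValueError("pre/post sweep command voltages differ")
        if s_pre.time.shape != s_post.time.shape or not np.allclose(
            s_pre.time, s_post.time
        ):
            raise ValueError("pre/post sweep sampling differs")
        s_out.value = s_pre.value - s_post.value
    out.metadata["sctx_sensitive"] = True
    return out


def fractional_reduction(
    pre_series: SweepSeries, post_series: SweepSeries, command: float
) -> float:
    """Fractional steady-state current block at one step potential.

    Returns ``(I_pre - I_post) / I_pre`` using the late-step steady-state
    current of the sweep whose command voltage equals ``command``.
    """
    def pick(series: SweepSeries) -> Sweep:
        for s in series.sweeps:
            if np.isclose(s.command, command):
                return s
        raise ValueError(f"no sweep at {command} mV")

    end = pre_series.metadata.get("tail_start_ms")
    i_pre = _steady_state(pick(pre_series), end_ms=end)
    i_post = _steady_state(pick(post_series), end_ms=end)
    if i_pre == 0:
        raise ValueError("zero pre-toxin current at requested step")
    return float((i_pre - i_post) / i_pre)


def fit_recovery(intervals, ratios, y0_form: bool = False) -> tuple[RecoveryFit, float]:
    """Single-exponential recovery from inactivation.

    Fits ``y = 1 - A exp(-dt/tau)`` to (interval ms, test/conditioning
    current ratio) data; ``y0_form`` instead fits
    ``y = y0 + (1 - y0)(1 - exp(-dt/tau))`` and reports A = 1 - y0.
    """
    t = np.asarray(intervals, dtype=float)
    y = np.asarray(ratios, dtype=float)
    if t.size < 4:
        raise ValueError("need >= 4 recovery intervals")
    if np.any((y < 0) | (y > 1.2)):
        raise ValueError("recovery ratios outside [0, 1.2]")
    tau0 = max(float(t.mean()), 1e-3)

    if y0_form:
        def f(tt, y0, tau):
            return y0 + (1 - y0) * (1 - np.exp(-tt / tau))
        p0, lb, ub = [float(y.min()), tau0], [0.0, 1e-6], [1.0, np.inf]
    else:
        def f(tt, a, tau):
            return 1.0 - a * np.exp(-tt / tau)
        p0, lb, ub = [1.0 - float(y.min()), tau0], [0.0, 1e-6], [1.0, np.inf]
    try:
        popt, _ = optimize.curve_fit(f, t, y, p0=p0, bounds=(lb, ub), maxfev=10000)
    except (RuntimeError, ValueError) as err:
        raise FitFailure(f"recovery fit failed: {err}") from err
    a = 1.0 - popt[0] if y0_form else popt[0]
    fit = RecoveryFit(amplitude=float(a), tau=float(popt[1]))
    return fit, _rms(y - f(t, *popt))


# ---------------------------------------------------------------------------
# current clamp


def detect_spikes(
    time: np.ndarray,
    voltage: np.ndarray,
    dvdt_threshold: float = 10.0,
    overshoot: float = 0.0,
    window_ms: float = 2.0,
) -> np.ndarray:
    """Indices of action-potential onsets in a voltage trace.

    A spike onset is the first sample of a run where dV/dt exceeds
    ``dvdt_threshold`` (mV/ms) and the voltage within the following
    ``window_ms`` exceeds ``overshoot`` (mV).
    """
    time = np.asarray(time, dtype=float)
    voltage = np.asarray(voltage, dtype=float)
    dt = time[1] - time[0]
    dvdt = np.gradient(voltage, dt)
    fast = dvdt >= dvdt_threshold
    onsets = np.flatnonzero(fast & ~np.roll(fast, 1))
    w = max(int(round(window_ms / dt)), 1)
    hits = [i for i in onsets if voltage[i : i + w].max() > overshoot]
    return np.asarray(hits, dtype=int)


def ap_threshold_ramp(
    sweep: Sweep,
    ramp: tuple[float, float, float] | None = None,
    dvdt_threshold: float = 10.0,
    overshoot: float = 0.0,
) -> float | None:
    """Injected current (pA) at the first spike under a current ramp.

    ``ramp`` = (i0_pA, i1_pA, duration_ms); taken from the sweep series
    metadata by the CLI.  Returns None when no spike is detected.
    """
    if ramp is None:
        raise ValueError("ramp metadata (i0, i1, duration) required")
    i0, i1, dur = ramp
    if i1 <= i0 or dur <= 0:
        raise ValueError("ramp command must be increasing")
    spikes = detect_spikes(sweep.time, sweep.value, dvdt_threshold, overshoot)
    if spikes.size == 0:
        return None
    t_spike = sweep.time[spikes[0]]
    return float(i0 + (i1 - i0) * min(t_spike / dur, 1.0))


def ap_threshold_step(
    series: SweepSeries,
    dvdt_threshold: float = 10.0,
    overshoot: float = 0.0,
) -> float | None:
    """Smallest step current (pA) eliciting a spike; None if none does."""
    commands = series.commands
    if np.any(np.diff(commands) <= 0) or commands[0] < 0:
        raise ValueError("step commands must increase strictly from >= 0")
    for s in series.sweeps:
        if detect_spikes(s.time, s.value, dvdt_threshold, overshoot).size:
            return float(s.command)
    return None


def capsaicin_responder(
    time: np.ndarray,
    current: np.ndarray,
    window: tuple[float, float],
    sd_multiple: float = 5.0,
) -> bool:
    """Call a neuron a capsaicin responder from a voltage-clamp trace.

    True iff the mean inward (negative) deflection inside the application
    window exceeds ``sd_multiple`` times the pre-application baseline SD.
    """
    time = np.asarray(time, dtype=float)
    current = np.asarray(current, dtype=float)
    t0, t1 = window
    if t0 < time[0] or t1 > time[-1] or t1 <= t0:
        raise ValueError("application window outside trace")
    pre = current[time < t0]
    if pre.size < 2:
        raise ValueError("no pre-application baseline available")
    base_mean = float(pre.mean())
    base_sd = float(pre.std(ddof=1))
    if base_sd == 0:
        base_sd = 1e-12
    inside = current[(time >= t0) & (time <= t1)]
    inward = -(inside.mean() - base_mean)
    return bool(inward > sd_multiple * base_sd)
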