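"""Pacing to pseudo-steady state and APD90 extraction.

Cells are paced with the model's own square-pulse stimulus using an adaptive
stiff solver (LSODA) with the tolerances used throughout this pipeline
(relative 1e-6, absolute 1e-8, maximum step below the stimulus duration).
Each pace is integrated in two segments split at the stimulus offset, so the
solver never steps across the discontinuity.

Pseudo-steady state is declared when the relative 2-norm change of the full
state vector between successive pace onsets drops below a tolerance
(default 1e-6).  A period-2 (alternans) rhythm prevents convergence by this
criterion; the engine then reports ``converged=False`` together with the final
pace, rather than masking the dynamics.

APD90 is measured on the final pace: baseline is the pre-stimulus potential at
pace onset, the threshold is 90 % of the amplitude below the peak, and the
duration runs from the maximum upstroke velocity to the first downward
threshold crossing (linearly interpolated).  Failure modes are flagged rather
than silently dropped: ``repolarisation_failure`` when the membrane stays
depolarised past the pacing period, ``no_depolarisation`` when the stimulus
fails to elicit an action potential from a polarised cell.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.integrate import odeint

from .ap_models import ModelSpec, ModelState

__all__ = [
    "SolverSettings",
    "SteadyStateResult",
    "APDResult",
    "IntegrationError",
    "integrate_pace",
    "pace_to_steady_state",
    "compute_apd",
    "delta_apd90",
]

# Membrane potentials above this at pace onset mean the previous pace never
# repolarised; used to distinguish a stuck-depolarised cell from a quiescent one.
_DEPOLARISED_BASELINE_MV = -40.0
_MIN_AP_AMPLITUDE_MV = 10.0


class IntegrationError(RuntimeError):
    """Adaptive solve failed (step-size collapse); carries the failure time."""

    def __init__(self, message: str, time: float):
        super().__init__(message)
        self.time = time


@dataclass(frozen=True)
class SolverSettings:
    """Adaptive-solver tolerances.

    ``max_step`` defaults to just below the stimulus duration, honouring the
    solver contract used for these stiff AP systems.
    """

    rel_tol: float = 1e-6
    abs_tol: float = 1e-8
    max_step: Optional[float] = None  # ms; None -> 0.999 x stimulus duration

    def resolve_max_step(self, stim_duration: float) -> float:
        if self.max_step is not None:
            if self.max_step >= stim_duration:
                raise ValueError(
                    f"max_step ({self.max_step} ms) must be below the stimulus "
                    f"duration ({stim_duration} ms)"
                )
            return self.max_step
        return 0.999 * stim_duration


@dataclass
class SteadyStateResult:
    final_state: ModelState
    n_paces: int
    converged: bool
    trace: Optional[tuple] = None  # (t_ms, V_mV) of the final pace
    alternans_suspected: bool = False


@dataclass(frozen=True)
class APDResult:
    apd90: Optional[float] = None
    repolarisation_failure: bool = False
    no_depolarisation: bool = False

    @property
    def flagged(self) -> bool:
        return self.repolarisation_failure or self.no_depolarisation

    @property
    def flag(self) -> Optional[str]:
        if self.repolarisation_failure:
            return "repolarisation_failure"
        if self.no_depolarisation:
            return "no_depolarisation"
        return None


def _segments(duration: float, period: float, sample_dt: Optional[float]):
    if sample_dt is None:
        return [np.array([0.0, duration]), np.array([duration, period])]
    n1 = max(2, int(round(duration / min(sample_dt, duration / 2))) + 1)
    t1 = np.linspace(0.0, duration, n1)
    t2 = np.arange(duration, period + sample_dt / 2, sample_dt)
    if t2[-1] < period:
        t2 = np.append(t2, period)
    return [t1, t2]


def integrate_pace(
    spec: ModelSpec,
    y: np.ndarray,
    settings: SolverSettings,
    sample_dt: Optional[float] = None,
):
    """Integrate one pacing cycle; returns (end state, optional (t, V) trace)."""
    stim = spec.stimulus
    hmax = settings.resolve_max_step(stim.duration)
    ts, vs = [], []
    for seg in _segments(stim.duration, stim.period, sample_dt):
        out, info = odeint(
            spec.rhs, y, seg, args=(spec.params,),
            rtol=settings.rel_tol, atol=settings.abs_tol,
            hmax=min(hmax, 1.0) if seg[0] >= stim.duration else hmax,
            tfirst=True, mxstep=2_000_000, full_output=True,
        )
        if info["message"] != "Integration successful.":
            raise IntegrationError(
                f"solver failure in {spec.name}: {info['message']}",
                time=float(info["tcur"][-1]) if len(info.get("tcur", [])) else float(seg[0]),
            )
        y = out[-1]
        if not np.all(np.isfinite(y)):
            raise IntegrationError(f"non-finite state in {spec.name}", time=float(seg[-1]))
        if sample_dt is not None:
            ts.append(seg)
            vs.append(out[:, spec.v_index])
    trace = None
    if sample_dt is not None:
        t = np.concatenate(ts)
        v = np.concatenate(vs)
        keep = np.concatenate([[True], np.diff(t) > 0])  # drop duplicated segment joins
        trace = (t[keep], v[keep])
    return y, trace


def pace_to_steady_state(
    spec: ModelSpec,
    initial_state: ModelState,
    rate: float = 1.0,
    solver: SolverSettings = SolverSettings(),
    convergence_tol: float = 1e-6,
    max_paces: int = 10_000,
    sample_dt: float = 0.1,
) -> SteadyStateResult:
    """Pace at ``rate`` Hz until the state at successive pace onsets stops changing.

    The final pace is re-run with trace sampling (default 0.1 ms) for APD
    extraction.  Deterministic for fixed inputs.
    """
    if max_paces < 1:
        raise ValueError("max_paces must be >= 1")
    period = 1000.0 / rate
    if abs(period - spec.stimulus.period) > 1e-9:
        spec = spec.with_stimulus(period=period)

    y = np.asarray(initial_state.values, dtype=float).copy()
    converged = False
    deltas = []
    n = 0
    for n in range(1, max_paces + 1):
        y_new, _ = integrate_pace(spec, y, solver)
        denom = np.linalg.norm(y)
        delta = np.linalg.norm(y_new - y) / denom if denom > 0 else np.inf
        deltas.append(delta)
        y = y_new
        if delta < convergence_tol:
            converged = True
            break

    # Alternans heuristic: onset-to-onset change stalls while alternating.
    alternans = False
    if not converged and len(deltas) >= 4:
        tail = deltas[-4:]
        alternans = max(tail) > 100 * convergence_tol and abs(tail[-1] - tail[-3]) < 0.1 * max(tail)
    if not converged and not alternans:
        warnings.warn(
            f"{spec.name}: no steady state within {max_paces} paces "
            f"(last onset change {deltas[-1]:.2e})",
            stacklevel=2,
        )

    y_final, trace = integrate_pace(spec, y, solver, sample_dt=sample_dt)
    return SteadyStateResult(
        final_state=ModelState(values=y_final, time=n * period),
        n_paces=n,
        converged=converged,
        trace=trace,
        alternans_suspected=alternans,
    )


def compute_apd(
    trace: tuple,
    repolarisation_percent: float = 90.0,
    pacing_period: float = 1000.0,
) -> APDResult:
    """Action-potential duration at ``repolarisation_percent`` from one pace."""
    t = np.asarray(trace[0], dtype=float)
    v = np.asarray(trace[1], dtype=float)
    if t.size < 3 or t.size != v.size:
        raise ValueError("trace must be two equal-length arrays covering one pace")
    if np.any(np.diff(t) <= 0):
        raise ValueError("trace times must be strictly increasing")

    baseline = v[0]  # pace onset, pre-stimulus
    if baseline > _DEPOLARISED_BASELINE_MV:
        # the cell entered this pace already depolarised: the preceding pace
        # never repolarised (covers both stuck plateaus and sustained
        # oscillations around depolarised potentials)
        return APDResult(repolarisation_failure=True)
    peak_idx = int(np.argmax(v))
    peak = v[peak_idx]
    amplitude = peak - baseline
    if amplitude < _MIN_AP_AMPLITUDE_MV:
        return APDResult(no_depolarisation=True)

    threshold = peak - (repolarisation_percent / 100.0) * amplitude
    upstroke_idx = int(np.argmax(np.diff(v) / np.diff(t)))
    t_up = t[upstroke_idx]

    after = slice(max(upstroke_idx, peak_idx), None)
    vv = v[after]
    tt = t[after]
    crossings = np.flatnonzero((vv[:-1] >= threshold) & (vv[1:] < threshold))
    if crossings.size == 0:
        return APDResult(repolarisation_failure=True)
    k = crossings[0]
    # linear interpolation between samples
    frac = (threshold - vv[k]) / (vv[k + 1] - vv[k])
    t_cross = tt[k] + frac * (tt[k + 1] - tt[k])
    apd = float(t_cross - t_up)
    if not (0.0 < apd < pacing_period):
        return APDResult(repolarisation_failure=True)
    return APDResult(apd90=apd)


def delta_apd90(apd_drug, apd_control):
    """Drug-minus-control APD90 (ms); failure flags propagate instead of a number."""
    def _unwrap(x):
        if isinstance(x, APDResult):
            if x.flagged:
                return None, x.flag
            return x.apd90, None
        return float(x), None

    d, dflag = _unwrap(apd_drug)
    c, cflag = _unwrap(apd_control)
    if dflag or cflag:
        return dflag or cflag
    return d - c
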