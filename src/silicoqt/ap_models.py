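"""Registry of human ventricular action-potential models with scalable conductances.

Three published myocyte models are available, each transcribed from its
published equation set and verified against a fixed-step reference
integration:

* ``tentusscher2006`` — ten Tusscher & Panfilov (2006), epicardial, 19 states
* ``grandi2010``      — Grandi, Pasqualini & Bers (2010), epicardial, 39 states
* ``ohara2011``       — O'Hara, Virag, Varro & Rudy (2011), endocardial, 41 states

Drug action enters exclusively through :func:`apply_block`, which multiplies
named maximal conductances (IKr, IKs, INa, ICaL, Ito, IK1) by Hill scale
factors in [0, 1].  In the Grandi model the Ito handle scales only the fast
(Kv4.3-like) component, matching what the screen measures; the other two
models have a single Ito conductance.  IK1 is scalable for completeness but no
screening dataset targets it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Mapping

import numpy as np

from . import _grandi, _ohara, _tt06
from .channel_pharm import Channel

__all__ = [
    "Stimulus",
    "ModelSpec",
    "ModelState",
    "ModelNotFoundError",
    "NumericalStateError",
    "MODEL_NAMES",
    "instantiate",
    "apply_block",
    "evaluate_derivatives",
    "model_metadata",
]

_REGISTRY = {m.NAME: m for m in (_tt06, _grandi, _ohara)}
MODEL_NAMES = tuple(_REGISTRY)

BLOCKABLE_CHANNELS = frozenset({"IKr", "IKs", "INa", "ICaL", "Ito", "IK1"})


class ModelNotFoundError(KeyError):
    pass


class NumericalStateError(ValueError):
    pass


@dataclass(frozen=True)
class Stimulus:
    """Square-pulse pacing stimulus (model-native defaults)."""

    amplitude: float  # uA/uF; sign as the model's published definition
    duration: float   # ms
    period: float     # ms


@dataclass(frozen=True)
class ModelSpec:
    """One registered AP model with its (possibly block-scaled) parameters."""

    name: str
    cell_variant: str
    n_state: int
    state_names: tuple
    v_index: int
    params: np.ndarray          # active parameter vector (conductances + stimulus)
    base_params: np.ndarray     # control parameter vector; never mutated
    param_names: tuple
    conductance_handles: Mapping[str, int]
    rhs: Callable
    provenance: str
    gate_indices: tuple = field(default=())

    @property
    def stimulus(self) -> Stimulus:
        names = self.param_names
        return Stimulus(
            amplitude=float(self.params[names.index("stim_amplitude")]),
            duration=float(self.params[names.index("stim_duration")]),
            period=float(self.params[names.index("stim_period")]),
        )

    def with_stimulus(self, amplitude=None, duration=None, period=None) -> "ModelSpec":
        p = self.params.copy()
        names = self.param_names
        if amplitude is not None:
            p[names.index("stim_amplitude")] = amplitude
        if duration is not None:
            p[names.index("stim_duration")] = duration
        if period is not None:
            p[names.index("stim_period")] = period
        return replace(self, params=p)


@dataclass
class ModelState:
    """State-variable vector (mV / dimensionless / mM, model-native) at a time."""

    values: np.ndarray
    time: float = 0.0

    def copy(self) -> "ModelState":
        return ModelState(values=self.values.copy(), time=self.time)


def instantiate(name: str) -> tuple[ModelSpec, ModelState]:
    """Build a registered model at its published parameterisation and
    published initial conditions."""
    if name not in _REGISTRY:
        raise ModelNotFoundError(
            f"unknown model {name!r}; registered models: {', '.join(MODEL_NAMES)}"
        )
    mod = _REGISTRY[name]
    spec = ModelSpec(
        name=mod.NAME,
        cell_variant=mod.CELL_VARIANT,
        n_state=mod.N_STATE,
        state_names=mod.STATE_NAMES,
        v_index=mod.V_INDEX,
        params=mod.P0.copy(),
        base_params=mod.P0.copy(),
        param_names=tuple(mod.PARAM_NAMES),
        conductance_handles=dict(mod.HANDLES),
        rhs=mod.rhs,
        provenance=mod.CITATION,
        gate_indices=mod.GATE_INDICES,
    )
    state = ModelState(values=mod.Y0.copy(), time=0.0)
    return spec, state


def apply_block(spec: ModelSpec, scale_factors: Mapping[str, float]) -> ModelSpec:
    """Scale named maximal conductances: g_j = factor x ḡ_j.

    Factors are applied to the CONTROL (base) conductances, so applying
    factors of 1.0 restores control exactly regardless of prior blocks.
    Channels not mentioned are left at their current values.
    """
    params = spec.params.copy()
    for channel, factor in scale_factors.items():
        key = channel.value if isinstance(channel, Channel) else str(channel)
        if key not in BLOCKABLE_CHANNELS:
            raise ValueError(
                f"unknown channel {key!r}; blockable channels: {sorted(BLOCKABLE_CHANNELS)}"
            )
        if not (0.0 <= factor <= 1.0):
            raise ValueError(f"scale factor for {key} must be in [0, 1], got {factor}")
        idx = spec.conductance_handles[key]
        params[idx] = factor * spec.base_params[idx]
    return replace(spec, params=params)


def evaluate_derivatives(spec: ModelSpec, state: ModelState, t: float | None = None) -> np.ndarray:
    """Right-hand side of the model ODEs at (state, t), stimulus included
    when t mod period falls inside the stimulus pulse."""
    y = np.asarray(state.values, dtype=float)
    if y.shape != (spec.n_state,):
        raise ValueError(f"state has shape {y.shape}, expected ({spec.n_state},)")
    bad = np.flatnonzero(~np.isfinite(y))
    if bad.size:
        names = ", ".join(spec.state_names[i] for i in bad[:5])
        raise NumericalStateError(f"non-finite state variable(s): {names}")
    tt = state.time if t is None else t
    return spec.rhs(tt, y, spec.params)


def model_metadata(name: str) -> dict:
    """Per-model metadata (JSON-serialisable) for the registry interface."""
    spec, _ = instantiate(name)
    return {
        "name": spec.name,
        "cell_variant": spec.cell_variant,
        "n_state": spec.n_state,
        "citation": spec.provenance,
        "conductance_handles": sorted(spec.conductance_handles),
        "stimulus": {
            "amplitude": spec.stimulus.amplitude,
            "duration_ms": spec.stimulus.duration,
            "period_ms": spec.stimulus.period,
        },
    }
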