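"""Concentration sweeps: from pIC50 panels to ΔAPD90–concentration curves.

For each compound x model x screening dataset, the pipeline paces the model
to a control steady state, then walks an ascending 20-point log-spaced
concentration grid (1 nM to 100 µM by default).  At each concentration the
screened channels' maximal conductances are rescaled by the Hill fraction of
unblocked channels and pacing continues from the previous concentration's
steady state (a warm-started ramp, matching the sequential protocol).
APD90 and its change from control are recorded per point; integration
failures and repolarisation failures are flagged, not dropped.

Screening datasets:

* ``Q``   — IonWorks Quattro pIC50s for all five channels.
* ``MQ``  — Quattro panel with the hERG (IKr) pIC50 replaced by the manual
  patch-clamp (GLP) value.
* ``BQ2`` — IonWorks Barracuda for IKr and ICaL plus a second Quattro screen
  for INa and IKs; Kv4.3 was not screened on this platform, so Ito is left
  unblocked (absent data is not a zero pIC50).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .ap_models import ModelSpec, ModelState, apply_block, instantiate
from .channel_pharm import Channel, ChannelAffinity, Source, conductance_scale_factor
from .pacing import (
    APDResult,
    IntegrationError,
    SolverSettings,
    compute_apd,
    delta_apd90,
    pace_to_steady_state,
)

__all__ = [
    "Dataset",
    "ConcentrationGrid",
    "CurvePoint",
    "DoseResponseCurve",
    "MissingAffinityError",
    "make_grid",
    "assemble_scale_factors",
    "run_sweep",
    "interpolate_delta",
]


class Dataset(str, enum.Enum):
    Q = "Q"
    BQ2 = "BQ2"
    MQ = "MQ"


class MissingAffinityError(KeyError):
    pass


@dataclass(frozen=True)
class ConcentrationGrid:
    points: tuple  # µM, ascending

    def __post_init__(self):
        pts = tuple(float(c) for c in self.points)
        if len(pts) < 1 or any(c <= 0 for c in pts) or list(pts) != sorted(pts):
            raise ValueError("grid must be ascending, strictly positive concentrations")
        object.__setattr__(self, "points", pts)


def make_grid(c_min: float = 1e-3, c_max: float = 1e2, n: int = 20) -> ConcentrationGrid:
    """n log10-equally-spaced concentrations, endpoints included (µM)."""
    if not (c_max > c_min > 0):
        raise ValueError(f"need c_max > c_min > 0, got [{c_min}, {c_max}]")
    if n < 2:
        raise ValueError("grid needs at least 2 points")
    return ConcentrationGrid(tuple(np.logspace(np.log10(c_min), np.log10(c_max), n)))


# Which (channel, source) pairs each dataset draws on.
_DATASET_SOURCES: dict[Dataset, dict[Channel, Source]] = {
    Dataset.Q: {
        Channel.IKr: Source.Q, Channel.ICaL: Source.Q, Channel.INa: Source.Q,
        Channel.IKs: Source.Q, Channel.Ito: Source.Q,
    },
    Dataset.MQ: {
        Channel.IKr: Source.M, Channel.ICaL: Source.Q, Channel.INa: Source.Q,
        Channel.IKs: Source.Q, Channel.Ito: Source.Q,
    },
    Dataset.BQ2: {
        Channel.IKr: Source.B, Channel.ICaL: Source.B,
        Channel.INa: Source.Q2, Channel.IKs: Source.Q2,
        # Ito deliberately absent: no Barracuda Kv4.3 screen
    },
}


def dataset_pic50s(
    affinities: Iterable[ChannelAffinity], dataset: Dataset | str
) -> dict[Channel, float]:
    """Select the per-channel pIC50s a dataset prescribes for one compound."""
    dataset = Dataset(dataset)
    by_key = {(a.channel, a.source): a for a in affinities}
    compounds = {a.compound_id for a in by_key.values()}
    if len(compounds) > 1:
        raise ValueError(f"affinities span multiple compounds: {sorted(compounds)}")
    out: dict[Channel, float] = {}
    for channel, source in _DATASET_SOURCES[dataset].items():
        aff = by_key.get((channel, source))
        if aff is None:
            cid = next(iter(compounds)) if compounds else "?"
            raise MissingAffinityError(
                f"compound {cid!r}: dataset {dataset.value} requires a "
                f"{channel.value} pIC50 from source {source.value}, none available"
            )
        out[channel] = aff.pic50
    return out


def assemble_scale_factors(
    affinities: Iterable[ChannelAffinity],
    dataset: Dataset | str,
    concentration: float,
) -> dict[str, float]:
    """Per-channel conductance scale factors at one concentration (µM)."""
    pic50s = dataset_pic50s(affinities, dataset)
    return {
        ch.value: conductance_scale_factor(concentration, pic50)
        for ch, pic50 in pic50s.items()
    }


@dataclass(frozen=True)
class CurvePoint:
    concentration: float        # µM
    apd90: Optional[float]      # ms, None when flagged
    delta_apd90: Optional[float]
    flag: Optional[str] = None  # repolarisation_failure / no_depolarisation / integration_error

    @property
    def numeric(self) -> bool:
        return self.flag is None


@dataclass
class DoseResponseCurve:
    compound_id: str
    model: str
    dataset: str
    control_apd90: float
    points: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "compound": self.compound_id,
                "model": self.model,
                "dataset": self.dataset,
                "concentration_uM": [p.concentration for p in self.points],
                "apd90_ms": [p.apd90 for p in self.points],
                "delta_apd90_ms": [p.delta_apd90 for p in self.points],
                "flag": [p.flag or "" for p in self.points],
            }
        )


def run_sweep(
    affinities: Iterable[ChannelAffinity],
    model: str | ModelSpec,
    dataset: Dataset | str,
    grid: Optional[ConcentrationGrid] = None,
    solver: SolverSettings = SolverSettings(),
    convergence_tol: float = 1e-6,
    max_paces: int = 10_000,
    control_state: Optional[ModelState] = None,
    compound_id: Optional[str] = None,
) -> DoseResponseCurve:
    """Warm-started ascending concentration sweep; deterministic.

    ``control_state`` may carry a pre-converged control steady state to avoid
    re-pacing from the published initial conditions (the control pace is still
    run to convergence from whatever state is supplied).
    """
    affinities = list(affinities)
    dataset = Dataset(dataset)
    grid = grid or make_grid()
    if isinstance(model, ModelSpec):
        spec = model
        if control_state is None:
            _, state = instantiate(spec.name)
        else:
            state = control_state
    else:
        spec, state = instantiate(model)
        if control_state is not None:
            state = control_state
    cid = compound_id or (affinities[0].compound_id if affinities else "?")
    pic50s = dataset_pic50s(affinities, dataset)  # validate once up front

    control = pace_to_steady_state(
        spec, state, solver=solver, convergence_tol=convergence_tol, max_paces=max_paces
    )
    control_apd = compute_apd(control.trace, pacing_period=spec.stimulus.period)
    if control_apd.flagged:
        raise RuntimeError(f"{spec.name} control pace flagged: {control_apd.flag}")

    curve = DoseResponseCurve(
        compound_id=cid, model=spec.name, dataset=dataset.value,
        control_apd90=control_apd.apd90,
    )
    y = control.final_state
    for conc in grid.points:
        factors = {
            ch.value: conductance_scale_factor(conc, p) for ch, p in pic50s.items()
        }
        blocked = apply_block(spec, factors)
        try:
            result = pace_to_steady_state(
                blocked, y, solver=solver,
                convergence_tol=convergence_tol, max_paces=max_paces,
            )
        except IntegrationError:
            curve.points.append(CurvePoint(conc, None, None, "integration_error"))
            continue
        y = result.final_state  # warm start the next concentration
        apd = compute_apd(result.trace, pacing_period=blocked.stimulus.period)
        if apd.flagged:
            curve.points.append(CurvePoint(conc, None, None, apd.flag))
        else:
            curve.points.append(
                CurvePoint(conc, apd.apd90, delta_apd90(apd, control_apd))
            )
    return curve


def interpolate_delta(curve: DoseResponseCurve, concentration: float):
    """ΔAPD90 at an arbitrary concentration by linear interpolation in log10 C.

    Clamps below/above the grid to the first/last point.  If either bracketing
    point is flagged, the flag string is returned instead of a number.
    """
    if not curve.points:
        raise ValueError("curve has no points")
    if concentration <= 0:
        raise ValueError("concentration must be > 0")
    pts = curve.points
    if concentration <= pts[0].concentration:
        return pts[0].delta_apd90 if pts[0].numeric else pts[0].flag
    if concentration >= pts[-1].concentration:
        return pts[-1].delta_apd90 if pts[-1].numeric else pts[-1].flag
    logc = np.log10(concentration)
    for lo, hi in zip(pts[:-1], pts[1:]):
        if lo.concentration <= concentration <= hi.concentration:
            if not lo.numeric:
                return lo.flag
            if not hi.numeric:
                return hi.flag
            x0, x1 = np.log10(lo.concentration), np.log10(hi.concentration)
            w = (logc - x0) / (x1 - x0)
            return float((1 - w) * lo.delta_apd90 + w * hi.delta_apd90)
    raise AssertionError("unreachable: grid ordering violated")
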