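"""Hill-curve pharmacology for ion-channel screening data.

Concentration–effect relationships from patch-clamp screens are summarised by
the Hill function with the coefficient fixed at one, so a single parameter —
the pIC50 (−log10 of the IC50 in molar) — captures a compound's potency at a
channel.  The same Hill fraction that describes the proportion of peak current
remaining also scales a model channel's maximal conductance under the
quasi-steady-state conductance-block approximation.

Units: concentrations are micromolar throughout the pipeline; pIC50 values are
on the molar scale (as screening platforms report them) and are converted at
the boundary by :func:`pic50_to_ic50_micromolar`.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import minimize_scalar

__all__ = [
    "Channel",
    "Source",
    "ConcentrationEffectPoint",
    "HillFit",
    "ChannelAffinity",
    "hill_fraction_remaining",
    "pic50_to_ic50_micromolar",
    "conductance_scale_factor",
    "fit_hill",
]


class Channel(str, enum.Enum):
    """Screened cardiac currents and the genes used to probe them."""

    IKr = "IKr"    # hERG
    IKs = "IKs"    # KCNQ1/MinK
    INa = "INa"    # NaV1.5
    ICaL = "ICaL"  # CaV1.2
    Ito = "Ito"    # Kv4.3/KChIP2.2
    IK1 = "IK1"    # not screened; scalable handle only


class Source(str, enum.Enum):
    """Assay platform / data source for a pIC50."""

    Q = "Q"    # IonWorks Quattro
    B = "B"    # IonWorks Barracuda
    Q2 = "Q2"  # second, independent Quattro screen
    M = "M"    # manual patch clamp (GLP regulatory submissions; hERG only)


@dataclass(frozen=True)
class ConcentrationEffectPoint:
    """One screening observation: fraction of peak current remaining at a dose."""

    concentration: float  # µM, strictly positive
    fraction_remaining: float  # dimensionless, clipped to [0, 1]

    def __post_init__(self) -> None:
        if not (self.concentration > 0) or not math.isfinite(self.concentration):
            raise ValueError(f"concentration must be finite and > 0, got {self.concentration}")
        object.__setattr__(
            self, "fraction_remaining", float(min(1.0, max(0.0, self.fraction_remaining)))
        )


@dataclass(frozen=True)
class HillFit:
    """Result of a one-parameter (n = 1) Hill fit.

    ``floored`` marks fits where the optimal pIC50 was ≤ 0 and has been
    replaced by exactly 0 — the convention for compounds with no measurable
    effect, which still enter simulations (0.01 % block at 100 µM).
    ``low_confidence`` marks single-point fits.
    """

    pic50: float
    hill_coefficient: float = 1.0
    floored: bool = False
    residual_sse: float = 0.0
    low_confidence: bool = False

    def __post_init__(self) -> None:
        if self.hill_coefficient != 1.0:
            raise ValueError("Hill coefficient is fixed at 1 in this pipeline")
        if not math.isfinite(self.pic50):
            raise ValueError("fitted pIC50 must be finite")
        if self.floored and self.pic50 != 0.0:
            raise ValueError("a floored fit must carry pic50 == 0")


@dataclass(frozen=True)
class ChannelAffinity:
    """A compound's potency at one channel from one assay source."""

    compound_id: str
    channel: Channel
    source: Source
    pic50: float  # −log10 molar, ≥ 0 by the flooring convention

    def __post_init__(self) -> None:
        if self.source is Source.M and self.channel is not Channel.IKr:
            raise ValueError("manual patch data exist only for hERG (IKr)")
        if self.channel is Channel.IK1:
            raise ValueError("IK1 is never screened; no affinity may target it")
        if not math.isfinite(self.pic50) or self.pic50 < 0:
            raise ValueError(f"pIC50 must be finite and ≥ 0 (floored), got {self.pic50}")


def pic50_to_ic50_micromolar(pic50: float) -> float:
    """Convert a molar-scale pIC50 to an IC50 in µM: 10**(6 − pIC50)."""
    if not math.isfinite(pic50):
        raise ValueError(f"pIC50 must be finite, got {pic50}")
    return 10.0 ** (6.0 - pic50)


def hill_fraction_remaining(concentration, pic50: float, n: float = 1.0):
    """Fraction of current remaining, ``(1 + (C/IC50)**n)**-1``.

    Accepts scalar or array concentrations (µM).  Returns 1 at C = 0 and is
    strictly decreasing in C, approaching 0 as C → ∞.
    """
    if n <= 0:
        raise ValueError(f"Hill coefficient must be > 0, got {n}")
    conc = np.asarray(concentration, dtype=float)
    if np.any(conc < 0) or not np.all(np.isfinite(conc)):
        raise ValueError("concentration must be finite and ≥ 0")
    ic50 = pic50_to_ic50_micromolar(pic50)
    out = 1.0 / (1.0 + (conc / ic50) ** n)
    if np.isscalar(concentration) or np.ndim(concentration) == 0:
        return float(out)
    return out


# Eq. for the blocked conductance: g_j = hill_fraction * ḡ_j.  The scale
# factor is literally the same Hill fraction; the alias keeps the pharmacology
# and the conductance-scaling call sites self-describing.
conductance_scale_factor = hill_fraction_remaining


def _sse(pic50: float, conc: np.ndarray, frac: np.ndarray) -> float:
    pred = 1.0 / (1.0 + conc * 10.0 ** (pic50 - 6.0))
    return float(np.sum((pred - frac) ** 2))


# Fixed multi-start grid for the one-parameter optimisation: reproducible and
# immune to the local minima a single start can hit on noisy screens.
_START_GRID = tuple(float(p) for p in range(0, 13))


def fit_hill(points: Iterable[ConcentrationEffectPoint] | Sequence) -> HillFit:
    """Least-squares fit of the n = 1 Hill curve to concentration–effect points.

    Ordinary least squares on the (clipped) fraction remaining.  Deterministic:
    bounded scalar minimisation started from a fixed grid of 13 initial pIC50s
    spanning 0–12; the best SSE wins, ties broken toward the smaller pIC50.
    Fits with an optimal pIC50 ≤ 0 are floored to exactly 0.  Single-point
    inputs are permitted but flagged ``low_confidence``.
    """
    pts = [
        p if isinstance(p, ConcentrationEffectPoint) else ConcentrationEffectPoint(*p)
        for p in points
    ]
    if not pts:
        raise ValueError("fit_hill requires at least one concentration-effect point")
    conc = np.array([p.concentration for p in pts])
    frac = np.array([p.fraction_remaining for p in pts])
    low_confidence = len(set(conc.tolist())) < 2

    best_pic50, best_sse = None, np.inf
    for start in _START_GRID:
        lo, hi = max(-6.0, start - 1.0), min(14.0, start + 1.0)
        res = minimize_scalar(
            _sse, bounds=(-6.0, 14.0), args=(conc, frac), method="bounded",
            options={"xatol": 1e-10},
        )
        # bounded Brent ignores the start; refine with a local bracket around
        # the grid point as well so plateaus at the boundary are explored.
        cand = [(res.x, res.fun)]
        res2 = minimize_scalar(
            _sse, bounds=(lo, hi), args=(conc, frac), method="bounded",
            options={"xatol": 1e-10},
        )
        cand.append((res2.x, res2.fun))
        for x, f in cand:
            if f < best_sse - 1e-15 or (abs(f - best_sse) <= 1e-15 and (best_pic50 is None or x < best_pic50)):
                best_pic50, best_sse = float(x), float(f)

    if best_pic50 <= 0.0:
        return HillFit(pic50=0.0, floored=True, residual_sse=_sse(0.0, conc, frac),
                       low_confidence=low_confidence)
    return HillFit(pic50=best_pic50, residual_sse=best_sse, low_confidence=low_confidence)
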