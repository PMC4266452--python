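"""Evaluation of simulated ΔAPD90 against Thorough QT (TQT) study outcomes.

A TQT study reports the mean change in heart-rate-corrected QT (ΔQTc) at the
highest dose tested, together with the peak plasma concentration (Cmax),
plasma protein binding and molecular weight.  The free (unbound) molar plasma
concentration is

    free_conc [µM] = (Cmax [ng/mL] / MW [g/mol]) x (1 − %bound/100)

(1 ng/mL = 1 µg/L, so dividing by g/mol gives µmol/L directly).

A simulation "predicts prolongation" when the interpolated ΔAPD90 reaches the
5 ms regulatory cut-off somewhere inside a fold-change window around that
concentration: window = [free_conc/fold, free_conc x fold], intersected with
the simulated grid.  fold = 1 is the point evaluation at the estimated TQT
concentration; wider windows express uncertainty in the exposure estimate.
The window rule is symmetric — it is applied identically to compounds with
and without observed prolongation, so widening the window can create false
positives as well as recover false negatives.

Observed positive means ΔQTc ≥ 5 ms (inclusive).  Counts are tallied into a
2x2 contingency table; sensitivity, specificity and accuracy are computed in
exact rational arithmetic and rendered as percentages.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .dose_response import DoseResponseCurve, interpolate_delta

__all__ = [
    "TQTRecord",
    "ContingencyTable",
    "free_plasma_concentration",
    "classify",
    "build_contingency",
    "summary_table",
    "QT_THRESHOLD_MS",
]

QT_THRESHOLD_MS = 5.0


def free_plasma_concentration(
    cmax: float, percent_bound: float, molecular_weight: float
) -> float:
    """Free plasma concentration in µM from Cmax (ng/mL), % bound, MW (g/mol)."""
    if molecular_weight <= 0:
        raise ValueError(f"molecular weight must be > 0, got {molecular_weight}")
    if cmax < 0:
        raise ValueError(f"Cmax must be >= 0, got {cmax}")
    if not (0.0 <= percent_bound <= 100.0):
        raise ValueError(f"percent bound must be in [0, 100], got {percent_bound}")
    return (cmax / molecular_weight) * (1.0 - percent_bound / 100.0)


@dataclass(frozen=True)
class TQTRecord:
    """Clinical comparator for one compound at the highest TQT dose."""

    compound_id: str
    cmax: float             # ng/mL
    percent_bound: float    # %
    molecular_weight: float  # g/mol
    delta_qtc: float        # ms, mean change at highest dose

    def __post_init__(self):
        if not np.isfinite(self.delta_qtc):
            raise ValueError("delta_qtc must be finite")
        # validates the exposure fields as a side effect
        free_plasma_concentration(self.cmax, self.percent_bound, self.molecular_weight)

    @property
    def free_conc(self) -> float:
        """Estimated free plasma concentration (µM)."""
        return free_plasma_concentration(
            self.cmax, self.percent_bound, self.molecular_weight
        )

    @property
    def observed_positive(self) -> bool:
        return self.delta_qtc >= QT_THRESHOLD_MS


def classify(
    curve: DoseResponseCurve,
    tqt_conc: float,
    fold_window: float = 1.0,
    threshold: float = QT_THRESHOLD_MS,
) -> bool:
    """Does the curve predict ≥ threshold ms prolongation within the window?

    The window [tqt_conc/fold, tqt_conc x fold] is intersected with the
    simulated concentration range; the prediction is positive when the maximum
    interpolated ΔAPD90 over that window reaches the threshold (inclusive).
    Flagged points (repolarisation failure) inside the window count as
    positive.  A window entirely outside the grid is clamped to the nearest
    grid point with a warning.
    """
    if tqt_conc <= 0:
        raise ValueError("tqt_conc must be > 0")
    if fold_window < 1:
        raise ValueError("fold_window must be >= 1")
    if not curve.points:
        raise ValueError("curve has no points")

    gmin = curve.points[0].concentration
    gmax = curve.points[-1].concentration
    lo = tqt_conc / fold_window
    hi = tqt_conc * fold_window
    if hi < gmin or lo > gmax:
        nearest = gmin if hi < gmin else gmax
        warnings.warn(
            f"{curve.compound_id}: evaluation window [{lo:.3g}, {hi:.3g}] µM lies "
            f"outside the simulated grid [{gmin:.3g}, {gmax:.3g}] µM; "
            f"classifying at the nearest grid point",
            stacklevel=2,
        )
        lo = hi = nearest
    lo = max(lo, gmin)
    hi = min(hi, gmax)

    candidates = [lo, hi] + [
        p.concentration for p in curve.points if lo <= p.concentration <= hi
    ]
    best = -np.inf
    for conc in candidates:
        val = interpolate_delta(curve, conc)
        if isinstance(val, str):  # failure flag counts as prolongation
            return True
        best = max(best, val)
    return best >= threshold


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 counts of simulated vs observed ≥ 5 ms prolongation."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def sensitivity(self) -> Optional[Fraction]:
        d = self.tp + self.fn
        return Fraction(100 * self.tp, d) if d else None

    @property
    def specificity(self) -> Optional[Fraction]:
        d = self.tn + self.fp
        return Fraction(100 * self.tn, d) if d else None

    @property
    def accuracy(self) -> Optional[Fraction]:
        return Fraction(100 * (self.tp + self.tn), self.total) if self.total else None

    def metrics_percent(self, ndigits: int = 0) -> dict:
        """Rounded percentage metrics; undefined metrics render as None."""
        out = {}
        for name in ("sensitivity", "specificity", "accuracy"):
            v = getattr(self, name)
            out[name] = None if v is None else round(float(v), ndigits)
        return out

    def __str__(self) -> str:
        m = self.metrics_percent()
        fmt = lambda v: "undefined" if v is None else f"{v:.0f}%"
        return (
            f"              observed +   observed -\n"
            f" predicted +  {self.tp:10d}   {self.fp:10d}\n"
            f" predicted -  {self.fn:10d}   {self.tn:10d}\n"
            f" sensitivity {fmt(m['sensitivity'])}, specificity {fmt(m['specificity'])}, "
            f"accuracy {fmt(m['accuracy'])}"
        )


def build_contingency(
    records: Iterable[tuple],
    threshold: float = QT_THRESHOLD_MS,
) -> ContingencyTable:
    """Tally (predicted_positive: bool, observed ΔQTc: ms) pairs."""
    records = list(records)
    if not records:
        raise ValueError("need at least one record")
    tp = fp = tn = fn = 0
    for predicted, dqtc in records:
        observed = dqtc >= threshold
        if predicted and observed:
            tp += 1
        elif predicted and not observed:
            fp += 1
        elif not predicted and observed:
            fn += 1
        else:
            tn += 1
    return ContingencyTable(tp=tp, fp=fp, tn=tn, fn=fn)


def summary_table(
    curves: Mapping,
    tqt_records: Sequence[TQTRecord],
    fold_windows: Sequence[float] = (1.0, 10.0, 100.0),
    threshold: float = QT_THRESHOLD_MS,
) -> pd.DataFrame:
    """Metrics grid over model x dataset x fold-window combinations.

    ``curves`` maps (model, dataset, compound_id) -> DoseResponseCurve.
    Combinations with no curve for a compound mark that compound unavailable
    and exclude it from that cell's counts.
    """
    combos = sorted({(m, d) for (m, d, _) in curves})
    rows = []
    for model, dataset in combos:
        for fold in fold_windows:
            pairs = []
            n_missing = 0
            for rec in tqt_records:
                curve = curves.get((model, dataset, rec.compound_id))
                if curve is None:
                    n_missing += 1
                    continue
                pairs.append(
                    (classify(curve, rec.free_conc, fold, threshold), rec.delta_qtc)
                )
            if not pairs:
                rows.append({
                    "model": model, "dataset": dataset, "fold_window": fold,
                    "n": 0, "n_missing": n_missing,
                    "sensitivity": None, "specificity": None, "accuracy": None,
                })
                continue
            table = build_contingency(pairs, threshold)
            m = table.metrics_percent(ndigits=1)
            rows.append({
                "model": model, "dataset": dataset, "fold_window": fold,
                "n": table.total, "n_missing": n_missing,
                "tp": table.tp, "fp": table.fp, "tn": table.tn, "fn": table.fn,
                **m,
            })
    return pd.DataFrame(rows)
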