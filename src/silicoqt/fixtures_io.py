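"""Bundled screening data and synthetic-data generators.

The package ships the 34-compound multi-channel pIC50 panel (Quattro,
Barracuda, second-Quattro and manual-patch hERG sources) as a long-format CSV.
Synthetic generators emulate the two upstream inputs that are not bundled:
raw concentration–effect screen output (for exercising the Hill fitter) and
TQT study exposure/outcome records (Cmax, protein binding, molecular weight,
ΔQTc), the latter with generating-truth labels retained so contingency counts
can be recomputed exactly in tests.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .channel_pharm import (
    Channel,
    ChannelAffinity,
    ConcentrationEffectPoint,
    Source,
    hill_fraction_remaining,
)
from .tqt_eval import TQTRecord, free_plasma_concentration

__all__ = [
    "PIC50Table",
    "SyntheticTQTCohort",
    "load_pic50_table",
    "generate_concentration_effect",
    "generate_synthetic_tqt",
]

_SCHEMA = ["compound_id", "display_name", "channel", "source", "pic50"]


@dataclass
class PIC50Table:
    """The screening panel: rows of ChannelAffinity plus display names.

    Absent cells (un-screened compound/channel/platform combinations) are kept
    as explicit rows with a missing pIC50.
    """

    frame: pd.DataFrame  # columns: compound_id, display_name, channel, source, pic50

    @property
    def compounds(self) -> list:
        return sorted(self.frame["compound_id"].unique())

    def affinities(self, compound_id: str) -> list:
        sub = self.frame[
            (self.frame["compound_id"] == compound_id) & self.frame["pic50"].notna()
        ]
        if sub.empty and compound_id not in set(self.frame["compound_id"]):
            raise KeyError(f"unknown compound {compound_id!r}")
        return [
            ChannelAffinity(
                compound_id=row.compound_id,
                channel=Channel(row.channel),
                source=Source(row.source),
                pic50=float(row.pic50),
            )
            for row in sub.itertuples()
        ]

    def write_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)


def _bundled_path() -> Path:
    return Path(importlib.resources.files("silicoqt") / "data" / "pic50_panel.csv")


def load_pic50_table(path=None) -> PIC50Table:
    """Load the bundled panel, or a CSV with the same schema.

    Numeric zeros are kept as 0.0 (floored fits); empty cells parse as absent.
    Malformed numerics raise with the offending row and column named.
    """
    src = Path(path) if path is not None else _bundled_path()
    frame = pd.read_csv(src, comment="#", dtype={c: str for c in _SCHEMA})
    missing_cols = [c for c in _SCHEMA if c not in frame.columns]
    if missing_cols:
        raise ValueError(f"{src}: missing columns {missing_cols}")
    pic50 = []
    for i, raw in enumerate(frame["pic50"]):
        if raw is None or (isinstance(raw, float) and np.isnan(raw)) or str(raw).strip() == "":
            pic50.append(np.nan)
            continue
        try:
            val = float(raw)
        except ValueError:
            row = frame.iloc[i]
            raise ValueError(
                f"{src}: malformed pIC50 {raw!r} at row {i + 2} "
                f"({row['compound_id']}/{row['channel']}/{row['source']})"
            ) from None
        if val < 0:
            row = frame.iloc[i]
            raise ValueError(
                f"{src}: negative pIC50 {val} at row {i + 2} "
                f"({row['compound_id']}/{row['channel']}/{row['source']}); "
                "fits <= 0 are stored as 0.0"
            )
        pic50.append(val)
    frame = frame.assign(pic50=pic50)
    for col, allowed in (("channel", {c.value for c in Channel}),
                         ("source", {s.value for s in Source})):
        bad = set(frame[col].unique()) - allowed
        if bad:
            raise ValueError(f"{src}: unknown {col} value(s) {sorted(bad)}")
    return PIC50Table(frame=frame)


def generate_concentration_effect(
    pic50: float,
    n: float = 1.0,
    noise_sd: float = 0.02,
    n_points: int = 8,
    c_range: tuple = (1e-3, 1e2),
    seed: int = 0,
) -> list:
    """Synthetic screen output: log-spaced doses with Gaussian response noise.

    Fractions are the Hill value plus Normal(0, noise_sd), clipped to [0, 1].
    """
    if n_points < 1:
        raise ValueError("n_points must be >= 1")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    lo, hi = c_range
    if not (hi > lo > 0):
        raise ValueError(f"invalid concentration range {c_range}")
    conc = np.logspace(np.log10(lo), np.log10(hi), n_points)
    rng = np.random.default_rng(seed)
    frac = hill_fraction_remaining(conc, pic50, n) + rng.normal(0.0, noise_sd, n_points)
    frac = np.clip(frac, 0.0, 1.0)
    return [ConcentrationEffectPoint(c, f) for c, f in zip(conc, frac)]


@dataclass
class SyntheticTQTCohort:
    """Generated TQT records plus the generating truth for each compound."""

    records: list          # TQTRecord
    truth: pd.DataFrame    # compound_id, true_effect_ms, observed_positive

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "compound_id": [r.compound_id for r in self.records],
                "cmax_ng_per_ml": [r.cmax for r in self.records],
                "percent_bound": [r.percent_bound for r in self.records],
                "molecular_weight": [r.molecular_weight for r in self.records],
                "delta_qtc_ms": [r.delta_qtc for r in self.records],
                "free_conc_uM": [r.free_conc for r in self.records],
            }
        )


def generate_synthetic_tqt(
    n_compounds: int,
    effect_model: str = "null",
    seed: int = 0,
    herg_pic50s: Optional[np.ndarray] = None,
    max_effect_ms: float = 20.0,
    noise_sd_ms: float = 2.0,
) -> SyntheticTQTCohort:
    """Emulated TQT exposure spreadsheet with known generating truth.

    Exposure covariates follow plausible small-molecule ranges: molecular
    weight uniform on [200, 700] g/mol, Cmax log-uniform on [10, 10^4] ng/mL,
    protein binding uniform on [0, 99] %.

    effect_model:
      * ``"null"`` — no true effect; ΔQTc ~ Normal(0, noise_sd_ms).
      * ``"herg"`` — ΔQTc = max_effect_ms x hERG block fraction at the free
        Cmax (per a supplied or drawn hERG pIC50) + Normal(0, noise_sd_ms).
    """
    if n_compounds < 1:
        raise ValueError("n_compounds must be >= 1")
    if effect_model not in ("null", "herg"):
        raise ValueError(f"unknown effect_model {effect_model!r}")
    rng = np.random.default_rng(seed)
    mw = rng.uniform(200.0, 700.0, n_compounds)
    cmax = 10.0 ** rng.uniform(1.0, 4.0, n_compounds)
    bound = rng.uniform(0.0, 99.0, n_compounds)
    if effect_model == "herg":
        pic50 = (
            np.asarray(herg_pic50s, dtype=float)
            if herg_pic50s is not None
            else rng.uniform(4.0, 8.0, n_compounds)
        )
        if pic50.shape != (n_compounds,):
            raise ValueError("herg_pic50s must have length n_compounds")
    records = []
    truth_rows = []
    for i in range(n_compounds):
        cid = f"synth{i:03d}"
        free = free_plasma_concentration(cmax[i], bound[i], mw[i])
        if effect_model == "null":
            true_effect = 0.0
        else:
            block = 1.0 - hill_fraction_remaining(free, pic50[i])
            true_effect = max_effect_ms * block
        dqtc = true_effect + rng.normal(0.0, noise_sd_ms)
        records.append(
            TQTRecord(
                compound_id=cid, cmax=float(cmax[i]), percent_bound=float(bound[i]),
                molecular_weight=float(mw[i]), delta_qtc=float(dqtc),
            )
        )
        truth_rows.append(
            {"compound_id": cid, "true_effect_ms": true_effect,
             "observed_positive": dqtc >= 5.0}
        )
    return SyntheticTQTCohort(records=records, truth=pd.DataFrame(truth_rows))
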