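"""Propagation of ion-channel assay variability into ΔAPD90 credible bands.

Screening pIC50s are uncertain: control-assay repeats on the same platform
scatter by a few tenths of a log unit.  To carry that uncertainty through the
simulation, each channel's observed pIC50 is perturbed independently as
Normal(pIC50_obs, σ(channel, source)), the concentration sweep is re-run for
every draw, and per-concentration 2.5th/97.5th percentiles of the sampled
ΔAPD90 values form a 95 % credible band around the point-estimate curve.
Draws whose pace fails to repolarise are counted separately
(``fraction_failed``) rather than entering the percentiles.

σ values are data, not code: they default to 0.2 log10 units per channel and
platform and should be replaced by measured control-assay variability where
available.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .channel_pharm import Channel, ChannelAffinity, Source
from .dose_response import (
    ConcentrationGrid,
    Dataset,
    DoseResponseCurve,
    make_grid,
    run_sweep,
)
from .pacing import SolverSettings

__all__ = ["AssayVariability", "CredibleBand", "sample_pic50s", "credible_band"]

DEFAULT_SIGMA = 0.2  # log10-molar units


@dataclass(frozen=True)
class AssayVariability:
    """Per-(channel, source) standard deviation of pIC50 (log10-molar units)."""

    sigma_pic50: Mapping = field(default_factory=dict)  # (Channel, Source) -> σ
    default_sigma: float = DEFAULT_SIGMA

    def __post_init__(self):
        for key, s in self.sigma_pic50.items():
            if s < 0:
                raise ValueError(f"negative σ for {key}: {s}")
        if self.default_sigma < 0:
            raise ValueError("negative default σ")

    def sigma(self, channel: Channel, source: Source) -> float:
        return float(self.sigma_pic50.get((channel, source), self.default_sigma))


@dataclass
class CredibleBand:
    concentrations: np.ndarray   # µM
    lower: np.ndarray            # ms; NaN where undefined
    upper: np.ndarray            # ms
    fraction_failed: np.ndarray  # per concentration, in [0, 1]
    level: float
    n_samples: int
    seed: int


def sample_pic50s(
    affinities: Sequence[ChannelAffinity],
    variability: AssayVariability,
    n_samples: int,
    seed: int,
) -> list:
    """n_samples independently perturbed affinity sets (floored at pIC50 = 0).

    Deterministic given the seed; the draw matrix is generated in one pass so
    results do not depend on evaluation order.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    affinities = list(affinities)
    sigmas = np.array([variability.sigma(a.channel, a.source) for a in affinities])
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal((n_samples, len(affinities))) * sigmas
    draws = []
    for row in noise:
        draws.append([
            ChannelAffinity(a.compound_id, a.channel, a.source,
                            max(0.0, a.pic50 + eps))
            for a, eps in zip(affinities, row)
        ])
    return draws


def credible_band(
    affinities: Sequence[ChannelAffinity],
    model: str,
    dataset: Dataset | str,
    grid: Optional[ConcentrationGrid] = None,
    variability: AssayVariability = AssayVariability(),
    n_samples: int = 500,
    seed: int = 0,
    level: float = 95.0,
    solver: SolverSettings = SolverSettings(),
    convergence_tol: float = 1e-6,
    max_paces: int = 10_000,
) -> tuple[DoseResponseCurve, CredibleBand]:
    """Point-estimate curve plus the empirical credible band over pIC50 draws."""
    if n_samples < 2:
        raise ValueError("a band needs n_samples >= 2")
    grid = grid or make_grid()
    kwargs = dict(
        model=model, dataset=dataset, grid=grid, solver=solver,
        convergence_tol=convergence_tol, max_paces=max_paces,
    )
    point = run_sweep(affinities, **kwargs)

    n_conc = len(grid.points)
    samples = np.full((n_samples, n_conc), np.nan)
    failed = np.zeros((n_samples, n_conc), dtype=bool)
    for i, draw in enumerate(sample_pic50s(affinities, variability, n_samples, seed)):
        curve = run_sweep(draw, **kwargs)
        for k, pt in enumerate(curve.points):
            if pt.numeric:
                samples[i, k] = pt.delta_apd90
            else:
                failed[i, k] = True

    alpha = (100.0 - level) / 2.0
    lower = np.full(n_conc, np.nan)
    upper = np.full(n_conc, np.nan)
    for k in range(n_conc):
        vals = samples[~failed[:, k], k]
        vals = vals[np.isfinite(vals)]
        if vals.size:
            lower[k] = np.percentile(vals, alpha)       # linear-interpolated
            upper[k] = np.percentile(vals, 100 - alpha)
    band = CredibleBand(
        concentrations=np.array(grid.points),
        lower=lower,
        upper=upper,
        fraction_failed=failed.mean(axis=0),
        level=level,
        n_samples=n_samples,
        seed=seed,
    )
    return point, band
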