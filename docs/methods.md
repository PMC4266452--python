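# Methods

## Scope and model

`silicoqt` predicts whether a drug will prolong the human ventricular action
potential — the cellular surrogate for QTc prolongation at 1 Hz pacing — from
multi-ion-channel screening data, and evaluates those predictions against
Thorough QT (TQT) study outcomes.

The pipeline is:

1. **Screen summarisation.** Concentration–effect points (fraction of peak
   current remaining vs dose) are fitted with the Hill function with the
   coefficient fixed at n = 1, so each compound x channel x platform cell is a
   single pIC50 (−log10 IC50 in molar). Fits with an optimal pIC50 ≤ 0 are
   floored to exactly 0 and still used in simulation: a pIC50 of 0 is only
   0.01 % block at the 100 µM sweep top, so carrying it is harmless and keeps
   the bookkeeping uniform.
2. **Conductance block.** Drug action is the quasi-steady-state
   conductance-block approximation: each screened channel's maximal
   conductance is multiplied by the unblocked Hill fraction
   `(1 + C/IC50)^-1`. Binding kinetics and state-dependence are out of scope.
3. **Action potential simulation.** Three published human ventricular myocyte
   models are paced at 1 Hz to pseudo-steady state; APD90 is measured on the
   final pace and compared with the drug-free control.
4. **Dose–response.** Steps 2–3 are repeated over a 20-point log-spaced grid
   from 1 nM to 100 µM, warm-starting each concentration from the previous
   one (an ascending ramp, matching the sequential experimental protocol).
5. **Uncertainty.** pIC50s are resampled from per-channel, per-platform
   normal distributions and the sweep repeated per draw; empirical
   2.5/97.5 percentiles give 95 % credible bands.
6. **Clinical evaluation.** Free plasma concentration at the highest TQT dose
   is `(Cmax/MW)·(1 − %bound/100)` µM; a prediction is positive when the
   interpolated ΔAPD90 reaches 5 ms inside a fold-change window around that
   concentration; 2x2 contingency tables give sensitivity, specificity and
   accuracy in exact rational arithmetic.

## Action potential models

Three models are shipped as hand-verified transcriptions of the published
equation sets (no runtime CellML parsing), each exposing named scalable
conductances {IKr, IKs, INa, ICaL, Ito, IK1} and its published square-pulse
stimulus:

| model | variant | states | stimulus |
|---|---|---|---|
| tentusscher2006 | epicardial | 19 | −52 µA/µF, 1 ms |
| grandi2010 | epicardial | 39 | +9.5 µA/µF, 5 ms |
| ohara2011 | endocardial | 41 | −80 µA/µF, 0.5 ms |

Notes on fidelity choices:

* The ten Tusscher & Panfilov (2006) epicardial system has 19 state
  variables (the widely quoted count of 17 belongs to the 2004 predecessor).
* The Grandi model's K⁺ concentration is clamped (dKi/dt = 0), as in the
  authors' distributed code; it still counts among the 39 states.
* Kv4.3 screens map to Ito. Grandi has distinct fast/slow transient-outward
  components, so the block factor scales only the fast (Kv4.3-like)
  conductance there; the other two models have a single Ito conductance that
  is scaled whole.
* IK1 is scalable (needed to reproduce single-channel-block phenotypology)
  but no screening dataset targets it.
* In the O'Hara model the published `anca` expression divides by the `jca`
  gate; it is implemented in the algebraically identical division-safe form
  `km2n/(k2n + km2n·(1+Kmn/cass)^4)` so degenerate states do not fault.
* Published initial conditions are printed to ~4 significant digits, so the
  raw resting dV/dt can be up to ~0.15 mV/ms; all three models relax to a
  stable quiescent rest within a few hundred stimulus-free milliseconds, which
  is what the quiescence test asserts.

## Numerics

* **Solver.** Each pace is integrated with LSODA (adaptive, stiff-capable)
  at relative/absolute tolerances 1e-6/1e-8 and a maximum step just below the
  stimulus duration. The pace is split into stimulus-on and stimulus-off
  segments so the solver never steps across the discontinuity. Right-hand
  sides are numba-compiled; removable GHK singularities at V → 0 (and
  V → +15 mV in ten Tusscher's ICaL) use their analytic limits.
* **Reference oracle.** Tests compare the adaptive solve against a
  fixed-step classical RK4 integration at 1 µs of the same equations —
  no shared solver code. Observed agreement for the control pace: max trace
  difference ≤ 0.23 mV, APD90 difference ≤ 0.007 ms (asserted at 1 mV / 1 ms).
* **Steady state.** Convergence is declared when the relative 2-norm change
  of the full state vector between successive pace onsets falls below a
  tolerance (pipeline default 1e-6, maximum 10 000 paces; both configurable).
  A period-2 (alternans) rhythm cannot converge by this criterion; the engine
  reports `converged=False` with the final pace and a heuristic alternans
  flag rather than masking the dynamics.
* **APD90.** Baseline is the pre-stimulus potential at pace onset; threshold
  is 90 % of amplitude below the peak; timing runs from maximum dV/dt to the
  first linearly interpolated downward crossing. Traces are sampled at
  0.1 ms, far below the 5 ms decision threshold. Failure handling: a pace
  whose onset potential is above −40 mV is classified as repolarisation
  failure (the previous pace never repolarised — this also catches sustained
  oscillation around depolarised potentials, as under full IKr block in the
  O'Hara model); an amplitude under 10 mV from a polarised baseline is
  no-depolarisation. Flagged points are serialised with their flag, excluded
  from interpolation, and counted as positive in window classification.
* **Interpolation and windows.** ΔAPD90 is linear in log10 concentration
  between grid points and clamped beyond the grid. The fold-change window is
  symmetric, `[c/fold, c·fold]`, and applied identically to observed-positive
  and observed-negative compounds; widening a window can therefore create
  false positives as well as recover false negatives. This symmetry is a
  design choice — the alternative (one-sided relaxation for positives only)
  is not adopted because it cannot degrade specificity by construction and
  would overstate performance.
* **Hill fitting.** Ordinary least squares on the clipped fraction
  remaining, one free parameter, deterministic multi-start (13 fixed initial
  pIC50s spanning 0–12, bounded scalar minimisation, ties to the smaller
  pIC50). Logit transforms and free Hill coefficients are deliberately not
  offered.

## Uncertainty model

The credible band treats each channel's pIC50 as
Normal(pIC50_obs, σ(channel, platform)), sampled independently per draw, with
floored values perturbed around 0 and re-floored. σ is data, not code: the
default 0.2 log10 units is a typical screening control-assay spread, and
users should substitute measured values per platform. The band is the
pointwise empirical 2.5–97.5 percentile range (linear-interpolated) over
draws; draws that fail to repolarise at a concentration are excluded from the
percentiles and reported as a `fraction_failed`. Draw streams derive from a
single seed in one pass, so results are independent of evaluation order.

## Synthetic data

Two generators stand in for inputs that cannot be bundled:

* **Concentration–effect screens**: log-spaced doses with Gaussian response
  noise (default sd 0.02 on the fraction scale, 8 points over 1 nM–100 µM),
  clipped to [0, 1]. This emulates a clean automated-platform read-out; it
  does not model well-to-well drift, solubility loss at high dose, or
  leak-subtraction artefacts, so fit-recovery results bound only the
  statistical (not systematic) error of the fitter.
* **TQT cohorts**: molecular weight uniform on 200–700 g/mol, Cmax
  log-uniform on 10–10⁴ ng/mL, protein binding uniform on 0–99 %, and ΔQTc
  from either a null model (Normal(0, 2 ms)) or a hERG-driven model
  (maximum effect x block fraction at the free Cmax, plus noise). Generating
  truth is retained so expected contingency counts can be recomputed exactly.
  These cohorts exercise the evaluation machinery; they do not reproduce the
  correlation structure of real clinical exposure data.

## Problem sizes used in tests and the acceptance script

The full protocol (convergence 1e-6, up to 10 000 paces, 20-point grids,
500-draw bands) is the library default. The test suite and
`scripts/acceptance.py` run scaled studies chosen for a single CPU:
steady-state tolerance 1e-4 with a 60-pace budget for controls (the slow
Na⁺/K⁺ drift beyond that moves APD90 by well under 0.1 ms per pace),
50-pace budgets for block phenotypes, 8-point grids for sweeps, 60–150-draw
bands, and a 2-point grid with single-pace solves for the band-coverage
study (200 replicates). Each scaled test states its own tolerances; the
solver tolerances are never loosened.

## Known limitations

* Single-cell APD90 is compared directly with ΔQTc; no tissue propagation,
  pseudo-ECG, or APD-to-QT rescaling is applied.
* Conductance block ignores binding kinetics, state preference and
  trafficking effects; compounds acting through unscreened mechanisms
  (e.g. Na⁺-channel activation) are invisible to the method.
* The clamped-K⁺ Grandi formulation cannot express long-term K⁺ loading
  effects.
* The clinical exposure table needed for the full 34-compound TQT benchmark
  is supplementary material of the originating study and is not bundled; the
  corresponding acceptance test documents the expected file and fails until
  it is supplied.
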