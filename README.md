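# silicoqt

**In-silico cardiac safety: from multi-ion-channel screens to APD90/TQT
prediction.**

Drug-induced QT prolongation is the canonical cardiac-safety liability in
drug development. Early screening measures how strongly a compound blocks a
handful of cardiac ion channels (hERG/I<sub>Kr</sub>, CaV1.2/I<sub>CaL</sub>,
NaV1.5/I<sub>Na</sub>, KCNQ1/I<sub>Ks</sub>, Kv4.3/I<sub>to</sub>), but the
clinical question — will this drug prolong QTc by ≥ 5 ms in a human Thorough
QT (TQT) study? — depends on how those blocks combine in a beating myocyte.
`silicoqt` answers it mechanistically: it integrates the screening panel into
human ventricular action-potential simulations and scores the resulting
predictions against clinical outcomes. The intended users are safety
pharmacologists and modellers triaging compounds before clinical ECG studies.

## Method

For a compound at concentration *C*, each screened channel *j* keeps the
unblocked fraction given by the Hill function with coefficient fixed at 1:

    g_j = ḡ_j · (1 + C / IC50_j)⁻¹ ,   pIC50 = −log₁₀(IC50 [M])

where ḡ_j is the control maximal conductance. The scaled model (one of
ten Tusscher & Panfilov 2006 epicardial, Grandi–Pasqualini–Bers 2010
epicardial, or O'Hara–Rudy 2011 endocardial) is paced at 1 Hz with an
adaptive stiff solver (tolerances 10⁻⁶/10⁻⁸) to pseudo-steady state, and the
action potential duration at 90 % repolarisation (APD90) is compared with
control. Sweeping 20 log-spaced concentrations from 1 nM to 100 µM yields a
ΔAPD90–concentration curve per compound x model x dataset; resampling pIC50s
from per-assay normal distributions yields 95 % credible bands. Predictions
are classified against the clinical 5 ms criterion at the estimated free
plasma concentration (Cmax corrected for protein binding and molecular
weight), optionally within a fold-change concentration window, producing
contingency tables with sensitivity/specificity/accuracy.

The package bundles the 34-compound screening panel (IonWorks Quattro and
Barracuda platforms plus GLP manual-patch hERG values) as
`src/silicoqt/data/pic50_panel.csv`.

## Worked example

Dofetilide — a pure hERG blocker with manual-patch pIC50 8.0 (IC50 = 0.01 µM)
— on the O'Hara model with the manual-hERG (M&Q) dataset:

```bash
silicoqt sweep --model ohara2011 --dataset MQ --compound dofetilide \
    --grid 1e-3:1e-1:5 --convergence-tol 1e-4 --max-paces 100
```

```
compound,model,dataset,concentration_uM,apd90_ms,delta_apd90_ms,flag
dofetilide,ohara2011,MQ,0.001,284.03,15.62,
dofetilide,ohara2011,MQ,0.00316,313.02,44.62,
dofetilide,ohara2011,MQ,0.01,380.47,112.07,
dofetilide,ohara2011,MQ,0.0316,496.88,228.47,
dofetilide,ohara2011,MQ,0.1,652.24,383.83,
```

Reading the output: the drug-free control APD90 is 268.4 ms; at 1 nM the
model already prolongs by ~16 ms (dofetilide is a potent torsadogen), and at
the manual-patch IC50 (0.01 µM, half the hERG conductance removed) the
prolongation is ~112 ms. At higher concentrations the O'Hara model fails to
repolarise entirely — such points carry a `repolarisation_failure` flag and
count as positive in classification. Every row is ≥ 5 ms, so dofetilide is
predicted QT-positive at any plausible exposure, matching its clinical
record.

Other entry points: `silicoqt fit` (Hill fits from concentration–effect
CSVs), `silicoqt band` (credible bands), `silicoqt evaluate` (contingency
tables from curves + TQT records), `silicoqt synth` (synthetic data
generators), `silicoqt model-info` (model registry metadata). The same
functionality is available as a library (`import silicoqt`).

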