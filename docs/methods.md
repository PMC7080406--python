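# Methods

This note documents the models behind each stage, the defaults and why
they were chosen, what the synthetic generators do and do not emulate, and
the numerical choices that affect results.

## Library preparation

Properties come from RDKit: average molecular weight, Crippen
atom-contribution logP, formal charge as written in the input SMILES (no
pKa-based protonation-state assignment — engine-specific protonation is
out of scope), and heavy-atom counts. The fragment-like window is
MW ≤ 250 Da, logP ∈ [1, 5], formal charge ∈ [−1, +1], all bounds
inclusive. Because logP estimators differ substantially between tools,
survivor counts on real vendor libraries will not match those produced by
proprietary property calculators; the filter logic, not the estimator, is
the tested contract. Rejections report the first failing rule in the fixed
order mw → logp → charge → reactive → pains.

PAINS filtering uses the published PAINS A/B/C substructure lists as
shipped with RDKit's FilterCatalog. The reactive-group list
(`data/reactive_patterns.smarts`) is this package's own declared set —
acyl halides, aldehydes, vinyl-ketone Michael acceptors, isocyanates,
activated alkyl halides — chosen to be short and auditable; screening
vendors use larger unpublished lists.

Fingerprints concatenate a Morgan radius-2/2048-bit circular fingerprint
with a 2048-bit RDKit path fingerprint (4096 bits total), mirroring
screening stacks that mix ECFP-like and linear fingerprints; novelty is
1 − Tanimoto similarity to the nearest reference ligand. On this
fingerprint, melatonin vs. its urea analog measures ≈ 0.07 and melatonin
vs. benzene ≈ 0.98. Circular-only fingerprints exaggerate the distance
between close analogs (0.20 for the same urea pair), which is why the
combined form is the default.

Diversity selection is greedy leader (Butina-style) clustering on
Tanimoto distance: compounds are processed best-docking-score-first (ties
broken lexically by id), each joining the first leader within the distance
threshold or founding a new cluster. Processing order makes every leader
its cluster's best-scoring member, hence the representative. The
partition, not an optimal clustering, is the contract — leader clustering
is order-dependent by construction, and the declared order makes it
deterministic.

## Enrichment benchmarking

Docking scores are energies (kJ/mol, lower = better). ROC curves use the
average-rank tie convention — a tied score group contributes a diagonal
segment — which is the unique convention under which an all-tied table
yields AUC 50. AUC is trapezoidal, reported ×100. An independent
Mann–Whitney formulation (concordant active–decoy pairs plus half-ties,
computed from ranks) is exposed alongside and agrees to ~1e-15 relative;
the test suite enforces 1e-10. Model selection is arg-max AUC with exact
ties broken by TPR at FPR = 0.1 and then lexically. The score cutoff
(−32.0 kJ/mol, the standard virtual-screening threshold for this engine
family) is inclusive at equality.

## Dose–response

The agonist model is the Hill equation parameterized on log10-molar
concentration, fitted by Levenberg–Marquardt least squares
(`scipy.optimize.curve_fit`) with asymptotic standard errors. The default
is the three-parameter form (slope fixed at 1, basal free) matching the
common workflow for these assays; a four-parameter free-slope form is
available. Fitting on the pEC50 scale (rather than EC50) gives
near-Gaussian parameter errors consistent with "pEC50 ± SEM" reporting.
Flat datasets — response span below 5× the pooled replicate SD (or below
1e-6 when unreplicated) — are refused with a no-response signal rather
than fitted. Optimizer failure is reported via a `converged` flag, never
an exception.

Competition binding uses the one-site model (top, bottom, logIC50) with
Cheng–Prusoff conversion Ki = IC50/(1 + [L]/Kd). The radioligand Kd is a
required configuration input; the synthetic fixtures use 0.1 nM, which is
a stand-in value for testing, not a measured constant.

Censored results (`ND`, `>30000`) are carried as bound objects end to end
and never coerced to numbers. A selectivity fold with a censored MT1 block
propagates as a lower bound, with an unreported Emax capped at its 100%
ceiling; the resulting bound is conservative (for the one censored
compound in the packaged table it is ≈ 130, smaller than the fold printed
for it in the source report, which is not derivable from the stated
formula).

## Hit metrics

Ligand efficiency is LE = c·pAct/N_heavy with c = 1.4 kcal/mol per log10
unit (≈ 2.303·R·T near physiological temperature; 1.37 for 298 K is
selectable). The published LE columns are reproduced within ±0.02 — the
exact constant and rounding path used upstream is not uniquely
recoverable, so LE checks are tolerance-based by design. Selectivity folds
are reported at one decimal with halves rounded away from zero, which is
required to reproduce printed values that sit near half-ulp (0.08 → 0.1).
Partial agonism is strict Emax < 70%; by that rule the packaged table
contains five MT2 partial agonists (the source's prose counts four but its
own formatting marks five — the threshold rule's answer is reported).
Hit thresholds: sub-micromolar EC50 < 1000 nM, potent < 100 nM, binding
confirmed pKi > 5 (Ki < 10 µM), each at ≥ 1 receptor.

## Operational model and bias

Curves on each pathway are fit globally with the Black–Leff operational
model, response = basal + (Em − basal)/(1 + ((1 + A/KA)/(R·A))^n), with
R = 10^logR = τ/KA the transduction coefficient. Identifiability drives
the constraint scheme: with n = 1 every operational curve is an exact
slope-1 Hill curve, so each curve carries two observables (top, EC50)
while the model wants two per-compound parameters plus shared Em — Em is
then structurally unidentifiable, and a mis-scaled Em shifts every logR
by −ΔlogEm uniformly (which cancels in ΔLog(τ/K_A) but not in logR
itself). Because responses are normalized to the reference agonist's
maximum and baseline-corrected, the defaults pin Em = 100, basal = 0 and
n = 1; all three can be freed. With no shared free parameters the
per-compound estimates are independent, so combining SEs in quadrature
for ΔLog and ΔΔLog is exact rather than conservative; Monte-Carlo checks
show 2-SE coverage of logR around 92–95% and nominal-95% coverage of
ΔΔLog within the 90–98% band at the 5%-noise study condition.

Bias orientation: ΔΔLog(τ/K_A) = ΔLog(G-protein) − ΔLog(arrestin), bias
factor = 10^ΔΔLog, so a compound with weakened arrestin recruitment
relative to the reference scores above 1 (G-protein-biased). Swapping
pathway order inverts the factor. The closed-form EC50 of the operational
curve, EC50 = KA/((2 + τ^n)^{1/n} − 1), is used as a consistency oracle
against Hill fits of generated curves.

The published bias factors for the two most biased hits (15.5 and 33.9)
are reachable only as arithmetic anchors — the underlying raw curves are
not published — so the factors are validated by the antilog mapping
(10^1.190 → 15.5, 10^1.530 → 33.9) plus parameter-recovery simulations,
not by refitting the original data.

## Synthetic generators

Generators emulate the study conditions: 20 actives vs. 780 decoys with
normal score components (defaults −35 ± 3 vs. −25 ± 3 kJ/mol — the normal
family is chosen for its closed-form AUC Φ(Δμ/√(σ₁²+σ₂²)) ≈ 99.1% at the
default separation, which anchors the enrichment oracle); agonist grids of
10 half-log steps ending at 10 µM; binding grids of 9 log-spaced points
spanning 100 fM–10 µM; additive homoscedastic Gaussian noise of 5% on the
normalized response scale with N = 3 replicates. Every generator is
deterministic given its seed (`numpy.random.default_rng`), and library
generation draws from packaged template molecules whose filter outcomes
were computed once with this package's own property routines and frozen as
annotations.

Not emulated: plate-level artifacts (background, edge effects, well QC),
heteroscedastic or correlated noise, docking poses and receptor
conformations, and vendor-availability structure of real libraries.
Passing recovery tests therefore demonstrates correctness of the
estimation machinery under the declared noise model, not robustness to
real assay pathologies.

## Problem sizes

Monte-Carlo calibration runs use 200 replicates per check (Hill recovery,
operational logR recovery) and 100 for interval-coverage properties;
random-table AUC equivalence uses 1000 tables. The demo pipeline runs 40
library molecules, 800-compound score tables and 3-compound assay
batches. These sizes give stable pass/fail behavior for the statistical
assertions while keeping the full suite in the seconds-to-minutes range.

## Known limitations

- logP and fingerprints are open-source estimators; numbers differ from
  proprietary screening stacks, so novelty distances and filter survivor
  counts on real libraries are approximate.
- The reactive-group list is deliberately minimal.
- Asymptotic SEs understate uncertainty for strongly censored or barely
  converged fits; a bootstrap is the escape hatch for small-n work.
- Printed-table reproduction inherits the source table's internal
  inconsistencies (a few rows whose printed EC50 is not the antilog of
  the printed pEC50); both columns are preserved as printed, and
  selectivity reproduction uses the printed EC50/Emax, never "corrected"
  values.
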