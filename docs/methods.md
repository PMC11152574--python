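# Methods

## Model

A repressor molecule is coarse-grained into two domains — ligand-binding
(LBD) and DNA-binding (DBD) — each with an inactive (I) and an active
(A) conformation; binding competence (to ligand and operator
respectively) is assigned to the active conformations only, and the
homodimeric architecture of TetR-like proteins is deliberately ignored
to keep the parameter count minimal. Four conformational states follow,
with free energies (kBT, LIDI as the zero):

| state | G |
|-------|---|
| LIDI  | 0 |
| LADI  | εL |
| LIDA  | εD |
| LADA  | εL + εD + γ |

γ is the inter-domain coupling penalty; γ > 0 makes simultaneous
activation of both domains unfavourable, which is what lets ligand
binding (selecting the active LBD) discourage operator binding (the
active DBD) — the basis of induction. Equilibrium statistics over these
states and the ligand/operator binding equilibria give the fold change
of the regulated gene,

    FC(c) = [1 + R* e^(−εD) (1 + e^(−εL−γ) x)/(1 + e^(−εL) x)]⁻¹,
    x = (c/K)²,

implemented in `twodom.model`. Direct consequences used throughout:
leakiness FC(0) depends only on εD (and inverts in closed form,
εD = −ln((1/leak − 1)/R*)); saturation FC(∞) = (1 + R* e^(−εD−γ))⁻¹ is
independent of εL; εL sets the EC50; and sign(dFC/dc) = sign(γ), so
γ < 0 turns the ligand into a corepressor and γ = 0 makes the curve
flat (EC50 undefined — `ec50` raises `FlatResponseError`).

### Constants

`R*` (rescaled repressor number) and `K` (ligand dissociation constant
of the active LBD) are taken as mutation-invariant system constants.
Their absolute values are not identifiable from fold-change data alone
together with εD; the package defaults are `R* = 100` — wild-type
leakiness ≈ 0.0099, i.e. tight repression — and `K = 3 nM`, which
places the wild-type EC50 (≈ 670 nM) inside the 0–1000 nM measurement
window. The exponent 2 on c/K reflects the two effective ligand sites
and is fixed (`SystemConstants.n_lig`, overridable but not part of the
supported surface).

### Numerics

FC is evaluated in log space: each factor `1 + e^a x` is handled as
`logaddexp(0, a + 2·log(c/K))`, so energies within [−20, 30] and c/K up
to 10⁶ neither overflow nor lose the small term, and c = 0 collapses
exactly (log x = −inf). The implementation is tested against a 50-digit
`decimal` term-by-term oracle to 1e−10 over 1000 random inputs. EC50 is
defined as the concentration where FC crosses
(leakiness + saturation)/2, bracketed geometrically from K and solved
with Brent's method (relative tolerance 1e−10); uniqueness follows from
strict monotonicity whenever γ ≠ 0.

## Synthetic data

`twodom.synth` emulates the plate-reader/flow dose-response assay the
model is fitted to in practice: per variant, ≥ 4 replicate fold-change
measurements at each point of the fixed 12-concentration aTC gradient
(0, 10, 20, 40, 60, 80, 100, 150, 250, 500, 750, 1000 nM). Replicate
noise is zero-mean Gaussian with sd = max(cv·FC, floor), clipped at
zero; defaults cv = 0.05, floor = 0.002. The relative component matches
the roughly constant relative error of normalised fluorescence; the
floor keeps near-zero fold changes at a finite, small error, which is
what allows tight credible intervals for dead variants whose whole
curve sits at FC ~ 0.01–0.05. A warning is emitted if more than 1% of
points clip (the Gaussian model is then visibly truncated).

What the generator does **not** emulate: day effects and replicate
correlation, instrument-specific error at the top of the range,
fold-change values above 1 from normalisation error, and any
concentration-calibration error. Passing recovery tests therefore
demonstrate correctness of the estimation machinery under the stated
noise model, not robustness to every artefact of real plate data.

The packaged panel (`panel_fixture`) carries the published posterior
medians and 95% credible bounds for 23 characterised variants under
two γ priors, plus the distances of the 21 mutated residues to operator
and ligand (structural metadata only). Published per-variant εD values
are graphical only, so `MutantPanel.params_for` defaults εD to the
wild-type reference 0 with an explicit override — a known limitation
for quantitative counterfactuals that depend on each variant's εD.

## Inference

Estimation is two-step, mirroring how the curve separates the
parameters:

1. **εD from leakiness.** The closed-form inversion applied to the mean
   of the c = 0 replicates; its standard error is the replicate SEM
   times |dεD/dleak| = 1/(leak(1−leak)) (first-order delta method),
   cross-checked in the tests against a 10⁵-draw parametric bootstrap.

2. **(εL, γ) by MCMC.** With εD fixed, the c > 0 observations are
   modelled as independent Gaussians around the model curve with one
   shared inferred scale σ. Priors: γ ~ N(5, 2.5²) kBT (alternative
   sd 5 for robustness checks), εL uniform on [−5, 25] kBT (wide enough
   to contain every published median with margin), σ half-normal with
   scale 0.1. Sampling is in (εL, γ, log σ) with the Jacobian included.

The sampler is emcee's affine-invariant ensemble (32 walkers,
differential-evolution + snooker moves), run in two phases: 600
exploration steps from overdispersed prior draws (redrawn per walker up
to 100 times if the posterior is non-finite), then all walkers
re-initialised in a 1e−3 ball around the best point found and 2400
production steps, discarding 400 and thinning by 8 (8000 retained
samples). The two-phase pattern exists because a single run from prior
draws leaves isolated walkers stranded for thousands of steps in a
secondary mode (flat curve + large σ) whose posterior mass is
negligible but whose basin is wide; the ball restart removes them
without touching the target distribution, and the long production phase
lets weakly identified ridges mix to split-chain R-hat < 1.05
(computed with arviz, walkers as chains, together with bulk ESS).
Identical seed and configuration reproduce the summary exactly.

Two deliberate simplifications are flagged rather than hidden:

- εD's standard error is **not** propagated into the (εL, γ) posterior —
  the two-step scheme conditions on the point estimate. For data whose
  leakiness is measured precisely this is harmless; with the default
  noise floor and only 4 replicates at c = 0, the plug-in error (~0.1
  kBT for the wild type) visibly degrades joint CI calibration, which
  is why recovery benchmarks condition on the generative εD.
- Curves that never approach saturation within the measured range
  (large γ, or the strongly right-shifted εL regime) leave γ
  prior-dominated. Such fits carry a `wide_gamma_ci` flag (γ CI wider
  than 3 kBT), and `prior_robustness` flags parameters whose medians
  move by more than 0.5 kBT across priors.

`posterior_predictive` simulates observations from posterior draws plus
the inferred σ and returns {5, 25, 50, 75, 95}th percentile bands per
concentration; around 90% of the generating observations should fall
inside the 5–95% band of a well-calibrated fit.

## Epistasis

`twodom.epistasis` implements the weighted additive model: per
parameter p, p(mut1+mut2) = p_WT + α1,p·δp1 + α2,p·δp2 with
δp = p_mut − p_WT and all six weights in [0, 1] (all ones = plain
additivity). Quenching a weight to zero expresses the hypothesis that
one mutation's contribution to one parameter is dominated by the other
mutation; the eight published weight sets ship as `WEIGHT_PRESETS`
(panels A–H). The printed weight lists do not state unambiguously which
constituent of each pair is "mutant 1", so `AdditiveModelSpec.swapped()`
exposes the other assignment instead of guessing.

Curve-level predictions draw parameter triples independently from the
three posteriors (no cross-mutant correlation information exists to do
better), apply the additive map per draw, and report 2.5/50/97.5
percentile bands. Epistasis is quantified against observations as the
RMS difference between the predicted median curve and per-concentration
replicate means, plus the fraction of those means outside the 95% band
— a package choice; visual curve comparison is the traditional
alternative.

## Landscape and pipeline

`fc1000_landscape` evaluates FC1000 on a rectangular (εL, γ) grid
(elementwise, no caching); `panel_correlation` reports the Pearson r
and OLS regression of γ on εL across the panel medians (r = −0.647,
slope = −0.776 for the packaged 23-variant panel — computed, and
snapshot in the tests rather than asserted against any external
number). `counterfactual_gamma` recomputes FC1000 with γ reset to a
reference (typically the wild-type 5.29 kBT), isolating how much of a
phenotype the coupling carries; with the shared εD = 0 default the four
weakened-coupling dead variants all gain FC1000 on reset, though their
absolute recovered values depend on the unknown per-variant εD, so only
the monotone increase is asserted.

`run_pipeline` chains simulate → fit → classify → epistasis → landscape
from a flat `key = value` config, writing per-variant fit JSONs, a
phenotype table, machine-readable landscape/correlation outputs and a
log that names every seed. All plotted-style quantities are emitted as
tables; no stage parses images.

## Problem sizes and test design

Unit and acceptance tests run the real sampler at its default
configuration (~1–2 s per fit): four recovery fits at published medians
(wild type; PIF, the strongest εL perturbation; R49G, a weakened-γ dead
variant; and the sign-flipped triple mutant Y132A-G102D-T26A with
εD = 4 so the corepressor curve is measurable), a 20-fit coverage sweep
over εL ∈ [2, 11], γ ∈ [1, 6] requiring ≥ 17/20 joint CI coverage, a
brute-force 200×200 grid-mode cross-check that must land inside the
MCMC cloud, and a full 23-variant pipeline run. Statistical assertions
on single seeds are written to the bulk of their sampling distribution
(a 95% interval covers a fixed truth in ~95% of realisations, not all);
systematic calibration is carried by the sweep.
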