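# Methods

## The reduced clock model

The model describes a single presomitic-mesoderm cell. Three Hes/Her
bHLH repressors interact: Her1 and Her7 are produced under delayed
negative feedback, Hes6 at a constant rate. All pairwise dimers form,
but only Her1:Her1 and Her7:Hes6 bind DNA; both repress the *her1* and
*her7* promoters through the same sites, so the two feedback loops are
parallel and redundant. Dimerization is assumed much faster than
production and turnover, so dimer levels are instantaneous products of
monomer levels (d11 = h1², d67 = h6·h7, ...). Repression is a Hill
function H(d) = 1/(1+dⁿ) of the summed DNA-binding dimer levels; the
Hill coefficient is phenomenological, standing in for the cooperativity
of multiple promoter binding sites, not for a binding mechanism.

Everything is dimensionless: time is measured in monomer lifetimes
(the linear turnover term is −h), dimer levels in units of the combined
half-repression threshold, and δ is the effective dimer-mediated
degradation rate — the loss of monomers that are degraded while
resident in dimers, δ·h_i·(h1+h6+h7). No mapping to minutes is asserted;
all period statements are relative.

Parameters (defaults on `ClockParameters`):

| parameter | meaning | default |
|---|---|---|
| κ1, κ7 | Her1/Her7 production rates | 10 |
| κ6 | Hes6 production rate | 90 (wildtype); 0 models the *hes6* mutant, 45 the heterozygote |
| τ1, τ7 | production delays | 1.02, 1.00 |
| n | Hill coefficient | 2 |
| δ | dimer-mediated degradation rate | 1 |

The 2% delay asymmetry τ1 > τ7 reflects the longer, more intron-rich
*her1* gene and is what places the *her7*-mutant period close to
wildtype; the wildtype κ6 = 90 places the wildtype period ≈6–8% below
the κ6 = 0 (hes6-mutant) period.

Exact functional forms of the published reduction are not available in
the transcription this package was built from; the equations here are
reconstructed from the model's verbal description. Two choices were
genuinely open:

* **Repressor combination.** d11 and d67 enter one Hill term
  additively, 1/(1+(d11+d67)ⁿ), because a single threshold governs both
  dimers; separate Hill factors per dimer were rejected as less
  parsimonious.
* **Homodimer loss stoichiometry.** The δ term uses the symmetric form
  h_i·(h1+h6+h7). The variant counting both monomers of a homodimer,
  h_i·(h1+h6+h7+h_i), is available as
  `ClockParameters(homodimer_double_loss=True)`; it changes no
  qualitative classification, but quantitative results depend on it —
  the κ6 = 90-vs-0 period difference is 8.0% with the symmetric form
  and 3.9% with the variant (the tests compute both facts).

Mutants zero the production rate(s) of the affected gene(s); the *hes6*
heterozygote halves κ6. Total protein for a factor counts its monomer
plus all monomers resident in equilibrium dimers (two per homodimer):
total1 = h1 + 2h1² + h1h6 + h1h7. Total Her1 is the headline
observable; her1-mutant conditions are read out on total Her7 instead
(there is nothing to read on total Her1).

The effective degradation rate of a monomer is its total per-capita
loss, r(s) = 1 + δ(h1+h6+h7), averaged over an integer number of
steady-state cycles (terminal value for non-oscillatory runs), with
half-life ln2/⟨r⟩. This is the quantity through which Hes6 tunes the
period: removing Hes6 lowers ⟨r⟩ for Her1/Her7 and slows the clock, and
conversely the oscillating Her1/Her7 levels modulate Hes6's own
effective stability, which is why total Hes6 oscillates despite
constant production.

## Numerical integration

Delay differential equations are integrated by the classical method of
steps: fixed-step explicit RK4 on a uniform grid, with delayed lookups
served from the stored solution by cubic Hermite interpolation (state
and derivative at the bracketing nodes) and by the history function for
arguments at or before t0. On a uniform grid the fractional offsets of
all delayed stage lookups are constant, so interpolation weights are
precomputed once. Requirements and defaults:

* dt ≤ min(positive delay)/10 is enforced; the default is
  min(τ1, τ7)/100 (0.01 for the reference set).
* History is constant zero; production bootstraps the dynamics and only
  the steady-state attractor is analyzed, so initial conditions are
  immaterial.
* Default horizon t_end = 300 gives ≈65 steady cycles after the
  transient at the reference parameters.
* The state is checked finite every step; blow-up aborts with the time
  reached. Components are clamped at zero if a step undershoots
  (never triggered at the reference parameters; tested).
* Convergence gate: halving dt changes the measured period by < 0.1%
  (tested; RK4 order ≈4 verified on exponential decay, and the
  neutrally stable linear DDE x' = −(π/2τ)·x(s−τ) reproduces its exact
  period 4τ to < 1%).

Adaptive stepping, state-dependent or distributed delays, and
stochastic simulation are out of scope.

## Oscillation analysis

The first half of every run is discarded as transient. Local maxima are
found by three-point comparison with parabolic sub-grid refinement
(plateau midpoints for exact ties); cycle amplitudes are peak minus
following trough. Classification:

* **sustained** — ≥10 cycles in the steady window whose amplitudes agree
  to < 1% relative spread and exceed the amplitude floor;
* **damped** — oscillations exist somewhere in the run (≥3 cycles above
  the floor) but decline (median per-cycle ratio < 0.99) or have fallen
  below the floor by the end;
* **fixed_point** — no meaningful oscillation at any time.

The amplitude floor is 10⁻³ of the observable's full-run range — the
range at the reference parameters is of order κ1, so the floor is small
relative to the production scale while remaining well-defined for any
observable. Period (mean of the last ≤10 peak intervals) is reported
only for sustained oscillations; the reported amplitude of a
non-sustained run is its asymptotic (terminal-window) value, i.e. 0 for
a damped oscillation. For damped conditions the decaying mode still has
a meaningful cycle time; `transient_period` measures it from the peak
intervals of the above-floor cycles, skipping the startup interval.
This is how the her7-mutant point (damped at κ6 = 90) enters period
comparisons.

## Full dimer-cloud model and the reduction

The nine-variable model tracks the monomers and all six dimers with a
shared association rate a, dissociation rate b and degradation rate c
(degradation acts equally on all Hes/Her species); repression reads the
actual delayed d11 and d67 levels over the threshold D0. Defaults make
dimerization 50× faster than turnover with K = b/a = 1, so the implied
reduced degradation rate c·a/(b+c) is within 2% of δ = 1, converging to
it as (a, b) are scaled up jointly.

Two monomer-bookkeeping conventions are provided. The default
(`buffered`) treats the free-monomer pool as exchanging rapidly with
the dimer pool, so sequestration appears in the monomer balance only as
the dimer-degradation loss channel; its fast-dimerization limit is
exactly the reduced model, which is the property `reduction_check`
verifies (period error 0.02% at 10× speed-up, 0.001% at 100×; maximum
phase-aligned monomer deviation falls from ~1% to ~0.2%). The
`mass_action` convention is fully mass-conserving (explicit ±
formation/dissociation fluxes, stoichiometry 2 for homodimers) and
satisfies an exact total-protein balance, but because an order-one
fraction of protein is sequestered at the reference parameters its slow
variable is total protein, not free monomer, and its fast-dimerization
limit is not the reduced model — it is retained as the conservative
reference variant and excluded from the reduction claim. Both variants
satisfy detailed balance at fixed points: a·h_i·h_j = (b+c)·d_ij.

Dimerization makes the system stiff; the full-model step is capped at
2/(b+c) (RK4-stable for the fast dimer relaxation), and additionally by
the monomer-exchange rate for the mass-action variant. The full-model
horizon default is 150 time units — ≈34 steady cycles after transient —
which keeps the 100× speed-up run (step 2×10⁻⁴) at tolerable cost.

## Scripted experiments

`kappa6_sweep` runs κ6 ∈ {0, 5, …, 150} by default (the plotted range
in the source analysis is unlabeled; this covers all named genotype
markers with headroom) for the κ7 = κ1 and κ7 = 0 scenarios.
`sensitivity` perturbs {κ1, κ7, κ6, τ1, τ7, δ, n} one at a time by
symmetric log-spaced multipliers {0.5, 0.8, 0.9, 1.1, 1.25, 2.0} (the
perturbation set is this package's choice and is echoed in the output).
`dimer_levels` averages monomers and equilibrium dimers over the steady
window — so ⟨d67⟩ includes the h6–h7 covariance — and reports the
half-repression threshold (1 in reduced units) alongside.

A caveat the delay scan makes visible: at κ6 = 0 the κ7 = 0 line is the
*her7;hes6* double mutant, whose period the model genuinely predicts to
exceed the *hes6* single mutant's (by ≈6% at τ1 = 1.02). The statement
that the her7-mutant period matches wildtype "almost independently" of
κ6 therefore holds on the interior of the κ6 range (gaps ≤1.5% at
κ6 = 30–90) but not at κ6 = 0, where the model's own double-mutant
period prediction takes over.

## Affinity and timing analyses

Binding titrations are fit by OLS of bound on free signal **with an
intercept** — background fluorescence is real in chip assays and a
constant offset does not bias the slope. In the sub-K_d regime the
slope is proportional to 1/K_d, so slope ratios are relative
affinities; each experiment is normalized to its strongest interaction.
Saturating points can be dropped with a free-signal cutoff; enforcing
the linear regime is otherwise the caller's responsibility. Slope
differences are compared by a two-sided z-test on the fitted standard
errors. Negative fitted slopes (noise around zero for non-binders) are
clamped to zero with a warning before normalization.

H-box scanning uses the permissive consensus CACGNG on both strands
(`strict=True` restricts position 5 to T/C, the in-vivo-relevant form).
Hits are 12-mers (3-nt flanks) in 0-based half-open coordinates; flanks
running past the sequence ends are padded with N (so coordinates can
extend past the ends — the 12-mer span is invariant); the palindromic
CACGTG core is reported once, on the + strand. The scanner is tested
against an independent brute-force regex enumeration on random 10-kb
sequences.

Somitogenesis periods are per-embryo OLS slopes of boundary-formation
time on somite index (≥3 boundaries; non-monotone series rejected as
annotation errors). Periods are normalized within each experimental
batch by the mean control period, then pooled — batch structure is
mandatory in the input so day effects cancel. Group comparison is a
two-tailed Mann-Whitney U test, exact when the smaller group has ≤8
tie-free observations, normal approximation with tie correction
otherwise; confidence intervals are mean ± 1.96·sd/√n (the normal
approximation; a t-quantile alternative would widen them slightly at
these n). The genotype column may be withheld until after fitting to
support genotype-blind analysis.

## Synthetic data

The generators produce exactly the inputs the analysis stages consume,
with ground truth serialized alongside, and are deterministic given the
seed:

* **Titrations** — free signal log-spaced over the linear regime; bound
  = background + slope·free·exp(ε), ε ~ N(0, CV). Multiplicative
  log-normal noise keeps signals positive with spread proportional to
  intensity, as for fluorescence. Default truth: bHLH pairs 4–20× above
  a non-bHLH negative control, ≤2-fold spread among bHLH pairs.
* **Boundary tables** — formation time linear in somite index with
  additive Gaussian noise (default sd 0.75 min = 3% of the 25-min
  wildtype period, a realistic annotation jitter) and a jittered onset
  per embryo; default cohort: 25 embryos per arm, somites 2–17,
  genotype periods 1.00/1.02/1.06× wildtype (the measured heterozygous
  and homozygous *hes6* effect sizes).
* **Promoters** — i.i.d. background at a given GC fraction (no
  dinucleotide structure — sufficient for recall/precision testing, not
  for promoter realism) with planted 12-mers spliced in; optionally all
  chance H-box cores are destroyed first so planted sites are the only
  hits (the single-H-box upstream-region scenario).

What passing the recovery tests shows — and does not show: the pipeline
recovers known effect sizes under the stated noise models (slope-ratio
bias < 5% at 10% CV; cohort period means within their 95% CIs; >95%
power at p < 0.01 for the 6% period effect at n = 25). Real chip data
add saturation, spatial artifacts and outliers, and real embryos add
correlated timing drift; none of these are emulated, so the tests
validate the estimators, not robustness to those artifacts.

## Known limitations

* The reduced-model equations are a reconstruction; quantitative
  results (e.g. the ≈8% period difference above vs the published ≈6%)
  carry that uncertainty, concentrated in the homodimer-loss
  stoichiometry noted above.
* Single-cell only: no Delta-Notch coupling, no presomitic-mesoderm
  gradients or wave patterns, no anterior slowing.
* mRNA is not a separate variable; transcription/translation enter only
  through the lumped production delays.
* Monomers and dimers share one degradation rate; cooperative-stability
  variants are not explored.
* Absolute K_d values and absolute times (minutes) are out of scope
  throughout; only relative quantities are reported.
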