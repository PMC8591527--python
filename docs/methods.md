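# Methods

## The resource balance analysis model

At a fixed growth rate µ (hr⁻¹) the cell model is the linear feasibility
problem over non-negative directed fluxes `v` (mmol gDCW⁻¹ hr⁻¹), enzyme
concentrations `[E]` and machinery concentrations `[M]` (mmol gDCW⁻¹):

1. **Mass balance** `S·v = 0` for every internal metabolite, with the biomass
   pseudo-reaction pinned to flux µ (it consumes the biomass composition per
   unit flux), the ATP-maintenance flux bounded below by NGAM + GAM·µ, and a
   growth-coupled PHB demand pinned to 3·µ mmol gDCW⁻¹ hr⁻¹.
2. **Enzyme capacity** for each direction of each catalysed reaction:
   `v_d ≤ k_app,d · Σ_alternatives [E]`. Reversible reactions are split into
   two non-negative directions, each with its own capacity constraint;
   isoenzyme alternatives are separate variables feeding the same constraint.
3. **Machinery coupling**: the ribosome must sustain translation of the whole
   protein pool, `µ·(Σ len·[E] + Σ len·[M] + R(µ)) ≤ rate_rib·[M_rib]`, where
   `R(µ)` is the non-enzymatic amino-acid reserve implied by the budget
   models; the chaperone covers a configurable folded fraction (default 10%)
   of the same load; RNA/DNA polymerases sustain fixed nucleotide pools
   scaled by µ. Machinery proteins count toward budgets and translation —
   the coupling is self-consistent at fixed µ.
4. **Compartment budgets**: per compartment,
   `Σ len·[E] + Σ len·[M] ≤ f_c(µ)·(1 − nonenz_c(µ))·pool`, with linear
   fraction models in µ and a total pool of 6.18 mmol amino acids gDCW⁻¹
   (0.68 g protein gDCW⁻¹ at a 110 g mol⁻¹ mean residue mass).

All constraints are linear at fixed µ; the LP is solved with HiGHS through
`scipy.optimize.linprog`. Growth maximization bisects µ over feasibility
(tolerance 10⁻⁴ hr⁻¹) under a documented monotone-feasibility contract:
substrate bounds are caps, never equalities, so relaxing µ never removes
feasible points. The reported solution at any µ minimizes total enzyme plus
machinery amino acids; this *minimal required abundance* is the numerator of
utilization. Where that optimum is degenerate (e.g. equally efficient
isoenzymes) the split between alternatives is solver-determined and the sum
is what is meaningful. Fluxes below 10⁻⁶ mmol gDCW⁻¹ hr⁻¹ count as zero.

Forced-flux scenarios pin net fluxes with equality rows and re-maximize
growth; the growth summary reports µ, q_S, biomass yield (gDCW per g
substrate) and net CO₂ exchange. The forced-CO₂-fixation experiment uses a
fructose condition whose uptake cap (10 C-mmol gDCW⁻¹ hr⁻¹) binds across the
whole forced range, so carbon input stays fixed while the forced cycle
drains ATP/NADH — the analogue of simulating at a fixed substrate uptake
rate. With a generous cap the optimizer sheds uptake instead and CO₂
emission falls with it, which answers a different question.

## The toy network

Carbon species are tracked in C-mmol so degree-of-reduction bookkeeping is
per C-mol (NADH carries 2 electrons, O₂ accepts 4). Lumped conversions:

| reaction | stoichiometry (per C-mmol in) |
|---|---|
| ED | fru → 5/6 pre + 1/6 CO₂ + 1/3 NADH + 0.5 ATP |
| SCD | suc → 0.75 pre + 0.25 CO₂ + 0.25 NADH + 0.25 ATP |
| FDH | for → CO₂ + NADH (two isoenzymes) |
| CBB | CO₂ + 2 NADH + 3 ATP → pre |
| TCA | pre → CO₂ + 2 NADH + 0.5 ATP |
| OXP | NADH + ½ O₂ → 2 ATP |
| PHBS | pre + 0.25 NADH → PHB |

Every conversion is electron-balanced exactly; the audit
(`network.electron_imbalance`) verifies it. Biomass consumes 40 C-mmol
precursor + 2.4 mmol NADH per gDCW → degree of reduction 4.12 per C-mol,
nearly equal to the fructose-like substrate's 4.0. This near-equality is the
structural reason forced CO₂ fixation cannot raise yield: there is no
surplus reducing power to pay the 2 NADH + 3 ATP per fixed CO₂.

Maintenance: NGAM 3 mmol ATP gDCW⁻¹ hr⁻¹, GAM 90 mmol ATP gDCW⁻¹ — chosen so
fructose yield lands near 0.5 gDCW/g, the realistic range for aerobic
heterotrophs. Ground-truth k_app values (9 000–45 000 hr⁻¹) are apparent
rates of lumped pathway complexes in C-mmol units, set so that the proteome
budget (not transport) limits growth at the chemostat dilution rates and the
three conditions (fructose and succinate at D = 0.25 hr⁻¹, formate at
0.05 hr⁻¹) are all sustainable. Machinery rates are in the published
bacterial range: ribosome 36 000 aa hr⁻¹ (10 aa/s), chaperone 30 000 aa hr⁻¹
over 10% of the proteome, RNA polymerase 1.98×10⁵ nt hr⁻¹ against
0.588 mmol RNA nucleotides gDCW⁻¹, DNA polymerase 2.16×10⁶ nt hr⁻¹ against
0.097 mmol gDCW⁻¹. Compartment fractions: cytoplasm 0.73 + 0.02µ, membrane
0.25 − 0.02µ; non-enzymatic fractions 0.55 − 0.25µ and 0.40 − 0.10µ (cells
shed reserve proteome as they grow faster).

## k_app calibration

For each chemostat condition the metabolic flux polytope is built with
growth fixed to the dilution rate and the measured substrate uptake fixed to
a ±0.1% band (chemostat mass balances close tightly; at ±1% the envelope of
small fluxes inflates by tens of percent). The polytope is sampled by ACHR
hit-and-run (cobrapy); when the chemostat constraints determine the fluxes
completely the unique feasible point is the sample. Flux variability
analysis bounds are computed alongside as a cross-check and as an optional
envelope source.

`k_app` per reaction direction = max over conditions of (envelope max flux) /
(measured enzyme concentration). Measured protein abundance maps to enzymes
by splitting shared proteins equally among their enzymes and limiting each
complex by its scarcest subunit; a reaction's abundance sums its
alternatives. Directions with no flux or no measurement receive the median
of the fitted distribution, flagged `median_filled`. The randomized ensemble
redraws each reaction's value independently, with replacement, from the
pooled fitted distribution (the resampling scheme is a package choice; a
whole-table permutation would preserve cross-reaction structure that the
per-reaction scheme deliberately breaks).

## Utilization

`U_E[%] = predicted minimal / measured × 100` per enzyme per condition.
Conventions: measured-but-unpredicted enzymes score 0 (expressed, unused);
predicted-but-unmeasured enzymes are flagged, not dropped; measured = 0 with
prediction > 0 is *undefined*, not infinite; values above 100 are kept with
an `over_unity` flag because they diagnose calibration error. Categories use
the mean across the designated conditions with boundaries inclusive on the
low side (low ≤ 33 < moderate ≤ 66 < high); both thresholds are arguments.
Abundance CV uses the sample (n−1) standard deviation. Note that
cross-condition means mix expression states: a transporter fully used on its
own substrate and absent from predictions elsewhere averages into "low" —
that is the expressed-but-underused signal, not an artifact.

## Essentiality

Insertions outside the central 80% of the ORF are discarded as likely
non-disrupting. `II_i = (n_i/k_i)/(n_r/k_r)` with the 100-gene window
centered on and *including* the target gene (excluding it changes II by
~1% at this window size), truncated at replicon ends (wrap available for
circular replicons). The two-gamma mixture is fitted jointly by EM:
responsibilities in the E-step, weighted gamma maximum likelihood (digamma
equation, Brent's method) in the M-step, initialized from a low/high split
at the empirical antimode located by two-means clustering of log II;
convergence at 10⁻⁸ relative log-likelihood within 500 iterations. Zero II
values, which a gamma density cannot carry, are spread deterministically
over (0, min_positive/2] — a point mass at any single replacement value
degenerates the MLE. Thresholds: on a 10⁻⁴-resolution grid, the lower
threshold is the largest II with weighted essential density ≥ fold × the
non-essential density and the upper the smallest II with the reverse
(fold = 5); genes between them, or with undefined II (empty window), are
*probably essential*. Crossing thresholds raise an error naming the fit
non-separable. Reaction propagation: any essential gene → essential
reaction; else any probably-essential gene → probably essential.

## Fitness

Per barcode, `f = log2((c_t + ψ)/N_t) − log2((c_0 + ψ)/N_0)` with
pseudocount ψ = 0.5 and library totals N; barcodes at zero in both samples
are excluded. Gene fitness is the inverse-Poisson-variance weighted mean of
its central-ORF barcodes (equal weights by flag), recentered so the median
of the designated neutral set — all genes by default, so the library must be
mostly neutral, as real libraries are — is zero per sample. Significance:
|F| ≥ 3 after ≥ 8 generations, boundary inclusive; the −2…2 band is the
typical neutral spread.

## Synthetic data: what it emulates, and what it does not

Proteomes are per-protein RBA abundances times mean-one lognormal noise of
chosen CV, with per-enzyme excess factors ≥ 1 creating known utilization
100/excess. Insertion libraries draw gene lengths lognormally (median
~0.95 kb), counts Poisson with a gamma-distributed per-gene rate effect
(shape 10) at 16 insertions/kb — the density of a pooled dense library —
scaled by 0.02 for essential genes; positions are uniform over the ORF.
Barcode abundances drift as `a₀·2^(F·g/g_ref)` with g_ref = 8 (fitness is
the log₂ fold change accrued at the first post-selection sampling) and are
read out as one multinomial draw per sample.

Passing recovery tests on these generators shows the estimators invert the
generative models they assume. Real data violate those models in ways the
generators deliberately omit: proteome noise is not homoscedastic lognormal
and shows shared (batch) structure; cells express proteins constitutively
across conditions rather than tracking the RBA optimum, so real utilization
is far below 100%; insertion rates have positional and GC biases; barcode
counts are over-dispersed relative to multinomial sampling and PCR
amplification adds correlated noise. Recovery here is therefore a
correctness check of the machinery, not evidence about organismal biology.

## Numerical choices

µ-bisection tolerance 10⁻⁴ hr⁻¹; flux-zero tolerance 10⁻⁶; LP solved by
HiGHS at default feasibility tolerances; binding constraints reported at
10⁻⁶ relative slack. Degenerate LP optima are resolved by the
minimum-enzyme objective and beyond that by the solver. EM tolerance 10⁻⁸,
max 500 iterations; threshold grid 10⁻⁴. Problem sizes throughout (20
reactions, 500-gene libraries, 10 seeds, 200 flux samples, 20–50 ensemble
draws, depth-10⁶ barcode counts) keep the full test suite and the
acceptance script to seconds-to-a-minute scale on one CPU while leaving the
statistical criteria (recall, RMSE, false-positive rate) well resolved.

## Known limitations

- No thermodynamic driving forces or nonlinear enzyme kinetics: `k_app` is a
  saturation-assuming proportionality, so predicted minimal abundances are
  lower bounds.
- The monotone-feasibility contract of the bisection can be broken by
  equality-forced exchange fluxes; the API therefore treats condition bounds
  as caps and reserves equalities for the explicit forced-flux interface.
- The JSON dialect is the full-fidelity network format; SBML round-trips the
  constraint-based core (stoichiometry, bounds, GPR) but not enzyme sizes,
  machinery or budgets, which follow the package's own schema.
- The gamma-mixture threshold behaviour at extreme library densities (II
  distributions without a visible antimode) degrades to a flagged degenerate
  fit rather than a hard guarantee.
- PHB demand is implemented as 3·µ mmol gDCW⁻¹ hr⁻¹ (per unit growth rate);
  the coupling constant is configurable where a different normalization is
  wanted.
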