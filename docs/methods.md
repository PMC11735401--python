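# Methods

This note records the model as implemented, the conventions and numerical
choices behind it, what the synthetic-data generator does and does not
emulate, and the known limitations.

## Liability-threshold prediction

The core object is the liability-threshold model: latent liability
ℓ = g + e, standard normal in the unedited population, disease when
ℓ > t = Φ⁻¹(1−K). All per-locus inputs are reduced to an *oriented locus*:
the frequency p of the undesirable allele (risk- or trait-increasing) and
its non-negative per-allele effect β on the model scale. Orientation flips
records published for the protective allele (frequency 1−p, effect −β), so
every downstream quantity is invariant to how the source GWAS chose its
effect allele; this flip invariance is enforced by property tests.

Scale conversions follow standard quantitative-genetics practice:

- disease log odds ratios → liability s.d.: β = β_logOR·K(1−K)/z, z = φ(t).
  This is the usual first-order probit approximation; it is linear, which
  is what makes the "10% overestimation ⇒ 10% outcome reduction" law exact
  on the liability scale.
- quantitative raw units → phenotypic s.d.: the phenotypic s.d. is
  estimated from the table itself as √(mean 2p_i(1−p_i)N_i·se_i²), the
  identity that makes a standardized-trait table return exactly 1. This
  avoids trusting heterogeneous unit conventions across source GWAS.

Editing the top m ranked loci homozygous protective shifts the mean
liability of edited genomes by Δ_m = Σ_{i≤m} 2p_iβ_i and the edited
prevalence is K_g = 1 − Φ(t + r_g·Δ_m). Loci are ranked by p·β, which is
half the per-locus gain 2pβ — the ordering that maximizes the cumulative
gain at every m. Ties break lexicographically on locus id so runs are
deterministic.

**Residual-variance convention.** The closed form holds the total
liability variance at 1 (its unedited value) and leaves the threshold
unchanged; it does not re-standardize after editing removes genetic
variance. An explicit-genotype simulation (x_i ~ HWE, residual
e ~ N(0, 1 − var(g)), edited genomes forced to x_i = 0) instead gives
1 − Φ((t+Δ)/σ_e). The two agree to within Monte-Carlo error precisely when
the edited loci explain a small share of liability variance — the
polygenic regime the model is meant for, with per-allele effects of a few
hundredths of a liability s.d. Oracle-equivalence tests therefore use
per-allele effects in 0.005–0.03 s.d.; with large single-locus effects
(β ≳ 0.1) the conventions visibly diverge and the closed form should be
read as the fixed-threshold approximation it is.

**Uncertainty bands.** Between-genome variation in the realized gain has
s.d. √(Σ 2p_i(1−p_i)β_i²) (the variance the edited loci explain in the
unedited population). Bands are computed by shifting the liability change
by ±1 s.d. *before* the probit map — not by transforming a prevalence
interval — so they are asymmetric on the prevalence scale, as they should
be near the tail. Prevalences below 10⁻¹² are reported as exactly 0 with a
warning; the normal survival function is used throughout for tail
accuracy.

**G×E / epistasis attenuation.** A genetic correlation r_g ∈ [0,1] between
effects estimated now and effects realized in the future environment
multiplies the liability shift (K_g(r_g) = 1 − Φ(t + r_g·Δ)); r_g = 0
reproduces the unedited prevalence exactly. Gene–gene interaction with the
unedited background is represented through the same single parameter, not
modelled separately.

## Sensitivity and fitness models

- *Misidentification*: effects at chosen rank positions are zeroed but the
  loci keep their slots — the edit list was chosen believing them causal.
  With equal per-locus contributions the quantitative outcome falls exactly
  proportionally; for disease, nulling top-ranked loci costs
  disproportionately more fold change because prevalence is convex in the
  liability shift.
- *Shrinkage*: all β multiplied by a factor in (0,1]; quantitative deltas
  scale exactly, disease curves are recomputed in closed form.
- *Off-target load*: each intended edit independently generates off-target
  mutations, each multiplying fitness by (1−s). With Poisson counts
  (default), the generating function gives E[(1−s)^X] = exp(−edits·q·s)
  exactly; a Binomial(edits, q) mode ((1−qs)^edits) is provided as the
  bounded-count alternative. Parameters: q = off-target probability per
  edit, s = selection coefficient per mutation.
- *Stabilizing selection*: Gaussian fitness profile
  exp(−(Δz−optimum)²/(2Vs)) for a phenotype displaced Δz phenotypic s.d.
  Vs defaults to 20 squared phenotypic s.d., the conventional
  weak-selection width (a one-s.d. displacement costs ≈2.5% fitness). Both
  fitness forms are this package's model choices; they are the simplest
  cumulative/quadratic forms consistent with the thresholds they are used
  to illustrate, and both are exposed for reparameterization.

## Risk-inequality simulation

Each of n individuals draws ℓ_i ~ N(0,1) and carries risk
R_i = 1 − Φ(ℓ_i + μ_E·E_i), with E_i indicating an edited genome and
μ_E = Φ⁻¹(1−K′) − Φ⁻¹(1−K) ≥ 0 the shift taking prevalence from K to K′.
R_i is a liability-percentile risk measure: in a fully unedited population
it is Uniform(0,1), so the baseline Gini index is 1/3 for every disease
and all relative curves share one normalizer. (An alternative
heritability-split risk, R_i = 1 − Φ((t−g_i−shift)/σ_e), would need an
explicit heritability and loses this universality; the percentile form is
the default and the only one used in the analyses.)

Two inequality measures are computed per edited fraction f:

- the ordinary (mean-normalized) Gini index G(f), in [0,1);
- the **absolute** Gini index G(f)·2·mean risk — the mean absolute
  pairwise risk difference E|R_i − R_j|.

The *relative* curve reported against f is the absolute measure normalized
to f = 0. This choice is substantive: compressing risks toward zero raises
relative dispersion, so the mean-normalized ratio stays above 1 for every
f > 0 and can never show inequality falling after widespread adoption.
The absolute measure does: decomposing over pair types,
MAD(f) = (1−f)²·E|U−U′| + 2f(1−f)·E|U−R| + f²·E|R−R′|, a quadratic in f
whose roots sit at f = 0 and — for this risk family — at exactly f = 1/2,
for any K′ < K. Relative inequality therefore rises above 1 for
0 < f < 1/2 (peak at f = 1/4), returns to baseline at exactly half, and
falls below it only when a majority of genomes is edited; in the
strong-editing limit K′ → 0 the whole curve is (1−f)(1+2f). The exact
limiting curve and crossing are implemented by quadrature
(`theoretical_relative_gini`, `theoretical_crossing_fraction`, using
E|X−Y| = ∫(F_X + F_Y − 2F_X F_Y)dt with the closed-form risk CDFs) as a
noise-free reference; the simulation's crossing on the default 0.01 grid
at n = 10⁶ lands within one grid step of 1/2, since the margin at one half
is exactly zero. The mean-normalized ratio is reported alongside in its
own column.

Numerical/estimation choices: the Gini estimator is the population form
via the sorted O(n log n) identity (no n/(n−1) correction; negligible at
n = 10⁶, simplest to state); edited individuals are the first ⌊fn⌋
indices (membership is exchangeable); every fraction reuses the same
seeded liability draw (common random numbers), which makes the curve
smooth in f and removes between-fraction jitter from the argmax and
crossing estimates; all-zero inputs raise rather than return a
conventional value.

Default problem sizes: n = 10⁶ individuals and a 101-point fraction grid
for the reported analyses (a five-disease sweep takes about a minute on
one CPU); smaller n is used freely in unit tests where only distributional
properties are asserted.

## Synthetic-data generator

The generator emulates the statistical structure of published GWS locus
tables so the full pipeline is testable without downloads:

- undesirable-allele frequencies from Uniform(0.01, 0.99) by default (a
  Beta option is available for frequency spectra concentrated near the
  extremes);
- true effects |N(0, effect_sd²·[2p(1−p)]^α)| with effect_sd = 0.05
  liability/phenotypic s.d. and α = −0.5 by default, the
  negative-selection coupling under which rarer variants have larger
  effects (α = −1 equalizes expected per-locus variance contributions;
  α = 0 decouples them);
- GWAS noise β̂ = β + N(0, se²) with se = 1/√(2p(1−p)N) at N = 100,000 by
  default, two-sided normal p-values, and a 5×10⁻⁸ genome-wide-significance
  flag;
- disease tables are emitted as log odds ratios via the inverse liability
  conversion, so round-tripping through the reader is part of the tested
  surface. All generated tables carry a SYNTHETIC header comment.

What it does *not* emulate: linkage disequilibrium between loci (the model
assumes linkage equilibrium, so loci are generated independent),
population stratification, assortative mating, indirect (parental)
effects, pleiotropy across traits, and non-normal liability. Passing tests
on synthetic tables therefore validate the *computational* pipeline and
the model's internal laws — not the biological accuracy of any specific
published locus list.

**Winner's curse.** `winners_curse_experiment` draws signed true effects
z ~ N(0, σ_i²) and estimates β̂ = z + N(0, se_i²), selects GWS loci,
orients each to the allele the estimate calls undesirable, and compares
the predicted gain Σ2p̃|β̂| with the true gain of that edit. Selection and
orientation are functions of β̂ alone, and E[z|β̂] = f_i·β̂ with
f_i = σ_i²/(σ_i²+se_i²), so scaling each selected estimate by its Bayes
factor gives a prediction that is unbiased for the true gain in
expectation — while the raw prediction overstates it whenever power is
incomplete. The experiment runs fully vectorized (10⁴ replicates in under
a second).

## Known limitations

- The closed-form prevalence map ignores the reduction in liability
  variance caused by fixing loci (see the residual-variance convention
  above); it is accurate in the small-per-locus-effect regime and
  increasingly optimistic for large-effect loci.
- Ranking uses point estimates; with noisy inputs the selected set is
  itself winner's-curse-biased (quantified, but not corrected, in the
  prediction commands — the shrinkage correction assumes the true prior
  scale is known).
- The inequality measure treats risk percentile as the welfare-relevant
  quantity; absolute-risk or cost-weighted inequality would cross baseline
  at different fractions.
- Fitness-cost forms (Poisson off-target load, Gaussian stabilizing
  profile) are deliberately minimal single-parameter models for
  order-of-magnitude statements, not calibrated population-genetic
  predictions.
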