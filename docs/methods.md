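# Methods

## The core clock model

The package models the cell-autonomous mammalian circadian clock in a
peripheral tissue (mouse liver is the reference configuration) with five
mRNA species: *Bmal1*, *Rev-erba* (a lumped Rev-erb/Ror nuclear-receptor
variable), *Per2*, *Cry1* and *Dbp*.  Each gene obeys a delay
differential equation

    dx/dt = d_x (M_x(t) − x),

where `d_x` is the mRNA degradation rate (1/h) and `M_x` is the product
of the gene's *modulation factors*, one per class of circadian promoter
element present in its regulatory region:

* **RRE (ROR element), repressive:** `(1 + a R(t−τ_R))^(−n)`, with `a`
  the repression strength, `R` the delayed Rev-erb mRNA level and `n`
  the number of functional elements.
* **E-box, activating with competitive repression:**
  `((1 + f·B̂)/(1 + B̂))^n` with
  `B̂ = b·B(t−τ_B) / (1 + p·P(t−τ_P) + c·C(t−τ_C))`.
  BMAL1 activates; PER2 and CRY1 act as competitive inhibitors of the
  activator.  `f ≥ 1` is the fold change from basal to fully activated
  transcription.
* **D-box, activating:** the same activating form driven by delayed
  Dbp (an optional competing-repressor slot covers E4BP4-like inputs
  and is off by default).

The wiring is: Bmal1 ← RRE; Rev-erba ← E-box × D-box; Per2 ← E-box ×
D-box; Cry1 ← E-box × D-box × RRE; Dbp ← E-box.  Default element counts
are Bmal1 R=3; Rev-erba E=3, D=1; Per2 E=2, D=1; Cry1 E=2, D=1, R=2;
Dbp E=3.  All intermediate protein steps (translation, modification,
nuclear import) are merged into one explicit delay `τ` per regulator
gene, measured from the regulator's mRNA peak to its protein's
regulatory action.

Because production is pre-multiplied by `d_x`, species are dimensionless
and a gene decoupled from its regulators relaxes exponentially to its
modulation factor.  Note that this normalization ties the concentration
scale to the modulation factors, so there is no global rescaling freedom
left in the equations; only the products `strength × level` inside each
factor are scale-free.

**PER/CRY repression is promoter-specific.**  Each E-box-carrying
promoter has its own PER2 and CRY1 inhibition constants.  This is the
package's declared design: promoter context (site arrangement,
co-factors, chromatin) sets how strongly the repressive complexes act at
a given E-box, and it is what lets an activation-dominated E-box gene
(sharp morning peak tracking BMAL1 protein, like Rev-erba) coexist with
a derepression-dominated one (later peak set by the PER/CRY trough, like
Dbp) in the same cell.

### Integration

Fixed-step classical RK4 by the method of steps.  Delayed look-ups
interpolate the stored solution with a 4-point Lagrange cubic (linear
within the first grid cell, where the constant pre-history makes the
solution only C0).  The step must satisfy `dt ≤ 0.1 h` and
`dt ≤ min(positive τ)/4` so that every RK4 stage reads only the computed
past; genes with `τ = 0` read the current stage state, which reduces the
scheme to standard RK4 for ODEs (verified against a stiff scipy solve to
<1e−4 relative error).  Default history is 1 for all species; the first
240 h are treated as transient and excluded from all analyses.
Descriptor extraction is dt-convergent: halving `dt` from 0.1 to 0.05 h
moves phases by <0.05 h and the period by <0.01 h.

### Rhythm descriptors and the CT anchor

From the post-transient limit cycle the package extracts, per gene: peak
phase, relative amplitude `(max−min)/(max+min)` over one cycle, and peak
width (time above the half-range level).  The period is the mean Bmal1
inter-peak interval; peaks are refined by quadratic interpolation.
Oscillations count as sustained when consecutive Bmal1 cycle amplitudes
agree within 1%.

Circadian time is anchored declaratively: the upward mean-crossing of
Bmal1 preceding its peak is assigned CT 16 (a cosine-like Bmal1 then
peaks a quarter period later, at CT 22, the canonical late-night Bmal1
peak).  The anchor is one constant applied uniformly to all genes, so
all phase structure is relative geometry of the limit cycle, not a
per-gene adjustment.

### Default parameters

Degradation rates are restricted to [0.05, 2] /h and delays to [0, 12] h
(mRNA half-lives of 20 min–14 h; protein-action lags of up to half a
day).  The shipped defaults place the model in its self-sustained ~24 h
regime with the canonical liver phase ordering; they were chosen once,
by exploring the bounded parameter space, and are the initial values
from which the evolutionary fit starts.  Degradation rates, delays and
site counts stay fixed during fitting.

## Evolutionary fitting

Targets are rhythm descriptors: per-gene peak phase, relative amplitude
and peak width, plus the global period.  The score is a weighted sum of
squared deviations scaled by per-descriptor tolerances (defaults:
period 0.5 h, phase 1 h, relative amplitude 20% of target, width 1 h);
phase deviations use the shortest arc on the 24 h circle.
Non-oscillating candidates receive a fixed penalty of 1e6.  The default
class weights are period 1, phase 3, relative amplitude 1, width 0.5:
peak phases are the best-determined descriptors of expression profiling
and the quantity the model exists to explain, whereas widths differ
substantially between platforms and tissues.  Under equal weights the
amplitude/width terms systematically drag the fitted Rev-erba peak
~2 h past its morning phase — a bias, not a better fit.

Each round draws `population` vectors log-uniformly from per-parameter
ranges (the 24 free regulatory constants; initial ranges span a factor
of 4 around the defaults, fold changes floored at 1), keeps the best 5%
oscillating vectors, and contracts each range to the elite span pulled
80% toward the round's best in log space.  Ten rounds by default; the
initial vector itself is included in the first population so a viable
elite exists from the start.  An all-penalized round restarts with
doubled ranges; three consecutive failures abort.  Everything is
deterministic given the seed.  Candidate evaluation integrates at
`dt = 0.1 h` for speed; the winner is re-measured at 0.05 h.

Self-target recovery (targets generated by a known parameter vector,
ranges spanning it) lands all descriptors within tolerances at modest
budgets — the acceptance surface for this module.

### Control analysis

Every scalar parameter (including the fixed rates and delays) is scaled
by 1±5%; logarithmic sensitivities d(period)/d(ln p) and per-gene
d(phase)/d(ln p) are estimated by central differences and tabulated,
sorted by absolute period control.  Perturbations that kill the
oscillation are flagged rather than dropped.  On the fitted model the
regulator delays rank among the strongest period controls, consistent
with delayed feedback setting the period.

## Clock-controlled genes

A CCG follows the same equation with its production term built from any
subset of {RRE, E-box, D-box} modulators evaluated on the *simulated*
core clock.  Since the drive is a known function of time the equation is
linear; it is integrated exactly (exponential integrator, piecewise
linear drive) on the clock grid.  Peak phases of flat outputs (relative
amplitude < 1e−3) are undefined and such genes are excluded but counted.

Population simulations draw, per gene: `d_CCG` uniform in
[0.2, 0.6] /h (typical mRNA turnover); promoter strength and fold
log-uniform over the range that element class spans in the fitted core
model (each regulator has its own absolute concentration scale under
the dimensionless normalization, so the core promoters — not one
generic interval — define what "weak" and "strong" mean per class; the
strength interval is additionally widened 2× at both ends); and each
regulator's action delay uniform within ±20% of the core model's
fitted delay for that regulator, the scale on which fitted delays vary
between tissue- and condition-specific core models.  The D-box action
lag is the exception: it is held at 2 h, the induction delay of D-box
targets after the Dbp peak.  E-box output promoters default to a
CRY1-dominated repression context (PER2 inhibition 0.5, CRY1
inhibition 2.0): CRY1 is the long-lived, broadly bound E-box repressor
on output genes, while PER2 acts more narrowly; a config switch
samples the repressor strengths instead.  Phase distributions are
summarized by the circular mode over 4 h bins stepped hourly (3 h
overlap), the same binning used for data.

The resulting modes reproduce the element-specific timing: RRE-only
populations cluster near CT 0 (Rev-erb peak + protein lag + half a
cycle of repression release + decay lag), E-box populations around
CT 10, D-box populations near CT 15 (Dbp peak + 2 h + decay lag).

## Harmonics (12 h rhythms)

Multiplying two sinusoidal regulations
`(1 + sin ωt)(1 + A sin(ωt+α))` expands to
`1 + sin ωt + A sin(ωt+α) + (A/2)[cos α − cos(2ωt+α)]`: the product
carries a 2ω component.  For `A → 1, α = 180°` the fundamentals cancel
and a pure 12 h rhythm remains.  `dominant_period` classifies signals by
comparing Fourier power at 24/k h (k = 1…6) over ≥4 cycles.  The same
mechanism operates inside the full model: a CCG whose E-box drive
(peaking in the subjective morning) is multiplied by a D-box drive
delayed into antiphase, at matched modulation depth, produces a
dominant 12 h component (the tests locate this regime by a small grid
scan over the two strengths, folds and the D-box delay).

## Rhythm detection in expression matrices

Biharmonic regression `y = m + a1 cos ωt + b1 sin ωt + a2 cos 2ωt +
b2 sin 2ωt` (ω = 2π/24) is solved by least squares for all probes at
once; rhythmicity is an F-test of the four rhythm coefficients against
the intercept-only model (df 4, N−5).  A probe is called rhythmic when
p < 0.01, relative amplitude > 0.3 and maximum expression exceeds the
platform cutoff (600 by default; 500 for adrenal-like sets) — all
strict inequalities, no multiple-testing correction, matching the
original filtering scheme.  Phase is the argmax of the full fitted
curve on a 0.01 h grid so 12 h-dominated profiles get meaningful peaks;
`phase24` additionally reports the fundamental's phase, which is the
right quantity for phase-accuracy statements about cosine-like profiles
(the full-curve argmax inherits noise from the 12 h terms).  Relative
amplitude is the fitted peak-to-trough range over twice the fitted
mean.  Top-k ranking sorts by relative amplitude with lexicographic tie
breaks; set overlaps are exact identifier intersections.

Type-I error is calibrated: on 10,000 white-noise probes the fraction
with p < 0.01 sits within the binomial band around 1%.

## qPCR normalization

Cp values become quantities `E^(−Cp)` with `E` the per-primer
amplification factor (≤2); each sample is divided by the geometric mean
of three reference genes and each gene rescaled to its maximum (or
mean).  Samples missing a reference gene are dropped with a warning.
The synthetic inverse (known abundances → Cp with per-sample loading
drift and cycle noise) round-trips to correlation > 0.99 at realistic
noise (0.03 cycles).

## ChIP-seq TFAS

Peaks (BED, 0-based half-open, score column 5) are associated with every
gene on the same chromosome whose start-codon first base lies strictly
within 5 kb of the peak center (unstranded absolute distance); both
`gene2peak` and `peak2gene` mapping counts are reported and peaks on
unannotated chromosomes are skipped and counted.  The per-gene score is
`TFAS = Σ score·exp(−distance/d0)` with `d0 = 500 bp`.  Factor targets
are genes with TFAS strictly above the per-factor cutoff (10 for the
E-box activator set, 0.5 for the RRE set); with replicate peak files a
gene is a target if it clears the cutoff in any replicate (union rule).
The three reported lists (A-only, B-only, both) partition the union by
construction.

## Synthetic data

The expression generator emulates a 2 h-resolution, 24 h, 4-replicate
circadian profiling design: a configurable rhythmic fraction follows
`baseline·(1 + relamp·cos(ω(t−φ)))` with phases drawn from a bimodal
von Mises mixture (components near CT 0 and CT 10, mirroring observed
bimodal phase distributions), relative amplitudes uniform in
[0.3, 0.8], ~1% of rhythmic probes carrying a dominant 12 h harmonic,
and multiplicative lognormal noise (CV 10%).  Baselines are lognormal
(median 1500, log-sd 1) so the expression-level filter is informative.
What it does not emulate: platform-specific probe effects,
cross-hybridization, heteroskedasticity beyond the multiplicative
model, or correlated noise between probes — so passing tests certify
the analysis logic, not robustness to array artifacts.

The peak generator plants factor targets on a synthetic chromosome
(genes every 20 kb), giving each target 1–2 peaks at exponential
(mean 1 kb) distances with scores that clear the TFAS cutoff, and a
fraction of non-targets sub-cutoff decoy peaks near the distance limit;
ground-truth membership makes target-set recovery exactly checkable.

All generators are seed-deterministic and emit files that round-trip
through the package's readers.

## Problem sizes used in the shipped analyses

The acceptance script and the end-to-end tests run the fit at
population 500 for 6 narrowing rounds (3000 model evaluations), CCG
populations of 250 genes, null-calibration matrices of 10,000 probes,
and TFAS instances of 100–200 genes — sizes at which every statistic
they compute is stable (the fit's descriptor phases move by well under
the reported tolerances between seeds).

## Known limitations

* Protein dynamics are collapsed into fixed delays; phenomena that
  depend on explicit protein pools (complex stoichiometry, titration)
  are outside the model.
* The five-gene reduction lumps paralogs (Per1/2/3, Cry1/2, Rev-erba/b,
  Rors); per-paralog predictions are not available.
* The evolutionary strategy is a heuristic: it finds descriptor-level
  fits, not global optima, and different seeds yield different
  parameter vectors with similar descriptors (the model is not
  identifiable from descriptors alone — by design, only the rhythm
  phenotype is constrained).
* Bifurcation structure (where oscillations are born/lost) is only
  probed indirectly through perturbation flags in the control analysis,
  not by continuation.
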