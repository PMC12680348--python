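# Methods

## Evolutionary model

Each STR locus is modeled on a grid of `n = 25` allele states at offsets
`k = x − x_opt ∈ {−12, …, +12}` around the optimal allele length `x_opt`
(repeat units). A frequency vector over this grid evolves one generation at
a time through three operators:

**Mutation.** A generalized stepwise model. The per-generation mutation
probability of an allele of length `x` is `μ_x = 10^(log10 μ0 + L·(x − r))`,
clamped into `[10⁻⁸, 10⁻³]`; `r` defaults to `x_opt`, so `μ0` is the rate of
the optimal allele and `L` (log10 units per repeat) captures the widely
observed increase of STR mutability with length. Mutant step sizes are
geometric, `P(|Δ| = d) = ρ(1 − ρ)^(d−1)`, and step direction is biased
toward the optimum: expansion probability `(1 − βρk)/2`, contraction
`(1 + βρk)/2`, clamped to `[0, 1]` and renormalized (the defaults never
reach the clamping regime on the default grid, but the operator is total).
These rules define a row-stochastic 25×25 transition matrix; step mass that
would leave the grid accumulates on the boundary allele, conserving
probability without inventing states outside the modeled range. On grids
whose optimum is closer than 12 units to length zero (short trinucleotides),
rates for sub-unit lengths are evaluated at length 1; with `L > 0` these
states sit at the rate floor and carry negligible frequency.

**Selection.** Allele fitness `w(k) = max(1 − s|k|, 0)`, with `s ∈ [0, 1]`
the homozygote-scale selection coefficient. Diploids mate at random and
fitness is additive (the mean of the two allele fitnesses), which yields the
standard deterministic update: allele `i` is reweighted by its marginal
fitness `(w_i + Σ_j p_j w_j)/2` and the vector renormalized by mean fitness.
`s = 0` is implemented as an exact identity. The zero floor on `w` keeps
weights nonnegative for large `s|k|`; a vector concentrated entirely on
zero-fitness alleles raises a degenerate-fitness error rather than dividing
by zero.

**Drift and demography.** One multinomial draw of `2·N_e` alleles per
generation. `N_e` follows a five-epoch European model: 50,000 burn-in
generations at 7,310 diploids; 14,474 from 5,920 generations ago; a
bottleneck to 1,861 at 2,040; 1,032 at 920; then continuous exponential
growth at rate 0.00307 to 205 generations ago and 0.0195 to the present
(N ≈ 5×10⁵). Epochs are half-open on the right: a size change dated `t`
generations ago is in force at exactly `t`. Growth is continuous
(`N(t) = N₀·e^(rt)`), matching the convention of the coalescent literature
the model derives from, evaluated at integer generations. Queries older than
the model span return the ancestral size.

After the final generation an end-sampling multinomial draw of `N` alleles
(default 1,068, i.e. 534 diploid samples) mimics a finite genotyped cohort.

### Rescaled runs

Full-span simulation costs ~55,920 generations per locus. The engine
supports the classical rescaling used throughout forward population
genetics: with factor λ, population sizes and epoch durations are divided by
λ while mutation rates, growth rates, and selection coefficients are
multiplied by λ (the rate floor/cap scale too; rescaled `s` is clamped at
1, which only affects the `s ≳ 0.1` regime where loci are monomorphic
anyway). This preserves the compound parameters `4Nμ` and `Ns` that shape
allele-frequency distributions, so a λ = 10 run reproduces full-span
heterozygosity distributions at a tenth of the cost (verified: mean neutral
dinucleotide heterozygosity 0.51 rescaled vs. 0.50 full-span). All
user-facing parameters stay in true units; validation protocols and the
test suite run at λ = 10.

## Joint DFE inference

A *class* is the set of loci sharing a canonicalized repeat unit and modal
allele; the modal allele is taken as the optimum (under at least modest
selection the mode almost always matches the optimum in this model — see the
`modal_match_fraction` diagnostic). Selection coefficients across the class
are modeled as `s ~ Γ(a, b)` with `b` the scale, so the DFE mean is `a·b`.

Priors: `a ~ U(0, 1)` (leptokurtic DFEs, as found for SNVs) and the mean
`a·b` lognormal with the underlying normal at mean `ln 0.0003` and standard
deviation `ln 30` (natural logs; the constants are configurable and
estimates are robust to them). Each of `z` rejection-ABC iterations draws
`(a, b)`, one `s` per locus, and a simulated heterozygosity per locus from a
precomputed lookup table; the draw's distance is the mean absolute
difference between the sorted simulated and sorted observed heterozygosity
vectors. The lowest 1% of distances (exactly `ceil(z·0.01)` draws, boundary
ties broken by draw order) are accepted, and the point estimate is the
accepted pair with the median `a·b` (lower median for even counts).
Observed sets larger than 1,000 loci are subsampled without replacement;
production runs use `z = 50,000`, validation runs `z = 2,000`.

**Lookup tables.** Keys are 0 plus every one-significant-digit value in
`[10⁻⁵, 1]` (47 keys); an `s` is served by the key it rounds to, with values
below 10⁻⁵ treated as neutral and values above 1 by the key 1. Each key
holds replicate end-sampled frequency vectors and heterozygosities.
Replicates per key are a Monte Carlo resolution knob: 50 (the default)
suffices for recovery of means ≥ 10⁻³, but with few replicates the accepted
set partially fits replicate-sampling noise, which inflates weak-selection
estimates toward the prior mode. The validation protocols therefore use 500
replicates per key, after which estimates at weak truth converge to the
noise-free limit (the prior truncated at the detection floor, below).

**Per-locus mode** runs the same machinery on a single locus's
heterozygosity over a discrete uniform prior on the table keys and reports
the accepted set's median. It is retained to demonstrate the confounding it
suffers at low-mutation loci (low variation ≈ low μ or high s), and it uses
the same heterozygosity summary as the joint mode so the two modes differ
only in pooling, not in summary statistic.

**Mutation-model selection** fixes `s = 0`, simulates a neutral replicate
pool per candidate model, pools ABC draws uniformly across candidates, and
reports each candidate's share of the accepted draws — an approximation to
relative model likelihoods under a uniform model prior. Shares are a noisy
functional of the finite neutral pools, so comparisons across candidates are
reliable when shares are lopsided (the regime the method is used in).

**Goodness of fit.** For a fitted class (neutral model or gamma DFE), 100
rounds each simulate a matched-size heterozygosity set from the lookup table
and compare it with the observed set by a two-sample, two-sided, asymptotic
KS test; the score counts rounds with p > 0.05. Classes scoring ≤ 50 are
flagged poor-fit and excluded from burden estimates. An optional subsample
cap (e.g. 50 loci) equalizes power across classes of very different sizes.

## Burden estimates

**De novo STR burden** for class `c` with `N_c` loci, optimal-allele rate
`μ_c`, step parameter ρ and DFE mean `s_c`:

    Burden_c = N_c · 2 · μ_c · Σ_{i=−20..20, i≠0} P(Δ = i) · s_c · 0.5 · |i|

with `P(Δ = i) = ½·ρ(1 − ρ)^(|i|−1)` (symmetric truncated geometric, the
k = 0 limit of the mutation model). Mass beyond |i| = 20 is dropped, not
renormalized, and the deficit `(1 − ρ)^20` is reported. The 0.5 converts
homozygote-scale `s` to the cost of one mutant allele. Summing well-fit
classes gives the genome-wide burden; the `scaled` flag halves burdens to
put them on the SNV (heterozygote) scale.

**De novo SNV burden** is the closed form `2·L·μ·s` with heterozygote-scale
mean `s`. Shipped reference categories: nonsynonymous (mean s = 6.6×10⁻³,
0.56 mutations/generation) and conserved noncoding (5.6×10⁻⁴, 2.54/gen),
from published SNV DFE estimates, plus a noncoding category (mean s =
6.5×10⁻⁴, per-bp rate 1.2×10⁻⁸, total target 1.83×10⁹ bp) parameterized by
the fraction of noncoding sites assumed under selection. A reference
genome-wide de novo STR aggregate (scaled mean s = 3.8×10⁻⁴, 13.78
mutations/generation, total scaled burden 0.0062) is included for the
STR-vs-SNV ratios.

**Inherited STR burden.** The DFE of standing variants is biased toward its
neutral tail — an allele far from the optimum that is nonetheless common
today can hardly sit at a strongly selected locus. Each variant is scored by
a frequency-weighted posterior draw: sample 1,000 `s` values from the class
DFE, fetch a simulated frequency vector for each (lookup table), record
`(s, allele frequency)` whenever the observed allele segregates, then draw
one `s` with probability proportional to frequency (normalized over the
recorded pairs). The fitness reduction is `|offset| · s`, with reductions
below 10⁻⁵ rounded to 0, above 1 clamped to 1; offsets beyond 12 repeat
units lie outside the modeled grid and score 0, as do alleles never seen in
any of the 1,000 simulations. Variant offsets are stored signed (allele
minus optimum) and the lookup uses the signed position; the burden uses the
magnitude. Noninherited (de novo or cell-line) alleles are scored
deterministically as `(|k_child| − |k_parent|)·s̄_c`.

## Synthetic datasets

`SyntheticDatasetSpec` + `generate_synthetic_dataset` emulate a genotyped
STR panel for one class: `n_loci` forward-simulated loci with true `s` drawn
from a fixed value or a gamma DFE, end-sampled to `N` alleles (default
1,068), optionally passed through the genotyping-error model (each observed
allele call wrong with probability 0.1%, off by ±1 repeat unit with equal
probability, boundary calls moving inward), and written as the native
tab-separated count table plus a truth sidecar. Everything derives from one
seed and the files are byte-identical across runs. What this emulates: the
sampling noise, error process, and class structure of a real panel. What it
does not: stutter artifacts correlated with allele length, reference-bias
dropout, population structure within the cohort, linked selection, or
mis-specified optima — so passing recovery tests demonstrates correctness of
the inference machinery under the model, not robustness to every artifact of
real genotype data.

## Numerical choices and conventions

* Frequency vectors must sum to 1 within 10⁻⁶ on input; mutation matrices
  are row-stochastic within 10⁻¹²; drift renormalizes exactly via counts.
* `round_s` returns decimal-canonical floats (`float("7e-2")`), so table
  keys compare exactly across serialization.
* Modal-allele ties break toward the smallest |k|, then toward the negative
  (contracted) allele; locus-level modal ties in count tables break toward
  the shorter allele, mirroring the simulator.
* Repeat units are canonicalized to the lexicographically minimal rotation
  over both strands (TG, CA, GT → AC), so biologically equivalent motifs
  share a class.
* Gamma draws with `a` or `b` ≤ 0 denote the degenerate neutral DFE (all
  `s = 0`). The measure-zero prior draw `a = 0` is floored at 10⁻¹².
* Coordinates in the file formats are 1-based metadata only.

## Validation protocol and problem sizes

The test suite validates parameter recovery at desk scale: λ = 10 rescaling,
100-locus datasets (1,000 for the low-mutation contrast, where joint
inference needs several hundred loci), `z = 2,000`, 10 ABC repeats per
dataset, lookup tables at 500 replicates per key. Under these conditions the
median inferred mean `s` falls within a factor of 3 of truth for means
10⁻⁴–10⁻² on a high-mutation dinucleotide class, mutation-model selection
identifies a 10× rate difference essentially always, and genotyping errors
at 0.1% leave estimates within the across-repeat spread.

## Known limitations

* **Detection floor.** Heterozygosity carries no information about
  selection below the drift limit of the demography, `s* ≈ 1/(2N)` over the
  long ancestral epoch (≈ 10⁻⁴ here; the ABC distance is measurably flat in
  the DFE mean below ~3×10⁻⁵). For data generated at or below the floor the
  posterior is the prior truncated at `s*`, whose median is ~1–2×10⁻⁵ —
  estimates for truly neutral or mean-s ≈ 10⁻⁵ classes therefore
  concentrate at that scale rather than at 0, and distinguishing
  "neutral" from "mean s = 10⁻⁵" is at the edge of what the summary
  statistic supports.
* A single symmetric optimum per locus; no dominance, no periodic or
  directional fitness surfaces, no migration or population structure.
* The mutation model is log-linear in length with motif-independent ρ and
  β per class; sequence imperfections and flanking effects are outside it.
* Inherited-burden scoring assumes the class DFE and lookup table transfer
  to the individual's loci; variants at classes with poor model fit are
  excluded rather than guessed.
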