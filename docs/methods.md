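# Methods

## Model

A diploid parent carries two phased haplotypes.  The genome is partitioned
into contiguous chromosome segments; the haplotype breeding value of phase
*j* over segment *i* is `h_ij = Σ_k z_kj · (effect_k/2)`, where `z` is the
0/1 alternate-allele indicator and `effect_k` the estimated
allele-substitution effect.  Effects are stored un-halved (effect files
conventionally carry full substitution estimates); the ÷2 is applied
inside the operations, so the paternal and maternal gamete values of a
mating add up to the offspring's direct genomic value on this scale, and
MGBV equals half a parent's own direct genomic value.

A gamete selects one phase per segment.  Per chromosome, the initial phase
is a fair coin; the number of crossovers follows the configured law
(Poisson with mean 0.3 per chromosome by default, an at-most-one-crossover
Bernoulli variant, or per-junction probabilities taken from the segment
map); each crossover lands on a uniformly chosen segment junction and
flips the phase.  Chromosomes are independent because each restarts with a
fresh coin — crossovers never span chromosomes.  Within-segment
recombination is ignored by construction; imprinting, dominance and
epistasis are not modelled.

MGBV and SDGBV are the mean and the (N−1)-denominator sample SD of the
gamete values (default N = 100 000 replicates).  The Poisson sampler draws
per-junction Poisson(rate/J) counts and flips on odd parity, which is
mathematically identical (Poisson splitting) to drawing the total count
and placing crossovers uniformly, but vectorizes over replicates.

## Exact moments

With `m_s = (h_pat + h_mat)/2` and `d_s = (h_pat − h_mat)/2`:

* MGBV = Σ m_s (exactly, any crossover law).
* Var  = Σ d_s² + 2 Σ_{s<t, same chrom} d_s d_t ρ_{s,t}, where ρ is the
  probability-weighted phase agreement.  For independent junction flips
  (Poisson, map laws) ρ is the product of (1 − 2r) over intervening
  junctions, evaluated by an O(S) recursion; the Poisson per-junction flip
  probability is r = (1 − exp(−2·rate/J))/2 (Haldane on equal
  sub-lengths).  For the at-most-one-crossover law junctions are
  *correlated* and the product form is wrong; the exact pair correlation
  1 − 2·rate·k/J (k junctions in between) is used instead, keeping the
  oracle exactly consistent with the sampler for every law.

The analytic path is the production default (`gamete_method: analytic` in
the pipeline); Monte-Carlo is retained as the reference implementation of
the defining simulation and is cross-checked against the closed form in
the tests (SDGBV within 2% relative at N = 100 000, MGBV within 4 SE) and
against full 2^S enumeration for small segment counts.

## Mating plan

Offspring of a sire × dam pair are modelled normal with
mBV = MGBV_s + MGBV_d and sBV = √(SDGBV_s² + SDGBV_d²); the sire–dam
covariance is fixed at zero (a covariance hook is deliberately left
unimplemented — in closed elite populations the assumption is only
approximate).  Exceedance probability is 1 − Φ((t − mBV)/sBV), degenerate
matings (sBV = 0) fall back to an indicator.  The number of matings for at
least one success with confidence γ is n* = ln(1−γ)/ln(1−p), rounded to
the nearest integer (≥ 1); p = 0 yields an undefined sentinel, rendered
"-" in file output.  γ defaults to 0.999 and nearest rounding is the
default because together they reproduce the most published
required-mating cells; no single rounding rule reproduces all of them,
and the residual cells are off by one.  File output prints probabilities
as percentages with one decimal, saturating at "100" for ≥ 99.95%, and
suppresses N for events whose probability prints as zero.

`plan_matings` ranks a bull portfolio per cow by exceedance probability
(ties: higher mBV, then bull id), excluding the cow's own sire and
offspring via the pedigree and anything rejected by a caller-supplied
ownership filter.

## Segment map

`build_segment_map` always places boundaries at chromosome ends.  Without
hotspot weights, segments are allocated to chromosomes by largest
remainder on SNP counts (≥ 1 per chromosome) and split into
as-equal-as-possible SNP blocks.  With per-interval weights (an empirical
crossover hotspot map), the highest-weight intervals become internal
boundaries, ties falling back to the equal-count positions.  SNP indices
are 0-based with half-open segments; genome positions are 1-based as in
VCF.  Region exclusion (`exclude_region`) zeroes the effects of all SNPs
in a closed base-pair window and recomputes the haplotype table with the
segment structure unchanged, which is how the contribution of a
large-effect region to SDGBV is quantified; the window is an explicit
parameter because no canonical centering rule exists.

## Inbreeding and base frequencies

F_G is the VanRaden GRM diagonal minus one:
`g_ii = Σ(m_ik − 2p_k)² / (2 Σ p_k(1−p_k))`.  SNPs whose base frequency
falls outside (0.01, 0.99) are excluded.  Base frequencies come either
from the mean gene content of genotyped pedigree founders, or from the
gene-content mixed model: per SNP, gene content = μ + u with cov(u) ∝ A,
p = μ̂/2, solved by sparse mixed-model equations with A⁻¹ from Henderson's
rules (with inbreeding).  The variance ratio defaults to 0.01 — gene
content is almost fully "heritable", the parameter mainly regularizes —
and one LU factorization is shared across all SNPs.  F_P is the kinship of
an animal's parents, computed by a memoized kinship recursion in
topological order; the tests pin it to the brute-force tabular-A oracle.

## Validation

The prediction is validated against the haplotype actually transmitted:
for each offspring, the parental-origin phase is identified
(`assign_parental_origin`: per segment, the offspring phase best matching
either sire haplotype is called paternal; ties inherit the previous
segment's call, leading ties stay unknown, and the dam's haplotypes break
ties when supplied), scored genome-wide with half effects, and the
within-progeny-group SD of those values is correlated with the sires'
predicted SDGBV across minimum-group-size cutoffs.  Observed group SDs
use the haploid transmitted values; the dam contribution is deliberately
not subtracted.  Normality of MGBV/SDGBV distributions is reported as an
observed-vs-fitted-normal quantile table rather than a graphic.

## Synthetic data

The gene-dropping simulator emulates a 50k-chip-like regime at reduced
scale: biallelic SNPs in linkage equilibrium among founders, founder
frequencies uniform on [0.05, 0.95], effects normal and scaled so the
founder additive SD is 1 (all gamete statistics are therefore in σ_a
units), descendants produced by the same segment-junction meiosis the
sampler uses, with every transmission recorded as ground truth.  Trait
"reliability" multiplies the estimated effects by the stated reliability
(0.69 for the default protein-like trait), mimicking BLUP shrinkage of
poorly predicted traits; a major-locus option (default: substitution
effect 0.8 σ_a at frequency 0.55, the published frequency of the
DGAT1 K232A variant) reproduces the bimodal SDGBV pattern of a fat-like
trait.  Selection rules `truncation-on-DGV` and `sires-only` (default
sire fraction 0.08–0.1) generate the inbreeding accumulation and
paternal-path trends used in the directional tests.

What the simulator does *not* emulate: population-level linkage
disequilibrium (the predictions do not require it, but origin assignment
is easier than on real data), genotyping error, lethal/defect haplotypes
(which truncate realized variation), and selective genotyping of elite
animals.  Passing tests therefore demonstrate internal consistency and
parameter recovery under the model's own assumptions, not field accuracy
on real chip data.

## Problem sizes and numerical choices

The heavier checks run on deliberately scaled-down designs chosen to keep
the full suite fast while leaving the statistics decisive: 50 animals ×
100 000 gametes for the Monte-Carlo/analytic comparison (the SD of a
sample SD at that N is ≈ 0.22%, an order below the 2% band); 50 sires ×
200 offspring (and a 10–400 log-spread companion) for the progeny-group
validation, where the predicted-SDGBV spread across sires is several
times the sampling noise of a 200-offspring SD, yielding r ≳ 0.95 for the
major-gene trait; a 200-founder, 6-generation cohort for the selection
claims.  "Unimodality restored" after region exclusion is operationalized
as the carrier/non-carrier SDGBV gap collapsing from ≈ 1 within-group SD
to < 0.25 — a group-contrast criterion that is sharper than an omnibus
multimodality test at these sample sizes.  Master seeds are explicit
everywhere; per-animal Monte-Carlo streams are spawned from
(seed, animal index) so population scans are reproducible and
order-independent.  Degenerate inputs are pinned down in tests: SDGBV = 0
iff the two phases agree on every segment, empty regions warn and return
identity, p = 0 gives the undefined mating sentinel, single birth years
give undefined trends.

## Known limitations

Zero sire–dam covariance overstates sBV in highly related pairs; the
normal offspring model is inaccurate in the tails when a single major
locus dominates (the very situation region exclusion is for); the
equal-sub-length Haldane junction probabilities ignore physical junction
spacing (supply a map-law segment map to override); and the
at-most-one-crossover law is a coarse approximation for long chromosomes.
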