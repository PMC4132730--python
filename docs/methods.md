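# Methods

## The crossover placement model

Each bivalent (one pair of homologous chromosomes, four chromatids) receives
crossovers from two independent, superposed point processes on the genetic
scale `[0, chrom_length]`, in Morgans:

* **Class I (interfering).** A stationary gamma-renewal process: inter-event
  distances are Gamma(ν, θ) with scale θ = `chrom_length`/(λ₁·ν), so the
  expected event count on the chromosome is λ₁ and the spacing coefficient
  of variation is 1/√ν. ν = 1 recovers a homogeneous Poisson process (no
  interference); larger ν spaces events more evenly, producing positive
  interference. The first event is drawn from the equilibrium residual-life
  distribution — sampled exactly as U·S with S from the length-biased
  spacing distribution Gamma(ν+1, θ) and U uniform on (0, 1) — so the
  process is stationary from the chromosome start with no burn-in or edge
  effects. Stationarity is verified by test (uniform positions, correct mean
  count, exponential gaps at ν = 1 after probability-integral transforming
  each gap against its window-censoring bound).
* **Class II (non-interfering).** A homogeneous Poisson process with mean
  count λ₂.

The two pathways are superposed without cross-pathway coupling, matching
the genetic architecture of the two CO pathways (interfering ZMM-dependent
class I; MUS81-dependent class II, insensitive to interference). Each event
then engages one maternal and one paternal chromatid, chosen uniformly and
independently per event — the standard no-chromatid-interference
assumption of tetrad analysis. Sister-chromatid exchanges are not modelled.

**Obligate crossover.** When enabled, a bivalent that drew zero events is
redrawn (rejection sampling), which is exactly conditioning on ≥ 1 event:
the event distribution given ≥ 1 event is unchanged, and a test compares
rejection output against explicitly conditioned output (KS on positions,
chi-square on counts). Note that this conditioning raises the *conditional*
crossover intensity everywhere on the chromosome by 1/P(≥ 1 CO), so map
distances of a genotype with the obligate CO enforced exceed the nominal
unconditioned interval lengths; the Poisson control preset leaves it off.

**Chromatid tracing.** An exchange at position p between maternal chromatid
i and paternal chromatid j joins the two *original* chromatid molecules at
p. Tracing therefore composes distal-segment swaps proximal-first: the
scalar tracer applies content swaps in decreasing position order, and the
batched tracer does the same per event-count group with fancy indexing.
The two implementations are checked against each other exactly, and both
against an independent label-walking tracer by exhaustive enumeration of
all placements of ≤ 2 crossovers per interval × all chromatid assignments
(441 cases).

**Units.** All positions and lengths are Morgans internally; centiMorgans
appear only at I/O boundaries. Genetic distance is expected crossovers per
*chromatid*, and each crossover involves 2 of 4 chromatids, so the nominal
coordinate scale is self-consistent exactly when the total bivalent
intensity is λ₁ + λ₂ = 2·`chrom_length`. The default configuration uses
λ₁ = 2·`chrom_length` so that, under ν = 1, an interval of d Morgans
measures 100·d cM by construction; this is the calibration every recovery
test relies on.

**Meiocytes.** A meiocyte outcome draws events independently for each of
`n_chrom_pairs` chromosome pairs (5 for *Arabidopsis*) under the same
per-bivalent model; a pair with ≥ 1 crossover is a bivalent at metaphase I,
otherwise a pair of univalents. With the obligate CO, every meiocyte shows
exactly `n_chrom_pairs` bivalents.

**Randomness.** One numpy `Generator` seeded from `seed` drives a whole
run, consumed in a fixed vectorised order, which makes output byte-identical
across runs at a given seed. Per-meiosis sub-streams were considered and
rejected: spawning 10⁶ `SeedSequence` children dominates runtime while
adding nothing at the population level, where draws are batched anyway.

## Classification

Per interval, each spore reduces to its two-locus genotype; against the
declared linkage phase the tetrad multiset is PD (both parental genotypes,
2:2), NPD (both recombinant genotypes, 2:2) or TT (all four genotypes).
Any other multiset (e.g. 3:1) is non-Mendelian; such tetrads, and tetrads
with any unscorable spore, are excluded whole and reported in `excluded` —
partial scoring would break the ditype logic. The canonical sufficient
statistic is the 3×3 joint (I2a, I2b) class table; finer tetrad
nomenclatures are derivable from the joint table but never needed by the
estimators. Phase defaults to coupling (one homolog carries all three
transgenes); repulsion is defined here as the middle marker in trans,
parental haplotypes (1,0,1)/(0,1,0). Classification is invariant to spore
order and, by construction, to the declared phase.

## Estimation and testing

* **Perkins distance** d = 100·(TT/2 + 3·NPD)/n corrects double crossovers
  through the NPD count. Its variance comes from the multinomial delta
  method, Var(d) = (100²/n)·(t(1−t)/4 + 9q(1−q) − 3tq), cross-checked
  against parametric bootstraps in the tests. When NPD = 0 the formula
  reduces to 50·TT/n; no Papazian-style correction is applied. The
  estimator ignores triple and higher crossover classes, giving a small
  negative bias that grows with distance (about −0.09 cM at 10 cM under
  Poisson placement, exact expectation from per-k class enumeration) —
  negligible at the interval sizes this toolkit targets and below
  Monte-Carlo resolution in the recovery tests.
* **Between-genotype comparison** uses z = (d₁ − d₂)/√(Var₁ + Var₂) with a
  two-sided normal p-value, plus the percent change 100·(d₁ − d₂)/d₂.
* **Interference ratio.** Tetrads are stratified by the conditioning
  interval (recombinant = TT ∪ NPD pooled, versus PD); the Perkins distance
  of the test interval is computed in each stratum and IR is their ratio.
  IR = 1 is tested by the same normal z on the stratified-distance
  difference, which is zero exactly when IR = 1; the difference
  parameterisation is preferred over the ratio because its variance is
  available directly from the two delta-method variances. The IR's own
  standard error (for confidence intervals) uses the ratio delta method,
  SE(IR) = IR·√(Var_w/d_w² + Var_wo/d_wo²).
* **Welch t from summaries** implements the usual Welch statistic and
  Satterthwaite degrees of freedom for (mean, SD, n) group summaries, as
  used for per-cell focus counts; with both SDs zero it degenerates to
  p = 1 (equal means) or p = 0.
* All p-values are two-sided and uncorrected.

Calibration measured by the test suite: the between-genotype Z test holds
its 5% size at n = 1,000 tetrads per genotype. The stratified IR = 1 test
holds its size once the recombinant stratum is reasonably large (empirical
size 5.8% at 10,000 tetrads/dataset, 4.7% at 20,000, 99% binomial band
3.2–6.8%) but is measurably anti-conservative for small strata (6.9% at
4,000 tetrads/dataset, where the stratum holds only ~400 tetrads and ~40
tetratypes). Interpret IR p-values cautiously when the recombinant stratum
is small. Against strong interference (ν = 10) the test rejects in well
over half of datasets and the estimated IR falls far below 1.

## Synthetic data: what it does and does not emulate

The generator stands in for FTL pollen-tetrad tables and metaphase-I
chromosome spreads. It reproduces the features the estimators actually
consume: Mendelian 2:2 segregation, PD/TT/NPD frequencies implied by a
chosen placement model, interference-driven association between adjacent
intervals, obligate-CO bivalent counts. It does not emulate scoring noise
(mis-called or missing fluorescence), segregation distortion, chromatid
interference, or between-plant heterogeneity — so passing tests demonstrate
correctness of the statistical chain under the stated model, not robustness
of scoring on real micrographs. Unscorable/non-Mendelian handling is
exercised through hand-built fixtures instead.

Genotype presets (`wild_type`, `zmm`, `fancm_like`, `mhf_like`,
`poisson_null`) encode the qualitative architecture — strong class I
interference (ν = 8) with a minor class II pathway; class I crippled to
10% in `zmm`; class II derepressed moderately or strongly in the
anti-CO-mutant-like presets. Their numeric values are illustrative and are
not fitted to any published data set: the genetic sizes of the real I2a/I2b
intervals per genotype are not available as printed numbers, so no
calibration to them is attempted.

## Numerical and design choices

* Simulation sizes in tests are chosen to keep Monte-Carlo error well below
  the tested tolerances at desk scale: 10,000 meioses for distributional
  checks, 50,000 tetrads for IR nulls, 200 × 2,000 tetrads for estimator
  recovery, 1,000 replicate datasets for size/power checks.
* Statistical tolerance conventions: 3 SE for means/frequencies, KS and
  chi-square at α = 0.01, binomial 99% bands for rejection rates, 10%
  relative tolerance between delta-method and bootstrap SDs.
* Degenerate inputs raise typed errors rather than returning NaN: zero
  scored tetrads, zero-variance Z tests, empty IR strata, a zero-distance
  IR denominator, obligate CO with zero total intensity.
* Class-count tables are written with `# n=` / `# excluded=` metadata and
  all nine categories; sparse tables are accepted only behind an explicit
  flag. Writers emit RFC-4180 CSV (CRLF); readers accept LF and CRLF.

## Known limitations

* No chromatid interference and no sister exchanges, by assumption.
* The IR = 1 test is anti-conservative for small recombinant strata (see
  above); a resampling-based p-value would be the natural extension.
* Perkins triple-crossover truncation biases distances downward for long
  intervals; mapping functions (Haldane/Kosambi) are out of scope.
* The simulator models one chromosome with three markers; multi-chromosome
  tetrad designs would need a thin wrapper per chromosome.
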