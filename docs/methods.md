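# Methods

## Generative model

One simulated event is one female meiosis of a P1/P2 (Oregon R-like /
w1118-like) heterozygote followed by the recovery cross.

**Bivalent and crossovers.** The bivalent holds four chromatids: two P1
sisters and two P2 sisters. Per arm, a crossover count is drawn from a
categorical prior over {0, 1, 2} and positions are uniform over that arm's
euchromatin (crossovers never fall in pericentric heterochromatin or the
unassembled centromeric satellite). Each crossover joins one of the four
non-sister chromatid pairs, chosen uniformly and independently — no
chromatid interference — and crossover counts are independent across arms —
no crossover interference. These independence assumptions match the
probability arguments the detection model rests on; they are *not*
realistic for fly meiosis (which shows strong positive interference), and
an interference-aware position process is deliberately out of scope.
A crossover exchanges the centromere-distal segments of the two chromatids:
chromatid identity follows the centromere, which is what makes both sisters
of a homolog share their pericentric genotype in every simulated event —
the ground truth the MI/MII classifier relies on.

**Segregation modes.** NORMAL inherits one chromatid of four; MI_NDJ one
chromatid of each homolog; MII_NDJ both sisters of one homolog;
MONOSOMY_RESCUE one chromatid, duplicated. The default mode mixture is
MI 49/63, MII 14/63, rescue 0 — the subgroup sizes of the study cohort this
emulates (49 MI and 14 MII of 63 events).

**Read counts.** The male is backcrossed to homozygous-P2 females and his
offspring are sequenced as one pool. With no male recombination, his two
chromosome-2 copies split Binomial(pool, 1/2) over the pool (drawn once per
sample); each offspring also carries a silent P2 maternal homolog. The
pool's alt-allele frequency at a SNP is therefore
(P1 copies transmitted)/(2·pool) — 0, ≈0.25 or 0.5 by genotype state. Depth
is Poisson per SNP and each read flips allele with the error rate.
Correctly segregating chromosomes (X, 3) are simulated as single-chromatid
tracks: the male is an ordinary heterozygote there, giving a two-state
track with expected frequencies {0, ≈0.25}.

**Defaults and why.** pool = 50 offspring, depth = 30, per-read error =
0.005, SNP spacing = 20 kb. Pool size and depth are unreported for the
emulated experiment; these are plausible values for a barcoded Nanopore
run and are config-exposed. The 20 kb panel is a deliberate scale-down of
the real ~294k-SNP panel (~0.17 kb spacing) so that a 500-event cohort
analyzes in under a minute; all resolution claims below are stated
relative to panel spacing, so they transfer. The crossover-count prior
{0: 0.15, 1: 0.65, 2: 0.20} gives ~1.05 crossovers per bivalent per arm,
approximating a ~107 cM chromosome-2 genetic map.

**Determinism.** A single integer seed drives one `numpy` Generator
through the whole cohort; identical configs produce byte-identical output
files.

## Detection-probability oracle

`detection_probability(mode, positions)` enumerates every equally likely
inheritance outcome of a bivalent (marginalizing uniformly over chromatid
pairs unless fixed) and counts an outcome as detected when its noiseless
expected-frequency track is non-constant in genotype state. This
reproduces the chromatid-sampling argument exactly: 50% single-crossover
detection for normal meioses and MI NDJ (with the 50/25/25 split of
one-recombinant / reciprocal / non-recombinant MI inheritance), 100% for
MII NDJ, 50% for monosomy rescue, 0 for crossoverless bivalents. The
Monte-Carlo pipeline (simulate → sequence → segment → call) is required by
the tests to converge to the enumerated values.

## SNP filtering

Panel rules: keep SNPs homozygous in both parental stocks for different
alleles (drop indels, heterozygous and missing calls); on chromosomes X
and 3 additionally drop SNPs whose variant allele occurs in the compound-
chromosome father's stock. Per-sample rule: mask observations with depth
< 8. Panel-wide rule: drop SNPs whose across-sample variance of alt
frequency is below 0.01, computed with the population (divide-by-n)
estimator over unmasked samples — the estimator is a declared choice, the
threshold is config. SNPs with fewer than two unmasked samples cannot be
evaluated and are kept with a warning. Whole samples whose fraction of
sufficiently covered panel SNPs is ≤ 0.5 can be excluded (the emulated
study dropped 14 of 77 males by eye; the threshold is explicit here).
Filters only mask or drop — counts are never altered — so they are
idempotent and order-stable (panel rules, then masks, then the variance
drop).

## Segmentation and crossover calls

The caller replaces visual inspection of allele-frequency tracks with a
deterministic maximum a posteriori path: binomial emissions
Binom(depth, f·(1−e)+(1−f)·e) over genotype states, a uniform
per-transition penalty (default ln 10⁴ ≈ 9.2 nats, i.e. a transition must
be supported by that much log-likelihood), and a persistence rule that
merges segments shorter than 10 SNPs into their likelier neighbor.

**Split calibration.** The idealized heterozygous frequency 0.25 is only
the expectation over the sperm-pool split; a given male's heterozygous
regions sit at k/(2·pool) or (pool−k)/(2·pool), k ~ Binomial(pool, 1/2),
an SD of ±0.035 at pool 50. With fixed 0.25/0.5 state frequencies,
samples with |k−25| ≳ 8 produce runaway spurious HET↔HOM_P1 segments.
Segmentation therefore runs twice: a first pass at nominal frequencies,
an estimate of q = k/(2·pool) from the depth-weighted, error-corrected
frequencies of first-pass heterozygous segments (each segment folded onto
[0.25, 0.5) since its carrier chromatid is unknown; clamped to
[0.25, 0.42]; nominal 0.25 kept when fewer than 20 HET SNPs exist), and a
second pass over four emission sub-states {0, 0.5−q, q, 0.5} that collapse
onto the three genotype states. Transitions between the two heterozygous
sub-states are never emitted as crossovers: both are the HET genotype, so
reciprocal-recombinant inheritance stays undetectable, as the detection
model requires.

**Persistence and track ends.** The 10-SNP merge rule sets the caller's
resolution scale: genotype features shorter than 10 panel SNPs (200 kb at
the default panel) are by construction not called, which with the
no-interference simulator silently absorbs the ~2% of double-crossover
arms whose transitions fall closer than that. A short *terminal* segment
is different: a genuine crossover near a telomere leaves nothing else, so
terminal segments at telomeric track ends are kept when their emission
advantage over the neighboring state exceeds the transition penalty.
Centromeric track ends get no such exemption — crossovers do not occur in
the assembled pericentric heterochromatin, and an exemption there lets
rare 2-SNP noise bursts corrupt the pericentric state that the division
call reads.

**Call intervals.** A call's flanking interval is the profile-likelihood
support set of the boundary: every split position within 10 nats
(`boundary_support`) of the best split. At clean boundaries
(HET↔HOM_P2, ~23 nats per SNP) this collapses to about one SNP interval;
at HET↔HOM_P1 boundaries (~3–4 nats per SNP at depth 30) it spans a few
SNPs, honestly reflecting that the breakpoint is only localized to that
window. The reported midpoint is the center of this interval. Direct
HOM_P1↔HOM_P2 transitions are flagged rather than counted as single
crossovers — impossible from one exchange in a two-chromatid male, they
are the monosomy-rescue discriminator. A state mismatch between the two
segments abutting the centromeric gap is emitted as a gap-interval call
(an exchange inside the SNP-free satellite); arms without proximal
coverage yield "undetermined" rather than silence.

## Classification

The division call reads the state of the innermost segment on each arm
within the pericentric window (heterochromatin plus 1 Mb of euchromatin):
HET ⇒ MI, either homozygous state ⇒ MII. Arms that disagree, or absent
pericentric coverage, yield an explicit undetermined call — never a
silent resolution. Monosomy rescue: tracks with no heterozygous segment
anywhere are "candidate" when a HOM↔HOM switch exists (within an arm or
across the gap) and "MII-or-rescue ambiguous" when uniformly homozygous —
the two are genuinely indistinguishable for a non-recombinant duplicated
chromatid.

Cause categories follow the strict precedence NO_CO > DISTAL_CO >
PERICENTRIC_CO > OTHER: no observable crossover; all crossovers within
the distal 24% (per arm by default on a metacentric, per chromosome on a
telocentric; configurable); at least one crossover in heterochromatin or
the proximal 15% of the arm's euchromatin; anything else. The 24% and 15%
zone fractions are marker-interval-derived constants of the comparison
scheme, not fitted values. On pathological maps where a call is both
distal and pericentric, the precedence applies and a warning is logged.

## Statistics

- Crossover-class fractions per event class cap counts at 2; the MII
  single-crossover fraction is halved when the detection adjustment is on
  (reported alongside the raw value, never renormalized; double-crossover
  fractions are never adjusted).
- The two-proportion z test uses the pooled estimator with the Yates
  continuity correction capped at |p̂₁−p̂₂| (the `prop.test` convention);
  corrected is the default and the result records which variant ran.
  One-tailed directions must be supplied by the caller.
- The Mann–Whitney test enumerates all group assignments of the pooled
  values when n₁+n₂ ≤ 12 — the value-based U handles ties, so identical
  samples give p = 1 exactly — and otherwise uses the normal
  approximation with tie and continuity corrections. The approximation's
  worst-case deviation from exact enumeration is below 0.005 from about
  18 observations per group.
- The coefficient of exchange divides binned crossover midpoints by
  events assayed and multiplies by the chromatid-sampling correction
  (×2 for NORMAL and MI, ×1 for MII; toggleable). The normalization is a
  documented choice of this package.
- Cross-chromosome comparisons (chromosome-2 crossover strata vs mean
  crossovers on X/3) use MI events only by default and skip empty strata
  with a notice.

## What the simulator does and does not emulate

It emulates: the four-chromatid inheritance logic and its detection
probabilities, the backcross dosage arithmetic including the finite
sperm-pool split, depth and per-read error noise, missing data through
the depth mask, and all four segregation classes. It does not emulate:
crossover interference (real double crossovers are much more dispersed
than the uniform prior's), realistic SNP density or spatial clustering,
mapping/alignment artifacts, copy-number or coverage biases from adaptive
sampling, or viability selection beyond the mode mixture. Passing tests
therefore demonstrate correctness of the inference machinery under the
stated noise model, not performance on raw Nanopore data.

## Numerical choices and degenerate inputs

State frequencies are clipped to [1e-12, 1−1e-12] before logs. Viterbi
ties resolve to the lower state index (deterministic). Empty tracks give
empty segmentations; empty cohorts give valid empty summaries; a
zero-depth SNP has undefined frequency and is always masked by the depth
rule. Support intervals are clamped to the two segments flanking a
boundary. Monte-Carlo batch segmentation processes samples in chunks of
2,000 to bound memory. Problem sizes used by the test suite — 500-event
recovery cohorts and 20,000-meiosis detection runs at the 20 kb panel —
were chosen so the whole suite completes in a few minutes on one CPU.

## Known limitations

- Breakpoint localization at HET↔HOM_P1 boundaries is intrinsically
  ~1 SNP noisy at depth 30; the support intervals express this, but
  midpoints should not be over-interpreted at sub-interval scale.
- The split-fraction estimate assumes at least one sizeable heterozygous
  region; fully homozygous samples fall back to the nominal 0.25 (their
  states are far apart, so calibration is not needed there).
- Cross-gap calls compare single flanking segments; two exchanges inside
  the gap would cancel and stay invisible, as in the real assay.
- NDJ *rates* are out of reach by design: the recovery cross has no
  normal-disjunction denominator.
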