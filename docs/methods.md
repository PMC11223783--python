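# Methods

`mitovar` detects homoplasmic and heteroplasmic variants on a single
mitochondrial contig from aligned short reads.  This note records the
models, the tunable parameters, the simulator's scope, and the numerical
and design choices behind them.

## Bayesian SNV/heteroplasmy calling

At each reference position the caller considers four homoplasmic
hypotheses HOM(X), X ∈ {A, C, G, T}, and one heteroplasmic hypothesis
HET(M, m, f) for every unordered pair of bases observed in the column,
where M is the better-supported (major) base and the minor fraction f is
fixed at its empirical estimate f̂ = n_m / (n_M + n_m).  Fixing f at f̂
rather than integrating over it keeps the computation closed-form and is
accurate whenever the column is deep enough for a heteroplasmy to be
callable at all (tens of minor reads).

The likelihood of one observation with base b and Phred quality q uses
the standard error model with e = 10^(−q/10), clamped to [10⁻⁶, 0.75]:

    P(b | HOM X)       = 1 − e        if b = X, else e/3
    P(b | HET M, m, f) = (1 − f)·P(b | HOM M) + f·P(b | HOM m)

Column log-likelihoods are sums over the retained observations, computed
over (base, quality) count classes — the likelihood is order-invariant,
so the multiset suffices.

The prior puts mass 1 − θ_het on the homoplasmic hypotheses, apportioned
by a per-position population allele-frequency table, and θ_het (default
0.01) spread evenly over the column's candidate heteroplasmies.  The
frequency table is optional TSV input (`pos, A, C, G, T`); absent
positions and absent tables fall back to uniform 0.25, so no external
download is required.  Loaded frequencies are floored at 10⁻⁴ and
renormalized, preventing −∞ log-priors at alleles a population panel
has never seen.  Posteriors are normalized in log space (log-sum-exp);
the suite asserts Σ posterior = 1 ± 10⁻¹² on every evaluated column.

The maximum-posterior hypothesis becomes the call.  Ties are broken
toward the reference-containing hypothesis, then lexicographic base
order, so output is deterministic.  A heteroplasmic selection must clear
two gates, otherwise the column falls back to its homoplasmic
(major-allele) reading:

* the non-reference allele level L ≥ `min_vaf` (default 0.02, the 2%
  heteroplasmy detection floor, user-adjustable);
* the minor allele has ≥ `min_minor_per_strand` (default 2) observations
  on **each** strand, suppressing strand-biased artifacts.

Columns below `min_depth` (default 10) are skipped.  When the selected
hypothesis contains no reference allele at all, the major allele is
emitted as a homoplasmic-style call and the minor as a gated
heteroplasmy.  Quality floors for pileup inclusion default to base
quality ≥ 20 and mapping quality ≥ 20, both configurable.

## Indel calling and fusion merging

The indel caller is deliberately naive: insertion/deletion observations
from the CIGARs are grouped by (anchor position, kind, sequence), and a
group is called when its fraction of the anchor's base depth reaches
`min_vaf` with ≥ 2 supporting reads per strand and anchor depth ≥
`min_depth`.  There is no haplotype assembly and no homopolymer-aware
error model, so it will underperform assembly-based callers in hard
repeat contexts on real data; it exists so the fusion workflow is fully
exercisable, and the merge step accepts any external indel VCF in its
place.

Before merging, calls are normalized: multiallelic records are split one
record per alternate allele, and each biallelic record is left-aligned
to its parsimonious form (drop shared trailing bases, extending left
from the reference when an allele would empty; then trim shared leading
bases).  The procedure is idempotent and is verified against an
enumeration oracle that lists every equivalent VCF representation of a
variant and selects the left-most most-parsimonious one.  A variant
whose canonical form would need extension past position 1 is rejected
rather than silently misplaced.

The fusion merge takes indel records from the indel call set and SNV
records from the Bayesian call set; SNV-type records in the indel
caller's output are discarded.  When both sets report a variant at the
same position, the indel wins.  The collision key is the position alone,
not the allele pair — overlapping reference spans that start at
different positions do not collide, which is the simplest reading of
"the same position" and is documented here as a choice.

## Binomial minimal trusted VAF

At depth N with per-base error probability p, sequencing error alone
produces Binomial(N, p) alt reads.  The minimal trusted alt count is

    k* = min { k : P(X ≥ k) < α },   X ~ Binomial(N, p),

and k*/N is the minimal trusted VAF.  α defaults to 0.05 with a strict
tail inequality; both are explicit configuration.  p is derived from the
mean base quality of the alt-supporting observations when the call
carries one, else from the column mean.  The tail is evaluated through
the regularized incomplete beta function (scipy's binomial survival
function) with an exact integer-index search, and the suite checks it
against an all-integer exact-arithmetic oracle over a grid up to
N = 10⁴.  Calls with alt support below k* are flagged
(`low_vaf_for_coverage`), never removed — the comparison is on alt read
counts, not on the rounded VAF, which avoids ties at k*/N.  The mean of
k*/N over covered positions is reported per sample as the mean
detectable VAF; at 2000× and Q30 it sits near 0.003, comfortably below
the 2% calling floor.

## Subsampling

Deep samples can be subsampled to a target mean coverage (default
2000×).  The kept fraction is min(1, target/mean), and the keep decision
per read is a keyed hash of the read name mapped to [0, 1), compared to
the fraction.  Because the decision depends only on (seed, name), the
kept set is invariant under input reordering, mates sharing a name stay
together, and re-runs are byte-identical.  The static default seed is 42
and overridable.  At depths well above the target, full and subsampled
analyses yield identical variant sites; variants whose observed fraction
straddles the detection floor are the one place the two can differ, as
with any resampling.

## Quality control

Every sample is checked before calling: mitochondrial contig name
(default accepted set {chrM, MT, chrMT, NC_012920.1, rCRS}), mean
coverage ≥ 50× by default, and mean base/mapping quality floors.  All
checks always run and every violated reason is reported, so an excluded
sample gets complete feedback; statistics (mean/median coverage, mean
MAPQ, mean base quality, % bases ≥ Q20, malformed-read tally, mean
detectable VAF) are filled regardless of the outcome.  The published
workflow states that coverage and contig checks exist but not their
cutoffs, so all thresholds here are explicit configuration.

## The read simulator and what passing tests show

The simulator generates a uniform-random ACGT contig (default 16,569 bp,
the human mtDNA length), spikes a truth set (default 35 heteroplasmic
SNVs + 8 heteroplasmic 1–5 bp indels per sample, positions ≥ 10 bp
apart, VAFs uniform on [0.02, 0.5] — the published VAF spectrum of the
gold standard is not printed, so the range spans the detection floor to
balanced heteroplasmy), and emits uniformly placed single-end 150 bp
reads at the requested coverage.  Each read carries every overlapping
truth variant independently with probability equal to its target VAF;
indels are realized directly in the read sequence and CIGAR, so reads
arrive "pre-aligned".  Sequencing errors are injected per base at the
Phred-implied rate (constant Q30 by default) with uniform substitution
among the other three bases.  One seed fixes the reference, the truth
sets, the reads and therefore the entire downstream evaluation.

The benchmark regenerated by `scripts/acceptance.py` and the acceptance
tests uses 30 such samples at 2000×, mirroring the published evaluation
design at desk scale.  What the simulator does **not** model bounds what
passing tests mean for real data: no alignment or mapping error, no
platform-specific error profiles (homopolymer, GC), no NUMT-derived
reads, no contamination mixtures, no paired-end overlap, no haplogroup
backbone variants (each sample is reference plus spikes), and the genome
is treated as linear — the circular junction at positions 1/16569 is
not represented.  Results on this benchmark therefore demonstrate the
correctness of the calling, normalization, merging and coverage
mathematics, not robustness to alignment artifacts.

A subtlety at the detection floor: a variant spiked at exactly 2% has,
by construction of the Bernoulli carrier model, roughly even odds of an
observed fraction below 0.02, so per-variant recall at the floor itself
hovers near 50% while recall strictly above the floor is complete.
Averaged over the uniform VAF spectrum this costs ≈ 0.1–0.2 sites per
43-variant sample, matching the sub-unit false-negative rates the
benchmark reports.

## Numerical and engineering choices

* Pileup observations are stored as a dense (position, strand, base,
  quality) count tensor filled by one vectorized `bincount` pass over
  pure-match reads; reads with indels or clips are walked individually.
  Deletions contribute no base depth; indel VAF uses base depth at the
  anchor.
* Reads overhanging the contig end are truncated and tallied; duplicate-
  flagged, secondary, supplementary and unmapped reads are excluded
  (duplicates toggleable).
* Coordinates are 1-based inclusive in all public types and VCF output;
  0-based arrays are private.
* SAM text is the mandatory interchange (parsed record-wise so a
  malformed read is tallied and skipped, not fatal); BAM is supported
  through pysam.  VCF 4.2 output declares all FILTER/INFO/FORMAT keys it
  uses and round-trips through the bundled reader.
* Batch runs treat samples as independent units; any execution order or
  concurrency yields output identical to a sequential run.

## Problem sizes used by the shipped checks

The test suite exercises hand-checkable fixtures (tens of reads), mid-
size simulations (kilobase contigs, 100–300×) for properties, and one
full-design benchmark (30 samples × 16,569 bp × 2000×) shared by the
acceptance tests and `scripts/acceptance.py`.  The subsampling
equivalence check uses an 8 kb contig at 10,000× subsampled to 2000×.

## Known limitations

Single contig only; no local realignment or base-quality recalibration;
no overlap-aware mate handling (overlapping mates would be double-
counted); position-only fusion collision; the indel stand-in makes no
claim of parity with assembly-based callers; circular-genome artifacts
at the reference junction are out of scope.
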