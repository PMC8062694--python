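# Methods

## Scope and model

`darkpep` implements a proteogenomic identification–quantification cascade
for peptides encoded outside annotated coding sequence, plus the
synthetic-data generators used to validate it. The statistical core is a
class-specific target–decoy false-discovery-rate estimate for the novel
peptide class; everything downstream (locus grouping, differential
expression, tissue specificity, dark-antigen screening, RNA-seq support)
consumes its accepted peptides.

### Search database

Targets are (i) known proteins, (ii) variant proteins produced by applying
missense substitutions to known proteins, and (iii) three-frame translations
of noncoding transcripts (pseudogene, lncRNA, repeat). Translation splits at
stop codons and keeps stop-free segments of ≥ 7 residues
(`min_segment_len`, configurable): whether to split at stops or demand full
ORFs is a genuinely open design point, and stop-splitting with a short floor
is the common proteogenomics-database practice — it admits every tryptic
peptide long enough to be detectable while keeping the database small.
Codons containing N translate to X, and X never matches in peptide lookups.
Decoys are full end-to-end protein reversals of every target (no
pseudo-reversal at K/R); palindromic targets are logged since their decoy is
uninformative. Each noncoding entry records the three genomic positions of
every residue's codon, so peptide placement later is exact coordinate
arithmetic, not re-alignment.

Variants are restricted to single-residue missense substitutions;
indels/frameshifts are out of scope.

### Peptide classes and the class-specific FDR

A peptide is **known** when, after stripping modification annotations and
collapsing I→L (isoleucine and leucine are mass-indistinguishable), it is a
contiguous substring of any known protein; **variant** when it instead
matches a variant sequence; otherwise **novel**. An optional ≤ 1-substitution
near-match mode (off by default) emulates more permissive homology removal.
Substring matching subsumes the tryptic-peptide case, so the
"tryptic-or-substring" rule reduces to one scan.

Before estimating novel-class FDR: target PSMs classified known/variant are
discarded, and decoy PSMs whose as-read peptide is a known tryptic peptide
(≤ 2 missed cleavages, length 7–45) are discarded. PSMs are collapsed to the
best score per peptide (peptide-level FDR is the default because results are
reported as peptide counts; a PSM-level mode exists). With target scores
{tᵢ} and decoy scores {dⱼ},

    FDR(s) = #{d ≥ s} / #{t ≥ s},    q(s) = min_{thresholds ≤ s} FDR(s'),

ties counting decoys against targets (conservative), no +1 correction and no
π₀ estimate — the plain decoy/target ratio. Acceptance is q ≤ α, default
α = 0.01. With zero surviving decoys all q-values are 0 and a warning is
emitted.

The point of class specificity: known-class PSMs score far higher than novel
ones, so a single FDR over all classes lets the known mass inflate the
target counts and drags the acceptance threshold into the score region where
incorrect novel matches live. `global_fdr_novel` implements that baseline
for comparison; on the standard simulation its realized novel-class
false-discovery proportion is roughly twice the class-specific one (about
2% vs 1.4% pooled over 20 simulated searches at α = 0.01).

### Genomic annotation

Accepted peptides are located by scanning every mapped noncoding entry
(I/L-insensitively, consistent with identification) and merging the matched
residues' codon positions into maximal contiguous blocks — a junction
peptide yields multiple blocks summing to 3× its length. All placements are
kept; repeat-derived peptides in particular are *not* discarded for
multi-mapping (multi-copy retroelement ORF products are a real signal class)
— a peptide whose placements all fall inside annotated repeat copies becomes
one retroelement locus grouped by family.

Each placement receives exactly one origin category under the fixed,
configurable precedence

    pseudogene > lncRNA > retroelement > utr > exonic_altframe >
    intron_exon_boundary > intronic > upstream > downstream > intergenic.

Only the head of this order (pseudogene first) is externally constrained;
the rest is a documented package choice, roughly "annotated noncoding gene
before coding-gene-relative before positional". `exonic_altframe` requires
CDS overlap on a *different* reading frame (opposite strand counts);
same-frame overlap falls through, since such a peptide would have been
removed as known. Upstream/downstream require ≤ 1 kb from the nearest UTR
boundary of a coding gene. Intergenic placements are clustered by
single linkage within 10 kb on the same strand (window configurable; the
grouping key for gene-associated categories is (host gene, category) rather
than coordinates). Loci with fewer than 2 unique peptides are dropped
(`k_min_peptides`), and pseudogene loci are tagged with their parental
gene's function class from a user-supplied lookup (`unannotated` when
missing).

Coordinates are 0-based half-open internally; GFF3/BED conversion happens
only in the I/O layer. Writers sort deterministically so write→read→write is
byte-identical.

### Quantification and differential testing

Label-free mode sums member-peptide log2 MS1 intensities per locus and
sample; a locus is missing only when all members are missing. Isobaric mode
takes the median member log2 ratio against the internal reference channel;
peptides with missing/non-positive reference are excluded with a warning.
Missing values are never imputed — every test uses complete observations
(complete pairs for the paired *t* test; ≥ 2 non-missing samples per group
for the Welch test). Loci failing the requirement are reported untested.
Zero-variance nonzero differences are degenerate: the p-value is floored at
the smallest positive float and flagged rather than reported as 0.
"Adjusted p" means Benjamini–Hochberg across tested loci. Locus-level
label-free sums are not re-normalized across samples.

Fold change is linear: 2^(mean tumor log2 − mean normal log2) over
non-missing values.

Tissue specificity: detected in 1 tissue → tissue-specific, 2–14 →
nonspecific, ≥ 15 → ubiquitous (`ubiquitous_min = 15`). The two inner band
edges overlap in common verbal statements of this rule; the package keeps
"ubiquitous = at least 15" verbatim and closes nonspecific at 14.
Detection means ≥ 1 quantified member peptide in ≥ 1 sample of the tissue;
no intensity floor. Recurrence bins use the within-dataset missing fraction
on half-open intervals [0,.25), [.25,.5), [.5,.75), [.75,1] (boundary
membership is a documented choice).

### Dark-antigen screening

All overlapping 9-mer windows of the translated segments of surviving loci
(segments that contain at least one accepted peptide of the locus) are
scored by three components in [0,1] — MHC class I binding, proteasomal
C-terminal cleavage, TAP transport — and combined additively:

    combined = mhc + 0.225·cleavage + 0.025·tap.

The phrase "weighted average" and the additive convention of the combined
MHC/cleavage/TAP predictors conflict; with weights of 0.225 and 0.025 the
additive form is the one those weights belong to, so it is the default and a
normalized weighted-average mode (`combination="normalized_average"`) is
provided rather than guessed silently. Scores become %-ranks against a
frozen background: `background_size = 1000` 9-mers sampled uniformly (with
replacement, seeded) from a supplied natural proteome and scored
identically; rank = 100 · #{background ≥ score}/N, ties counting against
the query. Candidates require %-rank ≤ 0.5 and source-locus fold change
≥ 1.5; the fold-change criterion applies only where a matched-normal fold
change exists. Identical 9-mers from different loci are reported per locus.

The built-in reference scorer is a deterministic toy with the same interface
as an external predictor plugin (9-mer + optional allele tag → three reals):
an anchor-position weight matrix over peptide positions 2 and 9 for MHC, a
C-terminal residue lookup for cleavage, and a normalized Kyte–Doolittle
hydropathy mean for TAP. It is *not* a trained immunological model — it
exists so ranking, backgrounds, and thresholds can be tested exactly; its
component tables are fixed literals, and `optimal_9mer`/`pessimal_9mer`
exploit the score's per-position separability to construct guaranteed
extreme binders for planted-recovery tests.

### RNA-seq support

A read supports a peptide placement when its reference span (from the
CIGAR) overlaps any placement block by ≥ `min_overlap` (default 1) bases
and its NM edit distance is ≤ `max_mismatch` (default 1); one count per
read per placement. Junction handling (any block vs all blocks) is a flag;
any-block is the default. Reads without an NM tag fail the filter unless
`missing_nm="zero"`. Input is SAM text at desk scale, read by a minimal
record scan so malformed or unmapped records are skipped and counted
instead of aborting; the scan is cross-checked against pysam in the test
suite. Spliced-alignment awareness beyond reference-span arithmetic is out
of scope.

## The synthetic world

`generate_world` lays out 3 chromosomes (capacity-checked; exceeding the
cap raises a sizing error) holding, by default, 40 coding genes (5′/3′ UTRs,
1–3 introns, CDS of 80–150 codons, 1 kb flanks, mixed strands), 12
pseudogenes, 10 lncRNAs and a 5-copy LINE-1-like repeat family. Pseudogenes
copy a parent CDS (without its stop codon) and apply substitutions at
`pseudogene_divergence = 0.08` per nt — enough that a typical pseudogene
yields several tryptic peptides absent from the parent; an indel mode is
deliberately absent so frame bookkeeping stays exactly testable. lncRNAs
carry one planted stop-free ORF (80–160 codons) and are sometimes
two-exonic, so junction-spanning peptides occur. Repeat copies diverge by
0.5%, so most repeat peptides map to every copy. All randomness flows from
one root seed through named substreams (`layout`, `genes`, `psms`, `quant`,
…), so stages are individually reproducible and a fixed config serializes
byte-identically.

Ground-truth novel peptides are tryptic peptides (length 7–30, no X) of the
world's translated noncoding segments that do not occur in the known
proteome under I/L collapse, up to 12 per noncoding gene.

PSM simulation draws class-conditional Gaussian scores — the pipeline needs
rank behavior, not any engine's score semantics — with defaults
known ~ N(4,1), correct novel ~ N(2.5,1), and incorrect/decoy ~ N(0,1),
and per-class PSM counts {known: 8000, novel_true: 700, novel_false: 600,
decoy: 600}. These
conditions make the class-specific-vs-global contrast structural: the known
class is large and high-scoring (so a global estimate is diluted), incorrect
novel matches and decoys share the null distribution, and the surviving
decoy count is comparable to the incorrect-target count so the novel-class
estimate is approximately calibrated (slightly anti-conservative without the
+1 correction; realized FDP at α = 0.01 runs near 1.5% and stays under 3%).

Quantification simulation gives each peptide a baseline log2 intensity
~ N(20, 1.5) constant across samples, adds i.i.d. noise (sd
`quant_noise_sd = 0.25`), adds the planted log2 effect
(`upregulated_effect = 1.0`) to every member peptide in tumor samples of
planted loci (11 by default), and masks entries completely at random at
`missingness_rate`. The differential-recovery and null-calibration
experiments run at zero missingness: under sum-summarization, a
completely-at-random missing peptide shifts a locus sum by an entire
baseline (~20 log2 units), which is a property of MCAR missingness colliding
with summed summarization, not of the test — real missingness concentrates
in low-abundance peptides. The missingness machinery is exercised where it
is scientifically load-bearing: detection, recurrence binning and
cross-dataset overlap. Dataset-detection simulation gives each locus a home
dataset plus recurrence in other datasets with probability 0.3 (pseudogene
loci) vs 0.09 (others), emulating the observation that pseudogene
translation recurs across cohorts far more than other origin classes.

Tissue panels plant the three expression classes directly (ubiquitous loci
detected in 15–31 tissues, nonspecific in 2–14, specific in 1). Read
simulation emits fixed-length 100 nt single-end reads, CIGAR all-match,
with Binomial(100, `mismatch_rate`) substitutions encoded in the read
sequence and the NM tag — the minimal valid SAM that still exercises the
mismatch filter.

What passing tests therefore show: the estimators and filters are correct
and calibrated under i.i.d. Gaussian scores, MCAR missingness, uniform
random placement, and an exactly known proteome. They do not show
robustness to correlated PSM scores, abundance-dependent missingness,
chimeric spectra, homology beyond I/L and planted divergence, or real
MHC binding physics.

## Problem sizes and numerics

The test suite and the acceptance script use: 20 simulated searches of
~9,900 PSMs for FDR calibration; 73 loci × 8 pairs × 20 seeds plus a
500-locus null for the differential experiments; a 219-locus, 31-tissue
panel; 10,000 random placements against the category oracle; and ~1,000
random instances per brute-force oracle (q-values, translation, %-rank,
read counting). These sizes were chosen so the full validation runs in a
few minutes on one CPU while keeping Monte-Carlo margins comfortable.

Numerical details worth knowing: q-value monotonization uses a cumulative
minimum over ascending scores; score ties are broken against the target;
p-values of degenerate (zero-variance) tests are floored at the smallest
positive double and flagged; BH adjustment spans only tested loci;
`%`-rank backgrounds are frozen per (scorer, seed) and bit-stable.

## Known limitations

- The BLASTP-equivalent known filter is exact substring under I/L collapse
  (optionally ≤ 1 substitution); no alignment, no e-values.
- Coordinate mapping relies on construction-time provenance; there is no
  genome-wide re-alignment, so peptides from unannotated duplications would
  be missed.
- The reference epitope scorer is a toy; real screening requires an
  external predictor behind the plugin interface.
- SAM handling is text-mode and desk-scale; binary alignments need
  conversion upstream.
- Isobaric normalization, batch correction, and imputation are deliberately
  absent.
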