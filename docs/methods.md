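# Methods

## Problem and model

Total-genomic-DNA sequencing of a plant yields reads from three compartments
at very different depths: plastid ≫ mitochondrion ≫ nucleus, because of
organellar copy number.  Plant mitochondrial genomes additionally carry
large integrated stretches of plastid DNA (MTPTs).  When reads are aligned
to the mitochondrial reference, plastid-origin reads pile up on those
integrated stretches; wherever the integrated copy has diverged from the
extant plastid sequence, the mixed pileup looks like intra-individual
polymorphism (heteroplasmy).  In date palm roughly 10.3% of the 715 kb
mitochondrial genome is plastid-derived (46.5% of the plastid genome), so
naive organellar SNP calling is dominated by this artifact.

The pipeline implements the conservative remedy: align every read
separately to the plastid and mitochondrial references and discard every
read that maps to both before SNP calling.  Record subtraction from the
original alignments replaces the original study's re-mapping of the
filtered read set; for an ungapped single-best-placement aligner the two
are equivalent, and subtraction keeps the stage idempotent and cheap.
Filtering is by read identity by default (a cross-mapping mate removes only
itself); a stricter pair-level mode is available behind a flag.  A read
counts as "mapped" irrespective of MAPQ — mapping-quality thresholds belong
to SNP retention, not to the filter.

## SNP calling

Pileups are built from ungapped alignments; reads below the MAPQ threshold
are excluded at this stage.  Retention requires read depth ≥ 10, MAPQ ≥ 20
and SNP quality ≥ 15 (the published thresholds; all configurable).

SNP quality is a defined binomial-tail score.  With per-base error
`e = 10^(-mean_baseq/10)` and `k` reads supporting the top non-reference
base out of depth `n`:

    Q = min(99, -10 * log10 P(X >= k)),   X ~ Binomial(n, e)

This is a reproducible stand-in for an upstream caller's QUAL column (whose
model the source analysis inherited from its tooling and is not specified);
no attempt is made to reproduce published Quality values numerically, and
no acceptance quantity depends on them.  One consequence worth knowing:
the score treats the total error rate as the rate for a single alternate
base (a ×3 conservatism), and at a fixed Q ≥ 15 cut over tens of thousands
of columns, i.i.d. sequencing error alone will clear the bar at a handful
of columns (order 10⁻³ per column at 100×, Q20 bases).  This low-fraction
background is unrelated to the cross-mapping artifact, which is why the
artifact-elimination experiment (below) uses error-free reads.

The alternate allele is the most frequent non-reference base, ties broken
alphabetically.  Multi-allelic columns emit one record with the runner-up
base noted separately (supported by ≥ 2 reads), mirroring the printed
tables' two-alternate rows which count once.  Bases that are neither
reference nor primary alternate contribute to read depth but to neither
depth field — the arithmetic the published tables obey (e.g. 21 = 0 + 20 +
1 other).

Zygosity follows the rule the printed tables encode typographically: a call
is **heteroplasmic** exactly when both reference- and alternate-supporting
reads are present, **homoplasmic** when the reference depth is zero.  The
rule is derived from the tables (every asterisked row and only asterisked
rows have both depths positive); the source text never states it
explicitly.

## Annotation

Context labels partition sites into coding (S/NS), intron and intergenic
spacer, resolved coding > intron > intergenic.  Effects are strictly
genomic (no RNA editing), computed on the spliced strand-oriented CDS with
NCBI translation table 11 for both organelles (no code is named in the
source; table 11 is the standard plastid/bacterial code and plant
mitochondria deviate from it only via editing, which is out of scope).
Context categories are counted over distinct genome positions, not
cultivar × position records — that is the unit under which the published
per-context totals sum to the number of SNP sites.

## Cohort statistics

Sharing is keyed on (position, primary alternate), which lets the one
two-alternate record join its nine-cultivar sharing group.  Uniqueness is
positional: a position is unique to a cultivar when no other cultivar has
any SNP there.  (The transcribed tables bold 14 plastid rows but contain 15
single-cultivar positions; the untagged one, position 12,167, belongs to a
cultivar the running text counts among those with a unique SNP, so the
positional definition is authoritative and the bold flag is stored only as
transcribed.)  The reference accession contributes no SNP records; it
enters only as the reference taxon of the character matrices.

## Phylogenetics

Character matrices code each taxon with its alternate allele at its SNP
sites and the reference allele elsewhere; the reference accession is an
extra, all-reference row.  Invariant columns are retained for likelihood
but are parsimony-uninformative.

* **Parsimony.** Fitch lengths via bottom-up set operations, vectorised
  over sites.  Heuristic search = stepwise addition (seed-determined taxon
  order) followed by NNI to a local optimum, incumbent kept on ties.  The
  heuristic is checked against full topology enumeration for ≤ 7 taxa.
* **Likelihood.** JC69 only: with at most a few dozen SNP sites nothing
  richer is identifiable, and the source names no model.  Branch lengths
  are optimised coordinate-wise by bounded Brent (per-edge conditional
  likelihoods make each inner iteration O(sites); convergence tolerance
  1e-6, branch lengths in [0, 10]).  Topology search is NNI from the
  parsimony tree, candidates screened with two optimisation passes and
  re-optimised fully on acceptance.  All-invariant matrices trigger a
  star-tree warning (any resolution is arbitrary).
* **Bootstrap.** Sites resampled with replacement; support = percentage of
  replicate ML trees containing each reference-tree bipartition; default
  1000 replicates.
* **ILD.** D = L(A+B) − [L(A) + L(B)] with L the heuristic-best Fitch
  length; the null repartitions pooled sites into pseudo-partitions of the
  original sizes; p = (1 + #{D_perm ≥ D}) / (1 + n_perm).  The published
  p = 0.63 is treated as qualitative ("not significantly incongruent") —
  the replicate count and search settings behind it are unstated — and the
  recomputed p on the transcribed matrices is reported, not asserted.

## Synthetic data

The generator produces what the method needs to be testable without any
download: a plastid/mito/nuclear reference trio in which a configurable
fraction of the mitochondrial genome (default 10.3%, five segments) is a
divergence-mutated copy of plastid sequence; cultivar SNP profiles with a
configurable heteroplasmic share (allele fractions uniform in a range,
realised per DNA fragment so mates agree); and paired-end reads with
per-genome depth proportional to copy number (default plastid:mito:nuclear
= 4:1:0.02 — the published coverage tables imply roughly 3–4× plastid over
mitochondrial depth, so 4:1 is a modelling choice, not a reported value).
Genomes are miniature (20/50/100 kb defaults) and linear; fragment starts
are uniform; errors are i.i.d. substitutions; base quality is constant per
run at Phred = −10·log10(error rate), capped at 40.  Planted SNPs avoid
transfer segments (they would be unrecoverable after filtering by
construction) and a 300 bp terminal margin (linear-genome coverage ramp).

Not emulated: circularity, indels and structural variants, GC or
position-dependent error, quality-score variation within and between
reads, real MTPT age structure (divergence is uniform), NUMT/NUPT content
beyond a uniform nuclear decoy.  Passing tests therefore demonstrate the
pipeline's behaviour under the stated generative model, not performance on
real libraries; the published mapping-statistics tables, per-cultivar
figure values and figure topologies depend on the real data and are
deliberately not reproduction targets.

## Problem sizes used in the checks

The artifact experiment runs one cultivar at 100× mitochondrial depth
(plastid 4:1) on the default miniature genomes — about 66,000 read pairs —
with error-free reads (rationale above), and asserts: at least one
spurious heteroplasmic mitochondrial call inside transfer segments before
filtering, zero after, with ≥ 95% of planted homoplasmic SNPs retained.
Observed values at seed 1: 117 before, 0 after, 100% retained, 66.6% of
mito-mapped reads surviving the filter (the real-data analogue printed in
the source is 53–66%, reproduced here only qualitatively since the true
copy ratios differ).  A companion test at 1% error on smaller genomes
checks that every filter-induced call change lies within one read length
of a transfer segment.  Statistical checks: JC69 two-taxon MLE vs the
closed form to 1e-6; ILD type-I rejection ≤ 0.10 at α = 0.05 over 200
congruent pairs (100 permutations each, 6 taxa × 40 sites); heteroplasmic
allele-fraction recovery within ±0.15 at ≥ 100× for ≥ 90% of planted
sites.

## Numerical and degenerate-input choices

Mapping: seeds are `max_mismatch + 1` non-overlapping k-mers (pigeonhole:
every placement within the mismatch budget shares at least one exact
seed), defaults k = 15 and max_mismatch = 5 for 100 bp reads (tolerates 2%
divergence plus error); MAPQ = 0 on ties, else min(60, 20·(second − best))
with second = max_mismatch + 1 when absent — an invented, fixed formula,
documented rather than faithful to any external aligner.  Ambiguous (non-
ACGT) bases never match a seed and always count as mismatches.  Pileup
columns with zero coverage are omitted.  Likelihoods are floored at 1e-300
before logs.  Newick export writes branch lengths to 6 significant
figures.  Empty cohorts produce 10 × 0 matrices; ML requires ≥ 4 taxa;
zero-coverage simulations warn and return empty read sets.
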