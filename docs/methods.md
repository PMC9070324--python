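# Methods

## Problem setting

A de novo plant transcriptome assembled from field-grown tissue is a mixed
bag: most transcripts are the host's, but endophytic/epiphytic fungi
contribute a sizeable minority (on the order of 10% in the agave communities
the bundled survey tables describe). `mycosieve` classifies each assembled
transcript by taxonomic origin and characterizes the fungal fraction. All
alignment, ORF prediction, quantification, and annotation tools are treated
as upstream: the package consumes their tabular outputs and never recomputes
alignments itself.

## Representative-isoform selection

Per locus (Trinity `_i<d>` isoform suffix stripped), the longest isoform is
kept among those with mean TPM strictly greater than 1 across all samples
and ORF length ≥ 255 nt. The ORF boundary is inclusive by default: the
survey's printed minimum CDS of 255 nt is only attainable with `>=`, so the
inclusive reading reconciles the reported tables; a strict `>` is available
via `orf_inclusive=False`. The TPM gate uses the mean over all samples
because no per-tissue rule is specified for this step; transcripts missing
from the expression table fail the gate (absence is never imputed as zero).
N50 is the largest length L such that transcripts of length ≥ L contain at
least half of all bases; an exhaustive oracle over random multisets backs
the implementation in the tests.

## Host-vs-fungus voting

Hits are ranked by a deterministic total order — ascending E-value, then
descending bit score, then ascending subject id — so every vote is
independent of input row order. After discarding hits with E-value above the
cutoff (default 10⁻¹⁰), the top 10 vote; the transcript is fungal when the
fungal share is ≥ 0.70. When fewer than 10 qualifying hits exist the vote is
taken over those available (minimum 1, configurable): discarding short hit
lists would systematically drop genuinely fungal transcripts with few
database relatives. "Fungal" means the subject lineage contains the taxon
name `Fungi` at any rank.

## Phylum consensus

Voting hits are categorized by subject phylum into Ascomycota,
Basidiomycota, or other. The default *unanimity* rule calls a main phylum
only when the main-phylum votes are unanimous; any Asco/Basidio mixture is
`ASCO_OR_BASIDIO`. Hits to other fungal phyla do not block a unanimous
main-phylum call (the main-phylum decision dominates); transcripts hitting
only other phyla are `OTHER_FUNGI`, and transcripts with no qualifying hits
are `NOT_APPLICABLE`. A majority-fraction rule (`rule="majority"`, default
0.9 of the main-phylum votes) is provided as an alternative consensus. A
subject lacking a phylum rank counts as "other" and is logged.

## Benchmark harness

A labeled pool stands in for a public fungal CDS collection. Query sets
(default 2,000 Ascomycota + 700 Basidiomycota) are sampled without
replacement with an explicit integer seed, and the reference is the pool
minus the query set — self-exclusion is structural, not an option. Because
the classifier is rule-based there is no training step; the full sampled set
is used for evaluation only. Confusion matrices are one-vs-rest per phylum
group, with `ASCO_OR_BASIDIO` and `NOT_APPLICABLE` calls landing in the
negatives (FN for the true class, TN elsewhere) under the standard
convention; TPR/FPR are reported as NaN when their denominator is zero. The
sweep grid defaults to E ∈ {10⁻¹⁰, 10⁻²⁰} × top-N ∈ {1, 3, 5, 10}.

## Tissue specificity (SPM)

With replicate-mean TPM per tissue, SPM_t = x_t/‖x‖₂. Squares sum to 1 for
any non-zero profile, so at most one tissue can exceed 1/√2 and the
threshold call (strictly > 0.95) is unique. All-zero profiles yield no
profile and no call. SPM is scale-invariant, so it is unaffected by
library-size rescaling of the mean vector.

## Enrichment

Term enrichment is the upper-tail hypergeometric probability
P(X ≥ k) computed by `scipy.stats.hypergeom.sf`, checked in the tests
against exhaustive enumeration of all C(N,n) draws for every N ≤ 12. The
background is the full fungal transcript set and significance is raw
p < 0.05 by default, matching common practice for these community profiles;
because that is anticonservative under multiplicity, Benjamini–Hochberg
(`correction="bh"`, via statsmodels) is available. Only enrichment (upper
tail) is tested, not depletion.

## Threshold filters

* Transporters: the *best-ranked* hit must have E ≤ 10⁻⁵ and query coverage
  ≥ 0.70 (both inclusive, "at least"); the family is that hit's subject id.
* Genus assignment: any hit with E < 10⁻¹⁰ and coverage > 0.70 (both strict,
  "below"/"above") assigns the transcript; the top qualifying subject is
  reported.
* Secreted CAZymes: a transcript contributes its CAZy families iff its
  signal-peptide score is strictly > 0.5; counts are keyed by class prefix
  (GH/GT/PL/CE/AA/CBM) and phylum group. Unparseable family strings are
  logged and skipped.
* Coverage is always computed against the *query* length (the aligned
  fraction of the transcript); translated-search alignment lengths are
  converted to nucleotide units (×3) before division. The subject-side
  denominator is not available in the consumed tabular format.

## Synthetic data: what it emulates, and what it does not

The generators are pure functions of `(design, seed)`; the root seed is
split into fixed per-generator streams (`sequences`, `pool`, `hits`,
`expression`, `annotations`, `genus`, `tcdb`) so any table can be
regenerated independently. Defaults describe one study-scale community:
22,000 host + 2,977 fungal transcripts (1,927/797/253 across
Asco/Basidio/other, the proportions of the largest bundled community),
lengths log-normal around ~550 nt, 3 tissues × 3 replicates, 90% of fungal
transcripts root-specific, 15% of Ascomycota transcripts carrying the
dominant-genus flag (≈ 9.7% of fungal), 6.2% of fungal transcripts
HSP-annotated.

Hit tables: each query draws 10 hits with E-values log-uniform in
[10⁻¹⁸⁰, 10⁻¹²] (inside every cutoff used), plus, for a fraction of queries,
a decoy hit with E in [10⁻⁸, 10⁻¹] that all stages must filter out. Label
noise ε swaps a hit's category at the level being voted: fungal-query flips
exchange the two main phyla (a flip to a minor phylum would not break a
unanimous call, so only main-phylum swaps produce the closed form), and a
correct unanimous call survives iff no voting hit flipped — TPR = (1−ε)^N
exactly, which the tests verify within 3 standard errors at n = 2,000.

Expression: tissue-specific transcripts get off-tissue means at 5% of the
major mean (noise-free SPM ≈ 0.9975, a deliberate margin above the 0.95
threshold); balanced transcripts sit at SPM = 1/√3 ≈ 0.577. Replicates
multiply the mean by log-normal noise with σ = 0.2, small enough that
planted calls remain exactly recoverable.

Annotations: each term marks carriers independently with a per-term
frequency drawn from the design's band; planted enrichment multiplies the
carrier *odds* for the designated group. Signal-peptide scores follow a
Beta(8,2)/Beta(1.5,8) mixture (secreted minority above 0.5).

What the generators do **not** emulate: real sequence homology (sequences
are random; hits are simulated directly, since every downstream computation
consumes hit tables, not alignments), assembly artifacts (chimeras,
fragmented ORFs), correlated annotation terms, compositional TPM coupling
between transcripts, or phylogenetic structure within phyla. Passing tests
therefore demonstrate the correctness of the classification, specificity,
and enrichment *rules* under controlled noise — not the upstream behavior of
aligners or annotators on real data. A k-mer containment scorer is included
purely as a smoke-test stand-in for producing hit-like scores from FASTA; it
is not an aligner.

## Numerical choices

* Hit-order ties break by subject id, making every downstream report
  deterministic; report TSVs are written with sorted rows and a fixed float
  format, so identical seeds give byte-identical files.
* The vote threshold uses `count/len >= fraction` on exact binary doubles;
  for ≤ 10 voting hits no representable ratio falls inside the gap around
  0.7, so the float comparison agrees with exact rational arithmetic (the
  tests enumerate all vote tables).
* Degenerate inputs: empty transcript sets error in summaries; empty hit
  lists yield `UNCLASSIFIED`/`NOT_APPLICABLE`; all-zero expression yields no
  SPM profile; percentages refuse a zero denominator.
* Null-calibration checks use a 4,000-transcript background with term
  frequencies in [0.2, 0.4] so the discrete hypergeometric tail is close to
  continuous; with small backgrounds the attainable p-values sit visibly
  below nominal levels purely from discreteness.
* Problem sizes in tests and the acceptance script (e.g. 2,000-query
  recovery runs, 200 calibration replicates, one study-scale end-to-end
  community of ~25,000 transcripts) were chosen as the smallest sizes at
  which the Monte-Carlo bands above are meaningful.

## Known limitations

* The genus-share denominator is ambiguous in community reports (total
  fungal vs Ascomycota-only); both are supported
  (`genus_denominator=`), defaulting to total fungal.
* BLASTn- and tBLASTx-style evidence streams are not merged internally; the
  classifier consumes one hit table at a time and stream merging is the
  caller's choice.
* One-vs-rest TN/FP conventions for the two no-call groups follow the
  standard definition; other conventions would shift FPR slightly.
* The expression generator draws TPM-like values independently per
  transcript; columns are not renormalized to sum to 10⁶.
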