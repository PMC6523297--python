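# Methods

## Transcript models and coordinates

All internal coordinates are 0-based, half-open genomic intervals; GTF I/O
converts to and from the 1-based closed convention at the file boundary, and
BED12 blocks map directly. A transcript is an ordered chain of disjoint,
non-adjacent exons on one chromosome and strand. Two derived objects drive
everything downstream: the *intron chain* (the identity key for collapse,
master IDs and replicate recurrence) and strand-aware *splice-site roles*
(the donor is the transcription-downstream edge of the upstream exon — an
exon end on `+`, an exon start on `-`).

Monoexonic transcripts are legal throughout. Because they have no intron
chain, they are collapsed by ≥ 95% reciprocal overlap (single linkage) and
keyed by their exact exon interval for master-ID purposes; against
annotation they are graded by containment (≥ 90% of the isoform inside the
reference exonic span scores 4, otherwise 1).

## Collapse and quantification

Full-length reads of one isoform differ mostly at their terminal ends
(5′ degradation, internal priming), so the collapse equivalence is intron-
chain identity, deliberately ignoring terminal-end differences; those
differences are instead reported downstream as terminal-variation events and
by the score-4/5 distinction. The representative is the member with the
greatest exonic length and the record count is the member sum, so collapse
conserves reads and is idempotent. TPM conversion treats each full-length
read as one molecule (no length normalization; a `length_normalize` switch
provides the short-read convention for comparisons). Per sample,
Σ TPM = 10⁶ to within floating-point error by construction.

## Annotation agreement score and event classification

The 0–5 rubric grades an isoform against each same-strand overlapping
reference transcript, keeping the best (ties: shared introns, then reference
length, then id):

| score | meaning |
|---|---|
| 5 | identical intron chain, both terminal ends within tolerance |
| 4 | identical intron chain, ends beyond tolerance |
| 3 | all isoform splice sites annotated, intron set differs |
| 2 | ≥ 1 shared intron and ≥ 1 novel splice site |
| 1 | exonic overlap only |
| 0 | no same-strand exonic overlap |

"Within tolerance" is strict (`< 50` nt by default); the same boundary
drives the terminal-variation labels (`≥ 50` nt), so a score-5 isoform never
carries an event label. Scores ≥ 2 are treated as acceptable matches with
interpretable splicing.

Event classification runs per isoform intron in a fixed decision order
(reference intron → exon splitting → alt acceptor → alt donor → skipping →
novel junction), with two rules that resolve ambiguity deliberately:

* an intron strictly inside one reference exon is always *exon splitting*,
  never an alternative-site call;
* introns flanking a *novel exon* (an isoform exon with zero reference-exon
  overlap) are attributed to that exon and receive no intron-level label —
  otherwise every inserted exon would spuriously contribute alt-site or
  novel-junction labels.

Retention is called per reference intron wholly contained in an isoform
exon. Site "knownness" is role-specific: a position only counts as a known
donor if some reference intron uses it as a donor. Classification is
invariant under genome-wide translation and strand mirroring.

## ORF prediction

The first AUG with an in-frame stop and ≥ `min_aa` residues is the accepted
ORF (default `min_aa` 30 in the API; the synthetic pipeline uses 10 because
its simulated UTR/CDS geometry is more compact than a human transcriptome).
Open-ended ORFs are rejected: a full-length cDNA contains its 3′ end, so a
genuine coding region terminates within it. `largest_orf` is the maximal-
length alternative (ties 5′-most); when both are requested downstream they
are suffixed a/b. Status is `C` when the protein equals the gene's canonical
protein and the transcript scores 5, `C*` when the protein is canonical but
the transcript is not, `novel` otherwise.

## Peptides

Tryptic digestion cleaves after K/R except before P; peptides at 0..k missed
cleavages carry residue positions, and the 0-missed set tiles the protein
exactly. Monoisotopic masses come from pyteomics with carbamidomethyl-C
(+57.02146 Da) as the default fixed modification (standard iodoacetamide
alkylation); m/z = (M + z·1.007276)/z. A *signature peptide* must (i) span
an isoform junction strictly inside its span, (ii) be ≥ 6 residues (MS
detectability; configurable), and (iii) occur neither in the canonical
digest at any missed-cleavage level nor anywhere as a substring of the
canonical protein — peptides unique merely by truncation are excluded
because only junction-spanning evidence is specific to the isoform.

In the pipeline, protein-level junction positions are derived from novel
splice junctions that fall inside the ORF: a junction at transcript position
j maps to the bond before residue ⌈(j − orf_start)/3⌉; an in-codon junction
therefore points at the bond following the chimeric codon's residue.

## Evidence confirmation

A junction at transcript position j is coverage-confirmed iff
[j − 50, j + 50) is covered gaplessly (the 100-nt window restates a
100-bp-read BLAST criterion in transcript coordinates; windows clipped at
transcript ends are flagged partial). An isoform is *confirmed* when all its
novel junctions are coverage-confirmed OR its intron chain recurs in a
replicate library — a disjunctive rule, since either line of evidence is
independently sufficient. TSS matching compares the strand-aware 5′ end to
annotated starts within 50 nt (configurable). Peptide matching is exact
string matching with I/L distinct.

## Trend statistics

Loci are binned by their canonical transcript's exon count (bin width 1);
per bin the mean of the top-k (default 5) per-locus isoform counts
summarizes the most isoform-rich loci. The Cochran–Armitage test for trend
on a 2 × k table uses the bin exon counts as scores and the exact
hypergeometric (margin-conditioned) variance,

    T = Σ s_j n_1j,  Var = R₁R₂ [N Σ c_j s_j² − (Σ c_j s_j)²] / (N²(N−1)),

so the analytic z agrees with a permutation null conditioned on all margins;
χ² = z², two-sided p from the standard normal, no continuity correction by
default. When two populations contribute counts to a locus they are summed.

## Synthetic data: what it emulates, and what it does not

The generator emulates the *structure* of a two-population full-length
RNA-seq experiment: genes of 2–16 exons (exons 80–300 nt, introns
60–400 nt) on one chromosome, GT..AG motifs on the coding strand of every
canonical intron, and a planted coding sequence (ATG at transcript position
12, cleared in-frame stops, TAA ~30 nt before the 3′ end) so ORF and
peptide stages operate on real reading frames. Novel isoforms apply exactly
one splice event to the canonical model, with geometric margins that make
labels identifiable: alternative sites shift ≥ 10 nt, split introns sit
≥ 10 nt inside an exon and are ≥ 20 nt long, novel exons keep ≥ 12 nt clear
of reference splice sites. Events are drawn from a configurable weight
profile (uniform by default — no quantitative per-locus event spectrum is
assumed); events that a locus's geometry cannot support are resampled.
Alternative-site, novel-exon and retention events additionally require
enough introns that at least one reference intron stays shared, keeping
every single-event isoform at score ≥ 2 and the label set unambiguous.

Isoform diversity scales with locus complexity — the per-locus novel count
is Poisson with mean 0.6 per intron (clipped to 0–12) — which is the signal
the short-read detection ceiling obscures. Half of novel isoforms are
population-specific. Full-length counts are Poisson with mean 30 per
isoform per population (the simplest adequate model for quantification
plumbing; no overdispersion). Short-read evidence is modeled at the
junction level: each junction is spanned gaplessly with probability
1 − dropout (default 0.2), a dropped junction leaving a 2-nt gap, and the
"SR-detected" set truncates each locus to its 4 highest-count isoforms —
emulating the observed detection ceiling rather than simulating
fragmentation and assembly. Paralog pairs copy a locus and substitute
exonic positions to a target identity ± 1%.

Consequently, passing tests demonstrate that the algorithms invert the
generator's grammar exactly and that calibrated rates (dropout, detection
probability) are recovered; they do not demonstrate robustness to
alignment noise, degraded 5′ ends, compound events on one isoform,
sequencing error, or non-GT/AG splicing, none of which the generator
produces.

## Numerical and design choices

* Per-stage RNG substreams are derived from `(seed, stage)` so adding a
  stage never perturbs earlier draws; all seeds stay below 2³¹.
* Deterministic ordering everywhere: master IDs in sorted chain-key order,
  GTF rows by (chrom, start, id), inclusion lists by m/z.
* Collapse ties (equal exonic length) break by transcript id.
* The demo pipeline's replicate library is a 0.8-probability subsample of
  the truth set; peptide observations use detection probability 0.5 on
  peptides ≥ 7 residues.
* Acceptance-scale runs use 200 genes (~1,000–1,250 isoforms), 60-gene
  calibration runs (~4,000 junctions), 1,000 collapse groups, and 3,000
  random 300-nt sequences for the ORF brute-force comparison.

## Known limitations

* The scoring rubric and event grammar are defined against a single best
  reference transcript; multi-reference composite matching is not modeled.
* Monoexonic single-linkage collapse is not guaranteed idempotent for
  adversarial overlap chains (A~B~C with A≁C); in practice terminal jitter
  is far below the 5% threshold.
* Signature-peptide junction positions assume the isoform protein is a
  concatenation of canonical segments; isoforms with novel coding sequence
  inside the junction peptide are still reported but the junction-span
  bookkeeping is approximate at in-codon junctions.
* The trend test is asymptotic; for very sparse tables a permutation
  p-value should be preferred (the test suite demonstrates agreement at
  moderate counts).
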