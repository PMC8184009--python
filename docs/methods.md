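# Methods

## Coordinate and junction conventions

All internal coordinates are 0-based half-open; GTF (1-based inclusive)
is converted at the boundary. A splice junction is stored as its intron
interval `[start, end)`, where `start` is the first intronic base and
`end` is one past the last. *Donor* (5' splice site) and *acceptor*
(3' splice site) always refer to transcriptional orientation: on the
plus strand donor = `start` / acceptor = `end`, on the minus strand the
reverse. This removes every ±1 ambiguity from junction arithmetic and
makes the genome↔mRNA mapping an exact bijection over exonic positions
(property-tested exhaustively on randomized transcripts of both
strands).

When a junction could belong to several overlapping transcripts, point
queries (exonic/intronic) use the union over transcripts, and the host
is the transcript carrying the annotated end, ties broken by longest
transcript, then lexicographic gene id, then transcript id. This
attribution precedence is a package decision (the underlying experiment
does not dictate one) and is recorded in the output.

## Split-read counting

A read contributes one count per CIGAR N-operation if it is a primary,
mapped, non-duplicate alignment with NM ≤ 0 (strictest reading of "no
mismatches": indels also disqualify) and the *shortest aligned block
immediately flanking that N-operation* is ≥ 8 nt. Overhang is measured
on aligned blocks, not on the raw read, so soft-clipped bases do not
count. Reads without an NM tag are excluded and reported. Library size
is the number of qualifying primary mapped reads; normalization is
counts-per-million of that size. Junction strand comes from the
aligner's XS tag when present, else from intron-terminal dinucleotides
(GT..AG / CT..AC), else the junction is held unstranded and resolved
against the annotation.

## PSI

PSI of junction *j* in sample *s* is its count share among all
junctions using either of *j*'s splice sites (including *j*). This is a
deterministic, local-splice-variant proxy computable from counts alone;
it deliberately does not reproduce any Bayesian posterior-based PSI
quantifier. PSI is *undefined* (not zero) when the local denominator is
zero; undefined values enter fold-change ratios as the epsilon
pseudocount.

## The filter cascade

Defaults (all exposed in `PipelineConfig`):

| parameter | default | meaning |
|---|---|---|
| `min_aggregate_reads` | 5 | split reads summed over all libraries |
| `count_fc_threshold` | 2 | CPM fold change vs control, strict `>` |
| `psi_fc_threshold` | 2 | PSI fold change vs control, strict `>` |
| `min_concordant_kd` | 2 (of 3) | knockdown conditions that must agree |
| `count_pseudocount` | 1 CPM | bounds count ratios, avoids division by zero |
| `psi_epsilon` | 0.01 | same for PSI ratios |

Count ratios use depth-normalized CPM (the raw-vs-normalized choice is
not dictated by the experiment; normalized was chosen so libraries of
unequal depth compare fairly). Pseudocounts are needed because cryptic
junctions typically have zero control reads. Raising any threshold can
only shrink the call set (tested property).

## Classification and metagene placement

A novel junction with both ends at annotated splice sites is
`novel_alternative`; with exactly one annotated end, the other end's
first intron-side base decides `exonic_*` vs `intronic_*`; anything
else is `unclassified` (a value, not an error). Metagene distances are
measured on the *mature mRNA* of the host transcript, not the genome,
because EJC deposition (~24 nt upstream of exon-exon junctions) is an
mRNA-space geometry; a site is flagged `within_ejc_footprint` when it
lies 24 ± 10 nt upstream of a junction (the 10 nt half-width is a
package choice, exposed in config).

## Splice-site and branchpoint models

Donor and acceptor models are log-odds PWMs over 3+6 and 14+3 nt
windows (covering the AG|GTAAGT donor consensus and the
polypyrimidine-proximal acceptor context), trained on all annotated
sites with pseudocount 1 and normalized min-max to [0, 1]. They are a
structural stand-in for neural-network splice-site scores: thresholds
like 0.75 ("strong site") are analogous in spirit but **not**
numerically comparable to any external scorer, and scores are never
used to veto re-splicing compatibility (functionally validated
regenerated sites can score near 0). `train_pwm`'s default background
is uniform — this guarantees the column-wise most-frequent sequence
scores exactly 1 even for degenerate inputs — while the
annotation-trained models pass the pooled base frequencies of their
training windows as background to reflect genomic composition.

The branchpoint motif (default width 7, exposed) is derived from
windows 15–45 nt upstream of up to 10,000 annotated acceptors by a
one-occurrence-per-sequence EM finder: the E-step computes a posterior
over motif start positions against a 0-order background, the M-step
updates expected counts with pseudocount 1; 5 random restarts, ≤ 200
iterations, convergence when the objective gains < 1e-6. The tracked
objective is the penalized (MAP) log-likelihood — data log-likelihood
plus the Dirichlet log-prior implied by the pseudocount — which EM
theory guarantees to be non-decreasing for this E/M pair. After the
restarts, the best solution is re-run from its ±1 column-shifted
phases and the highest-objective phase wins; this standard refinement
removes the phase ambiguity inherent to one-occurrence-per-sequence
models (without it, ~5 % of planted-motif runs converge to a 1-shifted
consensus). "75 % PWM match" for branchpoint scanning means normalized
min-max score ≥ 0.75, the common reading of percent-PWM-match.

Cryptic splice sites are scored on the *mRNA* context of their host
transcript when the site is exonic (the cryptic-intron side of the
window then reads canonical exon sequence, which is what the splicing
machinery sees on a mature mRNA); intronic or host-less sites fall back
to genomic context.

## Re-splicing scan

Removal of an intron can regenerate a splice-site mimic at the new
exon-exon junction: `...AG|` from the upstream exon (3' site) or
`|GT...` in the downstream exon (5' site). For a cryptic exonic donor
joined to annotated acceptor A, the partner is the regenerated 3' site
at the junction formed by removing the intron that ends at A (and
symmetrically for cryptic acceptors). Compatibility requires only the
invariant dinucleotide; PWM scores are attached for reporting. The
deletion span is the mRNA interval between the cryptic site and the
partner junction; every emitted event satisfies the identity that
deleting the span from the reconstructed mRNA and mapping the product
back to the genome reproduces the cryptic junction's genomic
donor/acceptor pair exactly (asserted on all simulator fixtures).
Events whose span touches a transcript end are dropped and counted;
multi-transcript calls produce per-transcript events de-duplicated by
mRNA sequence context; for spans crossing intermediate junctions only
the terminal partner is reported, intermediate junction indexes are
listed as metadata.

Coding consequences intersect the deletion with the CDS in mRNA
coordinates: no overlap → `noncoding`; overlap including the start or
stop codon → `spans_start_or_stop`; length ≢ 0 (mod 3) → `frameshift`;
otherwise `in_frame_deletion` with `aa_deleted` obtained by translating
the reference and deleted CDS and differencing the peptides (this is
codon-phase aware and also captures a premature stop introduced at the
new junctional codon as a larger peptide loss).

## Synthetic data: what it emulates, and what it does not

The generator mirrors the 4-library knockdown design: one control
(lacZ) and three knockdowns (eIF4AIII, mago, tsu), single-end 100 nt
reads, 200,000 qualifying reads per library (exact, padded with
ungapped filler reads). Genes (default 100; 3–6 exons of 80–300 nt,
introns 70–160 nt) carry GT..AG introns whose invariant dinucleotides
are always planted and whose extended consensus (GTAAGT / TTTCAG) and
branchpoint (CTAAC, 20–38 nt upstream of the acceptor) positions match
the consensus with probability 0.9 each. CDS regions are stop-free by
construction so coding-consequence arithmetic is well defined.
Annotated junctions are expressed at 50–150 reads/library; planted
cryptic junctions at 10 reads/library in control, × 8 in their
responsive knockdowns. Ten reads/library (40 in aggregate) represents a
clearly detectable junction several-fold above the 5-read aggregate
floor — planting junctions *at* the floor would benchmark counting
noise at the detection boundary rather than the cascade's behavior.
Optional negative-binomial noise (gamma-Poisson, dispersion 0.1, the
standard RNA-seq overdispersion model) replaces exact counts.

Deliberately not modelled: GC structure and sequence composition
(background is i.i.d. uniform), sequencing errors and quality scores,
paired ends, intron retention reads, multi-isoform genes, and any
correlation structure between knockdowns. Passing tests on this
generator therefore demonstrate the pipeline's arithmetic, filtering
logic and coordinate handling — not robustness to alignment artifacts
or biological covariation in real libraries.

The hand-designed re-splicing fixture plants the two validated
topologies: a gene whose third exon begins `GT` with a cryptic 3' site
54 nt downstream of the exon 2/3 junction, codon-aligned inside the CDS
(→ in-frame deletion of 18 amino acids), and a gene whose second exon
ends `AG` with a cryptic 5' site 110 nt upstream of the junction
(→ frameshift). Mutating either remnant dinucleotide away must abolish
the corresponding event (negative control, tested).

## Statistical checks and problem sizes

The overlap permutation test draws k uniform random same-size subsets
of the universe per permutation and counts their intersection; the
implementation samples the intersection sizes by the exact sequential
hypergeometric equivalence (the intersection of a uniform random subset
with a fixed set is hypergeometric; conditioned on its size, the
running intersection is again a uniform random subset), which is
distributionally identical to materializing the subsets and keeps
n_perm = 1e5–1e8 tractable. P-values carry the +1 Monte-Carlo
correction and never return 0. Calibration is verified against the
closed-form hypergeometric tail (k = 2) and by a KS uniformity check of
null three-set p-values; the null uses a 800-element universe with set
sizes 300–500 so the discrete support of the overlap statistic is fine
enough for a meaningful KS comparison.

Problem sizes used by the test-suite and the acceptance script — a
100-gene noise-free dataset at 2×10⁵ reads/library for the end-to-end
path, 20 count-level simulations for the noisy benchmark (the SAM round
trip is exercised by the noise-free path), 50 planted-motif datasets of
200 windows for EM recovery, 10⁵ permutations for calibration and
500 × 2000 for uniformity — were chosen so the whole suite completes in
well under a minute while keeping every Monte-Carlo standard error far
below the margins being asserted.

Specificity near the count floor: junctions expressed at the normal
annotated scale with no condition effect are essentially never called
(< 5 % tested; in practice ≪ 1 %), while decoys planted at the low
cryptic abundance pass at a few percent — the noisy benchmark bounds
this at 10 % of calls. Both regimes are asserted separately.

## Known limitations

- PSI is a local count share, not an isoform-aware posterior; junctions
  sharing sites across overlapping genes are pooled.
- The PWM scorer is position-independent (no dinucleotide coupling);
  scores are comparable only within one trained model.
- Re-splicing prediction is combinatorial: it reports all
  dinucleotide-compatible partners, not which partner is used in vivo,
  and does not model splicing order or kinetics.
- The consequence annotator assumes a single CDS per transcript and
  ignores NMD eligibility of frameshifted products.
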