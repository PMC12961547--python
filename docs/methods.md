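# Methods

## The allodiploid model

The package models an allodiploid cell line carrying two complete
haploid genomes from related rodent-like species, here called allele A
(mouse-like) and allele B (rat-like). Both alleles share one nucleus,
so any allele-specific difference in TF binding or in the
transcriptional response to TF induction is attributed to *cis*
(sequence near the locus), not *trans* (diffusible factors). Alleles
are represented as two whole separate genomes — there is no diploid
VCF/phasing layer; reads, peaks and genes live on one genome or the
other, and cross-genome identity is established by sequence alignment
(peaks) or by a curated homolog map (genes).

## Synthetic data generator

`cisdiv.simulate` produces the study inputs with exact truth tables.

**Genome pair.** Genome A is i.i.d. uniform ACGT. Genome B is derived
from A by per-site substitution at `subst_rate` and indel events at
`indel_rate` with geometric lengths (mean `mean_indel_len`; a single
parameter keeps the length model trivial). On top, each genome receives
`n_unalignable_blocks` lineage-specific insertions of i.i.d. random
sequence, 3× the 400 bp peak window long, which guarantees that a
window centred in a block cannot reach 70% identity against the other
genome — the planted "unaligned" class is unambiguous. Every aligned
column is recorded in a per-chromosome monotone coordinate map, so any
simulated position can be projected exactly and the map round-trips
(A→B→A is the identity on homologous sites).

Defaults: 2 chromosomes × 500 kb per genome, `subst_rate` 0.05 (about
the genome-wide divergence of the two rodent lineages the model
emulates), `indel_rate` 0.002, 100 blocks per genome. At these settings
the realised mismatch fraction over homologous columns is 0.05 within
binomial error.

**Peaks.** The PWM consensus is written into the genome at the planted
summit; peaks are emitted with the summit stored as an offset from the
interval start (narrowPeak column-10 convention) and q-values well
above the high-confidence cutoff. Classes: *conserved* — consensus at
homologous positions in both genomes, a peak in each; *loss* —
consensus and peak in one genome only, the homologous region exists but
is unbound (planted symmetrically, `n_peaks_loss` per genome);
*unaligned* — consensus at the centre of a lineage-specific block.
Planted summits keep a guard distance (window + 50 bp) from each other,
blocks and chromosome ends; an impossible request raises a sizing
error. Two optional knobs exist for targeted experiments and default
off: `loss_extra_mut_rate` (extra local mutation of the unbound homolog
window, letting matched-base comparisons separate conserved from loss)
and `loss_motif_ablation` (fraction of loss peaks planted without the
consensus, reproducing a declining motif frequency from conserved to
loss peaks).

**Reads.** Each peak contributes `reads_per_peak` (default 50) reads of
`read_len` 100 bp whose midpoints are uniform within half a fragment
(default fragment 250 bp, the midpoint of a typical 100–500 bp ChIP
size selection) of the summit, drawn from the allele carrying the peak,
strand random; background reads are Poisson at `background_read_rate`
per kb on both alleles. Reads are untrimmed, duplicate-free and
error-free by default (`read_error_rate` exists); QC and trimming are
deliberately out of scope.

**Expression.** Each of `n_genes` (default 2,000) homolog pairs draws a
regulation type from `type_proportions`, which default to the
published-scale five-way split (≈ 75.9 / 6.7 / 0.01 / 5.8 / 11.6%).
Counts are negative binomial with mean `mean_expression` (500) and
overdispersion `dispersion` (0.05; var = m + αm²); responsive alleles
shift by ±`effect_size_log2` (3.0) in log2 mean, with signs tied by the
type definition (opposite for type 2, shared for type 4).

What the generator does **not** emulate: mappability structure, GC
bias, PCR duplicates, spliced transcripts, base-quality error profiles,
replicate batch effects, and any correlation between a gene's
regulation type and its genomic position (gene anchors for the linkage
stage are placed relative to peaks by construction). Passing tests
therefore demonstrate the correctness of the decision rules and the
recoverability of planted structure under clean conditions — not
robustness to real-library artefacts.

## Allele assignment

Candidate loci are exact k-mer seeds (default k = 12, both
orientations) verified by banded edit-distance alignment of the full
read (edlib); the per-genome best hit minimises the Levenshtein
distance, ties broken leftmost (chromosome lexicographic, then start).
`max_edit` defaults to 10% of the read length. The label is the genome
with the strictly smaller edit distance; equal distances are
*ambiguous* and excluded from all per-allele counts — a conservative,
standard policy for allele-specific analysis where the underlying tie
behaviour of production aligners is not specified. Counting uses the
hit-interval midpoint: a read increments the one feature containing its
midpoint, which makes assignment single-valued without edge artefacts.
Tests verify the search against a full semi-global DP oracle on ≤ 5 kb
instances. MAPQ and duplicate filters of real pipelines are out of
scope because the generator emits neither multimapping structure nor
duplicates.

## Peak projection and classification

Each peak is reduced to the half-open 400 bp window
[summit−200, summit+200) (windows at chromosome edges are clipped and
flagged). The seeded aligner mimics blat: exact 11-mer seeds on both
strands with over-represented-seed masking (seeds occurring more than
24 times are dropped, the `.ooc` analogue), seeds chained by diagonal
(band 40 bp, ≥ 3 seeds per cluster, at most 12 clusters extended per
strand), and each chained span extended by local alignment. The
retained score is **matches − mismatches − gap_opens**; the *search*
however uses affine gap penalties (match +1, mismatch −1, open −2,
extend −1), because a literal zero extension cost would let the
optimiser align anything to anything by stitching exact words with free
gaps. Hits require identity ≥ 70% and score ≥ 100; the best-hit filter
drops hits covering < 70% of the query and declares *multi-mapped*
(excluded) when the runner-up scores ≥ 0.95× the best — near-ties are
genuinely ambiguous placements. Classification: no qualifying hit →
*unaligned*; aligned region covering strictly more than 50% of the
length of some target-genome peak → *conserved*; otherwise *loss*. On
≤ 1 kb homologous pairs the reported identity agrees with a full
global-DP oracle within 2 points.

## Motif scanning

Windows are scored with log2 odds against a 0-order background
(uniform by default, configurable), both strands, FIMO-style
pseudocount 0.1. P-values are exact tail probabilities of the score
distribution under the background, computed by dynamic programming over
scores discretised to 1/100 bit; a window's own score is discretised by
the same rule before lookup, so the DP p-value is exact for the
discretised score (verified against exhaustive 4^w enumeration for a
width-6 matrix). N bases contribute zero log-odds. The bundled MEME
matrix is a synthetic caudal-type homeodomain-like consensus for
testing; any user MEME file is a drop-in replacement.

## Threshold rules

High-confidence peaks require −log10(q) strictly greater than 4.
Accessibility calls: UP iff log2FC > 1 and the summed normalised pair
is ≥ 40 (the floor is applied to the summed pair after library
scaling); DOWN symmetric; else COMMON. Allele-stronger binding: one
allele's normalised count ≥ 2× the other's. Library scaling is
total-count scaling to the mean library size (a deliberate
simplification relative to median-of-ratios estimators; it preserves
within-sample ratios exactly). A pseudocount of 1 precedes every log
ratio, so fold changes are finite at zero counts.

## Regulation typing

An allele is *expressed* if it passes the floor (default 3, a
TPM-equivalent on the simulator's count scale) in at least one
condition; *candidates* are pairs with both alleles expressed, and
non-candidates are reported as type −1 rather than silently dropped. A
call is up/down when |log2FC| exceeds 1; the five-way type follows from
the two calls. Swapping allele labels maps types 1↔3 and fixes 0, 2, 4
exactly. Under a pure null simulation the fraction of non-zero types
equals the caller's realised false-positive rate, which the tests
report rather than hide; recovery of planted types within ±2
percentage points is demonstrated at dispersion 0.01 and mean 1,000 —
at the default dispersion 0.05 the same caller inflates types 1/3 by a
few points, which is the expected behaviour of a hard threshold on
noisy fold changes, not an error. Welch's t (on |log2FC|, two-sided p
from the t distribution, Welch–Satterthwaite df) and Pearson's r (with
the t-transform p) are implemented from their formulas and tested to
1e-6 against independent references.

## Peak–gene linkage

A peak links to a gene when its summit lies in the half-open 60 kb
window centred on the strand-aware TSS (clipped at chromosome bounds);
a peak may link to several genes. Summit containment was chosen over
any-overlap to avoid double-edge artefacts and is configurable in
spirit by widening the window. The per-type composition table reports
the conserved/loss/unaligned proportions of linked peaks for types 0,
1, 3, 4 (the opposite-response type is excluded as it is represented by
a single gene at published scale); a type with no linked peaks is NA,
never a row of zeros.

## DBD screen

Columns of a protein multiple alignment are reported when every
non-focal taxon carries one identical non-gap residue and the focal
taxon differs; gapped columns are skipped. Input must be pre-aligned
(homeodomains are typically equal-length); running an MSA tool is out
of scope, keeping the module dependency-free and deterministic. The
pairwise identity table uses mutually ungapped columns.

## Reporting conventions

Percentages round half-away-from-zero to one decimal (two decimals
below 1%) and are always recorded next to their raw counts, so every
printed percentage is re-derivable. The conserved-regulation share is
type 4 over types 1–4. `run_pipeline` logs per-stage results and embeds
truth-versus-recovered confusion tables when run on simulated data; two
runs with the same config produce identical reports (one RNG stream per
stage, derived deterministically from the single seed).

## Problem sizes

The default study uses 2 × 500 kb chromosomes per genome, 100 peaks per
orthology class, ~30,000 reads, and 2,000 homolog pairs; the acceptance
script assigns ~10,000 reads and re-runs typing at 2,000 pairs. These
sizes give binomial standard errors comfortably inside the tolerances
the tests assert while keeping a full end-to-end run around one minute
on a single CPU.

## Known limitations

- The seeded aligner is a blat-like approximation, not blat: its tiling
  score and ooc policy differ, and alignments of peaks > 5 kb or
  whole-genome chain/net liftover are out of scope.
- Differential calls are hard thresholds on fold changes; no shrinkage
  or replicate dispersion modelling (the declared scope replaces
  posterior fold-change estimators with the stated rules).
- RNA reads are unspliced; SAM/BAM emission is not provided — the
  interface is FASTA/narrowPeak/TSV.
- The command-line surface is the set of numbered scripts under
  `analysis/`; the library functions are the API.
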