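# Methods

## Scope and model

`peakstate` classifies transcription-factor binding peaks along three
axes: DNA-binding-domain motif content (Paired Domain vs Homeodomain),
distance to the nearest transcription start site, and the chromatin state
of the associated gene. It operates purely on interval and sequence data
— peak calls, a genome, gene models, mark peak sets — and makes no use of
read-level signal. Upstream steps (trimming, alignment, duplicate
removal, peak calling) are deliberately out of scope: the pipeline starts
where MACS2 output ends.

All internal coordinates are 0-based half-open (BED-native); GTF input is
converted on ingest (start − 1). A single convention everywhere removes
the classic off-by-one failure mode when mixing BED and GTF sources.
Overlap always means ≥ 1 bp of intersection between half-open intervals,
so abutting intervals never count as overlapping.

## Motif scanning

Patterns are degenerate consensi in IUPAC code with at most one bounded
gap `N{a,b}` (b ≤ 5), compiled to the finite set of fixed-length words
they realize and matched with zero-width-lookahead regular expressions so
that overlapping occurrences are all reported. The shipped set is

| label      | class | pattern          |
|------------|-------|------------------|
| PD_core    | PD    | `TYMYSS` (= T[T/C][C/A][C/T][G/C][G/C]) |
| PD_GTCAYGG | PD    | `GTCAYGG`        |
| HD_major   | HD    | `TAATN{2,3}ATTA` |

A hit from either PD pattern counts as PD. Minor HD variants reported in
the PAX binding-site literature have no canonical printed consensus, so
the default set carries only the major site; additional patterns can be
supplied per run as YAML/TSV rather than inventing sequences.

Both strands are scanned by default (binding sites are strand-agnostic;
the reverse complement of a peak is the same locus), with a
`--strand forward` switch. An `N` in the subject sequence satisfies no
motif position, including gap positions. Matches are deduplicated to
(pattern, offset, strand) keys — e.g. the two HD spacer lengths at one
offset count once; classification depends only on domain-class presence,
so deduplication cannot change a peak's class. The four-way hierarchy
(PDHD ≻ PD ≻ HD ≻ None) is total and mutually exclusive by construction.

Peaks are extended ±150 bp (full mono-nucleosome context) before
sequence extraction; extension beyond a chromosome end is clamped, not
rejected. Blacklist filtering is applied to the extended intervals — the
conservative reading, since artifact signal adjacent to a peak
contaminates its extended sequence; the pre-extension alternative is a
one-line change in the pipeline. Under uniform bases the PD 6-mer
matches a random position at rate 32/4096 = 1/128 per strand, the basis
of the chance-hit checks in the test suite.

## Nearest-TSS annotation

The peak reference point is the narrowPeak summit when present
(summits localize binding best), else the floor midpoint. The assigned
gene minimizes |reference − TSS| among same-chromosome genes (TSS =
start on +, end − 1 on −); ties break to the lexicographically smallest
gene_id so runs are deterministic. Peaks on chromosomes without genes
are flagged unannotated, never dropped silently. Distances are binned
half-open on absolute distance — `<5 kb`, `5–50 kb`, `≥50 kb` by
default, the `<5 kb` bin subdivided at 0.5 kb, with sub-bin percentages
reported relative to their parent bin.

## Chromatin-state calling

Two windows are built per gene: TSS ± 2 kb, and gene body ± 5 kb.
H3K4me1, H3K4me3, H3K27ac and ATAC are tested against the union of the
two; H3K27me3 is tested against the unextended gene body. The H3K27me3
exception is interpreted as "no extension" — the narrowest defensible
reading of a Polycomb-domain call, since 5 kb of slack around a gene
would let neighbouring repressed domains flip the flag; the
window-per-mark policy is configurable (`tss_only`, `gene_only`,
`union`, `gene_body`) because the choice is genuinely open.

States are called hierarchically in table order (Active → Primed →
Poised → Repressed → Closed), first match wins; the order only matters
for vectors matching multiple rows, which the literal table avoids.
Enumerating all 2⁵ = 32 flag vectors yields 3 Active, 3 Primed, 3
Poised, 1 Repressed, 8 Closed and 14 Unclassified — the package never
silently reassigns an Unclassified gene; a user-supplied override table
reproduces any manual curation explicitly. State is a property of the
gene: peaks annotated to the same gene share one call.

## Summaries and rounding

Percentages are count/total × 100 rounded to one decimal with
round-half-to-even (computed in decimal arithmetic, so printed-precision
checks are exact). Non-Active aggregates every non-Active state and by
default includes Unclassified — with the Unclassified count also
reported separately — because excluding it silently would hide
unresolved genes; a toggle reproduces accountings in which unassignable
genes were manually resolved first. Every table conserves its
partition: counts sum to totals and cross-tab margins agree with the
per-axis tables, which the test suite enforces property-style.

## Synthetic data

The generator inverts the pipeline's own rules to produce fixtures with
exact ground truth. Defaults describe a study-scale dataset: 837 peaks
across a 4 × 4.8 Mb genome, motif-class mix 81.7 / 0.5 / 16.2 / 1.6 %
(PD/HD/PDHD/None), gene-state mix 85 % Active with small Primed / Poised
/ Repressed / Closed / Unclassified fractions, background GC 0.41
(human-like), peak widths 150–300 bp, and a TSS-distance mixture of
55 / 6 / 25.9 / 13.1 % over `<0.5 kb` / `0.5–5 kb` / `5–50 kb` /
`50–60 kb`, reconciling a profile in which >60 % of peaks lie within
5 kb of a TSS, >90 % of those within 0.5 kb, and 13.1 % beyond 50 kb.
Distal draws are capped at 60 kb so nearest-gene assignment stays
provable at desk scale.

Genes sit on fixed TSS anchors in two tiers per chromosome: a dense tier
(16 kb pitch) hosting promoter-proximal peaks and an isolated tier
(130 kb pitch) hosting distal ones. The pitches guarantee (i) one gene's
planted marks can never fall inside a neighbour's evaluation windows
(bodies ≤ 5 kb, windows extend 5 kb) and (ii) a peak placed d ≤ 60 kb
from an isolated TSS has no closer TSS. Each placement is additionally
verified against a brute-force nearest-TSS check and redrawn within its
distance bin on failure, so bin fractions are preserved.

Background sequence is i.i.d. at the configured GC. In motif-scrubbed
mode (default), windows matching any pattern word on either strand are
iteratively resampled — vectorized over encoded arrays, independent of
the production regex scanner, and cross-checked against it in tests —
until zero matches remain. Planted words are sampled realizations of
the degenerate patterns written into the sequence centred on the peak
summit (PDHD peaks carry a PD and an HD word 4 bp apart; the summit is
the first planted word's midpoint, so planted distances are exact).
Because a PD word cannot occur inside an HD word or vice versa, the
only way a peak can change class is a junction artefact where planted
bases and background jointly complete a word of the other class; a
verification pass re-scans every extended window and locally re-scrubs
such artefacts with the planted positions frozen. Extended windows are
kept disjoint (10 bp guard), so peaks cannot contaminate each other.

Mark intervals realizing a target state are drawn uniformly from the
flag vectors the classifier maps to that state (Unclassified targets
from the 14 off-table vectors) and placed strictly inside the relevant
window (H3K27me3 at the gene-body centre, other tracks at the TSS).
Optional decoy peaks inside blacklist regions exercise the filtering
path. A single seed drives independent substreams per stage, so output
is byte-reproducible and changing the peak count does not perturb the
genome.

What passing the recovery test shows: the pipeline's coordinate
arithmetic, scanning, annotation and state logic are exactly inverse to
the generator's planting rules. What it does not show: robustness to
read-level noise, irregular peak shapes, overlapping genes, repeat
content, or marks straddling window boundaries — real data will exercise
those, synthetic data deliberately does not.

## Numerical and degenerate-input choices

- Out-of-bounds intervals clamp with a logged warning (extension can
  overrun chromosome ends); empty FASTA yields an empty genome plus a
  warning rather than an error.
- Malformed BED-family lines fail loudly with the offending line number;
  duplicate gene_ids and duplicate FASTA headers are errors.
- An empty peak list is an error for summaries (no denominators); empty
  mark tracks are legal, a *missing* track is a configuration error
  caught before any computation.
- Scrub non-convergence (pattern set too dense for the background)
  raises after a configurable iteration cap rather than looping.

## Problem sizes

Tests run the full pipeline at 150–200 peaks on 2 × 2 Mb genomes and the
recovery check at 2 000 peaks on 4 × 4.8 Mb; the acceptance script uses
the same 2 000-peak configuration plus 10⁴ random 300-mers for the
Monte-Carlo chance-rate estimate. These sizes give every distance bin
and state class double-digit representation while a complete suite run
stays around a minute.
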