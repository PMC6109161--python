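# Methods

This note records the models, conventions and numerical choices behind
each module, what the synthetic generators do and do not emulate, and
the known limitations.

## Coordinates and sequence conventions

Genomic coordinates are 1-based inclusive at every API boundary
(matching published prophage tables, where `left > right` marks a
reverse-orientation prophage); all internal arithmetic is 0-based
half-open, converted only at the boundary. Sequences are uppercase
A/C/G/T/N; GC% is computed over unambiguous bases with N excluded from
the denominator. Translation uses the bacterial genetic code (table 11).

## Attachment sites (`attsite`)

*Alignment.* attL/attR pairs are aligned globally at unit edit cost
with an infinitesimally heavier gap penalty (−1 − 1e−6), so among all
minimum-edit alignments the one with fewest indels wins and equal-length
homologs align gap-free. Substitutions and indels are reported
separately; their sum (`total_differences`) is the edit distance, which
unit tests verify against an independent dynamic-programming oracle.
Alignments needing more than `max_gaps` gap columns (default 1) are
flagged, not rejected: the two 34 bp cores among the 35 bp *dnaJ2*
homologs are treated as single-base deletions, not errors.

*Crossover inference.* Sites are merged into a star multiple alignment
against the longest site (adequate for attachment-site homologs, which
differ by point substitutions and ≤1 short indel); every maximal run of
columns identical across all sites is returned, sorted by length then
position. All maximal windows are reported and the consumer selects one
(`longest`, `nearest-3prime`, or by index) — on the published *dnaJ2*
set the 8 bp `TGAGCTGA` run is longest while the biologically attested
window is the 7 bp `GCAAGTT` run; with the virion attP sequences (not
published as text) the ranking could change, so no single window is
hard-coded.

*Derivation and excision.* attB/attP derivation swaps the aligned rows
after the crossover end, keeping exactly one copy of the overlap O per
product. Excision/integration are exact string surgery on the
B·O·B′ / P·O·P′ algebra; both take explicit crossover offsets per site
(`(offset, length)` or `(offset_in_site_a, offset_in_site_b, length)`)
because an indel can place O at different offsets in attL and attR, and
the integrate side takes an explicit attP interval on the circular
virion. These operations are exact inverses (property-tested over
arbitrary quartets) and conserve total nucleotide count.

## Shufflon (`shufflon`)

rix orientation is defined against the lexicographically smaller of
motif/reverse-complement; palindromic motifs are rejected, since
orientation — and hence inversion directionality — is undefined for
them. Repeat discovery seeds canonical k-mers at the minimum motif
length, extends each occurrence family maximally in both directions,
and reports every occurrence; nested or shifted families that are
genuine maximal repeats (e.g. when all Rv segments end with the same
stop codon adjacent to a rix) are all reported, and callers filter by
motif.

Recombination is modeled flip-only: inversion requires an oppositely
oriented rix pair and reverse-complements the block between the inner
edges of the two sites (bounding sites keep their orientations,
contained sites flip; applying a move twice is the identity). Deletion
between direct sites — whose avoidance in vivo is an open regulatory
question — is disallowed by default and available behind
`allow_deletion`. State enumeration is a breadth-first closure
deduplicated on the realized DNA string (tolerating duplicate
segments), in deterministic discovery order, with a hard `max_states`
cap that raises rather than truncating silently. An independent
string-level BFS oracle checks the closure for all cassettes with ≤5
segments.

*Allele calling.* The fused coding sequence is rc_head + the in-gene
rix retained once (it contributes junction codons) + the downstream
segment, translated in the Rc frame. The fusion counts as a full-length
allele only when its first in-frame stop terminates exactly at the
segment's 3′ boundary (the next rix); a premature stop, a read-through
past the boundary, or a missing stop returns none. When no rix follows
(degenerate cassette) any in-frame stop is accepted. This convention
makes reverse-complemented or frame-shifted segments invalid by
construction and bounds the distinct-allele count by the number of Rv
segments.

*Identity matrix.* Pairwise protein identity follows the EMBOSS-Needle
convention — identical positions divided by alignment length including
gaps — from a BLOSUM62 global alignment with gap open 10 and extension
0.5.

*Read support.* Variant junctions are the boundaries of the pairwise
common-prefix/common-suffix difference regions between references. A
read (matched on both strands, edit distance via infix alignment)
supports a variant only when strictly closer to it than to every other
variant and when its placement spans a junction with `junction_flank`
bases on each side; ties are discarded as ambiguous.

## Immunity (`immunity`)

The virion repressor form is obtained by excising the prophage and
re-calling the open reading frame from the annotated start in the
circular frame (reading across the attP junction to the first in-frame
stop); the prophage form is translated in the integrated frame. The
architecture is called integration-dependent when the virion ORF crosses
the attP junction. The ssrA-like tag is a configurable regular
expression over the C-terminal window (default: last 15 residues,
pattern `[AGCSTVLIMP]AA$`, i.e. an Ala-Ala terminus preceded by a
small/nonpolar residue); the published tag is shown only as a figure
inset, so no specific residue string is asserted anywhere — acceptance
logic uses extension length only.

## Induction (`induction`)

Fold enrichment divides mean prophage depth by mean host depth. By
default the prophage interval is excluded from the host mean so strong
induction does not inflate the denominator; `host_mean_includes_prophage`
restores the literal whole-genome denominator (the two differ by <1%
for a prophage occupying a few percent of the chromosome). Termini are
positions where the ratio of mean depths over the `window` bases
upstream versus downstream (or its inverse) exceeds `min_step` and is a
local maximum within `window`; ties break leftmost. Windows wrap
circularly by default (rotation-equivariant, suited to a circularized
replicating genome); `circular=False` suits a linear virion assembly,
where positions within `window` of the ends are not evaluated. Note
that a two-level circular track necessarily has two steps — the
complement of the terminus step appears at the origin.

## Flow cytometry (`flow`)

Gates are 3-D rectangles with open ends; "inside" is strictly within
the open interval on all three channels simultaneously, so an event
exactly at a printed boundary (e.g. FSC-H = 50) is retained. Debris
takes precedence over beads on overlap, making the three counts a
partition. Group comparison uses the two-tailed Welch t-test
(`equal_var` switches to pooled); the degenerate all-identical case
returns p = 1 instead of NaN. FCS binary parsing is out of scope:
events are consumed as CSV with FSC-H/SSC-H/FL1-H columns.

## Synthetic data (`synthetic`)

One top-level seed fans out to per-generator streams via
`SeedSequence([seed, crc32(name)])`, so components regenerate
independently and identical seeds give byte-identical output.

Defaults mirror the study conditions: att core 35 bp with a 7 bp
crossover and 3 flank mismatches per side; rix motif TTCCCTAACCC with
five Rv segments of 95–100 codons behind a 168-codon Rc head; host
Poisson depth λ=30 with fold enrichment in the 5–60 range and a
half-depth step at the terminus; flow mixtures of 75% debris, 20%
beads, 5% phage-like particles with a treated-sample particle
multiplier (the particle fraction is kept small — with fixed
background, the expected gated-abundance fold is e/(1−p+pe), which
approaches the planted effect only for small p); IS elements of
1,399 bp with 50 bp terminal inverted repeats and 3 bp target-site
duplications.

The lysogen generator builds the attB core as the 3′ end of a real
marker ORF and integrates the phage with the package's own `integrate`,
so excision truth (marker restoration, byte-identical round trip) holds
by construction. The shufflon generator manages reading frames so that
each correctly oriented Rv terminates the fused ORF exactly at its
boundary and no reverse-complemented segment can mimic a valid allele
(segments may not begin with TTA/CTA/TCA, whose reverse complements are
stop codons).

What the generators do **not** emulate: real mosaic homology between
related prophages, sequencing error profiles beyond uniform
substitutions (no indels or quality strings), GC skew or coverage bias,
instrument-specific flow artifacts (aggregation, compensation), or the
biological uncertainty in rix layout. Passing tests therefore
demonstrate algorithmic correctness on the planted architectures, not
robustness to every artifact of real data.

## Problem sizes and tolerances

The test suite runs at desk scale by design: 200 seeded lysogens
(1.2 kb hosts) for round-trip identity, 100 seeds each for crossover
recovery (cores 20–45 bp) and terminus localization (20 kb tracks,
window 100), folds {5, 10, 20, 60} at λ=20 with a 10% relative
tolerance, and flow pairs of 100,000 events with a 10% tolerance on the
planted effect. Alignment oracles cover all published site pairs plus
300 random pairs up to 60 bp. The entire suite completes in a few
seconds on one CPU.

## Known limitations

- The star multiple alignment is only appropriate for near-identical
  sites (≤`max_gaps` indels against the longest); it is not a general
  MSA.
- Unique-anchor chaining cannot place blocks inside long perfect
  repeats (anchors must be unique in both sequences); the IS-element
  workflow therefore evaluates uniqueness within the compared intervals
  only.
- `find_insertions` reports net extra sequence (`gap_a − gap_b`),
  which includes a target-site duplication when present; separating
  element from duplication is the job of `is_element_signature`.
- Inversion-state enumeration is exhaustive and intended for cassettes
  with at most ~8 rix sites; beyond that the closure growth makes the
  `max_states` cap necessary.
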