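# pforge

Computational characterization of temperate prophages in human
gut-associated *Bifidobacterium breve* and *B. longum*: attachment-site
reconstruction and in-silico excision, shufflon (Rin) inversion
enumeration and receptor-binding-protein (RBP) allele calling,
integration-dependent-immunity repressor reconstruction, sequencing-
coverage induction quantification, IS-element insertion signatures, and
flow-cytometry gating statistics.

The package is aimed at phage and microbiome bioinformaticians working
with lysogens: everything is importable library code, with ground-truth
synthetic-data generators so each analysis is testable without any
external downloads. Short narrative scripts live in `examples/`.

## The models

**Attachment sites.** A tyrosine integrase recombines the phage site
*attP* = P·O·P′ with the bacterial site *attB* = B·O·B′ across a short
common-core overlap *O* (the strand-exchange or crossover window),
leaving the hybrid sites *attL* = B·O·P′ and *attR* = P·O·B′ flanking
the prophage. `pforge.attsite` aligns attL/attR at minimum edit cost,
finds the maximal alignment-column runs conserved across a set of
sites (candidate crossover windows), derives the theoretical attB/attP
by swapping aligned rows at the crossover end, and performs the exact,
reversible string surgery of excision and integration implied by this
algebra. Eleven published prophage records and their attachment-core
sequences ship in `pforge.catalog` — including the 35 bp *dnaJ2*-locus
cores with 5–7 mismatches, the identical 26 bp tmRNA core and the 39 bp
tRNA-Met core — and serve as reference inputs.

**Shufflon.** The Rin shufflon varies the RBP: a constant 5′ gene
portion (*Rc*) is followed by variable 3′-end segments (*Rv*) delimited
by an asymmetric 11 bp crossover motif (*rix*, TTCCCTAACCC). Inversion
between two oppositely oriented rix sites reverse-complements the
intervening block, fusing a different Rv onto Rc. `pforge.shufflon`
discovers rix repeats on both strands, enumerates the breadth-first
closure of all inversion states, translates the fused Rc–Rv allele of
each state, and quantifies sequencing-read support for alternative
cassette orientations.

**Induction.** `pforge.induction` measures prophage replication as the
ratio of mean sequencing depth inside the prophage interval to the host
mean, and locates packaging termini as coverage-step discontinuities.
`pforge.flow` applies the fixed three-dimensional rectangular debris and
bead gates — debris FSC-H (−∞, 50), SSC-H (−∞, 100), FL1-H (−∞, 15);
beads FSC-H (150, 1000), SSC-H (800, 2700), FL1-H (15, 90) — and
summarizes treated/untreated pairs as fold changes in gated-event
abundance and median fluorescence, with Welch two-tailed t-tests across
strain-type groups.

## Worked example

```bash
python examples/attachment_sites.py
```

prints, among other lines:

```
  dnaJ2     Bb48phi1               core=35 bp  mm=7  indels=0
  tmRNA     Bb447phi1/Bb1192phi1   core=26 bp  mm=0  indels=0
  tRNA-Met  Bb423phi2/689b-1       core=39 bp  mm=1  indels=0

Conserved windows across all dnaJ2 att sites (len desc):
  column 25, 8 bp: TGAGCTGA
  column  7, 7 bp: GCAAGTT
```

The first block is the attL-vs-attR alignment per prophage: the aligned
common-core length, substitutions and indels (the two 34 bp cores align
with a single 1-nt gap). The conserved runs across all fourteen
*dnaJ2*-locus sequences include the 7 bp `GCAAGTT` window — the
candidate point of strand exchange — which the script then uses to
derive attB/attP for Bb48phi1. Other examples cover excision round
trips (`excision_roundtrip.py`), shufflon allele counting
(`shufflon_alleles.py`, five distinct Rc–Rv alleles from a five-variant
cassette), the 18-residue tagged repressor extension
(`immunity_repressor.py`), coverage enrichment and termini
(`induction_coverage.py`), IS-element signatures (`is_elements.py`) and
flow gating (`flow_gating.py`).

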