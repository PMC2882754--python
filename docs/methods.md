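# Methods

This note documents the models, conventions and design choices behind
`tailscreen`, and what the shipped tests do and do not demonstrate.

## Motif grammar and scanning

A motif is an ordered list of position constraints — exact residue,
residue class, inline alternative set, or wildcard — with an optional
C-terminal anchor. Matching is windowed, case-insensitive, reports all
(possibly overlapping) occurrences, and uses 1-based inclusive N→C
coordinates throughout.

Conventions that required a decision:

- **Φ = {L, I, M, F, V}.** The bulky-hydrophobic class is nowhere
  enumerated exhaustively in the literature on tyrosine-based signals;
  this is the conventional set, and both well-characterised YXXXΦN
  instances use L or I at the Φ position. The class registry is
  configurable, and a property test guarantees that enlarging a class
  can only add hits.
- **"Within k residues of the C-terminus"** is read literally: at most
  k residues may follow the final matched position. DXXLL is anchored
  at k = 3, so `...DXXLL`, `...DXXLLx`, `...DXXLLxx` and `...DXXLLxxx`
  all qualify.
- **KKXX** is anchored so the lysines occupy exactly the −4/−3
  positions from the C-terminus (pattern `K K x x @C<=0`), the standard
  dibasic ER-retrieval convention. A KXKXX-style relaxation would be a
  different pattern and can be supplied by the user.
- **Non-standard codes** (X/B/Z/U) match wildcards only, never exact
  residues or classes: an ambiguous residue should not create a motif.
- **Census counting is presence-based** (`has_motif`), so multiple
  copies of a motif in one tail count once; YXXXΦN and YXXΦ are counted
  independently even when instances share a tyrosine, because they are
  distinct signals recognised by different binding modes.

The scanner is verified against an independent brute-force
window-by-window matcher on 1000 random tails for all six built-in
patterns.

## Tail extraction

Single-pass records carry 1-based inclusive TMD coordinates. Type I
proteins contribute their post-TMD segment (cytoplasmic C-terminus),
type II their pre-TMD segment (cytoplasmic N-terminus), both stored N→C
as in the full-length protein. No minimum tail length is imposed: a
tail shorter than a pattern simply cannot match, and degenerate empty
tails are returned flagged rather than dropped silently. Census-style
analyses conventionally restrict to type I tails (the CLI `tails`
command takes `--topology`); type II tails are scanned N→C as stored.

## Library construction model

Digestion cuts immediately 5′ of every forward-strand GATC; the
palindromic site means forward-strand occurrences account for both
strands. On the coding strand a fragment is represented including its
leading GATC and excluding the trailing one, so a digest concatenates
back to the genome and no junction nucleotide is double-counted on
ligation. Flipping the (palindromic-ended) duplex gives the
reverse-orientation insert `GATC + revcomp(core)`.

Only the reporter's tail peptide `KRLKRRRI-PISTFHDDR` and the position
of the BamHI site in it (the dash) are fixed by the reporter design;
the shipped vector DNA is one concrete codon-level realization, chosen
so that the BamHI GGATCC spans the R8/I9 codon boundary (`CG|G ATC C`).
The GATC overhang of any ligated fragment then regenerates the R8–I9
junction and insert residues are read from frame 0 of the fragment
core. The vector is a `VectorContext` value and fully configurable; its
empty-vector translation invariant is enforced at construction.

Size selection is inclusive on both bounds, [50, 100] bp, the literal
reading of a 50–100 bp gel cut. Complete digestion is assumed; partial
digestion is out of scope. Sampling a library draws clones uniformly
over (fragment instance, orientation) pairs, so repeated genomic
sequences are proportionally overrepresented, as observed in real
pooled libraries; religated empty vector is excluded.

Clone statistics use the insert peptide as clone identity and report
distinct/singleton counts, observed insert residue frequencies, and a
chi-square goodness of fit against the frequencies of the eligible
fragment pool read in the ligation frame (df = 19 over the 20 residues;
residues absent from the pool are excluded with df reduced).

## Screen model

One-compartment uptake without recycling over a 40-minute window:
internalized fraction `f = 1 − exp(−k t)` with
`k = k0 · r · s/(s + E)`, where `r` is the tail's relative
internalization rate, `k0 = 0.04 min⁻¹` (≈ 80% uptake for a reference
signal at low expression), `E` is log-normal surface expression
(median 1, log-SD 1) and `s = 10` is the saturation scale — uptake
efficiency declines at high expression, as seen in the curvature of
real FACS profiles. Channels:

    green = E · (f + (1 − q)(1 − f)) · ε      (internalized + unquenched surface)
    red   = E · (1 − f) · ε′                  (surface relabel)

with quench efficiency `q = 0.9` (quenching is never complete; no
quantitative value is published, so this is an explicit configuration
default, not a claim) and independent log-normal channel noises
(log-SD 0.2).

The relative-rate rule ladder encodes the observed efficiency ordering
of reporter constructs: YXXΦ and the canonical acidic dileucine at 1.0;
FXNPXY and YXXXΦN at 0.5; a 4-spacer acidic dileucine at 0.9; 2- or
5-spacer variants at 0.5; a bare LL at 0.2 (a weak signal); no signal
at baseline 0.02. Two context modifiers double dileucine-type rates
(capped at 1.0): a proline at −1 of the leucine pair, and a DD pair
within eight residues downstream. First matching rule wins; the ladder
is an ordered, fully replaceable configuration.

Gating mirrors sorting at *equal, relatively low* surface expression:
an expression window (default the 10th–60th percentile of green+red,
which is nearly proportional to E when quenching is efficient) and
plus/minus gates at the top/bottom deciles of the in-window green/red
ratio. A construct counts as *recovered* with ≥ 3 plus-gate cells —
single stray cells are treated as noise, a threshold fixed by a pilot
run at the default screen size (200 constructs, 10% signal-bearing,
20,000 cells), at which plus-gate precision against planted truth is
1.0 across seeds.

## Synthetic data

The proteome generator emulates a tail database of single-pass
proteins: topology mix 27% type I (the proportion in the motivating
4794-tail database: 1266 type I, 3528 type II), log-normal tail lengths
(median ≈ 30 residues, log-SD 0.8, truncated to [4, 200]), uniform
background composition unless specified, hydrophobic 21-residue TMDs
and an 80-residue ectodomain. Motifs are planted per tail with the
specified probabilities at random anchor-respecting positions.

**Truth is defined post hoc by scanning the final tails** with an
independent brute-force matcher, not by the planting plan: incidental
motifs inevitably arise in background sequence (on uniform background
roughly a quarter of 30-residue tails contain an incidental YXXΦ), and
recovery tests should be exact against realized truth rather than
approximate against nominal rates. What passing recovery tests shows is
that the census faithfully counts what is present — not that real
proteomes resemble uniform background; real tail databases have biased
composition, disordered-region structure and correlated motif
placement that the generator does not model.

The genome generator alternates planted GATC sites with
geometric-length gaps (mean `mean_gap`, default 75 bp) assembled from a
codon-usage model, locally resampled so no unplanned GATC arises.
Under geometric spacing the 50–100 bp window captures
`(1−p)^45 − (1−p)^96` of internal fragments (p = 1/mean_gap), about 26%
at the default and at most ≈ 26.5% at any mean gap — so roughly a
quarter of a real Sau3AI digest of a yeast-sized genome is usable,
which is what the default pipeline reproduces.

### Screen-derived tail sequences

The five most efficiently internalized library tails (PIA, PNT, WPK,
RYR, STS) were published only as a figure; their complete sequences are
not machine-recoverable. The package ships **synthetic
reconstructions** (fixture names flagged `*_synthetic`,
`library_insert_tails()`), constrained to reproduce every textual
property: the three-letter insert prefixes; the mutagenesis-critical
triplets (DQD/ILS/PIL and the two IL pairs with acidic residues at
−1/−3/−5/−7 in PIA; RHN/TPL in PNT; WPK/LES/QLD and the C-terminal WF
in WPK; RYRRSLNHK with its Y2/L6/N7-critical YXXXΦN in RYR; YQSI in
STS); the vector context `KRLKRRRI…PISTFHDDR`; and the key census
property that exactly one of the five (STS) carries a classical
internalization motif. Tests against these fixtures validate the
scanner and the screen logic, not the identity of the experimental
clones.

## Problem sizes and numerics

Default test and acceptance problem sizes — 1000 random tails for
oracle equivalence, 5000 tails for census recovery, a 200 kb genome for
digestion statistics, 20,000 cells for the screen — were chosen as the
smallest sizes at which the binomial/Monte-Carlo tolerances used (3–4
standard errors) are already narrow; everything runs in seconds on one
CPU. All generators and simulators take explicit integer seeds and are
bit-reproducible. Ratio computations guard against division by zero
red signal; percentile gates use linear-interpolation percentiles.

## Known limitations

- No position-weight-matrix or affinity models; motifs are hard
  patterns, as in the underlying screen's database searches.
- No signal-peptide/TMD prediction: topology and TMD coordinates are
  inputs.
- The library model omits ligation bias, partial digestion and
  transformation bottlenecks; the screen model omits optics,
  compensation, dead-cell gating and recycling kinetics.
- The published database census values (e.g. the fraction of type I
  tails lacking classical signals) depended on a database snapshot that
  is no longer obtainable; the package reproduces the census
  *semantics* and verifies them on synthetic data instead. An external
  proteome TSV can be supplied for qualitative comparison.
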