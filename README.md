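# tailscreen

Short-linear-motif analysis and simulation tools for screens of
**endocytic sorting signals** in the cytoplasmic tails of single-pass
membrane proteins.

Cargo selection into clathrin-coated vesicles is driven by short linear
motifs in cytoplasmic tails: the classical internalization signals
YXXΦ (Φ = bulky hydrophobic: L/I/M/F/V), [D/E]XXXL[L/I] and FXNPXY,
plus the novel tyrosine-based signal YXXXΦN, the C-terminally restricted
GGA-binding signal DXXLL, and the KKXX ER-retrieval signal. `tailscreen`
implements the computational layer of a reporter-based screen for such
motifs:

- **`tailscreen.motifs`** — a pattern mini-language, compiler and
  scanner for positional motifs with residue classes and C-terminal
  distance anchors (e.g. `D x x L L @C<=3`), with the six signals above
  built in;
- **`tailscreen.tails`** — validated single-TMD protein records and
  topology-aware cytoplasmic-tail extraction (type I: C-terminal tail;
  type II: N-terminal tail);
- **`tailscreen.census`** — per-motif "at least one copy" presence
  counts and symmetric pairwise co-occurrence over a tail database;
- **`tailscreen.library`** — in-silico construction of a random-tail
  reporter library: Sau3AI (`^GATC`) digestion, 50–100 bp size
  selection, ligation in either orientation into a BamHI site inside
  the reporter tail (`KRLKRRRI-PISTFHDDR`), frame-aware translation and
  clone-diversity statistics;
- **`tailscreen.screen`** — simulation of the two-colour antibody-uptake
  FACS screen: log-normal surface expression, one-compartment uptake
  kinetics `f = 1 − exp(−k t)` with expression saturation, imperfect
  quenching of the surface (green) label, surface relabelling (red),
  ratio gating at equal low surface expression, and precision/recall of
  recovered constructs against planted truth;
- **`tailscreen.synth`** — seeded generators for synthetic proteomes
  (with motifs planted at controlled rates and scan-defined realized
  truth) and genomes (controlled GATC spacing and codon usage), plus
  the fixed reporter sequences.

## Worked example

```python
from tailscreen import builtin_motifs, scan_tail, run_census, \
    no_signal_fraction, classical_motifs
from tailscreen.synth import ProteomeSpec, synth_proteome

reg = builtin_motifs()

# The C-terminal octapeptide of CTLA-4 carries a YXXXΦN signal:
for h in scan_tail("QPYFIPIN", reg["YXXXΦN"]):
    print(f"{h.motif_name}: {h.matched_sequence} at {h.start}-{h.end}")

# Census over a synthetic proteome with planted motif frequencies:
spec = ProteomeSpec(n_proteins=1000,
                    plant_rates={"YXXΦ": 0.3, "[D/E]XXXL[L/I]": 0.2},
                    seed=1)
_, tails, truth = synth_proteome(spec)
table = run_census(tails, reg)
print("tails:", table.n_tails)
print("YXXΦ singles:", table.singles["YXXΦ"])
print("pair YXXΦ & [D/E]XXXL[L/I]:", table.pairs["YXXΦ"]["[D/E]XXXL[L/I]"])
print("no classical signal: %.0f%%"
      % (100 * no_signal_fraction(tails, classical_motifs().values())))
```

prints

```
YXXXΦN: YFIPIN at 3-8
tails: 1000
YXXΦ singles: 509
pair YXXΦ & [D/E]XXXL[L/I]: 103
no classical signal: 39%
```

`YFIPIN` matches Y-x-x-x-Φ-N at tail positions 3–8 (1-based,
inclusive). Of the 1000 synthetic tails, 509 contain at least one YXXΦ
window — the 30% planted plus incidental matches arising in background
sequence — 103 contain both a YXXΦ and an acidic dileucine, and 39%
contain none of the three classical internalization signals.

A command-line interface mirrors the library
(`tailscreen scan | tails | census | build-library | simulate-screen | synth`);
run `tailscreen --help` for details.

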