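"""Synthetic proteomes, genomes and literature-derived fixture sequences.

Every pipeline stage is testable without downloads: this module
generates (i) proteomes of single-pass membrane proteins with motifs
planted at controlled rates, (ii) genomes with controllable GATC-site
spacing and codon usage for the library simulator, and (iii) the small
set of fixed sequences used by the reporter system (designer tails, the
vector tail, and reconstructions of the library-derived tails).

Truth labels for planted proteomes are defined *post hoc* by an
independent brute-force scan of every generated tail, not by the
planting plan: incidental motifs inevitably arise in background
sequence, and recovery tests should compare against realized truth.
The brute-force matcher here is deliberately separate from the compiled
scanner in :mod:`tailscreen.motifs`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .library import Genome
from .motifs import MotifPattern, builtin_motifs
from .tails import CytoplasmicTail, MembraneProteinRecord, extract_tail

__all__ = [
    "ProteomeSpec",
    "GenomeSpec",
    "synth_proteome",
    "synth_genome",
    "brute_force_has_motif",
    "fixtures",
    "designer_tails",
    "library_insert_tails",
]

_AA20 = "ACDEFGHIKLMNPQRSTVWY"
_HYDROPHOBIC = "AFILMV"


@dataclass(frozen=True)
class ProteomeSpec:
    """Parameters of a synthetic single-pass proteome.

    ``plant_rates`` maps built-in motif names to per-tail planting
    probabilities; planted instances are written over background
    residues at random (anchor-respecting) tail positions. Tail lengths
    are drawn from a log-normal (in residues) truncated to
    ``[min_tail, max_tail]`` — short tails of a few tens of residues
    dominate, with a long right tail, loosely mimicking real
    single-pass-protein tail databases.
    """

    n_proteins: int = 1000
    topology_mix: float = 0.27  # fraction type I (1266 of 4794 in scale)
    tail_length_log_mean: float = 3.4  # exp(3.4) ~ 30 residues
    tail_length_log_sd: float = 0.8
    min_tail: int = 4
    max_tail: int = 200
    background_composition: Mapping[str, float] | None = None  # uniform if None
    plant_rates: Mapping[str, float] = field(default_factory=dict)
    ectodomain_length: int = 80
    tmd_length: int = 21
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.topology_mix <= 1.0):
            raise ValueError("topology_mix must be in [0, 1]")
        for nm, p in self.plant_rates.items():
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"plant rate for {nm!r} outside [0, 1]")
        if self.background_composition is not None:
            total = sum(self.background_composition.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError("background composition must sum to 1")


@dataclass(frozen=True)
class GenomeSpec:
    """Parameters of a synthetic genome for digestion experiments.

    Inter-GATC gaps are geometric with mean ``mean_gap`` (so fragment
    lengths are gap + 4); gap sequence is sampled codon-by-codon from
    ``codon_usage`` (uniform over the 61 sense codons if None), with
    local resampling so no unplanned GATC arises.
    """

    length: int = 50000
    mean_gap: float = 75.0
    codon_usage: Mapping[str, float] | None = None
    seed: int = 0

    def __post_init__(self):
        if self.length < 1:
            raise ValueError("length must be >= 1")
        if self.mean_gap <= 0:
            raise ValueError("mean_gap must be positive")


def _matches_brute(seq: str, pattern: MotifPattern, i: int) -> bool:
    for j, elem in enumerate(pattern.elements):
        ch = seq[i + j]
        if elem.allowed is not None and ch not in elem.allowed:
            return False
    return True


def brute_force_has_motif(seq: str, pattern: MotifPattern) -> bool:
    """Independent window-by-window matcher used to define truth labels."""
    seq = seq.upper()
    plen = len(pattern)
    for i in range(len(seq) - plen + 1):
        if pattern.anchored:
            if len(seq) - (i + plen) > pattern.max_tail_residues_after_match:
                continue
        if _matches_brute(seq, pattern, i):
            return True
    return False


def _sample_motif_instance(pattern: MotifPattern, rng, bg, bg_p) -> str:
    out = []
    for elem in pattern.elements:
        if elem.allowed is None:
            out.append(rng.choice(bg, p=bg_p))
        else:
            out.append(rng.choice(sorted(elem.allowed)))
    return "".join(out)


def _plant(tail: list, pattern: MotifPattern, rng, bg, bg_p) -> bool:
    """Overwrite a random anchor-respecting window with a motif instance."""
    plen = len(pattern)
    n = len(tail)
    if n < plen:
        return False
    if pattern.anchored:
        lo = max(0, n - plen - pattern.max_tail_residues_after_match)
        positions = range(lo, n - plen + 1)
    else:
        positions = range(0, n - plen + 1)
    positions = list(positions)
    if not positions:
        return False
    start = int(rng.choice(positions))
    inst = _sample_motif_instance(pattern, rng, bg, bg_p)
    tail[start : start + plen] = list(inst)
    return True


def synth_proteome(spec: ProteomeSpec):
    """Generate a proteome of single-pass proteins plus realized truth.

    Returns ``(records, tails, truth)`` where ``truth`` maps protein id
    to a dict of motif-name → bool presence labels, computed by the
    independent brute-force matcher on the final tail sequences (planted
    plus incidental occurrences).
    """
    rng = np.random.default_rng(spec.seed)
    registry = builtin_motifs()
    for nm in spec.plant_rates:
        if nm not in registry:
            raise KeyError(f"unknown motif {nm!r} in plant_rates")
    if spec.background_composition is None:
        bg = list(_AA20)
        bg_p = np.full(len(bg), 1.0 / len(bg))
    else:
        bg = [aa for aa, p in spec.background_composition.items() if p > 0]
        bg_p = np.array([spec.background_composition[aa] for aa in bg])
        bg_p = bg_p / bg_p.sum()

    records, tails_out, truth = [], [], {}
    for i in range(spec.n_proteins):
        pid = f"syn{i:05d}"
        topology = "I" if rng.random() < spec.topology_mix else "II"
        # draw a tail long enough for the longest planted motif
        max_retries = 50
        for _ in range(max_retries):
            tl = int(round(rng.lognormal(spec.tail_length_log_mean, spec.tail_length_log_sd)))
            tl = min(max(tl, spec.min_tail), spec.max_tail)
            planted_names = [
                nm for nm, p in spec.plant_rates.items() if rng.random() < p
            ]
            if all(len(registry[nm]) <= tl for nm in planted_names):
                break
        tail = list(rng.choice(bg, size=tl, p=bg_p))
        for nm in planted_names:
            _plant(tail, registry[nm], rng, bg, bg_p)
        tail_seq = "".join(tail)
        tmd = "".join(rng.choice(list(_HYDROPHOBIC), size=spec.tmd_length))
        ecto = "".join(rng.choice(bg, size=spec.ectodomain_length, p=bg_p))
        if topology == "I":
            seq = ecto + tmd + tail_seq
            tmd_start = len(ecto) + 1
        else:
            seq = tail_seq + tmd + ecto
            tmd_start = len(tail_seq) + 1
        rec = MembraneProteinRecord(
            id=pid,
            sequence=seq,
            tmd_start=tmd_start,
            tmd_end=tmd_start + spec.tmd_length - 1,
            topology=topology,
            source_note="synthetic",
        )
        records.append(rec)
        tails_out.append(extract_tail(rec))
        truth[pid] = {
            nm: brute_force_has_motif(tail_seq, pat) for nm, pat in registry.items()
        }
    return records, tails_out, truth


_BASES = "ACGT"
_STOPS = {"TAA", "TAG", "TGA"}
_SENSE_CODONS = [
    a + b + c
    for a in _BASES
    for b in _BASES
    for c in _BASES
    if a + b + c not in _STOPS
]


def synth_genome(spec: GenomeSpec) -> Genome:
    """Generate a genome with geometric GATC spacing and set codon usage.

    The sequence alternates planted GATC sites with gap stretches whose
    lengths are geometric with mean ``mean_gap``; gaps are assembled
    from codons drawn from ``codon_usage`` and locally resampled if they
    would create an unplanned GATC, so realized site spacing tracks the
    spacing model.
    """
    rng = np.random.default_rng(spec.seed)
    if spec.codon_usage is None:
        codons = _SENSE_CODONS
        codon_p = np.full(len(codons), 1.0 / len(codons))
    else:
        total = sum(spec.codon_usage.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError("codon usage must sum to 1")
        codons = [c for c, p in spec.codon_usage.items() if p > 0]
        codon_p = np.array([spec.codon_usage[c] for c in codons])
        codon_p = codon_p / codon_p.sum()

    p_gap = 1.0 / max(spec.mean_gap, 1.0)
    chunks = []
    total_len = 0
    while total_len < spec.length:
        gap_len = int(rng.geometric(p_gap))
        gap = _gap_sequence(gap_len, rng, codons, codon_p)
        chunks.append(gap)
        total_len += len(gap)
        if total_len >= spec.length:
            break
        chunks.append("GATC")
        total_len += 4
    seq = "".join(chunks)[: spec.length]
    return Genome(id=f"syngenome_seed{spec.seed}", sequence=seq, circular=False)


def _gap_sequence(n: int, rng, codons, codon_p) -> str:
    """A length-n stretch with no internal GATC (local resampling)."""
    out = ""
    while len(out) < n:
        for _ in range(100):
            codon = str(rng.choice(codons, p=codon_p))
            if "GATC" not in (out[-3:] + codon):
                out += codon
                break
        else:  # pragma: no cover - effectively unreachable
            out += "AAA"
    # trimming cannot create GATC, only destroy it
    return out[:n]


# --------------------------------------------------------------------------
# fixed sequences of the reporter system


def designer_tails() -> dict:
    """The four designer variable regions, assembled as P + 8 residues + V.

    Each region places its signal inside eight residues between the
    shared proline and valine: an all-alanine negative control and one
    representative of each classical internalization-signal class
    (YAAL for YXXΦ, EAAALL for [D/E]XXXL[L/I], FANPAY for FXNPXY).
    """
    regions = {
        "8xA": "AAAAAAAA",
        "YAAL": "AAYAALAA",
        "EAAALL": "AEAAALLA",
        "FANPAY": "AFANPAYA",
    }
    return {name: "P" + region + "V" for name, region in regions.items()}


def library_insert_tails() -> dict:
    """SYNTHETIC reconstructions of the five screen-derived reporter tails.

    The complete insert sequences were published only as a figure, so
    they cannot be transcribed here; these stand-ins are synthetic
    sequences constrained to reproduce every property reported in the
    text: the three-residue nomenclature prefix of each insert, the
    residue triplets probed by mutagenesis (e.g. DQD/ILS/PIL in the PIA
    tail, RHN/TPL in PNT, WPK/LES/QLD and the C-terminal WF in WPK, and
    RYRRSLNHK in RYR), the YQSI motif in STS, the vector context
    KRLKRRRI…PISTFHDDR, and — critically — that STS is the *only* one of
    the five carrying a classical internalization motif. Do not mistake
    them for the experimental clone sequences.
    """
    prefix = "KRLKRRRI"
    suffix = "PISTFHDDR"
    inserts = {
        # two IL pairs with acidic residues at -1/-3/-5/-7 of the second
        "PIA": "PIASDQDILSPIL",
        # RHN and TPL triplets; the dileucine-like TPL-IPI signal spans
        # the insert/vector junction
        "PNT": "PNTRHNSQSTPL",
        # no tyrosines, no dileucine-like pairs; C-terminal WF (the
        # insert carries a stop, so the vector C-terminus is absent)
        "WPK": "WPKLESQLDSGWF",
        # the novel-signal tail: YRRSLN = Y-x-x-x-Φ-N at residues 2-7
        "RYR": "RYRRSLNHKSG",
        # the single classical-motif carrier: YQSI = YXXΦ
        "STS": "STSAGYQSIES",
    }
    tails = {}
    for name, ins in inserts.items():
        if name == "WPK":
            tails[name] = prefix + ins  # stop-truncated before the vector C-terminus
        else:
            tails[name] = prefix + ins + suffix
    return tails


def fixtures() -> dict:
    """Named fixed sequences of the reporter system.

    Sequences recoverable verbatim from the published text (the vector
    tail peptide, the RYR insert prefix, the CTLA-4 C-terminal
    octapeptide, the designer regions) carry plain names; the five full
    library tails are figure-only and are shipped as clearly flagged
    synthetic reconstructions (``*_synthetic``), see
    :func:`library_insert_tails`.
    """
    fx = {
        "vector_tail": "KRLKRRRIPISTFHDDR",
        "ryr_insert_prefix": "RYRRSLNHK",
        "ctla4_cterm": "QPYFIPIN",
    }
    for name, tail in designer_tails().items():
        fx[f"designer_{name}"] = tail
    for name, tail in library_insert_tails().items():
        fx[f"library_tail_{name}_synthetic"] = tail
    return fx
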