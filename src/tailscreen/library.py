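"""In-silico construction of a random cytoplasmic-tail reporter library.

The library emulates the classic cloning route for random-tail reporter
chimeras: genomic DNA is digested with Sau3AI (which cuts ``^GATC`` and
leaves a BamHI-compatible 5′ overhang), fragments of 50–100 bp are size
selected, and each fragment is ligated — in either orientation — into a
BamHI site within the reporter's cytoplasmic-tail coding sequence. The
empty (religated) vector translates to the tail peptide
``KRLKRRRIPISTFHDDR``; an insert is spliced between the ``...KRLKRRRI``
and ``PISTFHDDR`` halves and read in the vector frame, so out-of-frame
inserts scramble or truncate the vector C-terminus.

Junction bookkeeping
--------------------
On the coding strand a Sau3AI fragment is represented *including its
leading GATC and excluding the trailing one* (which belongs to the next
fragment), so concatenating a digest reconstructs the genome and no
junction nucleotide is double-counted when splicing::

    vector:   ...C G | G A T C C ...        (BamHI G^GATCC)
    insert:         G A T C <core>
    ligated:  ...C G G A T C <core> G A T C C ...

Flipping a fragment end-for-end keeps its palindromic overhangs, so the
reverse-orientation insert is ``GATC + revcomp(core)``.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from Bio.Seq import Seq
from scipy import stats

__all__ = [
    "Genome",
    "RestrictionFragment",
    "VectorContext",
    "TailConstruct",
    "LibraryStats",
    "LigationError",
    "VECTOR_TAIL_PEPTIDE",
    "revcomp",
    "default_vector",
    "digest",
    "size_select",
    "ligate_and_translate",
    "build_constructs",
    "sample_library",
    "library_stats",
]

DNA_ALPHABET = frozenset("ACGT")

#: Cytoplasmic tail of the empty reporter vector; the insertion point
#: (BamHI site) sits between the I and the P.
VECTOR_TAIL_PEPTIDE = "KRLKRRRIPISTFHDDR"

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class LigationError(ValueError):
    """Fragment lacks the sticky ends required for ligation."""


@dataclass(frozen=True)
class Genome:
    """A DNA molecule to digest; may be circular (e.g. a plasmid)."""

    id: str
    sequence: str
    circular: bool = False

    def __post_init__(self):
        seq = self.sequence.upper()
        if not seq:
            raise ValueError("genome sequence is empty")
        bad = set(seq) - DNA_ALPHABET
        if bad:
            raise ValueError(f"genome {self.id!r} contains non-ACGT characters: {sorted(bad)}")
        object.__setattr__(self, "sequence", seq)


@dataclass(frozen=True)
class RestrictionFragment:
    """A digest product on the forward strand; 1-based inclusive coords.

    Internal fragments begin with the GATC overhang. For circular
    genomes the final fragment wraps past the origin, so ``end`` may
    exceed the genome length (positions are taken mod L).
    """

    start: int
    end: int
    sequence: str
    left_overhang_present: bool
    right_overhang_present: bool

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def id(self) -> str:
        return f"frag_{self.start}_{self.end}"


def digest(genome: Genome, site: str = "GATC") -> list:
    """Cut the genome immediately 5′ of every forward-strand ``site``.

    The recognition site must be palindromic (Sau3AI-style), so
    forward-strand occurrences account for both strands and cuts are
    blunt-positioned at the same point on either strand's GATC. Linear
    genomes yield overhang-free terminal fragments; circular genomes
    yield only overhang-bearing fragments (or one uncut circle).
    Concatenating the output reconstructs the genome (a rotation of it
    for circular input).
    """
    site = site.upper()
    if revcomp(site) != site:
        raise ValueError(f"recognition site {site!r} is not palindromic")
    if set(site) - DNA_ALPHABET:
        raise ValueError(f"recognition site {site!r} is not plain DNA")
    seq = genome.sequence
    L = len(seq)
    k = len(site)

    if genome.circular:
        extended = seq + seq[: k - 1]
        cuts = [i for i in range(L) if extended[i : i + k] == site]
        if not cuts:
            return [RestrictionFragment(1, L, seq, False, False)]
        frags = []
        for idx, c in enumerate(cuts):
            nxt = cuts[(idx + 1) % len(cuts)]
            if nxt > c:
                frag_seq = seq[c:nxt]
                end = nxt  # 1-based inclusive == nxt
            else:  # wraps the origin
                frag_seq = seq[c:] + seq[:nxt]
                end = L + nxt
            frags.append(RestrictionFragment(c + 1, end, frag_seq, True, True))
        return frags

    cuts = [i for i in range(L - k + 1) if seq[i : i + k] == site]
    bounds = [0] + cuts + [L]
    frags = []
    for idx in range(len(bounds) - 1):
        a, b = bounds[idx], bounds[idx + 1]
        if a == b:  # site at position 0: no leading fragment
            continue
        frags.append(
            RestrictionFragment(
                start=a + 1,
                end=b,
                sequence=seq[a:b],
                left_overhang_present=idx > 0,
                right_overhang_present=idx < len(bounds) - 2,
            )
        )
    return frags


def size_select(
    fragments: Iterable[RestrictionFragment], min_bp: int = 50, max_bp: int = 100
) -> list:
    """Gel-purification stage: keep fragments with min_bp ≤ length ≤ max_bp.

    Bounds are inclusive on both sides; input order is preserved.
    """
    if min_bp > max_bp:
        raise ValueError("min_bp must be <= max_bp")
    return [f for f in fragments if min_bp <= len(f) <= max_bp]


@dataclass(frozen=True)
class VectorContext:
    """Coding-strand context around the BamHI insertion point.

    ``upstream_coding`` runs from the first codon of the tail to the
    BamHI cut (G^GATCC); ``downstream_coding`` runs from the cut through
    the stop codon. The empty (religated) vector must translate exactly
    to ``KRLKRRRIPISTFHDDR``; this is checked at construction.
    ``frame_offset`` is ``len(upstream_coding) % 3``, i.e. how far into
    a codon the insertion point falls.
    """

    upstream_coding: str
    downstream_coding: str

    def __post_init__(self):
        object.__setattr__(self, "upstream_coding", self.upstream_coding.upper())
        object.__setattr__(self, "downstream_coding", self.downstream_coding.upper())
        pep = _translate(self.upstream_coding + self.downstream_coding)
        if pep != VECTOR_TAIL_PEPTIDE:
            raise ValueError(
                f"empty vector translates to {pep!r}, expected {VECTOR_TAIL_PEPTIDE!r}"
            )

    @property
    def frame_offset(self) -> int:
        return len(self.upstream_coding) % 3


def default_vector() -> VectorContext:
    """The shipped vector context.

    Only the tail peptide and the position of the BamHI site within it
    are fixed by the reporter design; the nucleotide sequence below is
    one concrete codon-level realization consistent with both, and is
    configurable. The BamHI GGATCC spans the R8/I9 codon boundary
    (``CG|G ATC C..``), so the GATC overhang of a ligated Sau3AI
    fragment regenerates the vector's own R-I junction codons and insert
    residues are read in frame 0 of the fragment core.
    """
    upstream = (
        "AAG" "CGT" "CTG" "AAG" "CGT" "CGT"  # K R L K R R
        + "CG"  # first two nt of the R codon CGG; BamHI cut after the next G
    )
    downstream = (
        "G"  # completes CGG = R
        + "ATC"  # I
        + "CCA"  # P
        + "ATC" "TCT" "ACT" "TTC" "CAC" "GAC" "GAC" "AGA"  # I S T F H D D R
        + "TAA"
    )
    return VectorContext(upstream_coding=upstream, downstream_coding=downstream)


def _translate(dna: str) -> str:
    """Translate from frame 0, stopping at the first stop codon."""
    usable = len(dna) - len(dna) % 3
    pep = str(Seq(dna[:usable]).translate())
    stop = pep.find("*")
    return pep if stop < 0 else pep[:stop]


@dataclass(frozen=True)
class TailConstruct:
    """One library clone: a translated reporter tail.

    ``tail_peptide`` always begins with the vector's ``KRLKRRRI``; if
    the insert preserved frame and introduced no stop codon it also ends
    with ``PISTFHDDR``. ``insert_peptide`` is the stretch encoded by the
    insert (and, for frameshifted clones, by out-of-frame vector
    sequence), used for clone-identity statistics.
    """

    fragment_id: str
    orientation: str  # "forward" | "reverse"
    tail_peptide: str
    truncated_by_stop: bool
    vector_cterm_in_frame: bool
    insert_peptide: str = ""


def ligate_and_translate(
    fragment: RestrictionFragment,
    orientation: str,
    vector: VectorContext,
) -> TailConstruct:
    """Splice a Sau3AI fragment into the vector and translate the tail.

    The insert contributes its sequence (reverse-complemented core for
    reverse orientation, with the palindromic GATC overhang regenerated)
    between the vector halves. Translation proceeds from the vector
    frame; a stop codon inside the insert — or one induced by a
    frameshift — truncates the peptide. The vector C-terminus is in
    frame iff the insert length is a multiple of 3.
    """
    if orientation not in ("forward", "reverse"):
        raise ValueError(f"orientation must be 'forward' or 'reverse', got {orientation!r}")
    if not (fragment.left_overhang_present and fragment.right_overhang_present):
        raise LigationError(
            f"fragment {fragment.id} lacks a Sau3AI overhang and cannot be ligated"
        )
    if orientation == "forward":
        insert = fragment.sequence
    else:
        insert = "GATC" + revcomp(fragment.sequence[4:])
    coding = vector.upstream_coding + insert + vector.downstream_coding
    full_len = len(coding) - len(coding) % 3
    raw = str(Seq(coding[:full_len]).translate())
    stop = raw.find("*")
    in_frame = len(insert) % 3 == 0
    if stop < 0:
        peptide = raw
        truncated = False  # frameshift ran through the vector stop
    else:
        peptide = raw[:stop]
        # the vector's own stop is the last codon only when frame is kept
        truncated = not (in_frame and stop == full_len // 3 - 1)
    after_prefix = peptide[len("KRLKRRRI") :]
    if in_frame and not truncated:
        insert_pep = after_prefix[: -len("PISTFHDDR")]
    else:
        insert_pep = after_prefix
    return TailConstruct(
        fragment_id=fragment.id,
        orientation=orientation,
        tail_peptide=peptide,
        truncated_by_stop=truncated,
        vector_cterm_in_frame=in_frame,
        insert_peptide=insert_pep,
    )


def build_constructs(
    fragments: Sequence[RestrictionFragment],
    vector: VectorContext | None = None,
) -> list:
    """Ligate every fragment in both orientations.

    One construct per (fragment instance, orientation), so uniform
    sampling over the result weights clones by fragment multiplicity in
    the digest and gives both orientations equal probability.
    Religation (the empty vector) is not represented.
    """
    if vector is None:
        vector = default_vector()
    constructs = []
    for frag in fragments:
        for orientation in ("forward", "reverse"):
            constructs.append(ligate_and_translate(frag, orientation, vector))
    return constructs


def sample_library(constructs: Sequence[TailConstruct], n: int, seed: int) -> list:
    """Draw ``n`` clones with replacement from the construct pool.

    Sampling is uniform over construct instances; because repeated
    genomic fragments appear as separate instances, repeats are
    proportionally overrepresented, as in a real pooled library.
    """
    if not constructs:
        raise ValueError("construct pool is empty")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(constructs), size=n)
    return [constructs[i] for i in idx]


@dataclass(frozen=True)
class LibraryStats:
    """Clone-diversity and composition statistics of a library sample."""

    n_clones: int
    n_distinct: int
    n_singletons: int
    aa_freq_observed: dict
    aa_freq_expected: dict
    gof_statistic: float
    gof_pvalue: float
    gof_df: int

    def __post_init__(self):
        if not (self.n_singletons <= self.n_distinct <= self.n_clones):
            raise ValueError("need n_singletons <= n_distinct <= n_clones")


_AA20 = "ACDEFGHIKLMNPQRSTVWY"


def _aa_counts(peptides: Iterable[str]) -> Counter:
    counts: Counter = Counter()
    for pep in peptides:
        counts.update(ch for ch in pep if ch in _AA20)
    return counts


def library_stats(
    sample: Sequence[TailConstruct],
    pool: Sequence[TailConstruct] | None = None,
) -> LibraryStats:
    """Diversity and amino-acid composition statistics of a clone sample.

    Clone identity is the insert peptide sequence. Observed residue
    frequencies are computed over the sampled insert peptides; expected
    frequencies come from the eligible construct pool read in the
    ligation frame (defaulting to the sample itself when no pool is
    given). The goodness-of-fit statistic is a chi-square over the 20
    residues (df = 19) comparing observed counts with pool-frequency
    expectations; residues absent from the pool are excluded from the
    statistic (with the df reduced accordingly).
    """
    if not sample:
        raise ValueError("sample is empty")
    peptides = [c.insert_peptide for c in sample]
    multiplicity = Counter(peptides)
    n_distinct = len(multiplicity)
    n_singletons = sum(1 for v in multiplicity.values() if v == 1)

    obs_counts = _aa_counts(peptides)
    pool_counts = _aa_counts(c.insert_peptide for c in (pool if pool else sample))
    n_obs = sum(obs_counts.values())
    n_pool = sum(pool_counts.values())
    observed = {aa: obs_counts.get(aa, 0) / n_obs if n_obs else 0.0 for aa in _AA20}
    expected = {aa: pool_counts.get(aa, 0) / n_pool if n_pool else 0.0 for aa in _AA20}

    support = [aa for aa in _AA20 if expected[aa] > 0]
    if n_obs and support:
        f_obs = np.array([obs_counts.get(aa, 0) for aa in support], dtype=float)
        f_exp = np.array([expected[aa] * n_obs for aa in support], dtype=float)
        chi2, pval = stats.chisquare(f_obs, f_exp)
        df = len(support) - 1
    else:
        chi2, pval, df = 0.0, 1.0, 0
    return LibraryStats(
        n_clones=len(sample),
        n_distinct=n_distinct,
        n_singletons=n_singletons,
        aa_freq_observed=observed,
        aa_freq_expected=expected,
        gof_statistic=float(chi2),
        gof_pvalue=float(pval),
        gof_df=df,
    )
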