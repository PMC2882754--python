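"""Short-linear-motif grammar and scanner for cytoplasmic tail sequences.

Endocytic sorting signals are short linear motifs: a handful of positions,
each constrained to an exact residue, a residue class (e.g. the bulky
hydrophobic class Φ) or left free. Some signals are only functional near
the C-terminus, so patterns may carry a C-terminal distance anchor.

Patterns are written in a whitespace-separated mini-language:

    ``Y x x {Phi}``            tyrosine-based YXXΦ signal
    ``[DE] x x x L [LI]``      acidic dileucine [D/E]XXXL[L/I]
    ``D x x L L @C<=3``        GGA-binding DXXLL, at most 3 residues
                               may follow the match before the C-terminus

Tokens: a single upper-case letter is an exact residue; ``x`` is a
wildcard; ``[..]`` is an inline alternative set; ``{name}`` references a
named :class:`ResidueClass`; an optional trailing ``@C<=k`` anchors the
match to the C-terminus. Coordinates in all reports are 1-based,
inclusive, N→C.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

__all__ = [
    "AMINO_ACIDS",
    "ResidueClass",
    "PositionSpec",
    "MotifPattern",
    "MotifHit",
    "PatternError",
    "default_classes",
    "compile_pattern",
    "format_pattern",
    "builtin_motifs",
    "classical_motifs",
    "scan_tail",
    "has_motif",
    "read_motif_table",
    "write_hits_tsv",
    "CLASSICAL_MOTIF_NAMES",
    "BUILTIN_MOTIF_SPECS",
]

#: The 20 standard one-letter amino-acid codes.
AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")

_ANCHOR_RE = re.compile(r"^@C<=(\d+)$")


class PatternError(ValueError):
    """Raised when a pattern string cannot be compiled."""


@dataclass(frozen=True)
class ResidueClass:
    """A named set of amino acids usable as one pattern position.

    The canonical example is Φ, the bulky hydrophobic class used by
    tyrosine-based sorting signals.
    """

    name: str
    members: frozenset

    def __post_init__(self):
        members = frozenset(str(m).upper() for m in self.members)
        if not members:
            raise PatternError(f"residue class {self.name!r} is empty")
        bad = members - AMINO_ACIDS
        if bad:
            raise PatternError(
                f"residue class {self.name!r} contains non-standard codes: {sorted(bad)}"
            )
        object.__setattr__(self, "members", members)


def default_classes() -> dict:
    """Registry of residue classes shipped with the built-in motifs.

    Φ is taken as {L, I, M, F, V}. This is the conventional bulky
    hydrophobic set, and both experimentally observed YXXXΦN instances
    use L or I at the Φ position. The set is configurable: pass your own
    registry to :func:`compile_pattern` to widen or narrow it.
    """
    return {"Phi": ResidueClass("Phi", frozenset("LIMFV"))}


@dataclass(frozen=True)
class PositionSpec:
    """One position of a compiled pattern.

    kind is ``exact``, ``class``, ``set`` or ``wildcard``. ``allowed`` is
    the frozenset of residues accepted at this position, or ``None`` for
    a wildcard (which accepts anything, including non-standard codes such
    as X/B/Z/U — those match *only* wildcards).
    """

    kind: str
    token: str
    allowed: frozenset | None

    def matches(self, residue: str) -> bool:
        if self.allowed is None:
            return True
        return residue in self.allowed


@dataclass(frozen=True)
class MotifPattern:
    """A compiled positional motif with an optional C-terminal anchor.

    ``max_tail_residues_after_match`` of ``None`` means unanchored;
    an integer k means at most k residues may follow the final pattern
    position before the C-terminus (k = 0 pins the match to the very end).
    """

    name: str
    elements: tuple
    max_tail_residues_after_match: int | None = None

    def __post_init__(self):
        if len(self.elements) < 2:
            raise PatternError(f"pattern {self.name!r} has fewer than 2 positions")
        if self.max_tail_residues_after_match is not None:
            if self.max_tail_residues_after_match < 0:
                raise PatternError(f"pattern {self.name!r} has a negative anchor")

    def __len__(self) -> int:
        return len(self.elements)

    @property
    def anchored(self) -> bool:
        return self.max_tail_residues_after_match is not None


@dataclass(frozen=True)
class MotifHit:
    """One match of a motif in a tail; 1-based inclusive coordinates."""

    motif_name: str
    tail_id: str
    start: int
    end: int
    matched_sequence: str


def _parse_token(token: str, classes: Mapping[str, ResidueClass]) -> PositionSpec:
    if token == "x":
        return PositionSpec("wildcard", "x", None)
    if token.startswith("[") and token.endswith("]"):
        inner = token[1:-1]
        if not inner:
            raise PatternError(f"empty alternative set in token {token!r}")
        residues = frozenset(inner.upper())
        bad = residues - AMINO_ACIDS
        if bad:
            raise PatternError(f"non-standard residues {sorted(bad)} in token {token!r}")
        return PositionSpec("set", "[" + "".join(sorted(residues)) + "]", residues)
    if token.startswith("{") and token.endswith("}"):
        cname = token[1:-1]
        if cname not in classes:
            raise PatternError(f"unknown residue class {cname!r} in token {token!r}")
        return PositionSpec("class", token, classes[cname].members)
    if len(token) == 1 and token.upper() in AMINO_ACIDS:
        res = token.upper()
        return PositionSpec("exact", res, frozenset((res,)))
    raise PatternError(f"malformed pattern token {token!r}")


def compile_pattern(
    spec: str,
    classes: Mapping[str, ResidueClass] | None = None,
    name: str | None = None,
) -> MotifPattern:
    """Compile a pattern string into a :class:`MotifPattern`.

    Parameters
    ----------
    spec
        Whitespace-separated pattern tokens, optionally ending with an
        ``@C<=k`` anchor.
    classes
        Residue-class registry for ``{name}`` tokens; defaults to
        :func:`default_classes`.
    name
        Registry name for the pattern; defaults to the spec string itself.
    """
    if classes is None:
        classes = default_classes()
    tokens = spec.split()
    if not tokens:
        raise PatternError("empty pattern")
    anchor = None
    if tokens and tokens[-1].startswith("@"):
        m = _ANCHOR_RE.match(tokens[-1])
        if m is None:
            raise PatternError(f"malformed anchor token {tokens[-1]!r}")
        anchor = int(m.group(1))
        tokens = tokens[:-1]
    for t in tokens:
        if t.startswith("@"):
            raise PatternError(f"anchor token {t!r} must come last")
    elements = tuple(_parse_token(t, classes) for t in tokens)
    return MotifPattern(
        name=name if name is not None else spec,
        elements=elements,
        max_tail_residues_after_match=anchor,
    )


def format_pattern(pattern: MotifPattern) -> str:
    """Render a compiled pattern back to its mini-language string.

    ``compile_pattern(format_pattern(p))`` scans identically to ``p``.
    """
    parts = [e.token for e in pattern.elements]
    if pattern.anchored:
        parts.append(f"@C<={pattern.max_tail_residues_after_match}")
    return " ".join(parts)


#: Pattern specs of the shipped motif registry. KKXX is anchored so the
#: two lysines occupy the −4 and −3 positions from the C-terminus (the
#: standard dibasic ER-retrieval convention); DXXLL is functional only
#: within three residues of the C-terminus.
BUILTIN_MOTIF_SPECS = {
    "YXXΦ": "Y x x {Phi}",
    "[D/E]XXXL[L/I]": "[DE] x x x L [LI]",
    "FXNPXY": "F x N P x Y",
    "YXXXΦN": "Y x x x {Phi} N",
    "DXXLL": "D x x L L @C<=3",
    "KKXX": "K K x x @C<=0",
}

#: The three motifs classically established as endocytic internalization
#: signals, separately addressable for "no classical signal" queries.
CLASSICAL_MOTIF_NAMES = ("YXXΦ", "[D/E]XXXL[L/I]", "FXNPXY")


def builtin_motifs(classes: Mapping[str, ResidueClass] | None = None) -> dict:
    """The six built-in sorting-signal patterns, as a name→pattern dict.

    Contains the three classical internalization signals (YXXΦ,
    [D/E]XXXL[L/I], FXNPXY), the novel tyrosine-based YXXXΦN signal, the
    C-terminally anchored GGA-binding DXXLL signal and the KKXX
    ER-retrieval signal.
    """
    return {
        nm: compile_pattern(spec, classes=classes, name=nm)
        for nm, spec in BUILTIN_MOTIF_SPECS.items()
    }


def classical_motifs(classes: Mapping[str, ResidueClass] | None = None) -> dict:
    """The classical internalization-signal subset of the registry."""
    reg = builtin_motifs(classes)
    return {nm: reg[nm] for nm in CLASSICAL_MOTIF_NAMES}


def _tail_seq_and_id(tail) -> tuple:
    # Accept a CytoplasmicTail-like object or a bare string.
    if isinstance(tail, str):
        return tail, ""
    return tail.sequence, getattr(tail, "protein_id", "")


def scan_tail(tail, pattern: MotifPattern) -> list:
    """Find every window of ``tail`` matching ``pattern``.

    Overlapping matches are all reported; hits are sorted by start
    position. Scanning is case-insensitive. A tail shorter than the
    pattern yields an empty list. Anchored patterns additionally require
    that at most ``max_tail_residues_after_match`` residues follow the
    final matched position.
    """
    seq, tail_id = _tail_seq_and_id(tail)
    seq = seq.upper()
    plen = len(pattern)
    n = len(seq)
    hits = []
    for i in range(n - plen + 1):
        if pattern.anchored:
            after = n - (i + plen)
            if after > pattern.max_tail_residues_after_match:
                continue
        window = seq[i : i + plen]
        if all(e.matches(window[j]) for j, e in enumerate(pattern.elements)):
            hits.append(
                MotifHit(
                    motif_name=pattern.name,
                    tail_id=tail_id,
                    start=i + 1,
                    end=i + plen,
                    matched_sequence=window,
                )
            )
    return hits


def has_motif(tail, pattern: MotifPattern) -> bool:
    """True iff the tail contains at least one copy of the motif."""
    seq, _ = _tail_seq_and_id(tail)
    seq = seq.upper()
    plen = len(pattern)
    n = len(seq)
    start = 0
    if pattern.anchored:
        # only windows close enough to the C-terminus can qualify
        start = max(0, n - plen - pattern.max_tail_residues_after_match)
    for i in range(start, n - plen + 1):
        window = seq[i : i + plen]
        if all(e.matches(window[j]) for j, e in enumerate(pattern.elements)):
            return True
    return False


def read_motif_table(
    path, classes: Mapping[str, ResidueClass] | None = None
) -> dict:
    """Read a motif registry from a TSV with columns ``name`` and ``spec``."""
    import csv

    registry: dict = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or not {"name", "spec"} <= set(reader.fieldnames):
            raise PatternError(f"{path}: motif table needs columns 'name' and 'spec'")
        for row in reader:
            nm = row["name"].strip()
            if nm in registry:
                raise PatternError(f"{path}: duplicate motif name {nm!r}")
            registry[nm] = compile_pattern(row["spec"].strip(), classes=classes, name=nm)
    return registry


def write_hits_tsv(hits: Iterable[MotifHit], path) -> None:
    """Write hits as TSV: tail_id, motif, start, end, match."""
    import csv

    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["tail_id", "motif", "start", "end", "match"])
        for h in hits:
            w.writerow([h.tail_id, h.motif_name, h.start, h.end, h.matched_sequence])
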