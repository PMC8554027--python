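"""Alphabet-safe DNA string primitives.

Sequences are plain Python ``str`` objects over the uppercase alphabet
``{A, C, G, T, N}``; every function validates its inputs.  Coordinates are
0-based, half-open, on the forward strand, everywhere inside the package;
1-based conventions exist only at I/O boundaries.
"""

from __future__ import annotations

from typing import Iterable, List, Mapping, Tuple

from .errors import SequenceError

ALPHABET = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: (contig id, 0-based forward-strand start, strand) of an exact occurrence
ExactMatch = Tuple[str, int, str]


def validate_dna(seq: str, *, allow_empty: bool = False, allow_n: bool = True,
                 what: str = "sequence") -> str:
    """Uppercase *seq* and reject characters outside the DNA alphabet."""
    if not isinstance(seq, str):
        raise SequenceError(f"{what} must be a string, got {type(seq).__name__}")
    up = seq.upper()
    if not up and not allow_empty:
        raise SequenceError(f"{what} is empty")
    allowed = ALPHABET if allow_n else frozenset("ACGT")
    for i, c in enumerate(up):
        if c not in allowed:
            raise SequenceError(f"{what} contains illegal character {c!r} at offset {i}")
    return up


def reverse_complement(seq: str) -> str:
    """Watson–Crick reverse complement; ``N`` maps to ``N``; '' -> ''."""
    validate_dna(seq, allow_empty=True)
    return seq.upper().translate(_COMPLEMENT)[::-1]


def gc_fraction(seq: str) -> float:
    """(#G + #C) / length.  Ambiguous ``N`` counts as non-GC."""
    s = validate_dna(seq)
    return (s.count("G") + s.count("C")) / len(s)


def hamming(a: str, b: str) -> int:
    """Number of mismatching positions between equal-length strings."""
    if len(a) != len(b):
        raise SequenceError("hamming distance requires equal lengths")
    return sum(x != y for x, y in zip(a, b))


def find_exact_matches(query: str, contigs: Mapping[str, str],
                       *, min_len: int = 11) -> List[ExactMatch]:
    """All exact occurrences of *query* on both strands of *contigs*.

    Reverse-strand hits are reported at the forward-strand coordinate of the
    occurrence of ``reverse_complement(query)``.  Occurrences may overlap.
    """
    q = validate_dna(query)
    if len(q) < min_len:
        raise SequenceError(f"query shorter than {min_len} nt")
    q_rc = reverse_complement(q)
    hits: List[ExactMatch] = []
    for name, contig in contigs.items():
        for probe, strand in ((q, "+"), (q_rc, "-")):
            if probe == q_rc and q_rc == q:
                continue  # palindromic query: forward pass already found it
            start = contig.find(probe)
            while start != -1:
                hits.append((name, start, strand))
                start = contig.find(probe, start + 1)
    hits.sort(key=lambda h: (h[0], h[1], h[2]))
    return hits


def contigs_of(genome) -> Mapping[str, str]:
    """Accept either a :class:`~alleleforge.io.Genome` or a plain mapping."""
    return genome.contigs if hasattr(genome, "contigs") else genome
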