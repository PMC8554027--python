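"""Off-target evaluation of homologous arms and mis-priming of primers.

Arms are screened with a seed-and-extend scanner: every exact seed
(default 11 nt, both strands) nominates a gapless diagonal, which is
extended to a full-arm ungapped alignment; alignments with identity at or
above the threshold (default 0.8) covering at least half the arm are
reported, excluding the intended locus.  Gapless extension only:
indel-containing paralogs are a documented limitation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Set, Tuple

from .params import DesignParameters
from .sequence import contigs_of, reverse_complement, validate_dna


@dataclass(frozen=True)
class OffTargetHit:
    query: str            # UHA/DHA or primer role
    contig: str
    start: int            # forward-strand, 0-based, of the aligned region
    strand: str           # "+" | "-"
    identity: float       # matches / aligned_length
    aligned_length: int


@dataclass(frozen=True)
class IntendedLocus:
    contig: str
    start: int
    end: int

    def overlaps(self, contig: str, start: int, end: int) -> bool:
        return contig == self.contig and start < self.end and end > self.start


def _seed_index(genome: Mapping[str, str], k: int
                ) -> Dict[str, List[Tuple[str, int]]]:
    index: Dict[str, List[Tuple[str, int]]] = {}
    for name, seq in genome.items():
        for i in range(len(seq) - k + 1):
            kmer = seq[i:i + k]
            if "N" in kmer:
                continue
            index.setdefault(kmer, []).append((name, i))
    return index


def _align_diagonal(arm: str, contig_seq: str, offset: int
                    ) -> Tuple[int, int, int]:
    """Ungapped alignment of the whole arm at diagonal *offset*.

    Returns (genome_start, aligned_length, matches); the alignment is the
    arm clipped to the contig bounds.
    """
    a_lo = max(0, -offset)
    a_hi = min(len(arm), len(contig_seq) - offset)
    matches = sum(arm[i] == contig_seq[i + offset]
                  for i in range(a_lo, a_hi))
    return a_lo + offset, a_hi - a_lo, matches


def scan_arm(arm: str, genome, intended: IntendedLocus,
             params: DesignParameters = DesignParameters(), *,
             query_name: str = "arm",
             seed_index: Dict[str, List[Tuple[str, int]]] = None
             ) -> List[OffTargetHit]:
    """Seed-and-extend search of *arm* against *genome* (both strands).

    ``seed_index`` may be supplied to reuse one genome k-mer index across
    many arms.  Reverse-strand hits are reported at forward-strand
    coordinates.  Hits overlapping ``intended`` (forward strand) are
    suppressed — the primary locus is never an off-target.
    """
    contigs = contigs_of(genome)
    k = params.offtarget_seed_len
    arm = validate_dna(arm, what="arm")
    if len(arm) < k:
        raise ValueError(f"arm shorter than the {k}-nt seed")
    if seed_index is None:
        seed_index = _seed_index(contigs, k)

    hits: List[OffTargetHit] = []
    for strand in ("+", "-"):
        probe = arm if strand == "+" else reverse_complement(arm)
        seen: Set[Tuple[str, int]] = set()
        for i in range(len(probe) - k + 1):
            for name, j in seed_index.get(probe[i:i + k], ()):
                diag = (name, j - i)
                if diag in seen:
                    continue
                seen.add(diag)
                start, alen, matches = _align_diagonal(
                    probe, contigs[name], j - i)
                if alen < params.offtarget_min_coverage * len(arm):
                    continue
                identity = matches / alen
                if identity < params.offtarget_identity_threshold:
                    continue
                if intended is not None and intended.overlaps(
                        name, start, start + alen):
                    continue
                hits.append(OffTargetHit(
                    query=query_name, contig=name, start=start,
                    strand=strand, identity=identity, aligned_length=alen))
    hits.sort(key=lambda h: (h.contig, h.start, h.strand))
    return hits


def scan_arm_naive(arm: str, genome, intended: IntendedLocus,
                   params: DesignParameters = DesignParameters(), *,
                   query_name: str = "arm") -> List[OffTargetHit]:
    """Exhaustive sliding-identity scan over every diagonal (test oracle).

    Quadratic; intended for fixtures up to ~100 kb only.
    """
    contigs = contigs_of(genome)
    hits: List[OffTargetHit] = []
    for strand in ("+", "-"):
        probe = arm if strand == "+" else reverse_complement(arm)
        for name, seq in contigs.items():
            for offset in range(-len(probe) + 1, len(seq)):
                start, alen, matches = _align_diagonal(probe, seq, offset)
                if alen < params.offtarget_min_coverage * len(arm):
                    continue
                identity = matches / alen
                if identity < params.offtarget_identity_threshold:
                    continue
                if intended is not None and intended.overlaps(
                        name, start, start + alen):
                    continue
                hits.append(OffTargetHit(
                    query=query_name, contig=name, start=start,
                    strand=strand, identity=identity, aligned_length=alen))
    hits.sort(key=lambda h: (h.contig, h.start, h.strand))
    return hits


def scan_primer_3prime(primer, genome, intended: IntendedLocus,
                       params: DesignParameters = DesignParameters()
                       ) -> List[OffTargetHit]:
    """Mis-priming warnings: genomic occurrences of the 3' terminal k-mer.

    The 3'-terminal ``misprime_kmer`` (default 12) of the primer's full
    sequence is searched on both strands; occurrences outside the
    intended binding site are returned as warnings (identity 1.0 over the
    k-mer).  The intended site itself is never reported.
    """
    contigs = contigs_of(genome)
    k = params.misprime_kmer
    tail3 = primer.full[-k:]
    if len(tail3) < k:
        return []
    hits: List[OffTargetHit] = []
    for name, seq in contigs.items():
        for probe, strand in ((tail3, "+"), (reverse_complement(tail3), "-")):
            start = seq.find(probe)
            while start != -1:
                if not (intended is not None
                        and intended.overlaps(name, start, start + k)):
                    hits.append(OffTargetHit(
                        query=primer.role, contig=name, start=start,
                        strand=strand, identity=1.0, aligned_length=k))
                start = seq.find(probe, start + 1)
    hits.sort(key=lambda h: (h.contig, h.start, h.strand))
    return hits
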