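"""Core design engine for suicide-plasmid point-mutation editing.

For one validated mutation task the engine

1. applies the edit to the anchored context and extracts the 20-nt
   *junction window* covering the mutation — the overlap shared by the
   upstream (UHA) and downstream (DHA) arm amplicons;
2. derives the optional design regions (ODRs) in which each primer's
   template match may sit, from the user's length ranges;
3. constructs the three 20-nt assembly overhangs (two vector ends, one
   junction window) as primer 5' tails;
4. optimizes all seven primers (primer-1/2/3/4 for arm amplification,
   test-primer-1/2/3 for crossover verification) by exhaustive scoring of
   every admissible (position, length) candidate;
5. sizes the four diagnostic amplicons and screens the primer set for
   self- and cross-dimers.

Verification is by simulation: :func:`assemble_in_silico` overlap-joins
the two amplicons with the vector into the suicide plasmid, and
:func:`predict_edited_genome` plays out both single-crossover events,
yielding the integrant (used to size the first verification amplicon) and
the final edited genome.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

from .errors import AlleleforgeError, AssemblyJunctionMismatch
from .io import Genome, MutationTask, VectorSequence
from .params import DesignParameters
from .sequence import reverse_complement
from .thermo import (TemplateThermo, ThermoResult, duplex_tm, hairpin_tm,
                     homodimer_tm, thermo_profile)
from .validate import AnchoredLocus, ValidationReport, validate_task

PRIMER_ROLES = ("primer-1", "primer-2", "primer-3", "primer-4",
                "test-primer-1", "test-primer-2", "test-primer-3")

#: the four PCR pairs: UHA, DHA, verification round 1, verification round 2
PRIMER_PAIRS = (("primer-1", "primer-2"), ("primer-3", "primer-4"),
                ("test-primer-1", "test-primer-2"),
                ("test-primer-1", "test-primer-3"))


@dataclass(frozen=True)
class EditedLocus:
    """The context with the edit applied, plus the junction window."""

    anchored: AnchoredLocus
    task: MutationTask
    edited_context: str
    junction_window: str
    window_start: int      # coordinate of window[0] within edited_context

    @property
    def window_end(self) -> int:
        return self.window_start + len(self.junction_window)


@dataclass(frozen=True)
class Primer:
    """A named oligo: optional 5' tail + 18-25 nt 3' template match."""

    role: str
    tail: str                    # "" for verification primers
    match: str                   # as synthesized, 5'->3'
    orientation: str             # "fwd" | "rev"
    match_target: str            # "genome" | "vector"
    site_start: int              # binding site, template forward-strand coords
    site_end: int
    thermo: ThermoResult         # tm/gc of match; dimer/hairpin of full oligo
    penalty: float

    @property
    def full(self) -> str:
        return self.tail + self.match


@dataclass(frozen=True)
class FailedTask:
    task_id: str
    stage: str                   # "validation" | "primer_design"
    reason: str
    message: str


@dataclass(frozen=True)
class DesignRegions:
    """Optional design regions; each is a range of anchor coordinates.

    Forward-primer anchors are match *start* positions; reverse-primer
    anchors are the exclusive right edge of the binding site (the
    template coordinate just past the primer's 5'-most matched base).
    ``odr_uis`` / ``odr_dis1`` / ``odr_dis2`` depend on the chosen arm
    boundaries and are ``None`` until those are supplied.
    """

    odr_uha: range
    odr_dha: range
    odr_uis: Optional[range] = None
    odr_dis1: Optional[range] = None
    odr_dis2: Optional[range] = None


@dataclass(frozen=True)
class DesignResult:
    task_id: str
    primers: Dict[str, Primer]
    uha_seq: str                 # edited arm incl. junction window
    dha_seq: str
    uha_amplicon_len: int
    dha_amplicon_len: int
    verification1_amplicon_len: int   # test-primer-1/2 on the integrant
    verification2_amplicon_len: int   # test-primer-1/3 on the edited genome
    worst_homodimer_tm: float
    worst_cross_dimer_tm: float
    cross_dimer_warnings: Tuple[Tuple[str, str, float], ...]
    # geometry retained for in-silico verification
    edited: EditedLocus
    uha_start: int               # edited-context coords
    dha_end: int
    tp1_start: int
    tp2_edge: int                # vector coords, exclusive right edge
    tp3_edge: int                # edited-context coords, exclusive right edge
    params: DesignParameters


class PrimerDesignError(AlleleforgeError):
    def __init__(self, reason: str, message: str):
        super().__init__(message)
        self.reason = reason


# ---------------------------------------------------------------------------
# stage 1: edit application

def build_edited_locus(anchored: AnchoredLocus, task: MutationTask,
                       params: DesignParameters) -> EditedLocus:
    """Apply the edit and extract the junction window.

    The edited base sits at ``params.window_offset`` (default 9) within
    the window: substitution — the substituted base; insertion — the
    inserted base; deletion — the base that followed the deleted one.
    """
    ctx, i = task.context, task.index
    kind = task.kind
    if kind == "substitution":
        edited = ctx[:i] + task.alt_allele + ctx[i + 1:]
        pos = i
    elif kind == "insertion":
        edited = ctx[:i + 1] + task.alt_allele + ctx[i + 1:]
        pos = i + 1
    else:  # deletion
        edited = ctx[:i] + ctx[i + 1:]
        pos = i
    ws = pos - params.window_offset
    we = ws + params.overlap_len
    if ws < 0 or we > len(edited):
        raise PrimerDesignError(
            "DESIGN_WINDOW_CLIPPED",
            f"task {task.id!r}: edit at {pos} leaves no room for the "
            f"{params.overlap_len}-nt junction window")
    return EditedLocus(anchored=anchored, task=task, edited_context=edited,
                       junction_window=edited[ws:we], window_start=ws)


# ---------------------------------------------------------------------------
# stage 2: overhangs and design regions

def make_overhangs(edited: EditedLocus, vector: VectorSequence,
                   params: DesignParameters) -> Dict[str, str]:
    """The four 5' tails (each ``overlap_len`` nt).

    primer-3 carries the junction window, primer-2 its reverse
    complement.  primer-1/primer-4 carry the vector terminal segments;
    which physical end seeds which primer is set by
    ``params.vector_end_convention`` (see :mod:`alleleforge.params`).
    Under the default "3prime" convention the final plasmid reads
    vector -> UHA -> window -> DHA -> (wrap), so primer-1 receives the
    vector's 3'-terminal segment and primer-4 the reverse complement of
    the 5'-terminal one.
    """
    k = params.overlap_len
    v = vector.bases
    if len(v) < 2 * k:
        raise PrimerDesignError(
            "VECTOR_TOO_SHORT",
            f"vector of {len(v)} nt cannot provide two {k}-nt overlap ends")
    if params.vector_end_convention == "3prime":
        tail1, tail4 = v[-k:], reverse_complement(v[:k])
    else:  # 5prime
        tail1, tail4 = v[:k], reverse_complement(v[-k:])
    w = edited.junction_window
    return {"primer-1": tail1, "primer-2": reverse_complement(w),
            "primer-3": w, "primer-4": tail4}


def compute_design_regions(edited: EditedLocus, vector: VectorSequence,
                           params: DesignParameters, *,
                           uha_start: Optional[int] = None,
                           dha_end: Optional[int] = None) -> DesignRegions:
    """Derive the ODRs from the configured length ranges.

    Arm regions: primer-1 starts such that the UHA (arm including the
    junction window, ``[uha_start, window_end)``) has length in
    ``[uha_min, uha_max]``; primer-4 right edges such that the DHA
    (``[window_start, dha_end)``) has length in ``[dha_min, dha_max]``.
    Verification regions need the chosen ``uha_start`` / ``dha_end``:
    test-primer-1 starts ``[uis_min, uis_max]`` upstream of the UHA;
    test-primer-2 right edges sit ``[dis1_min, dis1_max]`` into the
    backbone from the DHA-vector junction; test-primer-3 right edges sit
    ``[dis2_min, dis2_max]`` downstream of the DHA.  All regions are
    clipped to their template bounds.
    """
    ws, we = edited.window_start, edited.window_end
    n = len(edited.edited_context)

    def clipped(lo: int, hi: int, bound: int) -> range:
        """Anchors in [lo, hi] intersected with [0, bound]; may be empty."""
        lo, hi = max(lo, 0), min(hi, bound)
        return range(lo, hi + 1) if lo <= hi else range(0)

    odr_uha = clipped(we - params.uha_max, we - params.uha_min, n)
    odr_dha = clipped(ws + params.dha_min, ws + params.dha_max, n)
    odr_uis = odr_dis2 = None
    if uha_start is not None:
        odr_uis = clipped(uha_start - params.uis_max,
                          uha_start - params.uis_min, n)
    if dha_end is not None:
        odr_dis2 = clipped(dha_end + params.dis2_min,
                           dha_end + params.dis2_max, n)
    odr_dis1 = clipped(params.dis1_min, params.dis1_max, len(vector))
    return DesignRegions(odr_uha=odr_uha, odr_dha=odr_dha, odr_uis=odr_uis,
                         odr_dis1=odr_dis1, odr_dis2=odr_dis2)


# ---------------------------------------------------------------------------
# stage 3: primer optimization

@functools.lru_cache(maxsize=65536)
def _dimer_scores(match: str, salt_mM: float, oligo_nM: float,
                  divalent_mM: float) -> Tuple[float, float]:
    return (homodimer_tm(match, salt_mM, oligo_nM, divalent_mM),
            hairpin_tm(match, salt_mM, oligo_nM, divalent_mM))


def candidate_penalty(tm: float, gc: float, homod: float, hairp: float,
                      p: DesignParameters) -> float:
    """The shared scoring function (also used by the brute-force oracle)."""
    return (p.w_tm * abs(tm - p.tm_opt)
            + p.w_gc * abs(gc - p.gc_opt) * 100.0
            + p.w_dimer * max(0.0, homod - p.max_self_dimer_tm)
            + p.w_hairpin * max(0.0, hairp - p.max_self_dimer_tm))


def pick_primer(template: Union[str, TemplateThermo], odr: Iterable[int],
                orientation: str, constraints: DesignParameters, *,
                anchored_3prime: bool = False,
                label: str = "primer") -> Primer:
    """Exhaustively score every admissible (anchor, length) candidate.

    Forward anchors are match starts; reverse anchors are exclusive right
    edges of the binding site, so an anchored primer (``anchored_3prime``,
    a single-element ODR) varies only in length.  Candidates with any
    ``N``, Tm outside [tm_min, tm_max] or GC outside [gc_min, gc_max] are
    rejected; the survivor minimizing the penalty wins, ties broken by
    shorter length, then smaller site start.  Penalties are compared
    after rounding to 9 decimals so that the tie-break, not summation
    order, decides between thermodynamically identical windows.  Raises
    :class:`PrimerDesignError` with the dominant rejection reason when no
    candidate is admissible.
    """
    p = constraints
    tt = (template if isinstance(template, TemplateThermo)
          else TemplateThermo(template, p.salt_mM, p.oligo_nM, p.divalent_mM))
    n = len(tt.template)
    odr = list(odr)
    if anchored_3prime and len(odr) != 1:
        raise ValueError("anchored primer requires a single-anchor ODR")
    counts = {"with N": 0, "low tm": 0, "high tm": 0,
              "low gc": 0, "high gc": 0}
    considered = 0
    best = None
    best_key = None
    for anchor in odr:
        for length in range(p.match_len_min, p.match_len_max + 1):
            if orientation == "fwd":
                s, e = anchor, anchor + length
            else:
                s, e = anchor - length, anchor
            if s < 0 or e > n:
                continue
            considered += 1
            if tt.has_n(s, e):
                counts["with N"] += 1
                continue
            tm = tt.tm(s, e)
            if tm < p.tm_min:
                counts["low tm"] += 1
                continue
            if tm > p.tm_max:
                counts["high tm"] += 1
                continue
            gc = tt.gc(s, e)
            if gc < p.gc_min:
                counts["low gc"] += 1
                continue
            if gc > p.gc_max:
                counts["high gc"] += 1
                continue
            site = tt.template[s:e]
            match = site if orientation == "fwd" else reverse_complement(site)
            homod, hairp = _dimer_scores(match, p.salt_mM, p.oligo_nM,
                                         p.divalent_mM)
            pen = candidate_penalty(tm, gc, homod, hairp, p)
            key = (round(pen, 9), length, s)
            if best_key is None or key < best_key:
                best_key = key
                best = (match, s, e, tm, gc, homod, hairp, pen)
    if best is None:
        explain = ", ".join(f"{k} {v}" for k, v in counts.items())
        raise PrimerDesignError(
            "NO_ADMISSIBLE_PRIMER",
            f"{label}: considered {considered} candidates, {explain}, ok 0")
    match, s, e, tm, gc, homod, hairp, pen = best
    return Primer(role=label, tail="", match=match, orientation=orientation,
                  match_target="genome", site_start=s, site_end=e,
                  thermo=ThermoResult(tm=tm, gc=gc, homodimer_tm=homod,
                                      hairpin_tm=hairp),
                  penalty=pen)


def _finalize(primer: Primer, *, role: str, tail: str,
              match_target: str, params: DesignParameters) -> Primer:
    """Attach tail/role and recompute dimer/hairpin on the full oligo."""
    full = tail + primer.match
    thermo = ThermoResult(
        tm=primer.thermo.tm, gc=primer.thermo.gc,
        homodimer_tm=homodimer_tm(full, params.salt_mM, params.oligo_nM,
                                  params.divalent_mM),
        hairpin_tm=hairpin_tm(full, params.salt_mM, params.oligo_nM,
                              params.divalent_mM))
    return Primer(role=role, tail=tail, match=primer.match,
                  orientation=primer.orientation, match_target=match_target,
                  site_start=primer.site_start, site_end=primer.site_end,
                  thermo=thermo, penalty=primer.penalty)


# ---------------------------------------------------------------------------
# stage 4: whole-task design

def design_task(task: MutationTask, genome: Genome, vector: VectorSequence,
                params: DesignParameters = DesignParameters()
                ) -> Union[DesignResult, FailedTask]:
    """Run the full per-task pipeline; never raises on a per-task failure."""
    anchored = validate_task(task, genome, params)
    if isinstance(anchored, ValidationReport):
        return FailedTask(task_id=task.id, stage="validation",
                          reason=anchored.reason, message=anchored.message)
    try:
        edited = build_edited_locus(anchored, task, params)
        tails = make_overhangs(edited, vector, params)
        ctx_tt = TemplateThermo(edited.edited_context, params.salt_mM,
                                params.oligo_nM, params.divalent_mM)
        vec_tt = TemplateThermo(vector.bases, params.salt_mM,
                                params.oligo_nM, params.divalent_mM)
        regions = compute_design_regions(edited, vector, params)
        ws, we = edited.window_start, edited.window_end

        for name, odr in (("ODR_UHA", regions.odr_uha),
                          ("ODR_DHA", regions.odr_dha),
                          ("ODR_DIS1", regions.odr_dis1)):
            if len(odr) == 0:
                raise PrimerDesignError("ODR_EMPTY", f"{name} is empty")

        p1 = pick_primer(ctx_tt, regions.odr_uha, "fwd", params,
                         label="primer-1")
        p4 = pick_primer(ctx_tt, regions.odr_dha, "rev", params,
                         label="primer-4")
        p2 = pick_primer(ctx_tt, [ws], "rev", params, anchored_3prime=True,
                         label="primer-2")
        p3 = pick_primer(ctx_tt, [we], "fwd", params, anchored_3prime=True,
                         label="primer-3")
        uha_start, dha_end = p1.site_start, p4.site_end

        regions = compute_design_regions(edited, vector, params,
                                         uha_start=uha_start, dha_end=dha_end)
        for name, odr in (("ODR_UIS", regions.odr_uis),
                          ("ODR_DIS2", regions.odr_dis2)):
            if len(odr) == 0:
                raise PrimerDesignError("ODR_EMPTY", f"{name} is empty")
        tp1 = pick_primer(ctx_tt, regions.odr_uis, "fwd", params,
                          label="test-primer-1")
        tp2 = pick_primer(vec_tt, regions.odr_dis1, "rev", params,
                          label="test-primer-2")
        tp3 = pick_primer(ctx_tt, regions.odr_dis2, "rev", params,
                          label="test-primer-3")
    except PrimerDesignError as exc:
        return FailedTask(task_id=task.id, stage="primer_design",
                          reason=exc.reason, message=str(exc))

    primers = {
        "primer-1": _finalize(p1, role="primer-1", tail=tails["primer-1"],
                              match_target="genome", params=params),
        "primer-2": _finalize(p2, role="primer-2", tail=tails["primer-2"],
                              match_target="genome", params=params),
        "primer-3": _finalize(p3, role="primer-3", tail=tails["primer-3"],
                              match_target="genome", params=params),
        "primer-4": _finalize(p4, role="primer-4", tail=tails["primer-4"],
                              match_target="genome", params=params),
        "test-primer-1": _finalize(tp1, role="test-primer-1", tail="",
                                   match_target="genome", params=params),
        "test-primer-2": _finalize(tp2, role="test-primer-2", tail="",
                                   match_target="vector", params=params),
        "test-primer-3": _finalize(tp3, role="test-primer-3", tail="",
                                   match_target="genome", params=params),
    }

    ctx_e = edited.edited_context
    uha_seq = ctx_e[uha_start:we]
    dha_seq = ctx_e[ws:dha_end]
    k = params.overlap_len
    tp1_start, tp2_edge, tp3_edge = tp1.site_start, tp2.site_end, tp3.site_end
    # verification 1: forward test-primer-1 through UHA+window+DHA into the
    # backbone of the UHA-crossover integrant, back to test-primer-2.
    v1 = (dha_end - tp1_start) + tp2_edge
    v2 = tp3_edge - tp1_start

    worst_homo = max(pr.thermo.homodimer_tm for pr in primers.values())
    warnings: List[Tuple[str, str, float]] = []
    worst_cross = None
    roles = list(PRIMER_ROLES)
    for i, a in enumerate(roles):
        for b in roles[i + 1:]:
            tm = duplex_tm(primers[a].full, primers[b].full,
                           params.salt_mM, params.oligo_nM,
                           params.divalent_mM)
            if worst_cross is None or tm > worst_cross:
                worst_cross = tm
            if tm > params.max_cross_dimer_tm:
                warnings.append((a, b, tm))

    return DesignResult(
        task_id=task.id, primers=primers, uha_seq=uha_seq, dha_seq=dha_seq,
        uha_amplicon_len=k + len(uha_seq), dha_amplicon_len=len(dha_seq) + k,
        verification1_amplicon_len=v1, verification2_amplicon_len=v2,
        worst_homodimer_tm=worst_homo, worst_cross_dimer_tm=worst_cross,
        cross_dimer_warnings=tuple(warnings), edited=edited,
        uha_start=uha_start, dha_end=dha_end, tp1_start=tp1_start,
        tp2_edge=tp2_edge, tp3_edge=tp3_edge, params=params)


# ---------------------------------------------------------------------------
# stage 5: in-silico verification

def _pcr_amplicons(result: DesignResult) -> Tuple[str, str]:
    """Simulate PCR of the UHA and DHA amplicons from the edited template."""
    ctx = result.edited.edited_context
    p = result.primers
    ws, we = result.edited.window_start, result.edited.window_end
    amp_u = (p["primer-1"].tail + ctx[result.uha_start:ws]
             + reverse_complement(p["primer-2"].tail))
    amp_d = (p["primer-3"].tail + ctx[we:result.dha_end]
             + reverse_complement(p["primer-4"].tail))
    return amp_u, amp_d


def assemble_in_silico(result: DesignResult,
                       vector: VectorSequence) -> str:
    """Overlap-join UHA amplicon + DHA amplicon + vector into the plasmid.

    Each of the three 20-nt junctions is checked literally; any
    disagreement raises :class:`AssemblyJunctionMismatch`.  The returned
    circle is canonically rotated to start at vector position 0 and has
    length ``len(vector) + len(edited insert)``.
    """
    k = result.params.overlap_len
    v = vector.bases
    amp_u, amp_d = _pcr_amplicons(result)
    window = result.edited.junction_window
    if amp_u[-k:] != amp_d[:k] or amp_u[-k:] != window:
        raise AssemblyJunctionMismatch(
            f"task {result.task_id}: UHA/DHA junction mismatch: "
            f"{amp_u[-k:]} vs {amp_d[:k]} (window {window})")
    if amp_u[:k] != v[-k:]:
        hint = ("" if result.params.vector_end_convention == "3prime" else
                "; the '5prime' vector end convention places both vector "
                "overlaps in the same orientation as the backbone and "
                "cannot circularize")
        raise AssemblyJunctionMismatch(
            f"task {result.task_id}: vector/UHA junction mismatch: amplicon "
            f"starts with {amp_u[:k]}, vector 3' end is {v[-k:]}{hint}")
    if amp_d[-k:] != v[:k]:
        raise AssemblyJunctionMismatch(
            f"task {result.task_id}: DHA/vector junction mismatch: amplicon "
            f"ends with {amp_d[-k:]}, vector 5' end is {v[:k]}")
    circle = v + amp_u[k:] + amp_d[k:-k]
    return circle


@dataclass(frozen=True)
class CrossoverPrediction:
    """Outcome of simulating integration and resolution."""

    integrant: Genome            # after the 1st single crossover (via UHA)
    edited_genome: Genome        # resolution through the DHA-side repeat
    revertant: Genome            # resolution through the UHA-side repeat
    verification1_len: int       # test-primer-1/2 product on the integrant
    verification2_len: int       # test-primer-1/3 product on the edited genome


def predict_edited_genome(result: DesignResult, genome: Genome,
                          plasmid: str) -> CrossoverPrediction:
    """Simulate both crossovers of the allelic-exchange procedure.

    Integration (1st crossover, taken through the shared upstream arm
    segment) inserts the whole plasmid, duplicating the arms; the
    test-primer-1/2 product exists only on this integrant (test-primer-2
    has no binding site on wild type, which is the false-positive check).
    Resolution (2nd crossover) through the downstream repeat yields the
    edited genome; through the upstream repeat, the unchanged revertant.
    """
    anchored = result.edited.anchored
    task = result.edited.task
    contig = genome.contigs[anchored.contig]
    g0 = anchored.context_start
    ctx_e = result.edited.edited_context
    ws = result.edited.window_start
    # window start precedes the edit, so genomic and edited coords agree
    cut = g0 + ws
    rotated = ctx_e[ws:result.dha_end] + _vector_of(result, plasmid) \
        + ctx_e[result.uha_start:ws]
    integrant_seq = contig[:cut] + rotated + contig[cut:]

    edited_contig = (contig[:g0] + ctx_e
                     + contig[g0 + len(task.context):])
    integrant = _with_contig(genome, anchored.contig, integrant_seq,
                             suffix="integrant")
    edited = _with_contig(genome, anchored.contig, edited_contig,
                          suffix="edited")
    revertant = _with_contig(genome, anchored.contig, contig,
                             suffix="revertant")
    return CrossoverPrediction(
        integrant=integrant, edited_genome=edited, revertant=revertant,
        verification1_len=result.verification1_amplicon_len,
        verification2_len=result.verification2_amplicon_len)


def _vector_of(result: DesignResult, plasmid: str) -> str:
    """Backbone portion of the assembled circle (canonical rotation)."""
    insert_len = len(result.edited.edited_context[
        result.uha_start:result.dha_end])
    return plasmid[:len(plasmid) - insert_len]


def _with_contig(genome: Genome, contig_id: str, seq: str,
                 suffix: str) -> Genome:
    contigs = dict(genome.contigs)
    contigs[contig_id] = seq
    return Genome(name=f"{genome.name}-{suffix}", contigs=contigs)
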