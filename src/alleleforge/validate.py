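"""Pre-design input checks: length rule, mutation centrality, anchoring.

Check order is fixed — structure (handled at parse time), length rule,
centrality, genome anchoring — and the first failing check wins, so every
task ends in exactly one of an :class:`AnchoredLocus` or a single failed
:class:`ValidationReport`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

from .io import Genome, MutationTask
from .params import DesignParameters
from .sequence import find_exact_matches


@dataclass(frozen=True)
class ValidationReport:
    task_id: str
    status: str            # "ok" | "failed"
    reason: str = ""       # non-empty iff failed
    message: str = ""

    @property
    def ok(self) -> bool:
        return self.status == "ok"


@dataclass(frozen=True)
class AnchoredLocus:
    """A task context located exactly once on the genome's forward strand."""

    task_id: str
    contig: str
    context_start: int     # 0-based genome coordinate of context[0]
    mut_genome_pos: int    # coordinate of the edited base (insertion: the
                           # base after which insertion occurs)


def check_length_rule(task: MutationTask,
                      params: DesignParameters) -> ValidationReport:
    """Context must be strictly longer than UHA_max+DHA_max+UIS_max+DIS2_min."""
    bound = params.length_rule_bound
    if len(task.context) > bound:
        return ValidationReport(task.id, "ok")
    return ValidationReport(
        task.id, "failed", "LENGTH_TOO_SHORT",
        f"context length {len(task.context)} must exceed "
        f"uha_max+dha_max+uis_max+dis2_min = {bound}")


def check_mutation_centrality(task: MutationTask,
                              params: DesignParameters) -> ValidationReport:
    """The edit must leave template room on both sides (margins inclusive).

    Upstream margin (bases strictly before the edit) must cover
    ``uis_max + uha_max``; downstream margin (bases strictly after it)
    must cover ``dha_max + dis2_min``.
    """
    upstream = task.index
    downstream = len(task.context) - task.index - 1
    need_up = params.uis_max + params.uha_max
    need_down = params.dha_max + params.dis2_min
    if upstream >= need_up and downstream >= need_down:
        return ValidationReport(task.id, "ok")
    return ValidationReport(
        task.id, "failed", "MUTATION_NOT_CENTERED",
        f"edit at 0-based {task.index} leaves {upstream} nt upstream "
        f"(need >= {need_up}) and {downstream} nt downstream "
        f"(need >= {need_down})")


def anchor_in_genome(task: MutationTask,
                     genome: Genome) -> Union[AnchoredLocus, ValidationReport]:
    """Locate the context exactly once, forward strand, 100% identity.

    Strict consistency: any mismatch means no anchor.  Multi-mapping
    contexts (redundant loci) and reverse-strand-only matches are rejected
    with dedicated reasons rather than silently resolved.
    """
    hits = find_exact_matches(task.context, genome.contigs)
    fwd = [h for h in hits if h[2] == "+"]
    rev = [h for h in hits if h[2] == "-"]
    if len(fwd) == 1:
        contig, start, _ = fwd[0]
        return AnchoredLocus(task_id=task.id, contig=contig,
                             context_start=start,
                             mut_genome_pos=start + task.index)
    if len(fwd) > 1:
        loci = ", ".join(f"{c}:{s}" for c, s, _ in fwd[:5])
        return ValidationReport(
            task.id, "failed", "CONTEXT_MULTIMAPPED",
            f"context occurs {len(fwd)} times on the forward strand "
            f"({loci}{'...' if len(fwd) > 5 else ''}); the target locus is "
            "ambiguous")
    if rev:
        contig, start, _ = rev[0]
        return ValidationReport(
            task.id, "failed", "CONTEXT_REVERSE_STRAND",
            f"context matches only the reverse strand at {contig}:{start}; "
            "reverse-complement the context and restate index/ref/alt on "
            "the forward strand")
    return ValidationReport(
        task.id, "failed", "CONTEXT_NOT_IN_GENOME",
        "context has no exact match in the genome; the uploaded sequence "
        "must be strictly consistent with the target genome")


def validate_task(task: MutationTask, genome: Genome,
                  params: DesignParameters
                  ) -> Union[AnchoredLocus, ValidationReport]:
    """Run all checks in order; return the anchor or the first failure."""
    for check in (check_length_rule, check_mutation_centrality):
        report = check(task, params)
        if not report.ok:
            return report
    return anchor_in_genome(task, genome)
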