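"""Readers and writers for every file the tool touches.

Inputs: a multi-record genome FASTA, a plain-text linearized vector
sequence, and a CSV mutation task table (columns: ``id``, ``context``,
``index`` (1-based), ``ref``, ``alt``; ``-`` in ref/alt marks an
insertion/deletion).  Outputs: four CSV files (``design_results``,
``primer_order``, ``failed_task``, ``evaluation_result``) with optional
XLSX mirrors.

Conventions
-----------
* The CSV mutation ``index`` is 1-based (biologists' convention, matching
  allele names like C568T); it is converted to 0-based immediately on read.
* Insertion: the ``alt`` base is inserted immediately **after** the 1-based
  ``index`` position.  Deletion: the base **at** the index is removed.
* One single-nucleotide edit per row; multi-nucleotide edits are rejected.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

from Bio import SeqIO

from .errors import ParseError
from .sequence import validate_dna

MUTATION_COLUMNS = ("id", "context", "index", "ref", "alt")


@dataclass
class Genome:
    """A named collection of contigs (uppercase DNA strings)."""

    name: str
    contigs: Dict[str, str]

    def __post_init__(self):
        if not self.contigs:
            raise ParseError(f"genome {self.name!r} has no contigs")
        for cid, seq in self.contigs.items():
            if not seq:
                raise ParseError(f"contig {cid!r} is empty")

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.contigs.values())


@dataclass(frozen=True)
class VectorSequence:
    """Top strand (5'->3') of the linearized vector backbone."""

    bases: str

    def __post_init__(self):
        validate_dna(self.bases, allow_n=False, what="vector")
        if len(self.bases) < 60:
            raise ParseError(
                f"vector length {len(self.bases)} < 60 nt; a linearized "
                "backbone with two 20-nt assembly ends is required")

    def __len__(self) -> int:
        return len(self.bases)


@dataclass(frozen=True)
class MutationTask:
    """One requested single-nucleotide edit.

    ``index`` is stored 0-based; ``index0`` is the coordinate within
    ``context`` of the substituted/deleted base, or of the base after
    which the insertion occurs.
    """

    id: str
    context: str
    index: int            # 0-based position within context
    ref_allele: str       # single base, or "-" for insertion
    alt_allele: str       # single base, or "-" for deletion

    @property
    def kind(self) -> str:
        if self.ref_allele == "-":
            return "insertion"
        if self.alt_allele == "-":
            return "deletion"
        return "substitution"


@dataclass(frozen=True)
class RowError:
    """A mutation-table row that could not be parsed into a task."""

    id: str
    reason: str
    message: str


def read_genome_fasta(path) -> Genome:
    """Load a multi-record FASTA; sequences are uppercased and validated."""
    path = Path(path)
    contigs: Dict[str, str] = {}
    try:
        records = list(SeqIO.parse(str(path), "fasta"))
    except (ValueError, FileNotFoundError) as exc:
        raise ParseError(f"cannot parse FASTA {path}: {exc}") from exc
    if not records:
        raise ParseError(f"FASTA {path} contains no records")
    for rec in records:
        if rec.id in contigs:
            raise ParseError(f"duplicate FASTA record id {rec.id!r} in {path}")
        seq = str(rec.seq).upper()
        for off, ch in enumerate(seq):
            if ch not in "ACGTN":
                raise ParseError(
                    f"record {rec.id!r}: illegal character {ch!r} at offset {off}")
        if not seq:
            raise ParseError(f"record {rec.id!r} is empty")
        contigs[rec.id] = seq
    return Genome(name=path.stem, contigs=contigs)


def read_vector_txt(path) -> VectorSequence:
    """Read a raw-text single-sequence vector file (whitespace ignored)."""
    text = Path(path).read_text()
    if text.lstrip().startswith(">"):
        raise ParseError(
            "vector file looks like FASTA; supply the raw sequence text "
            "of the linearized backbone without a header line")
    seq = "".join(text.split()).upper()
    if not seq:
        raise ParseError("vector file is empty")
    try:
        validate_dna(seq, allow_n=False, what="vector")
    except Exception as exc:
        raise ParseError(str(exc)) from exc
    return VectorSequence(seq)


def read_mutation_table(path) -> Tuple[List[MutationTask], List[RowError]]:
    """Parse the mutation CSV; per-row errors are collected, not raised.

    Returns ``(tasks, row_errors)`` so one malformed row never aborts a
    batch; only a structurally unusable file (missing header/columns)
    raises :class:`ParseError`.
    """
    path = Path(path)
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise ParseError(f"mutation table {path} is empty")
        cols = [c.strip().lower() for c in reader.fieldnames]
        missing = [c for c in MUTATION_COLUMNS if c not in cols]
        if missing:
            raise ParseError(
                f"mutation table {path} lacks required columns {missing}; "
                f"expected header {list(MUTATION_COLUMNS)}")
        rows = [{k.strip().lower(): (v or "").strip() for k, v in row.items()}
                for row in reader]

    tasks: List[MutationTask] = []
    errors: List[RowError] = []
    seen = set()
    for lineno, row in enumerate(rows, start=2):
        tid = row.get("id", "")
        try:
            task = _parse_row(row, lineno)
        except ParseError as exc:
            errors.append(RowError(id=tid or f"<line {lineno}>",
                                   reason=_reason_of(exc), message=str(exc)))
            continue
        if task.id in seen:
            errors.append(RowError(id=task.id, reason="DUPLICATE_ID",
                                   message=f"duplicate task id {task.id!r}"))
            continue
        seen.add(task.id)
        tasks.append(task)
    return tasks, errors


class _Tagged(ParseError):
    def __init__(self, reason: str, message: str):
        super().__init__(message)
        self.reason = reason


def _reason_of(exc: Exception) -> str:
    return getattr(exc, "reason", "PARSE_ERROR")


def _parse_row(row: Dict[str, str], lineno: int) -> MutationTask:
    tid = row["id"]
    if not tid:
        raise _Tagged("MISSING_ID", f"line {lineno}: empty task id")
    try:
        context = validate_dna(row["context"], allow_n=False, what="context")
    except Exception as exc:
        raise _Tagged("BAD_CONTEXT", f"task {tid!r}: {exc}") from exc
    try:
        index1 = int(row["index"])
    except ValueError:
        raise _Tagged("BAD_INDEX",
                      f"task {tid!r}: index {row['index']!r} is not an integer")
    if not 1 <= index1 <= len(context):
        raise _Tagged("BAD_INDEX",
                      f"task {tid!r}: 1-based index {index1} outside context "
                      f"of length {len(context)}")
    ref, alt = row["ref"].upper(), row["alt"].upper()
    for name, allele in (("ref", ref), ("alt", alt)):
        if allele != "-" and allele not in ("A", "C", "G", "T"):
            raise _Tagged("BAD_ALLELE",
                          f"task {tid!r}: {name} allele {allele!r} must be a "
                          "single base A/C/G/T or '-'")
    if ref == "-" and alt == "-":
        raise _Tagged("BAD_ALLELE", f"task {tid!r}: ref and alt are both '-'")
    index0 = index1 - 1
    if ref != "-" and context[index0] != ref:
        raise _Tagged("REF_MISMATCH",
                      f"task {tid!r}: context[{index1}] is "
                      f"{context[index0]!r}, not ref {ref!r}")
    if ref != "-" and alt != "-" and ref == alt:
        raise _Tagged("BAD_ALLELE",
                      f"task {tid!r}: ref and alt are identical ({ref!r})")
    return MutationTask(id=tid, context=context, index=index0,
                        ref_allele=ref, alt_allele=alt)


# ---------------------------------------------------------------------------
# output writing

DESIGN_RESULT_COLUMNS = None  # built dynamically in design_result_row


def _write_csv(path: Path, header: Sequence[str], rows: List[Sequence]) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(header)
        w.writerows(rows)


def write_outputs(results, failures, offtarget_reports, outdir,
                  xlsx: bool = False) -> Dict[str, Path]:
    """Write the four output files; returns {logical name: path}.

    * ``design_results.csv`` — per task: primers (name, sequence, match
      length, Tm, GC), arm sequences/lengths, four amplicon lengths and
      the worst homodimer / cross-dimer Tm.
    * ``primer_order.csv`` — ``<taskid>-<role>``, sequence; 7 rows/task.
    * ``failed_task.csv`` — task id, stage, reason code, message.
    * ``evaluation_result.csv`` — per-arm off-target hits.

    CSV is canonical and byte-stable across runs; XLSX mirrors are opt-in.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    from .design import PRIMER_ROLES  # local import to avoid a cycle

    dr_header = ["task_id"]
    for role in PRIMER_ROLES:
        dr_header += [f"{role}_seq", f"{role}_match_len", f"{role}_tm",
                      f"{role}_gc"]
    dr_header += ["uha_seq", "uha_len", "dha_seq", "dha_len",
                  "uha_amplicon_len", "dha_amplicon_len",
                  "verification1_amplicon_len", "verification2_amplicon_len",
                  "worst_homodimer_tm", "worst_cross_dimer_tm"]
    dr_rows = []
    po_rows = []
    for res in results:
        row: List = [res.task_id]
        for role in PRIMER_ROLES:
            p = res.primers[role]
            row += [p.full, len(p.match), f"{p.thermo.tm:.2f}",
                    f"{p.thermo.gc:.3f}"]
            po_rows.append([f"{res.task_id}-{role}", p.full])
        row += [res.uha_seq, len(res.uha_seq), res.dha_seq, len(res.dha_seq),
                res.uha_amplicon_len, res.dha_amplicon_len,
                res.verification1_amplicon_len, res.verification2_amplicon_len,
                f"{res.worst_homodimer_tm:.2f}", f"{res.worst_cross_dimer_tm:.2f}"]
        dr_rows.append(row)

    ft_header = ["task_id", "stage", "reason", "message"]
    ft_rows = [[f.task_id, f.stage, f.reason, f.message] for f in failures]

    ev_header = ["task_id", "query", "contig", "start", "strand",
                 "identity", "aligned_length"]
    ev_rows = []
    for task_id, query_name, hits in offtarget_reports:
        for h in hits:
            ev_rows.append([task_id, query_name, h.contig, h.start, h.strand,
                            f"{h.identity:.4f}", h.aligned_length])

    paths = {}
    for name, header, rows in (
            ("design_results", dr_header, dr_rows),
            ("primer_order", ["primer_name", "sequence"], po_rows),
            ("failed_task", ft_header, ft_rows),
            ("evaluation_result", ev_header, ev_rows)):
        p = outdir / f"{name}.csv"
        _write_csv(p, header, rows)
        paths[name] = p
        if xlsx:
            _mirror_xlsx(p, outdir / f"{name}.xlsx")
    return paths


def _mirror_xlsx(csv_path: Path, xlsx_path: Path) -> None:
    from openpyxl import Workbook
    wb = Workbook()
    ws = wb.active
    with open(csv_path, newline="") as fh:
        for row in csv.reader(fh):
            ws.append(row)
    wb.save(xlsx_path)
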