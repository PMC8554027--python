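"""Seeded synthetic-data generator.

Emulates the three tool inputs — a random bacterial-scale genome FASTA, a
toy linearized backbone TXT, and a mutation task CSV whose contexts are
verbatim genome slices with the edit site centered — plus a ground-truth
ledger for assertions.  Everything is a pure function of the spec, so the
same spec reproduces byte-identical files.

The generator emulates sequence *geometry*, not composition: bases are
i.i.d. with an optional GC bias, so real-genome repeat structure exists
only where duplications are explicitly planted.
"""

from __future__ import annotations

import csv
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .io import Genome, MutationTask, VectorSequence

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class PlantedDuplication:
    """Copy genome[src] to dest (overwrite), optionally with mismatches."""

    src_contig: str
    src_start: int
    length: int
    dest_contig: str
    dest_start: int
    substitution_rate: float = 0.0


@dataclass(frozen=True)
class FixtureSpec:
    seed: int = 0
    genome_length: int = 50_000
    n_contigs: int = 1
    gc_bias: float = 0.5
    n_tasks: int = 10
    task_kinds: Tuple[str, ...] = ("substitution",)
    context_len: int = 2_400
    vector_length: int = 3_000
    planted_duplications: Tuple[PlantedDuplication, ...] = ()


@dataclass
class Fixture:
    spec: FixtureSpec
    genome: Genome
    vector: VectorSequence
    tasks: List[MutationTask]
    ledger: Dict


def _random_dna(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(_BASES, size=n, p=p).tobytes().decode()


def build_fixture(spec: FixtureSpec) -> Fixture:
    """Construct the fixture in memory (see :func:`generate_fixture`)."""
    rng = np.random.default_rng(spec.seed)
    per = spec.genome_length // spec.n_contigs
    contigs = {f"contig_{i + 1}": _random_dna(rng, per, spec.gc_bias)
               for i in range(spec.n_contigs)}

    dup_records = []
    for dup in spec.planted_duplications:
        src = contigs[dup.src_contig][dup.src_start:dup.src_start + dup.length]
        if len(src) < dup.length:
            raise ValueError("duplication source span outside contig")
        copy = np.frombuffer(src.encode(), dtype=np.uint8).copy()
        n_sub = 0
        if dup.substitution_rate > 0:
            mask = rng.random(dup.length) < dup.substitution_rate
            for i in np.flatnonzero(mask):
                alt = rng.choice(_BASES[_BASES != copy[i]])
                copy[i] = alt
            n_sub = int(mask.sum())
        dest = contigs[dup.dest_contig]
        if dup.dest_start + dup.length > len(dest):
            raise ValueError("duplication destination outside contig")
        contigs[dup.dest_contig] = (dest[:dup.dest_start]
                                    + copy.tobytes().decode()
                                    + dest[dup.dest_start + dup.length:])
        dup_records.append({**asdict(dup), "n_substitutions": n_sub})

    vector_seq = _random_dna(rng, spec.vector_length, 0.5)
    if vector_seq[:20] == vector_seq[-20:]:  # astronomically unlikely
        vector_seq = vector_seq[:-1] + ("A" if vector_seq[-1] != "A" else "C")

    tasks: List[MutationTask] = []
    ledger_tasks = []
    contig_ids = list(contigs)
    for t in range(spec.n_tasks):
        kind = spec.task_kinds[t % len(spec.task_kinds)]
        cid = contig_ids[int(rng.integers(len(contig_ids)))]
        contig = contigs[cid]
        if len(contig) < spec.context_len:
            raise ValueError(
                f"context_len {spec.context_len} exceeds contig {cid} length")
        start = int(rng.integers(0, len(contig) - spec.context_len + 1))
        context = contig[start:start + spec.context_len]
        pos = spec.context_len // 2     # 0-based, centered
        if kind == "substitution":
            ref = context[pos]
            alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        elif kind == "insertion":
            ref, alt = "-", str(rng.choice(list("ACGT")))
        elif kind == "deletion":
            ref, alt = context[pos], "-"
        else:
            raise ValueError(f"unknown task kind {kind!r}")
        tid = f"task{t + 1:03d}_{kind[:3]}"
        tasks.append(MutationTask(id=tid, context=context, index=pos,
                                  ref_allele=ref, alt_allele=alt))
        ledger_tasks.append({
            "id": tid, "kind": kind, "contig": cid, "context_start": start,
            "index0": pos, "mut_genome_pos": start + pos,
            "ref": ref, "alt": alt})

    genome = Genome(name="fixture", contigs=contigs)
    ledger = {"spec": {**asdict(spec),
                       "task_kinds": list(spec.task_kinds),
                       "planted_duplications": dup_records},
              "tasks": ledger_tasks}
    return Fixture(spec=spec, genome=genome,
                   vector=VectorSequence(vector_seq), tasks=tasks,
                   ledger=ledger)


def generate_fixture(spec: FixtureSpec, outdir) -> Dict[str, Path]:
    """Write genome.fasta, vector.txt, mutations.csv and ledger.json."""
    fx = build_fixture(spec)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {"genome": outdir / "genome.fasta",
             "vector": outdir / "vector.txt",
             "mutations": outdir / "mutations.csv",
             "ledger": outdir / "ledger.json"}

    with open(paths["genome"], "w") as fh:
        for cid, seq in fx.genome.contigs.items():
            fh.write(f">{cid}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i:i + 70] + "\n")
    paths["vector"].write_text(fx.vector.bases + "\n")
    with open(paths["mutations"], "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["id", "context", "index", "ref", "alt"])
        for task in fx.tasks:
            w.writerow([task.id, task.context, task.index + 1,
                        task.ref_allele, task.alt_allele])
    with open(paths["ledger"], "w") as fh:
        json.dump(fx.ledger, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return paths
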