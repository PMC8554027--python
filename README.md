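# alleleforge

Batch computer-aided design for **genomic point-mutation editing in
bacteria by two-round single-crossover allelic exchange** with a
non-replicating (suicide) counter-selection vector such as pK18*mobsacB*.

Introducing one defined substitution, insertion or deletion this way
requires, per mutation: an **upstream and a downstream homologous arm**
(UHA/DHA) flanking the edit, cloned into the linearized backbone by
overlap-based assembly (Gibson/CPEC/TEDA-style, 20-bp homologous ends),
and **seven primers in four pairs** — primer-1/2 and primer-3/4 amplify
the two arms with 20-nt 5′ overhang tails, test-primer-1/2 screen out
false-positive clones after the first crossover (integration), and
test-primer-1/3 produce the sequencing amplicon that confirms the edit
after the second crossover (resolution). Doing this by hand for tens or
thousands of mutations (saturation mutagenesis, reverse-engineering of
evolved strains) is error-prone; `alleleforge` does it as a deterministic
batch computation, for any bacterial genome supplied as FASTA.

For every requested edit the library

1. **validates** the input: context length must exceed
   UHA_max + DHA_max + UIS_max + DIS2_min, the edit must sit centrally
   enough to leave template on both sides, and the context must match the
   genome exactly once on the forward strand;
2. applies the edit and extracts the 20-nt **junction window** covering
   the mutation — the overlap shared by the two arm amplicons, and the 5′
   tail of primer-3 (its reverse complement is the tail of primer-2);
3. optimizes each primer's 18–25-nt 3′ template match **exhaustively**
   inside its optional design region (ODR), minimizing

   `penalty = w_tm·|Tm − Tm_opt| + w_gc·|GC − GC_opt|·100 +
   w_dimer·max(0, Tm_homodimer − ceiling) + w_hairpin·max(0, Tm_hairpin − ceiling)`

   with nearest-neighbor Tm (unified Allawi–SantaLucia parameters,
   SantaLucia-98 salt entropy, von Ahsen divalent equivalence);
4. screens the arms against the genome for **off-target** homology
   (seed-and-extend, gapless, identity ≥ 0.8 over ≥ 50 % of the arm) and
   primers for 3′ mis-priming sites;
5. **verifies** the design by simulating the overlap assembly into the
   circular suicide plasmid and both crossover events, recovering the
   integrant, the edited genome and the revertant.

Tasks whose local sequence admits no primer within the Tm/GC constraints
are reported in a failed-task table with the dominant rejection reason —
a normal outcome, not an error.

## Worked example

Generate a synthetic input set (random 40-kb genome, 3-kb toy backbone,
3 substitution tasks) and run the batch design:

```sh
alleleforge fixture --out demo --seed 5 --genome-length 40000 --n-tasks 3
alleleforge design --genome demo/genome.fasta --vector demo/vector.txt \
    --mutations demo/mutations.csv --out demo/out
# designed 1 task(s), 2 failed, 0 arm(s) with off-target hits; outputs in demo/out
```

Four CSV files appear in `demo/out`. `primer_order.csv` is ready for a
synthesis vendor, seven oligos per successful task:

```
primer_name,sequence
task002_sub-primer-1,AGGTTTTAACTAGCGCCGACAAGTTTGGCACACAGGGT
task002_sub-primer-2,GGGTGCAATCGTAATGCGATTTAGCGTATCCCACTACTACTG
task002_sub-primer-3,ATCGCATTACGATTGCACCCCCTAGATCGCATTTTGCTGG
...
```

`design_results.csv` carries the geometry and thermodynamics of the
design; for `task002_sub`:

| quantity | value | meaning |
|---|---|---|
| `uha_len` / `dha_len` | 758 / 589 | arm lengths, inside the configured 500–800 nt range |
| `uha_amplicon_len` | 778 | arm + one 20-nt vector tail |
| `verification1_amplicon_len` | 1785 | test-primer-1/2 product on the integrant (absent from wild type) |
| `verification2_amplicon_len` | 1849 | test-primer-1/3 sequencing product on the edited genome |
| `primer-1_tm` / `primer-1_gc` | 60.05 / 0.500 | 3′-match Tm (°C) and GC of the optimum |
| `worst_cross_dimer_tm` | 61.91 | expected: primer-2 and primer-3 are complementary over the junction window |

`failed_task.csv` explains the two undesignable tasks
(`primer-2: considered 8 candidates, … high tm 8, … ok 0`): their
junction-flanking sequence is too GC-rich for any admissible 18–25-mer.

The same run is available programmatically:

```python
from alleleforge import (FixtureSpec, build_fixture, design_task,
                         assemble_in_silico, predict_edited_genome)
fx = build_fixture(FixtureSpec(seed=5, genome_length=40_000, n_tasks=3))
result = design_task(fx.tasks[1], fx.genome, fx.vector)
plasmid = assemble_in_silico(result, fx.vector)        # raises on any bad junction
prediction = predict_edited_genome(result, fx.genome, plasmid)
```

## Layout

- `alleleforge.sequence`, `alleleforge.thermo` — DNA primitives and
  nearest-neighbor thermodynamics
- `alleleforge.io` — FASTA / vector TXT / mutation CSV readers, the four
  output writers (CSV, optional XLSX)
- `alleleforge.validate` — pre-design checks and genome anchoring
- `alleleforge.design` — ODRs, overhangs, primer optimization, in-silico
  assembly and crossover simulation
- `alleleforge.offtarget` — arm homology and mis-priming scans
- `alleleforge.fixtures` — seeded synthetic input generator
- `alleleforge.cli` — `alleleforge design | validate | fixture`

See `docs/methods.md` for the model, parameter semantics and known
limitations.
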