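# Methods

## Editing model

The package targets the classical two-step allelic-exchange workflow with
a non-replicating counter-selection vector (kan<sup>R</sup> for positive
selection of integrants, *sacB*-type marker for counter-selection of
resolvents). The vector carries the upstream homologous arm (UHA), the
point mutation, and the downstream homologous arm (DHA). Integration by a
single crossover through either arm duplicates the arm region; resolution
by a second crossover through the *other* repeat leaves the edited
allele, through the same repeat the wild type (hence the theoretical 50 %
editing efficiency of the technique). Everything downstream of primer
design — electroporation, selection, sucrose counter-selection — is out
of scope; the package designs and verifies, it does not model biology
beyond sequence bookkeeping.

## Geometry

All coordinates are 0-based half-open on the forward strand; 1-based
conventions exist only in the mutation CSV (and are converted on read).

Given a task (context sequence, index, ref → alt) anchored exactly once
in the genome, the edit is applied to the context and a 20-nt **junction
window** is cut from the edited context with the edited base at offset 9
(`window_offset`; for a deletion, the base that followed the deleted one;
for an insertion, the inserted base). The window is the UHA–DHA assembly
overlap and carries the mutation into *both* arm amplicons.

Arms are defined inclusive of the window:
`UHA = edited[uha_start : window_end]`, `DHA = edited[window_start :
dha_end]`, with lengths constrained to `[uha_min, uha_max]` /
`[dha_min, dha_max]` (defaults 500–800 nt — long arms favour efficient
recombination). The optional design regions follow by arithmetic:

| region | anchors | constraint |
|---|---|---|
| ODR_UHA | primer-1 match starts | UHA length in range |
| ODR_DHA | primer-4 site right edges | DHA length in range |
| ODR_UIS | test-primer-1 starts | 5′ end 50–300 nt upstream of the UHA |
| ODR_DIS1 | test-primer-2 right edges (vector) | 50–300 nt into the backbone from the DHA–vector junction |
| ODR_DIS2 | test-primer-3 right edges | 50–300 nt downstream of the DHA |

Regions are clipped to their templates; an empty region fails the task
with `ODR_EMPTY`. The input length rule (context >
UHA_max + DHA_max + UIS_max + DIS2_min, strict) and the centrality rule
(≥ UIS_max + UHA_max upstream, ≥ DHA_max + DIS2_min downstream, margins
inclusive) guarantee the genomic regions exist before design starts.
The length rule is enforced as printed with the DIS2 *minimum*, although
the maximum would be the conservative bound; the centrality margins
absorb the difference in practice.

## Overhangs and the vector-end convention

primer-3 carries the junction window as its 5′ tail; primer-2 its
reverse complement; primer-1 and primer-4 carry the two 20-nt vector
terminal segments, so that the UHA amplicon, DHA amplicon and backbone
share three 20-bp homologous ends and assemble into
`vector + UHA + window + DHA` (canonical rotation at vector position 0).

Which physical terminus of the supplied top strand seeds primer-1 is
`vector_end_convention`. The default, `"3prime"`, is the only geometry
whose three junctions can close a circle: primer-1 receives the vector's
3′-terminal 20-mer (the segment that precedes the UHA reading around the
circle) and primer-4 the reverse complement of the 5′-terminal one. The
alternative `"5prime"` assigns the ends the other way round — a mistake
easy to make when the linearized backbone is supplied in the opposite
orientation; those tails place both vector overlaps in the same
orientation as the backbone itself, so no fragment orientation yields
matching junctions. The setting exists so an end-labeling mix-up is
caught by `assemble_in_silico` with an explicit diagnostic rather than
surfacing as a failed cloning experiment. Insert orientation relative to
the backbone is irrelevant for homologous recombination, so the default
choice costs nothing biologically.

## Primer optimization

Every primer's 3′ template match is chosen by exhaustive enumeration of
all admissible (anchor, length) candidates, length 18–25 nt. primer-2/3
are anchored flush against the junction window (the mutation must sit in
the tail, which fixes the amplicon junction), so only their length
varies — eight candidates. Candidates containing `N`, or with Tm outside
[57, 63] °C or GC outside [0.40, 0.60], are rejected; survivors are
scored with

```
penalty = 1.0·|Tm − 60| + 0.2·|GC − 0.50|·100
        + 0.5·max(0, Tm_homodimer − 35) + 0.5·max(0, Tm_hairpin − 35)
```

and the minimum wins; ties break to shorter length, then smaller start.
Penalties are compared after rounding to 9 decimals so the documented
tie-break, not floating-point summation order, decides between
thermodynamically identical windows. The weights are package defaults,
exposed in configuration, chosen to make one degree of Tm error count
like one percentage point of GC error five-fold weighted, with dimer and
hairpin terms acting only above the 35 °C screening ceiling. During
optimization the dimer/hairpin screens run on the match alone (the tail
is fixed and shared by all candidates); reported primer annotations carry
Tm/GC of the match and dimer/hairpin of the full tailed oligo.

If no candidate survives, the task fails with a per-reason candidate
census (`considered 8 … high tm 8 … ok 0`). On random 50 %-GC sequence
roughly half of all loci are undesignable at the default constraints,
almost always at the anchored primers — loosening the Tm window or
moving `window_offset` recovers most of them. This is deliberate: a
failed task with a reason is more useful than a silently bad primer.

Cross-dimers over all 21 primer pairs are reported but never fail a task.
primer-2 and primer-3 are complementary across the full window by
construction, so the worst cross-dimer Tm of a successful design is
typically the window Tm (~60 °C); it documents the overlap, not a defect.

## Thermodynamics

Nearest-neighbor model: unified Allawi–SantaLucia (1997) stack
parameters with duplex-initiation terms, Tm from ΔH/ΔS with the
SantaLucia (1998) entropic salt correction
`ΔS += 0.368·(N−1)·ln[Na+]_eff` and strand concentration term
`R·ln(C)`. Divalent cations use the von Ahsen (2001) equivalence
`[Na+]_eff = [Na+] + 120·√[Mg2+]`; defaults Na⁺ = 50 mM, Mg²⁺ = 1.5 mM,
oligo = 50 nM describe the PCR buffer the primers will actually see.
Without the divalent term an 18–25-mer at 50 % GC melts around 50–59 °C
and the 57–63 °C acceptance window starves the anchored primers; with it
the window sits on the distribution's center, which is precisely why
primer-design software applies the same correction.

Dimer and hairpin screening scores the best *ungapped* complementary
alignment (maximal perfectly matched run ≥ 4 nt) with the same stack
table; hairpin stems additionally require a ≥ 3-nt loop. `−100 °C` is the
no-structure sentinel. Internal loops, bulges and dangling-end terms are
not modelled — these are screening scores for ranking, not folding
predictions. Inside the optimizer, slice Tm/GC come from prefix-sum
arrays over the template (valid for reverse primers because the unified
table is reverse-complement symmetric); the values are identical to the
string-based functions to ~1e-12 °C.

## Off-target evaluation

Arms are scanned with seed-and-extend: every exact 11-mer seed (both
strands) nominates a diagonal, extended without gaps across the whole
arm; alignments with identity ≥ 0.8 covering ≥ 50 % of the arm are
reported, the intended locus excluded. The scanner is bit-reproducible
and dependency-free, and on the synthetic fixtures it provably equals the
exhaustive all-diagonals scan (tested). Limitations: a paralog whose
matching positions never form an 11-mer run is theoretically missable
(identity 0.8 only guarantees runs ≥ 4), and indel-containing paralogs
are invisible to gapless extension. Mis-priming warnings report genomic
occurrences of each primer's 3′-terminal 12-mer outside its intended
site.

## In-silico verification

`assemble_in_silico` rebuilds both amplicons from the edited template via
the chosen primers and literally checks the three 20-mers before
overlap-merging them with the backbone; any disagreement raises — this
fires on corrupted tails and on the non-circularizable convention, never
on a valid default design. `predict_edited_genome` constructs the
integrant (crossover placed at the window boundary inside the shared
upstream arm segment), on which the test-primer-1/2 product exists and is
sized, while test-primer-2 has no binding site on wild type (the
false-positive screen); resolution yields the edited genome (sized for
the test-primer-1/3 sequencing product) and the revertant, which is
byte-identical to the input.

## Synthetic data

The fixture generator emulates the three inputs with i.i.d. bases
(optional GC bias), a 3-kb toy backbone with distinct termini, and task
contexts cut verbatim from the genome with the edit site centered
(default context 2,400 nt — the smallest round size clearing the default
length and centrality rules with margin). Duplications can be planted
(optionally with point substitutions) to exercise multi-mapping and
off-target reporting. What passing tests show is therefore correctness of
geometry, optimization and simulation — not performance on real genomes,
whose repeat families, skewed composition and mobile elements exist here
only as planted copies. Problem sizes in the test suite (50–200-kb
genomes, up to 200-task batches) were chosen so the exhaustive oracles
remain tractable; the design itself runs at roughly a quarter second per
task on one CPU, independent of batch size.

## Defaults worth knowing

| parameter | default | unit | note |
|---|---|---|---|
| uha/dha length | 500–800 | nt | arm range; ODR width 301 |
| uis, dis1, dis2 | 50–300 | nt | verification-primer placement |
| match length | 18–25 | nt | all seven primers |
| overlap length | 20 | nt | all three assembly junctions |
| window_offset | 9 | nt | edited base position in the window |
| Tm | 57 / 60 / 63 | °C | min / opt / max of the 3′ match |
| GC | 0.40 / 0.50 / 0.60 | — | min / opt / max |
| dimer ceiling | 35 | °C | self and cross |
| Na⁺, Mg²⁺, oligo | 50 mM, 1.5 mM, 50 nM | | Tm conditions |
| off-target | seed 11, identity 0.8, coverage 0.5 | | arm scan |
| misprime k-mer | 12 | nt | 3′ scan |

All are overridable via `DesignParameters`, a `key = value` parameter
file, or CLI flags.
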