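"""Design parameters: arm/primer length ranges, thermodynamic thresholds.

Symbols follow the allelic-exchange design geometry: UHA/DHA are the
upstream/downstream homologous arms; UIS positions the forward
verification primer (test-primer-1) upstream of the UHA; DIS1 positions
the vector-side reverse verification primer (test-primer-2) measured from
the DHA-vector junction into the backbone; DIS2 positions the genomic
reverse verification primer (test-primer-3) downstream of the DHA.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Dict

from .errors import ParseError

#: which physical terminus of the supplied vector top strand seeds the
#: 5' tail of primer-1. "3prime" (default): the 3'-terminal 20-mer — the
#: segment that precedes the UHA reading around the final circle, the
#: only geometry whose three junctions can close a circle. "5prime": the
#: 5'-terminal 20-mer; those tails cannot form a circle and in-silico
#: assembly rejects them (kept so end-labeling mix-ups are caught
#: loudly rather than silently).
VECTOR_END_CONVENTIONS = ("3prime", "5prime")


@dataclass(frozen=True)
class DesignParameters:
    # homologous arm length ranges (nt)
    uha_min: int = 500
    uha_max: int = 800
    dha_min: int = 500
    dha_max: int = 800
    # verification-primer placement spans (nt)
    uis_min: int = 50
    uis_max: int = 300
    dis1_min: int = 50
    dis1_max: int = 300
    dis2_min: int = 50
    dis2_max: int = 300
    # primer geometry (nt)
    match_len_min: int = 18
    match_len_max: int = 25
    overlap_len: int = 20
    window_offset: int = 9   # 0-based offset of the edited base in the window
    # thermodynamic constraints
    tm_min: float = 57.0
    tm_opt: float = 60.0
    tm_max: float = 63.0
    gc_min: float = 0.40
    gc_opt: float = 0.50
    gc_max: float = 0.60
    max_self_dimer_tm: float = 35.0
    max_cross_dimer_tm: float = 35.0
    salt_mM: float = 50.0
    divalent_mM: float = 1.5
    oligo_nM: float = 50.0
    # penalty weights
    w_tm: float = 1.0
    w_gc: float = 0.2
    w_dimer: float = 0.5
    w_hairpin: float = 0.5
    # off-target scanning
    offtarget_seed_len: int = 11
    offtarget_identity_threshold: float = 0.8
    offtarget_min_coverage: float = 0.5
    misprime_kmer: int = 12
    # assembly geometry
    vector_end_convention: str = "3prime"

    def __post_init__(self):
        def bad(msg):
            raise ParseError(f"invalid design parameters: {msg}")
        for lo, hi in (("uha_min", "uha_max"), ("dha_min", "dha_max"),
                       ("uis_min", "uis_max"), ("dis1_min", "dis1_max"),
                       ("dis2_min", "dis2_max"),
                       ("match_len_min", "match_len_max")):
            if getattr(self, lo) > getattr(self, hi):
                bad(f"{lo} > {hi}")
            if getattr(self, lo) < 1:
                bad(f"{lo} < 1")
        if not self.tm_min <= self.tm_opt <= self.tm_max:
            bad("tm_min <= tm_opt <= tm_max violated")
        if not 0 <= self.gc_min <= self.gc_opt <= self.gc_max <= 1:
            bad("gc_min <= gc_opt <= gc_max in [0,1] violated")
        if self.overlap_len < 1:
            bad("overlap_len < 1")
        if not 0 <= self.window_offset < self.overlap_len:
            bad("window_offset outside the junction window")
        if self.vector_end_convention not in VECTOR_END_CONVENTIONS:
            bad(f"vector_end_convention must be one of {VECTOR_END_CONVENTIONS}")
        if not 0 < self.offtarget_identity_threshold <= 1:
            bad("offtarget_identity_threshold outside (0,1]")

    @property
    def length_rule_bound(self) -> int:
        """Minimum context length: UHA_max + DHA_max + UIS_max + DIS2_min."""
        return self.uha_max + self.dha_max + self.uis_max + self.dis2_min

    def override(self, **kwargs) -> "DesignParameters":
        return replace(self, **kwargs)


_INT_FIELDS = {f.name for f in fields(DesignParameters) if f.type == "int"}
_STR_FIELDS = {"vector_end_convention"}


def read_params_file(path) -> DesignParameters:
    """Parse a plain ``key = value`` parameter file (``#`` comments)."""
    values: Dict[str, object] = {}
    known = {f.name for f in fields(DesignParameters)}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ParseError(f"params line {lineno}: expected 'key = value'")
        key, val = (part.strip() for part in line.split("=", 1))
        key = key.lower()
        if key not in known:
            raise ParseError(f"params line {lineno}: unknown parameter {key!r}")
        try:
            if key in _STR_FIELDS:
                values[key] = val
            elif key in _INT_FIELDS:
                values[key] = int(val)
            else:
                values[key] = float(val)
        except ValueError as exc:
            raise ParseError(f"params line {lineno}: bad value {val!r}") from exc
    return DesignParameters(**values)
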