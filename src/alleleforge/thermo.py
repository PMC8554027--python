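"""Nearest-neighbor DNA thermodynamics.

Melting temperatures use the unified nearest-neighbor parameter set of
Allawi & SantaLucia (1997) with the SantaLucia (1998) entropic correction
for monovalent salt:

    Tm = 1000 * dH / (dS + 0.368 * (N - 1) * ln[Na+] + R * ln(C)) - 273.15

with dH in kcal/mol, dS in cal/(mol*K), R = 1.987 cal/(mol*K), [Na+] the
effective monovalent cation molarity and C the oligo molar concentration
(for a non-self-complementary duplex at equal strand concentrations,
C = Ct).  Divalent cations enter through the von Ahsen (2001) equivalence
used by standard primer-design software, [Na+]_eff = [Na+] +
120*sqrt([Mg2+]) (mM); the defaults (50 mM monovalent, 1.5 mM Mg2+,
50 nM oligo) describe a standard PCR buffer, since every primer designed
here is destined for PCR.

Dimer and hairpin screening uses the same stack table on the best ungapped
complementary alignment; internal loops and bulges are out of scope, so
the reported values are screening scores, not full secondary-structure
predictions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np

from .errors import SequenceError
from .sequence import reverse_complement, validate_dna

R_GAS = 1.987  # cal / (mol K)

#: Sentinel returned when no complementary run of >= MIN_DUPLEX_RUN exists.
NO_DUPLEX_TM = -100.0
MIN_DUPLEX_RUN = 4
MIN_HAIRPIN_LOOP = 3

# Unified NN stack parameters, (dH kcal/mol, dS cal/mol/K), keyed by the
# top-strand dinucleotide (value identical for its reverse complement).
NN_STACKS = {
    "AA": (-7.9, -22.2), "TT": (-7.9, -22.2),
    "AT": (-7.2, -20.4),
    "TA": (-7.2, -21.3),
    "CA": (-8.5, -22.7), "TG": (-8.5, -22.7),
    "GT": (-8.4, -22.4), "AC": (-8.4, -22.4),
    "CT": (-7.8, -21.0), "AG": (-7.8, -21.0),
    "GA": (-8.2, -22.2), "TC": (-8.2, -22.2),
    "CG": (-10.6, -27.2),
    "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9), "CC": (-8.0, -19.9),
}

# Duplex initiation per terminal base pair.
INIT_AT = (2.3, 4.1)
INIT_GC = (0.1, -2.8)

DEFAULT_SALT_MM = 50.0
DEFAULT_OLIGO_NM = 50.0
DEFAULT_DIVALENT_MM = 1.5


def effective_monovalent(salt_mM: float, divalent_mM: float) -> float:
    """von Ahsen (2001) monovalent equivalent of a Mg2+-containing buffer."""
    return salt_mM + 120.0 * math.sqrt(divalent_mM) if divalent_mM > 0 else salt_mM


@dataclass(frozen=True)
class ThermoResult:
    """Thermodynamic annotations of one oligo."""

    tm: float             # duplex melting temperature, deg C
    gc: float             # GC fraction in [0, 1]
    homodimer_tm: float   # best self-dimer Tm, deg C (NO_DUPLEX_TM if none)
    hairpin_tm: float     # best hairpin stem Tm, deg C (NO_DUPLEX_TM if none)


def _nn_sum(seq: str) -> Tuple[float, float]:
    """Raw dH (kcal/mol), dS (cal/mol/K) for a perfectly matched duplex."""
    dh, ds = 0.0, 0.0
    for term in (seq[0], seq[-1]):
        inc = INIT_AT if term in "AT" else INIT_GC
        dh += inc[0]
        ds += inc[1]
    for i in range(len(seq) - 1):
        inc = NN_STACKS[seq[i:i + 2]]
        dh += inc[0]
        ds += inc[1]
    return dh, ds


def _tm_from_sums(dh: float, ds: float, n: int, mon_mM: float,
                  oligo_nM: float) -> float:
    ds_corr = ds + 0.368 * (n - 1) * math.log(mon_mM * 1e-3)
    return 1000.0 * dh / (ds_corr + R_GAS * math.log(oligo_nM * 1e-9)) - 273.15


def melting_temperature(seq: str, salt_mM: float = DEFAULT_SALT_MM,
                        oligo_nM: float = DEFAULT_OLIGO_NM,
                        divalent_mM: float = DEFAULT_DIVALENT_MM) -> float:
    """Nearest-neighbor Tm (deg C) of *seq* against its perfect complement.

    Length must lie in [2, 60]; ``N`` is rejected because stack enthalpies
    are undefined for ambiguous bases.
    """
    s = validate_dna(seq, allow_n=False, what="oligo")
    if not 2 <= len(s) <= 60:
        raise SequenceError(f"oligo length {len(s)} outside [2, 60]")
    dh, ds = _nn_sum(s)
    return _tm_from_sums(dh, ds, len(s),
                         effective_monovalent(salt_mM, divalent_mM), oligo_nM)


def _run_tm(seq: str, mon_mM: float, oligo_nM: float) -> float:
    dh, ds = _nn_sum(seq)
    return _tm_from_sums(dh, ds, len(seq), mon_mM, oligo_nM)


def _matching_runs(a: str, c: str) -> List[Tuple[int, int, int]]:
    """Maximal equal runs between *a* and *c* over every ungapped offset.

    Yields (a_start, c_start, length) with length >= MIN_DUPLEX_RUN;
    positions holding ``N`` never match.
    """
    runs = []
    la, lc = len(a), len(c)
    for shift in range(-(lc - 1), la):
        i = max(0, shift)
        end = min(la, shift + lc)
        run_start = None
        while i <= end:
            match = i < end and a[i] != "N" and a[i] == c[i - shift]
            if match and run_start is None:
                run_start = i
            elif not match and run_start is not None:
                if i - run_start >= MIN_DUPLEX_RUN:
                    runs.append((run_start, run_start - shift, i - run_start))
                run_start = None
            i += 1
    return runs


def duplex_tm(a: str, b: str, salt_mM: float = DEFAULT_SALT_MM,
              oligo_nM: float = DEFAULT_OLIGO_NM,
              divalent_mM: float = DEFAULT_DIVALENT_MM) -> float:
    """Tm of the best ungapped complementary alignment of *a* with *b*.

    The duplex is scored as the longest-stability perfectly matched run
    between ``a`` and ``reverse_complement(b)``; returns
    :data:`NO_DUPLEX_TM` when no complementary run of at least
    :data:`MIN_DUPLEX_RUN` nt exists.  ``duplex_tm(s, s)`` is the homodimer
    screen; ``duplex_tm(s, reverse_complement(s))`` recovers the perfect
    duplex and equals :func:`melting_temperature`.
    """
    a = validate_dna(a, what="duplex strand a")
    b = validate_dna(b, what="duplex strand b")
    c = reverse_complement(b)
    best = NO_DUPLEX_TM
    mon = effective_monovalent(salt_mM, divalent_mM)
    for a_start, _, length in _matching_runs(a, c):
        tm = _run_tm(a[a_start:a_start + length], mon, oligo_nM)
        if tm > best:
            best = tm
    return best


def homodimer_tm(seq: str, salt_mM: float = DEFAULT_SALT_MM,
                 oligo_nM: float = DEFAULT_OLIGO_NM,
                 divalent_mM: float = DEFAULT_DIVALENT_MM) -> float:
    """Self-dimer screening Tm: ``duplex_tm(seq, seq)``."""
    return duplex_tm(seq, seq, salt_mM, oligo_nM, divalent_mM)


def hairpin_tm(seq: str, salt_mM: float = DEFAULT_SALT_MM,
               oligo_nM: float = DEFAULT_OLIGO_NM,
               divalent_mM: float = DEFAULT_DIVALENT_MM) -> float:
    """Best hairpin stem Tm with a loop of >= MIN_HAIRPIN_LOOP nt.

    A stem is an intramolecular complementary run: position i pairs with
    position n-1-k on the same strand.  Runs are trimmed so the loop
    between the stem halves is at least MIN_HAIRPIN_LOOP nt; stems shorter
    than MIN_DUPLEX_RUN are ignored (sentinel returned).
    """
    s = validate_dna(seq, what="hairpin oligo")
    n = len(s)
    c = reverse_complement(s)
    best = NO_DUPLEX_TM
    mon = effective_monovalent(salt_mM, divalent_mM)
    for a_start, c_start, length in _matching_runs(s, c):
        # a index i pairs with partner n-1-(i-shift); i+partner is constant
        shift = a_start - c_start
        pair_sum = n - 1 + shift
        # keep only i with loop = partner - i - 1 >= MIN_HAIRPIN_LOOP
        i_max = (pair_sum - MIN_HAIRPIN_LOOP - 1) // 2
        stem_len = min(a_start + length - 1, i_max) - a_start + 1
        if stem_len >= MIN_DUPLEX_RUN:
            tm = _run_tm(s[a_start:a_start + stem_len], mon, oligo_nM)
            if tm > best:
                best = tm
    return best


def thermo_profile(seq: str, salt_mM: float = DEFAULT_SALT_MM,
                   oligo_nM: float = DEFAULT_OLIGO_NM,
                   divalent_mM: float = DEFAULT_DIVALENT_MM,
                   tm_of: Optional[str] = None) -> ThermoResult:
    """Full :class:`ThermoResult` for one primer.

    ``tm_of`` optionally names a sub-sequence (the 3' template match of a
    tailed primer) whose Tm and GC are reported, while dimer and hairpin
    screens run on the full oligo.
    """
    core = tm_of if tm_of is not None else seq
    from .sequence import gc_fraction
    return ThermoResult(
        tm=melting_temperature(core, salt_mM, oligo_nM, divalent_mM),
        gc=gc_fraction(core),
        homodimer_tm=homodimer_tm(seq, salt_mM, oligo_nM, divalent_mM),
        hairpin_tm=hairpin_tm(seq, salt_mM, oligo_nM, divalent_mM),
    )


class TemplateThermo:
    """O(1) Tm/GC of any slice of a fixed template via prefix sums.

    Used by the primer optimizer, which scores thousands of candidate
    windows of one template; results are numerically identical to
    :func:`melting_temperature` / GC on the slice (reverse-complement
    symmetry of the unified table makes the forward-strand sums valid for
    reverse primers as well).
    """

    def __init__(self, template: str, salt_mM: float = DEFAULT_SALT_MM,
                 oligo_nM: float = DEFAULT_OLIGO_NM,
                 divalent_mM: float = DEFAULT_DIVALENT_MM):
        self.template = validate_dna(template, what="template")
        self.salt_mM = salt_mM
        self.oligo_nM = oligo_nM
        self.divalent_mM = divalent_mM
        t = self.template
        n = len(t)
        dh = np.zeros(n, dtype=float)   # dh[i]: stack of t[i:i+2]
        ds = np.zeros(n, dtype=float)
        for i in range(n - 1):
            pair = t[i:i + 2]
            if "N" in pair:
                continue
            dh[i], ds[i] = NN_STACKS[pair]
        self._dh_cum = np.concatenate(([0.0], np.cumsum(dh)))
        self._ds_cum = np.concatenate(([0.0], np.cumsum(ds)))
        gc = np.frombuffer(t.encode(), dtype=np.uint8)
        self._gc_cum = np.concatenate(
            ([0], np.cumsum((gc == ord("G")) | (gc == ord("C")))))
        self._n_cum = np.concatenate(([0], np.cumsum(gc == ord("N"))))
        self._log_salt = math.log(
            effective_monovalent(salt_mM, divalent_mM) * 1e-3)
        self._log_conc = math.log(oligo_nM * 1e-9)

    def has_n(self, start: int, end: int) -> bool:
        return bool(self._n_cum[end] - self._n_cum[start])

    def gc(self, start: int, end: int) -> float:
        return float(self._gc_cum[end] - self._gc_cum[start]) / (end - start)

    def tm(self, start: int, end: int) -> float:
        """Tm of template[start:end] (equivalently of its reverse complement)."""
        t = self.template
        dh = float(self._dh_cum[end - 1] - self._dh_cum[start])
        ds = float(self._ds_cum[end - 1] - self._ds_cum[start])
        for term in (t[start], t[end - 1]):
            inc = INIT_AT if term in "AT" else INIT_GC
            dh += inc[0]
            ds += inc[1]
        n = end - start
        ds += 0.368 * (n - 1) * self._log_salt
        return 1000.0 * dh / (ds + R_GAS * self._log_conc) - 273.15
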