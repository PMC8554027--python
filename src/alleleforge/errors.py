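"""Typed exceptions shared across the package."""


class AlleleforgeError(Exception):
    """Base class for all package errors."""


class SequenceError(AlleleforgeError):
    """Illegal characters, empty input, or length out of range."""


class ParseError(AlleleforgeError):
    """A malformed input file (FASTA, vector TXT, mutation CSV, params)."""


class AssemblyJunctionMismatch(AlleleforgeError):
    """A 20-nt assembly junction did not match during in-silico assembly.

    Must never fire on a design produced under the default (circularizable)
    vector end convention; it is the negative control for corrupted tails
    and for the non-assemblable "5prime" tail convention.
    """
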