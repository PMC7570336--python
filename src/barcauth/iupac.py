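"""IUPAC nucleotide-code arithmetic shared by curation, matching and haplotyping.

All comparisons in the package are ambiguity-aware: a base ``b`` is *compatible*
with a code ``c`` iff their expansion sets intersect, and ``b`` is *contained* in
``c`` iff expansion(b) is a subset of expansion(c).  Sequences are handled as DNA
(T); RNA input is normalized upstream.
"""

from __future__ import annotations

IUPAC_DNA: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_CODE_FOR: dict[frozenset[str], str] = {v: k for k, v in IUPAC_DNA.items()}

GAP = "-"

_COMPLEMENT = {
    "A": "T", "C": "G", "G": "C", "T": "A",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N", GAP: GAP,
}

#: every pair of distinct IUPAC codes whose expansions intersect; passed to edlib
#: as additionalEqualities so that ambiguity codes align as matches.
COMPATIBLE_PAIRS: list[tuple[str, str]] = [
    (a, b)
    for a in IUPAC_DNA
    for b in IUPAC_DNA
    if a < b and IUPAC_DNA[a] & IUPAC_DNA[b]
]


def is_iupac(ch: str) -> bool:
    return ch in IUPAC_DNA


def expand(code: str) -> frozenset[str]:
    """Set of unambiguous bases denoted by *code*."""
    try:
        return IUPAC_DNA[code]
    except KeyError:
        raise ValueError(f"not an IUPAC nucleotide code: {code!r}") from None


def minimal_code(bases) -> str:
    """The single IUPAC letter covering exactly the union of *bases*."""
    union = frozenset().union(*(expand(b) for b in bases))
    if not union:
        raise ValueError("cannot encode an empty base set")
    return _CODE_FOR[union]


def compatible(a: str, b: str) -> bool:
    """True iff codes *a* and *b* could denote the same underlying base."""
    return bool(expand(a) & expand(b))


def contains(code: str, base: str) -> bool:
    """True iff every base denoted by *base* is also denoted by *code*."""
    return expand(base) <= expand(code)


def complement(ch: str) -> str:
    return _COMPLEMENT[ch]


def revcomp(seq: str) -> str:
    """Reverse complement, ambiguity-code aware; preserves case."""
    out = []
    for ch in reversed(seq):
        up = ch.upper()
        comp = _COMPLEMENT.get(up)
        if comp is None:
            raise ValueError(f"cannot complement {ch!r}")
        out.append(comp.lower() if ch.islower() else comp)
    return "".join(out)
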