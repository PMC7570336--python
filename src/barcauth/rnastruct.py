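"""RNA secondary-structure characters.

Three structure-derived characters support the sequence barcodes:

* the psbA 3' UTR stem-loop of the psbA-trnH spacer, whose truncation
  (a deletion shortening the stem to roughly half its length) is
  characteristic of the target species — extracted between two conserved
  anchor motifs, folded, and classified LONG/SHORT by stem base-pair count;
* compensatory base changes (CBCs) between ITS2 secondary structures:
  aligned pair sites where both partners differ while pairing is maintained
  (a hemi-CBC changes one partner only);
* a single-letter sequence+structure encoding, 12 letters covering
  (base x unpaired/opening/closing), for structure-aware alignment display.

Folding is base-pair maximization (Nussinov) over canonical pairs
{AU, UA, GC, CG, GU, UG} with a minimum hairpin loop of 3, chosen because the
diagnostic character here is stem length, not free energy; the traceback is
deterministic (pairing preferred over leaving a base unpaired at co-optimal
ties, 5'-most partner first), and externally computed minimum-free-energy
dot-brackets can be supplied instead wherever a StructuredSequence is
accepted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import edlib

from .errors import AnchorError, DataError
from .iupac import GAP, compatible

CANONICAL_PAIRS = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
WOBBLE_PAIRS = {("G", "U"), ("U", "G")}

DEFAULT_MIN_LOOP = 3
DEFAULT_SHORT_MAX_BP = 8


def _to_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def _can_pair(a: str, b: str, allow_gu: bool = True) -> bool:
    if (a, b) in CANONICAL_PAIRS:
        return True
    return allow_gu and (a, b) in WOBBLE_PAIRS


def _parse_pairs(structure: str) -> dict[int, int]:
    """Pair map (both directions, 0-based) from a dot-bracket string."""
    stack: list[int] = []
    pairs: dict[int, int] = {}
    for i, ch in enumerate(structure):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            if not stack:
                raise DataError(f"unbalanced ')' at position {i + 1}")
            j = stack.pop()
            pairs[i] = j
            pairs[j] = i
        elif ch not in ".-":
            raise DataError(f"invalid structure character {ch!r} at position {i + 1}")
    if stack:
        raise DataError(f"unbalanced '(' at position {stack[-1] + 1}")
    return pairs


@dataclass
class StructuredSequence:
    """An RNA sequence with its dot-bracket structure (gapped rows allowed)."""

    sequence: str
    structure: str
    min_loop: int = DEFAULT_MIN_LOOP
    allow_gu: bool = True

    def __post_init__(self) -> None:
        self.sequence = _to_rna(self.sequence)
        if len(self.sequence) != len(self.structure):
            raise DataError("sequence and structure differ in length")
        pairs = _parse_pairs(self.structure)
        for i, j in pairs.items():
            if i < j:
                a, b = self.sequence[i], self.sequence[j]
                if GAP in (a, b):
                    raise DataError(f"gap column {i + 1} or {j + 1} is base-paired")
                if not _can_pair(a, b, self.allow_gu):
                    raise DataError(
                        f"non-canonical pair {a}{b} at positions {i + 1}/{j + 1}"
                    )
                if j - i - 1 < self.min_loop and not any(
                    k in pairs for k in range(i + 1, j)
                ):
                    raise DataError(
                        f"hairpin loop shorter than {self.min_loop} at {i + 1}/{j + 1}"
                    )
        for i, ch in enumerate(self.sequence):
            if (ch == GAP) != (self.structure[i] == GAP) and GAP in (
                ch,
                self.structure[i],
            ):
                raise DataError(f"gap mismatch between rows at column {i + 1}")

    def pair_map(self) -> dict[int, int]:
        return _parse_pairs(self.structure)

    @property
    def n_pairs(self) -> int:
        return self.structure.count("(")


# ---------------------------------------------------------------------------
# folding


def fold_hairpin(
    seq: str, min_loop: int = DEFAULT_MIN_LOOP, allow_gu: bool = True
) -> StructuredSequence:
    """Maximum-base-pair fold under canonical pairing and a minimum loop.

    Nussinov dynamic program; the traceback prefers closing a pair over
    leaving the 3' base unpaired whenever co-optimal, taking the 5'-most
    admissible partner, which keeps helices contiguous and makes the result
    deterministic.  T is accepted and read as U.
    """
    s = _to_rna(seq)
    n = len(s)
    if n < min_loop + 2:
        raise DataError(f"sequence too short to fold (need >= {min_loop + 2} nt)")
    dp = [[0] * n for _ in range(n)]
    for span in range(min_loop + 1, n):
        for i in range(n - span):
            j = i + span
            best = dp[i][j - 1]
            for k in range(i, j - min_loop):
                if _can_pair(s[k], s[j], allow_gu):
                    left = dp[i][k - 1] if k > i else 0
                    cand = left + dp[k + 1][j - 1] + 1
                    if cand > best:
                        best = cand
            dp[i][j] = best

    structure = ["."] * n
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if i >= j or dp[i][j] == 0:
            continue
        paired = False
        for k in range(i, j - min_loop):
            if _can_pair(s[k], s[j], allow_gu):
                left = dp[i][k - 1] if k > i else 0
                if left + dp[k + 1][j - 1] + 1 == dp[i][j]:
                    structure[k] = "("
                    structure[j] = ")"
                    if k > i:
                        stack.append((i, k - 1))
                    stack.append((k + 1, j - 1))
                    paired = True
                    break
        if not paired:
            stack.append((i, j - 1))
    return StructuredSequence("".join(s), "".join(structure), min_loop, allow_gu)


# ---------------------------------------------------------------------------
# stem-loop extraction


@dataclass
class StemLoopModel:
    """The terminal hairpin of a psbA 3' UTR region with its class call."""

    region_start: int  # 1-based inclusive on the input spacer
    region_end: int
    sequence: str  # RNA, region between the anchors
    structure: str
    stem_bp: int
    loop_seq: str
    loop_label: str
    stem_class: str  # "LONG" | "SHORT"
    archetype_closest: Optional[str] = None
    archetype_agrees: Optional[bool] = None


def _find_motif(seq: str, motif: str) -> list[int]:
    """0-based start positions where the IUPAC motif matches (DNA alphabet)."""
    hits = []
    m = len(motif)
    for i in range(len(seq) - m + 1):
        if all(compatible(seq[i + k], motif[k]) for k in range(m)):
            hits.append(i)
    return hits


def _terminal_helix(ss: StructuredSequence) -> tuple[int, tuple[int, int]]:
    """(stem_bp, closing pair of the apex) of the deepest hairpin helix.

    The helix is the chain of nested pairs enclosing a hairpin loop through
    which no multiloop branching occurs; interior loops and bulges are
    allowed.  The hairpin with the longest such helix wins (5'-most on ties).
    """
    pairs = ss.pair_map()
    opening = sorted(i for i, j in pairs.items() if i < j)
    if not opening:
        raise DataError("structure contains no base pairs")
    # nesting: parent of a pair = nearest enclosing pair
    children: dict[Optional[int], list[int]] = {None: []}
    stack: list[int] = []
    for i, ch in enumerate(ss.structure):
        if ch == "(":
            parent = stack[-1] if stack else None
            children.setdefault(parent, []).append(i)
            children.setdefault(i, [])
            stack.append(i)
        elif ch == ")":
            stack.pop()
    hairpins = [i for i in opening if not children[i]]
    parent_of: dict[int, Optional[int]] = {}
    for par, kids in children.items():
        for k in kids:
            parent_of[k] = par
    best_bp, best_close = 0, None
    for h in hairpins:
        bp, node = 1, h
        while True:
            par = parent_of.get(node)
            if par is None or len(children[par]) != 1:
                break
            bp += 1
            node = par
        if bp > best_bp or (bp == best_bp and (best_close is None or h < best_close)):
            best_bp, best_close = bp, h
    return best_bp, (best_close, pairs[best_close])


def extract_stem_loop(
    seq: Union[str, "object"],
    anchors: Optional[tuple[str, str]] = None,
    min_loop: int = DEFAULT_MIN_LOOP,
    short_max_bp: int = DEFAULT_SHORT_MAX_BP,
    allow_gu: bool = True,
    archetypes: Optional[dict[str, str]] = None,
) -> StemLoopModel:
    """Locate, fold and classify the stem-loop between two conserved anchors.

    Each anchor motif (IUPAC, DNA alphabet) must match exactly once; the
    region between them is folded with :func:`fold_hairpin` and the terminal
    helix measured.  class SHORT iff stem_bp <= ``short_max_bp``.  When
    archetype region sequences are supplied (keys "long"/"short") the closer
    one (edit distance) is recorded as supporting evidence and compared with
    the fold-based class; classification itself uses the fold.
    """
    raw = seq if isinstance(seq, str) else seq.sequence
    dna = raw.upper().replace("U", "T")
    if anchors is None:
        anchors = default_anchors()
    five, three = anchors
    hits5 = _find_motif(dna, five.upper())
    hits3 = _find_motif(dna, three.upper())
    for name, motif, hits in (("5'", five, hits5), ("3'", three, hits3)):
        if len(hits) != 1:
            raise AnchorError(
                f"{name} anchor {motif!r} matched {len(hits)} times at "
                f"{[h + 1 for h in hits]} (need exactly one)"
            )
    start = hits5[0] + len(five)
    end = hits3[0]
    if end <= start:
        raise AnchorError("anchors out of order or overlapping")
    region = dna[start:end]
    ss = fold_hairpin(region, min_loop=min_loop, allow_gu=allow_gu)
    stem_bp, (ci, cj) = _terminal_helix(ss)
    loop = ss.sequence[ci + 1 : cj]
    loop_unpaired = "".join(
        ch for k, ch in enumerate(loop, start=ci + 1) if ss.structure[k] == "."
    )
    cls = "SHORT" if stem_bp <= short_max_bp else "LONG"
    closest = agrees = None
    if archetypes:
        dists = {
            label: edlib.align(region, arch.upper().replace("U", "T"), mode="NW")[
                "editDistance"
            ]
            for label, arch in archetypes.items()
        }
        closest = min(sorted(dists), key=lambda k: dists[k])
        agrees = closest.upper() == cls
    return StemLoopModel(
        region_start=start + 1,
        region_end=end,
        sequence=ss.sequence,
        structure=ss.structure,
        stem_bp=stem_bp,
        loop_seq=loop_unpaired,
        loop_label=loop_unpaired,
        stem_class=cls,
        archetype_closest=closest,
        archetype_agrees=agrees,
    )


def default_anchors() -> tuple[str, str]:
    """The packaged synthetic psbA 3' UTR anchor motifs."""
    from .synthetic import PSBA_ANCHOR_5, PSBA_ANCHOR_3

    return PSBA_ANCHOR_5, PSBA_ANCHOR_3


# ---------------------------------------------------------------------------
# sequence+structure single-letter encoding

_UNPAIRED = {"A": "A", "C": "C", "G": "G", "U": "U"}
_OPENING = {"A": "E", "C": "F", "G": "I", "U": "K"}
_CLOSING = {"A": "L", "C": "M", "G": "P", "U": "Q"}

_DECODE = {}
for _base, _letter in _UNPAIRED.items():
    _DECODE[_letter] = (_base, ".")
for _base, _letter in _OPENING.items():
    _DECODE[_letter] = (_base, "(")
for _base, _letter in _CLOSING.items():
    _DECODE[_letter] = (_base, ")")

ALPHABET_12 = "".join(sorted(_DECODE))


def encode_structure_alphabet(ss: StructuredSequence) -> str:
    """Encode (base, pairing state) per position into the 12-letter alphabet.

    Unpaired bases keep their letter (A C G U); opening partners map to
    E F I K and closing partners to L M P Q respectively.  Gap columns encode
    as '-'.  The encoding is invertible (:func:`decode_structure_alphabet`).
    """
    out = []
    for base, state in zip(ss.sequence, ss.structure):
        if base == GAP:
            out.append(GAP)
        elif state == ".":
            out.append(_UNPAIRED[base])
        elif state == "(":
            out.append(_OPENING[base])
        else:
            out.append(_CLOSING[base])
    return "".join(out)


def decode_structure_alphabet(encoded: str) -> StructuredSequence:
    seq, struct = [], []
    for i, letter in enumerate(encoded, start=1):
        if letter == GAP:
            seq.append(GAP)
            struct.append(GAP)
            continue
        try:
            base, state = _DECODE[letter]
        except KeyError:
            raise DataError(f"invalid encoded letter {letter!r} at position {i}") from None
        seq.append(base)
        struct.append(state)
    return StructuredSequence("".join(seq), "".join(struct))


# ---------------------------------------------------------------------------
# compensatory base changes


@dataclass
class CbcCounts:
    cbc: int
    hemi_cbc: int
    shared_pairs: int


def count_cbc(a: StructuredSequence, b: StructuredSequence) -> CbcCounts:
    """Count compensatory and hemi-compensatory changes between two rows.

    Both rows must occupy the same gapped frame (equal length).  Over the
    column pairs base-paired in *both* structures: a CBC when the two rows
    differ at both partners, a hemi-CBC when they differ at exactly one.
    Symmetric in its arguments; count_cbc(a, a) is zero.
    """
    if len(a.sequence) != len(b.sequence):
        raise DataError("rows are not in a common frame (length mismatch)")
    pa = {(i, j) for i, j in a.pair_map().items() if i < j}
    pb = {(i, j) for i, j in b.pair_map().items() if i < j}
    shared = pa & pb
    cbc = hemi = 0
    for i, j in shared:
        d5 = a.sequence[i] != b.sequence[i]
        d3 = a.sequence[j] != b.sequence[j]
        if d5 and d3:
            cbc += 1
        elif d5 or d3:
            hemi += 1
    return CbcCounts(cbc, hemi, len(shared))
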