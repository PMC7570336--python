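"""Pharmacopoeial reference-barcode matching.

A reference barcode is a case-encoded IUPAC pattern in one or more segments:
lowercase letters are *essential* bases that a test sequence must match
exactly (ambiguity-code aware), uppercase letters contribute only to the
overall identity, which must reach the barcode's threshold (default 95%,
inclusive).  This mirrors a diagnostic botanical key: the essential bases are
the diagnostic distinguishers and the identity requirement contextualizes them
within the full barcode.

Matching aligns each segment semi-globally to the test sequence (free end
gaps on the test side, so the segment is located as an infix of the test),
tries both strands, and reports per-site evidence.  A gap at an essential
position is a failure; a gap or mismatch at a non-essential position counts
against identity only.

File format: FASTA-like text, one record per segment, all records sharing the
barcode name::

    >HperforatumITS segment=ITS1 threshold=0.95 species=Hypericum_perforatum
    TACCgTGAArCCTG...
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import edlib

from .errors import DataError, ParseError
from .iupac import COMPATIBLE_PAIRS, compatible, is_iupac, revcomp
from .seqio import SequenceRecord


@dataclass
class Segment:
    name: str
    pattern: str  # uppercase IUPAC
    essential_mask: list[bool]

    def __post_init__(self) -> None:
        if len(self.pattern) != len(self.essential_mask):
            raise DataError(f"segment {self.name!r}: mask/pattern length mismatch")


@dataclass
class ReferenceBarcode:
    name: str
    segments: list[Segment]
    identity_threshold: float = 0.95
    target_species: str = "unknown"

    def __post_init__(self) -> None:
        if not 0 < self.identity_threshold <= 1:
            raise DataError("identity_threshold must lie in (0, 1]")
        if not any(any(s.essential_mask) for s in self.segments):
            raise DataError("reference barcode must define at least one essential base")

    @classmethod
    def from_case_patterns(
        cls,
        name: str,
        patterns: dict[str, str],
        identity_threshold: float = 0.95,
        target_species: str = "unknown",
    ) -> "ReferenceBarcode":
        """Build from case-encoded patterns: lowercase = essential."""
        segments = []
        for seg_name, pat in patterns.items():
            _validate_pattern(pat, f"{name}/{seg_name}")
            segments.append(
                Segment(seg_name, pat.upper(), [c.islower() for c in pat])
            )
        return cls(name, segments, identity_threshold, target_species)


@dataclass
class EssentialFailure:
    position: int  # 1-based within segment pattern
    expected: str  # IUPAC code
    observed: str  # base, or "-" for a gap


@dataclass
class SegmentMatch:
    segment: str
    identity: float
    essential_failures: list[EssentialFailure]
    aligned_span: tuple[int, int]  # 1-based inclusive on the (oriented) test


@dataclass
class MatchResult:
    passed: bool
    per_segment: list[SegmentMatch]
    overall_identity: float
    identity_threshold: float
    strand: str = "+"
    combine: str = "length_weighted"

    @property
    def essential_failures(self) -> list[EssentialFailure]:
        return [f for seg in self.per_segment for f in seg.essential_failures]


def _validate_pattern(pattern: str, context: str) -> None:
    for i, ch in enumerate(pattern, start=1):
        if not is_iupac(ch.upper()):
            raise ParseError(f"{context}: non-IUPAC character {ch!r} at position {i}")


def parse_reference_barcode(path: Union[str, Path]) -> ReferenceBarcode:
    """Parse the case-encoded reference-barcode file (see module docstring)."""
    path = Path(path)
    name = None
    species = "unknown"
    threshold = 0.95
    patterns: dict[str, str] = {}
    header: Optional[str] = None
    body: list[str] = []

    def flush():
        nonlocal header, body
        if header is None:
            return
        tokens = header[1:].split()
        if not tokens:
            raise ParseError(f"{path}: empty reference header")
        rec_name = tokens[0]
        attrs = dict(t.split("=", 1) for t in tokens[1:] if "=" in t)
        seg = attrs.get("segment", f"segment{len(patterns) + 1}")
        pattern = "".join(body)
        if not pattern:
            raise ParseError(f"{path}: segment {seg!r} has no pattern")
        _validate_pattern(pattern, f"{path}:{seg}")
        nonlocal name, species, threshold
        if name is None:
            name = rec_name
            species = attrs.get("species", "unknown").replace("_", " ")
            if "threshold" in attrs:
                threshold = float(attrs["threshold"])
        elif rec_name != name:
            raise ParseError(f"{path}: segments belong to different barcodes "
                             f"({name!r} vs {rec_name!r})")
        if seg in patterns:
            raise ParseError(f"{path}: duplicate segment {seg!r}")
        patterns[seg] = pattern
        header, body = None, []

    for line in path.read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            flush()
            header = line
        else:
            body.append(line)
    flush()
    if name is None:
        raise ParseError(f"{path}: no reference records found")
    return ReferenceBarcode.from_case_patterns(name, patterns, threshold, species)


def write_reference_barcode(ref: ReferenceBarcode, path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        for seg in ref.segments:
            fh.write(
                f">{ref.name} segment={seg.name} threshold={ref.identity_threshold}"
                f" species={ref.target_species.replace(' ', '_')}\n"
            )
            cased = "".join(
                c.lower() if m else c for c, m in zip(seg.pattern, seg.essential_mask)
            )
            for i in range(0, len(cased), 70):
                fh.write(cased[i : i + 70] + "\n")


# ---------------------------------------------------------------------------
# alignment


@dataclass
class PatternAlignment:
    """Semi-global alignment of a pattern onto a test sequence.

    ``pairs`` holds one entry per alignment column: (pattern_pos, test_pos),
    either side None for a gap; positions 0-based.  The pattern is aligned as
    an infix of the test (free end gaps on the test side) at unit edit cost
    with IUPAC-compatible characters counting as matches; edlib's leftmost
    deterministic traceback is used.
    """

    pairs: list[tuple[Optional[int], Optional[int]]]
    span: tuple[int, int]  # 0-based inclusive on the test
    edit_distance: int


def align_to_reference(test: str, pattern: str) -> PatternAlignment:
    if not test:
        raise DataError("empty test sequence")
    if not pattern:
        raise DataError("empty pattern")
    res = edlib.align(
        pattern.upper(),
        test.upper(),
        mode="HW",
        task="path",
        additionalEqualities=COMPATIBLE_PAIRS,
    )
    start, end = res["locations"][0]
    if start is None:  # degenerate: empty-span location
        start = 0
    pairs: list[tuple[Optional[int], Optional[int]]] = []
    p, t = 0, start
    num = ""
    for ch in res["cigar"]:
        if ch.isdigit():
            num += ch
            continue
        n = int(num)
        num = ""
        if ch in "=X":
            for _ in range(n):
                pairs.append((p, t))
                p += 1
                t += 1
        elif ch == "I":  # consumes pattern only: deletion in the test
            for _ in range(n):
                pairs.append((p, None))
                p += 1
        elif ch == "D":  # consumes test only: insertion in the test
            for _ in range(n):
                pairs.append((None, t))
                t += 1
        else:
            raise DataError(f"unexpected cigar op {ch!r}")
    return PatternAlignment(pairs, (start, end), res["editDistance"])


# ---------------------------------------------------------------------------
# matching


def _match_segment(test: str, seg: Segment) -> SegmentMatch:
    aln = align_to_reference(test, seg.pattern)
    observed: dict[int, Optional[str]] = {}
    for p, t in aln.pairs:
        if p is not None:
            observed[p] = test[t] if t is not None else None
    failures = []
    n_compatible = 0
    for p, code in enumerate(seg.pattern):
        base = observed.get(p)
        ok = base is not None and compatible(base, code)
        if ok:
            n_compatible += 1
        elif seg.essential_mask[p]:
            failures.append(EssentialFailure(p + 1, code, base or "-"))
    identity = n_compatible / len(seg.pattern)
    return SegmentMatch(seg.name, identity, failures, (aln.span[0] + 1, aln.span[1] + 1))


def match_reference(
    test: Union[SequenceRecord, str],
    ref: ReferenceBarcode,
    combine: str = "length_weighted",
    try_both_strands: bool = True,
) -> MatchResult:
    """Match a test sequence against a reference barcode.

    Per segment the identity is compatible columns / pattern length; the
    overall identity combines segments by length-weighted mean (default) or
    per-segment minimum.  ``passed`` iff no essential failure in any segment
    and overall identity >= threshold (inclusive).  Both strands are tried and
    the better-scoring orientation reported (ties favour the forward strand).
    Failures are results, not errors.
    """
    if combine not in {"length_weighted", "min"}:
        raise ValueError(f"unknown combine mode {combine!r}")
    seq = test.sequence if isinstance(test, SequenceRecord) else test
    seq = seq.upper().replace("U", "T")
    if not seq:
        raise DataError("empty test sequence")

    def evaluate(oriented: str, strand: str) -> MatchResult:
        seg_matches = [_match_segment(oriented, s) for s in ref.segments]
        lengths = [len(s.pattern) for s in ref.segments]
        if combine == "length_weighted":
            overall = sum(m.identity * l for m, l in zip(seg_matches, lengths)) / sum(lengths)
        else:
            overall = min(m.identity for m in seg_matches)
        passed = (
            not any(m.essential_failures for m in seg_matches)
            and overall >= ref.identity_threshold
        )
        return MatchResult(passed, seg_matches, overall, ref.identity_threshold,
                           strand, combine)

    fwd = evaluate(seq, "+")
    if not try_both_strands:
        return fwd
    rev = evaluate(revcomp(seq), "-")
    return max(fwd, rev, key=lambda m: (m.passed, m.overall_identity, m.strand == "+"))
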