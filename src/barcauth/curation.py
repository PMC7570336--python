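"""Curated panel database construction.

Implements the quality-control steps used to turn a raw pile of repository
accessions into a small panel database suitable for defining a reference
barcode: rejection of unreliable singleton accessions, IUPAC consensus /
subtype construction for intraspecific variants, detection of sites that
discriminate the target species from the adulterant panel, and scanning for
variability hotspots.

Identity measure
----------------
The package-wide pairwise identity between two unaligned sequences is
matches / aligned columns (gap-gap pairs excluded), computed on a global
alignment scored match +1, mismatch 0, gap -1.  Rows that are already in a
common alignment are compared column-wise with the same convention.  Outlier
screening against remote BLAST distance trees is replaced by this local
identity filter using the same 95% criterion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
from Bio.Align import PairwiseAligner

from .errors import DataError
from .iupac import GAP, compatible, expand, minimal_code
from .seqio import MultipleAlignment, SequenceRecord

_MESEGUER_CLADES = {"B", "C", "D", "E", "unknown"}
_PANEL_FLAGS = ("REL", "MPNS", "CULT", "ADULT")


@dataclass
class PanelSpecies:
    """One species of the restricted adulterant panel, with selection flags.

    Flags: REL close relative of the target (same Section), MPNS listed with a
    medicinal-plant reference, CULT ornamental/cultivated, ADULT reported
    adulterant of commercial material.
    """

    name: str
    attribution: str = ""
    section: str = ""
    robson_clade: str = "unknown"
    meseguer_clade: str = "unknown"
    flags: frozenset = frozenset()

    def __post_init__(self) -> None:
        if self.meseguer_clade not in _MESEGUER_CLADES:
            raise DataError(f"{self.name}: unknown clade {self.meseguer_clade!r}")
        bad = set(self.flags) - set(_PANEL_FLAGS)
        if bad:
            raise DataError(f"{self.name}: unknown flags {sorted(bad)}")


def read_panel_table(path: Union[str, Path]) -> list[PanelSpecies]:
    """Read the panel metadata TSV (name, attribution, section, clades, flags)."""
    species = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        if line.startswith("name\t"):
            continue
        fields = line.split("\t")
        name, attribution, section, robson, meseguer = fields[:5]
        flagset = frozenset(
            flag for flag, tok in zip(_PANEL_FLAGS, fields[5:9]) if tok.strip() == "Y"
        )
        species.append(
            PanelSpecies(name, attribution, section, robson or "unknown",
                         meseguer or "unknown", flagset)
        )
    names = [s.name for s in species]
    if len(set(names)) != len(names):
        raise DataError("duplicate species in panel table")
    return species


@dataclass
class SubtypeConsensus:
    """An artificial consensus sequence summarizing one intraspecific cluster."""

    species: str
    subtype_label: str
    consensus: str
    member_ids: list[str]
    polymorphic_columns: list[int]
    dropped_columns: list[int] = field(default_factory=list)


@dataclass
class Hotspot:
    start: int  # 1-based inclusive
    end: int
    score: float
    flagged: bool = False


@dataclass
class SiteReport:
    """Discriminating-site survey of an alignment against a target species."""

    target: str
    unique_sites: list[int]
    pairwise_sites: dict[tuple[str, str], list[int]]
    hotspot_windows: list[Hotspot] = field(default_factory=list)


# ---------------------------------------------------------------------------
# identity


def _aligner(match: float = 1.0, mismatch: float = 0.0, gap: float = -1.0) -> PairwiseAligner:
    a = PairwiseAligner()
    a.mode = "global"
    a.match_score = match
    a.mismatch_score = mismatch
    a.open_gap_score = gap
    a.extend_gap_score = gap
    return a


def pairwise_identity(a: str, b: str) -> float:
    """Global-alignment identity between two unaligned sequences."""
    aln = _aligner().align(a.upper(), b.upper())[0]
    ra, rb = str(aln[0]), str(aln[1])
    return aligned_identity(ra, rb)


def aligned_identity(row_a: str, row_b: str) -> float:
    """Identity between two equal-length gapped rows (gap-gap columns excluded)."""
    if len(row_a) != len(row_b):
        raise DataError("rows differ in length")
    cols = matches = 0
    for x, y in zip(row_a.upper(), row_b.upper()):
        if x == GAP and y == GAP:
            continue
        cols += 1
        if x == y and x != GAP:
            matches += 1
    return matches / cols if cols else 1.0


def _identity_matrix(records: Sequence[SequenceRecord], prealigned: bool) -> np.ndarray:
    n = len(records)
    m = np.ones((n, n))
    fn = aligned_identity if prealigned else pairwise_identity
    for i in range(n):
        for j in range(i + 1, n):
            m[i, j] = m[j, i] = fn(records[i].sequence, records[j].sequence)
    return m


def _single_linkage(m: np.ndarray, threshold: float) -> list[list[int]]:
    n = m.shape[0]
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            if m[i, j] >= threshold:
                parent[find(i)] = find(j)
    clusters: dict[int, list[int]] = {}
    for i in range(n):
        clusters.setdefault(find(i), []).append(i)
    return list(clusters.values())


# ---------------------------------------------------------------------------
# operations


def filter_outliers(
    records: Sequence[SequenceRecord],
    identity_threshold: float = 0.95,
    prealigned: bool = False,
) -> tuple[list[SequenceRecord], list[SequenceRecord]]:
    """Discard unreliable singleton accessions from a conspecific set.

    Records are clustered by single linkage at ``identity_threshold``; a record
    is discarded iff it forms a singleton cluster (its identity to every other
    record is below threshold) while at least one multi-member cluster exists.
    When no such core group exists nothing is discarded — two mutually distant
    sequences are evidence of variation, not of an outlier.  Idempotent.
    """
    if not records:
        raise DataError("filter_outliers: empty input")
    if len(records) == 1:
        return list(records), []
    m = _identity_matrix(records, prealigned)
    clusters = _single_linkage(m, identity_threshold)
    if not any(len(c) > 1 for c in clusters):
        return list(records), []
    kept_idx = sorted(i for c in clusters if len(c) > 1 for i in c)
    dropped_idx = sorted(i for c in clusters if len(c) == 1 for i in c)
    return [records[i] for i in kept_idx], [records[i] for i in dropped_idx]


def build_consensus(
    rows: Sequence[Union[SequenceRecord, str]],
    ambiguity_floor: float = 0.25,
    species: str = "unknown",
    subtype_label: str = "I",
) -> SubtypeConsensus:
    """IUPAC consensus of aligned conspecific rows.

    Per column: gaps are ignored in the frequency counts unless more than half
    the rows are gapped, in which case the column is dropped (its 1-based
    coordinate recorded in ``dropped_columns``).  Ambiguity codes in the input
    contribute fractionally to each base they denote.  If one base reaches
    frequency >= 1 - ambiguity_floor it is emitted alone; otherwise the minimal
    IUPAC code covering all bases at frequency >= ambiguity_floor (falling back
    to the modal base set if none reaches the floor).
    """
    seqs = [r.sequence if isinstance(r, SequenceRecord) else r for r in rows]
    ids = [r.id if isinstance(r, SequenceRecord) else f"row{i+1}" for i, r in enumerate(rows)]
    if not seqs:
        raise DataError("build_consensus: empty alignment")
    if len({len(s) for s in seqs}) != 1:
        raise DataError("build_consensus: rows differ in length")
    out = []
    polymorphic: list[int] = []
    dropped: list[int] = []
    for col in range(len(seqs[0])):
        symbols = [s[col].upper() for s in seqs]
        n_gap = symbols.count(GAP)
        if n_gap * 2 > len(symbols):
            dropped.append(col + 1)
            continue
        bases = [s for s in symbols if s != GAP]
        freq: dict[str, float] = {}
        for sym in bases:
            exp = expand(sym)
            for b in exp:
                freq[b] = freq.get(b, 0.0) + 1.0 / len(exp)
        total = len(bases)
        for b in freq:
            freq[b] /= total
        top = max(freq.values())
        top_bases = sorted(b for b, f in freq.items() if f == top)
        if top >= 1.0 - ambiguity_floor:
            out.append(top_bases[0])
        else:
            over = sorted(b for b, f in freq.items() if f >= ambiguity_floor)
            out.append(minimal_code(over or top_bases))
        if len(set(bases)) > 1:
            polymorphic.append(col + 1)
    return SubtypeConsensus(species, subtype_label, "".join(out), ids, polymorphic, dropped)


_ROMAN = ["I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X"]


def _roman(n: int) -> str:
    return _ROMAN[n - 1] if n <= len(_ROMAN) else str(n)


def detect_subtypes(
    records: Sequence[SequenceRecord],
    link_identity: float = 0.995,
    ambiguity_floor: float = 0.25,
    species: Optional[str] = None,
) -> list[SubtypeConsensus]:
    """Cluster aligned conspecific rows into subtypes by single linkage.

    Rows whose pairwise identity reaches ``link_identity`` are linked; each
    cluster yields one :class:`SubtypeConsensus` via :func:`build_consensus`.
    Clusters are ordered by (size desc, consensus lexicographic, member ids),
    so labels are invariant to the input row order.
    """
    if not records:
        raise DataError("detect_subtypes: empty input")
    sp = species or records[0].species
    m = _identity_matrix(records, prealigned=True)
    clusters = _single_linkage(m, link_identity)
    built = []
    for idx in clusters:
        members = [records[i] for i in sorted(idx, key=lambda i: records[i].id)]
        cons = build_consensus(members, ambiguity_floor, species=sp)
        built.append(cons)
    built.sort(key=lambda c: (-len(c.member_ids), c.consensus, c.member_ids))
    for i, cons in enumerate(built, start=1):
        cons.subtype_label = _roman(i)
    return built


def find_discriminating_sites(
    aln: MultipleAlignment,
    target: str,
    subtypes_as_target_rows: bool = True,
    exclude_gap_columns: bool = True,
) -> SiteReport:
    """Locate alignment columns that discriminate species.

    ``unique_sites``: columns where all target rows are mutually compatible
    (their IUPAC expansions share a state) and every non-target row is
    incompatible with that shared state.  ``pairwise_sites[(A, B)]``: columns
    where every row of A is incompatible with every row of B.  Gap-containing
    columns are excluded by default.  With ``subtypes_as_target_rows`` False
    the target rows are first collapsed to a single zero-floor consensus.
    """
    by_species: dict[str, list[str]] = {}
    for r in aln.records:
        by_species.setdefault(r.species, []).append(r.sequence)
    if target not in by_species:
        raise DataError(f"target species {target!r} absent from alignment")
    if len(by_species) < 2:
        raise DataError("alignment must contain at least one non-target species")
    if not subtypes_as_target_rows:
        cons = build_consensus(by_species[target], ambiguity_floor=0.0, species=target)
        by_species = dict(by_species)
        by_species[target] = [cons.consensus]

    n_cols = aln.column_count
    usable = []
    for col in range(n_cols):
        syms = {rows[col] for sp in by_species.values() for rows in (s for s in sp)}
        if exclude_gap_columns and GAP in syms:
            continue
        usable.append(col)

    unique: list[int] = []
    for col in usable:
        shared = frozenset("ACGT")
        ok = True
        for row in by_species[target]:
            shared = shared & expand(row[col])
            if not shared:
                ok = False
                break
        if not ok:
            continue
        if all(
            not (expand(row[col]) & shared)
            for sp, rows in by_species.items()
            if sp != target
            for row in rows
        ):
            unique.append(col + 1)

    pairwise: dict[tuple[str, str], list[int]] = {}
    names = sorted(by_species)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            cols = [
                col + 1
                for col in usable
                if all(
                    not compatible(ra[col], rb[col])
                    for ra in by_species[a]
                    for rb in by_species[b]
                )
            ]
            if cols:
                pairwise[(a, b)] = cols
    return SiteReport(target, unique, pairwise)


def scan_hotspots(
    aln: MultipleAlignment,
    window: int,
    step: int = 1,
    flag_quantile: float = 0.9,
) -> list[Hotspot]:
    """Sliding-window variability scan.

    A column is variable when it holds more than one distinct non-gap symbol.
    Window score = variable columns / window; windows whose score reaches the
    ``flag_quantile`` of all (positive) scores are flagged.
    """
    if window <= 0:
        raise DataError("window must be positive")
    if window > aln.column_count:
        raise DataError(
            f"window {window} exceeds alignment length {aln.column_count}"
        )
    if step <= 0:
        raise DataError("step must be positive")
    variable = np.zeros(aln.column_count, dtype=bool)
    for col in range(aln.column_count):
        syms = {r.sequence[col] for r in aln.records} - {GAP}
        variable[col] = len(syms) > 1
    scores = []
    starts = list(range(0, aln.column_count - window + 1, step))
    for s in starts:
        scores.append(variable[s : s + window].sum() / window)
    scores = np.asarray(scores)
    cut = np.quantile(scores, flag_quantile) if len(scores) else 0.0
    return [
        Hotspot(s + 1, s + window, float(sc), bool(sc > 0 and sc >= cut))
        for s, sc in zip(starts, scores)
    ]
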