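"""Reading, writing and normalization of the external formats.

Sequence formats (FASTA, aligned FASTA, Clustal) are parsed with Biopython;
this module adds the normalization and invariant checks the computational
modules rely on: uppercase sequences, U->T for DNA work, unique record ids,
rectangular alignments, and a restricted IUPAC alphabet (gaps only inside
alignments).

Character tables are tab-separated with the documented header
``sample_id  nominal_species  its_result  its_closest  stem_class  rbcl_label``
using the token vocabulary of the St John's Wort case study: its_result
Yes/No/blank, stem L/S/Sa (lowercase s tolerated, noted), rbcL labels such as
1, 1p, 1(p), 1-2, 2.  A "No" ITS result means the sequence was obtained but
failed the reference match; when ``its_closest`` names a species the failed
sequence matched an adulterant reference (MATCH_ADULTERANT), otherwise it is a
plain FAIL.

All coordinates in this package are 1-based inclusive, and every report header
says so.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Optional, Union

from Bio import AlignIO, SeqIO

from .errors import DataError, ParseError
from .iupac import GAP, is_iupac

REGIONS = {"ITS", "ITS1", "ITS2", "rbcL", "psbA-trnH", "matK", "other"}

COORDINATE_NOTE = "coordinates: 1-based inclusive"


@dataclass
class SequenceRecord:
    """A labelled barcode sequence.

    ``species`` is a binomial or "unknown"; ``region`` one of REGIONS;
    ``source`` free-text provenance (voucher / accession).
    """

    id: str
    sequence: str
    species: str = "unknown"
    region: str = "other"
    source: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise DataError(f"record {self.id!r}: empty sequence")
        if self.region not in REGIONS:
            self.region = "other"

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class MultipleAlignment:
    """Equal-length gapped rows sharing a named coordinate system."""

    records: list[SequenceRecord]
    coordinate_name: str = "unnamed"

    def __post_init__(self) -> None:
        if not self.records:
            raise DataError("alignment must contain at least one row")
        lengths = {len(r.sequence) for r in self.records}
        if len(lengths) != 1:
            raise DataError(f"ragged alignment: row lengths {sorted(lengths)}")
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise DataError(f"duplicate record ids in alignment: {dupes}")

    @property
    def column_count(self) -> int:
        return len(self.records[0].sequence)

    def column(self, pos: int) -> str:
        """Column *pos* (1-based) as a string, one character per row."""
        if not 1 <= pos <= self.column_count:
            raise IndexError(f"column {pos} outside 1..{self.column_count}")
        return "".join(r.sequence[pos - 1] for r in self.records)

    def rows_for_species(self, species: str) -> list[SequenceRecord]:
        return [r for r in self.records if r.species == species]


class ItsResult(Enum):
    PASS = "PASS"
    MATCH_ADULTERANT = "MATCH_ADULTERANT"
    FAIL = "FAIL"
    NO_DATA = "NO_DATA"


class StemClass(Enum):
    LONG = "LONG"
    SHORT = "SHORT"
    SHORT_AAA = "SHORT_AAA"
    NO_DATA = "NO_DATA"


@dataclass
class CharacterRow:
    sample_id: str
    nominal_species: str
    its_result: ItsResult
    its_closest: Optional[str] = None
    stem_class: StemClass = StemClass.NO_DATA
    rbcl_label: Optional[str] = None
    note: str = ""


@dataclass
class SampleCharacterTable:
    rows: list[CharacterRow] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r.sample_id for r in self.rows]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise DataError(f"duplicate sample ids: {dupes}")

    def __len__(self) -> int:
        return len(self.rows)

    def __iter__(self):
        return iter(self.rows)


# ---------------------------------------------------------------------------
# sequence I/O


def _meta_from_description(description: str) -> dict[str, str]:
    meta = {}
    for token in description.split()[1:]:
        if "=" in token:
            k, v = token.split("=", 1)
            meta[k] = v.replace("_", " ")
    return meta


def _normalize(seq: str, to_dna: bool, allow_gap: bool, rec_id: str) -> str:
    out = seq.upper()
    if to_dna:
        out = out.replace("U", "T")
    for i, ch in enumerate(out, start=1):
        if ch == GAP:
            if allow_gap:
                continue
            raise ParseError(
                f"record {rec_id!r}: gap character at position {i} outside an alignment"
            )
        if ch == "U" and not to_dna:
            continue
        if not is_iupac(ch):
            raise ParseError(f"record {rec_id!r}: invalid character {ch!r} at position {i}")
    return out


def _check_fasta_shape(path: Path) -> None:
    """Line-level sanity check so parse errors can name a line number."""
    seen_header = False
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith(">"):
            seen_header = True
            if len(line) == 1:
                raise ParseError(f"{path}:{lineno}: empty FASTA header")
        elif not seen_header:
            raise ParseError(f"{path}:{lineno}: sequence data before any FASTA header")


def read_sequences(
    path: Union[str, Path],
    fmt: str = "fasta",
    to_dna: bool = True,
    coordinate_name: Optional[str] = None,
) -> Union[list[SequenceRecord], MultipleAlignment]:
    """Read ``fasta`` (-> list of records), ``aligned_fasta`` or ``clustal``
    (-> MultipleAlignment).

    Records are normalized to uppercase with U->T when ``to_dna`` (gap columns
    preserved in alignment mode).  Malformed input raises :class:`ParseError`;
    duplicate ids and ragged alignments raise :class:`DataError`.
    """
    path = Path(path)
    if fmt not in {"fasta", "aligned_fasta", "clustal"}:
        raise ValueError(f"unknown format {fmt!r}")
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    aligned = fmt in {"aligned_fasta", "clustal"}
    if fmt != "clustal":
        _check_fasta_shape(path)
        try:
            raw = list(SeqIO.parse(str(path), "fasta"))
        except ValueError as exc:
            raise ParseError(f"{path}: {exc}") from exc
    else:
        try:
            raw = list(AlignIO.read(str(path), "clustal"))
        except ValueError as exc:
            raise ParseError(f"{path}: {exc}") from exc
    if not raw:
        raise ParseError(f"{path}: no records")

    records = []
    for rec in raw:
        meta = _meta_from_description(rec.description)
        records.append(
            SequenceRecord(
                id=rec.id,
                sequence=_normalize(str(rec.seq), to_dna, aligned, rec.id),
                species=meta.get("species", "unknown"),
                region=meta.get("region", "other"),
                source=meta.get("source", ""),
            )
        )
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise DataError(f"{path}: duplicate record ids {dupes}")
    if aligned:
        return MultipleAlignment(records, coordinate_name or path.stem)
    return records


def write_sequences(
    records: Union[Iterable[SequenceRecord], MultipleAlignment],
    path: Union[str, Path],
) -> None:
    """Write records (or alignment rows) as FASTA with key=value metadata."""
    if isinstance(records, MultipleAlignment):
        records = records.records
    with open(path, "w") as fh:
        for rec in records:
            meta = (
                f"species={rec.species.replace(' ', '_')}"
                f" region={rec.region}"
            )
            if rec.source:
                meta += f" source={rec.source.replace(' ', '_')}"
            fh.write(f">{rec.id} {meta}\n")
            for i in range(0, len(rec.sequence), 70):
                fh.write(rec.sequence[i : i + 70] + "\n")


# ---------------------------------------------------------------------------
# character tables

_CHAR_COLUMNS = [
    "sample_id",
    "nominal_species",
    "its_result",
    "its_closest",
    "stem_class",
    "rbcl_label",
]

_STEM_TOKENS = {
    "L": StemClass.LONG,
    "S": StemClass.SHORT,
    "Sa": StemClass.SHORT_AAA,
}


def _parse_character_row(rownum: int, row: dict[str, str]) -> CharacterRow:
    its_token = (row.get("its_result") or "").strip()
    closest = (row.get("its_closest") or "").strip() or None
    if its_token == "Yes":
        its = ItsResult.PASS
    elif its_token == "No":
        its = ItsResult.MATCH_ADULTERANT if closest else ItsResult.FAIL
    elif its_token == "":
        its = ItsResult.NO_DATA
    else:
        raise ParseError(f"row {rownum}: unknown its_result token {its_token!r}")

    stem_token = (row.get("stem_class") or "").strip()
    note = ""
    if stem_token == "":
        stem = StemClass.NO_DATA
    elif stem_token in _STEM_TOKENS:
        stem = _STEM_TOKENS[stem_token]
    elif stem_token == "s":
        # undefined lowercase variant observed in the field data; read as SHORT
        stem = StemClass.SHORT
        note = "stem token 's' normalized to SHORT"
    else:
        raise ParseError(f"row {rownum}: unknown stem_class token {stem_token!r}")

    rbcl = (row.get("rbcl_label") or "").strip().replace("–", "-") or None
    return CharacterRow(
        sample_id=row["sample_id"].strip(),
        nominal_species=row["nominal_species"].strip(),
        its_result=its,
        its_closest=closest,
        stem_class=stem,
        rbcl_label=rbcl,
        note=note,
    )


def read_character_table(path: Union[str, Path]) -> SampleCharacterTable:
    """Read a per-sample character TSV (see module docstring for the dialect)."""
    path = Path(path)
    text = path.read_text()
    return parse_character_table(text, source=str(path))


def parse_character_table(text: str, source: str = "<string>") -> SampleCharacterTable:
    lines = [l for l in text.splitlines() if not l.startswith("#")]
    reader = csv.DictReader(io.StringIO("\n".join(lines)), delimiter="\t")
    if reader.fieldnames is None:
        raise ParseError(f"{source}: empty table")
    missing = [c for c in _CHAR_COLUMNS if c not in reader.fieldnames and c != "its_closest"]
    if missing:
        raise ParseError(f"{source}: missing required columns {missing}")
    rows = []
    for rownum, row in enumerate(reader, start=2):
        try:
            rows.append(_parse_character_row(rownum, row))
        except ParseError as exc:
            raise ParseError(f"{source}: {exc}") from None
    return SampleCharacterTable(rows)


def write_character_table(table: SampleCharacterTable, path: Union[str, Path]) -> None:
    _TOKEN_FOR_STEM = {
        StemClass.LONG: "L",
        StemClass.SHORT: "S",
        StemClass.SHORT_AAA: "Sa",
        StemClass.NO_DATA: "",
    }
    with open(path, "w") as fh:
        fh.write("\t".join(_CHAR_COLUMNS) + "\n")
        for r in table:
            its = {
                ItsResult.PASS: "Yes",
                ItsResult.MATCH_ADULTERANT: "No",
                ItsResult.FAIL: "No",
                ItsResult.NO_DATA: "",
            }[r.its_result]
            fh.write(
                "\t".join(
                    [
                        r.sample_id,
                        r.nominal_species,
                        its,
                        r.its_closest or "",
                        _TOKEN_FOR_STEM[r.stem_class],
                        r.rbcl_label or "",
                    ]
                )
                + "\n"
            )


def write_verdict_report(
    table: SampleCharacterTable,
    verdicts: dict[str, "object"],
    path: Union[str, Path],
    header_note: str = "",
) -> None:
    """Write verdicts as a deterministic TSV with a per-code tally block.

    ``verdicts`` maps sample_id -> Verdict (see :mod:`barcauth.verdict`); every
    row must have one.  Re-running on identical input is byte-identical.
    """
    missing = [r.sample_id for r in table if r.sample_id not in verdicts]
    if missing:
        raise DataError(f"verdict missing for samples: {missing}")
    lines = [f"# barcauth verdict report | {COORDINATE_NOTE}"]
    if header_note:
        lines.append(f"# {header_note}")
    lines.append(
        "sample_id\tnominal_species\tits_result\tstem_class\trbcl_label\tcode\trationale"
    )
    tally: dict[str, int] = {}
    for r in table:
        v = verdicts[r.sample_id]
        tally[v.code] = tally.get(v.code, 0) + 1
        lines.append(
            "\t".join(
                [
                    r.sample_id,
                    r.nominal_species,
                    r.its_result.value,
                    r.stem_class.value,
                    r.rbcl_label or "",
                    v.code,
                    "; ".join(v.rationale),
                ]
            )
        )
    lines.append("# tally: " + ", ".join(f"{c}={n}" for c, n in sorted(tally.items())))
    Path(path).write_text("\n".join(lines) + "\n")
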