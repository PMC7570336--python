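"""Chloroplast haplotype assignment from a small coordinate-mapped SNP key.

The rbcL barcode in *Hypericum* carries too little variation to discriminate
species directly, but a handful of coinherited SNPs split the panel into two
core haplotypes (type 1: derived states at the 5' sites; type 2: derived
states at the 3' sites), with an intermediate all-consensus pattern designated
1-2 and two *H. perforatum*-related marker SNPs (positions 66 and 263) layered
on top: a type-1 call with both markers is displayed "1p", with one marker
"1(p)".  Marker SNPs are evaluated independently of the core type so that
e.g. maculatum samples carrying the perforatum markers remain representable.

Core patterns are evaluated in priority order (type 1 before type 2); a state
vector matching no pattern and not all-consensus is called "novel", and a
missing state at a core site degrades the call to "insufficient data".
Coordinates are 1-based in the key's named coordinate system.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional, Union

import edlib

from .errors import DataError, ParseError
from .seqio import SequenceRecord

_VALID_BASES = set("ACGT")


@dataclass
class CoreType:
    label: str
    required_states: dict[int, str]
    priority: int


@dataclass
class HaplotypeKey:
    coordinate_name: str
    positions: list[int]
    consensus: dict[int, str]
    core_types: list[CoreType]
    marker_snps: dict[int, str]
    marker_label: str = "p"
    intermediate_label: str = "1-2"

    def __post_init__(self) -> None:
        if self.positions != sorted(self.positions) or len(set(self.positions)) != len(
            self.positions
        ):
            raise DataError("key positions must be strictly increasing")
        listed = set(self.positions)
        for ct in self.core_types:
            if not set(ct.required_states) <= listed:
                raise DataError(f"core type {ct.label!r} keyed on unlisted positions")
        if not set(self.marker_snps) <= listed:
            raise DataError("marker SNPs keyed on unlisted positions")
        prios = [ct.priority for ct in self.core_types]
        if len(set(prios)) != len(prios):
            raise DataError("core type priorities must be unique")

    @property
    def core_sites(self) -> list[int]:
        """Key positions that are not marker SNPs (the core haplotype sites)."""
        return [p for p in self.positions if p not in self.marker_snps]


@dataclass
class HaplotypeCall:
    core_label: str  # "1", "2", "1-2", "novel", or "insufficient"
    marker_count: int
    display_label: str
    states: dict[int, Optional[str]] = field(default_factory=dict)


def load_key(path: Union[str, Path]) -> HaplotypeKey:
    """Load a haplotype key from its JSON config."""
    try:
        raw = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    return _key_from_dict(raw)


def _key_from_dict(raw: dict) -> HaplotypeKey:
    return HaplotypeKey(
        coordinate_name=raw["coordinate_name"],
        positions=[int(p) for p in raw["positions"]],
        consensus={int(p): b for p, b in raw["consensus"].items()},
        core_types=[
            CoreType(ct["label"], {int(p): b for p, b in ct["required_states"].items()},
                     int(ct["priority"]))
            for ct in raw["core_types"]
        ],
        marker_snps={int(p): b for p, b in raw["marker_snps"].items()},
        marker_label=raw.get("marker_label", "p"),
        intermediate_label=raw.get("intermediate_label", "1-2"),
    )


def default_rbcl_key() -> HaplotypeKey:
    """The packaged rbcLa panel haplotype key (coordinate system rbcLa-panel-v1)."""
    text = resources.files("barcauth.data").joinpath("rbcl_key.json").read_text()
    return _key_from_dict(json.loads(text))


def extract_states(
    sample: Union[SequenceRecord, str],
    key: HaplotypeKey,
    reference: Optional[str] = None,
) -> dict[int, Optional[str]]:
    """Read one base per key position from a sample sequence.

    With no ``reference`` the sample is taken to be a row already in the key's
    coordinate system (position *p* reads the p-th base).  With a reference
    sequence in key coordinates, the sample is located within the reference by
    semi-global alignment and positions are transferred.  Positions outside
    the aligned span report None (the call will degrade to insufficient data).
    """
    seq = (sample.sequence if isinstance(sample, SequenceRecord) else sample).upper()
    states: dict[int, Optional[str]] = {}
    if reference is None:
        for p in key.positions:
            states[p] = seq[p - 1] if p <= len(seq) else None
        return states
    res = edlib.align(seq, reference.upper(), mode="HW", task="path")
    start, _ = res["locations"][0]
    ref_to_sample: dict[int, Optional[int]] = {}
    rpos, spos = start, 0
    num = ""
    for ch in res["cigar"]:
        if ch.isdigit():
            num += ch
            continue
        n, num = int(num), ""
        if ch in "=X":
            for _ in range(n):
                ref_to_sample[rpos] = spos
                rpos += 1
                spos += 1
        elif ch == "I":  # sample-only column
            spos += n
        elif ch == "D":  # reference-only column: sample has a gap here
            for _ in range(n):
                ref_to_sample[rpos] = None
                rpos += 1
    for p in key.positions:
        idx = ref_to_sample.get(p - 1, "outside")
        if idx == "outside":
            states[p] = None
        elif idx is None:
            states[p] = "-"
        else:
            states[p] = seq[idx]
    return states


def assign_haplotype(states: dict[int, Optional[str]], key: HaplotypeKey) -> HaplotypeCall:
    """Assign a haplotype call to a vector of observed states.

    Core types are evaluated in priority order and the first fully satisfied
    pattern wins; an all-consensus vector at the core sites is the
    intermediate type; anything else is novel.  The marker count is the number
    of marker SNPs whose derived state is observed, displayed only on type-1
    calls ("1p" two markers, "1(p)" one).
    """
    missing = [
        p
        for p in key.core_sites
        if states.get(p) is None or states[p] not in _VALID_BASES
    ]
    if missing:
        return HaplotypeCall(
            "insufficient", 0, "insufficient data", dict(states)
        )
    marker_count = sum(
        1 for p, b in key.marker_snps.items() if states.get(p) == b
    )
    core_label = None
    for ct in sorted(key.core_types, key=lambda c: c.priority):
        if all(states[p] == b for p, b in ct.required_states.items()):
            core_label = ct.label
            break
    if core_label is None:
        if all(states[p] == key.consensus[p] for p in key.core_sites):
            core_label = key.intermediate_label
        else:
            core_label = "novel"

    first = key.core_types[0].label if key.core_types else "1"
    if core_label == first:
        if marker_count >= 2:
            display = f"{core_label}{key.marker_label}"
        elif marker_count == 1:
            display = f"{core_label}({key.marker_label})"
        else:
            display = core_label
    elif core_label == "novel":
        obs = ",".join(f"{p}={states[p]}" for p in key.positions if states.get(p))
        display = f"novel:{obs}"
    else:
        display = core_label
    return HaplotypeCall(core_label, marker_count, display, dict(states))


def call_sample(
    sample: Union[SequenceRecord, str],
    key: HaplotypeKey,
    reference: Optional[str] = None,
) -> HaplotypeCall:
    """Convenience: extract_states then assign_haplotype."""
    return assign_haplotype(extract_states(sample, key, reference), key)
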