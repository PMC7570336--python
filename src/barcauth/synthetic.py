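"""Synthetic panels, test collections and structure fixtures.

Real curated barcode databases are built from repository accessions; this
module generates stand-ins with the same statistical structure so that every
computational step is testable without downloads: an adulterant panel with
planted species-specific SNPs and intraspecific subtypes, rbcL sequences
carrying named haplotype states, psbA-trnH spacers with long/short stem-loop
variants and homopolymer jitter, and an ITS2-like structure panel with a
planted compensatory-base-change gradient across clades.

The generator emulates the *Hypericum* case-study conditions: a panel of 20
species, three target (perforatum) ITS subtypes and two for the adulterant
(maculatum), seven subtype-defining columns, substitution-only noise with on
average one substitution per accession, and ~30% ITS sequencing dropout in
test collections.  Randomness comes exclusively from numpy's PCG64 generator
seeded from ``SimConfig.seed``, so a fixed seed gives byte-identical output
on every platform.

The transcription of the case study's 38-sample character table ships as a
checked-in fixture (checksum-verified), not generated data.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional

import numpy as np

from .errors import DataError
from .haplotype import HaplotypeKey, default_rbcl_key
from .iupac import revcomp
from .refmatch import ReferenceBarcode
from .curation import build_consensus, read_panel_table
from .seqio import (
    MultipleAlignment,
    SampleCharacterTable,
    SequenceRecord,
    parse_character_table,
)

_BASES = np.array(list("ACGT"))

# ---------------------------------------------------------------------------
# psbA 3' UTR stem-loop archetype constants (synthetic; the published anchor
# and archetype strings are figure content and not machine-readable, so these
# are constructed to have the described properties: GC stem of 12 bp in the
# long form and 6 bp in the short form, a 3-base AAA/UUU apex that cannot
# pair, A/T-rich homopolymeric flanks).

PSBA_ANCHOR_5 = "TCGACGGATCAC"
PSBA_ANCHOR_3 = "GTGCATCCAGTC"
STEM_ARM_LONG = "GGCGGCCGGCGG"  # 12 bp terminal helix
STEM_ARM_SHORT = STEM_ARM_LONG[:6]  # deletion truncates the stem to 6 bp

_FLANK5_RUNS = [("A", 2), ("T", 4), ("A", 4), ("T", 3), ("A", 2), ("T", 4)]
_FLANK3_RUNS = [("T", 3), ("A", 4), ("T", 4), ("A", 3), ("T", 2), ("A", 4)]

#: rbcL core-haplotype assignment of the panel species (unlisted species carry
#: the intermediate all-consensus pattern).
DEFAULT_RBCL_ASSIGNMENT = {
    "Hypericum perforatum": "1p",
    "Hypericum maculatum": "1",
    "Hypericum tetrapterum": "1",
    "Hypericum undulatum": "1",
    "Hypericum montanum": "1",
    "Hypericum hirsutum": "1",
    "Hypericum androsaemum": "2",
    "Hypericum ascyron": "2",
    "Hypericum calycinum": "2",
    "Hypericum crux-andreae": "2",
    "Hypericum japonicum": "2",
}


@dataclass
class SubtypeSpec:
    n_subtypes: int
    n_diff_columns: int
    accessions_per_subtype: int = 4


def _default_subtype_spec() -> dict[str, SubtypeSpec]:
    return {
        "Hypericum perforatum": SubtypeSpec(3, 7, 4),
        "Hypericum maculatum": SubtypeSpec(2, 4, 4),
    }


@dataclass
class SimConfig:
    """Study-condition parameters for the generators (see module docstring)."""

    seed: int = 0
    n_species: int = 20
    sites: int = 700
    n_accessions: int = 2
    species_snp_count: int = 2
    subtype_spec: dict[str, SubtypeSpec] = field(default_factory=_default_subtype_spec)
    noise_rate: float = 1.0  # expected substitutions per accession
    its_dropout: float = 0.3  # fraction of test samples without an ITS sequence
    rbcl_length: int = 520
    aaa_apex_fraction: float = 0.25  # short stems carrying the AAA apex


@dataclass
class PanelTruth:
    ancestral: str
    unique_sites: dict[str, list[int]]  # species -> planted 1-based columns
    subtype_templates: dict[str, dict[str, str]]
    row_species: dict[str, str]
    row_subtype: dict[str, Optional[str]]


@dataclass
class PanelSim:
    alignment: MultipleAlignment
    truth: PanelTruth


def _panel_names(n: int) -> list[str]:
    names = [sp.name for sp in load_panel_metadata()]
    while len(names) < n:
        names.append(f"Hypericum synthsp{len(names) + 1:02d}")
    return names[:n]


def load_panel_metadata():
    """The packaged restricted-panel species table."""
    with resources.as_file(
        resources.files("barcauth.data").joinpath("panel_species.tsv")
    ) as p:
        return read_panel_table(p)


def _abbrev(species: str) -> str:
    parts = species.split()
    return (parts[-1][:4] if parts else species[:4]).lower()


def _mutate(rng: np.random.Generator, seq: list[str], pos: int) -> None:
    alternatives = [b for b in "ACGT" if b != seq[pos]]
    seq[pos] = alternatives[rng.integers(len(alternatives))]


def generate_panel(cfg: SimConfig) -> PanelSim:
    """Generate an aligned species panel with planted truth.

    An ancestral sequence is mutated per species at ``species_snp_count``
    dedicated columns (the planted species-specific SNPs); species with a
    subtype spec get templates differing pairwise at their subtype columns;
    accessions are templates plus Poisson(noise_rate) random substitutions.
    Returns the alignment and the truth tables for parameter-recovery tests.
    """
    rng = np.random.default_rng(cfg.seed)
    names = _panel_names(cfg.n_species)
    needed = cfg.species_snp_count * cfg.n_species + sum(
        s.n_diff_columns for sp, s in cfg.subtype_spec.items() if sp in names
    )
    if needed > cfg.sites:
        raise DataError(
            f"infeasible config: {needed} planted columns exceed {cfg.sites} sites"
        )
    ancestral = "".join(rng.choice(_BASES, cfg.sites))
    pool = [int(x) for x in rng.permutation(cfg.sites)]

    unique_sites: dict[str, list[int]] = {}
    species_seq: dict[str, list[str]] = {}
    for sp in names:
        seq = list(ancestral)
        cols = sorted(pool.pop() for _ in range(cfg.species_snp_count))
        for c in cols:
            _mutate(rng, seq, c)
        unique_sites[sp] = [c + 1 for c in cols]
        species_seq[sp] = seq

    subtype_templates: dict[str, dict[str, str]] = {}
    roman = ["I", "II", "III", "IV", "V"]
    for sp, spec in cfg.subtype_spec.items():
        if sp not in names:
            continue
        cols = sorted(pool.pop() for _ in range(spec.n_diff_columns))
        templates = {roman[t]: list(species_seq[sp]) for t in range(spec.n_subtypes)}
        # pairwise-distinct states per subtype column
        for c in cols:
            perm = rng.permutation(_BASES)
            for t in range(spec.n_subtypes):
                templates[roman[t]][c] = str(perm[t])
        subtype_templates[sp] = {lab: "".join(s) for lab, s in templates.items()}

    records: list[SequenceRecord] = []
    row_species: dict[str, str] = {}
    row_subtype: dict[str, Optional[str]] = {}
    for sp in names:
        if sp in subtype_templates:
            plan = [
                (lab, tmpl)
                for lab, tmpl in subtype_templates[sp].items()
                for _ in range(cfg.subtype_spec[sp].accessions_per_subtype)
            ]
        else:
            plan = [(None, "".join(species_seq[sp]))] * cfg.n_accessions
        for k, (lab, tmpl) in enumerate(plan, start=1):
            seq = list(tmpl)
            n_subs = rng.poisson(cfg.noise_rate)
            if n_subs:
                for pos in rng.choice(cfg.sites, size=min(n_subs, cfg.sites), replace=False):
                    _mutate(rng, seq, int(pos))
            rid = f"{_abbrev(sp)}-{k:02d}"
            records.append(
                SequenceRecord(rid, "".join(seq), species=sp, region="ITS")
            )
            row_species[rid] = sp
            row_subtype[rid] = lab
    aln = MultipleAlignment(records, coordinate_name=f"synthetic-panel-seed{cfg.seed}")
    return PanelSim(
        aln,
        PanelTruth(ancestral, unique_sites, subtype_templates, row_species, row_subtype),
    )


def reference_from_panel(
    sim: PanelSim,
    target: str = "Hypericum perforatum",
    identity_threshold: float = 0.95,
    n_segments: int = 2,
) -> ReferenceBarcode:
    """Build a reference barcode for the target from the panel truth.

    The pattern is the zero-floor IUPAC consensus of the target's subtype
    templates (so every legitimate subtype is covered by ambiguity codes);
    the planted target-unique SNPs become the essential lowercase bases.
    """
    templates = sim.truth.subtype_templates.get(target)
    rows = list(templates.values()) if templates else [
        sim.alignment.rows_for_species(target)[0].sequence
    ]
    cons = build_consensus(rows, ambiguity_floor=0.0, species=target).consensus
    essential = set(sim.truth.unique_sites[target])
    cased = "".join(
        c.lower() if (i + 1) in essential else c for i, c in enumerate(cons)
    )
    bounds = np.linspace(0, len(cased), n_segments + 1).astype(int)
    patterns = {
        f"seg{k + 1}": cased[bounds[k]: bounds[k + 1]] for k in range(n_segments)
    }
    return ReferenceBarcode.from_case_patterns(
        f"{_abbrev(target)}-reference", patterns, identity_threshold, target
    )


# ---------------------------------------------------------------------------
# rbcL haplotype sequences


def states_for_label(label: str, key: Optional[HaplotypeKey] = None) -> dict[int, str]:
    """Canonical state vector carrying a given display label.

    "1p" plants both marker SNPs on the type-1 core, "1(p)" one (position 66,
    the marker observed in every target accession), "1" none; "2" and "1-2"
    follow the core patterns.
    """
    key = key or default_rbcl_key()
    states = dict(key.consensus)
    label = label.replace("–", "-")
    if label in ("1", "1(p)", "1p"):
        states.update({180: "T", 300: "G", 372: "C"})
        markers = sorted(key.marker_snps)
        if label == "1p":
            for p in markers:
                states[p] = key.marker_snps[p]
        elif label == "1(p)":
            states[markers[0]] = key.marker_snps[markers[0]]
    elif label == "2":
        states.update({378: "G", 492: "T"})
    elif label == "1-2":
        pass
    else:
        raise DataError(f"no canonical states for label {label!r}")
    return states


def rbcl_background(cfg: SimConfig, key: Optional[HaplotypeKey] = None) -> str:
    """Deterministic rbcL coordinate-reference sequence with consensus states
    planted at the key positions."""
    key = key or default_rbcl_key()
    if cfg.rbcl_length < max(key.positions):
        raise DataError("rbcl_length shorter than the haplotype key span")
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0xB2]))
    seq = list("".join(rng.choice(_BASES, cfg.rbcl_length)))
    for p, b in key.consensus.items():
        seq[p - 1] = b
    return "".join(seq)


def rbcl_sequence_for_label(
    label: str, cfg: SimConfig, key: Optional[HaplotypeKey] = None
) -> str:
    key = key or default_rbcl_key()
    seq = list(rbcl_background(cfg, key))
    for p, b in states_for_label(label, key).items():
        seq[p - 1] = b
    return "".join(seq)


# ---------------------------------------------------------------------------
# psbA-trnH stem-loop variants


def stem_region(kind: str, apex: str = "AAA") -> str:
    """The stem-loop region between the anchors (DNA alphabet)."""
    arm = {"long": STEM_ARM_LONG, "short": STEM_ARM_SHORT}[kind]
    return arm + apex.replace("U", "T") + revcomp(arm)


def _flank(runs, rng: Optional[np.random.Generator]) -> str:
    out = []
    for base, length in runs:
        if rng is not None:
            length = max(1, length + int(rng.integers(-1, 2)))
        out.append(base * length)
    return "".join(out)


def psba_spacer(
    kind: str, apex: str = "AAA", rng: Optional[np.random.Generator] = None
) -> str:
    """A synthetic psbA-trnH spacer: A/T-rich homopolymeric flanks around the
    anchored stem-loop; run lengths jittered when an rng is supplied."""
    return (
        _flank(_FLANK5_RUNS, rng)
        + PSBA_ANCHOR_5
        + stem_region(kind, apex)
        + PSBA_ANCHOR_3
        + _flank(_FLANK3_RUNS, rng)
    )


def generate_stem_variants(
    cfg: SimConfig, n_long: int = 3, n_short: int = 3
) -> tuple[list[SequenceRecord], dict[str, tuple[str, str]]]:
    """FASTA-ready spacer variants with truth {id: (class, apex)}.

    Short variants carry an AAA apex with probability ``aaa_apex_fraction``
    (UUU otherwise); long variants keep the AAA apex.  Homopolymer runs in
    the flanks are jittered per record.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0x5E]))
    records, truth = [], {}
    for k in range(n_long):
        rid = f"long-{k + 1:02d}"
        records.append(
            SequenceRecord(rid, psba_spacer("long", "AAA", rng), region="psbA-trnH")
        )
        truth[rid] = ("LONG", "AAA")
    for k in range(n_short):
        apex = "AAA" if rng.random() < cfg.aaa_apex_fraction else "TTT"
        rid = f"short-{k + 1:02d}"
        records.append(
            SequenceRecord(rid, psba_spacer("short", apex, rng), region="psbA-trnH")
        )
        truth[rid] = ("SHORT", apex)
    return records, truth


def load_archetypes() -> dict[str, str]:
    """Packaged synthetic long/short archetype stem-loop regions."""
    return {"long": stem_region("long"), "short": stem_region("short")}


# ---------------------------------------------------------------------------
# ITS2 structure panel with a planted CBC gradient


_CBC_ARM = "GCGAUCGAUG"
_CBC_LOOP = "GAAA"

#: planted CBC counts relative to the target, following the clade gradient of
#: the case study (same-clade species 0, then 1/2/4-5 with increasing
#: distance; the one clade-D anomaly carries 5).
CBC_GRADIENT = {
    "Hypericum delphicum": 0,
    "Hypericum montanum": 0,
    "Hypericum barbatum": 0,
    "Hypericum attenuatum": 0,
    "Hypericum maculatum": 0,
    "Hypericum perforatum": 0,
    "Hypericum tetrapterum": 0,
    "Hypericum undulatum": 0,
    "Hypericum hirsutum": 0,
    "Hypericum olympicum": 0,
    "Hypericum acmosepalum": 1,
    "Hypericum calycinum": 1,
    "Hypericum kouytchense": 1,
    "Hypericum patulum": 1,
    "Hypericum androsaemum": 2,
    "Hypericum crux-andreae": 4,
    "Hypericum ascyron": 5,
    "Hypericum japonicum": 5,
}


def generate_cbc_panel():
    """ITS2-like hairpins sharing one frame, with planted CBCs vs the target.

    Returns (structures, expected) where structures maps species to
    :class:`~barcauth.rnastruct.StructuredSequence` and expected maps species
    to the planted CBC count relative to *H. perforatum*.  k CBCs are planted
    by reversing the orientation of the k outermost stem pairs (G-C -> C-G),
    which changes both partners while preserving pairing.
    """
    from .rnastruct import StructuredSequence

    arm = _CBC_ARM
    rc = revcomp(arm.replace("U", "T")).replace("T", "U")
    n = len(arm)
    base_seq = arm + _CBC_LOOP + rc
    structure = "(" * n + "." * len(_CBC_LOOP) + ")" * n
    structures = {}
    for species, k in CBC_GRADIENT.items():
        seq = list(base_seq)
        for idx in range(k):
            i, j = idx, len(base_seq) - 1 - idx
            seq[i], seq[j] = seq[j], seq[i]
        structures[species] = StructuredSequence("".join(seq), structure)
    return structures, dict(CBC_GRADIENT)


# ---------------------------------------------------------------------------
# test collections


TABLE5_SHA256 = "de7a37f732d82abbf7083907d31c9d4dc03cd6c9a16dfa56fe617f30f0de5573"


def table5_characters() -> SampleCharacterTable:
    """The checked-in transcription of the case study's 38-sample table."""
    text = resources.files("barcauth.data").joinpath("test_collection_characters.tsv").read_text()
    digest = hashlib.sha256(text.encode()).hexdigest()
    if digest != TABLE5_SHA256:
        raise DataError(
            f"test-collection fixture checksum mismatch ({digest[:12]}...)"
        )
    return parse_character_table(text, source="test_collection_characters.tsv")


@dataclass
class TestCollection:
    table: SampleCharacterTable
    sequences: dict[str, dict[str, str]]  # sample_id -> region -> sequence
    truth: dict[str, dict]  # sample_id -> planted characters
    reference: Optional[ReferenceBarcode] = None


_RBCL_LABEL_P = (["1p", "1", "1(p)", "1-2"], [0.8, 0.1, 0.05, 0.05])
_RBCL_LABEL_M = (["1p", "1", "1(p)", "1-2"], [0.5, 0.25, 0.125, 0.125])


def generate_test_collection(
    cfg: SimConfig,
    n_target: int = 22,
    n_adulterant: int = 16,
    sequence_mode: bool = False,
    target: str = "Hypericum perforatum",
    adulterant: str = "Hypericum maculatum",
) -> TestCollection:
    """A synthetic field collection emulating the case-study test samples.

    Target samples carry short stems (AAA apex at ``aaa_apex_fraction``) and
    mostly the marker-bearing type-1p haplotype; adulterant samples carry long
    stems and the label mixture observed in the field data.  ITS results drop
    out at ``its_dropout``.  In sequence mode each sample also receives ITS,
    rbcL and psbA-trnH sequences consistent with its planted characters, and
    the matching ITS reference barcode is returned.
    """
    from .seqio import CharacterRow, ItsResult, StemClass

    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0x7C]))
    key = default_rbcl_key()
    rows, truth, sequences = [], {}, {}

    its_len = 300
    ess_positions = [40, 150, 260]
    its_template = None
    reference = None
    if sequence_mode:
        its_bg = list("".join(rng.choice(_BASES, its_len)))
        its_template = {"target": list(its_bg), "adulterant": list(its_bg)}
        for p in ess_positions:
            _mutate(rng, its_template["target"], p - 1)  # derived target state
        cased = "".join(
            c.lower() if (i + 1) in ess_positions else c
            for i, c in enumerate("".join(its_template["target"]))
        )
        half = its_len // 2
        reference = ReferenceBarcode.from_case_patterns(
            "synthetic-target-reference",
            {"seg1": cased[:half], "seg2": cased[half:]},
            0.95,
            target,
        )

    def emit(idx, species, is_target):
        sid = f"{_abbrev(species)} {idx:02d}"
        dropout = rng.random() < cfg.its_dropout
        if dropout:
            its, closest = ItsResult.NO_DATA, None
        elif is_target:
            its, closest = ItsResult.PASS, None
        else:
            its, closest = ItsResult.MATCH_ADULTERANT, adulterant
        if is_target:
            apex = "AAA" if rng.random() < cfg.aaa_apex_fraction else "TTT"
            stem = StemClass.SHORT_AAA if apex == "AAA" else StemClass.SHORT
            kind = "short"
        else:
            apex, stem, kind = "AAA", StemClass.LONG, "long"
        labels, probs = _RBCL_LABEL_P if is_target else _RBCL_LABEL_M
        rbcl = str(rng.choice(labels, p=probs))
        rows.append(
            CharacterRow(sid, species, its, closest, stem, rbcl)
        )
        truth[sid] = {
            "species": species,
            "stem_class": "SHORT" if is_target else "LONG",
            "apex": apex,
            "rbcl_label": rbcl,
            "its_dropout": dropout,
        }
        if sequence_mode:
            tmpl = its_template["target" if is_target else "adulterant"]
            sequences[sid] = {
                "ITS": "".join(tmpl),
                "rbcL": rbcl_sequence_for_label(rbcl, cfg, key),
                "psbA-trnH": psba_spacer(kind, apex, rng),
            }

    for i in range(n_target):
        emit(i + 1, target, True)
    for i in range(n_adulterant):
        emit(i + 1, adulterant, False)
    return TestCollection(SampleCharacterTable(rows), sequences, truth, reference)
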