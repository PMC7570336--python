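"""Combined multi-locus identification verdicts.

The primary identification of a sample is the ITS match against the target
reference barcode; the psbA stem-loop class and rbcL haplotype are
corroborative.  The verdict codes are M (confirmed adulterant), m (possible
adulterant), P (confirmed target), p (possible target) and U (undetermined).

Rule cascade (deterministic, first match wins):

1. ITS passes the target reference                          -> P
2. ITS matched an adulterant reference:
     long stem and rbcL not the anomalous intermediate 1-2  -> M
     otherwise                                              -> m
3. ITS obtained but failed all references                   -> U
4. no ITS data:
     short stem (incl. AAA-loop variant)                    -> p
     long stem, nominally an adulterant                     -> m
     long stem, nominally the target                        -> U
     no stem data                                           -> U ("no evidence")

The rbcL character only ever downgrades M to m (rule 2): the perforatum
marker SNPs proved unreliable on field samples, so the haplotype is treated
as corroborative, never decisive.  Rule 4's asymmetric long-stem handling is
a reconstruction from the case-study truth table, not an independently stated
rule, and is flagged as such in the rationale it emits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .seqio import CharacterRow, ItsResult, SampleCharacterTable, StemClass

TARGET_SPECIES = "Hypericum perforatum"

CODES = ("M", "m", "P", "p", "U")

_SHORT = {StemClass.SHORT, StemClass.SHORT_AAA}


@dataclass
class Verdict:
    code: str
    rationale: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.code not in CODES:
            raise ValueError(f"unknown verdict code {self.code!r}")
        if not self.rationale:
            raise ValueError("verdict rationale must not be empty")


def decide_identity(chars: CharacterRow, target_species: str = TARGET_SPECIES) -> Verdict:
    """Apply the rule cascade (module docstring) to one sample's characters."""
    its, stem, rbcl = chars.its_result, chars.stem_class, chars.rbcl_label

    if its is ItsResult.PASS:
        return Verdict("P", ["ITS matched the target reference barcode"])

    if its is ItsResult.MATCH_ADULTERANT:
        who = chars.its_closest or "an adulterant"
        if stem is StemClass.LONG and rbcl != "1-2":
            return Verdict(
                "M",
                [f"ITS matched {who}", "long psbA stem corroborates",
                 f"rbcL type {rbcl or 'n/a'} not anomalous"],
            )
        reasons = [f"ITS matched {who}"]
        if stem is not StemClass.LONG:
            reasons.append(f"psbA stem {stem.value} does not corroborate")
        if rbcl == "1-2":
            reasons.append("anomalous intermediate rbcL type 1-2")
        return Verdict("m", reasons)

    if its is ItsResult.FAIL:
        return Verdict("U", ["ITS sequence failed all reference criteria"])

    # no ITS data
    if stem in _SHORT:
        return Verdict("p", ["no ITS data", "short psbA stem consistent with target"])
    if stem is StemClass.LONG:
        if chars.nominal_species != target_species:
            return Verdict(
                "m",
                ["no ITS data", "long psbA stem consistent with nominal adulterant",
                 "(reconstructed rule: long stem + adulterant label)"],
            )
        return Verdict(
            "U",
            ["no ITS data", "long psbA stem contradicts nominal target",
             "(reconstructed rule: long stem + target label)"],
        )
    return Verdict("U", ["no evidence"])


def decide_table(
    table: SampleCharacterTable, target_species: str = TARGET_SPECIES
) -> dict[str, Verdict]:
    return {r.sample_id: decide_identity(r, target_species) for r in table}


def tally_verdicts(
    table: SampleCharacterTable, verdicts: dict[str, Verdict]
) -> dict[str, dict]:
    """Summary counts: verdict codes per nominal species, plus per-character
    tallies (stem classes and ITS results per nominal species)."""
    codes: dict[str, dict[str, int]] = {}
    stems: dict[str, dict[str, int]] = {}
    its: dict[str, dict[str, int]] = {}
    for row in table:
        sp = row.nominal_species
        v = verdicts[row.sample_id]
        codes.setdefault(sp, {})
        codes[sp][v.code] = codes[sp].get(v.code, 0) + 1
        stems.setdefault(sp, {})
        stems[sp][row.stem_class.value] = stems[sp].get(row.stem_class.value, 0) + 1
        its.setdefault(sp, {})
        its[sp][row.its_result.value] = its[sp].get(row.its_result.value, 0) + 1
    return {"codes": codes, "stem_classes": stems, "its_results": its}
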