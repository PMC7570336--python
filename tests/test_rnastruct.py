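"""Folding, stem-loop classification, structure encoding and CBC counting."""

from functools import lru_cache

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from barcauth import synthetic
from barcauth.errors import AnchorError, DataError
from barcauth.rnastruct import (
    StructuredSequence,
    count_cbc,
    decode_structure_alphabet,
    encode_structure_alphabet,
    extract_stem_loop,
    fold_hairpin,
)

_CANON = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}


def max_pairs_oracle(seq, min_loop=3):
    """Independent exhaustive-enumeration maximum pair count (5'-anchored
    recursion over 'first base unpaired or paired with k')."""
    s = seq.upper().replace("T", "U")

    @lru_cache(maxsize=None)
    def best(i, j):
        if j - i < min_loop + 1:
            return 0
        res = best(i + 1, j)
        for k in range(i + min_loop + 1, j + 1):
            if (s[i], s[k]) in _CANON:
                res = max(res, 1 + best(i + 1, k - 1) + best(k + 1, j))
        return res

    return best(0, len(s) - 1)


# ---------------------------------------------------------------------------
# folding


def test_perfect_hairpin_folds_fully():
    ss = fold_hairpin("GGGAAACCC")
    assert ss.structure == "(((...)))"
    assert ss.n_pairs == 3 == max_pairs_oracle("GGGAAACCC")


def test_unpairable_sequence_stays_open():
    assert fold_hairpin("AAAAA").structure == "....."


def test_too_short_sequence_errors():
    with pytest.raises(DataError):
        fold_hairpin("GAAA")


def test_fold_respects_min_loop():
    ss = fold_hairpin("GGGAACCC")  # only 2 bases available for a 3-loop apex
    pairs = ss.pair_map()
    for i, j in pairs.items():
        if i < j:
            inner = range(i + 1, j)
            assert sum(ss.structure[k] == "." and k not in pairs for k in inner) >= 3 or any(
                k in pairs for k in inner
            )


def test_fold_is_deterministic():
    rng = np.random.default_rng(4)
    for _ in range(20):
        seq = "".join(rng.choice(list("ACGU"), 12))
        assert fold_hairpin(seq).structure == fold_hairpin(seq).structure


def test_fold_matches_enumeration_on_random_short_sequences():
    rng = np.random.default_rng(0)
    for _ in range(100):
        n = int(rng.integers(5, 15))
        seq = "".join(rng.choice(list("ACGU"), n))
        assert fold_hairpin(seq).n_pairs == max_pairs_oracle(seq), seq


def test_fold_output_is_valid_structure():
    rng = np.random.default_rng(8)
    for _ in range(30):
        seq = "".join(rng.choice(list("ACGU"), 14))
        ss = fold_hairpin(seq)  # StructuredSequence validates pairs and loops
        assert len(ss.structure) == len(seq)


# ---------------------------------------------------------------------------
# stem-loop extraction


def test_short_archetype_classified_short_with_aaa_loop():
    m = extract_stem_loop(synthetic.psba_spacer("short", "AAA"))
    assert m.stem_class == "SHORT" and m.loop_label == "AAA"
    assert m.stem_bp == 6


def test_long_archetype_classified_long():
    m = extract_stem_loop(synthetic.psba_spacer("long", "AAA"))
    assert m.stem_class == "LONG" and m.stem_bp == 12


def test_apex_mutation_changes_label_not_class():
    short_aaa = extract_stem_loop(synthetic.psba_spacer("short", "AAA"))
    short_uuu = extract_stem_loop(synthetic.psba_spacer("short", "TTT"))
    assert short_uuu.loop_label == "UUU"
    assert short_uuu.stem_class == short_aaa.stem_class == "SHORT"
    assert short_uuu.stem_bp == short_aaa.stem_bp


def test_homopolymer_jitter_never_flips_class():
    rng = np.random.default_rng(17)
    for _ in range(10):
        assert extract_stem_loop(synthetic.psba_spacer("short", "AAA", rng)).stem_class == "SHORT"
        assert extract_stem_loop(synthetic.psba_spacer("long", "AAA", rng)).stem_class == "LONG"


def test_archetype_evidence_recorded():
    m = extract_stem_loop(
        synthetic.psba_spacer("short", "AAA"), archetypes=synthetic.load_archetypes()
    )
    assert m.archetype_closest == "short" and m.archetype_agrees


def test_missing_anchor_reported():
    with pytest.raises(AnchorError, match="0 times"):
        extract_stem_loop("ACGTACGTACGTACGT")


def test_duplicated_anchor_reported():
    spacer = synthetic.psba_spacer("short", "AAA")
    with pytest.raises(AnchorError, match="2 times"):
        extract_stem_loop(spacer + spacer)


# ---------------------------------------------------------------------------
# 12-letter encoding


def test_encoding_positionwise_classes():
    ss = StructuredSequence("GGGAAACCC", "(((...)))")
    enc = encode_structure_alphabet(ss)
    assert len(enc) == 9
    assert enc == "IIIAAAMMM"  # opening-G x3, unpaired-A x3, closing-C x3


def test_unpaired_bases_encode_as_themselves():
    enc = encode_structure_alphabet(StructuredSequence("ACGU", "...."))
    assert enc == "ACGU"


@given(st.integers(0, 2**32 - 1))
@settings(derandomize=True, max_examples=40)
def test_encode_decode_round_trip(seed):
    rng = np.random.default_rng(seed)
    seq = "".join(rng.choice(list("ACGU"), 14))
    ss = fold_hairpin(seq)
    back = decode_structure_alphabet(encode_structure_alphabet(ss))
    assert back.sequence == ss.sequence and back.structure == ss.structure


def test_decode_rejects_unknown_letter():
    with pytest.raises(DataError):
        decode_structure_alphabet("AXZ")


# ---------------------------------------------------------------------------
# CBC counting


def _brute_cbc(a, b):
    """Independent stack-parse and explicit double loop."""

    def pairs(structure):
        stack, out = [], set()
        for i, ch in enumerate(structure):
            if ch == "(":
                stack.append(i)
            elif ch == ")":
                out.add((stack.pop(), i))
        return out

    shared = pairs(a.structure) & pairs(b.structure)
    cbc = hemi = 0
    for i, j in shared:
        di = a.sequence[i] != b.sequence[i]
        dj = a.sequence[j] != b.sequence[j]
        cbc += di and dj
        hemi += di != dj
    return cbc, hemi, len(shared)


def test_identical_rows_zero_counts():
    a = StructuredSequence("GGAAACC", "((...))")
    c = count_cbc(a, a)
    assert (c.cbc, c.hemi_cbc) == (0, 0) and c.shared_pairs == 2


def test_single_pair_flip_is_one_cbc():
    a = StructuredSequence("GAAAC", "(...)")
    b = StructuredSequence("CAAAG", "(...)")
    c = count_cbc(a, b)
    assert (c.cbc, c.hemi_cbc, c.shared_pairs) == (1, 0, 1) == _brute_cbc(a, b)


def test_inner_pair_flip_outer_conserved():
    a = StructuredSequence("GGAAACC", "((...))")
    b = StructuredSequence("GCAAAGC", "((...))")
    c = count_cbc(a, b)
    assert (c.cbc, c.hemi_cbc) == (1, 0)
    assert _brute_cbc(a, b) == (1, 0, 2)


def test_two_cbc_construction():
    a = StructuredSequence("GGAAACC", "((...))")
    b = StructuredSequence("CCAAAGG", "((...))")
    c = count_cbc(a, b)
    assert (c.cbc, c.hemi_cbc, c.shared_pairs) == (2, 0, 2) == _brute_cbc(a, b)


def test_hemi_cbc_single_side_change():
    a = StructuredSequence("GAAAC", "(...)")
    b = StructuredSequence("GAAAU", "(...)")  # G-C -> G-U wobble
    c = count_cbc(a, b)
    assert (c.cbc, c.hemi_cbc) == (0, 1)


def test_cbc_properties_on_random_pairs():
    rng = np.random.default_rng(23)
    for _ in range(200):
        n = int(rng.integers(10, 22))
        a = fold_hairpin("".join(rng.choice(list("ACGU"), n)))
        b = fold_hairpin("".join(rng.choice(list("ACGU"), n)))
        ab, ba = count_cbc(a, b), count_cbc(b, a)
        assert (ab.cbc, ab.hemi_cbc, ab.shared_pairs) == (ba.cbc, ba.hemi_cbc, ba.shared_pairs)
        assert ab.cbc + ab.hemi_cbc <= ab.shared_pairs
        self_count = count_cbc(a, a)
        assert self_count.cbc == 0 and self_count.hemi_cbc == 0
        assert (ab.cbc, ab.hemi_cbc, ab.shared_pairs) == _brute_cbc(a, b)


def test_frame_mismatch_errors():
    a = StructuredSequence("GAAAC", "(...)")
    b = StructuredSequence("GAAACC", "(...).")
    with pytest.raises(DataError):
        count_cbc(a, b)


def test_clade_gradient_fixture():
    """Planted CBC counts follow the clade gradient: same clade as the target
    0, then 1 / 2 / 4-5 with increasing distance, including the one clade-D
    anomaly at 5."""
    structures, expected = synthetic.generate_cbc_panel()
    target = structures["Hypericum perforatum"]
    panel = {p.name: p for p in synthetic.load_panel_metadata()}
    for species, ss in structures.items():
        c = count_cbc(target, ss)
        assert c.cbc == expected[species], species
        assert c.hemi_cbc == 0
    clades = {"E": set(), "D": set(), "C": set(), "B": set()}
    for species in structures:
        clade = panel[species].meseguer_clade
        clades[clade].add(expected[species])
    assert clades["E"] == {0}
    assert 1 in clades["D"] and 2 in clades["C"] and max(clades["B"]) >= 4
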