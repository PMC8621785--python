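"""Lasso nomenclature, fingerprint grammar and evolution-flower moves."""

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lassokit.classify import (FingerprintError, classify_loop,
                               enumerate_minors, fingerprint,
                               flower_neighbors, major_piercings,
                               parse_fingerprint, parse_minor)

from conftest import all_minor_labels

sign_lists = st.lists(st.sampled_from("+-"), max_size=4)


@pytest.mark.parametrize(
    "n_signs, c_signs, minor, major, klass",
    [
        ([], ["-"], "L-1C", "L1", "L"),
        (["-"], [], "L-1N", "L1", "L"),
        (["-", "-"], [], "LS2--N", "LS2", "LS"),
        ([], ["+", "+"], "LS2++C", "LS2", "LS"),
        (["+"], ["+", "-"], "LL+1,+2", "LL1,2", "LL"),
        ([], [], "L0", "L0", "L0"),
        ([], ["+", "-", "+"], "L+3C", "L3", "L"),
        ([], ["+", "+", "-"], "LS3++-C", "LS3", "LS"),
        (["-", "-"], ["+", "-"], "LLS2--,+2", "LLS2,2", "LLS"),
        (["+", "-", "+", "-"], [], "L+4N", "L4", "L"),
    ],
)
def test_classify_loop_labels(n_signs, c_signs, minor, major, klass):
    t = classify_loop(n_signs, c_signs)
    assert (t.minor, t.major, t.klass) == (minor, major, klass)


def test_classify_accepts_unicode_minus():
    assert classify_loop([], ["−"]).minor == "L-1C"


def test_classify_rejects_bad_symbols():
    with pytest.raises(ValueError):
        classify_loop(["x"], [])


def test_klass_partitions():
    """Class membership follows tail occupancy and supercoiling exactly."""
    for ns_len in range(3):
        for cs_len in range(3):
            for ns in itertools.product("+-", repeat=ns_len):
                for cs in itertools.product("+-", repeat=cs_len):
                    t = classify_loop(ns, cs)
                    if not ns and not cs:
                        assert t.klass == "L0"
                    elif bool(ns) != bool(cs):
                        assert t.klass in ("L", "LS")
                    else:
                        assert t.klass in ("LL", "LLS")
                    sc = any(a == b for a, b in zip(ns, ns[1:])) or \
                         any(a == b for a, b in zip(cs, cs[1:]))
                    assert t.klass.endswith("S") == (sc and t.klass != "L0")


def test_fingerprint_compression_and_l0_suppression():
    l1 = classify_loop([], ["-"])
    l0 = classify_loop([], [])
    assert fingerprint([l1, l1]).text == "2L1"
    assert fingerprint([l0, l1]).text == "L1"
    assert fingerprint([]).text == ""
    mixed = [classify_loop([], s) for s in (["-", "-", "+"], ["-"], ["+"], ["+", "+"])]
    assert fingerprint(mixed).text == "LS32L1LS2"


def test_fingerprint_nonconsecutive_duplicates_stay_expanded():
    l1 = classify_loop([], ["-"])
    l2 = classify_loop([], ["-", "+"])
    assert fingerprint([l1, l2, l1]).text == "L1L2L1"


@pytest.mark.parametrize(
    "text, majors, total",
    [
        ("LS32L1LS2", ["LS3", "L1", "L1", "LS2"], 7),
        ("L1L2L12L2", ["L1", "L2", "L1", "L2", "L2"], 8),
        ("LL4,3L2", ["LL4,3", "L2"], 9),
        ("2L1", ["L1", "L1"], 2),
        ("", [], 0),
        ("LLS2,2", ["LLS2,2"], 4),
    ],
)
def test_parse_fingerprint(text, majors, total):
    got_majors, got_total = parse_fingerprint(text)
    assert got_majors == majors
    assert got_total == total


def test_parse_fingerprint_error_carries_position():
    with pytest.raises(FingerprintError) as err:
        parse_fingerprint("L1XYZ")
    assert err.value.position is not None


def test_major_piercings_two_sided_sum():
    assert major_piercings("LL4,3") == 7
    assert major_piercings("L2") == 2
    assert major_piercings("LS3") == 3


def test_fingerprint_roundtrip_exhaustive():
    """fingerprint -> parse_fingerprint is the identity for every type list
    of length <= 3 over majors with <= 3 piercings."""
    majors = ["L1", "L2", "L3", "LS2", "LS3",
              "LL1,1", "LL1,2", "LL2,1", "LLS1,2", "LLS2,1"]
    for length in range(4):
        for combo in itertools.product(majors, repeat=length):
            fp = fingerprint(list(combo))
            parsed, total = parse_fingerprint(fp.text)
            assert parsed == list(combo), fp.text
            assert total == sum(major_piercings(m) for m in combo)


def test_minor_label_roundtrip():
    for label in all_minor_labels(3):
        ns, cs = parse_minor(label)
        assert classify_loop(ns, cs).minor == label


def test_sign_flip_symmetry():
    """Flipping every sign mirrors minors but leaves majors unchanged."""
    flip = {"+": "-", "-": "+"}
    for label in all_minor_labels(3):
        ns, cs = parse_minor(label)
        t1 = classify_loop(ns, cs)
        t2 = classify_loop([flip[s] for s in ns], [flip[s] for s in cs])
        assert t1.major == t2.major
        assert t1.minor == t2.minor.translate(str.maketrans("+-", "-+"))


def test_tail_swap_symmetry():
    for label in all_minor_labels(3):
        ns, cs = parse_minor(label)
        t1, t2 = classify_loop(ns, cs), classify_loop(cs, ns)
        if t1.klass in ("L", "LS"):
            swap = {"N": "C", "C": "N"}
            assert t2.minor == t1.minor[:-1] + swap[t1.minor[-1]]
        elif t1.klass in ("LL", "LLS"):
            i, j = len(ns), len(cs)
            assert t2.major == t1.major.replace(f"{i},{j}", f"{j},{i}")


@settings(derandomize=True, max_examples=300, deadline=None)
@given(ns=sign_lists, cs=sign_lists)
def test_minor_label_is_faithful(ns, cs):
    """The minor label encodes the sign lists losslessly."""
    t = classify_loop(ns, cs)
    back_ns, back_cs = parse_minor(t.minor)
    assert (list(back_ns), list(back_cs)) == (ns, cs)
    assert t.total_piercings == len(ns) + len(cs)


@settings(derandomize=True, max_examples=200, deadline=None)
@given(majors=st.lists(st.sampled_from(
    ["L1", "L2", "L3", "L4", "LS2", "LS3", "LL1,1", "LL1,2", "LL2,1",
     "LLS1,2", "LLS2,2"]), max_size=6))
def test_fingerprint_roundtrip_random_lists(majors):
    parsed, total = parse_fingerprint(fingerprint(majors).text)
    assert parsed == majors
    assert total == sum(major_piercings(m) for m in majors)


def test_l1_has_exactly_four_minor_subtypes():
    minors = {t.minor for t in enumerate_minors("L1")}
    assert minors == {"L+1N", "L-1N", "L+1C", "L-1C"}


def test_flower_terminal_piercing_from_trivial():
    assert flower_neighbors("L0", "terminal_piercing") == {"L1"}


def test_flower_terminal_piercing_from_l1():
    nb = flower_neighbors("L1", "terminal_piercing")
    assert {"L0", "L2", "LS2", "LL1,1"} <= nb


def test_flower_slipknot_reaches_l3_but_not_full_supercoil():
    """A terminal slipknot turns a single piercing into a triple one, but
    can never produce the all-same-sign winding variant."""
    assert "L3" in flower_neighbors("L1", "terminal_slipknot")
    minors = flower_neighbors("L1", "terminal_slipknot", level="minor")
    assert "LS3---C" not in minors and "LS3+++C" not in minors
    assert "LS3--+C" in minors
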