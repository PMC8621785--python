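"""Lasso-type nomenclature, fingerprints and the evolution flower.

A covalent loop pierced by its terminal tails is classified by the ordered,
signed crossing sequence of each tail (ordered from the loop outward):

* ``L0``  — no piercing at all;
* ``Ln``  — one tail pierces *n* times, each consecutive piercing from the
  opposite side of the loop surface (alternating signs);
* ``LSn`` — one tail pierces *n* times with at least two consecutive
  piercings from the same side (the tail winds, i.e. supercoils, around
  the loop);
* ``LLi,j`` — both tails pierce (*i* piercings by the N-tail, *j* by the
  C-tail), each tail alternating;
* ``LLSi,j`` — both tails pierce and at least one of them supercoils.

A *minor* label keeps piercing directions and the piercing tail
(``L-1C``, ``LS2--N``, ``LL+1,+2``, ``LLS2--,+2``); the *major* label
suppresses both (``L1``, ``LS2``, ``LL1,2``, ``LLS2,2``).  The sign shown
in ``Ln``/``LL`` minors is that of the loop-proximal (rank-1) piercing.

The *fingerprint* of a chain concatenates the major labels of all pierced
loops in sequential order, suppressing ``L0`` and compressing runs of
identical consecutive majors with a multiplicity prefix (``2L1``).
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

__all__ = [
    "LassoType",
    "Fingerprint",
    "classify_loop",
    "fingerprint",
    "parse_fingerprint",
    "parse_major",
    "parse_minor",
    "major_piercings",
    "enumerate_minors",
    "flower_neighbors",
    "FingerprintError",
]

Sign = Literal["+", "-"]

#: characters accepted as a "minus" sign (ASCII hyphen and Unicode minus)
_MINUS = {"-", "−"}


class FingerprintError(ValueError):
    """Raised when a fingerprint or label string cannot be parsed."""

    def __init__(self, message: str, position: int | None = None):
        self.position = position
        if position is not None:
            message = f"{message} (at position {position})"
        super().__init__(message)


def _norm_sign(s: str) -> Sign:
    if s == "+":
        return "+"
    if s in _MINUS:
        return "-"
    raise ValueError(f"invalid sign symbol {s!r}; expected '+' or '-'")


def _norm_signs(signs: Iterable[str]) -> list[Sign]:
    return [_norm_sign(s) for s in signs]


def _is_supercoiled(signs: Sequence[Sign]) -> bool:
    """True if the tail crosses twice in a row from the same side."""
    return any(a == b for a, b in zip(signs, signs[1:]))


@dataclass(frozen=True)
class LassoType:
    """Structured lasso classification of a single covalent loop."""

    n_signs: tuple[Sign, ...]
    c_signs: tuple[Sign, ...]
    klass: str  # one of L0, L, LL, LS, LLS
    minor: str
    major: str

    @property
    def total_piercings(self) -> int:
        return len(self.n_signs) + len(self.c_signs)

    @property
    def pierced(self) -> bool:
        return self.total_piercings > 0


def _single_tail_label(signs: Sequence[Sign], tail: str) -> tuple[str, str, str]:
    n = len(signs)
    if _is_supercoiled(signs):
        minor = f"LS{n}{''.join(signs)}{tail}"
        return "LS", minor, f"LS{n}"
    minor = f"L{signs[0]}{n}{tail}"
    return "L", minor, f"L{n}"


def _ll_tail_token(signs: Sequence[Sign]) -> str:
    # alternating tails: sign of the rank-1 piercing + count; supercoiled
    # tails: count + explicit sign string (cf. LLS2--,+2)
    if _is_supercoiled(signs):
        return f"{len(signs)}{''.join(signs)}"
    return f"{signs[0]}{len(signs)}"


def classify_loop(n_signs: Iterable[str], c_signs: Iterable[str]) -> LassoType:
    """Classify one covalent loop from its per-tail signed piercing lists.

    Parameters
    ----------
    n_signs, c_signs
        Piercing signs of the N-terminal and C-terminal tail, ordered from
        the loop outward (rank 1 first).  ``+``/``-`` strings; the Unicode
        minus sign is accepted.
    """
    ns = tuple(_norm_signs(n_signs))
    cs = tuple(_norm_signs(c_signs))
    if not ns and not cs:
        return LassoType(ns, cs, "L0", "L0", "L0")
    if not ns or not cs:
        signs, tail = (cs, "C") if cs else (ns, "N")
        klass, minor, major = _single_tail_label(signs, tail)
        return LassoType(ns, cs, klass, minor, major)
    i, j = len(ns), len(cs)
    if _is_supercoiled(ns) or _is_supercoiled(cs):
        minor = f"LLS{_ll_tail_token(ns)},{_ll_tail_token(cs)}"
        return LassoType(ns, cs, "LLS", minor, f"LLS{i},{j}")
    minor = f"LL{ns[0]}{i},{cs[0]}{j}"
    return LassoType(ns, cs, "LL", minor, f"LL{i},{j}")


# ---------------------------------------------------------------------------
# fingerprints
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Fingerprint:
    """Concatenated major labels of all pierced loops, in sequence order."""

    majors: tuple[str, ...]
    text: str

    @property
    def total_piercings(self) -> int:
        return sum(major_piercings(m) for m in self.majors)


def fingerprint(types: Sequence[LassoType | str]) -> Fingerprint:
    """Build the chain fingerprint from per-loop types in sequential order.

    ``L0`` entries are suppressed; runs of identical consecutive majors are
    compressed with a multiplicity prefix (``[L1, L1] -> "2L1"``).
    """
    majors = [t.major if isinstance(t, LassoType) else str(t) for t in types]
    majors = [m for m in majors if m != "L0"]
    parts: list[str] = []
    for major, run in itertools.groupby(majors):
        k = len(list(run))
        parts.append(major if k == 1 else f"{k}{major}")
    return Fingerprint(tuple(majors), "".join(parts))


_MAJOR_RE = re.compile(r"^(LLS|LL)(\d+),(\d+)$|^(LS|L)(\d+)$")


def parse_major(label: str) -> tuple[str, int, int]:
    """Parse a major label into ``(klass, n_piercings_N_or_total, c)``.

    Returns ``(klass, i, j)`` where single-tail classes use ``j == 0``.
    """
    label = label.replace("−", "-")
    m = _MAJOR_RE.match(label)
    if not m:
        raise FingerprintError(f"not a major lasso label: {label!r}")
    if m.group(1):
        i, j = int(m.group(2)), int(m.group(3))
        if i < 1 or j < 1:
            raise FingerprintError(f"two-sided label needs both tails: {label!r}")
        return m.group(1), i, j
    klass, n = m.group(4), int(m.group(5))
    if klass == "L" and n == 0:
        return "L0", 0, 0
    if n < 1 or (klass == "LS" and n < 2):
        raise FingerprintError(f"impossible piercing count in {label!r}")
    return klass, n, 0


def major_piercings(label: str) -> int:
    """Total piercings encoded by a major label (``LLi,j`` counts i+j)."""
    _, i, j = parse_major(label)
    return i + j


def _parse_items(text: str, pos: int) -> list[str] | None:
    """Backtracking parse of a fingerprint tail starting at ``pos``.

    Returns the expanded major list or None.  Counts and multiplicities are
    tried shortest-first, which resolves the grammar's inherent ambiguity
    the way the printed composites read (``L1L2L12L2`` = L1 L2 L1 2(L2)).
    """
    if pos == len(text):
        return []
    # optional multiplicity prefix
    mults: list[tuple[int, int]] = [(1, pos)]
    k = pos
    while k < len(text) and text[k].isdigit():
        k += 1
        mults.append((int(text[pos:k]), k))
    for mult, mpos in mults:
        if mult < 1 or mpos == len(text):
            continue
        for keyword in ("LLS", "LL", "LS", "L"):
            if not text.startswith(keyword, mpos):
                continue
            d = mpos + len(keyword)
            e = d
            while e < len(text) and text[e].isdigit():
                e += 1
            for stop in range(d + 1, e + 1):
                i = int(text[d:stop])
                if keyword in ("LL", "LLS"):
                    if stop == len(text) or text[stop] != ",":
                        continue
                    f = stop + 1
                    g = f
                    while g < len(text) and text[g].isdigit():
                        g += 1
                    for jstop in range(f + 1, g + 1):
                        j = int(text[f:jstop])
                        if i < 1 or j < 1:
                            continue
                        rest = _parse_items(text, jstop)
                        if rest is not None:
                            return [f"{keyword}{i},{j}"] * mult + rest
                else:
                    if i < 1 or (keyword == "LS" and i < 2):
                        continue
                    rest = _parse_items(text, stop)
                    if rest is not None:
                        return [f"{keyword}{i}"] * mult + rest
    return None


def parse_fingerprint(text: str) -> tuple[list[str], int]:
    """Parse a fingerprint string into its expanded major list.

    Returns ``(majors, total_piercings)``; the inverse of :func:`fingerprint`
    up to L0 suppression.

    >>> parse_fingerprint("LS32L1LS2")
    (['LS3', 'L1', 'L1', 'LS2'], 7)
    """
    text = text.replace("−", "-").strip()
    if not text:
        return [], 0
    majors = _parse_items(text, 0)
    if majors is None:
        # locate the longest parseable prefix for the error message
        for pos in range(len(text), -1, -1):
            if _parse_items(text[:pos], 0) is not None:
                raise FingerprintError("unparseable fingerprint", position=pos)
        raise FingerprintError("unparseable fingerprint", position=0)
    return majors, sum(major_piercings(m) for m in majors)


# ---------------------------------------------------------------------------
# minor labels and enumeration
# ---------------------------------------------------------------------------

_SINGLE_ALT_RE = re.compile(r"^L([+\-])(\d+)([NC])$")
_SINGLE_SC_RE = re.compile(r"^LS(\d+)([+\-]+)([NC])$")
_LL_RE = re.compile(r"^(LLS|LL)([^,]+),(.+)$")


def _alternating(first: Sign, n: int) -> tuple[Sign, ...]:
    other: Sign = "-" if first == "+" else "+"
    return tuple(first if k % 2 == 0 else other for k in range(n))


def _parse_ll_token(token: str) -> tuple[Sign, ...]:
    if token[0] in "+-":
        return _alternating(_norm_sign(token[0]), int(token[1:]))
    # supercoiled token: count prefix + explicit signs
    m = re.match(r"^(\d+)([+\-]+)$", token)
    if not m or len(m.group(2)) != int(m.group(1)):
        raise FingerprintError(f"bad two-sided tail token {token!r}")
    return tuple(_norm_signs(m.group(2)))


def parse_minor(label: str) -> tuple[tuple[Sign, ...], tuple[Sign, ...]]:
    """Invert a minor label into its ``(n_signs, c_signs)`` lists."""
    label = label.replace("−", "-")
    if label == "L0":
        return (), ()
    m = _SINGLE_ALT_RE.match(label)
    if m:
        signs = _alternating(_norm_sign(m.group(1)), int(m.group(2)))
        return (signs, ()) if m.group(3) == "N" else ((), signs)
    m = _SINGLE_SC_RE.match(label)
    if m:
        signs = tuple(_norm_signs(m.group(2)))
        if len(signs) != int(m.group(1)) or not _is_supercoiled(signs):
            raise FingerprintError(f"inconsistent supercoil label {label!r}")
        return (signs, ()) if m.group(3) == "N" else ((), signs)
    m = _LL_RE.match(label)
    if m:
        ns = _parse_ll_token(m.group(2))
        cs = _parse_ll_token(m.group(3))
        if classify_loop(ns, cs).minor != label:
            raise FingerprintError(f"inconsistent two-sided label {label!r}")
        return ns, cs
    raise FingerprintError(f"not a minor lasso label: {label!r}")


def _sign_seqs(n: int) -> list[tuple[Sign, ...]]:
    return [seq for seq in itertools.product("+-", repeat=n)]  # type: ignore[return-value]


def enumerate_minors(major: str) -> list[LassoType]:
    """All minor subtypes consistent with a major label.

    Single-tail majors expand over both tails and all admissible sign
    sequences; e.g. ``L1`` has exactly the four subtypes L+1N, L-1N,
    L+1C, L-1C.
    """
    klass, i, j = parse_major(major)
    out: list[LassoType] = []
    if klass == "L0":
        return [classify_loop((), ())]
    if klass in ("L", "LS"):
        want_sc = klass == "LS"
        for signs in _sign_seqs(i):
            if _is_supercoiled(signs) != want_sc:
                continue
            out.append(classify_loop(signs, ()))
            out.append(classify_loop((), signs))
        return out
    want_sc = klass == "LLS"
    for ns in _sign_seqs(i):
        for cs in _sign_seqs(j):
            if (_is_supercoiled(ns) or _is_supercoiled(cs)) != want_sc:
                continue
            out.append(classify_loop(ns, cs))
    return out


# ---------------------------------------------------------------------------
# evolution flower
# ---------------------------------------------------------------------------

def _apply_moves(
    ns: tuple[Sign, ...], cs: tuple[Sign, ...], move: str
) -> list[tuple[tuple[Sign, ...], tuple[Sign, ...]]]:
    results = []
    if move == "terminal_piercing":
        for s in "+-":
            results.append((ns + (s,), cs))
            results.append((ns, cs + (s,)))
        if ns:
            results.append((ns[:-1], cs))
        if cs:
            results.append((ns, cs[:-1]))
    elif move == "terminal_slipknot":
        for pair in (("+", "-"), ("-", "+")):
            results.append((ns + pair, cs))
            results.append((ns, cs + pair))
    else:
        raise ValueError(f"unknown flower move {move!r}")
    return results


def flower_neighbors(
    major: str,
    move: Literal["terminal_piercing", "terminal_slipknot"],
    level: Literal["major", "minor"] = "major",
) -> set[str]:
    """Lasso types reachable from ``major`` by one evolution-flower move.

    ``terminal_piercing`` appends or removes one piercing at the free end of
    either tail; ``terminal_slipknot`` appends an opposite-sign pair (a
    slipknot threaded through the loop) at a tail end.  The move is applied
    to every minor subtype of the given major and the resulting labels are
    collected at the requested level.
    """
    out: set[str] = set()
    for minor_type in enumerate_minors(major):
        for ns, cs in _apply_moves(minor_type.n_signs, minor_type.c_signs, move):
            t = classify_loop(ns, cs)
            out.add(t.major if level == "major" else t.minor)
    return out
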