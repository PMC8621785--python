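"""Deterministic lasso fixtures and random ideal chains.

``make_lasso_fixture`` builds, for any minor lasso label, a chain whose
covalent loop is a regular planar polygon closed by a synthetic disulfide,
with each prescribed piercing realised by routing the tail vertically
through the loop interior at laterally separated crossing points.  Because
the loop is planar, the minimal spanning surface is the flat polygon, so
the signed crossing sequence of the constructed chain is known exactly —
the fixtures are the ground-truth oracle for the whole detection pipeline.

``sample_ideal_chain`` draws closed equilateral random polygons with
freely-jointed tails (no excluded volume, unit bonds) for property tests
and Monte-Carlo piercing statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .classify import parse_minor
from .structure_io import Bridge, Chain, Residue

__all__ = [
    "FixtureSpec",
    "make_lasso_fixture",
    "make_multi_lasso_fixture",
    "sample_ideal_chain",
    "write_xyz",
    "write_pdb",
]


@dataclass
class FixtureSpec:
    """Recipe for a prescribed-lasso chain.

    minor_label    : target minor lasso label (classification grammar)
    loop_len       : residues in the covalent loop polygon (>= 6)
    tail_clearance : height (Angstrom) at which tails travel above/below
                     the loop plane between crossings
    bond_len       : loop CA-CA spacing (Angstrom)
    """

    minor_label: str
    loop_len: int = 12
    tail_clearance: float = 6.0
    bond_len: float = 3.8

    def __post_init__(self):
        if self.loop_len < 6:
            raise ValueError("loop_len must be >= 6")
        parse_minor(self.minor_label)  # validates the label


def _tail_waypoints(signs, x_offsets, y_off, attach_xy, radius, r_out, h):
    """Waypoints (one residue each) realising a signed crossing sequence.

    Returned in loop-outward order, starting just off the attachment
    vertex.  A ``+`` crossing rises through the loop plane, ``-`` descends;
    consecutive same-sign crossings wrap around the outside of the loop to
    return to the entry side.
    """
    pts: list[tuple[float, float, float]] = []
    u = attach_xy / np.linalg.norm(attach_xy)
    side = -h if signs[0] == "+" else h  # entry side of the first crossing
    exit_pt = (radius + 0.5 * r_out - 0.5 * radius) * u
    pts.append((exit_pt[0], exit_pt[1], side))
    for k, s in enumerate(signs):
        start = -h if s == "+" else h
        if side != start:
            # wrap outside the loop boundary to the required side
            pts.append((r_out, y_off, side))
            pts.append((r_out, y_off, start))
            side = start
        pts.append((x_offsets[k], y_off, side))
        pts.append((x_offsets[k], y_off, -side))  # the crossing segment
        side = -side
    # depth padding: march away so the final crossing is never "shallow"
    pts.append((r_out, y_off, side))
    for j in range(1, 6):
        pts.append((r_out + 3.8 * j, y_off, side))
    return pts


def make_lasso_fixture(spec: FixtureSpec | str, **kwargs) -> tuple[Chain, Bridge]:
    """Build a chain with a prescribed minor lasso type.

    Accepts a :class:`FixtureSpec` or a bare minor label.  The returned
    chain carries CYS residues with SG atoms at the bridge, so the full
    detection pipeline (bridge detection included) reproduces the label.
    Coordinates are deterministic: identical specs give identical chains.

    Raises
    ------
    ValueError
        If the label needs more crossings than fit inside the loop at the
        requested ``loop_len`` (use a larger loop).
    """
    if isinstance(spec, str):
        spec = FixtureSpec(spec, **kwargs)
    n_signs, c_signs = parse_minor(spec.minor_label)
    n = spec.loop_len
    radius = spec.bond_len / (2.0 * math.sin(math.pi / n))
    apothem = radius * math.cos(math.pi / n)
    h = spec.tail_clearance
    r_out = radius + 2.0 * spec.bond_len

    # loop polygon, counterclockwise seen from +z => surface normal +z;
    # vertex 0 sits on the -x axis, the bridge closes vertex n-1 -> 0
    theta = math.pi + 2.0 * math.pi * np.arange(n) / n
    loop_xy = radius * np.stack([np.cos(theta), np.sin(theta)], axis=1)

    def offsets(m: int) -> list[float]:
        dx = 3.0
        xs = [(k - (m - 1) / 2.0) * dx for k in range(m)]
        if xs and math.hypot(max(abs(x) for x in xs), 1.0) > 0.8 * apothem:
            raise ValueError(
                f"{spec.minor_label}: {m} crossings do not fit in a "
                f"{n}-residue loop; increase loop_len")
        return xs

    # N-tail: chain order runs toward the loop, so build the outward walk
    # with flipped crossing directions and reverse it
    n_walk = []
    if n_signs:
        flipped = ["-" if s == "+" else "+" for s in n_signs]
        n_walk = _tail_waypoints(
            flipped, offsets(len(n_signs)), -1.0, loop_xy[0], radius, r_out, h)
    c_walk = []
    if c_signs:
        c_walk = _tail_waypoints(
            c_signs, offsets(len(c_signs)), 1.0, loop_xy[n - 1], radius, r_out, h)

    coords: list[np.ndarray] = []
    for p in reversed(n_walk):
        coords.append(np.array(p, dtype=float))
    loop_start = len(coords) + 1
    for xy in loop_xy:
        coords.append(np.array([xy[0], xy[1], 0.0]))
    loop_end = loop_start + n - 1
    for p in c_walk:
        coords.append(np.array(p, dtype=float))

    residues = []
    for k, ca in enumerate(coords, start=1):
        residues.append(Residue(k, "GLY", ca))
    # synthetic disulfide: SG atoms placed between the two bridge CAs
    ca_i, ca_j = coords[loop_start - 1], coords[loop_end - 1]
    for idx, other in ((loop_start, ca_j), (loop_end, ca_i)):
        res = residues[idx - 1]
        res.name = "CYS"
        sg = res.ca + 0.3 * (other - res.ca)
        res.atoms = {"CA": res.ca, "SG": sg}
        res.element = {"CA": "C", "SG": "S"}
    chain = Chain("A", residues)
    chain.models.append(chain.ca)
    return chain, Bridge(loop_start, loop_end, "disulfide", "geometry")


def make_multi_lasso_fixture(labels, spacing: float = 80.0, **kwargs):
    """Concatenate single-loop fixtures along x into one multi-loop chain.

    Consecutive fixtures are joined by elevated connector residues routed
    around the outside of each loop, so no connector segment crosses any
    spanning surface.  Returns ``(chain, bridges)`` with bridges in loop
    order.
    """
    parts = [make_lasso_fixture(lbl, **kwargs) for lbl in labels]
    coords: list[np.ndarray] = []
    names: list[str] = []
    sgs: dict[int, np.ndarray] = {}
    bridges: list[Bridge] = []
    for k, (chain, bridge) in enumerate(parts):
        shift = np.array([k * spacing, 0.0, 0.0])
        if k > 0:
            # connector: climb vertically clear of the previous fixture,
            # travel high above both loop planes, drop onto the next
            # fixture's first residue; every connector segment is either
            # vertical over exterior ground or far above every surface
            prev_end = coords[-1]
            target = chain.residues[0].ca + shift
            high = 30.0
            coords.append(np.array([prev_end[0], prev_end[1], high]))
            coords.append(np.array([target[0], target[1], high]))
            names += ["GLY"] * 2
        offset = len(coords)
        for res in chain.residues:
            coords.append(res.ca + shift)
            names.append(res.name)
            if "SG" in res.atoms:
                sgs[offset + res.index] = res.atoms["SG"] + shift
        bridges.append(Bridge(offset + bridge.res_i, offset + bridge.res_j,
                              "disulfide", "geometry"))
    residues = []
    for k, ca in enumerate(coords, start=1):
        res = Residue(k, names[k - 1], ca)
        if k in sgs:
            res.atoms = {"CA": ca, "SG": sgs[k]}
            res.element = {"CA": "C", "SG": "S"}
        residues.append(res)
    chain = Chain("A", residues)
    chain.models.append(chain.ca)
    return chain, bridges


def sample_ideal_chain(loop_len: int, tail_len: int, seed: int) -> tuple[Chain, Bridge]:
    """Closed equilateral random loop plus a freely jointed tail.

    The loop is a closed walk of ``loop_len`` unit steps obtained by
    alternately removing the mean step and renormalising step lengths
    until both the closure defect and the bond-length defect fall below
    1e-13; the tail continues from the bridge residue with ``tail_len``
    uniform random unit steps.  All bond lengths, including the closing
    bridge bond, equal 1 within 1e-12 (dimensionless units).
    """
    if loop_len < 3:
        raise ValueError("loop_len must be >= 3")
    rng = np.random.default_rng(seed)
    steps = rng.normal(size=(loop_len, 3))
    steps /= np.linalg.norm(steps, axis=1, keepdims=True)
    for _ in range(10000):
        steps = steps - steps.mean(axis=0)
        norms = np.linalg.norm(steps, axis=1, keepdims=True)
        steps = steps / norms
        if (np.abs(norms - 1.0).max() < 1e-13
                and np.abs(steps.sum(axis=0)).max() < 1e-13):
            break
    pos = np.vstack([[0.0, 0.0, 0.0], np.cumsum(steps, axis=0)[:-1]])
    tail_steps = rng.normal(size=(tail_len, 3))
    tail_steps /= np.linalg.norm(tail_steps, axis=1, keepdims=True)
    tail = pos[-1] + np.cumsum(tail_steps, axis=0)
    coords = np.vstack([pos, tail])
    residues = [Residue(k, "GLY", ca) for k, ca in enumerate(coords, start=1)]
    chain = Chain("A", residues)
    chain.models.append(chain.ca)
    return chain, Bridge(1, loop_len, "link", "geometry")


def write_xyz(path, chain: Chain) -> None:
    """Write a chain in the plain ``index x y z`` dialect."""
    with open(path, "w") as fh:
        for r in chain.residues:
            fh.write(f"{r.index} {r.ca[0]:.6f} {r.ca[1]:.6f} {r.ca[2]:.6f}\n")


def write_pdb(path, chain: Chain, bridge: Bridge | None = None) -> None:
    """Write a minimal CA(+SG) PDB with an SSBOND record for the bridge."""
    lines = []
    if bridge is not None:
        lines.append(
            f"SSBOND   1 CYS {chain.cid} {bridge.res_i:4d}    "
            f"CYS {chain.cid} {bridge.res_j:4d}")
    serial = 1
    for r in chain.residues:
        for name in ("CA",) + (("SG",) if "SG" in r.atoms else ()):
            x, y, z = r.atoms.get(name, r.ca)
            elem = "S" if name == "SG" else "C"
            lines.append(
                f"ATOM  {serial:5d}  {name:<3s}{r.name:>4s} {chain.cid}"
                f"{r.index:4d}    {x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00"
                f"          {elem:>2s}")
            serial += 1
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
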