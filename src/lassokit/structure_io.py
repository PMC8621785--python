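"""Structure input, gap modelling, bridge detection and covalent loops.

Structures come from PDB/mmCIF files (parsed with gemmi) or from a plain
``xyz`` dialect (``index x y z`` per line) for generic polymers.  Residues
are renumbered 1-based and sequential; the author numbering is kept as
metadata.  Missing stretches (gaps) are modelled as straight intervals of
equidistant virtual residues so every chain has a contiguous CA trace.

A *bridge* is a loop-closing inter-residue bond.  Disulfides are detected
geometrically (CYS SG-SG within a threshold); other chemistries (amide,
ester, thioester, C-C) are accepted only from explicit LINK/struct_conn
records, because distance-inferred non-disulfide bonds are frequently
artefactual.  Each bridge spanning at least four residues defines a
covalent loop with its two terminal tails.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "Residue",
    "Gap",
    "Chain",
    "Bridge",
    "CovalentLoop",
    "ValidityReport",
    "read_structure",
    "model_gaps",
    "detect_bridges",
    "extract_loops",
    "validate",
    "write_bridge_table",
]

BACKBONE_ATOMS = {"N", "CA", "C", "O", "OXT"}

#: element pair (sorted) -> bridge chemistry; N-C amide-type, C-O ester-type,
#: C-S thioester-type, C-C aryl coupling, S-S disulfide
_CHEMISTRY = {
    ("S", "S"): "disulfide",
    ("C", "N"): "amide",
    ("C", "O"): "ester",
    ("C", "S"): "thioester",
    ("C", "C"): "CC",
}


@dataclass
class Residue:
    index: int  # 1-based sequential position within the chain
    name: str  # 3-letter residue code
    ca: np.ndarray  # CA coordinate (Angstrom)
    bfactor: float | None = None
    atoms: dict = field(default_factory=dict)  # atom name -> coordinate
    element: dict = field(default_factory=dict)  # atom name -> element symbol
    virtual: bool = False  # modelled-in gap residue
    auth_id: str | None = None  # author chain/seqid/icode from the file
    auth_key: tuple[int, str] | None = None  # (author seqid, icode)

    def __post_init__(self):
        self.ca = np.asarray(self.ca, dtype=float)


@dataclass
class Gap:
    """A stretch of residues missing from the file.

    Before gap modelling ``start``/``end`` are the flanking real residue
    indices; after modelling they delimit the inserted virtual residues.
    """

    start: int
    end: int
    n_missing: int
    modelled: bool = False
    auth_flanks: tuple[str, str] | None = None


@dataclass
class _RawLink:
    """A LINK/struct_conn record resolved to sequential residue indices."""

    res_i: int
    res_j: int
    atom_i: str
    atom_j: str
    elem_i: str
    elem_j: str


@dataclass
class Chain:
    cid: str
    residues: list[Residue]
    models: list[np.ndarray] = field(default_factory=list)  # CA sets, (n, 3)
    gaps: list[Gap] = field(default_factory=list)
    links: list[_RawLink] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def ca(self) -> np.ndarray:
        return np.array([r.ca for r in self.residues])

    @property
    def sequence(self) -> list[str]:
        return [r.name for r in self.residues]


@dataclass(frozen=True)
class Bridge:
    res_i: int
    res_j: int
    chemistry: str  # disulfide, amide, ester, thioester, thioether, ether, amine, CC, other
    source: str  # geometry | link_record

    def __post_init__(self):
        if self.res_i == self.res_j:
            raise ValueError("bridge endpoints must differ")
        if self.res_i > self.res_j:
            object.__setattr__(self, "res_i", self.res_j)
            object.__setattr__(self, "res_j", self.res_i)


@dataclass(frozen=True)
class CovalentLoop:
    """Backbone span closed by a bridge, plus its terminal tails."""

    bridge: Bridge
    res_i: int
    res_j: int
    chain_len: int

    @property
    def span(self) -> range:
        return range(self.res_i, self.res_j + 1)

    @property
    def n_tail(self) -> range:
        return range(1, self.res_i)

    @property
    def c_tail(self) -> range:
        return range(self.res_j + 1, self.chain_len + 1)


@dataclass
class ValidityReport:
    status: str  # "certain" | "artifact"
    reasons: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------

def read_structure(path, format: str | None = None) -> list[Chain]:
    """Read a structure file into chains.

    Parameters
    ----------
    path
        PDB, mmCIF or xyz file.
    format
        "pdb", "cif" or "xyz"; inferred from the suffix when omitted.

    Chains with fewer than 4 CA positions are skipped with a warning;
    HETATM-only chains are skipped.  NMR MODEL blocks populate
    ``Chain.models`` (the first model provides the working coordinates).
    """
    path = Path(path)
    if format is None:
        suffix = path.suffix.lower().lstrip(".")
        format = {"ent": "pdb", "mmcif": "cif"}.get(suffix, suffix)
    if format == "xyz":
        return _read_xyz(path)
    if format not in ("pdb", "cif"):
        raise ValueError(f"unknown structure format {format!r}")
    import gemmi

    fmt = gemmi.CoorFormat.Pdb if format == "pdb" else gemmi.CoorFormat.Mmcif
    st = gemmi.read_structure(str(path), format=fmt)
    st.setup_entities()
    return _chains_from_gemmi(st)


def _read_xyz(path: Path) -> list[Chain]:
    residues = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 4:
                raise ValueError(f"xyz line needs 'index x y z': {line!r}")
            residues.append((int(parts[0]), [float(x) for x in parts[1:4]]))
    residues.sort(key=lambda r: r[0])
    chain = Chain("A", [])
    prev_num = None
    for k, (num, xyz) in enumerate(residues, start=1):
        if prev_num is not None and num - prev_num > 1:
            chain.gaps.append(
                Gap(k - 1, k, num - prev_num - 1, auth_flanks=(str(prev_num), str(num)))
            )
        chain.residues.append(Residue(k, "UNK", xyz, auth_id=str(num)))
        prev_num = num
    return [chain]


def _chains_from_gemmi(st) -> list[Chain]:
    first = st[0]
    chains: list[Chain] = []
    index_map: dict[tuple[str, int, str], tuple[str, int]] = {}
    for gch in first:
        residues: list[Residue] = []
        any_atom_record = False
        prev_num = None
        gaps: list[Gap] = []
        for gres in gch:
            if gres.is_water():
                continue
            atoms: dict[str, np.ndarray] = {}
            elements: dict[str, str] = {}
            occ: dict[str, float] = {}
            bfac = None
            for atom in gres:
                name = atom.name
                if name in atoms and atom.occ <= occ.get(name, -1.0):
                    continue  # keep the highest-occupancy altLoc
                atoms[name] = np.array([atom.pos.x, atom.pos.y, atom.pos.z])
                elements[name] = atom.element.name.upper()
                occ[name] = atom.occ
                if name == "CA":
                    bfac = atom.b_iso
            if "CA" not in atoms:
                continue
            if gres.het_flag == "A":
                any_atom_record = True
            num = gres.seqid.num
            k = len(residues) + 1
            if prev_num is not None and num - prev_num > 1:
                gaps.append(Gap(k - 1, k, num - prev_num - 1,
                                auth_flanks=(str(prev_num), str(num))))
            icode = gres.seqid.icode.strip()
            auth = f"{gch.name}/{num}{icode}"
            residues.append(
                Residue(k, gres.name, atoms["CA"], bfac, atoms, elements,
                        auth_id=auth, auth_key=(num, icode))
            )
            index_map[(gch.name, num, gres.seqid.icode.strip())] = (gch.name, k)
            prev_num = num
        if len(residues) < 4:
            if residues:
                warnings.warn(f"chain {gch.name}: fewer than 4 CA atoms, skipped")
            continue
        if not any_atom_record:
            continue  # HETATM-only chain
        ch = Chain(gch.name, residues, gaps=gaps)
        ch.models.append(ch.ca)
        chains.append(ch)

    # additional NMR models: matched by author numbering
    for model in list(st)[1:]:
        for ch in chains:
            gch = None
            for cand in model:
                if cand.name == ch.cid:
                    gch = cand
                    break
            if gch is None:
                continue
            coords = {}
            for gres in gch:
                ca = gres.find_atom("CA", "*")
                if ca is not None:
                    coords[(gres.seqid.num, gres.seqid.icode.strip())] = (
                        np.array([ca.pos.x, ca.pos.y, ca.pos.z]))
            try:
                arr = np.array([coords[r.auth_key] for r in ch.residues])
            except KeyError:
                warnings.warn(
                    f"chain {ch.cid}: model with mismatched residues ignored")
                continue
            ch.models.append(arr)

    # LINK / struct_conn records resolved to sequential indices
    for con in st.connections:
        p1, p2 = con.partner1, con.partner2
        key1 = (p1.chain_name, p1.res_id.seqid.num, p1.res_id.seqid.icode.strip())
        key2 = (p2.chain_name, p2.res_id.seqid.num, p2.res_id.seqid.icode.strip())
        if key1 not in index_map or key2 not in index_map:
            continue
        (c1, i1), (c2, i2) = index_map[key1], index_map[key2]
        if c1 != c2:
            continue  # inter-chain bond: no covalent loop on a single chain
        for ch in chains:
            if ch.cid != c1:
                continue
            r1, r2 = ch.residues[i1 - 1], ch.residues[i2 - 1]
            a1, a2 = p1.atom_name, p2.atom_name
            if a1 not in r1.atoms or a2 not in r2.atoms:
                warnings.warn(
                    f"LINK names missing atom ({a1}/{a2}); record dropped")
                continue
            ch.links.append(
                _RawLink(i1, i2, a1, a2, r1.element[a1], r2.element[a2]))
    return chains


# ---------------------------------------------------------------------------
# gap modelling
# ---------------------------------------------------------------------------

def model_gaps(chain: Chain) -> Chain:
    """Model every gap as a straight interval of equidistant virtual residues.

    A gap of *g* missing residues between flanking CAs *p* and *q* gets
    virtual CAs at ``p + (q - p) * k / (g + 1)`` for ``k = 1..g``.  The
    operation is idempotent; gap records are retained and re-pointed at
    the inserted span.
    """
    if len(chain) < 2:
        raise ValueError("gap modelling needs a chain of >= 2 residues")
    pending = [g for g in chain.gaps if not g.modelled]
    if not pending:
        return chain
    new_residues: list[Residue] = []
    new_models: list[list[np.ndarray]] = [[] for _ in chain.models]
    by_start = {g.start: g for g in pending}
    for res in chain.residues:
        new_residues.append(res)
        for mi, mdl in enumerate(chain.models):
            new_models[mi].append(mdl[res.index - 1])
        gap = by_start.get(res.index)
        if gap is None:
            continue
        nxt = chain.residues[gap.end - 1]
        g = gap.n_missing
        first_virtual = len(new_residues) + 1
        for k in range(1, g + 1):
            frac = k / (g + 1)
            ca = res.ca + (nxt.ca - res.ca) * frac
            new_residues.append(Residue(0, "UNK", ca, virtual=True))
            for mi, mdl in enumerate(chain.models):
                p, q = mdl[res.index - 1], mdl[nxt.index - 1]
                new_models[mi].append(p + (q - p) * frac)
        gap.start, gap.end = first_virtual, first_virtual + g - 1
        gap.modelled = True
    for k, res in enumerate(new_residues, start=1):
        res.index = k
    chain.residues = new_residues
    chain.models = [np.array(m) for m in new_models]
    return chain


# ---------------------------------------------------------------------------
# bridges and loops
# ---------------------------------------------------------------------------

def detect_bridges(
    chain: Chain,
    max_ss_dist: float = 2.5,
    use_links: bool = True,
    permissive: bool = False,
    permissive_dist: float = 1.8,
) -> list[Bridge]:
    """Detect loop-closing bridges on one chain.

    Disulfides are found geometrically: CYS SG-SG pairs within
    ``max_ss_dist`` Angstrom.  Non-disulfide chemistries come from
    LINK/struct_conn records between atoms of two residues of the same
    chain (at least one atom side-chain), with the chemistry inferred from
    the element pair.  Bonds between sequence-adjacent residues (peptide
    bonds) are excluded.  ``permissive`` additionally infers bonds from
    side-chain heavy-atom pairs closer than ``permissive_dist``.
    """
    found: dict[tuple[int, int], Bridge] = {}
    cys = [r for r in chain.residues if r.name == "CYS" and "SG" in r.atoms]
    for a in range(len(cys)):
        for b in range(a + 1, len(cys)):
            ri, rj = cys[a], cys[b]
            if abs(ri.index - rj.index) <= 1:
                continue
            if np.linalg.norm(ri.atoms["SG"] - rj.atoms["SG"]) <= max_ss_dist:
                key = (min(ri.index, rj.index), max(ri.index, rj.index))
                found[key] = Bridge(key[0], key[1], "disulfide", "geometry")
    if use_links:
        for link in chain.links:
            if abs(link.res_i - link.res_j) <= 1:
                continue
            if link.atom_i in BACKBONE_ATOMS and link.atom_j in BACKBONE_ATOMS:
                continue
            key = (min(link.res_i, link.res_j), max(link.res_i, link.res_j))
            if key in found:
                continue
            chem = _CHEMISTRY.get(tuple(sorted((link.elem_i, link.elem_j))), "other")
            found[key] = Bridge(key[0], key[1], chem, "link_record")
    if permissive:
        for ri in chain.residues:
            for rj in chain.residues:
                if rj.index - ri.index <= 1:
                    continue
                for ai, pi in ri.atoms.items():
                    if ai in BACKBONE_ATOMS or ri.element.get(ai) == "H":
                        continue
                    for aj, pj in rj.atoms.items():
                        if aj in BACKBONE_ATOMS or rj.element.get(aj) == "H":
                            continue
                        if np.linalg.norm(pi - pj) <= permissive_dist:
                            key = (ri.index, rj.index)
                            if key not in found:
                                chem = _CHEMISTRY.get(
                                    tuple(sorted((ri.element[ai], rj.element[aj]))),
                                    "other")
                                found[key] = Bridge(key[0], key[1], chem, "geometry")
    return sorted(found.values(), key=lambda b: (b.res_i, b.res_j))


def extract_loops(chain: Chain, bridges: list[Bridge]) -> list[CovalentLoop]:
    """One covalent loop per bridge, sorted by loop start.

    Bridges spanning fewer than 4 residues cannot close a meaningful loop
    and are omitted with a warning.  Overlapping and nested loops are all
    retained (multi-loop chains are real).
    """
    loops = []
    for b in bridges:
        if b.res_j - b.res_i + 1 < 4:
            warnings.warn(
                f"bridge ({b.res_i},{b.res_j}): span shorter than 4 residues, omitted")
            continue
        loops.append(CovalentLoop(b, b.res_i, b.res_j, len(chain)))
    return sorted(loops, key=lambda l: (l.res_i, l.res_j))


def validate(
    chain: Chain,
    loop: CovalentLoop,
    max_loop_gap: int = 2,
    piercings=None,
    piercing_margin: int = 3,
) -> ValidityReport:
    """Flag chains whose lasso assignment is geometrically uncertain.

    A loop is an artifact when a gap longer than ``max_loop_gap`` lies
    inside the loop span, when any gap lies within ``piercing_margin``
    residues of a detected piercing segment, or when a bridge atom was
    absent.  Otherwise the assignment is topologically certain.
    """
    reasons: list[str] = []
    if len(chain) < 4:
        reasons.append("chain-too-short")
    for gap in chain.gaps:
        lo, hi = gap.start, gap.end
        if gap.n_missing > max_loop_gap and lo <= loop.res_j and hi >= loop.res_i:
            reasons.append("gap-in-loop")
        if piercings:
            for p in piercings:
                a, b = p.crossing.segment
                if lo <= b + piercing_margin and hi >= a - piercing_margin:
                    reasons.append("gap-near-piercing")
                    break
    for idx in (loop.bridge.res_i, loop.bridge.res_j):
        res = chain.residues[idx - 1]
        # a cysteine residue that lost its SG cannot support the claimed
        # disulfide; atom-less generic polymers (xyz) are not penalised
        if (loop.bridge.chemistry == "disulfide" and res.name == "CYS"
                and "SG" not in res.atoms):
            reasons.append("missing-bridge-atom")
    reasons = sorted(set(reasons))
    return ValidityReport("artifact" if reasons else "certain", reasons)


def write_bridge_table(path, chain: Chain, loops, reports=None) -> None:
    """Write a loop/bridge TSV: chain, res_i, res_j, chemistry, status."""
    import pandas as pd

    rows = []
    for k, loop in enumerate(loops):
        status = reports[k].status if reports else ""
        rows.append(
            dict(chain=chain.cid, res_i=loop.res_i, res_j=loop.res_j,
                 chemistry=loop.bridge.chemistry, status=status))
    pd.DataFrame(rows, columns=["chain", "res_i", "res_j", "chemistry", "status"]
                 ).to_csv(path, sep="\t", index=False)
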