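"""Shared fixtures: label enumeration and tiny text-format structures."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from lassokit.classify import classify_loop


def all_minor_labels(max_piercings: int = 3) -> list[str]:
    """Every minor lasso label realisable with at most ``max_piercings``."""
    labels = set()
    for total in range(1, max_piercings + 1):
        for signs in itertools.product("+-", repeat=total):
            labels.add(classify_loop(signs, ()).minor)
            labels.add(classify_loop((), signs).minor)
        for i in range(1, total):
            for ns in itertools.product("+-", repeat=i):
                for cs in itertools.product("+-", repeat=total - i):
                    labels.add(classify_loop(ns, cs).minor)
    return sorted(labels)


def pdb_lines(records: list[str]) -> str:
    return "\n".join(records) + "\nEND\n"


def atom_record(serial, name, resname, chain, resseq, x, y, z,
                bfac=0.0, element=None, het=False) -> str:
    element = element or name[0]
    tag = "HETATM" if het else "ATOM  "
    return (f"{tag}{serial:5d}  {name:<3s}{resname:>4s} {chain}{resseq:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00{bfac:6.2f}          {element:>2s}")


@pytest.fixture
def gapped_pdb(tmp_path):
    """Chain with author numbering 10, 11, 15 (a 3-residue gap after 11)."""
    lines = []
    coords = [(0, 0, 0), (3.8, 0, 0), (19.0, 0, 0)]
    for k, (num, xyz) in enumerate(zip((10, 11, 15), coords), start=1):
        lines.append(atom_record(k, "CA", "GLY", "A", num, *xyz))
    # pad to >= 4 CA so the chain is not skipped
    lines.append(atom_record(4, "CA", "GLY", "A", 16, 22.8, 0, 0))
    lines.append(atom_record(5, "CA", "GLY", "A", 17, 26.6, 0, 0))
    path = tmp_path / "gapped.pdb"
    path.write_text(pdb_lines(lines))
    return path


@pytest.fixture
def two_model_pdb(tmp_path):
    """Minimal NMR-style entry with two MODEL blocks, shifted at residue 3."""
    def block(n, shift):
        rows = [f"MODEL {n:8d}"]
        for k in range(1, 6):
            dz = shift if k == 3 else 0.0
            rows.append(atom_record(k, "CA", "ALA", "A", k, 3.8 * k, 0.0, dz))
        rows.append("ENDMDL")
        return rows

    path = tmp_path / "nmr.pdb"
    path.write_text(pdb_lines(block(1, 0.0) + block(2, 2.0)))
    return path


@pytest.fixture
def disulfide_pdb(tmp_path):
    """Six-residue chain with one geometric CYS SG-SG disulfide (1-6)."""
    lines = []
    serial = 1
    zig = [(0, 0, 0), (3.8, 0, 0), (7.6, 1, 0), (7.6, 4.8, 0), (3.8, 5.8, 0), (0, 3.8, 0)]
    for k, xyz in enumerate(zig, start=1):
        name = "CYS" if k in (1, 6) else "GLY"
        lines.append(atom_record(serial, "CA", name, "A", k, *xyz))
        serial += 1
        if k in (1, 6):
            # SG atoms 2.0 apart between the terminal CAs
            sx = 0.0 if k == 1 else 0.0
            sy = 0.9 if k == 1 else 2.9
            lines.append(atom_record(serial, "SG", "CYS", "A", k, sx, sy, 0.0,
                                     element="S"))
            serial += 1
    path = tmp_path / "ss.pdb"
    path.write_text(pdb_lines(lines))
    return path


@pytest.fixture
def link_pdb(tmp_path):
    """Miniprotein-style amide: LYS side-chain NZ linked to a backbone C."""
    lines = [
        "LINK         NZ  LYS A   2                 C   GLY A   8",
    ]
    serial = 1
    for k in range(1, 9):
        resname = "LYS" if k == 2 else "GLY"
        lines.append(atom_record(serial, "CA", resname, "A", k, 3.8 * k, 0, 0))
        serial += 1
        if k == 2:
            lines.append(atom_record(serial, "NZ", "LYS", "A", k, 7.6, 1.4, 0,
                                     element="N"))
            serial += 1
        if k == 8:
            lines.append(atom_record(serial, "C", "GLY", "A", k, 30.9, 0.7, 0))
            serial += 1
    path = tmp_path / "link.pdb"
    path.write_text(pdb_lines(lines))
    return path
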