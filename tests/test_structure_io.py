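"""Structure reading, gap modelling, bridge and loop extraction, validity."""

import numpy as np
import pytest

from lassokit.structure_io import (Bridge, Chain, Gap, Residue,
                                   detect_bridges, extract_loops, model_gaps,
                                   read_structure, validate)


def straight_chain(n, spacing=3.8, gaps=None):
    residues = [Residue(k, "GLY", [spacing * (k - 1), 0, 0]) for k in range(1, n + 1)]
    return Chain("A", residues, gaps=list(gaps or []))


# -- reading -----------------------------------------------------------------

def test_xyz_identity_parse(tmp_path):
    path = tmp_path / "chain.xyz"
    path.write_text("1 0 0 0\n2 1 0 0\n3 2 0 0\n")
    (chain,) = read_structure(path)
    assert len(chain) == 3
    np.testing.assert_allclose(chain.residues[1].ca, [1, 0, 0])


def test_xyz_gap_from_index_delta(tmp_path):
    path = tmp_path / "chain.xyz"
    path.write_text("1 0 0 0\n2 1 0 0\n5 4 0 0\n6 5 0 0\n")
    (chain,) = read_structure(path)
    assert [(g.start, g.end, g.n_missing) for g in chain.gaps] == [(2, 3, 2)]


def test_pdb_numbering_gap_recorded(gapped_pdb):
    (chain,) = read_structure(gapped_pdb)
    assert len(chain.gaps) == 1
    gap = chain.gaps[0]
    assert gap.n_missing == 3
    assert gap.auth_flanks == ("11", "15")


def test_pdb_two_models_equal_residues(two_model_pdb):
    (chain,) = read_structure(two_model_pdb)
    assert len(chain.models) == 2
    assert chain.models[0].shape == chain.models[1].shape == (5, 3)
    # models differ only at residue 3
    diff = np.linalg.norm(chain.models[0] - chain.models[1], axis=1)
    assert diff[2] == pytest.approx(2.0)
    assert np.all(diff[[0, 1, 3, 4]] == 0)


def test_short_chain_skipped_with_warning(tmp_path):
    from conftest import atom_record, pdb_lines

    path = tmp_path / "short.pdb"
    path.write_text(pdb_lines(
        [atom_record(k, "CA", "GLY", "A", k, 3.8 * k, 0, 0) for k in (1, 2, 3)]))
    with pytest.warns(UserWarning):
        chains = read_structure(path)
    assert chains == []


def test_unreadable_file_raises(tmp_path):
    with pytest.raises(Exception):
        read_structure(tmp_path / "missing.pdb")


# -- gap modelling -----------------------------------------------------------

def test_gap_of_one_midpoint():
    chain = straight_chain(2, spacing=3.0)
    chain.residues[0].ca = np.array([0.0, 0.0, 0.0])
    chain.residues[1].ca = np.array([0.0, 0.0, 3.0])
    chain.gaps = [Gap(1, 2, 1)]
    model_gaps(chain)
    assert len(chain) == 3
    np.testing.assert_allclose(chain.residues[1].ca, [0, 0, 1.5])
    assert chain.residues[1].virtual


def test_gap_of_three_equidistant():
    chain = straight_chain(2)
    chain.residues[0].ca = np.array([0.0, 0.0, 0.0])
    chain.residues[1].ca = np.array([4.0, 0.0, 0.0])
    chain.gaps = [Gap(1, 2, 3)]
    model_gaps(chain)
    xs = [r.ca[0] for r in chain.residues]
    assert xs == pytest.approx([0.0, 1.0, 2.0, 3.0, 4.0])
    assert chain.gaps[0].modelled
    assert (chain.gaps[0].start, chain.gaps[0].end) == (2, 4)


def test_no_gaps_identity():
    chain = straight_chain(5)
    before = chain.ca.copy()
    model_gaps(chain)
    np.testing.assert_array_equal(chain.ca, before)


def test_gap_modelling_idempotent():
    chain = straight_chain(3)
    chain.gaps = [Gap(2, 3, 2)]
    model_gaps(chain)
    first = chain.ca.copy()
    model_gaps(chain)
    np.testing.assert_array_equal(chain.ca, first)
    assert len(chain.gaps) == 1


def test_gap_modelling_applies_to_all_models():
    chain = straight_chain(3)
    chain.models = [chain.ca, chain.ca + np.array([0, 0, 1.0])]
    chain.gaps = [Gap(1, 2, 1)]
    model_gaps(chain)
    assert all(m.shape == (4, 3) for m in chain.models)
    np.testing.assert_allclose(chain.models[1][1], [1.9, 0, 1.0])


# -- bridges -----------------------------------------------------------------

def _cys_pair_chain(sg_dist):
    chain = straight_chain(8)
    for idx in (2, 7):
        res = chain.residues[idx - 1]
        res.name = "CYS"
        res.atoms = {"CA": res.ca, "SG": res.ca + np.array([0, 1.0, 0])}
        res.element = {"CA": "C", "SG": "S"}
    chain.residues[6].atoms["SG"] = chain.residues[1].atoms["SG"] + \
        np.array([sg_dist, 0, 0])
    return chain


def test_disulfide_within_threshold():
    bridges = detect_bridges(_cys_pair_chain(2.05))
    assert [(b.res_i, b.res_j, b.chemistry) for b in bridges] == \
        [(2, 7, "disulfide")]


def test_no_disulfide_beyond_threshold():
    assert detect_bridges(_cys_pair_chain(4.0)) == []


def test_disulfide_threshold_configurable():
    assert len(detect_bridges(_cys_pair_chain(4.0), max_ss_dist=4.5)) == 1


def test_geometric_pdb_disulfide(disulfide_pdb):
    (chain,) = read_structure(disulfide_pdb)
    bridges = detect_bridges(chain)
    assert [(b.res_i, b.res_j, b.chemistry) for b in bridges] == \
        [(1, 6, "disulfide")]


def test_link_record_gives_amide_bridge(link_pdb):
    """A LYS side-chain N bonded to a backbone C closes an amide loop."""
    (chain,) = read_structure(link_pdb)
    bridges = detect_bridges(chain)
    assert [(b.res_i, b.res_j, b.chemistry, b.source) for b in bridges] == \
        [(2, 8, "amide", "link_record")]


def test_bridges_invariant_under_rigid_motion():
    from scipy.spatial.transform import Rotation

    chain = _cys_pair_chain(2.05)
    ref = detect_bridges(chain)
    rot = Rotation.from_euler("xyz", [0.5, 1.0, -0.3]).as_matrix()
    shift = np.array([4.0, 5.0, 6.0])
    for res in chain.residues:
        res.ca = res.ca @ rot.T + shift
        res.atoms = {k: v @ rot.T + shift for k, v in res.atoms.items()}
    moved = detect_bridges(chain)
    assert [(b.res_i, b.res_j) for b in moved] == [(b.res_i, b.res_j) for b in ref]


# -- loops -------------------------------------------------------------------

def test_loop_span_and_tails():
    chain = straight_chain(50)
    (loop,) = extract_loops(chain, [Bridge(10, 30, "disulfide", "geometry")])
    assert (loop.res_i, loop.res_j) == (10, 30)
    assert list(loop.n_tail) == list(range(1, 10))
    assert list(loop.c_tail) == list(range(31, 51))


def test_loops_sorted_and_all_retained():
    chain = straight_chain(50)
    bridges = [Bridge(35, 45, "disulfide", "geometry"),
               Bridge(10, 30, "disulfide", "geometry")]
    loops = extract_loops(chain, bridges)
    assert [(l.res_i, l.res_j) for l in loops] == [(10, 30), (35, 45)]


def test_short_span_omitted():
    chain = straight_chain(20)
    with pytest.warns(UserWarning):
        loops = extract_loops(chain, [Bridge(5, 7, "disulfide", "geometry")])
    assert loops == []


# -- validity ----------------------------------------------------------------

def test_large_gap_in_loop_is_artifact():
    chain = straight_chain(40)
    chain.gaps = [Gap(15, 19, 5, modelled=True)]
    (loop,) = extract_loops(chain, [Bridge(10, 30, "disulfide", "geometry")])
    report = validate(chain, loop)
    assert report.status == "artifact"
    assert "gap-in-loop" in report.reasons


def test_small_gap_in_loop_is_certain():
    chain = straight_chain(40)
    chain.gaps = [Gap(15, 15, 1, modelled=True)]
    (loop,) = extract_loops(chain, [Bridge(10, 30, "disulfide", "geometry")])
    assert validate(chain, loop).status == "certain"


def test_gap_free_chain_certain():
    chain = straight_chain(40)
    (loop,) = extract_loops(chain, [Bridge(10, 30, "disulfide", "geometry")])
    report = validate(chain, loop)
    assert report.status == "certain" and report.reasons == []


def test_gap_near_piercing_is_artifact():
    from lassokit.piercing import Crossing, Piercing

    chain = straight_chain(40)
    chain.gaps = [Gap(33, 33, 1, modelled=True)]
    (loop,) = extract_loops(chain, [Bridge(10, 30, "disulfide", "geometry")])
    piercing = Piercing(
        Crossing("C", (34, 35), "+", np.zeros(3), 0.5, 4), 6, 1)
    report = validate(chain, loop, piercings=[piercing])
    assert report.status == "artifact"
    assert "gap-near-piercing" in report.reasons
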