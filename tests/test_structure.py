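"""PDB handling, metal sites, amide building, distances, blind sphere."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from clusterblind import (
    Atom,
    Structure,
    ToySiteSpec,
    blind_sphere_radius,
    build_amide_protons,
    count_protons_within,
    covalent_graph,
    find_metal_sites,
    load_structure,
    make_toy_structure,
    metal_proton_distances,
    write_structure,
)
from clusterblind.structure import PDBParseError, table_ids

TWO_ATOM_PDB = """\
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00  0.00           N
ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00  0.00           C
END
"""


def _tripeptide():
    """Gly tripeptide with ideal-ish planar backbone geometry."""
    atoms = []
    # residue 1: only C matters for the amide of residue 2
    atoms.append(Atom("A", 1, "GLY", "N", "N", (0.0, 1.4, 0.0)))
    atoms.append(Atom("A", 1, "GLY", "CA", "C", (0.8, 0.5, 0.0)))
    atoms.append(Atom("A", 1, "GLY", "C", "C", (0.0, -0.8, 0.0)))
    # residue 2: N at origin, CA along +x; C(1)-N-CA all in z=0 plane
    atoms.append(Atom("A", 2, "GLY", "N", "N", (0.0, 0.5, 0.0)))
    atoms.append(Atom("A", 2, "GLY", "CA", "C", (1.2, 1.2, 0.0)))
    atoms.append(Atom("A", 2, "GLY", "C", "C", (2.2, 0.2, 0.0)))
    # residue 3 with complete backbone
    atoms.append(Atom("A", 3, "GLY", "N", "N", (3.2, 0.9, 0.0)))
    atoms.append(Atom("A", 3, "GLY", "CA", "C", (4.5, 0.4, 0.0)))
    atoms.append(Atom("A", 3, "GLY", "C", "C", (5.4, 1.5, 0.0)))
    return Structure(atoms)


def test_load_minimal_pdb():
    s = load_structure(TWO_ATOM_PDB)
    assert len(s.atoms) == 2
    assert s.atoms[0].element == "N"
    assert s.atoms[0].xyz == pytest.approx((11.104, 6.134, -6.504))


def test_malformed_record_names_the_line():
    bad = TWO_ATOM_PDB.replace("11.639", "xx.yyy")
    with pytest.raises(PDBParseError, match="line 2"):
        load_structure(bad)
    with pytest.raises(PDBParseError, match="no ATOM/HETATM"):
        load_structure("REMARK nothing here\nEND\n")


def test_altloc_resolved_to_highest_occupancy():
    pdb = (
        "ATOM      1  CA AALA A   1       0.000   0.000   0.000  0.40  0.00           C\n"
        "ATOM      2  CA BALA A   1       1.000   0.000   0.000  0.60  0.00           C\n"
        "END\n"
    )
    s = load_structure(pdb)
    assert len(s.atoms) == 1
    assert s.atoms[0].xyz[0] == pytest.approx(1.0)


def test_toy_structure_roundtrips_through_pdb(toy_site):
    s, _ = toy_site
    s2 = load_structure(write_structure(s))
    assert len(s2.atoms) == len(s.atoms)
    by_id = {a.atom_id(): np.array(a.xyz) for a in s.atoms}
    for a in s2.atoms:
        assert np.allclose(np.array(a.xyz), by_id[a.atom_id()], atol=1e-3)


def test_find_metal_sites_toy_cluster(toy_site):
    s, _ = toy_site
    sites = find_metal_sites(s)
    assert len(sites) == 2
    assert sites[0].cluster_id == sites[1].cluster_id
    with pytest.raises(ValueError, match="no metal site"):
        find_metal_sites(s, {"Zn"})


def test_two_separated_clusters_get_distinct_ids():
    """A dimer-like arrangement: 4 Fe in two pairs 30 A apart -> 2 clusters."""
    atoms = []
    for i, offset in enumerate([0.0, 30.0]):
        atoms.append(Atom("A", 201 + i, "FES", "FE1", "FE",
                          (offset, 0.0, 0.0), het=True))
        atoms.append(Atom("A", 201 + i, "FES", "FE2", "FE",
                          (offset + 2.7, 0.0, 0.0), het=True))
    sites = find_metal_sites(Structure(atoms))
    assert len(sites) == 4
    assert len({m.cluster_id for m in sites}) == 2


def test_metal_proton_distance_hand_oracle():
    atoms = [
        Atom("A", 201, "FES", "FE1", "FE", (0.0, 0.0, 0.0), het=True),
        Atom("A", 201, "FES", "FE2", "FE", (10.0, 0.0, 0.0), het=True),
        Atom("A", 1, "GLY", "H", "H", (3.0, 4.0, 0.0)),
    ]
    s = Structure(atoms)
    d = metal_proton_distances(s, find_metal_sites(s))
    assert len(d) == 1
    assert d.iloc[0]["r_angstrom"] == pytest.approx(5.0)
    assert d.iloc[0]["fe_label"] == "FE1"


def test_coincident_proton_flagged_degenerate():
    atoms = [
        Atom("A", 201, "FES", "FE1", "FE", (0.0, 0.0, 0.0), het=True),
        Atom("A", 1, "GLY", "H", "H", (0.0, 0.0, 0.0)),
    ]
    s = Structure(atoms)
    d = metal_proton_distances(s, find_metal_sites(s))
    assert bool(d.iloc[0]["degenerate"])
    assert count_protons_within(d, 10.0) == 0   # degenerate rows excluded


def test_amide_proton_geometry():
    s = build_amide_protons(_tripeptide())
    h2 = s.find("A", 2, "H")
    h3 = s.find("A", 3, "H")
    assert h2 is not None and h3 is not None
    n = np.array(s.find("A", 2, "N").xyz)
    ca = np.array(s.find("A", 2, "CA").xyz)
    c_prev = np.array(s.find("A", 1, "C").xyz)
    h = np.array(h2.xyz)
    assert np.linalg.norm(h - n) == pytest.approx(1.01, abs=1e-3)
    assert h[2] == pytest.approx(0.0, abs=1e-9)   # stays in the backbone plane

    def angle(a, b, c):
        u, v = a - b, c - b
        return np.degrees(np.arccos(u @ v / np.linalg.norm(u) / np.linalg.norm(v)))

    assert angle(h, n, ca) == pytest.approx(angle(h, n, c_prev), abs=1e-6)


def test_amide_building_is_idempotent_and_skips_n_terminus():
    s1 = build_amide_protons(_tripeptide())
    s2 = build_amide_protons(s1)
    assert len(s2.atoms) == len(s1.atoms)
    h_ids = sorted(a.atom_id() for a in s1.atoms if a.is_hydrogen)
    assert h_ids == ["A:2:H", "A:3:H"]          # no H on the N-terminal residue
    # existing H coordinates untouched
    for a, b in zip(s1.atoms, s2.atoms):
        assert a.xyz == b.xyz


def test_amide_count_matches_independent_residue_scan():
    """On a synthetic chain, the number of built H equals the count of
    non-Pro, non-terminal residues with complete backbone."""
    rng = np.random.default_rng(5)
    atoms = []
    n_res = 12
    for i in range(1, n_res + 1):
        resname = "PRO" if i in (4, 9) else "ALA"
        base = np.array([3.3 * i, 0.0, 0.0])
        atoms.append(Atom("A", i, resname, "N", "N", tuple(base)))
        atoms.append(Atom("A", i, resname, "CA", "C",
                          tuple(base + [1.2, 0.9, 0.0])))
        # C placed to bond the next residue's N (~1.4 A away from it)
        atoms.append(Atom("A", i, resname, "C", "C",
                          tuple(base + [2.4, 0.2, 0.0])))
    s = Structure(atoms)
    built = build_amide_protons(s)
    n_h = sum(1 for a in built.atoms if a.name == "H")
    expected = sum(
        1 for i in range(2, n_res + 1) if ("PRO" if i in (4, 9) else "ALA") != "PRO"
    )
    assert n_h == expected


def test_count_protons_within_reference_table(reference_distances):
    assert count_protons_within(reference_distances, 4.0) == 9
    assert count_protons_within(reference_distances.iloc[0:0], 4.0) == 0
    with pytest.raises(ValueError):
        count_protons_within(reference_distances, -1.0)


@given(st.floats(min_value=0.5, max_value=15.0), st.floats(min_value=0.0, max_value=5.0))
def test_count_monotone_in_radius(radius, bump):
    from clusterblind.io import load_reference_distances

    d = load_reference_distances()
    assert count_protons_within(d, radius + bump + 1e-9) >= \
        count_protons_within(d, radius)


def test_blind_sphere_rule(reference_distances):
    table = pd.DataFrame({
        "chain": ["A"] * 4, "resnum": [1, 2, 3, 4], "resname": ["ALA"] * 4,
        "atom": ["H"] * 4, "fe_label": ["FE1"] * 4,
        "r_angstrom": [3.0, 5.5, 7.9, 14.0], "bonds": [np.nan] * 4,
        "fe_coord_label": [None] * 4, "r_coord_angstrom": [np.nan] * 4,
        "degenerate": [False] * 4,
    })
    ids = set(table_ids(table))
    result = blind_sphere_radius(table, ids)
    assert result.radius_angstrom == pytest.approx(8.0)   # 7.9 rounds to 8.0
    assert result.outliers == ["A:4:H"]
    assert blind_sphere_radius(table, set()).radius_angstrom == 0.0
    only_far = blind_sphere_radius(table, {"A:4:H"})
    assert only_far.radius_angstrom == 0.0 and only_far.outliers == ["A:4:H"]
    with pytest.raises(ValueError, match="not in table"):
        blind_sphere_radius(table, {"B:9:H"})


def test_blind_sphere_monotone_under_subset(reference_distances):
    ids = sorted(table_ids(reference_distances))
    rng = np.random.default_rng(0)
    for _ in range(20):
        k = rng.integers(1, len(ids))
        u2 = set(rng.choice(ids, size=k, replace=False))
        u1 = set(rng.choice(sorted(u2), size=max(1, k // 2), replace=False))
        r1 = blind_sphere_radius(reference_distances, u1).radius_angstrom
        r2 = blind_sphere_radius(reference_distances, u2).radius_angstrom
        assert r1 <= r2


def test_distances_invariant_under_rigid_transform(toy_site):
    s, _ = toy_site
    rng = np.random.default_rng(42)
    # random rotation via QR, plus translation
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    t = rng.normal(scale=20.0, size=3)
    moved = Structure([
        Atom(a.chain, a.resnum, a.resname, a.name, a.element,
             tuple(q @ np.array(a.xyz) + t), het=a.het)
        for a in s.atoms
    ])
    d0 = metal_proton_distances(s, find_metal_sites(s))
    d1 = metal_proton_distances(moved, find_metal_sites(moved))
    assert np.allclose(d0["r_angstrom"], d1["r_angstrom"], atol=1e-6)


def test_bond_counts_match_bfs_on_toy_site():
    """Through-bond counts equal shortest paths on the covalent graph for a
    toy site whose protons are attached to ligand donors."""
    import networkx as nx

    spec = ToySiteSpec(protons=(), seed=3)
    s, _ = make_toy_structure(spec)
    # attach one H 1.0 A from the Cys-72 SG: expect H-SG-FE1 = 2 bonds
    sg = s.find("A", 72, "SG")
    fe1 = np.array(s.find("A", 201, "FE1").xyz)
    away = (np.array(sg.xyz) - fe1) / np.linalg.norm(np.array(sg.xyz) - fe1)
    h = Atom("A", 72, "CYS", "HG", "H", tuple(np.array(sg.xyz) + away))
    s = Structure(s.atoms + [h])
    sites = find_metal_sites(s)
    d = metal_proton_distances(s, sites)
    row = d[(d["resnum"] == 72) & (d["atom"] == "HG")].iloc[0]
    g = covalent_graph(s)
    fe = [m for m in sites if m.label == row["fe_coord_label"]][0]
    fe_atom = [a for a in s.atoms if np.allclose(a.xyz, fe.xyz)][0]
    bfs = nx.shortest_path_length(g, h.atom_id(), fe_atom.atom_id())
    assert row["bonds"] == bfs == 2
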