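"""Structure handling: metal sites, amide protons, metal-proton distances,
blind-sphere statistics.

PDB reading/writing is delegated to gemmi; this module adds what a
paramagnetic-NMR analysis needs on top: locating the iron ions of Fe-S
clusters, rebuilding backbone amide protons with idealized geometry,
tabulating nearest-iron distances for selected protons (with through-bond
counts over a covalent graph), and turning lists of undetected amides
into a "blind sphere" radius around the cluster.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import gemmi
import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

NH_BOND_ANGSTROM = 1.01
GENERIC_BOND_ANGSTROM = 1.9
COORDINATION_BOND_ANGSTROM = 2.6
CLUSTER_GROUP_ANGSTROM = 3.5
DEFAULT_OUTLIER_CUTOFF = 12.0

METALS = {
    "FE", "ZN", "CU", "MN", "NI", "CO", "MG", "CA", "NA", "K", "MO", "W",
}

DISTANCE_COLUMNS = [
    "chain", "resnum", "resname", "atom", "fe_label", "r_angstrom", "bonds",
    "fe_coord_label", "r_coord_angstrom", "degenerate",
]


@dataclass(frozen=True)
class Atom:
    chain: str
    resnum: int
    resname: str
    name: str
    element: str
    xyz: tuple[float, float, float]
    altloc: str = ""
    occupancy: float = 1.0
    het: bool = False

    @property
    def is_water(self) -> bool:
        return self.resname in ("HOH", "WAT")

    @property
    def is_hydrogen(self) -> bool:
        return self.element == "H"

    def atom_id(self) -> str:
        return f"{self.chain}:{self.resnum}:{self.name}"


@dataclass
class Structure:
    """Flat atom list with coordinate access as an (n, 3) array."""

    atoms: list[Atom] = field(default_factory=list)

    def __post_init__(self):
        for a in self.atoms:
            if not all(np.isfinite(a.xyz)):
                raise ValueError(f"non-finite coordinates for {a.atom_id()}")
            if not a.element:
                raise ValueError(f"atom {a.atom_id()} has no element")

    def coords(self) -> np.ndarray:
        return np.array([a.xyz for a in self.atoms], dtype=float).reshape(-1, 3)

    def without_waters(self) -> "Structure":
        return Structure([a for a in self.atoms if not a.is_water])

    def chains(self) -> list[str]:
        seen = dict.fromkeys(a.chain for a in self.atoms)
        return list(seen)

    def residues(self, chain: str) -> list[tuple[int, str]]:
        seen = dict.fromkeys(
            (a.resnum, a.resname) for a in self.atoms if a.chain == chain
        )
        return list(seen)

    def find(self, chain: str, resnum: int, name: str) -> Atom | None:
        for a in self.atoms:
            if a.chain == chain and a.resnum == resnum and a.name == name:
                return a
        return None


@dataclass(frozen=True)
class MetalSite:
    label: str
    cluster_id: int
    chain: str
    xyz: tuple[float, float, float]
    element: str

    def __post_init__(self):
        if self.element not in METALS:
            raise ValueError(f"{self.element} is not a metal")


@dataclass
class BlindSphere:
    """Blind-sphere radius plus undetected amides attributed to other causes."""

    radius_angstrom: float
    outliers: list[str]
    n_undetected: int


class PDBParseError(ValueError):
    pass


def _validate_pdb_text(text: str) -> int:
    n = 0
    for lineno, line in enumerate(text.splitlines(), start=1):
        if line.startswith(("ATOM  ", "HETATM")):
            n += 1
            try:
                for sl in (slice(30, 38), slice(38, 46), slice(46, 54)):
                    float(line[sl])
            except (ValueError, IndexError):
                raise PDBParseError(
                    f"malformed coordinate record at line {lineno}: {line!r}"
                ) from None
    return n


def load_structure(pdb_text: str, keep_waters: bool = True) -> Structure:
    """Parse PDB text into a Structure.

    Alternate locations are resolved to the highest-occupancy conformer;
    waters are kept (drop them with ``keep_waters=False`` or
    :meth:`Structure.without_waters`).
    """
    if _validate_pdb_text(pdb_text) == 0:
        raise PDBParseError("no ATOM/HETATM records in input")
    st = gemmi.read_pdb_string(pdb_text)
    st.setup_entities()
    atoms: dict[tuple, Atom] = {}
    model = st[0]
    for chain in model:
        for res in chain:
            for at in res:
                a = Atom(
                    chain=chain.name,
                    resnum=res.seqid.num,
                    resname=res.name.strip(),
                    name=at.name,
                    element=at.element.name.upper(),
                    xyz=(at.pos.x, at.pos.y, at.pos.z),
                    altloc=at.altloc,
                    occupancy=at.occ,
                    het=res.het_flag == "H",
                )
                key = (a.chain, a.resnum, a.resname, a.name)
                prev = atoms.get(key)
                if prev is None or a.occupancy > prev.occupancy:
                    atoms[key] = a
    result = Structure([replace(a, altloc="") for a in atoms.values()])
    return result if keep_waters else result.without_waters()


def write_structure(s: Structure) -> str:
    """Serialize a Structure back to PDB text (ATOM/HETATM/TER/END)."""
    st = gemmi.Structure()
    st.name = "clusterblind"
    model = gemmi.Model("1")
    for chain_name in s.chains():
        chain = gemmi.Chain(chain_name)
        for resnum, resname in s.residues(chain_name):
            res = gemmi.Residue()
            res.name = resname
            res.seqid = gemmi.SeqId(resnum, " ")
            members = [a for a in s.atoms
                       if a.chain == chain_name and a.resnum == resnum
                       and a.resname == resname]
            res.het_flag = "H" if members and members[0].het else "A"
            for a in members:
                at = gemmi.Atom()
                at.name = a.name
                at.element = gemmi.Element(a.element)
                at.pos = gemmi.Position(*a.xyz)
                at.occ = a.occupancy
                res.add_atom(at)
            chain.add_residue(res)
        model.add_chain(chain)
    st.add_model(model)
    return st.make_pdb_string()


def find_metal_sites(s: Structure,
                     elements: frozenset[str] | set[str] = frozenset({"FE"})
                     ) -> list[MetalSite]:
    """One MetalSite per matching atom; ions within 3.5 A share a cluster id."""
    elements = {e.upper() for e in elements}
    matches = [a for a in s.atoms if a.element in elements]
    if not matches:
        raise ValueError(
            f"no metal site: no atoms with element in {sorted(elements)}"
        )
    xyz = np.array([a.xyz for a in matches])
    g = nx.Graph()
    g.add_nodes_from(range(len(matches)))
    if len(matches) > 1:
        tree = cKDTree(xyz)
        for i, j in tree.query_pairs(CLUSTER_GROUP_ANGSTROM):
            g.add_edge(i, j)
    sites = []
    for cid, component in enumerate(sorted(nx.connected_components(g),
                                           key=lambda c: min(c))):
        for i in sorted(component):
            a = matches[i]
            label = a.name if a.name != a.element else f"{a.element}{i + 1}"
            sites.append(MetalSite(label=label, cluster_id=cid, chain=a.chain,
                                   xyz=a.xyz, element=a.element))
    return sites


def build_amide_protons(s: Structure) -> Structure:
    """Add backbone amide H atoms with idealized geometry.

    H sits 1.01 A from N, in the C(i-1)-N-CA plane, opposite the bisector
    of the N-CA and N-C(i-1) bonds. Prolines, chain N-termini, residues
    with existing H and residues with incomplete backbone are skipped.
    """
    new_atoms = list(s.atoms)
    for chain in s.chains():
        residues = [r for r in s.residues(chain)
                    if any(a.chain == chain and a.resnum == r[0]
                           and a.name == "N" and not a.het for a in s.atoms)]
        residues.sort(key=lambda r: r[0])
        for idx in range(1, len(residues)):
            resnum, resname = residues[idx]
            if resname == "PRO":
                continue
            if s.find(chain, resnum, "H") is not None:
                continue
            n = s.find(chain, resnum, "N")
            ca = s.find(chain, resnum, "CA")
            prev_num = residues[idx - 1][0]
            c_prev = s.find(chain, prev_num, "C")
            if n is None or ca is None or c_prev is None:
                continue
            npos = np.array(n.xyz)
            # peptide-bond continuity guard: C(i-1) must actually bond N(i)
            if np.linalg.norm(np.array(c_prev.xyz) - npos) > 1.8:
                continue
            u1 = np.array(ca.xyz) - npos
            u2 = np.array(c_prev.xyz) - npos
            u1 /= np.linalg.norm(u1)
            u2 /= np.linalg.norm(u2)
            bisector = u1 + u2
            norm = np.linalg.norm(bisector)
            if norm < 1e-6:
                continue
            h_xyz = npos - NH_BOND_ANGSTROM * bisector / norm
            new_atoms.append(Atom(
                chain=chain, resnum=resnum, resname=resname, name="H",
                element="H", xyz=tuple(h_xyz),
            ))
    return Structure(new_atoms)


def covalent_graph(s: Structure) -> nx.Graph:
    """Distance-threshold covalent graph over atom ids.

    Edges: pairs closer than 1.9 A (2.6 A when one atom is a metal and the
    other a typical donor, covering Fe-S and Fe-N coordination bonds);
    H-H pairs are never bonded.
    """
    g = nx.Graph()
    for a in s.atoms:
        g.add_node(a.atom_id(), element=a.element)
    xyz = s.coords()
    if len(s.atoms) < 2:
        return g
    tree = cKDTree(xyz)
    for i, j in tree.query_pairs(COORDINATION_BOND_ANGSTROM):
        ai, aj = s.atoms[i], s.atoms[j]
        if ai.is_hydrogen and aj.is_hydrogen:
            continue
        d = float(np.linalg.norm(xyz[i] - xyz[j]))
        metal_pair = (ai.element in METALS and aj.element in {"S", "N", "O"}) \
            or (aj.element in METALS and ai.element in {"S", "N", "O"})
        cutoff = COORDINATION_BOND_ANGSTROM if metal_pair else GENERIC_BOND_ANGSTROM
        if d < cutoff:
            g.add_edge(ai.atom_id(), aj.atom_id(), length=d)
    return g


def _select_hydrogens(s: Structure, selection) -> list[Atom]:
    hydrogens = [a for a in s.atoms if a.is_hydrogen]
    if selection in (None, "all"):
        return hydrogens
    if selection == "HN":
        return [a for a in hydrogens if a.name == "H"]
    if callable(selection):
        return [a for a in hydrogens if selection(a)]
    names = set(selection)
    return [a for a in hydrogens if a.name in names]


def metal_proton_distances(s: Structure, sites: list[MetalSite],
                           selection="all", max_bonds: int = 8) -> pd.DataFrame:
    """Nearest-iron distance table for selected protons.

    Columns: chain, resnum, resname, atom, fe_label, r_angstrom (nearest
    metal), bonds (covalent path length to that metal through the
    coordinating ligand atom; NaN when the proton's residue does not
    coordinate it), fe_coord_label / r_coord_angstrom (metal coordinated by
    the proton's residue, when any), degenerate (proton essentially on top
    of a metal; excluded from blind-sphere work).
    """
    protons = _select_hydrogens(s, selection)
    if not sites:
        raise ValueError("no metal sites supplied")
    rows = []
    site_xyz = np.array([m.xyz for m in sites])
    graph = covalent_graph(s) if protons else None
    # residues coordinating each metal: any heavy atom within coordination range
    coordinating: dict[int, set] = {i: set() for i in range(len(sites))}
    for a in s.atoms:
        if a.is_hydrogen or a.element not in {"S", "N", "O"}:
            continue
        d = np.linalg.norm(site_xyz - np.array(a.xyz), axis=1)
        for i in np.where(d < COORDINATION_BOND_ANGSTROM)[0]:
            coordinating[int(i)].add((a.chain, a.resnum))
    for a in protons:
        d = np.linalg.norm(site_xyz - np.array(a.xyz), axis=1)
        nearest = int(np.argmin(d))
        res_key = (a.chain, a.resnum)
        coord_idx = [i for i, members in coordinating.items() if res_key in members]
        bonds = np.nan
        fe_coord_label, r_coord = None, np.nan
        if coord_idx:
            best = min(coord_idx, key=lambda i: d[i])
            fe_coord_label = sites[best].label
            r_coord = float(d[best])
            fe_node = None
            for m in s.atoms:
                if m.element == sites[best].element and \
                        np.allclose(m.xyz, sites[best].xyz):
                    fe_node = m.atom_id()
                    break
            if fe_node is not None and graph is not None:
                try:
                    bonds = float(nx.shortest_path_length(
                        graph, a.atom_id(), fe_node))
                except nx.NetworkXNoPath:
                    bonds = np.nan
        rows.append({
            "chain": a.chain, "resnum": a.resnum, "resname": a.resname,
            "atom": a.name, "fe_label": sites[nearest].label,
            "r_angstrom": float(d[nearest]), "bonds": bonds,
            "fe_coord_label": fe_coord_label, "r_coord_angstrom": r_coord,
            "degenerate": bool(d[nearest] < 1e-6),
        })
    if not rows:
        import warnings
        warnings.warn("selection matched no hydrogens; empty distance table")
    df = pd.DataFrame(rows, columns=DISTANCE_COLUMNS)
    bad = df[(~df["degenerate"]) & (df["r_angstrom"] <= 0)]
    if len(bad):
        raise ValueError("non-positive distances for non-degenerate protons")
    return df


def table_ids(d: pd.DataFrame) -> pd.Series:
    return d["chain"].astype(str) + ":" + d["resnum"].astype(str) + ":" + d["atom"]


def count_protons_within(d: pd.DataFrame, radius: float,
                         selection=None) -> int:
    """Number of selected protons strictly closer than ``radius`` (A)."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    df = d[~d["degenerate"]]
    if selection == "HN":
        df = df[df["atom"] == "H"]
    elif selection is not None and selection != "all":
        df = df[df["atom"].isin(set(selection))]
    return int((df["r_angstrom"] < radius).sum())


def blind_sphere_radius(d: pd.DataFrame, undetected: set[str],
                        outlier_cutoff: float = DEFAULT_OUTLIER_CUTOFF
                        ) -> BlindSphere:
    """Blind-sphere radius from a set of undetected amide ids.

    The radius is the largest nearest-iron distance among undetected amides
    closer than ``outlier_cutoff``; undetected amides beyond the cutoff are
    attributed to non-paramagnetic causes and reported as outliers. The
    radius is rounded to 0.5 A, matching the granularity at which such
    radii are meaningfully quoted.
    """
    ids = set(table_ids(d))
    unknown = set(undetected) - ids
    if unknown:
        raise ValueError(f"undetected ids not in table: {sorted(unknown)[:5]}")
    df = d[~d["degenerate"]].copy()
    df = df[table_ids(df).isin(set(undetected))]
    inside = df[df["r_angstrom"] < outlier_cutoff]
    outliers = sorted(table_ids(df[df["r_angstrom"] >= outlier_cutoff]))
    if inside.empty:
        return BlindSphere(0.0, outliers, len(undetected))
    radius = round(2.0 * float(inside["r_angstrom"].max())) / 2.0
    return BlindSphere(radius, outliers, len(undetected))
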