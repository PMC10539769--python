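"""Synthetic inputs with known ground truth for every pipeline stage.

The generators emulate the data a paramagnetic NMR study of an [Fe2S2]
protein consumes: a toy cluster site with ligand protons at chosen
metal-proton distances, forward-modeled hyperfine peak tables at several
temperatures, rigid-rotor 15N relaxation tables with noise, and sparse
NOE difference peak lists built from a known ground-truth assignment.
All randomness is routed through an explicit seed; regeneration with the
same spec is reproducible bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .relaxation import Calibration, calibrated_prediction, simulate_n15_relaxation
from .spinladder import HyperfineCoupling, SpinSystem, contact_shift
from .structure import Atom, Structure

MIN_CONTACT_ANGSTROM = 0.8


@dataclass(frozen=True)
class ProtonSpec:
    """One ligand proton to place at a given distance from one iron."""

    resname: str
    resnum: int
    atom: str
    r_angstrom: float
    site: int = 1          # 1 -> FE1, 2 -> FE2


@dataclass(frozen=True)
class PartnerSpec:
    """An extra proton placed near a host proton (an NOE partner)."""

    host_index: int        # index into ToySiteSpec.protons
    atom: str
    r_from_host: float


@dataclass(frozen=True)
class ToySiteSpec:
    """A minimal [Fe2S2]-like site: 2 Fe, 2 bridging S, Cys/His ligands.

    Defaults mimic a 3-Cys/1-His coordination: three thiolate sulfurs at
    2.3 A and one imidazole nitrogen at 2.1 A, iron-iron distance 2.7 A.
    """

    fe_fe_angstrom: float = 2.7
    cys_s_angstrom: float = 2.3
    his_n_angstrom: float = 2.1
    protons: tuple = (
        ProtonSpec("CYS", 72, "HB3", 4.35, 1),
        ProtonSpec("CYS", 74, "HB2", 4.25, 1),
        ProtonSpec("CYS", 83, "HB3", 4.32, 2),
        ProtonSpec("HIS", 87, "HE2", 4.94, 2),
        ProtonSpec("HIS", 87, "HD2", 5.18, 2),
    )
    partners: tuple = ()
    seed: int = 0

    def __post_init__(self):
        if self.fe_fe_angstrom <= 0 or self.cys_s_angstrom <= 0 \
                or self.his_n_angstrom <= 0:
            raise ValueError("distances must be positive")
        for p in self.protons:
            if p.r_angstrom <= 0:
                raise ValueError(f"proton distance must be positive: {p}")
            if p.site not in (1, 2):
                raise ValueError("site must be 1 or 2")


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _place(center: np.ndarray, r: float, occupied: list[np.ndarray],
           rng: np.random.Generator,
           avoid: list[tuple[np.ndarray, float]] = (),
           tries: int = 400) -> np.ndarray:
    """Random point at distance r from center, clash-free, required to stay
    closer to `center` than to each point listed in `avoid`."""
    for _ in range(tries):
        pos = center + r * _random_unit(rng)
        if any(np.linalg.norm(pos - q) < MIN_CONTACT_ANGSTROM for q in occupied):
            continue
        if any(np.linalg.norm(pos - p) <= r for p, _ in avoid):
            continue
        return pos
    raise ValueError("infeasible geometry: could not place atom without clash")


def make_toy_structure(spec: ToySiteSpec = ToySiteSpec()
                       ) -> tuple[Structure, pd.DataFrame]:
    """Build the toy site and its ground-truth distance table.

    Returns (structure, table); the table holds the *requested* per-proton
    nearest-iron distances, which the geometry reproduces exactly by
    construction (protons are placed on a sphere of the requested radius
    around their iron, constrained to stay nearer to it than to the other
    iron).
    """
    rng = np.random.default_rng(spec.seed)
    fe1 = np.zeros(3)
    fe2 = np.array([spec.fe_fe_angstrom, 0.0, 0.0])
    bridge = 2.2
    h = np.sqrt(max(bridge ** 2 - (spec.fe_fe_angstrom / 2) ** 2, 0.25))
    s1 = np.array([spec.fe_fe_angstrom / 2, 0.0, h])
    s2 = np.array([spec.fe_fe_angstrom / 2, 0.0, -h])
    atoms = [
        Atom("A", 201, "FES", "FE1", "FE", tuple(fe1), het=True),
        Atom("A", 201, "FES", "FE2", "FE", tuple(fe2), het=True),
        Atom("A", 201, "FES", "S1", "S", tuple(s1), het=True),
        Atom("A", 201, "FES", "S2", "S", tuple(s2), het=True),
    ]
    occupied = [fe1, fe2, s1, s2]

    # terminal ligand donors, pointing away from the partner iron
    def donor(center, other, r):
        away = (center - other) / np.linalg.norm(center - other)
        for _ in range(400):
            tilt = _random_unit(rng)
            u = away + 0.7 * tilt
            u /= np.linalg.norm(u)
            pos = center + r * u
            if all(np.linalg.norm(pos - q) >= MIN_CONTACT_ANGSTROM
                   for q in occupied):
                return pos
        raise ValueError("infeasible geometry: ligand placement failed")

    ligand_atoms = {
        ("CYS", 72): ("SG", "S", donor(fe1, fe2, spec.cys_s_angstrom)),
        ("CYS", 74): ("SG", "S", donor(fe1, fe2, spec.cys_s_angstrom)),
        ("CYS", 83): ("SG", "S", donor(fe2, fe1, spec.cys_s_angstrom)),
        ("HIS", 87): ("ND1", "N", donor(fe2, fe1, spec.his_n_angstrom)),
    }
    for (resname, resnum), (name, element, pos) in ligand_atoms.items():
        atoms.append(Atom("A", resnum, resname, name, element, tuple(pos)))
        occupied.append(pos)

    fe_xyz = {1: fe1, 2: fe2}
    rows = []
    proton_positions = []
    for p in spec.protons:
        center = fe_xyz[p.site]
        other = fe_xyz[3 - p.site]
        pos = _place(center, p.r_angstrom, occupied, rng,
                     avoid=[(other, 0.0)])
        atoms.append(Atom("A", p.resnum, p.resname, p.atom, "H", tuple(pos)))
        occupied.append(pos)
        proton_positions.append(pos)
        rows.append({
            "chain": "A", "resnum": p.resnum, "resname": p.resname,
            "atom": p.atom, "fe_label": f"FE{p.site}",
            "r_angstrom": p.r_angstrom, "bonds": np.nan,
            "fe_coord_label": f"FE{p.site}", "r_coord_angstrom": p.r_angstrom,
            "degenerate": False,
        })
    for q in spec.partners:
        host = proton_positions[q.host_index]
        hp = spec.protons[q.host_index]
        pos = _place(host, q.r_from_host, occupied, rng)
        atoms.append(Atom("A", hp.resnum, hp.resname, q.atom, "H", tuple(pos)))
        occupied.append(pos)
    return Structure(atoms), pd.DataFrame(rows)


def make_peak_table(sys: SpinSystem,
                    couplings: list[tuple[HyperfineCoupling, float, float, bool]],
                    temperatures: list[float],
                    calibration: Calibration,
                    noise_ppm: float = 0.0,
                    seed: int = 0) -> pd.DataFrame:
    """Forward-model a hyperfine peak table.

    ``couplings``: list of (HyperfineCoupling, r_angstrom, diamagnetic
    offset ppm, exchangeable). Shifts come from the spin-ladder contact
    model plus the diamagnetic offset (plus Gaussian noise); linewidths
    from the r^-6 calibrated prediction at the proton's distance.
    Long-format columns: label, T_kelvin, shift_ppm, linewidth_hz,
    exchangeable.
    """
    if not temperatures:
        raise ValueError("need at least one temperature")
    rng = np.random.default_rng(seed)
    rows = []
    for coupling, r, diamag, exch in couplings:
        dnu = calibrated_prediction(calibration, r)
        for t in sorted(temperatures):
            shift = contact_shift(sys, coupling, t) + diamag
            if noise_ppm > 0:
                shift += rng.normal(0.0, noise_ppm)
            rows.append({
                "label": coupling.proton_id, "T_kelvin": float(t),
                "shift_ppm": float(shift), "linewidth_hz": float(dnu),
                "exchangeable": bool(exch),
            })
    return pd.DataFrame(rows)


def make_relaxation_table(tau_c_ns: float, field_mhz: float, n_residues: int,
                          noise_fraction: float = 0.0,
                          seed: int = 0) -> pd.DataFrame:
    """Rigid-rotor 15N relaxation table with multiplicative Gaussian noise."""
    if not 1.0 <= tau_c_ns <= 50.0:
        raise ValueError("tau_c must be within 1-50 ns")
    rng = np.random.default_rng(seed)
    r1, r2, noe = simulate_n15_relaxation(tau_c_ns, field_mhz)
    rows = []
    for resnum in range(1, n_residues + 1):
        f1 = 1.0 + rng.normal(0.0, noise_fraction) if noise_fraction > 0 else 1.0
        f2 = 1.0 + rng.normal(0.0, noise_fraction) if noise_fraction > 0 else 1.0
        rows.append({
            "resnum": resnum,
            "R1": r1 * f1,
            "R2": r2 * f2,
            "NOE": noe,
            "field_mhz": field_mhz,
        })
    return pd.DataFrame(rows)


def make_noe_observations(structure: Structure,
                          assignment: dict,
                          shift_table: dict,
                          irradiated: list[str],
                          dropout: float = 0.0,
                          seed: int = 0,
                          cutoff: float = 5.0) -> pd.DataFrame:
    """Simulated 1D NOE difference peak lists from a known assignment.

    ``assignment``: signal label -> proton id; ``shift_table``: proton
    id -> diamagnetic-region shift (ppm). For each irradiated label, the
    observed peaks are the shifts of its structure-predicted NOE partners
    (those present in the shift table), with a fraction ``dropout``
    removed at random — emulating how sparse and weak NOEs from
    fast-relaxing hyperfine signals are.
    """
    from .assignment import predict_noe_partners

    if not 0.0 <= dropout <= 1.0:
        raise ValueError("dropout must be in [0, 1]")
    rng = np.random.default_rng(seed)
    rows = []
    for label in irradiated:
        pid = assignment[label]
        partners = predict_noe_partners(structure, pid, cutoff)
        for partner_id, _, _ in partners:
            if partner_id not in shift_table:
                continue
            if dropout > 0 and rng.random() < dropout:
                continue
            rows.append({
                "irradiated_label": label,
                "peak_shift_ppm": float(shift_table[partner_id]),
            })
    return pd.DataFrame(rows, columns=["irradiated_label", "peak_shift_ppm"])
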