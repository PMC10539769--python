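"""Distance- and NOE-based assignment of hyperfine-shifted signals,
plus the combined amide chemical-shift perturbation statistic.

The assignment logic mirrors how hyperfine 1H signals of cluster-bound
residues are assigned in practice:

1. protons closer than ~4 A to a metal ion are broadened beyond
   detection and discarded;
2. protons too many chemical bonds away from the metal cannot carry a
   contact coupling above ~1 MHz and are excluded from the strongly
   shifted set — unless they sit on the conjugated imidazole ring of a
   coordinating histidine, where spin delocalization reaches further;
3. exchangeable signals can only be nitrogen-bound protons;
4. what remains is a small candidate set, resolved (when possible) by
   comparing observed 1D NOE difference peaks against NOE patterns
   predicted from the structure with r^-6 intensities.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .structure import Structure

DISTANCE_CUTOFF_ANGSTROM = 4.0
BOND_MAX = 3
NOE_CUTOFF_ANGSTROM = 5.0
NOE_TOLERANCE_PPM = 0.05

#: ring protons of a coordinating histidine (PDB v3 names): exempt from the
#: bond-count exclusion because the imidazole pi system delocalizes spin
HIS_RING_PROTONS = {"HD1", "HD2", "HE1", "HE2"}
#: nitrogen-bound side-chain protons by residue (plus backbone "H" always)
N_BOUND_SIDECHAIN = {
    "HIS": {"HD1", "HE2"},
    "TRP": {"HE1"},
    "ARG": {"HE", "HH11", "HH12", "HH21", "HH22"},
    "LYS": {"HZ1", "HZ2", "HZ3"},
    "ASN": {"HD21", "HD22"},
    "GLN": {"HE21", "HE22"},
}


@dataclass(frozen=True)
class HyperfineSignal:
    """One hyperfine-shifted 1H signal with its temperature series."""

    label: str
    shifts: tuple            # ((T kelvin, ppm), ...)
    linewidth_hz: float
    exchangeable: bool = False

    def __post_init__(self):
        if self.linewidth_hz <= 0:
            raise ValueError("linewidth must be positive")
        if len(self.shifts) < 1:
            raise ValueError("need at least one temperature")


@dataclass
class CandidatePartition:
    """Exhaustive, disjoint partition of the distance table's protons."""

    beyond_detection: list[str] = field(default_factory=list)
    bond_excluded: list[str] = field(default_factory=list)
    exchange_constrained: list[str] = field(default_factory=list)
    candidates: list[str] = field(default_factory=list)
    rule_trace: dict = field(default_factory=dict)


def _is_ring_proton(resname: str, atom: str) -> bool:
    return resname == "HIS" and atom in HIS_RING_PROTONS


def _is_n_bound(resname: str, atom: str) -> bool:
    return atom == "H" or atom in N_BOUND_SIDECHAIN.get(resname, set())


def filter_candidates(d: pd.DataFrame,
                      distance_cutoff: float = DISTANCE_CUTOFF_ANGSTROM,
                      bond_max: int = BOND_MAX) -> CandidatePartition:
    """Partition cluster-bound protons by the detectability/coupling rules.

    Returns a :class:`CandidatePartition` whose four lists are disjoint and
    exhaustive over the table ids; ``rule_trace`` records, per id, which
    rule fired. ``exchange_constrained`` holds the nitrogen-bound survivors
    (only these may match exchangeable signals); ``candidates`` holds the
    carbon-bound survivors eligible for non-exchangeable signals.
    """
    if d.empty:
        raise ValueError("empty distance table")
    part = CandidatePartition()
    for _, row in d.iterrows():
        pid = f"{row['chain']}:{row['resnum']}:{row['atom']}"
        if row["r_angstrom"] < distance_cutoff:
            part.beyond_detection.append(pid)
            part.rule_trace[pid] = (
                f"r = {row['r_angstrom']:.2f} A < {distance_cutoff} A: "
                "broadened beyond detection"
            )
            continue
        ring = _is_ring_proton(row["resname"], row["atom"])
        bonds = row["bonds"]
        if not ring and pd.notna(bonds) and bonds > bond_max:
            part.bond_excluded.append(pid)
            part.rule_trace[pid] = (
                f"{int(bonds)} bonds from the metal (> {bond_max}) and not a "
                "coordinating-His ring proton: contact coupling < 1 MHz class"
            )
            continue
        if _is_n_bound(row["resname"], row["atom"]):
            part.exchange_constrained.append(pid)
            part.rule_trace[pid] = "N-bound survivor: exchangeable-only candidate"
        else:
            part.candidates.append(pid)
            part.rule_trace[pid] = "survivor: hyperfine candidate"
    return part


def predict_noe_partners(s: Structure, proton_id: str,
                         cutoff: float = NOE_CUTOFF_ANGSTROM
                         ) -> list[tuple[str, float, float]]:
    """Hydrogens within ``cutoff`` of the given proton, with r^-6 intensities.

    Returns (partner id, distance A, relative intensity) sorted by
    intensity, normalized to the strongest partner.
    """
    target = None
    for a in s.atoms:
        if a.atom_id() == proton_id:
            target = a
            break
    if target is None:
        raise ValueError(f"proton id {proton_id!r} not in structure")
    if not target.is_hydrogen:
        raise ValueError(f"{proton_id!r} is not a hydrogen")
    t_xyz = np.array(target.xyz)
    partners = []
    for a in s.atoms:
        if not a.is_hydrogen or a.atom_id() == proton_id:
            continue
        r = float(np.linalg.norm(np.array(a.xyz) - t_xyz))
        if 0 < r < cutoff:
            partners.append((a.atom_id(), r, r ** -6))
    if not partners:
        return []
    top = max(i for _, _, i in partners)
    return sorted(
        ((pid, r, i / top) for pid, r, i in partners),
        key=lambda x: -x[2],
    )


@dataclass
class AssignmentResult:
    """Outcome of exhaustive signal-to-candidate matching."""

    assignment: dict            # signal label -> candidate id (best matching)
    score: float
    ambiguous: bool
    alternatives: list          # all optimal matchings when tied
    per_signal_score: dict


def match_assignments(candidates: list[str],
                      observed_noe: dict,
                      predicted: dict,
                      tolerance_ppm: float = NOE_TOLERANCE_PPM
                      ) -> AssignmentResult:
    """Exhaustive one-to-one matching of irradiated signals to candidates.

    Parameters
    ----------
    candidates:
        Proton ids eligible for assignment.
    observed_noe:
        Mapping irradiated signal label -> list of observed NOE peak
        shifts (ppm).
    predicted:
        Mapping candidate id -> list of (partner shift ppm, relative
        intensity) predicted from the structure.

    The score of pairing a signal with a candidate is the
    intensity-weighted count of observed peaks matching a predicted
    partner within the tolerance. The best total-score bijection wins;
    ties are reported as ambiguous, never broken silently. With more
    signals than candidates, surplus signals are left unassigned.
    """
    labels = sorted(observed_noe)
    if not candidates:
        raise ValueError("no candidates")

    def pair_score(label, cand):
        peaks = observed_noe[label]
        preds = predicted.get(cand, [])
        score = 0.0
        for ppm in peaks:
            best = 0.0
            for pshift, intensity in preds:
                if abs(ppm - pshift) <= tolerance_ppm:
                    best = max(best, intensity)
            score += best
        return score

    k = min(len(labels), len(candidates))
    best_total, best_matchings = -1.0, []
    for subset in itertools.permutations(candidates, k):
        matching = dict(zip(labels, subset))
        total = sum(pair_score(lb, cd) for lb, cd in matching.items())
        if total > best_total + 1e-12:
            best_total, best_matchings = total, [matching]
        elif abs(total - best_total) <= 1e-12:
            best_matchings.append(matching)
    best = best_matchings[0]
    for label in labels[k:]:
        best[label] = None
    return AssignmentResult(
        assignment=best,
        score=best_total,
        ambiguous=len(best_matchings) > 1,
        alternatives=best_matchings,
        per_signal_score={lb: pair_score(lb, cd)
                          for lb, cd in best.items() if cd is not None},
    )


def delta_hn(delta_h_ppm: float, delta_n_ppm: float) -> float:
    """Combined amide shift perturbation sqrt(dH^2 + (dN/5)^2) in ppm.

    The nitrogen term is scaled by 5 to put 15N shifts on the 1H scale.
    """
    if not (np.isfinite(delta_h_ppm) and np.isfinite(delta_n_ppm)):
        raise ValueError("shift differences must be finite")
    return float(np.hypot(delta_h_ppm, delta_n_ppm / 5.0))


def significance_threshold(delta_hn_values) -> float:
    """Mean + 1 SD cutoff over per-residue combined perturbations."""
    v = np.asarray(list(delta_hn_values), dtype=float)
    if v.size == 0:
        raise ValueError("no perturbation values")
    return float(v.mean() + v.std(ddof=0))


def perturbation_table(records) -> pd.DataFrame:
    """Per-residue ΔHN table with a significance flag.

    ``records``: iterable of (residue, delta_H ppm, delta_N ppm).
    """
    rows = [{"residue": r, "delta_h_ppm": dh, "delta_n_ppm": dn,
             "delta_hn_ppm": delta_hn(dh, dn)} for r, dh, dn in records]
    df = pd.DataFrame(rows)
    thr = significance_threshold(df["delta_hn_ppm"])
    df["significant"] = df["delta_hn_ppm"] > thr
    df.attrs["threshold_ppm"] = thr
    return df
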