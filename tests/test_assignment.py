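"""Candidate filtering, NOE prediction/matching and shift perturbations."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from clusterblind import (
    Atom,
    Structure,
    delta_hn,
    filter_candidates,
    match_assignments,
    predict_noe_partners,
    significance_threshold,
)
from clusterblind.assignment import perturbation_table

BOLD_CANDIDATES = {"A:72:HB3", "A:74:HB2", "A:83:HB3", "A:87:HD2"}
BEYOND = {"A:72:HA", "A:72:HB2", "A:74:H", "A:74:HB3",
          "A:83:HA", "A:83:HB2", "A:87:H", "A:87:HB3", "A:87:HE1"}


def test_reference_partition_reproduces_bold_candidates(reference_distances):
    """Distance + bond rules leave exactly the four strongly coupled CH
    protons as A-E candidates and nine protons beyond detection."""
    part = filter_candidates(reference_distances)
    assert set(part.candidates) == BOLD_CANDIDATES
    assert set(part.beyond_detection) == BEYOND
    assert len(part.beyond_detection) == 9


def test_exchangeable_signal_uniquely_matches_his_ring_nh(reference_distances):
    """The only N-bound survivor is the coordinating His ring NH."""
    part = filter_candidates(reference_distances)
    assert part.exchange_constrained == ["A:87:HE2"]


def test_partition_is_exhaustive_and_disjoint(reference_distances):
    part = filter_candidates(reference_distances)
    groups = [part.beyond_detection, part.bond_excluded,
              part.exchange_constrained, part.candidates]
    all_ids = list(itertools.chain(*groups))
    assert len(all_ids) == len(set(all_ids)) == len(reference_distances)
    assert set(part.rule_trace) == set(all_ids)


def test_far_protons_all_survive():
    d = pd.DataFrame({
        "chain": ["A"] * 3, "resnum": [1, 2, 3], "resname": ["ALA"] * 3,
        "atom": ["HB1", "HB2", "HB3"], "fe_label": ["FE1"] * 3,
        "r_angstrom": [11.0, 12.5, 14.0], "bonds": [np.nan] * 3,
    })
    part = filter_candidates(d)
    assert len(part.candidates) == 3
    assert not part.beyond_detection and not part.bond_excluded


def test_partition_matches_brute_force_on_random_tables(rng):
    """The partition equals a literal re-application of the three rules."""
    resnames = ["CYS", "HIS", "ALA"]
    atoms = ["H", "HA", "HB2", "HB3", "HD2", "HE1", "HE2"]
    for _ in range(200):
        n = rng.integers(1, 12)
        d = pd.DataFrame({
            "chain": ["A"] * n,
            "resnum": rng.integers(1, 99, size=n),
            "resname": rng.choice(resnames, size=n),
            "atom": rng.choice(atoms, size=n),
            "r_angstrom": rng.uniform(1.0, 12.0, size=n),
            "bonds": rng.choice([1, 2, 3, 4, 5, 6, np.nan], size=n),
        })
        d["fe_label"] = "FE1"
        d = d.drop_duplicates(subset=["chain", "resnum", "atom"])
        part = filter_candidates(d)
        for _, row in d.iterrows():
            pid = f"{row['chain']}:{row['resnum']}:{row['atom']}"
            ring = row["resname"] == "HIS" and row["atom"] in \
                {"HD1", "HD2", "HE1", "HE2"}
            nbound = row["atom"] == "H" or (row["resname"] == "HIS"
                                            and row["atom"] in {"HD1", "HE2"})
            if row["r_angstrom"] < 4.0:
                assert pid in part.beyond_detection
            elif not ring and not np.isnan(row["bonds"]) and row["bonds"] > 3:
                assert pid in part.bond_excluded
            elif nbound:
                assert pid in part.exchange_constrained
            else:
                assert pid in part.candidates


def test_empty_table_rejected():
    with pytest.raises(ValueError, match="empty"):
        filter_candidates(pd.DataFrame(columns=["chain"]))


def test_geminal_pair_tops_noe_partner_list():
    atoms = [
        Atom("A", 1, "CYS", "HB2", "H", (0.0, 0.0, 0.0)),
        Atom("A", 1, "CYS", "HB3", "H", (1.75, 0.0, 0.0)),
        Atom("A", 2, "ALA", "HA", "H", (0.0, 3.5, 0.0)),
        Atom("A", 3, "GLY", "HA", "H", (0.0, 0.0, 20.0)),   # outside cutoff
    ]
    partners = predict_noe_partners(Structure(atoms), "A:1:HB2")
    assert [p for p, _, _ in partners] == ["A:1:HB3", "A:2:HA"]
    assert partners[0][2] == pytest.approx(1.0)


def test_noe_intensity_ratio_is_r6():
    atoms = [
        Atom("A", 1, "CYS", "HB2", "H", (0.0, 0.0, 0.0)),
        Atom("A", 2, "ALA", "HA", "H", (2.0, 0.0, 0.0)),
        Atom("A", 3, "GLY", "HA", "H", (4.0, 0.0, 0.0)),
    ]
    partners = predict_noe_partners(Structure(atoms), "A:1:HB2")
    assert partners[0][2] / partners[1][2] == pytest.approx(64.0)
    with pytest.raises(ValueError, match="not in structure"):
        predict_noe_partners(Structure(atoms), "A:9:HZ")


def test_single_candidate_single_signal_match():
    result = match_assignments(
        ["A:1:HB2"], {"X": [4.2]}, {"A:1:HB2": [(4.2, 1.0)]})
    assert result.assignment == {"X": "A:1:HB2"}
    assert result.score == pytest.approx(1.0)
    assert not result.ambiguous


def test_match_score_invariant_under_relabeling():
    candidates = ["c1", "c2", "c3"]
    predicted = {"c1": [(1.0, 1.0)], "c2": [(2.0, 1.0)], "c3": [(3.0, 0.5)]}
    observed = {"A": [1.0], "B": [2.0], "C": [3.0]}
    base = match_assignments(candidates, observed, predicted)
    relabeled = match_assignments(
        candidates, {"Z": [1.0], "Y": [2.0], "X": [3.0]}, predicted)
    assert base.score == relabeled.score
    assert base.assignment["A"] == relabeled.assignment["Z"] == "c1"


def test_surplus_signals_left_unassigned():
    result = match_assignments(
        ["c1"], {"A": [1.0], "B": [2.0]}, {"c1": [(1.0, 1.0)]})
    assert sorted(result.assignment) == ["A", "B"]
    assert None in result.assignment.values()


def test_ties_are_reported_ambiguous():
    predicted = {"c1": [(1.0, 1.0)], "c2": [(1.0, 1.0)]}
    result = match_assignments(["c1", "c2"], {"A": [1.0]}, predicted)
    assert result.ambiguous
    assert len(result.alternatives) == 2


def test_synthetic_noe_roundtrip_recovers_ground_truth(noe_toy):
    """With one discriminating NOE per irradiated signal, exhaustive
    matching recovers the known assignment."""
    from clusterblind import make_noe_observations

    structure, _, partner_shifts, truth = noe_toy
    observed_df = make_noe_observations(
        structure, truth, partner_shifts, irradiated=["A", "D", "E"],
        dropout=0.0, seed=0, cutoff=3.0)
    observed = {lab: grp["peak_shift_ppm"].tolist()
                for lab, grp in observed_df.groupby("irradiated_label")}
    candidates = sorted(truth.values())
    predicted = {
        c: [(partner_shifts[p], w)
            for p, _, w in predict_noe_partners(structure, c, cutoff=3.0)
            if p in partner_shifts]
        for c in candidates
    }
    result = match_assignments(candidates, observed, predicted)
    assert not result.ambiguous
    for label in ("A", "D", "E"):
        assert result.assignment[label] == truth[label]


def test_delta_hn_arithmetic():
    assert delta_hn(0.0, 0.0) == 0.0
    assert delta_hn(0.1, 0.5) == pytest.approx(np.sqrt(0.02))
    assert delta_hn(0.0, 1.0) == pytest.approx(0.2)
    with pytest.raises(ValueError):
        delta_hn(np.nan, 0.0)


@given(
    st.tuples(st.floats(-5, 5), st.floats(-5, 5)),
    st.tuples(st.floats(-5, 5), st.floats(-5, 5)),
)
def test_delta_hn_is_a_norm(u, v):
    assert delta_hn(*u) >= 0
    assert (delta_hn(*u) == 0) == (u == (0.0, 0.0))
    combined = delta_hn(u[0] + v[0], u[1] + v[1])
    assert combined <= delta_hn(*u) + delta_hn(*v) + 1e-12


def test_significance_threshold_mean_plus_sd():
    values = [0.1, 0.2, 0.3, 1.5]
    assert significance_threshold(values) == \
        pytest.approx(np.mean(values) + np.std(values))
    df = perturbation_table([("R1", 0.1, 0.0), ("R2", 0.0, 0.5),
                             ("R3", 0.02, 0.1), ("R4", 0.9, 2.0)])
    assert df["significant"].tolist() == [False, False, False, True]
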