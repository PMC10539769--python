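import numpy as np
import pytest
from hypothesis import settings

from clusterblind import (
    Calibration,
    HyperfineCoupling,
    PartnerSpec,
    ProtonSpec,
    SpinSystem,
    ToySiteSpec,
    make_toy_structure,
)
from clusterblind.io import load_reference_distances, load_reference_signals

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def reference_signals():
    """Packaged hyperfine peak table (two temperatures, 600 MHz)."""
    return load_reference_signals()


@pytest.fixture(scope="session")
def reference_distances():
    """Packaged metal-to-proton distance table of the cluster-bound residues."""
    return load_reference_distances()


@pytest.fixture(scope="session")
def af_dimer():
    """Antiferromagnetic homodimer of two high-spin ferric ions."""
    return SpinSystem(2.5, 2.5, 300.0)


@pytest.fixture(scope="session")
def toy_site():
    structure, truth = make_toy_structure(ToySiteSpec(seed=7))
    return structure, truth


@pytest.fixture(scope="session")
def noe_toy():
    """Toy site whose four candidate protons each carry a private NOE partner."""
    spec = ToySiteSpec(
        protons=(
            ProtonSpec("CYS", 72, "HB3", 4.35, 1),
            ProtonSpec("CYS", 74, "HB2", 4.25, 1),
            ProtonSpec("CYS", 83, "HB3", 4.32, 2),
            ProtonSpec("HIS", 87, "HD2", 5.18, 2),
        ),
        partners=(
            PartnerSpec(0, "HA", 2.4),
            PartnerSpec(1, "HA", 2.3),
            PartnerSpec(2, "HA", 2.5),
            PartnerSpec(3, "HE1", 2.6),
        ),
        seed=11,
    )
    structure, truth = make_toy_structure(spec)
    partner_shifts = {
        "A:72:HA": 4.10,
        "A:74:HA": 4.55,
        "A:83:HA": 3.90,
        "A:87:HE1": 7.20,
    }
    ground_truth = {
        "A": "A:87:HD2",
        "C": "A:83:HB3",
        "D": "A:74:HB2",
        "E": "A:72:HB3",
    }
    return structure, truth, partner_shifts, ground_truth


@pytest.fixture(scope="session")
def calibration():
    """Anchor: exchangeable His ring NH at 4.94 A observed at 2500 Hz."""
    return Calibration(4.94, 2500.0, 30.0)


@pytest.fixture
def rng():
    return np.random.default_rng(20211)
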