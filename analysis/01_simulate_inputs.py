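#!/usr/bin/env python
"""Generate every synthetic input the downstream analyses consume.

Writes, under results/simulated/: a toy [Fe2S2] site as PDB with its
ground-truth distance table, a forward-modeled hyperfine peak table at
283/293 K, and rigid-rotor 15N relaxation tables (noiseless and with 5%
noise) for an 11.64 ns tumbler at 500 MHz.
"""

import argparse
from pathlib import Path

from clusterblind import (
    Calibration,
    HyperfineCoupling,
    SpinSystem,
    ToySiteSpec,
    io,
    make_peak_table,
    make_relaxation_table,
    make_toy_structure,
    write_structure,
)

RESULTS = Path(__file__).resolve().parent.parent / "results" / "simulated"


def main() -> int:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()
    RESULTS.mkdir(parents=True, exist_ok=True)

    structure, truth = make_toy_structure(ToySiteSpec(seed=args.seed))
    (RESULTS / "toy_site.pdb").write_text(write_structure(structure))
    io.write_tsv(truth, RESULTS / "toy_site_distances.tsv",
                 "ground-truth nearest-iron distances of the toy [Fe2S2] site")
    print(f"toy site: {len(structure.atoms)} atoms, "
          f"{len(truth)} protons -> {RESULTS / 'toy_site.pdb'}")

    # forward-model a hyperfine fingerprint: AF homodimer of two Fe3+,
    # couplings in the 1-3 MHz range, anchored on a 2500 Hz line at 4.94 A
    sys_ = SpinSystem(2.5, 2.5, 300.0)
    cal = Calibration(4.94, 2500.0, 30.0)
    couplings = [
        (HyperfineCoupling("A", 2.6, 2, ), 5.18, 3.0, False),
        (HyperfineCoupling("B", 2.2, 2), 4.94, 7.0, True),
        (HyperfineCoupling("C", 2.0, 2), 4.32, 3.0, False),
        (HyperfineCoupling("D", 1.6, 1), 4.25, 3.0, False),
        (HyperfineCoupling("E", 1.2, 1), 4.35, 3.0, False),
    ]
    peaks = make_peak_table(sys_, couplings, [283.0, 293.0], cal,
                            noise_ppm=0.05, seed=args.seed)
    io.write_tsv(peaks, RESULTS / "peaks.tsv",
                 "forward-modeled hyperfine peak table, AF homodimer "
                 "S1=S2=5/2, J=300 cm^-1")
    print(f"peak table: {peaks['label'].nunique()} signals x "
          f"{peaks['T_kelvin'].nunique()} temperatures -> {RESULTS / 'peaks.tsv'}")

    for noise, name in [(0.0, "relaxation_clean.tsv"),
                        (0.05, "relaxation_noisy.tsv")]:
        table = make_relaxation_table(11.64, 500.0, 40, noise, seed=args.seed)
        io.write_tsv(table, RESULTS / name,
                     f"rigid-rotor 15N relaxation, tau_c=11.64 ns, 500 MHz, "
                     f"noise={noise:.0%}")
    print(f"relaxation tables (0% and 5% noise, 40 residues) -> {RESULTS}")
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
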