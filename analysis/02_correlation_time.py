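#!/usr/bin/env python
"""Estimate the rotational correlation time from 15N R2/R1.

A 19.4 kDa homodimer near 298 K should tumble at tau_c ~ 0.6 ns/kDa =
11.64 ns. This driver forward-simulates rigid-rotor 15N relaxation at
500 MHz at exactly that tau_c, inverts the R2/R1 ratio per residue, and
reports the recovered value — noiseless (exact round trip) and with 5%
Gaussian noise over 40 residues (median and scatter). Writes
results/correlation_time.tsv.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from clusterblind import io, simulate_n15_relaxation, tauc_from_mass, tauc_from_n15
from clusterblind.synth import make_relaxation_table

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> int:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()
    RESULTS.mkdir(parents=True, exist_ok=True)

    truth = tauc_from_mass(19.4)
    print(f"empirical mass rule: 0.6 ns/kDa x 19.4 kDa = {truth:.2f} ns")

    r1, r2, noe = simulate_n15_relaxation(truth, 500.0)
    exact = tauc_from_n15(r1, r2, 500.0)
    print(f"noiseless round trip at 500 MHz: R1={r1:.2f} R2={r2:.2f} "
          f"NOE={noe:.2f} -> tau_c = {exact:.2f} ns (recovered to "
          f"{abs(exact - truth):.1e} ns)")

    table = make_relaxation_table(truth, 500.0, 40, noise_fraction=0.05,
                                  seed=args.seed)
    estimates = []
    for _, row in table.iterrows():
        try:
            estimates.append(tauc_from_n15(row["R1"], row["R2"], 500.0))
        except ValueError:
            continue
    est = np.array(estimates)
    print(f"5% noise, 40 residues: median tau_c = {np.median(est):.1f} ns, "
          f"sd = {est.std():.2f} ns ({len(est)} residues invertible)")

    out = pd.DataFrame({"resnum": range(1, len(est) + 1), "tauc_ns": est})
    io.write_tsv(out, RESULTS / "correlation_time.tsv",
                 f"per-residue tau_c from noisy rigid-rotor 15N data; "
                 f"truth {truth:.2f} ns; seed {args.seed}")
    print(f"-> {RESULTS / 'correlation_time.tsv'}")
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
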