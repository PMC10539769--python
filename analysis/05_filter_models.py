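#!/usr/bin/env python
"""Relaxation-tailored filter models and the blind-sphere comparison.

Evaluates the inversion-recovery R1 filter (null point, suppression
band), the INEPT/CON transfer efficiency (standard 12.5 ms vs tailored
8 ms delay, crossover R2, optimal delays), and composes them with r^-6
linewidth predictions on a synthetic amide shell to show how the
tailored filter shrinks the blind sphere around the cluster. Writes
results/inept_efficiency.tsv and results/blind_sphere.tsv.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from clusterblind import (
    Calibration,
    INEPTConfig,
    IRFilterConfig,
    blind_sphere_radius,
    calibrated_prediction,
    inept_crossover_r2,
    inept_efficiency,
    io,
    ir_null_r1,
    ir_steady_state,
    optimal_transfer_time,
)
from clusterblind.filters import efficiency_curve

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> int:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()
    RESULTS.mkdir(parents=True, exist_ok=True)

    ir = IRFilterConfig(tau_ir=0.018, acquisition=0.0165, recycle=0.011)
    null = ir_null_r1(ir)
    print(f"IR filter (18 ms inversion, 27.5 ms recovery): null at "
          f"R1 = {null:.1f} 1/s — amides with R1 < ~20 1/s are suppressed")
    for r1 in (5.0, 20.0, 40.0, 80.0):
        print(f"  R1={r1:5.0f} 1/s -> M = {ir_steady_state(r1, ir):+.3f}")

    standard = INEPTConfig(delta=0.0125, j_cn=15.0)
    tailored = INEPTConfig(delta=0.008, j_cn=15.0)
    r_star = inept_crossover_r2(standard, tailored)
    print(f"\nINEPT C'-N transfer (J = 15 Hz): 8 ms delay beats 12.5 ms for "
          f"R2 > {r_star:.0f} 1/s")
    loss10 = inept_efficiency(10.0, standard) / inept_efficiency(0.0, standard)
    print(f"  at R2 = 10 1/s the standard transfer keeps {loss10:.0%} of its "
          f"relaxation-free efficiency")
    for r2 in (0.0, 10.0, 50.0):
        print(f"  optimal total transfer time at R2={r2:4.0f}: "
              f"{optimal_transfer_time(r2, 15.0) * 1e3:.1f} ms")
    grid = np.linspace(0.0, 100.0, 201)
    curves = pd.DataFrame({
        "r2_s": grid,
        "eff_12p5ms": np.asarray(inept_efficiency(grid, standard)),
        "eff_8ms": np.asarray(inept_efficiency(grid, tailored)),
    })
    io.write_tsv(curves, RESULTS / "inept_efficiency.tsv",
                 "C'-N INEPT efficiency vs R2, standard vs shortened delay")

    # blind-sphere comparison on a synthetic amide shell (3-12 A, 0.5 A
    # steps from the iron). Linewidths and paramagnetic R1 both follow the
    # package's own models: the r^-6 anchor for linewidths and the Solomon
    # dipolar R1 (11.6 ns tumbler, 1e-10 s electron, ladder-averaged
    # moment at 298 K). The conventional experiment only sees lines that
    # stay sharp (<= 300 Hz); the IR-tailored experiment tolerates
    # hyperfine broadening up to the 4 kHz bound but suppresses the
    # slow-relaxing background — the two are complementary, and their
    # union is what shrinks the blind sphere.
    from clusterblind import RelaxationEnvironment, SpinSystem, \
        dipolar_rate, effective_s_squared, recoverable_set

    cal = Calibration(4.94, 2500.0, 30.0)
    env = RelaxationEnvironment.from_proton_mhz(
        700.0, t_kelvin=298.0, tau_r=11.6e-9, tau_s=1e-10)
    ssq = effective_s_squared(SpinSystem(2.5, 2.5, 300.0), 298.0, 1)
    radii = np.arange(3.0, 12.01, 0.5)
    rows, r1_by_id, dnu_by_id = [], {}, {}
    for i, r in enumerate(radii):
        pid = f"A:{100 + i}:H"
        dnu_by_id[pid] = calibrated_prediction(cal, float(r))
        r1_by_id[pid] = 1.0 + dipolar_rate(env, 0, float(r), "R1",
                                           s_squared=ssq)
        rows.append({"chain": "A", "resnum": 100 + i, "resname": "ALA",
                     "atom": "H", "fe_label": "FE1", "r_angstrom": float(r),
                     "bonds": np.nan, "fe_coord_label": None,
                     "r_coord_angstrom": np.nan, "degenerate": False})
    shell = pd.DataFrame(rows)
    conventional = set(recoverable_set(r1_by_id, dnu_by_id, ir=None,
                                       detection_threshold_hz=300.0))
    tailored = set(recoverable_set(r1_by_id, dnu_by_id, ir=ir,
                                   detection_threshold_hz=4000.0))
    all_ids = set(r1_by_id)
    bs_std = blind_sphere_radius(shell, all_ids - conventional)
    bs_comb = blind_sphere_radius(shell, all_ids - (conventional | tailored))
    shell["detected_conventional"] = [pid in conventional for pid in r1_by_id]
    shell["detected_combined"] = [pid in (conventional | tailored)
                                  for pid in r1_by_id]
    recovered = sorted(tailored - conventional)
    print(f"\nsynthetic amide shell (3-12 A, 0.5 A steps):")
    print(f"  conventional experiment detects {len(conventional)}/{len(all_ids)} "
          f"amides; blind sphere {bs_std.radius_angstrom:.1f} A")
    print(f"  IR-tailored experiment recovers {len(recovered)} additional "
          f"amides ({', '.join(recovered)})")
    print(f"  combined blind sphere: {bs_comb.radius_angstrom:.1f} A — the "
          f"innermost shell stays broadened beyond the 4 kHz bound, and an "
          f"amide whose R1 falls on the filter null (~{null:.0f} 1/s) remains "
          f"invisible to both experiments")
    io.write_tsv(shell, RESULTS / "blind_sphere.tsv",
                 "synthetic amide shell with per-experiment detectability")
    print(f"-> {RESULTS / 'blind_sphere.tsv'}")
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
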