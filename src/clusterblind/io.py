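"""TSV dialects and packaged fixtures.

All tables are tab-separated with '#' comment headers and explicit unit
suffixes in the column names (r_angstrom, linewidth_hz, T_kelvin, ...).
Two reference tables ship with the package: the hyperfine peak table of
oxidized [Fe2S2] mitoNEET (two temperatures, 600 MHz) and the
metal-to-proton distance table of its cluster-binding residues.
"""

from __future__ import annotations

from importlib import resources
from io import StringIO
from pathlib import Path

import numpy as np
import pandas as pd

from .assignment import HyperfineSignal

SIGNALS_COLUMNS = ["label", "T_kelvin", "shift_ppm", "linewidth_hz", "exchangeable"]
DISTANCE_REQUIRED = ["chain", "resnum", "resname", "atom", "fe_label",
                     "r_angstrom", "bonds"]
RELAXATION_COLUMNS = ["resnum", "R1", "R2", "NOE", "field_mhz"]
NOE_COLUMNS = ["irradiated_label", "peak_shift_ppm"]


def _read_tsv(source) -> pd.DataFrame:
    return pd.read_csv(source, sep="\t", comment="#")


def _require(df: pd.DataFrame, columns, what: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{what}: missing required column(s) {missing}; "
                         f"found {list(df.columns)}")


def read_signals(source) -> pd.DataFrame:
    df = _read_tsv(source)
    _require(df, SIGNALS_COLUMNS, "signals table")
    df["exchangeable"] = df["exchangeable"].astype(bool)
    return df


def read_distances(source) -> pd.DataFrame:
    df = _read_tsv(source)
    _require(df, DISTANCE_REQUIRED, "distance table")
    if "degenerate" not in df.columns:
        df["degenerate"] = False
    if "fe_coord_label" not in df.columns:
        df["fe_coord_label"] = df["fe_label"]
        df["r_coord_angstrom"] = df["r_angstrom"]
    if (df.loc[~df["degenerate"], "r_angstrom"] <= 0).any():
        raise ValueError("distance table: non-positive r_angstrom")
    return df


def read_relaxation(source) -> pd.DataFrame:
    df = _read_tsv(source)
    _require(df, RELAXATION_COLUMNS, "relaxation table")
    return df


def read_noe(source) -> pd.DataFrame:
    df = _read_tsv(source)
    _require(df, NOE_COLUMNS, "NOE table")
    return df


def write_tsv(df: pd.DataFrame, path, header_comment: str | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)


def _fixture_text(name: str) -> str:
    return resources.files("clusterblind.data").joinpath(name).read_text()


def load_reference_signals() -> pd.DataFrame:
    """Packaged hyperfine peak table (oxidized state, 283/293 K, 600 MHz)."""
    return read_signals(StringIO(_fixture_text("table1_signals.tsv")))


def load_reference_distances() -> pd.DataFrame:
    """Packaged metal-to-proton distance table for cluster-bound residues."""
    return read_distances(StringIO(_fixture_text("table2_distances.tsv")))


def signals_from_table(df: pd.DataFrame) -> list[HyperfineSignal]:
    """Collapse a long-format signals table into HyperfineSignal objects."""
    out = []
    for label, grp in df.groupby("label", sort=False):
        shifts = tuple(sorted(zip(grp["T_kelvin"], grp["shift_ppm"])))
        out.append(HyperfineSignal(
            label=str(label),
            shifts=shifts,
            linewidth_hz=float(grp["linewidth_hz"].iloc[0]),
            exchangeable=bool(grp["exchangeable"].iloc[0]),
        ))
    return out
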