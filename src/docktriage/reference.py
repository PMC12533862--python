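"""Packaged reference values from the SGLT2–MAP17 repurposing screen.

Two small fixture tables ship with the package: the empagliflozin re-docking
benchmark (symmetry-corrected RMSD of ten docking method/search-volume
combinations against the crystal pose) and the post-docking MD stability
table (per-compound median ligand RMSD over the final nanosecond of three
10 ns replicates). They serve as worked-example inputs for the benchmark
selector and the stability ranking.
"""

from __future__ import annotations

import importlib.resources

import pandas as pd

__all__ = ["load_docking_benchmark", "load_window_medians"]


def _read(name: str) -> pd.DataFrame:
    path = importlib.resources.files("docktriage.data").joinpath(name)
    with importlib.resources.as_file(path) as p:
        return pd.read_csv(p, sep="\t")


def load_docking_benchmark() -> dict[str, float]:
    """Docking-method labels → symmetry-corrected re-docking RMSD in Å."""
    df = _read("docking_benchmark.tsv")
    return dict(zip(df["label"], df["rmsd"].astype(float)))


def load_window_medians() -> pd.DataFrame:
    """MD stability table: compound, window-median ligand RMSD (Å), inhibitor flag."""
    df = _read("md_window_medians.tsv")
    df["is_inhibitor"] = df["is_inhibitor"].astype(bool)
    return df
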