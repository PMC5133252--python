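"""Amino-acid scale tables shipped with the package.

All scales cover the 20 standard residues: Kyte-Doolittle hydropathy
(GRAVY), the Boman protein-binding scale, the 10 normalized Kidera
factors, average residue masses, the EMBOSS pKa set, and the nine-class
composition table. Files live under ``data/scales`` with a version stamp.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .types import STANDARD_AA

WATER_MASS = 18.01524  # Da, added once per peptide

__all__ = ["ScaleTables", "load_scales", "WATER_MASS"]


@dataclass(frozen=True)
class ScaleTables:
    kyte_doolittle: dict[str, float]
    boman_scale: dict[str, float]
    kidera_table: dict[str, tuple[float, ...]]
    residue_masses: dict[str, float]
    pka_set: dict[str, tuple[float, int]]  # group -> (pKa, charge sign +1/-1)
    class_table: dict[str, frozenset[str]]
    version: str

    def __post_init__(self) -> None:
        residues = set(STANDARD_AA)
        for name, table in (
            ("kyte_doolittle", self.kyte_doolittle),
            ("boman_scale", self.boman_scale),
            ("kidera_table", self.kidera_table),
            ("residue_masses", self.residue_masses),
        ):
            if set(table) != residues:
                raise ValueError(f"scale {name} does not cover the 20 residues")


def _read(name: str) -> pd.DataFrame:
    ref = resources.files("bcelldev.data.scales").joinpath(name)
    with resources.as_file(ref) as path:
        return pd.read_csv(path)


_CACHE: ScaleTables | None = None


def load_scales() -> ScaleTables:
    """Load (and cache) the bundled scale tables."""
    global _CACHE
    if _CACHE is not None:
        return _CACHE
    kd = _read("kyte_doolittle.csv").set_index("residue")["value"].to_dict()
    boman = _read("boman.csv").set_index("residue")["value"].to_dict()
    kdf = _read("kidera.csv").set_index("residue")
    kidera = {r: tuple(row) for r, row in kdf.iterrows()}
    masses = _read("residue_masses.csv").set_index("residue")["average_mass"].to_dict()
    pka_df = _read("pka_emboss.csv")
    pka = {
        row["group"]: (float(row["pka"]), 1 if row["sign"] == "positive" else -1)
        for _, row in pka_df.iterrows()
    }
    classes_df = _read("classes.csv")
    classes = {
        row["class"]: frozenset(row["residues"]) for _, row in classes_df.iterrows()
    }
    version = (
        resources.files("bcelldev.data.scales").joinpath("VERSION")
        .read_text().splitlines()[0].strip()
    )
    _CACHE = ScaleTables(
        kyte_doolittle=kd,
        boman_scale=boman,
        kidera_table=kidera,
        residue_masses=masses,
        pka_set=pka,
        class_table=classes,
        version=version,
    )
    return _CACHE
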