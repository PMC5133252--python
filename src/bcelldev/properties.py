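"""CDR3 physicochemical descriptors.

Per-sequence descriptors of the anchor-free CDR3 peptide: length, GRAVY
(mean Kyte-Doolittle hydropathy), Boman index (mean protein-binding
potential, kcal/mol per residue), molecular weight (average masses, Da),
isoelectric point (Henderson-Hasselbalch net charge, EMBOSS pKa set,
bisection root), Ikai's aliphatic index, nine amino-acid class counts,
and the mean of the 10 Kidera factors. All mean-type descriptors reduce
to the single-residue table entry on a homopolymer.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .scales import WATER_MASS, ScaleTables, load_scales
from .types import STANDARD_AA, Clonotype

logger = logging.getLogger(__name__)

__all__ = [
    "ScoringError",
    "gravy",
    "boman_index",
    "molecular_weight",
    "isoelectric_point",
    "net_charge",
    "aliphatic_index",
    "class_counts",
    "kidera_factors",
    "property_vector",
    "property_table",
    "PROPERTY_COLUMNS",
    "KIDERA_COLUMNS",
]


class ScoringError(ValueError):
    """Sequence contains a residue outside the 20-letter alphabet."""


def _check(seq: str) -> None:
    if not seq:
        raise ScoringError("empty sequence")
    for i, aa in enumerate(seq):
        if aa not in STANDARD_AA:
            raise ScoringError(f"non-standard residue {aa!r} at position {i}")


def _mean_scale(seq: str, table: dict[str, float]) -> float:
    _check(seq)
    return sum(table[aa] for aa in seq) / len(seq)


def gravy(seq: str, scales: ScaleTables | None = None) -> float:
    """Grand average of hydropathy (mean Kyte-Doolittle value)."""
    scales = scales or load_scales()
    return _mean_scale(seq, scales.kyte_doolittle)


def boman_index(seq: str, scales: ScaleTables | None = None) -> float:
    """Mean residue-wise protein-binding potential (higher = more prone)."""
    scales = scales or load_scales()
    return _mean_scale(seq, scales.boman_scale)


def molecular_weight(seq: str, scales: ScaleTables | None = None) -> float:
    """Peptide Mr in Da: sum of average residue masses plus one water."""
    scales = scales or load_scales()
    _check(seq)
    return sum(scales.residue_masses[aa] for aa in seq) + WATER_MASS


def net_charge(seq: str, ph: float, scales: ScaleTables | None = None) -> float:
    """Henderson-Hasselbalch net charge at a given pH (termini included)."""
    scales = scales or load_scales()
    _check(seq)
    groups = [("Nterm", 1), ("Cterm", 1)]
    for aa in seq:
        if aa in scales.pka_set:
            groups.append((aa, 1))
    charge = 0.0
    for name, n in groups:
        pka, sign = scales.pka_set[name]
        if sign > 0:
            charge += n / (1.0 + 10.0 ** (ph - pka))
        else:
            charge -= n / (1.0 + 10.0 ** (pka - ph))
    return charge


def isoelectric_point(
    seq: str,
    scales: ScaleTables | None = None,
    tol: float = 1e-4,
) -> float:
    """pH at which the net charge crosses zero, by bisection on [0, 14].

    The charge function is strictly decreasing in pH, so the root is
    unique. The interval is bisected until it is narrower than 1e-7 pH
    (well past ``tol`` in charge even where the titration curve is
    shallow), which pins the root to far better than 0.001 pH.
    """
    scales = scales or load_scales()
    _check(seq)
    lo, hi = 0.0, 14.0
    while hi - lo > 1e-7:
        mid = 0.5 * (lo + hi)
        if net_charge(seq, mid, scales) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def aliphatic_index(seq: str) -> float:
    """Ikai's aliphatic index: X_Ala + 2.9 X_Val + 3.9 (X_Ile + X_Leu),
    where X are mole percentages."""
    _check(seq)
    n = len(seq)
    x = lambda aa: 100.0 * seq.count(aa) / n
    return x("A") + 2.9 * x("V") + 3.9 * (x("I") + x("L"))


def class_counts(seq: str, scales: ScaleTables | None = None) -> dict[str, int]:
    """Residue counts in each of the nine amino-acid classes."""
    scales = scales or load_scales()
    _check(seq)
    return {
        cls: sum(1 for aa in seq if aa in members)
        for cls, members in scales.class_table.items()
    }


def kidera_factors(seq: str, scales: ScaleTables | None = None) -> np.ndarray:
    """Component-wise mean of the 10 Kidera factors over the sequence."""
    scales = scales or load_scales()
    _check(seq)
    rows = np.array([scales.kidera_table[aa] for aa in seq])
    return rows.mean(axis=0)


CLASS_NAMES = (
    "tiny", "small", "aliphatic", "aromatic", "nonpolar",
    "polar", "charged", "basic", "acidic",
)
KIDERA_COLUMNS = tuple(f"kf{i}" for i in range(1, 11))
PROPERTY_COLUMNS = (
    ("length", "gravy", "boman", "mw", "pi", "aliphatic_index")
    + CLASS_NAMES
    + KIDERA_COLUMNS
)


def property_vector(seq: str, scales: ScaleTables | None = None) -> dict[str, float]:
    """All descriptors of one CDR3 peptide, keyed by column name."""
    scales = scales or load_scales()
    vec: dict[str, float] = {
        "length": len(seq),
        "gravy": gravy(seq, scales),
        "boman": boman_index(seq, scales),
        "mw": molecular_weight(seq, scales),
        "pi": isoelectric_point(seq, scales),
        "aliphatic_index": aliphatic_index(seq),
    }
    vec.update(class_counts(seq, scales))
    vec.update(dict(zip(KIDERA_COLUMNS, kidera_factors(seq, scales))))
    return vec


def property_table(
    clonotypes: Iterable[Clonotype],
    scales: ScaleTables | None = None,
) -> pd.DataFrame:
    """One descriptor row per clonotype.

    Clonotypes whose CDR3 peptide is empty or contains non-standard
    residues are skipped with a logged reason (the CDR3-stage filters
    normally remove them upstream).
    """
    scales = scales or load_scales()
    rows = []
    n_skipped = 0
    for i, cl in enumerate(clonotypes):
        seq = cl.cdr3_aa
        cid = cl.representative.read_id or str(i)
        try:
            vec = property_vector(seq, scales)
        except ScoringError as exc:
            logger.info("skipping clonotype %s: %s", cid, exc)
            n_skipped += 1
            continue
        row = {
            "clonotype_id": cid,
            "donor_id": cl.donor_id,
            "subset": cl.subset,
            "chain": cl.chain,
        }
        row.update(vec)
        rows.append(row)
    if n_skipped:
        logger.info("property_table skipped %d clonotypes", n_skipped)
    columns = ["clonotype_id", "donor_id", "subset", "chain", *PROPERTY_COLUMNS]
    return pd.DataFrame(rows, columns=columns)
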