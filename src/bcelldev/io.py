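"""Reading and writing annotated-rearrangement tables.

The native dialect is the community AIRR rearrangement TSV (``sequence_id``,
``v_call``, ``d_call``, ``j_call``, ``junction``, ``junction_aa``,
``productive`` ...) extended with ``donor_id`` and ``subset`` columns.
An adapter maps IMGT/HighV-QUEST Summary-table headers onto the same
internal model. Internally the CDR3 excludes the conserved anchors
(C104 and W/F118); IMGT-convention ``junction`` columns, which include
them, are trimmed on load. Tables written by this module use the AIRR
``cdr3``/``cdr3_aa`` columns, which are anchor-free by definition, so a
write/read round trip is exact.
"""

from __future__ import annotations

import logging
from dataclasses import asdict
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio.Seq import Seq

from .types import CHAINS, Rearrangement, GeneNameError, parse_gene_name

logger = logging.getLogger(__name__)

__all__ = [
    "ConfigurationError",
    "read_rearrangements",
    "write_rearrangements",
    "write_table",
    "rearrangements_to_frame",
]


class ConfigurationError(ValueError):
    """Input table does not match the expected schema."""


_AIRR_REQUIRED = (
    "sequence_id",
    "v_call",
    "j_call",
    "productive",
    "donor_id",
    "subset",
)

# IMGT/HighV-QUEST Summary-table headers -> AIRR names
_IMGT_SUMMARY_MAP = {
    "Sequence ID": "sequence_id",
    "V-GENE and allele": "v_call",
    "D-GENE and allele": "d_call",
    "J-GENE and allele": "j_call",
    "JUNCTION": "junction",
    "AA JUNCTION": "junction_aa",
    "Functionality": "productive",
    "donor_id": "donor_id",
    "subset": "subset",
    "locus": "locus",
}

_TRUE = {"t", "true", "1", "yes", "productive"}
_FALSE = {"f", "false", "0", "no", "unproductive", "non-productive"}


def _parse_productive(value) -> bool:
    if isinstance(value, bool):
        return value
    text = str(value).strip().lower()
    if text in _TRUE or text.startswith("productive"):
        return True
    if text in _FALSE or text.startswith("unproductive"):
        return False
    raise ConfigurationError(f"cannot interpret productive flag {value!r}")


def _translate(nt: str) -> str:
    if not nt or len(nt) % 3 != 0:
        return ""
    aa = str(Seq(nt).translate())
    return "" if "*" in aa else aa


def _cell(row, col: str) -> str:
    val = row.get(col, "")
    if val is None or (isinstance(val, float) and pd.isna(val)):
        return ""
    return str(val).strip()


def read_rearrangements(
    path: str | Path,
    format: str = "airr_tsv",
    junction_includes_anchors: bool = True,
) -> list[Rearrangement]:
    """Load one :class:`Rearrangement` per row of an annotated table.

    Parameters
    ----------
    path:
        TSV (``airr_tsv``) or IMGT Summary CSV/TSV (``imgt_csv``) file.
    junction_includes_anchors:
        Whether a ``junction`` column follows the IMGT convention of
        including C104 and W/F118 (default); anchors are trimmed on load.
        Ignored when the table carries anchor-free ``cdr3`` columns.

    Rows with unparseable gene names or with a D call on a light chain
    are returned flagged (``record.flags``), not dropped; accepted and
    flagged counts are logged.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        if format == "airr_tsv":
            df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        elif format == "imgt_csv":
            df = pd.read_csv(path, sep=None, engine="python", dtype=str,
                             keep_default_na=False)
            df = df.rename(columns=_IMGT_SUMMARY_MAP)
        else:
            raise ConfigurationError(f"unknown format {format!r}")
    except pd.errors.EmptyDataError:
        logger.warning("empty input file %s", path)
        return []

    if df.empty and not len(df.columns):
        logger.warning("empty input file %s", path)
        return []

    for col in _AIRR_REQUIRED:
        if col not in df.columns:
            raise ConfigurationError(f"missing required column {col!r}")
    if "junction" not in df.columns and "cdr3" not in df.columns:
        raise ConfigurationError("missing required column 'junction' (or 'cdr3')")
    if "locus" not in df.columns and "chain" not in df.columns:
        raise ConfigurationError("missing required column 'locus'")
    chain_col = "locus" if "locus" in df.columns else "chain"
    has_cdr3 = "cdr3" in df.columns

    records: list[Rearrangement] = []
    n_flagged = 0
    for _, row in df.iterrows():
        flags: list[str] = []
        chain = _cell(row, chain_col)
        if chain not in CHAINS:
            raise ConfigurationError(f"unknown chain/locus value {chain!r}")
        v_call = _cell(row, "v_call")
        d_call = _cell(row, "d_call") or None
        j_call = _cell(row, "j_call")
        for seg, call in (("v_call", v_call), ("j_call", j_call)):
            try:
                parse_gene_name(call)
            except GeneNameError:
                flags.append(f"unparseable_gene:{seg}")
        if d_call is not None:
            if chain != "IGH":
                flags.append("d_call_on_light_chain")
            else:
                try:
                    parse_gene_name(d_call)
                except GeneNameError:
                    flags.append("unparseable_gene:d_call")

        if has_cdr3:
            cdr3_nt = _cell(row, "cdr3")
            cdr3_aa = _cell(row, "cdr3_aa")
        else:
            junction = _cell(row, "junction")
            junction_aa = _cell(row, "junction_aa")
            if junction_includes_anchors and len(junction) >= 6:
                cdr3_nt = junction[3:-3]
                cdr3_aa = junction_aa[1:-1] if len(junction_aa) >= 2 else ""
            else:
                cdr3_nt = junction
                cdr3_aa = junction_aa
        productive = _parse_productive(row["productive"])
        if productive and cdr3_nt and not cdr3_aa:
            cdr3_aa = _translate(cdr3_nt)
        if (
            productive
            and cdr3_aa
            and len(cdr3_aa) != len(cdr3_nt) // 3
        ):
            flags.append("cdr3_translation_mismatch")

        dup = _cell(row, "duplicate_count")
        rec = Rearrangement(
            read_id=_cell(row, "sequence_id"),
            donor_id=_cell(row, "donor_id"),
            subset=_cell(row, "subset"),
            chain=chain,
            v_call=v_call,
            d_call=d_call,
            j_call=j_call,
            cdr3_nt=cdr3_nt,
            cdr3_aa=cdr3_aa,
            productive=productive,
            duplicate_count=int(dup) if dup else 1,
            sequence=_cell(row, "sequence"),
            flags=flags,
        )
        if flags:
            n_flagged += 1
        records.append(rec)
    logger.info(
        "read %d rearrangements from %s (%d flagged)",
        len(records), path, n_flagged,
    )
    if not records:
        logger.warning("no rows in %s", path)
    return records


def rearrangements_to_frame(records: Iterable[Rearrangement]) -> pd.DataFrame:
    """Tabulate records with AIRR column names (anchor-free ``cdr3``)."""
    rows = []
    for r in records:
        d = asdict(r)
        rows.append(
            {
                "sequence_id": d["read_id"],
                "donor_id": d["donor_id"],
                "subset": d["subset"],
                "locus": d["chain"],
                "v_call": d["v_call"],
                "d_call": d["d_call"] or "",
                "j_call": d["j_call"],
                "cdr3": d["cdr3_nt"],
                "cdr3_aa": d["cdr3_aa"],
                "productive": "T" if d["productive"] else "F",
                "duplicate_count": d["duplicate_count"],
                "sequence": d["sequence"],
            }
        )
    columns = [
        "sequence_id", "donor_id", "subset", "locus", "v_call", "d_call",
        "j_call", "cdr3", "cdr3_aa", "productive", "duplicate_count",
        "sequence",
    ]
    return pd.DataFrame(rows, columns=columns)


def write_rearrangements(records: Sequence[Rearrangement], path: str | Path) -> None:
    """Write records as an AIRR-style TSV (see :func:`rearrangements_to_frame`)."""
    rearrangements_to_frame(records).to_csv(path, sep="\t", index=False)


def write_table(records, path: str | Path) -> None:
    """Write any tabular result as CSV (TSV if the suffix is ``.tsv``).

    Accepts a DataFrame or an iterable of dataclasses/dicts; always writes
    a header with a reproducible column order, UTF-8 encoded.
    """
    if records is None:
        raise ValueError("records must not be None")
    path = Path(path)
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        rows = [asdict(r) if hasattr(r, "__dataclass_fields__") else dict(r)
                for r in records]
        df = pd.DataFrame(rows)
    sep = "\t" if path.suffix == ".tsv" else ","
    df.to_csv(path, sep=sep, index=False, encoding="utf-8")
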