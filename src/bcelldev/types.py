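"""Core domain types for annotated immunoglobulin rearrangements.

The pipeline operates on the annotated-rearrangement layer: each record is
one sequencing read that has already been assigned germline V/(D)/J genes
and a junction, labelled with its donor and the sorted B-cell subset it came
from. Four developmental subsets are modelled (pre-B and immature from bone
marrow; transitional and naive from peripheral blood) across the three
immunoglobulin loci (IGH heavy chain, IGK/IGL light chains).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

SUBSETS: tuple[str, ...] = ("preB", "immature", "transitional", "naive")
#: bone-marrow vs peripheral-blood compartments (pre-B/immature are sorted
#: from marrow, transitional/naive from blood of the same donors)
BONE_MARROW_SUBSETS: tuple[str, ...] = ("preB", "immature")
PERIPHERAL_SUBSETS: tuple[str, ...] = ("transitional", "naive")
CHAINS: tuple[str, ...] = ("IGH", "IGK", "IGL")
LIGHT_CHAINS: tuple[str, ...] = ("IGK", "IGL")
SEGMENTS: tuple[str, ...] = ("V", "D", "J")

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"

_GENE_RE = re.compile(
    r"^(?P<locus>IG[HKL])(?P<segment>[VDJ])(?P<family>\d+)"
    r"(?P<rest>[-S/].*)?$"
)


class GeneNameError(ValueError):
    """Raised when a gene call cannot be parsed as an IMGT-style name."""


@dataclass(frozen=True, slots=True)
class GeneName:
    """A parsed immunoglobulin gene segment name.

    ``family`` is the leading digit group after the segment letter
    ("IGHV3-30" -> 3, "IGHJ6" -> 6); allele suffixes ("*01") are stripped.
    """

    locus: str
    segment: str
    family: int
    gene_label: str

    @property
    def family_label(self) -> str:
        """Family-level name, e.g. ``IGHV3``."""
        return f"{self.locus}{self.segment}{self.family}"


def parse_gene_name(raw: str) -> GeneName:
    """Parse an IMGT-style gene call such as ``IGHV3-23*01``.

    The allele suffix is removed deterministically (everything from the
    first ``*``). Raises :class:`GeneNameError` for names that do not
    follow the ``IG[HKL][VDJ]<family>...`` convention.
    """
    if not raw:
        raise GeneNameError("empty gene name")
    label = raw.strip().split("*", 1)[0].split(",", 1)[0].strip()
    # IMGT sometimes prefixes the species, e.g. "Homsap IGHV3-23"
    if " " in label:
        label = label.split()[-1]
    m = _GENE_RE.match(label)
    if m is None:
        raise GeneNameError(f"cannot parse gene name: {raw!r}")
    return GeneName(
        locus=m.group("locus"),
        segment=m.group("segment"),
        family=int(m.group("family")),
        gene_label=label,
    )


@dataclass(slots=True)
class Rearrangement:
    """One annotated read: gene calls, junction, and sample labels.

    ``cdr3_nt``/``cdr3_aa`` exclude the conserved anchor residues
    (C104 and W/F118); loaders trim anchors off IMGT-convention junction
    columns. ``duplicate_count`` counts reads collapsed into this record
    (1 for a raw read).
    """

    read_id: str
    donor_id: str
    subset: str
    chain: str
    v_call: str
    j_call: str
    cdr3_nt: str
    d_call: str | None = None
    cdr3_aa: str = ""
    productive: bool = True
    duplicate_count: int = 1
    sequence: str = ""
    #: populated by loaders when the row violates an invariant; the record
    #: is returned flagged rather than silently dropped
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.subset not in SUBSETS:
            raise ValueError(f"unknown subset {self.subset!r}")
        if self.chain not in CHAINS:
            raise ValueError(f"unknown chain {self.chain!r}")
        if self.duplicate_count < 1:
            raise ValueError("duplicate_count must be >= 1")

    @property
    def cdr3_aa_length(self) -> int:
        return len(self.cdr3_aa)

    def copy(self, **changes) -> "Rearrangement":
        new = replace(self, **changes)
        if "flags" not in changes:
            new.flags = list(self.flags)
        return new


@dataclass(slots=True)
class Clonotype:
    """A unique gene rearrangement after PCR-duplicate collapse.

    ``representative`` is the modal member (most frequent sequence, ties
    broken lexicographically); ``member_count`` is the number of reads
    the cluster absorbed.
    """

    representative: Rearrangement
    member_ids: list[str]

    @property
    def member_count(self) -> int:
        return len(self.member_ids)

    @property
    def donor_id(self) -> str:
        return self.representative.donor_id

    @property
    def subset(self) -> str:
        return self.representative.subset

    @property
    def chain(self) -> str:
        return self.representative.chain

    @property
    def v_call(self) -> str:
        return self.representative.v_call

    @property
    def j_call(self) -> str:
        return self.representative.j_call

    @property
    def d_call(self) -> str | None:
        return self.representative.d_call

    @property
    def cdr3_nt(self) -> str:
        return self.representative.cdr3_nt

    @property
    def cdr3_aa(self) -> str:
        return self.representative.cdr3_aa
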