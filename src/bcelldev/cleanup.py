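"""Quality filtering and PCR-duplicate collapse.

Antigen-naive repertoires contain no true clonal expansions, so reads
sharing a CDR3 are treated as PCR duplicates of a single gene
rearrangement. Reads are filtered (CDR3 length window 1-35 aa for heavy
chain, 1-20 aa for light chain; productivity for the CDR3-property stage),
then single-linkage clustered on CDR3 nucleotide edit distance within each
donor x subset x chain x V x J group, and each cluster is collapsed to a
modal representative.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Iterable, Sequence

import edlib

from .types import Clonotype, GeneNameError, Rearrangement, parse_gene_name

__all__ = [
    "FilterPolicy",
    "apply_filters",
    "levenshtein",
    "cluster_duplicates",
    "modal_representative",
]


@dataclass(frozen=True)
class FilterPolicy:
    """CDR3-length windows (inclusive, amino acids) and productivity rule.

    Defaults follow the normal length distributions used for cleanup:
    1-35 aa for heavy chains, 1-20 aa for light chains. ``require_productive``
    applies only at the CDR3-property stage; gene-usage analyses keep
    unproductive rearrangements.
    """

    heavy_cdr3_aa_min: int = 1
    heavy_cdr3_aa_max: int = 35
    light_cdr3_aa_min: int = 1
    light_cdr3_aa_max: int = 20
    require_productive: bool = True

    def __post_init__(self) -> None:
        for lo, hi in (
            (self.heavy_cdr3_aa_min, self.heavy_cdr3_aa_max),
            (self.light_cdr3_aa_min, self.light_cdr3_aa_max),
        ):
            if lo < 1 or hi < lo:
                raise ValueError("length window must satisfy 1 <= min <= max")

    def window(self, chain: str) -> tuple[int, int]:
        if chain == "IGH":
            return self.heavy_cdr3_aa_min, self.heavy_cdr3_aa_max
        return self.light_cdr3_aa_min, self.light_cdr3_aa_max


_STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")


def _gene_stage_reason(rec: Rearrangement) -> str | None:
    if any(f.startswith("unparseable_gene") for f in rec.flags):
        return "unparseable_gene"
    if "d_call_on_light_chain" in rec.flags:
        return "d_call_on_light_chain"
    try:
        parse_gene_name(rec.v_call)
        parse_gene_name(rec.j_call)
        if rec.d_call:
            parse_gene_name(rec.d_call)
    except GeneNameError:
        return "unparseable_gene"
    if not rec.cdr3_nt:
        return "no_cdr3"
    return None


def _cdr3_stage_reason(rec: Rearrangement, policy: FilterPolicy) -> str | None:
    reason = _gene_stage_reason(rec)
    if reason is not None:
        return reason
    if policy.require_productive and not rec.productive:
        return "unproductive"
    if not rec.cdr3_aa:
        return "untranslatable_cdr3"
    if set(rec.cdr3_aa) - _STANDARD_AA:
        return "nonstandard_residue"
    lo, hi = policy.window(rec.chain)
    if not lo <= len(rec.cdr3_aa) <= hi:
        return "cdr3_length"
    return None


def apply_filters(
    records: Iterable[Rearrangement],
    policy: FilterPolicy | None = None,
    stage: str = "cdr3_stage",
) -> tuple[list[Rearrangement], list[tuple[Rearrangement, str]]]:
    """Partition records into (kept, removed-with-reason).

    ``gene_stage`` keeps everything with parseable gene calls and a CDR3
    (used for gene-usage analyses); ``cdr3_stage`` additionally enforces
    productivity, a translatable standard-alphabet CDR3, and the
    chain-specific length window (used for physicochemical analyses).
    Every removed record carries exactly one primary reason code and
    ``kept + removed`` is a partition of the input.
    """
    if policy is None:
        policy = FilterPolicy()
    if stage not in ("gene_stage", "cdr3_stage"):
        raise ValueError(f"unknown filter stage {stage!r}")
    reason_of = _gene_stage_reason if stage == "gene_stage" else (
        lambda r: _cdr3_stage_reason(r, policy)
    )
    kept: list[Rearrangement] = []
    removed: list[tuple[Rearrangement, str]] = []
    for rec in records:
        reason = reason_of(rec)
        if reason is None:
            kept.append(rec)
        else:
            removed.append((rec, reason))
    return kept, removed


def levenshtein(a: str, b: str) -> int:
    """Unit-cost edit distance (substitution/insertion/deletion)."""
    if a == b:
        return 0
    return edlib.align(a, b, mode="NW", task="distance")["editDistance"]


def modal_representative(members: Sequence[Rearrangement]) -> Rearrangement:
    """Modal member of a duplicate cluster.

    The member whose full read sequence (falling back to CDR3 nucleotides
    when no read sequence is stored) is most frequent, ties broken by the
    lexicographically smallest sequence. The returned copy carries the
    cluster size in ``duplicate_count``.
    """
    if not members:
        raise ValueError("modal_representative of empty member list")
    keys = [m.sequence or m.cdr3_nt for m in members]
    counts = Counter(keys)
    best = min(counts.items(), key=lambda kv: (-kv[1], kv[0]))[0]
    rep = min(
        (m for m, k in zip(members, keys) if k == best),
        key=lambda m: (m.cdr3_nt, m.read_id),
    )
    total = sum(m.duplicate_count for m in members)
    return rep.copy(duplicate_count=total)


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def cluster_duplicates(
    records: Sequence[Rearrangement],
    threshold: int = 1,
    key: str = "donor_subset_chain_vj",
) -> list[Clonotype]:
    """Collapse PCR duplicates into unique gene rearrangements.

    Single-linkage clusters under ``levenshtein(cdr3_nt) <= threshold``
    within each grouping-key cell; threshold 0 reduces to exact CDR3
    grouping. ``key`` selects the cell: ``donor_subset_chain_vj``
    (default; a rearrangement shares its gene calls) or
    ``donor_subset_chain`` (CDR3-only clustering).

    The sum of member counts over the output equals the total input
    duplicate count, and output order is deterministic.
    """
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    if key == "donor_subset_chain_vj":
        keyfunc = lambda r: (r.donor_id, r.subset, r.chain, r.v_call, r.j_call)
    elif key == "donor_subset_chain":
        keyfunc = lambda r: (r.donor_id, r.subset, r.chain)
    else:
        raise ValueError(f"unknown grouping key {key!r}")

    groups: dict[tuple, list[Rearrangement]] = defaultdict(list)
    for rec in records:
        groups[keyfunc(rec)].append(rec)

    clonotypes: list[Clonotype] = []
    for gkey in sorted(groups):
        members = groups[gkey]
        # collapse exact CDR3 duplicates first; cluster unique strings only
        by_cdr3: dict[str, list[Rearrangement]] = defaultdict(list)
        for rec in members:
            by_cdr3[rec.cdr3_nt].append(rec)
        uniq = sorted(by_cdr3)
        uf = _UnionFind(len(uniq))
        if threshold > 0:
            # length difference bounds the edit distance from below
            order = sorted(range(len(uniq)), key=lambda i: len(uniq[i]))
            for a in range(len(order)):
                ia = order[a]
                for b in range(a + 1, len(order)):
                    ib = order[b]
                    if len(uniq[ib]) - len(uniq[ia]) > threshold:
                        break
                    if uf.find(ia) == uf.find(ib):
                        continue
                    d = edlib.align(
                        uniq[ia], uniq[ib], mode="NW", task="distance", k=threshold
                    )["editDistance"]
                    if d != -1:
                        uf.union(ia, ib)
        clusters: dict[int, list[Rearrangement]] = defaultdict(list)
        for i, cdr3 in enumerate(uniq):
            clusters[uf.find(i)].extend(by_cdr3[cdr3])
        for root in sorted(clusters):
            cl_members = clusters[root]
            rep = modal_representative(cl_members)
            # the representative CDR3 must be the modal CDR3 string
            cdr3_counts = Counter()
            for m in cl_members:
                cdr3_counts[m.cdr3_nt] += m.duplicate_count
            modal_cdr3 = min(cdr3_counts.items(), key=lambda kv: (-kv[1], kv[0]))[0]
            if rep.cdr3_nt != modal_cdr3:
                donor = min(
                    (m for m in cl_members if m.cdr3_nt == modal_cdr3),
                    key=lambda m: m.read_id,
                )
                rep = donor.copy(duplicate_count=rep.duplicate_count)
            clonotypes.append(
                Clonotype(
                    representative=rep,
                    member_ids=sorted(m.read_id for m in cl_members),
                )
            )
    return clonotypes
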