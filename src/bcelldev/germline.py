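"""Synthetic germline gene bundle for the repertoire simulator.

Gene names follow the standard human immunoglobulin nomenclature for the
loci and families the analyses care about; the nucleotide sequences are
synthetic (deterministically generated from a seed), constructed so that
CDR3 extraction is well defined: every V gene ends in-frame with a
conserved Cys codon (TGT/TGC) followed by a short CDR3 tail, and every J
gene carries a conserved Trp (heavy) or Phe (light) codon followed by a
Gly codon. A pre-generated bundle is checked into ``data/germline``.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .types import parse_gene_name

__all__ = ["GermlineBundle", "build_germline_bundle", "load_bundled_germline",
           "DEFAULT_BUNDLE_SEED", "GENE_NAMES"]

DEFAULT_BUNDLE_SEED = 20170301

V_TAIL_NT = 6   # germline nucleotides after the Cys codon contributing to CDR3
J_HEAD_NT = 9   # germline nucleotides before the J anchor contributing to CDR3
V_PREFIX_CODONS = 20
J_TAIL_NT = 18

GENE_NAMES: dict[tuple[str, str], list[str]] = {
    ("IGH", "V"): [
        "IGHV1-2", "IGHV1-3", "IGHV1-18", "IGHV1-46", "IGHV1-69",
        "IGHV2-5", "IGHV2-26",
        "IGHV3-7", "IGHV3-9", "IGHV3-11", "IGHV3-15", "IGHV3-21",
        "IGHV3-23", "IGHV3-30", "IGHV3-33", "IGHV3-48", "IGHV3-53",
        "IGHV3-74",
        "IGHV4-4", "IGHV4-31", "IGHV4-34", "IGHV4-39", "IGHV4-59",
        "IGHV5-51", "IGHV6-1", "IGHV7-4-1",
    ],
    ("IGH", "D"): [
        "IGHD1-1", "IGHD1-7", "IGHD1-26", "IGHD2-2", "IGHD2-15",
        "IGHD2-21", "IGHD3-3", "IGHD3-10", "IGHD3-22", "IGHD4-17",
        "IGHD5-12", "IGHD6-13", "IGHD6-19", "IGHD7-27",
    ],
    ("IGH", "J"): ["IGHJ1", "IGHJ2", "IGHJ3", "IGHJ4", "IGHJ5", "IGHJ6"],
    ("IGK", "V"): [
        "IGKV1-5", "IGKV1-39", "IGKV2-28", "IGKV2-30", "IGKV3-11",
        "IGKV3-15", "IGKV3-20", "IGKV4-1",
    ],
    ("IGK", "J"): ["IGKJ1", "IGKJ2", "IGKJ3", "IGKJ4", "IGKJ5"],
    ("IGL", "V"): [
        "IGLV1-40", "IGLV1-44", "IGLV1-51", "IGLV2-8", "IGLV2-11",
        "IGLV2-14", "IGLV2-23", "IGLV3-1", "IGLV3-21", "IGLV3-25",
    ],
    ("IGL", "J"): ["IGLJ1", "IGLJ2", "IGLJ3"],
}

_NT = np.array(list("ACGT"))
_STOPS = {"TAA", "TAG", "TGA"}


def _random_codons(rng: np.random.Generator, n: int) -> str:
    """n stop-free codons."""
    out = []
    while len(out) < n:
        codon = "".join(rng.choice(_NT, size=3))
        if codon not in _STOPS:
            out.append(codon)
    return "".join(out)


@dataclass(frozen=True)
class GermlineBundle:
    """Gene table with sequences and CDR3 anchor bookkeeping."""

    genes: pd.DataFrame  # gene, locus, segment, family, sequence

    def sequence(self, gene: str) -> str:
        return self._seq_map[gene]

    @property
    def _seq_map(self) -> dict[str, str]:
        return dict(zip(self.genes["gene"], self.genes["sequence"]))

    def names(self, locus: str, segment: str) -> list[str]:
        sel = self.genes[
            (self.genes["locus"] == locus) & (self.genes["segment"] == segment)
        ]
        return list(sel["gene"])

    def v_tail(self, gene: str) -> str:
        """Germline CDR3 contribution of a V gene (after the Cys codon)."""
        return self.sequence(gene)[-V_TAIL_NT:]

    def v_anchor_codon(self, gene: str) -> str:
        seq = self.sequence(gene)
        return seq[-V_TAIL_NT - 3 : -V_TAIL_NT]

    def j_head(self, gene: str) -> str:
        """Germline CDR3 contribution of a J gene (before the anchor)."""
        return self.sequence(gene)[:J_HEAD_NT]

    def j_anchor_codon(self, gene: str) -> str:
        return self.sequence(gene)[J_HEAD_NT : J_HEAD_NT + 3]

    def j_rest(self, gene: str) -> str:
        return self.sequence(gene)[J_HEAD_NT + 3 :]

    def to_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for _, row in self.genes.iterrows():
                fh.write(f">{row['gene']}\n{row['sequence']}\n")

    def to_table(self, path: str | Path) -> None:
        self.genes.to_csv(path, sep="\t", index=False)


def build_germline_bundle(seed: int = DEFAULT_BUNDLE_SEED) -> GermlineBundle:
    """Deterministically generate the synthetic germline set.

    V sequences end with ``<prefix codons> TGT/TGC <6 nt tail>`` so the
    conserved Cys sits in-frame; J sequences are ``<9 nt head> TGG|TTC
    GGx <tail>`` with Trp for heavy and Phe for light chains.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for (locus, segment), names in GENE_NAMES.items():
        for name in names:
            g = parse_gene_name(name)
            if segment == "V":
                cys = "TGT" if rng.random() < 0.7 else "TGC"
                seq = (
                    _random_codons(rng, V_PREFIX_CODONS)
                    + cys
                    + "".join(rng.choice(_NT, size=V_TAIL_NT))
                )
            elif segment == "D":
                length = int(rng.integers(12, 22))
                seq = "".join(rng.choice(_NT, size=length))
            else:
                anchor = "TGG" if locus == "IGH" else "TTC"
                seq = (
                    "".join(rng.choice(_NT, size=J_HEAD_NT))
                    + anchor
                    + "GG" + str(rng.choice(_NT))
                    + "".join(rng.choice(_NT, size=J_TAIL_NT - 3))
                )
            rows.append(
                {
                    "gene": name,
                    "locus": locus,
                    "segment": segment,
                    "family": g.family,
                    "sequence": seq,
                }
            )
    return GermlineBundle(genes=pd.DataFrame(rows))


def load_bundled_germline() -> GermlineBundle:
    """Load the pre-generated bundle shipped under ``data/germline``."""
    ref = resources.files("bcelldev.data.germline").joinpath("genes.tsv")
    with resources.as_file(ref) as path:
        genes = pd.read_csv(path, sep="\t")
    return GermlineBundle(genes=genes)
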