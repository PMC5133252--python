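"""V(D)J repertoire simulator with ground truth.

Generates annotated rearrangements with the statistical structure the
downstream analyses assume: four developmental subsets (three for light
chains, which pre-B cells have not yet rearranged) across multiple
donors, subset-specific V/D/J family-usage shifts at the effect sizes
the analyses are meant to recover, CDR3 length distributions that shrink
from pre-B to naive (attenuated in older donors), junctional trimming
and N-nucleotide insertion, PCR duplication, and per-base sequencing
error. Every read maps to exactly one true clonotype, so each pipeline
stage can be scored against ground truth.

Baseline family frequencies are synthetic constructs chosen so that the
subset *differences* are the recoverable signal; they are not
measurements of any real repertoire.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .germline import GermlineBundle, load_bundled_germline
from .types import Rearrangement, SUBSETS, parse_gene_name

__all__ = [
    "SubsetProfile",
    "SimulationConfig",
    "GroundTruth",
    "SimulationResult",
    "default_profiles",
    "simulate_repertoire",
]

_NT = np.array(list("ACGT"))
_STOPS = ("TAA", "TAG", "TGA")

LIGHT_SUBSETS = ("immature", "transitional", "naive")


class ProfileError(ValueError):
    """A subset profile is unusable (empty support, bad normalization)."""


@dataclass(frozen=True)
class SubsetProfile:
    """Gene-usage and junction statistics of one subset x chain.

    Family-frequency maps must sum to 1; ``per_gene_weights`` gives
    relative weights of named genes within their family (unnamed genes
    weight 1). ``cdr3_len_mean``/``sd`` are in amino acids of the
    anchor-free CDR3; ``trim_mean`` (nt, geometric) and
    ``n_insert_mean`` (nt, Poisson) parameterize junction formation.
    """

    subset: str
    chain: str
    v_family_freqs: dict[int, float]
    j_family_freqs: dict[int, float]
    d_family_freqs: dict[int, float] | None = None
    per_gene_weights: dict[str, float] = field(default_factory=dict)
    cdr3_len_mean: float = 15.0
    cdr3_len_sd: float = 3.0
    trim_mean: float = 2.0
    n_insert_mean: float = 4.0

    def __post_init__(self) -> None:
        maps = [self.v_family_freqs, self.j_family_freqs]
        if self.chain == "IGH":
            if self.d_family_freqs is None:
                raise ProfileError("heavy-chain profile needs d_family_freqs")
            maps.append(self.d_family_freqs)
        for m in maps:
            if not m:
                raise ProfileError("empty family support")
            if any(p < 0 for p in m.values()):
                raise ProfileError("negative family probability")
            if abs(sum(m.values()) - 1.0) > 1e-9:
                raise ProfileError("family frequencies must sum to 1")


def _shift(base: dict[int, float], targets: dict[int, float]) -> dict[int, float]:
    """Fix some family frequencies, redistribute the rest proportionally."""
    remaining = 1.0 - sum(targets.values())
    others = {f: p for f, p in base.items() if f not in targets}
    total = sum(others.values())
    out = dict(targets)
    for f, p in others.items():
        out[f] = p * remaining / total
    return {f: out[f] for f in sorted(out)}


# Baseline family frequencies (synthetic constructs; the planted subset
# deltas below are the signal the pipeline must recover).
_IGH_V_BASE = {1: 0.15, 2: 0.04, 3: 0.55, 4: 0.15, 5: 0.05, 6: 0.03, 7: 0.03}
_IGH_D_BASE = {1: 0.12, 2: 0.16, 3: 0.24, 4: 0.10, 5: 0.10, 6: 0.20, 7: 0.08}
_IGH_J_BASE = {1: 0.08, 2: 0.05, 3: 0.15, 4: 0.40, 5: 0.12, 6: 0.20}
_IGK_V = {1: 0.35, 2: 0.15, 3: 0.35, 4: 0.15}
_IGK_J = {1: 0.30, 2: 0.25, 3: 0.15, 4: 0.20, 5: 0.10}
_IGL_V_BASE = {1: 0.40, 2: 0.25, 3: 0.35}
_IGL_J_BASE = {1: 0.08, 2: 0.37, 3: 0.55}

# Planted subset deltas (percentage points / 100), each strictly above the
# bound the recovery analyses must clear:
#   IGHV3: pre-B 0.55 -> naive 0.41 (-14 pts), transitional 0.48
#   IGHJ6: transitional +9.5 pts over the 0.20 baseline; naive 0.15
#   IGHD2: bone marrow 0.16 -> transitional/naive 0.09 (-7 pts)
#   IGHD3: transitional +5.5 pts over the others' 0.24
#   IGLV2: immature 0.25 -> transitional/naive 0.37 (+12 pts)
#   IGLJ1: immature 0.08 -> transitional/naive 0.115 (+3.5 pts),
#          at the expense of IGLJ3
_IGH_V_BY_SUBSET = {
    "preB": _IGH_V_BASE,
    "immature": _IGH_V_BASE,
    "transitional": _shift(_IGH_V_BASE, {3: 0.48}),
    "naive": _shift(_IGH_V_BASE, {3: 0.41}),
}
_IGH_D_BY_SUBSET = {
    "preB": _IGH_D_BASE,
    "immature": _IGH_D_BASE,
    "transitional": _shift(_IGH_D_BASE, {2: 0.09, 3: 0.295}),
    # D3 pinned at baseline so the transitional D3 excess is exactly as
    # planted; D2's complement is redistributed over the other families
    "naive": _shift(_IGH_D_BASE, {2: 0.09, 3: 0.24}),
}
_IGH_J_BY_SUBSET = {
    "preB": _IGH_J_BASE,
    "immature": _IGH_J_BASE,
    "transitional": _shift(_IGH_J_BASE, {6: 0.295}),
    "naive": _shift(_IGH_J_BASE, {6: 0.15}),
}
_IGL_V_BY_SUBSET = {
    "immature": _IGL_V_BASE,
    "transitional": _shift(_IGL_V_BASE, {2: 0.37}),
    "naive": _shift(_IGL_V_BASE, {2: 0.37}),
}
_IGL_J_BY_SUBSET = {
    "immature": _IGL_J_BASE,
    "transitional": _shift(_IGL_J_BASE, {1: 0.115, 2: 0.37}),
    "naive": _shift(_IGL_J_BASE, {1: 0.115, 2: 0.37}),
}

# CDR3 length means (aa) shrink through development for heavy chains
_IGH_CDR3_MEAN = {"preB": 16.0, "immature": 15.7, "transitional": 15.4, "naive": 15.0}
_STAGE_FRACTION = {"preB": 0.0, "immature": 1 / 3, "transitional": 2 / 3, "naive": 1.0}

# within-family gene weights for genes with distinctive individual-gene
# behaviour in peripheral subsets (relative; unnamed genes weight 1)
_PERIPHERAL_GENE_WEIGHTS_IGH = {
    "IGHV3-15": 0.6, "IGHV3-30": 0.6, "IGHV3-33": 0.6, "IGHV3-9": 1.8,
    "IGHV1-18": 1.4, "IGHV1-69": 1.4,
}
_PERIPHERAL_GENE_WEIGHTS_IGL = {
    "IGLV2-14": 1.6, "IGLV2-23": 1.25, "IGLV2-8": 0.6, "IGLV2-11": 0.55,
}
_PERIPHERAL_GENE_WEIGHTS_IGK = {"IGKV3-11": 1.3, "IGKV3-20": 0.8, "IGKV4-1": 0.8}


def default_profiles(
    chain: str = "IGH", variant: str = "full"
) -> list[SubsetProfile]:
    """Default per-subset profiles embedding the planted effect sizes.

    Heavy chains cover all four subsets; light chains cover
    immature/transitional/naive (pre-B cells have not completed
    light-chain rearrangement). Kappa family usage is flat across
    subsets; the lambda IGLV2/IGLJ1 increases are planted in the
    peripheral subsets.

    ``variant`` (heavy chain only) selects which subset shifts are
    planted: ``"full"`` (all of them; the default), ``"transitional_only"``
    (only the transitional-specific shifts, the other three subsets
    share the bone-marrow baseline — used to probe whether clustering
    isolates transitional cells), or ``"null"`` (no shifts at all).
    """
    profiles = []
    if chain == "IGH":
        for subset in SUBSETS:
            if variant == "full":
                v, d, j = (_IGH_V_BY_SUBSET[subset], _IGH_D_BY_SUBSET[subset],
                           _IGH_J_BY_SUBSET[subset])
            elif variant == "transitional_only":
                if subset == "transitional":
                    v, d, j = (_IGH_V_BY_SUBSET[subset],
                               _IGH_D_BY_SUBSET[subset],
                               _IGH_J_BY_SUBSET[subset])
                else:
                    v, d, j = _IGH_V_BASE, _IGH_D_BASE, _IGH_J_BASE
            elif variant == "null":
                v, d, j = _IGH_V_BASE, _IGH_D_BASE, _IGH_J_BASE
            else:
                raise ProfileError(f"unknown profile variant {variant!r}")
            weights = (
                _PERIPHERAL_GENE_WEIGHTS_IGH
                if variant == "full" and subset in ("transitional", "naive")
                else {}
            )
            profiles.append(
                SubsetProfile(
                    subset=subset, chain="IGH",
                    v_family_freqs=v,
                    d_family_freqs=d,
                    j_family_freqs=j,
                    per_gene_weights=weights,
                    cdr3_len_mean=_IGH_CDR3_MEAN[subset],
                    cdr3_len_sd=3.0,
                )
            )
    elif chain == "IGK":
        for subset in LIGHT_SUBSETS:
            weights = (
                _PERIPHERAL_GENE_WEIGHTS_IGK if subset == "naive" else {}
            )
            profiles.append(
                SubsetProfile(
                    subset=subset, chain="IGK",
                    v_family_freqs=_IGK_V, j_family_freqs=_IGK_J,
                    per_gene_weights=weights,
                    cdr3_len_mean=9.2, cdr3_len_sd=1.5,
                    n_insert_mean=2.0,
                )
            )
    elif chain == "IGL":
        for subset in LIGHT_SUBSETS:
            weights = (
                _PERIPHERAL_GENE_WEIGHTS_IGL
                if subset in ("transitional", "naive") else {}
            )
            profiles.append(
                SubsetProfile(
                    subset=subset, chain="IGL",
                    v_family_freqs=_IGL_V_BY_SUBSET[subset],
                    j_family_freqs=_IGL_J_BY_SUBSET[subset],
                    per_gene_weights=weights,
                    cdr3_len_mean=9.5, cdr3_len_sd=1.5,
                    n_insert_mean=2.0,
                )
            )
    else:
        raise ProfileError(f"unknown chain {chain!r}")
    return profiles


@dataclass
class SimulationConfig:
    """Scale, noise, and reproducibility knobs of one simulation.

    ``pcr_copies_mean`` is the mean reads per clonotype (>= 1; each
    clonotype yields ``1 + Poisson(pcr_copies_mean - 1)`` reads);
    substitution/indel error rates are per base per read.
    ``age_length_coupling`` adds that many amino acids of mean CDR3
    length per decade past age 50, scaled by developmental stage, so the
    pre-B -> naive length decline is attenuated in older donors.
    """

    n_donors: int = 5
    donor_ages: list[float] | None = None
    clonotypes_per_subset: int = 5000
    pcr_copies_mean: float = 2.5
    error_rate_sub: float = 0.002
    error_rate_indel: float = 0.0005
    seed: int = 1
    age_length_coupling: float = 0.25
    productive_fraction: float = 2 / 3
    store_sequences: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.error_rate_sub <= 0.05:
            raise ValueError("error_rate_sub must be in [0, 0.05]")
        if not 0 <= self.error_rate_indel <= 0.05:
            raise ValueError("error_rate_indel must be in [0, 0.05]")
        if self.pcr_copies_mean < 1:
            raise ValueError("pcr_copies_mean must be >= 1")
        if self.donor_ages is None:
            # spread across the sampled adult age range (24-86 years)
            self.donor_ages = list(
                np.round(np.linspace(24, 86, self.n_donors), 1)
            )
        if len(self.donor_ages) != self.n_donors:
            raise ValueError("donor_ages length must equal n_donors")


@dataclass
class GroundTruth:
    """Per-read truth: clonotype membership and injected errors."""

    clone_of: dict[str, str]
    n_true_clonotypes: int
    profiles: list[SubsetProfile]
    error_counts: dict[str, int]  # read_id -> number of injected errors (absent = 0)
    config: SimulationConfig


@dataclass
class SimulationResult:
    records: list[Rearrangement]
    truth: GroundTruth

    def to_frame(self) -> pd.DataFrame:
        from .io import rearrangements_to_frame

        df = rearrangements_to_frame(self.records)
        df["clone_id"] = [self.truth.clone_of[r.read_id] for r in self.records]
        return df

    def write(self, tsv_path, fasta_path=None) -> None:
        self.to_frame().to_csv(tsv_path, sep="\t", index=False)
        if fasta_path is not None:
            with open(fasta_path, "w") as fh:
                for r in self.records:
                    fh.write(f">{r.read_id}\n{r.sequence or r.cdr3_nt}\n")


def _gene_samplers(bundle: GermlineBundle, profile: SubsetProfile):
    """Per-segment (families, probs, genes-by-family, weights) lookups."""
    samplers = {}
    seg_maps = {"V": profile.v_family_freqs, "J": profile.j_family_freqs}
    if profile.chain == "IGH":
        seg_maps["D"] = profile.d_family_freqs
    for segment, fam_freqs in seg_maps.items():
        names = bundle.names(profile.chain, segment)
        by_family: dict[int, tuple[list[str], np.ndarray]] = {}
        for fam in fam_freqs:
            genes = [n for n in names if parse_gene_name(n).family == fam]
            if not genes:
                raise ProfileError(
                    f"no bundled genes for {profile.chain}{segment} family {fam}"
                )
            w = np.array(
                [profile.per_gene_weights.get(g, 1.0) for g in genes], float
            )
            by_family[fam] = (genes, w / w.sum())
        fams = sorted(fam_freqs)
        probs = np.array([fam_freqs[f] for f in fams], float)
        samplers[segment] = (fams, probs / probs.sum(), by_family)
    return samplers


def _strip_stops(core: str, rng: np.random.Generator) -> str:
    """Replace in-frame stop codons with random non-stop codons."""
    codons = [core[i : i + 3] for i in range(0, len(core), 3)]
    for i, c in enumerate(codons):
        while codons[i] in _STOPS:
            codons[i] = "".join(rng.choice(_NT, size=3))
    return "".join(codons)


def _apply_errors(
    seq: str, rng: np.random.Generator, sub_rate: float, indel_rate: float
) -> tuple[str, int]:
    n = len(seq)
    n_sub = rng.binomial(n, sub_rate)
    n_indel = rng.binomial(n, indel_rate)
    if n_sub == 0 and n_indel == 0:
        return seq, 0
    chars = list(seq)
    for pos in rng.integers(0, len(chars), size=n_sub):
        old = chars[pos]
        choices = [c for c in "ACGT" if c != old]
        chars[pos] = choices[int(rng.integers(0, 3))]
    for _ in range(n_indel):
        pos = int(rng.integers(0, len(chars)))
        if rng.random() < 0.5 and len(chars) > 1:
            del chars[pos]
        else:
            chars.insert(pos, str(rng.choice(_NT)))
    return "".join(chars), int(n_sub + n_indel)


def simulate_repertoire(
    cfg: SimulationConfig,
    profiles: list[SubsetProfile] | None = None,
    chain: str = "IGH",
    bundle: GermlineBundle | None = None,
) -> SimulationResult:
    """Simulate an annotated repertoire for one chain.

    Per clonotype: V/(D)/J sampled by family frequency then within-family
    gene weight; a target CDR3 length is drawn from the subset's length
    distribution (shifted by donor age through ``age_length_coupling``);
    the CDR3 is assembled from the germline V tail, N insertions, the
    trimmed D (heavy chain), more N nucleotides, and the trimmed J head,
    then adjusted to the target length (productive clonotypes in-frame
    and stop-free, the rest frame-shifted). Each clonotype is expanded
    into ``1 + Poisson(pcr_copies_mean - 1)`` reads with per-base
    substitution and indel errors. All draws come from one generator
    seeded with ``cfg.seed``, so identical configs reproduce identical
    outputs.
    """
    if profiles is None:
        profiles = default_profiles(chain)
    profiles = [p for p in profiles if p.chain == chain]
    if not profiles:
        raise ProfileError(f"no profiles supplied for chain {chain}")
    if bundle is None:
        bundle = load_bundled_germline()
    rng = np.random.default_rng(cfg.seed)
    records: list[Rearrangement] = []
    clone_of: dict[str, str] = {}
    error_counts: dict[str, int] = {}
    n_clono = 0

    for d in range(cfg.n_donors):
        donor_id = f"D{d+1:02d}"
        age = cfg.donor_ages[d]
        age_extra = cfg.age_length_coupling * max(0.0, age - 50.0) / 10.0
        for profile in profiles:
            samplers = _gene_samplers(bundle, profile)
            n = cfg.clonotypes_per_subset
            len_mean = (
                profile.cdr3_len_mean
                + age_extra * _STAGE_FRACTION.get(profile.subset, 1.0)
            )
            hi = 35 if chain == "IGH" else 20
            target_aa = np.clip(
                np.rint(rng.normal(len_mean, profile.cdr3_len_sd, size=n)),
                5, hi,
            ).astype(int)
            productive = rng.random(n) < cfg.productive_fraction
            copies = 1 + rng.poisson(max(0.0, cfg.pcr_copies_mean - 1.0), size=n)

            seg_choices = {}
            for segment, (fams, probs, by_family) in samplers.items():
                fam_idx = rng.choice(len(fams), size=n, p=probs)
                genes = np.empty(n, dtype=object)
                for k, fam in enumerate(fams):
                    idx = np.flatnonzero(fam_idx == k)
                    if len(idx):
                        gene_list, gw = by_family[fam]
                        genes[idx] = rng.choice(gene_list, size=len(idx), p=gw)
                seg_choices[segment] = genes

            trim_p = 1.0 / (1.0 + profile.trim_mean)
            for i in range(n):
                v_gene = seg_choices["V"][i]
                j_gene = seg_choices["J"][i]
                d_gene = seg_choices["D"][i] if chain == "IGH" else None
                v_tail = bundle.v_tail(v_gene)
                v_trim = int(rng.geometric(trim_p)) - 1  # mean = trim_mean
                v_part = v_tail[: max(0, len(v_tail) - v_trim)]
                j_head = bundle.j_head(j_gene)
                j_trim = int(rng.geometric(trim_p)) - 1
                j_part = j_head[min(len(j_head), j_trim):]
                mid = ""
                if d_gene is not None:
                    dseq = bundle.sequence(d_gene)
                    lt = rng.geometric(trim_p) - 1
                    rt = rng.geometric(trim_p) - 1
                    if lt + rt < len(dseq):
                        mid = dseq[lt : len(dseq) - rt]
                n1 = "".join(rng.choice(_NT, size=rng.poisson(profile.n_insert_mean)))
                n2 = "".join(rng.choice(_NT, size=rng.poisson(profile.n_insert_mean)))
                core = v_part + n1 + mid + n2 + j_part

                T = 3 * int(target_aa[i])
                if not productive[i]:
                    T += int(rng.integers(1, 3))  # frame shift
                if len(core) > T:
                    keep_left = (T + 1) // 2
                    core = core[:keep_left] + core[len(core) - (T - keep_left):]
                elif len(core) < T:
                    fill = "".join(rng.choice(_NT, size=T - len(core)))
                    h = len(core) // 2
                    core = core[:h] + fill + core[h:]
                if productive[i]:
                    core = _strip_stops(core, rng)
                    cdr3_aa = str(Seq(core).translate())
                else:
                    cdr3_aa = ""

                clone_id = f"{donor_id}_{profile.subset}_{chain}_c{i:06d}"
                n_clono += 1
                for k in range(int(copies[i])):
                    read_id = f"{clone_id}_r{k}"
                    obs, n_err = _apply_errors(
                        core, rng, cfg.error_rate_sub, cfg.error_rate_indel
                    )
                    if n_err and len(obs) % 3 == 0:
                        aa = str(Seq(obs).translate())
                        obs_aa = "" if "*" in aa else aa
                        obs_prod = bool(obs_aa)
                    elif n_err:
                        obs_aa, obs_prod = "", False
                    else:
                        obs_aa, obs_prod = cdr3_aa, bool(productive[i])
                    seq = ""
                    if cfg.store_sequences:
                        v_full = bundle.sequence(v_gene)
                        seq = (
                            v_full[: len(v_full) - len(v_tail)]
                            + obs
                            + bundle.j_anchor_codon(j_gene)
                            + bundle.j_rest(j_gene)
                        )
                    rec = Rearrangement(
                        read_id=read_id,
                        donor_id=donor_id,
                        subset=profile.subset,
                        chain=chain,
                        v_call=v_gene,
                        d_call=d_gene,
                        j_call=j_gene,
                        cdr3_nt=obs,
                        cdr3_aa=obs_aa,
                        productive=obs_prod,
                        sequence=seq,
                    )
                    records.append(rec)
                    clone_of[read_id] = clone_id
                    if n_err:
                        error_counts[read_id] = n_err

    truth = GroundTruth(
        clone_of=clone_of,
        n_true_clonotypes=n_clono,
        profiles=profiles,
        error_counts=error_counts,
        config=cfg,
    )
    return SimulationResult(records=records, truth=truth)
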