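"""End-to-end orchestration with a run manifest.

A single YAML-style config drives simulation (or loading of an annotated
TSV), cleanup and PCR-duplicate collapse, and the toggled analyses
(gene usage, CDR3 properties, mixed-model tests, PCA with permutation
control, Minkowski clustering). Every output table is recorded in a
manifest with its SHA-256 checksum together with the config hash, so a
rerun with an identical config is verifiably identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import cleanup, io, multivariate, properties, simulate, usage

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "StageFailure"]


class StageFailure(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Pipeline configuration; exactly one of ``input_path``/``simulation``."""

    out_dir: str
    input_path: str | None = None
    simulation: dict | None = None  # SimulationConfig kwargs (+ 'chain')
    dedup_threshold: int = 1
    filter_policy: dict = field(default_factory=dict)
    run_usage: bool = True
    run_properties: bool = True
    run_pca: bool = True
    run_minkowski: bool = True
    run_mixed_model: bool = False
    pca_n_perm: int = 199
    seed: int = 1

    def __post_init__(self) -> None:
        if (self.input_path is None) == (self.simulation is None):
            raise ValueError("exactly one of input_path/simulation must be set")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)

    def to_dict(self) -> dict:
        return {
            "out_dir": self.out_dir,
            "input_path": self.input_path,
            "simulation": self.simulation,
            "dedup_threshold": self.dedup_threshold,
            "filter_policy": self.filter_policy,
            "run_usage": self.run_usage,
            "run_properties": self.run_properties,
            "run_pca": self.run_pca,
            "run_minkowski": self.run_minkowski,
            "run_mixed_model": self.run_mixed_model,
            "pca_n_perm": self.pca_n_perm,
            "seed": self.seed,
        }


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(cfg: RunConfig) -> dict:
    """Run all enabled stages in dependency order; return the manifest.

    On stage failure a :class:`StageFailure` names the stage and partial
    outputs are preserved in ``out_dir``.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": cfg.to_dict(),
        "config_hash": hashlib.sha256(
            json.dumps(cfg.to_dict(), sort_keys=True).encode()
        ).hexdigest(),
        "inputs": {},
        "outputs": {},
    }

    def emit(name: str, df: pd.DataFrame) -> None:
        path = out / name
        io.write_table(df, path)
        manifest["outputs"][name] = _sha256(path)

    stage = "load"
    try:
        if cfg.simulation is not None:
            stage = "simulate"
            sim_kwargs = dict(cfg.simulation)
            chain = sim_kwargs.pop("chain", "IGH")
            sim_kwargs.setdefault("seed", cfg.seed)
            sim_cfg = simulate.SimulationConfig(**sim_kwargs)
            result = simulate.simulate_repertoire(sim_cfg, chain=chain)
            records = result.records
            reads_path = out / "reads.tsv"
            result.write(reads_path)
            manifest["outputs"]["reads.tsv"] = _sha256(reads_path)
        else:
            records = io.read_rearrangements(cfg.input_path)
            manifest["inputs"][str(cfg.input_path)] = _sha256(Path(cfg.input_path))
            chain = records[0].chain if records else "IGH"

        stage = "cleanup"
        policy = cleanup.FilterPolicy(**cfg.filter_policy)
        gene_kept, gene_removed = cleanup.apply_filters(
            records, policy, stage="gene_stage"
        )
        emit("removed_gene_stage.csv", pd.DataFrame(
            [{"sequence_id": r.read_id, "reason": reason}
             for r, reason in gene_removed]
        ))

        stage = "dedup"
        clonotypes = cleanup.cluster_duplicates(
            gene_kept, threshold=cfg.dedup_threshold
        )
        emit("clonotypes.csv", pd.DataFrame(
            [{
                "clonotype_id": c.representative.read_id,
                "donor_id": c.donor_id, "subset": c.subset, "chain": c.chain,
                "v_call": c.v_call, "d_call": c.d_call or "",
                "j_call": c.j_call, "cdr3": c.cdr3_nt, "cdr3_aa": c.cdr3_aa,
                "member_count": c.member_count,
            } for c in clonotypes]
        ))

        usage_tables = {}
        if cfg.run_usage:
            stage = "usage"
            segs = ("V", "D", "J") if chain == "IGH" else ("V", "J")
            frames = []
            for seg in segs:
                table = usage.usage_frequencies(
                    clonotypes, axis="family", chain=chain, segment=seg
                )
                usage_tables[seg] = table
                df = table.data.copy()
                df.insert(0, "segment", seg)
                frames.append(df)
            emit("family_usage.csv", pd.concat(frames, ignore_index=True))
            combo = usage.combination_tensor(clonotypes, chain=chain)
            emit("combination_usage.csv", combo.data)
            emit("combination_means.csv",
                 combo.subset_means().reset_index())

        prop_df = None
        if cfg.run_properties:
            stage = "properties"
            cdr3_kept, cdr3_removed = cleanup.apply_filters(
                [c.representative for c in clonotypes], policy, stage="cdr3_stage"
            )
            kept_ids = {r.read_id for r in cdr3_kept}
            prop_df = properties.property_table(
                [c for c in clonotypes if c.representative.read_id in kept_ids]
            )
            emit("cdr3_properties.csv", prop_df)

        if cfg.run_mixed_model and prop_df is not None and len(prop_df):
            stage = "mixed_model"
            rows = []
            for prop in ("length", "gravy", "boman", "charged", "kf1"):
                try:
                    res = usage.mixed_model_lrt(prop_df, prop)
                except ValueError as exc:
                    logger.warning("mixed model for %s skipped: %s", prop, exc)
                    continue
                rows.append({
                    "property": prop, "lrt": res.statistic, "p": res.raw_p,
                    "effect": res.effect, "note": res.note,
                })
            emit("mixed_model.csv", pd.DataFrame(rows))

        if cfg.run_pca and cfg.run_usage and "V" in usage_tables:
            stage = "pca"
            m = multivariate.donor_means(usage_tables["V"])
            pca = multivariate.run_pca(m)
            emit("pca_scores.csv", pca.scores.reset_index())
            emit("pca_loadings.csv", pca.loadings.reset_index())
            emit("pca_variance.csv", pca.summary())

        if cfg.run_minkowski and cfg.run_usage and "V" in usage_tables:
            stage = "minkowski"
            m = multivariate.donor_means(usage_tables["V"])
            dend = multivariate.minkowski_cluster(m)
            newick_path = out / "dendrogram.nwk"
            newick_path.write_text(dend.newick + "\n")
            manifest["outputs"]["dendrogram.nwk"] = _sha256(newick_path)
    except StageFailure:
        raise
    except Exception as exc:  # halt with the failing stage's name
        manifest_path = out / "manifest.json"
        manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
        raise StageFailure(stage, exc) from exc

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
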