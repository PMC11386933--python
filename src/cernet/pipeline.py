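"""Stage orchestration: simulate → DE → enrich → GSEA → targets → network.

Every stage is a pure function over files in ``config.outdir`` so any stage
can be re-run alone; ``run_all`` executes them in dependency order, skipping
stages whose outputs already exist (unless forced or an upstream stage was
re-run) and logging a manifest entry (config hash, seed, row counts) per
stage. Defaults reproduce the reference study's thresholds: circRNA |FC|>2,
miRNA/mRNA |FC|>1.5 at p<0.05; ORA FDR<0.05; GSEA gates p<0.05, |NES|>1,
FDR<0.25; ceRNA SCC<−0.7, PCC>0.9, sponge p<0.05.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import cerna_network, diffexpr, enrichment, gsea, io_formats, synthetic, target_prediction
from .errors import CernetError, MissingInputError

STAGES = ("simulate", "de", "enrich", "gsea", "targets", "network")

_STAGE_DEPS = {
    "simulate": (),
    "de": ("simulate",),
    "enrich": ("de",),
    "gsea": ("simulate",),
    "targets": ("de",),
    "network": ("de", "targets"),
}

CLASSES = ("circRNA", "miRNA", "mRNA")


@dataclass
class PipelineConfig:
    outdir: str = "results/pipeline"
    simulation: synthetic.SimulationConfig = field(default_factory=synthetic.SimulationConfig)
    thresholds: diffexpr.DEThresholds = field(default_factory=diffexpr.DEThresholds)
    normalization: str = "cpm"
    enrichment_alpha: float = 0.05
    gsea_n_perm: int = 500
    gsea_perm_mode: str = "gene_set"
    align_threshold: float = 80.0
    scc_threshold: float = 0.7
    pcc_threshold: float = 0.9
    sponge_alpha: float = 0.05
    rng_seed: int = 1

    def __post_init__(self) -> None:
        if isinstance(self.simulation, dict):
            sim = dict(self.simulation)
            if "nb_mean_log_range" in sim:
                sim["nb_mean_log_range"] = tuple(sim["nb_mean_log_range"])
            self.simulation = synthetic.SimulationConfig(**sim)
        if isinstance(self.thresholds, dict):
            self.thresholds = diffexpr.DEThresholds(**self.thresholds)
        self.simulation.rng_seed = self.rng_seed

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["simulation"]["nb_mean_log_range"] = list(d["simulation"]["nb_mean_log_range"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return cls(**d)

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


class StageError(CernetError):
    """A stage failed; the message names the stage."""


# ---------------------------------------------------------------------------
# stage outputs


def _paths(config: PipelineConfig) -> dict[str, Path]:
    out = Path(config.outdir)
    return {
        **{f"counts_{c}": out / f"counts_{c}.tsv" for c in CLASSES},
        "groups": out / "groups.tsv",
        "fasta_miRNA": out / "mirna.fasta",
        "fasta_circRNA": out / "circrna.fasta",
        "fasta_mRNA": out / "mrna.fasta",
        "gmt": out / "gene_sets.gmt",
        "truth": out / "truth.json",
        **{f"de_{c}": out / f"de_{c}.tsv" for c in CLASSES},
        **{f"de_{c}_gated": out / f"de_{c}_gated.tsv" for c in CLASSES},
        "enrichment": out / "enrichment.tsv",
        "gsea": out / "gsea.tsv",
        "targets": out / "targets.tsv",
        "triplets": out / "triplets.tsv",
        "network_tsv": out / "network.tsv",
        "network_sif": out / "network.sif",
        "manifest": out / "manifest.json",
    }


_STAGE_OUTPUTS = {
    "simulate": [f"counts_{c}" for c in CLASSES]
    + ["groups", "fasta_miRNA", "fasta_circRNA", "fasta_mRNA", "gmt", "truth"],
    "de": [f"de_{c}" for c in CLASSES] + [f"de_{c}_gated" for c in CLASSES],
    "enrich": ["enrichment"],
    "gsea": ["gsea"],
    "targets": ["targets"],
    "network": ["triplets", "network_tsv", "network_sif"],
}


def _read_counts(config: PipelineConfig, cls: str) -> io_formats.CountMatrix:
    p = _paths(config)
    f = p[f"counts_{cls}"]
    if not f.exists():
        raise MissingInputError(f"expected count matrix {f}; run the simulate stage first")
    return io_formats.read_count_matrix(f, p["groups"], cls)


def _require(config: PipelineConfig, *keys: str) -> dict[str, Path]:
    p = _paths(config)
    for key in keys:
        if not p[key].exists():
            raise MissingInputError(f"missing input {p[key]}; run its producing stage first")
    return p


# ---------------------------------------------------------------------------
# stages


def stage_simulate(config: PipelineConfig) -> dict:
    p = _paths(config)
    Path(config.outdir).mkdir(parents=True, exist_ok=True)
    circ, mir, mrna, truth = synthetic.simulate_counts(config.simulation)
    seqs = synthetic.simulate_sequences(config.simulation, truth)
    sets = synthetic.simulate_gene_sets(config.simulation, truth)
    for cls, cm in (("circRNA", circ), ("miRNA", mir), ("mRNA", mrna)):
        io_formats.write_count_matrix(cm, p[f"counts_{cls}"], p["groups"])
    for cls in CLASSES:
        io_formats.write_fasta(seqs[cls], p[f"fasta_{cls}"])
    io_formats.write_gmt(sets, p["gmt"])
    io_formats.write_json(
        {
            "de_features": truth.de_features,
            "triplets": truth.triplets,
            "enriched_terms": truth.enriched_terms,
            "site_positions": truth.site_positions,
        },
        p["truth"],
    )
    return {
        "n_features": {"circRNA": len(circ.feature_ids), "miRNA": len(mir.feature_ids), "mRNA": len(mrna.feature_ids)},
        "n_planted_triplets": len(truth.triplets),
    }


def stage_de(config: PipelineConfig) -> dict:
    p = _require(config, *(f"counts_{c}" for c in CLASSES), "groups")
    counts = {}
    for cls in CLASSES:
        matrix = _read_counts(config, cls)
        records = diffexpr.test_de(matrix, config.thresholds, method=config.normalization)
        gated = diffexpr.gate(records, config.thresholds, cls)
        records.to_csv(p[f"de_{cls}"], sep="\t", index=False)
        gated.to_csv(p[f"de_{cls}_gated"], sep="\t", index=False)
        counts[cls] = {"tested": len(records), "gated": len(gated)}
    return counts


def _gated_ids(config: PipelineConfig, cls: str) -> list[str]:
    p = _require(config, f"de_{cls}_gated")
    df = pd.read_csv(p[f"de_{cls}_gated"], sep="\t")
    return [] if df.empty else list(df["id"].astype(str))


def stage_enrich(config: PipelineConfig) -> dict:
    p = _require(config, "gmt", "de_mRNA_gated", "counts_mRNA")
    sets = io_formats.read_gmt(p["gmt"])
    matrix = _read_counts(config, "mRNA")
    de_ids = _gated_ids(config, "mRNA")
    if not de_ids:
        pd.DataFrame().to_csv(p["enrichment"], sep="\t", index=False)
        return {"tested_terms": 0, "significant": 0}
    result = enrichment.enrich(
        de_ids, matrix.feature_ids, sets, alpha=config.enrichment_alpha
    )
    result.to_csv(p["enrichment"], sep="\t", index=False)
    return {
        "tested_terms": len(result),
        "significant": int(result["significant"].sum()) if len(result) else 0,
    }


def stage_gsea(config: PipelineConfig) -> dict:
    p = _require(config, "gmt", "counts_mRNA")
    sets = io_formats.read_gmt(p["gmt"])
    matrix = _read_counts(config, "mRNA")
    result = gsea.gsea_test(
        matrix,
        sets,
        n_perm=config.gsea_n_perm,
        perm_mode=config.gsea_perm_mode,
        rng_seed=config.rng_seed,
        method=config.normalization,
    )
    result.to_csv(p["gsea"], sep="\t", index=False)
    return {
        "tested_sets": len(result),
        "significant": int(result["significant"].sum()) if len(result) else 0,
    }


def stage_targets(config: PipelineConfig) -> dict:
    p = _require(config, "fasta_miRNA", "fasta_circRNA", "fasta_mRNA")
    mirna_seqs = io_formats.read_fasta(p["fasta_miRNA"])
    circ_seqs = io_formats.read_fasta(p["fasta_circRNA"])
    mrna_seqs = io_formats.read_fasta(p["fasta_mRNA"])
    de_mir = set(_gated_ids(config, "miRNA"))
    de_circ = set(_gated_ids(config, "circRNA"))
    de_mrna = set(_gated_ids(config, "mRNA"))
    params = target_prediction.AlignParams(threshold=config.align_threshold)
    predictions = target_prediction.predict_targets(
        {m: s for m, s in mirna_seqs.items() if m in de_mir},
        {
            "circRNA": {t: s for t, s in circ_seqs.items() if t in de_circ},
            "mRNA": {t: s for t, s in mrna_seqs.items() if t in de_mrna},
        },
        mode="intersection",
        params=params,
    )
    predictions.to_csv(p["targets"], sep="\t", index=False)
    return {
        "predicted_sites": len(predictions),
        "predicted_pairs": len(target_prediction.target_pairs(predictions)),
    }


def stage_network(config: PipelineConfig) -> dict:
    p = _require(config, "targets", *(f"de_{c}_gated" for c in CLASSES))
    targets = pd.read_csv(p["targets"], sep="\t")
    de_circ = _gated_ids(config, "circRNA")
    de_mir = _gated_ids(config, "miRNA")
    de_mrna = _gated_ids(config, "mRNA")
    expression = cerna_network.expression_table(
        [_read_counts(config, c) for c in CLASSES], method=config.normalization
    )
    sponge_pairs = cerna_network.select_sponge_pairs(
        de_circ, de_mrna, de_mir, expression, targets, config.scc_threshold
    )
    coexpressed = cerna_network.select_coexpressed(
        de_circ, de_mrna, expression, sponge_pairs, config.pcc_threshold
    )
    universe = sorted({m for m in targets["mirna_id"]} & set(de_mir)) if len(targets) else []
    if universe:
        net, triplets = cerna_network.build_network(
            sponge_pairs, coexpressed, targets, universe, config.sponge_alpha
        )
    else:
        import networkx as nx

        net, triplets = nx.Graph(), pd.DataFrame(
            columns=["circ_id", "mirna_id", "mrna_id", "scc_circ_mir",
                     "scc_mrna_mir", "pcc_circ_mrna", "sponge_p"]
        )
    triplets.to_csv(p["triplets"], sep="\t", index=False)
    io_formats.write_network(net, p["network_tsv"], dialect="tsv")
    io_formats.write_network(net, p["network_sif"], dialect="sif")
    return {
        "sponge_pairs": len(sponge_pairs),
        "coexpressed_pairs": len(coexpressed),
        "triplets": len(triplets),
        "nodes": net.number_of_nodes(),
        "edges": net.number_of_edges(),
    }


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "de": stage_de,
    "enrich": stage_enrich,
    "gsea": stage_gsea,
    "targets": stage_targets,
    "network": stage_network,
}


# ---------------------------------------------------------------------------
# orchestration


def _outputs_exist(config: PipelineConfig, stage: str) -> bool:
    p = _paths(config)
    return all(p[key].exists() for key in _STAGE_OUTPUTS[stage])


def _log_manifest(config: PipelineConfig, stage: str, info: dict) -> None:
    p = _paths(config)
    manifest = {}
    if p["manifest"].exists():
        manifest = json.loads(p["manifest"].read_text())
    manifest[stage] = {
        "config_hash": config.config_hash(),
        "rng_seed": config.rng_seed,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "counts": info,
    }
    p["manifest"].write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")


def run_stage(name: str, config: PipelineConfig) -> dict:
    """Run one stage; raises :class:`StageError` naming the stage on failure."""
    if name not in _STAGE_FUNCS:
        raise StageError(f"unknown stage {name!r}; choose from {STAGES}")
    Path(config.outdir).mkdir(parents=True, exist_ok=True)
    try:
        info = _STAGE_FUNCS[name](config)
    except MissingInputError:
        raise
    except CernetError as exc:
        raise StageError(f"stage {name!r} failed: {exc}") from exc
    _log_manifest(config, name, info)
    return info


def run_all(config: PipelineConfig, force: bool = False) -> dict[str, dict]:
    """Run all stages in dependency order.

    A stage is skipped when its outputs exist, none of its upstream stages
    re-ran in this invocation, and ``force`` is False — so deleting one
    intermediate regenerates that stage and everything downstream of it.
    """
    results: dict[str, dict] = {}
    reran: set[str] = set()
    for stage in STAGES:
        upstream_dirty = any(dep in reran for dep in _STAGE_DEPS[stage])
        if not force and not upstream_dirty and _outputs_exist(config, stage):
            results[stage] = {"skipped": True}
            continue
        results[stage] = run_stage(stage, config)
        reran.add(stage)
    return results
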