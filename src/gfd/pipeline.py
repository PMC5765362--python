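"""End-to-end orchestration: simulate (or ingest) -> divergence -> clusters
-> conversion permutation test -> monophyly comparison, with a JSON manifest
recording inputs, parameters, per-stage seeds and output hashes.

Per-stage seeds are derived from the global seed by hashing the stage name,
so any stage can be re-run independently and reproducibly. A failing stage
is recorded (status "failed", error message) and the remaining stages run;
the manifest's ``status`` is "completed_with_flags" in that case.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import yaml

from . import __version__
from .cluster_synteny import call_clusters, clusters_to_bed
from .conversion_test import permutation_test
from .core_io import read_fasta, read_gff3_gene_models
from .divergence import pairwise_matrix
from .phylo import jc69_matrix, monophyly_comparison, neighbor_joining, tree_newick
from .synthetic_data import SimulationConfig, emit, simulate

logger = logging.getLogger("gfd")


@dataclass
class PipelineConfig:
    outdir: str
    seed: int = 0
    simulate: dict | None = None
    inputs: list[dict] | None = None  # [{species, gff, genome_fasta}, ...]
    max_gap: int = 50_000
    n_permutations: int = 100_000
    n_random_starts: int = 5
    min_cluster_size_for_phylo: int = 2

    def __post_init__(self) -> None:
        if (self.simulate is None) == (self.inputs is None):
            raise ValueError("config must provide exactly one of 'simulate' or 'inputs'")

    @staticmethod
    def from_yaml(path: str | Path) -> "PipelineConfig":
        return PipelineConfig(**(yaml.safe_load(Path(path).read_text()) or {}))


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed: blake2s of '<seed>:<stage>', mod 2^31."""
    digest = hashlib.blake2s(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "tool": "gfd",
        "version": __version__,
        "seed": config.seed,
        "parameters": {
            "max_gap": config.max_gap,
            "n_permutations": config.n_permutations,
            "n_random_starts": config.n_random_starts,
        },
        "stages": [],
        "status": "completed",
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    flagged = False

    def record(name, params, outputs, status="ok", error=None, started=None):
        nonlocal flagged
        entry = {
            "name": name,
            "params": params,
            "outputs": {str(p): _sha256(Path(p)) for p in outputs},
            "status": status,
        }
        if error:
            entry["error"] = error
            flagged = True
        if started is not None:
            entry["seconds"] = round(time.time() - started, 3)
        manifest["stages"].append(entry)
        logger.info("stage %s: %s", name, status)

    # ---- input stage
    t0 = time.time()
    models_by_species: dict[str, list] = {}
    if config.simulate is not None:
        sim_cfg = SimulationConfig(
            **{**config.simulate, "seed": config.simulate.get("seed", stage_seed(config.seed, "simulate"))}
        )
        output = simulate(sim_cfg)
        written = emit(output, outdir / "sim")
        models_by_species = output.models_by_species
        record("simulate", sim_cfg.to_dict(), written.values(), started=t0)
    else:
        for entry in config.inputs:
            fasta = read_fasta(entry["genome_fasta"])
            models = read_gff3_gene_models(entry["gff"], fasta, species=entry["species"])
            models_by_species[entry["species"]] = models
        record(
            "ingest",
            {"inputs": config.inputs},
            [e["gff"] for e in config.inputs] + [e["genome_fasta"] for e in config.inputs],
            started=t0,
        )

    for species in sorted(models_by_species):
        models = [m for m in models_by_species[species] if m.cds_seq]
        prefix = outdir / species
        # ---- divergence matrix
        t0 = time.time()
        matrix = None
        if len(models) >= 2:
            matrix = pairwise_matrix(models, metric="nt_identity")
            mpath = prefix.with_suffix(".identity.tsv")
            matrix.to_tsv(mpath)
            record(f"{species}:divergence", {"metric": "nt_identity"}, [mpath], started=t0)
        else:
            record(f"{species}:divergence", {}, [], "failed",
                   f"{species}: fewer than 2 genes", started=t0)
            continue
        # ---- clusters
        t0 = time.time()
        clusters = call_clusters(models, config.max_gap)
        bpath = prefix.with_suffix(".clusters.bed")
        clusters_to_bed(clusters, bpath)
        record(f"{species}:clusters", {"max_gap": config.max_gap}, [bpath], started=t0)
        # ---- conversion permutation test
        t0 = time.time()
        try:
            result = permutation_test(
                matrix,
                clusters,
                n_permutations=config.n_permutations,
                seed=stage_seed(config.seed, f"convtest:{species}"),
            )
            jpath = prefix.with_suffix(".convtest.json")
            result.to_json(jpath)
            record(
                f"{species}:convtest",
                {"n_permutations": config.n_permutations},
                [jpath],
                started=t0,
            )
        except ValueError as exc:
            record(f"{species}:convtest", {}, [], "failed", str(exc), started=t0)
        # ---- phylogeny: NJ tree + monophyly comparison
        t0 = time.time()
        try:
            seqs = {m.gene_id: m.cds_seq for m in models}
            if len(seqs) >= 3:
                nj = neighbor_joining(jc69_matrix(seqs, cap=3.0))
                tpath = prefix.with_suffix(".nj.nwk")
                tpath.write_text(tree_newick(nj) + "\n")
            else:
                raise ValueError(f"{species}: fewer than 3 genes for a tree")
            comparison = monophyly_comparison(
                seqs,
                clusters,
                n_random_starts=config.n_random_starts,
                seed=stage_seed(config.seed, f"monophyly:{species}"),
            )
            cpath = prefix.with_suffix(".monophyly.json")
            comparison.to_json(cpath)
            record(
                f"{species}:phylo",
                {"n_random_starts": config.n_random_starts},
                [tpath, cpath],
                started=t0,
            )
        except ValueError as exc:
            record(f"{species}:phylo", {}, [], "failed", str(exc), started=t0)

    if flagged:
        manifest["status"] = "completed_with_flags"
    mpath = outdir / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
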