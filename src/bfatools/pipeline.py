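"""End-to-end pipeline orchestration.

Runs simulate -> emit reads -> extract -> error-correct (per lane) ->
merge lanes / remove chimeras -> GC filter -> home-environment
assignment -> fitness inference, writing TSV artifacts plus a
provenance manifest (seeds, thresholds, checksums).  Completed stages
are skipped on re-run when their inputs are unchanged, unless forced.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .clustering import build_centroids, cluster_barcodes, merge_lanes, remove_chimeras
from .extraction import observations_to_counts, parse_library_label, process_read_pairs, read_fastq_pairs
from .filters import apply_gc_filter, assign_home_environments, TimepointExclusions, exclude_timepoints
from .fitness import estimate_fitness_table
from .simulate import (
    GroundTruth,
    SimulationConfig,
    apply_gc_bias,
    emit_reads,
    make_index_table,
    simulate_pool,
    simulate_subpool_reads,
    write_counts,
    write_fastq_pair,
)

log = logging.getLogger("bfatools")

STAGES = ("simulate", "extract", "correct", "filter", "fitness")


@dataclass
class PipelineConfig:
    out_dir: str = "bfa_out"
    seed: int = 0
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    generations_per_timepoint: float | None = None  # defaults to sim transfer size
    min_valid_reads: int = 10
    exclusions: TimepointExclusions = field(default_factory=TimepointExclusions)
    subpool_reads_per_lineage: int = 20
    force: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = raw.pop("simulation", {})
        if "spike_ratio" in sim and sim["spike_ratio"] is not None:
            sim["spike_ratio"] = tuple(sim["spike_ratio"])
        excl = raw.pop("exclusions", [])
        return cls(
            simulation=SimulationConfig(**sim),
            exclusions=TimepointExclusions(entries=list(excl)),
            **raw,
        )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 20), b""):
            h.update(block)
    return h.hexdigest()


class Manifest:
    def __init__(self, path: Path):
        self.path = path
        self.data = (
            json.loads(path.read_text()) if path.exists() else {"stages": {}}
        )

    def stage_current(self, stage: str, inputs: list[Path], outputs: list[Path]) -> bool:
        rec = self.data["stages"].get(stage)
        if rec is None:
            return False
        if not all(p.exists() for p in outputs):
            return False
        if {str(p): _sha256(p) for p in inputs if p.exists()} != rec.get("inputs", {}):
            return False
        return {str(p): _sha256(p) for p in outputs} == rec.get("outputs", {})

    def record(self, stage: str, inputs: list[Path], outputs: list[Path], **meta) -> None:
        self.data["stages"][stage] = {
            "inputs": {str(p): _sha256(p) for p in inputs if p.exists()},
            "outputs": {str(p): _sha256(p) for p in outputs},
            **meta,
        }
        self.save()

    def save(self) -> None:
        self.data["version"] = __version__
        self.path.write_text(json.dumps(self.data, indent=2, default=str))


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute all stages; returns the artifact directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = Manifest(out / "manifest.json")
    manifest.data["config"] = json.loads(json.dumps(asdict(config), default=str))

    sim = config.simulation
    truth_path = out / "truth.json"
    counts_path = out / "sim_counts.tsv"
    r1, r2 = out / "reads_R1.fastq", out / "reads_R2.fastq"
    index_path = out / "index_table.json"
    subpool_path = out / "subpool_counts.tsv"

    def needs(stage: str, inputs: list[Path], outputs: list[Path]) -> bool:
        if not config.force and manifest.stage_current(stage, inputs, outputs):
            log.info("stage %s up to date; skipping", stage)
            return False
        log.info("running stage %s", stage)
        return True

    # --- simulate ---------------------------------------------------------
    sim_outputs = [truth_path, counts_path, r1, r2, index_path, subpool_path]
    if needs("simulate", [], sim_outputs):
        truth, counts = simulate_pool(sim)
        if sim.gc_bias_strength > 0:
            counts = apply_gc_bias(counts, truth, sim.gc_bias_strength)
        truth.to_json(truth_path)
        write_counts(counts, counts_path)
        rng = np.random.default_rng(sim.seed + 17)
        index_table = make_index_table(counts, rng)
        index_path.write_text(json.dumps(index_table, indent=2))
        n = write_fastq_pair(emit_reads(counts, sim, index_table, rng), r1, r2)
        write_counts(
            simulate_subpool_reads(truth, config.subpool_reads_per_lineage, seed=sim.seed + 29),
            subpool_path,
        )
        manifest.record("simulate", [], sim_outputs, read_pairs=n, seed=sim.seed)

    # --- extract ----------------------------------------------------------
    obs_path = out / "observations.tsv"
    qc_path = out / "extraction_qc.json"
    if needs("extract", [r1, r2, index_path], [obs_path, qc_path]):
        index_table = json.loads(index_path.read_text())
        observations, qc = process_read_pairs(read_fastq_pairs(r1, r2), index_table)
        observations_to_counts(observations).to_csv(obs_path, sep="\t", index=False)
        qc.to_json(qc_path)
        manifest.record("extract", [r1, r2, index_path], [obs_path, qc_path])

    # --- correct (per lane), merge lanes, remove chimeras ----------------
    centroid_path = out / "centroids.tsv"
    if needs("correct", [obs_path], [centroid_path]):
        obs = pd.read_csv(obs_path, sep="\t")
        parsed = obs["library"].map(parse_library_label)
        obs["timepoint"] = [p[0] for p in parsed]
        obs["replicate"] = [p[1] for p in parsed]
        obs["lane"] = [p[2] for p in parsed]
        lane_tables = []
        for lane, lane_obs in obs.groupby("lane"):
            env_counts = lane_obs.groupby("env_bc")["count"].sum().to_dict()
            lin_counts = lane_obs.groupby("lineage_bc")["count"].sum().to_dict()
            env_map, _ = cluster_barcodes(env_counts)
            lin_map, _ = cluster_barcodes(lin_counts)
            centroids, discarded = build_centroids(
                lane_obs, env_map, lin_map, sample_columns=("timepoint", "replicate")
            )
            centroids["lane"] = lane
            lane_tables.append(centroids)
            log.info("lane %s: %d centroids rows, %d reads discarded", lane, len(centroids), discarded)
        merged = merge_lanes(lane_tables)
        kept, chimeras = remove_chimeras(merged)
        kept.to_csv(centroid_path, sep="\t", index=False)
        manifest.record("correct", [obs_path], [centroid_path], chimeras_removed=len(chimeras))

    # --- filter: GC exclusion, timepoint exclusion, home environments ----
    filtered_path = out / "filtered_counts.tsv"
    homes_path = out / "home_environments.tsv"
    if needs("filter", [centroid_path, subpool_path], [filtered_path, homes_path]):
        centroids = pd.read_csv(centroid_path, sep="\t")
        kept, gc_excluded = apply_gc_filter(centroids)
        kept = exclude_timepoints(kept, config.exclusions)
        kept.to_csv(filtered_path, sep="\t", index=False)
        subpools = pd.read_csv(subpool_path, sep="\t")
        assign_home_environments(subpools).to_csv(homes_path, sep="\t", index=False)
        manifest.record(
            "filter",
            [centroid_path, subpool_path],
            [filtered_path, homes_path],
            gc_excluded=int(gc_excluded[["env_bc", "lineage_bc"]].drop_duplicates().shape[0]),
        )

    # --- fitness ----------------------------------------------------------
    fitness_path = out / "fitness.tsv"
    if needs("fitness", [filtered_path, truth_path], [fitness_path]):
        counts = pd.read_csv(filtered_path, sep="\t")
        truth = GroundTruth.from_json(truth_path)
        neutral_keys = {
            (r.env_bc, r.lineage_bc)
            for r in truth.lineages.itertuples()
            if r.neutral
        }
        dg = config.generations_per_timepoint or float(sim.generations_per_transfer)
        table = estimate_fitness_table(
            counts, neutral_keys, generations_per_timepoint=dg, min_reads=config.min_valid_reads
        )
        table.to_csv(fitness_path, sep="\t", index=False)
        recovery = _recovery_metrics(table, truth)
        manifest.record("fitness", [filtered_path, truth_path], [fitness_path], **recovery)

    manifest.save()
    return out


def _recovery_metrics(fitness: pd.DataFrame, truth: GroundTruth) -> dict:
    comb = fitness[fitness["replicate"] == "combined"]
    merged = comb.merge(truth.lineages, on=["env_bc", "lineage_bc"])
    if merged.empty:
        return {"n_recovered": 0}
    err = merged["s_hat"] - merged["s"]
    return {
        "n_recovered": int(len(merged)),
        "rmse": float(np.sqrt(np.mean(err**2))),
        "spearman": float(merged["s_hat"].corr(merged["s"], method="spearman")),
    }
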