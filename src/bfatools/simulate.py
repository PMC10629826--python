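"""Synthetic double-barcode lineage data.

Generates ground-truth barcoded lineages evolving under serial batch
transfer, their bulk-fitness-assay (BFA) count trajectories, and raw
paired-end amplicon reads with the error processes seen in real barcode
sequencing: per-base substitution errors, PCR (UMI) duplicates, chimeric
barcode pairs, and GC-content read-depth bias.

The population model is deterministic exponential selection between
transfers with multinomial sampling noise at each bottleneck and at read
sampling:

    f_i(t + dg)  ∝  f_i(t) · exp(s_i · dg)

where ``s_i`` is the per-generation selection coefficient of lineage *i*
and ``dg`` the generations elapsed per transfer.  Neutral lineages have
``s = 0`` exactly; adding a constant to every ``s`` leaves all frequency
trajectories unchanged (softmax invariance).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

# Amplicon layout constants.  Each mate is
#   UMI(8) + inline index + left pad(10) + LEFT_FLANK + barcode + RIGHT_FLANK + right pad(10)
# Read 1 carries the high-complexity lineage barcode, read 2 the
# low-complexity environment barcode (configurable swap downstream).
LEFT_FLANK = "GGTACC"
RIGHT_FLANK = "ATAACT"
UMI_LENGTH = 8
PAD_LENGTH = 10
INDEX_LENGTH = 6
DEFAULT_QUALITY_CHAR = "F"  # Phred+33 Q37

_BASES = np.array(list("ACGT"))
# Left pads exclude G: every left-flank motif starts with G, so a G-free pad
# cannot seed a spurious leftmost flank match during extraction.
_PAD_BASES_LEFT = np.array(list("ACT"))

COUNT_COLUMNS = ["env_bc", "lineage_bc", "timepoint", "replicate", "lane", "count"]


@dataclass
class SimulationConfig:
    """Parameters of a simulated barcoded evolution / fitness assay.

    ``fitness_distribution`` names the law for non-neutral selection
    coefficients: ``{"name": "uniform", "low": ..., "high": ...}``,
    ``{"name": "normal", "mean": ..., "sd": ...}`` or
    ``{"name": "point", "value": ...}``.  ``s`` is per generation.
    """

    n_lineages: int = 100
    n_neutral: int = 20
    fitness_distribution: dict = field(
        default_factory=lambda: {"name": "uniform", "low": -0.2, "high": 0.3}
    )
    generations_per_transfer: int = 8
    n_timepoints: int = 5
    bottleneck_size: int | None = 100_000
    read_depth: int = 1_000_000
    n_replicates: int = 1
    n_lanes: int = 1
    n_environments: int = 1
    base_error_rate: float = 0.0
    chimera_rate: float = 0.0
    umi_duplication_rate: float = 0.0
    gc_bias_strength: float = 0.0
    spike_ratio: tuple[int, int] | None = None  # (ancestor, pool), e.g. (9, 1)
    barcode_length: int = 26
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("base_error_rate", "chimera_rate", "umi_duplication_rate"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be a probability in [0, 1], got {p}")
        if self.n_neutral > self.n_lineages:
            raise ValueError("n_neutral must not exceed n_lineages")
        if self.generations_per_transfer < 1:
            raise ValueError("generations_per_transfer must be >= 1")
        if not 24 <= self.barcode_length <= 28:
            raise ValueError(
                "barcode_length must lie in [24, 28] to survive the "
                f"extraction pattern, got {self.barcode_length}"
            )
        if self.gc_bias_strength < 0:
            raise ValueError("gc_bias_strength must be >= 0")
        if self.spike_ratio is not None:
            a, b = self.spike_ratio
            if a <= 0 or b <= 0:
                raise ValueError("spike_ratio parts must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "spike_ratio" in raw and raw["spike_ratio"] is not None:
            raw["spike_ratio"] = tuple(raw["spike_ratio"])
        return cls(**raw)


@dataclass
class GroundTruth:
    """Truth channel for recovery tests.

    ``lineages`` has one row per lineage (including a spiked-in ancestor
    when configured): lineage_id, env_bc, lineage_bc, environment, s,
    neutral, ancestor.  ``frequencies`` is the noise-free expected
    frequency matrix, shape (n_lineages, n_timepoints); columns sum to 1.
    ``generations`` gives the generation stamp of each timepoint.
    """

    lineages: pd.DataFrame
    frequencies: np.ndarray
    generations: np.ndarray

    def to_json(self, path: str | Path) -> None:
        payload = {
            "lineages": self.lineages.to_dict(orient="list"),
            "frequencies": self.frequencies.tolist(),
            "generations": self.generations.tolist(),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        return cls(
            lineages=pd.DataFrame(payload["lineages"]),
            frequencies=np.asarray(payload["frequencies"], dtype=float),
            generations=np.asarray(payload["generations"], dtype=float),
        )


def random_barcodes(n: int, length: int, rng: np.random.Generator) -> list[str]:
    """Distinct random A/C/G/T barcodes."""
    out: set[str] = set()
    while len(out) < n:
        block = rng.integers(0, 4, size=(n - len(out), length))
        out.update("".join(_BASES[row]) for row in block)
    return sorted(out)[:n] if len(out) == n else sorted(out)[:n]


def _draw_fitnesses(cfg: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    dist = dict(cfg.fitness_distribution)
    name = dist.pop("name")
    n_sel = cfg.n_lineages - cfg.n_neutral
    if name == "uniform":
        s = rng.uniform(dist["low"], dist["high"], size=n_sel)
    elif name == "normal":
        s = rng.normal(dist["mean"], dist["sd"], size=n_sel)
    elif name == "point":
        s = np.full(n_sel, float(dist["value"]))
    else:
        raise ValueError(f"unknown fitness distribution {name!r}")
    return np.concatenate([s, np.zeros(cfg.n_neutral)])


def _selection_update(freq: np.ndarray, s: np.ndarray, dg: float) -> np.ndarray:
    # log-space softmax: numerically safe for large s·dg
    logw = np.log(np.clip(freq, 1e-300, None)) + s * dg
    logw -= logw.max()
    w = np.exp(logw)
    w[freq <= 0] = 0.0
    return w / w.sum()


def simulate_pool(config: SimulationConfig) -> tuple[GroundTruth, pd.DataFrame]:
    """Simulate lineage frequencies and per-timepoint read counts.

    Returns the ground truth plus a tidy count table with columns
    ``env_bc, lineage_bc, timepoint, replicate, lane, count``.
    Deterministic given ``config.seed``.
    """
    if config.n_timepoints < 2:
        raise ValueError("n_timepoints must be >= 2")
    rng = np.random.default_rng(config.seed)

    env_seqs = random_barcodes(config.n_environments, config.barcode_length, rng)
    lineage_seqs = random_barcodes(config.n_lineages, config.barcode_length, rng)
    envs = [f"env{(i % config.n_environments) + 1}" for i in range(config.n_lineages)]
    env_bcs = [env_seqs[i % config.n_environments] for i in range(config.n_lineages)]
    s = _draw_fitnesses(config, rng)
    neutral = np.zeros(config.n_lineages, dtype=bool)
    neutral[config.n_lineages - config.n_neutral :] = True
    ancestor = np.zeros(config.n_lineages, dtype=bool)

    f0 = np.full(config.n_lineages, 1.0 / config.n_lineages)
    if config.spike_ratio is not None:
        a, b = config.spike_ratio
        pool_share = b / (a + b)
        f0 = np.concatenate([f0 * pool_share, [a / (a + b)]])
        anc_env, anc_lin = random_barcodes(2, config.barcode_length, rng)
        envs.append("ancestor")
        env_bcs.append(anc_env)
        lineage_seqs = lineage_seqs + [anc_lin]
        s = np.concatenate([s, [0.0]])
        neutral = np.concatenate([neutral, [True]])
        ancestor = np.concatenate([ancestor, [True]])

    n = len(s)
    dg = float(config.generations_per_transfer)
    generations = np.arange(config.n_timepoints) * dg

    # Noise-free expected trajectory (the truth channel).
    true_freq = np.empty((n, config.n_timepoints))
    f = f0.copy()
    for t in range(config.n_timepoints):
        true_freq[:, t] = f
        f = _selection_update(f, s, dg)

    rows: list[pd.DataFrame] = []
    for rep in range(1, config.n_replicates + 1):
        f = f0.copy()
        for t in range(config.n_timepoints):
            if t > 0:
                f = _selection_update(f, s, dg)
                if config.bottleneck_size:
                    cells = rng.multinomial(config.bottleneck_size, f)
                    f = cells / cells.sum()
            for lane in range(1, config.n_lanes + 1):
                depth = config.read_depth // config.n_lanes
                counts = rng.multinomial(depth, f)
                rows.append(
                    pd.DataFrame(
                        {
                            "env_bc": env_bcs,
                            "lineage_bc": lineage_seqs,
                            "timepoint": t,
                            "replicate": rep,
                            "lane": lane,
                            "count": counts,
                        }
                    )
                )
    table = pd.concat(rows, ignore_index=True)
    table = table[table["count"] > 0].reset_index(drop=True)

    truth = GroundTruth(
        lineages=pd.DataFrame(
            {
                "lineage_id": np.arange(n),
                "env_bc": env_bcs,
                "lineage_bc": lineage_seqs,
                "environment": envs,
                "s": s,
                "neutral": neutral,
                "ancestor": ancestor,
            }
        ),
        frequencies=true_freq,
        generations=generations,
    )
    return truth, table


def gc_fraction(sequence: str) -> float:
    if not sequence:
        return 0.0
    return sum(1 for b in sequence if b in "GCgc") / len(sequence)


def _largest_remainder_round(values: np.ndarray, total: int) -> np.ndarray:
    """Integer-round non-negative values so they sum exactly to ``total``."""
    floors = np.floor(values).astype(np.int64)
    shortfall = int(total - floors.sum())
    if shortfall > 0:
        order = np.argsort(-(values - floors), kind="stable")
        floors[order[:shortfall]] += 1
    return floors


def apply_gc_bias(
    counts: pd.DataFrame, truth: GroundTruth, strength: float
) -> pd.DataFrame:
    """Distort read counts by barcode GC content.

    Each lineage's expected count is multiplied by
    ``exp(strength · (GC − 0.5))`` where GC is the G+C fraction of the
    concatenated (environment + lineage) barcode, then each library is
    renormalized to its original total.  ``strength = 0`` is the identity.
    """
    if strength < 0:
        raise ValueError("strength must be >= 0")
    if strength == 0:
        return counts.copy()
    gc = {
        (r.env_bc, r.lineage_bc): gc_fraction(r.env_bc + r.lineage_bc)
        for r in truth.lineages.itertuples()
    }
    out = counts.copy()
    keys = list(zip(out["env_bc"], out["lineage_bc"]))
    weights = np.array([np.exp(strength * (gc.get(k, 0.5) - 0.5)) for k in keys])
    new_counts = np.empty(len(out), dtype=np.int64)
    for _, idx in out.groupby(["timepoint", "replicate", "lane"]).groups.items():
        idx = np.asarray(idx)
        sub = out.loc[idx, "count"].to_numpy(dtype=float) * weights[
            out.index.get_indexer(idx)
        ]
        total = int(counts.loc[idx, "count"].sum())
        scaled = sub * (total / sub.sum())
        new_counts[out.index.get_indexer(idx)] = _largest_remainder_round(scaled, total)
    out["count"] = new_counts
    return out


def _random_seq(rng: np.random.Generator, length: int, bases: np.ndarray = _BASES) -> str:
    return "".join(bases[rng.integers(0, len(bases), size=length)])


def _substitute(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    for i in hits:
        current = arr[i].decode()
        choices = [b for b in "ACGT" if b != current]
        arr[i] = choices[rng.integers(0, len(choices))]
    return arr.tobytes().decode()


def library_label(timepoint: int, replicate: int, lane: int) -> str:
    return f"t{timepoint}_r{replicate}_l{lane}"


def make_index_table(counts: pd.DataFrame, rng: np.random.Generator) -> dict[str, str]:
    """Assign a distinct inline index sequence to each library in ``counts``."""
    libs = sorted(
        {
            library_label(t, r, l)
            for t, r, l in zip(counts["timepoint"], counts["replicate"], counts["lane"])
        }
    )
    seqs = random_barcodes(len(libs), INDEX_LENGTH, rng)
    return dict(zip(seqs, libs))


def emit_reads(
    counts: pd.DataFrame,
    config: SimulationConfig,
    index_table: dict[str, str] | None = None,
    rng: np.random.Generator | None = None,
) -> Iterator[tuple[str, str, str, str, str]]:
    """Yield paired amplicon reads ``(read_id, seq1, qual1, seq2, qual2)``.

    One molecule per counted read: read 1 carries the lineage barcode,
    read 2 the environment barcode, each as
    UMI + inline index + pad + GGTACC + barcode + ATAACT + pad.
    Chimeras re-pair a molecule's environment barcode with one drawn from
    another molecule (count-weighted); substitution errors hit every base
    downstream of the inline index; UMI duplicates re-emit the post-error
    read with the same UMI.
    """
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    index_by_lib = (
        {lib: seq for seq, lib in index_table.items()} if index_table else {}
    )
    env_pool = counts["env_bc"].to_numpy()
    env_weights = counts["count"].to_numpy(dtype=float)
    env_weights = env_weights / env_weights.sum()
    serial = 0
    # distinct molecules get distinct UMIs within a library (redraw on the
    # rare collision) so only deliberate duplicates share a UMI
    seen_umis: dict[str, set[str]] = {}
    for row in counts.itertuples():
        lib = library_label(row.timepoint, row.replicate, row.lane)
        index_seq = index_by_lib.get(lib, "")
        lib_umis = seen_umis.setdefault(lib, set())
        for _ in range(int(row.count)):
            env_bc = row.env_bc
            if config.chimera_rate > 0 and rng.random() < config.chimera_rate:
                env_bc = env_pool[rng.choice(len(env_pool), p=env_weights)]
            while True:
                umi1 = _random_seq(rng, UMI_LENGTH)
                umi2 = _random_seq(rng, UMI_LENGTH)
                if umi1 + umi2 not in lib_umis:
                    lib_umis.add(umi1 + umi2)
                    break
            body1 = (
                _random_seq(rng, PAD_LENGTH, _PAD_BASES_LEFT)
                + LEFT_FLANK
                + row.lineage_bc
                + RIGHT_FLANK
                + _random_seq(rng, PAD_LENGTH)
            )
            body2 = (
                _random_seq(rng, PAD_LENGTH, _PAD_BASES_LEFT)
                + LEFT_FLANK
                + env_bc
                + RIGHT_FLANK
                + _random_seq(rng, PAD_LENGTH)
            )
            body1 = _substitute(body1, config.base_error_rate, rng)
            body2 = _substitute(body2, config.base_error_rate, rng)
            seq1 = umi1 + index_seq + body1
            seq2 = umi2 + index_seq + body2
            q1 = DEFAULT_QUALITY_CHAR * len(seq1)
            q2 = DEFAULT_QUALITY_CHAR * len(seq2)
            serial += 1
            yield (f"sim:{lib}:{serial}", seq1, q1, seq2, q2)
            while (
                config.umi_duplication_rate > 0
                and rng.random() < config.umi_duplication_rate
            ):
                serial += 1
                yield (f"sim:{lib}:{serial}:dup", seq1, q1, seq2, q2)


def write_fastq_pair(
    reads: Iterator[tuple[str, str, str, str, str]],
    r1_path: str | Path,
    r2_path: str | Path,
) -> int:
    """Write paired reads to two 4-line FASTQ files; returns pair count."""
    n = 0
    with open(r1_path, "w") as f1, open(r2_path, "w") as f2:
        for read_id, s1, q1, s2, q2 in reads:
            f1.write(f"@{read_id}/1\n{s1}\n+\n{q1}\n")
            f2.write(f"@{read_id}/2\n{s2}\n+\n{q2}\n")
            n += 1
    return n


def simulate_subpool_reads(
    truth: GroundTruth,
    reads_per_lineage: int = 20,
    cross_contamination: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate sub-pool barcode sequencing used for home-environment calls.

    Each lineage's reads land in its own environment's sub-pool library,
    except a ``cross_contamination`` fraction scattered uniformly over the
    other sub-pools.  Returns columns ``env_bc, lineage_bc, subpool, count``.
    """
    rng = np.random.default_rng(seed)
    pools = sorted(set(truth.lineages["environment"]) - {"ancestor"})
    rows = []
    for r in truth.lineages.itertuples():
        if r.environment == "ancestor":
            continue
        n_cross = rng.binomial(reads_per_lineage, cross_contamination)
        per_pool = {r.environment: reads_per_lineage - n_cross}
        for _ in range(n_cross):
            other = pools[rng.integers(0, len(pools))]
            per_pool[other] = per_pool.get(other, 0) + 1
        for pool, cnt in per_pool.items():
            if cnt:
                rows.append((r.env_bc, r.lineage_bc, pool, cnt))
    return pd.DataFrame(rows, columns=["env_bc", "lineage_bc", "subpool", "count"])


def simulate_barcode_errors(
    true_counts: Mapping[str, int], error_rate: float, seed: int = 0
) -> pd.DataFrame:
    """Apply per-base substitution errors to reads of known true barcodes.

    Returns a read-level tally with columns ``sequence, generator, count``
    where ``generator`` is the true barcode each (possibly erroneous)
    observed sequence came from — the truth channel for error-correction
    recovery tests.
    """
    rng = np.random.default_rng(seed)
    tally: dict[tuple[str, str], int] = {}
    for true_bc, n_reads in true_counts.items():
        length = len(true_bc)
        n_err = rng.binomial(n_reads, 1.0 - (1.0 - error_rate) ** length)
        key = (true_bc, true_bc)
        tally[key] = tally.get(key, 0) + (n_reads - n_err)
        for _ in range(n_err):
            seq = true_bc
            while seq == true_bc:
                seq = _substitute(true_bc, error_rate, rng)
            key = (seq, true_bc)
            tally[key] = tally.get(key, 0) + 1
    return pd.DataFrame(
        [(s, g, c) for (s, g), c in sorted(tally.items())],
        columns=["sequence", "generator", "count"],
    )


def write_counts(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t", index=False)


def read_counts(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
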