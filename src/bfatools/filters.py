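"""Post-correction lineage filters.

GC-content exclusion (PCR under-amplifies very AT-rich amplicons, making
frequencies unreliable), manual timepoint exclusion, and sub-pool-based
home-environment assignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import yaml

GC_WINDOW = 26
GC_MIN = 4  # windows with fewer G/C bases than this exclude the barcode
HOME_MIN_READS = 3
HOME_MIN_FRACTION = 0.95  # strict: the top sub-pool must hold > 95% of reads

UNASSIGNED = "unassigned"


@dataclass
class LineageRecord:
    env_bc: str
    lineage_bc: str
    home_environment: str = UNASSIGNED
    ploidy: str = "unknown"  # "1N" | "2N" | "unknown"
    gc_excluded: bool = False
    chimera: bool = False
    assigned: bool = False


def min_gc_window(sequence: str, window_length: int = GC_WINDOW) -> int:
    """Minimum G+C base count over all sliding windows of ``window_length``.

    A sequence shorter than the window is treated as its own single
    window.  Invariant under reverse complement.
    """
    if not sequence:
        raise ValueError("empty sequence")
    seq = sequence.upper()
    is_gc = [1 if b in "GC" else 0 for b in seq]
    if len(seq) <= window_length:
        return sum(is_gc)
    window = sum(is_gc[:window_length])
    best = window
    for i in range(window_length, len(seq)):
        window += is_gc[i] - is_gc[i - window_length]
        best = min(best, window)
    return best


def gc_filter(
    env_bc: str,
    lineage_bc: str,
    window_length: int = GC_WINDOW,
    min_gc: int = GC_MIN,
) -> bool:
    """True (keep) iff the minimum GC window over the concatenated barcode
    region (env + lineage barcode) is at least ``min_gc``; a minimum of
    exactly ``min_gc`` is kept."""
    return min_gc_window(env_bc + lineage_bc, window_length) >= min_gc


def apply_gc_filter(centroids: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split a centroid table into (kept, gc_excluded)."""
    keep = pd.Series(
        [gc_filter(e, l) for e, l in zip(centroids["env_bc"], centroids["lineage_bc"])],
        index=centroids.index,
    )
    return centroids[keep].reset_index(drop=True), centroids[~keep].reset_index(
        drop=True
    )


@dataclass
class TimepointExclusions:
    """Manually excluded (assay, environment, replicate, timepoint) cells.

    Typically transcribed from by-eye review of neutral-class diagnostics;
    ships empty by default.
    """

    entries: list[dict] = field(default_factory=list)

    _KEYS = {"assay", "environment", "replicate", "timepoint"}

    def __post_init__(self) -> None:
        for e in self.entries:
            unknown = set(e) - self._KEYS
            if unknown:
                raise ValueError(f"unknown exclusion keys: {sorted(unknown)}")
            if "timepoint" not in e:
                raise ValueError("each exclusion entry needs a timepoint")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "TimepointExclusions":
        raw = yaml.safe_load(Path(path).read_text()) or []
        return cls(entries=list(raw))

    def matches(self, row: Mapping) -> bool:
        for e in self.entries:
            if all(str(row.get(k)) == str(v) for k, v in e.items()):
                return True
        return False


def exclude_timepoints(
    counts: pd.DataFrame, exclusions: TimepointExclusions
) -> pd.DataFrame:
    """Drop excluded timepoint rows before fitness inference.

    A replicate whose every timepoint is excluded simply yields no
    fitness estimates downstream (missing, not zero).
    """
    if not exclusions.entries:
        return counts.copy()
    mask = counts.apply(lambda row: exclusions.matches(row), axis=1)
    return counts[~mask].reset_index(drop=True)


def assign_home_environment(
    subpool_counts: Mapping[str, int],
    min_reads: int = HOME_MIN_READS,
    min_fraction: float = HOME_MIN_FRACTION,
) -> str:
    """Assign a barcode to its home environment from sub-pool read counts.

    Assigned iff total reads >= ``min_reads`` and the top sub-pool holds
    strictly more than ``min_fraction`` of them; ties and misses are
    unassigned.
    """
    total = sum(subpool_counts.values())
    if total < min_reads or total == 0:
        return UNASSIGNED
    pool, top = max(subpool_counts.items(), key=lambda kv: (kv[1], kv[0]))
    if top / total > min_fraction:
        return pool
    return UNASSIGNED


def assign_home_environments(
    subpool_table: pd.DataFrame,
    min_reads: int = HOME_MIN_READS,
    min_fraction: float = HOME_MIN_FRACTION,
) -> pd.DataFrame:
    """Vectorized assignment over a tidy sub-pool count table.

    Expects columns ``env_bc, lineage_bc, subpool, count``; returns one
    row per barcode with its ``home_environment`` (or "unassigned").
    """
    rows = []
    for (env, lin), grp in subpool_table.groupby(["env_bc", "lineage_bc"]):
        counts = dict(zip(grp["subpool"], grp["count"]))
        rows.append((env, lin, assign_home_environment(counts, min_reads, min_fraction)))
    return pd.DataFrame(rows, columns=["env_bc", "lineage_bc", "home_environment"])


def restrict_to_environments(
    lineages: pd.DataFrame, environments: Iterable[str]
) -> pd.DataFrame:
    """Keep only lineages whose home environment is in the configured set."""
    allowed = set(environments)
    return lineages[lineages["home_environment"].isin(allowed)].reset_index(drop=True)


def neutral_gc_diagnostic(
    counts: pd.DataFrame, neutral_keys: set[tuple[str, str]]
) -> pd.DataFrame:
    """Per-timepoint diagnostic table for manual GC-bias review.

    For each (replicate, timepoint) reports the neutral-class read share
    and the mean minimum-GC-window of neutral barcodes observed there.
    """
    df = counts.copy()
    df["is_neutral"] = [
        (e, l) in neutral_keys for e, l in zip(df["env_bc"], df["lineage_bc"])
    ]
    rows = []
    for (rep, tp), grp in df.groupby(["replicate", "timepoint"]):
        neut = grp[grp["is_neutral"]]
        share = neut["count"].sum() / max(grp["count"].sum(), 1)
        mean_gc = (
            sum(min_gc_window(e + l) for e, l in zip(neut["env_bc"], neut["lineage_bc"]))
            / len(neut)
            if len(neut)
            else float("nan")
        )
        rows.append((rep, tp, share, mean_gc))
    return pd.DataFrame(
        rows, columns=["replicate", "timepoint", "neutral_read_share", "neutral_mean_min_gc"]
    )
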