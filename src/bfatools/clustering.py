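"""Deletion-neighborhood barcode error correction.

Observed barcode sequences are mostly true barcodes plus a cloud of PCR
and sequencing errors one or two edits away.  The correction groups
barcodes into *deletion neighborhoods* — connected components of the
graph that joins two sequences whenever their single-base-deletion sets
(including the sequence itself) intersect, which captures every pair one
substitution, insertion or deletion apart — then calls *peaks* (true
barcodes) within each neighborhood and folds the remaining members into
the nearest peak by Levenshtein distance.

Peak criteria, applied in descending count order (lexicographic
tie-break):

1. no uncalled base ('N');
2. no single-edit neighbor in the neighborhood with more total counts;
3. more than 10 total counts;
4. more than 3 edits away from every already-accepted peak.

Non-peaks correct to a peak at edit distance <= 3 (the highest-count such
peak); barcodes with no peak within 3 edits are discarded, with their
reads tallied for exact read conservation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

PEAK_MIN_COUNT = 10  # strict: a peak needs more than this many reads
CORRECTION_MAX_EDITS = 3
CENTROID_MIN_COUNT = 10  # strict: centroids with <= this many reads are dropped
CHIMERA_FOLD = 100.0


def levenshtein(a: str, b: str) -> int:
    """Standard edit distance (substitution, insertion, deletion all cost 1)."""
    if a == b:
        return 0
    if not a:
        return len(b)
    if not b:
        return len(a)
    if len(a) < len(b):
        a, b = b, a
    previous = list(range(len(b) + 1))
    for i, ca in enumerate(a, start=1):
        current = [i] + [0] * len(b)
        for j, cb in enumerate(b, start=1):
            current[j] = min(
                previous[j] + 1,
                current[j - 1] + 1,
                previous[j - 1] + (ca != cb),
            )
        previous = current
    return previous[-1]


def deletion_set(sequence: str) -> frozenset[str]:
    """The sequence itself plus every single-base deletion of it.

    Self-inclusion makes the overlap test catch insertion/deletion
    neighbors (pure deletion sets of different-length strings never
    intersect); it also connects a few distance-2 pairs, which is
    harmless because the final assignment re-checks true edit distance.
    """
    if not sequence:
        raise ValueError("empty sequence has no deletion set")
    return frozenset(
        [sequence] + [sequence[:i] + sequence[i + 1 :] for i in range(len(sequence))]
    )


@dataclass
class Neighborhood:
    """A connected component of the deletion-overlap graph."""

    members: dict[str, int]  # sequence -> total count
    peaks: list[str] = field(default_factory=list)
    corrections: dict[str, str | None] = field(default_factory=dict)


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
            self.parent[rj] = ri


def build_neighborhoods(counts: Mapping[str, int]) -> list[Neighborhood]:
    """Partition counted barcodes into deletion neighborhoods.

    Uses a hash index from deletion-set element to barcode, so the
    construction is linear in total deletion-set size rather than
    quadratic in the number of barcodes.
    """
    seqs = sorted(counts)
    uf = _UnionFind(len(seqs))
    index: dict[str, int] = {}
    for i, seq in enumerate(seqs):
        for d in deletion_set(seq):
            if d in index:
                uf.union(index[d], i)
            else:
                index[d] = i
    components: dict[int, dict[str, int]] = {}
    for i, seq in enumerate(seqs):
        components.setdefault(uf.find(i), {})[seq] = int(counts[seq])
    return [Neighborhood(members=m) for _, m in sorted(components.items())]


def build_neighborhoods_naive(counts: Mapping[str, int]) -> list[set[str]]:
    """All-pairs oracle for the hashed construction (tests only)."""
    seqs = sorted(counts)
    dsets = [deletion_set(s) for s in seqs]
    uf = _UnionFind(len(seqs))
    for i in range(len(seqs)):
        for j in range(i + 1, len(seqs)):
            if dsets[i] & dsets[j]:
                uf.union(i, j)
    comps: dict[int, set[str]] = {}
    for i, s in enumerate(seqs):
        comps.setdefault(uf.find(i), set()).add(s)
    return list(comps.values())


def call_peaks(
    neighborhood: Neighborhood, min_count: int = PEAK_MIN_COUNT
) -> list[str]:
    """Identify true-barcode peaks within one neighborhood."""
    ordered = sorted(neighborhood.members.items(), key=lambda kv: (-kv[1], kv[0]))
    peaks: list[str] = []
    for seq, count in ordered:
        if "N" in seq:
            continue
        if count <= min_count:
            continue
        if any(
            abs(len(seq) - len(p)) <= CORRECTION_MAX_EDITS
            and levenshtein(seq, p) <= CORRECTION_MAX_EDITS
            for p in peaks
        ):
            continue
        if _has_bigger_single_edit_neighbor(seq, count, ordered):
            continue
        peaks.append(seq)
    neighborhood.peaks = peaks
    return peaks


def _has_bigger_single_edit_neighbor(
    seq: str, count: int, ordered: list[tuple[str, int]]
) -> bool:
    for other, other_count in ordered:
        if other_count <= count:
            break  # sorted descending: no later member can have more counts
        if abs(len(other) - len(seq)) <= 1 and levenshtein(seq, other) == 1:
            return True
    return False


def correct_errors(
    neighborhood: Neighborhood, max_edits: int = CORRECTION_MAX_EDITS
) -> dict[str, str | None]:
    """Map every member to its peak, or to None (discarded).

    Peaks map to themselves.  A member within ``max_edits`` of several
    peaks corrects to the one with more total counts (lexicographic
    tie-break for determinism).
    """
    peaks = neighborhood.peaks
    members = neighborhood.members
    peak_set = set(peaks)
    corrections: dict[str, str | None] = {}
    for seq in members:
        if seq in peak_set:
            corrections[seq] = seq
            continue
        candidates = [
            p
            for p in peaks
            if abs(len(seq) - len(p)) <= max_edits
            and levenshtein(seq, p) <= max_edits
        ]
        if candidates:
            # higher count wins; among equal counts the lexicographically
            # smaller peak is chosen for determinism
            corrections[seq] = min(candidates, key=lambda p: (-members[p], p))
        else:
            corrections[seq] = None
    neighborhood.corrections = corrections
    return corrections


def cluster_barcodes(
    counts: Mapping[str, int],
    min_peak_count: int = PEAK_MIN_COUNT,
    max_edits: int = CORRECTION_MAX_EDITS,
) -> tuple[dict[str, str | None], list[Neighborhood]]:
    """Full correction of one barcode class.

    Returns (correction map over all observed sequences, neighborhoods).
    """
    neighborhoods = build_neighborhoods(counts)
    correction: dict[str, str | None] = {}
    for nb in neighborhoods:
        call_peaks(nb, min_count=min_peak_count)
        correction.update(correct_errors(nb, max_edits=max_edits))
    return correction, neighborhoods


def build_centroids(
    observations: pd.DataFrame,
    env_correction: Mapping[str, str | None],
    lineage_correction: Mapping[str, str | None],
    min_total: int = CENTROID_MIN_COUNT,
    sample_columns: Sequence[str] = (),
) -> tuple[pd.DataFrame, int]:
    """Aggregate corrected (env, lineage) barcode pairs into centroids.

    ``observations`` needs columns ``env_bc, lineage_bc, count`` plus any
    ``sample_columns`` (library/timepoint/replicate keys) to keep.
    Combinations with total count <= ``min_total`` are dropped.  Returns
    (centroid table, discarded read count); input reads are exactly
    conserved as kept + discarded.
    """
    df = observations.copy()
    total_in = int(df["count"].sum())
    df["env_bc"] = df["env_bc"].map(lambda s: env_correction.get(s, None))
    df["lineage_bc"] = df["lineage_bc"].map(lambda s: lineage_correction.get(s, None))
    bad = df["env_bc"].isna() | df["lineage_bc"].isna()
    discarded = int(df.loc[bad, "count"].sum())
    df = df[~bad]
    keys = ["env_bc", "lineage_bc", *sample_columns]
    agg = df.groupby(keys, sort=True, as_index=False)["count"].sum()
    totals = agg.groupby(["env_bc", "lineage_bc"])["count"].transform("sum")
    low = totals <= min_total
    discarded += int(agg.loc[low, "count"].sum())
    centroids = agg[~low].reset_index(drop=True)
    assert int(centroids["count"].sum()) + discarded == total_in
    return centroids, discarded


def merge_lanes(lane_tables: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Intersect centroid tables over lanes and sum their counts.

    A (env_bc, lineage_bc) combination missing from any lane is dropped —
    lane-specific contamination does not survive the intersection.
    """
    if not lane_tables:
        raise ValueError("need at least one lane table")
    keysets = [
        set(zip(t["env_bc"], t["lineage_bc"])) for t in lane_tables
    ]
    common = set.intersection(*keysets)
    frames = []
    for t in lane_tables:
        mask = [
            (e, l) in common for e, l in zip(t["env_bc"], t["lineage_bc"])
        ]
        frames.append(t[pd.Series(mask, index=t.index)])
    merged = pd.concat(frames, ignore_index=True)
    keys = [c for c in merged.columns if c not in ("count", "lane")]
    return merged.groupby(keys, sort=True, as_index=False)["count"].sum()


def remove_chimeras(
    centroids: pd.DataFrame, fold: float = CHIMERA_FOLD
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop centroids that look like PCR chimeras.

    A centroid is removed iff another centroid shares its lineage barcode
    under a different environment barcode with at least ``fold`` times its
    total reads.  Returns (kept, removed).
    """
    totals = (
        centroids.groupby(["env_bc", "lineage_bc"], as_index=False)["count"]
        .sum()
        .rename(columns={"count": "total"})
    )
    removed_keys: set[tuple[str, str]] = set()
    for _, grp in totals.groupby("lineage_bc"):
        if len(grp) < 2:
            continue
        vals = grp["total"].to_numpy(dtype=float)
        envs = grp["env_bc"].to_numpy()
        top = vals.max()
        top2 = np.partition(vals, -2)[-2] if len(vals) > 1 else 0.0
        for env, v in zip(envs, vals):
            rival = top if v < top else top2
            if rival >= fold * v:
                removed_keys.add((env, grp["lineage_bc"].iloc[0]))
    mask = [
        (e, l) in removed_keys
        for e, l in zip(centroids["env_bc"], centroids["lineage_bc"])
    ]
    mask = pd.Series(mask, index=centroids.index)
    return (
        centroids[~mask].reset_index(drop=True),
        centroids[mask].reset_index(drop=True),
    )


def correction_qc(
    neighborhoods: Iterable[Neighborhood],
) -> dict[str, int]:
    n_nb = n_peaks = n_discarded = 0
    for nb in neighborhoods:
        n_nb += 1
        n_peaks += len(nb.peaks)
        n_discarded += sum(
            nb.members[s] for s, t in nb.corrections.items() if t is None
        )
    return {
        "neighborhoods": n_nb,
        "peaks": n_peaks,
        "discarded_reads": n_discarded,
    }
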