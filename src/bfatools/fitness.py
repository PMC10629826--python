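"""Neutral-scaled fitness inference from barcode count trajectories.

For each lineage the per-generation selection coefficient is estimated
from the slope of the natural log of its frequency between consecutive
valid timepoints (both endpoints need >= 10 reads), scaled by
subtracting, per timepoint pair, the median log-frequency slope of a
putatively neutral lineage class.  Per-replicate estimates are the mean
of the scaled pair slopes (standard error = sample SD / sqrt(n));
replicates combine by inverse-variance weighting.

When too few neutral lineages remain countable at a timepoint pair
(e.g. the neutral class is being swept out under strong selection), the
counts of the two lowest-count neutral lineages are merged repeatedly
until at least three merged lineages are valid at the pair; pairs that
still fail are unusable assay-wide.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

MIN_VALID_READS = 10
MIN_NEUTRAL_LINEAGES = 3


@dataclass
class FitnessEstimate:
    """Per-generation selection coefficient with its uncertainty."""

    s_hat: float
    se: float | None
    n_pairs: int
    replicate: int | str | None = None
    combined: bool = False
    flagged: bool = False  # e.g. unweighted combination because no se existed


@dataclass
class NeutralReference:
    """Per-pair median neutral log-frequency slope; NaN = unusable pair."""

    reference: np.ndarray  # length n_timepoints - 1
    n_merges: int = 0
    merge_log: list[tuple[int, int]] = field(default_factory=list)

    def usable(self, k: int) -> bool:
        return bool(np.isfinite(self.reference[k]))


def pair_slopes(
    counts: Sequence[int],
    totals: Sequence[int],
    generations: Sequence[float],
    min_reads: int = MIN_VALID_READS,
) -> list[tuple[int, float]]:
    """Log-frequency slopes per generation between consecutive valid timepoints.

    Returns ``(pair index k, slope_k)`` for each adjacent pair where both
    timepoints carry at least ``min_reads`` reads; an empty list means the
    lineage's fitness is missing (not zero).
    """
    counts = np.asarray(counts, dtype=float)
    totals = np.asarray(totals, dtype=float)
    generations = np.asarray(generations, dtype=float)
    if not (np.diff(generations) > 0).all():
        raise ValueError("generation stamps must be strictly increasing")
    if (counts > totals).any():
        raise ValueError("counts cannot exceed library totals")
    out = []
    for k in range(len(counts) - 1):
        if counts[k] >= min_reads and counts[k + 1] >= min_reads:
            f0 = counts[k] / totals[k]
            f1 = counts[k + 1] / totals[k + 1]
            dg = generations[k + 1] - generations[k]
            out.append((k, (math.log(f1) - math.log(f0)) / dg))
    return out


def neutral_reference(
    neutral_counts: np.ndarray,
    totals: Sequence[int],
    generations: Sequence[float],
    min_reads: int = MIN_VALID_READS,
    min_lineages: int = MIN_NEUTRAL_LINEAGES,
) -> NeutralReference:
    """Median neutral slope per timepoint pair, with iterative merging.

    ``neutral_counts`` is (n_neutral_lineages, n_timepoints).  While any
    pair has fewer than ``min_lineages`` valid neutral lineages and more
    than ``min_lineages`` lineages remain, the two lowest-total-count
    lineages are merged (counts summed).  Pairs that still fail are NaN
    and must be excluded assay-wide.
    """
    counts = np.asarray(neutral_counts, dtype=float)
    if counts.ndim != 2 or counts.shape[0] == 0:
        raise ValueError("need a non-empty (lineages x timepoints) neutral count matrix")
    totals = np.asarray(totals, dtype=float)
    generations = np.asarray(generations, dtype=float)
    n_pairs = counts.shape[1] - 1
    merge_log: list[tuple[int, int]] = []

    def valid_per_pair(c: np.ndarray) -> np.ndarray:
        ok = c >= min_reads
        return (ok[:, :-1] & ok[:, 1:]).sum(axis=0)

    while (valid_per_pair(counts) < min_lineages).any() and counts.shape[0] > min_lineages:
        order = np.argsort(counts.sum(axis=1), kind="stable")
        i, j = sorted((int(order[0]), int(order[1])))
        merge_log.append((i, j))
        counts[i] += counts[j]
        counts = np.delete(counts, j, axis=0)

    ref = np.full(n_pairs, np.nan)
    for k in range(n_pairs):
        slopes = []
        for row in counts:
            if row[k] >= min_reads and row[k + 1] >= min_reads:
                f0 = row[k] / totals[k]
                f1 = row[k + 1] / totals[k + 1]
                dg = generations[k + 1] - generations[k]
                slopes.append((math.log(f1) - math.log(f0)) / dg)
        if len(slopes) >= min_lineages:
            ref[k] = float(np.median(slopes))
    return NeutralReference(reference=ref, n_merges=len(merge_log), merge_log=merge_log)


def scaled_fitness(
    counts: Sequence[int],
    totals: Sequence[int],
    generations: Sequence[float],
    reference: NeutralReference,
    min_reads: int = MIN_VALID_READS,
    replicate: int | str | None = None,
) -> FitnessEstimate | None:
    """Neutral-scaled fitness of one lineage in one replicate.

    Mean over valid pairs of (slope - neutral reference); None when no
    pair is both lineage-valid and reference-usable.
    """
    scaled = [
        slope - reference.reference[k]
        for k, slope in pair_slopes(counts, totals, generations, min_reads)
        if reference.usable(k)
    ]
    if not scaled:
        return None
    n = len(scaled)
    s_hat = float(np.mean(scaled))
    se = float(np.std(scaled, ddof=1) / math.sqrt(n)) if n >= 2 else None
    return FitnessEstimate(s_hat=s_hat, se=se, n_pairs=n, replicate=replicate)


def combine_replicates(estimates: Sequence[FitnessEstimate]) -> FitnessEstimate | None:
    """Inverse-variance-weighted combination across replicates.

    Replicates without a standard error (single valid pair) are excluded;
    if none has one, the unweighted mean is returned with a flag and no
    combined standard error.
    """
    estimates = [e for e in estimates if e is not None]
    if not estimates:
        return None
    weighted = [e for e in estimates if e.se is not None and e.se > 0]
    if weighted:
        w = np.array([1.0 / e.se**2 for e in weighted])
        s = np.array([e.s_hat for e in weighted])
        return FitnessEstimate(
            s_hat=float((w * s).sum() / w.sum()),
            se=float(math.sqrt(1.0 / w.sum())),
            n_pairs=sum(e.n_pairs for e in weighted),
            combined=True,
        )
    return FitnessEstimate(
        s_hat=float(np.mean([e.s_hat for e in estimates])),
        se=None,
        n_pairs=sum(e.n_pairs for e in estimates),
        combined=True,
        flagged=True,
    )


def estimate_fitness_table(
    counts: pd.DataFrame,
    neutral_keys: set[tuple[str, str]],
    generations_per_timepoint: float = 8.0,
    min_reads: int = MIN_VALID_READS,
    generation_stamps: dict[int, float] | None = None,
) -> pd.DataFrame:
    """Fitness estimates for every lineage in a tidy count table.

    ``counts`` needs columns ``env_bc, lineage_bc, timepoint, replicate,
    count`` (lane already merged).  Library totals per (replicate,
    timepoint) are the sums over the analyzed barcode set.  Returns one
    row per lineage per replicate plus a combined row (replicate
    "combined").
    """
    rows = []
    per_lineage: dict[tuple[str, str], list[FitnessEstimate]] = {}
    for rep, rep_df in counts.groupby("replicate"):
        tps = sorted(rep_df["timepoint"].unique())
        if generation_stamps is not None:
            gens = np.array([generation_stamps[t] for t in tps], dtype=float)
        else:
            gens = np.array(tps, dtype=float) * generations_per_timepoint
        mat = rep_df.pivot_table(
            index=["env_bc", "lineage_bc"],
            columns="timepoint",
            values="count",
            aggfunc="sum",
            fill_value=0,
        ).reindex(columns=tps, fill_value=0)
        totals = mat.sum(axis=0).to_numpy(dtype=float)
        neutral_mask = np.array([key in neutral_keys for key in mat.index])
        if not neutral_mask.any():
            raise ValueError(f"no neutral lineages observed in replicate {rep}")
        ref = neutral_reference(
            mat.to_numpy(dtype=float)[neutral_mask], totals, gens, min_reads
        )
        for key, row in zip(mat.index, mat.to_numpy(dtype=float)):
            est = scaled_fitness(row, totals, gens, ref, min_reads, replicate=rep)
            if est is None:
                continue
            per_lineage.setdefault(key, []).append(est)
            rows.append(
                {
                    "env_bc": key[0],
                    "lineage_bc": key[1],
                    "replicate": str(rep),
                    "s_hat": est.s_hat,
                    "se": est.se,
                    "n_pairs": est.n_pairs,
                    "flagged": est.flagged,
                }
            )
    for key, ests in sorted(per_lineage.items()):
        comb = combine_replicates(ests)
        rows.append(
            {
                "env_bc": key[0],
                "lineage_bc": key[1],
                "replicate": "combined",
                "s_hat": comb.s_hat,
                "se": comb.se,
                "n_pairs": comb.n_pairs,
                "flagged": comb.flagged,
            }
        )
    return pd.DataFrame(
        rows, columns=["env_bc", "lineage_bc", "replicate", "s_hat", "se", "n_pairs", "flagged"]
    )
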