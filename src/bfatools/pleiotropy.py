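"""Pleiotropy profiling of adaptive lineages.

A lineage's pleiotropic profile is its vector of neutral-scaled fitness
estimates across the assay environments.  Effects are classified against
measurement noise (|s| > k·se), pleiotropy is present when any non-home
environment is non-neutral, and adaptation is cost-free when the home
effect is beneficial with no deleterious non-home effect.  A permutation
test asks whether mutations in the same gene have more similar profiles
than mutations in different genes from the same home environment.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

NOISE_SIGMAS = 2.0  # "within the bounds of measurement noise": +/- 2 se
MIN_SHARED_ENVIRONMENTS = 3

Effect = Literal["beneficial", "neutral", "deleterious", "missing"]


@dataclass
class FitnessProfile:
    """Fitness vector of one lineage across assay environments."""

    lineage: str
    home_environment: str
    values: dict[str, tuple[float, float | None]]  # env -> (s_hat, se)
    gene: str | None = None


def classify_effect(
    s_hat: float | None, se: float | None, k: float = NOISE_SIGMAS
) -> Effect:
    """beneficial iff s > k·se, deleterious iff s < -k·se, else neutral."""
    if s_hat is None or not math.isfinite(s_hat) or se is None:
        return "missing"
    if s_hat > k * se:
        return "beneficial"
    if s_hat < -k * se:
        return "deleterious"
    return "neutral"


def classify_effect_fixed(
    s_hat: float | None,
    beneficial_above: float,
    deleterious_below: float,
) -> Effect:
    """Fixed-cutoff classification mode (for narrative-style thresholds)."""
    if s_hat is None or not math.isfinite(s_hat):
        return "missing"
    if s_hat > beneficial_above:
        return "beneficial"
    if s_hat < deleterious_below:
        return "deleterious"
    return "neutral"


def pleiotropy_present(profile: FitnessProfile, k: float = NOISE_SIGMAS) -> bool | None:
    """True iff any non-home environment is non-neutral; None = no data."""
    classes = [
        classify_effect(s, se, k)
        for env, (s, se) in profile.values.items()
        if env != profile.home_environment
    ]
    classes = [c for c in classes if c != "missing"]
    if not classes:
        return None
    return any(c in ("beneficial", "deleterious") for c in classes)


def cost_free(profile: FitnessProfile, k: float = NOISE_SIGMAS) -> bool | None:
    """Beneficial at home with no deleterious non-home effect."""
    home = profile.values.get(profile.home_environment)
    if home is None:
        return None
    if classify_effect(*home, k) != "beneficial":
        return False
    non_home = [
        classify_effect(s, se, k)
        for env, (s, se) in profile.values.items()
        if env != profile.home_environment
    ]
    non_home = [c for c in non_home if c != "missing"]
    if not non_home:
        return None
    return not any(c == "deleterious" for c in non_home)


def _pair_distance(
    a: Mapping[str, tuple[float, float | None]],
    b: Mapping[str, tuple[float, float | None]],
    min_shared: int = MIN_SHARED_ENVIRONMENTS,
) -> float | None:
    shared = [e for e in a if e in b]
    if len(shared) < min_shared:
        return None
    va = np.array([a[e][0] for e in shared])
    vb = np.array([b[e][0] for e in shared])
    return float(np.linalg.norm(va - vb))


@dataclass
class SimilarityTestResult:
    statistic: float  # mean within-gene distance - mean between-gene distance
    p_value: float
    n_permutations: int
    n_profiles: int
    n_genes: int


def profile_similarity_test(
    profiles: Sequence[FitnessProfile],
    n_permutations: int = 10_000,
    seed: int = 0,
    min_shared: int = MIN_SHARED_ENVIRONMENTS,
) -> SimilarityTestResult | None:
    """Do same-gene mutations have more similar profiles than different-gene ones?

    Statistic: mean within-gene pairwise Euclidean distance (over shared
    measured environments) minus mean between-gene distance; negative
    means within-gene profiles are closer.  Null distribution by
    permuting gene labels; one-sided p-value with +1 correction.
    Requires >= 2 genes with >= 2 profiles each; otherwise None.
    """
    labeled = [p for p in profiles if p.gene]
    gene_sizes = pd.Series([p.gene for p in labeled]).value_counts()
    if (gene_sizes >= 2).sum() < 2:
        return None
    n = len(labeled)
    dist = np.full((n, n), np.nan)
    for i, j in itertools.combinations(range(n), 2):
        d = _pair_distance(labeled[i].values, labeled[j].values, min_shared)
        if d is not None:
            dist[i, j] = dist[j, i] = d
    genes = np.array([p.gene for p in labeled])

    def statistic(labels: np.ndarray) -> float:
        same = labels[:, None] == labels[None, :]
        iu = np.triu_indices(n, 1)
        d = dist[iu]
        s = same[iu]
        ok = np.isfinite(d)
        within = d[ok & s]
        between = d[ok & ~s]
        if len(within) == 0 or len(between) == 0:
            return math.nan
        return float(within.mean() - between.mean())

    observed = statistic(genes)
    if not math.isfinite(observed):
        return None
    rng = np.random.default_rng(seed)
    hits = 0
    valid = 0
    for _ in range(n_permutations):
        perm = statistic(rng.permutation(genes))
        if math.isfinite(perm):
            valid += 1
            if perm <= observed:
                hits += 1
    p = (hits + 1) / (valid + 1)
    return SimilarityTestResult(
        statistic=observed,
        p_value=p,
        n_permutations=valid,
        n_profiles=n,
        n_genes=int(gene_sizes.size),
    )


def profiles_from_table(
    fitness: pd.DataFrame,
    home_map: Mapping[str, str],
    gene_map: Mapping[str, str] | None = None,
) -> list[FitnessProfile]:
    """Build profiles from a tidy fitness table.

    Expects columns ``lineage, environment, s_hat, se``; ``home_map`` and
    the optional ``gene_map`` key on the lineage label.
    """
    profiles = []
    for lineage, grp in fitness.groupby("lineage"):
        values = {
            r.environment: (float(r.s_hat), None if pd.isna(r.se) else float(r.se))
            for r in grp.itertuples()
        }
        profiles.append(
            FitnessProfile(
                lineage=str(lineage),
                home_environment=home_map.get(str(lineage), "unassigned"),
                values=values,
                gene=(gene_map or {}).get(str(lineage)),
            )
        )
    return profiles


def collapse_identical_mutations(
    fitness: pd.DataFrame, mutation_map: Mapping[str, str]
) -> pd.DataFrame:
    """Optional display aggregation: median fitness over lineages sharing a
    mutation, per environment."""
    df = fitness.copy()
    df["mutation"] = df["lineage"].map(mutation_map)
    df = df[df["mutation"].notna()]
    return (
        df.groupby(["mutation", "environment"], as_index=False)
        .agg(s_hat=("s_hat", "median"), se=("se", "median"), n_lineages=("lineage", "nunique"))
    )


def classification_report(
    profiles: Sequence[FitnessProfile], k: float = NOISE_SIGMAS
) -> pd.DataFrame:
    rows = []
    for p in profiles:
        home = p.values.get(p.home_environment)
        rows.append(
            {
                "lineage": p.lineage,
                "home_environment": p.home_environment,
                "gene": p.gene,
                "home_class": classify_effect(*home, k) if home else "missing",
                "pleiotropy_present": pleiotropy_present(p, k),
                "cost_free": cost_free(p, k),
            }
        )
    return pd.DataFrame(rows)
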