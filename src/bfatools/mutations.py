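"""Adaptive-mutation curation and spectrum tabulation.

Consumes variant tables produced by external callers (VCF or VCF-like
TSV), applies the downstream filtering rules (mitochondrial, FLO1/FLO9,
clone coverage, condition-level background fraction, quality, ref:alt
contamination flag), identifies adaptive genes by recurrence and
home-fitness, and tabulates mutational spectra per (home environment,
ploidy, gene).  A packaged fixture transcribes the curated adaptive
mutation lists for the three focal conditions (clotrimazole CLM,
fluconazole FLC4, glycerol/ethanol GlyEtOH) at both ploidies.

Mutation-string dialect: ``X123Y`` missense, ``X123*`` nonsense,
``..._fs`` frameshift (coding in/del), multi-residue strings in-frame
indels (coding in/del), ``<pos><REF>><ALT>`` non-coding, ``+/`` prefix a
heterozygous diploid call, comma-joined missense pairs a double mutant.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

EFFECT_CLASSES = ("missense", "nonsense", "coding_indel", "non_coding")

MITO_NAMES = {"chrm", "chrmito", "mito", "mt", "chrmt"}
BLOCKED_GENES = {"FLO1", "FLO9"}
BACKGROUND_THRESHOLD = 0.12  # strict >
QUALITY_MIN = 150.0
COVERAGE_MIN = {"1N": 10.0, "2N": 15.0}
REFALT_RATIO_FLAG = 3.0

_NONCODING = re.compile(r"\d+[ACGT]+>[ACGT]+")
_MISSENSE = re.compile(r"[A-Z]\d+[A-Z]")
_INFRAME = re.compile(r"[A-Z]+\d+[A-Z]+")


@dataclass(frozen=True)
class MutationFixtureEntry:
    home_environment: str
    ploidy: str
    gene: str
    mutation: str
    heterozygous: bool
    effect_class: str


def classify_mutation(mutation: str) -> str:
    """Effect class of a printed mutation string (see module docstring)."""
    s = mutation.strip()
    if s.startswith("+/"):
        s = s[2:]
    if _NONCODING.fullmatch(s):
        return "non_coding"
    if "*" in s:
        return "nonsense"
    if s.endswith("_fs"):
        return "coding_indel"
    if "," in s:
        parts = [p.strip() for p in s.split(",")]
        if all(_MISSENSE.fullmatch(p) for p in parts):
            return "missense"
        raise ValueError(f"unclassifiable compound mutation string: {mutation!r}")
    if _MISSENSE.fullmatch(s):
        return "missense"
    if _INFRAME.fullmatch(s):
        return "coding_indel"
    raise ValueError(f"unclassifiable mutation string: {mutation!r}")


def load_adaptive_mutation_fixture() -> pd.DataFrame:
    """The packaged curated adaptive-mutation list (one row per mutation)."""
    with resources.files("bfatools.data").joinpath("table2_mutations.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t")
    df["heterozygous"] = df["mutation"].str.startswith("+/")
    df["effect_class"] = df["mutation"].map(classify_mutation)
    return df


def tabulate_spectrum(entries: pd.DataFrame) -> pd.DataFrame:
    """Counts of distinct mutations per (home environment, ploidy, gene).

    Input needs columns ``home_environment, ploidy, gene, mutation`` and
    optionally ``effect_class`` (derived from the string otherwise).
    Output columns: total, missense, nonsense, coding_indel, non_coding;
    class counts sum to the total by construction.
    """
    if entries.empty:
        return pd.DataFrame(
            columns=["home_environment", "ploidy", "gene", "total", *EFFECT_CLASSES]
        )
    df = entries.drop_duplicates(["home_environment", "ploidy", "gene", "mutation"]).copy()
    if "effect_class" not in df.columns:
        df["effect_class"] = df["mutation"].map(classify_mutation)
    bad = ~df["effect_class"].isin(EFFECT_CLASSES)
    if bad.any():
        raise ValueError(f"unknown effect classes: {sorted(df.loc[bad, 'effect_class'])}")
    pivot = (
        df.pivot_table(
            index=["home_environment", "ploidy", "gene"],
            columns="effect_class",
            values="mutation",
            aggfunc="nunique",
            fill_value=0,
        )
        .reindex(columns=list(EFFECT_CLASSES), fill_value=0)
        .reset_index()
    )
    pivot.columns.name = None
    pivot["total"] = pivot[list(EFFECT_CLASSES)].sum(axis=1)
    return pivot[["home_environment", "ploidy", "gene", "total", *EFFECT_CLASSES]]


def ploidy_overlap(spectrum: pd.DataFrame) -> dict[str, dict[str, set[str]]]:
    """Per environment: gene sets mutated in haploids only, diploids only, both."""
    out: dict[str, dict[str, set[str]]] = {}
    for env, grp in spectrum.groupby("home_environment"):
        hap = set(grp.loc[grp["ploidy"] == "1N", "gene"])
        dip = set(grp.loc[grp["ploidy"] == "2N", "gene"])
        out[env] = {
            "haploid_only": hap - dip,
            "diploid_only": dip - hap,
            "shared": hap & dip,
        }
    return out


@dataclass
class CurationOverrides:
    """Manual curation encoded as explicit per-variant decisions.

    ``keep`` whitelists variant keys past the quality filter; ``drop``
    removes variants that automated rules would keep.  Keys are
    ``(chrom, pos, ref, alt)`` tuples.
    """

    keep: set[tuple] = None
    drop: set[tuple] = None

    def __post_init__(self) -> None:
        self.keep = set(self.keep or ())
        self.drop = set(self.drop or ())

    @classmethod
    def from_mapping(cls, raw: Mapping) -> "CurationOverrides":
        unknown = set(raw) - {"keep", "drop"}
        if unknown:
            raise ValueError(f"unknown override keys: {sorted(unknown)}")
        return cls(
            keep={tuple(k) for k in raw.get("keep", [])},
            drop={tuple(k) for k in raw.get("drop", [])},
        )


def filter_variants(
    records: pd.DataFrame,
    background_threshold: float = BACKGROUND_THRESHOLD,
    quality_min: float = QUALITY_MIN,
    coverage_min: Mapping[str, float] = COVERAGE_MIN,
    ratio_flag: float = REFALT_RATIO_FLAG,
    overrides: CurationOverrides | Mapping | None = None,
) -> pd.DataFrame:
    """Apply the downstream variant filters; order-independent.

    Expects columns ``clone, condition, ploidy, chrom, pos, ref, alt,
    gene, effect_class, zygosity, quality, clone_coverage, ref_depth,
    alt_depth``.  Returns kept records with a boolean
    ``suspected_contamination`` flag (heterozygous ref:alt > 3:1 is
    flagged, not dropped).
    """
    if overrides is None:
        overrides = CurationOverrides()
    elif isinstance(overrides, Mapping):
        overrides = CurationOverrides.from_mapping(overrides)
    df = records.copy()
    key = list(zip(df["chrom"], df["pos"], df["ref"], df["alt"]))
    df["_key"] = key

    df = df[~df["chrom"].str.lower().isin(MITO_NAMES)]
    df = df[~df["gene"].isin(BLOCKED_GENES)]
    cov_floor = df["ploidy"].map(lambda p: coverage_min[p])
    df = df[df["clone_coverage"] >= cov_floor]

    # background: variant present in > threshold of the clones from the
    # same evolutionary condition
    keep_rows = []
    for cond, grp in df.groupby("condition"):
        n_clones = grp["clone"].nunique()
        carriers = grp.groupby("_key")["clone"].nunique()
        background = set(carriers[carriers / n_clones > background_threshold].index)
        keep_rows.append(grp[~grp["_key"].isin(background)])
    df = pd.concat(keep_rows) if keep_rows else df.iloc[0:0]

    low_q = df["quality"] < quality_min
    whitelisted = df["_key"].isin(overrides.keep)
    df = df[~low_q | whitelisted]
    df = df[~df["_key"].isin(overrides.drop)]

    het = df["zygosity"].astype(str).str.lower().eq("het")
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = df["ref_depth"] / df["alt_depth"].replace(0, np.nan)
    df = df.copy()
    df["suspected_contamination"] = het & (ratio > ratio_flag)
    return df.drop(columns="_key").sort_values(
        ["condition", "clone", "chrom", "pos"], kind="stable"
    ).reset_index(drop=True)


def identify_adaptive_genes(
    variants: pd.DataFrame,
    home_fitness: Mapping[str, float],
    pathway_allowlist: Iterable[str] = (),
) -> tuple[dict[str, set[str]], pd.DataFrame, list[str]]:
    """Recurrently mutated, home-beneficial, coding-hit genes per condition.

    A gene is adaptive in a condition iff it carries distinct mutations in
    more than one clone lineage, the median home-environment fitness of
    the carrier lineages is > 0, and at least one mutation is coding.
    ``home_fitness`` maps clone id to its home-condition fitness;
    ``pathway_allowlist`` admits additional manually curated genes.
    Returns (adaptive genes per condition, per-lineage candidate mutation
    table, deferred genes lacking any fitness data).
    """
    allow = set(pathway_allowlist)
    adaptive: dict[str, set[str]] = {}
    deferred: list[str] = []
    candidates = []
    for cond, grp in variants.groupby("condition"):
        genes: set[str] = set()
        for gene, g in grp.groupby("gene"):
            n_lineages = g["clone"].nunique()
            n_distinct = g.drop_duplicates(["chrom", "pos", "ref", "alt"]).shape[0]
            if gene in allow:
                genes.add(gene)
                continue
            if n_lineages < 2 or n_distinct < 2:
                continue
            if not (g["effect_class"] != "non_coding").any():
                continue
            fits = [home_fitness[c] for c in g["clone"].unique() if c in home_fitness]
            if not fits:
                deferred.append(f"{cond}:{gene}")
                continue
            if np.median(fits) > 0:
                genes.add(gene)
        adaptive[cond] = genes
        cand = grp[grp["gene"].isin(genes)]
        candidates.append(cand)
    table = (
        pd.concat(candidates, ignore_index=True)
        if candidates
        else variants.iloc[0:0].copy()
    )
    return adaptive, table, deferred


def match_clone_barcodes(
    clone_reads: Mapping[str, Mapping[str, int]],
    known_barcodes: Iterable[str],
    min_reads: int = 2,
    min_fold: float = 3.0,
) -> dict[str, str | None]:
    """Assign each clone a known barcode from its WGS barcode reads.

    Extracted barcodes error-correct to a known barcode when their
    deletion sets share any element (a single sequencing error).  A clone
    is assigned the top known barcode iff it has at least ``min_reads``
    supporting reads and at least ``min_fold`` times the runner-up's
    reads; otherwise None.
    """
    from .clustering import deletion_set

    known = list(dict.fromkeys(known_barcodes))
    index: dict[str, str] = {}
    for kb in known:
        for d in deletion_set(kb):
            index.setdefault(d, kb)
    out: dict[str, str | None] = {}
    for clone, reads in clone_reads.items():
        support: dict[str, int] = {}
        for seq, n in reads.items():
            target = None
            if seq in known:
                target = seq
            else:
                for d in deletion_set(seq):
                    if d in index:
                        target = index[d]
                        break
            if target is not None:
                support[target] = support.get(target, 0) + int(n)
        if not support:
            out[clone] = None
            continue
        ranked = sorted(support.items(), key=lambda kv: (-kv[1], kv[0]))
        top_bc, top_n = ranked[0]
        runner = ranked[1][1] if len(ranked) > 1 else 0
        if top_n >= min_reads and top_n >= min_fold * runner:
            out[clone] = top_bc
        else:
            out[clone] = None
    return out


def read_variant_table(path: str | Path) -> pd.DataFrame:
    """Read a VCF or VCF-like TSV into the variant-record schema.

    TSV input must already carry the schema columns.  VCF input (``.vcf``)
    is parsed minimally: CHROM/POS/REF/ALT/QUAL plus ``GENE``, ``EFFECT``,
    ``CLONE``, ``CONDITION``, ``PLOIDY``, ``COVERAGE``, ``ZYG``, ``AD``
    INFO keys when present.
    """
    path = Path(path)
    if path.suffix.lower() != ".vcf":
        return pd.read_csv(path, sep="\t")
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            chrom, pos, _id, ref, alt, qual = f[0], int(f[1]), f[2], f[3], f[4], f[5]
            info = dict(
                kv.split("=", 1) for kv in f[7].split(";") if "=" in kv
            )
            ad = info.get("AD", "0,0").split(",")
            rows.append(
                {
                    "clone": info.get("CLONE", "unknown"),
                    "condition": info.get("CONDITION", "unknown"),
                    "ploidy": info.get("PLOIDY", "1N"),
                    "chrom": chrom,
                    "pos": pos,
                    "ref": ref,
                    "alt": alt,
                    "gene": info.get("GENE", ""),
                    "effect_class": info.get("EFFECT", "missense"),
                    "zygosity": info.get("ZYG", "hom"),
                    "quality": float(qual) if qual != "." else 0.0,
                    "clone_coverage": float(info.get("COVERAGE", 0)),
                    "ref_depth": int(ad[0]),
                    "alt_depth": int(ad[1]) if len(ad) > 1 else 0,
                }
            )
    return pd.DataFrame(rows)


def overlap_to_json(overlap: dict, path: str | Path) -> None:
    serializable = {
        env: {k: sorted(v) for k, v in parts.items()} for env, parts in overlap.items()
    }
    Path(path).write_text(json.dumps(serializable, indent=2))
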