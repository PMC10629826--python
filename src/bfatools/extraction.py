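"""Paired-read barcode extraction.

Turns paired FASTQ amplicon reads into UMI-deduplicated barcode
observations: inline-index demultiplexing, fuzzy-flank regex extraction,
a mean-quality filter over the barcode region, and per-library UMI
deduplication.  The flank pattern tolerates one substitution (or a
single-base slip) on either side of a 24–28 base barcode.
"""

from __future__ import annotations

import gzip
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .simulate import UMI_LENGTH

# One-error-tolerant flank search around a 24-28 base barcode (group 2).
BARCODE_PATTERN = re.compile(
    r"\D*?"
    r"(GTACC|GGACC|GGTCC|G.TACC|GG.ACC|GGT.CC|GGTA.C|GGTAC.)"
    r"(\D{24,28})"
    r"(.TAACT|A.AACT|AT.ACT|ATA.CT|ATAA.T|ATAAC|AAACT|ATACT|ATAAT)"
    r"\D*"
)

DEFAULT_LIBRARY = "library"
UNASSIGNED = "unassigned"
QUALITY_MIN_MEAN = 30.0


@dataclass
class ReadPair:
    """A paired-end read; quality strings are Phred+33 by default."""

    id: str
    seq1: str
    qual1: str
    seq2: str
    qual2: str

    def __post_init__(self) -> None:
        if len(self.seq1) != len(self.qual1) or len(self.seq2) != len(self.qual2):
            raise ValueError(f"sequence/quality length mismatch in read {self.id}")


@dataclass
class BarcodeObservation:
    """One UMI-tagged molecule: 16-base UMI plus the two captured barcodes."""

    umi: str
    env_bc: str | None
    lineage_bc: str | None
    library: str = DEFAULT_LIBRARY


@dataclass
class ExtractionQC:
    reads_in: int = 0
    matched: int = 0
    no_match: int = 0
    quality_failed: int = 0
    umi_duplicates: int = 0
    per_library: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2))


def read_fastq_pairs(r1_path: str | Path, r2_path: str | Path) -> Iterator[ReadPair]:
    """Stream paired reads from two (optionally gzipped) FASTQ files."""

    def _open(p):
        p = str(p)
        return gzip.open(p, "rt") if p.endswith(".gz") else open(p)

    with _open(r1_path) as f1, _open(r2_path) as f2:
        for (id1, s1, q1), (_id2, s2, q2) in zip(
            FastqGeneralIterator(f1), FastqGeneralIterator(f2)
        ):
            yield ReadPair(id1.split()[0], s1, q1, s2, q2)


def extract_barcode(sequence: str) -> str | None:
    """Leftmost barcode capture from the region after UMI/index, or None."""
    m = BARCODE_PATTERN.search(sequence)
    return m.group(2) if m else None


def extract_barcode_span(sequence: str) -> tuple[str, int, int] | None:
    m = BARCODE_PATTERN.search(sequence)
    return (m.group(2), m.start(2), m.end(2)) if m else None


def demultiplex(
    reads: Iterable[ReadPair], index_table: dict[str, str] | None
) -> Iterator[tuple[ReadPair, str]]:
    """Assign each read pair to a library by its inline index.

    The index sits immediately after the 8-base UMI on both mates; read 1's
    index decides.  An empty/None table sends everything to one default
    library; reads matching no index go to the "unassigned" sink.  The
    table is a mapping index -> library, or (index, library) pairs, with
    duplicate index sequences rejected as ambiguous.
    """
    if index_table is not None and not isinstance(index_table, dict):
        pairs = list(index_table)
        seqs = [s for s, _ in pairs]
        if len(set(seqs)) != len(seqs):
            raise ValueError("ambiguous index table: duplicate index sequences")
        index_table = dict(pairs)
    if index_table:
        seqs = list(index_table)
        lengths = {len(s) for s in seqs}
        if len(lengths) != 1:
            raise ValueError("index sequences must share one length")
        (index_len,) = lengths
        for pair in reads:
            idx = pair.seq1[UMI_LENGTH : UMI_LENGTH + index_len]
            yield pair, index_table.get(idx, UNASSIGNED)
    else:
        for pair in reads:
            yield pair, DEFAULT_LIBRARY


def mean_quality(qual: str, offset: int = 33) -> float:
    if not qual:
        return 0.0
    return sum(ord(c) - offset for c in qual) / len(qual)


def quality_filter(
    pair: ReadPair,
    span1: tuple[int, int] | None,
    span2: tuple[int, int] | None,
    min_mean: float = QUALITY_MIN_MEAN,
    offset: int = 33,
) -> bool:
    """Keep iff the mean Phred over the barcode regions is >= ``min_mean``.

    Falls back to the whole mate when its barcode span is unknown.  The
    boundary reading of the discard rule ("less than 30") keeps a mean of
    exactly 30.0.
    """
    q1 = pair.qual1[span1[0] : span1[1]] if span1 else pair.qual1
    q2 = pair.qual2[span2[0] : span2[1]] if span2 else pair.qual2
    qual = q1 + q2
    return mean_quality(qual, offset) >= min_mean


def dedup_umis(observations: Iterable[BarcodeObservation]) -> list[BarcodeObservation]:
    """Within each library keep the first observation per UMI."""
    seen: set[tuple[str, str]] = set()
    kept = []
    for obs in observations:
        key = (obs.library, obs.umi)
        if key in seen:
            continue
        seen.add(key)
        kept.append(obs)
    return kept


def process_read_pairs(
    reads: Iterable[ReadPair],
    index_table: dict[str, str] | None = None,
    lineage_on_read1: bool = True,
    min_mean_quality: float = QUALITY_MIN_MEAN,
    phred_offset: int = 33,
    drop_unassigned: bool = True,
) -> tuple[list[BarcodeObservation], ExtractionQC]:
    """Full extraction: demultiplex, extract, quality-filter, UMI-dedup.

    Reads failing extraction on either mate are tallied as no-match; the
    quality filter runs after extraction so it can use the barcode span.
    """
    qc = ExtractionQC()
    index_len = 0
    if index_table:
        index_len = len(next(iter(index_table)))
    raw: list[BarcodeObservation] = []
    for pair, library in demultiplex(reads, index_table):
        qc.reads_in += 1
        if drop_unassigned and index_table and library == UNASSIGNED:
            continue
        skip = UMI_LENGTH + index_len
        body1 = pair.seq1[skip:]
        body2 = pair.seq2[skip:]
        hit1 = extract_barcode_span(body1)
        hit2 = extract_barcode_span(body2)
        if hit1 is None or hit2 is None:
            qc.no_match += 1
            continue
        bc1, a1, b1 = hit1
        bc2, a2, b2 = hit2
        if not quality_filter(
            pair,
            (skip + a1, skip + b1),
            (skip + a2, skip + b2),
            min_mean_quality,
            phred_offset,
        ):
            qc.quality_failed += 1
            continue
        qc.matched += 1
        umi = pair.seq1[:UMI_LENGTH] + pair.seq2[:UMI_LENGTH]
        lineage_bc, env_bc = (bc1, bc2) if lineage_on_read1 else (bc2, bc1)
        raw.append(BarcodeObservation(umi, env_bc, lineage_bc, library))
    kept = dedup_umis(raw)
    qc.umi_duplicates = len(raw) - len(kept)
    for obs in kept:
        qc.per_library[obs.library] = qc.per_library.get(obs.library, 0) + 1
    return kept, qc


def observations_to_counts(observations: Iterable[BarcodeObservation]) -> pd.DataFrame:
    """Aggregate observations into a (library, env_bc, lineage_bc) count table."""
    df = pd.DataFrame(
        [(o.library, o.env_bc, o.lineage_bc) for o in observations],
        columns=["library", "env_bc", "lineage_bc"],
    )
    if df.empty:
        return pd.DataFrame(columns=["library", "env_bc", "lineage_bc", "count"])
    return (
        df.groupby(["library", "env_bc", "lineage_bc"], sort=True)
        .size()
        .rename("count")
        .reset_index()
    )


def parse_library_label(label: str) -> tuple[int, int, int]:
    """Invert the simulator's ``t{tp}_r{rep}_l{lane}`` library labels."""
    m = re.fullmatch(r"t(\d+)_r(\d+)_l(\d+)", label)
    if not m:
        raise ValueError(f"not a simulator library label: {label!r}")
    return int(m.group(1)), int(m.group(2)), int(m.group(3))
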