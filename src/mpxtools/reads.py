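"""Read processing: FASTQ -> deduplicated, error-corrected edge list.

Reads are anchored positionally on the BS1/BS2 binding-site motifs
(rejected above 10% mismatch per motif), demultiplexed on the protein
barcode (<=1 mismatch, safe because panel barcodes are pairwise
Hamming distance >= 3), collapsed on the (UMI, UPI-A) key that defines
a unique AOC molecule, and error-corrected by directional clustering
of near-identical keys (merge b into a when Hamming(a,b) <= max_dist
and reads(a) >= 2*reads(b) - 1, representative = most frequent).
"""

from __future__ import annotations

import json
from collections import Counter, defaultdict
from dataclasses import dataclass, field, asdict
from typing import Iterable, Iterator, NamedTuple

import numpy as np
import pandas as pd

from .panel import PanelConfig, hamming

EDGE_COLUMNS = ["upia", "upib", "marker", "umi", "reads"]


class FastqRead(NamedTuple):
    name: str
    sequence: str
    quality: str


@dataclass(frozen=True)
class ParsedMolecule:
    umi: str
    marker: str
    upia: str
    upib: str


@dataclass(frozen=True)
class Rejection:
    reason: str  # length | quality | motif | barcode


@dataclass
class EdgeRecord:
    upia: str
    upib: str
    marker: str
    umi: str
    reads: int = 1


@dataclass
class QCReport:
    total_reads: int = 0
    rejected_length: int = 0
    rejected_quality: int = 0
    rejected_motif: int = 0
    rejected_barcode: int = 0
    unique_molecules: int = 0
    reads_per_molecule_mean: float = 0.0
    reads_per_molecule_max: int = 0

    @property
    def accepted_reads(self) -> int:
        return (self.total_reads - self.rejected_length - self.rejected_quality
                - self.rejected_motif - self.rejected_barcode)

    def count(self, outcome: ParsedMolecule | Rejection) -> None:
        self.total_reads += 1
        if isinstance(outcome, Rejection):
            setattr(self, f"rejected_{outcome.reason}",
                    getattr(self, f"rejected_{outcome.reason}") + 1)

    def summarize(self, records: list[EdgeRecord]) -> None:
        self.unique_molecules = len(records)
        if records:
            reads = [r.reads for r in records]
            self.reads_per_molecule_mean = float(np.mean(reads))
            self.reads_per_molecule_max = int(max(reads))

    def to_json(self, path) -> None:
        doc = asdict(self)
        doc["accepted_reads"] = self.accepted_reads
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=2)


def parse_read(
    read: FastqRead,
    panel: PanelConfig,
    bs_max_mismatch_frac: float = 0.10,
    barcode_max_mismatch: int = 1,
    min_mean_quality: float = 20.0,
) -> ParsedMolecule | Rejection:
    """Parse one amplicon read against the panel layout.

    BS1 and BS2 are checked independently at their expected offsets;
    a mismatch fraction strictly above ``bs_max_mismatch_frac`` in
    either rejects the read.
    """
    seq = read.sequence
    if len(seq) < panel.read_length:
        return Rejection("length")
    if read.quality and min_mean_quality > 0:
        mean_q = np.frombuffer(read.quality.encode(), dtype=np.uint8).mean() - 33.0
        if mean_q < min_mean_quality:
            return Rejection("quality")
    slices = panel.field_slices()
    for motif, expected in (("bs1", panel.bs1), ("bs2", panel.bs2)):
        observed = seq[slices[motif]]
        if hamming(observed, expected) / len(expected) > bs_max_mismatch_frac:
            return Rejection("motif")
    marker = panel.marker_for_barcode(seq[slices["barcode"]],
                                      max_mismatch=barcode_max_mismatch)
    if marker is None:
        return Rejection("barcode")
    return ParsedMolecule(
        umi=seq[slices["umi"]],
        marker=marker,
        upia=seq[slices["upia"]],
        upib=seq[slices["upib"]],
    )


def read_fastq(path) -> Iterator[FastqRead]:
    """Iterate a FASTQ file (plain or gzip) as FastqRead tuples."""
    import pysam

    with pysam.FastxFile(str(path)) as fh:
        for entry in fh:
            yield FastqRead(entry.name, entry.sequence, entry.quality or "")


def collapse_molecules(parsed: Iterable[ParsedMolecule]) -> list[EdgeRecord]:
    """Collapse PCR duplicates on the (UMI, UPI-A) molecule key.

    Within a group the representative marker and UPI-B are each the
    most frequent value, ties broken lexicographically.
    """
    groups: dict[tuple[str, str], list[ParsedMolecule]] = defaultdict(list)
    for p in parsed:
        groups[(p.umi, p.upia)].append(p)
    out = []
    for (umi, upia), members in groups.items():
        marker = _majority(Counter(m.marker for m in members))
        upib = _majority(Counter(m.upib for m in members))
        out.append(EdgeRecord(upia=upia, upib=upib, marker=marker,
                              umi=umi, reads=len(members)))
    out.sort(key=lambda r: (r.upia, r.umi))
    return out


def _majority(counts: Counter) -> str:
    return min(counts, key=lambda k: (-counts[k], k))


# ---------------------------------------------------------------------------
# directional error correction


class _NeighborIndex:
    """Pigeonhole Hamming index: split keys into max_dist+1 chunks; two
    keys within max_dist share at least one exact chunk."""

    def __init__(self, length: int, max_dist: int):
        n_chunks = max_dist + 1
        bounds = np.linspace(0, length, n_chunks + 1).astype(int)
        self.slices = [slice(bounds[i], bounds[i + 1]) for i in range(n_chunks)]
        self.buckets: list[dict[str, list[str]]] = [
            defaultdict(list) for _ in self.slices
        ]

    def add(self, key: str) -> None:
        for sl, bucket in zip(self.slices, self.buckets):
            bucket[key[sl]].append(key)

    def candidates(self, key: str) -> set[str]:
        out: set[str] = set()
        for sl, bucket in zip(self.slices, self.buckets):
            out.update(bucket.get(key[sl], ()))
        return out


def directional_cluster(
    counts: dict[str, int], max_dist: int
) -> dict[str, str]:
    """Cluster keys by iterated greedy directional merging.

    Returns a mapping key -> representative. Passes repeat until a
    fixed point, which makes the overall correction idempotent.
    """
    if max_dist < 0:
        raise ValueError("max_dist must be >= 0")
    assignment = {k: k for k in counts}
    if max_dist == 0 or len(counts) < 2:
        return assignment
    current = dict(counts)
    length = len(next(iter(counts)))
    while True:
        merged_any = False
        order = sorted(current, key=lambda k: (-current[k], k))
        index = _NeighborIndex(length, max_dist)
        reps: dict[str, int] = {}
        parent: dict[str, str] = {}
        for key in order:
            cnt = current[key]
            best = None
            for cand in index.candidates(key):
                if reps[cand] >= 2 * cnt - 1 and hamming(cand, key) <= max_dist:
                    if best is None or (reps[cand], _neg(cand)) > (reps[best], _neg(best)):
                        best = cand
            if best is not None:
                reps[best] += cnt
                parent[key] = best
                merged_any = True
            else:
                reps[key] = cnt
                parent[key] = key
                index.add(key)
        assignment = {k: parent[assignment[k]] for k in assignment}
        current = reps
        if not merged_any:
            return assignment


class _neg:
    """Reverses lexicographic comparison so max() prefers smaller keys."""

    __slots__ = ("s",)

    def __init__(self, s: str):
        self.s = s

    def __gt__(self, other) -> bool:
        return self.s < other.s


def correct_sequences(
    records: list[EdgeRecord], max_dist: int = 2
) -> list[EdgeRecord]:
    """Error-correct collapsed molecules by clustering UMI·UPI-A keys.

    Keys within ``max_dist`` merge directionally into the most frequent
    key; merged records sum their reads and inherit the representative
    UMI/UPI-A. UPI-B variants inside each merged cluster are corrected
    by the same directional rule before a weighted majority vote.
    """
    if max_dist < 0:
        raise ValueError("max_dist must be >= 0")
    if not records:
        return []
    key_of = {}
    counts: dict[str, int] = defaultdict(int)
    for r in records:
        k = r.umi + r.upia
        key_of[id(r)] = k
        counts[k] += r.reads
    assignment = directional_cluster(dict(counts), max_dist)

    clusters: dict[str, list[EdgeRecord]] = defaultdict(list)
    for r in records:
        clusters[assignment[key_of[id(r)]]].append(r)

    umi_len = len(records[0].umi)
    out = []
    for rep_key, members in clusters.items():
        total = sum(m.reads for m in members)
        marker = _majority_weighted([(m.marker, m.reads) for m in members])
        upib_counts: dict[str, int] = defaultdict(int)
        for m in members:
            upib_counts[m.upib] += m.reads
        if len(upib_counts) > 1:
            sub = directional_cluster(dict(upib_counts), max_dist)
            corrected: dict[str, int] = defaultdict(int)
            for upib, c in upib_counts.items():
                corrected[sub[upib]] += c
            upib_counts = corrected
        upib = _majority_weighted(list(upib_counts.items()))
        out.append(EdgeRecord(
            upia=rep_key[umi_len:], upib=upib, marker=marker,
            umi=rep_key[:umi_len], reads=total,
        ))
    out.sort(key=lambda r: (r.upia, r.umi))
    return out


def _majority_weighted(pairs: list[tuple[str, int]]) -> str:
    agg: dict[str, int] = defaultdict(int)
    for value, weight in pairs:
        agg[value] += weight
    return min(agg, key=lambda k: (-agg[k], k))


# ---------------------------------------------------------------------------
# convenience wrappers


def process_fastq(
    path,
    panel: PanelConfig,
    max_dist: int = 2,
    bs_max_mismatch_frac: float = 0.10,
    barcode_max_mismatch: int = 1,
    min_mean_quality: float = 20.0,
) -> tuple[pd.DataFrame, QCReport]:
    """FASTQ -> (edge list DataFrame, QC report)."""
    qc = QCReport()
    parsed = []
    for read in read_fastq(path):
        outcome = parse_read(
            read, panel,
            bs_max_mismatch_frac=bs_max_mismatch_frac,
            barcode_max_mismatch=barcode_max_mismatch,
            min_mean_quality=min_mean_quality,
        )
        qc.count(outcome)
        if isinstance(outcome, ParsedMolecule):
            parsed.append(outcome)
    records = correct_sequences(collapse_molecules(parsed), max_dist=max_dist)
    qc.summarize(records)
    return records_to_frame(records), qc


def records_to_frame(records: list[EdgeRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.upia, r.upib, r.marker, r.umi, r.reads) for r in records],
        columns=EDGE_COLUMNS,
    )


def frame_to_records(df: pd.DataFrame) -> list[EdgeRecord]:
    return [EdgeRecord(*row) for row in
            df[EDGE_COLUMNS].itertuples(index=False, name=None)]
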