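"""From paired reads to a deduplicated gene x barcode UMI count matrix.

Stages: positional parsing of the 31 nt barcode+UMI mate, k-mer barcode
demultiplexing with a 2-mismatch budget, UMI template validation, exact-match
gene assignment against a toy transcriptome (or an imported read -> gene
table from an external aligner), read-level filtering (ribosomal, named
self-priming artefacts such as MALAT1, invalid UMIs, ambiguous genes), and
UMI collapse by single-linkage Hamming clustering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .array_model import (
    BarcodeWhitelist,
    MalformedReadError,
    UmiPattern,
    UNASSIGNED,
    build_kmer_index,
    encode_sequence,
    match_barcode,
)

AMBIGUOUS = "AMBIGUOUS"

BARCODE_SLICE = slice(0, 18)   # R1 positions 0..17, half-open 0-based
UMI_SLICE = slice(18, 27)      # R1 positions 18..26


def parse_read_pair(
    r1: str, r2: str, r1_length: int = 31, r2_length: int = 121
) -> tuple[str, str, str]:
    """Split a read pair into (barcode, UMI, transcript) by fixed offsets.

    R1 carries the 18 nt spot barcode then the 9 nt UMI; the remaining R1
    bases (oligo-dT) are ignored.  Short mates raise
    :class:`MalformedReadError` so callers can count and skip them.
    """
    if len(r1) < r1_length:
        raise MalformedReadError(f"R1 length {len(r1)} < {r1_length}")
    if len(r2) < r2_length:
        raise MalformedReadError(f"R2 length {len(r2)} < {r2_length}")
    return r1[BARCODE_SLICE], r1[UMI_SLICE], r2[:r2_length]


class ToyTranscriptome:
    """Exact-substring gene assigner over one transcript per gene.

    Stands in for a full spliced aligner in simulated data: a read maps to a
    gene iff it occurs verbatim in that gene's transcript.  Seed 25-mers at
    every offset narrow the candidates before full-length verification.
    """

    SEED_K = 25

    def __init__(self, transcripts: dict[str, str]):
        self.transcripts = dict(transcripts)
        self._seeds: dict[str, str] = {}
        for gene, seq in self.transcripts.items():
            for i in range(len(seq) - self.SEED_K + 1):
                kmer = seq[i : i + self.SEED_K]
                prev = self._seeds.get(kmer)
                if prev is None:
                    self._seeds[kmer] = gene
                elif prev != gene:
                    self._seeds[kmer] = AMBIGUOUS

    def assign(self, read: str) -> str:
        """gene_id, AMBIGUOUS (>= 2 genes contain the read) or UNASSIGNED."""
        if len(read) < self.SEED_K:
            return UNASSIGNED
        hit = self._seeds.get(read[: self.SEED_K])
        if hit is None:
            return UNASSIGNED
        if hit != AMBIGUOUS:
            return hit if read in self.transcripts[hit] else UNASSIGNED
        matches = [g for g, seq in self.transcripts.items() if read in seq]
        if not matches:
            return UNASSIGNED
        return matches[0] if len(matches) == 1 else AMBIGUOUS


def assign_gene(read: str, transcriptome: ToyTranscriptome) -> str:
    """Exact-match gene assignment; see :meth:`ToyTranscriptome.assign`."""
    return transcriptome.assign(read)


def demux_reads(
    read_pairs,
    whitelist: BarcodeWhitelist,
    transcriptome: ToyTranscriptome | None = None,
    gene_table: pd.DataFrame | None = None,
    pattern: UmiPattern | None = None,
    max_mismatches: int = 2,
    segment_length: int = 6,
    r1_length: int = 31,
    r2_length: int = 121,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Annotate an iterable of (read_id, r1, r2) tuples.

    Gene identity comes either from the toy transcriptome or from an imported
    ``gene_table`` (columns read_id, gene_id — e.g. parsed from an external
    alignment).  Returns the annotated-read table and a counter dict
    (total, malformed, barcode_unassigned).
    """
    if (transcriptome is None) == (gene_table is None):
        raise ValueError("provide exactly one of transcriptome or gene_table")
    pattern = pattern or UmiPattern()
    index = build_kmer_index(whitelist, segment_length)
    gene_of = (
        None if gene_table is None
        else dict(zip(gene_table["read_id"], gene_table["gene_id"]))
    )
    counters = {"total": 0, "malformed": 0, "barcode_unassigned": 0}
    rows = {k: [] for k in
            ("read_id", "barcode_id", "barcode_distance", "umi", "umi_valid",
             "gene_id")}
    for read_id, r1, r2 in read_pairs:
        counters["total"] += 1
        try:
            barcode_seq, umi, transcript = parse_read_pair(
                r1, r2, r1_length=r1_length, r2_length=r2_length
            )
        except MalformedReadError:
            counters["malformed"] += 1
            continue
        hit = match_barcode(barcode_seq, whitelist, index,
                            max_mismatches=max_mismatches,
                            segment_length=segment_length)
        if hit is None:
            counters["barcode_unassigned"] += 1
            barcode_id, distance = UNASSIGNED, -1
        else:
            barcode_id, distance = hit
        try:
            valid = pattern.is_valid(umi)
        except MalformedReadError:
            valid = False
        if gene_of is not None:
            gene = gene_of.get(read_id, UNASSIGNED)
        else:
            gene = transcriptome.assign(transcript)
        rows["read_id"].append(read_id)
        rows["barcode_id"].append(barcode_id)
        rows["barcode_distance"].append(distance)
        rows["umi"].append(umi)
        rows["umi_valid"].append(valid)
        rows["gene_id"].append(gene)
    return pd.DataFrame(rows), counters


def apply_read_filters(
    reads: pd.DataFrame,
    annotations: pd.DataFrame,
    remove_genes: set[str] | None = None,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Drop reads that must not enter counting; tally reasons.

    Removed: unassigned barcodes, unassigned/ambiguous genes, invalid UMIs,
    reads on ribosomal-flagged genes and reads on the named-removal list
    (default ``{"MALAT1"}``; matched against the gene id or its suffix after
    a species prefix, to cover self-priming artefacts like MALAT1).  A gene
    absent from the annotation table is a hard error.
    """
    if remove_genes is None:
        remove_genes = {"MALAT1"}
    known = set(annotations.index)
    assigned = set(reads["gene_id"]) - {UNASSIGNED, AMBIGUOUS}
    unknown = assigned - known
    if unknown:
        raise KeyError(f"genes missing from annotation table: {sorted(unknown)[:5]}")

    def named(gene: str) -> bool:
        return gene in remove_genes or gene.split("-", 1)[-1] in remove_genes

    report = {k: 0 for k in ("input", "barcode_unassigned", "gene_unassigned",
                             "ambiguous_gene", "invalid_umi", "ribosomal",
                             "named_removed", "retained")}
    report["input"] = len(reads)
    keep = pd.Series(True, index=reads.index)

    mask = reads["barcode_id"] == UNASSIGNED
    report["barcode_unassigned"] = int(mask.sum()); keep &= ~mask
    mask = (reads["gene_id"] == UNASSIGNED) & keep
    report["gene_unassigned"] = int(mask.sum()); keep &= ~mask
    mask = (reads["gene_id"] == AMBIGUOUS) & keep
    report["ambiguous_gene"] = int(mask.sum()); keep &= ~mask
    mask = ~reads["umi_valid"] & keep
    report["invalid_umi"] = int(mask.sum()); keep &= ~mask
    ribo = reads["gene_id"].map(
        lambda g: bool(annotations["is_ribosomal"].get(g, False))
    )
    mask = ribo & keep
    report["ribosomal"] = int(mask.sum()); keep &= ~mask
    mask = reads["gene_id"].map(named) & keep
    report["named_removed"] = int(mask.sum()); keep &= ~mask
    report["retained"] = int(keep.sum())
    return reads.loc[keep].reset_index(drop=True), report


def dedup_umis(umis, threshold: int = 1) -> int:
    """Molecules = connected components of UMIs linked at Hamming <= threshold.

    Exact duplicates always collapse; at threshold 0 the count is the number
    of distinct sequences.  Single-linkage components are the simplest
    reading of cluster-based duplicate removal.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    unique = sorted(set(umis))
    n = len(unique)
    if n <= 1 or threshold == 0:
        return n
    enc = np.stack([encode_sequence(u) for u in unique])
    diff = (enc[:, None, :] != enc[None, :, :]).sum(axis=2)
    adjacency = csr_matrix(diff <= threshold)
    n_components, _ = connected_components(adjacency, directed=False)
    return int(n_components)


@dataclass
class CountMatrix:
    """Genes x barcodes molecule counts with read-level sidecars.

    ``counts`` are UMI-collapsed molecules; ``read_counts`` the raw reads per
    (gene, barcode) before collapse; ``raw_reads`` per-barcode read totals.
    Axes are sorted and unique.
    """

    counts: pd.DataFrame
    read_counts: pd.DataFrame
    raw_reads: pd.Series
    gene_annotations: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        if (self.counts.to_numpy() > self.read_counts.to_numpy()).any():
            raise ValueError("molecule counts cannot exceed read counts")

    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    @property
    def barcodes(self) -> pd.Index:
        return self.counts.columns


def build_count_matrix(
    reads: pd.DataFrame,
    umi_threshold: int = 1,
    genes=None,
    barcodes=None,
    gene_annotations: pd.DataFrame | None = None,
) -> CountMatrix:
    """Collapse filtered annotated reads into a :class:`CountMatrix`.

    ``genes``/``barcodes`` optionally declare the full axes so that empty
    rows/columns are kept (needed for exact comparison against simulator
    truth).  Within each (gene, barcode) cell, molecules are counted as UMI
    Hamming clusters at ``umi_threshold``.
    """
    gene_axis = pd.Index(sorted(genes) if genes is not None
                         else sorted(set(reads["gene_id"])), name="gene_id")
    barcode_axis = pd.Index(sorted(barcodes) if barcodes is not None
                            else sorted(set(reads["barcode_id"])),
                            name="barcode_id")
    counts = pd.DataFrame(0, index=gene_axis, columns=barcode_axis, dtype=np.int64)
    read_counts = counts.copy()
    if len(reads):
        grouped = reads.groupby(["gene_id", "barcode_id"], sort=False)["umi"]
        for (gene, barcode), umis in grouped:
            read_counts.loc[gene, barcode] = len(umis)
            counts.loc[gene, barcode] = dedup_umis(list(umis), threshold=umi_threshold)
    raw_reads = read_counts.sum(axis=0)
    raw_reads.name = "raw_reads"
    return CountMatrix(counts=counts, read_counts=read_counts,
                       raw_reads=raw_reads, gene_annotations=gene_annotations)


def run_pipeline(
    read_pairs,
    whitelist: BarcodeWhitelist,
    transcriptome: ToyTranscriptome | None = None,
    gene_table: pd.DataFrame | None = None,
    annotations: pd.DataFrame | None = None,
    remove_genes: set[str] | None = None,
    umi_threshold: int = 1,
    max_mismatches: int = 2,
    genes=None,
    barcodes=None,
) -> tuple[CountMatrix, dict[str, int]]:
    """Full demultiplex -> filter -> count pipeline over an iterable of pairs."""
    annotated, counters = demux_reads(
        read_pairs, whitelist, transcriptome=transcriptome,
        gene_table=gene_table, max_mismatches=max_mismatches,
    )
    if annotations is None:
        raise ValueError("gene annotation table is required for filtering")
    filtered, report = apply_read_filters(annotated, annotations,
                                          remove_genes=remove_genes)
    report = {**counters, **report}
    cm = build_count_matrix(filtered, umi_threshold=umi_threshold,
                            genes=genes, barcodes=barcodes,
                            gene_annotations=annotations)
    return cm, report
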