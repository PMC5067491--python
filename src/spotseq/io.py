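"""On-disk formats: paired FASTQ (gzip), MatrixMarket count matrices with
genes/barcodes TSV sidecars, plain TSV tables and key-value config echoes."""

from __future__ import annotations

import gzip
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from scipy import sparse
from scipy.io import mmread, mmwrite

from .demux_count import CountMatrix

_CONST_QUALITY = 37  # constant emitted quality; realism is a non-goal


def write_fastq_pair(reads: pd.DataFrame, out_dir, prefix: str = "sim") -> tuple[Path, Path]:
    """Write a reads table (read_id, r1, r2) as <prefix>_R1/_R2.fastq.gz."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = (out_dir / f"{prefix}_R1.fastq.gz", out_dir / f"{prefix}_R2.fastq.gz")
    for path, col in zip(paths, ("r1", "r2")):
        records = (
            SeqRecord(
                Seq(seq), id=rid, description="",
                letter_annotations={"phred_quality": [_CONST_QUALITY] * len(seq)},
            )
            for rid, seq in zip(reads["read_id"], reads[col])
        )
        with gzip.open(path, "wt") as handle:
            SeqIO.write(records, handle, "fastq")
    return paths


def read_fastq_pair(r1_path, r2_path):
    """Iterate (read_id, r1_seq, r2_seq) from a gzip (or plain) FASTQ pair."""
    def _open(p):
        p = Path(p)
        return gzip.open(p, "rt") if p.suffix == ".gz" else open(p)

    with _open(r1_path) as h1, _open(r2_path) as h2:
        for rec1, rec2 in zip(SeqIO.parse(h1, "fastq"), SeqIO.parse(h2, "fastq")):
            if rec1.id != rec2.id:
                raise ValueError(f"unsynchronised mates: {rec1.id} vs {rec2.id}")
            yield rec1.id, str(rec1.seq), str(rec2.seq)


def write_count_matrix(cm: CountMatrix, out_dir) -> None:
    """MTX + genes.tsv + barcodes.tsv (+ annotations and read counts)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    mmwrite(out_dir / "matrix.mtx", sparse.csr_matrix(cm.counts.to_numpy()))
    mmwrite(out_dir / "read_counts.mtx", sparse.csr_matrix(cm.read_counts.to_numpy()))
    pd.Series(cm.genes, name="gene_id").to_csv(out_dir / "genes.tsv", sep="\t",
                                               index=False)
    pd.Series(cm.barcodes, name="barcode_id").to_csv(out_dir / "barcodes.tsv",
                                                     sep="\t", index=False)
    cm.raw_reads.to_csv(out_dir / "raw_reads.tsv", sep="\t")
    if cm.gene_annotations is not None:
        cm.gene_annotations.to_csv(out_dir / "gene_annotations.tsv", sep="\t")


def read_count_matrix(out_dir) -> CountMatrix:
    out_dir = Path(out_dir)
    genes = pd.read_csv(out_dir / "genes.tsv", sep="\t")["gene_id"]
    barcodes = pd.read_csv(out_dir / "barcodes.tsv", sep="\t")["barcode_id"]
    counts = pd.DataFrame(np.asarray(mmread(out_dir / "matrix.mtx").todense()),
                          index=pd.Index(genes, name="gene_id"),
                          columns=pd.Index(barcodes, name="barcode_id"),
                          dtype=np.int64)
    read_counts = pd.DataFrame(
        np.asarray(mmread(out_dir / "read_counts.mtx").todense()),
        index=counts.index, columns=counts.columns, dtype=np.int64,
    )
    raw = pd.read_csv(out_dir / "raw_reads.tsv", sep="\t", index_col=0)["raw_reads"]
    raw.index.name = "barcode_id"
    annot_path = out_dir / "gene_annotations.tsv"
    annotations = (pd.read_csv(annot_path, sep="\t", index_col=0)
                   if annot_path.exists() else None)
    return CountMatrix(counts=counts, read_counts=read_counts, raw_reads=raw,
                       gene_annotations=annotations)


def write_config_echo(config: dict, path) -> None:
    """Flat key<TAB>value echo of the parameters a run used."""
    with open(path, "w") as handle:
        for key, value in sorted(config.items()):
            handle.write(f"{key}\t{value}\n")


def read_table(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)


def write_table(df: pd.DataFrame, path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)
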