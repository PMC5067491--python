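"""Spot occupancy annotation and library-level quality control.

Links imaged cell centroids to array spots, classifies each spot's occupancy
group (background / single / doublet / cluster), and computes the standard
QC statistics: sequencing-saturation curves by read subsampling, dropout
rates between expression profiles, CV-versus-rank series, the background
top-N gene removal list, mean-read library filtering and the fraction of
reads landing on empty spots.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .array_model import ArrayLayout, ConfigurationError
from .demux_count import CountMatrix, dedup_umis
from .simulate import GROUP_BACKGROUND, occupancy_group


def colocalize(
    centroids: pd.DataFrame,
    layout: ArrayLayout,
    radius_um: float = 50.0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Assign each imaged cell to the spot whose centre lies within radius.

    ``centroids`` needs columns cell_id, x_um, y_um.  The radius must not
    exceed half the pitch, so a cell can match at most one spot.  Returns the
    per-spot annotation (spot_id, barcode_id, n_cells, group) covering every
    non-frame spot, and a cell -> spot_id Series (NaN when unassigned).
    """
    if radius_um > layout.pitch_um / 2:
        raise ConfigurationError("radius must be <= pitch/2 to keep assignment unique")
    spots = layout.barcode_spots
    tree = cKDTree(spots[["x_um", "y_um"]].to_numpy(dtype=float))
    dist, idx = tree.query(centroids[["x_um", "y_um"]].to_numpy(dtype=float))
    assigned = dist <= radius_um
    assignment = pd.Series(
        np.where(assigned, spots["spot_id"].to_numpy()[idx], None),
        index=centroids["cell_id"], name="spot_id", dtype=object,
    )
    counts = assignment.dropna().value_counts()
    n_cells = spots["spot_id"].map(counts).fillna(0).astype(int)
    annotation = pd.DataFrame(
        {
            "spot_id": spots["spot_id"],
            "barcode_id": spots["barcode_id"],
            "n_cells": n_cells,
            "group": [occupancy_group(n) for n in n_cells],
        }
    ).reset_index(drop=True)
    return annotation, assignment


def saturation_curve(
    reads: pd.DataFrame,
    depths,
    repeats: int = 10,
    seed: int | np.random.Generator = 0,
    umi_threshold: int = 1,
) -> pd.DataFrame:
    """Unique molecules and genes recovered at subsampled read depths.

    For each depth, reads (rows with barcode_id, gene_id, umi) are subsampled
    without replacement ``repeats`` times; UMI collapse is re-run on each
    subsample.  Depths beyond the available reads are truncated with a
    warning.  The returned series is monotone non-decreasing in depth in
    expectation and exactly equals the full-data value at maximal depth.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    total = len(reads)
    rows = []
    for depth in depths:
        if depth > total:
            warnings.warn(f"depth {depth} exceeds {total} reads; truncated")
            depth = total
        mols, genes = [], []
        n_rep = 1 if depth in (0, total) else repeats
        for _ in range(n_rep):
            if depth == 0:
                mols.append(0); genes.append(0)
                continue
            pick = rng.choice(total, size=depth, replace=False)
            sub = reads.iloc[pick]
            m = sum(
                dedup_umis(list(u), threshold=umi_threshold)
                for _, u in sub.groupby(["gene_id", "barcode_id"], sort=False)["umi"]
            )
            mols.append(m)
            genes.append(sub["gene_id"].nunique())
        rows.append(dict(depth=int(depth),
                         mean_unique_molecules=float(np.mean(mols)),
                         mean_unique_genes=float(np.mean(genes))))
    return pd.DataFrame(rows)


def dropout_rate(profile_a, profile_b) -> float:
    """Percentage of genes expressed in b but absent from a.

    ``DOR(a | b) = 100 * |expressed(b) \\ expressed(a)| / |expressed(b)|`` —
    asymmetric by construction; inputs are gene sets (expressed means a
    post-collapse count above zero).
    """
    a, b = set(profile_a), set(profile_b)
    if not b:
        raise ValueError("reference profile b expresses no genes; DOR undefined")
    return 100.0 * len(b - a) / len(b)


def cv_vs_rank(
    linear_matrix: pd.DataFrame, window: int = 25
) -> pd.DataFrame:
    """Per-gene CV against expression rank with a rolling-mean smoother.

    Genes are ranked by mean normalized (pre-log) expression, descending;
    CV = sd/mean per gene; zero-mean genes are excluded (CV undefined).
    """
    means = linear_matrix.mean(axis=1)
    keep = means > 0
    if int(keep.sum()) < window:
        raise ValueError("fewer nonzero-mean genes than the smoothing window")
    sub = linear_matrix.loc[keep]
    means = means[keep]
    cv = sub.std(axis=1, ddof=1) / means
    order = means.sort_values(ascending=False).index
    out = pd.DataFrame(
        {
            "gene_id": order,
            "rank": np.arange(1, len(order) + 1),
            "mean_expression": means.loc[order].to_numpy(),
            "cv": cv.loc[order].to_numpy(),
        }
    )
    out["mean_cv"] = out["cv"].rolling(window, min_periods=1).mean()
    return out


def background_gene_filter(
    cm: CountMatrix,
    background_barcodes,
    housekeeping,
    top_n: int = 50,
) -> list[str]:
    """Top-N most expressed genes in empty-spot libraries, minus housekeeping.

    These dominate ambient cell-free RNA and are removed from downstream
    analysis.  Genes are ranked by total background counts (ties broken by
    gene id for determinism).
    """
    background_barcodes = list(background_barcodes)
    if not background_barcodes:
        raise ValueError("no background barcodes supplied")
    totals = cm.counts[background_barcodes].sum(axis=1)
    hk = set(housekeeping)
    ranked = totals.sort_index().sort_values(ascending=False, kind="stable")
    picked = [g for g in ranked.index if g not in hk and ranked[g] > 0]
    return picked[:top_n]


def filter_libraries_by_mean(
    raw_reads: pd.Series, inclusive: bool = False
) -> list[str]:
    """Keep single-cell libraries with raw reads above the cohort mean.

    The threshold is the arithmetic mean over the supplied libraries; strict
    ``>`` by default (``inclusive`` switches to ``>=``).  With one library
    the strict rule keeps nothing — degenerate, so a warning is emitted.
    """
    if len(raw_reads) == 0:
        raise ValueError("no single-cell libraries supplied")
    if len(raw_reads) == 1:
        warnings.warn("single library: mean filter is degenerate")
    threshold = float(raw_reads.mean())
    mask = raw_reads >= threshold if inclusive else raw_reads > threshold
    return list(raw_reads.index[mask])


def background_read_fraction(
    cm: CountMatrix, spot_annotation: pd.DataFrame
) -> float:
    """Share of raw reads on background-group barcodes."""
    covered = set(spot_annotation["barcode_id"])
    missing = set(cm.barcodes) - covered
    if missing:
        raise ValueError(f"annotation missing barcodes: {sorted(missing)[:5]}")
    bg = spot_annotation.loc[
        spot_annotation["group"] == GROUP_BACKGROUND, "barcode_id"
    ]
    total = float(cm.raw_reads.sum())
    if total == 0:
        return 0.0
    return float(cm.raw_reads[cm.raw_reads.index.isin(bg)].sum()) / total
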