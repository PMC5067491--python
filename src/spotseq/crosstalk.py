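"""Barcode crosstalk from a two-species (barnyard) mixing experiment.

When cells of two species are mixed on one array, any read whose gene
belongs to the *other* species than the imaged cell under the barcode must
have been misassigned (barcode swapping, ambient RNA or decoding error).
Orthologous genes cannot distinguish species and are excluded; the
species-specific remainder yields per-barcode purity and an overall
misassignment percentage.  Species can also be called without imaging, by
2-way hierarchical clustering of the species-specific profiles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

UNRESOLVED = "UNRESOLVED"


@dataclass
class SpeciesAnnotation:
    """gene -> species map plus declared ortholog pairs.

    ``specific_sets`` maps each species to its genes *excluding* every gene
    that appears in the ortholog table; only those carry species information.
    """

    species_of: pd.Series            # index gene_id -> species token
    orthologs: pd.DataFrame          # columns gene_a, gene_b
    specific_sets: dict[str, set[str]] = field(init=False)

    def __post_init__(self) -> None:
        paired = set(self.orthologs["gene_a"]) | set(self.orthologs["gene_b"])
        self.specific_sets = {
            sp: set(idx) - paired
            for sp, idx in self.species_of.groupby(self.species_of).groups.items()
        }

    @property
    def species(self) -> list[str]:
        return sorted(self.specific_sets)

    @classmethod
    def from_annotations(
        cls, annotations: pd.DataFrame, orthologs: pd.DataFrame
    ) -> "SpeciesAnnotation":
        return cls(species_of=annotations["species"], orthologs=orthologs)


def species_specific_counts(
    matrix: pd.DataFrame, annotation: SpeciesAnnotation
) -> pd.DataFrame:
    """Per-barcode read totals over each species' specific gene set.

    ``matrix`` is genes x barcodes (raw read counts, matching how purity is
    assessed before UMI collapse).  A matrix gene missing from the species
    map is a hard error.
    """
    uncovered = set(matrix.index) - set(annotation.species_of.index)
    if uncovered:
        raise KeyError(f"genes without species annotation: {sorted(uncovered)[:5]}")
    out = {}
    for sp in annotation.species:
        genes = [g for g in matrix.index if g in annotation.specific_sets[sp]]
        out[sp] = matrix.loc[genes].sum(axis=0)
    return pd.DataFrame(out)


def misassignment_rate(
    per_barcode_counts: pd.DataFrame, true_species: pd.Series
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Wrong-species read percentages, per barcode and aggregated.

    For each barcode with known (imaged or simulated) species, misassigned =
    species-specific reads belonging to any other species.  Barcodes with no
    species-specific reads are excluded with a warning.  Returns the
    per-barcode table (wrong, total, pct) and an aggregate dict with one
    overall percentage per species plus ``overall``.
    """
    common = per_barcode_counts.index.intersection(true_species.index)
    counts = per_barcode_counts.loc[common]
    totals = counts.sum(axis=1)
    empty = totals == 0
    if empty.any():
        warnings.warn(f"{int(empty.sum())} barcodes without species-specific reads excluded")
        counts, totals = counts.loc[~empty], totals.loc[~empty]
    truth = true_species.loc[counts.index]
    right = pd.Series(
        [counts.at[b, truth[b]] for b in counts.index], index=counts.index
    )
    wrong = totals - right
    per_barcode = pd.DataFrame(
        {
            "true_species": truth,
            "wrong_reads": wrong.astype(int),
            "total_reads": totals.astype(int),
            "pct_misassigned": 100.0 * wrong / totals,
        }
    )
    aggregate = {}
    for sp in per_barcode_counts.columns:
        sub = per_barcode.loc[per_barcode["true_species"] == sp]
        if len(sub) and sub["total_reads"].sum() > 0:
            aggregate[sp] = float(
                100.0 * sub["wrong_reads"].sum() / sub["total_reads"].sum()
            )
    aggregate["overall"] = float(
        100.0 * per_barcode["wrong_reads"].sum() / per_barcode["total_reads"].sum()
    )
    return per_barcode, aggregate


def call_species(
    matrix: pd.DataFrame,
    annotation: SpeciesAnnotation,
    majority_margin: float = 0.6,
) -> pd.Series:
    """Label each barcode's species from non-orthologous genes alone.

    Barcode profiles restricted to species-specific genes are clustered
    hierarchically (1 - Pearson correlation distance, average linkage) and
    cut into two groups; each group is labelled by the species contributing
    the majority of its species-specific reads.  Groups whose majority falls
    below ``majority_margin`` are labelled :data:`UNRESOLVED` rather than
    guessed.
    """
    species = annotation.species
    if len(species) != 2:
        raise ValueError("species calling requires exactly two species")
    genes = sorted(set().union(*(annotation.specific_sets[sp] for sp in species))
                   & set(matrix.index))
    profiles = matrix.loc[genes].T  # barcodes x genes
    if len(profiles) < 2:
        raise ValueError("need at least two barcodes to call species")
    variances = profiles.var(axis=1)
    degenerate = variances == 0
    if degenerate.all():
        warnings.warn("all profiles constant; species call degenerate")
        return pd.Series(UNRESOLVED, index=profiles.index, name="species")
    kept = profiles.loc[~degenerate]
    dist = pdist(kept.to_numpy(dtype=float), metric="correlation")
    labels = fcluster(linkage(dist, method="average"), t=2, criterion="maxclust")
    ss = species_specific_counts(matrix, annotation)
    calls = pd.Series(index=profiles.index, dtype=object, name="species")
    for k in np.unique(labels):
        members = kept.index[labels == k]
        totals = ss.loc[members].sum(axis=0)
        grand = totals.sum()
        if grand == 0:
            calls.loc[members] = UNRESOLVED
            continue
        top = totals.idxmax()
        calls.loc[members] = top if totals[top] / grand >= majority_margin else UNRESOLVED
    calls.loc[profiles.index[degenerate]] = UNRESOLVED
    return calls
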