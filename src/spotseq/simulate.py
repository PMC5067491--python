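"""Synthetic data generator for the barcoded-array single-cell pipeline.

Emulates the statistical structure the pipeline assumes so that every stage
is verifiable offline: cells smeared or sorted onto spots (background /
single / doublet / cluster occupancy), per-cell negative-binomial expression
with Bernoulli dropout, cell-free background RNA on empty spots, UMIs drawn
uniformly from the semi-randomized WSNNWSNNV space (collisions allowed),
paired 31 nt / 121 nt reads with substitution errors and barcode swapping,
and a two-species mixture for crosstalk experiments.  All outputs are
deterministic under a fixed seed, and ground truth is retained down to the
individual read.

The module also ships small matrix-level generators (low-rank structure,
two-part null/shifted expression, cell-cycle phase programs) used to
calibrate the statistical routines against known truth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .array_model import (
    ArrayLayout,
    BarcodeWhitelist,
    UmiPattern,
    ConfigurationError,
)

BASES = "ACGT"

GROUP_BACKGROUND = "background"
GROUP_SINGLE = "single"
GROUP_DOUBLET = "doublet"
GROUP_CLUSTER = "cluster"

PHASES = ("G1/S", "S", "G2/M", "M", "M/G1")


def occupancy_group(n_cells: int) -> str:
    """Map an imaged per-spot cell count to its occupancy group."""
    if n_cells < 0:
        raise ValueError("cell count must be non-negative")
    if n_cells == 0:
        return GROUP_BACKGROUND
    if n_cells == 1:
        return GROUP_SINGLE
    if n_cells == 2:
        return GROUP_DOUBLET
    return GROUP_CLUSTER


@dataclass
class SimulationConfig:
    """Study conditions for a simulated array experiment.

    Two placement modes: when ``occupancy`` is set, each interior spot
    independently receives cells with that probability (indexed sorting;
    default 0.47 matches the typical sorting efficiency) and the occupied
    multiplicity is drawn from ``multiplicity_probs``; when ``n_cells`` is
    set instead, that many cells land on uniformly random spots (smearing).
    """

    # --- cell placement
    occupancy: float | None = 0.47
    n_cells: int | None = None
    multiplicity_probs: tuple[tuple[int, float], ...] = (
        (1, 0.75), (2, 0.15), (3, 0.06), (4, 0.04),
    )
    placement_jitter_um: float = 30.0
    # --- species / gene universe
    species_mix: tuple[tuple[str, float], ...] = (("human", 1.0),)
    genes_per_species: int = 120
    n_orthologs: int = 40            # leading genes paired across species
    n_ribosomal: int = 6
    n_mito: int = 4
    n_housekeeping: int = 8
    include_malat1_like: bool = True
    # --- expression model (negative binomial + dropout)
    mean_log2_loc: float = 2.0       # lognormal grid of per-gene means
    mean_log2_scale: float = 1.2
    dispersion: float = 2.0          # NB size parameter theta
    dropout: float = 0.3             # zero-inflation probability per gene/cell
    n_programs: int = 1
    program_genes: int = 20
    program_log2_fold: float = 2.0
    # --- background cell-free RNA
    background_fraction: float = 0.05
    # --- read generation
    reads_per_molecule: float = 1.5  # mean sequencing duplication (>= 1)
    substitution_rate: float = 0.0
    swap_rate: float = 0.0
    transcript_length: int = 500
    read1_length: int = 31
    read2_length: int = 121
    seed: int = 0

    def validate(self) -> None:
        probs = [
            self.dropout, self.background_fraction,
            self.substitution_rate, self.swap_rate,
        ]
        if self.occupancy is not None:
            probs.append(self.occupancy)
        for p in probs:
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"probability {p} outside [0, 1]")
        if self.occupancy is None and self.n_cells is None:
            raise ConfigurationError("set either occupancy or n_cells")
        if abs(sum(w for _, w in self.species_mix) - 1.0) > 1e-9:
            raise ConfigurationError("species mix proportions must sum to 1")
        if abs(sum(w for _, w in self.multiplicity_probs) - 1.0) > 1e-9:
            raise ConfigurationError("multiplicity probabilities must sum to 1")
        if self.reads_per_molecule < 1.0:
            raise ConfigurationError("reads_per_molecule must be >= 1")
        if self.transcript_length < self.read2_length:
            raise ConfigurationError("transcripts must cover one full read")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class GroundTruth:
    """Complete simulator truth: spots, cells, molecules and reads.

    ``true_counts`` holds drawn molecules per (gene, barcode); ``reads``
    carries one row per sequenced read with its true origin, UMI, molecule id
    and background/swap flags.  At zero substitution error the per-read table
    aggregates exactly back to ``true_counts`` via distinct molecule ids.
    """

    spots: pd.DataFrame       # spot_id, barcode_id, n_cells, group
    cells: pd.DataFrame       # cell_id, spot_id, barcode_id, species, program, x_um, y_um
    true_counts: pd.DataFrame  # genes x barcodes, drawn molecules
    annotations: pd.DataFrame  # per-gene: species, flags
    orthologs: pd.DataFrame    # gene_a, gene_b
    transcripts: dict[str, str]
    config: SimulationConfig
    reads: pd.DataFrame | None = None
    molecules: pd.DataFrame | None = None  # molecule_id, barcode_id, gene_id, umi, is_background

    def expected_dedup_counts(self, threshold: int = 1) -> pd.DataFrame:
        """Molecule counts after UMI collapse, from the true UMIs drawn.

        Distinct molecules whose UMIs fall in the same Hamming-``threshold``
        cluster are merged, exactly as the pipeline's deduplication would
        merge them; this is the matrix a zero-error run must reproduce.
        """
        from .demux_count import dedup_umis

        if self.molecules is None:
            raise ValueError("reads/molecules were not simulated")
        out = pd.DataFrame(
            0, index=self.true_counts.index, columns=self.true_counts.columns
        )
        grouped = self.molecules.groupby(["gene_id", "barcode_id"], sort=False)["umi"]
        for (gene, barcode), umis in grouped:
            out.loc[gene, barcode] = dedup_umis(list(umis), threshold=threshold)
        return out

    def true_species_per_barcode(self) -> pd.Series:
        """Species of the imaged cell for single-cell barcodes."""
        singles = self.spots.loc[self.spots["group"] == GROUP_SINGLE, "barcode_id"]
        per_cell = self.cells.set_index("barcode_id")["species"]
        return per_cell.loc[per_cell.index.intersection(singles)]


# ---------------------------------------------------------------------------
# gene universe


def build_gene_universe(config: SimulationConfig, rng: np.random.Generator):
    """Gene annotation table, ortholog pairs and per-gene expression means.

    Gene ids carry a species prefix.  The first ``n_orthologs`` regular genes
    of each species are declared orthologous pairs; the remainder are
    species-specific.  Ribosomal, mitochondrial and one MALAT1-like decoy per
    species are appended with high means so the read filters and background
    removal have something to act on.
    """
    species = [s for s, _ in config.species_mix]
    rows = []
    ortho_rows = []
    means = {}
    for sp in species:
        prefix = sp[:2].upper()
        for i in range(config.genes_per_species):
            gid = f"{prefix}-G{i + 1:04d}"
            rows.append(
                dict(gene_id=gid, species=sp, is_ribosomal=False, is_mito=False,
                     is_housekeeping=i < config.n_housekeeping)
            )
            means[gid] = float(
                2.0 ** rng.normal(config.mean_log2_loc, config.mean_log2_scale)
            )
        for i in range(config.n_ribosomal):
            gid = f"{prefix}-RPL{i + 1:02d}"
            rows.append(dict(gene_id=gid, species=sp, is_ribosomal=True,
                             is_mito=False, is_housekeeping=False))
            means[gid] = float(2.0 ** (config.mean_log2_loc + 3.0))
        for i in range(config.n_mito):
            gid = f"{prefix}-MT{i + 1:02d}"
            rows.append(dict(gene_id=gid, species=sp, is_ribosomal=False,
                             is_mito=True, is_housekeeping=False))
            means[gid] = float(2.0 ** (config.mean_log2_loc + 2.0))
        if config.include_malat1_like:
            gid = f"{prefix}-MALAT1"
            rows.append(dict(gene_id=gid, species=sp, is_ribosomal=False,
                             is_mito=False, is_housekeeping=False))
            means[gid] = float(2.0 ** (config.mean_log2_loc + 3.0))
    if len(species) == 2:
        a, b = species
        pa, pb = a[:2].upper(), b[:2].upper()
        for i in range(min(config.n_orthologs, config.genes_per_species)):
            ortho_rows.append(
                dict(gene_a=f"{pa}-G{i + 1:04d}", gene_b=f"{pb}-G{i + 1:04d}")
            )
    annotations = pd.DataFrame(rows).set_index("gene_id")
    orthologs = pd.DataFrame(ortho_rows, columns=["gene_a", "gene_b"])
    return annotations, orthologs, pd.Series(means, name="mean")


def _random_transcript(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list(BASES))[rng.integers(0, 4, size=length)])


def build_transcriptome(
    gene_ids, rng: np.random.Generator, length: int = 500
) -> dict[str, str]:
    """One random transcript per gene (deterministic under the seed)."""
    return {g: _random_transcript(rng, length) for g in gene_ids}


# ---------------------------------------------------------------------------
# cells and expression


def simulate_cells(
    layout: ArrayLayout, config: SimulationConfig, rng: np.random.Generator
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Place cells on spots and derive per-spot occupancy groups.

    Returns (spots table, cells table).  Sorted mode occupies each interior
    spot independently; smear mode scatters ``n_cells`` uniformly.  Cell
    centroids are jittered uniformly within ``placement_jitter_um`` of the
    spot centre, well inside the colocalization radius.
    """
    config.validate()
    spots = layout.barcode_spots
    n_spots = len(spots)
    if config.occupancy is not None:
        occupied = rng.random(n_spots) < config.occupancy
        mults, probs = zip(*config.multiplicity_probs)
        counts = np.zeros(n_spots, dtype=int)
        counts[occupied] = rng.choice(mults, size=int(occupied.sum()), p=probs)
    else:
        max_mult = max(m for m, _ in config.multiplicity_probs)
        if config.n_cells > n_spots * max_mult:
            raise ConfigurationError("more cells than spots can hold")
        counts = np.bincount(
            rng.integers(0, n_spots, size=config.n_cells), minlength=n_spots
        )
    species_names = [s for s, _ in config.species_mix]
    species_probs = [w for _, w in config.species_mix]
    cell_rows = []
    cid = 0
    for i, n in enumerate(counts):
        for _ in range(int(n)):
            cid += 1
            theta = rng.uniform(0, 2 * np.pi)
            r = config.placement_jitter_um * np.sqrt(rng.random())
            cell_rows.append(
                dict(
                    cell_id=f"cell{cid:05d}",
                    spot_id=spots.loc[i, "spot_id"],
                    barcode_id=spots.loc[i, "barcode_id"],
                    species=rng.choice(species_names, p=species_probs),
                    program=int(rng.integers(0, config.n_programs)),
                    x_um=spots.loc[i, "x_um"] + r * np.cos(theta),
                    y_um=spots.loc[i, "y_um"] + r * np.sin(theta),
                )
            )
    cells = pd.DataFrame(
        cell_rows,
        columns=["cell_id", "spot_id", "barcode_id", "species", "program",
                 "x_um", "y_um"],
    )
    spot_table = pd.DataFrame(
        {
            "spot_id": spots["spot_id"],
            "barcode_id": spots["barcode_id"],
            "n_cells": counts,
            "group": [occupancy_group(int(n)) for n in counts],
        }
    )
    return spot_table, cells


def _nb_counts(
    rng: np.random.Generator, mu: np.ndarray, theta: float, dropout: float
) -> np.ndarray:
    """Negative binomial draws (size theta) with Bernoulli zero inflation."""
    p = theta / (theta + mu)
    counts = rng.negative_binomial(theta, p)
    if dropout > 0:
        counts = np.where(rng.random(mu.shape) < dropout, 0, counts)
    return counts


def simulate_expression(
    spot_table: pd.DataFrame,
    cells: pd.DataFrame,
    annotations: pd.DataFrame,
    gene_means: pd.Series,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """True molecule counts per (gene, barcode): cells plus shared background.

    Each cell draws NB(theta, mu) counts over its own species' genes with
    Bernoulli dropout; expression-program membership up-regulates a block of
    genes by ``program_log2_fold``.  Empty spots draw cell-free background
    molecules from the pooled mean profile, scaled so that the expected
    background share of all molecules equals ``background_fraction``.
    """
    genes = list(annotations.index)
    gene_pos = {g: i for i, g in enumerate(genes)}
    barcodes = list(spot_table["barcode_id"])
    mat = np.zeros((len(genes), len(barcodes)), dtype=np.int64)
    col_of = {b: j for j, b in enumerate(barcodes)}

    # program -> up-regulated gene block (within each species' regular genes)
    program_sets: dict[tuple[str, int], np.ndarray] = {}
    for sp in annotations["species"].unique():
        regular = [
            g for g in genes
            if annotations.loc[g, "species"] == sp
            and not annotations.loc[g, ["is_ribosomal", "is_mito"]].any()
            and "MALAT1" not in g
        ]
        for prog in range(config.n_programs):
            start = (prog * config.program_genes) % max(1, len(regular))
            block = regular[start : start + config.program_genes]
            program_sets[(sp, prog)] = np.array([gene_pos[g] for g in block])

    for _, cell in cells.iterrows():
        sp = cell["species"]
        sp_genes = [g for g in genes if annotations.loc[g, "species"] == sp]
        idx = np.array([gene_pos[g] for g in sp_genes])
        mu = gene_means.loc[sp_genes].to_numpy(dtype=float).copy()
        up = program_sets.get((sp, int(cell["program"])))
        if up is not None and config.n_programs > 1:
            fold = 2.0 ** config.program_log2_fold
            in_up = np.isin(idx, up)
            mu[in_up] *= fold
        counts = _nb_counts(rng, mu, config.dispersion, config.dropout)
        mat[idx, col_of[cell["barcode_id"]]] += counts

    total_cell_molecules = int(mat.sum())
    bg_cols = [col_of[b] for b, g in zip(spot_table["barcode_id"], spot_table["group"])
               if g == GROUP_BACKGROUND]
    f = config.background_fraction
    if bg_cols and f > 0 and total_cell_molecules > 0:
        # pooled cell-free profile over all species weighted by the mix
        profile = np.zeros(len(genes))
        for sp, w in config.species_mix:
            sp_genes = [g for g in genes if annotations.loc[g, "species"] == sp]
            idx = np.array([gene_pos[g] for g in sp_genes])
            profile[idx] += w * gene_means.loc[sp_genes].to_numpy(dtype=float)
        profile /= profile.sum()
        n_bg = rng.poisson(f / (1.0 - f) * total_cell_molecules)
        per_spot = rng.multinomial(n_bg, np.full(len(bg_cols), 1.0 / len(bg_cols)))
        for col, n in zip(bg_cols, per_spot):
            if n:
                mat[:, col] += rng.multinomial(n, profile)
    return pd.DataFrame(mat, index=pd.Index(genes, name="gene_id"),
                        columns=pd.Index(barcodes, name="barcode_id"))


# ---------------------------------------------------------------------------
# reads


def _apply_substitutions(
    seqs: list[str], rate: float, rng: np.random.Generator
) -> list[str]:
    if rate <= 0 or not seqs:
        return seqs
    out = []
    for s in seqs:
        arr = np.frombuffer(s.encode(), dtype=np.uint8).copy()
        hits = np.nonzero(rng.random(arr.size) < rate)[0]
        for p in hits:
            current = chr(arr[p])
            arr[p] = ord(rng.choice([b for b in BASES if b != current]))
        out.append(arr.tobytes().decode())
    return out


def simulate_reads(
    truth_counts: pd.DataFrame,
    spot_table: pd.DataFrame,
    whitelist: BarcodeWhitelist,
    transcripts: dict[str, str],
    config: SimulationConfig,
    rng: np.random.Generator,
    pattern: UmiPattern | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Emit paired reads for every true molecule, with errors and swaps.

    R1 = barcode (18) + UMI (9, drawn uniformly from the WSNNWSNNV space,
    collisions allowed) + oligo-dT filler; R2 = a 121 nt substring of the
    gene's transcript.  Each molecule is sequenced ``1 + Poisson(mean - 1)``
    times.  Substitution errors corrupt both mates at the configured per-base
    rate; with probability ``swap_rate`` a read is written with a different
    barcode's sequence (crosstalk) and flagged in the truth table.

    Returns (reads, read_truth, molecules) tables.
    """
    pattern = pattern or UmiPattern()
    bg_of = dict(zip(spot_table["barcode_id"],
                     spot_table["group"] == GROUP_BACKGROUND))
    filler = "T" * (config.read1_length - whitelist.length - pattern.length)
    seq_of = dict(zip(whitelist.ids, whitelist.sequences))
    all_ids = list(whitelist.ids)

    mol_rows = []
    read_r1, read_r2, read_ids = [], [], []
    truth_rows = []
    mol_counter = 0
    read_counter = 0
    nz = truth_counts.to_numpy().nonzero()
    genes = truth_counts.index.to_numpy()
    barcodes = truth_counts.columns.to_numpy()
    for gi, bi in zip(*nz):
        gene, barcode = genes[gi], barcodes[bi]
        n_mol = int(truth_counts.iat[gi, bi])
        umis = pattern.sample(rng, n_mol)
        tx = transcripts[gene]
        max_start = len(tx) - config.read2_length
        for umi in umis:
            mol_counter += 1
            mol_id = f"mol{mol_counter:07d}"
            mol_rows.append(dict(molecule_id=mol_id, barcode_id=barcode,
                                 gene_id=gene, umi=umi,
                                 is_background=bool(bg_of[barcode])))
            n_reads = 1 + int(rng.poisson(config.reads_per_molecule - 1.0))
            for _ in range(n_reads):
                read_counter += 1
                rid = f"read{read_counter:08d}"
                obs_barcode = barcode
                swapped = False
                if config.swap_rate > 0 and rng.random() < config.swap_rate:
                    swapped = True
                    while True:
                        other = all_ids[int(rng.integers(0, len(all_ids)))]
                        if other != barcode:
                            break
                    obs_barcode = other
                start = int(rng.integers(0, max_start + 1))
                read_ids.append(rid)
                read_r1.append(seq_of[obs_barcode] + umi + filler)
                read_r2.append(tx[start : start + config.read2_length])
                truth_rows.append(
                    dict(read_id=rid, true_barcode_id=barcode,
                         obs_barcode_id=obs_barcode, umi=umi, gene_id=gene,
                         molecule_id=mol_id, is_background=bool(bg_of[barcode]),
                         is_swapped=swapped)
                )
    read_r1 = _apply_substitutions(read_r1, config.substitution_rate, rng)
    read_r2 = _apply_substitutions(read_r2, config.substitution_rate, rng)
    reads = pd.DataFrame({"read_id": read_ids, "r1": read_r1, "r2": read_r2})
    read_truth = pd.DataFrame(
        truth_rows,
        columns=["read_id", "true_barcode_id", "obs_barcode_id", "umi",
                 "gene_id", "molecule_id", "is_background", "is_swapped"],
    )
    molecules = pd.DataFrame(
        mol_rows,
        columns=["molecule_id", "barcode_id", "gene_id", "umi", "is_background"],
    )
    return reads, read_truth, molecules


def simulate_experiment(
    layout: ArrayLayout,
    whitelist: BarcodeWhitelist,
    config: SimulationConfig,
    with_reads: bool = True,
) -> tuple[pd.DataFrame | None, GroundTruth]:
    """Run the full generator: cells -> expression -> reads.

    Returns ``(reads, truth)``; ``reads`` is None when ``with_reads`` is
    False (matrix-level simulations).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    annotations, orthologs, gene_means = build_gene_universe(config, rng)
    transcripts = build_transcriptome(
        annotations.index, rng, length=config.transcript_length
    )
    spot_table, cells = simulate_cells(layout, config, rng)
    true_counts = simulate_expression(
        spot_table, cells, annotations, gene_means, config, rng
    )
    truth = GroundTruth(
        spots=spot_table, cells=cells, true_counts=true_counts,
        annotations=annotations, orthologs=orthologs,
        transcripts=transcripts, config=config,
    )
    reads = None
    if with_reads:
        reads, read_truth, molecules = simulate_reads(
            true_counts, spot_table, whitelist, transcripts, config, rng
        )
        truth.reads = read_truth
        truth.molecules = molecules
    return reads, truth


# ---------------------------------------------------------------------------
# matrix-level generators for statistical calibration


def simulate_low_rank(
    n_cells: int = 100,
    n_genes: int = 500,
    rank: int = 2,
    signal: float = 80.0,
    seed: int = 0,
) -> np.ndarray:
    """Planted low-rank structure plus iid N(0,1) noise, gene-centred.

    Singular values step down from ``signal`` (80, 60, ...), far above the
    Marchenko-Pastur noise edge (~32 at 100 x 500), so the planted rank is
    unambiguous for permutation-based component significance.
    """
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal((n_cells, n_genes))
    u, _ = np.linalg.qr(rng.standard_normal((n_cells, rank)))
    v, _ = np.linalg.qr(rng.standard_normal((n_genes, rank)))
    s = np.array([signal * (0.75 ** k) for k in range(rank)])
    x = noise + (u * s) @ v.T
    return x - x.mean(axis=0, keepdims=True)


def simulate_two_part_matrix(
    n_genes: int = 2000,
    cells_per_cluster: int = 50,
    n_clusters: int = 2,
    detect_prob: float = 0.7,
    mu: float = 4.0,
    sigma: float = 1.0,
    log2_fold: float = 0.0,
    shifted_fraction: float = 1.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series, np.ndarray]:
    """Log-scale two-part expression: Bernoulli detection + Normal positives.

    Under the null (``log2_fold`` 0) every cluster shares (detect_prob, mu);
    otherwise the last cluster's positive mean is shifted by ``log2_fold``
    for the leading ``shifted_fraction`` of genes.  Returns (matrix genes x
    cells, cluster labels, boolean shifted-gene mask).
    """
    rng = np.random.default_rng(seed)
    n_cells = cells_per_cluster * n_clusters
    labels = pd.Series(
        np.repeat([f"c{k}" for k in range(n_clusters)], cells_per_cluster),
        index=[f"cell{i:04d}" for i in range(n_cells)], name="cluster",
    )
    shifted = np.zeros(n_genes, dtype=bool)
    shifted[: int(round(shifted_fraction * n_genes))] = log2_fold != 0.0
    detected = rng.random((n_genes, n_cells)) < detect_prob
    values = rng.normal(mu, sigma, size=(n_genes, n_cells))
    if log2_fold:
        last = labels.to_numpy() == f"c{n_clusters - 1}"
        values[np.ix_(shifted, last)] += log2_fold
    values = np.clip(values, 0.05, None)  # log-scale positives stay positive
    mat = np.where(detected, values, 0.0)
    df = pd.DataFrame(mat, index=[f"g{i:05d}" for i in range(n_genes)],
                      columns=labels.index)
    return df, labels, shifted


def simulate_phase_programs(
    n_cells: int = 500,
    genes_per_phase: int = 60,
    n_noise_genes: int = 100,
    effect: float = 3.0,
    cycling_fraction: float | None = None,
    decoys_per_phase: int = 3,
    seed: int = 0,
):
    """Cell-cycle phase programs on a z-like expression scale.

    Every cell gets a phase drawn uniformly from the five phases; its phase's
    gene block is shifted up by ``effect`` standard deviations.  When
    ``cycling_fraction`` is given, only that (Bernoulli) share of cells
    carries a phase program and the rest are pure noise — the regime used to
    test cycling-cell calling.  Candidate phase gene lists include
    ``decoys_per_phase`` pure-noise genes so the correlation filter is
    exercised.

    Returns (matrix genes x cells, candidate_sets, truth) where truth has
    per-cell ``phase`` (empty string for non-cycling) and ``cycling``.
    """
    rng = np.random.default_rng(seed)
    phases = list(PHASES)
    gene_ids = []
    phase_of_gene = {}
    for p_i, phase in enumerate(phases):
        for g in range(genes_per_phase):
            gid = f"P{p_i}-g{g:03d}"
            gene_ids.append(gid)
            phase_of_gene[gid] = phase
    noise_ids = [f"NZ-g{g:03d}" for g in range(n_noise_genes)]
    gene_ids += noise_ids

    cells = [f"cell{i:04d}" for i in range(n_cells)]
    if cycling_fraction is None:
        cycling = np.ones(n_cells, dtype=bool)
    else:
        cycling = rng.random(n_cells) < cycling_fraction
    phase_idx = rng.integers(0, len(phases), size=n_cells)

    mat = rng.standard_normal((len(gene_ids), n_cells))
    for j in range(n_cells):
        if not cycling[j]:
            continue
        phase = phases[phase_idx[j]]
        rows = [i for i, g in enumerate(gene_ids) if phase_of_gene.get(g) == phase]
        mat[rows, j] += effect
    df = pd.DataFrame(mat, index=gene_ids, columns=cells)

    candidate_sets = {}
    noise_pool = list(noise_ids)
    for p_i, phase in enumerate(phases):
        own = [g for g in gene_ids if phase_of_gene.get(g) == phase]
        decoys = noise_pool[p_i * decoys_per_phase : (p_i + 1) * decoys_per_phase]
        candidate_sets[phase] = own + decoys
    truth = pd.DataFrame(
        {
            "cell_id": cells,
            "phase": [phases[k] if c else "" for k, c in zip(phase_idx, cycling)],
            "cycling": cycling,
        }
    ).set_index("cell_id")
    return df, candidate_sets, truth
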