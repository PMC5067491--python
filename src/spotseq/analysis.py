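"""Expression analysis: normalization, gene selection, dimensionality
reduction with permutation-based component significance, embedding,
hierarchical clustering and two-part likelihood-ratio differential
expression.

Scaling conventions: counts are library-size normalized to a fixed total per
barcode (200,000 for cell-line libraries, "TP200K"; 10,000 for small
lymphocytes, "TP10K"), a pseudocount is added and values move to log2.
Variable-gene selection and abundance filtering operate on the pre-log
scaled values; clustering and differential expression on the log values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform
from scipy.stats import chi2
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE

TP200K = 200_000
TP10K = 10_000


@dataclass
class NormalizedMatrix:
    """Library-size normalized expression on linear and log2 scales.

    ``linear`` columns sum exactly to ``scale_n`` for every retained barcode;
    ``log2`` is ``log2(linear + pseudocount)``.
    """

    linear: pd.DataFrame
    log2: pd.DataFrame
    scale_n: float
    pseudocount: float = 1.0
    centred: bool = False

    @property
    def genes(self) -> pd.Index:
        return self.linear.index

    @property
    def barcodes(self) -> pd.Index:
        return self.linear.columns


def normalize(
    counts: pd.DataFrame, scale_n: float = TP200K, pseudocount: float = 1.0
) -> NormalizedMatrix:
    """Scale each barcode's counts to ``scale_n`` total, then log2(x + pc).

    All-zero barcodes cannot be scaled and are dropped with a warning;
    negative counts are a hard error.
    """
    if scale_n <= 0:
        raise ValueError("scale_n must be positive")
    arr = counts.to_numpy()
    if (arr < 0).any():
        raise ValueError("negative counts")
    colsums = counts.sum(axis=0)
    empty = colsums == 0
    if empty.any():
        warnings.warn(f"dropping {int(empty.sum())} all-zero barcodes")
        counts = counts.loc[:, ~empty]
        colsums = colsums[~empty]
    linear = counts.div(colsums, axis=1) * scale_n
    log2 = np.log2(linear + pseudocount)
    return NormalizedMatrix(linear=linear, log2=log2, scale_n=float(scale_n),
                            pseudocount=float(pseudocount))


def select_variable_genes(nm: NormalizedMatrix, n: int = 2000) -> list[str]:
    """Top-n genes by coefficient of variation of pre-log normalized values.

    Ties (including the all-constant CV = 0 block) break deterministically
    by gene id.
    """
    if n > len(nm.genes):
        raise ValueError("n exceeds the number of genes")
    means = nm.linear.mean(axis=1)
    sd = nm.linear.std(axis=1, ddof=1)
    cv = pd.Series(np.where(means > 0, sd / means.replace(0, np.nan), 0.0),
                   index=nm.genes).fillna(0.0)
    ranked = cv.sort_index().sort_values(ascending=False, kind="stable")
    return list(ranked.index[:n])


def abundance_filter(
    nm: NormalizedMatrix, min_mean: float = 6.5
) -> tuple[list[str], pd.DataFrame]:
    """Keep genes with mean pre-log expression >= min_mean, then mean-centre.

    The default of 6.5 is on the TP10K scale used for small-lymphocyte
    libraries.  Returns the retained gene list and the per-gene mean-centred
    log2 matrix restricted to them.
    """
    means = nm.linear.mean(axis=1)
    kept = list(means.index[means >= min_mean])
    centred = nm.log2.loc[kept].sub(nm.log2.loc[kept].mean(axis=1), axis=0)
    return kept, centred


@dataclass
class PcSignificance:
    """Permutation-tested principal components (parallel-analysis style)."""

    eigenvalues: np.ndarray
    p_values: np.ndarray
    n_significant: int
    scores: np.ndarray       # cells x components (observed PCA)
    components: np.ndarray   # components x genes

    @property
    def significant_scores(self) -> np.ndarray:
        return self.scores[:, : self.n_significant]


def significant_pcs(
    matrix: pd.DataFrame | np.ndarray,
    alpha: float = 0.01,
    n_perm: int = 100,
    seed: int | np.random.Generator = 0,
    n_components: int | None = None,
) -> PcSignificance:
    """Permutation test for how many leading PCs carry real structure.

    ``matrix`` is cells x genes (centred or centred here).  Each permutation
    independently shuffles every gene's values across cells, destroying
    gene-gene covariance while preserving marginals; the p-value of component
    i is ``(1 + #{perm eigenvalue_i >= observed_i}) / (n_perm + 1)``.  The
    result is the leading run of components with p < alpha.
    """
    if n_perm < int(np.ceil(1.0 / alpha)) - 1:
        raise ValueError("n_perm too small to resolve p-values below alpha")
    x = np.asarray(matrix, dtype=float)
    if x.shape[0] < 3:
        raise ValueError("need at least 3 cells")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    x = x - x.mean(axis=0, keepdims=True)
    k = n_components or min(x.shape[0] - 1, x.shape[1], 30)
    pca = PCA(n_components=k, svd_solver="full" if min(x.shape) < 500 else "auto",
              random_state=0)
    scores = pca.fit_transform(x)
    observed = pca.explained_variance_[:k]
    exceed = np.zeros(k, dtype=int)
    for _ in range(n_perm):
        perm = rng.permuted(x, axis=0)
        perm -= perm.mean(axis=0, keepdims=True)
        sv = np.linalg.svd(perm, compute_uv=False)[:k]
        lam = np.zeros(k)
        lam[: sv.size] = sv**2 / (x.shape[0] - 1)
        exceed += lam >= observed
    p = (1.0 + exceed) / (n_perm + 1.0)
    sig = 0
    for pi in p:
        if pi < alpha:
            sig += 1
        else:
            break
    return PcSignificance(eigenvalues=observed, p_values=p, n_significant=sig,
                          scores=scores, components=pca.components_)


def tsne_embed(
    scores: np.ndarray,
    dims: int = 2,
    n_iter: int = 10_000,
    seed: int = 0,
    perplexity: float = 30.0,
) -> np.ndarray:
    """t-SNE embedding of PC scores; deterministic under a fixed seed."""
    scores = np.asarray(scores, dtype=float)
    if dims not in (2, 3):
        raise ValueError("dims must be 2 or 3")
    if dims > scores.shape[1]:
        raise ValueError("dims exceeds the number of components")
    if scores.shape[0] <= 3 * perplexity:
        raise ValueError("perplexity too large for this many cells")
    tsne = TSNE(n_components=dims, max_iter=n_iter, perplexity=perplexity,
                random_state=seed, init="pca")
    return tsne.fit_transform(scores)


def pearson_distance_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    """1 - Pearson r between cells (columns of a genes x cells matrix)."""
    corr = np.corrcoef(matrix.to_numpy(dtype=float), rowvar=False)
    return pd.DataFrame(1.0 - corr, index=matrix.columns, columns=matrix.columns)


def hcluster(
    matrix: pd.DataFrame,
    k: int | None = None,
    height: float | None = None,
    method: str = "average",
    cells_as_columns: bool = True,
) -> tuple[pd.Series, np.ndarray]:
    """Agglomerative clustering of cells under 1 - Pearson distance.

    ``matrix`` is genes x cells by default (set ``cells_as_columns=False``
    for cells x features, e.g. PC scores).  Zero-variance cell profiles have
    undefined correlation and are excluded with a warning (label -1).
    Returns (labels, scipy linkage matrix); labels come from a cut at ``k``
    clusters or at ``height``.
    """
    cells = matrix.columns if cells_as_columns else matrix.index
    data = matrix.T if cells_as_columns else matrix
    if len(cells) < 2:
        raise ValueError("need at least two cells")
    variances = data.var(axis=1, ddof=0)
    bad = variances == 0
    if bad.any():
        warnings.warn(f"excluding {int(bad.sum())} zero-variance profiles")
    kept = data.loc[~bad]
    dist = pdist(kept.to_numpy(dtype=float), metric="correlation")
    z = linkage(dist, method=method)
    labels = pd.Series(-1, index=cells, dtype=int, name="cluster")
    if k is not None:
        cut = fcluster(z, t=k, criterion="maxclust")
    elif height is not None:
        cut = fcluster(z, t=height, criterion="distance")
    else:
        cut = np.ones(len(kept), dtype=int)
    labels.loc[kept.index] = cut
    return labels, z


@dataclass
class DEResult:
    """Per-gene two-part likelihood-ratio test results."""

    table: pd.DataFrame  # statistic, df, p_value, pi_<k>, mu_<k>
    alpha: float = 0.001

    @property
    def significant(self) -> pd.Index:
        return self.table.index[self.table["p_value"] < self.alpha]


def _bernoulli_ll(n_pos: int, n_tot: int) -> float:
    if n_tot == 0 or n_pos in (0, n_tot):
        return 0.0
    p = n_pos / n_tot
    return n_pos * np.log(p) + (n_tot - n_pos) * np.log(1 - p)


def lrt_de(
    log_matrix: pd.DataFrame,
    labels: pd.Series,
    alpha: float = 0.001,
) -> DEResult:
    """Two-part likelihood-ratio test for expression differences across clusters.

    Each gene is modelled as detection (value > 0) ~ Bernoulli(pi) plus
    positive log-values ~ Normal(mu, sigma^2) with sigma pooled across
    clusters.  Null: shared (pi, mu); alternative: cluster-specific
    (pi_k, mu_k).  Lambda = 2 (l_alt - l_null) is referred to chi-square with
    2 (K - 1) degrees of freedom.  A component's term is dropped — with the
    matching df reduction — when it is not identifiable: the Normal part when
    fewer than two clusters have positive observations, the Bernoulli part
    when detection is constant (all-positive or all-zero overall).  All-zero
    genes are excluded.
    """
    common = log_matrix.columns.intersection(labels.index)
    x = log_matrix[common]
    lab = labels.loc[common]
    groups = sorted(lab.unique())
    if len(groups) < 2:
        raise ValueError("need at least two clusters")
    for g in groups:
        if (lab == g).sum() < 2:
            raise ValueError(f"cluster {g} has fewer than 2 cells")
    masks = {g: (lab == g).to_numpy() for g in groups}
    rows = []
    for gene, values in x.iterrows():
        v = values.to_numpy(dtype=float)
        pos = v > 0
        n_pos_tot, n_tot = int(pos.sum()), v.size
        if n_pos_tot == 0:
            continue
        stat = 0.0
        df = 0
        # --- detection component
        if 0 < n_pos_tot < n_tot:
            ll_null = _bernoulli_ll(n_pos_tot, n_tot)
            ll_alt = sum(
                _bernoulli_ll(int(pos[m].sum()), int(m.sum()))
                for m in masks.values()
            )
            stat += 2.0 * (ll_alt - ll_null)
            df += len(groups) - 1
        # --- positive-mean component (pooled variance)
        with_pos = [g for g in groups if pos[masks[g]].sum() > 0]
        if len(with_pos) >= 2 and n_pos_tot >= 2:
            y = v[pos]
            sse_null = float(((y - y.mean()) ** 2).sum())
            sse_alt = 0.0
            for g in with_pos:
                yk = v[pos & masks[g]]
                sse_alt += float(((yk - yk.mean()) ** 2).sum())
            if sse_alt > 0:
                stat += n_pos_tot * (np.log(sse_null) - np.log(sse_alt))
                df += len(with_pos) - 1
        stat = max(stat, 0.0)
        p = float(chi2.sf(stat, df)) if df > 0 else 1.0
        row = {"gene_id": gene, "statistic": stat, "df": df, "p_value": p}
        for g in masks:
            m = masks[g]
            row[f"pi_{g}"] = float(pos[m].mean())
            row[f"mu_{g}"] = float(v[pos & m].mean()) if pos[m].any() else np.nan
        rows.append(row)
    table = pd.DataFrame(rows).set_index("gene_id")
    return DEResult(table=table, alpha=alpha)


def top_abundant_overlap(
    matrices: dict[str, NormalizedMatrix | pd.DataFrame], top_n: int = 500
) -> dict:
    """Overlap structure of each group's top-N most expressed genes.

    Ranks genes by mean linear expression per group; reports per-group
    exclusive counts, every pairwise intersection and the intersection of
    all groups.
    """
    tops = {}
    for name, m in matrices.items():
        linear = m.linear if isinstance(m, NormalizedMatrix) else m
        means = linear.mean(axis=1)
        ranked = means.sort_index().sort_values(ascending=False, kind="stable")
        tops[name] = set(ranked.index[:top_n])
    names = sorted(tops)
    exclusive = {
        n: len(tops[n] - set().union(*(tops[m] for m in names if m != n)))
        for n in names
    }
    pairwise = {
        (a, b): len(tops[a] & tops[b])
        for i, a in enumerate(names) for b in names[i + 1:]
    }
    shared = len(set.intersection(*tops.values())) if names else 0
    return {"top_genes": tops, "exclusive": exclusive,
            "pairwise": pairwise, "shared_all": shared}


def remove_named_background_genes(
    matrix: pd.DataFrame,
    names=("BCYRN1",),
    include_mito: bool = False,
    annotations: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Drop named background genes (and optionally mitochondrial genes).

    Names match the gene id exactly or its suffix after a species prefix.
    Absent names only warn.  ``include_mito=True`` additionally removes every
    gene flagged ``is_mito`` in the annotation table.
    """
    names = set(names)
    def matches(gene: str) -> bool:
        return gene in names or gene.split("-", 1)[-1] in names

    drop = {g for g in matrix.index if matches(g)}
    found_names = {n for n in names
                   if any(g == n or g.split("-", 1)[-1] == n for g in matrix.index)}
    for miss in names - found_names:
        warnings.warn(f"gene {miss!r} not present; nothing removed for it")
    if include_mito:
        if annotations is None:
            raise ValueError("annotations required when include_mito=True")
        drop |= set(annotations.index[annotations["is_mito"]]) & set(matrix.index)
    return matrix.drop(index=sorted(drop))
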