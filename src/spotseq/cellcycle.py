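"""Cell-cycle phase scoring from five phase gene sets.

Each cell receives one score per phase (G1/S, S, G2/M, M, M/G1) built from
curated phase gene lists: candidate genes are first filtered by requiring
Pearson r > 0.3 against their phase's mean profile, then scores are
normalized in two steps — z-scoring each gene across cells before averaging
into a raw phase score, and z-scoring each phase's scores across cells —
followed by centring the five scores within each cell.  A cell whose
maximal phase score clears a threshold is called cycling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simulate import PHASES


class EmptyPhaseError(ValueError):
    """A phase retained no genes after the correlation filter."""


@dataclass
class PhaseGeneSets:
    """Filtered per-phase gene lists with their phase-profile correlations."""

    sets: dict[str, list[str]]
    correlations: dict[str, pd.Series] = field(default_factory=dict)
    r_threshold: float = 0.3

    @property
    def phases(self) -> list[str]:
        return list(self.sets)


@dataclass
class PhaseScores:
    """cells x 5 twice-normalized phase scores with per-cell calls."""

    scores: pd.DataFrame       # cells x phases, per-cell mean 0
    argmax_phase: pd.Series
    cycling: pd.Series
    threshold: float

    @property
    def cycling_fraction(self) -> float:
        return float(self.cycling.mean())


def filter_phase_genes(
    matrix: pd.DataFrame,
    candidate_sets: dict[str, list[str]],
    r_threshold: float = 0.3,
) -> PhaseGeneSets:
    """Retain candidates correlated (Pearson r > threshold) with their phase.

    For each phase the reference is the mean expression profile of that
    phase's candidate genes across cells; genes tracking the programme pass,
    uncorrelated contaminants fall away.  A phase left empty is a hard
    error naming the phase.
    """
    if not candidate_sets:
        raise ValueError("no candidate phase sets supplied")
    sets: dict[str, list[str]] = {}
    correlations: dict[str, pd.Series] = {}
    for phase, candidates in candidate_sets.items():
        present = [g for g in candidates if g in matrix.index]
        if not present:
            raise EmptyPhaseError(f"phase {phase!r} has no genes in the matrix")
        profile = matrix.loc[present].mean(axis=0)
        rs = {}
        for g in present:
            values = matrix.loc[g]
            if values.std(ddof=0) == 0 or profile.std(ddof=0) == 0:
                rs[g] = 0.0
            else:
                rs[g] = float(np.corrcoef(values, profile)[0, 1])
        rs = pd.Series(rs, name=phase)
        kept = list(rs.index[rs > r_threshold])
        if not kept:
            raise EmptyPhaseError(
                f"phase {phase!r} retained no genes at r > {r_threshold}"
            )
        sets[phase] = kept
        correlations[phase] = rs
    return PhaseGeneSets(sets=sets, correlations=correlations,
                         r_threshold=r_threshold)


def phase_scores(
    matrix: pd.DataFrame,
    gene_sets: PhaseGeneSets | dict[str, list[str]],
    score_threshold: float = 1.0,
    groups: pd.Series | None = None,
) -> PhaseScores:
    """Two-step normalized average phase scores per cell.

    (1) z-score each gene across cells (zero-variance genes dropped with a
    warning); (2) raw phase score = mean z over the phase's genes; (3)
    z-score each phase's raw scores across cells; (4) centre the five scores
    within each cell, so a cell's scores express relative phase preference.
    The per-cell argmax phase and the cycling call (max score >=
    ``score_threshold``) are recorded.

    With ``groups`` given (e.g. patient subsets), steps 1 and 3 are redone
    within each group, yielding group-specific scores on a common frame.
    """
    sets = gene_sets.sets if isinstance(gene_sets, PhaseGeneSets) else gene_sets
    if groups is not None:
        parts = []
        for g in sorted(groups.unique()):
            cols = groups.index[groups == g].intersection(matrix.columns)
            part = phase_scores(matrix[cols], sets, score_threshold=score_threshold)
            parts.append(part.scores)
        scores = pd.concat(parts).loc[matrix.columns.intersection(groups.index)]
    else:
        sd = matrix.std(axis=1, ddof=0)
        dead = sd == 0
        if dead.any():
            warnings.warn(f"dropping {int(dead.sum())} zero-variance genes")
        z = matrix.loc[~dead].sub(matrix.loc[~dead].mean(axis=1), axis=0).div(
            sd[~dead], axis=0
        )
        raw = {}
        for phase, genes in sets.items():
            present = [g for g in genes if g in z.index]
            if not present:
                raise EmptyPhaseError(f"phase {phase!r} has no usable genes")
            raw[phase] = z.loc[present].mean(axis=0)
        raw = pd.DataFrame(raw)  # cells x phases
        step3 = (raw - raw.mean(axis=0)) / raw.std(axis=0, ddof=0)
        scores = step3.sub(step3.mean(axis=1), axis=0)
    argmax = scores.idxmax(axis=1)
    argmax.name = "phase"
    cycling = scores.max(axis=1) >= score_threshold
    cycling.name = "cycling"
    return PhaseScores(scores=scores, argmax_phase=argmax, cycling=cycling,
                       threshold=score_threshold)


def call_cycling(
    scores: PhaseScores,
    score_threshold: float | None = None,
    groups: pd.Series | None = None,
) -> tuple[pd.Series, dict[str, float] | float]:
    """Flag cycling cells (max phase score >= threshold); report fractions.

    Returns the per-cell flags and either the overall cycling fraction or a
    per-group dict when ``groups`` is supplied.
    """
    threshold = scores.threshold if score_threshold is None else score_threshold
    flags = scores.scores.max(axis=1) >= threshold
    flags.name = "cycling"
    if groups is None:
        return flags, float(flags.mean())
    fractions = {
        g: float(flags.loc[groups.index[groups == g].intersection(flags.index)].mean())
        for g in sorted(groups.unique())
    }
    return flags, fractions
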