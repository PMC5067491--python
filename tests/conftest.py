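"""Shared fixtures: small whitelists, layouts and simulated experiments.

Everything is generated programmatically and seeded; session scope keeps the
more expensive simulations to one run each.
"""

import numpy as np
import pandas as pd
import pytest

import spotseq as ss


def oracle_hamming(a: str, b: str) -> int:
    """Independent per-character Hamming distance; N mismatches everything."""
    return sum(1 for x, y in zip(a, b) if x != y or x == "N" or y == "N")


def oracle_match(observed: str, whitelist, max_mismatches: int = 2):
    """Pure-python full-scan decoder used as the reference in tests."""
    dists = [oracle_hamming(observed, s) for s in whitelist.sequences]
    best = min(dists)
    if best > max_mismatches or dists.count(best) > 1:
        return None
    return whitelist.ids[dists.index(best)], best


def oracle_components(umis, threshold: int) -> int:
    """Union-find over brute-force pairwise distances (independent oracle)."""
    unique = sorted(set(umis))
    parent = list(range(len(unique)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(unique)):
        for j in range(i + 1, len(unique)):
            if oracle_hamming(unique[i], unique[j]) <= threshold:
                parent[find(i)] = find(j)
    return len({find(i) for i in range(len(unique))})


@pytest.fixture(scope="session")
def small_whitelist():
    return ss.generate_whitelist(100, min_distance=5, seed=11)


@pytest.fixture(scope="session")
def small_layout(small_whitelist):
    wl = ss.BarcodeWhitelist(
        ids=small_whitelist.ids[:49], sequences=small_whitelist.sequences[:49]
    )
    return ss.default_layout(wl, n_rows=9, n_cols=9, reserve_corners=False), wl


@pytest.fixture(scope="session")
def clean_experiment(small_layout):
    """Zero-error, zero-swap simulation plus its pipeline output."""
    layout, wl = small_layout
    config = ss.SimulationConfig(
        occupancy=0.5, seed=3, genes_per_species=40, background_fraction=0.05
    )
    reads, truth = ss.simulate_experiment(layout, wl, config)
    tx = ss.ToyTranscriptome(truth.transcripts)
    cm, report = ss.run_pipeline(
        ((r.read_id, r.r1, r.r2) for r in reads.itertuples()),
        wl,
        transcriptome=tx,
        annotations=truth.annotations,
        genes=list(truth.annotations.index),
        barcodes=layout.barcode_ids,
    )
    return dict(layout=layout, whitelist=wl, config=config, reads=reads,
                truth=truth, cm=cm, report=report, transcriptome=tx)
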