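"""Shared test utilities: independent oracles and a pipeline runner.

The oracles deliberately avoid the implementation paths they check:
brute-force recursion for folding, nested-loop counting for k-mers,
pair counting for AUROC, a regex for the DRACH predicate.
"""

from __future__ import annotations

import re

import numpy as np

import m6asite as m
from m6asite import classifier as clf
from m6asite import evaluation as ev
from m6asite.datasets import SplitSpec, build_datasets
from m6asite.features import assemble_matrix
from m6asite.synthetic import SyntheticConfig, generate_dataset

# --- DRACH oracle -----------------------------------------------------------

DRACH_RE = re.compile(r"(?=([AGT][AG]AC[ACT]))")


def drach_positions_regex(seq: str) -> list[int]:
    """Central-A positions of DRACH matches, via regex lookahead."""
    return [mo.start() + 2 for mo in DRACH_RE.finditer(seq)]


# --- folding oracle ---------------------------------------------------------

_PAIR_E = {
    ("G", "C"): -3.0, ("C", "G"): -3.0,
    ("A", "T"): -2.0, ("T", "A"): -2.0,
    ("G", "T"): -1.0, ("T", "G"): -1.0,
}


def brute_force_mfe(seq: str) -> float:
    """Exhaustive minimum over all pseudoknot-free structures.

    Decomposes on the leftmost base (unpaired, or paired with any
    admissible partner enclosing >= 3 unpaired bases); no memoization,
    so every structure is enumerated.  Only usable for short sequences.
    """

    def best(i: int, j: int) -> float:
        if j - i < 4:
            return 0.0
        b = best(i + 1, j)
        for k in range(i + 4, j + 1):
            e = _PAIR_E.get((seq[i], seq[k]), 0.0)
            if e < 0.0:
                cand = e + best(i + 1, k - 1) + best(k + 1, j)
                if cand < b:
                    b = cand
        return b

    return best(0, len(seq) - 1)


# --- k-mer oracle -----------------------------------------------------------

def naive_kmer_spectrum(window: str, ks=(3, 4)) -> np.ndarray:
    """Nested-loop k-mer frequencies, lexicographic within each k."""
    from itertools import product

    blocks = []
    for k in ks:
        mers = ["".join(p) for p in product("ACGT", repeat=k)]
        counted = [
            window[i : i + k]
            for i in range(len(window) - k + 1)
            if "N" not in window[i : i + k]
        ]
        counts = np.array([sum(1 for c in counted if c == mer) for mer in mers],
                          dtype=float)
        blocks.append(counts / len(counted) if counted else counts)
    return np.concatenate(blocks)


# --- AUROC oracle -----------------------------------------------------------

def auroc_pair_counting(scores, labels) -> float:
    """Fraction of (positive, negative) pairs ranked correctly, ties 1/2."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1.0
            elif p == n:
                wins += 0.5
    return wins / (len(pos) * len(neg))


# --- pipeline runner --------------------------------------------------------

def run_pipeline(
    config: SyntheticConfig,
    mode: str,
    seed: int,
    C: float | None = None,
    gamma: float | None = None,
    grid: bool = False,
) -> dict:
    """simulate -> split -> encode -> train -> calibrate -> evaluate."""
    bundle = generate_dataset(config)
    transcripts = [m.Transcript(t.id, t.seq, mode=mode) for t in bundle.transcripts]
    tmap = {t.id: t for t in transcripts}
    train_set, test_set = build_datasets(
        transcripts,
        bundle.positives,
        SplitSpec(seed=seed),
        excluded_intervals=bundle.exclusion_intervals(),
    )

    def xy(sites):
        X = assemble_matrix(sites, tmap, mode, seed=seed)
        y = np.array([1 if s.label == "positive" else 0 for s in sites])
        return X, y

    X_train, y_train = xy(train_set)
    X_test, y_test = xy(test_set)
    if grid:
        C, gamma = clf.grid_search(
            X_train, y_train,
            C_grid=(0.5, 8.0, 128.0),
            gamma_grid=(2.0 ** -10, 2.0 ** -7, 2.0 ** -4),
            k_folds=3, seed=seed,
        )
    predictor = clf.train(X_train, y_train, mode, C=C, gamma=gamma, seed=seed)
    clf.calibrate_thresholds(predictor, X_train, y_train)
    report = ev.evaluate_independent(predictor, X_test, y_test)
    return {
        "bundle": bundle,
        "transcripts": transcripts,
        "tmap": tmap,
        "train_set": train_set,
        "test_set": test_set,
        "X_train": X_train,
        "y_train": y_train,
        "X_test": X_test,
        "y_test": y_test,
        "predictor": predictor,
        "report": report,
    }
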