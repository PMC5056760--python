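"""Labeled dataset construction: negative sampling, splits, pooling.

Training follows the protocol used for miCLIP-derived m6A site lists:
positives are methylated DRACH adenosines; negatives are DRACH
adenosines sampled uniformly from the same transcripts after removing
anything overlapping a positive or a supplied exclusion interval (e.g.
known methylation peaks).  75% of the positives plus an equal number of
negatives form the balanced training set; the remaining 25% plus ten
negatives per positive form the unbalanced (1:10) independent test set,
matching the scarcity of methylated adenosines in real transcriptomes.

Site identity is the pair (transcript_id, pos); train and test are
globally disjoint at that level, and every sampling step is
reproducible from a single integer seed.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .sequences import Transcript, scan_drach

LABELS = ("positive", "negative")


@dataclass(frozen=True)
class LabeledSite:
    transcript_id: str
    pos: int
    label: str
    taxon: Optional[str] = None

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}, got {self.label!r}")

    @property
    def key(self) -> tuple:
        return (self.transcript_id, self.pos)


@dataclass(frozen=True)
class SplitSpec:
    """Train/test partition parameters (defaults mirror the protocol)."""

    train_fraction: float = 0.75
    test_neg_ratio: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.test_neg_ratio < 1:
            raise ValueError("test_neg_ratio must be >= 1")


def _interval_index(intervals: Iterable[tuple]) -> dict:
    """Map transcript id -> merged, sorted [start, end) intervals."""
    by_id: dict = {}
    for chrom, start, end in intervals:
        by_id.setdefault(chrom, []).append((int(start), int(end)))
    for chrom, ivals in by_id.items():
        ivals.sort()
        merged = [list(ivals[0])]
        for start, end in ivals[1:]:
            if start <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], end)
            else:
                merged.append([start, end])
        by_id[chrom] = [tuple(iv) for iv in merged]
    return by_id


def _in_intervals(index: dict, chrom: str, pos: int) -> bool:
    ivals = index.get(chrom)
    if not ivals:
        return False
    i = bisect.bisect_right(ivals, (pos, float("inf"))) - 1
    return i >= 0 and ivals[i][0] <= pos < ivals[i][1]


def eligible_negatives(
    transcripts: Sequence[Transcript],
    positives: Iterable,
    excluded_intervals: Iterable[tuple] = (),
) -> list[LabeledSite]:
    """All DRACH adenosines usable as negatives, in deterministic order."""
    pos_keys = {(p.transcript_id, p.pos) for p in positives}
    index = _interval_index(excluded_intervals)
    out = []
    for t in transcripts:
        for cand in scan_drach(t):
            if cand.key in pos_keys:
                continue
            if _in_intervals(index, t.id, cand.pos):
                continue
            out.append(LabeledSite(t.id, cand.pos, "negative"))
    return out


def sample_negatives(
    transcripts: Sequence[Transcript],
    positives: Iterable,
    excluded_intervals: Iterable[tuple],
    count: int,
    rng: np.random.Generator,
) -> list[LabeledSite]:
    """Uniform sample (without replacement) of eligible DRACH negatives."""
    pool = eligible_negatives(transcripts, positives, excluded_intervals)
    if count > len(pool):
        raise ValueError(
            f"requested {count} negatives but only {len(pool)} eligible "
            f"DRACH adenosines exist (shortfall {count - len(pool)})"
        )
    idx = rng.choice(len(pool), size=count, replace=False)
    return [pool[i] for i in sorted(idx)]


def split_dataset(
    positives: Sequence[LabeledSite], spec: SplitSpec
) -> tuple[list[LabeledSite], list[LabeledSite]]:
    """Random train/test split of the positives.

    ``round(train_fraction * n)`` sites go to training, the rest to
    testing; the two parts are disjoint and their union is the input.
    Duplicate (transcript_id, pos) records collapse to one.
    """
    uniq: dict = {}
    for p in positives:
        uniq.setdefault(p.key, p)
    records = list(uniq.values())
    if len(records) < 2:
        raise ValueError("need at least 2 positive sites to split")
    rng = np.random.default_rng(spec.seed)
    order = rng.permutation(len(records))
    n_train = round(spec.train_fraction * len(records))
    train = [records[i] for i in order[:n_train]]
    test = [records[i] for i in order[n_train:]]
    return train, test


def build_training_set(
    train_pos: Sequence[LabeledSite],
    negatives_pool: Sequence[LabeledSite],
    rng: np.random.Generator,
    exclude: Iterable[tuple] = (),
) -> list[LabeledSite]:
    """Balanced (1:1) training set: the positives plus as many negatives."""
    return _with_sampled_negatives(train_pos, negatives_pool, len(train_pos), rng, exclude)


def build_test_set(
    test_pos: Sequence[LabeledSite],
    negatives_pool: Sequence[LabeledSite],
    rng: np.random.Generator,
    ratio: int = 10,
    exclude: Iterable[tuple] = (),
) -> list[LabeledSite]:
    """Unbalanced test set with ``ratio`` negatives per positive."""
    return _with_sampled_negatives(
        test_pos, negatives_pool, ratio * len(test_pos), rng, exclude
    )


def _with_sampled_negatives(positives, pool, n_neg, rng, exclude):
    pos_keys = {p.key for p in positives}
    excluded = set(exclude) | pos_keys
    avail = [s for s in pool if s.key not in excluded]
    if n_neg > len(avail):
        raise ValueError(
            f"negative pool too small: need {n_neg}, have {len(avail)} "
            f"(shortfall {n_neg - len(avail)})"
        )
    idx = rng.choice(len(avail), size=n_neg, replace=False)
    sampled = [avail[i] for i in sorted(idx)]
    return list(positives) + sampled


def build_datasets(
    transcripts: Sequence[Transcript],
    positives: Sequence[LabeledSite],
    spec: SplitSpec,
    excluded_intervals: Iterable[tuple] = (),
    min_separation: int = 101,
) -> tuple[list[LabeledSite], list[LabeledSite]]:
    """End-to-end dataset assembly with global train/test disjointness.

    Splits positives 75/25 (per ``spec``), samples training negatives
    1:1 and test negatives 1:``spec.test_neg_ratio`` from the eligible
    pool, and asserts that no (transcript_id, pos) occurs in both sets.

    Test negatives are additionally required to lie at least
    ``min_separation`` nt from every training-set site, so that no
    101-nt feature window of the independent test set shares sequence
    with a training window.  On a full transcriptome such collisions
    are vanishingly rare; at simulation scale they would leak training
    content into the evaluation.
    """
    train_pos, test_pos = split_dataset(positives, spec)
    rng = np.random.default_rng(spec.seed + 1)
    pool = eligible_negatives(transcripts, positives, excluded_intervals)
    train = build_training_set(train_pos, pool, rng)
    train_keys = {s.key for s in train}
    guard = _interval_index(
        (tid, pos - (min_separation - 1), pos + min_separation)
        for tid, pos in train_keys
    )
    test_pool = [
        s for s in pool if not _in_intervals(guard, s.transcript_id, s.pos)
    ]
    test = build_test_set(
        test_pos, test_pool, rng, ratio=spec.test_neg_ratio, exclude=train_keys
    )
    overlap = train_keys & {s.key for s in test}
    assert not overlap, f"train/test overlap at {sorted(overlap)[:5]}"
    return train, test


def pool_taxa(*datasets: Sequence[LabeledSite]) -> list[LabeledSite]:
    """Concatenate per-taxon datasets, keeping taxon provenance."""
    out: list[LabeledSite] = []
    for part in datasets:
        out.extend(part)
    return out


# ---------------------------------------------------------------------------
# plain-text I/O

def read_sites_tsv(path: Union[str, Path]) -> list[LabeledSite]:
    """Read labeled sites from TSV (transcript_id, pos, label[, taxon])."""
    df = pd.read_csv(path, sep="\t", dtype={"transcript_id": str})
    required = {"transcript_id", "pos", "label"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    has_taxon = "taxon" in df.columns
    return [
        LabeledSite(
            row.transcript_id,
            int(row.pos),
            row.label,
            taxon=(None if not has_taxon or pd.isna(row.taxon) else row.taxon),
        )
        for row in df.itertuples()
    ]


def write_sites_tsv(sites: Iterable[LabeledSite], path: Union[str, Path]) -> None:
    rows = [
        {"transcript_id": s.transcript_id, "pos": s.pos, "label": s.label,
         "taxon": s.taxon}
        for s in sites
    ]
    df = pd.DataFrame(rows, columns=["transcript_id", "pos", "label", "taxon"])
    if df["taxon"].isna().all():
        df = df.drop(columns=["taxon"])
    df.to_csv(path, sep="\t", index=False)


def read_exclusion_bed(path: Union[str, Path]) -> list[tuple]:
    """Exclusion intervals as (chrom, start, end) from a BED file."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}: BED line with <3 columns: {line!r}")
            out.append((parts[0], int(parts[1]), int(parts[2])))
    return out


def write_split_manifest(path: Union[str, Path], spec: SplitSpec, **counts) -> None:
    """Small key=value manifest recording the split parameters."""
    with open(path, "w") as fh:
        fh.write(f"train_fraction={spec.train_fraction}\n")
        fh.write(f"test_neg_ratio={spec.test_neg_ratio}\n")
        fh.write(f"seed={spec.seed}\n")
        for key, val in counts.items():
            fh.write(f"{key}={val}\n")
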