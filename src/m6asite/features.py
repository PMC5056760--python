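"""Fixed-order feature encoding of candidate m6A sites.

Two prediction modes share the same building blocks but combine them
differently:

* mature mRNA mode (366 dimensions):
  11-nt positional one-hot (44) + 3-mer spectrum (64) + 4-mer spectrum
  (256) over the 101-nt window + relative transcript position (1) +
  structure-stability Z-score (1);
* full transcript mode (444 dimensions):
  31-nt positional one-hot (124) + 3-mer spectrum (64) + 4-mer
  spectrum (256).

The positional code maps A -> 0001, T -> 0010, C -> 0100, G -> 1000,
i.e. the four bits read left-to-right as (G, C, T, A); the gap
character 'N' encodes as 0000.  k-mer frequencies are counted over the
101-nt window centred on the site; k-mers containing 'N' are skipped
and excluded from the normalizing denominator.  Relative position is
pos / (len - 1), so both transcript ends are attainable.  Feature
extraction is a pure function of (sequence, position, mode, seed).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from itertools import product
from typing import Optional, Sequence

import numpy as np

from .folding import Folder, mfe_zscore
from .sequences import CandidateSite, Transcript, extract_window

#: flanking bases on each side of the site in the positional one-hot
POSITIONAL_FLANK = {"mature": 5, "full": 15}
#: 101-nt window (site +/- 50) used for the k-mer spectrum and folding
CONTEXT_FLANK = 50
CONTEXT_LEN = 2 * CONTEXT_FLANK + 1
KMER_KS = (3, 4)
N_SHUFFLES = 100

_BITS = {
    "A": (0.0, 0.0, 0.0, 1.0),
    "T": (0.0, 0.0, 1.0, 0.0),
    "C": (0.0, 1.0, 0.0, 0.0),
    "G": (1.0, 0.0, 0.0, 0.0),
    "N": (0.0, 0.0, 0.0, 0.0),
}
_BIT_ORDER = "GCTA"  # bit identity left-to-right within one position

_KMER_INDEX = {
    k: {"".join(p): i for i, p in enumerate(product("ACGT", repeat=k))}
    for k in KMER_KS
}


@dataclass(frozen=True)
class FeatureVector:
    """Encoded candidate: values plus the named block layout."""

    values: np.ndarray
    mode: str
    layout: tuple  # of (block_name, length)

    def __len__(self) -> int:
        return len(self.values)


def feature_dim(mode: str) -> int:
    flank = POSITIONAL_FLANK[mode]
    dim = (2 * flank + 1) * 4 + sum(4 ** k for k in KMER_KS)
    if mode == "mature":
        dim += 2  # relative position + structure Z-score
    return dim


def feature_layout(mode: str) -> tuple:
    flank = POSITIONAL_FLANK[mode]
    blocks = [
        ("positional", (2 * flank + 1) * 4),
        ("kmer3", 4 ** 3),
        ("kmer4", 4 ** 4),
    ]
    if mode == "mature":
        blocks += [("relpos", 1), ("structure", 1)]
    return tuple(blocks)


def feature_names(mode: str) -> list[str]:
    """Column names in vector order (e.g. pos_-5_G, kmer3_AAC, relpos)."""
    flank = POSITIONAL_FLANK[mode]
    names = [
        f"pos_{off}_{base}"
        for off in range(-flank, flank + 1)
        for base in _BIT_ORDER
    ]
    for k in KMER_KS:
        names += [f"kmer{k}_{mer}" for mer in _KMER_INDEX[k]]
    if mode == "mature":
        names += ["relpos", "struct_z"]
    return names


def encode_positional(window: str) -> np.ndarray:
    """Per-position 4-bit one-hot of a window, concatenated 5'->3'."""
    out = np.empty(4 * len(window))
    for i, ch in enumerate(window):
        try:
            out[4 * i : 4 * i + 4] = _BITS[ch]
        except KeyError:
            raise ValueError(f"unexpected character {ch!r} in window") from None
    return out


def kmer_spectrum(
    window: str, ks: Sequence[int] = KMER_KS, window_len: int = CONTEXT_LEN
) -> np.ndarray:
    """k-mer frequency spectrum of the 101-nt context window.

    For each k the counts over the sliding windows are divided by the
    number of k-mers actually counted; windows containing 'N' do not
    count toward the denominator.  Within each k the order is
    lexicographic (A < C < G < T); blocks are concatenated by
    increasing k.
    """
    if len(window) != window_len:
        raise ValueError(
            f"expected a {window_len}-nt window, got {len(window)} nt"
        )
    blocks = []
    for k in ks:
        index = _KMER_INDEX.get(k) or {
            "".join(p): i for i, p in enumerate(product("ACGT", repeat=k))
        }
        counts = np.zeros(4 ** k)
        total = 0
        for i in range(len(window) - k + 1):
            mer = window[i : i + k]
            idx = index.get(mer)
            if idx is not None:  # skip k-mers containing 'N'
                counts[idx] += 1
                total += 1
        blocks.append(counts / total if total else counts)
    return np.concatenate(blocks)


def relative_position(pos: int, transcript_len: int) -> float:
    """Scaled distance from the transcript start, in [0, 1]."""
    if transcript_len < 2:
        raise ValueError("transcript_len must be >= 2")
    if not 0 <= pos < transcript_len:
        raise ValueError(f"position {pos} outside transcript of length {transcript_len}")
    return pos / (transcript_len - 1)


def site_rng_seed(base_seed: int, transcript_id: str, pos: int) -> int:
    """Stable per-site seed so shuffle-based features are reproducible
    regardless of the order in which sites are encoded."""
    h = zlib.crc32(f"{transcript_id}:{pos}".encode())
    return (int(base_seed) * 2654435761 + h) % (2 ** 31)


def assemble_features(
    site: CandidateSite,
    transcript: Transcript,
    mode: Optional[str] = None,
    seed: int = 0,
    n_shuffles: int = N_SHUFFLES,
    backend: Optional[Folder] = None,
) -> FeatureVector:
    """Encode one candidate site for its prediction mode.

    mature -> [positional(11 nt), kmer3, kmer4, relpos, struct_z];
    full   -> [positional(31 nt), kmer3, kmer4].
    """
    if site.transcript_id != transcript.id:
        raise ValueError(
            f"site belongs to {site.transcript_id!r}, not {transcript.id!r}"
        )
    if mode is None:
        mode = transcript.mode
    elif mode != transcript.mode:
        raise ValueError(
            f"requested mode {mode!r} but transcript is tagged {transcript.mode!r}"
        )
    flank = POSITIONAL_FLANK[mode]
    parts = [
        encode_positional(extract_window(transcript, site.pos, flank)),
        kmer_spectrum(extract_window(transcript, site.pos, CONTEXT_FLANK)),
    ]
    if mode == "mature":
        parts.append(np.array([relative_position(site.pos, len(transcript))]))
        rng = np.random.default_rng(site_rng_seed(seed, site.transcript_id, site.pos))
        z = mfe_zscore(
            extract_window(transcript, site.pos, CONTEXT_FLANK),
            n_shuffles=n_shuffles,
            rng=rng,
            backend=backend,
        )
        parts.append(np.array([z]))
    return FeatureVector(np.concatenate(parts), mode, feature_layout(mode))


def assemble_matrix(
    sites: Sequence[CandidateSite],
    transcripts: dict,
    mode: str,
    seed: int = 0,
    n_shuffles: int = N_SHUFFLES,
    backend: Optional[Folder] = None,
) -> np.ndarray:
    """Stack feature vectors for many sites into an (n, d) matrix.

    ``transcripts`` maps transcript id -> Transcript.
    """
    rows = []
    for site in sites:
        t = transcripts[site.transcript_id]
        rows.append(
            assemble_features(
                site, t, mode=mode, seed=seed, n_shuffles=n_shuffles, backend=backend
            ).values
        )
    return np.vstack(rows) if rows else np.empty((0, feature_dim(mode)))


def features_to_tsv(matrix: np.ndarray, mode: str, path) -> None:
    """Export a feature matrix as TSV with one named column per feature."""
    import pandas as pd

    pd.DataFrame(matrix, columns=feature_names(mode)).to_csv(
        path, sep="\t", index=False
    )
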