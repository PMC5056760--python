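"""Synthetic transcripts with planted m6A signal for testing the pipeline.

The generator emulates the signal structure the predictor's features
are designed to detect, without any external data:

* background transcripts are i.i.d. draws from configurable nucleotide
  frequencies, with lengths uniform in a range;
* positive sites are planted by writing an 11-nt context sampled from a
  per-position categorical profile (a PWM) whose centre is always a
  DRACH-consistent pentamer; ``signal_strength`` in [0, 1] interpolates
  the profile between the background composition (0, no signal) and a
  sharp consensus (1);
* positive placement can be biased toward the 3' end of transcripts
  (Beta-distributed relative position), mirroring the known enrichment
  of m6A near stop codons / 3' ends;
* optionally, a complementary stem is written around a fraction of the
  positives so their 101-nt windows fold more stably than shuffled
  composition-mates, giving the structure Z-score feature something to
  find.

Planted sites are kept >= 50 nt apart so truth labels are unambiguous.
A JSON-able manifest of every generative parameter (including the
seed) suffices to regenerate a bundle bit-identically.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np

from .datasets import LabeledSite, write_sites_tsv
from .sequences import (
    DRACH_D,
    DRACH_H,
    DRACH_R,
    Transcript,
    scan_drach,
    write_fasta,
)

BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: consensus context written at full signal strength (offsets -5..+5);
#: the centre pentamer GGACT is the canonical methylation consensus
CONSENSUS_CONTEXT = "TGTGGGACTGA"
#: offsets -2..+2 constrained to the DRACH classes when sampling
_DRACH_CLASSES = {-2: DRACH_D, -1: DRACH_R, 0: {"A"}, 1: {"C"}, 2: DRACH_H}

MIN_SITE_SPACING = 50
#: margin keeping the planted context and its optional stem inside the
#: sequence; kept small so planted sites see transcript edges (and the
#: resulting N-padded windows) about as often as background sites do
_EDGE_MARGIN = 25


@dataclass(frozen=True)
class SyntheticConfig:
    """Generative parameters; defaults give a strongly separable bundle."""

    n_transcripts: int = 200
    length_min: int = 1200
    length_max: int = 2000
    background: tuple = (0.25, 0.25, 0.25, 0.25)  # A, C, G, T
    n_positive: int = 300
    signal_strength: float = 0.8
    three_prime_bias: bool = True
    structure_signal: bool = True
    structure_fraction: float = 0.5
    min_spacing: int = MIN_SITE_SPACING
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.background) - 1.0) > 1e-9:
            raise ValueError("background frequencies must sum to 1")
        if not 0.0 <= self.signal_strength <= 1.0:
            raise ValueError("signal_strength must be in [0, 1]")
        if self.length_min < 2 * _EDGE_MARGIN + 1:
            raise ValueError(f"length_min must be >= {2 * _EDGE_MARGIN + 1}")

    def to_manifest(self) -> dict:
        return asdict(self)

    @classmethod
    def from_manifest(cls, manifest: dict) -> "SyntheticConfig":
        d = dict(manifest)
        d["background"] = tuple(d["background"])
        return cls(**d)


def null_config(seed: int = 0, **overrides) -> SyntheticConfig:
    """Zero planted signal: positives indistinguishable from background.

    Sized larger than the default bundle so that a held-out AUROC has
    a tight enough sampling distribution to detect leakage.
    """
    params = dict(
        signal_strength=0.0, three_prime_bias=False, structure_signal=False,
        n_transcripts=700, n_positive=1200, seed=seed,
    )
    params.update(overrides)
    return SyntheticConfig(**params)


def generate_background(config: SyntheticConfig) -> list[Transcript]:
    """i.i.d. background transcripts; deterministic given the seed."""
    rng = np.random.default_rng(config.seed)
    transcripts = []
    for i in range(config.n_transcripts):
        length = int(rng.integers(config.length_min, config.length_max + 1))
        seq = "".join(
            rng.choice(list(BASES), size=length, p=list(config.background))
        )
        transcripts.append(Transcript(f"syn{i:05d}", seq))
    return transcripts


def _context_profile(config: SyntheticConfig) -> list[dict]:
    """Per-offset base distributions of the planted 11-nt context."""
    bg = dict(zip(BASES, config.background))
    s = config.signal_strength
    profile = []
    for off in range(-5, 6):
        preferred = CONSENSUS_CONTEXT[off + 5]
        allowed = _DRACH_CLASSES.get(off, set(BASES))
        probs = {}
        for base in BASES:
            if base not in allowed:
                probs[base] = 0.0
                continue
            p_bg = bg[base] / sum(bg[b] for b in allowed)
            probs[base] = (1 - s) * p_bg + s * (1.0 if base == preferred else 0.0)
        total = sum(probs.values())
        profile.append({b: p / total for b, p in probs.items()})
    return profile


def _sample_context(profile: list[dict], rng: np.random.Generator) -> str:
    return "".join(
        rng.choice(list(p.keys()), p=list(p.values())) for p in profile
    )


def plant_positive_sites(
    transcripts: list[Transcript], config: SyntheticConfig
) -> tuple[list[Transcript], list[LabeledSite]]:
    """Write positive contexts into the transcripts; return both.

    Placement: relative position ~ Beta(4, 1.5) under 3'-bias (mean
    ~0.73), uniform otherwise, rejected when closer than
    ``min_spacing`` to an already-planted site.
    """
    rng = np.random.default_rng(config.seed + 1)
    profile = _context_profile(config)
    seqs = {t.id: list(t.seq) for t in transcripts}
    planted: dict = {t.id: [] for t in transcripts}
    ids = [t.id for t in transcripts]
    positives: list[LabeledSite] = []
    attempts = 0
    max_attempts = 200 * config.n_positive
    while len(positives) < config.n_positive:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(
                f"could not place {config.n_positive} sites with spacing "
                f"{config.min_spacing}; placed {len(positives)}"
            )
        tid = ids[int(rng.integers(len(ids)))]
        seq = seqs[tid]
        span = len(seq) - 2 * _EDGE_MARGIN
        rel = rng.beta(4.0, 1.5) if config.three_prime_bias else rng.uniform()
        pos = _EDGE_MARGIN + int(rel * span)
        pos = min(pos, len(seq) - _EDGE_MARGIN - 1)
        if any(abs(pos - q) < config.min_spacing for q in planted[tid]):
            continue
        context = _sample_context(profile, rng)
        seq[pos - 5 : pos + 6] = list(context)
        if config.structure_signal and rng.random() < config.structure_fraction:
            stem = "".join(seq[pos + 8 : pos + 23])
            seq[pos - 23 : pos - 8] = list(stem.translate(_COMPLEMENT)[::-1])
        planted[tid].append(pos)
        positives.append(LabeledSite(tid, pos, "positive"))
    out = [Transcript(t.id, "".join(seqs[t.id]), mode=t.mode) for t in transcripts]
    # planting order is rng-driven; sort for a deterministic record order
    positives.sort(key=lambda s: s.key)
    _verify_planted(out, positives)
    return out, positives


def _verify_planted(transcripts: list[Transcript], positives: list[LabeledSite]) -> None:
    by_id = {t.id: t for t in transcripts}
    for p in positives:
        cand_positions = {c.pos for c in scan_drach(by_id[p.transcript_id])}
        if p.pos not in cand_positions:
            raise AssertionError(
                f"planted site {p.transcript_id}:{p.pos} is not a DRACH candidate"
            )


@dataclass
class SyntheticBundle:
    transcripts: list[Transcript]
    positives: list[LabeledSite]
    manifest: dict

    def exclusion_intervals(self, flank: int = 100) -> list[tuple]:
        """Intervals around planted sites, for screening negatives.

        The default +/-100 nt mirrors how negatives are screened
        against known methylation *peaks* (100-200 nt regions) rather
        than against the site coordinate alone; it also keeps the
        101-nt feature windows of negatives from overlapping a planted
        context."""
        return [
            (p.transcript_id, p.pos - flank, p.pos + flank + 1)
            for p in self.positives
        ]


def generate_dataset(
    config: SyntheticConfig, out_dir: Optional[Union[str, Path]] = None
) -> SyntheticBundle:
    """Complete train/test-ready bundle (+ optional FASTA/TSV/JSON files)."""
    background = generate_background(config)
    transcripts, positives = plant_positive_sites(background, config)
    manifest = {"generator": "m6asite.synthetic", "config": config.to_manifest()}
    bundle = SyntheticBundle(transcripts, positives, manifest)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_fasta(transcripts, out_dir / "transcripts.fasta")
        write_sites_tsv(positives, out_dir / "positives.tsv")
        (out_dir / "manifest.json").write_text(
            json.dumps(manifest, indent=2) + "\n"
        )
    return bundle


def regenerate_from_manifest(manifest: dict) -> SyntheticBundle:
    """Rebuild a bundle bit-identically from its manifest."""
    return generate_dataset(SyntheticConfig.from_manifest(manifest["config"]))
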