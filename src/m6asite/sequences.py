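"""Transcript ingestion, normalization and DRACH candidate scanning.

m6A deposition is almost exclusively observed at adenosines inside the
DRACH consensus pentamer (D = A/G/T, R = A/G, the methylated A itself,
C, H = A/C/T, written in DNA alphabet).  Every downstream stage of the
predictor therefore operates on *candidate sites*: DRACH-centred
adenosines with enough flanking sequence for the 5-nt motif to lie
fully inside the transcript.

Sequences are normalized on ingestion: RNA spelling (U) is mapped to T,
case is folded, and IUPAC ambiguity codes or other letters become 'N'.
Candidates whose pentamer contains an 'N' are never emitted.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Union

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

MODES = ("mature", "full")

#: nucleotide classes of the DRACH consensus, DNA alphabet
DRACH_D = frozenset("AGT")
DRACH_R = frozenset("AG")
DRACH_H = frozenset("ACT")

_KEEP = set("ACGT")
_ALPHA_TO_N = {c: "N" for c in "BDEFHIJKLMOPQRSVWXYZN"}


class FastaError(ValueError):
    """Raised for malformed or empty FASTA input."""


def normalize_sequence(raw: str) -> str:
    """Fold case, map U->T and squash ambiguity codes to 'N'.

    Any non-alphabetic character is rejected.
    """
    s = raw.strip().upper().replace("U", "T")
    out = []
    for ch in s:
        if ch in _KEEP:
            out.append(ch)
        elif ch in _ALPHA_TO_N:
            out.append("N")
        else:
            raise ValueError(f"invalid character {ch!r} in nucleotide sequence")
    return "".join(out)


@dataclass(frozen=True)
class Transcript:
    """A named nucleotide sequence plus the prediction mode it belongs to.

    ``mode`` selects the feature set and model applied later:
    ``"mature"`` for spliced mRNA, ``"full"`` for pre-mRNA / genomic
    sequence.  It does not change how the sequence itself is handled.
    """

    id: str
    seq: str
    mode: str = "mature"

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("transcript id must be non-empty")
        if not self.seq:
            raise ValueError(f"transcript {self.id!r}: empty sequence")
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")
        bad = set(self.seq) - _KEEP - {"N"}
        if bad:
            raise ValueError(
                f"transcript {self.id!r}: un-normalized characters {sorted(bad)}; "
                "use normalize_sequence() or read_fasta()"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class CandidateSite:
    """A DRACH-centred adenosine.

    ``pos`` is the 0-based index of the (potentially methylated) A;
    ``motif`` is the pentamer ``seq[pos-2 : pos+3]``.
    """

    transcript_id: str
    pos: int
    motif: str = field(compare=False)

    @property
    def key(self) -> tuple:
        return (self.transcript_id, self.pos)


def is_drach(motif: str) -> bool:
    """True iff a 5-mer matches the DRACH consensus (DNA alphabet)."""
    return (
        len(motif) == 5
        and motif[0] in DRACH_D
        and motif[1] in DRACH_R
        and motif[2] == "A"
        and motif[3] == "C"
        and motif[4] in DRACH_H
    )


def scan_drach(transcript: Transcript) -> list[CandidateSite]:
    """All candidate m6A sites of a transcript, ascending by position.

    A candidate requires the full pentamer inside the sequence, so the
    first two and last two positions can never yield one; sequences
    shorter than 5 nt give an empty list.
    """
    seq = transcript.seq
    sites = []
    for pos in range(2, len(seq) - 2):
        if seq[pos] != "A":
            continue
        motif = seq[pos - 2 : pos + 3]
        if is_drach(motif):
            sites.append(CandidateSite(transcript.id, pos, motif))
    return sites


def extract_window(
    transcript: Union[Transcript, str], pos: int, flank: int
) -> str:
    """Window of length ``2*flank + 1`` centred at ``pos``, 'N'-padded.

    Positions falling outside the sequence are filled with the gap
    character 'N' so the window length is invariant.
    """
    seq = transcript.seq if isinstance(transcript, Transcript) else transcript
    if not 0 <= pos < len(seq):
        raise IndexError(f"position {pos} outside sequence of length {len(seq)}")
    lo, hi = pos - flank, pos + flank + 1
    core = seq[max(lo, 0) : min(hi, len(seq))]
    return "N" * max(0, -lo) + core + "N" * max(0, hi - len(seq))


def read_fasta(path: Union[str, Path], mode: str = "mature") -> list[Transcript]:
    """Load transcripts from a FASTA file, preserving record order.

    Record ids are the first whitespace-delimited token of the header.
    Sequences are normalized (U->T, case folded, ambiguity codes -> N).
    Duplicate ids, empty records and files with no records are errors.
    """
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise FastaError(f"{path}: empty FASTA file")
    if not text.lstrip().startswith(">"):
        raise FastaError(f"{path}: not FASTA (missing '>' header)")
    transcripts: list[Transcript] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(io.StringIO(text), "fasta"):
        if rec.id in seen:
            raise FastaError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        try:
            seq = normalize_sequence(str(rec.seq))
        except ValueError as exc:
            raise FastaError(f"{path}: record {rec.id!r}: {exc}") from exc
        if not seq:
            raise FastaError(f"{path}: record {rec.id!r} has an empty sequence")
        transcripts.append(Transcript(rec.id, seq, mode=mode))
    if not transcripts:
        raise FastaError(f"{path}: no FASTA records found")
    return transcripts


def write_fasta(transcripts: Iterable[Transcript], path: Union[str, Path]) -> None:
    records = [SeqRecord(Seq(t.seq), id=t.id, description="") for t in transcripts]
    SeqIO.write(records, str(path), "fasta")


def candidates_to_bed(
    sites: Iterable[CandidateSite], path: Union[str, Path]
) -> None:
    """Export candidates as 6-column BED (one line per site, strand '+')."""
    with open(path, "w") as fh:
        for s in sites:
            fh.write(f"{s.transcript_id}\t{s.pos}\t{s.pos + 1}\t{s.motif}\t0\t+\n")
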