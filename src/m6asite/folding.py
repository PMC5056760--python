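"""Secondary-structure stability scoring for m6A context windows.

The structure feature of the predictor is a Z-score comparing the
minimum free energy (MFE) of the 101-nt window around a candidate site
with the MFE distribution of shuffled versions of the same window:

    z = (MFE(window) - mean(MFE of shuffles)) / sd(MFE of shuffles)

A window folding more stably than its shuffled composition-mates gives
z < 0.  The default folding backend is a built-in deterministic
dynamic-programming folder over pseudoknot-free structures with a
simple base-pair energy model (GC = -3, AT = -2, GT wobble = -1 energy
units, hairpin loops of at least 3 unpaired bases, 'N' pairs with
nothing).  An adapter seam allows an external folder (e.g. RNAfold) to
be plugged in instead; the same backend must be used for a window and
all of its shuffles, so the Z-score is backend-consistent even though
absolute energies differ between backends.
"""

from __future__ import annotations

import re
import subprocess
from dataclasses import dataclass
from typing import Optional, Protocol, Sequence

import numpy as np
from numba import njit

#: minimum number of unpaired bases enclosed by a pair (hairpin loop)
MIN_LOOP = 3

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}

# pair energies, symmetric; 0.0 means "cannot pair"
_PAIR_ENERGY = np.zeros((5, 5))
_PAIR_ENERGY[_CODE["G"], _CODE["C"]] = _PAIR_ENERGY[_CODE["C"], _CODE["G"]] = -3.0
_PAIR_ENERGY[_CODE["A"], _CODE["T"]] = _PAIR_ENERGY[_CODE["T"], _CODE["A"]] = -2.0
_PAIR_ENERGY[_CODE["G"], _CODE["T"]] = _PAIR_ENERGY[_CODE["T"], _CODE["G"]] = -1.0


@dataclass(frozen=True)
class FoldResult:
    """MFE of a sequence and, optionally, one optimal structure."""

    mfe: float
    structure: Optional[str] = None


class Folder(Protocol):
    """Backend contract: map a sequence to its reported MFE."""

    name: str

    def mfe(self, seq: str) -> float: ...


def _encode(seq: str) -> np.ndarray:
    try:
        return np.array([_CODE[c] for c in seq], dtype=np.int8)
    except KeyError as exc:
        raise ValueError(f"invalid nucleotide {exc.args[0]!r}") from exc


@njit(cache=True)
def _energy_matrix(codes, pair_e):  # pragma: no cover - jitted
    n = codes.shape[0]
    E = np.zeros((n, n))
    for span in range(1, n):
        for i in range(0, n - span):
            j = i + span
            best = E[i + 1, j]
            if E[i, j - 1] < best:
                best = E[i, j - 1]
            if span > MIN_LOOP:
                e = pair_e[codes[i], codes[j]]
                if e < 0.0:
                    cand = E[i + 1, j - 1] + e
                    if cand < best:
                        best = cand
            for k in range(i + 1, j - 1):
                cand = E[i, k] + E[k + 1, j]
                if cand < best:
                    best = cand
            E[i, j] = best
    return E


def _traceback(codes: np.ndarray, E: np.ndarray) -> str:
    """Recover one optimal dot-bracket structure from the filled matrix."""
    n = len(codes)
    dots = ["."] * n
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if i >= j:
            continue
        if E[i, j] == E[i + 1, j]:
            stack.append((i + 1, j))
            continue
        if E[i, j] == E[i, j - 1]:
            stack.append((i, j - 1))
            continue
        e = _PAIR_ENERGY[codes[i], codes[j]]
        if j - i > MIN_LOOP and e < 0.0 and E[i, j] == E[i + 1, j - 1] + e:
            dots[i], dots[j] = "(", ")"
            stack.append((i + 1, j - 1))
            continue
        for k in range(i + 1, j - 1):
            if E[i, j] == E[i, k] + E[k + 1, j]:
                stack.append((i, k))
                stack.append((k + 1, j))
                break
        else:  # defensive; cannot happen on a correctly filled matrix
            raise RuntimeError("traceback failed")
    return "".join(dots)


class BuiltinFolder:
    """Deterministic Nussinov-style folder with weighted pairs.

    Maximizes the (negative) sum of pair energies over all
    pseudoknot-free structures with hairpin loops >= MIN_LOOP.
    Energies are in arbitrary units, not kcal/mol.
    """

    name = "builtin"

    def mfe(self, seq: str) -> float:
        codes = _encode(seq)
        return float(_energy_matrix(codes, _PAIR_ENERGY)[0, len(codes) - 1])


class CommandLineFolder:
    """Adapter for an external folding program (e.g. ``RNAfold --noPS``).

    The program receives the sequence on stdin and must print the MFE
    as the last parenthesized float of its output, the convention of
    the ViennaRNA tools.
    """

    _MFE_RE = re.compile(r"\(\s*(-?\d+(?:\.\d+)?)\s*\)\s*$")

    def __init__(self, argv: Sequence[str] = ("RNAfold", "--noPS")):
        self.argv = list(argv)
        self.name = self.argv[0]

    def mfe(self, seq: str) -> float:
        proc = subprocess.run(
            self.argv, input=seq + "\n", capture_output=True, text=True, check=True
        )
        for line in reversed(proc.stdout.strip().splitlines()):
            m = self._MFE_RE.search(line.strip())
            if m:
                return float(m.group(1))
        raise ValueError(
            f"{self.name}: could not parse an MFE from output:\n{proc.stdout}"
        )


_DEFAULT_FOLDER = BuiltinFolder()


def fold_mfe(
    seq: str, backend: Optional[Folder] = None, with_structure: bool = False
) -> FoldResult:
    """Fold a sequence and return its minimum free energy.

    With the built-in backend, ``with_structure=True`` additionally
    returns one optimal dot-bracket structure.  External backends
    report only the energy.
    """
    if not seq:
        raise ValueError("cannot fold an empty sequence")
    if backend is None or isinstance(backend, BuiltinFolder):
        codes = _encode(seq)
        E = _energy_matrix(codes, _PAIR_ENERGY)
        mfe = float(E[0, len(codes) - 1])
        structure = _traceback(codes, E) if with_structure else None
        return FoldResult(mfe=mfe, structure=structure)
    return FoldResult(mfe=float(backend.mfe(seq)))


def shuffle_sequence(seq: str, rng: np.random.Generator) -> str:
    """Uniform random permutation of the characters of ``seq``.

    Mononucleotide composition is preserved exactly; the result is
    deterministic given the generator state.
    """
    if not seq:
        raise ValueError("cannot shuffle an empty sequence")
    return "".join(rng.permutation(list(seq)))


def mfe_zscore(
    seq: str,
    n_shuffles: int = 100,
    rng: Optional[np.random.Generator] = None,
    backend: Optional[Folder] = None,
) -> float:
    """Structure-stability Z-score of a window against its shuffles.

    The window MFE is compared with the MFE of ``n_shuffles``
    mononucleotide shuffles; the spread uses the sample (n-1) standard
    deviation.  Degenerate windows whose shuffles all fold to the same
    energy (sd == 0, e.g. homopolymers) return 0.0 by convention.
    """
    if n_shuffles < 2:
        raise ValueError("n_shuffles must be >= 2")
    if rng is None:
        rng = np.random.default_rng(0)
    observed = fold_mfe(seq, backend=backend).mfe
    null = np.array(
        [fold_mfe(shuffle_sequence(seq, rng), backend=backend).mfe
         for _ in range(n_shuffles)]
    )
    sd = float(np.std(null, ddof=1))
    if sd == 0.0:
        return 0.0
    return float((observed - null.mean()) / sd)
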