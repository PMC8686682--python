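"""Validated sequences with break-aware windowing.

A :class:`Sequence` is a string over a finite alphabet (DNA by default).
Characters outside the alphabet (``N`` runs, IUPAC ambiguity codes, record
boundaries in multi-record FASTA) act as *breaks*: no k-mer, window or
context may span them, so the sequence decomposes into independent
fragments.  All positions are 0-based; a k-mer's position is its start.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np

DNA = "ACGT"

#: character used to join records / mark breaks when round-tripping
BREAK_CHAR = "N"


class TooShortError(ValueError):
    """Raised when no fragment admits a single window of w k-mers."""


@dataclass(frozen=True)
class Sequence:
    """A string over a finite alphabet with window-break bookkeeping.

    Parameters
    ----------
    text:
        Raw residues (case-insensitive).  Characters outside ``alphabet``
        are kept in place but treated as breaks.
    alphabet:
        Ordered alphabet; its length is sigma.  Must have 2..16 symbols.
    """

    text: str
    alphabet: str = DNA
    codes: np.ndarray = field(init=False, repr=False, compare=False)
    fragments: tuple[tuple[int, int], ...] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not 2 <= len(self.alphabet) <= 16:
            raise ValueError("alphabet size must be in [2, 16]")
        object.__setattr__(self, "text", self.text.upper())
        lut = np.full(256, -1, dtype=np.int16)
        for i, ch in enumerate(self.alphabet.upper()):
            lut[ord(ch)] = i
            lut[ord(ch.lower())] = i
        raw = np.frombuffer(self.text.encode("ascii"), dtype=np.uint8)
        codes = lut[raw]
        codes.flags.writeable = False
        object.__setattr__(self, "codes", codes)
        object.__setattr__(self, "fragments", _runs(codes >= 0))

    # ------------------------------------------------------------------
    @property
    def sigma(self) -> int:
        return len(self.alphabet)

    def __len__(self) -> int:
        return len(self.text)

    @property
    def breaks(self) -> np.ndarray:
        """Positions of non-alphabet characters."""
        return np.flatnonzero(self.codes < 0)

    # ------------------------------------------------------------------
    def kmer_codes(self, k: int) -> tuple[np.ndarray, np.ndarray]:
        """Packed integer code of every k-mer start, plus a validity mask.

        Returns ``(codes, valid)`` of length ``len(self) - k + 1`` (empty if
        the sequence is shorter than k).  ``codes[i]`` packs the k residues
        starting at i in base sigma; it is meaningless where ``valid`` is
        False (k-mer spans a break or runs off the end).
        """
        if k < 1:
            raise ValueError("k must be >= 1")
        if k * np.log2(self.sigma) > 62:
            raise ValueError("k too large to pack into 63-bit codes")
        n = len(self.text)
        if n < k:
            return np.empty(0, np.int64), np.empty(0, bool)
        c = self.codes
        win = np.lib.stride_tricks.sliding_window_view(c, k)
        powers = (self.sigma ** np.arange(k - 1, -1, -1)).astype(np.int64)
        packed = win.astype(np.int64) @ powers
        valid = (win >= 0).all(axis=1)
        return packed, valid

    def kmer_starts(self, k: int) -> np.ndarray:
        """Sorted array of valid k-mer start positions."""
        _, valid = self.kmer_codes(k)
        return np.flatnonzero(valid)

    def n_kmers(self, k: int) -> int:
        return int(self.kmer_codes(k)[1].sum())

    def kmer_at(self, pos: int, k: int) -> str:
        word = self.text[pos : pos + k]
        if len(word) < k or any(ch not in self.alphabet for ch in word):
            raise ValueError(f"position {pos} is not a valid {k}-mer start")
        return word

    def window_fragments(self, w: int, k: int) -> list[tuple[int, int]]:
        """Fragments long enough to hold at least one window of w k-mers."""
        need = w + k - 1
        return [(a, b) for a, b in self.fragments if b - a >= need]

    def require_windows(self, w: int, k: int) -> list[tuple[int, int]]:
        frags = self.window_fragments(w, k)
        if not frags:
            raise TooShortError(
                f"no fragment of length >= w+k-1 = {w + k - 1} (|S| = {len(self)})"
            )
        return frags


def _runs(mask: np.ndarray) -> tuple[tuple[int, int], ...]:
    """Half-open (start, end) runs of True in a boolean array."""
    if mask.size == 0:
        return ()
    edges = np.flatnonzero(np.diff(mask.astype(np.int8)))
    starts = list(edges[mask[edges + 1]] + 1)
    ends = list(edges[~mask[edges + 1]] + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        ends.append(mask.size)
    return tuple(zip(starts, ends))


# ----------------------------------------------------------------------
# FASTA I/O (Biopython-backed)
# ----------------------------------------------------------------------

def read_fasta(path_or_handle, alphabet: str = DNA) -> Sequence:
    """Read a (multi-record) FASTA file into one Sequence.

    Records are concatenated with a single break character between them so
    no window can span a record boundary.
    """
    from Bio import SeqIO

    if isinstance(path_or_handle, (str, bytes)):
        handle: io.TextIOBase | str = str(path_or_handle)
    else:
        handle = path_or_handle
    parts = [str(rec.seq) for rec in SeqIO.parse(handle, "fasta")]
    if not parts:
        raise ValueError("no FASTA records found")
    return Sequence(BREAK_CHAR.join(parts), alphabet=alphabet)


def write_fasta(path, seq: str | Sequence, name: str = "seq", width: int = 70) -> None:
    text = seq.text if isinstance(seq, Sequence) else seq
    with open(path, "w") as fh:
        fh.write(f">{name}\n")
        for i in range(0, len(text), width):
            fh.write(text[i : i + width] + "\n")
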