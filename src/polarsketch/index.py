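"""Suffix-array index and the linked-blocks structure.

:class:`SuffixIndex` holds the suffix array, inverse suffix array and LCP
(heights) table of the sequence text, built once per sequence with numpy
prefix doubling.  For a fixed k it answers "all positions sharing the
k-mer at position t" by scanning outward from isa[t] while LCP >= k, in
time proportional to the occurrence count.

:class:`LinkedBlocks` stores a set of selected positions at most one per
block of width h = floor(w/2) — guaranteed for polar occurrences since
their pairwise spacing exceeds w/2 — and maintains the link-energy
aggregates (Acov, Aele, Aseg, L) incrementally under add/remove, using
only nearest-neighbour (peek) queries that touch a constant number of
blocks.
"""

from __future__ import annotations

import numpy as np

from .sequence import Sequence


# ----------------------------------------------------------------------
# Suffix array construction
# ----------------------------------------------------------------------

def build_suffix_array(text: bytes | np.ndarray) -> np.ndarray:
    """Suffix array by prefix doubling (numpy lexsort), O(n log^2 n)."""
    s = np.frombuffer(text, dtype=np.uint8) if isinstance(text, (bytes, bytearray)) else np.asarray(text)
    n = s.size
    if n == 0:
        return np.empty(0, np.int64)
    rank = np.unique(s, return_inverse=True)[1].astype(np.int64)
    step = 1
    idx = np.arange(n)
    while True:
        key2 = np.full(n, -1, np.int64)
        key2[: n - step] = rank[step:]
        order = np.lexsort((key2, rank))
        new_rank = np.empty(n, np.int64)
        diff = np.ones(n, bool)
        diff[1:] = (rank[order[1:]] != rank[order[:-1]]) | (
            key2[order[1:]] != key2[order[:-1]]
        )
        new_rank[order] = np.cumsum(diff) - 1
        rank = new_rank
        if rank[order[-1]] == n - 1:
            return order
        step *= 2
        _ = idx  # keep flake quiet


def lcp_kasai(s: np.ndarray, sa: np.ndarray, isa: np.ndarray) -> np.ndarray:
    """Heights table: lcp[i] = LCP of suffixes sa[i-1] and sa[i] (lcp[0]=0)."""
    n = s.size
    lcp = np.zeros(n, np.int64)
    h = 0
    for i in range(n):
        r = isa[i]
        if r > 0:
            j = sa[r - 1]
            while i + h < n and j + h < n and s[i + h] == s[j + h]:
                h += 1
            lcp[r] = h
            if h:
                h -= 1
        else:
            h = 0
    return lcp


class SuffixIndex:
    """Suffix array / inverse / LCP of a sequence, serving k-mer queries."""

    def __init__(self, seq: Sequence, k: int):
        if k < 1:
            raise ValueError("k must be >= 1")
        self.seq = seq
        self.k = k
        self.n = len(seq)
        self._s = np.frombuffer(seq.text.encode("ascii"), dtype=np.uint8)
        self.sa = build_suffix_array(self._s)
        self.isa = np.empty(self.n, np.int64)
        self.isa[self.sa] = np.arange(self.n)
        self.lcp = lcp_kasai(self._s, self.sa, self.isa)

    def occurrences(self, t: int) -> list[int]:
        """All positions whose k-mer equals the k-mer at t, sorted.

        Scans outward from isa[t] while the heights table stays >= k, so
        the cost is proportional to the number of occurrences.
        """
        if not 0 <= t <= self.n - self.k:
            raise IndexError(f"position {t} is not a valid {self.k}-mer start")
        r = self.isa[t]
        lo = r
        while lo > 0 and self.lcp[lo] >= self.k:
            lo -= 1
        hi = r
        while hi + 1 < self.n and self.lcp[hi + 1] >= self.k:
            hi += 1
        out = sorted(int(p) for p in self.sa[lo : hi + 1] if p <= self.n - self.k)
        return out

    def kmer_counts(self) -> np.ndarray:
        """Occurrence count of the k-mer starting at each position.

        Entries are 0 where no valid k-mer starts (breaks or tail).
        Positions in the same LCP-run (>= k shared prefix) share a count.
        """
        n, k = self.n, self.k
        group = np.cumsum(self.lcp < k) - 1  # group id per sa rank
        # group sizes counted over suffixes long enough to hold a k-mer
        long_enough = self.sa <= n - k
        sizes = np.bincount(group[long_enough], minlength=group[-1] + 1 if n else 0)
        counts = np.zeros(n, np.int64)
        counts[self.sa[long_enough]] = sizes[group[long_enough]]
        _, valid = self.seq.kmer_codes(k)
        full = np.zeros(n, np.int64)
        full[: valid.size][valid] = counts[: valid.size][valid]
        return full


# ----------------------------------------------------------------------
# Linked blocks
# ----------------------------------------------------------------------

class LinkedBlocks:
    """Block array of selected positions with incremental link-energy stats.

    Positions live in blocks of width h = floor(w/2); each block holds at
    most one selected position (``add`` on an occupied block is an error).
    The maintained aggregates treat every stored position as an uncovered
    polar occurrence:

    - ``Aele``: number of stored positions;
    - ``Aseg``: maximal runs at consecutive gaps <= w;
    - ``Acov``: context slots [t-w, t] covered by any stored position
      (counted on the unclipped context line, so the identity below is
      exact everywhere, including near fragment ends);
    - ``L`` = 2*Acov/(w+1) - Aele - Aseg, tracked as an integer numerator
      scaled by (w+1) and equal to the pairwise link-energy sum.
    """

    def __init__(self, n: int, w: int):
        if w < 2:
            raise ValueError("w must be >= 2")
        self.n = n
        self.w = w
        self.h = w // 2
        nblocks = (n + self.h - 1) // self.h if n else 0
        self.C = np.full(nblocks, -1, np.int64)
        self.Acov = 0
        self.Aele = 0
        self.n_links = 0
        self.Lnum = 0  # (w+1) * L

    # -- queries --------------------------------------------------------
    @property
    def Aseg(self) -> int:
        return self.Aele - self.n_links

    @property
    def L(self) -> float:
        return self.Lnum / (self.w + 1)

    def __contains__(self, x: int) -> bool:
        b = x // self.h
        return 0 <= b < self.C.size and self.C[b] == x - b * self.h

    def positions(self) -> np.ndarray:
        """Sorted stored positions (linear scan; for checks and exports)."""
        occupied = np.flatnonzero(self.C >= 0)
        return occupied * self.h + self.C[occupied]

    def peek_left(self, x: int) -> int | None:
        """Closest stored position p with x - w <= p <= x (x itself counts)."""
        return self._scan(x, inclusive=True, left=True)

    def peek_right(self, x: int) -> int | None:
        """Closest stored position p with x <= p <= x + w."""
        return self._scan(x, inclusive=True, left=False)

    def _scan(self, x: int, *, inclusive: bool, left: bool) -> int | None:
        h, w = self.h, self.w
        if left:
            lo_block = max(0, (x - w) // h)
            blocks = range(min(x // h, self.C.size - 1), lo_block - 1, -1)
        else:
            hi_block = min((x + w) // h, self.C.size - 1)
            blocks = range(max(0, x // h), hi_block + 1)
        for b in blocks:
            off = self.C[b]
            if off < 0:
                continue
            p = b * h + off
            if left:
                if (p < x or (inclusive and p == x)) and x - p <= w:
                    return int(p)
            else:
                if (p > x or (inclusive and p == x)) and p - x <= w:
                    return int(p)
        return None

    def _neighbor_left(self, x: int) -> int | None:
        """Nearest stored p strictly left of x with x - p <= w."""
        return self._scan(x, inclusive=False, left=True)

    def _neighbor_right(self, x: int) -> int | None:
        return self._scan(x, inclusive=False, left=False)

    # -- updates --------------------------------------------------------
    def add(self, x: int) -> float:
        """Insert x; returns the link-energy change.  Block must be empty."""
        b = x // self.h
        if not 0 <= x < self.n:
            raise IndexError(f"position {x} out of range")
        if self.C[b] != -1:
            raise ValueError(f"block {b} already holds position {b * self.h + self.C[b]}")
        before = self.Lnum
        p = self._neighbor_left(x)
        q = self._neighbor_right(x)
        self._apply_neighbors(x, p, q, sign=+1)
        self.C[b] = x - b * self.h
        self.Aele += 1
        return (self.Lnum - before) / (self.w + 1)

    def remove(self, x: int) -> float:
        """Delete x; returns the link-energy change.  x must be stored."""
        b = x // self.h
        if not (0 <= b < self.C.size and self.C[b] == x - b * self.h):
            raise ValueError(f"position {x} is not selected")
        before = self.Lnum
        self.C[b] = -1
        p = self._neighbor_left(x)
        q = self._neighbor_right(x)
        self._apply_neighbors(x, p, q, sign=-1)
        self.Aele -= 1
        return (self.Lnum - before) / (self.w + 1)

    def _apply_neighbors(self, x: int, p: int | None, q: int | None, sign: int) -> None:
        """Stats delta for inserting (+1) or deleting (-1) x between p and q."""
        w = self.w
        cov = w + 1
        if p is not None:
            cov -= w + 1 - (x - p)
            self.n_links += sign
            self.Lnum += sign * (2 * (x - p) - (w + 1))
        if q is not None:
            cov -= w + 1 - (q - x)
            self.n_links += sign
            self.Lnum += sign * (2 * (q - x) - (w + 1))
        if p is not None and q is not None and q - p <= w:
            cov += w + 1 - (q - p)
            self.n_links -= sign
            self.Lnum -= sign * (2 * (q - p) - (w + 1))
        self.Acov += sign * cov

    # -- verification ---------------------------------------------------
    def recompute(self) -> tuple[int, int, int, int]:
        """(Acov, Aele, Aseg, Lnum) from scratch over the stored positions."""
        from .polar import link_stats_from_positions

        stats = link_stats_from_positions(self.positions(), self.w)
        return stats.Acov, stats.Aele, stats.Aseg, round(stats.L * (self.w + 1))
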