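"""Total orders on k-mers: seeded pseudo-random orders and compatible orders.

A minimizer is defined by a strict total order on k-mers.  The *random
minimizer* baseline orders k-mers by a seeded avalanche hash of the packed
k-mer code.  An order *compatible* with a priority list of k-mer sets
(layers) places every k-mer of layer i below every k-mer of layer j > i and
below every k-mer outside all layers; within a stratum the hash decides.
Hash collisions are broken by the packed code itself, so the order is a
strict total order and fully deterministic given (layers, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence as TSequence

import numpy as np

_GOLDEN = np.uint64(0x9E3779B97F4A7C15)
_M1 = np.uint64(0xBF58476D1CE4E5B9)
_M2 = np.uint64(0x94D049BB133111EB)


def mix64(codes: np.ndarray, seed: int) -> np.ndarray:
    """SplitMix64 finalizer of ``code XOR f(seed)``; near-uniform on uint64."""
    x = codes.astype(np.uint64, copy=True)
    with np.errstate(over="ignore"):
        x ^= (np.uint64(seed & 0xFFFFFFFFFFFFFFFF) + np.uint64(1)) * _GOLDEN
        x ^= x >> np.uint64(30)
        x *= _M1
        x ^= x >> np.uint64(27)
        x *= _M2
        x ^= x >> np.uint64(31)
    return x


def pack_kmer(kmer: str, alphabet: str) -> int:
    """Pack a k-mer string into its base-sigma integer code."""
    code = 0
    for ch in kmer.upper():
        idx = alphabet.index(ch)
        code = code * len(alphabet) + idx
    return code


def unpack_kmer(code: int, k: int, alphabet: str) -> str:
    sigma = len(alphabet)
    out = []
    for _ in range(k):
        out.append(alphabet[code % sigma])
        code //= sigma
    return "".join(reversed(out))


@dataclass(frozen=True)
class KmerOrder:
    """Strict total order on packed k-mer codes.

    Parameters
    ----------
    layers:
        Priority list of k-mer code sets; earlier layers compare smaller.
        Codes may appear in at most one layer.
    seed:
        Seed of the pseudo-random rank used within each stratum.
    """

    layers: tuple[frozenset[int], ...] = ()
    seed: int = 0
    _sorted_layers: tuple[np.ndarray, ...] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        layers = tuple(frozenset(layer) for layer in self.layers)
        seen: set[int] = set()
        for layer in layers:
            if layer & seen:
                raise ValueError("layers must be pairwise disjoint")
            seen |= layer
        object.__setattr__(self, "layers", layers)
        object.__setattr__(
            self,
            "_sorted_layers",
            tuple(np.sort(np.fromiter(layer, np.int64, len(layer))) for layer in layers),
        )

    @classmethod
    def from_kmers(
        cls, layers: TSequence[Iterable[str]], seed: int = 0, alphabet: str = "ACGT"
    ) -> "KmerOrder":
        return cls(
            tuple(frozenset(pack_kmer(m, alphabet) for m in layer) for layer in layers),
            seed=seed,
        )

    # ------------------------------------------------------------------
    def layer_rank(self, codes: np.ndarray) -> np.ndarray:
        """Index of the first layer containing each code (len(layers) if none)."""
        out = np.full(codes.shape, len(self.layers), dtype=np.int32)
        for i in reversed(range(len(self._sorted_layers))):
            member = _isin_sorted(codes, self._sorted_layers[i])
            out[member] = i
        return out

    def key(self, code: int) -> tuple[int, int, int]:
        """Comparable key of one packed code: (layer, hash, code)."""
        arr = np.asarray([code], np.int64)
        return (
            int(self.layer_rank(arr)[0]),
            int(mix64(arr, self.seed)[0]),
            int(code),
        )

    def rank_of(self, codes: np.ndarray) -> np.ndarray:
        """Dense ranks of an array of packed codes under this order.

        Equal codes receive equal ranks; the returned int64 array preserves
        the order's comparisons (smaller rank = smaller k-mer).
        """
        u, inv = np.unique(np.asarray(codes, np.int64), return_inverse=True)
        h = mix64(u, self.seed)
        if self.layers:
            lr = self.layer_rank(u)
            order = np.lexsort((u, h, lr))
        else:
            order = np.lexsort((u, h))
        rank_u = np.empty(u.size, np.int64)
        rank_u[order] = np.arange(u.size)
        return rank_u[inv]


def _isin_sorted(values: np.ndarray, table: np.ndarray) -> np.ndarray:
    if table.size == 0:
        return np.zeros(values.shape, bool)
    idx = np.searchsorted(table, values)
    idx[idx == table.size] = table.size - 1
    return table[idx] == values
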