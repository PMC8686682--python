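"""Polar sets, layered polar sets, link energy and density bounds.

A *polar set* A with slackness s < 1/2 is a k-mer set whose occurrences in
S are pairwise at least (1-s)w bases apart, so no window contains two
members.  A *layered* polar set is a priority list of sets A1..Am where
each occurrence of an Aj member is either that far from every occurrence
of {A1..Aj} or *covered* — flanked within w bases by two earlier-layer
occurrences.

Two uncovered member occurrences l <= w bases apart form a *link* of
energy 2l/(w+1) - 1; the total link energy L predicts the density saving
of a compatible minimizer over the random baseline:

    1 + E0 - X - L  <=  E[#selected]  <=  1 + E0 + D - L.

L is also computable from aggregate counts as 2*Acov/(w+1) - Aele - Aseg,
with Acov the number of context slots containing an uncovered occurrence,
Aele the number of uncovered occurrences and Aseg the number of maximal
runs of occurrences at gaps <= w.  Both routes are evaluated in integer
arithmetic scaled by (w+1) and must agree exactly.
"""

from __future__ import annotations

import math
from bisect import bisect_left, bisect_right
from dataclasses import dataclass
from typing import Iterable, Sequence as TSequence

import numpy as np

from .energy import energy_profile
from .order import pack_kmer, unpack_kmer
from .sequence import Sequence


class InvalidPolarSetError(ValueError):
    """Raised when an operation requires a valid (layered) polar set."""

    def __init__(self, verdict: "Verdict"):
        self.verdict = verdict
        super().__init__(
            f"polar set invalid: {len(verdict.violations)} violation(s); "
            f"first: {verdict.violations[0] if verdict.violations else None}"
        )


def spacing_threshold(w: int, s: float) -> int:
    """Integer distance threshold ceil((1-s)w); 'at least' is inclusive."""
    if not 0 <= s < 0.5:
        raise ValueError(f"slackness s must satisfy 0 <= s < 1/2, got {s}")
    return math.ceil(round((1 - s) * w, 9))


@dataclass(frozen=True)
class LayeredPolarSet:
    """Ordered layers of k-mers with slackness s (single layer = plain polar set)."""

    layers: tuple[frozenset[str], ...]
    s: float = 0.0
    k: int | None = None  # inferred from the k-mers when omitted

    def __post_init__(self) -> None:
        layers = tuple(frozenset(m.upper() for m in layer) for layer in self.layers)
        object.__setattr__(self, "layers", layers)
        if not 0 <= self.s < 0.5:
            raise ValueError(f"slackness s must satisfy 0 <= s < 1/2, got {self.s}")
        ks = {len(m) for layer in layers for m in layer}
        if len(ks) > 1:
            raise ValueError("all k-mers must share one length")
        if self.k is not None and ks and self.k != next(iter(ks)):
            raise ValueError("declared k does not match the k-mers")
        if self.k is None:
            object.__setattr__(self, "k", ks.pop() if ks else 0)
        seen: set[str] = set()
        for layer in layers:
            if layer & seen:
                raise ValueError("layers must be pairwise disjoint")
            seen |= layer

    @classmethod
    def single(cls, kmers: Iterable[str], s: float = 0.0) -> "LayeredPolarSet":
        return cls((frozenset(kmers),), s=s)

    @property
    def n_layers(self) -> int:
        return len(self.layers)

    @property
    def all_kmers(self) -> frozenset[str]:
        out: frozenset[str] = frozenset()
        for layer in self.layers:
            out |= layer
        return out

    def min_gap(self, w: int) -> int:
        return spacing_threshold(w, self.s)

    def code_layers(self, alphabet: str) -> tuple[frozenset[int], ...]:
        return tuple(
            frozenset(pack_kmer(m, alphabet) for m in layer) for layer in self.layers
        )


@dataclass(frozen=True)
class Violation:
    layer: int          # 1-based layer of the offending occurrence
    position: int       # its position in S
    other_position: int  # occurrence it is too close to
    distance: int


@dataclass(frozen=True)
class Verdict:
    valid: bool
    violations: tuple[Violation, ...]
    threshold: int


@dataclass(frozen=True)
class LinkStats:
    """Aggregate link-energy statistics of a layered polar set on S.

    ``Acov`` counts only contexts that actually exist (clipped to each
    fragment's context range); ``acov_unclipped`` counts the full slot
    range [t-w, t] per occurrence.  The identity
    ``L == 2*acov_unclipped/(w+1) - Aele - Aseg`` is exact always, and
    holds with the clipped ``Acov`` as well whenever no occurrence lies
    within w bases of a fragment end (in particular on every interior
    configuration).  ``ea_min`` is the number of charged contexts every
    compatible order is guaranteed to produce inside covered segments;
    it feeds the lower density bound.
    """

    Acov: int   # existing contexts containing >= 1 uncovered occurrence
    Aele: int   # uncovered occurrences (in fragments that admit windows)
    Aseg: int   # maximal runs of occurrences at consecutive gaps <= w
    L: float    # total link energy (pairwise definition)
    links: tuple[tuple[int, int, float], ...]  # (left_pos, right_pos, energy)
    w: int
    acov_unclipped: int = 0
    ea_min: int = 0

    @property
    def n_links(self) -> int:
        return len(self.links)

    def formula_L(self) -> float:
        return 2 * self.Acov / (self.w + 1) - self.Aele - self.Aseg

    @property
    def L_upper(self) -> float:
        """Link-energy credit certain for the upper density bound."""
        return 2 * self.Acov / (self.w + 1) - self.Aele - self.Aseg

    @property
    def L_lower(self) -> float:
        """Link-energy credit certain for the lower density bound."""
        return 2 * self.Acov / (self.w + 1) - self.ea_min


# ----------------------------------------------------------------------
# Occurrence and coverage machinery
# ----------------------------------------------------------------------

def layer_occurrences(seq: Sequence, lps: LayeredPolarSet) -> list[np.ndarray]:
    """Sorted occurrence positions of each layer's k-mers in S."""
    if lps.k == 0:
        return [np.empty(0, np.int64) for _ in lps.layers]
    codes, valid = seq.kmer_codes(lps.k)
    out = []
    for layer_codes in lps.code_layers(seq.alphabet):
        if not layer_codes:
            out.append(np.empty(0, np.int64))
            continue
        table = np.sort(np.fromiter(layer_codes, np.int64, len(layer_codes)))
        idx = np.searchsorted(table, codes)
        idx[idx == table.size] = 0
        member = (table[idx] == codes) & valid
        out.append(np.flatnonzero(member).astype(np.int64))
    return out


def fragment_ids(seq: Sequence) -> np.ndarray:
    """Per-position fragment index (-1 on break characters)."""
    ids = np.full(len(seq), -1, np.int64)
    for i, (a, b) in enumerate(seq.fragments):
        ids[a:b] = i
    return ids


def is_covered(
    t: int, earlier_sorted: TSequence[int], w: int, frag_of: np.ndarray | None = None
) -> bool:
    """Covered: earlier-layer occurrences l < t < h with h - l <= w.

    When ``frag_of`` is given, both flanks must lie in the same fragment
    as t (a window must be able to contain all three positions).
    """
    i = bisect_left(earlier_sorted, t)
    if i == 0 or i == len(earlier_sorted):
        return False
    left = earlier_sorted[i - 1]
    j = bisect_right(earlier_sorted, t)
    if j == len(earlier_sorted):
        return False
    right = earlier_sorted[j]
    if not (left < t < right and right - left <= w):
        return False
    if frag_of is not None and not (frag_of[left] == frag_of[t] == frag_of[right]):
        return False
    return True


def uncovered_occurrences(seq: Sequence, lps: LayeredPolarSet, w: int) -> np.ndarray:
    """Sorted positions of all member occurrences not covered by earlier layers."""
    occs = layer_occurrences(seq, lps)
    frag_of = fragment_ids(seq)
    earlier: list[int] = []
    keep: list[int] = []
    for j, occ in enumerate(occs):
        for t in occ.tolist():
            if j == 0 or not is_covered(t, earlier, w, frag_of):
                keep.append(t)
        earlier = sorted(earlier + occ.tolist())
    return np.asarray(sorted(keep), np.int64)


# ----------------------------------------------------------------------
# Validation
# ----------------------------------------------------------------------

def validate_layered(seq: Sequence, lps: LayeredPolarSet, w: int) -> Verdict:
    """Check the layered polar set condition occurrence by occurrence.

    For each occurrence t of an Aj k-mer: accept if covered by layers
    < j, or if at least ceil((1-s)w) bases from every other occurrence of
    any k-mer in A1..Aj.  Reports every violating pair.
    """
    thr = spacing_threshold(w, lps.s)
    occs = layer_occurrences(seq, lps)
    frag_of = fragment_ids(seq)
    violations: list[Violation] = []
    upto: list[int] = []  # all occurrences of layers 1..j, sorted
    earlier: list[int] = []  # layers 1..j-1
    for j, occ in enumerate(occs):
        upto = sorted(upto + occ.tolist())
        for t in occ.tolist():
            if j > 0 and is_covered(t, earlier, w, frag_of):
                continue
            i = bisect_left(upto, t)
            for nb in (i - 1, i + 1):
                if 0 <= nb < len(upto) and upto[nb] != t:
                    d = abs(upto[nb] - t)
                    if d < thr:
                        violations.append(Violation(j + 1, t, upto[nb], d))
        earlier = list(upto)
    return Verdict(valid=not violations, violations=tuple(violations), threshold=thr)


def validate_polar(seq: Sequence, kmers: Iterable[str], w: int, s: float = 0.0) -> Verdict:
    """Plain polar-set check: all member occurrences pairwise >= ceil((1-s)w) apart."""
    return validate_layered(seq, LayeredPolarSet.single(kmers, s=s), w)


# ----------------------------------------------------------------------
# Link energy
# ----------------------------------------------------------------------

def link_energy(
    seq: Sequence, lps: LayeredPolarSet, w: int, *, check: bool = True
) -> LinkStats:
    """Total link energy of a layered polar set on S, computed two ways.

    Pairwise route: consecutive uncovered occurrences at gap l <= w (never
    across a break) contribute 2l/(w+1) - 1 each.  Aggregate route:
    2*Acov/(w+1) - Aele - Aseg, evaluated in integers scaled by (w+1) and
    verified against the pairwise sum.  Occurrences in fragments too short
    for a single window are excluded (they can never be selected).
    """
    if check:
        verdict = validate_layered(seq, lps, w)
        if not verdict.valid:
            raise InvalidPolarSetError(verdict)
    elems = uncovered_occurrences(seq, lps, w)
    k = lps.k
    links: list[tuple[int, int, float]] = []
    lnum_pair = 0
    acov = acov_unclip = aele = aseg = ea_min = 0
    for a, b in seq.fragments:
        nk = b - a - k + 1
        if nk < w:
            continue
        lo_i = int(np.searchsorted(elems, a))
        hi_i = int(np.searchsorted(elems, b - k, side="right"))
        frag_elems = elems[lo_i:hi_i].tolist()
        if not frag_elems:
            continue
        aele += len(frag_elems)
        win_lo, win_hi = a, a + nk - w     # window start range
        ctx_lo, ctx_hi = a, a + nk - w - 1  # context start range (may be empty)
        runs: list[list[int]] = [[frag_elems[0]]]
        for t in frag_elems[1:]:
            if t - runs[-1][-1] <= w:
                runs[-1].append(t)
            else:
                runs.append([t])
        for run in runs:
            aseg += 1
            for u, v in zip(run, run[1:]):
                links.append((u, v, 2 * (v - u) / (w + 1) - 1))
                lnum_pair += 2 * (v - u) - (w + 1)
            acov_unclip += run[-1] - run[0] + w + 1
            if ctx_hi >= ctx_lo:
                acov += max(0, min(run[-1], ctx_hi) - max(run[0] - w, ctx_lo) + 1)
            ea_min += _guaranteed_charges(run, w, win_lo, win_hi, ctx_lo, ctx_hi)
    assert lnum_pair == 2 * acov_unclip - (aele + aseg) * (w + 1), "formula mismatch"
    return LinkStats(
        Acov=acov, Aele=aele, Aseg=aseg, L=lnum_pair / (w + 1),
        links=tuple(links), w=w, acov_unclipped=acov_unclip, ea_min=ea_min,
    )


def _guaranteed_charges(
    run: list[int], w: int, win_lo: int, win_hi: int, ctx_lo: int, ctx_hi: int
) -> int:
    """Charged contexts every compatible order must produce in one segment.

    A member with a 'solo' window inside the fragment (a window where it is
    the only member) is always selected; the selected position is
    non-decreasing as windows slide, so d_solo distinct selections force at
    least d_solo - 1 internal charges.  The entering charge (first window
    holding a member versus its predecessor) and the leaving charge (last
    window holding a member versus its successor) are certain whenever the
    corresponding context exists.  Away from fragment ends this evaluates
    to d + 1 exactly.
    """
    d = len(run)
    d_solo = 0
    for i, t in enumerate(run):
        lo = max(win_lo, t - w + 1, run[i - 1] + 1 if i > 0 else win_lo)
        hi = min(win_hi, t, run[i + 1] - w if i + 1 < d else win_hi)
        d_solo += lo <= hi
    if ctx_hi < ctx_lo:
        return 0
    entering = run[0] - w >= ctx_lo
    leaving = run[-1] <= ctx_hi
    return max(0, d_solo - 1) + int(entering) + int(leaving)


def link_stats_from_positions(positions: np.ndarray | TSequence[int], w: int) -> LinkStats:
    """LinkStats of a bare position set (no fragment clipping).

    Treats every stored position as an uncovered occurrence on an
    unbounded context line: this is the convention the LinkedBlocks ledger
    maintains, and the exact-identity route for interior fixtures.
    """
    pos = np.asarray(sorted(int(p) for p in positions), np.int64)
    links: list[tuple[int, int, float]] = []
    lnum_pair = 0  # (w+1) * pairwise L
    Acov = 0
    Aseg = 0
    run_start = None
    for t in pos.tolist():
        if run_start is None:
            run_start, run_end = t, t
            Aseg += 1
        elif t - run_end <= w:
            lnum_pair += 2 * (t - run_end) - (w + 1)
            links.append((run_end, t, (2 * (t - run_end)) / (w + 1) - 1))
            run_end = t
        else:
            Acov += run_end - run_start + w + 1
            run_start, run_end = t, t
            Aseg += 1
    if run_start is not None:
        Acov += run_end - run_start + w + 1
    Aele = int(pos.size)
    lnum_formula = 2 * Acov - (Aele + Aseg) * (w + 1)
    assert lnum_formula == lnum_pair, "link-energy formula mismatch"
    return LinkStats(
        Acov=Acov, Aele=Aele, Aseg=Aseg, L=lnum_pair / (w + 1), links=tuple(links),
        w=w, acov_unclipped=Acov, ea_min=Aele + Aseg,
    )


def density_bounds(
    seq: Sequence, lps: LayeredPolarSet, w: int, *, check: bool = True
) -> tuple[float, float]:
    """Sandwich on E[#selected] for any order compatible with the layers.

    Returns ``(1 + E0 - X - L_lower, 1 + E0 + D - L_upper)`` where the two
    link-energy credits coincide with L away from fragment ends and carry
    exact boundary corrections otherwise.  Requires s < 1/2 (the lower
    bound does not hold otherwise), enforced by LayeredPolarSet.
    """
    prof = energy_profile(seq, w, lps.k)
    stats = link_energy(seq, lps, w, check=check)
    lo = 1 + prof.E0 - prof.X - stats.L_lower
    hi = 1 + prof.E0 + prof.D - stats.L_upper
    return lo, hi


# ----------------------------------------------------------------------
# Layered k-mer set TSV I/O
# ----------------------------------------------------------------------

def write_layers_tsv(
    path, lps: LayeredPolarSet, w: int, k: int | None = None, seed: int | None = None
) -> None:
    """Write `kmer<TAB>layer` lines with a '#'-commented parameter header."""
    k = k if k is not None else lps.k
    with open(path, "w") as fh:
        fh.write(f"# w={w}\n# k={k}\n# s={lps.s}\n")
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        for j, layer in enumerate(lps.layers, start=1):
            for kmer in sorted(layer):
                fh.write(f"{kmer}\t{j}\n")


def read_layers_tsv(path) -> tuple[LayeredPolarSet, dict]:
    """Read a layered k-mer TSV; returns the set and its header metadata."""
    meta: dict[str, float | int] = {}
    by_layer: dict[int, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if "=" in body:
                    key, val = body.split("=", 1)
                    key, val = key.strip(), val.strip()
                    meta[key] = float(val) if "." in val else int(val)
                continue
            kmer, layer_s = line.split("\t")
            by_layer.setdefault(int(layer_s), set()).add(kmer.upper())
    if by_layer:
        m = max(by_layer)
        layers = tuple(frozenset(by_layer.get(j, set())) for j in range(1, m + 1))
    else:
        layers = ()
    s = float(meta.get("s", 0.0))
    return LayeredPolarSet(layers, s=s), meta


__all__ = [
    "LayeredPolarSet",
    "LinkStats",
    "Verdict",
    "Violation",
    "InvalidPolarSetError",
    "spacing_threshold",
    "layer_occurrences",
    "uncovered_occurrences",
    "is_covered",
    "validate_layered",
    "validate_polar",
    "link_energy",
    "link_stats_from_positions",
    "density_bounds",
    "write_layers_tsv",
    "read_layers_tsv",
    "pack_kmer",
    "unpack_kmer",
]
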