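"""Synthetic sequences and baseline sampling schemes.

Generators cover the regimes the theory distinguishes:

- ``uniform``: i.i.d. characters, the setting where a random minimizer has
  expected density 2/(w+1);
- ``periodic``: period-w sequences with w distinct k-mers, the extreme in
  which every context is an energy saver;
- ``planted_perfect``: a uniform sequence short enough (|S| < eps*w*sigma^k/2)
  that fixed-interval sampling yields a perfect minimizer with probability
  at least 1 - eps;
- ``repeat_mosaic``: tiled, lightly mutated repeat units producing
  high-frequency k-mers that stress the filters.

``fixed_interval_set`` is the every-w-th-k-mer baseline used to define a
compatible minimizer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .sequence import DNA, Sequence


@dataclass(frozen=True)
class SynthSpec:
    """Declarative description of a synthetic sequence."""

    kind: str  # uniform | periodic | planted_perfect | repeat_mosaic
    n: int
    sigma: int = 4
    w: int = 10
    k: int = 15
    period: int | None = None
    unit_len: int = 200
    mutation_rate: float = 0.02
    rng_seed: int = 0
    epsilon: float = 0.01


def _alphabet(sigma: int) -> str:
    if not 2 <= sigma <= 4:
        raise ValueError("sigma must be in [2, 4] for DNA-style alphabets")
    return DNA[:sigma]


def generate(spec: SynthSpec) -> Sequence:
    """Deterministic dispatch over the generator kinds."""
    if spec.kind == "uniform":
        return uniform_sequence(spec.n, sigma=spec.sigma, seed=spec.rng_seed)
    if spec.kind == "periodic":
        period = spec.period if spec.period is not None else spec.w
        return periodic_sequence(spec.n, period, spec.k, sigma=spec.sigma, seed=spec.rng_seed)
    if spec.kind == "planted_perfect":
        return planted_perfect_sequence(
            spec.n, spec.w, spec.k, sigma=spec.sigma, seed=spec.rng_seed, epsilon=spec.epsilon
        )
    if spec.kind == "repeat_mosaic":
        return repeat_mosaic_sequence(
            spec.n, unit_len=spec.unit_len, mutation_rate=spec.mutation_rate,
            sigma=spec.sigma, seed=spec.rng_seed,
        )
    raise ValueError(f"unknown generator kind {spec.kind!r}")


def uniform_sequence(n: int, sigma: int = 4, seed: int = 0) -> Sequence:
    """i.i.d. uniform characters over the first sigma DNA letters."""
    alpha = _alphabet(sigma)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, sigma, size=n)
    text = "".join(alpha[i] for i in range(sigma)).encode()
    arr = np.frombuffer(text, np.uint8)[idx]
    return Sequence(arr.tobytes().decode("ascii"), alphabet=alpha)


def periodic_sequence(n: int, period: int, k: int, sigma: int = 4, seed: int = 0) -> Sequence:
    """Period-``period`` sequence whose ``period`` k-mers are all distinct.

    Random unit strings are drawn until the circular unit's k-mers are
    pairwise distinct (requires sigma**k >= period).
    """
    if sigma**k < period:
        raise ValueError("sigma^k must be >= period to fit distinct k-mers")
    alpha = _alphabet(sigma)
    rng = np.random.default_rng(seed)
    for _ in range(10_000):
        unit = "".join(alpha[i] for i in rng.integers(0, sigma, size=period))
        circ = unit + unit[: k - 1]
        kmers = {circ[i : i + k] for i in range(period)}
        if len(kmers) == period:
            reps = -(-n // period)
            return Sequence((unit * reps)[:n], alphabet=alpha)
    raise RuntimeError("could not sample a distinct-k-mer period; widen sigma or k")


def planted_perfect_sequence(
    n: int, w: int, k: int, sigma: int = 4, seed: int = 0, epsilon: float = 0.01,
    warn: bool = True,
) -> Sequence:
    """Uniform sequence in the short regime |S| < eps*w*sigma^k/2.

    In this regime fixed-interval sampling gives a perfect minimizer with
    probability at least 1 - eps; outside it a warning is emitted.
    """
    import warnings

    if warn and n >= epsilon * w * sigma**k / 2:
        warnings.warn(
            f"n = {n} is not below eps*w*sigma^k/2 = {epsilon * w * sigma ** k / 2:.3g};"
            " a perfect fixed-interval set is not probable",
            stacklevel=2,
        )
    return uniform_sequence(n, sigma=sigma, seed=seed)


def repeat_mosaic_sequence(
    n: int, unit_len: int = 200, mutation_rate: float = 0.02, sigma: int = 4, seed: int = 0,
) -> Sequence:
    """Tandem copies of a random unit with point mutations: frequent k-mers."""
    alpha = _alphabet(sigma)
    rng = np.random.default_rng(seed)
    unit = rng.integers(0, sigma, size=unit_len)
    reps = -(-n // unit_len)
    arr = np.tile(unit, reps)[:n]
    mut = rng.random(n) < mutation_rate
    arr[mut] = (arr[mut] + rng.integers(1, sigma, size=int(mut.sum()))) % sigma
    text = "".join(alpha[i] for i in range(sigma)).encode()
    return Sequence(
        np.frombuffer(text, np.uint8)[arr].tobytes().decode("ascii"), alphabet=alpha
    )


def fixed_interval_set(seq: Sequence, w: int, k: int, offset: int = 0) -> set[str]:
    """k-mers occurring at valid positions t = offset (mod w).

    A minimizer compatible with this set is perfect exactly when those
    k-mers occur nowhere else in S.
    """
    if not 0 <= offset < w:
        raise ValueError("offset must be in [0, w)")
    starts = seq.kmer_starts(k)
    picks = starts[starts % w == offset]
    return {seq.text[t : t + k] for t in picks.tolist()}
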