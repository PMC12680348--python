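"""Summary statistics and distances for STR allele-frequency data.

Heterozygosity, ``h = 1 - sum_j p_j^2`` (the probability that two randomly
drawn alleles differ), is the per-locus summary statistic used throughout the
inference layer. Sets of loci are compared through the L1 distance between
their sorted heterozygosity vectors, and inferred gamma DFEs are combined into
locus-count-weighted empirical CDFs of selection coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .evo_model import validate_frequencies

__all__ = [
    "LocusSet",
    "EmpiricalCDF",
    "heterozygosity",
    "het_distance",
    "subsample_to_match",
    "weighted_dfe_cdf",
]


@dataclass
class LocusSet:
    """Per-locus heterozygosities for one STR class.

    ``class_key`` is ``(repeat_unit, optimal_allele)``; the optimal allele is
    taken to be the modal allele of the class.
    """

    class_key: tuple[str, int]
    hets: np.ndarray
    locus_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.hets = np.asarray(self.hets, dtype=float)
        if self.hets.ndim != 1 or len(self.hets) == 0:
            raise ValueError("hets must be a non-empty 1-D array")
        if np.any(self.hets < 0) or np.any(self.hets >= 1):
            raise ValueError("heterozygosities must lie in [0, 1)")
        if self.locus_ids is not None and len(self.locus_ids) != len(self.hets):
            raise ValueError("locus_ids length must match hets")

    @property
    def n_loci(self) -> int:
        return len(self.hets)


def heterozygosity(freqs: np.ndarray) -> float:
    """``1 - sum(p**2)`` for a normalized frequency vector.

    Exactly 0 for a monomorphic locus, and always below 1.
    """
    p = validate_frequencies(freqs)
    return float(1.0 - np.dot(p, p))


def het_distance(obs, sim) -> float:
    """Mean absolute difference between sorted heterozygosity vectors.

    Both vectors must have the same length (subsample the larger one first,
    e.g. with :func:`subsample_to_match`). The vectors are sorted internally,
    so the metric is symmetric and permutation-invariant, and zero iff the
    sorted vectors coincide.
    """
    a = np.sort(np.asarray(obs, dtype=float))
    b = np.sort(np.asarray(sim, dtype=float))
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    return float(np.abs(a - b).mean())


def subsample_to_match(
    a: np.ndarray, b: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Subsample the larger vector without replacement to the smaller's size."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) > len(b):
        a = rng.choice(a, size=len(b), replace=False)
    elif len(b) > len(a):
        b = rng.choice(b, size=len(a), replace=False)
    return a, b


@dataclass
class EmpiricalCDF:
    """Empirical CDF over pooled selection-coefficient draws."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.sort(np.asarray(self.values, dtype=float))
        if len(self.values) == 0:
            raise ValueError("empirical CDF needs at least one value")

    def __call__(self, x) -> np.ndarray | float:
        """Fraction of pooled draws <= x."""
        frac = np.searchsorted(self.values, x, side="right") / len(self.values)
        return float(frac) if np.isscalar(x) else frac

    def to_tsv(self, path) -> None:
        cum = np.arange(1, len(self.values) + 1) / len(self.values)
        with open(path, "w") as fh:
            fh.write("s\tcumulative_fraction\n")
            for v, c in zip(self.values, cum):
                fh.write(f"{v:.10g}\t{c:.10g}\n")


def weighted_dfe_cdf(
    fits: list[tuple[tuple[str, int], float, float, int]],
    rng: np.random.Generator,
    n_draws_per_locus: int = 1,
) -> EmpiricalCDF:
    """Locus-count-weighted empirical CDF of s across inferred class DFEs.

    ``fits`` holds ``(class_key, a, b, n_loci)`` records; for each class,
    ``n_loci * n_draws_per_locus`` gamma(a, scale=b) variates are drawn and
    pooled, so classes contribute in proportion to their locus counts.
    Degenerate DFEs (``a`` or ``b`` equal to 0) contribute point mass at 0.
    """
    draws = []
    for _key, a, b, n_loci in fits:
        if n_loci < 1:
            raise ValueError("every fit needs n_loci >= 1")
        size = n_loci * n_draws_per_locus
        if a <= 0 or b <= 0:
            draws.append(np.zeros(size))
        else:
            draws.append(rng.gamma(shape=a, scale=b, size=size))
    return EmpiricalCDF(np.concatenate(draws))
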