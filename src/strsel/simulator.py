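"""Forward Wright-Fisher simulation of STR loci and ABC lookup tables.

A locus starts fixed for the optimal allele and evolves for the full span of
the demographic model; each generation applies mutation (transition-matrix
product), deterministic selection, and multinomial drift at that generation's
diploid size. After the final generation an end-sampling step draws ``N``
alleles to mimic a finite genotyped sample.

Many loci sharing a demography can be advanced in lock-step, which is how the
ABC lookup tables (replicate heterozygosities and frequency vectors indexed by
a rounded selection coefficient) are built at practical cost.

Rescaled runs
-------------
``rescale=lambda`` applies the classical population-genetic rescaling: sizes
and epoch durations are divided by lambda while mutation rates, growth rates,
and selection coefficients are multiplied by lambda (s clamped at 1). This
preserves the compound parameters 4*N*mu and N*s that shape allele-frequency
distributions, so scaled runs emulate full-span runs at a fraction of the
cost. All user-facing parameters stay in true (unscaled) units.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .evo_model import (
    AlleleGrid,
    DemographicModel,
    MutationModel,
    SelectionModel,
    build_mutation_matrix,
    validate_frequencies,
)

__all__ = [
    "SimulatedLocus",
    "LookupTable",
    "ErrorModel",
    "TableCoverageError",
    "round_s",
    "s_key_indices",
    "default_s_grid",
    "DEFAULT_S_KEYS",
    "simulate_batch",
    "simulate_locus",
    "end_sample",
    "build_lookup_table",
    "modal_allele",
    "modal_match_fraction",
    "inject_genotyping_errors",
]


class TableCoverageError(KeyError):
    """Raised when a lookup table lacks a required selection-coefficient key."""


# ---------------------------------------------------------------------------
# selection-coefficient rounding (the lookup-table index)

_N_DECADES = 5  # keys span 1e-5 .. 1


def round_s(s: float) -> float:
    """Round ``s`` to its lookup key: one significant digit, ``< 1e-5 -> 0``.

    Values above 1 map to the key 1.0 (the fitness model caps s at 1). Two s
    values "match" for table lookups iff their keys are equal.
    """
    if s < 0:
        raise ValueError(f"s must be >= 0, got {s}")
    if s < 1e-5:
        return 0.0
    if s >= 0.95:
        return 1.0
    exp = math.floor(math.log10(s))
    mant = round(s / 10.0**exp)
    if mant == 10:
        mant, exp = 1, exp + 1
    # decimal-canonical float (7e-1 is exactly float("0.7"), not 7 * 0.1)
    return float(f"{mant}e{exp}")


def default_s_grid() -> list[float]:
    """All lookup keys: 0 plus every one-significant-digit value in [1e-5, 1]."""
    keys = [0.0]
    for exp in range(-_N_DECADES, 0):
        keys.extend(float(f"{m}e{exp}") for m in range(1, 10))
    keys.append(1.0)
    return keys


DEFAULT_S_KEYS: np.ndarray = np.array(default_s_grid())


def s_key_indices(s: np.ndarray) -> np.ndarray:
    """Map selection coefficients to indices into :data:`DEFAULT_S_KEYS`.

    Index 0 is the neutral key (s < 1e-5); the last index is 1.0. Vectorized
    companion of :func:`round_s`.
    """
    s = np.asarray(s, dtype=float)
    if np.any(s < 0):
        raise ValueError("s values must be >= 0")
    idx = np.zeros(s.shape, dtype=np.intp)
    nz = s >= 1e-5
    if np.any(nz):
        v = np.minimum(s[nz], 1.0)
        exp = np.floor(np.log10(v)).astype(np.intp)
        mant = np.round(v / 10.0**exp).astype(np.intp)
        carry = mant == 10
        mant[carry] = 1
        exp[carry] += 1
        sub = np.where(exp >= 0, 9 * _N_DECADES, (exp + _N_DECADES) * 9 + (mant - 1))
        idx[nz] = 1 + sub
    return idx


# ---------------------------------------------------------------------------
# core simulation


@dataclass(frozen=True)
class SimulatedLocus:
    """Output of a single-locus forward simulation (after end sampling)."""

    final_freqs: np.ndarray
    s: float
    class_key: tuple[str, int] | None = None
    seed: int | None = None


def _rescaled_inputs(
    mut: MutationModel,
    s_values: np.ndarray,
    demog: DemographicModel,
    rescale: float,
) -> tuple[MutationModel, np.ndarray, DemographicModel]:
    if rescale == 1:
        return mut, np.minimum(s_values, 1.0), demog
    return (
        mut.rescaled(rescale),
        np.minimum(s_values * rescale, 1.0),
        demog.rescaled(rescale),
    )


def simulate_batch(
    mut: MutationModel,
    s_values: np.ndarray,
    demog: DemographicModel,
    grid: AlleleGrid,
    rng: np.random.Generator,
    sample_size: int | None = None,
    rescale: float = 1,
) -> np.ndarray:
    """Simulate one frequency vector per entry of ``s_values``, in lock-step.

    Every locus starts with all mass on the optimal allele and experiences
    mutation, selection at its own ``s``, and shared-demography drift each
    generation. If ``sample_size`` is given, an end-sampling multinomial draw
    of that many alleles is applied per locus. Returns an ``(m, n)`` array.
    """
    s_values = np.atleast_1d(np.asarray(s_values, dtype=float))
    mut_r, s_r, demog_r = _rescaled_inputs(mut, s_values, demog, rescale)
    T = build_mutation_matrix(mut_r, grid)
    sizes = demog_r.size_trajectory()

    m, n = len(s_r), grid.n
    p = np.zeros((m, n))
    p[:, grid.center] = 1.0
    W = np.maximum(1.0 - np.outer(s_r, np.abs(grid.offsets)), 0.0)
    neutral = np.all(s_r == 0.0)

    for neff in sizes:
        p = p @ T
        if not neutral:
            mean_w = (p * W).sum(axis=1, keepdims=True)
            if np.any(mean_w <= 0):
                raise ValueError("population mean fitness reached zero")
            p *= 0.5 * (W + mean_w)
        p /= p.sum(axis=1, keepdims=True)
        counts = rng.multinomial(2 * int(neff), p)
        p = counts / (2 * int(neff))

    if sample_size is not None:
        if sample_size < 2:
            raise ValueError(f"sample_size must be >= 2, got {sample_size}")
        counts = rng.multinomial(sample_size, p)
        p = counts / sample_size
    return p


def simulate_locus(
    mut: MutationModel,
    sel: SelectionModel,
    demog: DemographicModel,
    grid: AlleleGrid,
    sample_size: int,
    rng: np.random.Generator,
    rescale: float = 1,
    class_key: tuple[str, int] | None = None,
    seed: int | None = None,
) -> SimulatedLocus:
    """Full-trajectory simulation of one locus followed by end sampling."""
    freqs = simulate_batch(
        mut,
        np.array([sel.s]),
        demog,
        grid,
        rng,
        sample_size=sample_size,
        rescale=rescale,
    )[0]
    return SimulatedLocus(final_freqs=freqs, s=sel.s, class_key=class_key, seed=seed)


def end_sample(freqs: np.ndarray, N: int, rng: np.random.Generator) -> np.ndarray:
    """Multinomial draw of ``N`` observed alleles; returns count frequencies."""
    if N < 2:
        raise ValueError(f"N must be >= 2, got {N}")
    p = validate_frequencies(freqs)
    counts = rng.multinomial(N, p / p.sum())
    return counts / N


# ---------------------------------------------------------------------------
# lookup tables


@dataclass
class LookupTable:
    """Replicate simulations indexed by rounded selection coefficient.

    ``hets[i, r]`` and ``freqs[i, r]`` hold the heterozygosity and frequency
    vector of replicate ``r`` at ``s_keys[i]``. Keys must be valid outputs of
    :func:`round_s` (0 or one significant digit).
    """

    class_key: tuple[str, int]
    s_keys: np.ndarray
    hets: np.ndarray
    freqs: np.ndarray
    sample_size: int | None = None
    _row_of_default: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.s_keys = np.asarray(self.s_keys, dtype=float)
        for key in self.s_keys:
            if round_s(key) != key:
                raise ValueError(f"{key} is not a valid rounded-s key")
        if len(self.s_keys) != len(np.unique(self.s_keys)):
            raise ValueError("duplicate s keys")
        if self.hets.shape[0] != len(self.s_keys) or self.freqs.shape[:2] != self.hets.shape:
            raise ValueError("table arrays are inconsistent with the key list")
        row_of_default = np.full(len(DEFAULT_S_KEYS), -1, dtype=np.intp)
        row_of_default[s_key_indices(self.s_keys)] = np.arange(len(self.s_keys))
        self._row_of_default = row_of_default

    @property
    def n_reps(self) -> int:
        return self.hets.shape[1]

    def rows_for(self, s: np.ndarray) -> np.ndarray:
        """Table rows serving each (unrounded) selection coefficient."""
        rows = self._row_of_default[s_key_indices(s)]
        if np.any(rows < 0):
            missing = DEFAULT_S_KEYS[s_key_indices(s)][rows < 0]
            raise TableCoverageError(
                f"lookup table for class {self.class_key} lacks s key "
                f"{float(np.unique(missing)[0]):g}"
            )
        return rows

    def sample_hets(self, s: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        """One random replicate heterozygosity per requested s value."""
        rows = self.rows_for(s)
        reps = rng.integers(0, self.n_reps, size=rows.shape)
        return self.hets[rows, reps]

    def sample_freqs(self, s: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        """One random replicate frequency vector per requested s value."""
        rows = self.rows_for(s)
        reps = rng.integers(0, self.n_reps, size=rows.shape)
        return self.freqs[rows, reps]

    # -- plain-text serialization (one row per replicate) -------------------

    def to_tsv(self, path) -> None:
        unit, xopt = self.class_key
        with open(path, "w") as fh:
            fh.write("class_key\ts_key\treplicate\theterozygosity\tfreqs\n")
            for i, key in enumerate(self.s_keys):
                for r in range(self.n_reps):
                    freq_str = ",".join(f"{v:.10g}" for v in self.freqs[i, r])
                    fh.write(
                        f"{unit}:{xopt}\t{key:.10g}\t{r}\t"
                        f"{self.hets[i, r]:.10g}\t{freq_str}\n"
                    )

    @classmethod
    def from_tsv(cls, path) -> "LookupTable":
        keys: list[float] = []
        records: dict[float, list[tuple[float, np.ndarray]]] = {}
        class_key = None
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            if header[:2] != ["class_key", "s_key"]:
                raise ValueError(f"unrecognized lookup-table header in {path}")
            for line in fh:
                ck, s_key, _rep, het, freq_str = line.rstrip("\n").split("\t")
                unit, xopt = ck.split(":")
                class_key = (unit, int(xopt))
                key = float(s_key)
                if key not in records:
                    keys.append(key)
                    records[key] = []
                freq = np.array([float(v) for v in freq_str.split(",")])
                records[key].append((float(het), freq))
        if class_key is None:
            raise ValueError(f"empty lookup table: {path}")
        n_reps = min(len(v) for v in records.values())
        hets = np.array([[records[k][r][0] for r in range(n_reps)] for k in keys])
        freqs = np.array([[records[k][r][1] for r in range(n_reps)] for k in keys])
        return cls(class_key=class_key, s_keys=np.array(keys), hets=hets, freqs=freqs)


def build_lookup_table(
    class_key: tuple[str, int],
    mut: MutationModel,
    demog: DemographicModel,
    grid: AlleleGrid,
    sample_size: int,
    rng: np.random.Generator,
    s_grid: list[float] | None = None,
    reps_per_s: int = 50,
    rescale: float = 1,
) -> LookupTable:
    """Simulate ``reps_per_s`` loci per rounded-s key for ABC lookups.

    The default key grid is 0 plus every one-significant-digit value spanning
    1e-5..1, covering the effective support of the gamma prior.
    """
    if s_grid is None:
        s_grid = default_s_grid()
    if not s_grid:
        raise ValueError("s_grid must not be empty")
    keys = np.array([round_s(s) for s in s_grid], dtype=float)
    if len(np.unique(keys)) != len(keys):
        raise ValueError("s_grid contains values that round to the same key")
    if reps_per_s < 1:
        raise ValueError("reps_per_s must be >= 1")

    s_all = np.repeat(keys, reps_per_s)
    freqs = simulate_batch(
        mut, s_all, demog, grid, rng, sample_size=sample_size, rescale=rescale
    ).reshape(len(keys), reps_per_s, grid.n)
    hets = 1.0 - (freqs**2).sum(axis=2)
    return LookupTable(
        class_key=class_key,
        s_keys=keys,
        hets=hets,
        freqs=freqs,
        sample_size=sample_size,
    )


# ---------------------------------------------------------------------------
# modal-allele diagnostics


def modal_allele(freqs: np.ndarray, grid: AlleleGrid) -> int:
    """Offset of the most frequent allele.

    Ties break toward the smallest ``|k|``, then toward negative ``k``
    (contraction), so a tie between -2 and +2 returns -2.
    """
    p = validate_frequencies(freqs)
    best = p.max()
    candidates = grid.offsets[p == best]
    order = sorted(candidates, key=lambda k: (abs(k), k))
    return int(order[0])


def modal_match_fraction(
    mut: MutationModel,
    sel: SelectionModel,
    demog: DemographicModel,
    grid: AlleleGrid,
    n_loci: int,
    rng: np.random.Generator,
    sample_size: int | None = None,
    rescale: float = 1,
) -> float:
    """Fraction of simulated loci whose modal allele equals the optimum."""
    if n_loci < 1:
        raise ValueError("n_loci must be >= 1")
    freqs = simulate_batch(
        mut,
        np.full(n_loci, sel.s),
        demog,
        grid,
        rng,
        sample_size=sample_size,
        rescale=rescale,
    )
    matches = sum(modal_allele(f, grid) == 0 for f in freqs)
    return matches / n_loci


# ---------------------------------------------------------------------------
# genotyping-error injection


@dataclass(frozen=True)
class ErrorModel:
    """Per-allele genotyping-error model: each observed allele call is wrong
    with probability ``per_allele_error_rate`` and then off by one repeat unit
    in either direction with equal probability."""

    per_allele_error_rate: float = 0.001

    def __post_init__(self) -> None:
        if not 0.0 <= self.per_allele_error_rate <= 1.0:
            raise ValueError("error rate must be in [0, 1]")


def inject_genotyping_errors(
    freqs: np.ndarray,
    N: int,
    err: ErrorModel,
    grid: AlleleGrid,
    rng: np.random.Generator,
) -> np.ndarray:
    """Materialize ``N`` allele calls, perturb each with the error model.

    Erroneous calls move +-1 repeat unit with equal probability; calls on a
    grid boundary move inward. Returns the recomputed sample frequencies.
    """
    if N < 2:
        raise ValueError(f"N must be >= 2, got {N}")
    p = validate_frequencies(freqs)
    counts = rng.multinomial(N, p / p.sum())
    if err.per_allele_error_rate == 0.0:
        return counts / N

    n = grid.n
    out = counts.astype(np.int64).copy()
    for i in range(n):
        c = int(counts[i])
        if c == 0:
            continue
        n_flip = rng.binomial(c, err.per_allele_error_rate)
        if n_flip == 0:
            continue
        out[i] -= n_flip
        if i == 0:
            up = n_flip
        elif i == n - 1:
            up = 0
        else:
            up = rng.binomial(n_flip, 0.5)
        if up:
            out[i + 1] += up
        if n_flip - up:
            out[i - 1] += n_flip - up
    return out / N
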