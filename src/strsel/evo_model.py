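"""Mutation, selection, and demographic models for STR allele-frequency evolution.

Short tandem repeats (STRs) mutate by gaining or losing whole repeat units. The
model here is a generalized stepwise mutation model (GSM) with two extensions
supported by de novo mutation data:

* **length-dependent rate** — the per-generation mutation probability of an
  allele of length ``x`` repeat units follows ``log10(mu_x) = log10(mu0) +
  L*(x - r)``, where ``mu0`` is the rate at the reference length ``r``
  (by default the optimal allele) and ``L`` is the slope per added unit;
* **directional bias** — alleles longer than the optimum preferentially
  contract and shorter alleles preferentially expand, controlled by the
  length-constraint parameter ``beta``.

Step sizes are geometric with parameter ``rho`` (single-unit steps have
probability ``rho``). Fitness declines linearly with distance from the optimal
allele, ``w(x) = 1 - s*|x - xopt|``, floored at zero; diploid fitness is the
average of the two allele fitnesses (additive model), so ``s`` is the
homozygote-scale selection coefficient. Drift is multinomial resampling at the
diploid effective size of each generation, which follows a multi-epoch
demographic model (piecewise-constant sizes plus exponential-growth epochs).

Frequency vectors are plain ``numpy`` arrays of length ``grid.n`` over the
allele grid (offsets ``k = x - xopt``); :func:`validate_frequencies` checks the
simplex invariant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "RATE_FLOOR",
    "RATE_CAP",
    "AlleleGrid",
    "MutationModel",
    "SelectionModel",
    "Epoch",
    "DemographicModel",
    "InvalidGridError",
    "DegenerateFitnessError",
    "validate_frequencies",
    "allele_mutation_rate",
    "step_direction_probs",
    "build_mutation_matrix",
    "apply_selection",
    "apply_drift",
    "population_size_at",
    "european_demography",
    "default_mutation_model",
    "DEFAULT_MUTATION_MODELS",
]

RATE_FLOOR = 1e-8
RATE_CAP = 1e-3

_FREQ_TOL = 1e-9


class InvalidGridError(ValueError):
    """Raised for allele lengths or grids outside the modeled range."""


class DegenerateFitnessError(ValueError):
    """Raised when selection drives population mean fitness to zero."""


@dataclass(frozen=True)
class AlleleGrid:
    """Grid of ``n`` allele states centered on the optimal allele.

    Parameters
    ----------
    xopt : int
        Optimal allele length in repeat units.
    repeat_unit_len : int
        Repeat-unit length in bp (2, 3, or 4).
    n : int
        Number of modeled alleles; must be odd so offsets are symmetric
        around 0 (default 25, offsets -12..+12).
    """

    xopt: int
    repeat_unit_len: int
    n: int = 25

    def __post_init__(self) -> None:
        if self.n < 3 or self.n % 2 == 0:
            raise InvalidGridError(f"n must be odd and >= 3, got {self.n}")
        if self.repeat_unit_len not in (2, 3, 4):
            raise InvalidGridError(
                f"repeat_unit_len must be 2, 3, or 4, got {self.repeat_unit_len}"
            )
        if self.xopt < 1:
            raise InvalidGridError(f"xopt must be >= 1, got {self.xopt}")

    @property
    def half_width(self) -> int:
        return self.n // 2

    @property
    def offsets(self) -> np.ndarray:
        """Integer offsets ``k = x - xopt``, consecutive and centered on 0."""
        return np.arange(-self.half_width, self.half_width + 1)

    @property
    def center(self) -> int:
        """Index of the optimal allele (offset 0)."""
        return self.half_width

    def index_of(self, k: int) -> int:
        if abs(k) > self.half_width:
            raise InvalidGridError(f"offset {k} outside grid of width {self.n}")
        return k + self.half_width


@dataclass(frozen=True)
class MutationModel:
    """Length-dependent generalized stepwise mutation model.

    ``ref_len`` is the allele length (repeat units) at which ``mu0`` applies;
    ``None`` anchors it to the grid's optimal allele at evaluation time.
    Rates are clamped into ``[rate_floor, rate_cap]``.
    """

    mu0: float
    L: float = 0.0
    rho: float = 0.9
    beta: float = 0.0
    ref_len: int | None = None
    rate_floor: float = RATE_FLOOR
    rate_cap: float = RATE_CAP

    def __post_init__(self) -> None:
        if not 0.0 < self.mu0 <= self.rate_cap:
            raise ValueError(f"mu0 must be in (0, rate_cap], got {self.mu0}")
        if not 0.0 <= self.rate_floor < self.rate_cap <= 1.0:
            raise ValueError(
                f"need 0 <= rate_floor < rate_cap <= 1, got "
                f"({self.rate_floor}, {self.rate_cap})"
            )
        if not 0.0 < self.rho <= 1.0:
            raise ValueError(f"rho must be in (0, 1], got {self.rho}")
        if self.beta < 0.0:
            raise ValueError(f"beta must be >= 0, got {self.beta}")

    def rescaled(self, factor: float) -> "MutationModel":
        """Multiply rates (and clamp bounds) by ``factor`` for rescaled runs."""
        cap = min(self.rate_cap * factor, 1.0)
        return replace(
            self,
            mu0=min(self.mu0 * factor, cap),
            rate_floor=min(self.rate_floor * factor, cap / 10),
            rate_cap=cap,
        )


@dataclass(frozen=True)
class SelectionModel:
    """Linear selection around the optimal allele, homozygote scale."""

    s: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.s <= 1.0:
            raise ValueError(f"s must be in [0, 1], got {self.s}")

    def fitness(self, offsets: np.ndarray) -> np.ndarray:
        """Allele fitness ``w(k) = max(1 - s*|k|, 0)``."""
        return np.maximum(1.0 - self.s * np.abs(offsets), 0.0)


def validate_frequencies(freqs: np.ndarray, tol: float = 1e-6) -> np.ndarray:
    """Check a frequency vector is nonnegative and sums to 1; return as array."""
    p = np.asarray(freqs, dtype=float)
    if p.ndim != 1:
        raise ValueError(f"frequency vector must be 1-D, got shape {p.shape}")
    if np.any(p < 0):
        raise ValueError("frequencies must be nonnegative")
    total = p.sum()
    if abs(total - 1.0) > tol:
        raise ValueError(f"frequencies must sum to 1 (got {total!r})")
    return p


# ---------------------------------------------------------------------------
# mutation


def allele_mutation_rate(model: MutationModel, k: int, xopt: int) -> float:
    """Per-generation mutation rate of the allele at offset ``k``.

    Evaluates ``10**(log10(mu0) + L*((xopt + k) - ref_len))`` clamped into
    ``[rate_floor, rate_cap]``. With ``ref_len`` anchored at the optimum, the
    optimal allele mutates at exactly ``mu0``.
    """
    length = xopt + k
    if length < 1:
        raise InvalidGridError(
            f"allele length {length} (xopt={xopt}, k={k}) is nonpositive"
        )
    return _rate_at_length(model, length, xopt)


def _rate_at_length(model: MutationModel, length: float, xopt: int) -> float:
    ref = model.ref_len if model.ref_len is not None else xopt
    rate = 10.0 ** (math.log10(model.mu0) + model.L * (length - ref))
    return min(max(rate, model.rate_floor), model.rate_cap)


def step_direction_probs(beta: float, rho: float, k: int) -> tuple[float, float]:
    """Probabilities that a mutation expands vs. contracts at offset ``k``.

    ``p_expand = (1 - beta*rho*k)/2`` and ``p_contract = (1 + beta*rho*k)/2``,
    clamped into [0, 1] and renormalized. At the optimum both are 1/2; for
    long alleles (k > 0) contraction is favored, mirrored for short alleles.
    """
    if beta < 0:
        raise ValueError("beta must be >= 0")
    if not 0.0 < rho <= 1.0:
        raise ValueError("rho must be in (0, 1]")
    raw = beta * rho * k
    p_expand = min(max((1.0 - raw) / 2.0, 0.0), 1.0)
    p_contract = min(max((1.0 + raw) / 2.0, 0.0), 1.0)
    total = p_expand + p_contract
    return p_expand / total, p_contract / total


def build_mutation_matrix(model: MutationModel, grid: AlleleGrid) -> np.ndarray:
    """Row-stochastic per-generation allele transition matrix.

    ``T[i, j]`` is the probability an allele at offset ``k_i`` becomes
    ``k_j`` in one generation. The diagonal carries ``1 - mu(k_i)``; the
    mutant mass splits between directions by :func:`step_direction_probs`
    and over step sizes ``d`` as ``rho*(1-rho)**(d-1)``. Geometric mass for
    steps past the grid edge accumulates on the boundary allele so every
    row sums to exactly 1.

    Allele lengths below one repeat unit (possible on symmetric grids with a
    small optimum) have their rate evaluated at length 1; with ``L > 0``
    those states sit at or near the rate floor.
    """
    n = grid.n
    offsets = grid.offsets
    T = np.zeros((n, n))
    for i, k in enumerate(offsets):
        length = max(grid.xopt + int(k), 1)
        mu = _rate_at_length(model, length, grid.xopt)
        p_exp, p_con = step_direction_probs(model.beta, model.rho, int(k))
        T[i, i] += 1.0 - mu
        for sign, p_dir in ((1, p_exp), (-1, p_con)):
            max_d = (n - 1 - i) if sign > 0 else i
            if max_d == 0:
                # already on the boundary in this direction: mass stays put
                T[i, i] += mu * p_dir
                continue
            for d in range(1, max_d + 1):
                if d < max_d:
                    mass = model.rho * (1.0 - model.rho) ** (d - 1)
                else:
                    # geometric tail: all steps of size >= max_d hit the edge
                    mass = (1.0 - model.rho) ** (d - 1)
                T[i, i + sign * d] += mu * p_dir * mass
    return T


# ---------------------------------------------------------------------------
# selection and drift


def apply_selection(
    freqs: np.ndarray, sel: SelectionModel, grid: AlleleGrid
) -> np.ndarray:
    """One deterministic generation of viability selection.

    Random-mating diploids with additive fitness: allele ``i`` is reweighted
    by its marginal fitness ``(w_i + sum_j p_j w_j) / 2`` and the vector is
    renormalized by population mean fitness. Neutral input (``s = 0``) is
    returned unchanged.
    """
    p = validate_frequencies(freqs)
    if sel.s == 0.0:
        return p.copy()
    w = sel.fitness(grid.offsets)
    pbar = float(p @ w)
    marginal = 0.5 * (w + pbar)
    out = p * marginal
    total = out.sum()
    if total <= 0.0:
        raise DegenerateFitnessError("population mean fitness is zero")
    return out / total


def apply_drift(
    freqs: np.ndarray, neff: int, rng: np.random.Generator
) -> np.ndarray:
    """One generation of multinomial drift at diploid size ``neff``."""
    if neff < 1:
        raise ValueError(f"neff must be >= 1, got {neff}")
    p = validate_frequencies(freqs)
    counts = rng.multinomial(2 * neff, p / p.sum())
    return counts / (2 * neff)


# ---------------------------------------------------------------------------
# demography


@dataclass(frozen=True)
class Epoch:
    """One demographic epoch: ``N(t) = initial_size * exp(growth_rate * t)``
    for elapsed generations ``t`` in ``[0, duration]``. A constant epoch has
    ``growth_rate = 0``."""

    duration: int
    initial_size: float
    growth_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.duration < 1:
            raise ValueError(f"epoch duration must be >= 1, got {self.duration}")
        if self.initial_size < 1:
            raise ValueError(f"epoch size must be >= 1, got {self.initial_size}")

    def size_at(self, elapsed: float) -> float:
        return self.initial_size * math.exp(self.growth_rate * elapsed)


@dataclass(frozen=True)
class DemographicModel:
    """Ordered epochs, oldest first; total span = burn-in + recent history."""

    epochs: tuple[Epoch, ...]

    def __post_init__(self) -> None:
        if not self.epochs:
            raise ValueError("demographic model needs at least one epoch")

    @property
    def total_generations(self) -> int:
        return sum(e.duration for e in self.epochs)

    def size_at_forward(self, f: float) -> int:
        """Diploid size at forward time ``f`` generations after model start."""
        if f < 0:
            raise ValueError(f"forward time must be >= 0, got {f}")
        start = 0
        for epoch in self.epochs:
            if f < start + epoch.duration:
                return max(1, round(epoch.size_at(f - start)))
            start += epoch.duration
        # f == total span: end of the final epoch
        last = self.epochs[-1]
        return max(1, round(last.size_at(min(f - (start - last.duration), last.duration))))

    def size_trajectory(self) -> np.ndarray:
        """Per-generation diploid sizes, oldest generation first.

        Entry ``g`` equals :meth:`size_at_forward` at forward time ``g``
        (epochs are half-open on the right, so a size change takes effect in
        the generation it is dated to).
        """
        sizes = []
        for epoch in self.epochs:
            t = np.arange(0, epoch.duration, dtype=float)
            n = epoch.initial_size * np.exp(epoch.growth_rate * t)
            sizes.append(np.maximum(1, np.round(n)).astype(np.int64))
        return np.concatenate(sizes)

    def rescaled(self, factor: float) -> "DemographicModel":
        """Divide sizes and durations by ``factor``, multiply growth rates."""
        if factor <= 0:
            raise ValueError("rescale factor must be positive")
        new = tuple(
            Epoch(
                duration=max(1, round(e.duration / factor)),
                initial_size=max(1.0, e.initial_size / factor),
                growth_rate=e.growth_rate * factor,
            )
            for e in self.epochs
        )
        return DemographicModel(new)

    def to_config(self) -> list[dict]:
        """Epoch list as plain mappings (for YAML/JSON round-tripping)."""
        return [
            {
                "duration": e.duration,
                "initial_size": e.initial_size,
                "growth_rate": e.growth_rate,
            }
            for e in self.epochs
        ]

    @classmethod
    def from_config(cls, epochs: list[dict]) -> "DemographicModel":
        """Build from an epoch list of mappings with ``duration``,
        ``initial_size``, and optional ``growth_rate`` keys."""
        return cls(tuple(Epoch(**e) for e in epochs))


def population_size_at(demog: DemographicModel, generations_before_present: float) -> int:
    """Diploid effective size ``t`` generations before present.

    Times older than the model span return the ancestral (first-epoch) size;
    negative times raise.
    """
    t = generations_before_present
    if t < 0:
        raise ValueError(f"generations before present must be >= 0, got {t}")
    total = demog.total_generations
    if t > total:
        return max(1, round(demog.epochs[0].initial_size))
    return demog.size_at_forward(total - t)


# European demographic model: 50,000 burn-in generations at the ancestral
# size, expansion 5,920 generations ago, out-of-Africa bottleneck 2,040
# generations ago, European/Asian divergence 920 generations ago, then two
# exponential-growth phases to the present.
_EUR_GROWTH1_START = 1032.0
_EUR_GROWTH1_RATE = 0.00307
_EUR_GROWTH2_RATE = 0.0195


def european_demography(burn_in: int = 50_000) -> DemographicModel:
    """Built-in European demographic model (default 55,920-generation span)."""
    growth2_start = _EUR_GROWTH1_START * math.exp(_EUR_GROWTH1_RATE * 715)
    return DemographicModel(
        (
            Epoch(burn_in, 7310.0),
            Epoch(5920 - 2040, 14474.0),
            Epoch(2040 - 920, 1861.0),
            Epoch(920 - 205, _EUR_GROWTH1_START, _EUR_GROWTH1_RATE),
            Epoch(205, growth2_start, _EUR_GROWTH2_RATE),
        )
    )


# Default per-repeat-unit-length mutation models. Baselines anchor to de novo
# mutation-rate studies: dinucleotides are the most mutable (~1e-4 per
# generation at a typical 11-unit optimum), trinucleotides and tetranucleotides
# roughly an order of magnitude slower. Single-unit steps dominate (rho close
# to 1, decreasing with motif length) and a moderate length constraint
# (beta = 0.3) pulls long alleles back toward the optimum.
DEFAULT_MUTATION_MODELS: dict[int, MutationModel] = {
    2: MutationModel(mu0=1e-4, L=0.05, rho=0.9, beta=0.3),
    3: MutationModel(mu0=1e-5, L=0.05, rho=0.8, beta=0.3),
    4: MutationModel(mu0=1e-5, L=0.05, rho=0.7, beta=0.3),
}


def default_mutation_model(repeat_unit_len: int) -> MutationModel:
    """Default mutation model for a repeat-unit length (2, 3, or 4 bp)."""
    try:
        return DEFAULT_MUTATION_MODELS[repeat_unit_len]
    except KeyError:
        raise InvalidGridError(
            f"no default mutation model for unit length {repeat_unit_len}"
        ) from None
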