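"""Approximate Bayesian computation for STR selection inference.

Joint mode
----------
For a set of STR loci sharing a repeat unit and optimal allele, the selection
coefficient at each locus is assumed drawn from a gamma distribution,
``s ~ Gamma(a, b)`` (``b`` is the scale, so the DFE mean is ``a*b``). The
prior puts ``a ~ Uniform(0, 1)`` and a lognormal on the mean ``a*b``. Each of
``z`` ABC iterations draws ``(a, b)``, draws one ``s`` per locus, fetches a
simulated heterozygosity per locus from a precomputed lookup table (matching
``s`` after rounding to one significant digit, values below 1e-5 treated as
neutral), and scores the draw by the mean absolute difference between sorted
simulated and observed heterozygosity vectors. The lowest-distance fraction
(default 1%) is accepted, and the accepted pair with the median ``a*b`` is
the point estimate.

Per-locus mode
--------------
The older single-locus strategy: ABC over a discrete set of candidate ``s``
values against the one observed heterozygosity. Retained for comparison; at
loci with little variation it cannot separate low mutation rate from strong
selection, which is the failure mode joint estimation fixes.

Also here: mutation-model selection for putatively neutral loci (the
proportion of pooled ABC acceptances per candidate model approximates its
relative likelihood under a uniform model prior) and a simulation-based
Kolmogorov-Smirnov goodness-of-fit score.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .evo_model import AlleleGrid, DemographicModel, MutationModel
from .simulator import LookupTable, build_lookup_table, simulate_batch
from .summaries import LocusSet

__all__ = [
    "GammaPrior",
    "ABCConfig",
    "DFEPosterior",
    "PerLocusPosterior",
    "MutationModelFit",
    "RecoveryReport",
    "sample_prior",
    "joint_infer_dfe",
    "per_locus_infer",
    "select_mutation_model",
    "ks_fit_score",
    "validate_recovery",
]


@dataclass(frozen=True)
class GammaPrior:
    """Prior on the gamma DFE: ``a ~ U(a_low, a_high)`` and the mean ``a*b``
    lognormal with the underlying normal centered at ``mean_log_center`` with
    standard deviation ``mean_log_sd`` (natural logs). Defaults center the
    mean at 3e-4 with a spread factor of 30."""

    a_low: float = 0.0
    a_high: float = 1.0
    mean_log_center: float = math.log(0.0003)
    mean_log_sd: float = math.log(30.0)

    def __post_init__(self) -> None:
        if not self.a_low < self.a_high:
            raise ValueError("need a_low < a_high")
        if self.mean_log_sd <= 0:
            raise ValueError("mean_log_sd must be positive")


@dataclass(frozen=True)
class ABCConfig:
    """Rejection-ABC settings: ``n_draws`` prior draws, the lowest
    ``accept_fraction`` of distances accepted, observed sets subsampled to
    ``subset_size`` loci."""

    n_draws: int = 50_000
    accept_fraction: float = 0.01
    subset_size: int = 1000

    def __post_init__(self) -> None:
        if self.n_draws < 1:
            raise ValueError("n_draws must be >= 1")
        if not 0.0 < self.accept_fraction <= 1.0:
            raise ValueError("accept_fraction must be in (0, 1]")
        if self.n_draws * self.accept_fraction < 1:
            raise ValueError("n_draws * accept_fraction must be >= 1")
        if self.subset_size < 1:
            raise ValueError("subset_size must be >= 1")

    @property
    def n_accept(self) -> int:
        return math.ceil(self.n_draws * self.accept_fraction)


@dataclass
class DFEPosterior:
    """Accepted ``(a, b, distance)`` triples plus the median-``a*b`` point
    estimate. ``mean_s`` is ``a*b`` of the point estimate."""

    accepted_a: np.ndarray
    accepted_b: np.ndarray
    accepted_distance: np.ndarray
    point_estimate: tuple[float, float]

    def __post_init__(self) -> None:
        if len(self.accepted_a) == 0:
            raise ValueError("accepted set must be non-empty")

    @property
    def mean_s(self) -> float:
        a, b = self.point_estimate
        return a * b

    def to_tsv(self, path) -> None:
        pa, pb = self.point_estimate
        with open(path, "w") as fh:
            fh.write("a\tb\tmean_s\tdistance\tpoint_estimate\n")
            for a, b, d in zip(self.accepted_a, self.accepted_b, self.accepted_distance):
                flag = int(a == pa and b == pb)
                fh.write(f"{a:.10g}\t{b:.10g}\t{a * b:.10g}\t{d:.10g}\t{flag}\n")


@dataclass
class PerLocusPosterior:
    """Accepted per-locus selection coefficients and their median."""

    accepted_s: np.ndarray
    median_s: float


@dataclass
class MutationModelFit:
    """Per-candidate share of pooled ABC acceptances; ``best`` is argmax."""

    candidates: list[MutationModel]
    acceptance_proportions: np.ndarray
    best_index: int

    @property
    def best(self) -> MutationModel:
        return self.candidates[self.best_index]


def sample_prior(
    prior: GammaPrior, rng: np.random.Generator, size: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Draw ``(a, b)`` from the prior: ``a`` uniform, mean ``m`` lognormal,
    ``b = m / a``."""
    n = 1 if size is None else size
    a = rng.uniform(prior.a_low, prior.a_high, size=n)
    a = np.maximum(a, 1e-12)  # guard the measure-zero a == 0 draw
    m = rng.lognormal(prior.mean_log_center, prior.mean_log_sd, size=n)
    b = m / a
    if size is None:
        return float(a[0]), float(b[0])
    return a, b


def _subsample_hets(
    hets: np.ndarray, subset_size: int, rng: np.random.Generator
) -> np.ndarray:
    if len(hets) > subset_size:
        return rng.choice(hets, size=subset_size, replace=False)
    return np.asarray(hets, dtype=float)


def joint_infer_dfe(
    obs: LocusSet,
    table: LookupTable,
    rng: np.random.Generator,
    prior: GammaPrior | None = None,
    cfg: ABCConfig | None = None,
) -> DFEPosterior:
    """Jointly infer the gamma DFE for a set of loci by rejection ABC.

    The observed set is subsampled to ``cfg.subset_size`` loci if larger.
    Acceptance keeps exactly ``ceil(n_draws * accept_fraction)`` draws, ties
    at the boundary broken by draw order; with an even accepted set the
    point estimate is the lower-median ``a*b`` member.
    """
    prior = prior or GammaPrior()
    cfg = cfg or ABCConfig()
    obs_hets = np.sort(_subsample_hets(obs.hets, cfg.subset_size, rng))
    n_loci = len(obs_hets)
    z = cfg.n_draws

    a, b = sample_prior(prior, rng, size=z)
    s = rng.gamma(shape=a[:, None], scale=b[:, None], size=(z, n_loci))
    sim = table.sample_hets(s, rng)
    sim.sort(axis=1)
    dist = np.abs(sim - obs_hets[None, :]).mean(axis=1)

    order = np.argsort(dist, kind="stable")
    acc = order[: cfg.n_accept]
    acc_a, acc_b, acc_d = a[acc], b[acc], dist[acc]
    ab_order = np.argsort(acc_a * acc_b, kind="stable")
    med = ab_order[(len(acc) - 1) // 2]  # lower median
    return DFEPosterior(
        accepted_a=acc_a,
        accepted_b=acc_b,
        accepted_distance=acc_d,
        point_estimate=(float(acc_a[med]), float(acc_b[med])),
    )


def per_locus_infer(
    obs_freqs: np.ndarray,
    table: LookupTable,
    rng: np.random.Generator,
    s_prior: np.ndarray | None = None,
    cfg: ABCConfig | None = None,
) -> PerLocusPosterior:
    """Single-locus ABC over a discrete set of candidate s values.

    Each draw picks a candidate ``s`` uniformly, fetches a random lookup
    replicate at its rounded key, and scores ``|h_obs - h_sim|``; the lowest
    fraction is accepted and summarized by its median.
    """
    from .summaries import heterozygosity

    cfg = cfg or ABCConfig()
    h_obs = heterozygosity(obs_freqs)
    s_prior = np.asarray(table.s_keys if s_prior is None else s_prior, dtype=float)
    if len(s_prior) == 0:
        raise ValueError("s_prior must not be empty")

    z = cfg.n_draws
    s = s_prior[rng.integers(0, len(s_prior), size=z)]
    sim = table.sample_hets(s, rng)
    dist = np.abs(sim - h_obs)
    order = np.argsort(dist, kind="stable")
    acc_s = s[order[: cfg.n_accept]]
    return PerLocusPosterior(accepted_s=acc_s, median_s=float(np.median(acc_s)))


def select_mutation_model(
    obs: LocusSet,
    candidates: list[MutationModel],
    demog: DemographicModel,
    grid: AlleleGrid,
    rng: np.random.Generator,
    cfg: ABCConfig | None = None,
    sample_size: int = 1068,
    sims_per_candidate: int = 200,
    rescale: float = 1,
) -> MutationModelFit:
    """Score candidate mutation models for putatively neutral loci.

    Simulates a neutral (``s = 0``) replicate pool per candidate, then pools
    ABC draws uniformly across candidates: each draw picks a candidate,
    assembles a simulated heterozygosity set of matched size from its pool,
    and is scored by the sorted-vector L1 distance. The per-candidate share
    of the accepted draws approximates relative model likelihoods under a
    uniform model prior.
    """
    if not candidates:
        raise ValueError("need at least one candidate model")
    cfg = cfg or ABCConfig(n_draws=2000)
    obs_hets = np.sort(_subsample_hets(obs.hets, cfg.subset_size, rng))
    n_loci = len(obs_hets)

    pools = np.empty((len(candidates), sims_per_candidate))
    for c, mut in enumerate(candidates):
        freqs = simulate_batch(
            mut,
            np.zeros(sims_per_candidate),
            demog,
            grid,
            rng,
            sample_size=sample_size,
            rescale=rescale,
        )
        pools[c] = 1.0 - (freqs**2).sum(axis=1)

    z = cfg.n_draws
    cand = rng.integers(0, len(candidates), size=z)
    reps = rng.integers(0, sims_per_candidate, size=(z, n_loci))
    sim = pools[cand[:, None], reps]
    sim.sort(axis=1)
    dist = np.abs(sim - obs_hets[None, :]).mean(axis=1)
    acc = np.argsort(dist, kind="stable")[: cfg.n_accept]
    counts = np.bincount(cand[acc], minlength=len(candidates))
    proportions = counts / counts.sum()
    return MutationModelFit(
        candidates=list(candidates),
        acceptance_proportions=proportions,
        best_index=int(np.argmax(proportions)),
    )


def ks_fit_score(
    fitted: tuple[float, float] | None,
    obs: LocusSet,
    table: LookupTable,
    rng: np.random.Generator,
    n_rounds: int = 100,
    subsample_cap: int | None = None,
) -> int:
    """Kolmogorov-Smirnov goodness-of-fit score in [0, n_rounds].

    ``fitted`` is the inferred gamma DFE ``(a, b)``, or ``None`` for a
    neutral (``s = 0``) mutation-model fit. Each round simulates a
    heterozygosity set of matched size from the lookup table and compares it
    to the observed set with a two-sample, two-sided, asymptotic KS test; the
    score counts rounds with p > 0.05. Scores <= n_rounds/2 flag a poor fit
    (such classes are excluded from burden estimates).
    """
    score = 0
    for _ in range(n_rounds):
        obs_hets = obs.hets
        if subsample_cap is not None and len(obs_hets) > subsample_cap:
            obs_hets = rng.choice(obs_hets, size=subsample_cap, replace=False)
        n = len(obs_hets)
        if fitted is None:
            s = np.zeros(n)
        else:
            a, b = fitted
            s = rng.gamma(shape=a, scale=b, size=n) if a > 0 and b > 0 else np.zeros(n)
        sim = table.sample_hets(s, rng)
        res = stats.ks_2samp(obs_hets, sim, method="asymp")
        if res.pvalue > 0.05:
            score += 1
    return score


@dataclass
class RecoveryReport:
    """Output of a parameter-recovery validation run."""

    truth: tuple[float, float]
    estimates: list[tuple[float, float]] = field(default_factory=list)
    bin_edges: np.ndarray | None = None
    inferred_bin_fractions: np.ndarray | None = None
    true_bin_fractions: np.ndarray | None = None

    @property
    def mean_s_estimates(self) -> np.ndarray:
        return np.array([a * b for a, b in self.estimates])

    @property
    def mean_of_mean_s(self) -> float:
        return float(self.mean_s_estimates.mean())

    @property
    def median_mean_s(self) -> float:
        return float(np.median(self.mean_s_estimates))


DEFAULT_S_BIN_EDGES = np.array([0.0, 1e-5, 1e-4, 1e-3, 1e-2, 1e-1, 1.0, np.inf])


def validate_recovery(
    truth: tuple[float, float],
    mut: MutationModel,
    demog: DemographicModel,
    grid: AlleleGrid,
    rng: np.random.Generator,
    table: LookupTable | None = None,
    sample_size: int = 1068,
    n_loci: int = 1000,
    n_repeats: int = 20,
    sims_per_repeat: int = 2000,
    prior: GammaPrior | None = None,
    rescale: float = 1,
    n_bin_draws: int = 1000,
) -> RecoveryReport:
    """Ground-truth recovery protocol for the joint DFE inference.

    Simulates one dataset of ``n_loci`` loci with ``s ~ Gamma(truth)``, runs
    the joint ABC ``n_repeats`` times with ``sims_per_repeat`` draws each,
    and reports all point estimates plus binned inferred-vs-true s fractions
    (each bin row sums to 1).
    """
    a_true, b_true = truth
    class_key = ("sim", grid.xopt)
    if table is None:
        table = build_lookup_table(
            class_key, mut, demog, grid, sample_size, rng, rescale=rescale
        )
    s_true = (
        rng.gamma(shape=a_true, scale=b_true, size=n_loci)
        if a_true > 0 and b_true > 0
        else np.zeros(n_loci)
    )
    freqs = simulate_batch(
        mut, s_true, demog, grid, rng, sample_size=sample_size, rescale=rescale
    )
    obs = LocusSet(class_key=class_key, hets=1.0 - (freqs**2).sum(axis=1))

    cfg = ABCConfig(n_draws=sims_per_repeat, subset_size=n_loci)
    report = RecoveryReport(truth=truth)
    for _ in range(n_repeats):
        post = joint_infer_dfe(obs, table, rng, prior=prior, cfg=cfg)
        report.estimates.append(post.point_estimate)

    edges = DEFAULT_S_BIN_EDGES
    a_hat, b_hat = report.estimates[_lower_median_index(report.mean_s_estimates)]
    inferred_draws = (
        rng.gamma(shape=a_hat, scale=b_hat, size=n_bin_draws)
        if a_hat > 0 and b_hat > 0
        else np.zeros(n_bin_draws)
    )
    true_draws = (
        rng.gamma(shape=a_true, scale=b_true, size=n_bin_draws)
        if a_true > 0 and b_true > 0
        else np.zeros(n_bin_draws)
    )
    report.bin_edges = edges
    report.inferred_bin_fractions = _bin_fractions(inferred_draws, edges)
    report.true_bin_fractions = _bin_fractions(true_draws, edges)
    return report


def _lower_median_index(values: np.ndarray) -> int:
    order = np.argsort(values, kind="stable")
    return int(order[(len(values) - 1) // 2])


def _bin_fractions(draws: np.ndarray, edges: np.ndarray) -> np.ndarray:
    # first bin is closed on the left so s == 0 draws are counted
    counts, _ = np.histogram(draws, bins=edges)
    return counts / len(draws)
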