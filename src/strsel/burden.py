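"""Per-genome fitness-burden estimates for STR and SNV variation.

De novo STR burden per class ``c`` (repeat unit + optimal allele):

    Burden_c = N_c * 2 * mu_c * sum_{i=-20..20, i!=0} P(step = i) * s_c * 0.5 * |i|

where ``N_c`` is the locus count, ``mu_c`` the optimal-allele mutation rate,
``P(step = i) = 0.5 * rho * (1 - rho)**(|i| - 1)`` (symmetric truncated
geometric; mass past |i| = 20 is dropped and reported as a deficit), and the
factor 0.5 converts the homozygote-scale ``s_c`` to the effect of a single
mutant allele. Classes whose mutation/selection model fit poorly (KS score
<= 50 out of 100) contribute zero and are flagged.

De novo SNV burden uses the closed form ``Burden = 2 * L * mu * s`` with the
per-category mean selection coefficient on the heterozygote scale.

Inherited STR burden weights the DFE by present-day allele frequency: for an
observed allele at ``|offset|`` repeat units from the optimum, selection
coefficients are drawn from the class DFE, frequencies of that allele are
simulated under each draw, and one ``s`` is resampled with probability
proportional to the frequency with which that allele segregates — alleles far
from the optimum that are nonetheless common must sit at loci from the
neutral tail of the DFE.

The ``scaled`` flags divide STR burdens by 2 so they are comparable to SNV
conventions, where ``s`` refers to the heterozygote.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .simulator import LookupTable

__all__ = [
    "KS_EXCLUSION_THRESHOLD",
    "StrClassRecord",
    "SnvClassRecord",
    "InheritedVariant",
    "ClassBurden",
    "GenomewideBurden",
    "InheritedBurden",
    "denovo_str_class_burden",
    "genomewide_str_burden",
    "denovo_snv_burden",
    "table_draw_probabilities",
    "sample_s_from_pairs",
    "inherited_str_allele_s",
    "inherited_str_burden",
    "score_mutation",
    "NONSYNONYMOUS_SNVS",
    "CONSERVED_NONCODING_SNVS",
    "noncoding_snv_record",
]

KS_EXCLUSION_THRESHOLD = 50
MAX_INHERITED_OFFSET = 12  # simulations model 25 alleles, offsets -12..+12
MIN_BURDEN = 1e-5  # per-variant reductions below this round to 0
SNV_PER_BP_RATE = 1.2e-8
NONCODING_TARGET_BP = 1.83e9  # noncoding sites that could harbor selected SNVs


@dataclass(frozen=True)
class StrClassRecord:
    """Summary of one STR class: locus count, mutation-rate and DFE
    parameters, and the KS goodness-of-fit score (0-100)."""

    class_key: tuple[str, int]
    n_loci: int
    mu_opt: float
    rho: float
    mean_s: float
    ks_score: int
    a: float = 0.0
    b: float = 0.0

    def __post_init__(self) -> None:
        if self.n_loci < 0:
            raise ValueError("n_loci must be >= 0")
        if not 0 <= self.ks_score <= 100:
            raise ValueError("ks_score must be in [0, 100]")
        if not 0.0 < self.rho <= 1.0:
            raise ValueError("rho must be in (0, 1]")

    @property
    def excluded(self) -> bool:
        return self.ks_score <= KS_EXCLUSION_THRESHOLD


@dataclass(frozen=True)
class SnvClassRecord:
    """One SNV category with its heterozygote-scale mean s and either an
    explicit expected mutation count per diploid genome per generation or a
    (target size, per-bp rate) pair from which ``2 * L * mu`` is derived."""

    label: str
    mean_s: float
    mutations_per_generation: float | None = None
    target_size: float | None = None
    mu: float | None = None

    def __post_init__(self) -> None:
        if self.mutations_per_generation is None and (
            self.target_size is None or self.mu is None
        ):
            raise ValueError("need mutations_per_generation or (target_size, mu)")

    @property
    def expected_mutations(self) -> float:
        if self.mutations_per_generation is not None:
            return self.mutations_per_generation
        return 2.0 * self.target_size * self.mu


@dataclass(frozen=True)
class InheritedVariant:
    """One inherited STR allele call. ``offset`` is signed (allele minus
    optimal, repeat units); the burden uses its magnitude."""

    class_key: tuple[str, int]
    offset: int
    zygosity: str = "het"


class ClassBurden(NamedTuple):
    value: float
    excluded: bool
    truncation_deficit: float


def _step_burden_sum(rho: float, s: float, max_step: int) -> float:
    """sum over i = -max_step..max_step of P(step=i) * s * 0.5 * |i|."""
    i = np.arange(1, max_step + 1)
    p_one_side = 0.5 * rho * (1.0 - rho) ** (i - 1)
    return float(2.0 * np.sum(p_one_side * s * 0.5 * i))


def denovo_str_class_burden(
    rec: StrClassRecord, max_step: int = 20, scaled: bool = False
) -> ClassBurden:
    """Expected per-generation de novo burden for one STR class.

    Returns a flagged zero for poor-fit classes (KS score <= 50). The
    ``truncation_deficit`` is the geometric step mass beyond ``max_step``
    (dropped, not renormalized).
    """
    deficit = (1.0 - rec.rho) ** max_step
    if rec.excluded:
        return ClassBurden(0.0, True, deficit)
    value = rec.n_loci * 2.0 * rec.mu_opt * _step_burden_sum(rec.rho, rec.mean_s, max_step)
    if scaled:
        value /= 2.0
    return ClassBurden(value, False, deficit)


@dataclass
class GenomewideBurden:
    total_burden: float
    total_mutations: float
    excluded_classes: list[tuple[str, int]]

    @property
    def mean_burden_per_mutation(self) -> float:
        if self.total_mutations == 0:
            return 0.0
        return self.total_burden / self.total_mutations


def genomewide_str_burden(
    records: list[StrClassRecord], scaled: bool = False, max_step: int = 20
) -> GenomewideBurden:
    """Sum class burdens over well-fit classes; also totals expected
    mutations per generation (``2 * mu_c * N_c`` summed over the same
    classes)."""
    if not records:
        raise ValueError("need at least one class record")
    total = 0.0
    mutations = 0.0
    excluded = []
    for rec in records:
        cb = denovo_str_class_burden(rec, max_step=max_step, scaled=scaled)
        if cb.excluded:
            excluded.append(rec.class_key)
            continue
        total += cb.value
        mutations += 2.0 * rec.mu_opt * rec.n_loci
    return GenomewideBurden(
        total_burden=total, total_mutations=mutations, excluded_classes=excluded
    )


def denovo_snv_burden(rec: SnvClassRecord) -> float:
    """``Burden = 2 * L * mu * s`` = expected mutations x mean s."""
    return rec.expected_mutations * rec.mean_s


# Published SNV DFE bookkeeping (heterozygote-scale mean s; expected de novo
# mutation counts per diploid genome per generation).
NONSYNONYMOUS_SNVS = SnvClassRecord(
    label="nonsynonymous", mean_s=0.0066, mutations_per_generation=0.56
)
CONSERVED_NONCODING_SNVS = SnvClassRecord(
    label="conserved-noncoding", mean_s=0.00056, mutations_per_generation=2.54
)

# Reference genome-wide de novo STR summary (2-4 bp repeat units, classes
# with reliable model fit), on the allele (SNV-comparable, halved) scale.
# These aggregates summarize a genome-wide class table; they are the STR side
# of the STR-vs-SNV burden comparisons.
GENOMEWIDE_STR_MEAN_S_SCALED = 0.00038
GENOMEWIDE_STR_MUTATIONS_PER_GEN = 13.78
GENOMEWIDE_STR_BURDEN_SCALED = 0.0062


def noncoding_snv_record(fraction_under_selection: float) -> SnvClassRecord:
    """Noncoding SNV category assuming a fraction of noncoding sites is under
    selection (mean s 6.5e-4 on the heterozygote scale)."""
    if not 0.0 < fraction_under_selection <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    return SnvClassRecord(
        label=f"noncoding@{fraction_under_selection:g}",
        mean_s=0.00065,
        target_size=fraction_under_selection * NONCODING_TARGET_BP,
        mu=SNV_PER_BP_RATE,
    )


# ---------------------------------------------------------------------------
# inherited STR burden


def table_draw_probabilities(pairs: list[tuple[float, float]]) -> np.ndarray:
    """Draw probabilities over an (s, allele frequency) table: each s is
    drawn with probability proportional to its recorded frequency. A table
    {(1e-4, 0.5), (1e-3, 0.2), (1e-2, 0.1)} gives 5/8, 1/4, 1/8."""
    freqs = np.array([f for _s, f in pairs], dtype=float)
    total = math.fsum(freqs)
    if np.any(freqs < 0) or total <= 0:
        raise ValueError("frequencies must be nonnegative with positive total")
    return freqs / total


def sample_s_from_pairs(
    pairs: list[tuple[float, float]], rng: np.random.Generator
) -> float:
    """Draw one s from an (s, frequency) table, frequency-weighted."""
    probs = table_draw_probabilities(pairs)
    idx = rng.choice(len(pairs), p=probs)
    return float(pairs[idx][0])


def inherited_str_allele_s(
    class_rec: StrClassRecord,
    offset: int,
    table: LookupTable,
    rng: np.random.Generator,
    n_draws: int = 1000,
) -> float:
    """Frequency-weighted posterior draw of s for one inherited allele.

    Draws ``n_draws`` selection coefficients from the class DFE, pulls a
    simulated frequency vector for each (via the lookup table), records
    ``(s, frequency of the observed allele)`` whenever the allele segregates,
    and resamples one s proportionally to frequency. Returns 0 if the allele
    is the optimum, lies more than 12 repeat units away, or never appeared
    in any simulation.
    """
    k = abs(int(offset))
    if k == 0 or k > MAX_INHERITED_OFFSET:
        return 0.0
    half = table.freqs.shape[2] // 2
    if k > half:
        return 0.0
    if class_rec.a > 0 and class_rec.b > 0:
        s_draws = rng.gamma(shape=class_rec.a, scale=class_rec.b, size=n_draws)
    else:
        s_draws = np.zeros(n_draws)
    freqs = table.sample_freqs(s_draws, rng)
    col = half + int(offset) if abs(int(offset)) <= half else half + k
    allele_freq = freqs[:, col]
    seg = allele_freq > 0
    if not np.any(seg):
        return 0.0
    pairs = list(zip(s_draws[seg], allele_freq[seg]))
    return sample_s_from_pairs(pairs, rng)


@dataclass
class InheritedBurden:
    total_burden: float
    n_variants_scored: int
    n_variants_excluded: int


def inherited_str_burden(
    variants: list[InheritedVariant],
    records: dict[tuple[str, int], StrClassRecord],
    tables: dict[tuple[str, int], LookupTable],
    rng: np.random.Generator,
    scaled: bool = False,
    n_draws: int = 1000,
) -> InheritedBurden:
    """Total inherited STR burden over a genome's variant alleles.

    Per variant: ``reduction = |offset| * s`` with s drawn by
    :func:`inherited_str_allele_s`; reductions below 1e-5 round to 0 and
    above 1 clamp to 1. Poor-fit classes are excluded; with ``scaled`` all
    reductions are halved for SNV comparability.
    """
    total = 0.0
    scored = 0
    excluded = 0
    for var in variants:
        try:
            rec = records[var.class_key]
        except KeyError:
            raise KeyError(f"no class record for {var.class_key}") from None
        if rec.excluded:
            excluded += 1
            continue
        s = inherited_str_allele_s(
            rec, var.offset, tables[var.class_key], rng, n_draws=n_draws
        )
        reduction = abs(var.offset) * s
        if reduction < MIN_BURDEN:
            reduction = 0.0
        elif reduction > 1.0:
            reduction = 1.0
        if scaled:
            reduction /= 2.0
        total += reduction
        scored += 1
    return InheritedBurden(
        total_burden=total, n_variants_scored=scored, n_variants_excluded=excluded
    )


def score_mutation(
    class_rec: StrClassRecord, parent_offset: int, child_offset: int
) -> float:
    """Fitness change of a new (noninherited) allele relative to its parent:
    ``|child| * s - |parent| * s``; positive means more deleterious."""
    return (abs(child_offset) - abs(parent_offset)) * class_rec.mean_s
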