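"""File formats, locus filtering, class grouping, and synthetic datasets.

The native allele-frequency format is a tab-separated table with columns
``locus_id, chrom, pos, repeat_unit, ref_len_units, call_rate, counts``
where ``counts`` packs per-allele-length observation counts as
``"len:count,len:count,..."`` (lengths in repeat units). A minimal VCF
dialect carrying a repeat-unit INFO key and allele-count annotations can be
read as well.

Loci are filtered the way genotyping pipelines do before selection inference
(call-rate floor, per-unit-class minimum reference length) and grouped into
classes by canonicalized repeat unit and modal allele — the modal allele
stands in for the unknown optimal allele.

The synthetic-dataset generator runs the forward simulator under a known DFE
(or fixed s) and writes the same table format plus a truth sidecar, providing
fully reproducible ground-truth datasets for validation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .evo_model import AlleleGrid, DemographicModel, MutationModel
from .simulator import ErrorModel, inject_genotyping_errors, simulate_batch
from .summaries import LocusSet

logger = logging.getLogger(__name__)

__all__ = [
    "AlleleFreqRecord",
    "FreqTableError",
    "SyntheticDatasetSpec",
    "DEFAULT_MIN_LEN_UNITS",
    "canonical_repeat_unit",
    "read_freq_table",
    "write_freq_table",
    "read_vcf_counts",
    "filter_loci",
    "group_into_classes",
    "generate_synthetic_dataset",
]

DEFAULT_MIN_LEN_UNITS = {2: 11, 3: 5, 4: 7}

_COLUMNS = [
    "locus_id",
    "chrom",
    "pos",
    "repeat_unit",
    "ref_len_units",
    "call_rate",
    "counts",
]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


class FreqTableError(ValueError):
    """Raised for malformed allele-frequency tables, with line numbers."""


@dataclass
class AlleleFreqRecord:
    """Observed allele counts at one STR locus.

    ``allele_counts`` maps allele length in repeat units to the number of
    observed allele calls; coordinates are 1-based metadata only.
    """

    locus_id: str
    repeat_unit: str
    ref_len_units: int
    allele_counts: dict[int, int]
    call_rate: float = 1.0
    chrom: str | None = None
    pos: int | None = None

    def __post_init__(self) -> None:
        if len(self.repeat_unit) not in (2, 3, 4):
            raise ValueError(
                f"{self.locus_id}: repeat unit length must be 2-4 bp, "
                f"got {self.repeat_unit!r}"
            )
        if any(c not in "ACGT" for c in self.repeat_unit.upper()):
            raise ValueError(f"{self.locus_id}: repeat unit must be ACGT only")
        if any(c < 0 for c in self.allele_counts.values()):
            raise ValueError(f"{self.locus_id}: negative allele count")
        if self.total_alleles <= 0:
            raise ValueError(f"{self.locus_id}: zero total allele count")
        if not 0.0 <= self.call_rate <= 1.0:
            raise ValueError(f"{self.locus_id}: call_rate outside [0, 1]")

    @property
    def total_alleles(self) -> int:
        return sum(self.allele_counts.values())

    @property
    def unit_len(self) -> int:
        return len(self.repeat_unit)

    def modal_allele(self) -> int:
        """Most frequent allele length; ties break toward the shorter."""
        best = max(self.allele_counts.values())
        return min(a for a, c in self.allele_counts.items() if c == best)

    def frequencies(self) -> tuple[np.ndarray, np.ndarray]:
        """(sorted allele lengths, frequencies) for this locus."""
        lengths = np.array(sorted(self.allele_counts))
        counts = np.array([self.allele_counts[a] for a in lengths], dtype=float)
        return lengths, counts / counts.sum()

    def heterozygosity(self) -> float:
        _, p = self.frequencies()
        return float(1.0 - np.dot(p, p))


def canonical_repeat_unit(unit: str) -> str:
    """Lexicographically minimal rotation over both strands.

    Groups equivalent motifs: "TG" and "CA" both canonicalize to "AC".
    """
    unit = unit.upper()
    rc = unit.translate(_COMPLEMENT)[::-1]
    candidates = [
        seq[i:] + seq[:i] for seq in (unit, rc) for i in range(len(seq))
    ]
    return min(candidates)


# ---------------------------------------------------------------------------
# native TSV format


def _parse_counts(text: str) -> dict[int, int]:
    counts: dict[int, int] = {}
    for part in text.split(","):
        length_str, count_str = part.split(":")
        length, count = int(length_str), int(count_str)
        counts[length] = counts.get(length, 0) + count
    return counts


def read_freq_table(path) -> list[AlleleFreqRecord]:
    """Read the native allele-frequency TSV; raises :class:`FreqTableError`
    listing every malformed row with its line number."""
    records: list[AlleleFreqRecord] = []
    problems: list[str] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _COLUMNS:
            raise FreqTableError(
                f"{path}: expected columns {_COLUMNS}, got {header}"
            )
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != len(_COLUMNS):
                problems.append(f"line {lineno}: expected {len(_COLUMNS)} fields")
                continue
            try:
                records.append(
                    AlleleFreqRecord(
                        locus_id=fields[0],
                        chrom=fields[1] or None,
                        pos=int(fields[2]) if fields[2] else None,
                        repeat_unit=fields[3],
                        ref_len_units=int(fields[4]),
                        call_rate=float(fields[5]),
                        allele_counts=_parse_counts(fields[6]),
                    )
                )
            except (ValueError, KeyError) as exc:
                problems.append(f"line {lineno}: {exc}")
    if problems:
        raise FreqTableError(f"{path}: " + "; ".join(problems))
    return records


def write_freq_table(records: list[AlleleFreqRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_COLUMNS) + "\n")
        for rec in records:
            counts = ",".join(
                f"{a}:{rec.allele_counts[a]}" for a in sorted(rec.allele_counts)
            )
            fh.write(
                f"{rec.locus_id}\t{rec.chrom or ''}\t{rec.pos or ''}\t"
                f"{rec.repeat_unit}\t{rec.ref_len_units}\t{rec.call_rate:g}\t"
                f"{counts}\n"
            )


# ---------------------------------------------------------------------------
# minimal VCF dialect


def read_vcf_counts(
    path, ru_key: str = "RU", call_rate_key: str | None = "CALLRATE"
) -> list[AlleleFreqRecord]:
    """Read per-allele counts from an STR-genotyper VCF.

    Needs a repeat-unit INFO key (default ``RU``) and the standard ``AC``/
    ``AN`` allele-count annotations; allele lengths are converted from bp
    spans to repeat units. Records lacking the repeat unit, with a unit
    length outside 2-4 bp, or with spans that do not divide evenly by the
    unit are skipped with a warning. Alleles whose lengths collide are
    merged.
    """
    import pysam

    records: list[AlleleFreqRecord] = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            unit = rec.info.get(ru_key)
            if isinstance(unit, tuple):
                unit = unit[0]
            if unit is None:
                logger.warning("%s:%s lacks %s; skipped", rec.chrom, rec.pos, ru_key)
                continue
            unit = str(unit).upper()
            if len(unit) not in (2, 3, 4):
                logger.warning(
                    "%s:%s unit %r outside 2-4 bp; skipped", rec.chrom, rec.pos, unit
                )
                continue
            an = rec.info.get("AN")
            ac = rec.info.get("AC", ())
            if isinstance(ac, int):
                ac = (ac,)
            if an is None:
                logger.warning("%s:%s lacks AN; skipped", rec.chrom, rec.pos)
                continue
            alleles_bp = [len(rec.ref)] + [
                len(alt) for alt in (rec.alts or ())
            ]
            counts_bp = [an - sum(ac)] + list(ac)
            allele_counts: dict[int, int] = {}
            ok = True
            for span, count in zip(alleles_bp, counts_bp):
                if span % len(unit) != 0:
                    logger.warning(
                        "%s:%s allele span %d not a multiple of unit %r; skipped",
                        rec.chrom,
                        rec.pos,
                        span,
                        unit,
                    )
                    ok = False
                    break
                units = span // len(unit)
                allele_counts[units] = allele_counts.get(units, 0) + count
            if not ok:
                continue
            call_rate = 1.0
            if call_rate_key and call_rate_key in vcf.header.info:
                call_rate = rec.info.get(call_rate_key, 1.0)
                if isinstance(call_rate, tuple):
                    call_rate = call_rate[0]
            records.append(
                AlleleFreqRecord(
                    locus_id=rec.id or f"{rec.chrom}:{rec.pos}",
                    chrom=rec.chrom,
                    pos=rec.pos,
                    repeat_unit=unit,
                    ref_len_units=len(rec.ref) // len(unit),
                    call_rate=float(call_rate),
                    allele_counts=allele_counts,
                )
            )
    return records


# ---------------------------------------------------------------------------
# filtering and grouping


def filter_loci(
    records: list[AlleleFreqRecord],
    min_call_rate: float = 0.8,
    min_len_units: dict[int, int] | None = None,
) -> tuple[list[AlleleFreqRecord], dict[str, int]]:
    """Drop loci with low call rates or short reference alleles.

    The default length floors (11 units for dinucleotides, 5 for
    trinucleotides, 7 for tetranucleotides) remove repeats that are
    typically not polymorphic. Returns the kept records and a per-reason
    drop report; the operation is idempotent.
    """
    if min_len_units is None:
        min_len_units = DEFAULT_MIN_LEN_UNITS
    kept: list[AlleleFreqRecord] = []
    report = {"low_call_rate": 0, "short_reference": 0, "kept": 0}
    for rec in records:
        if rec.call_rate < min_call_rate:
            report["low_call_rate"] += 1
        elif rec.ref_len_units < min_len_units.get(rec.unit_len, 1):
            report["short_reference"] += 1
        else:
            kept.append(rec)
            report["kept"] += 1
    return kept, report


def group_into_classes(records: list[AlleleFreqRecord]) -> list[LocusSet]:
    """Group loci into (canonical repeat unit, modal allele) classes.

    Computes each locus's heterozygosity from count proportions; the modal
    allele (ties toward the shorter length) is assumed optimal. Classes come
    back sorted by key for reproducibility.
    """
    groups: dict[tuple[str, int], list[AlleleFreqRecord]] = {}
    for rec in records:
        key = (canonical_repeat_unit(rec.repeat_unit), rec.modal_allele())
        groups.setdefault(key, []).append(rec)
    out = []
    for key in sorted(groups):
        members = groups[key]
        out.append(
            LocusSet(
                class_key=key,
                hets=np.array([m.heterozygosity() for m in members]),
                locus_ids=[m.locus_id for m in members],
            )
        )
    return out


# ---------------------------------------------------------------------------
# synthetic datasets


@dataclass
class SyntheticDatasetSpec:
    """Recipe for a ground-truth dataset generated by the forward simulator.

    ``truth`` is either a fixed selection coefficient (float) or gamma DFE
    parameters ``(a, b)``. All randomness derives from ``seed``, so the
    output files are byte-identical across runs.
    """

    class_key: tuple[str, int]
    n_loci: int
    mutation_model: MutationModel
    demography: DemographicModel
    truth: float | tuple[float, float] = 0.0
    sample_size: int = 1068
    grid_n: int = 25
    error_model: ErrorModel | None = None
    rescale: float = 1
    seed: int = 0

    def draw_true_s(self, rng: np.random.Generator) -> np.ndarray:
        if isinstance(self.truth, tuple):
            a, b = self.truth
            if a <= 0 or b <= 0:
                return np.zeros(self.n_loci)
            return rng.gamma(shape=a, scale=b, size=self.n_loci)
        return np.full(self.n_loci, float(self.truth))


def generate_synthetic_dataset(
    spec: SyntheticDatasetSpec, out_prefix: str | Path | None = None
) -> tuple[list[AlleleFreqRecord], np.ndarray]:
    """Simulate a dataset under known selection and optionally write it.

    Returns the allele-frequency records and the per-locus true selection
    coefficients. With ``out_prefix`` set, writes ``<prefix>.tsv`` (the
    native format) and ``<prefix>.truth.tsv`` (locus id, true s, plus the
    spec parameters as comment lines).
    """
    unit, xopt = spec.class_key
    grid = AlleleGrid(xopt=xopt, repeat_unit_len=len(unit), n=spec.grid_n)
    rng = np.random.default_rng(spec.seed)
    s_true = spec.draw_true_s(rng)
    freqs = simulate_batch(
        spec.mutation_model,
        s_true,
        spec.demography,
        grid,
        rng,
        sample_size=None if spec.error_model else spec.sample_size,
        rescale=spec.rescale,
    )
    if spec.error_model is not None:
        freqs = np.array(
            [
                inject_genotyping_errors(
                    f, spec.sample_size, spec.error_model, grid, rng
                )
                for f in freqs
            ]
        )
    counts = np.rint(freqs * spec.sample_size).astype(int)
    offsets = grid.offsets
    records = []
    for i in range(spec.n_loci):
        allele_counts = {
            int(xopt + k): int(c) for k, c in zip(offsets, counts[i]) if c > 0
        }
        records.append(
            AlleleFreqRecord(
                locus_id=f"synth_{i}",
                chrom="chrS",
                pos=1000 * (i + 1),
                repeat_unit=unit,
                ref_len_units=xopt,
                call_rate=1.0,
                allele_counts=allele_counts,
            )
        )
    if out_prefix is not None:
        prefix = Path(out_prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        write_freq_table(records, f"{prefix}.tsv")
        with open(f"{prefix}.truth.tsv", "w") as fh:
            fh.write(f"# class_key={unit}:{xopt} n_loci={spec.n_loci}\n")
            fh.write(
                f"# truth={spec.truth} sample_size={spec.sample_size} "
                f"rescale={spec.rescale} seed={spec.seed}\n"
            )
            mm = spec.mutation_model
            fh.write(
                f"# mu0={mm.mu0:g} L={mm.L:g} rho={mm.rho:g} beta={mm.beta:g}\n"
            )
            fh.write("locus_id\ttrue_s\n")
            for i, s in enumerate(s_true):
                fh.write(f"synth_{i}\t{s:.10g}\n")
    return records, s_true
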