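"""Measures of within- and among-population variation for marker ranking.

Three statistics are computed per marker from population haplotype
frequencies:

* **Ae**, the effective number of alleles: the reciprocal of homozygosity,
  ``Ae = 1 / sum(p_i**2)``. A within-population diversity measure and a
  proxy for a marker's power for individual identification. Computed
  independently for each population and summarized as the unweighted
  arithmetic mean over populations.
* **In**, Rosenberg's informativeness for assignment: the difference in
  information content between the pooled allele frequency distribution and
  the per-population distributions,
  ``In = sum_j( -pbar_j * ln(pbar_j) + sum_i (p_ij / K) * ln(p_ij) )``
  over K populations, natural logarithm, with the ``0 * ln 0 = 0``
  convention. Bounded by ``0 <= In <= ln K``; a proxy for ancestry-inference
  power.
* **FST**, the fixation index in the Weir & Cockerham (1984)
  variance-component formulation. Each haplotype is treated as one allele
  of a multiallelic locus; per-allele estimates ``a / (a + b + c)`` are
  averaged (unweighted) over the alleles with a nonzero denominator.

The module also provides marker geometry: core marker length and distance
to the closest non-overlapping marker on the same chromosome.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .tables import Database, FrequencyRecord, MarkerDefinition

__all__ = [
    "PopulationFrequencyMatrix",
    "effective_number_of_alleles",
    "mean_ae",
    "informativeness",
    "fst_weir_cockerham",
    "marker_length",
    "closest_nonoverlapping_distance",
    "annotate_stats",
]

_ROW_SUM_TOL = 1e-9


@dataclass
class PopulationFrequencyMatrix:
    """K x N matrix of haplotype frequencies for one marker.

    Row ``i`` holds the frequency vector of population ``populations[i]``
    over the marker's N observed haplotypes (union over populations);
    haplotypes unobserved in a population appear with frequency 0. Each row
    sums to 1 within 1e-9.
    """

    marker: str
    populations: list[str]
    haplotypes: list[str]
    p: np.ndarray
    counts: Optional[np.ndarray] = None
    sample_sizes: Optional[np.ndarray] = None

    def __post_init__(self):
        self.p = np.asarray(self.p, dtype=float)
        if self.p.shape != (len(self.populations), len(self.haplotypes)):
            raise ValueError(
                f"frequency matrix shape {self.p.shape} does not match "
                f"{len(self.populations)} populations x {len(self.haplotypes)} haplotypes"
            )
        if np.any(self.p < -_ROW_SUM_TOL) or np.any(self.p > 1 + _ROW_SUM_TOL):
            raise ValueError("frequencies must lie in [0, 1]")
        sums = self.p.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > _ROW_SUM_TOL):
            bad = self.populations[int(np.argmax(np.abs(sums - 1.0)))]
            raise ValueError(
                f"marker {self.marker}: frequencies for population {bad} sum to "
                f"{sums.max():.9f}, expected 1"
            )

    @classmethod
    def from_records(
        cls, records: Sequence[FrequencyRecord], marker: Optional[str] = None
    ) -> "PopulationFrequencyMatrix":
        """Assemble the matrix from frequency records of a single marker.

        Rows are renormalized to sum exactly to 1, absorbing the rounding
        drift allowed in the flat files. When raw counts are present for
        every record, frequencies are recomputed from the counts instead.
        """
        records = list(records)
        if marker is not None:
            records = [r for r in records if r.marker == marker]
        if not records:
            raise ValueError("no frequency records supplied")
        names = {r.marker for r in records}
        if len(names) > 1:
            raise ValueError(f"records span multiple markers: {sorted(names)}")
        marker = records[0].marker
        populations = sorted({r.population for r in records})
        haplotypes = sorted({r.haplotype for r in records})
        pop_index = {p: i for i, p in enumerate(populations)}
        hap_index = {h: j for j, h in enumerate(haplotypes)}
        p = np.zeros((len(populations), len(haplotypes)))
        have_counts = all(r.count is not None for r in records)
        counts = np.zeros_like(p, dtype=int) if have_counts else None
        for r in records:
            i, j = pop_index[r.population], hap_index[r.haplotype]
            p[i, j] = r.frequency
            if have_counts:
                counts[i, j] = r.count
        if have_counts and counts.sum():
            totals = counts.sum(axis=1, keepdims=True)
            with np.errstate(invalid="ignore"):
                p = np.where(totals > 0, counts / np.maximum(totals, 1), p)
            sizes = counts.sum(axis=1)
        else:
            sizes = None
        p = p / p.sum(axis=1, keepdims=True)
        return cls(
            marker=marker,
            populations=populations,
            haplotypes=haplotypes,
            p=p,
            counts=counts,
            sample_sizes=sizes,
        )

    @property
    def num_populations(self) -> int:
        return len(self.populations)


def effective_number_of_alleles(p: Iterable[float]) -> float:
    """Effective number of alleles ``Ae = 1 / sum(p_i**2)``.

    Equals 1 iff a single haplotype is observed, and the number of
    haplotypes iff all are equally frequent. The input is renormalized over
    its nonzero entries, so a row sliced out of a multi-population matrix
    (with zeros for haplotypes absent from that population) is scored on
    its own conditional distribution.
    """
    p = np.asarray(list(p) if not isinstance(p, np.ndarray) else p, dtype=float)
    if p.size == 0:
        raise ValueError("empty frequency vector")
    if np.any(p < 0):
        raise ValueError("frequencies must be non-negative")
    total = p.sum()
    if total <= 0:
        raise ValueError("frequency vector sums to zero")
    p = p / total
    return float(1.0 / np.sum(p**2))


def mean_ae(matrix: PopulationFrequencyMatrix) -> tuple[dict[str, float], float]:
    """Per-population Ae and its unweighted mean across populations."""
    by_population = {
        pop: effective_number_of_alleles(row)
        for pop, row in zip(matrix.populations, matrix.p)
    }
    return by_population, float(np.mean(list(by_population.values())))


def informativeness(matrix: PopulationFrequencyMatrix) -> float:
    """Rosenberg's informativeness for assignment, in nats.

    ``In = sum_j( -pbar_j ln pbar_j + sum_i (p_ij / K) ln p_ij )`` where
    ``pbar_j`` is the unweighted mean of allele j's frequency over the K
    populations. Zero frequencies contribute nothing (``0 ln 0 = 0``).
    Equals 0 when all populations share one frequency vector and reaches
    ``ln K`` when no allele is shared between populations.
    """
    if matrix.num_populations < 2:
        raise ValueError("informativeness requires at least two populations")
    p = matrix.p
    k = matrix.num_populations
    pbar = p.mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        pooled = np.where(pbar > 0, -pbar * np.log(np.where(pbar > 0, pbar, 1.0)), 0.0)
        within = np.where(p > 0, (p / k) * np.log(np.where(p > 0, p, 1.0)), 0.0)
    value = float(pooled.sum() + within.sum())
    # The statistic is non-negative; residuals near 0 are float noise
    # (identical rows cancel only approximately in floating point).
    return 0.0 if abs(value) < 1e-12 else value


# -- Weir & Cockerham FST ------------------------------------------------


def _wc_components(
    n: np.ndarray, p: np.ndarray, h: np.ndarray
) -> tuple[float, float, float]:
    """Variance components (a, b, c) of Weir & Cockerham (1984) for one allele.

    ``n``: diploid sample sizes per population; ``p``: allele frequencies;
    ``h``: observed heterozygote proportions for the allele.
    """
    r = len(n)
    nbar = n.mean()
    nc = (r * nbar - np.sum(n**2) / (r * nbar)) / (r - 1)
    pbar = np.sum(n * p) / (r * nbar)
    s2 = np.sum(n * (p - pbar) ** 2) / ((r - 1) * nbar)
    hbar = np.sum(n * h) / (r * nbar)
    a = (nbar / nc) * (
        s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
    )
    c = hbar / 2
    return float(a), float(b), float(c)


def fst_weir_cockerham(
    diplotypes: dict[str, Sequence[tuple[str, str]]],
    average: str = "mean_of_ratios",
) -> float:
    """Mean per-allele Weir-Cockerham FST over a marker's haplotype alleles.

    Parameters
    ----------
    diplotypes
        population id -> list of per-individual diplotypes, each a pair of
        haplotype strings (the individual's two phased marker haplotypes,
        treated as one diploid genotype at a multiallelic locus). Haploid
        individuals (single-haplotype tuples, e.g. males at X markers) are
        excluded from this diploid estimator.
    average
        ``"mean_of_ratios"`` (default): unweighted mean of the per-allele
        ratios ``a / (a + b + c)`` over alleles with a nonzero denominator;
        negative per-allele estimates are retained and no clamping to
        [0, 1] is applied. ``"ratio_of_means"``: ``sum(a) / sum(a + b + c)``
        over the same alleles.

    Returns
    -------
    float
        The averaged estimate, or ``nan`` when undefined (fewer than two
        populations with diploid individuals, or a marker monomorphic
        across all populations).
    """
    if average not in ("mean_of_ratios", "ratio_of_means"):
        raise ValueError(f"unknown averaging mode {average!r}")
    pops = []
    for pop, genos in diplotypes.items():
        diploid = [g for g in genos if len(g) == 2]
        if diploid:
            pops.append((pop, diploid))
    if len(pops) < 2:
        return float("nan")
    alleles = sorted({h for _, genos in pops for g in genos for h in g})
    n = np.array([len(genos) for _, genos in pops], dtype=float)
    ratios = []
    a_sum = abc_sum = 0.0
    for allele in alleles:
        p = np.empty(len(pops))
        h = np.empty(len(pops))
        for i, (_, genos) in enumerate(pops):
            copies = sum((g[0] == allele) + (g[1] == allele) for g in genos)
            hets = sum((g[0] == allele) != (g[1] == allele) for g in genos)
            p[i] = copies / (2 * len(genos))
            h[i] = hets / len(genos)
        a, b, c = _wc_components(n, p, h)
        denom = a + b + c
        if denom != 0.0:
            ratios.append(a / denom)
            a_sum += a
            abc_sum += denom
    if not ratios:
        return float("nan")
    if average == "ratio_of_means":
        return float(a_sum / abc_sum)
    return float(np.mean(ratios))


# -- marker geometry -----------------------------------------------------


def marker_length(
    marker: MarkerDefinition, ref_lengths: Optional[Sequence[int]] = None
) -> int:
    """Core marker length: bases spanning the most distal variants, inclusive.

    For single-nucleotide variants this is ``last - first + 1``. When
    ``ref_lengths`` is given (reference allele length per variant, parallel
    to the marker's positions), each variant's span ends at
    ``pos + ref_len - 1``, so deletion-containing markers count their full
    reference footprint.
    """
    if ref_lengths is None:
        end = marker.end
    else:
        if len(ref_lengths) != marker.num_variants:
            raise ValueError("ref_lengths not parallel to marker positions")
        end = max(p + int(l) - 1 for p, l in zip(marker.positions, ref_lengths))
    return end - marker.start + 1


def closest_nonoverlapping_distance(
    markers: Sequence[MarkerDefinition],
) -> dict[str, Optional[int]]:
    """Distance from each marker to its closest non-overlapping neighbor.

    The distance is the number of bases strictly between the two marker
    spans (0 for abutting spans). Markers that overlap (share at least one
    position) are not neighbors. A marker alone on its chromosome, or
    overlapping everything there, gets ``None``.
    """
    result: dict[str, Optional[int]] = {}
    by_chrom: dict[str, list[MarkerDefinition]] = {}
    for m in markers:
        by_chrom.setdefault(m.chromosome, []).append(m)
    for chrom_markers in by_chrom.values():
        spans = [(m.start, m.end) for m in chrom_markers]
        for i, m in enumerate(chrom_markers):
            best: Optional[int] = None
            s1, e1 = spans[i]
            for j, (s2, e2) in enumerate(spans):
                if j == i:
                    continue
                if s2 <= e1 and s1 <= e2:  # overlapping spans
                    continue
                gap = s2 - e1 - 1 if s2 > e1 else s1 - e2 - 1
                if best is None or gap < best:
                    best = gap
            result[m.name] = best
    return result


def filter_markers(
    markers: Sequence[MarkerDefinition],
    exclude_x: bool = False,
    max_length: Optional[int] = None,
) -> list[MarkerDefinition]:
    """Subset markers for cross-statistic correlation analyses.

    X-chromosome markers (whose F_ST excludes male genotypes) and
    ultra-long markers (outliers in every statistic) can be dropped via
    ``exclude_x`` and ``max_length`` (core length in bp, inclusive bound).
    """
    result = []
    for marker in markers:
        if exclude_x and marker.chromosome == "chrX":
            continue
        if max_length is not None and marker_length(marker) > max_length:
            continue
        result.append(marker)
    return result


# -- database annotation -------------------------------------------------


def annotate_stats(
    db: Database,
    records: Optional[Sequence[FrequencyRecord]] = None,
    diplotypes: Optional[dict[str, dict[str, Sequence[tuple[str, str]]]]] = None,
    fst_average: str = "mean_of_ratios",
) -> Database:
    """Fill the Ae/In/Fst columns of the marker table from frequency data.

    Parameters
    ----------
    db
        Database to annotate (modified in place and returned).
    records
        Frequency records to compute from; defaults to ``db.frequencies``.
    diplotypes
        Optional marker name -> population -> per-individual diplotypes,
        required for the FST column (the Weir-Cockerham estimator needs
        genotypic, not just allelic, counts). Markers absent from the
        mapping get a missing FST.
    fst_average
        Per-allele averaging mode passed to :func:`fst_weir_cockerham`.

    Markers without frequency data keep missing values in all three
    columns; statistics are stored at the 4-decimal resolution of the flat
    marker table.
    """
    if records is None:
        records = db.frequencies
    by_marker: dict[str, list[FrequencyRecord]] = {}
    for r in records:
        by_marker.setdefault(r.marker, []).append(r)
    for marker in db.markers:
        recs = by_marker.get(marker.name)
        if not recs:
            continue
        matrix = PopulationFrequencyMatrix.from_records(recs)
        _, ae = mean_ae(matrix)
        in_stat = (
            informativeness(matrix) if matrix.num_populations >= 2 else None
        )
        fst = None
        if diplotypes is not None and marker.name in diplotypes:
            value = fst_weir_cockerham(diplotypes[marker.name], average=fst_average)
            fst = None if math.isnan(value) else value
        db.stats[marker.name] = {
            "Ae": round(ae, 4),
            "In": None if in_stat is None else round(in_stat, 4),
            "Fst": None if fst is None else round(fst, 4),
        }
    return db
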