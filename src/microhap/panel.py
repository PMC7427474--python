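"""Haplotype frequency estimation from phased genotype panels.

A :class:`PhasedPanel` holds phased genotype calls for a cohort of
individuals partitioned into population samples, typically read from a
phased VCF plus a two-column sample-to-population mapping. Per-marker
haplotypes are read directly off the phase strands: for each individual the
alleles on the same strand across the marker's component variants, in
position order, form one haplotype. Autosomal (and female X) individuals
contribute two haplotypes; males contribute the single haplotype observed
at X-chromosome markers. Tallies are compiled per population and
normalized by the population's allele total to give frequency estimates.

An individual is excluded from a marker (and from its denominator)
whenever any component call is missing, or is unphased and heterozygous —
a partial or unphaseable haplotype is not a haplotype. Homozygous calls
carry their phase trivially and are never excluded for lack of a phase
separator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .tables import FrequencyRecord, MarkerDefinition, normalize_chromosome

__all__ = [
    "Variant",
    "Individual",
    "PhasedPanel",
    "HaplotypeTally",
    "extract_individual_haplotypes",
    "tally_marker",
    "estimate_frequencies",
    "estimate_all",
    "marker_diplotypes",
    "read_population_map",
]

logger = logging.getLogger(__name__)

#: genotype array sentinel: no call at this variant for this sample
MISSING = -1
#: genotype array sentinel: no second allele (haploid call)
ABSENT = -2


@dataclass(frozen=True)
class Variant:
    """One genotyped variant site of the panel."""

    rsid: str
    chromosome: str
    position: int
    ref: str
    alts: tuple[str, ...]

    @property
    def alleles(self) -> tuple[str, ...]:
        return (self.ref,) + self.alts


@dataclass(frozen=True)
class Individual:
    id: str
    population: str
    sex: Optional[str] = None  # "M"/"F" when known


@dataclass
class PhasedPanel:
    """Phased genotypes for a multi-population cohort.

    ``genotypes[rsid]`` is an ``(n_samples, 2)`` int8 array of allele
    indices into the variant's ``alleles`` tuple; ``MISSING`` marks a
    missing call and ``ABSENT`` in the second column marks a haploid call.
    ``phased[rsid]`` is a boolean per-sample phase flag (haploid calls are
    trivially phased).
    """

    individuals: list[Individual]
    variants: dict[str, Variant] = field(default_factory=dict)
    genotypes: dict[str, np.ndarray] = field(default_factory=dict)
    phased: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        self._sample_index = {ind.id: i for i, ind in enumerate(self.individuals)}
        if len(self._sample_index) != len(self.individuals):
            raise ValueError("duplicate sample ids in panel")
        self._position_index = {}
        for v in self.variants.values():
            self._position_index[(v.chromosome, v.position)] = v.rsid

    def sample_index(self, sample: str) -> int:
        return self._sample_index[sample]

    @property
    def samples(self) -> list[str]:
        return [ind.id for ind in self.individuals]

    @property
    def populations(self) -> list[str]:
        return sorted({ind.population for ind in self.individuals})

    def add_variant(
        self, variant: Variant, genotypes: np.ndarray, phased: np.ndarray
    ) -> None:
        if variant.rsid in self.variants:
            raise ValueError(f"duplicate variant {variant.rsid}")
        self.variants[variant.rsid] = variant
        self.genotypes[variant.rsid] = genotypes
        self.phased[variant.rsid] = phased
        self._position_index[(variant.chromosome, variant.position)] = variant.rsid

    def resolve_variant(self, marker: MarkerDefinition, index: int) -> Optional[str]:
        """Resolve one component variant to a panel rsID.

        Matching is by rsID primarily, with a (chromosome, position)
        fallback; when both resolve and disagree, the rsID match wins and a
        warning is logged.
        """
        rsid = marker.rsids[index]
        by_rsid = rsid if rsid in self.variants else None
        key = (marker.chromosome, marker.positions[index])
        by_pos = self._position_index.get(key)
        if by_rsid is not None:
            if by_pos is not None and by_pos != by_rsid:
                logger.warning(
                    "marker %s: rsID %s and position %s:%d resolve to different "
                    "panel variants; using the rsID match",
                    marker.name,
                    rsid,
                    *key,
                )
            return by_rsid
        return by_pos

    @classmethod
    def from_vcf(
        cls,
        vcf_path: str | Path,
        population_map: dict[str, str] | str | Path,
        sexes: Optional[dict[str, str]] = None,
    ) -> "PhasedPanel":
        """Read a phased VCF (plain or bgzipped) and a sample->population map.

        Sex metadata, when provided, is cross-checked against the observed
        ploidy of X-chromosome calls (a haploid X call from a sample marked
        female, or vice versa, is logged); ploidy itself is always taken
        from the genotype field.
        """
        import pysam

        if not isinstance(population_map, dict):
            population_map = read_population_map(population_map)
        sexes = sexes or {}
        with pysam.VariantFile(str(vcf_path)) as vcf:
            samples = list(vcf.header.samples)
            unmapped = [s for s in samples if s not in population_map]
            if unmapped:
                raise ValueError(
                    f"{len(unmapped)} VCF sample(s) missing from the population "
                    f"map, e.g. {unmapped[0]!r}"
                )
            individuals = [
                Individual(id=s, population=population_map[s], sex=sexes.get(s))
                for s in samples
            ]
            panel = cls(individuals=individuals)
            n = len(samples)
            for rec in vcf:
                rsid = rec.id if rec.id not in (None, ".") else f"{rec.chrom}:{rec.pos}"
                chrom = normalize_chromosome(rec.chrom)
                genotypes = np.full((n, 2), MISSING, dtype=np.int8)
                phased = np.zeros(n, dtype=bool)
                for i, s in enumerate(samples):
                    call = rec.samples[s]
                    gt = call["GT"]
                    if gt is None or len(gt) == 0:
                        continue
                    alleles = [MISSING if a is None else a for a in gt]
                    if len(alleles) == 1:
                        genotypes[i] = (alleles[0], ABSENT)
                        phased[i] = True  # haploid calls are trivially phased
                    else:
                        genotypes[i] = alleles[:2]
                        phased[i] = bool(call.phased)
                variant = Variant(
                    rsid=rsid,
                    chromosome=chrom,
                    position=rec.pos,
                    ref=rec.ref,
                    alts=tuple(rec.alts or ()),
                )
                panel.add_variant(variant, genotypes, phased)
                if chrom == "chrX":
                    _crosscheck_sex(variant, genotypes, individuals)
        return panel


def _crosscheck_sex(
    variant: Variant, genotypes: np.ndarray, individuals: Sequence[Individual]
) -> None:
    for i, ind in enumerate(individuals):
        if ind.sex is None:
            continue
        haploid = genotypes[i, 1] == ABSENT
        if haploid and ind.sex == "F":
            logger.warning(
                "sample %s marked female but haploid at %s", ind.id, variant.rsid
            )
        elif not haploid and ind.sex == "M" and genotypes[i, 0] != MISSING:
            logger.warning(
                "sample %s marked male but diploid at %s", ind.id, variant.rsid
            )


def read_population_map(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV mapping sample id to population id.

    A header line is detected (and skipped) when its first field is
    ``sample`` case-insensitively.
    """
    mapping: dict[str, str] = {}
    with open(path, encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}, line {lineno}: expected 2 columns")
            if lineno == 1 and fields[0].lower() in ("sample", "sampleid", "sample_id"):
                continue
            mapping[fields[0]] = fields[1]
    return mapping


@dataclass
class HaplotypeTally:
    """Per-population haplotype counts for one marker.

    ``totals[pop]`` is the allele denominator: twice the number of included
    diploid individuals plus the number of included haploid (male X)
    individuals. ``excluded[pop]`` counts individuals dropped for missing
    or unphased component calls.
    """

    marker: str
    counts: dict[str, dict[str, int]] = field(default_factory=dict)
    totals: dict[str, int] = field(default_factory=dict)
    excluded: dict[str, int] = field(default_factory=dict)

    def validate(self) -> None:
        for pop, haps in self.counts.items():
            if sum(haps.values()) != self.totals.get(pop, 0):
                raise ValueError(
                    f"tally for ({self.marker}, {pop}): counts do not sum to "
                    f"the allele total"
                )


def extract_individual_haplotypes(
    panel: PhasedPanel, marker: MarkerDefinition, sample: str
) -> list[str]:
    """The phased marker haplotypes of one individual.

    Returns two comma-joined haplotype strings for diploid individuals, one
    for haploid (male X) individuals, or an empty list when the individual
    must be excluded: any component call missing, any heterozygous call
    unphased, or inconsistent ploidy across component variants.
    """
    rsids = []
    for i in range(marker.num_variants):
        rsid = panel.resolve_variant(marker, i)
        if rsid is None:
            raise KeyError(
                f"marker {marker.name}: variant {marker.rsids[i]} absent from panel"
            )
        rsids.append(rsid)
    idx = panel.sample_index(sample)
    strands: list[list[str]] = [[], []]
    ploidy = None
    for rsid in rsids:
        g = panel.genotypes[rsid][idx]
        variant = panel.variants[rsid]
        if g[0] == MISSING or (g[1] == MISSING):
            logger.debug("sample %s missing call at %s", sample, rsid)
            return []
        this_ploidy = 1 if g[1] == ABSENT else 2
        if ploidy is None:
            ploidy = this_ploidy
        elif ploidy != this_ploidy:
            logger.warning(
                "sample %s: inconsistent ploidy across %s; excluded", sample, marker.name
            )
            return []
        if this_ploidy == 2 and g[0] != g[1] and not panel.phased[rsid][idx]:
            logger.debug("sample %s unphased heterozygote at %s", sample, rsid)
            return []
        strands[0].append(variant.alleles[g[0]])
        if this_ploidy == 2:
            strands[1].append(variant.alleles[g[1]])
    if ploidy == 1:
        return [",".join(strands[0])]
    return [",".join(strands[0]), ",".join(strands[1])]


def tally_marker(panel: PhasedPanel, marker: MarkerDefinition) -> HaplotypeTally:
    """Compile per-population haplotype counts for one marker.

    Populations with no samples are omitted. Individuals excluded for
    missing or unphased calls reduce the allele denominator and are
    counted in the tally's ``excluded`` map.
    """
    tally = HaplotypeTally(marker=marker.name)
    for individual in panel.individuals:
        haplotypes = extract_individual_haplotypes(panel, marker, individual.id)
        pop = individual.population
        if not haplotypes:
            tally.excluded[pop] = tally.excluded.get(pop, 0) + 1
            tally.counts.setdefault(pop, {})
            tally.totals.setdefault(pop, 0)
            continue
        pop_counts = tally.counts.setdefault(pop, {})
        for hap in haplotypes:
            pop_counts[hap] = pop_counts.get(hap, 0) + 1
        tally.totals[pop] = tally.totals.get(pop, 0) + len(haplotypes)
    excluded_total = sum(tally.excluded.values())
    if excluded_total:
        logger.warning(
            "marker %s: %d individual(s) excluded for missing or unphased calls",
            marker.name,
            excluded_total,
        )
    return tally


def estimate_frequencies(tally: HaplotypeTally) -> list[FrequencyRecord]:
    """Normalize a tally by its per-population allele totals.

    Frequencies within each population sum to exactly 1 before any file
    rounding; raw counts are carried on the records. Populations with a
    zero allele total are skipped with a warning.
    """
    records: list[FrequencyRecord] = []
    for pop in sorted(tally.counts):
        total = tally.totals.get(pop, 0)
        if total == 0:
            logger.warning(
                "marker %s, population %s: no haplotypes observed; skipped",
                tally.marker,
                pop,
            )
            continue
        for hap in sorted(tally.counts[pop]):
            count = tally.counts[pop][hap]
            records.append(
                FrequencyRecord(
                    marker=tally.marker,
                    population=pop,
                    haplotype=hap,
                    frequency=count / total,
                    count=count,
                )
            )
    return records


def estimate_all(
    panel: PhasedPanel, markers: Sequence[MarkerDefinition]
) -> tuple[list[FrequencyRecord], dict[str, list[str]]]:
    """Estimate frequencies for every marker typable on the panel.

    Markers with at least one component variant absent from the panel's
    variant registry are excluded and reported in the returned mapping of
    marker name -> missing variant identifiers.
    """
    records: list[FrequencyRecord] = []
    exclusions: dict[str, list[str]] = {}
    for marker in markers:
        missing = [
            marker.rsids[i]
            for i in range(marker.num_variants)
            if panel.resolve_variant(marker, i) is None
        ]
        if missing:
            exclusions[marker.name] = missing
            continue
        records.extend(estimate_frequencies(tally_marker(panel, marker)))
    return records, exclusions


def marker_diplotypes(
    panel: PhasedPanel, marker: MarkerDefinition
) -> dict[str, list[tuple[str, ...]]]:
    """Per-population lists of individual diplotypes for one marker.

    Each included individual contributes a tuple of its marker haplotypes
    (length 2, or 1 for male X); this is the genotypic input the
    Weir-Cockerham FST estimator requires.
    """
    result: dict[str, list[tuple[str, ...]]] = {}
    for individual in panel.individuals:
        haplotypes = extract_individual_haplotypes(panel, marker, individual.id)
        if haplotypes:
            result.setdefault(individual.population, []).append(tuple(haplotypes))
    return result
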