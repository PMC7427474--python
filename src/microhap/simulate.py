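"""Synthetic marker panels and phased genotype cohorts with known truth.

The generator emulates the shape of a phased multi-population reference
panel: a set of microhaplotype markers on one or more chromosomes, a
companion reference sequence, and a cohort of individuals partitioned into
population samples whose two marker haplotypes are drawn i.i.d. from known
per-population haplotype distributions (males carry a single haplotype at
X-chromosome markers). Because the generating distributions are explicit,
every downstream estimate has an exact oracle. No linkage-disequilibrium
decay or mutation model is imposed between markers; distributions are
specified directly.

Determinism: all randomness flows from a single integer seed. Each marker
(and each chromosome and population) consumes an independent substream
keyed by hashing its name together with the seed, so enlarging a
simulation does not perturb the records already generated.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from itertools import product
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .panel import ABSENT, Individual, PhasedPanel, Variant
from .tables import (
    Database,
    MarkerDefinition,
    PopulationSample,
    chromosome_sort_key,
    write_database,
)

__all__ = [
    "SimulatedMarkers",
    "GeneratingModel",
    "SimulatedPanel",
    "simulate_markers",
    "random_model",
    "simulate_panel",
    "panel_to_vcf",
    "write_fixture",
    "fixture_database",
    "DEFAULT_POPULATIONS",
]

#: 26 population samples, the size of the global reference cohort the
#: estimation pipeline is designed around.
DEFAULT_POPULATIONS = tuple(f"POP{i:02d}" for i in range(1, 27))

#: Default cohort size per population (26 x 96 = 2,496 individuals,
#: matching the scale of the 2,504-genome global reference panel).
DEFAULT_POP_SIZE = 96

_BASES = np.array(list("ACGT"))


def _substream(seed: int, *names: str | int) -> np.random.Generator:
    """Independent generator keyed by the seed and a sequence of labels."""
    entropy = [seed & 0x7FFFFFFF]
    for name in names:
        if isinstance(name, int):
            entropy.append(name)
        else:
            entropy.append(zlib.crc32(name.encode("utf-8")))
    return np.random.default_rng(entropy)


def _chromosome_number(chromosome: str) -> str:
    base = chromosome[3:] if chromosome.startswith("chr") else chromosome
    return f"{int(base):02d}" if base.isdigit() else f"0{base.upper()}"


@dataclass
class SimulatedMarkers:
    """Markers plus the companion reference they were planted in."""

    markers: list[MarkerDefinition]
    variants: dict[str, Variant]
    reference: dict[str, str]
    seed: int

    def marker_variants(self, marker: MarkerDefinition) -> list[Variant]:
        return [self.variants[rsid] for rsid in marker.rsids]


def simulate_markers(
    n_markers: int,
    snp_count_range: tuple[int, int] = (2, 5),
    length_range: tuple[int, int] = (8, 150),
    chromosomes: Sequence[str] = ("chr1", "chr2", "chr3"),
    seed: int = 0,
    flank: int = 500,
    source: str = "synthetic",
) -> SimulatedMarkers:
    """Generate non-overlapping markers and a covering reference sequence.

    Markers are assigned to chromosomes round-robin and placed left to
    right with random inter-marker gaps; each marker draws its SNP count
    and core length (first-to-last variant span, inclusive) from the given
    ranges, with the length floored at the SNP count so positions can be
    strictly increasing. The reference covers every marker with at least
    ``flank`` bases on each side. Reproducible: a fixed seed yields
    identical output.
    """
    if snp_count_range[0] < 2 or snp_count_range[0] > snp_count_range[1]:
        raise ValueError(f"invalid SNP count range {snp_count_range}")
    if length_range[0] > length_range[1] or length_range[1] < snp_count_range[0]:
        raise ValueError(
            f"infeasible length range {length_range} for SNP counts {snp_count_range}"
        )
    chromosomes = [str(c) for c in chromosomes]
    markers: list[MarkerDefinition] = []
    variants: dict[str, Variant] = {}
    cursors = {c: flank for c in chromosomes}
    snp_sites: dict[str, list[tuple[int, str, tuple[str, ...]]]] = {
        c: [] for c in chromosomes
    }
    for serial in range(1, n_markers + 1):
        chrom = chromosomes[(serial - 1) % len(chromosomes)]
        name = f"mh{_chromosome_number(chrom)}SIM-{serial:04d}"
        rng = _substream(seed, name)
        n_snps = int(rng.integers(snp_count_range[0], snp_count_range[1] + 1))
        lo = max(length_range[0], n_snps)
        if lo > length_range[1]:
            raise ValueError(
                f"marker {name}: cannot fit {n_snps} variants in a span of at "
                f"most {length_range[1]} bp"
            )
        length = int(rng.integers(lo, length_range[1] + 1))
        gap = int(rng.integers(200, 1501))
        first = cursors[chrom] + gap
        last = first + length - 1
        interior = sorted(
            int(p)
            for p in rng.choice(
                np.arange(first + 1, last), size=n_snps - 2, replace=False
            )
        )
        positions = tuple([first] + interior + [last])
        rsids = tuple(
            f"rs{90000000 + serial * 100 + k}" for k in range(n_snps)
        )
        for k, (pos, rsid) in enumerate(zip(positions, rsids)):
            ref = str(rng.choice(_BASES))
            n_alts = 2 if rng.random() < 0.1 else 1
            others = [b for b in "ACGT" if b != ref]
            alts = tuple(
                str(a) for a in rng.choice(others, size=n_alts, replace=False)
            )
            variants[rsid] = Variant(
                rsid=rsid, chromosome=chrom, position=pos, ref=ref, alts=alts
            )
            snp_sites[chrom].append((pos, ref, alts))
        markers.append(
            MarkerDefinition(
                name=name,
                chromosome=chrom,
                positions=positions,
                rsids=rsids,
                source=source,
            )
        )
        cursors[chrom] = last
    reference: dict[str, str] = {}
    for chrom in chromosomes:
        length = cursors[chrom] + flank
        rng = _substream(seed, chrom)
        bases = rng.choice(_BASES, size=length)
        for pos, ref, _ in snp_sites[chrom]:
            bases[pos - 1] = ref
        reference[chrom] = "".join(bases)
    return SimulatedMarkers(
        markers=markers, variants=variants, reference=reference, seed=seed
    )


@dataclass
class GeneratingModel:
    """Known per-population haplotype distributions driving a simulation."""

    markers: SimulatedMarkers
    distributions: dict[str, dict[str, dict[str, float]]]
    population_sizes: dict[str, int]
    sex_ratio: float = 0.5
    seed: int = 0

    def __post_init__(self):
        for name, by_pop in self.distributions.items():
            marker = next(m for m in self.markers.markers if m.name == name)
            site_alleles = [
                set(v.alleles) for v in self.markers.marker_variants(marker)
            ]
            for pop, dist in by_pop.items():
                total = sum(dist.values())
                if abs(total - 1.0) > 1e-9:
                    raise ValueError(
                        f"distribution for ({name}, {pop}) sums to {total}"
                    )
                for hap in dist:
                    tokens = hap.split(",")
                    if len(tokens) != marker.num_variants or any(
                        t not in site_alleles[k] for k, t in enumerate(tokens)
                    ):
                        raise ValueError(
                            f"haplotype {hap!r} inconsistent with the variant "
                            f"alleles of marker {name}"
                        )


def random_model(
    markers: SimulatedMarkers,
    populations: Sequence[str] = DEFAULT_POPULATIONS,
    n_per_pop: int | dict[str, int] = DEFAULT_POP_SIZE,
    sex_ratio: float = 0.5,
    max_haplotypes: int = 8,
    concentration_range: tuple[float, float] = (5.0, 200.0),
    seed: Optional[int] = None,
) -> GeneratingModel:
    """Draw a generating model with population structure.

    For each marker, a base haplotype distribution is drawn over a random
    subset of the allelically possible haplotypes (2 to ``max_haplotypes``),
    and each population's distribution is a Dirichlet perturbation of the
    base with a per-marker concentration drawn log-uniformly from
    ``concentration_range``. Low concentrations yield strongly
    differentiated populations (high In and FST), high concentrations
    yield near-homogeneous ones, so a random marker set spans a realistic
    range of both statistics.
    """
    seed = markers.seed if seed is None else seed
    if isinstance(n_per_pop, int):
        sizes = {pop: n_per_pop for pop in populations}
    else:
        sizes = dict(n_per_pop)
    distributions: dict[str, dict[str, dict[str, float]]] = {}
    log_lo, log_hi = np.log(concentration_range[0]), np.log(concentration_range[1])
    for marker in markers.markers:
        rng = _substream(seed, marker.name, "model")
        site_alleles = [v.alleles for v in markers.marker_variants(marker)]
        combos = [",".join(c) for c in product(*site_alleles)]
        n_haps = int(rng.integers(2, min(max_haplotypes, len(combos)) + 1))
        chosen = sorted(rng.choice(combos, size=n_haps, replace=False))
        base = rng.dirichlet(np.ones(n_haps))
        theta = float(np.exp(rng.uniform(log_lo, log_hi)))
        by_pop: dict[str, dict[str, float]] = {}
        for pop in populations:
            p = rng.dirichlet(base * theta + 1e-3)
            by_pop[pop] = {hap: float(x) for hap, x in zip(chosen, p)}
        distributions[marker.name] = by_pop
    return GeneratingModel(
        markers=markers,
        distributions=distributions,
        population_sizes=sizes,
        sex_ratio=sex_ratio,
        seed=seed,
    )


@dataclass
class SimulatedPanel:
    """A drawn cohort: the phased panel plus the per-individual truth."""

    panel: PhasedPanel
    #: (marker name, sample id) -> tuple of the haplotypes actually drawn
    haplotypes: dict[tuple[str, str], tuple[str, ...]] = field(repr=False, default_factory=dict)


def simulate_panel(model: GeneratingModel) -> SimulatedPanel:
    """Draw a phased cohort from the generating model.

    Each individual's two haplotypes at each marker are drawn i.i.d. from
    the individual's population distribution; males receive a single
    haplotype at X-chromosome markers. The phase assignment in the
    resulting panel is consistent across a marker's component variants, so
    haplotype extraction inverts the simulation exactly.
    """
    populations = sorted(model.population_sizes)
    individuals: list[Individual] = []
    for pop in populations:
        rng = _substream(model.seed, pop, "sex")
        n = model.population_sizes[pop]
        males = rng.random(n) < model.sex_ratio
        for i in range(n):
            individuals.append(
                Individual(
                    id=f"{pop}-{i + 1:04d}",
                    population=pop,
                    sex="M" if males[i] else "F",
                )
            )
    panel = PhasedPanel(individuals=individuals)
    n_total = len(individuals)
    male_mask = np.array([ind.sex == "M" for ind in individuals])
    pop_slices: dict[str, slice] = {}
    offset = 0
    for pop in populations:
        n = model.population_sizes[pop]
        pop_slices[pop] = slice(offset, offset + n)
        offset += n

    result = SimulatedPanel(panel=panel)
    for marker in model.markers.markers:
        by_pop = model.distributions[marker.name]
        haps = sorted({h for dist in by_pop.values() for h in dist})
        hap_tokens = [h.split(",") for h in haps]
        on_x = marker.chromosome == "chrX"
        rng = _substream(model.seed, marker.name, "draw")
        draws = np.zeros((n_total, 2), dtype=np.int64)
        for pop in populations:
            sl = pop_slices[pop]
            p = np.array([by_pop[pop].get(h, 0.0) for h in haps])
            p = p / p.sum()
            draws[sl] = rng.choice(len(haps), size=(sl.stop - sl.start, 2), p=p)
        variants = model.markers.marker_variants(marker)
        for k, variant in enumerate(variants):
            allele_index = {a: i for i, a in enumerate(variant.alleles)}
            token_idx = np.array(
                [allele_index[tokens[k]] for tokens in hap_tokens], dtype=np.int8
            )
            genotypes = np.stack(
                [token_idx[draws[:, 0]], token_idx[draws[:, 1]]], axis=1
            )
            if on_x:
                genotypes[male_mask, 1] = ABSENT
            panel.add_variant(
                variant, genotypes, np.ones(n_total, dtype=bool)
            )
        for i, ind in enumerate(individuals):
            if on_x and male_mask[i]:
                drawn = (haps[draws[i, 0]],)
            else:
                drawn = (haps[draws[i, 0]], haps[draws[i, 1]])
            result.haplotypes[(marker.name, ind.id)] = drawn
    return result


def panel_to_vcf(model: GeneratingModel, panel: PhasedPanel) -> str:
    """Serialize the panel as a minimal phased VCF v4.2 text (GT-only).

    Records are sorted by chromosome and position, one record per
    component SNP, ``|`` as the phase separator and bare haploid calls for
    males at X-chromosome variants. Output is byte-identical for a fixed
    model.
    """
    lines = ["##fileformat=VCFv4.2", "##source=microhap-simulate"]
    for chrom in sorted(model.markers.reference, key=chromosome_sort_key):
        lines.append(
            f"##contig=<ID={chrom},length={len(model.markers.reference[chrom])}>"
        )
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    samples = panel.samples
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples)
    )
    ordered = sorted(
        panel.variants.values(),
        key=lambda v: (chromosome_sort_key(v.chromosome), v.position),
    )
    for variant in ordered:
        genotypes = panel.genotypes[variant.rsid]
        calls = [
            str(g[0]) if g[1] == ABSENT else f"{g[0]}|{g[1]}" for g in genotypes
        ]
        lines.append(
            "\t".join(
                [
                    variant.chromosome,
                    str(variant.position),
                    variant.rsid,
                    variant.ref,
                    ",".join(variant.alts),
                    ".",
                    ".",
                    ".",
                    "GT",
                ]
                + calls
            )
        )
    return "\n".join(lines) + "\n"


def _wrap_fasta(sequence: str, width: int = 80) -> list[str]:
    return [sequence[i : i + width] for i in range(0, len(sequence), width)]


def fixture_database(
    model: GeneratingModel, flank: int = 200, population_source: str = "synthetic"
) -> Database:
    """A queryable database for the simulated markers (no frequencies yet).

    Stored per-marker sequences window the reference by ``flank`` bases on
    each side of the marker span.
    """
    db = Database()
    db.markers = list(model.markers.markers)
    db.populations = [
        PopulationSample(id=pop, name=pop, source=population_source)
        for pop in sorted(model.population_sizes)
    ]
    for marker in db.markers:
        ref = model.markers.reference[marker.chromosome]
        start = max(1, marker.start - flank)
        end = min(len(ref), marker.end + flank)
        db.sequences[marker.name] = (start, ref[start - 1 : end])
    db.variantmap = sorted(
        (rsid, m.name) for m in db.markers for rsid in m.rsids
    )
    db.sort()
    return db


def write_fixture(
    model: GeneratingModel, simulated: SimulatedPanel, directory: str | Path
) -> None:
    """Write the complete synthetic fixture to a directory.

    Emits ``panel.vcf`` (phased genotypes), ``populations.tsv`` (the
    sample-to-population map), ``reference.fasta``, ``truth.tsv`` (the
    generating distributions, for test oracles), and the database tables
    for the markers (``marker.tsv`` etc.).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_database(fixture_database(model), directory)
    with open(directory / "panel.vcf", "w", encoding="utf-8", newline="\n") as out:
        out.write(panel_to_vcf(model, simulated.panel))
    with open(directory / "populations.tsv", "w", encoding="utf-8", newline="\n") as out:
        out.write("sample\tpopulation\n")
        for ind in simulated.panel.individuals:
            out.write(f"{ind.id}\t{ind.population}\n")
    with open(directory / "reference.fasta", "w", encoding="utf-8", newline="\n") as out:
        for chrom in sorted(model.markers.reference, key=chromosome_sort_key):
            out.write(f">{chrom}\n")
            for line in _wrap_fasta(model.markers.reference[chrom]):
                out.write(line + "\n")
    with open(directory / "truth.tsv", "w", encoding="utf-8", newline="\n") as out:
        out.write("Marker\tPopulation\tHaplotype\tFrequency\n")
        for name in sorted(model.distributions):
            for pop in sorted(model.distributions[name]):
                dist = model.distributions[name][pop]
                for hap in sorted(dist):
                    out.write(f"{name}\t{pop}\t{hap}\t{dist[hap]!r}\n")
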