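"""File-backed microhaplotype database: markers, populations, frequencies.

The database is a directory of plain-text tab-delimited tables. Three core
tables (``marker.tsv``, ``population.tsv``, ``frequency.tsv``) carry the
marker definitions, population sample descriptions, and per-population
haplotype frequencies. Ancillary tables (``idmap.tsv``, ``variantmap.tsv``,
``sequence.tsv``, ``altcoords.tsv``) carry cross-references, marker flanking
sequences, and alternate-assembly coordinates. All tables are UTF-8 with LF
line endings and a header row, so the whole database can be read with any
spreadsheet or dataframe library.

Coordinates are 1-based inclusive in all files and public attributes,
matching dbSNP/VCF convention; interval arithmetic elsewhere in the package
converts to 0-based half-open internally.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

__all__ = [
    "MarkerDefinition",
    "PopulationSample",
    "FrequencyRecord",
    "Database",
    "DatabaseError",
    "MissingTableError",
    "IntegrityError",
    "load_database",
    "write_database",
    "merge_sources",
    "FREQUENCY_SUM_TOLERANCE",
]

#: Maximum allowed drift of a per-(marker, population) frequency sum from 1.
#: Published tables are commonly rounded to three decimals, so a few parts
#: per thousand of drift is tolerated on load; exact renormalization is only
#: applied when explicitly requested.
FREQUENCY_SUM_TOLERANCE = 0.005

# Standard nomenclature: "mh" + two-character chromosome designator + lab
# designator (2+ letters) + "-" + identifier, e.g. mh01KK-172, mh06PK-25713.
_NAME_PATTERN = re.compile(r"^mh(\d{2}|0?[XY])[A-Za-z]{2,}-\S+$")

_MARKER_COLUMNS = ["Name", "Source", "Chrom", "Offsets", "Ae", "In", "Fst", "RSIDs"]
_POPULATION_COLUMNS = ["ID", "Name", "Source"]
_FREQUENCY_COLUMNS = ["Marker", "Population", "Allele", "Frequency", "Count"]


class DatabaseError(Exception):
    """Base class for database validation and I/O failures."""


class MissingTableError(DatabaseError):
    """A required core table file is absent from the database directory."""


class IntegrityError(DatabaseError):
    """A record violates a type invariant or a cross-table reference."""


def normalize_chromosome(label: str) -> str:
    """Normalize a chromosome label to the ``chr``-prefixed dialect.

    Accepts both ``1`` and ``chr1`` style labels on input; ``MT`` is mapped
    to ``chrM``.
    """
    label = str(label).strip()
    if label.lower().startswith("chr"):
        label = label[3:]
    if label.upper() == "MT":
        label = "M"
    return f"chr{label}"


def chromosome_sort_key(chromosome: str):
    """Sort key placing autosomes numerically, then X, Y, M, then others."""
    base = chromosome[3:] if chromosome.lower().startswith("chr") else chromosome
    if base.isdigit():
        return (0, int(base), "")
    special = {"X": 23, "Y": 24, "M": 25}
    if base.upper() in special:
        return (0, special[base.upper()], "")
    return (1, 0, base)


@dataclass(frozen=True)
class MarkerDefinition:
    """A microhaplotype marker: an ordered set of >= 2 variants on one chromosome.

    Parameters
    ----------
    name
        Marker designator. Standard nomenclature is
        ``mh<chrom><lab designator>-<id>`` (e.g. ``mh01KK-172``); legacy
        names are accepted but reported by :attr:`standard_nomenclature`.
    chromosome
        Chromosome label; normalized to the ``chr`` prefix.
    positions
        1-based coordinates of the component variants on the primary
        assembly, strictly increasing.
    rsids
        dbSNP identifiers, parallel to ``positions``.
    source
        Publication or source label.
    alt_positions
        Optional parallel coordinates on a second (alternate) assembly.
    """

    name: str
    chromosome: str
    positions: tuple[int, ...]
    rsids: tuple[str, ...]
    source: str = ""
    alt_positions: Optional[tuple[int, ...]] = None

    def __post_init__(self):
        object.__setattr__(self, "chromosome", normalize_chromosome(self.chromosome))
        object.__setattr__(self, "positions", tuple(int(p) for p in self.positions))
        object.__setattr__(self, "rsids", tuple(str(r) for r in self.rsids))
        if self.alt_positions is not None:
            object.__setattr__(
                self, "alt_positions", tuple(int(p) for p in self.alt_positions)
            )
        if len(self.positions) < 2:
            raise IntegrityError(
                f"marker {self.name}: needs >= 2 component variants, "
                f"got {len(self.positions)}"
            )
        if len(self.rsids) != len(self.positions):
            raise IntegrityError(
                f"marker {self.name}: {len(self.positions)} positions but "
                f"{len(self.rsids)} rsIDs"
            )
        if any(b <= a for a, b in zip(self.positions, self.positions[1:])):
            raise IntegrityError(
                f"marker {self.name}: positions must be strictly increasing, "
                f"got {self.positions}"
            )
        if self.alt_positions is not None and len(self.alt_positions) != len(
            self.positions
        ):
            raise IntegrityError(
                f"marker {self.name}: alternate coordinates not parallel to positions"
            )

    @property
    def num_variants(self) -> int:
        return len(self.positions)

    @property
    def start(self) -> int:
        """1-based coordinate of the first component variant."""
        return self.positions[0]

    @property
    def end(self) -> int:
        """1-based coordinate of the last component variant."""
        return self.positions[-1]

    @property
    def standard_nomenclature(self) -> bool:
        """Whether the name follows the community ``mhNNXX-id`` convention."""
        return bool(_NAME_PATTERN.match(self.name))

    def definition_key(self):
        """Identity of the definition irrespective of name and source."""
        return (self.chromosome, self.positions, self.rsids)


@dataclass(frozen=True)
class PopulationSample:
    """A population sample or cohort for which frequencies may be reported."""

    id: str
    name: str
    source: str = ""


@dataclass(frozen=True)
class FrequencyRecord:
    """Frequency of one haplotype of one marker in one population.

    The haplotype is a comma-joined allele string with one token per
    component variant (e.g. ``"A,T,C"``). Deletion alleles use the token
    ``del``; insertion alleles spell out the full inserted sequence.
    """

    marker: str
    population: str
    haplotype: str
    frequency: float
    count: Optional[int] = None

    def __post_init__(self):
        object.__setattr__(self, "frequency", float(self.frequency))
        if not 0.0 <= self.frequency <= 1.0:
            raise IntegrityError(
                f"frequency record ({self.marker}, {self.population}, "
                f"{self.haplotype}): frequency {self.frequency} outside [0, 1]"
            )
        if self.count is not None:
            object.__setattr__(self, "count", int(self.count))
            if self.count < 0:
                raise IntegrityError(
                    f"frequency record ({self.marker}, {self.population}, "
                    f"{self.haplotype}): negative count {self.count}"
                )

    @property
    def alleles(self) -> tuple[str, ...]:
        return tuple(self.haplotype.split(","))


def _marker_sort_key(marker: MarkerDefinition):
    return (chromosome_sort_key(marker.chromosome), marker.start, marker.name)


@dataclass
class Database:
    """In-memory view of the tab-delimited microhaplotype database.

    Attributes
    ----------
    markers
        Marker definitions, kept in coordinate order (chromosome, start,
        name).
    populations
        Population sample descriptions, keyed lookups via :meth:`population`.
    frequencies
        Per-(marker, population) haplotype frequency records.
    idmap
        (third-party identifier, canonical marker name) cross-references.
    variantmap
        (rsID, marker name) pairs; derivable from the markers but stored so
        the flat files are self-contained.
    sequences
        marker name -> (1-based start coordinate, flanking sequence).
    stats
        marker name -> {"Ae": float|None, "In": float|None, "Fst": float|None},
        the summary statistics column values of the marker table.
    collisions
        Names that collided during a merge (same name, different
        definition); informational, not serialized.
    """

    markers: list[MarkerDefinition] = field(default_factory=list)
    populations: list[PopulationSample] = field(default_factory=list)
    frequencies: list[FrequencyRecord] = field(default_factory=list)
    idmap: list[tuple[str, str]] = field(default_factory=list)
    variantmap: list[tuple[str, str]] = field(default_factory=list)
    sequences: dict[str, tuple[int, str]] = field(default_factory=dict)
    stats: dict[str, dict[str, Optional[float]]] = field(default_factory=dict)
    collisions: list[str] = field(default_factory=list, compare=False)

    # -- lookups ---------------------------------------------------------

    def marker(self, name: str) -> MarkerDefinition:
        for marker in self.markers:
            if marker.name == name:
                return marker
        raise KeyError(name)

    def population(self, population_id: str) -> PopulationSample:
        for pop in self.populations:
            if pop.id == population_id:
                return pop
        raise KeyError(population_id)

    @property
    def marker_names(self) -> set[str]:
        return {m.name for m in self.markers}

    def markers_by_rsid(self, rsid: str) -> list[MarkerDefinition]:
        names = {name for rs, name in self.variantmap if rs == rsid}
        names.update(m.name for m in self.markers if rsid in m.rsids)
        return [m for m in self.markers if m.name in names]

    def frequencies_for(
        self, marker: Optional[str] = None, population: Optional[str] = None
    ) -> list[FrequencyRecord]:
        records = self.frequencies
        if marker is not None:
            records = [r for r in records if r.marker == marker]
        if population is not None:
            records = [r for r in records if r.population == population]
        return records

    def sort(self) -> None:
        """Impose the canonical record order on all collections."""
        self.markers.sort(key=_marker_sort_key)
        self.populations.sort(key=lambda p: p.id)
        self.frequencies.sort(key=lambda r: (r.marker, r.population, r.haplotype))
        self.idmap.sort()
        self.variantmap.sort()

    # -- validation ------------------------------------------------------

    def validate(self, renormalize: bool = False) -> None:
        """Check all type and referential invariants, raising on violation.

        With ``renormalize=True``, per-group frequency sums within the load
        tolerance of 1 are rescaled to sum exactly to 1; sums outside the
        tolerance are an error either way.
        """
        seen = set()
        marker_names = {}
        for marker in self.markers:
            if marker.name in seen:
                raise IntegrityError(f"duplicate marker name {marker.name!r}")
            seen.add(marker.name)
            marker_names[marker.name] = marker
        pop_ids = set()
        for pop in self.populations:
            if pop.id in pop_ids:
                raise IntegrityError(f"duplicate population id {pop.id!r}")
            pop_ids.add(pop.id)
        groups: dict[tuple[str, str], float] = {}
        for i, record in enumerate(self.frequencies):
            if record.marker not in marker_names:
                raise IntegrityError(
                    f"frequency row {i + 1} ({record.marker}, {record.population}, "
                    f"{record.haplotype}): unknown marker {record.marker!r}"
                )
            if record.population not in pop_ids:
                raise IntegrityError(
                    f"frequency row {i + 1} ({record.marker}, {record.population}, "
                    f"{record.haplotype}): unknown population {record.population!r}"
                )
            expected = marker_names[record.marker].num_variants
            if len(record.alleles) != expected:
                raise IntegrityError(
                    f"frequency row {i + 1} ({record.marker}, {record.population}, "
                    f"{record.haplotype}): haplotype has {len(record.alleles)} "
                    f"allele tokens, marker defines {expected} variants"
                )
            key = (record.marker, record.population)
            groups[key] = groups.get(key, 0.0) + record.frequency
        for (marker_name, pop), total in groups.items():
            if abs(total - 1.0) > FREQUENCY_SUM_TOLERANCE:
                raise IntegrityError(
                    f"frequencies for ({marker_name}, {pop}) sum to {total:.6f}, "
                    f"outside 1 +/- {FREQUENCY_SUM_TOLERANCE}"
                )
        if renormalize:
            self.frequencies = [
                replace(r, frequency=r.frequency / groups[(r.marker, r.population)])
                for r in self.frequencies
            ]
        for rsid, name in self.variantmap:
            if name not in marker_names:
                raise IntegrityError(
                    f"variantmap entry ({rsid}, {name}): unknown marker {name!r}"
                )
            if rsid not in marker_names[name].rsids:
                raise IntegrityError(
                    f"variantmap entry ({rsid}, {name}): rsID not among the "
                    f"marker's component variants"
                )
        for name in self.sequences:
            if name not in marker_names:
                raise IntegrityError(f"sequence entry for unknown marker {name!r}")
        nonstandard = [m.name for m in self.markers if not m.standard_nomenclature]
        if nonstandard:
            warnings.warn(
                f"{len(nonstandard)} marker name(s) do not follow the standard "
                f"mhNNXX-id nomenclature: {', '.join(sorted(nonstandard)[:5])}"
                + ("..." if len(nonstandard) > 5 else ""),
                stacklevel=2,
            )


# -- serialization -------------------------------------------------------


def _format_stat(value: Optional[float]) -> str:
    return "" if value is None else f"{value:.4f}"


def _read_table(path: Path, columns: Sequence[str]) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in columns if c not in frame.columns]
    if missing:
        raise IntegrityError(f"{path.name}: missing column(s) {missing}")
    return frame


def load_database(directory: str | Path, renormalize: bool = False) -> Database:
    """Read a database directory and return a fully validated :class:`Database`.

    The three core tables are required; ancillary tables are loaded when
    present. Any invariant violation raises :class:`IntegrityError` naming
    the offending row.
    """
    directory = Path(directory)
    for required in ("marker.tsv", "population.tsv", "frequency.tsv"):
        if not (directory / required).exists():
            raise MissingTableError(f"required table {required} not found in {directory}")
    db = Database()

    alt_offsets: dict[str, tuple[int, ...]] = {}
    altpath = directory / "altcoords.tsv"
    if altpath.exists():
        for _, row in _read_table(altpath, ["Name", "Chrom", "Offsets"]).iterrows():
            alt_offsets[row["Name"]] = tuple(
                int(x) for x in row["Offsets"].split(",") if x
            )

    markers = _read_table(directory / "marker.tsv", _MARKER_COLUMNS)
    for _, row in markers.iterrows():
        positions = tuple(int(x) for x in row["Offsets"].split(",") if x)
        rsids = tuple(x for x in row["RSIDs"].split(",") if x)
        db.markers.append(
            MarkerDefinition(
                name=row["Name"],
                chromosome=row["Chrom"],
                positions=positions,
                rsids=rsids,
                source=row["Source"],
                alt_positions=alt_offsets.get(row["Name"]),
            )
        )
        stats = {
            key: (float(row[key]) if row[key] != "" else None)
            for key in ("Ae", "In", "Fst")
        }
        if any(v is not None for v in stats.values()):
            db.stats[row["Name"]] = stats

    for _, row in _read_table(directory / "population.tsv", _POPULATION_COLUMNS).iterrows():
        db.populations.append(
            PopulationSample(id=row["ID"], name=row["Name"], source=row["Source"])
        )

    for i, row in _read_table(directory / "frequency.tsv", _FREQUENCY_COLUMNS).iterrows():
        try:
            frequency = float(row["Frequency"])
        except ValueError as exc:
            raise IntegrityError(
                f"frequency.tsv row {i + 1}: bad frequency {row['Frequency']!r}"
            ) from exc
        count = int(row["Count"]) if row["Count"] != "" else None
        db.frequencies.append(
            FrequencyRecord(
                marker=row["Marker"],
                population=row["Population"],
                haplotype=row["Allele"],
                frequency=frequency,
                count=count,
            )
        )

    idpath = directory / "idmap.tsv"
    if idpath.exists():
        for _, row in _read_table(idpath, ["Xref", "Name"]).iterrows():
            db.idmap.append((row["Xref"], row["Name"]))
    vmpath = directory / "variantmap.tsv"
    if vmpath.exists():
        for _, row in _read_table(vmpath, ["Variant", "Marker"]).iterrows():
            db.variantmap.append((row["Variant"], row["Marker"]))
    else:
        db.variantmap = sorted(
            (rsid, m.name) for m in db.markers for rsid in m.rsids
        )
    seqpath = directory / "sequence.tsv"
    if seqpath.exists():
        for _, row in _read_table(seqpath, ["Marker", "Start", "Sequence"]).iterrows():
            db.sequences[row["Marker"]] = (int(row["Start"]), row["Sequence"])

    db.validate(renormalize=renormalize)
    return db


def write_database(db: Database, directory: str | Path) -> None:
    """Write all tables of ``db`` to ``directory`` (created if needed).

    ``load_database(write_database(db))`` reproduces the database
    field-for-field: text fields byte-identical, frequencies at full float
    precision, statistics at the 4-decimal file resolution.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    def emit(name: str, columns: Sequence[str], rows: Iterable[Sequence[str]]):
        with open(directory / name, "w", encoding="utf-8", newline="\n") as out:
            out.write("\t".join(columns) + "\n")
            for row in rows:
                out.write("\t".join(str(x) for x in row) + "\n")

    emit(
        "marker.tsv",
        _MARKER_COLUMNS,
        (
            [
                m.name,
                m.source,
                m.chromosome,
                ",".join(str(p) for p in m.positions),
                _format_stat(db.stats.get(m.name, {}).get("Ae")),
                _format_stat(db.stats.get(m.name, {}).get("In")),
                _format_stat(db.stats.get(m.name, {}).get("Fst")),
                ",".join(m.rsids),
            ]
            for m in db.markers
        ),
    )
    emit(
        "population.tsv",
        _POPULATION_COLUMNS,
        ([p.id, p.name, p.source] for p in db.populations),
    )
    emit(
        "frequency.tsv",
        _FREQUENCY_COLUMNS,
        (
            [
                r.marker,
                r.population,
                r.haplotype,
                repr(r.frequency),
                "" if r.count is None else r.count,
            ]
            for r in db.frequencies
        ),
    )
    emit("idmap.tsv", ["Xref", "Name"], db.idmap)
    emit("variantmap.tsv", ["Variant", "Marker"], db.variantmap)
    emit(
        "sequence.tsv",
        ["Marker", "Start", "Sequence"],
        ([name, start, seq] for name, (start, seq) in sorted(db.sequences.items())),
    )
    alt = [m for m in db.markers if m.alt_positions is not None]
    if alt:
        emit(
            "altcoords.tsv",
            ["Name", "Chrom", "Offsets"],
            (
                [m.name, m.chromosome, ",".join(str(p) for p in m.alt_positions)]
                for m in alt
            ),
        )


def database_files(directory: str | Path) -> list[Path]:
    """Resolved paths of the table files present in a database directory."""
    directory = Path(directory)
    names = [
        "marker.tsv",
        "population.tsv",
        "frequency.tsv",
        "idmap.tsv",
        "variantmap.tsv",
        "sequence.tsv",
        "altcoords.tsv",
    ]
    return [directory / n for n in names if (directory / n).exists()]


# -- aggregation ---------------------------------------------------------


def merge_sources(sources: Sequence[Database]) -> Database:
    """Aggregate independently valid databases into one sorted database.

    Fully identical records are collapsed (markers that differ only in
    source label are collapsed with their source labels joined by ``;``).
    Markers sharing a name but differing in definition are both retained:
    later arrivals are renamed with a numeric suffix (``name.2``, ...) and
    the colliding name is listed in the result's ``collisions`` attribute.
    The output is sorted by (chromosome, start, name) for markers and by
    (marker, population, haplotype) for frequencies, so the merge is
    deterministic and idempotent.
    """
    merged = Database()
    by_name: dict[str, MarkerDefinition] = {}
    renames_per_source: list[dict[str, str]] = []
    collisions: list[str] = []

    for source_db in sources:
        renames: dict[str, str] = {}
        for marker in source_db.markers:
            existing = by_name.get(marker.name)
            if existing is None:
                by_name[marker.name] = marker
                continue
            if existing.definition_key() == marker.definition_key():
                if marker.source and marker.source not in existing.source.split(";"):
                    joined = ";".join(
                        s for s in [existing.source, marker.source] if s
                    )
                    by_name[marker.name] = replace(existing, source=joined)
                continue
            # Same name, different definition: keep both under distinct names.
            if marker.name not in collisions:
                collisions.append(marker.name)
            suffix = 2
            while f"{marker.name}.{suffix}" in by_name:
                candidate = by_name[f"{marker.name}.{suffix}"]
                if candidate.definition_key() == marker.definition_key():
                    break
                suffix += 1
            new_name = f"{marker.name}.{suffix}"
            renames[marker.name] = new_name
            by_name[new_name] = replace(marker, name=new_name)
        renames_per_source.append(renames)

    merged.markers = sorted(by_name.values(), key=_marker_sort_key)

    seen_pops: dict[str, PopulationSample] = {}
    for source_db in sources:
        for pop in source_db.populations:
            existing = seen_pops.get(pop.id)
            if existing is None:
                seen_pops[pop.id] = pop
            elif existing != pop and pop.id not in collisions:
                collisions.append(pop.id)
    merged.populations = sorted(seen_pops.values(), key=lambda p: p.id)

    freq_seen: dict[tuple[str, str, str], FrequencyRecord] = {}
    for source_db, renames in zip(sources, renames_per_source):
        for record in source_db.frequencies:
            name = renames.get(record.marker, record.marker)
            record = replace(record, marker=name)
            key = (record.marker, record.population, record.haplotype)
            existing = freq_seen.get(key)
            if existing is None:
                freq_seen[key] = record
            elif existing != record and f"frequency:{key}" not in collisions:
                collisions.append(f"frequency:{key}")
        for xref, name in source_db.idmap:
            pair = (xref, renames.get(name, name))
            if pair not in merged.idmap:
                merged.idmap.append(pair)
        for name, (start, seq) in source_db.sequences.items():
            merged.sequences.setdefault(renames.get(name, name), (start, seq))
        for name, stats in source_db.stats.items():
            merged.stats.setdefault(renames.get(name, name), dict(stats))
    merged.frequencies = sorted(
        freq_seen.values(), key=lambda r: (r.marker, r.population, r.haplotype)
    )
    merged.variantmap = sorted(
        {(rsid, m.name) for m in merged.markers for rsid in m.rsids}
    )
    merged.collisions = collisions
    merged.idmap.sort()
    return merged
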