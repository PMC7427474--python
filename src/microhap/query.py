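"""Query surface: selectors, detail views, FASTA export, amplicon design.

All coordinates in this module are 1-based inclusive (genome-browser
convention); region strings follow the ``chr5``, ``chr5:1000000``,
``chr5:1000000-2000000`` syntax.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Union

from .stats import PopulationFrequencyMatrix, effective_number_of_alleles, marker_length
from .tables import Database, MarkerDefinition, chromosome_sort_key

__all__ = [
    "GenomicRegion",
    "AmpliconView",
    "query_markers",
    "amplicon_bounds",
    "build_amplicon",
    "render_marker_detail",
    "markers_to_fasta",
    "population_detail",
    "population_ae",
]

_REGION_RE = re.compile(r"^(?P<chrom>[\w.]+?)(:(?P<start>\d+)(-(?P<end>\d+))?)?$")


@dataclass(frozen=True)
class GenomicRegion:
    """A chromosome interval, 1-based inclusive; ``end`` absent = whole chromosome."""

    chromosome: str
    start: Optional[int] = None
    end: Optional[int] = None

    def __post_init__(self):
        from .tables import normalize_chromosome

        object.__setattr__(self, "chromosome", normalize_chromosome(self.chromosome))
        if self.start is not None and self.start < 1:
            raise ValueError("region start must be >= 1")
        if self.start is not None and self.end is not None and self.start > self.end:
            raise ValueError("region start greater than end")

    @classmethod
    def parse(cls, text: str) -> "GenomicRegion":
        match = _REGION_RE.match(text)
        if match is None:
            raise ValueError(f"cannot parse region string {text!r}")
        start = match.group("start")
        end = match.group("end")
        return cls(
            chromosome=match.group("chrom"),
            start=int(start) if start else None,
            end=int(end) if end else None,
        )

    def contains_span(self, chromosome: str, start: int, end: int) -> bool:
        """Whether the span [start, end] intersects this region."""
        if chromosome != self.chromosome:
            return False
        lo = self.start if self.start is not None else 1
        hi = self.end if self.end is not None else float("inf")
        return start <= hi and end >= lo


Selector = Union[None, str, GenomicRegion]


def query_markers(db: Database, selector: Selector = None) -> list[MarkerDefinition]:
    """Markers matching a selector, in coordinate order.

    ``selector`` may be ``None`` (all markers), a :class:`GenomicRegion`,
    or a string resolved in precedence order: exact marker name, rsID (via
    the variant map), third-party identifier (via the id map), source
    label, then region string. An ambiguous token (e.g. resolving both as
    a name and an rsID) triggers a warning and uses the highest-precedence
    match. An unknown identifier yields an empty list, never an exception.
    """
    ordered = sorted(
        db.markers,
        key=lambda m: (chromosome_sort_key(m.chromosome), m.start, m.name),
    )
    if selector is None:
        return ordered
    if isinstance(selector, GenomicRegion):
        return [m for m in ordered if selector.contains_span(m.chromosome, m.start, m.end)]

    token = str(selector)
    matches: list[tuple[str, set[str]]] = []
    by_name = {m.name for m in ordered if m.name == token}
    if by_name:
        matches.append(("marker name", by_name))
    by_rsid = {m.name for m in db.markers_by_rsid(token)}
    if by_rsid:
        matches.append(("rsID", by_rsid))
    by_xref = {name for xref, name in db.idmap if xref == token}
    if by_xref:
        matches.append(("third-party id", by_xref))
    by_source = {m.name for m in ordered if token in m.source.split(";")}
    if by_source:
        matches.append(("source", by_source))
    if len(matches) > 1:
        warnings.warn(
            f"selector {token!r} is ambiguous ({' and '.join(kind for kind, _ in matches)}); "
            f"using the {matches[0][0]} interpretation",
            stacklevel=2,
        )
    if matches:
        names = matches[0][1]
        return [m for m in ordered if m.name in names]
    try:
        region = GenomicRegion.parse(token)
    except ValueError:
        return []
    if not any(m.chromosome == region.chromosome for m in ordered):
        return []
    return [m for m in ordered if region.contains_span(m.chromosome, m.start, m.end)]


def _bounded_interval(
    first: int, last: int, delta: int, min_length: int, lo: int, hi: int
) -> tuple[int, int]:
    """Extend [first, last] by delta, pad to min_length, clip to [lo, hi].

    Padding to ``min_length`` is split as evenly as possible with the odd
    base going right; clipping at either bound shifts the deficit to the
    other side while room remains, so the final length is
    ``max(span + 2*delta, min_length)`` whenever the bounding interval is
    long enough.
    """
    start = first - delta
    end = last + delta
    shortfall = min_length - (end - start + 1)
    if shortfall > 0:
        start -= shortfall // 2
        end += shortfall - shortfall // 2
    if start < lo:
        end = min(hi, end + (lo - start))
        start = lo
    if end > hi:
        start = max(lo, start - (end - hi))
        end = hi
    return start, end


def amplicon_bounds(
    marker: MarkerDefinition, delta: int, min_length: int, chrom_length: int
) -> tuple[int, int]:
    """Candidate amplicon interval for a marker, 1-based inclusive.

    Starts from the marker span extended by ``delta`` on each side; if
    still shorter than ``min_length``, both sides are extended as evenly as
    possible (odd surplus base to the right). The interval is clipped to
    ``[1, chrom_length]``, shifting any clipped deficit to the other side,
    so the final length is ``max(span + 2*delta, min_length)`` unless the
    chromosome itself is too short.
    """
    if delta < 0 or min_length < 0:
        raise ValueError("delta and min_length must be non-negative")
    if chrom_length < marker.end:
        raise ValueError(
            f"chromosome length {chrom_length} shorter than marker end {marker.end}"
        )
    return _bounded_interval(
        marker.start, marker.end, delta, min_length, 1, chrom_length
    )


@dataclass
class AmpliconView:
    """A marker's target sequence with component-variant offsets.

    ``offsets`` are 0-based positions of the component variants within
    ``sequence``; ``start`` is the 1-based genomic coordinate of
    ``sequence[0]``.
    """

    marker: MarkerDefinition
    sequence: str
    start: int
    offsets: tuple[int, ...]
    haplotypes: tuple[str, ...] = ()

    @property
    def end(self) -> int:
        return self.start + len(self.sequence) - 1

    @property
    def region(self) -> str:
        return f"{self.marker.chromosome}:{self.start}-{self.end}"


def build_amplicon(
    db: Database, marker: MarkerDefinition, delta: int = 25, min_length: int = 0
) -> AmpliconView:
    """Amplicon view for a marker from the database's stored flanking sequence.

    The stored sequence window acts as the available reference; the
    amplicon interval is computed within it, so requests larger than the
    stored flanks are clipped to the window.
    """
    if marker.name not in db.sequences:
        raise KeyError(f"no sequence stored for marker {marker.name}")
    seq_start, sequence = db.sequences[marker.name]
    seq_end = seq_start + len(sequence) - 1
    if marker.start < seq_start or marker.end > seq_end:
        raise ValueError(
            f"stored sequence window {seq_start}-{seq_end} does not cover "
            f"marker {marker.name} span {marker.start}-{marker.end}"
        )
    start, end = _bounded_interval(
        marker.start, marker.end, delta, min_length, seq_start, seq_end
    )
    haplotypes = tuple(
        sorted({r.haplotype for r in db.frequencies_for(marker=marker.name)})
    )
    return AmpliconView(
        marker=marker,
        sequence=sequence[start - seq_start : end - seq_start + 1],
        start=start,
        offsets=tuple(p - start for p in marker.positions),
        haplotypes=haplotypes,
    )


def _wrap(sequence: str, width: int = 80) -> list[str]:
    return [sequence[i : i + width] for i in range(0, len(sequence), width)]


def render_marker_detail(
    db: Database,
    marker: MarkerDefinition,
    delta: int = 25,
    min_length: int = 0,
) -> str:
    """Fixed-layout text detail view of one marker.

    Shows name, source, per-variant rsIDs and coordinates, the core span
    and its length, the candidate amplicon sequence with component-variant
    positions marked, and the observed haplotypes. Markers without a
    stored sequence get the same view minus the sequence section, with a
    warning.
    """
    lines: list[str] = []
    header = f"[ {marker.name} ]"
    lines.append(header.center(78, "-"))
    lines.append(f"Source: {marker.source or '-'}")
    lines.append(f"Chromosome: {marker.chromosome}")
    lines.append(
        f"Core span: {marker.chromosome}:{marker.start}-{marker.end} "
        f"({marker_length(marker)} bp)"
    )
    lines.append(f"Variants ({marker.num_variants}):")
    for rsid, pos in zip(marker.rsids, marker.positions):
        lines.append(f"  {rsid:<15} {marker.chromosome}:{pos}")
    lines.append("")
    if marker.name in db.sequences:
        view = build_amplicon(db, marker, delta=delta, min_length=min_length)
        lines.append(f"Amplicon: {view.region} ({len(view.sequence)} bp)")
        offset_set = set(view.offsets)
        for block, chunk in enumerate(_wrap(view.sequence)):
            lines.append(chunk)
            marks = "".join(
                "*" if block * 80 + i in offset_set else " "
                for i in range(len(chunk))
            )
            lines.append(marks.rstrip())
        haplotypes = view.haplotypes
    else:
        warnings.warn(f"no sequence stored for marker {marker.name}", stacklevel=2)
        haplotypes = tuple(
            sorted({r.haplotype for r in db.frequencies_for(marker=marker.name)})
        )
    lines.append("")
    if haplotypes:
        lines.append(f"Observed haplotypes ({len(haplotypes)}):")
        lines.extend(f"  {hap}" for hap in haplotypes)
    else:
        lines.append("Observed haplotypes: none observed")
    lines.append("-" * 78)
    return "\n".join(lines) + "\n"


def markers_to_fasta(
    db: Database,
    markers: Sequence[MarkerDefinition],
    delta: int = 25,
    min_length: int = 0,
) -> str:
    """FASTA export of marker amplicons, one record per marker.

    Headers carry the marker name, the amplicon region, and the 0-based
    variant offsets within the record sequence; sequences are wrapped at
    80 columns.
    """
    chunks: list[str] = []
    for marker in markers:
        view = build_amplicon(db, marker, delta=delta, min_length=min_length)
        offsets = ",".join(str(o) for o in view.offsets)
        chunks.append(f">{marker.name} region={view.region} offsets={offsets}")
        chunks.extend(_wrap(view.sequence))
    return "\n".join(chunks) + ("\n" if chunks else "")


def population_detail(db: Database, population_id: str) -> tuple[int, int]:
    """(markers with frequency data, distinct haplotypes observed) for a population."""
    db.population(population_id)  # raises KeyError for unknown ids
    records = db.frequencies_for(population=population_id)
    markers = {r.marker for r in records}
    haplotypes = {(r.marker, r.haplotype) for r in records}
    return len(markers), len(haplotypes)


def population_ae(db: Database, marker_name: str, population_id: str) -> float:
    """Effective number of alleles of one marker within one population."""
    records = db.frequencies_for(marker=marker_name, population=population_id)
    if not records:
        raise KeyError(
            f"no frequency data for marker {marker_name!r} in population "
            f"{population_id!r}"
        )
    return effective_number_of_alleles([r.frequency for r in records])
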