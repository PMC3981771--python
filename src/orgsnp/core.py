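"""Shared record types for the organellar SNP pipeline.

Coordinates are 1-based inclusive everywhere (SAM/VCF/GFF convention), which
is also how positions are printed in the published SNP tables this package
reproduces.
"""
from __future__ import annotations

from dataclasses import dataclass, field

BASES = "ACGT"
IUPAC = set("ACGTRYSWKMBDHVN")

HOMOPLASMIC = "homoplasmic"
HETEROPLASMIC = "heteroplasmic"


@dataclass
class AlignmentRecord:
    """One read mate's placement on one reference (ungapped)."""

    read_id: str
    mate: int  # 1 or 2; 0 for unpaired
    reference_name: str | None
    position: int  # 1-based leftmost; 0 if unmapped
    strand: str  # '+' or '-'
    mismatches: int
    mapping_quality: int  # 0-60; 0 whenever the best placement ties
    mapped: bool
    seq: str = ""  # bases in reference-strand orientation
    qual: str = ""  # Phred+33, same orientation as seq

    @property
    def end(self) -> int:
        """1-based inclusive rightmost aligned position."""
        return self.position + len(self.seq) - 1

    @property
    def identifier(self) -> str:
        """Mate-resolved read identity, the unit of cross-map filtering."""
        return f"{self.read_id}/{self.mate}" if self.mate else self.read_id


@dataclass
class PileupColumn:
    position: int
    ref_base: str
    base_counts: dict[str, int]
    mean_mapq: float
    mean_baseq: float

    @property
    def depth(self) -> int:
        return sum(self.base_counts.values())


@dataclass
class CallThresholds:
    """SNP retention thresholds; the defaults are the published ones."""

    min_depth: int = 10
    min_mapq: int = 20
    min_snp_quality: float = 15.0


@dataclass
class SnpRecord:
    """One cultivar x position call, mirroring one row of the SNP tables."""

    cultivar: str
    genome: str  # 'mito' or 'plastid'
    position: int
    ref_base: str
    alt_base: str  # primary alternate
    quality: float
    read_depth: int
    depth_reference: int
    depth_alternate: int
    zygosity: str = ""  # homoplasmic | heteroplasmic
    location_label: str = ""
    secondary_alt: str = ""  # extra alternate base at multi-allelic columns

    @property
    def alt_display(self) -> str:
        if self.secondary_alt:
            return f"{self.alt_base},{self.secondary_alt}"
        return self.alt_base


@dataclass
class PublishedSnpRow:
    """A transcribed row of the published mitochondrial/plastid SNP tables.

    ``unique_flag`` encodes the bold typography (SNP unique to one cultivar);
    ``polymorphic_flag`` the asterisk (both alleles seen in the reads).
    """

    cultivar: str
    position: int
    ref_base: str
    alt_bases: str  # verbatim, possibly multi-allelic e.g. "T,G"
    quality: float
    read_depth: int
    depth_reference: int
    depth_alternate: int
    location_label: str
    unique_flag: bool
    polymorphic_flag: bool

    @property
    def primary_alt(self) -> str:
        return self.alt_bases.split(",")[0]

    def to_snp_record(self, genome: str) -> SnpRecord:
        alts = self.alt_bases.split(",")
        rec = SnpRecord(
            cultivar=self.cultivar,
            genome=genome,
            position=self.position,
            ref_base=self.ref_base,
            alt_base=alts[0],
            quality=self.quality,
            read_depth=self.read_depth,
            depth_reference=self.depth_reference,
            depth_alternate=self.depth_alternate,
            location_label=self.location_label,
            secondary_alt=alts[1] if len(alts) > 1 else "",
        )
        rec.zygosity = (
            HETEROPLASMIC
            if rec.depth_reference > 0 and rec.depth_alternate > 0
            else HOMOPLASMIC
        )
        return rec


@dataclass
class Feature:
    """One annotated interval: a gene, exon or intron."""

    feature_id: str
    type: str  # gene | exon | intron
    start: int  # 1-based inclusive
    end: int
    strand: str  # '+' or '-'
    parent: str = ""  # gene id for exons/introns
    name: str = ""

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"feature {self.feature_id}: start > end")
        if not self.name:
            self.name = self.feature_id

    def __contains__(self, position: int) -> bool:
        return self.start <= position <= self.end

    def __len__(self) -> int:
        return self.end - self.start + 1


@dataclass
class FeatureTrack:
    """Flat gene/exon/intron annotation for one genome."""

    features: list[Feature] = field(default_factory=list)

    def genes(self) -> list[Feature]:
        return [f for f in self.features if f.type == "gene"]

    def of_gene(self, gene_id: str, type: str) -> list[Feature]:
        return [
            f for f in self.features if f.parent == gene_id and f.type == type
        ]


@dataclass
class FilterReport:
    """Per-genome mapping statistics before/after cross-map filtering,
    in the column layout of the published alignment-summary tables."""

    genome: str
    total_reads: int
    reads_mapped: int
    reads_mapped_after_filtering: int
    mean_coverage: float
    mean_coverage_after_filtering: float

    @property
    def pct_mapped(self) -> float:
        return 100.0 * self.reads_mapped / self.total_reads if self.total_reads else 0.0

    @property
    def pct_mapped_after_filtering(self) -> float:
        if not self.total_reads:
            return 0.0
        return 100.0 * self.reads_mapped_after_filtering / self.total_reads

    COLUMNS = (
        "genome",
        "total_reads",
        "reads_mapped",
        "reads_mapped_after_filtering",
        "coverage",
        "filtered_coverage",
        "pct_reads_mapped",
        "pct_reads_mapped_after_filtering",
    )

    def as_row(self) -> dict:
        return {
            "genome": self.genome,
            "total_reads": self.total_reads,
            "reads_mapped": self.reads_mapped,
            "reads_mapped_after_filtering": self.reads_mapped_after_filtering,
            "coverage": round(self.mean_coverage),
            "filtered_coverage": round(self.mean_coverage_after_filtering),
            "pct_reads_mapped": round(self.pct_mapped, 2),
            "pct_reads_mapped_after_filtering": round(
                self.pct_mapped_after_filtering, 2
            ),
        }


def revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]
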