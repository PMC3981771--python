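"""Cross-genome read filtering.

Plastid-derived insertions make up a tenth of the date palm mitochondrial
genome, so reads from the (much higher copy) plastid map cleanly onto those
mitochondrial regions and masquerade as intra-individual variation.  The
remedy implemented here is deliberately blunt: any read that maps to BOTH
organellar references is removed from both alignments before SNP calling.

Filtering operates on read identity by default (a crossmapping mate removes
only itself); ``by="pair"`` removes the whole template.  A read counts as
"mapped" regardless of MAPQ — mapping-quality thresholds belong to SNP
retention, not to this filter.
"""
from __future__ import annotations

from .core import AlignmentRecord, FilterReport


def _ident(rec: AlignmentRecord, by: str) -> str:
    if by == "pair":
        return rec.read_id
    if by == "read":
        return rec.identifier
    raise ValueError(f"unknown filter mode {by!r}")


def crossmapped_ids(
    mito_records: list[AlignmentRecord],
    plastid_records: list[AlignmentRecord],
    by: str = "read",
) -> set[str]:
    """Identifiers with at least one mapped record in both alignments."""
    mito = {_ident(r, by) for r in mito_records if r.mapped}
    plastid = {_ident(r, by) for r in plastid_records if r.mapped}
    return mito & plastid


def apply_filter(
    records: list[AlignmentRecord],
    crossmapped: set[str],
    by: str = "read",
) -> list[AlignmentRecord]:
    """Drop every record whose identifier is in ``crossmapped``.

    Record order is preserved; the operation is idempotent.
    """
    return [r for r in records if _ident(r, by) not in crossmapped]


def filter_report(
    records_before: list[AlignmentRecord],
    records_after: list[AlignmentRecord],
    genome_length: int,
    total_reads: int,
    genome: str = "",
) -> FilterReport:
    """Mapping statistics in the layout of the published alignment tables.

    Mean coverage is the sum of aligned read lengths over the genome length.
    """
    if genome_length <= 0:
        raise ValueError("genome_length must be positive")

    def stats(records):
        mapped = [r for r in records if r.mapped]
        cov = sum(len(r.seq) for r in mapped) / genome_length
        return len(mapped), cov

    n_before, cov_before = stats(records_before)
    n_after, cov_after = stats(records_after)
    if n_after > n_before:
        raise ValueError("more mapped reads after filtering than before")
    return FilterReport(
        genome=genome,
        total_reads=total_reads,
        reads_mapped=n_before,
        reads_mapped_after_filtering=n_after,
        mean_coverage=cov_before,
        mean_coverage_after_filtering=cov_after,
    )
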