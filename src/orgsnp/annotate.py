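"""Genomic-context annotation of SNPs.

Each SNP is labelled with the partition used by the published tables:
``S-<gene>`` / ``NS-<gene>`` for synonymous / nonsynonymous coding changes,
``I-<gene>`` for introns, and ``IGS`` (optionally ``IGS-<left>:<right>`` with
the flanking gene names) for intergenic spacers.  Overlaps resolve as
coding > intron > intergenic.  Effects are computed strictly on the genomic
codon (no RNA editing) with the bacterial/plastid genetic code (NCBI
translation table 11) by default for both organelles.
"""
from __future__ import annotations

from collections import Counter

from Bio.Data import CodonTable
from Bio.Seq import Seq

from .core import Feature, FeatureTrack, SnpRecord, revcomp

CONTEXT_CATEGORIES = ("gene-S", "gene-NS", "intron", "IGS")


def _coding_exons(track: FeatureTrack, gene: Feature) -> list[Feature]:
    exons = sorted(track.of_gene(gene.feature_id, "exon"), key=lambda f: f.start)
    if not exons:
        # a gene without explicit exons is a single-exon gene
        exons = [Feature(gene.feature_id + ".e1", "exon", gene.start,
                         gene.end, gene.strand, parent=gene.feature_id)]
    return exons


def _introns(track: FeatureTrack, gene: Feature) -> list[Feature]:
    explicit = track.of_gene(gene.feature_id, "intron")
    if explicit:
        return explicit
    exons = _coding_exons(track, gene)
    introns = []
    for a, b in zip(exons, exons[1:]):
        if b.start > a.end + 1:
            introns.append(
                Feature(f"{gene.feature_id}.i", "intron", a.end + 1,
                        b.start - 1, gene.strand, parent=gene.feature_id,
                        name=gene.name)
            )
    return introns


def cds_index(position: int, gene: Feature, exons: list[Feature]) -> int:
    """0-based index of ``position`` in the spliced, strand-oriented CDS."""
    exons = sorted(exons, key=lambda f: f.start)
    offsets, total = [], 0
    for ex in exons:
        offsets.append(total)
        total += len(ex)
    for ex, off in zip(exons, offsets):
        if position in ex:
            fwd = off + (position - ex.start)
            return fwd if gene.strand == "+" else total - 1 - fwd
    raise ValueError(f"position {position} not exonic in {gene.feature_id}")


def spliced_cds(gene: Feature, exons: list[Feature], genome_seq: str) -> str:
    parts = [genome_seq[ex.start - 1:ex.end]
             for ex in sorted(exons, key=lambda f: f.start)]
    cds = "".join(parts)
    return cds if gene.strand == "+" else revcomp(cds)


def snp_effect(
    position: int,
    ref_base: str,
    alt_base: str,
    gene: Feature,
    genome_seq: str,
    track: FeatureTrack | None = None,
    table: int = 11,
) -> str:
    """Classify a coding substitution as 'synonymous' or 'nonsynonymous'."""
    if genome_seq[position - 1] != ref_base:
        raise ValueError(
            f"reference base mismatch at {position}: genome has "
            f"{genome_seq[position - 1]}, SNP says {ref_base}"
        )
    exons = _coding_exons(track, gene) if track else [gene]
    idx = cds_index(position, gene, exons)
    cds = spliced_cds(gene, exons, genome_seq)
    codon_start = (idx // 3) * 3
    codon = cds[codon_start:codon_start + 3]
    within = idx % 3
    sub = alt_base if gene.strand == "+" else revcomp(alt_base)
    alt_codon = codon[:within] + sub + codon[within + 1:]
    code = CodonTable.unambiguous_dna_by_id[table]
    aa_ref = str(Seq(codon).translate(table=table))
    aa_alt = str(Seq(alt_codon).translate(table=table))
    # start/stop handling: translate() maps stops to '*', which compares fine
    return "synonymous" if aa_ref == aa_alt else "nonsynonymous"


def classify_location(
    position: int,
    track: FeatureTrack,
    genome_seq: str | None = None,
    ref_base: str | None = None,
    alt_base: str | None = None,
    table: int = 11,
) -> str:
    """Context label for one genome position.

    For coding positions the S/NS decision needs ``genome_seq`` and both
    alleles; without them the bare label ``CDS-<gene>`` is returned.
    """
    if genome_seq is not None and not (1 <= position <= len(genome_seq)):
        raise ValueError(f"position {position} outside genome")
    genes = sorted(track.genes(), key=lambda g: g.start)
    for gene in genes:
        if position not in gene:
            continue
        for ex in _coding_exons(track, gene):
            if position in ex:
                if genome_seq is None or ref_base is None or alt_base is None:
                    return f"CDS-{gene.name}"
                eff = snp_effect(position, ref_base, alt_base, gene,
                                 genome_seq, track, table)
                prefix = "S" if eff == "synonymous" else "NS"
                return f"{prefix}-{gene.name}"
        for intr in _introns(track, gene):
            if position in intr:
                return f"I-{gene.name}"
        return f"I-{gene.name}"  # inside gene but in no exon: intronic
    left = max((g for g in genes if g.end < position),
               key=lambda g: g.end, default=None)
    right = min((g for g in genes if g.start > position),
                key=lambda g: g.start, default=None)
    if left is not None and right is not None:
        return f"IGS-{left.name}:{right.name}"
    return "IGS"


def annotate_snps(
    snps: list[SnpRecord],
    track: FeatureTrack,
    genome_seq: str,
    table: int = 11,
) -> list[SnpRecord]:
    """Fill ``location_label`` for every record, in place, and return them."""
    for s in snps:
        s.location_label = classify_location(
            s.position, track, genome_seq, s.ref_base, s.alt_base, table
        )
    return snps


def parse_label(label: str) -> str:
    """Map a location label to its context category."""
    prefix = label.split("-")[0]
    if prefix == "IGS":
        return "IGS"
    if prefix == "I":
        return "intron"
    if prefix == "S":
        return "gene-S"
    if prefix == "NS":
        return "gene-NS"
    raise ValueError(f"unknown location label {label!r}")


def summarize_contexts(snps) -> dict[str, int]:
    """Count context categories over DISTINCT genome positions.

    Distinct positions (not cultivar x position records) are the unit, which
    is how the published per-context totals add up to the number of SNP
    sites.  Accepts SnpRecords or transcribed table rows (anything with
    ``position`` and ``location_label``).
    """
    seen: dict[int, str] = {}
    for s in snps:
        seen.setdefault(s.position, parse_label(s.location_label))
    counts = Counter(seen.values())
    return {cat: counts.get(cat, 0) for cat in CONTEXT_CATEGORIES}
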