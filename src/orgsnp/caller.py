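"""Pileup construction, variant-quality scoring and threshold SNP calling.

Retention thresholds default to read depth >= 10, mapping quality >= 20 and
SNP quality >= 15.  The mapping-quality gate is applied per read when the
pileup is built; depth and SNP-quality gates are applied per column.

Variant quality is a defined binomial-tail score: with per-base error
probability e = 10^(-mean_baseq/10) and k reads supporting the top
non-reference base out of depth n, the score is
``min(99, -10*log10 P(X >= k))`` for X ~ Binomial(n, e).  It is a
reproducible stand-in for an upstream caller's QUAL and is not meant to
match any published Quality column numerically.

Zygosity follows the rule the printed tables obey: a call is heteroplasmic
exactly when reads supporting BOTH the reference and the alternate allele
are present, homoplasmic when the reference-supporting depth is zero.
"""
from __future__ import annotations

import numpy as np
from scipy import stats

from .core import (
    BASES,
    HETEROPLASMIC,
    HOMOPLASMIC,
    AlignmentRecord,
    CallThresholds,
    PileupColumn,
    SnpRecord,
)


def pileup(
    records: list[AlignmentRecord],
    reference: str,
    min_mapq: int = 20,
) -> list[PileupColumn]:
    """Stack ungapped alignments into per-position base counts.

    Reads with MAPQ below ``min_mapq`` are excluded entirely.  Only columns
    with nonzero depth are returned, in position order.
    """
    L = len(reference)
    counts = np.zeros((L, 4), dtype=np.int64)
    mapq_sum = np.zeros(L)
    baseq_sum = np.zeros(L)
    from .mapper import encode

    for rec in records:
        if not rec.mapped or rec.mapping_quality < min_mapq:
            continue
        if rec.position < 1 or rec.end > L:
            raise ValueError(
                f"record {rec.identifier} extends past the reference end"
            )
        start = rec.position - 1
        codes = encode(rec.seq)
        valid = codes < 4
        pos = start + np.nonzero(valid)[0]
        np.add.at(counts, (pos, codes[valid].astype(np.int64)), 1)
        mapq_sum[pos] += rec.mapping_quality
        if rec.qual:
            quals = np.frombuffer(rec.qual.encode(), dtype=np.uint8) - 33
            baseq_sum[pos] += quals[valid]
        else:
            baseq_sum[pos] += 30
    columns = []
    for pos0 in np.nonzero(counts.sum(axis=1))[0]:
        depth = int(counts[pos0].sum())
        columns.append(
            PileupColumn(
                position=int(pos0) + 1,
                ref_base=reference[pos0],
                base_counts={b: int(counts[pos0, i]) for i, b in enumerate(BASES)},
                mean_mapq=mapq_sum[pos0] / depth,
                mean_baseq=baseq_sum[pos0] / depth,
            )
        )
    return columns


def variant_quality(column: PileupColumn) -> float:
    """Phred-scaled binomial-tail score for the top non-reference base."""
    depth = column.depth
    if depth < 1:
        raise ValueError("empty column")
    non_ref = {b: c for b, c in column.base_counts.items() if b != column.ref_base}
    k = max(non_ref.values(), default=0)
    if k == 0:
        return 0.0
    e = 10 ** (-column.mean_baseq / 10)
    # P(X >= k) on the log scale to survive extreme tails
    log_sf = stats.binom.logsf(k - 1, depth, e)
    score = -10 * log_sf / np.log(10)
    return float(min(99.0, score))


def call_snps(
    columns: list[PileupColumn],
    thresholds: CallThresholds = CallThresholds(),
    cultivar: str = "sample",
    genome: str = "mito",
) -> list[SnpRecord]:
    """Emit one SNP record per column passing the retention thresholds.

    The alternate allele is the most frequent non-reference base (ties broken
    alphabetically); at multi-allelic columns the runner-up base is kept in
    ``secondary_alt`` when supported by at least two reads, and the record
    still counts as a single SNP.  Bases that are neither reference nor
    primary alternate contribute to ``read_depth`` but to neither depth
    field, matching the printed tables' arithmetic.
    """
    calls = []
    for col in columns:
        if col.depth < thresholds.min_depth:
            continue
        non_ref = sorted(
            ((b, c) for b, c in col.base_counts.items()
             if b != col.ref_base and c > 0),
            key=lambda bc: (-bc[1], bc[0]),
        )
        if not non_ref:
            continue
        qual = variant_quality(col)
        if qual < thresholds.min_snp_quality:
            continue
        alt, alt_count = non_ref[0]
        secondary = ""
        if len(non_ref) > 1 and non_ref[1][1] >= 2:
            secondary = non_ref[1][0]
        rec = SnpRecord(
            cultivar=cultivar,
            genome=genome,
            position=col.position,
            ref_base=col.ref_base,
            alt_base=alt,
            quality=round(qual, 1),
            read_depth=col.depth,
            depth_reference=col.base_counts[col.ref_base],
            depth_alternate=alt_count,
            secondary_alt=secondary,
        )
        rec.zygosity = classify_zygosity(rec)
        calls.append(rec)
    return calls


def classify_zygosity(snp: SnpRecord) -> str:
    """Heteroplasmic iff both reference- and alternate-supporting reads exist."""
    if snp.depth_alternate == 0:
        raise ValueError("not a SNP: no alternate-supporting reads")
    if snp.depth_reference > 0:
        return HETEROPLASMIC
    return HOMOPLASMIC
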