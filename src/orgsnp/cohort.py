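"""Cohort-level SNP statistics across cultivars.

Sharing is keyed on (position, primary alternate allele): a multi-allelic
record matches other cultivars through its primary alternate, which is how
the published nine-cultivar totals add up.  The reference accession
contributes no SNP records (it *is* the reference) and enters the analysis
only as the reference taxon of the phylogenetic matrices.
"""
from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field

import pandas as pd

from .core import HETEROPLASMIC, PublishedSnpRow, SnpRecord


@dataclass
class CohortTable:
    records: list[SnpRecord]
    cultivars: list[str]
    genome: str = "mito"

    def __post_init__(self):
        seen = set()
        for r in self.records:
            key = (r.cultivar, r.genome, r.position)
            if key in seen:
                raise ValueError(f"duplicate record {key}")
            seen.add(key)
            if r.cultivar not in self.cultivars:
                raise ValueError(f"record cultivar {r.cultivar!r} not in cohort")

    @classmethod
    def from_records(cls, records: list[SnpRecord], genome: str | None = None,
                     cultivars: list[str] | None = None) -> "CohortTable":
        if genome is None:
            genome = records[0].genome if records else "mito"
        if cultivars is None:
            cultivars = sorted({r.cultivar for r in records})
        return cls(records=list(records), cultivars=list(cultivars), genome=genome)

    @classmethod
    def from_published_rows(cls, rows: list[PublishedSnpRow], genome: str) -> "CohortTable":
        return cls.from_records([r.to_snp_record(genome) for r in rows], genome)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cultivar": [r.cultivar for r in self.records],
                "genome": [r.genome for r in self.records],
                "position": [r.position for r in self.records],
                "ref": [r.ref_base for r in self.records],
                "alt": [r.alt_display for r in self.records],
                "quality": [r.quality for r in self.records],
                "read_depth": [r.read_depth for r in self.records],
                "depth_reference": [r.depth_reference for r in self.records],
                "depth_alternate": [r.depth_alternate for r in self.records],
                "zygosity": [r.zygosity for r in self.records],
                "location": [r.location_label for r in self.records],
            }
        )


def per_cultivar_counts(table: CohortTable) -> dict[str, int]:
    """Number of SNP records per cultivar."""
    counts = Counter(r.cultivar for r in table.records)
    return {c: counts[c] for c in table.cultivars if counts[c]}


def heteroplasmic_count(table: CohortTable) -> int:
    return sum(1 for r in table.records if r.zygosity == HETEROPLASMIC)


def _share_groups(table: CohortTable) -> dict[tuple[int, str], set[str]]:
    groups: dict[tuple[int, str], set[str]] = defaultdict(set)
    for r in table.records:
        groups[(r.position, r.alt_base)].add(r.cultivar)
    return groups


def sharing_spectrum(table: CohortTable) -> dict[int, int]:
    """k -> number of distinct (position, alt) SNPs found in exactly k cultivars."""
    spectrum: Counter = Counter()
    for cultivars in _share_groups(table).values():
        spectrum[len(cultivars)] += 1
    return dict(sorted(spectrum.items()))


def unique_snps(table: CohortTable) -> dict[str, list[int]]:
    """Positions carried by exactly one cultivar, keyed by that cultivar.

    Uniqueness is positional: a position is unique to cultivar c when c is
    the only cultivar with any SNP there.
    """
    by_position: dict[int, set[str]] = defaultdict(set)
    for r in table.records:
        by_position[r.position].add(r.cultivar)
    out: dict[str, list[int]] = defaultdict(list)
    for pos, cultivars in sorted(by_position.items()):
        if len(cultivars) == 1:
            out[next(iter(cultivars))].append(pos)
    return dict(out)


@dataclass
class SiteDelta:
    """Change at one (cultivar, position) between two call sets."""

    cultivar: str
    position: int
    category: str  # filtered-out | gained | zygosity-change | allele-change
    before: SnpRecord | None = None
    after: SnpRecord | None = None


def compare_filtered_unfiltered(
    calls_before: list[SnpRecord], calls_after: list[SnpRecord]
) -> list[SiteDelta]:
    """Per-site differences between unfiltered and filtered call sets.

    Unchanged sites are omitted; identical inputs give an empty delta.
    """
    before = {(r.cultivar, r.position): r for r in calls_before}
    after = {(r.cultivar, r.position): r for r in calls_after}
    deltas = []
    for key in sorted(set(before) | set(after)):
        b, a = before.get(key), after.get(key)
        if b is not None and a is None:
            deltas.append(SiteDelta(key[0], key[1], "filtered-out", b, None))
        elif b is None and a is not None:
            deltas.append(SiteDelta(key[0], key[1], "gained", None, a))
        elif b.alt_base != a.alt_base:
            deltas.append(SiteDelta(key[0], key[1], "allele-change", b, a))
        elif b.zygosity != a.zygosity:
            deltas.append(SiteDelta(key[0], key[1], "zygosity-change", b, a))
    return deltas


def summary(table: CohortTable) -> dict:
    """JSON-ready cohort summary."""
    uniq = unique_snps(table)
    return {
        "genome": table.genome,
        "n_records": len(table.records),
        "n_sites": len({r.position for r in table.records}),
        "n_heteroplasmic": heteroplasmic_count(table),
        "per_cultivar": per_cultivar_counts(table),
        "unique_positions": {c: p for c, p in uniq.items()},
        "n_unique": sum(len(p) for p in uniq.values()),
        "sharing_spectrum": sharing_spectrum(table),
    }
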