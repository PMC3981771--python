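"""Synthetic organellar genomes, cultivar variant profiles and paired-end
reads with full truth tracking.

The generator emulates the situation the pipeline is built for: a
mitochondrial genome in which a sizeable fraction of the sequence is
plastid-derived insertion (default 10.3%), plastid read depth several-fold
above mitochondrial depth (default 4:1, with both far above a nuclear decoy),
and cultivar SNPs that are either homoplasmic (allele fraction 1) or
heteroplasmic (fraction < 1, realised per DNA fragment).  Genomes are
miniature (default plastid 20 kb / mito 50 kb / nuclear 100 kb) and linear;
reads never wrap around an origin.

Fragment starts are uniform; sequencing errors are i.i.d. substitutions at a
configurable rate and the base-quality string is constant per run with
Phred = round(-10*log10(error_rate)), capped at 40.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import BASES, revcomp


@dataclass
class TransferSegment:
    """One plastid-to-mitochondrion DNA transfer (1-based inclusive)."""

    mito_start: int
    mito_end: int
    plastid_start: int
    plastid_end: int
    divergence: float

    def __post_init__(self):
        if self.mito_end - self.mito_start != self.plastid_end - self.plastid_start:
            raise ValueError("transfer segment lengths differ between genomes")
        if not 0 <= self.divergence <= 1:
            raise ValueError("divergence must be in [0, 1]")

    def __len__(self) -> int:
        return self.mito_end - self.mito_start + 1

    def contains_mito(self, position: int) -> bool:
        return self.mito_start <= position <= self.mito_end


@dataclass
class ReferencePair:
    plastid_seq: str
    mito_seq: str
    transfers: list[TransferSegment]
    nuclear_seq: str = ""

    def in_transfer(self, position: int) -> bool:
        """True if a 1-based mitochondrial position lies in a transfer copy."""
        return any(t.contains_mito(position) for t in self.transfers)

    def genome(self, which: str) -> str:
        return {"plastid": self.plastid_seq, "mito": self.mito_seq,
                "nuclear": self.nuclear_seq}[which]


@dataclass
class Variant:
    genome: str  # 'mito' or 'plastid'
    position: int
    ref_base: str
    alt_base: str
    allele_fraction: float  # 1 = homoplasmic, < 1 = heteroplasmic


@dataclass
class CultivarProfile:
    name: str
    variants: list[Variant] = field(default_factory=list)

    def for_genome(self, genome: str) -> list[Variant]:
        return [v for v in self.variants if v.genome == genome]


@dataclass
class ReadTruth:
    read_id: str
    genome: str  # mito | plastid | nuclear
    start: int  # 1-based fragment start
    insert_size: int
    read_len: int
    variants_carried: list[tuple[str, int, str]] = field(default_factory=list)


def _random_seq(rng, length: int) -> str:
    return "".join(np.array(list(BASES))[rng.integers(0, 4, size=length)])


def _diverge(rng, seq: str, divergence: float) -> str:
    if divergence == 0:
        return seq
    arr = np.array(list(seq))
    hit = rng.random(len(arr)) < divergence
    for i in np.nonzero(hit)[0]:
        others = [b for b in BASES if b != arr[i]]
        arr[i] = others[rng.integers(0, 3)]
    return "".join(arr)


def _place_nonoverlapping(rng, genome_len: int, lengths: list[int],
                          max_tries: int = 1000) -> list[int]:
    """Sample non-overlapping 1-based start positions for the given lengths."""
    occupied: list[tuple[int, int]] = []
    starts: list[int] = []
    for ln in lengths:
        for _ in range(max_tries):
            s = int(rng.integers(1, genome_len - ln + 2))
            if all(s + ln - 1 < a or s > b for a, b in occupied):
                occupied.append((s, s + ln - 1))
                starts.append(s)
                break
        else:
            raise RuntimeError("could not place non-overlapping segments")
    return starts


def simulate_references(
    plastid_len: int = 20_000,
    mito_len: int = 50_000,
    nuclear_len: int = 100_000,
    transfer_fraction: float = 0.103,
    n_segments: int = 5,
    divergence: float = 0.02,
    seed: int = 0,
) -> ReferencePair:
    """Generate a plastid/mito/nuclear reference trio with plastid-derived
    insertions occupying ``transfer_fraction`` of the mitochondrial genome."""
    if not 0 <= transfer_fraction < 1:
        raise ValueError("transfer_fraction must be in [0, 1)")
    if min(plastid_len, mito_len) < 1000:
        raise ValueError("genome lengths must be >= 1000")
    total = round(transfer_fraction * mito_len)
    if total > plastid_len:
        raise ValueError(
            "transfer_fraction * mito_len exceeds plastid length: "
            "cannot source the segments"
        )
    rng = np.random.default_rng(seed)
    plastid = _random_seq(rng, plastid_len)
    mito = list(_random_seq(rng, mito_len))
    nuclear = _random_seq(rng, nuclear_len) if nuclear_len else ""
    transfers: list[TransferSegment] = []
    if n_segments > 0 and total > 0:
        base = total // n_segments
        lengths = [base] * n_segments
        lengths[-1] += total - base * n_segments
        p_starts = _place_nonoverlapping(rng, plastid_len, lengths)
        m_starts = _place_nonoverlapping(rng, mito_len, lengths)
        for ln, ps, ms in zip(lengths, p_starts, m_starts):
            source = plastid[ps - 1:ps - 1 + ln]
            copy = _diverge(rng, source, divergence)
            mito[ms - 1:ms - 1 + ln] = list(copy)
            transfers.append(
                TransferSegment(ms, ms + ln - 1, ps, ps + ln - 1, divergence)
            )
        transfers.sort(key=lambda t: t.mito_start)
    return ReferencePair("".join(plastid), "".join(mito), transfers, nuclear)


def simulate_cultivar(
    refs: ReferencePair,
    name: str = "CV1",
    n_mito_snps: int = 10,
    n_plastid_snps: int = 5,
    het_fraction: float = 0.0,
    af_range: tuple[float, float] = (0.3, 0.7),
    seed: int = 0,
    avoid_transfers: bool = True,
    edge_margin: int = 300,
) -> CultivarProfile:
    """Plant SNPs on the two organellar genomes.

    A ``het_fraction`` share of each genome's variants is heteroplasmic with
    allele fraction drawn uniformly from ``af_range``; the rest are
    homoplasmic (fraction 1).  With ``avoid_transfers`` (default) positions
    inside transfer segments (and their plastid sources) are excluded so
    planted variants stay recoverable after cross-map filtering.  The first
    and last ``edge_margin`` positions are likewise excluded: the genomes
    are linear, so read depth ramps down inside one insert length of the
    ends.
    """
    lo, hi = af_range
    if not (0 < lo <= hi <= 1):
        raise ValueError("af_range must lie within (0, 1]")
    rng = np.random.default_rng(seed)
    variants: list[Variant] = []
    for genome, n_snps in (("mito", n_mito_snps), ("plastid", n_plastid_snps)):
        if n_snps == 0:
            continue
        seq = refs.genome(genome)
        mask = np.ones(len(seq), dtype=bool)
        if edge_margin:
            mask[:edge_margin] = False
            mask[len(seq) - edge_margin:] = False
        if avoid_transfers:
            for t in refs.transfers:
                if genome == "mito":
                    mask[t.mito_start - 1:t.mito_end] = False
                else:
                    mask[t.plastid_start - 1:t.plastid_end] = False
        allowed = np.arange(1, len(seq) + 1)[mask]
        if n_snps > len(allowed):
            raise ValueError(f"not enough placeable positions on {genome}")
        positions = sorted(rng.choice(allowed, size=n_snps, replace=False))
        n_het = round(het_fraction * n_snps)
        het_idx = set(rng.choice(n_snps, size=n_het, replace=False))
        for i, pos in enumerate(positions):
            ref_base = seq[pos - 1]
            alt = [b for b in BASES if b != ref_base][rng.integers(0, 3)]
            af = float(rng.uniform(lo, hi)) if i in het_idx else 1.0
            variants.append(Variant(genome, int(pos), ref_base, alt, af))
    return CultivarProfile(name, variants)


DEFAULT_COPY_NUMBERS = {"plastid": 4.0, "mito": 1.0, "nuclear": 0.02}


def simulate_reads(
    refs: ReferencePair,
    profile: CultivarProfile,
    copy_numbers: dict[str, float] | None = None,
    base_coverage: float = 100.0,
    read_len: int = 100,
    insert_mean: int = 300,
    insert_sd: int = 30,
    error_rate: float = 0.01,
    seed: int = 0,
) -> tuple[list, list, list[ReadTruth]]:
    """Simulate paired-end reads for one cultivar across all three genomes.

    Expected depth per genome is ``copy_number * base_coverage``.
    Heteroplasmic variants are realised per fragment (both mates agree) with
    probability equal to their allele fraction.  Returns
    (mate-1 reads, mate-2 reads, truth records) where reads are
    (id, sequence, quality) tuples with ``/1`` / ``/2`` id suffixes.
    """
    if copy_numbers is None:
        copy_numbers = DEFAULT_COPY_NUMBERS
    if any(cn <= 0 for cn in copy_numbers.values()):
        raise ValueError("copy numbers must be positive")
    if read_len >= insert_mean:
        raise ValueError("read_len must be below insert_mean")
    rng = np.random.default_rng(seed)
    phred = min(40, round(-10 * math.log10(error_rate))) if error_rate > 0 else 40
    qual = chr(33 + phred) * read_len
    reads1, reads2, truths = [], [], []
    for genome, cn in copy_numbers.items():
        seq = refs.genome(genome)
        if not seq:
            continue
        L = len(seq)
        variants = profile.for_genome(genome)
        var_by_pos = {v.position: v for v in variants}
        var_positions = np.array(sorted(var_by_pos), dtype=np.int64)
        n_pairs = round(cn * base_coverage * L / (2 * read_len))
        if n_pairs == 0:
            warnings.warn(f"coverage too low: zero {genome} read pairs")
            continue
        for i in range(n_pairs):
            insert = int(np.clip(round(rng.normal(insert_mean, insert_sd)),
                                 read_len, L))
            start = int(rng.integers(1, L - insert + 2))
            frag = list(seq[start - 1:start - 1 + insert])
            carried = []
            if len(var_positions):
                lo_i = np.searchsorted(var_positions, start)
                hi_i = np.searchsorted(var_positions, start + insert - 1, "right")
                for pos in var_positions[lo_i:hi_i]:
                    v = var_by_pos[int(pos)]
                    if v.allele_fraction >= 1 or rng.random() < v.allele_fraction:
                        frag[pos - start] = v.alt_base
                        carried.append((genome, int(pos), v.alt_base))
            frag = "".join(frag)
            r1 = frag[:read_len]
            r2 = revcomp(frag[-read_len:])
            if error_rate > 0:
                r1 = _apply_errors(rng, r1, error_rate)
                r2 = _apply_errors(rng, r2, error_rate)
            rid = f"{genome}_{i:07d}"
            reads1.append((f"{rid}/1", r1, qual))
            reads2.append((f"{rid}/2", r2, qual))
            truths.append(ReadTruth(rid, genome, start, insert, read_len, carried))
    return reads1, reads2, truths


def _apply_errors(rng, seq: str, error_rate: float) -> str:
    hit = rng.random(len(seq)) < error_rate
    if not hit.any():
        return seq
    arr = list(seq)
    for i in np.nonzero(hit)[0]:
        others = [b for b in BASES if b != arr[i]]
        arr[i] = others[rng.integers(0, 3)]
    return "".join(arr)


# ---------------------------------------------------------------------------
# Truth sidecar TSV

def write_truth(truths: list[ReadTruth], path) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\tgenome\tstart\tinsert_size\tread_len\tvariants\n")
        for t in truths:
            vs = ";".join(f"{g}:{p}:{a}" for g, p, a in t.variants_carried)
            fh.write(f"{t.read_id}\t{t.genome}\t{t.start}\t{t.insert_size}\t"
                     f"{t.read_len}\t{vs}\n")


def read_truth(path) -> list[ReadTruth]:
    out = []
    with open(path) as fh:
        fh.readline()
        for ln in fh:
            rid, genome, start, insert, rl, vs = ln.rstrip("\n").split("\t")
            carried = []
            if vs:
                for item in vs.split(";"):
                    g, p, a = item.split(":")
                    carried.append((g, int(p), a))
            out.append(ReadTruth(rid, genome, int(start), int(insert),
                                 int(rl), carried))
    return out
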