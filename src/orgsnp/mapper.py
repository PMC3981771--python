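"""Minimal seed-and-verify read aligner.

Placements are found by exact k-mer seeding and verified by ungapped Hamming
comparison on both strands; the best placement is the one with the fewest
mismatches.  With ``max_mismatch + 1`` disjoint seeds per read, any placement
with at most ``max_mismatch`` mismatches must contain at least one exact
seed, so the candidate set provably contains every acceptable placement
(pigeonhole).  Mapping quality is 0 whenever the best placement ties and
``min(60, 20 * (second_best - best))`` otherwise, with ``second_best`` taken
as ``max_mismatch + 1`` when no second candidate exists.  This is a fixed,
documented formula, not an emulation of any external aligner's MAPQ.
"""
from __future__ import annotations

import numpy as np

from .core import AlignmentRecord, revcomp

_CODE = np.full(256, 255, dtype=np.uint8)
for i, b in enumerate("ACGT"):
    _CODE[ord(b)] = i
    _CODE[ord(b.lower())] = i


def encode(seq: str) -> np.ndarray:
    """2-bit encode a sequence (non-ACGT characters become code 255)."""
    return _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


class SeedIndex:
    """Exact k-mer index of one reference: k-mer -> all 1-based positions."""

    def __init__(self, reference: str, k: int = 15):
        if k < 1:
            raise ValueError("k must be positive")
        if k > len(reference):
            raise ValueError("k exceeds reference length")
        self.k = k
        self.reference = reference
        self.codes = encode(reference)
        n = len(reference) - k + 1
        windows = np.lib.stride_tricks.sliding_window_view(self.codes, k)
        valid = ~(windows == 255).any(axis=1)
        powers = (4 ** np.arange(k - 1, -1, -1, dtype=np.int64))
        kmers = windows.astype(np.int64) @ powers
        self._index: dict[int, np.ndarray] = {}
        order = np.argsort(kmers[valid], kind="stable")
        pos = (np.nonzero(valid)[0] + 1)[order]  # 1-based
        sorted_kmers = kmers[valid][order]
        bounds = np.flatnonzero(np.diff(sorted_kmers)) + 1
        for chunk, km in zip(
            np.split(pos, bounds), sorted_kmers[np.r_[0, bounds]] if len(pos) else []
        ):
            self._index[int(km)] = chunk
        self.n_kmers = int(valid.sum())
        assert self.n_kmers <= n

    def lookup(self, kmer_codes: np.ndarray) -> np.ndarray:
        """Positions (1-based) of an exact k-mer given as a code array."""
        if (kmer_codes == 255).any():
            return np.empty(0, dtype=np.int64)
        powers = 4 ** np.arange(self.k - 1, -1, -1, dtype=np.int64)
        return self._index.get(int(kmer_codes.astype(np.int64) @ powers),
                               np.empty(0, dtype=np.int64))


def _seed_offsets(read_len: int, k: int, max_mismatch: int) -> list[int]:
    n_seeds = min(max_mismatch + 1, read_len // k)
    offsets = [i * k for i in range(n_seeds)]
    if read_len - k not in offsets and read_len >= k:
        offsets.append(read_len - k)
    return offsets


def map_read(
    read_seq: str,
    index: SeedIndex,
    max_mismatch: int = 5,
    read_id: str = "read",
    mate: int = 0,
    qual: str = "",
    reference_name: str = "ref",
) -> AlignmentRecord:
    """Place one read on the indexed reference (both strands, ungapped)."""
    L = len(read_seq)
    if L < index.k:
        raise ValueError("read shorter than seed length")
    ref_codes = index.codes
    ref_len = len(ref_codes)
    offsets = _seed_offsets(L, index.k, max_mismatch)

    candidates: dict[tuple[int, str], int] = {}
    for strand, seq in (("+", read_seq), ("-", revcomp(read_seq))):
        codes = encode(seq)
        starts: set[int] = set()
        for off in offsets:
            for hit in index.lookup(codes[off:off + index.k]):
                s = int(hit) - off
                if 1 <= s and s + L - 1 <= ref_len:
                    starts.add(s)
        for s in starts:
            mm = int(np.count_nonzero(ref_codes[s - 1:s - 1 + L] != codes))
            candidates[(s, strand)] = mm

    if not candidates:
        return AlignmentRecord(read_id, mate, None, 0, "+", 0, 0, False,
                               read_seq, qual)

    # deterministic order: fewest mismatches, then position, then '+' first
    ranked = sorted(candidates.items(), key=lambda kv: (kv[1], kv[0][0], kv[0][1]))
    (best_pos, best_strand), best_mm = ranked[0]
    if best_mm > max_mismatch:
        return AlignmentRecord(read_id, mate, None, 0, "+", 0, 0, False,
                               read_seq, qual)
    tie = len(ranked) > 1 and ranked[1][1] == best_mm
    if tie:
        mapq = 0
    else:
        second = ranked[1][1] if len(ranked) > 1 else max_mismatch + 1
        second = min(second, max_mismatch + 1)
        mapq = min(60, 20 * (second - best_mm))
    if best_strand == "-":
        seq_out, qual_out = revcomp(read_seq), qual[::-1]
    else:
        seq_out, qual_out = read_seq, qual
    return AlignmentRecord(
        read_id, mate, reference_name, best_pos, best_strand,
        best_mm, mapq, True, seq_out, qual_out,
    )


def map_read_bruteforce(read_seq: str, reference: str, max_mismatch: int = 5):
    """Exhaustive all-position, both-strand Hamming scan (test oracle).

    Returns (best_position, strand, mismatches, is_tie) or None if no
    placement has <= max_mismatch mismatches.
    """
    ref_codes = encode(reference)
    L = len(read_seq)
    hits = []
    for strand, seq in (("+", read_seq), ("-", revcomp(read_seq))):
        codes = encode(seq)
        for s in range(1, len(reference) - L + 2):
            mm = int(np.count_nonzero(ref_codes[s - 1:s - 1 + L] != codes))
            if mm <= max_mismatch:
                hits.append((mm, s, strand))
    if not hits:
        return None
    hits.sort(key=lambda h: (h[0], h[1], h[2]))
    mm, s, strand = hits[0]
    tie = len(hits) > 1 and hits[1][0] == mm
    return s, strand, mm, tie


def map_library(
    reads1: list[tuple[str, str, str]],
    reads2: list[tuple[str, str, str]] | None,
    reference: str,
    reference_name: str = "ref",
    k: int = 15,
    max_mismatch: int = 5,
) -> list[AlignmentRecord]:
    """Map a (paired) read library; each mate is placed independently."""
    index = SeedIndex(reference, k)
    records = []
    if reads2 is not None:
        if len(reads1) != len(reads2):
            raise ValueError("mate count mismatch between the two files")
        for (id1, s1, q1), (id2, s2, q2) in zip(reads1, reads2):
            base1, base2 = id1.rsplit("/", 1)[0], id2.rsplit("/", 1)[0]
            if base1 != base2:
                raise ValueError(f"unpaired mates: {id1} vs {id2}")
            records.append(map_read(s1, index, max_mismatch, base1, 1, q1,
                                    reference_name))
            records.append(map_read(s2, index, max_mismatch, base2, 2, q2,
                                    reference_name))
    else:
        for rid, seq, qual in reads1:
            records.append(map_read(seq, index, max_mismatch,
                                    rid.rsplit("/", 1)[0], 0, qual,
                                    reference_name))
    return records
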