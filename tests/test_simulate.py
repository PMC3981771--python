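import numpy as np
import pytest

from orgsnp import io, simulate


class TestSimulateReferences:
    def test_deterministic_for_fixed_seed(self):
        a = simulate.simulate_references(seed=5)
        b = simulate.simulate_references(seed=5)
        assert a.mito_seq == b.mito_seq and a.plastid_seq == b.plastid_seq
        assert a.transfers == b.transfers

    def test_zero_divergence_copy_is_exact_substring(self):
        refs = simulate.simulate_references(
            plastid_len=5000, mito_len=10_000, nuclear_len=0,
            transfer_fraction=0.1, n_segments=1, divergence=0.0, seed=1,
        )
        [seg] = refs.transfers
        copy = refs.mito_seq[seg.mito_start - 1:seg.mito_end]
        assert copy in refs.plastid_seq
        assert copy == refs.plastid_seq[seg.plastid_start - 1:seg.plastid_end]

    def test_zero_transfer_fraction_gives_no_segments(self):
        refs = simulate.simulate_references(
            plastid_len=5000, mito_len=10_000, transfer_fraction=0.0,
            n_segments=3, seed=2,
        )
        assert refs.transfers == []

    def test_transfer_fraction_recovered_from_segments(self):
        """Recompute the planted fraction directly from the emitted
        segment coordinates."""
        refs = simulate.simulate_references(
            plastid_len=20_000, mito_len=50_000, transfer_fraction=0.103,
            n_segments=5, divergence=0.02, seed=3,
        )
        total = sum(seg.mito_end - seg.mito_start + 1
                    for seg in refs.transfers)
        assert 0.093 <= total / 50_000 <= 0.113

    def test_segments_nonoverlapping_and_in_bounds(self):
        refs = simulate.simulate_references(
            transfer_fraction=0.2, n_segments=8, seed=4,
        )
        segs = sorted(refs.transfers, key=lambda s: s.mito_start)
        for s in segs:
            assert 1 <= s.mito_start <= s.mito_end <= len(refs.mito_seq)
            assert 1 <= s.plastid_start <= s.plastid_end <= len(refs.plastid_seq)
        for a, b in zip(segs, segs[1:]):
            assert a.mito_end < b.mito_start

    def test_divergence_realised_binomially(self):
        refs = simulate.simulate_references(
            transfer_fraction=0.103, n_segments=3, divergence=0.05, seed=6,
        )
        for seg in refs.transfers:
            src = refs.plastid_seq[seg.plastid_start - 1:seg.plastid_end]
            cpy = refs.mito_seq[seg.mito_start - 1:seg.mito_end]
            rate = sum(a != b for a, b in zip(src, cpy)) / len(src)
            # 3 sigma around 0.05 for ~1.7 kb segments
            assert abs(rate - 0.05) < 3 * (0.05 * 0.95 / len(src)) ** 0.5

    def test_unsourceable_transfer_rejected(self):
        with pytest.raises(ValueError, match="cannot source"):
            simulate.simulate_references(
                plastid_len=1000, mito_len=50_000, transfer_fraction=0.5,
            )


class TestSimulateCultivar:
    def test_zero_het_fraction_all_homoplasmic(self, small_refs):
        profile = simulate.simulate_cultivar(
            small_refs, n_mito_snps=10, n_plastid_snps=5,
            het_fraction=0.0, seed=1,
        )
        assert len(profile.variants) == 15
        assert all(v.allele_fraction == 1.0 for v in profile.variants)

    def test_zero_counts_give_empty_profile(self, small_refs):
        profile = simulate.simulate_cultivar(
            small_refs, n_mito_snps=0, n_plastid_snps=0, seed=1,
        )
        assert profile.variants == []

    def test_het_variants_drawn_from_af_range(self, small_refs):
        profile = simulate.simulate_cultivar(
            small_refs, n_mito_snps=0, n_plastid_snps=8,
            het_fraction=1.0, af_range=(0.4, 0.6), seed=2,
        )
        plastid = profile.for_genome("plastid")
        assert len(plastid) == 8
        assert all(0.4 <= v.allele_fraction <= 0.6 for v in plastid)

    def test_ref_bases_match_reference_and_positions_unique(self, small_refs):
        profile = simulate.simulate_cultivar(
            small_refs, n_mito_snps=20, n_plastid_snps=10, seed=3,
        )
        for v in profile.variants:
            seq = small_refs.genome(v.genome)
            assert seq[v.position - 1] == v.ref_base
            assert v.alt_base != v.ref_base
        for genome in ("mito", "plastid"):
            pos = [v.position for v in profile.for_genome(genome)]
            assert len(pos) == len(set(pos))

    def test_invalid_af_range_rejected(self, small_refs):
        with pytest.raises(ValueError, match="af_range"):
            simulate.simulate_cultivar(small_refs, af_range=(0.0, 1.2))


class TestSimulateReads:
    def test_deterministic_fastq_output(self, small_refs, tmp_path):
        profile = simulate.simulate_cultivar(small_refs, seed=1)
        outs = []
        for run in range(2):
            r1, r2, _ = simulate.simulate_reads(
                small_refs, profile, {"mito": 1.0}, base_coverage=5, seed=9,
            )
            path = tmp_path / f"run{run}.fastq"
            io.write_fastq(r1 + r2, path)
            outs.append(path.read_bytes())
        assert outs[0] == outs[1]

    def test_truth_records_conserved(self, small_refs):
        profile = simulate.CultivarProfile("CV0", [])
        r1, r2, truths = simulate.simulate_reads(
            small_refs, profile, {"mito": 1.0, "plastid": 1.0},
            base_coverage=5, seed=1,
        )
        assert len(truths) == len(r1) == len(r2)

    def test_error_free_reads_match_genome(self, small_refs):
        profile = simulate.CultivarProfile("CV0", [])
        r1, r2, truths = simulate.simulate_reads(
            small_refs, profile, {"mito": 1.0}, base_coverage=5,
            error_rate=0.0, seed=2,
        )
        from orgsnp.core import revcomp

        genome = small_refs.mito_seq
        for (rid1, s1, _), (rid2, s2, _), t in zip(r1, r2, truths):
            frag = genome[t.start - 1:t.start - 1 + t.insert_size]
            assert s1 == frag[:t.read_len]
            assert s2 == revcomp(frag[-t.read_len:])

    def test_quality_string_encodes_error_rate(self, small_refs):
        profile = simulate.CultivarProfile("CV0", [])
        r1, _, _ = simulate.simulate_reads(
            small_refs, profile, {"mito": 1.0}, base_coverage=2,
            error_rate=0.01, seed=3,
        )
        assert set(r1[0][2]) == {chr(33 + 20)}  # Q20 for 1% error

    def test_copy_number_sets_depth_ratio(self):
        """plastid:mito = 5:1 gives realized depth ratio in [4, 6] over
        non-transfer sites (counted from the truth intervals)."""
        refs = simulate.simulate_references(
            plastid_len=2000, mito_len=4000, nuclear_len=0,
            transfer_fraction=0.1, n_segments=1, seed=4,
        )
        profile = simulate.CultivarProfile("CV0", [])
        _, _, truths = simulate.simulate_reads(
            refs, profile, {"plastid": 5.0, "mito": 1.0},
            base_coverage=60, seed=5,
        )
        depth = {g: np.zeros(len(refs.genome(g)) + 2) for g in ("mito", "plastid")}
        for t in truths:
            for start in (t.start, t.start + t.insert_size - t.read_len):
                depth[t.genome][start:start + t.read_len] += 1
        outside = {
            "mito": [p for p in range(1, 4001) if not refs.in_transfer(p)],
            "plastid": list(range(1, 2001)),
        }
        means = {g: depth[g][outside[g]].mean() for g in depth}
        assert means["mito"] >= 50
        assert 4.0 <= means["plastid"] / means["mito"] <= 6.0

    def test_allele_fraction_realised_on_reads(self, small_refs):
        """A 0.5-fraction plastid variant at ~200x appears on 40-60% of
        covering fragments."""
        pos = 1000
        var = simulate.Variant("plastid", pos,
                               small_refs.plastid_seq[pos - 1],
                               "ACGT".replace(small_refs.plastid_seq[pos - 1], "")[0],
                               0.5)
        profile = simulate.CultivarProfile("CV1", [var])
        _, _, truths = simulate.simulate_reads(
            small_refs, profile, {"plastid": 2.0}, base_coverage=100, seed=6,
        )
        covering = [t for t in truths
                    if t.start <= pos <= t.start + t.insert_size - 1]
        assert len(covering) > 100
        frac = np.mean([len(t.variants_carried) > 0 for t in covering])
        assert 0.4 <= frac <= 0.6

    def test_zero_coverage_warns_and_returns_empty(self, small_refs):
        profile = simulate.CultivarProfile("CV0", [])
        with pytest.warns(UserWarning, match="zero"):
            r1, r2, truths = simulate.simulate_reads(
                small_refs, profile, {"mito": 1.0}, base_coverage=0.001,
                seed=7,
            )
        assert r1 == [] and truths == []

    def test_truth_sidecar_round_trip(self, small_refs, tmp_path):
        profile = simulate.simulate_cultivar(small_refs, het_fraction=0.5,
                                             seed=8)
        _, _, truths = simulate.simulate_reads(
            small_refs, profile, {"mito": 1.0}, base_coverage=3, seed=8,
        )
        path = tmp_path / "truth.tsv"
        simulate.write_truth(truths, path)
        assert simulate.read_truth(path) == truths
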