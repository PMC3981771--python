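"""Readers and writers for the standard formats the pipeline touches.

FASTA via Bio.SeqIO, FASTQ via Biopython's fast iterator, SAM/VCF via pysam,
Newick via dendropy.  GFF3 is read with a small flat parser (the annotation
here is a plain gene/exon/intron track; no feature hierarchy is needed).
The published SNP tables ship as TSV fixtures and are loaded with pandas,
with their printed aggregate structure checked at load time.
"""
from __future__ import annotations

import os
from importlib import resources

import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqIO.QualityIO import FastqGeneralIterator
from Bio.SeqRecord import SeqRecord

from .core import IUPAC, AlignmentRecord, Feature, FeatureTrack, PublishedSnpRow

# ---------------------------------------------------------------------------
# FASTA / FASTQ

def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into an ordered {name: sequence} mapping.

    Sequences are upper-cased; non-IUPAC characters raise ValueError.
    """
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        bad = set(seq) - IUPAC
        if bad:
            raise ValueError(f"non-IUPAC characters in {rec.id}: {sorted(bad)}")
        seqs[rec.id] = seq
    if not seqs:
        raise ValueError(f"no sequences in {path}")
    return seqs


def write_fasta(seqs: dict[str, str], path, width: int = 60) -> None:
    records = [
        SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def read_fastq(path) -> list[tuple[str, str, str]]:
    """Read FASTQ as (id, sequence, quality) tuples (Phred+33 kept as text)."""
    with open(path) as fh:
        return [(rid, seq, qual) for rid, seq, qual in FastqGeneralIterator(fh)]


def write_fastq(reads: list[tuple[str, str, str]], path, header_comment: str = "") -> None:
    with open(path, "w") as fh:
        for rid, seq, qual in reads:
            if header_comment:
                fh.write(f"@{rid} {header_comment}\n{seq}\n+\n{qual}\n")
            else:
                fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")


# ---------------------------------------------------------------------------
# SAM (minimal ungapped dialect, via pysam)

_MATE_FLAGS = {1: 0x1 | 0x40, 2: 0x1 | 0x80, 0: 0}


def write_sam(records: list[AlignmentRecord], references: dict[str, int], path) -> None:
    """Write ungapped alignment records as plain-text SAM.

    ``references`` maps reference name to length (the @SQ header lines).
    Unmapped records are preserved with flag 0x4.
    """
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": n, "LN": ln} for n, ln in references.items()],
    }
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for rec in records:
            a = pysam.AlignedSegment(out.header)
            a.query_name = rec.read_id
            flag = _MATE_FLAGS[rec.mate]
            if not rec.mapped:
                flag |= 0x4
            if rec.mapped and rec.strand == "-":
                flag |= 0x10
            a.flag = flag
            a.query_sequence = rec.seq or None
            if rec.qual:
                a.query_qualities = pysam.qualitystring_to_array(rec.qual)
            if rec.mapped:
                a.reference_id = out.header.get_tid(rec.reference_name)
                if a.reference_id < 0:
                    raise ValueError(
                        f"reference {rec.reference_name!r} not in header"
                    )
                a.reference_start = rec.position - 1
                a.mapping_quality = rec.mapping_quality
                a.cigarstring = f"{len(rec.seq)}M"
                a.set_tag("NM", rec.mismatches)
            else:
                a.reference_id = -1
                a.reference_start = -1
                a.mapping_quality = 0
            out.write(a)


def read_sam(path) -> list[AlignmentRecord]:
    """Read a SAM file back into AlignmentRecords (mandatory columns + NM)."""
    records = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for a in sam.fetch(until_eof=True):
            mate = 1 if a.flag & 0x40 else (2 if a.flag & 0x80 else 0)
            qual = (
                pysam.qualities_to_qualitystring(a.query_qualities)
                if a.query_qualities is not None
                else ""
            )
            if a.is_unmapped:
                records.append(
                    AlignmentRecord(
                        a.query_name, mate, None, 0, "+", 0, 0, False,
                        a.query_sequence or "", qual,
                    )
                )
            else:
                records.append(
                    AlignmentRecord(
                        a.query_name,
                        mate,
                        a.reference_name,
                        a.reference_start + 1,
                        "-" if a.is_reverse else "+",
                        int(a.get_tag("NM")) if a.has_tag("NM") else 0,
                        a.mapping_quality,
                        True,
                        a.query_sequence or "",
                        qual,
                    )
                )
    return records


# ---------------------------------------------------------------------------
# Published SNP-table fixtures

TABLE_FILES = {"mito": "published_mito_snps.tsv", "plastid": "published_plastid_snps.tsv"}
# printed aggregate structure, checked at load time
_TABLE_SHAPE = {"mito": (188, 37), "plastid": (30, 20)}
_LOCATION_PREFIXES = {"IGS", "I", "S", "NS"}


def fixture_path(which: str):
    return resources.files("orgsnp") / "data" / TABLE_FILES[which]


def load_published_table(path=None, which: str = "mito") -> list[PublishedSnpRow]:
    """Load a transcribed published SNP table.

    With ``path=None`` the bundled fixture for ``which`` is used and its
    row/position totals are checked against the printed table structure.
    """
    bundled = path is None
    if bundled:
        path = fixture_path(which)
    df = pd.read_csv(path, sep="\t", dtype=str)
    rows = []
    for i, r in df.iterrows():
        line_no = i + 2  # header is line 1
        try:
            depth = int(r["read_depth"])
            dref = int(r["depth_reference"])
            dalt = int(r["depth_alternate"])
            qual = float(r["quality"])
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path}: malformed depth/quality at line {line_no}") from exc
        if dref + dalt > depth:
            raise ValueError(f"{path}: depths exceed read depth at line {line_no}")
        if qual < 0:
            raise ValueError(f"{path}: negative quality at line {line_no}")
        loc = r["location"]
        if loc.split("-")[0] not in _LOCATION_PREFIXES:
            raise ValueError(f"{path}: unknown location label {loc!r} at line {line_no}")
        rows.append(
            PublishedSnpRow(
                cultivar=r["cultivar"],
                position=int(r["position"]),
                ref_base=r["ref"],
                alt_bases=r["alt"],
                quality=qual,
                read_depth=depth,
                depth_reference=dref,
                depth_alternate=dalt,
                location_label=loc,
                unique_flag=r["unique"] == "1",
                polymorphic_flag=r["polymorphic"] == "1",
            )
        )
    if bundled:
        n_rows, n_pos = _TABLE_SHAPE[which]
        if len(rows) != n_rows or len({r.position for r in rows}) != n_pos:
            raise ValueError(f"fixture {which} does not match its printed structure")
    return rows


# ---------------------------------------------------------------------------
# VCF

def write_vcf(snps, reference_name: str, path) -> None:
    """Write SNP records as VCF 4.2 with INFO DP/DPR/DPA depth fields."""
    header = pysam.VariantHeader()
    header.add_line('##INFO=<ID=DP,Number=1,Type=Integer,Description="Total read depth">')
    header.add_line('##INFO=<ID=DPR,Number=1,Type=Integer,Description="Reads supporting the reference allele">')
    header.add_line('##INFO=<ID=DPA,Number=1,Type=Integer,Description="Reads supporting the alternate allele">')
    header.add_line('##INFO=<ID=CULT,Number=1,Type=String,Description="Cultivar">')
    header.add_line('##INFO=<ID=LOC,Number=1,Type=String,Description="Genomic context label">')
    max_pos = max((s.position for s in snps), default=0)
    header.contigs.add(reference_name, length=max(max_pos + 1, 1))
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for s in sorted(snps, key=lambda x: (x.position, x.cultivar)):
            alts = [s.alt_base] + ([s.secondary_alt] if s.secondary_alt else [])
            rec = out.new_record(
                contig=reference_name,
                start=s.position - 1,
                stop=s.position,
                alleles=tuple([s.ref_base] + alts),
                qual=s.quality,
            )
            rec.info["DP"] = s.read_depth
            rec.info["DPR"] = s.depth_reference
            rec.info["DPA"] = s.depth_alternate
            rec.info["CULT"] = s.cultivar
            if s.location_label:
                rec.info["LOC"] = s.location_label
            out.write(rec)


def read_vcf(path):
    """Read a VCF written by :func:`write_vcf` back into plain tuples."""
    out = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            out.append(
                {
                    "position": rec.pos,
                    "ref": rec.ref,
                    "alts": list(rec.alts or ()),
                    "qual": rec.qual,
                    "DP": rec.info.get("DP"),
                    "DPR": rec.info.get("DPR"),
                    "DPA": rec.info.get("DPA"),
                    "cultivar": rec.info.get("CULT"),
                }
            )
    return out


# ---------------------------------------------------------------------------
# GFF3 (flat gene/exon/intron track)

def read_gff(path) -> FeatureTrack:
    """Parse a GFF3 file into a flat FeatureTrack (1-based inclusive)."""
    feats = []
    with open(path) as fh:
        for ln in fh:
            ln = ln.strip()
            if not ln or ln.startswith("#"):
                continue
            cols = ln.split("\t")
            if len(cols) != 9:
                raise ValueError(f"malformed GFF line: {ln!r}")
            _, _, ftype, start, end, _, strand, _, attrs = cols
            if ftype not in ("gene", "exon", "intron"):
                continue
            attr = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            feats.append(
                Feature(
                    feature_id=attr.get("ID", f"{ftype}:{start}-{end}"),
                    type=ftype,
                    start=int(start),
                    end=int(end),
                    strand=strand,
                    parent=attr.get("Parent", ""),
                    name=attr.get("Name", attr.get("ID", "")),
                )
            )
    return FeatureTrack(feats)


def write_gff(track: FeatureTrack, seqid: str, path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in track.features:
            attrs = f"ID={f.feature_id}"
            if f.parent:
                attrs += f";Parent={f.parent}"
            if f.name and f.name != f.feature_id:
                attrs += f";Name={f.name}"
            fh.write(
                f"{seqid}\torgsnp\t{f.type}\t{f.start}\t{f.end}\t.\t{f.strand}\t.\t{attrs}\n"
            )


# ---------------------------------------------------------------------------
# Newick

def read_newick(source: str):
    """Parse a Newick string into a dendropy Tree (error on malformed input)."""
    import dendropy

    if os.path.exists(str(source)):
        source = open(source).read()
    if source.count("(") != source.count(")"):
        raise ValueError("unbalanced parentheses in Newick input")
    return dendropy.Tree.get(data=source, schema="newick")


def write_newick(tree, path=None) -> str:
    s = tree.as_string(schema="newick", suppress_rooting=True)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(s)
    return s
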