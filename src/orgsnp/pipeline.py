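"""End-to-end orchestration: simulate -> map -> filter -> call -> cohort ->
phylo, with every stage's output written to a run directory and a JSON
summary recording the resolved configuration, its hash and the seed."""
from __future__ import annotations

import hashlib
import json
import logging
import warnings
from pathlib import Path

import pandas as pd

from . import caller, cohort, crossmap, io, mapper, phylo, simulate
from .core import CallThresholds

log = logging.getLogger("orgsnp")

DEFAULT_CONFIG = {
    "seed": 1,
    "n_cultivars": 4,
    "plastid_len": 20_000,
    "mito_len": 50_000,
    "nuclear_len": 100_000,
    "transfer_fraction": 0.103,
    "n_segments": 5,
    "divergence": 0.02,
    "copy_numbers": {"plastid": 4.0, "mito": 1.0, "nuclear": 0.02},
    "base_coverage": 40.0,
    "read_len": 100,
    "insert_mean": 300,
    "insert_sd": 30,
    "error_rate": 0.01,
    "n_mito_snps": 10,
    "n_plastid_snps": 5,
    "het_fraction": 0.3,
    "af_range": [0.3, 0.7],
    "k": 15,
    "max_mismatch": 5,
    "min_depth": 10,
    "min_mapq": 20,
    "min_snp_quality": 15,
    "skip_filter": False,
    "bootstrap_replicates": 1000,
    "run_phylo": False,
}


def resolve_config(overrides: dict | None = None) -> dict:
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))
    for key, value in (overrides or {}).items():
        if key not in cfg:
            raise KeyError(f"unknown config key {key!r}")
        cfg[key] = value
    return cfg


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True).encode()
    ).hexdigest()[:12]


def run_pipeline(config: dict | None = None, outdir="run") -> dict:
    """Run the full synthetic pipeline; returns the JSON summary dict."""
    cfg = resolve_config(config)
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    thresholds = CallThresholds(
        cfg["min_depth"], cfg["min_mapq"], cfg["min_snp_quality"]
    )

    log.info("stage simulate: references")
    refs = simulate.simulate_references(
        cfg["plastid_len"], cfg["mito_len"], cfg["nuclear_len"],
        cfg["transfer_fraction"], cfg["n_segments"], cfg["divergence"],
        seed=seed,
    )
    io.write_fasta(
        {"plastid": refs.plastid_seq, "mito": refs.mito_seq,
         "nuclear": refs.nuclear_seq},
        out / "references.fasta",
    )
    genome_len = {"mito": len(refs.mito_seq), "plastid": len(refs.plastid_seq)}

    calls: dict[str, dict[str, list]] = {"mito": {}, "plastid": {}}
    reports = []
    truth_profiles = {}
    for ci in range(int(cfg["n_cultivars"])):
        name = f"CV{ci + 1}"
        profile = simulate.simulate_cultivar(
            refs, name, cfg["n_mito_snps"], cfg["n_plastid_snps"],
            cfg["het_fraction"], tuple(cfg["af_range"]), seed=seed + 101 + ci,
        )
        truth_profiles[name] = profile
        reads1, reads2, truths = simulate.simulate_reads(
            refs, profile, cfg["copy_numbers"], cfg["base_coverage"],
            cfg["read_len"], cfg["insert_mean"], cfg["insert_sd"],
            cfg["error_rate"], seed=seed + 201 + ci,
        )
        io.write_fastq(reads1, out / f"{name}_1.fastq", f"seed={seed}")
        io.write_fastq(reads2, out / f"{name}_2.fastq", f"seed={seed}")
        simulate.write_truth(truths, out / f"{name}_truth.tsv")
        log.info("stage map: %s (%d pairs)", name, len(reads1))
        aln = {}
        for genome in ("mito", "plastid"):
            aln[genome] = mapper.map_library(
                reads1, reads2, refs.genome(genome), genome,
                k=cfg["k"], max_mismatch=cfg["max_mismatch"],
            )
        crossed = crossmap.crossmapped_ids(aln["mito"], aln["plastid"])
        log.info("stage filter: %s, %d cross-mapping identifiers",
                 name, len(crossed))
        total_reads = 2 * len(reads1)
        for genome in ("mito", "plastid"):
            before = aln[genome]
            after = (before if cfg["skip_filter"]
                     else crossmap.apply_filter(before, crossed))
            io.write_sam(after, genome_len, out / f"{name}_{genome}.sam")
            rep = crossmap.filter_report(
                before, after, genome_len[genome], total_reads, genome
            )
            reports.append({"cultivar": name, **rep.as_row()})
            cols = caller.pileup(after, refs.genome(genome),
                                 min_mapq=cfg["min_mapq"])
            snps = caller.call_snps(cols, thresholds, cultivar=name,
                                    genome=genome)
            calls[genome][name] = snps
            io.write_vcf(snps, genome, out / f"{name}_{genome}.vcf")
            log.info("stage call: %s %s -> %d SNPs", name, genome, len(snps))

    pd.DataFrame(reports).to_csv(out / "filter_report.tsv", sep="\t",
                                 index=False)

    summary = {
        "config": cfg,
        "config_hash": config_hash(cfg),
        "seed": seed,
        "cultivars": sorted(truth_profiles),
        "calls": {},
    }
    for genome in ("mito", "plastid"):
        records = [s for snps in calls[genome].values() for s in snps]
        table = cohort.CohortTable.from_records(
            records, genome, sorted(truth_profiles)
        )
        table.to_dataframe().to_csv(out / f"cohort_{genome}.tsv", sep="\t",
                                    index=False)
        summary["calls"][genome] = cohort.summary(table)
        if cfg["run_phylo"] and len(truth_profiles) >= 3 and records:
            matrix = phylo.build_matrix(table, reference_taxon="REF")
            matrix.to_tsv(out / f"matrix_{genome}.tsv")
            if matrix.n_taxa >= 4 and matrix.n_sites >= 1:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    tree, ll = phylo.ml_tree(matrix, seed=seed)
                (out / f"ml_{genome}.nwk").write_text(tree.to_newick())
                summary["calls"][genome]["ml_log_likelihood"] = ll

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=str)
    return summary


def artifact_experiment(
    seed: int = 1,
    error_rate: float = 0.0,
    base_coverage: float = 100.0,
    n_mito_snps: int = 20,
    plastid_len: int = 20_000,
    mito_len: int = 50_000,
    nuclear_len: int = 100_000,
) -> dict:
    """The cross-mapping artifact study: one cultivar sequenced at a 4:1
    plastid:mito copy ratio over references where 10.3% of the mitochondrial
    genome is plastid-derived insertion (2% diverged), called with and
    without the cross-map read filter.

    Error-free reads isolate the DNA-transfer mechanism: every
    heteroplasmic mitochondrial call then traces to reads from another
    genome, not to sequencing noise.  Returns the measured counts.
    """
    thresholds = CallThresholds()
    refs = simulate.simulate_references(
        plastid_len=plastid_len, mito_len=mito_len, nuclear_len=nuclear_len,
        transfer_fraction=0.103, divergence=0.02, seed=seed,
    )
    profile = simulate.simulate_cultivar(
        refs, "CV1", n_mito_snps=n_mito_snps, n_plastid_snps=5,
        het_fraction=0.0, seed=seed + 1,
    )
    reads1, reads2, _ = simulate.simulate_reads(
        refs, profile, {"plastid": 4.0, "mito": 1.0, "nuclear": 0.02},
        base_coverage=base_coverage, error_rate=error_rate, seed=seed + 2,
    )
    mito_aln = mapper.map_library(reads1, reads2, refs.mito_seq, "mito")
    plastid_aln = mapper.map_library(reads1, reads2, refs.plastid_seq,
                                     "plastid")
    crossed = crossmap.crossmapped_ids(mito_aln, plastid_aln)
    mito_filtered = crossmap.apply_filter(mito_aln, crossed)

    def call(records):
        cols = caller.pileup(records, refs.mito_seq, min_mapq=thresholds.min_mapq)
        return caller.call_snps(cols, thresholds, "CV1", "mito")

    calls_before = call(mito_aln)
    calls_after = call(mito_filtered)
    het = lambda calls, inside: sum(
        1 for c in calls
        if c.zygosity == "heteroplasmic"
        and refs.in_transfer(c.position) == inside
    )
    planted = {v.position for v in profile.for_genome("mito")}
    retained = planted & {c.position for c in calls_after}
    deltas = cohort.compare_filtered_unfiltered(calls_before, calls_after)
    return {
        "n_read_pairs": len(reads1),
        "n_crossmapped": len(crossed),
        "mito_mapped_before": sum(r.mapped for r in mito_aln),
        "mito_mapped_after": sum(r.mapped for r in mito_filtered),
        "het_in_transfers_before": het(calls_before, True),
        "het_in_transfers_after": het(calls_after, True),
        "het_outside_before": het(calls_before, False),
        "het_outside_after": het(calls_after, False),
        "planted_mito_snps": len(planted),
        "planted_retained_after_filter": len(retained),
        "n_calls_before": len(calls_before),
        "n_calls_after": len(calls_after),
        "n_deltas": len(deltas),
        "refs": refs,
        "deltas": deltas,
    }
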