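# orgsnp

Organellar SNP analysis for cultivar fingerprinting, with cross-genome read
filtering to remove plastid→mitochondrion DNA-transfer artifacts.

Plant mitochondrial genomes carry large integrated copies of plastid DNA
(in date palm, ~10.3% of the mitochondrial genome; 46.5% of the plastid
genome).  When total genomic DNA is sequenced and aligned to the
mitochondrial reference, the far more abundant plastid reads pile up on
those integrated copies, and every site where the copy has diverged looks
like intra-individual polymorphism.  `orgsnp` implements the conservative
fix — discard every read that aligns to **both** organellar genomes before
calling — together with everything needed to study it end to end:

* a synthetic-data generator (references with plastid→mito transfer
  segments, cultivar SNP profiles with configurable heteroplasmy,
  paired-end reads with a truth sidecar);
* a minimal seed-and-verify read mapper (ungapped, both strands,
  documented MAPQ rule) — externally produced SAM is accepted at the same
  interface;
* the cross-map read filter with mapping-statistics reports;
* a pileup SNP caller with the published retention thresholds (depth ≥ 10,
  MAPQ ≥ 20, SNP quality ≥ 15) and the homoplasmic/heteroplasmic
  classification rule (heteroplasmic ⇔ reads support both alleles);
* genomic-context annotation (synonymous/nonsynonymous, intron, intergenic
  spacer);
* cohort statistics (per-cultivar totals, cultivar-unique SNPs, the
  shared-by-k spectrum);
* SNP-matrix phylogenetics: Fitch parsimony, JC69 maximum likelihood with
  NNI search, nonparametric bootstrap, and the incongruence length
  difference (ILD) permutation test,
  `p = (1 + #{D_perm ≥ D}) / (1 + n_perm)` with
  `D = L(A+B) − [L(A) + L(B)]`.

The published mitochondrial and plastid SNP tables for the nine Saudi
Arabian date palm cultivars ship as TSV fixtures
(`src/orgsnp/data/published_{mito,plastid}_snps.tsv`), so the cohort, classification,
annotation-summary and phylogenetic stages can be exercised on the real
calls without any download.

## Worked example

Cohort statistics recomputed from the transcribed plastid SNP table:

```sh
$ orgsnp cohort --which plastid
{
  "genome": "plastid",
  "n_records": 30,
  "n_sites": 20,
  "n_heteroplasmic": 30,
  "per_cultivar": {
    "AJW": 4, "DEK": 3, "MOS-A": 8, "MOS-H": 1, "PER": 6,
    "RAB": 2, "SHA": 1, "SUK-A": 4, "SUK-Q": 1
  },
  ...
  "n_unique": 15,
  "sharing_spectrum": {"1": 15, "2": 2, "3": 1, "4": 2}
}
```

Reading: the nine cultivars carry 30 plastid SNP records at 20 distinct
sites, between 1 and 8 per cultivar; every record is heteroplasmic (reads
supporting both alleles); 15 sites occur in a single cultivar, and every
cultivar except DEK and SHA has at least one unique SNP usable as a
fingerprint.  `--which mito` gives the mitochondrial analogue (188 records
at 37 sites, 18–25 per cultivar, only 15 heteroplasmic after cross-map
filtering, sharing spectrum `{9:16, 8:2, 5:1, 3:1, 2:3, 1:14}`).

The full synthetic pipeline (simulate → map → filter → call → cohort) runs
as:

```sh
orgsnp run --seed 1 --out run/          # add --skip-filter to see the artifact
```

and the stages are individually available as `orgsnp map / filter / call /
annotate / cohort / phylo / ild` (see `--help` for each).

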