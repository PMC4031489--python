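# famvar

Family-based exome variant prioritization and inheritance analysis.

`famvar` re-implements, as a tested reusable pipeline, a family-exome
analysis for a two-generation breast-cancer family: a six-stage filter
cascade over multi-sample variant calls, pedigree-based germline vs.
de novo partitioning, recurrence and sister-sharing summaries, stratified
transition/transversion statistics with an exact 2x2 test, and
genomic-context interval annotation. A pedigree-aware simulator generates
synthetic families with known truth so every stage is testable end to end.

## Layout

| module | what it does |
| --- | --- |
| `famvar.core` | domain types (`VariantKey`, `CohortCallset`, `Pedigree`, ...) and VCF/PED/BED/annotation-TSV readers and writers |
| `famvar.cascade` | caller consensus, unaffected-control subtraction, MAF / functional-class / deleteriousness filters, paternal-transmission removal, audit log |
| `famvar.inheritance` | germline vs. de novo classification per mother-daughter pair, recurrence and sister-sharing summaries, gene-set overlap |
| `famvar.spectrum` | Ti/Tv classification and stratified ratio table, exact Fisher 2x2 test by hypergeometric enumeration, interval-context annotation |
| `famvar.simulate` | synthetic family generator (founder germline transmission, de novo spike-ins, common background) with truth labels and recovery scoring |
| `famvar.datasets` | bundled plain-text study fixtures (per-caller VCFs, PED, annotation table, presence matrices, fragile-site BED) |

## CLI

```bash
# run the full prioritization cascade
famvar filter --vcf varscan=varscan.vcf --vcf gatk=gatk.vcf \
    --ann variants.tsv --ped family.ped --config config.yaml \
    --out-table final.tsv --audit audit.log

# label daughter-carried variants germline / de novo
famvar classify --vcf varscan=calls.vcf --ped family.ped \
    --mother 2 --father 9 --daughter 5 --daughter 6

# recurrence classes and sister sharing
famvar share --vcf varscan=calls.vcf --ped family.ped --sisters 1,2,4

# Ti/Tv table by recurrence stratum + exact test
famvar titv --vcf varscan=calls.vcf --ped family.ped

# interval-context annotation
famvar annotate --vcf varscan=calls.vcf --track fragile_sites=sites.bed

# synthetic family with truth labels
famvar simulate --seed 1 --out-dir sim/
```

The `filter` config is YAML with `FilterConfig` fields, e.g.

```yaml
maf_threshold: 0.001
sift_damaging_max: 0.05
polyphen_damaging_min: 0.447
caller_mode: intersection
control_ids: ["3"]
require_confirmation: true
```

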