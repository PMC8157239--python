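# famvar

Familial germline variant prioritization toolkit for small family cohorts of
a rare tumor: verify declared relationships against genomic data, run a
tiered SNV/indel filter cascade, group structural variants by breakpoint
overlap, scan candidate loci, and compare the familial arm to an unrelated
reference cohort. A fully seeded synthetic family-cohort generator with
ground-truth bookkeeping makes every stage testable without any external or
controlled-access data.

## What's inside

| module | purpose |
|---|---|
| `famvar.variant_model` | core types (`AnnotatedVariant`, `BreakendPair`, `GeneModel`, `FamilyCohort`) and multiallelic decomposition / parsimony trimming |
| `famvar.io_formats` | VCF (SNV + SV dialects, via pysam), PED, BED gene models, PoN / SV-catalogue / patients / genetic-map TSVs, funnel reports, YAML run config |
| `famvar.pedigree` | recursive kinship coefficients and degree-of-relationship classification from declared pedigrees |
| `famvar.relatedness` | genotype-based relatedness: robust moment (KING-style) kinship, exact-match IBD segments on phased haplotypes, two-stage degree classification, pedigree concordance |
| `famvar.snv` | tier-1/2 analysis: within-family sharing, quality/rarity/pool-of-normals filters, exonic window, consequence + 3-of-5 predictor consensus, CADD tiers, cross-family variants, recurrent genes, candidate-locus scan |
| `famvar.sv` | tier-3 analysis: catalogue removal, breakpoint-overlap grouping (connected components), family-sharing filter, gene annotation, cross-family gene recurrence, chromosome-dosage flags |
| `famvar.compare` | age summaries, Welch/Student t-test, stage proportions, candidate presence in the reference arm |
| `famvar.simulate` | synthetic cohort generator: founder AF spectra, label-tracked gene dropping, planted shared SNVs/SVs with guaranteed inheritance, annotation synthesis, decoys and catalogue SVs, ground-truth JSON |
| `famvar.cli` | `famvar` subcommand CLI with run manifests (config snapshot, input digests, timings) |

## CLI quick start

```bash
famvar simulate --seed 1 --out data/            # synthetic cohort + ground truth
famvar all --in data/ --out results/            # every analysis stage
# or stage by stage:
famvar relatedness   --vcf data/cohort.vcf --ped data/cohort.ped --map data/genetic_map.tsv --out results/rel
famvar prioritize-snv --vcf data/cohort.vcf --ped data/cohort.ped --genes data/genes.bed --pon data/pon.tsv --out results/snv
famvar prioritize-sv  --sv-vcf data/svs.vcf --ped data/cohort.ped --genes data/genes.bed --catalogue data/sv_catalogue.tsv --out results/sv
famvar locus-scan    --vcf data/cohort.vcf --genes data/genes.bed --symbols GENE1,GENE2 --out results/scan
famvar compare       --patients data/patients.tsv --out results/cmp
famvar report        --funnel results/snv/funnel.tsv --out results/funnel.md
```

Every subcommand writes a `manifest.json` with the tool version, seed,
config snapshot, SHA-256 digests of its inputs, stage counts and timings.
Thresholds (population AF cutoff, CADD tiers, predictor consensus, exon
padding, locus flank, SV gap, IBD minimum length...) live in a YAML config
(`famvar.io_formats.RunConfig`); flags override config values.

## Design notes

- Coordinates are 1-based inclusive (VCF convention); BED input is converted
  on read. Multiallelic records are decomposed and parsimony-trimmed before
  any filter logic runs.
- Missing population AF counts as rare (absence from databases is evidence
  of rarity); missing genotypes never count as shared; missing predictor
  calls count against the 3-of-5 consensus.
- The moment kinship estimator is used for close relationships (through
  degree 3); deeper pairs fall back to IBD-segment totals, which retain
  power for the 5th-degree pairs the family designs include.
- SV grouping is a connected-components partition under a breakend-proximity
  relation (CI-expanded windows plus a configurable gap), checked in the
  tests against a brute-force transitive-closure oracle.
- The simulator tracks founder-haplotype labels through every meiosis, so
  planted variants are placed on founder haplotypes that all affected family
  members provably inherit (re-dropping with derived seeds when a sharing
  path does not exist), and emitted genotypes are Mendelian by construction.
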