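# appia

An AODE-based predictor of protein functional associations.

`appia` combines five evolutionary interaction-prediction signals —
phylogenetic profiles (PP), gene-context conservation (GC), gene fusion
(GF, ingested from an external z-score list), mirror tree (MT) and
in silico two-hybrid (I2H) — into a 19-attribute representation per
protein pair (5 method scores, 10 protein-centered rank attributes, 4
protein features) and classifies pairs with an Averaged One-Dependence
Estimators (AODE) model whose missing-value semantics treat absent
evidence as genuinely unknown, never as a flag value.

The package also provides:

* readers/writers for every input format (ortholog tables, GFF3 gene
  coordinates, aligned FASTA, pair lists) and versioned JSON model
  serialization;
* gold-standard construction (positive sources, regulon expansion,
  negative sampling) and the 20%/80% balanced 2/3–1/3 train/test split;
* evaluation: ROC curves, cost curves with exact lower-envelope
  construction, top-n accuracy curves, MCC, and ranking of external pair
  lists by classifier probability;
* a synthetic world generator that plants correlated presence/absence
  profiles, conserved sub-300-bp gene neighborhoods, coupled
  substitution processes and co-varying alignment columns, so the whole
  pipeline is testable offline.

## Command line

```sh
# generate a synthetic input world
appia synth --config world.yaml --out world/

# score pairs with any subset of the five methods
appia score pp gc gf mt i2h \
    --orthologs world/orthologs.tsv --gff-dir world/gff \
    --aln-dir world/aln --gf world/gf.tsv --out scores.tsv

# assemble the 19-attribute feature matrix (rank filter included)
appia features --scores scores.tsv --orthologs world/orthologs.tsv \
    --proteins world/proteins.tsv --out features.tsv

# build the balanced gold-standard split
appia goldstd build --positives world/positives.tsv \
    --features features.tsv --seed 17 --out-dir gold/

# train, predict, evaluate
appia train --features features.tsv --split gold/train.tsv --out model.json
appia predict --model model.json --features features.tsv --out scored.tsv
appia eval roc --scores predictions.tsv --out roc.tsv
appia eval costcurve --scores predictions.tsv --out costcurve.tsv
appia eval topn --scores scored.tsv --gold world/positives.tsv --out topn.tsv

# or run the whole pipeline from one YAML config
appia run --config run.yaml
```

A `run.yaml` names the input files, a seed, an output directory and any
parameter overrides (see `appia.pipeline.RunConfig` /
`appia.pipeline.RunParams`; the defaults carry the published constants:
300 bp gene-context threshold, rank cutoff 100, ≥50 instances per
discretization band, 2/3 training positives, 4 negatives per positive).

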