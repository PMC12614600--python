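# multiprot

Anchor-paired contrastive alignment of multi-modal protein
representations — at desk scale, with no GPUs, downloads, or pretrained
weights.

A protein can be described by its amino-acid sequence, its 3D structure,
a discrete structure-token string, its binding pocket, or free-text
annotations. `multiprot` binds one encoder per modality into a single
unit-sphere latent space by contrastive training on (sequence, other)
pairs only: the sequence modality anchors every batch, and an InfoNCE
loss applied symmetrically in both directions pulls matched pairs
together. Modalities that were never paired with each other during
training still end up aligned through the anchor (*emergent alignment*),
which the evaluation suite measures directly.

Everything runs on synthetic corpora: each generated protein owns a
hidden latent vector from which all its modalities and task labels are
derived, so cross-modal signal exists by construction and every stage of
the pipeline is testable offline.

## What is in the box

| Module | Purpose |
| --- | --- |
| `multiprot.synthetic` | latent-driven corpus generator, MSA-family simulator, identity-threshold splitting |
| `multiprot.io_formats` | FASTA / minimal-PDB / TSV tables / embedding containers |
| `multiprot.corpus_io` | plain-text corpus persistence |
| `multiprot.autodiff` | minimal reverse-mode autodiff on NumPy (all trainable parts run on it) |
| `multiprot.encoders` | transformer (sequence, tokens, text), geometric message-passing GNN (structure, pocket), LoRA adapters, MLM objective |
| `multiprot.heads` | 1D (masked) convolution, attention/mean/cls pooling, projection + L2 normalization |
| `multiprot.alignment` | InfoNCE + symmetric loss, modality pipelines, round-robin anchor-paired training |
| `multiprot.retrieval` | R@k / median-rank evaluation over trained and emergent tasks |
| `multiprot.probing` | frozen-embedding MLP probes; Spearman, ROC AUC, Fmax, per-class AUPR |
| `multiprot.compare` | Wilcoxon rank-sum (exact + approximate), IQR summaries, normalized performance drop, exhaustive modality ablations |
| `multiprot.zero_shot` | Hamming-ranked relatedness groups, cosine-similarity separation, cavity-pair ROC AUC |
| `multiprot.cli` | `multiprot` command-line interface |

## Command-line usage

Every subcommand writes a self-describing run directory (effective
config, log, outputs as TSV).

```bash
multiprot generate --n 200 --d-z 6 --seed 1 --out runs/gen
multiprot train --corpus runs/gen/corpus --out runs/train --steps 500 --seed 1
multiprot eval-retrieval --corpus runs/gen/corpus --model-dir runs/train --out runs/eval
multiprot probe --corpus runs/gen/corpus --model-dir runs/train --out runs/probe
multiprot ablate --corpus runs/gen/corpus --out runs/ablate --optional-modalities structure,tokens
multiprot evolve --model-dir runs/train --out runs/evolve
multiprot pair-auc --corpus runs/gen/corpus --model-dir runs/train --out runs/pair
multiprot report --run runs/eval
```

## Notes

* Training policies per modality: `freeze`, `full`, or `lora`
  (only the low-rank factors update; the base matrix is provably
  untouched). At desk scale there is no pretrained anchor, so the demo
  configuration trains the sequence encoder fully.
* Set `OMP_NUM_THREADS=1` (the test suite and acceptance script do this
  themselves): the workload is many small matrix products, and BLAS
  thread pools only slow it down.
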