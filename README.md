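# rpinet

Prediction of ncRNA–protein interactions from sequence, for computational
biologists studying RNA-binding proteins and long non-coding RNAs.
Experimental mapping of RNA–protein interactions (RPIs) is slow and
expensive; `rpinet` provides a sequence-based classifier that scores a
candidate (RNA, protein) pair with the probability that the two molecules
interact.

## Method

Variable-length sequences are encoded as fixed-length k-mer relative
frequency vectors of the conjoint-triad family. Proteins are rewritten in a
reduced 7-letter alphabet (amino acids grouped by dipole moment and
side-chain volume) and counted over k = 1..3 (7 + 7² + 7³ = 399 features);
RNA uses A,C,G,U with k = 1..4 (340). A structure-augmented variant appends
k-mer blocks over secondary-structure alphabets — three-state H/E/C for
protein, two-state paired/unpaired from dot-bracket strings for RNA —
giving 438/370 features.

Each pair is scored by four **basic modules**, two network architectures ×
two codings:

* **CNN modules** (`Conjoint-CNN`, `Conjoint-Struct-CNN`): per-molecule
  branches Conv-45-64-45 (1-D, kernel 6, max-pool 2 between convolutions,
  batch-norm + ReLU) → Dense-128 embedding;
* **SAE modules** (`Conjoint-SAE`, `Conjoint-Struct-SAE`): per-molecule
  Dense-256-128-64 stacked auto-encoder branches, greedily pretrained
  layer-wise on reconstruction error, then fine-tuned.

Branch embeddings are concatenated into a Dense-128-64-2 softmax head
trained on binary cross-entropy with an Adam→SGD schedule and
best-checkpoint early stopping on training accuracy. An **ensemble head**
(Dense-16-8-2) combines the four modules' probability outputs, with the
basic modules frozen. Performance is reported as Acc, Sn, Sp, Pre, MCC and
AUC under stratified five-fold cross-validation.

Balanced training sets are constructed by randomly re-pairing the RNAs and
proteins of the observed interactions and discarding any candidate (R1, P1)
for which a known interaction (R2, P2) exists with identity(R1,R2) ≥ 80%
and identity(P1,P2) ≥ 40% (global-alignment matches over the shorter
sequence).

A seeded synthetic-data generator with a planted motif-conjunction rule
(positive ⇔ RNA motif present ∧ protein motif present) makes the whole
pipeline testable without downloading any benchmark. See
`docs/methods.md` for conventions, defaults and limitations.

## Worked example

```python
import rpinet as rp

config = rp.SyntheticConfig(n_rna=60, n_protein=60, n_positive=120,
                            rna_length_range=(50, 150),
                            protein_length_range=(50, 150), seed=42)
dataset = rp.simulate_dataset_with_structures(config)
print(f"{len(dataset.pairs)} pairs over {len(dataset.rnas)} RNAs x "
      f"{len(dataset.proteins)} proteins")

result = rp.cross_validate(dataset, rp.ModuleConfig.quick(seed=0), k=5, seed=0)
print(result.summary().round(3))
```

Output:

```
240 pairs over 60 RNAs x 60 proteins
        acc     sn     sp    pre    mcc    auc
fold
0     0.833  0.917  0.750  0.786  0.676  0.913
1     0.896  0.917  0.875  0.880  0.792  0.970
2     0.812  0.958  0.667  0.742  0.653  0.844
3     0.938  0.958  0.917  0.920  0.876  0.979
4     0.875  0.875  0.875  0.875  0.750  0.951
mean  0.871  0.925  0.817  0.841  0.750  0.932
sd    0.050  0.035  0.105  0.074  0.090  0.055
```

Each fold row is the held-out fold's metrics: `acc` is the fraction of
pairs classified correctly at threshold 0.5, `sn`/`sp` the true-positive
and true-negative rates, `pre` the precision, `mcc` the Matthews
correlation (0 = chance, 1 = perfect), and `auc` the area under the ROC
curve. The planted rule is recovered well (mean AUC 0.93) from only 192
training pairs per fold; larger datasets push these toward 1 (the
2000-pair benchmark below reaches mean acc ≈ 0.98, AUC ≈ 1.0).

The same pipeline runs from the shell:

```bash
rpinet simulate --out data/ --n-positive 120 --n-rna 60 --n-protein 60 --seed 42
rpinet cv --rna-fasta data/rna.fasta --protein-fasta data/protein.fasta \
          --pairs data/pairs.tsv --rna-structs data/rna_struct.fasta \
          --protein-structs data/protein_struct.fasta \
          --k 5 --seed 0 --out report.tsv
rpinet train --rna-fasta data/rna.fasta --protein-fasta data/protein.fasta \
             --pairs data/pairs.tsv --rna-structs data/rna_struct.fasta \
             --protein-structs data/protein_struct.fasta --out model/
rpinet predict --model model/ --rna-fasta data/rna.fasta \
               --protein-fasta data/protein.fasta --pairs data/pairs.tsv \
               --rna-structs data/rna_struct.fasta \
               --protein-structs data/protein_struct.fasta --out scores.tsv
```

`rpinet encode` writes feature matrices, and `rpinet negatives` generates
identity-filtered negative pairs for positive-only pair tables.

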