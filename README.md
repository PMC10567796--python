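# cmkn — position-aware motif kernel networks

`cmkn` is a sequence-classification toolkit built around a *position-aware
motif kernel*: a product kernel that compares short sequence motifs
(encoded as normalized position frequency matrices, nPFMs) together with
their positions, the latter mapped onto the upper half of the unit circle.
A Nyström projection onto a small, learnable set of motif–position anchor
points turns the kernel into the first layer of a neural network that is
trainable end-to-end with plain gradient descent — and, because the head
is strictly linear, directly interpretable:

* **global interpretation** — per-position, per-class importance scores
  obtained by a backward recursion over positive-weight edges, sliding-window
  peak detection, and class-associated weighted mean motifs;
* **local interpretation** — per-input explanations that rank the class
  mean motifs at selected positions by the ℓ2-norm of their
  position-smoothed *motif functions* evaluated on the input.

The network (kernel layer → linear hidden layer → linear output layer),
its training loop (Adam, binary cross-entropy with logits, anchor
constraint projection after every step) and the evaluation metrics are
implemented in NumPy; no deep-learning framework is required.

## Layout

| module | contents |
|---|---|
| `cmkn.seq_io` | alphabets (DNA/protein + ambiguity codes), one-hot encoding, FASTA/label-TSV I/O, position → unit-circle mapping |
| `cmkn.pam_kernel` | nPFM type, position/motif comparison kernels, product kernel `k0`, sequence-level kernel `k_pam` |
| `cmkn.nystrom_layer` | anchor sets, k-means++ initialization, constraint projection, Gram inverse square root, window projection / per-sequence feature maps |
| `cmkn.cmkn_model` | model config, training, prediction, metrics (accuracy/F1/MCC/auROC/auPRC), stratified CV harness, JSON model archive |
| `cmkn.interpretation` | importance recursion, peak detection, class mean motifs, motif-function norms, local explanations |
| `cmkn.synthetic_data` | deterministic generator for the two-class planted-motif DNA benchmark |

## CLI

```bash
# generate the synthetic benchmark (FASTA + label TSV)
cmkn synth --n 1000 --length 100 --seed 0 --out data.fasta --labels data.tsv

# train (beta "auto" = L^2/10)
cmkn train --fasta data.fasta --labels data.tsv --alphabet dna \
    --k 5 --sigma 4 --alpha 1 --beta 1000 --anchors 50 --hidden 200 \
    --epochs 50 --seed 0 --out model.json

# evaluate / cross-validate
cmkn eval --model model.json --fasta data.fasta --labels data.tsv --report report.json
cmkn cv --fasta data.fasta --labels data.tsv --folds 5 --epochs 10 --report cv.json

# interpretation: per-position importances, peaks with top residues,
# and (with --fasta) per-input local explanations
cmkn interpret --model model.json --top 10 --window 11 --fasta data.fasta --out interp

# small dense Gram matrices (testing aid)
cmkn gram --fasta small.fasta --k 3 --beta 14.4 --sigma 2 --out gram.tsv
```

## Notes

* The motif-function expression used for local interpretation is a
  documented reconstruction: the product of the motif match score with the
  positional smoothing kernel, evaluated on the integer position grid. It
  reduces to the classical oligo function for one-hot motifs and exact
  matches; only the rank order of the norms is used downstream.
* Windows are left-aligned (`p = 1 … L − k + 1`); a window's circle
  position is that of its start.
* `K_ZZ^{-1/2}` is recomputed from the current anchors at every optimizer
  step and treated as a constant within the step (stop-gradient).
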