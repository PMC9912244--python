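# Methods

## Scope and model overview

`cas13guide` models the two guide-intrinsic determinants of CRISPR-Cas13d
(CasRx) screening behaviour: **on-target efficiency** — how strongly a
guide depletes when its target matters for proliferation — and the
**off-target viability effect** — efficiency-coupled depletion observed
even for guides targeting non-essential genes, attributed to collateral
RNA cleavage by the activated nuclease. Around these sit the supporting
stages of a proliferation-screen analysis: guide design, count
normalization under explicit negative-control choices, a calibrated
gene-level negative-selection test, and attribution of the trained
model's predictions back to sequence positions.

## Target normalization

Raw guide log2 fold changes (LFC; negative = depleted) are squashed into
(0, 1) by a customized sigmoid

    S(x) = 1 / (1 + exp(-n·x + b)),

with (n, b) solved exactly from two calibration constraints, by default
S(0) = 0.3 and S(−0.3) = 0.7 (closed form: b = ln(7/3) ≈ 0.8473,
n = −2b/0.3 ≈ −5.6487). The constraints place the bulk of the observed
LFC distribution ([−0.3, 0]) over a wide stretch of the target range
while pushing effective guides (LFC ≤ −0.5) close to 1. S is a strictly
decreasing bijection onto (0, 1) and symmetric about its midpoint
(−0.15, 0.5). Binary "effective guide" labels use LFC ≤ −0.5; the
boundary is inclusive and configurable.

## Secondary structure

Guides are folded as naked spacers (the direct repeat is excluded from
the model's structure channel; DR+spacer folding is exposed separately
as the "crRNA energy" feature). Two engines implement one interface:

* **thermo** — ViennaRNA's minimum-free-energy model (kcal/mol),
  the default when the `RNA` bindings are importable;
* **maxpair** — a Nussinov-style maximum base-pairing folder
  (Watson-Crick + G·U, hairpin loop ≥ 3) with deterministic traceback
  (leftmost base pairs with its largest optimum-achieving partner) and
  energy proxy −1·pair_count. It exists so every pipeline runs with no
  external dependency and is verified against exhaustive enumeration of
  all nested structures on sequences up to 12 nt.

The minimum hairpin loop of 3 is the standard steric constraint; the
G·U wobble is standard RNA pairing.

## Guide encoding

Each guide becomes an L×4 one-hot sequence matrix (A, C, G, U) and an
L×3 one-hot dot-bracket matrix ('.', '(', ')'), right-padded with
all-zero rows to the model length L (default 30, accommodating both
22-nt and 27-nt libraries) plus a binary validity mask. The 3-symbol
structure alphabet (rather than a 2-state paired/unpaired flag) keeps
pairing directionality. Encoding round-trips exactly.

## The efficiency network

Two parallel branches (sequence, structure), each:

    conv(k=4) → batch-norm → ReLU
    conv(k=4) → batch-norm → ReLU
    dropout 0.5 → mask → max-pool(2) → LSTM → dropout 0.3 → dense

Branch embeddings are concatenated, passed through one fully connected
layer, and a single sigmoid unit emits the deep score in [0, 1]
(higher = predicted more effective). Training minimizes MSE against the
sigmoid-normalized LFC. Convolutions run along the sequence axis with
the one-hot channels as input channels — the (4, full-width) 2-D kernel
written as a 1-D operation. Padded positions are zeroed before pooling
so mixed guide lengths do not leak padding into the recurrent stage.

Defaults: 32 filters, kernel 4, 64 LSTM units, 64 dense units, Adam at
1e-3, batch 64, 100 epochs. Only the topology and the two dropout rates
(50% convolutional, 30% recurrent) are treated as fixed; all sizes are
configurable, and an exhaustive grid search over dense units, dropout,
optimizer and learning rate (selection by held-out MSE) is provided.

The network is implemented directly on a small reverse-mode automatic
differentiation core over numpy (float64, seeded, bit-reproducible on a
device): conv/pool/LSTM/batch-norm forward passes with exact gradients,
verified against central finite differences. The model is < 1 M
parameters and trains on CPU; exact input gradients are what the
Integrated-Gradients attribution differentiates.

## Curated features and baselines

The classical comparison and the off-target model use a fixed, ordered
set of exactly 185 curated features: 120 per-position nucleotide
indicators (30 positions × 4), 16 dinucleotide and 4 mononucleotide
frequencies, composition summaries (GC content, GC of positions 15–23,
terminal 4-mer GC at both ends, longest homopolymer, length), energy
terms ("Energy" = spacer MFE; "crRNA energy" = DR+spacer MFE), structure
summaries (paired fraction, 30 per-position paired flags, stem count,
longest stem) and 4 target-region indicators (CDS/UTR5/UTR3/noncoding).
The name order is canonical and pinned by a checksum; extraction is a
pure function of (spacer, fold, crRNA energy, region). Baselines (RF,
XGBoost, SVM, AdaBoost, GBM) use library defaults with a fixed seed —
no per-method tuning.

## Off-target viability model

Among guides targeting non-essential genes, the lowest quartile by LFC
(inclusive boundary, ties broken by guide id) is labelled
"strong depletion" and contrasted against the rest with a 500-tree
random forest over the 185 features; importances are normalized to sum
to 1. An on-target comparison model is built symmetrically from
essential-gene guides (same quantile). The Pearson correlation between
the two importance vectors is the package-level statement of the
finding that off-target viability effects track on-target activity.

## Screen analysis

Size factors are classic median-ratio (DESeq-style) computed on the
chosen control subset: all guides ("none"), non-targeting guides, or
non-essential-target guides. Guide LFC is log2((mean t1 + 1)/(mean t0
+ 1)). Gene-level negative selection is deliberately lighter than robust
rank aggregation: the gene score is the mean rank of its guides' LFCs
(ascending over all supplied guides), and the p-value is the lower-tail
probability of that score under seeded resampling of same-sized rank
sets from a null pool, with the +1 correction (so p ≥ 1/(n_perm+1));
FDR is Benjamini–Hochberg. The null pool is the chosen control set —
all guides when no controls are used. Because a per-sample size factor
shifts every LFC equally, the control choice acts on this rank test
through the null pool (in MAGeCK it additionally acts through the
normalization); the benchmark therefore isolates the statistical role
of the control population. Under exchangeable LFCs the p-values are
uniform (KS-tested across seeds) and valid (P(p ≤ α) ≤ α + Monte-Carlo
tolerance).

The control benchmark sweeps FDR cutoffs and reports the true positive
rate on known essential genes and the false positive rate on known
non-essential genes for each control choice.

## Synthetic screens

The generator emulates the tiling proliferation-screen design: 60 genes
× 30 uniform-random 22-nt guides by default, half essential, plus 100
non-targeting guides. Planted efficiency is

    eff = logistic( 4.0·(2·CG(15–23) − 1) + 1.5·(MFE/5 + 1) )

so C/G enrichment in the central window and an open fold raise
efficiency. The weights were calibrated once so that ranking guides by
true efficiency separates effective from ineffective guides at the
level real tiling screens exhibit (oracle AUC ≈ 0.9 against LFC ≤ −0.5
labels); they are the generator's defining condition, not a tuning
knob. Expected LFC is −2.0·eff for essential targets plus an
off-target term −0.3·eff applied to *every targeting* guide (collateral
cleavage requires an activated, target-bound nuclease, so non-targeting
guides sit at 0), plus Gaussian guide-level noise (sd 0.3, the scale of
replicate scatter in deep screens). Start counts are multinomial at
depth 10⁶ (≈ 500 reads/guide) from a mildly skewed (log-normal σ=0.3)
library; end counts are negative binomial around t0·2^LFC with
dispersion 0.1. End-point columns are not rescaled to the nominal
depth, so realized LFCs track the planted values and composition
effects enter through the normalization step where they belong.

What the generator does **not** emulate: real sequence composition
biases, position-dependent mismatch tolerance, transcript abundance and
accessibility effects, PCR amplification bias, or mechanistic
collateral cleavage. Passing tests therefore demonstrate that the
pipeline recovers the signals it is built to recover under the stated
model of the data, not performance on any real screen. Benchmarking
against real tiling-screen datasets requires downloading deposited
screen data and is deliberately outside the test surface.

## Interpretation

Integrated Gradients uses the all-zero encoding ("no sequence") as the
baseline and a right-Riemann path approximation; the completeness
residual |ΣIG − (F(x) − F(x'))| is recorded on every map and falls
below 1% of the score difference at 256 steps. Attribution is computed
on the bounded output (the reported score space); padded positions get
exactly zero attribution. Position/nucleotide preference summaries
average, per position, the attribution of the observed nucleotide
across guides.

## Problem sizes and numerical choices

Simulation-based checks run at desk scale by design: 2 010 guides for
the cross-validated recovery check (5-fold, 30 epochs), 40-gene screens
for the importance-consistency analysis (coupling 0.5 — a condition
under which the collateral effect is detectable from a few hundred
guides, mirroring the regime in which it was originally measured), the
default 60-gene screen for the control benchmark, and 1 000–2 000
permutations for gene tests. Sigmoid solving is closed-form with a
1e-10 residual guard; AUC uses the midrank convention for ties;
undefined metrics (single-class AUC, zero-variance correlations) are
reported as NaN or raised, never silently 0.

## Known limitations

* The fallback folder maximizes pair count, not free energy; its
  energies are proxies on a different scale from ViennaRNA's.
* The uniqueness screen in guide design scans only the supplied
  transcript set (Hamming distance ≤ 1, both strands), not a genome
  index.
* The gene test is a calibrated mean-rank permutation test, not robust
  rank aggregation; it shares MAGeCK's intent but not its statistic.
* Model weights are not interchangeable with any published tool's
  weights; scores agree in meaning (bounded efficiency), not in value.
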