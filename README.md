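# chromnmf

Combinatorial chromatin-profile discovery from multi-mark ChIP-seq and
DNase-seq signal by consensus non-negative matrix factorization.

Histone modifications, transcription-factor occupancy and chromatin
accessibility do not act as isolated signals: recurrent *combinations* of
marks demarcate promoters, enhancers, transcribed gene bodies and repressed
domains. `chromnmf` turns read alignments for a panel of epigenetic marks
into a bins-by-marks signal matrix and decomposes it into a small number of
additive chromatin profiles, the soft analogue of chromatin states. It is a
library first (importable API plus the short scripts in `examples/`), with a
thin `chromnmf` command-line wrapper for running stages from a shell.

## Model

1. **Binned fold-enrichment.** The genome is tiled into 200-bp bins. For
   replicate *i* of mark *k*, the observed count R(j,k,i) in bin *j* is
   compared with the count expected under uniform placement over the
   uniquely mappable genome, E(j,k,i) = C(i)·M(j)/G. Replicates are pooled:
   S(j,k) = Σᵢ R / Σᵢ E.
2. **Negative-binomial background.** Per mark, coverage is modelled as a
   Poisson–Gamma mixture: a Gamma(β, α) distributed Poisson rate gives
   P(N = n) = C(n+β−1, n) (α/(α+1))ⁿ (1/(α+1))^β with mean αβ. β is the
   gamma-shape MLE on positive coverage, and α = μ/β anchors the mean to the
   genome-wide mean coverage μ. Bins where at least one mark beats the 1%
   upper-tail threshold form the significant-bin matrix Vˢ.
3. **Sigmoid scaling.** Each mark is compressed into [0, 1) by
   X′ = 2/(1 + e^(−2x/y)) − 1 with y its 95th percentile, so the transform is
   near-linear below y (X′(y) = tanh 1) and saturates above it.
4. **Consensus NMF.** Vˢ ≈ W H with W (bins × r) the profile weights per bin
   and H (r × marks) the mark composition of each profile, fitted by
   Lee–Seung multiplicative updates for the generalized Kullback–Leibler
   divergence from random uniform starts. Stability over restarts is
   summarized by the consensus of mark connectivity matrices (marks sharing
   their strongest profile) and its cophenetic correlation; the rank r* is
   the smallest r whose real-data stability exceeds the stability of
   column-permuted null matrices by four standard deviations, here and at
   r+1.
5. **Profiles downstream.** Each bin takes the argmax profile of its W row;
   relative weight contributions (RWC = weight / row max) quantify ambiguous
   bins; profiles are evaluated by 2×2 fold-enrichment (ad/bc with one-tail
   Fisher exact p) against annotations, TSS distance distributions, ROC
   recovery of features, transition enrichment along the genome and
   expression-stratified frequency maps.

A fully parameterized synthetic-data generator (`chromnmf.simulate`) plants
profile regions with negative-binomial noise on a toy genome, emits reads,
annotations and an expression table tied to the same ground truth, and is
the basis of the test suite.

## Worked example

`python examples/01_simulate_and_factorize.py` simulates a 6,000-bin
13-mark matrix, filters it against the NB background, rescales it and
factorizes at rank 7:

```
simulated 6000 bins x 13 marks (4794 signal bins planted)
significant bins at the 1% NB tail: 1688
rank-7 factorization: KL loss 271.0, cophenetic stability 0.979

profile -> strongest marks (coefficient matrix H):
  profile 1: CTCF (0.37), H2A.Z (0.18), DNaseHS (0.17)
  profile 2: H3K27me3 (0.51), H3K4me3 (0.14), Pol2 (0.03)
  profile 3: H3K36me3 (0.41), H3K79me1 (0.30), H3K4me2 (0.02)
  profile 4: H3K4me2 (0.24), H3K4me3 (0.21), H2A.Z (0.20)
  profile 5: H3K9me3 (0.56), Pol2 (0.04), H3K4me2 (0.02)
  profile 6: Pol2 (0.31), DNaseHS (0.24), H3K27ac (0.24)
  profile 7: H3K4me1 (0.38), H3K27ac (0.18), H3K9ac (0.15)
```

Each recovered profile is a recognizable chromatin signature: profile 6 is
the active-promoter combination (Pol2 + open chromatin + H3K27ac), profile 4
transcription initiation (H3K4me2/3 + H2A.Z), profile 3 the transcribed
gene body, profiles 2 and 5 the polycomb and heterochromatin repressed
states, profile 1 the CTCF-bound regulatory class and profile 7 the H3K4me1
enhancer class. The cophenetic stability of 0.979 says the ten restarts
almost always agreed on this mark clustering. The other examples
cover rank selection against the permuted null, coverage from BED reads,
annotation enrichment with ROC recovery, and expression-stratified patterns
with transition enrichment.

## Command line

```
chromnmf simulate --preset paper13 --bins 20000 --seed 1 --out sim/
chromnmf coverage --reads H3K4me3=sim/H3K4me3.bed --chrom-sizes sim/chrom.sizes --out matrix.tsv
chromnmf filter --matrix matrix.tsv --tail 0.01 --out-prefix run
chromnmf transform --matrix run.filtered.tsv --out run.transformed.tsv
chromnmf select-rank --matrix run.transformed.tsv --ranks 3:13 --runs 30 --out rank.json
chromnmf factorize --matrix run.transformed.tsv --rank 7 --out-prefix fit
chromnmf assign --w fit.W.tsv --matrix run.transformed.tsv --out profiles.bed
```

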