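# pbhmda — path-based microbe–disease association prediction

`pbhmda` implements PBHMDA, a path-based model for prioritising candidate
microbe–disease associations from a curated catalogue of known ones (an
HMDAD-style two-column list). Human microbiome surveys keep linking
microbial taxa to diseases — gut dysbiosis to cirrhosis, airway communities
to asthma — but the catalogue of confirmed associations is small and
expensive to grow. Under the guilt-by-association premise (microbes involved
in phenotypically similar diseases tend to be functionally similar), a
predictor can rank the untested pairs so that experimental effort goes to
the most promising candidates.

## Model

Let **Y** be the binary `nm × nd` adjacency matrix over microbes and
diseases. The model uses only Y:

1. **Gaussian interaction profile (GIP) kernel similarity.** Each disease's
   interaction profile IP(d) is its column of Y; each microbe's is its row.
   Similarities are

   KD(dᵢ,dⱼ) = exp(−γ_d‖IP(dᵢ)−IP(dⱼ)‖²),  γ_d = γ′_d / ( (1/n_d)·Σᵢ‖IP(dᵢ)‖² ),

   and symmetrically KM for microbes (γ′ = 1 by default).

2. **Heterogeneous network.** One undirected weighted graph with
   microbe–disease edges (weight 1 where Y = 1), microbe–microbe edges (KM)
   and disease–disease edges (KD); similarity edges below a threshold T are
   dropped (default T = 0 keeps all).

3. **Path scoring.** For each pair, every cycle-free path p of at most L
   edges (default 3) found by depth-first search contributes

   S(p) = ( Π_e w_e(p) )^(α·len(p)),

   with decay coefficient α (default 2.26), and the pair's total score is
   TS(m,d) = Σ S(p). Short paths through heavy edges dominate; candidate
   pairs are ranked by TS.

Evaluation ships as the three standard protocols — global LOOCV (each known
pair held out and ranked against all unverified pairs), local LOOCV (ranked
within its own disease) and repeated 5-fold CV — all of which recompute the
kernels, network and scores from the reduced matrix each round, so held-out
information never leaks into its own test.

## Worked example

Simulate a small planted-community catalogue, score it, and cross-validate:

```sh
$ pbhmda simulate --preset block --seed 7 --n-microbes 12 --n-diseases 4 --n-blocks 2 -o toy.tsv
INFO pbhmda: simulated 12 x 4 matrix with 15 associations

$ pbhmda predict -i toy.tsv -o scores.tsv
INFO pbhmda: loaded 12 microbes x 4 diseases, 15 known associations
INFO pbhmda: effective config: L=3 alpha=2.26 T=0 gamma'_m=1 gamma'_d=1
INFO pbhmda: scored 48 pairs in 0.00s

$ head -9 scores.tsv
# L = 3
# T = 0.0
# alpha = 2.26
# gamma_prime_d = 1.0
# gamma_prime_m = 1.0
disease	microbe	score	rank
d001	m0009	2.03131972866	1
d001	m0011	2.03131972866	2
d001	m0007	1.06501459902	3
```

Each row is a candidate pair with its aggregated path score TS and its rank
within the disease (`--global-rank` ranks across all diseases instead).
Here `m0009` already has a known edge to `d001` (its direct length-1 path
contributes score 1; known pairs are scored like any other and excluded from
candidate sets only during evaluation), and the extra ≈1.03 comes from
indirect paths through similar microbes and diseases.

```sh
$ pbhmda loocv --mode global -i toy.tsv -o report.json
INFO pbhmda: global_loocv: AUC=0.6939 over 15 rounds in 0.00s
```

The JSON report carries the AUC, the ROC points, per-round rank records and
the effective configuration. `pbhmda kfold --k 5 --repeats 100 --seed 1 …`
runs repeated 5-fold CV the same way. On realistic problem sizes (hundreds
of microbes) the planted signal is strong and AUCs reach ≈0.9; a 12×4 toy
like this is at the edge of what profile-based similarity can resolve.

Everything is also available as a library:

```python
from pbhmda import BlockModelSpec, generate_block_associations, global_loocv
Y = generate_block_associations(BlockModelSpec(seed=1))
print(global_loocv(Y).auc)
```

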