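# topsel — target-oriented prioritization for multi-trait genomic selection

Breeders rarely want the best individual for one trait; they want the
candidate whose whole trait profile is closest to an ideotype — a commercial
check variety, or that variety with flowering time pulled 5% earlier.
Truncation tools (independent culling, linear selection indices) degrade
quickly as the number of jointly considered traits grows, because they chase
a corner of phenotype space that antagonistic trait correlations leave almost
empty.  `topsel` implements **target-oriented prioritization (TOP)**: learn,
on a training population with both observed and genomically predicted
phenotypes, how much each trait should count in a similarity measure, then
rank selection candidates by that similarity to the target profile.

## The model

Candidates are compared through a softmax similarity over weighted L1
distances.  For a target profile *Y* and candidate *n* with genomically
predicted profile *Ŷ*ⁿ over *d* traits,

    P(Y, Ŷⁿ) = exp(−Σᵢ wᵢ |Yᵢ − Ŷᵢⁿ|) / Σₘ exp(−Σᵢ wᵢ |Yᵢ − Ŷᵢᵐ|),

normalised over the candidate pool.  The weights *w* are learned by
maximising the self-identification likelihood L(w) = Πₙ P(Yⁿ, Ŷⁿ) on a
training set where each individual's observed profile should single out its
own prediction among all candidates — traits that are predicted well and
discriminate individuals earn large weights, noisy traits earn small (or
negative) ones.  Optimisation is quasi-Newton (BFGS with Armijo backtracking,
analytic gradient, start at w = 1, stop at ‖g‖ < 10⁻⁶).

Predictions come from single-trait **GBLUP**: y = Xb + μ + ε with
μ ~ N(0, K σ²_g), K the centred-crossproduct genomic relationship matrix,
variance components by REML (profile likelihood over h² after one
eigendecomposition of K), and genetic values of unphenotyped individuals via
μ̂ = σ²_g K_{new,train} V⁻¹ (y − Xb).

Around the core the package provides: an NCII factorial-cross simulator
(inbred parents, F1 dosage = parental mean, multi-trait phenotypes with
target heritabilities and genetic correlations, genetically coupled omics
layers, diagonal-strip training designs), PCA composition of omics layers
into traits with accuracy/weight filtering, the pool-based
identification-rate protocol with its 1/N₀ chance baseline, ideotype
construction and scoring, and the two classical comparators (independent
culling; desired-gains index b = P⁻¹G*[G*ᵀP⁻¹G*]⁻¹Q with Smith–Hazel
economic values a = G⁻¹Pb).

## Worked example

Simulate a 60 × 15 NCII population (900 hybrids, 6 traits with h² from 0.3
to 0.8), train on three diagonal strips of the mating grid, learn trait
weights on 10-fold self-predictions, and measure identification rates on the
720 testing hybrids:

```python
import numpy as np
from topsel import SimulationConfig, run_ncii_study, pool_sweep

config = SimulationConfig(n_maternal=60, n_paternal=15, n_markers=500,
                          n_qtl=100, h2=np.linspace(0.3, 0.8, 6), seed=7)
study = run_ncii_study(config, seed=7)
print(study.top_results.summary())

tp = study.testing_predictions
report = pool_sweep(tp.observed, tp.predicted, study.weights,
                    [20, 50, 100], n_pools=100, seed=7, ids=tp.individual_ids)
print(report.to_frame().to_string(index=False))
```

```
Target-oriented prioritization (softmax similarity, weighted L1)
training individuals: 180   traits: 6
neg. log-likelihood: 712.169565   converged: True (18 iterations, ||g|| = 7.32e-07)
  trait  weight  accuracy_r
trait01  0.0205      0.1349
trait02  0.0972      0.4181
trait03  0.1000      0.5265
trait04  0.1182      0.5209
trait05  0.1591      0.7530
trait06  0.2555      0.8341
 pool_size  identification_rate  random_baseline  improvement
        20               0.4055             0.05         8.11
        50               0.2550             0.02        12.75
       100               0.1631             0.01        16.31
```

The learned weights track prediction accuracy (trait06, h² = 0.8, r = 0.83,
gets 12× the weight of the nearly unpredictable trait01), and the
identification rate — the fraction of pool trials in which the true target
individual ranks first — beats random identification 8-fold in pools of 20
and 16-fold in pools of 100.

The same stages are scriptable from the shell:

```bash
topsel simulate --seed 3 --out-dir sim/
topsel predict  --genotypes sim/hybrid_genotypes.csv --phenotypes sim/phenotypes.csv \
                --train sim/train_ids.txt --kfold 10 --seed 5 --out pred.csv
topsel train-top --predictions pred.csv --out weights.json
topsel identify  --weights weights.json --candidates pred.testing.csv \
                 --target-base check.csv --modify DTT=0.95 --top-k 100 --out rank.tsv
topsel evaluate  --predictions pred.testing.csv --weights weights.json \
                 --pool-sizes 20,50,100,200 --n-pools 200 --seed 7 --out report.json
topsel compare   --predictions pred.testing.csv --weights weights.json \
                 --index-q q.yaml --top-n 100 --out compare.json
```

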