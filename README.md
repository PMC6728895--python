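# catlasso

**LASSO-based item-trait pattern detection for replenished items in
multidimensional computerized adaptive testing (MCAT).**

When an operational adaptive test pool is replenished with new, uncalibrated
items, each new item must be assigned an *item-trait pattern*: the subset of
the K latent traits it actually measures (a row of the test's Q-matrix).
Misspecifying the pattern propagates into item calibration and examinee
scoring. `catlasso` detects these patterns from the pretest data an MCAT
administration produces anyway, and ships the full simulation machinery —
item pools, adaptive administration, evaluation indices — needed to study
the method's operating characteristics.

## The model and the method

Responses follow the compensatory multidimensional two-parameter logistic
model (M2PLM): examinee *i* answers item *j* correctly with probability

```
P(Y_ij = 1 | θ_i, a_j, b_j) = exp(a_j'θ_i + b_j) / (1 + exp(a_j'θ_i + b_j))
```

with trait vector θ_i ∈ R^K, discrimination vector a_j ≥ 0 entrywise on its
support, and intercept b_j. The item-trait pattern Q_j is the 0/1 support of
a_j.

Detection proceeds in three steps:

1. **Collect.** N examinees take the adaptive test: Z0 operational items
   chosen by D-optimality (`argmax det(I_S(θ̂) + I_i(θ̂))`) or Bayesian
   A-optimality (`argmin trace[(I_S(θ̂) + I_i(θ̂) + Σ0⁻¹)⁻¹]`), scored by MAP
   after every response; each examinee also answers Z1 replenished items,
   whose responses never enter θ̂. With the default group design each
   replenished item collects n = 400 responses.
2. **Fit the penalized path.** For each replenished item with responses Y
   and respondent scores Θ̂, solve for every λ on the grid
   {T/W, 2T/W, …, T} (default T=120, W=80):

   ```
   min_{b, a}  −ℓ(b, a; Y, Θ̂) + λ Σ_k |a_k|
   ```

   by cyclical coordinate descent with an unpenalized intercept. The
   support of â(λ) is a candidate pattern.
3. **Select by BIC.** Each candidate pattern is scored with
   BIC = −2ℓ̂ + df·log n evaluated at the relaxed (unpenalized) refit of
   its support, df = |support| + 1; the pattern combination minimizing the
   summed BIC across the item group is selected, and final item parameters
   are refit restricted to the detected supports.

## Worked example

```bash
python examples/01_detect_patterns.py
```

builds three synthetic items (true patterns `(1,0)`, `(0,1)`, `(1,1)`),
simulates 400 responses each, and detects:

```
item  true Q   detected Q   lambda*   refit a            refit b
   0  (1, 0)   (1, 0)         73.5   ( 1.366,  0.000)    0.265
   1  (0, 1)   (0, 1)         73.5   ( 0.000,  1.260)   -0.352
   2  (1, 1)   (1, 1)         73.5   ( 1.477,  1.301)   -0.144

correct specification rate: 1.000
```

All three supports are recovered exactly (CSR = 1.0), and the relaxed refits
are close to the generating values (a = 1.5, 1.2, and (1.3, 1.4)).
`examples/02_adaptive_test.py` walks one examinee through fixed- and
variable-length adaptive tests; `examples/03_study_replication.py` runs a
reduced end-to-end simulation and prints every evaluation index.

The same pipeline is scriptable from the shell:

```bash
catlasso run --design study1_high --criterion D --stopping fixed:50 \
             --grid 120:80 --replications 5 --seed 20190830 --out results/
catlasso detect --responses responses.csv --scores scores.csv --out patterns.csv
```

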