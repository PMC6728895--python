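"""Detect which latent traits a handful of new items measure.

Builds three synthetic items with known trait patterns, simulates 400
binary responses per item at known 2-D abilities, runs the penalized
logistic path (T=120, W=80) with BIC pattern selection, and prints the
detected patterns next to the truth together with the relaxed parameter
refits.
"""

import warnings

import numpy as np
from scipy.special import expit

from catlasso import csr, detect_patterns, lambda_grid

warnings.filterwarnings("ignore", category=RuntimeWarning)

rng = np.random.default_rng(7)
n, K = 400, 2

# (discrimination vector, intercept): supports are the item-trait patterns
items = [
    (np.array([1.5, 0.0]), 0.3),   # measures trait 1 only
    (np.array([0.0, 1.2]), -0.4),  # measures trait 2 only
    (np.array([1.3, 1.4]), 0.0),   # measures both traits
]

theta = rng.standard_normal((n, K))          # known ability scores
responses, scores = [], []
for a, b in items:
    p = expit(theta @ a + b)
    responses.append((rng.random(n) < p).astype(int))
    scores.append(theta)

result = detect_patterns(responses, scores, lambda_grid(T=120, W=80))

Q_true = np.array([(a != 0).astype(int) for a, _ in items])
print("item  true Q   detected Q   lambda*   refit a            refit b")
for j, (a, b) in enumerate(items):
    print(
        f"{j:4d}  {tuple(int(q) for q in Q_true[j])}   "
        f"{tuple(int(q) for q in result.patterns[j])}     "
        f"{result.selected_lambdas[j]:6.1f}   "
        f"({result.a_refit[j][0]: .3f}, {result.a_refit[j][1]: .3f})   "
        f"{result.b_refit[j]: .3f}"
    )
print(f"\ncorrect specification rate: {csr(Q_true, result.patterns):.3f}")
print("A detected 1 marks a trait the BIC-optimal penalized fit keeps;")
print("the refits are unpenalized estimates restricted to that support.")
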