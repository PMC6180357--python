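"""Train the simplified fixed Hessian (SFH) model on synthetic data and
compare it with the exact maximum-likelihood fit.

The SFH method replaces the Newton-Raphson Hessian with a fixed diagonal
lower bound and linearises the sigmoid, so a single iteration is a shallow
arithmetic circuit.  The AUC gap against IRLS shows what those
approximations cost.
"""

import numpy as np

from sfhlogit import (
    draw_beta,
    gen_synthetic,
    irls_reference,
    roc_auc,
    score_dataset,
    sfh_train,
    train_test_split,
)

rng = np.random.default_rng(3)
beta_true = draw_beta(31, rng, scale=2.5)
data = gen_synthetic(6000, 31, "continuous", beta_true, seed=3)
train, test = train_test_split(data, 1000)

m1 = sfh_train(train, iters=1)
m100 = sfh_train(train, iters=100)
mref = irls_reference(train)

for label, model in [("SFH 1 iter", m1), ("SFH 100 iters", m100), ("IRLS", mref)]:
    auc = roc_auc(score_dataset(model, test), test.y).auc
    print(f"{label:14s} AUC = {auc:.4f}")

print(
    "\nThe one-iteration model already ranks most records correctly; more\n"
    "iterations close most of the remaining gap to the exact ML fit."
)
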