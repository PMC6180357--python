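# sfhlogit

Privacy-preserving **training** of binary logistic-regression models on
homomorphically encrypted data.

A hospital consortium or a group of banks wants a pooled risk model —
cancer status from genomic markers, fraud probability from transaction
features — without any party (or the compute server) ever seeing the
records.  `sfhlogit` implements the full pipeline: data owners encode and
encrypt their tables, an untrusted server evaluates one training iteration
as an arithmetic circuit on ciphertexts, and only the model owner decrypts
the resulting coefficients.

## The method

Exact Newton–Raphson maximisation of the logistic log likelihood
ℓ(β) = −Σᵢ log(1 + e^(−yᵢβᵀxᵢ)) is hopeless on encrypted data, so the
**simplified fixed Hessian (SFH)** method applies three simplifications,
each with a guarantee:

- the Hessian is replaced by the constant bound H̄ = −¼XᵀX
  (valid since σ(1−σ) ≤ ¼; convergence by the fixed-Hessian argument);
- H̄ is replaced by the diagonal matrix H̃ of its row sums
  (H̄ ⪰ H̃ by Gerschgorin's circle theorem when X ≥ 0);
- σ(z) ≈ ½ + z/4, and each scalar reciprocal 1/a is one division-free
  Newton step x₀(2 − a·x₀) from a public start value x₀.

One iteration from β = 0 then costs exactly **5 ciphertext–ciphertext
multiplication stages**, independent of the dataset size, evaluated over
the FV somewhat-homomorphic scheme (R_q = Z_q[X]/(X^4096+1), q = 2^186)
with sparse **w-NIBNAF** fixed-point encodings and the plaintext modulus
split into CRT factors (t = 5179·5189·5197 at w=715 for binary data,
t = 2237·2239 at w=150 for unit-interval data).  Computation on
ciphertexts is *exact* in the plaintext ring: the decrypted model equals
the plaintext trainer's output to encoding precision (~1e−8).

See `docs/methods.md` for the full account.

## Worked example

```python
import numpy as np
from sfhlogit import (
    PARAM_PRESETS, ENCODING_PRESETS, draw_beta, gen_synthetic,
    encrypt_dataset, encrypted_sfh_iteration, decrypt_model, sfh_train,
)
from sfhlogit.fv import keygen

params, cfg = PARAM_PRESETS["toy"], ENCODING_PRESETS["toy"]
data = gen_synthetic(10, 3, "binary", draw_beta(3, np.random.default_rng(5)), seed=20)

km = keygen(params, seed=7)
enc = encrypt_dataset(data, cfg, params, km.pk, seed=8)
beta_enc, report = encrypted_sfh_iteration(enc, cfg, params, km.rlk, iters=1)
model = decrypt_model(km.sk, beta_enc, cfg, params)

print(report.ct_mults)                      # 5
print(model.beta)                           # [ 0.       -0.19     -0.1875    0.25875 ]
print(sfh_train(data, iters=1, inversion="newton").beta)
                                            # [ 0.       -0.19     -0.1875    0.25875 ]
```

The circuit report counts 5 multiplication stages; the decrypted
coefficients agree with the plaintext trainer to 4e−8 — the only deviation
is the fixed-point truncation of the public constants.  The scripts in
`examples/` walk through each capability (plaintext training vs the IRLS
reference, encoding and CRT, FV basics, encrypted training, and a fully
seeded experiment); each prints the numbers it computes and what they mean.

A thin CLI wraps the same calls for shell use:

```sh
sfhlogit simulate --n 100 --d 5 --out data.csv
sfhlogit keygen --params toy
sfhlogit encrypt-data data.csv --params toy --encoding toy --out enc/
sfhlogit train-encrypted enc/ --params toy --encoding toy --out model_enc/
sfhlogit decrypt-model model_enc/ --params toy --encoding toy --out model.txt
sfhlogit evaluate model.txt data.csv
```

Note: the `toy` and `mini` parameter sets are for tests and examples only
and offer **no security**; the `full` set (D=4096, q=2^186, σ=20) carries
an externally estimated 78 bits.

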