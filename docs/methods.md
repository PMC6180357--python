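# Methods

This note records the model, the numerical choices and the limits of what
the test suite demonstrates.

## The simplified fixed Hessian (SFH) method

Binary logistic regression with labels y ∈ {−1, +1} and covariate vectors
x = (1, x₁, …, x_d) models Pr(y | x, β) = σ(y βᵀx).  The maximum-likelihood
Newton iteration β ← β − H(β)⁻¹∇ℓ(β) is unusable on encrypted data: the
Hessian changes every step, matrix inversion has no shallow circuit, and σ
is not a polynomial.  Three successive simplifications fix this:

1. **Fixed Hessian.** H(β) = −Σᵢ σᵢ(1−σᵢ) xᵢxᵢᵀ satisfies
   H(β) ⪰ H̄ := −¼ XᵀX in the Loewner order (σ(1−σ) ≤ ¼), and the
   Böhning–Lindsay argument shows Newton's method still converges when the
   Hessian is replaced by any fixed negative-definite lower bound.
2. **Diagonalisation.** H̄ is replaced by the diagonal matrix H̃ whose
   entries are the row sums of H̄.  For a matrix with non-positive entries
   (true for H̄ whenever X ≥ 0, i.e. binary or min-max-normalised
   covariates), A − diag(rowsums A) is non-negative definite by
   Gerschgorin's circle theorem, so H̄ ⪰ H̃ and the convergence guarantee
   survives.  Inverting H̃ is d+1 scalar reciprocals.
3. **Polynomialisation.** σ(z) ≈ ½ + z/4 (first-order Taylor), and each
   reciprocal 1/a is computed by the division-free Newton step
   x₁ = x₀(2 − a x₀), whose relative error is (1 − a x₀)²: one step from a
   start within 30% of the true reciprocal is already within 10%.

Starting from β = 0 the update is β ← β − H̃⁻¹ ∇ℓ̃(β) with the linearised
gradient ∇ℓ̃(β) = ½Xᵀy − ¼XᵀXβ.  H̃ and its (approximate) inverse are
computed once, before the loop.  The reciprocal start value is public,
derived only from the data dimensions: x₀ = −4/((d+1)·N·μ̂), because H̃
entries scale like −¼·N·(d+1)·E[x]²; μ̂ defaults to 1 for binary and ½ for
unit-interval covariates.  With exact reciprocals and many iterations the
method converges to the fixed point of the linearised gradient
(β* = 2(XᵀX)⁻¹Xᵀy, a least-squares-like solution), not the MLE; the whole
point of the method is that *one* iteration already ranks well.

The **row-sum-first order** matters for complexity: H̃ₖ =
−¼ Σᵢ x_{i,k}(Σⱼ x_{i,j}) is evaluated by forming the per-record row sums
first (additions only) and then one matrix–vector product, N(d+2) scalar
multiplications instead of the O(N d²) of building H̄.

The exact-ML reference (`irls_reference`) is a binomial GLM with logit
link fitted by IRLS via statsmodels.  On (quasi-)separable data the MLE
diverges while SFH remains well defined, so the reference warns and caps
coefficients at ±30 instead of failing.

## w-NIBNAF encoding

Reals enter the plaintext ring Z_t[X]/(X^D+1) through a greedy signed-digit
expansion in a non-integral base 1 < b_w < 2: repeatedly subtract the
nearest power ±b_w^e (ties take the smaller exponent).  The remainder after
a step at exponent e is at most b_w^e(b_w−1)/2, so consecutive nonzero
digits are at least w apart exactly when b_w^w(b_w−1) ≤ b_w+1.  We use the
largest such base — the root of that equation in (1,2), solved by Brent's
method on its log form — giving the sparsest encoding that still carries
the spacing guarantee.  (For w = 1 the bound is vacuous below 2 and the
golden ratio is used by convention.)

The expansion is truncated at `precision` fractional digits; the default is
the smallest p with b_w^(−p)(1+b_w)/2 ≤ 1e−7, so round trips on [−1, 1]
stay well inside 1e−6 (p = 28 at w=2, 569 at w=150, 2077 at w=715).
Negative exponents fold onto the top ring coefficients with a sign flip
(X^(−j) = −X^(D−j)); each encoded value carries its exponent range
(e_min, e_max) as metadata.  Sums take the union of ranges,
products add them — this is how the decoder knows which top coefficients
are fractional after homomorphic arithmetic, and overflowing the ring
degree raises instead of silently wrapping.

Because evaluation at b_w is a ring homomorphism, sums and products of
encodings decode to sums and products of the encoded reals — exactly, as
long as no integer coefficient of the (unreduced) result reaches t/2.
That threshold is the package's t_min analysis: `plain_circuit_growth`
replays the training circuit over Z and reports the largest coefficient.
When a single factor small enough for the noise analysis cannot cover the
growth, t is a product of coprime factors (CRT): the published
factorizations are 5179·5189·5197 with w=715 (binary "genomic" data, three
factors) and 2237·2239 with w=150 ("financial" data, two factors).  The
whole circuit runs once per factor, and the results are recombined
coefficient-wise with centered representatives.

## The FV layer

Standard FV over R_q = Z_q[X]/(X^D+1): ternary secret and encryption keys,
discrete-Gaussian errors (σ = 20, rounded and truncated at 6σ), Δ = ⌊q/t⌋
scaling, tensor-and-round multiplication with version-1 relinearization
(decomposition base 2^32).  All coefficients are exact Python integers with
centered representatives; q = 2^186 is represented exactly.

Polynomial products use Kronecker substitution: each operand is evaluated
at X = 2^k (one big integer), multiplied with CPython's native arithmetic,
and the signed product coefficients are read back by balanced-digit
extraction, with k sized so coefficients cannot overlap.  This is bit-exact
— the suite checks it against a schoolbook negacyclic convolution — and
about two orders of magnitude faster in pure Python than an explicit NTT
at these modulus sizes (~0.1 s per D = 4096 product).

The noise budget is reported as log2(Δ/(2‖e‖∞)), read off the scaled
residue [t(c₀+c₁s)]_q so that it goes negative once the noise has wrapped
(a definition that self-references the decrypted plaintext cannot detect
overflow).

Parameter sets:

| preset | D | q | t | purpose |
|---|---|---|---|---|
| `full` | 4096 | 2^186 | one CRT factor at a time | full-scale runs; 78-bit security per the external estimate, asserted by configuration |
| `toy`   | 512  | 2^240 | 2^30+35 (prime) | fast end-to-end tests; **no security** |
| `mini`  | 64   | 2^120 | 257 | FV correctness suite; **no security** |

The toy set deliberately keeps q large: with a single plaintext factor the
coefficient-growth bound forces t ≈ 2^30, and each multiplication costs
roughly log2(t) + log2(D) + O(1) ≈ 42 bits of budget; the depth-4 circuit
plus relinearization noise needs ~180 bits, which a "small-q" toy set
cannot supply.  Speed comes from the small ring degree, not from q.

## The encrypted training circuit

Per record, the d covariates and the label are encoded, reduced modulo
each CRT factor and encrypted — d+1 ciphertexts per record per factor, so
a dataset costs T(d+1)N ciphertexts and T(d+1)N·2D·log2(q) bits (one
serialized ciphertext at the full-scale set is 2·4096·186 bits = 186 kB).
The intercept column is the public constant 1 and is never encrypted; the
public constants ¼, ½ and 2 enter as plaintext polynomials.

One iteration evaluates, per factor:

| stage | computes | ct-ct products |
|---|---|---|
| 1 `hessian-diag` | h_k = −¼ Σᵢ x_{k,i} rᵢ with rᵢ = 1+Σⱼx_{i,j} | N·d |
| 2 `gradient` | g_j = ½ Σᵢ yᵢ x_{i,j} | N·d |
| 3 `reciprocal-ax0` | u_k = h_k · x₀ | d+1 |
| 4 `reciprocal-outer` | inv_k = x₀ · (2 − u_k) | d+1 |
| 5 `model-update` | β_k = −(inv_k · g_k) | d+1 |

Exactly **5 ciphertext–ciphertext multiplication stages** per iteration
(a stage applied elementwise across the d+1 coordinates counts once);
operation counts grow linearly in N and in d.  Tensor products inside the
two summation stages are accumulated unrelinearized and key-switched once
per output coordinate, which changes nothing semantically and saves most
relinearizations.

The reciprocal stages run ct-ct even though x₀ is public: x₀ enters as the
transparent ciphertext (Δ·m, 0).  For any further reciprocal refinement the
input x_k *is* a ciphertext (the output of the previous step), so this
keeps the circuit uniform in the inversion depth and makes the published
per-iteration multiplication count hold as stated; evaluating them as
plaintext multiplications instead would be a constant-folding optimisation
of the k=1 case.  Only iters ∈ {0, 1} are supported: a second model
iteration needs the gradient at β ≠ 0, a structurally different (and
deeper) circuit than the shipped parameter sets can absorb — and one
iteration is the method's operating point.

Homomorphic evaluation is exact: decrypting the circuit output yields,
coefficient for coefficient, the polynomials the same circuit produces
directly in R_t (the suite asserts this identity).  The only deviation
from the float-arithmetic trainer is the truncation of the encoded
constants — about 1e−8 per coefficient at the shipped precisions, with
≥100 bits of noise budget left at the full-scale set and >2000× coefficient
headroom below t/2.

**Preset pairing caveat:** the full-scale equivalence run uses binary
covariates with the financial encoding (w=150, T=2).  The genomic preset's
w=715 needs ~2100 fractional digits per encoded constant for 1e−6
accuracy, and the circuit multiplies four constant encodings together, so
its fractional span (~8000) cannot fit in D=4096 for this circuit; it
remains fully usable for encoding/decoding and for shallower circuits, or
at reduced constant precision.

## Synthetic data

Two shapes emulate the study regimes: binary covariates Bernoulli(p_j)
with p_j ~ U[0.1, 0.5] per column (genomic-style, up to 1581×103), and
continuous covariates U[0, 1] (financial-style, min-max-normalised scale,
up to 20000×32).  Labels are drawn from the logistic model itself:
y = +1 with probability σ(β_trueᵀx).  Ground-truth coefficients default to
iid normal entries with the intercept set to −Σβⱼ/2 (centred logits,
roughly balanced classes); scale 2.5 puts the ML reference at AUC ≈ 0.94,
matching the published discriminability of the financial study.

What passing tests do **not** show about real data: real covariates are
correlated, heterogeneous and possibly imbalanced in class frequency; none
of that is emulated.  The accuracy-parity study in the acceptance suite
shows the practical consequence: on iid synthetic draws the one-iteration
AUC gap to IRLS has mean ≈ 0.034 but a tail — roughly a quarter of draws
exceed 0.05, wider than the 0.005–0.032 range published for the real
(correlated) financial data, and the 1→100-iteration AUC trend reverses
slightly in ~20% of draws because the linearised-gradient fixed point is
not the MLE.  These are properties of the method on this data law, not
implementation artefacts — the trainer is verified against hand-computed
examples, finite differences, eigenvalue checks and the encrypted circuit
to 1e−8.

## Evaluation

Classification is score ≥ τ → +1 (inclusive, default τ = ½).  The ROC
curve sweeps the unique scores descending (ties grouped), prepends (0,0)
and appends (1,1), and AUC is the trapezoidal area — equal to the
normalised Mann–Whitney U statistic, which the tests verify pairwise.
Undefined rates (no actual positives/negatives) raise instead of silently
reporting 0.

## Numerical conventions

- Centered representatives in (−M/2, M/2] everywhere (plaintext, ciphertext
  and CRT residues); decoding refuses coefficients at the boundary, the
  symptom of an undersized t.
- Greedy-encoding ties (θ equidistant between two powers) take the smaller
  exponent, for determinism.
- Eigenvalue non-negativity tolerance 1e−9; gradient finite-difference
  tolerance 1e−6 — double-precision conditioning of XᵀX at these problem
  sizes.
- Every sampler (keys, errors, data) draws from a seeded numpy Generator;
  identical seeds give identical transcripts, keys, ciphertexts and report
  files.
- Test problem sizes: the equivalence runs use N=30, d=5 (the full-scale
  one takes ~8 minutes of big-integer arithmetic on one core); the
  accuracy study uses N_train=1000, N_test=5000, d=31 over 20 seeds.
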