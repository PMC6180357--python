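"""Encode reals as sparse signed-digit polynomials and split them across
CRT plaintext factors.

w-NIBNAF expands a real in a non-integral base 1 < b_w < 2 with digits in
{-1, 0, 1}, at most one nonzero digit per w consecutive positions.  The
sparse encodings keep coefficient growth small, which is what lets the
homomorphic scheme use a small plaintext modulus.
"""

from sfhlogit import ENCODING_PRESETS, crt_join, crt_split, laurent_fold
from sfhlogit.encoding import nibnaf_decode, nibnaf_encode

cfg = ENCODING_PRESETS["financial"]  # w = 150, t = 2237 * 2239, D = 4096
theta = 0.637

digits = nibnaf_encode(theta, cfg)
print(f"encoding {theta} with w={cfg.w}, base b_w={cfg.b_w:.6f}:")
print(f"  {len(digits.digits)} nonzero digits at exponents "
      f"{sorted(digits.digits)}")
print(f"  decoded back: {digits.value(cfg.b_w):.10f}")

poly = laurent_fold(digits, cfg.D)
print(f"  folded into the ring: {sum(1 for c in poly.coeffs if c)} nonzero "
      f"of {cfg.D} coefficients")

residues = crt_split(poly.reduce(cfg.t), cfg.t_factors)
joined = crt_join(residues, cfg.t_factors)
value = nibnaf_decode(joined, cfg, digits.frac_span)
print(f"  after CRT split into factors {cfg.t_factors} and rejoin: {value:.10f}")
print("\nRound trip through digits, ring fold and CRT is exact to the "
      "truncation tail (~1e-7 here).")
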