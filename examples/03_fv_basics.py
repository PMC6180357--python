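"""Key generation, encryption and homomorphic arithmetic with the FV
scheme on small (insecure, test-only) parameters.

A ciphertext carries a noise term that grows with every operation; the
noise budget (in bits) is the remaining margin before decryption fails.
"""

from sfhlogit import PARAM_PRESETS
from sfhlogit.fv import (
    ct_add,
    ct_mul,
    decrypt,
    encrypt,
    keygen,
    noise_budget,
    serialize_ciphertext,
)

params = PARAM_PRESETS["mini"]  # D = 64, q = 2^120, t = 257
km = keygen(params, seed=0)

m2 = [2] + [0] * (params.D - 1)
m3 = [3] + [0] * (params.D - 1)
c2 = encrypt(km.pk, m2, params, seed=1)
c3 = encrypt(km.pk, m3, params, seed=2)

print(f"fresh noise budget: {noise_budget(km.sk, c2, params):.1f} bits")

s = ct_add(c2, c3)
p = ct_mul(c2, c3, km.rlk, params)
print(f"decrypt(Enc(2) + Enc(3)) = {decrypt(km.sk, s, params)[0]}")
print(f"decrypt(Enc(2) * Enc(3)) = {decrypt(km.sk, p, params)[0]}")
print(f"budget after the multiplication: {noise_budget(km.sk, p, params):.1f} bits")
print(f"serialized ciphertext: {len(serialize_ciphertext(c2))} bytes")
print("\nEach multiplication costs a fixed number of budget bits; parameters"
      "\nare chosen so the one-iteration training circuit fits with margin.")
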