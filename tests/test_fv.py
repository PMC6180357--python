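"""FV scheme correctness on small parameters: round trips, homomorphism
against the plaintext-ring oracle, noise accounting, determinism and the
bit-exact serialization format."""

import numpy as np
import pytest

from sfhlogit import fv
from sfhlogit.fv import (
    Ciphertext,
    FVError,
    FVParams,
    PARAM_PRESETS,
    ciphertext_nbytes,
    ct_add,
    ct_mul,
    ct_neg,
    ct_add_plain,
    decrypt,
    deserialize_ciphertext,
    encrypt,
    keygen,
    noise_budget,
    pt_mul,
    serialize_ciphertext,
)
from sfhlogit.ringpoly import (
    centered_vec,
    negacyclic_mul_schoolbook,
    poly_add,
    negacyclic_mul,
)


def _random_plaintext(rng, params):
    half = params.t // 2
    return [int(v) for v in rng.integers(-half + 1, half + 1, size=params.D)]


class TestParams:
    def test_delta_is_floor(self):
        p = FVParams(D=8, q=1000, t=7)
        assert p.Delta == 142

    def test_power_of_two_degree_required(self):
        with pytest.raises(ValueError):
            FVParams(D=6, q=2**40, t=7)

    def test_preset_shapes(self):
        p = PARAM_PRESETS["full"]
        assert (p.D, p.q, p.sigma_err) == (4096, 2**186, 20.0)
        assert p.qbits == 186


class TestKeygen:
    def test_public_key_relation_has_small_norm(self, mini_params, mini_keys):
        # [b + a s]_q must equal the sampled error, bounded by 6 sigma
        chk = poly_add(
            mini_keys.pk[0],
            negacyclic_mul(mini_keys.pk[1], mini_keys.sk, mini_params.q),
            mini_params.q,
        )
        assert max(abs(c) for c in chk) <= 6 * mini_params.sigma_err

    def test_deterministic_under_seed(self, mini_params):
        a = keygen(mini_params, 99)
        b = keygen(mini_params, 99)
        assert a.sk == b.sk and a.pk == b.pk and a.rlk == b.rlk
        c = keygen(mini_params, 100)
        assert c.sk != a.sk

    def test_full_parameter_set_keygen(self):
        km = keygen(PARAM_PRESETS["full"], 0)
        assert len(km.sk) == 4096
        assert all(v in (-1, 0, 1) for v in km.sk)


class TestEncryptDecrypt:
    def test_roundtrip_random_plaintexts(self, mini_params, mini_keys):
        rng = np.random.default_rng(2)
        for seed in range(5):
            m = _random_plaintext(rng, mini_params)
            ct = encrypt(mini_keys.pk, m, mini_params, seed)
            assert decrypt(mini_keys.sk, ct, mini_params) == m

    def test_encryption_of_zero_is_masked(self, mini_params, mini_keys):
        ct = encrypt(mini_keys.pk, [0] * mini_params.D, mini_params, 3)
        assert any(c != 0 for c in ct.c[0])
        assert any(c != 0 for c in ct.c[1])

    def test_fresh_noise_budget_positive_at_full_set(self):
        params = PARAM_PRESETS["full"]
        km = keygen(params, 1)
        m = [0] * params.D
        m[0] = 1
        ct = encrypt(km.pk, m, params, 2)
        assert noise_budget(km.sk, ct, params) > 100.0

    def test_out_of_range_plaintext_rejected(self, mini_params, mini_keys):
        m = [mini_params.t] + [0] * (mini_params.D - 1)
        with pytest.raises(ValueError):
            encrypt(mini_keys.pk, m, mini_params, 1)


class TestHomomorphism:
    def test_add_identity_and_commutativity(self, mini_params, mini_keys):
        rng = np.random.default_rng(4)
        m = _random_plaintext(rng, mini_params)
        c1 = encrypt(mini_keys.pk, m, mini_params, 5)
        c0 = encrypt(mini_keys.pk, [0] * mini_params.D, mini_params, 6)
        assert decrypt(mini_keys.sk, ct_add(c1, c0), mini_params) == m
        m2 = _random_plaintext(rng, mini_params)
        c2 = encrypt(mini_keys.pk, m2, mini_params, 7)
        assert decrypt(mini_keys.sk, ct_add(c1, c2), mini_params) == decrypt(
            mini_keys.sk, ct_add(c2, c1), mini_params
        )

    def test_repeated_addition_counts(self, mini_params, mini_keys):
        one = [1] + [0] * (mini_params.D - 1)
        ct = encrypt(mini_keys.pk, one, mini_params, 8)
        acc = ct
        for _ in range(16):
            acc = ct_add(acc, ct)
        out = decrypt(mini_keys.sk, acc, mini_params)
        assert out[0] == 17 and all(c == 0 for c in out[1:])

    def test_integer_product_two_times_three(self, mini_params, mini_keys):
        two = [2] + [0] * (mini_params.D - 1)
        three = [3] + [0] * (mini_params.D - 1)
        c = ct_mul(
            encrypt(mini_keys.pk, two, mini_params, 9),
            encrypt(mini_keys.pk, three, mini_params, 10),
            mini_keys.rlk,
            mini_params,
        )
        out = decrypt(mini_keys.sk, c, mini_params)
        assert out[0] == 6 and all(v == 0 for v in out[1:])
        assert c.level == 1

    def test_pt_mul_identity_and_plain_add(self, mini_params, mini_keys):
        rng = np.random.default_rng(11)
        m = _random_plaintext(rng, mini_params)
        ct = encrypt(mini_keys.pk, m, mini_params, 12)
        one = [1] + [0] * (mini_params.D - 1)
        assert decrypt(mini_keys.sk, pt_mul(ct, one), mini_params) == m
        shift = [5] + [0] * (mini_params.D - 1)
        out = decrypt(mini_keys.sk, ct_add_plain(ct, shift), mini_params)
        assert out == centered_vec(
            [a + b for a, b in zip(m, shift)], mini_params.t
        )

    def test_mul_requires_matching_params(self, mini_params, mini_keys):
        other = FVParams(D=mini_params.D, q=mini_params.q, t=mini_params.t + 2)
        c1 = encrypt(mini_keys.pk, [0] * mini_params.D, mini_params, 1)
        c2 = Ciphertext(c=[list(x) for x in c1.c], params=other)
        with pytest.raises(FVError):
            ct_add(c1, c2)

    def test_encoded_half_squared_is_quarter(self, toy_params, toy_keys, toy_cfg):
        from sfhlogit.encoding import laurent_fold, nibnaf_decode, nibnaf_encode
        from sfhlogit.encoding import PlaintextPoly

        d = nibnaf_encode(0.5, toy_cfg)
        m = laurent_fold(d, toy_cfg.D).reduce(toy_params.t)
        ct = encrypt(toy_keys.pk, m.coeffs, toy_params, 13)
        sq = ct_mul(ct, ct, toy_keys.rlk, toy_params)
        out = PlaintextPoly(decrypt(toy_keys.sk, sq, toy_params), toy_params.t)
        val = nibnaf_decode(out, toy_cfg, 2 * d.frac_span)
        assert val == pytest.approx(0.25, abs=1e-6)


class TestNoise:
    def test_budget_decreases_across_multiplications(self, mini_params, mini_keys):
        m = [1] + [0] * (mini_params.D - 1)
        ct = encrypt(mini_keys.pk, m, mini_params, 14)
        budgets = [noise_budget(mini_keys.sk, ct, mini_params)]
        for _ in range(3):
            ct = ct_mul(ct, ct, mini_keys.rlk, mini_params)
            budgets.append(noise_budget(mini_keys.sk, ct, mini_params))
        assert all(a > b for a, b in zip(budgets, budgets[1:]))

    def test_overflow_flips_budget_sign_and_breaks_decryption(self):
        # small q so that repeated squaring exhausts the budget quickly
        params = FVParams(D=64, q=2**48, t=257, sigma_err=20.0)
        km = keygen(params, 3)
        m = [1] + [0] * 63
        ct = encrypt(km.pk, m, params, 4)
        ok = True
        for _ in range(6):
            ct = ct_mul(ct, ct, km.rlk, params)
            budget = noise_budget(km.sk, ct, params)
            correct = decrypt(km.sk, ct, params) == m
            if budget > 0:
                assert correct
            else:
                ok = False
                break
        assert not ok, "noise never overflowed; parameters too roomy for test"


class TestSerialization:
    def test_ciphertext_roundtrip_bit_exact(self, mini_params, mini_keys):
        rng = np.random.default_rng(15)
        m = _random_plaintext(rng, mini_params)
        ct = encrypt(mini_keys.pk, m, mini_params, 16)
        blob = serialize_ciphertext(ct)
        back = deserialize_ciphertext(blob, mini_params)
        assert back.c == ct.c and back.level == ct.level
        assert serialize_ciphertext(back) == blob

    def test_payload_size_formula(self, mini_params):
        # 2 * D * ceil(log2 q) bits for the two packed coefficient arrays
        assert ciphertext_nbytes(mini_params) == 2 * (
            (mini_params.D * mini_params.qbits + 7) // 8
        )

    def test_truncated_blob_rejected(self, mini_params, mini_keys):
        ct = encrypt(mini_keys.pk, [0] * mini_params.D, mini_params, 17)
        blob = serialize_ciphertext(ct)
        with pytest.raises(FVError, match="truncated"):
            deserialize_ciphertext(blob[:-3], mini_params)

    def test_key_roundtrips(self, mini_params, mini_keys):
        assert (
            fv.deserialize_secret_key(
                fv.serialize_secret_key(mini_keys), mini_params
            )
            == mini_keys.sk
        )
        assert (
            fv.deserialize_public_key(
                fv.serialize_public_key(mini_keys), mini_params
            )
            == mini_keys.pk
        )
        assert (
            fv.deserialize_relin_key(
                fv.serialize_relin_key(mini_keys), mini_params
            )
            == mini_keys.rlk
        )
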