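"""The Fan-Vercauteren (FV) somewhat-homomorphic encryption scheme.

Plaintexts live in R_t = Z_t[X]/(X^D + 1), ciphertexts are pairs of
elements of R_q with q >> t.  A ciphertext (c0, c1) under secret key s
satisfies [c0 + c1 s]_q = Delta*m + e with Delta = floor(q/t); decryption
divides by Delta and rounds, and succeeds while the noise e stays below
Delta/2.  Homomorphic addition adds components; multiplication computes the
scaled tensor round(t/q * (c (x) d)) followed by relinearization (version-1
base-decomposition key switching) back to two components.

All randomness flows through a numpy Generator, so identical seeds give
identical transcripts.  Coefficients are exact big integers with centered
representatives in (-q/2, q/2]; the full-scale modulus q = 2^186 is
represented exactly.

Security note: the full-scale parameter set (D=4096, q=2^186, sigma=20)
carries an externally estimated 78 bits of security, asserted by
configuration; the small test sets are NOT secure and exist only to
exercise correctness.
"""

from __future__ import annotations

import io
import math
import struct
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .ringpoly import (
    centered,
    centered_vec,
    negacyclic_mul,
    poly_add,
    poly_neg,
    poly_sub,
    round_div,
)

__all__ = [
    "FVParams",
    "KeyMaterial",
    "Ciphertext",
    "keygen",
    "encrypt",
    "decrypt",
    "ct_add",
    "ct_sub",
    "ct_neg",
    "ct_add_plain",
    "ct_mul",
    "pt_mul",
    "relinearize",
    "noise_budget",
    "serialize_ciphertext",
    "deserialize_ciphertext",
    "serialize_secret_key",
    "deserialize_secret_key",
    "serialize_public_key",
    "deserialize_public_key",
    "serialize_relin_key",
    "deserialize_relin_key",
    "ciphertext_nbytes",
    "PARAM_PRESETS",
]


class FVError(RuntimeError):
    pass


@dataclass(frozen=True)
class FVParams:
    """Scheme parameters for one plaintext-modulus factor.

    D           power-of-two ring degree
    q           ciphertext modulus
    t           plaintext modulus (a single CRT factor)
    sigma_err   standard deviation of the error distribution chi_err
    relin_base  decomposition base of the relinearization key
    depth_budget  advisory ciphertext-multiplication depth; exceeding it
                  warns but does not fail (tests check noise directly)
    """

    D: int
    q: int
    t: int
    sigma_err: float = 20.0
    relin_base: int = 2**32
    depth_budget: int = 8

    def __post_init__(self) -> None:
        if self.D < 2 or self.D & (self.D - 1):
            raise ValueError("D must be a power of two")
        if not self.q > self.t > 1:
            raise ValueError("q >> t > 1 required")
        if self.sigma_err <= 0 or self.relin_base < 2:
            raise ValueError("invalid sigma_err or relin_base")

    @property
    def Delta(self) -> int:
        return self.q // self.t

    @property
    def qbits(self) -> int:
        """Bits per serialized coefficient: ceil(log2 q)."""
        return (self.q - 1).bit_length()

    def with_t(self, t: int) -> "FVParams":
        return FVParams(
            self.D, self.q, t, self.sigma_err, self.relin_base, self.depth_budget
        )


@dataclass
class KeyMaterial:
    sk: list[int]
    pk: tuple[list[int], list[int]]  # (b, a)
    rlk: list[tuple[list[int], list[int]]]
    params: FVParams


@dataclass
class Ciphertext:
    """Two (or, pre-relinearization, three) ring elements mod q plus the
    count of ciphertext-ciphertext multiplications consumed."""

    c: list[list[int]]
    params: FVParams
    level: int = 0

    @property
    def size(self) -> int:
        return len(self.c)


def _sample_ternary(rng: np.random.Generator, D: int) -> list[int]:
    return [int(v) - 1 for v in rng.integers(0, 3, size=D)]


def _sample_gaussian(rng: np.random.Generator, sigma: float, D: int) -> list[int]:
    """Discrete Gaussian by rounding a continuous one, rejecting |x| > 6 sigma."""
    out: list[int] = []
    bound = 6.0 * sigma
    while len(out) < D:
        draw = rng.normal(0.0, sigma, size=D - len(out))
        for v in draw:
            if abs(v) <= bound:
                out.append(int(round(v)))
    return out


def _sample_uniform_q(rng: np.random.Generator, q: int, D: int) -> list[int]:
    """Uniform coefficients mod q (centered), by rejection on random bits."""
    bits = q.bit_length()
    nbytes = (bits + 7) // 8
    mask = (1 << bits) - 1
    out: list[int] = []
    while len(out) < D:
        raw = rng.bytes((D - len(out)) * nbytes + 16)
        for i in range(0, len(raw) - nbytes + 1, nbytes):
            v = int.from_bytes(raw[i : i + nbytes], "little") & mask
            if v < q:
                out.append(centered(v, q))
                if len(out) == D:
                    break
    return out


def keygen(params: FVParams, seed: int | np.random.Generator) -> KeyMaterial:
    """Sample s from the ternary key distribution, a uniform in R_q,
    b = [-(a s + e)]_q, and the relinearization key for s^2."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    q, D = params.q, params.D
    s = _sample_ternary(rng, D)
    a = _sample_uniform_q(rng, q, D)
    e = _sample_gaussian(rng, params.sigma_err, D)
    b = centered_vec(poly_neg(poly_add(negacyclic_mul(a, s, q), e)), q)
    s2 = negacyclic_mul(s, s, q)
    T = params.relin_base
    ell = _decomp_len(params)
    rlk = []
    power = 1
    for _ in range(ell):
        ai = _sample_uniform_q(rng, q, D)
        ei = _sample_gaussian(rng, params.sigma_err, D)
        bi = [
            centered(-(x + y) + power * z, q)
            for x, y, z in zip(negacyclic_mul(ai, s, q), ei, s2)
        ]
        rlk.append((bi, ai))
        power *= T
    return KeyMaterial(sk=s, pk=(b, a), rlk=rlk, params=params)


def _decomp_len(params: FVParams) -> int:
    return int(math.ceil(params.qbits / math.log2(params.relin_base))) or 1


def encrypt(
    pk: tuple[list[int], list[int]],
    m: Sequence[int],
    params: FVParams,
    seed: int | np.random.Generator,
) -> Ciphertext:
    """c0 = Delta m + b u + e1, c1 = a u + e2 with u ternary and e1, e2
    Gaussian.  ``m`` must be reduced mod t (centered)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    q, t, D = params.q, params.t, params.D
    m = list(m)
    if len(m) != D:
        raise ValueError("plaintext degree must equal D")
    if any(abs(c) > t // 2 for c in m):
        raise ValueError("plaintext coefficients must be reduced mod t")
    b, a = pk
    u = _sample_ternary(rng, D)
    e1 = _sample_gaussian(rng, params.sigma_err, D)
    e2 = _sample_gaussian(rng, params.sigma_err, D)
    Delta = params.Delta
    c0 = [
        centered(Delta * mi + bu + e, q)
        for mi, bu, e in zip(m, negacyclic_mul(b, u, q), e1)
    ]
    c1 = poly_add(negacyclic_mul(a, u, q), e2, q)
    return Ciphertext(c=[c0, c1], params=params)


def _raw_decrypt(sk: list[int], ct: Ciphertext) -> list[int]:
    """[c0 + c1 s (+ c2 s^2)]_q, centered."""
    q = ct.params.q
    acc = list(ct.c[0])
    s_pow = sk
    for comp in ct.c[1:]:
        acc = poly_add(acc, negacyclic_mul(comp, s_pow, q), q)
        s_pow = negacyclic_mul(s_pow, sk, q)
    return acc


def decrypt(sk: list[int], ct: Ciphertext, params: FVParams) -> list[int]:
    """Divide [c0 + c1 s]_q by Delta, round, reduce into R_t (centered).

    Correct exactly when the noise infinity norm is below Delta/2; a noise
    overflow silently yields a wrong plaintext (use noise_budget to guard).
    """
    mt = _raw_decrypt(sk, ct)
    Delta = params.Delta
    return [centered(round_div(c, Delta), params.t) for c in mt]


def ct_add(c1: Ciphertext, c2: Ciphertext) -> Ciphertext:
    if c1.params != c2.params:
        raise FVError("ciphertexts under different parameters")
    n = max(c1.size, c2.size)
    q = c1.params.q
    comps = []
    for i in range(n):
        a = c1.c[i] if i < c1.size else [0] * c1.params.D
        b = c2.c[i] if i < c2.size else [0] * c1.params.D
        comps.append(poly_add(a, b, q))
    return Ciphertext(c=comps, params=c1.params, level=max(c1.level, c2.level))


def ct_sub(c1: Ciphertext, c2: Ciphertext) -> Ciphertext:
    return ct_add(c1, ct_neg(c2))


def ct_neg(ct: Ciphertext) -> Ciphertext:
    q = ct.params.q
    return Ciphertext(
        c=[poly_neg(comp, q) for comp in ct.c], params=ct.params, level=ct.level
    )


def ct_add_plain(ct: Ciphertext, m: Sequence[int]) -> Ciphertext:
    """Add a plaintext polynomial (reduced mod t) without extra noise:
    c0 += Delta * m."""
    q, Delta = ct.params.q, ct.params.Delta
    c0 = [centered(c + Delta * mi, q) for c, mi in zip(ct.c[0], m)]
    return Ciphertext(c=[c0] + [list(x) for x in ct.c[1:]], params=ct.params,
                      level=ct.level)


def pt_mul(ct: Ciphertext, p: Sequence[int]) -> Ciphertext:
    """Multiply by a plaintext polynomial.  Does not consume a
    relinearization and does not count toward the multiplication depth;
    noise scales by roughly the l1 norm of ``p``."""
    q = ct.params.q
    return Ciphertext(
        c=[negacyclic_mul(comp, list(p), q) for comp in ct.c],
        params=ct.params,
        level=ct.level,
    )


def ct_mul(
    c1: Ciphertext,
    c2: Ciphertext,
    rlk: list[tuple[list[int], list[int]]] | None,
    params: FVParams,
    relin: bool = True,
) -> Ciphertext:
    """FV tensor-scale-round multiplication.

    The tensor is computed over the integers (3 big multiplications via the
    Karatsuba identity), each component scaled by t/q with rounding, giving
    a 3-component ciphertext decryptable under (1, s, s^2); with ``relin``
    it is key-switched back to two components.  Increments ``level`` and
    warns past the advisory depth budget.
    """
    if c1.params != c2.params:
        raise FVError("ciphertexts under different parameters")
    if c1.size != 2 or c2.size != 2:
        raise FVError("ct_mul operands must be 2-component (relinearize first)")
    q, t = params.q, params.t
    a0, a1 = c1.c
    b0, b1 = c2.c
    d0 = negacyclic_mul(a0, b0)  # exact integer products
    d2 = negacyclic_mul(a1, b1)
    cross = negacyclic_mul(poly_add(a0, a1), poly_add(b0, b1))
    d1 = [x - y - z for x, y, z in zip(cross, d0, d2)]
    comps = [
        [centered(round_div(t * c, q), q) for c in d] for d in (d0, d1, d2)
    ]
    out = Ciphertext(c=comps, params=params, level=max(c1.level, c2.level) + 1)
    if out.level > params.depth_budget:
        import warnings

        warnings.warn(
            f"ciphertext level {out.level} exceeds the advisory depth budget "
            f"{params.depth_budget}",
            RuntimeWarning,
            stacklevel=2,
        )
    if relin:
        if rlk is None:
            raise FVError("relinearization key required")
        out = relinearize(out, rlk, params)
    return out


def relinearize(
    ct: Ciphertext, rlk: list[tuple[list[int], list[int]]], params: FVParams
) -> Ciphertext:
    """Key-switch a 3-component ciphertext back to 2 components by signed
    base-T decomposition of the quadratic component against the
    relinearization key."""
    if ct.size == 2:
        return ct
    if ct.size != 3:
        raise FVError("can only relinearize 3-component ciphertexts")
    q, D, T = params.q, params.D, params.relin_base
    c0, c1, c2 = ct.c
    ell = _decomp_len(params)
    # non-negative base-T digits of the [0, q) representative
    digits: list[list[int]] = [[0] * D for _ in range(ell)]
    for pos in range(D):
        v = c2[pos] % q
        for i in range(ell):
            digits[i][pos] = v % T
            v //= T
    r0, r1 = list(c0), list(c1)
    for i in range(ell):
        bi, ai = rlk[i]
        r0 = poly_add(r0, negacyclic_mul(bi, digits[i], q), q)
        r1 = poly_add(r1, negacyclic_mul(ai, digits[i], q), q)
    return Ciphertext(c=[r0, r1], params=params, level=ct.level)


def noise_budget(
    sk: list[int], ct: Ciphertext, params: FVParams
) -> float:
    """Remaining noise margin in bits: log2(Delta / (2 ||e||_inf)).

    The noise is read off the scaled residue w = [t (c0 + c1 s)]_q, which
    equals t*e (up to a small m-dependent term) while the ciphertext is
    valid, so the budget matches log2(Delta/(2||e||)) there -- and becomes
    negative once the noise has wrapped modulo q, when w is of size ~q/2.
    Positive iff decryption still recovers the plaintext.
    """
    mt = _raw_decrypt(sk, ct)
    q, t = params.q, params.t
    w = max(abs(centered(t * c, q)) for c in mt)
    if w == 0:
        return float(params.Delta.bit_length())
    return math.log2(q) - 1.0 - math.log2(w) - math.log2(t)


# ----------------------------------------------------------------------
# serialization: header + fixed-width little-endian coefficient payload
# ----------------------------------------------------------------------

_MAGIC_CT = b"SFHC"
_MAGIC_SK = b"SFHS"
_MAGIC_PK = b"SFHP"
_MAGIC_RK = b"SFHR"


def _pack_coeffs(coeffs: Sequence[int], q: int, qbits: int) -> bytes:
    """Bit-pack [0, q) representatives at qbits bits per coefficient."""
    acc = 0
    for c in reversed(coeffs):
        acc = (acc << qbits) | (c % q)
    nbytes = (len(coeffs) * qbits + 7) // 8
    return acc.to_bytes(nbytes, "little")


def _unpack_coeffs(raw: bytes, n: int, q: int, qbits: int) -> list[int]:
    acc = int.from_bytes(raw, "little")
    mask = (1 << qbits) - 1
    out = []
    for _ in range(n):
        out.append(centered(acc & mask, q))
        acc >>= qbits
    return out


def ciphertext_nbytes(params: FVParams) -> int:
    """Payload size of a 2-component ciphertext: 2 * D * ceil(log2 q) bits."""
    return 2 * ((params.D * params.qbits + 7) // 8)


def serialize_ciphertext(ct: Ciphertext) -> bytes:
    p = ct.params
    head = _MAGIC_CT + struct.pack(
        "<IIHB", p.D, p.qbits, len(ct.c), ct.level
    )
    body = b"".join(_pack_coeffs(comp, p.q, p.qbits) for comp in ct.c)
    return head + body


def deserialize_ciphertext(raw: bytes, params: FVParams) -> Ciphertext:
    if raw[:4] != _MAGIC_CT:
        raise FVError("not a ciphertext blob")
    D, qbits, ncomp, level = struct.unpack("<IIHB", raw[4:15])
    if D != params.D or qbits != params.qbits:
        raise FVError("ciphertext parameters do not match")
    per = (D * qbits + 7) // 8
    if len(raw) != 15 + ncomp * per:
        raise FVError(f"truncated ciphertext blob (expected {15 + ncomp * per} "
                      f"bytes, got {len(raw)})")
    comps = []
    for i in range(ncomp):
        chunk = raw[15 + i * per : 15 + (i + 1) * per]
        comps.append(_unpack_coeffs(chunk, D, params.q, qbits))
    return Ciphertext(c=comps, params=params, level=level)


def serialize_secret_key(km: KeyMaterial) -> bytes:
    p = km.params
    return _MAGIC_SK + struct.pack("<II", p.D, p.qbits) + _pack_coeffs(
        km.sk, p.q, p.qbits
    )


def deserialize_secret_key(raw: bytes, params: FVParams) -> list[int]:
    if raw[:4] != _MAGIC_SK:
        raise FVError("not a secret-key blob")
    D, qbits = struct.unpack("<II", raw[4:12])
    if D != params.D or qbits != params.qbits:
        raise FVError("key parameters do not match")
    per = (D * qbits + 7) // 8
    if len(raw) != 12 + per:
        raise FVError("truncated secret-key blob")
    return _unpack_coeffs(raw[12:], D, params.q, qbits)


def serialize_public_key(km: KeyMaterial) -> bytes:
    p = km.params
    return (
        _MAGIC_PK
        + struct.pack("<II", p.D, p.qbits)
        + _pack_coeffs(km.pk[0], p.q, p.qbits)
        + _pack_coeffs(km.pk[1], p.q, p.qbits)
    )


def deserialize_public_key(
    raw: bytes, params: FVParams
) -> tuple[list[int], list[int]]:
    if raw[:4] != _MAGIC_PK:
        raise FVError("not a public-key blob")
    D, qbits = struct.unpack("<II", raw[4:12])
    if D != params.D or qbits != params.qbits:
        raise FVError("key parameters do not match")
    per = (D * qbits + 7) // 8
    if len(raw) != 12 + 2 * per:
        raise FVError("truncated public-key blob")
    return (
        _unpack_coeffs(raw[12 : 12 + per], D, params.q, qbits),
        _unpack_coeffs(raw[12 + per :], D, params.q, qbits),
    )


def serialize_relin_key(km: KeyMaterial) -> bytes:
    p = km.params
    out = io.BytesIO()
    out.write(_MAGIC_RK + struct.pack("<IIH", p.D, p.qbits, len(km.rlk)))
    for bi, ai in km.rlk:
        out.write(_pack_coeffs(bi, p.q, p.qbits))
        out.write(_pack_coeffs(ai, p.q, p.qbits))
    return out.getvalue()


def deserialize_relin_key(
    raw: bytes, params: FVParams
) -> list[tuple[list[int], list[int]]]:
    if raw[:4] != _MAGIC_RK:
        raise FVError("not a relinearization-key blob")
    D, qbits, n = struct.unpack("<IIH", raw[4:14])
    if D != params.D or qbits != params.qbits:
        raise FVError("key parameters do not match")
    per = (D * qbits + 7) // 8
    if len(raw) != 14 + 2 * n * per:
        raise FVError("truncated relinearization-key blob")
    rlk = []
    off = 14
    for _ in range(n):
        bi = _unpack_coeffs(raw[off : off + per], D, params.q, qbits)
        ai = _unpack_coeffs(raw[off + per : off + 2 * per], D, params.q, qbits)
        rlk.append((bi, ai))
        off += 2 * per
    return rlk


#: Scheme presets.  "full" is the full-scale production set (78-bit security
#: asserted by configuration, never recomputed).  "toy" pairs with the toy
#: encoding preset and is sized by the package's own noise analysis for the
#: one-iteration training circuit; "mini" is for fast correctness tests.
#: Neither small set offers any security.
PARAM_PRESETS: dict[str, FVParams] = {
    "full": FVParams(D=4096, q=2**186, t=2237, sigma_err=20.0),
    "toy": FVParams(D=512, q=2**240, t=1073741827, sigma_err=20.0),
    "mini": FVParams(D=64, q=2**120, t=257, sigma_err=20.0),
}
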