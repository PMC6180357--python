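"""Integer polynomial arithmetic in the negacyclic ring Z[X]/(X^D + 1).

Coefficients are arbitrary-precision Python integers so the ciphertext
modulus (q = 2^186 for the full-scale parameter set) is represented exactly.
Ring elements are plain lists of ints of length D, with centered
representatives in (-M/2, M/2] whenever a modulus M applies.

The workhorse is :func:`negacyclic_mul`, implemented by Kronecker
substitution: evaluate both polynomials at X = 2^k for a slot width k large
enough that no two coefficients of the product overlap, multiply the two
resulting big integers with CPython's native arithmetic, and read the signed
product coefficients back out with a balanced-digit extraction.  This is
bit-exact (a property the test suite checks against a schoolbook oracle) and
much faster in pure Python than an explicit NTT for 186-bit moduli.
"""

from __future__ import annotations

from typing import Sequence

__all__ = [
    "centered",
    "centered_vec",
    "poly_add",
    "poly_sub",
    "poly_neg",
    "poly_scalar_mul",
    "negacyclic_mul",
    "negacyclic_mul_schoolbook",
    "round_div",
]


def centered(x: int, m: int) -> int:
    """Centered representative of ``x`` modulo ``m``, in (-m/2, m/2]."""
    r = x % m
    if 2 * r > m:
        r -= m
    return r


def centered_vec(coeffs: Sequence[int], m: int) -> list[int]:
    return [centered(c, m) for c in coeffs]


def poly_add(a: Sequence[int], b: Sequence[int], m: int | None = None) -> list[int]:
    if m is None:
        return [x + y for x, y in zip(a, b, strict=True)]
    return [centered(x + y, m) for x, y in zip(a, b, strict=True)]


def poly_sub(a: Sequence[int], b: Sequence[int], m: int | None = None) -> list[int]:
    if m is None:
        return [x - y for x, y in zip(a, b, strict=True)]
    return [centered(x - y, m) for x, y in zip(a, b, strict=True)]


def poly_neg(a: Sequence[int], m: int | None = None) -> list[int]:
    if m is None:
        return [-x for x in a]
    return [centered(-x, m) for x in a]


def poly_scalar_mul(a: Sequence[int], s: int, m: int | None = None) -> list[int]:
    if m is None:
        return [s * x for x in a]
    return [centered(s * x, m) for x in a]


def round_div(n: int, d: int) -> int:
    """round(n / d) for integers, half away from zero, exact in big ints."""
    if d < 0:
        n, d = -n, -d
    if n >= 0:
        return (2 * n + d) // (2 * d)
    return -((-2 * n + d) // (2 * d))


def _pack(coeffs: Sequence[int], slot_bytes: int) -> int:
    """Evaluate the polynomial at X = 2^(8*slot_bytes).

    Signed coefficients are handled by assembling the non-negative and
    negative parts byte-wise and subtracting once.
    """
    n = len(coeffs)
    pos = bytearray(n * slot_bytes)
    neg = bytearray(n * slot_bytes)
    any_neg = False
    for i, c in enumerate(coeffs):
        if c > 0:
            pos[i * slot_bytes : i * slot_bytes + slot_bytes] = c.to_bytes(
                slot_bytes, "little"
            )
        elif c < 0:
            any_neg = True
            neg[i * slot_bytes : i * slot_bytes + slot_bytes] = (-c).to_bytes(
                slot_bytes, "little"
            )
    a = int.from_bytes(bytes(pos), "little")
    if any_neg:
        a -= int.from_bytes(bytes(neg), "little")
    return a


def _unpack_balanced(value: int, nslots: int, slot_bytes: int) -> list[int]:
    """Recover signed slot digits d_j with |d_j| < 2^(slot_bits-1) from
    value = sum_j d_j * 2^(slot_bits * j)."""
    slot_bits = 8 * slot_bytes
    # Shift into the strictly-positive range; the offset lands entirely in
    # slot index `nslots`, which we never read back.
    shifted = value + (1 << (slot_bits * nslots))
    raw = shifted.to_bytes(slot_bytes * (nslots + 1) + 8, "little")
    half = 1 << (slot_bits - 1)
    full = 1 << slot_bits
    out = [0] * nslots
    carry = 0
    for j in range(nslots):
        u = int.from_bytes(raw[j * slot_bytes : (j + 1) * slot_bytes], "little") + carry
        if u >= half:
            u -= full
            carry = 1
        else:
            carry = 0
        out[j] = u
    return out


def negacyclic_mul(
    a: Sequence[int], b: Sequence[int], modulus: int | None = None
) -> list[int]:
    """Product of ``a`` and ``b`` in Z[X]/(X^D + 1), D = len(a) = len(b).

    With ``modulus`` the result is reduced to centered representatives;
    without it the exact integer coefficients are returned (needed for the
    FV tensor-and-scale multiplication step).
    """
    d = len(a)
    if len(b) != d:
        raise ValueError("operands must share the ring degree")
    max_a = max((abs(c) for c in a), default=0)
    max_b = max((abs(c) for c in b), default=0)
    if max_a == 0 or max_b == 0:
        return [0] * d
    # |product coefficient| <= D * max|a| * max|b|; one spare bit for the
    # balanced representation, one for safety.
    bound = d * max_a * max_b
    slot_bits = bound.bit_length() + 2
    slot_bytes = (slot_bits + 7) // 8
    prod = _pack(a, slot_bytes) * _pack(b, slot_bytes)
    digits = _unpack_balanced(prod, 2 * d, slot_bytes)
    out = [0] * d
    for i in range(d):
        out[i] = digits[i] - digits[i + d]
    if modulus is not None:
        out = centered_vec(out, modulus)
    return out


def negacyclic_mul_schoolbook(
    a: Sequence[int], b: Sequence[int], modulus: int | None = None
) -> list[int]:
    """O(D^2) reference multiplication; the oracle the fast path is tested
    against."""
    d = len(a)
    if len(b) != d:
        raise ValueError("operands must share the ring degree")
    out = [0] * d
    for i, ai in enumerate(a):
        if ai == 0:
            continue
        for j, bj in enumerate(b):
            if bj == 0:
                continue
            k = i + j
            if k < d:
                out[k] += ai * bj
            else:
                out[k - d] -= ai * bj
    if modulus is not None:
        out = centered_vec(out, modulus)
    return out
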