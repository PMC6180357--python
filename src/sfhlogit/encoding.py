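"""w-NIBNAF fixed-point encoding and CRT plaintext decomposition.

Real numbers are expanded greedily in a non-integral base 1 < b_w < 2 with
signed digits in {-1, 0, 1}; by construction any w consecutive exponents
carry at most one nonzero digit, so the encodings are very sparse ternary
Laurent polynomials.  Substituting the ring variable X for b_w and folding
negative exponents onto the top coefficients of Z[X]/(X^D + 1) (using
X^D = -1, which flips their sign) turns every real into a plaintext ring
element; addition and multiplication of encodings then mirror addition and
multiplication of the underlying reals, up to the truncation tail.

Sparsity is what lets the plaintext modulus t stay small.  When even the
small t that the homomorphic noise analysis allows is too small for the
coefficients the computation produces, t is chosen as a product of pairwise
coprime factors t_1 ... t_n and the whole computation runs once per factor;
:func:`crt_split` / :func:`crt_join` implement the corresponding ring
isomorphism R_t -> R_{t_1} x ... x R_{t_n} coefficient-wise with centered
representatives.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Mapping, Sequence

from scipy.optimize import brentq

from .ringpoly import centered

__all__ = [
    "EncodingConfig",
    "LaurentDigits",
    "PlaintextPoly",
    "nibnaf_base",
    "nibnaf_encode",
    "laurent_fold",
    "laurent_unfold",
    "nibnaf_decode",
    "crt_split",
    "crt_join",
    "default_precision",
    "ENCODING_PRESETS",
]


class EncodingError(ValueError):
    """Raised when a value cannot be represented under the given config."""


@lru_cache(maxsize=None)
def nibnaf_base(w: int) -> float:
    """Base b_w of the w-NIBNAF expansion.

    The greedy expansion subtracts the nearest power s*b^e at each step,
    leaving a remainder of at most b^e (b-1)/2.  The next nonzero digit sits
    at least w positions lower for every input exactly when that worst-case
    remainder does not exceed the midpoint b^(e-w) (1+b)/2, i.e. when
    b^w (b - 1) <= b + 1.  We take the largest such base (the sparsest
    encoding still guaranteeing the spacing property), the root in (1, 2) of

        w*log b + log(b - 1) - log(b + 1) = 0,

    solved by bisection/Brent on the (monotone) log form.
    """
    if w < 1:
        raise ValueError("w must be a positive integer")
    if w == 1:
        # the spacing bound b(b-1) <= b+1 holds for every base below 2, so
        # there is no maximal base in (1, 2); use the classic non-integral
        # base, the golden ratio
        return (1.0 + math.sqrt(5.0)) / 2.0

    def g(b: float) -> float:
        return w * math.log(b) + math.log(b - 1.0) - math.log(b + 1.0)

    return float(brentq(g, 1.0 + 1e-14, 2.0, xtol=1e-15, rtol=1e-15))


def default_precision(w: int, tail: float = 1e-7) -> int:
    """Number of fractional digits keeping the truncation tail below ``tail``.

    Stopping the greedy expansion at exponent -p leaves a remainder smaller
    than b^-p (1+b)/2; the default targets 1e-7 so that round trips on
    [-1, 1] stay well inside 1e-6.
    """
    b = nibnaf_base(w)
    return int(math.ceil(math.log((1.0 + b) / (2.0 * tail)) / math.log(b)))


@dataclass(frozen=True)
class EncodingConfig:
    """Parameters of the plaintext encoding.

    w           spacing parameter (>= 1); larger w gives sparser encodings.
    b_w         the base; computed from w unless overridden.
    D           ring degree the folded encodings must fit in.
    t_factors   pairwise-coprime plaintext moduli; their product is the
                logical plaintext modulus t.
    precision   truncation bound on fractional digits.
    """

    w: int
    D: int
    t_factors: tuple[int, ...]
    precision: int | None = None
    b_w: float | None = None

    def __post_init__(self) -> None:
        if self.w < 1 or self.D < 2:
            raise ValueError("w >= 1 and D >= 2 required")
        if not self.t_factors:
            raise ValueError("at least one plaintext modulus factor required")
        for i, ti in enumerate(self.t_factors):
            if ti <= 1:
                raise ValueError("plaintext moduli must exceed 1")
            for tj in self.t_factors[i + 1 :]:
                if math.gcd(ti, tj) != 1:
                    raise ValueError(
                        f"t_factors must be pairwise coprime, got {ti} and {tj}"
                    )
        if self.b_w is None:
            object.__setattr__(self, "b_w", nibnaf_base(self.w))
        if not (1.0 < self.b_w < 2.0):
            raise ValueError("b_w must lie in (1, 2)")
        if self.precision is None:
            object.__setattr__(self, "precision", default_precision(self.w))

    @property
    def t(self) -> int:
        return math.prod(self.t_factors)

    def with_precision(self, precision: int) -> "EncodingConfig":
        return replace(self, precision=precision)

    @classmethod
    def from_file(cls, path) -> "EncodingConfig":
        """Read a key=value config: w, D, t_factors (comma separated),
        optional precision and b_w override.  Lines starting with # are
        comments."""
        fields: dict[str, str] = {}
        with open(path) as fh:
            for ln, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                if "=" not in line:
                    raise ValueError(f"{path}:{ln}: expected key=value")
                key, val = line.split("=", 1)
                fields[key.strip()] = val.strip()
        required = {"w", "D", "t_factors"}
        missing = required - set(fields)
        if missing:
            raise ValueError(f"{path}: missing keys {sorted(missing)}")
        unknown = set(fields) - required - {"precision", "b_w"}
        if unknown:
            raise ValueError(f"{path}: unknown keys {sorted(unknown)}")
        return cls(
            w=int(fields["w"]),
            D=int(fields["D"]),
            t_factors=tuple(int(v) for v in fields["t_factors"].split(",")),
            precision=int(fields["precision"]) if "precision" in fields else None,
            b_w=float(fields["b_w"]) if "b_w" in fields else None,
        )

    def to_file(self, path) -> None:
        lines = [
            "# w-NIBNAF encoding configuration",
            f"w={self.w}",
            f"D={self.D}",
            f"t_factors={','.join(str(t) for t in self.t_factors)}",
            f"precision={self.precision}",
            f"b_w={self.b_w!r}",
        ]
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")


@dataclass(frozen=True)
class LaurentDigits:
    """Sparse signed-digit expansion: map exponent -> digit in {-1, 0, 1}."""

    digits: Mapping[int, int]
    validate: bool = True

    def __post_init__(self) -> None:
        if self.validate:
            for e, a in self.digits.items():
                if a not in (-1, 1):
                    raise ValueError("digits must be -1 or +1 (omit zeros)")
        object.__setattr__(self, "digits", dict(self.digits))

    @property
    def max_exp(self) -> int:
        return max(self.digits, default=0)

    @property
    def min_exp(self) -> int:
        return min(self.digits, default=0)

    @property
    def frac_span(self) -> int:
        """Number of fractional (negative-exponent) positions in use."""
        return max(0, -self.min_exp)

    def value(self, base: float) -> float:
        return sum(a * base**e for e, a in self.digits.items())


@dataclass
class PlaintextPoly:
    """Element of R_M (or of R when ``modulus`` is None), centered coefficients."""

    coeffs: list[int]
    modulus: int | None = None

    def __post_init__(self) -> None:
        self.coeffs = [int(c) for c in self.coeffs]
        if self.modulus is not None:
            self.coeffs = [centered(c, self.modulus) for c in self.coeffs]

    @property
    def D(self) -> int:
        return len(self.coeffs)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PlaintextPoly):
            return NotImplemented
        return self.coeffs == other.coeffs and self.modulus == other.modulus

    def reduce(self, modulus: int) -> "PlaintextPoly":
        return PlaintextPoly([centered(c, modulus) for c in self.coeffs], modulus)


def nibnaf_encode(theta: float, cfg: EncodingConfig) -> LaurentDigits:
    """Greedy w-NIBNAF expansion of ``theta``, truncated at ``cfg.precision``
    fractional digits.

    Raises EncodingError when the required exponent span exceeds D - 1.
    """
    b = cfg.b_w
    digits: dict[int, int] = {}
    rem = float(theta)
    min_exp = -cfg.precision
    logb = math.log(b)
    while rem != 0.0:
        mag = abs(rem)
        e = math.floor(math.log(mag) / logb)
        # guard against floating-point drift of the floor
        while b ** (e + 1) <= mag:
            e += 1
        while b**e > mag:
            e -= 1
        # nearest of b^e and b^(e+1); ties take the smaller exponent
        if (mag - b**e) <= (b ** (e + 1) - mag):
            pick = e
        else:
            pick = e + 1
        if pick < min_exp:
            break
        sign = 1 if rem > 0 else -1
        if pick in digits:  # cannot happen for a correct base; belt & braces
            raise EncodingError("digit collision in greedy expansion")
        digits[pick] = sign
        rem -= sign * b**pick
    out = LaurentDigits(digits, validate=False)
    if digits and out.max_exp - out.min_exp >= cfg.D:
        raise EncodingError(
            f"exponent span {out.max_exp - out.min_exp + 1} exceeds ring degree {cfg.D}"
        )
    return out


def laurent_fold(digits: LaurentDigits, D: int) -> PlaintextPoly:
    """Map a Laurent expansion into Z[X]/(X^D + 1).

    Non-negative exponents land at their own position; exponent -j wraps to
    position D - j with a sign flip (X^-j = -X^(D-j) since X^D = -1).
    """
    if digits.digits and digits.max_exp - digits.min_exp >= D:
        raise EncodingError("exponent span exceeds ring degree")
    coeffs = [0] * D
    for e, a in digits.digits.items():
        if e >= 0:
            pos, val = e, a
        else:
            pos, val = D + e, -a
        if pos >= D:
            raise EncodingError("exponent exceeds ring degree")
        if coeffs[pos] != 0:
            raise EncodingError(
                f"coefficient collision at position {pos}: ring degree too small"
            )
        coeffs[pos] = val
    return PlaintextPoly(coeffs, modulus=None)


def laurent_unfold(poly: PlaintextPoly, frac_span: int) -> dict[int, int]:
    """Inverse of the fold: read the top ``frac_span`` coefficients back as
    negative exponents (with the sign flipped back).  Returns a dense map
    exponent -> integer coefficient (not restricted to ternary digits, since
    after homomorphic arithmetic coefficients grow)."""
    D = poly.D
    if not 0 <= frac_span < D:
        raise ValueError("frac_span must satisfy 0 <= frac_span < D")
    out: dict[int, int] = {}
    for pos, c in enumerate(poly.coeffs):
        if c == 0:
            continue
        if pos >= D - frac_span:
            out[pos - D] = -c
        else:
            out[pos] = c
    return out


def nibnaf_decode(poly: PlaintextPoly, cfg: EncodingConfig, frac_span: int) -> float:
    """Evaluate a (possibly computed-upon) plaintext polynomial at b_w.

    ``frac_span`` declares how many top coefficients hold fractional
    positions; after k homomorphic multiplications it is the sum of the
    operands' spans.  Raises EncodingError when a coefficient sits at the
    centered-representative boundary of the modulus, i.e. when its sign is
    ambiguous and t was too small for the computation.
    """
    if poly.modulus is not None:
        lim = poly.modulus // 2
        for c in poly.coeffs:
            if abs(c) >= lim:
                raise EncodingError(
                    "coefficient at the modulus boundary: plaintext modulus too "
                    "small for this computation"
                )
    b = cfg.b_w
    total = 0.0
    for e, c in sorted(laurent_unfold(poly, frac_span).items()):
        total += c * b**e
    return total


def _crt_basis(t_factors: Sequence[int]) -> tuple[int, list[int]]:
    t = math.prod(t_factors)
    basis = []
    for ti in t_factors:
        mi = t // ti
        basis.append(mi * pow(mi, -1, ti))
    return t, basis


def crt_split(poly: PlaintextPoly, t_factors: Sequence[int]) -> list[PlaintextPoly]:
    """Coefficient-wise reduction of a plaintext polynomial modulo each
    factor, centered representatives."""
    for i, ti in enumerate(t_factors):
        for tj in t_factors[i + 1 :]:
            if math.gcd(ti, tj) != 1:
                raise ValueError("t_factors must be pairwise coprime")
    return [poly.reduce(ti) for ti in t_factors]


def crt_join(
    residues: Sequence[PlaintextPoly], t_factors: Sequence[int]
) -> PlaintextPoly:
    """Chinese-remainder reconstruction, inverse of :func:`crt_split` for
    coefficients in (-t/2, t/2]."""
    if len(residues) != len(t_factors):
        raise ValueError("one residue polynomial per modulus factor required")
    for i, ti in enumerate(t_factors):
        for tj in t_factors[i + 1 :]:
            if math.gcd(ti, tj) != 1:
                raise ValueError("t_factors must be pairwise coprime")
    D = residues[0].D
    if any(r.D != D for r in residues):
        raise ValueError("residue polynomials must share the ring degree")
    t, basis = _crt_basis(t_factors)
    coeffs = []
    for pos in range(D):
        acc = 0
        for r, m in zip(residues, basis):
            acc += r.coeffs[pos] * m
        coeffs.append(centered(acc, t))
    return PlaintextPoly(coeffs, modulus=t)


#: Shipped encoding presets.  "genomic" and "financial" use the published
#: plaintext factorizations for the two study datasets at ring degree 4096;
#: "toy" pairs with the small FV test parameters (see fv.PARAM_PRESETS) and
#: uses a single prime chosen from the package's own coefficient-growth bound
#: for the one-iteration training circuit (see docs/methods.md).
ENCODING_PRESETS: dict[str, EncodingConfig] = {
    "genomic": EncodingConfig(w=715, D=4096, t_factors=(5179, 5189, 5197)),
    "financial": EncodingConfig(w=150, D=4096, t_factors=(2237, 2239)),
    "toy": EncodingConfig(w=2, D=512, t_factors=(1073741827,)),
}
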