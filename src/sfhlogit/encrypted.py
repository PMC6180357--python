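"""One iteration of SFH logistic-regression training as an encrypted circuit.

The data owner encodes every covariate and label with w-NIBNAF, reduces the
encoding modulo each plaintext factor t_i, and encrypts one ciphertext per
value per factor (the intercept column is the public constant 1 and is
never encrypted, so a record costs d + 1 ciphertexts per factor: d
covariates plus the label).  The server then evaluates, independently for
every CRT factor:

  1. record row sums r_i = 1 + sum_j x_{i,j}          (additions only)
  2. Htilde diagonal  h_k = -1/4 sum_i x_{k,i} r_i    (ct-ct stage 1)
  3. gradient at beta=0  g_j = 1/2 sum_i y_i x_{i,j}  (ct-ct stage 2)
  4. one Newton-reciprocal step per diagonal entry,
     inv_k = x0 (2 - h_k x0)                          (ct-ct stages 3 and 4)
  5. model update  beta_k = -(inv_k * g_k)            (ct-ct stage 5)

for a total of exactly 5 ciphertext-ciphertext multiplication stages per
iteration (a stage applied elementwise across coordinates counts once; the
public constants 1/4, 1/2 and 2 enter as plaintext operations).  The
row-sum-first evaluation order keeps the operation count O(N d).

The same circuit can be replayed directly on the encoded plaintexts in
R_{t_i}; decryption of the homomorphic run must match it coefficient for
coefficient, which is the exactness property the test suite pins down.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from . import fv
from .encoding import (
    EncodingConfig,
    EncodingError,
    PlaintextPoly,
    crt_join,
    laurent_fold,
    nibnaf_decode,
    nibnaf_encode,
)
from .fv import Ciphertext, FVParams, KeyMaterial
from .ringpoly import centered, negacyclic_mul, poly_add, poly_neg
from .sfh import Dataset, ModelVector, newton_inversion_start

__all__ = [
    "CircuitReport",
    "EncValue",
    "EncryptedDataset",
    "encrypt_dataset",
    "encrypted_sfh_iteration",
    "decrypt_model",
    "plain_circuit_reference",
    "plain_circuit_growth",
    "encrypted_dataset_size_bits",
]


@dataclass
class CircuitReport:
    """Instrumentation of one circuit evaluation.

    ct_mults counts ciphertext-ciphertext multiplication *stages* (a stage
    applied elementwise across the d+1 coordinates counts once,
    multiplications by public plaintext constants are excluded);
    ct_ct_products is the raw number of tensor products behind them.
    """

    ct_mults: int = 0
    ct_adds: int = 0
    pt_mults: int = 0
    ct_ct_products: int = 0
    max_level: int = 0
    stages: list[str] = field(default_factory=list)

    def to_text(self) -> str:
        lines = [
            "circuit report",
            f"  ct-ct multiplication stages: {self.ct_mults}",
            f"  stage names: {', '.join(self.stages) if self.stages else '-'}",
            f"  raw ct-ct tensor products:   {self.ct_ct_products}",
            f"  ciphertext additions:        {self.ct_adds}",
            f"  plaintext multiplications:   {self.pt_mults}",
            f"  max multiplicative level:    {self.max_level}",
        ]
        return "\n".join(lines)


@dataclass
class _Meta:
    """Exponent-range bookkeeping for an encoded value.

    emin/emax bound the Laurent exponents in use; the fractional decode
    window is -emin, and it grows additively under multiplication.
    """

    emax: int
    emin: int

    def add(self, other: "_Meta") -> "_Meta":
        return _Meta(max(self.emax, other.emax), min(self.emin, other.emin))

    def mul(self, other: "_Meta") -> "_Meta":
        return _Meta(self.emax + other.emax, self.emin + other.emin)

    @property
    def frac_span(self) -> int:
        return max(0, -self.emin)


@dataclass
class EncValue:
    """One encoded real, encrypted once per CRT factor."""

    cts: list[Ciphertext]
    meta: _Meta


@dataclass
class EncryptedDataset:
    """Record-wise encrypted training set.

    x[i][j] is covariate j+1 of record i (the intercept is public and not
    stored); y[i] is the label.  Ciphertext count is T*(d+1)*N.
    """

    x: list[list[EncValue]]
    y: list[EncValue]
    N: int
    d: int
    cfg: EncodingConfig
    params: FVParams

    @property
    def T(self) -> int:
        return len(self.cfg.t_factors)

    @property
    def ciphertext_count(self) -> int:
        return self.T * (self.d + 1) * self.N

    @property
    def size_bits(self) -> int:
        return encrypted_dataset_size_bits(
            self.T, self.d, self.N, self.params.D, self.params.qbits
        )

    def manifest(self) -> dict:
        return {
            "N": self.N,
            "d": self.d,
            "T": self.T,
            "D": self.params.D,
            "qbits": self.params.qbits,
            "w": self.cfg.w,
            "precision": self.cfg.precision,
            "t_factors": list(self.cfg.t_factors),
            "ciphertext_count": self.ciphertext_count,
            "size_bits": self.size_bits,
        }


def encrypted_dataset_size_bits(T: int, d: int, N: int, D: int, log2q: int) -> int:
    """The closed-form encrypted-dataset size: T (d+1) N 2 D log2(q) bits."""
    return T * (d + 1) * N * 2 * D * log2q


def _factor_params(cfg: EncodingConfig, params: FVParams) -> list[FVParams]:
    return [params.with_t(ti) for ti in cfg.t_factors]


def _encode_meta(theta: float, cfg: EncodingConfig):
    digits = nibnaf_encode(theta, cfg)
    poly = laurent_fold(digits, cfg.D)
    if digits.digits:
        meta = _Meta(digits.max_exp, digits.min_exp)
    else:
        meta = _Meta(0, 0)
    return poly, meta


def encrypt_dataset(
    data: Dataset,
    cfg: EncodingConfig,
    params: FVParams,
    pk: tuple[list[int], list[int]],
    seed: int | np.random.Generator,
) -> EncryptedDataset:
    """Encode, CRT-split and encrypt every covariate and label of ``data``.

    Covariates must be encodable at the configured precision; binary values
    encode exactly as single digits.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    fparams = _factor_params(cfg, params)

    def enc_value(theta: float) -> EncValue:
        poly, meta = _encode_meta(theta, cfg)
        cts = []
        for fp in fparams:
            m = poly.reduce(fp.t)
            cts.append(fv.encrypt(pk, m.coeffs, fp, rng))
        return EncValue(cts=cts, meta=meta)

    x = [
        [enc_value(float(data.X[i, j + 1])) for j in range(data.d)]
        for i in range(data.N)
    ]
    y = [enc_value(float(data.y[i])) for i in range(data.N)]
    return EncryptedDataset(x=x, y=y, N=data.N, d=data.d, cfg=cfg, params=params)


class _CipherOps:
    """Homomorphic evaluation backend (one ciphertext per CRT factor)."""

    def __init__(
        self,
        cfg: EncodingConfig,
        params: FVParams,
        rlk,
        report: CircuitReport,
    ) -> None:
        self.cfg = cfg
        self.fparams = _factor_params(cfg, params)
        self.rlk = rlk
        self.report = report

    def begin_stage(self, name: str) -> None:
        self.report.ct_mults += 1
        self.report.stages.append(name)

    def constant(self, theta: float) -> EncValue:
        """Embed a public scalar as the transparent ciphertext (Delta*m, 0).

        It decrypts under any key and participates in genuine ct-ct
        multiplications; see docs/methods.md for why the reciprocal stages
        run ct-ct."""
        poly, meta = _encode_meta(theta, self.cfg)
        cts = []
        for fp in self.fparams:
            m = poly.reduce(fp.t)
            c0 = [centered(fp.Delta * c, fp.q) for c in m.coeffs]
            cts.append(Ciphertext(c=[c0, [0] * fp.D], params=fp))
        return EncValue(cts=cts, meta=meta)

    def add(self, a: EncValue, b: EncValue) -> EncValue:
        self.report.ct_adds += 1
        return EncValue(
            cts=[fv.ct_add(x, y) for x, y in zip(a.cts, b.cts)],
            meta=a.meta.add(b.meta),
        )

    def accumulate(self, vals: list[EncValue]) -> EncValue:
        out = vals[0]
        for v in vals[1:]:
            out = self.add(out, v)
        return out

    def add_const(self, a: EncValue, theta: float) -> EncValue:
        poly, meta = _encode_meta(theta, self.cfg)
        cts = [
            fv.ct_add_plain(ct, poly.reduce(fp.t).coeffs)
            for ct, fp in zip(a.cts, self.fparams)
        ]
        return EncValue(cts=cts, meta=a.meta.add(meta))

    def neg(self, a: EncValue) -> EncValue:
        return EncValue(cts=[fv.ct_neg(ct) for ct in a.cts], meta=a.meta)

    def _mul_meta(self, a: EncValue, b: EncValue) -> _Meta:
        meta = a.meta.mul(b.meta)
        if meta.emax - meta.emin >= self.cfg.D:
            raise EncodingError(
                "product exponent span exceeds the ring degree; increase D "
                "or lower the encoding precision"
            )
        return meta

    def tensor(self, a: EncValue, b: EncValue) -> EncValue:
        """ct-ct product without relinearization (3-component result)."""
        self.report.ct_ct_products += 1
        cts = [
            fv.ct_mul(x, y, None, fp, relin=False)
            for x, y, fp in zip(a.cts, b.cts, self.fparams)
        ]
        self.report.max_level = max(
            self.report.max_level, max(ct.level for ct in cts)
        )
        return EncValue(cts=cts, meta=self._mul_meta(a, b))

    def relin(self, a: EncValue) -> EncValue:
        return EncValue(
            cts=[
                fv.relinearize(ct, self.rlk, fp)
                for ct, fp in zip(a.cts, self.fparams)
            ],
            meta=a.meta,
        )

    def mul(self, a: EncValue, b: EncValue) -> EncValue:
        return self.relin(self.tensor(a, b))

    def pt_mul(self, a: EncValue, theta: float) -> EncValue:
        self.report.pt_mults += 1
        poly, meta = _encode_meta(theta, self.cfg)
        dummy = EncValue(cts=a.cts, meta=meta)
        out_meta = self._mul_meta(a, dummy)
        cts = [
            fv.pt_mul(ct, poly.reduce(fp.t).coeffs)
            for ct, fp in zip(a.cts, self.fparams)
        ]
        return EncValue(cts=cts, meta=out_meta)


class _PlainOps:
    """The same circuit on encoded plaintexts in R_{t_i} (or over the
    integers with ``moduli=[None]`` to measure coefficient growth)."""

    def __init__(
        self,
        cfg: EncodingConfig,
        moduli: list[int | None],
        report: CircuitReport | None = None,
    ) -> None:
        self.cfg = cfg
        self.moduli = moduli
        self.report = report or CircuitReport()

    def begin_stage(self, name: str) -> None:
        self.report.ct_mults += 1
        self.report.stages.append(name)

    def _reduce(self, poly: PlaintextPoly) -> list[PlaintextPoly]:
        return [
            poly if m is None else poly.reduce(m) for m in self.moduli
        ]

    def value(self, theta: float):
        poly, meta = _encode_meta(theta, self.cfg)
        return (self._reduce(poly), meta)

    constant = value

    def add(self, a, b):
        self.report.ct_adds += 1
        polys = [
            PlaintextPoly(poly_add(x.coeffs, y.coeffs), m)
            for x, y, m in zip(a[0], b[0], self.moduli)
        ]
        return (polys, a[1].add(b[1]))

    def accumulate(self, vals):
        out = vals[0]
        for v in vals[1:]:
            out = self.add(out, v)
        return out

    def add_const(self, a, theta: float):
        c, meta = self.value(theta)
        polys = [
            PlaintextPoly(poly_add(x.coeffs, y.coeffs), m)
            for x, y, m in zip(a[0], c, self.moduli)
        ]
        return (polys, a[1].add(meta))

    def neg(self, a):
        return (
            [PlaintextPoly(poly_neg(x.coeffs), m) for x, m in zip(a[0], self.moduli)],
            a[1],
        )

    def _mul(self, a, b):
        meta = a[1].mul(b[1])
        if meta.emax - meta.emin >= self.cfg.D:
            raise EncodingError("product exponent span exceeds the ring degree")
        polys = [
            PlaintextPoly(negacyclic_mul(x.coeffs, y.coeffs, m), m)
            for x, y, m in zip(a[0], b[0], self.moduli)
        ]
        return (polys, meta)

    def tensor(self, a, b):
        self.report.ct_ct_products += 1
        return self._mul(a, b)

    def relin(self, a):
        return a

    def mul(self, a, b):
        self.report.ct_ct_products += 1
        return self._mul(a, b)

    def pt_mul(self, a, theta: float):
        self.report.pt_mults += 1
        return self._mul(a, self.value(theta))


def _sfh_circuit(ops, xv, yv, N: int, d: int, x0: float):
    """The shared one-iteration circuit body; ``ops`` is either the
    homomorphic or the plaintext backend."""
    # row sums r_i = 1 + sum_j x_{i,j}: additions only
    r = [
        ops.add_const(ops.accumulate([xv[i][j] for j in range(d)]), 1.0)
        for i in range(N)
    ]
    # stage 1: Htilde diagonal, row-sum-first order (O(N d) products)
    ops.begin_stage("hessian-diag")
    h = [ops.accumulate(r)]  # entry 0: intercept column is all ones
    for k in range(d):
        acc = ops.accumulate([ops.tensor(xv[i][k], r[i]) for i in range(N)])
        h.append(ops.relin(acc))
    h = [ops.pt_mul(hk, -0.25) for hk in h]
    # stage 2: gradient at beta = 0 is (1/2) X^T y
    ops.begin_stage("gradient")
    g = [ops.accumulate(yv)]
    for j in range(d):
        acc = ops.accumulate([ops.tensor(yv[i], xv[i][j]) for i in range(N)])
        g.append(ops.relin(acc))
    g = [ops.pt_mul(gj, 0.5) for gj in g]
    # Newton reciprocal of each diagonal entry: inv = x0 (2 - h x0).
    # x0 is public but enters as a (transparent) ciphertext so both
    # reciprocal multiplications are ct-ct stages.
    ct_x0 = ops.constant(x0)
    ops.begin_stage("reciprocal-ax0")
    u = [ops.mul(hk, ct_x0) for hk in h]
    v = [ops.add_const(ops.neg(uk), 2.0) for uk in u]
    ops.begin_stage("reciprocal-outer")
    inv = [ops.mul(ct_x0, vk) for vk in v]
    # stage 5: beta = -Htilde^{-1} grad, componentwise
    ops.begin_stage("model-update")
    beta = [ops.neg(ops.mul(ik, gk)) for ik, gk in zip(inv, g)]
    return beta


def encrypted_sfh_iteration(
    enc: EncryptedDataset,
    cfg: EncodingConfig,
    params: FVParams,
    rlk,
    iters: int = 1,
    x0: float | None = None,
    mean_magnitude: float = 1.0,
) -> tuple[list[EncValue], CircuitReport]:
    """Evaluate ``iters`` (0 or 1) SFH iterations homomorphically.

    Returns the encrypted model coefficients and the circuit report.  The
    reciprocal start value ``x0`` is public, derived from the dataset
    dimensions (see :func:`sfhlogit.sfh.newton_inversion_start`).
    """
    if iters not in (0, 1):
        raise ValueError(
            "the encrypted circuit supports iters in {0, 1}: deeper circuits "
            "would exceed the scheme's practical depth for these parameters"
        )
    report = CircuitReport()
    if iters == 0:
        fparams = _factor_params(cfg, params)
        zero = [
            EncValue(
                cts=[
                    Ciphertext(c=[[0] * fp.D, [0] * fp.D], params=fp)
                    for fp in fparams
                ],
                meta=_Meta(0, 0),
            )
            for _ in range(enc.d + 1)
        ]
        return zero, report
    if x0 is None:
        x0 = newton_inversion_start(enc.N, enc.d, mean_magnitude)
    ops = _CipherOps(cfg, params, rlk, report)
    beta = _sfh_circuit(ops, enc.x, enc.y, enc.N, enc.d, x0)
    return beta, report


def decrypt_model(
    sk: list[int],
    enc_beta: list[EncValue],
    cfg: EncodingConfig,
    params: FVParams,
) -> ModelVector:
    """Per-factor decryption, CRT join, decode at the propagated fractional
    span.  Raises EncodingError when a joined coefficient sits at the
    modulus boundary (t too small for this computation)."""
    fparams = _factor_params(cfg, params)
    coeffs = []
    for ev in enc_beta:
        residues = [
            PlaintextPoly(fv.decrypt(sk, ct, fp), fp.t)
            for ct, fp in zip(ev.cts, fparams)
        ]
        joined = crt_join(residues, cfg.t_factors)
        coeffs.append(nibnaf_decode(joined, cfg, ev.meta.frac_span))
    return ModelVector(np.array(coeffs))


def _plain_inputs(ops: _PlainOps, data: Dataset):
    xv = [
        [ops.value(float(data.X[i, j + 1])) for j in range(data.d)]
        for i in range(data.N)
    ]
    yv = [ops.value(float(data.y[i])) for i in range(data.N)]
    return xv, yv


def plain_circuit_reference(
    data: Dataset,
    cfg: EncodingConfig,
    x0: float | None = None,
    mean_magnitude: float = 1.0,
) -> tuple[list[PlaintextPoly], list[int], ModelVector]:
    """Replay the circuit on the encoded plaintexts in R_t.

    Returns the per-coefficient result polynomials (joined mod t), their
    fractional spans, and the decoded model.  This is the oracle the
    homomorphic evaluation must match exactly.
    """
    if x0 is None:
        x0 = newton_inversion_start(data.N, data.d, mean_magnitude)
    ops = _PlainOps(cfg, list(cfg.t_factors))
    xv, yv = _plain_inputs(ops, data)
    beta = _sfh_circuit(ops, xv, yv, data.N, data.d, x0)
    polys, spans, vals = [], [], []
    for polys_k, meta in beta:
        joined = crt_join(polys_k, cfg.t_factors)
        polys.append(joined)
        spans.append(meta.frac_span)
        vals.append(nibnaf_decode(joined, cfg, meta.frac_span))
    return polys, spans, ModelVector(np.array(vals))


def plain_circuit_growth(
    data: Dataset,
    cfg: EncodingConfig,
    x0: float | None = None,
    mean_magnitude: float = 1.0,
) -> int:
    """Largest absolute integer coefficient the circuit produces when run
    over Z (no modulus): the package's own t_min analysis.  Decoding is
    correct iff this stays below t/2."""
    if x0 is None:
        x0 = newton_inversion_start(data.N, data.d, mean_magnitude)
    ops = _PlainOps(cfg, [None])
    xv, yv = _plain_inputs(ops, data)
    beta = _sfh_circuit(ops, xv, yv, data.N, data.d, x0)
    return max(
        max((abs(c) for c in polys[0].coeffs), default=0) for polys, _ in beta
    )
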