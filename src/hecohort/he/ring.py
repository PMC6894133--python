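"""Arithmetic in R_q = Z_q[X]/(X^n + 1) with q = 2^K.

Elements are stored as base-2^30 limb arrays (see :mod:`.limbs`).  Products
are exact: operands are reduced modulo a pool of NTT-friendly word primes,
multiplied by negacyclic NTT, and the integer result is recovered by a
Garner (mixed-radix) reconstruction directly into limb form, where the
BFV rescaling-by-t/q becomes a rounding bit shift.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import kernels, limbs
from .primes import primes_for_bound, primitive_root_2n

__all__ = ["RingElement", "ring_multiply", "ConvContext", "get_context"]


# --------------------------------------------------------------------------
# NTT plans and CRT contexts
# --------------------------------------------------------------------------

_plan_cache: dict[tuple[int, int], tuple] = {}
_ctx_cache: dict[tuple[int, tuple[int, ...]], "ConvContext"] = {}


def _bit_reverse_perm(n: int) -> np.ndarray:
    logn = n.bit_length() - 1
    idx = np.arange(n, dtype=np.int64)
    rev = np.zeros(n, dtype=np.int64)
    for _ in range(logn):
        rev = (rev << 1) | (idx & 1)
        idx >>= 1
    return rev


def _plan(n: int, p: int) -> tuple:
    key = (n, p)
    if key not in _plan_cache:
        psi = primitive_root_2n(p, 2 * n)
        ipsi = pow(psi, p - 2, p)
        rev = _bit_reverse_perm(n)
        pw = np.empty(n, dtype=np.int64)
        ipw = np.empty(n, dtype=np.int64)
        x = y = 1
        for i in range(n):
            pw[i] = x
            ipw[i] = y
            x = x * psi % p
            y = y * ipsi % p
        ninv = pow(n, p - 2, p)
        _plan_cache[key] = (pw[rev].copy(), ipw[rev].copy(), ninv)
    return _plan_cache[key]


def _mixed_radix_digits(x: int, primes: tuple[int, ...]) -> np.ndarray:
    out = np.empty(len(primes), dtype=np.int64)
    for i, p in enumerate(primes):
        out[i] = x % p
        x //= p
    return out


class ConvContext:
    """Cached NTT/CRT machinery for one (ring dimension, prime set) pair."""

    def __init__(self, n: int, primes: tuple[int, ...]):
        self.n = n
        self.primes = primes
        self.plans = [(p, 1.0 / p) + _plan(n, p) for p in primes]
        P = len(primes)
        # Garner tables
        self.prefix_mod = np.zeros((P, P), dtype=np.int64)
        self.invs = np.zeros(P, dtype=np.int64)
        for i, p in enumerate(primes):
            acc = 1
            for j in range(i):
                self.prefix_mod[i, j] = acc % p
                acc = acc * primes[j] % p
            self.invs[i] = pow(acc, p - 2, p) if i else 1
        M = 1
        for p in primes:
            M *= p
        self.modulus = M
        self.half_digits = _mixed_radix_digits((M - 1) // 2, primes)
        self._recon_cache: dict[int, tuple] = {}
        self._primes_arr = np.array(primes, dtype=np.int64)

    # -- residue side -----------------------------------------------------
    def residues_from_limbs(self, a: np.ndarray, K: int, centered: bool) -> np.ndarray:
        """(P, ...) residues of limb array ``a`` (shape (NB, ..., n))."""
        nb = a.shape[0]
        flat = np.ascontiguousarray(a.reshape(nb, -1))
        m = flat.shape[1]
        out = np.empty((len(self.primes), m), dtype=np.int64)
        topw, topb = divmod(K - 1, limbs.LIMB_BITS)
        for i, p in enumerate(self.primes):
            pows = np.array(
                [pow(2, limbs.LIMB_BITS * j, p) for j in range(nb)], dtype=np.int64
            )
            qtop = np.array([pow(2, K, p), topw, topb], dtype=np.int64)
            kernels.limbs_mod_p(flat, pows, p, 1 if centered else 0, qtop, out[i])
        return out.reshape((len(self.primes),) + a.shape[1:])

    def residues_from_small(self, vec: np.ndarray) -> np.ndarray:
        """Residues of small signed integer coefficients (shape (..., n))."""
        v = vec.astype(np.int64)
        return v[None, ...] % self._primes_arr.reshape(
            (len(self.primes),) + (1,) * v.ndim
        )

    # -- transforms --------------------------------------------------------
    def fwd(self, R: np.ndarray) -> np.ndarray:
        flat = R.reshape(len(self.primes), -1, self.n)
        for i, (p, pinv, psis, _ipsis, _ninv) in enumerate(self.plans):
            kernels.ntt_forward(flat[i], psis, p, pinv)
        return R

    def inv(self, R: np.ndarray) -> np.ndarray:
        flat = R.reshape(len(self.primes), -1, self.n)
        for i, (p, pinv, _psis, ipsis, ninv) in enumerate(self.plans):
            kernels.ntt_inverse(flat[i], ipsis, ninv, p, pinv)
        return R

    def mul_acc(self, out: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
        """out += a * b pointwise per prime (NTT domain)."""
        fo = out.reshape(len(self.primes), -1, self.n)
        fa = a.reshape(len(self.primes), -1, self.n)
        fb = b.reshape(len(self.primes), -1, self.n)
        for i, (p, pinv, *_rest) in enumerate(self.plans):
            kernels.pointwise_mul_acc(fo[i], fa[i], fb[i], p, pinv)
        return out

    # -- reconstruction ----------------------------------------------------
    def _recon_tables(self, B_bits: int) -> tuple:
        nb = limbs.num_limbs(B_bits)
        if nb not in self._recon_cache:
            P = len(self.primes)
            mod = 1 << (limbs.LIMB_BITS * nb)
            q_limbs = np.zeros((P, nb), dtype=np.int64)
            acc = 1
            for i, p in enumerate(self.primes):
                v = acc % mod
                for l in range(nb):
                    q_limbs[i, l] = (v >> (limbs.LIMB_BITS * l)) & limbs.LIMB_MASK
                acc *= p
            m_limbs = np.zeros(nb, dtype=np.int64)
            v = self.modulus % mod
            for l in range(nb):
                m_limbs[l] = (v >> (limbs.LIMB_BITS * l)) & limbs.LIMB_MASK
            self._recon_cache[nb] = (q_limbs, m_limbs, nb)
        return self._recon_cache[nb]

    def reconstruct(self, R: np.ndarray, S: int, K_out: int) -> np.ndarray:
        """Centered CRT value of residues ``R``, rounded-shifted by ``S``
        bits and reduced mod 2^K_out.  Returns limbs (NB_out, ..., n)."""
        P = len(self.primes)
        lead = R.shape[1:]
        flat = np.ascontiguousarray(R.reshape(P, -1))
        digits = np.empty_like(flat)
        kernels.garner_digits(flat, self._primes_arr, self.prefix_mod, self.invs, digits)
        q_limbs, m_limbs, nb = self._recon_tables(S + K_out)
        acc = np.empty((nb, flat.shape[1]), dtype=np.int64)
        kernels.digits_to_limbs(digits, self.half_digits, q_limbs, m_limbs, nb, acc)
        out = limbs.shift_right_round(acc, S, K_out)
        return out.reshape((out.shape[0],) + lead)


def get_context(n: int, bound_bits: float) -> ConvContext:
    """Context whose CRT modulus exceeds 2**bound_bits (signed-safe when the
    caller's magnitudes stay below 2**(bound_bits-1))."""
    primes = tuple(primes_for_bound(bound_bits))
    key = (n, primes)
    if key not in _ctx_cache:
        _ctx_cache[key] = ConvContext(n, primes)
    return _ctx_cache[key]


# --------------------------------------------------------------------------
# Public ring element
# --------------------------------------------------------------------------


@dataclass
class RingElement:
    """Element of Z_q[X]/(X^n+1), q = 2^K, coefficients stored in [0, q)."""

    limbs: np.ndarray  # (NB, n) int64
    n: int
    K: int

    @classmethod
    def from_coefficients(cls, coeffs, n: int, K: int) -> "RingElement":
        coeffs = list(coeffs)
        if len(coeffs) != n:
            raise ValueError(f"expected {n} coefficients, got {len(coeffs)}")
        return cls(limbs.from_ints(coeffs, K), n, K)

    @property
    def coefficients(self) -> list[int]:
        """Coefficients as Python ints in [0, q)."""
        return limbs.to_ints(self.limbs)

    def centered(self) -> list[int]:
        """Coefficients mapped to the centered interval (-q/2, q/2]."""
        q = 1 << self.K
        return [c - q if c > q // 2 else c for c in self.coefficients]

    def copy(self) -> "RingElement":
        return RingElement(self.limbs.copy(), self.n, self.K)

    def __add__(self, other: "RingElement") -> "RingElement":
        self._check(other)
        return RingElement(limbs.add(self.limbs.copy(), other.limbs, self.K), self.n, self.K)

    def __sub__(self, other: "RingElement") -> "RingElement":
        self._check(other)
        return RingElement(limbs.sub(self.limbs.copy(), other.limbs, self.K), self.n, self.K)

    def __neg__(self) -> "RingElement":
        return RingElement(limbs.neg(self.limbs.copy(), self.K), self.n, self.K)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, RingElement)
            and self.n == other.n
            and self.K == other.K
            and np.array_equal(self.limbs, other.limbs)
        )

    def _check(self, other: "RingElement") -> None:
        if self.n != other.n or self.K != other.K:
            raise ValueError("ring element mismatch: different n or q")


def ring_multiply(a: RingElement, b: RingElement) -> RingElement:
    """Negacyclic product a*b mod (X^n+1, 2^K), computed exactly."""
    a._check(b)
    n, K = a.n, a.K
    bound = 2 + math.log2(n) + 2 * (K - 1)
    ctx = get_context(n, bound)
    ra = ctx.residues_from_limbs(a.limbs, K, centered=True)
    rb = ctx.residues_from_limbs(b.limbs, K, centered=True)
    ctx.fwd(ra)
    ctx.fwd(rb)
    out = np.zeros_like(ra)
    ctx.mul_acc(out, ra, rb)
    ctx.inv(out)
    return RingElement(ctx.reconstruct(out, 0, K), n, K)
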