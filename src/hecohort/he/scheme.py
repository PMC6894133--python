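"""Textbook Fan-Vercauteren (FV/BFV) somewhat-homomorphic encryption.

Scalar integer payloads are encoded as constant polynomials of R_t and
scaled by Delta = q/t; secret keys and encryption randomness are ternary;
errors are centered-binomial.  Supported homomorphic operations are
exactly the ones the encrypted-cohort analyses exercise: addition chains
and bounded-depth multiplication with base-2^w relinearization.

Batched variants (``encrypt_batch``, ``decrypt_batch``, ``ct_sum``) are
vectorized forms of the scalar operations used by the pipelines; they are
bit-identical to looping the scalar API.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import limbs
from .params import HEParams
from .ring import ConvContext, RingElement, get_context

__all__ = [
    "SecretKey",
    "PublicKey",
    "RelinKey",
    "Plaintext",
    "Ciphertext",
    "NoiseExhaustedError",
    "keygen",
    "encrypt",
    "encrypt_batch",
    "decrypt",
    "decrypt_batch",
    "he_add",
    "he_mult",
    "he_mult_no_relin",
    "relinearize",
    "noise_budget",
    "checked_decrypt",
    "ct_sum",
]


class NoiseExhaustedError(RuntimeError):
    """Raised by checked_decrypt when the noise corrupted the payload."""


# --------------------------------------------------------------------------
# Key material and containers
# --------------------------------------------------------------------------


@dataclass
class SecretKey:
    s: np.ndarray  # ternary coefficients, shape (n,), int64
    params: HEParams
    _s2: np.ndarray | None = field(default=None, repr=False)  # s^2, small ints

    @property
    def s_squared(self) -> np.ndarray:
        if self._s2 is None:
            n = self.params.n
            ctx = get_context(n, 2 + math.log2(n))
            r = ctx.residues_from_small(self.s[None, :])
            ctx.fwd(r)
            out = np.zeros_like(r)
            ctx.mul_acc(out, r, r)
            ctx.inv(out)
            lim = ctx.reconstruct(out, 0, 2 * (n.bit_length() + 1))
            vals = limbs.to_ints(lim)
            K2 = 2 * (n.bit_length() + 1)
            q2 = 1 << K2
            object.__setattr__(
                self,
                "_s2",
                np.array([v - q2 if v > q2 // 2 else v for v in vals], dtype=np.int64),
            )
        return self._s2


@dataclass
class PublicKey:
    p0: RingElement
    p1: RingElement
    params: HEParams
    _enc_cache: dict = field(default_factory=dict, repr=False)


@dataclass
class RelinKey:
    pairs: list[tuple[RingElement, RingElement]]
    w_bits: int
    params: HEParams
    _ntt_cache: dict = field(default_factory=dict, repr=False)


@dataclass
class Plaintext:
    """Signed scalar payload, encoded as a constant polynomial of R_t."""

    value: int

    def encode(self, params: HEParams) -> int:
        if abs(self.value) > params.max_value:
            raise ValueError(
                f"payload {self.value} outside plaintext range "
                f"[-{params.max_value}, {params.max_value}]"
            )
        return self.value % params.t

    @staticmethod
    def decode(residue: int, params: HEParams) -> int:
        t = params.t
        r = residue % t
        return r - t if r > t // 2 else r


@dataclass
class Ciphertext:
    parts: list[RingElement]
    params: HEParams

    @property
    def size(self) -> int:
        return len(self.parts)

    def copy(self) -> "Ciphertext":
        return Ciphertext([p.copy() for p in self.parts], self.params)


# --------------------------------------------------------------------------
# Sampling
# --------------------------------------------------------------------------


def _ternary(rng: np.random.Generator, shape) -> np.ndarray:
    return rng.integers(-1, 2, size=shape, dtype=np.int64)


def _cbd(rng: np.random.Generator, shape, eta: int) -> np.ndarray:
    return (rng.binomial(2 * eta, 0.5, size=shape) - eta).astype(np.int64)


def _uniform_limbs(rng: np.random.Generator, K: int, shape) -> np.ndarray:
    nb = limbs.num_limbs(K)
    out = np.empty((nb,) + shape, dtype=np.int64)
    for i in range(nb - 1):
        out[i] = rng.integers(0, 1 << limbs.LIMB_BITS, size=shape, dtype=np.int64)
    out[nb - 1] = rng.integers(0, limbs.top_mask(K) + 1, size=shape, dtype=np.int64)
    return out


# --------------------------------------------------------------------------
# Contexts per parameter set
# --------------------------------------------------------------------------


def _enc_ctx(p: HEParams) -> ConvContext:
    # centered operand (<= q/2) times ternary: |coeff| <= n*q/2
    return get_context(p.n, math.log2(p.n) + p.qbits + 2)


def _mult_ctx(p: HEParams, extra_bits: float = 0.0) -> ConvContext:
    # centered x centered, two cross terms: |coeff| <= n*q^2/2
    return get_context(p.n, math.log2(p.n) + 2 * p.qbits + 2 + extra_bits)


def _relin_ctx(p: HEParams) -> ConvContext:
    ell = p.relin_terms
    return get_context(
        p.n, math.log2(ell) + math.log2(p.n) + p.w_bits + p.qbits + 2
    )


def _dec_ctx(p: HEParams, s2_max: int) -> ConvContext:
    extra = max(1, int(s2_max)).bit_length()
    return get_context(p.n, math.log2(p.n) + p.qbits + 2 + extra)


# --------------------------------------------------------------------------
# Key generation
# --------------------------------------------------------------------------


def keygen(
    params: HEParams, rng: np.random.Generator
) -> tuple[SecretKey, PublicKey, RelinKey]:
    """Generate (secret, public, relinearization) keys.

    Deterministic in the generator state: the same seeded ``rng`` yields
    bit-identical keys.
    """
    n, K = params.n, params.qbits
    s = _ternary(rng, n)
    sk = SecretKey(s, params)
    ctx = _enc_ctx(params)
    rs = ctx.residues_from_small(s[None, :])
    ctx.fwd(rs)

    def minus_as_plus_e(a_limbs: np.ndarray, e: np.ndarray) -> np.ndarray:
        """-(a*s + e) mod q, from limbs of a and small e."""
        ra = ctx.residues_from_limbs(a_limbs, K, centered=True)
        ctx.fwd(ra)
        acc = np.zeros_like(ra)
        ctx.mul_acc(acc, ra, rs)
        ctx.inv(acc)
        prod = ctx.reconstruct(acc, 0, K)  # a*s mod q, shape (NB, 1, n)
        out = limbs.add(prod, limbs.from_int64(e, K), K)
        return limbs.neg(out, K)

    # public key
    a = _uniform_limbs(rng, K, (1, n))
    e = _cbd(rng, (1, n), params.error_eta)
    p0 = minus_as_plus_e(a, e)
    pk = PublicKey(
        RingElement(p0[:, 0, :], n, K),
        RingElement(a[:, 0, :], n, K),
        params,
    )

    # relinearization key: b_i = -(a_i s + e_i) + 2^(w i) s^2
    s2 = sk.s_squared
    s2_limbs = limbs.from_int64(s2[None, :], K)
    pairs = []
    for i in range(params.relin_terms):
        a_i = _uniform_limbs(rng, K, (1, n))
        e_i = _cbd(rng, (1, n), params.error_eta)
        b_i = minus_as_plus_e(a_i, e_i)
        term = limbs.shift_left(s2_limbs, params.w_bits * i, K)
        b_i = limbs.add(b_i, term, K)
        pairs.append(
            (RingElement(b_i[:, 0, :], n, K), RingElement(a_i[:, 0, :], n, K))
        )
    rlk = RelinKey(pairs, params.w_bits, params)
    return sk, pk, rlk


# --------------------------------------------------------------------------
# Encryption / decryption
# --------------------------------------------------------------------------


def _pk_ntt(pk: PublicKey) -> tuple[np.ndarray, np.ndarray, ConvContext]:
    ctx = _enc_ctx(pk.params)
    key = id(ctx)
    if key not in pk._enc_cache:
        K = pk.params.qbits
        r0 = ctx.residues_from_limbs(pk.p0.limbs[:, None, :], K, centered=True)
        r1 = ctx.residues_from_limbs(pk.p1.limbs[:, None, :], K, centered=True)
        ctx.fwd(r0)
        ctx.fwd(r1)
        pk._enc_cache[key] = (r0, r1)
    r0, r1 = pk._enc_cache[key]
    return r0, r1, ctx


def encrypt_batch(
    pk: PublicKey, values, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Encrypt a vector of payloads; returns limb arrays (NB, B, n) x2."""
    p = pk.params
    n, K = p.n, p.qbits
    encoded = [Plaintext(int(v)).encode(p) for v in np.asarray(values).ravel()]
    B = len(encoded)
    r0, r1, ctx = _pk_ntt(pk)
    u = _ternary(rng, (B, n))
    e1 = _cbd(rng, (B, n), p.error_eta)
    e2 = _cbd(rng, (B, n), p.error_eta)
    ru = ctx.residues_from_small(u)
    ctx.fwd(ru)
    prim = np.array(ctx.primes, dtype=np.int64).reshape(-1, 1, 1)
    prod0 = (ru * r0) % prim
    prod1 = (ru * r1) % prim
    ctx.inv(prod0)
    ctx.inv(prod1)
    c0 = ctx.reconstruct(prod0, 0, K)
    c1 = ctx.reconstruct(prod1, 0, K)
    c0 += limbs.from_int64(e1, K)
    c1 += limbs.from_int64(e2, K)
    # Delta * m goes on the constant coefficient only
    dm = limbs.shift_left(limbs.from_ints(encoded, K), p.delta_bits, K)
    c0[:, :, 0] += dm
    limbs.normalize(c0, K)
    limbs.normalize(c1, K)
    return c0, c1


def encrypt(pk: PublicKey, m, rng: np.random.Generator) -> Ciphertext:
    """Encrypt one payload (int or Plaintext) into a size-2 ciphertext."""
    value = m.value if isinstance(m, Plaintext) else int(m)
    c0, c1 = encrypt_batch(pk, [value], rng)
    n, K = pk.params.n, pk.params.qbits
    return Ciphertext(
        [RingElement(c0[:, 0, :], n, K), RingElement(c1[:, 0, :], n, K)],
        pk.params,
    )


def _phase_batch(sk: SecretKey, parts: list[np.ndarray]) -> np.ndarray:
    """v = c0 + c1*s (+ c2*s^2) mod q for batched limb parts (NB, B, n)."""
    p = sk.params
    n, K = p.n, p.qbits
    s2_max = int(np.abs(sk.s_squared).max()) if len(parts) == 3 else 1
    ctx = _dec_ctx(p, s2_max)
    rs = ctx.residues_from_small(sk.s[None, :])
    ctx.fwd(rs)
    B = parts[1].shape[1]
    acc = None
    keys = [None, sk.s, sk.s_squared if len(parts) == 3 else None]
    for idx in (1, 2):
        if idx >= len(parts):
            break
        rc = ctx.residues_from_limbs(parts[idx], K, centered=True)
        ctx.fwd(rc)
        rk = ctx.residues_from_small(keys[idx][None, :])
        ctx.fwd(rk)
        if acc is None:
            acc = np.zeros_like(rc)
        prim = np.array(ctx.primes, dtype=np.int64).reshape(-1, 1, 1)
        acc = (acc + rc * rk) % prim
    ctx.inv(acc)
    prod = ctx.reconstruct(acc, 0, K)
    v = limbs.add(prod, parts[0], K)
    return v


def decrypt_batch(sk: SecretKey, parts: list[np.ndarray]) -> np.ndarray:
    """Decrypt batched limb parts; returns int64 array of payloads (B,)."""
    p = sk.params
    v = _phase_batch(sk, parts)
    m_u = limbs.shift_right_round(v, p.delta_bits, p.tbits + 1)
    residue = (m_u[0, :, 0] % p.t).astype(np.int64)
    t = p.t
    return np.where(residue > t // 2, residue - t, residue)


def _ct_limbs(ct: Ciphertext) -> list[np.ndarray]:
    return [part.limbs[:, None, :] for part in ct.parts]


def decrypt(sk: SecretKey, ct: Ciphertext) -> int:
    """Decrypt a size-2 or size-3 ciphertext to its signed payload."""
    if ct.size not in (2, 3):
        raise ValueError("ciphertext must have 2 or 3 parts")
    return int(decrypt_batch(sk, _ct_limbs(ct))[0])


def checked_decrypt(sk: SecretKey, ct: Ciphertext, expected: int) -> int:
    """Known-plaintext noise audit (testing utility, not an analysis op).

    Decrypts and compares with the expected payload; a mismatch means the
    noise budget was exhausted somewhere along the homomorphic circuit.
    """
    got = decrypt(sk, ct)
    if got != expected:
        raise NoiseExhaustedError(
            f"noise exhausted: decrypted {got}, expected {expected}"
        )
    return got


def noise_budget(sk: SecretKey, ct: Ciphertext) -> float:
    """Remaining headroom, in bits: log2(q / (2 t |noise|)), clipped at 0.

    Diagnostic only -- requires the secret key and never appears on the
    analysis path.
    """
    p = sk.params
    v = _phase_batch(sk, _ct_limbs(ct))
    m_u = limbs.shift_right_round(v, p.delta_bits, p.tbits + 1)
    residue = m_u[0, :, 0] % p.t
    dm = limbs.shift_left(
        limbs.from_ints([int(r) for r in residue], p.qbits), p.delta_bits, p.qbits
    )
    r = v.copy()
    r[:, :, 0] -= dm
    limbs.normalize(r, p.qbits)
    mag = limbs.centered_abs_max(r, p.qbits)
    mag = max(mag, 1.0)
    return max(0.0, p.qbits - 1 - p.tbits - math.log2(mag))


# --------------------------------------------------------------------------
# Homomorphic operations
# --------------------------------------------------------------------------


def _check_compat(ct1: Ciphertext, ct2: Ciphertext) -> None:
    if ct1.params != ct2.params:
        raise ValueError("ciphertexts under different parameter sets")


def he_add(ct1: Ciphertext, ct2: Ciphertext) -> Ciphertext:
    """Homomorphic addition; size-2 operands are zero-padded to match a
    size-3 operand."""
    _check_compat(ct1, ct2)
    p = ct1.params
    n, K = p.n, p.qbits
    size = max(ct1.size, ct2.size)
    zero = RingElement(limbs.zeros(K, (n,)), n, K)
    parts = []
    for i in range(size):
        a = ct1.parts[i] if i < ct1.size else zero
        b = ct2.parts[i] if i < ct2.size else zero
        parts.append(a + b)
    return Ciphertext(parts, p)


def he_mult_no_relin(ct1: Ciphertext, ct2: Ciphertext) -> Ciphertext:
    """Tensor product with t/q rescaling: size-3 ciphertext, no relin."""
    _check_compat(ct1, ct2)
    if ct1.size != 2 or ct2.size != 2:
        raise ValueError("multiplication requires size-2 operands")
    p = ct1.params
    n, K = p.n, p.qbits
    ctx = _mult_ctx(p)
    r = [
        ctx.residues_from_limbs(part.limbs[:, None, :], K, centered=True)
        for part in (*ct1.parts, *ct2.parts)
    ]
    for x in r:
        ctx.fwd(x)
    c0r, c1r, d0r, d1r = r
    prim = np.array(ctx.primes, dtype=np.int64).reshape(-1, 1, 1)
    e0 = (c0r * d0r) % prim
    e1 = (c0r * d1r + c1r * d0r) % prim
    e2 = (c1r * d1r) % prim
    parts = []
    S = p.qbits - p.tbits  # multiply by t/q = 2^-(K - tau), rounding
    for e in (e0, e1, e2):
        ctx.inv(e)
        parts.append(RingElement(ctx.reconstruct(e, S, K)[:, 0, :], n, K))
    return Ciphertext(parts, p)


def relinearize(ct: Ciphertext, rlk: RelinKey) -> Ciphertext:
    """Key-switch a size-3 ciphertext back to size 2."""
    if ct.size != 3:
        raise ValueError("relinearization expects a size-3 ciphertext")
    p = ct.params
    n, K = p.n, p.qbits
    ctx = _relin_ctx(p)
    key = id(ctx)
    if key not in rlk._ntt_cache:
        cache = []
        for b_i, a_i in rlk.pairs:
            rb = ctx.residues_from_limbs(b_i.limbs[:, None, :], K, centered=True)
            ra = ctx.residues_from_limbs(a_i.limbs[:, None, :], K, centered=True)
            ctx.fwd(rb)
            ctx.fwd(ra)
            cache.append((rb, ra))
        rlk._ntt_cache[key] = cache
    cache = rlk._ntt_cache[key]
    # base-2^w digits of c2 (unsigned representation)
    c2 = ct.parts[2].limbs
    digits = _extract_digits(c2, K, rlk.w_bits)
    acc_b = None
    acc_a = None
    prim = np.array(ctx.primes, dtype=np.int64).reshape(-1, 1, 1)
    for d, (rb, ra) in zip(digits, cache):
        rd = ctx.residues_from_small(d[None, :])
        ctx.fwd(rd)
        if acc_b is None:
            acc_b = np.zeros_like(rd)
            acc_a = np.zeros_like(rd)
        acc_b = (acc_b + rd * rb) % prim
        acc_a = (acc_a + rd * ra) % prim
    ctx.inv(acc_b)
    ctx.inv(acc_a)
    add_b = ctx.reconstruct(acc_b, 0, K)[:, 0, :]
    add_a = ctx.reconstruct(acc_a, 0, K)[:, 0, :]
    c0 = RingElement(limbs.add(ct.parts[0].limbs.copy(), add_b, K), n, K)
    c1 = RingElement(limbs.add(ct.parts[1].limbs.copy(), add_a, K), n, K)
    return Ciphertext([c0, c1], p)


def _extract_digits(a: np.ndarray, K: int, w_bits: int) -> list[np.ndarray]:
    """Base-2^w digits (int64, < 2^w) of limb vectors in [0, 2^K)."""
    ints_needed = -(-K // w_bits)
    out = []
    for i in range(ints_needed):
        lo_bit = w_bits * i
        word, rem = divmod(lo_bit, limbs.LIMB_BITS)
        val = a[word] >> rem
        got = limbs.LIMB_BITS - rem
        j = word + 1
        while got < w_bits and j < a.shape[0]:
            val = val | (a[j] << got)
            got += limbs.LIMB_BITS
            j += 1
        out.append(val & ((1 << w_bits) - 1))
    return out


def he_mult(ct1: Ciphertext, ct2: Ciphertext, rlk: RelinKey) -> Ciphertext:
    """Homomorphic multiplication with relinearization (size-2 result)."""
    return relinearize(he_mult_no_relin(ct1, ct2), rlk)


def ct_sum(cts: list[Ciphertext]) -> Ciphertext:
    """Homomorphic sum of many ciphertexts (repeated he_add, vectorized)."""
    if not cts:
        raise ValueError("empty ciphertext sum")
    p = cts[0].params
    for ct in cts:
        _check_compat(cts[0], ct)
    size = max(ct.size for ct in cts)
    n, K = p.n, p.qbits
    parts = []
    for i in range(size):
        stack = [ct.parts[i].limbs for ct in cts if ct.size > i]
        acc = np.sum(np.stack(stack, axis=0), axis=0)
        parts.append(RingElement(limbs.normalize(acc, K), n, K))
    return Ciphertext(parts, p)
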