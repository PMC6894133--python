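"""Numba kernels: exact negacyclic NTT and CRT-to-limb reconstruction.

All arithmetic is exact int64.  Modular products use the float-reciprocal
trick: with ``p < 2^31`` the product ``v*S`` fits in int64 and the float64
estimate of ``v*S/p`` is within one unit of the true quotient, so a single
conditional correction lands the remainder in ``[0, p)``.
"""

from __future__ import annotations

import numpy as np
from numba import njit

LIMB_BITS = 30
LIMB_MASK = (1 << LIMB_BITS) - 1


@njit(cache=True)
def ntt_forward(a, psis, p, pinv):
    """In-place forward negacyclic NTT (Cooley-Tukey, decimation in time).

    ``a`` has shape (batch, n) with entries in [0, p); ``psis`` holds powers
    of a primitive 2n-th root of unity in bit-reversed order.  Output is the
    negacyclic spectrum in bit-reversed order (consistent with ntt_inverse).
    """
    batch, n = a.shape
    for b in range(batch):
        row = a[b]
        t = n
        m = 1
        while m < n:
            t //= 2
            for i in range(m):
                S = psis[m + i]
                Sf = S * pinv
                j1 = 2 * i * t
                for j in range(j1, j1 + t):
                    v = row[j + t]
                    q = np.int64(np.float64(v) * Sf)
                    r = v * S - q * p
                    if r < 0:
                        r += p
                    elif r >= p:
                        r -= p
                    u = row[j]
                    x = u + r
                    if x >= p:
                        x -= p
                    y = u - r
                    if y < 0:
                        y += p
                    row[j] = x
                    row[j + t] = y
            m *= 2


@njit(cache=True)
def ntt_inverse(a, ipsis, ninv, p, pinv):
    """In-place inverse of :func:`ntt_forward` (Gentleman-Sande)."""
    batch, n = a.shape
    ninvf = ninv * pinv
    for b in range(batch):
        row = a[b]
        t = 1
        m = n
        while m > 1:
            h = m // 2
            for i in range(h):
                S = ipsis[h + i]
                Sf = S * pinv
                j1 = 2 * i * t
                for j in range(j1, j1 + t):
                    u = row[j]
                    v = row[j + t]
                    x = u + v
                    if x >= p:
                        x -= p
                    d = u - v
                    if d < 0:
                        d += p
                    q = np.int64(np.float64(d) * Sf)
                    r = d * S - q * p
                    if r < 0:
                        r += p
                    elif r >= p:
                        r -= p
                    row[j] = x
                    row[j + t] = r
            t *= 2
            m = h
        for j in range(n):
            v = row[j]
            q = np.int64(np.float64(v) * ninvf)
            r = v * ninv - q * p
            if r < 0:
                r += p
            elif r >= p:
                r -= p
            row[j] = r


@njit(cache=True)
def pointwise_mul_acc(out, a, b, p, pinv):
    """out += a*b (mod p), elementwise, shapes (batch, n)."""
    batch, n = out.shape
    for i in range(batch):
        for j in range(n):
            v = a[i, j] * b[i, j]
            q = np.int64(np.float64(a[i, j]) * (b[i, j] * pinv))
            r = v - q * p
            if r < 0:
                r += p
            elif r >= p:
                r -= p
            x = out[i, j] + r
            if x >= p:
                x -= p
            out[i, j] = x


@njit(cache=True)
def limbs_mod_p(limbs, pows, p, centered, qtop_residue, out):
    """Reduce base-2^30 limb vectors modulo a small prime.

    ``limbs`` has shape (NB, m) and represents values in [0, 2^K).  When
    ``centered`` is nonzero, values with bit K-1 set (top bit of the top
    limb, passed via ``qtop_residue = (2^K mod p, topbit_limb, topbit)``)
    are interpreted as value - 2^K.
    """
    nb, m = limbs.shape
    qmodp = qtop_residue[0]
    top_l = qtop_residue[1]
    top_b = qtop_residue[2]
    for j in range(m):
        acc = np.int64(0)
        for i in range(nb):
            acc = (acc + limbs[i, j] * pows[i]) % p
        if centered != 0:
            if (limbs[top_l, j] >> top_b) & 1:
                acc -= qmodp
                if acc < 0:
                    acc += p
        out[j] = acc


@njit(cache=True)
def garner_digits(res, primes, prefix_mod, invs, out):
    """Mixed-radix (Garner) digits of the CRT value.

    ``res``: (P, m) residues; ``prefix_mod[i, j] = (p_0*...*p_{j-1}) mod p_i``;
    ``invs[i] = (p_0*...*p_{i-1})^{-1} mod p_i``.  ``out``: (P, m) digits with
    ``x = sum_i out[i] * p_0*...*p_{i-1}``, each ``out[i] in [0, p_i)``.
    """
    P, m = res.shape
    for j in range(m):
        for i in range(P):
            p = primes[i]
            v = np.int64(0)
            for k in range(i):
                v = (v + out[k, j] * prefix_mod[i, k]) % p
            d = (res[i, j] - v) % p
            if i > 0:
                d = (d * invs[i]) % p
            out[i, j] = d


@njit(cache=True)
def digits_to_limbs(digits, half_digits, q_limbs, m_limbs, nb, out):
    """Centered CRT value as base-2^30 limbs modulo 2^B.

    ``digits``: (P, m) Garner digits of x in [0, M).  ``half_digits``: the
    mixed-radix digits of floor(M/2).  ``q_limbs[i]``: limbs of
    (p_0*...*p_{i-1}) mod 2^B.  ``m_limbs``: limbs of M mod 2^B.  Output
    ``out``: (nb, m) limbs of (x if x <= M/2 else x - M) mod 2^B, i.e. the
    two's-complement image of the centered value.
    """
    P, m = digits.shape
    for j in range(m):
        for l in range(nb):
            out[l, j] = 0
        # accumulate sum_i d_i * Q_i with periodic carry propagation
        for i in range(P):
            d = digits[i, j]
            carry = np.int64(0)
            for l in range(nb):
                v = out[l, j] + d * q_limbs[i, l] + carry
                out[l, j] = v & LIMB_MASK
                carry = v >> LIMB_BITS
            # carry out of the top limb is dropped: arithmetic is mod 2^B
        # lexicographic compare with M/2 from the most significant digit
        greater = False
        for i in range(P - 1, -1, -1):
            if digits[i, j] != half_digits[i]:
                greater = digits[i, j] > half_digits[i]
                break
        if greater:
            borrow = np.int64(0)
            for l in range(nb):
                v = out[l, j] - m_limbs[l] + borrow
                out[l, j] = v & LIMB_MASK
                borrow = v >> LIMB_BITS
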