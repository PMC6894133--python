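"""Base-2^30 limb vectors over int64 numpy arrays.

A ring element modulo ``q = 2^K`` is stored as an array of shape
``(NB, n)`` with ``NB = ceil(K/30)``; limb ``i`` holds bits
``[30*i, 30*i+30)`` of each coefficient.  Everything here is vectorized
int64 with explicit carry propagation, so no Python bignums appear on hot
paths; conversion helpers to and from Python integers exist for
serialization and tests.
"""

from __future__ import annotations

import numpy as np

LIMB_BITS = 30
LIMB_MASK = (1 << LIMB_BITS) - 1


def num_limbs(K: int) -> int:
    return -(-K // LIMB_BITS)


def top_mask(K: int) -> int:
    """Bit mask for the (partial) top limb of a K-bit value."""
    r = K - LIMB_BITS * (num_limbs(K) - 1)
    return (1 << r) - 1


def zeros(K: int, shape: tuple[int, ...]) -> np.ndarray:
    return np.zeros((num_limbs(K),) + shape, dtype=np.int64)


def normalize(a: np.ndarray, K: int) -> np.ndarray:
    """Propagate carries/borrows in place; reduce mod 2^K."""
    nb = a.shape[0]
    carry = None
    for i in range(nb):
        if carry is not None:
            a[i] += carry
        carry = a[i] >> LIMB_BITS
        a[i] &= LIMB_MASK
    a[nb - 1] &= top_mask(K)
    return a


def add(a: np.ndarray, b: np.ndarray, K: int) -> np.ndarray:
    return normalize(a + b, K)


def sub(a: np.ndarray, b: np.ndarray, K: int) -> np.ndarray:
    return normalize(a - b, K)


def neg(a: np.ndarray, K: int) -> np.ndarray:
    return normalize(-a, K)


def iadd(a: np.ndarray, b: np.ndarray, K: int) -> np.ndarray:
    a += b
    return normalize(a, K)


def from_ints(values, K: int) -> np.ndarray:
    """Limbs of an iterable of Python ints (values taken mod 2^K)."""
    vals = [int(v) % (1 << K) for v in values]
    nb = num_limbs(K)
    out = np.empty((nb, len(vals)), dtype=np.int64)
    for i in range(nb):
        out[i] = [(v >> (LIMB_BITS * i)) & LIMB_MASK for v in vals]
    return out


def to_ints(a: np.ndarray) -> list[int]:
    nb = a.shape[0]
    flat = a.reshape(nb, -1)
    out = [0] * flat.shape[1]
    for i in range(nb):
        row = flat[i]
        for j in range(flat.shape[1]):
            out[j] |= int(row[j]) << (LIMB_BITS * i)
    return out


def from_int64(vec: np.ndarray, K: int) -> np.ndarray:
    """Limbs of a vector of small signed ints (taken mod 2^K)."""
    nb = num_limbs(K)
    out = np.zeros((nb,) + vec.shape, dtype=np.int64)
    neg_mask = vec < 0
    v = np.abs(vec.astype(np.int64))
    for i in range(nb):
        if LIMB_BITS * i >= 63:
            break
        out[i] = (v >> (LIMB_BITS * i)) & LIMB_MASK
    if neg_mask.any():
        out[:, neg_mask] *= -1
        normalize(out, K)
    return out


def shift_left(a: np.ndarray, bits: int, K: int) -> np.ndarray:
    """(a << bits) mod 2^K, carry-normalized."""
    nb = num_limbs(K)
    words, rem = divmod(bits, LIMB_BITS)
    out = np.zeros_like(a)
    for i in range(nb):
        src = i - words
        if src < 0:
            continue
        out[i] = (a[src] << rem) & LIMB_MASK
        if rem and src >= 1:
            out[i] |= a[src - 1] >> (LIMB_BITS - rem)
    out[nb - 1] &= top_mask(K)
    return out


def shift_right_round(a: np.ndarray, S: int, K_out: int) -> np.ndarray:
    """floor((a + 2^(S-1)) / 2^S) mod 2^K_out on two's-complement limbs.

    ``a`` holds at least S + K_out significant bits; the result is exact
    for centered values by the usual two's-complement argument.
    """
    a = a.copy()
    if S > 0:
        w, b = divmod(S - 1, LIMB_BITS)
        a[w] += 1 << b
        normalize(a, a.shape[0] * LIMB_BITS)
    nb_out = num_limbs(K_out)
    words, rem = divmod(S, LIMB_BITS)
    out = np.zeros((nb_out,) + a.shape[1:], dtype=np.int64)
    nb_in = a.shape[0]
    for i in range(nb_out):
        src = i + words
        if src >= nb_in:
            break
        out[i] = a[src] >> rem
        if rem and src + 1 < nb_in:
            out[i] |= (a[src + 1] << (LIMB_BITS - rem)) & LIMB_MASK
    out[nb_out - 1] &= top_mask(K_out)
    return out


def top_bit(a: np.ndarray, K: int) -> np.ndarray:
    """Boolean array: is bit K-1 set (i.e. value >= 2^(K-1))."""
    w, b = divmod(K - 1, LIMB_BITS)
    return ((a[w] >> b) & 1).astype(bool)


def to_float(a: np.ndarray) -> np.ndarray:
    """Approximate float64 value of each coefficient (for diagnostics)."""
    out = np.zeros(a.shape[1:], dtype=np.float64)
    for i in range(a.shape[0]):
        out += a[i].astype(np.float64) * float(2 ** (LIMB_BITS * i))
    return out


def centered_abs_max(a: np.ndarray, K: int) -> float:
    """max |centered value| over the vector, as a float (diagnostic)."""
    vals = to_float(a)
    q = float(2**K)
    vals = np.where(vals > q / 2, q - vals, vals)
    return float(vals.max()) if vals.size else 0.0


def small_to_unsigned(vec: np.ndarray, K: int) -> np.ndarray:
    """Limbs of small signed int64 values reduced into [0, 2^K)."""
    return from_int64(vec, K)
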