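"""NTT-friendly prime pool.

The exact negacyclic convolutions behind ring multiplication run modulo a
set of word-sized primes and are recombined by the Chinese remainder
theorem.  Every prime ``p`` satisfies ``p = 1 (mod 2^17)`` so a primitive
``2n``-th root of unity exists for every supported ring dimension
(``n <= 2^16``), and ``p < 2^31`` so NTT butterflies stay inside exact
int64 arithmetic.
"""

from __future__ import annotations

import math

import sympy

MAX_LOG2_N = 16  # largest supported ring dimension is 2**16
_STEP = 1 << (MAX_LOG2_N + 1)
_HI = 1 << 31

_pool: list[int] = []


def ntt_primes(count: int) -> list[int]:
    """Return the first ``count`` primes ``p < 2^31`` with ``p = 1 mod 2^17``.

    Scans downward from ``2^31`` so the pool is deterministic; results are
    cached for the lifetime of the process.
    """
    c = _pool[-1] - _STEP if _pool else (_HI // _STEP) * _STEP + 1
    while len(_pool) < count:
        if c < _HI and sympy.isprime(c):
            _pool.append(c)
        c -= _STEP
    return _pool[:count]


def primes_for_bound(bound_bits: float) -> list[int]:
    """Smallest prefix of the pool whose product exceeds ``2**bound_bits``.

    The caller guarantees every reconstructed integer has magnitude below
    ``2**(bound_bits - 1)`` so that centered CRT lifting is unambiguous.
    """
    acc = 0.0
    k = 0
    while acc <= bound_bits:
        k += 1
        acc = sum(math.log2(p) for p in ntt_primes(k))
    return ntt_primes(k)


def primitive_root_2n(p: int, two_n: int) -> int:
    """A primitive ``two_n``-th root of unity modulo ``p``."""
    g = sympy.primitive_root(p)
    return pow(g, (p - 1) // two_n, p)
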