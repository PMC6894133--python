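"""Parameter selection for the FV scheme.

A parameter set fixes the ring dimension ``n``, ciphertext modulus
``q = 2^K``, plaintext modulus ``t`` (a power of two exceeding twice the
largest payload magnitude), the error distribution, and the
relinearization decomposition base.  ``derive_params`` picks the smallest
ring from a fixed security table that leaves enough modulus headroom for
the requested multiplicative depth, using a heuristic noise-growth model
whose constants were fixed by direct measurement of decryption residuals
(see docs/methods.md); the depth guarantee is certified empirically by
``certify_depth``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = ["HEParams", "derive_params", "SECURITY_TABLE", "ParameterError"]

# Maximum log2(q) per (security level, ring dimension) for ternary secrets,
# classical security, following the published homomorphic-encryption
# security standard.
SECURITY_TABLE: dict[int, dict[int, int]] = {
    128: {1024: 27, 2048: 54, 4096: 109, 8192: 218, 16384: 438, 32768: 881},
    256: {1024: 14, 2048: 29, 4096: 58, 8192: 118, 16384: 237, 32768: 476},
}

# Centered-binomial error: e = Binomial(2*eta, 1/2) - eta, sd = sqrt(eta/2).
ERROR_ETA = 20  # sd = sqrt(10) ~ 3.16, the standard sigma ~ 3.2 choice

# Noise model constants (bits), calibrated against measured residuals.
_C_FRESH = 5.0  # fresh noise ~ sigma * sqrt(n) * 2^_C_FRESH
_C_MULT = 5.0  # per-multiplication growth ~ t * sqrt(n) * 2^_C_MULT
_C_RELIN = 3.0
_HEADROOM = 20.0  # post-depth budget left for additions


class ParameterError(ValueError):
    """No parameter set in the security table satisfies the request."""


@dataclass(frozen=True)
class HEParams:
    """FV parameter set over R_q = Z_q[X]/(X^n+1), q = 2^K.

    Attributes
    ----------
    n : ring dimension (power of two)
    qbits : K, with ciphertext modulus q = 2^K
    t : plaintext modulus (power of two, > 2*max_value)
    error_eta : centered-binomial parameter (sd = sqrt(eta/2))
    w_bits : relinearization decomposition base is 2^w_bits
    security_bits : targeted classical security level (128 or 256)
    mult_depth : certified multiplicative depth L
    max_value : largest payload magnitude the plaintext space must hold
    """

    n: int
    qbits: int
    t: int
    error_eta: int
    w_bits: int
    security_bits: int
    mult_depth: int
    max_value: int

    def __post_init__(self):
        if self.n & (self.n - 1) or self.n < 2:
            raise ValueError("ring dimension must be a power of two >= 2")
        if self.t <= 2 * self.max_value:
            raise ValueError("plaintext modulus must exceed 2*max_value")
        if self.delta < 2:
            raise ValueError("scaling factor q/t must be at least 2")

    @property
    def q(self) -> int:
        return 1 << self.qbits

    @property
    def tbits(self) -> int:
        return self.t.bit_length() - 1

    @property
    def delta_bits(self) -> int:
        """log2 of the plaintext scaling factor Delta = q/t."""
        return self.qbits - self.tbits

    @property
    def delta(self) -> int:
        return 1 << self.delta_bits

    @property
    def sigma(self) -> float:
        """Standard deviation of the error distribution."""
        return math.sqrt(self.error_eta / 2.0)

    @property
    def relin_terms(self) -> int:
        """Number of base-2^w digits in a relinearization key."""
        return -(-self.qbits // self.w_bits)


def _fresh_bits(n: int) -> float:
    return math.log2(math.sqrt(ERROR_ETA / 2.0)) + 0.5 * math.log2(n) + _C_FRESH


def _level_bits(n: int, tbits: int) -> float:
    return tbits + 0.5 * math.log2(n) + _C_MULT


def _relin_bits(n: int, qbits: int, w_bits: int) -> float:
    ell = -(-qbits // w_bits)
    return (
        math.log2(ell)
        + w_bits
        + 0.5 * math.log2(n)
        + math.log2(math.sqrt(ERROR_ETA / 2.0))
        + _C_RELIN
    )


def _required_qbits(n: int, tbits: int, L: int, w_bits: int) -> int:
    """Fixed-point solve for the modulus size needed at depth L."""
    K = 40
    for _ in range(8):
        start = _fresh_bits(n)
        if L > 0:
            start = max(start, _relin_bits(n, K, w_bits))
        K_new = math.ceil(1 + tbits + start + L * _level_bits(n, tbits) + _HEADROOM)
        if K_new == K:
            break
        K = K_new
    return K


def plaintext_modulus_for(max_value: int) -> int:
    """Smallest power-of-two plaintext modulus with t > 2*max_value."""
    t = 1 << (2 * max_value + 1).bit_length()
    if t <= 2 * max_value:  # exact power of two edge
        t <<= 1
    return max(t, 4)


def derive_params(
    security_bits: int, max_value: int = 1000, mult_depth: int = 0
) -> HEParams:
    """Smallest table entry supporting the requested security level,
    payload range and multiplicative depth.

    Raises :class:`ParameterError` when even the largest ring at the
    requested security level cannot accommodate the depth, naming the
    binding constraint.
    """
    if security_bits not in SECURITY_TABLE:
        raise ParameterError(
            f"unsupported security level {security_bits}; "
            f"choose one of {sorted(SECURITY_TABLE)}"
        )
    if max_value < 1:
        raise ParameterError("max_value must be at least 1")
    if mult_depth < 0:
        raise ParameterError("mult_depth must be non-negative")
    t = plaintext_modulus_for(max_value)
    tbits = t.bit_length() - 1
    table = SECURITY_TABLE[security_bits]
    for n in sorted(table):
        cap = table[n]
        # decomposition base: small for small moduli, larger once digit
        # counts would explode (noise floor stays far below the budget)
        for w_bits in (8, 32):
            K = _required_qbits(n, tbits, mult_depth, w_bits)
            if w_bits == 8 and K > 160:
                continue
            if K <= cap and K > tbits + 1:
                return HEParams(
                    n=n,
                    qbits=K,
                    t=t,
                    error_eta=ERROR_ETA,
                    w_bits=w_bits,
                    security_bits=security_bits,
                    mult_depth=mult_depth,
                    max_value=max_value,
                )
    raise ParameterError(
        "parameters unattainable: depth "
        f"L={mult_depth} with plaintext modulus t={t} needs "
        f"~{_required_qbits(max(table), tbits, mult_depth, 32)} modulus bits, "
        f"but the largest ring (n={max(table)}) at {security_bits}-bit "
        f"security allows only {table[max(table)]}"
    )
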