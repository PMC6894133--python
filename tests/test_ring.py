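"""Ring arithmetic in Z_q[X]/(X^n+1): exactness against a schoolbook oracle."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from hecohort.he import limbs
from hecohort.he.ring import RingElement, ring_multiply

from conftest import schoolbook_negacyclic


@pytest.mark.parametrize(
    "n,K",
    [(8, 20), (16, 45), (32, 62), (64, 94), (16, 263), (8, 457)],
)
def test_multiply_matches_schoolbook_oracle(n, K):
    """NTT/CRT products equal the brute-force negacyclic convolution,
    across single-limb and many-limb modulus sizes."""
    q = 1 << K
    rng = np.random.default_rng(n * 1000 + K)
    for _ in range(3):
        a = [int.from_bytes(rng.bytes(K // 8 + 1), "little") % q for _ in range(n)]
        b = [int.from_bytes(rng.bytes(K // 8 + 1), "little") % q for _ in range(n)]
        got = ring_multiply(
            RingElement.from_coefficients(a, n, K),
            RingElement.from_coefficients(b, n, K),
        )
        assert got.coefficients == schoolbook_negacyclic(a, b, n, q)


def test_negacyclic_wraparound_closed_form():
    """(1 + X)(1 - X) = 1 - X^2 = 2 in Z_q[X]/(X^2+1)."""
    n, K = 2, 30
    a = RingElement.from_coefficients([1, 1], n, K)
    b = RingElement.from_coefficients([1, (1 << K) - 1], n, K)
    assert ring_multiply(a, b).coefficients == [2, 0]


def test_multiplicative_identity():
    n, K = 16, 76
    rng = np.random.default_rng(0)
    a = RingElement.from_coefficients(
        [int(x) << 20 for x in rng.integers(0, 2**30, n)], n, K
    )
    one = RingElement.from_coefficients([1] + [0] * (n - 1), n, K)
    assert ring_multiply(a, one) == a


def test_ring_axioms_additive():
    n, K = 8, 45
    q = 1 << K
    rng = np.random.default_rng(3)
    a, b = (
        RingElement.from_coefficients([int(x) for x in rng.integers(0, q, n)], n, K)
        for _ in range(2)
    )
    assert (a + b).coefficients == [(x + y) % q for x, y in zip(a.coefficients, b.coefficients)]
    assert a + b == b + a
    assert (a - a).coefficients == [0] * n
    assert (-a + a).coefficients == [0] * n


def test_mismatched_elements_rejected():
    a = RingElement.from_coefficients([1, 2], 2, 30)
    b = RingElement.from_coefficients([1, 2, 3, 4], 4, 30)
    c = RingElement.from_coefficients([1, 2], 2, 40)
    with pytest.raises(ValueError):
        ring_multiply(a, b)
    with pytest.raises(ValueError):
        ring_multiply(a, c)
    with pytest.raises(ValueError):
        RingElement.from_coefficients([1, 2, 3], 4, 30)


@given(
    st.lists(st.integers(min_value=-(2**80), max_value=2**80), min_size=1, max_size=8),
    st.sampled_from([31, 45, 62, 90, 130]),
)
def test_limb_int_roundtrip(values, K):
    """from_ints/to_ints are mutually inverse modulo 2^K."""
    arr = limbs.from_ints(values, K)
    assert limbs.to_ints(arr) == [v % (1 << K) for v in values]


@given(
    st.lists(st.integers(min_value=0, max_value=2**90 - 1), min_size=2, max_size=6),
    st.integers(min_value=0, max_value=89),
)
def test_limb_shift_right_round(values, S):
    """Rounding right-shift on limbs equals integer rounding division."""
    K_in = 90
    K_out = K_in - S if K_in > S else 1
    arr = limbs.from_ints(values, K_in)
    got = limbs.to_ints(limbs.shift_right_round(arr, S, K_out))
    expect = [((v + (1 << (S - 1) if S else 0)) >> S) % (1 << K_out) for v in values]
    assert got == expect


def test_limb_add_sub_carry_chain():
    K = 95
    q = 1 << K
    vals = [q - 1, q // 2, 12345, 0]
    other = [1, q // 2 + 5, q - 1, q - 1]
    a = limbs.from_ints(vals, K)
    b = limbs.from_ints(other, K)
    assert limbs.to_ints(limbs.add(a.copy(), b, K)) == [(x + y) % q for x, y in zip(vals, other)]
    assert limbs.to_ints(limbs.sub(a.copy(), b, K)) == [(x - y) % q for x, y in zip(vals, other)]
    assert limbs.to_ints(limbs.neg(a.copy(), K)) == [(-x) % q for x in vals]
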