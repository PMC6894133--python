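"""FV scheme: roundtrips, homomorphisms, noise behavior, serialization."""

import numpy as np
import pytest

import hecohort as hc
from hecohort.he import serialize
from hecohort.he.params import derive_params
from hecohort.he.scheme import decrypt_batch, encrypt_batch


# --------------------------------------------------------------------------
# encrypt / decrypt
# --------------------------------------------------------------------------


def test_roundtrip_sweep(add_params, add_keys, rng):
    """decrypt(encrypt(m)) = m for 100 random payloads across the range."""
    sk, pk, _ = add_keys
    M = add_params.max_value
    vals = rng.integers(-M, M + 1, 100)
    c0, c1 = encrypt_batch(pk, vals, rng)
    assert np.array_equal(decrypt_batch(sk, [c0, c1]), vals)


def test_roundtrip_boundaries(add_params, add_keys, rng):
    sk, pk, _ = add_keys
    M = add_params.max_value
    for m in (0, 1, -1, M, -M):
        assert hc.decrypt(sk, hc.encrypt(pk, m, rng)) == m


def test_out_of_range_payload_rejected(add_params, add_keys, rng):
    _, pk, _ = add_keys
    with pytest.raises(ValueError, match="range"):
        hc.encrypt(pk, add_params.max_value + 1, rng)


def test_probabilistic_encryption(add_keys, rng):
    """Two encryptions of one payload differ but decrypt identically."""
    sk, pk, _ = add_keys
    a = hc.encrypt(pk, 17, rng)
    b = hc.encrypt(pk, 17, rng)
    assert a.parts[0] != b.parts[0]
    assert hc.decrypt(sk, a) == hc.decrypt(sk, b) == 17


def test_keygen_and_encryption_deterministic(add_params):
    sk1, pk1, rlk1 = hc.keygen(add_params, np.random.default_rng(99))
    sk2, pk2, rlk2 = hc.keygen(add_params, np.random.default_rng(99))
    assert np.array_equal(sk1.s, sk2.s)
    assert pk1.p0 == pk2.p0 and pk1.p1 == pk2.p1
    assert all(b1 == b2 and a1 == a2
               for (b1, a1), (b2, a2) in zip(rlk1.pairs, rlk2.pairs))
    ct1 = hc.encrypt(pk1, 23, np.random.default_rng(7))
    ct2 = hc.encrypt(pk2, 23, np.random.default_rng(7))
    assert ct1.parts[0] == ct2.parts[0] and ct1.parts[1] == ct2.parts[1]


# --------------------------------------------------------------------------
# homomorphisms
# --------------------------------------------------------------------------


def test_additive_homomorphism(add_keys, rng):
    sk, pk, _ = add_keys
    a, b = hc.encrypt(pk, 3, rng), hc.encrypt(pk, 4, rng)
    assert hc.decrypt(sk, hc.he_add(a, b)) == 7
    assert hc.decrypt(sk, hc.he_add(b, a)) == 7
    z = hc.he_add(hc.encrypt(pk, 0, rng), hc.encrypt(pk, 0, rng))
    assert hc.decrypt(sk, z) == 0


def test_flag_counting_matches_plaintext(rng):
    """A homomorphic sum of 1000 0/1 flags decrypts to the number of ones
    (plaintext modulus sized to hold the count)."""
    params = hc.counting_params(1000)
    sk, pk, _ = hc.keygen(params, rng)
    flags = rng.integers(0, 2, 1000)
    c0, c1 = encrypt_batch(pk, flags, rng)
    from hecohort.he import limbs
    from hecohort.he.ring import RingElement

    p = pk.params
    s0 = limbs.normalize(c0.sum(axis=1), p.qbits)
    s1 = limbs.normalize(c1.sum(axis=1), p.qbits)
    total = hc.Ciphertext(
        [RingElement(s0, p.n, p.qbits), RingElement(s1, p.n, p.qbits)], p
    )
    assert hc.decrypt(sk, total) == int(flags.sum())


def test_ct_sum_equals_folded_he_add(add_keys, rng):
    sk, pk, _ = add_keys
    vals = [5, -3, 11, 0, 7]
    cts = [hc.encrypt(pk, v, rng) for v in vals]
    folded = cts[0]
    for ct in cts[1:]:
        folded = hc.he_add(folded, ct)
    summed = hc.ct_sum(cts)
    assert hc.decrypt(sk, summed) == hc.decrypt(sk, folded) == sum(vals)


def test_multiplicative_homomorphism(mult_keys, rng):
    sk, pk, rlk = mult_keys
    x, y = hc.encrypt(pk, 6, rng), hc.encrypt(pk, 7, rng)
    assert hc.decrypt(sk, hc.he_mult(x, y, rlk)) == 42
    zero = hc.encrypt(pk, 0, rng)
    m = hc.encrypt(pk, 55, rng)
    assert hc.decrypt(sk, hc.he_mult(m, zero, rlk)) == 0


def test_random_products_exact(mult_params, mult_keys, rng):
    sk, pk, rlk = mult_keys
    lim = int(np.sqrt(mult_params.max_value))
    for _ in range(25):
        a, b = (int(v) for v in rng.integers(-lim, lim + 1, 2))
        ct = hc.he_mult(hc.encrypt(pk, a, rng), hc.encrypt(pk, b, rng), rlk)
        assert hc.decrypt(sk, ct) == a * b


def test_size3_decrypt_equals_relinearized(mult_keys, rng):
    """Decryption with s^2 before relinearization matches after."""
    sk, pk, rlk = mult_keys
    for a, b in [(9, 8), (-7, 6), (10, -10)]:
        raw = hc.he_mult_no_relin(hc.encrypt(pk, a, rng), hc.encrypt(pk, b, rng))
        assert raw.size == 3
        rel = hc.relinearize(raw, rlk)
        assert rel.size == 2
        assert hc.decrypt(sk, raw) == hc.decrypt(sk, rel) == a * b


def test_size3_plus_size2_addition(mult_keys, rng):
    sk, pk, rlk = mult_keys
    prod = hc.he_mult_no_relin(hc.encrypt(pk, 4, rng), hc.encrypt(pk, 5, rng))
    ct = hc.he_add(prod, hc.encrypt(pk, 3, rng))
    assert ct.size == 3
    assert hc.decrypt(sk, ct) == 23


def test_parameter_mismatch_rejected(add_keys, mult_keys, rng):
    _, pk_a, _ = add_keys
    _, pk_m, _ = mult_keys
    with pytest.raises(ValueError, match="parameter"):
        hc.he_add(hc.encrypt(pk_a, 1, rng), hc.encrypt(pk_m, 1, rng))


# --------------------------------------------------------------------------
# noise behavior
# --------------------------------------------------------------------------


def test_fresh_ciphertext_has_positive_budget(add_keys, mult_keys, rng):
    for sk, pk, _ in (add_keys, mult_keys):
        assert hc.noise_budget(sk, hc.encrypt(pk, 5, rng)) > 0


def test_noise_budget_monotone_decreasing(mult_keys, rng):
    sk, pk, rlk = mult_keys
    ct = hc.encrypt(pk, 2, rng)
    b0 = hc.noise_budget(sk, ct)
    added = hc.he_add(ct, hc.encrypt(pk, 3, rng))
    b_add = hc.noise_budget(sk, added)
    mult = hc.he_mult(ct, hc.encrypt(pk, 3, rng), rlk)
    b_mult = hc.noise_budget(sk, mult)
    assert b_add <= b0
    assert b_mult < b0


def test_multiplication_consumes_more_budget_than_addition(mult_keys, rng):
    """Paired trials: mean budget loss per multiplication exceeds the mean
    loss per addition (noise grows faster under multiplication)."""
    sk, pk, rlk = mult_keys
    add_losses, mult_losses = [], []
    for _ in range(30):
        a = hc.encrypt(pk, int(rng.integers(1, 10)), rng)
        b = hc.encrypt(pk, int(rng.integers(1, 10)), rng)
        b0 = hc.noise_budget(sk, a)
        add_losses.append(b0 - hc.noise_budget(sk, hc.he_add(a, b)))
        mult_losses.append(b0 - hc.noise_budget(sk, hc.he_mult(a, b, rlk)))
    assert np.mean(mult_losses) > np.mean(add_losses)


def test_checked_decrypt_flags_noise_exhaustion(mult_params, mult_keys, rng):
    """Chaining multiplications past the certified depth corrupts the
    payload, and the known-plaintext audit reports it."""
    sk, pk, rlk = mult_keys
    ct = hc.encrypt(pk, 2, rng)
    assert hc.checked_decrypt(sk, ct, 2) == 2
    for _ in range(12):  # far beyond mult_depth = 1
        ct = hc.he_mult(ct, hc.encrypt(pk, 1, rng), rlk)
        if hc.noise_budget(sk, ct) == 0.0:
            break
    with pytest.raises(hc.NoiseExhaustedError, match="noise exhausted"):
        hc.checked_decrypt(sk, ct, 2)


@pytest.mark.parametrize("lam,depth,trials", [(128, 1, 10), (128, 4, 3), (128, 8, 2)])
def test_depth_certificate(lam, depth, trials):
    """Parameter sets derived for depth L survive an L-step multiplication
    chain with budget to spare."""
    p = derive_params(lam, max_value=1000, mult_depth=depth)
    for trial in range(trials):
        rng = np.random.default_rng(1000 + trial)
        sk, pk, rlk = hc.keygen(p, rng)
        ct = hc.encrypt(pk, 2, rng)
        for _ in range(depth):
            ct = hc.he_mult(ct, hc.encrypt(pk, 1, rng), rlk)
        assert hc.decrypt(sk, ct) == 2
        assert hc.noise_budget(sk, ct) > 0


# --------------------------------------------------------------------------
# serialization
# --------------------------------------------------------------------------


def test_key_serialization_roundtrip(mult_keys):
    sk, pk, rlk = mult_keys
    sk2 = serialize.load_secret_key(serialize.dump_secret_key(sk))
    pk2 = serialize.load_public_key(serialize.dump_public_key(pk))
    rlk2 = serialize.load_relin_key(serialize.dump_relin_key(rlk))
    assert np.array_equal(sk.s, sk2.s)
    assert pk.p0 == pk2.p0 and pk.p1 == pk2.p1
    assert sk.params == sk2.params == pk2.params
    assert all(b1 == b2 and a1 == a2
               for (b1, a1), (b2, a2) in zip(rlk.pairs, rlk2.pairs))


def test_ciphertext_serialization_roundtrip(mult_keys, rng):
    sk, pk, rlk = mult_keys
    ct2 = hc.encrypt(pk, -42, rng)
    ct3 = hc.he_mult_no_relin(hc.encrypt(pk, 6, rng), hc.encrypt(pk, 9, rng))
    for ct in (ct2, ct3):
        back = serialize.load_ciphertext(serialize.dump_ciphertext(ct))
        assert back.size == ct.size
        assert all(p1 == p2 for p1, p2 in zip(ct.parts, back.parts))
        assert hc.decrypt(sk, back) == hc.decrypt(sk, ct)


def test_serialization_rejects_wrong_kind(mult_keys):
    sk, pk, _ = mult_keys
    blob = serialize.dump_public_key(pk)
    with pytest.raises(ValueError, match="kind"):
        serialize.load_secret_key(blob)
    bad = dict(blob, version=99)
    with pytest.raises(ValueError, match="version"):
        serialize.load_public_key(bad)
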