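"""Encrypted cohort analyses.

Two challenges run over the encrypted cohort:

1. *Responder identification*: every patient's per-month 0/1 responder
   flag is encrypted individually; the per-month homomorphic sum over
   patients yields the cumulative identification curve, decrypted once at
   the end of the study.
2. *Total drug exposure*: per patient and month, encrypted body weight
   (integer kg) is multiplied by encrypted dose (fixed-point tenths of
   mg/kg) under encryption and the monthly products are summed, giving
   total exposure in 0.1 mg units with a single final decryption.

Neither analysis touches a secret key: counting and exposure aggregation
are functions of public-key material and ciphertexts only; decryption of
the aggregate results is a separate, final step.  Plaintext oracles for
both analyses live here as well and back the exactness tests.
"""

from __future__ import annotations

import math
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import Cohort, CohortParams, PatientRecord
from .he import limbs
from .he.params import HEParams, ParameterError, derive_params
from .he.ring import RingElement, get_context
from .he.scheme import (
    Ciphertext,
    PublicKey,
    SecretKey,
    decrypt_batch,
    encrypt_batch,
    keygen,
)

__all__ = [
    "EncryptedFlagMatrix",
    "IdentificationCurve",
    "ExposureResult",
    "TimingLog",
    "MilestoneUnreached",
    "encrypt_flag_matrix",
    "count_responders_by_month",
    "decrypt_counts",
    "milestone_months",
    "encrypted_total_exposure",
    "run_study",
    "timing_harness",
    "oracle_identification_curve",
    "oracle_total_exposure",
    "counting_params",
    "exposure_params",
    "exposure_max_value",
]


class MilestoneUnreached(ValueError):
    """The identification curve never reaches the requested milestone."""


# --------------------------------------------------------------------------
# Data containers
# --------------------------------------------------------------------------


@dataclass
class EncryptedFlagMatrix:
    """Per-patient, per-month encrypted responder flags.

    Limb arrays have shape (NB, n_patients, study_months, n); no plaintext
    flag is retained.
    """

    c0: np.ndarray
    c1: np.ndarray
    params: HEParams

    @property
    def n_patients(self) -> int:
        return self.c0.shape[1]

    @property
    def study_months(self) -> int:
        return self.c0.shape[2]

    def ciphertext(self, patient: int, month: int) -> Ciphertext:
        n, K = self.params.n, self.params.qbits
        return Ciphertext(
            [
                RingElement(self.c0[:, patient, month, :].copy(), n, K),
                RingElement(self.c1[:, patient, month, :].copy(), n, K),
            ],
            self.params,
        )


@dataclass
class IdentificationCurve:
    """Cumulative count of identified exceptional responders per month."""

    counts: np.ndarray  # (study_months,) non-negative ints

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if (np.diff(self.counts) < 0).any():
            raise ValueError("identification curve must be non-decreasing")

    @property
    def months(self) -> np.ndarray:
        return np.arange(self.counts.size)

    @property
    def final_count(self) -> int:
        return int(self.counts[-1]) if self.counts.size else 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"month": self.months, "count": self.counts})


@dataclass
class ExposureResult:
    """Total drug exposure for one patient, in fixed-point 0.1 mg units."""

    patient_id: str
    total_units: int
    n_months: int

    @property
    def total_exposure_mg(self) -> float:
        return self.total_units / 10.0


@dataclass
class TimingLog:
    """Wall-clock seconds per pipeline stage, shaped like the study's
    timing tables (informational; hardware-dependent)."""

    rows: list[dict] = field(default_factory=list)

    def add(self, **kwargs) -> None:
        self.rows.append(kwargs)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


# --------------------------------------------------------------------------
# Parameter helpers
# --------------------------------------------------------------------------


def counting_params(n_patients: int, security_bits: int = 128) -> HEParams:
    """Parameters for flag counting: the plaintext space must hold the
    final count, i.e. t > n_patients."""
    return derive_params(security_bits, max_value=max(1000, n_patients), mult_depth=0)


def exposure_max_value(params: CohortParams) -> int:
    """Worst-case fixed-point exposure total: months x max kg x max tenths."""
    return int(
        params.study_months * round(params.weight_max) * round(params.dose_max * 10)
    )


def exposure_params(cohort_params: CohortParams, security_bits: int = 128) -> HEParams:
    return derive_params(
        security_bits, max_value=exposure_max_value(cohort_params), mult_depth=1
    )


# --------------------------------------------------------------------------
# Plaintext oracles
# --------------------------------------------------------------------------


def oracle_identification_curve(cohort: Cohort) -> IdentificationCurve:
    """Plaintext-equivalent identification curve: per-month sum of flags.

    Flags are sticky (1 from the achievement month onward), so the
    monthly sum is directly the cumulative count.
    """
    return IdentificationCurve(cohort.flags_matrix().sum(axis=0))


def oracle_total_exposure(patient: PatientRecord) -> int:
    """Plaintext fixed-point exposure total, in 0.1 mg units."""
    return int(np.sum(patient.weight_kg * patient.dose_tenths))


# --------------------------------------------------------------------------
# Encrypted counting
# --------------------------------------------------------------------------


def encrypt_flag_matrix(
    cohort: Cohort, pk: PublicKey, rng: np.random.Generator
) -> EncryptedFlagMatrix:
    """Encrypt every per-patient per-month flag individually."""
    p = pk.params
    flags = cohort.flags_matrix()
    n_pat, months = flags.shape
    if p.t <= n_pat:
        raise ValueError(
            f"count overflow risk: plaintext modulus t={p.t} must exceed "
            f"the patient count {n_pat}"
        )
    c0, c1 = encrypt_batch(pk, flags.ravel(), rng)
    nb = c0.shape[0]
    shape = (nb, n_pat, months, p.n)
    return EncryptedFlagMatrix(c0.reshape(shape), c1.reshape(shape), p)


def count_responders_by_month(efm: EncryptedFlagMatrix) -> list[Ciphertext]:
    """Per-month homomorphic sum over patients of the encrypted flags.

    Operates on ciphertexts only; no secret key is in scope.
    """
    p = efm.params
    n, K = p.n, p.qbits
    out = []
    for m in range(efm.study_months):
        s0 = limbs.normalize(efm.c0[:, :, m, :].sum(axis=1), K)
        s1 = limbs.normalize(efm.c1[:, :, m, :].sum(axis=1), K)
        out.append(
            Ciphertext([RingElement(s0, n, K), RingElement(s1, n, K)], p)
        )
    return out


def decrypt_counts(sk: SecretKey, monthly: list[Ciphertext]) -> IdentificationCurve:
    """Single final decryption of the per-month encrypted totals."""
    c0 = np.stack([ct.parts[0].limbs for ct in monthly], axis=1)
    c1 = np.stack([ct.parts[1].limbs for ct in monthly], axis=1)
    return IdentificationCurve(decrypt_batch(sk, [c0, c1]))


def milestone_months(curve: IdentificationCurve, k) -> int:
    """First 0-based study month with cumulative count >= k.

    ``k`` may be an integer or ``"all"`` (month when the final total is
    first reached).  Raises :class:`MilestoneUnreached` if never reached.
    """
    counts = curve.counts
    if isinstance(k, str):
        if k != "all":
            raise ValueError("k must be an integer or 'all'")
        target = curve.final_count
        if target == 0:
            raise MilestoneUnreached("no responder was ever identified")
    else:
        target = int(k)
        if target > curve.final_count:
            raise MilestoneUnreached(
                f"milestone unreached: {target} > final total {curve.final_count}"
            )
    return int(np.argmax(counts >= target))


# --------------------------------------------------------------------------
# Encrypted exposure
# --------------------------------------------------------------------------


def _exposure_ctx(p: HEParams, months: int):
    bound = math.log2(p.n) + 2 * p.qbits + 3 + math.log2(max(months, 1))
    return get_context(p.n, bound)


def _tensor_accumulate(
    ctx, p: HEParams, cw: tuple[np.ndarray, np.ndarray], cd
) -> list[np.ndarray]:
    """Sum over months of the ciphertext tensor products, rescaled once.

    Accumulating the exact integer tensor coefficients before the single
    t/q rounding is decryption-equivalent to rescaling each product and
    adding (the rounding noise is strictly smaller); tests pin this
    equality against the he_mult/he_add composition.
    """
    K = p.qbits
    parts = []
    r = [
        ctx.residues_from_limbs(x, K, centered=True) for x in (*cw, *cd)
    ]
    for x in r:
        ctx.fwd(x)
    c0w, c1w, c0d, c1d = r
    prim = np.array(ctx.primes, dtype=np.int64).reshape(-1, 1, 1)
    e0 = ((c0w * c0d) % prim).sum(axis=1, keepdims=True) % prim
    e1 = ((c0w * c1d + c1w * c0d) % prim).sum(axis=1, keepdims=True) % prim
    e2 = ((c1w * c1d) % prim).sum(axis=1, keepdims=True) % prim
    S = p.qbits - p.tbits
    for e in (e0, e1, e2):
        ctx.inv(e)
        parts.append(ctx.reconstruct(e, S, K))
    return parts


def encrypted_total_exposure(
    patient: PatientRecord,
    pk: PublicKey,
    sk: SecretKey,
    rng: np.random.Generator,
) -> ExposureResult:
    """Total drug exposure for one patient, computed under encryption.

    Weight (kg) and dose (0.1 mg/kg units) are encrypted per month; the
    monthly ciphertext products are combined homomorphically and decrypted
    once, yielding the exact fixed-point total in 0.1 mg units.
    """
    p = pk.params
    months = len(patient.visit_months)
    worst = p.max_value
    if months == 0:
        return ExposureResult(patient.patient_id, 0, 0)
    w = patient.weight_kg.astype(np.int64)
    d = patient.dose_tenths
    if months * int(w.max()) * int(d.max()) > worst:
        raise ValueError(
            f"overflow risk: worst-case exposure {months * int(w.max()) * int(d.max())}"
            f" exceeds the parameter set's max_value {worst}"
        )
    ctx = _exposure_ctx(p, months)
    cw = encrypt_batch(pk, w, rng)
    cd = encrypt_batch(pk, d, rng)
    parts = _tensor_accumulate(ctx, p, cw, cd)
    total = int(decrypt_batch(sk, parts)[0])
    return ExposureResult(patient.patient_id, total, months)


# --------------------------------------------------------------------------
# Study runner and timing harness
# --------------------------------------------------------------------------


def run_study(
    cohort: Cohort,
    he_params: HEParams | None = None,
    seed: int = 0,
) -> tuple[IdentificationCurve, TimingLog]:
    """End-to-end encrypted identification study.

    Encrypts each month's flags, sums them homomorphically, and performs
    one final decryption of the monthly totals.  Months are streamed so
    memory stays bounded for large cohorts; the result is identical to
    materializing the full encrypted flag matrix.  Wall-clock per stage is
    recorded; the feasibility observation (encryption plus counting per
    month versus one month of calendar time) is logged, not asserted.
    """
    p = he_params or counting_params(cohort.n_patients)
    if p.t <= cohort.n_patients:
        raise ValueError("count overflow risk: t must exceed the cohort size")
    ss = np.random.SeedSequence(seed)
    rng_keys, rng_enc = [np.random.default_rng(s) for s in ss.spawn(2)]
    t0 = time.perf_counter()
    sk, pk, _ = keygen(p, rng_keys)
    t_keygen = time.perf_counter() - t0
    flags = cohort.flags_matrix()
    months = flags.shape[1]
    n, K = p.n, p.qbits
    t_encrypt = t_add = 0.0
    monthly = []
    for m in range(months):
        t0 = time.perf_counter()
        c0, c1 = encrypt_batch(pk, flags[:, m], rng_enc)
        t_encrypt += time.perf_counter() - t0
        t0 = time.perf_counter()
        s0 = limbs.normalize(c0.sum(axis=1), K)
        s1 = limbs.normalize(c1.sum(axis=1), K)
        t_add += time.perf_counter() - t0
        monthly.append(
            Ciphertext([RingElement(s0, n, K), RingElement(s1, n, K)], p)
        )
    t0 = time.perf_counter()
    curve = decrypt_counts(sk, monthly)
    t_decrypt = time.perf_counter() - t0
    log = TimingLog()
    log.add(
        analysis="identification",
        n_values=cohort.n_patients,
        security_bits=p.security_bits,
        mult_depth=p.mult_depth,
        keygen_s=round(t_keygen, 4),
        encrypt_s=round(t_encrypt, 4),
        add_s=round(t_add, 4),
        add_x100_s=round(100 * t_add, 4),
        multiply_s=None,
        decrypt_s=round(t_decrypt, 4),
        feasible=(t_encrypt + t_add) / months < 30 * 86400,
    )
    return curve, log


def timing_harness(
    sizes=(1000, 5000),
    configs=((128, 8), (256, 8), (256, 16)),
    n_sample: int = 32,
    exposure_months: int = 48,
    seed: int = 0,
) -> TimingLog:
    """Microbenchmark harness shaped like the study's timing tables.

    For each (security level, depth) configuration it measures, on
    ``n_sample`` values, per-value encryption / homomorphic addition /
    final decryption, scales the addition column to each cohort size, and
    appends the x100-variables extrapolation.  A second set of rows times
    the per-patient exposure computation (encrypt, multiply, add,
    decrypt).  All values are wall-clock seconds and are informational
    only -- they depend on hardware and are never asserted.
    """
    log = TimingLog()
    ss = np.random.SeedSequence(seed)
    for lam, depth in configs:
        # the plaintext modulus must hold the largest cohort's count; if
        # that plaintext space cannot sustain the requested depth at this
        # security level, report the deepest attainable circuit instead
        p = None
        for d in range(depth, -1, -1):
            try:
                p = derive_params(lam, max_value=max(max(sizes), 1000), mult_depth=d)
                break
            except ParameterError:
                continue
        if p is None:
            continue
        rngs = [np.random.default_rng(s) for s in ss.spawn(3)]
        sk, pk, rlk = keygen(p, rngs[0])
        vals = rngs[1].integers(0, 2, n_sample)
        t0 = time.perf_counter()
        c0, c1 = encrypt_batch(pk, vals, rngs[2])
        enc_per_value = (time.perf_counter() - t0) / n_sample
        t0 = time.perf_counter()
        limbs.normalize(c0.sum(axis=1), p.qbits)
        limbs.normalize(c1.sum(axis=1), p.qbits)
        add_per_value = (time.perf_counter() - t0) / n_sample
        t0 = time.perf_counter()
        decrypt_batch(sk, [c0[:, :1], c1[:, :1]])
        dec_s = time.perf_counter() - t0
        for size in sizes:
            add_s = add_per_value * size
            log.add(
                analysis="identification",
                n_values=size,
                security_bits=lam,
                mult_depth=depth,
                encrypt_s=round(enc_per_value * size, 4),
                add_s=round(add_s, 4),
                add_x100_s=round(100 * add_s, 4),
                multiply_s=None,
                decrypt_s=round(dec_s, 4),
            )
        # exposure-style row (per patient): the plaintext space must hold
        # the worst-case fixed-point total, so derive dedicated parameters;
        # if the requested depth cannot be attained with that larger
        # plaintext modulus, fall back to the deepest attainable circuit
        # (exposure itself needs depth 1)
        mexp = exposure_months
        p_exp = None
        for d in range(max(depth, 1), 0, -1):
            try:
                p_exp = derive_params(lam, max_value=mexp * 150 * 60, mult_depth=d)
                break
            except ParameterError:
                continue
        if p_exp is None:
            continue
        sk_e, pk_e, _ = keygen(p_exp, rngs[0])
        w = rngs[1].integers(40, 151, mexp)
        d = rngs[1].integers(1, 61, mexp)
        t0 = time.perf_counter()
        cw = encrypt_batch(pk_e, w, rngs[2])
        cd = encrypt_batch(pk_e, d, rngs[2])
        enc_s = time.perf_counter() - t0
        ctx = _exposure_ctx(p_exp, mexp)
        t0 = time.perf_counter()
        parts = _tensor_accumulate(ctx, p_exp, cw, cd)
        mult_s = time.perf_counter() - t0
        t0 = time.perf_counter()
        decrypt_batch(sk_e, parts)
        dec2_s = time.perf_counter() - t0
        total = enc_s + mult_s + dec2_s
        log.add(
            analysis="exposure",
            n_values=mexp,
            security_bits=lam,
            mult_depth=depth,
            encrypt_s=round(enc_s, 4),
            add_s=0.0,
            add_x100_s=0.0,
            multiply_s=round(mult_s, 4),
            decrypt_s=round(dec2_s, 4),
            total_patient_s=round(total, 4),
            est_5000_patients_h=round(total * 5000 / 3600, 2),
        )
    return log
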