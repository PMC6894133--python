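# Methods

## Overview

`hecohort` is a proof-of-concept learning system for identifying
*exceptional responders* — cancer patients whose survival under a
treatment greatly exceeds the norm — while every patient-level datum
stays homomorphically encrypted.  It has four parts: a leveled
Fan–Vercauteren (FV/BFV) encryption scheme built from scratch, a
longitudinal cohort simulator, the two encrypted analyses (monthly
responder counting and per-patient drug exposure), and a chi-squared
power analysis that sizes the cohorts the system would need.

## The FV scheme

### Construction

Plaintexts are signed scalars encoded as constant polynomials of
`R_t = Z_t[X]/(X^n+1)` and scaled by `Δ = q/t`; ciphertexts are pairs
(or, transiently after multiplication, triples) of elements of
`R_q = Z_q[X]/(X^n+1)`:

- secret key `s`: uniform ternary coefficients in {−1, 0, 1};
- public key `(p0, p1) = (−(a·s + e), a)` with `a` uniform in `R_q` and
  `e` from the error distribution;
- encryption of `m`: `(Δ·[m]_t + p0·u + e1, p1·u + e2)` with ternary `u`;
- decryption: `m = ⌊ t/q · [c0 + c1·s (+ c2·s²)]_q ⌉ mod t`, mapped to the
  centered interval;
- addition: component-wise; multiplication: the integer tensor product
  scaled by `t/q` and rounded, giving a size-3 ciphertext, followed by
  base-`2^w` relinearization with the evaluation key
  `(b_i, a_i) = (−(a_i·s + e_i) + 2^{wi}·s², a_i)`.

The error distribution is the centered binomial
`Binomial(40, 1/2) − 20`, standard deviation `σ = √10 ≈ 3.16` — the
standard "σ ≈ 3.2" choice, sampled exactly in integers so results are
reproducible bit-for-bit across platforms.

### Moduli and representation

Both `q = 2^K` and `t` are powers of two.  This keeps `Δ = 2^{K−τ}`
exact, and turns every rescaling (`t/q` in multiplication, `1/Δ` in
decryption) into a rounding bit-shift.  Ring-LWE security depends only on
`(n, log2 q)` for a given secret/error distribution, so nothing is lost
against the security table.  Coefficients are stored as base-`2^30` limb
vectors in int64 numpy arrays; no arbitrary-precision objects appear on
hot paths.

Ring products are computed exactly by negacyclic NTTs modulo a pool of
31-bit primes `p ≡ 1 (mod 2^17)` (numba kernels, float-reciprocal modular
multiplication with single-correction, all int64) and recombined by a
Garner mixed-radix reconstruction that lands directly in two's-complement
limb form modulo `2^{S+K}`, where the `S`-bit rounding shift is then
exact for centered values.  The prime count per product is chosen from an
a-priori bound on the convolution magnitude (`n · max|a| · max|b|`, plus
a bit for sign and accumulation).  A schoolbook `O(n²)` oracle pins the
NTT path in the test suite.  This is plain exact integer arithmetic —
ciphertexts are never kept in NTT or RNS form, there is no batching, and
no bootstrapping; the scheme stays leveled and somewhat homomorphic.

### Parameter selection

`derive_params(λ, M, L)` fixes `t` as the smallest power of two exceeding
`2M`, then scans ring dimensions upward through a fixed security table
(maximum `log2 q` per `(λ, n)`, ternary secret, classical security, per
the published homomorphic-encryption standard; `λ ∈ {128, 256}`) until
the modulus budget covers depth `L` under a calibrated noise model:

    K ≥ 1 + log2(t) + max(fresh, relin) + L·level + headroom
    fresh = log2 σ + ½·log2 n + 5        (fresh-ciphertext noise)
    level = log2 t + ½·log2 n + 5        (per-multiplication growth)
    relin = log2 ℓ + w + ½·log2 n + log2 σ + 3   (relinearization floor)

with 20 bits of headroom left for additions.  The `½·log2 n` terms are
the average-case expansion of ternary-by-noise products (worst case would
be `log2 n`); the additive constants were set from measured decryption
residuals and leave the empirical depth certificates passing with >20
bits of margin (e.g. the depth-16 chain at λ=256 lands on `n = 32768`,
`K = 457`, and finishes with ~25 bits of budget).  The decomposition base
is `w = 2^8` for `K ≤ 160` and `2^32` for larger moduli: at ~450-bit `q`
a byte-wise base would mean ~57 key-switching products per
multiplication for no useful noise improvement, since the relinearization
floor is negligible against the depth budget either way.

`noise_budget` reports `log2(q / (2·t·‖v − Δ·m‖∞))`, clipped at zero; it
needs the secret key and exists only as a test/diagnostic utility, as
does `checked_decrypt`, the known-plaintext audit that raises once the
budget is exhausted.  Neither appears on the analysis path.

## Cohort simulator

The simulator emulates the study conditions: `n` patients (1000 or 5000
in the analyses), 5% *exceptional* with survival `N(11, 1²)` months and
95% *standard* with `N(8, 1²)` months ("±" read as one standard
deviation), converted at a fixed 30 days/month, truncated at ≥ 1 day and
rounded to whole days; enrollment uniform over the first 6 × 30 days;
48 monthly visit records while alive and on study, each carrying body
weight (truncated normal, 75 ± 10 kg on [40, 150], integer kg) and dose
(truncated normal, 2.5 ± 0.5 mg/kg on (0, 6], tenths of mg/kg).  Weight
and dose distributions are not constrained by the analyses — any
stationary positive distribution exercises the multiplicative pipeline —
so plausible adult oncology values were chosen once.

The responder flag array is the two-step construction: response data
first, then a sticky 0/1 flag per study month.  An exceptional-group
patient's flag turns on in the study month containing
`start_day + survival_days` — the month the unusually long survival has
been fully observed — and stays on; standard-group flags stay zero.  The
alternative reading (flag when a fixed survival threshold is crossed
while alive) would shift the curve by roughly the threshold-to-death gap
but leave its shape unchanged; the death-month rule is the one that
reproduces the expected identification timeline (ten responders by
about month 13, all by about month 21) and is used throughout.  Months
are 0-based indices from study opening everywhere, including the CSV
(`month_index`) and the milestone reports.

What the simulator does *not* model: real enrollment dynamics, censoring
and drop-out, measurement error in weight/dose, correlated visit
schedules, or any tumor-type/mutation structure.  Passing tests therefore
certify the cryptographic pipeline and the statistical machinery on a
clean generative model, not robustness to real-world data artifacts.

## Encrypted analyses

**Counting.**  Every flag is encrypted individually under the public key;
for each month the encrypted flags are summed homomorphically over
patients (pure ciphertext additions), and the 48 monthly totals are
decrypted once at the end, yielding the cumulative identification curve
because flags are sticky.  The plaintext modulus must exceed the patient
count (`t > n`), which the parameter helpers enforce.  For large cohorts
the runner streams month by month so peak memory stays bounded; the
result is bit-identical to materializing the full encrypted flag matrix.

**Exposure.**  Weight (integer kg) and dose (integer tenths of mg/kg) are
encrypted per month; the monthly ciphertext-times-ciphertext products are
combined and decrypted once, giving the exact fixed-point total in 0.1 mg
units.  Internally the integer tensor products are accumulated *before*
the single `t/q` rescaling and the size-3 sum is decrypted directly with
`(s, s²)`; this is decryption-equivalent to the literal
multiply–rescale–relinearize–add chain (the single rounding strictly
reduces noise) and the equality is pinned by a test against the
`he_mult`/`he_add` composition.  Parameters must hold the worst-case
total (`48 × 150 kg × 6.0 mg/kg = 432000` units), checked at setup rather
than silently wrapping.

Both analyses are functions of public material and ciphertexts only; the
secret key appears exactly once, in the final aggregate decryption.

**Timing.**  The timing harness reproduces the shape of the study's
timing tables (per-stage wall-clock for encrypt / add / ×100-variables
extrapolation / decrypt, and the per-patient exposure pipeline with a
5000-patient extrapolation).  The values are hardware-dependent and are
logged, never asserted.

## Power analysis

For a chi-squared test with `df` degrees of freedom at level `α`, effect
size is Cohen's `w`, and the alternative distribution is noncentral
chi-squared with noncentrality `λ = n·w²`.  Power is
`P[X > χ²_{df,1−α}]`, evaluated with scipy's `ncx2` survival function; an
independent Monte-Carlo oracle (simulating `Σ(Z_i + δ_i)²`) checks it in
the tests.  `required_n` inverts by bisection (with the minimality
contract tested), `detectable_effect` by Brent root-finding to well below
`10⁻⁸` in power.  The headline anchors — a 30% effect detectable with
1000 patients, and about 13% with 5000, at `df = 100`, `α = 0.001`, 95%
power — come out as `required_n = 959` and `w = 0.1314`; the percentages
are Cohen's `w` times 100, the only reading under which both anchors
reproduce.  Why `df = 100` is taken as given; it is not derived from a
specific contingency-table design.

## Problem sizes used in the checks

The exactness checks run the encrypted counting study at 1000 patients ×
48 months (48,000 ciphertexts) and the encrypted exposure totals for all
1000 patients (96,000 encryptions, 48,000 encrypted products), both
verified *exactly* against plaintext oracles.  Depth certificates run
full multiplication chains at L ∈ {1, 4, 16}; the identification
timeline averages 20 independent 5000-patient cohorts through the
plaintext-equivalent curve, which is itself proven equal to the encrypted
path.  These sizes keep the complete suite comfortably on a desktop-class
machine while exercising every pipeline at full fidelity.

## Known limitations

- Scalar encoding only: one integer per ciphertext; no SIMD batching, so
  throughput is far below what a batched implementation would achieve.
  The analyses treat this as acceptable because correctness, not speed,
  is the claim being supported.
- The noise model is heuristic (average-case) with generous margins, not
  a proven worst-case bound; the depth guarantee is empirical, via
  `certify`-style chain tests.
- Record linkage across providers, consent bookkeeping, and the
  tag/metadata layer of the envisioned data mart are out of scope.
- The security table pins `(n, log2 q)` pairs; no fresh lattice-security
  estimation is performed.
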