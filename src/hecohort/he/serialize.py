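"""Versioned JSON envelopes for keys and ciphertexts.

Every artifact is a JSON object ``{"format": "hecohort-fv", "version": 1,
"scheme": "FV", "kind": ..., "params": {...}, "payload": {...}}``.  Ring
elements are serialized exactly as base64 of fixed-width little-endian
coefficient arrays (``ceil(qbits/8)`` bytes per coefficient); the ternary
secret key is stored as one byte per coefficient (value + 1).
"""

from __future__ import annotations

import base64
import json
from pathlib import Path

import numpy as np

from .params import HEParams
from .ring import RingElement
from .scheme import Ciphertext, PublicKey, RelinKey, SecretKey

FORMAT = "hecohort-fv"
VERSION = 1


def params_to_dict(p: HEParams) -> dict:
    return {
        "n": p.n,
        "qbits": p.qbits,
        "t": p.t,
        "error_eta": p.error_eta,
        "w_bits": p.w_bits,
        "security_bits": p.security_bits,
        "mult_depth": p.mult_depth,
        "max_value": p.max_value,
    }


def params_from_dict(d: dict) -> HEParams:
    return HEParams(**d)


def _encode_ring(r: RingElement) -> str:
    width = -(-r.K // 8)
    buf = bytearray()
    for c in r.coefficients:
        buf += int(c).to_bytes(width, "little")
    return base64.b64encode(bytes(buf)).decode("ascii")


def _decode_ring(s: str, n: int, K: int) -> RingElement:
    width = -(-K // 8)
    raw = base64.b64decode(s.encode("ascii"))
    if len(raw) != width * n:
        raise ValueError("ring element payload has wrong length")
    coeffs = [
        int.from_bytes(raw[i * width : (i + 1) * width], "little") for i in range(n)
    ]
    return RingElement.from_coefficients(coeffs, n, K)


def _envelope(kind: str, params: HEParams, payload: dict) -> dict:
    return {
        "format": FORMAT,
        "version": VERSION,
        "scheme": "FV",
        "kind": kind,
        "params": params_to_dict(params),
        "payload": payload,
    }


def _check(obj: dict, kind: str) -> None:
    if obj.get("format") != FORMAT or obj.get("scheme") != "FV":
        raise ValueError("not a hecohort FV artifact")
    if obj.get("version") != VERSION:
        raise ValueError(f"unsupported envelope version {obj.get('version')}")
    if obj.get("kind") != kind:
        raise ValueError(f"expected kind {kind!r}, found {obj.get('kind')!r}")


def dump_secret_key(sk: SecretKey) -> dict:
    payload = {
        "s": base64.b64encode(
            (sk.s.astype(np.int64) + 1).astype(np.uint8).tobytes()
        ).decode("ascii")
    }
    return _envelope("secret_key", sk.params, payload)


def load_secret_key(obj: dict) -> SecretKey:
    _check(obj, "secret_key")
    p = params_from_dict(obj["params"])
    raw = base64.b64decode(obj["payload"]["s"])
    s = np.frombuffer(raw, dtype=np.uint8).astype(np.int64) - 1
    if s.shape[0] != p.n:
        raise ValueError("secret key has wrong length")
    return SecretKey(s.copy(), p)


def dump_public_key(pk: PublicKey) -> dict:
    return _envelope(
        "public_key",
        pk.params,
        {"p0": _encode_ring(pk.p0), "p1": _encode_ring(pk.p1)},
    )


def load_public_key(obj: dict) -> PublicKey:
    _check(obj, "public_key")
    p = params_from_dict(obj["params"])
    return PublicKey(
        _decode_ring(obj["payload"]["p0"], p.n, p.qbits),
        _decode_ring(obj["payload"]["p1"], p.n, p.qbits),
        p,
    )


def dump_relin_key(rlk: RelinKey) -> dict:
    pairs = [
        {"b": _encode_ring(b), "a": _encode_ring(a)} for b, a in rlk.pairs
    ]
    return _envelope("relin_key", rlk.params, {"w_bits": rlk.w_bits, "pairs": pairs})


def load_relin_key(obj: dict) -> RelinKey:
    _check(obj, "relin_key")
    p = params_from_dict(obj["params"])
    pairs = [
        (
            _decode_ring(d["b"], p.n, p.qbits),
            _decode_ring(d["a"], p.n, p.qbits),
        )
        for d in obj["payload"]["pairs"]
    ]
    return RelinKey(pairs, obj["payload"]["w_bits"], p)


def dump_ciphertext(ct: Ciphertext) -> dict:
    return _envelope(
        "ciphertext",
        ct.params,
        {"parts": [_encode_ring(part) for part in ct.parts]},
    )


def load_ciphertext(obj: dict) -> Ciphertext:
    _check(obj, "ciphertext")
    p = params_from_dict(obj["params"])
    parts = [_decode_ring(s, p.n, p.qbits) for s in obj["payload"]["parts"]]
    if len(parts) not in (2, 3):
        raise ValueError("ciphertext must have 2 or 3 parts")
    return Ciphertext(parts, p)


def save_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj))


def load_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
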