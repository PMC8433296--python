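"""Binary <-> nucleotide transcoding.

A codec maps byte payloads to sequences over {A, C, G, T} and back. Its
declared cost is the *base factor* ``a`` — bases emitted per input bit — so
the bare-stream storage density is ``d = 1/a`` bits per base. Two reference
codecs are shipped:

``quaternary``
    The defining two-bits-per-base mapping A=00, C=01, G=10, T=11;
    a = 0.5 bases/bit (d = 2 bits/base). No run-length guarantees.

``rot``
    A rotating ternary code: each 5-byte word becomes 26 base-3 digits, and
    each digit picks one of the three bases *different from the previous
    base* (cyclic rotation), so consecutive bases never repeat and no
    homopolymer longer than one base is ever emitted. a = 26/40 = 0.65
    bases/bit (d ~ 1.54 bits/base), close to the ~1.6 bits/base of
    constrained codes used in practice.

Both codecs are exactly invertible on arbitrary byte strings; a trailing
partial word is encoded with the shortest digit count that still covers its
value range, which also makes the input length self-delimiting.
"""

from __future__ import annotations

from abc import ABC, abstractmethod

import numpy as np

from .errors import DecodeError

NUCLEOTIDES = "ACGT"

# --- bit-string helpers -------------------------------------------------

def bits_to_bytes(bits: str) -> bytes:
    """Pack a '0'/'1' string (length multiple of 8, MSB first) into bytes."""
    if len(bits) % 8:
        raise ValueError("bit string length must be a multiple of 8")
    if bits and set(bits) - {"0", "1"}:
        raise ValueError("bit string may contain only '0' and '1'")
    return bytes(int(bits[i:i + 8], 2) for i in range(0, len(bits), 8))


def bytes_to_bits(data: bytes) -> str:
    return "".join(f"{b:08b}" for b in data)


class Codec(ABC):
    """Deterministic, invertible byte <-> nucleotide transcoder."""

    name: str
    base_factor_a: float  # bases per input bit

    @abstractmethod
    def encode(self, data: bytes) -> str:
        """Transcode bytes to a sequence over {A,C,G,T}."""

    @abstractmethod
    def decode(self, seq: str) -> bytes:
        """Exact inverse of :meth:`encode`."""


def encode_bits(bits: str, codec: Codec) -> str:
    """Encode a '0'/'1' string (byte-aligned) through *codec*."""
    return codec.encode(bits_to_bytes(bits))


def decode_bits(seq: str, codec: Codec) -> str:
    """Decode a sequence back to a '0'/'1' string."""
    return bytes_to_bits(codec.decode(seq))


class QuaternaryCodec(Codec):
    """Two bits per base: A=00, C=01, G=10, T=11, MSB-first within a byte."""

    name = "quaternary"
    base_factor_a = 0.5

    _BYTE_TO_SEQ = [
        "".join(NUCLEOTIDES[(b >> s) & 3] for s in (6, 4, 2, 0))
        for b in range(256)
    ]
    _BASE_TO_VAL = {c: i for i, c in enumerate(NUCLEOTIDES)}

    def encode(self, data: bytes) -> str:
        table = self._BYTE_TO_SEQ
        return "".join(table[b] for b in data)

    def decode(self, seq: str) -> bytes:
        if len(seq) % 4:
            raise DecodeError(
                f"sequence length {len(seq)} is not a multiple of 4")
        vals = self._BASE_TO_VAL
        out = bytearray(len(seq) // 4)
        for i in range(0, len(seq), 4):
            acc = 0
            for j, ch in enumerate(seq[i:i + 4]):
                v = vals.get(ch)
                if v is None:
                    raise DecodeError(f"invalid symbol {ch!r}",
                                      position=i + j)
                acc = (acc << 2) | v
            out[i // 4] = acc
        return bytes(out)


class RotatingCodec(Codec):
    """Homopolymer-free rotating ternary codec (5 bytes -> 26 trits).

    3**26 > 2**40, so 26 ternary digits cover every 5-byte word. The digit
    stream is turned into bases by ``base[i] = (base[i-1] + 1 + trit) mod 4``
    starting from a virtual previous base A, which guarantees adjacent bases
    always differ. A trailing word of k in {1,2,3,4} bytes uses the minimal
    digit count with 3**m >= 256**k (6, 11, 16, 21 digits respectively);
    those counts are distinct mod 26, so the decoder recovers the original
    byte length from the sequence length alone.
    """

    name = "rot"
    WORD_BYTES = 5
    WORD_TRITS = 26
    base_factor_a = WORD_TRITS / (WORD_BYTES * 8)  # 0.65 bases/bit

    _TAIL_TRITS = {1: 6, 2: 11, 3: 16, 4: 21}
    _TAIL_BYTES = {m: k for k, m in _TAIL_TRITS.items()}
    _POW3 = np.array([3 ** i for i in range(WORD_TRITS)], dtype=np.int64)
    _LUT = np.frombuffer(b"ACGT", dtype=np.uint8)
    _LUT_INV = np.full(256, 255, dtype=np.uint8)
    for _i, _c in enumerate(b"ACGT"):
        _LUT_INV[_c] = _i
    del _i, _c

    def _word_trits(self, vals: np.ndarray, n_trits: int) -> np.ndarray:
        """Digit-expand int64 word values, least significant trit last."""
        out = np.empty((len(vals), n_trits), dtype=np.int64)
        v = vals.copy()
        for j in range(n_trits - 1, -1, -1):
            out[:, j] = v % 3
            v //= 3
        return out

    def encode(self, data: bytes) -> str:
        if not data:
            return ""
        arr = np.frombuffer(data, dtype=np.uint8).astype(np.int64)
        n_full = len(data) // self.WORD_BYTES
        chunks = []
        if n_full:
            words = arr[: n_full * self.WORD_BYTES].reshape(-1, self.WORD_BYTES)
            vals = np.zeros(n_full, dtype=np.int64)
            for col in range(self.WORD_BYTES):
                vals = (vals << 8) | words[:, col]
            chunks.append(self._word_trits(vals, self.WORD_TRITS).ravel())
        tail = arr[n_full * self.WORD_BYTES:]
        if len(tail):
            val = 0
            for b in tail:
                val = (val << 8) | int(b)
            m = self._TAIL_TRITS[len(tail)]
            chunks.append(self._word_trits(
                np.array([val], dtype=np.int64), m).ravel())
        trits = np.concatenate(chunks)
        # rotation: cumulative sum of (1 + trit) from virtual base A (=0)
        bases = np.cumsum(trits + 1) % 4
        return self._LUT[bases].tobytes().decode("ascii")

    def decode(self, seq: str) -> bytes:
        if not seq:
            return b""
        raw = np.frombuffer(seq.encode("ascii", errors="replace"),
                            dtype=np.uint8)
        idx = self._LUT_INV[raw].astype(np.int64)
        bad = np.nonzero(idx == 255)[0]
        if len(bad):
            pos = int(bad[0])
            raise DecodeError(f"invalid symbol {seq[pos]!r}", position=pos)
        prev = np.concatenate(([np.int64(0)], idx[:-1]))
        trits = (idx - prev - 1) % 4
        rep = np.nonzero(trits == 3)[0]
        if len(rep):
            pos = int(rep[0])
            raise DecodeError("repeated base breaks the rotation",
                              position=pos)
        n_full, leftover = divmod(len(trits), self.WORD_TRITS)
        if leftover and leftover not in self._TAIL_BYTES:
            raise DecodeError(
                f"sequence length leaves {leftover} trailing digits, which "
                "no byte count produces")
        out = bytearray()
        if n_full:
            mat = trits[: n_full * self.WORD_TRITS].reshape(
                -1, self.WORD_TRITS)
            vals = mat[:, ::-1] @ self._POW3
            if (vals >= 1 << 40).any():
                pos = int(np.nonzero(vals >= 1 << 40)[0][0])
                raise DecodeError("word value out of 5-byte range",
                                  position=pos * self.WORD_TRITS)
            for v in vals:
                out += int(v).to_bytes(self.WORD_BYTES, "big")
        if leftover:
            tail = trits[n_full * self.WORD_TRITS:]
            val = 0
            for t in tail:
                val = val * 3 + int(t)
            k = self._TAIL_BYTES[leftover]
            if val >= 1 << (8 * k):
                raise DecodeError("trailing word value out of range",
                                  position=n_full * self.WORD_TRITS)
            out += val.to_bytes(k, "big")
        return bytes(out)


_CODECS: dict[str, Codec] = {
    QuaternaryCodec.name: QuaternaryCodec(),
    RotatingCodec.name: RotatingCodec(),
}


def get_codec(name: str) -> Codec:
    try:
        return _CODECS[name]
    except KeyError:
        raise ValueError(
            f"unknown codec {name!r}; available: {sorted(_CODECS)}") from None


def register_codec(codec: Codec) -> None:
    """Make a custom codec selectable by name (pluggable interface)."""
    _CODECS[codec.name] = codec
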