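"""MSB-first bit streams and the Elias gamma/delta universal codes.

Bit order is most-significant-bit-first within bytes, so a stream's byte
image is identical across platforms (serialization tests rely on this).
"""

from __future__ import annotations


class BitWriter:
    """Append-only bit stream, MSB-first; pads the final byte with zeros."""

    def __init__(self) -> None:
        self._buf = bytearray()
        self._acc = 0
        self._nacc = 0
        self.nbits = 0

    def write(self, value: int, nbits: int) -> None:
        if nbits < 0 or (nbits == 0 and value != 0) or value >> nbits:
            raise ValueError(f"value {value} does not fit in {nbits} bits")
        self._acc = (self._acc << nbits) | value
        self._nacc += nbits
        self.nbits += nbits
        while self._nacc >= 8:
            self._nacc -= 8
            self._buf.append((self._acc >> self._nacc) & 0xFF)
        self._acc &= (1 << self._nacc) - 1

    def write_unary(self, nzeros: int) -> None:
        """``nzeros`` zero bits followed by a one bit."""
        self.write(1, nzeros + 1)

    def write_gamma(self, v: int) -> None:
        """Elias gamma: floor(log2 v) zeros then v's binary digits."""
        if v < 1:
            raise ValueError("gamma code requires v >= 1")
        lb = v.bit_length() - 1
        self.write(v, 2 * lb + 1)

    def write_delta(self, v: int) -> None:
        """Elias delta: gamma(1 + floor(log2 v)) then the low floor(log2 v) bits."""
        if v < 1:
            raise ValueError("delta code requires v >= 1")
        lb = v.bit_length() - 1
        self.write_gamma(lb + 1)
        if lb:
            self.write(v & ((1 << lb) - 1), lb)

    def getvalue(self) -> bytes:
        out = bytes(self._buf)
        if self._nacc:
            out += bytes([(self._acc << (8 - self._nacc)) & 0xFF])
        return out

    def bitstring(self) -> str:
        b = "".join(f"{byte:08b}" for byte in self.getvalue())
        return b[: self.nbits]


class BitReader:
    """Positioned reader over an MSB-first bit stream."""

    def __init__(self, data: bytes, nbits: int | None = None) -> None:
        self.data = data
        self.nbits = len(data) * 8 if nbits is None else nbits
        self.pos = 0

    def seek(self, pos: int) -> None:
        if not 0 <= pos <= self.nbits:
            raise ValueError("seek out of range")
        self.pos = pos

    def read(self, n: int) -> int:
        if self.pos + n > self.nbits:
            raise EOFError("bit stream exhausted")
        start, end = self.pos >> 3, (self.pos + n + 7) >> 3
        chunk = int.from_bytes(self.data[start:end], "big")
        shift = end * 8 - (self.pos + n)
        self.pos += n
        return (chunk >> shift) & ((1 << n) - 1)

    def read_unary(self) -> int:
        """Number of zero bits before the next one bit (the one is consumed)."""
        z = 0
        while self.read(1) == 0:
            z += 1
        return z

    def read_gamma(self) -> int:
        z = self.read_unary()
        return (1 << z) | (self.read(z) if z else 0)

    def read_delta(self) -> int:
        lb = self.read_gamma() - 1
        return (1 << lb) | (self.read(lb) if lb else 0)


def elias_delta(v: int) -> str:
    """Elias delta code of a positive integer as a '0'/'1' string."""
    bw = BitWriter()
    bw.write_delta(v)
    return bw.bitstring()


def elias_delta_decode(bits: str) -> int:
    """Inverse of :func:`elias_delta`; the string must be exactly one code."""
    nbits = len(bits)
    if nbits == 0:
        raise ValueError("empty code")
    # left-align the bits in a byte image
    data = (int(bits, 2) << ((-nbits) % 8)).to_bytes((nbits + 7) // 8, "big")
    br = BitReader(data, nbits)
    v = br.read_delta()
    if br.pos != nbits:
        raise ValueError("trailing bits after delta code")
    return v
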