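"""Core sequence container and low-level DNA utilities.

Everything downstream works on :class:`LinearGenome`, a named DNA sequence
with an explicit topology flag — the elements this package screens for are
*linear* replicons, and several operations (terminal inverted repeats,
ends-origin replichore inference) are only meaningful for linear molecules.

Internally sequences are encoded as ``uint8`` arrays with A,C,G,T -> 0..3 and
anything else (N, IUPAC ambiguity codes) -> 4.  Code 4 never matches itself in
repeat or overlap comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i

_DECODE = np.frombuffer(b"ACGTN", dtype=np.uint8)

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: multiplicative inverse of 5 modulo 2**64 (for rolling polynomial hashes)
_INV5 = pow(5, -1, 1 << 64)


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string to uint8 codes (A,C,G,T -> 0..3, other -> 4)."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    """Inverse of :func:`encode`; code 4 renders as ``N``."""
    return _DECODE[codes].tobytes().decode("ascii")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (case preserved, N -> N)."""
    return seq.translate(_COMP)[::-1]


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    """Reverse complement in code space; code 4 stays 4."""
    out = codes[::-1].copy()
    acgt = out < 4
    out[acgt] = 3 - out[acgt]
    return out


def gc_fraction(seq: str | np.ndarray) -> float:
    """G+C over A+C+G+T (ambiguous bases excluded from the denominator)."""
    codes = encode(seq) if isinstance(seq, str) else seq
    acgt = int((codes < 4).sum())
    if acgt == 0:
        return 0.0
    gc = int(((codes == 1) | (codes == 2)).sum())
    return gc / acgt


def poly_prefix_hashes(codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rolling polynomial prefix hashes modulo 2**64.

    Returns ``(pref, invpow)`` with ``pref[i] = sum_{j<i} codes[j] * 5**j`` and
    ``invpow[i] = 5**-i``, both mod 2**64, so the canonical hash of the slice
    ``[i, j)`` is ``(pref[j] - pref[i]) * invpow[i]``.  Unsigned wraparound is
    intentional (arithmetic mod 2**64).
    """
    n = len(codes)
    fives = np.full(n, 5, dtype=np.uint64)
    if n:
        fives[0] = 1
    powers = np.multiply.accumulate(fives) if n else fives
    pref = np.zeros(n + 1, dtype=np.uint64)
    if n:
        np.cumsum(codes.astype(np.uint64) * powers, out=pref[1:])
    invs = np.full(n + 1, _INV5, dtype=np.uint64)
    invs[0] = 1
    invpow = np.multiply.accumulate(invs)
    return pref, invpow


@dataclass
class LinearGenome:
    """A named DNA sequence; the unit of screening.

    Parameters
    ----------
    id : str
        Sequence identifier (FASTA header word).
    seq : str
        DNA sequence, IUPAC alphabet.
    topology : str
        ``"linear"`` (default) or ``"circular"``.
    source : str, optional
        Free-text provenance (sample name, simulation tag, ...).
    """

    id: str
    seq: str
    topology: str = "linear"
    source: str | None = None

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def gc(self) -> float:
        return gc_fraction(self.seq)


def as_genome(genome: "LinearGenome | str", default_id: str = "seq") -> LinearGenome:
    """Coerce a raw string to a :class:`LinearGenome` (convenience for APIs)."""
    if isinstance(genome, LinearGenome):
        return genome
    return LinearGenome(id=default_id, seq=genome)
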