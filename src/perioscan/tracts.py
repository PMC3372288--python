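"""A-tract definitions and occurrence detection.

An A-tract is a short adenine (or, on the complementary strand, thymine)
element whose periodic spacing at ~10.5 bp is the sequence signature of
intrinsic DNA curvature.  Ten alternative tract definitions are supported:

* ``AT`` — a single A or T (k = 1);
* ``A2T2`` … ``A5T5`` — uninterrupted runs of A or of T of length k = 2–5;
* ``AT2`` … ``AT6`` — length-k words made of A's followed by T's
  (``A^i T^(k-i)``, i = 0..k), i.e. words containing only the dinucleotides
  AA, AT and TT; there are k + 1 such words.

Every pattern set is closed under reverse complementation, which makes all
downstream statistics strand-symmetric.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "METHOD_CODES",
    "TractMethod",
    "TractOccurrenceSet",
    "build_method",
    "find_tracts",
    "reverse_complement",
]

#: The ten supported A-tract definitions, in the conventional order.
METHOD_CODES = (
    "AT",
    "A2T2",
    "A3T3",
    "A4T4",
    "A5T5",
    "AT2",
    "AT3",
    "AT4",
    "AT5",
    "AT6",
)

_A = ord("A")
_T = ord("T")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(sequence: str) -> str:
    """Reverse complement of a nucleotide string.

    Characters outside ACGTN (either case) are passed through unchanged;
    they never match an A-tract pattern either way.
    """
    return sequence.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class TractMethod:
    """One of the ten A-tract definitions.

    Attributes
    ----------
    code:
        Label such as ``"A2T2"``.
    k:
        Tract length in bp.
    pattern_set:
        The set of length-``k`` words counted as tract occurrences.
    """

    code: str
    k: int
    pattern_set: frozenset[str]

    def __post_init__(self) -> None:
        for p in self.pattern_set:
            if len(p) != self.k:
                raise ValueError(f"pattern {p!r} does not have length k={self.k}")


@dataclass(frozen=True)
class TractOccurrenceSet:
    """Sorted 0-based start coordinates of every tract occurrence.

    Occurrences are overlapping fixed-length matches: a run ``AAA`` contains
    the word ``AA`` at two offsets and both are counted.
    """

    method: TractMethod
    positions: np.ndarray = field(repr=False)
    seq_length: int

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=np.int64)
        object.__setattr__(self, "positions", pos)
        if pos.size:
            if pos[0] < 0 or pos[-1] > self.seq_length - self.method.k:
                raise ValueError("occurrence position out of sequence bounds")
            if np.any(np.diff(pos) <= 0):
                raise ValueError("positions must be strictly increasing")

    def __len__(self) -> int:
        return int(self.positions.size)


def build_method(code: str) -> TractMethod:
    """Return the :class:`TractMethod` for one of the ten supported codes.

    Raises
    ------
    ValueError
        If ``code`` is not one of :data:`METHOD_CODES`.
    """
    if code not in METHOD_CODES:
        raise ValueError(
            f"unknown A-tract method {code!r}; valid codes: {', '.join(METHOD_CODES)}"
        )
    if code == "AT":
        return TractMethod("AT", 1, frozenset({"A", "T"}))
    k = int(code[-1])
    if code.startswith("A") and code[1].isdigit():  # AkTk homopolymer runs
        return TractMethod(code, k, frozenset({"A" * k, "T" * k}))
    # ATk: A^i T^(k-i) for i = 0..k
    patterns = frozenset("A" * i + "T" * (k - i) for i in range(k + 1))
    return TractMethod(code, k, patterns)


def sequence_codes(sequence) -> np.ndarray:
    """Uppercase ASCII byte codes of a sequence as a uint8 array.

    Accepts ``str``, ``bytes`` or a pre-encoded uint8 array (returned as-is).
    """
    if isinstance(sequence, np.ndarray):
        if sequence.dtype != np.uint8:
            raise TypeError("sequence arrays must be uint8 ASCII codes")
        return sequence
    if isinstance(sequence, str):
        sequence = sequence.upper().encode("ascii")
    elif isinstance(sequence, (bytes, bytearray)):
        sequence = bytes(sequence).upper()
    else:
        raise TypeError(f"unsupported sequence type {type(sequence)!r}")
    return np.frombuffer(sequence, dtype=np.uint8)


def occurrence_mask(codes: np.ndarray, method: TractMethod) -> np.ndarray:
    """Boolean mask over offsets 0..L-k marking tract occurrences.

    Vectorised over the three structural families; any window containing a
    non-A/T character (including N and other IUPAC codes) never matches an
    A/T-only pattern, so masking with N suppresses occurrences in place.
    """
    L = codes.size
    k = method.k
    n = L - k + 1
    if n <= 0:
        return np.zeros(0, dtype=bool)
    a = codes == _A
    t = codes == _T
    if k == 1:
        return a | t
    if method.code.startswith("A") and method.code[1].isdigit():
        run_a = a[0:n].copy()
        run_t = t[0:n].copy()
        for j in range(1, k):
            run_a &= a[j : j + n]
            run_t &= t[j : j + n]
        return run_a | run_t
    # ATk: all characters in {A, T} and no T immediately followed by A
    ok = (a | t)[0:n].copy()
    for j in range(1, k):
        ok &= (a | t)[j : j + n]
    for j in range(k - 1):
        ok &= ~(t[j : j + n] & a[j + 1 : j + 1 + n])
    return ok


def find_tracts(sequence, method: TractMethod | str) -> TractOccurrenceSet:
    """Locate every (overlapping) occurrence of a tract pattern.

    Parameters
    ----------
    sequence:
        Nucleotide string (lowercase accepted), bytes, or uint8 code array.
    method:
        A :class:`TractMethod` or one of the ten method codes.
    """
    if isinstance(method, str):
        method = build_method(method)
    codes = sequence_codes(sequence)
    mask = occurrence_mask(codes, method)
    positions = np.flatnonzero(mask).astype(np.int64)
    return TractOccurrenceSet(method=method, positions=positions, seq_length=codes.size)
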