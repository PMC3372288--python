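"""Synthetic sequences with controlled periodic structure.

Two generators cover all testing needs without any genome downloads:

* :func:`bernoulli_sequence` — the homogeneous Bernoulli null model
  (independently drawn nucleotides at fixed frequencies), used for
  significance calibration;
* :func:`plant_periodicity` — a Bernoulli background with a tract string
  (e.g. ``AA``) written in at phase positions spaced by a real-valued
  period (e.g. 10.5 bp), emulating the phased A-tract structure of
  intrinsically curved DNA.  Planting density and a per-site jitter model
  partial and imperfect phasing.

:func:`make_genbank_fixture` assembles a small annotated record (planted
periodic region plus CDS features inside and outside it) for end-to-end
annotation-handling tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "PlantedPeriodicitySpec",
    "bernoulli_sequence",
    "bernoulli_codes",
    "plant_periodicity",
    "make_genbank_fixture",
    "validate_frequencies",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def validate_frequencies(freqs) -> np.ndarray:
    freqs = np.asarray(freqs, dtype=np.float64)
    if freqs.shape != (4,):
        raise ValueError("base_frequencies must be a 4-vector (A, C, G, T)")
    if np.any(freqs < 0) or abs(freqs.sum() - 1.0) > 1e-9:
        raise ValueError("base_frequencies must be nonnegative and sum to 1")
    return freqs


def gc_frequencies(gc: float) -> tuple[float, float, float, float]:
    """Equal-within-class base frequencies for a target G+C fraction."""
    if not 0.0 <= gc <= 1.0:
        raise ValueError("G+C fraction must be in [0, 1]")
    at = (1.0 - gc) / 2.0
    return (at, gc / 2.0, gc / 2.0, at)


def bernoulli_codes(rng: np.random.Generator, length: int, freqs) -> np.ndarray:
    """Random sequence as uint8 ASCII codes (fast path, no string round trip)."""
    freqs = validate_frequencies(freqs)
    idx = rng.choice(4, size=length, p=freqs)
    return _BASES[idx]


def bernoulli_sequence(
    length: int,
    base_frequencies=(0.25, 0.25, 0.25, 0.25),
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> str:
    """I.i.d. random nucleotide sequence; deterministic under a fixed seed.

    ``base_frequencies`` is ordered (A, C, G, T).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    return bernoulli_codes(rng, length, base_frequencies).tobytes().decode("ascii")


@dataclass(frozen=True)
class PlantedPeriodicitySpec:
    """Specification of a sequence with a planted phased-tract region.

    Phase positions are ``round(region_start + i * period)`` for i = 0, 1,
    ...; each receives the tract string with probability ``density``,
    displaced by an integer jitter drawn uniformly from ``[-jitter,
    jitter]``.  Real-valued periods are realised by rounding the phase
    lattice per planting, so consecutive plantings average to the requested
    period.
    """

    length: int
    period: float
    tract: str = "AA"
    base_frequencies: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    region: tuple[int, int] | None = None  # [start, end); None -> whole sequence
    density: float = 1.0
    jitter: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.period < 2:
            raise ValueError("period must be >= 2 bp")
        if not 0.0 <= self.density <= 1.0:
            raise ValueError("density must be in [0, 1]")
        if self.jitter < 0:
            raise ValueError("jitter must be >= 0")
        region = self.region if self.region is not None else (0, self.length)
        if not 0 <= region[0] < region[1] <= self.length:
            raise ValueError("planted region must lie within the sequence")
        validate_frequencies(self.base_frequencies)


def plant_periodicity(spec: PlantedPeriodicitySpec) -> tuple[str, list[int]]:
    """Bernoulli background with periodically planted tract strings.

    Returns ``(sequence, ground_truth)`` where ``ground_truth`` lists the
    0-based start of every planting still intact in the final sequence
    (later plantings may overwrite earlier ones).
    """
    rng = np.random.default_rng(spec.seed)
    codes = bernoulli_codes(rng, spec.length, spec.base_frequencies).copy()
    start, end = spec.region if spec.region is not None else (0, spec.length)
    tract = np.frombuffer(spec.tract.upper().encode("ascii"), dtype=np.uint8)
    k = tract.size
    planted: list[int] = []
    i = 0
    while True:
        phase = int(round(start + i * spec.period))
        i += 1
        if phase + k > end:
            break
        if spec.density < 1.0 and rng.random() >= spec.density:
            continue
        pos = phase
        if spec.jitter:
            pos += int(rng.integers(-spec.jitter, spec.jitter + 1))
            pos = min(max(pos, start), end - k)
        codes[pos : pos + k] = tract
        planted.append(pos)
    sequence = codes.tobytes().decode("ascii")
    ground_truth = sorted(
        {p for p in planted if sequence[p : p + k] == spec.tract.upper()}
    )
    return sequence, ground_truth


def make_genbank_fixture(path: str | Path | None = None, seed: int = 0):
    """Small synthetic annotated record with one strongly periodic region.

    A 30 kb sequence with an 11-bp-phased AA region over [10000, 20000)
    and CDS features placed either deep inside the planted region or far
    outside any window that can be selected by a periodicity cutoff.
    Returns the Biopython ``SeqRecord``; if ``path`` is given the record
    is also written there in GenBank format.
    """
    from Bio.Seq import Seq
    from Bio.SeqFeature import SeqFeature, SimpleLocation
    from Bio.SeqRecord import SeqRecord

    spec = PlantedPeriodicitySpec(
        length=30_000,
        period=11.0,
        tract="AA",
        region=(10_000, 20_000),
        density=1.0,
        jitter=0,
        seed=seed,
    )
    sequence, _ = plant_periodicity(spec)
    record = SeqRecord(
        Seq(sequence),
        id="SYNFIX01",
        name="SYNFIX01",
        description="synthetic fixture with 11 bp phased-AA region 10001..20000",
        annotations={"molecule_type": "DNA", "topology": "linear"},
    )

    def cds(start0, end0, strand, locus, product):
        return SeqFeature(
            SimpleLocation(start0, end0, strand),
            type="CDS",
            qualifiers={"locus_tag": [locus], "product": [product]},
        )

    record.features = [
        cds(1_000, 2_200, 1, "SYN0001", "background protein A"),
        cds(2_800, 4_000, -1, "SYN0002", "background protein B"),
        cds(11_000, 12_500, 1, "SYN0101", "periodic-region protein A"),
        cds(13_000, 14_800, -1, "SYN0102", "periodic-region protein B"),
        cds(16_000, 18_700, 1, "SYN0103", "periodic-region protein C"),
        cds(26_000, 27_500, 1, "SYN0201", "background protein C"),
        cds(28_000, 29_000, -1, "SYN0202", "background protein D"),
    ]
    if path is not None:
        from Bio import SeqIO

        SeqIO.write(record, str(path), "genbank")
    return record
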