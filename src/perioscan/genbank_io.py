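"""Sequence input, CDS masking and annotation-aware postprocessing.

Sequences are read from single-entry FASTA or GenBank files.  GenBank
annotation serves two purposes:

* masking — protein-coding positions (``CDS`` features) or, conversely,
  all non-coding positions can be replaced with ``N`` before the
  periodicity analysis; coordinates are preserved (no excision), so tract
  spacings never span collapsed gaps;
* postprocessing — annotated features overlapping scan windows whose
  periodicity over a chosen period range is above (or below) a cutoff are
  extracted into a filtered GenBank feature table and a compact
  tab-delimited report.

GenBank coordinates are 1-based inclusive; internally everything is
0-based half-open.  The conversion is centralised here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from io import StringIO
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

from .scan import ScanResult

__all__ = [
    "FeatureRecord",
    "WindowSelection",
    "read_sequence",
    "mask_sequence",
    "select_windows",
    "extract_features",
]

logger = logging.getLogger(__name__)

_FASTA_SUFFIXES = {".fa", ".fasta", ".fna", ".ffn", ".frn"}
_GENBANK_SUFFIXES = {".gb", ".gbk", ".gbff", ".genbank"}


@dataclass(frozen=True)
class FeatureRecord:
    """One annotated feature in GenBank coordinates (1-based inclusive).

    ``spans`` lists the exon intervals of ``join()`` locations in
    ascending genomic order; for simple locations it holds the single
    (start, end) pair.
    """

    feature_type: str
    start: int
    end: int
    strand: str
    qualifiers: dict[str, str] = field(default_factory=dict)
    spans: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise ValueError("require 1 <= start <= end")
        if self.strand not in {"+", "-"}:
            raise ValueError("strand must be '+' or '-'")
        if not self.spans:
            object.__setattr__(self, "spans", ((self.start, self.end),))


def _detect_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        if fmt not in {"fasta", "genbank"}:
            raise ValueError("format must be 'fasta' or 'genbank'")
        return fmt
    suffix = path.suffix.lower()
    if suffix in _FASTA_SUFFIXES:
        return "fasta"
    if suffix in _GENBANK_SUFFIXES:
        return "genbank"
    raise ValueError(
        f"cannot infer format from suffix {suffix!r}; pass format='fasta' or 'genbank'"
    )


def _feature_from_seqfeature(f: SeqFeature, seq_length: int) -> FeatureRecord | None:
    parts = f.location.parts
    starts = [int(p.start) for p in parts]
    in_order = starts == sorted(starts) or starts == sorted(starts, reverse=True)
    if not in_order:
        logger.warning(
            "skipping feature %s with non-collinear location (origin-spanning "
            "features of circular sequences are not supported)",
            f.type,
        )
        return None
    spans = tuple(
        sorted((int(p.start) + 1, int(p.end)) for p in parts)
    )  # to 1-based inclusive
    if spans[0][0] < 1 or spans[-1][1] > seq_length:
        logger.warning("skipping feature %s outside the sequence", f.type)
        return None
    quals = {k: str(v[0]) if isinstance(v, list) else str(v) for k, v in f.qualifiers.items()}
    return FeatureRecord(
        feature_type=f.type,
        start=spans[0][0],
        end=spans[-1][1],
        strand="-" if f.location.strand == -1 else "+",
        qualifiers=quals,
        spans=spans,
    )


def read_sequence(
    path: str | Path, fmt: str | None = None
) -> tuple[str, list[FeatureRecord]]:
    """Read a single-entry FASTA or GenBank file.

    Returns the uppercased sequence and, for GenBank input, its feature
    records (``source`` features excluded — they always span the whole
    sequence and carry no positional information).
    """
    path = Path(path)
    fmt = _detect_format(path, fmt)
    records = list(SeqIO.parse(str(path), fmt))
    if len(records) != 1:
        raise ValueError(
            f"{path} contains {len(records)} sequence entries; exactly one is required"
        )
    record = records[0]
    sequence = str(record.seq).upper()
    features: list[FeatureRecord] = []
    if fmt == "genbank":
        for f in record.features:
            if f.type == "source":
                continue
            fr = _feature_from_seqfeature(f, len(sequence))
            if fr is not None:
                features.append(fr)
    return sequence, features


_MASK_MODES = {
    "none": "none",
    "cds": "cds",
    "mask_cds": "cds",
    "noncoding": "noncoding",
    "mask_noncoding": "noncoding",
}


def mask_sequence(
    sequence: str, features: list[FeatureRecord], mode: str
) -> str:
    """Replace coding (or non-coding) positions with N, preserving length.

    ``mode`` is ``none``, ``cds`` (mask CDS positions) or ``noncoding``
    (mask everything not covered by a CDS span).
    """
    if mode not in _MASK_MODES:
        raise ValueError(f"unknown mask mode {mode!r}; use none, cds or noncoding")
    mode = _MASK_MODES[mode]
    if mode == "none":
        return sequence
    if not features:
        raise ValueError(f"mask mode {mode!r} requires GenBank annotation")
    covered = np.zeros(len(sequence), dtype=bool)
    for fr in features:
        if fr.feature_type != "CDS":
            continue
        for a, b in fr.spans:  # 1-based inclusive -> 0-based half-open
            covered[a - 1 : b] = True
    codes = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8).copy()
    target = covered if mode == "cds" else ~covered
    codes[target] = ord("N")
    return codes.tobytes().decode("ascii")


@dataclass(frozen=True)
class WindowSelection:
    """Scan windows whose in-range periodicity clears (or stays under) a cutoff."""

    direction: str
    cutoff: float
    period_range: tuple[float, float]
    windows: tuple[tuple[int, int], ...]


def select_windows(
    scan: ScanResult,
    direction: str,
    cutoff: float,
    period_range: tuple[float, float],
) -> WindowSelection:
    """Select retained windows by their maximum Q* over a period range.

    ``direction='above'`` keeps windows with ``max Q* >= cutoff`` in the
    range; ``'below'`` keeps the complement (``max Q* < cutoff``).
    """
    if direction not in {"above", "below"}:
        raise ValueError("direction must be 'above' or 'below'")
    p_a, p_b = period_range
    if not p_a < p_b:
        raise ValueError("period_range must satisfy P_a < P_b")
    if scan.periods.size == 0:
        raise ValueError("scan has no spectra")
    if p_a < scan.periods[0] - 1e-9 or p_b > scan.periods[-1] + 1e-9:
        raise ValueError(
            f"period_range {period_range} outside the spectrum grid "
            f"[{scan.periods[0]}, {scan.periods[-1]}]"
        )
    mask = (scan.periods >= p_a - 1e-12) & (scan.periods <= p_b + 1e-12)
    if not mask.any():
        raise ValueError("period_range contains no grid points")
    peak = scan.spectra[:, mask].max(axis=1)
    keep = peak >= cutoff if direction == "above" else peak < cutoff
    windows = tuple(w for w, k in zip(scan.windows, keep) if k)
    return WindowSelection(
        direction=direction,
        cutoff=float(cutoff),
        period_range=(float(p_a), float(p_b)),
        windows=windows,
    )


def _overlaps(fr: FeatureRecord, windows) -> bool:
    for a, b in fr.spans:
        lo, hi = a - 1, b  # 0-based half-open
        for ws, we in windows:
            if lo < we and ws < hi:
                return True
    return False


def _to_seqfeature(fr: FeatureRecord) -> SeqFeature:
    strand = -1 if fr.strand == "-" else 1
    locs = [SimpleLocation(a - 1, b, strand) for a, b in fr.spans]
    location = locs[0] if len(locs) == 1 else CompoundLocation(
        locs if strand == 1 else locs[::-1]
    )
    return SeqFeature(
        location,
        type=fr.feature_type,
        qualifiers={k: [v] for k, v in fr.qualifiers.items()},
    )


def extract_features(
    features: list[FeatureRecord],
    selection: WindowSelection,
    sequence: str,
    record_id: str = "filtered",
) -> tuple[str, str]:
    """Report every feature overlapping a selected window by >= 1 bp.

    Returns ``(genbank_text, tsv_text)``: a filtered feature table in
    GenBank format (with the original sequence, so it round-trips through
    :func:`read_sequence`) and a tab-delimited report with the columns
    locus_tag, start, end, strand, product.  A feature appears once even
    if it overlaps several selected windows; for ``join()`` locations any
    overlapping exon span triggers reporting of the whole feature.
    """
    selected = [fr for fr in features if _overlaps(fr, selection.windows)]

    record = SeqRecord(
        Seq(sequence),
        id=record_id,
        name=record_id[:16],
        description=(
            f"features overlapping windows with periodicity {selection.direction} "
            f"{selection.cutoff} over periods "
            f"{selection.period_range[0]}-{selection.period_range[1]} bp"
        ),
        annotations={"molecule_type": "DNA"},
    )
    record.features = [_to_seqfeature(fr) for fr in selected]
    gb = StringIO()
    SeqIO.write(record, gb, "genbank")

    tsv = StringIO()
    tsv.write("locus_tag\tstart\tend\tstrand\tproduct\n")
    for fr in selected:
        tsv.write(
            "\t".join(
                [
                    fr.qualifiers.get("locus_tag", ""),
                    str(fr.start),
                    str(fr.end),
                    fr.strand,
                    fr.qualifiers.get("product", ""),
                ]
            )
            + "\n"
        )
    return gb.getvalue(), tsv.getvalue()
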