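"""Mutational opportunity: how many sites, weighted by copy number, are
available to each of the 96 channels.

Every base with a complete, unambiguous trinucleotide context can mutate
into three alternative bases, i.e. it contributes to exactly three
channels (pyrimidine-collapsed). The opportunity vector accumulates, for
every such base in the territory of interest, the local copy number into
those three channels. Copy number is taken from per-sample segment files
and treated as static; bases outside any segment take a configurable
default (diploid by default).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .channels import N_CHANNELS, _BASES, channel_of, channel_names

__all__ = [
    "CopySegment",
    "GenomicWindow",
    "flat_opportunity",
    "tile_windows",
    "opportunity_from_sequence",
    "read_segments_tsv",
    "read_regions_tsv",
]


@dataclass(frozen=True)
class CopySegment:
    """A copy-number segment, 0-based half-open."""

    chrom: str
    start: int
    end: int
    copy_number: float

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"empty segment {self.chrom}:{self.start}-{self.end}")
        if self.copy_number < 0:
            raise ValueError("copy number must be >= 0")


@dataclass(frozen=True)
class GenomicWindow:
    """A genomic interval, 0-based half-open, with an optional label."""

    chrom: str
    start: int
    end: int
    label: str | None = None

    @property
    def id(self) -> str:
        return self.label if self.label is not None else (
            f"{self.chrom}:{self.start}-{self.end}"
        )


def flat_opportunity(n_samples: int, n_channels: int = N_CHANNELS) -> np.ndarray:
    """Opportunity matrix of ones: the variant that ignores opportunity."""
    return np.ones((n_samples, n_channels))


def tile_windows(
    contig_lengths: Mapping[str, int], window_size: int
) -> list[GenomicWindow]:
    """Tile contigs with non-overlapping windows; the last window of a
    contig may be shorter."""
    if window_size <= 0:
        raise ValueError("window_size must be positive")
    windows = []
    for chrom, length in contig_lengths.items():
        for start in range(0, length, window_size):
            windows.append(GenomicWindow(chrom, start, min(start + window_size, length)))
    return windows


# trinucleotide-code (4*4*4, base order ACGT, N excluded) -> the three
# channel indices the central base contributes to
def _build_code_map() -> np.ndarray:
    out = np.zeros((64, 3), dtype=np.int64)
    for c5 in range(4):
        for cc in range(4):
            for c3 in range(4):
                tri = _BASES[c5] + _BASES[cc] + _BASES[c3]
                alts = [b for b in _BASES if b != tri[1]]
                code = c5 * 16 + cc * 4 + c3
                out[code] = [channel_of(tri, a).index for a in alts]
    return out


_CODE_MAP = _build_code_map()
_BASE_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i
    _BASE_CODE[ord(_b.lower())] = _i


def _encode(seq: str) -> np.ndarray:
    return _BASE_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _copy_number_track(
    length: int, segments: Sequence[CopySegment], default: float
) -> np.ndarray:
    cn = np.full(length, default, dtype=float)
    prev_end = {}
    for seg in sorted(segments, key=lambda s: s.start):
        if seg.start < prev_end.get(seg.chrom, -1):
            raise ValueError(
                f"overlapping copy-number segments on {seg.chrom} near {seg.start}"
            )
        prev_end[seg.chrom] = seg.end
        cn[max(seg.start, 0) : min(seg.end, length)] = seg.copy_number
    return cn


def _accumulate(codes: np.ndarray, cn: np.ndarray, start: int, end: int) -> np.ndarray:
    """Opportunity vector for bases in [start, end) of one contig.

    A base contributes only if its full trinucleotide lies inside the
    contig and contains no ambiguous base; attribution is by the mutated
    base's own position.
    """
    omega = np.zeros(N_CHANNELS)
    lo = max(start, 1)
    hi = min(end, len(codes) - 1)
    if hi <= lo:
        return omega
    c5, cc, c3 = codes[lo - 1 : hi - 1], codes[lo:hi], codes[lo + 1 : hi + 1]
    ok = (c5 >= 0) & (cc >= 0) & (c3 >= 0)
    if not ok.any():
        return omega
    tri = (c5[ok] * 16 + cc[ok] * 4 + c3[ok]).astype(np.int64)
    weight = cn[lo:hi][ok]
    per_code = np.bincount(tri, weights=weight, minlength=64)
    for slot in range(3):
        np.add.at(omega, _CODE_MAP[:, slot], per_code)
    return omega


def opportunity_from_sequence(
    reference: Mapping,
    segments: Sequence[CopySegment] | None = None,
    scope: Sequence[GenomicWindow] | None = None,
    *,
    default_copy_number: float = 2.0,
) -> np.ndarray | pd.DataFrame:
    """Compute opportunity vectors from a reference and copy-number segments.

    With ``scope=None`` the whole reference is one territory and a single
    length-96 vector is returned. Otherwise one vector per scope element
    (window or labelled region) is returned as a DataFrame indexed by the
    element id, channels as columns.

    Segments must be non-overlapping; bases not covered by any segment
    take ``default_copy_number``.
    """
    segments = list(segments) if segments is not None else []
    by_chrom: dict[str, list[CopySegment]] = {}
    for seg in segments:
        by_chrom.setdefault(seg.chrom, []).append(seg)

    codes = {chrom: _encode(str(reference[chrom][:])) for chrom in _contigs(reference)}
    tracks = {
        chrom: _copy_number_track(len(c), by_chrom.get(chrom, []), default_copy_number)
        for chrom, c in codes.items()
    }

    if scope is None:
        omega = np.zeros(N_CHANNELS)
        for chrom, c in codes.items():
            omega += _accumulate(c, tracks[chrom], 0, len(c))
        return omega

    rows = []
    for win in scope:
        if win.chrom not in codes:
            raise KeyError(f"scope contig {win.chrom!r} not in reference")
        rows.append(_accumulate(codes[win.chrom], tracks[win.chrom], win.start, win.end))
    return pd.DataFrame(
        np.asarray(rows).reshape(len(rows), N_CHANNELS),
        index=pd.Index([w.id for w in scope], name="scope"),
        columns=channel_names(),
    )


def _contigs(reference: Mapping) -> list[str]:
    try:
        return list(reference.keys())
    except AttributeError:  # pyfaidx.Fasta
        return [rec.name for rec in reference]


def read_segments_tsv(path) -> list[CopySegment]:
    """Read copy-number segments from a BED-like TSV
    (chrom, start, end, copy_number; no header required)."""
    df = pd.read_csv(
        path, sep="\t", comment="#",
        names=["chrom", "start", "end", "copy_number"],
        dtype={"chrom": str},
    )
    return [
        CopySegment(r.chrom, int(r.start), int(r.end), float(r.copy_number))
        for r in df.itertuples(index=False)
    ]


def read_regions_tsv(path) -> list[GenomicWindow]:
    """Read labelled regions from a BED-like TSV (chrom, start, end, label)."""
    df = pd.read_csv(
        path, sep="\t", comment="#",
        names=["chrom", "start", "end", "label"], dtype={"chrom": str, "label": str},
    )
    return [
        GenomicWindow(r.chrom, int(r.start), int(r.end), r.label)
        for r in df.itertuples(index=False)
    ]
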