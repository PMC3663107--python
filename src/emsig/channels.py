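"""The 96 trinucleotide mutation channels and count-matrix construction.

Somatic single-base substitutions are classified by the substituted base
pair and its immediate 5'/3' sequence context. Collapsing the two strands
onto the pyrimidine-carrying strand gives six substitution classes
(C>A, C>G, C>T, T>A, T>C, T>G) times sixteen trinucleotide contexts:
96 channels in total. Channel order is the conventional one: classes in
the order above, contexts sorted by the 5' and then the 3' base
(A < C < G < T).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "N_CHANNELS",
    "ChannelIndex",
    "MutationRecord",
    "CountMatrix",
    "RejectionReport",
    "enumerate_channels",
    "channel_of",
    "channel_names",
    "build_count_matrix",
    "read_mutations_tsv",
    "read_mutations_vcf",
    "revcomp",
]

N_CHANNELS = 96

_BASES = "ACGT"
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
_PYRIMIDINES = {"C", "T"}
# pyrimidine-strand substitution classes in canonical order
_CLASSES = [("C", "A"), ("C", "G"), ("C", "T"), ("T", "A"), ("T", "C"), ("T", "G")]
_CLASS_INDEX = {cls: i for i, cls in enumerate(_CLASSES)}


def revcomp(seq: str) -> str:
    """Reverse complement of an ACGT string."""
    return "".join(_COMPLEMENT[b] for b in reversed(seq))


@dataclass(frozen=True)
class ChannelIndex:
    """One of the 96 (substitution class, trinucleotide context) channels."""

    ref: str  # pyrimidine-strand reference base, C or T
    alt: str  # pyrimidine-strand alternate base
    context5: str
    context3: str
    index: int

    @property
    def substitution(self) -> str:
        return f"{self.ref}>{self.alt}"

    @property
    def trinucleotide(self) -> str:
        return self.context5 + self.ref + self.context3

    @property
    def name(self) -> str:
        """Canonical column name, e.g. ``C>A@ACA``."""
        return f"{self.substitution}@{self.trinucleotide}"


def enumerate_channels() -> list[ChannelIndex]:
    """Return the 96 channels in canonical order.

    Classes run C>A, C>G, C>T, T>A, T>C, T>G; within each class the 16
    contexts are ordered by 5' then 3' base, each A < C < G < T, i.e.
    from ApCpA, ApCpC, ... to TpCpG, TpCpT.
    """
    channels = []
    for ci, (ref, alt) in enumerate(_CLASSES):
        for fi, five in enumerate(_BASES):
            for ti, three in enumerate(_BASES):
                channels.append(
                    ChannelIndex(ref, alt, five, three, ci * 16 + fi * 4 + ti)
                )
    return channels


_CHANNELS = enumerate_channels()
_CHANNEL_NAMES = [c.name for c in _CHANNELS]
_LOOKUP: dict[tuple[str, str], ChannelIndex] = {
    (c.trinucleotide, c.alt): c for c in _CHANNELS
}


def channel_names() -> list[str]:
    """Canonical channel column names (``C>A@ACA`` ... ``T>G@TTT``)."""
    return list(_CHANNEL_NAMES)


def channel_of(trinucleotide: str, alt: str) -> ChannelIndex:
    """Map a mutation given as (trinucleotide around the site, alt base)
    to its pyrimidine-collapsed channel.

    If the central base is a purine, the trinucleotide and the alternate
    base are reverse-complemented before lookup, so the two strand
    representations of a mutation map to the same channel.

    Raises
    ------
    ValueError
        If any base is not in ACGT or the central base equals ``alt``.
    """
    trinucleotide = trinucleotide.upper()
    alt = alt.upper()
    if len(trinucleotide) != 3:
        raise ValueError(f"need a trinucleotide, got {trinucleotide!r}")
    if any(b not in _BASES for b in trinucleotide) or alt not in _BASES:
        raise ValueError(
            f"ambiguous or invalid base in {trinucleotide!r}>{alt!r}"
        )
    if trinucleotide[1] == alt:
        raise ValueError(f"ref equals alt in {trinucleotide!r}>{alt!r}")
    if trinucleotide[1] not in _PYRIMIDINES:
        trinucleotide = revcomp(trinucleotide)
        alt = _COMPLEMENT[alt]
    return _LOOKUP[(trinucleotide, alt)]


@dataclass(frozen=True)
class MutationRecord:
    """A somatic single-nucleotide variant (1-based position)."""

    sample: str
    chrom: str
    pos: int
    ref: str
    alt: str


@dataclass
class RejectionReport:
    """Per-reason tallies and records rejected during counting."""

    reasons: dict[str, int] = field(default_factory=dict)
    records: list[tuple[MutationRecord, str]] = field(default_factory=list)

    def add(self, record: MutationRecord, reason: str) -> None:
        self.reasons[reason] = self.reasons.get(reason, 0) + 1
        self.records.append((record, reason))

    @property
    def total(self) -> int:
        return sum(self.reasons.values())


@dataclass
class CountMatrix:
    """Per-tumor, per-channel mutation counts (M samples x 96 channels)."""

    values: np.ndarray
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2 or self.values.shape[1] != N_CHANNELS:
            raise ValueError(
                f"count matrix must have {N_CHANNELS} columns, "
                f"got shape {self.values.shape}"
            )
        if (self.values < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=pd.Index(self.sample_ids, name="sample"),
            columns=_CHANNEL_NAMES,
        )


def read_mutations_tsv(path) -> pd.DataFrame:
    """Read a mutation table (columns: sample, chrom, pos, ref, alt)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "sample": str})
    required = ["sample", "chrom", "pos", "ref", "alt"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"mutation table missing columns: {missing}")
    return df[required]


def read_mutations_vcf(path, sample: str) -> pd.DataFrame:
    """Read SNV records from a (single-sample) VCF into a mutation table.

    Only biallelic records where both REF and ALT are single bases are
    kept; all records are attributed to ``sample``.
    """
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 5:
                continue
            chrom, pos, _, ref, alt = parts[:5]
            if len(ref) == 1 and len(alt) == 1 and ref != alt:
                rows.append((sample, chrom, int(pos), ref.upper(), alt.upper()))
    return pd.DataFrame(rows, columns=["sample", "chrom", "pos", "ref", "alt"])


def _fetch_trinuc(reference, chrom: str, pos: int) -> str | None:
    """Trinucleotide centred on 1-based ``pos``; None at contig edges."""
    seq = reference[chrom]
    start = pos - 2  # 0-based start of the trinucleotide
    if start < 0:
        return None
    tri = str(seq[start : start + 3]).upper()
    if len(tri) < 3:
        return None
    return tri


def build_count_matrix(
    mutations: pd.DataFrame | Iterable[MutationRecord],
    reference: Mapping,
    *,
    sample_ids: list[str] | None = None,
    on_ref_mismatch: str = "reject",
) -> tuple[CountMatrix, RejectionReport]:
    """Build the M x 96 count matrix from a mutation table and a reference.

    ``reference`` is any mapping from contig name to a sliceable sequence
    (a ``pyfaidx.Fasta``, or a plain dict of strings for tests). Records
    are validated against the reference: the stated ref base must match,
    and the trinucleotide context must be complete and unambiguous.
    Failing records are rejected and tallied in the returned report
    (``on_ref_mismatch="abort"`` raises instead).

    Soft-masked (lowercase) reference bases are uppercased before lookup.
    """
    if on_ref_mismatch not in ("reject", "abort"):
        raise ValueError("on_ref_mismatch must be 'reject' or 'abort'")
    if isinstance(mutations, pd.DataFrame):
        records = [
            MutationRecord(str(r.sample), str(r.chrom), int(r.pos),
                           str(r.ref).upper(), str(r.alt).upper())
            for r in mutations.itertuples(index=False)
        ]
    else:
        records = list(mutations)

    if sample_ids is None:
        seen: dict[str, None] = {}
        for rec in records:
            seen.setdefault(rec.sample, None)
        sample_ids = list(seen)
    row_of = {s: i for i, s in enumerate(sample_ids)}

    counts = np.zeros((len(sample_ids), N_CHANNELS), dtype=np.int64)
    report = RejectionReport()
    for rec in records:
        if rec.sample not in row_of:
            report.add(rec, "unknown_sample")
            continue
        if rec.ref not in _BASES or rec.alt not in _BASES or rec.ref == rec.alt:
            report.add(rec, "not_a_snv")
            continue
        if rec.chrom not in reference:
            report.add(rec, "unknown_contig")
            continue
        tri = _fetch_trinuc(reference, rec.chrom, rec.pos)
        if tri is None:
            report.add(rec, "contig_edge")
            continue
        if tri[1] != rec.ref:
            if on_ref_mismatch == "abort":
                raise ValueError(
                    f"reference mismatch at {rec.chrom}:{rec.pos}: "
                    f"table says {rec.ref}, reference has {tri[1]}"
                )
            report.add(rec, "ref_mismatch")
            continue
        if any(b not in _BASES for b in tri):
            report.add(rec, "ambiguous_context")
            continue
        counts[row_of[rec.sample], channel_of(tri, rec.alt).index] += 1
    return CountMatrix(counts, sample_ids), report
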