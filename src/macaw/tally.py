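"""Per-site stranded base-count ("tally") data structures and I/O.

The canonical interchange format is a TSV with a ``#``-prefixed header
line listing sample labels (ancestor first) and one row per reference
site::

    #chrom  pos  ref  ANC  M5  M19 ...
    scf_1   1    A    8,0,0,0,7,0,0,0  ...

Each sample field holds eight comma-separated integers: A,C,G,T counts on
the forward strand followed by A,C,G,T on the reverse strand.  Positions
are 1-based inclusive throughout.  Reading is gzip-transparent.

A converter from ``samtools mpileup`` text output is provided; mapping-
and base-quality filtering is an upstream contract (apply ``-q``/``-Q``
when generating the pileup), though a residual per-base quality cutoff
can be applied here from the pileup's quality strings.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

from .model import BASES, BASE_INDEX


class TallyFormatError(ValueError):
    """Malformed tally or pileup input; message carries file line context."""


@dataclass
class StrandedBaseCount:
    """Counts of A, C, G, T reads at one site for one sample, split by strand."""

    fwd: np.ndarray
    rev: np.ndarray

    def __post_init__(self):
        self.fwd = np.asarray(self.fwd, dtype=np.int64)
        self.rev = np.asarray(self.rev, dtype=np.int64)
        if self.fwd.shape != (4,) or self.rev.shape != (4,):
            raise ValueError("strand count vectors must have length 4")
        if np.any(self.fwd < 0) or np.any(self.rev < 0):
            raise ValueError("negative base counts")

    @classmethod
    def zeros(cls) -> "StrandedBaseCount":
        return cls(np.zeros(4, dtype=np.int64), np.zeros(4, dtype=np.int64))

    def collapsed(self) -> np.ndarray:
        """Strand-summed 4-vector R used by the likelihood model."""
        return self.fwd + self.rev

    def total(self) -> int:
        return int(self.fwd.sum() + self.rev.sum())

    def __eq__(self, other):
        return (
            isinstance(other, StrandedBaseCount)
            and np.array_equal(self.fwd, other.fwd)
            and np.array_equal(self.rev, other.rev)
        )


@dataclass
class SiteRecord:
    """One reference position: ancestor counts plus ordered descendant counts."""

    chrom: str
    pos: int
    ref: str
    ancestor: StrandedBaseCount
    descendants: list[StrandedBaseCount]

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError("pos is 1-based and must be >= 1")


class Tally:
    """Column-matrix view of a tally: the batch container for the callers.

    Arrays: ``anc_fwd``/``anc_rev`` of shape (S, 4) and ``desc_fwd``/
    ``desc_rev`` of shape (S, n, 4), with site coordinates and sample
    labels (ancestor label first in ``samples``).
    """

    def __init__(self, chrom, pos, ref, anc_fwd, anc_rev, desc_fwd, desc_rev,
                 samples: Sequence[str]):
        self.chrom = np.asarray(chrom, dtype=object)
        self.pos = np.asarray(pos, dtype=np.int64)
        self.ref = np.asarray(ref, dtype=object)
        self.anc_fwd = np.asarray(anc_fwd, dtype=np.int64)
        self.anc_rev = np.asarray(anc_rev, dtype=np.int64)
        self.desc_fwd = np.asarray(desc_fwd, dtype=np.int64)
        self.desc_rev = np.asarray(desc_rev, dtype=np.int64)
        self.samples = list(samples)
        if len(self.samples) != self.desc_fwd.shape[1] + 1:
            raise ValueError("sample labels must cover ancestor + descendants")

    def __len__(self) -> int:
        return len(self.pos)

    @property
    def n_lines(self) -> int:
        return self.desc_fwd.shape[1]

    @property
    def line_labels(self) -> list[str]:
        return self.samples[1:]

    def anc_collapsed(self) -> np.ndarray:
        return self.anc_fwd + self.anc_rev

    def desc_collapsed(self) -> np.ndarray:
        return self.desc_fwd + self.desc_rev

    def record(self, i: int) -> SiteRecord:
        return SiteRecord(
            chrom=str(self.chrom[i]),
            pos=int(self.pos[i]),
            ref=str(self.ref[i]),
            ancestor=StrandedBaseCount(self.anc_fwd[i].copy(), self.anc_rev[i].copy()),
            descendants=[
                StrandedBaseCount(self.desc_fwd[i, j].copy(), self.desc_rev[i, j].copy())
                for j in range(self.n_lines)
            ],
        )

    def records(self) -> Iterator[SiteRecord]:
        for i in range(len(self)):
            yield self.record(i)

    @classmethod
    def from_records(cls, records: Iterable[SiteRecord],
                     samples: Sequence[str] | None = None) -> "Tally":
        records = list(records)
        if not records:
            raise ValueError("empty record set")
        n = len(records[0].descendants)
        if samples is None:
            samples = ["ancestor"] + [f"L{i+1}" for i in range(n)]
        anc_fwd = np.stack([r.ancestor.fwd for r in records])
        anc_rev = np.stack([r.ancestor.rev for r in records])
        desc_fwd = np.stack([[d.fwd for d in r.descendants] for r in records])
        desc_rev = np.stack([[d.rev for d in r.descendants] for r in records])
        return cls(
            [r.chrom for r in records], [r.pos for r in records],
            [r.ref for r in records], anc_fwd, anc_rev, desc_fwd, desc_rev,
            samples,
        )


# ---------------------------------------------------------------------------
# Tally TSV
# ---------------------------------------------------------------------------

def _open_text(path, mode="rt"):
    if hasattr(path, "read") or hasattr(path, "write"):
        return path
    p = str(path)
    if p.endswith(".gz"):
        return gzip.open(p, mode)
    return open(p, mode)


def _parse_sample_field(text: str, lineno: int) -> StrandedBaseCount:
    parts = text.split(",")
    if len(parts) != 8:
        raise TallyFormatError(
            f"line {lineno}: sample field has {len(parts)} values, expected 8"
        )
    try:
        vals = [int(x) for x in parts]
    except ValueError as exc:
        raise TallyFormatError(f"line {lineno}: non-integer count: {exc}") from None
    if any(v < 0 for v in vals):
        raise TallyFormatError(f"line {lineno}: negative count")
    return StrandedBaseCount(np.array(vals[:4]), np.array(vals[4:]))


def read_tally(path) -> Iterator[SiteRecord]:
    """Stream :class:`SiteRecord` rows from a tally TSV (gzip-transparent).

    The first record is preceded by the header; sample labels are exposed
    via :func:`read_tally_header` or by loading a full :class:`Tally` with
    :func:`read_tally_matrix`.
    """
    fh = _open_text(path)
    close = not (hasattr(path, "read"))
    try:
        n_samples = None
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                n_samples = len(line.lstrip("#").split("\t")) - 3
                continue
            fields = line.split("\t")
            if n_samples is not None and len(fields) - 3 != n_samples:
                raise TallyFormatError(
                    f"line {lineno}: {len(fields) - 3} sample columns, "
                    f"header declares {n_samples}"
                )
            if len(fields) < 5:
                raise TallyFormatError(f"line {lineno}: too few columns")
            chrom, pos_s, ref = fields[0], fields[1], fields[2]
            try:
                pos = int(pos_s)
            except ValueError:
                raise TallyFormatError(f"line {lineno}: bad position {pos_s!r}") from None
            counts = [_parse_sample_field(f, lineno) for f in fields[3:]]
            yield SiteRecord(chrom, pos, ref, counts[0], counts[1:])
    finally:
        if close:
            fh.close()


def read_tally_header(path) -> list[str]:
    """Return the sample labels from a tally file's header line."""
    fh = _open_text(path)
    try:
        for line in fh:
            if line.startswith("#"):
                return line.lstrip("#").rstrip("\n").split("\t")[3:]
            break
    finally:
        if not hasattr(path, "read"):
            fh.close()
    raise TallyFormatError("missing '#' header line")


def read_tally_matrix(path) -> Tally:
    """Load an entire tally TSV into a :class:`Tally` matrix."""
    samples = read_tally_header(path)
    if hasattr(path, "seek"):
        path.seek(0)
    return Tally.from_records(read_tally(path), samples=samples)


def write_tally(tally_or_records, path, samples: Sequence[str] | None = None) -> None:
    """Write a :class:`Tally` or an iterable of :class:`SiteRecord` as TSV."""
    if isinstance(tally_or_records, Tally):
        tally = tally_or_records
        samples = tally.samples
        records = tally.records()
    else:
        records = iter(tally_or_records)
        first = next(records)
        import itertools
        records = itertools.chain([first], records)
        if samples is None:
            samples = ["ancestor"] + [
                f"L{i+1}" for i in range(len(first.descendants))
            ]
    fh = _open_text(path, "wt")
    close = not hasattr(path, "write")
    try:
        fh.write("#chrom\tpos\tref\t" + "\t".join(samples) + "\n")
        for rec in records:
            cols = [rec.chrom, str(rec.pos), rec.ref]
            for c in [rec.ancestor] + list(rec.descendants):
                cols.append(",".join(str(int(v)) for v in np.concatenate([c.fwd, c.rev])))
            fh.write("\t".join(cols) + "\n")
    finally:
        if close:
            fh.close()


# ---------------------------------------------------------------------------
# samtools-mpileup conversion
# ---------------------------------------------------------------------------

def _parse_pileup_bases(bases: str, quals: str, ref: str, lineno: int,
                        min_base_quality: int = 0) -> StrandedBaseCount:
    """Count A/C/G/T calls from one pileup base string.

    Handles the standard dialect: ``.``/``,`` reference match on fwd/rev
    strand, upper/lower-case base for fwd/rev mismatch, ``^X`` read start
    (mapping quality byte skipped), ``$`` read end, ``+N.../-N...`` indel
    sequences (skipped), ``*``/``#`` deletion placeholders and ``<``/``>``
    reference skips (ignored).  Bases below ``min_base_quality`` (Phred,
    offset 33) are discarded when a quality string is supplied.
    """
    fwd = np.zeros(4, dtype=np.int64)
    rev = np.zeros(4, dtype=np.int64)
    ref_idx = BASE_INDEX.get(ref.upper(), None)
    i = 0
    qi = 0
    n = len(bases)
    have_quals = bool(quals)
    while i < n:
        ch = bases[i]
        if ch == "^":
            i += 2  # caret plus mapping-quality byte
            continue
        if ch == "$":
            i += 1
            continue
        if ch in "+-":
            i += 1
            num = ""
            while i < n and bases[i].isdigit():
                num += bases[i]
                i += 1
            if not num:
                raise TallyFormatError(f"line {lineno}: malformed indel in pileup")
            i += int(num)
            continue
        # every remaining symbol consumes one quality char
        q = None
        if have_quals:
            if qi >= len(quals):
                raise TallyFormatError(
                    f"line {lineno}: quality string shorter than base string"
                )
            q = ord(quals[qi]) - 33
            qi += 1
        i += 1
        if ch in "*#><Nn":
            continue
        if q is not None and q < min_base_quality:
            continue
        if ch == ".":
            if ref_idx is not None:
                fwd[ref_idx] += 1
        elif ch == ",":
            if ref_idx is not None:
                rev[ref_idx] += 1
        elif ch.upper() in BASE_INDEX:
            if ch.isupper():
                fwd[BASE_INDEX[ch]] += 1
            else:
                rev[BASE_INDEX[ch.upper()]] += 1
        else:
            raise TallyFormatError(
                f"line {lineno}: unexpected pileup symbol {ch!r}"
            )
    return StrandedBaseCount(fwd, rev)


def from_mpileup(stream, min_base_quality: int = 0) -> Iterator[SiteRecord]:
    """Parse samtools-mpileup text (ancestor column first) into SiteRecords.

    The pileup must have been generated with the desired mapping/base
    quality cutoffs (``samtools mpileup -q/-Q``); ``min_base_quality``
    applies an additional per-base filter from the quality strings.
    """
    fh = _open_text(stream)
    close = not hasattr(stream, "read")
    try:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if (len(fields) - 3) % 3 != 0 or len(fields) < 6:
                raise TallyFormatError(
                    f"line {lineno}: expected chrom, pos, ref + 3 columns per sample"
                )
            chrom, pos_s, ref = fields[0], fields[1], fields[2]
            try:
                pos = int(pos_s)
            except ValueError:
                raise TallyFormatError(f"line {lineno}: bad position {pos_s!r}") from None
            counts = []
            for s in range(3, len(fields), 3):
                bases, quals = fields[s + 1], fields[s + 2]
                counts.append(
                    _parse_pileup_bases(bases, quals, ref, lineno, min_base_quality)
                )
            yield SiteRecord(chrom, pos, ref, counts[0], counts[1:])
    finally:
        if close:
            fh.close()


# ---------------------------------------------------------------------------
# Non-reference-frequency diagnostic
# ---------------------------------------------------------------------------

def nonref_frequency_profile(tally: Tally | Iterable[SiteRecord],
                             n_bins: int = 20) -> pd.DataFrame:
    """Per-sample summary of non-reference read fractions across sites.

    Flags anomalous lines (elevated heteroplasmic-like noise): returns a
    DataFrame indexed by sample label with ``mean_nonref`` and a histogram
    of per-site non-reference fractions over [0, 1] in ``n_bins`` bins
    (columns ``bin_00`` ...).  Zero-coverage sites are excluded from a
    sample's denominator; sites with unknown reference base are skipped.
    """
    if not isinstance(tally, Tally):
        tally = Tally.from_records(tally)
    ref_idx = np.array([BASE_INDEX.get(str(r).upper(), -1) for r in tally.ref])
    keep = ref_idx >= 0
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    rows = {}
    all_counts = np.concatenate(
        [tally.anc_collapsed()[:, None, :], tally.desc_collapsed()], axis=1
    )  # (S, 1+n, 4)
    for j, label in enumerate(tally.samples):
        counts = all_counts[keep, j, :]
        depth = counts.sum(axis=1)
        ok = depth > 0
        ref_reads = counts[np.arange(len(counts)), ref_idx[keep]]
        frac = (depth[ok] - ref_reads[ok]) / depth[ok]
        hist, _ = np.histogram(frac, bins=edges)
        rows[label] = {
            "mean_nonref": float(frac.mean()) if len(frac) else np.nan,
            **{f"bin_{k:02d}": int(hist[k]) for k in range(n_bins)},
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "sample"
    return out
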