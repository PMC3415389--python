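"""Domain types and readers/writers for the formats the tool touches.

All coordinates are 0-based internally; BED intervals are half-open, and the
1-based SAM convention is converted at parse time and nowhere else.  For a
minus-strand alignment the read's 5' end is the highest coordinate of the
alignment interval.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .read_model import ReadSpatialDistribution

log = logging.getLogger(__name__)

__all__ = [
    "ReadAlignment",
    "BindingEvent",
    "GenomeAccessor",
    "ParseError",
    "parse_reads",
    "write_events",
    "parse_events",
    "write_read_distribution",
    "read_read_distribution",
    "write_meme",
    "write_fasta",
]


class ParseError(ValueError):
    """Malformed input line; the message names the offending line number."""


@dataclass(frozen=True, slots=True)
class ReadAlignment:
    """One mapped read reduced to its chromosome, 5' coordinate and strand."""

    chrom: str
    pos5: int
    strand: str

    def __post_init__(self) -> None:
        if self.pos5 < 0:
            raise ValueError(f"pos5 must be >= 0, got {self.pos5}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")


@dataclass(slots=True)
class BindingEvent:
    """A called binding event: the single base at the center of the
    protein-DNA interaction, with its effective read count (strength),
    significance and optional motif annotation."""

    chrom: str
    pos: int
    strength: float
    p_value: float = 1.0
    q_value: float = 1.0
    fold: float = math.inf
    motif_offset: int | None = None
    motif_strand: str | None = None

    def __post_init__(self) -> None:
        if self.strength < 0:
            raise ValueError("strength must be non-negative")


class GenomeAccessor:
    """Chromosome name -> sequence over {A,C,G,T,N}.

    Subsequence queries outside chromosome bounds raise; ``fetch_clipped``
    clips instead.  There is never silent wraparound.
    """

    def __init__(self, seqs: Mapping[str, str]):
        self._seqs = {c: s.upper() for c, s in seqs.items()}

    @classmethod
    def from_fasta(cls, path: str | Path) -> "GenomeAccessor":
        from pyfaidx import Fasta

        fa = Fasta(str(path), as_raw=True, sequence_always_upper=True)
        return cls({name: str(fa[name][:]) for name in fa.keys()})

    @property
    def chroms(self) -> list[str]:
        return list(self._seqs)

    @property
    def lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self._seqs.items()}

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self._seqs.values())

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._seqs

    def fetch(self, chrom: str, start: int, end: int) -> str:
        seq = self._seqs[chrom]
        if start < 0 or end > len(seq) or start > end:
            raise ValueError(
                f"query {chrom}:{start}-{end} outside chromosome bounds [0,{len(seq)})"
            )
        return seq[start:end]

    def fetch_clipped(self, chrom: str, start: int, end: int) -> str:
        seq = self._seqs[chrom]
        return seq[max(0, start) : min(len(seq), end)]


# ---------------------------------------------------------------------------
# read parsing
# ---------------------------------------------------------------------------

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")
_REF_CONSUMING = set("MDN=X")


def _cigar_ref_span(cigar: str) -> int:
    span = 0
    matched = 0
    for m in _CIGAR_RE.finditer(cigar):
        matched += len(m.group(0))
        if m.group(2) in _REF_CONSUMING:
            span += int(m.group(1))
    if matched != len(cigar):
        raise ValueError(f"bad CIGAR {cigar!r}")
    return span


def parse_reads(
    path: str | Path,
    format: str | None = None,
    min_mapq: int | None = None,
    dup_cap: int | None = None,
) -> list[ReadAlignment]:
    """Parse a BED6 or SAM file into ReadAlignments.

    ``format`` is inferred from the suffix when omitted.  Unmapped SAM records
    are skipped (with a logged count).  ``min_mapq`` optionally drops
    low-quality alignments; ``dup_cap`` optionally caps the number of reads
    sharing one (chrom, pos5, strand), both off by default.
    """
    path = Path(path)
    if format is None:
        suffix = path.suffix.lower()
        format = {".bed": "bed", ".sam": "sam"}.get(suffix)
        if format is None:
            raise ValueError(f"cannot infer format from suffix {suffix!r}")
    if format == "bed":
        reads = _parse_bed(path)
    elif format == "sam":
        reads = _parse_sam(path, min_mapq=min_mapq)
    else:
        raise ValueError(f"unknown format {format!r}")

    if dup_cap is not None:
        seen: dict[tuple[str, int, str], int] = {}
        capped = []
        for r in reads:
            key = (r.chrom, r.pos5, r.strand)
            n = seen.get(key, 0)
            if n < dup_cap:
                capped.append(r)
            seen[key] = n + 1
        reads = capped
    return reads


def _parse_bed(path: Path) -> list[ReadAlignment]:
    reads = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 6:
                raise ParseError(f"{path}:{ln}: BED6 needs 6 fields, got {len(fields)}")
            try:
                chrom, start, end, strand = fields[0], int(fields[1]), int(fields[2]), fields[5]
            except ValueError as exc:
                raise ParseError(f"{path}:{ln}: {exc}") from exc
            if strand not in ("+", "-"):
                raise ParseError(f"{path}:{ln}: bad strand {strand!r}")
            if end <= start:
                raise ParseError(f"{path}:{ln}: empty interval")
            pos5 = start if strand == "+" else end - 1
            reads.append(ReadAlignment(chrom, pos5, strand))
    return reads


def _parse_sam(path: Path, min_mapq: int | None = None) -> list[ReadAlignment]:
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("@"):
        try:
            return _parse_sam_pysam(path, min_mapq)
        except Exception as exc:  # pragma: no cover - fall through to text parser
            log.warning("pysam failed on %s (%s); using text parser", path, exc)
    return _parse_sam_text(path, min_mapq)


def _parse_sam_pysam(path: Path, min_mapq: int | None) -> list[ReadAlignment]:
    import pysam

    reads = []
    skipped = 0
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for aln in fh:
            if aln.is_unmapped:
                skipped += 1
                continue
            if min_mapq is not None and aln.mapping_quality < min_mapq:
                continue
            if aln.is_reverse:
                pos5 = aln.reference_end - 1
                strand = "-"
            else:
                pos5 = aln.reference_start
                strand = "+"
            reads.append(ReadAlignment(aln.reference_name, pos5, strand))
    if skipped:
        log.info("skipped %d unmapped SAM records in %s", skipped, path)
    return reads


def _parse_sam_text(path: Path, min_mapq: int | None) -> list[ReadAlignment]:
    reads = []
    skipped = 0
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("@"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 11:
                raise ParseError(f"{path}:{ln}: SAM needs 11 fields, got {len(fields)}")
            try:
                flag = int(fields[1])
                pos1 = int(fields[3])
                mapq = int(fields[4])
            except ValueError as exc:
                raise ParseError(f"{path}:{ln}: {exc}") from exc
            if flag & 0x4 or fields[2] == "*":
                skipped += 1
                continue
            if min_mapq is not None and mapq < min_mapq:
                continue
            start0 = pos1 - 1
            if flag & 0x10:
                try:
                    span = _cigar_ref_span(fields[5])
                except ValueError as exc:
                    raise ParseError(f"{path}:{ln}: {exc}") from exc
                reads.append(ReadAlignment(fields[2], start0 + span - 1, "-"))
            else:
                reads.append(ReadAlignment(fields[2], start0, "+"))
    if skipped:
        log.info("skipped %d unmapped SAM records in %s", skipped, path)
    return reads


# ---------------------------------------------------------------------------
# event table
# ---------------------------------------------------------------------------

_EVENT_COLUMNS = [
    "chrom",
    "pos",
    "strength",
    "fold",
    "p_value",
    "q_value",
    "motif_offset",
    "motif_strand",
]


def _fmt_real(x: float) -> str:
    if math.isinf(x):
        return "inf"
    return f"{x:.6g}"


def write_events(events: Sequence[BindingEvent], path: str | Path) -> None:
    """Write a sorted event table (tab-delimited, header line first)."""
    keys = [(e.chrom, e.pos) for e in events]
    if keys != sorted(keys):
        raise ValueError("events must be sorted by (chrom, pos)")
    with open(path, "w") as fh:
        fh.write("\t".join(_EVENT_COLUMNS) + "\n")
        for e in events:
            fh.write(
                "\t".join(
                    [
                        e.chrom,
                        str(e.pos),
                        _fmt_real(e.strength),
                        _fmt_real(e.fold),
                        _fmt_real(e.p_value),
                        _fmt_real(e.q_value),
                        "." if e.motif_offset is None else str(e.motif_offset),
                        "." if e.motif_strand is None else e.motif_strand,
                    ]
                )
                + "\n"
            )


def parse_events(path: str | Path) -> list[BindingEvent]:
    events = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _EVENT_COLUMNS:
            raise ParseError(f"{path}:1: unexpected header {header}")
        for ln, line in enumerate(fh, 2):
            f = line.rstrip("\n").split("\t")
            if len(f) != len(_EVENT_COLUMNS):
                raise ParseError(f"{path}:{ln}: expected {len(_EVENT_COLUMNS)} fields")
            events.append(
                BindingEvent(
                    chrom=f[0],
                    pos=int(f[1]),
                    strength=float(f[2]),
                    fold=float(f[3]),
                    p_value=float(f[4]),
                    q_value=float(f[5]),
                    motif_offset=None if f[6] == "." else int(f[6]),
                    motif_strand=None if f[7] == "." else f[7],
                )
            )
    return events


# ---------------------------------------------------------------------------
# read spatial distribution text format
# ---------------------------------------------------------------------------


def write_read_distribution(dist: ReadSpatialDistribution, path: str | Path) -> None:
    """Two-column text: signed offset (bp), plus-strand probability."""
    with open(path, "w") as fh:
        for off, p in zip(dist.support, dist.prob_plus):
            fh.write(f"{off}\t{p:.10g}\n")


def read_read_distribution(path: str | Path, W: int | None = None) -> ReadSpatialDistribution:
    offsets = []
    probs = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            f = line.split()
            if len(f) != 2:
                raise ParseError(f"{path}:{ln}: expected two columns")
            try:
                off, p = int(f[0]), float(f[1])
            except ValueError as exc:
                raise ParseError(f"{path}:{ln}: {exc}") from exc
            if offsets and off <= offsets[-1]:
                raise ParseError(f"{path}:{ln}: offsets must be strictly increasing")
            if p < 0:
                raise ParseError(f"{path}:{ln}: negative probability")
            offsets.append(off)
            probs.append(p)
    if not offsets:
        raise ParseError(f"{path}: empty distribution")
    if W is None:
        W = max(abs(offsets[0]), abs(offsets[-1]))
    prob = np.zeros(2 * W + 1)
    for off, p in zip(offsets, probs):
        if abs(off) > W:
            raise ParseError(f"{path}: offset {off} outside support [-{W},{W}]")
        prob[off + W] = p
    return ReadSpatialDistribution(prob, W=W)


# ---------------------------------------------------------------------------
# motif + sequence output
# ---------------------------------------------------------------------------


def write_meme(pwms, path: str | Path, background: np.ndarray | None = None) -> None:
    """Write PWMs in MEME minimal motif format (letter-probability matrices)."""
    if background is None:
        background = np.full(4, 0.25)
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        fh.write(
            "Background letter frequencies\n"
            f"A {background[0]:.5f} C {background[1]:.5f} "
            f"G {background[2]:.5f} T {background[3]:.5f}\n\n"
        )
        for i, pwm in enumerate(pwms, 1):
            probs = pwm.probabilities()
            fh.write(f"MOTIF {getattr(pwm, 'name', None) or f'motif_{i}'}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {probs.shape[0]} "
                f"nsites= 20 E= {pwm.p_hyper:.3g}\n"
            )
            for row in probs:
                fh.write(" ".join(f"{x:.6f}" for x in row) + "\n")
            fh.write("\n")


def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
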