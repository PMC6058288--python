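"""Transposon-tag verification, junction mapping, and insertion profiles.

Reads from a TraDIS library begin with a fixed transposon tag; the genomic
remainder starts at the base immediately downstream of the insertion
junction.  This module strips the tag, places the genomic remainder on the
reference by exact k-mer lookup (both strands, circular chromosome), and
aggregates placements into per-sample insertion profiles.

Coordinate convention: the insertion coordinate is the first genomic base
after the junction in the forward reference frame; for reverse-strand reads
this is the last reference base covered by the match.  Same-coordinate
opposite-strand sites are two distinct unique insertion sites (UIS).
"""

from __future__ import annotations

import gzip
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, NamedTuple

import numpy as np

from .simlib import reverse_complement

__all__ = [
    "TagSpec",
    "TrimResult",
    "MapResult",
    "GenomeIndex",
    "InsertionProfile",
    "check_and_trim_tag",
    "map_read",
    "build_insertion_profile",
    "process_reads",
    "read_fastq_sequences",
    "profile_to_tsv",
    "profile_from_tsv",
    "write_per_base_plot",
    "profile_from_sam",
    "profile_from_bed",
]

# Trim / map status codes
OK = "ok"
REJECT_TOO_SHORT = "too_short"
REJECT_TAG_MISMATCH = "tag_mismatch"
MAPPED = "mapped"
AMBIGUOUS = "ambiguous"
UNMAPPED = "unmapped"

_AMBIGUOUS_SENTINEL = ("ambiguous", -1, "")


@dataclass(frozen=True)
class TagSpec:
    """The expected transposon prefix of every read."""

    tag_sequence: str
    max_mismatches: int = 0

    def __post_init__(self) -> None:
        if len(self.tag_sequence) < 1:
            raise ValueError("tag must have length >= 1")
        if self.max_mismatches < 0:
            raise ValueError("max_mismatches must be >= 0")


class TrimResult(NamedTuple):
    status: str  # OK / REJECT_TOO_SHORT / REJECT_TAG_MISMATCH
    trimmed: str | None


class MapResult(NamedTuple):
    status: str  # MAPPED / AMBIGUOUS / UNMAPPED
    position: int | None
    strand: str | None


def check_and_trim_tag(read: str, spec: TagSpec) -> TrimResult:
    """Strip the transposon tag if the read prefix matches within tolerance.

    Reads whose prefix is farther than ``max_mismatches`` (Hamming) from the
    tag are rejected; reads not longer than the tag are rejected with a
    distinct reason code.
    """
    tag = spec.tag_sequence
    if len(read) <= len(tag):
        return TrimResult(REJECT_TOO_SHORT, None)
    prefix = read[: len(tag)]
    if prefix == tag:
        return TrimResult(OK, read[len(tag):])
    mismatches = sum(a != b for a, b in zip(prefix, tag))
    if mismatches <= spec.max_mismatches:
        return TrimResult(OK, read[len(tag):])
    return TrimResult(REJECT_TAG_MISMATCH, None)


class GenomeIndex:
    """Exact k-mer index over both strands of a (circular) reference.

    Lookup tables are built lazily per k-mer length and cached.  A k-mer
    occurring at more than one (position, strand) is marked ambiguous so the
    corresponding reads can be discarded rather than creating phantom sites.
    """

    def __init__(self, sequence: str, circular: bool = True) -> None:
        if not sequence:
            raise ValueError("empty reference sequence")
        self.sequence = sequence
        self.circular = circular
        self._tables: dict[int, dict[str, tuple]] = {}

    def _build(self, k: int) -> dict[str, tuple]:
        seq = self.sequence
        length = len(seq)
        table: dict[str, tuple] = {}

        def add(kmer: str, hit: tuple) -> None:
            prev = table.get(kmer)
            if prev is None:
                table[kmer] = hit
            elif prev != hit:
                table[kmer] = _AMBIGUOUS_SENTINEL

        if self.circular:
            reps = k // length + 2
            ext = (seq * reps)[: length + k - 1]
            fwd_range = range(length)
        else:
            ext = seq
            fwd_range = range(max(length - k + 1, 0))
        for i in fwd_range:
            add(ext[i : i + k], (MAPPED, i, "+"))

        rc = reverse_complement(seq)
        if self.circular:
            reps = k // length + 2
            rc_ext = (rc * reps)[: length + k - 1]
            rc_range = range(length)
        else:
            rc_ext = rc
            rc_range = range(max(length - k + 1, 0))
        # the first base of a reverse-complement k-mer starting at rc index i
        # is reference position (length - 1 - i); it is the LAST reference
        # base of the forward-frame match, i.e. the insertion coordinate.
        for i in rc_range:
            pos = (length - 1 - i) % length
            add(rc_ext[i : i + k], (MAPPED, pos, "-"))
        return table

    def lookup(self, kmer: str) -> tuple:
        table = self._tables.get(len(kmer))
        if table is None:
            table = self._build(len(kmer))
            self._tables[len(kmer)] = table
        return table.get(kmer, (UNMAPPED, None, None))


def map_read(trimmed: str, index: GenomeIndex) -> MapResult:
    """Place a tag-stripped read on the reference by exact match.

    Returns the 0-based coordinate of the first genomic base after the
    transposon junction (forward frame) and the strand; multi-locus matches
    are ambiguous, absent k-mers unmapped.
    """
    if not trimmed:
        raise ValueError("empty trimmed read")
    status, pos, strand = index.lookup(trimmed)
    if status == MAPPED:
        return MapResult(MAPPED, pos, strand)
    if status == AMBIGUOUS or (status, pos, strand) == _AMBIGUOUS_SENTINEL:
        return MapResult(AMBIGUOUS, None, None)
    return MapResult(UNMAPPED, None, None)


@dataclass
class InsertionProfile:
    """Per-sample mapping (position, strand) -> read count, with bookkeeping.

    ``counts`` is keyed by (0-based position, '+'/'-').  The unique insertion
    sites (UIS) of a sample are the distinct keys.
    """

    genome_length: int
    counts: dict[tuple[int, str], int] = field(default_factory=dict)
    n_reads_total: int = 0
    n_reads_tagged: int = 0
    n_reads_mapped: int = 0
    n_reads_ambiguous: int = 0
    n_reads_unmapped: int = 0
    n_reads_rejected: int = 0

    def __post_init__(self) -> None:
        for (pos, strand), c in self.counts.items():
            if not 0 <= pos < self.genome_length:
                raise ValueError(f"position {pos} outside genome")
            if strand not in ("+", "-"):
                raise ValueError(f"invalid strand {strand!r}")
            if c < 0:
                raise ValueError("negative count")
        mapped = sum(self.counts.values())
        if mapped != self.n_reads_mapped:
            raise ValueError("profile counts do not sum to n_reads_mapped")
        if not (self.n_reads_mapped <= self.n_reads_tagged <= self.n_reads_total):
            raise ValueError("bookkeeping totals inconsistent")

    @property
    def uis(self) -> int:
        return len(self.counts)

    def conserved(self) -> bool:
        """Exact read partition: total = rejected + unmapped + ambiguous + mapped."""
        return self.n_reads_total == (
            self.n_reads_rejected
            + self.n_reads_unmapped
            + self.n_reads_ambiguous
            + self.n_reads_mapped
        )


def build_insertion_profile(
    mappings: Iterable[tuple[int, str]],
    genome_length: int,
    n_reads_total: int | None = None,
    n_reads_tagged: int | None = None,
) -> InsertionProfile:
    """Aggregate mapped (position, strand) pairs into a profile."""
    counts = Counter(mappings)
    n_mapped = sum(counts.values())
    return InsertionProfile(
        genome_length=genome_length,
        counts=dict(counts),
        n_reads_total=n_mapped if n_reads_total is None else n_reads_total,
        n_reads_tagged=n_mapped if n_reads_tagged is None else n_reads_tagged,
        n_reads_mapped=n_mapped,
    )


def process_reads(
    reads: Iterable[str], spec: TagSpec, index: GenomeIndex
) -> InsertionProfile:
    """Full per-sample pass: tag check, trim, map, aggregate.

    Identical read sequences are deduplicated internally (their trim and map
    outcomes are identical), which makes processing cost scale with the
    number of distinct reads rather than sequencing depth.
    """
    seq_counts = Counter(str(r.seq) if hasattr(r, "seq") else r for r in reads)
    counts: Counter = Counter()
    total = tagged = mapped = ambiguous = unmapped = rejected = 0
    for seq, n in seq_counts.items():
        total += n
        status, trimmed = check_and_trim_tag(seq, spec)
        if status != OK:
            rejected += n
            continue
        tagged += n
        res = map_read(trimmed, index)
        if res.status == MAPPED:
            mapped += n
            counts[(res.position, res.strand)] += n
        elif res.status == AMBIGUOUS:
            ambiguous += n
        else:
            unmapped += n
    return InsertionProfile(
        genome_length=len(index.sequence),
        counts=dict(counts),
        n_reads_total=total,
        n_reads_tagged=tagged,
        n_reads_mapped=mapped,
        n_reads_ambiguous=ambiguous,
        n_reads_unmapped=unmapped,
        n_reads_rejected=rejected,
    )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def read_fastq_sequences(path: str | Path) -> Iterator[str]:
    """Yield read sequences from FASTQ, transparently handling gzip."""
    from Bio import SeqIO

    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            yield str(rec.seq)


def profile_to_tsv(profile: InsertionProfile, path: str | Path) -> None:
    """Write ``position<TAB>strand<TAB>count`` sorted by coordinate."""
    with open(path, "w") as fh:
        fh.write(f"# genome_length={profile.genome_length}"
                 f"\ttotal={profile.n_reads_total}"
                 f"\ttagged={profile.n_reads_tagged}"
                 f"\tmapped={profile.n_reads_mapped}"
                 f"\tambiguous={profile.n_reads_ambiguous}"
                 f"\tunmapped={profile.n_reads_unmapped}"
                 f"\trejected={profile.n_reads_rejected}\n")
        fh.write("position\tstrand\tcount\n")
        for (pos, strand), c in sorted(profile.counts.items()):
            fh.write(f"{pos}\t{strand}\t{c}\n")


def profile_from_tsv(path: str | Path) -> InsertionProfile:
    meta: dict[str, int] = {}
    counts: dict[tuple[int, str], int] = {}
    with open(path) as fh:
        header = fh.readline()
        if header.startswith("#"):
            for kv in header[1:].strip().split("\t"):
                k, v = kv.split("=")
                meta[k] = int(v)
            fh.readline()  # column header
        for line in fh:
            pos, strand, c = line.rstrip("\n").split("\t")
            counts[(int(pos), strand)] = int(c)
    mapped = sum(counts.values())
    return InsertionProfile(
        genome_length=meta.get("genome_length", (max(p for p, _ in counts) + 1) if counts else 0),
        counts=counts,
        n_reads_total=meta.get("total", mapped),
        n_reads_tagged=meta.get("tagged", mapped),
        n_reads_mapped=meta.get("mapped", mapped),
        n_reads_ambiguous=meta.get("ambiguous", 0),
        n_reads_unmapped=meta.get("unmapped", 0),
        n_reads_rejected=meta.get("rejected", 0),
    )


def write_per_base_plot(profile: InsertionProfile, path: str | Path) -> None:
    """Two-column per-base insert plot (forward count, reverse count).

    One row per genome base, the format consumed by common TraDIS plotters.
    """
    fwd = np.zeros(profile.genome_length, dtype=np.int64)
    rev = np.zeros(profile.genome_length, dtype=np.int64)
    for (pos, strand), c in profile.counts.items():
        (fwd if strand == "+" else rev)[pos] += c
    np.savetxt(path, np.column_stack([fwd, rev]), fmt="%d", delimiter=" ")


def profile_from_sam(path: str | Path, genome_length: int | None = None) -> InsertionProfile:
    """Ingest externally mapped reads (SAM/BAM) as an insertion profile.

    Forward alignments contribute their leftmost reference coordinate on
    '+'; reverse alignments their rightmost coordinate on '-', matching the
    junction convention used by the internal mapper.
    """
    import pysam

    mappings: list[tuple[int, str]] = []
    total = 0
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        if genome_length is None:
            genome_length = sum(fh.lengths)
        for aln in fh:
            if aln.is_secondary or aln.is_supplementary:
                continue
            total += 1
            if aln.is_unmapped:
                continue
            if aln.is_reverse:
                mappings.append((aln.reference_end - 1, "-"))
            else:
                mappings.append((aln.reference_start, "+"))
    profile = build_insertion_profile(mappings, genome_length, n_reads_total=total,
                                      n_reads_tagged=total)
    profile.n_reads_unmapped = total - profile.n_reads_mapped
    return profile


def profile_from_bed(path: str | Path, genome_length: int) -> InsertionProfile:
    """Ingest insertion points from BED6 (score column = read count)."""
    mappings: dict[tuple[int, str], int] = Counter()
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            cols = line.rstrip("\n").split("\t")
            pos = int(cols[1])
            strand = cols[5] if len(cols) > 5 else "+"
            count = int(float(cols[4])) if len(cols) > 4 and cols[4] not in (".", "") else 1
            mappings[(pos, strand)] += count
    n = sum(mappings.values())
    return InsertionProfile(
        genome_length=genome_length,
        counts=dict(mappings),
        n_reads_total=n,
        n_reads_tagged=n,
        n_reads_mapped=n,
    )
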