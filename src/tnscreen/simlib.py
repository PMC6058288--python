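"""Synthetic TraDIS data: genomes, saturating Tn5 libraries, phage selection, reads.

The generator emulates a pooled transposon-mutant library of a bacterial
chromosome at saturating density (one insertion site per ~47 bp by default),
a phage-selection experiment in which mutants of "susceptibility genes"
expand and mutants of "resistance genes" contract, and the resulting
transposon-directed sequencing reads: 50-bp single-end reads whose first
10 bp are transposon sequence and whose remainder is the genomic sequence
immediately downstream of the insertion junction.

All randomness derives from a single integer seed; identical configuration
and seed produce byte-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from itertools import repeat
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "SimConfig",
    "Gene",
    "GenomeAnnotation",
    "MutantLibrary",
    "FitnessMap",
    "simulate_genome",
    "simulate_library",
    "apply_selection",
    "generate_reads",
    "generate_read_sequences",
    "write_fasta",
    "write_gff3",
    "read_gff3",
    "write_fastq",
    "write_ground_truth",
    "reverse_complement",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_RC_TABLE = str.maketrans("ACGTacgt", "TGCAtgca")

# Independent random streams for the three stochastic stages, so that e.g.
# redrawing a library does not perturb the genome sequence.
_STAGE_GENOME = 1
_STAGE_LIBRARY = 2
_STAGE_READS = 3


def reverse_complement(seq: str) -> str:
    return seq.translate(_RC_TABLE)[::-1]


def _rng(stage: int, seed: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(stage,)))


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the simulated screen.

    Defaults mirror the study design the simulator emulates: a saturating
    Tn5 library with one insertion per 47 bp, 50-bp single-end reads with a
    10-bp transposon tag, and selections sampled at a depth of 2e5 reads
    per sample.  ``generations`` is the per-selection growth-cycle count by
    which gene fitness is compounded (dose and exposure time both act
    through it).
    """

    n_genes: int = 200
    gene_length_bp: int = 600
    intergenic_length_bp: int = 150
    essential_fraction: float = 0.05
    insertion_density_bp: float = 47.0
    read_length_bp: int = 50
    tag_length_bp: int = 10
    tag_sequence: str = "ATACACATCT"  # 3' end of the Tn5 mosaic end
    depth_per_sample: int = 200_000
    generations: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 0:
            raise ValueError("n_genes must be >= 0")
        for name in ("gene_length_bp", "intergenic_length_bp", "read_length_bp",
                     "tag_length_bp", "depth_per_sample"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0.0 <= self.essential_fraction <= 1.0:
            raise ValueError("essential_fraction must lie in [0, 1]")
        if self.insertion_density_bp <= 0:
            raise ValueError("insertion_density_bp must be > 0")
        if self.tag_length_bp >= self.read_length_bp:
            raise ValueError("tag_length_bp must be < read_length_bp")
        if len(self.tag_sequence) != self.tag_length_bp:
            raise ValueError("tag_sequence length must equal tag_length_bp")
        if self.generations < 0:
            raise ValueError("generations must be >= 0")

    def with_seed(self, seed: int) -> "SimConfig":
        return replace(self, seed=seed)


@dataclass(frozen=True)
class Gene:
    gene_id: str
    start: int  # 0-based inclusive
    end: int    # 0-based exclusive
    strand: str
    essential: bool = False


@dataclass
class GenomeAnnotation:
    """Reference sequence plus non-overlapping gene intervals.

    Coordinates are 0-based half-open internally; GFF3 output converts to
    1-based inclusive at the I/O boundary.
    """

    sequence: str
    genes: list[Gene] = field(default_factory=list)

    def __post_init__(self) -> None:
        length = len(self.sequence)
        self.genes = sorted(self.genes, key=lambda g: g.start)
        seen: set[str] = set()
        prev_end = 0
        for g in self.genes:
            if not 0 <= g.start < g.end <= length:
                raise ValueError(f"gene {g.gene_id} outside genome bounds")
            if g.start < prev_end:
                raise ValueError(f"gene {g.gene_id} overlaps a previous gene")
            if g.gene_id in seen:
                raise ValueError(f"duplicate gene_id {g.gene_id}")
            seen.add(g.gene_id)
            prev_end = g.end
        self._starts = np.array([g.start for g in self.genes], dtype=np.int64)
        self._ends = np.array([g.end for g in self.genes], dtype=np.int64)

    def __len__(self) -> int:
        return len(self.sequence)

    def gene_index_of(self, positions: np.ndarray) -> np.ndarray:
        """Index of the gene containing each position, or -1 if intergenic."""
        positions = np.asarray(positions, dtype=np.int64)
        if len(self.genes) == 0:
            return np.full(positions.shape, -1, dtype=np.int64)
        idx = np.searchsorted(self._starts, positions, side="right") - 1
        inside = (idx >= 0) & (positions < self._ends[np.clip(idx, 0, None)])
        return np.where(inside, idx, -1)

    def essential_mask(self) -> np.ndarray:
        """Boolean per-base mask of essential-gene territory."""
        mask = np.zeros(len(self.sequence), dtype=bool)
        for g in self.genes:
            if g.essential:
                mask[g.start:g.end] = True
        return mask


@dataclass
class MutantLibrary:
    """Pooled transposon library: (position, strand) sites with abundances.

    Strand is encoded 0 for '+' and 1 for '-'.  Same-position opposite-strand
    insertions are distinct mutants (Tn5 inserts in either orientation).
    """

    positions: np.ndarray
    strands: np.ndarray
    abundance: np.ndarray
    genome_length: int

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.strands = np.asarray(self.strands, dtype=np.int8)
        self.abundance = np.asarray(self.abundance, dtype=np.float64)
        if not (len(self.positions) == len(self.strands) == len(self.abundance)):
            raise ValueError("positions, strands, abundance must align")
        if len(self.positions) and (
            self.positions.min() < 0 or self.positions.max() >= self.genome_length
        ):
            raise ValueError("insertion positions outside genome")
        if np.any(self.abundance < 0):
            raise ValueError("abundances must be non-negative")

    @property
    def n_insertions(self) -> int:
        return len(self.positions)

    def strand_chars(self) -> np.ndarray:
        return np.where(self.strands == 0, "+", "-")


@dataclass
class FitnessMap:
    """Per-gene relative fitness under selection.

    w = 1 is neutral; w > 1 models susceptibility-gene mutants expanding
    under phage pressure, w < 1 resistance-gene mutants contracting.
    Insertions outside any gene grow at ``default_w``; genes absent from
    the mapping are neutral.
    """

    w: Mapping[str, float] = field(default_factory=dict)
    default_w: float = 1.0

    def __post_init__(self) -> None:
        if self.default_w < 0 or any(v < 0 for v in self.w.values()):
            raise ValueError("fitness values must be >= 0")

    def for_gene(self, gene_id: str | None) -> float:
        if gene_id is None:
            return self.default_w
        return float(self.w.get(gene_id, 1.0))


def simulate_genome(config: SimConfig) -> GenomeAnnotation:
    """Lay out a genome as alternating intergenic and gene blocks.

    The first ``ceil(n_genes * essential_fraction)`` genes are flagged
    essential (deterministic assignment; essentiality acts only through
    insertion rejection in :func:`simulate_library`).
    """
    rng = _rng(_STAGE_GENOME, config.seed)
    n = config.n_genes
    length = (n + 1) * config.intergenic_length_bp + n * config.gene_length_bp
    seq = rng.choice(_BASES, size=length).tobytes().decode("ascii")
    n_essential = math.ceil(n * config.essential_fraction)
    strands = rng.choice(np.array(["+", "-"]), size=n) if n else np.array([])
    genes = []
    width = max(5, len(str(max(n, 1))))
    for i in range(n):
        start = (i + 1) * config.intergenic_length_bp + i * config.gene_length_bp
        genes.append(
            Gene(
                gene_id=f"gene_{i:0{width}d}",
                start=start,
                end=start + config.gene_length_bp,
                strand=str(strands[i]),
                essential=i < n_essential,
            )
        )
    return GenomeAnnotation(sequence=seq, genes=genes)


def simulate_library(
    genome: GenomeAnnotation, config: SimConfig, seed: int | None = None
) -> MutantLibrary:
    """Draw a saturating library over the genome.

    Each base hosts an insertion with probability 1/insertion_density_bp
    (so the number of sites is Binomial(L, 1/d), mean L/d); each insertion
    gets a uniform random orientation and unit abundance.  Sites landing in
    essential genes are rejected: such mutants are never recovered.
    """
    length = len(genome)
    if length == 0:
        raise ValueError("cannot mutagenise a genome of length 0")
    rng = _rng(_STAGE_LIBRARY, config.seed if seed is None else seed)
    hits = rng.random(length) < 1.0 / config.insertion_density_bp
    positions = np.nonzero(hits)[0].astype(np.int64)
    strands = rng.integers(0, 2, size=len(positions), dtype=np.int8)
    if len(genome.genes):
        viable = ~genome.essential_mask()[positions]
        positions, strands = positions[viable], strands[viable]
    return MutantLibrary(
        positions=positions,
        strands=strands,
        abundance=np.ones(len(positions)),
        genome_length=length,
    )


def apply_selection(
    library: MutantLibrary,
    annotation: GenomeAnnotation,
    fitness: FitnessMap,
    generations: float,
) -> MutantLibrary:
    """Grow the pool under selection for ``generations`` growth cycles.

    Every insertion's abundance is multiplied by w_g**generations, where g
    is the gene containing the insertion (``default_w`` for intergenic
    sites), then renormalised to sum to 1.  The step is deterministic;
    sampling noise enters only at read generation.
    """
    if generations < 0:
        raise ValueError("generations must be >= 0")
    gene_idx = annotation.gene_index_of(library.positions)
    w_by_gene = np.array(
        [fitness.for_gene(g.gene_id) for g in annotation.genes] + [fitness.default_w]
    )
    w = w_by_gene[gene_idx]  # index -1 picks the intergenic default
    abundance = library.abundance * np.power(w, generations)
    total = abundance.sum()
    if total <= 0:
        raise ValueError("selection drove all abundances to zero")
    return MutantLibrary(
        positions=library.positions.copy(),
        strands=library.strands.copy(),
        abundance=abundance / total,
        genome_length=library.genome_length,
    )


def _oriented_suffix_sources(genome: GenomeAnnotation, k: int) -> tuple[str, str, int]:
    """Forward and reverse-complement sequence, extended for circular wrap."""
    fwd = genome.sequence
    length = len(fwd)
    reps = k // max(length, 1) + 2
    ext_fwd = (fwd * reps)[: length + k]
    rc = reverse_complement(fwd)
    ext_rc = (rc * reps)[: length + k]
    return ext_fwd, ext_rc, length


def genomic_suffix(genome: GenomeAnnotation, position: int, strand: int, k: int) -> str:
    """The k genomic bases read outward from an insertion junction.

    Forward-strand reads run from ``position`` rightward; reverse-strand
    reads cover the k bases ending at ``position`` and are emitted as the
    reverse complement.  The chromosome is treated as circular.
    """
    ext_fwd, ext_rc, length = _oriented_suffix_sources(genome, k)
    if strand == 0:
        return ext_fwd[position : position + k]
    start = length - 1 - position
    return ext_rc[start : start + k]


def generate_read_sequences(
    library: MutantLibrary,
    genome: GenomeAnnotation,
    config: SimConfig,
    seed: int | None = None,
) -> list[str]:
    """Draw ``depth_per_sample`` read sequences multinomially over insertions.

    Each read is the transposon tag followed by the genomic bases downstream
    of the junction in the insertion's orientation, ``read_length_bp`` total.
    """
    if library.n_insertions == 0:
        raise ValueError("cannot generate reads from an empty library")
    if config.depth_per_sample <= 0:
        raise ValueError("depth_per_sample must be > 0")
    rng = _rng(_STAGE_READS, config.seed if seed is None else seed)
    total = library.abundance.sum()
    if total <= 0:
        raise ValueError("library has zero total abundance")
    counts = rng.multinomial(config.depth_per_sample, library.abundance / total)
    k = config.read_length_bp - config.tag_length_bp
    ext_fwd, ext_rc, length = _oriented_suffix_sources(genome, k)
    reads: list[str] = []
    tag = config.tag_sequence
    for pos, strand, c in zip(library.positions, library.strands, counts):
        if c == 0:
            continue
        if strand == 0:
            suffix = ext_fwd[pos : pos + k]
        else:
            start = length - 1 - pos
            suffix = ext_rc[start : start + k]
        reads.extend(repeat(tag + suffix, int(c)))
    return reads


def generate_reads(
    library: MutantLibrary,
    genome: GenomeAnnotation,
    config: SimConfig,
    seed: int | None = None,
    sample: str = "sample",
):
    """FASTQ records (Biopython SeqRecords, constant base quality Q40)."""
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    seqs = generate_read_sequences(library, genome, config, seed=seed)
    records = []
    for i, s in enumerate(seqs):
        rec = SeqRecord(Seq(s), id=f"{sample}_read_{i:07d}", description="")
        rec.letter_annotations["phred_quality"] = [40] * len(s)
        records.append(rec)
    return records


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

CHROM_NAME = "chromosome"


def write_fasta(genome: GenomeAnnotation, path: str | Path) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    rec = SeqRecord(Seq(genome.sequence), id=CHROM_NAME, description="simulated genome")
    SeqIO.write([rec], str(path), "fasta")


def write_gff3(genome: GenomeAnnotation, path: str | Path) -> None:
    """GFF3 with 1-based inclusive coordinates and an ``essential`` attribute."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {CHROM_NAME} 1 {len(genome)}\n")
        for g in genome.genes:
            attrs = f"ID={g.gene_id};essential={'true' if g.essential else 'false'}"
            fh.write(
                f"{CHROM_NAME}\ttnscreen\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\t{attrs}\n"
            )


def read_gff3(path: str | Path, sequence: str) -> GenomeAnnotation:
    """Read gene intervals from GFF3 (the constrained dialect written above)."""
    genes = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 9 or cols[2] != "gene":
                continue
            attrs = dict(
                kv.split("=", 1) for kv in cols[8].split(";") if "=" in kv
            )
            genes.append(
                Gene(
                    gene_id=attrs.get("ID", f"gene_at_{cols[3]}"),
                    start=int(cols[3]) - 1,
                    end=int(cols[4]),
                    strand=cols[6],
                    essential=attrs.get("essential", "false").lower() == "true",
                )
            )
    return GenomeAnnotation(sequence=sequence, genes=genes)


def write_fastq(
    reads: Sequence[str], path: str | Path, sample: str = "sample", quality_char: str = "I"
) -> None:
    """Write read sequences as FASTQ with constant base quality.

    A plain-text writer is used for speed at simulation depths; records are
    standard four-line FASTQ readable by any parser.
    """
    with open(path, "w") as fh:
        for i, seq in enumerate(reads):
            fh.write(f"@{sample}_read_{i:07d}\n{seq}\n+\n{quality_char * len(seq)}\n")


def write_ground_truth(
    genome: GenomeAnnotation, fitness: FitnessMap, path: str | Path
) -> None:
    import pandas as pd

    rows = [
        {
            "gene_id": g.gene_id,
            "w": fitness.for_gene(g.gene_id),
            "essential": g.essential,
        }
        for g in genome.genes
    ]
    pd.DataFrame(rows, columns=["gene_id", "w", "essential"]).to_csv(
        path, sep="\t", index=False
    )
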