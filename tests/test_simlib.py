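"""Synthetic genome, library, selection, and read generation."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from tnscreen import simlib


class TestSimulateGenome:
    def test_alternating_layout(self):
        config = simlib.SimConfig(n_genes=2, gene_length_bp=600, intergenic_length_bp=100)
        genome = simlib.simulate_genome(config)
        assert len(genome) == 1500
        assert [(g.start, g.end) for g in genome.genes] == [(100, 700), (800, 1400)]

    def test_zero_genes_is_one_intergenic_block(self):
        config = simlib.SimConfig(n_genes=0, intergenic_length_bp=250)
        genome = simlib.simulate_genome(config)
        assert len(genome) == 250
        assert genome.genes == []

    def test_deterministic_given_seed(self):
        config = simlib.SimConfig(n_genes=5, seed=42)
        g1 = simlib.simulate_genome(config)
        g2 = simlib.simulate_genome(config)
        assert g1.sequence == g2.sequence
        assert g1.genes == g2.genes

    def test_essential_count_is_ceiling(self):
        config = simlib.SimConfig(n_genes=10, essential_fraction=0.25)
        genome = simlib.simulate_genome(config)
        essential = [g for g in genome.genes if g.essential]
        assert len(essential) == 3  # ceil(10 * 0.25)
        assert all(g.gene_id == genome.genes[i].gene_id for i, g in enumerate(essential))

    def test_sequence_is_nucleotides(self, tiny_genome):
        assert set(tiny_genome.sequence) <= set("ACGT")


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_genes": -1},
            {"essential_fraction": 1.5},
            {"insertion_density_bp": 0},
            {"tag_length_bp": 50, "read_length_bp": 50, "tag_sequence": "A" * 50},
            {"tag_sequence": "ACGT"},  # length mismatch with tag_length_bp
            {"depth_per_sample": 0},
        ],
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            simlib.SimConfig(**kwargs)


class TestSimulateLibrary:
    def test_mean_uis_matches_density(self):
        """Mean site count over 200 seeds approximates L/d = 100."""
        config = simlib.SimConfig(n_genes=0, intergenic_length_bp=4700,
                                  insertion_density_bp=47)
        genome = simlib.simulate_genome(config)
        counts = [
            simlib.simulate_library(genome, config, seed=s).n_insertions
            for s in range(200)
        ]
        mean = np.mean(counts)
        sem = np.std(counts, ddof=1) / np.sqrt(len(counts))
        assert abs(mean - 100.0) <= 3 * sem + 1e-9

    def test_fully_essential_genome_yields_empty_library(self):
        genome = simlib.GenomeAnnotation(
            sequence="ACGT" * 250,
            genes=[simlib.Gene("g1", 0, 1000, "+", essential=True)],
        )
        config = simlib.SimConfig(insertion_density_bp=10)
        library = simlib.simulate_library(genome, config)
        assert library.n_insertions == 0

    def test_no_insertions_in_essential_genes(self):
        config = simlib.SimConfig(n_genes=40, essential_fraction=0.2,
                                  insertion_density_bp=20, seed=3)
        genome = simlib.simulate_genome(config)
        library = simlib.simulate_library(genome, config)
        essential = genome.essential_mask()
        assert library.n_insertions > 0
        assert not essential[library.positions].any()

    def test_empty_genome_rejected(self):
        with pytest.raises(ValueError):
            simlib.simulate_library(
                simlib.GenomeAnnotation(sequence="", genes=[]), simlib.SimConfig()
            )

    def test_unit_abundance(self, tiny_library):
        assert np.all(tiny_library.abundance == 1.0)


class TestApplySelection:
    def test_neutral_selection_preserves_proportions(self, tiny_genome, tiny_library):
        out = simlib.apply_selection(
            tiny_library, tiny_genome, simlib.FitnessMap(), generations=7.0
        )
        expected = tiny_library.abundance / tiny_library.abundance.sum()
        np.testing.assert_allclose(out.abundance, expected)

    def test_relative_gain_is_w_to_the_t(self, tiny_genome, tiny_library):
        """One gene at w=2 over 3 generations gains a factor 8 pre-normalisation."""
        target = tiny_genome.genes[-1]
        fitness = simlib.FitnessMap(w={target.gene_id: 2.0})
        out = simlib.apply_selection(tiny_library, tiny_genome, fitness, generations=3.0)
        in_gene = (tiny_library.positions >= target.start) & (
            tiny_library.positions < target.end
        )
        assert in_gene.any() and (~in_gene).any()
        ratio_selected = out.abundance[in_gene][0] / out.abundance[~in_gene][0]
        ratio_before = (
            tiny_library.abundance[in_gene][0] / tiny_library.abundance[~in_gene][0]
        )
        assert ratio_selected / ratio_before == pytest.approx(8.0)

    def test_lethal_gene_zeroed(self, tiny_genome, tiny_library):
        target = tiny_genome.genes[-1]
        fitness = simlib.FitnessMap(w={target.gene_id: 0.0})
        out = simlib.apply_selection(tiny_library, tiny_genome, fitness, generations=2.0)
        in_gene = (tiny_library.positions >= target.start) & (
            tiny_library.positions < target.end
        )
        assert np.all(out.abundance[in_gene] == 0.0)
        assert out.abundance.sum() == pytest.approx(1.0)

    def test_all_zero_abundance_rejected(self, tiny_genome, tiny_library):
        fitness = simlib.FitnessMap(
            w={g.gene_id: 0.0 for g in tiny_genome.genes}, default_w=0.0
        )
        with pytest.raises(ValueError):
            simlib.apply_selection(tiny_library, tiny_genome, fitness, generations=1.0)


class TestGenerateReads:
    def test_read_structure(self, tiny_genome, tiny_library, tiny_config):
        reads = simlib.generate_read_sequences(tiny_library, tiny_genome, tiny_config)
        assert len(reads) == tiny_config.depth_per_sample
        k = tiny_config.read_length_bp - tiny_config.tag_length_bp
        assert all(len(r) == tiny_config.read_length_bp for r in reads[:100])
        assert all(r.startswith(tiny_config.tag_sequence) for r in reads[:100])
        assert len(reads[0]) - tiny_config.tag_length_bp == k == 40

    def test_single_insertion_library_gives_identical_reads(self, tiny_genome, tiny_config):
        library = simlib.MutantLibrary(
            positions=np.array([500]), strands=np.array([0]),
            abundance=np.array([1.0]), genome_length=len(tiny_genome),
        )
        reads = simlib.generate_read_sequences(library, tiny_genome, tiny_config)
        assert len(set(reads)) == 1

    def test_empty_library_rejected(self, tiny_genome, tiny_config):
        empty = simlib.MutantLibrary(
            positions=np.array([], dtype=int), strands=np.array([], dtype=int),
            abundance=np.array([]), genome_length=len(tiny_genome),
        )
        with pytest.raises(ValueError):
            simlib.generate_read_sequences(empty, tiny_genome, tiny_config)

    def test_circular_wraparound_at_genome_end(self, tiny_genome, tiny_config):
        pos = len(tiny_genome) - 5
        library = simlib.MutantLibrary(
            positions=np.array([pos]), strands=np.array([0]),
            abundance=np.array([1.0]), genome_length=len(tiny_genome),
        )
        read = simlib.generate_read_sequences(library, tiny_genome, tiny_config)[0]
        suffix = read[tiny_config.tag_length_bp:]
        expected = tiny_genome.sequence[pos:] + tiny_genome.sequence[:35]
        assert suffix == expected

    def test_reverse_strand_read_is_reverse_complement(self, tiny_genome, tiny_config):
        pos = 600
        library = simlib.MutantLibrary(
            positions=np.array([pos]), strands=np.array([1]),
            abundance=np.array([1.0]), genome_length=len(tiny_genome),
        )
        read = simlib.generate_read_sequences(library, tiny_genome, tiny_config)[0]
        suffix = read[tiny_config.tag_length_bp:]
        expected = simlib.reverse_complement(tiny_genome.sequence[pos - 39 : pos + 1])
        assert suffix == expected

    def test_fastq_byte_identical_across_runs(self, tiny_genome, tiny_library,
                                              tiny_config, tmp_path):
        paths = [tmp_path / "a.fastq", tmp_path / "b.fastq"]
        for p in paths:
            reads = simlib.generate_read_sequences(tiny_library, tiny_genome, tiny_config)
            simlib.write_fastq(reads, p)
        assert paths[0].read_bytes() == paths[1].read_bytes()

    def test_effect_size_links_to_fitness(self):
        """A gene's read-share logFC approximates t*log2(w) at high depth."""
        config = simlib.SimConfig(
            n_genes=1, gene_length_bp=500, intergenic_length_bp=50_000,
            essential_fraction=0.0, depth_per_sample=200_000, seed=5,
        )
        genome = simlib.simulate_genome(config)
        library = simlib.simulate_library(genome, config)
        gene = genome.genes[0]
        fitness = simlib.FitnessMap(w={gene.gene_id: 2.0})
        selected = simlib.apply_selection(library, genome, fitness, generations=3.0)

        def gene_share(lib, seed):
            # reads from the gene carry a genomic suffix originating inside it
            in_gene = (lib.positions >= gene.start) & (lib.positions < gene.end)
            gene_suffixes = {
                simlib.genomic_suffix(genome, int(p), int(s), 40)
                for p, s in zip(lib.positions[in_gene], lib.strands[in_gene])
            }
            reads = simlib.generate_read_sequences(lib, genome, config, seed=seed)
            return sum(r[10:] in gene_suffixes for r in reads) / len(reads)

        share_ctrl = gene_share(library, seed=101)
        share_sel = gene_share(selected, seed=102)
        logfc = np.log2(share_sel / share_ctrl)
        assert logfc == pytest.approx(3.0, abs=0.2)


@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_library_determinism_property(seed):
    """Identical seeds reproduce the library exactly."""
    config = simlib.SimConfig(n_genes=2, gene_length_bp=200, intergenic_length_bp=50,
                              insertion_density_bp=10)
    genome = simlib.simulate_genome(config)
    a = simlib.simulate_library(genome, config, seed=seed)
    b = simlib.simulate_library(genome, config, seed=seed)
    assert np.array_equal(a.positions, b.positions)
    assert np.array_equal(a.strands, b.strands)
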