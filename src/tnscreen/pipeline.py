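"""End-to-end screen: simulated reads through consensus calls.

Glue for running the whole pipeline on synthetic data with known ground
truth — the harness used by the test suite, the acceptance script, and the
``simulate`` CLI.  The default scenario is the package's standard benchmark:
a ~150-kb genome of 200 genes (5% essential), a saturating library at one
insertion per 47 bp, 20 susceptibility genes and 10 resistance genes with
per-replicate effect |generations * log2(w)| = 4, four replicate selections
(two doses x two time points, modelled as equal-strength growth rounds),
and 2e5 reads per sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import consensus as cns
from . import diffstats, quant, simlib, tagproc

__all__ = ["Replicate", "ScreenScenario", "ScreenResult", "run_screen", "evaluate_calls"]

CONTROL = "control"


@dataclass(frozen=True)
class Replicate:
    """One selection: a label and its effective number of growth cycles."""

    label: str
    generations: float


def _default_replicates() -> tuple[Replicate, ...]:
    # two doses x two time points; dose and time both act through the
    # selection strength, held equal across replicates by default
    return (
        Replicate("dose_low_t1", 4.0),
        Replicate("dose_low_t2", 4.0),
        Replicate("dose_high_t1", 4.0),
        Replicate("dose_high_t2", 4.0),
    )


@dataclass(frozen=True)
class ScreenScenario:
    """Ground-truth design of a simulated phage-selection screen."""

    config: simlib.SimConfig = field(default_factory=simlib.SimConfig)
    n_susceptibility: int = 20
    n_resistance: int = 10
    w_susceptibility: float = 2.0
    w_resistance: float = 0.5
    replicates: tuple[Replicate, ...] = field(default_factory=_default_replicates)

    def __post_init__(self) -> None:
        if self.n_susceptibility < 0 or self.n_resistance < 0:
            raise ValueError("effect-gene counts must be >= 0")
        if self.w_susceptibility <= 0 or self.w_resistance <= 0:
            raise ValueError("effect fitness values must be > 0")
        if not self.replicates:
            raise ValueError("at least one replicate required")


@dataclass
class ScreenResult:
    genome: simlib.GenomeAnnotation
    fitness: simlib.FitnessMap
    truth: pd.DataFrame  # gene_id, w, essential, true_class
    table: quant.GeneCountTable
    comparisons: dict[str, pd.DataFrame]
    calls: pd.DataFrame


def assign_fitness(
    genome: simlib.GenomeAnnotation, scenario: ScreenScenario, seed: int
) -> simlib.FitnessMap:
    """Pick effect genes uniformly among non-essential genes."""
    nonessential = [g.gene_id for g in genome.genes if not g.essential]
    n_effect = scenario.n_susceptibility + scenario.n_resistance
    if n_effect > len(nonessential):
        raise ValueError("more effect genes requested than non-essential genes")
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(4,)))
    chosen = rng.choice(len(nonessential), size=n_effect, replace=False)
    w = {nonessential[i]: scenario.w_susceptibility for i in chosen[: scenario.n_susceptibility]}
    w.update(
        {nonessential[i]: scenario.w_resistance for i in chosen[scenario.n_susceptibility:]}
    )
    return simlib.FitnessMap(w=w, default_w=1.0)


def truth_table(genome: simlib.GenomeAnnotation, fitness: simlib.FitnessMap) -> pd.DataFrame:
    rows = []
    for g in genome.genes:
        w = fitness.for_gene(g.gene_id)
        if g.essential:
            cls = "essential"
        elif w > 1:
            cls = cns.SUSCEPTIBILITY
        elif w < 1:
            cls = cns.RESISTANCE
        else:
            cls = cns.NONE
        rows.append({"gene_id": g.gene_id, "w": w, "essential": g.essential,
                     "true_class": cls})
    return pd.DataFrame(rows)


def run_screen(
    scenario: ScreenScenario,
    seed: int,
    cuts: cns.CutoffConfig = cns.CutoffConfig(),
    test_config: diffstats.TestConfig = diffstats.TestConfig(),
    min_reads: int = quant.DEFAULT_MIN_READS,
) -> ScreenResult:
    """Simulate one full screen and analyse it back to consensus calls."""
    config = scenario.config.with_seed(seed)
    genome = simlib.simulate_genome(config)
    library = simlib.simulate_library(genome, config)
    fitness = assign_fitness(genome, scenario, seed)

    # distinct read-sampling seeds per sample, derived from the master seed
    seed_rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(5,)))
    sample_seeds = seed_rng.integers(0, 2**31 - 1, size=1 + len(scenario.replicates))

    tag_spec = tagproc.TagSpec(config.tag_sequence)
    index = tagproc.GenomeIndex(genome.sequence)

    profiles: dict[str, tagproc.InsertionProfile] = {}
    reads = simlib.generate_read_sequences(library, genome, config, seed=int(sample_seeds[0]))
    profiles[CONTROL] = tagproc.process_reads(reads, tag_spec, index)
    for i, rep in enumerate(scenario.replicates):
        selected = simlib.apply_selection(library, genome, fitness, rep.generations)
        reads = simlib.generate_read_sequences(
            selected, genome, config, seed=int(sample_seeds[1 + i])
        )
        profiles[rep.label] = tagproc.process_reads(reads, tag_spec, index)

    table = quant.GeneCountTable.from_profiles(profiles, genome)
    table = quant.flag_unassayable(table, [CONTROL], min_reads=min_reads)
    comparisons = {
        rep.label: diffstats.compare(table, rep.label, CONTROL, config=test_config)
        for rep in scenario.replicates
    }
    calls = cns.consensus_calls(list(comparisons.values()), cuts)
    return ScreenResult(
        genome=genome,
        fitness=fitness,
        truth=truth_table(genome, fitness),
        table=table,
        comparisons=comparisons,
        calls=calls,
    )


def evaluate_calls(calls: pd.DataFrame, truth: pd.DataFrame) -> dict[str, float]:
    """Sensitivity and precision of consensus calls against ground truth.

    A call is correct only if its class matches the gene's true class;
    essential genes are excluded from the truth set (they are unassayable
    by construction).
    """
    merged = calls.merge(truth, on="gene_id", validate="1:1")
    is_true_effect = merged["true_class"].isin([cns.SUSCEPTIBILITY, cns.RESISTANCE])
    called = merged["class"] != cns.NONE
    correct = called & (merged["class"] == merged["true_class"])
    n_true = int(is_true_effect.sum())
    n_called = int(called.sum())
    return {
        "sensitivity": float(correct.sum() / n_true) if n_true else float("nan"),
        "precision": float(correct.sum() / n_called) if n_called else float("nan"),
        "n_true_effect": n_true,
        "n_called": n_called,
        "n_called_susceptibility": int((merged["class"] == cns.SUSCEPTIBILITY).sum()),
        "n_called_resistance": int((merged["class"] == cns.RESISTANCE).sum()),
    }
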