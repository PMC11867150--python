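"""Germinal-centre B-cell evolution simulator.

Birth–death simulation with carrying-capacity competition, 5-mer
context-sensitive mutation, and selection toward a target amino-acid
sequence.  Sites of the (concatenated heavy + light chain) coding genome are
partitioned into *paratope* positions that enter a weighted amino-acid
distance to the target, *structural* positions at which only synonymous
nucleotide changes are accepted, and free positions.  At the end of the run
the highest-affinity cells are sampled; identical sampled genomes are
collapsed into genotype abundances and the pruned, collapsed genealogy is
returned as the true history.

The mapping from weighted target distance to expected offspring is not a
published curve; this implementation uses a bounded decreasing exponential
scaled by a linear density factor (see :func:`expected_offspring`), both
configurable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from Bio.Seq import Seq

from ._seq import BASES
from .context import MutabilityModel, context_5mer
from .sdag import History, HistoryNode, history_from_tree


class ExtinctionError(RuntimeError):
    """The simulated population died out before sampling."""


@dataclass(frozen=True)
class SimConfig:
    """Simulation parameters; defaults follow the benchmark setup."""

    n_initial: int = 100
    carrying_capacity: int = 1000
    target_distance: int = 10
    min_target_distance: float = 2.0
    n_paratope_sites: int = 60
    n_structural_sites: int = 100
    n_sampled: int = 70
    generations: int = 35
    heavy_length: int = 420  # nucleotides; heavy + light ~ 700 (codon multiple)
    light_length: int = 282
    mutation_rate: float = 0.3  # expected mutations per offspring
    base_fitness: float = 2.0  # expected offspring at minimal distance, low density
    fitness_decay: float = 0.3  # exponential decay per unit distance
    seed: int = 0

    @property
    def genome_length(self) -> int:
        return self.heavy_length + self.light_length

    @property
    def n_codons(self) -> int:
        return self.genome_length // 3

    def validate(self) -> None:
        if self.genome_length % 3:
            raise ValueError("heavy_length + light_length must be a codon multiple")
        if self.n_paratope_sites + self.n_structural_sites > self.n_codons:
            raise ValueError("site partition exceeds protein length")
        if self.target_distance > self.n_paratope_sites:
            raise ValueError("target_distance exceeds number of paratope sites")
        if self.n_sampled < 1 or self.n_initial < 1:
            raise ValueError("need at least one cell")


@dataclass
class SitePartition:
    """Disjoint amino-acid position classes plus paratope weights."""

    paratope: np.ndarray  # sorted aa positions
    structural: np.ndarray
    weights: np.ndarray  # per-paratope-position weight in [0, 1]

    def __post_init__(self):
        if set(self.paratope.tolist()) & set(self.structural.tolist()):
            raise ValueError("paratope and structural sites overlap")


@dataclass
class Cell:
    uid: int
    genome: str
    parent: Optional[int]  # uid of parent cell, None for the naive founder root


STOP_CODONS = {"TAA", "TAG", "TGA"}


def translate(genome: str) -> str:
    return str(Seq(genome).translate())


def _random_coding_sequence(length: int, rng: np.random.Generator) -> str:
    codons = []
    while len(codons) * 3 < length:
        codon = "".join(rng.choice(list(BASES), size=3))
        if codon not in STOP_CODONS:
            codons.append(codon)
    return "".join(codons)


def make_naive_and_target(config: SimConfig, rng: Optional[np.random.Generator] = None):
    """Random naive genome, target protein, site partition and weights.

    The target equals the naive protein except at ``target_distance``
    randomly chosen paratope positions, where it carries a different amino
    acid.  Paratope weights are uniform draws from [0, 1].
    """
    config.validate()
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    naive = _random_coding_sequence(config.genome_length, rng)
    protein = translate(naive)
    positions = rng.permutation(config.n_codons)
    paratope = np.sort(positions[: config.n_paratope_sites])
    structural = np.sort(
        positions[config.n_paratope_sites : config.n_paratope_sites + config.n_structural_sites]
    )
    weights = rng.uniform(0.0, 1.0, size=config.n_paratope_sites)
    partition = SitePartition(paratope=paratope, structural=structural, weights=weights)

    aas = "ACDEFGHIKLMNPQRSTVWY"
    target = list(protein)
    mutated = rng.choice(config.n_paratope_sites, size=config.target_distance, replace=False)
    for idx in mutated:
        pos = int(paratope[idx])
        choices = [a for a in aas if a != protein[pos]]
        target[pos] = choices[rng.integers(len(choices))]
    return naive, "".join(target), partition


def weighted_target_distance(genome: str, target: str, partition: SitePartition) -> float:
    """Weighted amino-acid Hamming distance to the target over paratope sites."""
    protein = translate(genome)
    return float(
        sum(
            w
            for pos, w in zip(partition.paratope, partition.weights)
            if protein[pos] != target[pos]
        )
    )


def base_fitness(distance: float, config: SimConfig) -> float:
    """Low-density expected offspring; decays from ``base_fitness`` to 1.

    Distances below ``min_target_distance`` give no further gain; every cell
    multiplies when competition is absent.
    """
    effective = max(0.0, distance - config.min_target_distance)
    return 1.0 + (config.base_fitness - 1.0) * float(
        np.exp(-config.fitness_decay * effective)
    )


def expected_offspring(
    distance: float,
    n_cells: int,
    config: SimConfig,
    mean_base: Optional[float] = None,
) -> float:
    """Mean offspring count under competition for antigen.

    The cell's base fitness is divided by a crowding factor
    ``1 + (mean_base - 1) * N / K`` built from the population's mean base
    fitness, so growth is unrestricted at low density and the population
    mean offspring is exactly 1 at carrying capacity, while fitter cells
    keep a relative advantage.
    """
    base = base_fitness(distance, config)
    if mean_base is None:
        mean_base = base
    crowding = 1.0 + (mean_base - 1.0) * n_cells / config.carrying_capacity
    return base / crowding


def _mutate_genome(
    genome: str,
    model: MutabilityModel,
    partition: SitePartition,
    config: SimConfig,
    rng: np.random.Generator,
    max_tries: int = 50,
) -> str:
    n_mut = rng.poisson(config.mutation_rate)
    if n_mut == 0:
        return genome
    structural = set(partition.structural.tolist())
    seq = list(genome)
    for _ in range(n_mut):
        site, base = _draw_mutation("".join(seq), model, rng)
        tries = 0
        while not _acceptable(seq, site, base, structural):
            tries += 1
            if tries >= max_tries:
                site = None
                break
            site, base = _draw_mutation("".join(seq), model, rng)
        if site is not None:
            seq[site] = base
    return "".join(seq)


def _acceptable(seq: list, site: int, base: str, structural: set) -> bool:
    aa_pos = site // 3
    if aa_pos not in structural:
        return True
    start = aa_pos * 3
    codon = seq[start : start + 3]
    new_codon = list(codon)
    new_codon[site - start] = base
    return translate("".join(codon)) == translate("".join(new_codon))


def _draw_mutation(
    genome: str, model: MutabilityModel, rng: np.random.Generator
) -> tuple[int, str]:
    """Draw (0-based site, new base) with site probability proportional to the
    5-mer targeting rate and base drawn from the substitution distribution."""
    profile = model.rate_profile(genome)
    probs = profile / profile.sum()
    site = int(rng.choice(len(genome), p=probs))
    _, subs = model.lookup(context_5mer(genome, site + 1))
    bases = [b for b in BASES if b != genome[site]]
    weights = np.array([subs[b] for b in bases])
    weights = weights / weights.sum()
    base = str(rng.choice(bases, p=weights))
    return site, base


def step_generation(
    population: list,
    model: MutabilityModel,
    target: str,
    partition: SitePartition,
    config: SimConfig,
    rng: np.random.Generator,
    registry: dict,
    next_uid: int,
) -> tuple[list, int]:
    """One synchronous generation of reproduction, selection and mutation."""
    if not population:
        raise ExtinctionError("population is empty")
    n = len(population)
    distances = [
        weighted_target_distance(cell.genome, target, partition)
        for cell in population
    ]
    mean_base = float(np.mean([base_fitness(d, config) for d in distances]))
    new_population = []
    for cell, d in zip(population, distances):
        mu = expected_offspring(d, n, config, mean_base=mean_base)
        n_offspring = rng.poisson(mu)
        for _ in range(n_offspring):
            genome = _mutate_genome(cell.genome, model, partition, config, rng)
            child = Cell(uid=next_uid, genome=genome, parent=cell.uid)
            registry[next_uid] = child
            next_uid += 1
            new_population.append(child)
    if not new_population:
        raise ExtinctionError("population went extinct")
    return new_population, next_uid


@dataclass
class SimResult:
    """Sampled genotypes with abundances plus the pruned true history."""

    naive: str
    target: str
    partition: SitePartition
    genotypes: dict  # sequence -> abundance
    true_history: History
    config: SimConfig


def run_simulation(
    config: SimConfig, model: MutabilityModel
) -> SimResult:
    """Run the full simulation and sample the final generation."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    naive, target, partition = make_naive_and_target(config, rng)
    root = Cell(uid=0, genome=naive, parent=None)
    registry = {0: root}
    next_uid = 1
    population = []
    for _ in range(config.n_initial):
        cell = Cell(uid=next_uid, genome=naive, parent=0)
        registry[next_uid] = cell
        next_uid += 1
        population.append(cell)
    for _ in range(config.generations):
        population, next_uid = step_generation(
            population, model, target, partition, config, rng, registry, next_uid
        )
    genotypes, true_history = sample_cells(
        population, target, partition, config, rng, registry, naive
    )
    return SimResult(
        naive=naive,
        target=target,
        partition=partition,
        genotypes=genotypes,
        true_history=true_history,
        config=config,
    )


def sample_cells(
    population: list,
    target: str,
    partition: SitePartition,
    config: SimConfig,
    rng: np.random.Generator,
    registry: dict,
    naive: str,
) -> tuple[dict, History]:
    """Affinity-ranked sampling of the final generation.

    Takes the ``n_sampled`` cells with the smallest weighted target distance
    (ties broken by a seeded shuffle), collapses identical genomes into
    genotype abundances, and prunes the genealogy to the sampled leaves with
    equal-genome edges collapsed.
    """
    if len(population) < config.n_sampled:
        raise ValueError(
            f"population {len(population)} smaller than sample size {config.n_sampled}"
        )
    order = rng.permutation(len(population))
    ranked = sorted(
        order, key=lambda i: weighted_target_distance(population[i].genome, target, partition)
    )
    sampled = [population[i] for i in ranked[: config.n_sampled]]

    abundances: dict[str, int] = {}
    for cell in sampled:
        abundances[cell.genome] = abundances.get(cell.genome, 0) + 1

    true_history = _build_true_history(sampled, registry, naive)
    return abundances, true_history


def _build_true_history(sampled: list, registry: dict, naive: str) -> History:
    """Genealogy of the sampled cells, genotype-collapsed.

    Keeps one leaf per distinct sampled genome; passthrough ancestors are
    spliced out, and zero-mutation edges are collapsed.  If the same genome
    appears as a leaf in several independent lineages, only the first
    occurrence (in a deterministic traversal) is kept as a taxon.
    """
    children: dict[int, list[int]] = {}
    keep = set()
    for cell in sampled:
        uid = cell.uid
        while uid is not None and uid not in keep:
            keep.add(uid)
            uid = registry[uid].parent
    for uid in keep:
        parent = registry[uid].parent
        if parent is not None:
            children.setdefault(parent, []).append(uid)

    sampled_uids = {c.uid for c in sampled}
    seen_leaf_genomes = set()

    def build(uid: int):
        """Return a nested (label, [subtrees]) tree or None if empty."""
        cell = registry[uid]
        kids = sorted(children.get(uid, []))
        subtrees = [t for k in kids if (t := build(k)) is not None]
        is_sampled = uid in sampled_uids
        if is_sampled and not subtrees:
            if cell.genome in seen_leaf_genomes:
                return None
            seen_leaf_genomes.add(cell.genome)
            return cell.genome
        if not subtrees:
            return None
        if len(subtrees) == 1 and not is_sampled:
            return subtrees[0]  # splice out passthrough ancestors
        return (cell.genome, subtrees)

    tree = build(0)
    if tree is None:
        raise ValueError("no sampled cells survive pruning")
    if isinstance(tree, str):
        history = history_from_tree(tree)
    else:
        # ensure the naive founder is the root label
        if tree[0] != naive:
            tree = (naive, [tree])
        history = history_from_tree(tree)
    return history.collapse()
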