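"""Synthetic fixture worlds with plantable signals.

A world bundles every input the pipeline consumes — ortholog table, gene
coordinates, per-protein ortholog alignments, an external gene-fusion
z-score list, regulons and a positive gold standard — generated
deterministically from a seed.  Planted positive pairs receive, with
configurable strengths:

* correlated presence/absence profiles (phylogenetic-profile signal),
* conserved sub-300-bp gene adjacency (gene-context signal),
* coupled per-branch substitution processes on a shared species tree
  (mirror-tree signal),
* co-varying inter-protein alignment column pairs (two-hybrid signal),
* occasional external fusion z-scores.

Decoy pairs can be planted that fool exactly one method (profile-only or
adjacency-only), which is what makes the combined classifier measurably
better than any single method on these worlds.

Sequence evolution is a Poisson substitution process with uniform
replacement over a random bifurcating (or star) tree: fixtures need
controllable correlation, not biological realism.  One family per protein;
paralogy is not modeled.
"""

from __future__ import annotations

import dataclasses
import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import yaml

from . import gold_standard
from .features import ProteinRecord
from .io_formats import (
    GeneLocation,
    OrthologAlignment,
    OrthologTable,
    PairList,
    canonical_pair,
    write_alignment,
    write_gene_coordinates,
    write_ortholog_table,
    write_pair_list,
    write_protein_lengths,
    write_regulons,
)

log = logging.getLogger(__name__)

AMINO_ACIDS = "ARNDCQEGHILKMFPSTWYV"

#: source tags cycled over directly planted pairs
_PLANT_SOURCES = ("pathway_kegg", "complex_curated", "physical_lt", "literature")


# ---------------------------------------------------------------------------
# Species trees
# ---------------------------------------------------------------------------

@dataclass
class Tree:
    """Rooted tree in topological order: ``parents[0] == -1`` is the root;
    every other index has ``parents[i] < i``.  ``leaf_names`` maps leaf
    node indices to species ids."""

    parents: list[int]
    leaf_names: dict[int, str]

    @property
    def n_nodes(self) -> int:
        return len(self.parents)

    @property
    def leaves(self) -> list[str]:
        return [self.leaf_names[i] for i in sorted(self.leaf_names)]


def star_tree(leaves: Iterable[str]) -> Tree:
    leaves = list(leaves)
    parents = [-1] + [0] * len(leaves)
    return Tree(parents=parents, leaf_names={i + 1: name for i, name in enumerate(leaves)})


def random_bifurcating_tree(leaves: Iterable[str], rng: np.random.Generator) -> Tree:
    """Random topology built by recursive random splits of the leaf set."""
    leaves = list(leaves)
    parents: list[int] = [-1]
    leaf_names: dict[int, str] = {}

    def build(subset: list[str], node: int) -> None:
        if len(subset) == 1:
            leaf_names[node] = subset[0]
            return
        k = int(rng.integers(1, len(subset)))
        for part in (subset[:k], subset[k:]):
            parents.append(node)
            build(part, len(parents) - 1)

    order = [leaves[i] for i in rng.permutation(len(leaves))]
    build(order, 0)
    return Tree(parents=parents, leaf_names=leaf_names)


# ---------------------------------------------------------------------------
# Sequence simulation
# ---------------------------------------------------------------------------

#: one substitution event: (column index, replacement residue)
Event = tuple[int, str]


def _draw_events(
    tree: Tree, length: int, rate: float, rng: np.random.Generator
) -> dict[int, list[Event]]:
    """Per-branch Poisson substitution events (branch = node it leads to)."""
    events: dict[int, list[Event]] = {}
    for node in range(1, tree.n_nodes):
        count = int(rng.poisson(rate * length))
        events[node] = [
            (int(rng.integers(length)), AMINO_ACIDS[int(rng.integers(len(AMINO_ACIDS)))])
            for _ in range(count)
        ]
    return events


def _couple_events(
    base: dict[int, list[Event]],
    tree: Tree,
    length: int,
    rate: float,
    coupling: float,
    rng: np.random.Generator,
) -> dict[int, list[Event]]:
    """Derived event set: each base event is kept with probability
    ``coupling``; private events arrive at rate ``(1 - coupling) * rate``.
    Total rate is preserved; ``coupling == 1`` reproduces ``base`` exactly."""
    derived: dict[int, list[Event]] = {}
    for node in range(1, tree.n_nodes):
        kept = [e for e in base.get(node, []) if rng.random() < coupling]
        n_private = int(rng.poisson((1.0 - coupling) * rate * length))
        private = [
            (int(rng.integers(length)), AMINO_ACIDS[int(rng.integers(len(AMINO_ACIDS)))])
            for _ in range(n_private)
        ]
        derived[node] = kept + private
    return derived


def _leaf_sequences(
    tree: Tree, root: np.ndarray, events: dict[int, list[Event]]
) -> dict[str, str]:
    sequences: dict[int, np.ndarray] = {0: root}
    out: dict[str, str] = {}
    for node in range(1, tree.n_nodes):
        seq = sequences[tree.parents[node]].copy()
        for column, residue in events.get(node, []):
            seq[column] = residue
        sequences[node] = seq
        if node in tree.leaf_names:
            out[tree.leaf_names[node]] = "".join(seq)
    if 0 in tree.leaf_names:  # degenerate single-leaf tree
        out[tree.leaf_names[0]] = "".join(root)
    return out


def generate_coupled_alignments(
    tree: Tree,
    coupling: float,
    length: int,
    rng: np.random.Generator,
    rate: float = 0.08,
    species_a: Iterable[str] | None = None,
    species_b: Iterable[str] | None = None,
    proteins: tuple[str, str] = ("A", "B"),
) -> tuple[OrthologAlignment, OrthologAlignment]:
    """Two alignments over a shared species tree with correlated
    substitution loads.  ``coupling == 1`` yields identical alignments
    (hence identical distance matrices); ``coupling == 0`` independent
    event processes."""
    if not 0.0 <= coupling <= 1.0:
        raise ValueError("coupling must be in [0, 1]")
    root = np.array(list(AMINO_ACIDS))[rng.integers(len(AMINO_ACIDS), size=length)]
    events_a = _draw_events(tree, length, rate, rng)
    events_b = _couple_events(events_a, tree, length, rate, coupling, rng)
    rows_a = _leaf_sequences(tree, root, events_a)
    rows_b = _leaf_sequences(tree, root, events_b)
    keep_a = set(species_a) if species_a is not None else set(rows_a)
    keep_b = set(species_b) if species_b is not None else set(rows_b)
    aln_a = OrthologAlignment(
        protein=proteins[0], rows={s: rows_a[s] for s in tree.leaves if s in keep_a}
    )
    aln_b = OrthologAlignment(
        protein=proteins[1], rows={s: rows_b[s] for s in tree.leaves if s in keep_b}
    )
    return aln_a, aln_b


def generate_profile_pair(
    correlation: float,
    n_genomes: int,
    rng: np.random.Generator,
    presence_prob: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Two presence vectors: identical at correlation 1, independent at 0."""
    if not 0.0 <= correlation <= 1.0:
        raise ValueError("correlation must be in [0, 1]")
    a = (rng.random(n_genomes) < presence_prob).astype(np.uint8)
    independent = (rng.random(n_genomes) < presence_prob).astype(np.uint8)
    b = np.where(rng.random(n_genomes) < correlation, a, independent).astype(np.uint8)
    return a, b


# ---------------------------------------------------------------------------
# World configuration and container
# ---------------------------------------------------------------------------

@dataclass
class WorldConfig:
    seed: int = 0
    n_genomes: int = 24
    n_proteins: int = 120
    n_positive_pairs: int = 24
    n_regulons: int = 0
    regulon_size: tuple[int, int] = (3, 6)
    # signal strengths, one per method channel
    profile_correlation: float = 0.8
    neighborhood_prob: float = 0.8
    coupling: float = 0.8
    covariation: float = 0.8
    fusion_prob: float = 0.3
    # world shape
    presence_prob: float = 0.75
    alignment_length: int = 24
    mutation_rate: float = 0.08
    min_align_species: int = 16  # alignments need more than 15 sequences
    n_aligned_proteins: int | None = None
    # nuisance structure
    n_decoy_gc: int = 0
    n_decoy_pp: int = 0
    gc_noise: float = 0.02
    n_noise_gf: int = 0

    def __post_init__(self) -> None:
        for name in (
            "profile_correlation", "neighborhood_prob", "coupling",
            "covariation", "fusion_prob", "presence_prob", "gc_noise",
        ):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        if self.n_genomes < 16:
            raise ValueError("need at least 16 genomes so alignments can qualify")
        if self.n_positive_pairs > self.n_proteins // 2:
            raise ValueError(
                f"cannot plant {self.n_positive_pairs} disjoint pairs "
                f"among {self.n_proteins} proteins"
            )


@dataclass
class World:
    config: WorldConfig
    genomes: list[str]
    proteins: list[str]
    tree: Tree
    table: OrthologTable
    coordinates: dict[tuple[str, str], GeneLocation]
    alignments: dict[str, OrthologAlignment]
    protein_lengths: dict[str, int]
    regulons: dict[str, set[str]]
    positives: PairList
    gf: PairList
    planted_pairs: list[tuple[str, str]] = field(default_factory=list)
    decoys_gc: list[tuple[str, str]] = field(default_factory=list)
    decoys_pp: list[tuple[str, str]] = field(default_factory=list)

    def protein_records(self) -> dict[str, ProteinRecord]:
        return {
            p: ProteinRecord(
                protein=p,
                length=self.protein_lengths[p],
                n_orthologs=self.table.n_orthologs(p),
            )
            for p in self.proteins
        }

    def write(self, directory: str | Path) -> None:
        """Write every input file; all outputs are deterministic text."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        write_ortholog_table(self.table, directory / "orthologs.tsv")
        write_protein_lengths(self.protein_lengths, directory / "proteins.tsv")
        gff_dir = directory / "gff"
        gff_dir.mkdir(exist_ok=True)
        for genome in self.genomes:
            per_genome = {
                key: loc for key, loc in self.coordinates.items() if key[0] == genome
            }
            write_gene_coordinates(per_genome, gff_dir / f"{genome}.gff3")
        aln_dir = directory / "aln"
        aln_dir.mkdir(exist_ok=True)
        for protein in sorted(self.alignments):
            write_alignment(self.alignments[protein], aln_dir / f"{protein}.fasta")
        write_pair_list(self.gf, directory / "gf.tsv", with_scores=True)
        with (directory / "positives.tsv").open("w") as handle:
            for pair in self.positives:
                for source in sorted(self.positives.sources_of(pair)):
                    handle.write(f"{pair[0]}\t{pair[1]}\t{source}\n")
        write_regulons(self.regulons, directory / "regulons.tsv")
        with (directory / "config.yaml").open("w") as handle:
            yaml.safe_dump(dataclasses.asdict(self.config), handle, sort_keys=True)


# ---------------------------------------------------------------------------
# World generation
# ---------------------------------------------------------------------------

def _sample_disjoint_pairs(
    proteins: list[str], count: int, rng: np.random.Generator
) -> list[tuple[str, str]]:
    chosen = rng.choice(len(proteins), size=2 * count, replace=False)
    return sorted(
        canonical_pair(proteins[chosen[2 * i]], proteins[chosen[2 * i + 1]])
        for i in range(count)
    )


def _sample_universe_pairs(
    universe: list[str],
    count: int,
    exclude: set[tuple[str, str]],
    rng: np.random.Generator,
) -> list[tuple[str, str]]:
    """Random non-excluded pairs among ``universe`` (used for GF noise)."""
    out: set[tuple[str, str]] = set()
    n = len(universe)
    if count > n * (n - 1) // 2 - len(exclude):
        raise ValueError("not enough pairs in the universe for the requested decoys")
    while len(out) < count:
        i, j = rng.integers(n), rng.integers(n)
        if i == j:
            continue
        pair = canonical_pair(universe[int(i)], universe[int(j)])
        if pair not in exclude and pair not in out:
            out.add(pair)
    return sorted(out)


def _sample_decoy_matching(
    universe: list[str],
    count: int,
    exclude: set[tuple[str, str]],
    rng: np.random.Generator,
) -> list[tuple[str, str]]:
    """Decoy pairs forming a matching (no shared proteins among decoys).

    Disjointness lets adjacency planting succeed for decoys exactly as it
    does for directly planted positives, so a decoy fools its target
    method with full strength.
    """
    if 2 * count > len(universe):
        raise ValueError(
            f"cannot plant {count} disjoint decoy pairs among {len(universe)} proteins"
        )
    order = rng.permutation(len(universe))
    out: list[tuple[str, str]] = []
    position = 0
    while len(out) < count and position + 1 < len(universe):
        pair = canonical_pair(
            universe[int(order[position])], universe[int(order[position + 1])]
        )
        position += 2
        if pair not in exclude:
            out.append(pair)
    if len(out) < count:
        raise ValueError("not enough disjoint decoy pairs outside the positive set")
    return sorted(out)


def generate_world(config: WorldConfig) -> World:
    rng = np.random.default_rng(config.seed)
    genomes = [f"G{i:03d}" for i in range(config.n_genomes)]
    proteins = [f"P{i:05d}" for i in range(config.n_proteins)]
    tree = random_bifurcating_tree(genomes, rng)

    # --- positive structure ------------------------------------------------
    planted = _sample_disjoint_pairs(proteins, config.n_positive_pairs, rng)
    positives = PairList()
    for i, (a, b) in enumerate(planted):
        positives.add(a, b, source=_PLANT_SOURCES[i % len(_PLANT_SOURCES)])
    regulons: dict[str, set[str]] = {}
    if config.n_regulons:
        lo, hi = config.regulon_size
        regulators = rng.choice(len(proteins), size=config.n_regulons, replace=False)
        for r in regulators:
            regulator = proteins[int(r)]
            size = int(rng.integers(lo, hi + 1))
            targets = {
                proteins[int(t)]
                for t in rng.choice(len(proteins), size=size, replace=False)
            } - {regulator}
            regulons[regulator] = targets
        coregulated, regulator_target = gold_standard.coregulated_from_regulons(regulons)
        positives.update(coregulated)
        positives.update(regulator_target)
    positive_pairs = sorted(positives.pairs)
    universe = sorted(positives.proteins())

    decoys_gc = _sample_decoy_matching(universe, config.n_decoy_gc, positives.pairs, rng)
    decoys_pp = _sample_decoy_matching(
        universe, config.n_decoy_pp, positives.pairs | set(decoys_gc), rng
    )

    # --- profiles and ortholog table --------------------------------------
    index = {p: i for i, p in enumerate(proteins)}
    bits = (rng.random((config.n_proteins, config.n_genomes)) < config.presence_prob
            ).astype(np.uint8)
    for a, b in positive_pairs + decoys_pp:
        copy_mask = rng.random(config.n_genomes) < config.profile_correlation
        bits[index[b]] = np.where(copy_mask, bits[index[a]], bits[index[b]])
    entries: dict[tuple[str, str], str] = {}
    for i, protein in enumerate(proteins):
        for j, genome in enumerate(genomes):
            if bits[i, j]:
                entries[(protein, genome)] = f"{protein}_{genome}"
    table = OrthologTable(genomes=genomes, proteins=proteins, entries=entries)

    protein_lengths = {p: int(rng.integers(80, 601)) for p in proteins}

    # --- coordinates with planted adjacency --------------------------------
    coordinates: dict[tuple[str, str], GeneLocation] = {}
    adjacency_pairs = positive_pairs + decoys_gc
    for j, genome in enumerate(genomes):
        present = [p for p in proteins if bits[index[p], j]]
        blocks: list[list[str]] = [[p] for p in present]
        block_of = {p: k for k, p in enumerate(present)}
        for a, b in adjacency_pairs:
            if a not in block_of or b not in block_of:
                continue
            if rng.random() >= config.neighborhood_prob:
                continue
            for first, second in ((a, b), (b, a)):
                ka, kb = block_of[first], block_of[second]
                if ka == kb:
                    break
                # adjacency only holds edge-to-edge; otherwise skip the merge
                if blocks[ka][-1] == first and blocks[kb][0] == second:
                    merged = blocks[ka] + blocks[kb]
                    blocks[ka] = merged
                    blocks[kb] = []
                    for p in merged:
                        block_of[p] = ka
                    break
        blocks = [blk for blk in blocks if blk]
        order = rng.permutation(len(blocks))
        cursor = 1
        for k in order:
            block = blocks[int(k)]
            for position, protein in enumerate(block):
                gene_length = 3 * protein_lengths[protein]
                strand = "+" if rng.random() < 0.5 else "-"
                coordinates[(genome, f"{protein}_{genome}")] = GeneLocation(
                    genome=genome,
                    contig="chr",
                    start=cursor,
                    end=cursor + gene_length - 1,
                    strand=strand,
                )
                cursor += gene_length
                if position < len(block) - 1:
                    cursor += int(rng.integers(20, 150))
            if rng.random() < config.gc_noise:
                cursor += int(rng.integers(20, 150))
            else:
                cursor += int(rng.integers(400, 2000))

    # --- alignments with coupled evolution and planted co-variation --------
    popcount = bits.sum(axis=1)
    eligible = [p for p in proteins if popcount[index[p]] >= config.min_align_species]
    if config.n_aligned_proteins is not None and len(eligible) > config.n_aligned_proteins:
        in_positives = set(universe)
        eligible.sort(key=lambda p: (p not in in_positives, p))
        eligible = sorted(eligible[: config.n_aligned_proteins])
    aligned = set(eligible)
    length = config.alignment_length
    rate = config.mutation_rate
    events: dict[str, dict[int, list[Event]]] = {}
    roots: dict[str, np.ndarray] = {}
    aa = np.array(list(AMINO_ACIDS))
    for a, b in positive_pairs:
        if a not in aligned or b not in aligned:
            continue
        if a not in events:
            roots[a] = aa[rng.integers(len(aa), size=length)]
            events[a] = _draw_events(tree, length, rate, rng)
        if b not in events:
            roots[b] = roots[a]
            events[b] = _couple_events(events[a], tree, length, rate, config.coupling, rng)
    for p in eligible:
        if p not in events:
            roots[p] = aa[rng.integers(len(aa), size=length)]
            events[p] = _draw_events(tree, length, rate, rng)
    row_arrays: dict[str, dict[str, np.ndarray]] = {}
    for p in eligible:
        rows = _leaf_sequences(tree, roots[p], events[p])
        present = {genomes[j] for j in range(config.n_genomes) if bits[index[p], j]}
        row_arrays[p] = {
            s: np.array(list(rows[s])) for s in tree.leaves if s in present
        }
    n_plant_columns = int(round(config.covariation * 6))
    for a, b in positive_pairs:
        if a not in aligned or b not in aligned or n_plant_columns == 0:
            continue
        common = sorted(set(row_arrays[a]) & set(row_arrays[b]))
        if not common:
            continue
        for _ in range(n_plant_columns):
            col_a = int(rng.integers(length))
            col_b = int(rng.integers(length))
            mapping = dict(zip(AMINO_ACIDS, aa[rng.permutation(len(aa))]))
            for species, row in row_arrays[b].items():
                if species in set(common):
                    row[col_b] = mapping[str(row_arrays[a][species][col_a])]
                else:
                    row[col_b] = aa[int(rng.integers(len(aa)))]
    alignments = {
        p: OrthologAlignment(
            protein=p, rows={s: "".join(r) for s, r in row_arrays[p].items()}
        )
        for p in eligible
        if row_arrays[p]
    }

    # --- external gene-fusion z-scores -------------------------------------
    gf = PairList()
    for a, b in positive_pairs:
        if rng.random() < config.fusion_prob:
            gf.add(a, b, score=float(rng.uniform(2.0, 10.0)))
    if config.n_noise_gf:
        for a, b in _sample_universe_pairs(
            universe, config.n_noise_gf, positives.pairs, rng
        ):
            gf.add(a, b, score=float(rng.uniform(0.5, 4.0)))

    return World(
        config=config,
        genomes=genomes,
        proteins=proteins,
        tree=tree,
        table=table,
        coordinates=coordinates,
        alignments=alignments,
        protein_lengths=protein_lengths,
        regulons=regulons,
        positives=positives,
        gf=gf,
        planted_pairs=planted,
        decoys_gc=decoys_gc,
        decoys_pp=decoys_pp,
    )


# ---------------------------------------------------------------------------
# Plain gold standards (no signal; dataset-builder fixtures)
# ---------------------------------------------------------------------------

def generate_plain_gold(
    n_positives: int, n_negatives: int, seed: int
) -> tuple[PairList, PairList]:
    """A structureless gold standard with exact class sizes.

    Useful for exercising the dataset builder's ratios in isolation.
    """
    total = n_positives + n_negatives
    n_proteins = 3
    while n_proteins * (n_proteins - 1) // 2 < total:
        n_proteins += 1
    proteins = [f"P{i:05d}" for i in range(n_proteins)]
    rng = np.random.default_rng(seed)
    all_pairs = list(itertools.combinations(proteins, 2))
    chosen = rng.choice(len(all_pairs), size=total, replace=False)
    positives = PairList()
    negatives = PairList()
    for k, pair_index in enumerate(chosen):
        a, b = all_pairs[int(pair_index)]
        if k < n_positives:
            positives.add(a, b, source="pathway_kegg")
        else:
            negatives.add(a, b, source="negative")
    return positives, negatives
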