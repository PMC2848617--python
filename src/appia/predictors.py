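"""The five per-pair functional-association scores.

Methods and their score orientation (recorded in :data:`ORIENTATIONS`):

========  ==========================================  ====================
method    score                                       stronger association
========  ==========================================  ====================
PP        Hamming distance of phylogenetic profiles   smaller
GC        # genomes with orthologs < 300 bp apart     larger
GF        externally supplied gene-fusion z-score     larger
MT        Pearson r of ortholog distance matrices     larger
I2H       fraction of co-varying inter-protein        larger
          column pairs (r >= r_cut)
========  ==========================================  ====================

Missingness is semantic: when a method's preconditions fail the score is
``None`` (never a flag value).
"""

from __future__ import annotations

import importlib.resources
import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np

from .io_formats import (
    GeneLocation,
    OrthologAlignment,
    OrthologTable,
    PairList,
    canonical_pair,
)

log = logging.getLogger(__name__)

METHODS = ("PP", "GC", "GF", "MT", "I2H")

#: True means ascending-is-better (a smaller score is a stronger prediction).
ORIENTATIONS: dict[str, bool] = {
    "PP": True,
    "GC": False,
    "GF": False,
    "MT": False,
    "I2H": False,
}

GAP_CHARS = frozenset("-.")

DEFAULT_GC_THRESHOLD = 300  # base pairs, strict
DEFAULT_MIN_COMMON = 11  # minimum common species for MT / I2H
DEFAULT_R_CUT = 0.5  # I2H co-variation cutoff
DEFAULT_MAX_GAP_FRAC = 0.5  # I2H: columns with more gaps are excluded
MIN_SITE_ROWS = 4  # minimum paired non-gap rows for a site correlation


# ---------------------------------------------------------------------------
# Phylogenetic profiles (PP)
# ---------------------------------------------------------------------------

@dataclass
class PhyloProfile:
    """Presence/absence vector of a protein's orthologs, in genome order."""

    protein: str
    bits: np.ndarray  # uint8 vector of 0/1, aligned to OrthologTable.genomes

    def popcount(self) -> int:
        return int(self.bits.sum())


def build_profile(protein: str, table: OrthologTable) -> PhyloProfile:
    bits = np.fromiter(
        ((protein, g) in table.entries for g in table.genomes),
        dtype=np.uint8,
        count=len(table.genomes),
    )
    return PhyloProfile(protein=protein, bits=bits)


def pp_score(a: PhyloProfile, b: PhyloProfile) -> int:
    """Hamming distance between two profiles; smaller = stronger."""
    if a.bits.shape != b.bits.shape:
        raise ValueError(
            f"profile length mismatch: {a.bits.shape[0]} vs {b.bits.shape[0]}"
        )
    return int(np.count_nonzero(a.bits != b.bits))


def profile_matrix(table: OrthologTable) -> tuple[list[str], np.ndarray]:
    """All profiles stacked: returns (proteins, matrix of shape P x G)."""
    mat = np.zeros((len(table.proteins), len(table.genomes)), dtype=np.uint8)
    genome_index = {g: j for j, g in enumerate(table.genomes)}
    protein_index = {p: i for i, p in enumerate(table.proteins)}
    for (protein, genome) in table.entries:
        mat[protein_index[protein], genome_index[genome]] = 1
    return list(table.proteins), mat


def pp_score_matrix(profiles: np.ndarray) -> np.ndarray:
    """Pairwise Hamming distances for a stacked 0/1 profile matrix.

    Uses the identity  H(a, b) = |a| + |b| - 2 a.b  for binary vectors.
    """
    x = profiles.astype(np.int32)
    pop = x.sum(axis=1)
    inner = x @ x.T
    return pop[:, None] + pop[None, :] - 2 * inner


# ---------------------------------------------------------------------------
# Gene context (GC)
# ---------------------------------------------------------------------------

def neighborhood_distance(la: GeneLocation, lb: GeneLocation) -> int | None:
    """Gap in base pairs between two gene intervals, or None if undefined.

    Undefined across genomes or contigs; 0 for overlapping intervals;
    otherwise ``max(start) - min(end) - 1`` (1-based inclusive intervals).
    Strand is ignored.
    """
    if la.genome != lb.genome or la.contig != lb.contig:
        return None
    gap = max(la.start, lb.start) - min(la.end, lb.end) - 1
    return max(gap, 0)


def gc_score(
    protein_a: str,
    protein_b: str,
    table: OrthologTable,
    coords: Mapping[tuple[str, str], GeneLocation],
    threshold: int = DEFAULT_GC_THRESHOLD,
) -> int:
    """Number of genomes in which the two orthologs lie strictly closer
    than ``threshold`` base pairs on the same contig.  Larger = stronger."""
    count = 0
    for genome in table.genomes:
        gene_a = table.entries.get((protein_a, genome))
        gene_b = table.entries.get((protein_b, genome))
        if gene_a is None or gene_b is None:
            continue
        loc_a = coords.get((genome, gene_a))
        loc_b = coords.get((genome, gene_b))
        if loc_a is None or loc_b is None:
            continue
        distance = neighborhood_distance(loc_a, loc_b)
        if distance is not None and distance < threshold:
            count += 1
    return count


def gc_scores_bulk(
    table: OrthologTable,
    coords: Mapping[tuple[str, str], GeneLocation],
    threshold: int = DEFAULT_GC_THRESHOLD,
) -> dict[tuple[str, str], int]:
    """All pair counts at once via a per-genome positional sweep.

    Only pairs with a nonzero count appear in the result.
    """
    gene_to_protein: dict[str, dict[str, str]] = {g: {} for g in table.genomes}
    for (protein, genome), gene in table.entries.items():
        gene_to_protein[genome][gene] = protein
    counts: dict[tuple[str, str], int] = {}
    for genome in table.genomes:
        located = [
            (loc, gene_to_protein[genome][gene])
            for (g, gene), loc in coords.items()
            if g == genome and gene in gene_to_protein[genome]
        ]
        located.sort(key=lambda item: (item[0].contig, item[0].start, item[0].end))
        for i, (loc_i, prot_i) in enumerate(located):
            for loc_j, prot_j in located[i + 1:]:
                if loc_j.contig != loc_i.contig:
                    break
                if loc_j.start - loc_i.end - 1 >= threshold:
                    # sorted by start: no later gene on this contig can be closer
                    break
                if prot_i == prot_j:
                    continue
                distance = neighborhood_distance(loc_i, loc_j)
                if distance is not None and distance < threshold:
                    pair = canonical_pair(prot_i, prot_j)
                    counts[pair] = counts.get(pair, 0) + 1
    return counts


# ---------------------------------------------------------------------------
# Mirror tree (MT)
# ---------------------------------------------------------------------------

@dataclass
class DistanceMatrix:
    """Symmetric sequence-distance matrix over an ordered species list."""

    species: list[str]
    d: np.ndarray  # square, symmetric, zero diagonal, values in [0, 1]

    def __post_init__(self) -> None:
        n = len(self.species)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match species list")

    def submatrix(self, species: Iterable[str]) -> "DistanceMatrix":
        wanted = list(species)
        index = {s: i for i, s in enumerate(self.species)}
        rows = [index[s] for s in wanted]
        return DistanceMatrix(species=wanted, d=self.d[np.ix_(rows, rows)])


def _encode_rows(alignment: OrthologAlignment) -> tuple[list[str], np.ndarray]:
    species = alignment.species
    arr = np.frombuffer(
        "".join(alignment.rows[s] for s in species).encode("ascii"), dtype=np.uint8
    ).reshape(len(species), alignment.length)
    return species, arr


_GAP_CODES = np.array([ord(c) for c in sorted(GAP_CHARS)], dtype=np.uint8)


def distance_matrix(alignment: OrthologAlignment) -> DistanceMatrix:
    """Pairwise distances: 1 - fractional identity over mutually ungapped
    columns.  A row pair with zero comparable positions is an error."""
    if len(alignment.rows) < 2:
        raise ValueError(f"alignment {alignment.protein!r} needs >= 2 rows")
    species, arr = _encode_rows(alignment)
    ungapped = ~np.isin(arr, _GAP_CODES)
    n = len(species)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            comparable = ungapped[i] & ungapped[j]
            total = int(comparable.sum())
            if total == 0:
                raise ValueError(
                    f"alignment {alignment.protein!r}: rows {species[i]!r}/{species[j]!r} "
                    "share no comparable positions"
                )
            mismatches = int(np.count_nonzero(arr[i][comparable] != arr[j][comparable]))
            d[i, j] = d[j, i] = mismatches / total
    return DistanceMatrix(species=species, d=d)


def mt_score(
    matrix_a: DistanceMatrix,
    matrix_b: DistanceMatrix,
    min_common: int = DEFAULT_MIN_COMMON,
) -> float | None:
    """Pearson correlation of the two matrices' strict upper triangles,
    restricted to common species.  Returns None when fewer than
    ``min_common`` species are shared or a triangle has zero variance."""
    common = sorted(set(matrix_a.species) & set(matrix_b.species))
    if len(common) < min_common:
        return None
    da = matrix_a.submatrix(common).d
    db = matrix_b.submatrix(common).d
    iu = np.triu_indices(len(common), k=1)
    va, vb = da[iu], db[iu]
    if np.ptp(va) == 0 or np.ptp(vb) == 0:
        log.debug("mt_score: zero variance in a distance triangle")
        return None
    return float(np.corrcoef(va, vb)[0, 1])


# ---------------------------------------------------------------------------
# In silico two-hybrid (I2H)
# ---------------------------------------------------------------------------

_AA_ORDER: str | None = None
_MCLACHLAN: np.ndarray | None = None


def mclachlan_matrix() -> tuple[str, np.ndarray]:
    """The packaged McLachlan amino-acid similarity matrix (order, values)."""
    global _AA_ORDER, _MCLACHLAN
    if _MCLACHLAN is None:
        resource = importlib.resources.files("appia.data").joinpath("mclachlan.tsv")
        lines = resource.read_text().splitlines()
        order = "".join(lines[0].strip().split("\t"))
        values = np.array(
            [[int(x) for x in line.split("\t")[1:]] for line in lines[1:]], dtype=float
        )
        _AA_ORDER, _MCLACHLAN = order, values
    return _AA_ORDER, _MCLACHLAN


def _residue_codes(column: Iterable[str]) -> np.ndarray:
    """Map residues to McLachlan indices; gaps/unknowns become -1."""
    order, _ = mclachlan_matrix()
    lookup = {aa: i for i, aa in enumerate(order)}
    return np.array([lookup.get(c.upper(), -1) for c in column], dtype=np.int64)


def mclachlan_site_correlation(
    column_a: Iterable[str], column_b: Iterable[str]
) -> float | None:
    """Correlation of McLachlan similarity patterns at two alignment columns.

    The two columns must be paired by species (same row order).  For every
    unordered species pair the similarity of the residues at each column is
    taken; the result is the Pearson correlation of the two similarity
    vectors.  Returns None with fewer than four mutually ungapped rows or
    when either column's similarity vector has zero variance.
    """
    _, matrix = mclachlan_matrix()
    ca = _residue_codes(column_a)
    cb = _residue_codes(column_b)
    if ca.shape != cb.shape:
        raise ValueError("columns are not paired: different row counts")
    valid = (ca >= 0) & (cb >= 0)
    ca, cb = ca[valid], cb[valid]
    n = ca.shape[0]
    if n < MIN_SITE_ROWS:
        return None
    iu, ju = np.triu_indices(n, k=1)
    sa = matrix[ca[iu], ca[ju]]
    sb = matrix[cb[iu], cb[ju]]
    if np.ptp(sa) == 0 or np.ptp(sb) == 0:
        return None
    return float(np.corrcoef(sa, sb)[0, 1])


def _column_codes_filtered(
    alignment: OrthologAlignment, species: list[str], max_gap_frac: float
) -> np.ndarray:
    """Residue codes (columns x species) for columns passing the gap filter."""
    arr = np.array(
        [_residue_codes(alignment.rows[s]) for s in species], dtype=np.int64
    )  # species x columns
    gap_frac = (arr < 0).mean(axis=0)
    keep = gap_frac <= max_gap_frac
    return arr[:, keep].T.copy()  # columns x species


def i2h_site_correlations(
    aln_a: OrthologAlignment,
    aln_b: OrthologAlignment,
    min_common: int = DEFAULT_MIN_COMMON,
    max_gap_frac: float = DEFAULT_MAX_GAP_FRAC,
) -> np.ndarray | None:
    """Matrix of inter-protein column-pair correlations (NaN = undefined).

    Vectorized, masked equivalent of calling
    :func:`mclachlan_site_correlation` on every (column in A, column in B).
    """
    _, matrix = mclachlan_matrix()
    common = sorted(set(aln_a.species) & set(aln_b.species))
    if len(common) < min_common:
        return None
    ca = _column_codes_filtered(aln_a, common, max_gap_frac)
    cb = _column_codes_filtered(aln_b, common, max_gap_frac)
    if ca.shape[0] == 0 or cb.shape[0] == 0:
        return None
    n_species = len(common)
    iu, ju = np.triu_indices(n_species, k=1)

    def site_vectors(codes: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        valid_rows = codes >= 0  # columns x species
        sims = matrix[codes.clip(min=0)[:, iu], codes.clip(min=0)[:, ju]]
        valid = valid_rows[:, iu] & valid_rows[:, ju]
        sims = np.where(valid, sims, 0.0)
        return sims, valid.astype(float), valid_rows.astype(float)

    sa, va, rows_a = site_vectors(ca)
    sb, vb, rows_b = site_vectors(cb)

    # pairwise-complete Pearson correlation via mask algebra
    n = va @ vb.T
    s_ab = sa @ sb.T
    s_a = sa @ vb.T
    s_b = va @ sb.T
    s_aa = (sa * sa) @ vb.T
    s_bb = va @ (sb * sb).T
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = s_ab - s_a * s_b / n
        var_a = s_aa - s_a * s_a / n
        var_b = s_bb - s_b * s_b / n
        r = cov / np.sqrt(var_a * var_b)
    m = rows_a @ rows_b.T  # mutually ungapped rows per column pair
    eps = 1e-12
    defined = (m >= MIN_SITE_ROWS) & (var_a > eps) & (var_b > eps)
    r[~defined] = np.nan
    return np.clip(r, -1.0, 1.0)


def i2h_score(
    aln_a: OrthologAlignment,
    aln_b: OrthologAlignment,
    r_cut: float = DEFAULT_R_CUT,
    min_common: int = DEFAULT_MIN_COMMON,
    max_gap_frac: float = DEFAULT_MAX_GAP_FRAC,
) -> float | None:
    """Fraction of defined inter-protein column pairs with correlation
    >= ``r_cut``.  Larger = stronger; None when nothing is defined."""
    r = i2h_site_correlations(aln_a, aln_b, min_common=min_common, max_gap_frac=max_gap_frac)
    if r is None:
        return None
    defined = ~np.isnan(r)
    total = int(defined.sum())
    if total == 0:
        return None
    return float((r[defined] >= r_cut).sum() / total)


# ---------------------------------------------------------------------------
# Gene fusion (GF, ingested from an external z-score list)
# ---------------------------------------------------------------------------

def ingest_gf(pairs: PairList) -> dict[tuple[str, str], float]:
    """Pass external gene-fusion z-scores through unchanged.

    Duplicate pairs were already collapsed to the maximum score at read
    time.  Pairs without a score are an error.
    """
    scores = pairs.scores
    missing = pairs.pairs - set(scores)
    if missing:
        raise ValueError(f"{len(missing)} gene-fusion pairs carry no score")
    return scores
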