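"""Assembly of the 19-attribute instance representation.

Three attribute groups per protein pair:

* 5 method scores (``score_pp`` ... ``score_i2h``),
* 10 protein-centered rank attributes (``rank_min_m`` / ``rank_max_m`` for
  each method ``m``): the smallest and largest of the pair's positions in
  the two proteins' strongest-first prediction lists,
* 4 protein features (``len_a``, ``len_b``, ``north_a``, ``north_b``):
  sequence length and number of orthologs of each protein.

Missing values are NaN (DataFrame form) or ``None`` (scalar form) — never a
flag value.  A missing method score implies both of its rank attributes are
missing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .io_formats import FormatError, canonical_pair
from .predictors import METHODS, ORIENTATIONS

log = logging.getLogger(__name__)

DEFAULT_RANK_CUTOFF = 100
DEFAULT_FILTER_METHODS = ("PP", "MT", "I2H")

SCORE_COLUMNS = [f"score_{m.lower()}" for m in METHODS]
RANK_COLUMNS = [
    f"rank_{kind}_{m.lower()}" for m in METHODS for kind in ("min", "max")
]
PROTEIN_COLUMNS = ["len_a", "len_b", "north_a", "north_b"]
#: the 19 attribute columns, in canonical order
ATTRIBUTE_COLUMNS = SCORE_COLUMNS + RANK_COLUMNS + PROTEIN_COLUMNS


@dataclass
class ProteinRecord:
    protein: str
    length: int
    n_orthologs: int

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError(f"{self.protein}: length must be >= 1")
        if self.n_orthologs < 0:
            raise ValueError(f"{self.protein}: negative ortholog count")


@dataclass
class FeatureVector:
    """One pair's 19 attributes plus identifiers and label."""

    protein_a: str
    protein_b: str
    score_pp: float | None = None
    score_gc: float | None = None
    score_gf: float | None = None
    score_mt: float | None = None
    score_i2h: float | None = None
    rank_min_pp: int | None = None
    rank_max_pp: int | None = None
    rank_min_gc: int | None = None
    rank_max_gc: int | None = None
    rank_min_gf: int | None = None
    rank_max_gf: int | None = None
    rank_min_mt: int | None = None
    rank_max_mt: int | None = None
    rank_min_i2h: int | None = None
    rank_max_i2h: int | None = None
    len_a: int | None = None
    len_b: int | None = None
    north_a: int | None = None
    north_b: int | None = None
    label: str = "unknown"

    def attributes(self) -> dict[str, float | None]:
        return {name: getattr(self, name) for name in ATTRIBUTE_COLUMNS}


def protein_centered_rank(
    protein: str,
    method: str,
    scores: Mapping[tuple[str, str], float],
) -> dict[tuple[str, str], int]:
    """Competition ranks of all of ``protein``'s pairs under one method.

    Pairs are sorted strongest-first according to the method's orientation;
    rank 1 is the strongest.  Ties share the smallest rank; the returned
    mapping lists tied pairs in canonical pair-id order.
    """
    ascending = ORIENTATIONS[method]
    mine = [(pair, s) for pair, s in scores.items() if protein in pair]
    sign = 1.0 if ascending else -1.0
    mine.sort(key=lambda item: (sign * item[1], item[0]))
    ranks: dict[tuple[str, str], int] = {}
    previous_score: float | None = None
    previous_rank = 0
    for position, (pair, score) in enumerate(mine, start=1):
        if previous_score is not None and score == previous_score:
            ranks[pair] = previous_rank
        else:
            ranks[pair] = position
            previous_rank = position
            previous_score = score
    return ranks


def rank_attributes(
    pair: tuple[str, str],
    method: str,
    ranks_a: Mapping[tuple[str, str], int],
    ranks_b: Mapping[tuple[str, str], int],
) -> tuple[int | None, int | None]:
    """(rank_min, rank_max) of the pair in the two proteins' lists.

    Both attributes are missing when the method did not score the pair.
    """
    ra = ranks_a.get(pair)
    rb = ranks_b.get(pair)
    if ra is None or rb is None:
        return (None, None)
    return (min(ra, rb), max(ra, rb))


def assemble(
    pair: tuple[str, str],
    scores: Mapping[str, float | None],
    rank_maps: Mapping[str, tuple[int | None, int | None]],
    protein_records: Mapping[str, ProteinRecord],
    label: str = "unknown",
) -> FeatureVector:
    """Build one pair's FeatureVector from per-method scores and ranks.

    ``scores`` maps method name -> score (or None); ``rank_maps`` maps
    method name -> (rank_min, rank_max).  A pair without any method score is
    uninformative and rejected; a protein without a record is an error.
    """
    a, b = canonical_pair(*pair)
    present = [m for m in METHODS if scores.get(m) is not None]
    if not present:
        raise ValueError(f"pair {pair}: no method score at all (uninformative)")
    for protein in (a, b):
        if protein not in protein_records:
            raise KeyError(f"no protein record for {protein!r}")
    vector = FeatureVector(protein_a=a, protein_b=b, label=label)
    for method in METHODS:
        m = method.lower()
        score = scores.get(method)
        setattr(vector, f"score_{m}", score)
        rmin, rmax = rank_maps.get(method, (None, None))
        if score is None:
            rmin = rmax = None
        setattr(vector, f"rank_min_{m}", rmin)
        setattr(vector, f"rank_max_{m}", rmax)
    vector.len_a = protein_records[a].length
    vector.len_b = protein_records[b].length
    vector.north_a = protein_records[a].n_orthologs
    vector.north_b = protein_records[b].n_orthologs
    return vector


def rank_filter(
    vectors: pd.DataFrame,
    cutoff: int = DEFAULT_RANK_CUTOFF,
    filter_methods: Iterable[str] = DEFAULT_FILTER_METHODS,
    keep_methods: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Noise filter on the rank attributes of the noisy methods.

    A vector is kept iff at least one rank attribute of ``filter_methods``
    is present and <= ``cutoff``, or it carries a score from any of
    ``keep_methods`` (default: every method not in ``filter_methods``).
    """
    filter_methods = tuple(filter_methods)
    if keep_methods is None:
        keep_methods = tuple(m for m in METHODS if m not in filter_methods)
    keep = pd.Series(False, index=vectors.index)
    for method in filter_methods:
        m = method.lower()
        for kind in ("min", "max"):
            column = vectors[f"rank_{kind}_{m}"]
            keep |= column.notna() & (column <= cutoff)
    for method in keep_methods:
        keep |= vectors[f"score_{method.lower()}"].notna()
    removed = int((~keep).sum())
    log.info("rank filter: kept %d vectors, removed %d", int(keep.sum()), removed)
    return vectors[keep]


# ---------------------------------------------------------------------------
# Bulk assembly (DataFrame path used by the pipeline)
# ---------------------------------------------------------------------------

def _method_wide(scores: pd.DataFrame, method: str) -> pd.DataFrame:
    """Wide frame for one method: score + rank_min + rank_max per pair."""
    m = method.lower()
    df = scores.loc[scores["method"] == method, ["protein_a", "protein_b", "score"]]
    if df.empty:
        return pd.DataFrame(
            columns=["protein_a", "protein_b", f"score_{m}", f"rank_min_{m}", f"rank_max_{m}"]
        )
    ascending = ORIENTATIONS[method]
    long = pd.concat(
        [
            df.assign(protein=df["protein_a"]),
            df.assign(protein=df["protein_b"]),
        ],
        ignore_index=True,
    )
    long["rank"] = (
        long.groupby("protein")["score"].rank(method="min", ascending=ascending)
    )
    grouped = long.groupby(["protein_a", "protein_b"])["rank"].agg(["min", "max"])
    wide = df.set_index(["protein_a", "protein_b"]).join(grouped)
    wide = wide.rename(
        columns={"score": f"score_{m}", "min": f"rank_min_{m}", "max": f"rank_max_{m}"}
    )
    return wide.reset_index()


def build_feature_table(
    scores: pd.DataFrame,
    protein_records: Mapping[str, ProteinRecord],
) -> pd.DataFrame:
    """Assemble the full (unfiltered) feature table from a long score frame.

    ``scores`` has columns ``protein_a, protein_b, method, score`` with
    canonical pairs.  Every protein appearing in a scored pair must have a
    record.  The result has one row per pair and the 19 attribute columns;
    the row order is sorted by pair id (deterministic).
    """
    bad = scores["protein_a"] >= scores["protein_b"]
    if bad.any():
        raise FormatError("score frame contains non-canonical or homodimer pairs")
    unknown = set(scores["method"]) - set(METHODS)
    if unknown:
        raise FormatError(f"unknown methods in score frame: {sorted(unknown)}")
    merged: pd.DataFrame | None = None
    for method in METHODS:
        wide = _method_wide(scores, method)
        if merged is None:
            merged = wide
        else:
            merged = merged.merge(wide, on=["protein_a", "protein_b"], how="outer")
    assert merged is not None
    merged = merged.sort_values(["protein_a", "protein_b"], ignore_index=True)
    for protein_column, length_column, north_column in (
        ("protein_a", "len_a", "north_a"),
        ("protein_b", "len_b", "north_b"),
    ):
        proteins = merged[protein_column]
        missing = set(proteins.unique()) - set(protein_records)
        if missing:
            raise KeyError(
                f"no protein record for {len(missing)} proteins, e.g. {sorted(missing)[:3]}"
            )
        merged[length_column] = proteins.map(
            {p: r.length for p, r in protein_records.items()}
        )
        merged[north_column] = proteins.map(
            {p: r.n_orthologs for p, r in protein_records.items()}
        )
    return merged[["protein_a", "protein_b"] + ATTRIBUTE_COLUMNS]


def write_feature_table(df: pd.DataFrame, path) -> None:
    """Feature matrix TSV; missing values encoded as empty fields."""
    df.to_csv(path, sep="\t", index=False, na_rep="")


def read_feature_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"protein_a": str, "protein_b": str})
    expected = {"protein_a", "protein_b", *ATTRIBUTE_COLUMNS}
    missing = expected - set(df.columns)
    if missing:
        raise FormatError(f"{path}: feature table lacks columns {sorted(missing)}")
    return df
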