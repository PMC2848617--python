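"""Positive/negative classes and the balanced train/test split.

The emitted sets are 20% positive / 80% negative by construction: each
set's negatives are exactly four times its positives, the training set
takes two thirds of the positives, and the test set the remaining third
(so the test set is half the training set when the positive count divides
by three).  Negatives are drawn only from non-positive pairs among the
proteins of the positive set, restricted to pairs for which at least one
prediction method produced a value.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np

from .io_formats import PairList, canonical_pair

log = logging.getLogger(__name__)

POSITIVE_SOURCES = (
    "pathway_kegg",
    "pathway_ecocyc",
    "regulator_regulated",
    "coregulated",
    "literature",
    "physical_lt",
    "complex_curated",
    "complex_ht",
)

TRAIN_POSITIVE_FRACTION = 2.0 / 3.0
NEGATIVE_MULTIPLIER = 4


@dataclass
class GoldStandard:
    positives: PairList
    negatives: PairList

    def __post_init__(self) -> None:
        overlap = self.positives.pairs & self.negatives.pairs
        if overlap:
            raise ValueError(f"{len(overlap)} pairs are both positive and negative")
        outside = self.negatives.proteins() - self.positives.proteins()
        if outside:
            raise ValueError(
                f"negative pairs involve {len(outside)} proteins outside the positive set"
            )


@dataclass
class DataSplit:
    train_positives: list[tuple[str, str]]
    train_negatives: list[tuple[str, str]]
    test_positives: list[tuple[str, str]]
    test_negatives: list[tuple[str, str]]
    seed: int

    @property
    def training(self) -> list[tuple[tuple[str, str], str]]:
        return [(p, "positive") for p in self.train_positives] + [
            (p, "negative") for p in self.train_negatives
        ]

    @property
    def test(self) -> list[tuple[tuple[str, str], str]]:
        return [(p, "positive") for p in self.test_positives] + [
            (p, "negative") for p in self.test_negatives
        ]

    def train_pairs(self) -> set[tuple[str, str]]:
        return set(self.train_positives) | set(self.train_negatives)


def build_positives(source_lists: Mapping[str, PairList]) -> PairList:
    """Union of the per-source pair lists, tagging each pair with every
    source that contributed it.  Homodimers never survive (PairList drops
    them at insertion)."""
    merged = PairList()
    for source, pairs in source_lists.items():
        for a, b in pairs:
            merged.add(a, b, source=source)
    if len(merged) == 0:
        raise ValueError("empty positive set")
    return merged


def coregulated_from_regulons(
    regulons: Mapping[str, Iterable[str]],
) -> tuple[PairList, PairList]:
    """Pairs derived from transcription regulons.

    Returns ``(coregulated, regulator_regulated)``: all unordered target
    pairs within each regulon (unioned across regulons), and the
    regulator-target links, tagged with their standard source names.
    """
    coregulated = PairList()
    regulator_target = PairList()
    for regulator in sorted(regulons):
        targets = sorted(set(regulons[regulator]))
        for target in targets:
            regulator_target.add(regulator, target, source="regulator_regulated")
        for a, b in itertools.combinations(targets, 2):
            coregulated.add(a, b, source="coregulated")
    return coregulated, regulator_target


def build_negatives(
    positives: PairList,
    scored_pairs: Iterable[tuple[str, str]],
) -> PairList:
    """Non-positive pairs among the positive set's proteins that carry at
    least one method value.  Pairs without any value are uninformative and
    excluded."""
    if len(positives) == 0:
        raise ValueError("positive set is empty")
    universe = positives.proteins()
    scored = set(scored_pairs)
    negatives = PairList()
    for a, b in sorted(scored):
        pair = canonical_pair(a, b)
        if pair in positives:
            continue
        if pair[0] not in universe or pair[1] not in universe:
            continue
        negatives.add(*pair, source="negative")
    return negatives


def make_split(positives: PairList, negatives: PairList, seed: int) -> DataSplit:
    """Seeded 2/3 - 1/3 positive split, each side completed with exactly
    four negatives per positive (sampled uniformly without replacement,
    disjoint between sets)."""
    pos = sorted(positives.pairs)
    neg = sorted(negatives.pairs)
    n_pos = len(pos)
    required = NEGATIVE_MULTIPLIER * n_pos
    if len(neg) < required:
        raise ValueError(
            f"insufficient negatives: need {required} (= {NEGATIVE_MULTIPLIER} x "
            f"{n_pos} positives), have {len(neg)}"
        )
    rng = np.random.default_rng(seed)
    pos_order = rng.permutation(n_pos)
    n_train_pos = int(TRAIN_POSITIVE_FRACTION * n_pos)
    train_pos = [pos[i] for i in pos_order[:n_train_pos]]
    test_pos = [pos[i] for i in pos_order[n_train_pos:]]
    neg_order = rng.choice(len(neg), size=required, replace=False)
    n_train_neg = NEGATIVE_MULTIPLIER * n_train_pos
    train_neg = [neg[i] for i in neg_order[:n_train_neg]]
    test_neg = [neg[i] for i in neg_order[n_train_neg:]]
    log.info(
        "split (seed %d): train %d+ / %d-, test %d+ / %d-; %d negatives discarded",
        seed, len(train_pos), len(train_neg), len(test_pos), len(test_neg),
        len(neg) - required,
    )
    return DataSplit(
        train_positives=train_pos,
        train_negatives=train_neg,
        test_positives=test_pos,
        test_negatives=test_neg,
        seed=seed,
    )
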