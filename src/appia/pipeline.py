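"""End-to-end orchestration: score -> features -> gold standard -> train ->
predict -> evaluate, driven by a single YAML config.

Methods are independently toggleable: the 19-attribute schema is always
emitted, with a disabled method's attributes all-missing.  Every stage
logs its instance counts so a run can be audited from the run log.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import aode, evaluation, features, gold_standard, predictors
from .features import ProteinRecord
from .io_formats import (
    read_tagged_pair_list,
    GeneLocation,
    OrthologAlignment,
    OrthologTable,
    PairList,
    read_alignment_dir,
    read_gene_coordinates_dir,
    read_ortholog_table,
    read_pair_list,
    read_protein_lengths,
    read_regulons,
    save_model,
    write_scores,
)

log = logging.getLogger(__name__)

DEFAULT_TOPN_GRID = (10, 20, 50, 100, 200, 500, 1000, 2000)


@dataclass
class RunParams:
    """All tunable constants of a pipeline run."""

    methods: tuple[str, ...] = predictors.METHODS
    gc_threshold: int = predictors.DEFAULT_GC_THRESHOLD
    rank_cutoff: int = features.DEFAULT_RANK_CUTOFF
    filter_methods: tuple[str, ...] = features.DEFAULT_FILTER_METHODS
    min_per_band: int = aode.DEFAULT_MIN_PER_BAND
    target_bands: int = aode.DEFAULT_TARGET_BANDS
    min_common: int = predictors.DEFAULT_MIN_COMMON
    r_cut: float = predictors.DEFAULT_R_CUT
    max_gap_frac: float = predictors.DEFAULT_MAX_GAP_FRAC
    train_pos_fraction: float = gold_standard.TRAIN_POSITIVE_FRACTION
    negative_multiplier: int = gold_standard.NEGATIVE_MULTIPLIER
    parent_frequency: int = aode.DEFAULT_PARENT_FREQUENCY
    threshold: float = 0.5
    topn_grid: tuple[int, ...] = DEFAULT_TOPN_GRID

    def __post_init__(self) -> None:
        for name in ("gc_threshold", "rank_cutoff", "min_per_band", "min_common",
                     "negative_multiplier"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 < self.train_pos_fraction <= 1.0:
            raise ValueError("train_pos_fraction must be in (0, 1]")
        unknown = set(self.methods) - set(predictors.METHODS)
        if unknown:
            raise ValueError(f"unknown methods: {sorted(unknown)}")


@dataclass
class PipelineInputs:
    table: OrthologTable
    coordinates: Mapping[tuple[str, str], GeneLocation]
    alignments: Mapping[str, OrthologAlignment]
    gf: PairList | None
    positives: PairList
    protein_lengths: Mapping[str, int]

    def protein_records(self) -> dict[str, ProteinRecord]:
        return {
            p: ProteinRecord(
                protein=p,
                length=self.protein_lengths[p],
                n_orthologs=self.table.n_orthologs(p),
            )
            for p in self.table.proteins
            if p in self.protein_lengths
        }


@dataclass
class RunResult:
    scores: pd.DataFrame
    feature_table: pd.DataFrame  # filtered, with labels
    split: gold_standard.DataSplit
    model: aode.AODEModel
    test_probabilities: pd.DataFrame
    roc_points: list
    cost_curve: evaluation.CostCurve
    test_mcc: float
    extended_ranking: pd.DataFrame  # pair + appia probability, strongest first
    topn: dict[str, list[tuple[int, float]]]  # per method + "APPIA"
    counts: dict[str, int] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------

def compute_scores(inputs: PipelineInputs, params: RunParams) -> pd.DataFrame:
    """Long score frame (protein_a, protein_b, method, score) for all
    enabled methods.

    PP scores every pair of proteins with at least one ortholog each; GC
    emits only nonzero adjacency counts; GF passes the external list
    through (restricted to known proteins); MT and I2H cover pairs of
    aligned proteins with enough common species.
    """
    frames: list[pd.DataFrame] = []
    if "PP" in params.methods:
        proteins, matrix = predictors.profile_matrix(inputs.table)
        keep = matrix.sum(axis=1) > 0
        kept = [p for p, k in zip(proteins, keep) if k]
        sub = matrix[keep]
        hamming = predictors.pp_score_matrix(sub)
        iu, ju = np.triu_indices(len(kept), k=1)
        frames.append(
            pd.DataFrame(
                {
                    "protein_a": np.asarray(kept, dtype=object)[iu],
                    "protein_b": np.asarray(kept, dtype=object)[ju],
                    "method": "PP",
                    "score": hamming[iu, ju].astype(float),
                }
            )
        )
    if "GC" in params.methods:
        counts = predictors.gc_scores_bulk(
            inputs.table, inputs.coordinates, threshold=params.gc_threshold
        )
        pairs = sorted(counts)
        frames.append(
            pd.DataFrame(
                {
                    "protein_a": [p[0] for p in pairs],
                    "protein_b": [p[1] for p in pairs],
                    "method": "GC",
                    "score": [float(counts[p]) for p in pairs],
                }
            )
        )
    if "GF" in params.methods and inputs.gf is not None:
        scores = predictors.ingest_gf(inputs.gf)
        known = set(inputs.table.proteins)
        pairs = sorted(p for p in scores if p[0] in known and p[1] in known)
        skipped = len(scores) - len(pairs)
        if skipped:
            log.info("GF: skipped %d pairs with unknown proteins", skipped)
        frames.append(
            pd.DataFrame(
                {
                    "protein_a": [p[0] for p in pairs],
                    "protein_b": [p[1] for p in pairs],
                    "method": "GF",
                    "score": [scores[p] for p in pairs],
                }
            )
        )
    need_alignments = {"MT", "I2H"} & set(params.methods)
    if need_alignments and inputs.alignments:
        aligned = sorted(inputs.alignments)
        matrices = {}
        if "MT" in params.methods:
            matrices = {p: predictors.distance_matrix(inputs.alignments[p]) for p in aligned}
        mt_rows, i2h_rows = [], []
        for i, a in enumerate(aligned):
            for b in aligned[i + 1:]:
                if "MT" in params.methods:
                    score = predictors.mt_score(
                        matrices[a], matrices[b], min_common=params.min_common
                    )
                    if score is not None:
                        mt_rows.append((a, b, score))
                if "I2H" in params.methods:
                    score = predictors.i2h_score(
                        inputs.alignments[a],
                        inputs.alignments[b],
                        r_cut=params.r_cut,
                        min_common=params.min_common,
                        max_gap_frac=params.max_gap_frac,
                    )
                    if score is not None:
                        i2h_rows.append((a, b, score))
        for method, rows in (("MT", mt_rows), ("I2H", i2h_rows)):
            if method in params.methods:
                frames.append(
                    pd.DataFrame(rows, columns=["protein_a", "protein_b", "score"]).assign(
                        method=method
                    )[["protein_a", "protein_b", "method", "score"]]
                )
    if not frames:
        raise ValueError("no method produced any scores")
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Feature matrices and training frames
# ---------------------------------------------------------------------------

def build_features(
    scores: pd.DataFrame,
    protein_records: Mapping[str, ProteinRecord],
    params: RunParams,
) -> pd.DataFrame:
    table = features.build_feature_table(scores, protein_records)
    return features.rank_filter(
        table, cutoff=params.rank_cutoff, filter_methods=params.filter_methods
    ).reset_index(drop=True)


def label_features(feature_table: pd.DataFrame, positives: PairList) -> pd.DataFrame:
    pairs = list(zip(feature_table["protein_a"], feature_table["protein_b"]))
    labels = ["positive" if p in positives else "negative" for p in pairs]
    return feature_table.assign(label=labels)


def _rows_for_pairs(
    feature_table: pd.DataFrame, pairs: Sequence[tuple[str, str]]
) -> pd.DataFrame:
    indexed = feature_table.set_index(["protein_a", "protein_b"])
    return indexed.loc[list(pairs)].reset_index()


# ---------------------------------------------------------------------------
# Full run
# ---------------------------------------------------------------------------

def run_core(inputs: PipelineInputs, params: RunParams, seed: int) -> RunResult:
    counts: dict[str, int] = {}
    scores = compute_scores(inputs, params)
    counts["scored_pairs"] = scores.groupby(["protein_a", "protein_b"]).ngroups
    records = inputs.protein_records()
    feature_table = build_features(scores, records, params)
    counts["feature_vectors"] = len(feature_table)

    feature_pairs = set(zip(feature_table["protein_a"], feature_table["protein_b"]))
    usable_positives = PairList()
    for a, b in inputs.positives:
        if (a, b) in feature_pairs:
            usable_positives.add(a, b, source="positive")
    dropped = len(inputs.positives) - len(usable_positives)
    if dropped:
        log.info("%d positives have no feature vector and are unusable", dropped)
    counts["usable_positives"] = len(usable_positives)
    negatives = gold_standard.build_negatives(usable_positives, feature_pairs)
    counts["negative_pool"] = len(negatives)
    split = gold_standard.make_split(usable_positives, negatives, seed=seed)

    labelled = label_features(feature_table, inputs.positives)
    attribute_frame = labelled[features.ATTRIBUTE_COLUMNS].astype(float)

    train_pairs = split.train_positives + split.train_negatives
    train_labels = ["positive"] * len(split.train_positives) + (
        ["negative"] * len(split.train_negatives)
    )
    pair_index = {
        pair: i
        for i, pair in enumerate(zip(labelled["protein_a"], labelled["protein_b"]))
    }
    train_rows = [pair_index[p] for p in train_pairs]
    discretizer = aode.fit_discretizer(
        attribute_frame.iloc[train_rows],
        min_per_band=params.min_per_band,
        target_bands=params.target_bands,
    )
    codes = aode.discretize(attribute_frame, discretizer)
    n_values = [discretizer.n_bands(a) for a in features.ATTRIBUTE_COLUMNS]
    model = aode.fit_aode(
        codes[train_rows],
        train_labels,
        attributes=features.ATTRIBUTE_COLUMNS,
        n_values=n_values,
        m=params.parent_frequency,
        discretizer=discretizer,
    )

    # --- test-set evaluation ------------------------------------------------
    test_pairs = split.test_positives + split.test_negatives
    test_labels = np.array(
        [True] * len(split.test_positives) + [False] * len(split.test_negatives)
    )
    test_rows = [pair_index[p] for p in test_pairs]
    test_probs = aode.positive_probability(model, codes[test_rows])
    test_probabilities = pd.DataFrame(
        {
            "protein_a": [p[0] for p in test_pairs],
            "protein_b": [p[1] for p in test_pairs],
            "probability": test_probs,
            "label": np.where(test_labels, "positive", "negative"),
        }
    )
    roc_points = evaluation.roc(test_probs, test_labels)
    curve = evaluation.lower_envelope(
        evaluation.cost_lines(roc_points) + evaluation.trivial_lines()
    )
    predicted = test_probs >= params.threshold
    test_mcc = evaluation.mcc(evaluation.confusion_counts(predicted, test_labels))

    # --- extended-set ranking and per-method accuracy curves ----------------
    train_set = split.train_pairs()
    all_pairs = list(zip(labelled["protein_a"], labelled["protein_b"]))
    extended_mask = np.array([p not in train_set for p in all_pairs])
    extended_rows = np.flatnonzero(extended_mask)
    counts["extended_pairs"] = len(extended_rows)
    extended_probs = aode.positive_probability(model, codes[extended_rows])
    extended = pd.DataFrame(
        {
            "protein_a": labelled["protein_a"].to_numpy()[extended_rows],
            "protein_b": labelled["protein_b"].to_numpy()[extended_rows],
            "probability": extended_probs,
        }
    ).sort_values(
        by=["probability", "protein_a", "protein_b"],
        ascending=[False, True, True],
        ignore_index=True,
    )

    gold_pairs = inputs.positives.pairs
    topn: dict[str, list[tuple[int, float]]] = {}
    topn["APPIA"] = evaluation.topn_accuracy(
        list(zip(extended["protein_a"], extended["protein_b"])),
        gold_pairs,
        params.topn_grid,
    )
    for method in params.methods:
        method_scores = scores[scores["method"] == method]
        pairs = list(zip(method_scores["protein_a"], method_scores["protein_b"]))
        values = method_scores["score"].to_numpy()
        in_extended = np.array([p not in train_set for p in pairs])
        pairs = [p for p, keep in zip(pairs, in_extended) if keep]
        values = values[in_extended]
        ascending = predictors.ORIENTATIONS[method]
        order = np.lexsort(
            (
                [p[1] for p in pairs],
                [p[0] for p in pairs],
                values if ascending else -values,
            )
        )
        ranked = [pairs[i] for i in order]
        topn[method] = evaluation.topn_accuracy(ranked, gold_pairs, params.topn_grid)

    return RunResult(
        scores=scores,
        feature_table=labelled,
        split=split,
        model=model,
        test_probabilities=test_probabilities,
        roc_points=roc_points,
        cost_curve=curve,
        test_mcc=test_mcc,
        extended_ranking=extended,
        topn=topn,
        counts=counts,
    )


# ---------------------------------------------------------------------------
# Config-file driven entry point
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    seed: int
    out_dir: str
    orthologs: str
    proteins: str
    gff_dir: str | None = None
    aln_dir: str | None = None
    gf: str | None = None
    positives: str | None = None
    regulons: str | None = None
    params: RunParams = field(default_factory=RunParams)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with Path(path).open() as handle:
            raw = yaml.safe_load(handle)
        params_raw = raw.pop("params", {})
        for key in ("methods", "filter_methods", "topn_grid"):
            if key in params_raw:
                params_raw[key] = tuple(params_raw[key])
        return cls(params=RunParams(**params_raw), **raw)


def load_inputs(config: RunConfig) -> PipelineInputs:
    table = read_ortholog_table(config.orthologs)
    coordinates = (
        read_gene_coordinates_dir(config.gff_dir) if config.gff_dir else {}
    )
    alignments = read_alignment_dir(config.aln_dir) if config.aln_dir else {}
    gf = read_pair_list(config.gf, source="gene_fusion") if config.gf else None
    positives = PairList()
    if config.positives:
        positives.update(read_tagged_pair_list(config.positives))
    if config.regulons:
        regulons = read_regulons(config.regulons)
        coregulated, regulator_target = gold_standard.coregulated_from_regulons(regulons)
        positives.update(coregulated)
        positives.update(regulator_target)
    if len(positives) == 0:
        raise ValueError("no positive pairs: provide positives and/or regulons")
    protein_lengths = read_protein_lengths(config.proteins)
    return PipelineInputs(
        table=table,
        coordinates=coordinates,
        alignments=alignments,
        gf=gf,
        positives=positives,
        protein_lengths=protein_lengths,
    )


def run_all(config: RunConfig) -> RunResult:
    """Execute the full pipeline and write every artifact to the run
    directory.  Idempotent for a fixed config and seed."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("appia")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        log.info("run config: %s", dataclasses.asdict(config))
        inputs = load_inputs(config)
        result = run_core(inputs, config.params, seed=config.seed)
        write_scores(result.scores, out / "scores.tsv")
        features.write_feature_table(result.feature_table, out / "features.tsv")
        save_model(result.model, out / "model.json")
        result.test_probabilities.to_csv(out / "predictions.tsv", sep="\t", index=False)
        evaluation.write_roc(result.roc_points, out / "roc.tsv")
        evaluation.write_cost_curve(result.cost_curve, out / "costcurve.tsv")
        for name, curve in result.topn.items():
            evaluation.write_topn(curve, out / f"topn_{name.lower()}.tsv")
        result.extended_ranking.to_csv(out / "extended_ranking.tsv", sep="\t", index=False)
        log.info("run complete: %s; test MCC %.4f", result.counts, result.test_mcc)
        return result
    except Exception as exc:  # noqa: BLE001 - annotate the failing stage
        log.error("run aborted: %s", exc)
        raise
    finally:
        root.removeHandler(handler)
        handler.close()
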