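"""End-to-end orchestration: features, cross-validated evaluation, ranking.

The full pipeline for a balanced sample of microbe-disease pairs is:

1. similarity bundle -> fused matrices FuD (diseases) and FuM (microbes);
2. initial pair vector = FuD row of the disease ++ FuM row of the microbe
   (width n_diseases + n_microbes; 1311 at reference scale);
3. low-rank block = GCN disease embedding ++ GCN microbe embedding
   (width 2*h2; 256 under defaults);
4. high-rank block = auto-encoder bottleneck code of the initial vector
   (144 under defaults);
5. final block = low-rank ++ high-rank (400 under defaults), classified by
   the cascade forest.

Cross-validation supports two protocols.  In "faithful" mode the similarity,
GCN and auto-encoder stages are trained once on the full association matrix
(test-fold positives visible to the unsupervised stages, as association
predictors are commonly evaluated).  In "masked" mode the test fold's
positive entries are zeroed before every training stage of that fold, so no
test information can leak into the features; this is the leakage-safe
protocol and the stricter measure of generalisation.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import (
    accuracy_score,
    average_precision_score,
    f1_score,
    precision_score,
    recall_score,
    roc_auc_score,
)

from .autoencoder import DAEConfig, encode, train_dae
from .cascade import CascadeConfig, fit_cascade, predict_proba
from .core_data import AssociationNetwork, DiseaseOntologyGraph
from .gcn import GCNConfig, GCNEmbeddings, train_gcn
from .negative_sampling import NegativeSamplingPlan, candidate_negatives, sample_negatives
from .similarity import SimilarityBundle, SimilarityConfig, build_similarity_bundle

__all__ = [
    "PipelineConfig",
    "EvaluationReport",
    "RankedPredictions",
    "assemble_initial_features",
    "assemble_final_features",
    "ablation_slice",
    "stratified_kfold",
    "compute_metrics",
    "run_cross_validation",
    "rank_candidates",
]

METRIC_NAMES = ("accuracy", "precision", "recall", "f1", "auc", "aupr")
ABLATIONS = ("LRF", "HRF", "LHRF")


@dataclass(frozen=True)
class PipelineConfig:
    """All stage configurations plus the evaluation protocol settings."""

    similarity: SimilarityConfig = field(default_factory=SimilarityConfig)
    gcn: GCNConfig = field(default_factory=GCNConfig)
    dae: DAEConfig | None = None  # None: sized from the network at run time
    cascade: CascadeConfig = field(default_factory=CascadeConfig)
    negatives: NegativeSamplingPlan = field(default_factory=NegativeSamplingPlan)
    n_folds: int = 10
    evaluation_mode: str = "faithful"
    ablation: str = "LHRF"
    threshold: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.evaluation_mode not in ("faithful", "masked"):
            raise ValueError("evaluation_mode must be 'faithful' or 'masked'")
        if self.ablation not in ABLATIONS:
            raise ValueError(f"ablation must be one of {ABLATIONS}")

    def reseeded(self, seed: int) -> "PipelineConfig":
        """Copy with every stage seed derived from ``seed``."""
        return dataclasses.replace(
            self,
            seed=seed,
            gcn=dataclasses.replace(self.gcn, seed=seed + 1),
            dae=dataclasses.replace(self.dae, seed=seed + 2) if self.dae else None,
            cascade=dataclasses.replace(self.cascade, seed=seed + 3),
            negatives=dataclasses.replace(self.negatives, seed=seed + 4),
        )


@dataclass(frozen=True)
class EvaluationReport:
    """Per-fold and aggregate metrics of one cross-validated run."""

    fold_metrics: tuple[dict, ...]
    mean: dict
    std: dict
    ablation: str
    evaluation_mode: str
    n_folds: int
    config: PipelineConfig


@dataclass(frozen=True)
class RankedPredictions:
    """Scored microbes for one disease, sorted by descending score."""

    disease_id: str
    mode: str
    ranking: tuple[tuple[str, float, int], ...]  # (microbe_id, score, rank)


def assemble_initial_features(
    bundle: SimilarityBundle, pairs: list[tuple[int, int]]
) -> np.ndarray:
    """Initial pair vectors: FuD row of the disease ++ FuM row of the microbe."""
    n_d = bundle.FuD.shape[0]
    n_m = bundle.FuM.shape[0]
    out = np.empty((len(pairs), n_d + n_m))
    for r, (i, j) in enumerate(pairs):
        if not (0 <= i < n_m and 0 <= j < n_d):
            raise IndexError(f"pair ({i}, {j}) out of range for {n_m} x {n_d}")
        out[r, :n_d] = bundle.FuD[j]
        out[r, n_d:] = bundle.FuM[i]
    return out


def assemble_final_features(
    emb: GCNEmbeddings, high_rank: np.ndarray, pairs: list[tuple[int, int]]
) -> np.ndarray:
    """Final pair vectors: LD row ++ LM row ++ auto-encoder code (row-aligned)."""
    high_rank = np.atleast_2d(high_rank)
    if len(high_rank) != len(pairs):
        raise ValueError("high-rank block is not aligned with the pair list")
    h2 = emb.LM.shape[1]
    out = np.empty((len(pairs), 2 * h2 + high_rank.shape[1]))
    for r, (i, j) in enumerate(pairs):
        out[r, :h2] = emb.LD[j]
        out[r, h2 : 2 * h2] = emb.LM[i]
        out[r, 2 * h2 :] = high_rank[r]
    return out


def ablation_slice(final: np.ndarray, ablation: str, h2: int) -> np.ndarray:
    """LRF = the 2*h2 embedding columns; HRF = the code columns; LHRF = all."""
    if ablation == "LRF":
        return final[:, : 2 * h2]
    if ablation == "HRF":
        return final[:, 2 * h2 :]
    if ablation == "LHRF":
        return final
    raise ValueError(f"unknown ablation {ablation!r}")


def stratified_kfold(
    labels: np.ndarray, k: int = 10, seed: int = 0
) -> list[np.ndarray]:
    """k disjoint test index sets covering all rows, class-balanced per fold."""
    labels = np.asarray(labels)
    if k > len(labels):
        raise ValueError(f"k={k} exceeds the {len(labels)} samples")
    rng = np.random.default_rng(seed)
    folds: list[list[int]] = [[] for _ in range(k)]
    for cls in np.unique(labels):
        idx = rng.permutation(np.flatnonzero(labels == cls))
        for f, chunk in enumerate(np.array_split(idx, k)):
            folds[(f + int(cls)) % k].extend(chunk)  # offset evens out remainders
    return [np.sort(np.array(f, dtype=int)) for f in folds]


def compute_metrics(
    labels: np.ndarray, scores: np.ndarray, threshold: float = 0.5
) -> dict:
    """Acc/Pre/Recall/F1 at the threshold plus ranking AUC and AUPR.

    AUC follows the Mann-Whitney convention (ties earn half credit); AUPR is
    the step-interpolated area under the precision-recall curve.
    """
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present to compute AUC/AUPR")
    pred = (scores >= threshold).astype(int)
    return {
        "accuracy": float(accuracy_score(labels, pred)),
        "precision": float(precision_score(labels, pred, zero_division=0)),
        "recall": float(recall_score(labels, pred, zero_division=0)),
        "f1": float(f1_score(labels, pred, zero_division=0)),
        "auc": float(roc_auc_score(labels, scores)),
        "aupr": float(average_precision_score(labels, scores)),
    }


def build_sample_set(
    net: AssociationNetwork,
    bundle: SimilarityBundle,
    plan: NegativeSamplingPlan,
    n_negatives: int | None = None,
) -> tuple[list[tuple[int, int]], np.ndarray]:
    """All positives plus cluster-sampled negatives; returns (pairs, labels).

    Negatives are clustered in the space of initial pair vectors (FuD row ++
    FuM row) so the selection spreads over the candidate feature space.
    """
    positives = net.edges()
    candidates = candidate_negatives(net)
    n_neg = len(positives) if n_negatives is None else n_negatives
    feats = (
        assemble_initial_features(bundle, candidates)
        if plan.strategy != "random"
        else None
    )
    negatives = sample_negatives(feats, candidates, plan, n_neg)
    pairs = positives + negatives
    labels = np.array([1] * len(positives) + [0] * len(negatives))
    return pairs, labels


def _stage_features(
    net: AssociationNetwork,
    dag: DiseaseOntologyGraph | None,
    cfg: PipelineConfig,
    all_pairs: list[tuple[int, int]],
    mask_pairs: set[tuple[int, int]] | None,
) -> np.ndarray:
    """Run similarity -> GCN -> DAE and assemble final features for ``all_pairs``.

    ``mask_pairs`` (masked mode) zeroes test-fold positives in Y before the
    bundle, GCN and DAE training see anything.  The DAE (unsupervised) trains
    on all sample rows in both modes; in masked mode those rows are computed
    from the masked Y, so held-out labels cannot reach any trained stage.
    """
    work_net = net.with_masked_pairs(mask_pairs) if mask_pairs else net
    bundle = build_similarity_bundle(work_net, dag, cfg.similarity)
    emb = train_gcn(work_net, bundle.FuM, bundle.FuD, cfg.gcn)

    initial_all = assemble_initial_features(bundle, all_pairs)
    dae_cfg = cfg.dae or DAEConfig.for_input_width(
        initial_all.shape[1], seed=cfg.seed + 2
    )
    dae_params = train_dae(initial_all, dae_cfg)
    high = encode(dae_params, initial_all)
    return assemble_final_features(emb, high, all_pairs)


def run_cross_validation(
    net: AssociationNetwork,
    dag: DiseaseOntologyGraph | None,
    config: PipelineConfig | None = None,
    *,
    pairs: list[tuple[int, int]] | None = None,
    labels: np.ndarray | None = None,
    ablations: tuple[str, ...] | None = None,
) -> EvaluationReport | dict[str, EvaluationReport]:
    """Cross-validated evaluation of the full pipeline.

    A balanced sample set (all positives + cluster-sampled negatives) is
    split into ``n_folds`` stratified folds.  Per fold, the feature stages
    are trained per the evaluation mode and the cascade forest is fitted on
    the training folds and scored on the test fold.  Passing ``ablations``
    evaluates several feature blocks (e.g. ("LRF", "HRF", "LHRF")) on the
    *same* trained stages and returns a dict of reports.
    """
    cfg = config or PipelineConfig()
    single = ablations is None
    abls = (cfg.ablation,) if single else ablations

    if pairs is None:
        bundle_full = build_similarity_bundle(net, dag, cfg.similarity)
        pairs, labels = build_sample_set(net, bundle_full, cfg.negatives)
    labels = np.asarray(labels)

    folds = stratified_kfold(labels, cfg.n_folds, cfg.seed)
    pair_set = set(map(tuple, pairs))
    per_abl: dict[str, list[dict]] = {a: [] for a in abls}

    shared_final: np.ndarray | None = None
    if cfg.evaluation_mode == "faithful":
        shared_final = _stage_features(net, dag, cfg, pairs, None)

    for test_idx in folds:
        test_mask = np.zeros(len(pairs), dtype=bool)
        test_mask[test_idx] = True
        train_rows = np.flatnonzero(~test_mask)
        if cfg.evaluation_mode == "masked":
            masked = {
                tuple(pairs[r]) for r in test_idx if labels[r] == 1
            }
            final = _stage_features(net, dag, cfg, pairs, masked)
        else:
            final = shared_final
        h2 = cfg.gcn.h2
        for abl in abls:
            X = ablation_slice(final, abl, h2)
            model = fit_cascade(X[train_rows], labels[train_rows], cfg.cascade)
            scores = predict_proba(model, X[test_idx])[:, 1]
            per_abl[abl].append(
                compute_metrics(labels[test_idx], scores, cfg.threshold)
            )

    def _report(abl: str) -> EvaluationReport:
        fm = per_abl[abl]
        mean = {k: float(np.mean([m[k] for m in fm])) for k in METRIC_NAMES}
        std = {k: float(np.std([m[k] for m in fm])) for k in METRIC_NAMES}
        return EvaluationReport(
            fold_metrics=tuple(fm),
            mean=mean,
            std=std,
            ablation=abl,
            evaluation_mode=cfg.evaluation_mode,
            n_folds=cfg.n_folds,
            config=cfg,
        )

    if single:
        return _report(abls[0])
    return {a: _report(a) for a in abls}


def rank_candidates(
    net: AssociationNetwork,
    dag: DiseaseOntologyGraph | None,
    config: PipelineConfig | None = None,
    disease_id: str = "",
    mode: str = "known",
    top_k: int | None = None,
) -> RankedPredictions:
    """Case-study ranking of microbes for one disease.

    mode="known": train on all known associations and score every microbe
    whose pair with the disease is currently unobserved (training positives
    are excluded from the output).  mode="novel": remove the disease's whole
    association column before every training stage, then score and rank ALL
    microbes for it.  Ties keep microbe input order.
    """
    cfg = config or PipelineConfig()
    if mode not in ("known", "novel"):
        raise ValueError("mode must be 'known' or 'novel'")
    j = net.disease_index(disease_id)

    train_net = net.with_masked_disease(disease_id) if mode == "novel" else net
    bundle = build_similarity_bundle(train_net, dag, cfg.similarity)
    train_pairs, train_labels = build_sample_set(train_net, bundle, cfg.negatives)

    if mode == "known":
        score_is = [i for i in range(net.n_microbes) if net.Y[i, j] == 0]
    else:
        score_is = list(range(net.n_microbes))
    score_pairs = [(i, j) for i in score_is]

    emb = train_gcn(train_net, bundle.FuM, bundle.FuD, cfg.gcn)
    initial_train = assemble_initial_features(bundle, train_pairs)
    dae_cfg = cfg.dae or DAEConfig.for_input_width(
        initial_train.shape[1], seed=cfg.seed + 2
    )
    dae_params = train_dae(initial_train, dae_cfg)

    X_train = assemble_final_features(
        emb, encode(dae_params, initial_train), train_pairs
    )
    initial_score = assemble_initial_features(bundle, score_pairs)
    X_score = assemble_final_features(
        emb, encode(dae_params, initial_score), score_pairs
    )
    h2 = cfg.gcn.h2
    model = fit_cascade(
        ablation_slice(X_train, cfg.ablation, h2), train_labels, cfg.cascade
    )
    scores = predict_proba(model, ablation_slice(X_score, cfg.ablation, h2))[:, 1]

    order = np.argsort(-scores, kind="stable")  # stable: ties keep input order
    ranking = tuple(
        (net.microbe_ids[score_is[o]], float(scores[o]), rank)
        for rank, o in enumerate(order, start=1)
    )
    if top_k is not None:
        ranking = ranking[:top_k]
    return RankedPredictions(disease_id=disease_id, mode=mode, ranking=ranking)
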