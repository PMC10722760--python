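"""Similarity kernels for diseases and microbes, and their fusion.

Four kernels per node set are computed from the association network (and,
for diseases, an ontology DAG):

* diseases — DAG semantic similarity (DS), Gaussian interaction profile
  kernel (GDS), cosine (CDS), sigmoid kernel (SDS);
* microbes — best-match functional similarity derived from DS (FMS), plus
  the same GIP / cosine / sigmoid kernels on microbe profiles
  (GMS, CMS, SMS).

The fused matrices FuD and FuM are the element-wise means of the four
disease and four microbe kernels respectively; their rows serve as the
initial node feature vectors for every downstream stage.

Semantic similarity follows the classic DAG-contribution scheme: each
ancestor k of a disease d contributes FC^depth (maximised over paths), the
disease itself contributes 1, and two diseases are similar in proportion to
the contribution mass of their shared ancestors relative to their total
semantic values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_data import AssociationNetwork, DiseaseOntologyGraph, profiles

__all__ = [
    "SimilarityConfig",
    "SimilarityBundle",
    "semantic_contributions",
    "semantic_value",
    "disease_semantic_similarity",
    "gip_similarity",
    "cosine_similarity",
    "sigmoid_kernel_similarity",
    "microbe_functional_similarity",
    "fuse",
    "build_similarity_bundle",
]


@dataclass(frozen=True)
class SimilarityConfig:
    """Tunable parameters of the similarity stage.

    Parameters
    ----------
    FC : float
        Semantic decay factor per DAG edge, in (0, 1).  Default 0.5.
    alpha_d, alpha_m : float
        GIP bandwidth numerators for diseases / microbes.  Default 1.
    sigmoid_norm_d, sigmoid_norm_m : float or None
        Scalars dividing the profile dot product inside tanh.  ``None``
        (default) means "count of the own node set": n_diseases for the
        disease kernel, n_microbes for the microbe kernel.
    """

    FC: float = 0.5
    alpha_d: float = 1.0
    alpha_m: float = 1.0
    sigmoid_norm_d: float | None = None
    sigmoid_norm_m: float | None = None

    def __post_init__(self) -> None:
        if not 0 < self.FC < 1:
            raise ValueError("FC must lie in (0, 1)")
        if self.alpha_d <= 0 or self.alpha_m <= 0:
            raise ValueError("GIP alpha parameters must be positive")
        for norm in (self.sigmoid_norm_d, self.sigmoid_norm_m):
            if norm is not None and norm <= 0:
                raise ValueError("sigmoid norms must be positive")


@dataclass(frozen=True)
class SimilarityBundle:
    """The eight kernel matrices, the two fused matrices, and realized GIP bandwidths."""

    DS: np.ndarray
    GDS: np.ndarray
    CDS: np.ndarray
    SDS: np.ndarray
    FMS: np.ndarray
    GMS: np.ndarray
    CMS: np.ndarray
    SMS: np.ndarray
    FuD: np.ndarray
    FuM: np.ndarray
    gamma_d: float
    gamma_m: float


def semantic_contributions(
    dag: DiseaseOntologyGraph, d: str, FC: float = 0.5
) -> dict[str, float]:
    """Semantic contribution SC_d(k) of every term k in T(d) to disease d.

    SC_d(d) = 1; for an ancestor k, SC_d(k) = max over children k' of k that
    lie within T(d) of FC * SC_d(k').  Unrolled, this equals the maximum of
    FC^L over all directed paths of length L from d up to k (with FC < 1,
    the shortest path wins).
    """
    if d not in dag:
        raise KeyError(f"unknown term {d!r}")
    T = dag.ancestors_and_self(d)
    sc: dict[str, float] = {d: 1.0}

    # Terms of T(d) in an order where every child inside T precedes its
    # parents, so each SC value is final when computed.
    remaining = set(T) - {d}
    while remaining:
        progressed = False
        for k in list(remaining):
            children_in_T = {c for c in dag.children(k) if c in T}
            if children_in_T <= sc.keys():
                sc[k] = max(FC * sc[c] for c in children_in_T)
                remaining.discard(k)
                progressed = True
        if not progressed:  # pragma: no cover - DAG guarantees progress
            raise RuntimeError("cycle encountered in ancestor closure")
    return sc


def semantic_value(contributions: dict[str, float]) -> float:
    """Final semantic value of a disease: sum of all its term contributions."""
    if not contributions:
        raise ValueError("empty contribution map")
    return float(sum(contributions.values()))


def disease_semantic_similarity(
    dag: DiseaseOntologyGraph,
    diseases: list[str] | tuple[str, ...],
    cfg: SimilarityConfig | None = None,
) -> np.ndarray:
    """Pairwise DAG semantic similarity matrix DS over an ordered disease list.

    DS(i, j) = sum over shared terms k of (SC_i(k) + SC_j(k)), divided by
    SemV(i) + SemV(j).  Diseases absent from the DAG get 0 off-diagonal and
    1 on the diagonal.
    """
    cfg = cfg or SimilarityConfig()
    n = len(diseases)
    sc_maps: list[dict[str, float] | None] = []
    for d in diseases:
        sc_maps.append(semantic_contributions(dag, d, cfg.FC) if d in dag else None)
    sem_vals = [semantic_value(m) if m is not None else None for m in sc_maps]

    DS = np.eye(n)
    for i in range(n):
        mi = sc_maps[i]
        if mi is None:
            continue
        for j in range(i + 1, n):
            mj = sc_maps[j]
            if mj is None:
                continue
            shared = mi.keys() & mj.keys()
            if not shared:
                continue
            num = sum(mi[k] + mj[k] for k in shared)
            DS[i, j] = DS[j, i] = num / (sem_vals[i] + sem_vals[j])
    return DS


def gip_similarity(P: np.ndarray, alpha: float = 1.0) -> tuple[np.ndarray, float]:
    """Gaussian interaction profile kernel over binary profile rows.

    The bandwidth gamma = alpha / mean squared profile norm; the kernel is
    K(i, j) = exp(-gamma * ||P_i - P_j||^2).  Returns (K, gamma).

    Raises
    ------
    ValueError
        If every profile is zero (the bandwidth denominator vanishes).
    """
    P = np.asarray(P, dtype=float)
    if P.ndim != 2 or P.shape[0] < 1:
        raise ValueError("P must be a non-empty 2-D profile matrix")
    sq_norms = (P * P).sum(axis=1)
    mean_sq = sq_norms.mean()
    if mean_sq == 0:
        raise ValueError(
            "GIP bandwidth is degenerate: all profiles are zero "
            "(mean squared norm is 0, so gamma would divide by zero)"
        )
    gamma = alpha / mean_sq
    # ||p_i - p_j||^2 = |p_i|^2 + |p_j|^2 - 2 p_i.p_j
    G = P @ P.T
    d2 = sq_norms[:, None] + sq_norms[None, :] - 2 * G
    np.maximum(d2, 0, out=d2)
    K = np.exp(-gamma * d2)
    K = (K + K.T) / 2
    np.fill_diagonal(K, 1.0)
    return K, float(gamma)


def cosine_similarity(P: np.ndarray) -> np.ndarray:
    """Cosine kernel over profile rows; zero profiles give 0 everywhere (even diagonal)."""
    P = np.asarray(P, dtype=float)
    norms = np.linalg.norm(P, axis=1)
    G = P @ P.T
    denom = norms[:, None] * norms[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        K = np.where(denom > 0, G / np.where(denom > 0, denom, 1.0), 0.0)
    return (K + K.T) / 2


def sigmoid_kernel_similarity(P: np.ndarray, norm: float) -> np.ndarray:
    """Sigmoid (tanh) kernel: K(i, j) = tanh(P_i . P_j / norm)."""
    if norm <= 0:
        raise ValueError("sigmoid kernel norm must be positive")
    P = np.asarray(P, dtype=float)
    K = np.tanh((P @ P.T) / norm)
    return (K + K.T) / 2


def microbe_functional_similarity(net: AssociationNetwork, DS: np.ndarray) -> np.ndarray:
    """Best-match functional similarity between microbes via their disease sets.

    For microbes i, j with disease sets D_i (size p) and D_j (size q),
    each disease d in D_i is matched to its most semantically similar member
    of D_j (and vice versa); FMS(i, j) is the sum of best matches in both
    directions divided by p + q.  Microbes without any disease get 0
    off-diagonal; the diagonal is 1.
    """
    DS = np.asarray(DS, dtype=float)
    if DS.shape != (net.n_diseases, net.n_diseases):
        raise ValueError("DS dimension must equal n_diseases")
    Y = net.Y.astype(float)
    p = Y.sum(axis=1)  # diseases per microbe

    # best[d, j] = max over d' in D_j of DS[d, d']  (0 when D_j empty)
    n_d, n_m = net.n_diseases, net.n_microbes
    best = np.zeros((n_d, n_m))
    for j in range(n_m):
        dj = np.flatnonzero(Y[j])
        if dj.size:
            best[:, j] = DS[:, dj].max(axis=1)

    # S[i, j] = sum over d in D_i of best[d, j]
    S = Y @ best
    denom = p[:, None] + p[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        FMS = np.where(denom > 0, (S + S.T) / np.where(denom > 0, denom, 1.0), 0.0)
    FMS[(p == 0)[:, None] | (p == 0)[None, :]] = 0.0
    np.fill_diagonal(FMS, 1.0)
    return FMS


def fuse(matrices: list[np.ndarray]) -> np.ndarray:
    """Element-wise arithmetic mean of exactly four equally-shaped kernels."""
    if len(matrices) != 4:
        raise ValueError(f"fusion takes exactly 4 matrices, got {len(matrices)}")
    shapes = {np.asarray(m).shape for m in matrices}
    if len(shapes) != 1:
        raise ValueError(f"shape mismatch across matrices: {sorted(shapes)}")
    return sum(np.asarray(m, dtype=float) for m in matrices) / 4.0


def build_similarity_bundle(
    net: AssociationNetwork,
    dag: DiseaseOntologyGraph | None = None,
    cfg: SimilarityConfig | None = None,
    mask_pairs: set[tuple[int, int]] | None = None,
) -> SimilarityBundle:
    """Compute all eight kernels and the fused matrices FuD, FuM.

    If ``mask_pairs`` is given, those Y entries are zeroed before any
    profile-based kernel or FMS is computed (leakage-safe evaluation mode);
    the DAG semantic kernel does not depend on Y and is unaffected.
    """
    cfg = cfg or SimilarityConfig()
    if mask_pairs:
        net = net.with_masked_pairs(mask_pairs)
    if dag is None:
        dag = DiseaseOntologyGraph(frozenset(), {})

    DS = disease_semantic_similarity(dag, list(net.disease_ids), cfg)

    P_d = profiles(net, "disease")
    P_m = profiles(net, "microbe")
    GDS, gamma_d = gip_similarity(P_d, cfg.alpha_d)
    GMS, gamma_m = gip_similarity(P_m, cfg.alpha_m)
    CDS = cosine_similarity(P_d)
    CMS = cosine_similarity(P_m)
    norm_d = cfg.sigmoid_norm_d if cfg.sigmoid_norm_d is not None else net.n_diseases
    norm_m = cfg.sigmoid_norm_m if cfg.sigmoid_norm_m is not None else net.n_microbes
    SDS = sigmoid_kernel_similarity(P_d, norm_d)
    SMS = sigmoid_kernel_similarity(P_m, norm_m)
    FMS = microbe_functional_similarity(net, DS)

    FuD = fuse([DS, GDS, CDS, SDS])
    FuM = fuse([FMS, GMS, CMS, SMS])
    return SimilarityBundle(
        DS=DS, GDS=GDS, CDS=CDS, SDS=SDS,
        FMS=FMS, GMS=GMS, CMS=CMS, SMS=SMS,
        FuD=FuD, FuM=FuM, gamma_d=gamma_d, gamma_m=gamma_m,
    )
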