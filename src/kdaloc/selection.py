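"""Gaussian kernel scale selection via edge/internal reconstruction errors.

The scale parameter ``s`` of the Gaussian kernel controls how far the KDA
discriminant subspace generalizes.  Grid search picks ``s`` by running the
full downstream classifier for every candidate; the selector implemented
here instead exploits a novelty-detection idea: for a well-chosen scale,
samples near a class boundary (edge samples) should have clearly larger
kernel reconstruction errors than samples deep inside the class (internal
samples), while the internal errors stay tightly concentrated.

Edge and internal samples are drawn from the largest class.  With ``c`` the
class centroid, ``m`` the median distance to ``c`` and ``eps`` the mean
distance to the ``u``-th nearest neighbor (a density scale), a sample is

- *edge* if its distance to ``c`` exceeds ``m`` AND its eps-neighborhood
  (over the whole dataset) contains samples of other classes;
- *internal* if its distance to ``c`` is below ``m`` AND its
  eps-neighborhood is pure.

Both rules are strict, so samples may end up in neither set.  The selected
scale maximizes

    f(s) = (max RE(edge) - max RE(internal)) / std(RE(internal))

over the candidate set, where RE is the kernel reconstruction error of a
KDA model fitted at scale ``s`` and std uses the n-1 denominator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from . import evaluation, kda
from .dataset import LabeledDataset

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_CANDIDATES",
    "ClassGeometry",
    "SampleSplit",
    "SelectionResult",
    "neighborhood_radius",
    "select_edge_internal",
    "objective",
    "select_scale",
    "grid_search",
]

DEFAULT_CANDIDATES = (0.1, 0.2, 0.3, 0.4, 1.0, 2.0, 3.0, 4.0)


@dataclass
class ClassGeometry:
    """Geometric summaries of one class used by the edge/internal rules."""

    centroid: np.ndarray
    median_dist: float
    radius: float  # eps, the mean u-th-nearest-neighbor distance
    u: int
    per_sample_dist: np.ndarray  # distance of each class member to the centroid


@dataclass
class SampleSplit:
    """Disjoint internal and edge index sets selected from one class.

    Indices refer to rows of the full dataset.
    """

    internal: np.ndarray
    edge: np.ndarray
    class_index: int
    geometry: ClassGeometry | None = None


@dataclass
class SelectionResult:
    """Outcome of a scale search over a candidate set."""

    candidates: list[float]
    objective_values: list[float]  # f(s) per candidate; NaN where undefined
    best: float
    diagnostics: dict = field(default_factory=dict)


def neighborhood_radius(X: np.ndarray, class_members: np.ndarray, u: int) -> float:
    """Mean distance from each class member to its u-th nearest neighbor.

    Neighbors are taken over the full collection ``X`` with the sample
    itself excluded.  The result is the neighborhood radius ``eps`` used by
    the edge/internal rules.
    """
    X = np.asarray(X, dtype=float)
    class_members = np.asarray(class_members)
    n_pool = X.shape[0] - 1  # self excluded
    if not 0 < u <= n_pool:
        raise ValueError(f"u={u} out of range: need 0 < u <= {n_pool} (pool size minus self)")
    D = cdist(X[class_members], X)
    # drop the zero self-distance, then the u-th nearest is order statistic u-1
    part = np.sort(D, axis=1)[:, 1:]
    return float(np.mean(part[:, u - 1]))


def select_edge_internal(data: LabeledDataset, class_index: int | None = None, u: int = 8) -> SampleSplit:
    """Split one class (default: the largest) into internal and edge samples.

    Applies the strict median-distance and neighborhood-purity rules
    described in the module docstring; samples satisfying neither rule are
    left unassigned.  Because the rules use distance to the class centroid
    rather than local tangent-plane geometry, a class lying on a spherical
    shell does not collapse to all-edge.

    Raises
    ------
    ValueError
        If either set comes out empty (the selection objective is undefined
        without both); try a different ``u``.
    """
    if class_index is None:
        class_index = data.largest_class()
    members = data.class_indices(class_index)
    if members.size < 2:
        raise ValueError(f"class {class_index} has fewer than 2 samples")

    eps = neighborhood_radius(data.X, members, u)
    pts = data.X[members]
    centroid = pts.mean(axis=0)
    dist = np.linalg.norm(pts - centroid, axis=1)
    m = float(np.median(dist))

    # eps-neighborhood purity over the FULL dataset (self included; it is
    # same-class so it never flips either rule)
    D_all = cdist(pts, data.X)
    other = data.y != class_index
    has_other = (D_all[:, other] <= eps).any(axis=1)

    edge_mask = (dist > m) & has_other
    internal_mask = (dist < m) & ~has_other
    split = SampleSplit(
        internal=members[internal_mask],
        edge=members[edge_mask],
        class_index=int(class_index),
        geometry=ClassGeometry(centroid, m, eps, u, dist),
    )
    if split.internal.size == 0 or split.edge.size == 0:
        raise ValueError(
            f"degenerate split for class {class_index} (|internal|={split.internal.size}, "
            f"|edge|={split.edge.size}); try a different neighbor count u"
        )
    return split


def objective(re_edge: np.ndarray, re_internal: np.ndarray) -> float:
    """Scale-selection objective f = (max|RE_edge| - max|RE_int|) / std(RE_int).

    Uses the infinity norm (maximum absolute component) and the sample
    standard deviation (n-1 denominator).  Returns NaN when the internal
    errors have zero spread (the objective is undefined there); such
    candidates are excluded from the argmax with a warning.
    """
    re_edge = np.asarray(re_edge, dtype=float)
    re_internal = np.asarray(re_internal, dtype=float)
    if re_edge.size == 0 or re_internal.size == 0:
        raise ValueError("both edge and internal reconstruction errors must be nonempty")
    if re_internal.size < 2:
        raise ValueError("need at least 2 internal samples for the standard deviation")
    sd = float(np.std(re_internal, ddof=1))
    if sd == 0.0:
        logger.warning("zero spread of internal reconstruction errors; objective undefined")
        return float("nan")
    return float((np.max(np.abs(re_edge)) - np.max(np.abs(re_internal))) / sd)


def select_scale(
    data: LabeledDataset,
    candidates=DEFAULT_CANDIDATES,
    d: int = 1,
    u: int = 8,
    class_index: int | None = None,
) -> SelectionResult:
    """Choose the Gaussian scale by maximizing the reconstruction-error objective.

    Selects edge/internal samples once from the largest class, then for
    each candidate scale fits KDA on the full labeled dataset, evaluates
    the reconstruction errors of the two sets and scores f(s).  No
    classifier is run.  Ties (and the argmax) resolve to the smallest
    scale.
    """
    candidates = [float(s) for s in candidates]
    if not candidates:
        raise ValueError("candidate set is empty")
    split = select_edge_internal(data, class_index=class_index, u=u)

    values: list[float] = []
    diags = {"per_candidate": [], "n_kda_fits": 0, "n_classifier_passes": 0}
    for s in candidates:
        model = kda.fit_kda(data, s, d)
        diags["n_kda_fits"] += 1
        re_edge = model.reconstruction_error(data.X[split.edge])
        re_int = model.reconstruction_error(data.X[split.internal])
        f = objective(re_edge, re_int)
        values.append(f)
        diags["per_candidate"].append(
            {
                "scale": s,
                "objective": f,
                "max_re_edge": float(np.max(re_edge)),
                "max_re_internal": float(np.max(re_int)),
                "std_re_internal": float(np.std(re_int, ddof=1)),
            }
        )
        logger.info("scale %-6g f(s)=%g", s, f)

    arr = np.asarray(values)
    if np.all(np.isnan(arr)):
        raise ValueError("objective undefined for every candidate scale")
    finite = np.where(np.isnan(arr), -np.inf, arr)
    best_val = finite.max()
    # ties (within float equality) resolve to the smallest candidate scale
    tied = [candidates[i] for i in np.flatnonzero(finite == best_val)]
    best = min(tied)
    if len(tied) > 1:
        logger.info("objective tie among %s; choosing smallest scale %g", tied, best)
    diags["split"] = {
        "class_index": split.class_index,
        "n_internal": int(split.internal.size),
        "n_edge": int(split.edge.size),
        "u": u,
    }
    return SelectionResult(candidates, values, best, diags)


def grid_search(
    data: LabeledDataset,
    candidates=DEFAULT_CANDIDATES,
    d: int = 1,
    knn_k: int = 20,
) -> SelectionResult:
    """Baseline scale search: pick the candidate with the best jackknife
    KNN accuracy in the KDA-reduced space.

    For each candidate, KDA is fitted once on the full dataset, all samples
    are projected, and leave-one-out KNN accuracy is measured on the
    projections.  Ties resolve to the smallest scale.
    """
    candidates = [float(s) for s in candidates]
    if not candidates:
        raise ValueError("candidate set is empty")
    accuracies: list[float] = []
    diags = {"per_candidate": [], "n_kda_fits": 0, "n_classifier_passes": 0}
    for s in candidates:
        model = kda.fit_kda(data, s, d)
        diags["n_kda_fits"] += 1
        coords = model.project(data.X)
        counts = evaluation.loo_knn_counts(coords, data.y, knn_k)
        diags["n_classifier_passes"] += 1
        q = evaluation.metrics(counts).q
        accuracies.append(q)
        diags["per_candidate"].append({"scale": s, "accuracy": q})
        logger.info("scale %-6g jackknife accuracy %.4f", s, q)

    arr = np.asarray(accuracies)
    best_val = arr.max()
    best = min(candidates[i] for i in np.flatnonzero(arr == best_val))
    return SelectionResult(candidates, accuracies, best, diags)
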