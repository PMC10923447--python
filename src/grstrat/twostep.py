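"""Two-step style clustering with log-likelihood distance and BIC model selection.

Patients are clustered on a small set of continuous features (here typically
GRS, %predicted FEV1 and age of onset).  The procedure:

1. z-standardize the features,
2. agglomerate from singletons under the log-likelihood merge distance,
3. pick the number of clusters with a two-stage BIC / distance-ratio
   heuristic,
4. cut the merge tree at the chosen count.

The cluster "tightness" of cluster v is

    xi_v = -N_v * sum_k 0.5 * log(s2_k + s2_vk)

with ``s2_vk`` the within-cluster biased variance of feature k and ``s2_k``
the whole-dataset biased variance (a regulariser that keeps singletons
finite), and the merge distance is d(j, s) = xi_j + xi_s - xi_{j u s}.
BIC(J) = -2 * sum_j xi_j + 2 * p * J * log(n).

The streaming pre-cluster tree of the original two-step procedure is
deliberately omitted at this scale; pure agglomeration from singletons is
used, which removes input-order sensitivity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "FeatureMatrix", "ClusterModel", "standardize", "cluster_tightness",
    "loglik_distance", "agglomerate", "choose_k", "fit",
]

#: constants of the two-stage automatic cluster-count heuristic
BIC_RATIO_MIN = 0.04
DISTANCE_RATIO_MIN = 1.15


@dataclass
class FeatureMatrix:
    """Complete-case n x p feature matrix with optional standardization state."""

    sample_ids: np.ndarray
    X: np.ndarray
    feature_names: tuple[str, ...]
    standardized: bool = False
    means: np.ndarray | None = None
    sds: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2 or self.X.shape[0] != len(self.sample_ids):
            raise ValueError("X must be n x p with one row per sample id")
        if len(self.feature_names) != self.X.shape[1]:
            raise ValueError("feature_names length must match X columns")
        if np.isnan(self.X).any():
            raise ValueError("feature matrix contains missing values; "
                             "apply listwise deletion first")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    def inverse_transform(self, Z: np.ndarray) -> np.ndarray:
        """Map standardized values back to the original scale."""
        if self.means is None or self.sds is None:
            raise ValueError("no standardization transform stored")
        return Z * self.sds + self.means


def standardize(features: FeatureMatrix) -> FeatureMatrix:
    """Center to mean 0 and scale to (sample) sd 1, storing the transform."""
    if features.n < 2:
        raise ValueError("need at least 2 rows to standardize")
    means = features.X.mean(axis=0)
    sds = features.X.std(axis=0, ddof=1)
    if (sds <= 0).any():
        bad = [features.feature_names[i] for i in np.flatnonzero(sds <= 0)]
        raise ValueError(f"zero-variance feature(s): {bad}")
    return FeatureMatrix(
        sample_ids=features.sample_ids.copy(),
        X=(features.X - means) / sds,
        feature_names=features.feature_names,
        standardized=True,
        means=means,
        sds=sds,
    )


# ---------------------------------------------------------------------------
# tightness / distance primitives (reference, non-vectorized forms)


def _base_var(X: np.ndarray) -> np.ndarray:
    v = X.var(axis=0)  # biased
    if (v <= 0).any():
        raise ValueError("whole-dataset variance must be positive per feature")
    return v


def cluster_tightness(X: np.ndarray, members: Sequence[int],
                      base_var: np.ndarray | None = None) -> float:
    """xi of one cluster (see module docstring)."""
    members = np.asarray(list(members), dtype=int)
    if members.size == 0:
        raise ValueError("cluster must be nonempty")
    if base_var is None:
        base_var = _base_var(np.asarray(X, dtype=float))
    sub = np.asarray(X, dtype=float)[members]
    within = sub.var(axis=0) if members.size > 1 else np.zeros(sub.shape[1])
    return float(-members.size * 0.5 * np.log(base_var + within).sum())


def loglik_distance(X: np.ndarray, cluster_j: Sequence[int], cluster_s: Sequence[int],
                    base_var: np.ndarray | None = None) -> float:
    """Merge cost d(j, s) = xi_j + xi_s - xi_{j u s}; symmetric, >= 0."""
    a, b = set(cluster_j), set(cluster_s)
    if a & b:
        raise ValueError("clusters overlap")
    if base_var is None:
        base_var = _base_var(np.asarray(X, dtype=float))
    return (
        cluster_tightness(X, cluster_j, base_var)
        + cluster_tightness(X, cluster_s, base_var)
        - cluster_tightness(X, sorted(a | b), base_var)
    )


# ---------------------------------------------------------------------------
# agglomeration


def _pair_distances(count_i, sum_i, sq_i, xi_i, counts, sums, sqs, xis, base_var):
    """Merge cost of cluster i against an array of clusters, from sufficient stats."""
    Nm = count_i + counts
    sm = sum_i + sums
    qm = sq_i + sqs
    mean = sm / Nm[:, None]
    var = np.maximum(qm / Nm[:, None] - mean ** 2, 0.0)
    xim = -Nm * 0.5 * np.log(base_var + var).sum(axis=1)
    return xi_i + xis - xim


def _agglomerate_core(X: np.ndarray):
    """Full merge tree from singletons.

    Returns ``(merges, sum_xi_at)`` where ``merges`` is the ordered list of
    ``(i, j, d)`` with i < j (cluster ids are smallest member indices) and
    ``sum_xi_at[J]`` is the total xi of the J-cluster solution.
    """
    n, p = X.shape
    base_var = _base_var(X)
    counts = np.ones(n)
    sums = X.copy()
    sqs = X ** 2
    xis = np.full(n, -0.5 * np.log(base_var).sum())

    D = np.full((n, n), np.inf)
    for i in range(n - 1):
        js = np.arange(i + 1, n)
        D[i, i + 1:] = _pair_distances(
            counts[i], sums[i], sqs[i], xis[i],
            counts[js], sums[js], sqs[js], xis[js], base_var)

    active = np.ones(n, dtype=bool)
    merges: list[tuple[int, int, float]] = []
    total_xi = float(xis.sum())
    sum_xi_at = {n: total_xi}
    m = n
    while m > 1:
        flat = int(np.argmin(D))
        i, j = divmod(flat, n)  # first occurrence => lexicographic tie-break
        d = float(D[i, j])
        merges.append((i, j, d))
        counts[i] += counts[j]
        sums[i] += sums[j]
        sqs[i] += sqs[j]
        xis[i] = xis[i] + xis[j] - d
        active[j] = False
        D[j, :] = np.inf
        D[:, j] = np.inf
        ks = np.flatnonzero(active)
        ks = ks[ks != i]
        if ks.size:
            dnew = _pair_distances(
                counts[i], sums[i], sqs[i], xis[i],
                counts[ks], sums[ks], sqs[ks], xis[ks], base_var)
            lo = np.minimum(ks, i)
            hi = np.maximum(ks, i)
            D[lo, hi] = dnew
        total_xi -= d
        m -= 1
        sum_xi_at[m] = total_xi
    return merges, sum_xi_at


@dataclass
class AgglomerationResult:
    """Merge tree plus the traces used for automatic cluster-count selection."""

    n: int
    n_features: int
    merges: list[tuple[int, int, float]]
    bic_trace: dict[int, float]
    #: merge_distances[J] = cost of merging the J-cluster solution into J-1
    merge_distances: dict[int, float]
    sum_xi_at: dict[int, float]

    def cut(self, k: int) -> np.ndarray:
        """Labels 1..k of the k-cluster solution (1-indexed, order of first
        appearance in the input)."""
        if not 1 <= k <= self.n:
            raise ValueError(f"k must lie in [1, {self.n}]")
        labels = np.arange(self.n)
        for i, j, _ in self.merges[: self.n - k]:
            labels[labels == j] = i
        out = np.zeros(self.n, dtype=int)
        seen: dict[int, int] = {}
        for idx, lab in enumerate(labels):
            if lab not in seen:
                seen[lab] = len(seen) + 1
            out[idx] = seen[lab]
        return out


def agglomerate(features: FeatureMatrix, J_max: int = 15) -> AgglomerationResult:
    """Agglomerate standardized features and record BIC / distance traces.

    ``bic_trace[J]`` covers J = 1..J_max; ``merge_distances[J]`` covers
    J = 2..J_max+1 (where defined), with d(J) the cost of the merge reducing
    the J-cluster solution to J-1 clusters.
    """
    if features.n == 0:
        raise ValueError("empty feature matrix")
    if J_max < 1:
        raise ValueError("J_max must be >= 1")
    X = features.X
    n, p = X.shape
    merges, sum_xi_at = _agglomerate_core(X)
    J_hi = min(J_max, n)
    bic = {J: -2.0 * sum_xi_at[J] + 2.0 * p * J * np.log(n) for J in range(1, J_hi + 1)}
    dists = {}
    for t, (_, _, d) in enumerate(merges):
        J_before = n - t  # this merge reduced J_before -> J_before - 1 clusters
        if J_before <= J_max + 1:
            dists[J_before] = d
    return AgglomerationResult(n=n, n_features=p, merges=merges,
                               bic_trace=bic, merge_distances=dists,
                               sum_xi_at={J: v for J, v in sum_xi_at.items() if J <= J_hi})


# ---------------------------------------------------------------------------
# automatic cluster count


def choose_k(bic_trace: dict[int, float], merge_distances: dict[int, float],
             J_max: int | None = None) -> tuple[int, dict]:
    """Two-stage automatic cluster count.

    Stage 1 (coarse, BIC changes): if BIC(2) >= BIC(1) return 1; otherwise
    J_c is the largest J whose entering improvement ratio
    [BIC(J-1) - BIC(J)] / [BIC(1) - BIC(2)] exceeds 0.04.

    Stage 2 (fine, distance-change ratios): among 2 <= J <= J_c compute
    R(J) = d(J) / d(J+1); take the two largest ratios and pick the J of the
    largest if it exceeds the runner-up by more than a factor of 1.15, else
    the larger of the two Js.
    """
    Js = sorted(bic_trace)
    if J_max is None:
        J_max = Js[-1]
    report: dict = {"J_max": J_max}
    if len(Js) < 2 or 2 not in bic_trace:
        report["rule"] = "trivial trace"
        return 1, report
    denom = bic_trace[1] - bic_trace[2]
    if denom <= 0:
        if all(np.isclose(bic_trace[J], bic_trace[Js[0]]) for J in Js):
            warnings.warn("degenerate BIC trace (all equal); returning k=1")
        report["rule"] = "BIC(2) >= BIC(1)"
        return 1, report

    ratios = {}
    for J in range(2, J_max + 1):
        if J in bic_trace and (J - 1) in bic_trace:
            ratios[J] = (bic_trace[J - 1] - bic_trace[J]) / denom
    J_coarse = max((J for J, r in ratios.items() if r > BIC_RATIO_MIN), default=1)
    report["bic_change_ratios"] = ratios
    report["J_coarse"] = J_coarse
    if J_coarse < 2:
        report["rule"] = "coarse stage found no improvement beyond 1"
        return 1, report

    R = {}
    for J in range(2, J_coarse + 1):
        dJ = merge_distances.get(J)
        dJ1 = merge_distances.get(J + 1)
        if dJ is None or dJ1 is None:
            continue
        R[J] = float("inf") if dJ1 <= 0 else dJ / dJ1
    report["distance_change_ratios"] = R
    if not R:
        report["rule"] = "no distance ratios available"
        return J_coarse, report
    ranked = sorted(R.items(), key=lambda kv: (-kv[1], kv[0]))
    if len(ranked) == 1:
        report["rule"] = "single fine-stage candidate"
        return ranked[0][0], report
    (J1, r1), (J2, r2) = ranked[0], ranked[1]
    if r2 == 0 or (np.isinf(r1) and not np.isinf(r2)) or r1 / r2 > DISTANCE_RATIO_MIN:
        report["rule"] = f"dominant distance ratio at J={J1}"
        return J1, report
    report["rule"] = f"ambiguous ratios; larger of J={J1}, J={J2}"
    return max(J1, J2), report


# ---------------------------------------------------------------------------
# fitted model


@dataclass
class ClusterModel:
    """Fitted clustering: assignments, traces and per-cluster summaries."""

    k: int
    assignments: np.ndarray
    sample_ids: np.ndarray
    feature_names: tuple[str, ...]
    cluster_sizes: np.ndarray
    cluster_means: np.ndarray   # k x p, original scale
    cluster_vars: np.ndarray    # k x p, original scale (ddof=1 where n > 1)
    bic_trace: dict[int, float]
    merge_distances: dict[int, float]
    selection: dict
    agglomeration: AgglomerationResult = field(repr=False)

    @property
    def n(self) -> int:
        return len(self.assignments)

    def members(self, label: int) -> np.ndarray:
        return np.flatnonzero(self.assignments == label)

    def summary_frame(self) -> "pd.DataFrame":  # noqa: F821 - lazy import
        import pandas as pd

        rows = []
        for c in range(1, self.k + 1):
            row = {"cluster": c, "n": int(self.cluster_sizes[c - 1])}
            for f, name in enumerate(self.feature_names):
                row[f"{name}_mean"] = self.cluster_means[c - 1, f]
                row[f"{name}_sd"] = float(np.sqrt(self.cluster_vars[c - 1, f]))
            rows.append(row)
        return pd.DataFrame(rows)


def fit(features: FeatureMatrix, J_max: int = 15) -> ClusterModel:
    """Standardize, agglomerate, choose k and cut the merge tree."""
    n = features.n
    if n < 2:
        raise ValueError("need at least 2 samples to cluster")
    if J_max > n:
        warnings.warn(f"J_max={J_max} exceeds n={n}; lowering to n")
        J_max = n
    std = features if features.standardized else standardize(features)
    agg = agglomerate(std, J_max=J_max)
    k, report = choose_k(agg.bic_trace, agg.merge_distances, J_max=J_max)
    labels = agg.cut(k)

    p = len(features.feature_names)
    sizes = np.zeros(k, dtype=int)
    means = np.zeros((k, p))
    variances = np.zeros((k, p))
    for c in range(1, k + 1):
        idx = np.flatnonzero(labels == c)
        sizes[c - 1] = idx.size
        sub = features.X[idx]
        means[c - 1] = sub.mean(axis=0)
        variances[c - 1] = sub.var(axis=0, ddof=1) if idx.size > 1 else 0.0
    return ClusterModel(
        k=k, assignments=labels, sample_ids=features.sample_ids.copy(),
        feature_names=features.feature_names, cluster_sizes=sizes,
        cluster_means=means, cluster_vars=variances,
        bic_trace=agg.bic_trace, merge_distances=agg.merge_distances,
        selection=report, agglomeration=agg,
    )
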