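"""Cell-type-enriched miRNA calling per condition.

Two routes are combined for each experimental condition. The unbiased
route clusters within-condition standardized expression profiles with
soft (fuzzy) c-means and keeps clusters whose centroid is elevated in a
single cell type. The supervised route thresholds the mean cell-type
z-score of each miRNA. A miRNA is called enriched in a cell type only
when both routes agree; a miRNA qualifying for two or more cell types is
Not Cell Specific. The persistence of the single-cell call across the
four conditions (sham, UUO-2, UUO-7, R-UUO) defines the consistency
tier: low (1 condition), moderate (2-3), high (all 4), or switching
(different cell types in different conditions).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import cdist
from sklearn.cluster import kmeans_plusplus

from .io_formats import CELL_TYPES, CONDITIONS, SampleSheet
from .preprocessing import NormalizedMatrix

NOT_CELL_SPECIFIC = "NotCellSpecific"
UNASSIGNED = "None"
#: Assignment states a miRNA can hold within one condition.
ASSIGN_STATES = CELL_TYPES + (NOT_CELL_SPECIFIC, UNASSIGNED)
TIERS = ("low", "moderate", "high", "switching", "none")


@dataclass
class ZscoreMatrix:
    """Row-standardized log expression within one condition's samples."""
    mirna_ids: list
    sample_ids: list
    z: np.ndarray
    condition: str
    constant_rows: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.z, index=self.mirna_ids, columns=self.sample_ids)


@dataclass
class FuzzyClusterModel:
    centroids: np.ndarray        # c x n_samples
    membership: np.ndarray       # n_mirna x c
    fuzzifier_m: float
    n_clusters_c: int
    objective_trace: list
    seed: int
    n_iter: int = 0
    converged: bool = False


def zscore_by_condition(log_expr: NormalizedMatrix, samples: SampleSheet,
                        condition: str, ddof: int = 1) -> ZscoreMatrix:
    """Standardize each miRNA over one condition's samples (all cell
    types pooled): z = (x - mean) / SD with the n-1 SD convention.

    Constant rows become all-zero and are flagged.
    """
    ids = samples.samples_for(condition=condition)
    if not ids:
        raise ValueError(f"condition {condition!r} absent from sample sheet")
    if len(ids) < 2:
        raise ValueError(f"condition {condition!r} has fewer than 2 samples")
    df = log_expr.to_frame()[ids]
    vals = df.to_numpy(float)
    mu = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, ddof=ddof, keepdims=True)
    constant = sd[:, 0] < 1e-12
    sd[constant] = 1.0
    z = (vals - mu) / sd
    z[constant] = 0.0
    return ZscoreMatrix(list(df.index), ids, z, condition,
                        constant_rows=[m for m, c in zip(df.index, constant) if c])


def mean_celltype_zscores(z: ZscoreMatrix, samples: SampleSheet,
                          cell_types=CELL_TYPES) -> pd.DataFrame:
    """Arithmetic mean z over each cell type's samples (miRNA x cell type)."""
    zdf = z.to_frame()
    out = {}
    for ct in cell_types:
        ids = [s for s in samples.samples_for(condition=z.condition, cell_type=ct)
               if s in zdf.columns]
        if not ids:
            raise ValueError(f"cell type {ct!r} has no samples in condition "
                             f"{z.condition!r}")
        out[ct] = zdf[ids].mean(axis=1)
    return pd.DataFrame(out)


def zscore_enriched(mean_z: pd.DataFrame, threshold: float = 1.15) -> dict:
    """Per cell type, the miRNAs with mean z strictly above the threshold.

    The cut is strict ('more than'): a miRNA sitting exactly at the
    threshold is excluded. A miRNA may appear in several sets here; the
    multi-cell conflict is resolved later at the intersection step.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    return {ct: set(mean_z.index[mean_z[ct] > threshold]) for ct in mean_z.columns}


def _memberships(X: np.ndarray, centroids: np.ndarray, m: float) -> np.ndarray:
    """Classic fuzzy c-means membership update (log-domain for stability).

    A point coincident with one or more centroids takes membership split
    over the zero-distance centroids (limit convention).
    """
    d2 = cdist(X, centroids, metric="sqeuclidean")
    zero = d2 < 1e-300
    U = np.zeros_like(d2)
    hit = zero.any(axis=1)
    if hit.any():
        U[hit] = zero[hit] / zero[hit].sum(axis=1, keepdims=True)
    rest = ~hit
    if rest.any():
        logw = -(1.0 / (m - 1.0)) * np.log(d2[rest])
        logw -= logw.max(axis=1, keepdims=True)
        w = np.exp(logw)
        U[rest] = w / w.sum(axis=1, keepdims=True)
    return U


def _fcm_objective(X, centroids, U, m) -> float:
    d2 = cdist(X, centroids, metric="sqeuclidean")
    return float(((U ** m) * d2).sum())


def _fcm_once(X, c, m, tol, max_iter, rng) -> FuzzyClusterModel:
    n = X.shape[0]
    if n >= c:
        centroids, _ = kmeans_plusplus(X, n_clusters=c,
                                       random_state=int(rng.integers(2 ** 31)))
    else:
        centroids = X[rng.integers(0, n, size=c)] + rng.normal(0, 1e-6, (c, X.shape[1]))
    U = _memberships(X, centroids, m)
    trace = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        Um = U ** m
        w = Um.sum(axis=0)
        empty = w < 1e-12
        if empty.any():
            # re-seed dead clusters at the currently worst-fit points
            d2 = cdist(X, centroids, metric="sqeuclidean")
            worst = np.argsort((U * d2).sum(axis=1))[::-1]
            for rank, k in enumerate(np.flatnonzero(empty)):
                centroids[k] = X[worst[rank % n]]
            U = _memberships(X, centroids, m)
            Um = U ** m
            w = Um.sum(axis=0)
        centroids = (Um.T @ X) / w[:, None]
        U_new = _memberships(X, centroids, m)
        trace.append(_fcm_objective(X, centroids, U_new, m))
        delta = np.abs(U_new - U).max()
        U = U_new
        if delta < tol:
            converged = True
            break
    return FuzzyClusterModel(centroids=centroids, membership=U, fuzzifier_m=m,
                             n_clusters_c=c, objective_trace=trace, seed=-1,
                             n_iter=it, converged=converged)


def fuzzy_cmeans(X, c: int = 16, m: float = 1.18, tol: float = 1e-6,
                 max_iter: int = 300, seed: int = 0,
                 n_restarts: int = 10) -> FuzzyClusterModel:
    """Fuzzy c-means with k-means++ seeding and multistart.

    u_ik = (sum_j (d_ik / d_jk)^(2/(m-1)))^-1 and
    v_k = sum_i u_ik^m x_i / sum_i u_ik^m with Euclidean d, iterated
    until the maximum membership change drops below ``tol``. The run
    with the lowest final objective J = sum_ik u_ik^m d_ik^2 over
    ``n_restarts`` seedings is returned; J is recorded per iteration.
    """
    X = np.asarray(X, float)
    if X.ndim != 2:
        raise ValueError("X must be a 2-D (items x features) array")
    if c < 2:
        raise ValueError("c must be >= 2")
    if m <= 1:
        raise ValueError("fuzzifier m must be > 1")
    rng = np.random.default_rng(seed)
    best: FuzzyClusterModel | None = None
    for _ in range(max(1, n_restarts)):
        model = _fcm_once(X, c, m, tol, max_iter, rng)
        if best is None or model.objective_trace[-1] < best.objective_trace[-1]:
            best = model
    best.seed = seed
    return best


def select_celltype_clusters(model: FuzzyClusterModel, samples: SampleSheet,
                             condition: str, sample_ids: list,
                             min_samples_elevated: int = 3,
                             max_other_elevated: int = 2,
                             cell_types=CELL_TYPES) -> dict:
    """Clusters whose centroid is elevated in exactly one cell type.

    A cluster maps to a cell type when its centroid (standardized space)
    is positive in at least ``min_samples_elevated`` of that type's
    samples and in at most ``max_other_elevated`` samples of every other
    type. Clusters elevated in zero or in two or more types stay
    unassigned.
    """
    ct_of = samples.cell_type_of()
    cols = np.array([ct_of[s] for s in sample_ids])
    out = {ct: set() for ct in cell_types}
    for k in range(model.n_clusters_c):
        pos = model.centroids[k] > 0
        n_pos = {ct: int(pos[cols == ct].sum()) for ct in cell_types}
        winners = [ct for ct in cell_types
                   if n_pos[ct] >= min_samples_elevated
                   and all(n_pos[o] <= max_other_elevated
                           for o in cell_types if o != ct)]
        if len(winners) == 1:
            out[winners[0]].add(k)
    return out


def cluster_member_sets(model: FuzzyClusterModel, mirna_ids,
                        membership_cutoff: float = 0.5) -> dict:
    """Hard member set per cluster: argmax membership, above the cutoff."""
    if not 0 < membership_cutoff < 1:
        raise ValueError("membership_cutoff must lie in (0, 1)")
    U = model.membership
    arg = U.argmax(axis=1)
    umax = U.max(axis=1)
    out = {k: set() for k in range(model.n_clusters_c)}
    for mid, k, u in zip(mirna_ids, arg, umax):
        if u >= membership_cutoff:
            out[int(k)].add(mid)
    return out


def intersect_enrichment(cluster_sets: dict, z_sets: dict,
                         mirna_ids, cell_types=CELL_TYPES) -> pd.DataFrame:
    """Combine the cluster and z-score routes into one assignment column.

    A miRNA is assigned to a cell type only when both routes nominate
    that same type; nomination by two or more types makes it Not Cell
    Specific; anything else is unassigned. Provenance flags record which
    route(s) ever nominated the miRNA.
    """
    rows = []
    for mid in mirna_ids:
        both = [ct for ct in cell_types
                if mid in cluster_sets.get(ct, ()) and mid in z_sets.get(ct, ())]
        via_cluster = any(mid in cluster_sets.get(ct, ()) for ct in cell_types)
        via_zscore = any(mid in z_sets.get(ct, ()) for ct in cell_types)
        if len(both) == 1:
            assigned = both[0]
        elif len(both) >= 2:
            assigned = NOT_CELL_SPECIFIC
        else:
            assigned = UNASSIGNED
        rows.append({"mirna_id": mid, "assigned_cell": assigned,
                     "via_cluster": via_cluster, "via_zscore": via_zscore})
    return pd.DataFrame(rows).set_index("mirna_id")


def consistency_classify(assignments: pd.DataFrame,
                         conditions=CONDITIONS) -> pd.DataFrame:
    """Tier each miRNA by the persistence of its single-cell assignment.

    Counting only conditions with a single-cell-type assignment: the
    same cell in 1 condition is low, in 2-3 moderate, in all 4 high;
    two or more distinct cell types across conditions is switching;
    no single-cell assignment anywhere is none.
    """
    missing = [c for c in conditions if c not in assignments.columns]
    if missing:
        raise ValueError(f"assignment columns missing conditions: {missing}")
    tiers, cells, counts = [], [], []
    for _, row in assignments[list(conditions)].iterrows():
        hits = [v for v in row if v in CELL_TYPES]
        distinct = set(hits)
        n = len(hits)
        if len(distinct) >= 2:
            tier, cell = "switching", None
        elif n == 0:
            tier, cell = "none", None
        else:
            cell = hits[0]
            tier = {1: "low", 2: "moderate", 3: "moderate", 4: "high"}[n]
        tiers.append(tier)
        cells.append(cell)
        counts.append(n)
    return pd.DataFrame({"tier": tiers, "cell": cells,
                         "n_conditions_enriched": counts},
                        index=assignments.index)


def trajectory_table(assignments: pd.DataFrame, conditions=CONDITIONS,
                     baseline_enriched_only: bool = False) -> pd.DataFrame:
    """Consecutive-condition transition counts over assignment states.

    With ``baseline_enriched_only`` the tally is restricted to miRNAs
    holding a single-cell assignment in the first condition (the
    trajectory-of-baseline-markers view).
    """
    df = assignments[list(conditions)]
    if baseline_enriched_only:
        df = df[df[conditions[0]].isin(CELL_TYPES)]
    rows = []
    for a, b in zip(conditions[:-1], conditions[1:]):
        counts = df.groupby([a, b], observed=True).size()
        for (src, dst), n in counts.items():
            rows.append({"step": f"{a}->{b}", "from_state": src,
                         "to_state": dst, "count": int(n)})
    return pd.DataFrame(rows, columns=["step", "from_state", "to_state", "count"])


def heatmap_order(values, method: str = "average", metric: str = "euclidean"):
    """Leaf orders of average-linkage dendrograms for display export.

    Returns (row_order, col_order) index arrays; columns are left in
    place when there are fewer than 2 of them.
    """
    values = np.asarray(values, float)
    if values.shape[0] < 2:
        raise ValueError("heatmap_order needs at least 2 rows")
    row_order = leaves_list(linkage(values, method=method, metric=metric))
    if values.shape[1] >= 2:
        col_order = leaves_list(linkage(values.T, method=method, metric=metric))
    else:
        col_order = np.arange(values.shape[1])
    return row_order, col_order


@dataclass
class EnrichmentResult:
    """Full enrichment call: per-condition assignments plus tiers."""
    assignments: pd.DataFrame            # miRNA x condition, ASSIGN_STATES
    tiers: pd.DataFrame                  # tier, cell, n_conditions_enriched
    provenance: dict                     # condition -> via_cluster/via_zscore frame
    mean_z: dict                         # condition -> miRNA x cell type frame
    models: dict                         # condition -> FuzzyClusterModel
    params: dict

    def summary(self) -> pd.DataFrame:
        return pd.concat([self.assignments, self.tiers], axis=1)

    def enriched_counts(self) -> pd.DataFrame:
        """Per-condition tallies before and after the multi-cell exclusion."""
        rows = {}
        for cond in self.assignments.columns:
            col = self.assignments[cond]
            rows[cond] = {
                "single_cell_assigned": int(col.isin(CELL_TYPES).sum()),
                "incl_not_cell_specific": int(col.isin(CELL_TYPES
                                                       + (NOT_CELL_SPECIFIC,)).sum()),
            }
        return pd.DataFrame(rows).T


def call_enrichment(log_expr: NormalizedMatrix, samples: SampleSheet, *,
                    n_clusters: int = 16, fuzzifier: float = 1.18,
                    z_threshold: float = 1.15, membership_cutoff: float = 0.5,
                    min_samples_elevated: int = 3, max_other_elevated: int = 2,
                    tol: float = 1e-6, max_iter: int = 300, seed: int = 0,
                    n_restarts: int = 10,
                    conditions=CONDITIONS) -> EnrichmentResult:
    """Run the full per-condition enrichment calling on log2-CPM input.

    All randomness flows from ``seed`` through one child stream per
    condition, so a fixed seed yields an identical result table.
    """
    child_seeds = [int(s.generate_state(1)[0] % (2 ** 31))
                   for s in np.random.SeedSequence(seed).spawn(len(conditions))]
    assign_cols, provenance, mean_z_by_cond, models = {}, {}, {}, {}
    for cond, cseed in zip(conditions, child_seeds):
        z = zscore_by_condition(log_expr, samples, cond)
        mean_z = mean_celltype_zscores(z, samples)
        z_sets = zscore_enriched(mean_z, threshold=z_threshold)
        model = fuzzy_cmeans(z.z, c=n_clusters, m=fuzzifier, tol=tol,
                             max_iter=max_iter, seed=cseed, n_restarts=n_restarts)
        chosen = select_celltype_clusters(model, samples, cond, z.sample_ids,
                                          min_samples_elevated=min_samples_elevated,
                                          max_other_elevated=max_other_elevated)
        members = cluster_member_sets(model, z.mirna_ids,
                                      membership_cutoff=membership_cutoff)
        cluster_sets = {ct: set().union(*(members[k] for k in ks)) if ks else set()
                        for ct, ks in chosen.items()}
        col = intersect_enrichment(cluster_sets, z_sets, z.mirna_ids)
        assign_cols[cond] = col["assigned_cell"]
        provenance[cond] = col[["via_cluster", "via_zscore"]]
        mean_z_by_cond[cond] = mean_z
        models[cond] = model
    assignments = pd.DataFrame(assign_cols)
    tiers = consistency_classify(assignments, conditions=conditions)
    params = dict(n_clusters=n_clusters, fuzzifier=fuzzifier,
                  z_threshold=z_threshold, membership_cutoff=membership_cutoff,
                  min_samples_elevated=min_samples_elevated,
                  max_other_elevated=max_other_elevated, seed=seed,
                  n_restarts=n_restarts)
    return EnrichmentResult(assignments=assignments, tiers=tiers,
                            provenance=provenance, mean_z=mean_z_by_cond,
                            models=models, params=params)
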