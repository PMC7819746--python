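"""Count normalization and sample QC.

Reproduces the semantics of the standard small-RNA-seq preprocessing
stack: counts-per-million scaling, low-expression filtering, TMM
(trimmed mean of M-values) between-sample normalization, log2 transform
with a library-size-scaled prior, and PCA-based outlier screening.

Only TMM/CPM semantics are reproduced; dispersion-related pseudo-count
machinery of full differential-expression toolkits is out of scope here.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .io_formats import CountMatrix, SampleSheet


@dataclass
class NormalizedMatrix:
    """CPM or log2-CPM values with the normalization provenance attached."""
    mirna_ids: list
    sample_ids: list
    values: np.ndarray
    norm_factors: np.ndarray
    log_base: str = "none"      # "none" | "log2"
    prior_count: float = 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.mirna_ids, columns=self.sample_ids)


@dataclass
class QcReport:
    """Principal-component coordinates plus advisory outlier flags."""
    coordinates: pd.DataFrame          # samples x PCs
    variance_ratio: np.ndarray
    flagged_outliers: list = field(default_factory=list)
    rule: str = ""


def cpm(counts: CountMatrix, norm_factors=None, log: bool = False,
        prior_count: float = 2.0) -> NormalizedMatrix:
    """Counts per million, optionally log2 with a library-scaled prior.

    value(i, j) = counts(i, j) / (libsize_j * factor_j) * 1e6. With
    ``log=True`` the prior count is rescaled per sample in proportion to
    its effective library size (so the prior is constant on the CPM
    scale), and log2 CPM is returned.
    """
    lib = counts.counts.sum(axis=0).astype(float)
    zero = np.flatnonzero(lib == 0)
    if zero.size:
        raise ValueError(f"zero library size for sample(s): "
                         f"{[counts.sample_ids[j] for j in zero]}")
    nf = np.ones(len(lib)) if norm_factors is None else np.asarray(norm_factors, float)
    if nf.shape != lib.shape:
        raise ValueError("norm_factors length must match number of samples")
    eff = lib * nf
    if not log:
        vals = counts.counts / eff * 1e6
        return NormalizedMatrix(list(counts.mirna_ids), list(counts.sample_ids),
                                vals, nf, log_base="none", prior_count=0.0)
    adj_prior = prior_count * eff / eff.mean()
    vals = np.log2((counts.counts + adj_prior) / (eff + 2.0 * adj_prior) * 1e6)
    return NormalizedMatrix(list(counts.mirna_ids), list(counts.sample_ids),
                            vals, nf, log_base="log2", prior_count=prior_count)


def filter_low_expression(cpm_matrix: NormalizedMatrix, min_cpm: float = 1.0,
                          min_samples: int = 3) -> list:
    """IDs of miRNAs with CPM > min_cpm in at least min_samples samples.

    Computed once on the full (unlogged) CPM matrix; the retained id list
    is then applied to the raw counts by the caller.
    """
    if cpm_matrix.log_base != "none":
        raise ValueError("filter_low_expression expects an unlogged CPM matrix")
    n = len(cpm_matrix.sample_ids)
    if min_samples > n:
        raise ValueError(f"min_samples={min_samples} exceeds sample count {n}")
    keep = (cpm_matrix.values > min_cpm).sum(axis=1) >= min_samples
    return [m for m, k in zip(cpm_matrix.mirna_ids, keep) if k]


def _quantile_ref(counts: np.ndarray, p: float = 0.75) -> int:
    lib = counts.sum(axis=0).astype(float)
    f = np.quantile(counts / lib, p, axis=0)
    return int(np.argmin(np.abs(f - f.mean())))


def _tmm_pair(obs, ref, lib_obs, lib_ref, trim_m, trim_a):
    """Log2 TMM factor of one sample against the reference sample."""
    obs = obs.astype(float)
    ref = ref.astype(float)
    mask = (obs > 0) & (ref > 0)
    if not mask.any():
        return None
    o, r = obs[mask], ref[mask]
    M = np.log2((o / lib_obs) / (r / lib_ref))
    A = 0.5 * np.log2((o / lib_obs) * (r / lib_ref))
    # asymptotic (delta-method) variance of M; weights are its inverse
    v = (lib_obs - o) / (lib_obs * o) + (lib_ref - r) / (lib_ref * r)
    if np.max(np.abs(M)) < 1e-6:
        return 0.0
    n = len(M)
    lo_m = np.floor(n * trim_m) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * trim_a) + 1
    hi_a = n + 1 - lo_a
    rank_m = pd.Series(M).rank().to_numpy()
    rank_a = pd.Series(A).rank().to_numpy()
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any():
        return 0.0
    f = np.nansum(M[keep] / v[keep]) / np.nansum(1.0 / v[keep])
    return float(f) if np.isfinite(f) else 0.0


def tmm_factors(counts: CountMatrix, trim_m: float = 0.30, trim_a: float = 0.05,
                ref_sample: str | None = None) -> np.ndarray:
    """TMM normalization factors, rescaled to geometric mean 1.

    The reference is the sample whose 75th-percentile CPM is closest to
    the mean 75th percentile unless ``ref_sample`` is given. A sample
    sharing no commonly expressed miRNA with the reference gets factor 1
    with a warning.
    """
    X = counts.counts
    if X.shape[1] < 2:
        raise ValueError("TMM requires at least 2 samples")
    lib = X.sum(axis=0).astype(float)
    if (lib == 0).any():
        raise ValueError("TMM requires positive library sizes")
    if ref_sample is None:
        ref_j = _quantile_ref(X)
    else:
        ref_j = counts.sample_ids.index(ref_sample)
    log_f = np.zeros(X.shape[1])
    for j in range(X.shape[1]):
        if j == ref_j:
            continue
        f = _tmm_pair(X[:, j], X[:, ref_j], lib[j], lib[ref_j], trim_m, trim_a)
        if f is None:
            warnings.warn(f"sample {counts.sample_ids[j]!r} shares no expressed "
                          "miRNA with the TMM reference; factor set to 1")
            f = 0.0
        log_f[j] = f
    factors = 2.0 ** log_f
    factors /= np.exp(np.mean(np.log(factors)))
    return factors


def pca_qc(logcpm: NormalizedMatrix, samples: SampleSheet | None = None,
           n_components: int = 2, outlier_sd: float = 3.0,
           top_n: int | None = 500) -> QcReport:
    """PCA of samples on per-miRNA-centered log2-CPM with outlier flags.

    Flags a sample when its PC1-PC2 distance from the centroid of the
    other members of its (cell_type, condition) group exceeds
    ``outlier_sd`` times the spread (SD of mutual distances) of those
    members. Flagging is advisory: exclusion is an explicit user action.
    """
    if logcpm.log_base != "log2":
        raise ValueError("pca_qc expects a logged matrix")
    vals = logcpm.values
    n_samples = vals.shape[1]
    if n_samples < n_components:
        raise ValueError(f"{n_samples} samples < {n_components} components")
    if top_n is not None and top_n < vals.shape[0]:
        order = np.argsort(vals.var(axis=1))[::-1][:top_n]
        vals = vals[np.sort(order)]
    X = vals.T - vals.T.mean(axis=0)     # per-miRNA centering
    pca = PCA(n_components=n_components, svd_solver="full")
    coords = pca.fit_transform(X)
    coord_df = pd.DataFrame(coords, index=logcpm.sample_ids,
                            columns=[f"PC{k + 1}" for k in range(n_components)])
    flagged: list = []
    rule = f"group leave-one-out distance > {outlier_sd} x group SD on PC1-PC2"
    if samples is not None:
        pc12 = coord_df.iloc[:, :2]
        groups = samples.df.groupby(["cell_type", "condition"])["sample_id"]
        for _, ids in groups:
            ids = [s for s in ids if s in pc12.index]
            if len(ids) < 3:
                continue
            pts = pc12.loc[ids].to_numpy()
            for i, sid in enumerate(ids):
                others = np.delete(pts, i, axis=0)
                centroid = others.mean(axis=0)
                spread = np.linalg.norm(others - centroid, axis=1)
                sd = spread.std(ddof=1) if len(spread) > 1 else 0.0
                dist = np.linalg.norm(pts[i] - centroid)
                if dist > outlier_sd * max(sd, 1e-12):
                    flagged.append(sid)
    return QcReport(coordinates=coord_df,
                    variance_ratio=pca.explained_variance_ratio_,
                    flagged_outliers=flagged, rule=rule)
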