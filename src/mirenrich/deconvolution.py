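"""Differential expression and enriched-set ECDF-shift deconvolution.

The deconvolution logic: take the log fold changes of a two-group
contrast, split them into the four high-consistency cell-enriched sets
plus the non-enriched background, and compare each set's empirical CDF
against the background with a two-sample Kolmogorov-Smirnov test. A
shift of an enriched set in bulk tissue that is absent in the matching
isolated population flags a cell-composition change rather than
within-cell transcription.

The negative-binomial test here is a deliberately simplified conditional
exact test with a common method-of-moments dispersion (the conditional
law of one group's total given the gene total is beta-binomial); it is
an approximation of the full empirical-Bayes machinery of dedicated DE
toolkits, which the downstream ECDF analysis does not require. An exact
label-permutation alternative is provided.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import betaln, gammaln
from statsmodels.distributions.empirical_distribution import ECDF
from statsmodels.stats.multitest import multipletests

from .io_formats import CELL_TYPES, CountMatrix, SampleSheet
from .preprocessing import tmm_factors


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, stable ties)."""
    p = np.asarray(p_values, float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _mom_common_dispersion(y: np.ndarray, groups: list) -> float:
    """Median method-of-moments NB dispersion over genes and groups."""
    ests = []
    for idx in groups:
        sub = y[:, idx]
        m = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        ok = m > 0
        ests.append(((v[ok] - m[ok]) / m[ok] ** 2))
    est = np.concatenate(ests)
    if est.size == 0:
        return 0.0
    return float(max(0.0, np.median(est)))


def _betabinom_two_sided_p(t: int, a_obs: int, alpha: float, beta: float) -> float:
    """Two-sided exact p for a ~ BetaBinomial(t, alpha, beta).

    Sums the probability of all outcomes no more likely than the
    observed one. alpha = beta = inf (dispersion 0) degenerates to the
    binomial conditional (the Poisson limit).
    """
    if t == 0:
        return 1.0
    a = np.arange(t + 1)
    if np.isinf(alpha):      # Poisson limit: binomial with p = nA/(nA+nB)
        raise ValueError("pass finite alpha/beta; handle the Poisson limit upstream")
    logpmf = (gammaln(t + 1) - gammaln(a + 1) - gammaln(t - a + 1)
              + betaln(a + alpha, t - a + beta) - betaln(alpha, beta))
    logpmf -= np.logaddexp.reduce(logpmf)
    keep = logpmf <= logpmf[a_obs] + 1e-10
    return float(min(1.0, np.exp(np.logaddexp.reduce(logpmf[keep]))))


def _binom_two_sided_p(t: int, a_obs: int, p: float) -> float:
    if t == 0:
        return 1.0
    a = np.arange(t + 1)
    logpmf = stats.binom.logpmf(a, t, p)
    keep = logpmf <= logpmf[a_obs] + 1e-10
    return float(min(1.0, np.exp(np.logaddexp.reduce(logpmf[keep]))))


def _conditional_p(t: int, a_obs: int, n_a: int, n_b: int, phi: float) -> float:
    """Exact conditional two-sided p for group-A total given gene total."""
    if t == 0:
        return 1.0
    if phi <= 0:
        return _binom_two_sided_p(t, a_obs, n_a / (n_a + n_b))
    alpha = n_a / phi
    beta = n_b / phi
    if t > 200_000:
        # normal approximation to the beta-binomial conditional
        p = alpha / (alpha + beta)
        var = t * p * (1 - p) * (alpha + beta + t) / (alpha + beta + 1)
        zlo = abs(a_obs - t * p) - 0.5
        return float(min(1.0, 2 * stats.norm.sf(max(zlo, 0.0) / math.sqrt(var))))
    return _betabinom_two_sided_p(t, a_obs, alpha, beta)


def de_test(counts: CountMatrix, samples: SampleSheet, group_a: str,
            group_b: str, group_col: str = "condition",
            cell_type: str | None = None, dispersion_mode: str = "exact",
            dispersion: float | None = None, prior: float = 0.125,
            fc_threshold: float = 1.5, fdr_threshold: float = 0.05,
            n_permutations: int = 2000, seed: int = 0) -> pd.DataFrame:
    """Two-group differential expression on TMM-normalized counts.

    logFC is log2 of the (mean normalized abundance + prior) ratio,
    group B over group A. ``dispersion_mode`` selects the conditional
    NB exact test ("exact") or an exact/Monte-Carlo label permutation of
    |logFC| ("permutation"). Significance encodes |fold change| >
    ``fc_threshold`` (two-sided) together with BH FDR < ``fdr_threshold``.
    """
    def _ids(label):
        sel = samples.df[group_col] == label
        if cell_type is not None:
            sel &= samples.df["cell_type"] == cell_type
        ids = samples.df.loc[sel, "sample_id"].tolist()
        ids = [s for s in ids if s in counts.sample_ids]
        if len(ids) < 2:
            raise ValueError(f"group {label!r} has fewer than 2 usable samples")
        return ids

    ids_a, ids_b = _ids(group_a), _ids(group_b)
    sub = counts.subset(samples=ids_a + ids_b)
    factors = tmm_factors(sub)
    lib = sub.counts.sum(axis=0).astype(float)
    eff = lib * factors
    y = sub.counts * (eff.mean() / eff)       # counts on a common library scale
    n_a, n_b = len(ids_a), len(ids_b)
    a_idx = np.arange(n_a)
    b_idx = np.arange(n_a, n_a + n_b)

    mean_a = y[:, a_idx].mean(axis=1)
    mean_b = y[:, b_idx].mean(axis=1)
    logfc = np.log2((mean_b + prior) / (mean_a + prior))

    if dispersion_mode == "exact":
        phi = dispersion if dispersion is not None else \
            _mom_common_dispersion(y, [a_idx, b_idx])
        ta = np.rint(y[:, a_idx].sum(axis=1)).astype(np.int64)
        tb = np.rint(y[:, b_idx].sum(axis=1)).astype(np.int64)
        p = np.array([_conditional_p(int(a + b), int(a), n_a, n_b, phi)
                      for a, b in zip(ta, tb)])
    elif dispersion_mode == "permutation":
        p = _permutation_p(y, n_a, n_b, prior, n_permutations, seed)
    else:
        raise ValueError(f"unknown dispersion_mode {dispersion_mode!r}")

    zero = (mean_a == 0) & (mean_b == 0)
    logfc[zero] = 0.0
    p[zero] = 1.0
    fdr = bh_fdr(p)
    sig = (np.abs(logfc) > np.log2(fc_threshold)) & (fdr < fdr_threshold)
    out = pd.DataFrame({"logFC": logfc, "p_value": p, "fdr": fdr,
                        "significant": sig, "mean_a": mean_a, "mean_b": mean_b},
                       index=sub.mirna_ids)
    out.attrs["contrast"] = (group_a, group_b)
    out.attrs["cell_type"] = cell_type
    out.attrs["dispersion_mode"] = dispersion_mode
    return out


def _permutation_p(y: np.ndarray, n_a: int, n_b: int, prior: float,
                   n_permutations: int, seed: int) -> np.ndarray:
    n = n_a + n_b
    obs = np.abs(np.log2((y[:, n_a:].mean(axis=1) + prior)
                         / (y[:, :n_a].mean(axis=1) + prior)))
    all_splits = math.comb(n, n_a)
    if all_splits <= 20_000:
        splits = [np.array(c) for c in combinations(range(n), n_a)]
        exact = True
    else:
        rng = np.random.default_rng(seed)
        splits = [rng.permutation(n)[:n_a] for _ in range(n_permutations)]
        exact = False
    count = np.zeros(y.shape[0])
    for a_cols in splits:
        mask = np.zeros(n, bool)
        mask[a_cols] = True
        stat = np.abs(np.log2((y[:, ~mask].mean(axis=1) + prior)
                              / (y[:, mask].mean(axis=1) + prior)))
        count += stat >= obs - 1e-12
    if exact:
        return count / len(splits)
    return (count + 1) / (len(splits) + 1)


def ecdf(values) -> ECDF:
    """Right-continuous empirical CDF; evaluation gives (#values <= x)/n."""
    values = np.asarray(values, float)
    if values.size == 0:
        raise ValueError("ecdf of an empty sample is undefined")
    return ECDF(values, side="right")


@dataclass
class KsResult:
    statistic: float
    p_value: float
    shift_sign: int
    median_shift: float
    n_set: int
    n_background: int


def ks_compare(set_values, background_values, mode: str = "auto") -> KsResult:
    """Two-sided two-sample Kolmogorov-Smirnov comparison.

    D is the sup-norm ECDF distance over the pooled support. The p-value
    is exact (distribution of D under the permutation null) when both
    samples are small, asymptotic otherwise; ``mode`` can force either
    ("exact_smalln" / "asymptotic"). The shift sign is the sign of
    median(set) - median(background).
    """
    x = np.asarray(set_values, float)
    y = np.asarray(background_values, float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    if mode == "exact_smalln":
        method = "exact"
    elif mode == "asymptotic":
        method = "asymp"
    elif mode == "auto":
        method = "exact" if (len(x) <= 12 and len(y) <= 12) \
            or len(x) * len(y) <= 10_000 else "asymp"
    else:
        raise ValueError(f"unknown mode {mode!r}")
    res = stats.ks_2samp(x, y, alternative="two-sided", method=method)
    shift = float(np.median(x) - np.median(y))
    return KsResult(statistic=float(res.statistic), p_value=float(res.pvalue),
                    shift_sign=int(np.sign(shift)), median_shift=shift,
                    n_set=len(x), n_background=len(y))


@dataclass
class SetShiftResult:
    """Per enriched set: logFC values, ECDF, and KS against background."""
    set_values: dict                      # cell type -> np.ndarray of logFC
    background_values: np.ndarray
    ks: dict                              # cell type -> KsResult | None
    skipped: list = field(default_factory=list)
    tier_filter: tuple = ("high",)

    def ecdfs(self) -> dict:
        out = {"background": ecdf(self.background_values)}
        for ct, v in self.set_values.items():
            if v.size:
                out[ct] = ecdf(v)
        return out


def set_shift_analysis(de: pd.DataFrame, enrichment: pd.DataFrame,
                       tier_filter=("high",), min_set: int = 3,
                       ks_mode: str = "auto") -> SetShiftResult:
    """Split a contrast's logFCs into enriched sets vs background and KS-test.

    ``enrichment`` needs 'tier' and 'cell' columns indexed by miRNA (the
    enrichment summary). Background = tested miRNAs not enriched in any
    tier; an enriched set with fewer than ``min_set`` members in the
    contrast is reported but its KS test is skipped.
    """
    tier_filter = tuple(tier_filter)
    common = de.index.intersection(enrichment.index)
    if common.empty:
        raise ValueError("no overlap between DE table and enrichment table")
    tiers = enrichment.loc[common, "tier"]
    cells = enrichment.loc[common, "cell"]
    bg_ids = common[~tiers.isin(("low", "moderate", "high", "switching"))]
    bg_ids = bg_ids.union(de.index.difference(enrichment.index))
    background = de.loc[bg_ids, "logFC"].to_numpy()
    set_values, ks, skipped = {}, {}, []
    for ct in CELL_TYPES:
        ids = common[(tiers.isin(tier_filter)) & (cells == ct)]
        vals = de.loc[ids, "logFC"].to_numpy()
        set_values[ct] = vals
        if len(vals) < min_set or background.size == 0:
            ks[ct] = None
            skipped.append(ct)
        else:
            ks[ct] = ks_compare(vals, background, mode=ks_mode)
    return SetShiftResult(set_values=set_values, background_values=background,
                          ks=ks, skipped=skipped, tier_filter=tier_filter)


@dataclass
class PairedShiftResult:
    """The same enriched set's shift in bulk vs the isolated population.

    A bulk shift without a within-cell shift flags a change in sample
    cellular composition rather than transcription.
    """
    bulk: KsResult | None
    cell: KsResult | None
    bulk_values: np.ndarray
    cell_values: np.ndarray
    bulk_background: np.ndarray
    cell_background: np.ndarray


def bulk_vs_population_shift(de_bulk: pd.DataFrame, de_cell: pd.DataFrame,
                             enriched_set, min_set: int = 3,
                             ks_mode: str = "auto") -> PairedShiftResult:
    """Compare one enriched set's logFC ECDF in bulk and isolated-cell data.

    Both tables must carry the same contrast. Each table contributes the
    set's values plus its own background (all other tested miRNAs).
    """
    ca, cb = de_bulk.attrs.get("contrast"), de_cell.attrs.get("contrast")
    if ca is not None and cb is not None and tuple(ca) != tuple(cb):
        raise ValueError(f"contrast mismatch: bulk {ca} vs cell {cb}")
    enriched_set = set(enriched_set)

    def _split(de):
        in_set = de.index.isin(enriched_set)
        return de.loc[in_set, "logFC"].to_numpy(), de.loc[~in_set, "logFC"].to_numpy()

    bulk_vals, bulk_bg = _split(de_bulk)
    cell_vals, cell_bg = _split(de_cell)
    bulk_ks = ks_compare(bulk_vals, bulk_bg, mode=ks_mode) \
        if len(bulk_vals) >= min_set and bulk_bg.size else None
    cell_ks = ks_compare(cell_vals, cell_bg, mode=ks_mode) \
        if len(cell_vals) >= min_set and cell_bg.size else None
    return PairedShiftResult(bulk=bulk_ks, cell=cell_ks,
                             bulk_values=bulk_vals, cell_values=cell_vals,
                             bulk_background=bulk_bg, cell_background=cell_bg)


def mean_celltype_expression(log_expr, samples: SampleSheet,
                             cell_types=CELL_TYPES) -> pd.DataFrame:
    """Mean log expression per cell type across all conditions (miRNA x cell)."""
    df = log_expr.to_frame()
    out = {}
    for ct in cell_types:
        ids = [s for s in samples.samples_for(cell_type=ct) if s in df.columns]
        if ids:
            out[ct] = df[ids].mean(axis=1)
    return pd.DataFrame(out)


def celltype_profile_overlay(external: pd.DataFrame, match: pd.DataFrame,
                             mean_expr: pd.DataFrame,
                             enrichment: pd.DataFrame | None = None,
                             tier_filter=("high",)):
    """Map external (human) DEmiRNAs onto mouse cell-type mean expression.

    ``match`` is a seed-match table with mouse_name / human_name /
    human_base / human_arm columns restricted to unique pairs; the join
    goes through the normalized external names. Returns ``(overlay,
    unmatched)`` where the overlay holds one row per matched external
    entry (duplicates collapsed) with the four cell-type means and the
    reported direction.
    """
    uniq = match[match["unique"]] if "unique" in match.columns else match
    key = uniq.assign(_k=uniq["human_base"] + "|" + uniq["human_arm"].fillna(""))
    lookup = key.drop_duplicates("_k").set_index("_k")["mouse_name"]
    rows, unmatched = [], []
    seen = set()
    for _, r in external.iterrows():
        k = f"{r['base_name']}|{r['arm'] or ''}"
        mouse = lookup.get(k)
        if mouse is None or mouse not in mean_expr.index:
            unmatched.append(r["mirna_name"])
            continue
        if (k, r["direction"]) in seen:
            continue
        seen.add((k, r["direction"]))
        if enrichment is not None:
            if mouse not in enrichment.index or \
                    enrichment.loc[mouse, "tier"] not in tier_filter:
                unmatched.append(r["mirna_name"])
                continue
        row = {"external_name": r["mirna_name"], "mouse_name": mouse,
               "direction": r["direction"]}
        row.update(mean_expr.loc[mouse].to_dict())
        rows.append(row)
    cols = ["external_name", "mouse_name", "direction", *mean_expr.columns]
    return pd.DataFrame(rows, columns=cols), unmatched


#: Ordered within-cell contrasts for temporal pattern labelling.
DYNAMIC_CONTRASTS = (("sham", "UUO2"), ("UUO2", "UUO7"), ("UUO7", "RUUO"))
DYNAMIC_LABELS = ("up-early", "up-late", "down-early", "down-late",
                  "transient", "stable")


def dynamic_cluster_assign(de_tables) -> pd.Series:
    """Assign each miRNA exactly one temporal pattern label.

    ``de_tables`` holds the three consecutive within-cell contrasts in
    time order. Decision table over (significant?, sign of logFC) per
    contrast: no significant contrast -> stable; significant contrasts
    in both directions -> transient; otherwise direction (up/down) plus
    timing (early when the first contrast is significant, late when the
    first significant contrast comes later).
    """
    de_tables = list(de_tables)
    if len(de_tables) != len(DYNAMIC_CONTRASTS) or any(t is None for t in de_tables):
        raise ValueError(f"need {len(DYNAMIC_CONTRASTS)} contrast tables in time order")
    idx = de_tables[0].index
    for t in de_tables[1:]:
        idx = idx.intersection(t.index)
    labels = []
    for mid in idx:
        sig = [bool(t.loc[mid, "significant"]) for t in de_tables]
        sign = [1 if t.loc[mid, "logFC"] > 0 else -1 for t in de_tables]
        active = [s for s, is_sig in zip(sign, sig) if is_sig]
        if not active:
            labels.append("stable")
        elif len(set(active)) > 1:
            labels.append("transient")
        else:
            direction = "up" if active[0] > 0 else "down"
            timing = "early" if sig[0] else "late"
            labels.append(f"{direction}-{timing}")
    return pd.Series(labels, index=idx, name="dynamic_pattern")
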