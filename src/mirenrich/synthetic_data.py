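"""Synthetic inputs with known ground truth.

Emulates the study design the pipeline targets: four sorted renal cell
populations (PT, Mac, EC, PDGFRB) profiled by small-RNA-seq across four
conditions (sham, UUO2, UUO7, RUUO) with ~4 replicates per group,
negative-binomial counts over log-normal baseline abundances, disjoint
planted cell-type-enriched miRNA subsets, optional condition-dependent
within-cell dynamics, bulk samples mixed from the cell profiles with
condition-dependent proportions (macrophage fraction rising with injury
and falling on repair), and qPCR Ct tables with a spike-in reference.

Defaults mirror the scale of the real data: 800 miRNAs, 4 x 4 x 4
samples, ~8% of miRNAs enriched per cell type, 8-fold enrichment boost,
NB dispersion 0.1.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import CELL_TYPES, CONDITIONS, CountMatrix, SampleSheet

#: Condition x cell-type mixture proportions for bulk samples. The
#: macrophage fraction rises from 5% (sham) to 30% (UUO7) and falls back
#: on repair while the proximal-tubule fraction mirrors the loss/recovery.
DEFAULT_MIXTURES = pd.DataFrame(
    [[0.70, 0.05, 0.15, 0.10],
     [0.55, 0.15, 0.15, 0.15],
     [0.35, 0.30, 0.15, 0.20],
     [0.55, 0.15, 0.15, 0.15]],
    index=list(CONDITIONS), columns=list(CELL_TYPES))

#: Per-condition expression multipliers of each temporal pattern
#: (sham, UUO2, UUO7, RUUO), parameterized by the dynamic fold f.
DYNAMIC_PATTERNS = {
    "up-early": lambda f: (1.0, f, f, f),
    "down-early": lambda f: (1.0, 1 / f, 1 / f, 1 / f),
    "up-late": lambda f: (1.0, 1.0, f, f),
    "down-late": lambda f: (1.0, 1.0, 1 / f, 1 / f),
    "transient": lambda f: (1.0, f, f, 1.0),
}


@dataclass
class SimulationSpec:
    n_mirna: int = 800
    cell_types: tuple = CELL_TYPES
    conditions: tuple = CONDITIONS
    replicates: int = 4
    enriched_fraction: float = 0.08
    enrichment_fold: float = 8.0
    dynamic_fraction: float = 0.10
    dynamic_fold: float = 3.0
    baseline_logmean_mu: float = 3.0
    baseline_logmean_sd: float = 1.5
    nb_dispersion: float = 0.1
    libsize_mu: float = 1.0e6
    libsize_cv: float = 0.3
    mixture_proportions: pd.DataFrame = field(
        default_factory=lambda: DEFAULT_MIXTURES.copy())
    bulk_replicates: int = 4
    seed: int = 0

    def __post_init__(self):
        mp = self.mixture_proportions
        if not np.allclose(mp.sum(axis=1), 1.0):
            raise ValueError("mixture proportion rows must sum to 1")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        total_enriched = self.enriched_fraction * len(self.cell_types)
        if total_enriched > 1.0:
            raise ValueError("enriched fractions exceed the miRNA pool")


@dataclass
class GroundTruth:
    home_cell: pd.Series             # cell type or None per miRNA
    dynamic_label: pd.Series         # pattern label per miRNA ("stable" = none)
    expected_expression: np.ndarray  # n_mirna x n_cell x n_condition
    proportions: pd.DataFrame
    mirna_ids: list

    def enriched_ids(self, cell_type: str) -> list:
        return self.home_cell[self.home_cell == cell_type].index.tolist()


def _rng_streams(seed: int, n: int):
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, phi: float) -> np.ndarray:
    """NB(mean, dispersion) draws; Poisson when the dispersion is zero."""
    mean = np.asarray(mean, float)
    if phi <= 0:
        return rng.poisson(mean)
    r = 1.0 / phi
    p = r / (r + mean)
    out = np.zeros(mean.shape, dtype=np.int64)
    pos = mean > 0
    out[pos] = rng.negative_binomial(r, p[pos])
    return out


def _libsizes(rng: np.random.Generator, n: int, mu: float, cv: float) -> np.ndarray:
    if cv <= 0:
        return np.full(n, mu)
    sigma2 = np.log1p(cv ** 2)
    return rng.lognormal(np.log(mu) - sigma2 / 2, np.sqrt(sigma2), n)


def _ground_truth(spec: SimulationSpec) -> GroundTruth:
    """Deterministic truth layer (baselines, planted sets, dynamics)."""
    rng = _rng_streams(spec.seed, 4)[0]
    ids = [f"mmu-miR-{1000 + i}-5p" for i in range(spec.n_mirna)]
    baseline = rng.lognormal(spec.baseline_logmean_mu, spec.baseline_logmean_sd,
                             spec.n_mirna)
    n_enr = int(round(spec.enriched_fraction * spec.n_mirna))
    perm = rng.permutation(spec.n_mirna)
    home = pd.Series([None] * spec.n_mirna, index=ids, dtype=object)
    for k, ct in enumerate(spec.cell_types):
        for i in perm[k * n_enr:(k + 1) * n_enr]:
            home.iloc[i] = ct
    dyn = pd.Series(["stable"] * spec.n_mirna, index=ids, dtype=object)
    n_dyn = int(round(spec.dynamic_fraction * spec.n_mirna))
    if n_dyn and spec.dynamic_fold > 1:
        labels = list(DYNAMIC_PATTERNS)
        chosen = rng.permutation(spec.n_mirna)[:n_dyn]
        for j, i in enumerate(chosen):
            dyn.iloc[i] = labels[j % len(labels)]
    n_ct, n_cond = len(spec.cell_types), len(spec.conditions)
    e = np.empty((spec.n_mirna, n_ct, n_cond))
    dyn_mult = np.ones((spec.n_mirna, n_cond))
    for i, lab in enumerate(dyn):
        if lab != "stable":
            dyn_mult[i] = DYNAMIC_PATTERNS[lab](spec.dynamic_fold)
    for a, ct in enumerate(spec.cell_types):
        boost = np.where(home.to_numpy() == ct, spec.enrichment_fold, 1.0)
        e[:, a, :] = (baseline * boost)[:, None] * dyn_mult
    return GroundTruth(home_cell=home, dynamic_label=dyn, expected_expression=e,
                       proportions=spec.mixture_proportions.copy(), mirna_ids=ids)


def simulate_cell_counts(spec: SimulationSpec):
    """Sorted-population count matrix, sample sheet, and ground truth.

    Counts for sample j of (cell type, condition) are NB with mean
    libsize_j x expected relative abundance in that group; all draws are
    deterministic under ``spec.seed``.
    """
    truth = _ground_truth(spec)
    rng = _rng_streams(spec.seed, 4)[1]
    cols, rows, meta = [], [], []
    for c_idx, cond in enumerate(spec.conditions):
        for a_idx, ct in enumerate(spec.cell_types):
            profile = truth.expected_expression[:, a_idx, c_idx]
            p = profile / profile.sum()
            libs = _libsizes(rng, spec.replicates, spec.libsize_mu, spec.libsize_cv)
            for r in range(spec.replicates):
                cols.append(_nb_draw(rng, p * libs[r], spec.nb_dispersion))
                sid = f"{ct}_{cond}_r{r + 1}"
                rows.append(sid)
                meta.append({"sample_id": sid, "cell_type": ct,
                             "condition": cond, "replicate": r + 1})
    counts = CountMatrix(truth.mirna_ids, rows, np.column_stack(cols))
    sheet = SampleSheet(pd.DataFrame(meta))
    return counts, sheet, truth


def simulate_bulk_counts(spec: SimulationSpec, truth: GroundTruth | None = None):
    """Bulk-tissue mixtures of the cell profiles with NB sampling.

    The bulk expected profile per condition is the proportion-weighted
    combination of the sum-normalized cell profiles; cell_type is
    ``Bulk`` in the returned sheet.
    """
    if truth is None:
        truth = _ground_truth(spec)
    rng = _rng_streams(spec.seed, 4)[2]
    props = spec.mixture_proportions
    cols, rows, meta = [], [], []
    for c_idx, cond in enumerate(spec.conditions):
        mix = np.zeros(spec.n_mirna)
        for a_idx, ct in enumerate(spec.cell_types):
            profile = truth.expected_expression[:, a_idx, c_idx]
            mix += props.loc[cond, ct] * profile / profile.sum()
        mix /= mix.sum()
        libs = _libsizes(rng, spec.bulk_replicates, spec.libsize_mu, spec.libsize_cv)
        for r in range(spec.bulk_replicates):
            cols.append(_nb_draw(rng, mix * libs[r], spec.nb_dispersion))
            sid = f"Bulk_{cond}_r{r + 1}"
            rows.append(sid)
            meta.append({"sample_id": sid, "cell_type": "Bulk",
                         "condition": cond, "replicate": r + 1})
    counts = CountMatrix(truth.mirna_ids, rows, np.column_stack(cols))
    sheet = SampleSheet(pd.DataFrame(meta))
    return counts, sheet


def expected_bulk_cpm(spec: SimulationSpec, truth: GroundTruth,
                      condition: str) -> np.ndarray:
    """Analytic bulk expected CPM for one condition (no sampling noise)."""
    c_idx = list(spec.conditions).index(condition)
    mix = np.zeros(spec.n_mirna)
    for a_idx, ct in enumerate(spec.cell_types):
        profile = truth.expected_expression[:, a_idx, c_idx]
        mix += spec.mixture_proportions.loc[condition, ct] * profile / profile.sum()
    return mix / mix.sum() * 1e6


def simulate_ct_table(n_per_group=(8, 7), group_labels=("PF", "DGF"),
                      group_effect_log2: float = 0.0,
                      target: str = "miR-18a-5p", reference: str = "cel-miR-39",
                      reference_ct_mu: float = 20.0, base_ct: float = 30.0,
                      noise_sd: float = 0.5, seed: int = 0):
    """qPCR Ct table for a two-group biomarker comparison, plus truth.

    Target Ct = base - log2(abundance) + noise, where the second group's
    abundance is boosted by 2^``group_effect_log2``; the reference assay
    (spike-in) is constant up to noise. Returns ``(frame, truth)``.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    rows = []
    for gi, (n, label) in enumerate(zip(n_per_group, group_labels)):
        abundance = 2.0 ** (group_effect_log2 * gi)
        for s in range(n):
            sid = f"{label}_{s + 1}"
            rows.append({"subject_id": sid, "group_label": label,
                         "assay": target, "is_reference": False,
                         "ct": base_ct - np.log2(abundance)
                         + rng.normal(0, noise_sd)})
            rows.append({"subject_id": sid, "group_label": label,
                         "assay": reference, "is_reference": True,
                         "ct": reference_ct_mu + rng.normal(0, noise_sd)})
    frame = pd.DataFrame(rows, columns=["subject_id", "group_label", "assay",
                                        "ct", "is_reference"])
    truth = {"group_effect_log2": group_effect_log2,
             "expected_rq_ratio": 2.0 ** group_effect_log2,
             "target": target, "reference": reference}
    return frame, truth


def simulate_external_de_list(truth: GroundTruth, cell_type: str = "Mac",
                              n: int = 10, direction: str = "up",
                              source_label: str = "synthetic-disease",
                              seed: int = 0) -> pd.DataFrame:
    """Human-style DEmiRNA list built from a cell type's planted set."""
    rng = np.random.default_rng(seed)
    ids = truth.enriched_ids(cell_type)
    pick = [ids[i] for i in rng.permutation(len(ids))[:n]]
    sign = 1.0 if direction == "up" else -1.0
    return pd.DataFrame({
        "mirna_name": [m.replace("mmu-", "hsa-") for m in pick],
        "direction": direction,
        "logFC": sign * rng.uniform(0.5, 3.0, len(pick)),
        "source_label": source_label,
    })


def simulate_mature_fasta_pair(n_shared: int = 20, n_mouse_only: int = 5,
                               n_human_only: int = 5, n_paralog_groups: int = 2,
                               seed: int = 0):
    """Synthetic mouse/human mature miRNA sets with known seed overlap.

    Returns ``(mouse_records, human_records, truth)`` where truth maps
    each shared base name to its seed. Paralog groups plant two mouse
    matures sharing one seed against a single human mature, so the
    uniqueness filter has known ambiguous cases.
    """
    from .io_formats import MatureMirnaRecord

    rng = np.random.default_rng(seed)
    alphabet = np.array(list("ACGU"))
    used_seeds = set()

    def seq(length=22):
        # distinct seeds by construction so overlap counts are exact
        while True:
            s = "".join(rng.choice(alphabet, length))
            if s[1:7] not in used_seeds:
                used_seeds.add(s[1:7])
                return s

    mouse, human, truth = [], [], {}
    for i in range(n_shared):
        s = seq()
        base = f"miR-{2000 + i}"
        mouse.append(MatureMirnaRecord(f"mmu-{base}-5p", f"MIMAT{i:07d}", "mmu", s))
        human.append(MatureMirnaRecord(f"hsa-{base}-5p", f"MIMAT{i + 5000:07d}", "hsa", s))
        truth[base.lower()] = s[1:7]
    for i in range(n_paralog_groups):
        s = seq()
        base = f"miR-{3000 + i}"
        # two mouse paralogs, same seed, one human counterpart
        mouse.append(MatureMirnaRecord(f"mmu-{base}a-5p", "", "mmu", s))
        mouse.append(MatureMirnaRecord(f"mmu-{base}b-5p", "", "mmu",
                                       s[:8] + seq(14)))
        human.append(MatureMirnaRecord(f"hsa-{base}a-5p", "", "hsa", s))
    for i in range(n_mouse_only):
        mouse.append(MatureMirnaRecord(f"mmu-miR-{4000 + i}-3p", "", "mmu", seq()))
    for i in range(n_human_only):
        human.append(MatureMirnaRecord(f"hsa-miR-{5000 + i}-3p", "", "hsa", seq()))
    return mouse, human, truth
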