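"""Species-specific peak classification.

A peak is called a species-specific *gain* when it is long enough
(>= min_length), shows a greater-than-F-fold density increase in the
target species over the comparison species (per ``fold_mode``: against
each comparison species' group mean, or against the pooled comparison
mean), and the target-vs-pooled-comparison rank-sum test survives
Benjamini-Hochberg FDR at alpha.  The screen comes first: FDR is applied
over the candidates that pass the length and fold filters, mirroring a
screen-then-test workflow; peaks outside the screen keep q = 1.  *Loss* calls mirror the definition with
roles reversed, restricted to peaks with appreciable signal in the
comparison species (presence floor).  A small pseudo-density epsilon keeps
folds finite on zero-background peaks.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from crosspeak._stats import bh_qvalues, ranksum_pvalues
from crosspeak.errors import ValidationError
from crosspeak.genomic_io import SampleMeta


@dataclass
class AnalysisConfig:
    """Thresholds for classification and downstream resampling stages."""

    fold_threshold: float = 2.0       # F; secondary (adult re-call) uses 1.5
    min_length: int = 500             # bp
    fdr_alpha: float = 0.05
    pseudo_density: float = 0.1       # epsilon, ppm/kb
    fold_mode: str = "each_species"   # or "pooled_average"
    presence_floor: float = 1.0       # ppm/kb, depletion candidate universe
    distance_thresholds: tuple[int, ...] = (1_000_000, 500_000)
    n_sims: int = 10_000
    rng_seed: int = 0

    def __post_init__(self):
        if not self.fold_threshold > 1:
            raise ValidationError("fold_threshold must be > 1")
        if self.min_length < 1:
            raise ValidationError("min_length must be >= 1")
        if not 0 < self.fdr_alpha < 1:
            raise ValidationError("fdr_alpha must be in (0, 1)")
        if not self.pseudo_density > 0:
            raise ValidationError("pseudo_density must be > 0")
        if self.fold_mode not in ("each_species", "pooled_average"):
            raise ValidationError(f"unknown fold_mode {self.fold_mode!r}")
        if self.n_sims < 1:
            raise ValidationError("n_sims must be >= 1")


@dataclass
class CallRecord:
    peak_id: str
    target_mean: float
    comparison_means: dict[str, float]
    folds: dict[str, float]
    p: float
    q: float
    label: str  # gain | loss | none


def calls_to_frame(calls: Sequence[CallRecord]) -> pd.DataFrame:
    rows = []
    for c in calls:
        row = {"peak_id": c.peak_id, "target_mean": c.target_mean,
               "p": c.p, "q": c.q, "label": c.label}
        for sp, m in c.comparison_means.items():
            row[f"mean_{sp}"] = m
        for sp, f in c.folds.items():
            row[f"fold_vs_{sp}"] = f
        rows.append(row)
    return pd.DataFrame(rows).set_index("peak_id")


def _group_columns(samples: Sequence[SampleMeta], species: str,
                   cell_type: str, columns) -> list[str]:
    in_matrix = set(columns)
    return [s.sample_id for s in samples
            if s.species == species and s.cell_type == cell_type
            and s.sample_id in in_matrix]


def _classify(density: pd.DataFrame, samples: Sequence[SampleMeta],
              target_species: str, comparison_species: Sequence[str],
              lengths: Mapping[str, int] | pd.Series, cfg: AnalysisConfig,
              direction: str, cell_type: str,
              universe: pd.Index | None = None) -> list[CallRecord]:
    eps = cfg.pseudo_density
    tcols = _group_columns(samples, target_species, cell_type, density.columns)
    comp_cols = {sp: _group_columns(samples, sp, cell_type, density.columns)
                 for sp in comparison_species}
    if len(tcols) < 2:
        raise ValidationError(f"target group {target_species!r} has <2 samples")
    for sp, cols in comp_cols.items():
        if len(cols) < 2:
            raise ValidationError(f"comparison group {sp!r} has <2 samples")

    mat = density if universe is None else density.loc[universe]
    tmat = mat[tcols].to_numpy(float)
    target_mean = tmat.mean(axis=1)
    comp_means = {sp: mat[cols].to_numpy(float).mean(axis=1)
                  for sp, cols in comp_cols.items()}
    all_comp_cols = [c for cols in comp_cols.values() for c in cols]
    pooled_mean = mat[all_comp_cols].to_numpy(float).mean(axis=1)

    if direction == "gain":
        folds = {sp: (target_mean + eps) / (m + eps) for sp, m in comp_means.items()}
        pooled_fold = (target_mean + eps) / (pooled_mean + eps)
    else:
        folds = {sp: (m + eps) / (target_mean + eps) for sp, m in comp_means.items()}
        pooled_fold = (pooled_mean + eps) / (target_mean + eps)

    if cfg.fold_mode == "each_species":
        fold_pass = np.all(
            np.stack([f > cfg.fold_threshold for f in folds.values()]), axis=0
        )
    else:
        fold_pass = pooled_fold > cfg.fold_threshold

    lens = pd.Series(lengths).reindex(mat.index)
    if lens.isna().any():
        raise ValidationError("peak in matrix but not in peak set")
    len_pass = lens.to_numpy(float) >= cfg.min_length

    test_mat = np.concatenate([tmat, mat[all_comp_cols].to_numpy(float)], axis=1)
    pvals = ranksum_pvalues(test_mat, len(tcols))
    # screen first, then correct: FDR runs over the peaks that survive the
    # length and fold filters; peaks never tested keep q = 1
    candidates = fold_pass & len_pass
    qvals = np.ones_like(pvals)
    if candidates.any():
        qvals[candidates] = bh_qvalues(pvals[candidates])
    sig_pass = qvals <= cfg.fdr_alpha

    label = direction if direction in ("gain", "loss") else "none"
    labels = np.where(fold_pass & len_pass & sig_pass, label, "none")

    records = []
    fold_report = dict(folds)
    fold_report["pooled"] = pooled_fold
    for i, pid in enumerate(mat.index):
        records.append(CallRecord(
            peak_id=pid,
            target_mean=float(target_mean[i]),
            comparison_means={sp: float(m[i]) for sp, m in comp_means.items()},
            folds={sp: float(f[i]) for sp, f in fold_report.items()},
            p=float(pvals[i]),
            q=float(qvals[i]),
            label=str(labels[i]),
        ))
    return records


def call_gain(density: pd.DataFrame, samples: Sequence[SampleMeta],
              target_species: str, comparison_species: Sequence[str],
              lengths: Mapping[str, int] | pd.Series, cfg: AnalysisConfig,
              cell_type: str = "NeuN+") -> list[CallRecord]:
    """Classify peaks with target-species-specific density gain."""
    return _classify(density, samples, target_species, comparison_species,
                     lengths, cfg, "gain", cell_type)


def call_depletion(density: pd.DataFrame, samples: Sequence[SampleMeta],
                   target_species: str, comparison_species: Sequence[str],
                   lengths: Mapping[str, int] | pd.Series, cfg: AnalysisConfig,
                   cell_type: str = "NeuN+") -> list[CallRecord]:
    """Classify peaks depleted in the target species (reciprocal approach).

    The candidate universe is restricted to peaks with pooled comparison
    mean density >= cfg.presence_floor, standing in for peak detection in
    the comparison species.
    """
    comp_cols = [c for sp in comparison_species
                 for c in _group_columns(samples, sp, cell_type, density.columns)]
    pooled = density[comp_cols].mean(axis=1)
    universe = density.index[pooled >= cfg.presence_floor]
    return _classify(density, samples, target_species, comparison_species,
                     lengths, cfg, "loss", cell_type, universe=universe)


def filter_celltype_enriched(calls: Sequence[CallRecord], density: pd.DataFrame,
                             samples: Sequence[SampleMeta], cfg: AnalysisConfig,
                             target_species: str = "human",
                             neuronal_cell_type: str = "NeuN+",
                             reference_cell_types: Sequence[str] = ("NeuN-",),
                             ) -> list[CallRecord]:
    """Restrict calls to peaks selectively enriched in neuronal chromatin.

    Keeps calls whose neuronal mean exceeds F x each reference cell type's
    mean (with epsilon), with BH q <= alpha on the neuronal-vs-first-reference
    rank-sum test (computed over the input call set).
    """
    labeled = [c for c in calls if c.label != "none"]
    if not labeled:
        return []
    eps = cfg.pseudo_density
    neu_cols = _group_columns(samples, target_species, neuronal_cell_type,
                              density.columns)
    ref_cols = {ct: _group_columns(samples, target_species, ct, density.columns)
                for ct in reference_cell_types}
    for ct, cols in ref_cols.items():
        if not cols:
            raise ValidationError(f"reference cell type {ct!r} absent from samples")
    ids = [c.peak_id for c in labeled]
    sub = density.loc[ids]
    neu_mean = sub[neu_cols].to_numpy(float).mean(axis=1)
    fold_pass = np.ones(len(ids), bool)
    for ct, cols in ref_cols.items():
        ref_mean = sub[cols].to_numpy(float).mean(axis=1)
        fold_pass &= (neu_mean + eps) / (ref_mean + eps) > cfg.fold_threshold

    primary_ref = list(ref_cols.values())[0]
    test_mat = np.concatenate(
        [sub[neu_cols].to_numpy(float), sub[primary_ref].to_numpy(float)], axis=1
    )
    pvals = ranksum_pvalues(test_mat, len(neu_cols))
    qvals = bh_qvalues(pvals)
    keep = fold_pass & (qvals <= cfg.fdr_alpha)
    return [replace(c, p=float(pvals[i]), q=float(qvals[i]))
            for i, c in enumerate(labeled) if keep[i]]


def intersect_calls(calls_a: set[str] | Sequence[str],
                    calls_b: set[str] | Sequence[str]) -> dict:
    """Exact peak-id set intersection report (|A|, |B|, |A&B|, Jaccard)."""
    a, b = set(calls_a), set(calls_b)
    inter = a & b
    union = a | b
    return {
        "n_a": len(a),
        "n_b": len(b),
        "n_intersection": len(inter),
        "jaccard": len(inter) / len(union) if union else 0.0,
        "intersection": sorted(inter),
    }


def select_control_peaks(density: pd.DataFrame, samples: Sequence[SampleMeta],
                         k: int, cfg: AnalysisConfig,
                         lengths: Mapping[str, int] | pd.Series | None = None,
                         target_lengths: Sequence[int] | None = None,
                         length_window: int | None = None,
                         species: Sequence[str] = ("human", "chimpanzee", "macaque"),
                         cell_type: str = "NeuN+") -> list[str]:
    """Peaks with the least cross-species difference in density.

    Ranks peaks by the maximum absolute log-fold across all species-pair
    group means (with epsilon) and returns the k smallest; optionally
    restricted to peaks whose length falls within +/- length_window of some
    target-set length.
    """
    eps = cfg.pseudo_density
    means = []
    for sp in species:
        cols = _group_columns(samples, sp, cell_type, density.columns)
        if not cols:
            raise ValidationError(f"no samples for species {sp!r}")
        means.append(density[cols].to_numpy(float).mean(axis=1))
    logm = np.log(np.stack(means) + eps)
    score = np.zeros(density.shape[0])
    for i in range(len(species)):
        for j in range(i + 1, len(species)):
            score = np.maximum(score, np.abs(logm[i] - logm[j]))

    eligible = np.ones(density.shape[0], bool)
    if length_window is not None and target_lengths is not None:
        lens = pd.Series(lengths).reindex(density.index).to_numpy(float)
        tl = np.sort(np.asarray(target_lengths, float))
        idx = np.searchsorted(tl, lens)
        near = np.full(lens.shape, np.inf)
        has_right = idx < tl.size
        near[has_right] = np.abs(tl[np.minimum(idx, tl.size - 1)][has_right]
                                 - lens[has_right])
        has_left = idx > 0
        near[has_left] = np.minimum(near[has_left],
                                    np.abs(tl[idx[has_left] - 1] - lens[has_left]))
        eligible = near <= length_window

    pool_ids = density.index[eligible]
    if k > len(pool_ids):
        raise ValidationError(f"k={k} exceeds eligible pool of {len(pool_ids)}")
    order = np.argsort(score[eligible], kind="stable")
    return list(pool_ids[order[:k]])
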