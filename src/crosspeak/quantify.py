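"""Tag-count normalization and sample-to-sample correlation.

Densities are expressed in ppm per kb: tags per million mapped tags in the
sample's library, further divided by the peak length in kb so peaks of
different lengths are comparable.  Raw ppm (no length term) is available
via ``per_kb=False``.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from crosspeak.errors import ValidationError
from crosspeak.genomic_io import SampleMeta


def normalize_density(counts: pd.DataFrame, samples: Sequence[SampleMeta],
                      lengths: Mapping[str, int] | pd.Series,
                      per_kb: bool = True) -> pd.DataFrame:
    """Convert raw tag counts to ppm (optionally per-kb) densities.

    density(p, s) = count(p, s) / (library_size(s) / 1e6) / (length(p) / 1e3)
    """
    meta = {s.sample_id: s for s in samples}
    missing = [c for c in counts.columns if c not in meta]
    if missing:
        raise ValidationError(f"samples missing from metadata: {missing}")
    libs = np.array([meta[c].library_size for c in counts.columns], float)
    dens = counts.to_numpy(float) / (libs / 1e6)[None, :]
    if per_kb:
        lens = pd.Series(lengths).reindex(counts.index)
        if lens.isna().any():
            raise ValidationError(
                f"peak lengths missing for {list(counts.index[lens.isna()])[:5]}"
            )
        dens = dens / (lens.to_numpy(float) / 1e3)[:, None]
    return pd.DataFrame(dens, index=counts.index, columns=counts.columns)


def input_correct(density: pd.DataFrame, input_density: pd.Series,
                  pseudo: float = 0.1) -> pd.DataFrame:
    """Rescale densities by per-peak input signal (off by default upstream).

    corrected(p, s) = density(p, s) * mean(input) / (input(p) + pseudo)

    Used when chromatin accessibility/nucleosome background differs by
    locus (the chimpanzee-genome analysis uses a mononucleosomal input
    library this way).
    """
    if pseudo < 0:
        raise ValidationError("pseudo must be non-negative")
    inp = input_density.reindex(density.index)
    if inp.isna().any():
        raise ValidationError("input densities do not cover all peaks")
    scale = inp.mean() / (inp + pseudo)
    return density.mul(scale, axis=0)


def sample_correlations(density: pd.DataFrame,
                        subset: Sequence[str] | None = None) -> pd.DataFrame:
    """Pearson R between all sample pairs over the chosen peak rows.

    Zero-variance samples yield NaN correlations for their pairs and a
    warning — never a silent 0.
    """
    mat = density.loc[list(subset)] if subset is not None else density
    if mat.shape[0] < 2:
        raise ValidationError("need at least 2 peaks to correlate samples")
    if not np.isfinite(mat.to_numpy(float)).all():
        raise ValidationError("densities must be finite")
    zero_var = mat.std(axis=0, ddof=0) == 0
    if zero_var.any():
        warnings.warn(
            f"zero-variance samples, correlations undefined: "
            f"{list(mat.columns[zero_var])}",
            stacklevel=2,
        )
    corr = mat.corr(method="pearson")
    # pandas leaves the diagonal at 1 even for zero-variance columns; mark
    # every pair involving such a sample as undefined instead
    if zero_var.any():
        bad = mat.columns[zero_var]
        corr.loc[bad, :] = np.nan
        corr.loc[:, bad] = np.nan
    np.fill_diagonal(corr.values, 1.0)
    return corr


def correlation_summary(corr: pd.DataFrame,
                        samples: Sequence[SampleMeta]) -> pd.DataFrame:
    """Mean +/- SD of off-diagonal R within/between (species, cell type) groups."""
    meta = {s.sample_id: s for s in samples}
    groups = {sid: (meta[sid].species, meta[sid].cell_type) for sid in corr.columns}
    rows = []
    cols = list(corr.columns)
    buckets: dict[tuple, list[float]] = {}
    for i, a in enumerate(cols):
        for b in cols[i + 1:]:
            key = tuple(sorted([groups[a], groups[b]]))
            buckets.setdefault(key, []).append(corr.loc[a, b])
    for (ga, gb), vals in sorted(buckets.items()):
        arr = np.asarray(vals, float)
        rows.append(
            {
                "group_a": f"{ga[0]}/{ga[1]}",
                "group_b": f"{gb[0]}/{gb[1]}",
                "n_pairs": arr.size,
                "mean_r": float(np.nanmean(arr)),
                "sd_r": float(np.nanstd(arr, ddof=1)) if arr.size > 1 else 0.0,
            }
        )
    return pd.DataFrame(rows)
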