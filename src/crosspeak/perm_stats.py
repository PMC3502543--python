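"""Resampling nulls for interval statistics.

The null model resamples peak *identities* from the full atlas (preserving
the atlas's chromosomal and positional structure) rather than re-placing
intervals uniformly on the genome: the question is always whether a chosen
subset of real peaks is unusual relative to equally-sized random subsets
of the same pool.

Two statistics ship with fast batch implementations:

* ``PairingStatistic`` — number of subset peaks with at least one other
  subset member on the same chromosome closer than ``d`` (midpoint
  distance by default; a pair-counting variant and edge-to-edge distances
  are options).
* ``SubsetCountStatistic`` — number of subset peaks carrying a boolean
  mark (e.g. overlapping an annotation category).

``resample_null`` also accepts any plain callable on index arrays.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from intervaltree import IntervalTree

from crosspeak.errors import ValidationError
from crosspeak.genomic_io import AnnotationSet, Peak


@dataclass
class PermResult:
    statistic: str
    observed: float
    null_mean: float
    null_sd: float
    fold_enrichment: float
    p: float
    n_sims: int
    rng_seed: int
    direction: str  # greater | less

    def as_dict(self) -> dict:
        return {
            "statistic": self.statistic,
            "observed": self.observed,
            "null_mean": self.null_mean,
            "null_sd": self.null_sd,
            "fold_enrichment": self.fold_enrichment,
            "p": self.p,
            "n_sims": self.n_sims,
            "rng_seed": self.rng_seed,
            "direction": self.direction,
        }


@dataclass
class OverlapCategories:
    """Counts over (target?, other?) annotation membership for a peak set."""

    both: int
    target_only: int
    other_only: int
    neither: int

    @property
    def total(self) -> int:
        return self.both + self.target_only + self.other_only + self.neither

    def as_dict(self) -> dict:
        return {"both": self.both, "target_only": self.target_only,
                "other_only": self.other_only, "neither": self.neither}


# ---------------------------------------------------------------------------
# statistics


def _peak_arrays(peaks: Sequence[Peak]):
    chroms = sorted({p.chrom for p in peaks})
    code = {c: i for i, c in enumerate(chroms)}
    return (np.array([code[p.chrom] for p in peaks], np.int64),
            np.array([p.midpoint for p in peaks], np.float64),
            np.array([p.start for p in peaks], np.float64),
            np.array([p.end for p in peaks], np.float64))


def pairing_count(peaks: Sequence[Peak], d: int, anchor: str = "midpoint",
                  count: str = "peaks") -> int:
    """Subset peaks with a same-chromosome neighbor closer than ``d`` bp.

    ``count="pairs"`` instead counts unordered pairs at distance < d.
    ``anchor="edge"`` uses gap between intervals (0 when they overlap).
    """
    if d <= 0:
        raise ValidationError("d must be > 0")
    chrom, mid, start, end = _peak_arrays(peaks)
    return int(_pairing_single(chrom, mid, start, end, d, anchor, count))


def _pairing_single(chrom, mid, start, end, d, anchor, count):
    n = chrom.size
    if n < 2:
        return 0
    if anchor == "midpoint":
        order = np.lexsort((mid, chrom))
        c, m = chrom[order], mid[order]
        gap = np.diff(m)
        same = np.diff(c) == 0
        near = (gap < d) & same
    elif anchor == "edge":
        order = np.lexsort((start, chrom))
        c, s, e = chrom[order], start[order], end[order]
        # sorted by start; neighbor gap = next start - running max end
        gap = s[1:] - np.maximum.accumulate(e)[:-1]
        same = np.diff(c) == 0
        near = (np.maximum(gap, 0) < d) & same
    else:
        raise ValidationError(f"unknown anchor {anchor!r}")
    if count == "pairs":
        if anchor != "midpoint":
            raise ValidationError("pair counting supports midpoint anchor only")
        # adjacent-only counting undercounts pairs; do it exactly per chrom
        return _pair_count_exact(c, m, d)
    if count != "peaks":
        raise ValidationError(f"unknown count mode {count!r}")
    has = np.zeros(n, bool)
    has[:-1] |= near
    has[1:] |= near
    return int(has.sum())


def _pair_count_exact(chrom_sorted, pos_sorted, d):
    total = 0
    for c in np.unique(chrom_sorted):
        pos = pos_sorted[chrom_sorted == c]
        right = np.searchsorted(pos, pos + d, side="left")
        total += int((right - np.arange(pos.size) - 1).sum())
    return total


@dataclass
class PairingStatistic:
    """Batchable pairing-within-distance statistic over a fixed pool."""

    pool: Sequence[Peak]
    d: int
    anchor: str = "midpoint"
    count: str = "peaks"

    def __post_init__(self):
        self._chrom, self._mid, self._start, self._end = _peak_arrays(self.pool)
        self.name = f"pairing_lt_{self.d}bp"

    def __call__(self, idx: np.ndarray) -> float:
        return _pairing_single(self._chrom[idx], self._mid[idx],
                               self._start[idx], self._end[idx],
                               self.d, self.anchor, self.count)

    def batch(self, idx_matrix: np.ndarray) -> np.ndarray:
        if self.anchor != "midpoint" or self.count != "peaks":
            return np.array([self(row) for row in idx_matrix], float)
        chrom = self._chrom[idx_matrix]
        mid = self._mid[idx_matrix]
        # sort each row by (chrom, midpoint) via a composite key
        span = mid.max() + 1.0 if mid.size else 1.0
        key = chrom * span + mid
        order = np.argsort(key, axis=1, kind="stable")
        c = np.take_along_axis(chrom, order, axis=1)
        m = np.take_along_axis(mid, order, axis=1)
        near = (np.diff(m, axis=1) < self.d) & (np.diff(c, axis=1) == 0)
        has = np.zeros(idx_matrix.shape, bool)
        has[:, :-1] |= near
        has[:, 1:] |= near
        return has.sum(axis=1).astype(float)


@dataclass
class SubsetCountStatistic:
    """Count of subset members carrying a boolean mark."""

    mark: np.ndarray
    name: str = "marked_count"

    def __call__(self, idx: np.ndarray) -> float:
        return float(self.mark[idx].sum())

    def batch(self, idx_matrix: np.ndarray) -> np.ndarray:
        return self.mark[idx_matrix].sum(axis=1).astype(float)


# ---------------------------------------------------------------------------
# annotation overlap


def annotation_membership(peaks: Sequence[Peak], annot: AnnotationSet) -> np.ndarray:
    """Boolean array: peak overlaps >= 1 bp of any interval in the set."""
    trees: dict[str, IntervalTree] = {}
    for chrom, start, end in annot.intervals:
        trees.setdefault(chrom, IntervalTree()).addi(start, end)
    out = np.zeros(len(peaks), bool)
    for i, p in enumerate(peaks):
        tree = trees.get(p.chrom)
        if tree is not None and tree.overlap(p.start, p.end):
            out[i] = True
    return out


def overlap_categories(peaks: Sequence[Peak], annot_target: AnnotationSet,
                       annot_other: AnnotationSet) -> OverlapCategories:
    """Partition a peak set by (target, other) annotation membership."""
    in_t = annotation_membership(peaks, annot_target)
    in_o = annotation_membership(peaks, annot_other)
    return OverlapCategories(
        both=int((in_t & in_o).sum()),
        target_only=int((in_t & ~in_o).sum()),
        other_only=int((~in_t & in_o).sum()),
        neither=int((~in_t & ~in_o).sum()),
    )


# ---------------------------------------------------------------------------
# resampling


def resample_null(pool_size: int, subset_size: int,
                  statistic: Callable[[np.ndarray], float], observed: float,
                  n_sims: int, seed: int, direction: str = "greater",
                  name: str | None = None,
                  batch_size: int = 2000) -> PermResult:
    """Empirical null for ``statistic`` over uniform subsets of the pool.

    Draws ``n_sims`` subsets of ``subset_size`` indices without replacement
    from ``range(pool_size)``, evaluates the statistic on each, and returns
    the add-one empirical p in the requested direction:
    p = (1 + #{null >= observed}) / (1 + n_sims)   (``greater``)
    """
    if subset_size > pool_size:
        raise ValidationError("subset_size exceeds pool size")
    if n_sims < 1:
        raise ValidationError("n_sims must be >= 1")
    if direction not in ("greater", "less"):
        raise ValidationError(f"unknown direction {direction!r}")
    rng = np.random.default_rng(seed)
    null = np.empty(n_sims)
    use_batch = hasattr(statistic, "batch")
    done = 0
    while done < n_sims:
        m = min(batch_size, n_sims - done)
        keys = rng.random((m, pool_size))
        idx = np.argpartition(keys, subset_size - 1, axis=1)[:, :subset_size]
        if use_batch:
            null[done:done + m] = statistic.batch(idx)
        else:
            for j in range(m):
                null[done + j] = statistic(idx[j])
        done += m
    if direction == "greater":
        exceed = int(np.count_nonzero(null >= observed))
    else:
        exceed = int(np.count_nonzero(null <= observed))
    null_mean = float(null.mean())
    null_sd = float(null.std(ddof=1)) if n_sims > 1 else 0.0
    return PermResult(
        statistic=name or getattr(statistic, "name", "statistic"),
        observed=float(observed),
        null_mean=null_mean,
        null_sd=null_sd,
        fold_enrichment=float(observed / null_mean) if null_mean > 0 else float("inf"),
        p=(1 + exceed) / (1 + n_sims),
        n_sims=n_sims,
        rng_seed=seed,
        direction=direction,
    )


def enrichment_test(subset_ids: Sequence[str], pool: Sequence[Peak],
                    *, d: int | None = None,
                    annotations: tuple[AnnotationSet, AnnotationSet] | None = None,
                    n_sims: int = 10_000, seed: int = 0,
                    direction: str = "greater", anchor: str = "midpoint",
                    count: str = "peaks"):
    """Test a peak subset against random same-size subsets of the pool.

    Clustering mode (``d`` given): statistic = pairing count within d.
    Overlap mode (``annotations`` given): one PermResult per overlap
    category count, returned as a dict.
    """
    pool_ids = [p.id for p in pool]
    pos = {pid: i for i, pid in enumerate(pool_ids)}
    missing = [s for s in subset_ids if s not in pos]
    if missing:
        raise ValidationError(f"subset peaks not in pool: {missing[:5]}")
    sub_idx = np.array([pos[s] for s in subset_ids], np.int64)

    if (d is None) == (annotations is None):
        raise ValidationError("provide exactly one of d (clustering) or annotations")

    if d is not None:
        stat = PairingStatistic(pool, d, anchor=anchor, count=count)
        observed = stat(sub_idx)
        return resample_null(len(pool), sub_idx.size, stat, observed,
                             n_sims, seed, direction)

    annot_target, annot_other = annotations
    in_t = annotation_membership(pool, annot_target)
    in_o = annotation_membership(pool, annot_other)
    marks = {
        "both": in_t & in_o,
        "target_only": in_t & ~in_o,
        "other_only": ~in_t & in_o,
        "neither": ~in_t & ~in_o,
    }
    results = {}
    for i, (cat, mark) in enumerate(marks.items()):
        stat = SubsetCountStatistic(mark, name=f"overlap_{cat}")
        observed = stat(sub_idx)
        results[cat] = resample_null(len(pool), sub_idx.size, stat, observed,
                                     n_sims, seed + i, direction)
    return results
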