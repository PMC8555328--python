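"""Masking cross-validation of the placement algorithm.

Mapped markers are split into k random, near-equal, non-overlapping
folds; each fold in turn is stripped from the map, placed back by LD
against the remaining anchors, and scored against its known positions:

* efficiency — % of masked markers assigned to any linkage group;
* accuracy  — % of placed markers assigned to the *correct* group;
* precision — mean and SD of |known - estimated| cM over markers placed
  on the correct group, plus the Pearson correlation of known vs
  estimated positions over the same set.

Wrong-chromosome placements count against accuracy but are excluded
from the distance and correlation statistics, where a cM difference
across different chromosomes would be meaningless.

`threshold_sweep` re-scores the same folds over a grid of r² cutoffs,
reusing each fold's r² profiles (LD does not depend on the cutoff) so
the sweep isolates the threshold effect exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _sps

from . import ld, placement
from .exceptions import ParameterError
from .io import GeneticMap, GenotypeMatrix

logger = logging.getLogger(__name__)

METRICS = ["efficiency", "accuracy", "mean_abs_distance", "sd_abs_distance", "pearson_r"]


def make_folds(mapped_ids: Iterable[str], k: int, seed: int) -> list[list[str]]:
    """Random partition of marker ids into k folds with sizes differing by <= 1.

    Ids are sorted before shuffling so the partition depends only on the
    id set and the seed, not on input order.
    """
    ids = sorted(set(mapped_ids))
    if k < 2:
        raise ParameterError(f"fold count k={k} must be >= 2")
    if k > len(ids):
        raise ParameterError(f"k={k} exceeds number of mapped markers ({len(ids)})")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    return [[ids[i] for i in chunk] for chunk in np.array_split(perm, k)]


@dataclass
class FoldScore:
    """Metrics for one cross-validation fold."""

    n_masked: int
    n_placed: int
    n_correct: int
    efficiency: float          # % of masked markers placed
    accuracy: float            # % of placed markers on the true linkage group (NaN if none placed)
    mean_abs_distance: float   # cM, over placed-and-correct markers
    sd_abs_distance: float
    pearson_r: float           # known vs estimated cM over placed-and-correct markers

    def as_dict(self) -> dict[str, float]:
        return {m: getattr(self, m) for m in METRICS}


def score_placements(
    placements: Sequence[placement.Placement], truth: GeneticMap
) -> FoldScore:
    """Score a set of placements against the held-out true map entries."""
    n_masked = len(placements)
    placed = [p for p in placements if p.placed]
    correct = [p for p in placed if p.linkage_group == truth.linkage_group(p.marker_id)]
    efficiency = 100.0 * len(placed) / n_masked if n_masked else float("nan")
    accuracy = 100.0 * len(correct) / len(placed) if placed else float("nan")
    if correct:
        known = np.array([truth.position(p.marker_id) for p in correct])
        est = np.array([p.position for p in correct])
        err = np.abs(known - est)
        mean_d = float(err.mean())
        sd_d = float(err.std(ddof=1)) if len(err) > 1 else 0.0
        if len(correct) > 1 and known.std() > 0 and est.std() > 0:
            pearson = float(_sps.pearsonr(known, est).statistic)
        else:
            pearson = float("nan")
    else:
        mean_d = sd_d = pearson = float("nan")
    return FoldScore(
        n_masked=n_masked,
        n_placed=len(placed),
        n_correct=len(correct),
        efficiency=efficiency,
        accuracy=accuracy,
        mean_abs_distance=mean_d,
        sd_abs_distance=sd_d,
        pearson_r=pearson,
    )


@dataclass
class CVReport:
    """Per-fold and aggregate cross-validation metrics."""

    k: int
    threshold: float
    seed: int
    per_fold: list[FoldScore]
    folds: list[list[str]] = field(repr=False, default_factory=list)

    @property
    def aggregate(self) -> dict[str, float]:
        """Unweighted mean and SD of each metric over folds (NaN-aware)."""
        out: dict[str, float] = {}
        for m in METRICS:
            vals = np.array([getattr(f, m) for f in self.per_fold], dtype=float)
            with np.errstate(invalid="ignore"):
                out[f"mean_{m}"] = float(np.nanmean(vals)) if not np.isnan(vals).all() else float("nan")
                defined = vals[~np.isnan(vals)]
                out[f"sd_{m}"] = float(defined.std(ddof=1)) if defined.size > 1 else 0.0
        return out

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for i, f in enumerate(self.per_fold, start=1):
            row = {"fold": str(i), "n_masked": f.n_masked,
                   "n_placed": f.n_placed, "n_correct": f.n_correct}
            row.update(f.as_dict())
            rows.append(row)
        agg = self.aggregate
        mean_row = {"fold": "mean"}
        sd_row = {"fold": "sd"}
        for m in METRICS:
            mean_row[m] = agg[f"mean_{m}"]
            sd_row[m] = agg[f"sd_{m}"]
        rows.extend([mean_row, sd_row])
        return pd.DataFrame(rows)


class _FoldCache:
    """Per-fold LD profiles, reusable across r² thresholds."""

    def __init__(self, g: GenotypeMatrix, gmap: GeneticMap, fold: list[str],
                 maf_min: float, min_complete: int):
        self.fold = fold
        self.reduced = gmap.drop(fold, require_linked=False)
        short = [lg for lg, members in self.reduced.groups().items() if len(members) < 2]
        if short:
            logger.warning(
                "fold leaves linkage group(s) %s with < 2 anchors; evaluating anyway",
                short[:5],
            )
        self.anchors = [m for m in self.reduced.markers if m in g]
        self.anchor_lgs = [self.reduced.linkage_group(a) for a in self.anchors]
        self.anchor_pos = np.array([self.reduced.position(a) for a in self.anchors])

        from .filters import marker_stats

        stats = {s.marker_id: s for s in marker_stats(g.take_markers(fold))}
        self.blocked: dict[str, str] = {}
        runnable = []
        for m in fold:
            s = stats[m]
            if s.monomorphic:
                self.blocked[m] = "monomorphic"
            elif not s.maf > maf_min:
                self.blocked[m] = f"maf {s.maf:.4g} <= {maf_min:g}"
            else:
                runnable.append(m)
        self.runnable = runnable
        if runnable:
            self.r2, _ = ld.r2_matrix(g, runnable, self.anchors, min_complete=min_complete)
        else:
            self.r2 = np.empty((0, len(self.anchors)))

    def place(self, threshold: float) -> placement.PlacementList:
        out = placement.PlacementList()
        rows = {m: i for i, m in enumerate(self.runnable)}
        for m in self.fold:
            if m in self.blocked:
                out.append(placement.Placement(
                    m, "unplaced", reason=placement.UNDEFINED_LD, detail=self.blocked[m]))
            else:
                out.append(placement._place_one(
                    m, self.anchors, self.anchor_lgs, self.anchor_pos,
                    self.r2[rows[m]], threshold))
        return out


def cross_validate(
    g: GenotypeMatrix,
    gmap: GeneticMap,
    k: int = 20,
    threshold: float = 0.1,
    seed: int = 0,
    maf_min: float = 0.0,
    min_complete: int = ld.DEFAULT_MIN_COMPLETE,
) -> CVReport:
    """k-fold masking cross-validation of LD placement on a mapped set."""
    folds = make_folds([m for m in gmap.markers if m in g], k, seed)
    scores = []
    for fold in folds:
        cache = _FoldCache(g, gmap, fold, maf_min, min_complete)
        scores.append(score_placements(cache.place(threshold), gmap))
    return CVReport(k=k, threshold=threshold, seed=seed, per_fold=scores, folds=folds)


def threshold_sweep(
    g: GenotypeMatrix,
    gmap: GeneticMap,
    thresholds: Sequence[float] = (0.01, 0.05, 0.1, 0.2, 0.3, 0.4, 0.5),
    k: int = 20,
    seed: int = 0,
    maf_min: float = 0.0,
    min_complete: int = ld.DEFAULT_MIN_COMPLETE,
) -> pd.DataFrame:
    """Cross-validate over a grid of r² thresholds with a shared fold partition.

    Returns one row per threshold with the mean (over folds) of every
    metric; the same folds and the same per-fold LD profiles are reused
    for each threshold, so differences are attributable to the cutoff
    alone.
    """
    thresholds = list(thresholds)
    if sorted(thresholds) != thresholds:
        raise ParameterError("thresholds must be sorted ascending")
    folds = make_folds([m for m in gmap.markers if m in g], k, seed)
    caches = [_FoldCache(g, gmap, fold, maf_min, min_complete) for fold in folds]
    rows = []
    for t in thresholds:
        report = CVReport(
            k=k, threshold=t, seed=seed,
            per_fold=[score_placements(c.place(t), gmap) for c in caches],
            folds=folds,
        )
        row = {"threshold": t}
        row.update(report.aggregate)
        rows.append(row)
    return pd.DataFrame(rows)
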