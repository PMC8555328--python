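"""Linkage disequilibrium from genotype allele counts, and LD decay.

r² here is the squared Pearson correlation between two markers' 0/1/2
allele-count vectors over pairwise-complete samples — no phasing.  For
large samples this genotype-count r² is equivalent to the classical
haplotype-frequency r², and it extends unchanged to pseudo-diploid coded
polyploids, which is exactly why it suits sparse-map marker placement.

A pair's r² is *undefined* (returned as NaN) when fewer than
``min_complete`` samples carry both calls or either restricted vector is
constant; downstream code treats NaN as "no evidence", never as zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _sps

from .exceptions import AnalysisError, ContractError
from .io import MISSING, GeneticMap, GenotypeMatrix

DEFAULT_MIN_COMPLETE = 10

_VAR_EPS = 1e-12


def pairwise_r2(
    x: Sequence[int] | np.ndarray,
    y: Sequence[int] | np.ndarray,
    min_complete: int = DEFAULT_MIN_COMPLETE,
) -> float:
    """Squared Pearson correlation of two genotype call vectors.

    Restricts to samples where both calls are non-missing; returns NaN
    when fewer than ``min_complete`` complete pairs remain or either
    restricted vector has zero variance.
    """
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape or x.ndim != 1:
        raise ContractError(f"call vectors differ in shape: {x.shape} vs {y.shape}")
    ok = (x != MISSING) & (y != MISSING)
    n = int(ok.sum())
    if n < max(2, min_complete):
        return float("nan")
    xv = x[ok].astype(np.float64)
    yv = y[ok].astype(np.float64)
    xv -= xv.mean()
    yv -= yv.mean()
    vx = float(xv @ xv)
    vy = float(yv @ yv)
    if vx <= _VAR_EPS or vy <= _VAR_EPS:
        return float("nan")
    c = float(xv @ yv)
    return min(1.0, (c * c) / (vx * vy))


def r2_matrix(
    g: GenotypeMatrix,
    target_ids: Sequence[str],
    anchor_ids: Sequence[str],
    min_complete: int = DEFAULT_MIN_COMPLETE,
) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise-complete r² between every target and every anchor marker.

    Returns ``(r2, n_complete)`` arrays of shape (targets, anchors); r² is
    NaN where undefined.  Implemented with masked cross-products so the
    whole block costs a handful of matrix multiplies.
    """
    T = g.columns(target_ids).astype(np.float64)
    A = g.columns(anchor_ids).astype(np.float64)
    Mt = (T != MISSING).astype(np.float64)
    Ma = (A != MISSING).astype(np.float64)
    T = T * Mt  # zero out missing so products ignore them
    A = A * Ma
    n = Mt.T @ Ma
    st = T.T @ Ma
    sa = Mt.T @ A
    stt = (T * T).T @ Ma
    saa = Mt.T @ (A * A)
    sta = T.T @ A
    with np.errstate(divide="ignore", invalid="ignore"):
        cov = n * sta - st * sa
        var_t = n * stt - st * st
        var_a = n * saa - sa * sa
        r2 = (cov * cov) / (var_t * var_a)
    r2[(var_t <= _VAR_EPS * np.maximum(n, 1) ** 2) | (var_a <= _VAR_EPS * np.maximum(n, 1) ** 2)] = np.nan
    r2[n < max(2, min_complete)] = np.nan
    return np.minimum(r2, 1.0), n.astype(np.int64)


@dataclass
class LDProfile:
    """One unmapped marker's r² against every eligible mapped marker.

    ``anchors`` holds (anchor_id, r2, n_complete) for pairs with a
    defined r²; undefined pairs are only counted in ``n_undefined``.
    """

    target_id: str
    anchors: list[tuple[str, float, int]] = field(default_factory=list)
    n_undefined: int = 0

    @property
    def anchor_ids(self) -> list[str]:
        return [a for a, _, _ in self.anchors]

    def __len__(self) -> int:
        return len(self.anchors)


def ld_profile(
    g: GenotypeMatrix,
    target_id: str,
    mapped_ids: Iterable[str],
    min_complete: int = DEFAULT_MIN_COMPLETE,
) -> LDProfile:
    """r² of one target marker against a set of mapped markers."""
    mapped = list(mapped_ids)
    if target_id in set(mapped):
        raise ContractError(f"target {target_id!r} is itself in the mapped set")
    r2, n = r2_matrix(g, [target_id], mapped, min_complete=min_complete)
    profile = LDProfile(target_id=target_id)
    for j, anchor in enumerate(mapped):
        v = r2[0, j]
        if np.isnan(v):
            profile.n_undefined += 1
        else:
            profile.anchors.append((anchor, float(v), int(n[0, j])))
    return profile


def intra_chromosomal_pairs(
    g: GenotypeMatrix,
    gmap: GeneticMap,
    max_distance: float = 100.0,
    min_complete: int = DEFAULT_MIN_COMPLETE,
) -> pd.DataFrame:
    """All same-linkage-group marker pairs within ``max_distance`` cM.

    Returns a DataFrame with columns marker_1, marker_2, linkage_group,
    distance_cM, r2, n_complete — one row per unordered pair with a
    defined r².  Pairs farther apart than ``max_distance`` (default 100
    cM) are excluded, matching common practice for decay plots.
    """
    records: list[tuple] = []
    for lg, members in gmap.groups().items():
        members = [m for m in members if m in g]
        if len(members) < 2:
            continue
        pos = np.array([gmap.position(m) for m in members])
        r2, n = r2_matrix(g, members, members, min_complete=min_complete)
        iu, ju = np.triu_indices(len(members), k=1)
        dist = np.abs(pos[iu] - pos[ju])
        keep = (dist <= max_distance) & ~np.isnan(r2[iu, ju])
        for i, j, d in zip(iu[keep], ju[keep], dist[keep]):
            records.append(
                (members[i], members[j], lg, float(d), float(r2[i, j]), int(n[i, j]))
            )
    return pd.DataFrame(
        records,
        columns=["marker_1", "marker_2", "linkage_group", "distance_cM", "r2", "n_complete"],
    )


@dataclass
class DecayProfile:
    """LD-decay summary: raw pairs, smoothed curve, threshold crossing."""

    distances: np.ndarray
    r2: np.ndarray
    grid: np.ndarray
    smooth: np.ndarray
    threshold: float
    decay_distance: float | None
    crossed: bool
    percentile_of_threshold: float

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"distance_cM": self.grid, "smoothed_r2": self.smooth})


def ld_decay(
    pairs: pd.DataFrame | Iterable[tuple[float, float]],
    threshold: float = 0.1,
    span: float = 0.5,
    smoother: str = "loess",
    bin_width: float = 1.0,
    grid_points: int = 200,
    min_pairs: int = 20,
) -> DecayProfile:
    """Smooth r² against genetic distance and locate the decay distance.

    Fits a LOESS curve (``span`` = fraction of pairs in each local fit;
    ``smoother="bins"`` uses fixed-width distance-bin means instead) on a
    uniform grid over the observed distance range.  The decay distance is
    the smallest grid distance at which the smoothed curve falls to or
    below ``threshold``; if the curve never crosses, ``decay_distance``
    is None and ``crossed`` False.  ``percentile_of_threshold`` is the
    empirical percentile of ``threshold`` within the raw r² values —
    e.g. a threshold sitting at the 75th percentile means three quarters
    of observed pairs are in weaker LD than the cutoff.
    """
    if isinstance(pairs, pd.DataFrame):
        dist = pairs["distance_cM"].to_numpy(dtype=float)
        r2 = pairs["r2"].to_numpy(dtype=float)
    else:
        arr = np.asarray(list(pairs), dtype=float)
        if arr.size == 0:
            arr = arr.reshape(0, 2)
        dist, r2 = arr[:, 0], arr[:, 1]
    ok = ~(np.isnan(dist) | np.isnan(r2))
    dist, r2 = dist[ok], r2[ok]
    if dist.size < min_pairs:
        raise AnalysisError(f"need >= {min_pairs} LD pairs, got {dist.size}")

    grid = np.linspace(dist.min(), dist.max(), grid_points)
    if smoother == "loess":
        from statsmodels.nonparametric.smoothers_lowess import lowess

        smooth = lowess(r2, dist, frac=span, xvals=grid)
    elif smoother == "bins":
        edges = np.arange(dist.min(), dist.max() + bin_width, bin_width)
        idx = np.clip(np.digitize(dist, edges) - 1, 0, len(edges) - 2)
        centers, means = [], []
        for b in range(len(edges) - 1):
            sel = idx == b
            if sel.any():
                centers.append((edges[b] + edges[b + 1]) / 2)
                means.append(r2[sel].mean())
        grid = np.asarray(centers)
        smooth = np.asarray(means)
    else:
        raise ValueError(f"unknown smoother {smoother!r}")

    below = np.nonzero(smooth <= threshold)[0]
    crossed = below.size > 0
    decay_distance = float(grid[below[0]]) if crossed else None
    percentile = float(_sps.percentileofscore(r2, threshold, kind="rank"))
    return DecayProfile(
        distances=dist,
        r2=r2,
        grid=grid,
        smooth=smooth,
        threshold=threshold,
        decay_distance=decay_distance,
        crossed=crossed,
        percentile_of_threshold=percentile,
    )


def binned_mean_r2(
    pairs: pd.DataFrame, bins: Sequence[tuple[float, float]]
) -> list[float]:
    """Mean r² within [lo, hi) distance windows; NaN for empty windows."""
    dist = pairs["distance_cM"].to_numpy(dtype=float)
    r2 = pairs["r2"].to_numpy(dtype=float)
    out = []
    for lo, hi in bins:
        sel = (dist >= lo) & (dist < hi)
        out.append(float(r2[sel].mean()) if sel.any() else float("nan"))
    return out
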