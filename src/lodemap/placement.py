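"""Two-step LD placement of unmapped markers on a genetic map.

Step one assigns a linkage group: the two mapped markers in strongest LD
with the candidate (r² strictly above the threshold) must agree on a
linkage group, otherwise the candidate stays unplaced.  Step two
estimates the cM position as the r²-weighted mean position of *all*
mapped markers on the assigned group whose r² exceeds the threshold —
multi-point anchoring, so a single spurious high-LD anchor cannot drag
the estimate far.

Every placement is independent (placed markers never become anchors
within a run) and fully deterministic: ties on r² are broken first in
favour of the anchor agreeing with the top anchor's linkage group, then
by lexicographically smallest marker id.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from . import ld
from .exceptions import ContractError, ValidationError
from .filters import marker_stats
from .io import GeneticMap, GenotypeMatrix

logger = logging.getLogger(__name__)

# unplaced reasons
NO_ANCHOR = "no_anchor_above_threshold"
SINGLE_ANCHOR = "single_anchor_only"
TOP_TWO_DISAGREE = "top_two_disagree"
UNDEFINED_LD = "undefined_ld"


@dataclass
class Placement:
    """Verdict for one candidate marker."""

    marker_id: str
    status: str  # "placed" | "unplaced"
    linkage_group: str | None = None
    position: float | None = None
    top_r2: float | None = None
    second_r2: float | None = None
    n_anchors_used: int = 0
    reason: str | None = None
    detail: str | None = None

    @property
    def placed(self) -> bool:
        return self.status == "placed"


class PlacementList(list):
    """List of Placement with an attached per-status/reason summary."""

    @property
    def summary(self) -> dict[str, int]:
        counts: dict[str, int] = {"placed": 0, "unplaced": 0}
        for p in self:
            counts[p.status] += 1
            if p.reason:
                counts[p.reason] = counts.get(p.reason, 0) + 1
        return counts


def _top_two(
    anchor_ids: Sequence[str],
    lgs: Sequence[str],
    r2s: np.ndarray,
) -> tuple[int, int]:
    """Indices of the two strongest anchors under the deterministic tie-break."""
    order = sorted(range(len(anchor_ids)), key=lambda i: (-r2s[i], anchor_ids[i]))
    top = order[0]
    rest = order[1:]
    best_r2 = r2s[rest[0]]
    tied = [i for i in rest if r2s[i] == best_r2]
    same_lg = [i for i in tied if lgs[i] == lgs[top]]
    pool = same_lg if same_lg else tied
    second = min(pool, key=lambda i: anchor_ids[i])
    return top, second


def assign_chromosome(
    profile: ld.LDProfile,
    gmap: GeneticMap,
    threshold: float = 0.1,
) -> tuple[str | None, str | None]:
    """Step one: linkage group from the two strongest supra-threshold anchors.

    Returns ``(linkage_group, None)`` when the top two anchors agree, else
    ``(None, reason)`` with the unplaced reason.
    """
    for a in profile.anchor_ids:
        if a not in gmap:
            raise ContractError(f"anchor {a!r} missing from the genetic map")
    ids = [a for a, r2, _ in profile.anchors if r2 > threshold]
    r2s = np.array([r2 for _, r2, _ in profile.anchors if r2 > threshold])
    if len(ids) == 0:
        return None, NO_ANCHOR
    if len(ids) == 1:
        return None, SINGLE_ANCHOR
    lgs = [gmap.linkage_group(a) for a in ids]
    top, second = _top_two(ids, lgs, r2s)
    if lgs[top] == lgs[second]:
        return lgs[top], None
    return None, TOP_TWO_DISAGREE


def estimate_position(
    profile: ld.LDProfile,
    gmap: GeneticMap,
    lg: str,
    threshold: float = 0.1,
) -> tuple[float, int]:
    """Step two: r²-weighted mean position over supra-threshold anchors on *lg*."""
    weights, positions = [], []
    for a, r2, _ in profile.anchors:
        if r2 > threshold and gmap.linkage_group(a) == lg:
            weights.append(r2)
            positions.append(gmap.position(a))
    if not weights:
        raise ContractError(f"no supra-threshold anchor on {lg!r} for {profile.target_id!r}")
    w = np.asarray(weights)
    p = np.asarray(positions)
    return float((w * p).sum() / w.sum()), len(weights)


def _place_one(
    marker_id: str,
    anchor_ids: Sequence[str],
    anchor_lgs: Sequence[str],
    anchor_pos: np.ndarray,
    r2_row: np.ndarray,
    threshold: float,
) -> Placement:
    """Run both steps for one candidate given its r² row against all anchors."""
    defined = ~np.isnan(r2_row)
    if not defined.any():
        return Placement(marker_id, "unplaced", reason=UNDEFINED_LD,
                         detail="no defined LD with any anchor")
    above = defined & (r2_row > threshold)
    idx = np.nonzero(above)[0]
    if idx.size == 0:
        return Placement(marker_id, "unplaced", reason=NO_ANCHOR,
                         top_r2=float(np.nanmax(r2_row)))
    if idx.size == 1:
        return Placement(marker_id, "unplaced", reason=SINGLE_ANCHOR,
                         top_r2=float(r2_row[idx[0]]))
    ids = [anchor_ids[i] for i in idx]
    lgs = [anchor_lgs[i] for i in idx]
    r2s = r2_row[idx]
    top, second = _top_two(ids, lgs, r2s)
    top_r2 = float(r2s[top])
    second_r2 = float(r2s[second])
    if lgs[top] != lgs[second]:
        return Placement(marker_id, "unplaced", reason=TOP_TWO_DISAGREE,
                         top_r2=top_r2, second_r2=second_r2)
    lg = lgs[top]
    on_lg = [i for i, l in enumerate(lgs) if l == lg]
    w = r2s[on_lg]
    p = anchor_pos[idx][on_lg]
    position = float((w * p).sum() / w.sum())
    return Placement(
        marker_id, "placed", linkage_group=lg, position=position,
        top_r2=top_r2, second_r2=second_r2, n_anchors_used=len(on_lg),
    )


def place_markers(
    g: GenotypeMatrix,
    gmap: GeneticMap,
    candidate_ids: Iterable[str],
    threshold: float = 0.1,
    maf_min: float = 0.01,
    min_complete: int = ld.DEFAULT_MIN_COMPLETE,
) -> PlacementList:
    """Place every candidate marker against the anchor map.

    Candidates failing the MAF floor (maf strictly > ``maf_min``
    required) are reported unplaced with reason ``undefined_ld`` and the
    filter verdict in ``detail``; the rest go through LD profiling,
    chromosome assignment and position estimation.  Output order matches
    input order.
    """
    candidates = list(candidate_ids)
    anchors = [m for m in gmap.markers if m in g]
    overlap = sorted(set(candidates) & set(gmap.markers))
    if overlap:
        raise ValidationError(f"candidate id(s) already on the map: {overlap[:5]}")
    if len(anchors) < len(gmap):
        logger.warning(
            "%d mapped marker(s) absent from the genotype matrix are ignored as anchors",
            len(gmap) - len(anchors),
        )
    results = PlacementList()
    if not candidates:
        return results

    stats = {s.marker_id: s for s in marker_stats(g.take_markers(candidates))}
    runnable = []
    for m in candidates:
        s = stats[m]
        if s.monomorphic:
            results.append(Placement(m, "unplaced", reason=UNDEFINED_LD,
                                     detail="monomorphic"))
        elif not s.maf > maf_min:
            results.append(Placement(m, "unplaced", reason=UNDEFINED_LD,
                                     detail=f"maf {s.maf:.4g} <= {maf_min:g}"))
        else:
            results.append(None)  # placeholder, filled below
            runnable.append((len(results) - 1, m))

    if runnable:
        anchor_lgs = [gmap.linkage_group(a) for a in anchors]
        anchor_pos = np.array([gmap.position(a) for a in anchors])
        r2, _ = ld.r2_matrix(g, [m for _, m in runnable], anchors, min_complete=min_complete)
        for row, (slot, m) in enumerate(runnable):
            results[slot] = _place_one(m, anchors, anchor_lgs, anchor_pos, r2[row], threshold)
    return results
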