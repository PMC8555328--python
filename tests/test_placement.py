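"""Two-step LD placement: chromosome assignment and position estimation."""

import numpy as np
import pytest

from lodemap import (
    GeneticMap,
    LodeModel,
    assign_chromosome,
    estimate_position,
    pairwise_r2,
    place_markers,
)
from lodemap.exceptions import ContractError, ValidationError
from lodemap.ld import LDProfile
from lodemap.placement import (
    NO_ANCHOR,
    SINGLE_ANCHOR,
    TOP_TWO_DISAGREE,
    UNDEFINED_LD,
)

from conftest import genotypes_from_columns


def profile(target, anchors):
    return LDProfile(target, anchors=[(a, r2, 100) for a, r2 in anchors])


MAP = GeneticMap(
    [("a1", "LG1", 0.0), ("a2", "LG1", 10.0), ("a3", "LG2", 5.0),
     ("a4", "LG1", 20.0), ("a5", "LG2", 15.0)]
)


# ---------------------------------------------------------- assign_chromosome
def test_top_two_agree_assigns_their_group():
    lg, reason = assign_chromosome(profile("t", [("a1", 0.9), ("a2", 0.8), ("a3", 0.7)]), MAP)
    assert lg == "LG1" and reason is None


def test_top_two_disagree_unplaced():
    lg, reason = assign_chromosome(profile("t", [("a1", 0.9), ("a3", 0.8)]), MAP)
    assert lg is None and reason == TOP_TWO_DISAGREE


def test_strict_threshold_and_too_few_anchors():
    lg, reason = assign_chromosome(profile("t", [("a1", 0.09), ("a2", 0.05)]), MAP, threshold=0.1)
    assert (lg, reason) == (None, NO_ANCHOR)
    lg, reason = assign_chromosome(profile("t", [("a1", 0.1), ("a2", 0.1)]), MAP, threshold=0.1)
    assert (lg, reason) == (None, NO_ANCHOR)  # exactly at the cutoff does not count
    lg, reason = assign_chromosome(profile("t", [("a1", 0.5), ("a2", 0.05)]), MAP)
    assert (lg, reason) == (None, SINGLE_ANCHOR)


def test_second_slot_tie_prefers_top_anchor_group_then_lexicographic():
    # a3 (LG2) and a2 (LG1) tie at the second-highest r2: the tie-break
    # prefers agreement with the top anchor's group, so LG1 is assigned.
    lg, reason = assign_chromosome(profile("t", [("a1", 0.9), ("a3", 0.5), ("a2", 0.5)]), MAP)
    assert lg == "LG1" and reason is None
    # all ties on one group: lexicographically smallest id wins (determinism)
    lg, _ = assign_chromosome(profile("t", [("a4", 0.5), ("a2", 0.5), ("a1", 0.5)]), MAP)
    assert lg == "LG1"


def test_unknown_anchor_is_contract_error():
    with pytest.raises(ContractError):
        assign_chromosome(profile("t", [("zz", 0.9), ("a1", 0.8)]), MAP)


# ---------------------------------------------------------- estimate_position
def test_weighted_mean_worked_example():
    # anchors at 10 cM (w = 0.3) and 20 cM (w = 0.1) -> (3 + 2) / 0.4 = 12.5 cM
    p = profile("t", [("a1", 0.3), ("a2", 0.1)])
    gmap = GeneticMap([("a1", "LG1", 10.0), ("a2", "LG1", 20.0)])
    pos, n = estimate_position(p, gmap, "LG1", threshold=0.05)
    assert pos == pytest.approx((0.3 * 10 + 0.1 * 20) / 0.4)  # = 12.5
    assert n == 2


def test_coincident_anchors_return_their_position():
    gmap = GeneticMap([("a1", "LG1", 7.0), ("a2", "LG1", 7.0)])
    pos, _ = estimate_position(profile("t", [("a1", 0.8), ("a2", 0.2)]), gmap, "LG1")
    assert pos == pytest.approx(7.0)


def test_equal_weights_give_arithmetic_mean():
    pos, n = estimate_position(
        profile("t", [("a1", 0.4), ("a2", 0.4), ("a4", 0.4)]), MAP, "LG1"
    )
    assert pos == pytest.approx((0.0 + 10.0 + 20.0) / 3)
    assert n == 3


def test_empty_anchor_set_is_contract_error():
    with pytest.raises(ContractError):
        estimate_position(profile("t", [("a3", 0.5)]), MAP, "LG1")


# ------------------------------------------------------------- place_markers
def test_duplicate_column_candidate_placed_by_self_ld(small_sim):
    from lodemap import GenotypeMatrix

    g = small_sim.genotypes
    anchor_id = small_sim.truth_map.markers[5]
    calls = np.column_stack([g.calls, g.column(anchor_id)])
    g2 = GenotypeMatrix(g.sample_ids, g.marker_ids + ["twin"], calls)
    placements = place_markers(g2, small_sim.truth_map, ["twin"])
    (p,) = placements
    assert p.placed and p.top_r2 == pytest.approx(1.0)
    assert p.linkage_group == small_sim.truth_map.linkage_group(anchor_id)


def test_independent_candidate_unplaced():
    rng = np.random.default_rng(3)
    n = 10_000
    cols = {f"a{i}": rng.binomial(2, 0.5, n).tolist() for i in range(6)}
    cols["t"] = rng.binomial(2, 0.5, n).tolist()
    g = genotypes_from_columns(cols)
    gmap = GeneticMap([(f"a{i}", "LG1", 10.0 * i) for i in range(6)])
    (p,) = place_markers(g, gmap, ["t"])
    assert not p.placed and p.reason == NO_ANCHOR


def test_empty_candidate_set_and_overlap_error(small_sim):
    g, gmap = small_sim.genotypes, small_sim.truth_map
    assert place_markers(g, gmap, []) == []
    with pytest.raises(ValidationError):
        place_markers(g, gmap, [gmap.markers[0]])


def test_low_maf_candidate_reported_as_undefined_ld():
    cols = {
        "a1": [0, 1, 2] * 20, "a2": [0, 1, 2] * 20,
        "rare": [0] * 59 + [1],       # maf = 1/120 < 0.01
        "mono": [2] * 60,
    }
    g = genotypes_from_columns(cols)
    gmap = GeneticMap([("a1", "LG1", 0.0), ("a2", "LG1", 5.0)])
    p_rare, p_mono = place_markers(g, gmap, ["rare", "mono"], maf_min=0.01)
    assert p_rare.reason == UNDEFINED_LD and "maf" in p_rare.detail
    assert p_mono.reason == UNDEFINED_LD and p_mono.detail == "monomorphic"


def test_convexity_and_determinism(masked_default):
    g, anchor, held = masked_default
    first = place_markers(g, anchor, held.markers, threshold=0.1)
    second = place_markers(g, anchor, held.markers, threshold=0.1)
    assert first == second  # dataclass equality: bit-identical outputs
    assert [p.marker_id for p in first] == held.markers  # input order kept
    for p in first:
        if p.placed:
            span = [anchor.position(a) for a in anchor.markers
                    if anchor.linkage_group(a) == p.linkage_group]
            assert min(span) <= p.position <= max(span)
            assert p.top_r2 >= p.second_r2 > 0.1
            assert p.n_anchors_used >= 2


def test_threshold_monotonicity(masked_default):
    g, anchor, held = masked_default
    placed = {}
    for t in (0.1, 0.2, 0.4):
        placements = place_markers(g, anchor, held.markers, threshold=t)
        placed[t] = {p.marker_id for p in placements if p.placed}
    assert placed[0.4] <= placed[0.2] <= placed[0.1]


def brute_force_place(g, gmap, candidates, threshold):
    """Independent reference: per-candidate loops over all anchors."""
    out = {}
    for t in candidates:
        scored = []
        for a in gmap.markers:
            r2 = pairwise_r2(g.column(t), g.column(a))
            if not np.isnan(r2) and r2 > threshold:
                scored.append((a, r2))
        if len(scored) < 2:
            out[t] = None
            continue
        ranked = sorted(scored, key=lambda ar: (-ar[1], ar[0]))
        top = ranked[0]
        tied = [x for x in ranked[1:] if x[1] == ranked[1][1]]
        same = [x for x in tied if gmap.linkage_group(x[0]) == gmap.linkage_group(top[0])]
        second = min(same or tied, key=lambda ar: ar[0])
        if gmap.linkage_group(top[0]) != gmap.linkage_group(second[0]):
            out[t] = None
            continue
        lg = gmap.linkage_group(top[0])
        on_lg = [(a, r2) for a, r2 in scored if gmap.linkage_group(a) == lg]
        wsum = sum(r2 for _, r2 in on_lg)
        pos = sum(r2 * gmap.position(a) for a, r2 in on_lg) / wsum
        out[t] = (lg, pos)
    return out


def test_agrees_with_brute_force_reference(small_sim):
    from lodemap import mask_map

    g = small_sim.genotypes
    anchor_ids = small_sim.truth_map.markers[::4][:20]  # <= 20 anchors
    gmap = small_sim.truth_map.subset(anchor_ids)
    candidates = [m for m in small_sim.truth_map.markers if m not in set(anchor_ids)][:25]
    ours = place_markers(g, gmap, candidates, threshold=0.1, maf_min=0.0)
    ref = brute_force_place(g, gmap, candidates, threshold=0.1)
    for p in ours:
        expected = ref[p.marker_id]
        if expected is None:
            assert not p.placed
        else:
            lg, pos = expected
            assert p.placed and p.linkage_group == lg
            assert p.position == pytest.approx(pos, abs=1e-9)


def test_model_results_interface(masked_default):
    g, anchor, held = masked_default
    res = LodeModel(g, anchor, candidates=held.markers).fit(r2_threshold=0.1)
    assert res.n_candidates == len(held.markers)
    assert 0 <= res.n_placed <= res.n_candidates
    df = res.to_dataframe()
    assert set(df["status"]) <= {"placed", "unplaced"}
    text = res.summary()
    assert "efficiency" in text and "candidates" in text
    ext = res.extended_map()
    assert (ext["source"] == "anchor").sum() == len(anchor)
    assert (ext["source"] == "ld_placed").sum() == res.n_placed


def test_model_validates_candidates(small_sim):
    g, gmap = small_sim.genotypes, small_sim.truth_map
    with pytest.raises(ValidationError):
        LodeModel(g, gmap, candidates=[gmap.markers[0]])
    with pytest.raises(ValidationError):
        LodeModel(g, gmap, candidates=["not_genotyped"])
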