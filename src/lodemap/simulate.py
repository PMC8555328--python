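"""Forward-in-time simulator of an elite breeding population.

The generator emulates the situation that makes LD-based map completion
work in practice: a population descended from a handful of founders, so
that markers close together on a chromosome are in strong disequilibrium
and LD decays smoothly with genetic distance.

Two mechanisms build that structure:

1. *Founder haplotype blocks.*  Founder haplotypes are drawn with
   distance-dependent allele correlation along each linkage group (a
   Markov copy chain with characteristic length ``founder_block_cm``),
   standing in for the long shared ancestry of a narrow elite gene pool.
2. *Random mating with recombination.*  Each generation is produced by
   sampling two parents uniformly with replacement; gametes follow a
   recombination walk where the crossover probability between adjacent
   markers at distance d cM is the Haldane map-function value
   (1 - exp(-2d/100))/2.  Markers on different linkage groups segregate
   independently (switch probability 1/2 at group boundaries).

Final diploids are coded 0/1/2 and missing calls are injected uniformly
at random.  Everything is driven by one numpy Generator, so a seed fixes
the output bit-for-bit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .exceptions import ParameterError
from .io import MISSING, GeneticMap, GenotypeMatrix

logger = logging.getLogger(__name__)


def haldane(d_cm: float | np.ndarray) -> float | np.ndarray:
    """Haldane map function: cM distance -> recombination fraction.

    c(d) = (1 - exp(-2d/100)) / 2, assuming no crossover interference;
    c(0) = 0 and c -> 1/2 as d -> infinity.
    """
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(d_cm) / 100.0))


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the breeding-population simulation.

    Defaults describe the standard test population: 3 linkage groups of
    100 cM with 200 markers each, 8 founders, 5 generations of random
    mating and a final sample of 500 individuals.
    """

    n_linkage_groups: int = 3
    lg_length: float = 100.0          # cM
    n_markers_per_lg: int = 200
    n_founders: int = 8
    n_generations: int = 5
    n_samples: int = 500
    founder_allele_freq_range: tuple[float, float] = (0.1, 0.9)
    founder_block_cm: float = 15.0    # haplotype-block correlation length in founders
    missing_rate: float = 0.02
    seed: int = 1

    def validate(self) -> None:
        if min(self.n_linkage_groups, self.n_markers_per_lg,
               self.n_founders, self.n_generations, self.n_samples) < 1:
            raise ParameterError("all counts must be >= 1")
        if self.lg_length <= 0:
            raise ParameterError("lg_length must be > 0")
        if not (0.0 <= self.missing_rate < 0.5):
            raise ParameterError("missing_rate must be in [0, 0.5)")
        lo, hi = self.founder_allele_freq_range
        if not (0.0 < lo <= hi < 1.0):
            raise ParameterError("founder_allele_freq_range must lie within (0, 1)")
        if self.founder_block_cm <= 0:
            raise ParameterError("founder_block_cm must be > 0")


@dataclass
class SimOutput:
    """Simulated genotypes plus the ground-truth map that generated them."""

    genotypes: GenotypeMatrix
    truth_map: GeneticMap
    provenance: SimConfig


def _founder_haplotypes(rng, positions_by_lg, cfg: SimConfig) -> np.ndarray:
    """Haplotypes (2*n_founders, n_markers) with block-correlated alleles."""
    n_hap = 2 * cfg.n_founders
    lo, hi = cfg.founder_allele_freq_range
    chunks = []
    for pos in positions_by_lg:
        m = len(pos)
        p = rng.uniform(lo, hi, size=m)
        fresh = rng.random((n_hap, m)) < p[None, :]
        copy_prob = np.exp(-np.diff(pos) / cfg.founder_block_cm)
        copy = np.empty((n_hap, m), dtype=bool)
        copy[:, 0] = False
        copy[:, 1:] = rng.random((n_hap, m - 1)) < copy_prob[None, :]
        hap = np.empty((n_hap, m), dtype=np.int8)
        hap[:, 0] = fresh[:, 0]
        for j in range(1, m):  # sequential copy chain along the chromosome
            hap[:, j] = np.where(copy[:, j], hap[:, j - 1], fresh[:, j])
        chunks.append(hap)
    return np.concatenate(chunks, axis=1)


def _gametes(rng, pop: np.ndarray, parent_idx: np.ndarray, switch_prob: np.ndarray) -> np.ndarray:
    """One gamete per row of parent_idx via a vectorized recombination walk."""
    n_gam = len(parent_idx)
    n_markers = pop.shape[2]
    start = rng.integers(0, 2, size=n_gam)
    switches = rng.random((n_gam, n_markers - 1)) < switch_prob[None, :]
    states = np.empty((n_gam, n_markers), dtype=np.int64)
    states[:, 0] = start
    states[:, 1:] = (start[:, None] + np.cumsum(switches, axis=1)) % 2
    return pop[parent_idx[:, None], states, np.arange(n_markers)[None, :]]


def simulate_population(cfg: SimConfig | None = None, **overrides) -> SimOutput:
    """Simulate genotypes and a truth map under a few-founder breeding design.

    Keyword overrides are applied on top of ``cfg`` (or the defaults),
    e.g. ``simulate_population(seed=7, n_samples=200)``.
    """
    cfg = replace(cfg or SimConfig(), **overrides)
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    # marker positions: uniform within each linkage group, then sorted
    positions_by_lg = [
        np.sort(rng.uniform(0.0, cfg.lg_length, size=cfg.n_markers_per_lg))
        for _ in range(cfg.n_linkage_groups)
    ]
    marker_ids, lgs, positions = [], [], []
    for gi, pos in enumerate(positions_by_lg):
        lg = f"LG{gi + 1}"
        for mi, p in enumerate(pos):
            marker_ids.append(f"{lg}_M{mi + 1:04d}")
            lgs.append(lg)
            positions.append(float(p))
    truth_map = GeneticMap(zip(marker_ids, lgs, positions))

    # adjacent-marker switch probabilities: Haldane within a group,
    # 1/2 at group boundaries (independent assortment)
    switch_prob = np.empty(len(marker_ids) - 1)
    offset = 0
    for gi, pos in enumerate(positions_by_lg):
        m = len(pos)
        switch_prob[offset:offset + m - 1] = haldane(np.diff(pos))
        if gi < cfg.n_linkage_groups - 1:
            switch_prob[offset + m - 1] = 0.5
        offset += m

    hap = _founder_haplotypes(rng, positions_by_lg, cfg)
    pop = hap.reshape(cfg.n_founders, 2, -1)  # (individuals, 2 haplotypes, markers)

    for _ in range(cfg.n_generations):
        parents = rng.integers(0, pop.shape[0], size=(cfg.n_samples, 2))
        g1 = _gametes(rng, pop, parents[:, 0], switch_prob)
        g2 = _gametes(rng, pop, parents[:, 1], switch_prob)
        pop = np.stack([g1, g2], axis=1).astype(np.int8)

    calls = pop.sum(axis=1, dtype=np.int8)  # 0/1/2 allele counts
    if cfg.missing_rate > 0:
        mask = rng.random(calls.shape) < cfg.missing_rate
        calls = np.where(mask, np.int8(MISSING), calls)
    sample_ids = [f"S{i + 1:05d}" for i in range(calls.shape[0])]
    genotypes = GenotypeMatrix(sample_ids, marker_ids, calls)
    return SimOutput(genotypes=genotypes, truth_map=truth_map, provenance=cfg)


def mask_map(
    truth: GeneticMap,
    fraction: float | None = None,
    ids: list[str] | None = None,
    seed: int | None = None,
) -> tuple[GeneticMap, GeneticMap]:
    """Split a truth map into (anchor map, held-out truth) for evaluation.

    Either ``fraction`` of markers is masked at random (seeded) or an
    explicit ``ids`` set is held out.  Masking every marker of a linkage
    group is allowed but logged as a warning.
    """
    if (fraction is None) == (ids is None):
        raise ParameterError("give exactly one of fraction or ids")
    if ids is None:
        if not (0.0 < fraction < 1.0):
            raise ParameterError(f"fraction {fraction} outside (0, 1)")
        markers = sorted(truth.markers)
        n_mask = max(1, round(fraction * len(markers)))
        rng = np.random.default_rng(seed)
        ids = [markers[i] for i in rng.choice(len(markers), size=n_mask, replace=False)]
    else:
        unknown = [m for m in ids if m not in truth]
        if unknown:
            raise ParameterError(f"id(s) not on the truth map: {unknown[:5]}")
    masked = set(ids)
    for lg, members in truth.groups().items():
        if all(m in masked for m in members):
            logger.warning("masking removed every marker of linkage group %s", lg)
    anchor = truth.drop(masked, require_linked=False)
    held_out = truth.subset(sorted(masked), require_linked=False)
    return anchor, held_out
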