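"""Model/Results interface over the LD placement algorithm.

`LodeModel` binds a genotype matrix to an anchor genetic map; `fit()`
runs the two-step placement for every candidate marker and returns a
`LodeResults` carrying the placements, support statistics and a
`summary()` table, statsmodels-style.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from . import io, placement
from .exceptions import ValidationError
from .io import GeneticMap, GenotypeMatrix


class LodeModel:
    """LD-based placement of unmapped markers on a sparse genetic map.

    Parameters
    ----------
    genotypes
        Samples x markers 0/1/2 call matrix covering both the mapped
        (anchor) markers and the candidates.
    genetic_map
        Anchor map: marker -> (linkage group, cM).
    candidates
        Marker ids to place.  Defaults to every genotyped marker absent
        from the map.
    """

    def __init__(
        self,
        genotypes: GenotypeMatrix,
        genetic_map: GeneticMap,
        candidates: Iterable[str] | None = None,
    ) -> None:
        self.genotypes = genotypes
        self.map = genetic_map
        if candidates is None:
            mapped = set(genetic_map.markers)
            candidates = [m for m in genotypes.marker_ids if m not in mapped]
        self.candidates = list(candidates)
        unknown = [m for m in self.candidates if m not in genotypes]
        if unknown:
            raise ValidationError(f"candidate id(s) not genotyped: {unknown[:5]}")
        overlap = sorted(set(self.candidates) & set(genetic_map.markers))
        if overlap:
            raise ValidationError(f"candidate id(s) already on the map: {overlap[:5]}")

    @classmethod
    def from_files(
        cls,
        genotype_path: str,
        map_path: str,
        dialect: str | None = None,
        candidates: Iterable[str] | None = None,
    ) -> "LodeModel":
        return cls(
            io.read_genotypes(genotype_path, dialect=dialect),
            io.read_genetic_map(map_path),
            candidates=candidates,
        )

    def fit(
        self,
        r2_threshold: float = 0.1,
        maf_min: float = 0.01,
        min_complete_pairs: int = 10,
    ) -> "LodeResults":
        """Place all candidates; returns a :class:`LodeResults`."""
        placements = placement.place_markers(
            self.genotypes,
            self.map,
            self.candidates,
            threshold=r2_threshold,
            maf_min=maf_min,
            min_complete=min_complete_pairs,
        )
        params = {
            "r2_threshold": r2_threshold,
            "maf_min": maf_min,
            "min_complete_pairs": min_complete_pairs,
        }
        return LodeResults(model=self, params=params, placements=placements)


@dataclass
class LodeResults:
    """Fitted placements plus diagnostics for a :class:`LodeModel`."""

    model: LodeModel
    params: dict
    placements: placement.PlacementList

    @property
    def n_candidates(self) -> int:
        return len(self.placements)

    @property
    def n_placed(self) -> int:
        return sum(p.placed for p in self.placements)

    @property
    def placed(self) -> list[placement.Placement]:
        return [p for p in self.placements if p.placed]

    @property
    def efficiency(self) -> float:
        """Percent of candidates assigned to a linkage group."""
        if not self.placements:
            return float("nan")
        return 100.0 * self.n_placed / self.n_candidates

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for p in self.placements:
            rows.append(
                {
                    "marker_id": p.marker_id,
                    "status": p.status,
                    "linkage_group": p.linkage_group,
                    "position_cM": p.position,
                    "top_r2": p.top_r2,
                    "second_r2": p.second_r2,
                    "n_anchors_used": p.n_anchors_used,
                    "reason": p.reason,
                }
            )
        return pd.DataFrame(rows)

    def extended_map(self) -> pd.DataFrame:
        """Anchor map plus placed markers as one table (anchors first)."""
        anchors = self.model.map.to_dataframe()
        anchors["source"] = "anchor"
        placed = pd.DataFrame(
            [
                {
                    "marker_id": p.marker_id,
                    "linkage_group": p.linkage_group,
                    "position_cM": p.position,
                    "source": "ld_placed",
                }
                for p in self.placed
            ],
            columns=["marker_id", "linkage_group", "position_cM", "source"],
        )
        out = pd.concat([anchors, placed], ignore_index=True)
        return out.sort_values(
            ["source", "linkage_group", "position_cM"], kind="stable"
        ).reset_index(drop=True)

    def save_extended_map(self, path: str) -> None:
        header = [f"{k} = {v}" for k, v in self.params.items()]
        io.write_extended_map(self.model.map, self.placements, path, header_lines=header)

    def save_report(self, path: str) -> None:
        header = [f"{k} = {v}" for k, v in self.params.items()]
        io.write_placement_report(self.placements, path, header_lines=header)

    def summary(self) -> str:
        """Human-readable fit summary."""
        counts = self.placements.summary
        placed = self.placed
        top = np.array([p.top_r2 for p in placed]) if placed else np.array([])
        lines = [
            "LD placement results",
            "=" * 54,
            f"anchors (mapped markers)   {len(self.model.map):>10d}",
            f"candidates                 {self.n_candidates:>10d}",
            f"placed                     {self.n_placed:>10d}",
            f"efficiency (% placed)      {self.efficiency:>10.2f}",
            f"r2 threshold               {self.params['r2_threshold']:>10.3g}",
            f"MAF minimum                {self.params['maf_min']:>10.3g}",
        ]
        if top.size:
            lines.append(f"median top r2 (placed)     {np.median(top):>10.3f}")
        unplaced = {k: v for k, v in counts.items() if k not in ("placed", "unplaced")}
        if unplaced:
            lines.append("-" * 54)
            for reason, n in sorted(unplaced.items()):
                lines.append(f"unplaced: {reason:<24s} {n:>8d}")
        lines.append("=" * 54)
        return "\n".join(lines)
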