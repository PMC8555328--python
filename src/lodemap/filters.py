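"""Per-marker quality statistics and inclusion filters.

The filters mirror standard SNP-array QC for breeding populations: a
minor-allele-frequency floor (strictly ``maf > maf_min``, the usual way
an "MAF > 0.01" rule is printed) and a call-rate floor (``call_rate >=
call_rate_min``).  Monomorphic markers are always dropped because their
LD with anything is undefined (zero variance).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ParameterError
from .io import MISSING, GenotypeMatrix


@dataclass(frozen=True)
class MarkerStats:
    """Quality summary for one marker.

    ``maf`` is min(p, 1-p) with p the alternate-allele frequency computed
    from 0/1/2 allele counts over non-missing calls; markers with no
    calls report maf 0, call_rate 0 and monomorphic=True.
    """

    marker_id: str
    maf: float
    call_rate: float
    monomorphic: bool
    n_called: int


@dataclass
class FilterReport:
    n_input: int
    n_kept: int
    dropped: list[tuple[str, str]]  # (marker_id, reason)

    @property
    def n_dropped(self) -> int:
        return len(self.dropped)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.dropped, columns=["marker_id", "reason"])


def marker_stats(g: GenotypeMatrix) -> list[MarkerStats]:
    """Compute MAF, call rate and monomorphism for every marker."""
    if g.n_samples < 1:
        raise ParameterError("genotype matrix has no samples")
    calls = g.calls
    present = calls != MISSING
    n_called = present.sum(axis=0)
    allele_sum = np.where(present, calls, 0).sum(axis=0, dtype=np.int64)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(n_called > 0, allele_sum / (2.0 * np.maximum(n_called, 1)), 0.0)
    maf = np.minimum(p, 1.0 - p)
    maf = np.where(n_called > 0, maf, 0.0)
    call_rate = n_called / g.n_samples
    # monomorphic = all non-missing calls identical (or no calls at all)
    masked = np.ma.masked_array(calls, mask=~present)
    spread = masked.max(axis=0) - masked.min(axis=0)
    mono = np.where(n_called > 0, np.ma.filled(spread, 0) == 0, True)
    return [
        MarkerStats(m, float(maf[j]), float(call_rate[j]), bool(mono[j]), int(n_called[j]))
        for j, m in enumerate(g.marker_ids)
    ]


def filter_markers(
    g: GenotypeMatrix,
    maf_min: float = 0.01,
    call_rate_min: float = 0.9,
) -> tuple[GenotypeMatrix, FilterReport]:
    """Keep markers with maf > maf_min, call_rate >= call_rate_min, polymorphic.

    The MAF comparison is strict and the call-rate one inclusive; marker
    order is preserved, and each dropped marker is listed once with the
    first failing reason (monomorphic, low_maf, low_call_rate).
    """
    if not (0.0 <= maf_min <= 0.5):
        raise ParameterError(f"maf_min {maf_min} outside [0, 0.5]")
    if not (0.0 <= call_rate_min <= 1.0):
        raise ParameterError(f"call_rate_min {call_rate_min} outside [0, 1]")
    kept: list[str] = []
    dropped: list[tuple[str, str]] = []
    for s in marker_stats(g):
        if s.monomorphic:
            dropped.append((s.marker_id, "monomorphic"))
        elif not s.maf > maf_min:
            dropped.append((s.marker_id, "low_maf"))
        elif s.call_rate < call_rate_min:
            dropped.append((s.marker_id, "low_call_rate"))
        else:
            kept.append(s.marker_id)
    report = FilterReport(n_input=g.n_markers, n_kept=len(kept), dropped=dropped)
    return g.take_markers(kept), report
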