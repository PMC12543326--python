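"""Poised/active enhancer catalogs and six-way differential enhancer states.

Biology: H3K4me1 marks primed (poised) enhancers; H3K27ac marks active
enhancers and promoters. A poised enhancer carries H3K4me1 without H3K27ac;
an active enhancer carries H3K27ac with or without H3K4me1. Differential
enhancer activity between knockout (KO) and wild-type (WT) is read off the
per-mark differentially bound regions (DBRs), with presence/absence of the
partner mark evaluated against the KO consensus peakset allowing a maximum
gap (default 1000 bp) for cross-mark overlap checks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple

from .intervals import (
    GenomicInterval,
    IntervalSet,
    _ChromIndex,
    subset_by_overlap,
)

__all__ = [
    "ENHANCER_STATES",
    "EnhancerCall",
    "BaselineEnhancers",
    "baseline_enhancers",
    "classify_differential_enhancers",
]

ENHANCER_STATES = (
    "poised_gained",
    "poised_lost",
    "active_noK4me1_gained",
    "active_noK4me1_lost",
    "active_withK4me1_gained",
    "active_withK4me1_lost",
)

#: side-table label for H3K4me1 DBRs with H3K27ac present (no defined state)
K4ME1_WITH_K27AC = "k4me1_k27ac_cooccurring"


@dataclass
class EnhancerCall:
    """A DBR with its differential enhancer state and supporting evidence.

    ``state`` is one of :data:`ENHANCER_STATES`, or ``k4me1_k27ac_cooccurring``
    for H3K4me1 DBRs excluded from the poised catalog because H3K27ac is
    present nearby (no state is defined for those; they are emitted as a side
    table). ``partner_distance`` is the gap in bp to the nearest KO consensus
    peak of the partner mark (None when the partner mark has no peak on the
    chromosome).
    """

    region: GenomicInterval
    state: str
    mark: str
    direction: str
    partner_distance: int | None = None

    @property
    def classified(self) -> bool:
        return self.state in ENHANCER_STATES


class BaselineEnhancers(NamedTuple):
    poised: IntervalSet
    active: IntervalSet
    active_with_k4me1: IntervalSet
    active_no_k4me1: IntervalSet


def baseline_enhancers(
    wt_k4me1: IntervalSet, wt_k27ac: IntervalSet, max_gap: int = 1000
) -> BaselineEnhancers:
    """WT poised/active enhancer catalogs from consensus peaksets.

    Poised: H3K4me1 consensus peaks with no H3K27ac peak within ``max_gap``.
    Active: all H3K27ac consensus peaks, also partitioned by H3K4me1
    co-occurrence within ``max_gap``.
    """
    poised = subset_by_overlap(wt_k4me1, wt_k27ac, max_gap, invert=True)
    active_with = subset_by_overlap(wt_k27ac, wt_k4me1, max_gap, invert=False)
    active_without = subset_by_overlap(wt_k27ac, wt_k4me1, max_gap, invert=True)
    return BaselineEnhancers(poised, wt_k27ac, active_with, active_without)


def _calls(
    dbrs: IntervalSet,
    partner_consensus: IntervalSet,
    max_gap: int,
    mark: str,
    direction: str,
    state_if_absent: str | None,
    state_if_present: str | None,
) -> list[EnhancerCall]:
    idx = _ChromIndex(partner_consensus)
    out = []
    for iv in dbrs:
        dist = idx.min_gap(iv)
        present = dist is not None and dist <= max_gap
        state = state_if_present if present else state_if_absent
        if state is None:
            continue
        out.append(EnhancerCall(iv, state, mark, direction, dist))
    return out


def classify_differential_enhancers(
    k4me1_gained: IntervalSet,
    k4me1_lost: IntervalSet,
    k27ac_gained: IntervalSet,
    k27ac_lost: IntervalSet,
    ko_k4me1_consensus: IntervalSet,
    ko_k27ac_consensus: IntervalSet,
    max_gap: int = 1000,
) -> list[EnhancerCall]:
    """Assign each per-mark DBR a differential enhancer state.

    Criteria, evaluated against the KO consensus peaksets:

    * gained/lost **poised**: H3K4me1 increase/decrease with *no* H3K27ac
      peak within ``max_gap``;
    * gained/lost **active without H3K4me1**: H3K27ac increase/decrease with
      *no* H3K4me1 peak within ``max_gap``;
    * gained/lost **active with H3K4me1**: H3K27ac increase/decrease *with*
      an H3K4me1 peak within ``max_gap``.

    Every input DBR appears in exactly one output record for its mark:
    H3K27ac DBRs split exhaustively into the with/without-H3K4me1 partitions;
    H3K4me1 DBRs failing the poised criterion are emitted with the
    ``k4me1_k27ac_cooccurring`` side label.
    """
    calls: list[EnhancerCall] = []
    calls += _calls(
        k4me1_gained, ko_k27ac_consensus, max_gap, "H3K4me1", "gained",
        "poised_gained", K4ME1_WITH_K27AC,
    )
    calls += _calls(
        k4me1_lost, ko_k27ac_consensus, max_gap, "H3K4me1", "lost",
        "poised_lost", K4ME1_WITH_K27AC,
    )
    calls += _calls(
        k27ac_gained, ko_k4me1_consensus, max_gap, "H3K27ac", "gained",
        "active_noK4me1_gained", "active_withK4me1_gained",
    )
    calls += _calls(
        k27ac_lost, ko_k4me1_consensus, max_gap, "H3K27ac", "lost",
        "active_noK4me1_lost", "active_withK4me1_lost",
    )
    return calls
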