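"""Strict presence/absence-variation (PAV) calling of AS isoforms.

An isoform counts as *present* in a condition only when its FPKM is at or
above the threshold tau (default 10, inclusive) in **every** biological
replicate of that condition.  The high threshold plus the all-replicates
rule trades sensitivity for confidence: isoforms called absent may not be
entirely absent, merely not expressed highly enough to be classified
present under this criterion — reports carry that caveat.

The universe for PAV calling is restricted beforehand to isoforms of AS
parent genes (genes with >= 2 structurally unique isoforms): presence
changes in single-isoform genes reflect transcription, not splicing.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

from .quantification import Condition, ExpressionMatrix, condition_slice

DEFAULT_TAU = 10.0

ABSENCE_CAVEAT = (
    "Isoforms called absent may not be entirely absent, only not expressed "
    "at a high enough level to be classified present under the strict "
    "all-replicates FPKM threshold."
)


@dataclass(frozen=True)
class PresenceCallSet:
    """Per-condition present/absent partition of the isoform universe."""

    condition: Condition
    threshold_tau: float
    present_ids: frozenset[str]
    absent_ids: frozenset[str]

    def __post_init__(self) -> None:
        if self.present_ids & self.absent_ids:
            raise ValueError("present and absent sets overlap")

    @property
    def universe(self) -> frozenset[str]:
        return self.present_ids | self.absent_ids


@dataclass(frozen=True)
class PavComparison:
    """Flight-only / ground-only / common present sets for one condition pair."""

    flight_condition: Condition
    ground_condition: Condition
    flight_only: frozenset[str]
    ground_only: frozenset[str]
    common: frozenset[str]

    @property
    def flight_present(self) -> frozenset[str]:
        return self.flight_only | self.common

    @property
    def ground_present(self) -> frozenset[str]:
        return self.ground_only | self.common


def restrict_to_as_isoforms(
    m: ExpressionMatrix,
    as_genes: Iterable[str],
    gene_of: Mapping[str, str],
) -> ExpressionMatrix:
    """Drop isoforms whose parent gene is not an AS parent gene.

    Every isoform in the matrix must have a gene mapping; an unmapped
    isoform is an annotation/matrix mismatch and raises ``KeyError``.
    """
    unmapped = [i for i in m.isoform_ids if i not in gene_of]
    if unmapped:
        raise KeyError(f"isoforms with no gene mapping: {sorted(unmapped)[:10]}")
    as_set = set(as_genes)
    keep = [i for i in m.isoform_ids if gene_of[i] in as_set]
    return m.restrict_isoforms(keep)


def call_presence(
    m: ExpressionMatrix, c: Condition, tau: float = DEFAULT_TAU
) -> PresenceCallSet:
    """Call each isoform present iff min FPKM over c's replicates >= tau."""
    if tau <= 0:
        raise ValueError("tau must be positive")
    sub = condition_slice(m, c)
    present = sub.min(axis=1) >= tau
    return PresenceCallSet(
        condition=c,
        threshold_tau=tau,
        present_ids=frozenset(sub.index[present]),
        absent_ids=frozenset(sub.index[~present]),
    )


def compare_pav(flight: PresenceCallSet, ground: PresenceCallSet) -> PavComparison:
    """Flight-exclusive, ground-exclusive and commonly present isoform sets."""
    if flight.universe != ground.universe:
        raise ValueError("presence call sets built over different isoform universes")
    if flight.threshold_tau != ground.threshold_tau:
        raise ValueError("presence call sets built with different tau")
    f, g = flight.present_ids, ground.present_ids
    return PavComparison(
        flight_condition=flight.condition,
        ground_condition=ground.condition,
        flight_only=frozenset(f - g),
        ground_only=frozenset(g - f),
        common=frozenset(f & g),
    )


def multiway_overlap(
    sets: Mapping[str, Iterable[str]] | Sequence[PresenceCallSet],
) -> dict[tuple[str, ...], int]:
    """Venn-region counts for k >= 2 labelled sets.

    Accepts either a mapping label -> id set, or a sequence of
    PresenceCallSets (labelled by condition, using their present sets).
    Returns one count per non-empty label subset, with exact-membership
    semantics: the region for subset S counts elements in every set of S
    and in no other set.  The 2^k - 1 regions partition the union.
    """
    if not isinstance(sets, Mapping):
        sets = {cs.condition.label: cs.present_ids for cs in sets}
    labels = list(sets)
    if len(labels) < 2:
        raise ValueError("multiway overlap requires at least 2 sets")
    as_sets = {lab: frozenset(v) for lab, v in sets.items()}
    regions: dict[tuple[str, ...], int] = {}
    for k in range(1, len(labels) + 1):
        for subset in combinations(labels, k):
            inside = set.intersection(*(set(as_sets[l]) for l in subset))
            outside = set().union(*(as_sets[l] for l in labels if l not in subset))
            regions[subset] = len(inside - outside)
    return regions
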