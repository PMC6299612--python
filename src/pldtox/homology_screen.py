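"""Acceptance rules for tabular similarity-search hits, and multi-round search
bookkeeping.

A subject is accepted when it has a high-coverage hit with E-value below a
strict single-query threshold (default 1e-05) to any one query, or below a
laxer threshold (default 1e-03) to at least two distinct queries.  Only hits
covering more than 75% of the query participate; strong hits failing the
coverage gate are flagged as fragmentary rather than accepted.  All
inequalities are strict (``E < cutoff``, ``coverage > cutoff``).

:func:`expand_rounds` chains several search rounds (secondary searches seeded
from earlier rounds' accepted subjects) and tags every subject with the
earliest round that reached it and the query chain that did.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .io_formats import HitRecord

__all__ = [
    "ScreenPolicy",
    "HitRationale",
    "ScreenResult",
    "coverage",
    "accept_hits",
    "expand_rounds",
]


@dataclass(frozen=True)
class ScreenPolicy:
    """Thresholds applied to collections of similarity-search hits."""

    e_single: float = 1e-05
    e_multi: float = 1e-03
    min_coverage: float = 0.75
    min_queries_multi: int = 2

    def __post_init__(self) -> None:
        if self.e_multi < self.e_single:
            raise ValueError("e_multi must be >= e_single")
        if not 0 < self.min_coverage <= 1:
            raise ValueError("min_coverage must lie in (0, 1]")
        if self.min_queries_multi < 1:
            raise ValueError("min_queries_multi must be >= 1")


@dataclass
class HitRationale:
    """Why a subject was accepted (or flagged)."""

    subject_id: str
    branch: str  # "single" | "multi"
    supporting_queries: tuple[str, ...]
    best_evalue: float


@dataclass
class ScreenResult:
    accepted: dict[str, HitRationale]
    flags: dict[str, str] = field(default_factory=dict)

    @property
    def accepted_subjects(self) -> frozenset[str]:
        return frozenset(self.accepted)


def coverage(hit: HitRecord) -> float:
    """Fraction of the query aligned: span length / query length.

    Values above 1 (possible when the alignment contains query gaps) are
    clamped to 1 with a warning.
    """
    if hit.query_length is None:
        raise ValueError(
            f"query length unknown for query {hit.query_id!r}; coverage undefined"
        )
    start, end = hit.query_span
    frac = (end - start + 1) / hit.query_length
    if frac > 1:
        warnings.warn(
            f"alignment span exceeds query length for {hit.query_id}->{hit.subject_id}; "
            "clamping coverage to 1",
            stacklevel=2,
        )
        frac = 1.0
    return frac


def _best_evalue_per_query(hits: Iterable[HitRecord]) -> dict[str, dict[str, float]]:
    """subject -> query -> best (lowest) E-value."""
    best: dict[str, dict[str, float]] = {}
    for hit in hits:
        per_query = best.setdefault(hit.subject_id, {})
        prev = per_query.get(hit.query_id)
        if prev is None or hit.evalue < prev:
            per_query[hit.query_id] = hit.evalue
    return best


def accept_hits(
    hits: Sequence[HitRecord], policy: ScreenPolicy = ScreenPolicy()
) -> ScreenResult:
    """Apply the acceptance rule to a hit table.

    A subject is accepted iff, among its hits with coverage strictly above
    ``policy.min_coverage``, either (a) some hit has ``E < e_single``
    (single-query branch), or (b) hits to at least ``min_queries_multi``
    distinct queries have ``E < e_multi`` (multi-query branch).  Subjects
    that would have been accepted but for the coverage gate are flagged
    ``"fragmentary hit"``.  Lowering any E-value can only grow the accepted
    set (monotonicity).
    """
    eligible = [h for h in hits if coverage(h) > policy.min_coverage]
    result = ScreenResult(accepted={}, flags={})

    def decide(table: dict[str, dict[str, float]], subject: str) -> HitRationale | None:
        per_query = table.get(subject, {})
        if not per_query:
            return None
        best_query = min(per_query, key=lambda q: (per_query[q], q))
        if per_query[best_query] < policy.e_single:
            return HitRationale(
                subject_id=subject,
                branch="single",
                supporting_queries=(best_query,),
                best_evalue=per_query[best_query],
            )
        multi = sorted(q for q, e in per_query.items() if e < policy.e_multi)
        if len(multi) >= policy.min_queries_multi:
            return HitRationale(
                subject_id=subject,
                branch="multi",
                supporting_queries=tuple(multi),
                best_evalue=min(per_query[q] for q in multi),
            )
        return None

    high_cov = _best_evalue_per_query(eligible)
    all_cov = _best_evalue_per_query(hits)
    for subject in sorted(all_cov):
        rationale = decide(high_cov, subject)
        if rationale is not None:
            result.accepted[subject] = rationale
        elif decide(all_cov, subject) is not None:
            result.flags[subject] = "fragmentary hit"
    return result


def expand_rounds(
    seed_queries: Iterable[str],
    round_results: Mapping[int, Sequence[HitRecord]],
    policy: ScreenPolicy = ScreenPolicy(),
    max_rounds: int | None = None,
) -> dict[str, tuple[int, tuple[str, ...]]]:
    """Union accepted subjects across successive search rounds.

    ``round_results`` maps round index (1-based) to the hit table searched with
    that round's queries; round r queries must be a subset of the seed queries
    plus subjects accepted in rounds < r.  Returns subject ->
    ``(earliest round, query chain)`` where the chain runs from a seed query to
    the subject.  The accepted set grows monotonically across rounds.
    """
    seeds = set(seed_queries)
    chains: dict[str, tuple[int, tuple[str, ...]]] = {}
    known: set[str] = set(seeds)
    rounds = sorted(round_results)
    if max_rounds is not None:
        rounds = rounds[:max_rounds]
    for r in rounds:
        hits = round_results[r]
        used_queries = {h.query_id for h in hits}
        stray = used_queries - known
        if stray:
            raise ValueError(
                f"round {r} uses queries outside the seed/accepted set: {sorted(stray)}"
            )
        result = accept_hits(hits, policy)
        for subject, rationale in result.accepted.items():
            if subject in chains or subject in seeds:
                continue  # keep earliest round of discovery
            parent = rationale.supporting_queries[0]
            parent_chain = chains.get(parent, (0, (parent,)))[1]
            chains[subject] = (r, parent_chain + (subject,))
        known |= set(result.accepted)
    return chains
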