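"""Sequence-filtering rules: redundancy, completeness, active-site divergence,
contamination, and evidence-based confidence.

The rules mirror common practice for curating a homology-search harvest before
phylogenetic analysis:

* near-identical records (>= 90% or 95% identity depending on the group) are
  collapsed to a single representative;
* highly incomplete records (< 225 residues, or covering < 75% of the
  reference domain) are removed, with named exceptions retainable;
* records whose catalytic core (His12, Glu32, His47) is nonconservatively
  replaced or deleted are set aside as functionally divergent;
* records nearly identical (> 50%) to a reference set but assigned to an
  incompatible lineage are flagged as probable cross-species contaminants;
* records from taxon groups supported by fewer than two independent data types
  (genome/transcriptome/EST/proteome) are labelled low-confidence.

Percent identity is computed from a global alignment (BLOSUM62, gap open 10,
extend 1) with free terminal gaps, and terminal-overhang columns are excluded
from the denominator, so fragments score by their overlap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Collection, Iterable, Mapping, Sequence

from Bio import Align
from Bio.Align import substitution_matrices

from .io_formats import SequenceRecord

__all__ = [
    "CurationPolicy",
    "ActiveSiteSpec",
    "ContaminantFlag",
    "pairwise_identity",
    "alignment_overlap_fraction",
    "filter_redundancy",
    "filter_fragments",
    "screen_active_site",
    "flag_contaminants",
    "flag_low_confidence",
]

# Decision order used by the pipeline; fragments and contaminants are pulled
# out before redundancy so a defect is attributed to exactly one rule.
CURATION_STAGES = ("contaminant", "fragment", "active_site", "redundancy")


@dataclass(frozen=True)
class CurationPolicy:
    """Thresholds for the curation rules.

    ``redundancy_identity`` is 90 by default; 95 is the conventional laxer
    setting for groups where close paralogs matter.  ``exceptions`` maps record
    ids that must never be removed to the reason for keeping them.
    """

    redundancy_identity: float = 90.0
    min_length: int = 225
    min_domain_fraction: float = 0.75
    contaminant_identity: float = 50.0
    required_evidence_types: int = 2
    exceptions: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("redundancy_identity", "contaminant_identity"):
            v = getattr(self, name)
            if not 0 < v <= 100:
                raise ValueError(f"{name} must lie in (0, 100]")
        if not 0 < self.min_domain_fraction <= 1:
            raise ValueError("min_domain_fraction must lie in (0, 1]")
        if self.min_length <= 0:
            raise ValueError("min_length must be > 0")


_CORE_POSITIONS = ("His12", "Glu32", "His47")
_CANONICAL = {
    "His12": "H",
    "Glu32": "E",
    "Asp34": "D",
    "His47": "H",
    "Asp91": "D",
    "Lys93": "K",
}


@dataclass(frozen=True)
class ActiveSiteSpec:
    """The catalytic positions screened for divergence (mature numbering).

    A record is *divergent* when every core position (His12, Glu32, His47) is
    nonconservatively replaced or missing; "nonconservative" means a
    substitution scoring <= 0 in the named matrix.
    """

    positions: Mapping[str, str] = field(default_factory=lambda: dict(_CANONICAL))
    core_positions: tuple[str, ...] = _CORE_POSITIONS
    matrix_name: str = "BLOSUM62"

    def __post_init__(self) -> None:
        for label, aa in self.positions.items():
            if len(aa) != 1 or aa not in "ACDEFGHIKLMNPQRSTVWY":
                raise ValueError(f"invalid canonical residue {aa!r} at {label}")
        missing = set(self.core_positions) - set(self.positions)
        if missing:
            raise ValueError(f"core positions absent from spec: {sorted(missing)}")

    def matrix(self):
        return _load_matrix(self.matrix_name)


@lru_cache(maxsize=4)
def _load_matrix(name: str):
    return substitution_matrices.load(name)


# ---------------------------------------------------------------------------
# Pairwise identity
# ---------------------------------------------------------------------------

GAP_OPEN = 10.0
GAP_EXTEND = 1.0
_ALIGNMENT_CAP = 2000  # co-optimal alignments examined (exhaustive for short pairs)

# Minimum aligned-core coverage of the shorter sequence for an identity value
# to count as contamination evidence (see flag_contaminants).
MIN_CONTAMINANT_OVERLAP = 0.5


@lru_cache(maxsize=1)
def _aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = _load_matrix("BLOSUM62")
    aligner.open_gap_score = -GAP_OPEN
    aligner.extend_gap_score = -GAP_EXTEND
    aligner.open_end_gap_score = 0.0  # terminal overhangs are free
    aligner.extend_end_gap_score = 0.0
    return aligner


def identity_from_alignment(row_a: str, row_b: str) -> float:
    """Percent identity of one gapped alignment, terminal overhangs excluded.

    A column is a terminal overhang when it lies before the first or after the
    last column in which *both* sequences have a residue.  Internal gap
    columns count in the denominator as non-matching.
    """
    both = [i for i, (x, y) in enumerate(zip(row_a, row_b)) if x != "-" and y != "-"]
    if not both:
        return 0.0
    lo, hi = both[0], both[-1] + 1
    columns = hi - lo
    matches = sum(1 for x, y in zip(row_a[lo:hi], row_b[lo:hi]) if x == y and x != "-")
    return 100.0 * matches / columns


def _identity_stats(sa: str, sb: str) -> tuple[float, float]:
    """(max identity over co-optimal alignments, overlap fraction).

    The overlap fraction is the aligned-core column count of the
    identity-maximising alignment divided by the shorter sequence's length; on
    identity ties the larger core wins.  Unrelated sequences under free
    terminal gaps often align optimally on a single high-scoring residue pair
    with everything else as overhang — a 100%-identity, near-zero-overlap
    degenerate that downstream rules must be able to recognise.
    """
    if not sa or not sb:
        raise ValueError("cannot compute identity of an empty sequence")
    if sa == sb:
        return 100.0, 1.0
    alignments = _aligner().align(sa, sb)
    best = (0.0, 0)  # (identity, core columns)
    for n, aln in enumerate(alignments):
        if n >= _ALIGNMENT_CAP:
            break
        row_a, row_b = str(aln[0]), str(aln[1])
        both = [
            i for i, (x, y) in enumerate(zip(row_a, row_b))
            if x != "-" and y != "-"
        ]
        if not both:
            continue
        core = both[-1] + 1 - both[0]
        ident = identity_from_alignment(row_a, row_b)
        best = max(best, (ident, core))
    return best[0], best[1] / min(len(sa), len(sb))


def _residues(x: str | SequenceRecord) -> str:
    return x.residues if isinstance(x, SequenceRecord) else x


def pairwise_identity(a: str | SequenceRecord, b: str | SequenceRecord) -> float:
    """Percent identity between two sequences under the package's alignment.

    Global alignment with BLOSUM62, gap open 10 / extend 1, free terminal
    gaps.  Because co-optimal alignments can disagree on identity, the value
    returned is the maximum identity over the optimal-score alignments
    (enumeration capped; the cap is far beyond what short sequences produce).
    Symmetric; identical sequences score 100 — as does any sequence identical
    to a contiguous part of the other, since overhangs are excluded.
    """
    return _identity_stats(_residues(a), _residues(b))[0]


def alignment_overlap_fraction(
    a: str | SequenceRecord, b: str | SequenceRecord
) -> float:
    """Aligned-core span of the identity-maximising alignment, as a fraction
    of the shorter sequence.  Near 1 for genuine duplicates and contained
    fragments; near 0 for unrelated sequences whose optimal free-end-gap
    alignment is a degenerate single-residue anchor."""
    return _identity_stats(_residues(a), _residues(b))[1]


# ---------------------------------------------------------------------------
# Redundancy filtering
# ---------------------------------------------------------------------------

def filter_redundancy(
    records: Sequence[SequenceRecord],
    threshold: float = 90.0,
    *,
    exceptions: Mapping[str, str] | None = None,
) -> tuple[list[SequenceRecord], dict[str, str]]:
    """Greedy redundancy clustering at a percent-identity threshold.

    Records are visited sorted by (length descending, id ascending) so longer,
    more complete sequences become representatives.  A record is removed and
    mapped to the first already-kept record it matches at ``identity >=
    threshold``; ids in ``exceptions`` are always kept.  Returns
    ``(representatives, removed_id -> representative_id)``.
    """
    exceptions = exceptions or {}
    kept: list[SequenceRecord] = []
    removed: dict[str, str] = {}
    for rec in sorted(records, key=lambda r: (-len(r.residues), r.id)):
        if rec.id in exceptions:
            kept.append(rec)
            continue
        rep = next(
            (k for k in kept if pairwise_identity(rec, k) >= threshold), None
        )
        if rep is None:
            kept.append(rec)
        else:
            removed[rec.id] = rep.id
    order = {r.id: i for i, r in enumerate(records)}
    kept.sort(key=lambda r: order[r.id])
    return kept, removed


# ---------------------------------------------------------------------------
# Fragment / completeness filtering
# ---------------------------------------------------------------------------

def filter_fragments(
    records: Sequence[SequenceRecord],
    domain_fraction: Mapping[str, float],
    policy: CurationPolicy = CurationPolicy(),
    *,
    missing_active_sites: Mapping[str, Collection[str]] | None = None,
) -> tuple[list[SequenceRecord], dict[str, str]]:
    """Remove highly incomplete records.

    ``domain_fraction`` gives each record's covered fraction of the reference
    domain (from the profile mapping).  Removal reasons, in order of
    precedence: ``"short (<N aa)"``, ``"incomplete domain"``, and
    ``"active-site deletion"`` for otherwise-complete records whose alignment
    leaves a catalytic position unmatched.  Records named in
    ``policy.exceptions`` are kept and flagged.
    """
    missing_active_sites = missing_active_sites or {}
    kept: list[SequenceRecord] = []
    removed: dict[str, str] = {}
    for rec in records:
        if rec.id not in domain_fraction:
            raise KeyError(f"record {rec.id!r} missing from domain_fraction map")
        reason = None
        if len(rec.residues) < policy.min_length:
            reason = f"short (<{policy.min_length} aa)"
        elif domain_fraction[rec.id] < policy.min_domain_fraction:
            reason = "incomplete domain"
        elif missing_active_sites.get(rec.id):
            sites = ",".join(sorted(missing_active_sites[rec.id]))
            reason = f"active-site deletion ({sites})"
        if reason is None:
            kept.append(rec)
        elif rec.id in policy.exceptions:
            kept.append(rec)
            removed[rec.id] = f"retained exception: {policy.exceptions[rec.id]}"
        else:
            removed[rec.id] = reason
    kept_only = [r for r in kept]
    return kept_only, removed


# ---------------------------------------------------------------------------
# Active-site divergence screening
# ---------------------------------------------------------------------------

def screen_active_site(
    record: SequenceRecord,
    mapping: Mapping[str, int | None],
    spec: ActiveSiteSpec = ActiveSiteSpec(),
) -> tuple[dict[str, str], str]:
    """Classify each catalytic position and render a verdict.

    ``mapping`` gives the record coordinate (1-based) of each reference
    position, or None where the alignment has a gap.  Position states:
    ``canonical`` (residue equals the spec), ``conservative`` (substitution
    score > 0), ``nonconservative`` (score <= 0), ``missing`` (gapped).  The
    verdict is ``"divergent"`` iff *all* core positions are nonconservative or
    missing, else ``"normal"``.
    """
    matrix = spec.matrix()
    states: dict[str, str] = {}
    for label, canonical in spec.positions.items():
        pos = mapping.get(label)
        if pos is None:
            states[label] = "missing"
            continue
        residue = record.residues[pos - 1]
        if residue == canonical:
            states[label] = "canonical"
        elif residue == "X":
            states[label] = "missing"
        else:
            score = matrix[canonical, residue]
            states[label] = "conservative" if score > 0 else "nonconservative"
    divergent = all(
        states[c] in ("nonconservative", "missing") for c in spec.core_positions
    )
    return states, ("divergent" if divergent else "normal")


# ---------------------------------------------------------------------------
# Contaminant flagging
# ---------------------------------------------------------------------------

@dataclass
class ContaminantFlag:
    record_id: str
    reference_id: str
    identity: float
    record_lineage: tuple[str, ...]
    reference_lineage: tuple[str, ...]


def flag_contaminants(
    records: Sequence[SequenceRecord],
    reference_records: Sequence[SequenceRecord],
    policy: CurationPolicy = CurationPolicy(),
    *,
    rank_index: int = 1,
) -> list[ContaminantFlag]:
    """Flag records highly similar to a reference set but from an incompatible
    lineage.

    A record is flagged iff its identity to some reference exceeds
    ``policy.contaminant_identity`` *and* the two lineages differ at
    ``rank_index`` (default 1, the phylum slot).  Identical cross-lineage
    pairs are always flagged.  The identity must come from an alignment
    covering at least half of the shorter sequence: under free terminal gaps
    the optimal alignment of *unrelated* sequences is typically a degenerate
    one-residue anchor whose overhang-excluded identity is 100%, which is not
    contamination evidence.  Records lacking lineage information are skipped
    with a warning.
    """
    flags: list[ContaminantFlag] = []
    for rec in records:
        if not rec.taxon:
            warnings.warn(f"record {rec.id} has no lineage; contaminant check skipped")
            continue
        best: ContaminantFlag | None = None
        for ref in reference_records:
            if ref.id == rec.id or not ref.taxon:
                continue
            if rec.rank(rank_index) == ref.rank(rank_index):
                continue  # same-lineage exemption
            ident, overlap = _identity_stats(rec.residues, ref.residues)
            if overlap < MIN_CONTAMINANT_OVERLAP:
                continue
            if ident > policy.contaminant_identity or ident == 100.0:
                if best is None or ident > best.identity:
                    best = ContaminantFlag(
                        record_id=rec.id,
                        reference_id=ref.id,
                        identity=ident,
                        record_lineage=rec.taxon,
                        reference_lineage=ref.taxon,
                    )
        if best is not None:
            flags.append(best)
    return flags


# ---------------------------------------------------------------------------
# Evidence-based confidence
# ---------------------------------------------------------------------------

def flag_low_confidence(
    records: Sequence[SequenceRecord],
    policy: CurationPolicy = CurationPolicy(),
    *,
    rank_index: int = 2,
) -> dict[str, str]:
    """Label records by the evidence supporting their taxon group.

    Evidence types are pooled across all records sharing a lineage prefix up
    to ``rank_index`` (default 2, the class slot); a record is
    ``"low-confidence"`` iff its group musters fewer than
    ``policy.required_evidence_types`` distinct types, else ``"confident"``.
    """
    groups: dict[tuple[str, ...], set[str]] = {}
    for rec in records:
        key = rec.taxon[: rank_index + 1]
        groups.setdefault(key, set()).update(rec.evidence)
    labels: dict[str, str] = {}
    for rec in records:
        key = rec.taxon[: rank_index + 1]
        n_types = len(groups.get(key, set()))
        labels[rec.id] = (
            "confident" if n_types >= policy.required_evidence_types else "low-confidence"
        )
    return labels
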