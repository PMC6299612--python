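"""Diagnostic sequence features of the GDPD-like SMase D/PLD family.

The family is recognised, and its three major clades distinguished, by a small
set of sequence signatures:

* a conserved C-terminal "plug" motif (Arg-Asp salt bridge, Ala/Pro
  hydrophobics, a buried Trp) plus interacting N-terminal residues — a shared
  derived character of the family, absent from GDPDs;
* a short βα1 loop — GDPDs carry a loop at least six residues longer, which
  accommodates the GDPD-I insert domain the family lacks;
* the catalytic (βα2) loop: length 15 with a conserved Cys pair (plus a
  βα6-linker Cys) in the ST-like clade; 9–13 residues and Cys-free in the
  AT-like clade; 17+ residues carrying the ST Cys pair plus at least one extra
  pair in the Aquatic clade; short and Cys-free in the basal sequences;
* 1–4 C-terminal cysteine-rich repeats (DUF-B: 10 conserved Cys, a Gly-rich
  stretch and a terminal Tyr) in most Aquatic-clade members.

Features are measured against a packaged :class:`ReferenceProfile` — a
column-annotated multiple alignment of synthetic family exemplars encoding the
signatures above (a user-supplied exemplar alignment can be substituted).
Records are aligned to the profile with an affine-gap log-odds dynamic
programme with free terminal gaps; loop lengths count record residues between
fixed anchor columns, so insertions within a loop count toward its length.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import SequenceRecord
from . import synthetic_data as synth
from .synthetic_data import DUFB_CYS, DUFB_LEN

__all__ = [
    "ReferenceProfile",
    "ProfileMapping",
    "FeatureProfile",
    "CladeSignatureSpec",
    "build_reference_profile",
    "compile_profile",
    "default_profile",
    "profile_to_json",
    "profile_from_json",
    "map_to_reference",
    "measure_loops",
    "score_plug_motif",
    "detect_dufb_repeats",
    "classify_clade",
    "extract_features",
    "column_frequencies",
]

_AA = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {a: i for i, a in enumerate(_AA)}
GAP_OPEN = 10.0
GAP_EXTEND = 1.0
PSEUDOCOUNT = 1.0
CALIBRATION_SEED = 97_301
CALIBRATION_N = 1000
GAP_COLUMN_PENALTY = -2.0  # per unmatched plug column when scoring via mapping

# Profile regions in order: (name, width).  Loop regions are padded to the
# widest exemplar; everything else is fixed-width framework.
_REGIONS = [
    ("nterm", 11),
    ("H12", 1),
    ("ba1", 3),
    ("alpha1", 16),
    ("E32", 1),
    ("x33", 1),
    ("D34", 1),
    ("beta2", 12),
    ("H47", 1),
    ("catloop", 23),
    ("mid", 28),
    ("D91", 1),
    ("x92", 1),
    ("K93", 1),
    ("linker", 17),
    ("cterm", 156),
    ("plug", 11),
    ("tail", 3),
]
_LOOP_REGIONS = ("ba1", "catloop")


@dataclass
class ReferenceProfile:
    """Column-annotated exemplar alignment compiled to a log-odds PSSM.

    ``pssm`` is (width x 20) log2-odds with Laplace pseudocount 1 against a
    uniform background; annotations give the column indices (0-based) of the
    loop regions, active sites, plug motif (6 N-terminal interacting columns +
    11 C-terminal motif columns) and the βα6 linker-cysteine column.
    ``plug_threshold`` and ``score_floor`` are calibrated against seeded
    shuffle nulls at profile build time (99th percentile), so that fewer than
    1% of shuffled sequences present a plug or map at all.
    """

    alignment: list[str]
    pssm: np.ndarray
    regions: dict[str, tuple[int, int]]  # half-open column spans
    active_site_cols: dict[str, int]
    plug_n_cols: tuple[int, ...]
    plug_c_cols: tuple[int, ...]
    linker_cys_col: int
    core_cols: tuple[int, ...]
    plug_threshold: float
    score_floor: float
    # Position-specific gap costs: deleting a loop-region column or inserting
    # record residues inside a loop region is free — loop columns model a
    # variable-length region, so their occupancy must not be penalised.
    del_open: np.ndarray = field(default=None, repr=False)
    del_ext: np.ndarray = field(default=None, repr=False)
    ins_open: np.ndarray = field(default=None, repr=False)
    ins_ext: np.ndarray = field(default=None, repr=False)

    @property
    def width(self) -> int:
        return self.pssm.shape[0]

    def loop_anchors(self, loop: str) -> tuple[int, int]:
        """(column before, column after) the given loop region."""
        lo, hi = self.regions[loop]
        return lo - 1, hi


def _exemplar_truths() -> list[tuple[str, "synth.FamilyTruth"]]:
    """Noise-free exemplars spanning the clade loop-length ranges."""
    wanted = {
        "ST": {15},
        "AT": {9, 10, 11, 12, 13},
        "Aquatic": {17, 19, 21, 23},
        "basal": {6, 7, 8},
    }
    clade_stream = {"ST": 11, "AT": 23, "Aquatic": 37, "basal": 51}
    out = []
    for clade, lengths in wanted.items():
        needed = set(lengths)
        seed = 0
        while needed and seed < 500:
            rec, truth = synth.make_family_sequence(
                clade, np.random.default_rng((clade_stream[clade], seed))
            )
            if truth.cat_loop_length in needed:
                needed.discard(truth.cat_loop_length)
                out.append((rec.residues, truth))
            seed += 1
        if needed:  # pragma: no cover - generator ranges guarantee coverage
            raise RuntimeError(f"could not realise loop lengths {needed} for {clade}")
    return out


def build_reference_profile(
    exemplars: Sequence[tuple[str, "synth.FamilyTruth"]] | None = None,
) -> ReferenceProfile:
    """Assemble the packaged reference profile (deterministic).

    ``exemplars`` may substitute a user-provided list of (sequence, truth)
    pairs; by default a fixed set of noise-free synthetic exemplars covering
    every clade's loop-length range is used.
    """
    exemplars = list(exemplars) if exemplars is not None else _exemplar_truths()

    regions: dict[str, tuple[int, int]] = {}
    col = 0
    for name, width in _REGIONS:
        regions[name] = (col, col + width)
        col += width
    width = col

    rows: list[str] = []
    for residues, truth in exemplars:
        rows.append(_exemplar_row(residues, truth, regions, width))
    return compile_profile(rows, regions)


def compile_profile(
    rows: Sequence[str], regions: Mapping[str, tuple[int, int]]
) -> ReferenceProfile:
    """Compile an annotated exemplar alignment into a scoring profile.

    ``rows`` is the alignment (equal width, gaps as ``-``); ``regions`` maps
    each architectural region name to its half-open column span.  Thresholds
    are recalibrated deterministically, so a profile serialised with
    :func:`profile_to_json` compiles back to an identical object.
    """
    rows = list(rows)
    regions = {k: (int(v[0]), int(v[1])) for k, v in regions.items()}
    if not rows:
        raise ValueError("empty exemplar alignment")
    width = len(rows[0])
    if any(len(r) != width for r in rows):
        raise ValueError("ragged exemplar alignment")
    missing = {name for name, _ in _REGIONS} - set(regions)
    if missing:
        raise ValueError(f"profile regions missing: {sorted(missing)}")

    counts = np.zeros((width, 20))
    for row in rows:
        for j, ch in enumerate(row):
            if ch in _AA_INDEX:
                counts[j, _AA_INDEX[ch]] += 1
    freqs = (counts + PSEUDOCOUNT) / (counts.sum(axis=1, keepdims=True) + 20 * PSEUDOCOUNT)
    pssm = np.log2(freqs / (1.0 / 20.0))

    active_site_cols = {
        "His12": regions["H12"][0],
        "Glu32": regions["E32"][0],
        "Asp34": regions["D34"][0],
        "His47": regions["H47"][0],
        "Asp91": regions["D91"][0],
        "Lys93": regions["K93"][0],
    }
    for label, j in active_site_cols.items():
        non_gap = sum(1 for row in rows if row[j] != "-") / len(rows)
        if non_gap < 0.9:
            raise ValueError(
                f"active-site column {label} is gapped in more than 10% of exemplars"
            )
    plug_n_cols = tuple(range(regions["nterm"][0], regions["nterm"][0] + 6))
    plug_c_cols = tuple(range(*regions["plug"]))
    core_cols = tuple(
        sorted(
            j
            for name, (lo, hi) in regions.items()
            if name not in _LOOP_REGIONS
            for j in range(lo, hi)
        )
    )
    # per-column gap costs (1-based over columns 1..width, index 0 unused)
    del_open = np.full(width + 1, GAP_OPEN)
    del_ext = np.full(width + 1, GAP_EXTEND)
    ins_open = np.full(width + 1, GAP_OPEN)
    ins_ext = np.full(width + 1, GAP_EXTEND)
    for name in _LOOP_REGIONS:
        lo, hi = regions[name]
        del_open[lo + 1 : hi + 1] = 0.0   # deleting loop columns is free
        del_ext[lo + 1 : hi + 1] = 0.0
        ins_open[lo : hi + 1] = 0.0       # inserting inside the loop is free
        ins_ext[lo : hi + 1] = 0.0
        if hi + 1 <= width:
            # a deletion chain leaving the free region must re-open: otherwise
            # free pad deletions could swallow the first framework column at
            # extension cost only
            del_ext[hi + 1] = GAP_OPEN

    profile = ReferenceProfile(
        alignment=rows,
        pssm=pssm,
        regions=regions,
        active_site_cols=active_site_cols,
        plug_n_cols=plug_n_cols,
        plug_c_cols=plug_c_cols,
        linker_cys_col=regions["linker"][0] + synth.LINKER_CYS_OFFSET,
        core_cols=core_cols,
        plug_threshold=0.0,
        score_floor=0.0,
        del_open=del_open,
        del_ext=del_ext,
        ins_open=ins_open,
        ins_ext=ins_ext,
    )
    _calibrate(profile)
    return profile


def _exemplar_row(residues: str, truth, regions, width) -> str:
    """Place an exemplar into profile columns using its truth coordinates."""
    row = ["-"] * width
    seq = residues

    def put(name: str, start_1: int, end_1: int) -> None:
        lo, hi = regions[name]
        segment = seq[start_1 - 1 : end_1]
        if len(segment) > hi - lo:
            raise ValueError(
                f"exemplar segment {name} ({len(segment)} aa) exceeds region width {hi - lo}"
            )
        for k, ch in enumerate(segment):
            row[lo + k] = ch

    a = truth.active_sites
    put("nterm", 1, a["His12"] - 1)
    put("H12", a["His12"], a["His12"])
    put("ba1", *truth.ba1_span)
    put("alpha1", truth.ba1_span[1] + 1, a["Glu32"] - 1)
    put("E32", a["Glu32"], a["Glu32"])
    put("x33", a["Glu32"] + 1, a["Glu32"] + 1)
    put("D34", a["Asp34"], a["Asp34"])
    put("beta2", a["Asp34"] + 1, a["His47"] - 1)
    put("H47", a["His47"], a["His47"])
    put("catloop", *truth.cat_loop_span)
    put("mid", truth.cat_loop_span[1] + 1, a["Asp91"] - 1)
    put("D91", a["Asp91"], a["Asp91"])
    put("x92", a["Asp91"] + 1, a["Asp91"] + 1)
    put("K93", a["Lys93"], a["Lys93"])
    linker_start = a["Lys93"] + 1
    put("linker", linker_start, linker_start + 16)
    cterm_start = linker_start + 17
    plug_start, plug_end = truth.plug_span
    put("cterm", cterm_start, plug_start - 1)
    put("plug", plug_start, plug_end)
    put("tail", plug_end + 1, plug_end + 3)
    return "".join(row)


def _calibrate(profile: ReferenceProfile) -> None:
    """Fix the plug-presence threshold and mapping score floor by shuffle null.

    1000 random shuffles of the ST exemplar consensus are scored; thresholds
    sit at the null's 99th percentile, bounding the false-positive rate at 1%.
    """
    rng = np.random.default_rng(CALIBRATION_SEED)
    base = list(synth.consensus_sequence("ST"))
    plug_scores = np.empty(CALIBRATION_N)
    map_scores = np.empty(CALIBRATION_N)
    for k in range(CALIBRATION_N):
        shuffled = "".join(rng.permutation(base))
        plug_scores[k] = _plug_window_scores(shuffled, profile)[0]
        if k < 200:  # mapping nulls are costlier; 200 suffices for a percentile
            _, _, score = _align_to_profile(shuffled, profile)
            map_scores[k] = score
    map_scores = map_scores[:200]
    profile.plug_threshold = float(np.percentile(plug_scores, 99))
    profile.score_floor = float(np.percentile(map_scores, 99))


@lru_cache(maxsize=1)
def default_profile() -> ReferenceProfile:
    return build_reference_profile()


def profile_to_json(profile: ReferenceProfile) -> str:
    """Serialise a profile as JSON (alignment + region annotations).

    Scores and thresholds are derived data: :func:`profile_from_json`
    recompiles them deterministically, so round-tripping is lossless.
    """
    import json

    return json.dumps(
        {
            "alignment": profile.alignment,
            "regions": {k: list(v) for k, v in sorted(profile.regions.items())},
        },
        indent=1,
        sort_keys=True,
    )


def profile_from_json(text: str) -> ReferenceProfile:
    """Recompile a profile serialised with :func:`profile_to_json`."""
    import json

    payload = json.loads(text)
    return compile_profile(payload["alignment"], payload["regions"])


# ---------------------------------------------------------------------------
# Sequence-to-profile alignment
# ---------------------------------------------------------------------------

@dataclass
class ProfileMapping:
    """Alignment of one record to the reference profile.

    ``col_to_pos[j]`` is the 1-based record position matched to profile column
    j, or None where the column is deleted.  ``insertions`` lists record
    positions consumed between columns, as (preceding column index, position).
    ``covered_fraction`` is the matched share of the annotated core columns.
    ``mappable`` is False when the alignment score falls below the calibrated
    floor, marking the record as non-family for downstream purposes.
    """

    record_id: str
    score: float
    col_to_pos: list[int | None]
    insertions: list[tuple[int, int]]
    covered_fraction: float
    mappable: bool

    def residues_between(self, col_before: int, col_after: int) -> list[int]:
        """Record positions aligned strictly between two profile columns."""
        if self.col_to_pos[col_before] is None or self.col_to_pos[col_after] is None:
            return []
        lo = self.col_to_pos[col_before]
        hi = self.col_to_pos[col_after]
        return list(range(lo + 1, hi))

    def anchored(self, col_before: int, col_after: int) -> bool:
        return (
            self.col_to_pos[col_before] is not None
            and self.col_to_pos[col_after] is not None
        )


def _encode(seq: str) -> np.ndarray:
    return np.array([_AA_INDEX.get(ch, -1) for ch in seq], dtype=np.int64)


def _align_to_profile(seq: str, profile: ReferenceProfile):
    """Affine-gap global alignment with free terminal gaps; returns
    (M/D/I matrices stacked, path, score).  Vectorised over record positions.
    """
    enc = _encode(seq)
    n = len(enc)
    w = profile.width
    S = np.where(enc[None, :] >= 0, profile.pssm[:, np.clip(enc, 0, None)], 0.0)  # w x n

    NEG = -1e30
    M = np.full((w + 1, n + 1), NEG)
    D = np.full((w + 1, n + 1), NEG)
    I = np.full((w + 1, n + 1), NEG)
    M[0, 0] = 0.0
    D[:, 0] = 0.0  # free leading column deletions
    I[0, :] = 0.0  # free leading record insertions
    D[0, :] = NEG
    D[0, 0] = 0.0

    idx = np.arange(n)
    for j in range(1, w + 1):
        prev_best = np.maximum(np.maximum(M[j - 1], D[j - 1]), I[j - 1])
        M[j, 1:] = S[j - 1] + prev_best[:-1]
        d_open, d_ext = profile.del_open[j], profile.del_ext[j]
        D[j, 1:] = np.maximum(
            np.maximum(M[j - 1, 1:] - d_open, I[j - 1, 1:] - d_open),
            D[j - 1, 1:] - d_ext,
        )
        # I[j, i] = max_{k<i} ( max(M[j,k], D[j,k]) - open - (i-1-k)*ext )
        i_open, i_ext = profile.ins_open[j], profile.ins_ext[j]
        A = np.maximum(M[j, :-1], D[j, :-1]) - i_open + i_ext * idx
        I[j, 1:] = np.maximum.accumulate(A) - i_ext * idx
    score = max(float(np.max(M[w])), float(np.max(D[w])), float(np.max(I[w])),
                float(np.max(M[:, n])), float(np.max(D[:, n])), float(np.max(I[:, n])))
    path = _traceback(M, D, I, S, score, w, n, profile)
    return (M, D, I), path, score


def _traceback(M, D, I, S, score, w, n, profile):
    """Recover one optimal path as a list of (col j or None, pos i or None)."""
    TOL = 1e-6

    # endpoint: free trailing gaps -> best cell on the last row or column
    best = None
    for j in range(w, -1, -1):
        for mat, state in ((M, "M"), (D, "D"), (I, "I")):
            if abs(mat[j, n] - score) < TOL:
                best = (j, n, state)
                break
        if best:
            break
    if best is None:
        for i in range(n, -1, -1):
            for mat, state in ((M, "M"), (D, "D"), (I, "I")):
                if abs(mat[w, i] - score) < TOL:
                    best = (w, i, state)
                    break
            if best:
                break
    j, i, state = best
    tail = [(None, p) for p in range(i + 1, n + 1)] if j == w else []
    tail += [(c, None) for c in range(j + 1, w + 1)] if i == n and j < w else []

    path: list[tuple[int | None, int | None]] = []
    while j > 0 or i > 0:
        if state == "M":
            if j == 0 or i == 0:
                break
            path.append((j, i))
            prev = M[j, i] - S[j - 1, i - 1]
            for mat, st in ((M, "M"), (D, "D"), (I, "I")):
                if abs(mat[j - 1, i - 1] - prev) < TOL:
                    state = st
                    break
            j, i = j - 1, i - 1
        elif state == "D":
            if i == 0:
                # free leading deletions: consume remaining columns
                for c in range(j, 0, -1):
                    path.append((c, None))
                j = 0
                break
            path.append((j, None))
            val = D[j, i]
            if abs(M[j - 1, i] - profile.del_open[j] - val) < TOL:
                state = "M"
            elif abs(D[j - 1, i] - profile.del_ext[j] - val) < TOL:
                state = "D"
            else:
                state = "I"
            j -= 1
        else:  # I
            if j == 0:
                for p in range(i, 0, -1):
                    path.append((None, p))
                i = 0
                break
            path.append((None, i))
            val = I[j, i]
            i_open = profile.ins_open[j]
            if abs(np.maximum(M[j, i - 1], D[j, i - 1]) - i_open - val) < TOL:
                state = "M" if abs(M[j, i - 1] - i_open - val) < TOL else "D"
            else:
                state = "I"
            i -= 1
    path.reverse()
    return path + tail


def map_to_reference(
    record: SequenceRecord | str,
    profile: ReferenceProfile | None = None,
) -> ProfileMapping:
    """Align a record to the reference profile and report the column mapping.

    The covered fraction counts matched annotated-core (non-loop) columns; an
    alignment scoring below the calibrated floor is returned with
    ``mappable=False`` and treated as non-family downstream.
    """
    profile = profile or default_profile()
    seq = record.residues if isinstance(record, SequenceRecord) else record
    rid = record.id if isinstance(record, SequenceRecord) else ""
    _, path, score = _align_to_profile(seq, profile)
    col_to_pos: list[int | None] = [None] * profile.width
    insertions: list[tuple[int, int]] = []
    last_col = 0
    for col, pos in path:
        if col is not None and pos is not None:
            col_to_pos[col - 1] = pos
            last_col = col
        elif col is None and pos is not None:
            insertions.append((last_col - 1, pos))
        elif col is not None:
            last_col = col
    covered = sum(1 for j in profile.core_cols if col_to_pos[j] is not None)
    fraction = covered / len(profile.core_cols)
    return ProfileMapping(
        record_id=rid,
        score=score,
        col_to_pos=col_to_pos,
        insertions=insertions,
        covered_fraction=fraction,
        mappable=score >= profile.score_floor,
    )


# ---------------------------------------------------------------------------
# Feature measurement
# ---------------------------------------------------------------------------

@dataclass
class FeatureProfile:
    """Extracted signature features of one sequence."""

    record_id: str
    plug_score: float
    plug_present: bool
    ba1_length: int | None
    cat_loop_length: int | None
    cat_loop_span: tuple[int, int] | None
    loop_cys_positions: tuple[int, ...]
    linker_cys_present: bool
    active_site_states: dict[str, str]
    dufb_repeat_count: int
    covered_fraction: float
    mappable: bool

    @property
    def loop_cys_count(self) -> int:
        return len(self.loop_cys_positions)


# Loops are measured between the long conserved framework blocks flanking
# them, not between the adjacent single active-site columns: a random loop can
# by chance contain the anchor residue (e.g. a His), making the single-column
# anchor ambiguous among co-optimal alignments, whereas a 10+-residue
# conserved block anchors uniquely.  Each span contains exactly one
# active-site residue (His12 or His47), excluded from the loop length.
_LOOP_FLANKS = {"ba1": ("nterm", "alpha1"), "catloop": ("beta2", "mid")}


def measure_loops(
    record: SequenceRecord | str,
    mapping: ProfileMapping,
    profile: ReferenceProfile | None = None,
) -> dict:
    """Measure βα1 and catalytic loop lengths and cysteine topology.

    A loop's length is the number of record residues between its flanking
    conserved-block anchor columns, minus the one active-site residue the
    span contains; insertions within the loop count toward the length.  If an
    anchor column is gapped the length is None (feature missing).
    """
    profile = profile or default_profile()
    seq = record.residues if isinstance(record, SequenceRecord) else record
    out: dict = {}
    for loop, (left, right) in _LOOP_FLANKS.items():
        before = profile.regions[left][1] - 1   # last column of left block
        after = profile.regions[right][0]       # first column of right block
        if not mapping.anchored(before, after):
            out[f"{loop}_length"] = None
            out[f"{loop}_span"] = None
            continue
        lo = mapping.col_to_pos[before]
        hi = mapping.col_to_pos[after]
        positions = list(range(lo + 1, hi))
        # the first position in the span is the active-site His; the rest is loop
        loop_positions = positions[1:]
        out[f"{loop}_length"] = len(loop_positions)
        out[f"{loop}_span"] = (
            (loop_positions[0], loop_positions[-1]) if loop_positions else None
        )
        if loop == "catloop":
            out["loop_cys_positions"] = tuple(
                p for p in loop_positions if seq[p - 1] == "C"
            )
    out.setdefault("loop_cys_positions", ())
    linker_pos = mapping.col_to_pos[profile.linker_cys_col]
    out["linker_cys_present"] = bool(linker_pos and seq[linker_pos - 1] == "C")
    return out


def _plug_window_scores(seq: str, profile: ReferenceProfile) -> tuple[float, float]:
    """Fallback plug component scores: best windows near the termini.

    Returns (C-terminal motif score, N-terminal interacting-residue score).
    """
    pssm = profile.pssm
    enc = _encode(seq)

    def best_window(cols: tuple[int, ...], lo: int, hi: int) -> float:
        width = len(cols)
        region = enc[lo:hi]
        if len(region) == 0:
            return -1e9
        if len(region) < width:
            return _window_score(region, cols, pssm)
        best = -np.inf
        for s in range(len(region) - width + 1):
            best = max(best, _window_score(region[s : s + width], cols, pssm))
        return best

    n = len(seq)
    c_score = best_window(profile.plug_c_cols, max(0, n - 40), n)
    n_score = best_window(profile.plug_n_cols, 0, min(15, n))
    return float(c_score), float(n_score)


def _window_score(window: np.ndarray, cols: tuple[int, ...], pssm: np.ndarray) -> float:
    total = 0.0
    for k, j in enumerate(cols[: len(window)]):
        a = window[k]
        total += pssm[j, a] if a >= 0 else 0.0
    return total


def score_plug_motif(
    record: SequenceRecord | str,
    profile: ReferenceProfile | None = None,
    mapping: ProfileMapping | None = None,
) -> tuple[float, bool, tuple[int, int] | None]:
    """Score the 17-column plug motif and decide presence.

    With a profile mapping the motif columns are scored at their mapped record
    positions (gap columns penalised); without one the best-scoring windows in
    the terminal regions are used.  Presence requires the *C-terminal motif
    component* to reach the profile's shuffle-null-calibrated threshold (99th
    percentile of 1000 seeded negatives); the N-terminal interacting residues
    only add support to the reported score — a sequence keeping a generic
    N-terminus but lacking the C-terminal motif has no plug.
    """
    profile = profile or default_profile()
    seq = record.residues if isinstance(record, SequenceRecord) else record
    if len(seq) < len(profile.plug_c_cols):
        return -np.inf, False, None
    span = None
    if mapping is not None and mapping.mappable:
        def component(cols: tuple[int, ...]) -> tuple[float, list[int]]:
            total, positions = 0.0, []
            for j in cols:
                pos = mapping.col_to_pos[j]
                if pos is None:
                    total += GAP_COLUMN_PENALTY
                    continue
                a = _AA_INDEX.get(seq[pos - 1], -1)
                total += profile.pssm[j, a] if a >= 0 else 0.0
                positions.append(pos)
            return total, positions

        c_score, c_positions = component(profile.plug_c_cols)
        n_score, _ = component(profile.plug_n_cols)
        if c_positions:
            span = (min(c_positions), max(c_positions))
    else:
        c_score, n_score = _plug_window_scores(seq, profile)
    score = c_score + max(n_score, 0.0)
    return float(score), c_score >= profile.plug_threshold, span


def detect_dufb_repeats(
    record: SequenceRecord | str, *, spacing_tolerance: int = 2
) -> tuple[int, list[tuple[int, int]]]:
    """Count C-terminal cysteine-rich (DUF-B) repeats.

    A repeat is 10 cysteines whose consecutive spacings each match the
    packaged consensus within ``spacing_tolerance`` (default ±2), with no
    intervening extra Cys, followed within 10 residues by a Gly-rich stretch
    (>= 3 Gly) containing or followed by a Tyr.  Non-overlapping matches are
    counted left to right; spans are 1-based inclusive.
    """
    seq = record.residues if isinstance(record, SequenceRecord) else record
    gaps = [b - a for a, b in zip(DUFB_CYS, DUFB_CYS[1:])]
    cys = [i for i, ch in enumerate(seq) if ch == "C"]
    spans: list[tuple[int, int]] = []
    k = 0
    while k + len(gaps) < len(cys):
        ok = True
        for g, (a, b) in zip(gaps, zip(cys[k:], cys[k + 1 :])):
            if abs((b - a) - g) > spacing_tolerance:
                ok = False
                break
        if ok:
            last = cys[k + len(gaps)]
            window = seq[last + 1 : last + 11]
            if window.count("G") >= 3 and "Y" in window:
                end = min(len(seq), last + 1 + (DUFB_LEN - DUFB_CYS[-1] - 1))
                spans.append((cys[k] + 1 - DUFB_CYS[0], end))
                k += len(gaps) + 1
                continue
        k += 1
    return len(spans), spans


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CladeSignatureSpec:
    """Per-clade diagnostic rule parameters.

    The AT-like length range sits below the ST-like length, which sits below
    the Aquatic minimum; the decoy gate requires a βα1 loop at least
    ``decoy_margin`` residues beyond the family maximum.
    """

    st_loop_length: int = 15
    st_tolerance: int = 1
    st_min_loop_cys: int = 2
    at_loop_range: tuple[int, int] = (9, 13)
    aquatic_min_length: int = 17
    aquatic_min_cys: int = 4
    ba1_max: int = 3
    decoy_margin: int = 6

    def __post_init__(self) -> None:
        if not (
            self.at_loop_range[0] <= self.at_loop_range[1] < self.st_loop_length
            < self.aquatic_min_length
        ):
            raise ValueError(
                "clade loop-length thresholds must be ordered AT < ST < Aquatic"
            )
        if min(self.st_tolerance, self.ba1_max, self.decoy_margin) < 0:
            raise ValueError("thresholds must be non-negative")


LABELS = ("ST-like", "AT-like", "Aquatic", "basal/unclassified", "non-family")


def classify_clade(
    features: FeatureProfile, spec: CladeSignatureSpec = CladeSignatureSpec()
) -> tuple[str, list[str]]:
    """Assign a clade label from measured features, with a rule trace.

    Decision order: non-family (no plug, unmappable, or long βα1 loop), then
    ST-like, Aquatic, AT-like, and finally basal/unclassified.  The catalytic
    loop signature cannot separate AT-like members from scattered basal
    sequences; the trace records that ambiguity.
    """
    trace: list[str] = []

    def done(label: str) -> tuple[str, list[str]]:
        trace.append(f"=> {label}")
        return label, trace

    if not features.mappable:
        trace.append("profile alignment below score floor")
        return done("non-family")
    if not features.plug_present:
        trace.append(f"plug absent (score {features.plug_score:.1f})")
        return done("non-family")
    trace.append(f"plug present (score {features.plug_score:.1f})")
    if features.ba1_length is None:
        trace.append("ba1 loop unmeasured")
        return done("non-family")
    if features.ba1_length > spec.ba1_max:
        trace.append(f"ba1 loop {features.ba1_length} > family max {spec.ba1_max}")
        return done("non-family")
    trace.append(f"ba1 loop {features.ba1_length} <= {spec.ba1_max} (family-like)")

    L = features.cat_loop_length
    cys = features.loop_cys_count
    if L is None:
        trace.append("catalytic loop unmeasured")
        return done("basal/unclassified")
    trace.append(f"catalytic loop length {L}, {cys} loop Cys")

    if abs(L - spec.st_loop_length) <= spec.st_tolerance and cys >= spec.st_min_loop_cys:
        trace.append(
            f"ST rule: |{L} - {spec.st_loop_length}| <= {spec.st_tolerance} "
            f"and Cys {cys} >= {spec.st_min_loop_cys}"
        )
        return done("ST-like")
    if L >= spec.aquatic_min_length and cys >= spec.aquatic_min_cys:
        trace.append(
            f"Aquatic rule: {L} >= {spec.aquatic_min_length} and Cys {cys} >= {spec.aquatic_min_cys}"
        )
        return done("Aquatic")
    lo, hi = spec.at_loop_range
    if lo <= L <= hi and cys == 0:
        trace.append(f"AT rule: {lo} <= {L} <= {hi} and no loop Cys")
        trace.append("note: AT-like vs basal not separable by loop signature alone")
        return done("AT-like")
    trace.append("no clade rule fired")
    trace.append("note: AT-like vs basal not separable by loop signature alone")
    return done("basal/unclassified")


def extract_features(
    record: SequenceRecord,
    profile: ReferenceProfile | None = None,
    mapping: ProfileMapping | None = None,
) -> FeatureProfile:
    """Measure every diagnostic feature of one record."""
    from .curation import ActiveSiteSpec, screen_active_site

    profile = profile or default_profile()
    mapping = mapping or map_to_reference(record, profile)
    loops = measure_loops(record, mapping, profile)
    plug_score, plug_present, _ = score_plug_motif(record, profile, mapping)
    dufb_count, _ = detect_dufb_repeats(record)
    site_map = {
        label: mapping.col_to_pos[col]
        for label, col in profile.active_site_cols.items()
    }
    states, _ = screen_active_site(record, site_map, ActiveSiteSpec())
    return FeatureProfile(
        record_id=record.id,
        plug_score=plug_score,
        plug_present=plug_present,
        ba1_length=loops["ba1_length"],
        cat_loop_length=loops["catloop_length"],
        cat_loop_span=loops["catloop_span"],
        loop_cys_positions=loops["loop_cys_positions"],
        linker_cys_present=loops["linker_cys_present"],
        active_site_states=states,
        dufb_repeat_count=dufb_count,
        covered_fraction=mapping.covered_fraction,
        mappable=mapping.mappable,
    )


def column_frequencies(
    alignment: Sequence[str], columns: Iterable[int] | None = None
) -> pd.DataFrame:
    """Per-column residue (plus gap) frequencies of an alignment.

    Frequencies in each column sum to 1 over the 20 residues and ``-``.  The
    output is TSV-ready input for logo rendering elsewhere.
    """
    if not alignment:
        raise ValueError("empty alignment")
    width = len(alignment[0])
    if any(len(row) != width for row in alignment):
        raise ValueError("ragged alignment rows")
    cols = list(columns) if columns is not None else list(range(width))
    symbols = list(_AA) + ["-"]
    data = {}
    for j in cols:
        counts = {s: 0 for s in symbols}
        for row in alignment:
            ch = row[j] if row[j] in counts else "-"
            counts[ch] += 1
        total = len(alignment)
        data[j] = {s: counts[s] / total for s in symbols}
    return pd.DataFrame(data).T
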