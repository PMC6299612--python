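"""Brute-force reference implementations ("oracles") used by the test suite.

Each oracle solves the same problem as a library function by exhaustive
enumeration, with no shared code, so agreement on random instances is strong
evidence of correctness.  All oracles are exponential-time and only usable on
tiny instances; tests keep instance sizes within their stated limits.
"""

from __future__ import annotations

import itertools
import math
from functools import lru_cache

import numpy as np
from Bio.Align import substitution_matrices

from pldtox.io_formats import SpeciesTree, read_newick

PRESENT, ABSENT, UNKNOWN = "present", "absent", "unknown"


# ---------------------------------------------------------------------------
# Random rooted trees (polytomies allowed)
# ---------------------------------------------------------------------------

def random_tree(rng: np.random.Generator, n_tips: int) -> SpeciesTree:
    """Random rooted tree over tips t0..t{n-1}, polytomies allowed."""
    names = [f"t{i}" for i in range(n_tips)]
    subtrees = list(names)
    while len(subtrees) > 1:
        k = int(rng.integers(2, min(4, len(subtrees)) + 1))  # join 2 or 3
        idx = sorted(rng.choice(len(subtrees), size=k, replace=False), reverse=True)
        joined = [subtrees.pop(i) for i in idx]
        subtrees.append("(" + ",".join(joined) + ")")
    return read_newick(subtrees[0] + ";")


# ---------------------------------------------------------------------------
# Exhaustive gain/loss minimisation
# ---------------------------------------------------------------------------

def _tree_arrays(tree: SpeciesTree):
    """Flatten the tree into (nodes, parent-index, leaf-name) arrays."""
    nodes = list(tree.nodes())  # preorder: parent before child
    index = {id(n): i for i, n in enumerate(nodes)}
    parent = [index[id(n.parent_node)] if n.parent_node else -1 for n in nodes]
    leaf_name = [n.taxon.label if n.is_leaf() else None for n in nodes]
    return nodes, parent, leaf_name


def brute_min_cost(
    tree: SpeciesTree,
    presence: dict[str, str],
    gain: float,
    loss: float,
) -> tuple[float, int]:
    """Exhaustive minimum event cost and number of co-optimal assignments.

    Enumerates every assignment of present/absent to internal nodes and to
    ``unknown`` tips.  A present root is charged one gain unless ``gain`` is
    infinite (single free origin; branch gains then forbidden).
    """
    nodes, parent, leaf_name = _tree_arrays(tree)
    dollo = math.isinf(gain)
    free = [
        i for i, name in enumerate(leaf_name)
        if name is None or presence[name] == UNKNOWN
    ]
    fixed = {
        i: (1 if presence[name] == PRESENT else 0)
        for i, name in enumerate(leaf_name)
        if name is not None and presence[name] != UNKNOWN
    }
    best, count = math.inf, 0
    for bits in itertools.product((0, 1), repeat=len(free)):
        state = dict(fixed)
        state.update(zip(free, bits))
        cost = 0.0
        if state[0] == 1 and not dollo:
            cost += gain
        ok = True
        for i in range(1, len(nodes)):
            p, c = state[parent[i]], state[i]
            if p == 0 and c == 1:
                if dollo:
                    ok = False
                    break
                cost += gain
            elif p == 1 and c == 0:
                cost += loss
        if not ok:
            continue
        if cost < best - 1e-12:
            best, count = cost, 1
        elif abs(cost - best) <= 1e-12:
            count += 1
    return best, count


def brute_dollo_losses(
    tree: SpeciesTree,
    presence: dict[str, str],
    origin_mode: str = "root",
) -> int:
    """Exhaustive minimal loss count under a single-gain (Dollo) model.

    The origin node is forced present; below it no absent->present transition
    is allowed; tips match their states (unknown tips are free).  Returns the
    minimum number of present->absent transitions over all valid assignments.
    """
    present_tips = {t for t, s in presence.items() if s == PRESENT}
    origin = tree.root if origin_mode == "root" else tree.mrca(present_tips)
    nodes = [origin] + [n for n in origin.preorder_iter() if n is not origin]
    index = {id(n): i for i, n in enumerate(nodes)}
    parent = [index[id(n.parent_node)] if i else -1 for i, n in enumerate(nodes)]
    free, fixed = [], {0: 1}  # origin present
    for i, n in enumerate(nodes):
        if i == 0:
            continue
        if n.is_leaf():
            s = presence[n.taxon.label]
            if s == UNKNOWN:
                free.append(i)
            else:
                fixed[i] = 1 if s == PRESENT else 0
        else:
            free.append(i)
    best = math.inf
    for bits in itertools.product((0, 1), repeat=len(free)):
        state = dict(fixed)
        state.update(zip(free, bits))
        losses = 0
        ok = True
        for i in range(1, len(nodes)):
            p, c = state[parent[i]], state[i]
            if p == 0 and c == 1:
                ok = False
                break
            if p == 1 and c == 0:
                losses += 1
        if ok:
            best = min(best, losses)
    return best


# ---------------------------------------------------------------------------
# Exhaustive optimal-alignment identity
# ---------------------------------------------------------------------------

_BLOSUM = substitution_matrices.load("BLOSUM62")
_ORACLE_GAP_OPEN = 10.0
_ORACLE_GAP_EXTEND = 1.0


@lru_cache(maxsize=None)
def _all_paths(la: int, lb: int) -> tuple[str, ...]:
    """Every monotone alignment path as a string over M (match column),
    A (residue in a only) and B (residue in b only)."""
    if la == 0 and lb == 0:
        return ("",)
    paths = []
    if la and lb:
        paths += [p + "M" for p in _all_paths(la - 1, lb - 1)]
    if la:
        paths += [p + "A" for p in _all_paths(la - 1, lb)]
    if lb:
        paths += [p + "B" for p in _all_paths(la, lb - 1)]
    return tuple(paths)


def _score_path(path: str, a: str, b: str) -> float:
    """Affine-gap score of one alignment; terminal gap runs are free."""
    score = 0.0
    i = j = 0
    runs: list[tuple[int, int]] = []  # (start, end) of each gap run in path
    prev = "M"
    for k, move in enumerate(path):
        if move == "M":
            score += _BLOSUM[a[i], b[j]]
            i += 1
            j += 1
        else:
            if move == prev:
                runs[-1] = (runs[-1][0], k)
            else:
                runs.append((k, k))
            i += move == "A"
            j += move == "B"
        prev = move
    for start, end in runs:
        if start == 0 or end == len(path) - 1:
            continue  # terminal overhang: free
        score -= _ORACLE_GAP_OPEN + _ORACLE_GAP_EXTEND * (end - start)
    return score


def _path_rows(path: str, a: str, b: str) -> tuple[str, str]:
    ra, rb = [], []
    i = j = 0
    for move in path:
        ra.append(a[i] if move != "B" else "-")
        rb.append(b[j] if move != "A" else "-")
        i += move != "B"
        j += move != "A"
    return "".join(ra), "".join(rb)


def brute_identity(a: str, b: str) -> float:
    """Max identity over all maximum-score alignments, by full enumeration.

    Identity convention mirrors the library: identical columns over all
    columns between the first and last residue-residue column.
    """
    if a == b:
        return 100.0
    paths = _all_paths(len(a), len(b))
    scores = [_score_path(p, a, b) for p in paths]
    best_score = max(scores)
    best_identity = 0.0
    for p, s in zip(paths, scores):
        if abs(s - best_score) > 1e-9:
            continue
        ra, rb = _path_rows(p, a, b)
        both = [k for k, (x, y) in enumerate(zip(ra, rb)) if x != "-" and y != "-"]
        if not both:
            continue
        lo, hi = both[0], both[-1] + 1
        matches = sum(
            1 for x, y in zip(ra[lo:hi], rb[lo:hi]) if x == y and x != "-"
        )
        best_identity = max(best_identity, 100.0 * matches / (hi - lo))
    return best_identity
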