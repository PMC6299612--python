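"""Gene gain/loss reconciliation of a family's presence/absence with a species tree.

Implements three related analyses used to weigh vertical-descent against
lateral-transfer explanations for a patchily distributed gene family:

* :func:`dollo_losses` — Dollo parsimony: the family is gained exactly once (at
  the root or at the MRCA of the present tips) and thereafter only lost.  The
  minimal loss set is the set of *maximal* all-absent subtrees below the
  origin, one loss event per subtree.
* :func:`min_cost_history` — minimum-cost ancestral-state reconstruction with
  asymmetric event costs (absent->present = gain, present->absent = loss),
  computed by a two-state Sankoff dynamic programme.  Letting the gain cost go
  to infinity recovers the Dollo solution.
* :func:`is_monophyletic` — deterministic monophyly predicate for a tip set on
  a rooted gene tree.

Polytomies are handled throughout: each child of a multifurcating node is an
independent subtree, so k all-absent sibling subtrees count k losses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import dendropy

from .io_formats import SpeciesTree

__all__ = [
    "EventCosts",
    "LossReport",
    "CostHistory",
    "dollo_losses",
    "min_cost_history",
    "scenario_table",
    "is_monophyletic",
]

PRESENT, ABSENT, UNKNOWN = "present", "absent", "unknown"
_STATES = (ABSENT, PRESENT)  # DP state order; index 0 = absent, 1 = present


@dataclass(frozen=True)
class EventCosts:
    """Costs for a gain (absent->present) and a loss (present->absent) event.

    ``gain = math.inf`` forbids gains below the root entirely (Dollo regime);
    the single origin at the root is then granted as an uncosted event.
    """

    gain: float = 1.0
    loss: float = 1.0

    def __post_init__(self) -> None:
        if not (self.gain > 0 and self.loss > 0):
            raise ValueError("event costs must be positive")


@dataclass
class LossReport:
    """Result of Dollo loss counting for one gene family."""

    family: str
    origin_label: str
    origin_tips: frozenset[str]
    loss_branches: list[frozenset[str]]
    unresolved_branches: list[frozenset[str]]
    present_tips: frozenset[str]

    @property
    def loss_count(self) -> int:
        return len(self.loss_branches)


@dataclass
class CostHistory:
    """Result of minimum-cost gain/loss reconstruction for one family."""

    family: str
    total_cost: float
    events: list[tuple[frozenset[str], str]]  # (tips below edge, "gain"/"loss")
    root_state: str
    n_optimal: int  # number of co-optimal full ancestral assignments

    @property
    def n_gains(self) -> int:
        return sum(1 for _, kind in self.events if kind == "gain")

    @property
    def n_losses(self) -> int:
        return sum(1 for _, kind in self.events if kind == "loss")


def _normalise_states(
    tree: SpeciesTree,
    presence: Mapping[str, str],
    unknown_mode: str,
) -> dict[str, str]:
    states: dict[str, str] = {}
    for tip in tree.tip_names:
        if tip not in presence:
            raise KeyError(f"tree tip {tip!r} missing from presence column")
        state = presence[tip]
        if state not in (PRESENT, ABSENT, UNKNOWN):
            raise ValueError(f"invalid presence state {state!r} for tip {tip!r}")
        if state == UNKNOWN:
            if unknown_mode == "as_absent":
                state = ABSENT
            elif unknown_mode == "as_present":
                state = PRESENT
            elif unknown_mode != "excluded":
                raise ValueError(f"invalid unknown_mode {unknown_mode!r}")
        states[tip] = state
    return states


def dollo_losses(
    tree: SpeciesTree,
    presence: Mapping[str, str],
    *,
    origin_mode: str = "mrca",
    unknown_mode: str = "excluded",
    family: str = "",
) -> LossReport:
    """Count gene losses under a single-gain (Dollo) vertical-descent model.

    The family is gained once, at the root (``origin_mode="root"``) or at the
    MRCA of the present tips (``"mrca"``), and each *maximal* subtree below the
    origin whose tips are all absent is one loss event.  Maximality guarantees
    the loss count is minimal among single-gain explanations.

    ``unknown_mode`` controls tips in state ``unknown``: ``"excluded"``
    (default) leaves them out of loss attribution — a subtree of only-unknown
    tips is reported under ``unresolved_branches`` rather than as a loss —
    while ``"as_absent"``/``"as_present"`` recode them first.
    """
    states = _normalise_states(tree, presence, unknown_mode)
    present_tips = frozenset(t for t, s in states.items() if s == PRESENT)
    if not present_tips:
        raise ValueError("no present tips: cannot place a gain")

    if origin_mode == "root":
        origin = tree.root
    elif origin_mode == "mrca":
        origin = tree.mrca(present_tips)
    else:
        raise ValueError(f"invalid origin_mode {origin_mode!r}")

    losses: list[frozenset[str]] = []
    unresolved: list[frozenset[str]] = []

    def walk(node: dendropy.Node) -> None:
        tips = tree.leaf_set(node)
        tip_states = {states[t] for t in tips}
        if PRESENT in tip_states:
            for child in node.child_nodes():
                walk(child)
        elif ABSENT in tip_states:
            losses.append(tips)  # maximal all-absent subtree
        else:
            unresolved.append(tips)  # unknown-only subtree

    if origin.is_leaf():
        pass  # origin on a single present tip: nothing below it to lose
    else:
        for child in origin.child_nodes():
            walk(child)

    return LossReport(
        family=family,
        origin_label=tree.node_label(origin) or "|".join(sorted(tree.leaf_set(origin)))[:80],
        origin_tips=tree.leaf_set(origin),
        loss_branches=losses,
        unresolved_branches=unresolved,
        present_tips=present_tips,
    )


def min_cost_history(
    tree: SpeciesTree,
    presence: Mapping[str, str],
    costs: EventCosts = EventCosts(),
    *,
    unknown_mode: str = "excluded",
    family: str = "",
) -> CostHistory:
    """Minimum-cost gain/loss history by two-state Sankoff dynamic programming.

    Transitions on a branch cost ``costs.gain`` (absent->present) or
    ``costs.loss`` (present->absent).  A present root is charged one gain (the
    origin), except in the Dollo regime (``gain = inf``) where branch gains are
    forbidden and the root origin is granted free of charge (but still reported
    as an event).  Ties at the root favour the absent state, i.e. the gain is
    placed as late as possible.  Unknown tips are free to take either state
    under ``unknown_mode="excluded"``.

    Returns one deterministic optimal event placement plus the number of
    co-optimal full ancestral-state assignments.
    """
    states = _normalise_states(tree, presence, unknown_mode)
    if all(s == UNKNOWN for s in states.values()):
        raise ValueError("presence column is entirely unknown")
    dollo_regime = math.isinf(costs.gain)
    trans = _transition_costs(costs, dollo_regime)

    # Bottom-up pass: cost[node][state], count[node][state]
    cost: dict[dendropy.Node, list[float]] = {}
    count: dict[dendropy.Node, list[int]] = {}
    for node in tree._tree.postorder_node_iter():
        if node.is_leaf():
            s = states[node.taxon.label]
            if s == UNKNOWN:
                cost[node], count[node] = [0.0, 0.0], [1, 1]
            elif s == ABSENT:
                cost[node], count[node] = [0.0, math.inf], [1, 0]
            else:
                cost[node], count[node] = [math.inf, 0.0], [0, 1]
            continue
        c = [0.0, 0.0]
        k = [1, 1]
        for child in node.child_nodes():
            for s in (0, 1):
                options = [trans[s][t] + cost[child][t] for t in (0, 1)]
                best = min(options)
                c[s] += best
                if math.isinf(best):
                    k[s] = 0
                else:
                    k[s] *= sum(
                        count[child][t]
                        for t in (0, 1)
                        if options[t] == best and count[child][t]
                    )
        cost[node], count[node] = c, k

    root = tree.root
    root_cost = [
        cost[root][0],
        cost[root][1] + (0.0 if dollo_regime else costs.gain),
    ]
    best_cost = min(root_cost)
    if math.isinf(best_cost):
        raise ValueError("no finite-cost history exists")
    n_optimal = sum(
        count[root][s] for s in (0, 1) if root_cost[s] == best_cost
    )
    root_state = 0 if root_cost[0] == best_cost else 1  # tie -> absent

    # Deterministic traceback: on ties keep the parent's state (fewest events).
    events: list[tuple[frozenset[str], str]] = []
    if root_state == 1:
        events.append((tree.leaf_set(root), "gain"))

    def trace(node: dendropy.Node, state: int) -> None:
        for child in node.child_nodes():
            options = [trans[state][t] + cost[child][t] for t in (0, 1)]
            best = min(options)
            child_state = state if options[state] == best else (1 - state)
            if child_state != state:
                kind = "gain" if child_state == 1 else "loss"
                events.append((tree.leaf_set(child), kind))
            if not child.is_leaf():
                trace(child, child_state)

    trace(root, root_state)
    return CostHistory(
        family=family,
        total_cost=best_cost,
        events=events,
        root_state=_STATES[root_state],
        n_optimal=n_optimal,
    )


def _transition_costs(costs: EventCosts, dollo_regime: bool):
    gain = math.inf if dollo_regime else costs.gain
    # trans[parent][child]
    return (
        (0.0, gain),  # parent absent
        (costs.loss, 0.0),  # parent present
    )


def scenario_table(
    tree: SpeciesTree,
    presence: Mapping[str, str],
    gain_costs: Iterable[float],
    *,
    loss_cost: float = 1.0,
    unknown_mode: str = "excluded",
    family: str = "",
) -> "pd.DataFrame":
    """Sweep the gain/loss cost ratio and tabulate the optimal event mix.

    One row per gain cost (in the given order) plus a final pure-Dollo row
    (``gain = inf``).  Columns: ``gain_cost``, ``ratio`` (gain/loss), ``gains``,
    ``losses``, ``total_cost``, ``n_optimal``.  As the ratio rises the optimal
    number of gains is non-increasing: expensive gains push the history toward
    a single ancient origin followed by losses.
    """
    import pandas as pd

    rows = []
    sweep = list(gain_costs) + [math.inf]
    for g in sweep:
        hist = min_cost_history(
            tree,
            presence,
            EventCosts(gain=g, loss=loss_cost),
            unknown_mode=unknown_mode,
            family=family,
        )
        rows.append(
            {
                "gain_cost": g,
                "ratio": g / loss_cost,
                "gains": hist.n_gains,
                "losses": hist.n_losses,
                "total_cost": hist.total_cost,
                "n_optimal": hist.n_optimal,
            }
        )
    return pd.DataFrame(rows)


def is_monophyletic(
    gene_tree: SpeciesTree, tip_set: Iterable[str]
) -> tuple[bool, int]:
    """Test whether ``tip_set`` forms a clade on a rooted gene tree.

    Returns ``(monophyletic, mrca_clade_size)``; the MRCA clade size equals
    ``len(tip_set)`` iff the set is monophyletic.  Singletons are monophyletic
    by convention.  Unknown tip names raise ``KeyError`` listing them.
    """
    names = set(tip_set)
    if not names:
        raise ValueError("empty tip set")
    missing = names - set(gene_tree.tip_names)
    if missing:
        raise KeyError(f"unknown tip names: {sorted(missing)}")
    mrca = gene_tree.mrca(names)
    clade = gene_tree.leaf_set(mrca)
    return clade == frozenset(names), len(clade)
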