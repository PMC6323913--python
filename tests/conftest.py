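"""Shared fixtures and independent oracles.

The oracles here deliberately re-derive results by a different route than
the library (fixed-point iteration instead of topological evaluation,
boolean matrix closure instead of graph algorithms) so the tests check the
implementation against an independent computation, not against itself.
"""

from __future__ import annotations

import numpy as np
import pytest

from genprops.matches import MatchTable
from genprops.model import (
    Evidence,
    EvidenceKind,
    GenomeProperty,
    PropertyRegistry,
    PropertyType,
    ResultState,
    Step,
)


def make_step(number, accessions, required=True, step_id=None):
    return Step(
        number=number,
        id=step_id or f"step_{number}",
        required=required,
        evidences=tuple(Evidence(a) for a in accessions),
    )


def make_prop(accession, ptype=PropertyType.PATHWAY, threshold=0, steps=(), name=None):
    return GenomeProperty(
        accession=accession,
        name=name or f"Property {accession}",
        type=ptype,
        threshold=threshold,
        steps=tuple(steps),
    )


def table_from_pairs(pairs, label="test"):
    """MatchTable from (protein, accession) pairs."""
    table = MatchTable(label=label)
    for protein, acc in pairs:
        table.matches.setdefault(protein, set()).add(acc)
    return table


# -- independent oracles ----------------------------------------------------

def fixed_point_states(registry, table, partial_counts=False):
    """Brute-force evaluator: iterate full re-evaluation until stable.

    Starts from all-NO and sweeps every property in accession order; since
    evidence matching is monotone in the sub-property states, this
    converges to the unique least fixed point that the topological
    evaluator must also produce.
    """
    states = {acc: ResultState.NO for acc in registry.accessions()}
    changed = True
    while changed:
        changed = False
        for acc in registry.accessions():
            prop = registry[acc]
            matched_required = 0
            total_required = 0
            for step in prop.steps:
                matched = False
                for ev in step.evidences:
                    if ev.kind is EvidenceKind.INTERPRO:
                        if any(ev.accession in accs for accs in table.matches.values()):
                            matched = True
                    elif ev.accession in states:
                        sub = states[ev.accession]
                        if sub is ResultState.YES or (
                            partial_counts and sub is ResultState.PARTIAL
                        ):
                            matched = True
                if step.required:
                    total_required += 1
                    matched_required += matched
            if total_required > 0 and matched_required == total_required:
                new = ResultState.YES
            elif matched_required > prop.threshold:
                new = ResultState.PARTIAL
            else:
                new = ResultState.NO
            if new is not states[acc]:
                states[acc] = new
                changed = True
    return states


def has_cycle_bruteforce(nodes, edges):
    """Transitive closure by boolean matrix powers; cycle iff any self-reach."""
    idx = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    adj = np.zeros((n, n), dtype=bool)
    for u, v in edges:
        if u in idx and v in idx:
            adj[idx[u], idx[v]] = True
    closure = adj.copy()
    for _ in range(n):
        closure = closure | (closure @ adj)
    return bool(np.diag(closure).any())


def reachable_bruteforce(roots, edges):
    """Plain BFS reachability (roots included)."""
    adj = {}
    for u, v in edges:
        adj.setdefault(u, []).append(v)
    seen = set(roots)
    frontier = list(roots)
    while frontier:
        node = frontier.pop()
        for nxt in adj.get(node, ()):
            if nxt not in seen:
                seen.add(nxt)
                frontier.append(nxt)
    return seen


# -- shared fixtures ---------------------------------------------------------

@pytest.fixture
def two_leaf_registry():
    """Two leaf pathways, a metapath citing both, a root category."""
    leaf_a = make_prop(
        "GenProp0001",
        threshold=0,
        steps=[make_step(1, ["IPR900001"]), make_step(2, ["IPR900002"])],
        name="Threonine biosynthesis from aspartate semialdehyde",
    )
    leaf_b = make_prop(
        "GenProp0002",
        threshold=0,
        steps=[make_step(1, ["IPR900003"]), make_step(2, ["IPR900004"])],
        name="Biotin synthesis",
    )
    metapath = make_prop(
        "GenProp0010",
        ptype=PropertyType.METAPATH,
        threshold=0,
        steps=[make_step(1, ["GenProp0001"]), make_step(2, ["GenProp0002"])],
        name="Amino acid and cofactor metapath",
    )
    category = make_prop(
        "GenProp0100",
        ptype=PropertyType.CATEGORY,
        steps=[
            make_step(1, ["GenProp0001"]),
            make_step(2, ["GenProp0002"]),
            make_step(3, ["GenProp0010"]),
        ],
        name="Root category",
    )
    return PropertyRegistry([leaf_a, leaf_b, metapath, category])
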