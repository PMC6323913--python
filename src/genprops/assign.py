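"""Assignment engine: assert each property YES/PARTIAL/NO for a proteome.

Semantics
---------
A step is matched when at least one of its evidence lines matches: an
InterPro evidence line matches when at least one protein in the table
carries that accession; a property evidence line matches when the cited
property itself evaluated YES (or YES/PARTIAL under ``partial_counts``).

Only *required* steps decide the outcome.  With R required steps, T the
property's threshold and m the number of matched required steps:

    m = R (R > 0)   ->  YES
    T < m < R       ->  PARTIAL
    m <= T          ->  NO

Optional steps are evaluated and reported but never change the state.  A
property with no required steps can never be YES and is reported NO (the
QC layer flags such records).

Properties are evaluated in topological order of their evidence
dependencies, so every cited property is resolved before its citers; the
whole computation is deterministic.

Three tabular report forms are provided: a summary (one row per
property), a long form adding one row per step, and a protein-centric
form listing which proteins satisfied which step evidence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

from .matches import MatchTable
from .model import (
    EvidenceKind,
    GenomeProperty,
    GraphCycleError,
    PropertyRegistry,
    ResultState,
    Step,
)

__all__ = [
    "StepResult",
    "PropertyResult",
    "evaluate_step",
    "evaluate_property",
    "evaluate_all",
    "summary_report",
    "long_report",
    "protein_report",
]


@dataclass(frozen=True)
class StepResult:
    """Outcome of one step: matched flag plus the evidence that fired.

    ``matched_by`` pairs each matched evidence accession with the sorted
    protein identifiers that carried it; the protein list is empty for
    property evidence satisfied by a sub-property's result.
    """

    number: int
    required: bool
    matched: bool
    matched_by: tuple[tuple[str, tuple[str, ...]], ...] = ()


@dataclass(frozen=True)
class PropertyResult:
    """Outcome of one property: state plus per-step detail and counts."""

    accession: str
    state: ResultState
    step_results: tuple[StepResult, ...]
    required_total: int
    required_matched: int


def evaluate_step(
    step: Step,
    table: MatchTable,
    resolved: Mapping[str, PropertyResult],
    partial_counts: bool = False,
    use_signatures: bool = False,
) -> StepResult:
    """Evaluate one step against the match table.

    ``resolved`` must already hold a result for every property cited as
    evidence by this step (guaranteed by :func:`evaluate_all`'s ordering);
    a missing entry is a programming error.  ``use_signatures`` lets an
    InterPro evidence line fall back to its raw member-database signatures
    when the integrated accession itself has no match.
    """
    matched_by: list[tuple[str, tuple[str, ...]]] = []
    for ev in step.evidences:
        if ev.kind is EvidenceKind.INTERPRO:
            proteins = table.proteins_matching(ev.accession)
            if not proteins and use_signatures and ev.raw_signatures:
                proteins = frozenset().union(
                    *(table.proteins_matching_signature(s) for s in ev.raw_signatures)
                )
            if proteins:
                matched_by.append((ev.accession, tuple(sorted(proteins))))
        else:
            if ev.accession not in resolved:
                raise KeyError(
                    f"evidence {ev.accession} of step {step.number} not resolved"
                )
            sub = resolved[ev.accession].state
            ok = sub is ResultState.YES or (
                partial_counts and sub is ResultState.PARTIAL
            )
            if ok:
                matched_by.append((ev.accession, ()))
    return StepResult(
        number=step.number,
        required=step.required,
        matched=bool(matched_by),
        matched_by=tuple(matched_by),
    )


def evaluate_property(
    prop: GenomeProperty,
    table: MatchTable,
    resolved: Mapping[str, PropertyResult],
    partial_counts: bool = False,
    use_signatures: bool = False,
) -> PropertyResult:
    """Evaluate one property, all of whose cited properties are resolved."""
    if not prop.steps:
        warnings.warn(f"{prop.accession} has no steps; reported NO", stacklevel=2)
    step_results = tuple(
        evaluate_step(step, table, resolved, partial_counts, use_signatures)
        for step in prop.steps
    )
    required = [r for r in step_results if r.required]
    required_total = len(required)
    required_matched = sum(r.matched for r in required)
    if required_total > 0 and required_matched == required_total:
        state = ResultState.YES
    elif required_matched > prop.threshold:
        state = ResultState.PARTIAL
    else:
        state = ResultState.NO
    return PropertyResult(
        accession=prop.accession,
        state=state,
        step_results=step_results,
        required_total=required_total,
        required_matched=required_matched,
    )


def evaluate_all(
    registry: PropertyRegistry,
    table: MatchTable,
    partial_counts: bool = False,
    use_signatures: bool = False,
) -> dict[str, PropertyResult]:
    """Evaluate every registered property against one match table.

    Properties are processed in (deterministic) topological order of the
    evidence graph; a cycle aborts with :class:`GraphCycleError` carrying
    the offending path.  The returned mapping is keyed and ordered by
    accession.
    """
    unresolved = registry.unresolved_evidence()
    if unresolved:
        raise KeyError(
            "dangling property evidence: "
            + ", ".join(f"{a}->{b}" for a, b in unresolved)
        )
    order = registry.topological_order()  # raises GraphCycleError on cycles
    resolved: dict[str, PropertyResult] = {}
    for acc in order:
        resolved[acc] = evaluate_property(
            registry[acc], table, resolved, partial_counts, use_signatures
        )
    return {acc: resolved[acc] for acc in registry.accessions()}


# -- reports ---------------------------------------------------------------

def _report_accessions(
    results: Mapping[str, PropertyResult],
    registry: PropertyRegistry,
    include_categories: bool,
) -> list[str]:
    accs = sorted(results)
    if not include_categories:
        accs = [
            a for a in accs
            if a not in registry or not registry[a].is_category
        ]
    return accs


def summary_report(
    results: Mapping[str, PropertyResult],
    registry: PropertyRegistry,
    include_categories: bool = False,
) -> str:
    """One row per property: accession, name, state (TSV, header row).

    Organisational categories are excluded by default; they carry no
    biological assertion of their own.
    """
    if not results:
        raise ValueError("no results to report")
    lines = ["accession\tname\tstate"]
    for acc in _report_accessions(results, registry, include_categories):
        name = registry[acc].name if acc in registry else ""
        lines.append(f"{acc}\t{name}\t{results[acc].state}")
    return "\n".join(lines) + "\n"


def long_report(
    results: Mapping[str, PropertyResult],
    registry: PropertyRegistry,
    include_categories: bool = False,
) -> str:
    """Summary rows interleaved with one row per step.

    Columns: accession, row kind (``property`` or the step number), name or
    step id, state or matched flag (``MATCHED``/``UNMATCHED``).
    """
    if not results:
        raise ValueError("no results to report")
    lines = ["accession\trow\tname\tvalue"]
    for acc in _report_accessions(results, registry, include_categories):
        res = results[acc]
        prop = registry.get(acc)
        name = prop.name if prop else ""
        lines.append(f"{acc}\tproperty\t{name}\t{res.state}")
        steps_by_number = {s.number: s for s in prop.steps} if prop else {}
        for sr in res.step_results:
            step_id = steps_by_number[sr.number].id if sr.number in steps_by_number else ""
            flag = "MATCHED" if sr.matched else "UNMATCHED"
            lines.append(f"{acc}\t{sr.number}\t{step_id}\t{flag}")
    return "\n".join(lines) + "\n"


def protein_report(
    results: Mapping[str, PropertyResult],
    registry: PropertyRegistry,
    include_categories: bool = True,
) -> str:
    """Protein-centric report: which proteins matched which step evidence.

    Columns: protein, property accession, step number, evidence accession;
    sorted by property accession, then step number, then protein.  Only
    InterPro evidence contributes protein rows, so an all-NO result set
    yields an empty body.
    """
    if not results:
        raise ValueError("no results to report")
    rows: list[tuple[str, str, int, str]] = []
    for acc in _report_accessions(results, registry, include_categories):
        for sr in results[acc].step_results:
            for evidence_acc, proteins in sr.matched_by:
                for protein in proteins:
                    rows.append((acc, sr.number, protein, evidence_acc))
    rows.sort()
    lines = ["protein\tproperty\tstep\tevidence"]
    for acc, step_no, protein, evidence_acc in rows:
        lines.append(f"{protein}\t{acc}\t{step_no}\t{evidence_acc}")
    return "\n".join(lines) + "\n"
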