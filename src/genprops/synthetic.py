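"""Deterministic synthetic registries, match tables and sidecars.

Everything in the package is testable without downloading real release
data: this module plants a ground truth (a target YES/PARTIAL/NO state per
property per proteome) and fabricates the artefacts -- a DESC flatfile, an
InterProScan-style TSV per proteome, FASTA sidecars -- that make the
assignment engine reproduce that truth exactly.

Synthetic identifiers live in reserved ranges so they can never collide
with real accessions: properties ``GenProp9xxx``, InterPro evidence
``IPR9xxxxx``, proteins ``<label>_P000N``.  All generation is a pure
function of the seed (byte-identical outputs on repeat).

The generator emulates the *structure* of release data (step counts,
required/optional mixes, metapath nesting, category wiring), not its
biology: evidence accessions are unique to one step, protein sequences are
random strings, and no real pathway content is represented.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import yaml

from .desc import FastaSidecar
from .model import (
    Evidence,
    GenomeProperty,
    PropertyRegistry,
    PropertyType,
    ResultState,
    Step,
)

__all__ = [
    "FixtureConfig",
    "make_registry",
    "make_matches",
    "make_sidecars",
    "random_feasible_states",
    "make_grouped_profiles",
    "synthesize_overlap_sets",
]

_AMINO = "ACDEFGHIKLMNPQRSTVWY"

#: leaf (non-organisational, non-nested) property types cycled by the generator
_LEAF_TYPES = (
    PropertyType.PATHWAY,
    PropertyType.SYSTEM,
    PropertyType.GUILD,
    PropertyType.COMPLEX,
)


@dataclass
class FixtureConfig:
    """Shape of a synthetic registry.

    ``threshold_rule`` is either ``"half"`` (threshold = (R-1)//2 for R
    required steps, which always leaves a PARTIAL window for R >= 2) or
    ``"zero"``.  ``steps_range`` is inclusive; leaf properties always get
    at least two required steps so every state is plantable.
    """

    n_pathway: int = 6
    n_system: int = 2
    n_guild: int = 1
    n_complex: int = 2
    n_metapath: int = 2
    n_category: int = 1
    steps_range: tuple[int, int] = (2, 4)
    required_fraction: float = 0.8
    threshold_rule: str = "half"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_category < 1:
            raise ValueError("need at least one category to root the hierarchy")
        if self.steps_range[0] < 2 or self.steps_range[1] < self.steps_range[0]:
            raise ValueError(f"bad steps_range {self.steps_range}")
        if not 0.0 < self.required_fraction <= 1.0:
            raise ValueError("required_fraction must be in (0, 1]")
        if self.threshold_rule not in {"half", "zero"}:
            raise ValueError(f"unknown threshold_rule {self.threshold_rule!r}")

    def leaf_counts(self) -> dict[PropertyType, int]:
        return {
            PropertyType.PATHWAY: self.n_pathway,
            PropertyType.SYSTEM: self.n_system,
            PropertyType.GUILD: self.n_guild,
            PropertyType.COMPLEX: self.n_complex,
        }

    @classmethod
    def from_yaml(cls, text: str) -> "FixtureConfig":
        data = yaml.safe_load(text) or {}
        if "steps_range" in data:
            data["steps_range"] = tuple(data["steps_range"])
        return cls(**data)


def _threshold(rule: str, n_required: int) -> int:
    if rule == "zero" or n_required < 2:
        return 0
    return (n_required - 1) // 2


def make_registry(config: FixtureConfig) -> PropertyRegistry:
    """Generate an acyclic registry wired to pass every release check.

    Leaf properties carry fresh ``IPR9xxxxx`` evidence (one or two
    alternative lines per step, never shared between steps); metapaths
    cite leaves; categories cite metapaths, the remaining leaves, and --
    for the root -- the other categories.  Deterministic in the seed.
    """
    rng = np.random.default_rng(config.seed)
    registry = PropertyRegistry()
    acc_counter = 9000
    ipr_counter = 900000
    leaves: list[str] = []

    leaf_specs: list[PropertyType] = []
    for ptype, count in config.leaf_counts().items():
        leaf_specs.extend([ptype] * count)

    for ptype in leaf_specs:
        accession = f"GenProp{acc_counter}"
        acc_counter += 1
        n_steps = int(rng.integers(config.steps_range[0], config.steps_range[1] + 1))
        n_required = max(2, round(config.required_fraction * n_steps))
        n_required = min(n_required, n_steps)
        steps = []
        for i in range(n_steps):
            n_ev = int(rng.integers(1, 3))
            evs = []
            for _ in range(n_ev):
                evs.append(Evidence(f"IPR{ipr_counter}"))
                ipr_counter += 1
            steps.append(
                Step(
                    number=i + 1,
                    id=f"{accession.lower()}_s{i + 1}",
                    required=i < n_required,
                    evidences=tuple(evs),
                )
            )
        registry.register(
            GenomeProperty(
                accession=accession,
                name=f"Synthetic {ptype.value.lower()} {accession[-4:]}",
                type=ptype,
                threshold=_threshold(config.threshold_rule, n_required),
                description=f"Synthetic fixture property of type {ptype.value}.",
                steps=tuple(steps),
            )
        )
        leaves.append(accession)

    # metapaths cite disjoint-ish slices of the leaves
    metapaths: list[str] = []
    metapath_cited: set[str] = set()
    for _ in range(config.n_metapath):
        accession = f"GenProp{acc_counter}"
        acc_counter += 1
        k = int(rng.integers(2, min(4, len(leaves)) + 1)) if leaves else 0
        cited = sorted(rng.choice(leaves, size=k, replace=False)) if k else []
        steps = tuple(
            Step(
                number=i + 1,
                id=f"{accession.lower()}_s{i + 1}",
                required=True,
                evidences=(Evidence(child),),
            )
            for i, child in enumerate(cited)
        )
        registry.register(
            GenomeProperty(
                accession=accession,
                name=f"Synthetic metapath {accession[-4:]}",
                type=PropertyType.METAPATH,
                threshold=_threshold(config.threshold_rule, len(steps)),
                steps=steps,
            )
        )
        metapaths.append(accession)
        metapath_cited |= set(cited)

    # categories: the root cites sub-categories + metapaths; leaves and
    # metapaths are distributed over the sub-categories (a property may be
    # cited by both a metapath and a category -- the hierarchy is a DAG)
    pool = leaves + metapaths
    if not pool:
        raise ValueError("config yields no leaf or metapath properties to categorise")
    sub_categories: list[str] = []
    category_accs = [f"GenProp{acc_counter + i}" for i in range(config.n_category)]
    acc_counter += config.n_category
    root_acc = category_accs[0]
    buckets: dict[str, list[str]] = {acc: [] for acc in category_accs[1:] or [root_acc]}
    bucket_keys = list(buckets)
    for i, member in enumerate(pool):
        buckets[bucket_keys[i % len(bucket_keys)]].append(member)
    if any(not members for members in buckets.values()):
        raise ValueError(
            f"{config.n_category} categories but only {len(pool)} properties to file"
        )

    for acc in category_accs[1:]:
        members = buckets[acc]
        steps = tuple(
            Step(number=i + 1, id=f"member_{i + 1}", evidences=(Evidence(m),))
            for i, m in enumerate(members)
        )
        registry.register(
            GenomeProperty(
                accession=acc,
                name=f"Synthetic category {acc[-4:]}",
                type=PropertyType.CATEGORY,
                threshold=0,
                steps=steps,
            )
        )
        sub_categories.append(acc)

    root_members = list(sub_categories)
    if root_acc in buckets:
        root_members += buckets[root_acc]
    steps = tuple(
        Step(number=i + 1, id=f"member_{i + 1}", evidences=(Evidence(m),))
        for i, m in enumerate(sorted(root_members))
    )
    registry.register(
        GenomeProperty(
            accession=root_acc,
            name="Synthetic root category",
            type=PropertyType.CATEGORY,
            threshold=0,
            steps=steps,
        )
    )
    return registry


def _is_leaf(prop: GenomeProperty) -> bool:
    return not prop.genprop_children()


def _partial_feasible(prop: GenomeProperty) -> bool:
    r = len(prop.required_steps)
    return prop.threshold + 1 <= r - 1


def _implied_state(prop: GenomeProperty, states: Mapping[str, ResultState]) -> ResultState:
    """State a property with property-evidence steps must take, given its
    children's planted states (strict semantics: a child satisfies a step
    only when YES)."""
    required_matched = 0
    required_total = 0
    for step in prop.steps:
        matched = any(
            states[ev.accession] is ResultState.YES
            for ev in step.evidences
            if ev.accession in states
        )
        if step.required:
            required_total += 1
            required_matched += matched
    if required_total > 0 and required_matched == required_total:
        return ResultState.YES
    if required_matched > prop.threshold:
        return ResultState.PARTIAL
    return ResultState.NO


def random_feasible_states(
    registry: PropertyRegistry,
    seed: int,
) -> dict[str, ResultState]:
    """A random full state vector the registry can actually realise.

    Leaf states are drawn uniformly from the feasible alternatives
    (PARTIAL only where the threshold leaves a window); nested properties
    take the state their children imply.
    """
    rng = np.random.default_rng(seed)
    states: dict[str, ResultState] = {}
    for acc in registry.topological_order():
        prop = registry[acc]
        if not prop.steps:
            states[acc] = ResultState.NO  # nothing to match; always NO
        elif _is_leaf(prop):
            choices = [ResultState.NO, ResultState.YES]
            if _partial_feasible(prop):
                choices.append(ResultState.PARTIAL)
            states[acc] = choices[int(rng.integers(len(choices)))]
        else:
            states[acc] = _implied_state(prop, states)
    return states


def make_matches(
    registry: PropertyRegistry,
    planted_states: Mapping[str, ResultState],
    seed: int,
    label: str = "synthetic",
) -> str:
    """InterProScan-style TSV text realising the planted state vector.

    For each leaf property the number of matched required steps is chosen
    to land in the right band: all of them for YES, uniform in
    (threshold, R) for PARTIAL, uniform in [0, threshold] for NO; matched
    optional steps are coin-flipped.  Nested properties cannot be planted
    independently -- their planted state must equal the one their
    children's states imply, otherwise the vector is infeasible and a
    ``ValueError`` is raised.  Evidence accessions are unique to one step,
    so ``evaluate_all`` on the parsed output reproduces the plant exactly.
    """
    rng = np.random.default_rng(seed)
    rows: list[str] = []
    protein_counter = 0

    def emit(step: Step) -> None:
        nonlocal protein_counter
        ev = step.evidences[0]
        for _ in range(int(rng.integers(1, 3))):
            protein_counter += 1
            protein = f"{label}_P{protein_counter:04d}"
            sig = ev.raw_signatures[0] if ev.raw_signatures else f"SYN{ev.accession[3:]}"
            length = int(rng.integers(120, 900))
            rows.append(
                "\t".join(
                    [
                        protein,
                        "0" * 32,
                        str(length),
                        "SYNTHETIC",
                        sig,
                        "synthetic signature",
                        "1",
                        str(length),
                        "1e-30",
                        "T",
                        "01-01-2020",
                        ev.accession,
                        "synthetic entry",
                    ]
                )
            )

    for acc in registry.topological_order():
        prop = registry[acc]
        if acc not in planted_states:
            raise ValueError(f"no planted state for {acc}")
        target = ResultState(planted_states[acc])
        if not prop.steps:
            if target is not ResultState.NO:
                raise ValueError(f"{acc}: has no steps, can only be NO")
            continue
        if not _is_leaf(prop):
            implied = _implied_state(prop, planted_states)
            if implied is not target:
                raise ValueError(
                    f"{acc}: planted {target.name} but children imply {implied.name}"
                )
            continue
        required = [s for s in prop.steps if s.required]
        optional = [s for s in prop.steps if not s.required]
        r, t = len(required), prop.threshold
        if target is ResultState.YES:
            m = r
        elif target is ResultState.PARTIAL:
            if not _partial_feasible(prop):
                raise ValueError(
                    f"{acc}: PARTIAL infeasible (threshold {t}, required {r})"
                )
            m = int(rng.integers(t + 1, r))
        else:
            m = int(rng.integers(0, min(t, r) + 1))
        idx = sorted(rng.choice(r, size=m, replace=False)) if m else []
        for i in idx:
            emit(required[i])
        for step in optional:
            if rng.random() < 0.5:
                emit(step)
    return "\n".join(rows) + ("\n" if rows else "")


def make_sidecars(
    registry: PropertyRegistry,
    seed: int,
    seq_length: int = 60,
) -> dict[str, FastaSidecar]:
    """Random-sequence FASTA sidecars covering every InterPro-evidenced step."""
    rng = np.random.default_rng(seed)
    out: dict[str, FastaSidecar] = {}
    for prop in registry:
        if prop.is_category:
            continue
        sidecar = FastaSidecar(accession=prop.accession)
        for step in prop.steps:
            if not any(ev.kind.name == "INTERPRO" for ev in step.evidences):
                continue
            seq = "".join(rng.choice(list(_AMINO), size=seq_length))
            header = f"{prop.accession}_{step.id} step={step.number}"
            sidecar.sequences.append((header, seq))
            sidecar.step_map[header] = step.number
        if sidecar.sequences:
            out[prop.accession] = sidecar
    return out


def make_grouped_profiles(
    n_groups: int,
    n_per_group: int,
    separation: float,
    seed: int,
    n_block: int = 8,
    n_background: int = 20,
) -> tuple[dict[str, dict[str, ResultState]], dict[str, str]]:
    """Grouped fingerprints with a tunable group signal, for ANOSIM power tests.

    Each group owns a block of ``n_block`` marker properties: with
    probability ``separation`` a proteome shows its own block YES and the
    other blocks NO, otherwise the cell is uniform noise.  Background
    properties share one base state across all proteomes, again perturbed
    to noise with probability ``1 - separation``.  At separation 1 the
    profiles are identical within groups and differ between them (ANOSIM
    R = 1); at separation 0 everything is noise (R near 0).
    """
    if not 0.0 <= separation <= 1.0:
        raise ValueError("separation must be in [0, 1]")
    rng = np.random.default_rng(seed)
    all_states = list(ResultState)
    block_props = {
        g: [f"BLK{g:02d}_{i:03d}" for i in range(n_block)] for g in range(n_groups)
    }
    background = [f"BG_{i:03d}" for i in range(n_background)]
    base = {p: all_states[int(rng.integers(3))] for p in background}

    results: dict[str, dict[str, ResultState]] = {}
    groups: dict[str, str] = {}
    for g in range(n_groups):
        for i in range(n_per_group):
            label = f"proteome_g{g}_{i}"
            groups[label] = f"group{g}"
            profile: dict[str, ResultState] = {}
            for b in range(n_groups):
                ideal = ResultState.YES if b == g else ResultState.NO
                for p in block_props[b]:
                    if rng.random() < separation:
                        profile[p] = ideal
                    else:
                        profile[p] = all_states[int(rng.integers(3))]
            for p in background:
                if rng.random() < separation:
                    profile[p] = base[p]
                else:
                    profile[p] = all_states[int(rng.integers(3))]
            results[label] = profile
    return results, groups


def synthesize_overlap_sets(
    region_counts: Mapping[tuple[str, ...], int],
    prefix: str = "seq",
) -> dict[str, set[str]]:
    """Construct three annotation sets realising given exclusive region sizes.

    ``region_counts`` is keyed like
    :class:`~genprops.profile.OverlapPartition.region_counts`: sorted
    tuples of source names over exactly three sources, one entry per
    non-empty region wanted.  Synthetic sequence identifiers are disjoint
    across regions, so the partition of the result is exactly the input.
    """
    sources: set[str] = set()
    for combo in region_counts:
        sources.update(combo)
    if len(sources) != 3:
        raise ValueError(f"region keys must span exactly 3 sources, got {sources}")
    sets: dict[str, set[str]] = {s: set() for s in sorted(sources)}
    counter = 0
    for combo, count in sorted(region_counts.items()):
        for _ in range(count):
            counter += 1
            ident = f"{prefix}{counter:06d}"
            for source in combo:
                sets[source].add(ident)
    return sets
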