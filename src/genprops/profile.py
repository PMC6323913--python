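"""Phylogenetic profiling of property fingerprints across proteomes.

The vector of YES/PARTIAL/NO results over all properties is a compact
functional fingerprint of a proteome.  Stacking fingerprints gives a
property x proteome matrix which, numerically encoded (NO=0, PARTIAL=1,
YES=2), feeds standard multivariate machinery: Gower distances between
proteomes, ANOSIM to test whether a grouping (e.g. phylum) explains the
distance structure, PCA/clustering on the encoded matrix (delegated to
standard numerics downstream).

Also here: the three-source annotation-overlap partition used to compare
how much of a proteome different annotation resources cover (all seven
disjoint regions of a three-set Venn diagram, plus the unannotated
remainder).
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform
from scipy.stats import rankdata

from .assign import PropertyResult
from .model import ResultState

__all__ = [
    "ProfileMatrix",
    "OverlapPartition",
    "AnosimResult",
    "build_matrix",
    "encode_numeric",
    "decode_numeric",
    "gower_distance",
    "gower_matrix",
    "anosim",
    "overlap_partition",
    "export_long_table",
    "export_json",
]


@dataclass
class ProfileMatrix:
    """Property x proteome grid of result states.

    Rows are property accessions (sorted), columns proteome labels (input
    order).  Complete by construction: every cell holds a
    :class:`~genprops.model.ResultState`.
    """

    data: pd.DataFrame  # object dtype cells of ResultState

    @property
    def properties(self) -> list[str]:
        return list(self.data.index)

    @property
    def proteomes(self) -> list[str]:
        return list(self.data.columns)

    def state(self, prop: str, proteome: str) -> ResultState:
        return self.data.at[prop, proteome]

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape


def _as_state(value: Union[ResultState, PropertyResult]) -> ResultState:
    if isinstance(value, PropertyResult):
        return value.state
    return ResultState(value)


def build_matrix(
    results_by_proteome: Mapping[str, Mapping[str, Union[ResultState, PropertyResult]]],
) -> ProfileMatrix:
    """Stack per-proteome result maps into a complete profile matrix.

    Every proteome must cover the same property set; ragged inputs raise
    with the missing accessions listed per proteome.
    """
    if not results_by_proteome:
        raise ValueError("no proteomes given")
    labels = list(results_by_proteome)
    all_props = sorted(set().union(*(set(m) for m in results_by_proteome.values())))
    problems = []
    for label, mapping in results_by_proteome.items():
        missing = sorted(set(all_props) - set(mapping))
        if missing:
            problems.append(f"{label}: missing {', '.join(missing)}")
    if problems:
        raise ValueError("ragged result maps -- " + "; ".join(problems))
    data = pd.DataFrame(
        {
            label: [_as_state(results_by_proteome[label][p]) for p in all_props]
            for label in labels
        },
        index=all_props,
        dtype=object,
    )
    return ProfileMatrix(data)


def encode_numeric(matrix: ProfileMatrix) -> pd.DataFrame:
    """Elementwise numeric encoding NO->0, PARTIAL->1, YES->2 (int dtype)."""
    return matrix.data.map(lambda s: int(ResultState(s))).astype(int)


def decode_numeric(numeric: pd.DataFrame) -> ProfileMatrix:
    """Inverse of :func:`encode_numeric`."""
    return ProfileMatrix(numeric.map(lambda v: ResultState(int(v))).astype(object))


# -- Gower distance --------------------------------------------------------

def gower_distance(
    x: Sequence[float],
    y: Sequence[float],
    ranges: Sequence[float],
) -> float:
    """Gower distance between two numeric vectors: mean_i |x_i-y_i|/range_i.

    Features with zero (or non-finite) range carry no information and are
    dropped from the mean.  Result lies in [0, 1] when every coordinate
    stays within its feature's range.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    r = np.asarray(ranges, dtype=float)
    if not (x.shape == y.shape == r.shape):
        raise ValueError(
            f"length mismatch: x {x.shape}, y {y.shape}, ranges {r.shape}"
        )
    keep = r > 0
    if not keep.any():
        return 0.0
    return float(np.mean(np.abs(x[keep] - y[keep]) / r[keep]))


def gower_matrix(
    numeric: pd.DataFrame,
    ranges: Optional[Sequence[float]] = None,
) -> pd.DataFrame:
    """Square symmetric Gower distance matrix between columns (proteomes).

    Rows are features (properties).  ``ranges`` defaults to the observed
    per-feature max-min across columns.
    """
    values = numeric.to_numpy(dtype=float)
    if ranges is None:
        r = values.max(axis=1) - values.min(axis=1)
    else:
        r = np.asarray(ranges, dtype=float)
        if r.shape != (values.shape[0],):
            raise ValueError("ranges must have one entry per feature row")
    n = values.shape[1]
    out = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        d = gower_distance(values[:, i], values[:, j], r)
        out[i, j] = out[j, i] = d
    return pd.DataFrame(out, index=numeric.columns, columns=numeric.columns)


# -- ANOSIM ----------------------------------------------------------------

@dataclass(frozen=True)
class AnosimResult:
    r: float
    p_value: float
    n_permutations: int


def _check_square(dm: np.ndarray) -> np.ndarray:
    dm = np.asarray(dm, dtype=float)
    if dm.ndim != 2 or dm.shape[0] != dm.shape[1]:
        raise ValueError(f"distance matrix must be square, got shape {dm.shape}")
    if not np.allclose(dm, dm.T):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(dm), 0.0):
        raise ValueError("distance matrix must have a zero diagonal")
    return dm


def anosim(
    distance_matrix: Union[np.ndarray, pd.DataFrame],
    groups: Sequence,
    n_permutations: int = 999,
    seed: Optional[int] = None,
) -> AnosimResult:
    """Analysis of similarities: are between-group distances larger than within?

    The n(n-1)/2 off-diagonal distances are ranked (mid-ranks for ties) and

        R = (mean between-group rank - mean within-group rank) / (n(n-1)/4)

    so R is 1 when every between-group distance exceeds every within-group
    one, near 0 when the grouping is uninformative, and negative when
    within-group distances dominate.  Significance is assessed by
    permuting group labels: p = (1 + #{R_perm >= R_obs}) / (1 + N_perm),
    reproducible for a fixed seed.  Requires at least two groups, each of
    size >= 2.  A constant distance matrix gives R = 0.
    """
    if isinstance(distance_matrix, pd.DataFrame):
        distance_matrix = distance_matrix.to_numpy()
    dm = _check_square(distance_matrix)
    labels = np.asarray(groups)
    n = dm.shape[0]
    if labels.shape[0] != n:
        raise ValueError("groups must have one label per sample")
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("need at least two groups")
    if counts.min() < 2:
        small = uniq[counts < 2]
        raise ValueError(f"every group needs >= 2 samples; too small: {list(small)}")
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")

    ranks = rankdata(squareform(dm, checks=False))
    iu, ju = np.triu_indices(n, k=1)
    denom = n * (n - 1) / 4.0

    def r_stat(lab: np.ndarray) -> float:
        within = lab[iu] == lab[ju]
        # both masks are non-empty for >=2 groups of size >=2
        return float((ranks[~within].mean() - ranks[within].mean()) / denom)

    r_obs = r_stat(labels)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        if r_stat(rng.permutation(labels)) >= r_obs:
            hits += 1
    p = (1 + hits) / (1 + n_permutations)
    return AnosimResult(r=r_obs, p_value=p, n_permutations=n_permutations)


# -- three-source annotation overlap ---------------------------------------

@dataclass(frozen=True)
class OverlapPartition:
    """Disjoint partition of a proteome by three annotation sources.

    ``region_counts`` is keyed by the sorted tuple of source names whose
    exclusive intersection the region is (7 keys: three singletons, three
    pairs, one triple).  The regions plus ``unannotated`` always sum to
    ``total``.
    """

    sources: tuple[str, str, str]
    region_counts: dict[tuple[str, ...], int]
    unannotated: int
    total: int

    def only(self, source: str) -> int:
        return self.region_counts[(source,)]

    def pair(self, a: str, b: str) -> int:
        return self.region_counts[tuple(sorted((a, b)))]

    @property
    def all_three(self) -> int:
        return self.region_counts[tuple(sorted(self.sources))]

    @property
    def annotated(self) -> int:
        return sum(self.region_counts.values())


def overlap_partition(
    annotations_by_source: Mapping[str, set],
    total: int,
) -> OverlapPartition:
    """Partition ``total`` sequences into the 7 exclusive regions + unannotated.

    ``annotations_by_source`` maps exactly three source names to the sets
    of protein identifiers each annotates; ``total`` must be at least the
    size of their union.
    """
    if len(annotations_by_source) != 3:
        raise ValueError(
            f"need exactly 3 sources, got {len(annotations_by_source)}"
        )
    names = tuple(annotations_by_source)
    sets = {k: set(v) for k, v in annotations_by_source.items()}
    union = set().union(*sets.values())
    if total < len(union):
        raise ValueError(
            f"total {total} is smaller than the union of annotations {len(union)}"
        )
    region_counts: dict[tuple[str, ...], int] = {}
    for k in (1, 2, 3):
        for combo in itertools.combinations(sorted(names), k):
            inside = set.intersection(*(sets[name] for name in combo))
            outside = set().union(
                *(sets[name] for name in names if name not in combo), set()
            )
            region_counts[combo] = len(inside - outside)
    return OverlapPartition(
        sources=names,
        region_counts=region_counts,
        unannotated=total - len(union),
        total=total,
    )


# -- viewer exports --------------------------------------------------------

def export_long_table(matrix: ProfileMatrix) -> pd.DataFrame:
    """Long-form table: one row per (property, proteome) with state + numeric."""
    records = [
        {
            "property": prop,
            "proteome": proteome,
            "state": str(matrix.data.at[prop, proteome]),
            "numeric": int(matrix.data.at[prop, proteome]),
        }
        for prop in matrix.properties
        for proteome in matrix.proteomes
    ]
    return pd.DataFrame.from_records(records)


def export_json(matrix: ProfileMatrix) -> str:
    """JSON matrix document for downstream viewers."""
    doc = {
        "properties": matrix.properties,
        "proteomes": matrix.proteomes,
        "states": [
            [str(matrix.data.at[p, s]) for s in matrix.proteomes]
            for p in matrix.properties
        ],
        "encoding": {"NO": 0, "PARTIAL": 1, "YES": 2},
    }
    return json.dumps(doc, indent=2)
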