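"""Per-proteome InterPro match tables from InterProScan TSV output.

The assignment engine needs only the mapping protein -> set of InterPro
entries it matches.  The standard InterProScan TSV layout is assumed:
column 1 the protein accession, column 5 the member-database signature
accession and column 12 the integrated InterPro accession (``-`` or absent
when the signature is not integrated).  A simplified two-column
``protein<TAB>IPR`` dialect is accepted for hand-written inputs.

The promiscuity filter removes every match of a step evidence that hits
more than a set number of distinct proteins in the proteome; such
non-specific models would otherwise inflate apparent coverage.  It is off
in the default assignment path and enabled explicitly (it matters for
resource-coverage comparisons, not for routine assignment).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import IO, Optional, Union

from .model import PropertyRegistry

__all__ = ["MatchTable", "parse_interproscan_tsv", "apply_promiscuity_filter"]

_MISSING = {"", "-"}


@dataclass
class MatchTable:
    """Protein -> InterPro accession sets for one proteome.

    ``signature_matches`` keeps the member-database signature accessions,
    used only by signature-level fallback matching.  Placeholder ``-``
    accessions are never stored; all sets are deduplicated.
    """

    label: str
    matches: dict[str, set[str]] = field(default_factory=dict)
    signature_matches: dict[str, set[str]] = field(default_factory=dict)
    skipped_rows: int = 0

    def proteins_matching(self, accession: str) -> frozenset[str]:
        return frozenset(
            p for p, accs in self.matches.items() if accession in accs
        )

    def proteins_matching_signature(self, signature: str) -> frozenset[str]:
        return frozenset(
            p for p, sigs in self.signature_matches.items() if signature in sigs
        )

    def annotated_proteins(self) -> frozenset[str]:
        return frozenset(self.matches)

    def accession_index(self) -> dict[str, set[str]]:
        """Reverse index: InterPro accession -> proteins matching it."""
        index: dict[str, set[str]] = {}
        for protein, accs in self.matches.items():
            for acc in accs:
                index.setdefault(acc, set()).add(protein)
        return index

    def copy(self) -> "MatchTable":
        return MatchTable(
            label=self.label,
            matches={p: set(a) for p, a in self.matches.items()},
            signature_matches={p: set(a) for p, a in self.signature_matches.items()},
            skipped_rows=self.skipped_rows,
        )


def parse_interproscan_tsv(
    source: Union[str, IO[str]],
    label: str,
    simple: bool = False,
) -> MatchTable:
    """Parse InterProScan TSV output (or the two-column dialect) for one proteome.

    Rows whose signature is not integrated into InterPro contribute only to
    ``signature_matches``.  Rows with fewer than five columns are skipped
    and counted (``skipped_rows``); duplicate (protein, accession) rows --
    e.g. the same entry matched at several domain locations -- collapse to
    one.  An empty stream yields an empty table.
    """
    text = source.read() if hasattr(source, "read") else source
    table = MatchTable(label=label)
    for line in text.splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        cols = line.rstrip("\n").split("\t")
        if simple:
            if len(cols) < 2:
                table.skipped_rows += 1
                continue
            protein, ipr = cols[0].strip(), cols[1].strip()
            if protein and ipr not in _MISSING:
                table.matches.setdefault(protein, set()).add(ipr)
            continue
        if len(cols) < 5:
            table.skipped_rows += 1
            continue
        protein = cols[0].strip()
        signature = cols[4].strip()
        ipr = cols[11].strip() if len(cols) >= 12 else "-"
        if signature not in _MISSING:
            table.signature_matches.setdefault(protein, set()).add(signature)
        if ipr not in _MISSING:
            table.matches.setdefault(protein, set()).add(ipr)
    if table.skipped_rows:
        warnings.warn(
            f"{label}: skipped {table.skipped_rows} row(s) with too few columns",
            stacklevel=2,
        )
    return table


def apply_promiscuity_filter(
    table: MatchTable,
    registry: PropertyRegistry,
    max_proteins: Optional[int] = 3,
) -> MatchTable:
    """Drop matches of evidence accessions hitting too many distinct proteins.

    For every InterPro accession used as step evidence anywhere in the
    registry, if it matches more than ``max_proteins`` distinct proteins in
    the table, *all* its protein matches are removed.  Accessions not used
    as evidence are untouched.  ``max_proteins=None`` disables the filter
    (identity).  Idempotent: a surviving accession's protein count never
    grows, so a second pass removes nothing.
    """
    if max_proteins is None:
        return table.copy()
    if max_proteins < 1:
        raise ValueError(f"max_proteins must be >= 1, got {max_proteins}")
    evidence = registry.evidence_accessions()
    index = table.accession_index()
    promiscuous = {
        acc
        for acc in evidence
        if len(index.get(acc, ())) > max_proteins
    }
    out = table.copy()
    if not promiscuous:
        return out
    for protein in list(out.matches):
        out.matches[protein] -= promiscuous
        if not out.matches[protein]:
            del out.matches[protein]
    return out
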