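# Methods

## The property model

A genome property is an ordered list of steps; each step carries one or
more evidence lines and a required/optional flag. Six property types are
admitted: `PATHWAY`, `METAPATH`, `SYSTEM`, `GUILD`, `COMPLEX` and
`CATEGORY`. The first five assert a biological attribute; categories are
purely organisational and may only cite other properties as evidence, so
the category/metapath citations double as the browse hierarchy. The
hierarchy is derived solely from these evidence edges — there is no
separate parent field — and is a DAG, not a tree: one property may be
filed under several categories. Cycles are rejected before evaluation.

Evidence kind is derived from the accession itself (`IPRnnnnnn` =
InterPro entry, `GenPropnnnn` = property); a permissive mode admits
legacy member-database identifiers for old records, but the strict
patterns are the default.

## Assignment semantics

Only required steps decide a property's state. With `R` required steps,
threshold `T` and `m` matched required steps: YES iff `m = R > 0`,
PARTIAL iff `T < m < R`, NO iff `m ≤ T`. The threshold is a curated
per-property integer absorbing hard-to-model steps and promiscuous
families; at or below it, scattered matches are treated as noise.

Decisions made where the behaviour was genuinely open:

- **Only required steps count toward the threshold.** YES is defined on
  required steps; letting optional matches count would allow a property
  rich in optional steps to go PARTIAL with zero required evidence.
  Optional step results are reported but never change the state.
- **A property with no required steps is never YES** (and a property
  with no steps at all is NO, with a warning); the QC layer flags such
  records rather than the evaluator guessing.
- **Property evidence requires YES by default.** A metapath step backed
  by a sub-property is satisfied only by a YES sub-result; the
  `partial_counts` flag relaxes this to YES-or-PARTIAL. The strict
  default is the conservative reading.
- **Categories are evaluated like metapaths but excluded from summary
  reports by default** (they assert nothing biological); an
  `include_categories` flag restores them.
- Evaluation order is the lexicographic topological order of the
  evidence DAG, making the whole computation deterministic; there is no
  randomness anywhere in assignment.

Signature-level fallback (satisfying an InterPro evidence line via its
raw member-database signatures when the integrated accession is absent
from the matches) exists behind a flag, default off.

## Match tables and the promiscuity filter

InterProScan TSV input is reduced to protein → {InterPro accession},
keeping member-database signatures separately. The standard column
layout is assumed (protein in column 1, signature in column 5,
integrated InterPro accession in column 12, `-` when unintegrated); rows
with fewer than five columns are counted and skipped rather than fatal.

The promiscuity filter removes *all* matches of any registry evidence
accession that hits more than `max_proteins` distinct proteins (default
3, i.e. an accession matching four or more proteins is dropped). It is
off in the default assignment path and enabled explicitly: it exists to
keep non-specific models from inflating apparent coverage when comparing
annotation resources, not to change routine assignment. The protein
count is taken within the input table as given, before any other
filtering.

## Profiling statistics

Fingerprints are encoded No = 0, Partial = 1, Yes = 2 — the ordering is
meaningful (increasing evidence of presence), so range-normalised
distances are sensible. Gower distance averages |x_i − y_i|/range_i over
features; features with zero observed range carry no information and are
dropped from the mean (a matrix with no informative features yields
distance 0). On encoded fingerprints the per-feature range defaults to
the observed max − min across proteomes.

ANOSIM ranks the n(n−1)/2 pairwise distances (mid-ranks for ties) and
contrasts mean between-group with mean within-group rank, normalised by
n(n−1)/4 so R ∈ [−1, 1]. The permutation p-value uses the standard +1
correction, p = (1 + #{R_perm ≥ R_obs}) / (1 + N_perm), and is exactly
reproducible for a fixed seed (numpy `default_rng`). Groups must number
at least two, each with at least two members; a constant distance matrix
gives R = 0. The implementation is cross-checked in the test suite
against scikit-bio's independent ANOSIM.

PCA and hierarchical clustering are deliberately delegated: the package
prepares and exports the encoded matrix (long-form TSV and a JSON matrix
document) and stops there.

The three-source overlap partition is plain set algebra: the seven
exclusive Venn regions of three annotation sources plus the unannotated
remainder, which always sum to the proteome total.

## DESC dialect

The flatfile follows the two-letter line-code convention of classic
protein-family DESC files: `CODE␣␣value`, records terminated by `//`.
Header codes AC/DE/TP/AU/TH/RN/RM/RT/RA/RL/DR/CC; step codes
SN/ID/DN/RQ/EV/TG, the step block starting at the first SN. AC, DE and
TP are mandatory; TH defaults to 0. EV lines are semicolon-terminated,
the first token being the evidence accession and the remainder raw
member-database signatures. Unknown codes are preserved verbatim so
newer dialects survive a round trip. CC text is whitespace-normalised on
parse and re-wrapped at column 80 on write, so round trips preserve the
normalised text rather than original line breaks. Parsing is lenient by
default for release files (per-record errors collected, parsing
continues) and strict for curation. FASTA sidecars link example
sequences to steps via a `step=N` header token — the linkage had to be
fixed by this package, as no convention is mandated by the format.
Status sidecars are two-column text (`accession<TAB>checked,public`);
only checked-and-public records are releasable, and release flatfiles
exclude non-public records.

## QC and curation heuristics

Connectivity is reachability from declared root categories along
evidence edges (roots default to the categories nothing cites); since
only categories and metapaths may carry property evidence, the traversal
edges coincide with the category-membership/metapath relation, and every
reachable property has a browse path. Evidence validity checks InterPro
accessions against a caller-supplied accession universe (property
citations are resolved by the registry itself). FASTA coverage requires
every non-category property with InterPro-evidenced steps to have a
sidecar covering each such step.

The evidence-selection heuristic for semi-automatically generated
properties prefers entries of type *family*, then maximal hierarchy
depth (most specific). "Broad taxonomic coverage" is operationalised
purely as a tie-break on the optional taxonomic-breadth count, followed
by the lexicographically smallest accession, making the choice
deterministic and order-invariant. Thresholds for semi-automatic
properties default to 0.

## The synthetic generator

The generator emulates the *structure* of release data so every module
is testable without downloads: leaf properties with 2–4 steps (at least
two required; default 80 % required fraction), thresholds from the
`half` rule T = (R−1)//2 — which always leaves a PARTIAL window —
metapaths citing 2–4 leaves, and categories wiring everything to a root.
Identifiers live in reserved ranges (`GenProp9xxx`, `IPR9xxxxx`,
`<label>_P000N`) to avoid colliding with real accessions. Match tables
are generated backwards from a planted state vector: leaf states are
free (PARTIAL only where feasible), nested states are whatever the
children imply, and the emitted TSV realises exactly the planted matched
counts, with evidence accessions unique to one step so there is no
cross-talk. All outputs are byte-identical for a given seed.

What the generator does **not** emulate: real domain architectures,
shared evidence between steps or properties, promiscuous families,
genomic context, or realistic sequences (sidecar FASTA entries are
random strings). Passing tests therefore demonstrate the correctness of
the formats, the evaluator's semantics and the statistics' calibration —
not biological accuracy of any real release's curation.

Grouped fingerprints for ANOSIM power checks give each group a block of
marker properties (YES for members, NO otherwise, with probability
`separation`; uniform noise otherwise) over a shared noisy background;
separation 1 yields R = 1 by construction, separation 0 a null R near 0.

## Problem sizes and numerics

The verification suite uses registries of at most 30 properties (about
14 at the defaults), 200 random registry/match-table pairs for the
oracle-equivalence check, 100 seeded configurations for planted-truth
recovery, and 999-permutation ANOSIM runs on 18–24 proteomes; these
sizes exercise every code path while keeping the whole suite fast.
Larger inputs are a matter of scaling, not of different code: the
evaluator is linear in total evidence lines, the profiling statistics
quadratic in proteomes.

Known limitations: no genomic-context (operon) validation — proteome
input discards gene order; no execution of sequence searches (FASTA
sidecars are checked for presence and coverage, not re-scanned);
category exemption from FASTA checks is this package's reading of which
properties "require" an example file.
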