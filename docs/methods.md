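# Methods

## Identity model

The unit of identity for all cross-namespace mapping is the *normalized
full-length mature sequence*: uppercase, DNA→RNA (`T`→`U`), whitespace
removed, compared by exact equality within one species.  Substring or
overhang matching of probe sequences is deliberately rejected: vendor
probes longer than the mature sequence must be pre-trimmed in the
annotation file.  Exact equality is the only reading of "same mature
sequence" that is reproducible across sources; any fuzzy alternative
would make the commonality relation depend on alignment parameters.
Cross-species pooling of identical sequences is likewise out of scope —
a namespace is always species-scoped.

Two asymmetries follow from the model and are worth spelling out:

- one sequence may legitimately carry several names (paralogous
  precursors yielding identical matures); that is data, reported with the
  `multiple` status, never an error;
- one name claiming two different sequences within one source is a
  defect (a vendor design or annotation error), surfaced as a curation
  finding (`duplicate_probe_name`) and excluded from the lookup maps
  rather than silently resolved either way.

History tracking uses a different key: the MIMAT accession.  Sequences
themselves can be revised between releases (`sequence_changed` events),
so the sequence cannot anchor identity over time; the accession is the
repository's stable handle.  Translation stays sequence-keyed, history
stays accession-keyed.

## Status taxonomy and the dead/missing distinction

Every translated name gets exactly one of six statuses (`stable`,
`renamed`, `multiple`, `dead`, `missing`, `unrecognized`), emitted as a
machine-readable column — downstream tooling needs data, not colour
shading.  `dead` is claimed only when an accession reachable from the
source sequence appears in the destination's retired set.  A platform
namespace has no accessions, so from a platform source an absent sequence
is always `missing`: retirement is never over-claimed.  When no explicit
dead list accompanies a release series, an accession present earlier and
absent later is inferred dead from the first absent release onward.

Name matching is case-sensitive after whitespace trimming.  A
case-insensitive fallback is attempted and accepted only when it rescues
a name *uniquely*, and the row's `note` records the rescue; silent
case-folding would mask genuine casing distinctions in vendor files
("hsa-miR" vs "hsa-mir" historically separated mature from precursor).

## History reconstruction

Given an ordered series of snapshots, the builder walks consecutive
releases and emits, per accession: `introduced` (first appearance;
entries alive in the earliest loaded release carry a `pre_series` flag,
since their true introduction predates the series), `renamed` (same
accession, different name), `sequence_changed` (same accession, different
sequence), `deleted` (presence → absence or dead-list membership).  An
accession absent from an intermediate release and present later is
recorded as deleted-then-reinstated — two events reflecting what the
loaded snapshots literally say, rather than an assumed continuity that
would hide load gaps.  Version labels are opaque strings ordered by an
explicit configuration list (real release labels mix "10.1" and "21", so
numeric parsing is fragile by construction).

Stringent queries require exact whole-name equality against any name the
entry bore at or after the chosen start release; unprefixed queries get
the selected species' prefix injected (or match any prefix when searching
all species).  Relaxed queries are case-insensitive substring
containment.  Every stringent hit is by construction also a relaxed hit.

## Synthetic fixtures

The generator emulates a miRBase-like release series and the vendor
files derived from it, with exact ground truth:

- sequences are uniform random over {A,C,G,U}, lengths 19–25 nt
  inclusive — the length range of mature miRNAs;
- at each version step every live record independently undergoes rename
  (default rate 0.12), deletion (0.06) or sequence revision (0.04), and
  new records are added (0.12 per initial-record slot).  Defaults were
  chosen to make renames the dominant event, deletions noticeably rarer,
  and several events of every kind appear in a 4–5 release series of a
  few dozen records — the regime the real repository's history sits in,
  compressed to desk scale;
- sequence collisions (distinct accessions, identical mature) are
  *scripted* by copying, never left to chance: the probability of chance
  22-mer collisions is negligible, and the tests need collisions with
  known membership;
- platforms sample (name, sequence) pairs verbatim from a chosen
  release, then a requested number of probes get a wrong sequence swapped
  in from another record, emulating vendor design errors; the injection
  manifest is returned as the curation oracle.  Control probes with
  non-miRNA names are appended;
- expression values are LogNormal(μ=5, σ=1) — the canonical
  right-skewed, strictly positive shape of hybridization intensities.
  The values are carriers for conservation checks, not biology: no
  correlation structure, differential expression, or noise model is
  simulated, so passing tests say nothing about statistical analysis of
  real data — only that annotation handling never alters or drops a
  value.

The synthetic species code is `syn`, so no fixture name can collide with
a real organism's annotation.  All generators are byte-stable under a
fixed seed.  What the fixtures do not emulate: vendor-specific file
quirks beyond the documented platform CSV schema, precursor (hairpin)
sequences, genomic coordinates, and realistic miRNA biology.

## Problem sizes

The test and acceptance workloads are sized so that exactness, not
volume, does the verifying: 20 scripted series of 5 releases × ~25–60
records for history recovery (every series ≥50 events), namespaces of
roughly 350–600 entries with 1000 random queries per seed for the
brute-force oracle comparisons, and 10 seeds each for conservation,
round-trip and curation checks.  Every check is exact (multiset equality,
bit-identical values), so larger instances would add runtime without
adding discrimination.

## Numerical and formatting choices

- Matrix values are written with `repr(float)` so read→write→read is
  bit-exact; empty cells and `NA`/`NaN` read as missing.
- All name sets in outputs are lexicographically sorted and joined with
  a configurable delimiter (default `;`); writers emit no timestamps, so
  output files are byte-stable.
- Untranslatable matrix rows are kept in input order by default; a
  `failures_last` flag stably sorts them to the bottom instead.  Input
  order is the default because it preserves the caller's row
  correspondence.
- The result-table column layout (`input_name, matched_sequence, status,
  output_names, output_accessions, note`, then sample columns) is a
  frozen contract.

## Known limitations

- Exact-equality matching means probes whose printed target is a trimmed
  or extended variant of the mature sequence will not map until the
  annotation file is corrected; this is by design but worth knowing.
- Curation only *flags* vendor inconsistencies; it never rewrites
  reported names.
- Dead/missing inference is only as good as the loaded series: with a
  single loaded release, nothing can be proven dead.
- Alias/previous-name lists are not used as a history source; history
  comes solely from diffing the loaded snapshots.
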