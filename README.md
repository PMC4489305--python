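# mirharmony

Sequence-keyed harmonization of miRNA nomenclature across miRBase release
versions and profiling-platform annotations.

## The problem

miRNA names drift: between annotation releases an entry can be renamed
(`hsa-miR-2-3p` → `hsa-miR-2b-3p`), retired ("dead"), given a revised
mature sequence, or joined by a paralog whose mature sequence is
byte-identical.  Meanwhile microarray and RT-qPCR platforms freeze
whatever release their probes were designed against, and vendor
annotation files occasionally attach the wrong sequence to a name
outright.  Any comparison of published miRNA lists or expression matrices
that goes by *name* therefore silently drops or mislabels entries.

The one stable identity is the **mature sequence**.  `mirharmony` keys
every mapping on the normalized full-length mature sequence (uppercase
RNA, exact equality, scoped to one species) and treats any source of
(name, sequence) pairs — a species-scoped miRBase release or a platform
probe set — as the same abstraction, a *namespace*.  On top of that it
provides:

- **translate** — rewrite a name list from one namespace into another,
  tagging every input with one of six statuses: `stable`, `renamed`,
  `multiple` (one sequence, several destination names), `dead` (accession
  retired), `missing` (absent, retirement unproven), `unrecognized`
  (not a miRNA name in the source, e.g. a control probe);
- **overlap** — the mature sequences two namespaces share, regardless of
  what either side calls them;
- **update** — re-annotate an expression matrix (miRNA rows × sample
  columns), carrying all values over bit-exactly;
- **intersect** — join two expression matrices on shared mature
  sequences, with destination names attached and a side report for
  everything that did not join;
- **timewarp** — reconstruct each accession's name history (introduced /
  renamed / sequence-changed / deleted / reinstated) across an ordered
  release series, query it stringently or by substring, and list which
  platforms can detect a given entry;
- **curate** — check a platform's name↔sequence consistency against the
  release it was designed on, flagging mismatches, unknown names, and
  names borne by probes with conflicting sequences.

Deciding `dead` vs `missing` needs accession continuity: a platform
without MIMAT accessions can never prove retirement, so its absent
sequences are always `missing`.

A deterministic synthetic-fixture generator (species code `syn`, never a
real organism) produces release series with a scripted event log,
platforms with injected defects plus the injection manifest, and
log-normal expression matrices — so the whole pipeline is testable
offline with exact ground truth.  Real miRBase release files (the mature
FASTA dialect) are read when you supply them; nothing is downloaded.

## Worked example

Build the toy two-release series (three entries in `v1`; `v2` renames
one, retires one, and adds two paralogs sharing one mature sequence) and
translate a name list from `v1` to `v2`:

```python
from mirharmony import fixtures as fx
from mirharmony import io as mio

index, events = fx.toy3()
for release in index:
    mio.write_release_tsv(f"{release.version_label}.tsv", release)
open("names.txt", "w").write("syn-miR-2-3p syn-miR-3 syn-miR-1-5p syn-miR-5a\n")
```

```
$ mirharmony translate --from mirbase:v1:syn --to mirbase:v2:syn --releases . names.txt
input_name,matched_sequence,status,output_names,output_accessions,note
syn-miR-2-3p,CCGAAUAGGGAUAUAGGCAAC,renamed,syn-miR-2b-3p,MIMAT0000002,
syn-miR-3,GACAUGUGCGGCGACCCUUGCGACA,dead,,,accession MIMAT0000003 retired in mirbase:v2:syn
syn-miR-1-5p,AAGCCCAAUAAACCACUCUGACUG,stable,syn-miR-1-5p,MIMAT0000001,
syn-miR-5a,,unrecognized,,,name not found in mirbase:v1:syn
```

Reading the rows: `syn-miR-2-3p` still exists in `v2` under a new name
(same sequence, same accession); `syn-miR-3` was retired, and its
accession proves it (`dead`, not merely `missing`); `syn-miR-1-5p` is
unchanged; `syn-miR-5a` is not a `v1` name at all, so from a `v1` source
it is `unrecognized`.  Translating the same list *within* `v2` shows the
paralog collision instead:

```
syn-miR-5a,GUGACGCUUUCGCCGUUGCCUAAAC,multiple,syn-miR-5a;syn-miR-5b,MIMAT0000004;MIMAT0000005,
```

One sequence, two names — exactly the case name-based comparisons
double-count or miss.  The same operations are available as library
functions (`translate_names`, `overlap_namespaces`, `update_matrix`,
`intersect_matrices`, `build_history`, `time_warp_query`,
`curate_platform`); the CLI is a thin wrapper.

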