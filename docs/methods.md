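# Methods

## Data model

A `GermlineSet` is a versioned, attributed collection of
`AlleleDescription` records for one locus (IGH, IGK, IGL, TRA, TRB,
TRG, TRD) of one species, optionally restricted to a subgroup
(locational population, breed, inbred or outbred strain). An
`AlleleDescription` carries the ungapped coding sequence; for V alleles
optionally a gapped alignment (stored, never computed here) and FR/CDR
delineations under one or more schemes (IMGT, Kabat, Chothia, or
custom); for J alleles the reading-frame orientation and donor splice
position; supporting evidence records; flags for sequences incomplete
at the 5' or 3' end; and an ordered alias list, oldest first, that
preserves the record's naming history. Constant (C) genes are not
modelled.

Conventions chosen where the field's practice, not a published rule,
decides: all coordinates are 1-based inclusive on the ungapped coding
sequence; the gap character is `.` with `-` normalised on input; IUPAC
ambiguity codes are legal in sequences but flagged at warning severity,
because registry matching is literal over ACGT. The functionality
vocabulary is the conventional functional / ORF / pseudogene triple
plus `unknown`, which is the default.

Validation returns violations as data (`Violation` objects with a field
path, message and severity) rather than raising, so a curation pipeline
can report every problem in one pass; a record or set is *valid* when
it has no error-severity violation. An empty germline set is valid and
carries a single info-severity note. Violations are ordered by allele
label then field path, so validation reports are deterministic and
diffable.

## Temporary nomenclature

Identifier encoding is a bijection between the integers 0…2²⁰−1 and
4-character strings: the value is split into four 5-bit groups,
most-significant group first (the stream order of RFC 4648), each group
indexing the base32 alphabet A–Z, 2–7. Decoding rejects any string
containing the omitted digits 0, 1, 8 or 9; the alphabet as stated is
treated as normative even for historically circulating strings like
`C89D` that predate it.

Parsing is deliberately minimal: a string is a temporary label iff it
matches the full template and its identifier is drawn from the
alphabet, with one guard — an all-digit identifier such as `2345` is
visually indistinguishable from a ratified gene number, so it is
accepted as temporary only while subgroup and allele still hold their
null values. Everything else with a recognised locus prefix is a
`LegacyLabel` carrying the raw string verbatim plus best-effort locus
and sequence type; no further meaning is ever parsed out of a name,
which is the schema's job.

## Registry workflow

The naming domain's scope (species vs subgroup) is a property fixed at
registry creation, never inferred. Matching normalises to uppercase and
strips gaps and whitespace; reverse-complement matching is not
performed (germline submissions are conventionally sense-strand) — a
documented limitation. Containment is exact string containment.

`propose` classifies each batch input as duplicate / subsequence /
supersequence / new; an input that is simultaneously a sub- and a
super-sequence of different records is reported `unresolved`. Multiple
containment matches are ordered by allocation date then identifier.
Withdrawn records take part in duplicate detection only and are flagged
as withdrawn duplicates. Repeated sequences within one batch collapse
onto their first occurrence.

`apply` is a hard gate: sub-/super-sequence proposals have no default
final action, and a batch containing an undecided one is rejected
without mutating the registry — whether a contained sequence is the
same allele is a curatorial judgement that may hinge on haplotype or
usage evidence. Allocation draws uniformly over the never-issued
identifiers by rejection sampling (switching to an explicit
set-difference draw past half occupancy so termination stays prompt),
is deterministic under the seed recorded in the allocation report, and
never re-uses an identifier, withdrawn records included. Because the
proposal file and registry CSV carry no locus information, `apply`
takes the locus and sequence type for minted labels as parameters
(CLI: `--locus`, `--type`, defaulting to IGH V).

`rename` enforces only uniqueness and alias capture — the previous
current label is appended to the alias list; no renaming policy is
encoded. `merge_registries` unions registries of the same domain;
identifier agreement with sequence disagreement (or vice versa) is a
clash, and any clash aborts the merge with a full report, matching a
version-control-style workflow where conflicts are resolved by humans.

The registry CSV is bit-exact by specification (fixed header, LF,
";"-joined aliases, fields quoted iff they contain `,`, `;`, `"` or a
newline), so `apply` under a fixed seed reproduces byte-identical
files; the quoting rule differs from vanilla RFC 4180 in quoting
semicolons, hence the small purpose-built formatter instead of the
`csv` module.

## Serialisation

JSON documents carry `schema_version` (`germline-kit-1.0`; unknown
versions are rejected rather than best-effort parsed). Key order is
fixed, alleles are sorted by label, indentation is two spaces: the
canonical form makes `write ∘ read ∘ write == write` and gives
byte-stable release diffs. A germline set is referenced as
`(germline_set_id, release_version)` with integer release versions.
Object equality is order-sensitive; generators emit alleles in
canonical order so `read(write(s)) == s` holds for sets produced by the
toolkit. Evidence is embedded inline. FASTA export writes label-only
headers and wraps at 60 columns; FASTA import builds a skeleton set
(labels and sequences, sequence type inferred by parsing the label) as
a migration path for legacy sets.

`diff_sets` pairs alleles by `allele_description_id`, then matches the
leftovers by resolving new labels (and their aliases) against old
labels and aliases, so renames — even with a changed description id —
pair up instead of appearing as remove+add. Changed field paths are
listed per modified allele; a pure rename reports `label`.

## Genotypes and personalisation

`classify_allele` is conservative: exact full-length equality is
`documented`; a strict substring of a documented allele, or a strict
superstring of one flagged incomplete, is `partial_match` with the
missing side derived from the match offset (or the record's incomplete
flags); promotion of a partial match to documented is a curator
decision, mirroring the registry's containment rule — AIRR-seq
inference is often inconclusive for the final 3' nucleotides, so
truncation is expected, not an error. When several records match
partially, the reported truncation side comes from the first match in
label order.

`personalize` validates the genotype against its referenced sets, then
copies one allele per documented call, appends one per undocumented
allele (fresh null-valued temporary label when a naming-domain registry
is supplied, placeholder `UND-<n>` otherwise), excludes deleted genes,
and carries phasing (an integer chromosome index; haplotype layout
reconstruction is out of scope) into evidence notes. Absence of a gene
from a repertoire is not represented: `deleted_genes` holds confirmed
deletions only.

## Synthetic data

The generator emulates the variation structure a curator faces: genes
with point-mutated allelic variants and 5'/3'-truncated sequences. The
defaults are a 10-gene set with 2 alleles per gene, per-site
substitution rate 0.02 (typical allelic divergence within a V gene),
lengths uniform in 280–320 nt (the V-gene range), and truncation
probability 0.1 with 5–20 nt removed. Sequences are uniform over ACGT
and carry no biological motifs — no recombination signal sequences,
leaders, or codon structure — so passing tests demonstrate correct data
handling, not biological realism; nothing here simulates repertoires or
somatic hypermutation. Generation is bit-reproducible under its
mandatory seed; at mutation rate 0 duplicate variants collapse with a
warning. `generate_genotype` samples documented calls without
replacement from non-deleted genes (half the surviving alleles, at
least one) and builds undocumented alleles by mutating set sequences at
rate 0.05 with rejection until absent from the set.

The packaged strain table transcribes the published inventory of
community-curated mouse germline sets: 38 (strain, locus-type, count)
rows over 20 inbred strains, including BALB/c IGHV = 164 and C57BL/6
IGHV = 102. `build_table1_sets` materialises one synthetic set per row
with exactly the published allele count — counts faithful, sequences
synthetic.

## Problem sizes and numerical choices

The exhaustive identifier check enumerates all 2²⁰ values (a few
seconds). Property tests run 1,000 randomised containment trials
(domains ≤ 100 records, sequences 4–400 nt) against a brute-force
all-pairs oracle, 10,000 allocation/withdrawal interleavings for
no-reuse, and 10,000 random label round-trips. Tie-breaks are
deterministic everywhere: containment matches by date then identifier,
validation reports by label then path, diff output sorted by label.

## Limitations

No reverse-complement or similarity matching (exact containment only);
no inference of genotypes from reads; no gapped-alignment computation;
no C genes; no REST service or archive packaging. The registry merge
detects clashes but does not auto-resolve them.
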