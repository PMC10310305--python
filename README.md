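# germline-kit

A curation toolkit for immunoglobulin (IG) and T-cell receptor (TR)
germline reference sets.

High-quality analysis of adaptive immune receptor repertoire sequencing
(AIRR-seq) data depends on complete germline sets, but in most species —
mouse and macaque prominently — many newly discovered V, D and J alleles
cannot yet be mapped to a gene at a genomic location, and so cannot
receive a ratified name. germline-kit implements the interim machinery
curators need in the meantime:

- **Temporary nomenclature.** An unmapped allele gets a label of the
  form `<locus><type><subgroup>-<identifier>*<allele>`, e.g.
  `IGHV0-A5B2*00`. Subgroup and allele designators hold null values
  (`0` / `00`) until real values are determined. The identifier is a
  random 20-bit value rendered as 4 characters of the RFC 4648 §6
  base32 alphabet (A–Z, 2–7; the visually ambiguous digits 0, 1, 8, 9
  are excluded), giving 32⁴ = 2²⁰ ≈ 1.05 million memorable identifiers
  per naming domain.
- **Naming-domain registries.** Identifiers are unique within a naming
  domain (a species, or a subgroup such as an inbred strain) and are
  never re-used, even after withdrawal. The registry is a plain CSV
  with a bit-exact serialisation, so it can live in version control and
  be merged across curation groups, with clash detection.
- **Two-phase allocation.** A batch of candidate sequences is first
  compared against the registry (exact duplicates, sub-/super-sequence
  containment, or new); the curator reviews the proposed actions —
  containment cases have no safe default — and only then is the
  registry mutated and fresh labels minted.
- **Alias traceability.** Renames keep the previous label as an alias,
  and synonyms from other databases can be recorded, so a sequence
  known under several names over time stays one resolvable record.
- **Versioned publication.** Germline sets serialise to canonical,
  byte-stable JSON (and label-only FASTA); releases are diffed into
  added / removed / modified alleles with changed field paths.
- **Per-subject genotypes.** A genotype records documented allele
  calls, undocumented alleles and confirmed gene deletions; from it the
  toolkit builds a personalised germline set, minting temporary labels
  for the novel alleles.

## Worked example

```python
from germline_kit import registry as reg

domain = reg.NamingDomain(
    domain_id="mouse-IGH",
    records=[reg.RegistryRecord(
        identifier="A5B2", current_label="IGHV0-A5B2*00",
        sequence="CAGGTGCAGCTGAAGGAGTCAGGACCTAGCCTCGTG", allocated="2022-03-01")],
)
candidates = [
    ("study-A-seq1", "CAGGTGCAGCTGAAGGAGTCAGGACCTAGCCTCGTG"),  # known
    ("study-A-seq2", "CAGGTGCAGCTGAAGGAGTCAGGACCTAGC"),        # 3'-truncated
    ("study-A-seq3", "GAGGTGCAGCTTCAGGAGTCAGGACCTAGCCTGGTG"),  # new
]
proposals = reg.propose(candidates, domain)
proposals[1].final_action = "assign_existing:A5B2"   # curator's call
domain, report = reg.apply(proposals, domain, seed=42)
```

Running `python examples/allocate_labels.py` (this workflow) prints:

```
study-A-seq1: proposed duplicate (matches ['A5B2'])
study-A-seq2: proposed subsequence (matches ['A5B2'])
study-A-seq3: proposed new
allocated: study-A-seq3 -> IGHV0-HEAG*00
assigned existing: study-A-seq1 -> IGHV0-A5B2*00
assigned existing: study-A-seq2 -> IGHV0-A5B2*00
```

The duplicate and the curator-confirmed truncated fragment are attached
to the existing record `A5B2`; the genuinely new sequence receives the
fresh null-valued label `IGHV0-HEAG*00` — subgroup `0` and allele `00`
stay null until curators assign real values, and `HEAG` is a uniform
draw from the identifiers never issued in the `mouse-IGH` domain.

The other examples show set publication and diffing
(`examples/publish_and_diff.py`) and genotype personalisation
(`examples/personalise_genotype.py`). A thin command-line interface
wraps the same functions:

```
germline-kit label propose --registry R.csv --in seqs.fasta --out proposals.csv
germline-kit label apply   --registry R.csv --proposals proposals.csv --seed 7
germline-kit set diff      --old v1.json --new v2.json
germline-kit genotype personalize --sets S.json --genotype G.json --out P.json
```

Exit codes: 0 success, 1 validation failure (JSON report on stdout),
2 usage error.

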