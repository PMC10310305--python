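"""Allocate temporary labels to newly discovered allele sequences.

Builds a tiny naming-domain registry, submits a batch of candidate
sequences, reviews the proposals, and applies them.  Run:

    python examples/allocate_labels.py
"""

from germline_kit import registry as reg

# a registry with one previously issued record
domain = reg.NamingDomain(
    domain_id="mouse-IGH",
    records=[
        reg.RegistryRecord(
            identifier="A5B2",
            current_label="IGHV0-A5B2*00",
            sequence="CAGGTGCAGCTGAAGGAGTCAGGACCTAGCCTCGTG",
            allocated="2022-03-01",
        )
    ],
)

# phase 1: three candidates — an exact duplicate, a 3'-truncated
# fragment of the known sequence, and a genuinely new sequence
candidates = [
    ("study-A-seq1", "CAGGTGCAGCTGAAGGAGTCAGGACCTAGCCTCGTG"),
    ("study-A-seq2", "CAGGTGCAGCTGAAGGAGTCAGGACCTAGC"),
    ("study-A-seq3", "GAGGTGCAGCTTCAGGAGTCAGGACCTAGCCTGGTG"),
]
proposals = reg.propose(candidates, domain)
for p in proposals:
    print(f"{p.input_id}: proposed {p.proposed_action}"
          + (f" (matches {p.matched_identifiers})" if p.matched_identifiers else ""))

# the curator must decide the truncated fragment: here we record it as
# the same allele as the full-length record rather than a new one
proposals[1].final_action = "assign_existing:A5B2"

# phase 2: apply, minting identifiers for confirmed-new sequences
domain, report = reg.apply(proposals, domain, seed=42, allocated_date="2023-02-19")
for input_id, label in report.allocations:
    print(f"allocated: {input_id} -> {label}")
for input_id, label in report.assigned:
    print(f"assigned existing: {input_id} -> {label}")

# The new label has null subgroup "0" and allele "00": those fields stay
# null until curators determine real values, and the 4-character
# identifier is unique in the domain forever.
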