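"""Publish a germline set as canonical JSON + FASTA, then diff releases.

Run:

    python examples/publish_and_diff.py
"""

import dataclasses

from germline_kit import fixtures as fx, setio

# a small synthetic IGHV set: 4 genes, 2 alleles each
gs = fx.generate_set(fx.SynthSpec(seed=11, n_base_alleles=4, alleles_per_gene=2))
print(f"set {gs.germline_set_id!r}: {len(gs.allele_descriptions)} alleles, "
      f"release {gs.release_version}")

json_text = setio.write_germline_set(gs)
fasta_text = setio.export_fasta(gs)
print(f"JSON: {len(json_text)} bytes (canonical: byte-stable across writes)")
print("first FASTA record:")
print("\n".join(fasta_text.splitlines()[:2]))

# next release: drop one allele, point-mutate another
alleles = [dataclasses.replace(d, aliases=list(d.aliases)) for d in gs.allele_descriptions]
removed = alleles.pop(0)
alleles[0].coding_sequence = "T" + alleles[0].coding_sequence[1:]
new = setio.bump_version(
    dataclasses.replace(gs, allele_descriptions=alleles),
    "drop one allele, correct one sequence",
    "2024-01-15",
)

diff = setio.diff_sets(gs, new)
print(f"release {gs.release_version} -> {new.release_version}:")
print(f"  added:    {diff.added}")
print(f"  removed:  {diff.removed}")
print(f"  modified: {diff.modified}")
# The removed label and the changed field path let users drill down to
# exactly what changed between the releases they cite.
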