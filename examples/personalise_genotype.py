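"""Build a personalised germline set from one subject's genotype.

Samples a genotype from a synthetic reference set (including two novel
alleles and one deleted gene), classifies the observed sequences, and
produces the per-subject set.  Run:

    python examples/personalise_genotype.py
"""

from germline_kit import fixtures as fx
from germline_kit.genotype import classify_allele, personalize
from germline_kit.registry import NamingDomain

reference = fx.generate_set(fx.SynthSpec(seed=3))
gset = fx.generate_genotype(
    reference, seed=4, n_undocumented=2, n_deleted=1, subject_id="D42"
)
genotype = gset.genotypes[0]
print(f"subject {gset.subject_id}: {len(genotype.documented_calls)} documented "
      f"calls, {len(genotype.undocumented_alleles)} undocumented alleles, "
      f"deleted genes: {genotype.deleted_genes}")

for und in genotype.undocumented_alleles:
    verdict = classify_allele(und.sequence, [reference]).verdict
    print(f"observed novel sequence ({len(und.sequence)} nt): classified {verdict}")

# give the novel alleles real temporary labels from a naming domain
personal = personalize(
    [reference], genotype, registry=NamingDomain("synthetic-IGH"),
    subject_id=gset.subject_id, seed=5,
)
print(f"personalised set: {len(personal.allele_descriptions)} alleles")
novel = [d.label for d in personal.allele_descriptions
         if d.allele_description_id.startswith("und-")]
print(f"labels minted for the undocumented alleles: {novel}")
# The personalised set is itself a valid germline set: annotation tools
# can load it in place of the full reference for this subject.
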