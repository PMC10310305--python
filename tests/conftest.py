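import pytest

from germline_kit import fixtures as fx
from germline_kit.model import (
    AlleleDescription,
    GermlineSet,
    Locus,
    SequenceType,
    Species,
)


def make_allele(
    label: str,
    seq: str,
    *,
    locus: Locus = Locus.IGH,
    seq_type: SequenceType = SequenceType.V,
    **kwargs,
) -> AlleleDescription:
    return AlleleDescription(
        allele_description_id=kwargs.pop("allele_description_id", f"id-{label}"),
        label=label,
        sequence_type=seq_type,
        locus=locus,
        coding_sequence=seq,
        **kwargs,
    )


def make_set(alleles, *, locus: Locus = Locus.IGH, set_id="gs-1", version=1) -> GermlineSet:
    return GermlineSet(
        germline_set_id=set_id,
        name="test set",
        species=Species(label="Mus musculus", taxon_id="10090"),
        locus=locus,
        release_version=version,
        allele_descriptions=sorted(alleles, key=lambda d: d.label),
    )


@pytest.fixture
def small_set() -> GermlineSet:
    return make_set(
        [
            make_allele("IGHV0-AAAA*01", "ACGTACGTACGTACGTACGT", gene_label="IGHV0-AAAA"),
            make_allele("IGHV0-AAAA*02", "ACGTACGTACGTACGTACGA", gene_label="IGHV0-AAAA"),
            make_allele("IGHV0-BCDE*01", "TTTTCCCCGGGGAAAATTTT", gene_label="IGHV0-BCDE"),
        ]
    )


@pytest.fixture
def synth_set() -> GermlineSet:
    return fx.generate_set(fx.SynthSpec(seed=7))
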