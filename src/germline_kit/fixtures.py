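"""Synthetic germline sets, genotypes, and the packaged strain table.

The generators here let every part of the toolkit be exercised without
downloading reference data.  They emulate the *variation structure* a
curator faces — genes with several point-mutated alleles, and sequences
truncated at the 5' or 3' end because inference was inconclusive there —
but deliberately carry no biological motifs (no recombination signal
sequences, leaders or realistic codon structure): they test data
handling, not biology.

``table1_fixture`` is a transcription of the published table of
community-curated mouse germline sets (per strain and locus type, the
number of sequences in the set); ``build_table1_sets`` materialises one
synthetic set per row with exactly the published allele count, so the
counts are faithful while the sequences are synthetic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .model import (
    AlleleDescription,
    DocumentedCall,
    Genotype,
    GenotypeSet,
    GermlineSet,
    GermlineSetRef,
    Locus,
    SequenceType,
    Species,
    SpeciesSubgroupType,
    UndocumentedAllele,
)
from .nomenclature import encode_identifier, format_label, null_label_for

__all__ = [
    "SynthSpec",
    "generate_set",
    "generate_genotype",
    "table1_fixture",
    "build_table1_sets",
    "random_sequence",
]

_NT = np.array(list("ACGT"))


@dataclass(frozen=True)
class SynthSpec:
    """Parameters of a synthetic germline set.

    ``n_base_alleles`` genes are created; each gets ``alleles_per_gene``
    allelic variants derived from the gene's base sequence by per-site
    substitution at ``point_mutation_rate`` (a rate of 0.02 is typical
    of the divergence between alleles of one V gene).  With probability
    ``truncation_prob`` a variant is shortened at the 5' or 3' end and
    flagged incomplete, emulating inference that is inconclusive for
    the terminal nucleotides.
    """

    locus: Locus = Locus.IGH
    sequence_type: SequenceType = SequenceType.V
    n_base_alleles: int = 10
    alleles_per_gene: int = 2
    point_mutation_rate: float = 0.02
    length_range: tuple[int, int] = (280, 320)
    truncation_prob: float = 0.1
    seed: int = 0

    def validate(self) -> None:
        if not 0 <= self.point_mutation_rate <= 1:
            raise ValueError("point_mutation_rate must be in [0, 1]")
        if not 0 <= self.truncation_prob <= 1:
            raise ValueError("truncation_prob must be in [0, 1]")
        if self.length_range[0] > self.length_range[1]:
            raise ValueError("length_range min > max")
        if self.n_base_alleles < 1:
            raise ValueError("n_base_alleles must be >= 1")
        if self.alleles_per_gene < 1:
            raise ValueError("alleles_per_gene must be >= 1")


def random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(_NT[rng.integers(0, 4, size=length)])


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    arr = np.array(list(seq))
    hits = rng.random(len(arr)) < rate
    for i in np.flatnonzero(hits):
        choices = [c for c in "ACGT" if c != arr[i]]
        arr[i] = choices[rng.integers(0, 3)]
    return "".join(arr)


def generate_set(spec: SynthSpec) -> GermlineSet:
    """Generate a deterministic synthetic germline set.

    Gene identifiers are drawn from the temporary-label identifier
    space, alleles of one gene share the gene's identifier and are
    numbered ``*01``, ``*02``, ...  Identical variants (possible at
    mutation rate 0) are collapsed with a warning so labels stay
    distinct and sequences unique per gene.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.length_range

    # distinct gene identifiers, deterministic under the seed
    identifiers: list[str] = []
    seen: set[int] = set()
    while len(identifiers) < spec.n_base_alleles:
        v = int(rng.integers(0, 32**4))
        if v not in seen:
            seen.add(v)
            identifiers.append(encode_identifier(v))

    alleles: list[AlleleDescription] = []
    collapsed = 0
    for g, identifier in enumerate(identifiers):
        base = random_sequence(rng, int(rng.integers(lo, hi + 1)))
        gene_label = f"{spec.locus.value}{spec.sequence_type.value}0-{identifier}"
        variants: list[str] = []
        for a in range(spec.alleles_per_gene):
            seq = base if a == 0 else _mutate(rng, base, spec.point_mutation_rate)
            incomplete_5p = incomplete_3p = False
            if rng.random() < spec.truncation_prob and len(seq) > 30:
                cut = int(rng.integers(5, 21))
                if rng.random() < 0.5:
                    seq, incomplete_5p = seq[cut:], True
                else:
                    seq, incomplete_3p = seq[:-cut], True
            if seq in variants:
                collapsed += 1
                continue
            variants.append(seq)
            alleles.append(
                AlleleDescription(
                    allele_description_id=f"synth-{spec.seed}-{g + 1}-{len(variants)}",
                    label=f"{gene_label}*{len(variants):02d}",
                    sequence_type=spec.sequence_type,
                    locus=spec.locus,
                    coding_sequence=seq,
                    gene_label=gene_label,
                    incomplete_5p=incomplete_5p,
                    incomplete_3p=incomplete_3p,
                    version=1,
                )
            )
    if collapsed:
        warnings.warn(
            f"{collapsed} variant(s) were identical to an existing allele of "
            "their gene and were collapsed"
        )
    alleles.sort(key=lambda d: d.label)  # canonical order, matches the JSON writer
    return GermlineSet(
        germline_set_id=f"synth-{spec.locus.value}{spec.sequence_type.value}-{spec.seed}",
        name=f"Synthetic {spec.locus.value}{spec.sequence_type.value} set (seed {spec.seed})",
        species=Species(label="synthetic organism"),
        locus=spec.locus,
        release_version=1,
        release_description="synthetic set for testing",
        allele_descriptions=alleles,
    )


def generate_genotype(
    gs: GermlineSet,
    seed: int,
    n_undocumented: int = 0,
    n_deleted: int = 0,
    subject_id: str = "synthetic-subject",
) -> GenotypeSet:
    """Sample a subject's genotype from a synthetic set.

    Documented calls are sampled without replacement from the alleles of
    non-deleted genes; undocumented alleles are mutated copies of set
    sequences, re-drawn until absent from the set, so they are
    guaranteed to classify as undocumented.
    """
    rng = np.random.default_rng(seed)
    genes = sorted({d.gene_label for d in gs.allele_descriptions if d.gene_label})
    if n_deleted > len(genes):
        raise ValueError(
            f"cannot delete {n_deleted} genes: set has only {len(genes)}"
        )
    deleted = (
        [genes[i] for i in rng.choice(len(genes), size=n_deleted, replace=False)]
        if n_deleted
        else []
    )
    candidates = [
        d
        for d in gs.allele_descriptions
        if d.gene_label is None or d.gene_label not in deleted
    ]
    if not candidates and n_undocumented == 0:
        raise ValueError("no alleles left to call after deletions")
    n_calls = max(1, len(candidates) // 2) if candidates else 0
    chosen = (
        [candidates[i] for i in rng.choice(len(candidates), size=n_calls, replace=False)]
        if n_calls
        else []
    )

    known = {d.coding_sequence for d in gs.allele_descriptions}
    undocumented: list[UndocumentedAllele] = []
    while len(undocumented) < n_undocumented:
        template = gs.allele_descriptions[
            int(rng.integers(0, len(gs.allele_descriptions)))
        ]
        seq = _mutate(rng, template.coding_sequence, 0.05)
        if seq not in known:
            known.add(seq)
            undocumented.append(
                UndocumentedAllele(
                    sequence=seq,
                    phasing=None,
                    notes=f"synthetic novel allele near {template.label}",
                )
            )

    genotype = Genotype(
        locus=gs.locus,
        germline_set_refs=[
            GermlineSetRef(
                germline_set_id=gs.germline_set_id,
                release_version=gs.release_version,
            )
        ],
        documented_calls=[
            DocumentedCall(label=d.label, ref_index=0)
            for d in sorted(chosen, key=lambda d: d.label)
        ],
        undocumented_alleles=undocumented,
        deleted_genes=sorted(deleted),
    )
    return GenotypeSet(
        genotype_set_id=f"synth-genotype-{seed}",
        subject_id=subject_id,
        genotypes=[genotype],
    )


# ---------------------------------------------------------------------------
# the packaged strain table: community-curated mouse germline sets,
# (strain, locus type, number of sequences), transcribed verbatim

_TABLE1: tuple[tuple[str, str, int], ...] = (
    ("129S1/SvImJ", "IGKV", 91),
    ("129S1/SvImJ", "IGLV", 3),
    ("A/J", "IGKV", 102),
    ("A/J", "IGLV", 3),
    ("AKR/J", "IGKV", 85),
    ("AKR/J", "IGLV", 3),
    ("BALB/c", "IGHV", 164),
    ("BALB/c/ByJ", "IGLV", 3),
    ("BALB/c/ByJ", "IGKV", 98),
    ("C3H/HeJ", "IGKV", 96),
    ("C3H/HeJ", "IGLV", 3),
    ("C57BL/6", "IGHV", 102),
    ("C57BL/6J", "IGKV", 91),
    ("C57BL/6J", "IGLV", 3),
    ("CAST/EiJ", "IGKV", 88),
    ("CAST/EiJ", "IGLV", 9),
    ("CBA/J", "IGKV", 82),
    ("CBA/J", "IGLV", 3),
    ("DBA/1J", "IGKV", 104),
    ("DBA/1J", "IGLV", 3),
    ("DBA/2J", "IGKV", 100),
    ("DBA/2J", "IGLV", 3),
    ("LEWES/EiJ", "IGKV", 87),
    ("LEWES/EiJ", "IGLV", 4),
    ("MRL/MpJ", "IGKV", 72),
    ("MRL/MpJ", "IGLV", 3),
    ("MSM/MsJ", "IGKV", 83),
    ("MSM/MsJ", "IGLV", 5),
    ("NOD/ShiLtJ", "IGKV", 62),
    ("NOD/ShiLtJ", "IGLV", 3),
    ("NOR/LtJ", "IGKV", 80),
    ("NOR/LtJ", "IGLV", 3),
    ("NZB/BlNJ", "IGKV", 105),
    ("NZB/BlNJ", "IGLV", 3),
    ("PWD/PhJ", "IGKV", 89),
    ("PWD/PhJ", "IGLV", 3),
    ("SJL/J", "IGKV", 67),
    ("SJL/J", "IGLV", 3),
)


def table1_fixture() -> list[tuple[str, str, int]]:
    """The published mouse strain table: (strain, locus type, count) rows."""
    return list(_TABLE1)


def build_table1_sets(seed: int = 0) -> dict[tuple[str, str], GermlineSet]:
    """Materialise one synthetic set per (strain, type) row of the table.

    Allele counts are exactly the published counts; sequences are
    synthetic.  Every set validates cleanly.
    """
    sets: dict[tuple[str, str], GermlineSet] = {}
    for row_i, (strain, locus_type, count) in enumerate(_TABLE1):
        locus = Locus(locus_type[:3])
        seq_type = SequenceType(locus_type[3])
        spec = SynthSpec(
            locus=locus,
            sequence_type=seq_type,
            n_base_alleles=count,
            alleles_per_gene=1,
            point_mutation_rate=0.0,
            truncation_prob=0.0,
            seed=seed * 1000 + row_i,
        )
        gs = generate_set(spec)
        gs.germline_set_id = f"mouse-{strain}-{locus_type}"
        gs.name = f"{strain} {locus_type} germline set"
        gs.species = Species(label="Mus musculus", taxon_id="10090")
        gs.species_subgroup = strain
        gs.species_subgroup_type = SpeciesSubgroupType.INBRED_STRAIN
        sets[(strain, locus_type)] = gs
    return sets
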