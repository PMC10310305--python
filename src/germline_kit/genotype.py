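"""Per-subject genotypes: allele classification and personalised sets.

An individual's genotype for a locus lists which documented alleles of
the referenced germline sets were found, any alleles that could not be
found in those sets ("undocumented"), and genes confirmed deleted in
that individual.  From a genotype, :func:`personalize` builds a
personalised germline set — the sets-containing-just-those-alleles form
that annotation tools can load directly in place of the full reference.

:func:`classify_allele` is deliberately conservative: an observed
sequence that is a strict sub- or super-sequence of a documented allele
is reported as a ``partial_match``, never silently promoted to
``documented``.  AIRR-seq inference is often inconclusive for the last
nucleotides at the 3' end, so a truncated observation genuinely may or
may not be the documented allele; the promotion is a curator's call,
mirroring the registry's sub-/super-sequence rule.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from .model import (
    AlleleDescription,
    Genotype,
    GenotypeSet,
    GermlineSet,
    GermlineSetRef,
    Locus,
    Species,
    SpeciesSubgroupType,
    SupportingEvidence,
    EvidenceType,
    is_valid,
    resolve_label,
    validate_genotype,
)
from .registry import NamingDomain, allocate_identifier, normalize_sequence
from .nomenclature import format_label, null_label_for
from .setio import SCHEMA_VERSION, SchemaValidationError, SchemaVersionError

import json

__all__ = [
    "AlleleClassification",
    "classify_allele",
    "personalize",
    "read_genotype_set",
    "write_genotype_set",
]


@dataclass
class AlleleClassification:
    """Outcome of looking one observed sequence up in germline sets."""

    sequence: str
    verdict: str  # "documented" | "partial_match" | "undocumented"
    matches: list[tuple[str, str]] = field(default_factory=list)  # (set id, label)
    truncation: str | None = None  # "5p" | "3p" | "both"


def classify_allele(
    sequence: str, sets: list[GermlineSet]
) -> AlleleClassification:
    """Classify one observed allele sequence against germline sets.

    Exact full-length equality with a documented coding sequence →
    ``documented``.  A strict substring of a documented allele — or a
    strict superstring of one flagged incomplete — → ``partial_match``,
    with the missing side reported (prefix missing → 5p, suffix missing
    → 3p).  Anything else → ``undocumented``.
    """
    if not sets:
        raise ValueError("at least one germline set is required")
    seq = normalize_sequence(sequence)
    if not seq:
        raise ValueError("empty sequence")

    exact: list[tuple[str, str]] = []
    for gs in sets:
        for d in gs.allele_descriptions:
            if d.coding_sequence == seq:
                exact.append((gs.germline_set_id, d.label))
    if exact:
        return AlleleClassification(sequence=seq, verdict="documented", matches=exact)

    partial: list[tuple[str, str]] = []
    truncation: str | None = None
    for gs in sets:
        for d in sorted(gs.allele_descriptions, key=lambda d: d.label):
            ref = d.coding_sequence
            if seq in ref and seq != ref:
                partial.append((gs.germline_set_id, d.label))
                if truncation is None:
                    offset = ref.index(seq)
                    missing_5p = offset > 0
                    missing_3p = offset + len(seq) < len(ref)
                    truncation = (
                        "both"
                        if missing_5p and missing_3p
                        else "5p" if missing_5p else "3p"
                    )
            elif (
                ref in seq
                and seq != ref
                and (d.incomplete_5p or d.incomplete_3p)
            ):
                # the documented record is the truncated one; report
                # which of its ends is known to be incomplete
                partial.append((gs.germline_set_id, d.label))
                if truncation is None:
                    truncation = (
                        "both"
                        if d.incomplete_5p and d.incomplete_3p
                        else "5p" if d.incomplete_5p else "3p"
                    )
    if partial:
        return AlleleClassification(
            sequence=seq,
            verdict="partial_match",
            matches=partial,
            truncation=truncation,
        )
    return AlleleClassification(sequence=seq, verdict="undocumented")


def personalize(
    sets: list[GermlineSet],
    genotype: Genotype,
    registry: NamingDomain | None = None,
    subject_id: str = "subject",
    seed: int = 0,
) -> GermlineSet:
    """Build a personalised germline set from one subject's genotype.

    The output contains one allele per documented call (copied from the
    referenced set) and one per undocumented allele.  Undocumented
    alleles receive a fresh null-valued temporary label when a naming
    domain registry is supplied, otherwise the placeholder ``UND-<n>``.
    No allele of a deleted gene appears; phasing is carried into the
    evidence notes.
    """
    violations = validate_genotype(
        GenotypeSet(genotype_set_id="tmp", subject_id=subject_id, genotypes=[genotype]),
        sets,
    )
    if not is_valid(violations):
        raise ValueError(
            "genotype does not validate against the referenced sets:\n"
            + "\n".join(str(v) for v in violations if v.severity == "error")
        )
    by_key = {(s.germline_set_id, s.release_version): s for s in sets}
    refs = [
        by_key[(r.germline_set_id, r.release_version)]
        for r in genotype.germline_set_refs
    ]
    deleted = set(genotype.deleted_genes)

    alleles: list[AlleleDescription] = []
    for call in genotype.documented_calls:
        src = refs[call.ref_index]
        desc = resolve_label(src, call.label)
        assert desc is not None  # validated above
        if desc.gene_label is not None and desc.gene_label in deleted:
            continue  # unreachable for valid genotypes; belt and braces
        copied = AlleleDescription(
            allele_description_id=desc.allele_description_id,
            label=desc.label,
            sequence_type=desc.sequence_type,
            locus=desc.locus,
            coding_sequence=desc.coding_sequence,
            gapped_sequence=desc.gapped_sequence,
            aliases=list(desc.aliases),
            delineations=list(desc.delineations),
            j_codon_frame=desc.j_codon_frame,
            j_donor_splice=desc.j_donor_splice,
            gene_label=desc.gene_label,
            functionality=desc.functionality,
            incomplete_5p=desc.incomplete_5p,
            incomplete_3p=desc.incomplete_3p,
            evidence=list(desc.evidence),
            version=desc.version,
            release_date=desc.release_date,
        )
        if call.phasing is not None:
            copied.evidence.append(
                SupportingEvidence(
                    evidence_type=EvidenceType.INFERRED,
                    notes=f"phasing: chromosome {call.phasing} in subject "
                    f"{subject_id!r}",
                )
            )
        alleles.append(copied)

    rng = random.Random(seed)
    working_registry = registry
    for n, und in enumerate(genotype.undocumented_alleles, start=1):
        seq = normalize_sequence(und.sequence)
        seq_type = alleles[0].sequence_type if alleles else None
        if working_registry is not None:
            identifier = allocate_identifier(working_registry, rng)
            # reserve the identifier locally so a second undocumented
            # allele in the same genotype cannot draw it again
            from .registry import RegistryRecord

            label = format_label(
                null_label_for(
                    genotype.locus,
                    seq_type or _dominant_type(refs),
                    identifier,
                )
            )
            working_registry = NamingDomain(
                domain_id=working_registry.domain_id,
                records=list(working_registry.records)
                + [
                    RegistryRecord(
                        identifier=identifier,
                        current_label=label,
                        sequence=seq,
                        notes=f"undocumented allele of subject {subject_id!r}",
                    )
                ],
            )
        else:
            label = f"UND-{n}"
        evidence = [
            SupportingEvidence(
                evidence_type=EvidenceType.INFERRED,
                notes=(und.notes or f"undocumented in subject {subject_id!r}")
                + (
                    f"; phasing: chromosome {und.phasing}"
                    if und.phasing is not None
                    else ""
                ),
            )
        ]
        alleles.append(
            AlleleDescription(
                allele_description_id=f"und-{subject_id}-{n}",
                label=label,
                sequence_type=seq_type or _dominant_type(refs),
                locus=genotype.locus,
                coding_sequence=seq,
                evidence=evidence,
                version=1,
            )
        )

    species = refs[0].species if refs else Species(label="unknown")
    return GermlineSet(
        germline_set_id=f"personal-{subject_id}-{genotype.locus.value}",
        name=f"Personalised {genotype.locus.value} set for subject {subject_id}",
        species=species,
        locus=genotype.locus,
        species_subgroup=refs[0].species_subgroup if refs else None,
        species_subgroup_type=(
            refs[0].species_subgroup_type if refs else SpeciesSubgroupType.NONE
        ),
        release_version=1,
        release_description=f"derived from the genotype of subject {subject_id}",
        allele_descriptions=alleles,
    )


def _dominant_type(refs: list[GermlineSet]):
    from .model import SequenceType

    for gs in refs:
        for d in gs.allele_descriptions:
            return d.sequence_type
    return SequenceType.V


# ---------------------------------------------------------------------------
# JSON (canonical form mirrors the germline-set writer)


def write_genotype_set(gset: GenotypeSet) -> str:
    doc = {
        "schema_version": SCHEMA_VERSION,
        "genotype_set_id": gset.genotype_set_id,
        "subject_id": gset.subject_id,
        "genotypes": [
            {
                "locus": gt.locus.value,
                "germline_set_refs": [
                    {
                        "germline_set_id": r.germline_set_id,
                        "release_version": r.release_version,
                    }
                    for r in gt.germline_set_refs
                ],
                "documented_calls": [
                    {
                        "label": c.label,
                        "ref_index": c.ref_index,
                        "phasing": c.phasing,
                    }
                    for c in gt.documented_calls
                ],
                "undocumented_alleles": [
                    {
                        "sequence": u.sequence,
                        "phasing": u.phasing,
                        "notes": u.notes,
                    }
                    for u in gt.undocumented_alleles
                ],
                "deleted_genes": list(gt.deleted_genes),
            }
            for gt in gset.genotypes
        ],
    }
    return json.dumps(doc, indent=2, ensure_ascii=False) + "\n"


def read_genotype_set(text: str) -> GenotypeSet:
    from .model import DocumentedCall, UndocumentedAllele

    obj = json.loads(text)
    version = obj.get("schema_version")
    if version != SCHEMA_VERSION:
        raise SchemaVersionError(
            f"unsupported schema_version {version!r} (expected {SCHEMA_VERSION!r})"
        )
    for key in ("genotype_set_id", "subject_id"):
        if key not in obj:
            raise SchemaValidationError(f"$.{key}", "required field is missing")
    genotypes = []
    for gi, gt in enumerate(obj.get("genotypes", [])):
        if "locus" not in gt:
            raise SchemaValidationError(
                f"$.genotypes[{gi}].locus", "required field is missing"
            )
        genotypes.append(
            Genotype(
                locus=Locus(gt["locus"]),
                germline_set_refs=[
                    GermlineSetRef(
                        germline_set_id=r["germline_set_id"],
                        release_version=int(r["release_version"]),
                    )
                    for r in gt.get("germline_set_refs", [])
                ],
                documented_calls=[
                    DocumentedCall(
                        label=c["label"],
                        ref_index=int(c["ref_index"]),
                        phasing=c.get("phasing"),
                    )
                    for c in gt.get("documented_calls", [])
                ],
                undocumented_alleles=[
                    UndocumentedAllele(
                        sequence=u["sequence"],
                        phasing=u.get("phasing"),
                        notes=u.get("notes", ""),
                    )
                    for u in gt.get("undocumented_alleles", [])
                ],
                deleted_genes=list(gt.get("deleted_genes", [])),
            )
        )
    return GenotypeSet(
        genotype_set_id=obj["genotype_set_id"],
        subject_id=obj["subject_id"],
        genotypes=genotypes,
    )
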