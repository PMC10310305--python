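"""Domain types for germline sets and genotypes, plus validation.

The objects here mirror the community data model for immune-receptor
germline curation: a :class:`GermlineSet` is a versioned, attributed
collection of :class:`AlleleDescription` records for one locus of one
species (optionally restricted to a subgroup such as an inbred strain),
and a :class:`GenotypeSet` records, per subject and per locus, which of
those alleles were found in one individual — including alleles that are
*not* in any referenced set ("undocumented") and genes confirmed deleted.

Validation never raises for bad data: each ``validate_*`` function
returns a list of :class:`Violation` values carrying a field path,
message and severity, so curation pipelines can report every problem at
once.  Only structurally impossible requests (e.g. a genotype referring
to a germline set that was not supplied) raise.

Coordinates are 1-based and inclusive on the ungapped coding sequence,
the convention of the immunogenetics literature.  The gap character in
gapped (alignment) sequences is ``"."``; ``"-"`` is accepted on input
and normalised.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

__all__ = [
    "SequenceType",
    "Locus",
    "Functionality",
    "SpeciesSubgroupType",
    "EvidenceType",
    "Violation",
    "Species",
    "Acknowledgement",
    "Delineation",
    "SupportingEvidence",
    "AlleleDescription",
    "GermlineSet",
    "DocumentedCall",
    "UndocumentedAllele",
    "GermlineSetRef",
    "Genotype",
    "GenotypeSet",
    "MissingReferencedSetError",
    "validate_allele_description",
    "validate_germline_set",
    "validate_genotype",
    "is_valid",
    "resolve_label",
    "normalize_gapped",
    "degap",
]

IUPAC_NT = set("ACGTRYSWKMBDHVN")
GAP_CHARS = ".-"
REGION_NAMES = ("FR1", "CDR1", "FR2", "CDR2", "FR3", "CDR3", "FR4")


class SequenceType(str, Enum):
    V = "V"
    D = "D"
    J = "J"


class Locus(str, Enum):
    IGH = "IGH"
    IGK = "IGK"
    IGL = "IGL"
    TRA = "TRA"
    TRB = "TRB"
    TRG = "TRG"
    TRD = "TRD"


class Functionality(str, Enum):
    FUNCTIONAL = "functional"
    ORF = "ORF"
    PSEUDOGENE = "pseudogene"
    UNKNOWN = "unknown"


class SpeciesSubgroupType(str, Enum):
    LOCATIONAL = "locational"
    BREED = "breed"
    INBRED_STRAIN = "inbred_strain"
    OUTBRED_STRAIN = "outbred_strain"
    NONE = "none"


class EvidenceType(str, Enum):
    GENOMIC = "genomic"
    INFERRED = "inferred"
    REARRANGED = "rearranged"


@dataclass(frozen=True)
class Violation:
    """One validation finding: where, what, and how bad."""

    path: str
    message: str
    severity: str = "error"  # "error" | "warning" | "info"

    def __str__(self) -> str:
        return f"[{self.severity}] {self.path}: {self.message}"


def is_valid(violations: list[Violation]) -> bool:
    """True when no error-severity violation is present."""
    return not any(v.severity == "error" for v in violations)


@dataclass(frozen=True)
class Species:
    label: str
    taxon_id: str | None = None


@dataclass(frozen=True)
class Acknowledgement:
    name: str
    institution: str = ""
    orcid_id: str = ""


@dataclass(frozen=True)
class Delineation:
    """FR/CDR region boundaries on the ungapped coding sequence.

    ``regions`` holds ``(region_name, start, end)`` triples with 1-based
    inclusive coordinates; regions must be non-overlapping with strictly
    ascending starts.
    """

    scheme: str  # "IMGT" | "Kabat" | "Chothia" | custom scheme name
    regions: tuple[tuple[str, int, int], ...] = ()


@dataclass(frozen=True)
class SupportingEvidence:
    evidence_type: EvidenceType
    repository: str = ""
    accession: str = ""
    notes: str = ""


def normalize_gapped(seq: str) -> str:
    """Uppercase a gapped sequence and normalise '-' gaps to '.'."""
    return seq.upper().replace("-", ".")


def degap(seq: str) -> str:
    """Strip gap characters from a sequence."""
    return "".join(c for c in seq if c not in GAP_CHARS)


@dataclass
class AlleleDescription:
    """Full description of a single germline V, D or J allele.

    ``label`` may be a temporary label or a legacy name; earlier names
    live in ``aliases`` (oldest first) so the allele stays traceable
    across renames.  ``gene_label`` is absent while the allele is
    unmapped.  J alleles may carry the donor splice position
    (``j_donor_splice``, 1-based on the coding sequence) and reading
    frame; V alleles may carry a gapped alignment whose degapped form
    must equal the coding sequence exactly.
    """

    allele_description_id: str
    label: str
    sequence_type: SequenceType
    locus: Locus
    coding_sequence: str
    gapped_sequence: str | None = None
    aliases: list[str] = field(default_factory=list)
    delineations: list[Delineation] = field(default_factory=list)
    j_codon_frame: int | None = None
    j_donor_splice: int | None = None
    gene_label: str | None = None
    functionality: Functionality = Functionality.UNKNOWN
    incomplete_5p: bool = False
    incomplete_3p: bool = False
    evidence: list[SupportingEvidence] = field(default_factory=list)
    version: int = 1
    release_date: str = "1970-01-01"


@dataclass
class GermlineSet:
    germline_set_id: str
    name: str
    species: Species
    locus: Locus
    species_subgroup: str | None = None
    species_subgroup_type: SpeciesSubgroupType = SpeciesSubgroupType.NONE
    release_version: int = 1
    release_date: str = "1970-01-01"
    release_description: str = ""
    license: str = "CC0 1.0"
    acknowledgements: list[Acknowledgement] = field(default_factory=list)
    allele_descriptions: list[AlleleDescription] = field(default_factory=list)


@dataclass(frozen=True)
class GermlineSetRef:
    germline_set_id: str
    release_version: int


@dataclass(frozen=True)
class DocumentedCall:
    label: str
    ref_index: int  # index into Genotype.germline_set_refs
    phasing: int | None = None


@dataclass(frozen=True)
class UndocumentedAllele:
    sequence: str
    phasing: int | None = None
    notes: str = ""


@dataclass
class Genotype:
    locus: Locus
    germline_set_refs: list[GermlineSetRef] = field(default_factory=list)
    documented_calls: list[DocumentedCall] = field(default_factory=list)
    undocumented_alleles: list[UndocumentedAllele] = field(default_factory=list)
    deleted_genes: list[str] = field(default_factory=list)


@dataclass
class GenotypeSet:
    genotype_set_id: str
    subject_id: str
    genotypes: list[Genotype] = field(default_factory=list)


class MissingReferencedSetError(KeyError):
    """A genotype references a germline set that was not supplied."""

    def __init__(self, ref: GermlineSetRef):
        self.ref = ref
        super().__init__(
            f"referenced germline set ({ref.germline_set_id}, "
            f"release {ref.release_version}) was not supplied"
        )


# ---------------------------------------------------------------------------
# validation


def _check_sequence(seq: str, path: str, out: list[Violation]) -> None:
    if not seq:
        out.append(Violation(path, "sequence is empty"))
        return
    if seq != seq.upper():
        out.append(Violation(path, "sequence must be uppercase"))
        return
    bad = sorted(set(seq) - IUPAC_NT)
    if bad:
        out.append(
            Violation(path, f"characters {bad!r} are not IUPAC nucleotide codes")
        )
    elif set(seq) - set("ACGT"):
        # Registry matching is literal, so ambiguity codes deserve a flag.
        out.append(
            Violation(
                path,
                "sequence contains IUPAC ambiguity codes; registry matching "
                "is literal on ACGT",
                severity="warning",
            )
        )


def validate_allele_description(desc: AlleleDescription) -> list[Violation]:
    """Check every invariant of one allele description.

    Returns an empty list when the record is fully clean; warnings (for
    IUPAC ambiguity codes) do not make the record invalid — see
    :func:`is_valid`.
    """
    out: list[Violation] = []
    n = len(desc.coding_sequence)
    _check_sequence(desc.coding_sequence, "coding_sequence", out)

    if desc.gapped_sequence is not None:
        if desc.sequence_type is not SequenceType.V:
            out.append(
                Violation(
                    "gapped_sequence",
                    "gapped alignment is only defined for V alleles",
                )
            )
        if degap(normalize_gapped(desc.gapped_sequence)) != desc.coding_sequence:
            out.append(
                Violation(
                    "gapped_sequence",
                    "degapped gapped_sequence does not equal coding_sequence",
                )
            )

    for fname, value in (
        ("j_codon_frame", desc.j_codon_frame),
        ("j_donor_splice", desc.j_donor_splice),
    ):
        if value is not None and desc.sequence_type is not SequenceType.J:
            out.append(Violation(fname, "only defined for J alleles"))
    if desc.j_codon_frame is not None and desc.j_codon_frame not in (1, 2, 3):
        out.append(Violation("j_codon_frame", "must be 1, 2 or 3"))
    if desc.j_donor_splice is not None and not 1 <= desc.j_donor_splice <= n:
        out.append(
            Violation(
                "j_donor_splice",
                f"position {desc.j_donor_splice} outside [1, {n}]",
            )
        )

    if len(set(desc.aliases)) != len(desc.aliases):
        out.append(Violation("aliases", "aliases must be pairwise distinct"))
    if desc.label in desc.aliases:
        out.append(Violation("aliases", "label must not appear among aliases"))

    for i, dl in enumerate(desc.delineations):
        prev_start = 0
        prev_end = 0
        for rname, start, end in dl.regions:
            path = f"delineations[{i}]"
            if rname not in REGION_NAMES:
                out.append(Violation(path, f"unknown region name {rname!r}"))
            if start > end:
                out.append(Violation(path, f"{rname}: start {start} > end {end}"))
            if not (1 <= start <= n and 1 <= end <= n):
                out.append(
                    Violation(
                        path,
                        f"{rname}: coordinates [{start}, {end}] outside "
                        f"[1, {n}]",
                    )
                )
            if start <= prev_start:
                out.append(
                    Violation(path, f"{rname}: starts not strictly ascending")
                )
            elif start <= prev_end:
                out.append(Violation(path, f"{rname}: regions overlap"))
            prev_start, prev_end = start, end

    for i, ev in enumerate(desc.evidence):
        if ev.repository and not ev.accession:
            out.append(
                Violation(
                    f"evidence[{i}].accession",
                    "accession required when repository is given",
                )
            )

    if desc.version < 1:
        out.append(Violation("version", "version must be >= 1"))
    return out


def validate_germline_set(gs: GermlineSet) -> list[Violation]:
    """Validate a germline set and all its alleles.

    Per-allele violations are prefixed with the allele's label; ordering
    is deterministic (allele label, then field path) so reports diff
    cleanly between runs.
    """
    out: list[Violation] = []
    if gs.release_version < 1:
        out.append(Violation("release_version", "must be >= 1"))

    per_allele: list[Violation] = []
    for desc in gs.allele_descriptions:
        prefix = f"allele_descriptions[{desc.label}]"
        for v in validate_allele_description(desc):
            per_allele.append(Violation(f"{prefix}.{v.path}", v.message, v.severity))
        if desc.locus is not gs.locus:
            per_allele.append(
                Violation(
                    f"{prefix}.locus",
                    f"allele locus {desc.locus.value} does not match set "
                    f"locus {gs.locus.value}",
                )
            )
    per_allele.sort(key=lambda v: v.path)
    out.extend(per_allele)

    seen_labels: dict[str, int] = {}
    seen_ids: dict[str, int] = {}
    for desc in gs.allele_descriptions:
        seen_labels[desc.label] = seen_labels.get(desc.label, 0) + 1
        seen_ids[desc.allele_description_id] = (
            seen_ids.get(desc.allele_description_id, 0) + 1
        )
    for label, count in sorted(seen_labels.items()):
        if count > 1:
            out.append(
                Violation(
                    "allele_descriptions",
                    f"label {label!r} appears {count} times",
                )
            )
    for did, count in sorted(seen_ids.items()):
        if count > 1:
            out.append(
                Violation(
                    "allele_descriptions",
                    f"allele_description_id {did!r} appears {count} times",
                )
            )
    labels = set(seen_labels)
    for desc in sorted(gs.allele_descriptions, key=lambda d: d.label):
        for alias in desc.aliases:
            if alias in labels and alias != desc.label:
                out.append(
                    Violation(
                        f"allele_descriptions[{desc.label}].aliases",
                        f"alias {alias!r} collides with the label of another "
                        "allele in the set",
                    )
                )
    if not gs.allele_descriptions:
        out.append(
            Violation("allele_descriptions", "set contains no alleles", "info")
        )
    return out


def resolve_label(gs: GermlineSet, label: str) -> AlleleDescription | None:
    """Find an allele by current label, falling back to aliases."""
    for desc in gs.allele_descriptions:
        if desc.label == label:
            return desc
    for desc in gs.allele_descriptions:
        if label in desc.aliases:
            return desc
    return None


def validate_genotype(
    gset: GenotypeSet, sets: list[GermlineSet]
) -> list[Violation]:
    """Validate a subject's genotype set against its referenced germline sets.

    Raises :class:`MissingReferencedSetError` when a referenced set is
    not supplied; everything else is reported as violations.
    """
    by_key = {(s.germline_set_id, s.release_version): s for s in sets}
    out: list[Violation] = []

    seen_loci: set[Locus] = set()
    for gi, gt in enumerate(gset.genotypes):
        gpath = f"genotypes[{gi}]"
        if gt.locus in seen_loci:
            out.append(
                Violation(gpath + ".locus", f"duplicate locus {gt.locus.value}")
            )
        seen_loci.add(gt.locus)

        refs: list[GermlineSet] = []
        for ref in gt.germline_set_refs:
            key = (ref.germline_set_id, ref.release_version)
            if key not in by_key:
                raise MissingReferencedSetError(ref)
            refs.append(by_key[key])

        deleted = set(gt.deleted_genes)
        for ci, call in enumerate(gt.documented_calls):
            cpath = f"{gpath}.documented_calls[{ci}]"
            if not 0 <= call.ref_index < len(refs):
                out.append(
                    Violation(cpath, f"ref_index {call.ref_index} out of range")
                )
                continue
            desc = resolve_label(refs[call.ref_index], call.label)
            if desc is None:
                out.append(
                    Violation(
                        cpath,
                        f"label {call.label!r} does not resolve in referenced "
                        "set (directly or via alias)",
                    )
                )
            elif desc.gene_label is not None and desc.gene_label in deleted:
                out.append(
                    Violation(
                        cpath,
                        f"documented call {call.label!r} is on gene "
                        f"{desc.gene_label!r} listed in deleted_genes",
                    )
                )
            if call.phasing is not None and call.phasing < 1:
                out.append(Violation(cpath + ".phasing", "phasing must be >= 1"))

        known = {
            desc.coding_sequence for s in refs for desc in s.allele_descriptions
        }
        for ui, und in enumerate(gt.undocumented_alleles):
            if und.sequence in known:
                out.append(
                    Violation(
                        f"{gpath}.undocumented_alleles[{ui}]",
                        "sequence is identical to a documented allele in a "
                        "referenced set",
                    )
                )
    return out
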