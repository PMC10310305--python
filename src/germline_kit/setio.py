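"""Germline-set serialisation, versioning and release diffing.

Sets are published in two interoperable forms: a JSON document carrying
the full schema (metadata, evidence, delineations, aliases) and a FASTA
file carrying labels and sequences only — tools are encouraged to take
everything beyond the sequence from the JSON rather than parsing it out
of the name.

The JSON writer is canonical: fixed key order, two-space indent, LF
line endings, alleles sorted by label.  Two equal sets therefore
serialise to byte-identical documents, which makes releases diffable in
ordinary version control and makes ``write(read(text))`` a
canonicalising round trip.

``diff_sets`` identifies what changed between two releases — added,
removed and modified alleles — matching records by their stable
description id first and then by resolving labels through aliases, so a
pure rename is reported as a modification of ``label``, not as a
removal plus an addition.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, fields, replace

from Bio import SeqIO

from .model import (
    Acknowledgement,
    AlleleDescription,
    Delineation,
    EvidenceType,
    Functionality,
    GermlineSet,
    Locus,
    SequenceType,
    Species,
    SpeciesSubgroupType,
    SupportingEvidence,
    degap,
    normalize_gapped,
)
from .nomenclature import parse_label

__all__ = [
    "SCHEMA_VERSION",
    "SetDiff",
    "SchemaVersionError",
    "SchemaValidationError",
    "FastaExportError",
    "ComparabilityError",
    "read_germline_set",
    "write_germline_set",
    "export_fasta",
    "import_fasta",
    "diff_sets",
    "bump_version",
]

SCHEMA_VERSION = "germline-kit-1.0"

_GERMLINE_SET_KEYS = (
    "schema_version",
    "germline_set_id",
    "name",
    "species",
    "species_subgroup",
    "species_subgroup_type",
    "locus",
    "release_version",
    "release_date",
    "release_description",
    "license",
    "acknowledgements",
    "allele_descriptions",
)
_ALLELE_KEYS = (
    "allele_description_id",
    "label",
    "sequence_type",
    "gene_label",
    "functionality",
    "coding_sequence",
    "gapped_sequence",
    "incomplete_5p",
    "incomplete_3p",
    "j_codon_frame",
    "j_donor_splice",
    "delineations",
    "aliases",
    "evidence",
    "version",
    "release_date",
)


class SchemaVersionError(ValueError):
    """The document's schema_version is missing or unsupported."""


class SchemaValidationError(ValueError):
    """A required field is missing or malformed; carries the JSON path."""

    def __init__(self, path: str, message: str):
        self.path = path
        super().__init__(f"{path}: {message}")


class FastaExportError(ValueError):
    """Gapped export was requested but some V alleles lack alignments."""

    def __init__(self, labels: list[str]):
        self.labels = labels
        super().__init__(
            "gapped export requested but no gapped_sequence on: "
            + ", ".join(labels)
        )


class ComparabilityError(ValueError):
    """Two sets cannot be diffed (different locus or species)."""


@dataclass
class SetDiff:
    """Changes between two releases of a germline set."""

    added: list[str] = field(default_factory=list)
    removed: list[str] = field(default_factory=list)
    modified: list[tuple[str, list[str]]] = field(default_factory=list)

    def is_empty(self) -> bool:
        return not (self.added or self.removed or self.modified)


# ---------------------------------------------------------------------------
# JSON


def _allele_to_dict(d: AlleleDescription) -> dict:
    return {
        "allele_description_id": d.allele_description_id,
        "label": d.label,
        "sequence_type": d.sequence_type.value,
        "gene_label": d.gene_label,
        "functionality": d.functionality.value,
        "coding_sequence": d.coding_sequence,
        "gapped_sequence": d.gapped_sequence,
        "incomplete_5p": d.incomplete_5p,
        "incomplete_3p": d.incomplete_3p,
        "j_codon_frame": d.j_codon_frame,
        "j_donor_splice": d.j_donor_splice,
        "delineations": [
            {
                "scheme": dl.scheme,
                "regions": [
                    {"region": r, "start": s, "end": e} for r, s, e in dl.regions
                ],
            }
            for dl in d.delineations
        ],
        "aliases": list(d.aliases),
        "evidence": [
            {
                "evidence_type": ev.evidence_type.value,
                "repository": ev.repository,
                "accession": ev.accession,
                "notes": ev.notes,
            }
            for ev in d.evidence
        ],
        "version": d.version,
        "release_date": d.release_date,
    }


def write_germline_set(gs: GermlineSet) -> str:
    """Serialise to canonical JSON text (UTF-8 conventions, LF, 2-space)."""
    doc = {
        "schema_version": SCHEMA_VERSION,
        "germline_set_id": gs.germline_set_id,
        "name": gs.name,
        "species": {"label": gs.species.label, "taxon_id": gs.species.taxon_id},
        "species_subgroup": gs.species_subgroup,
        "species_subgroup_type": gs.species_subgroup_type.value,
        "locus": gs.locus.value,
        "release_version": gs.release_version,
        "release_date": gs.release_date,
        "release_description": gs.release_description,
        "license": gs.license,
        "acknowledgements": [
            {"name": a.name, "institution": a.institution, "orcid_id": a.orcid_id}
            for a in gs.acknowledgements
        ],
        "allele_descriptions": [
            _allele_to_dict(d)
            for d in sorted(gs.allele_descriptions, key=lambda d: d.label)
        ],
    }
    return json.dumps(doc, indent=2, ensure_ascii=False) + "\n"


def _require(obj: dict, key: str, path: str):
    if key not in obj:
        raise SchemaValidationError(f"{path}.{key}", "required field is missing")
    return obj[key]


def _enum(cls, value, path: str):
    try:
        return cls(value)
    except ValueError:
        raise SchemaValidationError(
            path, f"{value!r} is not one of {[m.value for m in cls]}"
        ) from None


def _allele_from_dict(obj: dict, path: str) -> AlleleDescription:
    gapped = obj.get("gapped_sequence")
    return AlleleDescription(
        allele_description_id=_require(obj, "allele_description_id", path),
        label=_require(obj, "label", path),
        sequence_type=_enum(
            SequenceType, _require(obj, "sequence_type", path), f"{path}.sequence_type"
        ),
        locus=_enum(Locus, _require(obj, "locus", path), f"{path}.locus"),
        coding_sequence=_require(obj, "coding_sequence", path),
        gapped_sequence=normalize_gapped(gapped) if gapped is not None else None,
        aliases=list(obj.get("aliases", [])),
        delineations=[
            Delineation(
                scheme=dl.get("scheme", "custom"),
                regions=tuple(
                    (r["region"], r["start"], r["end"])
                    for r in dl.get("regions", [])
                ),
            )
            for dl in obj.get("delineations", [])
        ],
        j_codon_frame=obj.get("j_codon_frame"),
        j_donor_splice=obj.get("j_donor_splice"),
        gene_label=obj.get("gene_label"),
        functionality=_enum(
            Functionality,
            obj.get("functionality", "unknown"),
            f"{path}.functionality",
        ),
        incomplete_5p=bool(obj.get("incomplete_5p", False)),
        incomplete_3p=bool(obj.get("incomplete_3p", False)),
        evidence=[
            SupportingEvidence(
                evidence_type=_enum(
                    EvidenceType,
                    ev.get("evidence_type", "inferred"),
                    f"{path}.evidence[{i}].evidence_type",
                ),
                repository=ev.get("repository", ""),
                accession=ev.get("accession", ""),
                notes=ev.get("notes", ""),
            )
            for i, ev in enumerate(obj.get("evidence", []))
        ],
        version=int(obj.get("version", 1)),
        release_date=obj.get("release_date", "1970-01-01"),
    )


def read_germline_set(text: str) -> GermlineSet:
    """Parse a schema-compliant JSON document into a :class:`GermlineSet`."""
    obj = json.loads(text)
    version = obj.get("schema_version")
    if version != SCHEMA_VERSION:
        raise SchemaVersionError(
            f"unsupported schema_version {version!r} (expected {SCHEMA_VERSION!r})"
        )
    for key in (
        "germline_set_id",
        "name",
        "species",
        "locus",
        "release_version",
    ):
        if key not in obj:
            raise SchemaValidationError(f"$.{key}", "required field is missing")
    species = obj["species"]
    # each allele record stores its locus in memory but not in the JSON,
    # where the set-level locus is authoritative
    locus = _enum(Locus, obj["locus"], "$.locus")
    alleles = []
    for i, ad in enumerate(obj.get("allele_descriptions", [])):
        ad = dict(ad)
        ad.setdefault("locus", locus.value)
        alleles.append(_allele_from_dict(ad, f"$.allele_descriptions[{i}]"))
    return GermlineSet(
        germline_set_id=obj["germline_set_id"],
        name=obj["name"],
        species=Species(
            label=_require(species, "label", "$.species"),
            taxon_id=species.get("taxon_id"),
        ),
        species_subgroup=obj.get("species_subgroup"),
        species_subgroup_type=_enum(
            SpeciesSubgroupType,
            obj.get("species_subgroup_type", "none"),
            "$.species_subgroup_type",
        ),
        locus=locus,
        release_version=int(obj["release_version"]),
        release_date=obj.get("release_date", "1970-01-01"),
        release_description=obj.get("release_description", ""),
        license=obj.get("license", "CC0 1.0"),
        acknowledgements=[
            Acknowledgement(
                name=a.get("name", ""),
                institution=a.get("institution", ""),
                orcid_id=a.get("orcid_id", ""),
            )
            for a in obj.get("acknowledgements", [])
        ],
        allele_descriptions=alleles,
    )


# ---------------------------------------------------------------------------
# FASTA

_WRAP = 60


def export_fasta(gs: GermlineSet, gapped: bool = False) -> str:
    """Render the set as FASTA: one record per allele, label-only headers.

    With ``gapped=True``, V alleles are written with their alignment
    gaps (every V allele must carry one); D and J alleles are always
    written ungapped.
    """
    if gapped:
        missing = sorted(
            d.label
            for d in gs.allele_descriptions
            if d.sequence_type is SequenceType.V and d.gapped_sequence is None
        )
        if missing:
            raise FastaExportError(missing)
    lines: list[str] = []
    for d in sorted(gs.allele_descriptions, key=lambda d: d.label):
        if gapped and d.sequence_type is SequenceType.V:
            seq = d.gapped_sequence or d.coding_sequence
        else:
            seq = d.coding_sequence
        lines.append(f">{d.label}")
        for i in range(0, len(seq), _WRAP):
            lines.append(seq[i : i + _WRAP])
    return "\n".join(lines) + "\n" if lines else ""


def import_fasta(
    text: str,
    locus: Locus,
    species: Species,
    name: str = "imported set",
    germline_set_id: str = "imported",
) -> GermlineSet:
    """Build a skeleton germline set from a legacy FASTA file.

    The first whitespace-delimited header token becomes the label; the
    sequence type is inferred by parsing the label.  Metadata beyond
    that must be filled in by the curator.
    """
    from io import StringIO

    records = list(SeqIO.parse(StringIO(text), "fasta"))
    labels = [r.id for r in records]
    dupes = sorted({l for l in labels if labels.count(l) > 1})
    if dupes:
        raise ValueError("duplicate FASTA headers: " + ", ".join(dupes))
    alleles = []
    for i, rec in enumerate(records):
        parsed = parse_label(rec.id)
        seq_type = parsed.sequence_type or SequenceType.V
        raw = str(rec.seq).upper()
        alleles.append(
            AlleleDescription(
                allele_description_id=f"{germline_set_id}-{i + 1}",
                label=rec.id,
                sequence_type=seq_type,
                locus=locus,
                coding_sequence=degap(raw),
                gapped_sequence=(
                    normalize_gapped(raw)
                    if seq_type is SequenceType.V and set(raw) & set(".-")
                    else None
                ),
                version=1,
            )
        )
    return GermlineSet(
        germline_set_id=germline_set_id,
        name=name,
        species=species,
        locus=locus,
        release_version=1,
        allele_descriptions=alleles,
    )


# ---------------------------------------------------------------------------
# diffing and versioning

_COMPARED_FIELDS = tuple(
    f.name for f in fields(AlleleDescription) if f.name != "allele_description_id"
)


def _changed_fields(old: AlleleDescription, new: AlleleDescription) -> list[str]:
    return [
        name
        for name in _COMPARED_FIELDS
        if getattr(old, name) != getattr(new, name)
    ]


def diff_sets(old: GermlineSet, new: GermlineSet) -> SetDiff:
    """Identify additions, removals and modifications between releases.

    Alleles are paired by ``allele_description_id`` first; survivors
    are paired by resolving the new label against the old set's labels
    and aliases, so renames pair up.  Changed field paths are reported
    per modified allele (a pure rename shows as ``["label"]``).
    """
    if old.locus is not new.locus or old.species.label != new.species.label:
        raise ComparabilityError(
            "sets are not comparable: "
            f"({old.species.label}, {old.locus.value}) vs "
            f"({new.species.label}, {new.locus.value})"
        )
    old_by_id = {d.allele_description_id: d for d in old.allele_descriptions}
    new_by_id = {d.allele_description_id: d for d in new.allele_descriptions}

    pairs: list[tuple[AlleleDescription, AlleleDescription]] = []
    unmatched_new: list[AlleleDescription] = []
    matched_old_ids: set[str] = set()
    for d in new.allele_descriptions:
        if d.allele_description_id in old_by_id:
            pairs.append((old_by_id[d.allele_description_id], d))
            matched_old_ids.add(d.allele_description_id)
        else:
            unmatched_new.append(d)

    old_names: dict[str, AlleleDescription] = {}
    for d in old.allele_descriptions:
        old_names.setdefault(d.label, d)
        for alias in d.aliases:
            old_names.setdefault(alias, d)
    still_new: list[AlleleDescription] = []
    for d in unmatched_new:
        cand = None
        for label in (d.label, *d.aliases):
            hit = old_names.get(label)
            if hit is not None and hit.allele_description_id not in matched_old_ids:
                cand = hit
                break
        if cand is not None:
            pairs.append((cand, d))
            matched_old_ids.add(cand.allele_description_id)
        else:
            still_new.append(d)

    diff = SetDiff()
    for old_d, new_d in sorted(pairs, key=lambda p: p[1].label):
        changed = _changed_fields(old_d, new_d)
        if changed:
            diff.modified.append((new_d.label, changed))
    diff.added = sorted(d.label for d in still_new)
    diff.removed = sorted(
        d.label
        for d in old.allele_descriptions
        if d.allele_description_id not in matched_old_ids
    )
    return diff


def bump_version(
    gs: GermlineSet, description: str, release_date: str = "1970-01-01"
) -> GermlineSet:
    """Return the next release: version + 1, new date/description, same alleles."""
    return replace(
        gs,
        release_version=gs.release_version + 1,
        release_date=release_date,
        release_description=description,
        acknowledgements=list(gs.acknowledgements),
        allele_descriptions=list(gs.allele_descriptions),
    )
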