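"""Naming-domain registry and the two-phase label-allocation workflow.

A *naming domain* is the scope — a species, or a subgroup such as a
strain — within which temporary identifiers are guaranteed unique and
are never re-used, even after a record is withdrawn.  The registry is a
plain CSV file so it can live in version control and be merged across
curation groups.

Label allocation is deliberately two-phase.  ``propose`` compares a
batch of candidate sequences against the registry and reports, for each
input, whether it duplicates, is contained in, or contains an existing
record's sequence, or is new.  The curator reviews the proposals —
containment cases in particular have no safe default, because whether a
sub-sequence represents the same allele is a judgement call that may
depend on haplotype or usage evidence — and only then does ``apply``
mutate the registry, minting fresh identifiers for the sequences the
curator confirmed as new.

Matching is exact string containment on normalised sequences
(uppercased, gaps and whitespace stripped).  Reverse-complement
matching is not attempted: germline submissions are conventionally
sense-strand.
"""

from __future__ import annotations

import random
import re
from dataclasses import dataclass, field, replace
from pathlib import Path

from .model import Locus, SequenceType
from .nomenclature import (
    IDENTIFIER_SPACE,
    encode_identifier,
    format_label,
    null_label_for,
    parse_label,
)

__all__ = [
    "RegistryRecord",
    "NamingDomain",
    "ActionProposal",
    "AllocationReport",
    "Clash",
    "ClashReport",
    "RegistryError",
    "IntegrityError",
    "CapacityError",
    "CollisionError",
    "NotFoundError",
    "UnresolvedActionError",
    "DomainMismatchError",
    "REGISTRY_HEADER",
    "PROPOSAL_HEADER",
    "normalize_sequence",
    "load_registry",
    "save_registry",
    "load_proposals",
    "save_proposals",
    "read_sequence_input",
    "propose",
    "apply",
    "allocate_identifier",
    "rename",
    "resolve",
    "withdraw",
    "merge_registries",
    "audit",
]

REGISTRY_HEADER = "identifier,current_label,sequence,status,allocated,aliases,notes"
PROPOSAL_HEADER = "input_id,sequence,proposed_action,matched_identifiers,final_action"

_STATUSES = ("active", "withdrawn")


class RegistryError(Exception):
    """Base class for registry failures."""


class IntegrityError(RegistryError):
    """The registry violates its own invariants."""


class CapacityError(RegistryError):
    """All ~1 million identifiers in the domain have been issued."""


class CollisionError(RegistryError):
    """A rename would give two records the same label."""


class NotFoundError(RegistryError, KeyError):
    """No record carries the requested label or identifier."""


class UnresolvedActionError(RegistryError):
    """apply() was given proposals whose final_action is still unset."""

    def __init__(self, input_ids: list[str]):
        self.input_ids = input_ids
        super().__init__(
            "containment proposals need a curator decision before apply; "
            f"unresolved inputs: {', '.join(input_ids)}"
        )


class DomainMismatchError(RegistryError):
    """Two registries from different naming domains cannot be merged."""


@dataclass
class RegistryRecord:
    """One issued identifier and the sequence it names."""

    identifier: str
    current_label: str
    sequence: str
    status: str = "active"
    allocated: str = "1970-01-01"
    aliases: list[str] = field(default_factory=list)
    notes: str = ""


@dataclass
class NamingDomain:
    """A registry: all records ever issued within one naming domain."""

    domain_id: str
    records: list[RegistryRecord] = field(default_factory=list)

    def by_identifier(self, identifier: str) -> RegistryRecord:
        for rec in self.records:
            if rec.identifier == identifier:
                return rec
        raise NotFoundError(f"no record with identifier {identifier!r}")

    def issued_identifiers(self) -> set[str]:
        """Every identifier ever issued, including withdrawn records."""
        return {rec.identifier for rec in self.records}


@dataclass
class ActionProposal:
    """Proposed handling for one submitted sequence.

    ``final_action`` is one of ``assign_existing:<identifier>``,
    ``allocate_new`` or ``skip``.  Duplicate and new proposals get a
    default; sub-/super-sequence proposals are left unset for the
    curator (see module docstring).
    """

    input_id: str
    sequence: str
    proposed_action: str  # duplicate | subsequence | supersequence | new | unresolved
    matched_identifiers: list[str] = field(default_factory=list)
    final_action: str | None = None
    notes: str = ""


@dataclass
class AllocationReport:
    """What apply() did: (input_id, allocated/assigned label) pairs."""

    seed: int
    allocations: list[tuple[str, str]] = field(default_factory=list)
    assigned: list[tuple[str, str]] = field(default_factory=list)
    skipped: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class Clash:
    kind: str  # "identifier" | "sequence"
    identifier_a: str
    identifier_b: str
    detail: str


@dataclass
class ClashReport:
    clashes: list[Clash] = field(default_factory=list)

    def __bool__(self) -> bool:
        return bool(self.clashes)


def normalize_sequence(seq: str) -> str:
    """Uppercase and strip gap characters and whitespace."""
    return re.sub(r"[.\-\s]", "", seq.upper())


# ---------------------------------------------------------------------------
# CSV persistence.  The format is bit-exact by contract: UTF-8, LF line
# endings, fixed header, ";"-joined aliases, and a field is quoted iff it
# contains a comma, semicolon, double quote or newline (internal quotes
# doubled) — so two registries with equal content serialise identically.


def _format_field(value: str) -> str:
    if any(c in value for c in ',;"\n'):
        return '"' + value.replace('"', '""') + '"'
    return value


def _format_row(fields: list[str]) -> str:
    return ",".join(_format_field(f) for f in fields)


def _split_row(line: str, lineno: int, path: str) -> list[str]:
    fields: list[str] = []
    cur: list[str] = []
    in_quotes = False
    i = 0
    while i < len(line):
        c = line[i]
        if in_quotes:
            if c == '"':
                if i + 1 < len(line) and line[i + 1] == '"':
                    cur.append('"')
                    i += 1
                else:
                    in_quotes = False
            else:
                cur.append(c)
        elif c == '"':
            in_quotes = True
        elif c == ",":
            fields.append("".join(cur))
            cur = []
        else:
            cur.append(c)
        i += 1
    if in_quotes:
        raise IntegrityError(f"{path}:{lineno}: unterminated quoted field")
    fields.append("".join(cur))
    return fields


def save_registry(domain: NamingDomain, path: str | Path) -> None:
    """Write a registry CSV; records sorted by allocated date, then identifier."""
    records = sorted(domain.records, key=lambda r: (r.allocated, r.identifier))
    lines = [REGISTRY_HEADER]
    for rec in records:
        lines.append(
            _format_row(
                [
                    rec.identifier,
                    rec.current_label,
                    rec.sequence,
                    rec.status,
                    rec.allocated,
                    ";".join(rec.aliases),
                    rec.notes,
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8", newline="\n")


def load_registry(path: str | Path, domain_id: str | None = None) -> NamingDomain:
    """Read a registry CSV written by :func:`save_registry`.

    ``domain_id`` defaults to the file's stem: the CSV itself carries no
    domain column, since one file *is* one naming domain.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    lines = text.split("\n")
    if lines and lines[-1] == "":
        lines.pop()
    if not lines or lines[0] != REGISTRY_HEADER:
        raise IntegrityError(f"{path}:1: expected header {REGISTRY_HEADER!r}")
    records = []
    seen: set[str] = set()
    for lineno, line in enumerate(lines[1:], start=2):
        fields = _split_row(line, lineno, str(path))
        if len(fields) != 7:
            raise IntegrityError(
                f"{path}:{lineno}: expected 7 fields, found {len(fields)}"
            )
        identifier, label, sequence, status, allocated, aliases, notes = fields
        if identifier in seen:
            raise IntegrityError(
                f"{path}:{lineno}: duplicate identifier {identifier!r}"
            )
        seen.add(identifier)
        if status not in _STATUSES:
            raise IntegrityError(f"{path}:{lineno}: unknown status {status!r}")
        records.append(
            RegistryRecord(
                identifier=identifier,
                current_label=label,
                sequence=sequence,
                status=status,
                allocated=allocated,
                aliases=[a for a in aliases.split(";") if a],
                notes=notes,
            )
        )
    return NamingDomain(domain_id=domain_id or path.stem, records=records)


def save_proposals(proposals: list[ActionProposal], path: str | Path) -> None:
    lines = [PROPOSAL_HEADER]
    for p in proposals:
        lines.append(
            _format_row(
                [
                    p.input_id,
                    p.sequence,
                    p.proposed_action,
                    ";".join(p.matched_identifiers),
                    p.final_action or "",
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8", newline="\n")


def load_proposals(path: str | Path) -> list[ActionProposal]:
    path = Path(path)
    lines = path.read_text(encoding="utf-8").split("\n")
    if lines and lines[-1] == "":
        lines.pop()
    if not lines or lines[0] != PROPOSAL_HEADER:
        raise IntegrityError(f"{path}:1: expected header {PROPOSAL_HEADER!r}")
    out = []
    for lineno, line in enumerate(lines[1:], start=2):
        fields = _split_row(line, lineno, str(path))
        if len(fields) != 5:
            raise IntegrityError(
                f"{path}:{lineno}: expected 5 fields, found {len(fields)}"
            )
        input_id, sequence, action, matched, final = fields
        out.append(
            ActionProposal(
                input_id=input_id,
                sequence=sequence,
                proposed_action=action,
                matched_identifiers=[m for m in matched.split(";") if m],
                final_action=final or None,
            )
        )
    return out


def read_sequence_input(path: str | Path) -> list[tuple[str, str]]:
    """Read candidate sequences from FASTA or a two-column CSV.

    FASTA headers (first whitespace-delimited token) or the first CSV
    column become the input ids.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if text.lstrip().startswith(">"):
        out: list[tuple[str, str]] = []
        header: str | None = None
        chunks: list[str] = []
        for line in text.splitlines():
            if line.startswith(">"):
                if header is not None:
                    out.append((header, "".join(chunks)))
                header = line[1:].split()[0] if line[1:].split() else ""
                chunks = []
            elif header is not None:
                chunks.append(line.strip())
        if header is not None:
            out.append((header, "".join(chunks)))
        return out
    out = []
    lines = text.split("\n")
    if lines and lines[-1] == "":
        lines.pop()
    start = 1 if lines and lines[0].lower().startswith("input_id") else 0
    for lineno, line in enumerate(lines[start:], start=start + 1):
        fields = _split_row(line, lineno, str(path))
        if len(fields) < 2:
            raise IntegrityError(f"{path}:{lineno}: expected id,sequence")
        out.append((fields[0], fields[1]))
    return out


# ---------------------------------------------------------------------------
# phase 1: propose


def _sorted_matches(domain: NamingDomain, identifiers: set[str]) -> list[str]:
    # Tie-break for multiple containment matches: allocated date, then
    # identifier lexicographically.
    recs = [r for r in domain.records if r.identifier in identifiers]
    recs.sort(key=lambda r: (r.allocated, r.identifier))
    return [r.identifier for r in recs]


def propose(
    new_sequences: list[tuple[str, str]], domain: NamingDomain
) -> list[ActionProposal]:
    """Phase 1: compare a batch of sequences against the registry.

    For each input, in order: exact equality with an active record →
    ``duplicate``; strict substring of at least one active record →
    ``subsequence``; strict superstring → ``supersequence``; a sequence
    that is a substring of some records and a superstring of others →
    ``unresolved``; otherwise ``new``.  Withdrawn records take part in
    duplicate detection only, flagged in the proposal notes.  Repeats of
    an earlier input in the same batch are collapsed onto the first
    occurrence.
    """
    proposals: list[ActionProposal] = []
    seen_in_batch: dict[str, str] = {}
    active = [r for r in domain.records if r.status == "active"]
    withdrawn = [r for r in domain.records if r.status == "withdrawn"]

    for input_id, raw_seq in new_sequences:
        seq = normalize_sequence(raw_seq)
        if not seq:
            raise ValueError(f"input {input_id!r}: empty sequence")

        if seq in seen_in_batch:
            proposals.append(
                ActionProposal(
                    input_id=input_id,
                    sequence=seq,
                    proposed_action="duplicate",
                    final_action="skip",
                    notes=f"duplicate-in-batch of {seen_in_batch[seq]!r}",
                )
            )
            continue
        seen_in_batch[seq] = input_id

        equal = {r.identifier for r in active if r.sequence == seq}
        if equal:
            matched = _sorted_matches(domain, equal)
            proposals.append(
                ActionProposal(
                    input_id=input_id,
                    sequence=seq,
                    proposed_action="duplicate",
                    matched_identifiers=matched,
                    final_action=f"assign_existing:{matched[0]}",
                )
            )
            continue
        wd_equal = {r.identifier for r in withdrawn if r.sequence == seq}
        if wd_equal:
            proposals.append(
                ActionProposal(
                    input_id=input_id,
                    sequence=seq,
                    proposed_action="duplicate",
                    matched_identifiers=_sorted_matches(domain, wd_equal),
                    notes="withdrawn-duplicate: matches only withdrawn records",
                )
            )
            continue

        sub = {r.identifier for r in active if seq in r.sequence and seq != r.sequence}
        sup = {r.identifier for r in active if r.sequence in seq and seq != r.sequence}
        if sub and sup:
            action = "unresolved"
            matched = _sorted_matches(domain, sub | sup)
        elif sub:
            action = "subsequence"
            matched = _sorted_matches(domain, sub)
        elif sup:
            action = "supersequence"
            matched = _sorted_matches(domain, sup)
        else:
            proposals.append(
                ActionProposal(
                    input_id=input_id,
                    sequence=seq,
                    proposed_action="new",
                    final_action="allocate_new",
                )
            )
            continue
        proposals.append(
            ActionProposal(
                input_id=input_id,
                sequence=seq,
                proposed_action=action,
                matched_identifiers=matched,
            )
        )
    return proposals


# ---------------------------------------------------------------------------
# phase 2: apply


def allocate_identifier(
    domain: NamingDomain,
    rng: random.Random,
    issued: set[str] | None = None,
) -> str:
    """Draw a fresh identifier: uniform over the unissued 20-bit values.

    Collisions with *any* ever-issued identifier — withdrawn records
    included — are redrawn, so an identifier is never re-used.
    Deterministic under a fixed-seed ``rng``.  ``issued`` lets batch
    callers maintain the ever-issued set incrementally instead of
    rebuilding it per draw; it must be a superset snapshot of the
    domain's own issued identifiers.
    """
    if issued is None:
        issued = domain.issued_identifiers()
    if len(issued) >= IDENTIFIER_SPACE:
        raise CapacityError(
            f"naming domain {domain.domain_id!r} has issued all "
            f"{IDENTIFIER_SPACE} identifiers"
        )
    # Rejection sampling is uniform over the complement and fast while
    # the domain is sparsely populated; fall back to an explicit
    # set-difference draw when over half full so it always terminates
    # quickly.
    if len(issued) * 2 < IDENTIFIER_SPACE:
        while True:
            candidate = encode_identifier(rng.randrange(IDENTIFIER_SPACE))
            if candidate not in issued:
                return candidate
    free = sorted(
        set(encode_identifier(v) for v in range(IDENTIFIER_SPACE)) - issued
    )
    return rng.choice(free)


def apply(
    proposals: list[ActionProposal],
    domain: NamingDomain,
    seed: int,
    locus: Locus = Locus.IGH,
    sequence_type: SequenceType = SequenceType.V,
    allocated_date: str = "1970-01-01",
) -> tuple[NamingDomain, AllocationReport]:
    """Phase 2: execute curator-confirmed actions on a copy of the registry.

    Every proposal must carry a final action; containment proposals the
    curator left undecided abort the whole batch with no mutation.
    ``allocate_new`` mints a fresh identifier and a null-valued
    temporary label for the given locus and sequence type;
    ``assign_existing:<identifier>`` records the submission as a
    provenance note on that record; ``skip`` does nothing.
    """
    unresolved = [p.input_id for p in proposals if not p.final_action]
    if unresolved:
        raise UnresolvedActionError(unresolved)
    known = {r.identifier for r in domain.records}
    for p in proposals:
        if p.final_action and p.final_action.startswith("assign_existing:"):
            target = p.final_action.split(":", 1)[1]
            if target not in known:
                raise IntegrityError(
                    f"input {p.input_id!r}: assign_existing target "
                    f"{target!r} is not in the registry"
                )

    new_domain = NamingDomain(
        domain_id=domain.domain_id,
        records=[replace(r, aliases=list(r.aliases)) for r in domain.records],
    )
    rng = random.Random(seed)
    report = AllocationReport(seed=seed)
    issued = new_domain.issued_identifiers()
    for p in proposals:
        action = p.final_action
        assert action is not None
        if action == "skip":
            report.skipped.append(p.input_id)
        elif action == "allocate_new":
            identifier = allocate_identifier(new_domain, rng, issued)
            issued.add(identifier)
            label = format_label(null_label_for(locus, sequence_type, identifier))
            new_domain.records.append(
                RegistryRecord(
                    identifier=identifier,
                    current_label=label,
                    sequence=normalize_sequence(p.sequence),
                    status="active",
                    allocated=allocated_date,
                    notes=f"allocated for input {p.input_id!r}",
                )
            )
            report.allocations.append((p.input_id, label))
        elif action.startswith("assign_existing:"):
            identifier = action.split(":", 1)[1]
            rec = new_domain.by_identifier(identifier)
            note = f"also submitted as {p.input_id!r}"
            rec.notes = f"{rec.notes}; {note}" if rec.notes else note
            report.assigned.append((p.input_id, rec.current_label))
        else:
            raise UnresolvedActionError([p.input_id])
    return new_domain, report


# ---------------------------------------------------------------------------
# curation


def rename(domain: NamingDomain, identifier: str, new_label: str) -> NamingDomain:
    """Give a record a new current label, keeping the old one as an alias.

    Only uniqueness and alias capture are enforced; *why* a record is
    renamed is a curator's decision, not a rule of this tool.
    """
    parse_label(new_label)  # raises LabelParseError when malformed
    target = domain.by_identifier(identifier)
    for rec in domain.records:
        if rec.identifier == identifier:
            continue
        if rec.status == "active" and rec.current_label == new_label:
            raise CollisionError(
                f"label {new_label!r} is already the current label of "
                f"record {rec.identifier!r} (renaming {identifier!r})"
            )
        if new_label in rec.aliases:
            raise CollisionError(
                f"label {new_label!r} is an alias of record "
                f"{rec.identifier!r} (renaming {identifier!r})"
            )
    records = []
    for rec in domain.records:
        if rec.identifier == identifier:
            aliases = list(rec.aliases)
            if rec.current_label != new_label and rec.current_label not in aliases:
                aliases.append(rec.current_label)
            rec = replace(rec, current_label=new_label, aliases=aliases)
        records.append(rec)
    return NamingDomain(domain_id=domain.domain_id, records=records)


def add_alias(domain: NamingDomain, identifier: str, alias: str) -> NamingDomain:
    """Record a synonym (e.g. the same allele's name in another database)."""
    for rec in domain.records:
        if rec.identifier != identifier and (
            alias in rec.aliases
            or (rec.status == "active" and rec.current_label == alias)
        ):
            raise CollisionError(
                f"alias {alias!r} already names record {rec.identifier!r}"
            )
    records = []
    for rec in domain.records:
        if rec.identifier == identifier:
            if alias != rec.current_label and alias not in rec.aliases:
                rec = replace(rec, aliases=list(rec.aliases) + [alias])
        records.append(rec)
    domain.by_identifier(identifier)  # raises NotFoundError if absent
    return NamingDomain(domain_id=domain.domain_id, records=records)


def resolve(domain: NamingDomain, label: str) -> RegistryRecord:
    """Find the unique record named by a current label or any alias."""
    primary = [r for r in domain.records if r.current_label == label]
    secondary = [r for r in domain.records if label in r.aliases]
    # a healthy registry has the label in exactly one record, counting
    # current labels and aliases together
    hits = primary + [r for r in secondary if r not in primary]
    if not hits:
        raise NotFoundError(f"no record carries label {label!r}")
    if len(hits) > 1:
        raise IntegrityError(
            f"label {label!r} resolves to multiple records: "
            + ", ".join(r.identifier for r in hits)
        )
    return hits[0]


def withdraw(domain: NamingDomain, identifier: str, note: str = "") -> NamingDomain:
    """Mark a record withdrawn.  Its identifier remains issued forever."""
    domain.by_identifier(identifier)
    records = []
    for rec in domain.records:
        if rec.identifier == identifier:
            notes = f"{rec.notes}; {note}" if (rec.notes and note) else (note or rec.notes)
            rec = replace(rec, status="withdrawn", notes=notes)
        records.append(rec)
    return NamingDomain(domain_id=domain.domain_id, records=records)


def merge_registries(
    a: NamingDomain, b: NamingDomain
) -> NamingDomain | ClashReport:
    """Merge two copies of the same naming domain's registry.

    Records agreeing on identifier and sequence are unioned (aliases:
    a's order, then b's novel ones).  The same identifier with different
    sequences, or the same sequence under different identifiers, is a
    clash; any clash aborts the merge and returns the full report.
    """
    if a.domain_id != b.domain_id:
        raise DomainMismatchError(
            f"cannot merge naming domains {a.domain_id!r} and {b.domain_id!r}"
        )
    clashes: list[Clash] = []
    a_by_id = {r.identifier: r for r in a.records}
    b_by_id = {r.identifier: r for r in b.records}
    for identifier in sorted(set(a_by_id) & set(b_by_id)):
        ra, rb = a_by_id[identifier], b_by_id[identifier]
        if ra.sequence != rb.sequence:
            clashes.append(
                Clash(
                    kind="identifier",
                    identifier_a=identifier,
                    identifier_b=identifier,
                    detail="same identifier, different sequences",
                )
            )
    a_by_seq = {r.sequence: r.identifier for r in a.records}
    for rb in b.records:
        ia = a_by_seq.get(rb.sequence)
        if ia is not None and ia != rb.identifier:
            clashes.append(
                Clash(
                    kind="sequence",
                    identifier_a=ia,
                    identifier_b=rb.identifier,
                    detail="same sequence under different identifiers",
                )
            )
    if clashes:
        return ClashReport(clashes=clashes)

    merged: list[RegistryRecord] = []
    for ra in a.records:
        rb = b_by_id.get(ra.identifier)
        if rb is None:
            merged.append(replace(ra, aliases=list(ra.aliases)))
        else:
            aliases = list(ra.aliases) + [
                al for al in rb.aliases if al not in ra.aliases
            ]
            merged.append(replace(ra, aliases=aliases))
    for rb in b.records:
        if rb.identifier not in a_by_id:
            merged.append(replace(rb, aliases=list(rb.aliases)))
    return NamingDomain(domain_id=a.domain_id, records=merged)


def audit(domain: NamingDomain) -> list[str]:
    """Check the domain invariants; returns human-readable problems."""
    problems: list[str] = []
    seen_ids: set[str] = set()
    label_owner: dict[str, str] = {}
    alias_owner: dict[str, str] = {}
    for rec in domain.records:
        if rec.identifier in seen_ids:
            problems.append(f"identifier {rec.identifier!r} appears twice")
        seen_ids.add(rec.identifier)
        if not rec.sequence:
            problems.append(f"record {rec.identifier!r} has an empty sequence")
        if rec.status not in _STATUSES:
            problems.append(
                f"record {rec.identifier!r} has unknown status {rec.status!r}"
            )
        try:
            parse_label(rec.current_label)
        except Exception as exc:  # noqa: BLE001 - report, don't raise
            problems.append(
                f"record {rec.identifier!r}: unparseable label "
                f"{rec.current_label!r} ({exc})"
            )
        if rec.status == "active":
            if rec.current_label in label_owner:
                problems.append(
                    f"label {rec.current_label!r} is current on two active "
                    f"records ({label_owner[rec.current_label]!r}, "
                    f"{rec.identifier!r})"
                )
            label_owner[rec.current_label] = rec.identifier
        for alias in rec.aliases:
            if alias in alias_owner and alias_owner[alias] != rec.identifier:
                problems.append(
                    f"alias {alias!r} appears on two records "
                    f"({alias_owner[alias]!r}, {rec.identifier!r})"
                )
            alias_owner[alias] = rec.identifier
    return problems
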