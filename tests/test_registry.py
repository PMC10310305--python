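"""Naming-domain registry: CSV persistence, propose/apply, curation."""

import random

import pytest

from germline_kit import registry as reg
from germline_kit.nomenclature import parse_label, TempLabel
from germline_kit.registry import (
    ActionProposal,
    ClashReport,
    CollisionError,
    IntegrityError,
    NamingDomain,
    NotFoundError,
    RegistryRecord,
    UnresolvedActionError,
)


def record(identifier, label, seq, **kwargs):
    return RegistryRecord(
        identifier=identifier, current_label=label, sequence=seq, **kwargs
    )


def oracle_propose(seq: str, records: list[RegistryRecord]) -> tuple[str, set[str]]:
    """Brute-force all-pairs containment scan, independent of propose()."""
    active = [r for r in records if r.status == "active"]
    equal = {r.identifier for r in active if r.sequence == seq}
    if equal:
        return "duplicate", equal
    sub = {r.identifier for r in active if seq != r.sequence and seq in r.sequence}
    sup = {r.identifier for r in active if seq != r.sequence and r.sequence in seq}
    if sub and sup:
        return "unresolved", sub | sup
    if sub:
        return "subsequence", sub
    if sup:
        return "supersequence", sup
    return "new", set()


class TestCsvRoundTrip:
    def test_empty_domain(self, tmp_path):
        d = NamingDomain("mouse-IGH")
        p = tmp_path / "mouse-IGH.csv"
        reg.save_registry(d, p)
        assert reg.load_registry(p) == d
        assert p.read_text() == reg.REGISTRY_HEADER + "\n"

    def test_hundred_synthetic_records_field_for_field(self, tmp_path):
        rng = random.Random(3)
        d = NamingDomain("x")
        issued = set()
        for i in range(100):
            while True:
                from germline_kit.nomenclature import encode_identifier

                ident = encode_identifier(rng.randrange(32**4))
                if ident not in issued:
                    issued.add(ident)
                    break
            d.records.append(
                record(
                    ident,
                    f"IGHV0-{ident}*00",
                    "".join(rng.choice("ACGT") for _ in range(rng.randint(10, 50))),
                    status=rng.choice(["active", "withdrawn"]),
                    allocated=f"20{rng.randint(10, 25)}-01-0{rng.randint(1, 9)}",
                    aliases=[f"IGHV{j}-OLD*0{j}" for j in range(rng.randint(0, 3))],
                    notes=rng.choice(["", "has, comma", 'has "quote"', "semi;colon"]),
                )
            )
        p = tmp_path / "x.csv"
        reg.save_registry(d, p)
        loaded = reg.load_registry(p)
        by_id = {r.identifier: r for r in loaded.records}
        for r in d.records:
            assert by_id[r.identifier] == r

    def test_save_is_bit_stable(self, tmp_path):
        d = NamingDomain("x", [record("AAAA", "IGHV0-AAAA*00", "ACGT", notes="a;b,c")])
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        reg.save_registry(d, p1)
        reg.save_registry(reg.load_registry(p1, "x"), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_duplicate_identifier_rejected(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text(
            reg.REGISTRY_HEADER
            + "\nAAAA,IGHV0-AAAA*00,ACGT,active,2020-01-01,,\n"
            + "AAAA,IGHV0-AAAB*00,ACGA,active,2020-01-01,,\n"
        )
        with pytest.raises(IntegrityError, match="AAAA"):
            reg.load_registry(p)

    def test_malformed_row_reports_line_number(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text(reg.REGISTRY_HEADER + "\nAAAA,only-three-fields,ACGT\n")
        with pytest.raises(IntegrityError, match=":2"):
            reg.load_registry(p)


class TestPropose:
    @pytest.fixture
    def domain(self):
        return NamingDomain(
            "mouse-IGH", [record("AAAA", "IGHV0-AAAA*00", "ACGTACGT", allocated="2020-01-01")]
        )

    def test_duplicate(self, domain):
        (p,) = reg.propose([("s1", "ACGTACGT")], domain)
        assert p.proposed_action == "duplicate"
        assert p.matched_identifiers == ["AAAA"]
        assert p.final_action == "assign_existing:AAAA"

    def test_containment(self, domain):
        ps = reg.propose(
            [("sub", "GTAC"), ("sup", "TTACGTACGTTT"), ("new", "CCCC")], domain
        )
        assert [p.proposed_action for p in ps] == ["subsequence", "supersequence", "new"]
        assert ps[0].matched_identifiers == ["AAAA"]
        assert ps[0].final_action is None and ps[1].final_action is None
        assert ps[2].final_action == "allocate_new"

    def test_normalisation_before_matching(self, domain):
        (p,) = reg.propose([("s1", "acgt-ac.gt ")], domain)
        assert p.proposed_action == "duplicate"

    def test_batch_duplicates_collapsed(self, domain):
        ps = reg.propose([("a", "CCCC"), ("b", "CCCC")], domain)
        assert ps[0].proposed_action == "new"
        assert ps[1].proposed_action == "duplicate"
        assert "duplicate-in-batch" in ps[1].notes
        assert ps[1].final_action == "skip"

    def test_withdrawn_duplicate_reported(self, domain):
        domain.records[0].status = "withdrawn"
        (p,) = reg.propose([("s1", "ACGTACGT")], domain)
        assert p.proposed_action == "duplicate"
        assert "withdrawn" in p.notes

    def test_empty_sequence_rejected(self, domain):
        with pytest.raises(ValueError, match="empty"):
            reg.propose([("s1", "")], domain)

    def test_matches_ordered_by_date_then_identifier(self):
        d = NamingDomain(
            "x",
            [
                record("BBBB", "IGHV0-BBBB*00", "ACGTACGTAA", allocated="2021-01-01"),
                record("AAAA", "IGHV0-AAAA*00", "TTACGTACGT", allocated="2021-01-01"),
                record("CCCC", "IGHV0-CCCC*00", "CACGTACGTC", allocated="2019-01-01"),
            ],
        )
        (p,) = reg.propose([("q", "ACGTACGT")], d)
        assert p.proposed_action == "subsequence"
        assert p.matched_identifiers == ["CCCC", "AAAA", "BBBB"]

    def test_agrees_with_brute_force_oracle(self):
        """1,000 randomised trials against the all-pairs containment scan."""
        rng = random.Random(11)
        from germline_kit.nomenclature import encode_identifier

        trials = 0
        for batch in range(20):
            n_records = rng.randint(0, 100)
            idents = rng.sample(range(32**4), n_records)
            domain = NamingDomain(
                f"d{batch}",
                [
                    record(
                        encode_identifier(v),
                        f"IGHV0-{encode_identifier(v)}*00",
                        "".join(rng.choice("ACGT") for _ in range(rng.randint(4, 400))),
                        allocated=f"202{rng.randint(0, 5)}-0{rng.randint(1, 9)}-01",
                    )
                    for v in idents
                ],
            )
            queries = []
            for i in range(50):
                if domain.records and rng.random() < 0.5:
                    # bias towards hits: reuse, trim or extend a record's sequence
                    base = rng.choice(domain.records).sequence
                    mode = rng.random()
                    if mode < 0.3:
                        seq = base
                    elif mode < 0.6 and len(base) > 6:
                        a = rng.randint(0, len(base) - 4)
                        b = rng.randint(a + 4, len(base))
                        seq = base[a:b]
                    else:
                        seq = (
                            "".join(rng.choice("ACGT") for _ in range(rng.randint(0, 5)))
                            + base
                            + "".join(rng.choice("ACGT") for _ in range(rng.randint(0, 5)))
                        )
                else:
                    seq = "".join(rng.choice("ACGT") for _ in range(rng.randint(4, 400)))
                queries.append((f"q{i}", seq))
            seen: set[str] = set()
            for proposal, (qid, seq) in zip(reg.propose(queries, domain), queries):
                trials += 1
                if seq in seen:
                    assert proposal.proposed_action == "duplicate"
                    assert "duplicate-in-batch" in proposal.notes
                    continue
                seen.add(seq)
                action, matches = oracle_propose(seq, domain.records)
                assert proposal.proposed_action == action, (qid, seq)
                assert set(proposal.matched_identifiers) == matches
        assert trials == 1000


class TestApply:
    def test_fresh_allocation_has_null_label(self):
        domain = NamingDomain("mouse-IGH")
        proposals = reg.propose([("s1", "ACGTACGTACGT")], domain)
        new_domain, report = reg.apply(proposals, domain, seed=5)
        assert len(new_domain.records) == 1
        label = parse_label(report.allocations[0][1])
        assert isinstance(label, TempLabel)
        assert label.subgroup == "0" and label.allele == "00"
        assert domain.records == []  # input not mutated

    def test_unresolved_subsequence_rejected_without_mutation(self):
        domain = NamingDomain(
            "x", [record("AAAA", "IGHV0-AAAA*00", "ACGTACGT")]
        )
        proposals = reg.propose([("s1", "GTAC")], domain)
        with pytest.raises(UnresolvedActionError, match="s1"):
            reg.apply(proposals, domain, seed=1)
        assert len(domain.records) == 1

    def test_assign_existing_records_provenance(self):
        domain = NamingDomain("x", [record("AAAA", "IGHV0-AAAA*00", "ACGT")])
        proposals = [
            ActionProposal("s1", "GT", "subsequence", ["AAAA"], "assign_existing:AAAA")
        ]
        new_domain, report = reg.apply(proposals, domain, seed=1)
        assert report.assigned == [("s1", "IGHV0-AAAA*00")]
        assert "s1" in new_domain.records[0].notes

    def test_assign_existing_unknown_identifier_is_integrity_error(self):
        domain = NamingDomain("x")
        proposals = [ActionProposal("s1", "ACGT", "duplicate", [], "assign_existing:ZZZZ")]
        with pytest.raises(IntegrityError, match="ZZZZ"):
            reg.apply(proposals, domain, seed=1)

    def test_determinism_and_bit_reproducibility(self, tmp_path):
        domain = NamingDomain("x")
        proposals = reg.propose(
            [(f"s{i}", "".join(random.Random(i).choices("ACGT", k=30))) for i in range(20)],
            domain,
        )
        d1, r1 = reg.apply(proposals, domain, seed=99)
        d2, r2 = reg.apply(proposals, domain, seed=99)
        assert r1.allocations == r2.allocations
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        reg.save_registry(d1, p1)
        reg.save_registry(d2, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_thousand_allocations_pairwise_distinct(self):
        domain = NamingDomain("x")
        proposals = [
            ActionProposal(f"s{i}", f"ACGT{'A' * (i % 7)}CG{'T' * (i // 7)}", "new", [], "allocate_new")
            for i in range(1000)
        ]
        new_domain, report = reg.apply(proposals, domain, seed=0)
        idents = [r.identifier for r in new_domain.records]
        assert len(idents) == 1000
        assert len(set(idents)) == 1000


class TestAllocateIdentifier:
    def test_deterministic_under_seed(self):
        d = NamingDomain("x")
        a = reg.allocate_identifier(d, random.Random(123))
        b = reg.allocate_identifier(d, random.Random(123))
        assert a == b

    def test_single_remaining_identifier_found(self, monkeypatch):
        """When all but one value are issued, the set-difference draw
        must return exactly the hold-out."""
        from germline_kit.nomenclature import IDENTIFIER_SPACE, encode_identifier

        holdout = 29754
        issued = {
            encode_identifier(v) for v in range(IDENTIFIER_SPACE) if v != holdout
        }
        monkeypatch.setattr(NamingDomain, "issued_identifiers", lambda self: issued)
        d = NamingDomain("x")
        assert reg.allocate_identifier(d, random.Random(0)) == encode_identifier(holdout)

    def test_exhausted_domain_is_capacity_error(self, monkeypatch):
        d = NamingDomain("x")
        monkeypatch.setattr(
            NamingDomain,
            "issued_identifiers",
            lambda self: set(range(32**4)),  # identity irrelevant, only size checked
        )
        with pytest.raises(reg.CapacityError):
            reg.allocate_identifier(d, random.Random(0))


class TestCuration:
    @pytest.fixture
    def domain(self):
        return NamingDomain(
            "rhesus-IGH",
            [record("A5B2", "IGHV0-A5B2*00", "ACGTACGTACGTACGT", allocated="2020-01-01")],
        )

    def test_rename_appends_alias(self, domain):
        d = reg.rename(domain, "A5B2", "IGHV2-A5B2*01")
        rec = d.by_identifier("A5B2")
        assert rec.current_label == "IGHV2-A5B2*01"
        assert rec.aliases == ["IGHV0-A5B2*00"]

    def test_rename_collision(self, domain):
        domain.records.append(record("BBBB", "IGHV2-A5B2*01", "TTTT"))
        with pytest.raises(CollisionError, match="A5B2"):
            reg.rename(domain, "A5B2", "IGHV2-A5B2*01")

    def test_alias_traceability_across_renames(self):
        """The multiply-named rhesus allele: registered under one name,
        renamed once, two database synonyms recorded — one record, four
        names, every name resolves to it."""
        d = NamingDomain(
            "rhesus-IGH",
            [record("A5B2", "IGHV2-ABG*01", "ACGTACGTACGTACGT", allocated="2020-01-01")],
        )
        d = reg.rename(d, "A5B2", "IGHV2-118*01")
        d = reg.add_alias(d, "A5B2", "IGHV2-1*01")
        d = reg.add_alias(d, "A5B2", "IGHV2-174*02")
        assert len(d.records) == 1
        rec = d.by_identifier("A5B2")
        names = [rec.current_label, *rec.aliases]
        assert sorted(names) == sorted(
            ["IGHV2-118*01", "IGHV2-ABG*01", "IGHV2-1*01", "IGHV2-174*02"]
        )
        for name in names:
            assert reg.resolve(d, name) is rec
        assert reg.audit(d) == []

    def test_resolve_unknown_label(self, domain):
        with pytest.raises(NotFoundError):
            reg.resolve(domain, "IGHV9-ZZZZ*99")

    def test_resolve_integrity_error_on_double_hit(self, domain):
        domain.records.append(
            record("CCCC", "IGHV0-CCCC*00", "GGGG", aliases=["IGHV0-A5B2*00"])
        )
        with pytest.raises(IntegrityError):
            reg.resolve(domain, "IGHV0-A5B2*00")

    def test_withdrawn_identifier_never_reissued(self):
        domain = NamingDomain("x")
        proposals = [ActionProposal("s0", "ACGTACGT", "new", [], "allocate_new")]
        domain, report = reg.apply(proposals, domain, seed=1)
        withdrawn_id = domain.records[0].identifier
        domain = reg.withdraw(domain, withdrawn_id, "test withdrawal")
        proposals = [
            ActionProposal(f"s{i}", f"A{'C' * (i % 13 + 1)}G{'T' * (i // 13 + 1)}", "new", [], "allocate_new")
            for i in range(1, 1001)
        ]
        domain, _ = reg.apply(proposals, domain, seed=7)
        idents = [r.identifier for r in domain.records]
        assert idents.count(withdrawn_id) == 1  # only the withdrawn record itself
        assert len(set(idents)) == len(idents)


class TestMerge:
    def _domain(self):
        return NamingDomain(
            "m",
            [
                record("AAAA", "IGHV0-AAAA*00", "ACGT", aliases=["IGHV1-X*01"]),
                record("BBBB", "IGHV0-BBBB*00", "TTTT"),
            ],
        )

    def test_self_merge_idempotent(self):
        d = self._domain()
        merged = reg.merge_registries(d, self._domain())
        assert isinstance(merged, NamingDomain)
        assert merged == d

    def test_disjoint_union(self):
        a = self._domain()
        b = NamingDomain("m", [record("CCCC", "IGHV0-CCCC*00", "GGGG")])
        merged = reg.merge_registries(a, b)
        assert {r.identifier for r in merged.records} == {"AAAA", "BBBB", "CCCC"}

    def test_alias_union_preserves_order(self):
        a = self._domain()
        b = self._domain()
        b.records[0].aliases = ["IGHV1-X*01", "IGHV1-Y*02"]
        merged = reg.merge_registries(a, b)
        assert merged.by_identifier("AAAA").aliases == ["IGHV1-X*01", "IGHV1-Y*02"]

    def test_same_identifier_different_sequence_clashes(self):
        a = self._domain()
        b = self._domain()
        b.records[0].sequence = "CCCC"
        report = reg.merge_registries(a, b)
        assert isinstance(report, ClashReport)
        assert len(report.clashes) == 1
        assert report.clashes[0].kind == "identifier"

    def test_same_sequence_different_identifier_clashes(self):
        a = self._domain()
        b = NamingDomain("m", [record("DDDD", "IGHV0-DDDD*00", "ACGT")])
        report = reg.merge_registries(a, b)
        assert isinstance(report, ClashReport)
        assert report.clashes[0].kind == "sequence"

    def test_domain_mismatch(self):
        with pytest.raises(reg.DomainMismatchError):
            reg.merge_registries(NamingDomain("a"), NamingDomain("b"))
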