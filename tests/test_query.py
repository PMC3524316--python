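"""Query engine: evaluation, SQL translation, smart filtering, propagation."""

from random import Random

import pytest

from provdash.fixtures import TABLE_QUERIES, sqlite_path
from provdash.mapping import ColumnMapping, DataSourceConfig
from provdash.ontology import Ontology, RelationAssertion
from provdash.pattern import Condition, QueryPattern, parse_pattern
from provdash.query import (
    TranslationError,
    evaluate,
    execute_translated,
    link_out,
    propagate,
    smart_filter,
    translate,
    validate_pattern,
)

from helpers import candidate_oracle, fold_oracle_ids, random_pattern, scan_count


def _pat(onto, cfg, dsl):
    return validate_pattern(parse_pattern(dsl), onto, cfg)


class TestEvaluate:
    def test_empty_pattern_matches_everything(self, store):
        rs = evaluate(QueryPattern(), store)
        assert rs.total == len(store.experiments)

    def test_single_condition_matches_scan_count(self, onto, cfg, store):
        rs = evaluate(_pat(onto, cfg, TABLE_QUERIES["Q1"]), store)
        assert rs.total == scan_count(store, "Organism", "Homo Sapiens")

    @pytest.mark.parametrize("qname", sorted(TABLE_QUERIES))
    def test_benchmark_patterns_match_fold_oracle(self, onto, cfg, store, qname):
        p = _pat(onto, cfg, TABLE_QUERIES[qname])
        assert evaluate(p, store).match_ids() == fold_oracle_ids(p, store)

    def test_case_spellings_are_equivalent(self, onto, cfg, store):
        upper = _pat(onto, cfg, "Organism='Homo Sapiens'")
        lower = _pat(onto, cfg, "Organism='Homo sapiens'")
        assert evaluate(upper, store).match_ids() == evaluate(lower, store).match_ids()

    def test_grouping_partitions_matches(self, onto, cfg, store):
        rs = evaluate(_pat(onto, cfg, TABLE_QUERIES["Q4"]), store)
        sizes = [len(exps) for _, _, exps in rs.groups]
        assert sum(sizes) == rs.total
        assert all(s > 0 for s in sizes)
        pids = [pid for pid, _, _ in rs.groups]
        assert pids == sorted(pids)

    def test_pending_condition_refused(self, store):
        p = QueryPattern((Condition("Organism", None),), ())
        with pytest.raises(ValueError, match="no value"):
            evaluate(p, store)


class TestTranslate:
    def test_single_condition_single_bound_parameter(self, onto, cfg):
        tq = translate(_pat(onto, cfg, TABLE_QUERIES["Q1"]), cfg)
        assert tq.where == "organism = ? COLLATE NOCASE"
        assert tq.params == ("Homo Sapiens",)
        assert "Homo" not in tq.sql.replace("?", "")  # value never interpolated

    def test_left_fold_parenthesization(self, onto, cfg):
        tq = translate(_pat(onto, cfg, TABLE_QUERIES["Q3"]), cfg)
        assert tq.where == (
            "(((organism = ? COLLATE NOCASE AND cell_line = ? COLLATE NOCASE) "
            "OR perturbation = ? COLLATE NOCASE) OR subcellular_fraction = ? COLLATE NOCASE)"
        )

    @pytest.mark.parametrize("qname", sorted(TABLE_QUERIES))
    def test_sql_execution_equals_in_memory(self, onto, cfg, store, store_dir, qname):
        p = _pat(onto, cfg, TABLE_QUERIES[qname])
        got = execute_translated(translate(p, cfg), sqlite_path(store_dir))
        assert got == evaluate(p, store).match_ids()

    def test_random_patterns_triple_agreement(self, onto, cfg, store, store_dir):
        rng = Random(2024)
        vocab = {c: sorted(store.values_of(c)) for c in store.attribute_classes()}
        for _ in range(60):
            p = validate_pattern(random_pattern(rng, vocab), onto, cfg)
            mem = evaluate(p, store).match_ids()
            assert mem == fold_oracle_ids(p, store)
            assert mem == execute_translated(translate(p, cfg), sqlite_path(store_dir))

    def test_unmapped_class_fails_before_store_access(self, onto, cfg):
        partial = DataSourceConfig(
            name="partial", store_uri="s",
            mappings=tuple(m for m in cfg.mappings if m.class_name != "Organism"),
        )
        with pytest.raises(TranslationError, match="Organism"):
            validate_pattern(parse_pattern(TABLE_QUERIES["Q1"]), onto, partial)
        with pytest.raises(TranslationError, match="Organism"):
            translate(_pat(onto, cfg, TABLE_QUERIES["Q1"]), partial)


class TestSmartFilter:
    def test_empty_pattern_offers_all_store_values(self, store, onto):
        cs = smart_filter(QueryPattern(), None, store, onto)
        for cls, values in cs.per_class.items():
            assert set(values) == store.values_of(cls)

    def test_ephb2_restricts_cell_line_to_hct116(self, store, onto):
        p = parse_pattern("\"Bait gene\"='EPHB2'")
        cs = smart_filter(p, "Cell line", store, onto)
        assert cs.per_class == {"Cell line": ("HCT116",)}

    def test_matches_exhaustive_oracle_for_organism_context(self, store, onto):
        p = parse_pattern("Organism='Homo Sapiens'")
        cs = smart_filter(p, "Cell line", store, onto)
        expected = candidate_oracle(onto, store, [("Organism", "Homo Sapiens")], "Cell line")
        assert set(cs.per_class["Cell line"]) == expected

    def test_every_candidate_yields_results(self, store, onto):
        p = parse_pattern("\"Experiment Type\"='AP-MS' AND Organism='Mus musculus'")
        cs = smart_filter(p, None, store, onto)
        selected = [(c.class_name, c.value) for c in p.conditions]
        for cls, values in cs.per_class.items():
            base = [(c, v) for c, v in selected if c.casefold() != cls.casefold()]
            for v in values:
                conj = QueryPattern(
                    tuple(Condition(c, val) for c, val in base) + (Condition(cls, v),),
                    tuple("AND" for _ in base),
                )
                assert fold_oracle_ids(conj, store), (cls, v)

    def test_editing_class_keeps_current_value_selectable(self, store, onto):
        p = parse_pattern("\"Cell line\"='RKO' AND Organism='Homo Sapiens'")
        cs = smart_filter(p, "Cell line", store, onto)
        assert "RKO" in cs.per_class["Cell line"]

    def test_adding_conjunct_never_enlarges_candidates(self, store, onto):
        rng = Random(7)
        vocab = {c: sorted(store.values_of(c)) for c in store.attribute_classes()}
        for _ in range(20):
            p = random_pattern(rng, vocab, min_len=1, max_len=3)
            conj = QueryPattern(p.conditions, tuple("AND" for _ in p.connectives))
            cls = rng.choice(sorted(vocab))
            extra = Condition(cls, rng.choice(vocab[cls]))
            bigger = QueryPattern(conj.conditions + (extra,), conj.connectives + ("AND",))
            before = smart_filter(conj, None, store, onto).per_class
            after = smart_filter(bigger, None, store, onto).per_class
            for c in after:
                assert set(after[c]) <= set(before[c]), c

    def test_impossible_context_gives_empty_sets(self, store, onto):
        # EPHB2 pull-downs only exist in HCT116, so Embryonic stem + EPHB2 is empty
        p = parse_pattern("\"Cell line\"='Embryonic stem'")
        cs = smart_filter(p, "Bait gene", store, onto)
        assert "EPHB2" not in cs.per_class["Bait gene"]


class TestPropagate:
    def test_ctnnb1_to_ephb2_updates_cell_line(self, onto):
        p = parse_pattern("\"Bait gene\"='CTNNB1' AND \"Cell line\"='RKO'")
        edited = p.replace_value(0, "EPHB2")
        out = propagate(edited, 0, onto)
        assert out.conditions[1].value == "HCT116"

    def test_value_without_relations_changes_nothing(self, onto):
        p = parse_pattern("\"Bait gene\"='CTNNB1' AND \"Cell line\"='RKO'")
        edited = p.replace_value(0, "DNMT1")
        assert propagate(edited, 0, onto) == edited

    def test_already_compatible_value_untouched(self, onto):
        p = parse_pattern("\"Bait gene\"='EPHB2' AND \"Cell line\"='HCT116'")
        assert propagate(p, 0, onto) == p

    def test_multi_compatible_clears_instead_of_guessing(self, onto):
        ephb2 = onto.resolve_instance("Bait gene", "EPHB2")
        rko = onto.resolve_instance("Cell line", "RKO")
        variant = Ontology(
            onto.classes,
            onto.instances,
            onto.relations + (RelationAssertion(ephb2, "hadRole", rko),),
        )
        p = parse_pattern("\"Bait gene\"='CTNNB1' AND \"Cell line\"='Embryonic stem'")
        edited = p.replace_value(0, "EPHB2")
        out = propagate(edited, 0, variant)
        assert out.conditions[1].class_name == "Cell line"  # slot retained
        assert out.conditions[1].value is None


class TestLinkOut:
    def test_url_embeds_project_and_experiment(self, store):
        e = store.experiments[0]
        url = link_out(e, "https://labkey.example")
        assert url == f"https://labkey.example/project/{e.project_id}/experiment/{e.experiment_id}"

    def test_empty_base_gives_relative_path(self, store):
        e = store.experiments[0]
        assert link_out(e, "").startswith("/project/")

    def test_deterministic(self, store):
        e = store.experiments[5]
        assert link_out(e, "https://x") == link_out(e, "https://x")
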