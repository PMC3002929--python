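"""Mutation-string grammar, complex/hotspot classification and exact tests."""

import math

import numpy as np
import pytest

from cghcompare import tp53
from cghcompare.tp53 import (
    HOTSPOTS,
    MutationKind,
    classify,
    compare_groups,
    fisher_exact_two_tailed,
    group_summary,
    parse_mutation,
)


@pytest.mark.parametrize(
    "raw, kind, codon",
    [
        ("R213X", MutationKind.NONSENSE, 213),
        ("G266E", MutationKind.MISSENSE, 266),
        ("V216 M", MutationKind.MISSENSE, 216),
        ("239 insT", MutationKind.FRAMESHIFT_INS, 239),
        ("283insGC", MutationKind.FRAMESHIFT_INS, 283),
        ("183_184insC", MutationKind.FRAMESHIFT_INS, 183),
        ("110 delC", MutationKind.FRAMESHIFT_DEL, 110),
        ("205delT", MutationKind.FRAMESHIFT_DEL, 205),
        ("239_240delCA", MutationKind.FRAMESHIFT_DEL, 239),
        ("218delGTG", MutationKind.INFRAME_DEL, 218),
        ("255_256delTCA", MutationKind.INFRAME_DEL, 255),
        ("del 255", MutationKind.INFRAME_DEL, 255),
        ("del 155-156", MutationKind.INFRAME_DEL, 155),
        ("155_156del", MutationKind.INFRAME_DEL, 155),
        ("IVS5-2 A > C (splice)", MutationKind.SPLICE, None),
        ("224 splice G > A", MutationKind.SPLICE, None),
        ("wild type", MutationKind.WILD_TYPE, None),
        ("NA", MutationKind.NOT_SEQUENCED, None),
    ],
)
def test_parse_single_tokens(raw, kind, codon):
    (rec,) = parse_mutation(raw)
    assert rec.kind is kind
    assert rec.codon == codon


def test_parse_comma_list_yields_multiple_records():
    recs = parse_mutation("R248W, R280K, V218I")
    assert [r.kind for r in recs] == [MutationKind.MISSENSE] * 3
    assert [r.codon for r in recs] == [248, 280, 218]


@pytest.mark.parametrize("raw", ["?", "delta", "R213", "213RX", "ins", "12del"])
def test_unparseable_token_raises_with_token(raw):
    with pytest.raises(ValueError, match="unparseable"):
        parse_mutation(raw)


def test_empty_string_rejected():
    with pytest.raises(ValueError):
        parse_mutation("  ")


def test_parse_format_parse_is_stable():
    for raw in ["R213X, H214Y", "del 155-156", "IVS5-2 A > C (splice)", "239 insT"]:
        recs = parse_mutation(raw)
        for rec in recs:
            (again,) = parse_mutation(rec.format())
            assert again.kind is rec.kind and again.codon == rec.codon


@pytest.mark.parametrize(
    "raw, is_complex, is_hotspot",
    [
        ("R248W", False, True),
        ("K305X", True, False),
        ("T55I", False, False),
        ("Y220C", False, True),
        ("155_156del", True, False),
        ("wild type", False, False),
    ],
)
def test_classify_flags(raw, is_complex, is_hotspot):
    (rec,) = parse_mutation(raw)
    flags = classify(rec)
    assert flags["is_complex"] is is_complex
    assert flags["is_hotspot"] is is_hotspot


def test_hotspot_list_has_29_codons():
    assert len(HOTSPOTS) == 29
    assert ("R", 175) in HOTSPOTS and ("E", 285) in HOTSPOTS


# --- packaged fixture -------------------------------------------------------


@pytest.fixture(scope="module")
def fixture_records():
    return tp53.load_table1_records()


def test_fixture_parses_completely(fixture_records):
    assert len(fixture_records) > 100
    assert {r.group for r in fixture_records} == {
        "BRCA1", "BLBC", "luminal-H", "luminal-J"
    }


def test_fixture_complex_flags_reproduced(fixture_records):
    """The classifier must agree with the printed per-sample complex flag."""
    table = tp53.load_table1()
    printed = {
        (r["sample_id"], r["group"]): r["complex_flag"]
        for _, r in table.iterrows()
        if r["complex_flag"] in ("0", "1")
    }
    computed: dict = {}
    for rec in fixture_records:
        key = (rec.sample_id, rec.group)
        if rec.kind is MutationKind.NOT_SEQUENCED:
            continue
        computed[key] = computed.get(key, False) or classify(rec)["is_complex"]
    assert set(printed) == set(computed)
    for key, flag in printed.items():
        assert computed[key] == (flag == "1"), f"mismatch for sample {key}"


@pytest.mark.parametrize(
    "group, n_sequenced, n_mutated, n_complex",
    [
        ("BLBC", 21, 20, 12),
        ("BRCA1", 21, 19, 11),
        ("luminal-H", 31, 8, 2),
        ("luminal-J", 13, 6, 1),
    ],
)
def test_fixture_group_counts(fixture_records, group, n_sequenced, n_mutated, n_complex):
    s = group_summary(fixture_records, group)
    assert (s.n_sequenced, s.n_mutated, s.n_complex) == (
        n_sequenced, n_mutated, n_complex
    )


def test_group_summary_counts_tumors_not_mutations():
    recs = []
    for raw in ("R213X", "110 delC", "K305X"):
        recs.extend(parse_mutation(raw, sample_id="s1", group="G"))
    s = group_summary(recs, "G")
    assert (s.n_sequenced, s.n_mutated, s.n_complex) == (1, 1, 1)


def test_group_summary_all_wildtype():
    recs = [parse_mutation("wild type", sample_id=f"s{i}", group="G")[0] for i in range(4)]
    s = group_summary(recs, "G")
    assert (s.n_sequenced, s.n_mutated, s.n_complex, s.n_hotspot) == (4, 0, 0, 0)


def test_group_summary_abundance_filter():
    low = parse_mutation("R175H", sample_id="s1", group="G", abundance_fraction=0.1)[0]
    high = parse_mutation("R175H", sample_id="s2", group="G", abundance_fraction=0.6)[0]
    s = group_summary([low, high], "G")
    assert s.n_mutated == 1 and s.n_sequenced == 2


def test_group_summary_unknown_group(fixture_records):
    with pytest.raises(ValueError, match="unknown group"):
        group_summary(fixture_records, "no-such-group")


# --- Fisher exact test ------------------------------------------------------


def fisher_enumeration(table):
    """Independent oracle: full hypergeometric enumeration over fixed margins."""
    (a, b), (c, d) = table
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def prob(x):
        return math.comb(r1, x) * math.comb(r2, c1 - x) / math.comb(n, c1)

    p_obs = prob(a)
    return sum(
        prob(x)
        for x in range(max(0, c1 - r2), min(r1, c1) + 1)
        if prob(x) <= p_obs * (1 + 1e-12)
    )


def test_fisher_balanced_table_is_one():
    assert fisher_exact_two_tailed([[5, 5], [5, 5]]) == pytest.approx(1.0)


def test_fisher_zero_margin_is_one():
    assert fisher_exact_two_tailed([[0, 0], [3, 4]]) == 1.0


def test_fisher_matches_enumeration_oracle():
    rng = np.random.default_rng(42)
    tables = [[[20, 1], [8, 23]], [[11, 10], [1, 12]], [[12, 9], [2, 29]]]
    while len(tables) < 40:
        t = rng.integers(0, 9, size=(2, 2))
        if t.sum() <= 30 and t.sum(axis=0).all() and t.sum(axis=1).all():
            tables.append(t.tolist())
    for t in tables:
        assert fisher_exact_two_tailed(t) == pytest.approx(
            fisher_enumeration(t), abs=1e-12
        )


def test_fisher_invariance_to_transpose_and_swap():
    t = [[12, 9], [2, 29]]
    p = fisher_exact_two_tailed(t)
    assert fisher_exact_two_tailed([[12, 2], [9, 29]]) == pytest.approx(p, abs=1e-12)
    assert fisher_exact_two_tailed([[29, 2], [9, 12]]) == pytest.approx(p, abs=1e-12)


def test_compare_groups_feature_tables(fixture_records):
    blbc = group_summary(fixture_records, "BLBC")
    lumh = group_summary(fixture_records, "luminal-H")
    table, p = compare_groups(blbc, lumh, "complex")
    assert table == [[12, 9], [2, 29]]
    assert f"{p:.0e}" == "8e-05"


def test_compare_group_with_itself(fixture_records):
    s = group_summary(fixture_records, "BRCA1")
    _, p = compare_groups(s, s, "mutated")
    assert p == pytest.approx(1.0)


def test_hotspot_contrast_not_significant(fixture_records):
    brca = group_summary(fixture_records, "BRCA1")
    lumj = group_summary(fixture_records, "luminal-J")
    _, p = compare_groups(brca, lumj, "hotspot")
    assert p > 0.01


def test_compare_groups_unknown_feature(fixture_records):
    s = group_summary(fixture_records, "BRCA1")
    with pytest.raises(ValueError, match="unknown feature"):
        compare_groups(s, s, "frameshiftiness")
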