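"""Subsite rules, limit digestion, and the shipped enzyme rule sets."""

import json
from collections import Counter

import pytest
from hypothesis import given
from hypothesis import strategies as st

from mlgkit.digestion_sim import (
    EnzymeRuleSet,
    RULE_SETS,
    cleavable_bonds,
    digest_population,
    digest_table,
    limit_digest,
    limit_digest_ordered,
    load_rule_set,
    number_average_dp,
    redigest,
)
from mlgkit.glucan_core import GlucanChain, Linkage, parse_chain


def products(result):
    return Counter({str(c): k for c, k in result.products.items()})


# --- cleavable_bonds -------------------------------------------------------

def test_gh16_marks_both_cellobiosyl_flanking_bonds(c5b, gh16):
    assert cleavable_bonds(c5b, gh16) == {2, 4}


@pytest.mark.parametrize(
    "notation, rules_name",
    [
        ("G3G4G4G", "GH16_trichoderma"),   # the cellotetraosyl-unit DP-4 product
        ("G3G4G", "GH16_trichoderma"),     # below the minimum substrate
        ("G4G4G4G4G", "GH17_barley"),      # 1,4-glucan is no substrate for a 1,3-glucanase
        ("G4G4G4G4G", "GH16_trichoderma"),
        ("G3G4G3G4G", "GH12_aniger"),      # the minor-structure product resists re-digestion
    ],
)
def test_resistant_substrates_have_no_cleavable_bonds(notation, rules_name):
    assert cleavable_bonds(parse_chain(notation), RULE_SETS[rules_name]) == set()


# --- limit digestion -------------------------------------------------------

def test_gh16_converts_c5b_to_two_laminaribiose_and_glucose(c5b, gh16):
    result = limit_digest(c5b, gh16)
    assert products(result) == Counter({"G3G": 2, "G": 1})
    assert result.cleavage_events == 2


def test_gh16_smallest_substrate_yields_two_laminaribiose(gh16):
    assert products(limit_digest(parse_chain("G3G4G3G"), gh16)) == Counter({"G3G": 2})


def test_gh16_leaves_dp3_untouched(gh16):
    assert products(limit_digest(parse_chain("G3G4G"), gh16)) == Counter({"G3G4G": 1})


def test_gh12_excises_unit_products_from_canonical_chain(gh12):
    # tri-tri-tetra-tri interior: every interior product is a unit fragment
    chain = parse_chain("G4G4G3G4G4G3G4G4G4G3G4G4G")
    ordered = limit_digest_ordered(chain, gh12)
    interior = [str(c) for c in ordered[1:-1]]
    assert set(interior) <= {"G3G4G", "G3G4G4G"}
    assert len(interior) == 2


def test_gh12_leaves_cellobiosyl_pentasaccharide_intact_in_context(gh12):
    # cellotriosyl-cellobiosyl-cellotriosyl-cellotriosyl
    chain = parse_chain("G4G4G3G4G3G4G4G3G4G4G")
    result = limit_digest(chain, gh12)
    dp5 = [c for c in result.products if c.dp == 5]
    assert [str(c) for c in dp5] == ["G3G4G3G4G"]
    two_l3 = [
        c for c in result.products
        if sum(1 for l in c.linkages if l == Linkage.L3) == 2
    ]
    assert [c.dp for c in two_l3] == [5]


def test_sequential_mode_explores_both_documented_routes(c5b, gh16):
    """One-bond-at-a-time digestion is route-dependent on the cellobiosyl
    pentasaccharide: cutting the reducing-side bond first releases glucose
    and leaves G3G4G3G (then two laminaribiose); cutting the interior bond
    first strands a resistant G3G4G.  Both end states conserve mass; the
    default simultaneous mode always reaches the complete digestion."""
    routes = set()
    for seed in range(20):
        seq = limit_digest(c5b, gh16, sequential=True, seed=seed)
        assert seq.total_residues == c5b.n_residues
        routes.add(frozenset(products(seq).items()))
    assert routes == {
        frozenset({("G3G", 2), ("G", 1)}),
        frozenset({("G3G", 1), ("G3G4G", 1)}),
    }


def test_lichenase_classical_products():
    chain = parse_chain("G4G4G3G4G4G4G3G4G4G")  # tri + tetra + tri units
    assert products(limit_digest(chain, RULE_SETS["GH_lichenase"])) == Counter(
        {"G4G4G3G": 2, "G4G": 1}
    )


# --- populations and summary statistics ------------------------------------

def test_population_of_laminaribiose_is_inert(gh16):
    pop = [parse_chain("G3G")] * 5
    result = digest_population(pop, gh16)
    assert result.dp_mass_fraction == {2: 1.0}
    assert result.cleavage_events == 0


def test_double_digestion_is_identity(gh16):
    pop = [parse_chain("G3G4G3G4G"), parse_chain("G3G4G4G")]
    once = digest_population(pop, gh16)
    twice = redigest(once, gh16)
    assert once.products == twice.products
    assert twice.cleavage_events == once.cleavage_events


def test_empty_population_rejected(gh16):
    with pytest.raises(ValueError):
        digest_population([], gh16)


def test_number_average_dp(c5b, gh16):
    result = limit_digest(c5b, gh16)
    assert number_average_dp(result) == pytest.approx(5 / 3)
    intact = limit_digest(GlucanChain((Linkage.L4,) * 99), RULE_SETS["GH17_barley"])
    assert number_average_dp(intact) == 100


def test_gh16_reduces_average_size_where_gh17_cannot(gh16, gh17):
    from mlgkit.synthetic_data import MLGParams, generate_mlg

    pop = generate_mlg(MLGParams(seed=5, units_per_chain=200), 10)
    ndp16 = digest_population(pop, gh16).number_average_dp
    ndp17 = digest_population(pop, gh17).number_average_dp
    assert ndp17 == pytest.approx(sum(c.dp for c in pop) / len(pop))
    assert ndp16 < ndp17


# --- properties -------------------------------------------------------------

chains_st = st.lists(
    st.sampled_from([Linkage.L3, Linkage.L4]), min_size=0, max_size=30
).map(lambda ls: GlucanChain(tuple(ls)))

rules_st = st.one_of(
    st.sampled_from(sorted(RULE_SETS)).map(RULE_SETS.__getitem__),
    st.builds(
        EnzymeRuleSet,
        name=st.just("random"),
        cleavable_linkages=st.sets(
            st.sampled_from(["L3", "L4"]), min_size=1, max_size=2
        ).map(frozenset),
        required_linkage_minus2_minus1=st.sampled_from(
            ["L3", "L4", "any", "must_be_chain_end"]
        ),
        required_occupancy_minus2=st.booleans(),
        required_linkage_plus1_plus2=st.sampled_from(["L3", "L4", "any"]),
        plus2_may_be_empty=st.booleans(),
        min_substrate_dp=st.integers(2, 6),
    ),
)


@given(chains_st, rules_st)
def test_mass_conservation_and_idempotence(chain, rules):
    result = limit_digest(chain, rules)
    assert result.total_residues == chain.n_residues
    assert result.n_products - 1 == result.cleavage_events
    assert sum(result.dp_mass_fraction.values()) == pytest.approx(1.0, abs=1e-9)
    again = redigest(result, rules)
    assert again.products == result.products


@given(chains_st)
def test_relaxing_constraints_never_shrinks_cleavable_set(chain):
    base = RULE_SETS["GH16_trichoderma"]
    relaxations = [
        {"required_linkage_minus2_minus1": "any", "required_occupancy_minus2": False},
        {"required_linkage_plus1_plus2": "any"},
        {"plus2_may_be_empty": True},
        {"min_substrate_dp": 2},
        {"cleavable_linkages": frozenset({"L3", "L4"})},
    ]
    bonds = cleavable_bonds(chain, base)
    for update in relaxations:
        relaxed = base.model_copy(update={"name": "relaxed", **update})
        assert bonds <= cleavable_bonds(chain, relaxed)


# --- concordance of the shipped rule sets ----------------------------------

def test_shipped_rule_sets_reproduce_all_observations(gh12, gh16, gh17):
    # limit products of the 1,4-glucanase resist re-digestion by it
    for s in ("G3G4G", "G3G4G4G", "G3G4G3G4G"):
        assert cleavable_bonds(parse_chain(s), gh12) == set()
    # the 1,3(4)-glucanase degrades all-1,3 chains, not all-1,4 chains
    assert limit_digest(parse_chain("G3G3G3G3G"), gh16).cleavage_events > 0
    assert limit_digest(parse_chain("G4G4G4G4G4G4G"), gh16).cleavage_events == 0
    # the 1,3-glucanase needs two consecutive 1,3 bonds
    assert limit_digest(parse_chain("G3G3G3G"), gh17).cleavage_events > 0
    for s in ("G3G4G", "G3G4G4G", "G3G4G3G4G", "G4G3G"):
        assert cleavable_bonds(parse_chain(s), gh17) == set()


# --- serialization ----------------------------------------------------------

def test_rule_set_json_round_trip(gh16):
    assert EnzymeRuleSet.from_json(gh16.to_json()) == gh16


def test_packaged_rule_files_match_builtins():
    for name, builtin in RULE_SETS.items():
        assert load_rule_set(name.lower()) == builtin


def test_rule_set_validation():
    with pytest.raises(ValueError):
        EnzymeRuleSet(name="bad", cleavable_linkages=frozenset())
    with pytest.raises(ValueError):
        EnzymeRuleSet(name="bad", cleavable_linkages=frozenset({"L3"}), min_substrate_dp=1)
    with pytest.raises(KeyError):
        load_rule_set("no_such_enzyme")


def test_digest_table_mass_fractions(c5b, gh16):
    frame = digest_table(limit_digest(c5b, gh16))
    assert frame["mass_fraction"].sum() == pytest.approx(1.0)
    assert set(frame["product"]) == {"G3G", "G"}
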