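from decimal import Decimal

import numpy as np
import pandas as pd
import pytest
from scipy.special import ndtr

from siidanet.kinship import RelatednessMatrix, build_relatedness_matrix, parse_kin_path
from siidanet.networks import edge_reciprocity, siida_assortment
from siidanet.synthetic import (
    CommunityConfig,
    GiftGameParams,
    SRMGenerativeParams,
    _split_cents,
    generate_community,
    generate_kin_paths,
    generate_roster,
    simulate_gift_game,
    simulate_tie_layers,
)


def identity_relatedness(roster):
    return RelatednessMatrix(ids=roster.ids, values=np.eye(len(roster)))


# ---------------------------------------------------------------------------
# roster


def test_roster_conserves_count_and_interviews_all():
    cfg = CommunityConfig(n_individuals=10, n_siidas=2, interviewed_fraction=1.0, random_seed=1)
    roster = generate_roster(cfg)
    assert len(roster) == 10
    assert roster.table["interviewed"].sum() == 10
    assert roster.table.groupby("siida").size().sum() == 10
    assert set(roster.licensed_ids) >= set(roster.interviewed_ids)


def test_roster_deterministic_under_seed():
    cfg = CommunityConfig(n_individuals=10, n_siidas=2, interviewed_fraction=1.0, random_seed=1)
    pd.testing.assert_frame_equal(generate_roster(cfg).table, generate_roster(cfg).table)


def test_every_siida_nonempty():
    cfg = CommunityConfig(n_individuals=60, n_siidas=4, random_seed=7)
    roster = generate_roster(cfg)
    assert roster.table["siida"].nunique() == 4
    assert (roster.table.groupby("siida").size() >= 1).all()


def test_interviewed_count_is_ceiling():
    cfg = CommunityConfig(n_individuals=9, n_siidas=2, interviewed_fraction=0.5, random_seed=3)
    assert generate_roster(cfg).table["interviewed"].sum() == 5  # ceil(4.5)


def test_more_siidas_than_people_rejected():
    with pytest.raises(ValueError):
        CommunityConfig(n_individuals=3, n_siidas=5)


# ---------------------------------------------------------------------------
# kin paths


def test_kin_paths_have_expected_grammar(community):
    kin = community.kin_table
    assert set("".join(kin["path"])) <= set("MFBZSD")
    # sibling pairs are symmetric with gendered letters
    by_pair = {(r.ego, r.alter): r.path for r in kin.itertuples(index=False)}
    for (e, a), path in by_pair.items():
        assert (a, e) in by_pair, "every related pair is reported in both directions"
        assert len(by_pair[(a, e)]) == len(path), "link counts agree in both directions"


def test_sibling_parent_and_cousin_paths_present(community):
    paths = set(community.kin_table["path"])
    assert paths & {"B", "Z"}, "sibling paths present"
    assert paths & {"S", "D"}, "parent-to-child paths present"
    assert paths & {"F", "M"}, "child-to-parent paths present"
    cousin = {p for p in paths if len(p) == 3}
    assert cousin <= {a + b + c for a in "FM" for b in "BZ" for c in "SD"}


def test_cousin_paths_appear_when_families_linked():
    # large community with many families: cousin links occur with the
    # default linking probabilities
    cfg = CommunityConfig(n_individuals=80, n_siidas=4, random_seed=5)
    kin = generate_kin_paths(generate_roster(cfg), cfg)
    assert any(len(p) == 3 for p in kin["path"]), "expected at least one cousin pair"


def test_generated_relatedness_matches_link_counts(community):
    mat = build_relatedness_matrix(community.roster, community.kin_table)
    for row in community.kin_table.head(25).itertuples(index=False):
        k = parse_kin_path(row.path)
        assert mat.get(row.ego, row.alter) == 0.5**k


# ---------------------------------------------------------------------------
# tie layers


def test_null_model_density_half():
    cfg = CommunityConfig(n_individuals=60, n_siidas=2, interviewed_fraction=1.0, random_seed=2)
    roster = generate_roster(cfg)
    params = SRMGenerativeParams(
        intercept=0.0, beta_relatedness=0.0, beta_same_siida=0.0,
        beta_interviewed=0.0, sd_giver=0.0, sd_receiver=0.0,
        cor_giver_receiver=0.0, cor_dyadic=0.0,
    )
    layers = simulate_tie_layers(roster, identity_relatedness(roster), params, seed=8)
    m = 60 * 59
    for net in layers:
        se = np.sqrt(0.25 / m)
        assert abs(net.n_edges / m - 0.5) < 3 * se


def test_very_negative_intercept_gives_empty_networks():
    cfg = CommunityConfig(n_individuals=20, n_siidas=2, interviewed_fraction=1.0, random_seed=2)
    roster = generate_roster(cfg)
    params = SRMGenerativeParams(intercept=-40.0, beta_relatedness=0, beta_same_siida=0,
                                 beta_interviewed=0, sd_giver=0, sd_receiver=0,
                                 cor_giver_receiver=0, cor_dyadic=0)
    for net in simulate_tie_layers(roster, identity_relatedness(roster), params, seed=1):
        assert net.n_edges == 0


def test_probit_calibration_with_effects_off():
    """With sds = 0 the empirical within/between-siida frequencies match the
    closed-form probit probabilities within binomial error."""
    cfg = CommunityConfig(n_individuals=60, n_siidas=2, interviewed_fraction=1.0,
                          siida_concentration=50.0, random_seed=4)
    roster = generate_roster(cfg)
    params = SRMGenerativeParams(intercept=-1.0, beta_relatedness=0.0, beta_same_siida=1.5,
                                 beta_interviewed=0.0, sd_giver=0.0, sd_receiver=0.0,
                                 cor_giver_receiver=0.0, cor_dyadic=0.0)
    nets = simulate_tie_layers(roster, identity_relatedness(roster), params, seed=11,
                               layer_names=tuple(f"l{k}" for k in range(4)))
    siida = roster.siida_of()
    n_within = n_between = e_within = e_between = 0
    for net in nets:
        for i in roster.ids:
            for j in roster.ids:
                if i == j:
                    continue
                if siida[i] == siida[j]:
                    n_within += 1
                    e_within += net.has_edge(i, j)
                else:
                    n_between += 1
                    e_between += net.has_edge(i, j)
    p_w, p_b = ndtr(0.5), ndtr(-1.0)
    assert abs(e_within / n_within - p_w) < 3 * np.sqrt(p_w * (1 - p_w) / n_within)
    assert abs(e_between / n_between - p_b) < 3 * np.sqrt(p_b * (1 - p_b) / n_between)


def test_no_self_ties_ever(community):
    for net in community.layers:
        assert all(i != j for i, j in net.edges)


def test_invalid_covariance_names_parameter():
    cfg = CommunityConfig(n_individuals=6, n_siidas=2, random_seed=0)
    roster = generate_roster(cfg)
    bad = SRMGenerativeParams(sd_giver=-0.5)
    with pytest.raises(ValueError, match="sd_giver"):
        simulate_tie_layers(roster, identity_relatedness(roster), bad, seed=0)
    bad2 = SRMGenerativeParams(cor_dyadic=1.5)
    with pytest.raises(ValueError, match="cor_dyadic"):
        simulate_tie_layers(roster, identity_relatedness(roster), bad2, seed=0)


# ---------------------------------------------------------------------------
# gift game


def test_forced_single_recipient_gets_full_endowment(community):
    params = GiftGameParams(recipient_count_lambda=0.0)
    ledger = simulate_gift_game(
        community.roster, community.cooperation, community.relatedness, params, seed=3
    )
    gifts_per_giver = {}
    for rec in ledger.records:
        gifts_per_giver.setdefault(rec.giver, []).append(rec.litres)
    for giver, amounts in gifts_per_giver.items():
        assert amounts == [Decimal("35")]


def test_equal_split_of_35_among_4_is_875_each():
    assert _split_cents(3500, 4) == [875, 875, 875, 875]
    # Decimal conversion: 875 cents of a litre = 8.75 l
    assert Decimal(875) / Decimal(100) == Decimal("8.75")


def test_split_cents_always_conserves_total():
    for k in range(1, 12):
        cents = _split_cents(3500, k)
        assert sum(cents) == 3500
        assert max(cents) - min(cents) <= 1


def test_per_giver_totals_exactly_35(community):
    for giver, total in community.gift_ledger.totals_given().items():
        assert total == Decimal("35")


def test_dirichlet_split_also_conserves(community):
    params = GiftGameParams(split="dirichlet")
    ledger = simulate_gift_game(
        community.roster, community.cooperation, community.relatedness, params, seed=5
    )
    for total in ledger.totals_given().values():
        assert total == Decimal("35")
    assert all(rec.litres > 0 for rec in ledger.records)


def test_no_eligible_recipient_is_an_error():
    from siidanet.io import Roster

    roster = Roster(
        pd.DataFrame(
            {
                "id": ["a", "b"],
                "siida": ["s", "s"],
                "interviewed": [1, 0],
                "licence": [1, 0],
            }
        )
    )
    rel = RelatednessMatrix(ids=["a", "b"], values=np.eye(2))
    from siidanet.networks import DirectedBinaryNetwork

    coop = DirectedBinaryNetwork(nodes=frozenset(["a", "b"]), edges=frozenset())
    with pytest.raises(ValueError, match="eligible"):
        simulate_gift_game(roster, coop, rel, GiftGameParams(), seed=1)


# ---------------------------------------------------------------------------
# whole-dataset properties


def test_identical_seed_reproduces_dataset():
    a = generate_community(CommunityConfig(random_seed=99))
    b = generate_community(CommunityConfig(random_seed=99))
    pd.testing.assert_frame_equal(a.roster.table, b.roster.table)
    pd.testing.assert_frame_equal(a.kin_table, b.kin_table)
    pd.testing.assert_frame_equal(a.edge_table, b.edge_table)
    assert a.gift_ledger.to_frame().equals(b.gift_ledger.to_frame())


def test_total_litres_is_35_per_player(community):
    n_players = len(community.roster.interviewed_ids)
    total = sum((r.litres for r in community.gift_ledger.records), Decimal(0))
    assert total == Decimal(35) * n_players


def test_default_community_emulates_study_structure(community):
    """The frozen generator defaults should land near the study's
    qualitative network statistics."""
    recs = [edge_reciprocity(net) for net in community.layers]
    asss = [siida_assortment(net, community.roster) for net in community.layers]
    assert 0.15 <= np.mean(recs) <= 0.45
    assert 0.7 <= np.mean(asss) <= 0.95
    assert len(community.roster.interviewed_ids) == 30


def test_dataset_write_round_trips(tmp_path, community):
    from siidanet.io import read_edges, read_gifts, read_kin, read_roster

    paths = community.write(tmp_path / "data")
    roster = read_roster(paths["roster"])
    pd.testing.assert_frame_equal(roster.table, community.roster.table)
    kin = read_kin(paths["kin"])
    pd.testing.assert_frame_equal(kin, community.kin_table)
    edges = read_edges(paths["edges"], roster=roster)
    pd.testing.assert_frame_equal(edges, community.edge_table)
    ledger = read_gifts(paths["gifts"])
    assert ledger.totals_given() == community.gift_ledger.totals_given()
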