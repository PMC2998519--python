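"""Network construction, editing, filtering, endpoints, neighbourhoods,
distance matrices and membership queries."""

import random

import pytest

from pathnet import (
    FixtureParams,
    Network,
    NotFoundError,
    UsageError,
    endpoints,
    entities_in_min_pathways,
    filter_interactions,
    generate_repository,
    load_repository,
    neighborhood,
    network_edit,
    network_from_pathways,
    shared_gene_matrix,
)

import oracles


class TestNetworkFromPathways:
    def test_single_pathway_identity(self, rand_repo):
        net = network_from_pathways(rand_repo, ["pw0000"])
        assert net.interactions == set(rand_repo.pathway_interaction_ids("pw0000"))

    def test_union_matches_set_oracle(self, rand_repo, rand_doc):
        by_id = {p["id"]: set(p["interactions"]) for p in rand_doc["pathways"]}
        ids = sorted(by_id)[:6]
        net = network_from_pathways(rand_repo, ids)
        expected = set().union(*(by_id[i] for i in ids))
        assert net.interactions == expected

    def test_disjoint_pathways_sum(self, hormone_repo):
        a = len(network_from_pathways(hormone_repo, ["pw_bs_bio"]))
        b = len(network_from_pathways(hormone_repo, ["pw_ax_bio"]))
        both = network_from_pathways(hormone_repo, ["pw_bs_bio", "pw_ax_bio"])
        assert len(both) == a + b

    def test_unknown_pathway_raises(self, rand_repo):
        with pytest.raises(NotFoundError):
            network_from_pathways(rand_repo, ["nope"])


class TestNetworkEdit:
    def test_add_then_remove_restores(self, rand_repo, rand_doc):
        net = network_from_pathways(rand_repo, ["pw0000"])
        extra = next(
            i["id"] for i in rand_doc["interactions"]
            if i["id"] not in net.interactions
        )
        edited = network_edit(rand_repo, net, add=[extra])
        restored = network_edit(rand_repo, edited, remove=[extra])
        assert restored.interactions == net.interactions

    def test_duplicate_add_is_noop(self, rand_repo):
        net = network_from_pathways(rand_repo, ["pw0000"])
        some = next(iter(net.interactions))
        assert network_edit(rand_repo, net, add=[some]).interactions == net.interactions

    def test_removing_absent_id_is_noop(self, rand_repo):
        net = network_from_pathways(rand_repo, ["pw0000"])
        assert network_edit(rand_repo, net, remove=["ghost"]).interactions == net.interactions

    def test_unresolvable_add_raises(self, rand_repo):
        net = network_from_pathways(rand_repo, ["pw0000"])
        with pytest.raises(NotFoundError):
            network_edit(rand_repo, net, add=["ghost"])

    def test_random_edit_script_matches_replay(self, rand_repo, rand_doc):
        """A long random add/remove script agrees with naive set replay."""
        rng = random.Random(42)
        all_ids = [i["id"] for i in rand_doc["interactions"]]
        net = Network("scripted", set())
        reference: set[str] = set()
        for _ in range(200):
            batch_add = rng.sample(all_ids, rng.randint(0, 4))
            batch_remove = rng.sample(all_ids, rng.randint(0, 4))
            net = network_edit(rand_repo, net, add=batch_add, remove=batch_remove)
            reference = (reference | set(batch_add)) - set(batch_remove)
            assert net.interactions == reference


class TestFilterInteractions:
    def test_drop_clutter_leaves_core(self, clutter_repo):
        """Removing transcription/translation exposes the 5-step
        metabolic core."""
        net = network_from_pathways(clutter_repo, ["pw0"])
        core = filter_interactions(
            clutter_repo, net, drop_types=["transcription", "translation"]
        )
        assert len(core) == 5
        assert all(
            clutter_repo.interaction(i).interaction_type == "it_enzymatic_reaction"
            for i in core.interactions
        )

    def test_regulatory_only_without_regulation_is_empty(self, clutter_repo):
        net = network_from_pathways(clutter_repo, ["pw0"])
        assert len(filter_interactions(clutter_repo, net, regulatory_only=True)) == 0

    def test_regulatory_only_keeps_only_regulatory(self, rand_repo):
        net = Network("all", set(i.id for i in rand_repo.interactions()))
        reg = filter_interactions(rand_repo, net, regulatory_only=True)
        for iid in net.interactions:
            it = rand_repo.interaction(iid)
            flagged = rand_repo.interaction_type(it.interaction_type).is_regulatory
            assert (iid in reg.interactions) == flagged

    def test_idempotence(self, rand_repo):
        net = Network("all", set(i.id for i in rand_repo.interactions()))
        once = filter_interactions(rand_repo, net, keep_types=["transport"])
        twice = filter_interactions(rand_repo, once, keep_types=["transport"])
        assert once.interactions == twice.interactions

    def test_keep_and_drop_complement_agree(self, rand_repo):
        net = Network("all", set(i.id for i in rand_repo.interactions()))
        all_labels = {
            "enzymatic_reaction", "transport", "transcription",
            "translation", "activation", "inhibition",
        }
        keep = {"transport", "transcription"}
        kept = filter_interactions(rand_repo, net, keep_types=sorted(keep))
        dropped = filter_interactions(rand_repo, net, drop_types=sorted(all_labels - keep))
        assert kept.interactions == dropped.interactions

    def test_exactly_one_criterion_required(self, rand_repo):
        net = network_from_pathways(rand_repo, ["pw0000"])
        with pytest.raises(UsageError):
            filter_interactions(rand_repo, net)
        with pytest.raises(UsageError):
            filter_interactions(rand_repo, net, keep_types=["transport"],
                                regulatory_only=True)

    def test_unknown_type_label_raises(self, rand_repo):
        net = network_from_pathways(rand_repo, ["pw0000"])
        with pytest.raises(UsageError):
            filter_interactions(rand_repo, net, keep_types=["teleportation"])

    def test_input_network_unmodified(self, rand_repo):
        net = network_from_pathways(rand_repo, ["pw0000"])
        before = set(net.interactions)
        filter_interactions(rand_repo, net, keep_types=["transport"])
        assert net.interactions == before


class TestEndpoints:
    def test_chain_has_first_and_last(self, chain_repo):
        ep = endpoints(chain_repo, "pw0")
        assert ep.sources == {"m_A"}
        assert ep.sinks == {"m_C"}

    def test_cycle_has_none(self, cycle_repo):
        ep = endpoints(cycle_repo, "pw0")
        assert ep.sources == frozenset() and ep.sinks == frozenset()

    def test_sources_sinks_disjoint(self, rand_repo, rand_doc):
        for pw in rand_doc["pathways"]:
            ep = endpoints(rand_repo, pw["id"])
            assert not (ep.sources & ep.sinks)

    def test_matches_tally_oracle_over_seeds(self):
        for seed in range(10):
            doc = generate_repository(FixtureParams(seed=seed, n_pathways=8))
            repo = load_repository(doc)
            for pw in doc["pathways"]:
                ep = endpoints(repo, pw["id"])
                src, snk = oracles.endpoints_tally(doc, pw["interactions"])
                assert (set(ep.sources), set(ep.sinks)) == (src, snk)

    def test_modifier_only_entities_excluded(self, rand_repo, rand_doc):
        """Pure catalysts/regulators are not mass-flow endpoints."""
        net = Network("all", {i["id"] for i in rand_doc["interactions"]})
        ep = endpoints(rand_repo, net)
        le2e = oracles.le_entity_map(rand_doc)
        flow_entities = {
            le2e[p["local_entity"]]
            for i in rand_doc["interactions"]
            for p in i["participants"]
            if p["role"] in ("input", "output")
        }
        assert ep.sources <= flow_entities and ep.sinks <= flow_entities


class TestNeighborhood:
    def test_isolated_entity_is_empty(self, rand_repo, rand_doc):
        used = set()
        for ents in oracles.interaction_entities(rand_doc).values():
            used |= ents
        isolated = next(e["id"] for e in rand_doc["entities"] if e["id"] not in used)
        assert len(neighborhood(rand_repo, isolated, 3)) == 0

    def test_chain_levels(self, chain_repo):
        assert neighborhood(chain_repo, "m_A", 1).interactions == {"rx0"}
        assert neighborhood(chain_repo, "m_A", 2).interactions == {"rx0", "rx1"}

    def test_p_must_be_positive(self, chain_repo):
        with pytest.raises(UsageError):
            neighborhood(chain_repo, "m_A", 0)

    def test_unknown_entity_raises(self, chain_repo):
        with pytest.raises(NotFoundError):
            neighborhood(chain_repo, "nope", 1)

    def test_matches_bfs_oracle(self, rand_repo, rand_doc):
        for e in rand_doc["entities"][:80]:
            for p in (1, 2, 3):
                got = neighborhood(rand_repo, e["id"], p).interactions
                assert got == oracles.neighborhood_bfs(rand_doc, e["id"], p)

    def test_monotone_and_reaches_component(self, rand_repo, rand_doc):
        import networkx as nx

        g = oracles.bipartite_graph(rand_doc)
        n_interactions = len(rand_doc["interactions"])
        for e in rand_doc["entities"][:20]:
            prev: set[str] = set()
            for p in (1, 2, 3):
                cur = neighborhood(rand_repo, e["id"], p).interactions
                assert prev <= cur
                prev = cur
            full = neighborhood(rand_repo, e["id"], n_interactions).interactions
            comp = nx.node_connected_component(g, f"e:{e['id']}")
            assert full == {n[2:] for n in comp if n.startswith("i:")}


class TestSharedGeneMatrix:
    def test_single_pathway_diagonal(self, hormone_repo):
        m = shared_gene_matrix(hormone_repo, ["pw_bs_bio"])
        assert m.values.tolist() == [[3]]

    def test_disjoint_pathways_zero_offdiagonal(self, hormone_repo):
        m = shared_gene_matrix(hormone_repo, ["pw_bs_bio", "pw_ax_bio"])
        assert m.values[0, 1] == 0 == m.values[1, 0]

    def test_known_overlaps(self, hormone_repo):
        m = shared_gene_matrix(
            hormone_repo, ["pw_bs_bio", "pw_bs_sig", "pw_ax_sig"]
        )
        # shares: bio∩sig = {g3}; bio∩ax_sig = {g1}; sig∩ax_sig = {}
        assert m.values.tolist() == [[3, 1, 1], [1, 2, 0], [1, 0, 3]]

    def test_matches_brute_force(self, rand_repo, rand_doc):
        ids = [p["id"] for p in rand_doc["pathways"]]
        m = shared_gene_matrix(rand_repo, ids)
        assert m.values.tolist() == oracles.shared_gene_matrix(rand_doc, ids)

    def test_symmetry_and_bound_properties(self):
        """values(i,j) = values(j,i) <= min(diagonals), across seeds."""
        import numpy as np

        for seed in range(20):
            doc = generate_repository(FixtureParams(seed=seed, n_pathways=6))
            repo = load_repository(doc)
            ids = [p["id"] for p in doc["pathways"]]
            v = shared_gene_matrix(repo, ids).values
            assert (v == v.T).all()
            assert (v >= 0).all()
            d = np.diag(v)
            assert (v <= np.minimum.outer(d, d)).all()

    def test_duplicate_ids_rejected(self, rand_repo):
        with pytest.raises(UsageError):
            shared_gene_matrix(rand_repo, ["pw0000", "pw0000"])


class TestEntitiesInMinPathways:
    def test_k1_keeps_all_present(self, hormone_repo):
        genes = [f"g{i}" for i in range(1, 9)]
        assert entities_in_min_pathways(hormone_repo, genes, 1) == genes

    def test_k_above_total_is_empty(self, hormone_repo):
        genes = [f"g{i}" for i in range(1, 9)]
        assert entities_in_min_pathways(hormone_repo, genes, 6) == []

    def test_k2_matches_membership_counts(self, rand_repo, rand_doc):
        ids = [e["id"] for e in rand_doc["entities"]]
        got = entities_in_min_pathways(rand_repo, ids, 2)
        expected = [
            e for e in ids if len(oracles.pathways_of_entity(rand_doc, e)) >= 2
        ]
        assert got == expected

    def test_order_preserved(self, hormone_repo):
        out = entities_in_min_pathways(hormone_repo, ["g7", "g1", "g3"], 2)
        assert out == ["g7", "g1", "g3"]
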