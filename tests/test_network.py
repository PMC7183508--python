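"""Mass-difference pair finding, RT windows, node merging and scoring."""
import itertools

import numpy as np
import pytest

from dacmet.chem import (MassTolerance, default_reaction_table,
                         match_mass_difference)
from dacmet.network import (ConjugationNetwork, NetworkEdge, NetworkNode,
                            apply_rt_windows, extract_subnetworks,
                            find_difference_pairs, merge_coeluting_nodes,
                            plasma_only_percentage,
                            score_source_by_reference_shift)

REACTIONS = default_reaction_table()
GAINS = [r for r in REACTIONS if r.kind == "gain"]


def _node(nid, mass, rt=5.0, intensity=1000.0, **kw):
    return NetworkNode(node_id=nid, member_peaks=[nid], neutral_mass=mass,
                       rt=rt, max_intensity=intensity, **kw)


def brute_force_pairs(nodes, reactions, tol):
    """Independent oracle: all-pairs, all-reactions matching."""
    found = set()
    for a, b in itertools.combinations(nodes, 2):
        for reaction in reactions:
            if match_mass_difference(a.neutral_mass, b.neutral_mass,
                                     reaction, tol):
                light, heavy = sorted((a, b), key=lambda n: n.neutral_mass)
                if reaction.kind == "gain":
                    found.add((light.node_id, heavy.node_id, reaction.name))
                else:
                    found.add((heavy.node_id, light.node_id, reaction.name))
    return found


class TestFindDifferencePairs:
    def test_licorice_conjugate_family(self):
        nodes = [_node("a", 256.07356), _node("b", 336.03038),
                 _node("c", 432.10565), _node("d", 512.06247)]
        edges = find_difference_pairs(nodes, GAINS, MassTolerance(5))
        keyed = {(e.source, e.target, e.reaction) for e in edges}
        assert keyed == {
            ("a", "b", "sulfation"),
            ("a", "c", "glucuronidation"),
            ("b", "d", "glucuronidation"),
            ("c", "d", "sulfation"),
        }
        # 256 -> 512 (both conjugations at once) matches no single reaction
        assert not any({e.source, e.target} == {"a", "d"} for e in edges)

    def test_single_node_no_edges(self):
        assert find_difference_pairs([_node("a", 300.0)], GAINS) == []

    def test_exact_delta_zero_residual(self):
        gluc_delta = next(r.delta_mass for r in GAINS
                          if r.name == "glucuronidation")
        nodes = [_node("a", 300.0), _node("b", 300.0 + gluc_delta)]
        edges = find_difference_pairs(nodes, GAINS, MassTolerance(5))
        gluc = [e for e in edges if e.reaction == "glucuronidation"]
        assert len(gluc) == 1
        assert gluc[0].mass_residual_ppm == pytest.approx(0.0, abs=1e-3)

    def test_loss_reaction_directed_heavier_to_lighter(self):
        nodes = [_node("aglycone", 256.07356, rt=9.0),
                 _node("glycoside", 418.12638, rt=7.0)]
        edges = find_difference_pairs(nodes, REACTIONS, MassTolerance(5))
        deglyc = [e for e in edges if e.reaction == "deglycosylation"]
        assert len(deglyc) == 1
        assert (deglyc[0].source, deglyc[0].target) == ("glycoside", "aglycone")
        assert deglyc[0].rt_shift == pytest.approx(2.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        masses = rng.uniform(150, 650, size=30)
        # plant some true deltas so the comparison is not vacuous
        for i in range(5):
            masses[i + 20] = masses[i] + GAINS[i % len(GAINS)].delta_mass \
                * (1 + rng.normal(0, 2e-6))
        nodes = [_node(f"n{i}", m, rt=float(rng.uniform(1, 14)))
                 for i, m in enumerate(masses)]
        tol = MassTolerance(5)
        fast = {(e.source, e.target, e.reaction)
                for e in find_difference_pairs(nodes, REACTIONS, tol)}
        assert fast == brute_force_pairs(nodes, REACTIONS, tol)


class TestRtWindows:
    @pytest.mark.parametrize("reaction,shift,expected", [
        ("glucuronidation", -1.7, True),
        ("sulfation", -1.3, True),
        ("sulfation", -2.8, True),
        ("glucuronidation", -3.2, False),
        ("sulfation", 0.2, True),     # closed upper boundary
        ("sulfation", -3.0, True),    # closed lower boundary
        ("sulfation", 0.3, False),
        ("glycine conjugation", 4.9, True),
    ])
    def test_window_flags(self, reaction, shift, expected):
        edge = NetworkEdge("s", "t", reaction, 0.0, shift)
        net_nodes = [_node("s", 300.0), _node("t", 380.0)]
        apply_rt_windows([edge], REACTIONS)
        assert edge.within_window is expected

    def test_out_of_window_edges_retained(self):
        edge = NetworkEdge("s", "t", "glucuronidation", 0.0, -3.2)
        out = apply_rt_windows([edge], REACTIONS)
        assert len(out) == 1 and not out[0].within_window


class TestMergeCoelutingNodes:
    def test_close_rt_same_mass_merge(self):
        nodes = [_node("P8722", 432.10565, rt=8.30, intensity=5000.0),
                 _node("N6061", 432.10565, rt=8.35, intensity=1000.0)]
        merged = merge_coeluting_nodes(nodes)
        assert len(merged) == 1
        assert merged[0].node_id == "P8722/N6061"  # most intense first
        assert merged[0].rt == 8.30

    def test_rt_gap_keeps_nodes_separate(self):
        nodes = [_node("a", 432.10565, rt=8.30), _node("b", 432.10565, rt=8.60)]
        assert len(merge_coeluting_nodes(nodes)) == 2

    def test_exception_pair_never_merges(self):
        nodes = [_node("eph", 165.11536, rt=4.00),
                 _node("pseudo", 165.11536, rt=4.05)]
        merged = merge_coeluting_nodes(nodes, exceptions=[("eph", "pseudo")])
        assert len(merged) == 2

    def test_order_independent(self):
        rng = np.random.default_rng(0)
        nodes = [_node(f"n{i}", 300.0, rt=5.0 + 0.15 * i, intensity=100.0 * i)
                 for i in range(6)]
        nodes += [_node(f"m{i}", 410.0, rt=3.0 + 0.5 * i) for i in range(4)]
        reference = None
        for _ in range(5):
            perm = list(nodes)
            rng.shuffle(perm)
            ids = sorted(n.node_id for n in merge_coeluting_nodes(perm))
            if reference is None:
                reference = ids
            assert ids == reference

    def test_mass_gap_keeps_nodes_separate(self):
        nodes = [_node("a", 432.10565, rt=8.30),
                 _node("b", 432.11565, rt=8.32)]  # 23 ppm apart
        assert len(merge_coeluting_nodes(nodes)) == 2


class TestReferenceShiftScoring:
    def _net(self):
        nodes = [_node("LG", 256.07356, rt=9.0),
                 _node("ILG", 256.07356, rt=10.5),
                 _node("conj336", 336.03038, rt=7.7)]
        edges = [
            NetworkEdge("LG", "conj336", "sulfation", 0.0, -1.3,
                        within_window=True),
            NetworkEdge("ILG", "conj336", "sulfation", 0.0, -2.8,
                        within_window=True),
        ]
        return ConjugationNetwork(nodes, edges)

    def test_closest_to_reference_preferred(self):
        net = score_source_by_reference_shift(self._net(), reactions=REACTIONS)
        by_src = {e.source: e for e in net.edges}
        assert by_src["LG"].shift_score == pytest.approx(0.1)
        assert by_src["ILG"].shift_score == pytest.approx(1.4)
        assert by_src["LG"].preferred and not by_src["ILG"].preferred

    def test_single_candidate_preferred(self):
        nodes = [_node("LG", 256.07356, rt=9.0), _node("c", 336.03038, rt=7.7)]
        edges = [NetworkEdge("LG", "c", "sulfation", 0.0, -1.3,
                             within_window=True)]
        net = score_source_by_reference_shift(
            ConjugationNetwork(nodes, edges), reactions=REACTIONS)
        assert net.edges[0].preferred and not net.edges[0].ambiguous

    def test_tie_marks_ambiguous(self):
        nodes = [_node("a", 256.07356, rt=9.0), _node("b", 256.07356, rt=9.0),
                 _node("c", 336.03038, rt=7.6)]
        edges = [NetworkEdge("a", "c", "sulfation", 0.0, -1.4, within_window=True),
                 NetworkEdge("b", "c", "sulfation", 0.0, -1.4, within_window=True)]
        net = score_source_by_reference_shift(
            ConjugationNetwork(nodes, edges), reactions=REACTIONS)
        assert all(e.preferred and e.ambiguous for e in net.edges)

    def test_unreferenced_reaction_left_unscored(self):
        nodes = [_node("a", 300.0, rt=5.0), _node("b", 357.02146, rt=5.5)]
        edges = [NetworkEdge("a", "b", "glycine conjugation", 0.0, 0.5,
                             within_window=True)]
        net = score_source_by_reference_shift(
            ConjugationNetwork(nodes, edges), reactions=REACTIONS)
        assert net.edges[0].shift_score is None

    def test_out_of_window_never_preferred(self):
        nodes = [_node("in", 256.07356, rt=9.0), _node("out", 256.07356, rt=11.0),
                 _node("c", 432.10565, rt=7.3)]
        edges = [
            NetworkEdge("in", "c", "glucuronidation", 0.0, -1.7,
                        within_window=True),
            NetworkEdge("out", "c", "glucuronidation", 0.0, -3.7,
                        within_window=False),
        ]
        net = score_source_by_reference_shift(
            ConjugationNetwork(nodes, edges), reactions=REACTIONS)
        by_src = {e.source: e for e in net.edges}
        assert by_src["in"].preferred and not by_src["out"].preferred


class TestSubnetworks:
    def test_edgeless_network_one_component_per_node(self):
        nodes = [_node(f"n{i}", 200.0 + i) for i in range(4)]
        net = ConjugationNetwork(nodes, [])
        subnets = extract_subnetworks(net)
        assert len(subnets) == 4

    def test_labels_by_size_then_mass(self):
        nodes = [_node("a", 300.0), _node("b", 380.0), _node("c", 150.0)]
        edges = [NetworkEdge("a", "b", "sulfation", 0.0, -1.0,
                             within_window=True)]
        net = ConjugationNetwork(nodes, edges)
        subnets = extract_subnetworks(net)
        assert subnets["A"] == ["a", "b"]
        assert subnets["B"] == ["c"]
        assert net.nodes["c"].subnetwork == "B"

    def test_dropping_edges_never_decreases_component_count(self):
        nodes = [_node(f"n{i}", 200.0 + i) for i in range(6)]
        edges = [NetworkEdge(f"n{i}", f"n{i+1}", "sulfation", 0.0, -1.0,
                             within_window=True) for i in range(5)]
        net = ConjugationNetwork(nodes, edges)
        n_before = len(extract_subnetworks(net))
        for e in net.edges:
            e.within_window = False
        assert len(extract_subnetworks(net)) >= n_before


class TestOriginOverlay:
    def test_origin_from_herb_plasma(self, subnet_result):
        nodes = subnet_result.network.nodes
        assert nodes["N6443"].origin == {"licorice"}
        assert nodes["P2001"].origin == {"ephedra"}
        assert nodes["N6443"].in_plasma and not nodes["N6443"].in_extract
        assert nodes["P5000"].in_extract

    def test_plasma_only_percentage(self):
        nodes = [_node(f"n{i}", 200.0 + i, in_extract=(i < 17))
                 for i in range(82)]
        pct = plasma_only_percentage(nodes)
        assert pct == pytest.approx(100 * 65 / 82)
        with pytest.raises(ValueError):
            plasma_only_percentage([])


def test_edge_referencing_unknown_node_rejected():
    with pytest.raises(ValueError, match="unknown node"):
        ConjugationNetwork([_node("a", 300.0)],
                           [NetworkEdge("a", "ghost", "sulfation", 0.0, -1.0)])
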