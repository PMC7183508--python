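"""Mass-difference conjugation networks.

Nodes are metabolites (merged peak groups carrying a representative neutral
mass and RT); edges are biotransformations found by exhaustive pairwise
mass-difference matching against a reaction table.  Edges are then
annotated with the RT-shift window check, herbal-origin overlay, and
reference-shift source scoring.  Edges are never deleted — out-of-window
candidates stay in the graph flagged ``within_window=False`` so the audit
trail survives to export.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .chem import (MassTolerance, ReactionDelta, mass_residual_ppm,
                   match_mass_difference)
from .io import FeatureTable, SampleDesign

logger = logging.getLogger(__name__)

__all__ = [
    "NetworkNode",
    "NetworkEdge",
    "ConjugationNetwork",
    "build_nodes",
    "find_difference_pairs",
    "apply_rt_windows",
    "merge_coeluting_nodes",
    "score_source_by_reference_shift",
    "overlay_origin",
    "extract_subnetworks",
    "plasma_only_percentage",
]

HERBS = ("ephedra", "apricot", "cinnamon", "licorice")


@dataclass
class NetworkNode:
    """A metabolite node: representative mass/RT of its member peaks."""

    node_id: str
    member_peaks: list[str]
    neutral_mass: float
    rt: float
    label: str | None = None
    formula: str | None = None
    origin: set[str] = field(default_factory=set)
    in_extract: bool = False
    in_plasma: bool = False
    msi_level: str = "unknown"
    subnetwork: str | None = None
    max_intensity: float = 0.0

    def __post_init__(self) -> None:
        bad = set(self.origin) - set(HERBS)
        if bad:
            raise ValueError(f"unknown herb(s) in origin: {', '.join(sorted(bad))}")


@dataclass
class NetworkEdge:
    """A candidate biotransformation between two nodes.

    ``rt_shift`` is signed as target RT minus source RT, so conjugates that
    elute earlier than their source carry negative shifts.
    """

    source: str
    target: str
    reaction: str
    mass_residual_ppm: float
    rt_shift: float
    within_window: bool = False
    shift_score: float | None = None
    preferred: bool = False
    ambiguous: bool = False
    evidence: set[str] = field(default_factory=set)

    @property
    def pair(self) -> frozenset:
        return frozenset((self.source, self.target))


class ConjugationNetwork:
    """Metabolite nodes plus reaction edges, with evidence annotations."""

    def __init__(self, nodes: Iterable[NetworkNode] = (),
                 edges: Iterable[NetworkEdge] = ()):
        self.nodes: dict[str, NetworkNode] = {}
        for node in nodes:
            if node.node_id in self.nodes:
                raise ValueError(f"duplicate node id {node.node_id!r}")
            self.nodes[node.node_id] = node
        self.edges: list[NetworkEdge] = []
        for edge in edges:
            self.add_edge(edge)

    def add_edge(self, edge: NetworkEdge) -> None:
        if edge.source not in self.nodes or edge.target not in self.nodes:
            raise ValueError(
                f"edge {edge.source}->{edge.target} references unknown node")
        self.edges.append(edge)

    def __len__(self) -> int:
        return len(self.nodes)

    def edges_to(self, node_id: str) -> list[NetworkEdge]:
        return [e for e in self.edges if e.target == node_id]

    def to_networkx(self):
        import networkx as nx

        g = nx.DiGraph()
        for node in self.nodes.values():
            g.add_node(node.node_id,
                       members=";".join(node.member_peaks),
                       neutral_mass=float(node.neutral_mass),
                       rt=float(node.rt),
                       label=node.label or "",
                       formula=node.formula or "",
                       origin=";".join(sorted(node.origin)),
                       in_extract=bool(node.in_extract),
                       in_plasma=bool(node.in_plasma),
                       msi_level=str(node.msi_level),
                       subnetwork=node.subnetwork or "")
        for e in self.edges:
            g.add_edge(e.source, e.target,
                       reaction=e.reaction,
                       mass_residual_ppm=float(e.mass_residual_ppm),
                       rt_shift=float(e.rt_shift),
                       within_window=bool(e.within_window),
                       shift_score=(float("nan") if e.shift_score is None
                                    else float(e.shift_score)),
                       preferred=bool(e.preferred),
                       ambiguous=bool(e.ambiguous),
                       evidence=";".join(sorted(e.evidence)))
        return g

    @classmethod
    def from_networkx(cls, g) -> "ConjugationNetwork":
        nodes = []
        for nid, attrs in g.nodes(data=True):
            nodes.append(NetworkNode(
                node_id=nid,
                member_peaks=[m for m in attrs.get("members", "").split(";") if m]
                             or [nid],
                neutral_mass=float(attrs.get("neutral_mass", 0.0)),
                rt=float(attrs.get("rt", 0.0)),
                label=attrs.get("label") or None,
                formula=attrs.get("formula") or None,
                origin={o for o in attrs.get("origin", "").split(";") if o},
                in_extract=bool(attrs.get("in_extract", False)),
                in_plasma=bool(attrs.get("in_plasma", False)),
                msi_level=str(attrs.get("msi_level", "unknown")),
                subnetwork=attrs.get("subnetwork") or None))
        edges = []
        for src, dst, attrs in g.edges(data=True):
            score = attrs.get("shift_score")
            if score is not None and np.isnan(score):
                score = None
            edges.append(NetworkEdge(
                source=src, target=dst,
                reaction=attrs.get("reaction", ""),
                mass_residual_ppm=float(attrs.get("mass_residual_ppm", 0.0)),
                rt_shift=float(attrs.get("rt_shift", 0.0)),
                within_window=bool(attrs.get("within_window", False)),
                shift_score=score,
                preferred=bool(attrs.get("preferred", False)),
                ambiguous=bool(attrs.get("ambiguous", False)),
                evidence={e for e in attrs.get("evidence", "").split(";") if e}))
        return cls(nodes, edges)


def build_nodes(table: FeatureTable, groups: Sequence[Sequence[str]],
                ) -> list[NetworkNode]:
    """Turn merged peak groups into metabolite nodes.

    The representative (most intense) member supplies the node's neutral
    mass and RT; the node id joins member ids with ``/`` (representative
    first), mirroring the P8722/N6061 naming convention.
    """
    nodes = []
    for members in groups:
        members = list(members)
        rep = table.peaks[members[0]]
        max_int = float(np.nanmax(
            table.intensity.loc[members].to_numpy(dtype=float), initial=0.0))
        nodes.append(NetworkNode(
            node_id="/".join(members),
            member_peaks=members,
            neutral_mass=rep.neutral_mass,
            rt=rep.rt,
            max_intensity=max_int))
    return nodes


def find_difference_pairs(nodes: Sequence[NetworkNode],
                          reactions: Sequence[ReactionDelta],
                          tol: MassTolerance = MassTolerance(),
                          ) -> list[NetworkEdge]:
    """All node pairs whose mass difference matches a reaction delta.

    Exhaustive over unordered pairs (results identical to the O(n^2) brute
    force; implemented with a sorted-mass bisection for speed).  Gain-type
    reactions are directed lighter -> heavier, loss-type reactions
    heavier -> lighter.  Every edge carries its signed ppm residual and RT
    shift; window flags are applied separately by :func:`apply_rt_windows`.
    """
    order = sorted(range(len(nodes)), key=lambda i: nodes[i].neutral_mass)
    masses = np.array([nodes[i].neutral_mass for i in order])
    edges: list[NetworkEdge] = []
    for reaction in reactions:
        delta = reaction.delta_mass
        # widest possible Da window for this reaction at these masses
        slack = tol.ppm * 1e-6 * (masses.max() + delta) * 1.5 + 1e-9
        lo = np.searchsorted(masses, masses + delta - slack, side="left")
        hi = np.searchsorted(masses, masses + delta + slack, side="right")
        for ii in range(len(masses)):
            for jj in range(lo[ii], hi[ii]):
                if jj == ii:
                    continue
                light, heavy = nodes[order[ii]], nodes[order[jj]]
                if heavy.neutral_mass <= light.neutral_mass:
                    continue
                if not match_mass_difference(light.neutral_mass,
                                             heavy.neutral_mass, reaction, tol):
                    continue
                if reaction.kind == "gain":
                    src, dst = light, heavy
                else:
                    src, dst = heavy, light
                edges.append(NetworkEdge(
                    source=src.node_id, target=dst.node_id,
                    reaction=reaction.name,
                    mass_residual_ppm=mass_residual_ppm(
                        light.neutral_mass, heavy.neutral_mass, reaction),
                    rt_shift=dst.rt - src.rt))
    edges.sort(key=lambda e: (e.source, e.target, e.reaction))
    return edges


def apply_rt_windows(edges: Iterable[NetworkEdge],
                     reactions: Sequence[ReactionDelta]) -> list[NetworkEdge]:
    """Flag each edge by whether its RT shift lies in the reaction's window.

    Out-of-window edges are retained (flagged) rather than dropped.
    """
    by_name = {r.name: r for r in reactions}
    out = []
    for edge in edges:
        reaction = by_name.get(edge.reaction)
        if reaction is None:
            raise ValueError(f"edge reaction {edge.reaction!r} not in table")
        edge.within_window = reaction.shift_in_window(edge.rt_shift)
        out.append(edge)
    return out


def merge_coeluting_nodes(nodes: Sequence[NetworkNode], rt_tol: float = 0.2,
                          ppm: float = 5.0,
                          exceptions: Iterable[frozenset] = (),
                          ) -> list[NetworkNode]:
    """Merge nodes with equal neutral mass that co-elute within ``rt_tol``.

    Greedy chaining by ascending RT with transitive closure: a run of
    same-mass nodes whose consecutive RT gaps are all <= ``rt_tol``
    collapses to one node (representative = most intense member).
    Exception pairs (by node id or label) never merge.  Output is
    independent of input order.
    """
    exceptions = {frozenset(p) for p in exceptions}

    def excepted(a: NetworkNode, b: NetworkNode) -> bool:
        # exception pairs may name node ids, member peak ids, or labels
        keys_a = {a.node_id, *a.member_peaks} | ({a.label} if a.label else set())
        keys_b = {b.node_id, *b.member_peaks} | ({b.label} if b.label else set())
        return any(frozenset((ka, kb)) in exceptions
                   for ka in keys_a for kb in keys_b)

    def same_mass(a: NetworkNode, b: NetworkNode) -> bool:
        heavier = max(a.neutral_mass, b.neutral_mass)
        return abs(a.neutral_mass - b.neutral_mass) / heavier * 1e6 <= ppm

    merged: list[NetworkNode] = []

    def flush(cluster: list[NetworkNode]) -> None:
        if not cluster:
            return
        rep = max(cluster, key=lambda n: (n.max_intensity, n.node_id))
        members: list[str] = []
        for n in sorted(cluster, key=lambda n: (n is not rep, n.node_id)):
            members.extend(n.member_peaks)
        merged.append(NetworkNode(
            node_id="/".join(members),
            member_peaks=members,
            neutral_mass=rep.neutral_mass,
            rt=rep.rt,
            label=rep.label or next((n.label for n in cluster if n.label), None),
            formula=rep.formula or next((n.formula for n in cluster if n.formula), None),
            origin=set().union(*(n.origin for n in cluster)),
            in_extract=any(n.in_extract for n in cluster),
            in_plasma=any(n.in_plasma for n in cluster),
            max_intensity=rep.max_intensity))

    # group by mass (chained ppm adjacency in mass order), then chain each
    # group by ascending RT
    by_mass = sorted(nodes, key=lambda n: (n.neutral_mass, n.rt, n.node_id))
    mass_groups: list[list[NetworkNode]] = []
    for node in by_mass:
        if mass_groups and same_mass(mass_groups[-1][-1], node):
            mass_groups[-1].append(node)
        else:
            mass_groups.append([node])

    for group in mass_groups:
        group.sort(key=lambda n: (n.rt, n.node_id))
        cluster: list[NetworkNode] = []
        for node in group:
            if cluster and node.rt - cluster[-1].rt <= rt_tol \
                    and not any(excepted(c, node) for c in cluster):
                cluster.append(node)
            else:
                flush(cluster)
                cluster = [node]
        flush(cluster)
    merged.sort(key=lambda n: (n.neutral_mass, n.rt, n.node_id))
    return merged


def score_source_by_reference_shift(network: ConjugationNetwork,
                                    reference_shifts: Mapping[str, float] | None = None,
                                    reactions: Sequence[ReactionDelta] = (),
                                    ) -> ConjugationNetwork:
    """Rank candidate sources of each conjugate by calibrated RT shift.

    For every (target, reaction) group of edges, ``shift_score`` is the
    absolute deviation of the observed RT shift from the reaction's
    reference shift (calibrated on a standard such as 7-hydroxycoumarin).
    The within-window edge with the smallest score is marked ``preferred``;
    exact ties are all marked preferred and flagged ``ambiguous``.
    Reactions without a reference shift are left unscored.
    """
    refs = dict(reference_shifts or {})
    for r in reactions:
        if r.reference_shift is not None:
            refs.setdefault(r.name, r.reference_shift)

    groups: dict[tuple[str, str], list[NetworkEdge]] = {}
    for edge in network.edges:
        groups.setdefault((edge.target, edge.reaction), []).append(edge)

    for (target, reaction), edges in groups.items():
        ref = refs.get(reaction)
        if ref is None:
            logger.info("no reference shift for %r; edges to %s left unscored",
                        reaction, target)
            continue
        for edge in edges:
            edge.shift_score = abs(edge.rt_shift - ref)
        candidates = [e for e in edges if e.within_window]
        if not candidates:
            continue
        best = min(e.shift_score for e in candidates)
        winners = [e for e in candidates if e.shift_score == best]
        for e in winners:
            e.preferred = True
            e.ambiguous = len(winners) > 1
    return network


def overlay_origin(network: ConjugationNetwork, table: FeatureTable,
                   design: SampleDesign) -> ConjugationNetwork:
    """Superimpose herbal origin and extract/plasma presence on nodes.

    A node's origin is the set of herbs whose single-herb rat-plasma
    samples detect any member peak; ``in_extract`` / ``in_plasma`` record
    detection in the extract and in human (pre/post) plasma samples.
    """
    detected = table.detected()
    herb_samples = design.herb_samples()
    extract_samples = [s for s in design.samples_of_class("extract")
                       if s in detected.columns]
    plasma_samples = [s for s in design.samples_of_class("pre")
                      + design.samples_of_class("post") if s in detected.columns]
    for node in network.nodes.values():
        members = [m for m in node.member_peaks if m in detected.index]
        if not members:
            continue
        det = detected.loc[members]
        origin = set()
        for herb, samples in herb_samples.items():
            cols = [s for s in samples if s in det.columns]
            if cols and det[cols].any().any():
                origin.add(herb)
        node.origin = origin
        if len(origin) > 1:
            logger.info("node %s detected for multiple herbs: %s",
                        node.node_id, ", ".join(sorted(origin)))
        node.in_extract = bool(extract_samples
                               and det[extract_samples].any().any())
        node.in_plasma = bool(plasma_samples
                              and det[plasma_samples].any().any())
    return network


def extract_subnetworks(network: ConjugationNetwork) -> dict[str, list[str]]:
    """Partition nodes into connected components over retained edges.

    Components are computed on the undirected graph of within-window edges
    and labelled A, B, C, ... by descending size, ties broken by ascending
    smallest member mass.  Labels are written back onto the nodes.
    """
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(network.nodes)
    for edge in network.edges:
        if edge.within_window:
            g.add_edge(edge.source, edge.target)
    components = [sorted(c) for c in nx.connected_components(g)]
    components.sort(key=lambda c: (
        -len(c), min(network.nodes[n].neutral_mass for n in c)))

    def label_for(i: int) -> str:
        letters = ""
        i += 1
        while i:
            i, rem = divmod(i - 1, 26)
            letters = chr(ord("A") + rem) + letters
        return letters

    out: dict[str, list[str]] = {}
    for i, comp in enumerate(components):
        label = label_for(i)
        out[label] = comp
        for nid in comp:
            network.nodes[nid].subnetwork = label
    return out


def plasma_only_percentage(nodes: Iterable[NetworkNode]) -> float:
    """Percent of metabolites detected in plasma but not in the extract.

    These are the converted forms — compounds that do not exist in the
    administered material and appear only after in-vivo transformation.
    """
    nodes = list(nodes)
    if not nodes:
        raise ValueError("no nodes")
    plasma_only = sum(1 for n in nodes if not n.in_extract)
    return 100.0 * plasma_only / len(nodes)
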