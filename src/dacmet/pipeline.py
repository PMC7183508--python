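"""End-to-end orchestration: filter -> merge -> network -> evidence -> kinetics.

:class:`RunConfig` collects every threshold the pipeline uses; a run logs
each of them exactly once and embeds the effective configuration (plus the
package version) in the run report, so outputs are fully reproducible:
identical inputs and config give byte-identical artifacts.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .chem import MassTolerance, default_reaction_table, load_reaction_table
from .evidence import annotate_network
from .filtration import FiltrationParams, filter_candidates, merge_duplicate_ions
from .io import (AnnotationTable, FeatureTable, SampleDesign,
                 read_annotation_table, read_feature_table,
                 read_isotope_patterns, read_msms_mgf, read_sample_design,
                 write_network_graphml, write_network_sif,
                 write_node_edge_tables)
from .kinetics import (autoscale, build_kinetics_matrix, coclustering_report,
                       impute_half_min, ward_cluster)
from .network import (ConjugationNetwork, apply_rt_windows, build_nodes,
                      extract_subnetworks, find_difference_pairs,
                      merge_coeluting_nodes, overlay_origin,
                      plasma_only_percentage,
                      score_source_by_reference_shift)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "RunResult", "run_all"]


@dataclass
class RunConfig:
    """Every tunable the pipeline uses, serializable for provenance."""

    ppm: float = 5.0
    min_samples_detected: int = 2
    min_ion_count: float = 1000.0
    post_fraction: float = 0.5
    rt_merge_tol: float = 0.2
    merge_exceptions: tuple = ()            # pairs of peak ids / labels
    reaction_table_path: str | None = None
    glutathione_variant: str = "dehydro"
    reference_shifts: dict = field(default_factory=dict)
    msi_standard_rt_tol: float = 0.2
    msi_shift_agreement_tol: float = 0.5
    msms_frag_tol: float = 0.5
    n_clusters: int = 3
    include_pre_in_kinetics: bool = True

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["merge_exceptions"] = [sorted(p) for p in self.merge_exceptions]
        return d

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "merge_exceptions" in raw:
            raw["merge_exceptions"] = tuple(
                tuple(p) for p in raw["merge_exceptions"])
        return cls(**raw)

    def reactions(self):
        if self.reaction_table_path:
            return load_reaction_table(self.reaction_table_path)
        return default_reaction_table(self.glutathione_variant)


@dataclass
class RunResult:
    """In-memory results of a full pipeline run."""

    kept: list[str]
    report: object
    groups: list[list[str]]
    network: ConjugationNetwork
    subnetworks: dict[str, list[str]]
    kinetics_matrix: object | None
    clusters: object | None
    cocluster: object | None


def _log_config(config: RunConfig) -> list[str]:
    lines = [f"dacmet {__version__}"]
    for key, value in config.to_dict().items():
        lines.append(f"{key} = {value}")
        logger.info("config %s = %s", key, value)
    return lines


def run_all(table: FeatureTable | str | Path,
            design: SampleDesign | str | Path,
            config: RunConfig = RunConfig(),
            annotations: AnnotationTable | str | Path | None = None,
            msms=None, isotopes=None,
            outdir: str | Path | None = None) -> RunResult:
    """Run the full annotation pipeline and optionally write all artifacts.

    Inputs may be in-memory objects or paths to the canonical file
    formats.  Artifacts written to ``outdir``: ``kept.tsv``,
    ``filtration_report.tsv``, ``net.sif``, ``net.graphml``,
    ``annotated.graphml``, ``nodes.tsv``, ``edges.tsv``, ``clusters.tsv``,
    ``cocluster.tsv`` and ``report.txt``.
    """
    if not isinstance(table, FeatureTable):
        table = read_feature_table(table)
    if not isinstance(design, SampleDesign):
        design = read_sample_design(design)
    if annotations is not None and not isinstance(annotations, AnnotationTable):
        annotations = read_annotation_table(annotations)
    if msms is not None and not isinstance(msms, dict):
        msms = read_msms_mgf(msms)
    if isotopes is not None and not isinstance(isotopes, dict):
        isotopes = read_isotope_patterns(isotopes)

    log_lines = _log_config(config)
    reactions = config.reactions()
    tol = MassTolerance(config.ppm)
    params = FiltrationParams(
        min_samples_detected=config.min_samples_detected,
        min_ion_count=config.min_ion_count,
        post_fraction=config.post_fraction,
        rt_merge_tol=config.rt_merge_tol,
        merge_exceptions=frozenset(
            frozenset(p) for p in config.merge_exceptions))

    if len(table) == 0:
        logger.warning("empty feature table; emitting empty outputs")
        network = ConjugationNetwork()
        result = RunResult([], None, [], network, {}, None, None, None)
        if outdir is not None:
            _write_outputs(result, table, config, log_lines, outdir)
        return result

    kept, report = filter_candidates(table, design, params)
    log_lines.append(f"peaks kept after filtration: {len(kept)} / {len(table)}")

    groups = merge_duplicate_ions(
        table, kept, rt_tol=config.rt_merge_tol, ppm=config.ppm,
        exceptions=params.merge_exceptions)
    log_lines.append(f"metabolite groups after duplicate-ion merging: {len(groups)}")

    nodes = build_nodes(table, groups)
    nodes = merge_coeluting_nodes(nodes, rt_tol=config.rt_merge_tol,
                                  ppm=config.ppm,
                                  exceptions=params.merge_exceptions)
    edges = find_difference_pairs(nodes, reactions, tol)
    edges = apply_rt_windows(edges, reactions)
    network = ConjugationNetwork(nodes, edges)
    network = overlay_origin(network, table, design)
    network = score_source_by_reference_shift(
        network, config.reference_shifts, reactions)
    network = annotate_network(
        network, annotations, msms, isotopes, ppm=config.ppm,
        standard_rt_tol=config.msi_standard_rt_tol,
        shift_agreement_tol=config.msi_shift_agreement_tol,
        frag_tol=config.msms_frag_tol)
    subnetworks = extract_subnetworks(network)
    n_within = sum(1 for e in network.edges if e.within_window)
    log_lines.append(
        f"network: {len(network.nodes)} nodes, {len(network.edges)} candidate "
        f"edges ({n_within} within RT windows), {len(subnetworks)} subnetworks")
    if network.nodes:
        log_lines.append(
            "plasma-only (converted) fraction: "
            f"{plasma_only_percentage(network.nodes.values()):.1f}%")

    matrix = clusters = cocluster = None
    if len(network.nodes) >= 2:
        matrix = build_kinetics_matrix(
            table, design, network, include_pre=config.include_pre_in_kinetics)
        matrix = matrix.loc[[i for i in matrix.index
                             if not matrix.loc[i].isna().all()]]
        if len(matrix) >= 2:
            scaled = autoscale(impute_half_min(matrix))
            k = min(config.n_clusters, len(scaled))
            clusters = ward_cluster(scaled, k=k)
            cocluster = coclustering_report(clusters, network)
            matrix = scaled

    result = RunResult(kept, report, groups, network, subnetworks,
                       matrix, clusters, cocluster)
    if outdir is not None:
        _write_outputs(result, table, config, log_lines, outdir)
    return result


def _write_outputs(result: RunResult, table: FeatureTable, config: RunConfig,
                   log_lines: list[str], outdir) -> None:
    import pandas as pd

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({"peak_id": result.kept}).to_csv(
        outdir / "kept.tsv", sep="\t", index=False)
    if result.report is not None:
        result.report.to_frame().to_csv(
            outdir / "filtration_report.tsv", sep="\t", index=False)
    write_network_sif(result.network, outdir / "net.sif")
    write_network_graphml(result.network, outdir / "net.graphml")
    write_network_graphml(result.network, outdir / "annotated.graphml")
    write_node_edge_tables(result.network, outdir / "nodes.tsv",
                           outdir / "edges.tsv")
    if result.clusters is not None:
        pd.DataFrame({
            "node_id": list(result.clusters.labels),
            "cluster": list(result.clusters.labels.values()),
        }).to_csv(outdir / "clusters.tsv", sep="\t", index=False)
        result.cocluster.to_csv(outdir / "cocluster.tsv", sep="\t", index=False)
    with open(outdir / "report.txt", "w") as fh:
        fh.write("\n".join(log_lines) + "\n")
        fh.write("effective_config = ")
        fh.write(json.dumps(config.to_dict(), sort_keys=True))
        fh.write("\n")
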