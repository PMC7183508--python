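"""Readers and writers for every external artifact.

Canonical formats, all plain text:

* feature table — TSV/CSV with columns ``peak_id``, ``ion_mode`` (optional,
  else inferred from the P/N id prefix), ``mz``, ``adduct``, ``rt``
  (minutes), then one intensity column per sample.  Empty cells or zeros
  mean *not detected* and are kept distinct from measured values.
* sample design — TSV with ``sample_id``, ``subject``, ``class``
  (pre/post/mock/extract/herb_plasma), ``timepoint`` (hours, post only),
  ``herb`` (herb_plasma only).
* MS/MS spectra — MGF keyed by TITLE=peak_id (via pyteomics).
* isotopologue patterns — TSV ``peak_id``, ``offset_mz``,
  ``relative_intensity``.
* annotation table — TSV ``name``, ``formula``, ``origin``, ``rt``
  (blank if no authentic standard), ``msi_level``.
* networks — SIF, GraphML (via networkx) and node/edge TSVs.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .chem import PROTON_MASS

logger = logging.getLogger(__name__)

__all__ = [
    "Peak",
    "FeatureTable",
    "SampleDesign",
    "MsmsSpectrum",
    "AnnotationTable",
    "read_feature_table",
    "write_feature_table",
    "union_feature_tables",
    "read_sample_design",
    "write_sample_design",
    "read_msms_mgf",
    "write_msms_mgf",
    "read_isotope_patterns",
    "write_isotope_patterns",
    "read_annotation_table",
    "write_annotation_table",
    "write_network_sif",
    "write_network_graphml",
    "read_network_graphml",
    "write_node_edge_tables",
]

SAMPLE_CLASSES = ("pre", "post", "mock", "extract", "herb_plasma")

# neutral mass = mz - offset, singly charged species.
DEFAULT_ADDUCT_OFFSETS: dict[str, float] = {
    "[M+H]+": PROTON_MASS,
    "[M-H]-": -PROTON_MASS,
    "[M+Na]+": 22.989218,       # Na minus electron
    "[M+K]+": 38.963158,
    "[M+NH4]+": 18.033823,
    "[M+Cl]-": -34.969402,
    "[M+HCOO]-": -44.998201,
}


def _normalize_adduct(adduct: str) -> str:
    # tolerate unicode minus signs in adduct strings
    return str(adduct).replace("−", "-").replace("–", "-").strip()


@dataclass
class Peak:
    """One aligned LC-MS feature: observed m/z, adduct hypothesis and RT."""

    peak_id: str
    ion_mode: str               # "positive" | "negative"
    mz: float
    adduct: str
    rt: float                   # minutes
    neutral_mass: float = 0.0   # deionized monoisotopic Da

    def __post_init__(self) -> None:
        if self.ion_mode not in ("positive", "negative"):
            raise ValueError(f"peak {self.peak_id}: bad ion_mode {self.ion_mode!r}")
        if self.rt < 0:
            raise ValueError(f"peak {self.peak_id}: negative RT")


class FeatureTable:
    """Aligned peaks x samples intensity matrix with per-peak metadata.

    ``intensity`` is a DataFrame indexed by peak id with one column per
    sample; NaN marks *not detected* (the canonical file encodes it as an
    empty cell or 0).
    """

    def __init__(self, peaks: Sequence[Peak], intensity: pd.DataFrame):
        ids = [p.peak_id for p in peaks]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicated peak_id(s): {', '.join(dupes)}")
        if list(intensity.index) != ids:
            raise ValueError("intensity index does not match peak list")
        neg = intensity.to_numpy(dtype=float)
        if np.nanmin(neg, initial=0.0) < 0:
            raise ValueError("negative intensities are not allowed")
        self.peaks: dict[str, Peak] = {p.peak_id: p for p in peaks}
        self.intensity = intensity.astype(float)

    @property
    def peak_ids(self) -> list[str]:
        return list(self.peaks)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.intensity.columns)

    def __len__(self) -> int:
        return len(self.peaks)

    def detected(self) -> pd.DataFrame:
        """Boolean detection mask (NaN and 0 count as not detected)."""
        return self.intensity.notna() & (self.intensity > 0)

    def subset(self, peak_ids: Sequence[str]) -> "FeatureTable":
        peaks = [self.peaks[i] for i in peak_ids]
        return FeatureTable(peaks, self.intensity.loc[list(peak_ids)])


REQUIRED_FEATURE_COLUMNS = ("peak_id", "mz", "adduct", "rt")


def _infer_ion_mode(peak_id: str) -> str | None:
    if peak_id.startswith("P"):
        return "positive"
    if peak_id.startswith("N"):
        return "negative"
    return None


def _deionize(mz: float, adduct: str, ion_mode: str,
              adduct_offsets: Mapping[str, float], peak_id: str,
              row_number: int) -> float:
    adduct = _normalize_adduct(adduct)
    if adduct in adduct_offsets:
        return mz - adduct_offsets[adduct]
    # fallback: assume +/-H by ion mode
    offset = PROTON_MASS if ion_mode == "positive" else -PROTON_MASS
    logger.warning(
        "row %d (peak %s): unparseable adduct %r; assuming %s",
        row_number, peak_id, adduct,
        "[M+H]+" if ion_mode == "positive" else "[M-H]-")
    return mz - offset


def read_feature_table(path, dialect: Mapping[str, str] | None = None,
                       adduct_offsets: Mapping[str, float] | None = None,
                       ) -> FeatureTable:
    """Read a feature table from delimited text.

    ``dialect`` remaps canonical column names to the file's actual headers,
    e.g. ``{"peak_id": "Peak ID", "rt": "RT(min)"}``.  The neutral mass of
    every peak is computed from its m/z and adduct hypothesis; unknown
    adducts fall back to +/-H with a logged warning.
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, dtype={0: str})
    if dialect:
        df = df.rename(columns={v: k for k, v in dialect.items()})
    for col in REQUIRED_FEATURE_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"missing required column: {col!r}")
    meta_cols = [c for c in ("peak_id", "ion_mode", "mz", "adduct", "rt")
                 if c in df.columns]
    sample_cols = [c for c in df.columns if c not in meta_cols]
    offsets = dict(DEFAULT_ADDUCT_OFFSETS)
    if adduct_offsets:
        offsets.update({_normalize_adduct(k): v for k, v in adduct_offsets.items()})

    peaks = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1-based + header
        rec = dict(zip(df.columns, row))
        peak_id = str(rec["peak_id"])
        mode = rec.get("ion_mode")
        if mode is None or (isinstance(mode, float) and np.isnan(mode)):
            mode = _infer_ion_mode(peak_id)
            if mode is None:
                raise ValueError(
                    f"row {i}: no ion_mode column and peak id {peak_id!r} "
                    "has no P/N prefix")
        adduct = _normalize_adduct(rec["adduct"])
        if adduct.endswith("+") and mode == "negative" or \
           adduct.endswith("-") and mode == "positive":
            raise ValueError(
                f"row {i}: adduct {adduct!r} inconsistent with ion mode {mode}")
        mz = float(rec["mz"])
        neutral = _deionize(mz, adduct, mode, offsets, peak_id, i)
        if neutral <= 0:
            raise ValueError(f"row {i}: non-positive neutral mass for {peak_id}")
        peaks.append(Peak(peak_id, mode, mz, adduct, float(rec["rt"]), neutral))

    intensity = df[sample_cols].apply(pd.to_numeric, errors="coerce")
    intensity = intensity.where(intensity > 0)  # 0 and blank -> not detected
    intensity.index = pd.Index([p.peak_id for p in peaks], name="peak_id")
    return FeatureTable(peaks, intensity)


def write_feature_table(table: FeatureTable, path) -> None:
    """Write a feature table in the canonical TSV/CSV layout."""
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    meta = pd.DataFrame({
        "peak_id": table.peak_ids,
        "ion_mode": [p.ion_mode for p in table.peaks.values()],
        "mz": [f"{p.mz:.5f}" for p in table.peaks.values()],
        "adduct": [p.adduct for p in table.peaks.values()],
        "rt": [f"{p.rt:.3f}" for p in table.peaks.values()],
    })
    inten = table.intensity.reset_index(drop=True)
    out = pd.concat([meta, inten], axis=1)
    out.to_csv(path, sep=sep, index=False, float_format="%.6g", na_rep="")


def union_feature_tables(a: FeatureTable, b: FeatureTable,
                         alignment: Sequence[tuple[str, str]] = (),
                         ) -> FeatureTable:
    """Union of two feature tables with matched pairs collapsed.

    ``alignment`` is a list of ``(id_in_a, id_in_b)`` pairs declaring that
    the two peaks are the same compound; each pair collapses to the peak
    from ``a`` (its metadata wins; intensities are merged column-wise with
    ``a`` taking precedence on shared samples).  The result has
    ``len(a) + len(b) - len(alignment)`` peaks.
    """
    b_to_a: dict[str, str] = {}
    for ida, idb in alignment:
        if ida not in a.peaks:
            raise ValueError(f"alignment references unknown id in first table: {ida!r}")
        if idb not in b.peaks:
            raise ValueError(f"alignment references unknown id in second table: {idb!r}")
        b_to_a[idb] = ida

    samples = list(dict.fromkeys(a.sample_ids + b.sample_ids))
    peaks: list[Peak] = list(a.peaks.values())
    rows: dict[str, dict[str, float]] = {
        pid: a.intensity.loc[pid].dropna().to_dict() for pid in a.peaks
    }
    for pid, peak in b.peaks.items():
        target = b_to_a.get(pid)
        if target is None:
            if pid in rows:
                raise ValueError(
                    f"peak id {pid!r} present in both tables but not aligned")
            peaks.append(peak)
            rows[pid] = b.intensity.loc[pid].dropna().to_dict()
        else:
            merged = b.intensity.loc[pid].dropna().to_dict()
            merged.update(rows[target])  # a takes precedence
            rows[target] = merged
    intensity = pd.DataFrame(
        [[rows[p.peak_id].get(s, np.nan) for s in samples] for p in peaks],
        index=pd.Index([p.peak_id for p in peaks], name="peak_id"),
        columns=samples)
    return FeatureTable(peaks, intensity)


# ---------------------------------------------------------------------------
# sample design


class SampleDesign:
    """Maps each sample to (subject, class, timepoint, herb)."""

    def __init__(self, frame: pd.DataFrame):
        required = {"sample_id", "subject", "class"}
        missing = required - set(frame.columns)
        if missing:
            raise ValueError(f"missing design column(s): {', '.join(sorted(missing))}")
        frame = frame.copy()
        for col in ("timepoint", "herb"):
            if col not in frame.columns:
                frame[col] = np.nan
        frame["timepoint"] = pd.to_numeric(frame["timepoint"], errors="coerce")
        bad = set(frame["class"]) - set(SAMPLE_CLASSES)
        if bad:
            raise ValueError(f"unknown sample class(es): {', '.join(sorted(map(str, bad)))}")
        if frame["sample_id"].duplicated().any():
            raise ValueError("duplicated sample_id in design")
        post = frame[frame["class"] == "post"]
        if post["timepoint"].isna().any():
            raise ValueError("post samples must carry a timepoint")
        herb = frame[frame["class"] == "herb_plasma"]
        if herb["herb"].isna().any():
            raise ValueError("herb_plasma samples must carry a herb label")
        self.frame = frame.set_index("sample_id", drop=False)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame.index)

    def samples_of_class(self, cls: str) -> list[str]:
        return list(self.frame.index[self.frame["class"] == cls])

    @property
    def subjects(self) -> list[str]:
        post = self.frame[self.frame["class"].isin(("pre", "post"))]
        return sorted(post["subject"].astype(str).unique())

    @property
    def post_timepoints(self) -> list[float]:
        post = self.frame[self.frame["class"] == "post"]
        return sorted(post["timepoint"].unique())

    def post_samples_at(self, timepoint: float) -> list[str]:
        mask = (self.frame["class"] == "post") & (self.frame["timepoint"] == timepoint)
        return list(self.frame.index[mask])

    def herb_samples(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        herb = self.frame[self.frame["class"] == "herb_plasma"]
        for sample_id, row in herb.iterrows():
            out.setdefault(str(row["herb"]), []).append(sample_id)
        return out


def read_sample_design(path) -> SampleDesign:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "subject": str})
    return SampleDesign(df)


def write_sample_design(design: SampleDesign, path) -> None:
    design.frame.to_csv(path, sep="\t", index=False, na_rep="")


# ---------------------------------------------------------------------------
# MS/MS and isotopologue patterns


@dataclass
class MsmsSpectrum:
    """A product-ion spectrum: precursor m/z plus (m/z, intensity) pairs."""

    precursor_mz: float
    fragments: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for mz, inten in self.fragments:
            if mz >= self.precursor_mz + 0.5:
                raise ValueError(
                    f"fragment m/z {mz} above precursor {self.precursor_mz}")
            if inten < 0:
                raise ValueError("negative fragment intensity")


def read_msms_mgf(path) -> dict[str, MsmsSpectrum]:
    """Read MGF spectra keyed by TITLE (which carries the peak id)."""
    from pyteomics import mgf

    spectra: dict[str, MsmsSpectrum] = {}
    with mgf.MGF(str(path)) as reader:
        for spec in reader:
            title = spec["params"]["title"]
            precursor = float(spec["params"]["pepmass"][0])
            frags = list(zip(spec["m/z array"].tolist(),
                             spec["intensity array"].tolist()))
            spectra[title] = MsmsSpectrum(precursor, frags)
    return spectra


def write_msms_mgf(spectra: Mapping[str, MsmsSpectrum], path) -> None:
    from pyteomics import mgf

    entries = []
    for title, spec in spectra.items():
        mzs = np.array([f[0] for f in spec.fragments])
        intens = np.array([f[1] for f in spec.fragments])
        entries.append({
            "m/z array": mzs,
            "intensity array": intens,
            "params": {"title": title, "pepmass": (spec.precursor_mz, None)},
        })
    mgf.write(entries, str(path), file_mode="w")


def read_isotope_patterns(path) -> dict[str, list[tuple[float, float]]]:
    """Read isotopologue patterns: peak_id -> [(offset Da, relative intensity)]."""
    df = pd.read_csv(path, sep="\t", dtype={"peak_id": str})
    for col in ("peak_id", "offset_mz", "relative_intensity"):
        if col not in df.columns:
            raise ValueError(f"missing isotope-pattern column: {col!r}")
    patterns: dict[str, list[tuple[float, float]]] = {}
    for row in df.itertuples(index=False):
        patterns.setdefault(row.peak_id, []).append(
            (float(row.offset_mz), float(row.relative_intensity)))
    return patterns


def write_isotope_patterns(patterns: Mapping[str, Sequence[tuple[float, float]]],
                           path) -> None:
    rows = [(pid, f"{off:.5f}", f"{ri:.5f}")
            for pid, entries in patterns.items() for off, ri in entries]
    pd.DataFrame(rows, columns=["peak_id", "offset_mz", "relative_intensity"]
                 ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# annotation table


class AnnotationTable:
    """User-provided compound annotations (standards and literature).

    A row with a reference RT is an authentic standard (supports MSI
    level 1); a row without one is a database/literature annotation
    (supports MSI level 3).
    """

    def __init__(self, frame: pd.DataFrame):
        required = {"name", "formula"}
        missing = required - set(frame.columns)
        if missing:
            raise ValueError(f"missing annotation column(s): {', '.join(sorted(missing))}")
        if frame["name"].duplicated().any():
            dupes = frame["name"][frame["name"].duplicated()].tolist()
            raise ValueError(f"duplicated compound name(s): {', '.join(dupes)}")
        frame = frame.copy()
        for col in ("origin", "rt", "msi_level"):
            if col not in frame.columns:
                frame[col] = np.nan
        frame["rt"] = pd.to_numeric(frame["rt"], errors="coerce")
        # parse formulas eagerly so bad rows fail at load time
        from .chem import ElementalFormula
        frame["neutral_mass"] = [
            ElementalFormula.parse(f).mass for f in frame["formula"]]
        self.frame = frame.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)


def read_annotation_table(path) -> AnnotationTable:
    return AnnotationTable(pd.read_csv(path, sep="\t", dtype={"name": str}))


def write_annotation_table(table: AnnotationTable, path) -> None:
    cols = [c for c in table.frame.columns if c != "neutral_mass"]
    table.frame[cols].to_csv(path, sep="\t", index=False, na_rep="")


# ---------------------------------------------------------------------------
# network export (SIF / GraphML / TSV)


def write_network_sif(network, path) -> None:
    """Write one ``source<TAB>reaction<TAB>target`` line per retained edge."""
    with open(path, "w") as fh:
        for edge in network.edges:
            fh.write(f"{edge.source}\t{edge.reaction}\t{edge.target}\n")


def write_network_graphml(network, path) -> None:
    """Write the network as GraphML with full node/edge attributes."""
    import networkx as nx

    nx.write_graphml(network.to_networkx(), str(path))


def read_network_graphml(path):
    """Read a GraphML network back into a :class:`~dacmet.network.ConjugationNetwork`."""
    import networkx as nx

    from .network import ConjugationNetwork

    return ConjugationNetwork.from_networkx(nx.read_graphml(str(path)))


def write_node_edge_tables(network, node_path, edge_path) -> None:
    """Write node and edge attribute TSVs mirroring the GraphML content."""
    node_rows = []
    for node in network.nodes.values():
        node_rows.append({
            "node_id": node.node_id,
            "members": ";".join(node.member_peaks),
            "neutral_mass": f"{node.neutral_mass:.5f}",
            "rt": f"{node.rt:.3f}",
            "label": node.label or "",
            "origin": ";".join(sorted(node.origin)),
            "in_extract": node.in_extract,
            "in_plasma": node.in_plasma,
            "msi_level": node.msi_level,
            "subnetwork": node.subnetwork or "",
        })
    pd.DataFrame(node_rows).to_csv(node_path, sep="\t", index=False)
    edge_rows = []
    for edge in network.edges:
        edge_rows.append({
            "source": edge.source,
            "target": edge.target,
            "reaction": edge.reaction,
            "mass_residual_ppm": f"{edge.mass_residual_ppm:.3f}",
            "rt_shift": f"{edge.rt_shift:.3f}",
            "within_window": edge.within_window,
            "shift_score": "" if edge.shift_score is None else f"{edge.shift_score:.3f}",
            "preferred": edge.preferred,
            "ambiguous": edge.ambiguous,
            "evidence": ";".join(sorted(edge.evidence)),
        })
    pd.DataFrame(edge_rows).to_csv(edge_path, sep="\t", index=False)
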