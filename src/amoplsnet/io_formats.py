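"""Readers and writers for the formats an untargeted LC-MS/MS study touches.

The pipeline consumes the exports of a peak-picking tool (an aligned feature
quantification table in CSV and the paired MS/MS spectra in MGF), carries the
data through analysis in memory, and writes molecular networks to GraphML.
Two CSV dialects are supported for the feature table:

``mzmine_csv``
    Features as rows with ``row ID`` / ``row m/z`` / ``row retention time``
    header columns and one abundance column per sample, matched to sample ids
    by substring (export column names vary across tool versions, e.g.
    ``S01.mzML Peak area``).
``plain_csv``
    Samples as rows, first column ``sample_id``, one column per feature id;
    feature m/z and retention time come from a separate TSV.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from pyteomics import mgf as _mgf

logger = logging.getLogger(__name__)

SAMPLE_META_COLUMNS = ["sample_id", "cultivar", "date", "extract", "ion_mode", "is_qc", "replicate"]


@dataclass
class FeatureTable:
    """Samples x features intensity matrix plus sample and feature metadata.

    Parameters
    ----------
    intensities : pandas.DataFrame
        Non-negative areas, index = sample ids, columns = feature ids.
    sample_meta : pandas.DataFrame
        One row per sample; must carry at least ``sample_id`` and ``is_qc``;
        factor columns (``cultivar``, ``date``, ...) as present.
    feature_meta : pandas.DataFrame
        One row per feature with ``feature_id``, ``mz`` (Da) and ``rt`` (min).
    """

    intensities: pd.DataFrame
    sample_meta: pd.DataFrame
    feature_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.sample_meta = self.sample_meta.reset_index(drop=True)
        self.feature_meta = self.feature_meta.reset_index(drop=True)
        self.validate()

    def validate(self) -> None:
        ids = list(self.sample_meta["sample_id"])
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sample ids in sample_meta")
        fids = list(self.feature_meta["feature_id"])
        if len(set(fids)) != len(fids):
            raise ValueError("duplicate feature ids in feature_meta")
        if list(self.intensities.index) != ids:
            raise ValueError("intensity row index does not match sample_meta sample_id")
        if list(self.intensities.columns) != fids:
            raise ValueError("intensity columns do not match feature_meta feature_id")
        if (self.intensities.to_numpy() < 0).any():
            raise ValueError("negative intensities")

    # -- convenience accessors -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_features(self) -> int:
        return self.intensities.shape[1]

    @property
    def feature_ids(self) -> list[str]:
        return list(self.feature_meta["feature_id"])

    @property
    def sample_ids(self) -> list[str]:
        return list(self.sample_meta["sample_id"])

    def is_qc_mask(self) -> np.ndarray:
        return self.sample_meta["is_qc"].to_numpy(dtype=bool)

    def biological(self) -> "FeatureTable":
        """Subset to non-QC samples."""
        keep = ~self.is_qc_mask()
        return FeatureTable(
            self.intensities.loc[keep],
            self.sample_meta.loc[keep],
            self.feature_meta,
        )

    def copy_with(self, intensities: np.ndarray | pd.DataFrame) -> "FeatureTable":
        """New table with the same metadata and replaced intensity values."""
        mat = pd.DataFrame(
            np.asarray(intensities, dtype=float),
            index=self.intensities.index,
            columns=self.intensities.columns,
        )
        return FeatureTable(mat, self.sample_meta.copy(), self.feature_meta.copy())


@dataclass
class MsmsSpectrum:
    """One fragmentation spectrum keyed to a feature id.

    Peaks are kept sorted by fragment m/z; intensities are raw (no scaling).
    """

    feature_id: str
    precursor_mz: float
    rt: float
    peaks_mz: np.ndarray
    peaks_intensity: np.ndarray
    charge: int = 1

    def __post_init__(self) -> None:
        self.peaks_mz = np.asarray(self.peaks_mz, dtype=float)
        self.peaks_intensity = np.asarray(self.peaks_intensity, dtype=float)
        if self.peaks_mz.size == 0:
            raise ValueError(f"spectrum {self.feature_id}: no peaks")
        if (self.peaks_mz <= 0).any():
            raise ValueError(f"spectrum {self.feature_id}: non-positive fragment m/z")
        order = np.argsort(self.peaks_mz, kind="stable")
        self.peaks_mz = self.peaks_mz[order]
        self.peaks_intensity = self.peaks_intensity[order]

    @property
    def n_peaks(self) -> int:
        return int(self.peaks_mz.size)


def _read_sample_meta(path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if "sample_id" not in meta.columns:
        raise ValueError(f"{path}: sample metadata needs a 'sample_id' column")
    if "is_qc" in meta.columns:
        meta["is_qc"] = meta["is_qc"].astype(str).str.lower().isin(["true", "1", "yes"])
    else:
        meta["is_qc"] = False
    return meta


def read_feature_table(
    path: str | Path,
    sample_meta_path: str | Path,
    dialect: str = "mzmine_csv",
    feature_meta_path: str | Path | None = None,
) -> FeatureTable:
    """Read an aligned feature quantification table.

    Missing cells become 0 (the upstream export gap-fills; remaining holes are
    treated as absence) and the count is logged. Samples found in the matrix
    but missing from the metadata are a hard error, as are duplicated feature
    ids.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    meta = _read_sample_meta(sample_meta_path)

    if dialect == "mzmine_csv":
        raw = pd.read_csv(path)
        required = ["row ID", "row m/z", "row retention time"]
        for col in required:
            if col not in raw.columns:
                raise ValueError(f"{path}: mzmine_csv dialect needs column '{col}'")
        fids = raw["row ID"].astype(str)
        if fids.duplicated().any():
            dupes = sorted(fids[fids.duplicated()].unique())
            raise ValueError(f"duplicated feature ids: {dupes}")
        feature_meta = pd.DataFrame(
            {"feature_id": fids, "mz": raw["row m/z"].astype(float), "rt": raw["row retention time"].astype(float)}
        )
        sample_cols = [c for c in raw.columns if c not in required]
        # match per-sample area columns to metadata ids by substring
        col_for_sample: dict[str, str] = {}
        for sid in meta["sample_id"]:
            hits = [c for c in sample_cols if sid in c]
            if len(hits) > 1:
                exact = [c for c in hits if c == sid]
                if len(exact) == 1:
                    hits = exact
                else:
                    raise ValueError(f"sample id {sid!r} matches several columns: {hits}")
            if hits:
                col_for_sample[sid] = hits[0]
        claimed = set(col_for_sample.values())
        orphans = [c for c in sample_cols if c not in claimed]
        if orphans:
            raise ValueError(f"matrix columns without sample metadata: {orphans}")
        meta = meta[meta["sample_id"].isin(col_for_sample)].reset_index(drop=True)
        mat = raw[[col_for_sample[s] for s in meta["sample_id"]]].T
        mat.index = list(meta["sample_id"])
        mat.columns = list(feature_meta["feature_id"])
    elif dialect == "plain_csv":
        raw = pd.read_csv(path, dtype={"sample_id": str})
        if raw.columns[0] != "sample_id":
            raise ValueError(f"{path}: plain_csv dialect needs 'sample_id' as first column")
        if feature_meta_path is None:
            raise ValueError("plain_csv dialect needs feature_meta_path (TSV with feature_id, mz, rt)")
        feature_meta = pd.read_csv(feature_meta_path, sep="\t", dtype={"feature_id": str})
        fids = feature_meta["feature_id"]
        if fids.duplicated().any():
            raise ValueError(f"duplicated feature ids: {sorted(fids[fids.duplicated()].unique())}")
        missing_samples = [s for s in raw["sample_id"] if s not in set(meta["sample_id"])]
        if missing_samples:
            raise ValueError(f"samples present in matrix but absent from metadata: {missing_samples}")
        mat = raw.set_index("sample_id")[list(fids)]
        meta = meta[meta["sample_id"].isin(mat.index)].reset_index(drop=True)
        mat = mat.loc[list(meta["sample_id"])]
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    n_missing = int(mat.isna().to_numpy().sum())
    if n_missing:
        logger.warning("%s: %d missing intensity cells set to 0", path, n_missing)
        mat = mat.fillna(0.0)
    mat = mat.astype(float)
    return FeatureTable(mat, meta, feature_meta)


def write_feature_table(table: FeatureTable, path: str | Path, sample_meta_path: str | Path) -> None:
    """Write a table in the mzmine_csv dialect plus a sample-metadata TSV."""
    out = pd.DataFrame(
        {
            "row ID": table.feature_meta["feature_id"].to_numpy(),
            "row m/z": table.feature_meta["mz"].to_numpy(),
            "row retention time": table.feature_meta["rt"].to_numpy(),
        }
    )
    for sid in table.sample_ids:
        out[sid] = table.intensities.loc[sid].to_numpy()
    out.to_csv(path, index=False)
    table.sample_meta.to_csv(sample_meta_path, sep="\t", index=False)


# -- MGF -----------------------------------------------------------------------

def read_mgf(path: str | Path) -> list[MsmsSpectrum]:
    """Read MS/MS spectra; feature ids from FEATURE_ID=, falling back to SCANS=."""
    spectra: list[MsmsSpectrum] = []
    with _mgf.MGF(str(path)) as reader:
        for i, block in enumerate(reader):
            params = block["params"]
            if "pepmass" not in params or params["pepmass"][0] is None:
                raise ValueError(f"MGF block {i}: missing PEPMASS")
            fid = params.get("feature_id") or params.get("scans")
            if fid is None:
                raise ValueError(f"MGF block {i}: no FEATURE_ID or SCANS key")
            charge = 1
            if params.get("charge"):
                charge = int(params["charge"][0])
            rt = float(params.get("rtinseconds", 0.0)) / 60.0
            spectra.append(
                MsmsSpectrum(
                    feature_id=str(fid),
                    precursor_mz=float(params["pepmass"][0]),
                    rt=rt,
                    peaks_mz=block["m/z array"],
                    peaks_intensity=block["intensity array"],
                    charge=charge,
                )
            )
    return spectra


def write_mgf(spectra: Sequence[MsmsSpectrum], path: str | Path) -> None:
    entries = []
    for s in spectra:
        entries.append(
            {
                "m/z array": s.peaks_mz,
                "intensity array": s.peaks_intensity,
                "params": {
                    "feature_id": s.feature_id,
                    "pepmass": s.precursor_mz,
                    "rtinseconds": s.rt * 60.0,
                    "charge": s.charge,
                    "scans": s.feature_id,
                },
            }
        )
    _mgf.write(entries, str(path), file_mode="w")


# -- annotations ---------------------------------------------------------------

def read_annotations(path: str | Path, table: FeatureTable | None = None) -> pd.DataFrame:
    """Pass-through annotation table; unmatched feature ids are flagged."""
    ann = pd.read_csv(path, sep="\t", dtype={"feature_id": str})
    if "feature_id" not in ann.columns:
        raise ValueError(f"{path}: annotation table needs 'feature_id'")
    if table is not None:
        known = set(table.feature_ids)
        ann["unmatched"] = [fid not in known for fid in ann["feature_id"]]
    return ann


# -- GraphML -------------------------------------------------------------------

def write_graphml(network, path: str | Path) -> None:
    """Export a molecular network to GraphML (Cytoscape-readable).

    Node attributes: feature_id, mz, rt, total_intensity, per-group shares,
    marker_status. Edge attributes: cosine, matched_peaks, edge_type.
    """
    graph = network if isinstance(network, nx.Graph) else network.graph
    out = nx.Graph()
    for node, attrs in graph.nodes(data=True):
        clean = {k: (float(v) if isinstance(v, (np.floating, float)) else v) for k, v in attrs.items() if v is not None}
        out.add_node(node, **clean)
    for u, v, attrs in graph.edges(data=True):
        out.add_edge(u, v, **{k: (float(a) if isinstance(a, np.floating) else a) for k, a in attrs.items()})
    nx.write_graphml(out, str(path))


def read_graphml(path: str | Path) -> nx.Graph:
    return nx.read_graphml(str(path))
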