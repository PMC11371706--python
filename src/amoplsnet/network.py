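"""Feature-based molecular networking with ion-identity grouping.

Features whose MS/MS spectra are similar — modified cosine above a threshold
with a minimum number of matched fragment ions — are linked into a graph
whose connected components gather structurally related chemistry. The
modified cosine allows a fragment of one spectrum to match a fragment of the
other either directly or shifted by the difference of the precursor masses,
so that homologous fragments of related compounds still pair up. Intensities
are square-root transformed and each spectrum L2-normalised before matching
(the usual molecular-networking convention), and peak pairs are made
one-to-one greedily by descending intensity product.

A second edge type groups *ion identities*: features that are different
adducts of one compound. They co-elute (retention times within a tolerance),
their precursor m/z difference matches a characteristic adduct mass
difference, and their intensity profiles across samples co-vary (used here as
a proxy for shared chromatographic peak shape, which exported feature tables
no longer carry).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd

from .io_formats import FeatureTable, MsmsSpectrum
from .markers import MarkerSet

PROTON = 1.007276
# adduct masses relative to the neutral molecule M, positive mode
ADDUCT_MASS = {
    "[M+H]+": PROTON,
    "[M+NH4]+": 18.033823,
    "[M+Na]+": 22.989218,
    "[M-H2O+H]+": PROTON - 18.010565,
}


def default_adduct_diffs() -> dict[tuple[str, str], float]:
    """Absolute precursor m/z differences between all adduct pairs (charge 1)."""
    diffs = {}
    for (a, ma), (b, mb) in combinations(ADDUCT_MASS.items(), 2):
        diffs[(a, b)] = abs(ma - mb)
    return diffs


def modified_cosine(
    a: MsmsSpectrum,
    b: MsmsSpectrum,
    fragment_tol: float = 0.02,
    allow_precursor_shift: bool = True,
) -> tuple[float, int]:
    """Modified cosine similarity and number of matched peaks of two spectra.

    Candidate pairs are peaks within ``fragment_tol`` directly, plus (when
    ``allow_precursor_shift``) peaks whose difference matches the precursor
    mass difference within the same tolerance. Intensities are square-root
    transformed and L2-normalised per spectrum; pairs are accepted greedily by
    descending product, each peak used at most once. Symmetric in (a, b).
    """
    ia = np.sqrt(a.peaks_intensity)
    ib = np.sqrt(b.peaks_intensity)
    na, nb = np.linalg.norm(ia), np.linalg.norm(ib)
    if na == 0 or nb == 0:
        return 0.0, 0
    ia = ia / na
    ib = ib / nb
    shift = a.precursor_mz - b.precursor_mz

    dm = a.peaks_mz[:, None] - b.peaks_mz[None, :]
    cand = np.abs(dm) <= fragment_tol
    if allow_precursor_shift and shift != 0:
        cand |= np.abs(dm - shift) <= fragment_tol
    ii, jj = np.nonzero(cand)
    if ii.size == 0:
        return 0.0, 0
    products = ia[ii] * ib[jj]
    order = np.argsort(-products, kind="stable")
    used_a: set[int] = set()
    used_b: set[int] = set()
    score = 0.0
    matched = 0
    for k in order:
        i, j = int(ii[k]), int(jj[k])
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        score += float(products[k])
        matched += 1
    return min(score, 1.0), matched


@dataclass
class MolecularNetwork:
    """Graph of features with spectral and ion-identity edges."""

    graph: nx.Graph

    @property
    def components(self) -> list[set[str]]:
        return [set(c) for c in nx.connected_components(self.graph)]

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


def build_network(
    spectra: list[MsmsSpectrum],
    precursor_tol: float = 0.02,
    fragment_tol: float = 0.02,
    min_matched: int = 6,
    min_cosine: float = 0.7,
    allow_precursor_shift: bool = True,
) -> MolecularNetwork:
    """All-vs-all modified cosine; keep edges at or above both thresholds.

    Every input feature becomes a node (singletons allowed). Thresholds are
    inclusive: an edge at exactly ``min_cosine`` with exactly ``min_matched``
    matched peaks is kept.
    """
    ids = [s.feature_id for s in spectra]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate feature ids in spectra: {dupes}")
    g = nx.Graph()
    for s in spectra:
        g.add_node(s.feature_id, mz=float(s.precursor_mz), rt=float(s.rt))
    for a, b in combinations(spectra, 2):
        cos, matched = modified_cosine(a, b, fragment_tol, allow_precursor_shift)
        if cos >= min_cosine and matched >= min_matched:
            g.add_edge(a.feature_id, b.feature_id, cosine=float(cos), matched_peaks=int(matched), edge_type="spectral")
    return MolecularNetwork(graph=g)


def group_ion_identities(
    table: FeatureTable,
    spectra: list[MsmsSpectrum],
    adduct_diffs: dict[tuple[str, str], float] | None = None,
    rt_tol: float = 0.1,
    precursor_tol: float = 0.02,
    min_corr: float = 0.8,
) -> list[tuple[str, str, dict]]:
    """Edges linking features that look like adduct variants of one compound.

    Two features are linked when they co-elute (|drt| <= rt_tol), their
    precursor m/z difference matches one of the characteristic adduct-pair
    differences within ``precursor_tol``, and the Pearson correlation of
    their intensity profiles over biological samples is >= ``min_corr``.
    Returns (source, target, attrs) triples with edge_type "ion_identity".
    """
    if adduct_diffs is None:
        adduct_diffs = default_adduct_diffs()
    diffs = np.array(sorted(set(adduct_diffs.values())))
    bio = table.biological()
    inten = bio.intensities
    edges = []
    known = set(table.feature_ids)
    usable = [s for s in spectra if s.feature_id in known]
    for a, b in combinations(usable, 2):
        if abs(a.rt - b.rt) > rt_tol:
            continue
        dmz = abs(a.precursor_mz - b.precursor_mz)
        if not np.any(np.abs(diffs - dmz) <= precursor_tol):
            continue
        xa = inten[a.feature_id].to_numpy(dtype=float)
        xb = inten[b.feature_id].to_numpy(dtype=float)
        if xa.std() == 0 or xb.std() == 0:
            continue
        r = float(np.corrcoef(xa, xb)[0, 1])
        if r >= min_corr:
            edges.append((a.feature_id, b.feature_id, {"correlation": r, "mz_diff": float(dmz), "edge_type": "ion_identity"}))
    return edges


def add_ion_identity_edges(network: MolecularNetwork, edges: list[tuple[str, str, dict]]) -> MolecularNetwork:
    """Merge ion-identity edges into the graph; spectral edges take precedence."""
    for u, v, attrs in edges:
        if not network.graph.has_edge(u, v):
            network.graph.add_edge(u, v, **attrs)
    return network


@dataclass
class ClusterStats:
    n_components_ge3: int
    fraction_in_ge3: float
    n_features: int
    marker_counts: dict[int, int] = field(default_factory=dict)   # component idx -> marker count
    components_ge3_markers: list[int] = field(default_factory=list)
    component_sizes: list[int] = field(default_factory=list)


def cluster_stats(network: MolecularNetwork, min_size: int = 3, min_markers: int = 3) -> ClusterStats:
    """Cluster-level summary: how much of the feature space aggregates.

    Reports the number of connected components with >= ``min_size`` nodes, the
    fraction of features inside them, per-component marker counts (using the
    ``marker_status`` node attribute when present), and which components carry
    >= ``min_markers`` markers.
    """
    comps = sorted(network.components, key=lambda c: (-len(c), sorted(c)[0] if c else ""))
    n_feat = network.n_nodes
    big = [c for c in comps if len(c) >= min_size]
    in_big = sum(len(c) for c in big)
    marker_counts = {}
    flagged = []
    for idx, comp in enumerate(comps):
        count = sum(
            1
            for node in comp
            if network.graph.nodes[node].get("marker_status", "none") in ("attractive", "unattractive")
        )
        marker_counts[idx] = count
        if count >= min_markers and len(comp) >= min_size:
            flagged.append(idx)
    return ClusterStats(
        n_components_ge3=len(big),
        fraction_in_ge3=(in_big / n_feat) if n_feat else 0.0,
        n_features=n_feat,
        marker_counts=marker_counts,
        components_ge3_markers=flagged,
        component_sizes=[len(c) for c in comps],
    )


def decorate_nodes(
    network: MolecularNetwork,
    table: FeatureTable,
    markers: MarkerSet | None = None,
    grouping: list[str] = ("cultivar",),
) -> MolecularNetwork:
    """Attach intensity totals, per-group intensity shares and marker status.

    ``total_intensity`` sums over biological samples only; the share of each
    group (e.g. each cultivar, or each cultivar x date cell) is the group sum
    over the total. Features present in the graph but absent from the table
    are flagged ``missing_from_table`` with null shares.
    """
    grouping = list(grouping)
    bio = table.biological()
    for col in grouping:
        if col not in bio.sample_meta.columns:
            raise ValueError(f"grouping factor {col!r} not in sample metadata")
    if len(grouping) == 1:
        group_keys = bio.sample_meta[grouping[0]].astype(str)
    else:
        group_keys = bio.sample_meta[grouping].astype(str).agg("|".join, axis=1)
    group_keys = group_keys.to_numpy()
    known = set(table.feature_ids)
    for node in network.graph.nodes:
        attrs = network.graph.nodes[node]
        if node not in known:
            attrs["missing_from_table"] = True
            attrs["marker_status"] = markers.status_of(node) if markers else "none"
            continue
        x = bio.intensities[node].to_numpy(dtype=float)
        total = float(x.sum())
        attrs["total_intensity"] = total
        if total > 0:
            for gname in dict.fromkeys(group_keys):
                attrs[f"share_{gname}"] = float(x[group_keys == gname].sum() / total)
        else:
            attrs["zero_intensity"] = True
        attrs["marker_status"] = markers.status_of(node) if markers else "none"
    return network
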