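import numpy as np
import pandas as pd
import pytest
from scipy.optimize import linear_sum_assignment

from amoplsnet import (
    FeatureTable,
    MsmsSpectrum,
    build_network,
    cluster_stats,
    decorate_nodes,
    default_adduct_diffs,
    group_ion_identities,
    modified_cosine,
)
from amoplsnet.markers import MarkerRecord, merge_marker_sets
from amoplsnet.network import MolecularNetwork
from amoplsnet.synthetic import SpectralFamilySpec, generate_design, generate_feature_table, generate_spectra


def _random_spectrum(rng, n_peaks, fid="S"):
    return MsmsSpectrum(
        fid,
        precursor_mz=float(rng.uniform(300, 800)),
        rt=float(rng.uniform(0, 10)),
        peaks_mz=rng.uniform(50, 400, size=n_peaks),
        peaks_intensity=rng.uniform(1e2, 1e6, size=n_peaks),
    )


def _oracle_cosine(a, b, tol=0.02, allow_shift=True):
    """Optimal one-to-one matching over all candidate pairs (assignment oracle)."""
    ia = np.sqrt(a.peaks_intensity)
    ib = np.sqrt(b.peaks_intensity)
    ia = ia / np.linalg.norm(ia)
    ib = ib / np.linalg.norm(ib)
    shift = a.precursor_mz - b.precursor_mz
    dm = a.peaks_mz[:, None] - b.peaks_mz[None, :]
    cand = np.abs(dm) <= tol
    if allow_shift and shift != 0:
        cand |= np.abs(dm - shift) <= tol
    w = np.where(cand, ia[:, None] * ib[None, :], 0.0)
    rows, cols = linear_sum_assignment(w, maximize=True)
    return float(w[rows, cols].sum())


def test_self_similarity_is_one():
    rng = np.random.default_rng(0)
    s = _random_spectrum(rng, 11)
    cos, matched = modified_cosine(s, s)
    assert cos == pytest.approx(1.0, abs=1e-9)
    assert matched == 11


def test_disjoint_spectra_score_zero():
    a = MsmsSpectrum("a", 500.0, 1.0, np.array([100.0, 110.0]), np.array([1.0, 1.0]))
    b = MsmsSpectrum("b", 500.0, 1.0, np.array([200.0, 210.0]), np.array([1.0, 1.0]))
    assert modified_cosine(a, b) == (0.0, 0)


def test_greedy_matches_assignment_oracle_on_random_spectra():
    """Greedy one-to-one pairing tracks the optimal assignment on small spectra."""
    rng = np.random.default_rng(42)
    worst = 0.0
    for _ in range(100):
        a = _random_spectrum(rng, int(rng.integers(3, 6)), "a")
        b = _random_spectrum(rng, int(rng.integers(3, 6)), "b")
        # overlay some shared peaks so candidate structure is non-trivial
        k = int(rng.integers(1, 4))
        b.peaks_mz[:k] = a.peaks_mz[:k] + rng.uniform(-0.015, 0.015, size=k)
        b.peaks_mz = np.sort(b.peaks_mz)
        greedy, _ = modified_cosine(a, b)
        oracle = _oracle_cosine(a, b)
        assert greedy <= oracle + 1e-9  # greedy can never beat the optimum
        worst = max(worst, oracle - greedy)
    assert worst <= 1e-9, f"greedy diverged from optimal assignment by {worst}"


def test_cosine_symmetry():
    rng = np.random.default_rng(7)
    for _ in range(20):
        a = _random_spectrum(rng, 8, "a")
        b = _random_spectrum(rng, 6, "b")
        ab = modified_cosine(a, b)
        ba = modified_cosine(b, a)
        assert ab[0] == pytest.approx(ba[0], abs=1e-12)
        assert ab[1] == ba[1]


def test_matches_matchms_reference_implementation():
    """Cross-check against the community modified-cosine implementation."""
    matchms = pytest.importorskip("matchms")
    from matchms.similarity import ModifiedCosine

    rng = np.random.default_rng(3)
    sim = ModifiedCosine(tolerance=0.02)
    for _ in range(25):
        a = _random_spectrum(rng, 9, "a")
        b = _random_spectrum(rng, 7, "b")
        k = int(rng.integers(2, 6))
        b.peaks_mz[:k] = np.clip(a.peaks_mz[:k] + rng.uniform(-0.01, 0.01, size=k), 1, None)
        order = np.argsort(b.peaks_mz)
        b.peaks_mz, b.peaks_intensity = b.peaks_mz[order], b.peaks_intensity[order]
        ours, n_ours = modified_cosine(a, b)
        ma = matchms.Spectrum(mz=a.peaks_mz, intensities=np.sqrt(a.peaks_intensity),
                              metadata={"precursor_mz": a.precursor_mz}, metadata_harmonization=False)
        mb = matchms.Spectrum(mz=b.peaks_mz, intensities=np.sqrt(b.peaks_intensity),
                              metadata={"precursor_mz": b.precursor_mz}, metadata_harmonization=False)
        ref = sim.pair(ma, mb)
        assert ours == pytest.approx(float(ref["score"]), abs=1e-6)
        assert n_ours == int(ref["matches"])


def test_edge_kept_exactly_at_thresholds():
    """cosine == min_cosine with matched == min_matched is inclusive."""
    rng = np.random.default_rng(1)
    mz = np.sort(rng.uniform(100, 400, 6))
    inten = np.full(6, 100.0)
    a = MsmsSpectrum("a", 500.0, 1.0, mz, inten)
    b = MsmsSpectrum("b", 500.0, 1.1, mz.copy(), inten.copy())
    cos, matched = modified_cosine(a, b)
    assert cos == pytest.approx(1.0, abs=1e-9) and matched == 6
    # threshold set to the pair's exact score: the edge must be kept (>=, not >)
    net = build_network([a, b], min_matched=6, min_cosine=cos)
    assert net.n_edges == 1
    net_above = build_network([a, b], min_matched=7, min_cosine=cos)
    assert net_above.n_edges == 0


def test_impossible_cosine_threshold_gives_singletons():
    spectra, _ = generate_spectra([SpectralFamilySpec("F1", n_members=3)], decoy_n=2, seed=0)
    net = build_network(spectra, min_cosine=1.01)
    assert net.n_edges == 0
    assert all(len(c) == 1 for c in net.components)


def test_edge_count_monotone_in_thresholds():
    spectra, _ = generate_spectra(
        [SpectralFamilySpec("F1", n_members=4), SpectralFamilySpec("F2", n_members=4)], decoy_n=8, seed=5
    )
    counts_cos = [build_network(spectra, min_cosine=c).n_edges for c in (0.5, 0.7, 0.9)]
    assert counts_cos == sorted(counts_cos, reverse=True)
    counts_match = [build_network(spectra, min_matched=m).n_edges for m in (4, 6, 9)]
    assert counts_match == sorted(counts_match, reverse=True)


def test_network_order_invariant():
    rng = np.random.default_rng(9)
    spectra, _ = generate_spectra([SpectralFamilySpec("F1", n_members=4)], decoy_n=5, seed=9)
    net1 = build_network(spectra)
    shuffled = list(spectra)
    rng.shuffle(shuffled)
    net2 = build_network(shuffled)
    e1 = {tuple(sorted(e)): round(net1.graph.edges[e]["cosine"], 12) for e in net1.graph.edges}
    e2 = {tuple(sorted(e)): round(net2.graph.edges[e]["cosine"], 12) for e in net2.graph.edges}
    assert e1 == e2


def test_duplicate_feature_ids_rejected():
    rng = np.random.default_rng(0)
    pair = [_random_spectrum(rng, 5, "same"), _random_spectrum(rng, 5, "same")]
    with pytest.raises(ValueError, match="duplicate"):
        build_network(pair)


# -- ion identity -------------------------------------------------------------

def _adduct_table_and_spectra(rt_shift=0.0, correlated=True):
    design = generate_design(2, 2, 3, 1, seed=0)
    table, _ = generate_feature_table(design, 3, [], noise_sd=0.4, dilution_sd=0.0, seed=0)
    X = table.intensities.to_numpy().copy()
    if correlated:
        X[:, 1] = X[:, 0] * 0.35  # F0002 is an adduct of F0001: proportional profile
    table = table.copy_with(X)
    diffs = default_adduct_diffs()
    delta = diffs[("[M+H]+", "[M+Na]+")]
    spectra = [
        MsmsSpectrum("F0001", 501.0, 2.0, np.array([100.0]), np.array([1.0])),
        MsmsSpectrum("F0002", 501.0 + delta, 2.0 + rt_shift, np.array([110.0]), np.array([1.0])),
        MsmsSpectrum("F0003", 777.0, 5.0, np.array([120.0]), np.array([1.0])),
    ]
    return table, spectra


def test_adduct_pair_linked_and_rt_decoy_rejected():
    table, spectra = _adduct_table_and_spectra()
    edges = group_ion_identities(table, spectra)
    assert [(e[0], e[1]) for e in edges] == [("F0001", "F0002")]
    assert edges[0][2]["edge_type"] == "ion_identity"
    # same mass delta but eluting far apart: not an adduct pair
    table2, spectra2 = _adduct_table_and_spectra(rt_shift=1.0)
    assert group_ion_identities(table2, spectra2) == []


def test_uncorrelated_profiles_not_linked():
    table, spectra = _adduct_table_and_spectra(correlated=False)
    assert group_ion_identities(table, spectra) == []


def test_rt_tol_zero_with_jitter_gives_no_edges():
    table, spectra = _adduct_table_and_spectra(rt_shift=0.004)
    assert group_ion_identities(table, spectra, rt_tol=0.0) == []


def test_no_self_loops():
    table, spectra = _adduct_table_and_spectra()
    for u, v, _ in group_ion_identities(table, spectra):
        assert u != v


# -- cluster stats and decoration ---------------------------------------------

def _flood_fill_components(graph):
    seen, comps = set(), []
    for start in graph.nodes:
        if start in seen:
            continue
        stack, comp = [start], set()
        while stack:
            n = stack.pop()
            if n in comp:
                continue
            comp.add(n)
            stack.extend(graph.neighbors(n))
        seen |= comp
        comps.append(comp)
    return comps


def test_cluster_arithmetic():
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(f"single{i}" for i in range(10))
    g.add_edges_from([("a", "b"), ("b", "c"), ("c", "d"), ("d", "e")])
    stats = cluster_stats(MolecularNetwork(g))
    assert stats.n_components_ge3 == 1
    assert stats.fraction_in_ge3 == pytest.approx(5 / 15)


def test_component_count_matches_flood_fill_oracle():
    import networkx as nx

    rng = np.random.default_rng(11)
    for _ in range(50):
        g = nx.gnp_random_graph(12, 0.15, seed=int(rng.integers(0, 1 << 31)))
        net = MolecularNetwork(nx.relabel_nodes(g, str))
        assert len(net.components) == len(_flood_fill_components(net.graph))


def test_empty_network_stats():
    import networkx as nx

    stats = cluster_stats(MolecularNetwork(nx.Graph()))
    assert stats.n_components_ge3 == 0 and stats.fraction_in_ge3 == 0.0


def test_decorated_shares_sum_to_one_and_reflect_expression():
    import networkx as nx

    design = generate_design(4, 2, 2, 1, seed=3)
    table, _ = generate_feature_table(design, 4, [], noise_sd=0.1, dilution_sd=0.0, seed=3)
    X = table.intensities.to_numpy().copy()
    bio_mask = ~table.is_qc_mask()
    only_cv2 = (table.sample_meta["cultivar"] == "CV2").to_numpy()
    X[bio_mask & ~only_cv2, 0] = 0.0  # feature 1 expressed only in CV2
    table = table.copy_with(X)
    g = nx.Graph()
    g.add_nodes_from(table.feature_ids)
    markers = merge_marker_sets([[MarkerRecord("F0002", "ds", "tp1", 1.0, "attractive")]])
    net = decorate_nodes(MolecularNetwork(g), table, markers, grouping=["cultivar"])
    attrs = net.graph.nodes["F0001"]
    assert attrs["share_CV2"] == pytest.approx(1.0)
    shares = [v for k, v in attrs.items() if k.startswith("share_")]
    assert sum(shares) == pytest.approx(1.0, abs=1e-9)
    assert net.graph.nodes["F0002"]["marker_status"] == "attractive"
    assert net.graph.nodes["F0003"]["marker_status"] == "none"


def test_unattractive_enriched_feature_shares_fall_on_planted_cultivars():
    """Pie-chart reading: a feature planted high in unattractive cultivars
    has its two largest cultivar shares on those cultivars."""
    import networkx as nx
    from amoplsnet.synthetic import EffectSpec

    design = generate_design(4, 2, 3, 1, seed=8)
    spec = EffectSpec("cultivar", np.array([0]), {"CV1": -1.0, "CV2": -1.0, "CV3": 1.0, "CV4": 1.0})
    table, _ = generate_feature_table(design, 3, [spec], noise_sd=0.1, dilution_sd=0.0, seed=8)
    g = nx.Graph()
    g.add_nodes_from(table.feature_ids)
    net = decorate_nodes(MolecularNetwork(g), table, None, grouping=["cultivar"])
    shares = {cv: net.graph.nodes["F0001"][f"share_{cv}"] for cv in ("CV1", "CV2", "CV3", "CV4")}
    top2 = sorted(shares, key=shares.get, reverse=True)[:2]
    assert set(top2) == {"CV3", "CV4"}
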