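import numpy as np
import pandas as pd
import pytest

from amoplsnet import (
    anova_decompose,
    component_summary,
    fit_amopls,
    permutation_test,
    pqn_normalize,
    uv_scale,
)
from amoplsnet.synthetic import EffectSpec, generate_design, generate_feature_table


def _brute_force_decompose(X, design):
    """Explicit-loop cell/level means, the independent oracle."""
    Xc = X - X.mean(axis=0)
    n = X.shape[0]
    out = {}
    for factor in ("cultivar", "date"):
        mat = np.zeros_like(Xc)
        for i in range(n):
            rows = [j for j in range(n) if design[factor][j] == design[factor][i]]
            mat[i] = Xc[rows].mean(axis=0)
        out[factor] = mat
    inter = np.zeros_like(Xc)
    for i in range(n):
        rows = [
            j
            for j in range(n)
            if design["cultivar"][j] == design["cultivar"][i] and design["date"][j] == design["date"][i]
        ]
        inter[i] = Xc[rows].mean(axis=0) - out["cultivar"][i] - out["date"][i]
    out["cultivar:date"] = inter
    out["residuals"] = Xc - out["cultivar"] - out["date"] - inter
    return out


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_decomposition_matches_brute_force(seed):
    design = generate_design(4, 4, 3, 0, seed=seed)
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(len(design), 9))
    dec = anova_decompose(X, design)
    oracle = _brute_force_decompose(X, design)
    for eff in ("cultivar", "date", "cultivar:date"):
        np.testing.assert_allclose(dec.effect_matrices[eff], oracle[eff], atol=1e-9)
    np.testing.assert_allclose(dec.residuals, oracle["residuals"], atol=1e-9)


def test_decomposition_exact_and_orthogonal():
    """Blocks reassemble the centered matrix; all pairs mutually orthogonal."""
    design = generate_design(4, 4, 3, 0, seed=5)
    rng = np.random.default_rng(5)
    X = rng.normal(size=(len(design), 20))
    dec = anova_decompose(X, design)
    Xc = X - X.mean(axis=0)
    total = sum(dec.effect_matrices.values()) + dec.residuals
    assert np.linalg.norm(Xc - total) < 1e-9 * np.linalg.norm(Xc)
    assert sum(dec.rss.values()) == pytest.approx(100.0, abs=1e-9)
    blocks = list(dec.effect_matrices.values()) + [dec.residuals]
    norm2 = np.linalg.norm(Xc) ** 2
    for i in range(len(blocks)):
        for j in range(i + 1, len(blocks)):
            assert abs(np.sum(blocks[i] * blocks[j])) < 1e-8 * norm2


def test_pure_effect_rss():
    """A matrix that is constant within cultivar levels is 100% cultivar."""
    design = generate_design(4, 2, 2, 0, seed=0)
    offsets = {"CV1": 3.0, "CV2": 1.0, "CV3": -1.0, "CV4": -3.0}
    X = np.array([[offsets[c]] * 5 for c in design["cultivar"]], dtype=float)
    dec = anova_decompose(X, design)
    assert dec.rss["cultivar"] == pytest.approx(100.0, abs=1e-9)
    for other in ("date", "cultivar:date", "residuals"):
        assert dec.rss[other] == pytest.approx(0.0, abs=1e-9)


def test_rss_invariances():
    """RSS unchanged under feature permutation and orthogonal rotation."""
    design = generate_design(3, 2, 2, 0, seed=1)
    rng = np.random.default_rng(1)
    X = rng.normal(size=(len(design), 10))
    base = anova_decompose(X, design).rss
    perm = anova_decompose(X[:, rng.permutation(10)], design).rss
    Qr, _ = np.linalg.qr(rng.normal(size=(10, 10)))
    rot = anova_decompose(X @ Qr, design).rss
    for eff in base:
        assert perm[eff] == pytest.approx(base[eff], abs=1e-9)
        assert rot[eff] == pytest.approx(base[eff], abs=1e-9)


def test_decompose_errors():
    design = generate_design(2, 2, 2, 0, seed=0)
    with pytest.raises(ValueError, match="constant"):
        anova_decompose(np.ones((len(design), 3)), design)
    broken = design.copy()
    broken.loc[broken["cultivar"] == "CV1", "date"] = "D1"  # empties CV1 x D2
    with pytest.raises(ValueError, match="empty"):
        anova_decompose(np.random.default_rng(0).normal(size=(len(design), 3)), broken)


# -- model structure ----------------------------------------------------------

@pytest.fixture(scope="module")
def fitted():
    design = generate_design(4, 4, 3, 0, seed=11)
    rng = np.random.default_rng(11)
    X = rng.normal(size=(len(design), 60))
    amp = {"CV1": 1.0, "CV2": 0.5, "CV3": -0.5, "CV4": -1.0}
    X[:, :20] += np.array([amp[c] for c in design["cultivar"]])[:, None]
    dmp = {"D1": -0.8, "D2": -0.2, "D3": 0.2, "D4": 0.8}
    X[:, 20:40] += np.array([dmp[d] for d in design["date"]])[:, None]
    return design, X, fit_amopls(X, design)


def test_salience_columns_sum_to_100(fitted):
    """Block contributions are percentages summing to 100 per component."""
    _, _, model = fitted
    np.testing.assert_allclose(model.saliences.sum(axis=0), 100.0, atol=1e-9)


def test_auto_predictive_component_count(fitted):
    """Main effects with 4 levels each give (4-1)+(4-1)=6 predictive components."""
    _, _, model = fitted
    assert model.predictive_components == [f"tp{i}" for i in range(1, 7)]
    assert model.orthogonal_components == ["to1"]


def test_predictive_scores_mutually_orthogonal(fitted):
    _, _, model = fitted
    T = model.scores[model.predictive_components].to_numpy()
    for i in range(T.shape[1]):
        for j in range(i + 1, T.shape[1]):
            bound = 1e-8 * np.linalg.norm(T[:, i]) * np.linalg.norm(T[:, j])
            assert abs(T[:, i] @ T[:, j]) < max(bound, 1e-12)


def test_orthogonal_scores_uncorrelated_with_response(fitted):
    _, _, model = fitted
    to = model.scores[model.orthogonal_components].to_numpy()
    cov = to.T @ model.Y
    assert np.abs(cov).max() < 1e-8


def test_planted_effect_dominates_first_component():
    """Pure cultivar structure + tiny noise: cultivar salience >= 95%."""
    design = generate_design(4, 2, 2, 0, seed=3)
    amp = {"CV1": 2.0, "CV2": 1.0, "CV3": -1.0, "CV4": -2.0}
    for seed in range(1, 11):
        rng = np.random.default_rng(seed)
        X = rng.normal(scale=0.01, size=(len(design), 12))
        X += np.array([amp[c] for c in design["cultivar"]])[:, None]
        model = fit_amopls(X, design)
        summary = component_summary(model)
        top = summary.loc["cultivar", "top_component"]
        assert model.saliences.loc["cultivar", top] >= 95.0


def test_single_block_limit_matches_eigen_oracle():
    """One effect, no residual block: scores match the direct eigen solution."""
    rng = np.random.default_rng(4)
    design = pd.DataFrame({"g": np.repeat(["a", "b"], 5)})
    X = rng.normal(size=(10, 8))
    model = fit_amopls(X, design, effects=["g"], n_orthogonal=0)
    # oracle: plain OPLS predictive part = eigenvectors of P_Y (Xg Xg') P_Y
    dec = anova_decompose(X, design, ["g"])
    Xg = dec.effect_matrices["g"]
    Y = (design["g"] == "a").to_numpy(dtype=float)[:, None]
    Yc = Y - Y.mean(axis=0)
    P = Yc @ np.linalg.pinv(Yc.T @ Yc) @ Yc.T
    w = 1.0 / np.linalg.norm(Xg @ Xg.T)
    vals, vecs = np.linalg.eigh(P @ (w * Xg @ Xg.T) @ P)
    t_oracle = vecs[:, -1] * np.sqrt(vals[-1])
    t_fit = model.scores["tp1"].to_numpy()
    assert min(np.linalg.norm(t_fit - t_oracle), np.linalg.norm(t_fit + t_oracle)) < 1e-8


def test_n_predictive_exceeding_rank_errors():
    design = generate_design(2, 2, 2, 0, seed=0)
    X = np.random.default_rng(0).normal(size=(len(design), 5))
    with pytest.raises(ValueError, match="rank"):
        fit_amopls(X, design, n_predictive=5)


def test_parameter_recovery_planted_rss():
    """Planted 10% cultivar / 18% date shares recovered within +-5 points."""
    hits = 0
    for seed in range(1, 11):
        design = generate_design(4, 4, 3, 4, seed=seed)
        effects = [
            EffectSpec("cultivar", np.arange(0, 60), {"CV1": 1, "CV2": 1, "CV3": -1, "CV4": -1},
                       target_rss_share=0.10),
            EffectSpec("date", np.arange(60, 140), {"D1": -1.5, "D2": -0.5, "D3": 0.5, "D4": 1.5},
                       target_rss_share=0.18),
        ]
        table, _ = generate_feature_table(design, 300, effects, noise_sd=0.2, dilution_sd=0.3, seed=seed)
        bio = pqn_normalize(table).normalized.biological()
        scaled, *_ = uv_scale(bio.intensities.to_numpy())
        model = fit_amopls(scaled, bio.sample_meta)
        assert model.rss["cultivar"] == pytest.approx(10.0, abs=5.0)
        assert model.rss["date"] == pytest.approx(18.0, abs=5.0)
        top = component_summary(model).loc["cultivar", "top_component"]
        sal = model.saliences[top]
        if sal["cultivar"] == sal.max():
            hits += 1
    assert hits >= 9


def test_permutation_power_and_bounds():
    design = generate_design(4, 2, 3, 0, seed=1)
    rng = np.random.default_rng(2)
    X = rng.normal(size=(len(design), 40))
    amp = {"CV1": 2.0, "CV2": 1.0, "CV3": -1.0, "CV4": -2.0}
    X[:, :20] += np.array([amp[c] for c in design["cultivar"]])[:, None]
    p = permutation_test(X, design, ["cultivar", "date", "cultivar:date"], "cultivar", n_perm=199, seed=3)
    assert p <= 0.005
    assert 1.0 / 200 <= p <= 1.0
    with pytest.raises(ValueError, match="not among"):
        permutation_test(X, design, ["cultivar", "date"], "nope", n_perm=99)
    with pytest.raises(ValueError, match="at least 99"):
        permutation_test(X, design, ["cultivar", "date"], "cultivar", n_perm=10)


def test_summary_component_separates_labels(fitted):
    """The cultivar top component separates cultivars better than any other."""
    from sklearn.metrics import silhouette_score

    design, _, model = fitted
    top = component_summary(model).loc["cultivar", "top_component"]
    labels = design["cultivar"].to_numpy()
    scores = {
        c: silhouette_score(model.scores[[c]].to_numpy(), labels)
        for c in model.predictive_components
    }
    # allow float-level ties between components that separate equally well
    assert scores[top] >= max(scores.values()) - 1e-6


def test_summary_invariant_to_block_ordering(fitted):
    design, X, model = fitted
    alt = fit_amopls(X, design, effects=["date", "cultivar", "cultivar:date"])
    s1 = component_summary(model)
    s2 = component_summary(alt)
    for eff in ("cultivar", "date", "cultivar:date", "residuals"):
        assert s2.loc[eff, "rss_pct"] == pytest.approx(s1.loc[eff, "rss_pct"], abs=1e-9)
    assert s2.loc["cultivar", "top_component"] == s1.loc["cultivar", "top_component"]
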