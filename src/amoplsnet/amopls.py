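"""ANOVA-multiblock orthogonal PLS (AMOPLS) for designed omics experiments.

The centered data matrix is first decomposed into additive ANOVA effect
submatrices (one per design factor, optionally their interaction) plus
residuals; in a balanced design these blocks are mutually orthogonal and
their squared Frobenius norms partition the total sum of squares, giving each
effect's relative sum of squares (RSS).

The blocks — effects *and* residuals — are then combined into a consensus
kernel K = sum_b w_b X_b X_b', each block kernel scaled to unit Frobenius
norm so the residual block (usually the largest RSS) cannot dominate, and a
kernel OPLS is fitted against a dummy response Y encoding the main-effect
level memberships:

* predictive scores are the leading eigenvectors of P_Y K P_Y (the kernel
  projected onto the response space), scaled by the square root of their
  eigenvalue — they maximise design-related kernel variance and are exactly
  mutually orthogonal;
* orthogonal scores are the leading eigenvectors of (I - P_Y) K (I - P_Y),
  structured variation unrelated to the design.

For every component, the *block contribution* (salience) of block b is
w_b t' X_b X_b' t normalised over blocks to 100%: how much of that
component's variance each effect drives. Feature loadings are computed
against the full scaled matrix, one value per feature per component. Effect
significance is assessed by permutation of the effect's level labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

INTERACTION_SEP = ":"


def _effect_columns(effect: str) -> list[str]:
    return effect.split(INTERACTION_SEP)


def _level_codes(design: pd.DataFrame, factors: list[str]) -> tuple[np.ndarray, list]:
    """Integer cell codes (and level keys) for a factor or factor combination."""
    if len(factors) == 1:
        keys = design[factors[0]].astype(str).tolist()
    else:
        keys = list(map(tuple, design[factors].astype(str).to_numpy()))
    levels = list(dict.fromkeys(keys))  # first-appearance order, deterministic
    lut = {lv: i for i, lv in enumerate(levels)}
    return np.array([lut[k] for k in keys]), levels


def _group_mean_rows(Xc: np.ndarray, codes: np.ndarray) -> np.ndarray:
    """Row i = mean of Xc over the samples sharing sample i's group code."""
    n_groups = codes.max() + 1
    sums = np.zeros((n_groups, Xc.shape[1]))
    np.add.at(sums, codes, Xc)
    counts = np.bincount(codes, minlength=n_groups).astype(float)
    means = sums / counts[:, None]
    return means[codes]


@dataclass
class AnovaDecomposition:
    """Additive decomposition X - grand_mean = sum of effect matrices + residuals."""

    grand_mean: np.ndarray
    effect_matrices: dict[str, np.ndarray]
    residuals: np.ndarray
    rss: dict[str, float]  # percentages over effects + "residuals", sums to 100

    @property
    def centered(self) -> np.ndarray:
        total = self.residuals.copy()
        for mat in self.effect_matrices.values():
            total += mat
        return total


def anova_decompose(
    X: np.ndarray,
    design: pd.DataFrame,
    effects: tuple[str, ...] | list[str] = ("cultivar", "date", "cultivar:date"),
) -> AnovaDecomposition:
    """Decompose X into per-effect matrices of level means plus residuals.

    ``effects`` names factor columns of ``design``; an interaction is written
    ``"A:B"`` and its matrix holds cell means minus both main-effect matrices.
    RSS of each block is its squared Frobenius norm as a percentage of the
    centered matrix's.
    """
    X = np.asarray(X, dtype=float)
    if X.shape[0] != len(design):
        raise ValueError("X rows and design rows differ")
    grand = X.mean(axis=0)
    Xc = X - grand
    total_ss = float((Xc**2).sum())
    if total_ss == 0:
        raise ValueError("constant matrix: nothing to decompose")

    mains = [e for e in effects if INTERACTION_SEP not in e]
    inters = [e for e in effects if INTERACTION_SEP in e]
    mats: dict[str, np.ndarray] = {}
    for eff in mains:
        codes, levels = _level_codes(design, [eff])
        if len(levels) < 2:
            raise ValueError(f"factor {eff!r} has fewer than 2 levels")
        mats[eff] = _group_mean_rows(Xc, codes)
    for eff in inters:
        factors = _effect_columns(eff)
        codes, levels = _level_codes(design, factors)
        n_cells_expected = 1
        for f in factors:
            n_cells_expected *= design[f].nunique()
        if len(levels) < n_cells_expected:
            raise ValueError(f"interaction {eff!r}: empty design cells")
        cell = _group_mean_rows(Xc, codes)
        for f in factors:
            cell = cell - mats[f]
        mats[eff] = cell

    residuals = Xc.copy()
    for mat in mats.values():
        residuals -= mat
    rss = {e: float((m**2).sum()) / total_ss * 100.0 for e, m in mats.items()}
    rss["residuals"] = float((residuals**2).sum()) / total_ss * 100.0
    return AnovaDecomposition(grand_mean=grand, effect_matrices=mats, residuals=residuals, rss=rss)


def _dummy_response(design: pd.DataFrame, y_effects: list[str]) -> np.ndarray:
    """Centered level-membership dummy columns, concatenated over effects."""
    cols = []
    for eff in y_effects:
        codes, levels = _level_codes(design, _effect_columns(eff))
        for i in range(len(levels)):
            cols.append((codes == i).astype(float))
    Y = np.column_stack(cols)
    return Y - Y.mean(axis=0)


def _orth_basis(M: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the column space (SVD with relative tolerance)."""
    U, s, _ = np.linalg.svd(M, full_matrices=False)
    if s.size == 0 or s[0] == 0:
        return U[:, :0]
    rank = int((s > s[0] * 1e-10).sum())
    return U[:, :rank]


@dataclass
class AmoplsModel:
    blocks: list[str]                      # effect names + "residuals"
    Y: np.ndarray
    scores: pd.DataFrame                   # n x (P+O), columns tp1..tpP, to1..toO
    loadings: pd.DataFrame                 # p x (P+O)
    saliences: pd.DataFrame                # blocks x components, percentages
    eigenvalues: pd.Series                 # per component, consensus-kernel scale
    score_variances: pd.Series             # data variance along each score direction
    rss: dict[str, float]
    decomposition: AnovaDecomposition
    design: pd.DataFrame
    effects: list[str]
    y_effects: list[str]
    n_predictive: int
    n_orthogonal: int
    block_scaling: str
    p_values: dict[str, float] = field(default_factory=dict)
    n_permutations: int = 0
    seed: int | None = None

    @property
    def predictive_components(self) -> list[str]:
        return [c for c in self.scores.columns if c.startswith("tp")]

    @property
    def orthogonal_components(self) -> list[str]:
        return [c for c in self.scores.columns if c.startswith("to")]


def fit_amopls(
    X: np.ndarray,
    design: pd.DataFrame,
    effects: tuple[str, ...] | list[str] = ("cultivar", "date", "cultivar:date"),
    n_predictive: int | str = "auto",
    n_orthogonal: int = 1,
    block_scaling: str = "frobenius",
    y_effects: list[str] | None = None,
    feature_ids: list[str] | None = None,
) -> AmoplsModel:
    """Fit the consensus-kernel multiblock OPLS on the ANOVA blocks of X.

    ``X`` should already be normalized and unit-variance scaled. By default Y
    encodes main effects only, so the automatic number of predictive
    components is sum(levels - 1) over main factors; the interaction enters
    as a block but contributes no response columns.
    """
    X = np.asarray(X, dtype=float)
    effects = list(effects)
    dec = anova_decompose(X, design, effects)
    block_names = effects + ["residuals"]
    block_mats = [dec.effect_matrices[e] for e in effects] + [dec.residuals]

    if y_effects is None:
        y_effects = [e for e in effects if INTERACTION_SEP not in e]
    Y = _dummy_response(design, y_effects)
    Ybasis = _orth_basis(Y)
    y_rank = Ybasis.shape[1]
    if n_predictive == "auto":
        n_pred = y_rank
    else:
        n_pred = int(n_predictive)
        if n_pred > y_rank:
            raise ValueError(f"n_predictive={n_pred} exceeds response rank {y_rank}")

    # consensus kernel with per-block Frobenius weighting
    kernels = [mat @ mat.T for mat in block_mats]
    if block_scaling == "frobenius":
        weights = np.array([1.0 / np.linalg.norm(k) if np.linalg.norm(k) > 0 else 0.0 for k in kernels])
    elif block_scaling == "none":
        weights = np.ones(len(kernels))
    else:
        raise ValueError(f"unknown block_scaling {block_scaling!r}")
    K = sum(w * k for w, k in zip(weights, kernels))

    n = X.shape[0]
    P = Ybasis @ Ybasis.T
    Q = np.eye(n) - P

    def _top_eig(M: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
        M = (M + M.T) / 2.0
        vals, vecs = np.linalg.eigh(M)
        order = np.argsort(vals)[::-1][:k]
        return np.clip(vals[order], 0.0, None), vecs[:, order]

    lam_p, U_p = _top_eig(P @ K @ P, n_pred)
    lam_o, U_o = _top_eig(Q @ K @ Q, n_orthogonal) if n_orthogonal > 0 else (np.empty(0), np.empty((n, 0)))

    comp_names = [f"tp{i+1}" for i in range(n_pred)] + [f"to{i+1}" for i in range(len(lam_o))]
    lam = np.concatenate([lam_p, lam_o])
    U = np.column_stack([U_p, U_o]) if comp_names else np.empty((n, 0))
    T = U * np.sqrt(lam)

    # sign convention: the main-effect level with the largest |mean score|
    # sits on the positive side; ties broken by level order
    level_groups: list[np.ndarray] = []
    for eff in y_effects:
        codes, levels = _level_codes(design, _effect_columns(eff))
        for i in range(len(levels)):
            level_groups.append(codes == i)
    for c in range(T.shape[1]):
        means = np.array([T[g, c].mean() if g.any() else 0.0 for g in level_groups])
        if means.size and np.abs(means).max() > 0:
            if means[int(np.argmax(np.abs(means)))] < 0:
                T[:, c] = -T[:, c]

    # saliences: share of each component's variance carried by each block
    sal = np.zeros((len(block_names), T.shape[1]))
    for c in range(T.shape[1]):
        t = T[:, c]
        contrib = np.array([w * float(t @ k @ t) for w, k in zip(weights, kernels)])
        total = contrib.sum()
        sal[:, c] = contrib / total * 100.0 if total > 0 else np.nan

    # loadings against the full scaled matrix: p_c = X' t_c / (t_c' t_c);
    # score_variances = data variance along the (unit) score direction, which
    # carries effect amplitude (kernel eigenvalues do not once blocks are
    # Frobenius-normalized)
    loads = np.zeros((X.shape[1], T.shape[1]))
    svar = np.zeros(T.shape[1])
    for c in range(T.shape[1]):
        tt = float(T[:, c] @ T[:, c])
        loads[:, c] = X.T @ T[:, c] / tt if tt > 0 else 0.0
        svar[c] = float(np.sum((X.T @ T[:, c]) ** 2) / tt) if tt > 0 else 0.0

    fids = feature_ids if feature_ids is not None else [f"f{j}" for j in range(X.shape[1])]
    sample_index = design.index if design.index.is_unique else pd.RangeIndex(n)
    return AmoplsModel(
        blocks=block_names,
        Y=Y,
        scores=pd.DataFrame(T, columns=comp_names, index=sample_index),
        loadings=pd.DataFrame(loads, columns=comp_names, index=fids),
        saliences=pd.DataFrame(sal, index=block_names, columns=comp_names),
        eigenvalues=pd.Series(lam, index=comp_names),
        score_variances=pd.Series(svar, index=comp_names),
        rss=dec.rss,
        decomposition=dec,
        design=design.reset_index(drop=True),
        effects=effects,
        y_effects=y_effects,
        n_predictive=n_pred,
        n_orthogonal=len(lam_o),
        block_scaling=block_scaling,
    )


def _effect_statistic(model: AmoplsModel, effect: str) -> float:
    """Variance-weighted salience of an effect over predictive components.

    Components are weighted by the data variance captured along their score
    direction: a genuine effect concentrates large data variance on the
    components it dominates, whereas a permuted (null) effect aligns its
    components with noise-level variance only.
    """
    comps = model.predictive_components
    w = model.score_variances[comps].to_numpy()
    total = w.sum()
    if total <= 0:
        return 0.0
    sal = model.saliences.loc[effect, comps].to_numpy()
    return float((w / total * sal).sum())


def permutation_test(
    X: np.ndarray,
    design: pd.DataFrame,
    effects: tuple[str, ...] | list[str],
    effect: str,
    n_perm: int = 199,
    seed: int = 0,
    **fit_kwargs,
) -> float:
    """Permutation p-value for one effect of the AMOPLS model.

    The statistic is the effect's salience over predictive components,
    weighted by the data variance each component captures. The null permutes
    the effect's level labels: for a main effect, within the strata of the
    remaining design factors so the factorial stays balanced (the
    decomposition requires non-empty cells); for an interaction, the joint
    cell labels across all samples. p = (1 + #{null >= observed}) /
    (1 + n_perm).
    """
    effects = list(effects)
    if effect not in effects:
        raise ValueError(f"effect {effect!r} not among model effects {effects}")
    if n_perm < 99:
        raise ValueError("n_perm must be at least 99")
    observed = _effect_statistic(fit_amopls(X, design, effects, **fit_kwargs), effect)
    rng = np.random.default_rng(seed)
    factors = _effect_columns(effect)
    n = len(design)
    other_mains = [e for e in effects if INTERACTION_SEP not in e and e not in factors]
    if len(factors) == 1 and other_mains:
        strata, _ = _level_codes(design, other_mains)
    else:
        strata = np.zeros(n, dtype=int)  # interaction or single-factor: free permutation
    strata_idx = [np.flatnonzero(strata == s) for s in np.unique(strata)]
    exceed = 0
    for _ in range(n_perm):
        perm = np.arange(n)
        for idx in strata_idx:
            perm[idx] = idx[rng.permutation(len(idx))]
        d = design.copy()
        d[factors] = design[factors].to_numpy()[perm]
        stat = _effect_statistic(fit_amopls(X, d, effects, **fit_kwargs), effect)
        if stat >= observed:
            exceed += 1
    return (1 + exceed) / (1 + n_perm)


def run_permutation_tests(
    X: np.ndarray,
    design: pd.DataFrame,
    model: AmoplsModel,
    n_perm: int = 199,
    seed: int = 0,
) -> AmoplsModel:
    """Fill ``model.p_values`` for every effect block (residuals excluded)."""
    for i, eff in enumerate(model.effects):
        model.p_values[eff] = permutation_test(
            X,
            design,
            model.effects,
            eff,
            n_perm=n_perm,
            seed=seed + i,
            n_predictive=model.n_predictive,
            n_orthogonal=model.n_orthogonal,
            block_scaling=model.block_scaling,
            y_effects=model.y_effects,
        )
    model.n_permutations = n_perm
    model.seed = seed
    return model


def component_summary(model: AmoplsModel) -> pd.DataFrame:
    """One row per block: RSS%, permutation p, saliences, top predictive component.

    ``top_component`` is, per effect, the predictive component on which the
    effect's salience is maximal — e.g. the cultivar-dominated component
    inspected for markers downstream.
    """
    comps = list(model.scores.columns)
    pred = model.predictive_components
    rows = []
    for block in model.blocks:
        row: dict[str, object] = {"effect": block, "rss_pct": model.rss[block]}
        row["p_value"] = model.p_values.get(block, np.nan)
        for c in comps:
            row[c] = model.saliences.loc[block, c]
        if block != "residuals" and pred:
            sal = model.saliences.loc[block, pred]
            # near-ties (e.g. several components fully driven by one block in
            # a balanced design) resolved by captured data variance
            ranked = sorted(
                pred,
                key=lambda c: (round(float(sal[c]), 6), float(model.score_variances[c])),
                reverse=True,
            )
            row["top_component"] = ranked[0]
        else:
            row["top_component"] = ""
        rows.append(row)
    return pd.DataFrame(rows).set_index("effect")
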