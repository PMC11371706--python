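"""Synthetic factorial metabolomics data with known ground truth.

Emulates the structure of a designed berry-skin metabolomics study: a
balanced cultivar x sampling-date design with replicate extractions, pooled
QC injections, feature intensities that are log-normal with multiplicative
per-sample dilution (the regime PQN is built for), planted cultivar / date /
interaction effects with controllable shares of the total variance, MS/MS
spectral families that share a fragment scaffold plus adduct series of a
compound, and overdispersed egg-count tables for the behavioural arm.

Every generated entity is recorded in a :class:`GroundTruth` so downstream
recovery — ANOVA shares, marker selection, network clustering, adduct
grouping — can be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .io_formats import FeatureTable, MsmsSpectrum
from .network import ADDUCT_MASS

PROTON = 1.007276


@dataclass
class EffectSpec:
    """A planted design effect on a subset of features.

    ``effect_pattern`` maps factor level (or "A|B" cell for an interaction)
    to a log-scale offset; offsets are centered to sum to zero across levels
    so effects are identifiable. If ``target_rss_share`` is set the pattern
    is rescaled so the effect's expected relative sum of squares (after unit
    variance scaling) approximates that fraction.
    """

    factor: str                      # "cultivar", "date" or "cultivar:date"
    affected_features: np.ndarray    # feature indices
    effect_pattern: dict[str, float]
    target_rss_share: float | None = None

    def centered_pattern(self) -> dict[str, float]:
        vals = np.array(list(self.effect_pattern.values()), dtype=float)
        mean = vals.mean()
        return {k: v - mean for k, v in self.effect_pattern.items()}


@dataclass
class GroundTruth:
    """Complete record of what the generator planted."""

    seed: int
    effect_membership: dict[str, np.ndarray] = field(default_factory=dict)
    effect_offsets: dict[str, dict[str, float]] = field(default_factory=dict)
    dilutions: np.ndarray | None = None
    family_of: dict[str, str] = field(default_factory=dict)
    adduct_group_of: dict[str, str] = field(default_factory=dict)
    marker_direction: dict[str, str] = field(default_factory=dict)


def generate_design(
    n_cultivars: int = 4,
    n_dates: int = 4,
    n_reps: int = 3,
    n_qc: int = 4,
    seed: int = 0,
    extract: str = "MeOH",
    ion_mode: str = "pos",
) -> pd.DataFrame:
    """Balanced full-factorial sample sheet plus flagged QC injections."""
    if min(n_cultivars, n_dates, n_reps) < 1 or n_qc < 0:
        raise ValueError("counts must be >= 1 (n_qc >= 0)")
    rows = []
    for ci in range(n_cultivars):
        for di in range(n_dates):
            for r in range(n_reps):
                rows.append(
                    {
                        "sample_id": f"S_CV{ci+1}_D{di+1}_R{r+1}",
                        "cultivar": f"CV{ci+1}",
                        "date": f"D{di+1}",
                        "extract": extract,
                        "ion_mode": ion_mode,
                        "is_qc": False,
                        "replicate": r + 1,
                    }
                )
    for q in range(n_qc):
        rows.append(
            {
                "sample_id": f"QC{q+1}",
                "cultivar": "QC",
                "date": "QC",
                "extract": extract,
                "ion_mode": ion_mode,
                "is_qc": True,
                "replicate": q + 1,
            }
        )
    return pd.DataFrame(rows)


def _offset_rows(design_bio: pd.DataFrame, spec: EffectSpec) -> np.ndarray:
    """Per-sample offset vector for one effect (log scale, centered pattern)."""
    pattern = spec.centered_pattern()
    factors = spec.factor.split(":")
    if len(factors) == 1:
        keys = design_bio[factors[0]].astype(str)
    else:
        keys = design_bio[factors].astype(str).agg("|".join, axis=1)
    missing = sorted(set(keys) - set(pattern))
    if missing:
        raise ValueError(f"effect {spec.factor!r}: no offset for levels {missing}")
    return keys.map(pattern).to_numpy(dtype=float)


def _effect_df(spec: EffectSpec, design_bio: pd.DataFrame) -> int:
    factors = spec.factor.split(":")
    df = 1
    for f in factors:
        df *= design_bio[f].nunique() - 1
    return df


def _calibrate_scales(
    effects: list[EffectSpec],
    design_bio: pd.DataFrame,
    n_features: int,
    noise_sd: float,
) -> np.ndarray:
    """Per-effect amplitude scales hitting the requested RSS shares.

    Uses the expected ANOVA sums of squares of the planted linear (log-scale)
    model: for feature j, E[SS_e,j] = c_e^2 u_e 1[j affected] + df_e sigma^2
    and E[SS_tot,j] = sum_e c_e^2 u_e 1[affected] + (n-1) sigma^2; after unit
    variance scaling every feature contributes its *ratio*, so the expected
    share is the mean ratio over features. Solved by fixed-point iteration
    with a scalar root find per calibrated effect.
    """
    n = len(design_bio)
    u = np.array([float((_offset_rows(design_bio, e) ** 2).sum()) for e in effects])
    dfs = np.array([_effect_df(e, design_bio) for e in effects], dtype=float)
    member = np.zeros((len(effects), n_features), dtype=bool)
    for i, e in enumerate(effects):
        member[i, np.asarray(e.affected_features, dtype=int)] = True
    sigma2 = noise_sd**2
    scales = np.ones(len(effects))

    def expected_share(i: int, c2: float, c2_all: np.ndarray) -> float:
        c2_all = c2_all.copy()
        c2_all[i] = c2
        planted = (c2_all * u)[:, None] * member          # effects x features
        num = planted[i] + dfs[i] * sigma2
        den = planted.sum(axis=0) + (n - 1) * sigma2
        return float((num / den).mean())

    targets = [e.target_rss_share for e in effects]
    for _ in range(60):
        prev = scales.copy()
        for i, tgt in enumerate(targets):
            if tgt is None:
                continue
            c2_all = scales**2
            floor = expected_share(i, 0.0, c2_all)
            if tgt <= floor:
                scales[i] = 0.0
                continue
            hi = 1.0
            while expected_share(i, hi, c2_all) < tgt:
                hi *= 4.0
                if hi > 1e9:
                    raise ValueError(
                        f"effect {effects[i].factor!r}: target share {tgt} unreachable "
                        f"with {member[i].sum()}/{n_features} affected features"
                    )
            scales[i] = np.sqrt(brentq(lambda c2: expected_share(i, c2, c2_all) - tgt, 0.0, hi, xtol=1e-12))
        if np.allclose(scales, prev, atol=1e-10):
            break
    return scales


def generate_feature_table(
    design: pd.DataFrame,
    n_features: int,
    effects: list[EffectSpec] | None = None,
    noise_sd: float = 0.2,
    dilution_sd: float = 0.3,
    seed: int = 0,
    baseline_log_mean: float = 13.0,
    baseline_log_sd: float = 1.0,
) -> tuple[FeatureTable, GroundTruth]:
    """Log-normal intensities with planted effects and per-sample dilution.

    intensity_ij = exp(baseline_j + sum_e offset_e(i,j) + N(0, noise_sd^2))
    * dilution_i with dilution_i = exp(N(0, dilution_sd^2)) shared by every
    feature of sample i. QC rows are the feature-wise grand mean of the
    (undiluted) biological intensities with noise at noise_sd / 4, modelling
    pooled-material injections.
    """
    effects = list(effects or [])
    rng = np.random.default_rng(seed)
    bio_mask = ~design["is_qc"].to_numpy(dtype=bool)
    design_bio = design.loc[bio_mask].reset_index(drop=True)
    n_bio = len(design_bio)
    for e in effects:
        if len(e.affected_features) and int(np.max(e.affected_features)) >= n_features:
            raise ValueError("affected feature index exceeds n_features")

    scales = _calibrate_scales(effects, design_bio, n_features, noise_sd) if effects else np.empty(0)

    baseline = rng.normal(baseline_log_mean, baseline_log_sd, size=n_features)
    log_mean = np.tile(baseline, (n_bio, 1))
    truth = GroundTruth(seed=seed)
    for e, c in zip(effects, scales):
        rows = _offset_rows(design_bio, e) * c
        idx = np.asarray(e.affected_features, dtype=int)
        log_mean[:, idx] += rows[:, None]
        key = e.factor if e.factor not in truth.effect_membership else f"{e.factor}#{len(truth.effect_membership)}"
        truth.effect_membership[key] = idx
        truth.effect_offsets[key] = {lv: v * c for lv, v in e.centered_pattern().items()}

    noise = rng.normal(0.0, noise_sd, size=(n_bio, n_features)) if noise_sd > 0 else 0.0
    dil = np.exp(rng.normal(0.0, dilution_sd, size=n_bio)) if dilution_sd > 0 else np.ones(n_bio)
    bio_clean = np.exp(log_mean + noise)
    bio = bio_clean * dil[:, None]

    n_qc = int((~bio_mask).sum())
    pooled = bio_clean.mean(axis=0)
    qc_noise_sd = noise_sd / 4.0
    if n_qc:
        qc_noise = rng.normal(0.0, qc_noise_sd, size=(n_qc, n_features)) if qc_noise_sd > 0 else 0.0
        qc = pooled[None, :] * np.exp(qc_noise)
    X = np.empty((len(design), n_features))
    X[bio_mask] = bio
    if n_qc:
        X[~bio_mask] = qc

    fids = [f"F{j+1:04d}" for j in range(n_features)]
    feature_meta = pd.DataFrame(
        {
            "feature_id": fids,
            "mz": rng.uniform(150.0, 1200.0, size=n_features).round(4),
            "rt": rng.uniform(0.3, 9.0, size=n_features).round(3),
        }
    )
    mat = pd.DataFrame(X, index=list(design["sample_id"]), columns=fids)
    truth.dilutions = dil
    table = FeatureTable(mat, design.copy(), feature_meta)
    return table, truth


# -- MS/MS spectral families ---------------------------------------------------

@dataclass
class SpectralFamilySpec:
    """A family of compounds sharing a fragment scaffold.

    Members share at least ``shared_min`` scaffold fragments (jittered below
    the fragment mass tolerance) plus private fragments; for each listed
    adduct beyond the first, every member also gets an adduct-variant feature
    co-eluting with it at the characteristic precursor mass difference.
    """

    family_id: str
    n_members: int = 4
    scaffold_peaks: list[float] | None = None
    shared_min: int = 6
    adducts: tuple[str, ...] = ("[M+H]+",)
    n_scaffold: int = 10


def _count_shared(mz_a: np.ndarray, mz_b: np.ndarray, tol: float) -> int:
    return int((np.abs(mz_a[:, None] - mz_b[None, :]) <= tol).any(axis=1).sum())


def generate_spectra(
    families: list[SpectralFamilySpec],
    decoy_n: int = 10,
    fimt_jitter: float = 0.005,
    seed: int = 0,
    rt_jitter: float = 0.005,
) -> tuple[list[MsmsSpectrum], GroundTruth]:
    """Spectra for family members, their adduct variants, and decoys.

    Decoys are guaranteed by rejection to share fewer than ``shared_min``
    fragments with every scaffold and every other decoy, so they stay
    singletons under the family-recovery thresholds.
    """
    rng = np.random.default_rng(seed)
    truth = GroundTruth(seed=seed)
    spectra: list[MsmsSpectrum] = []

    scaffolds: dict[str, np.ndarray] = {}
    for fam in families:
        if fam.scaffold_peaks is not None:
            sc = np.asarray(fam.scaffold_peaks, dtype=float)
        else:
            n_sc = max(fam.n_scaffold, fam.shared_min)
            sc = np.sort(rng.uniform(60.0, 450.0, size=n_sc))
        if sc.size < fam.shared_min:
            raise ValueError(f"family {fam.family_id}: scaffold smaller than shared_min")
        scaffolds[fam.family_id] = sc
    fam_ids = list(scaffolds)
    for i, a in enumerate(fam_ids):
        for b in fam_ids[i + 1 :]:
            shared = _count_shared(scaffolds[a], scaffolds[b], 2 * fimt_jitter)
            smin = min(f.shared_min for f in families)
            if shared >= smin:
                raise ValueError(f"family scaffolds {a} and {b} share {shared} peaks (>= {smin})")

    for fam in families:
        sc = scaffolds[fam.family_id]
        # a fixed high-intensity core of shared_min peaks guarantees every
        # member pair matches >= shared_min fragments; a family-wide intensity
        # pattern keeps the cosine of member pairs high
        core = np.sort(rng.choice(sc.size, size=fam.shared_min, replace=False))
        pattern = rng.uniform(2e5, 1e6, size=sc.size)
        for m in range(fam.n_members):
            neutral = rng.uniform(460.0, 900.0)
            rt = rng.uniform(0.5, 8.5)
            rest = np.setdiff1d(np.arange(sc.size), core)
            n_extra = int(rng.integers(0, rest.size + 1))
            take = np.sort(np.concatenate([core, rng.choice(rest, size=n_extra, replace=False)]))
            n_private = int(rng.integers(2, 6))
            private = rng.uniform(60.0, 450.0, size=n_private)
            compound = f"{fam.family_id}_m{m+1}"
            for ai, adduct in enumerate(fam.adducts):
                n_take = take.size
                frag = np.concatenate(
                    [
                        sc[take] + rng.uniform(-fimt_jitter, fimt_jitter, size=n_take) * 0.9,
                        private + rng.uniform(-fimt_jitter, fimt_jitter, size=n_private) * 0.9,
                    ]
                )
                inten = np.concatenate(
                    [
                        pattern[take] * np.exp(rng.normal(0.0, 0.25, size=n_take)),
                        rng.uniform(1e3, 8e4, size=n_private),
                    ]
                )
                adduct_tag = adduct.strip("[]+").replace("+", "").replace("-", "x")
                fid = compound if ai == 0 else f"{compound}_{adduct_tag}"
                spectra.append(
                    MsmsSpectrum(
                        feature_id=fid,
                        precursor_mz=neutral + ADDUCT_MASS[adduct],
                        rt=rt + (rng.uniform(-rt_jitter, rt_jitter) if ai else 0.0),
                        peaks_mz=frag,
                        peaks_intensity=inten,
                    )
                )
                truth.family_of[fid] = fam.family_id
                truth.adduct_group_of[fid] = compound

    smin_all = min((f.shared_min for f in families), default=6)
    accepted_decoys: list[np.ndarray] = []
    for d in range(decoy_n):
        for _attempt in range(200):
            frag = np.sort(rng.uniform(60.0, 450.0, size=int(rng.integers(8, 16))))
            others = list(scaffolds.values()) + accepted_decoys
            if all(_count_shared(frag, o, 2 * fimt_jitter) < smin_all for o in others):
                break
        else:
            raise RuntimeError("could not place a decoy spectrum")
        accepted_decoys.append(frag)
        fid = f"DECOY{d+1:03d}"
        spectra.append(
            MsmsSpectrum(
                feature_id=fid,
                precursor_mz=rng.uniform(460.0, 900.0) + PROTON,
                rt=rng.uniform(0.5, 8.5),
                peaks_mz=frag,
                peaks_intensity=rng.uniform(1e3, 1e6, size=frag.size),
            )
        )
        truth.family_of[fid] = fid
        truth.adduct_group_of[fid] = fid
    return spectra, truth


# -- behavioural egg counts ----------------------------------------------------

def generate_egg_counts(
    cultivar_means: dict[str, float],
    n_boxes: int = 6,
    n_dates: int = 4,
    weight_range: tuple[float, float] = (1.0, 2.5),
    dispersion_k: float = 2.0,
    date_multipliers: dict[str, float] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """One berry per box x cultivar x date; overdispersed egg counts.

    Berry weight ~ Uniform(weight_range); eggs ~ negative binomial with mean
    cultivar_mean * weight (optionally modulated per date) and shape
    ``dispersion_k`` (Poisson is the k -> infinity limit).
    """
    if any(m < 0 for m in cultivar_means.values()):
        raise ValueError("cultivar means must be >= 0")
    rng = np.random.default_rng(seed)
    date_multipliers = date_multipliers or {}
    rows = []
    for b in range(n_boxes):
        for cv, mu in cultivar_means.items():
            for di in range(n_dates):
                date = f"D{di+1}"
                w = rng.uniform(*weight_range)
                mean = mu * w * date_multipliers.get(date, 1.0)
                if mean <= 0:
                    eggs = 0
                else:
                    p = dispersion_k / (dispersion_k + mean)
                    eggs = int(rng.negative_binomial(dispersion_k, p))
                rows.append({"box": f"B{b+1}", "cultivar": cv, "date": date, "eggs": eggs, "berry_weight": w})
    return pd.DataFrame(rows)


# -- full study scenario -------------------------------------------------------

def generate_study(
    seed: int = 0,
    n_features: int = 300,
    n_markers_per_side: int = 30,
    cultivar_amplitude: float = 0.5,
    date_rss_share: float = 0.18,
    noise_sd: float = 0.2,
    dilution_sd: float = 0.3,
    datasets: tuple[str, ...] = ("MeOH", "DCM"),
    n_shared_markers: int = 14,
) -> dict:
    """A full synthetic study: two extract datasets, spectra and egg counts.

    Cultivars CV1/CV2 are attractive, CV3/CV4 unattractive. Per dataset,
    ``n_markers_per_side`` features are over-expressed in the attractive pair
    and the same number in the unattractive pair (these are the planted
    markers); a date effect with a target variance share covers a further
    block of features. Each dataset gets its own feature-id namespace except
    ``n_shared_markers`` marker features (half per direction) detected in
    every dataset under a common id, so marker sets merged across datasets
    overlap the way two extraction solvents of one study do. Spectral
    families are built over marker features of the first dataset so markers
    aggregate into network clusters.
    """
    rng = np.random.default_rng(seed)
    out: dict = {
        "attractiveness": {"CV1": "attractive", "CV2": "attractive", "CV3": "unattractive", "CV4": "unattractive"},
        "datasets": {},
    }
    k = min(n_markers_per_side, n_features // 4)
    if k < 1:
        raise ValueError("n_features too small to plant markers")
    for d_i, ds in enumerate(datasets):
        design = generate_design(4, 4, 3, 4, seed=seed, extract=ds)
        att_idx = np.arange(0, k)
        unatt_idx = np.arange(k, 2 * k)
        date_idx = np.arange(2 * k, min(n_features, 2 * k + max(40, n_features // 5)))
        amp = cultivar_amplitude
        effects = [
            EffectSpec("cultivar", att_idx, {"CV1": amp, "CV2": amp, "CV3": -amp, "CV4": -amp}),
            EffectSpec("cultivar", unatt_idx, {"CV1": -amp, "CV2": -amp, "CV3": amp, "CV4": amp}),
            EffectSpec(
                "date",
                date_idx,
                {"D1": -1.5, "D2": -0.5, "D3": 0.5, "D4": 1.5},
                target_rss_share=date_rss_share,
            ),
        ]
        table, truth = generate_feature_table(
            design, n_features, effects, noise_sd=noise_sd, dilution_sd=dilution_sd, seed=seed + 101 * (d_i + 1)
        )
        # per-dataset id namespace; a small marker subset keeps a common id so
        # it is "detected" in every dataset (planted with the same direction)
        half = min(n_shared_markers // 2, k)
        shared_j = list(range(0, half)) + list(range(k, k + half))
        rename = {}
        for j, fid in enumerate(table.feature_ids):
            rename[fid] = fid.replace("F", "SHF", 1) if j in set(shared_j) else f"{ds}_{fid}"
        table.intensities.columns = [rename[f] for f in table.intensities.columns]
        table.feature_meta["feature_id"] = [rename[f] for f in table.feature_meta["feature_id"]]
        fids = table.feature_ids
        for j in att_idx:
            truth.marker_direction[fids[j]] = "attractive"
        for j in unatt_idx:
            truth.marker_direction[fids[j]] = "unattractive"
        out["datasets"][ds] = {"table": table, "truth": truth}

    # spectral families over the first dataset's marker features
    first = out["datasets"][datasets[0]]
    fids = first["table"].feature_ids
    families = [
        SpectralFamilySpec(family_id=f"FAM{i+1}", n_members=5, adducts=("[M+H]+", "[M+Na]+"))
        for i in range(4)
    ]
    spectra, spec_truth = generate_spectra(families, decoy_n=15, seed=seed + 7)
    # rename spectral features onto real feature ids: families 1-2 on marker
    # features, remaining on unaffected features
    marker_pool = list(fids[: 2 * k])
    other_pool = list(fids[2 * k :])
    mapping: dict[str, str] = {}
    mi = oi = 0
    for s in spectra:
        fam = spec_truth.family_of[s.feature_id]
        if fam in ("FAM1", "FAM2") and mi < len(marker_pool):
            mapping[s.feature_id] = marker_pool[mi]
            mi += 1
        else:
            mapping[s.feature_id] = other_pool[oi]
            oi += 1
    renamed = []
    for s in spectra:
        new_id = mapping[s.feature_id]
        renamed.append(
            MsmsSpectrum(
                feature_id=new_id,
                precursor_mz=s.precursor_mz,
                rt=s.rt,
                peaks_mz=s.peaks_mz,
                peaks_intensity=s.peaks_intensity,
                charge=s.charge,
            )
        )
        for attr in ("family_of", "adduct_group_of"):
            getattr(spec_truth, attr)[new_id] = getattr(spec_truth, attr).pop(s.feature_id)
    out["spectra"] = renamed
    out["spectra_truth"] = spec_truth

    out["egg_counts"] = generate_egg_counts(
        {
            "CV1": 12.0, "CV2": 9.0, "CV3": 0.4, "CV4": 0.3,
            "CV5": 2.0, "CV6": 1.5, "CV7": 1.0, "CV8": 0.6,
        },
        seed=seed + 31,
    )
    out["seed"] = seed
    return out
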