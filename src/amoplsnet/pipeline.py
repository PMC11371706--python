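"""End-to-end orchestration: normalize, model, select markers, network, report.

One metabolomics run processes each dataset (one extract x ionisation mode)
independently — PQN against the pooled QCs, unit-variance scaling, ANOVA
decomposition, multiblock OPLS with permutation tests — then picks, per
dataset, the predictive component on which the cultivar block's salience is
maximal, selects the extreme loadings on it as markers, merges marker sets
across datasets, builds the molecular network over the supplied spectra, and
decorates nodes with intensity shares and marker status. Identical
configuration and seed reproduce every numeric output exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import behavior as bh
from .amopls import AmoplsModel, component_summary, fit_amopls, run_permutation_tests
from .io_formats import FeatureTable, MsmsSpectrum, write_graphml
from .markers import MarkerSet, assign_direction, merge_marker_sets, select_extreme_loadings
from .network import (
    MolecularNetwork,
    add_ion_identity_edges,
    build_network,
    cluster_stats,
    decorate_nodes,
    group_ion_identities,
)
from .normalization import pqn_normalize, uv_scale

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    effects: tuple[str, ...] = ("cultivar", "date", "cultivar:date")
    pqn_reference: str = "qc_median"
    enable_log: bool = False
    log_offset: float = 1.0
    n_orthogonal: int = 1
    n_permutations: int = 199
    block_scaling: str = "frobenius"
    marker_k: int = 30
    marker_components: dict[str, str] | str = "auto"
    marker_factor: str = "cultivar"
    precursor_tol: float = 0.02
    fragment_tol: float = 0.02
    min_matched: int = 6
    min_cosine: float = 0.7
    rt_tol: float = 0.1
    min_corr: float = 0.8
    grouping: tuple[str, ...] = ("cultivar",)
    seed: int = 0


@dataclass
class DatasetResult:
    name: str
    model: AmoplsModel
    summary: pd.DataFrame
    cultivar_component: str
    scaled: np.ndarray
    feature_ids: list[str]


@dataclass
class ResultsBundle:
    datasets: dict[str, DatasetResult]
    markers: MarkerSet
    network: MolecularNetwork | None
    cluster_summary: object | None
    manifest: dict = field(default_factory=dict)


def analyse_dataset(name: str, table: FeatureTable, config: PipelineConfig) -> DatasetResult:
    """PQN -> (optional log) -> unit variance -> AMOPLS -> permutation tests."""
    from .normalization import log_transform

    norm = pqn_normalize(table, reference=config.pqn_reference).normalized
    if config.enable_log:
        norm = log_transform(norm, offset=config.log_offset)
    bio = norm.biological()
    scaled, _, _, kept = uv_scale(bio.intensities.to_numpy())
    fids = [f for f, keep in zip(bio.feature_ids, kept) if keep]
    design = bio.sample_meta
    model = fit_amopls(
        scaled,
        design,
        effects=config.effects,
        n_orthogonal=config.n_orthogonal,
        block_scaling=config.block_scaling,
        feature_ids=fids,
    )
    if config.n_permutations:
        run_permutation_tests(scaled, design, model, n_perm=config.n_permutations, seed=config.seed)
    summary = component_summary(model)
    if isinstance(config.marker_components, dict) and name in config.marker_components:
        comp = config.marker_components[name]
    else:
        comp = str(summary.loc[config.marker_factor, "top_component"])
    logger.info("%s: cultivar-dominated component = %s", name, comp)
    return DatasetResult(name=name, model=model, summary=summary, cultivar_component=comp, scaled=scaled, feature_ids=fids)


def run_metabolomics(
    datasets: dict[str, FeatureTable],
    attractiveness: dict[str, str],
    spectra: list[MsmsSpectrum] | None = None,
    config: PipelineConfig | None = None,
    out_dir: str | Path | None = None,
) -> ResultsBundle:
    """Full metabolomics analysis over one or more extract/mode datasets."""
    config = config or PipelineConfig()
    results: dict[str, DatasetResult] = {}
    record_sets = []
    for name, table in datasets.items():
        try:
            res = analyse_dataset(name, table, config)
        except Exception as exc:  # noqa: BLE001 - annotate stage/dataset
            raise RuntimeError(f"stage 'amopls' failed for dataset {name!r}: {exc}") from exc
        results[name] = res
        try:
            records = select_extreme_loadings(
                res.model.loadings[res.cultivar_component], res.cultivar_component, config.marker_k, name
            )
            assign_direction(records, res.model, attractiveness)
        except Exception as exc:  # noqa: BLE001
            raise RuntimeError(f"stage 'markers' failed for dataset {name!r}: {exc}") from exc
        record_sets.append(records)
    markers = merge_marker_sets(record_sets)

    net = None
    cstats = None
    if spectra is not None:
        first = next(iter(datasets.values()))
        net = build_network(
            spectra,
            precursor_tol=config.precursor_tol,
            fragment_tol=config.fragment_tol,
            min_matched=config.min_matched,
            min_cosine=config.min_cosine,
        )
        ii_edges = group_ion_identities(
            first, spectra, rt_tol=config.rt_tol, precursor_tol=config.precursor_tol, min_corr=config.min_corr
        )
        add_ion_identity_edges(net, ii_edges)
        decorate_nodes(net, first, markers, grouping=list(config.grouping))
        cstats = cluster_stats(net)

    bundle = ResultsBundle(datasets=results, markers=markers, network=net, cluster_summary=cstats)
    bundle.manifest = {"seed": config.seed, "config": {k: v for k, v in asdict(config).items()}, "outputs": {}}
    if out_dir is not None:
        _write_outputs(bundle, Path(out_dir))
    return bundle


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_outputs(bundle: ResultsBundle, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for name, res in bundle.datasets.items():
        p = out_dir / f"amopls_summary_{name}.tsv"
        res.summary.to_csv(p, sep="\t")
        written.append(p)
        p = out_dir / f"scores_{name}.tsv"
        res.model.scores.to_csv(p, sep="\t")
        written.append(p)
        p = out_dir / f"loadings_{name}.tsv"
        res.model.loadings.to_csv(p, sep="\t")
        written.append(p)
    p = out_dir / "markers.tsv"
    bundle.markers.to_frame().to_csv(p, sep="\t", index=False)
    written.append(p)
    if bundle.network is not None:
        p = out_dir / "network.graphml"
        write_graphml(bundle.network, p)
        written.append(p)
    for p in written:
        bundle.manifest["outputs"][p.name] = _sha256(p)
    (out_dir / "manifest.json").write_text(json.dumps(bundle.manifest, indent=2, default=str))


def run_behavior(
    egg_table: pd.DataFrame,
    infestation: pd.DataFrame | None = None,
    interaction_alpha: float = 0.05,
) -> dict:
    """Behavioural report: overall ANOVA, per-date follow-up, letter displays.

    The overall model is a 3-way fixed-effects ANOVA (box + cultivar + date +
    cultivar:date) of log(x+1) eggs per gram. When the cultivar x date
    interaction is significant, each date is re-analysed with a 2-way ANOVA
    (box + cultivar) and Bonferroni letters are computed per date.
    """
    df = egg_table.copy()
    df["eggs_per_gram"] = df["eggs"] / df["berry_weight"]
    overall = bh.anova_nway(df, ["box", "cultivar", "date", "cultivar:date"])
    report: dict = {"overall": overall, "per_date": {}, "letters": {}}
    inter_p = float(overall.loc["cultivar:date", "p"])
    report["interaction_p"] = inter_p
    report["per_date_triggered"] = inter_p < interaction_alpha
    if report["per_date_triggered"]:
        for date, sub in df.groupby("date"):
            report["per_date"][date] = bh.anova_nway(sub, ["box", "cultivar"])
            groups = {cv: np.log1p(g["eggs_per_gram"].to_numpy()) for cv, g in sub.groupby("cultivar")}
            _, letters = bh.bonferroni_pairwise(groups)
            report["letters"][date] = letters
    if infestation is not None:
        report["infestation"] = infestation.assign(
            rate_pct=[bh.infestation_rate(i, t) for i, t in zip(infestation["infested"], infestation["total"])]
        )
    return report
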