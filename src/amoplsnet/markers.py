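"""Marker selection from extreme feature loadings on design-related components.

After AMOPLS, the predictive component dominated by the factor of interest
(here: cultivar) carries, in its feature loadings, the features that most
separate the factor levels. The k most extreme positive and k most extreme
negative loadings per dataset are selected as candidate markers; merging the
per-dataset selections yields the unique marker set plus the ids shared
between datasets. Because the sign of a component is arbitrary, the
attractive/unattractive direction of a marker is anchored to external
attractiveness labels: the component is oriented so that attractive cultivars
score positive, and a marker's direction follows the sign of its loading
under that orientation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .amopls import AmoplsModel


@dataclass
class MarkerRecord:
    feature_id: str
    dataset: str
    component: str
    loading: float
    direction: str = "unassigned"  # attractive | unattractive | unassigned
    direction_conflict: bool = False


@dataclass
class MarkerSet:
    records: list[MarkerRecord]
    unique_ids: list[str] = field(default_factory=list)
    shared_ids: list[str] = field(default_factory=list)

    @property
    def n_records(self) -> int:
        return len(self.records)

    @property
    def n_unique(self) -> int:
        return len(self.unique_ids)

    @property
    def n_shared(self) -> int:
        return len(self.shared_ids)

    def status_of(self, feature_id: str) -> str:
        """Marker direction for a feature id, or "none" if not a marker."""
        for r in self.records:
            if r.feature_id == feature_id:
                return r.direction
        return "none"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "feature_id": r.feature_id,
                    "dataset": r.dataset,
                    "component": r.component,
                    "loading": r.loading,
                    "direction": r.direction,
                    "direction_conflict": r.direction_conflict,
                }
                for r in self.records
            ]
        )


def select_extreme_loadings(
    loadings: pd.Series,
    component: str,
    k: int,
    dataset: str,
) -> list[MarkerRecord]:
    """The k largest-positive and k most-negative loadings as marker records.

    Requires at least k strictly positive and k strictly negative loadings
    (zero loadings are never selected). Ties are broken by feature id so the
    selection is deterministic.
    """
    if k == 0:
        return []
    if k < 0:
        raise ValueError("k must be non-negative")
    s = pd.Series(loadings)
    s.index = s.index.astype(str)
    pos = s[s > 0]
    neg = s[s < 0]
    if len(pos) < k or len(neg) < k:
        raise ValueError(
            f"need at least {k} strictly positive and negative loadings; "
            f"have {len(pos)} positive, {len(neg)} negative"
        )
    # most extreme first; ties broken by feature id ascending
    pos_sel = sorted(pos.items(), key=lambda kv: (-kv[1], kv[0]))[:k]
    neg_sel = sorted(neg.items(), key=lambda kv: (kv[1], kv[0]))[:k]
    records = [
        MarkerRecord(feature_id=fid, dataset=dataset, component=component, loading=float(v))
        for fid, v in pos_sel + neg_sel
    ]
    return records


def merge_marker_sets(sets: list[list[MarkerRecord]]) -> MarkerSet:
    """Merge per-dataset selections; dedupe ids, flag cross-dataset conflicts.

    A feature selected in several datasets keeps every record but counts once
    in ``unique_ids``; ids seen in two or more datasets populate
    ``shared_ids``. Records of one id whose assigned directions disagree
    across datasets are kept and flagged ``direction_conflict``.
    """
    records = [r for group in sets for r in group]
    seen_pairs = set()
    for r in records:
        pair = (r.feature_id, r.dataset)
        if pair in seen_pairs:
            raise ValueError(f"duplicate record for {pair}")
        seen_pairs.add(pair)

    by_id: dict[str, list[MarkerRecord]] = {}
    for r in records:
        by_id.setdefault(r.feature_id, []).append(r)
    unique_ids = sorted(by_id)
    shared_ids = sorted(fid for fid, rs in by_id.items() if len({r.dataset for r in rs}) > 1)
    for fid, rs in by_id.items():
        directions = {r.direction for r in rs if r.direction != "unassigned"}
        if len(directions) > 1:
            for r in rs:
                r.direction_conflict = True
    return MarkerSet(records=records, unique_ids=unique_ids, shared_ids=shared_ids)


def assign_direction(
    records: list[MarkerRecord],
    model: AmoplsModel,
    attractiveness_labels: dict[str, str],
    cultivar_column: str = "cultivar",
) -> list[MarkerRecord]:
    """Label each marker attractive/unattractive via the score orientation.

    The orientation of a component is the sign of (mean score of attractive
    cultivars - mean score of unattractive cultivars); a marker whose loading
    has the same sign as the orientation marks the attractive side. Flipping
    the component's sign flips both factors and leaves directions unchanged.
    """
    labels = {str(k): v for k, v in attractiveness_labels.items()}
    cults = model.design[cultivar_column].astype(str)
    missing = sorted(set(cults) - set(labels))
    if missing:
        raise ValueError(f"cultivars without attractiveness label: {missing}")
    bad = sorted(set(labels.values()) - {"attractive", "unattractive"})
    if bad:
        raise ValueError(f"labels must be attractive/unattractive, got {bad}")

    orientations: dict[str, float] = {}
    for comp in {r.component for r in records}:
        scores = model.scores[comp].to_numpy()
        att = scores[[labels[c] == "attractive" for c in cults]]
        unatt = scores[[labels[c] == "unattractive" for c in cults]]
        diff = att.mean() - unatt.mean()
        if diff == 0:
            raise ValueError(f"component {comp}: attractive and unattractive mean scores tie")
        orientations[comp] = float(np.sign(diff))

    for r in records:
        r.direction = "attractive" if r.loading * orientations[r.component] > 0 else "unattractive"
    return records
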