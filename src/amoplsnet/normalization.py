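"""Sample normalization and feature scaling for LC-MS feature tables.

Probabilistic quotient normalization (PQN) removes per-sample dilution: each
sample is divided by the median ratio of its intensities to a reference
spectrum, here the feature-wise median over pooled QC injections (or over all
samples when no QCs exist). Zeros are treated as "absent" and excluded from
the quotient median, since gap-filled zeros would drag quotients toward zero.
Unit-variance scaling then gives every feature the same leverage in the
multivariate models regardless of its raw intensity range.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io_formats import FeatureTable

logger = logging.getLogger(__name__)


@dataclass
class NormalizationResult:
    normalized: FeatureTable
    quotients: np.ndarray          # per-sample dilution estimate, > 0
    reference: np.ndarray          # per-feature reference spectrum


def pqn_normalize(table: FeatureTable, reference: str = "qc_median") -> NormalizationResult:
    """Probabilistic quotient normalization of every sample (QCs included).

    Parameters
    ----------
    table : FeatureTable
    reference : {"qc_median", "all_median"}
        Reference spectrum = feature-wise median over QC samples, or over all
        samples when no QCs are available.

    Returns
    -------
    NormalizationResult
        ``quotients[i]`` is the median, over features positive in both sample
        i and the reference, of intensity/reference; sample i is divided by
        it. The reference is iterated to the fixed point of normalising the
        reference samples themselves (and pinned to median 1), which makes
        the procedure exactly idempotent and exactly invariant to arbitrary
        positive per-sample scalings.
    """
    X = table.intensities.to_numpy(dtype=float)
    qc = table.is_qc_mask()
    if reference == "qc_median":
        if not qc.any():
            raise ValueError("no QC samples flagged; use reference='all_median'")
        ref_rows = X[qc]
    elif reference == "all_median":
        ref_rows = X
    else:
        raise ValueError(f"unknown reference {reference!r}")

    def _quotient(row: np.ndarray, ref: np.ndarray) -> float:
        mask = (row > 0) & (ref > 0)
        if not mask.any():
            return np.nan
        return float(np.median(row[mask] / ref[mask]))

    def _pin(ref: np.ndarray) -> np.ndarray:
        pos = ref[ref > 0]
        if pos.size == 0:
            raise ValueError("reference spectrum is all zero")
        return ref / np.median(pos)

    ref = _pin(np.median(ref_rows, axis=0))
    for _ in range(500):
        q_ref = np.array([_quotient(row, ref) for row in ref_rows])
        if np.isnan(q_ref).any():
            raise ValueError("a reference sample shares no positive feature with the reference")
        new_ref = _pin(np.median(ref_rows / q_ref[:, None], axis=0))
        if np.max(np.abs(new_ref - ref)) <= 1e-13 * max(1.0, np.max(ref)):
            ref = new_ref
            break
        ref = new_ref

    quotients = np.empty(X.shape[0])
    for i in range(X.shape[0]):
        quotients[i] = _quotient(X[i], ref)
        if np.isnan(quotients[i]):
            sid = table.sample_ids[i]
            raise ValueError(f"sample {sid!r} shares no positive feature with the reference")
    normalized = table.copy_with(X / quotients[:, None])
    return NormalizationResult(normalized=normalized, quotients=quotients, reference=ref)


def uv_scale(matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Center each column and scale to unit sample standard deviation.

    Zero-variance columns are dropped with a warning; the returned boolean
    mask marks retained columns. Raises if every column is constant.

    Returns
    -------
    (scaled, means, sds, kept) where ``scaled`` has shape (n, kept.sum()).
    """
    X = np.asarray(matrix, dtype=float)
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1)
    kept = sds > 0
    if not kept.any():
        raise ValueError("all columns are constant; nothing to scale")
    n_dropped = int((~kept).sum())
    if n_dropped:
        logger.warning("uv_scale: dropping %d zero-variance columns", n_dropped)
    scaled = (X[:, kept] - means[kept]) / sds[kept]
    return scaled, means[kept], sds[kept], kept


def log_transform(table: FeatureTable, offset: float = 1.0) -> FeatureTable:
    """Elementwise log10(x + offset); offset must keep the argument positive."""
    X = table.intensities.to_numpy(dtype=float)
    if (X + offset <= 0).any():
        raise ValueError("log_transform: x + offset must be positive everywhere")
    return table.copy_with(np.log10(X + offset))
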