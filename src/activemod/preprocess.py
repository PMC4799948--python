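"""Microarray-style expression preprocessing.

Four steps, applied in this order: present-call filtering, quantile
normalization, correlation-based array outlier detection, and probe-to-gene
collapsing.  The pipeline operates on an already-summarized log2 intensity
matrix; probe-level background correction and median-polish summarization are
out of scope, so "normalization" here is the quantile-normalization step
applied to log2 values.  An externally normalized matrix can be passed
through unchanged.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "ProbeAnnotation",
    "filter_present",
    "quantile_normalize",
    "detect_outlier_samples",
    "collapse_to_genes",
]


@dataclass
class ExpressionMatrix:
    """Log2 intensity matrix with sample group labels.

    Parameters
    ----------
    values
        Genes/probes (rows) by samples (columns), log2 scale, all finite.
    groups
        Series mapping every sample id to a group label (e.g. case/control
        or an anatomical site).
    present_calls
        Optional boolean matrix of the same shape as ``values``; True means
        the transcript is detectably expressed in that sample.
    """

    values: pd.DataFrame
    groups: pd.Series
    present_calls: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.values.columns.duplicated().any():
            raise ValueError("duplicate sample ids in expression matrix")
        missing = set(self.values.columns) - set(self.groups.index)
        if missing:
            raise ValueError(f"group_labels do not cover samples: {sorted(missing)}")
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise ValueError("expression values must be finite")
        if self.present_calls is not None:
            if self.present_calls.shape != self.values.shape:
                raise ValueError("present_calls shape must match values")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    def group_samples(self, label: str) -> list[str]:
        """Sample ids carrying a given group label."""
        return [s for s in self.values.columns if self.groups.loc[s] == label]

    def subset_samples(self, keep: list[str]) -> "ExpressionMatrix":
        calls = self.present_calls[keep] if self.present_calls is not None else None
        return ExpressionMatrix(self.values[keep], self.groups.loc[keep], calls)


@dataclass
class ProbeAnnotation:
    """Probe id -> stable gene id map; probes absent from the map are
    unannotated and dropped at collapse time."""

    mapping: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        # dict keys are unique by construction; validate value types
        for k, v in self.mapping.items():
            if not isinstance(k, str) or not isinstance(v, str):
                raise ValueError("probe and gene ids must be strings")

    def gene_for(self, probe: str) -> str | None:
        return self.mapping.get(probe)


def derive_present_calls(m: ExpressionMatrix, quantile: float = 0.25) -> pd.DataFrame:
    """Surrogate detection calls: a probe is present in a sample when its
    log2 value exceeds that sample's ``quantile`` (default 25th percentile).

    Used when no vendor call matrix accompanies the data; the threshold is a
    per-sample quantile so arrays of different brightness are treated alike.
    """
    thresholds = m.values.quantile(quantile, axis=0)
    return m.values.gt(thresholds, axis=1)


def filter_present(m: ExpressionMatrix, min_fraction: float = 0.5) -> ExpressionMatrix:
    """Drop rows detectably expressed in fewer than ``min_fraction`` of samples.

    The removal rule is strict ("fewer than"): a row present in exactly
    ``min_fraction`` of samples is retained.
    """
    if m.values.empty:
        raise ValueError("empty expression matrix")
    calls = m.present_calls if m.present_calls is not None else derive_present_calls(m)
    frac = calls.mean(axis=1)
    keep = frac >= min_fraction
    out_vals = m.values.loc[keep]
    out_calls = calls.loc[keep]
    logger.info("filter_present: %d/%d rows retained (min_fraction=%.3g)",
                keep.sum(), len(keep), min_fraction)
    return ExpressionMatrix(out_vals, m.groups, out_calls)


def quantile_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample to share the same value distribution.

    Each column is replaced by the across-sample mean of the sorted values at
    its ranks, so all columns end with an identical sorted multiset.  With a
    single sample there is nothing to normalize: the matrix is returned
    unchanged with a warning.
    """
    x = m.values.to_numpy(dtype=float)
    if x.shape[1] < 2:
        warnings.warn("quantile_normalize: single sample, returned unchanged")
        return m
    order = np.argsort(x, axis=0, kind="stable")
    ranks = np.empty_like(order)
    rows = np.arange(x.shape[0])
    for j in range(x.shape[1]):
        ranks[order[:, j], j] = rows
    mean_sorted = np.sort(x, axis=0).mean(axis=1)
    out = mean_sorted[ranks]
    vals = pd.DataFrame(out, index=m.values.index, columns=m.values.columns)
    return ExpressionMatrix(vals, m.groups, m.present_calls)


def detect_outlier_samples(m: ExpressionMatrix) -> list[str]:
    """Flag outlying arrays by correlation distance.

    For each sample ``a``, D_a is the mean of (1 - Pearson r(a, b)) over all
    other samples b; a sample is flagged when D_a exceeds Q3(D) + 1.5*IQR(D)
    (Tukey fence, strict).  Zero-variance samples have undefined correlations
    and are auto-flagged as degenerate.  Removal is the caller's choice.
    """
    x = m.values.to_numpy(dtype=float)
    samples = list(m.values.columns)
    if x.shape[1] < 3:
        warnings.warn("detect_outlier_samples: fewer than 3 samples, no flags")
        return []
    sd = x.std(axis=0)
    degenerate = [s for s, v in zip(samples, sd) if v == 0]
    for s in degenerate:
        logger.warning("sample %s auto-flagged: degenerate (zero variance)", s)
    ok = [i for i, v in enumerate(sd) if v > 0]
    flagged = list(degenerate)
    if len(ok) >= 3:
        corr = np.corrcoef(x[:, ok].T)
        d = np.array([(1.0 - np.delete(corr[i], i)).mean() for i in range(len(ok))])
        q1, q3 = np.percentile(d, [25, 75])
        fence = q3 + 1.5 * (q3 - q1)
        for i, di in zip(ok, d):
            logger.info("outlier audit: sample=%s D=%.6g fence=%.6g",
                        samples[i], di, fence)
            if di > fence:
                flagged.append(samples[i])
    return flagged


def collapse_to_genes(m: ExpressionMatrix, ann: ProbeAnnotation) -> ExpressionMatrix:
    """Collapse probe rows to one row per mapped gene.

    Multi-probe genes take the arithmetic mean of their probe rows on the
    log2 scale; probes without an annotation record are removed.
    """
    genes = m.values.index.map(lambda p: ann.mapping.get(str(p)))
    mask = genes.notna()
    if not mask.any():
        raise ValueError("no probes mapped")
    dropped = (~mask).sum()
    if dropped:
        logger.info("collapse_to_genes: dropped %d unannotated probes", dropped)
    sub = m.values.loc[mask]
    collapsed = sub.groupby(genes[mask]).mean()
    collapsed.index.name = "gene_id"
    logger.info("collapse_to_genes: %d probes -> %d genes", mask.sum(), len(collapsed))
    return ExpressionMatrix(collapsed, m.groups, None)
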