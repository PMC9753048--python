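"""Spatiotemporal characterization of predictors and targeted re-decoding.

Two complementary maps describe where and when the category information
lives:

* the deviation index DI = (a - c) / (a + c), the signed contrast of
  category-mean high-gamma power (baseline-ratio normalized, so both
  means are positive and |DI| <= 1); positive = abstract-dominant,
  negative = concrete-dominant;
* the predictor-weight map, the fold-averaged absolute linear-SVM weight
  per (channel, bin).

Dimensions excluded by the rank-sum feature selection carry exactly 0 in
both maps.  Maps are aggregated into region x time-bin matrices, and
cells whose group-average weight exceeds the mean + SD of all cells
define the targeted feature subset for re-decoding.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .decoding import DecodingResult, FeatureMask, loocv_decode
from .io_core import REGIONS, AnalysisConfig, ElectrodeTable
from .preprocessing import BinnedPower

__all__ = [
    "TargetSet",
    "deviation_index",
    "build_di_map",
    "build_weight_map",
    "region_time_matrix",
    "aggregate_regions",
    "significant_predictors",
    "canonical_target_set",
    "allowed_feature_mask",
    "targeted_decode",
]


@dataclass(frozen=True)
class TargetSet:
    """Restricted feature space: (region, start_ms, end_ms) windows.

    Windows are relative to stimulus onset and align to analysis-bin
    edges.  The canonical restriction for this paradigm is the IFG in an
    early-to-mid window plus SM1 late (see :func:`canonical_target_set`).
    """

    windows: tuple  # of (region, start_ms, end_ms)

    def __post_init__(self):
        for region, lo, hi in self.windows:
            if region not in REGIONS:
                raise ValueError(f"unknown region {region!r}")
            if hi <= lo:
                raise ValueError(f"empty window [{lo}, {hi}] for {region}")

    def __len__(self) -> int:
        return len(self.windows)

    def to_json(self, path) -> None:
        with open(path, "w") as f:
            json.dump({"windows": [list(w) for w in self.windows]}, f, indent=2)

    @classmethod
    def from_json(cls, path) -> "TargetSet":
        with open(path) as f:
            d = json.load(f)
        return cls(windows=tuple((str(r), float(lo), float(hi)) for r, lo, hi in d["windows"]))


def canonical_target_set(variant: str = "significance") -> TargetSet:
    """The two published phrasings of the canonical restriction.

    ``'significance'``: IFG 250-1250 ms + SM1 1000-1500 ms (the windows
    flagged by the mean + SD rule); ``'extended'``: IFG 250-1500 ms +
    SM1 1000-1500 ms.
    """
    if variant == "significance":
        return TargetSet((("IFG", 250.0, 1250.0), ("SM1", 1000.0, 1500.0)))
    if variant == "extended":
        return TargetSet((("IFG", 250.0, 1500.0), ("SM1", 1000.0, 1500.0)))
    raise ValueError(f"unknown variant {variant!r}")


def deviation_index(mean_abstract, mean_concrete):
    """DI = (a - c) / (a + c); elementwise on arrays.

    Positive = abstract dominance, negative = concrete dominance.
    Bounded in [-1, 1] whenever both means are nonnegative.
    """
    a = np.asarray(mean_abstract, dtype=float)
    c = np.asarray(mean_concrete, dtype=float)
    denom = a + c
    if np.any(denom == 0):
        raise ZeroDivisionError("deviation index undefined where a + c = 0")
    return (a - c) / denom


def build_di_map(binned: BinnedPower, mask: FeatureMask,
                 config: AnalysisConfig) -> np.ndarray:
    """Deviation-index map over (channel, analysis bin).

    Power is normalized per channel by the mean baseline-window power of
    all trials (a positive ratio, so the DI is bounded); the DI contrasts
    the category means of the normalized power.  Dimensions excluded by
    ``mask`` are set exactly to 0.
    """
    labels = binned.labels
    base = binned.power[:, :, config.baseline_bins].mean(axis=(0, 2))  # per channel
    if np.any(base <= 0):
        raise ValueError("nonpositive baseline mean; cannot ratio-normalize")
    norm = binned.power[:, :, config.analysis_bins] / base[None, :, None]
    mean_a = norm[labels == 1].mean(axis=0)
    mean_c = norm[labels == -1].mean(axis=0)
    di = deviation_index(mean_a, mean_c)
    di[~mask.retained] = 0.0
    return di


def build_weight_map(result: DecodingResult, shape) -> np.ndarray:
    """Fold-averaged absolute SVM weight per (channel, bin).

    Each dimension's value is the mean of |weight| over the folds where
    it was retained, multiplied by the fraction of folds retaining it
    (equivalently, the sum of |weight| over folds divided by the number
    of folds); never-retained dimensions are exactly 0.
    """
    if len(result.folds) == 0:
        raise ValueError("need at least one fold")
    acc = np.zeros(shape)
    for f in result.folds:
        if f.mask.n_retained:
            acc[f.mask.retained] += np.abs(f.weights)
    return acc / len(result.folds)


def region_time_matrix(value_map: np.ndarray, electrodes: ElectrodeTable,
                       channel_ids) -> pd.DataFrame:
    """Average a (channel, bin) map over each region's channels.

    Excluded dimensions already carry 0 and are averaged as such.
    Returns a region x bin DataFrame covering the regions present.
    """
    region_ix = electrodes.region_indices(channel_ids)
    rows = {r: value_map[ix].mean(axis=0) for r, ix in region_ix.items()}
    regions = [r for r in REGIONS if r in rows]
    return pd.DataFrame([rows[r] for r in regions], index=regions)


def aggregate_regions(matrices) -> pd.DataFrame:
    """Unweighted group mean of per-participant region x bin matrices.

    A region absent from a participant (no channels) is simply missing
    from that participant's matrix and is excluded from the group mean
    for its cells.
    """
    matrices = list(matrices)
    if not matrices:
        raise ValueError("no matrices to aggregate")
    combined = pd.concat(matrices)
    group = combined.groupby(level=0).mean()
    order = [r for r in REGIONS if r in group.index]
    return group.loc[order]


def significant_predictors(weight_matrix: pd.DataFrame,
                           config: AnalysisConfig) -> TargetSet:
    """Cells strictly above the mean + SD of all region x bin weights,
    merged into per-region contiguous bin windows (ms)."""
    vals = weight_matrix.to_numpy().ravel()
    vals = vals[~np.isnan(vals)]
    thr = vals.mean() + vals.std()
    edges = config.analysis_bin_edges_ms
    windows = []
    for region in weight_matrix.index:
        above = weight_matrix.loc[region].to_numpy() > thr
        b = 0
        while b < len(above):
            if above[b]:
                b0 = b
                while b + 1 < len(above) and above[b + 1]:
                    b += 1
                windows.append((region, float(edges[b0]), float(edges[b + 1])))
            b += 1
    return TargetSet(tuple(windows))


def allowed_feature_mask(targets: TargetSet, electrodes: ElectrodeTable,
                         channel_ids, config: AnalysisConfig) -> np.ndarray:
    """Boolean (channel, analysis-bin) matrix of dimensions inside the
    TargetSet (channels via region labels, bins fully inside a window)."""
    region_of = electrodes.region_of()
    edges = config.analysis_bin_edges_ms
    n_bins = len(config.analysis_bins)
    allowed = np.zeros((len(channel_ids), n_bins), dtype=bool)
    for region, lo, hi in targets.windows:
        bins = [b for b in range(n_bins) if edges[b] >= lo and edges[b + 1] <= hi]
        chans = [i for i, ch in enumerate(channel_ids) if region_of.get(ch) == region]
        for i in chans:
            allowed[i, bins] = True
    return allowed


def targeted_decode(binned: BinnedPower, electrodes: ElectrodeTable,
                    config: AnalysisConfig, targets: TargetSet) -> DecodingResult:
    """Leave-one-out decoding restricted a priori to the TargetSet.

    Identical to the full pipeline except that the feature space is
    limited to (channel, bin) pairs inside the targeted windows before
    the per-fold rank-sum selection.
    """
    if len(targets) == 0:
        raise ValueError("TargetSet is empty")
    allowed = allowed_feature_mask(targets, electrodes, binned.channel_ids, config)
    if not allowed.any():
        raise ValueError("TargetSet restriction leaves no feature dimensions")
    return loocv_decode(binned, config, allowed=allowed)
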