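"""The six per-subject imaging features.

Four histogram-shape statistics are computed from the whole-brain
threshold sample (counts x_i, sample mean x̄, median Md, sample SD):

* ``SK``  — skewness, the moment ratio with n−1 denominators:
  [Σ(x_i−x̄)³/(n−1)] / [Σ(x_i−x̄)²/(n−1)]^(3/2)
* ``KUR`` — kurtosis, [Σ(x_i−x̄)⁴/(n−1)] / [Σ(x_i−x̄)²/(n−1)]²;
  the normal benchmark is 3.  ``excess=True`` subtracts 3.
* ``CSK`` — Cyhelsky's skewness coefficient,
  (n_below − n_above)/n_total, counting voxels strictly below/above the
  mean (ties at the mean counted in neither, but kept in n_total).
* ``MES`` — Pearson's median skewness, 3(x̄ − Md)/SD, bounded in [−3, 3].

Two volumetric features come from the grown striatal region:

* ``DTAV`` — dopamine-transporter activity volume: per-slice member area
  x slice thickness, summed over slices (mL in the feature table).
* ``DTAM`` — activity maximum: by default the maximum count inside the
  region (``max_count``, matching the count-scale magnitudes reported in
  patient cohorts); ``max_slice_volume`` gives the largest single-slice
  area x thickness instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .io import Volume
from .phantom import LabeledVolume
from .segmentation import DEFAULT_THRESHOLD, GrowConfig, find_seed, region_grow, threshold_mask

__all__ = [
    "CountSample",
    "FeatureVector",
    "FeatureConfig",
    "skewness",
    "kurtosis",
    "cyhelsky_skew",
    "pearson_median_skew",
    "dtav",
    "dtam",
    "compute_features",
    "feature_table",
    "SpectFeatureExtractor",
    "FEATURE_NAMES",
]

FEATURE_NAMES = ("SK", "KUR", "CSK", "MES", "DTAV", "DTAM")


@dataclass
class CountSample:
    """Summary of a masked-voxel count sample (the x_i of the formulas)."""

    values: np.ndarray
    n: int
    mean: float
    median: float
    sd: float
    n_below: int
    n_above: int

    @classmethod
    def from_values(cls, values) -> "CountSample":
        x = np.asarray(values, dtype=np.float64).ravel()
        if x.size == 0:
            raise ValueError("empty count sample")
        mean = float(x.mean())
        sd = float(x.std(ddof=1)) if x.size > 1 else 0.0
        return cls(
            values=x,
            n=int(x.size),
            mean=mean,
            median=float(np.median(x)),
            sd=sd,
            n_below=int((x < mean).sum()),
            n_above=int((x > mean).sum()),
        )


def _as_array(sample) -> np.ndarray:
    if isinstance(sample, CountSample):
        return sample.values
    return np.asarray(sample, dtype=np.float64).ravel()


def _central_sums(x: np.ndarray) -> tuple[np.ndarray, float]:
    d = x - x.mean()
    s2 = float((d * d).sum())
    return d, s2


def skewness(sample) -> float:
    """Moment skewness with n−1 denominators."""
    x = _as_array(sample)
    if x.size < 3:
        raise ValueError("skewness requires n >= 3")
    d, s2 = _central_sums(x)
    if s2 == 0.0:
        raise ValueError("skewness undefined for a constant sample")
    n1 = x.size - 1
    return float((d**3).sum() / n1 / (s2 / n1) ** 1.5)


def kurtosis(sample, excess: bool = False) -> float:
    """Moment kurtosis with n−1 denominators; normal benchmark 3."""
    x = _as_array(sample)
    if x.size < 4:
        raise ValueError("kurtosis requires n >= 4")
    d, s2 = _central_sums(x)
    if s2 == 0.0:
        raise ValueError("kurtosis undefined for a constant sample")
    n1 = x.size - 1
    k = float((d**4).sum() / n1 / (s2 / n1) ** 2)
    return k - 3.0 if excess else k


def cyhelsky_skew(sample) -> float:
    """(n_below − n_above) / n_total; ties at the mean counted in neither."""
    x = _as_array(sample)
    if x.size == 0:
        raise ValueError("empty sample")
    mean = x.mean()
    return float(((x < mean).sum() - (x > mean).sum()) / x.size)


def pearson_median_skew(sample) -> float:
    """3(mean − median)/SD with the n−1 (sample) standard deviation."""
    x = _as_array(sample)
    if x.size < 2:
        raise ValueError("Pearson median skewness requires n >= 2")
    sd = x.std(ddof=1)
    if sd == 0.0:
        raise ValueError("Pearson median skewness undefined for a constant sample")
    return float(3.0 * (x.mean() - np.median(x)) / sd)


def dtav(region: np.ndarray, spacing: Sequence[float]) -> float:
    """Region volume in mm^3: Σ_slices (member area × slice thickness).

    Algebraically equal to member-voxel count × voxel volume; computed
    slice-wise to mirror the per-slice definition.
    """
    if not region.any():
        raise ValueError("empty region")
    dx, dy, dz = spacing
    per_slice_area = region.sum(axis=(0, 1)) * dx * dy
    return float((per_slice_area * dz).sum())


def dtam(volume: Volume, region: np.ndarray, mode: str = "max_count") -> float:
    """Activity maximum inside the grown region.

    ``max_count``: maximum voxel count (default). ``max_slice_volume``:
    largest single-slice member area × slice thickness (mm^3).
    """
    if not region.any():
        raise ValueError("empty region")
    if mode == "max_count":
        return float(volume.counts[region].max())
    if mode == "max_slice_volume":
        dx, dy, dz = volume.spacing
        return float(region.sum(axis=(0, 1)).max() * dx * dy * dz)
    raise ValueError(f"unknown dtam mode {mode!r}")


@dataclass
class FeatureVector:
    """The six features for one subject (DTAV in mL, DTAM per dtam mode)."""

    SK: float
    KUR: float
    CSK: float
    MES: float
    DTAV: float
    DTAM: float

    def as_dict(self) -> dict[str, float]:
        return asdict(self)


@dataclass(frozen=True)
class FeatureConfig:
    """Extraction settings: whole-brain threshold, growth rule, conventions."""

    threshold: float = DEFAULT_THRESHOLD
    grow: GrowConfig = field(default_factory=GrowConfig)
    kurtosis_excess: bool = False
    dtam_mode: str = "max_count"


def compute_features(volume: Volume, cfg: FeatureConfig | None = None) -> FeatureVector:
    """Run both ROI procedures on one volume and evaluate all six features.

    SK/KUR/CSK/MES come from the whole-brain threshold sample; the seed is
    the hottest voxel within the brain mask; DTAV/DTAM come from the grown
    striatal region.  Deterministic.
    """
    cfg = cfg or FeatureConfig()
    brain = threshold_mask(volume, cfg.threshold)
    if not brain.any():
        raise ValueError(f"whole-brain mask empty at threshold {cfg.threshold}")
    sample = CountSample.from_values(volume.counts[brain])
    seed = find_seed(volume, within=brain)
    region = region_grow(volume, seed, cfg.grow)
    return FeatureVector(
        SK=skewness(sample),
        KUR=kurtosis(sample, excess=cfg.kurtosis_excess),
        CSK=cyhelsky_skew(sample),
        MES=pearson_median_skew(sample),
        DTAV=dtav(region, volume.spacing) / 1000.0,  # mm^3 -> mL
        DTAM=dtam(volume, region, cfg.dtam_mode),
    )


def feature_table(
    subjects: Iterable[LabeledVolume], cfg: FeatureConfig | None = None
) -> pd.DataFrame:
    """Per-subject feature rows (subject_id, stage, six features)."""
    rows = []
    for s in subjects:
        fv = compute_features(s.volume, cfg)
        rows.append({"subject_id": s.subject_id, "stage": s.stage, **fv.as_dict()})
    return pd.DataFrame(rows, columns=["subject_id", "stage", *FEATURE_NAMES])


class SpectFeatureExtractor(TransformerMixin, BaseEstimator):
    """Stateless sklearn transformer: Volumes in, feature matrix out.

    ``transform`` accepts an iterable of :class:`Volume` (or
    :class:`LabeledVolume`) and returns an (n_subjects, 6) DataFrame with
    columns ``FEATURE_NAMES``, composable with sklearn pipelines.
    """

    def __init__(
        self,
        threshold: float = DEFAULT_THRESHOLD,
        include_fraction: float = 0.5,
        connectivity: int = 26,
        kurtosis_excess: bool = False,
        dtam_mode: str = "max_count",
    ):
        self.threshold = threshold
        self.include_fraction = include_fraction
        self.connectivity = connectivity
        self.kurtosis_excess = kurtosis_excess
        self.dtam_mode = dtam_mode

    def _config(self) -> FeatureConfig:
        return FeatureConfig(
            threshold=self.threshold,
            grow=GrowConfig(
                connectivity=self.connectivity, include_fraction=self.include_fraction
            ),
            kurtosis_excess=self.kurtosis_excess,
            dtam_mode=self.dtam_mode,
        )

    def fit(self, X=None, y=None):
        return self

    def transform(self, X) -> pd.DataFrame:
        cfg = self._config()
        rows = []
        for item in X:
            vol = item.volume if isinstance(item, LabeledVolume) else item
            rows.append(compute_features(vol, cfg).as_dict())
        return pd.DataFrame(rows, columns=list(FEATURE_NAMES))
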