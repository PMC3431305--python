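"""Synthetic UPLC-TOF-MS feature tables with known ground truth.

Generates peak-area tables with the statistical structure the analysis
pipeline assumes: 45 wheat lines in 3 market classes (durum 6, hard
bread 27, soft bread 12) with color/habit subclasses, 9 technical
replicates per line (405 rows), and 3727 features. Feature intensities
are right-skewed (log-normal base levels) with multiplicative line-level
biological variation and proportional replicate noise. Three designed
feature strata make every pipeline stage exercisable:

* *noise* features suffer per-line dropout so the ">=80% present in some
  class" filter removes most of them,
* *low-mean* features are scaled below the mean-intensity threshold so
  the >=1.0 filter removes them,
* *marker* features carry a multiplicative class effect (3x by default)
  at the line level, plus weaker (1.5x) nested subclass effects, so the
  discriminant models and S-plot/jackknife selection can recover them.

The generator is a pure function of its config (seed mandatory).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .feature_table import (FeatureMeta, FeatureTable, ObservationMeta,
                            format_feature_id)


@dataclass(frozen=True)
class ClassSpec:
    """One market class: label, number of lines, and subclass sizes."""

    label: str
    n_lines: int
    subclasses: tuple[tuple[str, int], ...] = ()

    def __post_init__(self) -> None:
        if self.n_lines < 2:
            raise ValueError("class sizes must be >= 2")
        if self.subclasses and sum(n for _, n in self.subclasses) != self.n_lines:
            raise ValueError(f"subclass sizes must sum to n_lines for {self.label}")


#: the study design: 45 lines, 6/27/12, with color x habit subclasses
DEFAULT_CLASSES = (
    ClassSpec("DW", 6, (("DW", 6),)),
    ClassSpec("HBW", 27, (("HWW", 6), ("HWS", 4), ("HRW", 8), ("HRS", 9))),
    ClassSpec("SBW", 12, (("SWW", 6), ("SWS", 2), ("SRW", 4))),
)


@dataclass
class SimulationConfig:
    """Study-condition parameters for the synthetic generator."""

    classes: tuple[ClassSpec, ...] = DEFAULT_CLASSES
    replicates: int = 9
    n_features: int = 3727
    n_markers: int = 10                   # class-contrast markers
    marker_effect: float = 3.0            # multiplicative shift in elevated class
    n_subclass_markers: int = 3           # per subclass beyond the first
    subclass_effect: float = 1.5
    base_log_mean: float = 3.0            # log-normal location of base levels
    base_log_sd: float = 1.0
    line_log_sd: float = 0.25             # line-to-line biological spread
    replicate_cv: float = 0.2             # proportional technical noise
    dropout_prob: float = 0.7             # per-line dropout of noise features
    noise_fraction: float = 0.64          # fraction of features with dropout
    low_mean_fraction: float = 0.12       # fraction scaled below the mean filter
    low_mean_scale: float = 0.01          # intensity scale of low-mean features
    rt_range: tuple[float, float] = (0.0, 35.0)
    mz_range: tuple[float, float] = (50.0, 1500.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.marker_effect <= 0 or self.subclass_effect <= 0:
            raise ValueError("effects must be positive")
        for p in (self.dropout_prob, self.noise_fraction, self.low_mean_fraction):
            if not 0 <= p <= 1:
                raise ValueError("probabilities/fractions must be in [0, 1]")
        if self.noise_fraction + self.low_mean_fraction > 1:
            raise ValueError("noise + low-mean fractions exceed 1")
        if self.replicates < 1 or self.n_features < 1:
            raise ValueError("replicates and n_features must be >= 1")


@dataclass
class GroundTruth:
    """Planted structure: marker ids with elevated class, and true line means."""

    marker_direction: dict[str, str]          # feature id -> elevated class label
    subclass_marker_direction: dict[str, str] # feature id -> elevated subclass
    noise_feature_ids: list[str]
    low_mean_feature_ids: list[str]
    line_means: pd.DataFrame                  # lines x features true abundances

    @property
    def marker_ids(self) -> list[str]:
        return list(self.marker_direction)


def simulate_feature_table(cfg: SimulationConfig
                           ) -> tuple[FeatureTable, GroundTruth]:
    """Draw one synthetic feature table and its ground truth."""
    rng = np.random.default_rng(cfg.seed)

    # observation design
    line_ids, class_labels, subclass_labels = [], [], []
    for spec in cfg.classes:
        subs = spec.subclasses or ((spec.label, spec.n_lines),)
        for sub_label, n in subs:
            for _ in range(n):
                line_ids.append(f"{spec.label}-{len(line_ids) + 1:02d}")
                class_labels.append(spec.label)
                subclass_labels.append(sub_label)
    n_lines = len(line_ids)
    class_arr = np.array(class_labels, dtype=object)
    sub_arr = np.array(subclass_labels, dtype=object)

    # feature metadata: unique (rt, mz) identifiers
    features: list[FeatureMeta] = []
    used: set[str] = set()
    while len(features) < cfg.n_features:
        rt = rng.uniform(*cfg.rt_range)
        mz = rng.uniform(*cfg.mz_range)
        fid = format_feature_id(rt, mz)
        if fid not in used:
            used.add(fid)
            features.append(FeatureMeta(fid, round(rt, 2), round(mz, 4)))
    fids = [f.feature_id for f in features]

    # feature strata: markers first, then noise / low-mean / plain
    n_noise = int(round(cfg.noise_fraction * cfg.n_features))
    n_low = int(round(cfg.low_mean_fraction * cfg.n_features))
    # subclasses beyond the first of each class get nested marker features
    all_subs = [s for spec in cfg.classes
                for s, _ in (spec.subclasses[1:] if spec.subclasses else ())]
    n_submark = cfg.n_subclass_markers * len(all_subs)
    perm = rng.permutation(cfg.n_features)
    i = 0
    marker_idx = perm[i:i + cfg.n_markers]; i += cfg.n_markers
    submark_idx = perm[i:i + n_submark]; i += n_submark
    noise_idx = perm[i:i + n_noise]; i += n_noise
    low_idx = perm[i:i + n_low]; i += n_low

    # base log-normal levels per feature, line-level biological variation
    base = rng.lognormal(cfg.base_log_mean, cfg.base_log_sd, cfg.n_features)
    line_means = base[None, :] * rng.lognormal(
        0.0, cfg.line_log_sd, (n_lines, cfg.n_features))

    # plant class markers: elevated class assigned round-robin
    marker_direction: dict[str, str] = {}
    labels = [spec.label for spec in cfg.classes]
    for j, col in enumerate(marker_idx):
        elevated = labels[j % len(labels)]
        marker_direction[fids[col]] = elevated
        line_means[class_arr == elevated, col] *= cfg.marker_effect

    # plant nested subclass markers (weaker effect)
    subclass_marker_direction: dict[str, str] = {}
    for j, col in enumerate(submark_idx):
        elevated = all_subs[j % len(all_subs)]
        subclass_marker_direction[fids[col]] = elevated
        line_means[sub_arr == elevated, col] *= cfg.subclass_effect

    # low-mean features: scale far below the intensity threshold
    line_means[:, low_idx] *= cfg.low_mean_scale

    # per-line dropout of noise features (all replicates of a dropped
    # line share the zero, so the presence filter on the averaged table bites)
    dropped = rng.random((n_lines, len(noise_idx))) < cfg.dropout_prob
    for k, col in enumerate(noise_idx):
        line_means[dropped[:, k], col] = 0.0

    # replicate with proportional technical noise, floored at 0
    n_obs = n_lines * cfg.replicates
    intensities = np.repeat(line_means, cfg.replicates, axis=0)
    if cfg.replicate_cv > 0:
        noise = 1.0 + cfg.replicate_cv * rng.standard_normal(intensities.shape)
        intensities = np.clip(intensities * noise, 0.0, None)

    observations = []
    for li in range(n_lines):
        for r in range(1, cfg.replicates + 1):
            observations.append(ObservationMeta(
                line_id=line_ids[li], class_label=class_labels[li],
                subclass_label=subclass_labels[li], replicate=r))

    table = FeatureTable(intensities, features, observations)
    truth = GroundTruth(
        marker_direction=marker_direction,
        subclass_marker_direction=subclass_marker_direction,
        noise_feature_ids=[fids[c] for c in noise_idx],
        low_mean_feature_ids=[fids[c] for c in low_idx],
        line_means=pd.DataFrame(line_means, index=line_ids, columns=fids),
    )
    return table, truth


def presence_survival_probability(cfg: SimulationConfig,
                                  frac: float = 0.8) -> float:
    """Exact probability that one dropout feature survives the presence filter.

    The feature is present in a line with probability 1 - dropout_prob,
    independently; it survives iff, in at least one class, the binomial
    count of present lines reaches ``ceil(frac * n_class)``.
    """
    p_present = 1.0 - cfg.dropout_prob
    prob_all_fail = 1.0
    for spec in cfg.classes:
        need = int(np.ceil(frac * spec.n_lines))
        p_class_pass = float(stats.binom.sf(need - 1, spec.n_lines, p_present))
        prob_all_fail *= 1.0 - p_class_pass
    return 1.0 - prob_all_fail


def expected_filter_survivors(cfg: SimulationConfig, frac: float = 0.8
                              ) -> tuple[float, float]:
    """Expected count and binomial SD of dropout features passing the 80% rule."""
    n_noise = int(round(cfg.noise_fraction * cfg.n_features))
    p = presence_survival_probability(cfg, frac)
    return n_noise * p, float(np.sqrt(n_noise * p * (1 - p)))
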