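"""Feature-table data model, I/O, replicate averaging, ion filtering and Pareto scaling.

An untargeted UPLC-TOF-MS experiment yields a matrix of peak-area
intensities in which rows are observations (wheat line x technical
replicate) and columns are chemical features identified by a
``"<rt>_<mz>"`` string (retention time in minutes, m/z in daltons).
Absent peaks are encoded as 0, never as missing values.

The pre-modelling reduction pipeline is: average technical replicates
per line, drop features not present (> 0) in at least 80% of the lines
of at least one class, drop features whose pooled mean intensity is
below 1.0, then Pareto-scale (center, divide by sqrt of the sample
standard deviation) before any latent-variable modelling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: default metadata column names for feature-table CSVs
DEFAULT_SCHEMA = {
    "line_id": "line_id",
    "class_label": "class",
    "subclass_label": "subclass",
    "replicate": "replicate",
}


@dataclass(frozen=True)
class FeatureMeta:
    """One chemical feature: an (RT, m/z) pair with its string identifier."""

    feature_id: str
    rt: float
    mz: float

    def __post_init__(self) -> None:
        if self.rt < 0:
            raise ValueError(f"negative retention time for {self.feature_id!r}")
        if self.mz <= 0:
            raise ValueError(f"non-positive m/z for {self.feature_id!r}")


@dataclass(frozen=True)
class ObservationMeta:
    """One observed row: a wheat line, its class/subclass, and a replicate index."""

    line_id: str
    class_label: str
    subclass_label: str | None = None
    replicate: int = 1

    def __post_init__(self) -> None:
        if self.replicate < 1:
            raise ValueError("replicate index must be >= 1")


@dataclass(frozen=True)
class FilterReport:
    """Bookkeeping for one filtering stage; counts are conserved."""

    stage_name: str
    n_before: int
    n_removed: int
    n_retained: int

    def __post_init__(self) -> None:
        if self.n_before != self.n_removed + self.n_retained:
            raise ValueError("filter counts do not conserve: "
                             f"{self.n_before} != {self.n_removed} + {self.n_retained}")

    @property
    def removed_fraction(self) -> float:
        return self.n_removed / self.n_before if self.n_before else 0.0

    def to_tsv_line(self) -> str:
        return (f"{self.stage_name}\t{self.n_before}\t{self.n_removed}\t"
                f"{self.n_retained}\t{100.0 * self.removed_fraction:.1f}%")


def format_feature_id(rt: float, mz: float) -> str:
    """Canonical feature identifier: RT to 2 decimals, m/z to 4 decimals."""
    return f"{rt:.2f}_{mz:.4f}"


def parse_feature_id(feature_id: str) -> tuple[float, float]:
    """Parse ``"<rt>_<mz>"`` back to (rt, mz); tolerant of trailing-zero variants."""
    parts = feature_id.split("_")
    if len(parts) != 2:
        raise ValueError(f"feature id {feature_id!r} is not of the form '<rt>_<mz>'")
    try:
        rt, mz = float(parts[0]), float(parts[1])
    except ValueError as exc:
        raise ValueError(f"feature id {feature_id!r} has non-numeric parts") from exc
    return rt, mz


class FeatureTable:
    """Observations x features intensity matrix with row and column metadata.

    Parameters
    ----------
    intensities
        Nonnegative (n_obs, n_features) array; absence encoded as 0.
    features
        One :class:`FeatureMeta` per column, ids unique.
    observations
        One :class:`ObservationMeta` per row; (line_id, replicate) unique,
        and every line carries a single class label across its replicates.
    """

    def __init__(self, intensities: np.ndarray,
                 features: list[FeatureMeta],
                 observations: list[ObservationMeta]):
        intensities = np.asarray(intensities, dtype=float)
        if intensities.ndim != 2:
            raise ValueError("intensities must be a 2-D matrix")
        if intensities.shape != (len(observations), len(features)):
            raise ValueError(
                f"matrix shape {intensities.shape} does not match "
                f"{len(observations)} observations x {len(features)} features")
        if not np.isfinite(intensities).all():
            raise ValueError("intensities contain non-finite values")
        if (intensities < 0).any():
            raise ValueError("intensities must be nonnegative")

        ids = [f.feature_id for f in features]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate feature ids: {dupes}")

        keys = [(o.line_id, o.replicate) for o in observations]
        if len(set(keys)) != len(keys):
            dupes = sorted({k for k in keys if keys.count(k) > 1})
            raise ValueError(f"duplicate (line_id, replicate) pairs: {dupes}")

        by_line: dict[str, str] = {}
        for o in observations:
            prev = by_line.setdefault(o.line_id, o.class_label)
            if prev != o.class_label:
                raise ValueError(
                    f"line {o.line_id!r} carries inconsistent class labels "
                    f"({prev!r} vs {o.class_label!r})")

        self.intensities = intensities
        self.features = list(features)
        self.observations = list(observations)

    # -- convenience views ------------------------------------------------
    @property
    def n_obs(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_features(self) -> int:
        return self.intensities.shape[1]

    @property
    def feature_ids(self) -> list[str]:
        return [f.feature_id for f in self.features]

    @property
    def class_labels(self) -> np.ndarray:
        return np.array([o.class_label for o in self.observations], dtype=object)

    @property
    def subclass_labels(self) -> np.ndarray:
        return np.array([o.subclass_label for o in self.observations], dtype=object)

    @property
    def line_ids(self) -> np.ndarray:
        return np.array([o.line_id for o in self.observations], dtype=object)

    def select_features(self, mask: np.ndarray) -> "FeatureTable":
        mask = np.asarray(mask, dtype=bool)
        feats = [f for f, keep in zip(self.features, mask) if keep]
        return FeatureTable(self.intensities[:, mask], feats, self.observations)

    def select_observations(self, mask: np.ndarray) -> "FeatureTable":
        mask = np.asarray(mask, dtype=bool)
        obs = [o for o, keep in zip(self.observations, mask) if keep]
        return FeatureTable(self.intensities[mask, :], self.features, obs)

    def to_dataframe(self) -> pd.DataFrame:
        meta = pd.DataFrame({
            "line_id": self.line_ids,
            "class": self.class_labels,
            "subclass": [s if s is not None else "" for s in self.subclass_labels],
            "replicate": [o.replicate for o in self.observations],
        })
        data = pd.DataFrame(self.intensities, columns=self.feature_ids)
        return pd.concat([meta, data.set_index(meta.index)], axis=1)


# -- I/O -------------------------------------------------------------------

def read_feature_table(path, schema: dict[str, str] | None = None) -> FeatureTable:
    """Read a feature table from CSV (MarkerLynx-export-like layout).

    Metadata columns (per ``schema``, default line_id/class/subclass/replicate)
    come first; every remaining column is a feature named ``"<rt>_<mz>"``.
    """
    schema = dict(DEFAULT_SCHEMA, **(schema or {}))
    df = pd.read_csv(path, dtype={schema["line_id"]: str})

    for role in ("line_id", "class_label", "replicate"):
        if schema[role] not in df.columns:
            raise ValueError(f"missing metadata column {schema[role]!r} ({role})")
    has_subclass = schema["subclass_label"] in df.columns

    meta_cols = {schema["line_id"], schema["class_label"], schema["replicate"]}
    if has_subclass:
        meta_cols.add(schema["subclass_label"])
    feat_cols = [c for c in df.columns if c not in meta_cols]

    seen: dict[str, int] = {}
    for c in feat_cols:
        seen[c] = seen.get(c, 0) + 1
    # pandas mangles duplicate headers to "x.1"; detect that spelling too
    mangled = [c for c in feat_cols
               if "." in c and c.rsplit(".", 1)[-1].isdigit()
               and c.rsplit(".", 1)[0] in seen]
    dupes = sorted([c for c, n in seen.items() if n > 1]
                   + [c.rsplit(".", 1)[0] for c in mangled])
    if dupes:
        raise ValueError(f"duplicate feature columns: {sorted(set(dupes))}")

    features = []
    for c in feat_cols:
        rt, mz = parse_feature_id(c)
        features.append(FeatureMeta(feature_id=c, rt=rt, mz=mz))

    block = df[feat_cols]
    numeric = block.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & block.notna()
    if bad.any().any() or numeric.isna().any().any():
        r, c = np.argwhere(numeric.isna().to_numpy())[0]
        raise ValueError(
            f"non-numeric intensity at row {r}, column {feat_cols[c]!r}")

    observations = []
    for _, row in df.iterrows():
        sub = row[schema["subclass_label"]] if has_subclass else None
        if isinstance(sub, float) and np.isnan(sub):
            sub = None
        if sub == "":
            sub = None
        observations.append(ObservationMeta(
            line_id=str(row[schema["line_id"]]),
            class_label=str(row[schema["class_label"]]),
            subclass_label=None if sub is None else str(sub),
            replicate=int(row[schema["replicate"]]),
        ))

    return FeatureTable(numeric.to_numpy(dtype=float), features, observations)


def write_feature_table(ft: FeatureTable, path) -> None:
    """Write a feature table CSV in the same dialect ``read_feature_table`` reads."""
    ft.to_dataframe().to_csv(path, index=False)


# -- reduction pipeline ----------------------------------------------------

def average_replicates(ft: FeatureTable) -> FeatureTable:
    """Average technical replicates: one row per wheat line.

    Class/subclass metadata are carried through; the replicate index of
    the averaged row is 1. Order of first appearance of lines is kept.
    """
    order: list[str] = []
    rows: dict[str, list[int]] = {}
    for i, o in enumerate(ft.observations):
        if o.line_id not in rows:
            order.append(o.line_id)
            rows[o.line_id] = []
        rows[o.line_id].append(i)

    means = np.empty((len(order), ft.n_features))
    obs = []
    for j, line in enumerate(order):
        idx = rows[line]
        means[j] = ft.intensities[idx].mean(axis=0)
        first = ft.observations[idx[0]]
        # class consistency within a line is enforced by the FeatureTable
        # constructor; subclass must agree too
        subs = {ft.observations[i].subclass_label for i in idx}
        if len(subs) > 1:
            raise ValueError(f"line {line!r} carries inconsistent subclass labels")
        obs.append(ObservationMeta(line_id=line, class_label=first.class_label,
                                   subclass_label=first.subclass_label, replicate=1))
    return FeatureTable(means, ft.features, obs)


def filter_presence(ft: FeatureTable, frac: float = 0.8
                    ) -> tuple[FeatureTable, FilterReport]:
    """Retain features present (> 0) in >= ``frac`` of the rows of some class.

    A feature survives iff there exists at least one class in which the
    fraction of that class's rows with strictly positive intensity meets
    the threshold (inclusive). Intended to run on the replicate-averaged
    table so "rows" are wheat lines.
    """
    if not 0 < frac <= 1:
        raise ValueError("frac must be in (0, 1]")
    labels = ft.class_labels
    classes = pd.unique(labels)
    keep = np.zeros(ft.n_features, dtype=bool)
    for cls in classes:
        sub = ft.intensities[labels == cls]
        if sub.shape[0] == 0:
            raise ValueError(f"class {cls!r} has no rows")
        present = (sub > 0).mean(axis=0)
        keep |= present >= frac
    report = FilterReport("presence>=%.0f%%" % (100 * frac), ft.n_features,
                          int((~keep).sum()), int(keep.sum()))
    logger.info(report.to_tsv_line())
    return ft.select_features(keep), report


def filter_mean_intensity(ft: FeatureTable, min_mean: float = 1.0
                          ) -> tuple[FeatureTable, FilterReport]:
    """Retain features whose pooled mean intensity over all rows is >= ``min_mean``."""
    keep = ft.intensities.mean(axis=0) >= min_mean
    report = FilterReport(f"mean>={min_mean:g}", ft.n_features,
                          int((~keep).sum()), int(keep.sum()))
    logger.info(report.to_tsv_line())
    return ft.select_features(keep), report


@dataclass
class ParetoScaler:
    """Per-feature centering mean and standard deviation for Pareto scaling.

    Pareto scaling centers each column and divides by the *square root*
    of its sample standard deviation (n-1 denominator), damping the
    dominance of intense peaks while leaving more variance structure
    intact than unit-variance scaling. Columns with zero variance map
    to all-zero columns.
    """

    mean: np.ndarray
    sd: np.ndarray

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        divisor = np.sqrt(self.sd, where=self.sd > 0, out=np.ones_like(self.sd))
        out = (X - self.mean) / divisor
        out[:, self.sd == 0] = 0.0
        return out


def pareto_scale(ft: FeatureTable | np.ndarray
                 ) -> tuple[np.ndarray, ParetoScaler]:
    """Pareto-scale a feature table (or raw matrix) column-wise.

    Returns the scaled matrix and the fitted :class:`ParetoScaler` so new
    observations can be projected with the training parameters.
    """
    X = ft.intensities if isinstance(ft, FeatureTable) else np.asarray(ft, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("Pareto scaling requires at least 2 rows")
    scaler = ParetoScaler(mean=X.mean(axis=0), sd=X.std(axis=0, ddof=1))
    return scaler.transform(X), scaler
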