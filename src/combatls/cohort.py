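"""Cohort containers, delimited-text IO, adaptive QC filtering, log transform.

A :class:`Cohort` holds a subjects x features matrix plus the covariates the
harmonization and normative models condition on: age (in days), binarized sex
(female = 0 is the reference level), a categorical batch/site label, and an
optional scan-quality metric (Euler-index-like; larger = worse as supplied).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

#: 34 Desikan-Killiany cortical parcels per hemisphere.
DK_REGIONS = [
    "bankssts", "caudalanteriorcingulate", "caudalmiddlefrontal", "cuneus",
    "entorhinal", "frontalpole", "fusiform", "inferiorparietal",
    "inferiortemporal", "insula", "isthmuscingulate", "lateraloccipital",
    "lateralorbitofrontal", "lingual", "medialorbitofrontal", "middletemporal",
    "paracentral", "parahippocampal", "parsopercularis", "parsorbitalis",
    "parstriangularis", "pericalcarine", "postcentral", "posteriorcingulate",
    "precentral", "precuneus", "rostralanteriorcingulate",
    "rostralmiddlefrontal", "superiorfrontal", "superiorparietal",
    "superiortemporal", "supramarginal", "temporalpole", "transversetemporal",
]

DEFAULT_GLOBALS = ["GMV", "WMV", "sGMV", "Ventricles"]
DEFAULT_MEASURES = ["volume", "area", "thickness"]


@dataclass(frozen=True)
class FeatureSchema:
    """Names and categories of the neuroanatomical feature set.

    The default schema is 4 global tissue volumes plus 68 cortical regions
    (34 per hemisphere) x 3 measures = 208 features, partitioned into the
    categories global / volume / area / thickness.
    """

    global_names: tuple[str, ...]
    region_names: tuple[str, ...]
    measures: tuple[str, ...]
    category_of: dict[str, str] = field(hash=False)

    @property
    def feature_names(self) -> list[str]:
        return list(self.category_of)

    @property
    def n_features(self) -> int:
        return len(self.category_of)

    def categories(self, features: list[str] | None = None) -> np.ndarray:
        """Category label per feature, in the given (or schema) order."""
        feats = features if features is not None else self.feature_names
        return np.array([self.category_of[f] for f in feats])


def build_feature_schema(
    n_regions: int = 68,
    measures: list[str] | None = None,
    global_names: list[str] | None = None,
    region_names: list[str] | None = None,
) -> FeatureSchema:
    """Construct a feature schema with ``len(globals) + n_regions * len(measures)``
    features and a total category map.

    Region names default to left/right Desikan-Killiany parcels when
    ``n_regions`` is 68; otherwise they are generated as ``region_01`` ...
    Duplicate feature names raise ``ValueError``.
    """
    if n_regions < 0:
        raise ValueError("n_regions must be nonnegative")
    measures = DEFAULT_MEASURES if measures is None else list(measures)
    global_names = DEFAULT_GLOBALS if global_names is None else list(global_names)
    if region_names is None:
        if n_regions == 2 * len(DK_REGIONS):
            region_names = [f"{h}_{r}" for h in ("lh", "rh") for r in DK_REGIONS]
        else:
            region_names = [f"region_{i + 1:02d}" for i in range(n_regions)]
    if len(region_names) != n_regions:
        raise ValueError("region_names length must equal n_regions")

    category_of: dict[str, str] = {}
    for g in global_names:
        category_of[g] = "global"
    for r in region_names:
        for m in measures:
            category_of[f"{r}_{m}"] = m if m in ("area", "thickness") else "volume"
    n_expected = len(global_names) + n_regions * len(measures)
    if len(category_of) != n_expected:
        raise ValueError("duplicate feature names in schema")
    return FeatureSchema(
        tuple(global_names), tuple(region_names), tuple(measures), category_of
    )


@dataclass
class Cohort:
    """Validated subjects x features table with aligned covariates.

    ``features`` and ``covariates`` share an index of subject identifiers.
    ``covariates`` must contain ``age`` (days), ``sex`` (0 = female,
    1 = male) and ``batch``; ``qc`` is optional.
    """

    features: pd.DataFrame
    covariates: pd.DataFrame
    log_scale: bool = False
    n_dropped: int = 0

    def __post_init__(self) -> None:
        self.validate()

    # -- basic accessors -------------------------------------------------
    @property
    def n_subjects(self) -> int:
        return len(self.features)

    @property
    def feature_names(self) -> list[str]:
        return list(self.features.columns)

    @property
    def batch(self) -> pd.Series:
        return self.covariates["batch"]

    def validate(self, min_batch_size: int | None = None) -> None:
        if not self.features.index.equals(self.covariates.index):
            raise ValueError("features and covariates must share the same index")
        for col in ("age", "sex", "batch"):
            if col not in self.covariates.columns:
                raise ValueError(f"covariates missing required column '{col}'")
        if self.features.columns.duplicated().any():
            raise ValueError("feature names must be unique")
        if not np.all(np.isfinite(self.features.to_numpy(dtype=float))):
            raise ValueError("features contain missing or non-finite values")
        if (np.asarray(self.covariates["age"], dtype=float) < 0).any():
            raise ValueError("age must be nonnegative (days)")
        sex = np.asarray(self.covariates["sex"])
        if not np.isin(sex, [0, 1]).all():
            raise ValueError("sex must be binary {0=female, 1=male}")
        if min_batch_size is not None:
            counts = self.covariates["batch"].value_counts()
            small = counts[counts < min_batch_size]
            if len(small):
                raise ValueError(
                    f"batches with fewer than {min_batch_size} subjects: "
                    f"{dict(small)}"
                )

    def subset(self, mask: np.ndarray) -> "Cohort":
        return replace(
            self,
            features=self.features.loc[mask].copy(),
            covariates=self.covariates.loc[mask].copy(),
        )


def read_cohort(
    path,
    column_map: dict | str | None = None,
    delimiter: str = "\t",
) -> Cohort:
    """Read a delimited cohort table.

    ``column_map`` maps canonical names (``subject_id``, ``age``, ``sex``,
    ``batch``, optional ``qc``, and ``features``: a list of feature columns)
    to the file's column names; it may also be a path to a YAML file with the
    same structure.  Rows with missing values in any mapped column are dropped
    (listwise deletion) and the dropped count is logged and recorded on the
    returned cohort.
    """
    if isinstance(column_map, str):
        with open(column_map) as fh:
            column_map = yaml.safe_load(fh)
    df = pd.read_csv(path, sep=delimiter)
    column_map = column_map or {}
    rename = {
        column_map.get(k, k): k for k in ("subject_id", "age", "sex", "batch", "qc")
    }
    feature_cols = column_map.get("features")
    for want, canon in [(v, k) for v, k in rename.items() if k != "qc"]:
        if want not in df.columns:
            raise ValueError(f"required column '{want}' (for '{canon}') not found")
    df = df.rename(columns=rename)
    if feature_cols is None:
        known = {"subject_id", "age", "sex", "batch", "qc"}
        feature_cols = [c for c in df.columns if c not in known]
    else:
        missing = [c for c in feature_cols if c not in df.columns]
        if missing:
            raise ValueError(f"feature columns not found: {missing}")

    for c in feature_cols:
        converted = pd.to_numeric(df[c], errors="coerce")
        bad = converted.isna() & df[c].notna()
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise ValueError(
                f"non-numeric value in feature column '{c}' at row {row}: "
                f"{df[c].iloc[row]!r}"
            )
        df[c] = converted

    used = ["subject_id", "age", "sex", "batch"] + (
        ["qc"] if "qc" in df.columns else []
    ) + list(feature_cols)
    complete = df[used].notna().all(axis=1)
    n_dropped = int((~complete).sum())
    if n_dropped:
        logger.info("read_cohort: dropped %d rows with missing values", n_dropped)
    df = df.loc[complete].set_index("subject_id")

    cov_cols = ["age", "sex", "batch"] + (["qc"] if "qc" in df.columns else [])
    return Cohort(
        features=df[list(feature_cols)].astype(float),
        covariates=df[cov_cols],
        n_dropped=n_dropped,
    )


def write_cohort(cohort: Cohort, path, delimiter: str = "\t", provenance: dict | None = None) -> None:
    """Write the cohort as a delimited table plus a JSON provenance sidecar."""
    out = pd.concat([cohort.covariates, cohort.features], axis=1)
    out.index.name = "subject_id"
    out.to_csv(path, sep=delimiter, float_format="%.15g")
    record = {
        "n_subjects": cohort.n_subjects,
        "n_features": len(cohort.feature_names),
        "n_dropped": cohort.n_dropped,
        "log_scale": cohort.log_scale,
    }
    record.update(provenance or {})
    with open(f"{path}.provenance.json", "w") as fh:
        json.dump(record, fh, indent=2)


def euler_qc_filter(qc, batch, k: float = 2.0) -> np.ndarray:
    """Keep-mask for the adaptive scan-quality filter.

    Within each batch, subjects whose quality metric exceeds the batch median
    plus ``k`` raw median absolute deviations (no normal-consistency constant)
    are removed.  The metric is filtered on its high tail, so callers supply
    it with "greater = worse" orientation (e.g. ``|Euler|``).  Batches with
    fewer than 2 subjects pass unfiltered with a warning.
    """
    qc = np.asarray(qc, dtype=float)
    if not np.all(np.isfinite(qc)):
        raise ValueError("qc metric contains non-finite values")
    batch = np.asarray(batch)
    keep = np.ones(len(qc), dtype=bool)
    for lev in pd.unique(batch):
        idx = batch == lev
        if idx.sum() < 2:
            warnings.warn(
                f"batch {lev!r} has fewer than 2 subjects; passes QC unfiltered",
                stacklevel=2,
            )
            continue
        med = np.median(qc[idx])
        mad = np.median(np.abs(qc[idx] - med))
        keep[idx] = qc[idx] <= med + k * mad
    return keep


def log_transform(cohort: Cohort) -> Cohort:
    """Natural-log transform of all feature values (exact inverse: :func:`exp_transform`)."""
    if cohort.log_scale:
        raise ValueError("cohort is already on the log scale")
    vals = cohort.features.to_numpy(dtype=float)
    bad = vals <= 0
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"log transform requires strictly positive values; feature "
            f"'{cohort.features.columns[j]}' of subject "
            f"{cohort.features.index[i]!r} is {vals[i, j]}"
        )
    return replace(
        cohort,
        features=pd.DataFrame(
            np.log(vals), index=cohort.features.index, columns=cohort.features.columns
        ),
        log_scale=True,
    )


def exp_transform(cohort: Cohort) -> Cohort:
    """Inverse of :func:`log_transform`."""
    if not cohort.log_scale:
        raise ValueError("cohort is not on the log scale")
    return replace(
        cohort,
        features=pd.DataFrame(
            np.exp(cohort.features.to_numpy(dtype=float)),
            index=cohort.features.index,
            columns=cohort.features.columns,
        ),
        log_scale=False,
    )
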