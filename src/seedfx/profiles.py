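"""From per-cell features to per-well and per-sequence profiles.

The pipeline order is fixed and order matters:

1. per-plate robust normalization of every cell against the untreated
   cells of its plate: ``(x - median) / (MAD * 1.4826)``;
2. exclusion of features whose untreated MAD is zero on any plate;
3. per-well profile = featurewise median over the cells of the well
   (after any QC well exclusions);
4. PCA fit on all well profiles, keeping the smallest number of leading
   components whose cumulative explained variance reaches the threshold
   (default 99%), and projection of every well profile;
5. per-sequence profile = featurewise median of the reagent's replicate
   well profiles, taken in PCA space.

The 1.4826 factor makes the MAD a consistent estimator of the standard
deviation under normality, so normalized units are comparable to z-scores
while staying robust to the outlier cells every imaging experiment has.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .simulate import UNTREATED

__all__ = [
    "MAD_SCALE",
    "NormalizationStats",
    "FeatureMask",
    "PcaModel",
    "compute_norm_stats",
    "normalize",
    "build_feature_mask",
    "aggregate_wells",
    "fit_pca",
    "project",
    "aggregate_sequences",
]

logger = logging.getLogger("seedfx")

#: consistency constant relating the MAD to the standard deviation of a normal
MAD_SCALE = 1.4826

KEY_COLUMNS = ("Plate", "Well", "Cell")


def feature_columns(cells: pd.DataFrame) -> list[str]:
    return [c for c in cells.columns if c not in KEY_COLUMNS]


@dataclass(frozen=True)
class NormalizationStats:
    """Per-(plate, feature) median and raw MAD of untreated cells.

    ``median`` and ``mad`` are DataFrames indexed by plate with one
    column per feature. The MAD is stored unscaled (median absolute
    deviation from the median); the 1.4826 factor is applied at
    normalization time.
    """

    median: pd.DataFrame
    mad: pd.DataFrame

    @property
    def plates(self) -> list[str]:
        return list(self.median.index)

    @property
    def features(self) -> list[str]:
        return list(self.median.columns)


@dataclass(frozen=True)
class FeatureMask:
    """Which features survive the MAD = 0 exclusion rule."""

    features: tuple[str, ...]
    retained: tuple[bool, ...]

    @property
    def retained_features(self) -> list[str]:
        return [f for f, keep in zip(self.features, self.retained) if keep]

    @property
    def n_retained(self) -> int:
        return int(sum(self.retained))


@dataclass(frozen=True)
class PcaModel:
    """Fitted PCA with the retained-component count for a variance target.

    ``components`` holds all fitted loadings (rows = components, ordered
    by explained variance); only the first ``k`` are used when
    projecting. ``explained_variance_ratio`` covers all components and
    sums to 1.
    """

    mean: np.ndarray
    components: np.ndarray
    explained_variance_ratio: np.ndarray
    k: int
    feature_names: tuple[str, ...]
    variance_threshold: float

    @property
    def component_names(self) -> list[str]:
        return [f"PC_{i + 1:03d}" for i in range(self.k)]


def compute_norm_stats(cells: pd.DataFrame, metadata: pd.DataFrame) -> NormalizationStats:
    """Median and MAD per (plate, feature) over that plate's untreated cells.

    Raises ``ValueError`` naming the plate if any plate has no untreated
    cells — normalization statistics must come from unperturbed cells.
    """
    untreated_wells = metadata.loc[metadata["IsUntreated"].astype(bool), ["Plate", "Well"]]
    key = pd.MultiIndex.from_frame(untreated_wells)
    cell_key = pd.MultiIndex.from_frame(cells[["Plate", "Well"]])
    untreated_cells = cells[cell_key.isin(key)]

    feats = feature_columns(cells)
    medians, mads = {}, {}
    for plate in sorted(cells["Plate"].unique()):
        sub = untreated_cells[untreated_cells["Plate"] == plate]
        if len(sub) == 0:
            raise ValueError(f"plate {plate!r} has no untreated cells")
        values = sub[feats].to_numpy(float)
        med = np.median(values, axis=0)
        mad = np.median(np.abs(values - med), axis=0)
        medians[plate] = med
        mads[plate] = mad
    median_df = pd.DataFrame.from_dict(medians, orient="index", columns=feats)
    mad_df = pd.DataFrame.from_dict(mads, orient="index", columns=feats)
    return NormalizationStats(median=median_df, mad=mad_df)


def normalize(cells: pd.DataFrame, stats: NormalizationStats) -> pd.DataFrame:
    """Robust-normalize every cell against its plate's untreated statistics.

    ``value' = (value - median) / (MAD * 1.4826)``. Features whose MAD is
    zero on the cell's plate are left untouched — they are removed later
    by the feature mask, never divided by zero.
    """
    unknown = set(cells["Plate"].unique()) - set(stats.plates)
    if unknown:
        raise ValueError(f"no normalization stats for plate(s): {sorted(unknown)}")
    feats = stats.features
    out = cells.copy()
    values = out[feats].to_numpy(float)
    plate_codes = pd.Categorical(out["Plate"], categories=stats.plates).codes
    med = stats.median.to_numpy(float)[plate_codes]
    mad = stats.mad.to_numpy(float)[plate_codes]
    scale = mad * MAD_SCALE
    with np.errstate(divide="ignore", invalid="ignore"):
        normed = (values - med) / scale
    out[feats] = np.where(scale > 0, normed, values)
    return out


def build_feature_mask(stats: NormalizationStats) -> FeatureMask:
    """Retain a feature iff its untreated MAD is nonzero on every plate."""
    retained = (stats.mad.to_numpy(float) > 0).all(axis=0)
    return FeatureMask(features=tuple(stats.features), retained=tuple(map(bool, retained)))


def aggregate_wells(
    cells_normalized: pd.DataFrame,
    mask: FeatureMask,
    metadata: pd.DataFrame,
    excluded_wells: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-well profiles: featurewise median over the well's cells.

    ``excluded_wells`` (columns Plate, Well) are dropped before
    aggregation — the hook for image-QC exclusions. Wells present in the
    metadata but left with no cells are dropped with a warning. Returns a
    DataFrame with key columns Plate, Well and one column per retained
    feature; cell order within a well is irrelevant.
    """
    cells = cells_normalized
    if excluded_wells is not None and len(excluded_wells):
        bad = pd.MultiIndex.from_frame(excluded_wells[["Plate", "Well"]])
        cell_key = pd.MultiIndex.from_frame(cells[["Plate", "Well"]])
        cells = cells[~cell_key.isin(bad)]
    feats = mask.retained_features
    grouped = cells.groupby(["Plate", "Well"], sort=True)[feats].median()
    expected = metadata[["Plate", "Well"]]
    if excluded_wells is not None and len(excluded_wells):
        bad = pd.MultiIndex.from_frame(excluded_wells[["Plate", "Well"]])
        expected = expected[~pd.MultiIndex.from_frame(expected).isin(bad)]
    missing = set(map(tuple, expected.to_numpy())) - set(grouped.index)
    for plate, well in sorted(missing):
        logger.warning("well %s/%s has no cells after exclusions; dropped", plate, well)
    return grouped.reset_index()


def fit_pca(well_profiles: pd.DataFrame, variance_threshold: float = 0.99) -> PcaModel:
    """Fit PCA on all well profiles and pick the retained-component count.

    ``k`` is the smallest number of leading components whose cumulative
    explained-variance fraction reaches the threshold. The model is fit
    on every well profile, treated and untreated alike, defining one
    shared profile space for the experiment.
    """
    feats = [c for c in well_profiles.columns if c not in ("Plate", "Well")]
    X = well_profiles[feats].to_numpy(float)
    if X.shape[0] < 2:
        raise ValueError("PCA needs at least 2 well profiles")
    if not np.isfinite(X).all():
        raise ValueError("well profiles contain non-finite values")
    pca = PCA(n_components=None, svd_solver="full")
    pca.fit(X)
    ratios = pca.explained_variance_ratio_
    cumulative = np.cumsum(ratios)
    k = int(np.searchsorted(cumulative, variance_threshold - 1e-12) + 1)
    k = min(k, len(ratios))
    return PcaModel(
        mean=pca.mean_,
        components=pca.components_,
        explained_variance_ratio=ratios,
        k=k,
        feature_names=tuple(feats),
        variance_threshold=variance_threshold,
    )


def project(well_profiles: pd.DataFrame, model: PcaModel) -> pd.DataFrame:
    """Project centered well profiles onto the retained components."""
    feats = [c for c in well_profiles.columns if c not in ("Plate", "Well")]
    if tuple(feats) != model.feature_names:
        raise ValueError("feature set does not match the fitted PCA model")
    X = well_profiles[feats].to_numpy(float)
    scores = (X - model.mean) @ model.components[: model.k].T
    out = pd.DataFrame(scores, columns=model.component_names)
    out.insert(0, "Well", well_profiles["Well"].to_numpy())
    out.insert(0, "Plate", well_profiles["Plate"].to_numpy())
    return out


def aggregate_sequences(
    projected_profiles: pd.DataFrame, metadata: pd.DataFrame
) -> pd.DataFrame:
    """Per-sequence profiles: median of each reagent's replicate wells.

    Operates in PCA space; untreated wells are excluded. Reagents whose
    every replicate well was dropped upstream simply do not appear (a
    warning is logged). Returns one row per TreatmentID with PC columns.
    """
    meta = metadata[["Plate", "Well", "TreatmentID", "IsUntreated"]]
    merged = projected_profiles.merge(meta, on=["Plate", "Well"], how="left")
    treated = merged[~merged["IsUntreated"].astype(bool) & (merged["TreatmentID"] != UNTREATED)]
    pcs = [c for c in projected_profiles.columns if c.startswith("PC_")]
    seq = treated.groupby("TreatmentID", sort=True)[pcs].median().reset_index()
    all_ids = set(
        metadata.loc[~metadata["IsUntreated"].astype(bool), "TreatmentID"].unique()
    )
    for tid in sorted(all_ids - set(seq["TreatmentID"])):
        logger.warning("sequence %s has no surviving replicate wells; dropped", tid)
    return seq
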