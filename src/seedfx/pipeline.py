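"""End-to-end chains over the simulate -> profile -> analyze stages.

These are the programmatic equivalents of the CLI subcommands: each
takes a :class:`~seedfx.io.RunConfig` (or its pieces) and returns
in-memory artifacts, so tests and the acceptance machinery exercise
exactly the code users run.
"""

from __future__ import annotations

import logging

import pandas as pd

from . import analysis, io, profiles, simulate

logger = logging.getLogger("seedfx")


def run_simulation(config: io.RunConfig) -> tuple[pd.DataFrame, pd.DataFrame, simulate.GroundTruth]:
    """Library + layouts + cells for a config: (cells, metadata, truth)."""
    library = simulate.design_library(
        n_genes=config.design.n_genes,
        shrnas_per_gene=config.design.shrnas_per_gene,
        n_seed_pairs=config.design.n_seed_pairs,
        n_controls=config.design.n_controls,
        seed_config=config.seed_window,
        rng_seed=config.design.design_seed,
    )
    layouts = simulate.make_layouts(
        library,
        n_layout_replicates=config.layout.n_layout_replicates,
        plate_size=config.layout.plate_size,
        n_untreated_per_plate=config.layout.n_untreated_per_plate,
        rng_seed=config.layout.layout_seed,
    )
    cells, truth = simulate.simulate_cells(layouts, library, config.effects)
    metadata = simulate.library_metadata(library, layouts)
    return cells, metadata, truth


def run_profiling(
    cells: pd.DataFrame,
    metadata: pd.DataFrame,
    variance_threshold: float = 0.99,
    excluded_wells: pd.DataFrame | None = None,
    feature_subset: list[str] | None = None,
    sequence_space: str = "pca",
) -> dict:
    """Normalize, mask, aggregate and project one experiment.

    ``feature_subset`` restricts the pipeline to a named feature list
    *before* the mask and PCA — the hook for analyses limited to, say,
    nuclear shape features. ``sequence_space`` controls where replicate
    wells are median-aggregated into sequence profiles: ``"pca"``
    (default) takes medians of projected profiles, ``"feature"`` takes
    medians in normalized-feature space and projects the result — a
    sensitivity switch, since either order is defensible. Returns well
    profiles (feature and PCA space), sequence profiles, the PCA model,
    stats and mask.
    """
    if sequence_space not in ("pca", "feature"):
        raise ValueError(f"unknown sequence_space: {sequence_space!r}")
    if feature_subset is not None:
        keep = ["Plate", "Well", "Cell"] + [
            c for c in cells.columns if c in set(feature_subset)
        ]
        missing = set(feature_subset) - set(cells.columns)
        if missing:
            raise ValueError(f"feature subset names unknown features: {sorted(missing)[:5]}")
        cells = cells[keep]
    stats = profiles.compute_norm_stats(cells, metadata)
    normed = profiles.normalize(cells, stats)
    mask = profiles.build_feature_mask(stats)
    well_feature = profiles.aggregate_wells(normed, mask, metadata, excluded_wells)
    model = profiles.fit_pca(well_feature, variance_threshold)
    well_pca = profiles.project(well_feature, model)
    if sequence_space == "pca":
        seq_pca = profiles.aggregate_sequences(well_pca, metadata)
    else:
        # median in feature space, then project through the same model
        meta_cols = metadata[["Plate", "Well", "TreatmentID", "IsUntreated"]]
        merged = well_feature.merge(meta_cols, on=["Plate", "Well"], how="left")
        treated = merged[~merged["IsUntreated"].astype(bool)]
        feats = [c for c in well_feature.columns if c not in ("Plate", "Well")]
        seq_feature = treated.groupby("TreatmentID", sort=True)[feats].median()
        scores = (seq_feature.to_numpy(float) - model.mean) @ model.components[: model.k].T
        seq_pca = pd.DataFrame(scores, columns=model.component_names)
        seq_pca.insert(0, "TreatmentID", seq_feature.index.to_numpy())
    return {
        "stats": stats,
        "mask": mask,
        "well_profiles_features": well_feature,
        "pca_model": model,
        "well_profiles": well_pca,
        "sequence_profiles": seq_pca,
    }


def run_chain(config: io.RunConfig, excluded_wells: pd.DataFrame | None = None) -> dict:
    """simulate -> profile -> analyze under one config; full bundle."""
    cells, metadata, truth = run_simulation(config)
    prof = run_profiling(
        cells, metadata,
        variance_threshold=config.analysis.variance_threshold,
        excluded_wells=excluded_wells,
        sequence_space=config.analysis.sequence_space,
    )
    results = analysis.run_full_analysis(
        prof["sequence_profiles"],
        prof["well_profiles"],
        metadata,
        seed_config=config.seed_window,
        percentile=config.analysis.percentile,
        cross_layout_only=config.analysis.cross_layout_only,
        controls_only=config.analysis.controls_only,
        percentile_method=config.analysis.percentile_method,
    )
    return {
        "cells": cells,
        "metadata": metadata,
        "truth": truth,
        **prof,
        "results": results,
    }
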