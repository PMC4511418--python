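"""Correlation analysis of profiles against an empirical null.

Profile pairs are grouped by what the two reagents share:

- ``REPLICATE``: the identical reagent measured in two different wells
  (optionally restricted to wells from different plate layouts);
- ``SAME_GENE``: two distinct reagents designed against the same gene
  but carrying different seeds — the on-target concordance group;
- ``SAME_SEED``: two distinct reagents carrying the identical seed
  hexamer while targeting different genes — the off-target group;
- ``NULL_PAIR``: reagent pairs sharing neither gene nor seed, the
  empirical null that calibrates significance.

For each pair the Spearman rank correlation of the two profiles is
computed; "significant" means strictly above the 95th percentile of the
null correlations. Comparing the fraction significant (and the group
means, by a two-sided t-test) across groups quantifies whether on-target
or seed-mediated off-target signal dominates the profiles.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd
from scipy import stats as sps

from .simulate import SeedConfig, SEQUENCE_LENGTH, NUCLEOTIDES

__all__ = [
    "PairRelation",
    "CorrelationGroup",
    "NullModel",
    "GroupComparison",
    "extract_seed",
    "enumerate_pairs",
    "spearman",
    "pairwise_spearman",
    "build_null",
    "fraction_significant",
    "compare_groups",
    "run_full_analysis",
]

logger = logging.getLogger("seedfx")

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


class PairRelation(str, Enum):
    REPLICATE = "replicate"
    REPLICATE_CROSS_LAYOUT = "replicate_cross_layout"
    SAME_GENE = "same_gene"
    SAME_SEED = "same_seed"
    # "null_pair" rather than "null": the bare word is a default
    # missing-value marker for most CSV readers
    NULL_PAIR = "null_pair"


@dataclass(frozen=True)
class CorrelationGroup:
    """Correlations for all profile pairs of one relation at one level."""

    relation: PairRelation
    level: str  # "well" | "sequence"
    pairs: pd.DataFrame  # columns: id_a, id_b, rho

    @property
    def rhos(self) -> np.ndarray:
        return self.pairs["rho"].to_numpy(float)

    @property
    def n(self) -> int:
        return len(self.pairs)


@dataclass(frozen=True)
class NullModel:
    """Empirical null with its percentile threshold."""

    null_group: CorrelationGroup
    percentile: float
    threshold: float

    @property
    def n(self) -> int:
        return self.null_group.n


@dataclass(frozen=True)
class GroupComparison:
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    pct_significant_a: float | None
    pct_significant_b: float | None
    t_welch: float
    p_welch: float
    t_student: float
    p_student: float


def reverse_complement(sequence: str) -> str:
    return sequence.translate(_COMPLEMENT)[::-1]


def extract_seed(sense_sequence: str, config: SeedConfig = SeedConfig()) -> str:
    """Seed subsequence of a 21-nt reagent under the given convention.

    With ``anchor="sense"`` the window is read directly off the stored
    target (sense) sequence; with ``anchor="guide"`` it is read off the
    reverse complement, matching conventions that number seed positions
    on the guide strand.
    """
    if len(sense_sequence) != SEQUENCE_LENGTH:
        raise ValueError(
            f"sequence must be {SEQUENCE_LENGTH} nt, got {len(sense_sequence)}"
        )
    if set(sense_sequence) - set(NUCLEOTIDES):
        raise ValueError("sequence contains characters outside ACGT")
    strand = sense_sequence if config.anchor == "sense" else reverse_complement(sense_sequence)
    return strand[config.start - 1 : config.start - 1 + config.length]


def _sequence_table(metadata: pd.DataFrame, controls_only: bool) -> pd.DataFrame:
    """One row per reagent: TreatmentID, Gene, Seed (untreated dropped)."""
    meta = metadata[~metadata["IsUntreated"].astype(bool)].copy()
    is_ctrl = meta.get("IsControl")
    if is_ctrl is None:
        is_ctrl = pd.Series(False, index=meta.index)
    meta = meta[is_ctrl.astype(bool)] if controls_only else meta[~is_ctrl.astype(bool)]
    cols = ["TreatmentID", "Gene", "Seed"]
    table = meta[cols].drop_duplicates().sort_values("TreatmentID")
    dup = table["TreatmentID"].duplicated()
    if dup.any():
        raise ValueError(
            f"inconsistent metadata for reagent(s): "
            f"{sorted(table.loc[dup, 'TreatmentID'])}"
        )
    return table.reset_index(drop=True)


def enumerate_pairs(
    metadata: pd.DataFrame,
    relation: PairRelation,
    level: str,
    controls_only: bool = False,
) -> list[tuple[str, str]]:
    """All unordered id pairs satisfying a relation at a level.

    Sequence-level ids are TreatmentIDs; well-level ids are
    ``"plate:well"`` strings. Group definitions are mutually exclusive:
    SAME_GENE excludes shared-seed pairs, SAME_SEED excludes same-gene
    pairs, and NULL_PAIR excludes both. No-target controls are excluded
    unless ``controls_only`` is set, in which case each control construct
    label plays the role of a gene. Pairs are returned with id_a < id_b.
    """
    if not isinstance(relation, PairRelation):
        raise ValueError(f"unknown relation: {relation!r}")
    if level not in ("well", "sequence"):
        raise ValueError(f"unknown level: {level!r}")
    seq = _sequence_table(metadata, controls_only)
    if level == "sequence":
        if relation in (PairRelation.REPLICATE, PairRelation.REPLICATE_CROSS_LAYOUT):
            raise ValueError("replicate relations are defined at the well level")
        pairs = []
        rows = list(seq.itertuples(index=False))
        for a, b in itertools.combinations(rows, 2):
            same_gene = a.Gene == b.Gene
            same_seed = a.Seed == b.Seed
            if relation is PairRelation.SAME_GENE:
                keep = same_gene and not same_seed
            elif relation is PairRelation.SAME_SEED:
                keep = same_seed and not same_gene
            else:  # NULL_PAIR
                keep = not same_gene and not same_seed
            if keep:
                pairs.append(tuple(sorted((a.TreatmentID, b.TreatmentID))))
        return sorted(set(pairs))

    # well level
    meta = metadata[~metadata["IsUntreated"].astype(bool)].copy()
    if "IsControl" in meta.columns:
        flag = meta["IsControl"].astype(bool)
        meta = meta[flag] if controls_only else meta[~flag]
    meta = meta.sort_values(["Plate", "Well"])
    wells = [
        (f"{r.Plate}:{r.Well}", r.TreatmentID, r.Gene, r.Seed, r.Layout)
        for r in meta.itertuples(index=False)
    ]
    pairs = []
    for (ida, ta, ga, sa, la), (idb, tb, gb, sb, lb) in itertools.combinations(wells, 2):
        if relation is PairRelation.REPLICATE:
            keep = ta == tb
        elif relation is PairRelation.REPLICATE_CROSS_LAYOUT:
            keep = ta == tb and la != lb
        elif relation is PairRelation.SAME_GENE:
            keep = ta != tb and ga == gb and sa != sb
        elif relation is PairRelation.SAME_SEED:
            keep = ta != tb and sa == sb and ga != gb
        else:  # NULL_PAIR
            keep = ta != tb and ga != gb and sa != sb
        if keep:
            pairs.append(tuple(sorted((ida, idb))))
    return sorted(set(pairs))


def spearman(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman rank correlation: Pearson on average ranks.

    Ties receive the average of the ranks they span. Returns NaN if
    either vector has zero rank variance (a constant profile), in which
    case the correlation is undefined.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("spearman needs two equal-length vectors of length >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("spearman inputs must be finite")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    sx, sy = rx.std(), ry.std()
    if sx == 0 or sy == 0:
        return float("nan")
    return float(np.mean((rx - rx.mean()) * (ry - ry.mean())) / (sx * sy))


def pairwise_spearman(
    profiles: pd.DataFrame,
    id_column: str,
    pairs: list[tuple[str, str]],
    relation: PairRelation,
    level: str,
) -> CorrelationGroup:
    """Spearman correlations for many pairs drawn from one profile matrix.

    Rank-transforms every profile once and reads correlations off a
    single rank-correlation matrix, which is algebraically identical to
    calling :func:`spearman` per pair. Pairs involving a zero-rank-
    variance profile are dropped with a warning.
    """
    value_cols = [c for c in profiles.columns if c != id_column]
    ids = profiles[id_column].tolist()
    index = {pid: i for i, pid in enumerate(ids)}
    X = profiles[value_cols].to_numpy(float)
    ranks = sps.rankdata(X, axis=1)
    sd = ranks.std(axis=1)
    degenerate = sd == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(ranks)
    records, dropped = [], 0
    for a, b in pairs:
        ia, ib = index[a], index[b]
        if degenerate[ia] or degenerate[ib]:
            dropped += 1
            continue
        records.append((a, b, float(corr[ia, ib])))
    if dropped:
        logger.warning(
            "%d %s pair(s) dropped: constant profile (zero rank variance)",
            dropped, relation.value,
        )
    return CorrelationGroup(
        relation=relation,
        level=level,
        pairs=pd.DataFrame(records, columns=["id_a", "id_b", "rho"]),
    )


def build_null(
    null_corrs: CorrelationGroup, percentile: float = 95.0, method: str = "linear"
) -> NullModel:
    """Empirical percentile threshold from the null correlations.

    ``method`` is the percentile estimator: ``"linear"`` interpolates
    between the closest order statistics (default); ``"nearest-rank"``
    uses ``numpy``'s inverted-CDF convention.
    """
    rhos = null_corrs.rhos
    if len(rhos) < 20:
        raise ValueError(f"need >= 20 null correlations, got {len(rhos)}")
    np_method = {"linear": "linear", "nearest-rank": "inverted_cdf"}.get(method)
    if np_method is None:
        raise ValueError(f"unknown percentile method: {method!r}")
    threshold = float(np.percentile(rhos, percentile, method=np_method))
    return NullModel(null_group=null_corrs, percentile=percentile, threshold=threshold)


def fraction_significant(group: CorrelationGroup, null_model: NullModel) -> float:
    """Percentage of the group's correlations strictly above the threshold."""
    if group.n == 0:
        raise ValueError("cannot compute fraction significant of an empty group")
    return float(100.0 * np.mean(group.rhos > null_model.threshold))


def compare_groups(
    group_a: CorrelationGroup,
    group_b: CorrelationGroup,
    null_model: NullModel | None = None,
) -> GroupComparison:
    """Two-sided two-sample t-test between two groups' correlation means.

    Reports both the Welch (unequal-variance, the default interpretation)
    and the classic equal-variance Student statistic. If both groups are
    degenerate (zero variance), the p-values are NaN.
    """
    a, b = group_a.rhos, group_b.rhos
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both groups need >= 2 correlations")
    tw, pw = sps.ttest_ind(a, b, equal_var=False)
    ts, ps = sps.ttest_ind(a, b, equal_var=True)
    return GroupComparison(
        n_a=len(a), n_b=len(b),
        mean_a=float(a.mean()), mean_b=float(b.mean()),
        pct_significant_a=(fraction_significant(group_a, null_model)
                           if null_model else None),
        pct_significant_b=(fraction_significant(group_b, null_model)
                           if null_model else None),
        t_welch=float(tw), p_welch=float(pw),
        t_student=float(ts), p_student=float(ps),
    )


def _well_profiles_with_id(well_profiles: pd.DataFrame) -> pd.DataFrame:
    out = well_profiles.copy()
    out.insert(0, "id", out["Plate"].astype(str) + ":" + out["Well"].astype(str))
    return out.drop(columns=["Plate", "Well"])


def _analyze_groups(
    profiles: pd.DataFrame,
    id_column: str,
    metadata: pd.DataFrame,
    relations: list[PairRelation],
    level: str,
    percentile: float,
    controls_only: bool,
    percentile_method: str,
) -> dict:
    available = set(profiles[id_column])
    groups: dict[PairRelation, CorrelationGroup] = {}
    for rel in relations + [PairRelation.NULL_PAIR]:
        pairs = enumerate_pairs(metadata, rel, level, controls_only=controls_only)
        pairs = [(a, b) for a, b in pairs if a in available and b in available]
        groups[rel] = pairwise_spearman(profiles, id_column, pairs, rel, level)
    null_model = build_null(groups[PairRelation.NULL_PAIR], percentile,
                            method=percentile_method)
    summary_rows = []
    comparisons = {}
    for rel, grp in groups.items():
        pct = fraction_significant(grp, null_model) if grp.n else float("nan")
        summary_rows.append({
            "relation": rel.value, "level": level, "n": grp.n,
            "mean_rho": float(np.mean(grp.rhos)) if grp.n else float("nan"),
            "pct_significant": pct, "threshold": null_model.threshold,
        })
        if rel is not PairRelation.NULL_PAIR and grp.n >= 2:
            comparisons[rel.value + "_vs_null"] = compare_groups(
                grp, groups[PairRelation.NULL_PAIR], null_model
            )
    for ra, rb in itertools.combinations(relations, 2):
        if groups[ra].n >= 2 and groups[rb].n >= 2:
            comparisons[f"{ra.value}_vs_{rb.value}"] = compare_groups(
                groups[ra], groups[rb], null_model
            )
    return {
        "level": level,
        "groups": groups,
        "null_model": null_model,
        "summary": pd.DataFrame(summary_rows),
        "comparisons": comparisons,
    }


def run_full_analysis(
    sequence_profiles: pd.DataFrame,
    well_profiles: pd.DataFrame,
    metadata: pd.DataFrame,
    seed_config: SeedConfig = SeedConfig(),
    percentile: float = 95.0,
    cross_layout_only: bool = False,
    controls_only: bool = False,
    percentile_method: str = "linear",
) -> dict:
    """Well-level replicate analysis plus sequence-level group analysis.

    Returns a bundle with two sub-analyses, each holding the correlation
    groups, the null model, a summary table (n, mean rho, % significant,
    threshold) and pairwise t-tests:

    - ``"well"``: REPLICATE (or cross-layout replicate) pairs against the
      well-level null — profile reproducibility;
    - ``"sequence"``: SAME_GENE and SAME_SEED pairs against the
      sequence-level null — on-target vs seed-driven concordance.

    Seeds in the metadata are recomputed under ``seed_config`` when a
    Sequence column is present, so alternative seed conventions can be
    analyzed without regenerating profiles.
    """
    meta = metadata.copy()
    if "Sequence" in meta.columns:
        treated = ~meta["IsUntreated"].astype(bool)
        meta.loc[treated, "Seed"] = [
            extract_seed(s, seed_config) for s in meta.loc[treated, "Sequence"]
        ]
    replicate_rel = (PairRelation.REPLICATE_CROSS_LAYOUT if cross_layout_only
                     else PairRelation.REPLICATE)
    well = _analyze_groups(
        _well_profiles_with_id(well_profiles), "id", meta,
        [replicate_rel], "well", percentile, controls_only, percentile_method,
    )
    sequence = _analyze_groups(
        sequence_profiles, "TreatmentID", meta,
        [PairRelation.SAME_GENE, PairRelation.SAME_SEED], "sequence",
        percentile, controls_only, percentile_method,
    )
    summary = pd.concat([well["summary"], sequence["summary"]], ignore_index=True)
    return {"well": well, "sequence": sequence, "summary": summary}
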