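"""Synthetic shRNA morphological-profiling experiments with known ground truth.

The generator emulates an arrayed lentiviral shRNA screen read out by
image-based profiling: a library of 21-nt reagents targeting a panel of
genes (plus no-target controls), laid out on replicated 384-well plates in
two layouts, with per-cell feature vectors produced by a hierarchical
additive effect model.

Each reagent's phenotypic effect lives in a low-dimensional latent space
and decomposes as

    t = g + s + e

where ``g`` is the on-target gene effect (shared by all reagents against
the same gene), ``s`` is the seed-mediated off-target effect (shared by
all reagents carrying the same seed hexamer, regardless of target), and
``e`` is a sequence-specific residual. Latent effects are mapped into
feature space through a fixed loading matrix ``L`` with unit-norm columns,
so features are correlated and PCA on profiles is non-trivial. Per-cell
measurements add plate, well and cell-level Gaussian noise:

    x_cell = mu_plate + L t + w_well + eps_cell

Noise is correlated across features: plate, well and cell noise are drawn
in a ``noise_rank``-dimensional subspace and mapped to features through a
second fixed matrix with unit-norm rows, so each feature's marginal noise
standard deviation is exactly its configured sigma while the noise
covariance has low rank. This mirrors real image-derived features, whose
thousands of measurements are highly redundant (a 99%-variance PCA of
such data retains a few hundred directions, not thousands); white
per-feature noise would instead bury the profile space in an isotropic
variance floor that no real experiment shows.

Setting the seed-effect scale well above the gene-effect scale places the
simulation in the regime where reagents sharing a seed look more alike
than reagents sharing a target gene, which is the phenomenon the analysis
module is built to detect and quantify.
"""

from __future__ import annotations

import string
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SeedConfig",
    "ShRNA",
    "LibraryDesign",
    "PlateLayoutSet",
    "EffectParams",
    "GroundTruth",
    "DesignError",
    "design_library",
    "make_layouts",
    "simulate_cells",
    "UNTREATED",
    "CONTROL_LABELS",
]

NUCLEOTIDES = "ACGT"
#: sentinel treatment id for wells that received no reagent
UNTREATED = "UNTREATED"
#: construct names cycled over when generating no-target controls
CONTROL_LABELS = ("GFP", "LacZ", "Luciferase", "RFP")

SEQUENCE_LENGTH = 21


class DesignError(ValueError):
    """Raised when a library or layout request is infeasible."""


@dataclass(frozen=True)
class SeedConfig:
    """Where the seed hexamer sits on a 21-nt reagent sequence.

    ``anchor`` selects the strand the window is read from: ``"sense"``
    indexes the stored target (sense) sequence directly; ``"guide"``
    indexes the reverse complement. ``start`` is 1-based and inclusive.
    The default (sense strand, positions 12-17, length 6) matches the
    convention used when reporting shared seeds such as GAATGA at
    nucleotides 12-17.
    """

    anchor: str = "sense"
    start: int = 12
    length: int = 6

    def __post_init__(self) -> None:
        if self.anchor not in ("sense", "guide"):
            raise ValueError(f"anchor must be 'sense' or 'guide', got {self.anchor!r}")
        if self.length < 1:
            raise ValueError("seed length must be >= 1")
        if self.start < 1 or self.start + self.length - 1 > SEQUENCE_LENGTH:
            raise ValueError(
                f"seed window [{self.start}, {self.start + self.length - 1}] "
                f"outside 1..{SEQUENCE_LENGTH}"
            )


@dataclass(frozen=True)
class ShRNA:
    """A single reagent: 21-nt sense sequence plus its derived seed.

    ``target_gene`` is None for no-target controls; those carry the
    construct name (GFP, LacZ, ...) in ``control_label`` instead.
    """

    id: str
    target_gene: str | None
    sense_sequence: str
    seed: str
    control_label: str | None = None

    def __post_init__(self) -> None:
        if len(self.sense_sequence) != SEQUENCE_LENGTH:
            raise ValueError(
                f"{self.id}: sense sequence must be {SEQUENCE_LENGTH} nt, "
                f"got {len(self.sense_sequence)}"
            )
        if set(self.sense_sequence) - set(NUCLEOTIDES):
            raise ValueError(f"{self.id}: sequence contains non-ACGT characters")

    @property
    def is_control(self) -> bool:
        return self.target_gene is None


@dataclass(frozen=True)
class LibraryDesign:
    shrnas: tuple[ShRNA, ...]
    genes: tuple[str, ...]
    seed_pairs: tuple[tuple[str, str], ...]
    n_controls: int
    seed_config: SeedConfig

    def by_id(self) -> dict[str, ShRNA]:
        return {sh.id: sh for sh in self.shrnas}


@dataclass(frozen=True)
class PlateLayoutSet:
    """Well assignments: one row per (plate, well)."""

    #: columns: Plate, Layout, Well, TreatmentID, ReplicateIndex
    assignments: pd.DataFrame

    @property
    def plates(self) -> list[str]:
        return sorted(self.assignments["Plate"].unique())


@dataclass(frozen=True)
class EffectParams:
    """Scales and sizes of the hierarchical effect model.

    Latent scales (``sigma_gene``, ``sigma_seed``, ``sigma_seq``) are per
    latent dimension; noise scales (``sigma_well``, ``sigma_plate``,
    ``sigma_cell``) are per-feature marginal standard deviations. All are
    in normalized-feature units. ``noise_rank`` is the dimension of the
    correlated-noise subspace shared by plate, well and cell noise.
    """

    n_features: int = 300
    latent_dim: int = 25
    sigma_gene: float = 0.25
    sigma_seed: float = 1.0
    sigma_seq: float = 0.45
    sigma_well: float = 0.15
    sigma_plate: float = 0.2
    sigma_cell: float = 1.0
    cells_per_well: int = 60
    noise_rank: int = 5
    loading_seed: int = 20150721
    sampling_seed: int = 0

    def __post_init__(self) -> None:
        if not (self.n_features >= self.latent_dim >= 1):
            raise ValueError("need n_features >= latent_dim >= 1")
        if self.noise_rank < 1:
            raise ValueError("noise_rank must be >= 1")
        for name in ("sigma_gene", "sigma_seed", "sigma_seq",
                     "sigma_well", "sigma_plate", "sigma_cell"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.cells_per_well < 1:
            raise ValueError("cells_per_well must be >= 1")


@dataclass(frozen=True)
class GroundTruth:
    """Latent effects behind a simulated experiment.

    ``treatment_effects[id]`` is exactly ``gene_effects[gene] +
    seed_effects[seed] + sequence_effects[id]`` (with a zero gene vector
    for controls); two reagents sharing a seed share the identical seed
    vector object value.
    """

    gene_effects: dict[str, np.ndarray]
    seed_effects: dict[str, np.ndarray]
    sequence_effects: dict[str, np.ndarray]
    treatment_effects: dict[str, np.ndarray]
    loadings: np.ndarray  # (n_features, latent_dim), unit-norm columns
    params: EffectParams


def _random_seq(rng: np.random.Generator, length: int = SEQUENCE_LENGTH) -> str:
    return "".join(rng.choice(list(NUCLEOTIDES), size=length))


def _splice_seed(sequence: str, seed: str, cfg: SeedConfig) -> str:
    i = cfg.start - 1
    return sequence[:i] + seed + sequence[i + cfg.length:]


def design_library(
    n_genes: int = 20,
    shrnas_per_gene: int = 5,
    n_seed_pairs: int = 12,
    n_controls: int = 4,
    seed_config: SeedConfig = SeedConfig(),
    rng_seed: int = 0,
) -> LibraryDesign:
    """Draw a random shRNA library with engineered cross-gene seed pairs.

    Every reagent gets a random 21-mer; exactly ``n_seed_pairs`` pairs of
    reagents targeting *different* genes are forced to carry an identical
    hexamer at the configured seed position, emulating the shared-seed
    pairs that drive off-target concordance. All remaining seeds
    (including controls') are distinct from each other and from the
    engineered ones, so seed sharing in the library is exactly the
    engineered set.
    """
    if n_genes < 1 or shrnas_per_gene < 1:
        raise DesignError("need at least one gene and one shRNA per gene")
    n_targeting = n_genes * shrnas_per_gene
    if n_seed_pairs > n_targeting // 2:
        raise DesignError(
            f"{n_seed_pairs} seed pairs need {2 * n_seed_pairs} reagents, "
            f"library has only {n_targeting}"
        )
    if n_seed_pairs > 0 and n_genes < 2:
        raise DesignError("cross-gene seed pairs require >= 2 genes")

    n_seed_slots = n_seed_pairs + (n_targeting - 2 * n_seed_pairs) + n_controls
    n_possible = len(NUCLEOTIDES) ** seed_config.length
    if n_seed_slots > n_possible:
        raise DesignError(
            f"cannot draw {n_seed_slots} distinct {seed_config.length}-mers "
            f"(only {n_possible} exist)"
        )

    rng = np.random.default_rng(rng_seed)
    genes = [f"GENE{i + 1:02d}" for i in range(n_genes)]

    # distinct seed hexamers for every "seed slot"
    seeds: list[str] = []
    used = set()
    while len(seeds) < n_seed_slots:
        s = _random_seq(rng, seed_config.length)
        if s not in used:
            used.add(s)
            seeds.append(s)
    pair_seeds = seeds[:n_seed_pairs]
    solo_seeds = iter(seeds[n_seed_pairs:])

    # choose which reagent slots form cross-gene pairs: walk a shuffled
    # slot list, pairing consecutive slots from different genes
    slots = [(g, j) for g in range(n_genes) for j in range(shrnas_per_gene)]
    order = list(rng.permutation(len(slots)))
    paired: list[tuple[tuple[int, int], tuple[int, int]]] = []
    pool = [slots[i] for i in order]
    while len(paired) < n_seed_pairs:
        a = pool.pop(0)
        partner = next((i for i, b in enumerate(pool) if b[0] != a[0]), None)
        if partner is None:  # all remaining slots share a's gene
            raise DesignError("could not form the requested cross-gene pairs")
        paired.append((a, pool.pop(partner)))

    slot_seed: dict[tuple[int, int], str] = {}
    pair_ids: list[tuple[str, str]] = []
    for k, (a, b) in enumerate(paired):
        slot_seed[a] = pair_seeds[k]
        slot_seed[b] = pair_seeds[k]

    def slot_id(g: int, j: int) -> str:
        return f"sh{g * shrnas_per_gene + j + 1:04d}"

    shrnas: list[ShRNA] = []
    for g in range(n_genes):
        for j in range(shrnas_per_gene):
            seed = slot_seed.get((g, j)) or next(solo_seeds)
            seq = _splice_seed(_random_seq(rng), seed, seed_config)
            shrnas.append(ShRNA(slot_id(g, j), genes[g], seq, seed))
    pair_ids = [(slot_id(*a), slot_id(*b)) for a, b in paired]
    pair_ids = [tuple(sorted(p)) for p in pair_ids]

    for c in range(n_controls):
        label = CONTROL_LABELS[c % len(CONTROL_LABELS)]
        copy = c // len(CONTROL_LABELS) + 1
        seed = next(solo_seeds)
        seq = _splice_seed(_random_seq(rng), seed, seed_config)
        shrnas.append(
            ShRNA(f"ctrl_{label}_{copy}", None, seq, seed, control_label=label)
        )

    return LibraryDesign(
        shrnas=tuple(shrnas),
        genes=tuple(genes),
        seed_pairs=tuple(sorted(pair_ids)),
        n_controls=n_controls,
        seed_config=seed_config,
    )


def _well_labels(plate_size: int) -> list[str]:
    """Alphanumeric well labels (A01..P24 for 384-well) in row-major order."""
    n_cols = {6: 3, 12: 4, 24: 6, 48: 8, 96: 12, 384: 24, 1536: 48}.get(plate_size)
    if n_cols is None:
        n_cols = int(np.ceil(np.sqrt(plate_size * 1.5)))
    n_rows = int(np.ceil(plate_size / n_cols))
    rows = string.ascii_uppercase
    if n_rows > len(rows):
        raise DesignError(f"plate_size {plate_size} needs more than 26 rows")
    labels = [f"{rows[r]}{c + 1:02d}" for r in range(n_rows) for c in range(n_cols)]
    return labels[:plate_size]


def make_layouts(
    library: LibraryDesign,
    n_layout_replicates: int = 2,
    plate_size: int = 384,
    n_untreated_per_plate: int = 8,
    rng_seed: int = 0,
) -> PlateLayoutSet:
    """Assign the library to two randomized plate layouts, each replicated.

    Untreated wells occupy the same fixed positions on every plate; the
    treated positions are permuted independently per layout (the two
    layouts are guaranteed to differ for libraries of >= 2 reagents).
    Plates are named ``L<layout>R<replicate>``; each reagent's wells get
    replicate indices 1..2*n_layout_replicates.
    """
    n_shrnas = len(library.shrnas)
    if n_shrnas + n_untreated_per_plate > plate_size:
        raise DesignError(
            f"{n_shrnas} reagents + {n_untreated_per_plate} untreated wells "
            f"do not fit a {plate_size}-well plate"
        )
    rng = np.random.default_rng(rng_seed)
    wells = _well_labels(plate_size)
    # untreated at fixed positions spread across the plate, identical in
    # both layouts; position effects are modeled by sigma_well anyway
    step = max(1, plate_size // max(1, n_untreated_per_plate))
    untreated_wells = [wells[(i * step) % plate_size] for i in range(n_untreated_per_plate)]
    treated_wells = [w for w in wells if w not in untreated_wells]

    ids = [sh.id for sh in library.shrnas]
    layouts = [list(rng.permutation(ids)), list(rng.permutation(ids))]
    if n_shrnas >= 2:
        # make layout 2 a derangement of layout 1 so every reagent truly
        # occupies two distinct well positions: rotate the coinciding slots
        l1, l2 = layouts
        fixed = [i for i in range(n_shrnas) if l1[i] == l2[i]]
        if len(fixed) == 1:
            i = fixed[0]
            j = (i + 1) % n_shrnas
            l2[i], l2[j] = l2[j], l2[i]
        elif fixed:
            rotated = [l2[fixed[-1]]] + [l2[i] for i in fixed[:-1]]
            for i, v in zip(fixed, rotated):
                l2[i] = v

    rows = []
    for layout_idx, perm in enumerate(layouts, start=1):
        for rep in range(1, n_layout_replicates + 1):
            plate = f"L{layout_idx}R{rep}"
            replicate_index = (layout_idx - 1) * n_layout_replicates + rep
            for well, tid in zip(treated_wells, perm):
                rows.append((plate, layout_idx, well, tid, replicate_index))
            for well in untreated_wells:
                rows.append((plate, layout_idx, well, UNTREATED, 0))
    df = pd.DataFrame(
        rows, columns=["Plate", "Layout", "Well", "TreatmentID", "ReplicateIndex"]
    )
    df = df.sort_values(["Plate", "Well"], kind="mergesort").reset_index(drop=True)
    return PlateLayoutSet(assignments=df)


def _draw_latent(rng: np.random.Generator, scale: float, dim: int) -> np.ndarray:
    return rng.normal(0.0, scale, size=dim) if scale > 0 else np.zeros(dim)


def simulate_cells(
    layouts: PlateLayoutSet,
    library: LibraryDesign,
    params: EffectParams = EffectParams(),
) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate the per-cell feature table for a laid-out experiment.

    Returns the cell table (columns Plate, Well, Cell, f_0001..f_F) and
    the ground truth holding every latent vector, so downstream estimates
    can be checked against the parameters that generated them. The
    loading matrix and the noise-subspace basis are drawn once from
    ``loading_seed``; everything else (latent effects, plate/well/cell
    noise) from ``sampling_seed``. Untreated wells have a zero treatment
    effect; no-target controls have a zero gene component but real seed
    and sequence components.
    """
    F, d = params.n_features, params.latent_dim
    load_rng = np.random.default_rng(params.loading_seed)
    L = load_rng.normal(size=(F, d))
    L /= np.linalg.norm(L, axis=0, keepdims=True)
    # correlated-noise basis: unit rows keep each feature's marginal
    # noise sd exactly equal to the configured sigma
    N = load_rng.normal(size=(F, params.noise_rank))
    N /= np.linalg.norm(N, axis=1, keepdims=True)

    rng = np.random.default_rng(params.sampling_seed)
    by_id = library.by_id()

    genes = sorted({sh.target_gene for sh in library.shrnas if sh.target_gene})
    seeds = sorted({sh.seed for sh in library.shrnas})
    gene_eff = {g: _draw_latent(rng, params.sigma_gene, d) for g in genes}
    seed_eff = {s: _draw_latent(rng, params.sigma_seed, d) for s in seeds}
    seq_eff = {sh.id: _draw_latent(rng, params.sigma_seq, d)
               for sh in library.shrnas}
    zero = np.zeros(d)
    treat_eff = {
        sh.id: (gene_eff[sh.target_gene] if sh.target_gene else zero)
        + seed_eff[sh.seed] + seq_eff[sh.id]
        for sh in library.shrnas
    }

    assignments = layouts.assignments
    feature_cols = [f"f_{i + 1:04d}" for i in range(F)]
    r = params.noise_rank

    def _noise(scale: float, n: int | None = None) -> np.ndarray:
        shape = (r,) if n is None else (n, r)
        if scale == 0:
            return np.zeros(F) if n is None else np.zeros((n, F))
        return rng.normal(0.0, scale, size=shape) @ N.T

    blocks: list[np.ndarray] = []
    keys: list[tuple[str, str, int]] = []
    for plate in layouts.plates:
        plate_rows = assignments[assignments["Plate"] == plate]
        mu_p = _noise(params.sigma_plate)
        for _, row in plate_rows.iterrows():
            tid = row["TreatmentID"]
            t = treat_eff[tid] if tid != UNTREATED else zero
            w = _noise(params.sigma_well)
            eps = _noise(params.sigma_cell, params.cells_per_well)
            blocks.append(mu_p + L @ t + w + eps)
            keys.extend(
                (plate, row["Well"], c) for c in range(1, params.cells_per_well + 1)
            )
    X = np.vstack(blocks)
    cells = pd.DataFrame(X, columns=feature_cols)
    cells.insert(0, "Cell", [k[2] for k in keys])
    cells.insert(0, "Well", [k[1] for k in keys])
    cells.insert(0, "Plate", [k[0] for k in keys])

    truth = GroundTruth(
        gene_effects=gene_eff,
        seed_effects=seed_eff,
        sequence_effects=seq_eff,
        treatment_effects=treat_eff,
        loadings=L,
        params=params,
    )
    return cells, truth


def library_metadata(
    library: LibraryDesign, layouts: PlateLayoutSet
) -> pd.DataFrame:
    """Per-well treatment metadata table for a laid-out library.

    Columns: Plate, Well, Layout, TreatmentID, Gene, Sequence, Seed,
    ReplicateIndex, IsUntreated, IsControl. Control rows carry the
    construct label (GFP, LacZ, ...) in Gene and IsControl=True, so
    control-only analyses can treat each construct as a pseudo-gene while
    default analyses exclude them.
    """
    by_id = library.by_id()
    records = []
    for _, row in layouts.assignments.iterrows():
        tid = row["TreatmentID"]
        if tid == UNTREATED:
            gene, seq, seed, ctrl = "", "", "", False
        else:
            sh = by_id[tid]
            gene = sh.target_gene if sh.target_gene else (sh.control_label or "")
            seq, seed, ctrl = sh.sense_sequence, sh.seed, sh.is_control
        records.append(
            (row["Plate"], row["Well"], row["Layout"], tid, gene, seq, seed,
             row["ReplicateIndex"], tid == UNTREATED, ctrl)
        )
    return pd.DataFrame(
        records,
        columns=["Plate", "Well", "Layout", "TreatmentID", "Gene", "Sequence",
                 "Seed", "ReplicateIndex", "IsUntreated", "IsControl"],
    )
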