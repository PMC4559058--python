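"""Synthetic two-habitat ant landscapes with known ground truth.

The generator emulates the study design this package analyses: two habitat
classes (oil palm, forest) with unequal species pools that partially
overlap, skewed rank-abundance distributions with a long rare tail,
plots laid out in close pairs whose pair-clusters sit several kilometres
apart (so a three-level grain hierarchy is recoverable from coordinates
alone), and per-species body sizes and dry weights following subfamily
power-law allometry.

Defaults mirror the study conditions: 26 oil-palm and 21 forest plots;
105 / 181 species pools sharing 63 species; ~550 individuals per plot
(the printed totals divided by plot counts); within-pair plot spacing of
1.2–2.5 km and pair-cluster spacing of 8 km (inside the reported 1–4 km
and 6–45 km brackets). Every random draw flows through one seeded
generator, so a seed fully determines the landscape.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .community import (
    AbundanceMatrix,
    FOREST,
    OIL_PALM,
    ValidationError,
    validate_species_traits,
    write_abundance_table,
    write_sample_metadata,
    write_species_traits,
)

KM_PER_DEG_LAT = 111.195  # 2*pi*6371/360

#: subfamily -> (sampling weight, dimension type, typical dimension mm,
#:              allometric coefficient a, allometric exponent b) for W = a L^b
SUBFAMILY_TABLE: dict[str, tuple[float, str, float, float, float]] = {
    "Myrmicinae": (0.40, "pronotum_width", 0.55, 0.90, 2.8),
    "Formicinae": (0.20, "head_length", 1.00, 0.55, 2.7),
    "Ponerinae": (0.15, "tibia_length", 1.40, 0.35, 2.6),
    "Dolichoderinae": (0.10, "head_length", 0.75, 0.50, 2.7),
    "Pseudomyrmecinae": (0.05, "head_length", 0.90, 0.45, 2.6),
    "Dorylinae": (0.05, "head_length", 0.80, 0.50, 2.6),
    "Ectatomminae": (0.05, "tibia_length", 1.20, 0.40, 2.6),
}

ABUNDANCE_MODELS = ("log_series", "lognormal")


@dataclass(frozen=True)
class SyntheticTruth:
    """Generator parameters; the ground truth for parameter-recovery tests."""

    n_species_oil_palm: int = 105
    n_species_forest: int = 181
    n_shared: int = 63
    abundance_model: str = "log_series"
    log_series_x: float = 0.99
    lognormal_sigma: float = 1.2
    n_plots_oil_palm: int = 26
    n_plots_forest: int = 21
    individuals_per_plot: int = 550
    pair_distance_km: tuple[float, float] = (1.2, 2.5)
    cluster_spacing_km: float = 8.0
    #: when False both habitats share one abundance-rank assignment on the
    #: shared pool ordering (identical expected communities)
    independent_habitat_ranks: bool = True
    specimen_noise_sd: float = 0.15
    species_mass_scatter_sd: float = 0.20
    unweighed_fraction: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_shared > min(self.n_species_oil_palm, self.n_species_forest):
            raise ValidationError(
                f"n_shared={self.n_shared} exceeds the smaller pool "
                f"({min(self.n_species_oil_palm, self.n_species_forest)})"
            )
        if min(self.n_species_oil_palm, self.n_species_forest) < 1:
            raise ValidationError("species pools must be non-empty")
        if self.individuals_per_plot < 1:
            raise ValidationError("individuals_per_plot must be >= 1")
        if self.abundance_model not in ABUNDANCE_MODELS:
            raise ValidationError(
                f"abundance_model must be one of {ABUNDANCE_MODELS}"
            )
        if not 0 < self.log_series_x < 1:
            raise ValidationError("log_series_x must lie in (0, 1)")

    def analytic_sorensen(self) -> float:
        """Pool-level Sørensen overlap implied by the truth."""
        return 2.0 * self.n_shared / (self.n_species_oil_palm + self.n_species_forest)


def model_abundances(truth: SyntheticTruth, n_species: int) -> np.ndarray:
    """Expected relative abundance by rank (descending) under the model."""
    k = np.arange(1, n_species + 1, dtype=float)
    if truth.abundance_model == "log_series":
        p = truth.log_series_x**k / k
    else:
        # deterministic lognormal rank profile: equally spaced normal quantiles
        from scipy.stats import norm

        quantiles = (k - 0.5) / n_species
        p = np.exp(-truth.lognormal_sigma * norm.ppf(quantiles))
    return p / p.sum()


@dataclass(frozen=True)
class SpeciesPools:
    oil_palm_ids: tuple[str, ...]
    forest_ids: tuple[str, ...]
    shared_ids: tuple[str, ...]
    traits: pd.DataFrame
    expected_p: dict[str, pd.Series] = field(default_factory=dict)  # habitat -> p

    @property
    def union_ids(self) -> tuple[str, ...]:
        only_f = tuple(s for s in self.forest_ids if s not in set(self.shared_ids))
        return self.oil_palm_ids + only_f


def generate_species_pools(
    truth: SyntheticTruth, rng: np.random.Generator | None = None
) -> SpeciesPools:
    """Draw species identities, traits and expected abundances for both pools."""
    rng = np.random.default_rng(truth.seed) if rng is None else rng
    n_shared = truth.n_shared
    n_op_only = truth.n_species_oil_palm - n_shared
    n_fo_only = truth.n_species_forest - n_shared
    shared = tuple(f"sps{i:03d}" for i in range(1, n_shared + 1))
    op_only = tuple(f"spo{i:03d}" for i in range(1, n_op_only + 1))
    fo_only = tuple(f"spf{i:03d}" for i in range(1, n_fo_only + 1))
    op_ids = shared + op_only
    fo_ids = shared + fo_only
    union = op_ids + fo_only

    names = list(SUBFAMILY_TABLE)
    weights = np.array([SUBFAMILY_TABLE[n][0] for n in names])
    weights = weights / weights.sum()
    rows = []
    for sp in union:
        subfamily = names[rng.choice(len(names), p=weights)]
        _, dim_type, typ_mm, a, b = SUBFAMILY_TABLE[subfamily]
        dim = float(typ_mm * np.exp(rng.normal(0.0, 0.3)))
        mean_w = float(
            a * dim**b * np.exp(rng.normal(0.0, truth.species_mass_scatter_sd))
        )
        if rng.random() < truth.unweighed_fraction:
            n_spec = int(rng.integers(0, 3))  # too few: weight must be predicted
        else:
            n_spec = int(rng.integers(3, 6))
        specimens = [
            float(mean_w * np.exp(rng.normal(0.0, truth.specimen_noise_sd)))
            for _ in range(n_spec)
        ]
        rows.append(
            {
                "species_id": sp,
                "subfamily": subfamily,
                "caste": "none",
                "dimension_type": dim_type,
                "dimension_mm": dim,
                "dry_weights_mg": specimens,
            }
        )
    traits = validate_species_traits(pd.DataFrame(rows))

    expected_p: dict[str, pd.Series] = {}
    for habitat, ids in ((OIL_PALM, op_ids), (FOREST, fo_ids)):
        p_by_rank = model_abundances(truth, len(ids))
        if truth.independent_habitat_ranks:
            order = rng.permutation(len(ids))
        else:
            order = np.arange(len(ids))
        p = np.empty(len(ids))
        p[order] = p_by_rank
        expected_p[habitat] = pd.Series(p, index=list(ids))
    return SpeciesPools(
        oil_palm_ids=op_ids,
        forest_ids=fo_ids,
        shared_ids=shared,
        traits=traits,
        expected_p=expected_p,
    )


def sample_plot(
    expected_p, n_individuals: int, rng: np.random.Generator
) -> np.ndarray:
    """Multinomial draw of a plot's count vector over a species pool."""
    p = np.asarray(expected_p, dtype=float)
    if p.size == 0:
        raise ValidationError("cannot sample from an empty species pool")
    if n_individuals < 1:
        raise ValidationError("a plot must contain at least one individual")
    return rng.multinomial(n_individuals, p / p.sum())


def _grid_centers(n: int, spacing_km: float, cols: int = 4) -> np.ndarray:
    """(x, y) km positions of n pair-cluster centres on a compact grid."""
    idx = np.arange(n)
    return np.column_stack(((idx % cols) * spacing_km, (idx // cols) * spacing_km))


def _plot_positions(
    n_plots: int, truth: SyntheticTruth, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Plot (x, y) km positions and their pair-cluster index.

    Plots are placed two per cluster centre, within-pair spacing drawn from
    ``pair_distance_km``; an odd plot count leaves one isolated plot far
    (> level-2 cap) from every cluster, which the pairing stage will omit.
    """
    n_pairs = n_plots // 2
    centers = _grid_centers(n_pairs, truth.cluster_spacing_km)
    xy = np.empty((n_plots, 2))
    cluster = np.empty(n_plots, dtype=int)
    lo, hi = truth.pair_distance_km
    for c in range(n_pairs):
        d = rng.uniform(lo, hi)
        theta = rng.uniform(0.0, 2.0 * np.pi)
        off = 0.5 * d * np.array([np.cos(theta), np.sin(theta)])
        xy[2 * c] = centers[c] + off
        xy[2 * c + 1] = centers[c] - off
        cluster[2 * c] = cluster[2 * c + 1] = c
    if n_plots % 2:
        # isolated plot: beyond pairing range of every cluster
        xy[-1] = centers.min(axis=0) - 2.0 * truth.cluster_spacing_km
        cluster[-1] = n_pairs
    return xy, cluster


@dataclass(frozen=True)
class Landscape:
    matrix: AbundanceMatrix
    metadata: pd.DataFrame
    traits: pd.DataFrame
    truth: SyntheticTruth
    pools: SpeciesPools


def generate_landscape(truth: SyntheticTruth) -> Landscape:
    """Simulate the full landscape: counts, plot metadata, species traits."""
    rng = np.random.default_rng(truth.seed)
    pools = generate_species_pools(truth, rng)
    union = list(pools.union_ids)
    col_index = {sp: i for i, sp in enumerate(union)}

    habitat_specs = (
        (OIL_PALM, "op", truth.n_plots_oil_palm, 5.0, 117.0, pools.expected_p[OIL_PALM]),
        (FOREST, "fo", truth.n_plots_forest, 5.0, 118.2, pools.expected_p[FOREST]),
    )
    counts = []
    meta_rows = []
    for habitat, prefix, n_plots, lat0, lon0, expected in habitat_specs:
        xy, cluster = _plot_positions(n_plots, truth, rng)
        p_union = np.zeros(len(union))
        for sp, p in expected.items():
            p_union[col_index[sp]] = p
        for j in range(n_plots):
            counts.append(sample_plot(p_union, truth.individuals_per_plot, rng))
            meta_rows.append(
                {
                    "sample_id": f"{prefix}{j + 1:02d}",
                    "habitat": habitat,
                    "block": f"{prefix}_block_{cluster[j] + 1:02d}",
                    "latitude": lat0 + xy[j, 1] / KM_PER_DEG_LAT,
                    "longitude": lon0
                    + xy[j, 0] / (KM_PER_DEG_LAT * np.cos(np.radians(lat0))),
                    "year": 2011 if cluster[j] % 2 == 0 else 2012,
                }
            )
    metadata = pd.DataFrame(meta_rows).set_index("sample_id")
    matrix = AbundanceMatrix(
        pd.DataFrame(
            np.array(counts, dtype=float), index=metadata.index, columns=union
        ),
        "count",
    )
    return Landscape(
        matrix=matrix, metadata=metadata, traits=pools.traits, truth=truth, pools=pools
    )


def write_landscape(landscape: Landscape, outdir) -> None:
    """Write counts.csv, metadata.csv, traits.csv and a truth.json sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_abundance_table(landscape.matrix, outdir / "counts.csv")
    write_sample_metadata(landscape.metadata, outdir / "metadata.csv")
    write_species_traits(landscape.traits, outdir / "traits.csv")
    truth = asdict(landscape.truth)
    truth["pair_distance_km"] = list(truth["pair_distance_km"])
    truth["analytic_sorensen"] = landscape.truth.analytic_sorensen()
    (outdir / "truth.json").write_text(json.dumps(truth, indent=2, sort_keys=True))
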