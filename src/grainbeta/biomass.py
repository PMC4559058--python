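"""Count-to-biomass conversion with allometric weight prediction.

Each species (and caste, for dimorphic species) gets a mean individual dry
weight in mg: the arithmetic mean of measured specimens when at least
three were weighed, otherwise a prediction from a log–log (power-law)
regression of mean dry weight on a body dimension. Which dimension is
measured follows the subfamily convention of ant allometry work: head
length for Dolichoderinae, Formicinae and Pseudomyrmecinae; hind-tibia
length for Ponerinae; pronotum width for Myrmicinae. One regression is
fitted per dimension type; species whose dimension type has no fitted
model fall back to a pooled all-species model.

Count-matrix columns may carry a caste suffix (``species|major``,
``species|minor``); castes are converted separately and summed into a
single species column afterwards, so total biomass is exactly
``sum(count * mean weight)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .community import AbundanceMatrix, ValidationError

#: separator between species id and caste in count-matrix column names
CASTE_SEP = "|"
#: minimum number of weighed specimens for a measured (non-predicted) mean
MIN_SPECIMENS = 3
#: key of the pooled fallback regression in a model dictionary
POOLED_MODEL = "all"

#: subfamily -> measured body dimension, as conventional in ant allometry
DIMENSION_BY_SUBFAMILY = {
    "Dolichoderinae": "head_length",
    "Formicinae": "head_length",
    "Pseudomyrmecinae": "head_length",
    "Ponerinae": "tibia_length",
    "Myrmicinae": "pronotum_width",
}


@dataclass(frozen=True)
class AllometryModel:
    """Straight-line fit of log(mean dry weight, mg) on log(dimension, mm)."""

    dimension_type: str
    intercept: float
    slope: float
    n_points: int
    residual_var: float

    def predict(self, dimension_mm: float) -> float:
        if dimension_mm <= 0:
            raise ValidationError(f"dimension must be positive, got {dimension_mm}")
        return float(np.exp(self.intercept + self.slope * np.log(dimension_mm)))


@dataclass(frozen=True)
class SpeciesWeight:
    species_id: str
    caste: str
    mean_weight_mg: float
    source: str  # "measured" | "predicted"

    def __post_init__(self):
        if self.mean_weight_mg <= 0:
            raise ValidationError(
                f"mean weight must be positive for {self.species_id!r}"
            )


def split_column(column: str) -> tuple[str, str]:
    """Split a count-matrix column into (species_id, caste)."""
    if CASTE_SEP in column:
        species, caste = column.rsplit(CASTE_SEP, 1)
        return species, caste
    return column, "none"


def mean_measured_weight(
    traits: pd.DataFrame, species_id: str, caste: str = "none"
) -> SpeciesWeight | None:
    """Mean of measured dry weights, or None when fewer than 3 specimens."""
    rows = traits[(traits["species_id"] == species_id) & (traits["caste"] == caste)]
    if rows.empty:
        return None
    weights = list(rows.iloc[0]["dry_weights_mg"])
    if len(weights) < MIN_SPECIMENS:
        return None
    return SpeciesWeight(
        species_id=species_id,
        caste=caste,
        mean_weight_mg=float(np.mean(weights)),
        source="measured",
    )


def fit_allometry(
    traits: pd.DataFrame, strict: bool = True
) -> dict[str, AllometryModel]:
    """Fit one log–log regression per dimension type, plus a pooled model.

    Only species with a measured mean (>= 3 specimens) and a recorded
    dimension contribute points. A group present in the data but with
    fewer than two distinct dimension values is an error naming the group;
    with ``strict=False`` such a group is left unfitted instead, and
    predictions for it fall back to the pooled all-species model.
    """
    points: dict[str, list[tuple[float, float]]] = {}
    for _, row in traits.iterrows():
        weights = row["dry_weights_mg"]
        dim = row["dimension_mm"]
        if len(weights) < MIN_SPECIMENS or pd.isna(dim):
            continue
        x = float(np.log(float(dim)))
        y = float(np.log(np.mean(weights)))
        points.setdefault(str(row["dimension_type"]), []).append((x, y))
        points.setdefault(POOLED_MODEL, []).append((x, y))
    models: dict[str, AllometryModel] = {}
    for group, pts in points.items():
        xs = np.array([p[0] for p in pts])
        ys = np.array([p[1] for p in pts])
        if len(pts) < 2 or np.unique(xs).size < 2:
            if strict:
                raise ValidationError(
                    f"allometry group {group!r} needs >= 2 distinct dimension "
                    f"values (got {len(pts)} point(s))"
                )
            continue
        fit = stats.linregress(xs, ys)
        resid = ys - (fit.intercept + fit.slope * xs)
        dof = max(len(pts) - 2, 1)
        models[group] = AllometryModel(
            dimension_type=group,
            intercept=float(fit.intercept),
            slope=float(fit.slope),
            n_points=len(pts),
            residual_var=float((resid**2).sum() / dof),
        )
    if not models:
        raise ValidationError(
            "no species with >= 3 weighed specimens and a body dimension; "
            "cannot fit allometric regressions"
        )
    return models


def resolve_weights(
    traits: pd.DataFrame, models: dict[str, AllometryModel] | None = None
) -> dict[tuple[str, str], SpeciesWeight]:
    """Mean weight for every (species, caste) trait row, measured or predicted."""
    weights: dict[tuple[str, str], SpeciesWeight] = {}
    offenders: list[str] = []
    need_models = models
    for _, row in traits.iterrows():
        sp, caste = str(row["species_id"]), str(row["caste"])
        measured = mean_measured_weight(traits, sp, caste)
        if measured is not None:
            weights[(sp, caste)] = measured
            continue
        dim = row["dimension_mm"]
        if pd.isna(dim):
            offenders.append(f"{sp} ({caste})")
            continue
        if need_models is None:
            need_models = fit_allometry(traits)
        model = need_models.get(str(row["dimension_type"]), need_models.get(POOLED_MODEL))
        if model is None:
            offenders.append(f"{sp} ({caste})")
            continue
        weights[(sp, caste)] = SpeciesWeight(
            species_id=sp,
            caste=caste,
            mean_weight_mg=model.predict(float(dim)),
            source="predicted",
        )
    if offenders:
        raise ValidationError(
            "species lacking both measured weights and a usable body dimension: "
            + ", ".join(offenders)
        )
    return weights


def conversion_matrix(
    columns, weights: dict[tuple[str, str], SpeciesWeight]
) -> tuple[np.ndarray, list[str]]:
    """Linear map W from caste-level count columns to species biomass columns.

    ``counts @ W`` is the biomass matrix; species order follows first
    occurrence among the count columns.
    """
    species_order: list[str] = []
    col_species, col_weight = [], []
    missing: list[str] = []
    for col in columns:
        sp, caste = split_column(str(col))
        w = weights.get((sp, caste))
        if w is None:
            missing.append(f"{sp} ({caste})")
            continue
        if sp not in species_order:
            species_order.append(sp)
        col_species.append(sp)
        col_weight.append(w.mean_weight_mg)
    if missing:
        raise ValidationError(
            "count columns without a resolvable mean weight: " + ", ".join(missing)
        )
    W = np.zeros((len(col_species), len(species_order)))
    sp_index = {sp: k for k, sp in enumerate(species_order)}
    for i, (sp, w) in enumerate(zip(col_species, col_weight)):
        W[i, sp_index[sp]] = w
    return W, species_order


def counts_to_biomass(
    matrix: AbundanceMatrix,
    traits: pd.DataFrame,
    models: dict[str, AllometryModel] | None = None,
) -> AbundanceMatrix:
    """Convert a count matrix to biomass (mg), merging castes per species."""
    if matrix.value_kind != "count":
        raise ValidationError("counts_to_biomass expects a count matrix")
    weights = resolve_weights(traits, models)
    W, species_order = conversion_matrix(matrix.species_ids, weights)
    biomass = matrix.values @ W
    return AbundanceMatrix(
        pd.DataFrame(biomass, index=matrix.data.index, columns=species_order),
        "biomass",
    )


def model_report(models: dict[str, AllometryModel]) -> pd.DataFrame:
    """Tidy table of fitted allometric regressions."""
    rows = [
        {
            "group": key,
            "dimension_type": m.dimension_type,
            "intercept_log_mg": m.intercept,
            "slope": m.slope,
            "n_points": m.n_points,
            "residual_var": m.residual_var,
        }
        for key, m in sorted(models.items())
    ]
    return pd.DataFrame(rows)
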