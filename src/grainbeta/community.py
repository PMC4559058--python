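"""Containers and CSV I/O for site-by-species community tables.

The abundance matrix is the universal currency of the pipeline: rows are
samples (pitfall-trap plots, or pooled grain units), columns are species,
cells hold either individual counts or biomass in milligrams. Relative
abundances are always recomputed from the matrix at hand — proportions are
never carried through pooling, because pooling must conserve mass, not
proportions.

Samples whose row total is zero are rejected outright: a plot that yielded
no ants at all is either a data error or a suspect trap set, and silently
dropping it would bias every downstream mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

OIL_PALM = "oil_palm"
FOREST = "forest"
HABITATS = (OIL_PALM, FOREST)
VALUE_KINDS = ("count", "biomass")

CASTES = ("major", "minor", "none")
DIMENSION_TYPES = ("head_length", "tibia_length", "pronotum_width")

#: tolerance for a row of relative abundances summing to one
ROW_SUM_TOL = 1e-9


class ValidationError(ValueError):
    """A table violates a structural invariant."""


class ParseError(ValidationError):
    """A CSV cell could not be interpreted."""


def _check_unique(index: pd.Index, what: str) -> None:
    if index.has_duplicates:
        dups = index[index.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate {what} identifiers: {dups}")


@dataclass(frozen=True, eq=False)
class AbundanceMatrix:
    """Rectangular samples x species table of counts or biomass (mg)."""

    data: pd.DataFrame
    value_kind: str = "count"

    def __post_init__(self) -> None:
        if self.value_kind not in VALUE_KINDS:
            raise ValidationError(
                f"value_kind must be one of {VALUE_KINDS}, got {self.value_kind!r}"
            )
        df = self.data
        _check_unique(df.index, "sample")
        _check_unique(df.columns, "species")
        try:
            values = df.to_numpy(dtype=float)
        except (TypeError, ValueError) as exc:
            raise ParseError(f"non-numeric cell in abundance table: {exc}") from exc
        if values.size and not np.isfinite(values).all():
            raise ValidationError("abundance table contains NaN or infinite values")
        if values.size and (values < 0).any():
            r, c = map(int, np.argwhere(values < 0)[0])
            raise ValidationError(
                f"negative value at sample {df.index[r]!r}, species {df.columns[c]!r}"
            )
        if self.value_kind == "count" and values.size and (values % 1 != 0).any():
            r, c = map(int, np.argwhere(values % 1 != 0)[0])
            raise ValidationError(
                f"non-integral count {values[r, c]!r} at sample {df.index[r]!r}, "
                f"species {df.columns[c]!r}"
            )
        if values.shape[1] and (values.sum(axis=1) <= 0).any():
            bad = df.index[values.sum(axis=1) <= 0].tolist()
            raise ValidationError(f"samples with zero total abundance: {bad}")

    # -- basic geometry ----------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.data.index]

    @property
    def species_ids(self) -> list[str]:
        return [str(s) for s in self.data.columns]

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_species(self) -> int:
        return self.data.shape[1]

    # -- derived matrices --------------------------------------------------
    def subset_samples(self, sample_ids) -> "AbundanceMatrix":
        missing = [s for s in sample_ids if s not in self.data.index]
        if missing:
            raise KeyError(f"unknown sample ids: {missing}")
        return AbundanceMatrix(self.data.loc[list(sample_ids)], self.value_kind)

    def drop_empty_species(self) -> "AbundanceMatrix":
        """Remove species with zero total across all samples (idempotent)."""
        totals = self.values.sum(axis=0)
        return AbundanceMatrix(self.data.loc[:, totals > 0], self.value_kind)

    def to_relative(self) -> "RelativeAbundanceMatrix":
        v = self.values
        row_tot = v.sum(axis=1)
        if (row_tot <= 0).any():
            bad = self.data.index[row_tot <= 0].tolist()
            raise ValidationError(f"cannot normalise all-zero samples: {bad}")
        rel = v / row_tot[:, None]
        return RelativeAbundanceMatrix(
            pd.DataFrame(rel, index=self.data.index, columns=self.data.columns)
        )


@dataclass(frozen=True, eq=False)
class RelativeAbundanceMatrix:
    """Per-sample proportions; every row sums to one within ``ROW_SUM_TOL``."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "sample")
        _check_unique(self.data.columns, "species")
        v = self.data.to_numpy(dtype=float)
        if v.size and ((v < 0).any() or (v > 1).any()):
            raise ValidationError("relative abundances must lie in [0, 1]")
        if v.shape[1] and np.abs(v.sum(axis=1) - 1.0).max() > ROW_SUM_TOL:
            bad = self.data.index[np.abs(v.sum(axis=1) - 1.0) > ROW_SUM_TOL].tolist()
            raise ValidationError(f"rows do not sum to 1: {bad}")

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.data.index]


def to_relative(matrix: AbundanceMatrix) -> RelativeAbundanceMatrix:
    """Row-normalise an abundance matrix (functional form of the method)."""
    return matrix.to_relative()


def drop_empty_species(matrix: AbundanceMatrix) -> AbundanceMatrix:
    return matrix.drop_empty_species()


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def read_abundance_table(path, value_kind: str = "count") -> AbundanceMatrix:
    """Read a samples x species CSV (header = species ids, first column = sample ids)."""
    raw = pd.read_csv(path, index_col=0)
    raw.index = raw.index.astype(str)
    raw.columns = raw.columns.astype(str)
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna()
    if bad.to_numpy().any():
        r, c = map(int, np.argwhere(bad.to_numpy())[0])
        raise ParseError(
            f"non-numeric value {raw.iat[r, c]!r} at row {raw.index[r]!r}, "
            f"column {raw.columns[c]!r} of {path}"
        )
    return AbundanceMatrix(numeric, value_kind)


def write_abundance_table(matrix: AbundanceMatrix, path) -> None:
    df = matrix.data
    if matrix.value_kind == "count":
        df = df.astype(np.int64)
        df.to_csv(path)
    else:
        # 12 significant digits round-trips biomass within spec tolerance
        df.to_csv(path, float_format="%.12g")


def read_sample_metadata(path) -> pd.DataFrame:
    """Read per-sample metadata; index = sample_id.

    Required columns: habitat, latitude, longitude. Optional: block, year.
    """
    meta = pd.read_csv(path, index_col=0)
    meta.index = meta.index.astype(str)
    return validate_sample_metadata_frame(meta)


def validate_sample_metadata_frame(meta: pd.DataFrame) -> pd.DataFrame:
    _check_unique(meta.index, "sample")
    for col in ("habitat", "latitude", "longitude"):
        if col not in meta.columns:
            raise ValidationError(f"metadata is missing required column {col!r}")
    bad_hab = sorted(set(meta["habitat"]) - set(HABITATS))
    if bad_hab:
        raise ValidationError(f"unknown habitat labels {bad_hab}; expected {HABITATS}")
    coords = meta[["latitude", "longitude"]].to_numpy(dtype=float)
    if not np.isfinite(coords).all():
        bad = meta.index[~np.isfinite(coords).all(axis=1)].tolist()
        raise ValidationError(f"non-finite coordinates for samples: {bad}")
    return meta


def write_sample_metadata(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, index_label="sample_id")


def align_metadata(matrix: AbundanceMatrix, meta: pd.DataFrame) -> pd.DataFrame:
    """Check every sample has exactly one metadata record; return matrix order."""
    missing = [s for s in matrix.sample_ids if s not in meta.index]
    if missing:
        raise ValidationError(f"samples without metadata: {missing}")
    return meta.loc[matrix.sample_ids]


# ---------------------------------------------------------------------------
# Species traits
# ---------------------------------------------------------------------------

TRAIT_COLUMNS = (
    "species_id",
    "subfamily",
    "caste",
    "dimension_type",
    "dimension_mm",
    "dry_weights_mg",
)

_WEIGHT_SEP = ";"


def _parse_weight_list(cell) -> list[float]:
    if cell is None or (isinstance(cell, float) and np.isnan(cell)) or cell == "":
        return []
    if isinstance(cell, (list, tuple, np.ndarray)):
        weights = [float(w) for w in cell]
    else:
        weights = [float(tok) for tok in str(cell).split(_WEIGHT_SEP) if tok.strip()]
    if any(w <= 0 for w in weights):
        raise ValidationError(f"non-positive dry weight in {cell!r}")
    return weights


def validate_species_traits(traits: pd.DataFrame) -> pd.DataFrame:
    for col in TRAIT_COLUMNS:
        if col not in traits.columns:
            raise ValidationError(f"traits table is missing column {col!r}")
    traits = traits.copy()
    traits["species_id"] = traits["species_id"].astype(str)
    traits["caste"] = traits["caste"].fillna("none")
    bad_caste = sorted(set(traits["caste"]) - set(CASTES))
    if bad_caste:
        raise ValidationError(f"unknown caste labels {bad_caste}; expected {CASTES}")
    present = traits["dimension_type"].notna()
    bad_dim = sorted(set(traits.loc[present, "dimension_type"]) - set(DIMENSION_TYPES))
    if bad_dim:
        raise ValidationError(
            f"unknown dimension types {bad_dim}; expected {DIMENSION_TYPES}"
        )
    dims = pd.to_numeric(traits["dimension_mm"], errors="raise")
    if (dims.dropna() <= 0).any():
        bad = traits.loc[dims.notna() & (dims <= 0), "species_id"].tolist()
        raise ValidationError(f"non-positive body dimension for species: {bad}")
    traits["dry_weights_mg"] = [_parse_weight_list(c) for c in traits["dry_weights_mg"]]
    if traits.duplicated(["species_id", "caste"]).any():
        bad = traits.loc[
            traits.duplicated(["species_id", "caste"]), "species_id"
        ].tolist()
        raise ValidationError(f"duplicate (species, caste) trait rows: {bad}")
    return traits


def read_species_traits(path) -> pd.DataFrame:
    return validate_species_traits(pd.read_csv(path))


def write_species_traits(traits: pd.DataFrame, path) -> None:
    out = traits.copy()
    out["dry_weights_mg"] = [
        _WEIGHT_SEP.join(f"{w:.6g}" for w in ws) for ws in out["dry_weights_mg"]
    ]
    out.to_csv(path, index=False)
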