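"""Hill numbers and the multi-assemblage overlap family C_qN.

The effective number of species of order q for a relative-abundance vector
p is ``(sum_i p_i^q)^(1/(1-q))`` with the Shannon limit ``exp(-sum p ln p)``
at q = 1. For N equally weighted communities, gamma diversity is the Hill
number of the pooled mean proportions and alpha diversity is the
equal-weight multi-community generalisation; their ratio D_beta lies in
[1, N] and is mapped onto the [0, 1] overlap scale by

    C_qN = [ (1/D_beta)^(q-1) - (1/N)^(q-1) ] / [ 1 - (1/N)^(q-1) ]   (q != 1)
    C_1N = 1 - ln(D_beta) / ln(N)                                     (q -> 1)

C_qN reduces to the multi-assemblage Sørensen index at q = 0, the Horn
index at q = 1, and the Morisita–Horn generalisation at q = 2; beta
diversity on the [0, 1] scale is reported as 1 - C_qN.

All operations are abundance-agnostic: they accept counts or biomass and
always renormalise rows, so biomass acts as a drop-in surrogate for
individual counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .community import (
    AbundanceMatrix,
    RelativeAbundanceMatrix,
    ROW_SUM_TOL,
    ValidationError,
)

#: |q - 1| below this routes to the analytic Shannon limit
Q_ONE_TOL = 1e-9
#: slack allowed on the mathematical bounds 1 <= D_beta <= N and 0 <= C <= 1
CONSISTENCY_TOL = 1e-6


class ConsistencyError(ArithmeticError):
    """An internally computed quantity violated its mathematical bounds."""


def _as_probability_vector(p) -> np.ndarray:
    p = np.asarray(p, dtype=float).ravel()
    if p.size and (p < 0).any():
        raise ValidationError("relative abundances must be non-negative")
    return p


def _rel_rows(communities) -> np.ndarray:
    """Coerce input to an (N, S) array of row proportions."""
    if isinstance(communities, AbundanceMatrix):
        return communities.to_relative().values
    if isinstance(communities, RelativeAbundanceMatrix):
        return communities.values
    arr = np.asarray(communities, dtype=float)
    if arr.ndim != 2:
        raise ValidationError("expected a 2-D samples x species array")
    if (arr < 0).any():
        raise ValidationError("abundances must be non-negative")
    row_tot = arr.sum(axis=1)
    if (row_tot <= 0).any():
        raise ValidationError("every community must contain at least one individual")
    return arr / row_tot[:, None]


def hill_number(p, q: float) -> float:
    """Effective number of species of order q for one community.

    ``p`` must sum to one (within ``ROW_SUM_TOL``); zero entries contribute
    nothing. An empty (all-zero) vector yields 0 by convention.
    """
    if q < 0:
        raise ValidationError(f"diversity order q must be >= 0, got {q}")
    p = _as_probability_vector(p)
    pos = p[p > 0]
    if pos.size == 0:
        return 0.0
    if abs(p.sum() - 1.0) > ROW_SUM_TOL:
        raise ValidationError(f"abundances must sum to 1, got {p.sum()!r}")
    if abs(q - 1.0) < Q_ONE_TOL:
        return float(np.exp(-np.sum(pos * np.log(pos))))
    return float(np.sum(pos**q) ** (1.0 / (1.0 - q)))


def multi_gamma(communities, q: float) -> float:
    """Hill number of the equal-weight pooled proportions of N communities."""
    P = _rel_rows(communities)
    return hill_number(P.mean(axis=0), q)


def multi_alpha(communities, q: float) -> float:
    """Equal-weight multi-community alpha diversity of order q."""
    if q < 0:
        raise ValidationError(f"diversity order q must be >= 0, got {q}")
    P = _rel_rows(communities)
    n = P.shape[0]
    if abs(q - 1.0) < Q_ONE_TOL:
        with np.errstate(divide="ignore", invalid="ignore"):
            plogp = np.where(P > 0, P * np.log(np.where(P > 0, P, 1.0)), 0.0)
        return float(np.exp(-plogp.sum() / n))
    pos = P[P > 0]
    return float((np.sum(pos**q) / n) ** (1.0 / (1.0 - q)))


def beta_ratio(communities, q: float) -> float:
    """Multiplicative beta diversity D_beta = gamma / alpha, in [1, N]."""
    P = _rel_rows(communities)
    n = P.shape[0]
    d = multi_gamma(P, q) / multi_alpha(P, q)
    if d < 1.0 - CONSISTENCY_TOL or d > n + CONSISTENCY_TOL:
        raise ConsistencyError(f"D_beta = {d} outside [1, {n}] for q = {q}")
    return float(min(max(d, 1.0), float(n)))


@dataclass(frozen=True)
class OverlapResult:
    """C_qN overlap of N assemblages and its beta complement 1 - C_qN."""

    q: float
    n_assemblages: int
    cqn: float
    beta: float
    se: float | None = None
    grain: int | None = None
    habitat: str | None = None


def overlap_cqn(
    communities,
    q: float,
    se: float | None = None,
    grain: int | None = None,
    habitat: str | None = None,
) -> OverlapResult:
    """Percentage species overlap among N >= 2 equally weighted communities."""
    P = _rel_rows(communities)
    n = P.shape[0]
    if n < 2:
        raise ValidationError(f"C_qN needs at least 2 assemblages, got {n}")
    d = beta_ratio(P, q)
    if abs(q - 1.0) < Q_ONE_TOL:
        c = 1.0 - math.log(d) / math.log(n)
    else:
        r = q - 1.0
        c = ((1.0 / d) ** r - (1.0 / n) ** r) / (1.0 - (1.0 / n) ** r)
    if c < -CONSISTENCY_TOL or c > 1.0 + CONSISTENCY_TOL:
        raise ConsistencyError(f"C_qN = {c} outside [0, 1] for q = {q}")
    c = float(min(max(c, 0.0), 1.0))
    return OverlapResult(
        q=q, n_assemblages=n, cqn=c, beta=1.0 - c, se=se, grain=grain, habitat=habitat
    )


def overlap_profile(communities, qs) -> np.ndarray:
    """C_qN for several orders q at once (one pass over the data)."""
    P = _rel_rows(communities)
    return np.array([overlap_cqn(P, q).cqn for q in qs])


def pairwise_similarity(c1, c2, q: float) -> float:
    """C_qN with N = 2: Sørensen (q=0), Horn (q=1), Morisita–Horn (q=2)."""
    p1 = _as_probability_vector(c1)
    p2 = _as_probability_vector(c2)
    if p1.sum() <= 0 or p2.sum() <= 0:
        raise ValidationError("both communities must be nonempty")
    return overlap_cqn(np.vstack([p1 / p1.sum(), p2 / p2.sum()]), q).cqn


def pairwise_matrix(block_a, block_b, q: float) -> np.ndarray:
    """All pairwise similarities between the rows of two community blocks.

    Returns an (n_a, n_b) array; vectorised closed forms are used for
    q in {0, 1, 2}, the generic C_qN route otherwise. The closed forms are
    algebraically identical to ``pairwise_similarity`` (asserted in tests).
    """
    A = _rel_rows(block_a)
    B = _rel_rows(block_b)
    if A.shape[1] != B.shape[1]:
        raise ValidationError("community blocks must share a species axis")
    if q == 0:
        ia, ib = (A > 0).astype(float), (B > 0).astype(float)
        shared = ia @ ib.T
        return 2.0 * shared / (ia.sum(axis=1)[:, None] + ib.sum(axis=1)[None, :])
    if q == 2:
        num = 2.0 * (A @ B.T)
        den = (A**2).sum(axis=1)[:, None] + (B**2).sum(axis=1)[None, :]
        return num / den
    if abs(q - 1.0) < Q_ONE_TOL:
        def _entropy(M):
            with np.errstate(divide="ignore", invalid="ignore"):
                t = np.where(M > 0, M * np.log(np.where(M > 0, M, 1.0)), 0.0)
            return -t.sum(axis=-1)

        ha, hb = _entropy(A), _entropy(B)
        mix = 0.5 * (A[:, None, :] + B[None, :, :])
        h_mix = _entropy(mix)
        return 1.0 - (h_mix - 0.5 * (ha[:, None] + hb[None, :])) / math.log(2.0)
    out = np.empty((A.shape[0], B.shape[0]))
    for i in range(A.shape[0]):
        for j in range(B.shape[0]):
            out[i, j] = pairwise_similarity(A[i], B[j], q)
    return out


# ---------------------------------------------------------------------------
# Grain-level summaries
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MeanAlphaResult:
    """Mean per-community Hill diversity at one grain, with bootstrap SE."""

    q: float
    mean: float
    se: float | None
    n: int
    values: tuple[float, ...]


def mean_alpha(
    matrix, q: float, b: int = 1000, rng: np.random.Generator | None = None
) -> MeanAlphaResult:
    """Arithmetic mean over samples of the per-sample Hill number.

    The SE is a bootstrap over samples (the per-sample diversities are
    resampled with replacement ``b`` times), matching a unit-resampling
    bootstrap of the mean.
    """
    P = _rel_rows(matrix)
    if P.shape[0] == 0:
        raise ValidationError("mean alpha of an empty matrix is undefined")
    vals = np.array([hill_number(row, q) for row in P])
    se = None
    if b >= 2:
        rng = np.random.default_rng(0) if rng is None else rng
        idx = rng.integers(0, vals.size, size=(b, vals.size))
        se = float(vals[idx].mean(axis=1).std(ddof=1))
    return MeanAlphaResult(
        q=q, mean=float(vals.mean()), se=se, n=vals.size, values=tuple(vals)
    )


@dataclass(frozen=True)
class PairwiseMeanResult:
    """Mean between-habitat pairwise similarity at one grain."""

    q: float
    mean: float
    se: float | None
    n_pairs: int
    grain: int | None = None


def mean_pairwise_between(
    matrix,
    habitats: pd.Series,
    q: float,
    b: int = 500,
    rng: np.random.Generator | None = None,
    habitat_pair: tuple[str, str] = ("oil_palm", "forest"),
    grain: int | None = None,
) -> PairwiseMeanResult:
    """Mean similarity over all cross-habitat community pairs at one grain.

    The SE bootstraps communities within each habitat with replacement; as
    resampling only reweights existing pairs, the precomputed pairwise
    similarity matrix is simply re-indexed for each of the ``b`` iterations.
    """
    if not isinstance(matrix, AbundanceMatrix):
        raise ValidationError("mean_pairwise_between expects an AbundanceMatrix")
    lab_a, lab_b = habitat_pair
    ids_a = [s for s in matrix.sample_ids if habitats.get(s) == lab_a]
    ids_b = [s for s in matrix.sample_ids if habitats.get(s) == lab_b]
    if not ids_a or not ids_b:
        raise ValidationError(
            f"both habitats must be present (found {len(ids_a)} {lab_a!r}, "
            f"{len(ids_b)} {lab_b!r} communities)"
        )
    C = pairwise_matrix(
        matrix.subset_samples(ids_a), matrix.subset_samples(ids_b), q
    )
    se = None
    if b >= 2:
        rng = np.random.default_rng(0) if rng is None else rng
        na, nb = C.shape
        means = np.empty(b)
        for k in range(b):
            ia = rng.integers(0, na, size=na)
            ib = rng.integers(0, nb, size=nb)
            means[k] = C[np.ix_(ia, ib)].mean()
        se = float(means.std(ddof=1))
    return PairwiseMeanResult(
        q=q, mean=float(C.mean()), se=se, n_pairs=C.size, grain=grain
    )


def remove_singletons(matrix: AbundanceMatrix) -> AbundanceMatrix:
    """Drop species whose total count across the analysis set equals one.

    Singletons are defined on individual counts, before any biomass
    conversion; a biomass matrix is refused.
    """
    if matrix.value_kind != "count":
        raise ValidationError(
            "singletons are defined on counts; remove them before converting "
            "to biomass"
        )
    totals = matrix.values.sum(axis=0)
    return AbundanceMatrix(matrix.data.loc[:, totals != 1], "count")


def top_biomass_ranks(matrix: AbundanceMatrix, k: int = 20) -> pd.DataFrame:
    """Rank species by mean biomass per grain unit (descending, ties by id)."""
    if matrix.value_kind != "biomass":
        raise ValidationError("rank–biomass tables require a biomass matrix")
    per_unit = matrix.values.sum(axis=0) / matrix.n_samples
    table = pd.DataFrame(
        {"species_id": matrix.species_ids, "mean_biomass_mg_per_unit": per_unit}
    )
    table = table.sort_values(
        ["mean_biomass_mg_per_unit", "species_id"],
        ascending=[False, True],
        kind="mergesort",
    ).head(k)
    table.insert(0, "rank", np.arange(1, len(table) + 1))
    return table.reset_index(drop=True)
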