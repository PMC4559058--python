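"""Sample-based rarefaction and sample-coverage estimation.

Interpolation only: the question answered here is whether the realised
sampling effort was deep enough for diversity comparisons, not how many
species remain undetected. Expected richness at m of T samples uses the
analytic incidence-based interpolation

    S(m) = sum_i [ 1 - C(T - T_i, m) / C(T, m) ]

with T_i the number of samples containing species i, and coverage uses the
singleton/doubleton estimator

    C_hat = 1 - (f1 / n) * (n - 1) f1 / ((n - 1) f1 + 2 f2)

which equals 1 when the sample holds no singletons.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .community import AbundanceMatrix, ValidationError


def _as_matrix_values(matrix) -> np.ndarray:
    if isinstance(matrix, AbundanceMatrix):
        return matrix.values
    arr = np.asarray(matrix, dtype=float)
    if arr.ndim != 2:
        raise ValidationError("expected a 2-D samples x species array")
    return arr


def rarefy_richness(matrix, m: int) -> float:
    """Expected species richness of m pooled samples (incidence-based)."""
    v = _as_matrix_values(matrix)
    T = v.shape[0]
    if not 1 <= m <= T:
        raise ValidationError(f"m must lie in [1, {T}], got {m}")
    incidence = (v > 0).sum(axis=0)
    incidence = incidence[incidence > 0]
    cT = math.comb(T, m)
    # exact integer binomials; comb(T - Ti, m) is 0 when T - Ti < m
    absent = sum(math.comb(T - int(ti), m) for ti in incidence)
    return float(incidence.size - absent / cT)


def rarefy_richness_individuals(counts, n: int) -> float:
    """Expected richness of n individuals drawn without replacement (abundance-based)."""
    c = np.asarray(counts, dtype=float)
    c = c[c > 0].astype(int)
    N = int(c.sum())
    if not 1 <= n <= N:
        raise ValidationError(f"n must lie in [1, {N}], got {n}")
    cN = math.comb(N, n)
    absent = sum(math.comb(N - int(ci), n) for ci in c)
    return float(c.size - absent / cN)


@dataclass(frozen=True)
class RarefactionCurve:
    m: tuple[int, ...]
    richness: tuple[float, ...]
    label: str = ""

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"m": self.m, "expected_richness": self.richness, "label": self.label})


def rarefaction_curve(matrix, label: str = "") -> RarefactionCurve:
    v = _as_matrix_values(matrix)
    grid = range(1, v.shape[0] + 1)
    return RarefactionCurve(
        m=tuple(grid), richness=tuple(rarefy_richness(v, m) for m in grid), label=label
    )


@dataclass(frozen=True)
class CoverageEstimate:
    n: int
    f1: int
    f2: int
    coverage: float


def coverage(counts) -> CoverageEstimate:
    """Estimated sample coverage of a pooled count vector."""
    c = np.asarray(counts, dtype=float).ravel()
    if c.size == 0 or c.sum() <= 0:
        raise ValidationError("coverage of an empty sample is undefined")
    if (c < 0).any() or (c % 1 != 0).any():
        raise ValidationError("coverage requires non-negative integer counts")
    n = int(c.sum())
    f1 = int((c == 1).sum())
    f2 = int((c == 2).sum())
    if f1 == 0:
        cov = 1.0
    else:
        denom = (n - 1) * f1 + 2 * f2
        cov = 1.0 - (f1 / n) * ((n - 1) * f1 / denom) if denom > 0 else 0.0
    return CoverageEstimate(n=n, f1=f1, f2=f2, coverage=float(np.clip(cov, 0.0, 1.0)))


def coverage_curve(
    matrix,
    r_subsets: int = 200,
    rng: np.random.Generator | None = None,
    exhaustive_limit: int = 500,
    label: str = "",
) -> pd.DataFrame:
    """Mean coverage of m pooled samples, m = 1..T.

    All C(T, m) subsets are enumerated when there are at most
    ``exhaustive_limit`` of them; otherwise ``r_subsets`` seeded random
    subsets are averaged.
    """
    v = _as_matrix_values(matrix)
    T = v.shape[0]
    if T < 1:
        raise ValidationError("coverage curve needs at least one sample")
    rng = np.random.default_rng(0) if rng is None else rng
    rows = []
    for m in range(1, T + 1):
        if math.comb(T, m) <= exhaustive_limit:
            subsets = itertools.combinations(range(T), m)
            covs = [coverage(v[list(s)].sum(axis=0)).coverage for s in subsets]
        else:
            covs = [
                coverage(v[rng.choice(T, size=m, replace=False)].sum(axis=0)).coverage
                for _ in range(r_subsets)
            ]
        rows.append({"m": m, "coverage": float(np.mean(covs)), "label": label})
    return pd.DataFrame(rows)
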