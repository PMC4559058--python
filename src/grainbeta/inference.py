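"""Bootstrap standard errors, standardized Z tests, and BH-FDR control.

Two resampling schemes are exposed. ``resample_units`` redraws whole
communities (rows) with replacement and suits grains whose units pool
several plots; ``resample_individuals`` redraws each community's
individuals from a multinomial at the observed depth and suits the plot
grain, where unit resampling would be degenerate. The statistic may return
a scalar or a vector (e.g. C_qN at several orders q in one pass); the SE
is the bootstrap standard deviation, component-wise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .community import AbundanceMatrix, ValidationError

SCHEMES = ("resample_units", "resample_individuals")


@dataclass(frozen=True)
class BootstrapResult:
    estimate: float | np.ndarray
    se: float | np.ndarray
    b: int
    scheme: str
    n_failures: int = 0


def _values_of(matrix) -> np.ndarray:
    if isinstance(matrix, AbundanceMatrix):
        return matrix.values
    arr = np.asarray(matrix, dtype=float)
    if arr.ndim != 2:
        raise ValidationError("expected a 2-D samples x species array")
    return arr


def _resample(values: np.ndarray, rng: np.random.Generator, scheme: str) -> np.ndarray:
    n = values.shape[0]
    if scheme == "resample_units":
        return values[rng.integers(0, n, size=n)]
    if scheme == "resample_individuals":
        if (values % 1 != 0).any():
            raise ValidationError(
                "resample_individuals requires integer counts per cell"
            )
        out = np.empty_like(values)
        for j in range(n):
            row = values[j]
            tot = int(row.sum())
            if tot < 1:
                raise ValidationError("cannot resample an empty community")
            out[j] = rng.multinomial(tot, row / row.sum())
        return out
    raise ValidationError(f"unknown scheme {scheme!r}; expected one of {SCHEMES}")


def bootstrap_statistic(
    matrix,
    statistic,
    b: int = 1000,
    rng: np.random.Generator | None = None,
    scheme: str = "resample_units",
) -> BootstrapResult:
    """Bootstrap SE of ``statistic`` over ``b`` resamples of a community matrix.

    ``statistic`` receives the raw (resampled) values array and returns a
    float or a 1-D array. A statistic failure inside a resample is recorded
    and the resample redrawn; persistent failure aborts.
    """
    if b < 2:
        raise ValidationError(f"bootstrap needs b >= 2 iterations, got {b}")
    values = _values_of(matrix)
    rng = np.random.default_rng(0) if rng is None else rng
    point = np.atleast_1d(np.asarray(statistic(values), dtype=float))
    draws = np.empty((b, point.size))
    failures = 0
    for i in range(b):
        while True:
            res = _resample(values, rng, scheme)
            try:
                draws[i] = np.atleast_1d(np.asarray(statistic(res), dtype=float))
                break
            except Exception:
                failures += 1
                if failures > 10 * b:
                    raise RuntimeError(
                        "statistic failed in more than 10x the requested resamples"
                    )
    se = draws.std(axis=0, ddof=1)
    scalar = point.size == 1
    return BootstrapResult(
        estimate=float(point[0]) if scalar else point,
        se=float(se[0]) if scalar else se,
        b=b,
        scheme=scheme,
        n_failures=failures,
    )


@dataclass(frozen=True)
class ComparisonResult:
    label_a: str
    label_b: str
    estimate_a: float
    estimate_b: float
    difference: float
    z: float
    p: float


def z_test(
    est1: float,
    se1: float,
    est2: float,
    se2: float,
    label_a: str = "a",
    label_b: str = "b",
) -> ComparisonResult:
    """Two-sided standardized Z test for a difference of two estimates."""
    if se1 < 0 or se2 < 0:
        raise ValidationError("standard errors must be non-negative")
    pooled = float(np.hypot(se1, se2))
    if pooled == 0:
        raise ValidationError("both standard errors are zero; Z is undefined")
    diff = float(est1 - est2)
    z = diff / pooled
    p = float(2.0 * sps.norm.sf(abs(z)))
    return ComparisonResult(
        label_a=label_a,
        label_b=label_b,
        estimate_a=float(est1),
        estimate_b=float(est2),
        difference=diff,
        z=z,
        p=p,
    )


def bh_fdr(pvalues, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini–Hochberg step-up: (reject flags, adjusted p-values)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    if (p < 0).any() or (p > 1).any() or not np.isfinite(p).all():
        raise ValidationError("p-values must lie in [0, 1]")
    if not 0 < alpha < 1:
        raise ValidationError(f"alpha must lie in (0, 1), got {alpha}")
    reject, p_adj, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return reject, p_adj
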