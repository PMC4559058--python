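"""Hierarchical sampling-grain construction by proximity pairing.

Grain 1 is the individual plot. Grain 2 pools pairs of same-habitat plots
in close proximity (default cap ~5 km); grain 3 pools pairs of grain-2
units (default cap 45 km), so each grain-3 unit is the union of exactly
four plots. Total sampled area per retained unit is therefore fixed within
a level, and abundance is conserved exactly at every pooling step.

Pairing is a deterministic greedy matching on ascending great-circle
distance with ties broken lexicographically by sample id; plots left
without a partner within the cap are recorded as omitted, never silently
dropped. An explicit user-supplied pairing can override the matcher.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .community import AbundanceMatrix, ValidationError, align_metadata

EARTH_RADIUS_KM = 6371.0


def haversine_km(lat1, lon1, lat2, lon2):
    """Great-circle distance in km (array-capable)."""
    lat1, lon1, lat2, lon2 = (np.radians(np.asarray(x, float)) for x in (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def pairwise_distance(metadata: pd.DataFrame) -> pd.DataFrame:
    """Symmetric sample x sample great-circle distance table in km."""
    coords = metadata[["latitude", "longitude"]].to_numpy(dtype=float)
    if not np.isfinite(coords).all():
        bad = metadata.index[~np.isfinite(coords).all(axis=1)].tolist()
        raise ValidationError(f"missing or non-finite coordinates: {bad}")
    lat, lon = coords[:, 0], coords[:, 1]
    d = haversine_km(lat[:, None], lon[:, None], lat[None, :], lon[None, :])
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=metadata.index, columns=metadata.index)


@dataclass(frozen=True)
class Pairing:
    pairs: tuple[tuple[str, str], ...]
    omitted: tuple[tuple[str, str], ...]  # (sample_id, reason)


def pair_samples(distances: pd.DataFrame, max_km: float) -> Pairing:
    """Greedy matching on ascending distance subject to a distance cap."""
    ids = [str(i) for i in distances.index]
    candidates = []
    for i, a in enumerate(ids):
        for j in range(i + 1, len(ids)):
            b = ids[j]
            d = float(distances.iat[i, j])
            if d <= max_km:
                lo, hi = sorted((a, b))
                candidates.append((d, lo, hi))
    candidates.sort()
    matched: set[str] = set()
    pairs = []
    for _, a, b in candidates:
        if a not in matched and b not in matched:
            pairs.append((a, b))
            matched |= {a, b}
    omitted = tuple(
        (s, f"no unmatched partner within {max_km} km")
        for s in ids
        if s not in matched
    )
    return Pairing(pairs=tuple(sorted(pairs)), omitted=omitted)


def pool_samples(matrix: AbundanceMatrix, groups) -> AbundanceMatrix:
    """Sum constituent rows of each group into one pooled unit.

    Unit ids are the sorted member ids joined by '+'. A sample may belong
    to at most one group.
    """
    seen: set[str] = set()
    rows, index = [], []
    for group in groups:
        members = [str(m) for m in group]
        dup = [m for m in members if m in seen]
        if dup:
            raise ValidationError(f"samples assigned to more than one group: {dup}")
        seen.update(members)
        missing = [m for m in members if m not in matrix.data.index]
        if missing:
            raise ValidationError(f"pairing references unknown samples: {missing}")
        rows.append(matrix.data.loc[members].sum(axis=0))
        index.append("+".join(sorted(members)))
    pooled = pd.DataFrame(rows, index=index)
    pooled = pooled.sort_index()
    return AbundanceMatrix(pooled, matrix.value_kind)


@dataclass(frozen=True)
class GrainHierarchy:
    """Composition of one grain level in terms of grain-1 plots."""

    level: int
    units: dict[str, tuple[str, ...]] = field(default_factory=dict)
    omitted: dict[str, str] = field(default_factory=dict)


@dataclass(frozen=True)
class GrainLevel:
    level: int
    matrix: AbundanceMatrix
    metadata: pd.DataFrame  # habitat, latitude, longitude (centroid), n_plots
    hierarchy: GrainHierarchy


def _next_level(
    prev: GrainLevel, max_km: float, level: int, override=None
) -> GrainLevel | None:
    pairs_all: list[tuple[str, str]] = []
    omitted: dict[str, str] = {}
    if override is not None:
        pairs_all = [tuple(sorted((str(a), str(b)))) for a, b in override]
        used = {s for p in pairs_all for s in p}
        for s in prev.metadata.index:
            if s not in used:
                omitted[str(s)] = "not referenced by user-supplied pairing"
    else:
        for habitat, sub in prev.metadata.groupby("habitat", sort=True):
            if len(sub) < 2:
                for s in sub.index:
                    omitted[str(s)] = f"fewer than 2 units in habitat {habitat!r}"
                continue
            pairing = pair_samples(pairwise_distance(sub), max_km)
            pairs_all.extend(pairing.pairs)
            omitted.update(dict(pairing.omitted))
    if not pairs_all:
        warnings.warn(
            f"grain {level}: no poolable unit pairs within {max_km} km; "
            "level omitted",
            stacklevel=3,
        )
        return None
    matrix = pool_samples(prev.matrix, pairs_all)
    units: dict[str, tuple[str, ...]] = {}
    meta_rows = []
    for a, b in pairs_all:
        uid = "+".join(sorted((a, b)))
        members = tuple(sorted(prev.hierarchy.units[a] + prev.hierarchy.units[b]))
        units[uid] = members
        ma, mb = prev.metadata.loc[a], prev.metadata.loc[b]
        if ma["habitat"] != mb["habitat"]:
            raise ValidationError(f"pairing crosses habitats: {a!r} with {b!r}")
        meta_rows.append(
            {
                "unit_id": uid,
                "habitat": ma["habitat"],
                "latitude": (float(ma["latitude"]) + float(mb["latitude"])) / 2.0,
                "longitude": (float(ma["longitude"]) + float(mb["longitude"])) / 2.0,
                "n_plots": len(members),
            }
        )
    meta = pd.DataFrame(meta_rows).set_index("unit_id").sort_index()
    return GrainLevel(
        level=level,
        matrix=matrix,
        metadata=meta,
        hierarchy=GrainHierarchy(level=level, units=units, omitted=omitted),
    )


def build_hierarchy(
    matrix: AbundanceMatrix,
    metadata: pd.DataFrame,
    level2_max_km: float = 5.0,
    level3_max_km: float = 45.0,
    pairing_override: dict[int, list] | None = None,
) -> dict[int, GrainLevel]:
    """Build grain levels 1–3 by repeated same-habitat proximity pairing.

    Returns ``{level: GrainLevel}``; a level with no poolable pairs is
    absent (with a warning), mirroring a design where pooling is only
    meaningful when at least one pair can be formed.
    """
    meta = align_metadata(matrix, metadata)
    level1 = GrainLevel(
        level=1,
        matrix=matrix,
        metadata=pd.DataFrame(
            {
                "habitat": meta["habitat"],
                "latitude": meta["latitude"].astype(float),
                "longitude": meta["longitude"].astype(float),
                "n_plots": 1,
            },
            index=meta.index,
        ),
        hierarchy=GrainHierarchy(
            level=1, units={str(s): (str(s),) for s in meta.index}, omitted={}
        ),
    )
    override = pairing_override or {}
    levels = {1: level1}
    level2 = _next_level(level1, level2_max_km, 2, override.get(2))
    if level2 is None:
        return levels
    levels[2] = level2
    level3 = _next_level(level2, level3_max_km, 3, override.get(3))
    if level3 is not None:
        levels[3] = level3
    return levels
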