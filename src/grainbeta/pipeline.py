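"""End-to-end analysis: landscape -> biomass -> grains -> diversity -> inference.

``run_full_analysis`` reproduces the shape of the study's outputs on any
input landscape (loaded from CSV or simulated): a mean-alpha table by
habitat x grain x q, mean between-habitat pairwise similarity by grain x q
with between-grain Z/FDR contrasts, multi-assemblage C_qN and beta by
habitat x grain x q with between-grain and between-habitat Z/FDR
contrasts, an optional singleton-omitted rerun, rank–biomass tables, and
a machine-readable run manifest. Everything is deterministic given the
seed.

Bootstrap schemes follow the grain structure: at grain 1 the units are
single plots, so whole-unit resampling would be degenerate and each plot's
individuals are redrawn from a multinomial at observed depth (converted to
biomass inside the statistic); at grains 2–3 whole units are resampled.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .biomass import conversion_matrix, fit_allometry, model_report, resolve_weights
from .community import (
    AbundanceMatrix,
    FOREST,
    OIL_PALM,
    ValidationError,
    align_metadata,
    read_abundance_table,
    read_sample_metadata,
    read_species_traits,
)
from .diversity import (
    hill_number,
    mean_pairwise_between,
    overlap_profile,
    top_biomass_ranks,
)
from .grains import GrainLevel, build_hierarchy
from .inference import bh_fdr, bootstrap_statistic, z_test


def _rng(seed: int, *key) -> np.random.Generator:
    """Deterministic child generator for a labelled pipeline stage."""
    tail = [zlib.crc32(str(k).encode()) for k in key]
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, *tail])


# ---------------------------------------------------------------------------
# Study summary arithmetic
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StudySummary:
    """Shared/exclusive species arithmetic and per-habitat totals."""

    n_species_oil_palm: int
    n_species_forest: int
    n_shared: int
    n_union: int
    exclusive_pct_oil_palm: float
    exclusive_pct_forest: float
    individuals_oil_palm: float | None = None
    individuals_forest: float | None = None
    biomass_mg_oil_palm: float | None = None
    biomass_mg_forest: float | None = None

    def as_dict(self) -> dict:
        return asdict(self)


def shared_species_summary(
    matrix: AbundanceMatrix,
    metadata: pd.DataFrame,
    biomass: AbundanceMatrix | None = None,
) -> StudySummary:
    """Count per-habitat species, their overlap, and exclusivity percentages."""
    meta = align_metadata(matrix, metadata)
    present: dict[str, set] = {}
    individuals: dict[str, float] = {}
    for habitat in (OIL_PALM, FOREST):
        ids = meta.index[meta["habitat"] == habitat]
        if len(ids) == 0:
            raise ValidationError(f"habitat {habitat!r} absent from the data")
        sub = matrix.data.loc[ids]
        totals = sub.sum(axis=0)
        present[habitat] = set(totals.index[totals > 0])
        individuals[habitat] = float(sub.to_numpy().sum())
    s_op, s_fo = len(present[OIL_PALM]), len(present[FOREST])
    shared = len(present[OIL_PALM] & present[FOREST])
    union = s_op + s_fo - shared
    biomass_tot = {OIL_PALM: None, FOREST: None}
    if biomass is not None:
        bmeta = align_metadata(biomass, metadata)
        for habitat in (OIL_PALM, FOREST):
            ids = bmeta.index[bmeta["habitat"] == habitat]
            biomass_tot[habitat] = float(biomass.data.loc[ids].to_numpy().sum())
    return StudySummary(
        n_species_oil_palm=s_op,
        n_species_forest=s_fo,
        n_shared=shared,
        n_union=union,
        exclusive_pct_oil_palm=round(100.0 * (s_op - shared) / s_op, 1),
        exclusive_pct_forest=round(100.0 * (s_fo - shared) / s_fo, 1),
        individuals_oil_palm=individuals[OIL_PALM],
        individuals_forest=individuals[FOREST],
        biomass_mg_oil_palm=biomass_tot[OIL_PALM],
        biomass_mg_forest=biomass_tot[FOREST],
    )


# ---------------------------------------------------------------------------
# Configuration and report containers
# ---------------------------------------------------------------------------

@dataclass
class AnalysisConfig:
    """Inputs and statistical parameters of one full analysis run."""

    truth: object | None = None  # SyntheticTruth -> simulate; else load paths
    counts_path: str | None = None
    metadata_path: str | None = None
    traits_path: str | None = None
    qs: tuple[float, ...] = (0.0, 1.0, 2.0)
    level2_max_km: float = 5.0
    level3_max_km: float = 45.0
    b_pairwise: int = 500
    b_multi: int = 1000
    alpha: float = 0.05
    singleton_rerun: bool = True
    top_k_ranks: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if any(q < 0 for q in self.qs):
            raise ValidationError("diversity orders q must be >= 0")
        if self.b_pairwise < 2 or self.b_multi < 2:
            raise ValidationError("bootstrap iteration counts must be >= 2")


@dataclass
class AnalysisReport:
    summary: StudySummary
    alpha_table: pd.DataFrame
    pairwise: pd.DataFrame
    pairwise_contrasts: pd.DataFrame
    overlap: pd.DataFrame
    overlap_grain_contrasts: pd.DataFrame
    overlap_habitat_contrasts: pd.DataFrame
    ranks: pd.DataFrame
    allometry: pd.DataFrame
    run_log: dict
    no_singletons: "AnalysisReport | None" = None

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        ff = "%.10g"
        pd.DataFrame([self.summary.as_dict()]).to_csv(
            outdir / "summary.csv", index=False, float_format=ff
        )
        self.alpha_table.to_csv(outdir / "alpha.csv", index=False, float_format=ff)
        self.pairwise.to_csv(outdir / "pairwise.csv", index=False, float_format=ff)
        self.pairwise_contrasts.to_csv(
            outdir / "pairwise_contrasts.csv", index=False, float_format=ff
        )
        self.overlap.to_csv(outdir / "overlap.csv", index=False, float_format=ff)
        self.overlap_grain_contrasts.to_csv(
            outdir / "overlap_grain_contrasts.csv", index=False, float_format=ff
        )
        self.overlap_habitat_contrasts.to_csv(
            outdir / "overlap_habitat_contrasts.csv", index=False, float_format=ff
        )
        self.ranks.to_csv(outdir / "ranks.csv", index=False, float_format=ff)
        self.allometry.to_csv(outdir / "allometry.csv", index=False, float_format=ff)
        (outdir / "run_manifest.json").write_text(
            json.dumps(self.run_log, indent=2, sort_keys=True, default=str)
        )
        if self.no_singletons is not None:
            self.no_singletons.write(outdir / "no_singletons")


# ---------------------------------------------------------------------------
# Helpers
# ---------------------------------------------------------------------------

def strip_habitat_singletons(
    counts: AbundanceMatrix, metadata: pd.DataFrame
) -> tuple[AbundanceMatrix, dict[str, list[str]]]:
    """Zero out, per habitat, species represented by a single individual.

    Singletons are judged within each habitat's dataset, so a species can
    be removed from one habitat's communities while staying in the other's.
    """
    meta = align_metadata(counts, metadata)
    values = counts.values.copy()
    removed: dict[str, list[str]] = {}
    for habitat in sorted(meta["habitat"].unique()):
        rows = np.asarray(meta["habitat"] == habitat)
        totals = values[rows].sum(axis=0)
        single = totals == 1
        removed[habitat] = [
            sp for sp, s in zip(counts.species_ids, single) if s
        ]
        values[np.ix_(rows, single)] = 0
    stripped = AbundanceMatrix(
        pd.DataFrame(values, index=counts.data.index, columns=counts.data.columns),
        "count",
    )
    return stripped, removed


def _grain_counts(counts: AbundanceMatrix, level: GrainLevel) -> AbundanceMatrix:
    """Pool the raw count matrix to the units of an (already built) level."""
    if level.level == 1:
        return counts
    rows = {
        uid: counts.data.loc[list(members)].sum(axis=0)
        for uid, members in level.hierarchy.units.items()
    }
    return AbundanceMatrix(pd.DataFrame(rows).T.sort_index(), "count")


def _alpha_profile(values: np.ndarray, qs) -> np.ndarray:
    rel = values / values.sum(axis=1, keepdims=True)
    return np.array([np.mean([hill_number(r, q) for r in rel]) for q in qs])


def _safe_z(est1, se1, est2, se2, label_a, label_b):
    """Z test tolerating the degenerate zero-SE case (tiny problems)."""
    try:
        t = z_test(est1, se1, est2, se2, label_a=label_a, label_b=label_b)
        return t.difference, t.z, t.p
    except ValidationError:
        return float(est1 - est2), np.nan, np.nan


def _apply_fdr(df: pd.DataFrame, family_cols: list[str], alpha: float) -> pd.DataFrame:
    if df.empty:
        df["p_adj"] = []
        df["significant"] = []
        return df
    df = df.copy()
    df["p_adj"] = np.nan
    df["significant"] = False
    testable = df["p"].notna()
    for _, idx in df[testable].groupby(family_cols).groups.items():
        reject, p_adj = bh_fdr(df.loc[idx, "p"].to_numpy(), alpha)
        df.loc[idx, "p_adj"] = p_adj
        df.loc[idx, "significant"] = reject
    return df


# ---------------------------------------------------------------------------
# The full analysis
# ---------------------------------------------------------------------------

def _variant_tables(
    counts: AbundanceMatrix,
    metadata: pd.DataFrame,
    traits: pd.DataFrame,
    W: np.ndarray,
    species_order: list[str],
    models,
    cfg: AnalysisConfig,
    tag: str,
) -> dict:
    """All diversity/inference tables for one data variant (main or no-singleton)."""
    biomass = AbundanceMatrix(
        pd.DataFrame(counts.values @ W, index=counts.data.index, columns=species_order),
        "biomass",
    )
    levels = build_hierarchy(
        biomass, metadata, cfg.level2_max_km, cfg.level3_max_km
    )
    qs = list(cfg.qs)
    habitats = sorted({OIL_PALM, FOREST} & set(metadata["habitat"]))

    alpha_rows, overlap_rows, ranks_rows = [], [], []
    schemes: dict[int, str] = {}
    for lv, level in sorted(levels.items()):
        lvl_counts = _grain_counts(counts, level)
        for habitat in habitats:
            ids = [
                str(s)
                for s in level.metadata.index[level.metadata["habitat"] == habitat]
            ]
            if len(ids) < 2:
                continue
            sub_bio = biomass.subset_samples(ids) if lv == 1 else level.matrix.subset_samples(ids)
            if lv == 1:
                scheme = "resample_individuals"
                boot_input = lvl_counts.subset_samples(ids).values

                def stat_overlap(v, _W=W):
                    return overlap_profile(v @ _W, qs)

                def stat_alpha(v, _W=W):
                    return _alpha_profile(v @ _W, qs)

            else:
                scheme = "resample_units"
                boot_input = sub_bio.values
                stat_overlap = lambda v: overlap_profile(v, qs)  # noqa: E731
                stat_alpha = lambda v: _alpha_profile(v, qs)  # noqa: E731
            schemes[lv] = scheme

            res_a = bootstrap_statistic(
                boot_input,
                stat_alpha,
                b=cfg.b_multi,
                rng=_rng(cfg.seed, tag, "alpha", lv, habitat),
                scheme=scheme,
            )
            res_c = bootstrap_statistic(
                boot_input,
                stat_overlap,
                b=cfg.b_multi,
                rng=_rng(cfg.seed, tag, "overlap", lv, habitat),
                scheme=scheme,
            )
            est_a = np.atleast_1d(res_a.estimate)
            se_a = np.atleast_1d(res_a.se)
            est_c = np.atleast_1d(res_c.estimate)
            se_c = np.atleast_1d(res_c.se)
            for k, q in enumerate(qs):
                alpha_rows.append(
                    {
                        "habitat": habitat,
                        "grain": lv,
                        "q": q,
                        "n_units": len(ids),
                        "mean_alpha": est_a[k],
                        "se": se_a[k],
                    }
                )
                overlap_rows.append(
                    {
                        "habitat": habitat,
                        "grain": lv,
                        "q": q,
                        "n_units": len(ids),
                        "cqn": est_c[k],
                        "beta": 1.0 - est_c[k],
                        "se": se_c[k],
                        "scheme": scheme,
                    }
                )
            rk = top_biomass_ranks(sub_bio, cfg.top_k_ranks)
            rk.insert(0, "habitat", habitat)
            rk.insert(1, "grain", lv)
            ranks_rows.append(rk)

    alpha_table = pd.DataFrame(alpha_rows)
    overlap = pd.DataFrame(overlap_rows)
    ranks = (
        pd.concat(ranks_rows, ignore_index=True) if ranks_rows else pd.DataFrame()
    )

    # between-habitat mean pairwise similarity per grain and q
    pairwise_rows = []
    for lv, level in sorted(levels.items()):
        hab_series = level.metadata["habitat"]
        if {OIL_PALM, FOREST} - set(hab_series):
            continue
        mat = biomass if lv == 1 else level.matrix
        for q in qs:
            res = mean_pairwise_between(
                mat,
                hab_series,
                q,
                b=cfg.b_pairwise,
                rng=_rng(cfg.seed, tag, "pairwise", lv, q),
                grain=lv,
            )
            pairwise_rows.append(
                {
                    "grain": lv,
                    "q": q,
                    "n_pairs": res.n_pairs,
                    "mean_similarity": res.mean,
                    "se": res.se,
                }
            )
    pairwise = pd.DataFrame(pairwise_rows)

    # contrasts: between grains (families = fixed q [and habitat]), BH-FDR
    def grain_pairs(grains):
        grains = sorted(grains)
        return [(a, b) for i, a in enumerate(grains) for b in grains[i + 1 :]]

    pw_rows = []
    if not pairwise.empty:
        for q in qs:
            sub = pairwise[pairwise["q"] == q].set_index("grain")
            for a, b in grain_pairs(sub.index):
                diff, z, p = _safe_z(
                    sub.loc[a, "mean_similarity"],
                    sub.loc[a, "se"],
                    sub.loc[b, "mean_similarity"],
                    sub.loc[b, "se"],
                    f"grain{a}",
                    f"grain{b}",
                )
                pw_rows.append(
                    {
                        "q": q,
                        "contrast": f"grain{a}_vs_grain{b}",
                        "difference": diff,
                        "z": z,
                        "p": p,
                    }
                )
    pairwise_contrasts = _apply_fdr(pd.DataFrame(pw_rows), ["q"], cfg.alpha)

    og_rows = []
    for habitat in habitats:
        for q in qs:
            sub = overlap[(overlap["habitat"] == habitat) & (overlap["q"] == q)]
            sub = sub.set_index("grain")
            for a, b in grain_pairs(sub.index):
                diff, z, p = _safe_z(
                    sub.loc[a, "beta"],
                    sub.loc[a, "se"],
                    sub.loc[b, "beta"],
                    sub.loc[b, "se"],
                    f"grain{a}",
                    f"grain{b}",
                )
                og_rows.append(
                    {
                        "habitat": habitat,
                        "q": q,
                        "contrast": f"grain{a}_vs_grain{b}",
                        "difference": diff,
                        "z": z,
                        "p": p,
                    }
                )
    overlap_grain_contrasts = _apply_fdr(
        pd.DataFrame(og_rows), ["habitat", "q"], cfg.alpha
    )

    oh_rows = []
    if len(habitats) == 2:
        for q in qs:
            sub = overlap[overlap["q"] == q]
            for lv in sorted(sub["grain"].unique()):
                by_hab = sub[sub["grain"] == lv].set_index("habitat")
                if {OIL_PALM, FOREST} - set(by_hab.index):
                    continue
                diff, z, p = _safe_z(
                    by_hab.loc[OIL_PALM, "beta"],
                    by_hab.loc[OIL_PALM, "se"],
                    by_hab.loc[FOREST, "beta"],
                    by_hab.loc[FOREST, "se"],
                    OIL_PALM,
                    FOREST,
                )
                oh_rows.append(
                    {
                        "q": q,
                        "grain": lv,
                        "contrast": f"{OIL_PALM}_vs_{FOREST}",
                        "difference": diff,
                        "z": z,
                        "p": p,
                    }
                )
    overlap_habitat_contrasts = _apply_fdr(pd.DataFrame(oh_rows), ["q"], cfg.alpha)

    omissions = {
        str(lv): dict(level.hierarchy.omitted) for lv, level in sorted(levels.items())
    }
    return {
        "alpha_table": alpha_table,
        "pairwise": pairwise,
        "pairwise_contrasts": pairwise_contrasts,
        "overlap": overlap,
        "overlap_grain_contrasts": overlap_grain_contrasts,
        "overlap_habitat_contrasts": overlap_habitat_contrasts,
        "ranks": ranks,
        "biomass": biomass,
        "schemes": {str(k): v for k, v in sorted(schemes.items())},
        "omissions": omissions,
        "unit_counts": {
            str(lv): dict(level.metadata.groupby("habitat").size())
            for lv, level in sorted(levels.items())
        },
    }


def run_full_analysis(config: AnalysisConfig):
    """Execute the complete pipeline and return an :class:`AnalysisReport`."""
    from .synthetic import SyntheticTruth, generate_landscape

    if config.truth is not None:
        truth = config.truth
        if not isinstance(truth, SyntheticTruth):
            raise ValidationError("config.truth must be a SyntheticTruth")
        if truth.seed != config.seed:
            truth = SyntheticTruth(**{**asdict(truth), "seed": config.seed})
        landscape = generate_landscape(truth)
        counts, metadata, traits = (
            landscape.matrix,
            landscape.metadata,
            landscape.traits,
        )
    else:
        if not (config.counts_path and config.metadata_path and config.traits_path):
            raise ValidationError(
                "either config.truth or all three input paths must be given"
            )
        counts = read_abundance_table(config.counts_path, "count")
        metadata = read_sample_metadata(config.metadata_path)
        traits = read_species_traits(config.traits_path)
    metadata = align_metadata(counts, metadata)

    models = fit_allometry(traits, strict=False)
    weights = resolve_weights(traits, models)
    W, species_order = conversion_matrix(counts.species_ids, weights)

    main = _variant_tables(
        counts, metadata, traits, W, species_order, models, config, "main"
    )
    summary = shared_species_summary(counts, metadata, biomass=main["biomass"])

    no_singletons = None
    removed: dict[str, list[str]] = {}
    if config.singleton_rerun:
        stripped, removed = strip_habitat_singletons(counts, metadata)
        sub = _variant_tables(
            stripped, metadata, traits, W, species_order, models, config, "nosingle"
        )
        no_singletons = AnalysisReport(
            summary=shared_species_summary(stripped, metadata, biomass=sub["biomass"]),
            alpha_table=sub["alpha_table"],
            pairwise=sub["pairwise"],
            pairwise_contrasts=sub["pairwise_contrasts"],
            overlap=sub["overlap"],
            overlap_grain_contrasts=sub["overlap_grain_contrasts"],
            overlap_habitat_contrasts=sub["overlap_habitat_contrasts"],
            ranks=sub["ranks"],
            allometry=model_report(models),
            run_log={"variant": "singletons omitted per habitat"},
        )

    run_log = {
        "grainbeta_version": __version__,
        "seed": config.seed,
        "qs": list(config.qs),
        "level2_max_km": config.level2_max_km,
        "level3_max_km": config.level3_max_km,
        "b_pairwise": config.b_pairwise,
        "b_multi": config.b_multi,
        "alpha": config.alpha,
        "bootstrap_scheme_by_grain": main["schemes"],
        "omitted_units_by_grain": main["omissions"],
        "unit_counts_by_grain": main["unit_counts"],
        "grand_total_individuals": float(counts.values.sum()),
        "grand_total_biomass_mg": float(main["biomass"].values.sum()),
        "singletons_removed_per_habitat": {
            k: len(v) for k, v in sorted(removed.items())
        },
        "simulated": config.truth is not None,
    }
    return AnalysisReport(
        summary=summary,
        alpha_table=main["alpha_table"],
        pairwise=main["pairwise"],
        pairwise_contrasts=main["pairwise_contrasts"],
        overlap=main["overlap"],
        overlap_grain_contrasts=main["overlap_grain_contrasts"],
        overlap_habitat_contrasts=main["overlap_habitat_contrasts"],
        ranks=main["ranks"],
        allometry=model_report(models),
        run_log=run_log,
        no_singletons=no_singletons,
    )
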