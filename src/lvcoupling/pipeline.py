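"""End-to-end orchestration: indices -> windowed LV fits -> ranks -> Moran.

The driver consumes a long-format indicator panel plus a spatial structure
(edge list and region membership), fits the coupled Lotka-Volterra system
per entity, window, and pollution type, classifies ranks, and measures the
spatial autocorrelation of the numerically coded ranks under both a
contiguity and a region-block weight matrix.  Entities whose LV fit is
degenerate are excluded from the spatial stage (with the exclusion logged
and reflected in n), or abort the run in strict mode.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import coupling_rank, indices, lv_model, spatial
from .errors import (
    ConfigurationError,
    DuplicateKeyError,
    LVCouplingError,
    LabelError,
    ParseError,
)

logger = logging.getLogger(__name__)

POLLUTION_TYPES = ("industrial", "domestic")


@dataclass
class AnalysisConfig:
    """Run-wide settings; defaults mirror the published design."""

    windows: tuple[tuple[int, int], ...] = ((2011, 2015), (2016, 2020))
    industrial_weights: tuple[float, ...] | None = None
    domestic_weights: tuple[float, ...] | None = None
    goalposts: indices.Goalposts = field(default_factory=indices.Goalposts)
    convention: str = "consistent"
    rank_coding: dict[str, float] = field(
        default_factory=lambda: dict(spatial.DEFAULT_RANK_CODING))
    weights_scheme: str = "row_standardized"
    extra_links: tuple[tuple[str, str], ...] = ()
    n_permutations: int = 999
    significance: float = 0.1
    pooling_scope: str = "window"
    seed: int = 0
    strict: bool = False

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise ConfigurationError("n_permutations must be >= 1")
        if not (0 < self.significance < 1):
            raise ConfigurationError("significance must be in (0, 1)")
        spans = sorted(self.windows)
        for (a1, b1), (a2, b2) in zip(spans, spans[1:]):
            if a2 <= b1:
                raise ConfigurationError("windows must not overlap")

    @classmethod
    def from_dict(cls, doc: Mapping) -> "AnalysisConfig":
        doc = dict(doc)
        if "windows" in doc:
            doc["windows"] = tuple(tuple(w) for w in doc["windows"])
        if "extra_links" in doc:
            doc["extra_links"] = tuple(tuple(e) for e in doc["extra_links"])
        if "goalposts" in doc:
            doc["goalposts"] = indices.Goalposts(**doc["goalposts"])
        for key in ("industrial_weights", "domestic_weights"):
            if doc.get(key) is not None:
                doc[key] = tuple(doc[key])
        unknown = set(doc) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**doc)


@dataclass
class ResultsBundle:
    """All output tables of one run."""

    hdi: pd.DataFrame
    hdi_shares: pd.DataFrame
    effectiveness: pd.DataFrame        # columns entity, year, series, value
    lv_fits: pd.DataFrame
    assessments: pd.DataFrame
    quadrant_table: pd.DataFrame
    rank_table: pd.DataFrame
    global_moran: pd.DataFrame
    lisa: pd.DataFrame
    exclusions: pd.DataFrame
    manifest: dict


def read_indicator_panel(path: str | Path) -> pd.DataFrame:
    """Read and validate a long-format indicator CSV.

    Required columns: entity, year, indicator, value; year and value must
    be numeric and no (entity, year, indicator) key may repeat.
    """
    path = Path(path)
    try:
        panel = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise ParseError(f"{path}: empty file") from exc
    required = ["entity", "year", "indicator", "value"]
    missing = [c for c in required if c not in panel.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    for col in ("year", "value"):
        coerced = pd.to_numeric(panel[col], errors="coerce")
        bad = panel.index[coerced.isna() & panel[col].notna()]
        if len(bad) or panel[col].isna().any():
            line = int((bad if len(bad) else panel.index[panel[col].isna()])[0]) + 2
            raise ParseError(f"{path}: non-numeric {col} at line {line}")
        panel[col] = coerced
    panel["year"] = panel["year"].astype(int)
    dupes = panel.duplicated(subset=["entity", "year", "indicator"])
    if dupes.any():
        key = panel.loc[dupes.idxmax(), ["entity", "year", "indicator"]]
        raise DuplicateKeyError(
            f"duplicate key {tuple(key)} in {path}"
        )
    return panel[required]


def _window_years(window: tuple[int, int]) -> list[int]:
    return list(range(window[0], window[1] + 1))


def _window_tag(window: tuple[int, int]) -> str:
    return f"{window[0]}-{window[1]}"


def run_analysis(panel: pd.DataFrame,
                 edges: Sequence[tuple[str, str]],
                 region_of: Mapping[str, str],
                 config: AnalysisConfig | None = None) -> ResultsBundle:
    """Execute the full pipeline on one panel and spatial structure."""
    config = config or AnalysisConfig()
    all_years = sorted({y for w in config.windows for y in _window_years(w)})
    panel_years = set(panel["year"].unique())
    uncovered = [y for y in all_years if y not in panel_years]
    if uncovered:
        raise ConfigurationError(f"panel does not cover window years {uncovered}")
    entities = sorted(panel["entity"].unique())
    missing_region = [e for e in entities if e not in region_of]
    if missing_region:
        raise LabelError(f"entities without a region: {missing_region}")

    # --- indices ------------------------------------------------------
    hdi = indices.compute_hdi_panel(panel, config.goalposts, all_years)
    shares = indices.hdi_share_panel(hdi)
    merged = indices.apply_vehicle_merge(panel)
    baskets = {
        "industrial": (indices.INDUSTRIAL_INDICATORS, config.industrial_weights),
        "domestic": (indices.DOMESTIC_INDICATORS, config.domestic_weights),
    }
    eff: dict[tuple[str, tuple[int, int]], pd.DataFrame] = {}
    for ptype, (inds, weights) in baskets.items():
        if config.pooling_scope == "full-period":
            full = indices.effectiveness_panel(
                merged, inds, weights, all_years, config.pooling_scope)
            for window in config.windows:
                eff[(ptype, window)] = full.loc[_window_years(window)]
        else:
            for window in config.windows:
                eff[(ptype, window)] = indices.effectiveness_panel(
                    merged, inds, weights, _window_years(window),
                    config.pooling_scope)

    # --- LV fits and coupling assessments -----------------------------
    fit_rows, assess_rows, exclusion_rows = [], [], []
    for ptype in POLLUTION_TYPES:
        for window in config.windows:
            years = _window_years(window)
            for e in entities:
                try:
                    series = lv_model.CoupledSeries(
                        entity=e, window=window,
                        pollution=tuple(eff[(ptype, window)].loc[years, e]),
                        hdi_share=tuple(shares.loc[years, e]),
                    )
                    fit = lv_model.fit_lv_system(series, config.convention)
                    a = coupling_rank.assess(e, window, ptype, fit)
                except LVCouplingError as exc:
                    if config.strict:
                        raise
                    logger.warning("excluding %s %s %s: %s",
                                   e, _window_tag(window), ptype, exc)
                    exclusion_rows.append(
                        (e, _window_tag(window), ptype,
                         type(exc).__name__, str(exc)))
                    continue
                fit_rows.append((
                    e, _window_tag(window), ptype,
                    fit.a_i, fit.b_i, fit.c_i, fit.a_h, fit.b_h, fit.c_h,
                    fit.r_i, fit.r_h, fit.k_i, fit.k_h, fit.alpha, fit.beta,
                    fit.convention, *fit.residual_norms,
                ))
                assess_rows.append((
                    e, _window_tag(window), ptype, a.s_on_pollution,
                    a.s_on_hdi, a.s1, a.rank, a.quadrant,
                ))
    lv_fits = pd.DataFrame(fit_rows, columns=[
        "entity", "window", "pollution_type",
        "a_i", "b_i", "c_i", "a_h", "b_h", "c_h",
        "r_i", "r_h", "k_i", "k_h", "alpha", "beta",
        "convention", "resid_i", "resid_h",
    ])
    assessments = pd.DataFrame(assess_rows, columns=[
        "entity", "window", "pollution_type",
        "s_on_pollution", "s_on_hdi", "s1", "rank", "quadrant",
    ])
    exclusions = pd.DataFrame(exclusion_rows, columns=[
        "entity", "window", "pollution_type", "error", "message"])

    quadrant_table = assessments[
        ["entity", "window", "pollution_type", "quadrant"]].copy()
    rank_table = assessments[
        ["entity", "window", "pollution_type", "rank"]].copy()

    # --- spatial statistics -------------------------------------------
    queen_w = spatial.build_weights(
        edges, entities, config.extra_links, config.weights_scheme,
        strict=config.strict)
    block_w = spatial.region_block_weights(
        region_of, entities, config.weights_scheme)
    variants = {"contiguity": queen_w, "region_block": block_w}

    moran_rows, lisa_rows = [], []
    combo = 0
    for ptype in POLLUTION_TYPES:
        for window in config.windows:
            tag = _window_tag(window)
            sub = assessments[
                (assessments["pollution_type"] == ptype)
                & (assessments["window"] == tag)
            ].set_index("entity")
            kept = [e for e in entities if e in sub.index]
            if len(kept) < 2:
                logger.warning("skipping Moran for %s %s: <2 entities", ptype, tag)
                continue
            values = spatial.encode_ranks(
                [sub.loc[e, "rank"] for e in kept], config.rank_coding)
            for vname, w_full in variants.items():
                combo += 1
                seed = (config.seed * 7919 + combo) % (2**31)
                w = w_full.subset(kept) if len(kept) < len(entities) else w_full
                try:
                    g = spatial.permutation_test_global(
                        values, w, config.n_permutations, seed)
                    lisa = spatial.local_moran(
                        values, w, config.n_permutations, seed)
                except LVCouplingError as exc:
                    if config.strict:
                        raise
                    logger.warning("Moran failed for %s %s %s: %s",
                                   ptype, tag, vname, exc)
                    continue
                cats = spatial.classify_clusters(
                    values, w, lisa, config.significance)
                moran_rows.append((vname, tag, ptype, g.observed_i,
                                   g.expected_i, g.pseudo_p, g.p_two_sided,
                                   g.n_permutations, g.n, seed))
                for i, e in enumerate(kept):
                    lisa_rows.append((vname, tag, ptype, e,
                                      lisa.local_i[i], lisa.pseudo_p[i],
                                      cats[i]))
    global_moran = pd.DataFrame(moran_rows, columns=[
        "weights_variant", "window", "pollution_type", "moran_i",
        "expected_i", "pseudo_p", "p_two_sided", "n_permutations", "n",
        "seed"])
    lisa_df = pd.DataFrame(lisa_rows, columns=[
        "weights_variant", "window", "pollution_type", "entity",
        "local_i", "pseudo_p", "category"])

    manifest = {
        "config": _config_to_dict(config),
        "n_entities": len(entities),
        "n_excluded": len(exclusions),
        "versions": _versions(),
    }
    hdi_long = hdi.reset_index().melt(
        id_vars="year", var_name="entity", value_name="value")
    hdi_long["series"] = "hdi"
    shares_long = shares.reset_index().melt(
        id_vars="year", var_name="entity", value_name="value")
    shares_long["series"] = "hdi_share"
    eff_rows = []
    for (ptype, window), frame in eff.items():
        long = frame.reset_index().melt(
            id_vars="year", var_name="entity", value_name="value")
        long["series"] = f"effectiveness_{ptype}_{_window_tag(window)}"
        eff_rows.append(long)
    effectiveness = pd.concat(eff_rows, ignore_index=True)[
        ["entity", "year", "series", "value"]]

    return ResultsBundle(
        hdi=hdi_long[["entity", "year", "series", "value"]],
        hdi_shares=shares_long[["entity", "year", "series", "value"]],
        effectiveness=effectiveness,
        lv_fits=lv_fits,
        assessments=assessments,
        quadrant_table=quadrant_table,
        rank_table=rank_table,
        global_moran=global_moran,
        lisa=lisa_df,
        exclusions=exclusions,
        manifest=manifest,
    )


def _config_to_dict(config: AnalysisConfig) -> dict:
    doc = dataclasses.asdict(config)
    doc["goalposts"] = dataclasses.asdict(config.goalposts)
    return doc


def _versions() -> dict[str, str]:
    import scipy

    from . import __version__
    return {
        "lvcoupling": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scipy": scipy.__version__,
    }


def write_results(bundle: ResultsBundle, out_dir: str | Path) -> list[Path]:
    """Write every table of a bundle to CSV plus a JSON manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for name in ("hdi", "hdi_shares", "effectiveness", "lv_fits",
                 "assessments", "quadrant_table", "rank_table",
                 "global_moran", "lisa", "exclusions"):
        path = out / f"{name}.csv"
        getattr(bundle, name).to_csv(path, index=False, float_format="%.12g")
        written.append(path)
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(bundle.manifest, indent=2, sort_keys=True))
    written.append(manifest_path)
    return written
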