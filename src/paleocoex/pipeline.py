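"""End-to-end orchestration: synthetic or fixture-driven runs.

The pipeline mirrors the analysis chain: quality-filter and attribute the
chronometric dates (both filtering tiers by default), calibrate them,
estimate each region's NAI end and SAI start with the Bayesian phase model
and with OLE, optionally build KDE overlap surfaces, delimit biogeographic
regions, estimate herbivore carrying capacity per region, compute NAI/SAI
temporal overlaps, and run the spatially filtered correlation tests with
CI resampling.  Every artifact records the configuration hash and seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .biogeography import DcortConfig, cluster_npp, delimit_regions, dissimilarity_matrix, jaccard_dissimilarity
from .carrying_capacity import CCParams, HerbivoreSpecies, PCOM, estimate_cc
from .chronology import (
    BAMSettings,
    CalibrationCurve,
    KDEConfig,
    OLEConfig,
    PhaseEstimate,
    calibrate,
    fit_bam,
    filter_dates,
    kde_overlap,
    run_ole,
)
from .coexistence import BoundaryEstimate, temporal_overlap
from .npp import NPPSeries
from .spatial import ESFConfig, build_weights, moran_eigenvectors, resample_correlation
from .synthetic import WorldConfig, WorldData, generate_world

__all__ = [
    "PipelineConfig",
    "RunResult",
    "run_pipeline",
    "make_report",
    "estimate_region_chronology",
    "classify_percentile",
]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    world: WorldConfig | None = None
    input_dir: str | None = None
    criteria: tuple[str, ...] = ("fc1", "fc2")
    attribution_toggles: dict = field(default_factory=dict)
    bam: BAMSettings = field(default_factory=BAMSettings)
    ole: OLEConfig | None = field(default_factory=OLEConfig)
    kde: KDEConfig | None = None          # None skips the raster stage
    cc: CCParams = field(default_factory=CCParams)
    esf: ESFConfig = field(default_factory=ESFConfig)
    dcort: DcortConfig = field(default_factory=DcortConfig)
    grid_step_ka: float = 0.01
    resample_factor: float = 1.0           # global scale-down of resample counts
    region_mode: str = "given"             # 'given' | 'delimit'
    esf_pairs: tuple = (("overlap", "cc_medium"),)
    outdir: str | None = None
    seed: int = 0

    def config_hash(self) -> str:
        blob = _as_jsonable(self)
        blob.pop("outdir", None)  # hash the analysis settings, not the destination
        return hashlib.sha256(
            json.dumps(blob, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


def _as_jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _as_jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, (list, tuple)):
        return [_as_jsonable(v) for v in obj]
    if isinstance(obj, dict):
        return {str(k): _as_jsonable(v) for k, v in obj.items()}
    return obj


@dataclass
class RunResult:
    config: PipelineConfig
    world: WorldData | None
    chronology: dict[str, pd.DataFrame]    # per criteria tier
    overlaps: dict[str, pd.DataFrame]
    cc_table: pd.DataFrame
    region_metrics: pd.DataFrame
    esf_results: dict[str, dict]
    regions_delimited: pd.Series | None = None
    kde: object | None = None
    provenance: dict = field(default_factory=dict)


def classify_percentile(values: pd.Series) -> pd.Series:
    """L / M / H classification by inclusive quartiles; boundary ties go M."""
    v = values.astype(float)
    q1, q3 = np.percentile(v, [25, 75])
    out = pd.Series("M", index=v.index)
    out[v < q1] = "L"
    out[v > q3] = "H"
    return out


def estimate_region_chronology(
    dates: pd.DataFrame,
    curve: CalibrationCurve,
    window: tuple[float, float],
    bam: BAMSettings,
    ole: OLEConfig | None = None,
    grid_step_ka: float = 0.01,
    criteria: str = "fc1",
) -> pd.DataFrame:
    """NAI-end and SAI-start estimates per region (BAM, optionally OLE).

    ``dates`` must already be filtered/attributed (``species_class`` and
    ``region`` columns) with ages in ka.  Returns one row per region with
    phase modes, HPD bounds and, when enough dates exist, OLE endpoints.
    """
    rows = []
    for region, sub in dates.groupby("region"):
        row: dict = {"region": region}
        for cls, boundary in (("NAI", "end"), ("SAI", "start")):
            grp = sub[sub["species_class"] == cls]
            prefix = "nai" if cls == "NAI" else "sai"
            if grp.empty:
                row[f"{prefix}_n"] = 0
                continue
            dens = [
                calibrate(
                    r.age, r.error, curve, method=r.method,
                    grid_step_ka=grid_step_ka, units="ka", label=str(r.level),
                )
                for r in grp.itertuples()
            ]
            fit = fit_bam(dens, window=window, settings=bam, criteria=criteria)
            est: PhaseEstimate = getattr(fit, boundary)
            row[f"{prefix}_n"] = len(dens)
            row[f"{prefix}_mode"] = est.mode
            row[f"{prefix}_hpd68_young"] = est.hpd68_young
            row[f"{prefix}_hpd68_old"] = est.hpd68_old
            row[f"{prefix}_hpd95_young"] = est.hpd95_young
            row[f"{prefix}_hpd95_old"] = est.hpd95_old
            row[f"{prefix}_rhat"] = fit.rhat[boundary]
            if ole is not None and len(dens) >= ole.min_dates:
                meds = np.array([d.mean() for d in dens])
                sds = np.array([d.sd() for d in dens])
                cfg = dataclasses.replace(
                    ole,
                    k=min(ole.k, len(dens)) if len(dens) >= 5 else ole.k,
                    direction="last-appearance" if cls == "NAI" else "first-appearance",
                )
                res = run_ole(meds, sds, cfg)
                row[f"{prefix}_ole"] = res.estimate
                row[f"{prefix}_ole_low"] = res.ci_low
                row[f"{prefix}_ole_high"] = res.ci_high
        rows.append(row)
    return pd.DataFrame(rows).set_index("region")


def _boundary(row: pd.Series, prefix: str) -> BoundaryEstimate | None:
    if f"{prefix}_mode" not in row or pd.isna(row.get(f"{prefix}_mode", np.nan)):
        return None
    return BoundaryEstimate(
        mode=row[f"{prefix}_mode"],
        hpd68=(row[f"{prefix}_hpd68_young"], row[f"{prefix}_hpd68_old"]),
        hpd95=(row[f"{prefix}_hpd95_young"], row[f"{prefix}_hpd95_old"]),
    )


def overlaps_from_chronology(chron: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for region, row in chron.iterrows():
        res = temporal_overlap(_boundary(row, "nai"), _boundary(row, "sai"), region)
        if res is None:
            rows.append({"region": region, "minimal_ka": np.nan, "central_ka": np.nan,
                         "maximal_ka": np.nan, "coexistence": None})
            continue
        maximal = row["sai_hpd95_old"] - row["nai_hpd95_young"]
        rows.append(
            {
                "region": region,
                "minimal_ka": res.minimal_ka,
                "central_ka": res.central_ka,
                "maximal_ka": float(maximal),
                "coexistence": res.coexistence,
            }
        )
    return pd.DataFrame(rows).set_index("region")


def run_pipeline(config: PipelineConfig) -> RunResult:
    """Execute the full chain on a synthetic world or on loaded inputs."""
    if config.world is None and config.input_dir is None:
        raise ValueError("config needs either a synthetic WorldConfig or input_dir")
    stage = "generate"
    try:
        if config.world is not None:
            world = generate_world(config.world)
        else:
            world = _load_world(config.input_dir)
        window = world.config.window
        curve = world.curve

        # --- biogeographic region delimitation (reported; analysis units
        # follow config.region_mode) ---
        stage = "regions"
        regions_delimited = None
        if config.region_mode == "delimit" or config.world is not None:
            mat = dissimilarity_matrix(world.npp, config.dcort)
            npp_labels = cluster_npp(mat)
            guilds = {
                rid: set(inc.columns[(inc.sum(axis=0) > 0)])
                for rid, inc in world.fauna.items()
            }
            ids = sorted(guilds)
            jmat = pd.DataFrame(
                [[jaccard_dissimilarity(guilds[a], guilds[b]) for b in ids] for a in ids],
                index=ids, columns=ids,
            )
            fauna_labels = cluster_npp(jmat)
            climate = pd.Series("Dfc", index=npp_labels.index)
            lons = world.regions["longitude"]
            regions_delimited, _ = delimit_regions(
                npp_labels, climate.loc[npp_labels.index],
                fauna_labels.loc[npp_labels.index], lons.loc[npp_labels.index],
            )

        # --- filtering + calibration + phase models, per criteria tier ---
        chronology: dict[str, pd.DataFrame] = {}
        overlaps: dict[str, pd.DataFrame] = {}
        for tier in config.criteria:
            stage = f"chronology[{tier}]"
            filtered = filter_dates(world.dates, tier, config.attribution_toggles)
            analysed = filtered[filtered["species_class"].isin(["NAI", "SAI"])]
            if config.region_mode == "delimit" and regions_delimited is not None:
                analysed = analysed.copy()
                analysed["region"] = analysed["region"].map(regions_delimited)
            chron = estimate_region_chronology(
                analysed, curve, window, config.bam, config.ole,
                config.grid_step_ka, criteria=tier,
            )
            chronology[tier] = chron
            overlaps[tier] = overlaps_from_chronology(chron)

        # --- KDE surfaces (optional) ---
        stage = "kde"
        kde = None
        if config.kde is not None:
            tier = config.criteria[0]
            filtered = filter_dates(world.dates, tier, config.attribution_toggles)
            analysed = filtered[filtered["species_class"].isin(["NAI", "SAI"])]
            dens = [
                calibrate(r.age, r.error, curve, method=r.method,
                          grid_step_ka=config.grid_step_ka, units="ka")
                for r in analysed.itertuples()
            ]
            kde = kde_overlap(
                analysed["latitude"], analysed["longitude"],
                analysed["species_class"], dens, config.kde,
            )

        # --- carrying capacity per region ---
        stage = "carrying_capacity"
        masses = world.species_pool.set_index("species")["mass_kg"]
        cc_rows = []
        for rid in world.regions.index:
            inc = world.fauna[rid]
            present = [c for c in inc.columns if inc[c].sum() > 0]
            if not present:
                logger.warning("region %s has no observed fauna; CC skipped", rid)
                continue
            pcom = PCOM(rid, [HerbivoreSpecies(s, float(masses[s])) for s in present])
            est = estimate_cc(world.npp[rid], pcom, config.cc)
            row = {"region": rid}
            for cls in ("small", "medium", "large"):
                row[f"cc_{cls}"] = est.size_classes.loc[cls, "mean"]
                row[f"cc_{cls}_ll"] = est.size_classes.loc[cls, "ll"]
                row[f"cc_{cls}_ul"] = est.size_classes.loc[cls, "ul"]
            cc_rows.append(row)
        cc_table = pd.DataFrame(cc_rows).set_index("region")

        # --- region metric table ---
        stage = "metrics"
        metr = cc_table.copy()
        metr["npp_mean"] = [world.npp[r].mean() for r in metr.index]
        metr["npp_cv"] = [world.npp[r].cv_percent() for r in metr.index]
        nsteps = next(iter(world.npp.values())).values.size
        metr["npp_se"] = [world.npp[r].sd() / np.sqrt(nsteps) for r in metr.index]

        # --- ESF correlation tests with CI resampling ---
        stage = "esf"
        tier = config.criteria[0]
        ov = overlaps[tier].dropna(subset=["minimal_ka"])
        dropped = set(overlaps[tier].index) - set(ov.index)
        if dropped:
            logger.info("regions without SAI dropped from overlap regression: %s",
                        sorted(dropped))
        esf_results: dict[str, dict] = {}
        common = ov.index.intersection(metr.index)
        if len(common) >= 5:
            w = build_weights(
                world.regions.loc[common, "latitude"],
                world.regions.loc[common, "longitude"],
                ids=list(common),
            )
            eig = moran_eigenvectors(w, config.esf)
            n_res = max(1, int(config.esf.n_resamples * config.resample_factor))
            esf_cfg = dataclasses.replace(config.esf, n_resamples=n_res)
            chron = chronology[tier]
            y_tables = {
                "overlap": pd.DataFrame(
                    {
                        "estimate": ov.loc[common, "central_ka"],
                        "ci_low": ov.loc[common, "minimal_ka"],
                        "ci_high": ov.loc[common, "maximal_ka"],
                    }
                ),
                "nai_end": pd.DataFrame(
                    {
                        "estimate": chron.loc[common, "nai_mode"],
                        "ci_low": chron.loc[common, "nai_hpd95_young"],
                        "ci_high": chron.loc[common, "nai_hpd95_old"],
                    }
                ),
                "sai_start": pd.DataFrame(
                    {
                        "estimate": chron.loc[common, "sai_mode"],
                        "ci_low": chron.loc[common, "sai_hpd95_young"],
                        "ci_high": chron.loc[common, "sai_hpd95_old"],
                    }
                ),
            }

            def x_table(col):
                if col == "npp_mean":
                    se = metr.loc[common, "npp_se"]
                    est = metr.loc[common, "npp_mean"]
                    return pd.DataFrame(
                        {"estimate": est, "ci_low": est - 1.96 * se,
                         "ci_high": est + 1.96 * se}
                    )
                return pd.DataFrame(
                    {
                        "estimate": metr.loc[common, col],
                        "ci_low": metr.loc[common, f"{col}_ll"],
                        "ci_high": metr.loc[common, f"{col}_ul"],
                    }
                )

            for y_name, x_name in config.esf_pairs:
                if y_name not in y_tables:
                    continue
                res = resample_correlation(
                    y_tables[y_name], x_table(x_name), eig, w, esf_cfg
                )
                esf_results[f"{y_name}~{x_name}"] = res.summary() | {
                    "n_regions": int(len(common))
                }
        else:
            logger.warning("too few regions with overlap values for ESF stage")

        provenance = {
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "n_dates": int(len(world.dates)),
            "n_regions": int(len(world.regions)),
        }
        result = RunResult(
            config=config,
            world=world,
            chronology=chronology,
            overlaps=overlaps,
            cc_table=cc_table,
            region_metrics=metr,
            esf_results=esf_results,
            regions_delimited=regions_delimited,
            kde=kde,
            provenance=provenance,
        )
        if config.outdir:
            _write_artifacts(result, Path(config.outdir))
        return result
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc


def _load_world(input_dir) -> WorldData:
    """Rehydrate a written world directory (see WorldData.write)."""
    from .npp import read_npp_table

    p = Path(input_dir)
    manifest = json.loads((p / "manifest.json").read_text())
    cfg_raw = dict(manifest["config"])
    cfg_raw["window"] = tuple(cfg_raw["window"])
    config = WorldConfig(**cfg_raw)
    dates = pd.read_csv(p / "dates.csv")
    npp = read_npp_table(p / "npp_regions.csv")
    sites = pd.read_csv(p / "sites.csv").set_index("site")
    pool = pd.read_csv(p / "species_pool.csv")
    modern = pd.read_csv(p / "modern_densities.csv")
    fauna = {
        rid: pd.read_csv(p / f"fauna_{rid}.csv", index_col=0) for rid in npp
        if (p / f"fauna_{rid}.csv").exists()
    }
    curve = CalibrationCurve.from_file(p / "toy_curve.csv")
    regions = (
        sites.groupby("region")[["latitude", "longitude"]].mean()
        if "region" in sites.columns
        else pd.DataFrame()
    )
    history = None
    from .synthetic import TrueHistory, WorldData as WD

    hist_df = pd.DataFrame(
        {"region": list(npp), "nai_end_ka": np.nan, "sai_start_ka": np.nan,
         "true_overlap_ka": np.nan, "true_cc_medium": np.nan}
    ).set_index("region")
    hist_df["true_overlap_ka"] = hist_df["sai_start_ka"] - hist_df["nai_end_ka"]
    history = TrueHistory(hist_df)
    return WD(
        config=config, history=history, regions=regions, sites=sites, npp=npp,
        site_npp={}, occupations=pd.DataFrame(), dates=dates, fauna=fauna,
        species_pool=pool, modern_densities=modern, curve=curve,
    )


def _write_artifacts(result: RunResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    header = (
        f"# provenance: config={result.provenance['config_hash']} "
        f"seed={result.provenance['seed']}\n"
    )

    def write(df: pd.DataFrame, name: str) -> None:
        path = outdir / name
        with open(path, "w") as fh:
            fh.write(header)
            df.to_csv(fh)

    for tier, chron in result.chronology.items():
        write(chron, f"chronology_{tier}.csv")
        write(result.overlaps[tier], f"overlaps_{tier}.csv")
    write(result.cc_table, "carrying_capacity.csv")
    write(result.region_metrics, "region_metrics.csv")
    (outdir / "esf_results.json").write_text(
        json.dumps({"provenance": result.provenance, "tests": result.esf_results},
                   indent=2)
    )
    (outdir / "report.txt").write_text(make_report(result))


def make_report(result: RunResult) -> str:
    """Human-readable run summary with L/M/H percentile classifications."""
    lines = [
        "paleocoex run report",
        f"config hash: {result.provenance.get('config_hash', '?')}  "
        f"seed: {result.provenance.get('seed', '?')}",
        "",
        "Region chronologies (ka BP)",
    ]
    for tier, chron in result.chronology.items():
        lines.append(f"-- criteria {tier} --")
        lines.append(chron.round(2).to_string())
        lines.append("")
    lines.append("NAI/SAI temporal overlap (ka)")
    any_overlap = False
    for tier, ov in result.overlaps.items():
        valid = ov.dropna(subset=["minimal_ka"])
        if len(valid):
            any_overlap = True
        lines.append(f"-- criteria {tier} --")
        lines.append(ov.round(2).to_string())
        lines.append("")
    if not any_overlap:
        lines.append("no overlap computed (no region with both NAI and SAI phases)")
        lines.append("")
    metr = result.region_metrics
    lines.append("Ecosystem metrics with percentile classes (L < Q1 < M < Q3 < H)")
    classed = pd.DataFrame(index=metr.index)
    for col in ("npp_mean", "npp_cv", "cc_small", "cc_medium", "cc_large"):
        if col in metr.columns:
            classed[col] = metr[col].round(3)
            classed[f"{col}_class"] = classify_percentile(metr[col])
    lines.append(classed.to_string())
    lines.append("")
    if result.esf_results:
        lines.append("Spatially filtered correlation tests (CI-resampled)")
        for pair, summ in result.esf_results.items():
            lines.append(
                f"{pair}: median coef {summ['median_coefficient']:.4g}, "
                f"median p {summ['median_p']:.3g}, "
                f"fraction significant {summ['fraction_significant']:.2f} "
                f"(n={summ['n_regions']})"
            )
    return "\n".join(lines)
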