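"""Config-driven orchestration of the full analysis.

A run specification (YAML/JSON or an equivalent dict) names the input
tables — or a synthetic-data specification — plus seeds, randomization
counts and the stages to execute.  The pipeline then runs, per site ×
year: nest merging, the species-inclusion filters and the C-score null
model on the bait matrices (generalists), the Clark–Evans Monte-Carlo
dispersion test on the colony maps (both functional groups), and the
gradient regressions/ANCOVA across sites.  Results land as one CSV per
stage plus a ``run.log`` recording seeds, filter counts and plot
exclusions (e.g. bait-destroyed plots dropped from a year's design).

Identical config + seed gives byte-identical result CSVs.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as agio
from .cooccurrence import apply_inclusion_filters, null_model_test
from .data import GENERALIST, SEED_SPECIALIST, SiteRecord, forager_number
from .dispersion import clark_evans_z, site_dispersion_summary
from .gradient import ancova_slopes, linear_fit, spearman
from .simulate import (
    MatrixSpec,
    PointProcessSpec,
    simulate_occupancy,
    simulate_point_pattern,
)

logger = logging.getLogger("antgrad")

STAGES = ("cooccurrence", "dispersion", "gradient")


def table1_fixture() -> list[SiteRecord]:
    """The six study sites of the precipitation gradient, with 30-year
    mean annual precipitation (mm), rainfall of the 2007 and 2008 study
    years (mm), mean monthly temperature (°C) and mean herbaceous plant
    biomass (g m⁻² yr⁻¹)."""
    rows = [
        ("Sede Boqer", 94, {2007: 150, 2008: 69}, 18.7, 65),
        ("Hatzerim", 197, {2007: 182, 2008: 111}, 20.8, 149),
        ("Lahav", 308, {2007: 285, 2008: 203}, 19.6, 198),
        ("Amatzia", 380, {2007: 400, 2008: 246}, 19.6, 195),
        ("Karei Deshe", 550, {2007: 421, 2008: 310}, 22.5, 244),
        ("Ramot Menashe", 662, {2007: 599, 2008: 503}, 20.3, 370),
    ]
    return [SiteRecord(*r) for r in rows]


def demo_config() -> dict:
    """A self-contained synthetic run over the six packaged sites.

    Reproduces the two-year field design: three 20 × 15 m generalist
    plots per site (two at Lahav, Karei Deshe and Ramot Menashe in 2007,
    where one plot each was lost to bait destruction), 20 baits per
    plot, one 100 × 100 m seed-specialist plot per site.
    """
    return {
        "seed": 0,
        "n_rand": 1000,
        "stages": list(STAGES),
        "years": [2007, 2008],
        "output_dir": "antgrad_out",
        "exclusions": [
            {"year": 2007, "site": s, "n_plots": 2}
            for s in ("Lahav", "Karei Deshe", "Ramot Menashe")
        ],
        "synthetic": {
            "plots_per_site": 3,
            "plot_width": 20.0,
            "plot_height": 15.0,
            "baits_per_plot": 20,
            "n_species": 8,
            "occupancy_prob": 0.2,
            # pairwise segregation fades from the arid to the mesic end
            "segregation": {"intercept": -0.12, "slope": 0.00015},
            # generalist colonies per 20x15 plot declines with precipitation
            "colony_density": {"intercept": 16.41, "slope": -0.011},
            "generalist_pattern": {"kind": "hardcore", "min_dist": 2.0},
            # log10 mean forager number rises with log10 precipitation
            "forager_loglog": {"intercept": 0.9, "slope": 0.32},
            "specialist": {
                "plot_size": 100.0,
                "density": {"intercept": 10.0, "slope": 0.02},
                "pattern": {"kind": "hardcore", "min_dist": 7.0},
                "forager_loglog": {"intercept": 0.5, "slope": 0.55},
            },
        },
    }


def load_config(path: str | Path) -> dict:
    path = Path(path)
    with open(path) as fh:
        if path.suffix in (".yaml", ".yml"):
            return yaml.safe_load(fh)
        return json.load(fh)


def run_pipeline(config: dict | str | Path, output_dir: str | Path | None = None) -> dict:
    """Execute the configured stages; returns ``{stage: DataFrame}`` and
    writes ``<stage>.csv`` files plus ``run.log`` to the output dir."""
    if not isinstance(config, dict):
        config = load_config(config)
    out = Path(output_dir or config.get("output_dir", "antgrad_out"))
    out.mkdir(parents=True, exist_ok=True)
    stages = config.get("stages", list(STAGES))
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages {sorted(unknown)}; valid: {STAGES}")
    seed = int(config.get("seed", 0))
    n_rand = int(config.get("n_rand", 5000))
    years = [int(y) for y in config.get("years", [2007, 2008])]
    sites = (
        agio.read_sites(config["sites_csv"]) if "sites_csv" in config else table1_fixture()
    )
    log_lines = [f"seed={seed} n_rand={n_rand} stages={stages} years={years}"]

    colony_maps, matrices = _gather_inputs(config, sites, years, seed, log_lines)

    results: dict[str, pd.DataFrame] = {}
    if "cooccurrence" in stages:
        results["cooccurrence"] = _stage_cooccurrence(
            matrices, n_rand, seed, log_lines
        )
    if "dispersion" in stages:
        results["dispersion"] = _stage_dispersion(colony_maps, n_rand, seed, log_lines)
    if "gradient" in stages:
        results["gradient"] = _stage_gradient(sites, colony_maps, years, log_lines)

    for stage, df in results.items():
        df.to_csv(out / f"{stage}.csv", index=False)
    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    logger.info("pipeline wrote %s", sorted(p.name for p in out.iterdir()))
    return results


# ---------------------------------------------------------------------------
# input assembly


def _gather_inputs(config, sites, years, seed, log_lines):
    """Either read declared input tables or synthesize the full design."""
    if "inputs" in config:
        return _read_inputs(config, log_lines)
    syn = config.get("synthetic")
    if syn is None:
        raise ValueError("config must declare either 'inputs' or 'synthetic'")
    return _synthesize_inputs(syn, config, sites, years, seed, log_lines)


def _read_inputs(config, log_lines):
    colony_maps: dict = {}
    matrices: dict = {}
    for entry in config["inputs"].get("colony_tables", []):
        cmap = agio.read_colony_table(
            entry["path"], entry["plot_width"], entry["plot_height"],
            plot_id=entry.get("plot_id"), year=int(entry.get("year", 0)),
        )
        merged = agio.merge_close_nests(cmap)
        key = (entry["site"], int(entry.get("year", 0)), entry.get("group", GENERALIST))
        colony_maps.setdefault(key, []).append(merged)
        log_lines.append(
            f"read {entry['path']}: {len(cmap)} entrances -> {len(merged)} nests"
        )
    for entry in config["inputs"].get("occupancy", []):
        mat = agio.read_occupancy(entry["path"], entry.get("bait_plot_path"))
        matrices[(entry["site"], int(entry.get("year", 0)))] = mat
        log_lines.append(f"read {entry['path']}: {mat!r}")
    if not colony_maps and not matrices:
        raise ValueError("inputs section names no tables")
    return colony_maps, matrices


def _site_seed(base: int, site_idx: int, year: int, tag: int) -> int:
    return (base * 1_000_003 + site_idx * 10_007 + year * 101 + tag) % (2**31 - 1)


def _synthesize_inputs(syn, config, sites, years, seed, log_lines):
    colony_maps: dict = {}
    matrices: dict = {}
    excl = {
        (e["site"], int(e["year"])): int(e["n_plots"])
        for e in config.get("exclusions", [])
    }
    w, h = float(syn.get("plot_width", 20.0)), float(syn.get("plot_height", 15.0))
    n_plots_default = int(syn.get("plots_per_site", 3))
    n_species = int(syn.get("n_species", 8))
    spp = [f"gen{i + 1}" for i in range(n_species)]
    dens = syn.get("colony_density", {"intercept": 16.41, "slope": -0.011})
    seg = syn.get("segregation", {"intercept": 0.0, "slope": 0.0})
    fl = syn.get("forager_loglog", {"intercept": 0.9, "slope": 0.32})
    pat = syn.get("generalist_pattern", {"kind": "csr"})
    spec_cfg = syn.get("specialist")

    for si, site in enumerate(sites):
        for year in years:
            n_plots = excl.get((site.site_name, year), n_plots_default)
            if n_plots != n_plots_default:
                log_lines.append(
                    f"exclusion: {site.site_name} {year} uses {n_plots} plots"
                )
            gmaps = []
            bait_cols = []
            bait_plot = {}
            for p in range(n_plots):
                s = _site_seed(seed, si, year, 7 + p)
                n_col = max(2, round(dens["intercept"] + dens["slope"] * site.precip_mean))
                cmap = _synthetic_plot(
                    s, pat, n_col, w, h, spp, fl, site.precip_mean,
                    plot_id=f"{site.site_name}-p{p + 1}", year=year, group=GENERALIST,
                )
                gmaps.append(agio.merge_close_nests(cmap))
                for b in range(int(syn.get("baits_per_plot", 20))):
                    bait_cols.append(f"p{p + 1}b{b + 1}")
                    bait_plot[f"p{p + 1}b{b + 1}"] = f"p{p + 1}"
            colony_maps[(site.site_name, year, GENERALIST)] = gmaps
            rho = seg["intercept"] + seg["slope"] * site.precip_mean
            rho = float(np.clip(rho, -1.0 / (n_species - 1) + 1e-6, 0.99))
            mspec = MatrixSpec(
                n_species, len(bait_cols), (float(syn.get("occupancy_prob", 0.2)),) * n_species,
                segregation=rho, seed=_site_seed(seed, si, year, 3),
            )
            mat = simulate_occupancy(mspec)
            from .data import OccupancyMatrix

            matrices[(site.site_name, year)] = OccupancyMatrix(
                spp, bait_cols, mat.values, bait_plot
            )
            if spec_cfg:
                size = float(spec_cfg.get("plot_size", 100.0))
                d = spec_cfg["density"]
                n_col = max(2, round(d["intercept"] + d["slope"] * site.precip_mean))
                cmap = _synthetic_plot(
                    _site_seed(seed, si, year, 23), spec_cfg.get("pattern", {"kind": "csr"}),
                    n_col, size, size, ["Messor1", "Messor2"],
                    spec_cfg.get("forager_loglog", fl), site.precip_mean,
                    plot_id=f"{site.site_name}-M", year=year, group=SEED_SPECIALIST,
                )
                colony_maps[(site.site_name, year, SEED_SPECIALIST)] = [
                    agio.merge_close_nests(cmap)
                ]
    n_nests = sum(len(m) for maps in colony_maps.values() for m in maps)
    log_lines.append(f"synthesized {len(matrices)} matrices, {n_nests} nests")
    return colony_maps, matrices


def _synthetic_plot(seed, pattern, n_col, w, h, species_pool, fl, precip,
                    plot_id, year, group):
    pspec = PointProcessSpec(
        kind=pattern.get("kind", "csr"), n_points=n_col, plot_width=w, plot_height=h,
        min_dist=float(pattern.get("min_dist", 0.0)), seed=seed,
    )
    base = simulate_point_pattern(pspec, plot_id=plot_id, year=year)
    rng = np.random.default_rng(seed + 1)
    mean_foragers = 10 ** (fl["intercept"] + fl["slope"] * np.log10(precip))
    from .data import Colony, ColonyMap

    colonies = []
    for c in base.colonies:
        counts = tuple(int(v) for v in rng.poisson(mean_foragers, size=4))
        sp = species_pool[rng.integers(len(species_pool))]
        colonies.append(Colony(sp, group, c.x, c.y, counts))
    return ColonyMap(plot_id, w, h, year, colonies)


# ---------------------------------------------------------------------------
# stages


def _stage_cooccurrence(matrices, n_rand, seed, log_lines):
    rows = []
    for k, ((site, year), mat) in enumerate(sorted(matrices.items())):
        try:
            filtered = apply_inclusion_filters(mat)
        except ValueError as exc:
            log_lines.append(f"cooccurrence {site} {year}: skipped ({exc})")
            continue
        log_lines.append(
            f"cooccurrence {site} {year}: {mat.n_species}->{filtered.n_species} species"
        )
        res = null_model_test(
            filtered, n_rand=n_rand, rng=np.random.default_rng(_site_seed(seed, k, year, 1))
        )
        rows.append(
            {
                "stage": "cooccurrence", "site": site, "year": year,
                "c_obs": res.stat_obs, "null_mean": res.null_mean,
                "null_sd": res.null_sd, "ses": res.ses,
                "p_upper": res.p_upper, "p_lower": res.p_lower,
                "n_species": res.n_species, "n_baits": res.n_baits,
            }
        )
    return pd.DataFrame(rows)


def _stage_dispersion(colony_maps, n_rand, seed, log_lines):
    rows = []
    for k, ((site, year, group), maps) in enumerate(sorted(colony_maps.items())):
        per_plot = []
        for cmap in maps:
            if len(cmap) < 2:
                log_lines.append(
                    f"dispersion {site} {year} {group} {cmap.plot_id}: "
                    f"skipped (<2 colonies)"
                )
                continue
            res = clark_evans_z(
                cmap, n_rand=n_rand,
                rng=np.random.default_rng(_site_seed(seed, k, year, 2)),
            )
            per_plot.append(res)
            rows.append(
                {
                    "stage": "dispersion", "site": site, "year": year, "group": group,
                    "plot_id": cmap.plot_id, "level": "plot",
                    "n_points": res.n_points, "nnd_obs": res.nnd_obs,
                    "null_mean": res.nnd_sim_mean, "null_sd": res.nnd_sim_sd,
                    "z": res.z, "classification": res.classification,
                }
            )
        if per_plot:
            mean_z, mean_nnd, hetero = site_dispersion_summary(per_plot)
            if hetero:
                log_lines.append(
                    f"dispersion {site} {year} {group}: heterogeneous plot Z signs"
                )
            rows.append(
                {
                    "stage": "dispersion", "site": site, "year": year, "group": group,
                    "plot_id": "", "level": "site",
                    "n_points": sum(r.n_points for r in per_plot),
                    "nnd_obs": mean_nnd, "null_mean": np.nan, "null_sd": np.nan,
                    "z": mean_z,
                    "classification": "heterogeneous" if hetero else
                    ("segregated" if mean_z > 1.96 else
                     "aggregated" if mean_z < -1.96 else "random"),
                }
            )
    return pd.DataFrame(rows)


def _stage_gradient(sites, colony_maps, years, log_lines):
    precip = np.array([s.precip_mean for s in sites])
    biomass = np.array([s.biomass_mean for s in sites])
    rows = []

    rho, p = spearman(precip, biomass)
    rows.append({"stage": "gradient", "analysis": "spearman_precip_biomass",
                 "group": "", "year": "all", "slope": np.nan, "intercept": np.nan,
                 "stat": rho, "df1": np.nan, "df2": np.nan, "r2": np.nan, "p": p})

    for group in (GENERALIST, SEED_SPECIALIST):
        for year in years:
            dens, forag = [], []
            ok = True
            for s in sites:
                maps = colony_maps.get((s.site_name, year, group))
                if not maps:
                    ok = False
                    break
                dens.append(np.mean([len(m) for m in maps]))
                fn = [forager_number(c) for m in maps for c in m.colonies]
                forag.append(np.mean(fn) if fn else np.nan)
            if not ok:
                continue
            fit = linear_fit(precip, dens)
            rows.append({"stage": "gradient", "analysis": "colony_density",
                         "group": group, "year": year, "slope": fit.slope,
                         "intercept": fit.intercept, "stat": fit.f_stat,
                         "df1": fit.df[0], "df2": fit.df[1], "r2": fit.r2, "p": fit.p})
            if np.all(np.asarray(forag) > 0):
                fitf = linear_fit(np.log10(precip), forag, log10_y=True)
                rows.append({"stage": "gradient", "analysis": "forager_number_loglog",
                             "group": group, "year": year, "slope": fitf.slope,
                             "intercept": fitf.intercept, "stat": fitf.f_stat,
                             "df1": fitf.df[0], "df2": fitf.df[1],
                             "r2": fitf.r2, "p": fitf.p})

    for year in years:
        x, y, g = [], [], []
        for s in sites:
            for group in (GENERALIST, SEED_SPECIALIST):
                maps = colony_maps.get((s.site_name, year, group))
                if not maps:
                    continue
                fn = [forager_number(c) for m in maps for c in m.colonies]
                if fn:
                    x.append(np.log10(s.precip_mean))
                    y.append(np.log10(np.mean(fn)))
                    g.append(group)
        if len(set(g)) == 2 and min(g.count(a) for a in set(g)) >= 3:
            res = ancova_slopes(x, y, g)
            log_lines.append(
                f"ancova {year}: slopes "
                + ", ".join(f"{k}={v[0]:.3f}±{v[1]:.3f}"
                            for k, v in res.slope_by_group.items())
            )
            rows.append({"stage": "gradient", "analysis": "ancova_forager_slopes",
                         "group": "both", "year": year,
                         "slope_specialist": res.slope_by_group[SEED_SPECIALIST][0],
                         "slope_generalist": res.slope_by_group[GENERALIST][0],
                         "stat": res.interaction_f, "df1": res.interaction_df[0],
                         "df2": res.interaction_df[1], "r2": np.nan,
                         "p": res.interaction_p})
    return pd.DataFrame(rows)
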