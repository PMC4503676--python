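"""CSV readers/writers and shared preprocessing for the analysis stages.

File formats (comma-separated, UTF-8, header row required):

* colony tables — columns ``species, group, x, y, count_1..count_4``;
  missing trailing counts are allowed (empty cells);
* occupancy matrices — first column ``species``, remaining columns one
  per bait; cells strictly 0/1; an optional companion mapping file with
  columns ``bait, plot`` assigns baits to plots;
* site metadata — columns ``site, precip_mean, temp_mean, biomass_mean``
  plus one ``rain_<year>`` column per recorded year.

Preprocessing shared by all stages: :func:`merge_close_nests` collapses
same-species nest entrances less than 1 m apart into a single nest.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, is_dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .data import Colony, ColonyMap, OccupancyMatrix, SiteRecord

logger = logging.getLogger("antgrad")

_COUNT_COLS = ["count_1", "count_2", "count_3", "count_4"]


def read_colony_table(
    path: str | Path,
    plot_width: float,
    plot_height: float,
    plot_id: str | None = None,
    year: int = 0,
) -> ColonyMap:
    """Read a colony table CSV into a validated :class:`ColonyMap`.

    Rows with coordinates outside ``[0, plot_width] x [0, plot_height]``
    raise a validation error; malformed rows raise a parse error naming
    the offending line.
    """
    path = Path(path)
    if plot_id is None:
        plot_id = path.stem
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        logger.warning("colony table %s is empty; returning empty ColonyMap", path)
        return ColonyMap(plot_id, plot_width, plot_height, year, [])
    required = {"species", "group", "x", "y"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: missing required columns {sorted(required - set(df.columns))}")
    if df.empty:
        logger.warning("colony table %s has a header but no rows", path)
        return ColonyMap(plot_id, plot_width, plot_height, year, [])

    colonies: list[Colony] = []
    for idx, row in df.iterrows():
        line = idx + 2  # header is line 1
        try:
            x = float(row["x"])
            y = float(row["y"])
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}: malformed coordinate on line {line}: {exc}") from None
        if not np.isfinite(x) or not np.isfinite(y):
            raise ValueError(f"{path}: non-finite coordinate on line {line}")
        counts = []
        for col in _COUNT_COLS:
            if col in df.columns and pd.notna(row[col]):
                v = float(row[col])
                if v < 0 or v != int(v):
                    raise ValueError(
                        f"{path}: forager count must be a non-negative integer "
                        f"(line {line}, column {col})"
                    )
                counts.append(int(v))
        try:
            colonies.append(
                Colony(str(row["species"]), str(row["group"]), x, y, tuple(counts))
            )
        except ValueError as exc:
            raise ValueError(f"{path}: line {line}: {exc}") from None
    return ColonyMap(plot_id, plot_width, plot_height, year, colonies)


def write_colony_table(cmap: ColonyMap, path: str | Path) -> None:
    rows = []
    for c in cmap.colonies:
        row = {"species": c.species, "group": c.functional_group, "x": c.x, "y": c.y}
        for i, v in enumerate(c.forager_counts, start=1):
            row[f"count_{i}"] = v
        rows.append(row)
    cols = ["species", "group", "x", "y"] + _COUNT_COLS
    df = pd.DataFrame(rows)
    df = df.reindex(columns=[c for c in cols if c in df.columns or c in ("species", "group", "x", "y")])
    df.to_csv(path, index=False)


def merge_close_nests(cmap: ColonyMap, threshold: float = 1.0) -> ColonyMap:
    """Merge same-species nest entrances less than ``threshold`` meters
    apart into single nests.

    Clusters are formed by transitive closure of the strict
    ``distance < threshold`` relation within each species and collapsed
    to the centroid of their member entrances, with forager counts
    combined element-wise by maximum.  Closure is iterated to a fixed
    point so that the returned map has no same-species pair closer than
    the threshold — the operation is idempotent and order-independent.
    Different species are never merged.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    merged: list[Colony] = []
    for sp in sorted({c.species for c in cmap.colonies}):
        group = [c for c in cmap.colonies if c.species == sp]
        merged.extend(_merge_species(group, threshold))
    return ColonyMap(cmap.plot_id, cmap.plot_width, cmap.plot_height, cmap.year, merged)


def _merge_species(colonies: list[Colony], threshold: float) -> list[Colony]:
    # clusters of original entrance records; iterate centroid-merging to
    # a fixed point so no output pair is closer than the threshold
    clusters: list[list[Colony]] = [[c] for c in colonies]
    while len(clusters) > 1:
        centroids = np.array(
            [[np.mean([c.x for c in cl]), np.mean([c.y for c in cl])] for cl in clusters]
        )
        close = squareform(pdist(centroids)) < threshold
        np.fill_diagonal(close, False)
        if not close.any():
            break
        parent = list(range(len(clusters)))

        def find(i: int) -> int:
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i, j in zip(*np.nonzero(close)):
            ri, rj = find(int(i)), find(int(j))
            if ri != rj:
                parent[max(ri, rj)] = min(ri, rj)
        groups: dict[int, list[Colony]] = {}
        for i, cl in enumerate(clusters):
            groups.setdefault(find(i), []).extend(cl)
        if len(groups) == len(clusters):
            break
        clusters = [groups[k] for k in sorted(groups)]
    return [_collapse(cl) for cl in clusters]


def _collapse(cluster: list[Colony]) -> Colony:
    if len(cluster) == 1:
        return cluster[0]
    x = float(np.mean([c.x for c in cluster]))
    y = float(np.mean([c.y for c in cluster]))
    n_periods = max(len(c.forager_counts) for c in cluster)
    counts = tuple(
        max((c.forager_counts[i] for c in cluster if len(c.forager_counts) > i), default=0)
        for i in range(n_periods)
    )
    return Colony(cluster[0].species, cluster[0].functional_group, x, y, counts)


# ---------------------------------------------------------------------------
# occupancy matrices


def read_occupancy(
    path: str | Path, bait_plot_path: str | Path | None = None
) -> OccupancyMatrix:
    """Read a species × bait presence–absence CSV.

    Cells must be exactly 0 or 1 (no coercion of other values).  If
    ``bait_plot_path`` is given it must be a two-column CSV ``bait, plot``
    covering every bait; otherwise all baits are assigned to one plot.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(",")[1:]
    if len(set(header)) != len(header):
        raise ValueError(f"{path}: duplicate bait labels in header")
    df = pd.read_csv(path, index_col=0)
    if df.index.duplicated().any():
        raise ValueError(f"{path}: duplicate species labels")
    values = df.to_numpy()
    if not np.isin(values, (0, 1)).all():
        raise ValueError(f"{path}: occupancy cells must be 0 or 1")
    bait_plot = None
    if bait_plot_path is not None:
        mp = pd.read_csv(bait_plot_path)
        bait_plot = dict(zip(mp["bait"].astype(str), mp["plot"].astype(str)))
    return OccupancyMatrix(
        [str(s) for s in df.index], [str(b) for b in df.columns], values, bait_plot
    )


def write_occupancy(mat: OccupancyMatrix, path: str | Path) -> None:
    df = pd.DataFrame(mat.values, index=mat.species, columns=mat.baits)
    df.index.name = "species"
    df.to_csv(path)


# ---------------------------------------------------------------------------
# site metadata


def read_sites(path: str | Path) -> list[SiteRecord]:
    df = pd.read_csv(path)
    rain_cols = [c for c in df.columns if c.startswith("rain_")]
    records = []
    for _, row in df.iterrows():
        records.append(
            SiteRecord(
                site_name=str(row["site"]),
                precip_mean=float(row["precip_mean"]),
                precip_by_year={int(c[5:]): float(row[c]) for c in rain_cols},
                temp_mean=float(row["temp_mean"]),
                biomass_mean=float(row["biomass_mean"]),
            )
        )
    return records


def write_sites(records: Sequence[SiteRecord], path: str | Path) -> None:
    years = sorted({y for r in records for y in r.precip_by_year})
    rows = []
    for r in records:
        row = {
            "site": r.site_name,
            "precip_mean": r.precip_mean,
            "temp_mean": r.temp_mean,
            "biomass_mean": r.biomass_mean,
        }
        for y in years:
            row[f"rain_{y}"] = r.precip_by_year.get(y, np.nan)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def write_results(results: Iterable, path: str | Path) -> None:
    """Write an iterable of result dataclasses (or dicts) as one CSV row
    each; tuple-valued fields are flattened into separate columns."""
    rows = []
    for r in results:
        d = asdict(r) if is_dataclass(r) else dict(r)
        flat = {}
        for k, v in d.items():
            if isinstance(v, tuple) and len(v) == 2:
                flat[f"{k}_1"], flat[f"{k}_2"] = v
            elif isinstance(v, dict):
                for kk, vv in v.items():
                    if isinstance(vv, tuple):
                        flat[f"{k}_{kk}"], flat[f"{k}_{kk}_se"] = vv
                    else:
                        flat[f"{k}_{kk}"] = vv
            else:
                flat[k] = v
        rows.append(flat)
    pd.DataFrame(rows).to_csv(path, index=False)
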