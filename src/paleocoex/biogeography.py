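"""Delimiting biogeographic regions from NPP dynamics, climate and fauna.

Regions are built in three layers: (1) sites are clustered on the dCORT
dissimilarity of their NPP trajectories — a Euclidean distance between raw
series modulated by the correlation of their first differences, so two
series with similar values but opposite dynamics are kept apart; (2) each
NPP cluster is split wherever its sites fall in different Köppen-Geiger
climate classes; (3) and further split where the herbivore guilds differ
(Jaccard dissimilarity clustering).  The resulting partition is always a
refinement of the NPP clustering, and regions are numbered east to west.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
import yaml
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .npp import NPPSeries

__all__ = [
    "DcortConfig",
    "dcort_distance",
    "dissimilarity_matrix",
    "cluster_npp",
    "choose_n_clusters",
    "koppen_classify",
    "jaccard_dissimilarity",
    "delimit_regions",
    "Region",
]


@dataclass
class DcortConfig:
    """dCORT settings: adaptive weight k (>= 0) over a Euclidean base distance."""

    k_tuning: float = 2.0

    def __post_init__(self) -> None:
        if self.k_tuning < 0:
            raise ValueError("k_tuning must be non-negative")


def dcort_distance(s1: NPPSeries, s2: NPPSeries, config: DcortConfig | None = None) -> float:
    """Temporal-correlation-weighted dissimilarity between two series.

    ``phi_k(CORT(s1, s2)) * d_Euclid(s1, s2)`` with CORT the cosine
    similarity of first differences and ``phi_k(u) = 2 / (1 + exp(k u))``.
    With ``k_tuning = 0`` this reduces to the plain Euclidean distance.
    """
    config = config or DcortConfig()
    if s1.times_ka.shape != s2.times_ka.shape or not np.allclose(
        s1.times_ka, s2.times_ka
    ):
        raise ValueError("series must share an identical time grid")
    d1 = np.diff(s1.values)
    d2 = np.diff(s2.values)
    denom = np.linalg.norm(d1) * np.linalg.norm(d2)
    cort = float(d1 @ d2 / denom) if denom > 0 else 0.0
    phi = 2.0 / (1.0 + np.exp(config.k_tuning * cort))
    return float(phi * np.linalg.norm(s1.values - s2.values))


def dissimilarity_matrix(
    series: dict[str, NPPSeries], config: DcortConfig | None = None
) -> pd.DataFrame:
    """Symmetric dCORT matrix over a set of series (ids sorted)."""
    ids = sorted(series)
    n = len(ids)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = dcort_distance(
                series[ids[i]], series[ids[j]], config
            )
    return pd.DataFrame(mat, index=ids, columns=ids)


def choose_n_clusters(merge_heights: np.ndarray, max_k: int | None = None) -> int:
    """Pick the cut with the largest relative gap in merge heights."""
    h = np.asarray(merge_heights, dtype=float)
    n = h.size + 1
    best_k, best_gap = 1, -np.inf
    lo = 2 if max_k is None else max(2, n - max_k + 1)
    for i in range(lo - 1, h.size):
        prev = h[i - 1] if i > 0 else 0.0
        gap = (h[i] - prev) / max(prev, 1e-12)
        if gap > best_gap:
            best_gap = gap
            best_k = n - i  # cutting below merge i leaves n - i clusters
    return best_k


def cluster_npp(
    matrix: pd.DataFrame,
    n_clusters: int | None = None,
    method: str = "average",
) -> pd.Series:
    """Agglomerative clustering of a dissimilarity matrix.

    Labels are deterministic: clusters are numbered 1..k in order of their
    smallest member id.  ``n_clusters=None`` applies the largest relative
    merge-height gap rule.
    """
    ids = list(matrix.index)
    mat = matrix.to_numpy(dtype=float)
    if mat.shape[0] != mat.shape[1] or not np.allclose(mat, mat.T, atol=1e-10):
        raise ValueError("dissimilarity matrix must be square and symmetric")
    if np.any(np.diag(mat) != 0):
        raise ValueError("dissimilarity matrix must have a zero diagonal")
    n = len(ids)
    if n_clusters is not None and n_clusters > n:
        raise ValueError("cannot request more clusters than items")
    z = linkage(squareform(mat, checks=False), method=method)
    if n_clusters is None:
        n_clusters = choose_n_clusters(z[:, 2])
    raw = fcluster(z, t=n_clusters, criterion="maxclust")
    # deterministic relabeling by smallest member id (lexicographic)
    order = {}
    for sid in sorted(ids):
        lab = raw[ids.index(sid)]
        if lab not in order:
            order[lab] = len(order) + 1
    return pd.Series([order[r] for r in raw], index=ids, name="cluster")


# ---------------------------------------------------------------------------
# Köppen-Geiger classification (C/D/E families, Peel-style thresholds)
# ---------------------------------------------------------------------------

def _load_koppen_rules() -> dict:
    with resources.files("paleocoex.data").joinpath("koppen_rules.yaml").open() as fh:
        return yaml.safe_load(fh)


_KOPPEN_RULES = None


def koppen_classify(
    temperature_c,
    precipitation_mm,
    hemisphere: str = "north",
) -> str:
    """Köppen-Geiger class code from 12 monthly normals.

    Restricted to the extratropical families: E (EF/ET), and C/D with
    s/w/f precipitation and a/b/c temperature modifiers.  Summer is
    Apr-Sep in the northern hemisphere.
    """
    global _KOPPEN_RULES
    if _KOPPEN_RULES is None:
        _KOPPEN_RULES = _load_koppen_rules()
    rules = _KOPPEN_RULES
    t = np.asarray(temperature_c, dtype=float)
    p = np.asarray(precipitation_mm, dtype=float)
    if t.shape != (12,) or p.shape != (12,):
        raise ValueError("need 12 monthly temperature and precipitation values")
    if np.any(t < -90) or np.any(p < 0):
        raise ValueError("non-physical climate inputs")

    t_hot = float(t.max())
    t_cold = float(t.min())
    if t_hot < rules["polar"]["hottest_month_max"]:
        return "ET" if t_hot > rules["polar"]["tundra_hottest_min"] else "EF"
    if t_cold <= rules["continental"]["coldest_month_max"]:
        family = "D"
    elif t_cold < rules["temperate"]["coldest_month_max"]:
        family = "C"
    else:
        raise ValueError(
            "tropical climates (coldest month >= 18 C) are outside the "
            "supported classification subset"
        )

    summer = slice(3, 9) if hemisphere == "north" else None
    if summer is None:
        p_summer = np.concatenate([p[9:], p[:3]])
        p_winter = p[3:9]
    else:
        p_summer = p[summer]
        p_winter = np.concatenate([p[9:], p[:3]])
    pr = rules["precipitation"]
    if (
        p_summer.min() < pr["dry_summer_mm"]
        and p_summer.min() < p_winter.max() / pr["dry_summer_winter_ratio"]
    ):
        season = "s"
    elif p_winter.min() < p_summer.max() / pr["dry_winter_summer_ratio"]:
        season = "w"
    else:
        season = "f"

    tm = rules["temperature_modifier"]
    warm_months = int(np.sum(t >= tm["month_threshold"]))
    if t_hot >= tm["hot_summer_min"]:
        mod = "a"
    elif warm_months >= tm["warm_summer_months"]:
        mod = "b"
    else:
        mod = "c"
    return family + season + mod


def jaccard_dissimilarity(assemblage_a, assemblage_b) -> float:
    """1 - |A ∩ B| / |A ∪ B|; two empty assemblages give 0 by convention."""
    a, b = set(assemblage_a), set(assemblage_b)
    union = a | b
    if not union:
        import logging

        logging.getLogger(__name__).info(
            "Jaccard dissimilarity of two empty assemblages defined as 0"
        )
        return 0.0
    return 1.0 - len(a & b) / len(union)


# ---------------------------------------------------------------------------
# Region delimitation
# ---------------------------------------------------------------------------

@dataclass
class Region:
    region_id: str
    sites: list[str]
    npp_cluster: int
    climate_class: str
    fauna_cluster: int
    mean_longitude: float


def delimit_regions(
    npp_labels: pd.Series,
    climate_classes: pd.Series,
    fauna_labels: pd.Series,
    longitudes: pd.Series,
) -> tuple[pd.Series, list[Region]]:
    """Refine NPP clusters by climate class and fauna cluster.

    All four inputs are indexed by site id and must cover the same sites.
    Returns the per-site region id series (R_1 ... R_n, east to west by
    mean longitude) and the Region summaries.
    """
    sites = set(npp_labels.index)
    for s in (climate_classes, fauna_labels, longitudes):
        if set(s.index) != sites:
            raise ValueError("all labelings must cover the same site set")
    key = pd.DataFrame(
        {
            "npp": npp_labels,
            "climate": climate_classes,
            "fauna": fauna_labels,
            "lon": longitudes,
        }
    )
    groups = key.groupby(["npp", "climate", "fauna"], sort=False)
    summaries = []
    for (npp_c, clim, fauna_c), sub in groups:
        summaries.append(
            Region(
                region_id="",
                sites=sorted(sub.index),
                npp_cluster=int(npp_c),
                climate_class=str(clim),
                fauna_cluster=int(fauna_c),
                mean_longitude=float(sub["lon"].mean()),
            )
        )
    # east-to-west naming: R_1 is the easternmost region
    summaries.sort(key=lambda r: (-r.mean_longitude, r.sites[0]))
    site_to_region = {}
    for i, reg in enumerate(summaries, start=1):
        reg.region_id = f"R_{i}"
        for s in reg.sites:
            site_to_region[s] = reg.region_id
    labels = pd.Series(
        [site_to_region[s] for s in npp_labels.index],
        index=npp_labels.index,
        name="region",
    )
    return labels, summaries
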