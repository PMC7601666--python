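"""Cluster-based permutation analysis of correlation topographies.

For each electrode, the per-subject band-power contrast (stimulation −
rest) is rank-correlated (Spearman) with a scalar covariate — a
morphometric measure or the coma outcome.  The rho map is converted to t
values, thresholded at the 2.5th/97.5th quantiles of the permutation null
(t values pooled over electrodes and permutations; a parametric t(n−2)
mode is available), and supra-threshold electrodes are grouped into
sign-separated connected clusters on the 10-20 adjacency graph.  Cluster
mass is the sum of member t values.  The null distribution is the maximum
absolute cluster mass across N random permutations of the covariate, and
the cluster p-value uses the add-one estimator (b + 1)/(N + 1), whose
floor at N = 500 displays as 0.002.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import ClinicalRecord, MorphometryRecord
from .montage import load_adjacency

#: Cap applied to |t| when |rho| = 1 (flagged infinite).
T_CAP = 1e6


@dataclass(frozen=True)
class PermConfig:
    """Permutation-procedure parameters."""

    n_permutations: int = 500
    lower_quantile: float = 0.025
    upper_quantile: float = 0.975
    min_cluster_size: int = 1
    threshold_mode: str = "permutation"   # or "parametric"
    bonferroni_covariates: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.n_permutations < 100:
            raise ValueError("n_permutations must be at least 100")
        if abs((1.0 - self.upper_quantile) - self.lower_quantile) > 1e-12:
            raise ValueError("threshold quantiles must be symmetric")
        if self.min_cluster_size < 1:
            raise ValueError("min_cluster_size must be >= 1")
        if self.threshold_mode not in ("permutation", "parametric"):
            raise ValueError("threshold_mode must be 'permutation' or 'parametric'")


@dataclass
class Cluster:
    electrodes: tuple[str, ...]
    sign: int                 # +1 or -1
    mass: float               # sum of member t values
    p: float                  # permutation p (add-one estimator)
    p_corrected: float
    significant: bool


@dataclass
class ClusterTestResult:
    covariate: str
    clusters: list[Cluster]
    n_permutations: int
    n_subjects: int
    thresholds: tuple[float, float]
    rho: pd.Series            # electrode -> Spearman rho
    t: pd.Series              # electrode -> t value
    seed: int
    permutation_matrix: np.ndarray | None = None

    def significant_clusters(self) -> list[Cluster]:
        return [c for c in self.clusters if c.significant]


def spearman_rho(x, y) -> float:
    """Spearman rank correlation: Pearson correlation of midranks."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 4:
        raise ValueError("need at least 4 observations")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    if np.std(rx) == 0 or np.std(ry) == 0:
        raise ValueError("zero variance in ranked values: rho undefined")
    return float(np.corrcoef(rx, ry)[0, 1])


def rho_to_t(rho: float, n: int) -> float:
    """Standard t approximation for a rank correlation: t = ρ√((n−2)/(1−ρ²)).

    |rho| = 1 is returned as a signed large value (capped infinity flag).
    """
    if n < 4:
        raise ValueError("need n >= 4")
    if abs(rho) >= 1.0:
        return float(np.sign(rho) * T_CAP)
    return float(rho * np.sqrt((n - 2) / (1.0 - rho ** 2)))


def threshold_map(t_map: pd.Series, null_t: np.ndarray,
                  lower_quantile: float = 0.025,
                  upper_quantile: float = 0.975
                  ) -> tuple[list[str], list[str], tuple[float, float]]:
    """Supra-threshold electrodes, sign-separated.

    ``null_t`` is the pooled permutation t distribution.  Returns
    (positive electrodes, negative electrodes, (lo, hi) thresholds).
    """
    null_t = np.asarray(null_t, dtype=float).ravel()
    lo = float(np.quantile(null_t, lower_quantile))
    hi = float(np.quantile(null_t, upper_quantile))
    if lo == hi:
        raise ValueError("degenerate null distribution: all t values equal")
    positive = list(t_map.index[t_map > hi])
    negative = list(t_map.index[t_map < lo])
    return positive, negative, (lo, hi)


def form_clusters(electrodes: list[str], t_map: pd.Series,
                  adjacency: nx.Graph, min_size: int = 1
                  ) -> list[tuple[tuple[str, ...], float]]:
    """Connected components of supra-threshold electrodes with their mass."""
    sub = adjacency.subgraph(electrodes)
    clusters = []
    for component in nx.connected_components(sub):
        if len(component) < min_size:
            continue
        members = tuple(sorted(component))
        mass = float(t_map[list(members)].sum())
        clusters.append((members, mass))
    clusters.sort(key=lambda c: -abs(c[1]))
    return clusters


def _rho_matrix(rank_x: np.ndarray, rank_y: np.ndarray) -> np.ndarray:
    """Spearman rho of each column of rank_x against each row of rank_y.

    rank_x: (n_subjects, n_electrodes) midranks per electrode;
    rank_y: (n_perms, n_subjects) permuted covariate midranks.
    Returns (n_perms, n_electrodes).
    """
    zx = rank_x - rank_x.mean(axis=0, keepdims=True)
    sx = np.sqrt((zx ** 2).sum(axis=0))
    zy = rank_y - rank_y.mean(axis=1, keepdims=True)
    sy = np.sqrt((zy ** 2).sum(axis=1))
    num = zy @ zx
    return num / (sy[:, None] * sx[None, :])


def permutation_test(contrasts: pd.DataFrame, covariate: pd.Series,
                     config: PermConfig = PermConfig(),
                     adjacency: nx.Graph | None = None,
                     covariate_name: str = "covariate",
                     n_covariates: int = 1,
                     keep_permutations: bool = False) -> ClusterTestResult:
    """Cluster-based permutation test of one covariate.

    ``contrasts`` is subjects × electrodes (the per-subject contrast map);
    ``covariate`` is indexed by subject.  Subjects with a missing covariate
    are dropped with a warning; at least 5 complete subjects are required.
    The per-permutation null statistic is the maximum absolute cluster
    mass (two-sided, weak FWER control); ``n_covariates`` applies the
    Bonferroni correction across a covariate battery.
    """
    import warnings

    config.validate()
    if adjacency is None:
        adjacency = load_adjacency()
    cov = covariate.reindex(contrasts.index)
    missing = list(cov.index[cov.isna()])
    if missing:
        warnings.warn(f"{covariate_name}: dropped subjects with missing "
                      f"covariate: {missing}")
        cov = cov.dropna()
    X = contrasts.loc[cov.index]
    n = len(cov)
    if n < 5:
        raise ValueError(f"{covariate_name}: need >= 5 subjects with complete data")
    if cov.nunique() == 1:
        raise ValueError(f"{covariate_name}: covariate is constant")

    electrodes = list(X.columns)
    rank_x = np.apply_along_axis(stats.rankdata, 0, X.to_numpy())
    rank_c = stats.rankdata(cov.to_numpy())

    rng = np.random.default_rng(config.seed & 0x7FFFFFFF)
    n_perm = config.n_permutations
    perm_idx = np.stack([rng.permutation(n) for _ in range(n_perm)])
    perm_ranks = rank_c[perm_idx]                       # (n_perm, n)

    rho_obs = _rho_matrix(rank_x, rank_c[None, :])[0]   # (n_el,)
    rho_null = _rho_matrix(rank_x, perm_ranks)          # (n_perm, n_el)

    def _t(rho_arr):
        out = np.empty_like(rho_arr)
        flat = rho_arr.ravel()
        tflat = out.ravel()
        clipped = np.clip(flat, -0.9999999999, 0.9999999999)
        tflat[:] = clipped * np.sqrt((n - 2) / (1.0 - clipped ** 2))
        tflat[np.abs(flat) >= 1.0] = np.sign(flat[np.abs(flat) >= 1.0]) * T_CAP
        return out

    t_obs = pd.Series(_t(rho_obs), index=electrodes)
    t_null = _t(rho_null)

    if config.threshold_mode == "permutation":
        lo = float(np.quantile(t_null, config.lower_quantile))
        hi = float(np.quantile(t_null, config.upper_quantile))
        if lo == hi:
            raise ValueError("degenerate null distribution: all t values equal")
    else:
        hi = float(stats.t.ppf(config.upper_quantile, n - 2))
        lo = -hi

    def _clusters_of(t_map: pd.Series):
        pos = [e for e in electrodes if t_map[e] > hi]
        neg = [e for e in electrodes if t_map[e] < lo]
        out = []
        for members, mass in form_clusters(pos, t_map, adjacency,
                                           config.min_cluster_size):
            out.append((members, +1, mass))
        for members, mass in form_clusters(neg, t_map, adjacency,
                                           config.min_cluster_size):
            out.append((members, -1, mass))
        return out

    observed = _clusters_of(t_obs)
    null_max = np.zeros(n_perm)
    for k in range(n_perm):
        t_map_k = pd.Series(t_null[k], index=electrodes)
        clusters_k = _clusters_of(t_map_k)
        if clusters_k:
            null_max[k] = max(abs(mass) for _, _, mass in clusters_k)

    clusters = []
    for members, sign, mass in observed:
        b = int(np.sum(null_max >= abs(mass)))
        p = (b + 1) / (n_perm + 1)
        p_corr = min(1.0, p * n_covariates) if config.bonferroni_covariates else p
        clusters.append(Cluster(
            electrodes=members, sign=sign, mass=mass, p=p,
            p_corrected=p_corr, significant=p_corr < 0.05,
        ))
    clusters.sort(key=lambda c: c.p)
    return ClusterTestResult(
        covariate=covariate_name, clusters=clusters, n_permutations=n_perm,
        n_subjects=n, thresholds=(lo, hi), rho=pd.Series(rho_obs, index=electrodes),
        t=t_obs, seed=config.seed,
        permutation_matrix=perm_idx if keep_permutations else None,
    )


# ---------------------------------------------------------------------------
# covariate battery
# ---------------------------------------------------------------------------

#: Battery run against the theta contrast by default.
DEFAULT_BATTERY: tuple[str, ...] = (
    "total_gray_volume", "right_putamen", "right_insula",
    "surface_holes", "gose", "paracentral_thickness", "precentral_thickness",
)


def covariate_vector(name: str, morphometry: list[MorphometryRecord],
                     clinical: list[ClinicalRecord],
                     subjects: list[str]) -> pd.Series:
    """Build one named covariate across the given subjects."""
    morph = {m.subject_id: m for m in morphometry}
    clin = {c.subject_id: c for c in clinical}

    def _value(sid: str) -> float:
        if name == "total_gray_volume":
            return morph[sid].total_gray_volume
        if name == "surface_holes":
            return morph[sid].surface_holes
        if name == "gose":
            return float(clin[sid].gose)
        if name == "gcs":
            return float(clin[sid].gcs)
        if name.endswith("_thickness"):
            region = name[: -len("_thickness")]
            t = morph[sid].thickness
            vals = [t[h][region] for h in ("lh", "rh")
                    if h in t and region in t[h]]
            if not vals:
                raise KeyError(name)
            return float(np.mean(vals))
        key = name.replace("_", "-")
        if key in morph[sid].volumes:
            return morph[sid].volumes[key]
        raise KeyError(name)

    try:
        return pd.Series({sid: _value(sid) for sid in subjects}, name=name)
    except KeyError:
        available = ["total_gray_volume", "surface_holes", "gose", "gcs",
                     "<region>_thickness"]
        if morphometry:
            available += sorted(
                v.replace("-", "_") for v in morphometry[0].volumes)
        raise KeyError(
            f"unknown covariate {name!r}; available: {', '.join(available)}"
        ) from None


def run_covariate_battery(contrasts: pd.DataFrame,
                          morphometry: list[MorphometryRecord],
                          clinical: list[ClinicalRecord],
                          config: PermConfig = PermConfig(),
                          covariates=DEFAULT_BATTERY,
                          adjacency: nx.Graph | None = None
                          ) -> list[ClusterTestResult]:
    """One cluster-permutation test per covariate, Bonferroni across them.

    Covariate vectors are taken over the subjects present in ``contrasts``
    (the patient group).  Results are seed-reproducible: each covariate
    uses a sub-seed derived from the config seed and its battery position.
    """
    covariates = list(covariates)
    if not covariates:
        raise ValueError("covariate list is empty")
    if adjacency is None:
        adjacency = load_adjacency()
    subjects = list(contrasts.index)
    results = []
    for i, name in enumerate(covariates):
        vec = covariate_vector(name, morphometry, clinical, subjects)
        sub_config = PermConfig(
            n_permutations=config.n_permutations,
            lower_quantile=config.lower_quantile,
            upper_quantile=config.upper_quantile,
            min_cluster_size=config.min_cluster_size,
            threshold_mode=config.threshold_mode,
            bonferroni_covariates=config.bonferroni_covariates,
            seed=(config.seed * 1009 + i) & 0x7FFFFFFF,
        )
        results.append(
            permutation_test(contrasts, vec, sub_config, adjacency,
                             covariate_name=name, n_covariates=len(covariates))
        )
    return results


def cluster_table(results: list[ClusterTestResult]) -> pd.DataFrame:
    """Flatten battery results to one row per cluster (results schema)."""
    rows = []
    for res in results:
        for c in res.clusters:
            rows.append((res.covariate, ",".join(c.electrodes), c.sign,
                         c.mass, c.p, c.p_corrected, c.significant,
                         res.n_permutations, res.n_subjects))
    return pd.DataFrame(
        rows, columns=["covariate", "electrodes", "sign", "mass", "p",
                       "p_corrected", "significant", "n_permutations",
                       "n_subjects"],
    )


def correlation_map_text(result: ClusterTestResult) -> str:
    """Per-electrode rho/t with cluster-membership markers, as a text map."""
    significant = {e for c in result.significant_clusters() for e in c.electrodes}
    lines = [f"covariate: {result.covariate} (n={result.n_subjects}, "
             f"{result.n_permutations} permutations)"]
    for e in result.rho.index:
        star = " *" if e in significant else ""
        lines.append(f"  {e:>3s}  rho={result.rho[e]:+.3f}  "
                     f"t={result.t[e]:+.3f}{star}")
    return "\n".join(lines)
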