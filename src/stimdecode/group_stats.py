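"""Group-level inference on decoding scores.

Sensor space: a cluster-based Monte-Carlo permutation test across the three
stimulation protocols.  Per channel a dependent-samples one-way F statistic
(repeated-measures, subject as blocking factor) compares the within-subject
class scores; suprathreshold channels are clustered through the montage
neighbour graph, cluster mass (sum of F) is the cluster statistic, and the
null distribution of the maximum cluster mass is built by permuting class
labels within subjects.  Monte-Carlo p follows the (1 + #null >= observed) /
(1 + n_randomizations) convention and is never exactly zero.

Source/ROI space: Kruskal-Wallis across protocols per ROI with
Benjamini-Hochberg FDR over the ROI family, Wilcoxon signed-rank post-hocs,
and one-sided Wilcoxon tests of subject scores against the 1/3 chance level.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse, stats

from .exceptions import ConfigurationError, DegenerateDataError

logger = logging.getLogger(__name__)

CHANCE_LEVEL = 1.0 / 3.0


# ---------------------------------------------------------------------------
# Dependent-samples F and the cluster permutation test
# ---------------------------------------------------------------------------

def dependent_f(scores: np.ndarray) -> np.ndarray:
    """Repeated-measures one-way F across classes, per trailing item.

    ``scores`` has shape (n_subjects, n_classes, ...); subjects are the
    blocking factor.  Returns F with the leading two axes reduced.
    """
    x = np.asarray(scores, dtype=float)
    n, k = x.shape[0], x.shape[1]
    grand = x.mean(axis=(0, 1))
    ss_treat = n * ((x.mean(axis=0) - grand) ** 2).sum(axis=0)
    ss_subj = k * ((x.mean(axis=1) - grand) ** 2).sum(axis=0)
    ss_tot = ((x - grand) ** 2).sum(axis=(0, 1))
    ss_err = ss_tot - ss_treat - ss_subj
    df_t = k - 1
    df_e = (k - 1) * (n - 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        f = (ss_treat / df_t) / np.maximum(ss_err / df_e, 1e-300)
    return np.where(ss_err <= 1e-300, 0.0, f) if np.ndim(f) else float(f)


def _connected_clusters(mask: np.ndarray, adjacency: np.ndarray):
    """Connected components of suprathreshold channels in the neighbour graph."""
    idx = np.flatnonzero(mask)
    if len(idx) == 0:
        return []
    sub = adjacency[np.ix_(idx, idx)]
    n_comp, labels = sparse.csgraph.connected_components(
        sparse.csr_matrix(sub), directed=False)
    return [idx[labels == c] for c in range(n_comp)]


@dataclass
class ClusterResult:
    stat_map: np.ndarray
    threshold: float
    clusters: list[np.ndarray]
    cluster_mass: np.ndarray
    mc_p: np.ndarray
    n_randomizations: int
    channel_names: list[str] = field(default_factory=list)

    def significant(self, alpha: float = 0.05) -> list[np.ndarray]:
        return [c for c, p in zip(self.clusters, self.mc_p) if p < alpha]


def _max_cluster_mass(fmap, threshold, adjacency) -> float:
    clusters = _connected_clusters(fmap > threshold, adjacency)
    if not clusters:
        return 0.0
    return max(float(fmap[c].sum()) for c in clusters)


def cluster_permutation(scores: np.ndarray, adjacency: np.ndarray,
                        n_rand: int = 1000, seed=0,
                        threshold: float | None = None,
                        channel_names=None) -> ClusterResult:
    """Cluster-based Monte-Carlo permutation test over channels.

    ``scores``: (n_subjects, n_classes, n_channels); the test exchanges only
    the class labels within each subject, preserving subject structure.  The
    cluster-forming threshold defaults to the parametric 95th percentile of
    F(k-1, (k-1)(n-1)).
    """
    x = np.asarray(scores, dtype=float)
    n, k, n_ch = x.shape
    if n < 6:
        raise ConfigurationError("cluster test needs >= 6 subjects")
    if adjacency.shape != (n_ch, n_ch):
        raise ConfigurationError("adjacency does not match channel count")
    n_comp, _ = sparse.csgraph.connected_components(
        sparse.csr_matrix(adjacency), directed=False)
    if n_comp > 1:
        raise ConfigurationError("montage neighbour graph is disconnected")
    if n_rand < 100:
        warnings.warn("n_rand < 100 gives a coarse Monte-Carlo p",
                      stacklevel=2)
    if threshold is None:
        threshold = float(stats.f.ppf(0.95, k - 1, (k - 1) * (n - 1)))
    fmap = dependent_f(x)
    clusters = _connected_clusters(fmap > threshold, adjacency)
    mass = np.array([float(fmap[c].sum()) for c in clusters])

    rng = np.random.default_rng(seed)
    null = np.empty(n_rand)
    for r in range(n_rand):
        perm = x.copy()
        for s in range(n):  # independent within-subject label permutation
            perm[s] = perm[s, rng.permutation(k)]
        null[r] = _max_cluster_mass(dependent_f(perm), threshold, adjacency)
    mc_p = np.array([(1.0 + np.sum(null >= m)) / (1.0 + n_rand)
                     for m in mass])
    order = np.argsort(mass)[::-1]
    return ClusterResult(
        stat_map=fmap, threshold=threshold,
        clusters=[clusters[i] for i in order],
        cluster_mass=mass[order], mc_p=mc_p[order],
        n_randomizations=n_rand,
        channel_names=list(channel_names) if channel_names else [],
    )


def mean_power_contrast(delta_power: np.ndarray, adjacency: np.ndarray,
                        n_rand: int = 1000, seed=0,
                        threshold: float | None = None,
                        channel_names=None) -> ClusterResult:
    """Cluster permutation test on trial-averaged POST-PRE power.

    ``delta_power``: (n_subjects, n_classes, n_channels) of trial-averaged
    POST-PRE band power.  Identical machinery to :func:`cluster_permutation`;
    only the input quantity differs (raw power change instead of decoding
    scores).
    """
    return cluster_permutation(delta_power, adjacency, n_rand=n_rand,
                               seed=seed, threshold=threshold,
                               channel_names=channel_names)


# ---------------------------------------------------------------------------
# ROI-level nonparametric tests
# ---------------------------------------------------------------------------

def fdr(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (NaNs propagate)."""
    from statsmodels.stats.multitest import fdrcorrection

    p = np.asarray(p_values, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        out[ok] = fdrcorrection(p[ok])[1]
    return out


def kruskal_wallis(groups: list[np.ndarray]) -> tuple[float, float]:
    """Kruskal-Wallis H (midranks, tie-corrected) and chi-square p."""
    if any(len(g) < 3 for g in groups):
        raise ConfigurationError("Kruskal-Wallis needs >= 3 values per group")
    flat = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    if np.ptp(flat) == 0:
        return 0.0, 1.0
    h, p = stats.kruskal(*groups)
    return float(h), float(p)


def kruskal_wallis_roi(scores_by_roi: dict[str, np.ndarray]) -> pd.DataFrame:
    """Per-ROI Kruskal-Wallis across classes, BH-FDR over the ROI family.

    Values are (n_subjects, n_classes) arrays of scores.
    """
    rows = []
    for roi, vals in scores_by_roi.items():
        vals = np.asarray(vals, dtype=float)
        h, p = kruskal_wallis([vals[:, c] for c in range(vals.shape[1])])
        rows.append({"roi": roi, "H": h, "p_raw": p})
    out = pd.DataFrame(rows)
    out["p_fdr"] = fdr(out["p_raw"].to_numpy())
    return out


def wilcoxon_signed_rank(a: np.ndarray, b: np.ndarray | float,
                         alternative: str = "two-sided") -> tuple[float, float]:
    """Wilcoxon signed-rank Z and p (normal approximation, zeros dropped)."""
    a = np.asarray(a, dtype=float)
    b = np.broadcast_to(np.asarray(b, dtype=float), a.shape)
    d = a - b
    d = d[d != 0]
    if len(d) == 0:
        raise DegenerateDataError("all paired differences are zero")
    if len(d) < 5:
        raise ConfigurationError("signed-rank test needs >= 5 nonzero pairs")
    res = stats.wilcoxon(d, alternative=alternative, method="approx",
                         correction=False)
    return float(res.zstatistic), float(res.pvalue)


@dataclass
class PairwiseResult:
    table: pd.DataFrame  # columns: comparison, Z, p_raw, p_fdr


def wilcoxon_posthocs(scores: np.ndarray, class_names: list[str]) -> PairwiseResult:
    """All pairwise signed-rank post-hocs with FDR over the pair family."""
    x = np.asarray(scores, dtype=float)
    rows = []
    k = x.shape[1]
    for i in range(k):
        for j in range(i + 1, k):
            try:
                z, p = wilcoxon_signed_rank(x[:, i], x[:, j])
            except DegenerateDataError:
                z, p = np.nan, np.nan
            rows.append({"comparison": f"{class_names[i]} vs {class_names[j]}",
                         "Z": z, "p_raw": p})
    out = pd.DataFrame(rows)
    out["p_fdr"] = fdr(out["p_raw"].to_numpy())
    return PairwiseResult(table=out)


def chance_test(scores: np.ndarray, chance: float = CHANCE_LEVEL,
                labels=None) -> pd.DataFrame:
    """One-sided (greater) signed-rank test of subject scores against chance.

    ``scores``: (n_subjects, n_items) with one column per channel or ROI.
    Degenerate columns (all exactly at chance) are flagged with NaN.
    BH-FDR across the tested family.
    """
    x = np.atleast_2d(np.asarray(scores, dtype=float))
    if x.shape[0] < 6:
        raise ConfigurationError("chance test needs >= 6 subjects")
    p_raw = np.empty(x.shape[1])
    for i in range(x.shape[1]):
        try:
            _, p_raw[i] = wilcoxon_signed_rank(x[:, i], chance,
                                               alternative="greater")
        except DegenerateDataError:
            logger.warning("column %d identical to chance; flagged", i)
            p_raw[i] = np.nan
    out = pd.DataFrame({
        "item": labels if labels is not None else np.arange(x.shape[1]),
        "p_raw": p_raw,
        "p_fdr": fdr(p_raw),
    })
    return out


# ---------------------------------------------------------------------------
# Correlations
# ---------------------------------------------------------------------------

def band_correlation(x: np.ndarray, y: np.ndarray,
                     method: str = "pearson") -> tuple[float, float]:
    """Correlation of per-subject band scores (e.g. theta F1 vs alpha F1)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 5:
        raise ConfigurationError("correlation needs matched n >= 5")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateDataError("constant input: correlation undefined")
    if method == "pearson":
        r, p = stats.pearsonr(x, y)
    elif method == "spearman":
        r, p = stats.spearmanr(x, y)
    else:
        raise ConfigurationError(f"unknown correlation method {method!r}")
    return float(r), float(p)


def compare_correlations(r1: float, n1: int, r2: float, n2: int) -> tuple[float, float]:
    """Fisher-Z comparison of two independent correlations.

    Z = (atanh(r1) - atanh(r2)) / sqrt(1/(n1-3) + 1/(n2-3)), two-sided p.
    """
    for r in (r1, r2):
        if not -1 < r < 1:
            raise ConfigurationError("|r| must be < 1 for the Fisher transform")
    if min(n1, n2) < 4:
        raise ConfigurationError("need n > 3 in both samples")
    z = (np.arctanh(r1) - np.arctanh(r2)) / np.sqrt(
        1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    p = 2 * stats.norm.sf(abs(z))
    return float(z), float(p)
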