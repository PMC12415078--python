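"""Mechanochemical statistics: join Brillouin fits to Raman clusters and
compare viscoelastic parameters across biochemical groups.

Group comparisons use unequal-variance (Welch) procedures throughout: a
Welch t-test for two groups, Welch's ANOVA for three or more, and the
Games-Howell procedure for pairwise post-hoc comparisons.  The Brillouin
loss tangent BLT = Gamma_B / nu_B = M''/M' is computed per point and then
medianized per cluster (the ratio of medians is reported alongside, since
the two aggregations differ slightly).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats as sps

__all__ = ["join_colocalized", "cluster_medians", "welch_omnibus",
           "pairwise_comparisons", "shift_width_correlation",
           "build_histogram", "OmnibusResult", "HistogramSummary"]


@dataclass
class OmnibusResult:
    test: str          # "welch_anova" | "welch_t"
    statistic: float   # F or t
    df1: float
    df2: float
    p_value: float


@dataclass
class HistogramSummary:
    """Fixed-width histogram (default 50 MHz bins anchored at 0 GHz)."""
    bin_edges: np.ndarray
    counts: np.ndarray
    mode_bin_center: float

    @property
    def n_observations(self) -> int:
        return int(self.counts.sum())


def join_colocalized(brillouin_fits: pd.DataFrame,
                     cluster_labels: pd.DataFrame) -> pd.DataFrame:
    """Join per-point Brillouin fits to Raman cluster labels by point id.

    ``brillouin_fits`` needs columns (point, nu_B, gamma_B, valid);
    ``cluster_labels`` needs (point, cluster).  Invalid fits and discarded
    clusters (label -1) are excluded; the number of exclusions is recorded
    in ``DataFrame.attrs``.  Point sets must otherwise correspond one-to-one.
    """
    fits = brillouin_fits.copy()
    labels = cluster_labels.copy()
    missing = set(fits["point"]).symmetric_difference(set(labels["point"]))
    if missing:
        raise ValueError(
            f"position mismatch between fits and labels for points: "
            f"{sorted(missing)[:10]}")
    joined = fits.merge(labels, on="point", how="inner")
    n_invalid = int((~joined["valid"]).sum())
    n_offtarget = int((joined["cluster"] < 0).sum() if "cluster" in joined
                      else 0)
    joined = joined[joined["valid"] & (joined["cluster"] >= 0)].copy()
    joined["blt"] = joined["gamma_B"] / joined["nu_B"]
    joined = joined.sort_values("point", kind="stable").reset_index(drop=True)
    out = joined[["point", "cluster", "nu_B", "gamma_B", "blt"]]
    out.attrs["n_excluded_invalid"] = n_invalid
    out.attrs["n_excluded_offtarget"] = n_offtarget
    return out


def cluster_medians(joined: pd.DataFrame) -> pd.DataFrame:
    """Per-cluster n and medians of nu_B, Gamma_B and BLT.

    ``median_blt`` is the median of per-point BLT values;
    ``blt_of_medians`` = median(Gamma_B)/median(nu_B) is reported for
    comparison (the two differ in general).
    """
    g = joined.groupby("cluster")
    out = pd.DataFrame({
        "n": g.size(),
        "median_nu_B": g["nu_B"].median(),
        "median_gamma_B": g["gamma_B"].median(),
        "median_blt": g["blt"].median(),
    })
    out["blt_of_medians"] = out["median_gamma_B"] / out["median_nu_B"]
    return out


def _welch_anova(groups: list[np.ndarray]) -> OmnibusResult:
    # Welch (1951) heteroscedastic one-way ANOVA:
    #   w_i = n_i / s_i^2,  W = sum w_i,  xbar_w = sum w_i xbar_i / W
    #   A = sum w_i (xbar_i - xbar_w)^2 / (k - 1)
    #   L = sum (1 - w_i/W)^2 / (n_i - 1)
    #   F = A / (1 + 2 (k - 2) L / (k^2 - 1)),  df2 = (k^2 - 1) / (3 L)
    k = len(groups)
    n = np.array([g.size for g in groups], dtype=float)
    m = np.array([g.mean() for g in groups])
    v = np.array([g.var(ddof=1) for g in groups])
    w = n / v
    bw = w.sum()
    mw = np.sum(w * m) / bw
    a = np.sum(w * (m - mw) ** 2) / (k - 1)
    lam = np.sum((1 - w / bw) ** 2 / (n - 1))
    f = a / (1.0 + 2.0 * (k - 2) * lam / (k ** 2 - 1))
    df1 = k - 1
    df2 = (k ** 2 - 1) / (3.0 * lam)
    p = float(sps.f.sf(f, df1, df2))
    return OmnibusResult("welch_anova", float(f), float(df1), float(df2), p)


def welch_omnibus(joined: pd.DataFrame,
                  variable: str = "nu_B") -> OmnibusResult:
    """Omnibus comparison of ``variable`` across clusters.

    Two clusters: Welch's unequal-variance t-test (Welch-Satterthwaite
    degrees of freedom).  Three or more: Welch's ANOVA.
    """
    groups = [g[variable].to_numpy()
              for _, g in joined.groupby("cluster")]
    if len(groups) < 2:
        raise ValueError("need at least 2 clusters")
    for g in groups:
        if g.size < 2:
            raise ValueError("every cluster needs >= 2 points")
        if g.var(ddof=1) == 0:
            raise ValueError("zero-variance group: Welch statistics "
                             "undefined (all values identical)")
    if len(groups) == 2:
        t, p = sps.ttest_ind(groups[0], groups[1], equal_var=False)
        n1, n2 = groups[0].size, groups[1].size
        v1, v2 = groups[0].var(ddof=1), groups[1].var(ddof=1)
        df = (v1 / n1 + v2 / n2) ** 2 / (
            (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
        return OmnibusResult("welch_t", float(t), 1.0, float(df), float(p))
    return _welch_anova(groups)


def pairwise_comparisons(joined: pd.DataFrame,
                         variable: str = "nu_B") -> pd.DataFrame:
    """Games-Howell pairwise comparisons (unequal variances, studentized
    range reference) between clusters.

    For two clusters this reduces to the Welch t-test, returned in the same
    tabular shape.  The method name is recorded in the ``method`` column.
    """
    clusters = sorted(joined["cluster"].unique())
    if len(clusters) < 2:
        raise ValueError("need at least 2 clusters")
    if len(clusters) == 2:
        res = welch_omnibus(joined, variable)
        return pd.DataFrame([{
            "A": clusters[0], "B": clusters[1], "statistic": res.statistic,
            "df": res.df2, "p_adjust": res.p_value, "method": "welch_t",
        }])
    gh = pg.pairwise_gameshowell(data=joined, dv=variable, between="cluster")
    out = gh.rename(columns={"T": "statistic", "pval": "p_adjust"})[
        ["A", "B", "statistic", "df", "p_adjust"]].copy()
    out["method"] = "games_howell"
    return out


def shift_width_correlation(joined: pd.DataFrame,
                            by_cluster: bool = True) -> pd.DataFrame:
    """Pearson correlation of (nu_B, Gamma_B), per cluster or pooled.

    Poor correlation indicates that linewidth variation is dominated by
    heterogeneous broadening rather than genuine viscosity change.  Groups
    with fewer than 3 points or zero variance are flagged undefined.
    """
    def one(df, name):
        x, y = df["nu_B"].to_numpy(), df["gamma_B"].to_numpy()
        tiny = 1e-12
        if x.size < 3 or x.std() <= tiny * max(1.0, np.abs(x).max()) or \
                y.std() <= tiny * max(1.0, np.abs(y).max()):
            return {"cluster": name, "n": x.size, "r": np.nan,
                    "p_value": np.nan, "defined": False}
        r, p = sps.pearsonr(x, y)
        return {"cluster": name, "n": x.size, "r": float(r),
                "p_value": float(p), "defined": True}

    if by_cluster:
        rows = [one(g, c) for c, g in joined.groupby("cluster")]
    else:
        rows = [one(joined, "all")]
    return pd.DataFrame(rows)


def build_histogram(values, bin_width: float = 0.05) -> HistogramSummary:
    """Histogram with fixed-width bins anchored at 0 GHz.

    Bins are half-open [lo, hi): a value exactly on an edge counts in the
    right-hand bin.  The default 0.05 GHz width matches the standard
    50 MHz presentation of Brillouin shift/width distributions.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("no values to histogram")
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    idx = np.floor(values / bin_width).astype(int)
    lo, hi = idx.min(), idx.max()
    counts = np.bincount(idx - lo, minlength=hi - lo + 1)
    edges = np.arange(lo, hi + 2) * bin_width
    mode_center = (lo + int(np.argmax(counts)) + 0.5) * bin_width
    return HistogramSummary(bin_edges=edges, counts=counts,
                            mode_bin_center=float(mode_center))
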