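"""Replicate-core density/biomass aggregation and comparison statistics.

The sampling design is a set of replicate sediment sub-cores per site,
each sliced into 0-5 cm and 5-10 cm horizons and sorted to per-taxon
counts and carbon/nitrogen biomass.  This module scales per-core totals to
areal units (ind. m⁻², mg m⁻²), averages over replicate cores (mean ± SE,
n = cores), pools sediment layers, derives relative composition and
feeding-guild tables, screens for megafaunal outliers, and runs the
site/guild comparison statistics (Welch/Student t, Mann-Whitney U,
one-/two-way ANOVA, Kruskal-Wallis, with an in-repo Welch ANOVA and
Games-Howell post hoc).

Core tables are pandas DataFrames with columns
``core_id, site, layer, taxon, guild, count, c_biomass_mg, n_biomass_mg,
area_m2, fragment_flag``; one row per core × layer × taxon.  Headless
specimens and unidentified fragments carry ``fragment_flag=True``: they are
excluded from density but included in biomass.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import studentized_range

from .trophic import round_half_up

__all__ = [
    "CORE_TABLE_COLUMNS",
    "CoreSample",
    "SiteSummary",
    "ComparisonReport",
    "cores_to_frame",
    "read_core_table",
    "densities",
    "pool_layer_means",
    "exclude_megafauna",
    "composition",
    "compare_groups",
    "games_howell",
    "welch_anova",
    "sediment_descriptors",
]

CORE_TABLE_COLUMNS = (
    "core_id",
    "site",
    "layer",
    "taxon",
    "guild",
    "count",
    "c_biomass_mg",
    "n_biomass_mg",
    "area_m2",
    "fragment_flag",
)

_METRICS = {
    "density": ("count", "density"),
    "c_biomass": ("c_biomass_mg", "c_biomass"),
    "n_biomass": ("n_biomass_mg", "n_biomass"),
}


@dataclass(frozen=True)
class CoreSample:
    """Per-core, per-layer, per-taxon record with the core's sampled area."""

    core_id: str
    site: str
    layer: str
    taxon: str
    count: float
    c_biomass_mg: float
    n_biomass_mg: float
    area_m2: float
    guild: str = "unknown"
    fragment_flag: bool = False

    def __post_init__(self) -> None:
        if self.area_m2 <= 0:
            raise ValueError(f"core {self.core_id!r}: area must be positive")
        if self.count < 0 or self.c_biomass_mg < 0 or self.n_biomass_mg < 0:
            raise ValueError(f"core {self.core_id!r}: negative count/biomass")


def cores_to_frame(samples: Iterable[CoreSample]) -> pd.DataFrame:
    return pd.DataFrame(
        [{c: getattr(s, c) for c in CORE_TABLE_COLUMNS} for s in samples],
        columns=list(CORE_TABLE_COLUMNS),
    )


def read_core_table(path, delimiter: str = ",") -> pd.DataFrame:
    """Read a delimited core table and validate its schema."""
    df = pd.read_csv(path, sep=delimiter, skipinitialspace=True)
    missing = [c for c in CORE_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s): {missing}")
    _validate_cores(df)
    return df


def _validate_cores(cores: pd.DataFrame) -> None:
    missing = [c for c in CORE_TABLE_COLUMNS if c not in cores.columns]
    if missing:
        raise ValueError(f"core table missing required column(s): {missing}")
    if len(cores) and (cores["area_m2"] <= 0).any():
        raise ValueError("core areas must be positive")
    if len(cores) and (
        (cores["count"] < 0).any()
        or (cores[["c_biomass_mg", "n_biomass_mg"]] < 0).to_numpy().any()
    ):
        raise ValueError("counts and biomass must be non-negative")


@dataclass
class SiteSummary:
    """Pooled density/biomass summary for one site.

    ``table`` has one row per sediment layer plus a pooled 0-10 cm row,
    with mean and SE columns for density (ind. m⁻²) and C/N biomass
    (mg m⁻²); SEs are over the ``n_cores`` replicate cores.
    """

    site: str
    n_cores: int
    table: pd.DataFrame
    composition: pd.DataFrame | None = None
    guild_table: pd.DataFrame | None = None


def densities(cores: pd.DataFrame, pooling: str = "layer-means") -> SiteSummary:
    """Aggregate a single-site core table to areal density and biomass.

    Per-core layer totals are scaled by 1/area to ind. m⁻² and mg m⁻²,
    then averaged over replicate cores (mean ± SE).  The pooled 0-10 cm
    value is the sum of the layer means (``pooling="layer-means"``, the
    convention behind published site totals), or the mean of per-core
    pooled totals (``pooling="per-core"``; equivalent only when every core
    has every layer).  Fragment-flagged rows contribute to biomass but not
    to density.
    """
    _validate_cores(cores)
    if len(cores) == 0:
        raise ValueError("densities requires at least one core")
    sites = cores["site"].unique()
    if len(sites) != 1:
        raise ValueError(f"densities expects a single site, got {sorted(sites)}")
    if pooling not in ("layer-means", "per-core"):
        raise ValueError(f"unknown pooling rule {pooling!r}")

    core_ids = sorted(cores["core_id"].unique())
    layers = sorted(cores["layer"].unique())
    area = cores.groupby("core_id")["area_m2"].first()

    per = pd.DataFrame(
        index=pd.MultiIndex.from_product(
            [core_ids, layers], names=["core_id", "layer"]
        )
    )
    grouped = cores.groupby(["core_id", "layer"])
    countable = cores[~cores["fragment_flag"].astype(bool)]
    per["density"] = countable.groupby(["core_id", "layer"])["count"].sum()
    per["c_biomass"] = grouped["c_biomass_mg"].sum()
    per["n_biomass"] = grouped["n_biomass_mg"].sum()
    per = per.fillna(0.0)
    per = per.div(area.reindex(per.index.get_level_values("core_id")).values, axis=0)

    n = len(core_ids)
    rows = {}
    for layer in layers:
        sub = per.xs(layer, level="layer")
        rows[layer] = _mean_se_row(sub, n)
    if pooling == "layer-means":
        pooled = {
            f"{m}_mean": sum(rows[l][f"{m}_mean"] for l in layers) for m in per.columns
        }
        pooled.update({f"{m}_se": np.nan for m in per.columns})
    else:
        sub = per.groupby(level="core_id").sum()
        pooled = _mean_se_row(sub, n)
    rows["0-10 cm (pooled)"] = pooled

    table = pd.DataFrame(rows).T
    table.index.name = "layer"
    return SiteSummary(site=str(sites[0]), n_cores=n, table=table)


def _mean_se_row(sub: pd.DataFrame, n: int) -> dict:
    out = {}
    for m in sub.columns:
        v = sub[m].to_numpy()
        out[f"{m}_mean"] = float(v.mean())
        out[f"{m}_se"] = float(v.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    return out


def pool_layer_means(layer_means: Iterable[float]) -> float:
    """Pool sediment layers by summing per-layer mean areal values."""
    return float(np.sum(list(layer_means)))


def exclude_megafauna(
    cores: pd.DataFrame, k: float = 10.0
) -> tuple[pd.DataFrame, dict]:
    """Screen out megafaunal outliers by an order-of-magnitude rule.

    Individual C biomass (record biomass / count) is ranked; the top
    records are excluded when each is more than ``k`` times the largest
    remaining individual, i.e. the exclusion set is the prefix above the
    first factor-``k`` gap in the ranked individual biomasses.  A table
    with a single ranked record has no comparison basis and nothing is
    excluded.  Returns the filtered table and an exclusion report carrying
    the excluded rows and their aggregate areal biomass.
    """
    _validate_cores(cores)
    ranked = cores[cores["count"] > 0].copy()
    ranked["_indiv"] = ranked["c_biomass_mg"] / ranked["count"]
    ranked = ranked.sort_values("_indiv", ascending=False)
    b = ranked["_indiv"].to_numpy()

    cut = 0
    for i in range(len(b) - 1):
        if b[i] > k * b[i + 1] and b[i + 1] > 0:
            cut = i + 1
            break
    excluded_idx = ranked.index[:cut]
    excluded = cores.loc[excluded_idx]
    kept = cores.drop(index=excluded_idx)
    report = {
        "n_excluded": int(excluded["count"].sum()),
        "excluded": excluded,
        "c_biomass_per_m2": float(
            (excluded["c_biomass_mg"] / excluded["area_m2"]).sum()
        ),
        "n_biomass_per_m2": float(
            (excluded["n_biomass_mg"] / excluded["area_m2"]).sum()
        ),
        "threshold_factor": k,
    }
    return kept, report


def composition(cores: pd.DataFrame, level: str = "taxon") -> pd.DataFrame:
    """Relative density and C/N-biomass shares (%) per taxon or guild.

    Fragment-flagged rows (headless specimens, unidentified fragments) are
    excluded from the density shares but included in the biomass shares.
    Shares of each column sum to 100% up to rounding.
    """
    _validate_cores(cores)
    if level not in ("taxon", "guild"):
        raise ValueError(f"unknown composition level {level!r}; use 'taxon' or 'guild'")
    if len(cores) == 0:
        raise ValueError("composition requires a non-empty core table")

    not_frag = ~cores["fragment_flag"].astype(bool)
    dens = cores[not_frag].groupby(level)["count"].sum()
    cb = cores.groupby(level)["c_biomass_mg"].sum()
    nb = cores.groupby(level)["n_biomass_mg"].sum()
    out = pd.DataFrame(
        {
            "density_pct": 100.0 * dens / dens.sum() if dens.sum() > 0 else 0.0,
            "c_biomass_pct": 100.0 * cb / cb.sum() if cb.sum() > 0 else 0.0,
            "n_biomass_pct": 100.0 * nb / nb.sum() if nb.sum() > 0 else 0.0,
        }
    ).fillna(0.0)
    out.index.name = level
    return out.sort_values("density_pct", ascending=False)


def sediment_descriptors(chl_a: float, phaeo: float) -> dict:
    """Sediment pigment arithmetic: total pigments and chl-a/phaeo ratio.

    The ratio is reported half-up at two decimals; a zero phaeopigment
    concentration leaves it undefined (NaN).
    """
    if chl_a < 0 or phaeo < 0:
        raise ValueError("pigment concentrations must be non-negative")
    ratio = chl_a / phaeo if phaeo > 0 else float("nan")
    return {
        "total_pigments": chl_a + phaeo,
        "chl_phaeo_ratio": round_half_up(ratio, 2) if phaeo > 0 else float("nan"),
        "chl_phaeo_ratio_raw": ratio,
    }


# ----------------------------------------------------------------------
# comparison statistics


@dataclass
class ComparisonReport:
    """Result of a group comparison: chosen path, statistic, checks."""

    design: str
    path: str
    statistic: float
    df: float | tuple | None
    pvalue: float
    shapiro_p: float | None = None
    levene_p: float | None = None
    log10_applied: bool = False
    posthoc: pd.DataFrame | None = None
    table: pd.DataFrame | None = None
    warnings: list[str] = field(default_factory=list)


def compare_groups(
    data: Mapping[str, Sequence[float]] | pd.DataFrame,
    design: str = "one-way",
    *,
    welch: bool | None = None,
    nonparametric: bool = False,
    log10_transform: bool = False,
    posthoc: bool = False,
    factors: tuple[str, str] | None = None,
    value: str = "value",
    alpha: float = 0.05,
) -> ComparisonReport:
    """Compare groups with the design-appropriate test.

    For ``two-sample`` and ``one-way`` designs, ``data`` maps group label
    to values.  Residual normality is checked with Shapiro-Wilk and
    variance homogeneity with a Levene test (median-centred); parametric
    paths fall back to Welch corrections under heteroscedasticity and to
    rank tests (Mann-Whitney U / Kruskal-Wallis) under non-normality or on
    request.  For ``two-way``, ``data`` is a long DataFrame and ``factors``
    names the two fixed-factor columns; main effects and their interaction
    come from an OLS fit with a type-II ANOVA table.  ``posthoc=True``
    appends a Games-Howell pairwise table.
    """
    if design == "two-way":
        return _two_way(data, factors, value, log10_transform)
    if not isinstance(data, Mapping):
        raise TypeError("two-sample/one-way designs take a mapping of group -> values")
    labels = list(data)
    groups = [np.asarray(data[g], dtype=float) for g in labels]
    if len(groups) < 2:
        raise ValueError("at least two groups are required")
    if design == "two-sample" and len(groups) != 2:
        raise ValueError("two-sample design requires exactly two groups")
    if design not in ("two-sample", "one-way"):
        raise ValueError(f"unknown design {design!r}")

    warns: list[str] = []
    if log10_transform:
        if any((g <= 0).any() for g in groups):
            raise ValueError("log10 transform requires strictly positive values")
        groups = [np.log10(g) for g in groups]

    if any(len(g) < 2 for g in groups) and not nonparametric:
        warns.append("group with fewer than 2 values: using nonparametric path")
        nonparametric = True
    if not nonparametric and any(np.var(g, ddof=1) == 0 for g in groups):
        warns.append("degenerate zero-variance group: falling back to nonparametric")
        warnings.warn(warns[-1], stacklevel=2)
        nonparametric = True

    shapiro_p = levene_p = None
    normal = homogeneous = True
    if not nonparametric:
        residuals = np.concatenate([g - g.mean() for g in groups])
        if 3 <= len(residuals) <= 5000:
            shapiro_p = float(stats.shapiro(residuals).pvalue)
            normal = shapiro_p > alpha
        levene_p = float(stats.levene(*groups, center="median").pvalue)
        homogeneous = levene_p > alpha

    if nonparametric or not normal:
        if design == "two-sample":
            res = stats.mannwhitneyu(groups[0], groups[1], alternative="two-sided")
            path, statistic, dof = "mann-whitney", float(res.statistic), None
        else:
            res = stats.kruskal(*groups)
            path, statistic, dof = "kruskal-wallis", float(res.statistic), len(groups) - 1
        pvalue = float(res.pvalue)
    elif design == "two-sample":
        use_welch = welch if welch is not None else not homogeneous
        res = stats.ttest_ind(groups[0], groups[1], equal_var=not use_welch)
        path = "welch-t" if use_welch else "student-t"
        statistic, pvalue = float(res.statistic), float(res.pvalue)
        dof = float(res.df)
    else:
        use_welch = welch if welch is not None else not homogeneous
        if use_welch:
            statistic, dof, pvalue = welch_anova(groups)
            path = "welch-anova"
        else:
            res = stats.f_oneway(*groups)
            statistic, pvalue = float(res.statistic), float(res.pvalue)
            dof = (len(groups) - 1, sum(len(g) for g in groups) - len(groups))
            path = "anova"

    report = ComparisonReport(
        design=design,
        path=path,
        statistic=statistic,
        df=dof,
        pvalue=pvalue,
        shapiro_p=shapiro_p,
        levene_p=levene_p,
        log10_applied=log10_transform,
        warnings=warns,
    )
    if posthoc:
        report.posthoc = games_howell({l: g for l, g in zip(labels, groups)})
    return report


def _two_way(data, factors, value, log10_transform):
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    if factors is None or len(factors) != 2:
        raise ValueError("two-way design requires factors=(a, b)")
    if not isinstance(data, pd.DataFrame):
        raise TypeError("two-way design takes a long-format DataFrame")
    a, b = factors
    df = data[[value, a, b]].rename(columns={value: "y", a: "fa", b: "fb"}).copy()
    if log10_transform:
        if (df["y"] <= 0).any():
            raise ValueError("log10 transform requires strictly positive values")
        df["y"] = np.log10(df["y"])
    fit = smf.ols("y ~ C(fa) * C(fb)", data=df).fit()
    table = sm.stats.anova_lm(fit, typ=2)
    resid = fit.resid.to_numpy()
    shapiro_p = float(stats.shapiro(resid).pvalue) if 3 <= len(resid) <= 5000 else None
    inter = table.index[table.index.str.contains(":")][0]
    return ComparisonReport(
        design="two-way",
        path="ols-anova-typ2",
        statistic=float(table.loc[inter, "F"]),
        df=(float(table.loc[inter, "df"]), float(table.loc["Residual", "df"])),
        pvalue=float(table.loc[inter, "PR(>F)"]),
        shapiro_p=shapiro_p,
        log10_applied=log10_transform,
        table=table,
    )


def welch_anova(groups: Sequence[np.ndarray]) -> tuple[float, tuple, float]:
    """Welch's heteroscedastic one-way ANOVA (F*, (df1, df2), p)."""
    k = len(groups)
    n = np.array([len(g) for g in groups], dtype=float)
    m = np.array([np.mean(g) for g in groups])
    v = np.array([np.var(g, ddof=1) for g in groups])
    w = n / v
    mw = np.sum(w * m) / np.sum(w)
    a = np.sum(w * (m - mw) ** 2) / (k - 1)
    lam = np.sum((1 - w / np.sum(w)) ** 2 / (n - 1))
    f = a / (1 + 2 * (k - 2) / (k**2 - 1) * lam)
    df1 = k - 1
    df2 = (k**2 - 1) / (3 * lam)
    p = float(stats.f.sf(f, df1, df2))
    return float(f), (float(df1), float(df2)), p


def _gh_q_df(means, variances, ns):
    """Vectorized Games-Howell pairwise q statistics and Welch df.

    ``means``, ``variances``, ``ns`` have shape (..., k); returns
    ``(pairs, q, df)`` where ``q`` and ``df`` have shape (..., n_pairs).
    The q statistic is |t|·√2 with t the Welch t for the pair, referred to
    the studentized-range distribution with k groups.
    """
    means = np.asarray(means, dtype=float)
    variances = np.asarray(variances, dtype=float)
    ns = np.asarray(ns, dtype=float)
    k = means.shape[-1]
    pairs = list(itertools.combinations(range(k), 2))
    i = np.array([p[0] for p in pairs])
    j = np.array([p[1] for p in pairs])
    vi = variances[..., i] / ns[..., i]
    vj = variances[..., j] / ns[..., j]
    se2 = vi + vj
    t = (means[..., i] - means[..., j]) / np.sqrt(se2)
    df = se2**2 / (vi**2 / (ns[..., i] - 1) + vj**2 / (ns[..., j] - 1))
    q = np.abs(t) * np.sqrt(2.0)
    return pairs, q, df


def games_howell(groups: Mapping[str, Sequence[float]]) -> pd.DataFrame:
    """Games-Howell post-hoc pairwise comparisons.

    Pairwise Welch t statistics are referred to the studentized-range
    distribution with the number of groups and Welch-adjusted df, which
    controls the family-wise error rate under unequal variances.  With two
    groups the p-value coincides with the two-sided Welch t-test.
    """
    labels = list(groups)
    arrs = [np.asarray(groups[g], dtype=float) for g in labels]
    if len(arrs) < 2:
        raise ValueError("games_howell requires at least two groups")
    if any(len(a) < 2 for a in arrs):
        raise ValueError("games_howell requires at least two values per group")
    k = len(arrs)
    means = np.array([a.mean() for a in arrs])
    variances = np.array([a.var(ddof=1) for a in arrs])
    ns = np.array([len(a) for a in arrs])
    pairs, q, df = _gh_q_df(means, variances, ns)
    pvals = studentized_range.sf(q, k, df)
    rows = []
    for (i, j), qq, dd, pp in zip(pairs, q, df, np.atleast_1d(pvals)):
        se = np.sqrt(variances[i] / ns[i] + variances[j] / ns[j])
        rows.append(
            {
                "group_a": labels[i],
                "group_b": labels[j],
                "mean_diff": means[i] - means[j],
                "se": se,
                "t": (means[i] - means[j]) / se,
                "df": dd,
                "pvalue": float(np.clip(pp, 0.0, 1.0)),
            }
        )
    return pd.DataFrame(rows)
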