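"""Trait statistics: variance components and heritability, segregation
chi-square tests, marker-trait t-test profiles, and NIL similarity.

Heritability uses the multi-environment entry-mean formula
h2 = var(Line) / [var(Line) + var(Line:Loc)/e + var(Line:Year)/r
+ var(Residual)/(r e)], with e locations and r years.  Variance components
for the crossed line x location x year x replicate model come from
expected-mean-squares (ANOVA method-of-moments) estimation, which matches
restricted-likelihood estimates on the balanced designs the simulator
produces; negative estimates are clipped to zero and flagged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "VarianceComponents",
    "SegregationTestResult",
    "fit_variance_components",
    "heritability",
    "chi_square_ratio_test",
    "marker_trait_profile",
    "nil_similarity",
]


@dataclass
class VarianceComponents:
    """Estimated variance components (trait units squared)."""

    var_line: float
    var_line_loc: float
    var_line_year: float
    var_residual: float
    n_locations: int
    n_years: int
    n_reps: float
    clipped: list[str] = field(default_factory=list)


@dataclass
class SegregationTestResult:
    """Pearson chi-square test of observed class counts against a ratio."""

    observed: tuple[int, ...]
    expected: tuple[float, ...]
    chi2: float
    df: int
    p_value: float


def fit_variance_components(
    phenotypes: pd.DataFrame,
    line_col: str = "line",
    loc_col: str = "location",
    year_col: str = "year",
    value_col: str = "value",
) -> VarianceComponents:
    """Method-of-moments variance components of the crossed mixed model
    value = Line + Loc + Year + Line:Loc + Line:Year + error.

    Line, Line:Loc, Line:Year and the residual are random; location and year
    are treated as fixed and absorbed by the interaction contrasts.  Requires
    a (near-)balanced design; with a single replicate per line-location-year
    cell the three-way variation serves as the residual.  Negative estimates
    are clipped to 0 and recorded in ``clipped``.
    """
    df = phenotypes[[line_col, loc_col, year_col, value_col]].dropna()
    lines = df[line_col].unique()
    locs = df[loc_col].unique()
    years = df[year_col].unique()
    a, e, r = len(lines), len(locs), len(years)
    if a < 2:
        raise ValueError("need at least two lines to estimate var(Line)")
    cell_sizes = df.groupby([line_col, loc_col, year_col], observed=True)[value_col].size()
    m = float(cell_sizes.mean())
    if cell_sizes.nunique() > 1:
        warnings.warn(
            "unbalanced design: using mean cell size in expected mean squares "
            "(method-of-moments estimates are approximate)"
        )
    if df[value_col].nunique() == 1:
        return VarianceComponents(0.0, 0.0, 0.0, 0.0, e, r, m)

    grand = df[value_col].mean()
    line_means = df.groupby(line_col, observed=True)[value_col].mean()
    loc_means = df.groupby(loc_col, observed=True)[value_col].mean()
    year_means = df.groupby(year_col, observed=True)[value_col].mean()
    ll_means = df.groupby([line_col, loc_col], observed=True)[value_col].mean()
    ly_means = df.groupby([line_col, year_col], observed=True)[value_col].mean()
    cell_means = df.groupby([line_col, loc_col, year_col], observed=True)[value_col].mean()

    ms_line = e * r * m * float(line_means.var(ddof=1))

    ll = ll_means.reset_index()
    ll["dev"] = (
        ll[value_col]
        - line_means.reindex(ll[line_col]).to_numpy()
        - loc_means.reindex(ll[loc_col]).to_numpy()
        + grand
    )
    ms_line_loc = r * m * float((ll["dev"] ** 2).sum()) / max((a - 1) * (e - 1), 1) if e > 1 else np.nan

    ly = ly_means.reset_index()
    ly["dev"] = (
        ly[value_col]
        - line_means.reindex(ly[line_col]).to_numpy()
        - year_means.reindex(ly[year_col]).to_numpy()
        + grand
    )
    ms_line_year = e * m * float((ly["dev"] ** 2).sum()) / max((a - 1) * (r - 1), 1) if r > 1 else np.nan

    if m > 1:
        within = df[value_col].to_numpy() - cell_means.reindex(
            pd.MultiIndex.from_frame(df[[line_col, loc_col, year_col]])
        ).to_numpy()
        ms_res = float((within**2).sum()) / max(len(df) - a * e * r, 1)
    else:
        # no within-cell replication: three-way interaction is the residual
        cm = cell_means.reset_index()
        cm["dev"] = (
            cm[value_col]
            - ll_means.reindex(pd.MultiIndex.from_frame(cm[[line_col, loc_col]])).to_numpy()
            - ly_means.reindex(pd.MultiIndex.from_frame(cm[[line_col, year_col]])).to_numpy()
            + line_means.reindex(cm[line_col]).to_numpy()
        )
        dfree = max(a * (e - 1) * (r - 1), 1)
        ms_res = float((cm["dev"] ** 2).sum()) / dfree
        if e == 1 or r == 1:
            warnings.warn("single location or year with one replicate: residual confounded")

    sigma_res = ms_res
    sigma_ll = (ms_line_loc - ms_res) / (r * m) if e > 1 else 0.0
    sigma_ly = (ms_line_year - ms_res) / (e * m) if r > 1 else 0.0
    sigma_line = (
        ms_line
        - (ms_line_loc if e > 1 else ms_res)
        - (ms_line_year if r > 1 else ms_res)
        + ms_res
    ) / (e * r * m)

    clipped = []
    out = {}
    for name, val in [
        ("var_line", sigma_line),
        ("var_line_loc", sigma_ll),
        ("var_line_year", sigma_ly),
        ("var_residual", sigma_res),
    ]:
        if val < 0:
            clipped.append(name)
            warnings.warn(f"negative {name} estimate ({val:.4g}) clipped to 0")
            val = 0.0
        out[name] = float(val)
    return VarianceComponents(
        out["var_line"], out["var_line_loc"], out["var_line_year"],
        out["var_residual"], e, r, m, clipped,
    )


def heritability(
    components: VarianceComponents | dict,
    e: int | None = None,
    r: int | None = None,
) -> float:
    """Entry-mean heritability h2 = var(L)/[var(L) + var(LLoc)/e +
    var(LYear)/r + var(Res)/(re)]."""
    if isinstance(components, VarianceComponents):
        vl, vll, vly, vres = (
            components.var_line,
            components.var_line_loc,
            components.var_line_year,
            components.var_residual,
        )
        e = e if e is not None else components.n_locations
        r = r if r is not None else components.n_years
    else:
        vl = components["var_line"]
        vll = components["var_line_loc"]
        vly = components["var_line_year"]
        vres = components["var_residual"]
    if e is None or r is None or e < 1 or r < 1:
        raise ValueError("e (locations) and r (years) must be >= 1")
    if min(vl, vll, vly, vres) < 0:
        raise ValueError("variance components must be non-negative")
    denom = vl + vll / e + vly / r + vres / (r * e)
    if denom == 0:
        raise ValueError("all variance components are zero")
    return float(vl / denom)


def chi_square_ratio_test(
    counts, ratio
) -> SegregationTestResult:
    """Pearson chi-square of observed class counts against an expected ratio
    (e.g. (395, 403) vs (1, 1), or three classes vs (9, 3, 4))."""
    obs = np.asarray(counts, dtype=float)
    ratio = np.asarray(ratio, dtype=float)
    if obs.size != ratio.size:
        raise ValueError("counts and ratio must have the same length")
    if (obs < 0).any() or obs.sum() == 0:
        raise ValueError("counts must be non-negative with a positive total")
    if (ratio <= 0).any():
        raise ValueError("expected ratio proportions must be positive")
    expected = obs.sum() * ratio / ratio.sum()
    chi2, p = sps.chisquare(obs, expected)
    return SegregationTestResult(
        observed=tuple(int(c) for c in obs),
        expected=tuple(float(x) for x in expected),
        chi2=float(chi2),
        df=obs.size - 1,
        p_value=float(p),
    )


def marker_trait_profile(
    genotypes: np.ndarray,
    phenotype: np.ndarray,
    positions: pd.DataFrame | None = None,
    equal_var: bool = False,
) -> pd.DataFrame:
    """Per-marker two-sample t-test profile as -log10 p.

    ``genotypes`` is lines x markers (shared codes); heterozygous and missing
    calls are excluded, the two homozygote classes are compared with Welch's
    t-test by default (``equal_var=True`` for the pooled version).  Markers
    with fewer than two lines in either class are skipped with a warning.
    ``positions`` (optional: marker, chrom, pos) orders the output by
    position; the profile itself is invariant to input marker order.
    """
    G = np.atleast_2d(np.asarray(genotypes))
    y = np.asarray(phenotype, dtype=float)
    if G.shape[0] != y.size:
        raise ValueError("genotype rows must match phenotype length")
    records = []
    for j in range(G.shape[1]):
        g = G[:, j]
        ya, yb = y[g == 0], y[g == 2]
        if ya.size < 2 or yb.size < 2:
            warnings.warn(f"marker {j}: fewer than 2 lines per class; skipped")
            continue
        t, p = sps.ttest_ind(ya, yb, equal_var=equal_var)
        records.append(
            {"marker_index": j, "t": float(t), "p": float(p),
             "neglog10_p": float(-np.log10(p)) if p > 0 else np.inf}
        )
    prof = pd.DataFrame(records, columns=["marker_index", "t", "p", "neglog10_p"])
    if positions is not None:
        pos = positions.reset_index(drop=True)
        prof = prof.join(pos, on="marker_index")
        sort_cols = [c for c in ("chrom", "pos") if c in prof.columns]
        if sort_cols:
            prof = prof.sort_values(sort_cols).reset_index(drop=True)
    return prof


def nil_similarity(n_total_markers: int, n_discordant: int) -> float:
    """Percent marker concordance between two near-isogenic lines,
    100 (total - discordant) / total, reported to one decimal."""
    if n_total_markers <= 0:
        raise ValueError("marker total must be positive")
    if not 0 <= n_discordant <= n_total_markers:
        raise ValueError("discordant count must be within [0, total]")
    return round(100.0 * (n_total_markers - n_discordant) / n_total_markers, 1)
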