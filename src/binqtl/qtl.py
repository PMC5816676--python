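"""Genome scan for QTLs on a bin map.

The likelihood core is regression-based (Haley–Knott style) interval mapping
on bin genotypes: at each bin the LOD is (n/2) log10(RSS0/RSS1), comparing the
covariate-only fit with the fit adding the bin's additive coding (A = +1,
H = 0, B = -1; missing calls mean-imputed in the design column).  Composite
interval mapping adds forward-selected cofactor bins to the covariates,
dropping any cofactor within an exclusion window of the tested bin.
Significance thresholds come from permutations of the line phenotypes against
the whole genotype matrix, and support intervals from the 1.5-LOD-drop rule.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .binmap import BinMap
from .codes import to_additive

__all__ = [
    "ScanConfig",
    "lod_at_locus",
    "scan_genome",
    "select_cofactors",
    "permutation_threshold",
    "lod_drop_interval",
    "estimate_qtl_effects",
    "CIMScanner",
]

logger = logging.getLogger(__name__)

_MAX_LOD_R2 = 1 - 1e-12  # guards log10(RSS0/RSS1) when the fit is exact


@dataclass
class ScanConfig:
    """Scan parameters: permutation count and level, LOD-drop width,
    cofactor number and exclusion window."""

    n_permutations: int = 1000
    alpha: float = 0.05
    lod_drop: float = 1.5
    n_cofactors: int = 5
    window_cm: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must be in (0, 1]")
        if self.lod_drop <= 0:
            raise ValueError("lod_drop must be > 0")
        if self.n_cofactors < 0:
            raise ValueError("n_cofactors must be >= 0")


def _design_matrix(genotypes: np.ndarray) -> np.ndarray:
    """Additive coding with per-column mean imputation of missing calls."""
    X = to_additive(genotypes).astype(float)
    if np.isnan(X).any():
        col_mean = np.nanmean(np.where(np.isnan(X), np.nan, X), axis=0)
        col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
        nan_r, nan_c = np.nonzero(np.isnan(X))
        X[nan_r, nan_c] = col_mean[nan_c]
    return X


def _residualize(M: np.ndarray, C: np.ndarray) -> np.ndarray:
    """Project columns of M off the column space of C."""
    Q, _ = np.linalg.qr(C)
    return M - Q @ (Q.T @ M)


def lod_at_locus(
    genotypes: np.ndarray,
    phenotype: np.ndarray,
    covariates: np.ndarray | None = None,
) -> float:
    """LOD = (n/2) log10(RSS0/RSS1) for one locus.

    RSS0 fits intercept + covariates, RSS1 additionally the locus coding.
    A constant genotype column yields LOD 0 with a warning; an exact fit
    (zero residual) is capped rather than infinite.
    """
    y = np.asarray(phenotype, dtype=float)
    n = y.size
    x = _design_matrix(np.asarray(genotypes).reshape(-1, 1))[:, 0]
    C = np.column_stack([np.ones(n)] + ([covariates] if covariates is not None else []))
    if n < C.shape[1] + 2:
        raise ValueError("too few lines for the covariate set")
    if np.ptp(x) == 0:
        warnings.warn("constant genotype column; LOD set to 0")
        return 0.0
    y_r = _residualize(y[:, None], C)[:, 0]
    x_r = _residualize(x[:, None], C)[:, 0]
    rss0 = float(y_r @ y_r)
    if rss0 == 0:
        return 0.0
    denom = float(x_r @ x_r)
    if denom == 0:
        warnings.warn("genotype column collinear with covariates; LOD set to 0")
        return 0.0
    r2 = (float(x_r @ y_r)) ** 2 / (denom * rss0)
    r2 = min(r2, _MAX_LOD_R2)
    return float(-(n / 2) * np.log10(1 - r2))


def _scan_lods(
    X: np.ndarray,
    y: np.ndarray,
    chrom: np.ndarray,
    cm: np.ndarray,
    cofactor_idx: np.ndarray,
    window_cm: float,
) -> np.ndarray:
    """Vectorized LOD curve; cofactors within ``window_cm`` of the tested bin
    (same chromosome) are dropped from the covariate set for that test."""
    n, m = X.shape
    lods = np.zeros(m)
    cofactor_idx = np.asarray(cofactor_idx, dtype=int)
    # group bins by the subset of excluded cofactors
    if cofactor_idx.size:
        excl = np.zeros((m, cofactor_idx.size), dtype=bool)
        for j, c in enumerate(cofactor_idx):
            excl[:, j] = (chrom == chrom[c]) & (np.abs(cm - cm[c]) < window_cm)
        keys = [tuple(row) for row in excl]
    else:
        keys = [()] * m
    ones = np.ones((n, 1))
    for key in set(keys):
        cols = np.flatnonzero([k == key for k in keys])
        active = (
            cofactor_idx[~np.array(key, dtype=bool)] if key else cofactor_idx
        )
        C = np.column_stack([ones] + ([X[:, active]] if len(active) else []))
        y_r = _residualize(y[:, None], C)[:, 0]
        rss0 = float(y_r @ y_r)
        if rss0 == 0:
            continue
        G_r = _residualize(X[:, cols], C)
        num = G_r.T @ y_r
        denom = (G_r**2).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            r2 = np.where(denom > 0, num**2 / (denom * rss0), 0.0)
        r2 = np.minimum(r2, _MAX_LOD_R2)
        lods[cols] = -(n / 2) * np.log10(1 - r2)
    # tested bins that are themselves cofactors: compare against the other
    # cofactors only (their own column would make the test degenerate)
    for c in cofactor_idx:
        others = cofactor_idx[cofactor_idx != c]
        near = (chrom[others] == chrom[c]) & (np.abs(cm[others] - cm[c]) < window_cm)
        C = np.column_stack([ones] + ([X[:, others[~near]]] if (~near).sum() else []))
        y_r = _residualize(y[:, None], C)[:, 0]
        rss0 = float(y_r @ y_r)
        if rss0 == 0:
            continue
        g_r = _residualize(X[:, [c]], C)[:, 0]
        denom = float(g_r @ g_r)
        r2 = 0.0 if denom == 0 else (float(g_r @ y_r)) ** 2 / (denom * rss0)
        lods[c] = -(n / 2) * np.log10(1 - min(r2, _MAX_LOD_R2))
    return lods


def scan_genome(
    binmap: BinMap,
    phenotype: np.ndarray | pd.Series,
    cfg: ScanConfig | None = None,
    cofactors: np.ndarray | list[int] | None = None,
) -> pd.DataFrame:
    """LOD at every bin (composite interval mapping when cofactors given).

    ``phenotype`` holds one value per kept line (line means or a single
    environment).  Returns the scan table (bin_id, chrom, cm, mid_bp, lod).
    """
    cfg = cfg or ScanConfig()
    y = _phenotype_vector(binmap, phenotype)
    X = _design_matrix(binmap.genotypes)
    chrom = binmap.bins["chrom"].to_numpy()
    cm = _require_cm(binmap)
    cof = np.asarray(cofactors if cofactors is not None else [], dtype=int)
    lods = _scan_lods(X, y, chrom, cm, cof, cfg.window_cm)
    return pd.DataFrame(
        {
            "bin_id": binmap.bins["bin_id"],
            "chrom": chrom,
            "cm": cm,
            "mid_bp": binmap.bins["mid_bp"],
            "lod": lods,
        }
    )


def _phenotype_vector(binmap: BinMap, phenotype) -> np.ndarray:
    if isinstance(phenotype, pd.Series):
        phenotype = phenotype.reindex(binmap.line_ids).to_numpy()
    y = np.asarray(phenotype, dtype=float)
    if y.size != binmap.n_lines:
        raise ValueError("phenotype length does not match lines in the bin map")
    if np.isnan(y).all():
        raise ValueError("phenotype is entirely missing")
    if np.isnan(y).any():
        raise ValueError("missing phenotype values; average or drop lines first")
    return y


def _require_cm(binmap: BinMap) -> np.ndarray:
    if "cm" not in binmap.bins.columns:
        raise ValueError("bin map carries no genetic map; run estimate_genetic_map")
    return binmap.bins["cm"].to_numpy()


def select_cofactors(
    binmap: BinMap,
    phenotype: np.ndarray | pd.Series,
    k: int = 5,
    min_sep_cm: float = 10.0,
) -> np.ndarray:
    """Forward stepwise cofactor choice: repeatedly add the bin with the
    largest incremental LOD, at least ``min_sep_cm`` from already-selected
    bins on the same chromosome."""
    if k < 0:
        raise ValueError("k must be >= 0")
    if k == 0:
        return np.array([], dtype=int)
    y = _phenotype_vector(binmap, phenotype)
    X = _design_matrix(binmap.genotypes)
    chrom = binmap.bins["chrom"].to_numpy()
    cm = _require_cm(binmap)
    selected: list[int] = []
    eligible = np.ones(X.shape[1], dtype=bool)
    for _ in range(k):
        if not eligible.any():
            break
        lods = _scan_lods(X, y, chrom, cm, np.asarray(selected, dtype=int), 0.0)
        lods[~eligible] = -1.0
        best = int(np.argmax(lods))
        if lods[best] <= 0:
            break
        selected.append(best)
        eligible &= ~((chrom == chrom[best]) & (np.abs(cm - cm[best]) < min_sep_cm))
    return np.asarray(sorted(selected), dtype=int)


def permutation_threshold(
    binmap: BinMap,
    phenotype: np.ndarray | pd.Series,
    cfg: ScanConfig | None = None,
    return_maxlods: bool = False,
):
    """Genome-wide LOD cutoff from phenotype permutations.

    Line phenotypes are permuted jointly against the whole genotype matrix
    (preserving genotype LD); the cutoff is the m-th smallest of the B
    recorded genome-wide maximum LODs with m = max(1, ceil((1-alpha) B)).
    With cofactors configured, each permutation re-selects its own cofactors.
    Deterministic given ``cfg.seed``.
    """
    cfg = cfg or ScanConfig()
    y = _phenotype_vector(binmap, phenotype)
    X = _design_matrix(binmap.genotypes)
    chrom = binmap.bins["chrom"].to_numpy()
    cm = _require_cm(binmap)
    rng = np.random.default_rng(cfg.seed)
    B = cfg.n_permutations
    n, m = X.shape
    if cfg.n_cofactors == 0:
        perms = np.stack([rng.permutation(n) for _ in range(B)])
        Yp = y[perms].T  # n x B
        ones = np.ones((n, 1))
        Yr = _residualize(Yp, ones)
        Xr = _residualize(X, ones)
        num = Xr.T @ Yr  # m x B
        gss = (Xr**2).sum(axis=0)
        yss = (Yr**2).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            r2 = np.where(
                (gss[:, None] > 0) & (yss[None, :] > 0),
                num**2 / (gss[:, None] * yss[None, :]),
                0.0,
            )
        r2 = np.minimum(r2, _MAX_LOD_R2)
        maxlods = (-(n / 2) * np.log10(1 - r2)).max(axis=0)
    else:
        maxlods = np.empty(B)
        for b in range(B):
            yp = y[rng.permutation(n)]
            cof = select_cofactors_from_arrays(X, yp, chrom, cm, cfg.n_cofactors)
            maxlods[b] = _scan_lods(X, yp, chrom, cm, cof, cfg.window_cm).max()
    order = np.sort(maxlods)
    m_idx = max(1, int(np.ceil((1 - cfg.alpha) * B)))
    threshold = float(order[m_idx - 1])
    return (threshold, maxlods) if return_maxlods else threshold


def select_cofactors_from_arrays(X, y, chrom, cm, k, min_sep_cm=10.0) -> np.ndarray:
    """Array-level forward stepwise selection (used inside permutations)."""
    selected: list[int] = []
    eligible = np.ones(X.shape[1], dtype=bool)
    for _ in range(k):
        if not eligible.any():
            break
        lods = _scan_lods(X, y, chrom, cm, np.asarray(selected, dtype=int), 0.0)
        lods[~eligible] = -1.0
        best = int(np.argmax(lods))
        if lods[best] <= 0:
            break
        selected.append(best)
        eligible &= ~((chrom == chrom[best]) & (np.abs(cm - cm[best]) < min_sep_cm))
    return np.asarray(sorted(selected), dtype=int)


def lod_drop_interval(
    scan: pd.DataFrame,
    peak_idx: int,
    lod_drop: float = 1.5,
    binmap: BinMap | None = None,
) -> dict:
    """Support interval around a peak by the LOD-drop rule.

    The interval is the contiguous span around the peak with LOD above
    (peak - drop), expanded outward to the first bin falling below on each
    side; when one side never falls below, the interval clips at the
    chromosome end and is flagged.  Physical coordinates come from the bins'
    span when a bin map is supplied, else from the scan's mid_bp.
    """
    lod = scan["lod"].to_numpy()
    chrom = scan["chrom"].to_numpy()
    on_chrom = np.flatnonzero(chrom == chrom[peak_idx])
    j = int(np.flatnonzero(on_chrom == peak_idx)[0])
    sub = lod[on_chrom]
    cut = sub[j] - lod_drop
    left = j
    while left > 0 and sub[left] >= cut:
        left -= 1
    right = j
    while right < sub.size - 1 and sub[right] >= cut:
        right += 1
    clipped_left = sub[left] >= cut
    clipped_right = sub[right] >= cut
    lo, hi = on_chrom[left], on_chrom[right]
    cm = scan["cm"].to_numpy()
    if binmap is not None:
        start_bp = int(binmap.bins["start"].iloc[lo]) + 1  # 1-based report
        end_bp = int(binmap.bins["end"].iloc[hi])
    else:
        start_bp = int(scan["mid_bp"].iloc[lo])
        end_bp = int(scan["mid_bp"].iloc[hi])
    return {
        "chrom": chrom[peak_idx],
        "lo_idx": int(lo),
        "hi_idx": int(hi),
        "cm_lo": float(cm[lo]),
        "cm_hi": float(cm[hi]),
        "bp_lo": start_bp,
        "bp_hi": end_bp,
        "clipped": bool(clipped_left or clipped_right),
    }


def estimate_qtl_effects(
    genotypes: np.ndarray,
    phenotype: np.ndarray,
    parent_a: str = "A",
    parent_b: str = "B",
) -> dict:
    """Additive effect, PVE and positive allele at one locus.

    a = (mean_A - mean_B) / 2 over the homozygote classes; PVE is the model
    sum-of-squares fraction of the single-locus regression, in percent;
    the positive allele is the parent whose genotype increases the trait.
    """
    g = np.asarray(genotypes)
    y = np.asarray(phenotype, dtype=float)
    mask_a, mask_b = g == 0, g == 2
    if mask_a.sum() < 2 or mask_b.sum() < 2:
        raise ValueError("need >= 2 lines in each homozygote class")
    mean_a = float(y[mask_a].mean())
    mean_b = float(y[mask_b].mean())
    a = (mean_a - mean_b) / 2.0
    x = _design_matrix(g.reshape(-1, 1))[:, 0]
    y_c = y - y.mean()
    x_c = x - x.mean()
    tss = float(y_c @ y_c)
    r2 = 0.0 if tss == 0 or np.ptp(x) == 0 else (float(x_c @ y_c)) ** 2 / (
        float(x_c @ x_c) * tss
    )
    return {
        "additive_effect": a,
        "pve": 100.0 * r2,
        "positive_allele": parent_a if a > 0 else parent_b,
    }


class CIMScanner(BaseEstimator):
    """Composite-interval-mapping genome scan as a fit-style estimator.

    ``fit(binmap, y)`` selects cofactors, scans the genome, computes the
    permutation threshold, and extracts QTLs with LOD-drop support intervals
    and effect estimates.  Fitted attributes: ``scan_`` (LOD table),
    ``lod_``, ``threshold_``, ``perm_maxlods_``, ``cofactors_`` and ``qtls_``
    (a Table-1-style DataFrame: chrom, peak cM/bp, interval cM/bp, LOD, PVE,
    additive effect, positive allele).
    """

    def __init__(
        self,
        n_cofactors: int = 5,
        window_cm: float = 10.0,
        n_permutations: int = 1000,
        alpha: float = 0.05,
        lod_drop: float = 1.5,
        random_state: int = 0,
        parent_a: str = "A",
        parent_b: str = "B",
    ):
        self.n_cofactors = n_cofactors
        self.window_cm = window_cm
        self.n_permutations = n_permutations
        self.alpha = alpha
        self.lod_drop = lod_drop
        self.random_state = random_state
        self.parent_a = parent_a
        self.parent_b = parent_b

    def _scan_config(self) -> ScanConfig:
        return ScanConfig(
            n_permutations=self.n_permutations,
            alpha=self.alpha,
            lod_drop=self.lod_drop,
            n_cofactors=self.n_cofactors,
            window_cm=self.window_cm,
            seed=self.random_state,
        )

    def fit(self, X: BinMap, y) -> "CIMScanner":
        cfg = self._scan_config()
        self.cofactors_ = select_cofactors(X, y, self.n_cofactors, self.window_cm)
        self.scan_ = scan_genome(X, y, cfg, self.cofactors_)
        self.lod_ = self.scan_["lod"].to_numpy()
        self.threshold_, self.perm_maxlods_ = permutation_threshold(
            X, y, cfg, return_maxlods=True
        )
        self.qtls_ = self._extract_qtls(X, np.asarray(
            y.reindex(X.line_ids) if isinstance(y, pd.Series) else y, dtype=float
        ))
        return self

    def _extract_qtls(self, binmap: BinMap, y: np.ndarray) -> pd.DataFrame:
        lod = self.lod_.copy()
        cm = binmap.bins["cm"].to_numpy()
        chrom = binmap.bins["chrom"].to_numpy()
        records = []
        accepted: list[tuple[str, float, float]] = []
        available = np.ones(lod.size, dtype=bool)
        while True:
            masked = np.where(available, lod, -np.inf)
            peak = int(np.argmax(masked))
            if masked[peak] <= self.threshold_:
                break
            ci = lod_drop_interval(self.scan_, peak, self.lod_drop, binmap)
            # a support interval overlapping an accepted QTL's interval is a
            # shoulder of the same signal (e.g. a cofactor-exclusion ghost
            # peak), not a second QTL: retire it without recording
            overlaps = any(
                c == chrom[peak] and ci["cm_lo"] <= hi and ci["cm_hi"] >= lo
                for c, lo, hi in accepted
            )
            if overlaps:
                span = np.zeros(lod.size, dtype=bool)
                span[ci["lo_idx"] : ci["hi_idx"] + 1] = True
                available &= ~span
                available[peak] = False
                if not available.any():
                    break
                continue
            accepted.append((chrom[peak], ci["cm_lo"], ci["cm_hi"]))
            try:
                eff = estimate_qtl_effects(
                    binmap.genotypes[:, peak], y, self.parent_a, self.parent_b
                )
            except ValueError:
                eff = {"additive_effect": np.nan, "pve": np.nan, "positive_allele": ""}
            records.append(
                {
                    "chrom": chrom[peak],
                    "peak_cm": float(cm[peak]),
                    "peak_bp": int(binmap.bins["mid_bp"].iloc[peak]),
                    "ci_cm_lo": ci["cm_lo"],
                    "ci_cm_hi": ci["cm_hi"],
                    "ci_bp_lo": ci["bp_lo"],
                    "ci_bp_hi": ci["bp_hi"],
                    "lod": float(lod[peak]),
                    "pve": eff["pve"],
                    "additive_effect": eff["additive_effect"],
                    "positive_allele": eff["positive_allele"],
                    "interval_clipped": ci["clipped"],
                }
            )
            # retire the support interval plus a guard band around the peak
            guard = (chrom == chrom[peak]) & (
                np.abs(cm - cm[peak]) <= max(self.window_cm, ci["cm_hi"] - ci["cm_lo"])
            )
            span = np.zeros(lod.size, dtype=bool)
            span[ci["lo_idx"] : ci["hi_idx"] + 1] = True
            available &= ~(guard | span)
            if not available.any():
                break
        return pd.DataFrame(
            records,
            columns=[
                "chrom", "peak_cm", "peak_bp", "ci_cm_lo", "ci_cm_hi",
                "ci_bp_lo", "ci_bp_hi", "lod", "pve", "additive_effect",
                "positive_allele", "interval_clipped",
            ],
        )
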