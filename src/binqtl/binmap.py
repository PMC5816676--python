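"""Bin-map construction from noisy low-coverage genotype calls.

The pipeline turns sparse per-SNP parental-origin calls into a population bin
map: (1) a sliding-window consensus call per line smooths out single-read
noise and makes heterozygous segments visible, (2) lines with excessive
residual heterozygosity, too many breakpoints or too few genotyped SNPs are
dropped, (3) heterozygous consensus calls are recoded missing and every track
is completed with a two-state Viterbi path ("argmax" imputation), (4) the
chromosomes are partitioned into recombination-defined bins at the union of
all lines' breakpoints, (5) distorted or heterozygous bins are removed, and
(6) adjacent-bin recombination fractions are converted to centimorgans with
the selfed-RIL correction followed by the Kosambi map function.

All coordinates are 0-based half-open internally; report writers convert to
1-based inclusive at the boundary.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .codes import AA, AB, BB, MISSING
from .sim import RawGenotypeMatrix, SNPSet

__all__ = [
    "QCConfig",
    "BinMap",
    "kosambi_distance",
    "kosambi_inverse",
    "ril_fraction_from_meiotic",
    "meiotic_from_ril_fraction",
    "call_windows",
    "detect_breakpoints",
    "line_statistics",
    "filter_lines",
    "impute_argmax",
    "build_bins",
    "filter_bins",
    "estimate_genetic_map",
    "BinMapper",
]

logger = logging.getLogger(__name__)


@dataclass
class QCConfig:
    """Quality-control and windowing parameters of bin-map construction.

    Defaults follow the published pipeline: 20-SNP windows sliding by 2,
    lines removed above 10% heterozygosity or 200 breakpoints or below
    20,000 genotyped SNPs, bins removed above a 2:1 segregation ratio or 10%
    heterozygosity.  ``purity`` (window homozygote call threshold) and
    ``min_window_informative`` parameterize the window call rule itself.
    """

    window_size: int = 20
    step: int = 2
    purity: float = 0.7
    min_window_informative: int = 5
    min_genotyped: int = 20_000
    max_line_het: float = 0.10
    max_line_breakpoints: int = 200
    max_bin_distortion: float = 2.0
    max_bin_het: float = 0.10
    emission_error: float = 0.005
    min_pair_lines: int = 20

    def __post_init__(self) -> None:
        if self.window_size <= 0:
            raise ValueError("window_size must be > 0")
        if not 0 < self.step <= self.window_size:
            raise ValueError("step must satisfy 0 < step <= window_size")
        if not 0.5 < self.purity <= 1.0:
            raise ValueError("purity must be in (0.5, 1]")
        for name in ("max_line_het", "max_bin_het"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.max_bin_distortion < 1:
            raise ValueError("max_bin_distortion must be >= 1")
        if not 0 <= self.emission_error < 0.5:
            raise ValueError("emission_error must be in [0, 0.5)")


@dataclass
class BinMap:
    """Recombination-defined bins with per-line genotype codes.

    ``bins`` has columns ``bin_id``, ``chrom``, ``start``, ``end`` (0-based
    half-open bp), ``mid_bp``, ``n_snps`` and, once a genetic map has been
    estimated, ``cm``.  ``genotypes`` is lines x bins (shared int codes).
    """

    bins: pd.DataFrame
    genotypes: np.ndarray
    line_ids: list[str]
    chrom_lengths: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.genotypes.shape != (len(self.line_ids), len(self.bins)):
            raise ValueError("genotype matrix shape does not match bins/lines")

    @property
    def n_bins(self) -> int:
        return len(self.bins)

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    def chrom_indices(self, chrom: str) -> np.ndarray:
        return np.flatnonzero((self.bins["chrom"] == chrom).to_numpy())

    def genotype_counts(self) -> pd.DataFrame:
        """Per-bin counts of A/B/H calls across lines."""
        g = self.genotypes
        return pd.DataFrame(
            {
                "n_a": (g == AA).sum(axis=0),
                "n_b": (g == BB).sum(axis=0),
                "n_h": (g == AB).sum(axis=0),
                "n_missing": (g == MISSING).sum(axis=0),
            },
            index=self.bins.index,
        )

    def total_map_length(self) -> float:
        """Summed genetic length (cM) over chromosomes; needs a genetic map."""
        if "cm" not in self.bins.columns:
            raise ValueError("no genetic map estimated yet")
        return float(
            self.bins.groupby("chrom", sort=False)["cm"].agg(lambda c: c.max() - c.min()).sum()
        )


# ---------------------------------------------------------------------------
# map functions


def kosambi_distance(r):
    """Kosambi map distance d = 25 ln((1+2r)/(1-2r)) cM for 0 <= r < 0.5."""
    r = np.asarray(r, dtype=float)
    if np.any((r < 0) | (r >= 0.5)):
        raise ValueError("recombination fraction must be in [0, 0.5)")
    d = 25.0 * np.log((1 + 2 * r) / (1 - 2 * r))
    return float(d) if d.ndim == 0 else d


def kosambi_inverse(d_cm):
    """Inverse Kosambi: r = tanh(d/50)/2 for map distance d in cM."""
    d = np.asarray(d_cm, dtype=float)
    if np.any(d < 0):
        raise ValueError("map distance must be >= 0")
    r = 0.5 * np.tanh(d / 50.0)
    return float(r) if r.ndim == 0 else r


def ril_fraction_from_meiotic(r):
    """Observed discordance R between loci in a selfed RIL: R = 2r/(1+2r)."""
    r = np.asarray(r, dtype=float)
    if np.any((r < 0) | (r > 0.5)):
        raise ValueError("meiotic recombination fraction must be in [0, 0.5]")
    out = 2 * r / (1 + 2 * r)
    return float(out) if out.ndim == 0 else out


def meiotic_from_ril_fraction(R):
    """Inverse selfed-RIL correction: r = R/(2-2R) for observed R < 0.5."""
    R = np.asarray(R, dtype=float)
    if np.any((R < 0) | (R >= 0.5)):
        raise ValueError("observed RIL fraction must be in [0, 0.5)")
    r = R / (2 - 2 * R)
    return float(r) if r.ndim == 0 else r


# ---------------------------------------------------------------------------
# window calling


def call_windows(calls: np.ndarray, cfg: QCConfig | None = None) -> np.ndarray:
    """Sliding-window consensus genotype track for one line, one chromosome.

    Windows of ``window_size`` consecutive *observed* SNPs advance by
    ``step``; a window is called A (or B) when that parent's allele fraction
    among its calls (heterozygous calls contribute half) reaches ``purity``,
    H otherwise, and missing when it holds fewer than
    ``min_window_informative`` calls.  Each observed SNP then takes the
    majority call of the windows covering it (ties -> H); unobserved SNPs stay
    missing.  Input must be position-ordered.
    """
    cfg = cfg or QCConfig()
    calls = np.asarray(calls, dtype=np.int8)
    consensus = np.full(calls.shape, MISSING, dtype=np.int8)
    obs = np.flatnonzero(calls != MISSING)
    if obs.size < cfg.min_window_informative:
        return consensus
    oc = calls[obs]
    w = min(cfg.window_size, obs.size)
    starts = np.arange(0, obs.size - w + 1, cfg.step)
    if starts[-1] + w < obs.size:
        starts = np.append(starts, obs.size - w)
    ca = np.concatenate([[0], np.cumsum(oc == AA)])
    cb = np.concatenate([[0], np.cumsum(oc == BB)])
    ch = np.concatenate([[0], np.cumsum(oc == AB)])
    n_a = ca[starts + w] - ca[starts]
    n_b = cb[starts + w] - cb[starts]
    n_h = ch[starts + w] - ch[starts]
    n_inf = n_a + n_b + n_h
    with np.errstate(invalid="ignore", divide="ignore"):
        f_a = (2 * n_a + n_h) / (2 * n_inf)
        f_b = (2 * n_b + n_h) / (2 * n_inf)
    wcall = np.full(starts.shape, AB, dtype=np.int8)
    wcall[f_a >= cfg.purity] = AA
    wcall[f_b >= cfg.purity] = BB
    wcall[n_inf < cfg.min_window_informative] = MISSING

    # vote of covering windows per observed SNP, via interval increments
    votes = np.zeros((3, obs.size + 1), dtype=np.int32)
    for code in (AA, AB, BB):
        sel = wcall == code
        np.add.at(votes[code], starts[sel], 1)
        np.add.at(votes[code], starts[sel] + w, -1)
    votes = np.cumsum(votes[:, :-1], axis=1)
    total = votes.sum(axis=0)
    best = votes.max(axis=0)
    # strict majority needed for a homozygous call; ties resolve to H
    call = np.full(obs.size, MISSING, dtype=np.int8)
    covered = total > 0
    call[covered] = AB
    a_major = covered & (votes[AA] == best) & (votes[AA] > votes[BB]) & (votes[AA] > votes[AB])
    b_major = covered & (votes[BB] == best) & (votes[BB] > votes[AA]) & (votes[BB] > votes[AB])
    call[a_major] = AA
    call[b_major] = BB
    consensus[obs] = call
    return consensus


def detect_breakpoints(track: np.ndarray, pos_bp: np.ndarray) -> pd.DataFrame:
    """Genotype transitions of one consensus track (one line, one chromosome).

    Missing calls are skipped; a breakpoint sits at the midpoint between the
    last informative SNP of the left state and the first of the right state.
    """
    track = np.asarray(track)
    pos_bp = np.asarray(pos_bp)
    inf = np.flatnonzero(track != MISSING)
    states = track[inf]
    change = np.flatnonzero(np.diff(states) != 0)
    left = inf[change]
    right = inf[change + 1]
    return pd.DataFrame(
        {
            "left_snp": left,
            "right_snp": right,
            "left_pos": pos_bp[left],
            "right_pos": pos_bp[right],
            "mid_pos": (pos_bp[left] + pos_bp[right]) // 2,
            "from_state": states[change],
            "to_state": states[change + 1],
        }
    )


def line_statistics(
    raw: RawGenotypeMatrix, consensus: np.ndarray
) -> pd.DataFrame:
    """Per-line QC statistics: genotyped SNPs, heterozygosity, breakpoints."""
    snps = raw.snps
    pos = snps.table["pos"].to_numpy()
    n_lines = raw.n_lines
    informative = consensus != MISSING
    n_inf = informative.sum(axis=1)
    with np.errstate(invalid="ignore"):
        het = np.where(n_inf > 0, (consensus == AB).sum(axis=1) / np.maximum(n_inf, 1), 0.0)
    n_break = np.zeros(n_lines, dtype=int)
    for chrom in snps.chromosomes:
        idx = snps.chrom_indices(chrom)
        if idx.size == 0:
            continue
        for i in range(n_lines):
            n_break[i] += len(detect_breakpoints(consensus[i, idx], pos[idx]))
    return pd.DataFrame(
        {
            "line": raw.line_ids,
            "n_genotyped": raw.genotyped_counts(),
            "heterozygosity": het,
            "n_breakpoints": n_break,
        }
    )


def filter_lines(stats: pd.DataFrame, cfg: QCConfig | None = None) -> np.ndarray:
    """Boolean keep-mask: enough genotyped SNPs, low heterozygosity, few
    breakpoints.  Idempotent by construction."""
    cfg = cfg or QCConfig()
    keep = (
        (stats["n_genotyped"].to_numpy() >= cfg.min_genotyped)
        & (stats["heterozygosity"].to_numpy() <= cfg.max_line_het)
        & (stats["n_breakpoints"].to_numpy() <= cfg.max_line_breakpoints)
    )
    logger.info("line filter: kept %d of %d lines", int(keep.sum()), len(keep))
    return keep


# ---------------------------------------------------------------------------
# imputation


def _transition_logs(cm: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-gap log stay/switch probabilities for the two-state chain.

    Adjacent-locus discordance in a selfed RIL at map distance d cM is
    R = 2r/(1+2r) with r from the inverse Kosambi function.
    """
    gaps = np.diff(np.asarray(cm, dtype=float))
    r = kosambi_inverse(np.maximum(gaps, 0.0))
    big_r = np.clip(ril_fraction_from_meiotic(np.minimum(r, 0.5)), 1e-12, 0.5)
    return np.log1p(-big_r), np.log(big_r)


def impute_argmax(
    tracks: np.ndarray,
    cm: np.ndarray,
    error_rate: float = 0.005,
) -> np.ndarray:
    """Fill missing calls with the maximum-probability two-state path.

    ``tracks`` is (lines x SNPs) or (SNPs,) holding AA/BB/MISSING for one
    chromosome (heterozygous calls must have been recoded missing first, as
    in the published order of operations).  States are the two parental
    homozygotes; transition probabilities between adjacent SNPs follow their
    cM separation, emissions flip with ``error_rate``.  The Viterbi path is
    computed jointly over all lines, but observed calls are never overwritten
    — only missing cells receive the path state.
    """
    single = np.ndim(tracks) == 1
    tr = np.atleast_2d(np.asarray(tracks, dtype=np.int8)).copy()
    if tr.shape[1] == 0:
        raise ValueError("empty track")
    if tr.shape[1] != len(cm):
        raise ValueError("track length does not match cM positions")
    if (tr == AB).any():
        raise ValueError("recode heterozygous calls as missing before imputing")
    n, s = tr.shape
    log_stay, log_switch = _transition_logs(cm)
    e = error_rate
    # emission log-likelihood per cell and state
    emis = np.zeros((n, s, 2))
    if e > 0:
        emis[tr == AA] = [np.log(1 - e), np.log(e)]
        emis[tr == BB] = [np.log(e), np.log(1 - e)]
    else:
        emis[tr == AA] = [0.0, -np.inf]
        emis[tr == BB] = [-np.inf, 0.0]
    delta = emis[:, 0, :].copy()
    psi = np.zeros((s, n, 2), dtype=np.int8)
    for t in range(1, s):
        # cand[l, prev, cur]
        trans = np.array(
            [[log_stay[t - 1], log_switch[t - 1]], [log_switch[t - 1], log_stay[t - 1]]]
        )
        cand = delta[:, :, None] + trans[None, :, :]
        psi[t] = cand.argmax(axis=1)
        delta = cand.max(axis=1) + emis[:, t, :]
    states = np.zeros((n, s), dtype=np.int8)
    states[:, -1] = delta.argmax(axis=1)
    rows = np.arange(n)
    for t in range(s - 1, 0, -1):
        states[:, t - 1] = psi[t, rows, states[:, t]]
    path = np.where(states == 0, AA, BB).astype(np.int8)
    out = np.where(tr == MISSING, path, tr).astype(np.int8)
    return out[0] if single else out


# ---------------------------------------------------------------------------
# bins


def build_bins(
    tracks: np.ndarray,
    snps: SNPSet,
    line_ids: list[str],
) -> BinMap:
    """Partition chromosomes at the union of all lines' breakpoints.

    Adjacent SNPs between which no line changes genotype fall in the same
    bin, so bins are maximal segments with constant genotype columns; bin
    edges sit at the midpoint between the flanking SNPs (0-based half-open,
    first bin starts at 0, last ends at the chromosome length).
    """
    tracks = np.atleast_2d(np.asarray(tracks, dtype=np.int8))
    rows = []
    geno_cols = []
    pos_all = snps.table["pos"].to_numpy()
    for chrom in snps.chromosomes:
        idx = snps.chrom_indices(chrom)
        if idx.size == 0:
            continue
        sub = tracks[:, idx]
        pos = pos_all[idx]
        change = np.flatnonzero((np.diff(sub, axis=1) != 0).any(axis=0))
        edges_bp = (pos[change] + pos[change + 1]) // 2
        starts = np.concatenate([[0], edges_bp])
        ends = np.concatenate([edges_bp, [snps.chrom_lengths[chrom]]])
        first_snp = np.concatenate([[0], change + 1])
        last_snp = np.concatenate([change, [idx.size - 1]])
        for k in range(starts.size):
            rows.append(
                {
                    "bin_id": f"bin{_chrom_label(snps, chrom)}_{k + 1}",
                    "chrom": chrom,
                    "start": int(starts[k]),
                    "end": int(ends[k]),
                    "mid_bp": int((pos[first_snp[k]] + pos[last_snp[k]]) // 2),
                    "n_snps": int(last_snp[k] - first_snp[k] + 1),
                }
            )
            geno_cols.append(sub[:, first_snp[k]])
    bins = pd.DataFrame(rows, columns=["bin_id", "chrom", "start", "end", "mid_bp", "n_snps"])
    genotypes = (
        np.column_stack(geno_cols).astype(np.int8)
        if geno_cols
        else np.zeros((tracks.shape[0], 0), dtype=np.int8)
    )
    return BinMap(
        bins=bins,
        genotypes=genotypes,
        line_ids=list(line_ids),
        chrom_lengths=dict(snps.chrom_lengths),
    )


def _chrom_label(snps: SNPSet, chrom: str) -> str:
    digits = "".join(c for c in chrom if c.isdigit())
    return digits or chrom


def filter_bins(binmap: BinMap, cfg: QCConfig | None = None) -> BinMap:
    """Drop bins with distorted segregation (> max ratio between the two
    homozygote counts) or excess heterozygosity; idempotent."""
    cfg = cfg or QCConfig()
    counts = binmap.genotype_counts()
    n_a = counts["n_a"].to_numpy().astype(float)
    n_b = counts["n_b"].to_numpy().astype(float)
    n_h = counts["n_h"].to_numpy().astype(float)
    informative = n_a + n_b + n_h
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.maximum(n_a, n_b) / np.minimum(n_a, n_b)
        het = np.where(informative > 0, n_h / informative, np.nan)
    empty = informative == 0
    if empty.any():
        warnings.warn(f"removing {int(empty.sum())} bins with no informative lines")
    keep = ~empty & (ratio <= cfg.max_bin_distortion) & (het <= cfg.max_bin_het)
    logger.info("bin filter: kept %d of %d bins", int(keep.sum()), len(keep))
    bins = binmap.bins.loc[keep].reset_index(drop=True)
    return BinMap(
        bins=bins,
        genotypes=binmap.genotypes[:, keep],
        line_ids=list(binmap.line_ids),
        chrom_lengths=dict(binmap.chrom_lengths),
    )


def estimate_genetic_map(
    binmap: BinMap,
    population_type: str = "selfed-RIL",
    min_pair_lines: int = 20,
) -> BinMap:
    """Cumulative cM positions per chromosome from adjacent-bin discordance.

    For each adjacent bin pair the fraction R of lines with discordant
    homozygous genotypes (heterozygotes and missing ignored) is corrected to
    a meiotic fraction — r = R/(2-2R) for selfed RILs — and converted to cM
    with the Kosambi function.  Pairs with fewer than ``min_pair_lines``
    informative lines inherit the distance of the nearest informative pair on
    the chromosome (logged).  Returns a new BinMap whose ``bins`` carry a
    ``cm`` column.
    """
    if population_type not in ("selfed-RIL", "raw"):
        raise ValueError("population_type must be 'selfed-RIL' or 'raw'")
    g = binmap.genotypes
    bins = binmap.bins.copy()
    cm = np.zeros(len(bins))
    for chrom in dict.fromkeys(bins["chrom"]):
        idx = binmap.chrom_indices(chrom)
        if idx.size <= 1:
            cm[idx] = 0.0
            continue
        left = g[:, idx[:-1]]
        right = g[:, idx[1:]]
        hom = ((left == AA) | (left == BB)) & ((right == AA) | (right == BB))
        n_inf = hom.sum(axis=0)
        disc = ((left != right) & hom).sum(axis=0)
        with np.errstate(invalid="ignore"):
            big_r = np.where(n_inf > 0, disc / np.maximum(n_inf, 1), np.nan)
        big_r = np.where(n_inf < min_pair_lines, np.nan, big_r)
        clipped = big_r >= 0.5
        if np.nansum(clipped):
            warnings.warn(
                f"{int(np.nansum(clipped))} adjacent-bin pairs on {chrom} show "
                "discordance >= 0.5; clipped below 0.5"
            )
            big_r = np.where(clipped, 0.49999, big_r)
        r = np.full(big_r.shape, np.nan)
        ok = ~np.isnan(big_r)
        if population_type == "selfed-RIL":
            r[ok] = meiotic_from_ril_fraction(big_r[ok])
        else:
            r[ok] = big_r[ok]
        d = np.full(r.shape, np.nan)
        d[ok] = kosambi_distance(r[ok])
        if np.isnan(d).any():
            n_bad = int(np.isnan(d).sum())
            if ok.any():
                filled = pd.Series(d).ffill().bfill().to_numpy()
                logger.info(
                    "%s: %d adjacent pairs below %d informative lines; "
                    "borrowed nearest informative distance",
                    chrom, n_bad, min_pair_lines,
                )
                d = filled
            else:
                d = np.zeros_like(d)
                logger.warning("%s: no informative adjacent pairs; flat map", chrom)
        cm[idx] = np.concatenate([[0.0], np.cumsum(d)])
    bins["cm"] = cm
    return BinMap(
        bins=bins,
        genotypes=binmap.genotypes,
        line_ids=list(binmap.line_ids),
        chrom_lengths=dict(binmap.chrom_lengths),
    )


# ---------------------------------------------------------------------------
# estimator facade


class BinMapper(BaseEstimator):
    """Estimator running the full raw-calls -> bin-map pipeline.

    Parameters mirror :class:`QCConfig` plus the imputation emission error.
    After ``fit(raw)`` the results are available as fitted attributes:
    ``consensus_`` (window-called tracks for all input lines), ``line_stats_``,
    ``kept_lines_`` (boolean mask), ``imputed_`` (kept lines only),
    ``binmap_`` (filtered bins with a Kosambi genetic map) and
    ``genetic_map_length_``.  ``fit_transform`` returns ``binmap_``.
    """

    def __init__(
        self,
        window_size: int = 20,
        step: int = 2,
        purity: float = 0.7,
        min_window_informative: int = 5,
        min_genotyped: int = 20_000,
        max_line_het: float = 0.10,
        max_line_breakpoints: int = 200,
        max_bin_distortion: float = 2.0,
        max_bin_het: float = 0.10,
        emission_error: float = 0.005,
        min_pair_lines: int = 20,
        population_type: str = "selfed-RIL",
    ):
        self.window_size = window_size
        self.step = step
        self.purity = purity
        self.min_window_informative = min_window_informative
        self.min_genotyped = min_genotyped
        self.max_line_het = max_line_het
        self.max_line_breakpoints = max_line_breakpoints
        self.max_bin_distortion = max_bin_distortion
        self.max_bin_het = max_bin_het
        self.emission_error = emission_error
        self.min_pair_lines = min_pair_lines
        self.population_type = population_type

    def _config(self) -> QCConfig:
        return QCConfig(
            window_size=self.window_size,
            step=self.step,
            purity=self.purity,
            min_window_informative=self.min_window_informative,
            min_genotyped=self.min_genotyped,
            max_line_het=self.max_line_het,
            max_line_breakpoints=self.max_line_breakpoints,
            max_bin_distortion=self.max_bin_distortion,
            max_bin_het=self.max_bin_het,
            emission_error=self.emission_error,
            min_pair_lines=self.min_pair_lines,
        )

    def fit(self, X: RawGenotypeMatrix, y=None) -> "BinMapper":
        cfg = self._config()
        snps = X.snps
        pos = snps.table["pos"].to_numpy()
        cm = snps.table["cm"].to_numpy()
        n_lines = X.n_lines
        consensus = np.full(X.calls.shape, MISSING, dtype=np.int8)
        for chrom in snps.chromosomes:
            idx = snps.chrom_indices(chrom)
            for i in range(n_lines):
                consensus[i, idx] = call_windows(X.calls[i, idx], cfg)
        stats = line_statistics(X, consensus)
        keep = filter_lines(stats, cfg)
        kept_ids = [lid for lid, k in zip(X.line_ids, keep) if k]
        if not kept_ids:
            raise ValueError("no lines survive quality control")
        kept_tracks = consensus[keep].copy()
        kept_tracks[kept_tracks == AB] = MISSING  # het set missing before imputing
        imputed = np.empty_like(kept_tracks)
        for chrom in snps.chromosomes:
            idx = snps.chrom_indices(chrom)
            if idx.size == 0:
                continue
            imputed[:, idx] = impute_argmax(
                kept_tracks[:, idx], cm[idx], self.emission_error
            )
        raw_binmap = build_bins(imputed, snps, kept_ids)
        filtered = filter_bins(raw_binmap, cfg)
        mapped = estimate_genetic_map(
            filtered, self.population_type, self.min_pair_lines
        )
        self.consensus_ = consensus
        self.line_stats_ = stats
        self.kept_lines_ = keep
        self.imputed_ = imputed
        self.unfiltered_binmap_ = raw_binmap
        self.binmap_ = mapped
        self.genetic_map_length_ = mapped.total_map_length()
        return self

    def fit_transform(self, X: RawGenotypeMatrix, y=None) -> BinMap:
        return self.fit(X).binmap_

    def transform(self, X=None) -> BinMap:
        if not hasattr(self, "binmap_"):
            raise ValueError("BinMapper is not fitted yet")
        return self.binmap_
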