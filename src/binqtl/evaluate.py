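"""Truth-based scoring of bin-map reconstruction on simulated data.

These helpers compare a reconstructed genotype track against the simulation
truth: crossover recall and false-discovery rate of detected breakpoints,
and mask-and-recover accuracy for the imputation step.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .codes import AA, BB, MISSING
from .sim import TrueGenotypeSet

__all__ = [
    "BreakpointScore",
    "score_breakpoints",
    "mask_and_recover",
    "run_finemap_study",
]


@dataclass
class BreakpointScore:
    n_true: int
    n_detected: int
    n_matched_true: int
    n_spurious: int

    @property
    def recall(self) -> float:
        return self.n_matched_true / self.n_true if self.n_true else 1.0

    @property
    def fdr(self) -> float:
        return self.n_spurious / self.n_detected if self.n_detected else 0.0


def _transitions(track: np.ndarray, pos: np.ndarray) -> np.ndarray:
    """Midpoint positions of state changes, skipping missing calls."""
    inf = np.flatnonzero(track != MISSING)
    states = track[inf]
    change = np.flatnonzero(np.diff(states) != 0)
    return (pos[inf[change]] + pos[inf[change + 1]]) // 2


def _skeleton_transitions(track: np.ndarray, pos: np.ndarray) -> np.ndarray:
    """Truth crossovers recoverable from a homozygous-only reconstruction:
    transitions of the homozygous skeleton (heterozygous stretches collapse,
    so AA..AB..BB counts once and AA..AB..AA not at all)."""
    hom = np.flatnonzero((track == AA) | (track == BB))
    states = track[hom]
    change = np.flatnonzero(np.diff(states) != 0)
    return (pos[hom[change]] + pos[hom[change + 1]]) // 2


def score_breakpoints(
    truth: TrueGenotypeSet,
    tracks: np.ndarray,
    line_indices: np.ndarray,
    tolerance_bp: float,
) -> BreakpointScore:
    """Score detected breakpoints in reconstructed tracks against truth.

    ``tracks`` holds the reconstructed genotype tracks for the lines given by
    ``line_indices`` (rows into the truth set).  A truth crossover (homozygous
    -skeleton transition) counts as recovered when a detected breakpoint lies
    within ``tolerance_bp``; a detected breakpoint counts as spurious when no
    truth transition of any kind (including heterozygous-segment boundaries)
    lies within the tolerance.
    """
    pos_all = truth.snps.table["pos"].to_numpy()
    n_true = n_det = n_match = n_spur = 0
    for row, line in enumerate(np.asarray(line_indices)):
        for chrom in truth.snps.chromosomes:
            idx = truth.snps.chrom_indices(chrom)
            if idx.size == 0:
                continue
            pos = pos_all[idx]
            true_track = truth.genotypes[line, idx]
            det = _transitions(tracks[row, idx], pos)
            skel = _skeleton_transitions(true_track, pos)
            any_true = _transitions(true_track, pos)
            n_true += skel.size
            n_det += det.size
            if skel.size and det.size:
                nearest = np.min(np.abs(skel[:, None] - det[None, :]), axis=1)
                n_match += int((nearest <= tolerance_bp).sum())
            if det.size:
                if any_true.size:
                    nearest = np.min(np.abs(det[:, None] - any_true[None, :]), axis=1)
                    n_spur += int((nearest > tolerance_bp).sum())
                else:
                    n_spur += det.size
    return BreakpointScore(n_true, n_det, n_match, n_spur)


def mask_and_recover(
    tracks: np.ndarray,
    cm: np.ndarray,
    mask_fraction: float,
    error_rate: float = 0.005,
    seed: int = 0,
) -> float:
    """Fraction of deliberately masked homozygous calls the imputer recovers.

    Masks ``mask_fraction`` of the observed homozygous calls uniformly at
    random, re-imputes, and compares the filled values against the hidden
    originals.
    """
    from .binmap import impute_argmax

    rng = np.random.default_rng(seed)
    tr = np.atleast_2d(np.asarray(tracks, dtype=np.int8)).copy()
    observed = np.argwhere((tr == AA) | (tr == BB))
    k = int(round(mask_fraction * len(observed)))
    if k == 0:
        return 1.0
    chosen = observed[rng.choice(len(observed), size=k, replace=False)]
    hidden = tr[chosen[:, 0], chosen[:, 1]].copy()
    tr[chosen[:, 0], chosen[:, 1]] = MISSING
    filled = impute_argmax(tr, cm, error_rate)
    recovered = filled[chosen[:, 0], chosen[:, 1]] == hidden
    return float(recovered.mean())


def run_finemap_study(
    n_recombinants: int = 11,
    n_progeny_per_class: int = 25,
    effect: float = 3.0,
    sd: float = 1.0,
    alpha: float = 0.05,
    region_bp: tuple[int, int] = (3_200_000, 3_800_000),
    qtl_segment_bp: tuple[int, int] = (3_475_000, 3_525_000),
    n_markers: int = 20,
    chrom: str = "chr2",
    seed: int = 0,
):
    """One simulated recombinant-derived progeny-testing campaign.

    Recombinants carry uniformly placed breakpoints across the region with a
    random heterozygous side; each is crossed to the homozygous tester and its
    progeny phenotyped under a dominant QTL sitting inside ``qtl_segment_bp``.
    Subfamily t-tests become directional constraints which are intersected
    (weakest-evidence conflict resolution).  Returns the fine-map result and
    whether the interval still contains the true QTL position.
    """
    from .finemap import (
        classify_recombinant,
        constraint_from_test,
        intersect_assignments,
        progeny_test,
    )
    from .sim import simulate_progeny_subfamily

    rng = np.random.default_rng(np.random.SeedSequence([seed, 7]))
    lo, hi = region_bp
    qtl_bp = int(rng.integers(qtl_segment_bp[0], qtl_segment_bp[1]))
    marker_pos = np.sort(rng.choice(np.arange(lo, hi), size=n_markers, replace=False))
    markers = [(f"M{p}", int(p)) for p in marker_pos]
    constraints = []
    for i in range(n_recombinants):
        bp = int(rng.integers(lo, hi))
        het_side = "left" if rng.integers(0, 2) == 0 else "right"
        genotypes = [
            ("het" if (p < bp) == (het_side == "left") else "homB") for _, p in markers
        ]
        try:
            rec = classify_recombinant(f"R{i + 1}", markers, genotypes)
        except ValueError:
            continue  # breakpoint fell outside the marker span
        qtl_in_het = (qtl_bp < bp) == (het_side == "left")
        fam = simulate_progeny_subfamily(
            n_progeny_per_class, effect, sd, qtl_in_het, rng
        )
        test = progeny_test(fam, rec.recombinant_id, alpha)
        constraints.append(constraint_from_test(rec, test))
    if not constraints:
        return None, False
    try:
        result = intersect_assignments(
            constraints, chrom, lo, hi, on_conflict="drop-weakest"
        )
    except ValueError:
        return None, False
    contains = result.start_bp <= qtl_bp <= result.end_bp
    return result, contains
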