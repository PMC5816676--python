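"""Recombinant-derived progeny-test fine-mapping.

Starting from a QTL support interval, the strategy is: find a line
heterozygous across the region on an otherwise homozygous background, self it
to produce near-isogenic lines and recombinants, classify each recombinant by
the single het/hom transition among its region markers, test each
recombinant's tester-crossed progeny for a phenotype contrast between the
segregating genotype classes, turn each test into a directional constraint
(the QTL lies on the heterozygous side of the breakpoint when the contrast is
significant, on the homozygous side otherwise), and intersect the constraints
into a fine interval, which is finally overlapped with gene annotations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .binmap import BinMap
from .codes import AB, MISSING

__all__ = [
    "RecombinantRecord",
    "SubfamilyTest",
    "Constraint",
    "FineMapResult",
    "find_het_region_lines",
    "classify_recombinant",
    "progeny_test",
    "constraint_from_test",
    "intersect_assignments",
    "genes_in_interval",
    "NotARecombinantError",
]

HET = "het"
HOM_A = "homA"
HOM_B = "homB"
MISSING_CODE = "missing"
_VALID = {HET, HOM_A, HOM_B, MISSING_CODE}


class NotARecombinantError(ValueError):
    """Marker pattern is not a single het/hom recombinant."""


@dataclass
class RecombinantRecord:
    """One recombinant: het on one side of a single breakpoint, hom on the
    other.  The breakpoint interval spans the two flanking informative
    markers (missing markers widen it)."""

    recombinant_id: str
    markers: list[tuple[str, int]]
    genotypes: list[str]
    breakpoint_left: tuple[str, int]
    breakpoint_right: tuple[str, int]
    het_side: str  # "left" or "right"
    hom_parent: str  # "A" or "B"


@dataclass
class SubfamilyTest:
    """Progeny t-test of one recombinant x tester subfamily."""

    recombinant_id: str
    n_het: int
    n_hom: int
    mean_het: float
    mean_hom: float
    t: float
    p_value: float
    alpha: float
    qtl_side: str  # "heterozygous" or "homozygous"


@dataclass
class Constraint:
    """Directional bound on the QTL position derived from one subfamily."""

    recombinant_id: str
    direction: str  # "downstream_of" (QTL > pos) or "upstream_of" (QTL < pos)
    pos_bp: int
    p_value: float = float("nan")


@dataclass
class FineMapResult:
    chrom: str
    start_bp: int
    end_bp: int
    supporting: list[str] = field(default_factory=list)
    consistent: list[str] = field(default_factory=list)
    inconsistent: list[Constraint] = field(default_factory=list)

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp


def find_het_region_lines(
    binmap: BinMap,
    chrom: str,
    start_bp: int,
    end_bp: int,
    max_background_het: float = 0.05,
) -> list[str]:
    """Lines heterozygous across every bin overlapping the region whose
    genome-wide heterozygosity outside the region stays below the cap,
    ranked by background homozygosity (cleanest background first)."""
    bins = binmap.bins
    in_region = (
        (bins["chrom"] == chrom)
        & (bins["start"].to_numpy() < end_bp)
        & (bins["end"].to_numpy() > start_bp)
    ).to_numpy()
    if not in_region.any():
        raise ValueError(f"region {chrom}:{start_bp}-{end_bp} overlaps no bin")
    g = binmap.genotypes
    het_in_region = (g[:, in_region] == AB).all(axis=1)
    outside = g[:, ~in_region]
    informative = outside != MISSING
    with np.errstate(invalid="ignore"):
        bg_het = np.where(
            informative.sum(axis=1) > 0,
            (outside == AB).sum(axis=1) / np.maximum(informative.sum(axis=1), 1),
            1.0,
        )
    hits = np.flatnonzero(het_in_region & (bg_het <= max_background_het))
    order = hits[np.argsort(bg_het[hits], kind="stable")]
    return [binmap.line_ids[i] for i in order]


def classify_recombinant(
    recombinant_id: str,
    markers: list[tuple[str, int]],
    genotypes: list[str],
) -> RecombinantRecord:
    """Locate the single het/hom transition among ordered region markers.

    Raises :class:`NotARecombinantError` for all-het or all-hom patterns,
    and ``ValueError`` for double recombinants (more than one transition) or
    a homozygous side mixing both parents.
    """
    if len(markers) != len(genotypes):
        raise ValueError("markers and genotypes differ in length")
    bad = set(genotypes) - _VALID
    if bad:
        raise ValueError(f"unknown genotype labels {sorted(bad)}; valid: {sorted(_VALID)}")
    inf_idx = [i for i, g in enumerate(genotypes) if g != MISSING_CODE]
    if len(inf_idx) < 2:
        raise ValueError("need at least two informative markers")
    pos = [markers[i][1] for i in inf_idx]
    if any(b < a for a, b in zip(pos, pos[1:])):
        raise ValueError("markers must be ordered by position")
    states = ["het" if genotypes[i] == HET else "hom" for i in inf_idx]
    changes = [k for k in range(len(states) - 1) if states[k] != states[k + 1]]
    if not changes:
        raise NotARecombinantError(
            f"{recombinant_id}: all-{states[0]} across informative markers"
        )
    if len(changes) > 1:
        raise ValueError(f"{recombinant_id}: double recombinant, excluded")
    k = changes[0]
    hom_genos = {genotypes[i] for i, s in zip(inf_idx, states) if s == "hom"}
    if len(hom_genos) > 1:
        raise ValueError(f"{recombinant_id}: homozygous side mixes both parents")
    return RecombinantRecord(
        recombinant_id=recombinant_id,
        markers=list(markers),
        genotypes=list(genotypes),
        breakpoint_left=markers[inf_idx[k]],
        breakpoint_right=markers[inf_idx[k + 1]],
        het_side="left" if states[0] == "het" else "right",
        hom_parent="A" if hom_genos == {HOM_A} else "B",
    )


def progeny_test(
    subfamily: pd.DataFrame,
    recombinant_id: str = "",
    alpha: float = 0.05,
    equal_var: bool = False,
) -> SubfamilyTest:
    """t-test of the phenotype contrast between the two progeny genotype
    classes ("het" vs "homB") of a tester-crossed recombinant.

    A significant contrast (p < alpha) places the QTL in the recombinant's
    heterozygous segment, otherwise in the homozygous segment.
    """
    if not {"genotype_class", "value"} <= set(subfamily.columns):
        raise ValueError("subfamily needs 'genotype_class' and 'value' columns")
    het = subfamily.loc[subfamily["genotype_class"] == "het", "value"].to_numpy(float)
    hom = subfamily.loc[subfamily["genotype_class"] == "homB", "value"].to_numpy(float)
    if het.size < 2 or hom.size < 2:
        raise ValueError("both genotype classes need >= 2 plants")
    with np.errstate(invalid="ignore"):
        t, p = sps.ttest_ind(het, hom, equal_var=equal_var)
    if np.isnan(p):  # zero variance in both classes: no evidence of contrast
        t, p = 0.0, 1.0
    return SubfamilyTest(
        recombinant_id=recombinant_id,
        n_het=het.size,
        n_hom=hom.size,
        mean_het=float(het.mean()),
        mean_hom=float(hom.mean()),
        t=float(t),
        p_value=float(p),
        alpha=alpha,
        qtl_side="heterozygous" if p < alpha else "homozygous",
    )


def constraint_from_test(
    record: RecombinantRecord, test: SubfamilyTest
) -> Constraint:
    """Directional constraint: the QTL is bounded by the flanking marker on
    the side assigned *against* — e.g. QTL in the right-hand het segment
    means QTL downstream of the left (homozygous-side) flanking marker."""
    qtl_right = (test.qtl_side == "heterozygous") == (record.het_side == "right")
    if qtl_right:
        return Constraint(
            recombinant_id=record.recombinant_id,
            direction="downstream_of",
            pos_bp=record.breakpoint_left[1],
            p_value=test.p_value,
        )
    return Constraint(
        recombinant_id=record.recombinant_id,
        direction="upstream_of",
        pos_bp=record.breakpoint_right[1],
        p_value=test.p_value,
    )


def intersect_assignments(
    constraints: list[Constraint],
    prior_chrom: str,
    prior_start: int,
    prior_end: int,
    on_conflict: str = "error",
) -> FineMapResult:
    """Intersect directional constraints into a fine interval.

    ``downstream_of`` constraints raise the lower bound, ``upstream_of``
    constraints lower the upper bound; the result is clipped to the prior
    interval.  On an empty intersection, ``on_conflict="error"`` raises
    naming the clashing constraints; ``"drop-weakest"`` iteratively sets
    aside the conflicting constraint whose test evidence is weakest (p-value
    nearest the decision boundary) and reports it as inconsistent.
    Order-invariant and idempotent.
    """
    if not constraints:
        raise ValueError("need at least one constraint")
    if prior_end <= prior_start:
        raise ValueError("prior interval is empty")
    if on_conflict not in ("error", "drop-weakest"):
        raise ValueError("on_conflict must be 'error' or 'drop-weakest'")
    active = sorted(constraints, key=lambda c: (c.direction, c.pos_bp, c.recombinant_id))
    dropped: list[Constraint] = []
    while True:
        lower, lo_c = prior_start, None
        upper, hi_c = prior_end, None
        for c in active:
            if c.direction == "downstream_of":
                if c.pos_bp > lower:
                    lower, lo_c = c.pos_bp, c
            elif c.direction == "upstream_of":
                if c.pos_bp < upper:
                    upper, hi_c = c.pos_bp, c
            else:
                raise ValueError(f"unknown direction {c.direction!r}")
        if lower < upper:
            break
        clash = [c for c in (lo_c, hi_c) if c is not None]
        if on_conflict == "error" or not clash:
            names = ", ".join(
                f"{c.recombinant_id or '?'} ({c.direction} {c.pos_bp})" for c in clash
            )
            raise ValueError(f"constraints produce an empty interval: {names}")
        # weakest evidence = p-value closest to the significance boundary;
        # NaN p (no test attached) is treated as weakest of all
        def strength(c: Constraint) -> float:
            if np.isnan(c.p_value):
                return -1.0
            return abs(np.log10(max(c.p_value, 1e-300)) - np.log10(0.05))

        weakest = min(clash, key=strength)
        warnings.warn(
            f"dropping conflicting constraint from {weakest.recombinant_id or '?'} "
            f"({weakest.direction} {weakest.pos_bp}, p={weakest.p_value:.3g})"
        )
        dropped.append(weakest)
        active = [c for c in active if c is not weakest]
        if not active:
            raise ValueError("all constraints conflict; no interval remains")
    binding = {c.recombinant_id for c in (lo_c, hi_c) if c is not None}
    consistent = [
        c.recombinant_id for c in active if c.recombinant_id not in binding
    ]
    return FineMapResult(
        chrom=prior_chrom,
        start_bp=lower,
        end_bp=upper,
        supporting=sorted(binding),
        consistent=sorted(set(consistent)),
        inconsistent=dropped,
    )


def genes_in_interval(
    chrom: str,
    start_bp: int,
    end_bp: int,
    annotation: pd.DataFrame,
) -> pd.DataFrame:
    """Genes with any overlap (>= 1 bp) with the interval, sorted by start.

    ``annotation`` needs columns chrom, start, end (1-based inclusive), id.
    """
    required = {"chrom", "start", "end", "id"}
    missing = required - set(annotation.columns)
    if missing:
        raise ValueError(f"annotation lacks columns: {sorted(missing)}")
    hit = (
        (annotation["chrom"].astype(str) == str(chrom))
        & (annotation["start"] <= end_bp)
        & (annotation["end"] >= start_bp)
    )
    return annotation.loc[hit].sort_values("start").reset_index(drop=True)
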