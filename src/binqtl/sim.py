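"""Synthetic RIL population, low-coverage GBS and phenotype generator.

This module emulates the data-generating process of a biparental maize RIL
study: two fully homozygous parents differing at a dense panel of biallelic
SNPs, recombinant inbred lines produced by single-seed descent from the F1,
sparse (< 0.1x) genotyping-by-sequencing observations of each line, and
multi-environment phenotypes controlled by planted QTLs plus line-by-location,
line-by-year and residual variance components.  Every stage records its truth
(crossover positions, genotypes, genetic values, planted variance shares) so
that downstream bin-map construction, QTL scans and fine-mapping can be scored
against a known answer.

Crossovers are drawn as a Poisson process on the genetic map (no interference)
and the physical-to-genetic map is linear per chromosome (constant cM/Mb);
both choices are deliberate simplifications, see docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .codes import AA, AB, BB, MISSING

__all__ = [
    "SNPSet",
    "TrueGenotypeSet",
    "RawGenotypeMatrix",
    "QTLEffect",
    "SimPhenotypeSpec",
    "PhenotypeTruth",
    "simulate_parent_snps",
    "simulate_meiosis",
    "simulate_ril_population",
    "simulate_gbs_observations",
    "simulate_phenotypes",
    "paper_like_phenotype_spec",
    "line_means",
    "simulate_progeny_subfamily",
]

_NUCS = np.array(list("ACGT"))


@dataclass
class SNPSet:
    """Biallelic parental SNP panel with physical and genetic coordinates.

    ``table`` has one row per SNP with columns ``chrom``, ``pos`` (bp, 1-based),
    ``allele_a``, ``allele_b`` and ``cm``; rows are sorted by chromosome (in
    ``chrom_lengths`` order) then position.
    """

    table: pd.DataFrame
    chrom_lengths: dict[str, int]

    def __post_init__(self) -> None:
        required = {"chrom", "pos", "allele_a", "allele_b", "cm"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"SNP table lacks columns: {sorted(missing)}")
        for chrom, sub in self.table.groupby("chrom", sort=False):
            pos = sub["pos"].to_numpy()
            if not (np.diff(pos) > 0).all():
                raise ValueError(f"SNP positions not strictly increasing on {chrom}")
            if not (np.diff(sub["cm"].to_numpy()) >= 0).all():
                raise ValueError(f"genetic positions decrease on {chrom}")
        if (self.table["allele_a"].to_numpy() == self.table["allele_b"].to_numpy()).any():
            raise ValueError("parents share an allele at some SNP")

    @property
    def n_snps(self) -> int:
        return len(self.table)

    @property
    def chromosomes(self) -> list[str]:
        return list(self.chrom_lengths)

    def chrom_indices(self, chrom: str) -> np.ndarray:
        """Row indices (contiguous) of SNPs on one chromosome."""
        return np.flatnonzero((self.table["chrom"] == chrom).to_numpy())

    def locate(self, chrom: str, pos_bp: float) -> int:
        """Global index of the SNP nearest to ``pos_bp`` on ``chrom``."""
        idx = self.chrom_indices(chrom)
        if idx.size == 0:
            raise ValueError(f"no SNPs on chromosome {chrom!r}")
        pos = self.table["pos"].to_numpy()[idx]
        return int(idx[np.argmin(np.abs(pos - pos_bp))])


@dataclass
class TrueGenotypeSet:
    """Simulation truth: final RIL genotypes plus every drawn crossover.

    ``genotypes`` is lines x SNPs with codes 0/1/2 (AA/AB/BB).  ``crossovers``
    lists each meiotic crossover drawn on the surviving single-seed-descent
    lineage chain (columns ``line``, ``generation``, ``chrom``, ``pos_bp``);
    note that only a subset of drawn crossovers remains visible as a genotype
    transition in the final line.
    """

    snps: SNPSet
    line_ids: list[str]
    genotypes: np.ndarray
    crossovers: pd.DataFrame

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    def realized_breakpoints(self, line: int, chrom: str) -> np.ndarray:
        """Midpoint bp positions where the final genotype switches state."""
        idx = self.snps.chrom_indices(chrom)
        g = self.genotypes[line, idx]
        pos = self.snps.table["pos"].to_numpy()[idx]
        change = np.flatnonzero(np.diff(g) != 0)
        return (pos[change] + pos[change + 1]) // 2

    def residual_heterozygosity(self) -> float:
        """Population mean fraction of heterozygous loci."""
        return float((self.genotypes == AB).mean())


@dataclass
class RawGenotypeMatrix:
    """Observed low-coverage parental-origin calls (lines x SNPs).

    ``calls`` uses the shared codes (-1 missing); ``depth`` is the simulated
    read count per cell, with depth 0 if and only if the call is missing.
    """

    snps: SNPSet
    line_ids: list[str]
    calls: np.ndarray
    depth: np.ndarray

    def __post_init__(self) -> None:
        if self.calls.shape != self.depth.shape:
            raise ValueError("calls and depth shapes differ")
        if ((self.depth == 0) != (self.calls == MISSING)).any():
            raise ValueError("depth 0 must coincide with missing calls")

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    def genotyped_counts(self) -> np.ndarray:
        return (self.calls != MISSING).sum(axis=1)


@dataclass
class QTLEffect:
    """One planted QTL: additive effect ``a`` (trait units, +a for AA, -a for
    BB) and heterozygote value ``d`` (d = a is complete dominance of A)."""

    chrom: str
    pos_bp: float
    add: float
    dom: float = 0.0


@dataclass
class SimPhenotypeSpec:
    """Phenotype model: planted QTLs, a polygenic line effect and the
    variance components of a line x location x year x replicate trial."""

    qtls: list[QTLEffect] = field(default_factory=list)
    var_line_poly: float = 0.0
    var_line_loc: float = 0.0
    var_line_year: float = 0.0
    var_residual: float = 1.0
    n_locations: int = 2
    n_years: int = 2
    n_reps: int = 2
    intercept: float = 0.0
    loc_effects: list[float] | None = None
    year_effects: list[float] | None = None

    def __post_init__(self) -> None:
        for name in ("var_line_poly", "var_line_loc", "var_line_year", "var_residual"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("n_locations", "n_years", "n_reps"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    def genetic_variance(self) -> float:
        """Expected var(Line) under free segregation of the planted QTLs."""
        v = self.var_line_poly
        for q in self.qtls:
            v += q.add**2  # homozygote classes at +-a, each ~1/2 of lines
        return v

    def planted_pve(self, qtl_index: int = 0) -> float:
        """Expected % variance explained by one QTL among per-environment
        line means (mean over replicates within one location-year cell)."""
        v_env = (
            self.genetic_variance()
            + self.var_line_loc
            + self.var_line_year
            + self.var_residual / self.n_reps
        )
        return 100.0 * self.qtls[qtl_index].add ** 2 / v_env

    def planted_h2(self) -> float:
        """Broad-sense heritability implied by the planted components."""
        e, r = self.n_locations, self.n_years
        g = self.genetic_variance()
        if g + self.var_line_loc + self.var_line_year + self.var_residual == 0:
            return float("nan")
        return g / (
            g
            + self.var_line_loc / e
            + self.var_line_year / r
            + self.var_residual / (r * e)
        )


@dataclass
class PhenotypeTruth:
    """Per-line genetic values and the planted variance shares."""

    genetic_values: np.ndarray
    qtl_snp_index: list[int]
    planted_pve: list[float]
    planted_h2: float


def _spawn(seed: int, *path: int) -> np.random.Generator:
    """Derive an independent, reproducible stream for one simulation stage
    from the master seed and a stage path."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), *path]))


def simulate_parent_snps(
    n_snps: int,
    chrom_lengths: dict[str, int],
    cm_per_mb: float = 1.0,
    seed: int = 0,
) -> SNPSet:
    """Place ``n_snps`` biallelic SNPs uniformly over the chromosomes.

    SNP counts per chromosome are proportional to physical length
    (multinomial draw); positions are unique, sorted, 1-based bp.  The genetic
    coordinate is linear: cm = pos / 1e6 * cm_per_mb.
    """
    if n_snps < 0:
        raise ValueError("n_snps must be >= 0")
    if not chrom_lengths or any(length <= 0 for length in chrom_lengths.values()):
        raise ValueError("chromosome lengths must be positive")
    if cm_per_mb < 0:
        raise ValueError("cm_per_mb must be >= 0")
    rng = _spawn(seed, 0)
    lengths = np.array(list(chrom_lengths.values()), dtype=float)
    counts = rng.multinomial(n_snps, lengths / lengths.sum())
    frames = []
    for (chrom, length), k in zip(chrom_lengths.items(), counts):
        k = min(int(k), int(length))
        pos = np.sort(rng.choice(length, size=k, replace=False)) + 1
        ref = rng.integers(0, 4, size=k)
        alt = (ref + rng.integers(1, 4, size=k)) % 4
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "pos": pos.astype(np.int64),
                    "allele_a": _NUCS[ref],
                    "allele_b": _NUCS[alt],
                    "cm": pos / 1e6 * cm_per_mb,
                }
            )
        )
    table = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["chrom", "pos", "allele_a", "allele_b", "cm"]
    )
    return SNPSet(table=table, chrom_lengths=dict(chrom_lengths))


def simulate_meiosis(
    genetic_length: float, rng: np.random.Generator | int = 0
) -> np.ndarray:
    """Crossover positions (Morgans) of one gamete on one chromosome.

    Count ~ Poisson(genetic_length), positions uniform on [0, length): the
    interference-free (Haldane) crossover process.
    """
    if genetic_length < 0:
        raise ValueError("genetic length must be >= 0")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    n = rng.poisson(genetic_length)
    return np.sort(rng.uniform(0.0, genetic_length, size=n))


def _batch_gamete_masks(
    n_gametes: int,
    snp_morgans: np.ndarray,
    genetic_length: float,
    rng: np.random.Generator,
):
    """Draw crossovers for a batch of gametes and return, per gamete, the
    haplotype-choice mask at every SNP (0 -> haplotype 1, 1 -> haplotype 2)
    together with the flat crossover positions and their gamete index."""
    counts = rng.poisson(genetic_length, size=n_gametes)
    total = int(counts.sum())
    pos = rng.uniform(0.0, genetic_length, size=total)
    gamete_idx = np.repeat(np.arange(n_gametes), counts)
    s = snp_morgans.size
    toggles = np.zeros((n_gametes, s + 1), dtype=np.int32)
    np.add.at(toggles, (gamete_idx, np.searchsorted(snp_morgans, pos)), 1)
    parity = np.cumsum(toggles[:, :s], axis=1)
    start = rng.integers(0, 2, size=n_gametes)[:, None]
    mask = (parity + start) % 2
    return mask.astype(np.int8), pos, gamete_idx


def simulate_ril_population(
    parents: SNPSet,
    n_lines: int,
    n_selfing_generations: int = 6,
    seed: int = 0,
) -> TrueGenotypeSet:
    """Single-seed-descent RILs from an F1 of two inbred parents.

    Each line is an independent SSD lineage: starting from the F1 (one
    haplotype from each parent), every generation draws one egg and one pollen
    gamete from the current plant and the resulting single selfed seed
    continues the line.  ``n_selfing_generations`` counts selfing meioses
    applied to the F1, so g generations leave residual heterozygosity
    (1/2)^g per locus in expectation (g=6 corresponds to F7 plants, i.e.
    F6:7 families).
    """
    if parents.n_snps == 0:
        raise ValueError("parents carry no SNPs")
    if n_selfing_generations < 1:
        raise ValueError("need at least one selfing generation")
    if n_lines < 0:
        raise ValueError("n_lines must be >= 0")
    n_snps = parents.n_snps
    genotypes = np.zeros((n_lines, n_snps), dtype=np.int8)
    xo_rows: list[pd.DataFrame] = []
    cm = parents.table["cm"].to_numpy()
    for chrom in parents.chromosomes:
        idx = parents.chrom_indices(chrom)
        if idx.size == 0:
            continue
        snp_m = cm[idx] / 100.0
        chrom_len_m = max(
            float(snp_m[-1]), parents.chrom_lengths[chrom] / 1e6 * _cm_per_mb(parents, chrom) / 100.0
        )
        rng = _spawn(seed, 1, _chrom_key(parents, chrom))
        h1 = np.zeros((n_lines, idx.size), dtype=np.int8)  # parent A haplotype
        h2 = np.ones((n_lines, idx.size), dtype=np.int8)  # parent B haplotype
        for gen in range(1, n_selfing_generations + 1):
            for gamete in range(2):
                mask, pos_m, gidx = _batch_gamete_masks(
                    n_lines, snp_m, chrom_len_m, rng
                )
                if pos_m.size:
                    xo_rows.append(
                        pd.DataFrame(
                            {
                                "line": gidx,
                                "generation": gen,
                                "chrom": chrom,
                                "pos_bp": _morgans_to_bp(parents, chrom, pos_m),
                            }
                        )
                    )
                new = np.where(mask == 0, h1, h2)
                if gamete == 0:
                    egg = new
                else:
                    h1, h2 = egg, new
        genotypes[:, idx] = h1 + h2  # 0=AA, 1=AB, 2=BB
    crossovers = (
        pd.concat(xo_rows, ignore_index=True)
        if xo_rows
        else pd.DataFrame(columns=["line", "generation", "chrom", "pos_bp"])
    )
    line_ids = [f"L{i + 1:04d}" for i in range(n_lines)]
    return TrueGenotypeSet(
        snps=parents, line_ids=line_ids, genotypes=genotypes, crossovers=crossovers
    )


def _chrom_key(parents: SNPSet, chrom: str) -> int:
    return parents.chromosomes.index(chrom)


def _cm_per_mb(parents: SNPSet, chrom: str) -> float:
    idx = parents.chrom_indices(chrom)
    pos = parents.table["pos"].to_numpy()[idx]
    cm = parents.table["cm"].to_numpy()[idx]
    if idx.size < 2 or pos[-1] == pos[0]:
        return 1.0
    return float((cm[-1] - cm[0]) / ((pos[-1] - pos[0]) / 1e6))


def _morgans_to_bp(parents: SNPSet, chrom: str, pos_m: np.ndarray) -> np.ndarray:
    rate = _cm_per_mb(parents, chrom)
    if rate == 0:
        return np.zeros_like(pos_m)
    return (pos_m * 100.0 / rate * 1e6).astype(np.int64)


def simulate_gbs_observations(
    truth: TrueGenotypeSet,
    mean_depth: float,
    error_rate: float = 0.0,
    seed: int = 0,
) -> RawGenotypeMatrix:
    """Low-coverage per-SNP observations of every line.

    Per-cell read depth ~ Poisson(mean_depth); sites with depth 0 are missing.
    Each read reports the parental origin of one sampled chromosome and flips
    to the other parent with probability ``error_rate``.  A site is called
    heterozygous only when reads of both parental alleles are seen (hence
    depth >= 2); single-read sites are called homozygous for the observed
    allele, which is what makes heterozygous segments look like salt-and-pepper
    homozygous calls at < 0.1x coverage.
    """
    if mean_depth < 0:
        raise ValueError("mean_depth must be >= 0")
    if not 0 <= error_rate < 0.5:
        raise ValueError("error_rate must be in [0, 0.5)")
    rng = _spawn(seed, 2)
    g = truth.genotypes
    depth = rng.poisson(mean_depth, size=g.shape)
    p_b = np.where(g == AA, error_rate, np.where(g == BB, 1.0 - error_rate, 0.5))
    n_b = rng.binomial(depth, p_b)
    n_a = depth - n_b
    calls = np.full(g.shape, MISSING, dtype=np.int8)
    calls[(n_a > 0) & (n_b == 0)] = AA
    calls[(n_b > 0) & (n_a == 0)] = BB
    calls[(n_a > 0) & (n_b > 0)] = AB
    return RawGenotypeMatrix(
        snps=truth.snps, line_ids=list(truth.line_ids), calls=calls, depth=depth
    )


def paper_like_phenotype_spec() -> SimPhenotypeSpec:
    """Default trait architecture emulating the study conditions.

    One major completely dominant QTL (a = d = 1.41 trait units) and three
    minor additive QTLs (0.40, -0.52, 0.44), placed >= 60 cM apart so linkage
    covariance between planted effects is negligible; the polygenic and
    environmental components are chosen so the major QTL explains 25% of the
    per-environment line-mean variance and broad-sense heritability is 0.89
    in a 2-location x 2-year x 2-replicate balanced trial.
    """
    return SimPhenotypeSpec(
        qtls=[
            QTLEffect(chrom="chr2", pos_bp=3_400_000, add=1.41, dom=1.41),
            QTLEffect(chrom="chr1", pos_bp=25_000_000, add=0.40),
            QTLEffect(chrom="chr1", pos_bp=85_000_000, add=-0.52),
            QTLEffect(chrom="chr1", pos_bp=145_000_000, add=0.44),
        ],
        var_line_poly=3.76,
        var_line_loc=0.30,
        var_line_year=0.30,
        var_residual=1.951,
        n_locations=2,
        n_years=2,
        n_reps=2,
        intercept=10.5,
    )


def simulate_phenotypes(
    truth: TrueGenotypeSet,
    spec: SimPhenotypeSpec,
    seed: int = 0,
    max_snap_bp: float = 2e6,
) -> tuple[pd.DataFrame, PhenotypeTruth]:
    """Multi-environment phenotypes for every line under ``spec``.

    Each record is ``intercept + genetic value + loc + year + line:loc +
    line:year + residual``.  QTL positions are snapped to the nearest panel
    SNP (within ``max_snap_bp``); the genetic value of a line is the sum of
    its QTL genotype effects (+a / d / -a) plus a polygenic normal draw.
    Returns the long-format table (line, location, year, rep, value) and the
    truth record.
    """
    rng = _spawn(seed, 3)
    n = truth.n_lines
    genetic = np.zeros(n)
    qtl_idx: list[int] = []
    for q in spec.qtls:
        if q.chrom not in truth.snps.chromosomes:
            raise ValueError(f"QTL chromosome {q.chrom!r} not simulated")
        if not 0 <= q.pos_bp <= truth.snps.chrom_lengths[q.chrom]:
            raise ValueError(f"QTL position {q.pos_bp} outside {q.chrom}")
        j = truth.snps.locate(q.chrom, q.pos_bp)
        if abs(truth.snps.table["pos"].iloc[j] - q.pos_bp) > max_snap_bp:
            raise ValueError(f"no SNP within {max_snap_bp} bp of QTL at {q.pos_bp}")
        qtl_idx.append(j)
        g = truth.genotypes[:, j]
        genetic += np.where(g == AA, q.add, np.where(g == BB, -q.add, q.dom))
    genetic += rng.normal(0.0, np.sqrt(spec.var_line_poly), size=n)

    e, r, m = spec.n_locations, spec.n_years, spec.n_reps
    loc_eff = np.asarray(spec.loc_effects if spec.loc_effects is not None else np.zeros(e), float)
    year_eff = np.asarray(spec.year_effects if spec.year_effects is not None else np.zeros(r), float)
    if loc_eff.size != e or year_eff.size != r:
        raise ValueError("loc_effects / year_effects length must match design")
    line_loc = rng.normal(0.0, np.sqrt(spec.var_line_loc), size=(n, e))
    line_year = rng.normal(0.0, np.sqrt(spec.var_line_year), size=(n, r))
    resid = rng.normal(0.0, np.sqrt(spec.var_residual), size=(n, e, r, m))

    value = (
        spec.intercept
        + genetic[:, None, None, None]
        + loc_eff[None, :, None, None]
        + year_eff[None, None, :, None]
        + line_loc[:, :, None, None]
        + line_year[:, None, :, None]
        + resid
    )
    lines = np.repeat(np.arange(n), e * r * m)
    locs = np.tile(np.repeat(np.arange(e), r * m), n)
    years = np.tile(np.repeat(np.arange(r), m), n * e)
    reps = np.tile(np.arange(m), n * e * r)
    table = pd.DataFrame(
        {
            "line": np.asarray(truth.line_ids)[lines],
            "location": [f"loc{j + 1}" for j in locs],
            "year": [f"year{k + 1}" for k in years],
            "rep": reps + 1,
            "value": value.ravel(),
        }
    )
    pt = PhenotypeTruth(
        genetic_values=genetic,
        qtl_snp_index=qtl_idx,
        planted_pve=[spec.planted_pve(i) for i in range(len(spec.qtls))],
        planted_h2=spec.planted_h2(),
    )
    return table, pt


def line_means(
    phenotypes: pd.DataFrame,
    location: str | None = None,
    year: str | None = None,
) -> pd.Series:
    """Per-line phenotype means, optionally within one location/year cell."""
    df = phenotypes
    if location is not None:
        df = df[df["location"] == location]
    if year is not None:
        df = df[df["year"] == year]
    if df.empty:
        raise ValueError("no phenotype records match the requested environment")
    return df.groupby("line", sort=False)["value"].mean()


def simulate_progeny_subfamily(
    n_per_class: int,
    effect: float,
    sd: float,
    qtl_in_het: bool,
    rng: np.random.Generator | int = 0,
) -> pd.DataFrame:
    """Progeny of one recombinant x tester cross for a progeny test.

    Progeny segregate 1:1 into heterozygous and homozygous-tester classes at
    the recombinant's heterozygous segment.  If the QTL lies in that segment
    (``qtl_in_het``), the class means differ by ``effect`` trait units
    (dominant QTL: het class shifted); otherwise both classes share one mean.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    classes = np.array(["het"] * n_per_class + ["homB"] * n_per_class)
    values = rng.normal(0.0, sd, size=2 * n_per_class)
    if qtl_in_het:
        values[: n_per_class] += effect
    return pd.DataFrame({"genotype_class": classes, "value": values})
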