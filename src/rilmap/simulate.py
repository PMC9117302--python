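"""Synthetic biparental RIL populations with chromosome rearrangements.

The simulator produces the statistical structure the analysis stages
assume, together with full truth records, so every downstream method can
be tested against a known answer:

* meiosis is simulated explicitly for each selfing generation (single-seed
  descent from an F1), so the selfing depth F_k genuinely controls residual
  heterozygosity;
* crossover counts per chromosome are Poisson with mean equal to the
  genetic length (Haldane model, no interference) and crossover positions
  are uniform on the physical map at a constant cM/Mbp rate;
* a translocation heterozygote is modelled by its observable meiotic
  consequences rather than cytologically: the donor and recipient
  chromosomes segregate with a shared phase anchored in their largest
  non-recombining interval, crossovers are confined to the declared
  recombining regions of the quadrivalent, and gametes carrying the
  deficiency product (recipient distal region from the non-carrier parent
  together with the donor distal region from the carrier) survive with a
  configurable probability - which is what produces pseudo-linkage,
  recombination suppression and distortion toward the carrier parent;
* an inversion heterozygote permits crossovers only outside the inverted
  interval;
* phenotypes follow an additive QTL model with environment and residual
  noise; GBS-like degradation (missingness, spurious heterozygote calls,
  miscalls) is applied as an independent final step with the truth matrix
  retained.

Identical seeds give byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .genome import GenomeLayout, toy_layout
from .markers import A, B, H, MISSING, MarkerTable

PARENT_A, PARENT_B = 0, 1
_PARENT_IDX = {"A": PARENT_A, "B": PARENT_B}


# -- specs -------------------------------------------------------------------

@dataclass(frozen=True)
class QtlSpec:
    trait: str
    chromosome: str
    position_bp: int
    effect: float  # additive effect a; homozygous class means differ by 2a


@dataclass(frozen=True)
class TranslocationSpec:
    """Unbalanced translocation of a donor segment onto a recipient end.

    ``recombining_regions`` lists the intervals (on either chromosome, in
    bp) where the heterozygote's quadrivalent permits viable crossovers;
    everywhere else the two chromosomes co-segregate.  ``deficiency_survival``
    is the survival probability of gametes missing the translocated
    segment; values below 1 distort segregation toward the carrier.
    """

    donor: str
    recipient: str
    donor_region: tuple[int, int]      # bp on the donor chromosome
    recipient_region: tuple[int, int]  # bp the material occupies on the recipient
    carrier: str = "A"
    recombining_regions: tuple[tuple[str, int, int], ...] = ()
    deficiency_survival: float = 1.0


@dataclass(frozen=True)
class InversionSpec:
    """Inversion suppressing observable recombination in heterozygotes."""

    chromosome: str
    start_bp: int
    end_bp: int
    carrier: str = "A"


@dataclass(frozen=True)
class DistortionSpec:
    """Gametic selection at a locus: unfavoured gametes survive w.p. 1-s."""

    chromosome: str
    position_bp: int
    favored: str = "A"
    selection: float = 0.0


@dataclass
class SimConfig:
    """Study conditions for one simulated RIL population.

    Defaults emulate a mid-sized GBS-genotyped oat-style RIL population:
    200 F6 lines, 100 markers per chromosome, a sparse-data degradation of
    30% missing calls with 1% spurious heterozygotes and 1% miscalls.
    """

    layout: GenomeLayout = field(default_factory=lambda: toy_layout(2, 200))
    n_lines: int = 200
    generations: int = 6          # F_k; F1 -> F_k is k-1 selfings
    markers_per_chromosome: int = 100
    cm_per_mbp: float = 0.2
    translocations: tuple[TranslocationSpec, ...] = ()
    inversions: tuple[InversionSpec, ...] = ()
    distortions: tuple[DistortionSpec, ...] = ()
    qtls: tuple[QtlSpec, ...] = ()
    trait_mean: float = 50.0
    n_environments: int = 1
    environment_sd: float = 0.0
    residual_sd: float | None = None
    heritability: float = 0.5     # used to derive residual_sd when unset
    missing_rate: float = 0.30
    het_rate: float = 0.01
    miscall_rate: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("missing_rate", "het_rate", "miscall_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.generations < 2:
            raise ValueError("generations must be >= 2 (F2 or deeper)")
        if self.n_lines < 1 or self.markers_per_chromosome < 2:
            raise ValueError("need >= 1 line and >= 2 markers per chromosome")
        if self.seed is None:
            raise ValueError("a seed is mandatory for reproducibility")
        for q in self.qtls:
            if q.chromosome not in self.layout:
                raise ValueError(f"QTL chromosome {q.chromosome!r} not in layout")

    def resolved_residual_sd(self) -> float:
        """Residual SD implied by the per-environment heritability target.

        With allele scores of +-1 at frequency 1/2 the genetic variance is
        the sum of squared additive effects; ``heritability`` is the
        fraction of single-environment phenotypic variance it explains.
        """
        if self.residual_sd is not None:
            return self.residual_sd
        genetic_var = sum(q.effect ** 2 for q in self.qtls)
        if genetic_var == 0:
            return 1.0
        h2 = self.heritability
        if not 0.0 < h2 < 1.0:
            raise ValueError("heritability must be in (0, 1) to derive noise")
        return float(np.sqrt(genetic_var * (1.0 - h2) / h2))


# -- haplotypes --------------------------------------------------------------

class Haplotype:
    """Piecewise-constant founder origin along one chromosome."""

    __slots__ = ("starts", "origins")

    def __init__(self, starts: np.ndarray, origins: np.ndarray) -> None:
        self.starts = starts    # ascending, starts[0] == span.start
        self.origins = origins  # founder labels (0 = parent A, 1 = parent B)

    @classmethod
    def founder(cls, span, parent: int) -> "Haplotype":
        return cls(np.array([float(span.start)]),
                   np.array([parent], dtype=np.int8))

    def origin_at(self, positions) -> np.ndarray:
        idx = np.searchsorted(self.starts, np.atleast_1d(positions),
                              side="right") - 1
        return self.origins[idx]


def _splice(h1: Haplotype, h2: Haplotype, crossovers: np.ndarray,
            anchor: float, phase0: int, span) -> Haplotype:
    """Form a gamete from two haplotypes.

    The gamete copies ``h1`` where the phase is 0 and ``h2`` where it is 1;
    the phase equals ``phase0`` at ``anchor`` and flips at each crossover.
    """
    cx = np.sort(crossovers)
    starts = np.unique(np.concatenate(
        [[float(span.start)], h1.starts, h2.starts, cx]
    ))
    par = np.searchsorted(cx, starts, side="right") % 2
    par_anchor = int(np.searchsorted(cx, anchor, side="right") % 2)
    phase = phase0 ^ par ^ par_anchor
    o1 = h1.origin_at(starts)
    o2 = h2.origin_at(starts)
    origins = np.where(phase == 0, o1, o2).astype(np.int8)
    keep = np.empty(len(starts), dtype=bool)
    keep[0] = True
    keep[1:] = origins[1:] != origins[:-1]
    return Haplotype(starts[keep], origins[keep].copy())


# -- meiosis -----------------------------------------------------------------

def _region_lengths(regions: list[tuple[float, float]]) -> np.ndarray:
    return np.array([hi - lo for lo, hi in regions])


def _draw_crossovers(rng, regions: list[tuple[float, float]],
                     morgans_per_bp: float) -> np.ndarray:
    lengths = _region_lengths(regions)
    total = lengths.sum()
    lam = total * morgans_per_bp
    n = rng.poisson(lam)
    if n == 0:
        return np.empty(0)
    which = rng.choice(len(regions), size=n, p=lengths / total)
    u = rng.random(n)
    lo = np.array([regions[i][0] for i in which])
    hi = np.array([regions[i][1] for i in which])
    return lo + u * (hi - lo)


def _subtract_region(full: tuple[float, float],
                     holes: list[tuple[float, float]]
                     ) -> list[tuple[float, float]]:
    """Complement of ``holes`` within ``full`` (non-overlapping holes)."""
    out = []
    cur = full[0]
    for lo, hi in sorted(holes):
        if lo > cur:
            out.append((cur, lo))
        cur = max(cur, hi)
    if cur < full[1]:
        out.append((cur, full[1]))
    return out


def _largest_gap_midpoint(span, allowed: list[tuple[float, float]]) -> float:
    gaps = _subtract_region((float(span.start), float(span.end)), allowed)
    if not gaps:
        return float(span.start)
    lo, hi = max(gaps, key=lambda g: g[1] - g[0])
    return 0.5 * (lo + hi)


class _Meiosis:
    """One meiosis of one individual; resolves rearrangement zygosity."""

    def __init__(self, cfg: SimConfig, rng: np.random.Generator) -> None:
        self.cfg = cfg
        self.rng = rng
        self.morgans_per_bp = cfg.cm_per_mbp / 100.0 / 1e6

    def gamete(self, individual: dict[str, tuple[Haplotype, Haplotype]]
               ) -> dict[str, Haplotype]:
        while True:
            out = self._gamete_once(individual)
            if not self.cfg.distortions or self._survives(out):
                return out

    def _gamete_once(self, individual: dict[str, tuple[Haplotype, Haplotype]]
                     ) -> dict[str, Haplotype]:
        cfg, rng = self.cfg, self.rng
        out: dict[str, Haplotype] = {}
        handled: set[str] = set()

        for spec in cfg.translocations:
            h1r, h2r = individual[spec.recipient]
            h1d, h2d = individual[spec.donor]
            probe_r = 0.5 * (spec.recipient_region[0] + spec.recipient_region[1])
            probe_d = 0.5 * (spec.donor_region[0] + spec.donor_region[1])
            het = (h1r.origin_at(probe_r)[0] != h2r.origin_at(probe_r)[0]
                   or h1d.origin_at(probe_d)[0] != h2d.origin_at(probe_d)[0])
            if not het:
                continue
            carrier = _PARENT_IDX[spec.carrier]
            for _ in range(1000):
                phase0 = int(rng.integers(2))
                gams = {}
                for chrom in (spec.recipient, spec.donor):
                    span = cfg.layout[chrom]
                    allowed = [(float(s), float(e))
                               for c, s, e in spec.recombining_regions
                               if c == chrom]
                    anchor = _largest_gap_midpoint(span, allowed)
                    cx = (_draw_crossovers(rng, allowed, self.morgans_per_bp)
                          if allowed else np.empty(0))
                    h1, h2 = individual[chrom]
                    gams[chrom] = _splice(h1, h2, cx, anchor, phase0, span)
                deficient = (
                    gams[spec.recipient].origin_at(probe_r)[0] != carrier
                    and gams[spec.donor].origin_at(probe_d)[0] == carrier
                )
                if not deficient or rng.random() < spec.deficiency_survival:
                    break
            out.update(gams)
            handled.update((spec.recipient, spec.donor))

        inversions = {s.chromosome: s for s in cfg.inversions}
        for span in cfg.layout.spans:
            chrom = span.name
            if chrom in handled:
                continue
            h1, h2 = individual[chrom]
            allowed = [(float(span.start), float(span.end))]
            inv = inversions.get(chrom)
            if inv is not None:
                probe = 0.5 * (inv.start_bp + inv.end_bp)
                if h1.origin_at(probe)[0] != h2.origin_at(probe)[0]:
                    allowed = _subtract_region(
                        (float(span.start), float(span.end)),
                        [(float(inv.start_bp), float(inv.end_bp))],
                    )
            cx = (_draw_crossovers(rng, allowed, self.morgans_per_bp)
                  if allowed else np.empty(0))
            phase0 = int(rng.integers(2))
            out[chrom] = _splice(h1, h2, cx, float(span.start), phase0, span)
        return out

    def _survives(self, gamete: dict[str, Haplotype]) -> bool:
        for d in self.cfg.distortions:
            origin = gamete[d.chromosome].origin_at(float(d.position_bp))[0]
            if origin != _PARENT_IDX[d.favored] \
                    and self.rng.random() < d.selection:
                return False
        return True


# -- population simulation ---------------------------------------------------

def marker_positions(cfg: SimConfig) -> dict[str, np.ndarray]:
    """Evenly spaced marker positions per chromosome (bp, ends included)."""
    out = {}
    n = cfg.markers_per_chromosome
    for span in cfg.layout.spans:
        pos = span.start + np.round(
            np.arange(n) * (span.length - 1) / (n - 1)
        ).astype(np.int64)
        out[span.name] = pos
    return out


def simulate_ril(cfg: SimConfig) -> tuple[MarkerTable, pd.DataFrame]:
    """Simulate the population; returns the error-free truth matrix and a
    pedigree record (line id, generation, residual heterozygosity)."""
    rng = np.random.default_rng(cfg.seed)
    meiosis = _Meiosis(cfg, rng)
    positions = marker_positions(cfg)

    marker_rows = []
    for span in cfg.layout.spans:
        for p in positions[span.name]:
            marker_rows.append((f"{span.name}_{p}", span.name, int(p)))
    markers = pd.DataFrame(marker_rows,
                           columns=["marker", "chromosome", "position"])
    lines = [f"RIL{i + 1:04d}" for i in range(cfg.n_lines)]
    calls = np.empty((len(markers), cfg.n_lines), dtype=np.int8)

    het_frac = np.empty(cfg.n_lines)
    for li in range(cfg.n_lines):
        individual = {
            span.name: (Haplotype.founder(span, PARENT_A),
                        Haplotype.founder(span, PARENT_B))
            for span in cfg.layout.spans
        }
        for _ in range(cfg.generations - 1):
            g1 = meiosis.gamete(individual)
            g2 = meiosis.gamete(individual)
            individual = {c: (g1[c], g2[c]) for c in g1}
        col = []
        for span in cfg.layout.spans:
            h1, h2 = individual[span.name]
            o1 = h1.origin_at(positions[span.name])
            o2 = h2.origin_at(positions[span.name])
            geno = np.where(o1 == o2, np.where(o1 == PARENT_A, A, B), H)
            col.append(geno.astype(np.int8))
        column = np.concatenate(col)
        calls[:, li] = column
        het_frac[li] = float((column == H).mean())

    pedigree = pd.DataFrame({
        "line": lines,
        "generation": f"F{cfg.generations}",
        "het_fraction": het_frac,
    })
    return MarkerTable(markers, lines, calls), pedigree


def simulate_phenotypes(truth: MarkerTable, cfg: SimConfig,
                        seed: int | None = None) -> pd.DataFrame:
    """Additive-QTL phenotypes (long format: line, trait, environment, value).

    Each QTL contributes ``effect * score`` with scores +1/-1/0 for the
    A/B/H classes at the marker nearest the QTL position; environments add
    a shared normal shift and per-line residual noise on top.
    """
    rng = np.random.default_rng(cfg.seed + 1_000_003 if seed is None else seed)
    res_sd = cfg.resolved_residual_sd()
    traits = sorted({q.trait for q in cfg.qtls}) or ["trait"]
    score = {A: 1.0, B: -1.0, H: 0.0, MISSING: 0.0}

    genetic = {t: np.zeros(truth.n_lines) for t in traits}
    for q in cfg.qtls:
        idx = _nearest_marker(truth, q.chromosome, q.position_bp)
        s = np.vectorize(score.get)(truth.calls[idx])
        genetic[q.trait] = genetic[q.trait] + q.effect * s

    rows = []
    for t in traits:
        for env in range(1, cfg.n_environments + 1):
            env_shift = rng.normal(0.0, cfg.environment_sd) \
                if cfg.environment_sd > 0 else 0.0
            noise = rng.normal(0.0, res_sd, truth.n_lines)
            values = cfg.trait_mean + genetic[t] + env_shift + noise
            rows.extend(
                (line, t, f"env{env}", float(v))
                for line, v in zip(truth.lines, values)
            )
    return pd.DataFrame(rows, columns=["line", "trait", "environment", "value"])


def _nearest_marker(table: MarkerTable, chromosome: str, position_bp: int) -> int:
    chroms = table.markers["chromosome"].to_numpy()
    pos = table.markers["position"].to_numpy()
    rows = np.flatnonzero(chroms == chromosome)
    if rows.size == 0:
        raise ValueError(f"no markers on chromosome {chromosome!r}")
    return int(rows[np.argmin(np.abs(pos[rows] - position_bp))])


def degrade(truth: MarkerTable, cfg: SimConfig,
            seed: int | None = None) -> MarkerTable:
    """GBS-like degradation: per cell, missing with ``missing_rate``, else
    heterozygous with ``het_rate``, else miscalled (opposite parent) with
    ``miscall_rate``.  The truth table is left untouched."""
    rng = np.random.default_rng(cfg.seed + 2_000_003 if seed is None else seed)
    calls = truth.calls.copy()
    u = rng.random(calls.shape)
    to_missing = u < cfg.missing_rate
    to_het = ~to_missing & (u < cfg.missing_rate + cfg.het_rate)
    to_flip = (~to_missing & ~to_het
               & (u < cfg.missing_rate + cfg.het_rate + cfg.miscall_rate))
    calls[to_missing] = MISSING
    calls[to_het] = H
    flip_a = to_flip & (truth.calls == A)
    flip_b = to_flip & (truth.calls == B)
    calls[flip_a] = B
    calls[flip_b] = A
    return MarkerTable(truth.markers.copy(), list(truth.lines), calls)


@dataclass
class SimResult:
    truth: MarkerTable
    observed: MarkerTable
    phenotypes: pd.DataFrame
    pedigree: pd.DataFrame
    config: SimConfig


def simulate_population(cfg: SimConfig) -> SimResult:
    """Truth genotypes + degraded observations + phenotypes, one seed."""
    truth, pedigree = simulate_ril(cfg)
    observed = degrade(truth, cfg)
    phenotypes = simulate_phenotypes(truth, cfg)
    return SimResult(truth, observed, phenotypes, pedigree, cfg)
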