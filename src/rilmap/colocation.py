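"""Candidate-gene / QTL co-location statistics.

Given the QTL support intervals for a trait and the positions of the
candidate genes tested for that trait, the question is whether the number
of genes landing inside QTL intervals could be explained by chance.  Two
nulls are provided:

* a closed-form binomial: with ``M`` genes thrown independently into a
  genome of which a fraction ``p`` is covered by QTL intervals,
  ``P(K >= N) = sum_{k=N}^{M} C(M, k) p^k (1-p)^(M-k)``;
* a bootstrap that relaxes the binomial's assumptions: genes are placed on
  a genome of 1 Mbp units with probability proportional to a measured
  gene-density profile (uniform when none is supplied), no two genes may
  sit within ``min_sep`` Mbp of one another on the same chromosome, and
  co-locations are counted by the same integer-Mbp rule used on real data.

All interval arithmetic is on integer megabase units, inclusive of both
endpoints.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import GenomeLayout, Interval


# -- genome coverage ---------------------------------------------------------

def merge_intervals(intervals: list[Interval], layout: GenomeLayout,
                    widen: int = 0) -> list[Interval]:
    """Symmetrically widen, clip to chromosomes, and merge overlaps."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in intervals:
        span = layout[iv.chromosome]
        iv.validate(layout)
        lo = max(span.unit_start, iv.start - widen)
        hi = min(span.unit_end, iv.end + widen)
        by_chrom.setdefault(iv.chromosome, []).append((lo, hi))
    merged: list[Interval] = []
    for chrom in by_chrom:
        pieces = sorted(by_chrom[chrom])
        cur_lo, cur_hi = pieces[0]
        for lo, hi in pieces[1:]:
            if lo <= cur_hi + 1:
                cur_hi = max(cur_hi, hi)
            else:
                merged.append(Interval(chrom, cur_lo, cur_hi))
                cur_lo, cur_hi = lo, hi
        merged.append(Interval(chrom, cur_lo, cur_hi))
    return merged


def genome_coverage(intervals: list[Interval], layout: GenomeLayout,
                    widen: int = 0) -> float:
    """Fraction of the genome's Mbp units covered by the merged intervals."""
    merged = merge_intervals(intervals, layout, widen)
    covered = sum(iv.width for iv in merged)
    return covered / layout.total_units


# -- binomial tail -----------------------------------------------------------

def binomial_tail(m: int, p: float, n: int) -> float:
    """``P(K >= n)`` for K ~ Binomial(m, p), by direct summation."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p={p} outside [0, 1]")
    if not 0 <= n <= m:
        raise ValueError(f"need 0 <= N <= M, got N={n}, M={m}")
    if n == 0:
        return 1.0  # full support, exactly
    total = 0.0
    for k in range(n, m + 1):
        total += math.comb(m, k) * p ** k * (1.0 - p) ** (m - k)
    return min(total, 1.0)


# -- overlap counting --------------------------------------------------------

def count_overlaps(genes: list[tuple[str, str, int]],
                   intervals: list[Interval]) -> tuple[int, pd.DataFrame]:
    """Number of genes whose Mbp position falls inside any interval.

    ``genes`` holds (name, chromosome, position in integer Mbp, already
    rounded to the nearest Mbp).  Each gene counts at most once; interval
    endpoints are inclusive.
    """
    rows = []
    k = 0
    for name, chrom, unit in genes:
        inside = any(iv.contains_unit(chrom, int(unit)) for iv in intervals)
        k += inside
        rows.append({"gene": name, "chromosome": chrom, "mbp": int(unit),
                     "co_located": bool(inside)})
    return k, pd.DataFrame(rows, columns=["gene", "chromosome", "mbp",
                                          "co_located"])


# -- gene density ------------------------------------------------------------

@dataclass
class GeneDensityProfile:
    """Relative gene density per 1 Mbp unit, normalised to a probability."""

    layout: GenomeLayout
    weights: np.ndarray  # one weight per unit, genome order, sums to 1
    unit_chrom: np.ndarray = field(repr=False, default=None)  # chrom index per unit
    unit_pos: np.ndarray = field(repr=False, default=None)    # unit within chrom

    @classmethod
    def uniform(cls, layout: GenomeLayout) -> "GeneDensityProfile":
        n = layout.total_units
        return cls._build(layout, np.ones(n))

    @classmethod
    def from_weights(cls, layout: GenomeLayout, raw: np.ndarray
                     ) -> "GeneDensityProfile":
        raw = np.asarray(raw, dtype=float)
        if raw.shape != (layout.total_units,):
            raise ValueError(
                f"need one weight per Mbp unit ({layout.total_units}), "
                f"got {raw.shape}"
            )
        if np.any(raw < 0) or raw.sum() <= 0:
            raise ValueError("weights must be non-negative with positive sum")
        return cls._build(layout, raw)

    @classmethod
    def from_table(cls, layout: GenomeLayout, table: pd.DataFrame
                   ) -> "GeneDensityProfile":
        """Build from a per-Mbp gene-count table (chromosome, mbp, count),
        e.g. derived from any GFF3 gene annotation.  Unlisted units get
        weight zero."""
        raw = np.zeros(layout.total_units)
        index = cls._unit_index(layout)
        for chrom, unit, count in table[["chromosome", "mbp", "count"]]\
                .itertuples(index=False):
            raw[index[(chrom, int(unit))]] = float(count)
        return cls._build(layout, raw)

    @staticmethod
    def _unit_index(layout: GenomeLayout) -> dict[tuple[str, int], int]:
        index = {}
        k = 0
        for span in layout.spans:
            for u in range(span.unit_start, span.unit_end + 1):
                index[(span.name, u)] = k
                k += 1
        return index

    @classmethod
    def _build(cls, layout: GenomeLayout, raw: np.ndarray
               ) -> "GeneDensityProfile":
        unit_chrom = np.empty(layout.total_units, dtype=int)
        unit_pos = np.empty(layout.total_units, dtype=int)
        k = 0
        for ci, span in enumerate(layout.spans):
            n = span.n_units
            unit_chrom[k:k + n] = ci
            unit_pos[k:k + n] = np.arange(span.unit_start, span.unit_end + 1)
            k += n
        return cls(layout, raw / raw.sum(), unit_chrom, unit_pos)


# -- bootstrap null ----------------------------------------------------------

@dataclass
class BootstrapResult:
    tails: dict[int, float]      # N -> P(K >= N)
    se: dict[int, float]         # Monte-Carlo standard errors
    n_boot: int
    seed: int | None
    k_counts: np.ndarray         # histogram of K over replicates
    n_retry_exhausted: int = 0   # replicates that had to be redrawn


def bootstrap_colocation(intervals: list[Interval], m: int,
                         layout: GenomeLayout,
                         density: GeneDensityProfile | None = None,
                         n_boot: int = 100_000, min_sep: int = 100,
                         seed: int | None = None,
                         max_tries: int = 1_000,
                         batch: int = 200_000) -> BootstrapResult:
    """Bootstrap tail probabilities for candidate-gene co-location.

    Each replicate draws ``m`` gene positions sequentially from the density
    profile, rejecting a draw within ``min_sep`` Mbp of an already-accepted
    gene on the same chromosome (the separation constraint is undefined
    across chromosomes, so it applies within a chromosome only).  A
    replicate whose retry budget is exhausted is redrawn from scratch and
    counted in the diagnostics.
    """
    if density is None:
        density = GeneDensityProfile.uniform(layout)
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    if min_sep > 0:
        capacity = sum((s.n_units - 1) // min_sep + 1 for s in layout.spans)
        if m > capacity:
            raise ValueError(
                f"min_sep={min_sep} with M={m} genes exceeds the layout's "
                f"capacity of {capacity} separated positions"
            )
    rng = np.random.default_rng(seed)

    covered = np.zeros(layout.total_units, dtype=bool)
    index = GeneDensityProfile._unit_index(layout)
    for iv in intervals:
        iv.validate(layout)
        for u in range(iv.start, iv.end + 1):
            covered[index[(iv.chromosome, u)]] = True

    k_counts = np.zeros(m + 1, dtype=np.int64)
    n_exhausted = 0
    weights = density.weights
    n_units = weights.size

    done = 0
    while done < n_boot:
        nb = min(batch, n_boot - done)
        if min_sep <= 0:
            draws = rng.choice(n_units, size=(nb, m), p=weights) \
                if not np.allclose(weights, weights[0]) \
                else rng.integers(0, n_units, size=(nb, m))
            k = covered[draws].sum(axis=1)
        else:
            k, bad = _draw_separated(rng, weights, density, covered, nb, m,
                                     min_sep, max_tries)
            n_exhausted += bad
        k_counts += np.bincount(k, minlength=m + 1)
        done += nb

    surv = np.cumsum(k_counts[::-1])[::-1] / n_boot  # P(K >= N)
    tails = {n: float(surv[n]) for n in range(1, m + 1)}
    se = {n: float(np.sqrt(max(surv[n] * (1 - surv[n]), 0.0) / n_boot))
          for n in range(1, m + 1)}
    return BootstrapResult(tails, se, n_boot, seed, k_counts, n_exhausted)


def _draw_separated(rng, weights, density, covered, nb, m, min_sep,
                    max_tries) -> tuple[np.ndarray, int]:
    """Vectorised sequential placement with the same-chromosome separation
    constraint; returns K per replicate and the number of replicates whose
    per-gene retry budget ran out (those are redrawn whole)."""
    n_units = weights.size
    chrom = density.unit_chrom
    pos = density.unit_pos
    total_failed = 0
    k = np.empty(nb, dtype=np.int64)
    todo = np.arange(nb)
    while todo.size:
        nr = todo.size
        acc = np.empty((nr, m), dtype=np.int64)
        failed = np.zeros(nr, dtype=bool)
        for j in range(m):
            cand = rng.choice(n_units, size=nr, p=weights)
            if j > 0:
                pending = np.arange(nr)
                for _ in range(max_tries):
                    prev = acc[pending, :j]
                    same = chrom[prev] == chrom[cand[pending], None]
                    close = np.abs(pos[prev] - pos[cand[pending], None]) < min_sep
                    redo = pending[np.any(same & close, axis=1)]
                    if redo.size == 0:
                        pending = redo
                        break
                    cand[redo] = rng.choice(n_units, size=redo.size, p=weights)
                    pending = redo
                if pending.size:
                    failed[pending] = True
            acc[:, j] = cand
        ok = ~failed
        k[todo[ok]] = covered[acc[ok]].sum(axis=1)
        total_failed += int(failed.sum())
        todo = todo[failed]  # redraw exhausted replicates from scratch
    return k, total_failed


# -- full test ---------------------------------------------------------------

@dataclass
class ColocationTest:
    """Binomial and bootstrap co-location summary for one trait."""

    trait: str
    m: int                      # number of candidate genes
    p: float                    # genome coverage of the QTL intervals
    k_obs: int                  # observed co-locations
    binomial: dict[int, float]  # N -> P(K >= N), N = 1..M
    bootstrap: BootstrapResult | None = None
    genes: pd.DataFrame | None = None

    @property
    def p_observed(self) -> float:
        """Binomial tail probability at the observed overlap count."""
        return 1.0 if self.k_obs == 0 else self.binomial[self.k_obs]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for n in range(1, self.m + 1):
            row = {"trait": self.trait, "M": self.m, "p": self.p,
                   "K_obs": self.k_obs, "N": n,
                   "P_binomial": self.binomial[n]}
            if self.bootstrap is not None:
                row["P_bootstrap"] = self.bootstrap.tails[n]
                row["bootstrap_se"] = self.bootstrap.se[n]
            rows.append(row)
        return pd.DataFrame(rows)


def colocation_test(trait: str, genes: list[tuple[str, str, int]],
                    intervals: list[Interval], layout: GenomeLayout,
                    widen: int = 0, density: GeneDensityProfile | None = None,
                    n_boot: int = 0, min_sep: int = 100,
                    seed: int | None = None) -> ColocationTest:
    """Full co-location analysis for one trait.

    Coverage ``p`` is computed from the merged (optionally widened)
    intervals; the binomial tail is evaluated at every N; the bootstrap is
    run when ``n_boot > 0``.
    """
    m = len(genes)
    if m == 0:
        raise ValueError("no candidate genes supplied")
    p = genome_coverage(intervals, layout, widen)
    merged = merge_intervals(intervals, layout, widen)
    k_obs, gene_flags = count_overlaps(genes, merged)
    binomial = {n: binomial_tail(m, p, n) for n in range(1, m + 1)}
    boot = None
    if n_boot > 0:
        boot = bootstrap_colocation(merged, m, layout, density, n_boot,
                                    min_sep, seed)
    return ColocationTest(trait, m, p, k_obs, binomial, boot, gene_flags)


# -- I/O helpers -------------------------------------------------------------

def read_genes_tsv(path) -> list[tuple[str, str, int]]:
    """Read candidate genes as (name, chromosome, mbp) from a TSV."""
    df = pd.read_csv(path, sep="\t")
    need = {"gene", "chromosome", "mbp"}
    if not need.issubset(df.columns):
        raise ValueError(f"gene file needs columns {sorted(need)}")
    return [(str(g), str(c), int(u))
            for g, c, u in df[["gene", "chromosome", "mbp"]]
            .itertuples(index=False)]


def read_intervals_tsv(path) -> list[Interval]:
    """Read intervals as (chromosome, start_mbp, end_mbp) from a TSV."""
    df = pd.read_csv(path, sep="\t")
    need = {"chromosome", "start_mbp", "end_mbp"}
    if not need.issubset(df.columns):
        raise ValueError(f"interval file needs columns {sorted(need)}")
    return [Interval(str(c), int(s), int(e))
            for c, s, e in df[["chromosome", "start_mbp", "end_mbp"]]
            .itertuples(index=False)]
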