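"""Physically-scaled recombination matrices and rearrangement signatures.

The observed recombination rate ``r`` between two markers is the fraction
of lines with discordant homozygous parental calls among lines homozygous
and non-missing at both markers.  Under independent assortment in a RIL it
approaches 0.5; complete coupling gives 0.  Averaging ``r`` over all marker
pairs between two fixed-width physical windows yields a matrix scaled by
physical distance rather than marker density, in which chromosome
rearrangements leave characteristic signatures: blocks of near-zero ``r``
*between* chromosomes (pseudo-linkage from a translocation heterozygote)
and large off-pericentromeric near-zero blocks *within* a chromosome
(suppression, e.g. from a pericentric inversion).

``r`` is reported as the raw discordance fraction, not corrected back to a
meiotic recombination frequency; ``r_to_meiotic`` exposes the inverse
Haldane-Waller RIL map correction ``R = 2r/(1+2r)`` for users who want it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .genome import GenomeLayout, Interval
from .markers import A, B, MarkerTable

logger = logging.getLogger(__name__)


# -- pairwise recombination --------------------------------------------------

def pairwise_r(calls_i: np.ndarray, calls_j: np.ndarray,
               min_informative: int = 10) -> float:
    """Observed recombination fraction between two phased call vectors.

    Counts lines homozygous and non-missing at both markers; heterozygous
    and missing calls are excluded.  Returns ``nan`` when fewer than
    ``min_informative`` lines inform the estimate.
    """
    hi = np.isin(calls_i, (A, B))
    hj = np.isin(calls_j, (A, B))
    both = hi & hj
    n = int(both.sum())
    if n < min_informative:
        return float("nan")
    disc = int((calls_i[both] != calls_j[both]).sum())
    return disc / n


def pairwise_r_matrix(calls: np.ndarray, min_informative: int = 10,
                      cap: float = 0.5) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs observed recombination fractions.

    Returns ``(r, n_informative)`` for the markers x markers matrix; cells
    with fewer than ``min_informative`` doubly-homozygous lines are nan.
    Values above ``cap`` (sampling noise / residual phase error) are capped;
    the number of capped cells is logged.
    """
    g = np.zeros(calls.shape, dtype=np.float64)
    g[calls == A] = 1.0
    g[calls == B] = -1.0
    absg = np.abs(g)
    n_both = absg @ absg.T
    s = g @ g.T  # concordant minus discordant counts
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (n_both - s) / (2.0 * n_both)
    r[n_both < min_informative] = np.nan
    n_capped = int(np.sum(r > cap))
    if n_capped:
        logger.info("capped %d marker-pair r values above %.2f", n_capped, cap)
    np.clip(r, 0.0, cap, out=r)
    return r, n_both


def r_to_meiotic(r) -> np.ndarray:
    """Invert the Haldane-Waller selfed-RIL relation ``R = 2r/(1+2r)``.

    Maps an observed RIL discordance fraction ``R`` back to the per-meiosis
    recombination frequency ``r``; optional, off by default everywhere.
    """
    r = np.asarray(r, dtype=float)
    return r / (2.0 * (1.0 - r))


# -- window-pair matrix ------------------------------------------------------

@dataclass
class RecombinationMatrix:
    """Symmetric window-pair average recombination matrix.

    ``coordinates`` has one row per window (chromosome, center in Mbp);
    window centers sit at integer multiples of ``step`` so that coarser
    steps subsample finer ones at shared coordinates.
    """

    coordinates: pd.DataFrame  # columns: chromosome, center
    values: np.ndarray         # (n_windows, n_windows), nan = missing
    n_pairs: np.ndarray        # marker pairs contributing to each cell
    window: float              # full window width, Mbp
    step: float                # center spacing, Mbp

    @property
    def n_windows(self) -> int:
        return len(self.coordinates)

    def chromosome_windows(self) -> dict[str, np.ndarray]:
        chroms = self.coordinates["chromosome"].to_numpy()
        return {c: np.flatnonzero(chroms == c) for c in dict.fromkeys(chroms)}

    def to_long(self) -> pd.DataFrame:
        """Long-format export (upper triangle including the diagonal)."""
        rows = []
        coords = self.coordinates
        for i in range(self.n_windows):
            for j in range(i, self.n_windows):
                rows.append((
                    coords["chromosome"].iat[i], coords["center"].iat[i],
                    coords["chromosome"].iat[j], coords["center"].iat[j],
                    self.values[i, j], int(self.n_pairs[i, j]),
                ))
        return pd.DataFrame(rows, columns=[
            "chrom_i", "center_i_mbp", "chrom_j", "center_j_mbp", "r", "n_pairs",
        ])

    def to_tsv(self, path) -> None:
        self.to_long().to_csv(path, sep="\t", index=False)


def _window_members(positions_mbp: np.ndarray, centers: np.ndarray,
                    half_width: float) -> list[np.ndarray]:
    """Marker indices per window; empty windows borrow the markers
    immediately adjacent to the window on each side (one per side)."""
    members = []
    order = np.argsort(positions_mbp, kind="stable")
    pos_sorted = positions_mbp[order]
    for c in centers:
        inside = np.flatnonzero(np.abs(positions_mbp - c) <= half_width)
        if inside.size:
            members.append(inside)
            continue
        reps = []
        lo = np.searchsorted(pos_sorted, c - half_width)
        if lo > 0:
            reps.append(order[lo - 1])
        hi = np.searchsorted(pos_sorted, c + half_width, side="right")
        if hi < len(pos_sorted):
            reps.append(order[hi])
        members.append(np.array(reps, dtype=int))
    return members


def recombination_matrix(table: MarkerTable, layout: GenomeLayout,
                         window: float = 16.0, step: float = 10.0,
                         min_informative: int = 10) -> RecombinationMatrix:
    """Window-pair average recombination matrix over the whole layout.

    For each ordered pair of windows the cell value is the mean of
    ``pairwise_r`` over all distinct marker pairs drawn one from each
    window (self-pairs are excluded, which keeps the diagonal meaningful
    for windows with at least two markers).
    """
    half = window / 2.0
    chrom_rows = table.chromosome_blocks()
    for name in chrom_rows:
        if name not in layout:
            raise KeyError(f"marker chromosome {name!r} not in layout")

    coords = []
    member_lists: list[np.ndarray] = []
    for span in layout.spans:
        rows = chrom_rows.get(span.name)
        if rows is None or rows.size < 2:
            logger.warning("chromosome %s has < 2 markers; no windows emitted",
                           span.name)
            continue
        pos_mbp = table.markers["position"].to_numpy()[rows] / 1e6
        s0 = (span.start - 1) / 1e6
        end_mbp = span.end / 1e6
        n_centers = int((end_mbp - s0) // step)
        centers = s0 + step * np.arange(1, n_centers + 1)
        for c, mem in zip(centers,
                          _window_members(pos_mbp, centers, half)):
            coords.append((span.name, c))
            member_lists.append(rows[mem])

    if not coords:
        raise ValueError("no chromosome has enough markers for a matrix")

    r, _ = pairwise_r_matrix(table.calls, min_informative)
    valid = ~np.isnan(r)
    r_filled = np.where(valid, r, 0.0)

    n_win = len(coords)
    w = np.zeros((n_win, len(table.markers)))
    for i, mem in enumerate(member_lists):
        w[i, mem] = 1.0
    sums = w @ r_filled @ w.T
    counts = w @ valid.astype(float) @ w.T
    # remove self-pairs contributed by markers shared between two windows
    self_valid = np.diag(valid).astype(float)
    overlap = (w * self_valid) @ w.T
    counts = counts - overlap
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(counts > 0, sums / np.maximum(counts, 1e-300), np.nan)
    values = 0.5 * (values + values.T)  # enforce exact symmetry

    coordinates = pd.DataFrame(coords, columns=["chromosome", "center"])
    return RecombinationMatrix(coordinates, values, counts, window, step)


# -- anomaly detection -------------------------------------------------------

@dataclass(frozen=True)
class AnomalyCall:
    """A maximal contiguous block of low-recombination window pairs."""

    kind: str  # 'inter_chromosome_pseudolinkage' | 'intra_chromosome_suppression'
    region_i: Interval
    region_j: Interval
    mean_r: float
    n_window_pairs: int
    threshold: float


def _block_calls(sub: np.ndarray, win_i: np.ndarray, win_j: np.ndarray,
                 coords: pd.DataFrame, candidate: np.ndarray,
                 kind: str, min_block: int, threshold: float
                 ) -> list[AnomalyCall]:
    labels, n_lab = ndimage.label(candidate)
    calls = []
    for lab in range(1, n_lab + 1):
        cells = labels == lab
        if cells.sum() < min_block:
            continue
        ii, jj = np.nonzero(cells)
        ci = coords["center"].to_numpy()[win_i[ii]]
        cj = coords["center"].to_numpy()[win_j[jj]]
        chrom_i = coords["chromosome"].iat[win_i[0]]
        chrom_j = coords["chromosome"].iat[win_j[0]]
        region_i = Interval(chrom_i, int(round(ci.min())), int(round(ci.max())))
        region_j = Interval(chrom_j, int(round(cj.min())), int(round(cj.max())))
        calls.append(AnomalyCall(
            kind=kind, region_i=region_i, region_j=region_j,
            mean_r=float(np.nanmean(sub[cells])),
            n_window_pairs=int(cells.sum()), threshold=threshold,
        ))
    return calls


def detect_anomalies(matrix: RecombinationMatrix,
                     linkage_threshold: float = 0.2,
                     min_block: int = 2,
                     min_separation: float = 50.0,
                     pericentromere_fraction: float = 0.5
                     ) -> list[AnomalyCall]:
    """Report pseudo-linkage and suppression blocks in a recombination matrix.

    Inter-chromosome: any contiguous block of window pairs with
    ``r <= linkage_threshold`` of at least ``min_block`` cells.
    Intra-chromosome: the same, but window centers must be at least
    ``min_separation`` Mbp apart (close windows are genuinely linked) and
    cells with *both* windows inside the central ``pericentromere_fraction``
    of the chromosome are masked out, since recombination suppression
    towards the centromere is the expected baseline, not an anomaly.
    Region bounds are window-center positions, so their resolution is one
    window by construction.
    """
    by_chrom = matrix.chromosome_windows()
    chroms = list(by_chrom)
    coords = matrix.coordinates
    centers = coords["center"].to_numpy()
    calls: list[AnomalyCall] = []

    for a_idx, ca in enumerate(chroms):
        wa = by_chrom[ca]
        for cb in chroms[a_idx:]:
            wb = by_chrom[cb]
            sub = matrix.values[np.ix_(wa, wb)]
            low = sub <= linkage_threshold  # nan-safe: nan compares False
            if ca == cb:
                da = centers[wa]
                sep = np.abs(da[:, None] - da[None, :]) >= min_separation
                lo_c = da.min() + (da.max() - da.min()) * (0.5 - pericentromere_fraction / 2)
                hi_c = da.min() + (da.max() - da.min()) * (0.5 + pericentromere_fraction / 2)
                central = (da >= lo_c) & (da <= hi_c)
                expected = central[:, None] & central[None, :]
                candidate = low & sep & ~expected
                candidate = np.triu(candidate)  # report each pair once
                calls += _block_calls(sub, wa, wb, coords, candidate,
                                      "intra_chromosome_suppression",
                                      min_block, linkage_threshold)
            else:
                calls += _block_calls(sub, wa, wb, coords, low,
                                      "inter_chromosome_pseudolinkage",
                                      min_block, linkage_threshold)
    return calls


def anomalies_to_gff(calls: list[AnomalyCall], path) -> None:
    """Write anomaly region pairs as paired GFF3 features."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for k, call in enumerate(calls):
            pair_id = f"anomaly{k + 1}"
            for part, region in (("i", call.region_i), ("j", call.region_j)):
                fh.write("\t".join([
                    region.chromosome, "rilmap", call.kind,
                    str((region.start - 1) * 1_000_000 + 1),
                    str(region.end * 1_000_000),
                    f"{call.mean_r:.4f}", ".", ".",
                    f"ID={pair_id}.{part};Parent={pair_id};"
                    f"mean_r={call.mean_r:.4f};n_window_pairs={call.n_window_pairs}",
                ]) + "\n")


# -- heat map ----------------------------------------------------------------

# piecewise-linear blend anchored at r = 0 (yellow), 0.2 (teal), 0.5 (burgundy)
HEAT_ANCHORS = [
    (0.0, (1.0, 1.0, 0.0)),    # yellow
    (0.2, (0.0, 0.5, 0.5)),    # teal
    (0.5, (0.5, 0.0, 0.125)),  # burgundy
]


def heatmap_color(r: float) -> tuple[float, float, float]:
    """RGB for a recombination value under the anchored blend."""
    if np.isnan(r):
        return (0.7, 0.7, 0.7)
    r = min(max(r, 0.0), 0.5)
    for (r0, c0), (r1, c1) in zip(HEAT_ANCHORS, HEAT_ANCHORS[1:]):
        if r <= r1:
            t = (r - r0) / (r1 - r0)
            return tuple((1 - t) * a + t * b for a, b in zip(c0, c1))
    return HEAT_ANCHORS[-1][1]


def render_heatmap(matrix: RecombinationMatrix, out) -> None:
    """Triangular heat map of the matrix with Mbp-labelled axes."""
    import matplotlib
    matplotlib.use("Agg")
    from matplotlib import pyplot as plt
    from matplotlib.colors import LinearSegmentedColormap

    cmap = LinearSegmentedColormap.from_list(
        "recomb", [(r / 0.5, c) for r, c in HEAT_ANCHORS]
    )
    cmap.set_bad((0.7, 0.7, 0.7))
    vals = np.ma.masked_invalid(matrix.values.copy())
    tri = np.triu(np.ones_like(matrix.values, dtype=bool), k=1)
    vals = np.ma.masked_where(tri, vals)

    fig, ax = plt.subplots(figsize=(8, 8))
    im = ax.imshow(vals, cmap=cmap, vmin=0.0, vmax=0.5, interpolation="nearest")
    labels = [f"{c}:{int(m)}" for c, m in
              matrix.coordinates.itertuples(index=False)]
    stride = max(1, len(labels) // 25)
    ticks = np.arange(0, len(labels), stride)
    ax.set_xticks(ticks)
    ax.set_xticklabels([labels[i] for i in ticks], rotation=90, fontsize=6)
    ax.set_yticks(ticks)
    ax.set_yticklabels([labels[i] for i in ticks], fontsize=6)
    ax.set_xlabel("window center (Mbp)")
    ax.set_ylabel("window center (Mbp)")
    fig.colorbar(im, ax=ax, label="average recombination rate r", shrink=0.7)
    fig.tight_layout()
    fig.savefig(out, dpi=150)
    plt.close(fig)


# -- segregation distortion --------------------------------------------------

def distortion_profile(table: MarkerTable) -> pd.DataFrame:
    """Per-marker parent-A allele frequency and exact binomial deviation.

    The tail probability is the exact two-sided binomial test of the
    homozygous A:B counts against the 1:1 segregation expected in a
    biparental RIL.
    """
    counts = table.call_counts()
    na = counts["n_a"].to_numpy()
    nb = counts["n_b"].to_numpy()
    n = na + nb
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(n > 0, na / np.maximum(n, 1), np.nan)
    pvals = np.ones(len(n))
    for i in range(len(n)):
        if n[i] > 0:
            pvals[i] = stats.binomtest(int(na[i]), int(n[i]), 0.5).pvalue
        else:
            pvals[i] = np.nan
    out = table.markers[["marker", "chromosome", "position"]].copy()
    out["n_homozygous"] = n
    out["freq_a"] = freq
    out["p_binomial"] = pvals
    return out
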