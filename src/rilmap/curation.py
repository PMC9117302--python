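"""Heuristic curation of sparse biparental genotype matrices.

Genotyping-by-sequencing matrices are sparse and error-prone; before any
linkage or QTL work the marker matrix is (1) filtered on missingness, minor
allele frequency and heterozygosity, (2) phased to the two mapping parents,
(3) cleaned of reverse-phase and outlier markers using double-crossover
counts, and (4) imputed with conservative rules that emulate manual
curation.  A *double crossover* here is a homozygous call that differs from
both of its nearest non-missing homozygous neighbours while those
neighbours agree with each other - in a selfed RIL these are nearly always
technical artefacts rather than real tight double recombination events,
which makes their count a useful quality score for both markers and lines.

Every rule is parameterised; the defaults reproduce the published
filtering thresholds (max 50% missing, min 30% MAF, max 10% het).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .markers import MISSING, A, B, H, MarkerTable


@dataclass
class CurationReport:
    """Audit trail for one curation step (counts reconcile to the input)."""

    n_input: int = 0
    n_retained: int = 0
    n_removed_missing: int = 0
    n_removed_maf: int = 0
    n_removed_het: int = 0
    n_removed_uninformative: int = 0
    n_phase_flipped: int = 0
    n_outliers_removed: int = 0
    n_cells_imputed: int = 0
    n_singletons_repaired: int = 0
    converged: bool = True
    n_passes: int = 0
    dxo_per_line_before: pd.Series | None = None
    dxo_per_line_after: pd.Series | None = None

    def as_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items()
             if not isinstance(v, pd.Series)}
        return d


# -- filtering ---------------------------------------------------------------

def filter_markers(table: MarkerTable, max_missing: float = 0.50,
                   min_maf: float = 0.30, max_het: float = 0.10
                   ) -> tuple[MarkerTable, CurationReport]:
    """Filter markers on missingness, MAF and heterozygosity.

    Markers are *retained* at equality with each threshold.  MAF counts a
    heterozygous call as half an allele to each parent and is computed over
    non-missing calls, as is the het fraction.  Removals are attributed to
    the first failing rule in the order missing -> MAF -> het.
    """
    if table.n_markers == 0:
        raise ValueError("empty marker table")
    for name, v in (("max_missing", max_missing), ("min_maf", min_maf),
                    ("max_het", max_het)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name}={v} outside [0, 1]")

    counts = table.call_counts()
    n_lines = table.n_lines
    n_called = (counts["n_a"] + counts["n_b"] + counts["n_h"]).to_numpy(float)
    missing_frac = counts["n_missing"].to_numpy(float) / n_lines
    with np.errstate(invalid="ignore", divide="ignore"):
        freq_a = (counts["n_a"] + 0.5 * counts["n_h"]).to_numpy(float) / n_called
        het_frac = counts["n_h"].to_numpy(float) / n_called
    freq_a = np.where(n_called > 0, freq_a, 0.0)
    het_frac = np.where(n_called > 0, het_frac, 0.0)
    maf = np.minimum(freq_a, 1.0 - freq_a)
    maf = np.where(n_called > 0, maf, 0.0)

    fail_missing = missing_frac > max_missing
    fail_maf = ~fail_missing & (maf < min_maf)
    fail_het = ~fail_missing & ~fail_maf & (het_frac > max_het)
    keep = ~(fail_missing | fail_maf | fail_het)

    report = CurationReport(
        n_input=table.n_markers,
        n_retained=int(keep.sum()),
        n_removed_missing=int(fail_missing.sum()),
        n_removed_maf=int(fail_maf.sum()),
        n_removed_het=int(fail_het.sum()),
    )
    return table.select_markers(keep), report


# -- parent phasing ----------------------------------------------------------

def phase_to_parents(table: MarkerTable, parent_a: str, parent_b: str
                     ) -> tuple[MarkerTable, CurationReport]:
    """Recode progeny calls to parental origin and drop the parent columns.

    Markers where either parent is missing or heterozygous, or where the
    parents carry the same allele, are uninformative and dropped.  Where the
    parents are swapped relative to the stored coding, progeny calls are
    complemented so that ``A`` always means "allele of ``parent_a``".
    """
    ia, ib = table.line_index(parent_a), table.line_index(parent_b)
    pa, pb = table.calls[:, ia], table.calls[:, ib]
    informative = (
        np.isin(pa, (A, B)) & np.isin(pb, (A, B)) & (pa != pb)
    )
    swapped = informative & (pa == B)

    progeny_idx = [j for j in range(table.n_lines) if j not in (ia, ib)]
    calls = table.calls[:, progeny_idx].copy()
    flip = np.flatnonzero(swapped)
    sub = calls[flip]
    a_mask, b_mask = sub == A, sub == B
    sub[a_mask], sub[b_mask] = B, A
    calls[flip] = sub

    out = MarkerTable(
        table.markers[informative], [table.lines[j] for j in progeny_idx],
        calls[informative],
    )
    report = CurationReport(
        n_input=table.n_markers,
        n_retained=out.n_markers,
        n_removed_uninformative=int((~informative).sum()),
        n_phase_flipped=int(swapped.sum()),
    )
    return out, report


# -- double crossovers -------------------------------------------------------

def _flank_indices(codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row index of the nearest homozygous call before/after each row.

    ``codes`` is one chromosome block (markers x lines); -1 marks "none".
    """
    m = codes.shape[0]
    homo = (codes == A) | (codes == B)
    rows = np.arange(m)[:, None]
    idx = np.where(homo, rows, -1)
    prev_inclusive = np.maximum.accumulate(idx, axis=0)
    prev = np.vstack([np.full((1, codes.shape[1]), -1), prev_inclusive[:-1]])
    idx_rev = np.where(homo, rows, m)
    nxt_inclusive = np.minimum.accumulate(idx_rev[::-1], axis=0)[::-1]
    nxt = np.vstack([nxt_inclusive[1:], np.full((1, codes.shape[1]), m)])
    nxt = np.where(nxt == m, -1, nxt)
    return prev, nxt


def _dxo_masks(codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(double-crossover cells, scoreable cells) for one chromosome block.

    A cell is *scoreable* when it is homozygous and both flanking homozygous
    calls exist and agree; it is a double crossover when it additionally
    disagrees with those flanks.
    """
    homo = (codes == A) | (codes == B)
    prev, nxt = _flank_indices(codes)
    cols = np.arange(codes.shape[1])[None, :]
    prev_val = codes[np.clip(prev, 0, None), cols]
    next_val = codes[np.clip(nxt, 0, None), cols]
    scoreable = homo & (prev >= 0) & (nxt >= 0) & (prev_val == next_val)
    dxo = scoreable & (codes != prev_val)
    return dxo, scoreable


def count_double_crossovers(table: MarkerTable
                            ) -> tuple[pd.Series, pd.Series]:
    """Double-crossover counts per marker and per line.

    Chromosomes are scanned independently; heterozygous and missing calls
    are skipped when looking for flanks.
    """
    per_marker = np.zeros(table.n_markers, dtype=int)
    per_line = np.zeros(table.n_lines, dtype=int)
    for _, rows in table.chromosome_blocks().items():
        dxo, _ = _dxo_masks(table.calls[rows])
        per_marker[rows] = dxo.sum(axis=1)
        per_line += dxo.sum(axis=0)
    return (
        pd.Series(per_marker, index=table.markers["marker"], name="n_dxo"),
        pd.Series(per_line, index=table.lines, name="n_dxo"),
    )


# -- phase / outlier correction ----------------------------------------------

def correct_phase_and_outliers(table: MarkerTable,
                               flip_gain_threshold: float = 0.4,
                               outlier_rate_ceiling: float = 0.10,
                               min_scored: int = 8,
                               max_passes: int = 10
                               ) -> tuple[MarkerTable, CurationReport]:
    """Flip reverse-phase markers and remove double-crossover outliers.

    For each marker the double-crossover count is compared with the count
    obtained by complementing that marker's calls.  If flipping reduces the
    count by at least ``flip_gain_threshold`` (as a fraction of scoreable
    cells) the marker is phase-flipped.  After flipping, markers whose
    double-crossover rate still exceeds ``outlier_rate_ceiling`` are removed
    as outliers (a marker random with respect to its neighbours scores
    ~25% in either phase).  Iterates to a fixed point, capped at
    ``max_passes``; non-convergence is reported, not fatal.
    """
    work = table.copy()
    _, dxo_line_before = count_double_crossovers(work)
    n_flipped = 0
    n_removed = 0
    converged = False
    passes = 0

    for passes in range(1, max_passes + 1):
        changed = False
        # phase flips
        cnt = np.zeros(work.n_markers)
        scored = np.zeros(work.n_markers)
        for _, rows in work.chromosome_blocks().items():
            dxo, scoreable = _dxo_masks(work.calls[rows])
            cnt[rows] = dxo.sum(axis=1)
            scored[rows] = scoreable.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            # flipped count = scored - cnt, so the gain is 2*cnt/scored - 1
            gain = np.where(scored > 0, 2.0 * cnt / scored - 1.0, 0.0)
        flip = (scored >= min_scored) & (gain >= flip_gain_threshold)
        if flip.any():
            sub = work.calls[flip]
            a_mask, b_mask = sub == A, sub == B
            sub[a_mask], sub[b_mask] = B, A
            work.calls[flip] = sub
            n_flipped += int(flip.sum())
            changed = True
            # recompute rates in the corrected phase before outlier removal
            for _, rows in work.chromosome_blocks().items():
                dxo, scoreable = _dxo_masks(work.calls[rows])
                cnt[rows] = dxo.sum(axis=1)
                scored[rows] = scoreable.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            rate = np.where(scored > 0, cnt / scored, 0.0)
        outlier = (scored >= min_scored) & (rate > outlier_rate_ceiling)
        if outlier.any():
            work = work.select_markers(~outlier)
            n_removed += int(outlier.sum())
            changed = True
        if not changed:
            converged = True
            break

    _, dxo_line_after = count_double_crossovers(work)
    report = CurationReport(
        n_input=table.n_markers,
        n_retained=work.n_markers,
        n_phase_flipped=n_flipped,
        n_outliers_removed=n_removed,
        converged=converged,
        n_passes=passes,
        dxo_per_line_before=dxo_line_before,
        dxo_per_line_after=dxo_line_after,
    )
    return work, report


# -- imputation --------------------------------------------------------------

def _repair_singletons_inplace(codes: np.ndarray) -> int:
    """Set isolated homozygous calls that contradict agreeing flanks to the
    flank value.  Left-to-right in-place passes are iterated to a true fixed
    point, which makes the overall imputation idempotent.  Returns the
    number of repaired cells.
    """
    m, n = codes.shape
    repaired = 0
    for j in range(n):
        col = codes[:, j]
        homo_idx = np.flatnonzero((col == A) | (col == B))
        if homo_idx.size < 3:
            continue
        changed = True
        while changed:
            changed = False
            vals = col[homo_idx]
            for k in range(1, len(homo_idx) - 1):
                if vals[k - 1] == vals[k + 1] != vals[k]:
                    vals[k] = vals[k - 1]
                    col[homo_idx[k]] = vals[k - 1]
                    repaired += 1
                    changed = True
    return repaired


def _fill_missing_runs_inplace(codes: np.ndarray, uncertainty_zone: int,
                               fill_terminal: bool) -> int:
    """Fill missing runs from their homozygous flanks.

    Runs flanked by the same homozygous call become that call.  Runs with
    differing homozygous flanks are filled toward each flank up to the
    midpoint, leaving ``uncertainty_zone`` central cells missing.  Runs
    bounded by a heterozygous call or a chromosome end are left missing
    unless ``fill_terminal`` is set (terminal runs then copy the single
    available homozygous flank).  Returns the number of filled cells.
    """
    m, n = codes.shape
    filled = 0
    for j in range(n):
        col = codes[:, j]
        miss = np.flatnonzero(col == MISSING)
        if miss.size == 0:
            continue
        # group consecutive indices into runs
        splits = np.flatnonzero(np.diff(miss) > 1) + 1
        for run in np.split(miss, splits):
            lo, hi = run[0], run[-1]
            left = col[lo - 1] if lo > 0 else None
            right = col[hi + 1] if hi < m - 1 else None
            left_ok = left in (A, B)
            right_ok = right in (A, B)
            if left_ok and right_ok:
                if left == right:
                    col[run] = left
                    filled += run.size
                else:
                    n_fill = max(0, run.size - uncertainty_zone)
                    n_left = (n_fill + 1) // 2
                    n_right = n_fill // 2
                    if n_left:
                        col[run[:n_left]] = left
                    if n_right:
                        col[run[-n_right:]] = right
                    filled += n_fill
            elif fill_terminal and (left_ok or right_ok):
                col[run] = left if left_ok else right
                filled += run.size
    return filled


def impute_gbsi(table: MarkerTable, uncertainty_zone: int = 1,
                repair_singletons: bool = True,
                fill_terminal: bool = False
                ) -> tuple[MarkerTable, CurationReport]:
    """Heuristic imputation emulating manual curation.

    Per line and chromosome: residual double-crossover singletons are set to
    the flanking call, missing runs flanked by the same homozygous call are
    filled with it, and runs with differing flanks are filled toward the
    flanks leaving ``uncertainty_zone`` central cells missing.  Heterozygous
    calls are never changed, no information crosses a chromosome boundary,
    and leading/trailing runs stay missing by default (no second flank).
    The operation is idempotent.
    """
    if uncertainty_zone < 0:
        raise ValueError("uncertainty_zone must be >= 0")
    work = table.copy()
    n_repaired = 0
    n_filled = 0
    for _, rows in work.chromosome_blocks().items():
        block = work.calls[rows]
        if repair_singletons:
            n_repaired += _repair_singletons_inplace(block)
        n_filled += _fill_missing_runs_inplace(block, uncertainty_zone,
                                               fill_terminal)
        work.calls[rows] = block
    report = CurationReport(
        n_input=table.n_markers,
        n_retained=work.n_markers,
        n_cells_imputed=n_filled,
        n_singletons_repaired=n_repaired,
    )
    return work, report


# -- full chain --------------------------------------------------------------

def curate(table: MarkerTable, parent_a: str | None = None,
           parent_b: str | None = None, max_missing: float = 0.50,
           min_maf: float = 0.30, max_het: float = 0.10,
           flip_gain_threshold: float = 0.4,
           outlier_rate_ceiling: float = 0.10,
           uncertainty_zone: int = 1,
           chrom_order=None) -> tuple[MarkerTable, dict[str, CurationReport]]:
    """Filter -> phase -> sort -> correct -> impute, collecting reports."""
    reports: dict[str, CurationReport] = {}
    work = table
    if parent_a is not None and parent_b is not None:
        work, reports["phase"] = phase_to_parents(work, parent_a, parent_b)
    work, reports["filter"] = filter_markers(work, max_missing, min_maf, max_het)
    work = work.sorted_by_position(chrom_order)
    work, reports["correct"] = correct_phase_and_outliers(
        work, flip_gain_threshold, outlier_rate_ceiling
    )
    work, reports["impute"] = impute_gbsi(work, uncertainty_zone)
    return work, reports
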