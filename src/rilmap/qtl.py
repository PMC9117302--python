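"""Single-marker QTL mapping with permutation thresholds.

The scan statistic is a variance ratio: at each marker the lines that are
homozygous (and phenotyped) are split into the two parental classes and

    TS = n * ln(RSS_reduced / RSS_full)

where the full model fits a mean per marker class (plus a covariate-marker
class effect when one is declared) and the reduced model drops the marker
term.  TS is an approximation to the likelihood-ratio statistic and
converts to the familiar LOD scale exactly as ``LOD = TS / (2 ln 10)``, so
LOD 5 corresponds to TS ~ 23.03.  Genome-wide significance thresholds are
the empirical tail quantiles of the maximum TS over permutations that
shuffle phenotypes across lines while keeping genotypes fixed (max-T
resampling: one shared permutation per genome scan).

Peaks are called iteratively per chromosome; the support interval of a
peak is the contiguous marker run where TS stays at or above 80% of the
peak value (a "20% fall-off"), and further peaks on the same chromosome
are only sought outside the declared interval widened by 75 Mbp.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import Interval, mbp_unit
from .markers import A, B, MarkerTable

TWO_LN_TEN = 2.0 * math.log(10.0)


# -- phenotype preparation ---------------------------------------------------

def prepare_trait_values(pheno: pd.DataFrame, trait: str,
                         environments="means", min_environments: int = 1
                         ) -> pd.Series:
    """Per-line trait values, replicate-averaged and optionally env-averaged.

    ``environments`` may be ``"means"`` (average across all environments),
    a list of environment labels (average across that subset, so e.g. a
    single year can be analysed separately), or a single label.
    """
    sub = pheno[pheno["trait"] == trait].dropna(subset=["value"])
    if environments != "means":
        if isinstance(environments, str):
            environments = [environments]
        sub = sub[sub["environment"].isin(environments)]
    if sub.empty:
        raise ValueError(f"no phenotype records for trait {trait!r}")
    per_env = sub.groupby(["line", "environment"])["value"].mean()
    counts = per_env.groupby("line").size()
    means = per_env.groupby("line").mean()
    means = means[counts >= min_environments]
    if means.empty:
        raise ValueError(
            f"no line has data in >= {min_environments} environments"
        )
    means.name = trait
    return means


# -- the test statistic ------------------------------------------------------

def ts_to_lod(ts):
    """Convert the variance-ratio statistic to the LOD scale."""
    ts = np.asarray(ts, dtype=float)
    if np.any(ts[np.isfinite(ts)] < 0):
        raise ValueError("TS must be non-negative")
    return ts / TWO_LN_TEN


def single_marker_ts(genotypes: np.ndarray, values: np.ndarray,
                     covariate: np.ndarray | None = None,
                     min_lines: int = 20) -> dict:
    """Variance-ratio test of one marker against a phenotype vector.

    Uses lines homozygous at the marker (and at the covariate marker, when
    given) with a finite phenotype.  Returns a dict with ``ts``, ``lod``,
    ``n``, class means and the homozygous-substitution effect
    (mean(A) - mean(B)); ``ts`` is nan when a class is empty or too few
    lines inform the test.
    """
    genotypes = np.asarray(genotypes)
    values = np.asarray(values, dtype=float)
    use = np.isin(genotypes, (A, B)) & np.isfinite(values)
    if covariate is not None:
        use &= np.isin(covariate, (A, B))
    g = genotypes[use]
    y = values[use]
    n = int(use.sum())
    out = {"ts": float("nan"), "lod": float("nan"), "n": n,
           "mean_a": float("nan"), "mean_b": float("nan"),
           "effect": float("nan")}
    in_a, in_b = g == A, g == B
    if n < min_lines or not in_a.any() or not in_b.any():
        return out
    out["mean_a"] = float(y[in_a].mean())
    out["mean_b"] = float(y[in_b].mean())
    out["effect"] = out["mean_a"] - out["mean_b"]

    if covariate is None:
        rss_full = float(((y[in_a] - out["mean_a"]) ** 2).sum()
                         + ((y[in_b] - out["mean_b"]) ** 2).sum())
        rss_red = float(((y - y.mean()) ** 2).sum())
    else:
        c = covariate[use]
        x_red = np.column_stack([np.ones(n), (c == B).astype(float)])
        x_full = np.column_stack([x_red, in_b.astype(float)])
        rss_red = _lstsq_rss(x_red, y)
        rss_full = _lstsq_rss(x_full, y)
    if rss_red <= 0.0:
        raise ValueError("zero residual variance: phenotype is constant")
    if rss_full <= 0.0:
        raise ValueError("zero residual variance in the full model")
    out["ts"] = max(0.0, n * math.log(rss_red / rss_full))
    out["lod"] = out["ts"] / TWO_LN_TEN
    return out


def _lstsq_rss(x: np.ndarray, y: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    return float(resid @ resid)


def ts_matrix(calls: np.ndarray, values: np.ndarray,
              min_lines: int = 20) -> np.ndarray:
    """Vectorised no-covariate TS for all markers x all phenotype columns.

    ``calls`` is markers x lines; ``values`` is lines (1-D) or
    lines x n_phenotypes.  Lines with non-finite phenotype must be removed
    by the caller.  Returns TS with nan where a test is undefined.
    """
    y = np.atleast_2d(np.asarray(values, dtype=float).T).T  # lines x p
    ind_a = (calls == A).astype(np.float64)
    ind_b = (calls == B).astype(np.float64)
    na = ind_a.sum(axis=1, keepdims=True)
    nb = ind_b.sum(axis=1, keepdims=True)
    n = na + nb
    sum_a = ind_a @ y
    sum_b = ind_b @ y
    sumsq = (ind_a + ind_b) @ (y ** 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        rss_full = sumsq - sum_a ** 2 / na - sum_b ** 2 / nb
        rss_red = sumsq - (sum_a + sum_b) ** 2 / n
        ratio = rss_red / np.maximum(rss_full, 1e-300)
        ts = n * np.log(np.maximum(ratio, 1.0))
    undefined = (n < min_lines) | (na == 0) | (nb == 0)
    ts[np.broadcast_to(undefined, ts.shape)] = np.nan
    return ts if np.asarray(values).ndim > 1 else ts[:, 0]


# -- genome scan -------------------------------------------------------------

@dataclass
class ScanProfile:
    """Per-marker scan results for one trait/environment combination."""

    table: pd.DataFrame  # marker, chromosome, position, n, ts, lod, means, effect
    trait: str = ""
    environment: str = "means"
    covariate_marker: str | None = None

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def genome_scan(table: MarkerTable, values: pd.Series | np.ndarray,
                covariate_marker: str | None = None, min_lines: int = 20,
                trait: str = "", environment: str = "means") -> ScanProfile:
    """Single-marker TS at every marker, in genome order.

    ``values`` may be a Series indexed by line id (lines absent from the
    table are ignored and vice versa) or an array aligned to the table's
    lines.  The covariate marker is excluded from being tested against
    itself.  Per-marker failures leave nan in the profile; the scan
    continues.
    """
    y = _align_values(table, values)
    cov = None
    cov_idx = -1
    if covariate_marker is not None:
        cov_idx = table.marker_index(covariate_marker)
        cov = table.calls[cov_idx]

    keep = np.isfinite(y)
    calls = table.calls[:, keep]
    yk = y[keep]
    covk = cov[keep] if cov is not None else None

    rows = []
    if covk is None:
        ts = ts_matrix(calls, yk, min_lines)
        ind_a = (calls == A)
        ind_b = (calls == B)
        na = ind_a.sum(axis=1)
        nb = ind_b.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            mean_a = (ind_a @ yk) / np.maximum(na, 1)
            mean_b = (ind_b @ yk) / np.maximum(nb, 1)
        mean_a[na == 0] = np.nan
        mean_b[nb == 0] = np.nan
        prof = pd.DataFrame({
            "n": na + nb, "ts": ts, "mean_a": mean_a, "mean_b": mean_b,
        })
    else:
        for i in range(table.n_markers):
            res = single_marker_ts(calls[i], yk, covk, min_lines)
            rows.append((res["n"], res["ts"], res["mean_a"], res["mean_b"]))
        prof = pd.DataFrame(rows, columns=["n", "ts", "mean_a", "mean_b"])
    if cov_idx >= 0:
        prof.loc[cov_idx, "ts"] = np.nan
    prof["lod"] = prof["ts"] / TWO_LN_TEN
    prof["effect"] = prof["mean_a"] - prof["mean_b"]
    out = pd.concat(
        [table.markers[["marker", "chromosome", "position"]].reset_index(drop=True),
         prof], axis=1,
    )
    return ScanProfile(out, trait=trait, environment=environment,
                       covariate_marker=covariate_marker)


def _align_values(table: MarkerTable, values) -> np.ndarray:
    if isinstance(values, pd.Series):
        return values.reindex(table.lines).to_numpy(dtype=float)
    values = np.asarray(values, dtype=float)
    if values.shape != (table.n_lines,):
        raise ValueError(
            f"values shape {values.shape} does not match {table.n_lines} lines"
        )
    return values


# -- permutation thresholds --------------------------------------------------

@dataclass
class PermutationThresholds:
    """Genome-wide TS thresholds from max-T permutation resampling."""

    thresholds: dict[float, float]  # alpha -> TS
    n_permutations: int
    seed: int | None
    maxima: np.ndarray = field(repr=False, default=None)

    def ts(self, alpha: float) -> float:
        return self.thresholds[alpha]

    def lod(self, alpha: float) -> float:
        return self.thresholds[alpha] / TWO_LN_TEN

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "alpha": list(self.thresholds),
            "ts": list(self.thresholds.values()),
            "lod": [v / TWO_LN_TEN for v in self.thresholds.values()],
        })


def permutation_thresholds(table: MarkerTable, values,
                           n_perm: int = 10_000,
                           alphas=(0.05, 0.01, 0.005, 0.001),
                           seed: int | None = None,
                           min_lines: int = 20) -> PermutationThresholds:
    """Empirical genome-wide TS thresholds.

    Each permutation shuffles the phenotype vector across the phenotyped
    lines (genotypes fixed; one shared permutation for all markers) and
    records the genome-wide maximum TS.  ``threshold(alpha)`` is the
    ``floor(alpha * n_perm)``-th largest maximum, so exceeding it has null
    probability ~alpha.
    """
    if n_perm < 100:
        raise ValueError("n_perm < 100 gives unusable tail quantiles")
    y = _align_values(table, values)
    keep = np.isfinite(y)
    calls = table.calls[:, keep]
    yk = y[keep]
    rng = np.random.default_rng(seed)

    perm = np.empty((yk.size, n_perm))
    for p in range(n_perm):
        perm[:, p] = yk[rng.permutation(yk.size)]
    ts = ts_matrix(calls, perm, min_lines)
    maxima = np.nanmax(ts, axis=0)

    thresholds = {}
    order = np.sort(maxima)[::-1]
    for alpha in sorted(alphas, reverse=True):
        k = int(math.floor(alpha * n_perm))
        k = max(k, 1)
        thresholds[alpha] = float(order[k - 1])
    return PermutationThresholds(thresholds, n_perm, seed, maxima)


# -- peak calling ------------------------------------------------------------

@dataclass
class QtlPeak:
    """A declared QTL: peak marker, support interval and allele effect."""

    trait: str
    population: str
    chromosome: str
    peak_marker: str
    peak_mbp: int
    ts: float
    lod: float
    interval: Interval
    effect: float        # mean(A) - mean(B): homozygous substitution effect
    high_parent: str     # parent contributing the high value ('A' or 'B')
    threshold_ts: float

    @property
    def name(self) -> str:
        return f"{self.trait}.{self.population}.{self.peak_mbp}"


def call_peaks(profile: ScanProfile, ts_threshold: float,
               falloff: float = 0.80, exclusion_mbp: float = 75.0,
               population: str = "pop") -> list[QtlPeak]:
    """Iterative peak calling with fall-off intervals and exclusion masking.

    Per chromosome: take the maximum-TS marker strictly exceeding the
    threshold (ties break to the lowest coordinate); the support interval
    is the contiguous marker run around it with ``TS >= falloff * peak``;
    mask the interval widened by ``exclusion_mbp`` on each side; repeat.
    """
    peaks: list[QtlPeak] = []
    df = profile.table
    for chrom, sub in df.groupby("chromosome", sort=False):
        ts = sub["ts"].to_numpy(float)
        pos = sub["position"].to_numpy()
        marker = sub["marker"].to_numpy()
        eff = sub["effect"].to_numpy(float)
        available = np.isfinite(ts)
        while True:
            masked_ts = np.where(available, ts, -np.inf)
            if not np.any(masked_ts > ts_threshold):
                break
            peak = int(np.argmax(masked_ts))  # argmax takes first = lowest coord
            cutoff = falloff * ts[peak]
            # the run may not extend into regions already claimed by
            # (the exclusion zone of) previously declared QTLs
            in_run = available & np.isfinite(ts) & (ts >= cutoff)
            lo = peak
            while lo > 0 and in_run[lo - 1]:
                lo -= 1
            hi = peak
            while hi < len(ts) - 1 and in_run[hi + 1]:
                hi += 1
            interval = Interval(chrom, mbp_unit(int(pos[lo])),
                                mbp_unit(int(pos[hi])))
            effect = eff[peak]
            peaks.append(QtlPeak(
                trait=profile.trait or "trait", population=population,
                chromosome=chrom, peak_marker=str(marker[peak]),
                peak_mbp=mbp_unit(int(pos[peak])), ts=float(ts[peak]),
                lod=float(ts[peak]) / TWO_LN_TEN, interval=interval,
                effect=float(effect),
                high_parent="A" if effect >= 0 else "B",
                threshold_ts=float(ts_threshold),
            ))
            lo_bp = pos[lo] - exclusion_mbp * 1e6
            hi_bp = pos[hi] + exclusion_mbp * 1e6
            available &= ~((pos >= lo_bp) & (pos <= hi_bp))
    return peaks


def peaks_to_frame(peaks: list[QtlPeak]) -> pd.DataFrame:
    rows = [{
        "name": p.name, "trait": p.trait, "population": p.population,
        "chromosome": p.chromosome, "peak_marker": p.peak_marker,
        "peak_mbp": p.peak_mbp, "ts": p.ts, "lod": p.lod,
        "interval_start_mbp": p.interval.start,
        "interval_end_mbp": p.interval.end,
        "effect": p.effect, "high_parent": p.high_parent,
        "threshold_ts": p.threshold_ts,
    } for p in peaks]
    return pd.DataFrame(rows, columns=[
        "name", "trait", "population", "chromosome", "peak_marker",
        "peak_mbp", "ts", "lod", "interval_start_mbp", "interval_end_mbp",
        "effect", "high_parent", "threshold_ts",
    ])


# -- GFF3 export -------------------------------------------------------------

def export_gff(peaks: list[QtlPeak], path) -> None:
    """One GFF3 ``QTL`` feature per peak; interval bounds in bp."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for p in peaks:
            start_bp = (p.interval.start - 1) * 1_000_000 + 1
            end_bp = p.interval.end * 1_000_000
            attrs = (
                f"ID={p.name};Name={p.name};trait={p.trait};"
                f"population={p.population};peak_mbp={p.peak_mbp};"
                f"effect={p.effect:.6g};high_parent={p.high_parent}"
            )
            fh.write("\t".join([
                p.chromosome, "rilmap", "QTL", str(start_bp), str(end_bp),
                f"{p.lod:.4f}", ".", ".", attrs,
            ]) + "\n")


def read_qtl_gff(path) -> list[dict]:
    """Round-trip reader for the QTL GFF3 export."""
    out = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            seqid, _, ftype, start, end, score, _, _, attrs = \
                line.rstrip("\n").split("\t")
            if ftype != "QTL":
                continue
            a = dict(kv.split("=", 1) for kv in attrs.split(";") if "=" in kv)
            out.append({
                "chromosome": seqid,
                "interval": Interval(seqid, mbp_unit(int(start)),
                                     mbp_unit(int(end))),
                "lod": float(score),
                **a,
            })
    return out
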