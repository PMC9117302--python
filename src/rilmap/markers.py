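"""Genotype and phenotype containers and tab-delimited I/O.

Genotype calls are stored as a dense ``int8`` matrix (markers x lines) with
codes ``A`` (first parent), ``B`` (second parent), ``H`` (heterozygous) and
``MISSING``.  The on-disk format is tab-delimited with leading columns
``marker``, ``chromosome``, ``position`` (bp) followed by one column per
line; calls are coded ``A/B/H/U`` (``U`` = missing).  A numeric dialect
(``0/1/2/NA`` = homozygous-first / het / homozygous-second / missing) is
accepted by the reader for interoperability with SNP-matrix exports.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING, A, B, H = 0, 1, 2, 3

CODE_TO_CHAR = np.array(["U", "A", "B", "H"])
CHAR_TO_CODE = {"U": MISSING, "A": A, "B": B, "H": H,
                "N": MISSING, ".": MISSING, "-": MISSING, "": MISSING}
NUMERIC_TO_CODE = {"0": A, "1": H, "2": B, "NA": MISSING, "": MISSING,
                   "nan": MISSING, ".": MISSING}


@dataclass
class MarkerTable:
    """Phased biparental genotype matrix with physical marker positions."""

    markers: pd.DataFrame  # columns: marker, chromosome, position
    lines: list[str]
    calls: np.ndarray  # int8, shape (n_markers, n_lines)

    def __post_init__(self) -> None:
        self.markers = self.markers.reset_index(drop=True)
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.markers), len(self.lines)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.markers)} markers x {len(self.lines)} lines"
            )
        required = {"marker", "chromosome", "position"}
        if not required.issubset(self.markers.columns):
            raise ValueError(f"marker frame needs columns {sorted(required)}")

    # -- shape ---------------------------------------------------------------

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def n_lines(self) -> int:
        return len(self.lines)

    def copy(self) -> "MarkerTable":
        return MarkerTable(self.markers.copy(), list(self.lines), self.calls.copy())

    # -- selection -----------------------------------------------------------

    def select_markers(self, mask) -> "MarkerTable":
        mask = np.asarray(mask)
        idx = np.flatnonzero(mask) if mask.dtype == bool else mask
        return MarkerTable(
            self.markers.iloc[idx], list(self.lines), self.calls[idx]
        )

    def drop_lines(self, names) -> "MarkerTable":
        drop = set(names)
        keep = [i for i, l in enumerate(self.lines) if l not in drop]
        return MarkerTable(
            self.markers, [self.lines[i] for i in keep], self.calls[:, keep]
        )

    def line_index(self, name: str) -> int:
        try:
            return self.lines.index(name)
        except ValueError:
            raise KeyError(f"unknown line {name!r}") from None

    def marker_index(self, marker_id: str) -> int:
        hits = np.flatnonzero(self.markers["marker"].to_numpy() == marker_id)
        if hits.size == 0:
            raise KeyError(f"unknown marker {marker_id!r}")
        return int(hits[0])

    def sorted_by_position(self, chrom_order=None) -> "MarkerTable":
        """Stable sort by (chromosome, position).

        ``chrom_order`` fixes the chromosome order (e.g. from a layout);
        otherwise chromosomes keep their order of first appearance.
        """
        chroms = self.markers["chromosome"]
        if chrom_order is None:
            chrom_order = list(dict.fromkeys(chroms))
        rank = {c: i for i, c in enumerate(chrom_order)}
        unknown = set(chroms) - set(rank)
        if unknown:
            raise ValueError(f"chromosomes not in layout order: {sorted(unknown)}")
        key = chroms.map(rank).to_numpy() * (self.markers["position"].max() + 1.0) \
            + self.markers["position"].to_numpy()
        order = np.argsort(key, kind="stable")
        return self.select_markers(order)

    def chromosome_blocks(self) -> dict[str, np.ndarray]:
        """Marker row indices per chromosome, in table order."""
        out: dict[str, np.ndarray] = {}
        chroms = self.markers["chromosome"].to_numpy()
        for c in dict.fromkeys(chroms):
            out[c] = np.flatnonzero(chroms == c)
        return out

    # -- summaries -----------------------------------------------------------

    def call_counts(self) -> pd.DataFrame:
        """Per-marker counts of A/B/H/missing calls."""
        n = np.zeros((self.n_markers, 4), dtype=int)
        for code in (MISSING, A, B, H):
            n[:, code] = (self.calls == code).sum(axis=1)
        return pd.DataFrame(
            {"n_missing": n[:, MISSING], "n_a": n[:, A],
             "n_b": n[:, B], "n_h": n[:, H]}
        )


# -- genotype I/O ------------------------------------------------------------

META_COLUMNS = ["marker", "chromosome", "position"]


def read_genotypes(path, dialect: str = "char") -> MarkerTable:
    """Read a tab-delimited genotype matrix.

    ``dialect='char'`` expects A/B/H/U calls; ``dialect='numeric'`` expects
    0/1/2/NA (0 = first-parent homozygote, 2 = second-parent homozygote).
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing_meta = [c for c in META_COLUMNS if c not in df.columns]
    if missing_meta:
        raise ValueError(f"genotype file lacks columns {missing_meta}")
    lines = [c for c in df.columns if c not in META_COLUMNS]
    mapping = CHAR_TO_CODE if dialect == "char" else NUMERIC_TO_CODE
    if dialect not in ("char", "numeric"):
        raise ValueError(f"unknown genotype dialect {dialect!r}")
    calls = np.empty((len(df), len(lines)), dtype=np.int8)
    for j, line in enumerate(lines):
        col = df[line].str.strip()
        mapped = col.map(mapping)
        if mapped.isna().any():
            bad = sorted(set(col[mapped.isna()]))
            raise ValueError(f"unrecognised calls in column {line!r}: {bad}")
        calls[:, j] = mapped.to_numpy(dtype=np.int8)
    markers = df[META_COLUMNS].copy()
    markers["position"] = markers["position"].astype(np.int64)
    return MarkerTable(markers, lines, calls)


def write_genotypes(table: MarkerTable, path) -> None:
    """Write the char-dialect genotype matrix (bit-stable for fixed input)."""
    chars = pd.DataFrame(CODE_TO_CHAR[table.calls], columns=table.lines)
    out = pd.concat([table.markers[META_COLUMNS].reset_index(drop=True),
                     chars], axis=1)
    out.to_csv(path, sep="\t", index=False)


# -- phenotype I/O -----------------------------------------------------------

PHENO_COLUMNS = ["line", "trait", "environment", "value"]


def read_phenotypes(path) -> pd.DataFrame:
    """Read a long-format phenotype table (line, trait, environment, value)."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in PHENO_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"phenotype file lacks columns {missing}")
    df = df[PHENO_COLUMNS].copy()
    df["value"] = pd.to_numeric(df["value"], errors="coerce")
    return df


def write_phenotypes(df: pd.DataFrame, path) -> None:
    df[PHENO_COLUMNS].to_csv(path, sep="\t", index=False)
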