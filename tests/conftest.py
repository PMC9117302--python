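"""Shared fixtures: tiny hand-built tables and simulation scenarios."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import rilmap as rm

settings.register_profile("repro", deadline=None, derandomize=True)
settings.load_profile("repro")
from rilmap.markers import CHAR_TO_CODE, MarkerTable

MB = 1_000_000


def table_from_patterns(patterns: dict[str, str], chromosome: str = "chr1",
                        positions=None, chrom_per_marker=None) -> MarkerTable:
    """Build a MarkerTable from per-line call strings (one char per marker).

    ``patterns`` maps line id -> string over {A, B, H, U}; ``positions``
    defaults to 1, 2, ... Mbp.  ``chrom_per_marker`` optionally assigns a
    chromosome per marker.
    """
    lines = list(patterns)
    n_markers = len(next(iter(patterns.values())))
    assert all(len(s) == n_markers for s in patterns.values())
    if positions is None:
        positions = [(i + 1) * MB for i in range(n_markers)]
    if chrom_per_marker is None:
        chrom_per_marker = [chromosome] * n_markers
    markers = pd.DataFrame({
        "marker": [f"m{i + 1}" for i in range(n_markers)],
        "chromosome": chrom_per_marker,
        "position": positions,
    })
    calls = np.array(
        [[CHAR_TO_CODE[patterns[line][i]] for line in lines]
         for i in range(n_markers)], dtype=np.int8,
    )
    return MarkerTable(markers, lines, calls)


# -- simulation scenarios (shared study conditions) ---------------------------
#
# Toy chromosomes are 200 Mbp.  Rearrangement scenarios use a dense genetic
# map (4 cM/Mbp) so that the recombining arms span several Morgans and block
# bounds are resolvable at window (10 Mbp) resolution; the QTL scenario uses
# 0.1 cM/Mbp so that fall-off support intervals span tens of Mbp, like the
# wide physically-referenced intervals seen in a large suppressed-
# recombination genome.

def null_scenario(seed: int) -> rm.SimConfig:
    return rm.SimConfig(
        layout=rm.toy_layout(2, 200), n_lines=200, generations=6,
        markers_per_chromosome=100, cm_per_mbp=4.0, seed=seed,
    )


# truth: chr1 [100, 150] is coupled with chr2 [1, 150]
TRANS_TRUTH = {"chr1": (100, 150), "chr2": (1, 150)}


def translocation_scenario(seed: int, deficiency_survival: float = 1.0
                           ) -> rm.SimConfig:
    spec = rm.TranslocationSpec(
        donor="chr2", recipient="chr1",
        donor_region=(150 * MB, 200 * MB),
        recipient_region=(150 * MB, 200 * MB),
        carrier="A",
        recombining_regions=(
            ("chr1", 1, 100 * MB),
            ("chr1", 150 * MB, 200 * MB),
            ("chr2", 150 * MB, 200 * MB),
        ),
        deficiency_survival=deficiency_survival,
    )
    cfg = null_scenario(seed)
    return rm.SimConfig(**{**cfg.__dict__, "translocations": (spec,)})


def inversion_scenario(seed: int) -> rm.SimConfig:
    cfg = null_scenario(seed)
    inv = rm.InversionSpec("chr1", 1, 180 * MB)
    return rm.SimConfig(**{**cfg.__dict__, "inversions": (inv,)})


def qtl_scenario(seed: int) -> rm.SimConfig:
    return rm.SimConfig(
        layout=rm.toy_layout(3, 200), n_lines=200, generations=6,
        markers_per_chromosome=200, cm_per_mbp=0.1,
        qtls=(rm.QtlSpec("y", "chr2", 100 * MB, 1.0),),
        heritability=0.2, seed=seed,
    )


@pytest.fixture(scope="session")
def small_ril():
    """One modest curated-quality RIL population reused across tests."""
    cfg = rm.SimConfig(layout=rm.toy_layout(2, 100), n_lines=100,
                       generations=6, markers_per_chromosome=50,
                       cm_per_mbp=1.0, seed=1234)
    truth, pedigree = rm.simulate_ril(cfg)
    return cfg, truth, pedigree
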