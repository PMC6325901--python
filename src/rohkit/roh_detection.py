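"""Two runs-of-homozygosity callers over dense SNP-array genotypes.

SCAN caller
    The three-step workflow used with GERMLINE run in homozygosity-only
    mode with all internal filtering disabled: (1) find every maximal
    zero-heterozygote run spanning at least ``min_span`` bp (default
    500 kb); (2) merge neighbouring runs separated by strictly less than
    ``max_merge_gap`` bp (default 50 kb) — tightly clustered heterozygotes
    between two runs are typically genotyping error or small CNVs, so
    bridging them recovers long tracts; (3) drop merged tracts containing
    fewer than ``min_markers`` array markers (default 41), guarding
    against spurious calls in marker-poor regions.  The intended
    computation is implemented directly rather than by emulating
    GERMLINE's windowed internals.

WINDOWED caller
    The PLINK 1.07 sliding-window algorithm with the study's settings:
    41-SNP windows, zero heterozygous and zero missing calls allowed per
    window, per-SNP hit proportion threshold 0.05, minimum 41 SNPs and
    500 kb per segment, density and gap checks disabled.

Both callers report tracts whose endpoints are marker positions; length
is ``end - start + 1`` bp.  Output is a tidy DataFrame with columns
``sample, chrom, start, end, length_bp, n_markers, caller``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

from .genotype_io import HET, MISSING, GenotypePanel

logger = logging.getLogger(__name__)

TRACT_COLUMNS = ["sample", "chrom", "start", "end", "length_bp", "n_markers", "caller"]


@dataclass(frozen=True)
class ScanParams:
    """Parameters of the SCAN (zero-het run / merge / filter) caller."""

    min_span: int = 500_000
    max_merge_gap: int = 50_000  # sensitivity variant: 100_000
    min_markers: int = 41
    missing_policy: Literal["BREAK", "IGNORE"] = "BREAK"

    def __post_init__(self) -> None:
        if min(self.min_span, self.max_merge_gap, self.min_markers) <= 0:
            raise ValueError("ScanParams values must be positive")
        if self.max_merge_gap >= self.min_span:
            raise ValueError("max_merge_gap must be smaller than min_span")
        if self.missing_policy not in ("BREAK", "IGNORE"):
            raise ValueError(f"unknown missing policy {self.missing_policy!r}")


@dataclass(frozen=True)
class WindowParams:
    """Parameters of the WINDOWED (PLINK-1.07-style) caller.

    ``density_kb_per_snp`` and ``max_gap_kb`` correspond to PLINK's
    ``--homozyg-density`` / ``--homozyg-gap`` checks; the study set both
    high enough to have no effect, so they are explicitly disabled here
    (``None``) and enabling them is not supported.
    """

    window_snps: int = 41
    window_het_max: int = 0
    window_missing_max: int = 0
    window_hit_threshold: float = 0.05
    min_snps: int = 41
    min_kb: float = 500.0
    density_kb_per_snp: float | None = None  # disabled
    max_gap_kb: float | None = None  # disabled

    def __post_init__(self) -> None:
        if self.window_snps <= 0 or self.min_snps <= 0 or self.min_kb <= 0:
            raise ValueError("window/min sizes must be positive")
        if not 0.0 <= self.window_hit_threshold <= 1.0:
            raise ValueError("window_hit_threshold must be in [0, 1]")
        if self.density_kb_per_snp is not None or self.max_gap_kb is not None:
            raise NotImplementedError(
                "density/gap checks are intentionally disabled; run with None"
            )


# ---------------------------------------------------------------------------
# SCAN caller primitives
# ---------------------------------------------------------------------------


def find_homozygous_runs(
    calls: np.ndarray, positions: np.ndarray, params: ScanParams
) -> list[tuple[int, int, int, int]]:
    """Maximal runs of consecutive non-heterozygous markers on one chromosome.

    Under the default BREAK policy a missing call also terminates a run;
    under IGNORE it is treated as homozygous.  Returns
    ``(start_bp, end_bp, first_marker_idx, last_marker_idx)`` for every
    run whose span (first to last marker, inclusive) is at least
    ``params.min_span``.
    """
    calls = np.asarray(calls)
    positions = np.asarray(positions)
    if calls.size == 0:
        return []
    breaks = calls == HET
    if params.missing_policy == "BREAK":
        breaks |= calls == MISSING
    # boundaries of maximal runs of ~breaks
    padded = np.concatenate(([True], breaks, [True]))
    starts = np.flatnonzero(~padded[1:-1] & padded[:-2])
    ends = np.flatnonzero(~padded[1:-1] & padded[2:])
    out = []
    for i0, i1 in zip(starts, ends):
        span = int(positions[i1] - positions[i0] + 1)
        if span >= params.min_span:
            out.append((int(positions[i0]), int(positions[i1]), int(i0), int(i1)))
    return out


def merge_runs(
    runs: list[tuple[int, int, int, int]], params: ScanParams
) -> list[tuple[int, int]]:
    """Transitively merge sorted same-chromosome runs separated by < max gap.

    The gap between neighbours is ``next.start - prev.end``; merging is
    strict (a gap of exactly the threshold is not merged).
    """
    merged: list[tuple[int, int]] = []
    for start, end, *_ in runs:
        if merged and start - merged[-1][1] < params.max_merge_gap:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return merged


def filter_tracts(
    merged: list[tuple[int, int]], positions: np.ndarray, params: ScanParams
) -> list[tuple[int, int, int]]:
    """Drop merged tracts with fewer than ``min_markers`` array markers.

    The count includes every marker with position inside [start, end] —
    heterozygous markers inside merged gaps included.
    Returns ``(start, end, n_markers)`` for surviving tracts.
    """
    positions = np.asarray(positions)
    out = []
    for start, end in merged:
        n = int(
            np.searchsorted(positions, end, side="right")
            - np.searchsorted(positions, start, side="left")
        )
        if n >= params.min_markers:
            out.append((start, end, n))
    return out


def scan_roh(panel: GenotypePanel, params: ScanParams | None = None) -> pd.DataFrame:
    """Run the SCAN caller over every sample and chromosome of a panel."""
    params = params or ScanParams()
    rows = []
    mm = panel.markers
    for chrom in mm.chromosomes():
        sl = mm.chrom_slice(chrom)
        positions = mm.table["pos"].to_numpy()[sl]
        for i, sample in enumerate(panel.samples):
            runs = find_homozygous_runs(panel.calls[i, sl], positions, params)
            merged = merge_runs(runs, params)
            for start, end, n in filter_tracts(merged, positions, params):
                rows.append((sample, chrom, start, end, end - start + 1, n, "SCAN"))
    return pd.DataFrame(rows, columns=TRACT_COLUMNS)


# ---------------------------------------------------------------------------
# WINDOWED caller
# ---------------------------------------------------------------------------


def _windowed_chrom(
    calls: np.ndarray, positions: np.ndarray, params: WindowParams
) -> list[tuple[int, int, int]]:
    """PLINK-1.07-style windowed calls on one chromosome: (start, end, n)."""
    m = calls.size
    w = params.window_snps
    if m < w:
        logger.info("chromosome with %d markers shorter than one %d-SNP window", m, w)
        return []
    het = (calls == HET).astype(np.int64)
    mis = (calls == MISSING).astype(np.int64)
    chet = np.concatenate(([0], np.cumsum(het)))
    cmis = np.concatenate(([0], np.cumsum(mis)))
    n_win = m - w + 1
    win_idx = np.arange(n_win)
    hit = (chet[win_idx + w] - chet[win_idx] <= params.window_het_max) & (
        cmis[win_idx + w] - cmis[win_idx] <= params.window_missing_max
    )
    chit = np.concatenate(([0], np.cumsum(hit.astype(np.int64))))
    j = np.arange(m)
    lo = np.maximum(0, j - w + 1)
    hi = np.minimum(j, n_win - 1)
    n_containing = hi - lo + 1
    n_hits = chit[hi + 1] - chit[lo]
    qualifies = n_hits / n_containing >= params.window_hit_threshold

    homozygous = ~((calls == HET) | (calls == MISSING))
    out = []
    padded = np.concatenate(([False], qualifies, [False]))
    starts = np.flatnonzero(padded[1:-1] & ~padded[:-2])
    ends = np.flatnonzero(padded[1:-1] & ~padded[2:])
    for i0, i1 in zip(starts, ends):
        # trim to the outermost homozygous SNPs of the stretch
        idx = np.flatnonzero(homozygous[i0 : i1 + 1])
        if idx.size == 0:
            continue
        a, b = i0 + int(idx[0]), i0 + int(idx[-1])
        n_snps = b - a + 1
        span = int(positions[b] - positions[a] + 1)
        if n_snps >= params.min_snps and span >= params.min_kb * 1000:
            out.append((int(positions[a]), int(positions[b]), n_snps))
    return out


def windowed_roh(panel: GenotypePanel, params: WindowParams | None = None) -> pd.DataFrame:
    """Run the WINDOWED (PLINK-1.07-style) caller over a panel."""
    params = params or WindowParams()
    rows = []
    mm = panel.markers
    for chrom in mm.chromosomes():
        sl = mm.chrom_slice(chrom)
        positions = mm.table["pos"].to_numpy()[sl]
        for i, sample in enumerate(panel.samples):
            for start, end, n in _windowed_chrom(panel.calls[i, sl], positions, params):
                rows.append((sample, chrom, start, end, end - start + 1, n, "WINDOWED"))
    return pd.DataFrame(rows, columns=TRACT_COLUMNS)


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------


def validate_tracts(tracts: pd.DataFrame) -> None:
    """Assert the structural invariants of a tract table.

    Tracts of one sample on one chromosome must be sorted, non-overlapping,
    and internally consistent (length = end - start + 1 > 0).
    """
    if tracts.empty:
        return
    bad_len = tracts["length_bp"] != tracts["end"] - tracts["start"] + 1
    if bad_len.any():
        raise ValueError("tract length_bp inconsistent with start/end")
    if (tracts["length_bp"] <= 0).any():
        raise ValueError("non-positive tract length")
    for (sample, chrom), grp in tracts.groupby(["sample", "chrom"]):
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        if np.any(np.diff(starts) <= 0) or np.any(starts[1:] <= ends[:-1]):
            raise ValueError(f"tracts of {sample} on chromosome {chrom} overlap or are unsorted")
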