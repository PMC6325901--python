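"""Per-breed genomic ROH summaries: density maps, islands, length curves.

The local ROH density of a breed is, at each evaluation position, the
fraction of sampled dogs whose called tracts cover that position.  The
default evaluation grid is the marker positions themselves — no coverage
is invented between markers.  Regions where nearly every dog of a breed
carries an ROH ("ROH islands") mark deterministic loss of diversity from
drift or selective sweeps.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd

from .genotype_io import GenotypePanel
from .enrichment import cumulative_curve

logger = logging.getLogger(__name__)


def roh_density(
    tracts: pd.DataFrame,
    panel: GenotypePanel,
    breed: str,
    grid: dict[str, np.ndarray] | None = None,
) -> pd.DataFrame:
    """ROH density track for one breed.

    Returns columns ``breed, chrom, pos, density, n`` where density is
    (dogs with a covering tract) / n exactly.  ``grid`` optionally maps
    chromosome -> evaluation positions; the default is the marker grid.
    """
    members = [s for s in panel.samples if panel.breed(s) == breed]
    if not members:
        raise ValueError(f"no samples with breed {breed!r}")
    n = len(members)
    sub = tracts[tracts["sample"].isin(members)]
    rows = []
    for chrom in panel.markers.chromosomes():
        pos = (
            np.asarray(grid[chrom])
            if grid is not None and chrom in grid
            else panel.markers.positions(chrom)
        )
        if pos.size == 0:
            continue
        counts = np.zeros(pos.size, dtype=np.int64)
        tc = sub[sub["chrom"] == chrom]
        # interval stabbing via a difference array: tracts of one dog are
        # disjoint, so summing per-tract contributions counts dogs once.
        diff = np.zeros(pos.size + 1, dtype=np.int64)
        for start, end in zip(tc["start"], tc["end"]):
            i0 = int(np.searchsorted(pos, start, side="left"))
            i1 = int(np.searchsorted(pos, end, side="right"))
            diff[i0] += 1
            diff[i1] -= 1
        counts = np.cumsum(diff[:-1])
        rows.append(
            pd.DataFrame(
                {
                    "breed": breed,
                    "chrom": chrom,
                    "pos": pos,
                    "density": counts / n,
                    "n": n,
                }
            )
        )
    return pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(
        columns=["breed", "chrom", "pos", "density", "n"]
    )


def detect_islands(
    track: pd.DataFrame, threshold: float = 0.95, min_span: int = 500_000
) -> pd.DataFrame:
    """Maximal high-density intervals (ROH islands) of a density track.

    An island is a maximal run of consecutive evaluation positions with
    density >= ``threshold`` whose first-to-last span is at least
    ``min_span`` bp.  Both knobs are package parameters.
    """
    rows = []
    for (breed, chrom), grp in track.groupby(["breed", "chrom"]):
        grp = grp.sort_values("pos")
        dens = grp["density"].to_numpy()
        pos = grp["pos"].to_numpy()
        above = dens >= threshold
        padded = np.concatenate(([False], above, [False]))
        starts = np.flatnonzero(padded[1:-1] & ~padded[:-2])
        ends = np.flatnonzero(padded[1:-1] & ~padded[2:])
        for i0, i1 in zip(starts, ends):
            span = int(pos[i1] - pos[i0] + 1)
            if span >= min_span:
                rows.append(
                    {
                        "breed": breed,
                        "chrom": chrom,
                        "start": int(pos[i0]),
                        "end": int(pos[i1]),
                        "span": span,
                        "mean_density": float(dens[i0 : i1 + 1].mean()),
                    }
                )
    return pd.DataFrame(
        rows, columns=["breed", "chrom", "start", "end", "span", "mean_density"]
    )


def breed_cumulative(
    tracts: pd.DataFrame,
    metadata: pd.DataFrame,
    scope: str = "AUTOSOMES",
    grid: np.ndarray | None = None,
    weighted: bool = False,
) -> dict[str, pd.DataFrame]:
    """Per-breed cumulative ROH-by-length curves.

    ``scope`` is "AUTOSOMES" or "CHR_X"; for CHR_X only tracts of female
    dogs are used and breeds without females are skipped with a warning.
    """
    out: dict[str, pd.DataFrame] = {}
    breeds = sorted(set(metadata["breed"].dropna()))
    for breed in breeds:
        members = metadata.index[metadata["breed"] == breed]
        if scope == "CHR_X":
            members = [s for s in members if metadata.loc[s, "sex"] == "F"]
            if not members:
                logger.warning("breed %r has no females; skipped for CHR_X", breed)
                continue
            sub = tracts[tracts["sample"].isin(members) & (tracts["chrom"] == "X")]
        else:
            sub = tracts[tracts["sample"].isin(members) & (tracts["chrom"] != "X")]
        if sub.empty:
            logger.warning("breed %r has no %s tracts; skipped", breed, scope)
            continue
        out[breed] = cumulative_curve(sub["length_bp"].to_numpy(), grid=grid, weighted=weighted)
    return out


def write_bedgraph(track: pd.DataFrame, path: str) -> None:
    """Export a density track as BedGraph (0-based half-open intervals).

    Each evaluation position becomes an interval reaching to the next
    position; the last interval has unit width.
    """
    with open(path, "w") as fh:
        for (breed, chrom), grp in track.groupby(["breed", "chrom"]):
            grp = grp.sort_values("pos")
            pos = grp["pos"].to_numpy()
            dens = grp["density"].to_numpy()
            nxt = np.concatenate((pos[1:], [pos[-1] + 1]))
            for p, q, d in zip(pos, nxt, dens):
                fh.write(f"{chrom}\t{p - 1}\t{q - 1}\t{d:.6g}\n")
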