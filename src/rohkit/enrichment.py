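"""Enrichment of homozygous recessive disease genotypes in ROH.

The central analysis: every observed at-risk genotype (a dog homozygous
for a recessive disease allele) is assigned the length class of the ROH
tract containing its locus — or the sub-threshold class SUB when no
called tract contains it.  Comparing the class distribution of at-risk
genotypes against the average per-dog genome composition by class gives
a relative risk per class, baselined on SUB:

    RR(c) = [atrisk%(c) / genome%(c)] / [atrisk%(SUB) / genome%(SUB)]

so RR(SUB) = 1 by construction and RR is invariant to common rescaling
of the genome fractions.  A resampling null (1000 draws of k tracts,
uniformly without replacement from the cohort's full tract set) shows
whether the disease-overlapping tracts are a random sample of all
tracts; the observed cumulative length curve is compared against the
replicate envelope.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genotype_io import MarkerMap

logger = logging.getLogger(__name__)

#: Class order; SUB is the baseline (no containing tract / below threshold).
CLASSES = ("SUB", "SHORT", "MEDIUM", "LONG")


@dataclass(frozen=True)
class LengthClassSpec:
    """Tract length classes in bp; bounds are left-closed/right-open.

    Defaults: SUB < 0.5 Mb (below the detection threshold), SHORT
    [0.5, 2.5) Mb, MEDIUM [2.5, 5) Mb, LONG >= 5 Mb.
    """

    sub_max: int = 500_000
    short_max: int = 2_500_000
    medium_max: int = 5_000_000

    def __post_init__(self) -> None:
        if not 0 < self.sub_max < self.short_max < self.medium_max:
            raise ValueError("class bounds must be increasing and positive")

    def classify(self, length: int) -> str:
        if length < self.sub_max:
            return "SUB"
        if length < self.short_max:
            return "SHORT"
        if length < self.medium_max:
            return "MEDIUM"
        return "LONG"


def classify_at_risk(
    records: pd.DataFrame,
    tracts: pd.DataFrame,
    spec: LengthClassSpec | None = None,
    markers: MarkerMap | None = None,
) -> pd.DataFrame:
    """Assign each at-risk genotype the class of its containing tract.

    ``records`` needs columns ``sample, chrom, pos`` (plus any id
    columns, which are carried through).  A genotype whose locus position
    falls inside a tract of the same sample (start <= pos <= end) gets
    that tract's length class; with no containing tract it is SUB.  Loci
    off the marker span are excluded with a warning when ``markers`` is
    supplied.
    """
    spec = spec or LengthClassSpec()
    out = records.copy()
    if markers is not None and not out.empty:
        keep = []
        for _, row in out.iterrows():
            pos = markers.positions(str(row["chrom"]))
            ok = pos.size > 0 and pos[0] <= row["pos"] <= pos[-1]
            if not ok:
                logger.warning(
                    "at-risk locus %s:%s off the marker span; excluded",
                    row["chrom"],
                    row["pos"],
                )
            keep.append(ok)
        out = out[keep].reset_index(drop=True)

    classes, lengths = [], []
    for _, row in out.iterrows():
        t = tracts[
            (tracts["sample"] == row["sample"])
            & (tracts["chrom"].astype(str) == str(row["chrom"]))
            & (tracts["start"] <= row["pos"])
            & (tracts["end"] >= row["pos"])
        ]
        if t.empty:
            classes.append("SUB")
            lengths.append(0)
        else:
            length = int(t["length_bp"].iloc[0])
            classes.append(spec.classify(length))
            lengths.append(length)
    out["length_class"] = classes
    out["tract_length"] = lengths
    return out


def genome_fractions(
    tracts: pd.DataFrame,
    samples: Sequence[str],
    markers: MarkerMap,
    spec: LengthClassSpec | None = None,
    l_mode: str = "MARKER_SPAN",
    fixed_lengths: Mapping[str, int] | None = None,
    chromosomes: Sequence[str] | None = None,
) -> pd.Series:
    """Mean per-dog genome fraction in each tract length class.

    For each dog the class fractions are summed tract length / L with
    SUB = 1 - (SHORT + MEDIUM + LONG); the per-dog vectors are then
    averaged unweighted across dogs.  Fractions sum to 1 exactly per dog
    and hence on average.
    """
    spec = spec or LengthClassSpec()
    if chromosomes is None:
        chromosomes = [c for c in markers.chromosomes() if c != "X"]
    if l_mode == "MARKER_SPAN":
        L = sum(markers.chrom_span(c) for c in chromosomes)
    elif l_mode == "FIXED":
        if fixed_lengths is None:
            raise ValueError("l_mode FIXED requires fixed_lengths")
        L = sum(int(fixed_lengths[c]) for c in chromosomes)
    else:
        raise ValueError(f"unknown l_mode {l_mode!r}")

    per_dog = pd.DataFrame(0.0, index=list(samples), columns=list(CLASSES))
    in_scope = tracts[tracts["chrom"].isin(chromosomes)] if not tracts.empty else tracts
    for _, row in in_scope.iterrows():
        if row["sample"] not in per_dog.index:
            continue
        cls = spec.classify(int(row["length_bp"]))
        per_dog.loc[row["sample"], cls] += row["length_bp"] / L
    per_dog["SUB"] = 1.0 - per_dog[["SHORT", "MEDIUM", "LONG"]].sum(axis=1)
    return per_dog.mean(axis=0)


def at_risk_fractions(classified: pd.DataFrame) -> pd.Series:
    """Fraction of at-risk genotypes per length class (sums to 1)."""
    counts = classified["length_class"].value_counts()
    frac = pd.Series({c: counts.get(c, 0) for c in CLASSES}, dtype=float)
    total = frac.sum()
    if total == 0:
        raise ValueError("no at-risk genotypes to classify")
    return frac / total


def relative_risk(genome_frac: pd.Series, atrisk_frac: pd.Series) -> pd.Series:
    """Per-class relative risk vs the SUB baseline.

    A class with zero genome fraction has undefined density and is
    reported as NaN.
    """
    base = atrisk_frac["SUB"] / genome_frac["SUB"] if genome_frac["SUB"] else np.nan
    out = {"SUB": 1.0}
    for c in CLASSES[1:]:
        if genome_frac[c] == 0 or not np.isfinite(base):
            out[c] = np.nan
        elif base == 0:
            # no at-risk genotype fell outside ROH: enrichment is unbounded
            out[c] = np.inf if atrisk_frac[c] > 0 else np.nan
        else:
            out[c] = (atrisk_frac[c] / genome_frac[c]) / base
    return pd.Series(out, index=list(CLASSES))


def enrichment_table(
    tracts: pd.DataFrame,
    records: pd.DataFrame,
    samples: Sequence[str],
    markers: MarkerMap,
    spec: LengthClassSpec | None = None,
    cohort: str = "ALL",
    l_mode: str = "MARKER_SPAN",
    fixed_lengths: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Assemble the per-class enrichment table (genome %, at-risk %, RR)."""
    spec = spec or LengthClassSpec()
    caller = tracts["caller"].iloc[0] if not tracts.empty else "NONE"
    gf = genome_fractions(tracts, samples, markers, spec, l_mode, fixed_lengths)
    classified = classify_at_risk(records, tracts, spec, markers)
    af = at_risk_fractions(classified)
    rr = relative_risk(gf, af)
    return pd.DataFrame(
        {
            "length_class": list(CLASSES),
            "genome_pct": [100 * gf[c] for c in CLASSES],
            "atrisk_pct": [100 * af[c] for c in CLASSES],
            "relative_risk": [rr[c] for c in CLASSES],
            "cohort": cohort,
            "caller": caller,
        }
    )


# ---------------------------------------------------------------------------
# Cumulative length curves and the resampling null
# ---------------------------------------------------------------------------


def cumulative_curve(
    lengths: Sequence[int] | np.ndarray,
    grid: np.ndarray | None = None,
    weighted: bool = False,
) -> pd.DataFrame:
    """Cumulative tract-length curve: fraction of tracts with length >= x.

    Tracts are ordered longest to shortest.  With ``weighted`` the curve
    is length-weighted (fraction of total ROH bp in tracts >= x) instead
    of count-based.  Returns columns ``length`` and ``fraction``;
    ``grid`` defaults to the sorted unique lengths.
    """
    lengths = np.sort(np.asarray(lengths, dtype=np.int64))
    if lengths.size == 0:
        return pd.DataFrame(columns=["length", "fraction"])
    if grid is None:
        grid = np.unique(lengths)
    idx = np.searchsorted(lengths, grid, side="left")
    if weighted:
        tail = np.concatenate((np.cumsum(lengths[::-1])[::-1], [0]))
        frac = tail[idx] / lengths.sum()
    else:
        frac = (lengths.size - idx) / lengths.size
    return pd.DataFrame({"length": np.asarray(grid), "fraction": frac})


@dataclass
class NullEnvelope:
    """Pointwise envelope of resampled cumulative curves."""

    grid: np.ndarray
    lo: np.ndarray        # pointwise minimum over replicates
    hi: np.ndarray        # pointwise maximum
    quantiles: pd.DataFrame  # rows = quantile levels, columns = grid points
    replicates: np.ndarray   # (n_reps, len(grid))

    def contains(self, observed_lengths: Sequence[int], weighted: bool = False) -> bool:
        """True if the observed curve stays inside [lo, hi] at every grid point."""
        obs = cumulative_curve(observed_lengths, grid=self.grid, weighted=weighted)
        f = obs["fraction"].to_numpy()
        return bool(np.all((f >= self.lo) & (f <= self.hi)))


def resample_null(
    all_lengths: Sequence[int] | np.ndarray,
    k: int,
    n_reps: int = 1000,
    seed: int = 0,
    grid: np.ndarray | None = None,
    weighted: bool = False,
    quantile_levels: Sequence[float] = (0.025, 0.5, 0.975),
) -> NullEnvelope:
    """Resampling null for the disease-tract curve.

    Draws ``n_reps`` sets of ``k`` tracts uniformly without replacement
    from the cohort's full tract set and evaluates each set's cumulative
    curve on a common grid.
    """
    all_lengths = np.asarray(all_lengths, dtype=np.int64)
    if k > all_lengths.size:
        raise ValueError(f"cannot draw {k} tracts from a set of {all_lengths.size}")
    if k <= 0:
        raise ValueError("k must be positive")
    rng = np.random.default_rng(seed)
    if grid is None:
        grid = np.unique(all_lengths)
    reps = np.empty((n_reps, grid.size))
    for r in range(n_reps):
        draw = rng.choice(all_lengths, size=k, replace=False)
        reps[r] = cumulative_curve(draw, grid=grid, weighted=weighted)["fraction"].to_numpy()
    q = pd.DataFrame(
        np.quantile(reps, quantile_levels, axis=0),
        index=list(quantile_levels),
    )
    return NullEnvelope(
        grid=np.asarray(grid),
        lo=reps.min(axis=0),
        hi=reps.max(axis=0),
        quantiles=q,
        replicates=reps,
    )
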