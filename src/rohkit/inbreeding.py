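"""Genomic inbreeding coefficients from called ROH tracts.

F_ROH for individual j is the summed length of its ROH divided by the
genome length L:  F_ROH(j) = sum_k length(ROH_k) / L.

Two denominators are supported: ``MARKER_SPAN`` (default) uses the summed
first-to-last marker span of the in-scope chromosomes, which is
self-contained and matches the region the caller can actually see;
``FIXED`` accepts user-supplied assembly lengths (e.g. canFam3.1) for
comparability across arrays.  Chromosome X statistics are reported for
females only — males are hemizygous, so X "homozygosity" carries no
inbreeding signal.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genotype_io import MarkerMap

logger = logging.getLogger(__name__)

SCOPES = ("AUTOSOMES", "CHR_X")
L_MODES = ("MARKER_SPAN", "FIXED")


def _scope_chromosomes(markers: MarkerMap, scope: str) -> list[str]:
    if scope == "AUTOSOMES":
        return [c for c in markers.chromosomes() if c != "X"]
    if scope == "CHR_X":
        return [c for c in markers.chromosomes() if c == "X"]
    raise ValueError(f"unknown scope {scope!r}; expected one of {SCOPES}")


def compute_froh(
    tracts: pd.DataFrame,
    markers: MarkerMap,
    scope: str = "AUTOSOMES",
    l_mode: str = "MARKER_SPAN",
    fixed_lengths: Mapping[str, int] | None = None,
    samples: Sequence[str] | None = None,
    sex: pd.Series | None = None,
    pseudoautosomal: tuple[int, int] | None = None,
) -> pd.DataFrame:
    """Per-sample F_ROH over one scope from one caller's tracts.

    Parameters
    ----------
    tracts
        Tract table from a single caller/parameter set (mixing callers is
        a hard error: their tracts are not comparable).
    samples
        Samples to report; defaults to those present in ``tracts``.
        Samples without tracts get F_ROH = 0.
    sex
        Sample -> "F"/"M"/"U"; required to exclude males from CHR_X scope.
        Without it the whole panel is used with a logged caveat.
    pseudoautosomal
        Optional (start, end) bp interval excluded from the CHR_X scope;
        without it the whole X is used with a logged caveat.

    Returns a DataFrame with columns
    ``sample, scope, froh, roh_bp, L_bp, l_mode``.
    """
    if l_mode not in L_MODES:
        raise ValueError(f"unknown l_mode {l_mode!r}; expected one of {L_MODES}")
    if not tracts.empty and tracts["caller"].nunique() > 1:
        raise ValueError(
            "tracts from multiple callers supplied; F_ROH must be computed "
            "per caller"
        )
    chroms = _scope_chromosomes(markers, scope)
    if samples is None:
        samples = sorted(tracts["sample"].unique()) if not tracts.empty else []
    samples = list(samples)
    if scope == "CHR_X":
        if sex is not None:
            males = [s for s in samples if sex.get(s) == "M"]
            if males:
                logger.info("excluding %d male samples from CHR_X F_ROH", len(males))
            samples = [s for s in samples if sex.get(s) != "M"]
        else:
            logger.warning("no sex information supplied; CHR_X F_ROH includes all samples")

    # denominator
    if l_mode == "MARKER_SPAN":
        L = sum(markers.chrom_span(c) for c in chroms)
    else:
        if fixed_lengths is None:
            raise ValueError("l_mode FIXED requires fixed_lengths")
        L = sum(int(fixed_lengths[c]) for c in chroms)
    par_lo = par_hi = None
    if scope == "CHR_X":
        if pseudoautosomal is not None:
            par_lo, par_hi = pseudoautosomal
            L -= max(0, par_hi - par_lo + 1)
        else:
            logger.warning("no pseudoautosomal interval supplied; whole X used")

    in_scope = (
        tracts[tracts["chrom"].isin(chroms) & tracts["sample"].isin(samples)]
        if not tracts.empty
        else tracts
    )
    sums = {s: 0 for s in samples}
    for _, row in in_scope.iterrows():
        start, end = int(row["start"]), int(row["end"])
        if par_lo is not None:
            # clip out the pseudoautosomal interval
            if start >= par_lo and end <= par_hi:
                continue
            overlap = max(0, min(end, par_hi) - max(start, par_lo) + 1)
            sums[row["sample"]] += (end - start + 1) - overlap
        else:
            sums[row["sample"]] += end - start + 1

    out = pd.DataFrame(
        {
            "sample": samples,
            "scope": scope,
            "froh": [sums[s] / L if L else np.nan for s in samples],
            "roh_bp": [sums[s] for s in samples],
            "L_bp": L,
            "l_mode": l_mode,
        }
    )
    bad = out["froh"].dropna()
    if ((bad < 0) | (bad > 1)).any():
        raise ValueError("F_ROH outside [0, 1]: tracts exceed the declared genome length")
    return out


def froh_by_group(
    results: pd.DataFrame,
    metadata: pd.DataFrame | None = None,
    quantiles: Sequence[float] = (0.25, 0.5, 0.75),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Summarize F_ROH by breed.

    ``metadata`` is indexed by sample with a ``breed`` column; samples
    without a breed (or with no metadata at all) fall in an "unknown"
    group.  Returns ``(summary, per_sample)`` where ``summary`` has one
    row per breed (n, mean, one column per requested quantile) and
    ``per_sample`` is ``results`` with the breed attached.
    """
    per_sample = results.copy()
    if metadata is not None and "breed" in metadata.columns:
        breed = per_sample["sample"].map(metadata["breed"])
    else:
        breed = pd.Series([None] * len(per_sample), index=per_sample.index)
    per_sample["breed"] = breed.fillna("unknown").replace({None: "unknown"})

    rows = []
    for name, grp in per_sample.groupby("breed"):
        if len(grp) == 0:
            logger.warning("skipping empty breed group %r", name)
            continue
        row = {"breed": name, "n": len(grp), "mean": grp["froh"].mean()}
        for q in quantiles:
            row[f"q{int(q * 100)}"] = grp["froh"].quantile(q)
        rows.append(row)
    summary = pd.DataFrame(rows).sort_values("mean", ascending=False).reset_index(drop=True)
    return summary, per_sample
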