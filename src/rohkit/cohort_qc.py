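"""Cohort construction: LD pruning and relatedness (PI_HAT) filtering.

LD pruning follows the PLINK ``--indep-pairwise`` scheme: within sliding
windows of SNPs, while any retained pair exceeds the r-squared ceiling,
one member is removed; windows advance by a step.  r-squared is computed
on genotype dosages (0/1/2 allele counts), which matches the unphased
PLINK semantics.  The removal tie-break — drop the marker with lower
minor-allele frequency, then the later map position — is a documented
deterministic choice.

Relatedness uses the method-of-moments IBD estimator of Purcell et al.
(2007, PLINK): observed identity-by-state (IBS) class counts over
non-missing markers are equated with their expectations under IBD state
0/1/2 given panel allele frequencies, solved sequentially for
P(IBD=0), P(IBD=1), P(IBD=2) (clamped to [0,1] and renormalized), and
summarized as PI_HAT = P(IBD=2) + 0.5 * P(IBD=1).  Pairs with PI_HAT
above a threshold (0.45 flags parent-offspring / full siblings) are used
to drop dogs greedily by over-threshold degree.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypePanel

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# LD pruning
# ---------------------------------------------------------------------------


def _dosage(calls: np.ndarray) -> np.ndarray:
    """Genotype dosage with NaN for missing (call codes are 0/1/2/-1)."""
    d = calls.astype(float)
    d[calls == MISSING] = np.nan
    return d


def _pairwise_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared dosage correlation over pairwise-complete samples.

    Monomorphic markers have undefined correlation; their r2 is treated
    as 0 so they are never removed for LD.
    """
    ok = ~np.isnan(x) & ~np.isnan(y)
    if ok.sum() < 2:
        return 0.0
    xv, yv = x[ok], y[ok]
    sx, sy = xv.std(), yv.std()
    if sx == 0 or sy == 0:
        return 0.0
    r = np.corrcoef(xv, yv)[0, 1]
    return float(r * r)


def _maf(x: np.ndarray) -> float:
    ok = ~np.isnan(x)
    if not ok.any():
        return 0.0
    p = x[ok].mean() / 2.0
    return min(p, 1.0 - p)


def ld_prune(
    panel: GenotypePanel,
    window_snps: int = 200,
    step_snps: int = 100,
    r2_max: float = 0.90,
) -> list[str]:
    """Retained marker ids after windowed pairwise LD pruning.

    Within each window, while any retained pair has dosage r2 strictly
    greater than ``r2_max``, the pair member with the lower minor-allele
    frequency (tie: later map position) is removed.  Windows advance by
    ``step_snps`` along each chromosome.
    """
    mm = panel.markers
    dos = _dosage(panel.calls)
    removed: set[int] = set()
    for chrom in mm.chromosomes():
        sl = mm.chrom_slice(chrom)
        idx = list(range(sl.start, sl.stop))
        if len(idx) < 2:
            continue
        start = 0
        while start < len(idx):
            window = idx[start : start + window_snps]
            live = [i for i in window if i not in removed]
            changed = True
            while changed:
                changed = False
                for a, b in combinations(live, 2):
                    if _pairwise_r2(dos[:, a], dos[:, b]) > r2_max:
                        fa, fb = _maf(dos[:, a]), _maf(dos[:, b])
                        if fa < fb:
                            drop = a
                        elif fb < fa:
                            drop = b
                        else:
                            drop = max(a, b)  # tie: later map position
                        removed.add(drop)
                        live.remove(drop)
                        changed = True
                        break
            start += step_snps
    ids = mm.table["marker_id"].to_numpy()
    return [ids[i] for i in range(mm.n_markers) if i not in removed]


# ---------------------------------------------------------------------------
# Method-of-moments relatedness
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PairwiseRelatedness:
    sample1: str
    sample2: str
    ibs0: int
    ibs1: int
    ibs2: int
    p_ibd0: float
    p_ibd1: float
    p_ibd2: float
    pi_hat: float
    low_confidence: bool  # fewer than 100 informative markers


def allele_frequencies(panel: GenotypePanel) -> np.ndarray:
    """Frequency of allele B per marker from non-missing calls."""
    d = _dosage(panel.calls)
    with np.errstate(invalid="ignore"):
        return np.nanmean(d, axis=0) / 2.0


def pi_hat(
    panel: GenotypePanel,
    pair: tuple[str, str],
    freqs: np.ndarray | None = None,
) -> PairwiseRelatedness:
    """Method-of-moments IBD estimate for one sample pair."""
    if freqs is None:
        freqs = allele_frequencies(panel)
    i = panel.sample_index(pair[0])
    j = panel.sample_index(pair[1])
    d1 = _dosage(panel.calls[i])
    d2 = _dosage(panel.calls[j])
    p = np.asarray(freqs, dtype=float)
    ok = ~np.isnan(d1) & ~np.isnan(d2) & (p > 0) & (p < 1)
    n_inf = int(ok.sum())
    low_confidence = n_inf < 100
    if low_confidence:
        logger.warning(
            "pair (%s, %s): only %d informative markers; estimate is low-confidence",
            pair[0],
            pair[1],
            n_inf,
        )
    d1, d2, p = d1[ok], d2[ok], p[ok]
    q = 1.0 - p
    ibs = 2 - np.abs(d1 - d2).astype(int)
    n0 = int((ibs == 0).sum())
    n1 = int((ibs == 1).sum())
    n2 = int((ibs == 2).sum())

    # expected IBS-class probabilities under each IBD state
    e0_ibd0 = (2 * p**2 * q**2).sum()
    e1_ibd0 = (4 * p**3 * q + 4 * p * q**3).sum()
    e2_ibd0 = (p**4 + q**4 + 4 * p**2 * q**2).sum()
    e1_ibd1 = (2 * p**2 * q + 2 * p * q**2).sum()
    e2_ibd1 = (p**3 + q**3 + p**2 * q + p * q**2).sum()
    m = float(len(p))

    p0 = n0 / e0_ibd0 if e0_ibd0 > 0 else 0.0
    p1 = (n1 - p0 * e1_ibd0) / e1_ibd1 if e1_ibd1 > 0 else 0.0
    p2 = (n2 - p0 * e2_ibd0 - p1 * e2_ibd1) / m if m > 0 else 0.0
    probs = np.clip([p0, p1, p2], 0.0, 1.0)
    total = probs.sum()
    probs = probs / total if total > 0 else np.array([1.0, 0.0, 0.0])
    pi = float(probs[2] + 0.5 * probs[1])
    return PairwiseRelatedness(
        pair[0], pair[1], n0, n1, n2, *map(float, probs), pi, low_confidence
    )


def pairwise_pi_hat(panel: GenotypePanel, within_breed: bool = False) -> pd.DataFrame:
    """PI_HAT for all sample pairs (optionally only within-breed pairs)."""
    freqs = allele_frequencies(panel)
    rows = []
    for s1, s2 in combinations(panel.samples, 2):
        if within_breed and panel.breed(s1) != panel.breed(s2):
            continue
        r = pi_hat(panel, (s1, s2), freqs)
        rows.append(
            {
                "sample1": s1,
                "sample2": s2,
                "ibs0": r.ibs0,
                "ibs1": r.ibs1,
                "ibs2": r.ibs2,
                "pi_hat": r.pi_hat,
                "low_confidence": r.low_confidence,
            }
        )
    return pd.DataFrame(
        rows, columns=["sample1", "sample2", "ibs0", "ibs1", "ibs2", "pi_hat", "low_confidence"]
    )


def drop_close_relatives(
    panel: GenotypePanel,
    threshold: float = 0.45,
    pairs: pd.DataFrame | None = None,
) -> tuple[GenotypePanel, list[str]]:
    """Remove dogs until no within-breed pair has PI_HAT above threshold.

    Greedy rule: repeatedly drop the sample participating in the most
    over-threshold pairs (ties broken by lexicographic sample id).
    Returns the reduced panel and the removal log.
    """
    if pairs is None:
        pairs = pairwise_pi_hat(panel, within_breed=True)
    over = pairs[pairs["pi_hat"] > threshold][["sample1", "sample2"]]
    edges = {frozenset((a, b)) for a, b in over.itertuples(index=False)}
    removed: list[str] = []
    while edges:
        degree: dict[str, int] = {}
        for e in edges:
            for s in e:
                degree[s] = degree.get(s, 0) + 1
        # max degree, ties -> lexicographically smallest id
        worst = min(degree, key=lambda s: (-degree[s], s))
        removed.append(worst)
        edges = {e for e in edges if worst not in e}
    keep = [s for s in panel.samples if s not in removed]
    logger.info("drop_close_relatives removed %d samples: %s", len(removed), removed)
    return panel.subset_samples(keep), removed
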