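"""Synthetic inbred genotype panels with known autozygosity truth.

The generator emulates the data regime of a dense canine SNP array study:
~170k autosomal markers (one per ~12.8 kb) plus a chrX map, diploid
genotypes, autozygous tracts created by consanguineous pedigree loops of
configurable depth, recessive disease alleles planted on a single founder
haplotype background, genotyping error and missingness.

Model
-----
* Founder haplotypes are drawn marker-by-marker from per-marker allele
  frequencies ``p ~ Beta(a, b)``; an optional first-order Markov copy
  probability between adjacent markers stands in for LD.
* Meiosis places ``Poisson(length_cM / 100)`` crossovers uniformly in
  genetic distance; a constant cM/Mb rate makes this uniform in bp.
  No crossover interference.
* Every transmitted chromosome is a mosaic of founder haplotypes tracked
  as exact bp breakpoints, so truth autozygosity (both homologs descending
  from the same founder haplotype copy) is recorded exactly, before any
  error is applied.
* The error model flips HOM<->HET calls at rate ``error_rate`` and then
  masks calls at rate ``missing_rate``; truth segments are unaffected.

Pedigree loops: depth 0 is a full-sib mating (offspring F = 1/4), depth 1
first cousins (F = 1/16), depth ``d`` gives F = (1/4)^(d+1).  "unrelated"
produces outbred offspring with no autozygosity.

Chromosome X is transmitted like an autosome through the loop (a
simplification; male intermediates are not forced hemizygous) but final
male offspring receive a single maternal X reported as homozygous calls,
and no X truth segments are emitted for males.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .genotype_io import HET, HOM_A, HOM_B, MISSING, GenotypePanel, MarkerMap

logger = logging.getLogger(__name__)

__all__ = [
    "SimConfig",
    "HaplotypePool",
    "simulate_founders",
    "plant_disease_allele",
    "plant_neutral_allele",
    "simulate_pedigree",
    "at_risk_records",
    "autozygous_fraction",
    "truth_restricted_fraction",
    "base_precision",
    "truth_tract_lengths",
]


@dataclass
class SimConfig:
    """Parameters of one synthetic cohort.

    Defaults emulate the study regime: 38 autosomes of 58 Mb at one marker
    per 12.8 kb (~172k markers) plus a 124 Mb X at one per 28.2 kb, full-sib
    offspring, genotyping error 1e-4 (concordance > 99.99%) and missingness
    1e-3 (< 0.1%).  Tests and examples scale ``n_autosomes`` /
    ``autosome_length`` / ``marker_spacing`` down explicitly.
    """

    seed: int
    n_autosomes: int = 38
    autosome_length: int = 58_000_000
    marker_spacing: int = 12_800          # bp between autosomal markers
    x_length: int | None = 124_000_000    # None -> no X chromosome
    x_marker_spacing: int = 28_200
    n_founder_haplotypes: int | None = None  # None -> auto-sized per pedigree
    beta_a: float = 1.0
    beta_b: float = 1.0
    markov_r: float = 0.0                 # adjacent-marker copy probability (LD stand-in)
    recomb_rate_cm_per_mb: float = 1.0
    pedigree: str = "full_sib"            # "full_sib" | "first_cousin" | "cousin:<k>" | "unrelated"
    pedigree_mixture: dict[int, float] | None = None  # loop depth -> weight
    n_offspring: int = 100
    error_rate: float = 1e-4
    missing_rate: float = 1e-3
    breed_label: str | None = None
    male_fraction: float = 0.5

    def __post_init__(self) -> None:
        for name in ("error_rate", "missing_rate", "markov_r", "male_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.pedigree_mixture is not None:
            if not self.pedigree_mixture or any(w < 0 for w in self.pedigree_mixture.values()):
                raise ValueError("pedigree_mixture weights must be non-negative and non-empty")

    # -- derived geometry --------------------------------------------------
    def chromosomes(self) -> list[tuple[str, int, int]]:
        """(label, length bp, marker spacing bp) for every chromosome."""
        out = [
            (str(i + 1), self.autosome_length, self.marker_spacing)
            for i in range(self.n_autosomes)
        ]
        if self.x_length is not None:
            out.append(("X", self.x_length, self.x_marker_spacing))
        return out

    def marker_map(self) -> MarkerMap:
        chroms, ids, poss = [], [], []
        for label, length, spacing in self.chromosomes():
            n = max(2, length // spacing)
            pos = np.round((np.arange(n) + 0.5) * length / n).astype(np.int64)
            pos = np.maximum.accumulate(np.maximum(pos, 1))  # strictly positive
            chroms.extend([label] * n)
            ids.extend(f"chr{label}_m{j}" for j in range(n))
            poss.extend(pos.tolist())
        allowed = {label for label, _, _ in self.chromosomes()}
        return MarkerMap.from_arrays(chroms, ids, poss, allowed_chromosomes=allowed)


def _loop_depth(template: str) -> int | None:
    """Map a pedigree template name to loop depth; None means unrelated."""
    if template == "unrelated":
        return None
    if template == "full_sib":
        return 0
    if template == "first_cousin":
        return 1
    if template.startswith("cousin:"):
        d = int(template.split(":", 1)[1])
        if d < 0:
            raise ValueError("cousin depth must be >= 0")
        return d
    raise ValueError(f"unknown pedigree template {template!r}")


def _haps_needed(depth: int | None) -> int:
    """Founder haplotypes consumed by one pedigree instance."""
    if depth is None:
        return 4  # two unrelated parents
    return 4 + 4 * depth  # ancestor couple + one outcross mate per line per generation


# ---------------------------------------------------------------------------
# Founder haplotype pool
# ---------------------------------------------------------------------------


@dataclass
class HaplotypePool:
    """Phased founder haplotypes over a marker map.

    ``alleles``: (n_haps, n_markers) int8 in {0, 1}.  ``hap_ids`` gives the
    lineage identity of each row; rows created as background copies of a
    disease-origin haplotype keep their own id but carry an ``id_override``
    (chrom, start bp, end bp, origin id) marking the copied window as the
    origin lineage for truth purposes.
    """

    markers: MarkerMap
    alleles: np.ndarray
    hap_ids: np.ndarray
    freqs: np.ndarray
    id_overrides: dict[int, list[tuple[str, int, int, int]]] = field(default_factory=dict)
    planted: dict[int, dict] = field(default_factory=dict)  # marker index -> plant info

    @property
    def n_haps(self) -> int:
        return self.alleles.shape[0]

    def lineage_id(self, row: int, chrom: str, lo: int, hi: int) -> int:
        """Lineage id of pool row over the bp interval (lo, hi]."""
        for oc, os_, oe, oid in self.id_overrides.get(row, ()):
            if oc == chrom and lo >= os_ - 1 and hi <= oe:
                return oid
        return int(self.hap_ids[row])

    def override_cuts(self, row: int, chrom: str) -> list[int]:
        cuts = []
        for oc, os_, oe, _ in self.id_overrides.get(row, ()):
            if oc == chrom:
                cuts.extend((os_ - 1, oe))
        return cuts


def simulate_founders(config: SimConfig, n_haplotypes: int | None = None) -> HaplotypePool:
    """Draw a pool of phased founder haplotypes.

    Per-marker allele frequencies are Beta(a, b); with ``markov_r > 0``
    each allele copies its left neighbour with that probability (a crude
    LD stand-in), otherwise it is drawn fresh from the marker frequency.
    """
    rng = np.random.default_rng(config.seed)
    mm = config.marker_map()
    m = mm.n_markers
    if n_haplotypes is None:
        n_haplotypes = config.n_founder_haplotypes
    if n_haplotypes is None:
        depths = _draw_depths(config, np.random.default_rng(config.seed + 1))
        n_haplotypes = int(sum(_haps_needed(d) for d in depths))
    freqs = rng.beta(config.beta_a, config.beta_b, size=m)
    alleles = np.empty((n_haplotypes, m), dtype=np.int8)
    r = config.markov_r
    if r == 0.0:
        # chunk per chromosome to bound temporary memory
        for label, *_ in config.chromosomes():
            sl = mm.chrom_slice(label)
            alleles[:, sl] = rng.random((n_haplotypes, sl.stop - sl.start)) < freqs[sl]
    else:
        for label, *_ in config.chromosomes():
            sl = mm.chrom_slice(label)
            u = rng.random((n_haplotypes, sl.stop - sl.start))
            copy = rng.random((n_haplotypes, sl.stop - sl.start)) < r
            block = np.empty_like(u, dtype=np.int8)
            block[:, 0] = u[:, 0] < freqs[sl.start]
            for j in range(1, block.shape[1]):
                fresh = u[:, j] < freqs[sl.start + j]
                block[:, j] = np.where(copy[:, j], block[:, j - 1], fresh)
            alleles[:, sl] = block
    return HaplotypePool(
        markers=mm,
        alleles=alleles,
        hap_ids=np.arange(n_haplotypes, dtype=np.int64),
        freqs=freqs,
    )


def plant_disease_allele(
    pool: HaplotypePool,
    locus: tuple[str, int] | int,
    carrier_freq: float,
    seed: int,
    background_bp: int = 3_000_000,
) -> HaplotypePool:
    """Plant a recessive risk allele on a single founder haplotype lineage.

    The locus must coincide with a marker.  One pool haplotype becomes the
    origin: it carries the risk allele (coded 1) while every other
    haplotype carries 0.  Additional carriers, chosen to reach
    ``carrier_freq`` of the pool, are made literal copies of the origin
    over a ``background_bp`` window either side of the locus — the shared
    haplotype background a single ancestral mutation rides on — and the
    copied window is tagged with the origin lineage id so truth
    autozygosity treats it as one ancestral copy.

    A second origin at the same locus is rejected: each disease variant
    descends from a single mutation.
    """
    rng = np.random.default_rng(seed)
    mm = pool.markers
    if isinstance(locus, int):
        midx = locus
    else:
        chrom, pos = str(locus[0]), int(locus[1])
        sl = mm.chrom_slice(chrom)
        pos_arr = mm.table["pos"].to_numpy()[sl]
        hit = np.flatnonzero(pos_arr == pos)
        if hit.size == 0:
            raise ValueError(f"locus {chrom}:{pos} is not on the marker grid")
        midx = sl.start + int(hit[0])
    if midx in pool.planted:
        raise ValueError(
            "a second founder-haplotype origin was requested for an already "
            "planted locus; disease variants have a single origin"
        )
    if not 0.0 <= carrier_freq <= 1.0:
        raise ValueError("carrier_freq must be in [0, 1]")
    n_carriers = int(round(carrier_freq * pool.n_haps))
    if carrier_freq > 0 and n_carriers == 0:
        raise ValueError(
            f"carrier_freq {carrier_freq} rounds to zero carriers in a pool of "
            f"{pool.n_haps} haplotypes"
        )

    chrom = str(mm.table["chrom"].iat[midx])
    pos = int(mm.table["pos"].iat[midx])
    pool.alleles[:, midx] = 0
    carrier_rows: list[int] = []
    if n_carriers > 0:
        rows = rng.choice(pool.n_haps, size=n_carriers, replace=False)
        origin_row = int(rows[0])
        origin_id = int(pool.hap_ids[origin_row])
        sl = mm.chrom_slice(chrom)
        pos_arr = mm.table["pos"].to_numpy()[sl]
        w_lo, w_hi = max(1, pos - background_bp), pos + background_bp
        i0 = sl.start + int(np.searchsorted(pos_arr, w_lo, side="left"))
        i1 = sl.start + int(np.searchsorted(pos_arr, w_hi, side="right"))
        pool.alleles[origin_row, midx] = 1
        for r in rows[1:]:
            r = int(r)
            pool.alleles[r, i0:i1] = pool.alleles[origin_row, i0:i1]
            pool.id_overrides.setdefault(r, []).append((chrom, w_lo, w_hi, origin_id))
        carrier_rows = [int(r) for r in rows]
    pool.planted[midx] = {
        "chrom": chrom,
        "pos": pos,
        "carrier_rows": carrier_rows,
        "origin_row": carrier_rows[0] if carrier_rows else None,
        "risk_allele": 1,
    }
    return pool


def plant_neutral_allele(
    pool: HaplotypePool,
    locus: tuple[str, int] | int,
    carrier_freq: float,
    seed: int,
) -> int:
    """Plant a control allele with many independent origins (no shared background).

    Carrier haplotypes are chosen independently at ``carrier_freq``; no
    background is copied and no lineage ids are shared, so homozygotes at
    the locus arise by chance pairing of unrelated carriers rather than
    descent from a single mutation.  Used as the negative control for the
    disease-enrichment resampling test.  Returns the marker index.
    """
    rng = np.random.default_rng(seed)
    mm = pool.markers
    if isinstance(locus, int):
        midx = locus
    else:
        chrom, pos = str(locus[0]), int(locus[1])
        sl = mm.chrom_slice(chrom)
        pos_arr = mm.table["pos"].to_numpy()[sl]
        hit = np.flatnonzero(pos_arr == pos)
        if hit.size == 0:
            raise ValueError(f"locus {chrom}:{pos} is not on the marker grid")
        midx = sl.start + int(hit[0])
    pool.alleles[:, midx] = rng.random(pool.n_haps) < carrier_freq
    return midx


# ---------------------------------------------------------------------------
# Meiosis on breakpoint mosaics
# ---------------------------------------------------------------------------
# A transmitted chromosome is a list of (end_bp, pool_row) segments; segment k
# covers (end_{k-1}, end_k] with an implicit start at 0, last end = chrom
# length.  All positions are exact bp, so truth segments are exact.

Hap = dict[str, list[tuple[int, int]]]  # chrom -> [(end_bp, pool_row), ...]


def _slice_segments(segs: list[tuple[int, int]], lo: int, hi: int) -> list[tuple[int, int]]:
    out = []
    prev = 0
    for end, row in segs:
        if end > lo and prev < hi:
            out.append((min(end, hi), row))
        prev = end
        if prev >= hi:
            break
    return out


def _coalesce(segs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    out: list[tuple[int, int]] = []
    for end, row in segs:
        if out and out[-1][1] == row:
            out[-1] = (end, row)
        else:
            out.append((end, row))
    return out


def _meiosis(hap0: Hap, hap1: Hap, geometry, rate_cm_per_mb: float, rng) -> Hap:
    gamete: Hap = {}
    for chrom, length, _ in geometry:
        lam = length / 1e6 * rate_cm_per_mb / 100.0
        n_x = rng.poisson(lam)
        cuts = np.sort(rng.integers(1, length, size=n_x)).tolist() if n_x else []
        cur = int(rng.integers(0, 2))
        out: list[tuple[int, int]] = []
        lo = 0
        for c in cuts + [length]:
            if c > lo:
                src = hap0[chrom] if cur == 0 else hap1[chrom]
                out.extend(_slice_segments(src, lo, c))
                lo = c
            cur ^= 1
        gamete[chrom] = _coalesce(out)
    return gamete


def _founder_hap(row: int, geometry) -> Hap:
    return {chrom: [(length, row)] for chrom, length, _ in geometry}


def _draw_depths(config: SimConfig, rng) -> list[int | None]:
    if config.pedigree_mixture is not None:
        depths = sorted(config.pedigree_mixture)
        w = np.array([config.pedigree_mixture[d] for d in depths], dtype=float)
        w = w / w.sum()
        return [int(d) for d in rng.choice(depths, size=config.n_offspring, p=w)]
    return [_loop_depth(config.pedigree)] * config.n_offspring


def _simulate_one(
    depth: int | None, rows: Sequence[int], geometry, rate: float, rng
) -> tuple[Hap, Hap]:
    """Run one pedigree loop; returns the offspring's (maternal, paternal) gametes."""
    rows = list(rows)

    def take() -> tuple[Hap, Hap]:
        a, b = rows.pop(), rows.pop()
        return _founder_hap(a, geometry), _founder_hap(b, geometry)

    if depth is None:
        mother, father = take(), take()
        return (
            _meiosis(*mother, geometry, rate, rng),
            _meiosis(*father, geometry, rate, rng),
        )
    anc1, anc2 = take(), take()
    lines = []
    for _ in range(2):
        person = (
            _meiosis(*anc1, geometry, rate, rng),
            _meiosis(*anc2, geometry, rate, rng),
        )
        for _ in range(depth):
            mate = take()
            person = (
                _meiosis(*person, geometry, rate, rng),
                _meiosis(*mate, geometry, rate, rng),
            )
        lines.append(person)
    return (
        _meiosis(*lines[0], geometry, rate, rng),
        _meiosis(*lines[1], geometry, rate, rng),
    )


def _truth_segments(
    pool: HaplotypePool, gam_m: Hap, gam_p: Hap, geometry
) -> list[tuple[str, int, int, bool, int]]:
    """Tile each chromosome with (chrom, start, end, autozygous, founder) segments."""
    out = []
    for chrom, length, _ in geometry:
        cuts = {length}
        for segs in (gam_m[chrom], gam_p[chrom]):
            for end, row in segs:
                cuts.add(end)
                cuts.update(
                    c for c in pool.override_cuts(row, chrom) if 0 < c < length
                )
        prev = 0
        raw = []
        for c in sorted(cuts):
            row_m = next(r for e, r in gam_m[chrom] if e >= c)
            row_p = next(r for e, r in gam_p[chrom] if e >= c)
            id_m = pool.lineage_id(row_m, chrom, prev, c)
            id_p = pool.lineage_id(row_p, chrom, prev, c)
            auto = id_m == id_p
            raw.append((prev + 1, c, auto, id_m if auto else -1))
            prev = c
        # merge adjacent segments with identical truth state
        merged = [raw[0]]
        for s, e, a, f in raw[1:]:
            ls, le, la, lf = merged[-1]
            if a == la and f == lf:
                merged[-1] = (ls, e, a, f)
            else:
                merged.append((s, e, a, f))
        out.extend((chrom, s, e, a, f) for s, e, a, f in merged)
    return out


def _realize_alleles(pool: HaplotypePool, gam: Hap, geometry) -> np.ndarray:
    mm = pool.markers
    out = np.empty(mm.n_markers, dtype=np.int8)
    for chrom, _, _ in geometry:
        sl = mm.chrom_slice(chrom)
        pos = mm.table["pos"].to_numpy()[sl]
        prev = 0
        for end, row in gam[chrom]:
            i0 = int(np.searchsorted(pos, prev, side="right"))
            i1 = int(np.searchsorted(pos, end, side="right"))
            out[sl.start + i0 : sl.start + i1] = pool.alleles[row, sl.start + i0 : sl.start + i1]
            prev = end
    return out


def simulate_pedigree(
    config: SimConfig, pool: HaplotypePool
) -> tuple[GenotypePanel, pd.DataFrame]:
    """Simulate offspring of the configured pedigree loops from a founder pool.

    Returns the genotype panel (error model applied) and the truth table
    with columns ``sample, chrom, start, end, autozygous, founder`` whose
    segments tile every chromosome per sample (male X omitted).  Truth is
    recorded before genotyping error, so it is error-free.
    """
    rng = np.random.default_rng(config.seed + 1)
    geometry = config.chromosomes()
    mm = pool.markers
    depths = _draw_depths(config, rng)
    needs = [_haps_needed(d) for d in depths]
    total_need = sum(needs)

    sequential = pool.n_haps >= total_need
    if not sequential:
        logger.info(
            "founder pool (%d haplotypes) smaller than %d needed; founders will be reused",
            pool.n_haps,
            total_need,
        )
    next_row = 0
    samples, sexes = [], []
    calls = np.empty((config.n_offspring, mm.n_markers), dtype=np.int8)
    truth_rows = []
    x_sl = mm.chrom_slice("X") if config.x_length is not None else slice(0, 0)

    for i, (depth, need) in enumerate(zip(depths, needs)):
        if sequential:
            rows = list(range(next_row, next_row + need))
            next_row += need
        elif pool.n_haps >= need:
            rows = [int(r) for r in rng.choice(pool.n_haps, size=need, replace=False)]
        else:
            rows = [int(r) for r in rng.integers(0, pool.n_haps, size=need)]
        gam_m, gam_p = _simulate_one(depth, rows, geometry, config.recomb_rate_cm_per_mb, rng)
        sample = f"S{i:04d}"
        sex = "M" if rng.random() < config.male_fraction else "F"
        a_m = _realize_alleles(pool, gam_m, geometry)
        a_p = _realize_alleles(pool, gam_p, geometry)
        g = (a_m + a_p).astype(np.int8)  # 0/1/2 maps onto HOM_A/HET/HOM_B
        if sex == "M" and x_sl.stop > x_sl.start:
            g[x_sl] = (2 * a_m[x_sl]).astype(np.int8)  # hemizygous maternal X
        calls[i] = g
        samples.append(sample)
        sexes.append(sex)
        for chrom, s, e, auto, founder in _truth_segments(pool, gam_m, gam_p, geometry):
            if chrom == "X" and sex == "M":
                continue
            truth_rows.append(
                {
                    "sample": sample,
                    "chrom": chrom,
                    "start": s,
                    "end": e,
                    "autozygous": auto,
                    "founder": founder,
                }
            )

    # error model, applied after truth recording
    if config.error_rate > 0:
        flip = rng.random(calls.shape) < config.error_rate
        hom = (calls == HOM_A) | (calls == HOM_B)
        to_hom = rng.integers(0, 2, size=calls.shape).astype(np.int8) * 2
        calls = np.where(flip & hom, HET, np.where(flip & (calls == HET), to_hom, calls))
        calls = calls.astype(np.int8)
    if config.missing_rate > 0:
        calls[rng.random(calls.shape) < config.missing_rate] = MISSING

    metadata = pd.DataFrame(
        {"breed": [config.breed_label] * len(samples), "sex": sexes},
        index=pd.Index(samples, name="sample"),
    )
    panel = GenotypePanel(mm, samples, calls, metadata)
    truth = pd.DataFrame(
        truth_rows, columns=["sample", "chrom", "start", "end", "autozygous", "founder"]
    )
    return panel, truth


def at_risk_records(panel: GenotypePanel, pool: HaplotypePool) -> pd.DataFrame:
    """At-risk genotypes at planted loci: samples homozygous for the risk allele.

    Returns columns ``sample, locus_id, chrom, pos`` based on the panel's
    (possibly error-perturbed) calls; the risk allele is coded 1, so an
    at-risk call is HOM_B.
    """
    rows = []
    for midx, info in sorted(pool.planted.items()):
        lid = f"locus_{info['chrom']}_{info['pos']}"
        hit = np.flatnonzero(panel.calls[:, midx] == HOM_B)
        for i in hit:
            rows.append(
                {
                    "sample": panel.samples[int(i)],
                    "locus_id": lid,
                    "chrom": info["chrom"],
                    "pos": info["pos"],
                }
            )
    return pd.DataFrame(rows, columns=["sample", "locus_id", "chrom", "pos"])


# ---------------------------------------------------------------------------
# Truth-based evaluation helpers
# ---------------------------------------------------------------------------


def truth_tract_lengths(truth: pd.DataFrame) -> np.ndarray:
    """Lengths (bp) of all autozygous truth segments."""
    t = truth[truth["autozygous"]]
    return (t["end"] - t["start"] + 1).to_numpy()


def autozygous_fraction(
    truth: pd.DataFrame, chromosomes: Sequence[str] | None = None
) -> pd.Series:
    """Per-sample fraction of the tiled genome that is truth-autozygous."""
    t = truth if chromosomes is None else truth[truth["chrom"].isin(chromosomes)]
    lengths = t["end"] - t["start"] + 1
    total = lengths.groupby(t["sample"]).sum()
    auto = lengths.where(t["autozygous"], 0).groupby(t["sample"]).sum()
    return (auto / total).rename("autozygous_fraction")


def truth_restricted_fraction(
    truth: pd.DataFrame,
    min_length: int,
    chromosomes: Sequence[str] | None = None,
) -> pd.Series:
    """Per-sample autozygous fraction counting only segments >= ``min_length``.

    This is the detectable-truth target an ROH caller with a minimum tract
    length can at best recover.
    """
    t = truth if chromosomes is None else truth[truth["chrom"].isin(chromosomes)]
    lengths = t["end"] - t["start"] + 1
    total = lengths.groupby(t["sample"]).sum()
    keep = t["autozygous"] & (lengths >= min_length)
    auto = lengths.where(keep, 0).groupby(t["sample"]).sum()
    return (auto / total).rename("truth_restricted_fraction")


def _interval_overlap(
    a: np.ndarray, b: np.ndarray
) -> int:
    """Total overlap (bp) between two sets of disjoint sorted [start, end] intervals."""
    total = 0
    j = 0
    for s, e in a:
        while j < len(b) and b[j][1] < s:
            j += 1
        k = j
        while k < len(b) and b[k][0] <= e:
            total += min(e, b[k][1]) - max(s, b[k][0]) + 1
            k += 1
    return total


def base_precision(
    tracts: pd.DataFrame, truth: pd.DataFrame, min_tract_length: int = 0
) -> float:
    """Fraction of called ROH bases lying inside truth autozygous segments.

    Only called tracts with length >= ``min_tract_length`` contribute.
    """
    called = 0
    hit = 0
    t = tracts[(tracts["end"] - tracts["start"] + 1) >= min_tract_length]
    truth_auto = truth[truth["autozygous"]]
    for (sample, chrom), grp in t.groupby(["sample", "chrom"]):
        a = grp.sort_values("start")[["start", "end"]].to_numpy()
        tb = truth_auto[(truth_auto["sample"] == sample) & (truth_auto["chrom"] == chrom)]
        b = tb.sort_values("start")[["start", "end"]].to_numpy()
        called += int((a[:, 1] - a[:, 0] + 1).sum())
        hit += _interval_overlap(a, b)
    return hit / called if called else float("nan")
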