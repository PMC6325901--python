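"""End-to-end validation experiments on synthetic cohorts.

Two canned experiments exercise the whole pipeline against known truth:

``fullsib_recovery``
    A full-sib cohort (truth inbreeding F = 1/4) at array-like marker
    density; measures how well mean F_ROH from called tracts recovers the
    truth-restricted autozygous fraction (truth segments long enough to be
    detectable), and the base-level precision of called tracts against
    truth autozygosity.

``enrichment_control``
    A mixed-depth cohort (full-sib / first-cousin / second-cousin loops)
    with two planted variants on one chromosome each: a disease allele on
    a single founder haplotype background (carrier frequency 0.30,
    +/- 3 Mb shared background) and a rare neutral control allele
    (carrier frequency 0.10) with independent origins and no shared
    background.  The tracts containing disease homozygote loci should be
    a highly non-random sample of the cohort's tracts (their cumulative
    length curve exits the 1000-replicate resampling envelope), while the
    neutral locus — whose homozygotes arise by chance pairing of
    unrelated carriers — should stay inside.

Problem sizes are chosen so each experiment runs in about a minute on a
single core while leaving ample statistical resolution.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .enrichment import classify_at_risk, resample_null
from .genotype_io import HOM_B
from .inbreeding import compute_froh
from .roh_detection import ScanParams, scan_roh
from .synthetic_data import (
    SimConfig,
    at_risk_records,
    base_precision,
    plant_disease_allele,
    plant_neutral_allele,
    simulate_founders,
    simulate_pedigree,
    truth_restricted_fraction,
)


def fullsib_recovery(
    seed: int,
    n_offspring: int = 200,
    n_autosomes: int = 30,
    autosome_length: int = 64_000_000,
) -> dict:
    """Full-sib parameter recovery: mean F_ROH vs detectable truth.

    Returns mean F_ROH, the truth-restricted autozygous fraction
    (segments >= 500 kb), their absolute difference, the raw autozygous
    fraction, and called-base precision for tracts >= 2.5 Mb.
    """
    cfg = SimConfig(
        seed=seed,
        n_autosomes=n_autosomes,
        autosome_length=autosome_length,
        marker_spacing=12_800,
        x_length=None,
        n_offspring=n_offspring,
        error_rate=0.0,
        missing_rate=0.0,
        pedigree="full_sib",
    )
    pool = simulate_founders(cfg)
    panel, truth = simulate_pedigree(cfg, pool)
    params = ScanParams()
    tracts = scan_roh(panel, params)
    froh = compute_froh(tracts, panel.markers, samples=panel.samples)
    restricted = truth_restricted_fraction(truth, params.min_span)
    lengths = truth["end"] - truth["start"] + 1
    raw_auto = (
        lengths.where(truth["autozygous"], 0).sum() / lengths.sum()
    )
    return {
        "mean_froh": float(froh["froh"].mean()),
        "truth_restricted_fraction": float(restricted.mean()),
        "froh_truth_gap": float(abs(froh["froh"].mean() - restricted.mean())),
        "raw_autozygous_fraction": float(raw_auto),
        "precision_2p5mb": float(base_precision(tracts, truth, 2_500_000)),
        "n_tracts": int(len(tracts)),
        "n_offspring": n_offspring,
    }


def enrichment_control(
    seed: int,
    n_offspring: int = 300,
    n_autosomes: int = 8,
    autosome_length: int = 32_000_000,
    disease_carrier_freq: float = 0.30,
    neutral_carrier_freq: float = 0.10,
    n_reps: int = 1000,
) -> dict:
    """One seed of the disease/neutral resampling-null control experiment.

    Returns the two curve-vs-envelope outcomes plus the case and tract
    counts behind them.  ``disease_inside`` False means the disease-tract
    curve exited the envelope (the expected positive-control outcome);
    ``neutral_inside`` True is the expected negative-control outcome
    (trivially true when the rare neutral allele yields no in-tract
    homozygote).
    """
    cfg = SimConfig(
        seed=seed,
        n_autosomes=n_autosomes,
        autosome_length=autosome_length,
        marker_spacing=12_800,
        x_length=None,
        n_offspring=n_offspring,
        error_rate=0.0,
        missing_rate=0.0,
        pedigree_mixture={0: 0.10, 1: 0.35, 2: 0.55},
    )
    pool = simulate_founders(cfg)
    mm = pool.markers
    pos1, pos2 = mm.positions("1"), mm.positions("2")
    disease_locus = ("1", int(pos1[len(pos1) // 2]))
    neutral_locus = ("2", int(pos2[len(pos2) // 2]))
    plant_disease_allele(pool, disease_locus, disease_carrier_freq, seed=seed + 500)
    neutral_idx = plant_neutral_allele(pool, neutral_locus, neutral_carrier_freq, seed=seed + 600)

    panel, _ = simulate_pedigree(cfg, pool)
    tracts = scan_roh(panel)
    all_lengths = tracts["length_bp"].to_numpy()

    records = at_risk_records(panel, pool)
    classified = classify_at_risk(records, tracts, markers=mm)
    disease_obs = classified.loc[
        classified["length_class"] != "SUB", "tract_length"
    ].to_numpy()

    neutral_samples = [
        panel.samples[i] for i in np.flatnonzero(panel.calls[:, neutral_idx] == HOM_B)
    ]
    neutral_rec = pd.DataFrame(
        {"sample": neutral_samples, "chrom": neutral_locus[0], "pos": neutral_locus[1]}
    )
    neutral_cls = classify_at_risk(neutral_rec, tracts, markers=mm)
    neutral_obs = neutral_cls.loc[
        neutral_cls["length_class"] != "SUB", "tract_length"
    ].to_numpy()

    out = {
        "n_cases": int(len(records)),
        "k_disease": int(len(disease_obs)),
        "n_neutral_hom": int(len(neutral_samples)),
        "k_neutral": int(len(neutral_obs)),
        "n_tracts": int(len(all_lengths)),
    }
    env = resample_null(all_lengths, k=max(1, len(disease_obs)), n_reps=n_reps, seed=seed + 1)
    out["disease_inside"] = bool(env.contains(disease_obs)) if len(disease_obs) else True
    if len(neutral_obs):
        env2 = resample_null(all_lengths, k=len(neutral_obs), n_reps=n_reps, seed=seed + 2)
        out["neutral_inside"] = bool(env2.contains(neutral_obs))
    else:
        out["neutral_inside"] = True
    return out
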