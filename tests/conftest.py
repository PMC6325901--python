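from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from rohkit.genotype_io import GenotypePanel, MarkerMap


@pytest.fixture
def make_map():
    """Factory for a single- or multi-chromosome marker map."""

    def _make(positions_by_chrom: dict[str, list[int]]) -> MarkerMap:
        chroms, ids, poss = [], [], []
        for chrom, positions in positions_by_chrom.items():
            for k, p in enumerate(positions):
                chroms.append(chrom)
                ids.append(f"c{chrom}m{k}")
                poss.append(int(p))
        return MarkerMap.from_arrays(chroms, ids, poss)

    return _make


@pytest.fixture
def make_panel(make_map):
    """Factory for a panel from a call matrix and per-chromosome positions."""

    def _make(
        calls,
        positions_by_chrom: dict[str, list[int]],
        samples=None,
        sexes=None,
        breeds=None,
    ) -> GenotypePanel:
        calls = np.asarray(calls, dtype=np.int8)
        mm = _concat_map(make_map, positions_by_chrom)
        if samples is None:
            samples = [f"D{i}" for i in range(calls.shape[0])]
        meta = pd.DataFrame(
            {
                "breed": breeds if breeds is not None else [None] * len(samples),
                "sex": sexes if sexes is not None else ["U"] * len(samples),
            },
            index=pd.Index(samples, name="sample"),
        )
        return GenotypePanel(mm, list(samples), calls, meta)

    def _concat_map(factory, positions_by_chrom):
        return factory(positions_by_chrom)

    return _make


@pytest.fixture(scope="session")
def random_chromosome_fixtures():
    """Shared random chromosomes for both caller-vs-oracle equivalence checks.

    1000 chromosomes of up to 200 markers with varied heterozygosity,
    missingness and marker spacing, so runs of every relevant span and
    marker count occur.
    """
    rng = np.random.default_rng(20_240_901)
    fixtures = []
    for _ in range(1000):
        m = int(rng.integers(5, 201))
        spacing = rng.integers(2_000, 30_000, size=m)
        positions = np.cumsum(spacing) + int(rng.integers(1, 50_000))
        p_het = rng.uniform(0.0, 0.25)
        p_mis = rng.uniform(0.0, 0.05)
        u = rng.random(m)
        calls = np.full(m, 0, dtype=np.int8)
        calls[u < p_het] = 1  # HET
        calls[(u >= p_het) & (u < p_het + p_mis)] = -1  # MISSING
        hom_b = rng.random(m) < 0.5
        calls[(calls == 0) & hom_b] = 2
        fixtures.append((calls, positions.astype(np.int64)))
    return fixtures
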