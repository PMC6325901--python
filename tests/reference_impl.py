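"""Independent naive reference implementations used as test oracles.

These are deliberately written from the algorithm definitions with plain
loops and no shared code with the package, so agreement between the two
routes is meaningful.
"""

from __future__ import annotations

import numpy as np

from rohkit.genotype_io import HET, MISSING


def brute_force_scan(
    calls,
    positions,
    min_span: int = 500_000,
    max_gap: int = 50_000,
    min_markers: int = 41,
    missing_policy: str = "BREAK",
) -> list[tuple[int, int, int]]:
    """Enumerate-merge-filter oracle for the SCAN caller (O(n^2))."""
    n = len(calls)

    def bad(c) -> bool:
        return c == HET or (missing_policy == "BREAK" and c == MISSING)

    # all maximal runs without bad calls, kept if span >= min_span
    runs = []
    for i in range(n):
        if bad(calls[i]) or (i > 0 and not bad(calls[i - 1])):
            continue
        j = i
        while j + 1 < n and not bad(calls[j + 1]):
            j += 1
        if positions[j] - positions[i] + 1 >= min_span:
            runs.append((int(positions[i]), int(positions[j])))

    # transitive merge via union-find on the neighbour graph
    parent = list(range(len(runs)))

    def find(x):
        while parent[x] != x:
            x = parent[x]
        return x

    for a in range(len(runs)):
        for b in range(a + 1, len(runs)):
            if runs[b][0] - runs[a][1] < max_gap:
                parent[find(b)] = find(a)
    groups: dict[int, list[tuple[int, int]]] = {}
    for idx, r in enumerate(runs):
        groups.setdefault(find(idx), []).append(r)
    merged = sorted(
        (min(s for s, _ in g), max(e for _, e in g)) for g in groups.values()
    )

    out = []
    for s, e in merged:
        count = sum(1 for p in positions if s <= p <= e)
        if count >= min_markers:
            out.append((s, e, count))
    return out


def naive_windowed(
    calls,
    positions,
    w: int = 41,
    het_max: int = 0,
    mis_max: int = 0,
    threshold: float = 0.05,
    min_snps: int = 41,
    min_kb: float = 500.0,
) -> list[tuple[int, int, int]]:
    """Loop-based reference of the PLINK-1.07 windowed algorithm."""
    m = len(calls)
    if m < w:
        return []
    n_win = m - w + 1
    hits = []
    for i in range(n_win):
        win = calls[i : i + w]
        n_het = sum(1 for c in win if c == HET)
        n_mis = sum(1 for c in win if c == MISSING)
        hits.append(n_het <= het_max and n_mis <= mis_max)
    qualifies = []
    for j in range(m):
        lo = max(0, j - w + 1)
        hi = min(j, n_win - 1)
        frac = sum(hits[lo : hi + 1]) / (hi - lo + 1)
        qualifies.append(frac >= threshold)

    out = []
    j = 0
    while j < m:
        if not qualifies[j]:
            j += 1
            continue
        k = j
        while k + 1 < m and qualifies[k + 1]:
            k += 1
        hom_idx = [t for t in range(j, k + 1) if calls[t] not in (HET, MISSING)]
        if hom_idx:
            a, b = hom_idx[0], hom_idx[-1]
            if b - a + 1 >= min_snps and positions[b] - positions[a] + 1 >= min_kb * 1000:
                out.append((int(positions[a]), int(positions[b]), b - a + 1))
        j = k + 1
    return out


def stab_counts(intervals, grid) -> np.ndarray:
    """Per-position counts of covering intervals (brute force)."""
    out = np.zeros(len(grid), dtype=int)
    for i, p in enumerate(grid):
        out[i] = sum(1 for s, e in intervals if s <= p <= e)
    return out


def greedy_ld_prune(dosages, mafs, window: int, step: int, r2_max: float) -> list[int]:
    """Windowed greedy LD-prune oracle over one chromosome's marker indices.

    ``dosages``: (n_samples, m) float with NaN missing.  Returns retained
    column indices, using the same documented removal rule (lower MAF,
    tie -> later position) applied pair-by-pair in index order.
    """
    m = dosages.shape[1]
    removed: set[int] = set()
    start = 0
    while start < m:
        live = [i for i in range(start, min(start + window, m)) if i not in removed]
        while True:
            found = None
            for ai in range(len(live)):
                for bi in range(ai + 1, len(live)):
                    a, b = live[ai], live[bi]
                    x, y = dosages[:, a], dosages[:, b]
                    ok = ~np.isnan(x) & ~np.isnan(y)
                    if ok.sum() < 2 or x[ok].std() == 0 or y[ok].std() == 0:
                        continue
                    r = np.corrcoef(x[ok], y[ok])[0, 1]
                    if r * r > r2_max:
                        found = (a, b)
                        break
                if found:
                    break
            if not found:
                break
            a, b = found
            if mafs[a] < mafs[b]:
                drop = a
            elif mafs[b] < mafs[a]:
                drop = b
            else:
                drop = max(a, b)
            removed.add(drop)
            live.remove(drop)
        start += step
    return [i for i in range(m) if i not in removed]
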