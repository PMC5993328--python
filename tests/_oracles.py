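"""Independent brute-force oracles used to cross-check the package.

Everything here is deliberately naive (quadratic scans, full enumeration,
closed forms) and shares no code with the implementation under test.
"""

from __future__ import annotations

import itertools

import numpy as np


# --- variant calling -------------------------------------------------------


def naive_call_reads(reads, reference, min_read_q=30.0, min_codon_q=30.0,
                     max_mutated=1, anchor=20, min_reads=3):
    """Quadratic re-implementation of the caller contract.

    Scans every reference offset for an exact head-anchor match (then tail
    anchor), compares every codon, applies the quality and count filters.
    Returns (counts dict, n_wt, n_rejected).
    """
    ref = reference.upper()

    def unique_offset(sub):
        hits = [i for i in range(len(ref) - len(sub) + 1) if ref[i : i + len(sub)] == sub]
        return hits[0] if len(hits) == 1 else None

    tallies: dict[tuple[int, str, str], int] = {}
    n_wt = 0
    n_rej = 0
    for seq, quals in reads:
        seq = seq.upper()
        if len(seq) < anchor:
            n_rej += 1
            continue
        off = unique_offset(seq[:anchor])
        if off is None or off + len(seq) > len(ref):
            off_tail = unique_offset(seq[-anchor:])
            off = None
            if off_tail is not None:
                cand = off_tail + anchor - len(seq)
                if 0 <= cand and cand + len(seq) <= len(ref):
                    off = cand
        if off is None or off % 3 != 0:
            n_rej += 1
            continue
        if np.mean(quals) <= min_read_q:
            n_rej += 1
            continue
        muts = []
        for c in range(len(seq) // 3):
            i = 3 * c
            if seq[i : i + 3] != ref[off + i : off + i + 3]:
                muts.append((off // 3 + c + 1, ref[off + i : off + i + 3], seq[i : i + 3],
                             np.mean(quals[i : i + 3])))
        if len(muts) > max_mutated:
            n_rej += 1
            continue
        if any(q <= min_codon_q for *_, q in muts):
            n_rej += 1
            continue
        if not muts:
            n_wt += 1
            continue
        pos, wt, mut, _ = muts[0]
        tallies[(pos, wt, mut)] = tallies.get((pos, wt, mut), 0) + 1
    counts = {k: (v if v >= min_reads else 0) for k, v in tallies.items()}
    return counts, n_wt, n_rej


# --- statistics ------------------------------------------------------------


def beta_posterior_mean(k, n):
    """Closed-form posterior mean of Beta(k+1, n-k+1)."""
    return (k + 1) / (n + 2)


def spearman_by_hand(x, y):
    """Rank (average ranks for ties) then Pearson."""

    def ranks(v):
        v = np.asarray(v, dtype=float)
        order = np.argsort(v, kind="mergesort")
        r = np.empty(len(v), dtype=float)
        i = 0
        sorted_v = v[order]
        while i < len(v):
            j = i
            while j + 1 < len(v) and sorted_v[j + 1] == sorted_v[i]:
                j += 1
            r[order[i : j + 1]] = (i + j) / 2.0 + 1.0
            i = j + 1
        return r

    rx, ry = ranks(x), ranks(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float((rx * ry).sum() / np.sqrt((rx**2).sum() * (ry**2).sum()))


def mann_whitney_exact(x, y):
    """Exact one-sided mid-p (y stochastically greater) by full enumeration."""
    x = list(map(float, x))
    y = list(map(float, y))

    def u_stat(a, b):
        return sum((bj > ai) + 0.5 * (bj == ai) for ai in a for bj in b)

    u_obs = u_stat(x, y)
    pooled = x + y
    m = len(y)
    greater = equal = total = 0
    for comb in itertools.combinations(range(len(pooled)), m):
        chosen = set(comb)
        b = [pooled[i] for i in chosen]
        a = [pooled[i] for i in range(len(pooled)) if i not in chosen]
        u = u_stat(a, b)
        total += 1
        if u > u_obs:
            greater += 1
        elif u == u_obs:
            equal += 1
    return u_obs, (greater + 0.5 * equal) / total


# --- geometry --------------------------------------------------------------


def nn_grid_bruteforce(ddg, dist, fitness, resolution):
    """Cell-by-cell nearest-neighbour search in min-max normalised space."""
    ddg = np.asarray(ddg, dtype=float)
    dist = np.asarray(dist, dtype=float)

    def norm(v, lo, hi):
        return np.zeros_like(v) if hi == lo else (v - lo) / (hi - lo)

    x = np.linspace(ddg.min(), ddg.max(), resolution)
    y = np.linspace(dist.min(), dist.max(), resolution)
    px = norm(ddg, ddg.min(), ddg.max())
    py = norm(dist, dist.min(), dist.max())
    gx = norm(x, ddg.min(), ddg.max())
    gy = norm(y, dist.min(), dist.max())
    out = np.empty((resolution, resolution))
    for iy in range(resolution):
        for ix in range(resolution):
            best, best_d = 0, np.inf
            for j in range(len(px)):
                d = (gx[ix] - px[j]) ** 2 + (gy[iy] - py[j]) ** 2
                if d < best_d:  # strict: lowest index wins ties
                    best, best_d = j, d
            out[iy, ix] = fitness[best]
    return x, y, out


def min_atom_distance(atoms_a, point):
    return min(float(np.linalg.norm(np.asarray(a) - np.asarray(point))) for a in atoms_a)
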