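"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately avoid the package's own algorithms: the HMM
oracle enumerates hidden paths exhaustively, and the digestion oracle
scans every start position of the sequence.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from gametemap.simdata import HetSnpMap

_PATH_CACHE: dict[int, np.ndarray] = {}


def _paths(n: int) -> np.ndarray:
    """All binary hidden paths of length n, shape (2^n, n)."""
    if n not in _PATH_CACHE:
        bits = ((np.arange(2**n)[:, None] >> np.arange(n)[::-1]) & 1).astype(np.int8)
        _PATH_CACHE[n] = bits
    return _PATH_CACHE[n]


def brute_force_filter(obs, switch=0.2, emission=0.99, init=0.5):
    """Filtering distribution P(s_i = 1 | o_1..i) by summing the joint
    probability over every hidden prefix path."""
    obs = np.asarray(obs)
    switch = np.broadcast_to(np.asarray(switch, dtype=float), (max(obs.size - 1, 0),))
    out = np.empty(obs.size)
    for i in range(obs.size):
        paths = _paths(i + 1)
        logp = np.where(paths[:, 0] == 1, np.log(init), np.log(1 - init))
        if i > 0:
            sw = paths[:, 1:] != paths[:, :-1]
            logp = logp + np.where(sw, np.log(switch[:i]), np.log(1 - switch[:i])).sum(axis=1)
        o = obs[: i + 1]
        seen = o >= 0
        if seen.any():
            match = paths[:, seen] == o[seen]
            logp = logp + np.where(match, np.log(emission), np.log(1 - emission)).sum(axis=1)
        w = np.exp(logp - logp.max())
        p1 = w[paths[:, -1] == 1].sum()
        out[i] = p1 / w.sum()
    return out


def brute_force_bidirectional(obs, switch=0.2, emission=0.99, init=0.5, tie_tol=1e-12):
    """Consensus states and ambiguity per the stated criterion, computed
    entirely from enumerated filtering distributions."""
    obs = np.asarray(obs)
    switch = np.broadcast_to(np.asarray(switch, dtype=float), (max(obs.size - 1, 0),))
    pf = brute_force_filter(obs, switch, emission, init)
    pr = brute_force_filter(obs[::-1], switch[::-1], emission, init)[::-1]
    sf, sr = pf > 0.5, pr > 0.5
    tie = (np.abs(pf - 0.5) <= tie_tol) | (np.abs(pr - 0.5) <= tie_tol)
    return sf.astype(np.int8), (sf != sr) | tie, pf, pr


def brute_force_digest_cuts(seq: str, site: str, offset: int) -> list[int]:
    """Cut positions by checking every start position of the sequence."""
    cuts = set()
    for i in range(len(seq) - len(site) + 1):
        if seq[i : i + len(site)] == site:
            cut = i + offset
            if 0 < cut < len(seq):
                cuts.add(cut)
    return sorted(cuts)


def make_map(positions_by_chrom: dict[str, list[int]], length_pad: int = 1000) -> HetSnpMap:
    """Tiny marker map with fixed A/G parental alleles."""
    positions = {c: np.asarray(p, dtype=np.int64) for c, p in positions_by_chrom.items()}
    a0 = {c: np.array(["A"] * len(p), dtype=object) for c, p in positions_by_chrom.items()}
    a1 = {c: np.array(["G"] * len(p), dtype=object) for c, p in positions_by_chrom.items()}
    lengths = {c: int(max(p)) + length_pad for c, p in positions_by_chrom.items()}
    return HetSnpMap(positions, a0, a1, lengths)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_cell_frame():
    """Helper to build a GameteCell data frame from arrays."""
    from gametemap.simdata import GameteCell

    def build(cell_id, chrom, pos, gt, coverage=0.5):
        gt = np.asarray(gt, dtype=np.int8)
        ad0 = np.where(gt == 0, 3, 0)
        ad1 = np.where(gt == 1, 3, 0)
        ad0 = np.where(gt == 2, 2, ad0)
        ad1 = np.where(gt == 2, 2, ad1)
        data = pd.DataFrame(
            {"chrom": chrom, "pos": np.asarray(pos), "gt": gt, "ad0": ad0, "ad1": ad1}
        )
        return GameteCell(cell_id, data, coverage=coverage)

    return build
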