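import numpy as np
import pytest

from fatiguenet import SimulationConfig, simulate_epoch


FAST_SIM = dict(fs=128.0, epoch_seconds=30.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def fast_epoch():
    """One reduced-size epoch (30 s at 128 Hz) with its ground truth."""
    cfg = SimulationConfig(seed=42, **FAST_SIM)
    rec, events = simulate_epoch(cfg, 0, "normal", 1)
    return cfg, rec, events


@pytest.fixture(scope="session")
def default_epoch():
    """One full-scale epoch (3 min at 1000 Hz) with its ground truth."""
    cfg = SimulationConfig(seed=42)
    rec, events = simulate_epoch(cfg, 0, "normal", 1)
    return cfg, rec, events


def brute_force_metrics(adj):
    """Independent graph-metric oracle by direct enumeration.

    Clustering from the definition (edges among neighbours over possible
    pairs), distances by Floyd-Warshall; returns (C_per_node, C, L, G).
    """
    a = np.asarray(adj)
    n = a.shape[0]
    c = np.zeros(n)
    for i in range(n):
        nb = [j for j in range(n) if a[i, j]]
        d = len(nb)
        if d < 2:
            continue
        e = sum(a[u, v] for k, u in enumerate(nb) for v in nb[k + 1:])
        c[i] = e / (d * (d - 1) / 2)
    dist = np.where(a > 0, 1.0, np.inf)
    np.fill_diagonal(dist, 0.0)
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if dist[i, k] + dist[k, j] < dist[i, j]:
                    dist[i, j] = dist[i, k] + dist[k, j]
    off = dist[~np.eye(n, dtype=bool)]
    finite = off[np.isfinite(off)]
    L = finite.mean() if finite.size else np.nan
    G = np.where(np.isfinite(off), 1.0 / np.where(off == 0, 1, off), 0.0).mean() \
        if n > 1 else 0.0
    return c, c.mean(), L, G


def all_graphs(n):
    """Every labelled simple graph on n nodes, as adjacency matrices."""
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    for mask in range(2 ** len(pairs)):
        a = np.zeros((n, n), dtype=np.int8)
        for b, (i, j) in enumerate(pairs):
            if mask >> b & 1:
                a[i, j] = a[j, i] = 1
        yield a


def match_events(detected, truth, tol_samples):
    """Greedy onset matching; returns (n_hits, n_false_alarms)."""
    used = set()
    hits = 0
    for ev in truth:
        for i, d in enumerate(detected):
            if i not in used and abs(d.onset_sample - ev.onset_sample) <= tol_samples:
                used.add(i)
                hits += 1
                break
    return hits, len(detected) - len(used)
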