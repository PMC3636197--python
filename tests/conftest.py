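"""Shared fixtures and independent oracles for the test suite.

The oracle functions here are deliberately naive re-implementations
(brute-force path enumeration, exhaustive recounts) kept independent of
the library code paths they are used to check.
"""

from __future__ import annotations

import itertools
from collections import deque

import numpy as np
import pandas as pd
import pytest

from natprodnet import chemlib
from natprodnet.synthetic_data import gen_molecule_fixtures


@pytest.fixture(scope="session")
def molecule_fixtures():
    return {f.id: f for f in gen_molecule_fixtures()}


@pytest.fixture(scope="session")
def fixture_records(molecule_fixtures):
    return {fid: f.to_record() for fid, f in molecule_fixtures.items()}


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def bfs_distances(adj: dict, source) -> dict:
    dist = {source: 0}
    queue = deque([source])
    while queue:
        u = queue.popleft()
        for v in adj[u]:
            if v not in dist:
                dist[v] = dist[u] + 1
                queue.append(v)
    return dist


def enumerate_shortest_paths(adj: dict, s, t):
    """All shortest s->t paths by DFS down the BFS distance gradient."""
    dist_s = bfs_distances(adj, s)
    if t not in dist_s:
        return []
    paths = []

    def walk(node, path):
        if node == t:
            paths.append(tuple(path))
            return
        for nxt in adj[node]:
            if dist_s.get(nxt, -1) == dist_s[node] + 1 and dist_s[nxt] <= dist_s[t]:
                walk(nxt, path + [nxt])

    walk(s, [s])
    return paths


def brute_force_betweenness(nodes, edges) -> dict:
    """Normalized betweenness by explicit enumeration of all shortest paths.

    Exponential in the worst case — only usable on tiny graphs (<= ~12
    nodes), which is exactly what makes it a trustworthy oracle.
    """
    adj = {n: set() for n in nodes}
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)
    score = {n: 0.0 for n in nodes}
    for s, t in itertools.combinations(nodes, 2):
        paths = enumerate_shortest_paths(adj, s, t)
        if not paths:
            continue
        for node in nodes:
            if node in (s, t):
                continue
            on = sum(1 for p in paths if node in p)
            score[node] += on / len(paths)
    n = len(nodes)
    norm = (n - 1) * (n - 2) / 2.0 if n > 2 else 1.0
    return {k: v / norm for k, v in score.items()}


def recount_ro5_categories(descriptors: pd.DataFrame) -> dict:
    """Exhaustive per-molecule Rule-of-Five category recount."""
    counts = dict(all_satisfied=0, except_mw=0, except_acceptors=0,
                  except_donors=0, except_alogp=0, at_least_three=0)
    for _, row in descriptors.iterrows():
        mw_ok = row["mw"] < 500.0
        hba_ok = row["hba"] < 10
        hbd_ok = row["hbd"] < 5
        logp_ok = row["alogp"] < 5.0
        if mw_ok and hba_ok and hbd_ok and logp_ok:
            counts["all_satisfied"] += 1
        if hba_ok and hbd_ok and logp_ok:
            counts["except_mw"] += 1
        if mw_ok and hbd_ok and logp_ok:
            counts["except_acceptors"] += 1
        if mw_ok and hba_ok and logp_ok:
            counts["except_donors"] += 1
        if mw_ok and hba_ok and hbd_ok:
            counts["except_alogp"] += 1
        if sum([mw_ok, hba_ok, hbd_ok, logp_ok]) >= 3:
            counts["at_least_three"] += 1
    return counts


def random_small_graph(rng: np.random.Generator, max_nodes: int = 12):
    """A random Erdos-Renyi-style graph as (nodes, edge list)."""
    n = int(rng.integers(3, max_nodes + 1))
    nodes = [f"n{i}" for i in range(n)]
    p = float(rng.uniform(0.15, 0.6))
    edges = [(nodes[i], nodes[j]) for i in range(n) for j in range(i + 1, n)
             if rng.random() < p]
    return nodes, edges
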