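import numpy as np
import pandas as pd
import pytest

import vafclust as vc


@pytest.fixture(scope="session")
def strong_cohort():
    """A well-separated 3-species cohort with one F1 hybrid pair."""
    cfg = vc.SimulationConfig(
        n_species=3,
        samples_per_species=4,
        hybrids=((0, 1, 2),),
        n_sites=2000,
        divergence_F=0.5,
        mean_depth=30.0,
        error_rate=0.005,
        seed=11,
    )
    return cfg, vc.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def strong_vaf_matrix(strong_cohort, tmp_path_factory):
    """VAFMatrix assembled from the strong cohort through the I/O layer."""
    _, (truth, rec_frames, depth_table, _) = strong_cohort
    tmp = tmp_path_factory.mktemp("cohort")
    depth_path = tmp / "depth.tsv"
    depth_table.to_csv(depth_path, sep="\t")
    records = {s: vc.records_from_frame(f) for s, f in rec_frames.items()}
    sites = vc.union_sites(records)
    depth = vc.read_depth_table(depth_path, sites, list(records))
    return truth, vc.build_vaf_matrix(records, depth, sites)


def make_vaf_matrix(vaf, depth, samples=None):
    """Build a VAFMatrix directly from arrays (positions 1..m on one contig)."""
    vaf = np.asarray(vaf, dtype=float)
    depth = np.asarray(depth, dtype=float)
    n, m = vaf.shape
    if samples is None:
        samples = [f"s{i}" for i in range(n)]
    sites = vc.SiteSet([("chr_syn", p + 1, "A", "T") for p in range(m)])
    return vc.VAFMatrix(samples=list(samples), sites=sites, vaf=vaf, depth=depth)


@pytest.fixture
def vaf_matrix_factory():
    return make_vaf_matrix


def naive_masked_distance(vaf, depth, min_pair_depth=8):
    """Double-loop oracle for the masked pairwise-complete RMS distance."""
    n, m = vaf.shape
    d = np.full((n, n), np.nan)
    counts = np.zeros((n, n), dtype=int)
    for i in range(n):
        d[i, i] = 0.0
        # the pair mask applied to (i, i) counts the sample's covered sites
        counts[i, i] = sum(
            1 for p in range(m)
            if not np.isnan(depth[i, p]) and depth[i, p] >= min_pair_depth
        )
        for j in range(i + 1, n):
            acc, cnt = 0.0, 0
            for p in range(m):
                di, dj = depth[i, p], depth[j, p]
                if np.isnan(di) or np.isnan(dj):
                    continue
                if di >= min_pair_depth and dj >= min_pair_depth:
                    acc += (vaf[i, p] - vaf[j, p]) ** 2
                    cnt += 1
            counts[i, j] = counts[j, i] = cnt
            if cnt:
                d[i, j] = d[j, i] = np.sqrt(acc / cnt)
    return d, counts


def naive_ward(d):
    """Per-step recomputation oracle for ward.D2.

    Cluster-pair cost is recomputed from the original squared distances at
    every step via D^2(A, B) = 2 * (W(A u B) - W(A) - W(B)) with
    W(C) = (1/|C|) * sum over unordered pairs in C of d^2 — never through
    the Lance-Williams recurrence, so it is independent of the
    implementation it checks.
    """
    d2 = np.asarray(d, dtype=float) ** 2
    n = d2.shape[0]

    def within(cluster):
        cl = sorted(cluster)
        return sum(d2[a, b] for ai, a in enumerate(cl) for b in cl[ai + 1:]) / len(cl)

    clusters = {i: frozenset([i]) for i in range(n)}
    merges = []
    for t in range(n - 1):
        best = None
        for a in sorted(clusters):
            for b in sorted(clusters):
                if a >= b:
                    continue
                cost = 2.0 * (
                    within(clusters[a] | clusters[b])
                    - within(clusters[a])
                    - within(clusters[b])
                )
                key = (cost, a, b)
                if best is None or key < best:
                    best = key
        cost, a, b = best
        new_id = n + t
        merges.append((a, b, np.sqrt(max(cost, 0.0)), len(clusters[a] | clusters[b])))
        clusters[new_id] = clusters.pop(a) | clusters.pop(b)
    return merges


def random_distance_matrix(rng, n):
    """A random symmetric matrix in [0, 1] with zero diagonal."""
    x = rng.uniform(0.05, 1.0, size=(n, n))
    d = (x + x.T) / 2.0
    np.fill_diagonal(d, 0.0)
    return d


def distance_matrix_from_array(d, samples=None):
    d = np.asarray(d, dtype=float)
    n = d.shape[0]
    if samples is None:
        samples = [f"s{i}" for i in range(n)]
    return vc.DistanceMatrix(
        samples=list(samples),
        d=d,
        n_sites_used=np.full((n, n), 100, dtype=np.int64),
        defined=np.ones((n, n), dtype=bool),
    )
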