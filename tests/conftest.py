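import numpy as np
import pytest

from crepipe import arraydes, motif, simulate


@pytest.fixture(scope="session")
def pattern():
    return motif.cre_pattern()


@pytest.fixture(scope="session")
def small_experiment():
    """One-strain array experiment reused by several statistical tests."""
    spots, design, truth = simulate.simulate_array_experiment(
        n_genes=500, strains=["A"], seed=11
    )
    return spots, design, truth


# ---------------------------------------------------------------------------
# Independent oracles (deliberately naive implementations)


def brute_force_scan(genome: dict, pattern) -> list:
    """Enumerate every window on both strands and filter by matches()."""
    m = len(pattern)
    hits = []
    for contig in sorted(genome):
        seq = genome[contig].upper()
        for start in range(len(seq) - m + 1):
            window = seq[start : start + m]
            if any(b not in "ACGT" for b in window):
                continue
            count, ok = motif.mismatch_profile(window, pattern)
            if ok and count <= pattern.max_mismatches:
                hits.append((contig, start, "+", count))
            rc = motif.reverse_complement(window)
            count, ok = motif.mismatch_profile(rc, pattern)
            if ok and count <= pattern.max_mismatches:
                hits.append((contig, start, "-", count))
    return sorted(hits)


def brute_force_bh(p: np.ndarray) -> np.ndarray:
    """Step-up BH directly from its definition: q_(i) = min_{j>=i} m p_(j)/j."""
    p = np.asarray(p, float)
    m = p.size
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    for rank_i, idx in enumerate(order, start=1):
        q[idx] = min(
            min(m * p[order[j - 1]] / j for j in range(rank_i, m + 1)), 1.0
        )
    return q


def brute_force_gls(m_by_array: dict, rho: float) -> dict:
    """Intercept-only GLS with the explicit block covariance matrix."""
    ys, blocks = [], []
    for vals in m_by_array.values():
        v = np.asarray(vals, float)
        v = v[np.isfinite(v)]
        if v.size:
            ys.append(v)
            k = v.size
            blocks.append((1 - rho) * np.eye(k) + rho * np.ones((k, k)))
    y = np.concatenate(ys)
    n = y.size
    sigma = np.zeros((n, n))
    i = 0
    for b in blocks:
        k = b.shape[0]
        sigma[i : i + k, i : i + k] = b
        i += k
    si = np.linalg.inv(sigma)
    ones = np.ones(n)
    xtx = ones @ si @ ones
    beta = (ones @ si @ y) / xtx
    resid = y - beta
    rss = resid @ si @ resid
    return {"beta_hat": beta, "s2": rss / (n - 1), "df": n - 1, "v": 1.0 / xtx}
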