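"""Numba-compiled numerical kernels.

Two compute-heavy primitives live here:

* uniformization of the single-allele CME generator (action of the matrix
  exponential on a probability vector via the randomized-jump chain),
  written against the banded structure of the telegraph-family models —
  per allele state, mRNA production is a superdiagonal, degradation a
  subdiagonal, and gene-state switching couples the blocks; and
* an exact Gillespie (SSA) sampler for the two-allele reaction networks.

Both operate on the compact per-allele description of the reaction
network (see :func:`telegraphkit.models.allele_reactions`) so a single
kernel serves every model variant.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def uniformize_telegraph(switch, tx, k_d, p0, t, lam):
    """Evolve the single-allele CME by ``exp(R t)`` using uniformization.

    Parameters
    ----------
    switch : (n_s, n_s) array
        Gene-state switching rates, ``switch[dst, src]``; diagonal ignored.
    tx : (n_s,) array
        Transcription propensity per gene state (zeroed at the truncation
        boundary by the kernel).
    k_d : float
        Per-molecule degradation rate.
    p0 : (n_s, M+1) array
        Initial distribution over (gene state, mRNA count).
    t, lam : float
        Time and uniformization rate; ``lam`` must dominate every total
        outflow so the jump map stays substochastic.

    The iteration ``v_{k+1} = (I + R/lam) v_k`` is accumulated with
    Poisson(lam*t) weights carried in log space (lam*t of order 1e4 is
    routine).  Unconditionally stable: every iterate is a probability
    vector.
    """
    n_s, width = p0.shape
    M = width - 1
    v = p0.copy()
    out = np.zeros((n_s, width))
    lt = lam * t
    if lt <= 0.0:
        return v
    # per-state exit rate to gene switching
    srow = np.zeros(n_s)
    for s in range(n_s):
        for d in range(n_s):
            if d != s:
                srow[s] += switch[d, s]
    kmax = int(lt + 10.0 * np.sqrt(lt) + 25.0)
    logw = -lt
    wsum = 0.0
    for k in range(kmax + 1):
        w = np.exp(logw)
        if w > 1e-18:  # Poisson window: weights far below the mode are nil
            wsum += w
            for s in range(n_s):
                for m in range(width):
                    out[s, m] += w * v[s, m]
        if wsum > 1.0 - 1e-14:
            break
        if k > lt and w < 1e-18 and k > 10:
            break
        nv = np.zeros((n_s, width))
        for s in range(n_s):
            txs = tx[s] / lam
            for m in range(width):
                outflow = k_d * m + srow[s]
                if m < M:
                    outflow += tx[s]
                acc = (1.0 - outflow / lam) * v[s, m]
                if m > 0:
                    acc += txs * v[s, m - 1]
                if m < M:
                    acc += (k_d * (m + 1) / lam) * v[s, m + 1]
                for src in range(n_s):
                    if src != s and switch[s, src] > 0.0:
                        acc += (switch[s, src] / lam) * v[src, m]
                nv[s, m] = acc
        v = nv
        logw += np.log(lt) - np.log(k + 1.0)
    if wsum > 0.0:
        inv = 1.0 / wsum
        for s in range(n_s):
            for m in range(width):
                out[s, m] *= inv
    return out


@njit(cache=True)
def ssa_paths(n_paths, t_end, trans_src, trans_dst, trans_rate,
              tx_rate, k_d, m_cap, path_seeds):
    """Exact SSA for two independent alleles sharing one mRNA pool.

    ``trans_src/dst/rate`` describe single-allele state transitions;
    ``tx_rate[s]`` is the transcription propensity contributed by one
    allele in state ``s``; ``path_seeds`` is a well-mixed per-path seed
    array.  Both alleles start in state 0 with no mRNA.  Returns the mRNA
    copy number of each path at ``t_end`` and a flag array marking
    runaway trajectories that hit ``m_cap``.
    """
    counts = np.zeros(n_paths, dtype=np.int64)
    runaway = np.zeros(n_paths, dtype=np.uint8)
    n_trans = trans_src.size
    for p in range(n_paths):
        np.random.seed(path_seeds[p])
        a0 = 0
        a1 = 0
        m = 0
        t = 0.0
        while True:
            r_deg = k_d * m
            r_tx = tx_rate[a0] + tx_rate[a1]
            total = r_deg + r_tx
            for j in range(n_trans):
                if trans_src[j] == a0:
                    total += trans_rate[j]
                if trans_src[j] == a1:
                    total += trans_rate[j]
            if total <= 0.0:
                break
            t += -np.log(np.random.random()) / total
            if t > t_end:
                break
            u = np.random.random() * total
            acc = r_deg
            if u < acc:
                m -= 1
                continue
            acc += r_tx
            if u < acc:
                m += 1
                if m >= m_cap:
                    runaway[p] = 1
                    break
                continue
            done = False
            for j in range(n_trans):
                if trans_src[j] == a0:
                    acc += trans_rate[j]
                    if u < acc:
                        a0 = trans_dst[j]
                        done = True
                        break
            if done:
                continue
            for j in range(n_trans):
                if trans_src[j] == a1:
                    acc += trans_rate[j]
                    if u < acc:
                        a1 = trans_dst[j]
                        break
        counts[p] = m
    return counts, runaway
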