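"""Shared fixtures and independent brute-force oracles.

The oracle functions here are written straight from the textbook
definitions (explicit loops, no vectorized shortcuts shared with the
implementation) so they stay independent of the code paths they check.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from tregsig.io import CountMatrix


def make_count_matrix(
    counts: np.ndarray,
    groups: list[str] | None = None,
    donors: list[str] | None = None,
    gene_ids: list[str] | None = None,
) -> CountMatrix:
    """CountMatrix from a raw array; group strings are 'compartment.lineage'."""
    counts = np.asarray(counts)
    n_genes, n_samples = counts.shape
    if groups is None:
        half = n_samples // 2
        groups = ["thymus.Treg"] * half + ["thymus.Tconv"] * (n_samples - half)
    if donors is None:
        donors = [f"d{i}" for i in range(n_samples)]
    if gene_ids is None:
        gene_ids = [f"g{i:04d}" for i in range(n_genes)]
    comp = [g.split(".")[0] for g in groups]
    lin = [g.split(".")[1] for g in groups]
    meta = pd.DataFrame(
        {"donor_id": donors, "compartment": comp, "lineage": lin},
        index=pd.Index([f"s{i}" for i in range(n_samples)], name="sample_id"),
    )
    frame = pd.DataFrame(counts, index=pd.Index(gene_ids, name="gene_id"), columns=meta.index)
    return CountMatrix(counts=frame, samples=meta)


def random_nb_counts(
    rng: np.random.Generator, n_genes: int, n_samples: int, phi: float = 0.1
) -> np.ndarray:
    mu = rng.uniform(5, 500, size=n_genes)
    lam = rng.gamma(shape=1.0 / phi, scale=mu[:, None] * phi, size=(n_genes, n_samples))
    return rng.poisson(lam)


# ---------------------------------------------------------------------------
# Brute-force oracles
# ---------------------------------------------------------------------------


def tmm_oracle(counts: np.ndarray, trim_m: float = 0.30, trim_a: float = 0.05) -> np.ndarray:
    """TMM factors computed straight from the definition, gene by gene."""
    counts = np.asarray(counts, dtype=float)
    n_genes, n_samples = counts.shape
    lib = counts.sum(axis=0)
    f75 = np.array([np.quantile(counts[:, k], 0.75) / lib[k] for k in range(n_samples)])
    ref = int(np.argmin(np.abs(f75 - f75.mean())))
    factors = []
    for k in range(n_samples):
        if k == ref:
            factors.append(1.0)
            continue
        rows = [
            g for g in range(n_genes) if counts[g, k] > 0 and counts[g, ref] > 0
        ]
        m_vals, a_vals, w_vals = [], [], []
        for g in rows:
            pk = counts[g, k] / lib[k]
            pr = counts[g, ref] / lib[ref]
            m_vals.append(np.log2(pk / pr))
            a_vals.append(0.5 * np.log2(pk * pr))
            w_vals.append(
                1.0
                / (
                    1.0 / counts[g, k]
                    - 1.0 / lib[k]
                    + 1.0 / counts[g, ref]
                    - 1.0 / lib[ref]
                )
            )
        n = len(rows)
        lo_m = int(np.floor(n * trim_m)) + 1
        hi_m = n + 1 - lo_m
        lo_a = int(np.floor(n * trim_a)) + 1
        hi_a = n + 1 - lo_a
        order_m = sorted(range(n), key=lambda i: (m_vals[i], i))
        order_a = sorted(range(n), key=lambda i: (a_vals[i], i))
        rank_m = {i: r + 1 for r, i in enumerate(order_m)}
        rank_a = {i: r + 1 for r, i in enumerate(order_a)}
        num = den = 0.0
        for i in range(n):
            if lo_m <= rank_m[i] <= hi_m and lo_a <= rank_a[i] <= hi_a:
                num += w_vals[i] * m_vals[i]
                den += w_vals[i]
        factors.append(2.0 ** (num / den))
    factors = np.asarray(factors)
    return factors / np.exp(np.mean(np.log(factors)))


def holm_oracle(p: np.ndarray) -> np.ndarray:
    """Step-down Holm adjustment by direct enumeration of the definition."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m)
    running_max = 0.0
    for i, idx in enumerate(order):
        val = min(1.0, (m - i) * p[idx])
        running_max = max(running_max, val)
        adjusted[idx] = running_max
    return adjusted


def moment_prior_oracle(s2: np.ndarray, df: float) -> tuple[float, float]:
    """(d0, s0^2) from the closed-form moment equations, step by step.

    log(s^2) for chi-square-df sampling around a scaled-F prior has mean
    digamma(df/2) - log(df/2) + log(s0^2) + digamma(d0/2) - log(d0/2) and
    excess variance trigamma(d0/2); solving the trigamma equation by
    bisection gives d0.
    """
    from scipy.special import digamma, polygamma

    z = np.log(np.asarray(s2, dtype=float))
    e = z - digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(np.mean(e))
    evar = float(np.var(e, ddof=1)) - float(polygamma(1, df / 2.0))
    if evar <= 0:
        return np.inf, float(np.mean(np.asarray(s2, dtype=float)))
    lo, hi = 1e-8, 1e8
    for _ in range(200):
        mid = np.sqrt(lo * hi)
        if polygamma(1, mid) > evar:
            lo = mid
        else:
            hi = mid
    half_d0 = np.sqrt(lo * hi)
    d0 = 2.0 * half_d0
    s02 = float(np.exp(emean + digamma(half_d0) - np.log(half_d0)))
    return d0, s02


def reference_threshold_se(params) -> float:
    """Standard error of the recovered private-gene threshold under the
    generator's own parameters (delta-method NB log2 variance plus the
    donor effect, averaged over the three opposing libraries)."""
    mu = 2.0**params.reference_gene_tconv_log2_mean * params.lib_size_mean / 1e6
    var_log2 = (1.0 / mu + params.dispersion) / np.log(2.0) ** 2 + params.donor_sd**2
    return float(np.sqrt(var_log2 / 3.0))


@pytest.fixture(scope="session")
def small_experiment():
    """A modest synthetic experiment shared by recovery-style unit tests."""
    from tregsig.simulate import SimulationParams, simulate_experiment

    params = SimulationParams(n_genes=3000, seed=20240915)
    cm, truth = simulate_experiment(params)
    return params, cm, truth
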