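"""Aggregation and statistics of simulated current events.

Dwell-time analytics follow standard resistive-pulse practice: the off rate
k_off is the reciprocal mean event duration; duration distributions are fit
by maximum likelihood with single- or double-exponential models (optionally
left-censored, e.g. discarding events shorter than the recording filter
would resolve); voltage dependence of k_off is summarized by a straight
line in log10(k_off) vs V.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize

__all__ = ["EventRecord", "koff", "fit_exponential", "fit_double_exponential",
           "koff_vs_voltage", "scatter_table", "histogram"]


@dataclass(frozen=True)
class EventRecord:
    """One simulated current event."""

    tau_off: float          # s
    amplitude: float        # A/I0 in [0, 1]
    outcome: str            # translocated | escaped | max_steps
    bound: bool
    n_bindings: int = 0
    site_ids: tuple = ()
    voltage: float = float("nan")  # V
    seed: int = -1

    def __post_init__(self) -> None:
        if self.tau_off <= 0:
            raise ValueError("event duration must be positive")
        if not (0.0 <= self.amplitude <= 1.0):
            raise ValueError("relative amplitude must lie in [0, 1]")


def _durations(records) -> np.ndarray:
    if hasattr(records, "__len__") and len(records) == 0:
        raise ValueError("empty event set")
    arr = np.asarray([r.tau_off if isinstance(r, EventRecord) else r
                      for r in records], dtype=float)
    if (arr <= 0).any():
        raise ValueError("durations must be positive")
    return arr


def koff(records) -> float:
    """Off rate (1/s) as the reciprocal mean event duration."""
    return float(1.0 / _durations(records).mean())


def koff_ci(records, n_boot: int = 1000, seed: int = 0,
            level: float = 0.95) -> tuple[float, float]:
    """Nonparametric bootstrap confidence interval for :func:`koff`."""
    tau = _durations(records)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(tau), size=(n_boot, len(tau)))
    ks = 1.0 / tau[idx].mean(axis=1)
    q = (1 - level) / 2
    return tuple(np.quantile(ks, [q, 1 - q]))


def fit_exponential(durations, censor_below: float = 0.0,
                    ci_level: float = 0.95) -> dict:
    """Maximum-likelihood exponential rate fit.

    With left censoring at ``censor_below`` only events >= the threshold are
    used; by memorylessness the MLE is 1/(mean - threshold).  Returns a dict
    with ``rate`` (1/s), ``ci``, ``n``, and ``loglik``.
    """
    tau = _durations(durations)
    tau = tau[tau >= censor_below]
    n = len(tau)
    if n < 10:
        raise ValueError("need at least 10 (uncensored) durations")
    rate = 1.0 / (tau.mean() - censor_below)
    z = {0.95: 1.959964, 0.99: 2.575829}.get(ci_level, 1.959964)
    half = z * rate / np.sqrt(n)
    ll = n * np.log(rate) - rate * (tau - censor_below).sum()
    return {"rate": float(rate), "ci": (float(rate - half), float(rate + half)),
            "n": n, "loglik": float(ll)}


def _double_exp_negll(params, tau, t0):
    w = 1.0 / (1.0 + np.exp(-params[0]))
    k1, k2 = np.exp(params[1]), np.exp(params[2])
    f = w * k1 * np.exp(-k1 * tau) + (1 - w) * k2 * np.exp(-k2 * tau)
    S0 = w * np.exp(-k1 * t0) + (1 - w) * np.exp(-k2 * t0)
    return -(np.log(np.maximum(f, 1e-300)).sum() - len(tau) * np.log(max(S0, 1e-300)))


def fit_double_exponential(durations, censor_below: float = 0.0,
                           n_starts: int = 10, seed: int = 0) -> dict:
    """Two-component exponential mixture fit by direct likelihood
    maximization with random multistarts.

    Returns ``weights`` (w, 1-w), ``rates`` (k_d, k_d2) sorted slow-first,
    ``loglik``, and a ``converged`` flag (the best candidate is reported
    either way).  Censoring below a threshold renormalizes the likelihood
    by the mixture survival at the threshold.
    """
    tau = _durations(durations)
    tau = tau[tau >= censor_below]
    if len(tau) < 10:
        raise ValueError("need at least 10 (uncensored) durations")
    rng = np.random.default_rng(seed)
    k0 = 1.0 / max(tau.mean() - censor_below, 1e-12)
    best = None
    any_ok = False
    for s in range(n_starts):
        x0 = np.array([rng.normal(0, 1.5),
                       np.log(k0) + rng.normal(0, 1.5),
                       np.log(k0) + rng.normal(0, 1.5)])
        res = minimize(_double_exp_negll, x0, args=(tau, censor_below),
                       method="Nelder-Mead",
                       options={"maxiter": 4000, "xatol": 1e-8, "fatol": 1e-10})
        if best is None or res.fun < best.fun:
            best = res
        any_ok = any_ok or res.success
    w = 1.0 / (1.0 + np.exp(-best.x[0]))
    k1, k2 = np.exp(best.x[1]), np.exp(best.x[2])
    if k1 > k2:
        k1, k2, w = k2, k1, 1 - w
    return {"weights": (float(w), float(1 - w)),
            "rates": (float(k1), float(k2)),
            "loglik": float(-best.fun), "n": len(tau), "converged": bool(any_ok)}


def koff_vs_voltage(records) -> dict:
    """Least-squares line log10(k_off) = slope * V + intercept over voltage
    groups.  ``records`` is an iterable of EventRecords carrying voltages,
    or a mapping voltage -> durations.  Requires >= 2 groups."""
    if isinstance(records, dict):
        groups = {float(v): _durations(d) for v, d in records.items()}
    else:
        groups = {}
        for r in records:
            groups.setdefault(float(r.voltage), []).append(r.tau_off)
        groups = {v: np.asarray(d) for v, d in groups.items()}
    if len(groups) < 2:
        raise ValueError("need at least two voltage groups")
    V = np.array(sorted(groups))
    k = np.array([1.0 / groups[v].mean() for v in V])
    A = np.stack([V, np.ones_like(V)], axis=-1)
    coef, res, *_ = np.linalg.lstsq(A, np.log10(k), rcond=None)
    n = len(V)
    sigma2 = (res[0] / (n - 2)) if n > 2 and len(res) else 0.0
    cov = sigma2 * np.linalg.inv(A.T @ A)
    return {"slope": float(coef[0]), "intercept": float(coef[1]),
            "slope_se": float(np.sqrt(max(cov[0, 0], 0.0))),
            "voltages": V, "koff": k}


def scatter_table(records) -> pd.DataFrame:
    """(tau_off, A/I0, outcome, bound, ...) rows for export/plotting."""
    return pd.DataFrame([{
        "tau_off_s": r.tau_off, "amplitude": r.amplitude,
        "outcome": r.outcome, "bound": r.bound,
        "n_bindings": r.n_bindings,
        "site_ids": ",".join(map(str, r.site_ids)),
        "voltage_V": r.voltage, "seed": r.seed,
    } for r in records])


def histogram(records, bins=30, log: bool = True):
    """Dwell-time histogram; log-spaced bins by default (event durations
    span many decades).  Returns (counts, edges)."""
    if hasattr(records, "__len__") and len(records) == 0:
        return np.array([]), np.array([])
    tau = _durations(records)
    if log and np.isscalar(bins):
        edges = np.logspace(np.log10(tau.min() * 0.999),
                            np.log10(tau.max() * 1.001), int(bins) + 1)
    elif np.isscalar(bins):
        edges = np.linspace(tau.min() * 0.999, tau.max() * 1.001, int(bins) + 1)
    else:
        edges = np.asarray(bins)
    counts, edges = np.histogram(tau, bins=edges)
    return counts, edges
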