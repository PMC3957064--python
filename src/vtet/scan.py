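"""Maximum interval scan statistic and subject-level CNV-evidence p-values.

For a region of T probes with standardized intensities x_1..x_T, the interval
statistic for 1-based closed [a, b] is

    z_ab = sum(x_a..x_b) / sqrt(b - a + 1),

standard normal under the diploid null.  The scan maximizes a mode-signed
z_ab over all intervals of at least L probes: |z| for either CNV type,
-z for hemizygous deletions, +z for duplications.  The maximum is converted
to a p-value against a Monte-Carlo null table of the same (T, L, mode), or
(diagnostically) via a Siegmund-type analytic approximation.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.stats import norm

MODES = ("both", "deletion", "duplication")

__all__ = [
    "MODES",
    "ScanParams",
    "NullTable",
    "interval_statistic",
    "max_scan",
    "scan_maxima",
    "build_null_table",
    "mc_pvalue",
    "siegmund_pvalue",
    "siegmund_mc_diagnostic",
    "subject_region_pvalues",
]


@dataclass(frozen=True)
class ScanParams:
    """Scan configuration: minimum CNV span L (probes) and scan mode."""

    L: int = 3
    mode: str = "both"

    def __post_init__(self):
        if self.L < 3:
            raise ValueError("L must be >= 3")
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")


@lru_cache(maxsize=128)
def _intervals(T: int, L: int):
    """All 1-based closed intervals [a, b] with b-a+1 >= L, in lex (a, b) order.

    Returns (a, b, sqrt_len) arrays; lex order makes np.argmax respect the
    smallest-a-then-smallest-b tie break.
    """
    if T < L:
        raise ValueError(f"region length T={T} < minimum CNV span L={L}")
    a_list, b_list = [], []
    for a in range(1, T - L + 2):
        for b in range(a + L - 1, T + 1):
            a_list.append(a)
            b_list.append(b)
    a = np.array(a_list, dtype=np.int64)
    b = np.array(b_list, dtype=np.int64)
    return a, b, np.sqrt(b - a + 1.0)


def interval_statistic(x, a: int, b: int) -> float:
    """z_ab = sum(x[a..b]) / sqrt(b-a+1) with 1-based closed indices."""
    x = np.asarray(x, dtype=float)
    T = x.shape[-1]
    if not (1 <= a <= b <= T):
        raise IndexError(f"interval [{a},{b}] out of range for T={T}")
    return float(np.sum(x[a - 1 : b]) / np.sqrt(b - a + 1))


def _all_stats(X: np.ndarray, T: int, L: int) -> np.ndarray:
    """z_ab for every admissible interval; X has shape (n, T), output (n, K)."""
    a, b, w = _intervals(T, L)
    S = np.zeros((X.shape[0], T + 1))
    np.cumsum(X, axis=1, out=S[:, 1:])
    return (S[:, b] - S[:, a - 1]) / w


def _signed(stats: np.ndarray, mode: str) -> np.ndarray:
    if mode == "both":
        return np.abs(stats)
    if mode == "deletion":
        return -stats
    return stats


def max_scan(x, params: ScanParams):
    """Maximum mode-signed interval statistic and its arg-max interval.

    Returns ``(U, (a, b))`` with 1-based closed interval; ties broken by
    smallest a, then smallest b.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    T = x.shape[1]
    a, b, _ = _intervals(T, params.L)
    signed = _signed(_all_stats(x, T, params.L), params.mode)[0]
    k = int(np.argmax(signed))
    return float(signed[k]), (int(a[k]), int(b[k]))


def scan_maxima(X: np.ndarray, L: int, mode: str) -> np.ndarray:
    """Vectorized scan maxima for many subjects: X (n, T) -> U (n,)."""
    X = np.asarray(X, dtype=float)
    return _signed(_all_stats(X, X.shape[1], L), mode).max(axis=1)


@dataclass(frozen=True)
class NullTable:
    """Sorted Monte-Carlo draws of the scan maximum under i.i.d. N(0,1) input.

    The null distribution depends only on (T, L, mode), so one table serves
    every subject of every permutation of every dataset with that geometry.
    """

    T: int
    L: int
    mode: str
    draws: np.ndarray
    n_sim: int
    seed: int

    def __post_init__(self):
        draws = np.asarray(self.draws, dtype=float)
        if draws.shape != (self.n_sim,):
            raise ValueError("draws length must equal n_sim")
        if np.any(np.diff(draws) < 0):
            raise ValueError("draws must be sorted ascending")
        object.__setattr__(self, "draws", draws)

    def save(self, path) -> None:
        np.savez_compressed(
            path,
            draws=self.draws,
            meta=np.array([self.T, self.L, self.n_sim, self.seed], dtype=np.int64),
            mode=np.array(self.mode),
        )

    @classmethod
    def load(cls, path) -> "NullTable":
        with np.load(path, allow_pickle=False) as z:
            T, L, n_sim, seed = (int(v) for v in z["meta"])
            return cls(T, L, str(z["mode"]), z["draws"], n_sim, seed)


def build_null_table(
    T: int,
    L: int,
    mode: str = "both",
    n_sim: int = 10**6,
    seed: int = 0,
    cache_dir=None,
    chunk: int = 20_000,
) -> NullTable:
    """Simulate the null distribution of the scan maximum.

    Draws ``n_sim`` i.i.d. standard-normal vectors of length T and records the
    mode-signed scan maximum of each.  With ``cache_dir`` the table is stored
    on disk keyed by (T, L, mode, n_sim, seed) and reloaded on repeat calls.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    if n_sim < 10**3:
        raise ValueError("n_sim must be at least 1000")
    path = None
    if cache_dir is not None:
        os.makedirs(cache_dir, exist_ok=True)
        path = os.path.join(
            cache_dir, f"nulltable_T{T}_L{L}_{mode}_n{n_sim}_s{seed}.npz"
        )
        if os.path.exists(path):
            return NullTable.load(path)
    rng = np.random.default_rng(seed)
    out = np.empty(n_sim)
    n_intervals = len(_intervals(T, L)[0])
    chunk = max(1, min(chunk, int(2e7 / n_intervals)))  # bound peak memory
    done = 0
    while done < n_sim:
        k = min(chunk, n_sim - done)
        out[done : done + k] = scan_maxima(rng.standard_normal((k, T)), L, mode)
        done += k
    out.sort()
    table = NullTable(T, L, mode, out, n_sim, seed)
    if path is not None:
        table.save(path)
    return table


def mc_pvalue(U0, table: NullTable):
    """Permutation-style Monte-Carlo p-value (1 + #{draws >= U0}) / (n_sim + 1).

    Vectorized over U0.  Never returns 0; the floor is 1/(n_sim+1).
    """
    U0 = np.asarray(U0, dtype=float)
    n_ge = table.n_sim - np.searchsorted(table.draws, U0, side="left")
    p = (1.0 + n_ge) / (table.n_sim + 1.0)
    return float(p) if p.ndim == 0 else p


_LAMBDA = -0.583


def siegmund_pvalue(U0: float, T: int, L: int) -> float:
    """Random-walk analytic approximation to the scan-maximum tail probability.

    Evaluates 2*T*U0*lambda^-2*phi(U0)*[(s1-1)e^s1 - (s2-1)e^s2]/8 with
    lambda = -0.583, s1 = 2*lambda*U0/L - 1, s2 = 2*lambda*U0/T + 1.  As
    written this bracket is negative over the practically relevant range, so
    the magnitude is reported, clipped to (0, 1].  Reliable only for large
    regions (it degrades badly for T <= 50); Monte-Carlo tables are the
    authoritative route and this function is diagnostic.
    """
    if U0 <= 0:
        raise ValueError("U0 must be positive")
    if T <= 50:
        raise ValueError("approximation is unreliable for T <= 50")
    s1 = 2.0 * _LAMBDA * U0 / L - 1.0
    s2 = 2.0 * _LAMBDA * U0 / T + 1.0
    val = (
        2.0 * T * U0 * _LAMBDA**-2 * norm.pdf(U0)
        * ((s1 - 1.0) * np.exp(s1) - (s2 - 1.0) * np.exp(s2)) / 8.0
    )
    return float(np.clip(np.abs(val), np.finfo(float).tiny, 1.0))


def siegmund_mc_diagnostic(T: int, L: int, u_grid, n_sim: int = 10**5, seed: int = 0):
    """Tabulate analytic vs Monte-Carlo tail probabilities on a grid of U0.

    Returns a DataFrame with columns u, p_siegmund, p_mc, ratio — used to
    judge how far the analytic form is from the simulated truth.
    """
    table = build_null_table(T, L, "both", n_sim=n_sim, seed=seed)
    rows = []
    for u in np.asarray(u_grid, dtype=float):
        ps = siegmund_pvalue(u, T, L)
        pm = mc_pvalue(u, table)
        rows.append((u, ps, pm, ps / pm))
    return pd.DataFrame(rows, columns=["u", "p_siegmund", "p_mc", "ratio"])


def subject_region_pvalues(
    matrix,
    region,
    params: ScanParams,
    tables: dict,
    baf_params=None,
    eta2: float = 0.05,
) -> pd.DataFrame:
    """Per-subject scan maxima and evidence p-values for one region.

    Parameters
    ----------
    matrix : IntensityMatrix
        Must be normalized (LRR standard normal under the diploid null).
    region : (start, stop)
        0-based half-open probe index range; its length must match the
        null tables' T.
    tables : dict
        Mode -> NullTable for each mode to evaluate (any subset of
        both/deletion/duplication).
    baf_params : BafCombination or None
        When given, duplication and both modes scan the LRR+BAF fused series
        Z; the deletion scan always uses LRR alone.  None disables fusion.

    Returns a DataFrame with one row per subject: U/U_minus/U_plus, the
    corresponding p-values, and the arg-max interval per mode (1-based probe
    offsets within the region).
    """
    if not matrix.normalized:
        raise ValueError("matrix must be normalized before scanning")
    start, stop = region
    X = matrix.lrr[:, start:stop]
    T = X.shape[1]
    for mode, t in tables.items():
        if t.T != T or t.L != params.L or t.mode != mode:
            raise ValueError(f"null table for mode {mode} does not match (T={T}, L={params.L})")
    if baf_params is not None:
        from .baf import combine_lrr_baf

        Z = combine_lrr_baf(X, matrix.baf[:, start:stop], baf_params, eta2)
    else:
        Z = X
    a, b, _ = _intervals(T, params.L)
    out = {"subject_id": list(matrix.subjects)}
    series = {"deletion": X, "duplication": Z, "both": Z}
    col = {"both": ("U", "p"), "deletion": ("U_minus", "p_minus"),
           "duplication": ("U_plus", "p_plus")}
    for mode, table in tables.items():
        signed = _signed(_all_stats(series[mode], T, params.L), mode)
        k = np.argmax(signed, axis=1)
        U = signed[np.arange(len(k)), k]
        ucol, pcol = col[mode]
        out[ucol] = U
        out[pcol] = mc_pvalue(U, table)
        out[f"interval_{mode}"] = [(int(a[j]), int(b[j])) for j in k]
    return pd.DataFrame(out)
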