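"""Fusing B Allele Frequencies with LRR for duplication detection.

Under a single-copy duplication (CN3) the BAF of a heterozygous probe
clusters near 1/3 or 2/3 instead of 1/2, so the folded distance
d = |b - 1/2| carries duplication evidence.  For informative BAFs
(b in [0.2, 0.8]) we map d to a standard-normal quantile

    Y = ndtri(2*ndtr(d / eta2) - 1),

the probability-integral transform of d under the copy-neutral heterozygote
model b ~ N(1/2, eta2).  Y ~ N(0,1) for diploid heterozygotes and is large
when b sits near 1/3 or 2/3.  Y is fused with the standardized LRR X as

    Z = (X + Y) / sqrt(2 + 2*rho),      rho = -0.05,

with rho the empirically reported copy-neutral LRR-BAF correlation
(denominator 1.38); uninformative probes pass X through unchanged.
Z ~ N(0,1) under the diploid null, so scan null tables built for X apply
to Z as well.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import ndtr, ndtri

__all__ = ["BafCombination", "is_informative", "baf_quantile", "combine_lrr_baf"]


@dataclass(frozen=True)
class BafCombination:
    """Constants of the LRR-BAF fusion.

    window
        Informative BAF interval; outside it the BAF is consistent with a
        homozygote under every copy state and carries no duplication signal.
    rho
        Copy-neutral correlation between X and Y; a fixed method constant,
        not re-estimated from data.
    y_cap
        Clipping bound on |Y|: b exactly at 1/2 would map to -inf.
    """

    window: tuple = (0.2, 0.8)
    rho: float = -0.05
    y_cap: float = 5.0

    def __post_init__(self):
        lo, hi = self.window
        if not lo < hi:
            raise ValueError("window lower bound must be below upper bound")
        if not (-1.0 < self.rho < 1.0) or not 0 < self.denom < 2:
            raise ValueError("sqrt(2 + 2*rho) must lie in (0, 2)")
        if not (np.isfinite(self.y_cap) and self.y_cap > 3):
            raise ValueError("y_cap must be finite and > 3")

    @property
    def denom(self) -> float:
        """Fusion denominator sqrt(2 + 2*rho), ~1.38 at rho = -0.05."""
        return float(np.sqrt(2.0 + 2.0 * self.rho))


def is_informative(b, window=(0.2, 0.8)):
    """True where the BAF is present and inside the informative window."""
    b = np.asarray(b, dtype=float)
    lo, hi = window
    with np.errstate(invalid="ignore"):
        ok = np.isfinite(b) & (b >= lo) & (b <= hi)
    return bool(ok) if ok.ndim == 0 else ok


def baf_quantile(b, eta2: float, y_cap: float = 5.0):
    """Standard-normal evidence quantile Y of an informative BAF.

    Y = ndtri(2*ndtr(|b - 0.5| / eta2) - 1), clipped to [-y_cap, y_cap].
    eta2 is the heterozygote BAF standard deviation.
    """
    if eta2 <= 0:
        raise ValueError("eta2 must be positive")
    b = np.asarray(b, dtype=float)
    if not np.all(is_informative(b)):
        raise ValueError("baf_quantile requires informative BAF values")
    d = np.abs(b - 0.5)
    with np.errstate(divide="ignore"):
        y = ndtri(2.0 * ndtr(d / eta2) - 1.0)
    y = np.clip(y, -y_cap, y_cap)
    return float(y) if y.ndim == 0 else y


def combine_lrr_baf(x, b, comb: BafCombination = BafCombination(), eta2: float = 0.05):
    """Fuse standardized LRR with BAF evidence: Z = (X + Y)/denom, else Z = X.

    Vectorized; ``b`` may contain NaN (missing), which passes X through.
    """
    x = np.asarray(x, dtype=float)
    b = np.asarray(b, dtype=float)
    if x.shape != b.shape:
        raise ValueError("x and b must have the same shape")
    info = is_informative(b, comb.window)
    z = x.astype(float).copy()
    if np.isscalar(info) or info.ndim == 0:
        if info:
            return (x + baf_quantile(b, eta2, comb.y_cap)) / comb.denom
        return float(x)
    if np.any(info):
        y = baf_quantile(b[info], eta2, comb.y_cap)
        z[info] = (x[info] + y) / comb.denom
    return z
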