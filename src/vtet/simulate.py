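"""Synthetic case-control SNP-array intensity data with planted CNVs.

The generator mirrors the two-stage design used to validate the test:

1. **CNV events.**  With risk-CNV frequency f and odds ratio OR, carriers are
   Bernoulli(f) among controls and Bernoulli(f_plus) among cases, where
   f_plus = OR*f / (OR*f + 1 - f).  Each carrier receives one CNV covering
   ``cnv_len`` consecutive probes, placed uniformly at random in the region
   or at a fixed recurrent interval shared by all carriers.

2. **Intensities given copy state.**  Per-probe genotypes come from two
   haplotypes with probe-specific B-allele frequencies (by default MAF ~
   U[0.05, 0.5], linkage-free).  A hemizygous deletion (CN1) retains one
   haplotype chosen uniformly; a duplication (CN3) doubles one haplotype
   chosen uniformly.  LRR ~ N(mu_c, sigma_c) with the Illumina-550k-calibrated
   parameters mu = (-3, -0.45, 0, 0.30, 0.50), sigma = (1, 0.26, 0.16, 0.19,
   0.22) for copy numbers 0..4.  BAF given genotype:

   ======================  =============================================
   copy number 0           U[0, 1]
   A / AA / AAA            0.5 point mass at 0 + folded N(0, eta1), eta1=0.02
   B / BB / BBB            mirrored at 1
   AB                      N(1/2, eta2), eta2=0.05
   AAB                     N(1/3, eta2)
   ABB                     N(2/3, eta2)
   ======================  =============================================

   BAF is clipped to [0, 1].  CN4 parameters are carried for completeness
   but no CN4 events are generated.

The module also provides the known-truth "ideal" Fisher test (the power
ceiling of any intensity-based procedure) and Monte-Carlo power estimation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .baf import BafCombination
from .core import VtetParams, fisher_exact, permutation_test
from .io import IntensityMatrix, Phenotype, ProbeMap
from .scan import ScanParams, build_null_table, subject_region_pvalues

__all__ = [
    "NoiseModel",
    "SimulationConfig",
    "TruthSet",
    "case_frequency",
    "place_cnv",
    "simulate_genotypes",
    "simulate_intensities",
    "simulate_study",
    "ideal_test",
    "estimate_power",
    "load_haplotype_pool",
]


@dataclass(frozen=True)
class NoiseModel:
    """LRR means/SDs per copy number 0..4 and BAF SDs (homozygote, heterozygote)."""

    mu: tuple = (-3.0, -0.45, 0.0, 0.30, 0.50)
    sigma: tuple = (1.0, 0.26, 0.16, 0.19, 0.22)
    eta1: float = 0.02
    eta2: float = 0.05

    def __post_init__(self):
        if len(self.mu) != 5 or len(self.sigma) != 5:
            raise ValueError("mu and sigma must each have 5 entries (CN0..CN4)")
        if any(s <= 0 for s in self.sigma) or self.eta1 <= 0 or self.eta2 <= 0:
            raise ValueError("all scale parameters must be positive")


@dataclass
class SimulationConfig:
    """One replicate's design: sample sizes, region, CNV frequency and effect.

    ``standardize=True`` returns LRRs pre-standardized with the diploid
    parameters, X = (lrr - mu2)/sigma2, marking the matrix normalized (the
    simulation-pipeline analogue of genome-wide median/SD normalization).
    Genotypes come from the parametric MAF model unless ``haplotype_pool``
    (a boolean (n_haplotypes, T) array, e.g. a phased reference panel) is
    given, in which case each subject draws two pool haplotypes at random.
    """

    m: int = 1000
    n: int = 1000
    T: int = 20
    L: int = 3
    cnv_len: int = 5
    f: float = 0.01
    OR: float = 1.0
    cnv_type: str = "CN1"
    placement: str = "random"
    maf_range: tuple = (0.05, 0.5)
    haplotype_pool: np.ndarray | None = None
    noise: NoiseModel = field(default_factory=NoiseModel)
    seed: int = 0
    standardize: bool = True

    def __post_init__(self):
        if self.cnv_type not in ("CN1", "CN3", "mixed"):
            raise ValueError("cnv_type must be CN1, CN3 or mixed")
        if self.placement not in ("random", "recurrent"):
            raise ValueError("placement must be random or recurrent")
        if not self.L <= self.cnv_len <= self.T:
            raise ValueError("need L <= cnv_len <= T")
        if not 0 <= self.f < 1:
            raise ValueError("f must be in [0, 1)")
        if self.OR <= 0:
            raise ValueError("OR must be positive")
        if self.haplotype_pool is not None:
            pool = np.asarray(self.haplotype_pool, dtype=bool)
            if pool.ndim != 2 or pool.shape[1] != self.T or pool.shape[0] < 2:
                raise ValueError(
                    "haplotype_pool must have shape (n_haplotypes >= 2, T)"
                )
            self.haplotype_pool = pool


@dataclass
class TruthSet:
    """Planted ground truth: carrier flags, per-probe copy numbers, intervals.

    ``interval`` holds the 1-based closed probe interval per carrier (and
    (0, 0) for non-carriers); ``dup_hap`` the duplicated/retained haplotype
    index per subject (-1 where not applicable).
    """

    carrier: np.ndarray
    copy_number: np.ndarray
    interval: np.ndarray
    cnv_type: np.ndarray
    dup_hap: np.ndarray


def load_haplotype_pool(path) -> np.ndarray:
    """Read a phased haplotype pool: TSV of 0/1, one haplotype per row."""
    pool = np.loadtxt(path, delimiter="\t", dtype=np.int64)
    pool = np.atleast_2d(pool)
    if not np.isin(pool, (0, 1)).all():
        raise ValueError("haplotype pool entries must be 0 or 1")
    return pool.astype(bool)


def case_frequency(f: float, OR: float) -> float:
    """Risk-CNV frequency in cases, f_plus = OR*f / (OR*f + 1 - f)."""
    if not 0 <= f < 1:
        raise ValueError("f must be in [0, 1)")
    if OR <= 0:
        raise ValueError("OR must be positive")
    return OR * f / (OR * f + 1.0 - f)


def place_cnv(T: int, cnv_len: int, placement: str, rng, fixed=None):
    """One CNV interval (1-based closed).

    random: uniform start in {1..T-cnv_len+1}; recurrent: a fixed interval,
    centered in the region by default, identical for every carrier.
    """
    if cnv_len > T:
        raise ValueError("cnv_len exceeds region length")
    if placement == "random":
        a = int(rng.integers(1, T - cnv_len + 2))
        return a, a + cnv_len - 1
    if placement == "recurrent":
        if fixed is not None:
            return fixed
        a = (T - cnv_len) // 2 + 1
        return a, a + cnv_len - 1
    raise ValueError("placement must be random or recurrent")


def simulate_genotypes(T: int, maf, rng):
    """Two haplotypes of B-allele indicators, independent across probes.

    ``maf`` is a per-probe B-allele frequency vector (or scalar).
    """
    maf = np.broadcast_to(np.asarray(maf, dtype=float), (T,))
    return rng.random((2, T)) < maf[None, :]


def _sample_baf(c, nb, noise: NoiseModel, rng) -> np.ndarray:
    """BAF per probe given copy number ``c`` and B-allele count ``nb``."""
    c = np.asarray(c)
    nb = np.asarray(nb)
    baf = np.empty(c.shape, dtype=float)

    cn0 = c == 0
    baf[cn0] = rng.random(int(cn0.sum()))

    hom_a = (c > 0) & (nb == 0)
    hom_b = (c > 0) & (nb == c)
    for mask, at_one in ((hom_a, False), (hom_b, True)):
        k = int(mask.sum())
        if k == 0:
            continue
        vals = np.abs(rng.normal(0.0, noise.eta1, size=k))
        vals[rng.random(k) < 0.5] = 0.0  # point mass at the boundary
        baf[mask] = 1.0 - vals if at_one else vals

    het = {(2, 1): 0.5, (3, 1): 1.0 / 3.0, (3, 2): 2.0 / 3.0}
    for (cc, bb), center in het.items():
        mask = (c == cc) & (nb == bb)
        k = int(mask.sum())
        if k:
            baf[mask] = rng.normal(center, noise.eta2, size=k)
    return np.clip(baf, 0.0, 1.0)


def simulate_intensities(copy_number, haplotypes, hap_choice, noise: NoiseModel, rng):
    """LRR and BAF for one subject given copy states and haplotypes.

    ``hap_choice`` selects the retained haplotype under CN1 and the
    duplicated haplotype under CN3.
    """
    c = np.asarray(copy_number)
    hap = np.asarray(haplotypes, dtype=bool)
    if hap.shape != (2, c.size):
        raise ValueError("haplotypes must have shape (2, T)")
    if np.any((c < 0) | (c > 4)):
        raise ValueError("copy numbers must be in 0..4")
    nb = hap.sum(axis=0).astype(np.int64)  # diploid B count
    nb = np.where(c == 1, hap[hap_choice], nb)
    nb = np.where(c == 3, hap.sum(axis=0) + hap[hap_choice], nb)
    nb = np.where(c == 0, 0, nb)
    mu = np.asarray(noise.mu)[c]
    sigma = np.asarray(noise.sigma)[c]
    lrr = rng.normal(mu, sigma)
    baf = _sample_baf(c, nb, noise, rng)
    return lrr, baf


def simulate_study(config: SimulationConfig):
    """One full case-control replicate.

    Returns ``(IntensityMatrix, Phenotype, TruthSet)``.  Subject order is
    cases first, then controls.
    """
    rng = np.random.default_rng(config.seed)
    m, n, T = config.m, config.n, config.T
    N = m + n
    fp = case_frequency(config.f, config.OR)
    carrier = np.concatenate(
        [rng.random(m) < fp, rng.random(n) < config.f]
    )

    cn = np.full((N, T), 2, dtype=np.int64)
    interval = np.zeros((N, 2), dtype=np.int64)
    ctype = np.array(["CN2"] * N, dtype=object)
    dup_hap = np.full(N, -1, dtype=np.int64)
    recurrent_iv = None
    if config.placement == "recurrent":
        a = (T - config.cnv_len) // 2 + 1
        recurrent_iv = (a, a + config.cnv_len - 1)
    for i in np.flatnonzero(carrier):
        a, b = place_cnv(T, config.cnv_len, config.placement, rng, recurrent_iv)
        if config.cnv_type == "mixed":
            t = "CN1" if rng.random() < 0.5 else "CN3"
        else:
            t = config.cnv_type
        cn[i, a - 1 : b] = 1 if t == "CN1" else 3
        interval[i] = (a, b)
        ctype[i] = t
        dup_hap[i] = int(rng.integers(2))

    # vectorized equivalent of simulate_intensities across all subjects
    if config.haplotype_pool is not None:
        picks = rng.integers(len(config.haplotype_pool), size=(N, 2))
        hap = config.haplotype_pool[picks]
    else:
        lo, hi = config.maf_range
        maf = rng.uniform(lo, hi, size=T)
        hap = rng.random((N, 2, T)) < maf[None, None, :]
    hap_sel = hap[np.arange(N), np.maximum(dup_hap, 0)]
    nb = hap.sum(axis=1)
    nb = np.where(cn == 1, hap_sel, nb)
    nb = np.where(cn == 3, hap.sum(axis=1) + hap_sel, nb)
    nb = np.where(cn == 0, 0, nb)
    noise = config.noise
    lrr = rng.normal(np.asarray(noise.mu)[cn], np.asarray(noise.sigma)[cn])
    baf = _sample_baf(cn, nb, noise, rng)

    mu2, s2 = config.noise.mu[2], config.noise.sigma[2]
    if config.standardize:
        lrr = (lrr - mu2) / s2
    subjects = [f"case_{i:05d}" for i in range(m)] + [
        f"ctrl_{i:05d}" for i in range(n)
    ]
    probes = ProbeMap(
        np.array([f"rs{t + 1:06d}" for t in range(T)], dtype=object),
        np.array(["1"] * T, dtype=object),
        np.arange(1, T + 1) * 1000,
    )
    matrix = IntensityMatrix(
        subjects, probes, lrr, baf, normalized=config.standardize
    )
    pheno = Phenotype(
        np.array(subjects, dtype=object),
        np.array(["case"] * m + ["control"] * n, dtype=object),
    )
    truth = TruthSet(carrier, cn, interval, ctype, dup_hap)
    return matrix, pheno, truth


def ideal_test(truth: TruthSet, pheno: Phenotype, sided: str = "one") -> float:
    """Fisher exact p-value on the true carrier status (oracle power ceiling)."""
    case = pheno.label == "case"
    a = int(np.sum(truth.carrier & case))
    b = int(np.sum(truth.carrier & ~case))
    return fisher_exact(a, b, int(case.sum()), int((~case).sum()), sided)


_MODE_FOR_TYPE = {"CN1": "deletion", "CN3": "duplication", "mixed": "both"}


def estimate_power(
    config: SimulationConfig,
    n_replicates: int,
    alpha: float,
    methods=("vtet", "ideal"),
    seed: int = 0,
    n_perm: int = 10_000,
    null_draws: int = 10**5,
    mode: str | None = None,
    use_baf: bool = True,
):
    """Monte-Carlo power of VTET and/or the ideal known-truth test.

    Runs ``n_replicates`` independent studies drawn from ``config`` (the
    replicate seeds derive from ``seed``), tests each at level ``alpha`` and
    returns ``{method: (power, mc_se)}``.  The scan mode defaults to the one
    matching ``config.cnv_type``.  One null table (``null_draws`` draws) is
    shared across all replicates.
    """
    mode = mode or _MODE_FOR_TYPE[config.cnv_type]
    table = build_null_table(
        config.T, config.L, mode, n_sim=null_draws, seed=seed + 1
    )
    tables = {mode: table}
    pcol = {"both": "p", "deletion": "p_minus", "duplication": "p_plus"}[mode]
    baf_params = BafCombination() if (use_baf and mode != "deletion") else None
    ss = np.random.SeedSequence(seed)
    rej = {meth: 0 for meth in methods}
    for r, child in enumerate(ss.spawn(n_replicates)):
        rep_seed = int(child.generate_state(1)[0] % (2**31 - 1))
        cfg = SimulationConfig(**{**config.__dict__, "seed": rep_seed})
        matrix, pheno, truth = simulate_study(cfg)
        if "ideal" in rej and ideal_test(truth, pheno) <= alpha:
            rej["ideal"] += 1
        if "vtet" in rej:
            res = subject_region_pvalues(
                matrix, (0, config.T), ScanParams(config.L, mode), tables,
                baf_params=baf_params, eta2=config.noise.eta2,
            )
            vres = permutation_test(
                res[pcol].to_numpy(),
                pheno.case_mask(matrix.subjects),
                VtetParams(seed=rep_seed, max_permutations=n_perm),
            )
            if vres.perm_p <= alpha:
                rej["vtet"] += 1
    out = {}
    for meth, k in rej.items():
        p = k / n_replicates
        out[meth] = (p, float(np.sqrt(p * (1 - p) / n_replicates)))
    return out
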