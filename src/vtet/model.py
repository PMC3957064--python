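"""Model/Results front end for region-level and genome-wide CNV association.

:class:`RegionCNVTest` wraps the full per-region pipeline — subject-level
scan evidence, variable-threshold Fisher tests, permutation significance —
behind a ``fit()`` returning :class:`RegionCNVTestResults` with a
``summary()`` table.  :class:`GenomeCNVScan` does the same for the
segment-tiled genome-wide scan.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .baf import BafCombination
from .core import VtetParams, permutation_test
from .genome import bonferroni_threshold, partition_segments, qq_points, scan_genome
from .io import IntensityMatrix, Phenotype
from .scan import ScanParams, build_null_table, subject_region_pvalues

__all__ = [
    "RegionCNVTest",
    "RegionCNVTestResults",
    "GenomeCNVScan",
    "GenomeCNVScanResults",
]

_PCOL = {"both": "p", "deletion": "p_minus", "duplication": "p_plus"}


class RegionCNVTest:
    """CNV association test for one genomic region.

    Parameters
    ----------
    intensity : IntensityMatrix
        Normalized intensities.
    phenotype : Phenotype
        Case/control labels covering every subject.
    region : (start, stop) or None
        0-based half-open probe index range; None means all probes.
    mode : {'both', 'deletion', 'duplication'}
        Which CNV class to test.
    L : int
        Minimum CNV span in probes (>= 3).
    use_baf : bool
        Fuse BAF evidence into duplication/both scans.
    """

    def __init__(
        self,
        intensity: IntensityMatrix,
        phenotype: Phenotype,
        region=None,
        mode: str = "both",
        L: int = 3,
        use_baf: bool = True,
        vtet_params: VtetParams | None = None,
        baf_params: BafCombination | None = None,
    ):
        self.intensity = intensity
        self.phenotype = phenotype
        self.region = region if region is not None else (0, intensity.n_probes)
        self.mode = mode
        self.scan_params = ScanParams(L, mode)
        self.use_baf = use_baf
        self.vtet_params = vtet_params or VtetParams()
        self.baf_params = baf_params or BafCombination()

    def fit(
        self,
        null_table=None,
        null_draws: int = 10**5,
        seed: int | None = None,
        cache_dir=None,
    ) -> "RegionCNVTestResults":
        """Run the scan, the threshold grid and the permutation test."""
        start, stop = self.region
        T = stop - start
        seed = self.vtet_params.seed if seed is None else seed
        if null_table is None:
            null_table = build_null_table(
                T, self.scan_params.L, self.mode, n_sim=null_draws,
                seed=seed, cache_dir=cache_dir,
            )
        baf_params = (
            self.baf_params if (self.use_baf and self.mode != "deletion") else None
        )
        scan = subject_region_pvalues(
            self.intensity, self.region, self.scan_params,
            {self.mode: null_table}, baf_params=baf_params,
        )
        params = VtetParams(
            expected_false=self.vtet_params.expected_false,
            min_successes=self.vtet_params.min_successes,
            max_permutations=self.vtet_params.max_permutations,
            sided=self.vtet_params.sided,
            seed=seed,
        )
        vres = permutation_test(
            scan[_PCOL[self.mode]].to_numpy(),
            self.phenotype.case_mask(self.intensity.subjects),
            params,
        )
        return RegionCNVTestResults(self, scan, vres, null_table)


class RegionCNVTestResults:
    """Fitted region test: per-subject evidence and the VTET outcome.

    Attributes
    ----------
    scan : DataFrame
        Per-subject scan maxima, evidence p-values and best intervals.
    thresholds, count_cases, count_controls, fisher_p : arrays
        The variable-threshold grid and its 2x2 tables.
    Q, perm_p, n_perm_used
        Minimum Fisher p-value and its permutation significance.
    """

    def __init__(self, model, scan, vres, null_table):
        self.model = model
        self.scan = scan
        self.null_table = null_table
        self.thresholds = vres.thresholds
        self.count_cases = vres.count_cases
        self.count_controls = vres.count_controls
        self.fisher_p = vres.fisher_p
        self.Q = vres.Q
        self.perm_p = vres.perm_p
        self.n_perm_used = vres.n_perm_used

    def threshold_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "q": self.thresholds,
                "carriers_cases": self.count_cases,
                "carriers_controls": self.count_controls,
                "fisher_p": self.fisher_p,
            }
        )

    def summary(self) -> str:
        m = self.model.phenotype.m
        n = self.model.phenotype.n
        start, stop = self.model.region
        lines = [
            "Variable Threshold Exact Test (region CNV association)",
            "=" * 58,
            f"Mode: {self.model.mode:<12} Probes: [{start}, {stop})   "
            f"L = {self.model.scan_params.L}",
            f"Cases: {m}   Controls: {n}   "
            f"Null table: {self.null_table.n_sim} draws",
            "-" * 58,
            f"{'q':>12} {'cases':>8} {'controls':>9} {'Fisher p':>12}",
        ]
        for q, a, b, p in zip(
            self.thresholds, self.count_cases, self.count_controls, self.fisher_p
        ):
            lines.append(f"{q:>12.3e} {a:>8d} {b:>9d} {p:>12.4g}")
        lines += [
            "-" * 58,
            f"Q (min Fisher p): {self.Q:.4g}",
            f"Permutation p-value: {self.perm_p:.4g} "
            f"({self.n_perm_used} permutations)",
            "=" * 58,
        ]
        return "\n".join(lines)


class GenomeCNVScan:
    """Segment-tiled genome-wide CNV association scan."""

    def __init__(
        self,
        intensity: IntensityMatrix,
        phenotype: Phenotype,
        segment_size: int = 50,
        modes=("deletion", "duplication", "both"),
        L: int = 3,
        use_baf: bool = True,
        vtet_params: VtetParams | None = None,
    ):
        self.intensity = intensity
        self.phenotype = phenotype
        self.segments = partition_segments(intensity.probes, segment_size, L)
        self.modes = tuple(modes)
        self.L = L
        self.use_baf = use_baf
        self.vtet_params = vtet_params or VtetParams()

    def fit(
        self, n_sim: int = 10**5, seed: int = 0, cache_dir=None, checkpoint_dir=None
    ) -> "GenomeCNVScanResults":
        table = scan_genome(
            self.intensity,
            self.phenotype,
            self.segments,
            modes=self.modes,
            L=self.L,
            vtet_params=self.vtet_params,
            n_sim=n_sim,
            seed=seed,
            use_baf=self.use_baf,
            cache_dir=cache_dir,
            checkpoint_dir=checkpoint_dir,
        )
        return GenomeCNVScanResults(self, table)


class GenomeCNVScanResults:
    """Genome-wide scan results table plus multiplicity and QQ diagnostics."""

    def __init__(self, model, table: pd.DataFrame):
        self.model = model
        self.table = table

    @property
    def n_segments(self) -> int:
        return len(self.model.segments)

    def bonferroni(self, alpha: float = 0.05) -> float:
        return bonferroni_threshold(alpha, self.n_segments)

    def significant(self, alpha: float = 0.05) -> pd.DataFrame:
        thr = self.bonferroni(alpha)
        return self.table[self.table["perm_p"] <= thr]

    def qq(self, mode: str):
        sub = self.table[self.table["mode"] == mode]
        return qq_points(sub["perm_p"].to_numpy())

    def plot_qq(self, mode: str, ax=None):
        import matplotlib.pyplot as plt

        exp, obs = self.qq(mode)
        if ax is None:
            _, ax = plt.subplots()
        ax.scatter(exp, obs, s=8)
        lim = max(float(exp.max(initial=1.0)), float(obs.max(initial=1.0)))
        ax.plot([0, lim], [0, lim], color="grey", lw=1)
        ax.set_xlabel("expected $-\\log_{10} p$")
        ax.set_ylabel("observed $-\\log_{10} p$")
        ax.set_title(f"QQ, {mode} mode")
        return ax

    def summary(self) -> str:
        lines = [
            "Genome-wide CNV association scan",
            "=" * 48,
            f"Segments: {self.n_segments}   Modes: {', '.join(self.model.modes)}",
            f"Bonferroni 5% threshold: {self.bonferroni(0.05):.3g}",
        ]
        for mode in self.model.modes:
            sub = self.table[self.table["mode"] == mode]
            lines.append(
                f"{mode:>12}: min perm p = {sub['perm_p'].min():.3g}, "
                f"p=1 fraction = {np.mean(sub['perm_p'] == 1.0):.2f}"
            )
        lines.append("=" * 48)
        return "\n".join(lines)
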