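"""Intensity-matrix, probe-map and phenotype I/O plus per-sample LRR normalization.

File dialects
-------------
* LRR / BAF matrices: tab-delimited, probe-id header row, subject-id first
  column.  Missing BAF entries are empty fields or ``NA`` and become NaN.
* Probe map: 3-column TSV ``probe_id  chromosome  position`` (1-based bp).
* Phenotype: 2-column TSV ``subject_id  label`` with label in {case, control}.
* Region results: BED-like TSV, 0-based half-open genomic coordinates.

Internally probe intervals are 1-based closed ``[a, b]`` (the scan-statistic
convention); every file written by this module uses BED coordinates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ProbeMap",
    "IntensityMatrix",
    "Phenotype",
    "read_probe_map",
    "read_phenotype",
    "read_intensity",
    "read_intensity_long",
    "write_intensity",
    "normalize_lrr",
    "write_region_results",
    "read_region_results",
]


@dataclass(frozen=True)
class ProbeMap:
    """Ordered SNP-probe annotation: id, chromosome and 1-based position.

    Probes are sorted by (chromosome, position); ids are unique and positions
    strictly increase within a chromosome.
    """

    probe_id: np.ndarray
    chromosome: np.ndarray
    position: np.ndarray

    def __post_init__(self) -> None:
        pid = np.asarray(self.probe_id, dtype=object)
        chrom = np.asarray(self.chromosome, dtype=object)
        pos = np.asarray(self.position, dtype=np.int64)
        if not (len(pid) == len(chrom) == len(pos)):
            raise ValueError("probe map columns have unequal lengths")
        if len(np.unique(pid)) != len(pid):
            raise ValueError("probe ids are not unique")
        for c in pd.unique(chrom):
            p = pos[chrom == c]
            if np.any(np.diff(p) <= 0):
                raise ValueError(
                    f"positions not strictly increasing on chromosome {c}"
                )
        object.__setattr__(self, "probe_id", pid)
        object.__setattr__(self, "chromosome", chrom)
        object.__setattr__(self, "position", pos)

    def __len__(self) -> int:
        return len(self.probe_id)

    @property
    def n_probes(self) -> int:
        return len(self.probe_id)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "probe_id": self.probe_id,
                "chromosome": self.chromosome,
                "position": self.position,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ProbeMap":
        df = df.sort_values(["chromosome", "position"], kind="stable")
        return cls(
            df["probe_id"].to_numpy(dtype=object),
            df["chromosome"].to_numpy(dtype=object),
            df["position"].to_numpy(),
        )


@dataclass
class IntensityMatrix:
    """Per-subject, per-probe Log R Ratio (LRR) and B Allele Frequency (BAF).

    ``lrr`` and ``baf`` are float arrays of shape (n_subjects, n_probes);
    missing BAF values are NaN.  ``normalized`` records whether per-subject
    LRR standardization has been applied.
    """

    subjects: list
    probes: ProbeMap
    lrr: np.ndarray
    baf: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        self.subjects = list(self.subjects)
        self.lrr = np.asarray(self.lrr, dtype=float)
        self.baf = np.asarray(self.baf, dtype=float)
        shape = (len(self.subjects), len(self.probes))
        if self.lrr.shape != shape:
            raise ValueError(
                f"lrr shape {self.lrr.shape} != (subjects, probes) {shape}"
            )
        if self.baf.shape != shape:
            raise ValueError(
                f"baf shape {self.baf.shape} != (subjects, probes) {shape}"
            )
        if len(set(self.subjects)) != len(self.subjects):
            raise ValueError("subject ids are not unique")
        with np.errstate(invalid="ignore"):
            bad = (self.baf < 0) | (self.baf > 1)
        if np.any(bad):
            i, t = np.argwhere(bad)[0]
            raise ValueError(
                f"BAF outside [0,1] for subject {self.subjects[i]}, "
                f"probe {self.probes.probe_id[t]}"
            )

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_probes(self) -> int:
        return len(self.probes)


@dataclass(frozen=True)
class Phenotype:
    """Case/control labels for the subjects of an intensity matrix."""

    subject_id: np.ndarray
    label: np.ndarray
    _index: dict = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        sid = np.asarray(self.subject_id, dtype=object)
        lab = np.asarray(self.label, dtype=object)
        if len(sid) != len(lab):
            raise ValueError("subject_id and label lengths differ")
        bad = set(lab) - {"case", "control"}
        if bad:
            raise ValueError(f"labels must be 'case' or 'control', got {bad}")
        if len(set(sid)) != len(sid):
            raise ValueError("duplicate subject ids in phenotype")
        object.__setattr__(self, "subject_id", sid)
        object.__setattr__(self, "label", lab)
        object.__setattr__(self, "_index", {s: l for s, l in zip(sid, lab)})

    @property
    def m(self) -> int:
        """Number of cases."""
        return int(np.sum(self.label == "case"))

    @property
    def n(self) -> int:
        """Number of controls."""
        return int(np.sum(self.label == "control"))

    def case_mask(self, subjects) -> np.ndarray:
        """Boolean case indicator aligned to ``subjects`` order.

        Raises if any subject lacks a label.
        """
        missing = [s for s in subjects if s not in self._index]
        if missing:
            raise KeyError(f"subjects without phenotype label: {missing[:5]}")
        return np.array([self._index[s] == "case" for s in subjects])


def read_probe_map(path) -> ProbeMap:
    df = pd.read_csv(path, sep="\t", dtype={"probe_id": str, "chromosome": str})
    required = {"probe_id", "chromosome", "position"}
    if not required.issubset(df.columns):
        raise ValueError(f"probe map must have columns {sorted(required)}")
    return ProbeMap.from_frame(df)


def read_phenotype(path) -> Phenotype:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"subject_id", "label"}.issubset(df.columns):
        raise ValueError("phenotype file must have columns subject_id, label")
    return Phenotype(df["subject_id"].to_numpy(object), df["label"].to_numpy(object))


def _read_matrix(path, probes: ProbeMap, what: str) -> tuple[list, np.ndarray]:
    df = pd.read_csv(
        path, sep="\t", index_col=0, na_values=["NA", ""],
        float_precision="round_trip",
    )
    known = set(probes.probe_id)
    unknown = [c for c in df.columns if c not in known]
    if unknown:
        raise ValueError(
            f"{what} matrix contains probe(s) absent from the map: {unknown[:5]}"
        )
    missing = [p for p in probes.probe_id if p not in set(df.columns)]
    if missing:
        raise ValueError(f"{what} matrix is missing probe(s): {missing[:5]}")
    df = df[list(probes.probe_id)]
    return list(df.index.astype(str)), df.to_numpy(dtype=float)


def read_intensity(lrr_path, baf_path, probe_map_path) -> IntensityMatrix:
    """Read LRR and BAF matrices, ordering probes per the probe map.

    Missing BAF entries become NaN (never zero).  Any probe present in a
    matrix but absent from the map, or vice versa, is an error naming it.
    """
    probes = read_probe_map(probe_map_path)
    subj_l, lrr = _read_matrix(lrr_path, probes, "LRR")
    subj_b, baf = _read_matrix(baf_path, probes, "BAF")
    if subj_l != subj_b:
        raise ValueError("LRR and BAF matrices list different subjects")
    return IntensityMatrix(subj_l, probes, lrr, baf)


def read_intensity_long(path, probe_map_path) -> IntensityMatrix:
    """Read a long-format (final-report style) intensity export.

    Expects tab-delimited columns ``subject_id``, ``probe_id``,
    ``lrr``, ``baf`` (one row per subject x probe); pivots to matrices in
    probe-map order.  Missing BAF entries stay NaN.
    """
    probes = read_probe_map(probe_map_path)
    df = pd.read_csv(
        path, sep="\t", na_values=["NA", ""], float_precision="round_trip",
        dtype={"subject_id": str, "probe_id": str},
    )
    required = {"subject_id", "probe_id", "lrr", "baf"}
    if not required.issubset(df.columns):
        raise ValueError(f"long format requires columns {sorted(required)}")
    unknown = sorted(set(df["probe_id"]) - set(probes.probe_id))
    if unknown:
        raise ValueError(f"long format contains unknown probe(s): {unknown[:5]}")
    lrr = df.pivot(index="subject_id", columns="probe_id", values="lrr")
    baf = df.pivot(index="subject_id", columns="probe_id", values="baf")
    missing = [p for p in probes.probe_id if p not in lrr.columns]
    if missing or lrr.isna().any().any():
        bad = missing or ["(incomplete subject rows)"]
        raise ValueError(f"long format is missing probe data: {bad[:5]}")
    cols = list(probes.probe_id)
    return IntensityMatrix(
        list(lrr.index),
        probes,
        lrr[cols].to_numpy(dtype=float),
        baf[cols].to_numpy(dtype=float),
    )


def write_intensity(matrix: IntensityMatrix, lrr_path, baf_path, probe_map_path=None):
    """Write matrices in the dialect :func:`read_intensity` reads.

    Uses full repr precision so a write/read round trip is bitwise lossless.
    """
    cols = list(matrix.probes.probe_id)
    for arr, path in ((matrix.lrr, lrr_path), (matrix.baf, baf_path)):
        pd.DataFrame(arr, index=matrix.subjects, columns=cols).to_csv(
            path, sep="\t", float_format="%.17g", index_label="subject_id"
        )
    if probe_map_path is not None:
        matrix.probes.to_frame().to_csv(probe_map_path, sep="\t", index=False)


def normalize_lrr(matrix: IntensityMatrix, robust: bool = False) -> IntensityMatrix:
    """Standardize each subject's genome-wide LRR to median 0 and unit scale.

    The scale estimate is the sample SD by default; with ``robust=True`` it is
    1.4826*MAD, which down-weights probes inside real CNVs.  BAF is untouched.
    Raises on already-normalized input and on zero-variance subjects.
    """
    if matrix.normalized:
        raise ValueError("matrix is already normalized")
    med = np.median(matrix.lrr, axis=1, keepdims=True)
    centered = matrix.lrr - med
    if robust:
        scale = 1.4826 * np.median(np.abs(centered), axis=1, keepdims=True)
    else:
        scale = np.std(centered, axis=1, ddof=1, keepdims=True)
    zero = np.flatnonzero(scale.ravel() <= 0)
    if zero.size:
        raise ValueError(
            f"zero-variance LRR for subject {matrix.subjects[zero[0]]}"
        )
    return replace(matrix, lrr=centered / scale, baf=matrix.baf.copy(), normalized=True)


def write_region_results(results: pd.DataFrame, path) -> None:
    """Write per-segment results as BED-like TSV (0-based half-open).

    ``results`` carries 1-based ``start``/``end`` genomic positions (inclusive)
    plus chromosome, probe span and per-mode statistics; the written ``start``
    column is ``start - 1``.
    """
    out = results.copy()
    required = {"chromosome", "start", "end"}
    if not required.issubset(out.columns):
        raise ValueError(f"results must have columns {sorted(required)}")
    out["start"] = out["start"].astype(np.int64) - 1
    out["end"] = out["end"].astype(np.int64)
    lead = ["chromosome", "start", "end"]
    out = out[lead + [c for c in out.columns if c not in lead]]
    out.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_region_results(path) -> pd.DataFrame:
    """Read a file written by :func:`write_region_results`, restoring 1-based starts."""
    df = pd.read_csv(
        path, sep="\t", dtype={"chromosome": str}, float_precision="round_trip"
    )
    df["start"] = df["start"].astype(np.int64) + 1
    return df
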