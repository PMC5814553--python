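"""Genotype containers, QC filters, mean imputation, and the VanRaden GRM.

The realized additive relationship matrix built here is the genetic
covariance kernel of every GBLUP fit downstream.  QC mirrors the standard
GBS pipeline filters: drop individuals and markers with excessive
missingness, then markers below a minor-allele-frequency floor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GenotypeMatrix",
    "RelationshipMatrix",
    "QCReport",
    "qc_filter",
    "mean_impute",
    "vanraden_grm",
]


class GenotypeError(ValueError):
    pass


@dataclass
class GenotypeMatrix:
    """n x p SNP dosages (0/1/2 counts of one allele), NaN for missing."""

    dosages: np.ndarray
    genotype_ids: list
    marker_ids: list

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.genotype_ids = [str(g) for g in self.genotype_ids]
        self.marker_ids = [str(m) for m in self.marker_ids]
        n, p = self.dosages.shape
        if len(self.genotype_ids) != n or len(self.marker_ids) != p:
            raise GenotypeError("id lengths do not match dosage matrix shape")
        if len(set(self.genotype_ids)) != n:
            dup = [g for g in self.genotype_ids if self.genotype_ids.count(g) > 1]
            raise GenotypeError(f"duplicate genotype ids: {sorted(set(dup))}")
        obs = self.dosages[~np.isnan(self.dosages)]
        if obs.size and (obs.min() < 0 or obs.max() > 2):
            raise GenotypeError("dosages must lie in [0, 2] or be missing")

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.dosages)

    @property
    def shape(self):
        return self.dosages.shape

    def allele_frequencies(self) -> np.ndarray:
        """Per-marker frequency of the counted allele, from non-missing calls."""
        return np.nanmean(self.dosages, axis=0) / 2.0

    def minor_allele_frequencies(self) -> np.ndarray:
        p = self.allele_frequencies()
        return np.minimum(p, 1.0 - p)


@dataclass
class RelationshipMatrix:
    """Realized additive relationship matrix A (n x n, unitless)."""

    values: np.ndarray
    genotype_ids: list

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.genotype_ids = [str(g) for g in self.genotype_ids]
        n = len(self.genotype_ids)
        if self.values.shape != (n, n):
            raise GenotypeError("relationship matrix must be square over the ids")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise GenotypeError("relationship matrix must be symmetric (1e-10)")

    def index_of(self, ids) -> np.ndarray:
        lookup = {g: i for i, g in enumerate(self.genotype_ids)}
        try:
            return np.array([lookup[str(g)] for g in ids], dtype=int)
        except KeyError as e:  # noqa: PERF203
            raise KeyError(f"unknown genotype id {e.args[0]!r}") from None


@dataclass
class QCReport:
    n_individuals_dropped_missing: int = 0
    n_markers_dropped_missing: int = 0
    n_markers_dropped_maf: int = 0
    dropped_individuals: list = field(default_factory=list)


def qc_filter(g: GenotypeMatrix, max_missing: float = 0.95,
              min_maf: float = 0.05) -> tuple[GenotypeMatrix, QCReport]:
    """Drop high-missingness individuals, then markers, then low-MAF markers.

    Defaults are the conventional GBS thresholds: individuals/markers with
    more than 95% missing calls are removed, then markers with minor-allele
    frequency below 5% (computed on non-missing calls).
    """
    if not (0 <= max_missing <= 1) or not (0 <= min_maf <= 0.5):
        raise GenotypeError("need 0 <= max_missing <= 1 and 0 <= min_maf <= 0.5")
    report = QCReport()
    miss = np.isnan(g.dosages)

    keep_ind = miss.mean(axis=1) <= max_missing
    report.n_individuals_dropped_missing = int((~keep_ind).sum())
    report.dropped_individuals = [gid for gid, k in zip(g.genotype_ids, keep_ind)
                                  if not k]
    dos = g.dosages[keep_ind]
    ids = [gid for gid, k in zip(g.genotype_ids, keep_ind) if k]

    miss = np.isnan(dos)
    keep_m = miss.mean(axis=0) <= max_missing
    report.n_markers_dropped_missing = int((~keep_m).sum())
    dos = dos[:, keep_m]
    markers = [m for m, k in zip(g.marker_ids, keep_m) if k]

    with np.errstate(invalid="ignore"):
        freq = np.nanmean(dos, axis=0) / 2.0
    maf = np.minimum(freq, 1.0 - freq)
    keep_f = ~(maf < min_maf)  # keeps all-missing columns only if max_missing == 1
    keep_f &= ~np.isnan(maf) | (min_maf == 0)
    report.n_markers_dropped_maf = int(keep_m.sum() - keep_f.sum())
    dos = dos[:, keep_f]
    markers = [m for m, k in zip(markers, keep_f) if k]

    if dos.shape[1] == 0:
        raise GenotypeError("QC removed all markers")
    return GenotypeMatrix(dos, ids, markers), report


def mean_impute(g: GenotypeMatrix) -> GenotypeMatrix:
    """Replace missing calls by the marker's mean dosage."""
    dos = g.dosages.copy()
    n_obs = (~np.isnan(dos)).sum(axis=0)
    if np.any(n_obs == 0):
        bad = [m for m, k in zip(g.marker_ids, n_obs) if k == 0]
        raise GenotypeError(f"cannot impute markers with no observed calls: {bad}")
    col_mean = np.nanmean(dos, axis=0)
    idx = np.where(np.isnan(dos))
    dos[idx] = col_mean[idx[1]]
    return GenotypeMatrix(dos, list(g.genotype_ids), list(g.marker_ids))


def vanraden_grm(g: GenotypeMatrix) -> RelationshipMatrix:
    """VanRaden method-1 genomic relationship matrix.

    A = W W' / (2 sum_k p_k (1 - p_k)) with W the dosage matrix centered by
    twice the observed allele frequency.  Monomorphic markers have a zero
    centered column and are excluded from the scale term.
    """
    if np.isnan(g.dosages).any():
        raise GenotypeError("impute missing dosages before building the GRM")
    p = g.dosages.mean(axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    if poly.sum() < 2:
        raise GenotypeError("need >= 2 polymorphic markers for the GRM")
    w = g.dosages - 2.0 * p
    scale = 2.0 * np.sum(p[poly] * (1.0 - p[poly]))
    a = (w @ w.T) / scale
    a = 0.5 * (a + a.T)
    return RelationshipMatrix(a, list(g.genotype_ids))
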