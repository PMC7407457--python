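"""SNP dosage matrices, marker quality control and the genomic relationship matrix.

The genomic relationship matrix (GRM) follows VanRaden's method 1: markers are
column-standardized (mean 0, population standard deviation 1) and

    G = X X' / p

with ``p`` the number of markers.  Under the divisor-``n`` standardization used
here the diagonal of G averages exactly 1 and trace(G) = n.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import numpy.typing as npt

__all__ = [
    "MarkerMatrix",
    "GRMatrix",
    "EmptyPanelError",
    "qc_filter",
    "impute_and_standardize",
    "compute_grm",
]


class EmptyPanelError(ValueError):
    """Raised when quality control removes every marker."""


@dataclass
class MarkerMatrix:
    """Biallelic SNP dosages for a set of genotypes.

    Parameters
    ----------
    genotype_ids : array of str
        Row labels, unique.
    marker_ids : array of str
        Column labels, unique.
    dosage : (n, p) float array
        Minor/alternate allele counts in {0, 1, 2}; missing calls are NaN.
    """

    genotype_ids: npt.NDArray
    marker_ids: npt.NDArray
    dosage: npt.NDArray[np.floating]

    def __post_init__(self) -> None:
        self.genotype_ids = np.asarray(self.genotype_ids, dtype=object)
        self.marker_ids = np.asarray(self.marker_ids, dtype=object)
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.ndim != 2:
            raise ValueError("dosage must be a 2-D matrix")
        n, p = self.dosage.shape
        if len(self.genotype_ids) != n or len(self.marker_ids) != p:
            raise ValueError("ID lengths do not match dosage shape")
        if len(set(self.genotype_ids)) != n:
            raise ValueError("genotype IDs must be unique")
        if len(set(self.marker_ids)) != p:
            raise ValueError("marker IDs must be unique")
        finite = self.dosage[~np.isnan(self.dosage)]
        if finite.size and not np.isin(finite, (0.0, 1.0, 2.0)).all():
            bad = finite[~np.isin(finite, (0.0, 1.0, 2.0))][0]
            raise ValueError(f"dosages must be 0, 1, 2 or missing; found {bad!r}")

    @property
    def n_genotypes(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosage.shape[1]

    @property
    def missing_mask(self) -> npt.NDArray[np.bool_]:
        return np.isnan(self.dosage)

    def missing_fraction(self) -> npt.NDArray[np.floating]:
        """Per-marker fraction of missing calls."""
        return self.missing_mask.mean(axis=0)

    def minor_allele_frequency(self) -> npt.NDArray[np.floating]:
        """Per-marker MAF computed on non-missing calls only.

        Markers with no non-missing calls get MAF 0 (they are always
        removed by any positive MAF threshold).
        """
        with np.errstate(invalid="ignore"):
            freq = np.nanmean(self.dosage, axis=0) / 2.0
        freq = np.where(np.isnan(freq), 0.0, freq)
        return np.minimum(freq, 1.0 - freq)


@dataclass
class GRMatrix:
    """Genomic relationship matrix with its genotype ordering."""

    genotype_ids: npt.NDArray
    G: npt.NDArray[np.floating]

    def __post_init__(self) -> None:
        self.genotype_ids = np.asarray(self.genotype_ids, dtype=object)
        self.G = np.asarray(self.G, dtype=float)
        n = len(self.genotype_ids)
        if self.G.shape != (n, n):
            raise ValueError("G must be square and match genotype_ids")
        if not np.allclose(self.G, self.G.T, atol=1e-10):
            raise ValueError("G must be symmetric")

    def index_of(self, ids) -> npt.NDArray[np.intp]:
        """Row positions of the given genotype IDs (raises on unknown IDs)."""
        lookup = {g: i for i, g in enumerate(self.genotype_ids)}
        try:
            return np.array([lookup[g] for g in ids], dtype=np.intp)
        except KeyError as exc:  # pragma: no cover - message formatting
            raise KeyError(f"genotype {exc.args[0]!r} not present in GRM") from exc


def qc_filter(
    markers: MarkerMatrix,
    max_missing: float = 0.5,
    min_maf: float = 0.03,
) -> MarkerMatrix:
    """Drop markers failing missingness or minor-allele-frequency control.

    A marker is removed when its missing fraction exceeds ``max_missing``
    (strictly) or its MAF is below ``min_maf`` (strictly); the defaults encode
    the conventional ">50% missing or MAF < 3%" rule.  Genotype rows are never
    touched.

    Raises
    ------
    EmptyPanelError
        If no marker survives.
    """
    miss = markers.missing_fraction()
    maf = markers.minor_allele_frequency()
    keep = (miss <= max_missing) & (maf >= min_maf)
    if not keep.any():
        raise EmptyPanelError(
            f"all {markers.n_markers} markers removed by QC "
            f"(max_missing={max_missing}, min_maf={min_maf})"
        )
    return MarkerMatrix(
        genotype_ids=markers.genotype_ids.copy(),
        marker_ids=markers.marker_ids[keep],
        dosage=markers.dosage[:, keep],
    )


def impute_and_standardize(markers: MarkerMatrix) -> npt.NDArray[np.floating]:
    """Marker-mean imputation followed by column standardization.

    Missing dosages are replaced by the marker mean; each column is then
    centered and divided by its population (divisor-n) standard deviation.

    Raises
    ------
    ValueError
        If a column has zero variance after imputation (such markers should
        have been removed by :func:`qc_filter`).
    """
    X = markers.dosage.copy()
    col_mean = np.nanmean(X, axis=0)
    nan_r, nan_c = np.nonzero(np.isnan(X))
    X[nan_r, nan_c] = col_mean[nan_c]
    X -= col_mean
    sd = X.std(axis=0, ddof=0)
    zero = sd <= 0
    if zero.any():
        bad = markers.marker_ids[zero][:5]
        raise ValueError(
            f"zero-variance marker column(s) after imputation: {list(bad)}; "
            "run qc_filter first"
        )
    X /= sd
    return X


def compute_grm(X: npt.NDArray[np.floating], genotype_ids=None) -> GRMatrix:
    """VanRaden method-1 G = XX'/p from a column-standardized marker matrix."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] == 0:
        raise ValueError("X must be a 2-D matrix with at least one marker")
    n, p = X.shape
    G = X @ X.T / p
    G = (G + G.T) / 2.0  # enforce exact symmetry
    if genotype_ids is None:
        genotype_ids = np.array([f"G{i + 1}" for i in range(n)], dtype=object)
    return GRMatrix(genotype_ids=genotype_ids, G=G)
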