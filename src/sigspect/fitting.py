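"""Signature refitting by non-negative least squares.

A sample spectrum v (96 counts) is decomposed against a fixed reference
catalog S (signatures x 96 probability rows) by solving

    minimize  || v - S^T e ||^2   subject to  e >= 0,

where e are the exposures in mutation-count units. The attained minimum —
the *sum of squared residuals* — is reported as ``r_norm``. The solver is
Lawson–Hanson active-set NNLS (scipy); solutions satisfy the KKT
conditions: the gradient component is zero for active signatures and
nonnegative for signatures held at zero.

Spectra are fitted as raw counts; by scale equivariance of the NNLS
problem, relative exposures are identical whether or not the spectrum is
normalized first.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import nnls as _scipy_nnls

from .channels import SBS96_LABELS
from .spectra import SpectrumMatrix

_ROW_SUM_WARN_TOL = 1e-6


@dataclass
class SignatureCatalog:
    """Reference signatures as 96-dimensional probability vectors.

    ``profiles`` has one row per signature, columns in canonical channel
    order; every row sums to 1 (renormalized on load).
    """

    signature_ids: list[str]
    profiles: np.ndarray

    def __post_init__(self) -> None:
        self.profiles = np.asarray(self.profiles, dtype=float)
        if self.profiles.ndim != 2 or self.profiles.shape[0] != len(self.signature_ids):
            raise ValueError("profiles must be (n_signatures, n_channels)")
        if (self.profiles < 0).any():
            raise ValueError("negative entries in signature profiles")

    @property
    def n_signatures(self) -> int:
        return len(self.signature_ids)


def read_catalog(path: str | Path) -> SignatureCatalog:
    """Read a COSMIC-layout signature catalog TSV.

    The file holds 96 context rows (label column named ``Type`` or taken
    as the first column) and one numeric column per signature. Rows are
    reordered into canonical channel order regardless of file order and
    renormalized to sum to 1 (published catalogs carry rounding drift).
    """
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: need a label column plus >=1 signature column")
    label_col = "Type" if "Type" in df.columns else df.columns[0]
    labels = df[label_col].astype(str).tolist()
    if len(labels) != 96:
        raise ValueError(f"{path}: expected 96 context rows, found {len(labels)}")
    unknown = set(labels) - set(SBS96_LABELS)
    if unknown:
        raise ValueError(f"{path}: unknown channel label(s) {sorted(unknown)[:3]}")
    if len(set(labels)) != 96:
        raise ValueError(f"{path}: duplicate channel labels")
    values = df.drop(columns=[label_col])
    signature_ids = [str(c) for c in values.columns]
    mat = values.to_numpy(dtype=float)  # 96 x k
    if (mat < 0).any():
        raise ValueError(f"{path}: negative signature entries")
    order = {lab: i for i, lab in enumerate(labels)}
    mat = mat[[order[lab] for lab in SBS96_LABELS], :]
    col_sums = mat.sum(axis=0)
    if (col_sums <= 0).any():
        bad = [signature_ids[i] for i in np.nonzero(col_sums <= 0)[0]]
        raise ValueError(f"{path}: all-zero signature column(s) {bad}")
    if np.abs(col_sums - 1.0).max() > _ROW_SUM_WARN_TOL:
        warnings.warn(
            f"{path}: signature columns deviate from sum 1 "
            f"(max {np.abs(col_sums - 1.0).max():.2e}); renormalizing",
            stacklevel=2,
        )
    mat = mat / col_sums
    return SignatureCatalog(signature_ids=signature_ids, profiles=mat.T)


@dataclass
class ExposureResult:
    """NNLS exposures for one sample.

    ``exposures`` are in mutation-count units; ``r_norm`` is the sum of
    squared residuals of the decomposition.
    """

    sample_id: str
    signature_ids: list[str]
    exposures: np.ndarray
    r_norm: float


def nnls_fit(
    spectrum_row: np.ndarray,
    catalog: SignatureCatalog,
    sample_id: str = "sample",
) -> ExposureResult:
    """Fit one 96-channel spectrum against a catalog; deterministic."""
    v = np.asarray(spectrum_row, dtype=float)
    if catalog.n_signatures == 0:
        raise ValueError("empty signature catalog")
    if v.shape != (catalog.profiles.shape[1],):
        raise ValueError(
            f"spectrum length {v.shape} does not match catalog channels "
            f"{catalog.profiles.shape[1]}"
        )
    A = catalog.profiles.T  # channels x signatures
    exposures, _ = _scipy_nnls(A, v)
    residual = v - A @ exposures
    return ExposureResult(
        sample_id=sample_id,
        signature_ids=list(catalog.signature_ids),
        exposures=exposures,
        r_norm=float(residual @ residual),
    )


def relative_exposures(result: ExposureResult) -> np.ndarray:
    """Exposures normalized to proportions summing to 1.

    Undefined (raises ValueError) when every exposure is zero.
    """
    total = result.exposures.sum()
    if total <= 0:
        raise ValueError(
            f"sample {result.sample_id!r}: all exposures are zero; "
            "relative exposures undefined"
        )
    return result.exposures / total


@dataclass
class CohortExposures:
    """Stacked NNLS results for a cohort, sample order preserved."""

    sample_ids: list[str]
    signature_ids: list[str]
    exposures: np.ndarray  # samples x signatures
    r_norm: np.ndarray  # per sample

    def result(self, sample_id: str) -> ExposureResult:
        i = self.sample_ids.index(sample_id)
        return ExposureResult(
            sample_id=sample_id,
            signature_ids=list(self.signature_ids),
            exposures=self.exposures[i],
            r_norm=float(self.r_norm[i]),
        )

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.exposures, index=self.sample_ids, columns=self.signature_ids
        )
        df["r_norm"] = self.r_norm
        df.index.name = "Sample"
        return df


def fit_cohort(spectra: SpectrumMatrix, catalog: SignatureCatalog) -> CohortExposures:
    """Row-by-row NNLS refit of a spectrum matrix."""
    n = spectra.n_samples
    exposures = np.zeros((n, catalog.n_signatures))
    r_norm = np.zeros(n)
    for i, sample_id in enumerate(spectra.sample_ids):
        res = nnls_fit(spectra.counts[i], catalog, sample_id=sample_id)
        exposures[i] = res.exposures
        r_norm[i] = res.r_norm
    return CohortExposures(
        sample_ids=list(spectra.sample_ids),
        signature_ids=list(catalog.signature_ids),
        exposures=exposures,
        r_norm=r_norm,
    )
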