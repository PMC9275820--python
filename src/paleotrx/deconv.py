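"""Signature-based cell-type deconvolution of bulk expression profiles.

A signature matrix is built from cell-type reference profiles by a
marker rule: a gene is kept when its top cell type expresses it at or
above an expression threshold AND at least ``fold`` times higher than
*each* other cell type (default fivefold).  Bulk profiles are then
regressed on the marker rows to estimate cell-type fractions on the
simplex; the default solver is non-negative least squares (deterministic),
with a nu-support-vector-regression variant available for comparison.
A cell type whose estimated fraction falls below a small threshold tau is
called absent — the basis for presence/absence calls of immune cell
populations across species.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from paleotrx.data_io import ExpressionMatrix


@dataclass
class SignatureMatrix:
    """Marker-gene × cell-type expression values (TPM-like units)."""

    marker_gene_ids: list[str]
    cell_types: list[str]
    values: np.ndarray
    marker_of: list[str]  # defining cell type per marker gene
    fold_threshold: float
    expression_threshold: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.marker_gene_ids, columns=self.cell_types
        )


@dataclass
class MixtureFractions:
    """Per-sample cell-type fraction estimates on the simplex."""

    sample_ids: list[str]
    cell_types: list[str]
    fractions: np.ndarray  # samples x cell types
    residuals: np.ndarray  # per-sample relative residual norm

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.fractions, index=self.sample_ids, columns=self.cell_types)
        df["residual"] = self.residuals
        return df


def build_signature(
    reference: ExpressionMatrix,
    expression_threshold: float = 2.0,
    fold: float = 5.0,
) -> SignatureMatrix:
    """Select marker genes and assemble the signature matrix.

    ``reference`` is a gene × cell-type mean-expression table.  A gene is
    retained for its top cell type when that expression is >= the
    expression threshold and >= fold × the expression in every other cell
    type (a second-best of exactly top/fold passes).  Every cell type must
    end up with at least one marker.
    """
    if reference.n_samples < 2:
        raise ValueError("need at least 2 cell types")
    vals = np.nan_to_num(reference.values, nan=0.0)
    top = vals.argmax(axis=1)
    top_val = vals.max(axis=1)
    others_max = np.where(
        np.arange(vals.shape[1])[None, :] == top[:, None], -np.inf, vals
    ).max(axis=1)
    keep = (top_val >= expression_threshold) & (top_val >= fold * others_max)
    if not keep.any():
        raise ValueError("no genes pass the marker rule")
    genes = [g for g, k in zip(reference.gene_ids, keep) if k]
    marker_of = [reference.sample_ids[t] for t, k in zip(top, keep) if k]
    missing = [ct for ct in reference.sample_ids if ct not in set(marker_of)]
    if missing:
        raise ValueError(f"cell types with zero marker genes: {missing}")
    return SignatureMatrix(
        marker_gene_ids=genes,
        cell_types=list(reference.sample_ids),
        values=vals[keep],
        marker_of=marker_of,
        fold_threshold=fold,
        expression_threshold=expression_threshold,
    )


def deconvolve(
    bulk: ExpressionMatrix,
    sig: SignatureMatrix,
    method: str = "nnls",
    min_shared: float = 0.5,
) -> MixtureFractions:
    """Estimate cell-type fractions of bulk samples from the signature.

    Signature markers absent from the bulk table are dropped (at least
    ``min_shared`` of them must be present).  Fractions are non-negative
    and renormalized to sum to 1; the per-sample residual is the relative
    L2 norm of the unexplained signal.  ``nnls`` is deterministic;
    ``svr`` fits a linear nu-SVR per sample with nu in {0.25, 0.5, 0.75}
    chosen by lowest residual, clipping negative coefficients to 0.
    """
    shared = [g for g in sig.marker_gene_ids if g in bulk.gene_ids]
    if len(shared) < min_shared * len(sig.marker_gene_ids):
        raise ValueError(
            f"only {len(shared)}/{len(sig.marker_gene_ids)} signature genes in bulk data"
        )
    sig_rows = [sig.marker_gene_ids.index(g) for g in shared]
    bulk_rows = [bulk.gene_ids.index(g) for g in shared]
    S = sig.values[sig_rows]
    if np.linalg.matrix_rank(S) < S.shape[1]:
        corr = np.corrcoef(S.T)
        pairs = [
            (sig.cell_types[i], sig.cell_types[j])
            for i in range(len(sig.cell_types))
            for j in range(i + 1, len(sig.cell_types))
            if corr[i, j] > 0.999999
        ]
        raise ValueError(f"rank-deficient signature; collinear cell types: {pairs}")
    B = np.nan_to_num(bulk.values[bulk_rows], nan=0.0)
    n_samples = bulk.n_samples
    fracs = np.zeros((n_samples, len(sig.cell_types)))
    resid = np.zeros(n_samples)
    for j in range(n_samples):
        y = B[:, j]
        if method == "nnls":
            coef, _ = nnls(S, y)
        elif method == "svr":
            coef = _svr_coefficients(S, y)
        else:
            raise ValueError(f"unknown deconvolution method {method!r}")
        total = coef.sum()
        fracs[j] = coef / total if total > 0 else 0.0
        fit = S @ coef
        denom = np.linalg.norm(y)
        resid[j] = float(np.linalg.norm(y - fit) / denom) if denom > 0 else 0.0
    return MixtureFractions(
        sample_ids=list(bulk.sample_ids),
        cell_types=list(sig.cell_types),
        fractions=fracs,
        residuals=resid,
    )


def _svr_coefficients(S: np.ndarray, y: np.ndarray) -> np.ndarray:
    from sklearn.svm import NuSVR

    best_coef, best_res = None, np.inf
    for nu in (0.25, 0.5, 0.75):
        model = NuSVR(kernel="linear", nu=nu, C=1.0)
        model.fit(S, y)
        coef = np.clip(model.coef_.ravel(), 0.0, None)
        res = np.linalg.norm(y - S @ coef)
        if res < best_res:
            best_coef, best_res = coef, res
    return best_coef


def call_absent(
    fractions: MixtureFractions,
    cell_type: str,
    tau: float = 0.005,
) -> list[str]:
    """Presence/absence call per sample for one cell type.

    A cell type is called absent in a sample when its estimated fraction
    is below ``tau`` (default 0.5%).  Returns one of {"present",
    "absent"} per sample, ordered as ``fractions.sample_ids``.
    """
    if cell_type not in fractions.cell_types:
        raise ValueError(f"unknown cell type {cell_type!r}")
    j = fractions.cell_types.index(cell_type)
    return ["absent" if f < tau else "present" for f in fractions.fractions[:, j]]
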