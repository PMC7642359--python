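"""Leakage-corrected envelope-correlation connectomes and summaries.

Source leakage (here: instantaneous real mixing) induces spurious zero-lag
correlation between reconstructed signals.  Before correlating band power
envelopes, each analytic signal pair is therefore *pairwise orthogonalized*:
the component of y instantaneously collinear with x is removed,

    y_perp_x(t) = imag( y(t) * conj(x(t)) / |x(t)| ),

and the connectivity value is the average of the two orthogonalization
directions, each the product-moment correlation of 1-Hz low-pass-filtered
envelopes over edge-trimmed samples.  Matrices are symmetrized by averaging
with their transpose; the diagonal is fixed at zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from envnet.bands import BandSpec, get_band
from envnet.parcellation import Parcellation
from envnet.simulate import Recording
from envnet.spectral import (
    EDGE_TRIM_S,
    analytic,
    bandpass,
    lowpass_array,
    trim_edges,
)

logger = logging.getLogger(__name__)


@dataclass
class ConnectomeMatrix:
    """Symmetric envelope-correlation matrix with zero diagonal."""

    values: np.ndarray
    band: BandSpec
    subject: str | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("connectome must be square")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("connectome must be symmetric within 1e-12")
        if np.any(np.diag(v) != 0):
            raise ValueError("connectome diagonal must be fixed at 0")
        off = v[~np.eye(v.shape[0], dtype=bool)]
        if np.any(np.abs(off) > 1.0 + 1e-12):
            raise ValueError("off-diagonal entries must lie in [-1, 1]")
        self.values = v

    def upper_triangle(self) -> np.ndarray:
        iu = np.triu_indices(self.values.shape[0], k=1)
        return self.values[iu]


@dataclass
class PowerVector:
    """Per-node band power (signal variance)."""

    values: np.ndarray
    band: BandSpec
    subject: str | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1:
            raise ValueError("power vector must be 1-D")
        if np.any(v < 0):
            raise ValueError("power values must be non-negative")
        self.values = v


def orthogonalize_pair(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Component of analytic ``y`` instantaneously orthogonal to ``x``.

    Samples where ``|x|`` vanishes produce 0 and are counted; if more than 1%
    of samples are degenerate a warning is logged.  The operation is linear
    in ``y``.
    """
    x = np.asarray(x, dtype=complex)
    y = np.asarray(y, dtype=complex)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal lengths")
    mag = np.abs(x)
    zero = mag == 0
    n_zero = int(zero.sum())
    if n_zero:
        mag = np.where(zero, 1.0, mag)
    out = np.imag(y * np.conj(x) / mag)
    if n_zero:
        out[zero] = 0.0
        if n_zero > 0.01 * x.size:
            logger.warning(
                "orthogonalize_pair: %d/%d samples with zero |x| set to 0",
                n_zero, x.size,
            )
    return out


def _corr_or_zero(
    a: np.ndarray, b: np.ndarray, b_scale: float | None = None
) -> float:
    """Pearson correlation; a degenerate side contributes 0.

    Degeneracy is judged relative to ``b_scale`` (the magnitude of the series
    the orthogonalized residual came from): a collinear pair leaves only
    floating-point noise, whose std is nonzero but ~1e-16 of the signal.
    """
    sa, sb = a.std(), b.std()
    floor = 1e-8 * b_scale if b_scale is not None else 0.0
    if sa == 0 or sb <= floor:
        logger.info("degenerate direction (zero-variance envelope); contributes 0")
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def envelope_correlation_pair(
    x: np.ndarray, y: np.ndarray, fs: float, cutoff: float = 1.0
) -> float:
    """Leakage-corrected envelope correlation of two analytic signals.

    r = 1/2 [ corr(lp|x|, lp|y_perp_x|) + corr(lp|y|, lp|x_perp_y|) ], with
    lp the 1-Hz zero-phase low-pass and correlations over edge-trimmed
    samples.  Collinear pairs (both directions degenerate) return 0.
    """
    x = np.asarray(x, dtype=complex)
    y = np.asarray(y, dtype=complex)
    if x.shape[-1] < 10 * fs:
        raise ValueError("need at least 10 s of data for envelope correlation")

    def lp_trim(v: np.ndarray) -> np.ndarray:
        return trim_edges(lowpass_array(v, fs, cutoff), fs, EDGE_TRIM_S)

    r_xy = _corr_or_zero(
        lp_trim(np.abs(x)), lp_trim(np.abs(orthogonalize_pair(x, y))),
        b_scale=float(np.abs(y).std()),
    )
    r_yx = _corr_or_zero(
        lp_trim(np.abs(y)), lp_trim(np.abs(orthogonalize_pair(y, x))),
        b_scale=float(np.abs(x).std()),
    )
    return 0.5 * (r_xy + r_yx)


def uncorrected_envelope_correlation(
    x: np.ndarray, y: np.ndarray, fs: float, cutoff: float = 1.0
) -> float:
    """Plain envelope correlation without leakage correction (for contrast)."""
    def lp_trim(v):
        return trim_edges(lowpass_array(v, fs, cutoff), fs, EDGE_TRIM_S)

    return _corr_or_zero(lp_trim(np.abs(x)), lp_trim(np.abs(y)))


def _pairwise_orth_corr(Z: np.ndarray, fs: float, cutoff: float = 1.0) -> np.ndarray:
    """Directed matrix A[i, j] = corr(lp|z_i|, lp|z_j_perp_i|), vectorized per seed row."""
    n, _ = Z.shape
    mag = np.abs(Z)
    lp_env = trim_edges(lowpass_array(mag, fs, cutoff), fs, EDGE_TRIM_S)
    lp_env = lp_env - lp_env.mean(axis=1, keepdims=True)
    env_sd = lp_env.std(axis=1)
    A = np.zeros((n, n))
    safe_mag = np.where(mag == 0, 1.0, mag)
    for i in range(n):
        # all channels orthogonalized against channel i at once
        orth = np.abs(np.imag(Z * np.conj(Z[i]) / safe_mag[i]))
        lp_orth = trim_edges(lowpass_array(orth, fs, cutoff), fs, EDGE_TRIM_S)
        lp_orth = lp_orth - lp_orth.mean(axis=1, keepdims=True)
        orth_sd = lp_orth.std(axis=1)
        # collinear channels leave only float noise after orthogonalization
        denom = env_sd[i] * orth_sd
        ok = (orth_sd > 1e-8 * mag.std(axis=1)) & (denom > 0)
        cov = lp_orth @ lp_env[i] / lp_env.shape[1]
        A[i, ok] = cov[ok] / denom[ok]
        A[i, ~ok] = 0.0
    np.fill_diagonal(A, 0.0)
    return A


def build_connectome(
    rec: Recording, band: str | BandSpec, parc: Parcellation
) -> ConnectomeMatrix:
    """Leakage-corrected envelope-correlation connectome for one subject/band.

    All unordered node pairs are filled; the directed matrix is symmetrized by
    averaging with its transpose and the diagonal set to zero.
    """
    band = get_band(band)
    if rec.n_channels != parc.n_nodes:
        raise ValueError(
            f"recording has {rec.n_channels} channels but parcellation has "
            f"{parc.n_nodes} nodes"
        )
    Z = analytic(bandpass(rec.data, rec.fs, band), rec.fs)
    A = _pairwise_orth_corr(Z, rec.fs)
    vals = 0.5 * (A + A.T)
    np.fill_diagonal(vals, 0.0)
    return ConnectomeMatrix(np.clip(vals, -1.0, 1.0), band=band, subject=rec.subject)


def node_power(rec: Recording, band: str | BandSpec) -> PowerVector:
    """Band power per node: variance of the band-passed, edge-trimmed signal."""
    band = get_band(band)
    filt = trim_edges(bandpass(rec.data, rec.fs, band), rec.fs, EDGE_TRIM_S)
    return PowerVector(filt.var(axis=1), band=band, subject=rec.subject)


def summarize_connectome(
    conn: ConnectomeMatrix, power: PowerVector, parc: Parcellation
) -> pd.DataFrame:
    """Global and per-network connectivity/power summary rows for one subject.

    Global connectivity is the mean over all unordered pairs; network
    connectivity the mean over within-network pairs (for pVIS, the single
    left-V1/right-V1 entry); powers are node means.
    """
    n = parc.n_nodes
    if conn.values.shape[0] != n or power.values.shape[0] != n:
        raise ValueError("connectome/power size inconsistent with parcellation")
    rows = [{
        "subject": conn.subject,
        "band": conn.band.name,
        "scope": "global",
        "connectivity": float(conn.upper_triangle().mean()),
        "power": float(power.values.mean()),
    }]
    for net in parc.network_names:
        idx = parc.network_indices(net)
        if len(idx) < 2:
            raise ValueError(f"network {net!r} has fewer than 2 nodes")
        pairs = parc.within_pairs(net)
        rows.append({
            "subject": conn.subject,
            "band": conn.band.name,
            "scope": net,
            "connectivity": float(np.mean([conn.values[i, j] for i, j in pairs])),
            "power": float(power.values[idx].mean()),
        })
    return pd.DataFrame(rows)


def regress_confounds(
    values: "pd.DataFrame | np.ndarray",
    covariates: pd.DataFrame,
) -> "pd.DataFrame | np.ndarray":
    """Residualize features on covariates by OLS, preserving the grand level.

    For every feature column, ordinary least squares on
    ``[intercept, covariates]``; the returned value is residual + fitted
    intercept.  Categorical covariates (sex, system) are encoded as 0/1.
    Rank-deficient designs raise, naming the collinear columns.
    """
    is_df = isinstance(values, pd.DataFrame)
    vals = values.to_numpy(dtype=float) if is_df else np.asarray(values, dtype=float)
    if vals.ndim == 1:
        vals = vals[:, None]
    n = vals.shape[0]
    cols, names = [], []
    for name in covariates.columns:
        col = covariates[name]
        if col.dtype == object or str(col.dtype) == "category":
            levels = sorted(col.astype(str).unique())
            if len(levels) > 2:
                raise ValueError(f"covariate {name!r} has more than two levels")
            col = (col.astype(str) == levels[-1]).astype(float)
        cols.append(np.asarray(col, dtype=float))
        names.append(name)
    X = np.column_stack([np.ones(n)] + cols)
    if not np.all(np.isfinite(X)):
        raise ValueError("covariates must be finite")
    if n < X.shape[1] + 2:
        raise ValueError("need at least 2 more subjects than covariates")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        r = np.diag(np.linalg.qr(X, mode="r"))
        bad = [(["intercept"] + names)[k] for k in np.nonzero(np.abs(r) < 1e-10)[0]]
        raise ValueError(f"rank-deficient confound design; collinear columns: {bad}")
    beta, *_ = np.linalg.lstsq(X, vals, rcond=None)
    out = vals - X @ beta + beta[0]
    if is_df:
        return pd.DataFrame(out, index=values.index, columns=values.columns)
    return out if np.asarray(values).ndim > 1 else out[:, 0]
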