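"""Transient network dynamics: HMM on group-concatenated power envelopes.

The chain mirrors the established envelope-HMM recipe: per-subject envelopes
(wide band, windowed-averaged to 40 Hz) are demeaned per channel and
normalized by the global standard deviation pooled over all channels, then
temporally concatenated across subjects, prewhitened and reduced to their
leading principal components.  A K-state Gaussian-observation HMM with full
state covariances is fitted by EM with several seeded restarts, the model
with the best final log-likelihood is retained, and the Viterbi algorithm
yields mutually exclusive binary state time courses per subject.  States are
summarized by mean lifetime (MLT), fractional occupancy (FO), mean interval
length (MIL), and partial-correlation state power maps.

Restart selection by final log-likelihood stands in for variational
free-energy ranking; with maximum-likelihood EM the log-likelihood is the
natural model-selection objective.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from hmmlearn.hmm import GaussianHMM
from sklearn.base import BaseEstimator
from sklearn.cluster import KMeans

from envnet.spectral import EnvelopeSet

logger = logging.getLogger(__name__)


def normalize_subject(env: EnvelopeSet) -> EnvelopeSet:
    """Demean each channel; divide by the SD pooled over channels and samples.

    The result is scale invariant and has pooled variance 1 (channel means 0),
    so subjects contribute comparably to the group concatenation.
    """
    v = env.values
    if v.shape[1] < 2:
        raise ValueError("need at least 2 samples to normalize")
    centered = v - v.mean(axis=1, keepdims=True)
    pooled_sd = centered.std()
    if pooled_sd == 0:
        raise ValueError("zero global variance; cannot normalize")
    return replace(env, values=centered / pooled_sd, signed=True)


@dataclass
class PCSeries:
    """Prewhitened principal-component series of group-concatenated envelopes."""

    data: np.ndarray            # total samples x n_pcs, unit variance per PC
    weights: np.ndarray         # channels x n_pcs (projection: X @ weights)
    lengths: list               # per-subject sample counts, concatenation order
    subjects: list
    explained_variance: np.ndarray
    fs: float

    @property
    def n_pcs(self) -> int:
        return self.data.shape[1]

    def split(self) -> list:
        """Per-subject views in concatenation order."""
        idx = np.cumsum([0] + list(self.lengths))
        return [self.data[idx[i]:idx[i + 1]] for i in range(len(self.lengths))]


def concat_pca_prewhiten(envs: list, n_pcs: int = 40) -> PCSeries:
    """Concatenate normalized envelope sets, PCA-reduce and prewhiten.

    Principal axes come from the eigendecomposition of the concatenated
    sample covariance; retained components are scaled to unit variance.
    ``n_pcs`` is capped at the data rank with a logged warning.
    """
    if not envs:
        raise ValueError("need at least one envelope set")
    n_ch = envs[0].n_regions
    fs = envs[0].fs
    if any(e.n_regions != n_ch for e in envs):
        raise ValueError("all envelope sets must have equal channel counts")
    X = np.concatenate([e.values.T for e in envs], axis=0)  # T_total x channels
    T_total = X.shape[0]
    if n_pcs < 1:
        raise ValueError("n_pcs must be >= 1")
    Xc = X - X.mean(axis=0, keepdims=True)
    cov = (Xc.T @ Xc) / T_total
    w, v = np.linalg.eigh(cov)
    w, v = w[::-1], v[:, ::-1]  # descending
    tol = w[0] * max(cov.shape) * np.finfo(float).eps
    rank = int(np.sum(w > tol))
    rank = min(rank, T_total - 1, n_ch)
    if n_pcs > rank:
        logger.warning("n_pcs=%d exceeds data rank %d; capped", n_pcs, rank)
        n_pcs = rank
    keep_w, keep_v = w[:n_pcs], v[:, :n_pcs]
    weights = keep_v / np.sqrt(keep_w)  # projection includes whitening
    data = Xc @ weights
    return PCSeries(
        data=data,
        weights=weights,
        lengths=[e.n_samples for e in envs],
        subjects=[e.subject for e in envs],
        explained_variance=keep_w,
        fs=fs,
    )


@dataclass
class HmmFit:
    """Selected Gaussian HMM plus per-restart objectives."""

    model: GaussianHMM
    restart_scores: np.ndarray
    selected_restart: int
    pca_weights: np.ndarray | None = None

    @property
    def K(self) -> int:
        return self.model.n_components

    @property
    def means(self) -> np.ndarray:
        return self.model.means_

    @property
    def covariances(self) -> np.ndarray:
        return self.model.covars_

    @property
    def transition(self) -> np.ndarray:
        return self.model.transmat_

    @property
    def initial(self) -> np.ndarray:
        return self.model.startprob_


class EnvelopeHMM(BaseEstimator):
    """K-state Gaussian-observation HMM with seeded EM restarts.

    scikit-learn-style estimator: ``fit(X, lengths=...)`` trains
    ``n_restarts`` independently initialized models (k-means-based state
    assignment, one derived seed per restart) and keeps the one with the best
    final log-likelihood; ``predict`` returns the Viterbi state sequence.

    Parameters
    ----------
    K : number of transient states (default 8).
    n_restarts : independent EM initializations (default 10).
    max_iter, tol : EM stopping rule (log-likelihood gain below ``tol``).
    covariance_type : "full" by default — states are patterns of envelope
        covariance, not just mean shifts.
    reg_covar : diagonal loading added to state covariances, guarding
        against covariance collapse (logged by hmmlearn when triggered).
    random_state : master seed; restart seeds are derived from it.
    """

    def __init__(
        self,
        K: int = 8,
        n_restarts: int = 10,
        max_iter: int = 100,
        tol: float = 1e-2,
        covariance_type: str = "full",
        reg_covar: float = 1e-6,
        random_state: int = 0,
    ):
        self.K = K
        self.n_restarts = n_restarts
        self.max_iter = max_iter
        self.tol = tol
        self.covariance_type = covariance_type
        self.reg_covar = reg_covar
        self.random_state = random_state

    def fit(self, X: np.ndarray, y=None, lengths: list | None = None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (samples x features)")
        if self.K < 1 or self.n_restarts < 1:
            raise ValueError("K and n_restarts must be >= 1")
        T, d = X.shape
        if T < 10 * self.K * d:
            logger.warning(
                "only %d samples for K=%d states in %d dims; "
                "recommend at least %d", T, self.K, d, 10 * self.K * d,
            )
        seeds = np.random.SeedSequence(self.random_state).generate_state(
            self.n_restarts
        ) % (2**31 - 1)
        scores = np.full(self.n_restarts, -np.inf)
        models = []
        for r in range(self.n_restarts):
            m = GaussianHMM(
                n_components=self.K,
                covariance_type=self.covariance_type,
                n_iter=self.max_iter,
                tol=self.tol,
                min_covar=self.reg_covar,
                random_state=int(seeds[r]),
            )
            if self.K > 1:
                # k-means-based state assignment: means AND covariances come
                # from the cluster moments.  Initializing covariances from the
                # global data covariance (the library default) spans all
                # clusters, flattens the first-pass responsibilities, and
                # wipes out the mean initialization.
                km = KMeans(
                    n_clusters=self.K, n_init=5, random_state=int(seeds[r])
                ).fit(X)
                m.init_params = "st"
                m.means_ = km.cluster_centers_
                m.covars_ = self._cluster_covariances(X, km.labels_)
            m.fit(X, lengths)
            if not m.monitor_.converged:
                logger.warning(
                    "restart %d did not converge in %d iterations; "
                    "best iterate kept", r, self.max_iter,
                )
            scores[r] = m.monitor_.history[-1]
            models.append(m)
        best = int(np.argmax(scores))
        self.model_ = models[best]
        self.restart_scores_ = scores
        self.selected_restart_ = best
        self.means_ = self.model_.means_
        self.covars_ = self.model_.covars_
        self.transmat_ = self.model_.transmat_
        self.startprob_ = self.model_.startprob_
        self.n_features_in_ = d
        return self

    def _cluster_covariances(self, X: np.ndarray, labels: np.ndarray) -> np.ndarray:
        T, d = X.shape
        covs = np.empty((self.K, d, d))
        global_cov = np.cov(X.T, bias=True).reshape(d, d)
        for k in range(self.K):
            sel = X[labels == k]
            if sel.shape[0] <= d:
                covs[k] = global_cov
            else:
                covs[k] = np.cov(sel.T, bias=True).reshape(d, d)
            covs[k] += self.reg_covar * np.eye(d)
        return covs

    def predict(self, X: np.ndarray, lengths: list | None = None) -> np.ndarray:
        """Viterbi state sequence (labels 0..K-1)."""
        self._check_fitted()
        return self.model_.predict(np.asarray(X, dtype=float), lengths)

    def score(self, X: np.ndarray, lengths: list | None = None) -> float:
        self._check_fitted()
        return float(self.model_.score(np.asarray(X, dtype=float), lengths))

    def to_fit(self, pca_weights: np.ndarray | None = None) -> HmmFit:
        self._check_fitted()
        return HmmFit(
            model=self.model_,
            restart_scores=self.restart_scores_,
            selected_restart=self.selected_restart_,
            pca_weights=pca_weights,
        )

    def _check_fitted(self) -> None:
        if not hasattr(self, "model_"):
            raise RuntimeError("EnvelopeHMM is not fitted; call fit() first")


def fit_hmm(data: PCSeries | np.ndarray, K: int = 8, n_restarts: int = 10,
            max_iter: int = 100, tol: float = 1e-2, seed: int = 0) -> HmmFit:
    """Functional wrapper over :class:`EnvelopeHMM` for PC series."""
    if isinstance(data, PCSeries):
        X, lengths, w = data.data, data.lengths, data.weights
    else:
        X, lengths, w = np.asarray(data, dtype=float), None, None
    est = EnvelopeHMM(
        K=K, n_restarts=n_restarts, max_iter=max_iter, tol=tol,
        random_state=seed,
    ).fit(X, lengths=lengths)
    return est.to_fit(pca_weights=w)


@dataclass
class StatePath:
    """Mutually exclusive binary state activations, K x T, at ``fs_states``."""

    binary: np.ndarray
    fs_states: float
    subject: str | None = None

    def __post_init__(self) -> None:
        b = np.asarray(self.binary)
        if b.ndim != 2:
            raise ValueError("state path must be K x T")
        if not np.array_equal(b.sum(axis=0), np.ones(b.shape[1], dtype=b.dtype)):
            raise ValueError("exactly one state must be active per sample")
        self.binary = b.astype(np.int8)

    @property
    def K(self) -> int:
        return self.binary.shape[0]

    @property
    def n_samples(self) -> int:
        return self.binary.shape[1]


def states_to_binary(states: np.ndarray, K: int) -> np.ndarray:
    """Turn a 0-based label sequence into a K x T one-hot matrix."""
    states = np.asarray(states)
    b = np.zeros((K, states.shape[0]), dtype=np.int8)
    b[states, np.arange(states.shape[0])] = 1
    return b


def viterbi_path(
    fit: HmmFit, data: PCSeries | np.ndarray, lengths: list | None = None,
    fs_states: float | None = None, subjects: list | None = None,
) -> list:
    """Per-subject Viterbi state paths as binary K x T matrices."""
    if isinstance(data, PCSeries):
        X, lengths = data.data, data.lengths
        fs_states = fs_states or data.fs
        subjects = subjects or data.subjects
    else:
        X = np.asarray(data, dtype=float)
        lengths = lengths or [X.shape[0]]
        if fs_states is None:
            raise ValueError("fs_states required for raw arrays")
    labels = fit.model.predict(X, lengths)
    idx = np.cumsum([0] + list(lengths))
    paths = []
    for i in range(len(lengths)):
        seg = labels[idx[i]:idx[i + 1]]
        paths.append(StatePath(
            states_to_binary(seg, fit.K),
            fs_states=fs_states,
            subject=subjects[i] if subjects else None,
        ))
    return paths


def _runs(x: np.ndarray) -> list:
    """Lengths of maximal runs of 1s, in order (edge-truncated runs included)."""
    padded = np.concatenate([[0], x, [0]])
    d = np.diff(padded)
    starts = np.nonzero(d == 1)[0]
    ends = np.nonzero(d == -1)[0]
    return list(ends - starts)


def temporal_metrics(path: StatePath) -> pd.DataFrame:
    """MLT (s), FO, MIL (s) and visit count per state for one subject.

    MLT is the mean length of maximal activation runs (edge-truncated runs
    included); FO the active fraction of samples; MIL the mean complete gap
    between consecutive visits.  Never-visited states get FO = 0 and
    MLT/MIL reported as missing; an always-active state has no gaps, so its
    MIL is missing.
    """
    rows = []
    T = path.n_samples
    for k in range(path.K):
        x = path.binary[k]
        visits = _runs(x)
        n_visits = len(visits)
        fo = float(x.sum()) / T
        if n_visits == 0:
            mlt, mil = np.nan, np.nan
        else:
            mlt = float(np.mean(visits)) / path.fs_states
            gaps = _runs(1 - x)
            # complete gaps only: drop edge-touching inactive runs
            if x[0] == 0 and gaps:
                gaps = gaps[1:]
            if x[-1] == 0 and gaps:
                gaps = gaps[:-1]
            mil = float(np.mean(gaps)) / path.fs_states if gaps else np.nan
        rows.append({
            "subject": path.subject,
            "state": k + 1,
            "MLT_s": mlt,
            "FO": fo,
            "MIL_s": mil,
            "n_visits": n_visits,
        })
    return pd.DataFrame(rows)


def state_power_maps(
    paths: "StatePath | list", envelopes: np.ndarray
) -> np.ndarray:
    """Partial correlation between state indicators and channel envelopes.

    For state k and channel j, both the raw (non-demeaned) binary series and
    the demeaned envelope are residualized on the other K-1 binary series
    *without an intercept* — the exclusive indicators sum to one, so demeaning
    them all would make the controls exactly collinear — and the residuals are
    correlated.  Never-active states yield a missing (NaN) map row.
    """
    if isinstance(paths, StatePath):
        B = paths.binary.astype(float)
    else:
        B = np.concatenate([p.binary for p in paths], axis=1).astype(float)
    E = np.asarray(envelopes, dtype=float)
    if E.shape[1] != B.shape[1]:
        raise ValueError("envelopes and state paths must have equal sample counts")
    K, T = B.shape
    E = E - E.mean(axis=1, keepdims=True)
    maps = np.full((K, E.shape[0]), np.nan)
    for k in range(K):
        if B[k].sum() == 0:
            logger.warning("state %d never active; power map row missing", k + 1)
            continue
        others = np.delete(B, k, axis=0).T  # T x (K-1)
        s = B[k]
        if K > 1:
            coef_s, *_ = np.linalg.lstsq(others, s, rcond=None)
            rs = s - others @ coef_s
            coef_e, *_ = np.linalg.lstsq(others, E.T, rcond=None)
            re = E.T - others @ coef_e
        else:
            rs, re = s - s.mean(), E.T
        denom = np.linalg.norm(rs) * np.linalg.norm(re, axis=0)
        ok = denom > 0
        maps[k, ok] = (re.T @ rs)[ok] / denom[ok]
        maps[k, ~ok] = 0.0
    return np.clip(maps, -1.0, 1.0)
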