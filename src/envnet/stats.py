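"""Rank-based group comparisons with family-wise Bonferroni correction.

Three-group differences are assessed with Kruskal-Wallis omnibus tests
followed by post-hoc Tukey's range tests on midranks (Tukey-Kramer with rank
variance N(N+1)/12 and infinite error degrees of freedom).  Bonferroni
factors depend on the test family: the number of bands (3) for global
measures, bands x networks (18) for network means, the effective number of
band-specific connections (from the spatial degrees of freedom rho, capped at
the raw count) for connectomes, and K-1 for HMM temporal metrics (the
exclusivity constraint removes one degree of freedom among K states).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from envnet.connectome import regress_confounds
from envnet.parcellation import Parcellation

logger = logging.getLogger(__name__)

ALPHA = 0.05

FAMILIES = ("global", "network", "connectome", "hmm_states")


@dataclass
class GroupTestResult:
    """Omnibus + post-hoc outcome for one feature."""

    feature: str
    H: float
    p_omnibus: float
    pairwise: dict          # (group_i, group_j) -> post-hoc p
    bonferroni_factor: int
    significant: dict = field(default_factory=dict)  # pair -> bool

    def __post_init__(self) -> None:
        if not self.significant:
            self.significant = {
                pair: bool(p * self.bonferroni_factor < ALPHA)
                for pair, p in self.pairwise.items()
            }

    @property
    def any_significant(self) -> bool:
        return any(self.significant.values())


@dataclass(frozen=True)
class EffectiveComparisons:
    """Bonferroni factor from spatial degrees of freedom rho.

    n_eff = n_bands * rho * (rho - 1) / 2, rounded to the nearest integer —
    the number of effectively independent band-specific connections.
    """

    rho: int
    n_bands: int
    n_eff: int


def _clean_groups(groups: list) -> list:
    out = [np.asarray(g, dtype=float).ravel() for g in groups]
    if len(out) < 2:
        raise ValueError("need at least 2 groups")
    if any(g.size == 0 for g in out):
        raise ValueError("all groups must be non-empty")
    return out


def kruskal_wallis(groups: list) -> tuple:
    """Kruskal-Wallis H (tie-corrected) and chi-square p-value.

    Degenerate data (all pooled values identical) returns (0, 1) by
    convention, logged, so downstream tables never contain missing cells.
    """
    gs = _clean_groups(groups)
    n_total = sum(g.size for g in gs)
    if n_total < 5:
        logger.warning(
            "only %d observations; chi-square approximation is crude", n_total
        )
    pooled = np.concatenate(gs)
    if np.all(pooled == pooled[0]):
        logger.info("degenerate data (all values identical): H=0, p=1")
        return 0.0, 1.0
    H, p = sps.kruskal(*gs)
    return float(H), float(p)


def tukey_ranks_posthoc(groups: list) -> dict:
    """Pairwise post-hoc p-values from Tukey's range test on midranks.

    Pooled midranks; for pair (i, j):
    q = |Rbar_i - Rbar_j| / sqrt([N(N+1)/24] (1/n_i + 1/n_j)), referred to the
    studentized range distribution with k groups and infinite error degrees of
    freedom.  Rank-based, hence invariant under strictly monotone transforms.
    """
    gs = _clean_groups(groups)
    k = len(gs)
    if k < 3:
        logger.warning("fewer than 3 groups; the range test is degenerate")
    pooled = np.concatenate(gs)
    n = np.array([g.size for g in gs])
    N = pooled.size
    if np.all(pooled == pooled[0]):
        return {(i, j): 1.0 for i in range(k) for j in range(i + 1, k)}
    ranks = sps.rankdata(pooled)
    idx = np.cumsum([0] + list(n))
    mean_ranks = np.array([
        ranks[idx[i]:idx[i + 1]].mean() for i in range(k)
    ])
    out = {}
    for i in range(k):
        for j in range(i + 1, k):
            se = np.sqrt(N * (N + 1) / 24.0 * (1.0 / n[i] + 1.0 / n[j]))
            q = abs(mean_ranks[i] - mean_ranks[j]) / se
            out[(i, j)] = float(sps.studentized_range.sf(q, k, np.inf))
    return out


def spatial_dof(matrix: np.ndarray, tol: float | None = None) -> int:
    """Numerical rank of a mixing/leadfield matrix (spatial degrees of freedom).

    Counts singular values above ``tol * sigma_max * max(dim)`` (numpy's
    default rank tolerance when ``tol`` is None); a zero matrix has rho = 0.
    """
    matrix = np.asarray(matrix, dtype=float)
    if not np.all(np.isfinite(matrix)):
        raise ValueError("matrix must be finite")
    if not np.any(matrix):
        return 0
    if tol is None:
        return int(np.linalg.matrix_rank(matrix))
    s = np.linalg.svd(matrix, compute_uv=False)
    return int(np.sum(s > tol * s[0] * max(matrix.shape)))


def effective_comparisons(rho: int, n_bands: int = 3) -> EffectiveComparisons:
    """Effective number of band-specific connections from rho.

    n_eff = n_bands * rho * (rho - 1) / 2; e.g. rho = 19 with 3 bands gives
    513.  Requires rho >= 2 (fewer spatial degrees of freedom admit no
    connection).
    """
    if rho < 2:
        raise ValueError(f"rho must be >= 2, got {rho}")
    n_eff = int(round(n_bands * rho * (rho - 1) / 2))
    return EffectiveComparisons(rho=int(rho), n_bands=int(n_bands), n_eff=n_eff)


def family_factor(
    family: str,
    n_bands: int = 3,
    n_networks: int = 6,
    K: int = 8,
    n_eff: int | None = None,
    n_raw: int | None = None,
) -> int:
    """Bonferroni factor for a test family.

    ``connectome`` uses min(n_eff, n_raw) so the effective-comparison
    correction never exceeds raw Bonferroni.
    """
    if family == "global":
        return n_bands
    if family == "network":
        return n_bands * n_networks
    if family == "connectome":
        if n_eff is None or n_raw is None:
            raise ValueError("connectome family needs n_eff and n_raw")
        return min(int(n_eff), int(n_raw))
    if family == "hmm_states":
        return K - 1
    raise ValueError(f"unknown family {family!r}; known: {FAMILIES}")


def run_family(
    values: pd.DataFrame,
    groups: "pd.Series | np.ndarray",
    family: str,
    n_bands: int = 3,
    n_networks: int = 6,
    K: int = 8,
    n_eff: int | None = None,
    n_raw: int | None = None,
    covariates: pd.DataFrame | None = None,
    group_order: list | None = None,
) -> list:
    """Feature-wise omnibus + post-hoc tests with family-wise correction.

    ``values`` is subjects x features; ``groups`` assigns each subject to a
    group.  If ``covariates`` is given, features are confound-regressed first.
    Significance flags are ``p * factor < 0.05`` exactly.
    """
    factor = family_factor(family, n_bands, n_networks, K, n_eff, n_raw)
    groups = np.asarray(groups)
    if covariates is not None:
        values = regress_confounds(values, covariates)
    order = group_order or list(pd.unique(groups))
    results = []
    for col in values.columns:
        v = values[col].to_numpy(dtype=float)
        keep = np.isfinite(v)
        gs = [v[keep & (groups == g)] for g in order]
        if any(g.size == 0 for g in gs):
            raise ValueError(f"feature {col!r}: empty group after missing removal")
        H, p = kruskal_wallis(gs)
        pw = tukey_ranks_posthoc(gs)
        pairwise = {(order[i], order[j]): pv for (i, j), pv in pw.items()}
        results.append(GroupTestResult(
            feature=str(col), H=H, p_omnibus=p, pairwise=pairwise,
            bonferroni_factor=factor,
        ))
    return results


def results_table(results: list, family: str, band: str | None = None) -> pd.DataFrame:
    """Long-format table: one row per feature x group pair."""
    rows = []
    for r in results:
        for pair, p in r.pairwise.items():
            rows.append({
                "family": family,
                "band": band,
                "feature": r.feature,
                "H": r.H,
                "p_omnibus": r.p_omnibus,
                "pair": f"{pair[0]}|{pair[1]}",
                "p_posthoc": p,
                "factor": r.bonferroni_factor,
                "significant": r.significant[pair],
            })
    return pd.DataFrame(rows)


def link_proportions(flags: dict, parc: Parcellation) -> tuple:
    """Proportions of significant within- and cross-network connections.

    ``flags`` maps unordered node-index pairs to booleans and must cover all
    C(n,2) connections (496 for the default parcellation; 77 within + 419
    cross).
    """
    norm = {tuple(sorted(p)): bool(v) for p, v in flags.items()}
    all_pairs = parc.all_pairs()
    missing = [p for p in all_pairs if p not in norm]
    if missing:
        raise ValueError(
            f"flags must cover all {len(all_pairs)} connections; "
            f"{len(missing)} missing (e.g. {missing[0]})"
        )
    within = {p for net in parc.network_names for p in parc.within_pairs(net)}
    cross = [p for p in all_pairs if p not in within]
    n_within_sig = sum(norm[p] for p in within)
    n_cross_sig = sum(norm[p] for p in cross)
    return n_within_sig / len(within), n_cross_sig / len(cross)
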