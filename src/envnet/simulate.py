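"""Synthetic oscillatory cohorts with planted connectivity and state dynamics.

Each synthetic subject is a 32-region source-space recording built as a sum of
band-limited components.  Per band, slow positive envelopes with a planted
cross-region correlation structure multiply unit-variance narrowband Gaussian
carriers; a Markov chain of transient states modulates regional envelopes
(fractional gain per state per region), and an optional instantaneous real
mixing matrix emulates source leakage.  Group configurations plant the
age-group effects the analysis is meant to detect: band-power differences,
connectivity differences, and state-dwell-time differences.

Baseline envelopes are rectified low-pass-filtered correlated Gaussian
processes.  Rectification (taking |.|) shrinks correlations, so the Gaussian
correlation is *compensated*: it is chosen by inverting the closed-form
folded-normal correlation so that the rectified envelopes hit the requested
``base_corr``.  Only non-negative envelope-correlation targets are realizable
(the folded correlation is even in the Gaussian correlation), which is the
natural regime for power envelopes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
from scipy.optimize import brentq

from envnet.bands import BandSpec, get_band
from envnet.parcellation import Parcellation, default_parcellation

logger = logging.getLogger(__name__)

#: Additive envelope floor, as a fraction of the envelope SD, guaranteeing
#: strictly positive baselines.
ENVELOPE_FLOOR_FRAC = 0.1

#: Cutoff (Hz) of the baseline-envelope low-pass; keeps envelopes smooth on
#: the sub-second scale the 1-Hz envelope analysis resolves.
ENVELOPE_CUTOFF_HZ = 0.5

GROUP_NAMES = ("children", "young_adults", "elders")


@dataclass
class Recording:
    """One subject's regions x samples time series plus covariates."""

    data: np.ndarray
    fs: float
    subject: str = "synthetic"
    group: str | None = None
    sex: str | None = None
    system: str | None = None

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.fs <= 0:
            raise ValueError("fs must be positive")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


@dataclass
class MarkovPlan:
    """A K-state Markov chain with per-state regional envelope modulation.

    ``modulation[k, j]`` is the fractional envelope gain of region ``j`` while
    state ``k`` is active: samples in state k are multiplied by
    ``1 + modulation[k, j]``.  Entries may be negative (deactivation) but must
    stay above -1 so envelopes remain positive.
    """

    transition: np.ndarray
    initial: np.ndarray
    modulation: np.ndarray

    def __post_init__(self) -> None:
        self.transition = np.asarray(self.transition, dtype=float)
        self.initial = np.asarray(self.initial, dtype=float)
        self.modulation = np.asarray(self.modulation, dtype=float)
        self.validate()

    @property
    def K(self) -> int:
        return self.transition.shape[0]

    def validate(self) -> None:
        T = self.transition
        if T.ndim != 2 or T.shape[0] != T.shape[1]:
            raise ValueError("transition matrix must be square")
        if np.any(T < 0) or np.any(T > 1):
            raise ValueError("transition probabilities must lie in [0, 1]")
        rowsums = T.sum(axis=1)
        bad = np.nonzero(np.abs(rowsums - 1.0) > 1e-12)[0]
        if bad.size:
            raise ValueError(
                f"transition row(s) {bad.tolist()} do not sum to 1 "
                f"(sums {rowsums[bad].tolist()})"
            )
        if self.initial.shape != (self.K,):
            raise ValueError("initial distribution length must equal K")
        if np.any(self.initial < 0) or abs(self.initial.sum() - 1.0) > 1e-12:
            raise ValueError("initial distribution must be a probability vector")
        if self.modulation.ndim != 2 or self.modulation.shape[0] != self.K:
            raise ValueError("modulation must be K x n_regions")
        if np.any(self.modulation <= -1):
            raise ValueError("modulation entries must be > -1 (envelopes stay positive)")


def sample_state_sequence(
    plan: MarkovPlan, n_samples: int, seed: int | np.random.Generator
) -> np.ndarray:
    """Draw a state sequence (labels 1..K) from the plan's Markov chain."""
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    plan.validate()
    rng = np.random.default_rng(seed)
    # inverse-CDF sampling from per-row cumulative distributions
    cum_T = np.cumsum(plan.transition, axis=1)
    u = rng.random(n_samples)
    states = np.empty(n_samples, dtype=np.int64)
    states[0] = np.searchsorted(np.cumsum(plan.initial), u[0], side="right")
    for t in range(1, n_samples):
        states[t] = np.searchsorted(cum_T[states[t - 1]], u[t], side="right")
    return states + 1


def _slow_gaussians(
    n_roi: int, T: int, fs: float, rng: np.random.Generator
) -> np.ndarray:
    """Unit-variance smooth Gaussian processes, band-limited below 1 Hz.

    Synthesized circularly in the frequency domain (white spectrum shaped by
    a Butterworth-magnitude low-pass), which is exactly stationary — no
    filter edge transients to leak across channels.
    """
    white = rng.standard_normal((n_roi, T))
    f = np.fft.rfftfreq(T, d=1.0 / fs)
    h = 1.0 / (1.0 + (f / ENVELOPE_CUTOFF_HZ) ** 8)
    slow = np.fft.irfft(np.fft.rfft(white, axis=1) * h, n=T, axis=1)
    return slow / slow.std(axis=1, keepdims=True)


def folded_normal_corr(rho: float) -> float:
    """Correlation of |X|, |Y| for standard bivariate normal with corr ``rho``."""
    rho = float(np.clip(rho, -1.0, 1.0))
    num = (2 / np.pi) * (np.sqrt(1 - rho**2) + rho * np.arcsin(rho)) - 2 / np.pi
    return num / (1 - 2 / np.pi)


def compensate_rectification(target: float) -> float:
    """Gaussian correlation whose folded-normal correlation equals ``target``.

    Only targets in [0, 1] are realizable; the folded correlation is even in
    the Gaussian correlation, so negative targets raise.
    """
    if target < -1e-12:
        raise ValueError(
            f"envelope-correlation target {target} < 0 is not realizable by "
            "rectified Gaussians"
        )
    t = float(np.clip(target, 0.0, 1.0))
    if t <= 0:
        return 0.0
    if t >= 1:
        return 1.0
    return brentq(lambda r: folded_normal_corr(r) - t, 0.0, 1.0, xtol=1e-12)


def _nearest_psd(mat: np.ndarray, eps: float = 1e-10) -> np.ndarray:
    """Clip negative eigenvalues; renormalize to a unit diagonal."""
    w, v = np.linalg.eigh((mat + mat.T) / 2)
    if w.min() >= -eps:
        return mat
    w = np.clip(w, 0.0, None)
    out = (v * w) @ v.T
    d = np.sqrt(np.diag(out))
    out = out / np.outer(d, d)
    np.fill_diagonal(out, 1.0)
    return out


def _check_base_corr(base_corr: np.ndarray) -> np.ndarray:
    base_corr = np.asarray(base_corr, dtype=float)
    if base_corr.ndim != 2 or base_corr.shape[0] != base_corr.shape[1]:
        raise ValueError("base_corr must be square")
    if not np.allclose(base_corr, base_corr.T, atol=1e-10):
        raise ValueError("base_corr must be symmetric")
    if not np.allclose(np.diag(base_corr), 1.0, atol=1e-10):
        raise ValueError("base_corr must have a unit diagonal")
    w = np.linalg.eigvalsh((base_corr + base_corr.T) / 2)
    if w.min() < -1e-10:
        raise ValueError(
            f"base_corr must be positive semidefinite (min eigenvalue {w.min():.3g})"
        )
    return base_corr


def synth_envelopes(
    base_corr: np.ndarray,
    states: np.ndarray,
    modulation: np.ndarray,
    fs: float,
    seed: int | np.random.Generator,
) -> np.ndarray:
    """Smooth positive envelopes with planted correlation and state modulation.

    Baselines are |low-pass-filtered correlated Gaussians| + floor, with the
    Gaussian correlation rectification-compensated so the rectified envelopes
    approximate ``base_corr``.  Sample ``t`` of region ``j`` is then scaled by
    ``1 + modulation[states[t]-1, j]``.
    """
    base_corr = _check_base_corr(base_corr)
    states = np.asarray(states)
    modulation = np.asarray(modulation, dtype=float)
    if np.any(modulation <= -1):
        raise ValueError("modulation entries must be > -1")
    n_roi = base_corr.shape[0]
    if modulation.shape[1] != n_roi:
        raise ValueError("modulation column count must match base_corr size")
    T = states.shape[0]
    rng = np.random.default_rng(seed)

    # compensated Gaussian correlation, re-projected to PSD
    gauss_corr = np.ones_like(base_corr)
    iu = np.triu_indices(n_roi, k=1)
    comp = np.array([compensate_rectification(v) for v in base_corr[iu]])
    gauss_corr[iu] = comp
    gauss_corr.T[iu] = comp
    gauss_corr = _nearest_psd(gauss_corr)

    slow = _slow_gaussians(n_roi, T, fs, rng)
    # impose correlation via symmetric matrix square root
    w, v = np.linalg.eigh(gauss_corr)
    sqrt_c = (v * np.sqrt(np.clip(w, 0, None))) @ v.T
    correlated = sqrt_c @ slow

    folded = np.abs(correlated)
    env = folded + ENVELOPE_FLOOR_FRAC * folded.std()
    gain = 1.0 + modulation[states - 1, :].T  # (n_roi, T)
    return env * gain


def _narrowband_carrier(
    n_roi: int, T: int, fs: float, band: BandSpec, rng: np.random.Generator
) -> np.ndarray:
    """Unit-variance band-limited Gaussian noise per region."""
    from envnet.spectral import bandpass

    band.check_nyquist(fs)
    carrier = bandpass(rng.standard_normal((n_roi, T)), fs, band)
    return carrier / carrier.std(axis=1, keepdims=True)


def synth_recording(
    envelopes: np.ndarray,
    band: str | BandSpec,
    fs: float,
    seed: int | np.random.Generator,
    subject: str = "synthetic",
) -> Recording:
    """Recording whose per-region signal is envelope x narrowband carrier.

    Carriers are unit-variance band-limited Gaussian noise (not sinusoids), so
    Hilbert envelopes are nondegenerate; at least 90% of the output spectral
    power lies inside the band for canonical band widths.
    """
    band = get_band(band)
    env = np.atleast_2d(np.asarray(envelopes, dtype=float))
    rng = np.random.default_rng(seed)
    carrier = _narrowband_carrier(env.shape[0], env.shape[1], fs, band, rng)
    return Recording(env * carrier, fs=fs, subject=subject)


def apply_mixing(rec: Recording, mixing: np.ndarray) -> Recording:
    """Instantaneous real linear mixing: out[m, t] = sum_j mixing[m, j] in[j, t]."""
    mixing = np.asarray(mixing, dtype=float)
    if mixing.ndim != 2 or mixing.shape[1] != rec.n_channels:
        raise ValueError(
            f"mixing must be M x {rec.n_channels}, got {mixing.shape}"
        )
    if not np.all(np.isfinite(mixing)):
        raise ValueError("mixing matrix must be finite")
    return replace(rec, data=mixing @ rec.data)


@dataclass
class GroupConfig:
    """Generation recipe for one age group.

    ``band_power`` maps band name -> variance scale; ``base_corr`` maps band
    name -> 32x32 envelope-correlation target.  ``markov_plan`` plants the
    transient-state dynamics shared by all bands of a subject.
    """

    name: str
    n_subjects: int
    band_power: dict
    base_corr: dict
    markov_plan: MarkovPlan
    mixing: np.ndarray | None = None
    duration_s: float = 60.0
    fs: float = 250.0

    def __post_init__(self) -> None:
        if self.name not in GROUP_NAMES:
            raise ValueError(f"group name must be one of {GROUP_NAMES}")
        if self.n_subjects < 0:
            raise ValueError("n_subjects must be >= 0")
        if set(self.band_power) != set(self.base_corr):
            raise ValueError("band_power and base_corr must cover the same bands")
        hi = max(get_band(b).hi for b in self.band_power)
        if self.fs < 4 * hi:
            raise ValueError(
                f"fs={self.fs} must be at least 4 x the highest band edge ({hi} Hz)"
            )
        for b, c in self.base_corr.items():
            _check_base_corr(np.asarray(c))
        self.markov_plan.validate()


def _synth_subject(
    config: GroupConfig, subject: str, seed_seq: np.random.SeedSequence
) -> Recording:
    T = int(round(config.duration_s * config.fs))
    rng = np.random.default_rng(seed_seq)
    states = sample_state_sequence(config.markov_plan, T, rng)
    data = np.zeros((config.markov_plan.modulation.shape[1], T))
    for band_name in sorted(config.band_power):
        env = synth_envelopes(
            np.asarray(config.base_corr[band_name], dtype=float),
            states,
            config.markov_plan.modulation,
            config.fs,
            rng,
        )
        comp = synth_recording(env, band_name, config.fs, rng).data
        data += np.sqrt(config.band_power[band_name]) * comp
    rec = Recording(data, fs=config.fs, subject=subject, group=config.name)
    if config.mixing is not None:
        rec = apply_mixing(rec, config.mixing)
        rec.subject, rec.group = subject, config.name
    return rec


def make_cohort(configs: list, seed: int) -> list:
    """Generate all subjects of all groups with independent derived seeds.

    Covariates are assigned deterministically: sex alternates F/M within each
    group; the acquisition-system tag splits 50/50 (first half ``vectorview``,
    second half ``triux``).
    """
    if not configs:
        raise ValueError("configs must be non-empty")
    names = [c.name for c in configs]
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate group names in configs: {names}")
    master = np.random.SeedSequence(seed)
    children_seeds = master.spawn(sum(c.n_subjects for c in configs))
    recs = []
    i = 0
    for config in configs:
        for s in range(config.n_subjects):
            subject = f"{config.name}-{s:02d}"
            rec = _synth_subject(config, subject, children_seeds[i])
            rec.sex = "F" if s % 2 == 0 else "M"
            rec.system = "vectorview" if s < config.n_subjects / 2 else "triux"
            recs.append(rec)
            i += 1
    return recs


# ---------------------------------------------------------------------------
# Default cohort: planted age-group effects
# ---------------------------------------------------------------------------

def default_mixing(n: int = 32, strength: float = 0.3) -> np.ndarray:
    """Deterministic leakage stand-in: identity plus symmetric nearest-neighbor
    cross-talk of the given strength (cyclic node order)."""
    m = np.eye(n)
    idx = np.arange(n)
    m[idx, (idx + 1) % n] += strength
    m[idx, (idx - 1) % n] += strength
    return m


def _block_corr(
    parc: Parcellation, within: dict, cross: float
) -> np.ndarray:
    """Correlation target: ``within[net]`` inside each network, ``cross`` elsewhere."""
    n = parc.n_nodes
    c = np.full((n, n), cross)
    for net in parc.network_names:
        idx = parc.network_indices(net)
        c[np.ix_(idx, idx)] = within[net]
    np.fill_diagonal(c, 1.0)
    return _nearest_psd(c)


def _default_modulation(parc: Parcellation, K: int = 8) -> np.ndarray:
    """One activation state per network (+1.2 own nodes, -0.2 others), one
    global-activation state (+0.5), one quiescent state (0).

    The visual state carries a stronger, more distinctive signature (+2.5 on
    the two V1 nodes, -0.4 elsewhere): it modulates only two regions, so a
    gain comparable to the multi-node networks' would leave it poorly
    separable in envelope space.
    """
    g = np.full((K, parc.n_nodes), -0.2)
    for k, net in enumerate(parc.network_names):
        g[k, :] = -0.2
        g[k, parc.network_indices(net)] = 1.2
    vis = parc.network_names.index("pVIS")
    g[vis, :] = -0.4
    g[vis, parc.network_indices("pVIS")] = 2.5
    g[6, :] = 0.5
    g[7, :] = 0.0
    return g


def _default_plan(
    parc: Parcellation,
    fs: float,
    dwell_s: dict | None = None,
    K: int = 8,
) -> MarkovPlan:
    """Uniform-switching chain with per-state mean dwell times (default 0.25 s)."""
    dwell_s = dwell_s or {}
    T = np.zeros((K, K))
    for k in range(K):
        p_stay = 1.0 - 1.0 / (dwell_s.get(k, 0.25) * fs)
        T[k, :] = (1 - p_stay) / (K - 1)
        T[k, k] = p_stay
    return MarkovPlan(
        transition=T,
        initial=np.full(K, 1.0 / K),
        modulation=_default_modulation(parc, K),
    )


def default_group_configs(
    n_per_group: tuple = (15, 15, 15),
    duration_s: float = 60.0,
    fs: float = 250.0,
    mixing_strength: float = 0.3,
    parc: Parcellation | None = None,
) -> list:
    """Three group configs with planted age effects.

    Children: 2x theta power; weaker alpha/beta within-network connectivity.
    Young adults: strong alpha/beta connectivity, pVIS (V1-V1) at 0.8.
    Elders: like young adults except reduced pVIS beta connectivity (0.25)
    and a destabilized visual state (mean dwell 0.125 s vs 0.25 s).
    All groups share the same leakage mixing matrix.
    """
    parc = parc or default_parcellation()
    nets = parc.network_names
    mixing = default_mixing(parc.n_nodes, mixing_strength)
    visual_state = nets.index("pVIS")  # state index of the pVIS activation state

    def corr(bands_within):
        return {
            b: _block_corr(parc, {net: w for net in nets} | pv, cross=x)
            for b, (w, x, pv) in bands_within.items()
        }

    # connectivity maturation is planted both within and across networks,
    # mirroring the broad (not network-local) developmental increase
    child_corr = corr({
        "theta": (0.30, 0.10, {"pVIS": 0.40}),
        "alpha": (0.15, 0.05, {"pVIS": 0.30}),
        "beta": (0.15, 0.05, {"pVIS": 0.30}),
    })
    adult_corr = corr({
        "theta": (0.30, 0.10, {"pVIS": 0.40}),
        "alpha": (0.45, 0.15, {"pVIS": 0.80}),
        "beta": (0.45, 0.15, {"pVIS": 0.80}),
    })
    elder_corr = corr({
        "theta": (0.30, 0.10, {"pVIS": 0.40}),
        "alpha": (0.45, 0.15, {"pVIS": 0.80}),
        "beta": (0.45, 0.15, {"pVIS": 0.25}),
    })

    flat_power = {"theta": 1.0, "alpha": 1.0, "beta": 1.0}
    plan = _default_plan(parc, fs)
    elder_plan = _default_plan(parc, fs, dwell_s={visual_state: 0.125})

    return [
        GroupConfig(
            name="children",
            n_subjects=n_per_group[0],
            band_power={"theta": 2.0, "alpha": 1.0, "beta": 1.0},
            base_corr=child_corr,
            markov_plan=plan,
            mixing=mixing,
            duration_s=duration_s,
            fs=fs,
        ),
        GroupConfig(
            name="young_adults",
            n_subjects=n_per_group[1],
            band_power=dict(flat_power),
            base_corr=adult_corr,
            markov_plan=plan,
            mixing=mixing,
            duration_s=duration_s,
            fs=fs,
        ),
        GroupConfig(
            name="elders",
            n_subjects=n_per_group[2],
            band_power=dict(flat_power),
            base_corr=elder_corr,
            markov_plan=elder_plan,
            mixing=mixing,
            duration_s=duration_s,
            fs=fs,
        ),
    ]


# ---------------------------------------------------------------------------
# Cohort I/O: one HDF5 container per subject plus a delimited manifest
# ---------------------------------------------------------------------------

def write_cohort(recs: list, out_dir: str | Path) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in recs:
        fname = f"{rec.subject}.h5"
        with h5py.File(out_dir / fname, "w") as f:
            d = f.create_dataset("data", data=rec.data)
            d.attrs["fs"] = rec.fs
            for key in ("subject", "group", "sex", "system"):
                d.attrs[key] = getattr(rec, key) or ""
        rows.append({
            "subject": rec.subject,
            "group": rec.group,
            "sex": rec.sex,
            "system": rec.system,
            "fs": rec.fs,
            "duration_s": rec.duration_s,
            "file": fname,
        })
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.tsv", sep="\t", index=False)
    return out_dir / "manifest.tsv"


def read_cohort(manifest_path: str | Path) -> list:
    manifest_path = Path(manifest_path)
    manifest = pd.read_csv(manifest_path, sep="\t")
    recs = []
    for _, row in manifest.iterrows():
        with h5py.File(manifest_path.parent / row["file"], "r") as f:
            d = f["data"]
            recs.append(Recording(
                d[()],
                fs=float(d.attrs["fs"]),
                subject=row["subject"],
                group=row["group"],
                sex=row["sex"],
                system=row["system"],
            ))
    return recs
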