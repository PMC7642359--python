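"""Configuration and orchestration of the two analyses.

``run_pipeline`` executes simulate -> spectral -> static connectome ->
summaries -> HMM -> temporal metrics / state maps -> group statistics, and
writes every table (tab-delimited, 6 significant digits), the per-subject
arrays (HDF5 containers) and a run manifest (config hash, seed, versions).
Given the same configuration and seed the outputs are bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from envnet.bands import BANDS, get_band
from envnet.connectome import build_connectome, node_power, summarize_connectome
from envnet.dynamics import (
    concat_pca_prewhiten,
    fit_hmm,
    normalize_subject,
    state_power_maps,
    temporal_metrics,
    viterbi_path,
)
from envnet.parcellation import Parcellation, default_parcellation
from envnet.simulate import (
    Recording,
    default_group_configs,
    default_mixing,
    make_cohort,
    read_cohort,
    write_cohort,
)
from envnet.spectral import (
    EnvelopeSet,
    bandpass,
    envelope,
    trim_edges,
    window_average_downsample,
)
from envnet.stats import (
    effective_comparisons,
    link_proportions,
    results_table,
    run_family,
    spatial_dof,
)

logger = logging.getLogger(__name__)

FLOAT_FMT = "%.6g"


@dataclass
class PipelineConfig:
    """Validated configuration for a full run.

    Unknown keys in a config file are rejected before any computation; band
    names are resolved against the canonical band table at construction.
    """

    seed: int = 0
    out_dir: str = "envnet_results"
    log_level: str = "INFO"
    bands: list = field(default_factory=lambda: ["theta", "alpha", "beta"])
    input_manifest: str | None = None
    n_per_group: list = field(default_factory=lambda: [15, 15, 15])
    duration_s: float = 60.0
    fs: float = 250.0
    mixing_strength: float = 0.3
    K: int = 8
    n_pcs: int = 40
    n_restarts: int = 10
    max_iter: int = 20
    tol: float = 1.0
    group_hmm: str = "pooled"

    def __post_init__(self) -> None:
        for b in self.bands:
            get_band(b)
        if self.group_hmm not in ("pooled", "per_group"):
            raise ValueError("group_hmm must be 'pooled' or 'per_group'")
        if self.K < 1 or self.n_restarts < 1:
            raise ValueError("K and n_restarts must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def subject_envelope_downsampled(rec: Recording) -> EnvelopeSet:
    """Wide-band Hilbert envelope, window-averaged to the state rate,
    edge-trimmed."""
    wide = BANDS["wide"]
    env = envelope(bandpass(rec.data, rec.fs, wide), rec.fs,
                   band=wide, subject=rec.subject)
    ds = window_average_downsample(env)
    vals = trim_edges(ds.values, ds.fs, ds.edge_s)
    return EnvelopeSet(vals, fs=ds.fs, band=wide, subject=rec.subject, edge_s=0.0)


def _write_table(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def _covariate_frame(recs: list) -> pd.DataFrame:
    return pd.DataFrame({
        "subject": [r.subject for r in recs],
        "group": [r.group for r in recs],
        "sex": [r.sex for r in recs],
        "system": [r.system for r in recs],
    }).set_index("subject")


def stage_simulate(config: PipelineConfig, out: Path) -> list:
    if config.input_manifest:
        logger.info("loading cohort from %s", config.input_manifest)
        return read_cohort(config.input_manifest)
    logger.info("simulating default cohort (n=%s)", config.n_per_group)
    cohort = make_cohort(
        default_group_configs(
            n_per_group=tuple(config.n_per_group),
            duration_s=config.duration_s,
            fs=config.fs,
            mixing_strength=config.mixing_strength,
        ),
        seed=config.seed,
    )
    write_cohort(cohort, out / "cohort")
    return cohort


def stage_connectome(
    config: PipelineConfig, recs: list, parc: Parcellation, out: Path
) -> dict:
    """Per subject x band connectomes, node power, and summary rows."""
    conn_dir = out / "connectomes"
    conn_dir.mkdir(parents=True, exist_ok=True)
    summaries, long_rows = [], []
    conns, powers = {}, {}
    for rec in recs:
        for band_name in config.bands:
            conn = build_connectome(rec, band_name, parc)
            pw = node_power(rec, band_name)
            conns[(rec.subject, band_name)] = conn
            powers[(rec.subject, band_name)] = pw
            summaries.append(summarize_connectome(conn, pw, parc))
            mat = pd.DataFrame(conn.values, index=parc.labels, columns=parc.labels)
            mat.to_csv(conn_dir / f"{rec.subject}_{band_name}.tsv",
                       sep="\t", float_format=FLOAT_FMT)
            iu = np.triu_indices(parc.n_nodes, k=1)
            for i, j in zip(*iu):
                long_rows.append({
                    "subject": rec.subject, "band": band_name,
                    "node_i": parc.labels[i], "node_j": parc.labels[j],
                    "r": conn.values[i, j],
                })
    summary = pd.concat(summaries, ignore_index=True)
    _write_table(summary, out / "summaries.tsv")
    _write_table(pd.DataFrame(long_rows), out / "connectome_long.tsv")
    return {"summary": summary, "connectomes": conns, "powers": powers}


def stage_hmm(config: PipelineConfig, recs: list, out: Path) -> dict:
    """Envelope HMM chain: normalize, concatenate, PCA, fit, decode, summarize."""
    hmm_dir = out / "hmm"
    hmm_dir.mkdir(parents=True, exist_ok=True)
    groups = {rec.subject: rec.group for rec in recs}
    if config.group_hmm == "pooled":
        batches = [("pooled", recs)]
    else:
        names = list(dict.fromkeys(r.group for r in recs))
        batches = [(g, [r for r in recs if r.group == g]) for g in names]

    metrics_all, map_rows, paths_by_subject = [], [], {}
    for label, batch in batches:
        envs = [normalize_subject(subject_envelope_downsampled(r)) for r in batch]
        pcs = concat_pca_prewhiten(envs, n_pcs=config.n_pcs)
        fit = fit_hmm(
            pcs, K=config.K, n_restarts=config.n_restarts,
            max_iter=config.max_iter, tol=config.tol, seed=config.seed,
        )
        paths = viterbi_path(fit, pcs)
        concat_env = np.concatenate([e.values for e in envs], axis=1)
        maps = state_power_maps(paths, concat_env)
        for k in range(config.K):
            for j in range(concat_env.shape[0]):
                map_rows.append({
                    "batch": label, "state": k + 1, "node": j,
                    "partial_r": maps[k, j],
                })
        with h5py.File(hmm_dir / f"state_paths_{label}.h5", "w") as f:
            for p in paths:
                d = f.create_dataset(p.subject, data=p.binary)
                d.attrs["fs_states"] = p.fs_states
        for p in paths:
            paths_by_subject[p.subject] = p
            m = temporal_metrics(p)
            m.insert(1, "group", groups[p.subject])
            m.insert(0, "batch", label)
            metrics_all.append(m)
    metrics = pd.concat(metrics_all, ignore_index=True)
    _write_table(metrics, out / "hmm" / "temporal_metrics.tsv")
    maps_df = pd.DataFrame(map_rows)
    _write_table(maps_df, out / "hmm" / "state_maps.tsv")
    return {"metrics": metrics, "maps": maps_df, "paths": paths_by_subject,
            "fit": fit}


def stage_stats(
    config: PipelineConfig,
    recs: list,
    summary: pd.DataFrame,
    connectomes: dict,
    metrics: pd.DataFrame,
    parc: Parcellation,
    out: Path,
) -> pd.DataFrame:
    cov = _covariate_frame(recs)
    groups = cov["group"]
    order = list(dict.fromkeys(groups))
    n_bands = len(config.bands)
    tables = []

    glob = summary[summary["scope"] == "global"].set_index("subject")
    for band_name in config.bands:
        gb = glob[glob["band"] == band_name]
        gb = gb.loc[cov.index]
        base_cov = cov[["sex", "system"]]
        rs_cov = base_cov.copy()
        rs_cov["power"] = gb["power"]
        res = run_family(
            gb[["connectivity"]].rename(
                columns={"connectivity": f"{band_name}:global_connectivity"}),
            groups, "global", n_bands=n_bands,
            covariates=rs_cov, group_order=order,
        )
        res += run_family(
            gb[["power"]].rename(columns={"power": f"{band_name}:global_power"}),
            groups, "global", n_bands=n_bands,
            covariates=base_cov, group_order=order,
        )
        tables.append(results_table(res, "global", band_name))

        net = summary[(summary["scope"] != "global")
                      & (summary["band"] == band_name)]
        conn_wide = net.pivot(index="subject", columns="scope",
                              values="connectivity").loc[cov.index]
        pow_wide = net.pivot(index="subject", columns="scope",
                             values="power").loc[cov.index]
        res = run_family(
            conn_wide.add_prefix(f"{band_name}:net_conn:"), groups, "network",
            n_bands=n_bands, n_networks=len(parc.network_names),
            covariates=rs_cov, group_order=order,
        )
        res += run_family(
            pow_wide.add_prefix(f"{band_name}:net_power:"), groups, "network",
            n_bands=n_bands, n_networks=len(parc.network_names),
            covariates=base_cov, group_order=order,
        )
        tables.append(results_table(res, "network", band_name))

    # connectome family: 496 features per band, effective-comparison factor
    rho = spatial_dof(default_mixing(parc.n_nodes, config.mixing_strength))
    n_raw = n_bands * len(parc.all_pairs())
    n_eff = effective_comparisons(rho, n_bands).n_eff if rho >= 2 else n_raw
    prop_rows = []
    for band_name in config.bands:
        iu = parc.all_pairs()
        feat = pd.DataFrame({
            f"{i}-{j}": [connectomes[(s, band_name)].values[i, j]
                         for s in cov.index]
            for i, j in iu
        }, index=cov.index)
        rs_cov = cov[["sex", "system"]].copy()
        rs_cov["power"] = glob[glob["band"] == band_name].loc[cov.index, "power"]
        res = run_family(
            feat, groups, "connectome", n_bands=n_bands,
            n_eff=n_eff, n_raw=n_raw, covariates=rs_cov, group_order=order,
        )
        tables.append(results_table(res, "connectome", band_name))
        flags = {
            tuple(int(v) for v in r.feature.split("-")): r.any_significant
            for r in res
        }
        w, c = link_proportions(flags, parc)
        prop_rows.append({"band": band_name, "within_prop": w, "cross_prop": c})

    # HMM temporal metrics: per state x metric, factor K-1
    hm = metrics.set_index("subject")
    feats = {}
    for k in sorted(hm["state"].unique()):
        sk = hm[hm["state"] == k]
        for m in ("MLT_s", "FO", "MIL_s"):
            feats[f"state{k}:{m}"] = sk.loc[cov.index, m]
    res = run_family(
        pd.DataFrame(feats, index=cov.index), groups, "hmm_states",
        K=config.K, covariates=cov[["sex", "system"]], group_order=order,
    )
    tables.append(results_table(res, "hmm_states", None))

    all_results = pd.concat(tables, ignore_index=True)
    _write_table(all_results, out / "group_tests.tsv")
    _write_table(pd.DataFrame(prop_rows), out / "link_proportions.tsv")
    return all_results


def run_pipeline(config: PipelineConfig, out_dir: str | Path | None = None) -> dict:
    """Execute all stages; returns the in-memory result bundle."""
    out = Path(out_dir or config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), 20))
    parc = default_parcellation()

    recs = stage_simulate(config, out)
    static = stage_connectome(config, recs, parc, out)
    dyn = stage_hmm(config, recs, out)
    tests = stage_stats(
        config, recs, static["summary"], static["connectomes"],
        dyn["metrics"], parc, out,
    )

    # group-level aggregates: 3 bands x 3 groups rows per statistic family
    cov = _covariate_frame(recs)
    glob = static["summary"][static["summary"]["scope"] == "global"].copy()
    glob["group"] = glob["subject"].map(cov["group"])
    agg = (glob.groupby(["band", "group"], sort=False)
           [["connectivity", "power"]].mean().reset_index())
    _write_table(agg, out / "group_summaries.tsv")

    manifest = {
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "versions": {
            "envnet": "0.1.0",
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "n_subjects": len(recs),
    }
    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=2))
    return {
        "recordings": recs, "summary": static["summary"],
        "connectomes": static["connectomes"], "powers": static["powers"],
        "hmm": dyn, "tests": tests, "aggregates": agg, "out_dir": out,
    }
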