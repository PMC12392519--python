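"""End-to-end run: simulate cohorts, behavior gate, band-power tables,
PSD-change contrasts, amplitude transfer entropy, and shuffle-controlled
decoding, written to one reproducible run directory.

A single master seed spawns per-stage substreams deterministically, so two
runs from the same config produce byte-identical ``results.json``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import behavior as bh
from . import connectivity as cn
from . import decoding as dc
from . import spectral as sp
from .io import InclusionStatus, extract_epochs, include_subject, write_session
from .simulate import (DEFAULT_BEHAVIOR, Group, Phase, PRESETS, SimConfig,
                       simulate_behavior, simulate_session)

log = logging.getLogger("thetadefeat")

GROUP_LABEL = {  # decoder class labels
    Group.CON: "CON",
    Group.RSDS_SUSCEPTIBLE: "RSDS",
    Group.SALINE: "RSDS",
    Group.KETAMINE: "RSDS",
    Group.RSDS_RESILIENT: "RSDS",
}


@dataclass
class RunConfig:
    """Full configuration of one pipeline run; serialized into the output
    directory so a run can be reproduced exactly from its own record."""

    seed: int = 0
    groups: tuple[str, ...] = ("CON", "RSDS_SUSCEPTIBLE")
    n_subjects: int = 8
    sim: dict = field(default_factory=dict)  # SimConfig overrides
    hop_s: float = sp.HOP_S
    ate_band: tuple[float, float] = cn.THETA_BAND
    ate_lags: tuple[float, float, float] = (0.0, 0.5, 0.01)  # start, stop, step
    ate_bins: int = 4
    ate_surrogates: int = 0  # 0 disables the surrogate gate
    decode_repetitions: int = 200
    decode_unit: str = "epoch"
    decode_kernel: str = "rbf"
    write_sessions: bool = False
    make_figures: bool = True

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        for g in self.groups:
            Group(g)
        if self.decode_repetitions < 1:
            raise ValueError("decode_repetitions must be >= 1")

    def to_dict(self) -> dict:
        return asdict(self)


def _lag_grid(cfg: RunConfig) -> np.ndarray:
    start, stop, step = cfg.ate_lags
    return np.round(np.arange(start, stop + 1e-9, step), 10)


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        return wrapper
    return deco


@_stage("simulate")
def _simulate_cohorts(cfg: RunConfig, out: Path):
    sim_cfg = SimConfig(**{**cfg.sim, "seed": cfg.seed})
    subjects = []
    for group_name in cfg.groups:
        group = Group(group_name)
        for i in range(cfg.n_subjects):
            beh_seed = int(np.random.SeedSequence(
                entropy=cfg.seed, spawn_key=(list(Group).index(group), i, 7)
            ).generate_state(1)[0] % (2**31))
            beh = simulate_behavior(group, beh_seed)
            record = bh.BehaviorRecord(
                subject=f"{group.value}_{i:02d}", group=group.value,
                time_zone_no_cd1_s=beh["time_zone_no_cd1_s"],
                time_zone_with_cd1_s=beh["time_zone_with_cd1_s"],
                tst_immobility_s=beh["tst_immobility_s"],
            )
            sessions = {
                phase: simulate_session(sim_cfg, group, phase, subject=i)
                for phase in (Phase.NO_CD1, Phase.WITH_CD1)
            }
            if cfg.write_sessions:
                for phase, rec in sessions.items():
                    write_session(
                        rec, out / "sessions" / f"{record.subject}_{phase.value}",
                        behavior={k: v for k, v in beh.items()},
                    )
            subjects.append({"group": group, "record": record,
                             "sessions": sessions, "index": i})
    return subjects


@_stage("behavior")
def _behavior_stage(subjects, out: Path):
    frame = bh.records_to_frame([s["record"] for s in subjects])
    status = []
    for s in subjects:
        if s["group"] in (Group.RSDS_SUSCEPTIBLE, Group.SALINE):
            st = include_subject(s["record"])
        else:
            st = InclusionStatus.SUSCEPTIBLE_INCLUDED
        s["included"] = st is InclusionStatus.SUSCEPTIBLE_INCLUDED
        status.append(st.value)
    frame["inclusion"] = status
    frame.to_csv(out / "tables" / "behavior.csv", index=False)
    summary = bh.summarize_groups(frame)
    summary.to_csv(out / "tables" / "behavior_summary.csv")
    return frame, summary


@_stage("spectral")
def _spectral_stage(cfg: RunConfig, subjects, out: Path):
    rows = []
    for s in subjects:
        if not s["included"]:
            continue
        for phase, rec in s["sessions"].items():
            epochs, _ = extract_epochs(rec)
            table = sp.epoch_band_powers(epochs, phase=phase.value,
                                         hop_s=cfg.hop_s)
            table["subject"] = s["record"].subject
            table["group"] = s["group"].value
            rows.append(table)
    tidy = pd.concat(rows, ignore_index=True)
    tidy.to_csv(out / "tables" / "psd.csv", index=False)

    # subject-level means, then the With-minus-No PSD change per band/stage
    subj = (tidy.groupby(["subject", "group", "region", "band", "stage", "phase"])
            ["value"].mean().reset_index())
    wide = subj.pivot_table(index=["subject", "group", "region", "band", "stage"],
                            columns="phase", values="value").reset_index()
    wide["delta_psd"] = wide[Phase.WITH_CD1.value] - wide[Phase.NO_CD1.value]
    wide.to_csv(out / "tables" / "delta_psd.csv", index=False)
    return tidy, subj, wide


@_stage("connectivity")
def _ate_stage(cfg: RunConfig, subjects, out: Path):
    lags = _lag_grid(cfg)
    rows = []
    curves = {}
    for s in subjects:
        if not s["included"]:
            continue
        rec = s["sessions"][Phase.WITH_CD1]
        pair = cn.post_entry_envelope_pair(rec, band=cfg.ate_band)
        curve = cn.ate_curve(pair, lags, bins=cfg.ate_bins)
        row = {
            "subject": s["record"].subject, "group": s["group"].value,
            "peak": curve.peak, "peak_lag_s": curve.peak_lag_s, "auc": curve.auc,
        }
        if cfg.ate_surrogates:
            null = cn.ate_null(pair, lags, n_surrogates=cfg.ate_surrogates,
                               seed=cfg.seed + 13 * s["index"], bins=cfg.ate_bins)
            row["null_peak_q95"] = float(np.quantile(null["peak"], 0.95))
            row["null_auc_q95"] = float(np.quantile(null["auc"], 0.95))
        rows.append(row)
        curves[s["record"].subject] = curve
    table = pd.DataFrame(rows)
    table.to_csv(out / "tables" / "ate.csv", index=False)
    return table, curves


@_stage("decoding")
def _decode_stage(cfg: RunConfig, tidy: pd.DataFrame):
    full = tidy[(tidy["stage"] == sp.Stage.FULL.value)
                & (tidy["phase"] == Phase.WITH_CD1.value)].copy()
    full["sample_id"] = full["epoch_id"].str.rsplit(":", n=1).str[0]
    full["label"] = full["group"].map(
        lambda g: GROUP_LABEL[Group(g)])
    sample_table = full.rename(columns={"value": "value"})[
        ["sample_id", "subject", "label", "region", "band", "value"]]
    decoder = dc.StressDecoder(sample_table, unit=cfg.decode_unit,
                               kernel=cfg.decode_kernel)
    results = decoder.fit(n_repetitions=cfg.decode_repetitions, seed=cfg.seed + 101)
    report = dc.compare_featuresets(results)
    return results, report


def _figures(out: Path, delta: pd.DataFrame, ate_table: pd.DataFrame,
             curves, decode_results) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    figdir = out / "figures"
    figdir.mkdir(exist_ok=True)

    fig, axes = plt.subplots(1, 2, figsize=(8, 3), sharey=True)
    theta_post = delta[(delta["band"] == "theta") & (delta["stage"] == "POST")]
    for ax, region in zip(axes, ("BLA", "vHPC")):
        sub = theta_post[theta_post["region"] == region]
        means = sub.groupby("group")["delta_psd"].mean()
        sems = sub.groupby("group")["delta_psd"].sem()
        ax.bar(means.index, means.values, yerr=sems.values, capsize=4)
        ax.axhline(0, color="k", lw=0.5)
        ax.set_title(f"{region} theta, post-entry")
        ax.set_ylabel("PSD change (units$^2$/Hz)")
    fig.tight_layout()
    fig.savefig(figdir / "delta_psd.png", dpi=120)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(5, 3))
    by_group: dict[str, list] = {}
    subj_group = dict(zip(ate_table["subject"], ate_table["group"]))
    for subject, curve in curves.items():
        by_group.setdefault(subj_group[subject], []).append(curve)
    for group, cs in by_group.items():
        mean_te = np.mean([c.te_bits for c in cs], axis=0)
        ax.plot(cs[0].lags_s, mean_te, label=group)
    ax.set_xlabel("lag (s)")
    ax.set_ylabel("theta ATE (bits)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(figdir / "ate_curves.png", dpi=120)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(6, 3))
    width = 0.35
    xs = np.arange(len(dc.FEATURESETS))
    real = [decode_results[f].mean("real")["accuracy"] for f in dc.FEATURESETS]
    shuf = [decode_results[f].mean("shuffled")["accuracy"] for f in dc.FEATURESETS]
    ax.bar(xs - width / 2, real, width, label="real")
    ax.bar(xs + width / 2, shuf, width, label="shuffled")
    ax.set_xticks(xs, dc.FEATURESETS)
    ax.set_ylabel("accuracy (%)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(figdir / "decoder.png", dpi=120)
    plt.close(fig)


def cohort_theta_ate_stats(group: Group | str, seed: int, n_subjects: int = 8,
                           sim_overrides: dict | None = None) -> dict[str, float]:
    """Cohort-level means of the headline quantities for one group: theta PSD
    per region (With-CD1 phase), post-entry theta PSD change per region, and
    the ATE peak and AUC. Used for replicate-level direction checks."""
    from .io import extract_epochs as _extract

    group = Group(group)
    cfg = SimConfig(**{**(sim_overrides or {}), "seed": seed})
    acc: dict[str, list[float]] = {k: [] for k in
                                   ("bla_theta", "vhpc_theta", "bla_delta_post",
                                    "vhpc_delta_post", "ate_peak", "ate_auc")}
    for i in range(n_subjects):
        vals: dict = {}
        for phase in (Phase.NO_CD1, Phase.WITH_CD1):
            rec = simulate_session(cfg, group, phase, subject=i)
            epochs, _ = _extract(rec)
            for region in ("BLA", "vHPC"):
                for stage in (sp.Stage.POST, sp.Stage.FULL):
                    v = [sp.band_power(sp.stft_psd(e), "theta", stage).value
                         for e in epochs if e.region == region]
                    vals[(phase, region, stage)] = float(np.mean(v))
            if phase is Phase.WITH_CD1:
                curve = cn.ate_curve(cn.post_entry_envelope_pair(rec))
                acc["ate_peak"].append(curve.peak)
                acc["ate_auc"].append(curve.auc)
        acc["bla_theta"].append(vals[(Phase.WITH_CD1, "BLA", sp.Stage.FULL)])
        acc["vhpc_theta"].append(vals[(Phase.WITH_CD1, "vHPC", sp.Stage.FULL)])
        for region, key in (("BLA", "bla_delta_post"), ("vHPC", "vhpc_delta_post")):
            acc[key].append(vals[(Phase.WITH_CD1, region, sp.Stage.POST)]
                            - vals[(Phase.NO_CD1, region, sp.Stage.POST)])
    return {k: float(np.mean(v)) for k, v in acc.items()}


def direction_replicate(seed: int, n_subjects: int = 8,
                        sim_overrides: dict | None = None) -> dict[str, bool]:
    """One control-vs-susceptible replicate: did each reported group
    direction come out (BLA theta up, vHPC theta down, post-entry PSD change
    more negative in both regions, ATE peak and AUC lower)?"""
    con = cohort_theta_ate_stats(Group.CON, seed, n_subjects, sim_overrides)
    rsds = cohort_theta_ate_stats(Group.RSDS_SUSCEPTIBLE, seed, n_subjects,
                                  sim_overrides)
    return {
        "bla_theta_up": rsds["bla_theta"] > con["bla_theta"],
        "vhpc_theta_down": rsds["vhpc_theta"] < con["vhpc_theta"],
        "delta_psd_post_more_negative": (
            rsds["bla_delta_post"] < con["bla_delta_post"]
            and rsds["vhpc_delta_post"] < con["vhpc_delta_post"]),
        "ate_peak_lower": rsds["ate_peak"] < con["ate_peak"],
        "ate_auc_lower": rsds["ate_auc"] < con["ate_auc"],
    }


def run_pipeline(config: RunConfig, out: str | Path) -> Path:
    """Run every stage and write tables, figures and ``results.json``."""
    out = Path(out)
    (out / "tables").mkdir(parents=True, exist_ok=True)
    import yaml

    with open(out / "config.yaml", "w") as f:
        yaml.safe_dump(config.to_dict(), f, sort_keys=True)

    subjects = _simulate_cohorts(config, out)
    beh_frame, beh_summary = _behavior_stage(subjects, out)
    tidy, subj_means, delta = _spectral_stage(config, subjects, out)
    ate_table, curves = _ate_stage(config, subjects, out)
    decode_results, decode_report = _decode_stage(config, tidy)
    decode_report.to_csv(out / "tables" / "decoder.csv", index=False)

    results = _collect_results(config, beh_frame, subj_means, delta,
                               ate_table, decode_results)
    with open(out / "results.json", "w") as f:
        json.dump(results, f, indent=1, sort_keys=True)

    if config.make_figures:
        _figures(out, delta, ate_table, curves, decode_results)

    with open(out / "log.txt", "w") as f:
        f.write(f"seed={config.seed}\nnumpy={np.__version__}\n")
    return out


def _group_means(df: pd.DataFrame, value: str) -> dict:
    return {g: float(v) for g, v in df.groupby("group")[value].mean().items()}


def _collect_results(cfg, beh_frame, subj_means, delta, ate_table,
                     decode_results) -> dict:
    theta_with = subj_means[(subj_means["band"] == "theta")
                            & (subj_means["stage"] == sp.Stage.FULL.value)
                            & (subj_means["phase"] == Phase.WITH_CD1.value)]
    theta_post_delta = delta[(delta["band"] == "theta")
                             & (delta["stage"] == "POST")]
    con, rsds = cfg.groups[0], cfg.groups[1] if len(cfg.groups) > 1 else None

    out = {
        "seed": cfg.seed,
        "n_subjects": cfg.n_subjects,
        "behavior": {
            "si_ratio_mean": _group_means(beh_frame, "si_ratio"),
            "tst_immobility_mean": _group_means(beh_frame, "tst_immobility_s"),
        },
        "theta_psd_with_cd1": {
            region: _group_means(
                theta_with[theta_with["region"] == region], "value")
            for region in ("BLA", "vHPC")
        },
        "theta_delta_psd_post": {
            region: _group_means(
                theta_post_delta[theta_post_delta["region"] == region],
                "delta_psd")
            for region in ("BLA", "vHPC")
        },
        "ate": {
            "peak_mean": _group_means(ate_table, "peak"),
            "auc_mean": _group_means(ate_table, "auc"),
        },
        "decoder": {name: res.to_dict()
                    for name, res in decode_results.items()},
    }
    if rsds is not None:
        bla = out["theta_psd_with_cd1"]["BLA"]
        vhpc = out["theta_psd_with_cd1"]["vHPC"]
        dbla = out["theta_delta_psd_post"]["BLA"]
        dvh = out["theta_delta_psd_post"]["vHPC"]
        rsds_label = rsds
        out["headline_directions"] = {
            "bla_theta_higher_in_stressed": bla[rsds_label] > bla[con],
            "vhpc_theta_lower_in_stressed": vhpc[rsds_label] < vhpc[con],
            "post_delta_psd_more_negative_in_stressed":
                dbla[rsds_label] < dbla[con] and dvh[rsds_label] < dvh[con],
            "ate_peak_lower_in_stressed":
                out["ate"]["peak_mean"][rsds_label]
                < out["ate"]["peak_mean"][con],
            "decoder_real_above_shuffled": all(
                decode_results[f].mean("real")["accuracy"]
                > decode_results[f].mean("shuffled")["accuracy"]
                for f in dc.FEATURESETS
            ),
        }
    return out
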