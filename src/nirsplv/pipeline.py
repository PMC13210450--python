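"""End-to-end orchestration: simulate/load → preprocess → connectivity
→ network metrics → group statistics → behavior → report.

``run_pipeline`` is deterministic given its configuration: every
output table is accompanied by a manifest recording the config hash,
seed and software version, and re-running an identical config
reproduces all outputs exactly.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .behavior import BehaviorSummary, low_price_contrast, rt_contrast
from .config import RunConfig
from .connectivity import (
    ConnectivityMatrix,
    binarize,
    condition_matrices,
)
from .errors import DataError, NirsPlvError
from .io import (
    read_behavior_tsv,
    read_events_tsv,
    read_snirf,
    write_behavior_tsv,
    write_edge_list,
    write_events_tsv,
    write_matrix_tsv,
    write_snirf,
)
from .layout import ChannelLayout, default_roi_map
from .mbll import forward_mbll, mbll_invert
from .network import network_summary
from .paradigm import CONDITIONS, generate_paradigm
from .preprocess import epoch_and_baseline, preprocess
from .stats import (
    ContrastTable,
    channel_activation_contrast,
    connectivity_contrast,
    metric_contrast,
)
from .study import (
    StudyData,
    StudyEffects,
    activation_effect_study,
    null_study,
    seed_effect_study,
    simulate_study,
)

logger = logging.getLogger(__name__)


@dataclass
class RunReport:
    """All stage outputs of one pipeline run plus the provenance manifest."""

    config: RunConfig
    out_dir: Path
    manifest: dict
    activation: ContrastTable
    seed_contrast: ContrastTable
    roi_contrast: ContrastTable
    channel_pair_contrast: ContrastTable
    global_efficiency_result: object
    nodal_contrast: ContrastTable
    rt: BehaviorSummary | None
    low_price: BehaviorSummary | None
    mean_plv: dict[str, ConnectivityMatrix]
    outputs: dict[str, Path] = field(default_factory=dict)


def _effects_for(config: RunConfig) -> StudyEffects:
    preset = {
        "default": StudyEffects,
        "null": null_study,
        "seed_effect": seed_effect_study,
        "activation_effect": activation_effect_study,
    }[config.effects]
    if preset is StudyEffects:
        return StudyEffects(n_subjects=config.n_subjects)
    return preset(n_subjects=config.n_subjects)


def _network_tables(study: StudyData) -> dict[str, pd.DataFrame]:
    """Per-subject, per-condition flat metric tables keyed by condition."""
    rois = list(study.roi_map.roi_names)
    out = {}
    for cond in CONDITIONS:
        rows = []
        for s in range(study.effects.n_subjects):
            m = ConnectivityMatrix(study.roi[cond][s], tuple(rois))
            summary = network_summary(m)
            row: dict[str, float] = {
                "global_efficiency": float(summary["global_efficiency"].iloc[0])
            }
            for roi in rois:
                row[f"strength_{roi}"] = float(summary.loc[roi, "strength"])
                row[f"clustering_{roi}"] = float(summary.loc[roi, "clustering"])
                row[f"local_efficiency_{roi}"] = float(
                    summary.loc[roi, "local_efficiency"]
                )
            rows.append(row)
        out[cond] = pd.DataFrame(rows, index=study.subjects).rename_axis("subject")
    return out


def _load_study_from_files(config: RunConfig) -> StudyData:
    """Re-analysis mode: read per-subject SNIRF recordings and run the
    preprocessing + connectivity chain on each."""
    layout = ChannelLayout(
        distance_cm=config.distance_cm,
        wavelengths_nm=tuple(config.wavelengths_nm),
    )
    roi_map = default_roi_map()
    in_dir = Path(config.input_dir)
    snirfs = sorted(in_dir.glob("sub-*.snirf"))
    if not snirfs:
        raise DataError(f"no sub-*.snirf recordings found in {in_dir}")
    ext = np.asarray(config.extinction, dtype=float)
    plv_c, roi_c, prof_c = (
        {c: [] for c in CONDITIONS},
        {c: [] for c in CONDITIONS},
        {c: [] for c in CONDITIONS},
    )
    epochs_list, schedules = [], []
    for path in snirfs:
        raw = read_snirf(path, layout)
        hemo = mbll_invert(raw, tuple(config.dpf), ext, config.distance_cm)
        hemo.markers = raw.markers
        events_path = path.with_name(path.stem + "_events.tsv")
        events = read_events_tsv(events_path) if events_path.exists() else raw.markers
        schedule = _schedule_from_events(events, config)
        schedules.append(schedule)
        filtered = preprocess(
            hemo, schedule, config.target_hz, tuple(config.band_hz), config.filter_order
        )
        mats = condition_matrices(
            filtered, schedule, roi_map, config.edge_trim_s, config.min_segment_s
        )
        for cond in CONDITIONS:
            plv_c[cond].append(mats[cond]["channel"].values)
            roi_c[cond].append(mats[cond]["roi"].values)
            prof_c[cond].append(mats[cond]["seed"].to_numpy())
        epochs_list.append(
            epoch_and_baseline(
                filtered,
                schedule,
                tuple(config.epoch_window_s),
                tuple(config.baseline_window_s),
                subject=len(schedules),
            )
        )
    from .containers import EpochSet

    epochs = EpochSet(
        data=np.concatenate([e.data for e in epochs_list]),
        index=pd.concat([e.index for e in epochs_list], ignore_index=True),
        times=epochs_list[0].times,
        rate_hz=epochs_list[0].rate_hz,
        layout=layout,
    )
    behavior_path = in_dir / "behavior.tsv"
    behavior = read_behavior_tsv(behavior_path) if behavior_path.exists() else None
    effects = StudyEffects(n_subjects=len(snirfs))
    return StudyData(
        effects=effects,
        layout=layout,
        roi_map=roi_map,
        schedules=schedules,
        plv={c: np.stack(v) for c, v in plv_c.items()},
        roi={c: np.stack(v) for c, v in roi_c.items()},
        seed_profiles={c: np.stack(v) for c, v in prof_c.items()},
        epochs=epochs,
        behavior=behavior,
    )


def _schedule_from_events(events: pd.DataFrame, config: RunConfig):
    """Rebuild a trial schedule from a screen-level events table."""
    first = events.sort_values("onset_s")["condition"].iloc[0]
    lead = float(events["onset_s"].min()) - 0.5
    return generate_paradigm(
        n_trials_per_condition=int(
            (events["condition"] == first).sum() // events["screen_index"].max()
        ),
        first_condition=first,
        lead_in_s=lead,
    )


def write_subject_recordings(study: StudyData, config: RunConfig, out: Path) -> list[Path]:
    """Forward-model each subject's ΔHbO through the MBLL and write
    SNIRF + events files (the generator's file interface)."""
    from .synth import simulate_hemodynamics  # single-subject re-synthesis

    paths = []
    ext = np.asarray(config.extinction, dtype=float)
    for s, sched in enumerate(study.schedules, start=1):
        series = simulate_hemodynamics(
            sched, study.layout, seed=config.seed * 100_000 + s, rate_hz=config.rate_hz
        )
        raw = forward_mbll(series, tuple(config.dpf), ext, config.distance_cm)
        p = out / f"sub-{s:03d}.snirf"
        write_snirf(raw, p)
        write_events_tsv(sched.events, out / f"sub-{s:03d}_events.tsv")
        paths.append(p)
    return paths


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute every stage under one config; see module docstring."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}

    stage = "simulate"
    try:
        if config.mode == "simulate":
            study = simulate_study(_effects_for(config), seed=config.seed)
        else:
            stage = "load"
            study = _load_study_from_files(config)

        if config.write_recordings and config.mode == "simulate":
            for p in write_subject_recordings(study, config, out):
                outputs[p.name] = p

        stage = "stats"
        activation = channel_activation_contrast(
            study.epochs, tuple(config.summary_window_s), q=config.q
        )
        seed_contrast = connectivity_contrast(
            study.roi["OOC"], study.roi["SOC"], level="seed",
            labels=tuple(study.roi_map.roi_names), q=config.q,
        )
        roi_contrast = connectivity_contrast(
            study.roi["OOC"], study.roi["SOC"], level="roi-pair",
            labels=tuple(study.roi_map.roi_names), q=config.q,
        )
        pair_contrast = connectivity_contrast(
            study.plv["OOC"], study.plv["SOC"], level="channel-pair",
            labels=tuple(study.layout.channels), q=config.q,
        )

        stage = "network"
        metrics = _network_tables(study)
        ge_result, nodal = metric_contrast(metrics["OOC"], metrics["SOC"], q=config.q)

        stage = "behavior"
        rt = low = None
        if study.behavior is not None:
            rt = rt_contrast(study.behavior)
            low = low_price_contrast(study.behavior)

        stage = "report"
        mean_plv = {
            cond: ConnectivityMatrix(
                study.plv[cond].mean(axis=0), tuple(study.layout.channels)
            )
            for cond in CONDITIONS
        }
        tables: dict[str, pd.DataFrame] = {
            "activation_contrast.tsv": activation.to_frame(),
            "seed_contrast.tsv": seed_contrast.to_frame(),
            "roi_pair_contrast.tsv": roi_contrast.to_frame(),
            "channel_pair_contrast.tsv": pair_contrast.to_frame(),
            "network_contrast.tsv": pd.concat(
                [
                    pd.DataFrame(
                        [
                            {
                                "analysis": "global_efficiency",
                                "unit": "global_efficiency",
                                "t": ge_result.t,
                                "df": ge_result.df,
                                "p_raw": ge_result.p_raw,
                                "p_adj": ge_result.p_raw,
                                "dz": ge_result.dz,
                                "mean_diff": ge_result.mean_diff,
                                "significant": ge_result.p_raw < config.q,
                            }
                        ]
                    ),
                    nodal.to_frame(),
                ],
                ignore_index=True,
            ),
        }
        for cond in CONDITIONS:
            tables[f"network_metrics_{cond}.tsv"] = metrics[cond].reset_index()
        if rt is not None:
            tables["behavior_rt.tsv"] = rt.per_subject
            tables["behavior_low_price.tsv"] = low.per_subject
            tables["behavior_low_price_summary.tsv"] = (
                low.condition_summary.reset_index()
            )
            outputs["behavior_log.tsv"] = write_behavior_tsv(
                study.behavior, out / "behavior_log.tsv"
            )
        # Fig-4 style 0/1 significance heatmap over channel pairs
        n_ch = study.layout.n_channels
        heat = np.zeros((n_ch, n_ch), dtype=int)
        for r in pair_contrast.results:
            a, b = r.unit.split("-")
            i, j = study.layout.index(a), study.layout.index(b)
            heat[i, j] = heat[j, i] = int(r.p_adj < config.q)
        tables["significance_heatmap.tsv"] = pd.DataFrame(
            heat, index=list(study.layout.channels), columns=list(study.layout.channels)
        ).reset_index(names="node")

        for name, df in tables.items():
            p = out / name
            df.to_csv(p, sep="\t", index=False)
            outputs[name] = p
        for cond in CONDITIONS:
            outputs[f"plv_mean_{cond}.tsv"] = write_matrix_tsv(
                mean_plv[cond], out / f"plv_mean_{cond}.tsv"
            )
            outputs[f"binary_{cond}.tsv"] = write_edge_list(
                binarize(mean_plv[cond], config.binary_threshold),
                out / f"binary_{cond}.tsv",
            )
        write_events_tsv(study.schedules[0].events, out / "events_example.tsv")
        outputs["events_example.tsv"] = out / "events_example.tsv"

        manifest = {
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "version": __version__,
            "config": config.to_dict(),
            "outputs": sorted(outputs),
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        outputs["manifest.json"] = out / "manifest.json"
    except NirsPlvError as exc:
        raise type(exc)(f"stage '{stage}' failed: {exc}") from exc

    return RunReport(
        config=config,
        out_dir=out,
        manifest=manifest,
        activation=activation,
        seed_contrast=seed_contrast,
        roi_contrast=roi_contrast,
        channel_pair_contrast=pair_contrast,
        global_efficiency_result=ge_result,
        nodal_contrast=nodal,
        rt=rt,
        low_price=low,
        mean_plv=mean_plv,
        outputs=outputs,
    )
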