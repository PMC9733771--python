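"""End-to-end orchestration: simulate -> preprocess -> microstates ->
backfit -> fuse -> stats, with cached stage outputs and a run manifest.

Each stage writes its outputs under the run directory and is skipped when
they already exist; deterministic stages reproduce identical checksums
under a fixed master seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import backfit as bf
from . import eeg as eegmod
from . import fnirs as fnirsmod
from . import fusion as fus
from . import io as msio
from . import microstates as ms
from . import simulate as sim
from . import stats as st
from .config import PipelineConfig, dump_config
from .containers import MsfusionError

logger = logging.getLogger(__name__)

STAGES = ["simulate", "preprocess_eeg", "preprocess_fnirs", "microstates",
          "backfit", "fuse", "stats"]

EPOCH_KINDS = ("task_start", "error")


class StageFailure(MsfusionError):
    def __init__(self, stage: str, detail: str):
        super().__init__(f"stage '{stage}' failed: {detail}")
        self.stage = stage


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run(config: PipelineConfig, out_dir, stages=None, force: bool = False
        ) -> dict:
    """Run the pipeline (or a subset of stages) and return the manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stages = stages or STAGES
    manifest_path = out_dir / "run_manifest.json"
    manifest = {"config_hash": hashlib.sha256(
        dump_config(config).encode()).hexdigest(),
        "seed": config.seed, "stages": {}}
    if manifest_path.exists():
        old = json.loads(manifest_path.read_text())
        if old.get("config_hash") == manifest["config_hash"]:
            manifest["stages"] = old.get("stages", {})

    ctx = {"config": config, "out": out_dir}
    for stage in STAGES:
        if stage not in stages:
            continue
        fn = globals()[f"_stage_{stage}"]
        outputs = fn(ctx, check_only=True)
        if not force and outputs and all(Path(p).exists() for p in outputs):
            logger.info("stage %s: outputs present, skipping", stage)
        else:
            logger.info("stage %s: running", stage)
            t0 = time.time()
            try:
                fn(ctx, check_only=False)
            except Exception as exc:
                raise StageFailure(stage, str(exc)) from exc
            logger.info("stage %s done in %.1f s", stage, time.time() - t0)
        manifest["stages"][stage] = {
            "outputs": {str(Path(p).relative_to(out_dir)): _sha256(Path(p))
                        for p in fn(ctx, check_only=True)},
            "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        }
        manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest


# ---------------------------------------------------------------------------
# stage helpers

def _subjects(ctx) -> list[dict]:
    man = yaml.safe_load((ctx["out"] / "cohort" / "manifest.yaml").read_text())
    return man["subjects"]


def _subject_dir(ctx, s) -> Path:
    return ctx["out"] / "cohort" / s["dir"]


def _stage_simulate(ctx, check_only: bool):
    cfg = ctx["config"]
    cohort_dir = ctx["out"] / "cohort"
    outputs = [cohort_dir / "manifest.yaml"]
    if cohort_dir.exists():
        try:
            outputs += [_subject_dir(ctx, s) / f"{s['id']}_events.tsv"
                        for s in _subjects(ctx)]
        except FileNotFoundError:
            pass
    if check_only:
        return outputs
    simcfg = dataclasses.replace(cfg.sim, seed=cfg.seed)
    sim.gen_cohort(simcfg, cohort_dir, overwrite=True)


def _stage_preprocess_eeg(ctx, check_only: bool):
    prep = ctx["out"] / "prep"
    if not (ctx["out"] / "cohort" / "manifest.yaml").exists():
        return [] if check_only else None
    subs = _subjects(ctx)
    outputs = [prep / f"{s['id']}_eeg.npz" for s in subs] + \
        [prep / f"{s['id']}_eeg_report.json" for s in subs]
    if check_only:
        return outputs
    a = ctx["config"].analysis
    prep.mkdir(exist_ok=True)
    for s in subs:
        rec = msio.read_eeg(_subject_dir(ctx, s) / f"{s['id']}_eeg.vhdr")
        clean, report = eegmod.preprocess_eeg(
            rec, target_fs=a.eeg_target_fs, highpass_hz=a.highpass_hz,
            line_freq=a.line_freq, asr_k=a.asr_k, flat_sd=a.bad_flat_sd,
            corr_r=a.bad_corr_r, max_bad=a.max_bad_channels)
        lap = eegmod.surface_laplacian(clean)
        bp = eegmod.bandpower_envelope(lap, a.band_low_hz, a.band_high_hz,
                                       out_fs=ctx["config"].sim.fs_fnirs)
        np.savez_compressed(
            prep / f"{s['id']}_eeg.npz", data=clean.data, fs=clean.fs,
            positions=clean.channel_positions,
            names=np.array(clean.channel_names), bandpower=bp)
        (prep / f"{s['id']}_eeg_report.json").write_text(
            json.dumps(report.to_dict(), indent=2))


def _stage_preprocess_fnirs(ctx, check_only: bool):
    prep = ctx["out"] / "prep"
    if not (ctx["out"] / "cohort" / "manifest.yaml").exists():
        return [] if check_only else None
    subs = _subjects(ctx)
    outputs = [prep / f"{s['id']}_fnirs.npz" for s in subs]
    if check_only:
        return outputs
    a = ctx["config"].analysis
    prep.mkdir(exist_ok=True)
    for s in subs:
        rec = msio.read_fnirs(_subject_dir(ctx, s) / f"{s['id']}_fnirs.snirf",
                              ss_threshold_mm=a.ss_threshold_mm)
        rec, mask = fnirsmod.preprocess_fnirs(
            rec, amp_threshold_od=a.motion_amp_od,
            sd_factor=a.motion_sd_factor, sg_window_s=a.sg_window_s,
            sg_order=a.sg_order, low=a.nvc_low_hz, high=a.nvc_high_hz)
        np.savez_compressed(
            prep / f"{s['id']}_fnirs.npz", hbo=rec.hbo, fs=rec.fs,
            ls_index=rec.ls_index, ss_index=rec.ss_index,
            motion_fraction=mask.mask.mean())


def _load_eeg(ctx, sub_id: str):
    d = np.load(ctx["out"] / "prep" / f"{sub_id}_eeg.npz")
    from .containers import EegRecording

    return EegRecording(data=d["data"], fs=float(d["fs"]),
                        channel_names=[str(n) for n in d["names"]],
                        channel_positions=d["positions"]), d["bandpower"]


def _excluded(ctx, sub_id: str) -> bool:
    rep = json.loads((ctx["out"] / "prep" / f"{sub_id}_eeg_report.json"
                      ).read_text())
    return bool(rep.get("excluded"))


def _stage_microstates(ctx, check_only: bool):
    model_dir = ctx["out"] / "model"
    outputs = [model_dir / "microstate_model.json", model_dir / "k_table.tsv"]
    if check_only:
        return outputs
    a = ctx["config"].analysis
    model_dir.mkdir(exist_ok=True)
    rng_master = np.random.SeedSequence(ctx["config"].seed + 1)
    samples = []
    subs = [s for s in _subjects(ctx) if not _excluded(ctx, s["id"])]
    for s, child in zip(subs, rng_master.spawn(len(subs))):
        rec, _ = _load_eeg(ctx, s["id"])
        gfp = ms.compute_gfp(rec)
        samples += ms.find_gfp_peaks(
            gfp, rec.data, min_dist_ms=a.min_peak_distance_ms,
            n_per_subject=a.n_peaks_per_subject, sd_reject=a.gfp_sd_reject,
            seed=np.random.default_rng(child), subject=s["id"])
    model, table = ms.select_k(
        samples, k_range=(a.k_min, a.k_max), restarts=a.kmeans_restarts,
        max_iter=a.kmeans_max_iter, tol=a.kmeans_tol,
        seed=ctx["config"].seed + 2)
    (model_dir / "microstate_model.json").write_text(
        json.dumps(model.to_dict(), indent=2))
    table.to_csv(model_dir / "k_table.tsv", sep="\t", index=False)


def _load_model(ctx) -> ms.MicrostateModel:
    return ms.MicrostateModel.from_dict(json.loads(
        (ctx["out"] / "model" / "microstate_model.json").read_text()))


def _stage_backfit(ctx, check_only: bool):
    bdir = ctx["out"] / "backfit"
    outputs = [bdir / "microstate_stats.tsv", bdir / "transitions.json",
               bdir / "coverage_by_subject.tsv"]
    if check_only:
        return outputs
    a = ctx["config"].analysis
    bdir.mkdir(exist_ok=True)
    model = _load_model(ctx)
    stats_rows = []
    transitions = {}
    coverage_rows = []
    segs_by = {}
    for s in _subjects(ctx):
        if _excluded(ctx, s["id"]):
            continue
        rec, _ = _load_eeg(ctx, s["id"])
        events = msio.read_events_tsv(
            _subject_dir(ctx, s) / f"{s['id']}_events.tsv")
        for kind in EPOCH_KINDS:
            epochs = eegmod.epoch_extract(rec, events, kind,
                                          length_s=a.epoch_length_s)
            segs = []
            for ep in epochs:
                seg = bf.backfit_labels(ep, model, epoch_kind=kind, fs=rec.fs)
                segs.append(bf.temporal_smooth(seg, a.min_segment_ms))
            if not segs:
                continue
            segs_by.setdefault((s["group"], kind), []).append(
                (s["id"], segs, epochs))
    for (group, kind), entries in segs_by.items():
        all_segs = [seg for _, segs, _ in entries for seg in segs]
        all_eps = [ep for _, _, eps in entries for ep in eps]
        stats = bf.segment_stats(all_segs, all_eps, model)
        for _, row in stats.table.iterrows():
            stats_rows.append({"group": group, "epoch_kind": kind,
                               **row.to_dict()})
        tm = bf.transition_matrix(all_segs)
        transitions[f"{group}_{kind}"] = {"probs": tm.probs.tolist(),
                                          "counts": tm.counts.tolist()}
        for sub_id, segs, eps in entries:
            cov = bf.segment_stats(segs).coverage
            for j, c in enumerate(cov):
                coverage_rows.append({"subject": sub_id, "group": group,
                                      "epoch_kind": kind, "state": j + 1,
                                      "proportion": c})
    pd.DataFrame(stats_rows).to_csv(bdir / "microstate_stats.tsv", sep="\t",
                                    index=False)
    (bdir / "transitions.json").write_text(json.dumps(transitions, indent=2))
    pd.DataFrame(coverage_rows).to_csv(bdir / "coverage_by_subject.tsv",
                                       sep="\t", index=False)


def _stage_fuse(ctx, check_only: bool):
    fdir = ctx["out"] / "fusion"
    outputs = [fdir / "r_fit.tsv", fdir / "responses.npz"]
    if check_only:
        return outputs
    a = ctx["config"].analysis
    fdir.mkdir(exist_ok=True)
    r_rows = []
    responses = {}
    for s in _subjects(ctx):
        if _excluded(ctx, s["id"]):
            continue
        _, bp = _load_eeg(ctx, s["id"])
        d = np.load(ctx["out"] / "prep" / f"{s['id']}_fnirs.npz")
        hbo, fs5 = d["hbo"], float(d["fs"])
        ls, ss = d["ls_index"], d["ss_index"]
        n = min(bp.shape[1], hbo.shape[1])
        bpf = fus.nvc_bandlimit(bp[:, :n], fs5, a.nvc_low_hz, a.nvc_high_hz)
        design = fus.temporal_embed(bpf, fs5, a.tcca_max_lag_s,
                                    a.tcca_step_s)
        cca = fus.regularized_cca(design, hbo[ls, :n].T, reg=a.tcca_reg)
        regs = fus.select_regressors(cca, ct=a.cca_ct, max_n=a.cca_max_n)
        X, groups = fus.build_design(
            regs, hbo[ss, design.row_offset:n], drift_order=a.drift_order)
        fit = fus.glm_solve(hbo[ls, :n], X, groups,
                            row_offset=design.row_offset)
        for ch, r in zip(ls, fit.r_fit):
            r_rows.append({"subject": s["id"], "group": s["group"],
                           "channel": int(ch) + 1, "r_fit": r,
                           "n_regressors": len(groups["eeg"])})
        events = msio.read_events_tsv(
            _subject_dir(ctx, s) / f"{s['id']}_events.tsv")
        from .containers import ERROR_LABELS

        for kind, labels in (("task_start", ("task_start",)),
                             ("error", ERROR_LABELS)):
            resp = fus.epoch_response(
                fit, events.select(labels), fs5, a.epoch_length_s,
                recording_offset_s=design.row_offset / fs5)
            if resp is not None:
                responses[f"{s['id']}__{kind}"] = resp
    pd.DataFrame(r_rows).to_csv(fdir / "r_fit.tsv", sep="\t", index=False)
    np.savez_compressed(fdir / "responses.npz", **responses)


def _stage_stats(ctx, check_only: bool):
    sdir = ctx["out"] / "stats"
    outputs = [sdir / "channel_ttest.tsv", sdir / "anova.tsv"]
    if check_only:
        return outputs
    a = ctx["config"].analysis
    sdir.mkdir(exist_ok=True)
    groups = {s["id"]: s["group"] for s in _subjects(ctx)}
    resp = np.load(ctx["out"] / "fusion" / "responses.npz")
    ttest_rows = []
    for kind in EPOCH_KINDS:
        by_group = {"novice": [], "expert": []}
        for key in resp.files:
            sub_id, k = key.split("__")
            if k == kind:
                by_group[groups[sub_id]].append(resp[key].mean(axis=1))
        if all(len(v) >= 2 for v in by_group.values()):
            tt = st.channel_ttest(np.array(by_group["expert"]),
                                  np.array(by_group["novice"]), q=a.fdr_q)
            for _, row in tt.table.iterrows():
                ttest_rows.append({"epoch_kind": kind, **row.to_dict()})
    pd.DataFrame(ttest_rows).to_csv(sdir / "channel_ttest.tsv", sep="\t",
                                    index=False)

    cov = pd.read_csv(ctx["out"] / "backfit" / "coverage_by_subject.tsv",
                      sep="\t")
    anova_rows = []
    for kind in EPOCH_KINDS:
        sub = cov[cov["epoch_kind"] == kind].rename(
            columns={"group": "skill"})
        if sub.empty or sub["skill"].nunique() < 2:
            continue
        aov = st.anova_two_way(sub)
        for factor, row in aov.table.iterrows():
            anova_rows.append({
                "epoch_kind": kind, "factor": factor,
                "F": row.get("F", np.nan), "p": row.get("PR(>F)", np.nan),
                "df": row.get("df", np.nan),
                "normality_p": json.dumps(aov.normality_p)})
    pd.DataFrame(anova_rows).to_csv(sdir / "anova.tsv", sep="\t", index=False)
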