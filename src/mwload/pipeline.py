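"""End-to-end wiring: simulate datasets to disk, extract the block
feature table through every modality chain, and run the statistical
layer."""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from . import blockstats, cardiac, eeg, fnirs, ocular, synthio
from .config import PipelineConfig
from .types import (
    FEATURE_COLUMNS,
    Recording,
    design_from_frame,
    design_to_frame,
)

log = logging.getLogger("mwload")


def extract_task_session(
    tsd: synthio.TaskSessionData, cfg: PipelineConfig | None = None
) -> pd.DataFrame:
    """Run every modality chain on one task-session's recordings and
    return the long-format feature table."""
    cfg = cfg or PipelineConfig()
    rec = tsd.recordings
    rows: list[dict] = []
    if "fnirs_730" in rec and "fnirs_850" in rec:
        _, r = fnirs.process(rec["fnirs_730"], rec["fnirs_850"], tsd.design,
                             cfg.fnirs)
        rows += r
        log.info("fnirs: %d feature rows", len(r))
    if "eeg" in rec:
        eog_ref = None
        if "eog_h" in rec and "eog_v" in rec:
            n = rec["eeg"].n_samples
            eog_ref = Recording(
                "eog", rec["eeg"].sample_rate_hz, ["eog_h", "eog_v"],
                np.vstack([
                    rec["eog_h"].samples[0][:n],
                    rec["eog_v"].samples[0][:n],
                ]),
            )
        _, r = eeg.process(rec["eeg"], tsd.design, cfg.eeg, eog=eog_ref)
        rows += r
        log.info("eeg: %d feature rows", len(r))
    if "ecg" in rec or "ppg" in rec:
        r = cardiac.process(rec.get("ecg"), rec.get("ppg"), tsd.design,
                            cfg.cardiac)
        rows += r
        log.info("cardiac: %d feature rows", len(r))
    if "eog_h" in rec or "gaze" in rec:
        r = ocular.process(
            rec.get("eog_h"), rec.get("eog_v"), rec.get("gaze"),
            rec.get("pupil"), tsd.design, cfg.ocular,
        )
        rows += r
        log.info("ocular: %d feature rows", len(r))
    rows += tsd.behavior_rows
    return pd.DataFrame(rows, columns=list(FEATURE_COLUMNS))


# ---------------------------------------------------------------------------
# disk dataset
# ---------------------------------------------------------------------------

def simulate_dataset(
    out_dir: str | Path,
    cfg: PipelineConfig | None = None,
    tasks: list[str] | None = None,
    sessions: list[int] | None = None,
    modalities: tuple[str, ...] = ("fnirs", "eeg", "cardiac", "ocular"),
    force: bool = False,
) -> Path:
    """Write a synthetic dataset: per subject and task-session, one CSV +
    JSON sidecar per recording, the block design, ground truth and
    behavioural features; a manifest records the seed and layout."""
    cfg = cfg or PipelineConfig()
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not force:
        raise FileExistsError(f"{out} is not empty (use force=True)")
    out.mkdir(parents=True, exist_ok=True)
    schedules = synthio.generate_protocol(cfg.synth.n_subjects, cfg.seed)
    tasks = list(synthio.TASKS) if tasks is None else tasks
    manifest: dict = {
        "seed": cfg.seed,
        "n_subjects": cfg.synth.n_subjects,
        "modalities": list(modalities),
        "subjects": {},
    }
    for sched in schedules:
        sdir = out / sched.subject_id
        sdir.mkdir(exist_ok=True)
        entries = []
        for task in tasks:
            for ts in sessions or (1, 2, 3):
                tsd = synthio.simulate_task_session(
                    sched.subject_id, task, ts, cfg.synth, cfg.seed,
                    modalities=modalities,
                )
                tdir = sdir / f"{task}_s{ts}"
                tdir.mkdir(exist_ok=True)
                for name, rec in tsd.recordings.items():
                    rec.save(tdir / name)
                design_to_frame(tsd.design).to_csv(
                    tdir / "design.csv", index=False
                )
                (tdir / "truth.json").write_text(json.dumps(
                    [dataclasses.asdict(g) for g in tsd.truth], indent=1
                ))
                pd.DataFrame(tsd.behavior_rows).to_csv(
                    tdir / "behavior.csv", index=False
                )
                np.savetxt(tdir / "true_rpeaks.txt", tsd.true_rpeak_times_s)
                entries.append({"task": task, "task_session": ts,
                                "dir": str(tdir.relative_to(out))})
        manifest["subjects"][sched.subject_id] = entries
    cfg.save(out / "config.yaml")
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out


def extract_dataset(
    dataset_dir: str | Path, cfg: PipelineConfig | None = None
) -> pd.DataFrame:
    """Extract the feature table from a dataset directory written by
    :func:`simulate_dataset`.  Missing modality files are skipped with a
    warning; other modalities still complete."""
    dataset_dir = Path(dataset_dir)
    cfg = cfg or PipelineConfig()
    manifest = json.loads((dataset_dir / "manifest.json").read_text())
    frames = []
    for subject, entries in manifest["subjects"].items():
        for e in entries:
            tdir = dataset_dir / e["dir"]
            recordings = {}
            for name in ("fnirs_730", "fnirs_850", "eeg", "ecg", "ppg",
                         "eog_h", "eog_v", "gaze", "pupil"):
                try:
                    if (tdir / f"{name}.csv").exists():
                        recordings[name] = Recording.load(tdir / name)
                    else:
                        warnings.warn(f"{tdir}: missing {name}, skipped")
                except ValueError as exc:
                    raise ValueError(f"{tdir / name}: {exc}") from exc
            design = design_from_frame(pd.read_csv(tdir / "design.csv"))
            behavior = (
                pd.read_csv(tdir / "behavior.csv").to_dict("records")
                if (tdir / "behavior.csv").exists() else []
            )
            tsd = synthio.TaskSessionData(
                subject_id=subject,
                task_name=e["task"],
                task_session=e["task_session"],
                design=design,
                truth=[],
                recordings=recordings,
                true_rpeak_times_s=np.zeros(0),
                true_saccades=[],
                behavior_rows=behavior,
            )
            frames.append(extract_task_session(tsd, cfg))
    return pd.concat(frames, ignore_index=True)


def analyze_table(
    table: pd.DataFrame,
    cfg: PipelineConfig | None = None,
    pca_feature_subset: list[str] | None = None,
    seed: int | None = None,
) -> dict:
    """Statistical layer: per-measure LMMs, grouped FDR, report rows and
    the PCA variance partition.  Returns a dict of result objects."""
    cfg = cfg or PipelineConfig()
    if table.empty:
        raise ValueError("empty feature table")
    results, skipped = blockstats.fit_all_measures(
        table, cfg.stats.residual_structure
    )
    blockstats.apply_fdr(results, alpha=cfg.stats.alpha)
    report = blockstats.select_report_rows(
        results, cfg.stats.max_rows_per_modality, cfg.stats.alpha
    )
    pca = None
    try:
        pca = blockstats.pca_variance_partition(
            table, pca_feature_subset, cfg.stats.pca_n_repeats,
            cfg.seed if seed is None else seed,
        )
    except ValueError as exc:
        warnings.warn(f"PCA partition skipped: {exc}")
    return {
        "effects": results,
        "skipped_measures": skipped,
        "report_rows": report,
        "pca": pca,
    }
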