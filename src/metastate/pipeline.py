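"""End-to-end orchestration: files in, result tables out.

Every stage is also callable directly from the library with identical
results; the pipeline only chains them and handles file layout. Input
datasets are directories of ``<subject>_ses<1|2>.tsv`` time-series files
(volumes x regions, header = region labels) with optional
``<subject>_ses<k>.fd.tsv`` framewise-displacement sidecars.
"""

from __future__ import annotations

import json
import logging
import re
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as mio
from .centrality import centrality_sequence
from .clustering import elbow_select_k, match_states, two_stage_fit
from .config import AnalysisConfig
from .dynamics import group_difference_test, icc_matrix, state_dynamics
from .netbuild import censor_volumes, sliding_window_fc
from .synthgen import SyntheticSpec, generate_roi_timeseries, generate_state_sequence, state_templates

logger = logging.getLogger(__name__)

_FILE_RE = re.compile(r"^(?P<subject>.+)_ses(?P<session>\d+)\.tsv$")


def discover_dataset(input_dir: str | Path) -> dict[str, dict[int, Path]]:
    """Map subject -> session -> time-series path."""
    input_dir = Path(input_dir)
    out: dict[str, dict[int, Path]] = {}
    for p in sorted(input_dir.glob("*.tsv")):
        if p.name.endswith(".fd.tsv"):
            continue
        m = _FILE_RE.match(p.name)
        if m:
            out.setdefault(m["subject"], {})[int(m["session"])] = p
    if not out:
        raise ValueError(f"no '<subject>_ses<k>.tsv' files found in {input_dir}")
    return out


def _setup_logfile(out_dir: Path) -> None:
    handler = logging.FileHandler(out_dir / "pipeline.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logging.getLogger("metastate").addHandler(handler)


def run_pipeline(
    config: AnalysisConfig, input_dir: str | Path, out_dir: str | Path
) -> dict:
    """Censor, window, compute centrality, cluster, and summarize dynamics.

    Writes per-subject-session centrality TSVs, the metastate model JSONs,
    dwell/transition tables and — when two sessions are present — the
    matched-state ICC matrix. Deterministic given the config seed.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    _setup_logfile(out_dir)
    dataset = discover_dataset(input_dir)
    sessions = sorted({s for d in dataset.values() for s in d})
    logger.info(
        "pipeline start: %d subjects, sessions %s, width=%d step=%d density=%g seed=%d",
        len(dataset), sessions, config.window_width_volumes,
        config.window_step_volumes, config.density, config.seed,
    )

    # --- read, censor, window, centrality --------------------------------
    centr: dict[int, dict[str, np.ndarray]] = {s: {} for s in sessions}
    labels_ref: list[str] | None = None
    excluded: list[str] = []
    for subject, files in sorted(dataset.items()):
        drop = False
        per_session = {}
        for sess, path in sorted(files.items()):
            ts = mio.read_timeseries(path, tr_s=config.tr_s)
            if labels_ref is None:
                labels_ref = ts.labels
            elif ts.labels != labels_ref:
                raise ValueError(
                    f"{path}: region labels differ from the first subject's"
                )
            fd_path = path.with_name(path.name[: -len(".tsv")] + ".fd.tsv")
            if fd_path.exists():
                res = censor_volumes(
                    ts, mio.read_fd(fd_path), config.fd_threshold_mm, config.min_volumes
                )
                if res.excluded:
                    drop = True
                    break
                ts = res.timeseries
            wseq = sliding_window_fc(
                ts, config.window_width_volumes, config.window_step_volumes
            )
            cs = centrality_sequence(wseq, kind="eigenvector", density=config.density)
            per_session[sess] = cs.scores
            df = pd.DataFrame(cs.scores, columns=ts.labels)
            df.to_csv(
                out_dir / f"{subject}_ses{sess}_centrality.tsv",
                sep="\t", index=False, float_format=mio.FLOAT_FMT,
            )
        if drop:
            excluded.append(subject)
            logger.warning("subject %s excluded by motion censoring", subject)
            continue
        for sess, scores in per_session.items():
            centr[sess][subject] = scores
    subjects = sorted(set.intersection(*[set(centr[s]) for s in sessions]))
    if not subjects:
        raise ValueError("no subjects usable after censoring")

    # --- per-session two-stage clustering --------------------------------
    results: dict[int, dict] = {}
    for sess in sessions:
        mats = [centr[sess][subj] for subj in subjects]
        pooled = np.vstack(mats)
        validity = None
        if config.k_fixed is not None:
            k = config.k_fixed
        else:
            k, validity = elbow_select_k(pooled, config.k_range, seed=config.seed)
            logger.info("session %d: elbow selected k=%d", sess, k)
        fit = two_stage_fit(mats, k, seed=config.seed)
        model = fit.group_model
        model.validity_curve = validity
        (out_dir / f"ses{sess}_model.json").write_text(
            json.dumps(model.to_dict(), indent=1) + "\n"
        )
        results[sess] = {"k": k, "fit": fit}

    # --- state matching across sessions ----------------------------------
    if len(sessions) == 2 and results[sessions[0]]["k"] == results[sessions[1]]["k"]:
        s1, s2 = sessions
        matching = match_states(
            results[s2]["fit"].group_model.centers,
            results[s1]["fit"].group_model.centers,
        )
        results[s2]["fit"].subject_labels = [
            matching.permutation[lab] for lab in results[s2]["fit"].subject_labels
        ]
        logger.info("session %d states relabeled to session %d: %s",
                    s2, s1, matching.permutation.tolist())

    # --- dynamics ---------------------------------------------------------
    dyn: dict[int, list] = {}
    for sess in sessions:
        k = results[sess]["k"]
        fit = results[sess]["fit"]
        dyn[sess] = [
            state_dynamics(lab, config.tr_s, k) for lab in fit.subject_labels
        ]
        dwell = pd.DataFrame(
            np.stack([d.dwell_windows for d in dyn[sess]]),
            index=subjects, columns=[f"S{i + 1}" for i in range(k)],
        )
        dwell.to_csv(out_dir / f"ses{sess}_dwell_windows.tsv", sep="\t",
                     float_format=mio.FLOAT_FMT)
        trans = sum(d.transitions for d in dyn[sess])
        pd.DataFrame(
            trans, index=[f"S{i + 1}" for i in range(k)],
            columns=[f"S{i + 1}" for i in range(k)],
        ).to_csv(out_dir / f"ses{sess}_transitions_total.tsv", sep="\t",
                 float_format=mio.FLOAT_FMT)
        for subj, lab in zip(subjects, fit.subject_labels):
            pd.DataFrame({"window": np.arange(1, lab.size + 1), "state": lab + 1}).to_csv(
                out_dir / f"{subj}_ses{sess}_labels.tsv", sep="\t", index=False
            )

    summary = {
        "subjects": subjects,
        "excluded": excluded,
        "sessions": sessions,
        "k": {str(s): results[s]["k"] for s in sessions},
        "seed": config.seed,
    }

    # --- test-retest reliability -----------------------------------------
    if len(sessions) == 2 and results[sessions[0]]["k"] == results[sessions[1]]["k"]:
        s1, s2 = sessions
        k = results[s1]["k"]
        icc = icc_matrix(dyn[s1], dyn[s2])
        state_names = [f"S{i + 1}" for i in range(k)]
        icc_df = pd.DataFrame(icc, index=state_names, columns=state_names)
        icc_df.to_csv(out_dir / "icc_matrix.tsv", sep="\t", na_rep="NA",
                      float_format=mio.FLOAT_FMT)
        summary["icc_mean_defined"] = float(np.nanmean(icc))
        if len(subjects) >= 3:
            report = group_difference_test(
                np.stack([d.dwell_windows for d in dyn[s1]]),
                np.stack([d.dwell_windows for d in dyn[s2]]),
            )
            summary["anova_p"] = [report.anova_p_a, report.anova_p_b]
        else:
            logger.info("fewer than 3 subjects: group difference tests skipped")

    (out_dir / "summary.json").write_text(json.dumps(summary, indent=1) + "\n")
    logger.info("pipeline done: %s", out_dir)
    return summary


def require_two_sessions(dataset: dict[str, dict[int, Path]]) -> None:
    sessions = sorted({s for d in dataset.values() for s in d})
    if len(sessions) < 2:
        raise ValueError("two sessions required for test-retest analysis")


def simulate_dataset(spec: SyntheticSpec, out_dir: str | Path) -> dict:
    """Write a complete two-session synthetic dataset: time series, all-zero
    FD sidecars, and a truth.json with planted labels, templates and hub
    sets."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    labels = generate_state_sequence(spec)
    stream = np.random.default_rng(
        np.random.SeedSequence(spec.seed, spawn_key=(7,))
    )
    truth = {
        "spec": {
            "n_subjects": spec.n_subjects,
            "n_states": spec.n_states,
            "n_regions": spec.n_regions,
            "windows_per_session": spec.windows_per_session,
            "window_width_volumes": spec.window_width_volumes,
            "tr_s": spec.tr_s,
            "mean_dwell": spec.mean_dwell,
            "snr": spec.snr,
            "retest_rho": spec.retest_rho,
            "seed": spec.seed,
        },
        "hub_sets": [list(map(int, h)) for h in spec.hub_sets],
        "templates": state_templates(spec).tolist(),
        "labels": {},
    }
    for si, subj_labels in enumerate(labels):
        subject = f"sub{si + 1:02d}"
        truth["labels"][subject] = {}
        for sess, lab in enumerate(subj_labels, start=1):
            ts = generate_roi_timeseries(spec, lab, stream)
            stem = f"{subject}_ses{sess}"
            mio.write_timeseries(ts.signal, ts.labels, out_dir / f"{stem}.tsv")
            np.savetxt(out_dir / f"{stem}.fd.tsv", np.zeros(ts.n_volumes), fmt="%.1f")
            truth["labels"][subject][str(sess)] = lab.tolist()
    (out_dir / "truth.json").write_text(json.dumps(truth) + "\n")
    return truth
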