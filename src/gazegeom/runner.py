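"""Configuration-driven orchestration of the full analysis.

A run either simulates a cohort with the session generator or ingests a
session bundle from disk, then executes the per-condition analyses
end-to-end: per-trial medians, displacement/conceptual-change correlations
with group statistics, absolute-position geometry recovery, and (optional)
decoding.  Every output file is listed in a manifest with a content hash so
a run is verifiable and reproducible: identical config + seeds give
identical hashes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import conceptspace, decode, gazeprep, geomrec, synthgaze, trialstats
from .errors import ConfigurationError, DataError

__all__ = ["RunConfig", "run_pipeline", "validate_inputs", "load_config"]

CONDITIONS = ("number", "color", "animal")

#: default gaze coupling per domain (px per unit latent coordinate), chosen
#: so that the number condition reproduces a number-line slope of ~6.5 px
#: per unit with per-subject correlations of realistic size, the color ring
#: spans ~150 px on screen, and the animal frequency effect is moderate.
DOMAIN_COUPLING = {"number": 6.5, "color": 150.0, "animal": 0.1}


@dataclass
class RunConfig:
    """All parameters of one run; defaults mirror the experimental design
    (0.75 Hz pace, 500 ms pre-onset window, 1000 permutations, small/large
    split at 6)."""

    mode: str = "simulate"
    conditions: tuple = ("number",)
    out_dir: str = "gazegeom_out"
    seed: int = 0
    # simulate-mode cohort parameters
    n_subjects: int = 30
    n_blocks: int = 3
    n_trials: int = 90
    pace_hz: float = 0.75
    sample_rate_hz: float = 1000.0
    coupling: float | None = None   # None -> per-domain default
    noise_sd: float = 85.0
    drift_sd: float = 2.0
    dropout_rate: float = 0.05
    similarity_noise_sd: float = 0.8
    # analysis parameters
    window_ms: float = 500.0
    min_samples: int = 10
    run_decoding: bool = False
    n_perm: int = 1000
    # ingest-mode inputs
    bundle_dir: str | None = None
    frequency_path: str | None = None
    vectors_path: str | None = None
    clusters_path: str | None = None
    similarity_matrix_path: str | None = None

    def __post_init__(self):
        if self.mode not in ("simulate", "ingest"):
            raise ConfigurationError(f"unknown mode {self.mode!r}")
        self.conditions = tuple(self.conditions)
        for c in self.conditions:
            if c not in CONDITIONS:
                raise ConfigurationError(f"unknown condition {c!r}")


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**raw)


def validate_inputs(config: RunConfig) -> list[dict]:
    """Pre-flight checks; returns machine-readable issues, never raises."""
    issues: list[dict] = []

    def err(msg):
        issues.append({"level": "error", "message": msg})

    def warn(msg):
        issues.append({"level": "warning", "message": msg})

    if config.mode == "ingest":
        if config.bundle_dir is None:
            err("ingest mode requires bundle_dir")
            return issues
        bundle = Path(config.bundle_dir)
        events_path = bundle / "events.csv"
        if not events_path.exists():
            err(f"missing events table {events_path}")
            return issues
        events = pd.read_csv(events_path)
        need = {"subject", "block", "word", "onset_ms", "offset_ms"}
        if not need.issubset(events.columns):
            err(f"events table missing columns {sorted(need - set(events.columns))}")
            return issues
        for (subj, block), ev in events.groupby(["subject", "block"]):
            gpath = bundle / "gaze" / f"{subj}_b{block}.tsv"
            if not gpath.exists():
                err(f"missing gaze file {gpath}")
                continue
            rec = pd.read_csv(gpath, sep="\t")
            t = rec["time_ms"].to_numpy()
            if len(t) > 1 and not np.all(np.diff(t) > 0):
                err(f"{gpath}: timestamps not strictly increasing")
                continue
            if len(t) and ev["onset_ms"].max() > t[-1]:
                warn(f"{gpath}: event onset beyond gaze span")
        if "color" in config.conditions and not (bundle / "similarity.csv").exists():
            err("color condition requires similarity.csv in the bundle")
        if "animal" in config.conditions:
            if config.frequency_path is None:
                err("animal condition requires frequency_path")
            elif not Path(config.frequency_path).exists():
                err(f"missing frequency table {config.frequency_path}")
            else:
                freq = conceptspace.load_frequency_table(config.frequency_path)
                words = set(events.loc[events["word"].notna(), "word"].astype(str))
                missing = sorted(w for w in words if w not in freq)
                if missing:
                    for w in missing:
                        err(f"word {w!r} missing from frequency table")
    return issues


# ---------------------------------------------------------------------------

def _subject_geometry(condition: str, seed: int):
    if condition == "number":
        return synthgaze.LatentGeometry.number_line()
    if condition == "color":
        return synthgaze.LatentGeometry.color_ring()
    return synthgaze.LatentGeometry.animal_frequencies(seed=seed)


def _simulate_condition(config: RunConfig, condition: str) -> dict:
    """Simulate a cohort and return per-subject data keyed by subject id."""
    # stable per-condition offset (hash() is randomized per process)
    cond_offset = sum(ord(c) for c in condition)
    rng = np.random.default_rng(config.seed + cond_offset)
    geometry = _subject_geometry(condition, config.seed)
    coupling = (config.coupling if config.coupling is not None
                else DOMAIN_COUPLING[condition])
    center = (1920 / 2, 1080 / 2)
    subjects = {}
    for s in range(config.n_subjects):
        subj = f"s{s:02d}"
        sub_seed = int(rng.integers(2**31))
        affine = None
        if condition == "color":
            affine = synthgaze.random_isometry_affine(
                np.random.default_rng(sub_seed), scale=1.0, center=center)
        cfg = synthgaze.SessionConfig(
            domain=condition, n_trials=config.n_trials, pace_hz=config.pace_hz,
            sample_rate_hz=config.sample_rate_hz, coupling=coupling,
            noise_sd=config.noise_sd, drift_sd=config.drift_sd,
            dropout_rate=config.dropout_rate, affine=affine,
            window_ms=config.window_ms, seed=sub_seed)
        sessions = synthgaze.simulate_subject(cfg, geometry,
                                              n_blocks=config.n_blocks,
                                              subject=subj)
        sim = None
        if condition == "color":
            sim = synthgaze.generate_similarity_judgments(
                geometry, noise_sd=config.similarity_noise_sd, n_reps=2,
                seed=sub_seed + 1, subject=subj)
        subjects[subj] = {"sessions": sessions, "similarity": sim,
                          "seed": sub_seed}
    return {"geometry": geometry, "subjects": subjects}


def _ingest_condition(config: RunConfig, condition: str) -> dict:
    bundle = Path(config.bundle_dir)
    events = pd.read_csv(bundle / "events.csv")
    subjects = {}
    for subj, ev_subj in events.groupby("subject"):
        sessions = []
        for block, ev in ev_subj.groupby("block"):
            rec = gazeprep.GazeRecording.from_tsv(
                bundle / "gaze" / f"{subj}_b{block}.tsv")
            sessions.append(synthgaze.Session(recording=rec,
                                              events=ev.reset_index(drop=True),
                                              truth=pd.DataFrame()))
        sim = None
        if condition == "color":
            sim_all = pd.read_csv(bundle / "similarity.csv")
            sim = sim_all[sim_all["subject"].astype(str) == str(subj)]
        subjects[str(subj)] = {"sessions": sessions, "similarity": sim,
                               "seed": None}
    return {"geometry": None, "subjects": subjects}


def _subject_trials(data: dict, config: RunConfig) -> pd.DataFrame:
    frames = []
    for sess in data["sessions"]:
        frames.append(gazeprep.window_median_gaze(
            sess.recording, sess.events, window_ms=config.window_ms,
            min_samples=config.min_samples))
    return pd.concat(frames, ignore_index=True)


def _change_series(condition: str, trials: pd.DataFrame, data: dict,
                   config: RunConfig, bundle_resources: dict):
    """Concatenated conceptual change series over a subject's blocks."""
    parts = []
    offset = 0
    for block, t in trials.groupby("block", sort=False):
        seq = t["word"].astype(str).tolist()
        if condition == "number":
            parts.append(conceptspace.signed_number_change(seq, start_index=offset))
        elif condition == "color":
            emb = bundle_resources["embedding"]
            parts.append(conceptspace.mds_distance_series(seq, emb,
                                                          start_index=offset))
        else:
            parts.append(conceptspace.animal_distance_series(
                seq, "frequency", bundle_resources, start_index=offset))
        offset += len(t)
    return conceptspace.ConceptChangeSeries(
        parts[0].model, np.concatenate([p.values for p in parts]),
        np.concatenate([p.index for p in parts]))


def _analysis_plan(condition: str) -> list[tuple]:
    if condition == "number":
        return [("x_signed", "combined"), ("y_signed", "combined"),
                ("euclid_2d", "combined"), ("x_signed", "sign_only"),
                ("x_signed", "magnitude_only"),
                ("x_signed", "control_transition")]
    return [("x_signed", "combined"), ("y_signed", "combined"),
            ("euclid_2d", "combined"), ("x_signed", "magnitude_only"),
            ("y_signed", "magnitude_only")]


def run_pipeline(config: RunConfig) -> dict:
    """Execute every configured condition end-to-end; returns the report.

    Writes per-subject correlation CSV, group-stats JSON/CSV, geometry
    tables, optional decoding JSON, and a manifest of content hashes.
    """
    issues = validate_inputs(config)
    errors = [i for i in issues if i["level"] == "error"]
    if errors:
        raise ConfigurationError("; ".join(i["message"] for i in errors))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    per_subject_rows = []
    group_rows = []
    config_echo = dataclasses.asdict(config)
    config_echo.pop("out_dir")  # keep report content location-independent
    report: dict = {"config": config_echo, "issues": issues,
                    "conditions": {}}
    written: list[Path] = []

    for condition in config.conditions:
        cohort = (_simulate_condition(config, condition)
                  if config.mode == "simulate"
                  else _ingest_condition(config, condition))
        cond_report: dict = {}
        subj_results: dict = {}
        mean_pos_tables = []
        gaze_dms = []
        rsa_rhos = []

        for subj, data in cohort["subjects"].items():
            trials = _subject_trials(data, config)
            disp = gazeprep.displacement_series(trials)
            resources: dict = {}
            if condition == "color":
                dm = conceptspace.dissimilarity_from_judgments(
                    data["similarity"],
                    labels=sorted(trials["word"].astype(str).unique()))
                resources["embedding"] = conceptspace.classical_mds(dm)
                resources["concept_dm"] = dm
            elif condition == "animal":
                if config.mode == "simulate":
                    geom = cohort["geometry"]
                    resources["frequency"] = {w: float(geom.coords[w][0])
                                              for w in geom.labels}
                else:
                    resources["frequency"] = conceptspace.load_frequency_table(
                        config.frequency_path)
            change = _change_series(condition, trials, data, config, resources)

            for axis, mode in _analysis_plan(condition):
                if mode == "control_transition":
                    seqs = [t["word"].astype(str).tolist()
                            for _, t in trials.groupby("block", sort=False)]
                    counts = conceptspace.transition_count_series(seqs)
                    series = conceptspace.ConceptChangeSeries(
                        "transition_count",
                        np.concatenate([c.values for c in counts]),
                        np.concatenate([c.index for c in counts]))
                else:
                    series = change
                res = trialstats.condition_correlation(
                    disp, series, axis=axis, mode=mode, subject=subj,
                    condition=condition)
                per_subject_rows.append(dataclasses.asdict(res))
                subj_results.setdefault((axis, mode), []).append(res.z)

            mp = geomrec.concept_mean_positions(trials)
            mean_pos_tables.append(mp)
            if condition == "color" and len(mp) == 12:
                gdm = geomrec.distance_matrix_from_points(
                    mp.sort_values("word").reset_index(drop=True))
                cdm = resources["concept_dm"]
                order = [cdm.labels.index(w) for w in gdm.labels]
                cdm_sorted = conceptspace.DissimilarityMatrix(
                    gdm.labels, cdm.matrix[np.ix_(order, order)])
                rho, _ = geomrec.rsa_lower_triangle(gdm, cdm_sorted)
                rsa_rhos.append(rho)
                gaze_dms.append(gdm)

        for (axis, mode), zs in subj_results.items():
            gs = trialstats.group_t(zs)
            group_rows.append({"condition": condition, "axis": axis,
                               "mode": mode, **dataclasses.asdict(gs)})

        if condition == "number":
            values = {str(i): float(i) for i in range(1, 13)}
            usable = [t for t in mean_pos_tables if len(t) >= 2]
            reg = geomrec.group_position_regression(usable, values, axis="x")
            slope_stats = trialstats.group_t(reg.per_subject_slopes)
            cond_report["regression"] = {
                "slope": reg.slope, "intercept": reg.intercept,
                "t": slope_stats.t, "p": slope_stats.p,
                "bf10": slope_stats.bf10}
            pos = pd.concat(mean_pos_tables).groupby("word", sort=False).agg(
                mean_x_px=("mean_x_px", "mean"), mean_y_px=("mean_y_px", "mean"),
                n_trials=("n_trials", "sum")).reset_index()
            p = out / "number_positions.csv"
            pos.to_csv(p, index=False)
            written.append(p)
        if condition == "color" and gaze_dms:
            emb = geomrec.group_gaze_mds(gaze_dms)
            p = out / "color_group_embedding.csv"
            pd.DataFrame({"word": emb.labels, "dim1": emb.coords[:, 0],
                          "dim2": emb.coords[:, 1]}).to_csv(p, index=False)
            written.append(p)
            rsa_stats = trialstats.group_t(
                [trialstats.fisher_z(r, clip=True) for r in rsa_rhos])
            cond_report["rsa"] = {"mean_rho": float(np.mean(rsa_rhos)),
                                  "t": rsa_stats.t, "p": rsa_stats.p,
                                  "bf10": rsa_stats.bf10}

        if config.run_decoding and condition == "number":
            dec = {}
            for subj, data in cohort["subjects"].items():
                trials = _subject_trials(data, config)
                v = trials[trials["valid"]]
                labels = decode.small_large_labels(v["word"])
                res = decode.permutation_pvalue(
                    v["median_x_px"].to_numpy(float), labels,
                    n_perm=config.n_perm, seed=config.seed + 17)
                dec[subj] = res.to_dict()
            p = out / "decoding_number.json"
            p.write_text(json.dumps(dec, indent=2, sort_keys=True))
            written.append(p)
            cond_report["decoding"] = {
                "mean_observed": float(np.mean(
                    [d["observed_accuracy"] for d in dec.values()])),
                "n_significant": int(sum(d["p_perm"] < 0.05
                                         for d in dec.values()))}
        report["conditions"][condition] = cond_report

    per_subject = pd.DataFrame(per_subject_rows)
    p = out / "per_subject_correlations.csv"
    per_subject.to_csv(p, index=False)
    written.append(p)
    group = pd.DataFrame(group_rows)
    p = out / "group_stats.csv"
    group.to_csv(p, index=False)
    written.append(p)
    p = out / "group_stats.json"
    p.write_text(json.dumps(group_rows, indent=2, sort_keys=True))
    written.append(p)
    p = out / "report.json"
    p.write_text(json.dumps(report, indent=2, sort_keys=True, default=str))
    written.append(p)

    manifest = {"seed": config.seed,
                "files": {f.name: hashlib.sha256(f.read_bytes()).hexdigest()
                          for f in sorted(written)}}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  sort_keys=True))
    report["manifest"] = manifest
    return report
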