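"""Orchestration: configuration, seeding, end-to-end runs and reports.

A pipeline run emulates one recording day of the task protocol: five
12-min sessions of which the middle two can be dark (S3-S4), with the same
cell population throughout. Stages run in dependency order — behavior
(trial segmentation, direction-vector maps, template clustering on the
light sessions, sequence matching of light and dark trials against the
light templates), place-cell classification on the pooled first two light
sessions with the S1-S2 and S2-S5 stability gates, theta modulation and
phase precession, Poisson-GLM forward selection in the light and the
light/dark tuning-strength contrast — and populate a Report of per-trial,
per-cell and population tables. Every stage draws its randomness from
child seeds fanned out of the master seed with a counter-based scheme, so
a rerun with the same configuration is bit-identical and adding cells does
not perturb existing ones.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import behavior as bh
from . import glm
from . import placefields as pf
from . import synthetic as syn
from . import theta as th
from .core import Condition, SessionRecording, resample_behavior

logger = logging.getLogger("forageseq")

MAD_FACTOR = 10.0
MAD_CAP_FRACTION = 0.05


@dataclass
class PipelineConfig:
    """All thresholds default to the analysis' standard values."""

    master_seed: int = 0
    n_cells: int = 40
    n_trials_per_session: int = 30
    n_light_sessions: int = 3
    n_dark_sessions: int = 2
    sequence_fraction_true: float = 0.6
    dark_gain_direction: float = 0.3
    dark_gain_position: float = 1.0
    template_match_r: float = 0.6
    n_shuffles: int = 500
    min_shift_s: float = 5.0
    alpha: float = 0.05
    precession_alpha: float = 0.025
    min_phase_coverage_deg: float = 45.0
    min_spikes_in_field: int = 30
    speed_gate_cm_s: float = 2.5
    run_theta: bool = True
    run_glm: bool = True
    run_dark: bool = True

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


@dataclass
class Report:
    per_trial: pd.DataFrame = field(default_factory=pd.DataFrame)
    per_session: pd.DataFrame = field(default_factory=pd.DataFrame)
    place_cells: pd.DataFrame = field(default_factory=pd.DataFrame)
    theta_cells: pd.DataFrame = field(default_factory=pd.DataFrame)
    glm_cells: pd.DataFrame = field(default_factory=pd.DataFrame)
    light_dark: pd.DataFrame = field(default_factory=pd.DataFrame)
    population: dict = field(default_factory=dict)

    def tables(self) -> dict[str, pd.DataFrame]:
        return {
            "per_trial": self.per_trial,
            "per_session": self.per_session,
            "place_cells": self.place_cells,
            "theta_cells": self.theta_cells,
            "glm_cells": self.glm_cells,
            "light_dark": self.light_dark,
        }

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        links = []
        for name, df in self.tables().items():
            df.to_csv(out / f"{name}.csv", index=False)
            links.append(f'<li><a href="{name}.csv">{name}</a></li>')
        pop = pd.DataFrame([self.population])
        pop.to_csv(out / "population.csv", index=False)
        links.append('<li><a href="population.csv">population</a></li>')
        (out / "index.html").write_text(
            "<html><body><h1>forageseq report</h1><ul>"
            + "".join(links)
            + "</ul></body></html>"
        )


def child_seed(master_seed: int, *key: int) -> np.random.Generator:
    """Counter-based seed fan-out: independent stream per (stage, index)."""
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=tuple(key))
    return np.random.default_rng(ss)


def mad_outlier_mask(values: np.ndarray) -> np.ndarray:
    """Flag values more than 10 MAD from the median, at most 5% of the data
    (most extreme first). Zero MAD flags nothing (with a warning)."""
    v = np.asarray(values, dtype=float)
    med = np.median(v)
    mad = np.median(np.abs(v - med))
    mask = np.zeros(v.shape, dtype=bool)
    if mad == 0:
        logger.warning("mad_outlier_mask: MAD is zero, no values flagged")
        return mask
    dev = np.abs(v - med)
    cand = np.flatnonzero(dev > MAD_FACTOR * mad)
    cap = int(np.floor(MAD_CAP_FRACTION * v.size))
    if cand.size > cap:
        cand = cand[np.argsort(dev[cand])[::-1][:cap]]
    mask[cand] = True
    return mask


# --------------------------------------------------------------------------
# session synthesis for a full day
# --------------------------------------------------------------------------


def simulate_day(
    config: PipelineConfig,
) -> tuple[list[tuple[SessionRecording, dict]], list[syn.CellGroundTruth]]:
    """Simulate the day's sessions (light, then dark, then light) with one
    shared cell population."""
    rng = child_seed(config.master_seed, 0)
    cells = syn.default_cell_population(config.n_cells, rng)
    sessions: list[tuple[SessionRecording, dict]] = []
    n_total = config.n_light_sessions + (config.n_dark_sessions if config.run_dark else 0)
    # protocol order: light sessions sandwich the dark ones (S1 S2 D D S5)
    order: list[Condition] = [Condition.LIGHT] * n_total
    if config.run_dark:
        first_dark = min(2, config.n_light_sessions)
        for k in range(config.n_dark_sessions):
            order[first_dark + k] = Condition.DARK
    for k, cond in enumerate(order):
        sim = syn.SimConfig(
            seed=int(child_seed(config.master_seed, 1, k).integers(2**31)),
            n_trials=config.n_trials_per_session,
            sequence_fraction_true=config.sequence_fraction_true,
            cells=cells,
            dark_gain_direction=config.dark_gain_direction,
            dark_gain_position=config.dark_gain_position,
        )
        sess, truth = syn.simulate_session(sim, condition=cond, session_id=f"S{k + 1}")
        sessions.append((sess, truth))
    return sessions, cells


# --------------------------------------------------------------------------
# stages
# --------------------------------------------------------------------------


def _prep(sess: SessionRecording):
    frame = resample_behavior(sess)
    trials = bh.segment_trials(sess)
    return frame, trials


def analyze_behavior(sessions: list[SessionRecording], config: PipelineConfig) -> tuple[pd.DataFrame, pd.DataFrame, list[bh.SequenceTemplate]]:
    """Per-trial sequence flags and per-session behavior metrics.

    Templates are clustered from the light sessions only; dark trials are
    matched against the light templates.
    """
    rows, maps_all, owner = [], [], []
    per_session = []
    for sess in sessions:
        frame, trials = _prep(sess)
        metrics = bh.trial_metrics(trials, frame)
        metrics.update(session_id=sess.session_id, condition=sess.condition.value)
        per_session.append(metrics)
        for i, tr in enumerate(trials):
            maps_all.append(bh.direction_vector_map(frame, tr, trial_id=len(maps_all)))
            owner.append((sess.session_id, sess.condition, i, tr))
    light_idx = [k for k, o in enumerate(owner) if o[1] is Condition.LIGHT]
    templates = bh.cluster_templates([maps_all[k] for k in light_idx])
    flags, best, _ = bh.match_sequence_trials(maps_all, templates, threshold=config.template_match_r)
    for k, (sid, cond, i, tr) in enumerate(owner):
        rows.append(
            {
                "session_id": sid,
                "condition": cond.value,
                "trial_index": i,
                "t_start": tr.span[0],
                "t_end": tr.span[1],
                "is_sequence": bool(flags[k]),
                "template_id": int(best[k]),
            }
        )
    per_trial = pd.DataFrame(rows)
    per_session_df = pd.DataFrame(per_session)
    frac = (
        per_trial.groupby("session_id")["is_sequence"].mean().rename("sequence_fraction")
    )
    per_session_df = per_session_df.merge(frac, on="session_id", how="left")
    return per_trial, per_session_df, templates


def pool_sessions(sessions: list[SessionRecording]) -> SessionRecording:
    """Concatenate sessions on a common timeline (gap of 1 s between)."""
    t_off = 0.0
    tt, xx, yy, lfp = [], [], [], []
    spikes: dict[str, list] = {u: [] for u in sessions[0].spikes}
    events = []
    for s in sessions:
        shift = t_off - s.tracking_t[0]
        tt.append(s.tracking_t + shift)
        xx.append(s.tracking_x)
        yy.append(s.tracking_y)
        lfp.append(s.lfp)
        for u, st in s.spikes.items():
            spikes[u].append(st + shift)
        for e in s.events:
            events.append(dataclasses.replace(e, t=e.t + shift))
        t_off = tt[-1][-1] + 1.0
    return SessionRecording(
        session_id="+".join(s.session_id for s in sessions),
        condition=sessions[0].condition,
        tracking_t=np.concatenate(tt),
        tracking_x=np.concatenate(xx),
        tracking_y=np.concatenate(yy),
        spikes={u: np.concatenate(v) for u, v in spikes.items()},
        lfp=np.concatenate(lfp),
        events=events,
        zones=sessions[0].zones,
    )


def analyze_cells(
    sessions: list[SessionRecording],
    config: PipelineConfig,
    truths: list[dict] | None = None,
) -> Report:
    """Run the full cell-level battery and assemble the report."""
    report = Report()
    light = [s for s in sessions if s.condition is Condition.LIGHT]
    dark = [s for s in sessions if s.condition is Condition.DARK]

    report.per_trial, report.per_session, templates = analyze_behavior(sessions, config)

    pooled = pool_sessions(light[:2]) if len(light) >= 2 else light[0]
    frame, trials = _prep(pooled)
    spans = [t.span for t in trials]
    valid_bins = pf.visit_mask(frame, spans)

    # per-single-session frames for the stability gates
    frames_single = {}
    for s in light:
        frames_single[s.session_id] = _prep(s)

    phase = None
    if config.run_theta:
        phase = th.extract_theta_phase(pooled.lfp, frame)
        frame_phase = frame.with_phase(phase.phase)

    place_rows, theta_rows, glm_rows, ld_rows = [], [], [], []
    for ci, unit_id in enumerate(sorted(pooled.spikes)):
        rng = child_seed(config.master_seed, 2, ci)
        spikes = pooled.spikes[unit_id]
        try:
            res, rmap, ens = pf.classify_place_cell(
                unit_id, frame, spikes, trial_spans=spans, rng=rng,
                n_shuffles=config.n_shuffles,
            )
        except (pf.CoverageError, ValueError) as err:
            logger.warning("unit %s: place-cell stage failed (%s)", unit_id, err)
            continue
        gate = _stability_gate(light, frames_single, unit_id, rng, config) if dark else True
        place_rows.append(
            {
                "unit_id": unit_id,
                "tuning_strength": res.tuning_strength,
                "sig_tuning": res.sig_tuning,
                "prediction_p": res.prediction_p,
                "sig_prediction": res.sig_prediction,
                "stability_r": res.stability_r,
                "sig_stability": res.sig_stability,
                "is_place_cell": res.is_place_cell,
                "light_dark_gate": bool(gate),
            }
        )

        if config.run_theta and phase is not None:
            tuning = th.phase_tuning(spikes, phase, frame, n_shuffles=config.n_shuffles, rng=rng)
            row = {
                "unit_id": unit_id,
                "modulation_index": tuning.modulation_index,
                "preferred_phase": tuning.preferred_phase,
                "sig_modulation": tuning.sig_modulation,
            }
            row.update(_precession_row(res, rmap, ens, frame, phase, spikes))
            theta_rows.append(row)

        if config.run_glm and res.is_place_cell:
            try:
                sel, tuning_l, _ = glm.analyze_cell(frame, spikes, valid_bins)
            except glm.DegenerateCovariateError as err:
                logger.warning("unit %s: GLM stage skipped (%s)", unit_id, err)
                continue
            glm_rows.append(
                {
                    "unit_id": unit_id,
                    "chosen": "".join(sel.chosen),
                    "category": sel.category,
                    **{f"strength_{c}": (tuning_l.strengths.get(c, np.nan) if tuning_l else np.nan)
                       for c in glm.COV_ORDER},
                }
            )
            if dark and gate and sel.chosen:
                ld_rows.append(
                    _light_dark_row(unit_id, sel, tuning_l, dark, config)
                )

    report.place_cells = pd.DataFrame(place_rows)
    report.theta_cells = pd.DataFrame(theta_rows)
    report.glm_cells = pd.DataFrame(glm_rows)
    report.light_dark = pd.DataFrame([r for r in ld_rows if r])
    report.population = _population_summary(report)
    return report


def _stability_gate(light, frames_single, unit_id, rng, config) -> bool:
    """S1-S2 and S2-S5 stability both significant (light/dark analyses)."""
    if len(light) < 3:
        return True
    ids = [s.session_id for s in light]
    pairs = [(ids[0], ids[1]), (ids[1], ids[-1])]
    for a, b in pairs:
        fa, tr_a = frames_single[a]
        fb, tr_b = frames_single[b]
        sa = next(s for s in light if s.session_id == a)
        sb = next(s for s in light if s.session_id == b)
        va = pf.visit_mask(fa, [t.span for t in tr_a])
        vb = pf.visit_mask(fb, [t.span for t in tr_b])
        try:
            ma = pf.estimate_rate_map(fa, sa.spikes[unit_id], valid_bins=va)
            mb = pf.estimate_rate_map(fb, sb.spikes[unit_id], valid_bins=vb)
            r = pf.field_stability(ma, mb)
            ea = pf.shuffle_ensemble(fa, sa.spikes[unit_id], va, n=config.n_shuffles, rng=rng)
            eb = pf.shuffle_ensemble(fb, sb.spikes[unit_id], vb, n=config.n_shuffles, rng=rng)
            if not pf.stability_significance(r, ea, eb):
                return False
        except (pf.CoverageError, ValueError):
            return False
    return True


def _precession_row(res, rmap, ens, frame, phase, spikes) -> dict:
    out = {"precession_p": np.nan, "precession_slope": np.nan, "sig_precession": False}
    if not res.is_place_cell:
        return out
    boundary = th.field_boundary(rmap, ens)
    if boundary is None:
        return out
    d, spk = th.compute_pdcd(frame, boundary, spikes)
    ph = phase.phase_at(spk)
    ok = np.isfinite(ph)
    if ok.sum() < 2:
        return out
    pr = th.precession_test(ph[ok], d[ok])
    out.update(
        precession_p=pr.p, precession_slope=pr.slope, sig_precession=pr.significant
    )
    return out


def _light_dark_row(unit_id, sel, tuning_l, dark, config) -> dict | None:
    pooled_dark = pool_sessions(dark) if len(dark) > 1 else dark[0]
    frame_d, trials_d = _prep(pooled_dark)
    vb_d = pf.visit_mask(frame_d, [t.span for t in trials_d])
    try:
        data_d = glm.build_design(frame_d, pooled_dark.spikes[unit_id], vb_d)
        fit_d = glm.fit_poisson(data_d, sel.chosen)
        tuning_d = glm.tuning_from_fit(fit_d, data_d)
    except (glm.DegenerateCovariateError, ValueError):
        return None
    delta = glm.light_dark_contrast(tuning_l, tuning_d)
    return {
        "unit_id": unit_id,
        **{f"delta_{c}": delta.get(c, np.nan) for c in glm.COV_ORDER},
    }


def _population_summary(report: Report) -> dict:
    pop: dict = {}
    if len(report.place_cells):
        pop["n_units"] = int(len(report.place_cells))
        pop["n_place_cells"] = int(report.place_cells["is_place_cell"].sum())
        pop["fraction_place_cells"] = float(report.place_cells["is_place_cell"].mean())
    if len(report.theta_cells):
        pop["fraction_theta_modulated"] = float(report.theta_cells["sig_modulation"].mean())
        pc = report.theta_cells.merge(
            report.place_cells[["unit_id", "is_place_cell"]], on="unit_id"
        )
        sub = pc[pc["is_place_cell"]]
        if len(sub):
            pop["fraction_precessing_place_cells"] = float(sub["sig_precession"].mean())
    if len(report.glm_cells):
        for cat, n in report.glm_cells["category"].value_counts().items():
            pop[f"n_category_{cat}"] = int(n)
    if len(report.light_dark):
        for c in glm.COV_ORDER:
            col = f"delta_{c}"
            if col in report.light_dark:
                pop[f"mean_{col}"] = float(report.light_dark[col].mean())
    if len(report.per_session):
        pop["mean_sequence_fraction_light"] = float(
            report.per_session.query("condition == 'light'")["sequence_fraction"].mean()
        )
        if (report.per_session["condition"] == "dark").any():
            pop["mean_sequence_fraction_dark"] = float(
                report.per_session.query("condition == 'dark'")["sequence_fraction"].mean()
            )
    return pop


def run_pipeline(config: PipelineConfig, out_dir: str | Path | None = None) -> Report:
    """Simulate a day of sessions and run every enabled stage."""
    sessions_truth, _cells = simulate_day(config)
    sessions = [s for s, _ in sessions_truth]
    report = analyze_cells(sessions, config, truths=[t for _, t in sessions_truth])
    if out_dir is not None:
        report.write(out_dir)
    return report
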