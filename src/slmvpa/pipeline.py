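"""End-to-end pipeline: simulate -> GLM -> searchlight -> inference -> report.

The pipeline is driven by one JSON-serializable config and one seed. Every
stage's output is cached on disk under a key derived from the config hash,
so partial reruns resume from the last completed stage and deleting only a
late stage's outputs reuses the earlier caches bit-exactly.

An *analysis* is one decoding question: which label to decode
(direction / velocity / congruency), in which context, training and testing
on which phases (equal phases = within-phase folds; visible -> occluded =
cross-phase transfer), inside which ROI.
"""

from __future__ import annotations

import hashlib
import json
import logging
import pickle
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._rng import substream
from .design import Design, design_to_events, generate_design
from .glm import PatternSet, extract_roi_patterns, fit_lss_betas
from .history import history_contrasts, label_trial_sequences
from .inference import (
    cross_phase_permutation_null,
    group_level_p,
    select_informative_spheres,
    selection_statistic,
    sphere_center_overlap,
    subject_permutation_null,
)
from .searchlight import (
    build_searchlights,
    cross_phase_decode,
    make_partitions,
    searchlight_accuracy_map,
)
from .simulate import (
    EffectSpec,
    NoiseSpec,
    generate_grid_and_masks,
    save_bold_nifti,
    save_mask_nifti,
    simulate_bold,
)

__all__ = ["AnalysisSpec", "PipelineConfig", "run_full_pipeline", "default_demo_config"]

logger = logging.getLogger(__name__)

STAGES = ("simulate", "glm", "mvpa", "infer", "history", "report")


@dataclass
class AnalysisSpec:
    analysis_id: str
    label_column: str  # direction | velocity | congruency
    context: str  # HP | LP
    train_phase: str  # visible | occluded
    test_phase: str
    region: str = "lowerV1"

    @property
    def cross_phase(self) -> bool:
        return self.train_phase != self.test_phase


@dataclass
class PipelineConfig:
    seed: int
    n_subjects: int = 4
    grid_dims: tuple[int, int, int] = (12, 12, 12)
    region_size: int = 160
    trials_per_cell_per_run: int | None = None  # None = paper-faithful counts
    effects: EffectSpec = field(default_factory=EffectSpec)
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    analyses: list[AnalysisSpec] = field(default_factory=list)
    n_iter: int = 1000
    top_fraction: float = 0.05
    cutoff: float = 0.5
    out_dir: str = "slmvpa_out"
    run_history: bool = True
    write_nifti: bool = True

    def validate(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if not self.analyses:
            raise ValueError("at least one analysis must be configured")
        for a in self.analyses:
            if a.label_column not in ("direction", "velocity", "congruency"):
                raise ValueError(f"unknown label_column {a.label_column!r}")
            if a.label_column == "congruency" and a.context != "LP":
                raise ValueError(
                    f"{a.analysis_id}: congruency decoding requires the LP context"
                )

    @property
    def contexts(self) -> list[str]:
        ctx = {a.context for a in self.analyses}
        if self.run_history:
            ctx.add("LP")
        return sorted(ctx)

    def to_json(self) -> str:
        d = asdict(self)
        return json.dumps(d, sort_keys=True, default=str)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        d["effects"] = EffectSpec(**d.get("effects", {}))
        d["noise"] = NoiseSpec(**d.get("noise", {}))
        d["analyses"] = [AnalysisSpec(**a) for a in d.get("analyses", [])]
        d["grid_dims"] = tuple(d.get("grid_dims", (12, 12, 12)))
        return cls(**d)

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]


def default_demo_config(seed: int, out_dir: str = "slmvpa_out") -> PipelineConfig:
    """Desk-scale demo: 4 subjects, 12^3 grid, 64 trials/phase, 99 permutations."""
    analyses = [
        AnalysisSpec("direction_LP_crossphase", "direction", "LP", "visible", "occluded"),
        AnalysisSpec("velocity_LP_crossphase", "velocity", "LP", "visible", "occluded"),
        AnalysisSpec("congruency_LP_visible", "congruency", "LP", "visible", "visible"),
    ]
    return PipelineConfig(
        seed=seed,
        n_subjects=4,
        trials_per_cell_per_run=8,  # 64 trials per phase
        effects=EffectSpec(amplitude=1.5, incongruency_amplitude=1.0,
                           switch_increment=0.3),
        analyses=analyses,
        n_iter=99,
        out_dir=out_dir,
    )


# ---------------------------------------------------------------- caching

def _cache_path(cfg: PipelineConfig, stage: str) -> Path:
    d = Path(cfg.out_dir) / "cache" / cfg.config_hash
    d.mkdir(parents=True, exist_ok=True)
    return d / f"{stage}.pkl"


def _load_or_run(cfg: PipelineConfig, stage: str, fn, resume: bool = True):
    path = _cache_path(cfg, stage)
    if resume and path.exists():
        logger.info("stage %s: reusing cache %s", stage, path)
        with open(path, "rb") as fh:
            return pickle.load(fh)
    logger.info("stage %s: computing", stage)
    out = fn()
    with open(path, "wb") as fh:
        pickle.dump(out, fh)
    return out


def _subject_seed(cfg: PipelineConfig, subject: int) -> int:
    return int(substream(cfg.seed, "subject", subject).integers(2**31))


# ----------------------------------------------------------------- stages

def _stage_simulate(cfg: PipelineConfig) -> dict:
    grid, masks = generate_grid_and_masks(
        cfg.grid_dims, cfg.seed, region_size=cfg.region_size
    )
    out = {"grid": grid, "masks": masks, "subjects": {}}
    out_dir = Path(cfg.out_dir)
    for s in range(cfg.n_subjects):
        sseed = _subject_seed(cfg, s)
        sessions = {}
        for context in cfg.contexts:
            for phase in ("visible", "occluded"):
                design = generate_design(
                    context, phase, sseed,
                    trials_per_cell_per_run=cfg.trials_per_cell_per_run,
                )
                runs = simulate_bold(design, grid, masks, cfg.effects, cfg.noise, sseed)
                sessions[(context, phase)] = {"design": design, "runs": runs}
                sub_dir = out_dir / f"sub-{s:02d}"
                sub_dir.mkdir(parents=True, exist_ok=True)
                design_to_events(design).to_csv(
                    sub_dir / f"events_{context}_{phase}.tsv", sep="\t", index=False
                )
                if cfg.write_nifti:
                    for r, run in enumerate(runs):
                        save_bold_nifti(
                            run, grid, sub_dir / f"bold_{context}_{phase}_run-{r}.nii.gz"
                        )
                        run.motion_params.to_csv(
                            sub_dir / f"motion_{context}_{phase}_run-{r}.tsv",
                            sep="\t", index=False,
                        )
        out["subjects"][s] = sessions
    if cfg.write_nifti:
        for mask in masks:
            save_mask_nifti(mask, grid, out_dir / f"mask_{mask.region}.nii.gz")
    return out


def _stage_glm(cfg: PipelineConfig, sim: dict) -> dict:
    grid, masks = sim["grid"], sim["masks"]
    regions = sorted({a.region for a in cfg.analyses} | {"lowerV1"})
    mask_of = {m.region: m for m in masks}
    out: dict = {}
    for s, sessions in sim["subjects"].items():
        out[s] = {}
        for (context, phase), sess in sessions.items():
            design: Design = sess["design"]
            betas = fit_lss_betas(sess["runs"], design, grid=grid)
            patterns = {
                region: extract_roi_patterns(betas, mask_of[region], design)
                for region in regions
            }
            out[s][(context, phase)] = patterns
    return out


def _stage_mvpa(cfg: PipelineConfig, sim: dict, glm_out: dict) -> dict:
    grid = sim["grid"]
    out: dict = {}
    for a in cfg.analyses:
        out[a.analysis_id] = {}
        for s in glm_out:
            sseed = _subject_seed(cfg, s)
            train = glm_out[s][(a.context, a.train_phase)][a.region]
            spheres = build_searchlights(train.voxels, grid)
            if a.cross_phase:
                test = glm_out[s][(a.context, a.test_phase)][a.region]
                amap = cross_phase_decode(
                    train, test, spheres, seed=sseed,
                    label_column=a.label_column, analysis_id=a.analysis_id,
                )
            else:
                labels = train.labels[a.label_column].to_numpy()
                scheme = make_partitions(labels, train.chunks, seed=sseed)
                amap = searchlight_accuracy_map(train, spheres, scheme, a.analysis_id)
            out[a.analysis_id][s] = {"map": amap, "spheres": spheres}
            sub_dir = Path(cfg.out_dir) / f"sub-{s:02d}"
            sub_dir.mkdir(parents=True, exist_ok=True)
            amap.to_frame().to_csv(
                sub_dir / f"accuracy_{a.analysis_id}.tsv", sep="\t", index=False
            )
    return out


def _stage_infer(cfg: PipelineConfig, glm_out: dict, mvpa_out: dict) -> dict:
    rows = []
    selections: dict = {}
    for a in cfg.analyses:
        true_means, nulls, n_sel = [], [], []
        selections[a.analysis_id] = {}
        for s, payload in mvpa_out[a.analysis_id].items():
            amap, spheres = payload["map"], payload["spheres"]
            sel = select_informative_spheres(
                amap, subject_id=f"sub-{s:02d}",
                cutoff=cfg.cutoff, top_fraction=cfg.top_fraction,
            )
            selections[a.analysis_id][s] = sel
            if sel.is_empty:
                logger.warning(
                    "%s sub-%02d: no sphere above the cutoff; the subject "
                    "statistic falls back to the best sphere",
                    a.analysis_id, s,
                )
            sseed = _subject_seed(cfg, s)
            train = glm_out[s][(a.context, a.train_phase)][a.region]
            if a.cross_phase:
                test = glm_out[s][(a.context, a.test_phase)][a.region]
                null = cross_phase_permutation_null(
                    train, test, spheres, a.label_column, sel,
                    n_iter=cfg.n_iter, seed=sseed,
                    cutoff=cfg.cutoff, top_fraction=cfg.top_fraction,
                )
            else:
                labels = train.labels[a.label_column].to_numpy()
                null = subject_permutation_null(
                    train, spheres, labels, sel, n_iter=cfg.n_iter, seed=sseed,
                    cutoff=cfg.cutoff, top_fraction=cfg.top_fraction,
                )
            true_means.append(
                float(
                    selection_statistic(
                        amap.accuracies, cfg.cutoff, cfg.top_fraction
                    )[0]
                )
            )
            nulls.append(null)
            n_sel.append(sel.n_selected)
        if not true_means:
            rows.append({"analysis_id": a.analysis_id, "n_subjects": 0})
            continue
        dist = group_level_p(np.array(true_means), np.vstack(nulls))
        rows.append(
            {
                "analysis_id": a.analysis_id,
                "region": a.region,
                "context": a.context,
                "train_phase": a.train_phase,
                "test_phase": a.test_phase,
                "accuracy": round(dist.true_value, 6),
                "se": round(float(np.std(true_means, ddof=1) / np.sqrt(len(true_means)))
                            if len(true_means) > 1 else 0.0, 6),
                "p_perm": round(dist.p_value, 6),
                "p_perm_conservative": round(dist.p_value_conservative, 6),
                "n_spheres_mean": round(float(np.mean(n_sel)), 3),
                "n_spheres_sd": round(float(np.std(n_sel, ddof=1))
                                      if len(n_sel) > 1 else 0.0, 3),
                "n_subjects": len(true_means),
            }
        )
    report = pd.DataFrame(rows)

    overlap_rows = []
    subjects = sorted({s for a in mvpa_out.values() for s in a})
    for s in subjects:
        sets = [
            selections[a.analysis_id][s]
            for a in cfg.analyses
            if s in selections[a.analysis_id]
            and not selections[a.analysis_id][s].is_empty
        ]
        if len(sets) >= 2:
            ov = sphere_center_overlap(sets)
            overlap_rows.append(
                {
                    "subject": f"sub-{s:02d}",
                    "mean_pairwise_overlap": ov["mean_pairwise"],
                    "all_way_overlap": ov["all_way"],
                }
            )
    overlap = pd.DataFrame(overlap_rows)
    return {"report": report, "overlap": overlap, "selections": selections}


def _stage_history(cfg: PipelineConfig, glm_out: dict) -> pd.DataFrame | None:
    if not cfg.run_history:
        return None
    values, cats, subs = [], [], []
    for s in glm_out:
        for phase in ("visible", "occluded"):
            key = ("LP", phase)
            if key not in glm_out[s]:
                continue
            patterns: PatternSet = glm_out[s][key]["lowerV1"]
            design_trials = dict(zip(patterns.labels["trial"], patterns.matrix.mean(1)))
            # rebuild history labels from the trial table ordering
            lab = patterns.labels
            prev_run, prev_cong = None, None
            for _, row in lab.iterrows():
                if row["run"] == prev_run and prev_cong is not None:
                    cat = (
                        ("C" if prev_cong == "congruent" else "I")
                        + ("C" if row["congruency"] == "congruent" else "I")
                    )
                    values.append(design_trials[row["trial"]])
                    cats.append(cat)
                    subs.append(s)
                prev_run, prev_cong = row["run"], row["congruency"]
    if not values:
        return None
    summary = history_contrasts(np.array(values), np.array(cats), np.array(subs))
    frame = summary.contrasts.copy()
    frame.insert(0, "F", summary.f_value)
    frame.insert(1, "df", f"({summary.df[0]}, {summary.df[1]})")
    frame.insert(2, "p_anova", summary.p_value)
    frame.insert(3, "n_subjects", summary.n_subjects)
    return frame


def run_full_pipeline(
    config: PipelineConfig, resume: bool = True, until: str = "report"
) -> dict:
    """Run the configured pipeline; returns the report bundle.

    ``until`` stops after the named stage (one of %s).
    """ % (STAGES,)
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    logger.info("pipeline seed=%s config=%s", config.seed, config.config_hash)
    (out_dir / "config.json").write_text(config.to_json())

    bundle: dict = {"config_hash": config.config_hash}
    sim = _load_or_run(config, "simulate", lambda: _stage_simulate(config), resume)
    bundle["grid"], bundle["masks"] = sim["grid"], sim["masks"]
    if until == "simulate":
        return bundle
    glm_out = _load_or_run(config, "glm", lambda: _stage_glm(config, sim), resume)
    bundle["patterns"] = glm_out
    if until == "glm":
        return bundle
    mvpa_out = _load_or_run(
        config, "mvpa", lambda: _stage_mvpa(config, sim, glm_out), resume
    )
    bundle["maps"] = mvpa_out
    if until == "mvpa":
        return bundle
    infer_out = _load_or_run(
        config, "infer", lambda: _stage_infer(config, glm_out, mvpa_out), resume
    )
    bundle.update(infer_out)
    if until == "infer":
        return bundle
    hist = _load_or_run(
        config, "history", lambda: _stage_history(config, glm_out), resume
    )
    bundle["history"] = hist

    infer_out["report"].to_csv(out_dir / "group_report.tsv", sep="\t", index=False)
    if len(infer_out["overlap"]):
        infer_out["overlap"].to_csv(out_dir / "overlap.tsv", sep="\t", index=False)
    if hist is not None:
        hist.to_csv(out_dir / "history.tsv", sep="\t", index=False)
    return bundle
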