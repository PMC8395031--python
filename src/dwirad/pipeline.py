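"""End-to-end orchestration: phantom (or loaded) cohort -> segmentation ->
feature extraction -> ICC filter -> per-region selection -> rad-scores ->
nomogram -> evaluation, with deterministic seed fan-out and a run manifest.

One global seed drives everything: a ``numpy.random.SeedSequence`` rooted at
the seed spawns independent child streams for the cohort, the second-reader
mask perturbation and the evaluation bootstrap, so any stage can be re-run
in isolation and reproduce its output bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, io
from .evaluation import (
    DcaCurve,
    EvaluationReport,
    calibration_curve,
    decision_curve,
    delong_paired_test,
    operating_point,
    two_sample_t,
)
from .features import BankConfig, FeatureTable, extract_features, zscore_fit_apply
from .models import (
    LogisticModel,
    NomogramModel,
    build_nomogram,
    fit_logistic,
    nomogram_points,
    rad_score,
)
from .phantom import CaseRecord, PhantomConfig, cohort_frame, generate_cohort, perturb_mask
from .reproducibility import icc_filter
from .segmentation import RoiSet, peritumoral_ring, segment_intratumoral
from .selection import SelectionConfig, SelectionTrace, select_features

logger = logging.getLogger(__name__)

REGIONS = ("intra", "peri", "combined")
SCORE_NAMES = {"intra": "intra_rad_score", "peri": "peri_rad_score",
               "combined": "com_rad_score"}


@dataclass(frozen=True)
class RunConfig:
    """Declarative configuration of one pipeline run."""

    mode: str = "phantom"  # {phantom, real-images}
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    bank: BankConfig = field(default_factory=BankConfig)
    seed: int = 0
    n_icc: int = 60  # 0 disables the two-reader stability stage
    icc_perturb_px: float = 1.0
    icc_threshold: float = 0.8
    n_bootstrap: int = 2000
    seed_margin_px: int = 5  # margin added to the truth box forming the seed ROI
    make_plots: bool = True
    image_dir: str | None = None  # real-images mode
    clinical_csv: str | None = None

    def validate(self) -> None:
        if self.mode not in ("phantom", "real-images"):
            raise ValueError("mode must be 'phantom' or 'real-images'")
        if self.mode == "real-images" and not (self.image_dir and self.clinical_csv):
            raise ValueError("real-images mode requires image_dir and clinical_csv")
        self.phantom.validate()
        self.selection.validate()

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["phantom"]["lesion_area_range_mm2"] = list(
            self.phantom.lesion_area_range_mm2
        )
        return d

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        phantom = raw.pop("phantom", {})
        if "lesion_area_range_mm2" in phantom:
            phantom["lesion_area_range_mm2"] = tuple(phantom["lesion_area_range_mm2"])
        if "clinical_rates" in phantom:
            phantom["clinical_rates"] = {
                k: tuple(v) for k, v in phantom["clinical_rates"].items()
            }
        selection = raw.pop("selection", {})
        bank = raw.pop("bank", {})
        for key in ("categories", "glcm_distances", "glcm_directions",
                    "gabor_frequencies"):
            if key in bank:
                bank[key] = tuple(bank[key])
        return cls(
            phantom=PhantomConfig(**phantom),
            selection=SelectionConfig(**selection),
            bank=BankConfig(**bank),
            **raw,
        )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


@dataclass
class PipelineResult:
    config: RunConfig
    cases: list[CaseRecord]
    rois: dict[str, RoiSet] = field(default_factory=dict)
    cohort: pd.DataFrame | None = None
    features_raw: FeatureTable | None = None
    icc_report: pd.DataFrame | None = None
    retained: list[str] | None = None
    features_z: FeatureTable | None = None
    z_params: pd.DataFrame | None = None
    traces: dict[str, SelectionTrace] = field(default_factory=dict)
    rad_models: dict[str, LogisticModel] = field(default_factory=dict)
    scores: pd.DataFrame | None = None
    t_tests: dict[str, dict[str, tuple[float, float]]] = field(default_factory=dict)
    nomogram: NomogramModel | None = None
    nomogram_failure: str | None = None
    reports: dict[tuple[str, str], EvaluationReport] = field(default_factory=dict)
    delong: dict[str, pd.DataFrame] = field(default_factory=dict)
    calibration: dict[str, tuple[pd.DataFrame, pd.DataFrame]] = field(
        default_factory=dict
    )
    dca: DcaCurve | None = None

    @property
    def train_mask(self) -> np.ndarray:
        return (self.cohort["cohort"] == "training").to_numpy()

    @property
    def labels(self) -> np.ndarray:
        return self.cohort["label"].to_numpy()


def _seed_int(seq: np.random.SeedSequence) -> int:
    return int(seq.generate_state(1, np.uint32)[0]) & 0x7FFFFFFF


def _load_cases(config: RunConfig) -> list[CaseRecord]:
    table = pd.read_csv(config.clinical_csv, dtype={"case_id": str})
    cases = []
    for _, row in table.iterrows():
        cases.append(io.read_case_inputs(row["case_id"], config.image_dir, row))
    return cases


def _segment_case(case: CaseRecord, config: RunConfig) -> RoiSet:
    if case.truth_mask is None:
        raise ValueError(f"case {case.case_id}: no seed region available")
    rows = np.flatnonzero(case.truth_mask.any(axis=1))
    cols = np.flatnonzero(case.truth_mask.any(axis=0))
    m = config.seed_margin_px
    seed_box = np.zeros_like(case.truth_mask)
    seed_box[
        max(0, rows[0] - m) : rows[-1] + 1 + m, max(0, cols[0] - m) : cols[-1] + 1 + m
    ] = True
    intra = segment_intratumoral(case.images.b800, seed_box)
    ring = peritumoral_ring(
        intra, pixel_spacing_mm=case.images.pixel_spacing_mm
    )
    return RoiSet(intratumoral=intra, peritumoral=ring)


def _region_pool(columns: list[str], region: str) -> list[str]:
    """Candidate features per region; shape descriptors (of the intratumoral
    mask) join the intratumoral pool."""
    intra = [c for c in columns if c.startswith("shape__") or "__intra__" in c]
    peri = [c for c in columns if "__peri__" in c]
    return {"intra": intra, "peri": peri, "combined": intra + peri}[region]


def run_experiment(config: RunConfig, stop_after: str | None = None) -> PipelineResult:
    """Run the pipeline in memory; ``stop_after`` ends early at a stage
    boundary ('cohort', 'features', 'icc', 'selection', 'models')."""
    config.validate()
    root = np.random.SeedSequence(config.seed & 0x7FFFFFFF)
    cohort_seq, icc_seq, boot_seq = root.spawn(3)

    # --- cohort ------------------------------------------------------------
    if config.mode == "phantom":
        cases = generate_cohort(replace(config.phantom, seed=_seed_int(cohort_seq)))
    else:
        cases = _load_cases(config)
    result = PipelineResult(config=config, cases=cases, cohort=cohort_frame(cases))
    if stop_after == "cohort":
        return result

    # --- segmentation + extraction -----------------------------------------
    rows = {}
    for case in cases:
        try:
            roi = _segment_case(case, config)
            result.rois[case.case_id] = roi
            rows[case.case_id] = extract_features(case.images, roi, config.bank)
        except ValueError as exc:
            raise RuntimeError(f"[stage=extract, case={case.case_id}] {exc}") from exc
    result.features_raw = FeatureTable(pd.DataFrame(rows).T)
    if stop_after == "features":
        return result

    # --- two-reader ICC stability filter ------------------------------------
    table = result.features_raw
    if config.n_icc > 0:
        icc_rng = np.random.default_rng(icc_seq)
        per_class = max(1, min(config.n_icc, len(cases)) // 2)
        chosen: list[CaseRecord] = []
        for lab in (1, 0):
            pool = [c for c in cases if c.label == lab]
            idx = icc_rng.choice(len(pool), min(per_class, len(pool)), replace=False)
            chosen += [pool[i] for i in sorted(idx)]
        rows_b = {}
        for case in chosen:
            roi = result.rois[case.case_id]
            intra_b = perturb_mask(roi.intratumoral, config.icc_perturb_px, icc_rng)
            ring_b = peritumoral_ring(
                intra_b, pixel_spacing_mm=case.images.pixel_spacing_mm
            )
            ring_b &= ~intra_b
            rows_b[case.case_id] = extract_features(
                case.images, RoiSet(intra_b, ring_b), config.bank
            )
        ids = list(rows_b)
        reader_a = FeatureTable(table.data.loc[ids])
        reader_b = FeatureTable(pd.DataFrame(rows_b).T.loc[ids])
        retained, report = icc_filter(reader_a, reader_b, config.icc_threshold)
        result.icc_report = report
        result.retained = retained
        if not retained:
            raise RuntimeError("[stage=icc] no feature passed the stability filter")
        table = FeatureTable(table.data[retained])
    else:
        result.retained = list(table.data.columns)
    if stop_after == "icc":
        return result

    # --- z-scoring (training fit) and per-region selection ------------------
    train = result.train_mask
    train_table = FeatureTable(table.data.loc[train])
    all_table = FeatureTable(table.data)
    (train_z, all_z), z_params = zscore_fit_apply(train_table, all_table)
    result.features_z = all_z
    result.z_params = z_params
    y_train = result.labels[train]

    for region in REGIONS:
        pool = _region_pool(list(all_z.data.columns), region)
        trace = select_features(
            FeatureTable(train_z.data[pool]), y_train, config.selection
        )
        result.traces[region] = trace
    if stop_after == "selection":
        return result

    # --- rad-score models ----------------------------------------------------
    score_cols = {}
    for region in REGIONS:
        final = result.traces[region].final_names
        model = fit_logistic(train_z.data[final], y_train)
        result.rad_models[region] = model
        score_cols[SCORE_NAMES[region]] = rad_score(model, all_z.data)
    result.scores = pd.DataFrame(score_cols, index=all_z.data.index)
    result.scores.insert(0, "label", result.labels)
    result.scores.insert(1, "cohort", result.cohort["cohort"].to_numpy())

    for name in SCORE_NAMES.values():
        result.t_tests[name] = {}
        for cohort in ("training", "validation"):
            sel = result.scores["cohort"] == cohort
            pos = result.scores.loc[sel & (result.scores["label"] == 1), name]
            neg = result.scores.loc[sel & (result.scores["label"] == 0), name]
            if pos.size >= 2 and neg.size >= 2 and (pos.std() > 0 or neg.std() > 0):
                result.t_tests[name][cohort] = two_sample_t(pos, neg)

    # --- nomogram -------------------------------------------------------------
    clinical_cols = ["age_group", "er", "pr", "ki67"]
    clinical_train = result.cohort.loc[train, clinical_cols]
    try:
        result.nomogram = build_nomogram(
            clinical_train,
            result.scores.loc[train, "com_rad_score"].to_numpy(),
            y_train,
        )
    except ValueError as exc:
        result.nomogram_failure = str(exc)
        logger.warning("nomogram not buildable: %s", exc)
    if stop_after == "models":
        return result

    # --- evaluation ------------------------------------------------------------
    from .models import encode_clinical  # local import to avoid cycle confusion

    model_scores = {
        name: result.scores[name].to_numpy() for name in SCORE_NAMES.values()
    }
    if result.nomogram is not None:
        design = encode_clinical(result.cohort[clinical_cols])
        design["com_rad_score"] = result.scores["com_rad_score"].to_numpy()
        model_scores["nomogram"] = result.nomogram.predict_proba(design)

    boot_children = boot_seq.spawn(len(model_scores) * 2)
    i = 0
    for name, svec in model_scores.items():
        for cohort in ("training", "validation"):
            sel = (result.cohort["cohort"] == cohort).to_numpy()
            result.reports[(name, cohort)] = operating_point(
                svec[sel],
                result.labels[sel],
                n_bootstrap=config.n_bootstrap,
                seed=_seed_int(boot_children[i]),
            )
            i += 1

    names = list(model_scores)
    for cohort in ("training", "validation"):
        sel = (result.cohort["cohort"] == cohort).to_numpy()
        mat = pd.DataFrame(np.nan, index=names, columns=names)
        for a in names:
            for bname in names:
                if a == bname:
                    continue
                *_, p = delong_paired_test(
                    model_scores[a][sel], model_scores[bname][sel], result.labels[sel]
                )
                mat.loc[a, bname] = p
        result.delong[cohort] = mat

    if result.nomogram is not None:
        for cohort in ("training", "validation"):
            sel = (result.cohort["cohort"] == cohort).to_numpy()
            result.calibration[cohort] = calibration_curve(
                model_scores["nomogram"][sel], result.labels[sel]
            )
        val = (result.cohort["cohort"] == "validation").to_numpy()
        result.dca = decision_curve(model_scores["nomogram"][val], result.labels[val])

    return result


# ---------------------------------------------------------------------------
# artifact writing


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not serializable: {type(obj)}")


def _numeric_hash(result: PipelineResult) -> str:
    """Stable digest of the run's numeric outputs.

    Reruns with the same (config, seed) are bit-identical, so the raw float64
    bytes of the score and feature matrices hash stably.
    """
    h = hashlib.sha256()
    frames = [result.scores.select_dtypes("number")]
    if result.features_raw is not None:
        frames.append(result.features_raw.data)
    for frame in frames:
        h.update(frame.to_numpy(dtype=float).tobytes())
    for (name, cohort), report in sorted(result.reports.items()):
        h.update(f"{name}|{cohort}|{report.auc:.12g}".encode())
    return h.hexdigest()


def run_pipeline(config: RunConfig, outdir: Path) -> Path:
    """Run everything and persist artifacts + manifest under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result = run_experiment(config)

    result.cohort.to_csv(outdir / "cohort.csv")
    image_dir = outdir / "images"
    for case in result.cases:
        io.write_case(case, image_dir, result.rois.get(case.case_id))
    result.features_raw.to_csv(outdir / "features_raw.csv")
    result.features_z.to_csv(outdir / "features_z.csv")
    result.z_params.to_csv(outdir / "z_params.csv", index_label="feature")
    if result.icc_report is not None:
        result.icc_report.to_csv(outdir / "icc.csv", index=False)
        n_kept = int(result.icc_report["retained"].sum())
        logger.info("ICC retained %d / %d features", n_kept, len(result.icc_report))

    for region, trace in result.traces.items():
        with open(outdir / f"selection_{region}.json", "w") as fh:
            json.dump(trace.to_dict(), fh, indent=2, default=_json_default)
    for region, model in result.rad_models.items():
        with open(outdir / f"model_{region}.json", "w") as fh:
            json.dump(model.to_dict(), fh, indent=2, default=_json_default)
    result.scores.to_csv(outdir / "rad_scores.csv")

    if result.nomogram is not None:
        tables, curve = nomogram_points(result.nomogram)
        payload = {
            "predictors": result.nomogram.predictors,
            "model": result.nomogram.model.to_dict(),
            "univariate": [vars(r) for r in result.nomogram.univariate],
            "multivariate": [vars(r) for r in result.nomogram.multivariate],
        }
        with open(outdir / "nomogram.json", "w") as fh:
            json.dump(payload, fh, indent=2, default=_json_default)
        points = pd.concat(
            [t.assign(predictor=name) for name, t in tables.items()]
        )
        points.to_csv(outdir / "nomogram_points.csv", index=False)
        curve.to_csv(outdir / "nomogram_curve.csv", index=False)
    else:
        (outdir / "nomogram_failure.txt").write_text(result.nomogram_failure or "")

    eval_payload = {
        f"{name}__{cohort}": report.to_dict()
        for (name, cohort), report in result.reports.items()
    }
    with open(outdir / "evaluation.json", "w") as fh:
        json.dump(eval_payload, fh, indent=2, default=_json_default)
    for cohort, mat in result.delong.items():
        mat.to_csv(outdir / f"delong_{cohort}.csv")
    for cohort, (grouped, smoothed) in result.calibration.items():
        grouped.to_csv(outdir / f"calibration_{cohort}.csv", index=False)
        smoothed.to_csv(outdir / f"calibration_smooth_{cohort}.csv", index=False)
    if result.dca is not None:
        result.dca.to_frame().to_csv(outdir / "dca_validation.csv", index=False)

    if config.make_plots:
        _write_plots(result, outdir)

    manifest = {
        "config": config.to_dict(),
        "seed": config.seed,
        "versions": {
            "dwirad": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "n_cases": len(result.cases),
        "n_reports": len(result.reports),
        "numeric_hash": _numeric_hash(result),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=_json_default)
    return outdir


def _write_plots(result: PipelineResult, outdir: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from sklearn.metrics import roc_curve

    for cohort in ("training", "validation"):
        sel = (result.cohort["cohort"] == cohort).to_numpy()
        fig, ax = plt.subplots(figsize=(5, 5))
        for name in result.scores.columns:
            if name in ("label", "cohort"):
                continue
            fpr, tpr, _ = roc_curve(result.labels[sel], result.scores[name][sel])
            auc = result.reports[(name, cohort)].auc
            ax.plot(fpr, tpr, label=f"{name} (AUC {auc:.3f})")
        ax.plot([0, 1], [0, 1], "k--", lw=0.8)
        ax.set_xlabel("1 - specificity")
        ax.set_ylabel("sensitivity")
        ax.legend(fontsize=8)
        fig.savefig(outdir / f"roc_{cohort}.png", dpi=120)
        plt.close(fig)

    for cohort, (grouped, smoothed) in result.calibration.items():
        fig, ax = plt.subplots(figsize=(5, 5))
        ax.plot([0, 1], [0, 1], "k--", lw=0.8, label="ideal")
        ax.plot(smoothed["predicted"], smoothed["observed"], label="smoothed")
        ax.scatter(grouped["predicted"], grouped["observed"], s=18, label="deciles")
        ax.set_xlabel("predicted probability")
        ax.set_ylabel("observed rate")
        ax.legend(fontsize=8)
        fig.savefig(outdir / f"calibration_{cohort}.png", dpi=120)
        plt.close(fig)

    if result.dca is not None:
        frame = result.dca.to_frame()
        fig, ax = plt.subplots(figsize=(5, 4))
        ax.plot(frame["threshold"], frame["model"], label="nomogram")
        ax.plot(frame["threshold"], frame["treat_all"], label="treat all")
        ax.plot(frame["threshold"], frame["treat_none"], label="treat none")
        ax.set_ylim(-0.2, max(0.5, frame["model"].max() + 0.05))
        ax.set_xlabel("threshold probability")
        ax.set_ylabel("net benefit")
        ax.legend(fontsize=8)
        fig.savefig(outdir / "dca_validation.png", dpi=120)
        plt.close(fig)
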