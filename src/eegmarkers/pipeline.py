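"""End-to-end orchestration: recordings -> subject table -> statistics.

``run_pipeline`` executes the full analysis sequence on a directory of
recordings or a freshly simulated cohort: pre-processing, ROI spectra and
peak measures, ACW triplets, then the inference battery (peak-occurrence
chi-square, group contrasts, measure-ACW correlation matrices with BH
adjustment, mediation for theta-peak rows, tertile and median splits) and
the three-feature-set classification for both tasks.  Every stage and every
gate decision is recorded in a JSON manifest; all tables are written as CSV
with 12-significant-digit floats so repeated runs are byte-identical.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import classify as clf
from . import inference as inf
from .errors import DegenerateSignalError, InsufficientDataError, InvalidArgumentError
from .io import read_recording, write_ground_truth
from .peaks import measures_from_psd
from .preprocess import preprocess, select_rois
from .recording import EEGRecording, PreprocConfig
from .simulate import GroundTruth, simulate_cohort
from .spectral import roi_psd
from .timescales import roi_acw

__all__ = ["RunConfig", "run_pipeline", "build_subject_table", "analyze_recording"]

STAGES = ["simulate", "preprocess", "spectral", "peaks", "timescales",
          "inference", "classification"]

SPECTRAL_MEASURES = ["power", "frequency", "prominence", "width",
                     "power_ratio", "max_power", "min_power"]
ACW_MEASURES = ["acw50", "acw_e", "acw0"]
FLOAT_FMT = "%.12g"


@dataclass
class RunConfig:
    """Fully serializable description of one pipeline run."""

    # input: either a directory of recordings or a synthetic cohort
    input_dir: str | None = None
    n_control: int = 25
    n_mcs: int = 47
    n_uws: int = 48
    paths: tuple[float, float] = (0.6, 0.5)
    noise_sd: float = 1.0
    # stage parameters
    preproc: PreprocConfig = field(default_factory=PreprocConfig)
    welch_window_s: float = 3.0
    welch_overlap: float = 0.5
    min_prominence: float = 0.1
    min_distance_hz: float = 0.4
    acw_max_lag_s: float = 20.0
    n_boot: int = 5000
    k_folds: int = 10
    seed: int = 0
    out_dir: str = "eegmarkers_out"

    def to_dict(self) -> dict:
        d = asdict(self)
        d["paths"] = list(self.paths)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "preproc" in d and isinstance(d["preproc"], dict):
            pp = dict(d["preproc"])
            for key in ("band", "frontal_labels", "occipital_labels"):
                if key in pp:
                    pp[key] = tuple(pp[key])
            d["preproc"] = PreprocConfig(**pp)
        if "paths" in d:
            d["paths"] = tuple(d["paths"])
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise InvalidArgumentError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)


def analyze_recording(rec: EEGRecording, config: RunConfig | None = None) -> list[dict]:
    """Pre-process one recording and compute all measures for both ROIs."""
    config = config or RunConfig()
    clean, mask = preprocess(rec, config.preproc)
    frontal, occipital = select_rois(clean, config.preproc)
    rows = []
    for roi_name, roi in (("frontal", frontal), ("occipital", occipital)):
        psd = roi_psd(roi, config.welch_window_s, config.welch_overlap,
                      config.preproc.band)
        pm = measures_from_psd(psd, config.min_prominence, config.min_distance_hz)
        acw = roi_acw(roi, config.acw_max_lag_s)
        rows.append({
            "recording_id": rec.id, "roi": roi_name, "band": pm.band,
            "power": pm.power, "frequency": pm.frequency,
            "prominence": pm.prominence, "width": pm.width,
            "power_ratio": pm.power_ratio, "max_power": pm.max_power,
            "min_power": pm.min_power, "boundary": pm.boundary,
            "acw50": acw.acw50, "acw_e": acw.acw_e, "acw0": acw.acw0,
            "acw50_censored": acw.censored[0], "acw_e_censored": acw.censored[1],
            "acw0_censored": acw.censored[2], "censored_any": acw.any_censored,
            "n_bad_channels": mask.n_bad,
        })
    return rows


def build_subject_table(
    recordings: list[EEGRecording],
    truths: list[GroundTruth] | None = None,
    config: RunConfig | None = None,
) -> pd.DataFrame:
    """One row per (recording, ROI) with group/CRS-R metadata attached."""
    config = config or RunConfig()
    meta = {}
    if truths:
        meta = {gt.recording_id: gt for gt in truths}
    rows = []
    for rec in recordings:
        for row in analyze_recording(rec, config):
            gt = meta.get(rec.id)
            row["group"] = gt.group if gt else "unknown"
            row["crs_r"] = gt.crs_r_score if gt and gt.crs_r_score is not None else np.nan
            if gt is not None:
                row["latent_power"] = gt.latent_power
                row["latent_acw"] = gt.latent_acw
            rows.append(row)
    return pd.DataFrame(rows)


def _contrast_block(
    measures: list[str], group_a: pd.DataFrame, group_b: pd.DataFrame, label: str
) -> pd.DataFrame:
    """Normality-gated contrasts for several measures, BH-adjusted as one family."""
    results = []
    for measure in measures:
        x = group_a[measure].dropna().to_numpy()
        y = group_b[measure].dropna().to_numpy()
        if x.size < 3 or y.size < 3:
            continue
        res = inf.normality_gated_compare(x, y)
        results.append({
            "family": label, "measure": measure, "test": res.test_name,
            "statistic": res.statistic, "p_value": res.p_value,
            "n_a": res.n[0], "n_b": res.n[1], "direction": res.direction,
        })
    df = pd.DataFrame(results)
    if not df.empty:
        df["p_adjusted"] = inf.bh_adjust(df["p_value"].to_numpy())
    return df


def _occurrence_table(table: pd.DataFrame, roi: str) -> inf.ContingencyTable:
    """Controls vs DOC counts of alpha / theta / no peak for one ROI."""
    rows = table[table["roi"] == roi]
    counts = np.zeros((2, 3), dtype=int)
    for i, grp in enumerate(["control", "DOC"]):
        sel = rows["group"] == "control" if grp == "control" else rows["group"] != "control"
        bands = rows.loc[sel, "band"]
        counts[i] = [(bands == b).sum() for b in ("alpha", "theta", "none")]
    return inf.ContingencyTable(counts=counts, row_labels=["control", "DOC"],
                                col_labels=["alpha", "theta", "none"])


def run_inference(table: pd.DataFrame, config: RunConfig) -> dict:
    """The statistical battery on a populated subject table."""
    out: dict = {"gates": []}
    is_doc = table["group"] != "control"

    # 1. peak occurrence + chi-square per ROI
    occ_rows, chi_rows = [], []
    for roi in ("frontal", "occipital"):
        ct = _occurrence_table(table, roi)
        for r, grp in enumerate(ct.row_labels):
            occ_rows.append({"roi": roi, "group": grp,
                             **dict(zip(ct.col_labels, ct.counts[r]))})
        try:
            res = inf.chi_square(ct)
        except InvalidArgumentError as exc:  # degenerate table (e.g. one group)
            chi_rows.append({"roi": roi, "status": f"skipped: {exc}"})
            continue
        chi_rows.append({"roi": roi, "status": "ok", "statistic": res.statistic,
                         "p_value": res.p_value, "dof": res.extra["dof"],
                         "n": res.n[0]})
    out["peak_occurrence"] = pd.DataFrame(occ_rows)
    out["chi_square"] = pd.DataFrame(chi_rows)

    # 2. group contrasts: spectral measures on alpha rows, ACWs on all rows
    contrasts = []
    for roi in ("frontal", "occipital"):
        rows = table[table["roi"] == roi]
        alpha_rows = rows[rows["band"] == "alpha"]
        contrasts.append(_contrast_block(
            SPECTRAL_MEASURES,
            alpha_rows[~is_doc.loc[alpha_rows.index]], alpha_rows[is_doc.loc[alpha_rows.index]],
            f"spectral/{roi}"))
        ok = ~rows["censored_any"].astype(bool)
        contrasts.append(_contrast_block(
            ACW_MEASURES,
            rows[ok & ~is_doc.loc[rows.index]], rows[ok & is_doc.loc[rows.index]],
            f"acw/{roi}"))
    nonempty = [c for c in contrasts if not c.empty]
    out["group_contrasts"] = (pd.concat(nonempty, ignore_index=True)
                              if nonempty else pd.DataFrame())

    # 3. correlations between spectral measures and ACWs (per ROI, per cohort
    # side), plus ACW x CRS-R (Spearman forced) for peak-bearing DOC rows
    corr_rows = []
    for roi in ("frontal", "occipital"):
        rows = table[table["roi"] == roi]
        subsets = {
            "control": rows[(rows["group"] == "control") & (rows["band"] != "none")],
            "doc_peak": rows[(rows["group"] != "control") & (rows["band"] != "none")],
        }
        for name, sub in subsets.items():
            family = []
            for measure in SPECTRAL_MEASURES:
                for acw_m in ACW_MEASURES:
                    pair = sub[[measure, acw_m]].dropna()
                    if len(pair) < 4 or pair[measure].nunique() < 2:
                        continue
                    try:
                        res = inf.correlate(pair[measure], pair[acw_m])
                    except Exception:
                        continue
                    family.append({
                        "family": f"{name}/{roi}", "x": measure, "y": acw_m,
                        "method": res.test_name, "coef": res.statistic,
                        "p_value": res.p_value, "n": res.n[0],
                    })
            df = pd.DataFrame(family)
            if not df.empty:
                df["p_adjusted"] = inf.bh_adjust(df["p_value"].to_numpy())
                corr_rows.append(df)
        # CRS-R correlations, ordinal -> Spearman forced, one family per ROI
        theta = rows[(rows["group"] != "control") & (rows["band"] == "theta")]
        family = []
        for acw_m in ACW_MEASURES:
            pair = theta[[acw_m, "crs_r"]].dropna()
            if len(pair) < 4:
                continue
            try:
                res = inf.correlate(pair[acw_m], pair["crs_r"], force_ordinal=True)
            except Exception:
                continue
            family.append({
                "family": f"crsr_theta/{roi}", "x": acw_m, "y": "crs_r",
                "method": res.test_name, "coef": res.statistic,
                "p_value": res.p_value, "n": res.n[0],
            })
        df = pd.DataFrame(family)
        if not df.empty:
            df["p_adjusted"] = inf.bh_adjust(df["p_value"].to_numpy())
            corr_rows.append(df)
    out["correlations"] = (pd.concat(corr_rows, ignore_index=True)
                           if corr_rows else pd.DataFrame())

    # 4. mediation.  Measured models (the study reproduction): theta-peak DOC
    # rows pooled across ROIs, power or power_ratio -> ACW-e-1 -> CRS-R.
    # When generator ground truth is attached, a validation model on the
    # latent variables (peak-power latent -> ACW latent -> CRS-R) is run as
    # well: its indirect effect recovers the generator's a*b without the
    # attenuation the EEG measurement chain imposes.
    med_rows = []
    theta_rows = table[(table["group"] != "control") & (table["band"] == "theta")]
    theta_rows = theta_rows.dropna(subset=["power", "acw_e", "crs_r"])
    candidates: list[tuple[str, str, str, pd.DataFrame]] = [
        ("power", "acw_e", "crs_r", theta_rows),
        ("power_ratio", "acw_e", "crs_r", theta_rows),
    ]
    if {"latent_power", "latent_acw"} <= set(table.columns):
        gt_rows = (table[table["group"] != "control"]
                   .drop_duplicates("recording_id")
                   .dropna(subset=["latent_power", "latent_acw", "crs_r"]))
        candidates.append(("latent_power", "latent_acw", "crs_r", gt_rows))
    for predictor, mediator, outcome, rows_df in candidates:
        sub = rows_df.dropna(subset=[predictor, mediator, outcome])
        if len(sub) < 10:
            continue
        try:
            res = inf.mediation_bootstrap(
                sub[predictor].to_numpy(), sub[mediator].to_numpy(),
                sub[outcome].to_numpy(), n_boot=config.n_boot, seed=config.seed,
            )
        except (inf.CollinearityError, DegenerateSignalError) as exc:
            med_rows.append({"predictor": predictor, "mediator": mediator,
                             "outcome": outcome, "status": f"skipped: {exc}"})
            continue
        med_rows.append({
            "predictor": predictor, "mediator": mediator, "outcome": outcome,
            "status": "ok", "a": res.a, "b": res.b, "c_total": res.c_total,
            "c_direct": res.c_direct, "ab": res.ab,
            "ci_low": res.ci_low, "ci_high": res.ci_high, "p_ab": res.p_ab,
            "n": res.n, "n_boot": res.n_boot,
        })
    out["mediation"] = pd.DataFrame(med_rows)

    # 5. splits: ACW tertiles vs peak presence (DOC rows, per ROI); median
    # split of DOC peak rows on ACW-e-1
    split_rows, median_rows = [], []
    for roi in ("frontal", "occipital"):
        doc = table[(table["roi"] == roi) & (table["group"] != "control")]
        for acw_m in ACW_MEASURES:
            try:
                ct = inf.peak_presence_by_split(doc, acw_m, n_groups=3)
                res = inf.chi_square(ct)
            except (InsufficientDataError, InvalidArgumentError):
                continue
            split_rows.append({
                "roi": roi, "acw_measure": acw_m,
                **{f"peak_{lab}": ct.counts[i, 0] for i, lab in enumerate(ct.row_labels)},
                **{f"nopeak_{lab}": ct.counts[i, 1] for i, lab in enumerate(ct.row_labels)},
                "statistic": res.statistic, "p_value": res.p_value,
            })
        peaked = doc[(doc["band"] != "none") & ~doc["acw_e_censored"].astype(bool)]
        if len(peaked) >= 6:
            groups = inf.quantile_split(peaked["acw_e"].to_numpy(), 2)
            for measure in ("power", "power_ratio", "crs_r"):
                lo = peaked.loc[groups == 0, measure].dropna().to_numpy()
                hi = peaked.loc[groups == 1, measure].dropna().to_numpy()
                if lo.size < 3 or hi.size < 3:
                    continue
                res = (inf.normality_gated_compare(hi, lo))
                median_rows.append({
                    "roi": roi, "split_on": "acw_e", "measure": measure,
                    "test": res.test_name, "statistic": res.statistic,
                    "p_value": res.p_value, "direction_top_minus_bottom": res.direction,
                    "mean_top": float(np.mean(hi)), "mean_bottom": float(np.mean(lo)),
                })
    out["acw_tertile_splits"] = pd.DataFrame(split_rows)
    out["median_splits"] = pd.DataFrame(median_rows)
    return out


def run_classification(table: pd.DataFrame, config: RunConfig) -> pd.DataFrame:
    """All feature sets x both tasks; insufficient data is recorded, not fatal."""
    rows = []
    for task in ("two_class", "three_class"):
        for feature_set in ("alpha", "acw", "combined"):
            entry = {"task": task, "feature_set": feature_set}
            try:
                fm = clf.build_features(table, feature_set, task)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    rep = clf.crossval_ovo(fm, config.k_folds, config.seed)
            except (InsufficientDataError, InvalidArgumentError) as exc:
                entry.update({"status": f"skipped: {exc}"})
                rows.append(entry)
                continue
            entry.update({
                "status": "ok", "n_rows": fm.y.size,
                "mean_accuracy": rep.mean_accuracy, "sd_accuracy": rep.sd_accuracy,
                "macro_auc": rep.macro_auc, "n_folds": rep.n_folds,
                "n_binary_models": rep.n_binary_models,
                "confusion": json.dumps(rep.confusion.tolist()),
                "classes": "|".join(rep.classes),
                **{f"precision_{c}": rep.precision[c] for c in rep.classes},
                **{f"recall_{c}": rep.recall[c] for c in rep.classes},
                **{f"f1_{c}": rep.f1[c] for c in rep.classes},
            })
            rows.append(entry)
    return pd.DataFrame(rows)


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format=FLOAT_FMT)


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and write the output bundle to ``config.out_dir``."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"stages": STAGES, "config": config.to_dict(), "gates": {}}

    if config.input_dir:
        paths = sorted(
            p for p in Path(config.input_dir).iterdir()
            if p.suffix.lower() in (".edf", ".tsv", ".txt")
        )
        recordings = [read_recording(p) for p in paths]
        truths = None
        gt_csv = Path(config.input_dir) / "ground_truth.csv"
        if gt_csv.exists():
            truths = _truths_from_csv(gt_csv)
        manifest["input"] = {"dir": str(config.input_dir), "n": len(recordings)}
    else:
        recordings, truths = simulate_cohort(
            config.n_control, config.n_mcs, config.n_uws,
            config.paths, config.noise_sd, config.seed,
        )
        write_ground_truth(truths, out_dir / "ground_truth.csv")
        manifest["input"] = {"simulated": True, "n": len(recordings),
                            "seed": config.seed}

    table = build_subject_table(recordings, truths, config)
    _write_csv(table, out_dir / "subject_table.csv")
    manifest["gates"]["censored_rows"] = int(table["censored_any"].sum())
    manifest["gates"]["bands"] = table["band"].value_counts().to_dict()

    stats = run_inference(table, config)
    for name in ("peak_occurrence", "chi_square", "group_contrasts",
                 "correlations", "mediation", "acw_tertile_splits",
                 "median_splits"):
        _write_csv(stats[name], out_dir / f"{name}.csv")

    cls = run_classification(table, config)
    _write_csv(cls, out_dir / "classification.csv")

    manifest["outputs"] = sorted(p.name for p in out_dir.iterdir())
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return {"table": table, "stats": stats, "classification": cls,
            "manifest": manifest}


def _truths_from_csv(path: Path) -> list[GroundTruth]:
    from .simulate import PhenotypeParams

    df = pd.read_csv(path)
    truths = []
    for _, row in df.iterrows():
        center = row.get("oscillation_center_hz")
        pheno = PhenotypeParams(
            label=str(row["phenotype"]),
            aperiodic_exponent=float(row["aperiodic_exponent"]),
            oscillation_center_hz=None if pd.isna(center) else float(center),
            oscillation_bandwidth_hz=float(row["oscillation_bandwidth_hz"]),
            oscillation_amplitude=float(row["oscillation_amplitude"]),
            ar_timescale_s=float(row["ar_timescale_s"]),
            delta_amplitude=float(row.get("delta_amplitude", 0.0)),
        )
        crs = row.get("crs_r")
        truths.append(GroundTruth(
            phenotype=pheno,
            crs_r_score=None if pd.isna(crs) or crs == "" else int(crs),
            mediation_paths=(float(row["path_a"]), float(row["path_b"])),
            seed=int(row["seed"]), group=str(row["group"]),
            latent_power=float(row["latent_power"]),
            latent_acw=float(row["latent_acw"]),
            latent_score=float(row["latent_score"]),
            recording_id=str(row["recording_id"]),
        ))
    return truths
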