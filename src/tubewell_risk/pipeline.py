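"""End-to-end run orchestration: simulate/load -> qc -> stats -> risk ->
safelimit -> train -> attribute, with a consolidated, reproducible bundle.

A run writes per-stage CSVs, a GeoJSON of per-sample HQ/HI/FIR point
features, a JSON manifest (config echo, package version, seed, row counts)
and a human-readable summary.  Identical config + seed produces a
byte-identical bundle; the manifest is sufficient to replay a run.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .core_data import Dataset, export_geojson, load_guidelines, load_samples, validate_dataset
from .association import fit_depth_regression, pearson_matrix, run_pca
from .exposure import get_params, risk_frame, union_risk_summary
from .safe_intake import safe_intake_frame
from .surrogate import (SurrogateConfig, cross_validate, encode_features,
                        save_model, shapley_attribution, train_surrogate)
from .synthetic import SyntheticConfig, cohort_report, generate_dataset
from .water_quality import compliance_frame, compliance_table, descriptive_stats

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]

log = logging.getLogger("tubewell_risk")

_STAGES = ("qc", "stats", "risk", "safelimit", "train", "attribute")

_ASSOC_VARS = ["ph", "ec", "tds", "temperature", "salinity", "fe", "as", "depth"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Exactly one of ``input_csv`` / ``synthetic`` selects the input source."""

    input_csv: str | None = None
    synthetic: SyntheticConfig | None = None
    params_name: str = "table-consistent"
    registry_path: str | None = None
    out_dir: str = "run"
    seed: int = 0
    stages: tuple[str, ...] = _STAGES

    def __post_init__(self) -> None:
        if (self.input_csv is None) == (self.synthetic is None):
            raise ValueError("exactly one input source (input_csv | synthetic) required")
        unknown = set(self.stages) - set(_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")


def _manifest_config(cfg: RunConfig) -> dict:
    d = dataclasses.asdict(cfg)
    if cfg.synthetic is not None:
        syn = dataclasses.asdict(cfg.synthetic)
        syn["target_correlations"] = {
            "|".join(k): v for k, v in cfg.synthetic.target_correlations.items()}
        d["synthetic"] = syn
    return d


def _write_csv(df: pd.DataFrame, path: Path, *, index: bool = False) -> None:
    df.to_csv(path, index=index, lineterminator="\n")


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the configured stages; returns the manifest dictionary."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: list[str] = []
    summary_lines: list[str] = []

    def _stage(name):
        return name in cfg.stages

    def _record(path: Path, label: str) -> None:
        artifacts.append(path.name)
        log.info("%s -> %s", label, path)

    # -- input ---------------------------------------------------------------
    try:
        if cfg.synthetic is not None:
            syn = dataclasses.replace(cfg.synthetic, seed=cfg.seed)
            dataset = generate_dataset(syn)
        else:
            dataset = load_samples(cfg.input_csv)
    except Exception as e:
        raise PipelineError(f"stage input: {e}") from e
    n = len(dataset)
    summary_lines.append(f"input: {dataset.provenance} ({n} samples)")
    samples_path = out / "samples.csv"
    dataset.df.pipe(_write_csv, samples_path)
    _record(samples_path, "samples")

    registry = load_guidelines(cfg.registry_path)
    params = get_params(cfg.params_name)

    # -- qc -------------------------------------------------------------------
    if _stage("qc"):
        try:
            report = validate_dataset(dataset)
            cells = compliance_table(dataset, registry)
            comp = compliance_frame(cells)
            desc = descriptive_stats(dataset)
        except Exception as e:
            raise PipelineError(f"stage qc: {e}") from e
        _write_csv(comp, out / "compliance.csv")
        _record(out / "compliance.csv", "qc compliance")
        _write_csv(desc, out / "descriptive_stats.csv", index=True)
        _record(out / "descriptive_stats.csv", "qc descriptives")
        who = comp[comp["authority"] == "WHO"].set_index("parameter")["pct_exceeding"]
        summary_lines.append(
            f"qc: {len(report.issues)} invariant issues; "
            f"Fe>WHO {who['fe']}%, As>WHO {who['as']}%")

    # -- stats ---------------------------------------------------------------
    if _stage("stats"):
        try:
            corr = pearson_matrix(dataset, _ASSOC_VARS)
            fits = {a: fit_depth_regression(dataset, a) for a in ("fe", "as")}
            pca = run_pca(dataset, _ASSOC_VARS)
        except Exception as e:
            raise PipelineError(f"stage stats: {e}") from e
        _write_csv(corr, out / "pearson.csv", index=True)
        _record(out / "pearson.csv", "stats pearson")
        fit_df = pd.DataFrame(
            [{"analyte": a, "intercept": f.w0, "slope": f.w[0], "r": f.r,
              "r2": f.r2, "n": f.n} for a, f in fits.items()])
        _write_csv(fit_df, out / "depth_regressions.csv")
        _record(out / "depth_regressions.csv", "stats regressions")
        pca_df = pca.loadings.copy()
        pca_df.insert(0, "explained_pct", pca.explained_pct)
        _write_csv(pca_df, out / "pca.csv", index=True)
        _record(out / "pca.csv", "stats pca")
        summary_lines.append(
            f"stats: r(tds,ec)={corr.loc['tds', 'ec']:.2f}, "
            f"r(as,depth)={corr.loc['as', 'depth']:.2f}, "
            f"PC1 {pca.explained_pct[0]:.1f}%")

    # -- risk ----------------------------------------------------------------
    risk = None
    if _stage("risk"):
        try:
            risk = risk_frame(dataset, params)
            unions = union_risk_summary(dataset, params)
        except Exception as e:
            raise PipelineError(f"stage risk: {e}") from e
        _write_csv(risk, out / "risk.csv")
        _record(out / "risk.csv", "risk per-sample")
        _write_csv(unions, out / "risk_by_union.csv", index=True)
        _record(out / "risk_by_union.csv", "risk by union")
        summary_lines.append(
            f"risk[{params.name}]: HI range {risk['hi'].min():.2f}-{risk['hi'].max():.2f}; "
            f"{int((risk['hi'] > 1).sum())}/{n} samples with HI>1")

    # -- safelimit -----------------------------------------------------------
    safe = None
    if _stage("safelimit"):
        if risk is None:
            raise PipelineError(
                "stage safelimit: requires the risk stage (toggle it on)")
        try:
            safe = safe_intake_frame(dataset, params)
        except Exception as e:
            raise PipelineError(f"stage safelimit: {e}") from e
        _write_csv(safe, out / "safe_intake.csv")
        _record(out / "safe_intake.csv", "safe-intake limits")
        finite = safe.loc[np.isfinite(safe["fir_combined"]), "fir_combined"]
        summary_lines.append(
            f"safelimit: combined FIR median {finite.median():.2f} L/day "
            f"({len(finite)}/{n} finite)")
        geo = risk.merge(safe[["sample_id", "fir_fe", "fir_as", "fir_combined"]],
                         on="sample_id")
        export_geojson(geo, out / "samples.geojson")
        _record(out / "samples.geojson", "geojson")

    # -- train ---------------------------------------------------------------
    model = None
    features = None
    target_mask = None
    if _stage("train"):
        if safe is None:
            raise PipelineError("stage train: requires the safelimit stage")
        try:
            features = encode_features(dataset, registry)
            fir = safe["fir_combined"].to_numpy()
            target_mask = np.isfinite(fir)
            feats = features[target_mask].reset_index(drop=True)
            y = np.log(fir[target_mask])
            scfg = SurrogateConfig(seed=cfg.seed)
            model, fit = train_surrogate(feats, y, scfg)
            cv = cross_validate(feats, y, scfg)
        except Exception as e:
            raise PipelineError(f"stage train: {e}") from e
        save_model(model, out / "surrogate.json")
        _record(out / "surrogate.json", "surrogate model")
        _write_csv(cv.summary, out / "cv_summary.csv", index=True)
        _record(out / "cv_summary.csv", "cv summary")
        summary_lines.append(
            f"train: test R2 {fit.test_r2:.3f} (n_train {fit.n_train}, "
            f"n_test {fit.n_test}); best CV alpha "
            f"{cv.summary['mean_r2'].idxmax()}")

    # -- attribute -----------------------------------------------------------
    if _stage("attribute"):
        if model is None:
            raise PipelineError("stage attribute: requires the train stage")
        try:
            feats = features[target_mask].reset_index(drop=True)
            bg = feats.to_numpy(dtype=float)
            rows = []
            ids = dataset.df.loc[target_mask, "sample_id"].tolist()
            for i in range(len(feats)):
                att = shapley_attribution(model, feats.iloc[i], bg,
                                          sample_id=ids[i])
                rows.append({"sample_id": att.sample_id,
                             "baseline": att.baseline,
                             "prediction": att.prediction, **att.shap})
            shap_df = pd.DataFrame(rows)
        except Exception as e:
            raise PipelineError(f"stage attribute: {e}") from e
        _write_csv(shap_df, out / "shap.csv")
        _record(out / "shap.csv", "shapley attributions")
        mean_abs = shap_df.drop(columns=["sample_id", "baseline", "prediction"]) \
            .abs().mean().sort_values(ascending=False)
        summary_lines.append(
            "attribute: top features " + ", ".join(
                f"{k} ({v:.3f})" for k, v in mean_abs.head(3).items()))

    manifest = {
        "version": __version__,
        "seed": cfg.seed,
        "n_samples": n,
        "config": _manifest_config(cfg),
        "artifacts": sorted(artifacts),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    (out / "summary.txt").write_text("\n".join(summary_lines) + "\n")
    return manifest
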