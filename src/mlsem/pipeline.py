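"""I/O, filtering, orchestration and report generation.

Runs the full analysis workflow on a household questionnaire dataset:
household filtering (adults only, two or more members), listwise
deletion, stage-1 thresholds and polychoric correlations, the DWLS
measurement fit with stepwise freeing of error covariances, the null
and full two-level structural fits, intraclass correlations, explained
variance and collinearity diagnostics — then assembles everything into
a JSON- and Markdown-serializable report.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .synthetic import (HouseholdDataset, ITEM_NAMES, PREDICTOR_IND,
                        PREDICTOR_HH, SimulationConfig, default_config,
                        generate_households)
from .polychoric import polychoric_matrix
from .cfa import ModelSpec, fit_baseline, fit_dwls, fit_indices, \
    stepwise_free_covariances
from .msem import (MSEMSpec, fit_msem, fit_null_model, latent_icc,
                   explained_variance, hypothesis_tests, standardize)
from .diagnostics import collinearity, indicator_icc

__all__ = [
    "AnalysisConfig",
    "AnalysisReport",
    "read_dataset",
    "write_dataset",
    "filter_households",
    "listwise_deletion",
    "frequency_table",
    "run_full_analysis",
]

log = logging.getLogger("mlsem")

_REQUIRED = ["household_id", "person_id"] + ITEM_NAMES + PREDICTOR_IND \
    + PREDICTOR_HH
_VALID_CODES = {1, 2, 3, 4}


@dataclass
class AnalysisConfig:
    """Configuration of one full pipeline run."""

    input_path: str | None = None          # CSV; None -> simulate
    simulation: SimulationConfig | None = None
    out_dir: str | None = None
    seed: int = 0
    n_nodes: int = 15
    mi_threshold: float = 3.84
    two_stage: bool = True                 # False -> joint loadings in ML
    structural: bool = True                # False -> null model/ICCs only
    adult_age: float = 16.0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulation", None)
        cfg = cls(**raw)
        if sim is not None:
            cfg.simulation = SimulationConfig(**sim)
        return cfg

    def digest(self) -> str:
        d = dataclasses.asdict(self)
        if self.simulation is not None:
            d["simulation"] = self.simulation.to_json_dict()
        blob = json.dumps(d, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class AnalysisReport:
    sections: dict = field(default_factory=dict)

    def to_json(self, path=None) -> str:
        text = json.dumps(self.sections, indent=1, default=_jsonify)
        if path is not None:
            Path(path).write_text(text)
        return text

    def to_markdown(self, path=None) -> str:
        text = _render_markdown(self.sections)
        if path is not None:
            Path(path).write_text(text)
        return text


def _jsonify(x):
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, pd.DataFrame):
        return json.loads(x.to_json(orient="split"))
    raise TypeError(f"not JSON-serializable: {type(x)}")


# ---------------------------------------------------------------------------
# I/O and filtering
# ---------------------------------------------------------------------------

def read_dataset(path, require_items: bool = True) -> HouseholdDataset:
    """Read a wide-format CSV (one row per individual; 'NA' missing).

    Item codes must lie in {1, 2, 3, 4}; violations are reported with
    their row numbers.  Unknown columns are kept with a warning.
    """
    df = pd.read_csv(path, na_values=["NA"], keep_default_na=True)
    missing_cols = [c for c in _REQUIRED if c not in df.columns
                    and (require_items or c not in ITEM_NAMES)]
    if missing_cols:
        raise ValueError(f"missing required columns: {missing_cols}")
    extra = [c for c in df.columns
             if c not in _REQUIRED + ["eta_ind", "eta_hh"]]
    if extra:
        log.warning("unknown columns kept as-is: %s", extra)
    offenders = []
    for c in ITEM_NAMES:
        if c not in df.columns:
            continue
        vals = df[c].dropna()
        bad = vals[~vals.isin(_VALID_CODES)]
        offenders += [(int(i) + 2, c, v) for i, v in bad.items()]  # +2: header+0-base
    if offenders:
        listing = "; ".join(f"line {r}, column {c}: {v!r}"
                            for r, c, v in offenders[:20])
        raise ValueError(f"invalid item codes (must be 1-4 or NA): {listing}")
    truth = None
    sidecar = Path(path).with_suffix(".truth.json")
    if sidecar.exists():
        truth = json.loads(sidecar.read_text())
    return HouseholdDataset(df, ground_truth=truth)


def write_dataset(dataset: HouseholdDataset, path) -> None:
    dataset.to_csv(path)


def filter_households(dataset: HouseholdDataset, adult_age: float = 16.0
                      ) -> tuple[HouseholdDataset, dict]:
    """Drop households containing children and single-member households.

    Returns the filtered dataset and exclusion counts per reason
    (households with any member under ``adult_age`` count as 'child';
    remaining size-1 households as 'single').
    """
    df = dataset.df
    by_hh = df.groupby("household_id")
    has_child = by_hh["X1_age"].min() < adult_age
    size = by_hh.size()
    reason = pd.Series("kept", index=size.index)
    reason[size < 2] = "single"
    reason[has_child] = "child"   # child takes precedence
    keep = reason[reason == "kept"].index
    counts = {
        "child": int((reason == "child").sum()),
        "single": int((reason == "single").sum()),
        "kept": int((reason == "kept").sum()),
    }
    out = HouseholdDataset(df[df["household_id"].isin(keep)].reset_index(drop=True),
                           dataset.ground_truth)
    if counts["kept"] == 0:
        log.warning("all households excluded by the filter rules")
    return out, counts


def listwise_deletion(dataset: HouseholdDataset,
                      columns: list[str] | None = None
                      ) -> tuple[HouseholdDataset, int]:
    """Drop individuals with any missing analysis variable (applied once,
    globally, before all stages)."""
    cols = columns or (ITEM_NAMES + PREDICTOR_IND + PREDICTOR_HH)
    df = dataset.df
    keep = df[cols].notna().all(axis=1)
    out = HouseholdDataset(df[keep].reset_index(drop=True), dataset.ground_truth)
    return out, int((~keep).sum())


def frequency_table(dataset: HouseholdDataset) -> pd.DataFrame:
    """Item response frequencies, one row per item, N (%) per category."""
    rows = []
    for item in ITEM_NAMES:
        col = dataset.df[item].dropna()
        n = len(col)
        row = {"item": item, "N": n}
        for c in sorted(_VALID_CODES):
            cnt = int((col == c).sum())
            row[f"cat{c}_n"] = cnt
            row[f"cat{c}_pct"] = round(100 * cnt / n, 1) if n else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def run_full_analysis(config: AnalysisConfig) -> AnalysisReport:
    """Execute the complete workflow and assemble the report.

    Deterministic for a fixed configuration and seed.  Stage failures
    raise with the stage name; the partial report assembled so far is
    attached to the exception as ``.partial_report``.
    """
    logging.basicConfig(level=config.log_level)
    sections: dict = {}
    stage = "setup"
    try:
        stage = "data"
        if config.input_path is not None:
            ds = read_dataset(config.input_path)
        else:
            sim = config.simulation or default_config(seed=config.seed)
            if sim.thresholds is None:
                sim = default_config(**{**_sim_kwargs(sim), "seed": config.seed})
            ds = generate_households(sim)
        n_hh0, n_ind0 = ds.n_households, ds.n_individuals

        stage = "filter"
        ds, exclusions = filter_households(ds, adult_age=config.adult_age)
        ds, n_dropped = listwise_deletion(ds)
        # listwise deletion can leave a lone complete member in a retained
        # household; such households stay in the analysis set
        sections["data_summary"] = {
            "n_households_input": n_hh0,
            "n_individuals_input": n_ind0,
            "household_exclusions": exclusions,
            "individuals_dropped_listwise": n_dropped,
            "n_households_analysed": ds.n_households,
            "n_individuals_analysed": ds.n_individuals,
        }
        sections["frequency_table"] = frequency_table(ds)

        stage = "polychoric"
        polymat = polychoric_matrix(ds.df[ITEM_NAMES])
        sections["thresholds"] = polymat.thresholds.to_dict()

        stage = "measurement"
        start_spec = ModelSpec(n_items=12, item_names=list(ITEM_NAMES))
        final_spec, trail, cfa_fit = stepwise_free_covariances(
            polymat, start_spec, mi_threshold=config.mi_threshold)
        baseline = fit_baseline(polymat)
        indices = fit_indices(cfa_fit, baseline)
        sections["measurement"] = {
            "loadings": _loading_table(cfa_fit),
            "factor_variance": cfa_fit.psi,
            "free_error_covariances": [list(p) for p in final_spec.free_covs],
            "fit_indices": dataclasses.asdict(indices),
            "mi_trail": trail,
            "estimator": "DWLS",
        }

        stage = "msem-null"
        mspec = MSEMSpec.from_cfa(cfa_fit, polymat,
                                  estimate_loadings=not config.two_stage)
        null = fit_null_model(ds, mspec, n_nodes=config.n_nodes)
        icc_latent = latent_icc(null.psi_hh, null.psi_ind)
        item_iccs = {it: indicator_icc(ds, it).icc for it in ITEM_NAMES}
        sections["icc"] = {
            "latent": icc_latent,
            "indicators": item_iccs,
            "indicator_scale": "latent response (sigma2_b / (sigma2_b + 1))",
            "psi_null_ind": null.psi_ind,
            "psi_null_hh": null.psi_hh,
        }

        if config.structural:
            stage = "msem-full"
            fit = fit_msem(ds, mspec, n_nodes=config.n_nodes)
            std = standardize(fit, ds)
            tests = hypothesis_tests(fit)
            coll = collinearity(ds)
            sections["structural"] = {
                "estimator": ("two-stage ML (measurement fixed at DWLS "
                              "estimates)" if config.two_stage
                              else "joint ML"),
                "table": _structural_table(fit, std, coll),
                "psi_ind": fit.psi_ind, "psi_hh": fit.psi_hh,
                "psi_null_ind": null.psi_ind, "psi_null_hh": null.psi_hh,
                "loglik": fit.loglik, "aic": fit.aic, "bic": fit.bic,
                "converged": fit.converged, "boundary": fit.boundary,
            }
            sections["explained_variance"] = {
                "individual": explained_variance(null.psi_ind, fit.psi_ind),
                "household": explained_variance(null.psi_hh, fit.psi_hh),
            }
            sections["hypothesis_tests"] = tests
            sections["diagnostics"] = {
                "predictor_correlations": coll.correlations,
                "collinearity": coll.as_frame(),
                "max_abs_correlation": float(
                    np.abs(coll.correlations.to_numpy()
                           - np.eye(len(coll.predictors))).max()),
            }

        stage = "provenance"
        sections["provenance"] = {
            "config_digest": config.digest(),
            "seed": config.seed,
            "versions": {"mlsem": __version__, "numpy": np.__version__,
                         "pandas": pd.__version__},
        }
    except Exception as exc:
        exc.partial_report = AnalysisReport(sections)  # type: ignore[attr-defined]
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    report = AnalysisReport(sections)
    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        report.to_json(out / "report.json")
        report.to_markdown(out / "report.md")
    return report


def _sim_kwargs(sim: SimulationConfig) -> dict:
    return {f.name: getattr(sim, f.name)
            for f in dataclasses.fields(SimulationConfig)}


def _loading_table(cfa_fit) -> list[dict]:
    rows = []
    std = cfa_fit.standardized_loadings
    for p, item in enumerate(cfa_fit.spec.item_names or
                             [f"item{i+1}" for i in range(cfa_fit.spec.n_items)]):
        se = cfa_fit.se_loadings[p]
        est = cfa_fit.loadings[p]
        rows.append({
            "item": item, "estimate": float(est),
            "se": None if np.isnan(se) else float(se),
            "ci_lower": None if np.isnan(se) else float(est - 1.96 * se),
            "ci_upper": None if np.isnan(se) else float(est + 1.96 * se),
            "standardized": float(std[p]),
        })
    return rows


def _structural_table(fit, std, coll) -> list[dict]:
    rows = []
    est = fit.estimates()
    std_all = {**std["beta"], **std["gamma"]}
    for name in fit.spec.predictors_ind + fit.spec.predictors_hh:
        lo, hi = fit.conf_int(name)
        rows.append({
            "parameter": name, "level": ("household" if name in
                                         fit.spec.predictors_hh else "individual"),
            "estimate": float(est[name]), "se": float(fit.se.get(name, np.nan)),
            "ci_lower": float(lo), "ci_upper": float(hi),
            "standardized": float(std_all[name]),
            "tolerance": float(coll.tolerance[name]),
            "vif": float(coll.vif[name]),
        })
    return rows


# ---------------------------------------------------------------------------
# markdown rendering
# ---------------------------------------------------------------------------

def _records(obj) -> list[dict]:
    """Rows of a DataFrame or of its JSON (orient='split') round-trip."""
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="records")
    if isinstance(obj, dict) and {"columns", "data"} <= set(obj):
        idx = obj.get("index", range(len(obj["data"])))
        return [{"index": ix, **dict(zip(obj["columns"], row))}
                for ix, row in zip(idx, obj["data"])]
    return list(obj)


def _md_table(records: list[dict]) -> str:
    if not records:
        return "(empty)\n"
    cols = list(records[0].keys())
    fmt = lambda v: f"{v:.4g}" if isinstance(v, float) else str(v)
    lines = ["| " + " | ".join(cols) + " |",
             "|" + "|".join("---" for _ in cols) + "|"]
    for r in records:
        lines.append("| " + " | ".join(fmt(r.get(c, "")) for c in cols) + " |")
    return "\n".join(lines) + "\n"


def _render_markdown(sections: dict) -> str:
    # normalize through the JSON encoding so that rendering a live report
    # and re-rendering its persisted report.json give identical output
    sections = json.loads(json.dumps(sections, default=_jsonify))
    parts = ["# Multilevel latent-morbidity analysis report\n"]
    ds = sections.get("data_summary")
    if ds:
        parts.append("## Data\n")
        parts.append(_md_table([ds]))
    ft = sections.get("frequency_table")
    if ft is not None:
        parts.append("## Item response frequencies\n")
        parts.append(_md_table(_records(ft)))
    meas = sections.get("measurement")
    if meas:
        parts.append("## Measurement model (DWLS)\n")
        parts.append(_md_table(meas["loadings"]))
        fi = meas["fit_indices"]
        parts.append(f"\nchi2 = {fi['chi2']:.2f} (df = {fi['df']}), "
                     f"CFI = {fi['cfi']:.3f}, "
                     f"TLI = {fi['tli'] if fi['tli'] is None else round(fi['tli'], 3)}, "
                     f"RMSEA = {fi['rmsea'] if fi['rmsea'] is None else round(fi['rmsea'], 3)}, "
                     f"GFI = {fi['gfi']:.3f}\n")
        parts.append(f"\nError covariances freed stepwise: "
                     f"{len(meas['free_error_covariances'])}\n")
    icc = sections.get("icc")
    if icc:
        parts.append("## Intraclass correlations\n")
        parts.append(f"Latent-factor ICC: {icc['latent']:.3f} "
                     f"(psi_null_hh = {icc['psi_null_hh']:.4f}, "
                     f"psi_null_ind = {icc['psi_null_ind']:.4f})\n\n")
        parts.append(_md_table([{"item": k, "ICC": v}
                                for k, v in icc["indicators"].items()]))
    st = sections.get("structural")
    if st:
        parts.append("## Structural model (" + st["estimator"] + ")\n")
        parts.append(_md_table(st["table"]))
        parts.append(f"\npsi_ind = {st['psi_ind']:.4f} "
                     f"(null {st['psi_null_ind']:.4f}); "
                     f"psi_hh = {st['psi_hh']:.4f} "
                     f"(null {st['psi_null_hh']:.4f}); "
                     f"AIC = {st['aic']:.1f}, BIC = {st['bic']:.1f}\n")
    ev = sections.get("explained_variance")
    if ev:
        parts.append("## Explained variance\n")
        parts.append(f"Individual level: {100 * ev['individual']:.1f}%; "
                     f"household level: {100 * ev['household']:.1f}%\n")
    ht = sections.get("hypothesis_tests")
    if ht is not None:
        parts.append("## Directional hypothesis tests\n")
        parts.append(_md_table(_records(ht)))
    dg = sections.get("diagnostics")
    if dg:
        parts.append("## Collinearity\n")
        co = dg["collinearity"]
        if isinstance(co, pd.DataFrame):
            co = co.reset_index().rename(columns={"index": "predictor"})
        parts.append(_md_table(_records(co)))
    pv = sections.get("provenance")
    if pv:
        parts.append("\n---\n")
        parts.append(f"seed {pv['seed']}, config {pv['config_digest']}, "
                     f"mlsem {pv['versions']['mlsem']}\n")
    return "\n".join(parts)
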