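"""Reading and writing the package's tabular and config formats.

Tidy CSV schemas:

* trajectory — time_h, dna_nM, rna_nM, tsr, tlr, protein_dark_nM,
  protein_mat_nM, observed_rna_nM, observed_protein_nM;
* titration dataset — experiment_id, template_kind, template_nM, replicate,
  time_h, rna_nM, protein_nM;
* per-cell traces — population_id, batch_id, cell_id, radius_um, time_h,
  rna_nM, protein_nM;
* calibration — channel, known_nM, rfu, session_id.

Configs are YAML; fit results and profiles serialize to JSON.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import yaml

from .inference import FitResult, ProfileCurve, TitrationDataset
from .params import (
    BULK_MLE, CELL_MLE, PARAM_NAMES, PARAM_UNITS, KineticParams, ModelVariant,
    VARIANTS,
)
from .population import CellTrace, PopulationSummary

__all__ = [
    "write_trajectory", "read_titration", "write_titration",
    "read_cell_traces", "write_cell_traces", "write_population_summaries",
    "read_calibration_table", "params_from_config", "variant_from_config",
    "load_yaml", "fit_result_to_dict", "profile_to_dict",
    "write_parameter_table",
]


def load_yaml(path) -> dict:
    with open(path) as fh:
        out = yaml.safe_load(fh)
    return out or {}


def write_trajectory(traj, path) -> None:
    traj.to_frame().to_csv(path, index=False)


def write_titration(data: TitrationDataset, path) -> None:
    data.to_frame().to_csv(path, index=False)


def read_titration(path, batch: str = "") -> TitrationDataset:
    return TitrationDataset.from_frame(pd.read_csv(path), batch=batch)


def write_cell_traces(traces: list[CellTrace], path) -> None:
    rows = []
    for t in traces:
        rows.append(pd.DataFrame({
            "population_id": t.population_id,
            "batch_id": t.batch_id,
            "cell_id": t.cell_id,
            "radius_um": t.radius_um,
            "time_h": t.time_h,
            "rna_nM": t.rna_nM,
            "protein_nM": t.protein_nM,
        }))
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)


def read_cell_traces(path) -> list[CellTrace]:
    df = pd.read_csv(path)
    traces = []
    for cid, g in df.groupby("cell_id", sort=True):
        g = g.sort_values("time_h")
        traces.append(CellTrace(
            cell_id=str(cid),
            radius_um=float(g["radius_um"].iloc[0]),
            time_h=g["time_h"].to_numpy(float),
            rna_nM=g["rna_nM"].to_numpy(float),
            protein_nM=g["protein_nM"].to_numpy(float),
            population_id=str(g["population_id"].iloc[0]),
            batch_id=str(g["batch_id"].iloc[0]),
        ))
    return traces


def write_population_summaries(summaries: list[PopulationSummary], path) -> None:
    pd.DataFrame([s.as_dict() for s in summaries]).to_csv(path, index=False)


def read_calibration_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"channel", "known_nM", "rfu"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"calibration table missing columns: {sorted(missing)}")
    return df


_PARAM_PRESETS = {"bulk": BULK_MLE, "cell": CELL_MLE}


def params_from_config(spec) -> KineticParams:
    """Kinetic parameters from a YAML value: preset name or name→value map."""
    if isinstance(spec, str):
        try:
            return _PARAM_PRESETS[spec]
        except KeyError:
            raise ValueError(
                f"unknown parameter preset {spec!r}; use one of "
                f"{sorted(_PARAM_PRESETS)} or a mapping"
            ) from None
    if isinstance(spec, dict):
        unknown = set(spec) - set(PARAM_NAMES)
        if unknown:
            raise ValueError(f"unknown parameter name(s): {sorted(unknown)}")
        missing = set(PARAM_NAMES) - {"tau_l"} - set(spec)
        if missing:
            raise ValueError(f"missing parameter(s): {sorted(missing)}")
        return KineticParams(**{k: float(v) for k, v in spec.items()})
    raise ValueError("params must be a preset name or a mapping")


def variant_from_config(spec) -> ModelVariant:
    """Model variant from a YAML value: code ('V1'…'V7') or explicit fields."""
    if isinstance(spec, str):
        if spec not in VARIANTS:
            raise ValueError(f"unknown variant code {spec!r}")
        return VARIANTS[spec]
    if isinstance(spec, dict):
        allowed = {"tx_law", "tl_law", "tsr_degradation", "tlr_degradation"}
        unknown = set(spec) - allowed
        if unknown:
            raise ValueError(f"unknown variant field(s): {sorted(unknown)}")
        return ModelVariant(code="custom", **spec)
    raise ValueError("variant must be a code or a mapping")


def fit_result_to_dict(fit: FitResult) -> dict:
    d = fit.summary()
    d["noise"] = {
        "kind": fit.noise.kind,
        "sigma_rna": fit.noise.sigma_rna,
        "sigma_protein": fit.noise.sigma_protein,
    }
    d["start_nlls"] = [
        (None if not np.isfinite(v) else float(v)) for v in fit.start_nlls
    ]
    return d


def profile_to_dict(profile: ProfileCurve) -> dict:
    def inf_safe(x):
        if np.isnan(x):
            return None
        if np.isinf(x):
            return "+inf" if x > 0 else "-inf"
        return float(x)

    return {
        "parameter": profile.parameter,
        "theta_hat": profile.theta_hat,
        "nll_hat": profile.nll_hat,
        "grid": [float(g) for g in profile.grid],
        "nll": [inf_safe(v) for v in profile.nll],
        "ci_low": inf_safe(profile.ci_low),
        "ci_high": inf_safe(profile.ci_high),
    }


def write_parameter_table(
    fit: FitResult, cis: dict[str, tuple[float, float]], path
) -> None:
    """Parameter/estimate/CI summary table (CSV) for a fitted variant."""
    rows = []
    for name in PARAM_NAMES:
        if name in fit.free_names:
            lo, hi = cis.get(name, (float("nan"), float("nan")))
            rows.append({
                "parameter": name,
                "estimate": getattr(fit.theta_hat, name),
                "ci_low": lo,
                "ci_high": hi,
                "status": "free",
                "units": PARAM_UNITS[name],
            })
        elif name in fit.fixed:
            rows.append({
                "parameter": name,
                "estimate": fit.fixed[name],
                "ci_low": "",
                "ci_high": "",
                "status": "fixed",
                "units": PARAM_UNITS[name],
            })
    pd.DataFrame(rows).to_csv(path, index=False)
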