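"""Population statistics for synthetic-cell (liposome) expression data.

Per-cell time courses from monodisperse vesicle populations are summarized
into the quantities used to compare populations: endpoint means and SDs of
radius, mRNA and protein, their coefficients of variation (CV = SD/mean, a
scale-free dispersion measure), Gaussian moment fits for histogram overlay,
batch-to-batch CVs, and two-reporter expression ratios.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CellTrace",
    "PopulationSummary",
    "cv",
    "summarize_population",
    "batch_cv",
    "expression_ratio",
    "max_translation_rate",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CellTrace:
    """One synthetic cell: its radius and mRNA/protein time courses."""

    cell_id: str
    radius_um: float
    time_h: np.ndarray
    rna_nM: np.ndarray
    protein_nM: np.ndarray
    population_id: str = ""
    batch_id: str = ""

    def __post_init__(self) -> None:
        if not self.radius_um > 0:
            raise ValueError("radius must be > 0")
        if len(self.rna_nM) != len(self.time_h) or len(self.protein_nM) != len(
            self.time_h
        ):
            raise ValueError("series must match the time grid")


@dataclass
class PopulationSummary:
    """Endpoint summary of one population (radius, mRNA, protein)."""

    population_id: str
    n_cells: int
    endpoint_h: float
    radius_mean: float
    radius_sd: float
    radius_cv: float
    rna_mean: float
    rna_sd: float
    rna_cv: float
    protein_mean: float
    protein_sd: float
    protein_cv: float
    #: Gaussian (mean, variance) per channel for histogram overlays.
    gaussian_fits: dict[str, tuple[float, float]] = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "population_id": self.population_id,
            "n_cells": self.n_cells,
            "endpoint_h": self.endpoint_h,
            "radius_mean_um": self.radius_mean,
            "radius_sd_um": self.radius_sd,
            "radius_cv": self.radius_cv,
            "rna_mean_nM": self.rna_mean,
            "rna_sd_nM": self.rna_sd,
            "rna_cv": self.rna_cv,
            "protein_mean_nM": self.protein_mean,
            "protein_sd_nM": self.protein_sd,
            "protein_cv": self.protein_cv,
        }


def cv(values) -> float:
    """Coefficient of variation: sample SD (n−1 denominator) over mean."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("CV needs at least 2 values")
    mean = float(np.mean(x))
    if mean == 0.0:
        raise ValueError("CV undefined for zero mean")
    return float(np.std(x, ddof=1) / mean)


def _endpoint_value(trace: CellTrace, endpoint: float, channel: str) -> float:
    t = np.asarray(trace.time_h, dtype=float)
    i = int(np.argmin(np.abs(t - endpoint)))
    if abs(t[i] - endpoint) > 1e-9 and not (t[0] <= endpoint <= t[-1]):
        raise ValueError(f"endpoint {endpoint} h outside trace range")
    return float(getattr(trace, channel)[i])


def summarize_population(
    traces: list[CellTrace], endpoint: float | None = None
) -> PopulationSummary:
    """Endpoint means, SDs, and CVs of a single population.

    ``endpoint`` defaults to the final common time point. Gaussian moment
    fits (mean, variance) per channel are recorded for histogram overlays.
    """
    if not traces:
        raise ValueError("empty population")
    if len(traces) < 2:
        raise ValueError("population summary needs >= 2 cells")
    pids = {t.population_id for t in traces}
    if len(pids) > 1:
        raise ValueError(f"traces span multiple populations: {sorted(pids)}")
    if endpoint is None:
        endpoint = float(min(t.time_h[-1] for t in traces))
    radius = np.array([t.radius_um for t in traces])
    rna = np.array([_endpoint_value(t, endpoint, "rna_nM") for t in traces])
    prot = np.array([_endpoint_value(t, endpoint, "protein_nM") for t in traces])
    out = {}
    for name, x in (("radius", radius), ("rna", rna), ("protein", prot)):
        out[f"{name}_mean"] = float(np.mean(x))
        out[f"{name}_sd"] = float(np.std(x, ddof=1))
        out[f"{name}_cv"] = cv(x)
    return PopulationSummary(
        population_id=pids.pop(),
        n_cells=len(traces),
        endpoint_h=endpoint,
        gaussian_fits={
            "radius": (float(np.mean(radius)), float(np.var(radius, ddof=1))),
            "rna": (float(np.mean(rna)), float(np.var(rna, ddof=1))),
            "protein": (float(np.mean(prot)), float(np.var(prot, ddof=1))),
        },
        **out,
    )


def max_translation_rate(trace: CellTrace, smooth_window: int = 3) -> float:
    """Peak apparent translation rate (nM/h) of one trace.

    Centered finite differences of the protein series after a moving-average
    smooth (default 3 points); the window is configurable because measured
    traces need mild smoothing before differentiation.
    """
    t = np.asarray(trace.time_h, dtype=float)
    p = np.asarray(trace.protein_nM, dtype=float)
    if len(t) < 3:
        raise ValueError("need >= 3 points to differentiate")
    if smooth_window > 1:
        kernel = np.ones(smooth_window) / smooth_window
        pad = smooth_window // 2
        p = np.convolve(np.pad(p, pad, mode="edge"), kernel, mode="valid")
        p = p[: len(t)]
    return float(np.max(np.gradient(p, t)))


def batch_cv(
    batch_endpoint_protein, batch_max_rates=None
) -> tuple[float, float | None]:
    """Batch-to-batch CVs of endpoint protein and of peak translation rate.

    Inputs are batch-level values (e.g. each batch's population mean);
    at least two batches are required.
    """
    ep = np.asarray(batch_endpoint_protein, dtype=float)
    if ep.size < 2:
        raise ValueError("batch CV needs >= 2 batches")
    cv_ep = cv(ep)
    if batch_max_rates is None:
        return cv_ep, None
    mr = np.asarray(batch_max_rates, dtype=float)
    if mr.size < 2:
        raise ValueError("batch CV needs >= 2 batches")
    return cv_ep, cv(mr)


def expression_ratio(
    channel_a_endpoints, channel_b_endpoints
) -> tuple[float, float]:
    """Mean ± SD of the per-cell ratio of two reporter channels.

    Cells with a zero denominator are excluded with a warning. Used to
    check co-encapsulation consistency (e.g. eGFP/mCherry).
    """
    a = np.asarray(channel_a_endpoints, dtype=float)
    b = np.asarray(channel_b_endpoints, dtype=float)
    if a.shape != b.shape:
        raise ValueError("channels must be paired per cell")
    keep = b != 0
    if not np.all(keep):
        logger.warning(
            "%d cell(s) with zero denominator excluded from ratio",
            int(np.sum(~keep)),
        )
    a, b = a[keep], b[keep]
    if a.size == 0:
        raise ValueError("no cells with nonzero denominator")
    r = a / b
    sd = float(np.std(r, ddof=1)) if r.size > 1 else 0.0
    return float(np.mean(r)), sd
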