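"""Resource-limited transcription/translation dynamics.

The model tracks five states: transcript RNA (nM), transcription resource
TsR and translation resource TlR (unitless, start at 1, decrease to 0),
immature ("dark") reporter protein P_dark and mature fluorescent protein
P_mat (nM). DNA template is a constant input. Transcription and translation
draw down their resource pools; translation acts on the transcript
concentration a delay ``tau_d`` in the past, which reproduces the delayed
onset of protein signal seen in mRNA-titration experiments. Observed
(reported) channels are RNA and P_mat, shifted by the measurement lag
``tau_l``: data time ``t`` reads the model at ``t - tau_l`` and reads 0
before ``tau_l``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from ._kernels import integrate_dde
from .params import KineticParams, ModelVariant, VARIANTS

__all__ = ["ModelState", "Trajectory", "rhs", "simulate", "max_rates"]

logger = logging.getLogger(__name__)

#: Delays below this (h) are treated as zero and integrated as a plain ODE.
_TAU_D_FLOOR = 1e-3
#: Target integrator step (h); the actual step divides tau_d exactly.
_H_TARGET = 2e-3
#: Nonnegativity clips larger than this (nM) trigger a warning.
_CLIP_WARN = 1e-9


@dataclass(frozen=True)
class ModelState:
    """Instantaneous model state (concentrations in nM, resources unitless)."""

    DNA: float
    RNA: float
    TsR: float
    TlR: float
    P_dark: float
    P_mat: float

    def __post_init__(self) -> None:
        if min(self.DNA, self.RNA, self.P_dark, self.P_mat) < 0:
            raise ValueError("concentrations must be >= 0")
        if not (0.0 <= self.TsR <= 1.0 and 0.0 <= self.TlR <= 1.0):
            raise ValueError("resources must lie in [0, 1]")

    @classmethod
    def initial(cls, dna0: float, rna0: float = 0.0) -> "ModelState":
        return cls(DNA=dna0, RNA=rna0, TsR=1.0, TlR=1.0, P_dark=0.0, P_mat=0.0)


def _fluxes(state_vec, lagged_rna, dna, p, variant: ModelVariant):
    rna, tsr, tlr = state_vec[0], state_vec[1], state_vec[2]
    if variant.tx_law == "michaelis_menten":
        den = p.K_r + dna
        if den <= 0 and dna > 0:
            raise ZeroDivisionError("MM transcription with K_r + DNA = 0")
        v_tx = p.k_r * tsr * dna / den if den > 0 else 0.0
    else:
        v_tx = p.k_r * tsr * dna
    if variant.tl_law == "michaelis_menten":
        den = p.K_p + lagged_rna
        v_tl = p.k_p * tlr * lagged_rna / den if den > 0 else 0.0
    else:
        v_tl = p.k_p * tlr * lagged_rna
    return v_tx, v_tl


def rhs(
    state: ModelState,
    lagged_rna: float,
    params: KineticParams,
    variant: ModelVariant | str = "V1",
) -> dict[str, float]:
    """Time derivative of the model state.

    ``lagged_rna`` is RNA(t - tau_d), the translation substrate. Returns a
    dict of d/dt values keyed like :class:`ModelState` fields (dDNA = 0).
    """
    if isinstance(variant, str):
        variant = VARIANTS[variant]
    if lagged_rna < 0:
        raise ValueError("lagged_rna must be >= 0")
    p = params
    vec = (state.RNA, state.TsR, state.TlR)
    v_tx, v_tl = _fluxes(vec, lagged_rna, state.DNA, p, variant)

    d_tsr = -p.a * v_tx
    if variant.tsr_degradation == "first_order":
        d_tsr -= p.delta_TsR * state.TsR
    if variant.tlr_degradation == "michaelis_menten":
        den = p.K_l + state.TlR
        deg = p.delta_TlR * state.TlR / den if den > 0 else 0.0
    else:
        deg = p.delta_TlR * state.TlR
    return {
        "DNA": 0.0,
        "RNA": v_tx - p.delta_r * state.RNA,
        "TsR": d_tsr,
        "TlR": -p.b * v_tl - deg,
        "P_dark": v_tl - p.k_mat * state.P_dark,
        "P_mat": p.k_mat * state.P_dark,
    }


@dataclass
class Trajectory:
    """A simulated time course on a user grid, plus observed channels.

    ``time`` is the data-time grid (h, starting at 0). ``states`` holds the
    model state at each grid time (model clock). ``observed_rna`` and
    ``observed_protein`` are the reporter channels after applying the
    measurement lag tau_l (zero for t < tau_l).
    """

    time: np.ndarray
    dna: float
    rna0: float
    states: np.ndarray               # (n, 5): RNA, TsR, TlR, P_dark, P_mat
    observed_rna: np.ndarray
    observed_protein: np.ndarray
    params: KineticParams
    variant: ModelVariant
    fine_time: np.ndarray = field(repr=False, default=None)
    fine_states: np.ndarray = field(repr=False, default=None)
    fine_vtx: np.ndarray = field(repr=False, default=None)
    fine_vtl: np.ndarray = field(repr=False, default=None)

    @property
    def rna(self) -> np.ndarray:
        return self.states[:, 0]

    @property
    def tsr(self) -> np.ndarray:
        return self.states[:, 1]

    @property
    def tlr(self) -> np.ndarray:
        return self.states[:, 2]

    @property
    def protein_dark(self) -> np.ndarray:
        return self.states[:, 3]

    @property
    def protein_mat(self) -> np.ndarray:
        return self.states[:, 4]

    def to_frame(self):
        """Tidy table with one row per grid time."""
        import pandas as pd

        return pd.DataFrame({
            "time_h": self.time,
            "dna_nM": self.dna,
            "rna_nM": self.rna,
            "tsr": self.tsr,
            "tlr": self.tlr,
            "protein_dark_nM": self.protein_dark,
            "protein_mat_nM": self.protein_mat,
            "observed_rna_nM": self.observed_rna,
            "observed_protein_nM": self.observed_protein,
        })


def simulate(
    params: KineticParams,
    variant: ModelVariant | str = "V1",
    dna0: float = 0.0,
    rna0: float = 0.0,
    t_grid: np.ndarray | None = None,
    h_target: float | None = None,
    quiet: bool = False,
) -> Trajectory:
    """Simulate the delayed system and report observed channels on ``t_grid``.

    The delay is handled on a fixed Runge–Kutta grid commensurate with
    ``tau_d`` (constant history RNA(s) = ``rna0`` for s <= 0); ``tau_l``
    shifts the reported channels only. ``h_target`` overrides the default
    integrator step (the actual step is snapped to divide ``tau_d``).
    ``quiet`` demotes domain-clip warnings to debug level — used by the
    likelihood machinery, where optimizer excursions to extreme parameters
    routinely trigger clips.
    """
    if isinstance(variant, str):
        variant = VARIANTS[variant]
    if t_grid is None:
        t_grid = np.linspace(0.0, 8.0, 97)
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid[0] != 0.0 or np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must start at 0 and be strictly increasing")
    if dna0 < 0 or rna0 < 0:
        raise ValueError("initial template concentrations must be >= 0")

    t_end = float(t_grid[-1])
    h_t = _H_TARGET if h_target is None else float(h_target)
    if params.tau_d < _TAU_D_FLOOR:
        n = max(1, int(np.ceil(t_end / h_t)))
        h, m = t_end / n, 0
    else:
        m = max(1, int(round(params.tau_d / h_t)))
        h = params.tau_d / m

    p = params.to_array()
    tx, tl, tsd, tld = variant.codes()
    ts, Y, vtx, vtl, clip_conc, clip_res = integrate_dde(
        p, tx, tl, tsd, tld, float(dna0), float(rna0), t_end, h, m
    )
    if clip_conc > _CLIP_WARN:
        (logger.debug if quiet else logger.warning)(
            "concentration clipped to 0 by up to %.3g nM during integration",
            clip_conc,
        )
    if clip_res > 0:
        # expected at the TlR = 0 absorbing boundary when K_l is small
        logger.debug("resource clipped to [0, 1] by up to %.3g", clip_res)

    states = np.column_stack(
        [np.interp(t_grid, ts, Y[:, j]) for j in range(5)]
    )
    t_model = t_grid - params.tau_l
    obs = np.zeros((len(t_grid), 2))
    vis = t_model >= 0
    obs[vis, 0] = np.interp(t_model[vis], ts, Y[:, 0])
    obs[vis, 1] = np.interp(t_model[vis], ts, Y[:, 4])

    return Trajectory(
        time=t_grid, dna=float(dna0), rna0=float(rna0), states=states,
        observed_rna=obs[:, 0], observed_protein=obs[:, 1],
        params=params, variant=variant,
        fine_time=ts, fine_states=Y, fine_vtx=vtx, fine_vtl=vtl,
    )


def max_rates(traj: Trajectory) -> tuple[tuple[float, float], tuple[float, float]]:
    """Peak synthesis fluxes along a trajectory.

    Returns ``((v_tx_max, t_at_max), (v_tl_max, t_at_max))`` in nM/h and h,
    scanning the model fluxes on the integrator grid. Transcription typically
    peaks at t = 0 (TsR and the saturation term are maximal at the start);
    translation peaks once enough transcript has accumulated.
    """
    if traj.fine_vtx is None or len(traj.time) < 3:
        raise ValueError("trajectory must carry >= 3 points and flux records")
    i_tx = int(np.argmax(traj.fine_vtx))
    i_tl = int(np.argmax(traj.fine_vtl))
    return (
        (float(traj.fine_vtx[i_tx]), float(traj.fine_time[i_tx])),
        (float(traj.fine_vtl[i_tl]), float(traj.fine_time[i_tl])),
    )
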