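"""Kinetic parameters and structural model variants.

The model describes transcription and translation in a cell-free expression
system (CFES) fed by two phenomenological resource pools: a transcription
resource TsR and a translation resource TlR, both unitless, initialized at 1
and monotonically consumed. Thirteen kinetic parameters govern the dynamics;
seven structural variants differ in the kinetic laws used for the synthesis
fluxes and for resource degradation.
"""

from __future__ import annotations

from dataclasses import dataclass, fields, replace

import numpy as np

__all__ = [
    "KineticParams",
    "ModelVariant",
    "PARAM_NAMES",
    "PARAM_UNITS",
    "VARIANTS",
    "BULK_MLE",
    "CELL_MLE",
    "DEFAULT_BOUNDS",
    "PHYSICAL_BOUNDS",
]

#: Canonical parameter order used for vectorization (fitting, simulation).
PARAM_NAMES: tuple[str, ...] = (
    "k_r", "K_r", "delta_r", "k_p", "K_p", "k_mat",
    "delta_TsR", "delta_TlR", "K_l", "a", "b", "tau_d", "tau_l",
)

PARAM_UNITS: dict[str, str] = {
    "k_r": "nM/h",
    "K_r": "nM",
    "delta_r": "1/h",
    "k_p": "nM/h",
    "K_p": "nM",
    "k_mat": "1/h",
    "delta_TsR": "1/h",
    "delta_TlR": "1/h",
    "K_l": "",
    "a": "",
    "b": "",
    "tau_d": "h",
    "tau_l": "h",
}


@dataclass(frozen=True)
class KineticParams:
    """The 13 kinetic parameters of the resource-limited CFES model.

    Attributes
    ----------
    k_r : float
        Maximal transcription rate (nM/h).
    K_r : float
        RNAP–DNA dissociation constant (nM).
    delta_r : float
        First-order RNA degradation rate (1/h).
    k_p : float
        Maximal translation rate (nM/h).
    K_p : float
        Ribosome–mRNA dissociation constant (nM).
    k_mat : float
        First-order mCherry maturation rate (1/h).
    delta_TsR : float
        First-order TsR degradation rate (1/h).
    delta_TlR : float
        TlR degradation rate (1/h).
    K_l : float
        Michaelis–Menten constant for TlR degradation (unitless).
    a : float
        TsR consumed per nM transcribed (unitless/nM).
    b : float
        TlR consumed per nM translated (unitless/nM).
    tau_d : float
        Translation delay (h): translation acts on RNA(t - tau_d).
    tau_l : float
        Lag between reaction start and first measurement (h); a pure
        reporting-time shift, not a dynamical quantity.
    """

    k_r: float
    K_r: float
    delta_r: float
    k_p: float
    K_p: float
    k_mat: float
    delta_TsR: float
    delta_TlR: float
    K_l: float
    a: float
    b: float
    tau_d: float
    tau_l: float = 0.0

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(
                    f"parameter {f.name}={v!r} must be finite and >= 0"
                )

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in PARAM_NAMES], dtype=float)

    @classmethod
    def from_array(cls, vec: np.ndarray) -> "KineticParams":
        vec = np.asarray(vec, dtype=float)
        if vec.shape != (len(PARAM_NAMES),):
            raise ValueError(f"expected {len(PARAM_NAMES)} values, got {vec.shape}")
        return cls(**dict(zip(PARAM_NAMES, vec.tolist())))

    def replace(self, **kw: float) -> "KineticParams":
        return replace(self, **kw)

    def as_dict(self) -> dict[str, float]:
        return {n: getattr(self, n) for n in PARAM_NAMES}


@dataclass(frozen=True)
class ModelVariant:
    """A structural variant of the resource-limited model.

    ``tx_law``/``tl_law`` pick Michaelis–Menten or mass-action kinetics for
    the transcription/translation flux; ``tsr_degradation`` and
    ``tlr_degradation`` pick the spontaneous decay law of each resource pool.
    """

    code: str
    tx_law: str = "michaelis_menten"          # michaelis_menten | mass_action
    tl_law: str = "michaelis_menten"
    tsr_degradation: str = "first_order"      # none | first_order
    tlr_degradation: str = "michaelis_menten" # first_order | michaelis_menten

    _TX = ("michaelis_menten", "mass_action")
    _TSR = ("none", "first_order")
    _TLR = ("first_order", "michaelis_menten")

    def __post_init__(self) -> None:
        if self.tx_law not in self._TX or self.tl_law not in self._TX:
            raise ValueError("tx_law/tl_law must be michaelis_menten or mass_action")
        if self.tsr_degradation not in self._TSR:
            raise ValueError("tsr_degradation must be none or first_order")
        if self.tlr_degradation not in self._TLR:
            raise ValueError(
                "tlr_degradation must be first_order or michaelis_menten"
            )

    @property
    def active_params(self) -> tuple[str, ...]:
        """Parameters that enter the dynamics under this structure."""
        names = ["k_r"]
        if self.tx_law == "michaelis_menten":
            names.append("K_r")
        names += ["delta_r", "k_p"]
        if self.tl_law == "michaelis_menten":
            names.append("K_p")
        names.append("k_mat")
        if self.tsr_degradation == "first_order":
            names.append("delta_TsR")
        names.append("delta_TlR")
        if self.tlr_degradation == "michaelis_menten":
            names.append("K_l")
        names += ["a", "b", "tau_d", "tau_l"]
        return tuple(n for n in PARAM_NAMES if n in names)

    @property
    def n_active_params(self) -> int:
        return len(self.active_params)

    def n_free_params(self, fixed: dict[str, float] | None = None) -> int:
        fixed = fixed or {}
        return len([n for n in self.active_params if n not in fixed])

    def codes(self) -> tuple[int, int, int, int]:
        """Integer encoding for the compiled integrator kernel."""
        return (
            self._TX.index(self.tx_law),
            self._TX.index(self.tl_law),
            self._TSR.index(self.tsr_degradation),
            self._TLR.index(self.tlr_degradation),
        )


def _mk(code, tx, tl, tsr, tlr) -> ModelVariant:
    return ModelVariant(code=code, tx_law=tx, tl_law=tl,
                        tsr_degradation=tsr, tlr_degradation=tlr)


MM, MA = "michaelis_menten", "mass_action"

#: The seven candidate structures submitted to AIC model selection. V1 is the
#: full model (MM transcription and translation, first-order TsR decay,
#: MM TlR decay); V2 drops TsR degradation (the classic resource-limited
#: reference structure); V3/V4 simplify TlR decay to first order; V5–V7 swap
#: one or both synthesis fluxes to mass action.
VARIANTS: dict[str, ModelVariant] = {
    "V1": _mk("V1", MM, MM, "first_order", MM),
    "V2": _mk("V2", MM, MM, "none", MM),
    "V3": _mk("V3", MM, MM, "first_order", "first_order"),
    "V4": _mk("V4", MM, MM, "none", "first_order"),
    "V5": _mk("V5", MA, MM, "first_order", MM),
    "V6": _mk("V6", MM, MA, "first_order", MM),
    "V7": _mk("V7", MA, MA, "first_order", MM),
}


#: Reference maximum-likelihood estimates from bulk DNA/RNA titration
#: experiments (plate-reader time courses, full model V1).
BULK_MLE = KineticParams(
    k_r=2894.0, K_r=3.67, delta_r=0.0392,
    k_p=2568.0, K_p=703.0, k_mat=2.15,
    delta_TsR=0.231, delta_TlR=0.0884, K_l=1.21e-6,
    a=4.45e-4, b=1.78e-4, tau_d=0.433, tau_l=2.81e-9,
)

#: Reference maximum-likelihood estimates from synthetic-cell (liposome)
#: population DNA titrations, where the measurement lag tau_l is substantial.
CELL_MLE = KineticParams(
    k_r=1899.0, K_r=8.86, delta_r=0.0081,
    k_p=1954.0, K_p=1319.0, k_mat=2.15,
    delta_TsR=0.154, delta_TlR=0.244, K_l=0.232,
    a=6.60e-4, b=4.46e-13, tau_d=0.0576, tau_l=0.457,
)

#: Wide default optimization box (natural scale), applied to every parameter.
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    n: (1e-8, 1e8) for n in PARAM_NAMES
}

#: Physically informed per-parameter boxes used by the bundled fitting
#: studies: synthesis rates within plate-reader-plausible nM/h, binding
#: constants around reported enzyme/template scales, decay rates below 10/h.
PHYSICAL_BOUNDS: dict[str, tuple[float, float]] = {
    "k_r": (1e1, 1e5),
    "K_r": (1e-2, 1e3),
    "delta_r": (1e-4, 1e1),
    "k_p": (1e1, 1e5),
    "K_p": (1e0, 1e5),
    "k_mat": (1e-2, 1e2),
    "delta_TsR": (1e-3, 1e1),
    "delta_TlR": (1e-3, 1e1),
    "K_l": (1e-8, 1e1),
    "a": (1e-8, 1e-1),
    "b": (1e-8, 1e-1),
    "tau_d": (1e-3, 2.0),
    "tau_l": (1e-3, 2.0),
}
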