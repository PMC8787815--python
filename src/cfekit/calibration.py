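"""Fluorescence calibration and derived physical quantities.

Plate-reader and microscopy signals (RFU) are converted to nM through linear
calibration curves fitted to serial dilutions of purified reporter
standards. From fitted kinetic rates and the known composition of the
expression mix, per-enzyme turnover rates, the reporter maturation
half-time, and per-vesicle molecule counts are derived.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "CalibrationCurve",
    "UnitContext",
    "fit_calibration",
    "rfu_to_nm",
    "nm_to_rfu",
    "polymerase_rate_ntp_per_s",
    "ribosome_rate_aa_per_s",
    "maturation_half_time",
    "copy_number",
    "AVOGADRO",
]

logger = logging.getLogger(__name__)

AVOGADRO = 6.02214076e23  # 1/mol

_CHANNELS = ("broccoli_rna", "mcherry", "egfp")


@dataclass(frozen=True)
class CalibrationCurve:
    """Linear RFU-vs-concentration calibration for one fluorescence channel."""

    channel: str
    slope: float          # RFU per nM
    intercept: float      # RFU at zero concentration
    r_squared: float = float("nan")
    n_points: int = 0

    def __post_init__(self) -> None:
        if self.channel not in _CHANNELS:
            raise ValueError(f"unknown channel {self.channel!r}")
        if not self.slope > 0:
            raise ValueError("calibration slope must be > 0 (invertible)")


@dataclass(frozen=True)
class UnitContext:
    """Physical constants of the expression construct and reaction mix.

    Transcript length (nt), protein length (aa), and the nominal T7 RNA
    polymerase and ribosome concentrations of the reconstituted expression
    mix used to convert bulk synthesis rates (nM/h) into per-enzyme rates.
    """

    L_rna: float = 1087.0     # nt
    L_prot: float = 777.0     # aa
    C_RNAP: float = 100.0     # nM
    C_ribo: float = 2400.0    # nM
    avogadro: float = AVOGADRO

    def __post_init__(self) -> None:
        for name in ("L_rna", "L_prot", "C_RNAP", "C_ribo", "avogadro"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")


def fit_calibration(
    known_nM: np.ndarray, measured_rfu: np.ndarray, channel: str = "mcherry"
) -> CalibrationCurve:
    """Ordinary-least-squares line through a serial-dilution series.

    Requires at least 3 points at >= 2 distinct concentrations. A warning is
    logged when R² < 0.98, the quality expected of a clean dilution series.
    """
    x = np.asarray(known_nM, dtype=float)
    y = np.asarray(measured_rfu, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("known_nM and measured_rfu must be equal-length 1-D")
    if len(x) < 3:
        raise ValueError("calibration needs >= 3 points")
    if len(np.unique(x)) < 2:
        raise ValueError("calibration needs >= 2 distinct concentrations")
    res = stats.linregress(x, y)
    r2 = float(res.rvalue**2)
    if r2 < 0.98:
        logger.warning(
            "calibration R²=%.4f < 0.98 on channel %s", r2, channel
        )
    return CalibrationCurve(
        channel=channel, slope=float(res.slope),
        intercept=float(res.intercept), r_squared=r2, n_points=len(x),
    )


def rfu_to_nm(curve: CalibrationCurve, rfu):
    """Invert the calibration: (RFU − intercept) / slope.

    Signals below the intercept convert to negative concentrations; they are
    flagged (logged) but preserved so near-zero statistics stay unbiased.
    """
    rfu = np.asarray(rfu, dtype=float)
    out = (rfu - curve.intercept) / curve.slope
    n_neg = int(np.sum(out < 0))
    if n_neg:
        logger.info(
            "%d reading(s) below the calibration intercept on channel %s "
            "(negative nM preserved)", n_neg, curve.channel,
        )
    return out if out.ndim else float(out)


def nm_to_rfu(curve: CalibrationCurve, conc_nM):
    conc_nM = np.asarray(conc_nM, dtype=float)
    out = curve.slope * conc_nM + curve.intercept
    return out if out.ndim else float(out)


def polymerase_rate_ntp_per_s(k_r: float, ctx: UnitContext | None = None) -> float:
    """Per-polymerase elongation rate (NTP/s) implied by a bulk rate k_r.

    A bulk transcription rate of k_r nM/h of full transcripts corresponds to
    k_r·L_rna nM of nucleotides per hour, shared over C_RNAP of polymerase.
    """
    if k_r < 0:
        raise ValueError("k_r must be >= 0")
    ctx = ctx or UnitContext()
    return k_r * ctx.L_rna / (ctx.C_RNAP * 3600.0)


def ribosome_rate_aa_per_s(k_p: float, ctx: UnitContext | None = None) -> float:
    """Per-ribosome elongation rate (aa/s) implied by a bulk rate k_p."""
    if k_p < 0:
        raise ValueError("k_p must be >= 0")
    ctx = ctx or UnitContext()
    return k_p * ctx.L_prot / (ctx.C_ribo * 3600.0)


def maturation_half_time(k_mat: float) -> float:
    """Half-time (minutes) of first-order fluorophore maturation: 60·ln2/k."""
    if k_mat <= 0:
        raise ValueError("k_mat must be > 0")
    return 60.0 * math.log(2.0) / k_mat


def copy_number(
    radius_um: float, conc_nM: float, ctx: UnitContext | None = None
) -> float:
    """Molecule count in a spherical vesicle of the given radius.

    conc (mol/L) × volume (L) × N_A; the result is linear in concentration
    and cubic in radius.
    """
    if radius_um <= 0:
        raise ValueError("radius must be > 0")
    if conc_nM < 0:
        raise ValueError("concentration must be >= 0")
    ctx = ctx or UnitContext()
    volume_l = (4.0 / 3.0) * math.pi * (radius_um * 1e-6) ** 3 * 1e3
    return conc_nM * 1e-9 * volume_l * ctx.avogadro
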