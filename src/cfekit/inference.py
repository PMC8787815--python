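"""Maximum-likelihood fitting, AIC model selection, and profile likelihoods.

Candidate model structures are fitted jointly to mRNA/protein time courses
collected at several template concentrations (a titration dataset). The
objective is a Gaussian negative log-likelihood with per-channel noise
scales; variants are ranked by AIC = 2k + 2·NLL̂; parameter uncertainty is
quantified by profile likelihoods over a one-decade window each side of the
estimate, with likelihood-based confidence intervals. A profile that never
crosses the chi-squared threshold inside the window reports that bound as
±∞ — the parameter is non- or weakly identifiable at that scale.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import optimize, stats
from scipy.interpolate import PchipInterpolator
from scipy.stats import qmc

from .model import simulate
from .params import (
    DEFAULT_BOUNDS, KineticParams, ModelVariant, PARAM_NAMES, VARIANTS,
)

__all__ = [
    "Experiment",
    "TitrationDataset",
    "NoiseSpec",
    "OptimizerConfig",
    "FitResult",
    "ProfileCurve",
    "negative_log_likelihood",
    "fit_mle",
    "aic",
    "rank_models",
    "profile_likelihood",
    "likelihood_ci",
    "profile_function",
]

logger = logging.getLogger(__name__)

#: Finite sentinel returned when integration fails at extreme parameters.
NLL_PENALTY = 1e12

#: Default fixed parameters: the maturation rate is measured independently
#: (fluorophore maturation assay) and the measurement lag is negligible for
#: bulk plate-reader runs.
DEFAULT_FIXED = {"k_mat": 2.15, "tau_l": 0.0}


# ---------------------------------------------------------------------------
# data containers


@dataclass(frozen=True)
class Experiment:
    """One time course: a template at one concentration, one replicate."""

    experiment_id: str
    template_kind: str            # "dna" | "rna"
    template_nM: float
    replicate: int
    time_h: np.ndarray
    rna_nM: np.ndarray
    protein_nM: np.ndarray

    def __post_init__(self) -> None:
        if self.template_kind not in ("dna", "rna"):
            raise ValueError("template_kind must be 'dna' or 'rna'")
        if self.template_nM < 0:
            raise ValueError("template concentration must be >= 0")
        t = np.asarray(self.time_h, dtype=float)
        if np.any(np.diff(t) <= 0):
            raise ValueError("time grid must be strictly increasing")
        for arr in (self.rna_nM, self.protein_nM):
            if len(arr) != len(t):
                raise ValueError("series length must match time grid")


@dataclass
class TitrationDataset:
    """Joint mRNA/protein time courses across template concentrations."""

    experiments: list[Experiment]
    batch: str = ""

    def __post_init__(self) -> None:
        if not self.experiments:
            raise ValueError("dataset must contain at least one experiment")

    @property
    def template_levels(self) -> list[tuple[str, float]]:
        return sorted({(e.template_kind, e.template_nM) for e in self.experiments})

    def content_hash(self) -> str:
        h = hashlib.sha256()
        for e in sorted(self.experiments, key=lambda e: e.experiment_id):
            h.update(e.experiment_id.encode())
            for arr in (e.time_h, e.rna_nM, e.protein_nM):
                h.update(np.asarray(arr, dtype=float).tobytes())
        return h.hexdigest()[:16]

    def to_frame(self):
        import pandas as pd

        rows = []
        for e in self.experiments:
            rows.append(pd.DataFrame({
                "experiment_id": e.experiment_id,
                "template_kind": e.template_kind,
                "template_nM": e.template_nM,
                "replicate": e.replicate,
                "time_h": e.time_h,
                "rna_nM": e.rna_nM,
                "protein_nM": e.protein_nM,
            }))
        return pd.concat(rows, ignore_index=True)

    @classmethod
    def from_frame(cls, df, batch: str = "") -> "TitrationDataset":
        exps = []
        for eid, g in df.groupby("experiment_id", sort=True):
            g = g.sort_values("time_h")
            exps.append(Experiment(
                experiment_id=str(eid),
                template_kind=str(g["template_kind"].iloc[0]),
                template_nM=float(g["template_nM"].iloc[0]),
                replicate=int(g["replicate"].iloc[0]),
                time_h=g["time_h"].to_numpy(float),
                rna_nM=g["rna_nM"].to_numpy(float),
                protein_nM=g["protein_nM"].to_numpy(float),
            ))
        return cls(experiments=exps, batch=batch)


@dataclass(frozen=True)
class NoiseSpec:
    """Per-channel Gaussian noise model for the likelihood.

    ``kind``:
      * ``"fixed"`` — use the given SDs (nM);
      * ``"replicate"`` — SD per channel pooled from replicate scatter;
      * ``"concentrated"`` — SDs profiled out analytically, giving the
        concentrated NLL  n/2·(log(2π·RSS/n) + 1) per channel;
      * ``"auto"`` — replicate if replicates exist, else concentrated.
    """

    kind: str = "auto"
    sigma_rna: float | None = None
    sigma_protein: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("fixed", "replicate", "concentrated", "auto"):
            raise ValueError(f"unknown noise kind {self.kind!r}")
        if self.kind == "fixed" and not (
            self.sigma_rna and self.sigma_protein
            and self.sigma_rna > 0 and self.sigma_protein > 0
        ):
            raise ValueError("fixed noise requires positive channel SDs")


# ---------------------------------------------------------------------------
# likelihood


def _sim_groups(data: TitrationDataset):
    """Group experiments sharing (kind, conc, grid) so each is simulated once."""
    groups: dict = {}
    for e in data.experiments:
        key = (e.template_kind, e.template_nM, tuple(np.asarray(e.time_h)))
        groups.setdefault(key, []).append(e)
    return list(groups.items())


def _replicate_sigmas(data: TitrationDataset) -> tuple[float, float] | None:
    """Pooled per-channel SD across replicates, or None without replicates."""
    var_r, var_p, n = [], [], 0
    for (_, _, _), exps in _sim_groups(data):
        if len(exps) < 2:
            continue
        rna = np.stack([e.rna_nM for e in exps])
        prot = np.stack([e.protein_nM for e in exps])
        var_r.append(np.var(rna, axis=0, ddof=1))
        var_p.append(np.var(prot, axis=0, ddof=1))
        n += 1
    if n == 0:
        return None
    return (
        float(np.sqrt(np.mean(np.concatenate(var_r)))),
        float(np.sqrt(np.mean(np.concatenate(var_p)))),
    )


def resolve_noise(data: TitrationDataset, noise: NoiseSpec) -> NoiseSpec:
    """Turn an 'auto'/'replicate' spec into a concrete one for a dataset."""
    if noise.kind in ("fixed", "concentrated"):
        return noise
    sig = _replicate_sigmas(data)
    if sig is None:
        if noise.kind == "replicate":
            raise ValueError("replicate noise requested but no replicates found")
        return NoiseSpec(kind="concentrated")
    return NoiseSpec(kind="fixed", sigma_rna=sig[0], sigma_protein=sig[1])


def _gaussian_nll(rss: float, n: int, sigma: float | None) -> float:
    if n == 0:
        return 0.0
    if sigma is not None:
        return 0.5 * n * np.log(2.0 * np.pi * sigma**2) + rss / (2.0 * sigma**2)
    # sigma profiled out analytically
    rss = max(rss, 1e-300)
    return 0.5 * n * (np.log(2.0 * np.pi * rss / n) + 1.0)


def negative_log_likelihood(
    params: KineticParams,
    variant: ModelVariant | str,
    data: TitrationDataset,
    noise: NoiseSpec | None = None,
    h_target: float | None = None,
    channels: tuple[str, ...] = ("rna", "protein"),
) -> float:
    """Gaussian NLL of the model against a titration dataset.

    Simulates each distinct (template, grid) condition once, accumulates
    per-channel residual sums of squares over all replicates and time
    points, and applies the channel noise model. Integration failure at
    extreme parameters returns a large finite penalty (``NLL_PENALTY``)
    rather than raising, so optimizers can continue.
    """
    noise = resolve_noise(data, noise or NoiseSpec())
    if isinstance(variant, str):
        variant = VARIANTS[variant]
    rss_r = rss_p = 0.0
    n_r = n_p = 0
    for (kind, conc, _), exps in _sim_groups(data):
        dna0, rna0 = (conc, 0.0) if kind == "dna" else (0.0, conc)
        t_data = np.asarray(exps[0].time_h, dtype=float)
        if t_data[0] > 0.0:  # data may start after the reaction start
            t_sim = np.insert(t_data, 0, 0.0)
            sl = slice(1, None)
        else:
            t_sim, sl = t_data, slice(None)
        try:
            traj = simulate(
                params, variant, dna0=dna0, rna0=rna0,
                t_grid=t_sim, h_target=h_target, quiet=True,
            )
        except (ValueError, ZeroDivisionError, FloatingPointError):
            return NLL_PENALTY
        model_rna = traj.observed_rna[sl]
        model_prot = traj.observed_protein[sl]
        if not (
            np.all(np.isfinite(model_rna)) and np.all(np.isfinite(model_prot))
        ):
            return NLL_PENALTY
        for e in exps:
            if "rna" in channels:
                rss_r += float(np.sum((e.rna_nM - model_rna) ** 2))
                n_r += len(e.rna_nM)
            if "protein" in channels:
                rss_p += float(np.sum((e.protein_nM - model_prot) ** 2))
                n_p += len(e.protein_nM)
    if noise.kind == "fixed":
        return _gaussian_nll(rss_r, n_r, noise.sigma_rna) + _gaussian_nll(
            rss_p, n_p, noise.sigma_protein
        )
    return _gaussian_nll(rss_r, n_r, None) + _gaussian_nll(rss_p, n_p, None)


def aic(k: int, nll_hat: float) -> float:
    """Akaike information criterion, 2k − 2·logL = 2k + 2·NLL̂."""
    if k < 0:
        raise ValueError("k must be >= 0")
    return 2.0 * k + 2.0 * nll_hat


# ---------------------------------------------------------------------------
# fitting


@dataclass(frozen=True)
class OptimizerConfig:
    """Budget of the multistart optimizer.

    ``n_screen`` Latin-hypercube points are scored by plain NLL evaluation;
    the best ``n_starts`` (set in :func:`fit_mle`) are refined by L-BFGS-B
    with a numeric gradient, then polished by Nelder–Mead.
    """

    maxiter_grad: int = 300
    maxiter_polish: int = 600
    polish: bool = True
    n_screen: int = 192
    fd_step: float = 1e-6
    maxiter_stage: int = 120
    #: minimum log10-distance between multistart points taken from the
    #: screen; forcing well-separated starts covers distinct basins (the
    #: joint landscape has a known fast-RNA-degradation local minimum)
    start_separation: float = 3.0


#: Parameters whose effect is visible in the RNA channel alone; the RNA
#: dynamics have no feedback from translation, so these can be fitted first
#: on the RNA channel (staged strategy) before the joint refinement.
_TX_PARAMS = frozenset({"k_r", "K_r", "delta_r", "delta_TsR", "a", "tau_l"})


@dataclass
class FitResult:
    """A converged maximum-likelihood fit of one model variant."""

    variant: ModelVariant
    theta_hat: KineticParams
    free_names: tuple[str, ...]
    fixed: dict[str, float]
    nll_hat: float
    k: int
    aic: float
    seed: int
    noise: NoiseSpec
    data_hash: str
    bounds: dict[str, tuple[float, float]]
    h_target: float | None = None
    start_nlls: list[float] = field(default_factory=list)

    def summary(self) -> dict:
        return {
            "variant": self.variant.code,
            "nll_hat": self.nll_hat,
            "k": self.k,
            "aic": self.aic,
            "theta_hat": self.theta_hat.as_dict(),
            "free": list(self.free_names),
            "fixed": dict(self.fixed),
            "seed": self.seed,
            "data_hash": self.data_hash,
        }


def _assemble_params(
    z: np.ndarray, free_names: Sequence[str], base: dict[str, float]
) -> KineticParams:
    vals = dict(base)
    for name, zi in zip(free_names, z):
        vals[name] = 10.0 ** zi
    return KineticParams(**vals)


def _objective(
    free_names, base, variant, data, noise, h_target, lo, hi,
    channels=("rna", "protein"),
) -> Callable[[np.ndarray], float]:
    def fun(z: np.ndarray) -> float:
        zc = np.clip(z, lo, hi)
        penalty = float(np.sum((z - zc) ** 2))
        p = _assemble_params(zc, free_names, base)
        return (
            negative_log_likelihood(p, variant, data, noise, h_target, channels)
            + penalty
        )

    return fun


def fit_mle(
    data: TitrationDataset,
    variant: ModelVariant | str = "V1",
    bounds: dict[str, tuple[float, float]] | None = None,
    n_starts: int = 20,
    seed: int = 0,
    fixed: dict[str, float] | None = None,
    free: Sequence[str] | None = None,
    noise: NoiseSpec | None = None,
    optimizer: OptimizerConfig | None = None,
    h_target: float | None = None,
    init_params: Sequence[KineticParams | dict] | None = None,
) -> FitResult:
    """Multistart maximum-likelihood fit in log10-parameter space.

    Every active parameter of the variant is either free or pinned through
    ``fixed`` (by default the independently measured maturation rate and a
    zero measurement lag; population fits should release ``tau_l``).
    Starting points are a seeded Latin-hypercube sample of the log-bounds
    box (optionally preceded by explicit ``init_params`` warm starts); each
    start runs a staged refinement — transcription parameters against the
    RNA channel, translation parameters against the protein channel, then a
    joint L-BFGS-B stage and a Nelder–Mead polish. The same (data, config,
    seed) always reproduces the same result.
    """
    if isinstance(variant, str):
        variant = VARIANTS[variant]
    if len(data.template_levels) < 2:
        raise ValueError(
            "joint fitting requires >= 2 distinct template concentrations"
        )
    noise = resolve_noise(data, noise or NoiseSpec())
    optimizer = optimizer or OptimizerConfig()
    fixed = dict(DEFAULT_FIXED if fixed is None else fixed)
    active = variant.active_params
    fixed = {k: v for k, v in fixed.items() if k in active}
    if free is None:
        free_names = tuple(n for n in active if n not in fixed)
    else:
        unknown = set(free) - set(active)
        if unknown:
            raise ValueError(f"free parameters not active in {variant.code}: {unknown}")
        free_names = tuple(n for n in active if n in set(free))
        for n in active:
            if n not in free_names and n not in fixed:
                raise ValueError(f"active parameter {n} neither free nor fixed")
    bounds = {**DEFAULT_BOUNDS, **(bounds or {})}
    # inactive parameters do not enter the dynamics; pin them at 0
    base = {n: 0.0 for n in PARAM_NAMES}
    base.update(fixed)

    lo = np.array([np.log10(bounds[n][0]) for n in free_names])
    hi = np.array([np.log10(bounds[n][1]) for n in free_names])
    d = len(free_names)
    if d == 0:
        raise ValueError("no free parameters to fit")

    fun = _objective(free_names, base, variant, data, noise, h_target, lo, hi)
    fun_rna = _objective(
        free_names, base, variant, data, noise, h_target, lo, hi, ("rna",)
    )
    fun_prot = _objective(
        free_names, base, variant, data, noise, h_target, lo, hi, ("protein",)
    )

    starts: list[np.ndarray] = []
    mid = 0.5 * (lo + hi)
    for ip in init_params or ():
        vals = ip.as_dict() if isinstance(ip, KineticParams) else dict(ip)
        z = mid.copy()
        for j, n in enumerate(free_names):
            v = vals.get(n, 0.0)
            if v and v > 0:
                z[j] = np.clip(np.log10(v), lo[j], hi[j])
        starts.append(z)

    if len(starts) < n_starts:
        # screen a Latin-hypercube sample, then take the best candidates
        # subject to a minimum mutual separation so the starts cover
        # distinct basins
        sampler = qmc.LatinHypercube(d=d, seed=seed)
        n_screen = max(optimizer.n_screen, n_starts)
        cands = lo + sampler.random(n=n_screen) * (hi - lo)
        scores = np.array([fun(z) for z in cands])
        order = np.argsort(scores, kind="stable")
        chosen: list[np.ndarray] = []
        for i in order:
            if len(starts) + len(chosen) >= n_starts:
                break
            if all(
                np.linalg.norm(cands[i] - s) >= optimizer.start_separation
                for s in chosen
            ):
                chosen.append(cands[i])
        for i in order:  # backfill if the separation rule left too few
            if len(starts) + len(chosen) >= n_starts:
                break
            if not any(cands[i] is s for s in chosen):
                chosen.append(cands[i])
        starts.extend(chosen)

    i_tx = np.array(
        [j for j, n in enumerate(free_names) if n in _TX_PARAMS], dtype=int
    )
    i_tl = np.array(
        [j for j, n in enumerate(free_names) if n not in _TX_PARAMS], dtype=int
    )

    def _sub_minimize(obj, z, idx, maxiter):
        """Optimize the coordinates ``idx`` of ``z``, holding the rest."""
        if len(idx) == 0 or len(idx) == d:
            return z

        def f(w):
            zz = z.copy()
            zz[idx] = w
            return obj(zz)

        res = optimize.minimize(
            f, z[idx], method="L-BFGS-B",
            bounds=list(zip(lo[idx], hi[idx])),
            options={"maxiter": maxiter, "eps": optimizer.fd_step},
        )
        out = z.copy()
        out[idx] = res.x
        return out

    best_z, best_nll = None, np.inf
    start_nlls: list[float] = []
    n_fail = 0
    for z0 in starts:
        try:
            z0 = np.asarray(z0, dtype=float).copy()
            # stage 1: transcription parameters on the RNA channel (the RNA
            # dynamics are unaffected by the translation parameters)
            z0 = _sub_minimize(fun_rna, z0, i_tx, optimizer.maxiter_stage)
            # stage 2: translation parameters on the protein channel
            z0 = _sub_minimize(fun_prot, z0, i_tl, optimizer.maxiter_stage)
            # stage 3: joint refinement
            res = optimize.minimize(
                fun, z0, method="L-BFGS-B",
                bounds=list(zip(lo, hi)),
                options={"maxiter": optimizer.maxiter_grad,
                         "eps": optimizer.fd_step},
            )
            z, v = res.x, float(res.fun)
            if optimizer.polish:
                res2 = optimize.minimize(
                    fun, z, method="Nelder-Mead",
                    options={"maxfev": optimizer.maxiter_polish,
                             "xatol": 1e-6, "fatol": 1e-8},
                )
                if res2.fun < v:
                    z, v = np.clip(res2.x, lo, hi), float(res2.fun)
        except Exception:  # noqa: BLE001 - a failed start is diagnostic only
            n_fail += 1
            start_nlls.append(np.inf)
            continue
        start_nlls.append(v)
        if v < best_nll:
            best_z, best_nll = z, v
    if best_z is None or not np.isfinite(best_nll) or best_nll >= NLL_PENALTY:
        raise RuntimeError(
            f"all {n_starts} starts failed to converge "
            f"({n_fail} raised; best objective {best_nll:.3g})"
        )

    theta = _assemble_params(best_z, free_names, base)
    k = len(free_names)
    return FitResult(
        variant=variant, theta_hat=theta, free_names=free_names,
        fixed=fixed, nll_hat=float(best_nll), k=k,
        aic=aic(k, float(best_nll)), seed=seed, noise=noise,
        data_hash=data.content_hash(), bounds=bounds,
        h_target=h_target, start_nlls=start_nlls,
    )


def rank_models(fits: Sequence[FitResult]) -> list[FitResult]:
    """Fits ordered by ascending AIC; ties go to fewer parameters."""
    if len({f.data_hash for f in fits}) > 1:
        raise ValueError("fits were made on different datasets")
    return sorted(fits, key=lambda f: (f.aic, f.k, f.variant.code))


# ---------------------------------------------------------------------------
# profile likelihoods and confidence intervals


@dataclass
class ProfileCurve:
    """Profiled NLL of one parameter over a log-spaced window."""

    parameter: str
    grid: np.ndarray           # parameter values (natural scale)
    nll: np.ndarray
    nll_hat: float
    theta_hat: float
    ok: np.ndarray | None = None
    ci_low: float = float("nan")
    ci_high: float = float("nan")


def profile_function(
    nll_fn: Callable[[np.ndarray], float],
    z_hat: np.ndarray,
    index: int,
    nll_hat: float,
    n_grid: int = 21,
    window_decades: float = 1.0,
    lo: np.ndarray | None = None,
    hi: np.ndarray | None = None,
    optimizer: OptimizerConfig | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Profile an NLL over one coordinate of a log10 parameter vector.

    Walks the grid outward from the estimate in both directions, re-optimizing
    the remaining coordinates warm-started from the neighbouring solution.
    Returns ``(grid_log10, profiled_nll, ok)``; failed re-optimizations are
    flagged, not fatal.
    """
    optimizer = optimizer or OptimizerConfig(maxiter_grad=80, maxiter_polish=150)
    d = len(z_hat)
    zc = z_hat[index]
    grid = np.linspace(zc - window_decades, zc + window_decades, n_grid)
    order = np.argsort(np.abs(grid - zc), kind="stable")
    others = [j for j in range(d) if j != index]
    lo_o = None if lo is None else lo[others]
    hi_o = None if hi is None else hi[others]

    nll_vals = np.full(n_grid, np.nan)
    ok = np.zeros(n_grid, dtype=bool)
    warm: dict[int, np.ndarray] = {}

    def solve(zi: float, w0: np.ndarray) -> tuple[float, np.ndarray, bool]:
        if not others:
            z = np.array(z_hat, dtype=float)
            z[index] = zi
            return float(nll_fn(z)), w0, True

        def fun(w: np.ndarray) -> float:
            z = np.empty(d)
            z[index] = zi
            z[others] = w
            return nll_fn(z)

        bnds = None if lo_o is None else list(zip(lo_o, hi_o))
        try:
            res = optimize.minimize(
                fun, w0, method="L-BFGS-B", bounds=bnds,
                options={"maxiter": optimizer.maxiter_grad},
            )
            w, v = res.x, float(res.fun)
            if optimizer.polish:
                res2 = optimize.minimize(
                    fun, w, method="Nelder-Mead",
                    options={"maxfev": optimizer.maxiter_polish,
                             "xatol": 1e-6, "fatol": 1e-8},
                )
                if res2.fun < v:
                    w, v = res2.x, float(res2.fun)
                    if lo_o is not None:
                        w = np.clip(w, lo_o, hi_o)
            return v, w, v < NLL_PENALTY
        except Exception:  # noqa: BLE001
            return np.nan, w0, False

    for i in order:
        # warm start from the nearest already-solved neighbour toward center
        neigh = [j for j in (i - 1, i + 1) if j in warm]
        w0 = warm[neigh[0]] if neigh else np.array(z_hat[others], dtype=float)
        v, w, good = solve(float(grid[i]), w0)
        nll_vals[i] = v
        ok[i] = good
        warm[i] = w
    return grid, nll_vals, ok


def profile_likelihood(
    fit: FitResult,
    data: TitrationDataset,
    parameter: str,
    n_grid: int = 21,
    window_decades: float = 1.0,
    optimizer: OptimizerConfig | None = None,
) -> ProfileCurve:
    """Profile likelihood of one fitted parameter of the model.

    The grid spans one decade either side of the estimate (log-spaced); at
    each grid value every other free parameter is re-optimized, warm-started
    from the neighbouring grid point.
    """
    if parameter not in fit.free_names:
        raise ValueError(f"{parameter!r} is not a free parameter of this fit")
    free_names = fit.free_names
    base = {n: 0.0 for n in PARAM_NAMES}
    base.update(fit.fixed)
    lo = np.array([np.log10(fit.bounds[n][0]) for n in free_names])
    hi = np.array([np.log10(fit.bounds[n][1]) for n in free_names])
    fun = _objective(
        free_names, base, fit.variant, data, fit.noise, fit.h_target, lo, hi
    )
    z_hat = np.array(
        [np.log10(getattr(fit.theta_hat, n)) for n in free_names]
    )
    idx = free_names.index(parameter)
    grid_z, nll_vals, ok = profile_function(
        fun, z_hat, idx, fit.nll_hat, n_grid=n_grid,
        window_decades=window_decades, lo=lo, hi=hi, optimizer=optimizer,
    )
    return ProfileCurve(
        parameter=parameter, grid=10.0 ** grid_z, nll=nll_vals,
        nll_hat=fit.nll_hat, theta_hat=float(getattr(fit.theta_hat, parameter)),
        ok=ok,
    )


def likelihood_ci(
    profile: ProfileCurve,
    nll_hat: float | None = None,
    alpha: float = 0.95,
    df: int = 1,
    tol: float = 1e-4,
) -> tuple[float, float]:
    """Likelihood-based confidence interval from a profile curve.

    The CI is the connected region around the estimate where the profiled
    NLL stays below ``nll_hat + χ²(alpha, df)/2``. Crossings are located by
    monotone (PCHIP) interpolation in log-parameter space; a side that never
    crosses inside the profiled window is reported as ±∞. ``df`` follows the
    caller's convention — the number of model parameters reproduces the
    headline analysis; ``df=1`` gives conventional pointwise intervals.
    """
    nll_hat = profile.nll_hat if nll_hat is None else nll_hat
    threshold = nll_hat + 0.5 * stats.chi2.ppf(alpha, df)
    x = np.log10(profile.grid)
    y = np.asarray(profile.nll, dtype=float)
    good = np.isfinite(y) if profile.ok is None else (profile.ok & np.isfinite(y))
    if not np.any(good):
        raise ValueError("profile contains no valid points")
    if np.nanmin(y[good]) > threshold + tol:
        raise ValueError(
            "profile lies entirely above the threshold; inconsistent nll_hat"
        )
    ic = int(np.argmin(np.abs(x - np.log10(profile.theta_hat))))

    def cross(side: int) -> float:
        idx = range(ic, len(x)) if side > 0 else range(ic, -1, -1)
        idx = [i for i in idx if good[i]]
        prev = None
        for i in idx:
            if y[i] > threshold and prev is not None:
                a, b = (prev, i) if side > 0 else (i, prev)
                seg = slice(a, b + 1)
                xs, ys = x[seg], y[seg]
                f = PchipInterpolator(xs, ys - threshold)
                roots = [r for r in f.roots() if xs[0] <= r <= xs[-1]]
                r = roots[0] if side > 0 else roots[-1]
                return float(10.0 ** r)
            if y[i] <= threshold:
                prev = i
        return float("inf") if side > 0 else float("-inf")

    lo_ci, hi_ci = cross(-1), cross(+1)
    profile.ci_low, profile.ci_high = lo_ci, hi_ci
    return lo_ci, hi_ci
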