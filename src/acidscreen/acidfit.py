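"""Biphasic Hill model of growth versus extracellular pH, and pH50.

Cell growth over a pHe series is biphasic: protons are required for growth
(an activatory limb, half-maximal at [H+] = K) but become inhibitory in
excess (an inhibitory limb, half-maximal at [H+] = Q). Both limbs are
Hill terms with their own cooperativity, and the curve is scaled by a
maximal growth G_max, giving five free parameters:

    G(pH) = G_max * h^n_act / (h^n_act + K^n_act)
                  * Q^n_inh / (h^n_inh + Q^n_inh),    h = 10^(-pH)

With K < Q (activation half-point more alkaline than inhibition), G has an
interior optimum pH_opt; for n_act = n_inh = 1 the optimum sits at
h* = sqrt(K*Q), i.e. pH_opt = (pK_K + pK_Q)/2.

pH50 is the acid-side pHe at which predicted growth is half of growth at
pH_opt; it may fall below the measured range, in which case it is read off
the fitted curve by extrapolation, down to a floor (default pH 5.0) where
the estimate is reported as censored. Higher pH50 = more acid sensitive.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq, least_squares, minimize_scalar
from scipy.special import expit

LN10 = np.log(10.0)

PK_BOUNDS = (5.0, 9.0)
COOP_BOUNDS = (0.3, 8.0)
PH50_FLOOR = 5.0


@dataclass(frozen=True)
class BiphasicParams:
    """Parameters of the five-parameter biphasic Hill growth curve.

    ``K`` and ``Q`` are proton binding constants in mol/L; the convenience
    constructors/properties work in pK units (pK = -log10 of the constant).
    """

    g_max: float
    K: float
    n_act: float
    Q: float
    n_inh: float

    def __post_init__(self) -> None:
        for name in ("g_max", "K", "n_act", "Q", "n_inh"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_pk(cls, g_max: float, pk_act: float, n_act: float,
                pk_inh: float, n_inh: float) -> "BiphasicParams":
        return cls(g_max=g_max, K=10.0 ** (-pk_act), n_act=n_act,
                   Q=10.0 ** (-pk_inh), n_inh=n_inh)

    @property
    def pk_act(self) -> float:
        return -np.log10(self.K)

    @property
    def pk_inh(self) -> float:
        return -np.log10(self.Q)

    @property
    def has_interior_optimum(self) -> bool:
        return self.K < self.Q


def biphasic_growth(pH, params: BiphasicParams):
    """Predicted growth at pHe under the biphasic Hill model.

    Evaluated in logit space for numerical stability: each Hill term is a
    logistic function of pH, so 0 <= G <= G_max everywhere.
    """
    pH = np.asarray(pH, dtype=float)
    act = expit(params.n_act * LN10 * (params.pk_act - pH))
    inh = expit(params.n_inh * LN10 * (pH - params.pk_inh))
    G = params.g_max * act * inh
    return G if G.ndim else float(G)


def ph_optimum(params: BiphasicParams, *, lo: float = 3.0, hi: float = 11.0) -> float:
    """pHe of maximal predicted growth, located numerically to ~1e-8 pH."""
    res = minimize_scalar(lambda p: -biphasic_growth(p, params),
                          bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-10})
    return float(res.x)


@dataclass(frozen=True)
class BiphasicFit:
    """Result of fitting one group's growth-vs-pHe data."""

    params: BiphasicParams
    rss: float
    pH_opt: float
    pH50: float
    censored: bool
    n_points: int
    n_starts_converged: int = 0
    group: str | None = None


def compute_pH50(params: BiphasicParams, *, floor: float = PH50_FLOOR,
                 pH_opt: float | None = None) -> tuple[float, bool]:
    """Acid-side half-growth pHe for a fitted curve.

    Solves G(pH) = 0.5 * G(pH_opt) on [floor, pH_opt] by bracketed root
    finding. If growth at the floor still exceeds half-maximum (the acid
    limb never crosses within range), returns (floor, censored=True).
    """
    if pH_opt is None:
        pH_opt = ph_optimum(params)
    g_opt = biphasic_growth(pH_opt, params)
    if g_opt <= 0:
        return floor, True
    target = 0.5 * g_opt

    def f(p):
        return biphasic_growth(p, params) - target

    if f(floor) >= 0:
        return floor, True
    root = brentq(f, floor, pH_opt, xtol=1e-10)
    return float(root), False


def _theta_to_params(theta: np.ndarray) -> BiphasicParams:
    # theta = (log g_max, pk_act, log n_act, pk_inh, log n_inh)
    return BiphasicParams.from_pk(
        g_max=float(np.exp(theta[0])),
        pk_act=float(theta[1]), n_act=float(np.exp(theta[2])),
        pk_inh=float(theta[3]), n_inh=float(np.exp(theta[4])))


def fit_biphasic(ph, absorbance, *, group: str | None = None,
                 ph50_floor: float = PH50_FLOOR,
                 n_extra_starts: int = 0,
                 warm_start: BiphasicParams | None = None,
                 tol: float = 1e-14) -> BiphasicFit:
    """Fit the biphasic Hill curve to (pHe, absorbance) wells for one group.

    Nonlinear least squares on raw absorbance with a deterministic
    multi-start over a 3x3 grid of (pK_act, pK_inh) initial values (nine
    starts), keeping the lowest residual sum of squares. Cooperativities
    are bounded to [0.3, 8] and pK values to [5, 9]; G_max is fitted on a
    log scale. Order of wells does not affect the result.

    With ``warm_start`` the multi-start grid is replaced by that single
    start (used for bootstrap refits seeded from the full-data fit).
    """
    ph = np.asarray(ph, dtype=float)
    y = np.asarray(absorbance, dtype=float)
    if ph.shape != y.shape or ph.ndim != 1:
        raise ValueError("ph and absorbance must be matching 1-D arrays")
    if ph.size < 5:
        raise ValueError("need at least 5 points to fit 5 parameters")
    if np.all(y <= 0):
        raise ValueError("all-zero (or negative) absorbance: nothing to fit")
    if np.unique(ph).size < 5:
        raise ValueError("need at least 5 distinct pHe levels")
    # sort for determinism regardless of well order
    order = np.lexsort((y, ph))
    ph, y = ph[order], y[order]

    ymax = float(y.max())

    def resid(theta):
        return biphasic_growth(ph, _theta_to_params(theta)) - y

    lb = np.array([np.log(ymax * 1e-6), PK_BOUNDS[0], np.log(COOP_BOUNDS[0]),
                   PK_BOUNDS[0], np.log(COOP_BOUNDS[0])])
    ub = np.array([np.log(ymax * 1e3), PK_BOUNDS[1], np.log(COOP_BOUNDS[1]),
                   PK_BOUNDS[1], np.log(COOP_BOUNDS[1])])

    if warm_start is not None:
        starts = [np.array([np.log(warm_start.g_max),
                            np.clip(warm_start.pk_act, *PK_BOUNDS),
                            np.log(np.clip(warm_start.n_act, *COOP_BOUNDS)),
                            np.clip(warm_start.pk_inh, *PK_BOUNDS),
                            np.log(np.clip(warm_start.n_inh, *COOP_BOUNDS))])]
    else:
        pk_act_starts = (7.4, 8.1, 8.8)
        pk_inh_starts = (5.6, 6.4, 7.2)
        coop_starts = [1.0] + [1.0 + 0.5 * i
                               for i in range(1, n_extra_starts + 1)]
        starts = [np.array([np.log(max(ymax, 1e-9) * 1.05), pka,
                            np.log(coop), pki, np.log(coop)])
                  for pka, pki, coop in itertools.product(
                      pk_act_starts, pk_inh_starts, coop_starts)]
    best = None
    n_converged = 0
    for x0 in starts:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                sol = least_squares(resid, x0, bounds=(lb, ub),
                                    xtol=tol, ftol=tol, gtol=tol,
                                    max_nfev=2000)
            except Exception:
                continue
        if not np.all(np.isfinite(sol.x)):
            continue
        n_converged += 1
        rss = float(np.sum(sol.fun ** 2))
        if best is None or rss < best[0]:
            best = (rss, sol.x)
    if best is None:
        raise RuntimeError("no optimizer start converged for this group")
    rss, theta = best
    params = _theta_to_params(theta)
    pH_opt = ph_optimum(params)
    pH50, censored = compute_pH50(params, floor=ph50_floor, pH_opt=pH_opt)
    return BiphasicFit(params=params, rss=rss, pH_opt=pH_opt, pH50=pH50,
                       censored=censored, n_points=int(ph.size),
                       n_starts_converged=n_converged, group=group)


def fit_plate(plate: pd.DataFrame, *, group_col: str = "group",
              ph_col: str = "pHe", y_col: str = "absorbance",
              ph50_floor: float = PH50_FLOOR) -> dict[str, BiphasicFit]:
    """Fit every group on a tidy growth plate; returns group -> fit."""
    fits: dict[str, BiphasicFit] = {}
    for name, sub in plate.groupby(group_col, sort=True):
        fits[str(name)] = fit_biphasic(sub[ph_col].to_numpy(),
                                       sub[y_col].to_numpy(),
                                       group=str(name), ph50_floor=ph50_floor)
    return fits


def normalize_to_optimum(plate: pd.DataFrame, fit: BiphasicFit, *,
                         y_col: str = "absorbance") -> pd.DataFrame:
    """Express absorbance relative to predicted growth at the optimum pHe.

    Scale-invariant: multiplying all absorbances by c rescales G_max by c
    and leaves the normalized values unchanged.
    """
    g_opt = biphasic_growth(fit.pH_opt, fit.params)
    if g_opt <= 0:
        raise ValueError("fit predicts non-positive growth at optimum")
    out = plate.copy()
    out["relative_growth"] = out[y_col] / g_opt
    return out


@dataclass(frozen=True)
class PH50Comparison:
    """Bootstrap comparison of pH50 between two groups."""

    delta: float              # pH50_alt - pH50_ref; positive = more acid sensitive
    ci_low: float
    ci_high: float
    n_boot: int
    censored_fraction: float
    unreliable: bool
    boot_deltas: np.ndarray = field(repr=False, default=None)


def compare_pH50(fit_ref: BiphasicFit, fit_alt: BiphasicFit,
                 wells_ref: pd.DataFrame, wells_alt: pd.DataFrame, *,
                 n_boot: int = 1000, seed: int = 0,
                 ph_col: str = "pHe", y_col: str = "absorbance",
                 ci: float = 0.95) -> PH50Comparison:
    """Difference in pH50 with a case-resampling bootstrap CI.

    Wells are resampled with replacement within each group and both curves
    refitted per resample; the percentile interval of the refitted deltas
    is reported. If more than 20% of resamples give a censored pH50 the CI
    is flagged unreliable.
    """
    rng = np.random.default_rng(seed)
    deltas = np.empty(n_boot)
    censored = 0
    warm = (fit_ref.params, fit_alt.params)
    for b in range(n_boot):
        try:
            pair = []
            any_censored = False
            for wells, w0 in zip((wells_ref, wells_alt), warm):
                idx = rng.integers(0, len(wells), size=len(wells))
                sub = wells.iloc[idx]
                f = fit_biphasic(sub[ph_col].to_numpy(), sub[y_col].to_numpy(),
                                 warm_start=w0, tol=1e-10)
                any_censored |= f.censored
                pair.append(f.pH50)
            deltas[b] = pair[1] - pair[0]
            censored += any_censored
        except Exception:
            deltas[b] = np.nan
            censored += 1
    ok = deltas[np.isfinite(deltas)]
    if ok.size == 0:
        raise RuntimeError("every bootstrap resample failed to fit")
    alpha = (1.0 - ci) / 2.0
    lo, hi = np.quantile(ok, [alpha, 1.0 - alpha])
    frac = censored / n_boot
    return PH50Comparison(delta=fit_alt.pH50 - fit_ref.pH50,
                          ci_low=float(lo), ci_high=float(hi),
                          n_boot=n_boot, censored_fraction=float(frac),
                          unreliable=bool(frac > 0.2), boot_deltas=ok)
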