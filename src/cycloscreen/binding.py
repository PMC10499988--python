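"""Binding-assay models for macrocycle validation.

All fits use the exact two-species ligand-depletion equilibrium rather than
the P ≫ L hyperbolic approximation, because assay ligand concentrations
(1–50 µM) are comparable to the affinities measured (K_D of a few µM).

Models
------
Fraction bound (mass action, total concentrations):
    f = ((L+P+K) − sqrt((L+P+K)² − 4LP)) / (2L)

Fluorescence polarization:      r(P) = r_free + (r_bound − r_free)·f
¹⁹F NMR signal suppression:     S(P) = S₀·(1 − f); AC50 = K_D + L_tot/2
Alanine-scan ΔΔG:               ΔΔG = R·T·ln(K_D,mut / K_D,wt)
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

__all__ = [
    "R_KCAL",
    "BindingCurve",
    "KDEstimate",
    "DdgRecord",
    "fraction_bound",
    "fit_fp_curve",
    "fit_nmr_suppression",
    "ddg_from_kd",
    "correlate_ddg",
    "fp_signal",
    "nmr_signal",
]

#: gas constant, kcal/(mol·K)
R_KCAL = 1.987e-3


@dataclass(frozen=True)
class BindingCurve:
    """A titration: protein concentrations (µM) vs measured signal.

    ``ligand_conc`` is the total macrocycle concentration L_tot (µM); it is
    always explicit because published experiments used different values
    (20 µM in figure titrations, 50 µM in the typical NMR setup, 1 µM in FP).
    """

    protein_conc: tuple[float, ...]
    signal: tuple[float, ...]
    ligand_conc: float
    replicate: str = "r1"

    def __post_init__(self) -> None:
        p = np.asarray(self.protein_conc, dtype=float)
        s = np.asarray(self.signal, dtype=float)
        if len(p) != len(s):
            raise ValueError("protein_conc and signal lengths differ")
        if (p < 0).any() or (np.diff(p) <= 0).any():
            raise ValueError("protein concentrations must be nonnegative, strictly increasing")
        if not np.isfinite(s).all():
            raise ValueError("signal must be finite")
        if self.ligand_conc <= 0:
            raise ValueError("ligand_conc must be positive")


@dataclass
class KDEstimate:
    kd: float                     # µM
    ac50: float | None = None     # µM (NMR only)
    r_free: float | None = None   # FP baseline
    r_bound: float | None = None  # FP saturated anisotropy
    s0: float | None = None       # NMR zero-protein signal
    residual_ss: float = np.nan
    converged: bool = False
    warnings: tuple[str, ...] = ()


@dataclass
class DdgRecord:
    variant: str
    kd_wt: float
    kd_mut: float
    ddg_exp: float
    ddg_fep: float | None = None
    temperature: float = 298.15


def fraction_bound(l_tot, p_tot, kd):
    """Exact equilibrium fraction of ligand bound (ligand-depletion quadratic).

    Computed in the numerically stable form f = 2P / (b + sqrt(b² − 4LP))
    with b = L + P + K, which avoids cancellation for small P.  Accepts
    scalars or arrays (broadcast).
    """
    l_tot = np.asarray(l_tot, dtype=float)
    p_tot = np.asarray(p_tot, dtype=float)
    kd = np.asarray(kd, dtype=float)
    if (l_tot <= 0).any() if l_tot.ndim else l_tot <= 0:
        raise ValueError("l_tot must be positive")
    if (np.asarray(p_tot) < 0).any() or (np.asarray(kd) < 0).any():
        raise ValueError("p_tot and kd must be nonnegative")
    b = l_tot + p_tot + kd
    disc = np.maximum(b * b - 4.0 * l_tot * p_tot, 0.0)
    denom = b + np.sqrt(disc)
    f = np.divide(2.0 * p_tot, denom, out=np.zeros_like(b), where=denom > 0)
    out = np.clip(f, 0.0, 1.0)
    return float(out) if out.ndim == 0 else out


def fp_signal(p_tot, kd, r_free, r_bound, l_tot):
    return r_free + (r_bound - r_free) * fraction_bound(l_tot, p_tot, kd)


def nmr_signal(p_tot, kd, s0, l_tot):
    return s0 * (1.0 - fraction_bound(l_tot, p_tot, kd))


def _kd_starts(conc: np.ndarray, n_starts: int = 7) -> np.ndarray:
    lo, hi = conc[conc > 0].min() / 10.0, conc.max() * 10.0
    return np.geomspace(lo, hi, n_starts)


def fit_fp_curve(curve: BindingCurve) -> KDEstimate:
    """Least-squares single-site FP fit over (K_D, r_free, r_bound).

    Deterministic multistart: 7 log-spaced K_D initialisations spanning the
    titrated concentration range, best sum of squares wins.
    """
    p = np.asarray(curve.protein_conc, dtype=float)
    s = np.asarray(curve.signal, dtype=float)
    if len(p) < 5 or np.log10(p.max() / p[p > 0].min()) < 1.5:
        raise ValueError("need >= 5 concentrations spanning >= 1.5 decades")

    warns = []
    span = s.max() - s.min()
    scale = max(abs(s).max(), 1.0)
    if span < 1e-9 * scale:
        warns.append("unidentifiable-kd: signal independent of protein")
        return KDEstimate(kd=np.inf, r_free=float(s.mean()),
                          r_bound=float(s.mean()), converged=False,
                          warnings=tuple(warns))

    best = None
    for kd0 in _kd_starts(p):
        theta0 = np.array([np.log(kd0), s[0], s[-1]])

        def resid(theta):
            kd, r_free, r_bound = np.exp(theta[0]), theta[1], theta[2]
            return fp_signal(p, kd, r_free, r_bound, curve.ligand_conc) - s

        res = optimize.least_squares(resid, theta0, method="lm", max_nfev=2000)
        ssr = float(res.cost * 2)
        if best is None or ssr < best[0]:
            best = (ssr, res)
    ssr, res = best
    kd, r_free, r_bound = float(np.exp(res.x[0])), float(res.x[1]), float(res.x[2])
    return KDEstimate(kd=kd, r_free=r_free, r_bound=r_bound,
                      residual_ss=ssr, converged=bool(res.success),
                      warnings=tuple(warns))


def fit_nmr_suppression(curve: BindingCurve,
                        noise_tolerance: float = 0.05) -> KDEstimate:
    """Fit ¹⁹F signal suppression S(P) = S₀·(1 − f) and report K_D and AC50.

    AC50 (protein concentration halving the protein-free signal) follows in
    closed form as K_D + L_tot/2 under the single-site depletion model.  A
    rise in signal beyond ``noise_tolerance``·S₀ triggers a complex-binding
    warning; an ill-conditioned fit falls back to a model-free AC50 by
    monotone interpolation at S₀/2.
    """
    p = np.asarray(curve.protein_conc, dtype=float)
    s = np.asarray(curve.signal, dtype=float)
    warns = []
    s0_obs = s[0] if p[0] == 0 else float(s.max())

    rises = np.diff(s) > noise_tolerance * max(s0_obs, 1e-30)
    if rises.any():
        warns.append("complex-binding: signal not monotone beyond noise tolerance")

    if s.max() - s.min() < 1e-9 * max(abs(s0_obs), 1e-30):
        warns.append("no-binding: signal constant at S0")
        return KDEstimate(kd=np.inf, ac50=np.inf, s0=float(s0_obs),
                          converged=False, warnings=tuple(warns))

    best = None
    for kd0 in _kd_starts(p):
        theta0 = np.array([np.log(kd0), s0_obs if s0_obs > 0 else 1.0])

        def resid(theta):
            kd, s0 = np.exp(theta[0]), theta[1]
            return nmr_signal(p, kd, s0, curve.ligand_conc) - s

        res = optimize.least_squares(resid, theta0, method="lm", max_nfev=2000)
        ssr = float(res.cost * 2)
        if best is None or ssr < best[0]:
            best = (ssr, res)
    ssr, res = best
    kd, s0 = float(np.exp(res.x[0])), float(res.x[1])
    converged = bool(res.success) and np.isfinite(kd)

    if not converged:
        # model-free fallback: interpolate the titration at S0/2
        order = np.argsort(p)
        ac50 = float(np.interp(s0_obs / 2.0, s[order][::-1], p[order][::-1]))
        warns.append("model-free-ac50: fit ill-conditioned")
        return KDEstimate(kd=np.nan, ac50=ac50, s0=float(s0_obs),
                          residual_ss=ssr, converged=False, warnings=tuple(warns))

    return KDEstimate(kd=kd, ac50=kd + curve.ligand_conc / 2.0, s0=s0,
                      residual_ss=ssr, converged=converged, warnings=tuple(warns))


def ddg_from_kd(kd_mut: float, kd_wt: float, temperature: float = 298.15) -> float:
    """Mutational binding free-energy change, R·T·ln(K_D,mut/K_D,wt), kcal/mol."""
    if kd_mut <= 0 or kd_wt <= 0:
        raise ValueError("dissociation constants must be positive")
    return R_KCAL * temperature * float(np.log(kd_mut / kd_wt))


def correlate_ddg(records: list[DdgRecord]) -> tuple[float, float, float]:
    """Pearson r and OLS line (slope, intercept) of ΔΔG_FEP vs ΔΔG_exp."""
    pts = [(r.ddg_exp, r.ddg_fep) for r in records if r.ddg_fep is not None]
    if len(pts) < 3:
        raise ValueError("need >= 3 records with both ddg values")
    x = np.array([p[0] for p in pts])
    y = np.array([p[1] for p in pts])
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    fit = stats.linregress(x, y)
    return float(fit.rvalue), float(fit.slope), float(fit.intercept)
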