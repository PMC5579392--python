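"""Binding isotherms: protein-induced folding FRET titration and one-site ITC.

The FRET isotherm treats protein P binding RNA R as a two-state equilibrium
with apparent association constant K_A.  The complex concentration C is the
physically meaningful (smaller) root of

    C^2 - C (P_T + R_T + 1/K_A) + P_T R_T = 0

and the observed efficiency is E = E0 + dE * C / R_T, so E(0) = E0 and
E -> E0 + dE at saturating protein.  L7Ae-family proteins bind k-turns with
picomolar affinity, so titrations at 200 nM RNA are essentially
stoichiometric and K_A is only weakly identified; the fitter reports an
identifiability flag rather than pretending otherwise.

The ITC model is the standard one-set-of-sites (Wiseman) treatment: after
each injection the cell contents are diluted by the displaced volume, the
complex concentration is recomputed from the same quadratic with n binding
sites per RNA, and the measured heat is dH times the newly formed complex in
the cell.  Derived quantities use dG = -R T ln K with R = 1.9872 cal/mol/K,
dS = (dH - dG)/T and Kd = 1/K.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

R_CAL = 1.9872  # gas constant, cal mol^-1 K^-1


class FitError(RuntimeError):
    def __init__(self, message: str, last_params=None, residual_norm=None):
        super().__init__(message)
        self.last_params = last_params
        self.residual_norm = residual_norm


@dataclass(frozen=True)
class FretTitration:
    p_total: np.ndarray  # protein concentration series, M
    efret: np.ndarray
    r_total: float  # RNA concentration, M

    def __post_init__(self):
        p = np.asarray(self.p_total, dtype=float)
        e = np.asarray(self.efret, dtype=float)
        if p.shape != e.shape or p.size < 3:
            raise ValueError("need matched P_T / E_FRET series of length >= 3")
        if np.any(p < 0) or np.any(np.diff(p) <= 0):
            raise ValueError("P_T must be non-negative and strictly increasing")
        if self.r_total <= 0:
            raise ValueError("R_T must be positive")
        object.__setattr__(self, "p_total", p)
        object.__setattr__(self, "efret", e)


@dataclass(frozen=True)
class FretFitParams:
    e0: float
    de: float  # full-range change in E_FRET
    k_assoc: float  # apparent association constant, M^-1
    e0_se: float = float("nan")
    de_se: float = float("nan")
    log10_k_se: float = float("nan")
    k_identifiable: bool = True
    residuals: np.ndarray = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        if self.k_assoc <= 0:
            raise ValueError("K_A must be positive")


def complex_concentration(p_total, r_total, k_assoc):
    """Smaller root of the two-state mass-balance quadratic, in a
    cancellation-free form valid up to the stoichiometric (K -> inf) limit."""
    p = np.asarray(p_total, dtype=float)
    if np.any(p < 0) or r_total < 0:
        raise ValueError("concentrations must be non-negative")
    if k_assoc <= 0:
        raise ValueError("K_A must be positive")
    b = p + r_total + 1.0 / k_assoc
    disc = np.sqrt(np.maximum(b * b - 4.0 * p * r_total, 0.0))
    return 2.0 * p * r_total / (b + disc)


def efret_model(p_total, params: FretFitParams, r_total: float):
    c = complex_concentration(p_total, r_total, params.k_assoc)
    return params.e0 + params.de * c / r_total


def _fret_curve(p, e0, de, log10_k, r_total):
    c = complex_concentration(p, r_total, 10.0 ** log10_k)
    return e0 + de * c / r_total


def fit_fret(data: FretTitration) -> FretFitParams:
    """Unweighted least-squares fit of (E0, dE, K_A); K_A is fitted on a log
    scale with E0, dE bounded to [-0.5, 1.5]."""
    p, e, rt = data.p_total, data.efret, data.r_total
    if p.size < 4:
        raise ValueError("need >= 4 points to fit 3 parameters")
    x0 = np.array([e[0], e[-1] - e[0], np.log10(2.0 / rt)])
    x0[1] = np.clip(x0[1], -0.49, 1.49)
    res = least_squares(
        lambda x: _fret_curve(p, x[0], x[1], x[2], rt) - e,
        x0,
        bounds=([-0.5, -0.5, 0.0], [1.5, 1.5, 16.0]),
        xtol=1e-14, ftol=1e-14, gtol=1e-14,
    )
    if not res.success:
        raise FitError("FRET fit did not converge", res.x, float(np.linalg.norm(res.fun)))
    se = _standard_errors(res.jac, res.fun)
    identifiable = bool(np.isfinite(se[2]) and se[2] < 1.0 and abs(res.x[1]) > 1e-6)
    return FretFitParams(
        e0=float(res.x[0]), de=float(res.x[1]), k_assoc=float(10.0 ** res.x[2]),
        e0_se=se[0], de_se=se[1], log10_k_se=se[2],
        k_identifiable=identifiable, residuals=res.fun,
    )


def _standard_errors(jac: np.ndarray, resid: np.ndarray) -> np.ndarray:
    n, k = jac.shape
    dof = max(n - k, 1)
    try:
        cov = np.linalg.inv(jac.T @ jac) * (resid @ resid) / dof
        return np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        return np.full(k, np.inf)


@dataclass(frozen=True)
class ITCExperiment:
    injection_volumes_l: np.ndarray
    heats_cal: np.ndarray  # integrated heat per injection
    cell_rna_m: float
    syringe_protein_m: float
    cell_volume_l: float
    temperature_k: float = 298.0

    def __post_init__(self):
        v = np.asarray(self.injection_volumes_l, dtype=float)
        h = np.asarray(self.heats_cal, dtype=float)
        if v.shape != h.shape:
            raise ValueError("injection volumes and heats must be matched")
        if np.any(v <= 0) or self.cell_volume_l <= 0 or self.temperature_k <= 0:
            raise ValueError("volumes and temperature must be positive")
        object.__setattr__(self, "injection_volumes_l", v)
        object.__setattr__(self, "heats_cal", h)


@dataclass(frozen=True)
class ITCFitResult:
    dh: float  # cal mol^-1
    k_assoc: float  # M^-1
    n_sites: float  # protein per RNA
    temperature_k: float

    @property
    def dg(self) -> float:
        return -R_CAL * self.temperature_k * np.log(self.k_assoc)

    @property
    def ds(self) -> float:
        return (self.dh - self.dg) / self.temperature_k

    @property
    def kd(self) -> float:
        return 1.0 / self.k_assoc


def itc_one_site_heats(exp: ITCExperiment, dh: float, k_assoc: float, n_sites: float) -> np.ndarray:
    """Predicted heat (cal) per injection under the one-set-of-sites model.

    Each injection of volume v displaces a fraction v/V0 of the well-mixed
    cell contents; the heat of injection i is dH * V0 * (complex formed in
    the cell during injection i), with the displaced complex credited to
    earlier injections.
    """
    if not np.isfinite([dh, k_assoc, n_sites]).all() or k_assoc <= 0:
        raise ValueError("parameters must be finite with K > 0")
    v0 = exp.cell_volume_l
    if float(np.sum(exp.injection_volumes_l)) > v0:
        raise ValueError("cumulative injected volume exceeds the cell volume")
    rna, prot, bound_prev = exp.cell_rna_m, 0.0, 0.0
    heats = np.empty(exp.injection_volumes_l.size)
    for i, v in enumerate(exp.injection_volumes_l):
        f = v / v0
        rna *= 1.0 - f
        prot = prot * (1.0 - f) + exp.syringe_protein_m * f
        bound = float(complex_concentration(prot, n_sites * rna, k_assoc))
        heats[i] = dh * v0 * (bound - bound_prev * (1.0 - f))
        bound_prev = bound
    return heats


def fit_itc(exp: ITCExperiment, drop_first: bool = True) -> ITCFitResult:
    """Least-squares fit of (dH, K, n); the first injection (the small priming
    shot) is excluded by default."""
    if exp.injection_volumes_l.size < 5:
        raise ValueError("need >= 5 injections")
    mask = np.ones(exp.injection_volumes_l.size, dtype=bool)
    if drop_first:
        mask[0] = False
    obs = exp.heats_cal
    total = float(np.sum(obs))
    dh0 = total / (exp.cell_rna_m * exp.cell_volume_l)
    if dh0 == 0:
        dh0 = -1000.0
    x0 = np.array([dh0, np.log10(10.0 / exp.cell_rna_m), 1.0])

    def resid(x):
        pred = itc_one_site_heats(exp, x[0], 10.0 ** x[1], x[2])
        return (pred - obs)[mask]

    res = least_squares(
        resid, x0,
        bounds=([-np.inf, 0.0, 0.05], [np.inf, 16.0, 20.0]),
        x_scale=[max(abs(dh0), 1.0), 1.0, 1.0],
        xtol=1e-15, ftol=1e-15, gtol=1e-15,
    )
    if not res.success:
        raise FitError("ITC fit did not converge", res.x, float(np.linalg.norm(res.fun)))
    return ITCFitResult(
        dh=float(res.x[0]), k_assoc=float(10.0 ** res.x[1]), n_sites=float(res.x[2]),
        temperature_k=exp.temperature_k,
    )
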