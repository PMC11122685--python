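"""Single-site binding thermodynamics: the Wiseman ITC model and its fit.

The titration of ligand X (syringe) into macromolecule M (cell) with a
single class of n independent sites is described, at total concentrations
M_t and X_t in the cell after injection i, by the fraction of occupied
sites Θ solving

    Θ² − Θ(1 + X_t/(n·M_t) + K_d/(n·M_t)) + X_t/(n·M_t) = 0

(the smaller root of the quadratic).  The cumulative heat content of the
cell is Q = n·Θ·M_t·ΔH·V₀, and the measured per-injection heat is the
change in Q corrected for the heat carried out by the displaced volume:

    ΔQ_i = Q_i − Q_{i−1} + (v_i/V₀)·(Q_i + Q_{i−1})/2.

Dilution follows the perfusion model with constant cell volume: each
injection of volume v expels the fraction v/V₀ of the (well-mixed) cell
contents, so M_t ← M_t(1 − v/V₀) and X_t ← X_t(1 − v/V₀) + X_syr·v/V₀.
Conventions differ slightly between analysis programs; this one is chosen
because it conserves the stoichiometric total heat in the tight-binding
limit.

ΔG° = R·T·ln(K_d / 1 M), standard state 1 M, reported in kcal/mol.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import lmfit

from .constants import R_KCAL

__all__ = [
    "BindingFit",
    "delta_g_from_kd",
    "affinity_fold_change",
    "wiseman_model",
    "fit_isotherm",
]


@dataclass
class BindingFit:
    n: float
    kd_M: float
    dh_kcal: float
    dg_kcal: float
    rss: float
    stderr: dict[str, float]
    c_value: float
    warnings: list[str]

    @property
    def ka_per_M(self) -> float:
        return 1.0 / self.kd_M


def delta_g_from_kd(kd_M: float, temperature_K: float) -> float:
    """Standard binding free energy ΔG° = R·T·ln(Kd/1M), kcal/mol.

    Negative for sub-molar Kd; e.g. a dissociation constant of 55 nM at
    310.15 K gives −10.3 kcal/mol.
    """
    if kd_M <= 0 or temperature_K <= 0:
        raise ValueError("Kd and temperature must be positive")
    return R_KCAL * temperature_K * np.log(kd_M)


def affinity_fold_change(
    kd_mutant_M: float, kd_wt_M: float, temperature_K: float = 310.15
) -> tuple[float, float]:
    """(fold change, ΔΔG) of a mutant's affinity loss relative to wild type.

    fold = Kd_mut / Kd_wt; ΔΔG = ΔG_mut − ΔG_wt = R·T·ln(fold), kcal/mol.
    """
    if kd_mutant_M <= 0 or kd_wt_M <= 0:
        raise ValueError("dissociation constants must be positive")
    fold = kd_mutant_M / kd_wt_M
    ddg = delta_g_from_kd(kd_mutant_M, temperature_K) - delta_g_from_kd(
        kd_wt_M, temperature_K
    )
    return fold, ddg


def _occupancy(x_t: float, m_t: float, n: float, kd: float) -> float:
    """Smaller root of the one-site quadratic in site occupancy Θ ∈ [0, 1]."""
    nm = n * m_t
    b = 1.0 + x_t / nm + kd / nm
    disc = b * b - 4.0 * x_t / nm
    if disc < 0:
        if disc > -1e-12 * b * b:
            disc = 0.0
        else:  # impossible for valid inputs
            raise ArithmeticError("negative discriminant in binding quadratic")
    return (b - np.sqrt(disc)) / 2.0


def wiseman_model(
    injection_volumes_uL: np.ndarray,
    cell_volume_uL: float,
    cell_concentration_M: float,
    syringe_concentration_M: float,
    n: float,
    kd_M: float,
    dh_kcal: float,
) -> np.ndarray:
    """Predicted per-injection heats (μcal) for a single-site titration."""
    v0 = float(cell_volume_uL)
    if v0 <= 0 or cell_concentration_M <= 0 or syringe_concentration_M <= 0:
        raise ValueError("cell volume and concentrations must be positive")
    if kd_M <= 0:
        raise ValueError("Kd must be positive")
    vols = np.asarray(injection_volumes_uL, float)
    m_t = cell_concentration_M
    x_t = 0.0
    # Q in μcal: concentrations M × volume μL × ΔH kcal/mol = 1e-6 L × kcal
    # per mol → μcal numerically with ΔH in kcal/mol and V in μL.
    q_prev = 0.0
    heats = np.empty(vols.shape[0])
    for i, v in enumerate(vols):
        f = v / v0
        m_t = m_t * (1.0 - f)
        x_t = x_t * (1.0 - f) + syringe_concentration_M * f
        theta = _occupancy(x_t, m_t, n, kd_M)
        q = n * theta * m_t * dh_kcal * v0 * 1e3  # μcal
        heats[i] = q - q_prev + f * (q + q_prev) / 2.0
        q_prev = q
    return heats


def fit_isotherm(
    isotherm,
    n0: float = 1.0,
    kd0_M: float | None = None,
    dh0_kcal: float | None = None,
    weight_first_injection: bool = False,
) -> BindingFit:
    """Nonlinear least-squares fit of the single-site model to an isotherm.

    The first injection (a small priming injection in the usual schedule)
    is down-weighted to zero unless ``weight_first_injection``.  Kd is
    fitted on a log scale; standard errors come from the Jacobian at the
    optimum.  A c-value n·M_t/K_d outside [1, 1000] is flagged as a
    warning on the returned fit, not an error.
    """
    heats = np.asarray(isotherm.heats_ucal, float)
    vols = np.asarray(isotherm.injection_volumes_uL, float)
    informative = heats.shape[0] - (0 if weight_first_injection else 1)
    if informative < 6:
        raise ValueError("at least 6 informative injections are required")
    fit_warnings: list[str] = []
    scale = np.abs(heats[1:]).max()
    if scale == 0:
        fit_warnings.append("all heats are zero: ΔH ≈ 0 and Kd is unidentifiable")
        dg = 0.0
        return BindingFit(n0, 1.0, 0.0, dg, 0.0,
                          {"n": np.nan, "kd_M": np.nan, "dh_kcal": np.nan},
                          np.nan, fit_warnings)
    if kd0_M is None:
        kd0_M = isotherm.cell_concentration_M / 10.0
    if dh0_kcal is None:
        # crude: total heat / total macromolecule, sign preserved
        total = heats[1:].sum()
        dh0_kcal = total / (isotherm.cell_concentration_M * isotherm.cell_volume_uL * 1e3)
        if dh0_kcal == 0:
            dh0_kcal = -1.0
    w = np.ones_like(heats)
    if not weight_first_injection:
        w[0] = 0.0

    params = lmfit.Parameters()
    params.add("n", value=n0, min=1e-3, max=100)
    params.add("log_kd", value=np.log(kd0_M), min=np.log(1e-15), max=np.log(10.0))
    params.add("dh", value=dh0_kcal)

    def residual(p):
        pred = wiseman_model(
            vols,
            isotherm.cell_volume_uL,
            isotherm.cell_concentration_M,
            isotherm.syringe_concentration_M,
            p["n"].value,
            np.exp(p["log_kd"].value),
            p["dh"].value,
        )
        return w * (pred - heats)

    result = lmfit.minimize(residual, params, method="leastsq")
    if not result.success:
        raise RuntimeError(f"isotherm fit did not converge: {result.message}")
    n = result.params["n"].value
    kd = float(np.exp(result.params["log_kd"].value))
    dh = result.params["dh"].value
    rss = float((np.asarray(result.residual) ** 2).sum())
    stderr = {"n": np.nan, "kd_M": np.nan, "dh_kcal": np.nan}
    if result.params["n"].stderr is not None:
        stderr["n"] = float(result.params["n"].stderr)
    if result.params["log_kd"].stderr is not None:
        stderr["kd_M"] = float(kd * result.params["log_kd"].stderr)  # delta method
    if result.params["dh"].stderr is not None:
        stderr["dh_kcal"] = float(result.params["dh"].stderr)
    c = n * isotherm.cell_concentration_M / kd
    if not 1.0 <= c <= 1000.0:
        fit_warnings.append(
            f"c-value {c:.3g} outside [1, 1000]: titration shape weakly "
            "constrains Kd"
        )
    dg = delta_g_from_kd(kd, isotherm.temperature_K)
    return BindingFit(float(n), kd, float(dh), float(dg), rss, stderr, float(c), fit_warnings)
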