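"""Charge and base-excess arithmetic for whole-blood acid-base accounting.

The model in one paragraph: the plasma strong ion difference (SID) of
whole blood is not pH-independent — as pH falls, the titrable (imidazole)
charge Z_pH on albumin and hemoglobin rises, driving chloride, calcium and
water between plasma and red cells. The SID change *expected* from this
redistribution alone can be predicted either from the change in Z_pH
(``expected_sid``) or from the noncarbonic whole-blood buffer value β
(``expected_sid_beta``). Only the deviation of measured SID from the
expected SID reflects a true metabolic acid load, i.e. a change of the
whole-blood SID and hence of base excess: ΔSID_wb = r·(SID − SID_exp(β)),
with r the plasma/red-cell distribution ratio of bicarbonate.

Base excess itself follows the Lang–Zander formulation
BE = r·[(HCO3 − 24.26) + β·(pH − 7.4)] − s, with s = 0.2·[Hb]·(1 − sO2).
A simplified variant replaces the subject's fitted β by the CLSI analyzer
convention β = 1.43·[Hb] + 7.7.
"""

from __future__ import annotations

import math

from .params import DEFAULT_PARAMS, BufferParams
from .types import BloodGas, ElectrolytePanel

__all__ = [
    "compute_sid",
    "titrable_charge",
    "albumin_zph",
    "rbc_ph",
    "hemoglobin_zph",
    "expected_sid",
    "expected_sid_beta",
    "expected_sid_clsi",
    "beta_clsi",
    "bicarbonate_ratio",
    "base_excess",
    "base_excess_clsi",
    "delta_sid_wb",
    "hh_bicarbonate",
    "g_dl_to_mmol",
]


def compute_sid(e: ElectrolytePanel) -> float:
    """Plasma strong ion difference, mEq/L.

    SID = [Na+] + [K+] + [Ca2+] + [Mg2+] − [Cl−] − [Lac−], every term in
    mEq/L. Ionized calcium arrives in mMol/L of the divalent ion and is
    doubled; magnesium is taken as already expressed in mEq/L (analyzers
    report it at baseline only and it is held constant).
    """
    return e.na + e.k + 2.0 * e.ca_ionized + e.mg - e.cl - e.lac


def titrable_charge(c: float, n: float, ph: float, pk: float = 6.75) -> float:
    """Titrable imidazole charge Z_pH of a protein, mEq/L.

    Z_pH = c·n·10^(−pH) / (10^(−pK) + 10^(−pH)) for a protein at
    concentration ``c`` (mMol/L) carrying ``n`` titrable groups with a
    common dissociation constant ``pk``. Strictly decreasing in pH,
    bounded by (0, c·n), and equal to c·n/2 at pH = pK.
    """
    if not (math.isfinite(c) and math.isfinite(n) and math.isfinite(ph)
            and math.isfinite(pk)):
        raise ValueError("titrable_charge requires finite inputs")
    if c < 0:
        raise ValueError("protein concentration must be non-negative")
    if n <= 0:
        raise ValueError("number of titrable groups must be positive")
    h = 10.0 ** (-ph)
    return c * n * h / (10.0 ** (-pk) + h)


def g_dl_to_mmol(conc_g_dl: float, mw_g_mol: float) -> float:
    """Convert a protein concentration from g/dL to mMol/L."""
    return conc_g_dl * 10.0 / mw_g_mol * 1000.0


def albumin_zph(albumin: float, plasma_ph: float,
                p: BufferParams = DEFAULT_PARAMS) -> float:
    """Albumin titrable charge at plasma pH, mEq/L (albumin in g/dL)."""
    c = g_dl_to_mmol(albumin, p.mw_albumin)
    return titrable_charge(c, p.n_albumin, plasma_ph, p.pk_imidazole)


def rbc_ph(plasma_ph: float, p: BufferParams = DEFAULT_PARAMS) -> float:
    """Red-cell pH corresponding to a plasma pH (linear map).

    Hemoglobin titrates at intracellular pH, which tracks plasma pH with
    slope < 1 (Funder–Wieth-type relation). The default map is a
    calibrated constant of the package, see :mod:`sidexp.params`.
    """
    return p.rbc_ph_slope * plasma_ph + p.rbc_ph_intercept


def hemoglobin_zph(hb: float, plasma_ph: float,
                   p: BufferParams = DEFAULT_PARAMS) -> float:
    """Hemoglobin titrable charge at red-cell pH, mEq/L (Hb in g/dL).

    Hemoglobin is parameterized per tetramer; a per-monomer
    parameterization with n/4 and MW/4 is numerically identical.
    """
    c = g_dl_to_mmol(hb, p.mw_hemoglobin)
    return titrable_charge(c, p.n_hemoglobin, rbc_ph(plasma_ph, p),
                           p.pk_imidazole)


def expected_sid(sid_baseline: float, dz_albumin: float,
                 dz_hemoglobin: float = 0.0) -> float:
    """Expected SID from titrable-charge changes: SID(baseline) + ΔZ_pH.

    ΔZ terms are the changes from the baseline step. Whole blood uses
    albumin + hemoglobin; isolated-plasma callers pass dz_hemoglobin = 0.
    """
    return sid_baseline + dz_albumin + dz_hemoglobin


def expected_sid_beta(sid_baseline: float, ph_baseline: float, ph: float,
                      beta: float) -> float:
    """Expected SID from the buffer value: SID(baseline) − β·(pH − pH(baseline))."""
    if beta <= 0:
        raise ValueError("beta must be positive")
    return sid_baseline - beta * (ph - ph_baseline)


def beta_clsi(hb: float, p: BufferParams = DEFAULT_PARAMS) -> float:
    """CLSI whole-blood noncarbonic buffer value: 1.43·[Hb] + 7.7 (Hb in g/dL)."""
    if hb < 0:
        raise ValueError("hemoglobin must be non-negative")
    return p.clsi_slope * hb + p.clsi_intercept


def expected_sid_clsi(sid_baseline: float, ph_baseline: float, ph: float,
                      hb: float, p: BufferParams = DEFAULT_PARAMS) -> float:
    """Expected SID with the CLSI buffer value in place of the fitted β."""
    return expected_sid_beta(sid_baseline, ph_baseline, ph, beta_clsi(hb, p))


def bicarbonate_ratio(hb: float, p: BufferParams = DEFAULT_PARAMS) -> float:
    """Plasma/red-cell distribution ratio of bicarbonate: r = 1 − 0.0143·[Hb]."""
    if not 0 <= hb <= 25:
        raise ValueError(f"hemoglobin {hb} g/dL outside [0, 25]")
    r = 1.0 - p.r_coeff * hb
    if r <= 0:
        raise ValueError("hemoglobin too high: distribution ratio r <= 0")
    return r


def base_excess(gas: BloodGas, beta: float, hb: float,
                p: BufferParams = DEFAULT_PARAMS) -> float:
    """Whole-blood base excess, Lang–Zander formulation, mEq/L.

    BE = r·[(HCO3− − 24.26) + β·(pH − 7.4)] − s with
    r = 1 − 0.0143·[Hb] and s = 0.2·[Hb]·(1 − sO2). Exactly zero at the
    reference state (HCO3 24.26, pH 7.40, sO2 1) for any β and Hb.
    """
    if beta <= 0:
        raise ValueError("beta must be positive")
    r = bicarbonate_ratio(hb, p)
    s = p.s_coeff * hb * (1.0 - gas.so2)
    return r * ((gas.hco3 - p.hco3_ref) + beta * (gas.ph - p.ph_ref)) - s


def base_excess_clsi(gas: BloodGas, hb: float,
                     p: BufferParams = DEFAULT_PARAMS) -> float:
    """Base excess with the CLSI buffer value and no saturation term."""
    r = bicarbonate_ratio(hb, p)
    return r * ((gas.hco3 - p.hco3_ref) + beta_clsi(hb, p) * (gas.ph - p.ph_ref))


def delta_sid_wb(sid: float, sid_expected: float, r: float) -> float:
    """Change in whole-blood SID: ΔSID_wb = r·(SID − SID_exp).

    ``sid_expected`` is the β-based (or CLSI) expectation; ``r`` the
    bicarbonate distribution ratio. Equals the true metabolic acid load
    with opposite sign when the model holds.
    """
    if not 0 < r <= 1:
        raise ValueError("r must be in (0, 1]")
    return r * (sid - sid_expected)


def hh_bicarbonate(ph: float, pco2: float,
                   p: BufferParams = DEFAULT_PARAMS) -> float:
    """Plasma bicarbonate from Henderson–Hasselbalch, mEq/L.

    HCO3− = S·PCO2·10^(pH − pK'). Used by the simulator and consistency
    checks; analyzers report HCO3− directly.
    """
    if pco2 <= 0:
        raise ValueError("PCO2 must be positive")
    return p.hh_solubility * pco2 * 10.0 ** (ph - p.hh_pk)
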