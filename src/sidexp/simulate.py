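"""Forward simulator of whole-blood CO2 tonometry.

Generates synthetic tonometry datasets with the statistical structure the
analysis pipeline assumes: per-subject protein panels drawn from group
distributions, a noncarbonic buffer value β, a strong-acid load that
lowers base excess one-for-one, per-step pH solved so that the
Lang–Zander base excess and Henderson–Hasselbalch relations hold
simultaneously, plasma SID placed on the β-expectation line offset by the
acid load, electrolytes redistributed to hit that SID exactly, and
analyzer-grade Gaussian measurement noise on every reported analyte.

The truth model is, deliberately, the same charge/base-excess model the
analysis inverts — the simulator is a consistency engine for testing the
pipeline end to end, not an independent physical model of the red cell.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, field_validator
from scipy.optimize import brentq

from . import core
from .params import DEFAULT_PARAMS, BufferParams
from .types import (
    AcidKind,
    BloodGas,
    ElectrolytePanel,
    Group,
    ProteinPanel,
    SampleKind,
    TonometrySeries,
    TonometryStep,
)

#: mmHg of dry barometric pressure available to CO2 at 37 °C (760 − 47)
PB_MINUS_PH2O = 713.0

#: empirical equilibrator characteristic: gas CO2 fraction -> blood PCO2.
#: Tonometers do not equilibrate blood fully to the nominal fraction
#: (blood arrives with its own CO2 stores); these anchors are the mean
#: equilibration pressures observed at the nominal fractions.
_PCO2_ANCHORS = ((0.02, 18.2), (0.05, 32.1), (0.12, 68.3), (0.20, 124.4))


def equilibrated_pco2(fco2: float) -> float:
    """Blood PCO2 (mmHg) after tonometry at gas fraction ``fco2``.

    Piecewise-linear through the empirical anchors, continued with the
    ideal slope (760 − 47 mmHg per unit fraction) outside them.
    """
    xs = np.array([a[0] for a in _PCO2_ANCHORS])
    ys = np.array([a[1] for a in _PCO2_ANCHORS])
    if fco2 < xs[0]:
        return float(ys[0] - PB_MINUS_PH2O * (xs[0] - fco2))
    if fco2 > xs[-1]:
        return float(ys[-1] + PB_MINUS_PH2O * (fco2 - xs[-1]))
    return float(np.interp(fco2, xs, ys))


class NoSolutionError(ValueError):
    """The pH solver found no root in the physiologic bracket."""


# --------------------------------------------------------------------------
# group-level statistics (mean, SD) behind subject sampling
#
# Albumin/hemoglobin are the published group distributions; baseline SID
# and the electrolyte template come from each group's baseline tonometry
# column; baseline pH is N(7.40, 0.03) for every group (the baseline step
# is defined as the one closest to pH 7.4 / PCO2 40).

@dataclass(frozen=True)
class GroupStats:
    albumin: tuple[float, float]     # g/dL
    hemoglobin: tuple[float, float]  # g/dL
    sid_baseline: tuple[float, float]  # mEq/L
    ph_baseline: tuple[float, float]
    panel: ElectrolytePanel          # baseline electrolyte template


GROUP_STATS: dict[Group, GroupStats] = {
    Group.healthy: GroupStats(
        (4.8, 0.2), (14.2, 0.9), (36.6, 2.2), (7.40, 0.03),
        ElectrolytePanel(138.9, 4.25, 1.17, 2.11, 109.0, 1.7)),
    Group.septic: GroupStats(
        (3.1, 0.5), (10.4, 0.8), (33.4, 4.8), (7.40, 0.03),
        ElectrolytePanel(138.9, 4.32, 1.10, 2.05, 110.0, 3.6)),
    Group.diluted: GroupStats(
        (5.0, 0.2), (7.0, 0.9), (44.1, 1.9), (7.40, 0.03),
        ElectrolytePanel(141.6, 3.98, 1.28, 2.07, 104.0, 1.4)),
    Group.undiluted: GroupStats(
        (5.0, 0.3), (14.1, 1.7), (43.3, 2.3), (7.40, 0.03),
        ElectrolytePanel(142.0, 4.12, 1.28, 2.06, 105.0, 1.7)),
    Group.experiment3: GroupStats(
        (5.0, 0.2), (13.9, 1.3), (42.9, 2.5), (7.40, 0.03),
        ElectrolytePanel(142.9, 4.0, 1.1, 2.0, 106.4, 1.6)),
}


class NoiseModel(BaseModel):
    """Per-analyte Gaussian measurement SDs (analyzer-grade defaults)."""

    model_config = ConfigDict(frozen=True, extra="forbid")

    ph: float = Field(default=0.005, ge=0)
    pco2: float = Field(default=1.0, ge=0)     # mmHg
    hco3: float = Field(default=0.3, ge=0)     # mEq/L
    na: float = Field(default=0.5, ge=0)
    cl: float = Field(default=0.5, ge=0)
    k: float = Field(default=0.05, ge=0)
    ca: float = Field(default=0.01, ge=0)      # mMol/L
    lac: float = Field(default=0.1, ge=0)

    @classmethod
    def silent(cls) -> "NoiseModel":
        """A noise-free model, for round-trip and invariant tests."""
        return cls(ph=0, pco2=0, hco3=0, na=0, cl=0, k=0, ca=0, lac=0)


#: default allocation of a required SID change over analytes
#: (chloride shift dominates; fractions of the SID change, summing to 1
#: in absolute charge: |−0.55| + 0.40 + 0.04 + 0.01)
DEFAULT_SPLIT: dict[str, float] = {"cl": -0.55, "na": 0.40, "ca": 0.04,
                                   "k": 0.01}


class SimulationScenario(BaseModel):
    """Everything that determines one simulated dataset.

    ``acid_loads`` lists the sample conditions per subject, mirroring the
    acid-loading protocol (a control plus hydrochloric/lactic loads);
    ``fco2_levels`` the equilibration gas fractions. The seed fully
    determines the output.
    """

    model_config = ConfigDict(frozen=True, extra="forbid")

    group: Group = Group.healthy
    n_subjects: int = Field(default=10, ge=1)
    fco2_levels: tuple[float, ...] = (0.02, 0.05, 0.12, 0.20)
    acid_loads: tuple[tuple[AcidKind, float], ...] = ((AcidKind.none, 0.0),)
    noise: NoiseModel = NoiseModel()
    seed: int = 0
    params: BufferParams = DEFAULT_PARAMS
    beta_source: Literal["clsi", "zph"] = "clsi"
    split: dict[str, float] = DEFAULT_SPLIT

    @field_validator("fco2_levels")
    @classmethod
    def _levels_in_range(cls, v: tuple[float, ...]) -> tuple[float, ...]:
        for f in v:
            if not 0.01 <= f <= 0.25:
                raise ValueError(f"fco2 level {f} outside [0.01, 0.25]")
        return v

    @field_validator("split")
    @classmethod
    def _split_sums_to_one(cls, v: dict[str, float]) -> dict[str, float]:
        total = v.get("na", 0) + v.get("k", 0) + v.get("ca", 0) - v.get("cl", 0)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(
                f"allocation fractions must sum to 1 in SID charge, got {total}")
        return v


@dataclass
class GroundTruth:
    """Simulator-side truth, stored alongside the generated data.

    ``subjects``: one row per subject (true β, baseline SID/pH/BE,
    proteins). ``steps``: one row per generated step with the pre-noise
    pH, HCO3−, PCO2, SID and BE.
    """

    seed: int
    subjects: pd.DataFrame
    steps: pd.DataFrame

    def to_json_dict(self) -> dict:
        return {"seed": self.seed,
                "subjects": self.subjects.to_dict(orient="records"),
                "steps": self.steps.to_dict(orient="records")}


# --------------------------------------------------------------------------
# pieces

def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      k: float = 3.0) -> float:
    """Gaussian draw rejected outside mean ± k·SD."""
    if sd == 0:
        return mean
    while True:
        x = rng.normal(mean, sd)
        if abs(x - mean) <= k * sd:
            return float(x)


def sample_subject(group: Group, rng: np.random.Generator,
                   stats: Optional[dict[Group, GroupStats]] = None,
                   ) -> tuple[ProteinPanel, float, float, ElectrolytePanel]:
    """Draw one subject: proteins, baseline SID, baseline pH, panel template.

    Gaussian draws at the group's published means ± SD, truncated at
    ±3 SD (and clipped to the containers' validity ranges). ``stats``
    overrides the packaged group distributions.
    """
    st = (stats or GROUP_STATS)[group]
    alb = min(max(_truncated_normal(rng, *st.albumin), 0.5), 8.0)
    hb = min(max(_truncated_normal(rng, *st.hemoglobin), 0.0), 25.0)
    sid = _truncated_normal(rng, *st.sid_baseline)
    ph = _truncated_normal(rng, *st.ph_baseline)
    return ProteinPanel(albumin=alb, hemoglobin=hb), sid, ph, st.panel


def solve_ph(pco2: float, be_target: float, beta: float, hb: float,
             p: BufferParams = DEFAULT_PARAMS, so2: float = 1.0,
             bracket: tuple[float, float] = (6.5, 7.9)) -> float:
    """pH at which base excess equals ``be_target`` for a given PCO2.

    Solves BE(pH, HCO3(pH, PCO2)) = be_target by bisection (Brent). The
    residual is strictly increasing in pH (both HCO3− and the β·ΔpH term
    rise), so the root is unique when bracketed.
    """
    if not 10.0 <= pco2 <= 200.0:
        raise ValueError(f"pco2 {pco2} outside [10, 200] mmHg")

    def residual(ph: float) -> float:
        hco3 = core.hh_bicarbonate(ph, pco2, p)
        r = core.bicarbonate_ratio(hb, p)
        s = p.s_coeff * hb * (1.0 - so2)
        return r * ((hco3 - p.hco3_ref) + beta * (ph - p.ph_ref)) - s - be_target

    lo, hi = bracket
    if residual(lo) * residual(hi) > 0:
        raise NoSolutionError(
            f"no pH in [{lo}, {hi}] gives BE={be_target} at PCO2={pco2}")
    return float(brentq(residual, lo, hi, xtol=1e-12, rtol=8.9e-16))


def redistribute_electrolytes(sid_target: float, baseline: ElectrolytePanel,
                              acid: tuple[AcidKind, float] = (AcidKind.none, 0.0),
                              rng: Optional[np.random.Generator] = None,
                              split: dict[str, float] = DEFAULT_SPLIT,
                              ) -> ElectrolytePanel:
    """Move strong ions so that the panel's SID equals ``sid_target`` exactly.

    The added acid anion first enters plasma in full (hydrochloric →
    chloride, lactic → lactate); the remaining SID change is then
    allocated over analytes with the configured fractions (defaults:
    Cl −0.55, Na +0.40, Ca +0.04, K +0.01 of the required change),
    emulating the chloride/water shift into red cells. Exact by
    construction before measurement noise. ``rng`` is accepted for
    interface symmetry; the redistribution itself is deterministic.
    """
    if not math.isfinite(sid_target):
        raise ValueError("sid_target must be finite")
    total = (split.get("na", 0) + split.get("k", 0) + split.get("ca", 0)
             - split.get("cl", 0))
    if abs(total - 1.0) > 1e-9:
        raise ValueError("allocation fractions must sum to 1 in SID charge")

    kind, load = acid
    na, k, ca, mg, cl, lac = (baseline.na, baseline.k, baseline.ca_ionized,
                              baseline.mg, baseline.cl, baseline.lac)
    if kind is AcidKind.hcl:
        cl += load
    elif kind is AcidKind.lactic:
        lac += load
    elif load != 0:
        raise ValueError("nonzero acid load requires hcl or lactic")

    current = na + k + 2.0 * ca + mg - cl - lac
    delta = sid_target - current
    na += split.get("na", 0.0) * delta
    k += split.get("k", 0.0) * delta
    ca += split.get("ca", 0.0) * delta / 2.0  # divalent: mMol/L carries 2 mEq
    cl += split.get("cl", 0.0) * delta
    if min(na, k, ca, cl, lac) < 0:
        raise ValueError("redistribution drove a concentration negative")
    return ElectrolytePanel(na=na, k=k, ca_ionized=ca, mg=mg, cl=cl, lac=lac)


def _beta_from_zph(proteins: ProteinPanel, ph: float, p: BufferParams,
                   h: float = 0.01) -> float:
    """β implied by the titrable-charge model: −d(Z_alb + Z_hb)/dpH at ph."""
    def z(x: float) -> float:
        return (core.albumin_zph(proteins.albumin, x, p)
                + core.hemoglobin_zph(proteins.hemoglobin, x, p))
    return -(z(ph + h) - z(ph - h)) / (2.0 * h)


# --------------------------------------------------------------------------
# main entry point

def simulate_series(scenario: SimulationScenario,
                    ) -> tuple[list[TonometrySeries], GroundTruth]:
    """Generate a tonometry dataset plus its ground truth.

    Per subject: draw proteins and the baseline (SID, pH) anchor; fix the
    true β (CLSI or titrable-charge slope per ``beta_source``); each acid
    load lowers the true base excess one-for-one. Per CO2 level: solve pH
    from (PCO2, BE_true, β), take HCO3− from Henderson–Hasselbalch, place
    the true plasma SID on SID_exp(β) − load/r, redistribute electrolytes
    to hit it exactly, then add measurement noise.
    """
    p = scenario.params
    rng = np.random.default_rng(scenario.seed)
    noise = scenario.noise

    series_out: list[TonometrySeries] = []
    subj_rows, step_rows = [], []

    for i in range(scenario.n_subjects):
        sid_label = f"S{i + 1:03d}"
        proteins, sid_ref, ph_ref, template = sample_subject(scenario.group, rng)
        hb = proteins.hemoglobin
        r = core.bicarbonate_ratio(hb, p)
        if scenario.beta_source == "clsi":
            beta = core.beta_clsi(hb, p)
        else:
            beta = _beta_from_zph(proteins, ph_ref, p)
        panel_ref = redistribute_electrolytes(sid_ref, template,
                                              split=scenario.split)
        hco3_ref = core.hh_bicarbonate(ph_ref, 40.0, p)
        be_base = core.base_excess(BloodGas(ph_ref, 40.0, hco3_ref), beta, hb, p)
        subj_rows.append({
            "subject_id": sid_label, "albumin": proteins.albumin,
            "hemoglobin": hb, "beta_true": beta, "sid_baseline": sid_ref,
            "ph_baseline": ph_ref, "be_baseline": be_base})

        for kind, load in scenario.acid_loads:
            be_true = be_base - load
            steps = []
            for fco2 in sorted(scenario.fco2_levels):
                pco2 = equilibrated_pco2(fco2)
                ph = solve_ph(pco2, be_true, beta, hb, p)
                hco3 = core.hh_bicarbonate(ph, pco2, p)
                sid_true = sid_ref - beta * (ph - ph_ref) - load / r
                panel = redistribute_electrolytes(
                    sid_true, panel_ref, (kind, load), split=scenario.split)
                step_rows.append({
                    "subject_id": sid_label, "acid_kind": kind.value,
                    "acid_load": load, "fco2": fco2, "pco2": pco2,
                    "ph_true": ph, "hco3_true": hco3, "sid_true": sid_true,
                    "be_true": be_true})
                gas = BloodGas(
                    ph=ph + rng.normal(0, noise.ph) if noise.ph else ph,
                    pco2=pco2 + rng.normal(0, noise.pco2) if noise.pco2 else pco2,
                    hco3=hco3 + rng.normal(0, noise.hco3) if noise.hco3 else hco3,
                    so2=1.0)
                noisy = ElectrolytePanel(
                    na=max(panel.na + rng.normal(0, noise.na), 0.0),
                    k=max(panel.k + rng.normal(0, noise.k), 0.0),
                    ca_ionized=max(panel.ca_ionized + rng.normal(0, noise.ca), 0.0),
                    mg=panel.mg,
                    cl=max(panel.cl + rng.normal(0, noise.cl), 0.0),
                    lac=max(panel.lac + rng.normal(0, noise.lac), 0.0))
                steps.append(TonometryStep(
                    fco2=fco2, gas=gas, electrolytes=noisy,
                    sample_kind=SampleKind.whole_blood,
                    acid_load=load, acid_kind=kind))
            series_out.append(TonometrySeries(
                subject_id=sid_label, group=scenario.group,
                proteins=proteins, steps=tuple(steps)))

    truth = GroundTruth(seed=scenario.seed,
                        subjects=pd.DataFrame(subj_rows),
                        steps=pd.DataFrame(step_rows))
    return series_out, truth
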