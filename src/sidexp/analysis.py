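"""Tonometry analysis pipeline.

Per-series work: fit the noncarbonic buffer value β from the HCO3−/pH
titration curve, select the baseline step, and derive the full set of
per-step quantities (SID, titrable charges, expected SIDs, base excess,
ΔSID_wb). Study-level work: Bland–Altman agreement between measurement
routes, group comparisons, and the Fencl–Stewart comparator.

Baseline conventions follow the tonometry protocols: the step equilibrated
at 5% CO2 (experiment 1), at 12% CO2 (experiment 2), or the control
sample's step with PCO2 closest to 40 mmHg (experiment 3). Baseline steps
are never included in agreement sets — measured and expected SID coincide
there by definition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import core
from .params import DEFAULT_PARAMS, BufferParams
from .types import (
    AgreementResult,
    DerivedStep,
    ElectrolytePanel,
    FenclPartition,
    SampleKind,
    TonometrySeries,
    TonometryStep,
)

Experiment = Literal["exp1", "exp2", "exp3"]
BetaMode = Literal["fitted", "clsi"]

#: clinical acceptability thresholds for Bland–Altman agreement (mEq/L)
BIAS_LIMIT = 1.0
MAX_DIFF_LIMIT = 3.0


class InsufficientDataError(ValueError):
    """Too few observations for the requested estimate."""


class MissingBaselineError(ValueError):
    """The protocol-required baseline step is absent from a series."""


class DegenerateVarianceError(ValueError):
    """A statistical comparison is undefined for zero-variance input."""


# --------------------------------------------------------------------------
# β estimation and baseline selection

def estimate_beta(series: TonometrySeries) -> float:
    """Noncarbonic whole-blood buffer value β = −d[HCO3−]/dpH, mEq/L per pH.

    Fitted as the negated ordinary-least-squares slope of HCO3− on pH
    across the series' equilibration steps: the titration curve is close
    to linear over the tonometry range and a single slope is robust to
    analyzer noise. Positive for physiologic blood.
    """
    ph = np.array([s.gas.ph for s in series.steps], dtype=float)
    hco3 = np.array([s.gas.hco3 for s in series.steps], dtype=float)
    if len(np.unique(ph)) < 2:
        raise InsufficientDataError(
            "beta estimation needs at least 2 steps with distinct pH")
    slope, _ = np.polyfit(ph, hco3, 1)
    return float(-slope)


def select_baseline(series: TonometrySeries,
                    experiment: Experiment) -> TonometryStep:
    """Return the protocol baseline step of a series.

    exp1: the 5% CO2 step; exp2: the 12% CO2 step; exp3: among steps with
    no added acid, the one with PCO2 closest to 40 mmHg. Ties broken by
    smallest |PCO2 − 40|, then lowest step index.
    """
    nominal = {"exp1": 0.05, "exp2": 0.12}
    if experiment in nominal:
        level = nominal[experiment]
        candidates = [s for s in series.steps if abs(s.fco2 - level) < 0.005]
        if not candidates:
            raise MissingBaselineError(
                f"{experiment} requires a step equilibrated at "
                f"{level:.0%} CO2; levels present: "
                f"{[s.fco2 for s in series.steps]}")
    elif experiment == "exp3":
        candidates = [s for s in series.steps if s.acid_load == 0.0]
        if not candidates:
            raise MissingBaselineError(
                "exp3 baseline must come from a control (no added acid) series")
    else:
        raise ValueError(f"unknown experiment {experiment!r}")
    return min(candidates, key=lambda s: (abs(s.gas.pco2 - 40.0),
                                          series.steps.index(s)))


# --------------------------------------------------------------------------
# per-step derivation

def _series_beta(series: TonometrySeries, p: BufferParams,
                 beta_mode: BetaMode) -> float:
    if beta_mode == "clsi":
        return core.beta_clsi(series.proteins.hemoglobin, p)
    if series.beta_known is not None:
        return series.beta_known
    return estimate_beta(series)


def derive_series(series: TonometrySeries,
                  p: BufferParams = DEFAULT_PARAMS,
                  beta_mode: BetaMode = "fitted",
                  experiment: Experiment = "exp1",
                  baseline_step: Optional[TonometryStep] = None,
                  baseline_beta: Optional[float] = None,
                  ) -> list[DerivedStep]:
    """Derive SID, expected SIDs, base excess and ΔSID_wb for every step.

    ``baseline_step`` may come from another series of the same subject
    (the control sample in experiment 3); by default it is selected from
    this series. ``baseline_beta`` is the buffer value used for the
    baseline base excess (the control sample's own β); it defaults to this
    series' β. Isolated-plasma series use the albumin-only expectation and
    skip the β-based route entirely.

    Returns one :class:`DerivedStep` per step, in fco2 order.
    """
    own_baseline = baseline_step is None
    if own_baseline:
        baseline_step = select_baseline(series, experiment)

    alb = series.proteins.albumin
    hb = series.proteins.hemoglobin
    plasma = series.sample_kind is SampleKind.isolated_plasma

    ph_b = baseline_step.gas.ph
    sid_b = core.compute_sid(baseline_step.electrolytes)
    z_alb_b = core.albumin_zph(alb, ph_b, p)
    z_hb_b = 0.0 if plasma else core.hemoglobin_zph(hb, ph_b, p)

    if plasma:
        beta = baseline_beta = None
        be_b = be_clsi_b = None
    else:
        beta = _series_beta(series, p, beta_mode)
        if baseline_beta is None:
            baseline_beta = beta
        r = core.bicarbonate_ratio(hb, p)
        be_b = core.base_excess(baseline_step.gas, baseline_beta, hb, p)
        be_clsi_b = core.base_excess_clsi(baseline_step.gas, hb, p)

    out: list[DerivedStep] = []
    for step in series.steps:
        ph = step.gas.ph
        sid = core.compute_sid(step.electrolytes)
        z_alb = core.albumin_zph(alb, ph, p)
        z_hb = 0.0 if plasma else core.hemoglobin_zph(hb, ph, p)
        sid_exp = core.expected_sid(sid_b, z_alb - z_alb_b, z_hb - z_hb_b)
        sid_exp_clsi = core.expected_sid_clsi(sid_b, ph_b, ph, hb, p)
        is_baseline = own_baseline and step is baseline_step

        if plasma:
            out.append(DerivedStep(
                sid=sid, z_albumin=z_alb, z_hemoglobin=0.0,
                sid_exp=sid_exp, sid_exp_beta=None,
                sid_exp_clsi=sid_exp_clsi, be=None, be_clsi=None,
                delta_sid_wb=None, delta_sid_wb_clsi=None,
                delta_sid=sid - sid_b, delta_be=None, delta_be_clsi=None,
                is_baseline=is_baseline))
            continue

        sid_exp_beta = core.expected_sid_beta(sid_b, ph_b, ph, beta)
        be = core.base_excess(step.gas, beta, hb, p)
        be_clsi = core.base_excess_clsi(step.gas, hb, p)
        out.append(DerivedStep(
            sid=sid, z_albumin=z_alb, z_hemoglobin=z_hb,
            sid_exp=sid_exp, sid_exp_beta=sid_exp_beta,
            sid_exp_clsi=sid_exp_clsi, be=be, be_clsi=be_clsi,
            delta_sid_wb=core.delta_sid_wb(sid, sid_exp_beta, r),
            delta_sid_wb_clsi=core.delta_sid_wb(sid, sid_exp_clsi, r),
            delta_sid=sid - sid_b, delta_be=be - be_b,
            delta_be_clsi=be_clsi - be_clsi_b,
            is_baseline=is_baseline))
    return out


# --------------------------------------------------------------------------
# statistics

def bland_altman(pairs: Sequence[tuple[float, float]]) -> AgreementResult:
    """Bland–Altman agreement for paired values; differences are a − b.

    bias = mean difference, limits of agreement = bias ± 1.96·SD with the
    n−1 sample SD. The result is flagged acceptable when |bias| ≤ 1 mEq/L
    and the largest absolute difference is < 3 mEq/L.
    """
    if len(pairs) < 2:
        raise InsufficientDataError("Bland–Altman needs at least 2 pairs")
    a, b = np.asarray(pairs, dtype=float).T
    d = a - b
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    max_abs = float(np.max(np.abs(d)))
    return AgreementResult(
        bias=bias, sd_diff=sd,
        loa_low=bias - 1.96 * sd, loa_high=bias + 1.96 * sd,
        n_pairs=len(d), max_abs_diff=max_abs,
        acceptable=abs(bias) <= BIAS_LIMIT and max_abs < MAX_DIFF_LIMIT)


def compare_groups(values_a: Sequence[float],
                   values_b: Sequence[float]) -> tuple[float, float]:
    """Two-sample Student's t test; returns (t, two-tailed p)."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise InsufficientDataError("each group needs at least 2 values")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        if np.mean(a) == np.mean(b):
            return 0.0, 1.0
        raise DegenerateVarianceError(
            "zero variance in both groups with unequal means")
    t, pval = stats.ttest_ind(a, b, equal_var=True)
    return float(t), float(pval)


def pearson_corr(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Pearson's r between two variables; returns (r, two-tailed p)."""
    if len(x) < 2 or len(x) != len(y):
        raise InsufficientDataError("Pearson's r needs >= 2 equal-length vectors")
    res = stats.pearsonr(np.asarray(x, float), np.asarray(y, float))
    return float(res.statistic), float(res.pvalue)


# --------------------------------------------------------------------------
# Fencl–Stewart comparator

@dataclass(frozen=True)
class FenclVariant:
    """Constants of the bedside Fencl–Stewart partition (Story-type).

    sodium-chloride effect (Na − Cl) − ``nacl_ref``; albumin effect
    ``alb_coeff``·(``alb_ref_g_l`` − 10·albumin[g/dL]); lactate counted
    one-to-one when ``include_lactate``.
    """

    nacl_ref: float = 38.0
    alb_coeff: float = 0.25
    alb_ref_g_l: float = 42.0
    include_lactate: bool = True


def fencl_stewart_partition(e: ElectrolytePanel, albumin: float, be: float,
                            variant: FenclVariant = FenclVariant(),
                            ) -> FenclPartition:
    """Partition a base excess into bedside plasma components.

    The residual (``unmeasured_ions``) is whatever part of BE the
    sodium-chloride, albumin and lactate effects do not explain. The
    partition treats any SID deviation from a fixed reference as a
    one-to-one BE change, i.e. it ignores pH-driven electrolyte
    redistribution — which is exactly what comparison against ΔSID_wb
    exposes.
    """
    nacl = (e.na - e.cl) - variant.nacl_ref
    alb_eff = variant.alb_coeff * (variant.alb_ref_g_l - 10.0 * albumin)
    lac_eff = -e.lac if variant.include_lactate else 0.0
    return FenclPartition(
        sodium_chloride_effect=nacl,
        albumin_effect=alb_eff,
        lactate_effect=lac_eff,
        unmeasured_ions=be - (nacl + alb_eff + lac_eff))


# --------------------------------------------------------------------------
# experiment orchestration

@dataclass
class ExperimentReport:
    """Full output of one experiment's analysis.

    ``derived`` holds one row per (series, step) with measured and derived
    quantities; ``agreements`` the Bland–Altman results keyed by
    comparison name (pairs are (comparator, reference) and bias is
    comparator − reference); ``group_stats`` the between-group t tests and
    correlations; ``betas`` the per-series buffer values.
    """

    experiment: Experiment
    beta_mode: BetaMode
    derived: pd.DataFrame
    agreements: dict[str, AgreementResult] = field(default_factory=dict)
    group_stats: dict[str, object] = field(default_factory=dict)
    betas: dict[tuple[str, str, float], float] = field(default_factory=dict)

    def summary_dict(self) -> dict:
        """JSON-serializable summary (agreements + group statistics)."""
        return {
            "experiment": self.experiment,
            "beta_mode": self.beta_mode,
            "n_series": int(self.derived[["subject_id", "acid_kind",
                                          "acid_load"]].drop_duplicates().shape[0]),
            "agreements": {k: vars(v) for k, v in self.agreements.items()},
            "group_stats": self.group_stats,
            "betas": {"|".join([s, a, str(l)]): b
                      for (s, a, l), b in self.betas.items()},
        }


def _derived_frame(series: TonometrySeries, derived: list[DerivedStep],
                   beta: Optional[float]) -> pd.DataFrame:
    rows = []
    for step, d in zip(series.steps, derived):
        rows.append({
            "subject_id": series.subject_id, "group": series.group.value,
            "sample_kind": series.sample_kind.value,
            "acid_kind": series.acid_kind.value,
            "acid_load": series.acid_load, "beta": beta,
            "fco2": step.fco2, "pco2": step.gas.pco2, "ph": step.gas.ph,
            "hco3": step.gas.hco3, **vars(d)})
    return pd.DataFrame(rows)


def run_experiment(dataset: Iterable[TonometrySeries],
                   experiment: Experiment,
                   p: BufferParams = DEFAULT_PARAMS,
                   beta_mode: BetaMode = "fitted") -> ExperimentReport:
    """Analyze a full dataset the way the tonometry studies were analyzed.

    For experiments 1/2 every series carries its own baseline; for
    experiment 3 each subject's control series provides the baseline step
    (and the baseline base excess, via the control's own β) for that
    subject's acid-loaded series.

    Agreement sets (baseline steps always excluded):

    * ``sid_vs_sid_exp`` / ``sid_vs_sid_exp_clsi`` — measured vs expected
      plasma SID over control/respiratory steps;
    * exp3 adds ``sid_vs_sid_exp_beta`` (control series) and, for acid
      series, ΔSID and ΔSID_wb against ΔBE at the near-40-mmHg step
      (``*_metabolic``) and across all CO2 levels (``*_mixed``), plus the
      CLSI analogues.
    """
    dataset = list(dataset)
    if not dataset:
        raise InsufficientDataError("empty dataset")

    frames: list[pd.DataFrame] = []
    betas: dict[tuple[str, str, float], float] = {}

    by_subject: dict[str, list[TonometrySeries]] = {}
    for s in dataset:
        by_subject.setdefault(s.subject_id, []).append(s)

    for subject, series_list in by_subject.items():
        baseline_step = baseline_beta = None
        if experiment == "exp3":
            controls = [s for s in series_list if s.is_control]
            if not controls:
                raise MissingBaselineError(
                    f"subject {subject!r} has no control series for exp3")
            ctrl = controls[0]
            baseline_step = select_baseline(ctrl, "exp3")
            if ctrl.sample_kind is SampleKind.whole_blood:
                baseline_beta = _series_beta(ctrl, p, beta_mode)
        for series in series_list:
            own = experiment != "exp3"
            derived = derive_series(
                series, p, beta_mode=beta_mode, experiment=experiment,
                baseline_step=None if own else baseline_step,
                baseline_beta=None if own else baseline_beta)
            beta = (None if series.sample_kind is SampleKind.isolated_plasma
                    else _series_beta(series, p, beta_mode))
            if beta is not None:
                betas[(series.subject_id, series.acid_kind.value,
                       series.acid_load)] = beta
            df = _derived_frame(series, derived, beta)
            if experiment == "exp3" and series.is_control:
                # mark the subject-level baseline row in the control series
                idx = list(series.steps).index(baseline_step)
                df.loc[df.index[idx], "is_baseline"] = True
            frames.append(df)

    derived_df = pd.concat(frames, ignore_index=True)

    agreements: dict[str, AgreementResult] = {}
    nb = derived_df[~derived_df["is_baseline"]]
    resp = nb[nb["acid_load"] == 0.0]

    def _agree(key: str, sub: pd.DataFrame, col_a: str, col_b: str) -> None:
        sub = sub.dropna(subset=[col_a, col_b])
        if len(sub) >= 2:
            agreements[key] = bland_altman(list(zip(sub[col_a], sub[col_b])))

    _agree("sid_vs_sid_exp", resp, "sid", "sid_exp")
    _agree("sid_vs_sid_exp_clsi", resp, "sid", "sid_exp_clsi")

    if experiment == "exp3":
        _agree("sid_vs_sid_exp_beta", resp, "sid", "sid_exp_beta")
        acid = nb[nb["acid_load"] > 0.0]
        # metabolic acidosis: acid series at the CO2 level nearest baseline
        metabolic = (acid.assign(_d=(acid["pco2"] - 40.0).abs())
                     .sort_values("_d")
                     .groupby(["subject_id", "acid_kind", "acid_load"],
                              as_index=False).head(1))
        for tag, sub in (("metabolic", metabolic), ("mixed", acid)):
            _agree(f"dsid_vs_dbe_{tag}", sub, "delta_sid", "delta_be")
            _agree(f"dsidwb_vs_dbe_{tag}", sub, "delta_sid_wb", "delta_be")
            _agree(f"dsid_vs_dbeclsi_{tag}", sub, "delta_sid", "delta_be_clsi")
            _agree(f"dsidwbclsi_vs_dbeclsi_{tag}", sub,
                   "delta_sid_wb_clsi", "delta_be_clsi")

    group_stats: dict[str, object] = {}
    groups = sorted(derived_df["group"].unique())
    rises = {}
    for g in groups:
        gdf = derived_df[(derived_df["group"] == g)
                         & (derived_df["acid_load"] == 0.0)]
        per_subject = []
        for _, sdf in gdf.groupby("subject_id"):
            sdf = sdf.sort_values("fco2")
            if len(sdf) >= 2:
                per_subject.append(float(sdf["sid"].iloc[-1] - sdf["sid"].iloc[0]))
        if per_subject:
            rises[g] = per_subject
            group_stats[f"sid_rise_{g}"] = {
                "mean": float(np.mean(per_subject)),
                "sd": float(np.std(per_subject, ddof=1)) if len(per_subject) > 1
                      else math.nan,
                "n": len(per_subject)}
    if len(rises) == 2:
        (ga, va), (gb, vb) = rises.items()
        try:
            t, pval = compare_groups(va, vb)
            group_stats[f"sid_rise_t_{ga}_vs_{gb}"] = {"t": t, "p": pval}
        except InsufficientDataError:
            pass
    pairs = resp.dropna(subset=["sid", "sid_exp"])
    if len(pairs) >= 2:
        r, pval = pearson_corr(pairs["sid"], pairs["sid_exp"])
        group_stats["pearson_sid_vs_sid_exp"] = {"r": r, "p": pval}

    return ExperimentReport(experiment=experiment, beta_mode=beta_mode,
                            derived=derived_df, agreements=agreements,
                            group_stats=group_stats, betas=betas)
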