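"""Domain containers for tonometry records.

Light, frozen dataclasses. Physiologic-range checks emit warnings rather
than raising: tonometry deliberately drives blood far from normal, and a
hard error on an unusual electrolyte would make the analyzers' own data
unreadable. Structural violations (negative concentrations, non-finite
numbers, pH outside the measurable window) do raise.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass, field, replace  # noqa: F401  (replace re-exported)
from typing import Optional, Sequence


class PhysiologicRangeWarning(UserWarning):
    """A measured value is outside the usual physiologic window."""


class SampleKind(str, enum.Enum):
    whole_blood = "whole_blood"
    isolated_plasma = "isolated_plasma"


class AcidKind(str, enum.Enum):
    none = "none"
    hcl = "hcl"
    lactic = "lactic"


class Group(str, enum.Enum):
    healthy = "healthy"
    septic = "septic"
    diluted = "diluted"
    undiluted = "undiluted"
    experiment3 = "experiment3"


def _require_finite(**values: float) -> None:
    for name, v in values.items():
        if not math.isfinite(v):
            raise ValueError(f"{name} must be finite, got {v!r}")


@dataclass(frozen=True)
class ElectrolytePanel:
    """Measured plasma strong ions for one equilibration step.

    All fields in mEq/L except ionized calcium, which analyzers report in
    mMol/L of the divalent ion (it contributes 2 mEq per mMol to SID).
    """

    na: float
    k: float
    ca_ionized: float  # mMol/L
    mg: float
    cl: float
    lac: float

    def __post_init__(self) -> None:
        _require_finite(na=self.na, k=self.k, ca_ionized=self.ca_ionized,
                        mg=self.mg, cl=self.cl, lac=self.lac)
        for name in ("na", "k", "ca_ionized", "mg", "cl", "lac"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.na and not 100 <= self.na <= 200:
            warnings.warn(f"sodium {self.na} mEq/L outside [100, 200]",
                          PhysiologicRangeWarning, stacklevel=2)
        if self.cl and not 70 <= self.cl <= 140:
            warnings.warn(f"chloride {self.cl} mEq/L outside [70, 140]",
                          PhysiologicRangeWarning, stacklevel=2)


@dataclass(frozen=True)
class BloodGas:
    """Blood-gas record for one step: pH, PCO2 (mmHg), HCO3- (mEq/L), sO2."""

    ph: float
    pco2: float
    hco3: float
    so2: float = 1.0

    def __post_init__(self) -> None:
        _require_finite(ph=self.ph, pco2=self.pco2, hco3=self.hco3, so2=self.so2)
        if not 6.0 <= self.ph <= 8.2:
            raise ValueError(f"pH {self.ph} outside measurable window [6.0, 8.2]")
        if self.pco2 <= 0:
            raise ValueError("PCO2 must be positive")
        if self.hco3 <= 0:
            raise ValueError("HCO3- must be positive")
        if not 0.0 <= self.so2 <= 1.0:
            raise ValueError("sO2 must be a fraction in [0, 1]")


@dataclass(frozen=True)
class ProteinPanel:
    """Per-subject protein panel: albumin and hemoglobin in g/dL.

    Phosphate (mg/dL) is recorded when available but never enters any
    computation: its buffering is outside this model.
    """

    albumin: float
    hemoglobin: float
    phosphate: Optional[float] = None

    def __post_init__(self) -> None:
        _require_finite(albumin=self.albumin, hemoglobin=self.hemoglobin)
        if not 0 <= self.albumin <= 8:
            raise ValueError(f"albumin {self.albumin} g/dL outside (0, 8]")
        if not 0 <= self.hemoglobin <= 25:
            raise ValueError(f"hemoglobin {self.hemoglobin} g/dL outside [0, 25]")


@dataclass(frozen=True)
class TonometryStep:
    """One equilibration of a sample with a gas of fixed CO2 fraction."""

    fco2: float
    gas: BloodGas
    electrolytes: ElectrolytePanel
    sample_kind: SampleKind = SampleKind.whole_blood
    acid_load: float = 0.0    # mEq/L of added strong acid (0 for controls)
    acid_kind: AcidKind = AcidKind.none

    def __post_init__(self) -> None:
        if not 0.01 <= self.fco2 <= 0.25:
            raise ValueError(f"fco2 {self.fco2} outside [0.01, 0.25]")
        if self.acid_load < 0:
            raise ValueError("acid_load must be non-negative")
        if self.acid_load > 0 and self.acid_kind is AcidKind.none:
            raise ValueError("acid_load > 0 requires acid_kind hcl or lactic")


@dataclass(frozen=True)
class TonometrySeries:
    """Ordered equilibration steps for one sample of one subject.

    ``beta_known`` carries an externally determined noncarbonic buffer
    value (mEq/L per pH unit) for series too short to fit one, e.g.
    single-step group-mean tables.
    """

    subject_id: str
    group: Group
    proteins: ProteinPanel
    steps: tuple[TonometryStep, ...]
    beta_known: Optional[float] = None

    def __post_init__(self) -> None:
        steps = tuple(sorted(self.steps, key=lambda s: s.fco2))
        object.__setattr__(self, "steps", steps)
        if not steps:
            raise ValueError("a series needs at least one step")
        kinds = {s.sample_kind for s in steps}
        if len(kinds) > 1:
            raise ValueError("a series cannot mix whole blood and isolated plasma")

    @property
    def sample_kind(self) -> SampleKind:
        return self.steps[0].sample_kind

    @property
    def acid_load(self) -> float:
        return self.steps[0].acid_load

    @property
    def acid_kind(self) -> AcidKind:
        return self.steps[0].acid_kind

    @property
    def is_control(self) -> bool:
        return self.acid_load == 0.0


@dataclass(frozen=True)
class DerivedStep:
    """Per-step derived quantities (all mEq/L unless noted).

    At the baseline step every expectation equals the measured SID exactly
    and every delta field is zero by construction.
    """

    sid: float
    z_albumin: float
    z_hemoglobin: float
    sid_exp: float
    sid_exp_beta: Optional[float]
    sid_exp_clsi: float
    be: Optional[float]
    be_clsi: Optional[float]
    delta_sid_wb: Optional[float]
    delta_sid_wb_clsi: Optional[float]
    delta_sid: float
    delta_be: Optional[float]
    delta_be_clsi: Optional[float]
    is_baseline: bool


@dataclass(frozen=True)
class AgreementResult:
    """Bland–Altman agreement between two paired measurement routes.

    ``bias`` is the mean of the paired differences a − b, limits of
    agreement are bias ± 1.96·SD (sample SD, n−1). ``acceptable`` applies
    the clinical rule |bias| ≤ 1 mEq/L and max |difference| < 3 mEq/L.
    """

    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    n_pairs: int
    max_abs_diff: float
    acceptable: bool


@dataclass(frozen=True)
class FenclPartition:
    """Bedside decomposition of base excess into plasma components."""

    sodium_chloride_effect: float
    albumin_effect: float
    lactate_effect: float
    unmeasured_ions: float


def as_series(subject_id: str, group: Group, proteins: ProteinPanel,
              steps: Sequence[TonometryStep],
              beta_known: Optional[float] = None) -> TonometrySeries:
    """Convenience constructor accepting any step sequence."""
    return TonometrySeries(subject_id=subject_id, group=group,
                           proteins=proteins, steps=tuple(steps),
                           beta_known=beta_known)
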