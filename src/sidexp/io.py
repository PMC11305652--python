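"""Reading and writing tonometry tables, truth sidecars and run configs.

The CSV dialect is one row per equilibration step, grouped into series by
(subject_id, sample_kind, acid_kind, acid_load). Units are frozen in the
column names (``ca_mmol_l`` vs the mEq/L electrolytes) to keep the
mMol/mEq calcium distinction explicit. Missing sO2 means fully saturated;
missing acid columns mean a control sample. An optional ``beta_meq_ph``
column carries an externally determined buffer value for series too short
to fit one (group-mean tables).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Literal, Optional, Sequence, Union

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field

from .params import BufferParams
from .simulate import GroundTruth, SimulationScenario
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

REQUIRED_COLUMNS = [
    "subject_id", "group", "sample_kind", "albumin_g_dl", "hemoglobin_g_dl",
    "fco2", "pco2_mmhg", "ph", "hco3_meq_l", "so2",
    "na", "k", "ca_mmol_l", "mg_meq_l", "cl", "lac",
    "acid_kind", "acid_load_meq_l",
]
OPTIONAL_COLUMNS = ["beta_meq_ph"]
_NUMERIC = ["albumin_g_dl", "hemoglobin_g_dl", "fco2", "pco2_mmhg", "ph",
            "hco3_meq_l", "so2", "na", "k", "ca_mmol_l", "mg_meq_l", "cl",
            "lac", "acid_load_meq_l", "beta_meq_ph"]


class ParseError(ValueError):
    """A tonometry table violates the dialect; the message names the line."""


def _line(row_index: int) -> int:
    # header is line 1; pandas row i is file line i + 2
    return row_index + 2


def read_tonometry(path: Union[str, Path]) -> list[TonometrySeries]:
    """Read a tonometry CSV into series, one per sample, sorted by fco2."""
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype={"subject_id": str})
    except pd.errors.EmptyDataError:
        raise ParseError(f"{path}: empty file") from None
    if df.empty:
        raise ParseError(f"{path}: no data rows")

    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    unknown = [c for c in df.columns
               if c not in REQUIRED_COLUMNS + OPTIONAL_COLUMNS]
    if unknown:
        raise ParseError(f"{path}: unknown columns {unknown}")

    for col in _NUMERIC:
        if col not in df.columns:
            continue
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        if len(bad):
            raise ParseError(
                f"{path}: non-numeric {col!r} at line {_line(bad[0])}")
        df[col] = coerced

    # defaults for empty cells
    df["so2"] = df["so2"].fillna(1.0)
    df["acid_load_meq_l"] = df["acid_load_meq_l"].fillna(0.0)
    df["acid_kind"] = df["acid_kind"].fillna("none")

    series: list[TonometrySeries] = []
    keys = ["subject_id", "sample_kind", "acid_kind", "acid_load_meq_l"]
    for (subject, kind, acid_kind, acid_load), g in df.groupby(keys, sort=False):
        dup = g["fco2"].duplicated()
        if dup.any():
            raise ParseError(
                f"{path}: duplicate (subject, sample, fco2) at line "
                f"{_line(g.index[dup][0])}")
        try:
            proteins = ProteinPanel(albumin=float(g["albumin_g_dl"].iloc[0]),
                                    hemoglobin=float(g["hemoglobin_g_dl"].iloc[0]))
            steps = []
            for idx, row in g.iterrows():
                steps.append(TonometryStep(
                    fco2=float(row["fco2"]),
                    gas=BloodGas(ph=float(row["ph"]),
                                 pco2=float(row["pco2_mmhg"]),
                                 hco3=float(row["hco3_meq_l"]),
                                 so2=float(row["so2"])),
                    electrolytes=ElectrolytePanel(
                        na=float(row["na"]), k=float(row["k"]),
                        ca_ionized=float(row["ca_mmol_l"]),
                        mg=float(row["mg_meq_l"]), cl=float(row["cl"]),
                        lac=float(row["lac"])),
                    sample_kind=SampleKind(kind),
                    acid_load=float(acid_load),
                    acid_kind=AcidKind(acid_kind)))
            beta_known = None
            if "beta_meq_ph" in g.columns and g["beta_meq_ph"].notna().any():
                beta_known = float(g["beta_meq_ph"].dropna().iloc[0])
            series.append(TonometrySeries(
                subject_id=str(subject), group=Group(g["group"].iloc[0]),
                proteins=proteins, steps=tuple(steps), beta_known=beta_known))
        except (ValueError, KeyError) as exc:
            raise ParseError(
                f"{path}: invalid series for subject {subject!r}: {exc}") from exc
    return series


def write_tonometry(series: Sequence[TonometrySeries],
                    path: Union[str, Path]) -> None:
    """Write series to the tonometry CSV dialect (lossless to repr precision)."""
    rows = []
    for s in series:
        for st in s.steps:
            rows.append({
                "subject_id": s.subject_id, "group": s.group.value,
                "sample_kind": st.sample_kind.value,
                "albumin_g_dl": s.proteins.albumin,
                "hemoglobin_g_dl": s.proteins.hemoglobin,
                "fco2": st.fco2, "pco2_mmhg": st.gas.pco2, "ph": st.gas.ph,
                "hco3_meq_l": st.gas.hco3, "so2": st.gas.so2,
                "na": st.electrolytes.na, "k": st.electrolytes.k,
                "ca_mmol_l": st.electrolytes.ca_ionized,
                "mg_meq_l": st.electrolytes.mg, "cl": st.electrolytes.cl,
                "lac": st.electrolytes.lac,
                "acid_kind": st.acid_kind.value,
                "acid_load_meq_l": st.acid_load,
                "beta_meq_ph": s.beta_known})
    df = pd.DataFrame(rows)
    if df["beta_meq_ph"].isna().all():
        df = df.drop(columns=["beta_meq_ph"])
    df.to_csv(path, index=False)


def write_truth(truth: GroundTruth, path: Union[str, Path]) -> None:
    """Write a simulation's ground truth as a JSON sidecar."""
    Path(path).write_text(json.dumps(truth.to_json_dict(), indent=1))


def read_truth(path: Union[str, Path]) -> GroundTruth:
    d = json.loads(Path(path).read_text())
    return GroundTruth(seed=d["seed"],
                       subjects=pd.DataFrame(d["subjects"]),
                       steps=pd.DataFrame(d["steps"]))


class RunConfig(BaseModel):
    """Validated run configuration (YAML or JSON); unknown keys rejected."""

    model_config = ConfigDict(frozen=True, extra="forbid")

    params: BufferParams = BufferParams()
    experiment: Literal["exp1", "exp2", "exp3"] = "exp1"
    beta_mode: Literal["fitted", "clsi"] = "fitted"
    fencl_nacl_ref: float = 38.0
    fencl_alb_coeff: float = 0.25
    fencl_alb_ref_g_l: float = 42.0
    fencl_include_lactate: bool = True
    scenario: Optional[SimulationScenario] = None
    outdir: str = "out"
    seed: int = Field(default=0, ge=0)


def load_config(path: Union[str, Path]) -> RunConfig:
    """Load a RunConfig from YAML (.yaml/.yml) or JSON."""
    path = Path(path)
    text = path.read_text()
    data = (yaml.safe_load(text) if path.suffix in {".yaml", ".yml"}
            else json.loads(text))
    return RunConfig.model_validate(data or {})
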