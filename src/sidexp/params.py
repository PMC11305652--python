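"""Physical constants of the buffer model.

All charge arithmetic in the package is carried out in mEq/L; unit
conversions (g/dL of protein to mMol/L) happen only at type boundaries.
The defaults below encode:

* the imidazole titration model of plasma proteins (common pK 6.75,
  16 titrable groups on albumin, MW 66,500 g/mol);
* hemoglobin handled per tetramer (MW 64,458 g/mol) at red-cell pH,
  which is mapped linearly from plasma pH (Funder–Wieth-type relation);
* the Lang–Zander whole-blood base-excess convention (reference
  bicarbonate 24.26 mEq/L at pH 7.40, bicarbonate distribution ratio
  r = 1 − 0.0143·[Hb], saturation term s = 0.2·[Hb]·(1 − sO2));
* the CLSI whole-blood buffer value β = 1.43·[Hb] + 7.7;
* Henderson–Hasselbalch plumbing (pK' 6.105, CO2 solubility
  0.0307 mMol/L/mmHg) used by the simulator and consistency checks.

``n_hemoglobin`` and the red-cell pH map are calibrated constants: they
were fixed once by a least-maximum-error grid fit of the titrable-charge
model to published whole-blood tonometry group means, with the red-cell
pH at plasma pH 7.40 constrained to the physiologic 7.15–7.30 window.
"""

from __future__ import annotations

from pydantic import BaseModel, ConfigDict, Field


class BufferParams(BaseModel):
    """Every physical constant of the charge/base-excess model.

    Instances are immutable; use ``model_copy(update=...)`` to derive
    variants. Serializes to/from the run configuration file.
    """

    model_config = ConfigDict(frozen=True, extra="forbid")

    pk_imidazole: float = Field(default=6.75, gt=6.0, lt=8.0)
    n_albumin: float = Field(default=16.0, gt=0)
    mw_albumin: float = Field(default=66_500.0, gt=0)   # g/mol
    n_hemoglobin: float = Field(default=26.0, gt=0)     # per tetramer
    mw_hemoglobin: float = Field(default=64_458.0, gt=0)  # g/mol, tetramer
    rbc_ph_slope: float = Field(default=0.76, gt=0)
    rbc_ph_intercept: float = Field(default=1.571, gt=0)
    clsi_slope: float = Field(default=1.43, gt=0)       # mEq/L per g/dL
    clsi_intercept: float = Field(default=7.7, gt=0)    # mEq/L
    hco3_ref: float = Field(default=24.26, gt=0)        # mEq/L
    ph_ref: float = Field(default=7.40, gt=0)
    r_coeff: float = Field(default=0.0143, gt=0)        # per g/dL
    s_coeff: float = Field(default=0.2, gt=0)           # per g/dL
    hh_pk: float = Field(default=6.105, gt=0)
    hh_solubility: float = Field(default=0.0307, gt=0)  # mMol/L/mmHg


DEFAULT_PARAMS = BufferParams()
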