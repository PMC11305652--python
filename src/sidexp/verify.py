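"""Offline self-verification against the published group-mean tables.

Each check recomputes one published derived quantity from the packaged
measured columns through the package's own code path and compares it at a
tolerance reflecting table rounding (the tables print one decimal and the
checks chain several rounded means, so tolerances are 0.1–0.3 mEq/L).
Everything runs from packaged fixtures in well under a second.
"""

from __future__ import annotations

from dataclasses import dataclass

from . import core
from .analysis import run_experiment
from .datasets import PUBLISHED, load_table1, load_table2, load_table3
from .params import DEFAULT_PARAMS, BufferParams


@dataclass(frozen=True)
class Check:
    """One recomputed quantity vs its published value."""

    name: str
    value: float
    reference: float
    tol: float
    n: int  # subjects behind the published mean

    @property
    def passed(self) -> bool:
        return abs(self.value - self.reference) <= self.tol

    def __str__(self) -> str:
        flag = "ok  " if self.passed else "FAIL"
        return (f"[{flag}] {self.name}: {self.value:+.3f} "
                f"(published {self.reference:+.1f}, tol {self.tol})")


def run_checks(p: BufferParams = DEFAULT_PARAMS) -> list[Check]:
    """Recompute every packaged verification quantity; see module docstring."""
    checks: list[Check] = []
    t1 = PUBLISHED["table1"]
    t2 = PUBLISHED["table2"]
    t3 = PUBLISHED["table3"]

    # --- measured SID from the electrolyte columns -----------------------
    table1 = {s.subject_id: s for s in load_table1()}
    healthy_20 = table1["healthy_mean"].steps[-1]
    checks.append(Check("sid_healthy_20pct_co2",
                        core.compute_sid(healthy_20.electrolytes),
                        t1["healthy"]["sid"][-1], 0.2, t1["healthy"]["n"]))

    table2 = {s.subject_id: s for s in load_table2()}
    undiluted_2 = table2["undiluted_mean"].steps[0]
    checks.append(Check("sid_undiluted_2pct_co2",
                        core.compute_sid(undiluted_2.electrolytes),
                        t2["undiluted"]["sid"][0], 0.2, t2["undiluted"]["n"]))

    diluted = table2["diluted_mean"].steps
    rise = (core.compute_sid(diluted[-1].electrolytes)
            - core.compute_sid(diluted[0].electrolytes))
    checks.append(Check("sid_rise_diluted_2_to_20pct",
                        rise,
                        t2["diluted"]["sid"][-1] - t2["diluted"]["sid"][0],
                        0.3, t2["diluted"]["n"]))

    # --- titrable charges and the charge-based expected SID --------------
    checks.append(Check("z_albumin_healthy_20pct_co2",
                        core.albumin_zph(t1["healthy"]["albumin"],
                                         t1["healthy"]["ph"][-1], p),
                        t1["healthy"]["z_alb"][-1], 0.1, t1["healthy"]["n"]))

    sep = t1["septic"]
    b = t1["baseline_index"]
    checks.append(Check("sid_exp_septic_12pct_co2",
                        core.expected_sid(sep["sid"][b],
                                          sep["z_alb"][2] - sep["z_alb"][b],
                                          sep["z_hb"][2] - sep["z_hb"][b]),
                        sep["sid_exp"][2], 0.2, sep["n"]))

    # --- acid-loading experiment: ΔBE and ΔSID_wb through the pipeline ---
    report = run_experiment(load_table3(), "exp3", p, beta_mode="fitted")
    d = report.derived.set_index(["acid_kind", "acid_load"])
    cols = t3["columns"]
    loads = {"lac_7.5": ("lactic", 7.5), "cl_7.5": ("hcl", 7.5),
             "lac_15": ("lactic", 15.0), "cl_15": ("hcl", 15.0)}
    for label, key in loads.items():
        i = cols.index(label)
        row = d.loc[key]
        checks.append(Check(f"dbe_{label}", float(row["delta_be"]),
                            t3["dbe"][i], 0.15, t3["n"]))
        checks.append(Check(f"dsid_wb_{label}", float(row["delta_sid_wb"]),
                            t3["dsid_wb"][i], 0.2, t3["n"]))
    return checks
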