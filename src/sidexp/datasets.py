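"""Packaged group-mean tonometry tables and the published derived rows.

The CSVs under ``sidexp/data`` encode the published group means of three
whole-blood CO2-tonometry experiments (healthy vs septic donors over
2–20% CO2; diluted vs undiluted blood; acid-loaded samples at constant
CO2). They are the only data shipped with the package — per-subject raw
records are not public — so analyses against them treat each group-mean
column as a pseudo-subject.

``PUBLISHED`` holds the derived rows printed alongside those tables (SID,
titrable charges, expected SID, β, ΔBE, ΔSID_wb). They serve as
regression anchors for the model: recomputing them from the measured
columns must land within table-rounding tolerance.
"""

from __future__ import annotations

from importlib import resources

from .io import read_tonometry
from .types import TonometrySeries


def _load(name: str) -> list[TonometrySeries]:
    with resources.as_file(resources.files("sidexp") / "data" / name) as path:
        return read_tonometry(path)


def load_table1() -> list[TonometrySeries]:
    """Healthy vs septic whole blood, 2/5/12/20% CO2 (group means)."""
    return _load("table1_means.csv")


def load_table2() -> list[TonometrySeries]:
    """Diluted (anemic) vs undiluted whole blood, 2/12/20% CO2 (group means)."""
    return _load("table2_means.csv")


def load_table3() -> list[TonometrySeries]:
    """Control and acid-loaded samples near PCO2 40 mmHg (group means).

    Five single-step pseudo-series: Ctr, Lac 7.5, Cl 7.5, Lac 15, Cl 15;
    each carries its published per-sample buffer value in ``beta_known``.
    """
    return _load("table3_means.csv")


#: published derived rows (group means), indexed like the CSVs above
PUBLISHED: dict = {
    "table1": {
        "fco2": (0.02, 0.05, 0.12, 0.20),
        "healthy": {
            "ph": (7.61, 7.46, 7.24, 7.07),
            "sid": (32.8, 36.6, 41.6, 46.3),
            "z_alb": (1.4, 1.9, 2.8, 3.7),
            "z_hb": (11.2, 13.7, 17.9, 22.9),
            "sid_exp": (33.5, 36.6, 41.8, 46.8),
            "albumin": 4.8, "hemoglobin": 14.2, "n": 18,
        },
        "septic": {
            "ph": (7.56, 7.41, 7.17, 6.98),
            "sid": (30.7, 33.4, 37.1, 40.3),
            "z_alb": (1.0, 1.4, 2.1, 2.7),
            "z_hb": (8.7, 10.7, 14.3, 17.4),
            "sid_exp": (31.5, 33.4, 37.7, 41.6),
            "albumin": 3.1, "hemoglobin": 10.4, "n": 18,
        },
        "baseline_index": 1,  # the 5% CO2 step
    },
    "table2": {
        "fco2": (0.02, 0.12, 0.20),
        "diluted": {"sid": (38.8, 44.1, 46.6), "n": 10},
        "undiluted": {"sid": (35.5, 43.3, 47.8), "n": 10},
        "baseline_index": 1,  # the 12% CO2 step
    },
    "table3": {
        "columns": ("ctr", "lac_7.5", "cl_7.5", "lac_15", "cl_15"),
        "ph": (7.40, 7.30, 7.29, 7.18, 7.18),
        "hco3": (24.8, 19.6, 19.8, 15.3, 15.2),
        "sid": (42.9, 37.5, 38.0, 32.7, 33.3),
        "beta": (28.5, 30.6, 31.1, 33.1, 33.7),
        "dbe": (None, -6.6, -6.8, -13.4, -13.6),
        "dsid": (None, -5.4, -4.9, -10.2, -9.5),
        "dsid_wb": (None, -6.7, -6.7, -14.0, -13.5),
        "albumin": 5.0, "hemoglobin": 13.9, "n": 10,
    },
}
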