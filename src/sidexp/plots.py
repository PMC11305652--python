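"""Report figures: titration curves and Bland–Altman agreement plots."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .analysis import ExperimentReport

_PAIR_COLUMNS = {
    "sid_vs_sid_exp": ("sid", "sid_exp"),
    "sid_vs_sid_exp_beta": ("sid", "sid_exp_beta"),
    "sid_vs_sid_exp_clsi": ("sid", "sid_exp_clsi"),
    "dsid_vs_dbe_metabolic": ("delta_sid", "delta_be"),
    "dsidwb_vs_dbe_metabolic": ("delta_sid_wb", "delta_be"),
    "dsid_vs_dbe_mixed": ("delta_sid", "delta_be"),
    "dsidwb_vs_dbe_mixed": ("delta_sid_wb", "delta_be"),
}


def save_report_plots(report: ExperimentReport, outdir: Path) -> list[Path]:
    """Write titration-curve and Bland–Altman SVGs; returns the files."""
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    fig, ax = plt.subplots(figsize=(5, 4))
    for (subject, kind, load), g in report.derived.groupby(
            ["subject_id", "acid_kind", "acid_load"]):
        g = g.sort_values("ph")
        ax.plot(g["ph"], g["hco3"], marker="o", ms=3, lw=0.8, alpha=0.6)
    ax.set_xlabel("plasma pH")
    ax.set_ylabel("HCO$_3^-$ (mEq/L)")
    ax.set_title("CO$_2$ titration curves (slope = $-\\beta$)")
    path = outdir / "titration_curves.svg"
    fig.savefig(path, bbox_inches="tight")
    plt.close(fig)
    written.append(path)

    nb = report.derived[~report.derived["is_baseline"]]
    for name, result in report.agreements.items():
        cols = _PAIR_COLUMNS.get(name)
        if cols is None:
            continue
        a, b = cols
        sub = nb.dropna(subset=[a, b])
        if sub.empty:
            continue
        fig, ax = plt.subplots(figsize=(5, 4))
        mean_ab = (sub[a] + sub[b]) / 2.0
        ax.scatter(mean_ab, sub[a] - sub[b], s=12, alpha=0.7)
        for y, style in ((result.bias, "-"), (result.loa_low, "--"),
                         (result.loa_high, "--")):
            ax.axhline(y, color="k", ls=style, lw=0.8)
        ax.set_xlabel(f"mean of {a} and {b} (mEq/L)")
        ax.set_ylabel(f"{a} − {b} (mEq/L)")
        ax.set_title(f"{name}: bias {result.bias:+.2f} "
                     f"[{result.loa_low:+.2f}; {result.loa_high:+.2f}]")
        path = outdir / f"bland_altman_{name}.svg"
        fig.savefig(path, bbox_inches="tight")
        plt.close(fig)
        written.append(path)
    return written
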