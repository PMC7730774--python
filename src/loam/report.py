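"""Agreement plots and the assembled end-to-end analysis report.

The agreement plot generalises the Bland–Altman plot to many observers:
each measurement's deviation from its subject's mean, d_ijk = y_ijk -
ybar_i.., is scattered against that subject mean, with dashed lines at the
estimated +/- LOAM and a shaded band for the LOAM's confidence interval.
Points are coloured by observer so systematic over/under-readers stand out.

``run_report`` composes the whole analysis — dimensions, per-observer
summaries, LOAM (proposed and the fixed-effects comparison), variance
components with CIs, ICC(A,1) — and serialises it as text, a dict (JSON)
or a plot.  All numbers come straight from the estimation/interval
modules; nothing is re-derived here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import AgreementData, summarize_by_observer, summarize_by_subject
from .estimation import (
    icc_a1,
    jones_loam,
    loam_estimate,
    sums_of_squares,
    variance_components,
    z_multiplier,
)
from .intervals import (
    IntervalEstimate,
    icc_ci,
    loam_ci,
    sigma_A_ci,
    sigma_B_ci,
    sigma_E_ci,
)

__all__ = ["AgreementPlotData", "agreement_plot_data", "render_agreement_plot", "AgreementReport", "run_report", "analyze"]


@dataclass(frozen=True)
class AgreementPlotData:
    """Everything needed to draw an agreement plot.

    ``points`` has one row per measurement with columns ``subject_mean``,
    ``difference`` and ``observer``; ``loam`` carries the +/- limit and its
    CI band.  Differences within each subject sum to zero by construction.
    """

    points: pd.DataFrame
    loam: IntervalEstimate
    unit: str = ""


def agreement_plot_data(data: AgreementData, loam: IntervalEstimate) -> AgreementPlotData:
    """Per-measurement differences from the subject mean, plus LOAM lines."""
    a, b, c = data.dims
    subj_means = data.subject_means()
    diffs = data.values - subj_means[:, None, None]
    points = pd.DataFrame(
        {
            "subject": np.repeat(data.subject_ids, b * c),
            "observer": np.tile(np.repeat(data.observer_ids, c), a),
            "subject_mean": np.repeat(subj_means, b * c),
            "difference": diffs.ravel(),
        }
    )
    return AgreementPlotData(points=points, loam=loam, unit=data.unit)


def render_agreement_plot(plot_data: AgreementPlotData, path=None, ax=None):
    """Draw the agreement plot; save to ``path`` or draw on ``ax``."""
    import matplotlib

    if path is not None and ax is None:
        matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    created = ax is None
    if created:
        fig, ax = plt.subplots(figsize=(7, 5))
    else:
        fig = ax.figure

    loam = plot_data.loam
    for sign in (+1, -1):
        ax.axhspan(sign * loam.lower, sign * loam.upper, color="0.85", zorder=0)
        ax.axhline(sign * loam.point, linestyle="--", color="0.2", linewidth=1)
    ax.axhline(0.0, color="0.5", linewidth=0.8)

    for observer, grp in plot_data.points.groupby("observer", sort=False):
        ax.scatter(grp["subject_mean"], grp["difference"], s=14, label=str(observer), alpha=0.8)

    unit = f" ({plot_data.unit})" if plot_data.unit else ""
    ax.set_xlabel(f"Subject mean{unit}")
    ax.set_ylabel(f"Difference from subject mean{unit}")
    n_obs = plot_data.points["observer"].nunique()
    if n_obs <= 12:
        ax.legend(title="Observer", fontsize=8, ncol=2)
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return ax


@dataclass(frozen=True)
class AgreementReport:
    """Full agreement analysis of one balanced dataset."""

    data: AgreementData
    loam: IntervalEstimate
    jones: float
    sigma_A: IntervalEstimate
    sigma_B: IntervalEstimate
    sigma_E: IntervalEstimate
    icc: IntervalEstimate
    sigma2_A: float
    sigma2_B: float
    sigma2_E: float
    observer_summary: pd.DataFrame
    subject_summary: pd.DataFrame
    level: float

    @property
    def warnings(self) -> list[str]:
        out = []
        if self.sigma2_A < 0:
            out.append(
                "negative subject variance component estimate "
                f"(sigma2_A = {self.sigma2_A:.4g}); reported unclipped, sigma_A CI undefined"
            )
        if self.sigma2_B < 0:
            out.append(
                "negative observer variance component estimate "
                f"(sigma2_B = {self.sigma2_B:.4g}); reported unclipped, sigma_B CI undefined. "
                "Consider whether measurements by one observer could be negatively "
                "correlated across subjects, or whether more observers are needed."
            )
        if any(d < 0 for d in (self.sigma_A.lower, self.sigma_B.lower) if not math.isnan(d)):
            out.append("a delta-method lower bound is negative; reported as computed, not clipped at 0")
        return out

    def residuals(self) -> np.ndarray:
        """Two-way additive-fit residuals y_ijk - ybar_i.. - ybar_.j. + ybar...,
        exported for external diagnostics (QQ plots, residual-vs-fitted)."""
        v = self.data.values
        return (
            v
            - self.data.subject_means()[:, None, None]
            - self.data.observer_means()[None, :, None]
            + self.data.grand_mean()
        )

    def to_dict(self) -> dict:
        def iv(x: IntervalEstimate) -> dict:
            return {
                "point": x.point,
                "lower": x.lower,
                "upper": x.upper,
                "level": x.level,
                "method": x.method,
                "flags": sorted(x.flags),
            }

        a, b, c = self.data.dims
        return {
            "dimensions": {"subjects": a, "observers": b, "replicates": c},
            "unit": self.data.unit,
            "loam": iv(self.loam),
            "jones_loam": self.jones,
            "sigma_A": iv(self.sigma_A),
            "sigma_B": iv(self.sigma_B),
            "sigma_E": iv(self.sigma_E),
            "variance_components": {
                "sigma2_A": self.sigma2_A,
                "sigma2_B": self.sigma2_B,
                "sigma2_E": self.sigma2_E,
            },
            "icc_a1": iv(self.icc),
            "observer_summary": self.observer_summary.to_dict(orient="records"),
            "warnings": self.warnings,
        }

    def to_text(self, decimals: int = 1) -> str:
        """Human-readable report; rounding here is presentation only."""
        a, b, c = self.data.dims
        u = f" {self.data.unit}" if self.data.unit else ""
        pct = f"{self.level:.0%}"

        def fmt(x: float) -> str:
            return "NA" if math.isnan(x) else f"{x:.{decimals}f}"

        def line(name: str, iv: IntervalEstimate) -> str:
            return f"  {name}: {fmt(iv.point)}{u} ({pct} CI: {fmt(iv.lower)}, {fmt(iv.upper)})"

        rows = [
            "Agreement analysis (limits of agreement with the mean)",
            f"  design: {a} subjects x {b} observers x {c} replicate(s) = {a*b*c} measurements",
            line(f"{pct} LOAM (+/-)", self.loam),
            f"  Jones et al. LOAM (+/-): {fmt(self.jones)}{u}  [residual variation only]",
            line("sigma_A (inter-subject SD)", self.sigma_A),
            line("sigma_B (inter-observer SD)", self.sigma_B),
            line("sigma_E (intra-observer SD)", self.sigma_E),
            f"  ICC(A,1): {self.icc.point:.{max(decimals, 2)}f} "
            f"({pct} CI: {self.icc.lower:.{max(decimals, 2)}f}, {self.icc.upper:.{max(decimals, 2)}f})",
            "",
            "Per-observer summary (mean, SD):",
        ]
        summ = self.observer_summary
        for obs, m, s in zip(summ["observer"], summ["mean"], summ["sd"]):
            rows.append(f"  {obs}: {m:.{decimals}f}{u}, {s:.{decimals}f}{u}")
        for w in self.warnings:
            rows.append(f"WARNING: {w}")
        return "\n".join(rows)


def analyze(data: AgreementData, level: float = 0.95, loam_level: float = 0.95) -> AgreementReport:
    """Run the full agreement analysis on a validated dataset."""
    ss = sums_of_squares(data)
    vc = variance_components(ss)
    z = z_multiplier(loam_level)
    return AgreementReport(
        data=data,
        loam=loam_ci(ss, level=level, loam_level=loam_level),
        jones=jones_loam(ss, z=z),
        sigma_A=sigma_A_ci(vc, ss, level=level),
        sigma_B=sigma_B_ci(vc, ss, level=level),
        sigma_E=sigma_E_ci(ss, level=level),
        icc=icc_ci(ss, level=level),
        sigma2_A=vc.sigma2_A,
        sigma2_B=vc.sigma2_B,
        sigma2_E=vc.sigma2_E,
        observer_summary=summarize_by_observer(data),
        subject_summary=summarize_by_subject(data),
        level=level,
    )


def run_report(
    source,
    column_map=None,
    unit: str = "",
    level: float = 0.95,
    loam_level: float = 0.95,
    plot_path=None,
) -> AgreementReport:
    """Read a measurement table and produce the full agreement report.

    Data errors propagate; a plot-rendering failure degrades to the
    report alone with a warning on stderr.
    """
    from .data_model import read_agreement_table

    data = read_agreement_table(source, column_map=column_map, unit=unit)
    report = analyze(data, level=level, loam_level=loam_level)
    if plot_path is not None:
        try:
            render_agreement_plot(agreement_plot_data(data, report.loam), path=plot_path)
        except Exception as exc:  # plotting is best-effort; the numbers matter
            import sys

            print(f"warning: could not render agreement plot: {exc}", file=sys.stderr)
    return report
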