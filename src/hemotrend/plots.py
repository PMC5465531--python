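"""Publication-style figures: Bland-Altman, four-quadrant, polar, ROC.

Each function writes both PNG and SVG next to the given stem path.
"""

from __future__ import annotations

import math
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np


def _save(fig, stem) -> list[Path]:
    stem = Path(stem)
    paths = []
    for ext in ("png", "svg"):
        p = stem.with_suffix(f".{ext}")
        fig.savefig(p, dpi=150, bbox_inches="tight")
        paths.append(p)
    plt.close(fig)
    return paths


def bland_altman_plot(pairs, fitted, stem) -> list[Path]:
    """Differences vs pair means with solid bias and dashed LOA lines."""
    ref = np.array([p.co_ref for p in pairs])
    test = np.array([p.co_test for p in pairs])
    means, diffs = (ref + test) / 2.0, test - ref
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(means, diffs, s=18, color="k", alpha=0.7)
    ax.axhline(fitted.bias_, color="k", lw=1.5)
    for y in (fitted.loa_low_, fitted.loa_high_):
        ax.axhline(y, color="k", lw=1.0, ls="--")
    ax.set_xlabel("Mean CO of the two methods (L/min)")
    ax.set_ylabel("CO-TTE − CO-PAC (L/min)")
    ax.set_title(
        f"Bland–Altman: bias {fitted.bias_:.2f}, "
        f"LOA [{fitted.loa_low_:.2f}, {fitted.loa_high_:.2f}] L/min, "
        f"PE {fitted.pe_pct_:.0f}%"
    )
    return _save(fig, stem)


def four_quadrant_plot(deltas, fitted, stem) -> list[Path]:
    """Percentage change scatter with the central exclusion square."""
    pr = np.array([d.pct_ref for d in deltas])
    pt = np.array([d.pct_test for d in deltas])
    z = fitted.zone_pct
    lim = max(1.2 * max(np.abs(pr).max(), np.abs(pt).max()), 1.5 * z)
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.scatter(pr, pt, s=18, color="k", alpha=0.7)
    ax.add_patch(plt.Rectangle((-z, -z), 2 * z, 2 * z, fill=False, ls="--", color="grey"))
    ax.axhline(0, color="grey", lw=0.5)
    ax.axvline(0, color="grey", lw=0.5)
    ax.plot([-lim, lim], [-lim, lim], color="grey", lw=0.5, ls=":")
    ax.set_xlim(-lim, lim)
    ax.set_ylim(-lim, lim)
    ax.set_xlabel("ΔCO-PAC (%)")
    ax.set_ylabel("ΔCO-TTE (%)")
    ax.set_title(f"Four-quadrant plot: concordance {fitted.concordance_pct_:.0f}% (zone {z:g}%)")
    return _save(fig, stem)


def polar_plot(fitted, stem) -> list[Path]:
    """Half-circle polar plot with exclusion zone, ±band axes, radial LOA."""
    angles = np.array([p.angle_deg for p in fitted.points_])
    radii = np.array([p.radius for p in fitted.points_])
    inc = np.array([p.included for p in fitted.points_])
    fig = plt.figure(figsize=(5.5, 4))
    ax = fig.add_subplot(projection="polar")
    ax.set_thetamin(-90)
    ax.set_thetamax(90)
    ax.set_theta_zero_location("E")
    ax.scatter(np.radians(angles[inc]), radii[inc], s=18, color="k", alpha=0.8)
    if (~inc).any():
        ax.scatter(np.radians(angles[~inc]), radii[~inc], s=14, color="grey", alpha=0.5)
    rmax = max(1.2 * radii.max(), 1.0) if radii.size else 1.0
    theta_fill = np.linspace(-math.pi / 2, math.pi / 2, 91)
    ax.fill_between(theta_fill, 0, fitted.zone_lmin, color="lightgrey", alpha=0.6)
    for a in (-fitted.band_deg, fitted.band_deg):
        ax.plot([math.radians(a)] * 2, [0, rmax], color="k", lw=1.0)
    for a in (fitted.radial_loa_low_deg_, fitted.radial_loa_high_deg_):
        ax.plot([math.radians(a)] * 2, [0, rmax], color="k", lw=0.8, ls=":")
    ax.set_rmax(rmax)
    ax.set_title(
        f"Polar plot: mean angle {fitted.mean_angle_deg_:.1f}°, "
        f"radial LOA [{fitted.radial_loa_low_deg_:.1f}, {fitted.radial_loa_high_deg_:.1f}]°,\n"
        f"concordance {fitted.concordance_pct_:.0f}% within ±{fitted.band_deg:g}°"
    )
    return _save(fig, stem)


def roc_plot(fitted, stem) -> list[Path]:
    """Empirical ROC curve with the operating point marked."""
    curve = np.array([(100.0 - spec, sens) for _, sens, spec in fitted.curve_])
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    order = np.argsort(curve[:, 0], kind="stable")
    ax.plot(curve[order, 0], curve[order, 1], color="k", drawstyle="steps-post")
    ax.plot([0, 100], [0, 100], color="grey", lw=0.7, ls=":")
    ax.plot(
        100.0 - fitted.specificity_pct_,
        fitted.sensitivity_pct_,
        "o",
        color="red",
        label=f"ΔCO-TTE > {fitted.operating_threshold_pct:g}%",
    )
    ax.set_xlabel("100 − specificity (%)")
    ax.set_ylabel("Sensitivity (%)")
    ax.set_title(f"ROC: AUC {fitted.auc_:.2f} ({fitted.ci_low_:.2f}–{fitted.ci_high_:.2f})")
    ax.legend(loc="lower right", fontsize=8)
    return _save(fig, stem)
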