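"""Habitat-discharge response curves.

The habitat model is re-applied to hydraulics solved at ramped discharges
(default +-30% of baseflow in 10% steps, i.e. multipliers 0.7..1.3) while
substrate, temperature and channel geometry are held fixed.  Habitat
quantity per scenario is standardized two ways for cross-stream
comparison: habitat area per linear metre of channel, and percent change
relative to the baseflow scenario.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .habitat_model import FittedHabitatModel
from .habitat_mapping import binarize, predict_probability
from .hydraulics import compute_froude
from .synthetic_springbrook import ChannelTemplate, build_scene, HydraulicsError

__all__ = [
    "DEFAULT_MULTIPLIERS",
    "run_flow_scenarios",
    "standardize_per_metre",
    "relative_change",
    "plot_flow_response",
]

DEFAULT_MULTIPLIERS = (0.7, 0.8, 0.9, 1.0, 1.1, 1.2, 1.3)


def run_flow_scenarios(template: ChannelTemplate, model: FittedHabitatModel,
                       multipliers=DEFAULT_MULTIPLIERS,
                       cutpoint: float | None = None) -> pd.DataFrame:
    """Habitat quantity at each flow multiplier of the template baseflow.

    For each multiplier the hydraulics are re-solved, the Froude layer
    recomputed, the model applied and thresholded at its cutpoint.
    Returns one row per scenario with columns ``multiplier``, ``q_cms``,
    ``habitat_area_m2``, ``habitat_per_metre``, ``relative_change_pct``.
    """
    if cutpoint is None:
        cutpoint = model.cutpoint
    rows = []
    for m in multipliers:
        q = m * template.baseflow_q
        try:
            scene = build_scene(template, q=q, is_baseflow=np.isclose(m, 1.0))
        except HydraulicsError as exc:
            raise HydraulicsError(f"flow multiplier {m}: {exc}") from exc
        prob = predict_probability(scene, model)
        hmap = binarize(prob, cutpoint)
        rows.append({
            "multiplier": float(m),
            "q_cms": q,
            "habitat_area_m2": hmap.habitat_area,
        })
    results = pd.DataFrame(rows)
    results = standardize_per_metre(results, template.length)
    results = relative_change(results)
    return results


def standardize_per_metre(results: pd.DataFrame, channel_length: float) -> pd.DataFrame:
    """Populate habitat_per_metre = habitat_area / channel length."""
    if channel_length <= 0:
        raise ValueError("channel length must be positive")
    out = results.copy()
    out["habitat_per_metre"] = out["habitat_area_m2"] / channel_length
    return out


def relative_change(results: pd.DataFrame) -> pd.DataFrame:
    """Populate relative_change_pct = 100 * (H - H0) / H0 against baseflow.

    The baseflow row is the one with multiplier 1.0; its relative change
    is identically zero.  A zero baseflow habitat area leaves the change
    undefined and raises.
    """
    out = results.copy()
    base = out.loc[np.isclose(out["multiplier"], 1.0), "habitat_area_m2"]
    if len(base) != 1:
        raise ValueError("need exactly one baseflow (multiplier 1.0) scenario")
    h0 = float(base.iloc[0])
    if h0 == 0:
        raise ValueError("baseflow habitat area is zero; relative change undefined")
    out["relative_change_pct"] = 100.0 * (out["habitat_area_m2"] - h0) / h0
    out.loc[np.isclose(out["multiplier"], 1.0), "relative_change_pct"] = 0.0
    return out


def plot_flow_response(results: pd.DataFrame, path) -> None:
    """Bar graphs of both standardizations (a cosmetic artifact; the CSV
    numbers are the contract)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, (ax_a, ax_b) = plt.subplots(1, 2, figsize=(9, 3.5))
    labels = [f"{m:+.0%}"[:3] if m != 1.0 else "base"
              for m in results["multiplier"] - 1.0]
    ax_a.bar(labels, results["habitat_per_metre"], color="steelblue")
    ax_a.set_ylabel("habitat (m$^2$ per m of channel)")
    ax_a.set_xlabel("flow relative to baseflow")
    ax_b.bar(labels, results["relative_change_pct"], color="indianred")
    ax_b.set_ylabel("habitat change vs baseflow (%)")
    ax_b.set_xlabel("flow relative to baseflow")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
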