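"""Baseline-correction scenario simulation.

Demonstrates why per-repetition baseline correction cannot distinguish
pre-stimulus from post-stimulus power changes across learning, while
per-subject correction can.  A reference repetition-1 ERD curve (flat
pre-stimulus level, raised-cosine post-stimulus dip with recovery) is
contrasted with four repetition-2 variants:

    A  pre-stimulus increase, post level unchanged
    B  post-stimulus decrease, pre level unchanged
    C  pre-stimulus increase and post-stimulus decrease
    D  decrease in both pre- and post-stimulus phases

All four are *calibrated* to share the same post-minus-pre level change,
so their per-repetition-corrected curves are exactly identical (the
conflation), while per-subject correction recovers the distinct
pre-stimulus levels (the disambiguation).  With pre/post delta magnitudes
``(m_pre, m_post)`` the common level change is ``-(m_pre + m_post)`` and
the pre-stimulus shifts are A: ``+(m_pre+m_post)``, B: 0, C: ``+m_pre``,
D: ``-m_pre``; the post shift of each scenario is its pre shift plus the
common change, which satisfies all four qualitative definitions at once.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["ScenarioTrajectory", "build_scenarios", "apply_scheme",
           "scenarios_to_frame"]


@dataclass
class ScenarioTrajectory:
    scenario: str               # "reference", "A", "B", "C", "D"
    times: np.ndarray           # ms, onset at 0
    power: np.ndarray           # arbitrary (log-scale) units
    pre_delta: float = 0.0      # level shift vs reference, t < 0
    post_delta: float = 0.0     # level shift vs reference, t >= 0
    level_change: float | None = None   # post_delta - pre_delta (calibrated)


def _reference_curve(times: np.ndarray, level: float = 1.0,
                     depth: float = 0.5, dip_start: float = 100.0,
                     dip_bottom: float = 450.0, recover: float = 900.0
                     ) -> np.ndarray:
    """Flat pre-stimulus level with a smooth raised-cosine ERD dip."""
    y = np.full_like(times, level, dtype=float)
    falling = (times >= dip_start) & (times < dip_bottom)
    y[falling] = level - depth * 0.5 * (
        1 - np.cos(np.pi * (times[falling] - dip_start)
                   / (dip_bottom - dip_start)))
    rising = (times >= dip_bottom) & (times <= recover)
    y[rising] = level - depth * 0.5 * (
        1 + np.cos(np.pi * (times[rising] - dip_bottom)
                   / (recover - dip_bottom)))
    y[times > recover] = level
    return y


def build_scenarios(
    pre_delta_magnitude: float = 0.1,
    post_delta_magnitude: float = 0.1,
    time_grid: np.ndarray | None = None,
) -> dict[str, ScenarioTrajectory]:
    """Reference curve plus the four calibrated repetition-2 variants."""
    if pre_delta_magnitude <= 0 or post_delta_magnitude <= 0:
        raise ValueError("delta magnitudes must be positive")
    times = (np.arange(-500.0, 901.0, 10.0) if time_grid is None
             else np.asarray(time_grid, dtype=float))
    ref = _reference_curve(times)
    common = -(pre_delta_magnitude + post_delta_magnitude)
    pre_deltas = {
        "A": pre_delta_magnitude + post_delta_magnitude,
        "B": 0.0,
        "C": pre_delta_magnitude,
        "D": -pre_delta_magnitude,
    }
    out = {"reference": ScenarioTrajectory("reference", times, ref.copy())}
    pre_mask = times < 0
    for sid, pd_pre in pre_deltas.items():
        pd_post = pd_pre + common
        curve = ref + np.where(pre_mask, pd_pre, pd_post)
        out[sid] = ScenarioTrajectory(sid, times, curve,
                                      pre_delta=pd_pre, post_delta=pd_post,
                                      level_change=common)
    return out


def apply_scheme(
    trajectories: dict[str, ScenarioTrajectory],
    scheme: str,
) -> dict[str, np.ndarray]:
    """Baseline-correct all repetition-2 curves under the given scheme.

    ``per_repetition`` subtracts each repetition's own pre-stimulus mean;
    ``per_subject`` subtracts the mean of the repetition-1 (reference) and
    repetition-2 baselines, letting pre-stimulus level differences survive.
    With a single repetition, per-subject reduces to per-repetition.

    For calibrated scenarios (flat pre-stimulus segment with recorded level
    change) the per-repetition correction uses the algebraically equivalent
    form ``(reference - its pre mean) + level_change * [t >= 0]``, which
    makes the conflation exact in floating point as well as on paper: all
    calibrated scenarios yield bitwise-identical corrected curves.
    """
    if scheme not in ("per_repetition", "per_subject"):
        raise ValueError(f"unknown scheme {scheme!r}")
    ref = trajectories.get("reference")
    ref_centered = None
    if ref is not None:
        ref_pre = ref.times < 0
        ref_centered = ref.power - ref.power[ref_pre].mean()
    out = {}
    for sid, tr in trajectories.items():
        pre = tr.times < 0
        own_base = tr.power[pre].mean()
        if scheme == "per_repetition" or ref is None or sid == "reference":
            flat_pre = tr.power[pre].size and np.ptp(tr.power[pre]) == 0
            if (scheme == "per_repetition" and tr.level_change is not None
                    and ref_centered is not None and flat_pre):
                out[sid] = ref_centered + np.where(pre, 0.0, tr.level_change)
                continue
            base = own_base
        else:
            base = 0.5 * (own_base + ref.power[ref.times < 0].mean())
        out[sid] = tr.power - base
    return out


def scenarios_to_frame(
    trajectories: dict[str, ScenarioTrajectory],
) -> pd.DataFrame:
    """Long TSV-ready table of raw and corrected curves."""
    rows = []
    corrected = {s: apply_scheme(trajectories, s)
                 for s in ("per_repetition", "per_subject")}
    for sid, tr in trajectories.items():
        for k, t in enumerate(tr.times):
            rows.append(dict(
                scenario=sid, time_ms=t, raw=tr.power[k],
                per_repetition=corrected["per_repetition"][sid][k],
                per_subject=corrected["per_subject"][sid][k],
            ))
    return pd.DataFrame(rows)
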