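"""Band/window power extraction and ERS/ERD under two baseline schemes.

Event-related synchronization (ERS) and desynchronization (ERD) compare
post-stimulus band power against a pre-stimulus baseline.  Two correction
schemes are computed side by side, both in log10 units on the
aperiodic-adjusted path:

per repetition
    ``ers_erd_rep = post_power_sr - baseline_sr`` — each sequence
    repetition's own pre-stimulus activity is adjusted to zero.  This is
    the conventional definition, but it conflates pre- and post-stimulus
    changes across repetitions.

per subject
    the *average baseline* over all repetitions of a stimulus sequence is
    subtracted instead: ``ers_erd_subj = post_power_sr - average_baseline``.
    The residual per-repetition baseline variation
    ``prestim_sr = baseline_sr - average_baseline`` is the zero-mean
    pre-stimulus activity term used as the mediator downstream.

The identity ``ers_erd_subj = ers_erd_rep + prestim_sr`` holds exactly.
A conventional (non-adjusted) dB variant ``10*log10(post/baseline)`` on
linear power is provided for sensitivity analyses.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import BandConfig
from .iaf import BandDefinition
from .spectral import SpectralTensor

__all__ = [
    "extract_band_power", "ers_erd_per_repetition", "ers_erd_conventional",
    "prestim_and_subject_scheme", "build_band_power_table",
]


def extract_band_power(
    tensor: SpectralTensor,
    band: tuple[float, float],
    window: tuple[float, float],
    channels: list[str],
    slab: int | None = None,
) -> np.ndarray | float:
    """Mean log power over channels x frequency bins x time bins.

    Bins are included when their center lies inside the closed interval.
    Returns a scalar for a single slab, else one value per slab.
    """
    fsel = (tensor.frequencies >= band[0] - 1e-9) & (
        tensor.frequencies <= band[1] + 1e-9)
    tsel = (tensor.times >= window[0] - 1e-9) & (
        tensor.times <= window[1] + 1e-9)
    ch_idx = [tensor.channels.index(c) for c in channels]
    if not fsel.any() or not tsel.any() or not ch_idx:
        raise ValueError("empty channel/frequency/time selection")
    sub = tensor.log_power[..., fsel, :][..., tsel]
    sub = sub[:, ch_idx] if slab is None else sub[slab, ch_idx]
    axes = tuple(range(sub.ndim - 3, sub.ndim))
    out = sub.mean(axis=axes)
    return float(out) if np.isscalar(out) or out.ndim == 0 else out


def ers_erd_per_repetition(post_power_sr, baseline_sr):
    """Log-domain ERS/ERD with each repetition's baseline adjusted to zero.

    Negative values mean desynchronization, positive synchronization.
    """
    return np.asarray(post_power_sr) - np.asarray(baseline_sr)


def ers_erd_conventional(post_linear, baseline_linear):
    """Conventional dB formula on linear (non-adjusted) power."""
    post = np.asarray(post_linear, dtype=float)
    base = np.asarray(baseline_linear, dtype=float)
    if np.any(post <= 0) or np.any(base <= 0):
        raise ValueError("conventional ERS/ERD requires positive linear power")
    return 10.0 * np.log10(post / base)


def prestim_and_subject_scheme(table: pd.DataFrame) -> pd.DataFrame:
    """Fill average_baseline, prestim_sr and ers_erd_subj per sequence.

    The average baseline is taken over a sequence's repetitions within each
    (subject, sequence, band, region) cell; single-repetition sequences are
    flagged in a ``single_repetition`` column.
    """
    table = table.copy()
    keys = [k for k in ("subject", "sequence", "band", "region")
            if k in table.columns]
    grp = table.groupby(keys)["baseline_sr"]
    table["average_baseline"] = grp.transform("mean")
    table["single_repetition"] = grp.transform("size") < 2
    table["prestim_sr"] = table["baseline_sr"] - table["average_baseline"]
    table["ers_erd_subj"] = table["post_power_sr"] - table["average_baseline"]
    return table


def build_band_power_table(
    tensor: SpectralTensor,
    iaf_tbl: pd.DataFrame,
    frontal_channels: list[str],
    parietal_channels: list[str],
    band_cfg: BandConfig | None = None,
    include_mask: np.ndarray | None = None,
) -> pd.DataFrame:
    """Long-format per-repetition band power with both baseline schemes.

    One row per (subject, sequence, repetition, band): theta on the
    mid-frontal region, alpha on the parietal region, each with the
    subject's IAF-relative band edges.  Subjects without a detected IAF and
    slabs excluded by ``include_mask`` (QC) are dropped.
    """
    band_cfg = band_cfg or BandConfig()
    iaf_map = iaf_tbl.set_index("subject")
    rows = []
    for slab, meta in tensor.meta.iterrows():
        if include_mask is not None and not include_mask[slab]:
            continue
        subject = meta["subject"]
        if subject not in iaf_map.index or not bool(
                iaf_map.loc[subject, "detected"]):
            continue
        iaf = float(iaf_map.loc[subject, "iaf"])
        bands = {
            "theta": ((iaf + band_cfg.theta_rel[0],
                       iaf + band_cfg.theta_rel[1]),
                      band_cfg.theta_window, "midfrontal", frontal_channels),
            "alpha": ((iaf + band_cfg.alpha_rel[0],
                       iaf + band_cfg.alpha_rel[1]),
                      band_cfg.alpha_window, "parietal", parietal_channels),
        }
        for band_name, (band, window, region, chans) in bands.items():
            post = extract_band_power(tensor, band, window, chans, slab=slab)
            base = extract_band_power(tensor, band, band_cfg.baseline_window,
                                      chans, slab=slab)
            rows.append(dict(
                subject=subject, group=meta.get("group", ""),
                sequence=meta.get("sequence", 1),
                repetition=meta["repetition"],
                band=band_name, region=region,
                post_power_sr=float(post), baseline_sr=float(base),
                ers_erd_rep=float(post - base),
            ))
    table = pd.DataFrame(rows)
    if table.empty:
        raise ValueError("band power table is empty "
                         "(no repetitions survived IAF/QC exclusion)")
    return prestim_and_subject_scheme(table)
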