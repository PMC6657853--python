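"""Electrophysiological observables: current traces, peaks, spread, reports.

The measured response is reported the way the electrophysiology literature
does: as the relative drop in circulating current,
R(t) = 100 * (j_dark - j(t)) / j_dark (percent of dark current), with the
scalar summaries t_peak (time of maximal drop), peak drop, undershoot depth
(most negative post-recovery excursion, i.e. current transiently above the
dark level), and, on the sliver, the longitudinal signal spread: the length
of the z-interval over which the cGMP drop exceeds 1/e of its maximum at
t_peak.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd


@dataclass
class CurrentTrace:
    """Total circulating current over time with its dark baseline."""

    times: np.ndarray     # s
    j: np.ndarray         # pA
    j_dark: float         # pA

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.j = np.asarray(self.j, dtype=float)
        if len(self.times) != len(self.j):
            raise ValueError("times and currents must have equal length")

    @property
    def rel_drop(self) -> np.ndarray:
        """100 * (j_dark - j(t)) / j_dark, percent of dark current."""
        return 100.0 * (self.j_dark - self.j) / self.j_dark

    def to_csv(self, path) -> None:
        pd.DataFrame({"time_s": self.times, "j_pA": self.j,
                      "rel_drop_pct": self.rel_drop}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "CurrentTrace":
        df = pd.read_csv(path)
        j = df["j_pA"].to_numpy()
        # j_dark follows from inverting the stored relative drop at the
        # sample with the largest |drop| for conditioning; falls back to j[0].
        drop = df["rel_drop_pct"].to_numpy()
        k = int(np.argmax(np.abs(drop)))
        j_dark = j[k] / (1.0 - drop[k] / 100.0) if abs(drop[k]) > 0 else j[0]
        return cls(times=df["time_s"].to_numpy(), j=j, j_dark=float(j_dark))


@dataclass(frozen=True)
class TraceSummary:
    t_peak: float                  # s, parabolic-interpolated
    peak_drop_pct: float           # max of R(t)
    peak_drop_pA: float            # max of j_dark - j(t)
    undershoot_pct: Optional[float]  # most negative sustained R after peak
    final_drop_pct: float

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _parabolic_peak(t: np.ndarray, y: np.ndarray):
    """Vertex of the parabola through the discrete maximum and neighbours."""
    k = int(np.argmax(y))
    if k == 0 or k == len(y) - 1:
        return float(t[k]), float(y[k])
    y0, y1, y2 = y[k - 1], y[k], y[k + 1]
    denom = y0 - 2.0 * y1 + y2
    if denom == 0.0:
        return float(t[k]), float(y[k])
    delta = 0.5 * (y0 - y2) / denom
    dt = t[k + 1] - t[k]
    return float(t[k] + delta * dt), float(y1 - 0.25 * (y0 - y2) * delta)


def summarize_trace(trace: CurrentTrace,
                    undershoot_threshold_pct: float = 1e-3,
                    undershoot_min_steps: int = 3) -> TraceSummary:
    """Scalar summaries of one response trace.

    Undershoot is flagged only when the relative drop stays below
    -``undershoot_threshold_pct`` for at least ``undershoot_min_steps``
    consecutive samples after the peak, to avoid solver-noise artifacts.
    """
    R = trace.rel_drop
    if len(R) < 3:
        raise ValueError("trace too short to summarize")
    if not np.all(np.isfinite(R)):
        raise ValueError("non-finite values in trace")
    t_peak, peak = _parabolic_peak(trace.times, R)
    k = int(np.argmax(R))
    under = None
    post = R[k:]
    below = post < -undershoot_threshold_pct
    run = 0
    for flag in below:
        run = run + 1 if flag else 0
        if run >= undershoot_min_steps:
            under = float(post.min())
            break
    return TraceSummary(
        t_peak=t_peak, peak_drop_pct=peak,
        peak_drop_pA=peak * trace.j_dark / 100.0,
        undershoot_pct=under, final_drop_pct=float(R[-1]))


def peak_drop_ratio(a: CurrentTrace, b: CurrentTrace) -> float:
    """Ratio of peak relative drops of two traces (a over b)."""
    return (summarize_trace(a).peak_drop_pct
            / summarize_trace(b).peak_drop_pct)


def current_from_state(cg_sliver, ca_sliver, nodal_areas, params,
                       sigma_cone: float) -> float:
    """Instantaneous circulating current from sliver concentrations (pA).

    Surface integral of the CNG channel current density (plus the exchanger
    density under the channel_plus_exchanger convention) over the
    channel-bearing sliver, using per-node area weights.  A spatially
    uniform state returns density times total area exactly.
    """
    from . import params as bp

    cg = np.maximum(np.asarray(cg_sliver, dtype=float), 0.0)
    areas = np.asarray(nodal_areas, dtype=float)
    if cg.shape != areas.shape:
        raise ValueError("sliver field and nodal areas must align")
    dens = bp.channel_current_density(cg, params, sigma_cone)
    if params.current_convention == "channel_plus_exchanger":
        ca = np.maximum(np.asarray(ca_sliver, dtype=float), 0.0)
        dens = dens + bp.exchanger_current_density(ca, params, sigma_cone)
    return float(areas @ dens)


# ---------------------------------------------------------------------------
# Spatial spread
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpreadMeasure:
    z: np.ndarray
    drop: np.ndarray
    spread: Optional[float]     # um; None when the profile has no drop


def signal_spread(z: Sequence[float], drop: Sequence[float]) -> SpreadMeasure:
    """Length of the contiguous z-interval where drop > peak/e.

    ``drop`` is the cGMP depletion profile (dark minus current value) along
    the sliver at the time of peak suppression; crossings of the 1/e level
    are located by linear interpolation around the global maximum.
    """
    z = np.asarray(z, dtype=float)
    drop = np.asarray(drop, dtype=float)
    k = int(np.argmax(drop))
    peak = drop[k]
    if peak <= 0.0:
        return SpreadMeasure(z=z, drop=drop, spread=None)
    level = peak / math.e

    def cross_left() -> float:
        for a in range(k - 1, -1, -1):
            if drop[a] < level:
                frac = (level - drop[a]) / (drop[a + 1] - drop[a])
                return z[a] + frac * (z[a + 1] - z[a])
        return float(z[0])

    def cross_right() -> float:
        for b in range(k + 1, len(z)):
            if drop[b] < level:
                frac = (level - drop[b - 1]) / (drop[b] - drop[b - 1])
                return z[b - 1] + frac * (z[b] - z[b - 1])
        return float(z[-1])

    z_lo = cross_left()
    z_hi = cross_right()
    return SpreadMeasure(z=z, drop=drop, spread=float(z_hi - z_lo))


# ---------------------------------------------------------------------------
# Cross-model comparison
# ---------------------------------------------------------------------------

def compare_models(traces: dict, reference: str = "hom",
                   plot_path=None) -> pd.DataFrame:
    """Tabulate peak drops, peak times and exaggeration factors vs a reference.

    ``traces`` maps label -> CurrentTrace (labels like "hom/tpr").  Factors
    are peak-drop ratios relative to the reference model in the same
    scenario.  Optionally writes a comparison figure.
    """
    rows = []
    summaries = {k: summarize_trace(v) for k, v in traces.items()}
    for key, s in summaries.items():
        model, _, scen = key.partition("/")
        ref_key = f"{reference}/{scen}" if scen else reference
        factor = (s.peak_drop_pct / summaries[ref_key].peak_drop_pct
                  if ref_key in summaries else np.nan)
        rows.append({"run": key, "model": model, "scenario": scen,
                     "t_peak_ms": 1e3 * s.t_peak,
                     "peak_drop_pct": s.peak_drop_pct,
                     "peak_drop_pA": s.peak_drop_pA,
                     "undershoot_pct": s.undershoot_pct,
                     "factor_vs_ref": factor})
    df = pd.DataFrame(rows)
    if plot_path is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 4))
        for key, tr in traces.items():
            ax.plot(tr.times, tr.rel_drop, label=key)
        ax.set_xlabel("time after flash (s)")
        ax.set_ylabel("relative current drop (%)")
        ax.axhline(0.0, color="k", lw=0.5)
        ax.legend(fontsize=8)
        fig.tight_layout()
        fig.savefig(plot_path, dpi=150)
        plt.close(fig)
    return df


def save_summary_json(path, **payload) -> None:
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        raise TypeError(f"cannot serialize {type(o)}")
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=default)
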