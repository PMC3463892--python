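"""Derived quantities: transients, trigger fluxes, NCX aggregates,
line-scan images and cross-scenario comparisons.

Trigger flux is the maximum rate of rise of a Ca transient,
d[Ca]/dt_max, estimated by central differences on the solver output
grid (noise-free, so no smoothing), excluding the first millisecond
after the voltage step.  NCX aggregates evaluate the full exchanger
equation at mask-averaged Ca per frame -- the whole-compartment average
for I_NCXglobal, the sub-sarcolemmal shell average for I_NCXsarc.

Cross-scenario ratios follow the experimental normalization: the L-type
flux and the global trigger flux are each normalized by their 0 mV
maxima (which coincide at ~15 ms), so the L-type "share" of the trigger
flux at +50 mV is the ratio of the two normalized maxima.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import fluxes as fx
from .solver import Trajectory


class ObservableError(ValueError):
    pass


@dataclass
class TransientSeries:
    time: np.ndarray   # ms
    ca: np.ndarray     # uM
    label: str

    def __post_init__(self):
        if self.time.shape != self.ca.shape:
            raise ObservableError("time/ca shape mismatch")


@dataclass
class TriggerFluxResult:
    time: np.ndarray       # ms (derivative grid)
    dcadt: np.ndarray      # uM/s
    max_value: float       # uM/s
    t_max: float           # ms
    label: str = ""


@dataclass
class NCXAggregate:
    time: np.ndarray
    global_flux: np.ndarray   # uM/s, exchanger at compartment-mean Ca
    subsarc_flux: np.ndarray  # uM/s, exchanger at shell-mean Ca

    @property
    def scale_ratio(self) -> float:
        """Ratio of peak magnitudes, sub-sarcolemmal over global."""
        return float(np.max(np.abs(self.subsarc_flux))
                     / np.max(np.abs(self.global_flux)))


@dataclass
class LinescanImage:
    image: np.ndarray        # (n_position, n_time) uM
    pixel_um: float
    pixel_ms: float
    positions: np.ndarray    # um along the scan line


def spatial_average(traj: Trajectory, mask: np.ndarray | str,
                    label: str = "") -> TransientSeries:
    """Volume-weighted mean free Ca per frame over a voxel mask.

    The dense whole-run series recorded by the solver are available as
    the strings "global" and "subsarc"; an explicit boolean mask is
    averaged over the stored field snapshots instead (coarser cadence).
    """
    if isinstance(mask, str):
        if mask == "global":
            return TransientSeries(traj.times, traj.global_ca.copy(),
                                   label or "global")
        if mask == "subsarc":
            return TransientSeries(traj.times, traj.subsarc_ca.copy(),
                                   label or "subsarc")
        raise ObservableError(f"unknown recorded mask '{mask}'")
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ObservableError("empty mask")
    if not traj.snapshots:
        raise ObservableError("trajectory has no field snapshots")
    t = np.array([s.time for s in traj.snapshots])
    ca = np.array([s.Ca[mask].mean() for s in traj.snapshots])
    return TransientSeries(t, ca, label or "custom")


def probe_series(traj: Trajectory, name: str) -> TransientSeries:
    """Dense series at a named probe (mouth, distal, spot_1p5, spot_5p3)."""
    if name not in traj.probe_ca:
        raise ObservableError(f"unknown probe '{name}'")
    return TransientSeries(traj.times, traj.probe_ca[name].copy(), name)


def trigger_flux(series: TransientSeries,
                 exclude_ms: float = 1.0) -> TriggerFluxResult:
    """Central-difference d[Ca]/dt (uM/s) and its maximum for t >
    ``exclude_ms`` (skipping the step discontinuity)."""
    if series.time.size < 3:
        raise ObservableError("need at least 3 samples")
    dt = float(series.time[1] - series.time[0])
    d = (series.ca[2:] - series.ca[:-2]) / (2.0 * dt) * 1e3  # uM/s
    t = series.time[1:-1]
    sel = t > exclude_ms
    if not sel.any():
        raise ObservableError("exclusion window leaves no samples")
    i = int(np.argmax(np.where(sel, d, -np.inf)))
    return TriggerFluxResult(time=t, dcadt=d, max_value=float(d[i]),
                             t_max=float(t[i]), label=series.label)


def ncx_aggregate(traj: Trajectory, ncx: fx.NCXParams,
                  allosteric: bool = True) -> NCXAggregate:
    """Exchanger equation evaluated at the compartment-averaged and
    shell-averaged Ca per frame, at the step potential, in uM/s."""
    prot = traj.protocol
    cond = prot.conditions(prot.step_V)
    g = fx.ncx_flux(traj.global_ca, cond, ncx, allosteric) * 1e3
    s = fx.ncx_flux(traj.subsarc_ca, cond, ncx, allosteric) * 1e3
    return NCXAggregate(time=traj.times, global_flux=g, subsarc_flux=s)


def linescan_image(traj: Trajectory) -> LinescanImage:
    """Kymograph of Ca along the scan line (position x time); no optical
    blurring is applied."""
    if traj.linescan.size == 0:
        raise ObservableError("trajectory recorded no line-scan samples")
    return LinescanImage(image=traj.linescan.T.copy(),
                         pixel_um=traj.grid.voxel_size,
                         pixel_ms=traj.dt_out,
                         positions=traj.probes.linescan_positions.copy())


def normalize_and_compare(traj_0mV: Trajectory,
                          traj_50mV: Trajectory | None = None,
                          traj_0mV_na0: Trajectory | None = None,
                          traj_50mV_na0: Trajectory | None = None) -> dict:
    """Headline cross-scenario ratios, all referenced to the 0 mV maxima
    per the experimental normalization.

    Returns a dict with (as available):
      trigger_ratio_50_over_0   -- % of the 0 mV global trigger flux
      lcc_share_50mV            -- % of the trigger flux carried by LCC
      na0_reduction_0mV         -- % drop of trigger max without Na_i
      na0_reduction_50mV
      mouth_over_global_0mV     -- fold
      distal_trigger_0mV        -- uM/s
    """
    out = {}
    trig0 = trigger_flux(spatial_average(traj_0mV, "global"))
    lcc0_max = float(np.max(traj_0mV.fluxes["lcc"]))
    if lcc0_max <= 0 or trig0.max_value <= 0:
        raise ObservableError("0 mV reference maxima must be positive")
    out["global_trigger_0mV"] = trig0.max_value
    out["t_max_trigger_0mV"] = trig0.t_max
    mouth0 = trigger_flux(probe_series(traj_0mV, "mouth"))
    out["mouth_trigger_0mV"] = mouth0.max_value
    out["mouth_over_global_0mV"] = mouth0.max_value / trig0.max_value
    out["distal_trigger_0mV"] = trigger_flux(
        probe_series(traj_0mV, "distal")).max_value
    out["spot_trigger_1p5_0mV"] = trigger_flux(
        probe_series(traj_0mV, "spot_1p5")).max_value
    out["spot_trigger_5p3_0mV"] = trigger_flux(
        probe_series(traj_0mV, "spot_5p3")).max_value
    if traj_50mV is not None:
        trig50 = trigger_flux(spatial_average(traj_50mV, "global"))
        out["global_trigger_50mV"] = trig50.max_value
        out["trigger_ratio_50_over_0"] = 100.0 * trig50.max_value / trig0.max_value
        # both time-courses normalized by their 0 mV maxima
        norm_lcc = np.max(traj_50mV.fluxes["lcc"]) / lcc0_max
        norm_trig = trig50.max_value / trig0.max_value
        out["lcc_share_50mV"] = 100.0 * norm_lcc / norm_trig
        out["distal_trigger_50mV"] = trigger_flux(
            probe_series(traj_50mV, "distal")).max_value
        out["mouth_trigger_50mV"] = trigger_flux(
            probe_series(traj_50mV, "mouth")).max_value
    if traj_0mV_na0 is not None:
        t = trigger_flux(spatial_average(traj_0mV_na0, "global"))
        out["na0_reduction_0mV"] = 100.0 * (1.0 - t.max_value / trig0.max_value)
    if traj_50mV_na0 is not None and traj_50mV is not None:
        t = trigger_flux(spatial_average(traj_50mV_na0, "global"))
        t50 = trigger_flux(spatial_average(traj_50mV, "global"))
        out["na0_reduction_50mV"] = 100.0 * (1.0 - t.max_value / t50.max_value)
        mouth = trigger_flux(probe_series(traj_50mV_na0, "mouth"))
        out["na0_mouth_reduction_50mV"] = 100.0 * (
            1.0 - mouth.max_value / out["mouth_trigger_50mV"])
    return out
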