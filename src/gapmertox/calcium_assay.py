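"""FLIPR calcium-oscillation traces: amplitude-threshold scoring, peak
counting, and sigmoidal concentration-response fits.

Primary cortical neurons loaded with a fluorescent calcium indicator show
spontaneous calcium oscillations; fluorescence is recorded at 1 reading/s.
The ASO-screening protocol records a 100 s baseline, 200 s after ASO
addition and, after a pause, a second 300 s read.  An average control spike
amplitude is established from untreated wells over the 300 s read; each 1-s
read whose signal increase exceeds 50% of that control amplitude scores 1,
and the per-well sum is expressed as percent of the untreated-control sum.
Low percent-of-control therefore means suppressed oscillations, the in
vitro correlate of acute in vivo neurotoxicity.

"Signal increase" is fluorescence above a per-trace baseline level,
estimated as the median of the 100-s baseline segment (the simplest
protocol-consistent reference; configurable).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple, Optional, Sequence

import numpy as np
import scipy.optimize
import scipy.signal

SEGMENTS = ("baseline", "post_addition", "second_read")


@dataclass(frozen=True)
class FliprProtocol:
    """Recording protocol: segment durations in seconds at 1 reading/s."""

    baseline_s: int = 100
    post_addition_s: int = 200
    second_read_s: int = 300

    @property
    def total_s(self) -> int:
        return self.baseline_s + self.post_addition_s + self.second_read_s

    def segment_slice(self, segment: str) -> slice:
        if segment == "baseline":
            return slice(0, self.baseline_s)
        if segment == "post_addition":
            return slice(self.baseline_s, self.baseline_s + self.post_addition_s)
        if segment == "second_read":
            return slice(self.baseline_s + self.post_addition_s, self.total_s)
        raise ValueError(f"unknown segment {segment!r}")


DEFAULT_PROTOCOL = FliprProtocol()


@dataclass
class FliprTrace:
    """A 1 Hz fluorescence time series for one well."""

    values: np.ndarray
    protocol: FliprProtocol = DEFAULT_PROTOCOL
    well: str = ""
    treatment: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("trace values must be 1-D")
        if len(self.values) != self.protocol.total_s:
            raise ValueError(
                f"trace length {len(self.values)} != protocol total "
                f"{self.protocol.total_s}"
            )
        if (self.values < 0).any():
            raise ValueError("fluorescence values must be non-negative")

    def segment(self, name: str) -> np.ndarray:
        return self.values[self.protocol.segment_slice(name)]

    @property
    def baseline_level(self) -> float:
        """Per-trace reference level: median of the baseline segment."""
        return float(np.median(self.segment("baseline")))

    def signal_increase(self, segment: str = "second_read") -> np.ndarray:
        """Fluorescence above the per-trace baseline level."""
        return self.segment(segment) - self.baseline_level


def _spike_amplitudes(
    trace: FliprTrace, segment: str, min_prominence: float
) -> np.ndarray:
    increase = trace.signal_increase(segment)
    peaks, _ = scipy.signal.find_peaks(increase, prominence=min_prominence)
    return increase[peaks]


class ControlReference(NamedTuple):
    """Control normalisation constants: mean spike amplitude and mean
    supra-threshold read count of untreated wells."""

    amplitude: float
    raw_sum: float


def control_amplitude(
    control_traces: Sequence[FliprTrace],
    segment: str = "second_read",
    min_prominence: float = 1.0,
) -> float:
    """Average control spike amplitude: mean over untreated wells of the
    mean baseline-subtracted spike height in the 300-s read.

    ``min_prominence`` (fluorescence units) is the spike-detection
    threshold; wells with no detected spike are skipped, and an error is
    raised if no control well shows any spike.
    """
    if not control_traces:
        raise ValueError("need at least one control trace")
    per_well = [
        amps.mean()
        for t in control_traces
        if (amps := _spike_amplitudes(t, segment, min_prominence)).size
    ]
    if not per_well:
        raise ValueError("no spikes detected in any control trace")
    return float(np.mean(per_well))


@dataclass(frozen=True)
class OscillationScore:
    """Amplitude-threshold oscillation score for one well."""

    raw_sum: int
    percent_of_control: float


def oscillation_score(
    trace: FliprTrace,
    control_amp: float,
    control_raw_sum: float,
    segment: str = "second_read",
) -> OscillationScore:
    """Score a trace: one point per 1-s read whose signal increase exceeds
    50% of the control amplitude, expressed as percent of the control sum."""
    if control_amp <= 0:
        raise ValueError("control amplitude must be positive")
    if control_raw_sum <= 0:
        raise ValueError("control raw sum must be positive")
    raw = int(np.sum(trace.signal_increase(segment) > 0.5 * control_amp))
    return OscillationScore(
        raw_sum=raw, percent_of_control=100.0 * raw / control_raw_sum
    )


def control_reference(
    control_traces: Sequence[FliprTrace],
    segment: str = "second_read",
    min_prominence: float = 1.0,
) -> ControlReference:
    """Normalisation constants from untreated wells: the average spike
    amplitude and the mean supra-threshold read count at that amplitude."""
    amp = control_amplitude(control_traces, segment, min_prominence)
    raw = float(
        np.mean(
            [
                np.sum(t.signal_increase(segment) > 0.5 * amp)
                for t in control_traces
            ]
        )
    )
    if raw <= 0:
        raise ValueError("control traces have no supra-threshold reads")
    return ControlReference(amplitude=amp, raw_sum=raw)


def count_peaks(
    trace: FliprTrace,
    window_s: int = 180,
    segment: str = "second_read",
    control_amp: Optional[float] = None,
    prominence_frac: float = 0.2,
    min_prominence: float = 1.0,
    min_separation_s: int = 2,
) -> int:
    """Count oscillation peaks in the first ``window_s`` seconds of a
    segment (default: a 3-min window of the second read).

    A peak is a local maximum with prominence at least
    ``prominence_frac * control_amp`` when a control amplitude is supplied,
    else ``min_prominence`` fluorescence units, and at least
    ``min_separation_s`` seconds from its neighbours.
    """
    seg = trace.signal_increase(segment)
    if window_s > len(seg):
        raise ValueError(
            f"window {window_s}s longer than segment ({len(seg)}s)"
        )
    prominence = (
        prominence_frac * control_amp if control_amp is not None else min_prominence
    )
    peaks, _ = scipy.signal.find_peaks(
        seg[:window_s], prominence=prominence, distance=min_separation_s
    )
    return int(len(peaks))


def percent_of_vehicle(treated_count: float, vehicle_count: float) -> float:
    """Peak count of a treated well as percent of the vehicle control."""
    if vehicle_count <= 0:
        raise ValueError("vehicle peak count must be positive")
    return 100.0 * treated_count / vehicle_count


@dataclass(frozen=True)
class DoseResponseFit:
    """Four-parameter logistic (variable-slope sigmoid) fit.

    response(c) = bottom + (top - bottom) / (1 + (ec50 / c) ** hill_slope)
    """

    top: float
    bottom: float
    ec50: float
    hill_slope: float
    residual_norm: float
    degenerate: bool = False


def four_parameter_logistic(
    c: np.ndarray, top: float, bottom: float, ec50: float, hill_slope: float
) -> np.ndarray:
    return bottom + (top - bottom) / (1.0 + (ec50 / c) ** hill_slope)


def fit_dose_response(
    concentrations: Sequence[float], responses: Sequence[float]
) -> DoseResponseFit:
    """Least-squares 4PL fit of percent-of-vehicle responses vs
    concentration.

    Initialisation is deterministic: top/bottom from the response extremes,
    EC50 at the geometric mean of the concentration range, slope 1.  EC50 is
    optimised on the log scale to keep it positive.  Constant responses are
    degenerate (top == bottom, EC50 undefined) and flagged rather than
    fitted.
    """
    c = np.asarray(concentrations, dtype=float)
    y = np.asarray(responses, dtype=float)
    if c.shape != y.shape or c.ndim != 1:
        raise ValueError("concentrations and responses must align")
    if len(c) < 5:
        raise ValueError("need at least 5 concentration points")
    if (c <= 0).any():
        raise ValueError("concentrations must be positive")
    if np.ptp(y) == 0:
        warnings.warn("constant responses: EC50 unidentifiable")
        return DoseResponseFit(
            top=float(y[0]),
            bottom=float(y[0]),
            ec50=float("nan"),
            hill_slope=float("nan"),
            residual_norm=0.0,
            degenerate=True,
        )

    def residuals(theta):
        top, bottom, log_ec50, slope = theta
        pred = bottom + (top - bottom) / (
            1.0 + np.exp(slope * (log_ec50 - np.log(c)))
        )
        return pred - y

    x0 = np.array(
        [y.max(), y.min(), np.log(np.sqrt(c.min() * c.max())), 1.0]
    )
    sol = scipy.optimize.least_squares(
        residuals, x0, method="lm", xtol=1e-15, ftol=1e-15, gtol=1e-15,
        max_nfev=10000,
    )
    if not sol.success:
        raise RuntimeError(
            f"dose-response fit did not converge: {sol.message} "
            f"(nfev={sol.nfev}, cost={sol.cost:.3g})"
        )
    top, bottom, log_ec50, slope = sol.x
    return DoseResponseFit(
        top=float(top),
        bottom=float(bottom),
        ec50=float(np.exp(log_ec50)),
        hill_slope=float(slope),
        residual_norm=float(np.linalg.norm(sol.fun)),
    )
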