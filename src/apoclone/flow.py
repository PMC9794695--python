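"""Ploidy inference from flow-cytometry histograms.

Peaks are local maxima of a moving-average-smoothed histogram above a
prominence floor.  Leaf nuclei are called diploid or tetraploid from the
ratio of the dominant G1 peak to a known 2C control channel; a sample showing
substantial G1 peaks at both ~1x and ~2x the control is a 2n/4n chimera.
Endosperm histograms are summarized as a base C-value (3C for sexual seed,
6C when both fusing gametes are unreduced) plus the endoreduplication
doubling series above it.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .core import FlowHistogram


@dataclass(frozen=True)
class PloidyCallParams:
    smooth_width: int = 5
    prominence_frac: float = 0.05  # of the smoothed maximum
    diploid_band: tuple[float, float] = (0.8, 1.2)
    tetraploid_band: tuple[float, float] = (1.7, 2.3)
    # smallest G1 population that makes a chimera: above the typical leaf
    # G2/M share (~10-15% of nuclei), below a genuine mixed-ploidy sector
    minor_fraction: float = 0.25
    debris_quantile: float = 0.1   # baseline estimate for peak mass
    gate_halfwidth: float = 0.2    # peak mass gate, as a fraction of the peak channel


@dataclass
class PloidyCall:
    sample_id: str
    peak_channels: np.ndarray
    peak_ratios: np.ndarray
    peak_fractions: np.ndarray
    call: str  # DIPLOID | TETRAPLOID | CHIMERIC_2N_4N | UNCALLED


def _smooth(counts: np.ndarray, width: int) -> np.ndarray:
    if width <= 1:
        return counts.astype(float)
    kernel = np.ones(width) / width
    return np.convolve(counts.astype(float), kernel, mode="same")


def detect_peaks(hist: FlowHistogram, params: PloidyCallParams = PloidyCallParams()
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Peak channels and the fraction of above-baseline nuclei under each.

    Mass is summed in a proportional gate (+/- ``gate_halfwidth`` of the peak
    channel, constant-CV instruments have channel-proportional peak widths)
    after subtracting a low-quantile baseline standing in for uniform debris.
    Gates are additionally bounded by midpoints between adjacent peaks.
    """
    y = _smooth(hist.counts, params.smooth_width)
    floor = params.prominence_frac * y.max() if y.max() > 0 else np.inf
    idx, _ = find_peaks(y, prominence=floor)
    if not len(idx):
        return np.empty(0, dtype=int), np.empty(0)
    baseline = np.quantile(y, params.debris_quantile)
    net = np.maximum(y - baseline, 0.0)
    bounds = np.concatenate([[0], (idx[:-1] + idx[1:]) // 2, [len(y)]])
    masses = np.empty(len(idx))
    for k, peak in enumerate(idx):
        a = max(int(bounds[k]), int(peak * (1.0 - params.gate_halfwidth)))
        b = min(int(bounds[k + 1]), int(np.ceil(peak * (1.0 + params.gate_halfwidth))) + 1)
        masses[k] = net[a:b].sum()
    total = masses.sum()
    fractions = masses / total if total > 0 else masses
    return hist.channels[idx], fractions


def call_ploidy(hist: FlowHistogram, control_2c_channel: float,
                params: PloidyCallParams = PloidyCallParams(),
                sample_id: str = "") -> PloidyCall:
    """Classify a leaf-nuclei histogram against a diploid 2C control channel."""
    if control_2c_channel <= 0:
        raise ValueError("control_2c_channel must be positive")
    channels, fractions = detect_peaks(hist, params)
    ratios = np.asarray(channels, dtype=float) / control_2c_channel
    if not len(channels):
        return PloidyCall(sample_id, channels, ratios, fractions, "UNCALLED")
    dlo, dhi = params.diploid_band
    tlo, thi = params.tetraploid_band
    in_d = (ratios >= dlo) & (ratios <= dhi)
    in_t = (ratios >= tlo) & (ratios <= thi)
    if (in_d & (fractions >= params.minor_fraction)).any() and \
       (in_t & (fractions >= params.minor_fraction)).any():
        call = "CHIMERIC_2N_4N"
    else:
        primary = int(np.argmax(fractions))
        r = ratios[primary]
        if dlo <= r <= dhi:
            call = "DIPLOID"
        elif tlo <= r <= thi:
            call = "TETRAPLOID"
        else:
            call = "UNCALLED"
    return PloidyCall(sample_id, np.asarray(channels), ratios, fractions, call)


def endosperm_profile(hist: FlowHistogram, control_2c_channel: float,
                      params: PloidyCallParams = PloidyCallParams()
                      ) -> tuple[int, list[int]]:
    """Base endosperm C-value and its endoreduplication series.

    The smallest detected peak fixes the base (3C or 6C, whichever is
    nearer); every peak matching a doubling of the base within 20% joins the
    series.
    """
    if control_2c_channel <= 0:
        raise ValueError("control_2c_channel must be positive")
    channels, _ = detect_peaks(hist, params)
    if not len(channels):
        raise ValueError("no peaks detected in endosperm histogram")
    cvals = 2.0 * np.sort(np.asarray(channels, dtype=float)) / control_2c_channel
    base = 3 if abs(cvals[0] - 3) <= abs(cvals[0] - 6) else 6
    series = []
    for k in range(0, 6):
        target = base * 2 ** k
        if np.any(np.abs(cvals / target - 1.0) <= 0.2):
            series.append(target)
    return base, series
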