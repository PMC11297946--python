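"""Small quantification utilities: postsynaptic currents and tracing counts.

* PSC amplitude: extremum of the chosen polarity in a short search window
  after the stimulus, relative to the mean of the 5 ms pre-stimulus
  baseline — the local baseline makes the second response of a
  paired-pulse protocol measurable even when it rides on the decay of the
  first.
* Paired-pulse ratio (PPR): second / first peak amplitude at a 50 ms
  inter-stimulus interval; a presynaptic release-probability proxy.
* Connectivity index for monosynaptic rabies tracing: the fraction of
  retrogradely labeled cells in a region, normalized by the starter-cell
  count.
* Layer profiles: retrograde cell counts binned by distance from the
  midline, normalized within each projector type to sum to 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

DEFAULT_SEARCH_MS = 20.0
DEFAULT_BASELINE_MS = 5.0
DEFAULT_ISI_MS = 50.0


@dataclass
class PSCMeasurement:
    amp1: float
    amp2: float
    stim_times_s: tuple[float, float]
    ppr: float


def psc_amplitude(trace: np.ndarray, rate: float, stim_s: float,
                  search_ms: float = DEFAULT_SEARCH_MS,
                  baseline_ms: float = DEFAULT_BASELINE_MS,
                  polarity: str = "negative") -> float:
    """Peak amplitude (pA) of a PSC after ``stim_s``, local-baseline referenced.

    ``polarity`` is "negative" for inward currents (EPSC at -70 mV) or
    "positive" for outward ones (IPSC at 0 mV). The returned amplitude is
    always reported as a positive magnitude.
    """
    trace = np.asarray(trace, float)
    i_stim = int(round(stim_s * rate))
    n_search = int(round(search_ms * 1e-3 * rate))
    n_base = int(round(baseline_ms * 1e-3 * rate))
    if i_stim - n_base < 0 or i_stim + n_search > trace.size:
        raise ValueError(
            f"search/baseline window around stim at {stim_s}s exceeds the trace")
    baseline = trace[i_stim - n_base:i_stim].mean()
    seg = trace[i_stim:i_stim + n_search] - baseline
    if polarity == "negative":
        return float(-seg.min())
    if polarity == "positive":
        return float(seg.max())
    raise ValueError(f"polarity must be 'negative' or 'positive', got {polarity!r}")


def ppr(trace: np.ndarray, rate: float, stim1_s: float, stim2_s: float,
        search_ms: float = DEFAULT_SEARCH_MS,
        polarity: str = "negative") -> PSCMeasurement:
    """Paired-pulse ratio amp2/amp1 from a two-stimulus sweep."""
    amp1 = psc_amplitude(trace, rate, stim1_s, search_ms, polarity=polarity)
    amp2 = psc_amplitude(trace, rate, stim2_s, search_ms, polarity=polarity)
    if amp1 == 0:
        raise ValueError("first PSC amplitude is zero; PPR undefined")
    return PSCMeasurement(amp1, amp2, (stim1_s, stim2_s), amp2 / amp1)


def average_sweeps(sweeps: np.ndarray) -> np.ndarray:
    """Mean across sweeps (rows) for averaged-amplitude measurement."""
    return np.asarray(sweeps, float).mean(axis=0)


def connectivity_index(region_counts: dict[str, int] | np.ndarray,
                       starter_count: int) -> dict[str, float] | np.ndarray:
    """(region count / total labeled) / starter cells, per region."""
    if starter_count <= 0:
        raise ValueError("starter_count must be > 0")
    if isinstance(region_counts, dict):
        counts = np.array(list(region_counts.values()), float)
    else:
        counts = np.asarray(region_counts, float)
    if (counts < 0).any():
        raise ValueError("counts must be nonnegative")
    total = counts.sum()
    if total <= 0:
        raise ValueError("total labeled count must be > 0")
    index = counts / total / starter_count
    if isinstance(region_counts, dict):
        return dict(zip(region_counts.keys(), index))
    return index


def layer_profile(counts_by_distance: np.ndarray) -> np.ndarray:
    """Normalize one projector's distance-binned counts to sum to 1."""
    counts = np.asarray(counts_by_distance, float)
    if (counts < 0).any():
        raise ValueError("counts must be nonnegative")
    total = counts.sum()
    if total <= 0:
        raise ValueError("projector has zero total count; profile undefined")
    return counts / total
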