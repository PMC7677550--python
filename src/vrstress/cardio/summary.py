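"""Per-segment cardiorespiratory summaries."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..core import RespSignal
from ..errors import InvalidArgumentError
from .metrics import heart_rate, hrv_ti, rmssd, sdnn
from .nn import NNSeries
from .respiration import respiration_rate

__all__ = ["CardioSummary", "segment_summary", "default_segments"]


@dataclass
class CardioSummary:
    """Summary metrics for one time segment."""

    hr: float  # bpm
    rmssd: float  # ms
    sdnn: float  # ms
    hrvti: float
    rr: float  # breaths/min
    segment: tuple[float, float]
    n_beats: int
    missing: bool = False


def default_segments(duration: float = 90.0, block: float = 30.0):
    """Consecutive equal blocks covering the recording (default 3 x 30 s)."""
    edges = np.arange(0.0, duration + 1e-9, block)
    return [(float(a), float(b)) for a, b in zip(edges[:-1], edges[1:])]


def segment_summary(
    nn: NNSeries,
    resp: RespSignal | None,
    segments: list[tuple[float, float]],
) -> list[CardioSummary]:
    """Summaries per segment; segments with < 3 usable intervals are flagged.

    An interval belongs to a segment when its onset beat lies inside it.
    """
    if not segments:
        raise InvalidArgumentError("segment list must be non-empty")
    for (a0, b0), (a1, b1) in zip(segments[:-1], segments[1:]):
        if a1 < b0 - 1e-9:
            raise InvalidArgumentError("segments must be non-overlapping")
    out = []
    for start, end in segments:
        if end <= start:
            raise InvalidArgumentError("segment end must exceed start")
        mask = (nn.onset_times >= start) & (nn.onset_times < end)
        x = nn.intervals[mask]
        rr = float("nan")
        if resp is not None:
            i0 = int(max(0, np.floor((start - resp.t0) * resp.fs)))
            i1 = int(min(resp.n, np.ceil((end - resp.t0) * resp.fs)))
            if (i1 - i0) / resp.fs >= 10.0:
                rr = respiration_rate(
                    RespSignal(samples=resp.samples[i0:i1], fs=resp.fs, t0=start)
                )
        if x.size < 3:
            out.append(
                CardioSummary(
                    hr=float("nan"),
                    rmssd=float("nan"),
                    sdnn=float("nan"),
                    hrvti=float("nan"),
                    rr=rr,
                    segment=(start, end),
                    n_beats=int(x.size) + (1 if x.size else 0),
                    missing=True,
                )
            )
            continue
        out.append(
            CardioSummary(
                hr=heart_rate(x),
                rmssd=rmssd(x),
                sdnn=sdnn(x),
                hrvti=hrv_ti(x),
                rr=rr,
                segment=(start, end),
                n_beats=int(x.size) + 1,
                missing=False,
            )
        )
    return out
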