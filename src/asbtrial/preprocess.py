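"""Transformation chain from raw TLQ scores to the modelled response.

A session is segmented into PRE (T1-T5), a transient probe (T6), ONLINE
(T7-T16, during which stimulation/picture blocks run) and POST (T17-T21).
Each segment is detrended against a fixed reference probe — T1 for PRE,
T5 (the last PRE probe) for the transient+ONLINE stretch, and T16 (the
last ONLINE probe) for POST — so each point measures cumulative change
within its segment.  The detrended series is then reversed in sign, so
that larger values mean a larger *reduction* in perceived loudness
("the more, the better"), and shifted to the positive axis by a constant
(default 5) for numerical convenience.  The result Y is the response
variable of the hierarchical model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import Dataset, RawTLQSeries, Treatment, N_TIMEPOINTS

DEFAULT_SHIFT = 5.0


@dataclass(frozen=True)
class SegmentScheme:
    """Partition of the 21 probes into segments with detrending references.

    ``pre``/``transient``/``online``/``post`` are 1-based time-point tuples;
    ``references`` maps each segment to the time point its raw values are
    differenced against.  The transient probe T6 shares the ONLINE
    reference (T5).
    """

    pre: tuple[int, ...] = tuple(range(1, 6))
    transient: tuple[int, ...] = (6,)
    online: tuple[int, ...] = tuple(range(7, 17))
    post: tuple[int, ...] = tuple(range(17, 22))
    references: dict = field(default_factory=lambda: {
        "pre": 1, "transient": 5, "online": 5, "post": 16})

    def __post_init__(self) -> None:
        points = sorted(self.pre + self.transient + self.online + self.post)
        if points != list(range(1, N_TIMEPOINTS + 1)):
            raise ValueError("segments must partition time points 1..21")
        for seg in ("pre", "transient", "online", "post"):
            ref = self.references[seg]
            first = min(getattr(self, seg))
            if ref > first:
                raise ValueError(
                    f"reference T{ref} must not follow the start of segment {seg}")

    def segment_of(self, j: int) -> str:
        for seg in ("pre", "transient", "online", "post"):
            if j in getattr(self, seg):
                return seg
        raise ValueError(f"timepoint {j} outside 1..{N_TIMEPOINTS}")

    def reference_of(self, j: int) -> int:
        return self.references[self.segment_of(j)]


DEFAULT_SCHEME = SegmentScheme()


@dataclass
class TransformedSeries:
    """The shifted reverse-detrended response Y actually modelled."""

    subject_id: str
    session_index: int
    treatment: Treatment
    start: int
    y: np.ndarray
    shift_constant: float = DEFAULT_SHIFT


def detrend(series: RawTLQSeries, scheme: SegmentScheme = DEFAULT_SCHEME) -> np.ndarray:
    """Difference each probe against its segment's reference probe."""
    raw = np.asarray(series.responses, dtype=float)
    refs = np.array([raw[scheme.reference_of(j) - 1] for j in range(1, N_TIMEPOINTS + 1)])
    return raw - refs


def reverse_and_shift(
    detrended: np.ndarray, shift_constant: float = DEFAULT_SHIFT
) -> np.ndarray:
    """Y_j = shift - d_j: larger Y means greater loudness reduction."""
    return shift_constant - np.asarray(detrended, dtype=float)


def transform_series(
    series: RawTLQSeries,
    scheme: SegmentScheme = DEFAULT_SCHEME,
    shift_constant: float = DEFAULT_SHIFT,
) -> TransformedSeries:
    y = reverse_and_shift(detrend(series, scheme), shift_constant)
    return TransformedSeries(series.subject_id, series.session_index,
                             series.treatment, series.start, y, shift_constant)


def transform_dataset(
    dataset: Dataset,
    scheme: SegmentScheme = DEFAULT_SCHEME,
    shift_constant: float = DEFAULT_SHIFT,
) -> list[TransformedSeries]:
    return [transform_series(s, scheme, shift_constant) for s in dataset.series]


def invert_transform(
    y: np.ndarray,
    raw_t1: float,
    scheme: SegmentScheme = DEFAULT_SCHEME,
    shift_constant: float = DEFAULT_SHIFT,
) -> np.ndarray:
    """Recover a raw series from Y given the raw value at T1.

    Proceeds segment by segment: raw_j = raw_ref - (Y_j - shift), where the
    reference raw values are themselves reconstructed in time order.  Exact
    inverse of ``transform_series`` for real-valued raw responses; the
    simulator composes it with rounding/clamping to produce Likert data.
    """
    y = np.asarray(y, dtype=float)
    raw = np.empty(N_TIMEPOINTS)
    raw[0] = raw_t1
    for j in range(1, N_TIMEPOINTS + 1):
        ref = scheme.reference_of(j)
        if j == ref:
            continue
        raw[j - 1] = raw[ref - 1] - (y[j - 1] - shift_constant)
    # reference points themselves: pre's reference is T1 (given); T5 and T16
    # are recovered from their own segments before being used, which the
    # time ordering above guarantees (5 in pre, 16 in online).
    return raw


def transformed_frame(
    dataset: Dataset,
    scheme: SegmentScheme = DEFAULT_SCHEME,
    shift_constant: float = DEFAULT_SHIFT,
) -> pd.DataFrame:
    """Tidy table of the dataset with an added ``y_transformed`` column."""
    df = dataset.to_frame()
    ys = []
    for s in dataset.series:
        ys.append(transform_series(s, scheme, shift_constant).y)
    df["y_transformed"] = np.concatenate(ys)
    return df
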