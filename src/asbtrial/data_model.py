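"""Domain types and I/O for longitudinal tinnitus-loudness (TLQ) crossover data.

The canonical exchange format is a tidy long table with one row per TLQ
probe: columns ``subject, session, treatment, timepoint, tlq[, minutes]``.
Each subject contributes up to three sessions (a three-period crossover),
each session being a 21-point trajectory of 1-10 Likert loudness scores
under one of three treatments:

* ``PEI`` — positive emotion induction alone (active control),
* ``SP``  — sham stimulation concurrent with PEI,
* ``tP``  — active HD-tDCS concurrent with PEI.

Posterior draws are exchanged as a long CSV (parameter, chain, iteration,
value) with a JSON metadata sidecar.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

N_TIMEPOINTS = 21
LIKERT_MIN, LIKERT_MAX = 1, 10


class Treatment(str, Enum):
    """The three crossover arms; PEI is the reference treatment."""

    PEI = "PEI"
    SP = "SP"
    TP = "tP"

    @classmethod
    def parse(cls, label: "str | Treatment") -> "Treatment":
        if isinstance(label, Treatment):
            return label
        for t in cls:
            if t.value.lower() == str(label).strip().lower():
                return t
        raise ValidationError(f"unknown treatment label {label!r}; expected one of "
                              f"{[t.value for t in cls]}")


#: The six treatment orderings of a Williams design for three treatments:
#: the union of two mutually orthogonal 3x3 Latin squares, i.e. all six
#: permutations of {PEI, SP, tP}.  Enumerated in a fixed order (rows of the
#: first square, then rows of its mirror) so that seeded assignment is
#: reproducible.
WILLIAMS_SEQUENCES: tuple[tuple[Treatment, Treatment, Treatment], ...] = (
    (Treatment.PEI, Treatment.SP, Treatment.TP),
    (Treatment.SP, Treatment.TP, Treatment.PEI),
    (Treatment.TP, Treatment.PEI, Treatment.SP),
    (Treatment.TP, Treatment.SP, Treatment.PEI),
    (Treatment.SP, Treatment.PEI, Treatment.TP),
    (Treatment.PEI, Treatment.TP, Treatment.SP),
)


class ValidationError(ValueError):
    """Raised when input data violate a structural invariant."""


@dataclass
class RawTLQSeries:
    """One subject-session trajectory of 21 raw Likert responses."""

    subject_id: str
    session_index: int
    treatment: Treatment
    responses: Sequence[int]
    probe_minutes: Sequence[float] | None = None

    def __post_init__(self) -> None:
        self.responses = [int(r) if float(r).is_integer() else float(r)
                          for r in self.responses]
        if len(self.responses) != N_TIMEPOINTS:
            raise ValidationError(
                f"subject {self.subject_id} session {self.session_index}: "
                f"expected {N_TIMEPOINTS} responses, got {len(self.responses)}")
        bad = [r for r in self.responses if not (LIKERT_MIN <= r <= LIKERT_MAX)]
        if bad:
            raise ValidationError(
                f"subject {self.subject_id} session {self.session_index}: "
                f"TLQ values outside [{LIKERT_MIN},{LIKERT_MAX}]: {bad}")
        if not isinstance(self.treatment, Treatment):
            self.treatment = Treatment.parse(self.treatment)
        if self.probe_minutes is not None and len(self.probe_minutes) != N_TIMEPOINTS:
            raise ValidationError("probe_minutes must have 21 entries when given")

    @property
    def start(self) -> int:
        """Baseline covariate: the raw response at T1."""
        return self.responses[0]


@dataclass
class Dataset:
    """A collection of raw series with per-subject treatment sequences."""

    series: list[RawTLQSeries]
    sequences: dict[str, tuple[Treatment, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: dict[str, set[int]] = {}
        treatments: dict[str, set[Treatment]] = {}
        for s in self.series:
            sess = seen.setdefault(s.subject_id, set())
            if s.session_index in sess:
                raise ValidationError(
                    f"subject {s.subject_id}: duplicate session {s.session_index}")
            sess.add(s.session_index)
            trts = treatments.setdefault(s.subject_id, set())
            if s.treatment in trts:
                raise ValidationError(
                    f"subject {s.subject_id}: treatment {s.treatment.value} "
                    "appears in more than one session")
            trts.add(s.treatment)
            if len(sess) > 3:
                raise ValidationError(f"subject {s.subject_id}: more than 3 sessions")

    @property
    def subjects(self) -> list[str]:
        out: list[str] = []
        for s in self.series:
            if s.subject_id not in out:
                out.append(s.subject_id)
        return out

    def __len__(self) -> int:
        return len(self.series)

    @property
    def n_observations(self) -> int:
        return len(self.series) * N_TIMEPOINTS

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.series:
            for j, y in enumerate(s.responses, start=1):
                row = {
                    "subject": s.subject_id,
                    "session": s.session_index,
                    "treatment": s.treatment.value,
                    "timepoint": j,
                    "tlq": y,
                }
                if s.probe_minutes is not None:
                    row["minutes"] = s.probe_minutes[j - 1]
                rows.append(row)
        return pd.DataFrame(rows)


@dataclass
class PosteriorDraws:
    """Named MCMC draws, one (chain, iteration) matrix per parameter."""

    draws: dict[str, np.ndarray]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.draws:
            raise ValidationError("PosteriorDraws requires at least one parameter")
        shapes = {p: np.asarray(v).shape for p, v in self.draws.items()}
        first = next(iter(shapes.values()))
        if len(first) != 2:
            raise ValidationError("draws must be (chain, iteration) matrices")
        for p, sh in shapes.items():
            if sh != first:
                raise ValidationError(
                    f"parameter {p!r} has shape {sh}, expected {first}")
        self.draws = {p: np.asarray(v, dtype=float) for p, v in self.draws.items()}
        for p, v in self.draws.items():
            if _is_variance_name(p) and np.any(v <= 0):
                raise ValidationError(
                    f"variance parameter {p!r} has non-positive draws")

    @property
    def parameters(self) -> list[str]:
        return list(self.draws)

    @property
    def n_chains(self) -> int:
        return next(iter(self.draws.values())).shape[0]

    @property
    def n_iterations(self) -> int:
        return next(iter(self.draws.values())).shape[1]

    def flat(self, parameter: str) -> np.ndarray:
        """All draws of one parameter pooled across chains."""
        return self.draws[parameter].reshape(-1)


def _is_variance_name(name: str) -> bool:
    return name.startswith(("sigma2", "lambda2"))


# ---------------------------------------------------------------------------
# TLQ table I/O


def read_tlq_long(path: str | Path) -> Dataset:
    """Read a tidy TLQ table and assemble a validated :class:`Dataset`.

    The file must be delimited text with header columns
    ``subject, session, treatment, timepoint, tlq`` (optionally ``minutes``).
    Rows are grouped into 21-point series sorted by time point; duplicate or
    missing time points and out-of-range scores raise :class:`ValidationError`
    naming the offending series.
    """
    df = pd.read_csv(path)
    required = {"subject", "session", "treatment", "timepoint", "tlq"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"missing columns: {sorted(missing)}")
    return dataset_from_frame(df)


def dataset_from_frame(df: pd.DataFrame) -> Dataset:
    series: list[RawTLQSeries] = []
    for (subj, sess), grp in df.groupby(["subject", "session"], sort=True):
        grp = grp.sort_values("timepoint")
        tps = grp["timepoint"].astype(int).tolist()
        dup = {t for t in tps if tps.count(t) > 1}
        if dup:
            raise ValidationError(
                f"subject {subj} session {sess}: duplicate timepoints {sorted(dup)}")
        missing = sorted(set(range(1, N_TIMEPOINTS + 1)) - set(tps))
        if missing:
            raise ValidationError(
                f"subject {subj} session {sess}: missing timepoints {missing}")
        trts = grp["treatment"].unique()
        if len(trts) != 1:
            raise ValidationError(
                f"subject {subj} session {sess}: mixed treatment labels {list(trts)}")
        tlq = grp["tlq"].tolist()
        bad = grp[(grp["tlq"] < LIKERT_MIN) | (grp["tlq"] > LIKERT_MAX)]
        if len(bad):
            first = bad.iloc[0]
            raise ValidationError(
                f"subject {subj} session {sess} timepoint {int(first['timepoint'])}: "
                f"tlq={first['tlq']} outside [{LIKERT_MIN},{LIKERT_MAX}]")
        minutes = grp["minutes"].tolist() if "minutes" in grp.columns else None
        series.append(RawTLQSeries(str(subj), int(sess), Treatment.parse(trts[0]),
                                   tlq, minutes))
    seqs: dict[str, tuple[Treatment, ...]] = {}
    for s in series:
        seqs.setdefault(s.subject_id, ())
    for subj in seqs:
        ordered = sorted((x for x in series if x.subject_id == subj),
                         key=lambda x: x.session_index)
        seqs[subj] = tuple(x.treatment for x in ordered)
    return Dataset(series, seqs)


def write_tlq_long(dataset: Dataset, path: str | Path) -> None:
    dataset.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Williams-design sequence assignment


def assign_williams_sequences(
    n_subjects: int, seed: int
) -> list[tuple[Treatment, Treatment, Treatment]]:
    """Assign each subject one of the six Williams orderings, balanced.

    The full set of six sequences is tiled until ``n_subjects`` assignments
    exist, so counts per ordering differ by at most one; the remainder is
    drawn square by square (rows of one Latin square before the other) so
    that each treatment also appears in each period position with counts
    differing by at most one.  The result is shuffled with the given seed;
    deterministic given the seed.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    rng = np.random.default_rng(seed)
    full, remainder = divmod(n_subjects, len(WILLIAMS_SEQUENCES))
    pool = list(WILLIAMS_SEQUENCES) * full
    square_a = list(WILLIAMS_SEQUENCES[:3])
    square_b = list(WILLIAMS_SEQUENCES[3:])
    rng.shuffle(square_a)
    rng.shuffle(square_b)
    squares = [square_a, square_b]
    rng.shuffle(squares)
    pool.extend((squares[0] + squares[1])[:remainder])
    rng.shuffle(pool)
    return pool


# ---------------------------------------------------------------------------
# Posterior draw I/O


def write_draws(draws: PosteriorDraws, path: str | Path) -> None:
    """Write draws as long CSV plus a JSON metadata sidecar (``<path>.meta.json``)."""
    path = Path(path)
    frames = []
    for p, mat in draws.draws.items():
        n_chain, n_iter = mat.shape
        frames.append(pd.DataFrame({
            "parameter": p,
            "chain": np.repeat(np.arange(n_chain), n_iter),
            "iteration": np.tile(np.arange(n_iter), n_chain),
            "value": mat.reshape(-1),
        }))
    pd.concat(frames, ignore_index=True).to_csv(
        path, index=False, float_format="%.17g")
    meta = dict(draws.metadata)
    meta["parameters"] = draws.parameters
    with open(f"{path}.meta.json", "w") as fh:
        json.dump(meta, fh, indent=2, default=str)


def read_draws(path: str | Path) -> PosteriorDraws:
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"parameter", "chain", "iteration", "value"}
    if required - set(df.columns):
        raise ValidationError(
            f"draw file missing columns {sorted(required - set(df.columns))}")
    draws: dict[str, np.ndarray] = {}
    for p, grp in df.groupby("parameter", sort=False):
        try:
            mat = grp.pivot(index="chain", columns="iteration", values="value")
        except ValueError as exc:  # duplicated (chain, iteration)
            raise ValidationError(f"malformed draws for parameter {p!r}: {exc}")
        if mat.isna().any().any():
            raise ValidationError(f"malformed draws for parameter {p!r}: missing cells")
        draws[str(p)] = mat.to_numpy()
    meta_path = Path(f"{path}.meta.json")
    metadata = {}
    if meta_path.exists():
        with open(meta_path) as fh:
            metadata = json.load(fh)
        metadata.pop("parameters", None)
    return PosteriorDraws(draws, metadata)
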