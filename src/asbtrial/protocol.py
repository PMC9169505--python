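"""Session-protocol compiler: TLQ schedule, picture blocks, Stroop task.

A session interleaves 21 TLQ loudness probes with four resting-state (rs)
blocks of neutral pictures, ten positive-emotion-induction (PEI) blocks
(two runs of five consecutive blocks), and two emotional Stroop tasks
(EST), one before and one after the intervention.  Each picture block
shows 20 pictures for 5 s each with a 500 ms cue; the ten PEI blocks are
probed every 2 minutes, which is what maps TLQ probe times to stimulation
dose.  tP sessions add a 20-minute 2 mA stimulation window with 30 s
ramps; SP sessions deliver the ramps only (sham).

Pictures come from a valence/arousal catalog on 1-9 rating scales
(emulating NAPS normative ratings): neutral pictures satisfy 4 < Vr < 6
and Ar < 6; positive pictures Vr > 6, of which the high-arousal subset
(Ar > 6) opens each PEI block.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

# fixed response-key mapping for the Stroop task
EST_KEYS = {"green": "Z", "yellow": "X", "blue": "N", "red": "M"}
EST_COLORS = tuple(EST_KEYS)

# default word lists (six tinnitus-descriptor words matched with six
# neutral Portuguese words)
NEUTRAL_WORDS = ("Garrafa", "Banheiro", "Luz", "Antigo", "Milho", "Patio")
EMOTIONAL_WORDS = ("Cigarra", "Campainha", "Tom", "Apito", "Grilo", "Radio")

SESSION_TYPES = ("PEI", "SP", "tP")

PICTURE_SECONDS = 5.0
CUE_SECONDS = 0.5
BLOCK_SECONDS = 20 * (PICTURE_SECONDS + CUE_SECONDS)  # 110 s of pictures
TLQ_SECONDS = 10.0
EST_SECONDS = 600.0  # up to 10 min
STIM_RAMP_SECONDS = 30.0
STIM_MINUTES = 20.0
PROBE_SPACING_SECONDS = 120.0  # online TLQ probes every 2 min


@dataclass(frozen=True)
class PictureCatalogEntry:
    picture_id: str
    valence: float
    arousal: float

    def __post_init__(self) -> None:
        if not (1 <= self.valence <= 9 and 1 <= self.arousal <= 9):
            raise ValueError(
                f"picture {self.picture_id}: ratings must lie in [1,9]")

    @property
    def neutral_eligible(self) -> bool:
        return 4 < self.valence < 6 and self.arousal < 6

    @property
    def positive_eligible(self) -> bool:
        return self.valence > 6

    @property
    def high_arousal_positive(self) -> bool:
        return self.valence > 6 and self.arousal > 6


def read_picture_catalog(path) -> list[PictureCatalogEntry]:
    """CSV with columns id, valence, arousal."""
    df = pd.read_csv(path)
    return [PictureCatalogEntry(str(r.id), float(r.valence), float(r.arousal))
            for r in df.itertuples()]


def make_synthetic_catalog(seed: int = 0, n_neutral: int = 100,
                           n_positive: int = 120,
                           n_high_arousal: int = 50) -> list[PictureCatalogEntry]:
    """Synthetic valence/arousal catalog with the strata the protocol needs.

    Stands in for a normative picture database, which cannot be
    redistributed; ratings are drawn uniformly inside each stratum.
    """
    rng = np.random.default_rng(seed)
    entries = []
    for i in range(n_neutral):
        entries.append(PictureCatalogEntry(
            f"neu{i:03d}", rng.uniform(4.2, 5.8), rng.uniform(1.5, 5.5)))
    for i in range(n_positive):
        entries.append(PictureCatalogEntry(
            f"pos{i:03d}", rng.uniform(6.2, 8.8), rng.uniform(1.5, 5.5)))
    for i in range(n_high_arousal):
        entries.append(PictureCatalogEntry(
            f"hav{i:03d}", rng.uniform(6.2, 8.8), rng.uniform(6.2, 8.8)))
    return entries


# ---------------------------------------------------------------------------
# picture blocks


def build_picture_blocks(catalog: list[PictureCatalogEntry],
                         seed: int = 0) -> dict:
    """Playlists: 4 rs blocks x 20 neutral; 10 PEI blocks of 4 HAV + 16 HV.

    The ten PEI blocks form two runs of five consecutive blocks; within
    each run the positive pictures are drawn without replacement from a
    100-picture positive pool.  Deterministic given the seed.
    """
    rng = np.random.default_rng(seed)
    neutral = [p for p in catalog if p.neutral_eligible]
    positive = [p for p in catalog if p.positive_eligible]
    hav = [p for p in positive if p.high_arousal_positive]
    if len(neutral) < 80:
        raise ValueError(f"need >= 80 neutral-eligible pictures, have {len(neutral)}")
    if len(positive) < 100:
        raise ValueError(f"need a 100-picture positive pool, have {len(positive)}")
    if len(hav) < 40:
        raise ValueError(f"need >= 40 high-arousal positive pictures, have {len(hav)}")
    neutral_ids = [p.picture_id for p in neutral]
    rs_pick = rng.choice(len(neutral_ids), size=80, replace=False)
    rs_blocks = [[neutral_ids[i] for i in rs_pick[20 * b:20 * (b + 1)]]
                 for b in range(4)]
    # a fixed 100-picture positive set for the session
    pool_idx = rng.choice(len(positive), size=100, replace=False)
    pool = [positive[i] for i in pool_idx]
    hav_in_pool = [p for p in pool if p.high_arousal_positive]
    if len(hav_in_pool) < 20:
        raise ValueError(
            f"positive pool holds only {len(hav_in_pool)} high-arousal "
            "pictures; 20 are needed per 5-block run")
    pei_blocks = []
    for run in range(2):  # 2 x 5 consecutive PEI blocks, pool reused per run
        lead_idx = rng.choice(len(hav_in_pool), size=20, replace=False)
        leads = [hav_in_pool[i] for i in lead_idx]
        rest = [p for p in pool if p not in leads]
        rest_order = rng.permutation(len(rest))[:80]
        rest = [rest[i] for i in rest_order]
        for b in range(5):
            block = leads[4 * b:4 * (b + 1)] + rest[16 * b:16 * (b + 1)]
            pei_blocks.append([p.picture_id for p in block])
    return {"rs_blocks": rs_blocks, "pei_blocks": pei_blocks}


# ---------------------------------------------------------------------------
# emotional Stroop sequence


@dataclass(frozen=True)
class ESTTrial:
    stimulus: str
    category: str  # "neutral", "emotional" or "xxxx"
    color: str
    correct_key: str
    max_duration_s: float = 4.0
    cue_s: float = 0.5


def build_est_sequence(neutral_words=NEUTRAL_WORDS,
                       emotional_words=EMOTIONAL_WORDS,
                       seed: int = 0) -> list[ESTTrial]:
    """144-trial emotional Stroop sequence.

    Each of the 6+6 words appears four times in random order and random
    colors (48 word trials); every word trial is followed by two
    consecutive XXXX-string trials (96 filler trials) to wash out
    emotional carry-over.
    """
    if len(neutral_words) != 6 or len(emotional_words) != 6:
        raise ValueError("exactly six neutral and six emotional words required")
    rng = np.random.default_rng(seed)
    words = ([(w, "neutral") for w in neutral_words]
             + [(w, "emotional") for w in emotional_words]) * 4
    order = rng.permutation(len(words))
    trials: list[ESTTrial] = []
    for i in order:
        word, category = words[i]
        for stim, cat in ((word, category), ("XXXX", "xxxx"), ("XXXX", "xxxx")):
            color = EST_COLORS[rng.integers(len(EST_COLORS))]
            trials.append(ESTTrial(stim, cat, color, EST_KEYS[color]))
    return trials


# ---------------------------------------------------------------------------
# session schedule


@dataclass(frozen=True)
class ScheduleEvent:
    kind: str  # TLQ, rs_block, PEI_block, EST, stim_on, stim_off
    label: str
    start_s: float
    duration_s: float

    @property
    def end_s(self) -> float:
        return self.start_s + self.duration_s


@dataclass
class SessionSchedule:
    session_type: str
    events: list[ScheduleEvent] = field(default_factory=list)

    def of_kind(self, kind: str) -> list[ScheduleEvent]:
        return [e for e in self.events if e.kind == kind]

    @property
    def tlq_times(self) -> list[float]:
        return [e.start_s for e in self.of_kind("TLQ")]


def build_session_schedule(session_type: str, seed: int = 0) -> SessionSchedule:
    """Compile the canonical event list for one session.

    PRE: T1, rs1, T2, EST1, T3, rs2, T4, T5; ONLINE: T6 at the first PEI
    block onset, then a probe after each of the ten 2-minute blocks
    (T7-T16); POST: rs3 (T17, T18), EST2 (T19), rs4 (T20, T21).  tP
    sessions get a stim_on/stim_off pair spanning the ten PEI blocks
    (20 min plus 30 s ramps); SP sessions get ramp-only sham events.
    """
    if session_type not in SESSION_TYPES:
        raise ValueError(f"session_type must be one of {SESSION_TYPES}")
    sched = SessionSchedule(session_type)
    t = 0.0
    tlq_no = 0

    def add(kind: str, duration: float, label: str | None = None) -> None:
        nonlocal t, tlq_no
        if kind == "TLQ":
            tlq_no += 1
            label = f"T{tlq_no}"
        sched.events.append(ScheduleEvent(kind, label or kind, t, duration))
        t += duration

    # PRE ------------------------------------------------------------------
    add("TLQ", TLQ_SECONDS)            # T1
    add("rs_block", BLOCK_SECONDS, "rs1")
    add("TLQ", TLQ_SECONDS)            # T2
    add("EST", EST_SECONDS, "EST1")
    add("TLQ", TLQ_SECONDS)            # T3
    add("rs_block", BLOCK_SECONDS, "rs2")
    add("TLQ", TLQ_SECONDS)            # T4
    add("TLQ", TLQ_SECONDS)            # T5
    # ONLINE ---------------------------------------------------------------
    if session_type in ("tP", "SP"):
        ramp_tag = "ramp only (sham)" if session_type == "SP" else "2 mA active"
        sched.events.append(ScheduleEvent("stim_on", ramp_tag, t, STIM_RAMP_SECONDS))
    add("TLQ", TLQ_SECONDS)            # T6 at online onset, dose 0
    online_t0 = t
    for b in range(10):
        start = online_t0 + b * PROBE_SPACING_SECONDS
        sched.events.append(ScheduleEvent("PEI_block", f"PEI{b + 1}",
                                          start, BLOCK_SECONDS))
        tlq_no += 1
        sched.events.append(ScheduleEvent("TLQ", f"T{tlq_no}",
                                          start + BLOCK_SECONDS, TLQ_SECONDS))
    t = online_t0 + 10 * PROBE_SPACING_SECONDS
    if session_type in ("tP", "SP"):
        sched.events.append(ScheduleEvent(
            "stim_off", "ramp down", t, STIM_RAMP_SECONDS))
        t += STIM_RAMP_SECONDS
    # POST -----------------------------------------------------------------
    add("TLQ", TLQ_SECONDS)            # T17
    add("rs_block", BLOCK_SECONDS, "rs3")
    add("TLQ", TLQ_SECONDS)            # T18
    add("EST", EST_SECONDS, "EST2")
    add("TLQ", TLQ_SECONDS)            # T19
    add("rs_block", BLOCK_SECONDS, "rs4")
    add("TLQ", TLQ_SECONDS)            # T20
    add("TLQ", TLQ_SECONDS)            # T21
    return sched


def schedule_frame(schedule: SessionSchedule) -> pd.DataFrame:
    return pd.DataFrame([{
        "kind": e.kind, "label": e.label, "start_s": e.start_s,
        "duration_s": e.duration_s} for e in schedule.events])
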