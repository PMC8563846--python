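"""Randomized trial sequences for the four experiments.

Experiment 1 presents 350 two-second targets per session, 50 at each
spectral slope in {-2, -1, -0.5, 0, +0.5, +1, +2} dB/oct, in random
order.  Experiment 2 interleaves 150 adaptor trials (slopes ±1 dB/oct,
durations 1/2/4/8 s) with 150 two-second targets (slopes -1/0/+1),
300 trials total.  Experiment 3 repeats the Exp. 1 design with the
whole slope set shifted ±1 dB/oct in two separate sessions.
Experiment 4 replaces slopes with transfer-function morph levels in
[-0.5, 1.5], six levels per session and 50 trials per level, with two
overlapping context ranges analogous to Exp. 3.

Hard constraints respected by every design: no excerpt appears twice
within a session, speech sessions never present the same speaker on
consecutive trials, and per-level trial counts are exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .audio import AudioExcerpt

EXP1_SLOPES = (-2.0, -1.0, -0.5, 0.0, 0.5, 1.0, 2.0)
EXP2_TARGET_SLOPES = (-1.0, 0.0, 1.0)
EXP2_ADAPTOR_SLOPES = (-1.0, 1.0)
EXP2_ADAPTOR_DURATIONS_S = (1.0, 2.0, 4.0, 8.0)
EXP4_MORPHS = {
    "device_context": (-0.5, -0.25, 0.0, 0.25, 0.5, 0.75),
    "openear_context": (0.25, 0.5, 0.75, 1.0, 1.25, 1.5),
}
TRIALS_PER_LEVEL = 50

DESIGN_COLUMNS = ["session_id", "experiment_id", "context", "domain",
                  "index_n", "role", "coloration", "duration_s", "excerpt_id"]


@dataclass(frozen=True)
class Trial:
    """One stimulus presentation within a session (1-based ``index_n``)."""

    index_n: int
    role: str                  # "target" | "adaptor"
    coloration: float          # slope in dB/oct (Exps. 1-3) or morph level (Exp. 4)
    duration_s: float
    excerpt_id: str
    session_id: str
    experiment_id: str
    speaker_id: str | None = None


@dataclass
class SessionDesign:
    trials: list[Trial]
    context: str               # none | shift_minus_1 | shift_plus_1 | device_context | openear_context
    domain: str
    session_id: str
    experiment_id: str
    levels: tuple[float, ...] = field(default=())

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([
            {"session_id": t.session_id, "experiment_id": t.experiment_id,
             "context": self.context, "domain": self.domain, "index_n": t.index_n,
             "role": t.role, "coloration": t.coloration, "duration_s": t.duration_s,
             "excerpt_id": t.excerpt_id}
            for t in self.trials
        ], columns=DESIGN_COLUMNS)


def design_to_csv(design: SessionDesign, path) -> None:
    design.to_frame().to_csv(path, index=False)


def _eligible(corpus, domain: str, duration_s: float | None) -> list[AudioExcerpt]:
    """Domain filter; music excerpts must additionally match the duration exactly
    (speech durations are naturally variable and all eligible)."""
    out = [e for e in corpus if e.domain == domain]
    if duration_s is not None and domain == "music":
        out = [e for e in out if e.duration_s == duration_s]
    return out


def _sample_excerpts(pool: list[AudioExcerpt], n: int, rng: np.random.Generator,
                     what: str) -> list[AudioExcerpt]:
    if len(pool) < n:
        raise ValueError(f"corpus too small: {what} requires {n} excerpts, have {len(pool)}")
    idx = rng.choice(len(pool), size=n, replace=False)
    return [pool[i] for i in idx]


def _order_without_speaker_repeats(excerpts: list[AudioExcerpt],
                                   rng: np.random.Generator,
                                   max_restarts: int = 100) -> list[AudioExcerpt]:
    """Random order with no two consecutive excerpts by the same speaker."""
    items = list(excerpts)
    for _ in range(max_restarts):
        rng.shuffle(items)
        ok = True
        for i in range(1, len(items)):
            if items[i].speaker_id == items[i - 1].speaker_id:
                # swap in a later excerpt from a different speaker
                for j in range(i + 1, len(items)):
                    if (items[j].speaker_id != items[i - 1].speaker_id
                            and (i + 1 >= len(items)
                                 or items[j].speaker_id != items[i + 1].speaker_id)):
                        items[i], items[j] = items[j], items[i]
                        break
                else:
                    ok = False
                    break
        if ok:
            return items
    raise ValueError("could not order excerpts without speaker repeats")


def _slope_session(experiment_id: str, session_id: str, domain: str, corpus,
                   slopes, context: str, seed: int) -> SessionDesign:
    rng = np.random.default_rng(seed)
    n_trials = TRIALS_PER_LEVEL * len(slopes)
    levels = np.repeat(slopes, TRIALS_PER_LEVEL)
    rng.shuffle(levels)
    pool = _eligible(corpus, domain, 2.0)
    chosen = _sample_excerpts(pool, n_trials, rng, f"{experiment_id} ({domain})")
    if domain == "speech":
        chosen = _order_without_speaker_repeats(chosen, rng)
    trials = [
        Trial(i + 1, "target", float(levels[i]), chosen[i].duration_s,
              chosen[i].excerpt_id, session_id, experiment_id,
              speaker_id=chosen[i].speaker_id)
        for i in range(n_trials)
    ]
    return SessionDesign(trials, context, domain, session_id, experiment_id,
                         levels=tuple(slopes))


def design_exp1(domain: str, corpus, seed: int, session_id: str | None = None
                ) -> SessionDesign:
    """Exp. 1: 350 two-second targets, 50 per slope in the standard set."""
    if domain not in ("music", "speech"):
        raise ValueError(f"domain must be 'music' or 'speech', got {domain!r}")
    return _slope_session("exp1", session_id or f"exp1-{domain}-{seed}", domain,
                          corpus, EXP1_SLOPES, "none", seed)


def design_exp3(corpus, context: str, seed: int, session_id: str | None = None
                ) -> SessionDesign:
    """Exp. 3: Exp. 1 slope set shifted by -1 or +1 dB/oct (music only)."""
    shifts = {"shift_minus_1": -1.0, "shift_plus_1": 1.0}
    if context not in shifts:
        raise ValueError(f"context must be one of {sorted(shifts)}, got {context!r}")
    slopes = tuple(s + shifts[context] for s in EXP1_SLOPES)
    return _slope_session("exp3", session_id or f"exp3-{context}-{seed}", "music",
                          corpus, slopes, context, seed)


def design_exp2(corpus, seed: int, session_id: str | None = None,
                balanced: bool = True) -> SessionDesign:
    """Exp. 2: adaptor/target interleaving, 300 trials.

    Odd positions are adaptors (slope ±1 dB/oct, durations 1/2/4/8 s in
    near-equal counts), even positions are 2-s targets (slopes -1/0/+1,
    50 each).  With ``balanced=False`` the adaptor slope and duration
    are drawn independently at random instead of exactly balanced.
    """
    session_id = session_id or f"exp2-{seed}"
    rng = np.random.default_rng(seed)
    n_pairs = TRIALS_PER_LEVEL * len(EXP2_TARGET_SLOPES)  # 150

    target_slopes = np.repeat(EXP2_TARGET_SLOPES, TRIALS_PER_LEVEL)
    rng.shuffle(target_slopes)
    if balanced:
        adaptor_slopes = np.repeat(EXP2_ADAPTOR_SLOPES, n_pairs // 2)
        rng.shuffle(adaptor_slopes)
        base, extra = divmod(n_pairs, len(EXP2_ADAPTOR_DURATIONS_S))
        counts = [base + (1 if i < extra else 0) for i in range(len(EXP2_ADAPTOR_DURATIONS_S))]
        adaptor_durs = np.repeat(EXP2_ADAPTOR_DURATIONS_S, counts)
        rng.shuffle(adaptor_durs)
    else:
        adaptor_slopes = rng.choice(EXP2_ADAPTOR_SLOPES, size=n_pairs)
        adaptor_durs = rng.choice(EXP2_ADAPTOR_DURATIONS_S, size=n_pairs)

    pools = {}
    for d in EXP2_ADAPTOR_DURATIONS_S:
        pools[d] = [e for e in corpus if e.domain == "music" and e.duration_s == d]
        need = int(np.sum(adaptor_durs == d)) + (n_pairs if d == 2.0 else 0)
        if len(pools[d]) < need:
            raise ValueError(
                f"corpus too small: need {need} music excerpts of {d} s, have {len(pools[d])}"
            )
        rng.shuffle(pools[d])

    trials = []
    for p in range(n_pairs):
        adaptor_exc = pools[float(adaptor_durs[p])].pop()
        trials.append(Trial(2 * p + 1, "adaptor", float(adaptor_slopes[p]),
                            float(adaptor_durs[p]), adaptor_exc.excerpt_id,
                            session_id, "exp2"))
        target_exc = pools[2.0].pop()
        trials.append(Trial(2 * p + 2, "target", float(target_slopes[p]), 2.0,
                            target_exc.excerpt_id, session_id, "exp2"))
    return SessionDesign(trials, "none", "music", session_id, "exp2",
                         levels=EXP2_TARGET_SLOPES)


def design_exp4(corpus, tf_pair, context: str, seed: int,
                session_id: str | None = None) -> SessionDesign:
    """Exp. 4: 300 two-second targets, 50 per morph level, per-context grid."""
    if context not in EXP4_MORPHS:
        raise ValueError(f"context must be one of {sorted(EXP4_MORPHS)}, got {context!r}")
    if tf_pair is None:
        raise ValueError("a transfer-function pair is required for Exp. 4")
    rng = np.random.default_rng(seed)
    morphs = EXP4_MORPHS[context]
    levels = np.repeat(morphs, TRIALS_PER_LEVEL)
    rng.shuffle(levels)
    pool = _eligible(corpus, "music", 2.0)
    chosen = _sample_excerpts(pool, len(levels), rng, "exp4")
    session_id = session_id or f"exp4-{context}-{seed}"
    trials = [
        Trial(i + 1, "target", float(levels[i]), 2.0, chosen[i].excerpt_id,
              session_id, "exp4")
        for i in range(len(levels))
    ]
    return SessionDesign(trials, context, "music", session_id, "exp4", levels=morphs)
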