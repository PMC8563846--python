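"""Adaptive decision-criterion model of brightness judgments.

On every trial n the virtual listener answers *bright* iff the spectral
centroid of the current stimulus exceeds a criterion

    c[n] = alpha * med({SC of the trials in the last L seconds})
         + (1 - alpha) * med({long-term reference SCs}),

where the short-term window walks backward over whole previous trials
while their accumulated stimulus duration (silences excluded) is below
the integration length L, always containing at least trial n-1 and
never trial n itself.  ``alpha = 1`` gives the pure short-term (ST)
model, ``alpha = 0`` the pure long-term (LT) model, ``alpha = 0.5`` the
mean of the two (ST+LT).  A lapse rate flips the criterion-indicated
response on a small fraction of trials, modelling attention/internal
noise.  Ties (SC exactly equal to the criterion) count as *dull*.

The very first trial has no history; by default the model emits no
response there (it is excluded from aggregation), optionally a random
one (``first_trial_policy="chance"``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import SessionDesign

LT_MODES = ("session_median", "unprocessed_domain_median")
FIRST_TRIAL_POLICIES = ("skip", "chance")

RESPONSE_BRIGHT = "bright"
RESPONSE_DULL = "dull"
RESPONSE_NONE = "none"


@dataclass(frozen=True)
class DecisionModelParams:
    """Fully specifies a virtual listener.

    Parameters
    ----------
    alpha
        Weight of the short-term criterion, in [0, 1].
    integration_length_s
        L, the stimulus time (s) spanned by the short-term window.
    lapse_rate
        Probability of flipping the criterion-indicated response.
    lt_mode
        ``"session_median"`` — the long-term term is the median SC over
        all N trials of the session (as in the mixed criterion);
        ``"unprocessed_domain_median"`` — a fixed reference, the median
        SC of the unfiltered corpus for the stimulus domain (requires
        ``lt_reference_hz``).
    first_trial_policy
        ``"skip"`` (no response on trial 1) or ``"chance"``.
    lt_reference_hz
        The fixed long-term reference SC, used only with
        ``lt_mode="unprocessed_domain_median"``.
    """

    alpha: float = 1.0
    integration_length_s: float = 16.0
    lapse_rate: float = 0.05
    lt_mode: str = "session_median"
    first_trial_policy: str = "skip"
    lt_reference_hz: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must be in [0, 1], got {self.alpha}")
        if self.integration_length_s <= 0:
            raise ValueError("integration_length_s must be > 0")
        if not 0.0 <= self.lapse_rate < 0.5:
            raise ValueError(f"lapse_rate must be in [0, 0.5), got {self.lapse_rate}")
        if self.lt_mode not in LT_MODES:
            raise ValueError(f"lt_mode must be one of {LT_MODES}, got {self.lt_mode!r}")
        if self.first_trial_policy not in FIRST_TRIAL_POLICIES:
            raise ValueError(
                f"first_trial_policy must be one of {FIRST_TRIAL_POLICIES}, "
                f"got {self.first_trial_policy!r}"
            )
        if self.lt_mode == "unprocessed_domain_median" and self.lt_reference_hz is None:
            raise ValueError("lt_mode='unprocessed_domain_median' requires lt_reference_hz")


@dataclass
class SessionHistory:
    """Per-trial SCs and stimulus durations of one session, in trial order."""

    sc_by_trial: np.ndarray
    durations_s: np.ndarray

    def __post_init__(self) -> None:
        self.sc_by_trial = np.asarray(self.sc_by_trial, dtype=float)
        self.durations_s = np.asarray(self.durations_s, dtype=float)
        if self.sc_by_trial.shape != self.durations_s.shape:
            raise ValueError("sc_by_trial and durations_s must have equal length")
        if np.any(self.durations_s <= 0):
            raise ValueError("stimulus durations must be positive")

    @property
    def n_trials(self) -> int:
        return len(self.sc_by_trial)


@dataclass(frozen=True)
class ResponseRecord:
    index_n: int
    response: str              # bright | dull | none
    criterion_hz: float | None  # None when no criterion was evaluated
    lapsed: bool


class EmptyWindowError(ValueError):
    """Raised when the short-term window is requested on the first trial."""


def st_window(history: SessionHistory, n: int, L: float) -> np.ndarray:
    """SCs of the trials within the last ``L`` seconds of stimulus time.

    Walks backward from trial ``n-1`` while the running sum of stimulus
    durations is still below ``L``; always includes at least trial
    ``n-1``, never the current trial.  ``n`` is 1-based.
    """
    if n < 2:
        raise EmptyWindowError("trial 1 has no history for a short-term window")
    if n > history.n_trials + 1:
        raise ValueError(f"trial index {n} beyond history of {history.n_trials}")
    total = 0.0
    first = n - 1                              # 1-based index of earliest included trial
    for i in range(n - 1, 0, -1):
        if total >= L:
            break
        first = i
        total += history.durations_s[i - 1]
    return history.sc_by_trial[first - 1 : n - 1]


def decision_criterion(history: SessionHistory, n: int,
                       params: DecisionModelParams) -> float:
    """Eq.-style weighted sum of the ST-window median and the LT median."""
    if params.lt_mode == "session_median":
        lt = float(np.median(history.sc_by_trial))
    else:
        lt = float(params.lt_reference_hz)
    if params.alpha == 0.0:
        return lt
    st = float(np.median(st_window(history, n, params.integration_length_s)))
    return params.alpha * st + (1.0 - params.alpha) * lt


def respond(sc_n: float, criterion_hz: float, lapse_rate: float,
            rng: np.random.Generator, index_n: int = 0) -> ResponseRecord:
    """Bright iff SC strictly exceeds the criterion; lapses flip the response."""
    bright = sc_n > criterion_hz
    lapsed = bool(rng.random() < lapse_rate) if lapse_rate > 0 else False
    if lapsed:
        bright = not bright
    return ResponseRecord(index_n, RESPONSE_BRIGHT if bright else RESPONSE_DULL,
                          criterion_hz, lapsed)


def run_virtual_participant(design: SessionDesign, sc_table, params: DecisionModelParams,
                            seed: int) -> list[ResponseRecord]:
    """Simulate one session trial by trial.

    ``sc_table`` maps ``(excerpt_id, coloration)`` to the SC (Hz) of the
    colorated excerpt; every trial of the design (adaptors included —
    they enter the history like any stimulus) must be covered.
    """
    sc, durations = _session_sc_arrays(design, sc_table)
    history = SessionHistory(sc, durations)
    rng = np.random.default_rng(seed)
    records: list[ResponseRecord] = []
    for t in design.trials:
        n = t.index_n
        if n == 1 and params.alpha > 0.0:
            if params.first_trial_policy == "skip":
                records.append(ResponseRecord(n, RESPONSE_NONE, None, False))
                continue
            coin = RESPONSE_BRIGHT if rng.random() < 0.5 else RESPONSE_DULL
            records.append(ResponseRecord(n, coin, None, False))
            continue
        crit = decision_criterion(history, n, params)
        records.append(respond(sc[n - 1], crit, params.lapse_rate, rng, index_n=n))
    return records


def _session_sc_arrays(design: SessionDesign, sc_table) -> tuple[np.ndarray, np.ndarray]:
    sc = np.empty(design.n_trials)
    durations = np.empty(design.n_trials)
    for i, t in enumerate(design.trials):
        try:
            sc[i] = sc_table[(t.excerpt_id, t.coloration)]
        except KeyError:
            raise KeyError(
                f"sc_table missing SC for trial {t.index_n} "
                f"(excerpt {t.excerpt_id!r}, coloration {t.coloration})"
            ) from None
        durations[i] = t.duration_s
    return sc, durations


def simulate_participants(designs, sc_table, params: DecisionModelParams,
                          n_participants: int, seed: int) -> pd.DataFrame:
    """Run ``n_participants`` virtual listeners over an experiment's sessions.

    ``designs`` is either a fixed list of :class:`SessionDesign` (every
    participant then sees the same trial sequences) or a callable
    ``designs(design_seed) -> list[SessionDesign]`` giving each
    participant an independently randomized sequence, as in the human
    procedure.  Each participant additionally gets an independent
    lapse/response stream derived from ``seed``.  Returns a tidy
    trial-level DataFrame in the response serialization schema.
    """
    factory = designs if callable(designs) else (lambda _s, _d=list(designs): _d)
    rows = []
    design_seeds, response_seeds = np.random.SeedSequence(seed).spawn(2)
    design_seeds = design_seeds.generate_state(n_participants)
    response_seeds = response_seeds.generate_state(n_participants * 16)
    k = 0
    for p in range(n_participants):
        for design in factory(int(design_seeds[p])):
            records = run_virtual_participant(design, sc_table, params,
                                              int(response_seeds[k]))
            k += 1
            for t, r in zip(design.trials, records):
                rows.append((f"vp{p:03d}", design.session_id, design.experiment_id,
                             design.context, t.index_n, t.role, t.coloration,
                             r.response, r.criterion_hz, r.lapsed))
    return pd.DataFrame(rows, columns=[
        "participant_id", "session_id", "experiment_id", "context", "index_n",
        "role", "coloration", "response", "criterion_hz", "lapsed",
    ])
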