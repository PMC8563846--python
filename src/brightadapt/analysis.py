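"""Aggregation, inclusion, adaptation contrasts and model evaluation.

Responses are pooled into the condition cells the experiments are
analysed in: coloration level × previous-trial class × global context.
The previous-trial class is experiment specific — the sign of the
previous slope (Exp. 1), the preceding adaptor's context slope
(Exp. 2), or whether the previous coloration was below/above the
session mean (Exps. 3–4); in every case the class is labelled by
whether the preceding stimulation was relatively *dull* or *bright*.

Model selection follows the RMS-error-vs-integration-length procedure:
the candidate decision model simulates the experiments with 50 virtual
participants per integration length L, the simulated cell means are
compared against reference cell means, and the pooled RMS error (root
of the unweighted mean of squared cell errors over all cells of all
experiments) is minimized over L; the Pearson correlation between model
and reference cells is reported at the best L.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .model import DecisionModelParams, simulate_participants

PREV_DULL = "dull"
PREV_BRIGHT = "bright"

#: Global contexts whose overall stimulation is relatively dull (the
#: down-shifted slope range; the device-exaggerated morph range).
DULL_CONTEXTS = ("shift_minus_1", "device_context")
BRIGHT_CONTEXTS = ("shift_plus_1", "openear_context")

INCLUSION_GAIN_POINTS = {"exp1": 40.0, "exp2": 20.0, "exp3": 40.0, "exp4": 40.0}

MODEL_ALPHAS = {"lt": 0.0, "st_lt": 0.5, "st": 1.0}

CELL_KEYS = ["experiment_id", "context", "level", "prev_class"]


@dataclass(frozen=True)
class ConditionSummary:
    """p(bright) in one condition cell, with a bootstrap 95% CI."""

    experiment_id: str
    context: str
    level: float
    prev_class: str
    p_bright: float
    n_trials: int
    ci95: tuple[float, float]


@dataclass
class EvaluationResult:
    """RMS-error surface over integration lengths for one model type."""

    model_type: str
    rms_by_L: dict[float, float]
    best_L: float
    pearson_r: float
    cells_at_best: pd.DataFrame = field(repr=False, default=None)

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.rms_by_L.values()):
            raise ValueError("RMS errors must be non-negative")
        if abs(self.rms_by_L[self.best_L] - min(self.rms_by_L.values())) > 1e-12:
            raise ValueError("best_L must attain the minimum RMS")


def _with_prev_class(responses: pd.DataFrame, experiment_id: str) -> pd.DataFrame:
    """Trial table restricted to analysable trials, with ``prev_class`` added."""
    df = responses[responses["experiment_id"] == experiment_id].copy()
    if df.empty:
        raise ValueError(f"no responses for experiment {experiment_id!r}")
    df = df.sort_values(["participant_id", "session_id", "index_n"], kind="stable")
    grp = df.groupby(["participant_id", "session_id"], sort=False)
    df["prev_coloration"] = grp["coloration"].shift(1)
    if experiment_id in ("exp1", "exp2"):
        ref = 0.0
    else:  # previous trial relative to the mean coloration of the session
        ref = grp["coloration"].transform("mean")
    delta = df["prev_coloration"] - ref
    df["prev_class"] = np.select([delta < 0, delta > 0], [PREV_DULL, PREV_BRIGHT],
                                 default="")
    df = df[df["role"] == "target"]
    df = df[df["response"].isin(["bright", "dull"])]
    df = df[df["prev_class"] != ""]
    df["bright"] = (df["response"] == "bright").astype(float)
    return df


def cell_table(responses: pd.DataFrame, experiment_id: str) -> pd.DataFrame:
    """Cell means: one row per (context, level, prev_class).

    ``p_bright`` is the mean over participants of each participant's
    proportion of *bright* responses in the cell; ``n_trials`` counts
    the pooled trials.  Cells of the full design grid that received no
    analysable trials are reported with ``n_trials = 0`` and NaN p.
    """
    df = _with_prev_class(responses, experiment_id)
    per_part = (df.groupby(["context", "coloration", "prev_class", "participant_id"])
                ["bright"].agg(["mean", "count"]).reset_index())
    cells = (per_part.groupby(["context", "coloration", "prev_class"])
             .agg(p_bright=("mean", "mean"), n_trials=("count", "sum"))
             .reset_index())
    # report empty grid cells explicitly rather than dropping them
    contexts = responses.loc[responses["experiment_id"] == experiment_id, "context"].unique()
    levels = df["coloration"].unique()
    full = pd.MultiIndex.from_product(
        [sorted(contexts), sorted(levels), [PREV_DULL, PREV_BRIGHT]],
        names=["context", "coloration", "prev_class"])
    cells = (cells.set_index(["context", "coloration", "prev_class"])
             .reindex(full).reset_index())
    cells["n_trials"] = cells["n_trials"].fillna(0).astype(int)
    cells = cells.rename(columns={"coloration": "level"})
    cells.insert(0, "experiment_id", experiment_id)
    return cells


def aggregate_conditions(responses: pd.DataFrame, experiment_id: str,
                         n_boot: int = 2000, seed: int = 0) -> list[ConditionSummary]:
    """Condition-cell summaries with bootstrap 95% CIs over participants."""
    df = _with_prev_class(responses, experiment_id)
    cells = cell_table(responses, experiment_id)
    rng = np.random.default_rng(seed)
    out = []
    for row in cells.itertuples():
        sub = df[(df["context"] == row.context) & (df["coloration"] == row.level)
                 & (df["prev_class"] == row.prev_class)]
        if sub.empty:
            out.append(ConditionSummary(experiment_id, row.context, row.level,
                                        row.prev_class, float("nan"), 0,
                                        (float("nan"), float("nan"))))
            continue
        per_part = sub.groupby("participant_id")["bright"].mean().to_numpy()
        if n_boot > 0 and len(per_part) > 1:
            idx = rng.integers(0, len(per_part), size=(n_boot, len(per_part)))
            boots = per_part[idx].mean(axis=1)
            ci = (float(np.percentile(boots, 2.5)), float(np.percentile(boots, 97.5)))
        else:
            ci = (float(per_part.mean()), float(per_part.mean()))
        out.append(ConditionSummary(experiment_id, row.context, row.level,
                                    row.prev_class, float(per_part.mean()),
                                    int(row.n_trials), ci))
    return out


def summaries_to_frame(summaries: list[ConditionSummary]) -> pd.DataFrame:
    return pd.DataFrame([
        {"experiment_id": s.experiment_id, "context": s.context, "level": s.level,
         "prev_class": s.prev_class, "p_bright": s.p_bright, "n_trials": s.n_trials,
         "ci_lo": s.ci95[0], "ci_hi": s.ci95[1]}
        for s in summaries
    ])


def apply_inclusion_criterion(responses: pd.DataFrame, experiment_id: str) -> list[str]:
    """Participants whose slope sensitivity meets the inclusion threshold.

    Sensitivity is the gain in proportion-bright between the two most
    extreme coloration levels of each session (pooled over previous-
    trial classes), averaged over the participant's sessions; a mean
    gain of at least 40 percentage points (Exps. 1/3/4) or 20 points
    (Exp. 2) retains the participant (equality retains).
    """
    threshold = INCLUSION_GAIN_POINTS[experiment_id]
    df = responses[responses["experiment_id"] == experiment_id]
    if df.empty:
        raise ValueError(f"no responses for experiment {experiment_id!r}")
    df = df[(df["role"] == "target") & df["response"].isin(["bright", "dull"])].copy()
    df["bright"] = (df["response"] == "bright").astype(float)
    retained = []
    for pid, part in df.groupby("participant_id"):
        gains = []
        for _, sess in part.groupby("session_id"):
            p_level = sess.groupby("coloration")["bright"].mean()
            lo, hi = p_level.index.min(), p_level.index.max()
            if lo == hi:
                raise ValueError(f"session with a single coloration level for {pid}")
            gains.append(100.0 * (p_level[hi] - p_level[lo]))
        if np.mean(gains) >= threshold - 1e-9:  # equality retains
            retained.append(pid)
    return retained


def adaptation_contrast(summaries, level: float, by: str = "prev_class") -> float:
    """Percentage-point contrastive effect at one coloration level.

    ``by="prev_class"``: p(bright | previous dull) - p(bright | previous
    bright), pooled over contexts.  ``by="context"``: p(bright | dull
    global context) - p(bright | bright global context), pooled over
    previous-trial classes.  Positive values mean contrastive adaptation.
    """
    frame = summaries if isinstance(summaries, pd.DataFrame) else summaries_to_frame(summaries)
    sub = frame[(frame["level"] == level) & (frame["n_trials"] > 0)]
    if by == "prev_class":
        dull = sub[sub["prev_class"] == PREV_DULL]
        bright = sub[sub["prev_class"] == PREV_BRIGHT]
    elif by == "context":
        dull = sub[sub["context"].isin(DULL_CONTEXTS)]
        bright = sub[sub["context"].isin(BRIGHT_CONTEXTS)]
    else:
        raise ValueError(f"by must be 'prev_class' or 'context', got {by!r}")
    if dull.empty or bright.empty:
        raise ValueError(f"missing cell for contrast at level {level} (by={by})")
    w = lambda d: np.average(d["p_bright"], weights=d["n_trials"])
    return 100.0 * (w(dull) - w(bright))


def response_trajectory(responses: pd.DataFrame, shared_levels, window: int = 10
                        ) -> pd.DataFrame:
    """Participant-averaged p(bright) over trial index, smoothed.

    Only trials at the ``shared_levels`` colorations enter; per context
    the per-trial-index mean over participants is smoothed with a
    centered ``window``-point moving average (``window=1`` returns the
    raw means).  The trial index is retained for log-axis plotting.
    """
    df = responses[responses["response"].isin(["bright", "dull"])].copy()
    df = df[df["coloration"].isin(shared_levels)]
    df["bright"] = (df["response"] == "bright").astype(float)
    out = []
    for ctx, sub in df.groupby("context"):
        traj = sub.groupby("index_n")["bright"].mean().sort_index()
        if len(traj) < window:
            raise ValueError(
                f"context {ctx!r} has {len(traj)} trial indices at the shared "
                f"levels; need at least window={window}"
            )
        smooth = traj.rolling(window, center=True, min_periods=1).mean()
        out.append(pd.DataFrame({"context": ctx, "index_n": traj.index,
                                 "p_bright": smooth.to_numpy()}))
    return pd.concat(out, ignore_index=True)


def fit_logistic_context_model(responses: pd.DataFrame, experiment_id: str
                               ) -> pd.DataFrame:
    """Fixed-effects binomial logistic summary (sign/direction checks).

    Regresses the bright/dull response on the coloration level (numeric),
    the previous-trial class and — where the experiment has one — the
    global context, both effects-coded (dull = -1, bright = +1), with
    Wald 95% intervals.  Quasi-/complete separation is reported via the
    ``flagged`` column rather than raised.
    """
    import statsmodels.api as sm

    df = _with_prev_class(responses, experiment_id)
    X = pd.DataFrame({"level": df["coloration"].astype(float)})
    X["prev_class"] = np.where(df["prev_class"] == PREV_BRIGHT, 1.0, -1.0)
    contexts = df["context"].unique()
    if len(contexts) > 1:
        X["context"] = np.where(df["context"].isin(BRIGHT_CONTEXTS), 1.0, -1.0)
    X = sm.add_constant(X)
    flagged = False
    import warnings as _warnings

    from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

    try:
        with np.errstate(all="ignore"), _warnings.catch_warnings(record=True) as caught:
            _warnings.simplefilter("always")
            fit = sm.GLM(df["bright"].to_numpy(), X, family=sm.families.Binomial()).fit()
        coefs, ci = fit.params, fit.conf_int()
        if (any(issubclass(w.category, PerfectSeparationWarning) for w in caught)
                or np.any(np.abs(coefs) > 15) or not np.all(np.isfinite(fit.bse))):
            flagged = True
    except Exception:  # PerfectSeparationError and numerical failures
        flagged = True
        coefs = pd.Series(np.nan, index=X.columns)
        ci = pd.DataFrame(np.nan, index=X.columns, columns=[0, 1])
    return pd.DataFrame({
        "coef": coefs, "ci_lo": ci[0], "ci_hi": ci[1],
        "flagged": flagged,
    })


def pooled_rms(model_cells: pd.DataFrame, reference_cells: pd.DataFrame,
               pooling: str = "cells") -> float:
    """RMS error between model and reference cell means.

    ``pooling="cells"`` takes the root of the unweighted mean of squared
    errors over all cells of all experiments; ``pooling="experiments"``
    first averages squared errors within each experiment, then across
    experiments.  Cells with no trials on either side are excluded.
    """
    merged = _merge_cells(model_cells, reference_cells)
    err2 = (merged["p_bright_model"] - merged["p_bright_ref"]) ** 2
    if pooling == "cells":
        return float(np.sqrt(err2.mean()))
    if pooling == "experiments":
        per_exp = err2.groupby(merged["experiment_id"]).mean()
        return float(np.sqrt(per_exp.mean()))
    raise ValueError(f"pooling must be 'cells' or 'experiments', got {pooling!r}")


def _merge_cells(model_cells: pd.DataFrame, reference_cells: pd.DataFrame) -> pd.DataFrame:
    ref = reference_cells[reference_cells["n_trials"] > 0]
    mod = model_cells[model_cells["n_trials"] > 0]
    merged = ref.merge(mod, on=CELL_KEYS, how="left", suffixes=("_ref", "_model"))
    missing = merged[merged["p_bright_model"].isna()]
    if len(missing):
        cells = missing[CELL_KEYS].to_records(index=False).tolist()
        raise ValueError(f"model is missing {len(cells)} reference cells: {cells[:10]}")
    return merged


def evaluate_model(reference_cells: pd.DataFrame, model_type: str, L_grid,
                   designs_by_experiment: dict, sc_table, n_participants: int = 50,
                   seed: int = 0, alpha: float | None = None,
                   lapse_rate: float = 0.05, lt_reference_hz: float | None = None,
                   pooling: str = "cells") -> EvaluationResult:
    """RMS-error surface of one decision-model type over integration lengths.

    For every L in ``L_grid`` the four (or fewer) experiments given in
    ``designs_by_experiment`` (``experiment_id -> designs or factory``,
    see :func:`brightadapt.model.simulate_participants`) are simulated
    with ``n_participants`` virtual listeners, aggregated into the same
    cells as ``reference_cells``, and scored by pooled RMS error.  The
    same seed is used at every L (common random numbers), so the RMS
    differences across L reflect the integration length alone.
    """
    if model_type not in MODEL_ALPHAS:
        raise ValueError(f"model_type must be one of {sorted(MODEL_ALPHAS)}")
    a = MODEL_ALPHAS[model_type] if alpha is None else alpha
    lt_mode = "session_median" if lt_reference_hz is None else "unprocessed_domain_median"
    rms_by_L: dict[float, float] = {}
    cells_by_L: dict[float, pd.DataFrame] = {}
    for L in L_grid:
        params = DecisionModelParams(
            alpha=a, integration_length_s=float(L), lapse_rate=lapse_rate,
            lt_mode=lt_mode, lt_reference_hz=lt_reference_hz)
        frames = []
        for exp_id, designs in designs_by_experiment.items():
            responses = simulate_participants(designs, sc_table, params,
                                              n_participants, seed)
            frames.append(cell_table(responses, exp_id))
        model_cells = pd.concat(frames, ignore_index=True)
        rms_by_L[float(L)] = pooled_rms(model_cells, reference_cells, pooling)
        cells_by_L[float(L)] = model_cells
    best_L = min(rms_by_L, key=rms_by_L.get)
    merged = _merge_cells(cells_by_L[best_L], reference_cells)
    r = float(stats.pearsonr(merged["p_bright_model"], merged["p_bright_ref"])[0])
    return EvaluationResult(model_type=model_type, rms_by_L=rms_by_L,
                            best_L=best_L, pearson_r=r,
                            cells_at_best=cells_by_L[best_L])


def grid_search_decision_model(reference_cells: pd.DataFrame, designs_by_experiment: dict,
                               sc_table, alpha_grid, L_grid, n_participants: int = 50,
                               seed: int = 0, lapse_rate: float = 0.05,
                               lt_reference_hz: float | None = None):
    """Joint (alpha, L) grid search; returns (best_alpha, best_L, rms DataFrame)."""
    rows = []
    for a in alpha_grid:
        res = evaluate_model(reference_cells, "st", L_grid, designs_by_experiment,
                             sc_table, n_participants=n_participants, seed=seed,
                             alpha=float(a), lapse_rate=lapse_rate,
                             lt_reference_hz=lt_reference_hz)
        for L, rms in res.rms_by_L.items():
            rows.append({"alpha": float(a), "L": L, "rms": rms})
    table = pd.DataFrame(rows)
    best = table.loc[table["rms"].idxmin()]
    return float(best["alpha"]), float(best["L"]), table
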