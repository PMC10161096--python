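"""Behavioral measures computed from a trial log.

Learning: trials-to-criterion (first trial followed by >70% accuracy over the
next 10 trials), block learning curves (raw for the first three trials, then
a centered sliding-window mean), plateau accuracy after the criterion window,
and the proportion of blocks reaching criterion.  Efficiency: within-block RT
trajectories and the trial at which RTs begin a sustained decline
("inflection").  Flexibility: trials-to-criterion split by switch type
(ID/ED; novel-dimension transitions are excluded from headline contrasts) and
perseverative-error proportions split by whether the repeated unrewarded
feature is in the target or a distractor dimension.  Search: set-size slopes
of search time and accuracy, similarity-condition means, and speed of
processing (familiarization RT).
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .task import similarity_bin

__all__ = [
    "trials_to_criterion",
    "trials_to_criterion_bruteforce",
    "learning_curve",
    "plateau_accuracy",
    "smooth_curve",
    "rt_inflection_trial",
    "session_third",
    "compute_block_metrics",
    "switch_cost_metrics",
    "perseverative_errors",
    "vs_set_size_effects",
    "vs_similarity_effects",
    "speed_of_processing",
    "compute_session_metrics",
    "CRITERION_ACCURACY",
    "CRITERION_WINDOW",
]

#: Learning criterion: accuracy strictly above this level ...
CRITERION_ACCURACY = 0.7
#: ... over a complete window of this many subsequent trials.
CRITERION_WINDOW = 10


def trials_to_criterion(correct: Sequence[int]) -> int | None:
    """First trial (1-based) followed by >70% accuracy over the next 10 trials.

    The window of ``CRITERION_WINDOW`` *subsequent* trials must exist in
    full; returns ``None`` (censored) when no qualifying trial exists.
    """
    x = np.asarray(correct, dtype=float)
    n = len(x)
    if n == 0:
        raise ValueError("empty block")
    if n <= CRITERION_WINDOW:
        return None
    sums = np.convolve(x, np.ones(CRITERION_WINDOW), mode="valid")
    # sums[i] covers trials i+1 .. i+CRITERION_WINDOW (1-based window after trial i)
    for t in range(1, n - CRITERION_WINDOW + 1):
        if sums[t] / CRITERION_WINDOW > CRITERION_ACCURACY:
            return t
    return None


def trials_to_criterion_bruteforce(correct: Sequence[int]) -> int | None:
    """Reference scan over every explicit window (cross-check, not for production)."""
    x = list(correct)
    for t in range(1, len(x) + 1):
        window = x[t : t + CRITERION_WINDOW]
        if len(window) == CRITERION_WINDOW and sum(window) / len(window) > CRITERION_ACCURACY:
            return t
    return None


def smooth_curve(values: Sequence[float], window: int = 5, raw_until: int = 3) -> np.ndarray:
    """Centered moving average, leaving the first ``raw_until`` points raw.

    The window is truncated at the array edges; NaNs are ignored within a
    window.  ``window`` must be odd.
    """
    if window % 2 != 1:
        raise ValueError("smoothing window must be odd")
    x = np.asarray(values, dtype=float)
    out = x.copy()
    half = window // 2
    for i in range(raw_until, len(x)):
        lo, hi = max(0, i - half), min(len(x), i + half + 1)
        seg = x[lo:hi]
        if np.all(np.isnan(seg)):
            continue
        out[i] = np.nanmean(seg)
    return out


def learning_curve(
    blocks: Sequence[Sequence[int]], window: int = 5
) -> pd.DataFrame:
    """Across-block mean accuracy per trial since block start, smoothed.

    Trials 1–3 are reported raw; later trials are smoothed with a centered
    moving average of ``window`` trials.  Returns a frame with columns
    ``trial`` (1-based), ``accuracy`` (smoothed), ``accuracy_raw``, ``se``
    (across blocks) and ``n_blocks``; ``se`` is NaN where fewer than two
    blocks contribute.
    """
    if not blocks:
        raise ValueError("no blocks provided")
    max_len = max(len(b) for b in blocks)
    mat = np.full((len(blocks), max_len), np.nan)
    for i, b in enumerate(blocks):
        mat[i, : len(b)] = np.asarray(b, dtype=float)
    n = np.sum(~np.isnan(mat), axis=0)
    mean = np.nanmean(mat, axis=0)
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)
        sd = np.nanstd(mat, axis=0, ddof=1)
    se = np.where(n >= 2, sd / np.sqrt(np.maximum(n, 1)), np.nan)
    return pd.DataFrame(
        {
            "trial": np.arange(1, max_len + 1),
            "accuracy": smooth_curve(mean, window=window, raw_until=3),
            "accuracy_raw": mean,
            "se": se,
            "n_blocks": n,
        }
    )


def plateau_accuracy(correct: Sequence[int], t_criterion: int | None) -> float | None:
    """Mean accuracy over trials strictly after the criterion trial's window.

    Returns ``None`` when the block is censored or no post-window trials
    exist.
    """
    if t_criterion is None:
        return None
    x = np.asarray(correct, dtype=float)
    post = x[t_criterion + CRITERION_WINDOW :]
    if len(post) == 0:
        return None
    return float(post.mean())


def rt_inflection_trial(
    curve: Sequence[float], min_run: int = 2, exclude_until: int = 3
) -> int | None:
    """First trial at which a smoothed RT curve begins a sustained decline.

    Scans for the first 1-based trial ``t >= exclude_until`` (trial 2 is
    explicitly excluded) with ``curve[t] < curve[t-1]`` and the decline
    persisting for ``min_run`` consecutive steps (truncated at the end of the
    curve).  Returns ``None`` for flat or monotonically rising curves.
    """
    x = np.asarray(curve, dtype=float)
    n = len(x)
    for t in range(exclude_until, n + 1):  # 1-based trial index
        i = t - 1
        steps = 0
        j = i
        while j < n and j >= 1 and x[j] < x[j - 1]:
            steps += 1
            j += 1
            if steps >= min_run:
                break
        needed = min(min_run, n - i)  # cannot demand steps beyond the data
        if needed >= 1 and steps >= needed:
            return t
    return None


def session_third(block_index: int, n_blocks: int = 21) -> int:
    """Map a 1-based FRL block index to its session third (1, 2 or 3)."""
    if not 1 <= block_index <= n_blocks:
        raise ValueError(f"block index {block_index} outside 1..{n_blocks}")
    per = n_blocks // 3
    return min(3, (block_index - 1) // per + 1)


def _block_perseveration(grp: pd.DataFrame) -> tuple[int, int, int]:
    """Per-block counts: (target-dim persev trials, distractor-dim persev trials, errors).

    A trial is perseverative when the chosen object repeats a feature value
    that was chosen and unrewarded earlier in the same block; the trial is
    classed by the repeated feature's dimension (it can fall in both classes
    when it repeats features from both).
    """
    target_dim = grp["target_dimension"].iloc[0]
    unrewarded: set[tuple[str, str]] = set()
    n_target = n_distractor = n_errors = 0
    for chosen, correct, rewarded in zip(
        grp["chosen_features"], grp["correct"], grp["rewarded"]
    ):
        feats = [tuple(item.split("=", 1)) for item in chosen.split("|")] if chosen else []
        if not correct:
            n_errors += 1
            repeated = [f for f in feats if f in unrewarded]
            if any(d == target_dim for d, _ in repeated):
                n_target += 1
            if any(d != target_dim for d, _ in repeated):
                n_distractor += 1
        if not rewarded:
            unrewarded.update(feats)
    return n_target, n_distractor, n_errors


def compute_block_metrics(log: pd.DataFrame, rt_window: int = 5) -> pd.DataFrame:
    """Per-FRL-block metric table from a trial log.

    One row per block with trials-to-criterion (NaN when censored), the
    criterion-reached flag, plateau accuracy, the RT-inflection trial on the
    block's smoothed correct-trial RT series, switch type, load, session
    third and perseveration counts.
    """
    frl = log[log["task"] == "FRL"]
    if frl.empty:
        raise ValueError("trial log contains no FRL trials")
    n_blocks = int(frl["block"].max())
    rows = []
    for (subject, session, dose, block), grp in frl.groupby(
        ["subject", "session", "dose", "block"], sort=True
    ):
        grp = grp.sort_values("trial_in_block")
        correct = grp["correct"].to_numpy()
        ttc = trials_to_criterion(correct)
        correct_rts = grp.loc[grp["correct"] == 1, "rt_ms"].to_numpy()
        if len(correct_rts) >= 5:
            inflection = rt_inflection_trial(smooth_curve(correct_rts, window=rt_window))
        else:
            inflection = None
        pt, pd_, errors = _block_perseveration(grp)
        rows.append(
            {
                "subject": subject,
                "session": session,
                "dose": dose,
                "block": block,
                "third": session_third(int(block), n_blocks),
                "load": grp["load"].iloc[0],
                "switch_type": grp["switch_type"].iloc[0],
                "n_trials": len(grp),
                "trials_to_criterion": np.nan if ttc is None else ttc,
                "criterion_reached": ttc is not None,
                "plateau_accuracy": np.nan
                if (p := plateau_accuracy(correct, ttc)) is None
                else p,
                "rt_inflection_trial": np.nan if inflection is None else inflection,
                "mean_rt_correct": correct_rts.mean() if len(correct_rts) else np.nan,
                "persev_target_dim_errors": pt,
                "persev_distractor_dim_errors": pd_,
                "total_errors": errors,
            }
        )
    return pd.DataFrame(rows)


def switch_cost_metrics(
    block_metrics: pd.DataFrame, include_novel: bool = False
) -> pd.DataFrame:
    """Trials-to-criterion distribution per switch type.

    First blocks are always dropped; novel-dimension transitions are dropped
    from the headline contrast unless ``include_novel``.  Censored blocks are
    excluded from the mean/median but counted in ``n_blocks``.
    """
    keep = ["intradimensional", "extradimensional"]
    if include_novel:
        keep.append("novel_dimension")
    sub = block_metrics[block_metrics["switch_type"].isin(keep)]
    out = (
        sub.groupby("switch_type")["trials_to_criterion"]
        .agg(mean="mean", median="median", n_learned="count")
        .reset_index()
    )
    out["n_blocks"] = out["switch_type"].map(
        sub.groupby("switch_type").size()
    ).astype(int)
    return out


def perseverative_errors(
    log: pd.DataFrame, denominator: str = "trials"
) -> pd.DataFrame:
    """Perseverative-error proportions by dimension class, per session.

    ``denominator`` is ``"trials"`` (proportion of all FRL trials, the
    default) or ``"errors"`` (proportion of error trials); both conventions
    are in circulation, so both columns are always returned and the chosen
    one is duplicated into ``persev_target`` / ``persev_distractor``.
    """
    if denominator not in ("trials", "errors"):
        raise ValueError("denominator must be 'trials' or 'errors'")
    frl = log[log["task"] == "FRL"]
    rows = []
    for (subject, session, dose), sess in frl.groupby(
        ["subject", "session", "dose"], sort=True
    ):
        n_target = n_distractor = n_errors = 0
        for _, grp in sess.groupby("block"):
            t, d, e = _block_perseveration(grp.sort_values("trial_in_block"))
            n_target += t
            n_distractor += d
            n_errors += e
        n_trials = len(sess)
        row = {
            "subject": subject,
            "session": session,
            "dose": dose,
            "n_trials": n_trials,
            "n_errors": n_errors,
            "persev_target_per_trial": n_target / n_trials,
            "persev_distractor_per_trial": n_distractor / n_trials,
            "persev_target_per_error": n_target / n_errors if n_errors else np.nan,
            "persev_distractor_per_error": n_distractor / n_errors if n_errors else np.nan,
        }
        suffix = "per_trial" if denominator == "trials" else "per_error"
        row["persev_target"] = row[f"persev_target_{suffix}"]
        row["persev_distractor"] = row[f"persev_distractor_{suffix}"]
        rows.append(row)
    return pd.DataFrame(rows)


def _vs_positions(log: pd.DataFrame) -> pd.Series:
    """Label VS rows as first/second block by block id within each session."""
    vs = log[log["task"].isin(["VS", "VS_familiarization"])]
    firsts = vs.groupby(["subject", "session"])["block"].transform("min")
    return np.where(vs["block"] == firsts, "first", "second")


def vs_set_size_effects(log: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-set-size means and set-size slopes, per session and block position.

    Search times use correct trials only.  Slopes are ordinary least-squares
    fits of the per-set-size means against distractor count; a session
    missing a set size is fitted on the available sizes and flagged.
    """
    vs = log[log["task"] == "VS"].copy()
    if vs.empty:
        raise ValueError("trial log contains no VS search trials")
    vs["position"] = _vs_positions(vs)
    per_size = (
        vs.groupby(["subject", "session", "dose", "position", "set_size"])
        .agg(accuracy=("correct", "mean"), n_trials=("correct", "size"))
        .reset_index()
    )
    rt_correct = (
        vs[vs["correct"] == 1]
        .groupby(["subject", "session", "dose", "position", "set_size"])["rt_ms"]
        .mean()
        .rename("mean_rt")
        .reset_index()
    )
    per_size = per_size.merge(
        rt_correct, on=["subject", "session", "dose", "position", "set_size"], how="left"
    )
    slope_rows = []
    for (subject, session, dose, position), grp in per_size.groupby(
        ["subject", "session", "dose", "position"], sort=True
    ):
        grp = grp.dropna(subset=["mean_rt"])
        sizes = grp["set_size"].to_numpy(dtype=float)
        flagged = len(sizes) < 4
        rt_slope = (
            np.polyfit(sizes, grp["mean_rt"].to_numpy(), 1)[0] if len(sizes) >= 2 else np.nan
        )
        acc_slope = (
            np.polyfit(sizes, grp["accuracy"].to_numpy(), 1)[0] if len(sizes) >= 2 else np.nan
        )
        slope_rows.append(
            {
                "subject": subject,
                "session": session,
                "dose": dose,
                "position": position,
                "rt_slope": rt_slope,
                "accuracy_slope": acc_slope,
                "incomplete_sizes": flagged,
            }
        )
    return per_size, pd.DataFrame(slope_rows)


def vs_similarity_effects(log: pd.DataFrame) -> pd.DataFrame:
    """Search time (correct trials) and accuracy per similarity condition.

    Conditions bin the trial-mean shared-feature count at the documented
    tercile edges; an empty condition simply yields no row for it.
    """
    vs = log[log["task"] == "VS"].copy()
    if vs.empty:
        raise ValueError("trial log contains no VS search trials")
    vs["position"] = _vs_positions(vs)
    vs["similarity"] = vs["mean_shared_features"].map(similarity_bin)
    acc = (
        vs.groupby(["subject", "session", "dose", "position", "similarity"])
        .agg(accuracy=("correct", "mean"), n_trials=("correct", "size"))
        .reset_index()
    )
    rt = (
        vs[vs["correct"] == 1]
        .groupby(["subject", "session", "dose", "position", "similarity"])["rt_ms"]
        .mean()
        .rename("mean_rt")
        .reset_index()
    )
    return acc.merge(
        rt, on=["subject", "session", "dose", "position", "similarity"], how="left"
    )


def speed_of_processing(log: pd.DataFrame) -> pd.DataFrame:
    """Mean familiarization RT per VS block position and session."""
    fam = log[log["task"] == "VS_familiarization"].copy()
    if fam.empty:
        raise ValueError("trial log contains no familiarization trials")
    fam["position"] = _vs_positions(fam)
    return (
        fam.groupby(["subject", "session", "dose", "position"])
        .agg(mean_familiarization_rt=("rt_ms", "mean"), n_trials=("rt_ms", "size"))
        .reset_index()
    )


def compute_session_metrics(log: pd.DataFrame) -> pd.DataFrame:
    """Session-level summary: median trials-to-criterion (overall, by load and
    by third), criterion-reached proportion, plateau accuracy, mean correct RT
    and perseveration proportions."""
    blocks = compute_block_metrics(log)
    persev = perseverative_errors(log)
    rows = []
    for (subject, session, dose), grp in blocks.groupby(
        ["subject", "session", "dose"], sort=True
    ):
        row = {
            "subject": subject,
            "session": session,
            "dose": dose,
            "n_blocks": len(grp),
            "median_ttc": grp["trials_to_criterion"].median(),
            "criterion_reached_prop": grp["criterion_reached"].mean(),
            "plateau_accuracy": grp["plateau_accuracy"].mean(),
            "mean_rt_correct": grp["mean_rt_correct"].mean(),
        }
        for load in ("low", "high"):
            row[f"median_ttc_{load}"] = grp.loc[
                grp["load"] == load, "trials_to_criterion"
            ].median()
        for third in (1, 2, 3):
            row[f"median_ttc_third{third}"] = grp.loc[
                grp["third"] == third, "trials_to_criterion"
            ].median()
        rows.append(row)
    out = pd.DataFrame(rows)
    return out.merge(
        persev[["subject", "session", "dose", "persev_target", "persev_distractor"]],
        on=["subject", "session", "dose"],
        how="left",
    )
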