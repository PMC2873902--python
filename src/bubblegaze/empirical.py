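"""Context-independent empirical salience from fixation fractions.

The model assumes that on any stimulus the ratio of fixation counts between
two bubbles A and B equals the ratio of their global saliences E_A / E_B,
independent of which other bubbles are present.  Equivalently, for every
stimulus S and every bubble A in S,

    E_A - fbar_S(A) * sum_{B in S} E_B = 0,

where fbar_S(A) is the trial-averaged fraction of S's bubble-assigned
fixations that landed on A.  Stacking these equations over all stimuli and
solving in the least-squares sense under the scale constraint
sum_all E = 1 yields one positive salience per bubble.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stimulus import ScreenGeometry, Stimulus, Trial, assign_fixations

logger = logging.getLogger(__name__)

SALIENCE_FLOOR = 1e-6


def observed_fractions(
    trials: list[Trial],
    stimuli: dict[str, Stimulus] | list[Stimulus],
    geometry: ScreenGeometry | None = None,
) -> pd.DataFrame:
    """Per-(stimulus, bubble) mean fraction of bubble-assigned fixations.

    Each trial contributes the vector count_A / sum_B count_B over the
    stimulus's bubbles; trials in which no fixation was assigned to any
    bubble are skipped.  Returns a frame with columns ``stimulus_id``,
    ``bubble_id``, ``fraction``, ``n_trials``.
    """
    if not isinstance(stimuli, dict):
        stimuli = {s.stimulus_id: s for s in stimuli}
    sums: dict[tuple[str, str], float] = {}
    ntr: dict[str, int] = {}
    for t in trials:
        s = stimuli[t.stimulus_id]
        if s.is_fullfield:
            continue
        asg = assign_fixations(t, s, geometry)
        total = asg.n_assigned
        if total == 0:
            continue
        ntr[s.stimulus_id] = ntr.get(s.stimulus_id, 0) + 1
        for bid, c in asg.bubble_counts.items():
            key = (s.stimulus_id, bid)
            sums[key] = sums.get(key, 0.0) + c / total
    rows = [
        (sid, bid, total / ntr[sid], ntr[sid])
        for (sid, bid), total in sums.items()
    ]
    return pd.DataFrame(
        rows, columns=["stimulus_id", "bubble_id", "fraction", "n_trials"]
    ).sort_values(["stimulus_id", "bubble_id"], ignore_index=True)


def fractions_from_counts(counts: pd.DataFrame) -> pd.DataFrame:
    """Build the fraction table directly from per-trial fixation counts.

    ``counts`` has columns (trial, stimulus_id, bubble_id, count); used by
    the spatial-bias simulation where assignments are already known.
    """
    c = counts.copy()
    totals = c.groupby("trial")["count"].transform("sum")
    c = c[totals > 0].copy()
    c["fraction"] = c["count"] / c.groupby("trial")["count"].transform("sum")
    g = (
        c.groupby(["stimulus_id", "bubble_id"])
        .agg(fraction=("fraction", "mean"), n_trials=("fraction", "size"))
        .reset_index()
    )
    return g.sort_values(["stimulus_id", "bubble_id"], ignore_index=True)


@dataclass
class SalienceSolution:
    """Least-squares empirical saliences plus diagnostics."""

    salience: pd.Series  # bubble_id -> salience, sums to 1
    residual_norm: float
    clipped: list[str]  # bubbles whose solution went below the floor
    disconnected: list[str]  # bubbles never fixated anywhere

    def table(self, name: str = "empirical") -> pd.DataFrame:
        return pd.DataFrame(
            {"bubble_id": self.salience.index, name: self.salience.values}
        )


def solve_salience(
    fractions: pd.DataFrame,
    stimuli: dict[str, Stimulus] | list[Stimulus],
    weight_by_trials: bool = True,
    floor: float = SALIENCE_FLOOR,
) -> SalienceSolution:
    """Solve the stacked linear system for global empirical saliences.

    The scale constraint sum E = 1 is eliminated exactly by substituting
    E_n = 1 - sum_{i<n} E_i, so consistent (noiseless) systems are solved
    to machine precision.  Each (stimulus, bubble) equation is weighted by
    sqrt(n_trials) of its stimulus, giving more-seen stimuli more influence.
    Negative components are clipped to ``floor`` and the vector renormalized
    (downstream log transforms require positivity).
    """
    if not isinstance(stimuli, dict):
        stimuli = {s.stimulus_id: s for s in stimuli}
    all_bubbles = sorted(
        {b.bubble_id for s in stimuli.values() for b in s.bubbles}
    )
    seen = set(fractions["bubble_id"])
    disconnected = [b for b in all_bubbles if b not in seen]
    if disconnected:
        logger.warning(
            "%d bubbles never fixated; assigned floor salience", len(disconnected)
        )
    bubbles = [b for b in all_bubbles if b in seen]
    idx = {b: i for i, b in enumerate(bubbles)}
    n = len(bubbles)
    if n == 0:
        raise ValueError("empty fraction table: no bubble was ever fixated")

    rows_A, rows_b = [], []
    for sid, grp in fractions.groupby("stimulus_id"):
        members = [b for b in stimuli[sid].bubble_ids() if b in idx]
        w = float(np.sqrt(grp["n_trials"].iloc[0])) if weight_by_trials else 1.0
        for _, r in grp.iterrows():
            row = np.zeros(n)
            row[idx[r["bubble_id"]]] += 1.0
            for m in members:
                row[idx[m]] -= r["fraction"]
            rows_A.append(w * row)
            rows_b.append(0.0)
    A = np.array(rows_A)
    b = np.array(rows_b)
    # substitute E_n = 1 - sum_{i<n} E_i
    A_red = A[:, :-1] - A[:, -1:]
    b_red = b - A[:, -1]
    if n == 1:
        E = np.array([1.0])
        resid = float(np.linalg.norm(A @ E - b))
    else:
        x, *_ = np.linalg.lstsq(A_red, b_red, rcond=None)
        E = np.append(x, 1.0 - x.sum())
        resid = float(np.linalg.norm(A @ E - b))

    clipped = [bubbles[i] for i in np.nonzero(E < floor)[0]]
    if clipped:
        logger.info("clipped %d negative/sub-floor saliences", len(clipped))
    E = np.maximum(E, floor)

    full = pd.Series(floor, index=pd.Index(all_bubbles, name="bubble_id"))
    full.loc[bubbles] = E
    full /= full.sum()
    return SalienceSolution(full, resid, clipped, disconnected)


def predicted_fractions(
    salience: pd.Series, stimuli: dict[str, Stimulus] | list[Stimulus]
) -> pd.DataFrame:
    """Model-predicted fixation fractions f_S(A) = E_A / sum_{B in S} E_B."""
    if not isinstance(stimuli, dict):
        stimuli = {s.stimulus_id: s for s in stimuli}
    rows = []
    for sid, s in stimuli.items():
        ids = [b for b in s.bubble_ids() if b in salience.index]
        if not ids:
            continue
        vals = salience.loc[ids].to_numpy()
        for bid, f in zip(ids, vals / vals.sum()):
            rows.append((sid, bid, f))
    return pd.DataFrame(rows, columns=["stimulus_id", "bubble_id", "fraction"])


def reconstruction_accuracy(
    salience: pd.Series,
    fractions: pd.DataFrame,
    stimuli: dict[str, Stimulus] | list[Stimulus],
) -> float:
    """How faithfully the global saliences reproduce the observed per-
    stimulus fixation fractions: 100 * (1 - mean |predicted - observed|)
    over all (stimulus, bubble) cells, in percent."""
    if fractions.empty:
        raise ValueError("empty fraction table")
    pred = predicted_fractions(salience, stimuli)
    merged = fractions.merge(
        pred, on=["stimulus_id", "bubble_id"], suffixes=("_obs", "_pred")
    )
    err = np.abs(merged["fraction_pred"] - merged["fraction_obs"]).mean()
    return 100.0 * (1.0 - float(err))
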