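"""Task-dependent information: entropy measures, the probabilistic
integration model, and the global maximum-likelihood fit.

Every bubble carries a *response distribution*: the probability that a
subject seeing only that bubble decides for each class of the task.  Its
information is the maximal entropy minus the Shannon entropy (base 2); a
flat distribution carries 0 bit, a unanimous one log2(C) bit.

The response distribution of a multi-bubble stimulus is modelled as the
normalized component-wise product of its bubbles' distributions (the
*p-model*), i.e. optimal fusion of independent evidence.  Inverting this
model over all stimuli and responses via maximum likelihood yields one
distribution — hence one information value — per bubble, including bubbles
never shown alone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special

logger = logging.getLogger(__name__)

PROB_FLOOR = 1e-6


# ---------------------------------------------------------------------------
# entropy and information
# ---------------------------------------------------------------------------


def _validate_dist(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("response distribution must be a non-empty 1-d vector")
    if np.any(p < 0) or not np.isclose(p.sum(), 1.0, atol=1e-9):
        raise ValueError("response distribution must be nonnegative and sum to 1")
    return p


def shannon_entropy(p: np.ndarray) -> float:
    """Shannon entropy in bits; 0 log 0 = 0."""
    p = _validate_dist(p)
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


def stimulus_information(p: np.ndarray) -> float:
    """Information of a response distribution: E_max - H(p) in bits, where
    E_max = log2(C) is the entropy of the flat distribution over C classes
    (2 bit for the four-alternative expression task, 1 bit otherwise)."""
    p = _validate_dist(p)
    return float(np.log2(p.size)) - shannon_entropy(p)


# ---------------------------------------------------------------------------
# integration models
# ---------------------------------------------------------------------------


def integrate_pmodel(dists: list[np.ndarray] | np.ndarray) -> np.ndarray:
    """Fuse independent per-bubble response distributions: component-wise
    product, renormalized.  Commutative and associative; the flat
    distribution is the identity; a zero component is absorbing."""
    arr = np.atleast_2d(np.asarray(dists, dtype=float))
    if arr.shape[0] == 0:
        raise ValueError("need at least one distribution")
    for row in arr:
        _validate_dist(row)
    prod = np.prod(arr, axis=0)
    total = prod.sum()
    if total <= 0:
        raise ValueError(
            "degenerate evidence: the component-wise product has zero mass"
        )
    return prod / total


def integrate_maxmodel(dists: list[np.ndarray] | np.ndarray) -> np.ndarray:
    """Alternative integration rule: the stimulus inherits the distribution
    of its most informative bubble (ties broken by first index)."""
    arr = np.atleast_2d(np.asarray(dists, dtype=float))
    infos = [stimulus_information(row) for row in arr]
    return arr[int(np.argmax(infos))].copy()


# ---------------------------------------------------------------------------
# global maximum-likelihood fit
# ---------------------------------------------------------------------------


@dataclass
class BubbleInfoFit:
    """Per-bubble response distributions recovered by the global fit."""

    bubble_ids: list[str]
    distributions: np.ndarray  # (n_bubbles, C)
    information: np.ndarray  # bits, per bubble
    log_likelihood: float
    n_parameters: int  # n_bubbles * (C - 1)
    n_equations_c: int  # stimuli x C scalar equations
    n_equations_cm1: int  # stimuli x (C - 1) independent scalar equations
    converged: bool
    n_restarts: int = 0
    classes: tuple[str, ...] = ()

    def dist_of(self, bubble_id: str) -> np.ndarray:
        return self.distributions[self.bubble_ids.index(bubble_id)]

    def info_series(self) -> pd.Series:
        return pd.Series(
            self.information, index=pd.Index(self.bubble_ids, name="bubble_id")
        )

    def table(self) -> pd.DataFrame:
        out = pd.DataFrame(
            self.distributions,
            columns=[f"p_{c}" for c in (self.classes or range(self.distributions.shape[1]))],
        )
        out.insert(0, "bubble_id", self.bubble_ids)
        out["information_bits"] = self.information
        return out


def _aggregate_counts(
    responses: pd.DataFrame,
    stimulus_members: dict[str, tuple[str, ...]],
    classes: tuple[str, ...],
) -> tuple[list[tuple[str, ...]], np.ndarray]:
    """Collapse the response table to per-stimulus class counts."""
    cls_idx = {c: i for i, c in enumerate(classes)}
    sids = sorted(set(responses["stimulus_id"]) & set(stimulus_members))
    sid_idx = {s: i for i, s in enumerate(sids)}
    counts = np.zeros((len(sids), len(classes)))
    for sid, resp in zip(responses["stimulus_id"], responses["response"]):
        i = sid_idx.get(sid)
        if i is not None:
            counts[i, cls_idx[resp]] += 1
    members = [stimulus_members[s] for s in sids]
    return members, counts


def fit_bubble_distributions(
    responses: pd.DataFrame,
    stimuli,
    classes: tuple[str, ...],
    n_restarts: int = 5,
    seed: int = 0,
    tol: float = 1e-8,
    floor: float = PROB_FLOOR,
) -> BubbleInfoFit:
    """Globally fit one response distribution per bubble by maximizing the
    multinomial likelihood of all observed responses under the p-model.

    Each bubble is parameterized by C-1 unconstrained logits (last class
    pinned at 0) mapped through a softmax, so the reported free-parameter
    count is n_bubbles * (C - 1).  The p-model prediction for a stimulus is
    the normalized product of its members' distributions; the objective is
    sum over trials of log P_R(S)[response], floored at ``floor`` inside
    the log.  L-BFGS with analytic gradient, ``n_restarts`` seeded random
    restarts, best likelihood kept.

    ``responses`` needs columns ``stimulus_id`` and ``response``;
    ``stimuli`` is a list/dict of Stimulus or a mapping
    stimulus_id -> tuple of bubble ids.
    """
    if hasattr(stimuli, "values"):
        stim_list = list(stimuli.values())
    else:
        stim_list = list(stimuli)
    if stim_list and hasattr(stim_list[0], "bubble_ids"):
        members_map = {
            s.stimulus_id: s.bubble_ids() for s in stim_list if not s.is_fullfield
        }
    else:
        members_map = dict(stimuli)

    members, counts = _aggregate_counts(responses, members_map, classes)
    C = len(classes)
    bubble_ids = sorted({b for m in members for b in m})
    if not bubble_ids:
        raise ValueError("no bubbles referenced by the responded stimuli")
    bidx = {b: i for i, b in enumerate(bubble_ids)}
    B = len(bubble_ids)

    # membership matrix: stimulus x bubble (each stimulus has <= 5 bubbles)
    n_stim = len(members)
    M = np.zeros((n_stim, B))
    for s, m in enumerate(members):
        for b in m:
            M[s, bidx[b]] = 1.0
    N_s = counts.sum(axis=1)  # trials per stimulus

    def unpack(theta: np.ndarray) -> np.ndarray:
        logits = np.concatenate(
            [theta.reshape(B, C - 1), np.zeros((B, 1))], axis=1
        )
        return special.softmax(logits, axis=1)

    def neg_loglik_and_grad(theta: np.ndarray):
        P = unpack(theta)  # (B, C)
        logP = np.log(np.maximum(P, floor))
        logprod = M @ logP  # (n_stim, C)
        # normalized product = p-model stimulus prediction, stable in logs
        logz = logprod - special.logsumexp(logprod, axis=1, keepdims=True)
        ll = float(np.sum(counts * np.maximum(logz, np.log(floor))))
        z = np.exp(logz)
        # d loglik / d theta_{b,k} = sum_{S with b} n_{S,k} - N_S z_{S,k}
        grad = M.T @ (counts[:, : C - 1] - N_s[:, None] * z[:, : C - 1])
        return -ll, -grad.ravel()

    rng = np.random.default_rng(seed)
    best = None
    for r in range(n_restarts):
        theta0 = (
            np.zeros(B * (C - 1)) if r == 0 else rng.normal(0, 1.5, B * (C - 1))
        )
        res = optimize.minimize(
            neg_loglik_and_grad,
            theta0,
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": 2000, "ftol": tol, "gtol": 1e-8},
        )
        if best is None or res.fun < best.fun:
            best = res
    if not best.success:
        logger.warning("global fit did not fully converge: %s", best.message)

    P = unpack(best.x)
    info = np.array([stimulus_information(p) for p in P])
    return BubbleInfoFit(
        bubble_ids=bubble_ids,
        distributions=P,
        information=info,
        log_likelihood=-float(best.fun),
        n_parameters=B * (C - 1),
        n_equations_c=n_stim * C,
        n_equations_cm1=n_stim * (C - 1),
        converged=bool(best.success),
        n_restarts=n_restarts,
        classes=tuple(classes),
    )


def count_free_parameters(n_bubbles: int, n_classes: int) -> int:
    """Free parameters of the global fit: one distribution per bubble with
    C - 1 degrees of freedom each."""
    if n_classes < 2:
        raise ValueError("need at least 2 classes")
    return n_bubbles * (n_classes - 1)


# ---------------------------------------------------------------------------
# information versus bubble count
# ---------------------------------------------------------------------------


def predict_info_vs_count(
    single_bubble_dists: np.ndarray,
    n_bubbles: list[int] | range = range(1, 6),
    reps: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """p-model prediction of mean stimulus information as a function of the
    number of bubbles: draw n distributions at random from the pool
    (independent of image class), integrate, take the information; repeat
    ``reps`` times per count and average."""
    pool = np.atleast_2d(np.asarray(single_bubble_dists, dtype=float))
    if pool.shape[0] == 0:
        raise ValueError("empty pool of single-bubble distributions")
    rng = np.random.default_rng(seed)
    rows = []
    for n in n_bubbles:
        vals = np.empty(reps)
        for r in range(reps):
            idx = rng.integers(0, pool.shape[0], size=n)
            vals[r] = stimulus_information(integrate_pmodel(pool[idx]))
        rows.append((n, float(vals.mean()), float(vals.std(ddof=1)) if reps > 1 else 0.0))
    return pd.DataFrame(rows, columns=["n_bubbles", "mean_information", "sd"])


def observed_info_vs_count(
    responses: pd.DataFrame,
    stimuli,
    classes: tuple[str, ...],
    conditions: tuple[str, ...] = ("same",),
) -> pd.DataFrame:
    """Measured mean stimulus information per bubble count: per stimulus the
    information of the raw response proportions, averaged within count."""
    if hasattr(stimuli, "values"):
        stimuli = list(stimuli.values())
    by_id = {s.stimulus_id: s for s in stimuli}
    cls_idx = {c: i for i, c in enumerate(classes)}
    per_stim: dict[str, np.ndarray] = {}
    for sid, resp in zip(responses["stimulus_id"], responses["response"]):
        s = by_id.get(sid)
        if s is None or s.is_fullfield or s.condition not in conditions:
            continue
        per_stim.setdefault(sid, np.zeros(len(classes)))[cls_idx[resp]] += 1
    rows = []
    for sid, cnt in per_stim.items():
        if cnt.sum() == 0:
            continue
        rows.append(
            (
                sid,
                len(by_id[sid].bubbles),
                stimulus_information(cnt / cnt.sum()),
                int(cnt.sum()),
            )
        )
    df = pd.DataFrame(
        rows, columns=["stimulus_id", "n_bubbles", "information", "n_responses"]
    )
    return df


# ---------------------------------------------------------------------------
# prediction error and its sampling floor
# ---------------------------------------------------------------------------


def info_prediction_error(
    fit: BubbleInfoFit,
    responses: pd.DataFrame,
    stimuli,
    reps: int = 200,
    seed: int = 0,
) -> tuple[float, float]:
    """Mean absolute error (bits) between p-model-predicted and observed
    stimulus information, plus its finite-sample lower bound.

    The lower bound re-samples each stimulus's responses from the fitted
    prediction with the real per-stimulus trial counts and measures the
    same error; it is the error one would see even if the model were exactly
    true, driven by multinomial sampling noise in the observed proportions.
    """
    if hasattr(stimuli, "values"):
        stimuli = list(stimuli.values())
    members_map = {
        s.stimulus_id: s.bubble_ids() for s in stimuli if not s.is_fullfield
    }
    members, counts = _aggregate_counts(responses, members_map, fit.classes)
    dist_of = {b: d for b, d in zip(fit.bubble_ids, fit.distributions)}

    preds, obs_info, Ns = [], [], []
    for m, cnt in zip(members, counts):
        N = cnt.sum()
        if N == 0:
            continue
        z = integrate_pmodel([dist_of[b] for b in m])
        preds.append(z)
        obs_info.append(stimulus_information(cnt / N))
        Ns.append(int(N))
    if not preds:
        raise ValueError("no responded stimuli")
    pred_info = np.array([stimulus_information(z) for z in preds])
    realized = float(np.mean(np.abs(pred_info - np.array(obs_info))))

    rng = np.random.default_rng(seed)
    errs = np.empty(reps)
    for r in range(reps):
        tot = 0.0
        for z, pi, N in zip(preds, pred_info, Ns):
            sim = rng.multinomial(N, z) / N
            tot += abs(pi - stimulus_information(sim))
        errs[r] = tot / len(preds)
    return realized, float(errs.mean())


# ---------------------------------------------------------------------------
# bootstrap confidence intervals
# ---------------------------------------------------------------------------


def bootstrap_ci(
    values: np.ndarray,
    reps: int = 1000,
    level: float = 0.95,
    seed: int = 0,
    statistic=np.mean,
) -> tuple[float, float]:
    """Percentile bootstrap interval for a statistic of one cell's values
    (e.g. the mean stimulus information of all trials in one
    condition x bubble-count cell)."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("bootstrap needs at least 2 observations")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, values.size, size=(reps, values.size))
    boot = statistic(values[idx], axis=1)
    alpha = (1.0 - level) / 2.0
    return (
        float(np.quantile(boot, alpha)),
        float(np.quantile(boot, 1.0 - alpha)),
    )


def curves_differ(
    point_a: float, interval_b: tuple[float, float]
) -> bool:
    """Significance rule used for the information-vs-count curves: two
    curves differ at a cell when one's point estimate falls outside the
    other's bootstrap interval."""
    lo, hi = interval_b
    return point_a < lo or point_a > hi


# ---------------------------------------------------------------------------
# permuted-position response test
# ---------------------------------------------------------------------------


def permutation_position_test(
    pairs: list[tuple[np.ndarray, np.ndarray]],
    reps: int = 2000,
    level: float = 0.95,
    seed: int = 0,
) -> float:
    """Fraction of (normal, permuted) response-count pairs consistent with a
    single underlying response distribution.

    For each pair the statistic is the maximum absolute component
    difference of the two proportion vectors.  Its null distribution is
    simulated by drawing both sides from the pooled multinomial at the
    pair's actual sample sizes; a pair is "inside" when its statistic does
    not exceed the ``level`` quantile of that null.  Returns the inside
    fraction; values near ``level`` mean no detectable position effect.
    """
    rng = np.random.default_rng(seed)
    inside = 0
    for a, b in pairs:
        a = np.asarray(a, float)
        b = np.asarray(b, float)
        na, nb = a.sum(), b.sum()
        if na == 0 or nb == 0:
            raise ValueError("each pair needs responses on both sides")
        stat = float(np.max(np.abs(a / na - b / nb)))
        pooled = (a + b) / (na + nb)
        sa = rng.multinomial(int(na), pooled, size=reps) / na
        sb = rng.multinomial(int(nb), pooled, size=reps) / nb
        null = np.max(np.abs(sa - sb), axis=1)
        if stat <= np.quantile(null, level):
            inside += 1
    return inside / len(pairs)
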