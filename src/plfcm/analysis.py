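"""Similarity-based factor ranking, sensitivity analyses, and baselines.

The causal importance of a factor is read off as the similarity between its
steady PLTS and the outcome node's steady PLTS: factors that co-saturate
with the outcome end up close to it, so rank 1 (highest similarity) marks
the most influential factor.  First-level groups are scored by the mean rank
of their members (lower = more influential).

Two degenerate variants serve as comparison baselines:

* the hesitant variant drops all probabilities and iterates the membership
  channel alone (its membership trajectory is provably identical to the full
  model's, since that channel never reads probabilities);
* the crisp variant defuzzifies every PLTS to a scalar (states via
  score + g, weights via score / tau) and iterates a classical cognitive-map
  update on signed crisp weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .engine import (
    ConvergenceError,
    IterationSettings,
    IterationTrace,
    canonical_align,
    run,
    steady_state_plts,
)
from .measures import Z_FORMS, plts_similarity, similarity_from_distance, values_distance
from .model import PLFCModel
from .plts import g_transform

DEFAULT_LAMBDA_GRID = (2.0, 3.0, 4.0, 6.0, 8.0, 10.0)


@dataclass
class SimilarityRanking:
    """Per-factor similarity to the outcome, ranks, and group scores."""

    factors: list[str]
    similarities: dict[str, float]
    ranks: dict[str, float]
    group_scores: dict[str, float]
    z_form: str
    lam: float
    mode: str = "plfcm"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "factor": self.factors,
                "similarity": [self.similarities[f] for f in self.factors],
                "rank": [self.ranks[f] for f in self.factors],
            }
        )

    @property
    def rank_vector(self) -> tuple[float, ...]:
        return tuple(self.ranks[f] for f in self.factors)

    @property
    def spread(self) -> float:
        """Max - min similarity: how well factors are told apart."""
        vals = list(self.similarities.values())
        return max(vals) - min(vals)

    def top(self) -> str:
        return min(self.ranks, key=self.ranks.get)


def _make_ranking(
    model: PLFCModel,
    similarities: dict[str, float],
    z_form: str,
    lam: float,
    mode: str,
) -> SimilarityRanking:
    factors = model.factor_ids
    series = pd.Series({f: similarities[f] for f in factors})
    ranks = series.rank(ascending=False, method="average").to_dict()
    group_scores = {
        group: float(np.mean([ranks[f] for f in members]))
        for group, members in model.groups().items()
    }
    return SimilarityRanking(
        factors=factors,
        similarities={f: float(series[f]) for f in factors},
        ranks={f: float(r) for f, r in ranks.items()},
        group_scores=group_scores,
        z_form=z_form,
        lam=lam,
        mode=mode,
    )


def _require_fixed_point(trace: IterationTrace, what: str) -> None:
    if trace.status != "fixed_point":
        raise ConvergenceError(
            f"{what} did not converge: terminal status {trace.status!r}"
            + (f" (cycle length {trace.cycle_length})" if trace.cycle_length else "")
        )


# -- main method -------------------------------------------------------------------


def rank_factors(
    model: PLFCModel,
    settings: IterationSettings | None = None,
    z_form: str = "rational",
    trace: IterationTrace | None = None,
) -> SimilarityRanking:
    """Run the map to its fixed point and rank factors by steady similarity.

    A pre-computed ``trace`` may be passed to avoid re-iterating (used by the
    Z-form sensitivity sweep, which shares one fixed point across Z forms).
    """
    if settings is None:
        settings = IterationSettings()
    if trace is None:
        trace = run(model, settings)
    _require_fixed_point(trace, "map iteration")
    steady = steady_state_plts(trace, model)
    outcome = steady[model.outcome_id]
    sims = {
        f: plts_similarity(steady[f], outcome, z_form) for f in model.factor_ids
    }
    return _make_ranking(model, sims, z_form, settings.lam, "plfcm")


# -- sensitivity analyses ----------------------------------------------------------


@dataclass
class ZSensitivity:
    """One ranking per Z form, plus a rank-agreement flag."""

    rankings: dict[str, SimilarityRanking]
    ranks_agree: bool

    def to_frame(self) -> pd.DataFrame:
        frames = []
        for z, ranking in self.rankings.items():
            f = ranking.to_frame()
            f.insert(0, "z_form", z)
            frames.append(f)
        return pd.concat(frames, ignore_index=True)


def sensitivity_z(
    model: PLFCModel, settings: IterationSettings | None = None
) -> ZSensitivity:
    """Rank under each of the four Z forms (one shared fixed point)."""
    if settings is None:
        settings = IterationSettings()
    trace = run(model, settings)
    _require_fixed_point(trace, "map iteration")
    rankings = {
        z: rank_factors(model, settings, z_form=z, trace=trace) for z in Z_FORMS
    }
    vectors = {r.rank_vector for r in rankings.values()}
    return ZSensitivity(rankings=rankings, ranks_agree=len(vectors) == 1)


@dataclass
class LambdaSensitivity:
    """Rankings across a grid of threshold steepness values."""

    rankings: dict[float, SimilarityRanking]

    @property
    def spreads(self) -> dict[float, float]:
        return {lam: r.spread for lam, r in self.rankings.items()}

    def to_frame(self) -> pd.DataFrame:
        frames = []
        for lam, ranking in self.rankings.items():
            f = ranking.to_frame()
            f.insert(0, "lam", lam)
            frames.append(f)
        return pd.concat(frames, ignore_index=True)


def sensitivity_lambda(
    model: PLFCModel,
    lam_list: tuple[float, ...] = DEFAULT_LAMBDA_GRID,
    settings: IterationSettings | None = None,
    z_form: str = "rational",
) -> LambdaSensitivity:
    """Re-run the full pipeline for each steepness value on the grid."""
    if settings is None:
        settings = IterationSettings()
    rankings: dict[float, SimilarityRanking] = {}
    for lam in lam_list:
        s = IterationSettings(
            lam=float(lam),
            tol=settings.tol,
            max_iter=settings.max_iter,
            cycle_window=settings.cycle_window,
            threshold_fn=settings.threshold_fn,
            prob_apply_threshold=settings.prob_apply_threshold,
        )
        rankings[float(lam)] = rank_factors(model, s, z_form=z_form)
    return LambdaSensitivity(rankings=rankings)


# -- hesitant baseline (probabilities dropped) ---------------------------------------


def hflcm_membership_history(
    model: PLFCModel, settings: IterationSettings | None = None
) -> tuple[list[np.ndarray], str]:
    """Iterate the membership channel alone (probability-free variant).

    Returns the per-step membership matrices (step 0 included) and the
    terminal status.  Implemented as its own loop rather than through the
    two-channel engine, so the probability-independence of memberships can be
    checked against the full engine rather than assumed.
    """
    if settings is None:
        settings = IterationSettings()
    aligned = canonical_align(model)
    h = aligned.h0.copy()
    history = [h]
    status = "chaotic"
    for step in range(settings.max_iter):
        factors = np.where(
            aligned.adj[:, :, None], 1.0 - h[:, None, :] * aligned.wm, 1.0
        )
        a = 1.0 - np.prod(factors, axis=0)
        h_next = settings.squash(h + a - h * a)
        history.append(h_next)
        if np.abs(h_next - h).max() <= settings.tol:
            status = "fixed_point"
            break
        lo = max(0, len(history) - 1 - settings.cycle_window)
        recurred = False
        for back in range(len(history) - 3, lo - 1, -1):
            if np.abs(h_next - history[back]).max() <= settings.tol:
                status = "limit_cycle"
                recurred = True
                break
        if recurred:
            break
        h = h_next
    return history, status


def hflcm_run(
    model: PLFCModel,
    settings: IterationSettings | None = None,
    z_form: str = "rational",
) -> SimilarityRanking:
    """Rank factors with the hesitant (probability-free) variant.

    Similarity is computed on the steady membership vectors with uniform
    position weights (the probability factor is dropped from the distance).
    """
    if settings is None:
        settings = IterationSettings()
    history, status = hflcm_membership_history(model, settings)
    if status != "fixed_point":
        raise ConvergenceError(
            f"hesitant iteration did not converge: terminal status {status!r}"
        )
    final = history[-1]
    ids = model.node_ids
    idx = {nid: i for i, nid in enumerate(ids)}
    outcome = final[idx[model.outcome_id]]
    sims = {
        f: similarity_from_distance(
            values_distance(final[idx[f]], outcome), z_form
        )
        for f in model.factor_ids
    }
    return _make_ranking(model, sims, z_form, settings.lam, "hflcm")


# -- crisp baseline (classical cognitive map) ----------------------------------------


@dataclass
class FCMResult:
    """Crisp iteration history of the classical variant."""

    node_ids: list[str]
    history: list[np.ndarray]
    status: str
    initial: np.ndarray = field(default_factory=lambda: np.zeros(0))

    @property
    def final(self) -> np.ndarray:
        return self.history[-1]


def fcm_defuzzify(model: PLFCModel) -> tuple[np.ndarray, np.ndarray]:
    """Collapse the map to crisp activations and signed crisp weights.

    States: score on the state scale followed by g (unsigned, in [0, 1]).
    Weights: score on the weight scale divided by tau (signed, in [-1, 1]).
    """
    ids = model.node_ids
    idx = {nid: i for i, nid in enumerate(ids)}
    x0 = np.array(
        [
            g_transform(node.initial_state.score(), model.state_scale)
            for node in model.nodes
        ]
    )
    w = np.zeros((len(ids), len(ids)))
    for (src, dst), weight in model.edges.items():
        w[idx[src], idx[dst]] = weight.score() / model.weight_scale.tau
    return x0, w


def fcm_iterate(
    model: PLFCModel, settings: IterationSettings | None = None
) -> FCMResult:
    """Classical update ``x_i' = f(x_i + sum_j x_j w_ji)`` to a terminal state."""
    if settings is None:
        settings = IterationSettings()
    x0, w = fcm_defuzzify(model)
    x = x0.copy()
    history = [x]
    status = "chaotic"
    for step in range(settings.max_iter):
        raw = x + x @ w  # w[j, i] multiplies the source activation x_j
        x_next = np.tanh(settings.lam * raw)
        history.append(x_next)
        if np.abs(x_next - x).max() <= settings.tol:
            status = "fixed_point"
            break
        lo = max(0, len(history) - 1 - settings.cycle_window)
        recurred = False
        for back in range(len(history) - 3, lo - 1, -1):
            if np.abs(x_next - history[back]).max() <= settings.tol:
                status = "limit_cycle"
                recurred = True
                break
        if recurred:
            break
        x = x_next
    return FCMResult(node_ids=model.node_ids, history=history, status=status, initial=x0)


def fcm_run(
    model: PLFCModel,
    settings: IterationSettings | None = None,
    z_form: str = "rational",
) -> SimilarityRanking:
    """Rank factors with the classical crisp variant.

    The steady-activation distance ``|x_i - x_R|`` (clipped to [0, 1]) feeds
    the same Z-mapping similarity as the main method.
    """
    if settings is None:
        settings = IterationSettings()
    result = fcm_iterate(model, settings)
    if result.status != "fixed_point":
        raise ConvergenceError(
            f"crisp iteration did not converge: terminal status {result.status!r}"
        )
    idx = {nid: i for i, nid in enumerate(result.node_ids)}
    outcome = result.final[idx[model.outcome_id]]
    sims = {
        f: similarity_from_distance(
            min(abs(result.final[idx[f]] - outcome), 1.0), z_form
        )
        for f in model.factor_ids
    }
    return _make_ranking(model, sims, z_form, settings.lam, "fcm")
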