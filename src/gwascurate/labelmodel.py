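"""Generative label model for data programming (Naive Bayes over LF votes).

The latent class of candidate *i* is ``y_i ∈ {-1, +1}`` with prior
``P(y=+1) = π``.  Conditioned on ``y_i``, labeling function *j*
independently

* abstains with probability ``1 - β_j`` (propensity β_j),
* votes ``y_i`` with probability ``β_j · α_j`` (accuracy α_j),
* votes ``-y_i`` with probability ``β_j · (1 - α_j)``.

Because the abstain probability does not depend on ``y``, β factors cancel
in the class posterior; β is nevertheless estimated (it is the empirical
coverage) and reported.  Parameters are fit by EM on the marginal
likelihood — no ground-truth labels ever enter the fit — and the resulting
posteriors ``P(y_i = +1 | votes)`` are used directly as probabilistic
predictions.

The likelihood is invariant under the label swap ``(α, π) → (1-α, 1-π)``;
the fit resolves it by assuming LFs are better than random on average
(mean α ≥ 1/2) and flipping the solution if needed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .labeling import LabelMatrix

__all__ = ["LabelModelParams", "fit", "posterior", "predict", "log_likelihood"]

_EPS = 1e-12


@dataclass
class LabelModelParams:
    alpha: np.ndarray  # per-LF accuracy, in (0,1)
    beta: np.ndarray  # per-LF propensity (vote rate), in (0,1)
    pi: float  # class prior P(y=+1)
    n_iter: int = 0
    converged: bool = False
    ll_history: list | None = None  # marginal log-likelihood per EM iteration

    def __post_init__(self):
        self.alpha = np.asarray(self.alpha, dtype=float)
        self.beta = np.asarray(self.beta, dtype=float)
        if self.alpha.shape != self.beta.shape:
            raise ValueError("alpha and beta must have one entry per LF")
        for arr, name in ((self.alpha, "alpha"), (self.beta, "beta")):
            if not ((arr > 0) & (arr < 1)).all():
                raise ValueError(f"{name} must lie strictly inside (0, 1)")
        if not 0.0 < self.pi < 1.0:
            raise ValueError("pi must lie strictly inside (0, 1)")

    def to_json(self) -> str:
        return json.dumps(
            {
                "alpha": self.alpha.tolist(),
                "beta": self.beta.tolist(),
                "pi": self.pi,
                "n_iter": self.n_iter,
                "converged": self.converged,
            }
        )

    @classmethod
    def from_json(cls, s: str) -> "LabelModelParams":
        d = json.loads(s)
        return cls(
            np.array(d["alpha"]), np.array(d["beta"]), d["pi"],
            d.get("n_iter", 0), d.get("converged", False),
        )


def _class_likelihoods(params: LabelModelParams, values: np.ndarray):
    """Per-row joint likelihoods L(votes | y=+1), L(votes | y=-1)."""
    a, b = params.alpha, params.beta
    voted = values != 0
    agree_pos = values == 1  # vote agrees with y=+1
    # log-space product over LFs
    log_pos = np.where(
        voted,
        np.where(agree_pos, np.log(b * a + _EPS), np.log(b * (1 - a) + _EPS)),
        np.log(1 - b + _EPS),
    ).sum(axis=1)
    log_neg = np.where(
        voted,
        np.where(~agree_pos, np.log(b * a + _EPS), np.log(b * (1 - a) + _EPS)),
        np.log(1 - b + _EPS),
    ).sum(axis=1)
    return log_pos, log_neg


def log_likelihood(params: LabelModelParams, matrix: LabelMatrix) -> float:
    """Marginal log-likelihood Σ_i log Σ_y P(y) P(votes_i | y)."""
    log_pos, log_neg = _class_likelihoods(params, matrix.values)
    lp = log_pos + np.log(params.pi)
    ln = log_neg + np.log(1 - params.pi)
    hi = np.maximum(lp, ln)
    return float((hi + np.log(np.exp(lp - hi) + np.exp(ln - hi))).sum())


def posterior(params: LabelModelParams, matrix: LabelMatrix) -> np.ndarray:
    """Per-candidate P(y_i = +1 | votes) by Bayes' rule.

    All-abstain rows reduce to the prior π because abstention carries no
    class information under this model.
    """
    if matrix.m != len(params.alpha):
        raise ValueError(
            f"matrix has {matrix.m} LFs but params have {len(params.alpha)}"
        )
    log_pos, log_neg = _class_likelihoods(params, matrix.values)
    lp = log_pos + np.log(params.pi)
    ln = log_neg + np.log(1 - params.pi)
    return 1.0 / (1.0 + np.exp(ln - lp))


def fit(
    matrix: LabelMatrix,
    init: LabelModelParams | None = None,
    max_iter: int = 500,
    tol: float = 1e-6,
    seed: int | None = None,
) -> LabelModelParams:
    """Fit (α, β, π) to an unlabeled vote matrix by EM.

    M-steps are closed form with add-1 pseudo-counts, which keeps every
    parameter off the (0,1) boundary.  β has no latent dependence and is
    the (smoothed) empirical coverage.  The marginal log-likelihood is
    non-decreasing across iterations; iteration stops when it improves by
    less than ``tol`` or after ``max_iter`` rounds.  The fit is fully
    deterministic given ``init`` (``seed`` is accepted for interface
    symmetry with stochastic fitters but unused by EM).

    LFs that never vote keep their initial α, with a warning.
    """
    del seed  # EM from a fixed init is deterministic
    values = matrix.values
    n, m = values.shape
    if n == 0:
        raise ValueError("cannot fit on an empty label matrix")

    voted = values != 0
    coverage = voted.mean(axis=0)
    if init is None:
        beta0 = np.clip((voted.sum(axis=0) + 1.0) / (n + 2.0), _EPS, 1 - _EPS)
        init = LabelModelParams(np.full(m, 0.7), beta0, 0.5)

    alpha = init.alpha.copy()
    beta = init.beta.copy()
    pi = init.pi
    never_votes = coverage == 0
    if never_votes.any():
        import logging

        logging.getLogger(__name__).warning(
            "%d LF(s) never vote; their accuracy stays at initialization",
            int(never_votes.sum()),
        )

    # β: closed form, independent of y
    beta = (voted.sum(axis=0) + 1.0) / (n + 2.0)

    n_voted = voted.sum(axis=0)
    prev_ll = -np.inf
    params = LabelModelParams(alpha, beta, pi)
    history: list[float] = []
    it = 0
    converged = False
    for it in range(1, max_iter + 1):
        # E-step
        q = posterior(params, matrix)  # P(y_i=+1 | votes)
        # M-step with add-1 smoothing
        agree = (values == 1) * q[:, None] + (values == -1) * (1 - q)[:, None]
        new_alpha = (agree.sum(axis=0) + 1.0) / (n_voted + 2.0)
        new_alpha = np.where(never_votes, alpha, new_alpha)
        new_pi = (q.sum() + 1.0) / (n + 2.0)
        params = LabelModelParams(new_alpha, beta, new_pi)
        ll = log_likelihood(params, matrix)
        history.append(ll)
        if ll - prev_ll < tol and np.isfinite(prev_ll):
            converged = True
            break
        prev_ll = ll
        alpha = new_alpha

    # resolve label-swap symmetry: LFs better than random on average
    active = ~never_votes
    if active.any() and params.alpha[active].mean() < 0.5:
        params = LabelModelParams(1 - params.alpha, params.beta, 1 - params.pi)
    params.n_iter = it
    params.converged = converged
    params.ll_history = history
    return params


def predict(
    params: LabelModelParams, matrix: LabelMatrix, threshold: float = 0.5
) -> np.ndarray:
    """Accept candidate i iff its posterior strictly exceeds ``threshold``."""
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    return posterior(params, matrix) > threshold
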