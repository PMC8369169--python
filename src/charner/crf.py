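"""Linear-chain CRF: exact likelihood, marginals, and Viterbi decoding.

Scores a tag path as the sum of per-position emission scores and
first-order transition scores, with virtual START/STOP states:

    score(y) = t(START -> y_1) + sum_t e_t(y_t) + sum_t t(y_t -> y_{t+1})
             + t(y_L -> STOP).

The partition function is computed by the forward recursion in log
space; gradients of the negative log-likelihood come from
forward-backward marginals.  Transitions into START and out of STOP are
masked with a large finite negative constant so every quantity stays
differentiable and NaN-free.

All arithmetic is float64 numpy; sequences are handled one at a time
(tag sets are small, so this is never the bottleneck).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

#: Finite stand-in for -inf in masked transitions.
MASKED = -1.0e4


def logsumexp(x: np.ndarray, axis: int = -1) -> np.ndarray:
    m = np.max(x, axis=axis, keepdims=True)
    out = m.squeeze(axis) + np.log(np.exp(x - m).sum(axis=axis))
    return out


@dataclass
class CrfParameters:
    """Transition matrix over T tags plus virtual START (index T) and
    STOP (index T+1) states; shape (T+2, T+2)."""

    transitions: np.ndarray

    def __post_init__(self) -> None:
        n = self.transitions.shape[0]
        if self.transitions.shape != (n, n) or n < 3:
            raise ValueError(f"transitions must be (T+2, T+2), got {self.transitions.shape}")

    @property
    def n_tags(self) -> int:
        return self.transitions.shape[0] - 2

    @property
    def start(self) -> int:
        return self.n_tags

    @property
    def stop(self) -> int:
        return self.n_tags + 1

    @classmethod
    def zeros(cls, n_tags: int) -> "CrfParameters":
        t = np.zeros((n_tags + 2, n_tags + 2))
        return cls(apply_mask(t, n_tags))


def apply_mask(transitions: np.ndarray, n_tags: int) -> np.ndarray:
    """Mask transitions into START and out of STOP (in place)."""
    transitions[:, n_tags] = MASKED  # -> START
    transitions[n_tags + 1, :] = MASKED  # STOP ->
    return transitions


def _check(emissions: np.ndarray, crf: CrfParameters) -> np.ndarray:
    emissions = np.asarray(emissions, dtype=float)
    if emissions.ndim != 2:
        raise ValueError(f"emissions must be (L, T), got shape {emissions.shape}")
    if emissions.shape[0] < 1:
        raise ValueError("need at least one position")
    if emissions.shape[1] != crf.n_tags:
        raise ValueError(
            f"emissions have {emissions.shape[1]} tags, CRF has {crf.n_tags}"
        )
    return emissions


def path_score(
    emissions: np.ndarray, tags: Sequence[int], crf: CrfParameters
) -> float:
    """Unnormalized log-score of one tag path."""
    emissions = _check(emissions, crf)
    L, T = emissions.shape
    tags = list(tags)
    if len(tags) != L:
        raise ValueError(f"{L} positions but {len(tags)} tags")
    if any(not (0 <= t < T) for t in tags):
        bad = next(t for t in tags if not (0 <= t < T))
        raise ValueError(f"tag index {bad} out of range [0, {T})")
    tr = crf.transitions
    score = tr[crf.start, tags[0]] + emissions[0, tags[0]]
    for t in range(1, L):
        score += tr[tags[t - 1], tags[t]] + emissions[t, tags[t]]
    score += tr[tags[-1], crf.stop]
    return float(score)


def log_partition(emissions: np.ndarray, crf: CrfParameters) -> float:
    """log sum over all T^L paths of exp(path_score), via the forward
    recursion in log space."""
    emissions = _check(emissions, crf)
    L, T = emissions.shape
    tr = crf.transitions[:T, :T]
    alpha = crf.transitions[crf.start, :T] + emissions[0]
    for t in range(1, L):
        alpha = logsumexp(alpha[:, None] + tr, axis=0) + emissions[t]
    alpha = alpha + crf.transitions[:T, crf.stop]
    return float(logsumexp(alpha))


def viterbi_decode(
    emissions: np.ndarray, crf: CrfParameters
) -> tuple[list[int], float]:
    """Highest-scoring tag path and its score.

    Ties break toward the lowest tag index at each backtracking step
    (argmax returns the first maximizer).
    """
    emissions = _check(emissions, crf)
    L, T = emissions.shape
    tr = crf.transitions[:T, :T]
    delta = crf.transitions[crf.start, :T] + emissions[0]
    back = np.empty((L, T), dtype=int)
    for t in range(1, L):
        scores = delta[:, None] + tr  # (prev, cur)
        back[t] = np.argmax(scores, axis=0)
        delta = scores[back[t], np.arange(T)] + emissions[t]
    delta = delta + crf.transitions[:T, crf.stop]
    last = int(np.argmax(delta))
    best_score = float(delta[last])
    path = [last]
    for t in range(L - 1, 0, -1):
        path.append(int(back[t, path[-1]]))
    path.reverse()
    return path, best_score


def forward_backward(
    emissions: np.ndarray, crf: CrfParameters
) -> tuple[np.ndarray, np.ndarray, float]:
    """Log-space forward and backward tables and log Z.

    ``log_alpha[t, y]`` scores prefixes ending in tag y at position t
    (emission at t included); ``log_beta[t, y]`` scores suffixes from t
    given tag y at t (emission at t excluded).
    """
    emissions = _check(emissions, crf)
    L, T = emissions.shape
    tr = crf.transitions[:T, :T]
    log_alpha = np.empty((L, T))
    log_alpha[0] = crf.transitions[crf.start, :T] + emissions[0]
    for t in range(1, L):
        log_alpha[t] = logsumexp(log_alpha[t - 1][:, None] + tr, axis=0) + emissions[t]
    log_beta = np.empty((L, T))
    log_beta[L - 1] = crf.transitions[:T, crf.stop]
    for t in range(L - 2, -1, -1):
        log_beta[t] = logsumexp(tr + (emissions[t + 1] + log_beta[t + 1])[None, :], axis=1)
    log_z = float(logsumexp(log_alpha[L - 1] + log_beta[L - 1]))
    return log_alpha, log_beta, log_z


def nll_and_grad(
    emissions: np.ndarray, tags: Sequence[int], crf: CrfParameters
) -> tuple[float, np.ndarray, np.ndarray]:
    """Negative log-likelihood of the gold path and its gradients.

    Returns ``(nll, d_emissions (L,T), d_transitions (T+2,T+2))`` where
    gradients are expected feature counts minus observed counts.
    Masked transition cells receive zero gradient.
    """
    emissions = _check(emissions, crf)
    L, T = emissions.shape
    tags = list(tags)
    log_alpha, log_beta, log_z = forward_backward(emissions, crf)
    nll = log_z - path_score(emissions, tags, crf)

    # Unary marginals p(y_t = y).
    marg = np.exp(log_alpha + log_beta - log_z)  # (L, T)
    d_em = marg.copy()
    d_em[np.arange(L), tags] -= 1.0

    d_tr = np.zeros_like(crf.transitions)
    tr = crf.transitions[:T, :T]
    # Pairwise marginals p(y_t = a, y_{t+1} = b).
    for t in range(L - 1):
        pair = np.exp(
            log_alpha[t][:, None]
            + tr
            + (emissions[t + 1] + log_beta[t + 1])[None, :]
            - log_z
        )
        d_tr[:T, :T] += pair
    d_tr[crf.start, :T] += np.exp(log_alpha[0] + log_beta[0] - log_z)
    d_tr[:T, crf.stop] += np.exp(log_alpha[L - 1] + log_beta[L - 1] - log_z)
    # Observed counts.
    d_tr[crf.start, tags[0]] -= 1.0
    for t in range(L - 1):
        d_tr[tags[t], tags[t + 1]] -= 1.0
    d_tr[tags[-1], crf.stop] -= 1.0
    return float(nll), d_em, d_tr
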