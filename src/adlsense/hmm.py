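"""Two-state discrete-emission hidden Markov models for hourly label sequences.

Each sensing group (participant-proximal G2, ambient G3) gets its own HMM
over the composite hourly symbols produced by decision layer I.  The hidden
state space is fixed to {normal, AIA}; the model lambda = {T, B, pi}
consists of the 2x2 hidden transition matrix, the emission matrix over the
group's composite-symbol alphabet, and the initial-state probabilities.

Parameters are estimated by additive-smoothed supervised counting from
sequences with known hidden labels (here: simulator ground truth standing
in for clinician-curated seed data); expert-supplied matrices can be set
directly on the fitted attributes instead.  Inference is the standard
forward / forward-backward / Viterbi machinery, computed in log space so
day-length (24+) sequences stay numerically stable.  The day-level group
score D_pf (G2) or D_mo (G3) is the mean posterior probability of the AIA
state over the scoring window.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
from scipy.special import logsumexp
from sklearn.base import BaseEstimator

__all__ = ["DiscreteHMM"]

NEG_INF = -np.inf


def _safe_log(a: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore"):
        return np.log(a)


class DiscreteHMM(BaseEstimator):
    """Supervised discrete HMM with a fixed, named hidden-state space.

    Parameters
    ----------
    alphabet : ordered list of emission symbols; every scored sequence must
        be drawn from it.
    states : hidden state names; the default puts "normal" first so that
        argmax ties (Viterbi, labelling) resolve toward normal, biasing
        against false alarms.
    smoothing : additive (Laplace) pseudo-count for supervised estimation;
        with no observed AIA hours the AIA rows fall back to uniform.
    """

    def __init__(
        self,
        alphabet: Sequence[str],
        states: tuple[str, str] = ("normal", "AIA"),
        smoothing: float = 1.0,
    ):
        self.alphabet = list(alphabet)
        self.states = tuple(states)
        self.smoothing = smoothing

    # -- encoding -----------------------------------------------------------

    def _encode(self, sequence: Sequence[str]) -> np.ndarray:
        index = {s: i for i, s in enumerate(self.alphabet)}
        try:
            return np.asarray([index[s] for s in sequence], dtype=int)
        except KeyError as exc:
            raise ValueError(f"symbol {exc.args[0]!r} not in the model alphabet") from None

    def _state_index(self, labels: Sequence[str]) -> np.ndarray:
        index = {s: i for i, s in enumerate(self.states)}
        return np.asarray([index[l] for l in labels], dtype=int)

    @property
    def aia_index_(self) -> int:
        return self.states.index("AIA")

    # -- estimation ---------------------------------------------------------

    def fit(
        self,
        sequences: Iterable[Sequence[str]],
        state_labels: Iterable[Sequence[str]],
    ) -> "DiscreteHMM":
        """Supervised count estimation of pi, T and B.

        `sequences` are observation sequences; `state_labels` the aligned
        hidden labels.  Counts are pooled across sequences (transitions
        within each sequence only) and additively smoothed.
        """
        n, m = len(self.states), len(self.alphabet)
        trans = np.full((n, n), self.smoothing, dtype=float)
        emis = np.full((n, m), self.smoothing, dtype=float)
        start = np.full(n, self.smoothing, dtype=float)
        seen = False
        for seq, labels in zip(sequences, state_labels):
            obs = self._encode(seq)
            hid = self._state_index(labels)
            if len(obs) != len(hid):
                raise ValueError("sequence and state labels differ in length")
            if len(obs) == 0:
                continue
            seen = True
            start[hid[0]] += 1
            np.add.at(emis, (hid, obs), 1.0)
            np.add.at(trans, (hid[:-1], hid[1:]), 1.0)
        if not seen:
            raise ValueError("empty training corpus")
        for mat in (trans, emis):
            rowsum = mat.sum(axis=1, keepdims=True)
            uniform = np.full_like(mat, 1.0 / mat.shape[1])
            np.divide(mat, rowsum, out=mat, where=rowsum > 0)
            mat[rowsum[:, 0] == 0] = uniform[rowsum[:, 0] == 0]
        self.transmat_ = trans
        self.emissionprob_ = emis
        self.startprob_ = (start / start.sum() if start.sum() > 0
                           else np.full(n, 1.0 / n))
        return self

    def set_expert_params(
        self, startprob: np.ndarray, transmat: np.ndarray, emissionprob: np.ndarray
    ) -> "DiscreteHMM":
        """Install externally supplied lambda = {T, B, pi} (validated)."""
        startprob = np.asarray(startprob, dtype=float)
        transmat = np.asarray(transmat, dtype=float)
        emissionprob = np.asarray(emissionprob, dtype=float)
        n, m = len(self.states), len(self.alphabet)
        if startprob.shape != (n,) or transmat.shape != (n, n) \
                or emissionprob.shape != (n, m):
            raise ValueError("parameter shapes do not match states/alphabet")
        for name, arr in [("pi", startprob[None]), ("T", transmat), ("B", emissionprob)]:
            if (arr < 0).any() or not np.allclose(arr.sum(axis=1), 1.0, atol=1e-9):
                raise ValueError(f"rows of {name} must be non-negative and sum to 1")
        self.startprob_, self.transmat_, self.emissionprob_ = \
            startprob, transmat, emissionprob
        return self

    # -- inference ----------------------------------------------------------

    def _log_params(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return (_safe_log(self.startprob_), _safe_log(self.transmat_),
                _safe_log(self.emissionprob_))

    def loglikelihood(self, sequence: Sequence[str]) -> float:
        """log P(S | lambda) by the forward recursion in log space."""
        obs = self._encode(sequence)
        if len(obs) == 0:
            raise ValueError("empty sequence")
        log_pi, log_T, log_B = self._log_params()
        alpha = log_pi + log_B[:, obs[0]]
        for o in obs[1:]:
            alpha = logsumexp(alpha[:, None] + log_T, axis=0) + log_B[:, o]
        return float(logsumexp(alpha))

    def likelihood(self, sequence: Sequence[str]) -> float:
        """P(S | lambda); prefer :meth:`loglikelihood` for long sequences."""
        return float(np.exp(self.loglikelihood(sequence)))

    def _forward_linear(self, sequence: Sequence[str]) -> float:
        # unscaled linear-space forward pass; underflows past ~1e2 symbols,
        # kept as an internal cross-check of the log-space recursion
        obs = self._encode(sequence)
        alpha = self.startprob_ * self.emissionprob_[:, obs[0]]
        for o in obs[1:]:
            alpha = (alpha @ self.transmat_) * self.emissionprob_[:, o]
        return float(alpha.sum())

    def posterior(self, sequence: Sequence[str]) -> np.ndarray:
        """Forward-backward smoothing: (len, n_states) posteriors, rows sum to 1."""
        obs = self._encode(sequence)
        if len(obs) == 0:
            raise ValueError("empty sequence")
        log_pi, log_T, log_B = self._log_params()
        L, n = len(obs), len(self.states)
        log_alpha = np.empty((L, n))
        log_alpha[0] = log_pi + log_B[:, obs[0]]
        for t in range(1, L):
            log_alpha[t] = logsumexp(log_alpha[t - 1][:, None] + log_T, axis=0) \
                + log_B[:, obs[t]]
        log_beta = np.zeros((L, n))
        for t in range(L - 2, -1, -1):
            log_beta[t] = logsumexp(
                log_T + log_B[:, obs[t + 1]][None, :] + log_beta[t + 1][None, :], axis=1)
        log_gamma = log_alpha + log_beta
        log_gamma -= logsumexp(log_gamma, axis=1, keepdims=True)
        return np.exp(log_gamma)

    def viterbi(self, sequence: Sequence[str]) -> list[str]:
        """Most probable hidden path; exact ties resolve to the earlier state
        (i.e. toward "normal" with the default ordering)."""
        obs = self._encode(sequence)
        if len(obs) == 0:
            raise ValueError("empty sequence")
        log_pi, log_T, log_B = self._log_params()
        L, n = len(obs), len(self.states)
        delta = log_pi + log_B[:, obs[0]]
        back = np.zeros((L, n), dtype=int)
        for t in range(1, L):
            cand = delta[:, None] + log_T
            back[t] = cand.argmax(axis=0)
            delta = cand[back[t], np.arange(n)] + log_B[:, obs[t]]
        path = np.empty(L, dtype=int)
        path[-1] = int(delta.argmax())
        for t in range(L - 1, 0, -1):
            path[t - 1] = back[t, path[t]]
        return [self.states[i] for i in path]

    def viterbi_logprob(self, sequence: Sequence[str]) -> float:
        """log probability of the Viterbi path (<= forward log-likelihood)."""
        obs = self._encode(sequence)
        log_pi, log_T, log_B = self._log_params()
        delta = log_pi + log_B[:, obs[0]]
        for o in obs[1:]:
            delta = (delta[:, None] + log_T).max(axis=0) + log_B[:, o]
        return float(delta.max())

    # -- scoring ------------------------------------------------------------

    def score_window(self, sequence: Sequence[str]) -> tuple[float, float]:
        """Group score over a scoring window: (P(AIA), P(normal)).

        P(AIA) is the mean per-position posterior of the AIA state over the
        window (default use: one calendar day of 24 hourly symbols, or the
        day's candidate event hours).
        """
        if len(sequence) == 0:
            raise ValueError("empty scoring window")
        p_aia = float(self.posterior(sequence)[:, self.aia_index_].mean())
        return p_aia, 1.0 - p_aia
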