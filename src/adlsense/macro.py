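"""Daily-routine anomaly detection via Markov-chain entropy rates.

A person's day is summarised as a sequence of 144 ten-minute activity
states.  Days are first clustered into a low-active (D1) and a high-active
(D2) category; a second clustering maps each 10-minute multi-sensor window
to a discrete state.  For each category a first-order Markov chain is
fitted to the training days, and the entropy rate

    xi = - sum_{a,b} P_a * P_ab * log(P_ab)        (natural log, nats)

quantifies how regular the routine is: P_a is the empirical state
occupancy and P_ab the transition probability.  Unlike the plain
transition entropy ``eps = - sum P_ab log P_ab``, the entropy rate weights
each row by how often its state is actually visited, so it distinguishes
a->b from b->a traffic when the two states are unequally occupied.

Verification days give per-day entropy rates around the training rate
``xi_T``; their root-mean-square deviation sigma defines the boundary

    Delta = xi_T +/- mu * sigma

and test days whose entropy rate leaves Delta are flagged as anomalous
(two-sided by default — abnormally *regular* days, e.g. away days, are
anomalies too; the literal one-sided ``xi > upper`` rule is available).
By default a day's entropy rate is the cross entropy rate of its own
empirical chain scored under the trained category model, so days that are
internally regular but occupy unusual states (visitors, restlessness)
still deviate; the day's self-contained entropy rate is available as an
alternative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.cluster import KMeans

__all__ = [
    "DayCategories",
    "MarkovModel",
    "EntropyProfile",
    "cluster_days",
    "map_states",
    "fit_markov",
    "entropy",
    "entropy_rate",
    "deviation_bounds",
    "EntropyRateDetector",
    "weekly_sensitivity",
    "anomaly_notification_correlation",
]

CATEGORIES = ("D1", "D2")


@dataclass
class DayCategories:
    """Two fixed day-level centroids; D1 is the lower-activity category."""

    centroids: np.ndarray  # (2, n_features), row 0 = D1
    labels: np.ndarray  # training-day assignment, values in {"D1", "D2"}

    def assign(self, day_vectors: np.ndarray) -> np.ndarray:
        """Nearest-centroid assignment for (possibly unseen) days."""
        d = np.linalg.norm(day_vectors[:, None, :] - self.centroids[None], axis=2)
        return np.asarray(CATEGORIES, dtype=object)[d.argmin(axis=1)]


@dataclass
class MarkovModel:
    """Empirical first-order chain: occupancy P_a and transition matrix T.

    Rows of ``transitions`` with at least one observed transition sum to 1;
    rows never left (``row_observed`` False) are all-zero and contribute
    nothing to entropy quantities.
    """

    n_states: int
    transitions: np.ndarray  # (n_states, n_states)
    state_probs: np.ndarray  # (n_states,)
    row_observed: np.ndarray  # (n_states,) bool
    category: str | None = None


def cluster_days(day_vectors: np.ndarray, k: int = 2, seed: int | None = 0) -> DayCategories:
    """K-means over flattened training days, relabelled so D1 is low-activity.

    Centroids are learned once on the training days and frozen; later days
    are assigned by nearest centroid.  All-identical training days collapse
    to a single category (with a warning).
    """
    day_vectors = np.asarray(day_vectors, dtype=float)
    if day_vectors.ndim == 3:
        day_vectors = day_vectors.reshape(day_vectors.shape[0], -1)
    if len(day_vectors) < k:
        raise ValueError(f"need at least {k} training days, got {len(day_vectors)}")
    if len(np.unique(day_vectors, axis=0)) < k:
        warnings.warn("all training days identical; one day category is empty",
                      stacklevel=2)
        centroid = day_vectors[0]
        centroids = np.stack([centroid, centroid])
        labels = np.asarray(["D1"] * len(day_vectors), dtype=object)
        return DayCategories(centroids, labels)

    km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(day_vectors)
    order = np.argsort(km.cluster_centers_.sum(axis=1), kind="stable")
    centroids = km.cluster_centers_[order]
    relabel = {old: CATEGORIES[new] for new, old in enumerate(order)}
    labels = np.asarray([relabel[l] for l in km.labels_], dtype=object)
    return DayCategories(centroids, labels)


def map_states(
    windows: np.ndarray, n_states: int, seed: int | None = 0
) -> tuple[np.ndarray, KMeans]:
    """Learn the state codebook: K-means over all training 10-minute windows.

    `windows` is (n_windows, n_sensors); returns the (n_states, n_sensors)
    codebook and the fitted clusterer (used for nearest-centroid mapping of
    verification/test windows with the codebook frozen).
    """
    windows = np.asarray(windows, dtype=float)
    if n_states < 2:
        raise ValueError("n_states must be >= 2")
    if len(np.unique(windows, axis=0)) < n_states:
        raise ValueError("fewer distinct windows than requested states")
    km = KMeans(n_clusters=n_states, n_init=10, random_state=seed).fit(windows)
    return km.cluster_centers_.copy(), km


def discretise(grid_values: np.ndarray, km: KMeans) -> np.ndarray:
    """Map a (days, slots, sensors) tensor to (days, slots) state ids."""
    days, slots, n = grid_values.shape
    flat = grid_values.reshape(-1, n)
    return km.predict(flat).reshape(days, slots)


def fit_markov(
    sequences: list[np.ndarray] | np.ndarray,
    n_states: int,
    category: str | None = None,
) -> MarkovModel:
    """Count-and-normalise estimation of T and P_a from state sequences.

    Transitions are counted within each sequence only (a day's chain never
    crosses midnight into the next day); occupancy counts every position.
    """
    if isinstance(sequences, np.ndarray) and sequences.ndim == 1:
        sequences = [sequences]
    sequences = [np.asarray(s, dtype=int) for s in sequences]
    if not sequences or all(len(s) < 2 for s in sequences):
        raise ValueError("need at least one sequence of length >= 2")

    counts = np.zeros((n_states, n_states))
    occupancy = np.zeros(n_states)
    for seq in sequences:
        if seq.size and (seq.min() < 0 or seq.max() >= n_states):
            raise ValueError("state id outside [0, n_states)")
        np.add.at(occupancy, seq, 1.0)
        if len(seq) >= 2:
            np.add.at(counts, (seq[:-1], seq[1:]), 1.0)

    row_totals = counts.sum(axis=1)
    row_observed = row_totals > 0
    transitions = np.zeros_like(counts)
    transitions[row_observed] = counts[row_observed] / row_totals[row_observed, None]
    state_probs = occupancy / occupancy.sum()
    return MarkovModel(n_states, transitions, state_probs, row_observed, category)


def _xlogx(p: np.ndarray) -> np.ndarray:
    """p * log p with the 0 log 0 := 0 convention."""
    out = np.zeros_like(p)
    nz = p > 0
    out[nz] = p[nz] * np.log(p[nz])
    return out


def entropy(model: MarkovModel) -> float:
    """Transition entropy eps = -sum_ab P_ab log P_ab (nats)."""
    return float(-_xlogx(model.transitions).sum())


def entropy_rate(model: MarkovModel) -> float:
    """Entropy rate xi = -sum_ab P_a P_ab log P_ab (nats).

    Uses the empirical occupancy P_a of the fitted chain, matching the
    count-based estimation of T, rather than the stationary distribution
    of T (rows without observations would leave the latter undefined).
    """
    row_terms = -_xlogx(model.transitions).sum(axis=1)
    return float((model.state_probs * row_terms).sum())


@dataclass
class EntropyProfile:
    """Training entropy rate, verification rates, and the deviation band."""

    xi_T: float
    xi_V: np.ndarray
    mu: float
    sigma: float = field(init=False)
    delta: tuple[float, float] = field(init=False)

    def __post_init__(self) -> None:
        self.xi_V = np.asarray(self.xi_V, dtype=float)
        if self.xi_V.size == 0:
            raise ValueError("verification set must contain at least one day")
        self.sigma = float(np.sqrt(np.mean((self.xi_V - self.xi_T) ** 2)))
        self.delta = (self.xi_T - self.mu * self.sigma,
                      self.xi_T + self.mu * self.sigma)


def deviation_bounds(xi_T: float, xi_V: np.ndarray, mu: float = 2.0) -> EntropyProfile:
    """Deviation boundaries Delta = xi_T +/- mu * sigma.

    sigma is the RMS deviation of the verification-day entropy rates from
    the training rate: ``sigma = sqrt(sum_i (xi_i - xi_T)^2 / v)``, which
    absorbs both their spread and any systematic offset.
    """
    return EntropyProfile(float(xi_T), xi_V, float(mu))


def _day_entropy_rate(
    seq: np.ndarray,
    n_states: int,
    mode: str,
    train_model: MarkovModel | None,
    smoothing: float = 0.01,
) -> float:
    """Entropy rate for a single day's state sequence.

    ``mode='cross'`` (default) keeps the day's empirical P_a and P_ab but
    scores the transitions under the trained category model's
    log-probabilities (additively smoothed so transitions unseen in
    training stay finite); the result is the day-vs-model cross entropy
    rate, which grows whenever the day's sequence distribution deviates
    from the trained chain — including shifts in *which* states the day
    occupies.  ``mode='own'`` instead fits the day's own chain and
    evaluates its entropy rate, measuring only within-day regularity
    (it is blind to a day that is perfectly regular in unusual states).
    """
    day_model = fit_markov([seq], n_states)
    if mode == "own":
        return entropy_rate(day_model)
    if mode != "cross":
        raise ValueError(f"unknown day-entropy mode {mode!r}")
    assert train_model is not None
    t = train_model.transitions
    smoothed = (t + smoothing) / (t + smoothing).sum(axis=1, keepdims=True)
    weights = day_model.state_probs[:, None] * day_model.transitions
    return float(-(weights * np.log(smoothed)).sum())


class EntropyRateDetector(BaseEstimator):
    """Flag days whose entropy rate leaves the learned deviation band.

    Fitting learns, on training days only: the two day-category centroids,
    the state codebook, one Markov model per category, and per-category
    deviation boundaries from verification days.  All learned state is then
    frozen; prediction assigns each test day to its nearest category,
    discretises it with the frozen codebook, computes its entropy rate, and
    flags it when the rate leaves that category's band.

    Parameters
    ----------
    n_states : size of the state codebook; default (None) uses the number
        of active sensors, one centroid per sensor.
    mu : confidence coefficient; 2.0 covers roughly 95% of normal days
        under an approximately Gaussian spread of verification rates.
    mode : "two_sided" (default) or "one_sided" (flag only ``xi > upper``).
    day_entropy : "cross" (default; day transitions scored under the
        trained category model, sensitive to any deviation from the
        learned routine) or "own" (each day's own chain, sensitive only
        to within-day irregularity).
    cross_smoothing : additive smoothing of trained transition rows when
        cross-scoring, bounding the penalty for transitions unseen in
        training.
    """

    def __init__(
        self,
        n_states: int | None = None,
        mu: float = 2.0,
        mode: str = "two_sided",
        day_entropy: str = "cross",
        cross_smoothing: float = 0.01,
        random_state: int | None = 0,
    ):
        self.n_states = n_states
        self.mu = mu
        self.mode = mode
        self.day_entropy = day_entropy
        self.cross_smoothing = cross_smoothing
        self.random_state = random_state

    def fit(self, X: np.ndarray, X_verification: np.ndarray) -> "EntropyRateDetector":
        """Learn categories, codebook, chains and bands.

        `X` and `X_verification` are normalised (days, slots, sensors)
        tensors: the training and verification partitions of the history.
        """
        X = np.asarray(X, dtype=float)
        X_verification = np.asarray(X_verification, dtype=float)
        n_sensors = X.shape[2]
        self.n_states_ = self.n_states or n_sensors

        self.categories_ = cluster_days(X, seed=self.random_state)
        self.codebook_, self._km = map_states(
            X.reshape(-1, n_sensors), self.n_states_, seed=self.random_state)

        train_states = discretise(X, self._km)
        self.models_: dict[str, MarkovModel] = {}
        for cat in CATEGORIES:
            seqs = [train_states[i] for i in range(len(X))
                    if self.categories_.labels[i] == cat]
            if seqs:
                self.models_[cat] = fit_markov(seqs, self.n_states_, category=cat)
        if not self.models_:
            raise ValueError("no training days")

        verif_cats = self.categories_.assign(
            X_verification.reshape(len(X_verification), -1))
        verif_states = discretise(X_verification, self._km)
        if len(X_verification) == 0:
            raise ValueError("verification set must contain at least one day")
        # One sigma over the whole verification set (each day's deviation
        # measured from its own category's training rate): the confidence
        # band is estimated once, while each category keeps its own centre.
        verif_xi: dict[str, list[float]] = {c: [] for c in self.models_}
        deviations: list[float] = []
        for i in range(len(X_verification)):
            cat = verif_cats[i]
            if cat not in self.models_:  # empty training category
                cat = next(iter(self.models_))
            xi = _day_entropy_rate(
                verif_states[i], self.n_states_, self.day_entropy,
                self.models_[cat], self.cross_smoothing)
            verif_xi[cat].append(xi)
            deviations.append(xi - entropy_rate(self.models_[cat]))

        sigma = float(np.sqrt(np.mean(np.square(deviations))))
        self.sigma_ = sigma
        self.profiles_: dict[str, EntropyProfile] = {}
        for cat, model in self.models_.items():
            xi_T = entropy_rate(model)
            profile = EntropyProfile(xi_T, np.asarray(verif_xi[cat] or [xi_T]),
                                     self.mu)
            profile.sigma = sigma
            profile.delta = (xi_T - self.mu * sigma, xi_T + self.mu * sigma)
            self.profiles_[cat] = profile
        return self

    def score_days(self, X: np.ndarray, days: pd.DatetimeIndex | None = None) -> pd.DataFrame:
        """Per-day category, entropy rate, band and flag for a test tensor."""
        X = np.asarray(X, dtype=float)
        cats = self.categories_.assign(X.reshape(len(X), -1))
        states = discretise(X, self._km)
        rows = []
        for i in range(len(X)):
            cat = cats[i]
            if cat not in self.models_:
                cat = next(iter(self.models_))
            if len(states[i]) < 2:
                warnings.warn(f"day {i} has fewer than 2 windows; skipped", stacklevel=2)
                continue
            xi = _day_entropy_rate(
                states[i], self.n_states_, self.day_entropy, self.models_[cat],
                self.cross_smoothing)
            lo, hi = self.profiles_[cat].delta
            flagged = xi > hi if self.mode == "one_sided" else (xi < lo or xi > hi)
            rows.append((days[i] if days is not None else i, cat, xi, lo, hi, flagged))
        return pd.DataFrame(
            rows, columns=["date", "category", "xi", "delta_lower", "delta_upper",
                           "flagged"])

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Boolean anomaly flag per test day."""
        return self.score_days(X)["flagged"].to_numpy()


def weekly_sensitivity(
    day_flags: np.ndarray,
    truth_day_labels: list[str] | np.ndarray,
    days_per_week: int = 7,
    min_days_anomalous: int = 2,
) -> float | None:
    """Fraction of anomaly-labelled weeks confirmed by the ground truth.

    A week is *labelled* anomalous when it contains at least
    `min_days_anomalous` flagged days, and *confirmed* when the ground
    truth marks at least one of its days non-normal.  Returns
    ``W_val / W_tot``, or None when no week is labelled.
    """
    day_flags = np.asarray(day_flags, dtype=bool)
    truth = np.asarray(truth_day_labels, dtype=object)
    if len(day_flags) != len(truth):
        raise ValueError("flags and truth must be aligned")
    w_tot = w_val = 0
    for w0 in range(0, len(day_flags), days_per_week):
        flags = day_flags[w0:w0 + days_per_week]
        if flags.sum() >= min_days_anomalous:
            w_tot += 1
            if (truth[w0:w0 + days_per_week] != "normal").any():
                w_val += 1
    if w_tot == 0:
        return None
    return w_val / w_tot


def anomaly_notification_correlation(
    n_anomalies: np.ndarray, n_notifications: np.ndarray
) -> float | None:
    """Pearson correlation between per-participant anomaly and notification counts.

    Both vectors are min-max normalised first (this leaves the Pearson
    coefficient unchanged but mirrors how the counts are reported).
    Returns None with a warning when either vector is constant.
    """
    a = np.asarray(n_anomalies, dtype=float)
    b = np.asarray(n_notifications, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("need two aligned vectors of length >= 2")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        warnings.warn("correlation undefined for a constant count vector", stacklevel=2)
        return None
    a = (a - a.min()) / np.ptp(a)
    b = (b - b.min()) / np.ptp(b)
    return float(np.corrcoef(a, b)[0, 1])
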