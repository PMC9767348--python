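"""First-order Markov transition models and entropy-rate estimation.

The unpredictability of a combined-signal state sequence is quantified as
the entropy rate of a discrete-state first-order Markov process over the
eight signal combinations,

.. math::

    \\hat H = \\sum_i \\pi_i \\Big( -\\sum_{j \\ne i} p_{ij} \\log_2 p_{ij} \\Big)

in bits per transition, where :math:`p_{ij}` are the empirical
conditional probabilities of moving from combination *i* to *j* and
:math:`\\pi` is the stationary weighting over source states.  Because a
transition is defined as a *change* of combination, the diagonal is
structurally zero and the entropy rate lies in ``[0, log2(k-1)]`` — for
the eight-state space, 0 to 2.807 bits.  Zero means each combination is
always followed by one fixed other combination (perfectly predictable);
the maximum means every admissible next combination is equally likely.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .events import N_STATES, SessionRecord, StateSequence, build_state_sequence

__all__ = [
    "TransitionModel",
    "EntropyResult",
    "InsufficientDataError",
    "fit_transition_model",
    "entropy_rate",
    "session_entropy",
    "classify_unpredictability",
    "CutoffReport",
    "MarkovEntropy",
    "MarkovEntropyResults",
]

#: Transition counts below this leave the plug-in estimate flagged as noisy.
MIN_RELIABLE_TRANSITIONS = 10


class InsufficientDataError(ValueError):
    """Sequence has no transitions; the entropy rate is undefined."""


@dataclass
class TransitionModel:
    """Transition counts, row-stochastic probabilities and state weights.

    ``counts[i, j]`` is the number of observed i→j changes (diagonal is
    structurally zero: self-transitions are not defined for a process of
    combination *changes*).  ``probs`` row-normalizes the counts; rows of
    states never seen as a transition source are left at zero and listed
    in ``unvisited``.  ``state_dist`` is the stationary weighting π.
    """

    counts: np.ndarray
    probs: np.ndarray
    state_dist: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        self.probs = np.asarray(self.probs, dtype=float)
        self.state_dist = np.asarray(self.state_dist, dtype=float)
        k = self.n_states
        if self.counts.shape != (k, k) or self.probs.shape != (k, k):
            raise ValueError("counts and probs must be square and congruent")
        if np.any(np.diagonal(self.counts) != 0) or np.any(
            np.diagonal(self.probs) != 0
        ):
            raise ValueError("diagonal must be zero (self-transitions excluded)")
        if np.any(self.counts < 0) or np.any(self.probs < 0):
            raise ValueError("negative entries")
        row_sums = self.probs.sum(axis=1)
        visited = ~self.unvisited_rows
        if not np.allclose(row_sums[visited], 1.0, atol=1e-12):
            raise ValueError("visited rows of probs must sum to 1")
        if abs(self.state_dist.sum() - 1.0) > 1e-12:
            raise ValueError("state_dist must sum to 1")

    @property
    def n_states(self) -> int:
        return self.probs.shape[0]

    @property
    def unvisited_rows(self) -> np.ndarray:
        """Boolean mask of states never observed as a transition source."""
        return self.probs.sum(axis=1) == 0

    @property
    def n_transitions(self) -> int:
        return int(round(self.counts.sum()))


@dataclass
class EntropyResult:
    """Entropy rate of a fitted transition model, in bits per transition."""

    entropy_rate: float
    per_state_entropy: np.ndarray
    n_transitions: int
    n_states_visited: int
    session_id: str | None = None
    flags: list[str] = field(default_factory=list)


def fit_transition_model(
    seq: StateSequence | list[int],
    smoothing: float = 0.0,
    n_states: int = N_STATES,
    stationary: str = "empirical",
) -> TransitionModel:
    """Fit the first-order transition model of a state sequence.

    Parameters
    ----------
    seq : StateSequence or list of int
        Run-length-deduplicated states in ``0..n_states-1``.
    smoothing : float
        Optional additive (Laplace) count added to the *off-diagonal*
        cells of visited rows only; 0 (default) gives the maximum-
        likelihood plug-in.
    n_states : int
        State-space size (8 for the three-channel space).
    stationary : {"empirical", "eigen"}
        π as the empirical distribution of transition *source* states
        (default; robust on short sequences), or as the leading left
        eigenvector of the estimated matrix restricted to visited states.

    Raises
    ------
    InsufficientDataError
        If the sequence contains no transitions.
    """
    states = np.asarray(
        seq.states if isinstance(seq, StateSequence) else seq, dtype=int
    )
    if len(states) < 2:
        raise InsufficientDataError(
            "at least one transition is required to fit a transition model"
        )
    if smoothing < 0:
        raise ValueError("smoothing must be nonnegative")
    k = n_states
    counts = np.zeros((k, k))
    np.add.at(counts, (states[:-1], states[1:]), 1.0)
    if np.any(np.diagonal(counts) != 0):
        raise ValueError("sequence contains a self-transition; deduplicate first")
    row_sums = counts.sum(axis=1)
    visited = row_sums > 0
    work = counts.copy()
    if smoothing > 0:
        off_diag = ~np.eye(k, dtype=bool)
        work[np.ix_(visited, np.arange(k))] += smoothing * off_diag[visited]
        work[:, :] *= off_diag  # keep the structural zero diagonal
        work[~visited] = 0.0
    probs = np.zeros((k, k))
    denom = work.sum(axis=1)
    probs[visited] = work[visited] / denom[visited, None]
    if stationary == "empirical":
        pi = row_sums / row_sums.sum()
    elif stationary == "eigen":
        pi = _stationary_eigenvector(probs, visited)
    else:
        raise ValueError("stationary must be 'empirical' or 'eigen'")
    return TransitionModel(counts=counts, probs=probs, state_dist=pi)


def _stationary_eigenvector(probs: np.ndarray, visited: np.ndarray) -> np.ndarray:
    """Left eigenvector of the chain restricted to visited source states."""
    idx = np.flatnonzero(visited)
    sub = probs[np.ix_(idx, idx)]
    # renormalize rows: mass leaking to never-source states is dropped
    rs = sub.sum(axis=1)
    rs[rs == 0] = 1.0
    sub = sub / rs[:, None]
    vals, vecs = np.linalg.eig(sub.T)
    lead = np.argmin(np.abs(vals - 1.0))
    v = np.real(vecs[:, lead])
    v = np.abs(v)
    pi = np.zeros(probs.shape[0])
    pi[idx] = v / v.sum()
    return pi


def entropy_rate(model: TransitionModel) -> EntropyResult:
    """Entropy rate of a transition model, in bits per transition.

    Per-state entropies use base-2 logarithms with the convention
    ``0 * log 0 = 0``; unvisited states carry zero stationary weight and
    contribute nothing.
    """
    p = model.probs
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, -p * np.log2(np.where(p > 0, p, 1.0)), 0.0)
    h_states = terms.sum(axis=1)
    h = float(model.state_dist @ h_states)
    n_trans = model.n_transitions
    flags = []
    if n_trans < MIN_RELIABLE_TRANSITIONS:
        flags.append("few_transitions")
    return EntropyResult(
        entropy_rate=h,
        per_state_entropy=h_states,
        n_transitions=n_trans,
        n_states_visited=int((~model.unvisited_rows).sum()),
        flags=flags,
    )


def session_entropy(
    session: SessionRecord,
    smoothing: float = 0.0,
    stationary: str = "empirical",
) -> EntropyResult:
    """Entropy rate of one coded session (state construction + model fit)."""
    seq = build_state_sequence(session)
    try:
        model = fit_transition_model(seq, smoothing=smoothing, stationary=stationary)
    except InsufficientDataError as err:
        raise InsufficientDataError(
            f"session {session.session_id!r}: {err}"
        ) from err
    result = entropy_rate(model)
    result.session_id = session.session_id
    return result


@dataclass
class CutoffReport:
    """Extreme-group dichotomization of a set of entropy rates."""

    labels: list[str]
    cut_value: float
    quantile: float
    interpolation: str
    n_high: int
    n_low_moderate: int
    high_range: tuple[float, float] | None
    low_moderate_range: tuple[float, float] | None

    def to_dict(self) -> dict:
        return {
            "cut_value": self.cut_value,
            "quantile_rule": f"empirical {self.quantile:.0%} quantile, "
            f"{self.interpolation} interpolation; ties at the cut -> low_moderate",
            "n_high": self.n_high,
            "n_low_moderate": self.n_low_moderate,
            "high_range": list(self.high_range) if self.high_range else None,
            "low_moderate_range": list(self.low_moderate_range)
            if self.low_moderate_range
            else None,
        }


def classify_unpredictability(
    values, high_quantile: float = 0.85
) -> CutoffReport:
    """Label entropy rates as ``high`` vs ``low_moderate`` risk groups.

    Values strictly above the empirical ``high_quantile`` cut (linear
    interpolation between order statistics) are labeled ``high``; ties at
    the cut go to ``low_moderate``.  With the default 0.85 this isolates
    the highest-unpredictability 15% of a cohort as the extreme group.
    """
    x = np.asarray(values, dtype=float)
    if len(x) < 2:
        raise ValueError("at least two values are required to set a cut-off")
    if not np.all(np.isfinite(x)):
        raise ValueError("entropy rates must be finite")
    if not (0 < high_quantile < 1):
        raise ValueError("high_quantile must lie in (0, 1)")
    cut = float(np.quantile(x, high_quantile, method="linear"))
    if np.ptp(x) == 0:
        warnings.warn(
            "all entropy rates identical; no high group can be formed",
            UserWarning,
            stacklevel=2,
        )
    high = x > cut
    labels = ["high" if h else "low_moderate" for h in high]
    return CutoffReport(
        labels=labels,
        cut_value=cut,
        quantile=high_quantile,
        interpolation="linear",
        n_high=int(high.sum()),
        n_low_moderate=int((~high).sum()),
        high_range=(float(x[high].min()), float(x[high].max()))
        if high.any()
        else None,
        low_moderate_range=(float(x[~high].min()), float(x[~high].max()))
        if (~high).any()
        else None,
    )


class MarkovEntropy:
    """Markov unpredictability model for one coded session or state sequence.

    Statsmodels-style front end: construct from data, call :meth:`fit`.

    Examples
    --------
    >>> from entrate.events import SessionRecord, SignalEvent
    >>> s = SessionRecord("demo", 600, [SignalEvent("auditory", 10, 20)])
    >>> res = MarkovEntropy(s).fit()
    >>> res.entropy_rate
    0.0
    """

    def __init__(self, data: SessionRecord | StateSequence):
        if isinstance(data, SessionRecord):
            self.session = data
            self.sequence = build_state_sequence(data)
        elif isinstance(data, StateSequence):
            self.session = None
            self.sequence = data
        else:
            raise TypeError("data must be a SessionRecord or StateSequence")

    @classmethod
    def from_states(cls, states, session_id: str = "") -> "MarkovEntropy":
        return cls(StateSequence(session_id, tuple(states)))

    def fit(
        self, smoothing: float = 0.0, stationary: str = "empirical"
    ) -> "MarkovEntropyResults":
        model = fit_transition_model(
            self.sequence, smoothing=smoothing, stationary=stationary
        )
        result = entropy_rate(model)
        result.session_id = self.sequence.session_id
        return MarkovEntropyResults(self, model, result)


class MarkovEntropyResults:
    """Fitted transition structure and entropy rate of one session."""

    def __init__(
        self, model: MarkovEntropy, transition_model: TransitionModel,
        result: EntropyResult,
    ):
        self.model = model
        self.transition_model = transition_model
        self._result = result

    @property
    def entropy_rate(self) -> float:
        return self._result.entropy_rate

    @property
    def per_state_entropy(self) -> np.ndarray:
        return self._result.per_state_entropy

    @property
    def n_transitions(self) -> int:
        return self._result.n_transitions

    @property
    def n_states_visited(self) -> int:
        return self._result.n_states_visited

    @property
    def flags(self) -> list[str]:
        return self._result.flags

    def summary(self) -> str:
        r = self._result
        lines = [
            "Markov entropy-rate results",
            "=" * 40,
            f"session:          {r.session_id or '<sequence>'}",
            f"entropy rate:     {r.entropy_rate:.4f} bits/transition",
            f"theoretical max:  {np.log2(self.transition_model.n_states - 1):.4f}",
            f"transitions:      {r.n_transitions}",
            f"states visited:   {r.n_states_visited} / {self.transition_model.n_states}",
            f"flags:            {', '.join(r.flags) or 'none'}",
        ]
        return "\n".join(lines)
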