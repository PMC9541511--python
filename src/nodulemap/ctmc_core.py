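"""Three-state continuous-time Markov model of nodule-type evolution.

State space, in fixed order: NON = 0 (nonnodulating), FT = 1
(fixation-thread nodules), SYM = 2 (symbiosome nodules).  All matrices and
vectors in this package follow this order.

The primary model is irreversible: nodulation arose once, deep in the
ancestry of the clade under study, so only FT->NON, FT->SYM and SYM->NON
are allowed and NON is absorbing.  The root is constrained to FT by a
degenerate root prior (0, 1, 0).  Both the allowed-transition mask and the
root prior are configurable, so an all-transitions model or a uniform root
prior can be fitted for sensitivity analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .treedata_io import Chronogram, TipObservations

__all__ = [
    "NON",
    "FT",
    "SYM",
    "STATES",
    "TransitionModel",
    "FitResult",
    "ImpossibleDataError",
    "NonIdentifiableError",
    "ConvergenceError",
    "constrained_mask",
    "all_transitions_mask",
    "root_prior_ft",
    "root_prior_uniform",
    "build_rate_matrix",
    "transition_matrix",
    "expm_qt",
    "compute_partials",
    "prune_loglik",
    "fit_rates_ml",
]

NON, FT, SYM = 0, 1, 2
STATES = ("NON", "FT", "SYM")
N_STATES = 3

RATE_BOUNDS = (1e-8, 10.0)  # events per lineage per Myr


class ImpossibleDataError(ValueError):
    """Tip data have probability zero under the constrained model."""


class NonIdentifiableError(ValueError):
    """The likelihood carries no information about the rates."""


class ConvergenceError(RuntimeError):
    """All optimizer starts failed to converge."""


def constrained_mask() -> np.ndarray:
    """Default mask: FT->NON, FT->SYM, SYM->NON only (NON absorbing)."""
    m = np.zeros((3, 3), dtype=bool)
    m[FT, NON] = m[FT, SYM] = m[SYM, NON] = True
    return m


def all_transitions_mask() -> np.ndarray:
    return ~np.eye(3, dtype=bool)


def root_prior_ft() -> np.ndarray:
    return np.array([0.0, 1.0, 0.0])


def root_prior_uniform() -> np.ndarray:
    return np.full(3, 1.0 / 3.0)


def _state_index(s) -> int:
    if isinstance(s, str):
        return STATES.index(s.upper())
    return int(s)


def _reachability(mask: np.ndarray) -> np.ndarray:
    """Boolean closure: reach[i, j] iff j is reachable from i (incl. i)."""
    reach = mask | np.eye(3, dtype=bool)
    for _ in range(2):  # 3 states: two squarings suffice
        reach = reach | (reach @ reach)
    return reach


@dataclass
class TransitionModel:
    """Masked rate matrix plus root prior.

    ``rates`` maps allowed ordered state pairs to instantaneous rates in
    events per lineage per Myr; Q has those rates off-diagonal and
    row sums of zero.
    """

    mask: np.ndarray
    rates: dict[tuple[int, int], float]
    root_prior: np.ndarray
    Q: np.ndarray = field(init=False)
    reach: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != (3, 3) or self.mask.diagonal().any():
            raise ValueError("mask must be 3x3 boolean with a False diagonal")
        self.root_prior = np.asarray(self.root_prior, dtype=float)
        if self.root_prior.shape != (3,) or (self.root_prior < 0).any():
            raise ValueError("root prior must be a non-negative length-3 vector")
        tot = self.root_prior.sum()
        if not np.isclose(tot, 1.0):
            raise ValueError("root prior must sum to 1")
        self.root_prior = self.root_prior / tot
        Q = np.zeros((3, 3))
        for (i, j), r in self.rates.items():
            if i == j or not self.mask[i, j]:
                raise ValueError(
                    f"rate supplied for disallowed transition "
                    f"{STATES[i]}->{STATES[j]}"
                )
            if r < 0:
                raise ValueError(f"negative rate for {STATES[i]}->{STATES[j]}")
            Q[i, j] = r
        np.fill_diagonal(Q, -Q.sum(axis=1))
        self.Q = Q
        self.reach = _reachability(self.mask)

    def rate(self, a, b) -> float:
        return float(self.Q[_state_index(a), _state_index(b)])

    def transition_matrix(self, t: float) -> np.ndarray:
        return transition_matrix(self, t)

    def to_json_dict(self) -> dict:
        return {
            "states": list(STATES),
            "mask": self.mask.astype(int).tolist(),
            "rates": {
                f"{STATES[i]}->{STATES[j]}": r for (i, j), r in self.rates.items()
            },
            "Q": self.Q.tolist(),
            "root_prior": self.root_prior.tolist(),
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "TransitionModel":
        mask = np.asarray(d["mask"], dtype=bool)
        rates = {}
        for key, r in d["rates"].items():
            a, b = key.split("->")
            rates[(_state_index(a), _state_index(b))] = float(r)
        return cls(mask, rates, np.asarray(d["root_prior"], dtype=float))


def build_rate_matrix(
    rates: dict,
    mask: np.ndarray | None = None,
    root_prior: np.ndarray | None = None,
) -> TransitionModel:
    """Build a :class:`TransitionModel` from a transition->rate mapping.

    Keys may be ``(from, to)`` pairs of indices or state names, or
    ``"FT->NON"`` strings.  Allowed transitions without a supplied rate get
    rate 0; a rate on a masked transition is an error.
    """
    mask = constrained_mask() if mask is None else np.asarray(mask, dtype=bool)
    prior = root_prior_ft() if root_prior is None else root_prior
    norm: dict[tuple[int, int], float] = {}
    for key, r in rates.items():
        if isinstance(key, str):
            a, b = key.replace(" ", "").split("->")
        else:
            a, b = key
        norm[(_state_index(a), _state_index(b))] = float(r)
    return TransitionModel(mask, norm, prior)


# --- matrix exponential -----------------------------------------------------

# Pade(7) coefficients; with the operator norm scaled below 0.5 the
# approximant is accurate to ~1e-15 on these 3x3 generators.
_PADE7 = (17297280.0, 8648640.0, 1995840.0, 277200.0, 25200.0, 1512.0, 56.0, 1.0)


def expm_qt(Q: np.ndarray, t) -> np.ndarray:
    """exp(Q*t) for one duration or a batch of durations.

    Scaling-and-squaring with a Pade approximant, vectorized over the batch
    so per-branch transition matrices for a whole tree come from one call.
    Returns shape (3, 3) for scalar ``t`` and (len(t), 3, 3) otherwise.
    """
    scalar = np.isscalar(t) or np.ndim(t) == 0
    ts = np.atleast_1d(np.asarray(t, dtype=float))
    if (ts < 0).any():
        raise ValueError("durations must be non-negative")
    A = Q[None, :, :] * ts[:, None, None]
    norm = np.abs(A).sum(axis=2).max() if A.size else 0.0
    s = 0 if norm <= 0.5 else int(np.ceil(np.log2(norm / 0.5)))
    A = A / (2.0 ** s)
    I = np.broadcast_to(np.eye(3), A.shape)
    A2 = A @ A
    A4 = A2 @ A2
    A6 = A2 @ A4
    b = _PADE7
    U = A @ (b[7] * A6 + b[5] * A4 + b[3] * A2 + b[1] * I)
    V = b[6] * A6 + b[4] * A4 + b[2] * A2 + b[0] * I
    P = np.linalg.solve(V - U, V + U)
    for _ in range(s):
        P = P @ P
    P = np.clip(P, 0.0, 1.0)
    P[:, ~_reachability(Q != 0)] = 0.0  # structural zeros stay exactly zero
    P[ts == 0.0] = np.eye(3)
    return P[0] if scalar else P


def transition_matrix(model: TransitionModel, t: float) -> np.ndarray:
    """P(t) = exp(Q t): row-stochastic transition probabilities over t Myr."""
    if t < 0:
        raise ValueError("duration t must be non-negative")
    return expm_qt(model.Q, float(t))


# --- pruning likelihood -----------------------------------------------------


@dataclass
class Partials:
    """Post-order conditional likelihoods, rescaled per node.

    ``L[i]`` is proportional to P(data below node i | state of i), with the
    per-node rescaling factors accumulated in ``log_scale``.  ``pmats[i]``
    is the transition matrix along the branch above node i (identity at the
    root, where it is unused).
    """

    L: np.ndarray
    log_scale: float
    pmats: np.ndarray


def compute_partials(
    tree: Chronogram, obs: TipObservations, model: TransitionModel
) -> Partials:
    n = tree.n_nodes
    L = obs.likelihood_matrix(tree)
    pmats = expm_qt(model.Q, tree.branch_length)
    pmats[0] = np.eye(3)
    log_scale = 0.0
    for i in tree.postorder():
        if tree.is_tip[i]:
            continue
        v = np.ones(3)
        for c in tree.children[i]:
            v = v * (pmats[c] @ L[c])
        m = v.max()
        if m <= 0.0:
            raise ImpossibleDataError(
                f"tip data below node '{tree.labels[i]}' are impossible under "
                f"the constrained model"
            )
        L[i] = v / m
        log_scale += np.log(m)
    return Partials(L=L, log_scale=log_scale, pmats=pmats)


def prune_loglik(
    tree: Chronogram,
    obs: TipObservations,
    model: TransitionModel,
    partials: Partials | None = None,
) -> float:
    """Log-likelihood of the tip data under the model (pruning recursion)."""
    if partials is None:
        partials = compute_partials(tree, obs, model)
    lik = float(model.root_prior @ partials.L[0])
    if lik <= 0.0:
        raise ImpossibleDataError(
            "tip data are impossible under the constrained model and root prior"
        )
    return np.log(lik) + partials.log_scale


# --- maximum-likelihood rate fitting ----------------------------------------


@dataclass
class FitResult:
    model: TransitionModel
    loglik: float
    report: dict

    def to_json_dict(self) -> dict:
        d = self.model.to_json_dict()
        d["loglik"] = self.loglik
        d["optimizer"] = self.report
        return d


def fit_rates_ml(
    tree: Chronogram,
    obs: TipObservations,
    mask: np.ndarray | None = None,
    root_prior: np.ndarray | None = None,
    *,
    n_random_starts: int = 5,
    seed: int = 0,
    bounds: tuple[float, float] = RATE_BOUNDS,
    tol: float = 1e-8,
) -> FitResult:
    """Fit transition rates by maximum likelihood.

    Bounded quasi-Newton (L-BFGS-B) on log-rates, with ``n_random_starts``
    log-uniform random starts plus one start at 1/tree-height (the scale at
    which about one event per lineage is expected).  Rates are bounded to
    ``bounds`` events/Myr.
    """
    mask = constrained_mask() if mask is None else np.asarray(mask, dtype=bool)
    prior = root_prior_ft() if root_prior is None else np.asarray(root_prior, float)
    keys = [(i, j) for i in range(3) for j in range(3) if mask[i, j]]
    if not keys:
        raise ValueError("mask allows no transitions")
    tipL = obs.likelihood_matrix(tree)[tree.is_tip]
    if np.all(tipL == 1.0):
        raise NonIdentifiableError(
            "all tips are uninformative (every state equally likely); "
            "rates cannot be identified"
        )

    lo, hi = np.log(bounds[0]), np.log(bounds[1])

    def negloglik(x: np.ndarray) -> float:
        model = TransitionModel(mask, dict(zip(keys, np.exp(x))), prior)
        try:
            return -prune_loglik(tree, obs, model)
        except ImpossibleDataError:
            return 1e300

    rng = np.random.default_rng(seed)
    starts = [np.full(len(keys), np.log(1.0 / tree.height))]
    for _ in range(n_random_starts):
        starts.append(rng.uniform(lo, hi, size=len(keys)))

    results = []
    for x0 in starts:
        res = minimize(
            negloglik,
            np.clip(x0, lo, hi),
            method="L-BFGS-B",
            bounds=[(lo, hi)] * len(keys),
            options={"ftol": tol, "gtol": 1e-10, "maxiter": 500},
        )
        results.append(res)
    ok = [r for r in results if np.isfinite(r.fun)]
    if not ok:
        raise ConvergenceError("no optimizer start produced a finite likelihood")
    best = min(ok, key=lambda r: r.fun)
    if not any(r.success for r in ok):
        raise ConvergenceError(
            f"no start converged; best objective {best.fun:.6g} at rates "
            f"{np.exp(best.x)}"
        )
    model = TransitionModel(mask, dict(zip(keys, np.exp(best.x))), prior)
    report = {
        "n_starts": len(starts),
        "n_converged": sum(r.success for r in results),
        "iterations": int(best.nit),
        "grad_norm": float(np.max(np.abs(best.jac))),
        "start_objectives": [float(r.fun) for r in results],
    }
    return FitResult(model=model, loglik=-float(best.fun), report=report)
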