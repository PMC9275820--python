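"""Two-state reversible substitution model with FreeRate heterogeneity.

The character alphabet is {0 = not expressed, 1 = expressed}.  A two-state
general time-reversible model is fully determined, after normalizing the
rate matrix to one expected substitution per unit branch length, by the
equilibrium frequencies pi = (pi0, pi1).  The rate matrix is

    Q = [[-pi1, pi1], [pi0, -pi0]] / (2 pi0 pi1)

which gives the closed-form transition probabilities

    P_ij(t) = pi_j + (delta_ij - pi_j) * exp(-mu r t),   mu = 1/(2 pi0 pi1)

for a site evolving at relative rate r.  Among-site rate heterogeneity is
modeled as a FreeRate mixture: k categories with free rates r_c and
weights w_c, constrained to sum(w_c) = 1 and mean rate sum(w_c r_c) = 1.

Model fitting (maximum likelihood on a fixed tree) and information-
criterion model selection over a candidate set live here; the likelihood
engine itself is in :mod:`paleotrx.treelik`.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

#: lower floor on frequencies and mixture weights, to keep logs finite
PARAM_FLOOR = 1e-9


@dataclass
class BinaryModel:
    """Equilibrium frequencies plus FreeRate categories.

    Parameters
    ----------
    pi:
        Pair (pi0, pi1) of equilibrium frequencies, both positive, summing
        to 1.
    rate_categories:
        List of (rate, weight) pairs; weights sum to 1 and the weighted
        mean rate is 1 so branch lengths stay in expected substitutions
        per site.
    """

    pi: tuple[float, float] = (0.5, 0.5)
    rate_categories: list[tuple[float, float]] = field(
        default_factory=lambda: [(1.0, 1.0)]
    )
    free_pi: bool = True

    def __post_init__(self) -> None:
        pi = np.asarray(self.pi, dtype=float)
        if pi.shape != (2,) or np.any(pi <= 0) or abs(pi.sum() - 1) > 1e-8:
            raise ValueError(f"invalid equilibrium frequencies {self.pi}")
        self.pi = (float(pi[0]), float(pi[1]))
        cats = [(float(r), float(w)) for r, w in self.rate_categories]
        if not cats:
            raise ValueError("at least one rate category required")
        rates = np.array([r for r, _ in cats])
        weights = np.array([w for _, w in cats])
        if np.any(rates <= 0) or np.any(weights <= 0):
            raise ValueError("rates and weights must be positive")
        if abs(weights.sum() - 1) > 1e-8:
            raise ValueError("category weights must sum to 1")
        if abs(float(weights @ rates) - 1) > 1e-6:
            raise ValueError("mean rate must equal 1 (sum w_c r_c = 1)")
        # identifiability: sort categories by increasing rate
        order = np.argsort(rates)
        self.rate_categories = [cats[i] for i in order]

    # -- accessors --------------------------------------------------------

    @property
    def n_categories(self) -> int:
        return len(self.rate_categories)

    @property
    def rates(self) -> np.ndarray:
        return np.array([r for r, _ in self.rate_categories])

    @property
    def weights(self) -> np.ndarray:
        return np.array([w for _, w in self.rate_categories])

    @property
    def mu(self) -> float:
        """Normalization constant 1/(2 pi0 pi1)."""
        return 1.0 / (2.0 * self.pi[0] * self.pi[1])

    @property
    def n_free_params(self) -> int:
        """Free substitution-model parameters: 1 for ML frequencies, plus
        2(k-1) for a k-category FreeRate mixture."""
        return (1 if self.free_pi else 0) + 2 * (self.n_categories - 1)

    # -- serialization -----------------------------------------------------

    def to_json(self) -> str:
        return json.dumps(
            {
                "pi": list(self.pi),
                "rate_categories": [list(c) for c in self.rate_categories],
                "free_pi": self.free_pi,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "BinaryModel":
        d = json.loads(text)
        return cls(
            pi=tuple(d["pi"]),
            rate_categories=[tuple(c) for c in d["rate_categories"]],
            free_pi=d.get("free_pi", True),
        )


def transition_matrix(model: BinaryModel, t: float, r: float = 1.0) -> np.ndarray:
    """2x2 transition probability matrix over a branch of length ``t``.

    ``t`` is in expected substitutions per site at rate 1; ``r`` is the
    rate multiplier of the site category.  Rows index the parent state,
    columns the child state.
    """
    if t < 0:
        raise ValueError(f"negative branch length {t}")
    if r <= 0:
        raise ValueError(f"non-positive rate {r}")
    pi = np.asarray(model.pi)
    decay = math.exp(-model.mu * r * t)
    return pi[None, :] + (np.eye(2) - pi[None, :]) * decay


def aicc(loglik: float, k_params: int, n_sites: int) -> float:
    """Small-sample corrected Akaike information criterion.

    AICc = -2 lnL + 2k + 2k(k+1)/(n-k-1); requires n > k + 1.
    """
    if n_sites <= k_params + 1:
        raise ValueError(
            f"AICc undefined: n_sites={n_sites} <= k_params+1={k_params + 1}"
        )
    return -2.0 * loglik + 2.0 * k_params + 2.0 * k_params * (k_params + 1) / (
        n_sites - k_params - 1
    )


# ---------------------------------------------------------------------------
# model specs and fitting

_SPEC_RE = re.compile(r"^(EQ|GTR2(?:\+FO)?)((?:\+R\d+)?)$")

#: default candidate set for model selection
DEFAULT_CANDIDATES = [
    "EQ",
    "EQ+R2",
    "EQ+R3",
    "EQ+R4",
    "GTR2+FO",
    "GTR2+FO+R2",
    "GTR2+FO+R3",
    "GTR2+FO+R4",
]


def parse_spec(spec: str) -> tuple[bool, int]:
    """Parse a model spec string into (free_frequencies, n_categories).

    ``EQ`` is the equal-frequency two-state model; ``GTR2+FO`` estimates
    frequencies by ML; a ``+Rk`` suffix adds a k-category FreeRate mixture.
    """
    m = _SPEC_RE.match(spec.strip())
    if not m:
        raise ValueError(f"unrecognized model spec {spec!r}")
    free_pi = "FO" in m.group(1)
    k = int(m.group(2)[2:]) if m.group(2) else 1
    if k < 1:
        raise ValueError(f"invalid category count in {spec!r}")
    return free_pi, k


def model_from_spec(spec: str) -> BinaryModel:
    """Initial model for a spec string (uniform frequencies, spread rates)."""
    free_pi, k = parse_spec(spec)
    if k == 1:
        cats = [(1.0, 1.0)]
    else:
        # geometric spread around 1, renormalized to mean rate 1
        raw = np.geomspace(0.3, 3.0, k)
        w = np.full(k, 1.0 / k)
        raw = raw / (w @ raw)
        cats = list(zip(raw.tolist(), w.tolist()))
    return BinaryModel(pi=(0.5, 0.5), rate_categories=cats, free_pi=free_pi)


def _pack(model: BinaryModel) -> np.ndarray:
    """Unconstrained parameter vector: logit(pi1), then log-rates and
    weight logits of categories 2..k relative to category 1."""
    params = []
    if model.free_pi:
        params.append(math.log(model.pi[1] / model.pi[0]))
    k = model.n_categories
    if k > 1:
        r, w = model.rates, model.weights
        params.extend(np.log(r[1:] / r[0]))
        params.extend(np.log(w[1:] / w[0]))
    return np.array(params)


def _unpack(x: np.ndarray, free_pi: bool, k: int) -> BinaryModel:
    i = 0
    if free_pi:
        p1 = 1.0 / (1.0 + math.exp(-x[0]))
        p1 = min(max(p1, PARAM_FLOOR), 1 - PARAM_FLOOR)
        pi = (1 - p1, p1)
        i = 1
    else:
        pi = (0.5, 0.5)
    if k == 1:
        cats = [(1.0, 1.0)]
    else:
        log_r = np.concatenate([[0.0], x[i : i + k - 1]])
        log_w = np.concatenate([[0.0], x[i + k - 1 : i + 2 * (k - 1)]])
        r = np.exp(np.clip(log_r, -30, 30))
        w = np.exp(np.clip(log_w, -30, 30))
        w = np.maximum(w / w.sum(), PARAM_FLOOR)
        w /= w.sum()
        r = r / (w @ r)  # rescale to mean rate 1
        cats = list(zip(r.tolist(), w.tolist()))
    return BinaryModel(pi=pi, rate_categories=cats, free_pi=free_pi)


def fit_model_params(bm, tree, model: BinaryModel) -> tuple[BinaryModel, float]:
    """ML-fit frequencies and FreeRate categories on a fixed tree.

    Branch lengths are held fixed; returns the fitted model and its total
    log-likelihood.  Parameters are optimized unconstrained (logit
    frequencies, log rate ratios, weight logits) with the mean-rate
    constraint enforced by rescaling.
    """
    from paleotrx.treelik import LikelihoodEngine

    eng = LikelihoodEngine(tree, bm)
    free_pi, k = model.free_pi, model.n_categories
    x0 = _pack(model)
    if x0.size == 0:
        return model, eng.total_loglik(model)

    def neg(x):
        return -eng.total_loglik(_unpack(x, free_pi, k))

    res = minimize(neg, x0, method="L-BFGS-B")
    best = _unpack(res.x, free_pi, k)
    return best, -float(res.fun)


def fit_joint(
    bm,
    tree,
    model: BinaryModel,
    outer_tol: float = 0.5,
    max_rounds: int = 8,
) -> tuple[object, BinaryModel, float, bool]:
    """Alternate branch-length and model-parameter ML optimization.

    Inner branch sweeps use a tolerance an order of magnitude below the
    outer one (full precision is only needed at the joint optimum).
    Returns (tree, model, log-likelihood, converged).
    """
    from paleotrx.treelik import optimize_branch_lengths

    prev = -np.inf
    converged = False
    lnl = prev
    for _ in range(max_rounds):
        tree, lnl = optimize_branch_lengths(
            tree, bm, model, tol=max(outer_tol / 10.0, 1e-6)
        )
        model, lnl = fit_model_params(bm, tree, model)
        if lnl - prev < outer_tol:
            converged = True
            break
        prev = lnl
    return tree, model, float(lnl), converged


@dataclass
class ModelFitRow:
    spec: str
    model: BinaryModel
    tree: object
    loglik: float
    k_params: int
    aicc: float
    converged: bool = True


def model_select(
    bm,
    tree,
    candidates: list[str] | None = None,
    max_rounds: int = 8,
    tol: float = 0.05,
) -> list[ModelFitRow]:
    """Fit each candidate model by ML and rank by AICc.

    For every candidate, branch lengths are re-optimized jointly with the
    model parameters (alternating sweeps until the log-likelihood gain per
    round drops below ``tol``).  The parameter count entering AICc includes
    the branch lengths.  Returns rows sorted ascending by AICc; the first
    row is the selected model.
    """
    if candidates is None:
        candidates = list(DEFAULT_CANDIDATES)
    if not candidates:
        raise ValueError("empty candidate list")

    n_tips = tree.n_tips
    n_branch = 2 * n_tips - 3
    rows: list[ModelFitRow] = []
    for spec in candidates:
        model = model_from_spec(spec)
        cand_tree, model, lnl, converged = fit_joint(
            bm, tree.copy(), model, outer_tol=tol, max_rounds=max_rounds
        )
        k_params = model.n_free_params + n_branch
        rows.append(
            ModelFitRow(
                spec=spec,
                model=model,
                tree=cand_tree,
                loglik=float(lnl),
                k_params=k_params,
                aicc=aicc(float(lnl), k_params, bm.n_genes),
                converged=converged,
            )
        )
    rows.sort(key=lambda r: r.aicc)
    return rows
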