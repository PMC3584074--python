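"""Probabilistic link models for bipartite networks.

Three models assign every consumer-resource pair an independent Bernoulli
probability of interacting:

* **BPNM** (bipartite probabilistic niche model): resources sit at
  positions ``n_j`` on a latent one-dimensional niche axis; each consumer
  has a preferred center ``c_i`` and a niche width ``r_i``, and the
  interaction probability decays with the distance ``|n_j - c_i|`` through
  a generalized-Gaussian kernel

      p_ij = p_max * exp(-(|n_j - c_i| / (r_i / 2)) ** g)

  with a single global cutoff-shape exponent ``g`` (g = 2 is Gaussian;
  larger g is flatter in the middle and cuts off more sharply) and a
  global peak probability ``p_max``.
* **cascade**: each consumer carries an order parameter ``phi_i`` and each
  resource ``psi_j``; a link is possible only when ``psi_j < phi_i``, and
  every possible pair gets the same probability chosen so that the
  expected link count matches the observed one.
* **random**: every pair links with one constant probability.

All probabilities are clamped to ``[EPS, 1 - EPS]`` so the Bernoulli
log-likelihood is finite on every dataset.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

__all__ = [
    "EPS", "R_CAP", "G_MIN", "G_CAP",
    "BPNMParams", "CascadeParams", "RandomParams", "ProbabilityMatrix",
    "bpnm_probability", "bpnm_probability_matrix",
    "cascade_probability_matrix", "random_probability_matrix",
    "probability_matrix", "log_likelihood", "parameter_count", "aicc",
    "save_params", "load_params",
]

EPS = 1e-10       # probability clamp bound
R_CAP = 2.0       # a width of 2 spans the whole unit axis
G_MIN, G_CAP = 1.0, 20.0


def _clamp(p: np.ndarray | float):
    return np.clip(p, EPS, 1.0 - EPS)


@dataclass(frozen=True)
class BPNMParams:
    """Niche-model parameter set θ = (n, c, r, g, p_max)."""

    n: np.ndarray        # resource positions on [0, 1], length S_R
    c: np.ndarray        # consumer niche centers on [0, 1], length S_C
    r: np.ndarray        # consumer niche widths in (0, R_CAP], length S_C
    g: float = 2.0       # global cutoff-shape exponent in [1, 20]
    p_max: float = 0.9   # peak interaction probability in (0, 1]

    def __post_init__(self):
        n = np.asarray(self.n, dtype=float)
        c = np.asarray(self.c, dtype=float)
        r = np.asarray(self.r, dtype=float)
        if len(c) != len(r):
            raise ValueError("c and r must have one entry per consumer")
        if ((n < 0) | (n > 1)).any() or ((c < 0) | (c > 1)).any():
            raise ValueError("niche positions must lie on [0, 1]")
        if (r <= 0).any() or (r > R_CAP).any():
            raise ValueError(f"niche widths must lie in (0, {R_CAP}]")
        if not (G_MIN <= self.g <= G_CAP):
            raise ValueError(f"g must lie in [{G_MIN}, {G_CAP}]")
        if not (EPS < self.p_max <= 1.0):
            raise ValueError("p_max must lie in (0, 1]")
        object.__setattr__(self, "n", n)
        object.__setattr__(self, "c", c)
        object.__setattr__(self, "r", r)

    @property
    def s_r(self) -> int:
        return len(self.n)

    @property
    def s_c(self) -> int:
        return len(self.c)


@dataclass(frozen=True)
class CascadeParams:
    """Cascade order parameters: phi per consumer, psi per resource."""

    phi: np.ndarray
    psi: np.ndarray

    def __post_init__(self):
        phi = np.asarray(self.phi, dtype=float)
        psi = np.asarray(self.psi, dtype=float)
        if ((phi < 0) | (phi > 1)).any() or ((psi < 0) | (psi > 1)).any():
            raise ValueError("cascade order parameters must lie on [0, 1]")
        object.__setattr__(self, "phi", phi)
        object.__setattr__(self, "psi", psi)

    @property
    def s_c(self) -> int:
        return len(self.phi)

    @property
    def s_r(self) -> int:
        return len(self.psi)


@dataclass(frozen=True)
class RandomParams:
    """Constant link probability."""

    p: float

    def __post_init__(self):
        if not (0.0 < self.p < 1.0):
            raise ValueError("p must lie in (0, 1)")


@dataclass(frozen=True)
class ProbabilityMatrix:
    """Per-pair interaction probabilities, clamped to [EPS, 1 - EPS]."""

    p: np.ndarray
    model_kind: str = "bpnm"
    eps: float = EPS

    def __post_init__(self):
        p = _clamp(np.asarray(self.p, dtype=float))
        object.__setattr__(self, "p", p)

    @property
    def s_r(self) -> int:
        return self.p.shape[0]

    @property
    def s_c(self) -> int:
        return self.p.shape[1]

    @property
    def expected_links(self) -> float:
        return float(self.p.sum())


def bpnm_probability(n_j, c_i, r_i, g: float = 2.0, p_max: float = 0.9):
    """Interaction probability for one consumer-resource pair (clamped).

    Symmetric in the sign of ``n_j - c_i`` and strictly decreasing in the
    distance; equals ``p_max`` (pre-clamp) when the resource sits exactly
    on the consumer's niche optimum.
    """
    r_i = np.asarray(r_i, dtype=float)
    if (r_i <= 0).any() if r_i.ndim else r_i <= 0:
        raise ValueError("niche width must be positive")
    z = np.abs(np.asarray(n_j, dtype=float) - c_i) / (r_i / 2.0)
    return _clamp(p_max * np.exp(-(z ** g)))


def bpnm_probability_matrix(params: BPNMParams) -> ProbabilityMatrix:
    """Full (S_R, S_C) probability matrix from the niche kernel."""
    z = np.abs(params.n[:, None] - params.c[None, :]) / (params.r[None, :] / 2.0)
    return ProbabilityMatrix(params.p_max * np.exp(-(z ** params.g)), "bpnm")


def cascade_probability_matrix(params: CascadeParams, l_observed: int) -> ProbabilityMatrix:
    """Cascade probability matrix calibrated to the observed link count.

    Pairs with ``psi_j < phi_i`` are possible and share probability
    ``L / L_p`` (``L_p`` = number of possible pairs), so the pre-clamp
    expected number of links equals the observed ``L``; impossible pairs
    get the clamp floor.
    """
    allowed = params.psi[:, None] < params.phi[None, :]
    l_p = int(allowed.sum())
    if l_p == 0:
        raise ValueError("degenerate cascade parameters: no pair is possible")
    p = np.where(allowed, min(l_observed / l_p, 1.0 - EPS), EPS)
    return ProbabilityMatrix(p, "cascade")


def random_probability_matrix(params: RandomParams, s_c: int, s_r: int) -> ProbabilityMatrix:
    """Constant matrix of the single link probability."""
    return ProbabilityMatrix(np.full((s_r, s_c), params.p), "random")


def probability_matrix(params, net=None) -> ProbabilityMatrix:
    """Dispatch on parameter type; `net` supplies L / shape where needed."""
    if isinstance(params, BPNMParams):
        return bpnm_probability_matrix(params)
    if isinstance(params, CascadeParams):
        if net is None:
            raise ValueError("cascade model needs the observed network for L")
        return cascade_probability_matrix(params, net.n_links)
    if isinstance(params, RandomParams):
        if net is None:
            raise ValueError("random model needs the network shape")
        return random_probability_matrix(params, net.s_c, net.s_r)
    raise TypeError(f"unknown parameter type {type(params).__name__}")


def log_likelihood(net, matrix: ProbabilityMatrix) -> float:
    """Bernoulli log-likelihood of the observed adjacency under the model.

    Sum over all S_C*S_R cells of ``A*ln(p) + (1-A)*ln(1-p)``; always
    finite because probabilities are clamped, and never positive.
    """
    a = net.adjacency
    p = matrix.p
    if a.shape != p.shape:
        raise ValueError(f"shape mismatch: network {a.shape} vs matrix {p.shape}")
    return float(np.where(a == 1, np.log(p), np.log1p(-p)).sum())


def parameter_count(model_kind: str, s_c: int, s_r: int) -> int:
    """Free-parameter count k used in AICc.

    BPNM: one n per resource, c and r per consumer, plus global g and
    p_max.  Cascade: one order parameter per species.  Random: one.
    """
    if model_kind == "bpnm":
        return s_r + 2 * s_c + 2
    if model_kind == "cascade":
        return s_c + s_r
    if model_kind == "random":
        return 1
    raise ValueError(f"unknown model kind {model_kind!r}")


def aicc(log_l: float, k: int, n_obs: int) -> float:
    """Small-sample-corrected Akaike information criterion.

    ``n_obs`` is the number of binary observations, S_C * S_R.  Undefined
    (raises) when ``n_obs <= k + 1``; callers exclude such models from
    comparison.
    """
    if n_obs <= k + 1:
        raise ValueError(f"AICc undefined: n_obs={n_obs} <= k+1={k + 1}")
    return -2.0 * log_l + 2.0 * k + 2.0 * k * (k + 1) / (n_obs - k - 1)


# ---------------------------------------------------------------------------
# parameter-file round trip

def save_params(params, path) -> None:
    """Serialize a parameter set to JSON, exact to full double precision."""
    if isinstance(params, BPNMParams):
        obj = {"model_kind": "bpnm", "n": params.n.tolist(), "c": params.c.tolist(),
               "r": params.r.tolist(), "g": params.g, "p_max": params.p_max}
    elif isinstance(params, CascadeParams):
        obj = {"model_kind": "cascade", "phi": params.phi.tolist(), "psi": params.psi.tolist()}
    elif isinstance(params, RandomParams):
        obj = {"model_kind": "random", "p": params.p}
    else:
        raise TypeError(f"unknown parameter type {type(params).__name__}")
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1)


def load_params(path):
    with open(path) as fh:
        obj = json.load(fh)
    kind = obj.pop("model_kind")
    if kind == "bpnm":
        return BPNMParams(np.array(obj["n"]), np.array(obj["c"]), np.array(obj["r"]),
                          obj["g"], obj["p_max"])
    if kind == "cascade":
        return CascadeParams(np.array(obj["phi"]), np.array(obj["psi"]))
    if kind == "random":
        return RandomParams(obj["p"])
    raise ValueError(f"unknown model kind {kind!r}")
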