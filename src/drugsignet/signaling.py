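"""Recurrent prior-knowledge signaling network.

The signaling state of every protein node is iterated to steady state,

    h_{s+1} = mml(W h_s + b + u),

where ``W`` carries one trainable weight per prior-knowledge edge, ``b``
is a trainable per-node bias, ``u`` is the drug-derived input signal on
target nodes, and ``mml`` is a Michaelis-Menten-like activation: linear
with a small leak for negative inputs, identity up to a knot, and
saturating towards 1 above it.  Transcription-factor activity is read out
by scaling the steady state of TF nodes with trainable projection
weights.  A spectral-radius barrier keeps the update map contractive so
that 120 iterations suffice for convergence; further regularizers keep
edge weights on their prior signs, keep states in a dynamic range, and
keep biases and projections moderate.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor
from .exceptions import DivergenceError
from .pkn import SignalingNetwork

DEFAULT_LEAK = 0.01
DEFAULT_KNOT = 0.5
MAX_STEPS = 120
CONVERGENCE_TOL = 1e-8  # early-exit tolerance on max-abs state change
SIGN_PENALTY = 0.1
WEIGHT_REG_COEF = 1e-6
BIAS_REG_COEF = 1e-6
PROJECTION_CENTER = 1.2
SPECTRAL_BARRIER_SCALE = 1e10
SPECTRAL_LOSS_COEF = 1e-3
STATE_LOSS_COEF = 1e-5


def default_target_rho(max_steps: int = MAX_STEPS, residual: float = 1e-6) -> float:
    """Spectral-radius target e^{ln(residual)/max_steps} (~0.8913)."""
    return math.exp(math.log(residual) / max_steps)


# ------------------------------------------------------------------ MML

def mml_activation(x, leak: float = DEFAULT_LEAK, knot: float = DEFAULT_KNOT):
    """Michaelis-Menten-like activation (numpy).

    leak*x for x < 0; x on [0, knot]; 1 - knot^2/x above the knot.
    Continuous and monotone, saturating to 1.
    """
    x = np.asarray(x, dtype=float)
    return np.where(x < 0, leak * x, np.where(x <= knot, x, 1.0 - knot * knot / np.maximum(x, knot)))


def mml_prime(x, leak: float = DEFAULT_LEAK, knot: float = DEFAULT_KNOT):
    """First derivative of the MML activation."""
    x = np.asarray(x, dtype=float)
    return np.where(x < 0, leak, np.where(x <= knot, 1.0, knot * knot / np.maximum(x, knot) ** 2))


def _mml_t(x: Tensor, leak: float, knot: float) -> Tensor:
    out = mml_activation(x.data, leak, knot)
    deriv = mml_prime(x.data, leak, knot)

    def bwd(g, a=x, d=deriv):
        if a.requires_grad:
            a._accum(g * d)

    return Tensor._op(out, (x,), None)._with_bwd(bwd, (x,))


def _mml_prime_t(x: Tensor, leak: float, knot: float) -> Tensor:
    out = mml_prime(x.data, leak, knot)
    xd = x.data
    second = np.where(xd <= knot, 0.0, -2.0 * knot * knot / np.maximum(xd, knot) ** 3)

    def bwd(g, a=x, d=second):
        if a.requires_grad:
            a._accum(g * d)

    return Tensor._op(out, (x,), None)._with_bwd(bwd, (x,))


# ------------------------------------------------------------- parameters

@dataclass
class SignalingParams:
    """Trainable parameters of the recurrent signaling module.

    ``w[e]`` is the weight of edge ``e`` (row index = edge target, column
    index = edge source in the dense update matrix), ``signs[e]`` its
    prior sign, ``b`` the per-node bias and ``wp`` the TF projection
    weights in TF-node order.
    """

    net: SignalingNetwork
    edge_rows: np.ndarray
    edge_cols: np.ndarray
    signs: np.ndarray
    w: Tensor
    b: Tensor
    wp: Tensor
    tf_idx: np.ndarray
    target_idx: np.ndarray
    leak: float = DEFAULT_LEAK
    knot: float = DEFAULT_KNOT
    max_steps: int = MAX_STEPS
    tol: float = CONVERGENCE_TOL
    target_rho: float = field(default_factory=default_target_rho)

    @classmethod
    def from_network(cls, net: SignalingNetwork, seed: int = 0,
                     weight_scale: float = 0.8, **kwargs) -> "SignalingParams":
        """Initialize on a trimmed network; weights take prior signs and the
        dense matrix is rescaled so the linear-regime spectral radius is
        ``weight_scale * target_rho``."""
        rng = np.random.default_rng(seed)
        index = net.node_index()
        n = net.n_nodes
        rows = np.array([index[t] for _, t, _ in net.edges], dtype=int)
        cols = np.array([index[s] for s, _, _ in net.edges], dtype=int)
        signs = np.array([sg for _, _, sg in net.edges], dtype=float)
        w0 = signs * rng.uniform(0.5, 1.5, size=len(net.edges))
        dense = np.zeros((n, n))
        dense[rows, cols] = w0
        rho0 = _linear_spectral_radius(dense)
        trho = kwargs.get("target_rho", default_target_rho(kwargs.get("max_steps", MAX_STEPS)))
        if rho0 > weight_scale * trho:
            # only edges inside a strongly connected component contribute to
            # the spectral radius; scaling those blocks uniformly scales the
            # eigenvalues linearly while feed-forward strength is preserved
            import networkx as nx
            g = nx.DiGraph(zip([net.nodes[c] for c in cols], [net.nodes[r] for r in rows]))
            index = {nd: i for i, nd in enumerate(net.nodes)}
            scc_id = {}
            for k, comp in enumerate(nx.strongly_connected_components(g)):
                for nd in comp:
                    scc_id[index[nd]] = k
            cyclic = np.array([
                scc_id.get(r) == scc_id.get(c)
                and (r != c or dense[r, c] != 0)  # self-loops count
                for r, c in zip(rows, cols)])
            w0[cyclic] *= weight_scale * trho / rho0
        tf_idx = np.array([index[t] for t in net.tf_nodes], dtype=int)
        target_idx = np.array([index[t] for t in net.target_nodes], dtype=int)
        return cls(
            net=net, edge_rows=rows, edge_cols=cols, signs=signs,
            w=Tensor(w0, requires_grad=True),
            b=Tensor(1e-3 * np.ones(n), requires_grad=True),
            wp=Tensor(np.full(len(tf_idx), PROJECTION_CENTER), requires_grad=True),
            tf_idx=tf_idx, target_idx=target_idx, **kwargs,
        )

    def dense_w(self) -> Tensor:
        n = self.net.n_nodes
        return self.w.scatter_to(self.edge_rows, self.edge_cols, (n, n))

    def initial_state(self, n_samples: int) -> np.ndarray:
        h0 = np.full((n_samples, self.net.n_nodes), 1e-3)
        h0[:, self.tf_idx] = 0.5
        return h0

    def trainable(self) -> list[Tensor]:
        return [self.w, self.b, self.wp]


def _linear_spectral_radius(dense: np.ndarray) -> float:
    if dense.size == 0 or not dense.any():
        return 0.0
    return float(np.abs(np.linalg.eigvals(dense)).max())


# ------------------------------------------------------------ propagation

@dataclass
class StateTrajectory:
    """Final steady state plus convergence metadata for a batch."""

    final_state: np.ndarray       # (n_samples, n_nodes)
    converged: np.ndarray         # (n_samples,) bool
    delta: float                  # final max-abs state change
    n_steps: int
    states: np.ndarray | None = None  # (steps, n_samples, n_nodes) if tracked


def propagate_steady_state(
    u: Tensor | np.ndarray,
    params: SignalingParams,
    track_states: bool = False,
    min_steps: int = 1,
):
    """Iterate the recurrent update to steady state.

    ``u`` is the node-space input (n_samples x n_nodes).  Returns
    ``(h, z, traj)`` where ``h`` is the steady-state tensor, ``z`` the
    final preactivation tensor (cached for the spectral-radius Jacobian)
    and ``traj`` a :class:`StateTrajectory`.
    """
    if not isinstance(u, Tensor):
        u = Tensor(u)
    n_samples = u.shape[0]
    dense = params.dense_w()
    dense_t = dense.T
    bias_input = params.b + u  # (n, N) via broadcasting
    h = Tensor(params.initial_state(n_samples))
    z = None
    history = [] if track_states else None
    delta = np.inf
    step = 0
    per_sample_delta = np.full(n_samples, np.inf)
    for step in range(1, params.max_steps + 1):
        z = h @ dense_t + bias_input
        h_new = _mml_t(z, params.leak, params.knot)
        if not np.isfinite(h_new.data).all():
            raise DivergenceError(f"non-finite signaling state at iteration {step}")
        diff = np.abs(h_new.data - h.data)
        per_sample_delta = diff.max(axis=1) if diff.size else np.zeros(n_samples)
        delta = float(per_sample_delta.max()) if diff.size else 0.0
        h = h_new
        if history is not None:
            history.append(h.data.copy())
        if step >= min_steps and delta < params.tol:
            break
    traj = StateTrajectory(
        final_state=h.data.copy(),
        converged=per_sample_delta < params.tol,
        delta=delta,
        n_steps=step,
        states=np.array(history) if history is not None else None,
    )
    return h, z, traj


def project_to_tf(steady: Tensor | np.ndarray, wp: Tensor | np.ndarray, tf_idx: np.ndarray):
    """TF activity = projection weight x steady state of each TF node."""
    if isinstance(steady, Tensor):
        return steady.take_cols(tf_idx) * (wp if isinstance(wp, Tensor) else Tensor(wp))
    wp_data = wp.data if isinstance(wp, Tensor) else np.asarray(wp)
    return np.asarray(steady)[:, tf_idx] * wp_data


# ----------------------------------------------------------------- losses

def spectral_radius(params: SignalingParams, z: Tensor | np.ndarray,
                    n_iter: int = 50, seed: int = 0):
    """Spectral radius of the steady-state Jacobian, by power iteration.

    The Jacobian for sample s is diag(mml'(z_s)) W; iteration runs
    vectorized over the batch and the batch maximum is returned along
    with the exponential-barrier loss (active only above target_rho).
    Returns ``(rho: Tensor scalar, loss: Tensor scalar)``.
    """
    if not isinstance(z, Tensor):
        z = Tensor(z)
    dense_t = params.dense_w().T
    d = _mml_prime_t(z, params.leak, params.knot)  # (n, N)
    rng = np.random.default_rng(seed)
    n_samples, n_nodes = z.shape
    v = Tensor(rng.standard_normal((n_samples, n_nodes)))
    rho_rows = None
    for _ in range(n_iter):
        jv = d * (v @ dense_t)
        norms = (jv * jv).sum(axis=1, keepdims=True).sqrt() + 1e-300
        rho_rows = norms
        v = jv / norms
    rho = rho_rows.max(axis=0).max(axis=0)  # batch max, as scalar tensor
    if float(rho.data) > params.target_rho:
        loss = SPECTRAL_BARRIER_SCALE * ((10.0 * rho).exp() - 1.0)
    else:
        loss = Tensor(0.0)
    return rho, loss


def spectral_radius_exact(params: SignalingParams, z: np.ndarray) -> float:
    """Dense eigendecomposition oracle for the batch-max spectral radius."""
    dense = np.zeros((params.net.n_nodes,) * 2)
    dense[params.edge_rows, params.edge_cols] = params.w.data
    d = mml_prime(z, params.leak, params.knot)
    rho = 0.0
    for s in range(z.shape[0]):
        jac = d[s][:, None] * dense
        rho = max(rho, float(np.abs(np.linalg.eigvals(jac)).max()))
    return rho


def sign_constraint_loss(w: Tensor | np.ndarray, signs: np.ndarray):
    """0.1 * sum |w| over entries violating the prior sign (zero is fine)."""
    if not isinstance(w, Tensor):
        return SIGN_PENALTY * float(np.abs(np.asarray(w))[np.sign(w) * signs < 0].sum())
    violation = (w * Tensor(-signs)).relu()  # |w| where sign flipped, else 0
    return violation.sum() * SIGN_PENALTY


def regularize_weights(w: Tensor | np.ndarray, coef: float = WEIGHT_REG_COEF):
    """coef * sum(w^2 + 1/(w^2 + 0.5)): L2 plus an anti-zero-sticking term."""
    if not isinstance(w, Tensor):
        w = np.asarray(w, dtype=float)
        return coef * float((w ** 2 + 1.0 / (w ** 2 + 0.5)).sum())
    sq = w * w
    return (sq + 1.0 / (sq + 0.5)).sum() * coef


def state_loss(h: Tensor | np.ndarray, interval_max: float = 0.99):
    """Deviation of per-node state statistics from uniform[0, interval_max].

    Squared deviations of the empirical mean/variance/max/min across
    conditions from the uniform ideals, summed over nodes; a node whose
    maximum state is negative has its contribution multiplied by 10.
    Returns the raw sum (the trainer applies the 1e-5 coefficient).
    """
    if not isinstance(h, Tensor):
        h = Tensor(h)
    n_samples = h.shape[0]
    ideal_mean = interval_max / 2.0
    ideal_var = interval_max ** 2 / 12.0
    mean = h.mean(axis=0)
    dev = (mean - ideal_mean) ** 2
    if n_samples > 1:
        var = ((h - h.mean(axis=0, keepdims=True)) ** 2).mean(axis=0)
        dev = dev + (var - ideal_var) ** 2
    else:
        warnings.warn("single-condition batch: variance term of state loss skipped")
    mx = h.max(axis=0)
    mn = h.min(axis=0)
    dev = dev + (mx - interval_max) ** 2 + mn ** 2
    factor = np.where(h.data.max(axis=0) < 0, 10.0, 1.0)
    return dev.mask(factor).sum()


def bias_projection_losses(b: Tensor | np.ndarray, wp: Tensor | np.ndarray):
    """(biasLoss, projectionLoss) = 1e-6*sum(b^2), 1e-6*sum((wp-1.2)^2)."""
    if not isinstance(b, Tensor):
        b = Tensor(b)
    if not isinstance(wp, Tensor):
        wp = Tensor(wp)
    bias_loss = (b * b).sum() * BIAS_REG_COEF
    proj_loss = ((wp - PROJECTION_CENTER) ** 2).sum() * BIAS_REG_COEF
    return bias_loss, proj_loss
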