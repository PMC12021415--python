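"""Network parameters, masks, rate dynamics with STSP, and gradients.

Dynamics (discrete time, dt/tau leak, rectified-linear rates):

    u[t+1] = clip( u[t] + dt*((U - u[t])/tau_u + U*(1 - u[t])*h[t]) , 0, 1)
    x[t+1] = clip( x[t] + dt*((1 - x[t])/tau_x - u[t]*x[t]*h[t])   , 0, 1)
    s[t]   = u[t+1]*x[t+1]*h[t]   on excitatory units (h[t] on inhibitory)
    h[t+1] = relu( (1-a)*h[t] + a*(s[t] W_rec + inp[t] W_in + b) + noise )
    y[t+1] = h[t+1] W_out + b_out

Dale's principle and the module topology are enforced exactly by
parameterizing nonnegative magnitudes (absolute-valued raw weights) times a
fixed sign vector and a fixed connectivity mask, so no gradient step can
create a forbidden or wrong-signed connection.  The backward pass
differentiates through the full recursion, including the STSP state
updates (clipped states pass no gradient where the pre-clip value left
[0, 1]).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import NetworkConfig, epoch_steps


class DivergenceError(FloatingPointError):
    """Raised when unit activity becomes non-finite during simulation."""


@dataclass
class NetworkParams:
    """Raw (unconstrained) parameters plus the fixed masks."""

    config: NetworkConfig
    w_in: np.ndarray
    w_rec: np.ndarray
    b_rec: np.ndarray
    w_out: np.ndarray
    b_out: np.ndarray
    conn_mask: np.ndarray = field(repr=False)   # (N, N) allowed connections
    sign: np.ndarray = field(repr=False)        # (N,) +1 excitatory / -1 inhibitory
    in_mask: np.ndarray = field(repr=False)     # (n_in, N)
    out_mask: np.ndarray = field(repr=False)    # (N, n_out)
    stsp_mask: np.ndarray = field(repr=False)   # (N,) 1 where STSP applies (E units)
    tau_x: np.ndarray = field(repr=False)
    tau_u: np.ndarray = field(repr=False)
    big_u: np.ndarray = field(repr=False)

    def effective(self):
        """(W_in, W_rec, W_out) with masks and Dale signs applied.

        Magnitudes are |raw| so the sign constraint binds exactly while
        gradients never vanish at the constraint boundary.
        """
        W_in = np.abs(self.w_in) * self.in_mask
        W_rec = np.abs(self.w_rec) * self.conn_mask * self.sign[:, None]
        W_out = np.abs(self.w_out) * self.out_mask
        return W_in, W_rec, W_out

    def trainable(self):
        return {"w_in": self.w_in, "w_rec": self.w_rec, "b_rec": self.b_rec,
                "w_out": self.w_out, "b_out": self.b_out}


def _module_slices(config: NetworkConfig):
    U = config.units_per_module
    return [slice(m * U, (m + 1) * U) for m in range(config.n_modules)]


def build_masks(config: NetworkConfig, seed: int | None = None):
    """Connectivity mask, Dale signs, input/output masks, STSP constants.

    Within-module connectivity is dense (no self-connections); adjacent
    modules are linked in both directions through a seeded random half
    of the sender module's excitatory units, excitatory-to-excitatory
    only; inhibitory connections never leave their module.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    N, U, nE = config.n_units, config.units_per_module, config.n_exc_per_module
    mods = _module_slices(config)

    exc = np.zeros(N, dtype=bool)
    for sl in mods:
        exc[sl.start : sl.start + nE] = True
    sign = np.where(exc, 1.0, -1.0)

    conn = np.zeros((N, N), dtype=np.float32)
    for sl in mods:
        conn[sl, sl] = 1.0
    for m in range(config.n_modules - 1):
        a, b = mods[m], mods[m + 1]
        for src, dst in ((a, b), (b, a)):
            senders = src.start + rng.permutation(nE)[: int(round(config.p_inter * nE))]
            recv = np.arange(dst.start, dst.start + nE)
            conn[np.ix_(senders, recv)] = 1.0
    np.fill_diagonal(conn, 0.0)

    in_mask = np.zeros((config.n_inputs, N), dtype=np.float32)
    in_mask[:, mods[0].start : mods[0].start + nE] = 1.0
    out_mask = np.zeros((N, config.n_outputs), dtype=np.float32)
    out_mask[mods[-1].start : mods[-1].start + nE, :] = 1.0

    # alternate facilitating / depressing among each module's E units
    tau_x = np.full(N, config.stsp_dep[0])
    tau_u = np.full(N, config.stsp_dep[1])
    big_u = np.full(N, config.stsp_dep[2])
    for sl in mods:
        fac = np.arange(sl.start, sl.start + nE)[::2]
        tau_x[fac], tau_u[fac], big_u[fac] = config.stsp_fac
    stsp = exc.astype(np.float32)
    return conn, sign.astype(np.float32), in_mask, out_mask, stsp, \
        tau_x.astype(np.float32), tau_u.astype(np.float32), big_u.astype(np.float32)


def init_params(config: NetworkConfig, seed: int | None = None) -> NetworkParams:
    """Gamma-distributed nonnegative initial weights; the recurrent matrix
    is rescaled so the rest-state effective spectral radius is ~1."""
    seed = config.seed if seed is None else seed
    conn, sign, in_mask, out_mask, stsp, tau_x, tau_u, big_u = build_masks(config, seed)
    rng = np.random.default_rng(seed + 1)
    N = config.n_units
    w_in = rng.gamma(0.2, 1.0, size=(config.n_inputs, N)).astype(np.float32) * config.w_in_scale
    w_rec = rng.gamma(0.1, 1.0, size=(N, N)).astype(np.float32)
    w_out = rng.gamma(0.1, 1.0, size=(N, config.n_outputs)).astype(np.float32) * 0.1
    # rest-state STSP factor: u = U, x = 1
    rest = np.where(stsp > 0, big_u, 1.0)
    W_eff = np.abs(w_rec) * conn * sign[:, None] * rest[:, None]
    radius = np.max(np.abs(np.linalg.eigvals(W_eff.astype(np.float64))))
    w_rec *= np.float32(config.init_radius / max(radius, 1e-6))
    return NetworkParams(
        config=config,
        w_in=w_in,
        w_rec=w_rec,
        b_rec=np.zeros(N, dtype=np.float32),
        w_out=w_out,
        b_out=np.zeros(config.n_outputs, dtype=np.float32),
        conn_mask=conn, sign=sign, in_mask=in_mask, out_mask=out_mask,
        stsp_mask=stsp, tau_x=tau_x, tau_u=tau_u, big_u=big_u,
    )


def simulate(
    params: NetworkParams,
    inputs: np.ndarray,
    noise_on: bool = True,
    seed: int = 0,
    cache: bool = False,
):
    """Run the dynamics over an encoded batch.

    Returns (activity h (T, B, N), outputs y (T, B, n_out), states) where
    ``states`` holds the STSP traces (and, when ``cache``, everything the
    backward pass needs).  With ``noise_on`` False the run is
    deterministic for a given batch.
    """
    cfg = params.config
    T, B, _ = inputs.shape
    N = cfg.n_units
    W_in, W_rec, W_out = params.effective()
    dtype = params.w_rec.dtype
    alpha = dtype.type(cfg.alpha)
    dt = dtype.type(cfg.dt)
    rng = np.random.default_rng(seed)

    h = np.full((B, N), 0.1, dtype=dtype)
    u = np.tile(params.big_u, (B, 1)).astype(dtype)
    x = np.ones((B, N), dtype=dtype)

    H = np.empty((T + 1, B, N), dtype=dtype)
    Us = np.empty((T + 1, B, N), dtype=dtype)
    Xs = np.empty((T + 1, B, N), dtype=dtype)
    H[0], Us[0], Xs[0] = h, u, x
    Y = np.empty((T, B, cfg.n_outputs), dtype=dtype)
    Umask = np.empty((T, B, N), dtype=bool) if cache else None
    Xmask = np.empty((T, B, N), dtype=bool) if cache else None

    stsp = params.stsp_mask.astype(bool)
    inv_tu = dt / params.tau_u
    inv_tx = dt / params.tau_x
    bigU = params.big_u

    for t in range(T):
        u_pre = u + inv_tu * (bigU - u) + dt * bigU * (1.0 - u) * h
        x_pre = x + inv_tx * (1.0 - x) - dt * u * x * h
        if cache:
            Umask[t] = (u_pre >= 0.0) & (u_pre <= 1.0)
            Xmask[t] = (x_pre >= 0.0) & (x_pre <= 1.0)
        u = np.clip(u_pre, 0.0, 1.0)
        x = np.clip(x_pre, 0.0, 1.0)
        s = np.where(stsp, u * x * h, h)
        a = (1.0 - alpha) * h + alpha * (s @ W_rec + inputs[t] @ W_in + params.b_rec)
        if noise_on and cfg.noise_sd > 0:
            a = a + rng.normal(0.0, cfg.noise_sd, size=a.shape).astype(dtype)
        h = np.maximum(a, 0.0)
        if not np.all(np.isfinite(h)):
            raise DivergenceError(f"non-finite activity at step {t}")
        H[t + 1], Us[t + 1], Xs[t + 1] = h, u, x
        Y[t] = h @ W_out + params.b_out

    states = {"H": H, "U": Us, "X": Xs}
    if cache:
        states.update({"Umask": Umask, "Xmask": Xmask, "inputs": inputs})
    return H[1:], Y, states


def loss_mse(outputs: np.ndarray, targets: np.ndarray, loss_mask: np.ndarray) -> float:
    """Mean squared output error over the masked (test minus grace) steps."""
    if outputs.shape != targets.shape:
        raise ValueError("outputs/targets shape mismatch")
    m = np.asarray(loss_mask, bool)
    d = outputs[m] - targets[m]
    return float(np.mean(d * d))


def backward(
    params: NetworkParams,
    states: dict,
    outputs: np.ndarray,
    targets: np.ndarray,
    loss_mask: np.ndarray,
) -> dict:
    """Gradients of loss_mse (+ spike penalty) w.r.t. the raw parameters."""
    cfg = params.config
    H, Us, Xs = states["H"], states["U"], states["X"]
    Umask, Xmask, inputs = states["Umask"], states["Xmask"], states["inputs"]
    T, B, _ = outputs.shape
    N = cfg.n_units
    W_in, W_rec, W_out = params.effective()
    alpha = np.float32(cfg.alpha)
    dt = np.float32(cfg.dt)
    stsp = params.stsp_mask.astype(bool)
    bigU, inv_tu, inv_tx = params.big_u, dt / params.tau_u, dt / params.tau_x

    m = np.asarray(loss_mask, bool)
    n_loss = int(m.sum()) * B * cfg.n_outputs
    dY = np.zeros_like(outputs)
    dY[m] = 2.0 * (outputs[m] - targets[m]) / n_loss

    sp = np.float32(cfg.spike_penalty)
    n_act = T * B * N

    g = {k: np.zeros_like(v) for k, v in params.trainable().items()}
    gW_in = np.zeros_like(W_in)
    gW_rec = np.zeros_like(W_rec)
    gW_out = np.zeros_like(W_out)
    gh_next = np.zeros((B, N), dtype=np.float32)
    gu_next = np.zeros((B, N), dtype=np.float32)
    gx_next = np.zeros((B, N), dtype=np.float32)

    for t in range(T - 1, -1, -1):
        h_prev, h_new = H[t], H[t + 1]
        u1, x1 = Us[t + 1], Xs[t + 1]
        u0, x0 = Us[t], Xs[t]

        gW_out += h_new.T @ dY[t]
        g["b_out"] += dY[t].sum(axis=0)
        gh = dY[t] @ W_out.T + gh_next
        if sp > 0:
            gh = gh + (2.0 * sp / n_act) * h_new

        da = gh * (h_new > 0)
        delta = alpha * da
        s = np.where(stsp, u1 * x1 * h_prev, h_prev)
        gW_rec += s.T @ delta
        gW_in += inputs[t].T @ delta
        g["b_rec"] += delta.sum(axis=0)

        ds = delta @ W_rec.T
        gh_prev = (1.0 - alpha) * da + np.where(stsp, ds * u1 * x1, ds)
        gu1 = np.where(stsp, ds * x1 * h_prev, 0.0) + gu_next
        gx1 = np.where(stsp, ds * u1 * h_prev, 0.0) + gx_next
        guc = gu1 * Umask[t]
        gxc = gx1 * Xmask[t]

        gu_next = guc * (1.0 - inv_tu - dt * bigU * h_prev) + gxc * (-dt * x0 * h_prev)
        gx_next = gxc * (1.0 - inv_tx - dt * u0 * h_prev)
        gh_prev = gh_prev + guc * (dt * bigU * (1.0 - u0)) + gxc * (-dt * u0 * x0)
        gh_next = gh_prev

    # chain through the magnitude-times-sign parameterization
    g["w_in"] = gW_in * params.in_mask * np.sign(params.w_in)
    g["w_rec"] = gW_rec * params.sign[:, None] * params.conn_mask * np.sign(params.w_rec)
    g["w_out"] = gW_out * params.out_mask * np.sign(params.w_out)
    return g
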