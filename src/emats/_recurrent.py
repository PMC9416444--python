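"""LSTM forward/backward kernels (numba-jitted, single sequence).

Gate layout in the fused weight matrices is [input | forget | cell | output]
(blocks of H columns).  ``lstm_forward`` returns the hidden states plus the
per-step activations needed for backpropagation through time;
``lstm_backward`` consumes the gradient w.r.t. the hidden states and returns
gradients w.r.t. the inputs and parameters.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit
except ImportError:  # pragma: no cover
    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]
        return lambda f: f


@njit(cache=True)
def lstm_forward(X, W, U, b):
    """X: (T, D); W: (D, 4H); U: (H, 4H); b: (4H,).

    Returns (H_out, i, f, g, o, c, tc) where each activation array is (T, H)
    and tc = tanh(c).
    """
    T = X.shape[0]
    H = U.shape[0]
    Z = X @ W
    Hs = np.zeros((T, H))
    gi = np.zeros((T, H))
    gf = np.zeros((T, H))
    gg = np.zeros((T, H))
    go = np.zeros((T, H))
    cs = np.zeros((T, H))
    tc = np.zeros((T, H))
    h = np.zeros(H)
    c = np.zeros(H)
    for t in range(T):
        z = Z[t] + h @ U + b
        i_t = 1.0 / (1.0 + np.exp(-z[:H]))
        f_t = 1.0 / (1.0 + np.exp(-z[H:2 * H]))
        g_t = np.tanh(z[2 * H:3 * H])
        o_t = 1.0 / (1.0 + np.exp(-z[3 * H:]))
        c = f_t * c + i_t * g_t
        tct = np.tanh(c)
        h = o_t * tct
        gi[t] = i_t
        gf[t] = f_t
        gg[t] = g_t
        go[t] = o_t
        cs[t] = c
        tc[t] = tct
        Hs[t] = h
    return Hs, gi, gf, gg, go, cs, tc


@njit(cache=True)
def lstm_backward(X, W, U, Hs, gi, gf, gg, go, cs, tc, dH):
    """Backprop through time; returns (dX, dW, dU, db)."""
    T, D = X.shape
    H = U.shape[0]
    dZ = np.zeros((T, 4 * H))
    dh_next = np.zeros(H)
    dc_next = np.zeros(H)
    Ut = U.T.copy()
    for t in range(T - 1, -1, -1):
        dh = dH[t] + dh_next
        do = dh * tc[t]
        dc = dh * go[t] * (1.0 - tc[t] ** 2) + dc_next
        c_prev = cs[t - 1] if t > 0 else np.zeros(H)
        di = dc * gg[t]
        dg = dc * gi[t]
        df = dc * c_prev
        dc_next = dc * gf[t]
        dzi = di * gi[t] * (1.0 - gi[t])
        dzf = df * gf[t] * (1.0 - gf[t])
        dzg = dg * (1.0 - gg[t] ** 2)
        dzo = do * go[t] * (1.0 - go[t])
        dZ[t, :H] = dzi
        dZ[t, H:2 * H] = dzf
        dZ[t, 2 * H:3 * H] = dzg
        dZ[t, 3 * H:] = dzo
        dh_next = dZ[t] @ Ut
    dW = X.T @ dZ
    Hprev = np.zeros((T, H))
    Hprev[1:] = Hs[:-1]
    dU = Hprev.T @ dZ
    db = dZ.sum(axis=0)
    dX = dZ @ W.T
    return dX, dW, dU, db
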