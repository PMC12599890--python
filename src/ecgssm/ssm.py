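"""Core state-space recurrence: ZOH discretization and the sequential scan.

The continuous-time model is

    x'(t) = A x(t) + B u(t),      y(t) = C x(t) + D u(t),   D = 0,

with diagonal A (negative real parts for stability).  Zero-order-hold
discretization at step ``delta`` gives

    A_d = exp(A * delta),   B_d = integral_0^delta exp(A tau) B dtau
        = ((A_d - 1) / A) B       (elementwise over the diagonal),

with the limit ``delta * B`` as A -> 0, and C_d = C.  The scan here is a
plain sequential recurrence — a reference implementation, deliberately not a
fused kernel — used both as the spec-level primitive and as the oracle the
batched network scan is tested against.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class SSMParams:
    """Continuous-time parameters with diagonal state matrix A."""

    A: np.ndarray        # [N] diagonal entries, real(A) < 0 for stability
    B: np.ndarray        # [N, d]
    C: np.ndarray        # [d, N]
    delta: float

    def __post_init__(self) -> None:
        self.A = np.atleast_1d(np.asarray(self.A, dtype=float))
        self.B = np.atleast_2d(np.asarray(self.B, dtype=float))
        self.C = np.atleast_2d(np.asarray(self.C, dtype=float))
        if self.delta <= 0:
            raise ValueError("delta must be positive")


@dataclass
class DiscreteSSM:
    A_d: np.ndarray      # [N]
    B_d: np.ndarray      # [N, d]
    C_d: np.ndarray      # [d, N]


def discretize_zoh(A: np.ndarray, B: np.ndarray, delta: float,
                   C: np.ndarray | None = None) -> DiscreteSSM:
    """Discretize a diagonal-A SSM with the zero-order hold at step ``delta``."""
    if delta <= 0:
        raise ValueError("delta must be positive")
    A = np.atleast_1d(np.asarray(A, dtype=float))
    B = np.atleast_2d(np.asarray(B, dtype=float))
    A_d = np.exp(A * delta)
    small = np.abs(A) < 1e-8
    A_safe = np.where(small, 1.0, A)
    coeff = np.where(small, delta, (A_d - 1.0) / A_safe)
    B_d = coeff[:, None] * B
    C_d = None if C is None else np.atleast_2d(np.asarray(C, dtype=float))
    return DiscreteSSM(A_d=A_d, B_d=B_d, C_d=C_d)


def ssm_scan(params: DiscreteSSM, u: np.ndarray,
             h0: np.ndarray | None = None,
             convention: str = "absorb") -> np.ndarray:
    """Run the discrete recurrence over a token sequence ``u`` of shape [L, d].

    ``convention`` picks which state each output reads:

    * ``"absorb"`` (default): h[n] = A_d h[n-1] + B_d u[n], y[n] = C_d h[n] —
      every output reflects its own input, matching the selective-SSM lineage;
    * ``"literal"``: h[n+1] = A_d h[n] + B_d u[n], y[n] = C_d h[n] — the
      printed recurrence, in which y[0] reads the initial state.
    """
    if convention not in ("absorb", "literal"):
        raise ValueError(f"unknown convention {convention!r}")
    u = np.atleast_2d(np.asarray(u, dtype=float))
    L, d = u.shape
    N = params.A_d.shape[0]
    if params.B_d.shape != (N, d):
        raise ValueError(f"B_d shape {params.B_d.shape} inconsistent with "
                         f"state dim {N} and input dim {d}")
    if params.C_d is None or params.C_d.shape != (d, N):
        raise ValueError("C_d must have shape (d, N)")
    h = np.zeros(N) if h0 is None else np.asarray(h0, dtype=float).copy()
    if h.shape != (N,):
        raise ValueError("h0 shape mismatch")
    y = np.empty((L, d))
    for n in range(L):
        if convention == "literal":
            y[n] = params.C_d @ h
            h = params.A_d * h + params.B_d @ u[n]
        else:
            h = params.A_d * h + params.B_d @ u[n]
            y[n] = params.C_d @ h
    return y
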