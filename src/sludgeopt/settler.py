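"""One-dimensional ten-layer Takacs secondary settler.

Solids settle with the double-exponential velocity law and move between
layers by a threshold-limited gravity flux plus the bulk up-/down-flow;
soluble components are ideally advected (no reaction in the settler).
Defaults follow the widely used benchmark-simulation settler
parameterization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .asm2d import IDX, N_COMPONENTS, SOLUBLE_INDEX

__all__ = ["SettlerConfig", "SettlerState", "settling_velocity", "settler_derivatives", "settler_tss_inventory"]

# particulate groups entering the published solids inventory (Eq-style
# ASM1 naming mapped onto ASM2d): inerts, slowly biodegradable substrate,
# stored products (PHA + poly-P), heterotrophic and autotrophic+PAO biomass
Z_GROUPS = {
    "ZI": ("XI",),
    "ZS": ("XS",),
    "ZP": ("XPHA", "XPP"),
    "ZBH": ("XH",),
    "ZBA": ("XAUT", "XPAO"),
}


@dataclass
class SettlerConfig:
    """Geometry and double-exponential settling parameters.

    Ten layers (top = index 0 = effluent, bottom = index 9 = underflow),
    feed entering mid-depth.  The area and depth are site inputs; defaults
    are sized for the studied plant's flows (documented assumption).
    """

    n_layers: int = 10
    area: float = 1500.0          # m^2
    height: float = 4.0           # m total depth
    feed_layer: int = 4           # 0-based, i.e. the 5th of 10 layers
    v0: float = 474.0             # max theoretical settling velocity, m d^-1
    v0_max: float = 250.0         # max practical settling velocity, m d^-1
    r_h: float = 5.76e-4          # hindered settling parameter, m^3 g^-1
    r_p: float = 2.86e-3          # flocculant settling parameter, m^3 g^-1
    f_ns: float = 2.28e-3         # non-settleable fraction of feed solids
    X_threshold: float = 3000.0   # g m^-3, threshold for flux limitation

    def __post_init__(self):
        if self.n_layers != 10:
            raise ValueError("the layered settler is defined with 10 layers")
        if not 0 <= self.feed_layer < self.n_layers:
            raise ValueError("feed layer out of range")
        if self.area <= 0 or self.height <= 0:
            raise ValueError("area and height must be positive")

    @property
    def layer_height(self) -> float:
        return self.height / self.n_layers

    @property
    def layer_volume(self) -> float:
        return self.area * self.layer_height


@dataclass
class SettlerState:
    """Per-layer TSS and soluble concentrations (top to bottom)."""

    X: np.ndarray                         # (10,) TSS g m^-3
    solubles: np.ndarray                  # (10, n_solubles) g m^-3
    soluble_index: np.ndarray = field(default_factory=lambda: SOLUBLE_INDEX.copy())

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        self.solubles = np.asarray(self.solubles, dtype=float)
        if self.X.shape != (10,) or self.solubles.shape[0] != 10:
            raise ValueError("settler state needs 10 layers")
        if np.any(self.X < 0) or np.any(self.solubles < 0):
            raise ValueError("negative settler concentration")

    @classmethod
    def zeros(cls, n_solubles: int = len(SOLUBLE_INDEX)) -> "SettlerState":
        return cls(X=np.zeros(10), solubles=np.zeros((10, n_solubles)))

    def pack(self) -> np.ndarray:
        return np.concatenate([self.X, self.solubles.ravel()])

    @classmethod
    def unpack(cls, y: np.ndarray, n_solubles: int = len(SOLUBLE_INDEX)) -> "SettlerState":
        return cls(X=y[:10].copy(), solubles=y[10 : 10 + 10 * n_solubles].reshape(10, n_solubles).copy())


def settling_velocity(X, cfg: SettlerConfig, X_feed: float = 0.0):
    """Double-exponential settling velocity, clamped to [0, v0_max].

    v_s = v0 * (exp(-r_h X*) - exp(-r_p X*)) with X* = X - f_ns * X_feed the
    settleable excess over the non-settleable fraction of the feed solids.
    """
    X = np.asarray(X, dtype=float)
    if np.any(X < 0):
        raise ValueError("negative solids concentration")
    Xstar = np.maximum(X - cfg.f_ns * X_feed, 0.0)
    v = cfg.v0 * (np.exp(-cfg.r_h * Xstar) - np.exp(-cfg.r_p * Xstar))
    return np.clip(v, 0.0, cfg.v0_max)


def settler_derivatives(
    state: SettlerState,
    feed_X: float,
    feed_solubles: np.ndarray,
    Q_feed: float,
    Q_underflow: float,
    Q_effluent: float,
    cfg: SettlerConfig,
) -> np.ndarray:
    """Time derivatives of the packed settler state (flux-form balance).

    The gravity flux between layers is limited by the receiving layer
    (min rule) whenever the layer below the feed holds more solids than the
    threshold concentration; above the feed the flux is also capped by the
    sending layer's own flux.  Bulk flow moves upward above the feed layer
    (to the effluent) and downward below it (to the underflow).
    """
    if Q_feed < 0 or Q_underflow < 0 or Q_effluent < 0:
        raise ValueError("flows must be non-negative")
    if abs(Q_feed - Q_underflow - Q_effluent) > 1e-6 * max(Q_feed, 1.0):
        raise ValueError("settler flow imbalance: Q_feed != Q_underflow + Q_effluent")
    return _settler_rhs(state.X, state.solubles, feed_X, feed_solubles,
                        Q_underflow, Q_effluent, Q_feed, cfg)


def _settler_rhs(X, Sol, feed_X, feed_solubles, Q_underflow, Q_effluent, Q_feed, cfg):
    """Unvalidated flux-balance core shared with the plant hot loop."""
    n = cfg.n_layers
    fl = cfg.feed_layer
    A = cfg.area
    h = cfg.layer_height
    v_up = Q_effluent / A     # m d^-1
    v_dn = Q_underflow / A

    vs = settling_velocity(X, cfg, X_feed=feed_X)
    Js = vs * X               # gravity flux g m^-2 d^-1 leaving each layer downwards
    # threshold-limited flux crossing the interface below layer i (J[i+1]):
    # clarification zone (receiving layer at/above the feed): limited by the
    # receiver only when it is overloaded; thickening zone: min rule always
    upper = Js[:-1]
    lower_idx = np.arange(1, n)
    minflux = np.minimum(upper, Js[1:])
    clar = lower_idx <= fl
    J_mid = np.where(clar, np.where(X[1:] > cfg.X_threshold, minflux, upper), minflux)
    J = np.concatenate([[0.0], J_mid, [0.0]])  # no gravity in at top / out at bottom

    dX = (J[:-1] - J[1:]) / h
    dX[:fl] += (v_up / h) * (X[1 : fl + 1] - X[:fl])
    dX[fl] += (Q_feed * feed_X) / (A * h) - ((v_up + v_dn) / h) * X[fl]
    dX[fl + 1 :] += (v_dn / h) * (X[fl:-1] - X[fl + 1 :])

    # solubles: ideal advection, feed split at the feed layer
    fs = np.asarray(feed_solubles, dtype=float)
    dS = np.zeros_like(Sol)
    dS[:fl] = (v_up / h) * (Sol[1 : fl + 1] - Sol[:fl])
    dS[fl] = (Q_feed / (A * h)) * fs - ((v_up + v_dn) / h) * Sol[fl]
    dS[fl + 1 :] = (v_dn / h) * (Sol[fl:-1] - Sol[fl + 1 :])
    return np.concatenate([dX, dS.ravel()])


def settler_tss_inventory(state: SettlerState, cfg: SettlerConfig, z_fractions: np.ndarray | None = None) -> float:
    """Sludge inventory of the settler in kg.

    Sum over the ten layers of layer volume times the particulate
    concentration, scaled by the 0.75 density/porosity conversion used in
    the solids accounting.  ``z_fractions`` optionally rescales each
    layer's TSS into the particulate-COD groups; by default the stored TSS
    itself is used as the group sum.
    """
    X = state.X
    group_sum = X if z_fractions is None else X * np.asarray(z_fractions, dtype=float)
    return float(0.75 * cfg.layer_volume * group_sum.sum() / 1000.0)  # g -> kg
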