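"""One-dimensional six-mass model (6MM) of vocal-fold oscillation.

Each vocal fold is a 3 (longitudinal: posterior/medial/anterior) x 2
(vertical: lower/upper) mesh of point masses whose motion is restricted to
the lateral (medio-lateral) axis.  The two folds face each other across the
glottal midline (x = 0); left-fold positions are negative, right-fold
positions positive.  Masses are tied to lateral rest positions by damped
anchor springs with a cubic stiffening term, coupled vertically and
longitudinally by springs whose lateral response follows the elongation of
the full 3-D spring, pushed apart on contact by collision springs, and
driven outward by a Bernoulli subglottal-pressure force acting on the lower
mass of every open glottal column.

State tensors are laid out ``(..., side, section, vertical)`` =
``(..., 2, 3, 2)`` with side 0 = left, 1 = right; section 0 = posterior,
1 = medial, 2 = anterior; vertical 0 = lower, 1 = upper.

Internally everything is SI (m, kg, s, N, Pa); the public interfaces use
mm, g, ms as documented per field, with explicit conversion at the
boundary.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "PhysicalConfig",
    "ScalingVector",
    "RestPositionGrid",
    "SimState",
    "TrajectorySet",
    "SimulationUnstableError",
    "TRAJECTORY_LABELS",
    "spring_force",
    "anchor_force_lateral",
    "coupling_lateral_force",
    "collision_force",
    "driving_force",
    "total_acceleration",
    "rk4_step",
    "simulate",
    "simulate_batch",
    "extract_trajectories",
    "trajectory_std",
    "is_oscillating",
]

# unit factors to SI
MM = 1e-3
CM = 1e-2
G = 1e-3
MS = 1e-3

#: Row order of every 6-row trajectory array: (side, section).
TRAJECTORY_LABELS: tuple[tuple[str, str], ...] = (
    ("left", "posterior"),
    ("left", "medial"),
    ("left", "anterior"),
    ("right", "posterior"),
    ("right", "medial"),
    ("right", "anterior"),
)


class SimulationUnstableError(RuntimeError):
    """Raised when the integrator state becomes non-finite.

    Attributes ``step`` (first bad time-step index) and ``component``
    (flat index into the 2x3x2 state) locate the blow-up.
    """

    def __init__(self, step: int, component: int | None = None):
        self.step = step
        self.component = component
        msg = f"non-finite state at step {step}"
        if component is not None:
            msg += f" (state component {component})"
        super().__init__(msg)


@dataclass(frozen=True)
class PhysicalConfig:
    """Fixed model constants in the units of the reference specification.

    Masses in g, stiffnesses in N/m, pressure in Pa, damping in Ns/m,
    lengths as annotated, time in ms.  The defaults are the canonical
    per-section split (divide-by-3) of the classical two-mass-model
    constants.
    """

    default_mass_bottom: float = 0.125 / 3  # g
    default_mass_top: float = 0.025 / 3  # g
    default_k_a_bottom: float = 80.0 / 3  # N/m
    default_k_a_top: float = 8.0 / 3  # N/m
    default_P_S: float = 800.0  # Pa
    default_xi_c: float = 1.0  # collision stiffness proportionality
    xi_l: float = 0.2  # longitudinal stiffness proportionality
    # Vertical coupling and anchor damping follow the classical two-mass
    # constants split per section: k_v = 0.1 N/cm = 10 N/m and
    # r_a = 0.02/3 Ns/m (damping ratio ~0.1 for the lower masses).  With
    # values 100x smaller the model never loses enough energy for any
    # configuration to stop phonating, and the upper masses decouple.
    k_v: float = 10.0  # N/m, vertical coupling stiffness
    r_a: float = 0.02 / 3  # Ns/m, anchor damping
    eta: float = 100.0  # cm^-2, cubic anchor coefficient
    ell_l: float = 0.5  # cm, longitudinal free length
    ell_v: float = 0.2  # cm, vertical free length
    vf_length: float = 2.0  # cm, anterior-posterior elongation (= 4 * ell_l)
    anchor_lateral_posterior: float = 0.05  # mm, outward per side
    anchor_lateral_anterior: float = 0.0  # mm
    dt: float = 0.25  # ms
    n_steps: int = 1000
    initial_lower_deflection: float = 1.0  # mm, outward per side
    # The coupling springs apply their entire elongation force laterally;
    # the direction is the sign of the relative deflection, smoothed over
    # a length small against typical deflections so the force stays C-inf.
    # (The elongation itself vanishes quadratically at zero, so even the
    # hard sign would be continuous.)  At 1 mm and above the smoothing
    # weakens the coupling enough that the default configuration stops
    # phonating.
    sign_smoothing_eps: float = 0.1  # mm, coupling direction smoothing length

    def __post_init__(self):
        positive = (
            self.default_mass_bottom,
            self.default_mass_top,
            self.default_k_a_bottom,
            self.default_k_a_top,
            self.ell_l,
            self.ell_v,
            self.vf_length,
            self.dt,
            self.sign_smoothing_eps,
        )
        if any(not np.isfinite(v) or v <= 0 for v in positive):
            raise ValueError("masses, stiffnesses, lengths and dt must be > 0")
        if not np.isclose(self.vf_length, 4 * self.ell_l):
            raise ValueError("vf_length must equal 4 * ell_l")

    # ---- derived quantities (SI) -------------------------------------
    @property
    def dt_s(self) -> float:
        return self.dt * MS

    @property
    def eta_si(self) -> float:
        """Cubic coefficient in m^-2 (eta is stated per cm^2)."""
        return self.eta / CM**2

    def anchor_end_positions(self) -> np.ndarray:
        """Lateral fixed-end positions of the longitudinal chain (m).

        Returns shape (2 sides, 2 ends) with ends ordered (posterior,
        anterior); signed outward per side.  A medial value, were one
        needed, would interpolate linearly between the two.
        """
        sign = np.array([-1.0, 1.0])
        ends = np.array(
            [self.anchor_lateral_posterior, self.anchor_lateral_anterior]
        )
        return sign[:, None] * ends[None, :] * MM

    def segment_width(self) -> float:
        """Longitudinal width of one glottal column (m)."""
        return self.vf_length * CM / 3.0

    def plate_thickness(self) -> float:
        """Vertical thickness of a mass plate (m), taken from ell_v."""
        return self.ell_v * CM


@dataclass(frozen=True)
class ScalingVector:
    """The 14 positive multiplicative factors q defining one 6MM instance.

    ``inv_mass`` scales the *reciprocal* mass of each vertical pair (a
    factor of 2 halves the pair's effective mass), ``k_a_scale`` scales
    both anchor springs of a pair, ``p_s_scale`` the subglottal pressure
    and ``xi_c_scale`` the collision proportionality.  The 6-vectors are
    ordered like :data:`TRAJECTORY_LABELS`.  The identity vector (all
    ones) reproduces the config defaults.
    """

    inv_mass: np.ndarray  # (6,)
    k_a_scale: np.ndarray  # (6,)
    p_s_scale: float
    xi_c_scale: float

    def __post_init__(self):
        object.__setattr__(self, "inv_mass", np.asarray(self.inv_mass, float))
        object.__setattr__(self, "k_a_scale", np.asarray(self.k_a_scale, float))
        arr = self.to_array()
        if arr.shape != (14,) or not np.all(np.isfinite(arr)) or np.any(arr <= 0):
            raise ValueError("scaling vector must be 14 strictly positive reals")

    def to_array(self) -> np.ndarray:
        """Flatten to the canonical 14-vector (m^-1 x6, k_a x6, P_S, xi_c)."""
        return np.concatenate(
            [self.inv_mass, self.k_a_scale, [self.p_s_scale, self.xi_c_scale]]
        )

    @classmethod
    def from_array(cls, arr: np.ndarray) -> "ScalingVector":
        arr = np.asarray(arr, float)
        if arr.shape != (14,):
            raise ValueError("expected a 14-vector")
        return cls(arr[:6], arr[6:12], float(arr[12]), float(arr[13]))

    @classmethod
    def identity(cls) -> "ScalingVector":
        return cls(np.ones(6), np.ones(6), 1.0, 1.0)


#: Parameter index names matching ``ScalingVector.to_array`` order.
PARAMETER_NAMES: tuple[str, ...] = tuple(
    [f"inv_mass_{s[0]}{p[0].upper()}" for s, p in TRAJECTORY_LABELS]
    + [f"k_a_{s[0]}{p[0].upper()}" for s, p in TRAJECTORY_LABELS]
    + ["p_s", "xi_c"]
)


@dataclass(frozen=True)
class RestPositionGrid:
    """Six signed lateral rest positions in mm, ordered like the rows.

    Left entries are <= 0 and right entries >= 0 (left trajectories are
    negative by convention); midline crossings up to 0.2 mm are accepted
    because the sampled marginal law carries a small tail across zero — a
    slightly crossed rest position describes pre-phonatory contact, which
    the collision force resolves.  Each value applies to both vertical
    members of its pair.
    """

    x_r: np.ndarray  # (6,) mm

    #: permitted midline crossing of a rest position (mm)
    CROSSING_TOLERANCE = 0.2

    def __post_init__(self):
        object.__setattr__(self, "x_r", np.asarray(self.x_r, float))
        if self.x_r.shape != (6,) or not np.all(np.isfinite(self.x_r)):
            raise ValueError("rest grid must be 6 finite values")
        tol = self.CROSSING_TOLERANCE
        if np.any(self.x_r[:3] > tol) or np.any(self.x_r[3:] < -tol):
            raise ValueError("left rest positions must be <= 0, right >= 0")

    def as_tensor(self) -> np.ndarray:
        """Rest positions as a (2, 3) side x section array in metres."""
        return self.x_r.reshape(2, 3) * MM


@dataclass
class SimState:
    """Lateral positions (m), velocities (m/s) and time (s)."""

    x: np.ndarray  # (..., 2, 3, 2)
    v: np.ndarray  # (..., 2, 3, 2)
    t: float = 0.0

    def __post_init__(self):
        self.x = np.asarray(self.x, float)
        self.v = np.asarray(self.v, float)
        if self.x.shape[-3:] != (2, 3, 2) or self.v.shape != self.x.shape:
            raise ValueError("state tensors must have trailing shape (2, 3, 2)")


@dataclass
class TrajectorySet:
    """Six signed lateral-deflection time series (mm) at fixed dt (ms)."""

    values: np.ndarray  # (6, n) mm
    dt: float  # ms
    labels: tuple[tuple[str, str], ...] = TRAJECTORY_LABELS

    def __post_init__(self):
        self.values = np.asarray(self.values, float)
        if self.values.ndim != 2 or self.values.shape[0] != 6:
            raise ValueError("trajectory set must have exactly 6 rows")
        if self.values.shape[1] < 1:
            raise ValueError("trajectory set needs at least one sample")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("trajectory values must be finite")

    @property
    def n(self) -> int:
        return self.values.shape[1]

    @property
    def times_ms(self) -> np.ndarray:
        return np.arange(self.n) * self.dt

    def means(self) -> np.ndarray:
        """Time-averaged deflection per row (mm); the rest-position proxy."""
        return self.values.mean(axis=1)


# ---------------------------------------------------------------------------
# Elementary forces
# ---------------------------------------------------------------------------

def spring_force(
    deflection: np.ndarray,
    velocity: np.ndarray,
    k: float,
    r: float,
    ell: float,
) -> np.ndarray:
    """Damped linear spring force for a vectorial deflection ``s``.

    ``F = -[k (|s| - ell) + r (s/|s| . s_dot)] s/|s|``: elastic restoring
    toward the free length plus damping of the radial velocity component,
    both along the unit deflection.  Antisymmetric under
    ``(s, s_dot) -> (-s, -s_dot)``; the zero vector is returned at the
    origin when ``ell == 0``.
    """
    s = np.asarray(deflection, float)
    sd = np.asarray(velocity, float)
    if not (np.all(np.isfinite(s)) and np.all(np.isfinite(sd))):
        raise ValueError("non-finite spring inputs")
    norm = np.linalg.norm(s, axis=-1, keepdims=True)
    if np.any(norm == 0):
        if ell != 0:
            raise ValueError("zero deflection with non-zero free length")
        return np.zeros_like(s)
    unit = s / norm
    radial_v = np.sum(unit * sd, axis=-1, keepdims=True)
    return -(k * (norm - ell) + r * radial_v) * unit


def anchor_force_lateral(
    x: np.ndarray,
    v: np.ndarray,
    x_rest: np.ndarray,
    k_a: np.ndarray,
    r_a: float,
    eta: float,
) -> np.ndarray:
    """Cubic-stiffened damped anchor force (scalar lateral, SI).

    ``-k_a dx (1 + eta dx^2) - r_a v`` with ``dx = x - x_rest``; ``eta``
    in m^-2.  Reduces to the plain lateral spring for ``eta = 0``.
    """
    for a in (x, v, x_rest):
        if not np.all(np.isfinite(a)):
            raise ValueError("non-finite anchor inputs")
    dx = np.asarray(x, float) - np.asarray(x_rest, float)
    return -k_a * dx * (1.0 + eta * dx * dx) - r_a * np.asarray(v, float)


def _smooth_sign(dx: np.ndarray, eps: float) -> np.ndarray:
    # 2 sigmoid(dx/eps) - 1 == tanh(dx / (2 eps)); odd, in (-1, 1)
    return np.tanh(dx / (2.0 * eps))


def coupling_lateral_force(
    dx: np.ndarray, k: float | np.ndarray, ell: float, eps: float = MM
) -> np.ndarray:
    """Lateral response of a coupling spring with fixed transverse span.

    The spring connects two masses a fixed distance ``ell`` apart in its
    own (longitudinal or vertical) direction; a relative lateral
    deflection ``dx`` elongates it to ``sqrt(dx^2 + ell^2)``.  The whole
    elongation force ``k (sqrt(dx^2 + ell^2) - ell)`` is applied
    laterally, restoring ``dx`` toward zero, with the direction smoothed
    through ``2 sigmoid(dx/eps) - 1`` to stay continuous at ``dx = 0``.
    Odd in ``dx`` and exactly zero at ``dx = 0``.
    """
    if ell < 0:
        raise ValueError("free length must be >= 0")
    dx = np.asarray(dx, float)
    mag = np.sqrt(dx * dx + ell * ell) - ell
    return -k * mag * _smooth_sign(dx, eps)


# ---------------------------------------------------------------------------
# Effective (scaled) parameters
# ---------------------------------------------------------------------------

@dataclass
class _EffectiveParams:
    """Scaled model constants in SI, batched with leading axes ``B``."""

    m: np.ndarray  # (..., 2, 3, 2) kg
    k_a: np.ndarray  # (..., 2, 3, 2) N/m
    P_S: np.ndarray  # (...,) Pa
    xi_c: np.ndarray  # (...,)
    x_rest: np.ndarray  # (..., 2, 3) m
    cfg: PhysicalConfig


def _effective_params(
    q: np.ndarray, rest: np.ndarray, cfg: PhysicalConfig
) -> _EffectiveParams:
    """Assemble per-mass SI constants from scaling arrays.

    ``q``: (..., 14) positive scalings, ``rest``: (..., 6) mm signed.
    """
    q = np.asarray(q, float)
    rest = np.asarray(rest, float)
    if np.any(q <= 0) or not np.all(np.isfinite(q)):
        raise ValueError("scaling vectors must be strictly positive")
    inv_mass = q[..., :6].reshape(q.shape[:-1] + (2, 3))
    ka_scale = q[..., 6:12].reshape(q.shape[:-1] + (2, 3))
    m_default = np.array([cfg.default_mass_bottom, cfg.default_mass_top]) * G
    k_default = np.array([cfg.default_k_a_bottom, cfg.default_k_a_top])
    m = m_default / inv_mass[..., None]  # reciprocal scaling
    k_a = k_default * ka_scale[..., None]
    return _EffectiveParams(
        m=m,
        k_a=k_a,
        P_S=cfg.default_P_S * q[..., 12],
        xi_c=cfg.default_xi_c * q[..., 13],
        x_rest=rest.reshape(rest.shape[:-1] + (2, 3)) * MM,
        cfg=cfg,
    )


# ---------------------------------------------------------------------------
# Assembled force tensors (all (..., 2, 3, 2) lateral, SI)
# ---------------------------------------------------------------------------

def _anchor_forces(x, v, p: _EffectiveParams):
    # same formula as anchor_force_lateral, without the input validation:
    # the batch integrator deliberately lets NaN rows propagate
    dx = x - p.x_rest[..., None]
    return -p.k_a * dx * (1.0 + p.cfg.eta_si * dx * dx) - p.cfg.r_a * v


def _vertical_forces(x, p: _EffectiveParams):
    eps = p.cfg.sign_smoothing_eps * MM
    ell = p.cfg.ell_v * CM
    dxv = x[..., 1] - x[..., 0]  # upper - lower
    f_on_upper = coupling_lateral_force(dxv, p.cfg.k_v, ell, eps)
    return np.stack([-f_on_upper, f_on_upper], axis=-1)


def _longitudinal_forces(x, p: _EffectiveParams):
    cfg = p.cfg
    eps = cfg.sign_smoothing_eps * MM
    ell = cfg.ell_l * CM
    ends = cfg.anchor_end_positions()  # (2, 2) m
    batch = x.shape[:-3]
    # extended chain nodes: fixed_P, P, M, A, fixed_A  -> axis -2 length 5
    xe = np.empty(batch + (2, 5, 2), dtype=x.dtype)
    xe[..., :, 1:4, :] = x
    xe[..., :, 0, :] = ends[:, 0, None]
    xe[..., :, 4, :] = ends[:, 1, None]
    # segment stiffness = xi_l * summed adjacent anchor stiffnesses; a fixed
    # end is assigned its neighbouring mass's anchor stiffness
    ka = p.k_a
    k_seg = np.empty(batch + (2, 4, 2), dtype=x.dtype)
    k_seg[..., 0, :] = 2 * ka[..., 0, :]
    k_seg[..., 1, :] = ka[..., 0, :] + ka[..., 1, :]
    k_seg[..., 2, :] = ka[..., 1, :] + ka[..., 2, :]
    k_seg[..., 3, :] = 2 * ka[..., 2, :]
    k_seg *= cfg.xi_l
    dx_seg = xe[..., 1:, :] - xe[..., :-1, :]
    # f_right is the force on each segment's right node; the left node
    # receives the negative.  Mass node m is the right node of segment m
    # and the left node of segment m+1.
    f_right = coupling_lateral_force(dx_seg, k_seg, ell, eps)
    return f_right[..., :-1, :] - f_right[..., 1:, :]


def collision_force(state: SimState, params: _EffectiveParams) -> np.ndarray:
    """Midline collision push-back, per longitudinal/vertical position.

    Penetration depth per side is ``max(0, x_left - x_right) / 2``
    (symmetric about the midline); stiffness ``k_c = xi_c * k_a`` where
    ``k_a`` is the undivided whole-fold anchor stiffness (three times the
    per-section value, as specified: k_c = 80 xi_c bottom, 8 xi_c top),
    with the two sides averaged so the pair receives equal and opposite
    forces; zero free length.
    """
    x = state.x
    pen = np.maximum(0.0, x[..., 0, :, :] - x[..., 1, :, :])  # (..., 3, 2)
    k_c = params.xi_c[..., None, None] * 3.0 * 0.5 * (
        params.k_a[..., 0, :, :] + params.k_a[..., 1, :, :]
    )
    f = k_c * pen / 2.0
    return np.stack([-f, f], axis=-3)  # push left leftward, right rightward


def driving_force(state: SimState, P_S, geometry: PhysicalConfig) -> np.ndarray:
    """Bernoulli subglottal-pressure driving force (lateral outward, SI).

    Per longitudinal column, pressure loads the *lower* mass plate of an
    open column over its area (segment width x plate thickness) with
    ``P1 = P_S [1 - theta(g_min) (g_min/g_low)^2] theta(g_low)`` where
    ``g`` are the glottal gap widths at the two vertical levels.  The jet
    separates at the minimal section, so a divergent column (minimum at
    the lower level) carries no pressure and nothing acts above the
    minimal section; a column closed at the upper level feels the full
    subglottal pressure on its lower plate.  Linear in ``P_S``.
    """
    P_S = np.asarray(P_S, float)
    if np.any(P_S < 0):
        raise ValueError("subglottal pressure must be >= 0")
    x = state.x
    g_low = x[..., 1, :, 0] - x[..., 0, :, 0]  # (..., 3)
    g_up = x[..., 1, :, 1] - x[..., 0, :, 1]
    g_min = np.minimum(g_low, g_up)
    safe_low = np.where(g_low > 0, g_low, 1.0)
    bern = 1.0 - np.where(g_min > 0, (g_min / safe_low) ** 2, 0.0)
    p1 = P_S[..., None] * np.where(g_low > 0, bern, 0.0)
    area = geometry.segment_width() * geometry.plate_thickness()
    f_lower = p1 * area  # outward magnitude on each side's lower mass
    out = np.zeros(x.shape, dtype=x.dtype)
    out[..., 0, :, 0] = -f_lower
    out[..., 1, :, 0] = f_lower
    return out


def total_acceleration(
    state: SimState,
    q: ScalingVector | np.ndarray,
    rest: RestPositionGrid | np.ndarray,
    cfg: PhysicalConfig,
) -> np.ndarray:
    """Lateral acceleration tensor ``(F^a + F^v + F^c + F^d + F^l) / m``."""
    p = _params_of(q, rest, cfg)
    if not (np.all(np.isfinite(state.x)) and np.all(np.isfinite(state.v))):
        bad = int(np.argmax(~(np.isfinite(state.x) & np.isfinite(state.v)).reshape(-1)))
        raise SimulationUnstableError(step=-1, component=bad)
    a = _acceleration(state.x, state.v, p)
    if not np.all(np.isfinite(a)):
        bad = int(np.argmax(~np.isfinite(a).reshape(-1)))
        raise SimulationUnstableError(step=-1, component=bad)
    return a


def _params_of(q, rest, cfg) -> _EffectiveParams:
    q_arr = q.to_array() if isinstance(q, ScalingVector) else np.asarray(q, float)
    r_arr = rest.x_r if isinstance(rest, RestPositionGrid) else np.asarray(rest, float)
    return _effective_params(q_arr, r_arr, cfg)


def _acceleration(x, v, p: _EffectiveParams):
    st = SimState.__new__(SimState)  # skip validation in the hot loop
    st.x, st.v, st.t = x, v, 0.0
    f = (
        _anchor_forces(x, v, p)
        + _vertical_forces(x, p)
        + _longitudinal_forces(x, p)
        + collision_force(st, p)
        + driving_force(st, p.P_S, p.cfg)
    )
    return f / p.m


# ---------------------------------------------------------------------------
# Time integration
# ---------------------------------------------------------------------------

def rk4_step(state: SimState, dt: float, accel_fn) -> SimState:
    """One classical fourth-order Runge-Kutta update of (x, v)."""
    if dt <= 0:
        raise ValueError("dt must be > 0")
    x, v = state.x, state.v
    a1 = accel_fn(x, v)
    k1x, k1v = v, a1
    a2 = accel_fn(x + 0.5 * dt * k1x, v + 0.5 * dt * k1v)
    k2x, k2v = v + 0.5 * dt * k1v, a2
    a3 = accel_fn(x + 0.5 * dt * k2x, v + 0.5 * dt * k2v)
    k3x, k3v = v + 0.5 * dt * k2v, a3
    a4 = accel_fn(x + dt * k3x, v + dt * k3v)
    k4x, k4v = v + dt * k3v, a4
    nx = x + dt / 6.0 * (k1x + 2 * k2x + 2 * k3x + k4x)
    nv = v + dt / 6.0 * (k1v + 2 * k2v + 2 * k3v + k4v)
    return SimState(nx, nv, state.t + dt)


def _initial_state(p: _EffectiveParams, batch: tuple[int, ...]) -> SimState:
    cfg = p.cfg
    x = np.broadcast_to(p.x_rest[..., None], batch + (2, 3, 2)).copy()
    outward = np.array([-1.0, 1.0]) * cfg.initial_lower_deflection * MM
    x[..., :, :, 0] += outward[:, None]
    return SimState(x, np.zeros_like(x), 0.0)


def simulate_batch(
    q: np.ndarray,
    rest: np.ndarray,
    cfg: PhysicalConfig | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Integrate a batch of 6MM instances.

    Parameters
    ----------
    q : (B, 14) positive scaling vectors.
    rest : (B, 6) signed rest positions in mm.

    Returns
    -------
    history : (B, n_steps, 2, 3, 2) lateral positions in metres; samples
        that went non-finite are NaN from their first bad step on.
    first_bad_step : (B,) int, -1 for stable samples.
    """
    cfg = cfg or PhysicalConfig()
    p = _effective_params(q, rest, cfg)
    B = np.asarray(q).shape[0]
    state = _initial_state(p, (B,))
    history = np.empty((B, cfg.n_steps, 2, 3, 2))
    first_bad = np.full(B, -1, dtype=int)
    dt = cfg.dt_s

    def accel(x, v):
        return _acceleration(x, v, p)

    x, v = state.x, state.v
    with np.errstate(over="ignore", invalid="ignore"):
        for step in range(cfg.n_steps):
            history[:, step] = x
            st = SimState.__new__(SimState)
            st.x, st.v, st.t = x, v, step * dt
            nxt = rk4_step(st, dt, accel)
            x, v = nxt.x, nxt.v
            bad = ~np.isfinite(x).all(axis=(1, 2, 3))
            newly = bad & (first_bad < 0)
            if newly.any():
                first_bad[newly] = step + 1
                x[newly] = np.nan
                v[newly] = np.nan
    return history, first_bad


def simulate(
    q: ScalingVector | np.ndarray,
    rest: RestPositionGrid | np.ndarray,
    cfg: PhysicalConfig | None = None,
) -> np.ndarray:
    """Integrate one 6MM instance; returns (n_steps, 2, 3, 2) positions (m).

    Lower masses start deflected outward by the configured +-1 mm from
    their rest positions, upper masses at rest, all velocities zero.
    Raises :class:`SimulationUnstableError` on blow-up.
    """
    cfg = cfg or PhysicalConfig()
    q_arr = q.to_array() if isinstance(q, ScalingVector) else np.asarray(q, float)
    r_arr = rest.x_r if isinstance(rest, RestPositionGrid) else np.asarray(rest, float)
    history, first_bad = simulate_batch(q_arr[None], r_arr[None], cfg)
    if first_bad[0] >= 0:
        raise SimulationUnstableError(step=int(first_bad[0]))
    return history[0]


def extract_trajectories(
    history: np.ndarray | Sequence[SimState],
    cfg: PhysicalConfig | None = None,
) -> TrajectorySet:
    """Trajectories: per vertical pair, the member closest to the midline.

    The raw signed lateral value (mm) of the minimal-|x| member is
    recorded (it may cross zero during overlap); ties go to the lower
    mass.  Rows are ordered (left, right) x (P, M, A).
    """
    cfg = cfg or PhysicalConfig()
    if not isinstance(history, np.ndarray):
        if len(history) == 0:
            raise ValueError("empty history")
        history = np.stack([s.x for s in history])
    if history.ndim != 4 or history.shape[0] == 0:
        raise ValueError("history must be a non-empty (n, 2, 3, 2) array")
    lower = history[..., 0]  # (n, 2, 3)
    upper = history[..., 1]
    chosen = np.where(np.abs(lower) <= np.abs(upper), lower, upper)
    values = chosen.reshape(history.shape[0], 6).T / MM
    return TrajectorySet(values=values, dt=cfg.dt)


def trajectory_std(
    values_mm: np.ndarray, dt_ms: float, transient_cut_ms: float = 75.0
) -> np.ndarray:
    """Per-row standard deviation over the post-transient window, in the
    model's working length unit (cm), the unit the oscillation criterion
    is stated in."""
    start = int(round(transient_cut_ms / dt_ms))
    window = np.asarray(values_mm)[..., start:]
    if window.shape[-1] < 2:
        raise ValueError("no samples left after the transient cut")
    return window.std(axis=-1) * MM / CM


def is_oscillating(
    T: TrajectorySet,
    threshold: float = 1e-3,
    transient_cut_ms: float = 75.0,
    agg: str = "mean",
) -> bool:
    """Oscillation filter: trajectory std (cm working units) >= threshold.

    The statistic is the per-row standard deviation over the
    post-transient window, in the model's cm working unit, aggregated
    across the six rows (``mean`` by default, ``min`` available); the
    boundary case std == threshold passes.
    """
    stds = trajectory_std(T.values, T.dt, transient_cut_ms)
    stat = stds.min() if agg == "min" else stds.mean()
    return bool(stat >= threshold)
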