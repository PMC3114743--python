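"""Cell-centered finite-volume reaction-diffusion on the polygonal mesh.

One concentration per subcompartment.  The kinetic model is the yeast
pheromone-gradient mechanism: a species (active MAP kinase, Fus3PP) is
released at constant rate alpha in the shmoo-tip compartment (role B),
diffuses between cytoplasm/tip subcompartments with diffusion constant
gamma, is dephosphorylated at first-order rate beta in the cytoplasm
(role A), and cannot cross membrane compartments (role ``blocked``); the
image exterior (role ``outside``) carries no equation either.  For a
subcompartment i with neighbours N_i, contact lengths S_in, area V_i:

    dC_i/dt = gamma * sum_{n in N_i} w_in / V_i * (C_n - C_i) * [n in A u B]
              + alpha * [i in B]  -  beta * C_i * [i in A]

with w_in = S_in (``paper_literal`` flux) or S_in / d_in where d_in is the
centroid distance (``distance_normalized``, the consistent finite-volume
Laplacian).  Blocked/outside subcompartments keep their initial value.

The system is linear, dC/dt = M C + b; M is assembled sparse and doubles
as the exact Jacobian for the stiff integrator.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.integrate import solve_ivp

from .mesh import PolygonalMesh

__all__ = [
    "ROLE_CYTOPLASM",
    "ROLE_TIP",
    "ROLE_BLOCKED",
    "ROLE_OUTSIDE",
    "KineticModel",
    "Trajectory",
    "FiniteVolumeRHS",
    "build_rhs",
    "integrate",
    "steady_state",
    "compare_to_image",
    "ErrorMap",
    "IntegrationError",
    "SteadyStateError",
]

log = logging.getLogger(__name__)

ROLE_CYTOPLASM = "A"  # free diffusion + dephosphorylation
ROLE_TIP = "B"  # release source, diffusion
ROLE_BLOCKED = "blocked"  # membranes: no equation, no flux
ROLE_OUTSIDE = "outside"  # image exterior: no equation

_ROLES = {ROLE_CYTOPLASM, ROLE_TIP, ROLE_BLOCKED, ROLE_OUTSIDE}
_FLUX_MODES = {"paper_literal", "distance_normalized"}


@dataclass
class KineticModel:
    """Rates and the mapping of compartment types to model roles.

    alpha: release rate in the tip (a.u. / time).
    beta: dephosphorylation rate constant in the cytoplasm (1 / time).
    gamma: diffusion constant; px / time in ``paper_literal`` flux mode,
        px^2 / time in ``distance_normalized`` mode.
    role_map: compartment type label -> one of "A", "B", "blocked",
        "outside"; must cover every type present on the mesh.
    """

    alpha: float
    beta: float
    gamma: float
    role_map: dict[str, str] = field(default_factory=dict)
    flux_mode: str = "paper_literal"

    def __post_init__(self) -> None:
        for name in ("alpha", "beta", "gamma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.flux_mode not in _FLUX_MODES:
            raise ValueError(f"unknown flux_mode {self.flux_mode!r}")
        bad = {r for r in self.role_map.values() if r not in _ROLES}
        if bad:
            raise ValueError(f"unknown roles {bad}; expected one of {_ROLES}")

    def role_of(self, type_label: str) -> str:
        try:
            return self.role_map[type_label]
        except KeyError:
            raise KeyError(
                f"compartment type {type_label!r} has no role in the model"
            ) from None


@dataclass
class Trajectory:
    """Time series of per-subcompartment concentrations."""

    times: np.ndarray  # (T,)
    states: np.ndarray  # (T, n) indexed like ``ids``
    species: str
    ids: list[int]

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.states = np.atleast_2d(np.asarray(self.states, dtype=float))
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("trajectory times must be strictly increasing")
        if self.states.shape != (len(self.times), len(self.ids)):
            raise ValueError("states shape does not match times x ids")

    @property
    def final(self) -> np.ndarray:
        return self.states[-1]


class IntegrationError(RuntimeError):
    def __init__(self, message: str, last_good_time: float):
        super().__init__(f"{message} (last good time t={last_good_time:g})")
        self.last_good_time = last_good_time


class SteadyStateError(RuntimeError):
    def __init__(self, residual: float, t_reached: float):
        super().__init__(
            f"no steady state within budget: residual {residual:.3e} at t={t_reached:g}"
        )
        self.residual = residual


class FiniteVolumeRHS:
    """Callable right-hand side f(t, y) = M y + b of the assembled system.

    Rows of blocked/outside subcompartments are identically zero, so their
    concentrations are constants of the motion.  ``jacobian`` (= M, sparse)
    is handed to the stiff solver.
    """

    def __init__(
        self,
        matrix: sp.csr_matrix,
        source: np.ndarray,
        ids: list[int],
        roles: np.ndarray,
        volumes: np.ndarray,
    ) -> None:
        self.matrix = matrix
        self.source = source
        self.ids = ids
        self.roles = roles
        self.volumes = volumes

    def __call__(self, t: float, y: np.ndarray) -> np.ndarray:
        return self.matrix @ y + self.source

    @property
    def jacobian(self) -> sp.csr_matrix:
        return self.matrix

    def residual(self, y: np.ndarray) -> float:
        """max_i |dC_i/dt| normalized by max(1, max_i C_i)."""
        dydt = self(0.0, y)
        return float(np.abs(dydt).max(initial=0.0) / max(1.0, y.max(initial=0.0)))


def build_rhs(mesh: PolygonalMesh, model: KineticModel) -> FiniteVolumeRHS:
    """Assemble the linear finite-volume system for ``mesh`` and ``model``.

    Requires adjacency to be computed.  Raises ``KeyError`` if a mesh type
    has no role.
    """
    subs = mesh.subcompartments
    ids = [s.id for s in subs]
    pos = {sid: k for k, sid in enumerate(ids)}
    roles = np.array([model.role_of(s.type) for s in subs])
    volumes = np.array([s.area for s in subs])
    centroids = np.array([s.centroid for s in subs])
    active = np.isin(roles, [ROLE_CYTOPLASM, ROLE_TIP])

    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []
    for (i, n), contact in mesh.adjacency.items():
        a, b = pos[i], pos[n]
        if not (active[a] and active[b]):
            continue
        w = contact
        if model.flux_mode == "distance_normalized":
            d = float(np.hypot(*(centroids[a] - centroids[b])))
            if d <= 0:
                raise ValueError(f"coincident centroids for neighbours {i}, {n}")
            w /= d
        for p, q in ((a, b), (b, a)):
            coeff = model.gamma * w / volumes[p]
            rows += [p, p]
            cols += [q, p]
            vals += [coeff, -coeff]
    n = len(subs)
    matrix = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
    matrix += sp.diags(np.where(roles == ROLE_CYTOPLASM, -model.beta, 0.0))
    source = np.where(roles == ROLE_TIP, model.alpha, 0.0)
    return FiniteVolumeRHS(matrix.tocsr(), source, ids, roles, volumes)


def integrate(
    rhs,
    initial_state: np.ndarray,
    t_end: float,
    output_times=None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    species: str = "C",
    t_start: float = 0.0,
) -> Trajectory:
    """Integrate dC/dt = rhs(t, C) from ``t_start`` to ``t_end`` (stiff-capable).

    Uses BDF with the exact sparse Jacobian when the RHS provides one.
    ``output_times`` defaults to the solver's own steps.
    """
    y0 = np.asarray(initial_state, dtype=float)
    if t_end <= t_start:
        raise ValueError("t_end must exceed t_start")
    if np.any(y0 < 0):
        raise ValueError("initial state must be non-negative")
    jac = getattr(rhs, "jacobian", None)
    sol = solve_ivp(
        rhs,
        (t_start, t_end),
        y0,
        method="BDF",
        jac=jac,
        t_eval=None if output_times is None else np.asarray(output_times, float),
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise IntegrationError(sol.message, sol.t[-1] if len(sol.t) else t_start)
    times, states = sol.t, sol.y.T
    ids = getattr(rhs, "ids", list(range(len(y0))))
    # t_eval may exclude the start point; Trajectory wants >= 2 increasing times
    if len(times) == 1:
        times = np.array([t_start, t_end])
        states = np.vstack([y0, states])
    if times[0] > t_start:
        times = np.concatenate([[t_start], times])
        states = np.vstack([y0, states])
    return Trajectory(times, states, species, list(ids))


def steady_state(
    rhs,
    initial_state: np.ndarray,
    tol: float = 1e-8,
    t_budget: float = 1e6,
    rtol: float = 1e-10,
    atol: float = 1e-12,
) -> np.ndarray:
    """Integrate until the normalized residual max|dC/dt|/max(1, max C) < tol.

    Time is advanced in geometrically growing chunks; raises
    :class:`SteadyStateError` with the residual if the budget runs out.
    An already-stationary state (e.g. an all-blocked mesh) returns
    immediately.
    """
    if tol <= 0:
        raise ValueError("tol must be > 0")
    y = np.asarray(initial_state, dtype=float).copy()
    if hasattr(rhs, "residual"):
        resid = rhs.residual(y)
    else:
        resid = float(np.abs(rhs(0.0, y)).max(initial=0.0) / max(1.0, y.max(initial=0.0)))
    t, chunk = 0.0, 1.0
    while resid >= tol:
        if t >= t_budget:
            raise SteadyStateError(resid, t)
        chunk = min(chunk, t_budget - t)
        traj = integrate(rhs, np.maximum(y, 0.0), t + chunk, rtol=rtol, atol=atol, t_start=t)
        y = traj.final
        t += chunk
        chunk *= 4.0
        if hasattr(rhs, "residual"):
            resid = rhs.residual(y)
        else:
            resid = float(np.abs(rhs(0.0, y)).max(initial=0.0) / max(1.0, y.max(initial=0.0)))
    return y


def fit_to_image(
    mesh: PolygonalMesh,
    species: str,
    role_map: dict[str, str],
    gamma: float = 50.0,
    flux_mode: str = "distance_normalized",
    beta_bounds: tuple[float, float] | None = None,
    n_scan: int = 12,
    ss_tol: float = 1e-10,
) -> tuple[KineticModel, np.ndarray]:
    """Estimate release and dephosphorylation rates from a digitized image.

    With gamma fixed, the steady state is proportional to alpha, so alpha
    reduces to a scale factor; beta sets the gradient's decay length.  Both
    are fitted by minimizing the worst-case (minimax) deviation between the
    simulated steady state and the observed signal over cytoplasm (role A)
    subcompartments: a log-spaced scan over beta followed by a bounded 1D
    refinement.  Returns the fitted model and its scaled steady state.
    """
    from scipy.optimize import minimize_scalar

    subs = mesh.subcompartments
    obs = np.array([s.properties.get(species, math.nan) for s in subs])
    roles = np.array([role_map[s.type] for s in subs])
    fit_mask = (roles == ROLE_CYTOPLASM) & ~np.isnan(obs)
    if not fit_mask.any():
        raise ValueError("no cytoplasm subcompartment with an observed value to fit")
    obs_fit = obs[fit_mask]

    def misfit(beta: float) -> tuple[float, float, np.ndarray]:
        model = KineticModel(1.0, beta, gamma, role_map, flux_mode)
        rhs = build_rhs(mesh, model)
        u = steady_state(rhs, np.zeros(len(subs)), tol=ss_tol)
        u_fit = u[fit_mask]
        top = 3.0 * obs_fit.max() / max(u_fit.max(), 1e-300)
        res = minimize_scalar(
            lambda s: np.abs(s * u_fit - obs_fit).max(), bounds=(0.0, top), method="bounded"
        )
        return float(res.fun), float(res.x), u

    if beta_bounds is None:
        # center the scan on the diffusive decay-length guess from the mesh
        # extent: lambda ~ a tenth to the full bbox diagonal
        xmin, ymin, xmax, ymax = mesh.bbox
        diag = math.hypot(xmax - xmin, ymax - ymin)
        beta_bounds = (gamma / diag**2, gamma / (diag / 50.0) ** 2)
    betas = np.geomspace(beta_bounds[0], beta_bounds[1], n_scan)
    errs = [misfit(b)[0] for b in betas]
    k = int(np.argmin(errs))
    lo, hi = betas[max(0, k - 1)], betas[min(len(betas) - 1, k + 1)]
    res = minimize_scalar(lambda b: misfit(b)[0], bounds=(lo, hi), method="bounded")
    beta = float(res.x)
    _, alpha, u = misfit(beta)
    model = KineticModel(alpha, beta, gamma, role_map, flux_mode)
    return model, alpha * u


@dataclass
class ErrorMap:
    """Simulation-vs-image error per subcompartment.

    ``error`` maps id -> E_i = |C_sim - C_obs| for subcompartments in roles
    A u B with a non-missing observation; ``normalized`` is E / max(E);
    ``summary`` is max E over those subcompartments divided by the maximum
    observed value.
    """

    error: dict[int, float]
    normalized: dict[int, float]
    summary: float

    def argmax_id(self) -> int:
        return max(self.error, key=self.error.get)


def compare_to_image(
    simulated_state: np.ndarray,
    mesh: PolygonalMesh,
    model: KineticModel,
    species: str,
    include_types: tuple[str, ...] = (),
) -> ErrorMap:
    """Compare a simulated state with the digitized signal on the same mesh.

    The error field covers roles A and B; ``include_types`` additionally
    admits named blocked compartments — typically the nucleus, where a
    membrane-blocking model keeps the simulated concentration at its initial
    value while the image shows signal, so the discrepancy there is part of
    the model-vs-data picture.  The scalar ``summary`` is always taken over
    roles A u B only.
    """
    sim = np.asarray(simulated_state, dtype=float)
    subs = mesh.subcompartments
    if len(sim) != len(subs):
        raise ValueError("state length does not match mesh size")
    error: dict[int, float] = {}
    ab_max = 0.0
    obs_max = 0.0
    any_ab = False
    for k, sub in enumerate(subs):
        in_ab = model.role_of(sub.type) in (ROLE_CYTOPLASM, ROLE_TIP)
        if not in_ab and sub.type not in include_types:
            continue
        obs = sub.properties.get(species, math.nan)
        if math.isnan(obs):
            continue
        e = abs(float(sim[k]) - obs)
        error[sub.id] = e
        if in_ab:
            any_ab = True
            ab_max = max(ab_max, e)
            obs_max = max(obs_max, obs)
    if not any_ab:
        raise ValueError(f"no subcompartment in roles A/B has an observed {species!r}")
    emax = max(error.values())
    normalized = {i: (e / emax if emax > 0 else 0.0) for i, e in error.items()}
    summary = (ab_max / obs_max) if obs_max > 0 else math.inf
    return ErrorMap(error, normalized, summary)
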