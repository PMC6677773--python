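"""Model parameters, non-dimensional groups, and configuration I/O.

Single source of truth for every symbol used by the simulator.  The model
is parameterised by three dimensionless groups a user typically thinks in:

* ``chi``   — coordination strength relative to self-propulsion,
  :math:`\\chi = C_v L \\sqrt{L} / (m \\sqrt{\\beta})`.
* ``aleph`` — escape-to-hunting force-magnitude ratio,
  :math:`\\aleph = m \\beta_e / (M \\beta_h)`.
* ``kappa`` — influence-zone radius in units of the agent diameter,
  :math:`\\kappa = r_i / (2 r)`.

Time is reported in the dimensionless form :math:`\\tau = t / \\sqrt{L/\\beta}`.
"""

from __future__ import annotations

import dataclasses
import math
import tomllib
from dataclasses import dataclass, field


class InvalidParameterError(ValueError):
    """A physical parameter violates its admissible range."""


# ---------------------------------------------------------------------------
# non-dimensional groups
# ---------------------------------------------------------------------------

def chi_of(C_v: float, L: float, m: float, beta: float) -> float:
    """Coordination group chi = C_v * L * sqrt(L) / (m * sqrt(beta))."""
    for name, v in (("C_v", C_v), ("L", L), ("m", m), ("beta", beta)):
        if v <= 0:
            raise InvalidParameterError(f"{name} must be > 0, got {v}")
    return C_v * L * math.sqrt(L) / (m * math.sqrt(beta))


def cv_of(chi: float, L: float, m: float, beta: float) -> float:
    """Invert chi_of for the coordination coefficient C_v."""
    if chi < 0:
        raise InvalidParameterError(f"chi must be >= 0, got {chi}")
    for name, v in (("L", L), ("m", m), ("beta", beta)):
        if v <= 0:
            raise InvalidParameterError(f"{name} must be > 0, got {v}")
    return chi * m * math.sqrt(beta) / (L * math.sqrt(L))


def tau_of(t: float, L: float, beta: float) -> float:
    """Dimensionless time tau = t / sqrt(L / beta)."""
    if L <= 0 or beta <= 0:
        raise InvalidParameterError("L and beta must be > 0")
    if t < 0:
        raise InvalidParameterError(f"t must be >= 0, got {t}")
    return t / math.sqrt(L / beta)


def time_of(tau: float, L: float, beta: float) -> float:
    """Physical time for a given tau (inverse of :func:`tau_of`)."""
    if L <= 0 or beta <= 0:
        raise InvalidParameterError("L and beta must be > 0")
    if tau < 0:
        raise InvalidParameterError(f"tau must be >= 0, got {tau}")
    return tau * math.sqrt(L / beta)


def aleph_of(m: float, beta_e: float, M: float, beta_h: float) -> float:
    """Escape-to-hunting force ratio aleph = (m*beta_e) / (M*beta_h).

    The hunting force magnitude is velocity dependent; the zero-velocity
    magnitude M*beta_h is the only velocity-independent normalisation.
    """
    for name, v in (("m", m), ("beta_e", beta_e), ("M", M), ("beta_h", beta_h)):
        if v <= 0:
            raise InvalidParameterError(f"{name} must be > 0, got {v}")
    return (m * beta_e) / (M * beta_h)


def kappa_of(r_i: float, r: float) -> float:
    """Influence-radius-to-diameter ratio kappa = r_i / (2 r)."""
    if r_i <= 0 or r <= 0:
        raise InvalidParameterError("r_i and r must be > 0")
    return r_i / (2.0 * r)


@dataclass(frozen=True)
class NondimensionalGroups:
    chi: float
    tau: float
    aleph: float
    kappa: float

    def __post_init__(self) -> None:
        if self.chi < 0:
            raise InvalidParameterError("chi must be >= 0")
        if self.kappa <= 0:
            raise InvalidParameterError("kappa must be > 0")
        if self.aleph < 0:
            raise InvalidParameterError("aleph must be >= 0")


# Ranges of the published parametric study; accepted by the validator.
CHI_STUDY_RANGE = (121.0, 6039.0)
ALEPH_STUDY_RANGE = (0.0625, 1.250)

_INTERACTION_MODES = ("full_spring", "literal_attraction", "contact_only")


# ---------------------------------------------------------------------------
# simulation configuration
# ---------------------------------------------------------------------------

@dataclass
class SimulationConfig:
    """Every symbol of the model in one validated record.

    All radii/zones are stored resolved (absolute lengths), not as ratios.
    The stage/activation times ``t_h, t_w, t_s, t_TO`` and ``tau_end`` are
    dimensionless tau values; the engine converts them to physical time.
    """

    n: int = 2808                 # number of prey agents
    N_pred: int = 1               # number of predators (model supports 1)
    L: float = 1.0                # side of the square arena
    r: float = 0.003368           # prey radius
    R: float = 0.013473           # predator radius (4 r)
    r_w: float = 0.003368         # wall-particle radius (= r)
    r_d: float = 0.067364         # prey detection radius (20 r)
    r_i: float = 0.033682         # prey influence radius (2 kappa r)
    R_d: float = 0.067364         # predator detection radius (= r_d)
    R_i: float = 0.134729         # predator influence radius (10 R)
    R_k: float = 0.016841         # sure-kill radius (1.25 R)
    m: float = 1.0                # prey mass
    M: float = 16.0               # predator mass (area scaling of a 4x disk)
    beta: float = 1.0             # thrust coefficient
    alpha: float = 1.0            # speed-saturation coefficient
    beta_e: float = 8.0           # escape thrust (aleph * M * beta_h / m)
    beta_h: float = 1.0           # hunting thrust
    gamma: float = 1.0            # Rayleigh friction factor (predator)
    C_v: float = 604.0            # coordination coefficient
    k_n: float = 1.0e4            # contact spring stiffness
    k_a: float = 3.7              # long-range attraction stiffness (full_spring)
    t_h: float = 3.95             # tau at which hunting/escape activate
    t_w: float = 0.08             # waiting-stage period (tau)
    t_s: float = 0.08             # satisfaction-stage period (tau)
    t_TO: float = 0.32            # hunt time-out limit (tau)
    tau_end: float = 316.0        # total simulated tau
    dt: float = 1.0e-3            # integrator step (physical time)
    seed: int = 0
    predator_init: list = field(default_factory=lambda: [(0.93, 0.43)])
    consuming: bool = False       # remove prey on death instead of leaving disks
    interaction_mode: str = "full_spring"
    dead_drag: float = 0.0        # linear drag on dead prey (0 = literal equations)
    coordination_live_only: bool = False  # exclude dead prey from the velocity average

    # ---- derived views -------------------------------------------------

    def groups(self) -> NondimensionalGroups:
        return NondimensionalGroups(
            chi=chi_of(self.C_v, self.L, self.m, self.beta),
            tau=self.tau_end,
            aleph=aleph_of(self.m, self.beta_e, self.M, self.beta_h),
            kappa=kappa_of(self.r_i, self.r),
        )

    @property
    def t_end(self) -> float:
        """Physical run length."""
        return time_of(self.tau_end, self.L, self.beta)

    def tau(self, t: float) -> float:
        return tau_of(t, self.L, self.beta)

    def physical_time(self, tau: float) -> float:
        return time_of(tau, self.L, self.beta)

    # ---- construction --------------------------------------------------

    @classmethod
    def from_groups(
        cls,
        n: int = 2808,
        chi: float = 604.0,
        aleph: float = 0.5,
        kappa: float = 5.0,
        *,
        L: float = 1.0,
        packing_fraction: float = 0.10,
        tau_end: float = 316.0,
        seed: int = 0,
        **overrides,
    ) -> "SimulationConfig":
        """Build a config from the dimensionless groups of the study.

        Absolute lengths follow the published zone ratios
        (R = 4r, r_w = r, r_d = 20r, R_d = 5R, R_i = 10R, R_k = 1.25R,
        r_i = 2*kappa*r) with the prey radius set from a target packing
        fraction: r = sqrt(packing_fraction * L^2 / (pi * n)).
        """
        if not 0 < packing_fraction < 0.7:
            raise InvalidParameterError("packing_fraction must lie in (0, 0.7)")
        if n < 1:
            raise InvalidParameterError("n must be >= 1")
        r = math.sqrt(packing_fraction * L * L / (math.pi * n))
        m = overrides.pop("m", 1.0)
        beta = overrides.pop("beta", 1.0)
        M = overrides.pop("M", 16.0)
        beta_h = overrides.pop("beta_h", 1.0)
        r_i = 2.0 * kappa * r
        kw = dict(
            n=n, L=L, r=r, R=4 * r, r_w=r, r_d=20 * r, r_i=r_i,
            R_d=20 * r, R_i=40 * r, R_k=1.25 * 4 * r,
            m=m, beta=beta, M=M, beta_h=beta_h,
            C_v=cv_of(chi, L, m, beta),
            beta_e=aleph * M * beta_h / m,
            tau_end=tau_end, seed=seed,
            predator_init=[(0.93 * L, 0.43 * L)],
        )
        kw.update(overrides)
        k_n = kw.setdefault("k_n", 1.0e4)
        # cohesion is a weak perturbation: peak attraction (at the cutoff,
        # lambda = r_i - 2r) is 10% of the propulsion scale m*beta, enough to
        # transmit agitation without collapsing the swarm into a droplet
        kw.setdefault("k_a", 0.1 * m * beta / max(r_i - 2 * r, 1e-12))
        # spring restoring time resolved at ten steps per sqrt(m/k_n)
        kw.setdefault("dt", 0.1 * math.sqrt(m / k_n))
        return cls(**kw)

    # ---- validation ----------------------------------------------------

    def __post_init__(self) -> None:
        self.predator_init = [tuple(map(float, p)) for p in self.predator_init]
        self.validate()

    def validate(self) -> None:
        positive = (
            "L r R r_w r_d r_i R_d R_i R_k m M beta beta_e beta_h "
            "C_v k_n k_a t_h t_w t_s t_TO tau_end dt"
        ).split()
        for name in positive:
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be > 0, got {getattr(self, name)}")
        for name in ("alpha", "gamma", "dead_drag"):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"{name} must be >= 0")
        if self.n < 1 or self.N_pred != 1:
            raise InvalidParameterError("need n >= 1 prey and exactly one predator")
        if self.R_k < self.R:
            raise InvalidParameterError("R_k must be >= R (kill requires contact)")
        if self.interaction_mode not in _INTERACTION_MODES:
            raise InvalidParameterError(
                f"interaction_mode must be one of {_INTERACTION_MODES}")
        if self.n * math.pi * self.r ** 2 >= 0.7 * self.L ** 2:
            raise InvalidParameterError(
                "packing infeasible: n * pi * r^2 must be < 0.7 * L^2")
        for x, y in self.predator_init:
            if not (0.0 < x < self.L and 0.0 < y < self.L):
                raise InvalidParameterError(
                    f"predator start ({x}, {y}) must lie strictly inside the arena")

    # ---- file round trip ----------------------------------------------

    def to_file(self, path) -> None:
        lines = []
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if isinstance(v, bool):
                lines.append(f"{f.name} = {'true' if v else 'false'}")
            elif isinstance(v, (int, float)):
                lines.append(f"{f.name} = {v!r}")
            elif isinstance(v, str):
                lines.append(f'{f.name} = "{v}"')
            elif f.name == "predator_init":
                pts = ", ".join(f"[{x!r}, {y!r}]" for x, y in v)
                lines.append(f"predator_init = [{pts}]")
            else:  # pragma: no cover
                raise TypeError(f"unserialisable field {f.name}")
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path) -> "SimulationConfig":
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise InvalidParameterError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
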