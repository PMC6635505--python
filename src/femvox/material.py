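"""Isotropic elastic-damage constitutive law for homogenized bone.

The law honours the constraints the model family imposes: isotropy, a
density-dependent modulus and strength (power laws in the bone volume
fraction ρ, normalised so ρ = 1 gives the cortical-corrected poreless
values), a piecewise quadratic yield criterion with distinct tension and
compression branches selected by the sign of the stress trace, and a scalar
damage variable D ∈ [0, 1) that multiplies (1 − D) onto the elastic modulus.
Past the yield/ultimate surface the uniaxial compressive response plateaus at
the ultimate stress (no softening in compression) while the tensile response
softens exponentially; D is related to the accumulated inelastic measure κ by
D = 1 − exp(−κc·κ), i.e. κ ≡ −ln(1 − D)/κc.

The numeric default constants are implementation defaults of this package
(the underlying multi-axial trabecular-bone test data are not reprinted in
any single source); every one is overridable via `MaterialParams`.

Voigt convention: order (xx, yy, zz, yz, xz, xy), engineering shear strains.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "MaterialParams",
    "MaterialState",
    "MaterialError",
    "elastic_modulus",
    "stiffness_matrix",
    "yield_function",
    "integrate_stress",
    "uniaxial_response",
    "damage_stress_update",
    "von_mises",
]


class MaterialError(ValueError):
    pass


@dataclass(frozen=True)
class MaterialParams:
    """Bone material parameters (MPa, dimensionless).

    E0, sigma_c0, sigma_t0 are the poreless-bone (ρ = 1, cortical-corrected)
    modulus and compressive/tensile ultimate stresses; p_exp and q_exp the
    modulus- and strength-density exponents; kappa_c the damage-rate
    parameter relating κ to D; softening_rate the dimensionless e-folding
    rate of post-ultimate tensile softening.
    """

    E0: float = 12000.0
    nu: float = 0.3
    p_exp: float = 2.0
    sigma_c0: float = 180.0
    sigma_t0: float = 110.0
    q_exp: float = 1.8
    kappa_c: float = 200.0
    softening_tension: bool = True
    plateau_compression: bool = True
    softening_rate: float = 0.5

    def __post_init__(self) -> None:
        if self.E0 <= 0:
            raise MaterialError("E0 must be > 0")
        if not (0.0 <= self.nu < 0.5):
            raise MaterialError("nu must be in [0, 0.5)")
        if not (self.sigma_c0 > self.sigma_t0 > 0):
            raise MaterialError("require sigma_c0 > sigma_t0 > 0")
        if self.p_exp < 1 or self.q_exp < 1:
            raise MaterialError("density exponents must be >= 1")
        if self.kappa_c <= 0:
            raise MaterialError("kappa_c must be > 0")
        if self.softening_rate <= 0:
            raise MaterialError("softening_rate must be > 0")

    def strength(self, rho, tension: bool):
        s0 = self.sigma_t0 if tension else self.sigma_c0
        return s0 * np.asarray(rho, dtype=float) ** self.q_exp

    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        d = dataclasses.asdict(self)
        if path.suffix in (".yaml", ".yml"):
            import yaml

            path.write_text(yaml.safe_dump(d))
        else:
            path.write_text(json.dumps(d, indent=2))

    @classmethod
    def from_file(cls, path: str | Path) -> "MaterialParams":
        path = Path(path)
        if path.suffix in (".yaml", ".yml"):
            import yaml

            d = yaml.safe_load(path.read_text())
        else:
            d = json.loads(path.read_text())
        return cls(**d)


@dataclass
class MaterialState:
    """Integration-point state: total strain, stress (Voigt), D and κ."""

    strain: np.ndarray = None  # type: ignore[assignment]
    stress: np.ndarray = None  # type: ignore[assignment]
    D: float = 0.0
    kappa: float = 0.0

    def __post_init__(self) -> None:
        if self.strain is None:
            self.strain = np.zeros(6)
        if self.stress is None:
            self.stress = np.zeros(6)
        self.strain = np.asarray(self.strain, dtype=float)
        self.stress = np.asarray(self.stress, dtype=float)

    def copy(self) -> "MaterialState":
        return MaterialState(self.strain.copy(), self.stress.copy(), self.D, self.kappa)


def elastic_modulus(rho, params: MaterialParams, rho_min: float = 1e-6):
    """Density power law E = E0·ρ^p, strictly increasing in ρ ∈ (0, 1]."""
    r = np.asarray(rho, dtype=float)
    if np.any(r < rho_min) or np.any(r > 1.0 + 1e-12):
        raise MaterialError(f"rho outside ({rho_min:g}, 1]: "
                            f"range {r.min():g}–{r.max():g}")
    E = params.E0 * r ** params.p_exp
    return float(E) if np.isscalar(rho) else E


def stiffness_matrix(E: float, nu: float) -> np.ndarray:
    """Isotropic elasticity matrix, Voigt (engineering shear) convention."""
    lam = E * nu / ((1 + nu) * (1 - 2 * nu))
    mu = E / (2 * (1 + nu))
    C = np.zeros((6, 6))
    C[:3, :3] = lam
    C[np.arange(3), np.arange(3)] += 2 * mu
    C[np.arange(3, 6), np.arange(3, 6)] = mu
    return C


def von_mises(stress: np.ndarray) -> np.ndarray:
    """Von Mises equivalent of Voigt stresses; last axis is the 6 components."""
    s = np.asarray(stress, dtype=float)
    sx, sy, sz, tyz, txz, txy = (s[..., i] for i in range(6))
    return np.sqrt(0.5 * ((sx - sy) ** 2 + (sy - sz) ** 2 + (sz - sx) ** 2)
                   + 3.0 * (tyz ** 2 + txz ** 2 + txy ** 2))


def yield_function(stress: np.ndarray, rho: float, params: MaterialParams) -> float:
    """f ≤ 0 elastic.  Piecewise criterion: the von-Mises-type quadratic with
    the tensile radius σt0·ρ^q when tr σ > 0, the compressive radius σc0·ρ^q
    otherwise.  In uniaxial stress it reduces to |σ| = σ0·ρ^q at ultimate."""
    s = np.asarray(stress, dtype=float)
    tension = s[..., :3].sum() > 0.0
    return float(von_mises(s) - params.strength(rho, tension))


def _damage_candidate(s_eq, tension, sy_t, sy_c, params: MaterialParams):
    """Damage needed so (1−D)·s_eq lies on the post-yield response."""
    sy = np.where(tension, sy_t, sy_c)
    softens = np.where(tension, params.softening_tension,
                       not params.plateau_compression)
    over = s_eq > sy
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(over, s_eq / np.maximum(sy, 1e-300), 1.0)
        target = np.where(softens, sy * np.exp(-(ratio - 1.0) / params.softening_rate),
                          sy)
        D = np.where(over, 1.0 - target / np.maximum(s_eq, 1e-300), 0.0)
    return np.clip(D, 0.0, 1.0 - 1e-12)


def damage_stress_update(strain, D_old, E, syc, syt, params: MaterialParams):
    """Vectorized total-strain damage update (the solver's inner kernel).

    Parameters are per-point arrays: strain (m, 6), damage at the start of
    the step D_old (m,), undamaged modulus E (m,) and the two strength radii.
    Returns (stress (m, 6), D_new (m,), effective von Mises (m,)).
    """
    strain = np.atleast_2d(np.asarray(strain, dtype=float))
    E = np.asarray(E, dtype=float)
    lam = E * params.nu / ((1 + params.nu) * (1 - 2 * params.nu))
    mu = E / (2 * (1 + params.nu))
    tr = strain[:, :3].sum(axis=1)
    eff = np.empty_like(strain)
    eff[:, :3] = (lam * tr)[:, None] + 2 * mu[:, None] * strain[:, :3]
    eff[:, 3:] = mu[:, None] * strain[:, 3:]
    s_eq = von_mises(eff)
    tension = eff[:, :3].sum(axis=1) > 0.0
    D_cand = _damage_candidate(s_eq, tension, np.asarray(syt, dtype=float),
                               np.asarray(syc, dtype=float), params)
    D_new = np.maximum(np.asarray(D_old, dtype=float), D_cand)
    stress = (1.0 - D_new)[:, None] * eff
    return stress, D_new, s_eq


def integrate_stress(
    strain_increment: np.ndarray,
    state: MaterialState,
    rho: float,
    params: MaterialParams,
) -> MaterialState:
    """Advance one integration point by a total-strain increment.

    Elastic predictor with the damaged secant modulus; if the effective
    (undamaged) stress violates the branch criterion, damage grows to put the
    stress on the plateau (compression) or the softening curve (tension).
    D and κ never decrease; unloading follows the secant (1 − D)·E(ρ).
    """
    E = elastic_modulus(rho, params)
    strain = state.strain + np.asarray(strain_increment, dtype=float)
    stress, D_new, _ = damage_stress_update(
        strain[None, :], np.array([state.D]), np.array([E]),
        np.array([params.strength(rho, tension=False)]),
        np.array([params.strength(rho, tension=True)]), params)
    D = float(D_new[0])
    kappa = -np.log1p(-D) / params.kappa_c
    return MaterialState(strain=strain, stress=stress[0], D=D, kappa=kappa)


def uniaxial_response(
    rho: float,
    strain_path: np.ndarray,
    params: MaterialParams | None = None,
) -> np.ndarray:
    """Axial stress along a uniaxial-stress strain path (lateral strains free).

    ``strain_path`` are total axial strains starting at 0.  With scalar
    isotropic damage the lateral strain −ν·ε keeps the lateral stress exactly
    zero, so the material-point response is driven with that kinematics.
    Returns the axial stress path (MPa).
    """
    params = params or MaterialParams()
    path = np.asarray(strain_path, dtype=float)
    if path[0] != 0.0:
        raise MaterialError("strain path must start at 0")
    state = MaterialState()
    out = np.zeros(len(path))
    prev = 0.0
    for i, eps in enumerate(path):
        d = eps - prev
        inc = np.array([d, -params.nu * d, -params.nu * d, 0.0, 0.0, 0.0])
        state = integrate_stress(inc, state, rho, params)
        out[i] = state.stress[0]
        prev = eps
    return out
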