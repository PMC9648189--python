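"""Model electronic systems and their Metropolis sampler.

The dispersion estimator needs an explicit electronic wavefunction for the
solute.  This module provides analytic model systems (isotropic Gaussian
orbitals, hydrogen-like 1s densities, and a synthetic ground/excited pair
of tunable diffuseness), a single-electron-move Metropolis sampler of
|Psi|^2, and the escape-fraction construction of the damping parameter b.

All lengths are in bohr, energies in Hartree.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.special import erf, gammainc

from ._geometry import angular_grid, ray_union_intervals
from ._tables import solute_state_table
from .units import BOHR_TO_ANGSTROM

ELEMENT_CHARGES = {
    "H": 1, "He": 2, "Li": 3, "Be": 4, "B": 5, "C": 6, "N": 7, "O": 8,
    "F": 9, "Ne": 10, "P": 15, "S": 16, "Cl": 17,
}


@dataclass(frozen=True)
class Atom:
    """A solute nucleus: cavity spheres and b-spheres are centered here."""

    element: str
    position: np.ndarray
    nuclear_charge: float

    def __post_init__(self):
        object.__setattr__(self, "position", np.asarray(self.position, float))
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValueError("Atom position must be a finite 3-vector (bohr)")
        if self.nuclear_charge <= 0:
            raise ValueError("nuclear_charge must be positive")


def atom(element: str, position) -> Atom:
    return Atom(element, np.asarray(position, float),
                float(ELEMENT_CHARGES.get(element, 1)))


# ---------------------------------------------------------------------------
# analytic one-electron marginals
# ---------------------------------------------------------------------------

class SphericalMarginal:
    """Spherically symmetric one-electron density about a fixed center.

    Subclasses provide the 3-D density value as a function of the distance r
    from the center, the radial cumulative distribution (electron mass within
    radius r) and moment/cutoff information used by quadratures.
    """

    center: np.ndarray

    def log_density(self, r):  # pragma: no cover - interface
        raise NotImplementedError

    def density(self, r):
        return np.exp(self.log_density(r))

    def radial_cdf(self, r):  # pragma: no cover - interface
        raise NotImplementedError

    def cutoff_radius(self) -> float:  # pragma: no cover - interface
        raise NotImplementedError


@dataclass(frozen=True)
class GaussianOrbital(SphericalMarginal):
    """Isotropic Gaussian density with per-axis standard deviation sigma."""

    sigma: float
    center: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        object.__setattr__(self, "center", np.asarray(self.center, float))
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")

    def log_density(self, r):
        r = np.asarray(r, float)
        return -0.5 * (r / self.sigma) ** 2 - 1.5 * math.log(2 * math.pi * self.sigma**2)

    def radial_cdf(self, r):
        r = np.asarray(r, float)
        z = r / self.sigma
        return erf(z / math.sqrt(2)) - math.sqrt(2 / math.pi) * z * np.exp(-0.5 * z * z)

    def cutoff_radius(self):
        return 12.0 * self.sigma

    @property
    def second_moment(self):
        # <r^2> about the center
        return 3.0 * self.sigma**2

    @property
    def mean_radius(self):
        return 2.0 * math.sqrt(2.0 / math.pi) * self.sigma


@dataclass(frozen=True)
class Slater1s(SphericalMarginal):
    """Hydrogen-like 1s density, rho(r) = (Z^3/pi) exp(-2 Z r)."""

    Z: float
    center: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        object.__setattr__(self, "center", np.asarray(self.center, float))
        if self.Z <= 0:
            raise ValueError("Z must be positive")

    def log_density(self, r):
        r = np.asarray(r, float)
        return math.log(self.Z**3 / math.pi) - 2.0 * self.Z * r

    def radial_cdf(self, r):
        return gammainc(3, 2.0 * self.Z * np.asarray(r, float))

    def cutoff_radius(self):
        return 25.0 / self.Z

    @property
    def second_moment(self):
        return 3.0 / self.Z**2

    @property
    def mean_radius(self):
        return 1.5 / self.Z


# ---------------------------------------------------------------------------
# wavefunctions
# ---------------------------------------------------------------------------

class ModelWavefunction:
    """An n-electron model density, either analytic or user supplied.

    Analytic models are products of independent spherical one-electron
    marginals; these expose closed-form radial CDFs and support the
    deterministic quadrature oracles.  A user density is any callable
    mapping configurations of shape (..., n_electrons, 3) to non-negative
    density values (normalization is the caller's responsibility and is
    spot-checked by `normalization()` for small systems).
    """

    def __init__(self, *, marginals: Sequence[SphericalMarginal] | None = None,
                 density: Callable | None = None, n_electrons: int | None = None,
                 state_label: str = "ground",
                 center_of_charge=None):
        if (marginals is None) == (density is None):
            raise ValueError("provide exactly one of marginals= or density=")
        self.marginals = tuple(marginals) if marginals is not None else None
        self._density_fn = density
        if self.marginals is not None:
            self.n_electrons = len(self.marginals)
            coc = np.mean([m.center for m in self.marginals], axis=0)
        else:
            if n_electrons is None or n_electrons < 1:
                raise ValueError("n_electrons required for a callable density")
            self.n_electrons = int(n_electrons)
            coc = np.zeros(3)
        self.center_of_charge = (np.asarray(center_of_charge, float)
                                 if center_of_charge is not None else coc)
        if state_label not in ("ground", "excited"):
            raise ValueError("state_label must be 'ground' or 'excited'")
        self.state_label = state_label

    @property
    def has_analytic_marginals(self) -> bool:
        return self.marginals is not None

    def log_density(self, configs):
        x = np.asarray(configs, float)
        if x.shape[-2:] != (self.n_electrons, 3):
            raise ValueError(f"configurations must have shape (..., {self.n_electrons}, 3)")
        if self.marginals is not None:
            out = np.zeros(x.shape[:-2])
            for e, m in enumerate(self.marginals):
                r = np.linalg.norm(x[..., e, :] - m.center, axis=-1)
                out = out + m.log_density(r)
            return out
        d = np.asarray(self._density_fn(x), float)
        with np.errstate(divide="ignore"):
            return np.log(d)

    def density(self, configs):
        if self.marginals is not None:
            return np.exp(self.log_density(configs))
        return np.asarray(self._density_fn(np.asarray(configs, float)), float)

    def second_moment(self) -> float:
        """Sum over electrons of <|x_e - center_of_charge|^2> (bohr^2)."""
        if self.marginals is None:
            raise ValueError("second_moment requires analytic marginals")
        tot = 0.0
        for m in self.marginals:
            off = m.center - self.center_of_charge
            tot += m.second_moment + float(np.dot(off, off))
        return tot

    def normalization(self) -> float:
        """Quadrature check of the total density normalization."""
        if self.marginals is not None:
            from scipy.integrate import quad
            prod = 1.0
            for m in self.marginals:
                val, _ = quad(lambda r, m=m: 4 * math.pi * r * r * m.density(r),
                              0, m.cutoff_radius(), limit=200)
                prod *= val
            return prod
        if self.n_electrons != 2 and self.n_electrons != 1:
            raise ValueError("normalization check supported for <=2 electrons only")
        raise ValueError("normalization check requires analytic marginals")


def gaussian_wavefunction(sigma: float, center=(0.0, 0.0, 0.0),
                          n_electrons: int = 1,
                          state_label: str = "ground") -> ModelWavefunction:
    """Product of `n_electrons` identical isotropic Gaussian orbitals."""
    c = np.asarray(center, float)
    return ModelWavefunction(
        marginals=[GaussianOrbital(sigma, c) for _ in range(n_electrons)],
        state_label=state_label)


def hydrogen_like_wavefunction(Z: float = 1.0, center=(0.0, 0.0, 0.0)) -> ModelWavefunction:
    return ModelWavefunction(marginals=[Slater1s(Z, np.asarray(center, float))])


def make_two_state_fixture(diffuseness_ratio: float, *, sigma0: float = 1.2,
                           n_electrons: int = 2, center=(0.0, 0.0, 0.0)):
    """Synthetic ground/excited pair of model wavefunctions.

    The excited state is the ground state dilated by `diffuseness_ratio`
    (> 1): every orbital width is multiplied by the ratio so the electronic
    cloud of the excited state is strictly more diffuse, which is the
    qualitative feature driving a red dispersion shift.  The pair shares the
    electron count and the center of charge.
    """
    if diffuseness_ratio <= 1.0:
        raise ValueError("diffuseness_ratio must exceed 1")
    ground = gaussian_wavefunction(sigma0, center, n_electrons, "ground")
    excited = gaussian_wavefunction(sigma0 * diffuseness_ratio, center,
                                    n_electrons, "excited")
    return ground, excited


# ---------------------------------------------------------------------------
# electronic state parameters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ElectronicState:
    """Per-state solute parameters: I (Hartree), vertical energy (eV), b (1/bohr)."""

    label: str
    ionization_potential: float
    vertical_transition_energy: float = 0.0
    b: float | None = None

    def __post_init__(self):
        if self.label not in ("ground", "excited"):
            raise ValueError("label must be 'ground' or 'excited'")
        if self.ionization_potential <= 0:
            raise ValueError("ionization_potential must be positive (Hartree)")
        if self.vertical_transition_energy < 0:
            raise ValueError("vertical_transition_energy must be >= 0 (eV)")


def solute_state(solute: str, state: str) -> ElectronicState:
    """Packaged per-state data (b, I, vertical energy) for the carbonyl solutes."""
    df = solute_state_table()
    row = df[(df.solute == solute) & (df.state == state)]
    if row.empty:
        known = sorted(set(map(tuple, df[["solute", "state"]].values)))
        raise KeyError(f"no packaged data for ({solute!r}, {state!r}); known: {known}")
    r = row.iloc[0]
    if np.isnan(r.ionization_hartree):
        raise ValueError(f"ionization potential not tabulated for ({solute}, {state})")
    return ElectronicState(
        label="ground" if state == "ground" else "excited",
        ionization_potential=float(r.ionization_hartree),
        vertical_transition_energy=float(r.vertical_ev),
        b=float(r.b) if not np.isnan(r.b) else None)


# ---------------------------------------------------------------------------
# Metropolis sampler
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConfigurationSample:
    snapshots: np.ndarray  # (n_kept, n_electrons, 3), bohr
    seed: int
    n_kept: int
    acceptance_rate: float
    decorrelation_stride: int

    def __post_init__(self):
        if self.snapshots.shape[0] != self.n_kept:
            raise ValueError("n_kept inconsistent with snapshot array")


def sample_configurations(wf: ModelWavefunction, n: int, seed: int, *,
                          step_size: float = 0.8, burn_in: int = 1000,
                          stride: int = 10, n_walkers: int | None = None) -> ConfigurationSample:
    """Metropolis sampling of |Psi|^2 with single-electron Gaussian moves.

    Runs `n_walkers` independent chains in parallel (vectorized); each sweep
    proposes one Gaussian displacement per electron.  Snapshots are retained
    every `stride` sweeps after `burn_in` sweeps.  Identical seeds give
    bitwise-identical snapshot lists.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if step_size <= 0:
        raise ValueError("step_size must be positive")
    if stride < 1 or burn_in < 0:
        raise ValueError("stride >= 1 and burn_in >= 0 required")
    n_walkers = min(64, n) if n_walkers is None else int(n_walkers)
    kept_per = -(-n // n_walkers)  # ceil
    rng = np.random.default_rng(seed)
    nel = wf.n_electrons

    if wf.marginals is not None:
        x = np.stack([m.center + rng.normal(scale=1.0, size=(n_walkers, 3))
                      for m in wf.marginals], axis=1)
    else:
        x = wf.center_of_charge + rng.normal(scale=1.0, size=(n_walkers, nel, 3))
    logp = wf.log_density(x)
    if not np.all(np.isfinite(logp)):
        # fall back: nudge walkers until density is positive
        bad = ~np.isfinite(logp)
        tries = 0
        while np.any(bad):
            x[bad] = rng.normal(scale=0.5, size=(int(bad.sum()), nel, 3))
            logp = wf.log_density(x)
            bad = ~np.isfinite(logp)
            tries += 1
            if tries > 100:
                raise RuntimeError("could not initialize walkers in the density support")

    n_acc = 0
    n_att = 0
    kept = np.empty((kept_per, n_walkers, nel, 3))
    k = 0
    total_sweeps = burn_in + kept_per * stride
    for sweep in range(total_sweeps):
        for e in range(nel):
            prop = x.copy()
            prop[:, e, :] += rng.normal(scale=step_size, size=(n_walkers, 3))
            logp_new = wf.log_density(prop)
            # -inf (zero density) is a legal rejection; +inf or nan means the
            # density grows without bound and cannot be normalized
            if np.any(np.isposinf(logp_new)) or np.any(np.isnan(logp_new)):
                raise RuntimeError(
                    "sampler diverged: density appears non-normalizable")
            accept = np.log(rng.uniform(size=n_walkers)) < (logp_new - logp)
            x[accept] = prop[accept]
            logp[accept] = logp_new[accept]
            n_acc += int(accept.sum())
            n_att += n_walkers
        if sweep >= burn_in and (sweep - burn_in) % stride == 0:
            kept[k] = x
            k += 1
    if np.max(np.abs(kept)) > 1e6 or not np.all(np.isfinite(kept)):
        raise RuntimeError("sampler diverged: density appears non-normalizable")
    snaps = kept.reshape(kept_per * n_walkers, nel, 3)[:n]
    return ConfigurationSample(snapshots=snaps, seed=int(seed), n_kept=int(n),
                               acceptance_rate=n_acc / n_att,
                               decorrelation_stride=int(stride))


# ---------------------------------------------------------------------------
# escape fraction and the damping parameter b
# ---------------------------------------------------------------------------

def escape_fraction(wf: ModelWavefunction, centers, radius: float, *,
                    n_theta: int = 64, n_phi: int = 128) -> float:
    """Expected number of electrons outside the union of equal spheres.

    Spheres of common `radius` sit on `centers`.  For each electron the
    angular integral is a Gauss-Legendre x uniform product grid over
    directions from the electron's own center, with the radial mass inside
    the union accumulated from the closed-form radial CDF over the exact
    ray/union intersection intervals.
    """
    if wf.marginals is None:
        raise ValueError("escape_fraction requires analytic marginals")
    centers = [np.asarray(c, float) for c in centers]
    radii = [float(radius)] * len(centers)
    total = 0.0
    for m in wf.marginals:
        concentric = all(np.allclose(c, m.center) for c in centers)
        if concentric:
            inside = float(m.radial_cdf(radius))
        else:
            t_max = m.cutoff_radius()
            dirs, w = angular_grid(n_theta, n_phi)
            inside = 0.0
            for d, wd in zip(dirs, w):
                mass = 0.0
                for t0, t1 in ray_union_intervals(m.center, d, centers, radii, t_max):
                    mass += float(m.radial_cdf(t1) - m.radial_cdf(t0))
                inside += wd / (4.0 * math.pi) * mass
        total += 1.0 - inside
    return total


def _pairwise_overlap_reduction(centers, radius: float) -> float:
    """Sum over pairs of (lens volume / sphere volume) for equal spheres."""
    red = 0.0
    vol = 4.0 / 3.0 * math.pi * radius**3
    for i in range(len(centers)):
        for j in range(i + 1, len(centers)):
            d = float(np.linalg.norm(np.asarray(centers[i]) - np.asarray(centers[j])))
            if d < 2.0 * radius:
                lens = math.pi * (4.0 * radius + d) * (2.0 * radius - d) ** 2 / 12.0
                red += lens / vol
    return red


def effective_sphere_count(centers, radius: float) -> float:
    n = len(centers)
    return n - min(float(n - 1), _pairwise_overlap_reduction(centers, radius))


def escape_radius(wf: ModelWavefunction, heavy_centers, *,
                  target_per_sphere: float = 0.5, tol: float = 1e-6,
                  n_theta: int = 64, n_phi: int = 128):
    """Common sphere radius R at which the escaping-electron count equals
    target_per_sphere x effective sphere count.  Returns (R, fraction)."""
    if len(heavy_centers) == 0:
        raise ValueError("at least one heavy center is required")
    centers = [np.asarray(c.position if isinstance(c, Atom) else c, float)
               for c in heavy_centers]

    def g(R):
        return (escape_fraction(wf, centers, R, n_theta=n_theta, n_phi=n_phi)
                - target_per_sphere * effective_sphere_count(centers, R))

    r_lo, r_hi = 1e-4, 1.0
    g_lo = g(r_lo)
    if g_lo <= 0:
        raise ValueError("density too concentrated: escape target unreachable")
    while g(r_hi) > 0:
        r_hi *= 2.0
        if r_hi > 1e4:
            raise ValueError("density too diffuse: no finite radius reaches the escape target")
    R = brentq(g, r_lo, r_hi, xtol=1e-12, rtol=1e-14)
    frac = escape_fraction(wf, centers, R, n_theta=n_theta, n_phi=n_phi)
    target = target_per_sphere * effective_sphere_count(centers, R)
    if abs(frac - target) > tol:
        raise RuntimeError("escape-fraction root did not converge to tolerance")
    return float(R), float(frac)


DEFAULT_RADIUS_TO_B = 3.3


def estimate_b(wf: ModelWavefunction, heavy_centers, *,
               radius_to_b: Callable[[float], float] | None = None,
               target_per_sphere: float = 0.5, tol: float = 1e-6,
               n_theta: int = 64, n_phi: int = 128) -> float:
    """Damping parameter b (1/bohr) from the escape-fraction radius.

    The common radius R of equal spheres on the heavy centers is fixed so
    that `target_per_sphere` electrons per (overlap-reduced) sphere escape
    the union; b is then obtained through a monotone empirical map, by
    default b = 3.3/R, overridable via `radius_to_b`.  The tabulated b
    values shipped with the package may be used directly instead.
    """
    R, _ = escape_radius(wf, heavy_centers, target_per_sphere=target_per_sphere,
                         tol=tol, n_theta=n_theta, n_phi=n_phi)
    if radius_to_b is None:
        return DEFAULT_RADIUS_TO_B / R
    return float(radius_to_b(R))


# ---------------------------------------------------------------------------
# geometry I/O
# ---------------------------------------------------------------------------

def read_xyz(path) -> list[Atom]:
    """Read an XYZ geometry; positions are returned in bohr.

    The comment line may carry a unit tag ("unit=bohr" / "unit=angstrom" or
    the bare words); the default is angstrom, converted on input.
    """
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    if not lines:
        raise ValueError("empty XYZ file")
    try:
        count = int(lines[0].split()[0])
    except (ValueError, IndexError):
        raise ValueError("first XYZ line must be the atom count") from None
    comment = lines[1].lower() if len(lines) > 1 else ""
    in_bohr = ("bohr" in comment) or ("unit=au" in comment)
    atoms = []
    for ln in lines[2:2 + count]:
        parts = ln.split()
        if len(parts) < 4:
            raise ValueError(f"malformed XYZ atom line: {ln!r}")
        el = parts[0]
        pos = np.array([float(p) for p in parts[1:4]])
        if not in_bohr:
            pos = pos / BOHR_TO_ANGSTROM
        atoms.append(atom(el, pos))
    if len(atoms) != count:
        raise ValueError("XYZ atom count does not match the header")
    return atoms
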