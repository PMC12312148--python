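"""Composite small-angle scattering model for coexisting lipid phases.

The measured intensity of a fusogenic-liposome dispersion is modelled as a
linear superposition of three structural populations plus a flat incoherent
background::

    I(q) = scale_bcc * I_bcc(q) + scale_ves * I_ves(q)
         + scale_lam * I_lam(q) + I_B

* ``I_bcc`` — small vesicles arranged on a body-centred-cubic paracrystal
  (sphere form factor times an orientation-averaged BCC lattice factor with
  Gaussian positional disorder, quantified by the distortion factor
  g = Δa / d_nn).
* ``I_ves`` — large unilamellar vesicles (thin core–shell sphere).
* ``I_lam`` — stacks of bilayers (flat-sheet form factor times a
  one-dimensional paracrystalline stack interference function).

The scale factors are free amplitudes, not normalised volume fractions; each
one is proportional to the volume fraction of its phase, which is what the
temperature-dependent analysis compares.

All lengths are in Å, momentum transfer q in Å⁻¹, scattering length
densities in Å⁻².
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from numpy.polynomial.legendre import leggauss

__all__ = [
    "ScatteringCurve",
    "BCCParams",
    "VesicleParams",
    "LamellarParams",
    "CompositeParams",
    "FitResult",
    "sphere_form_factor",
    "bcc_lattice_factor",
    "bcc_intensity",
    "vesicle_intensity",
    "bilayer_form",
    "stack_interference",
    "lamellar_intensity",
    "composite_intensity",
    "smear_gaussian",
    "fit_composite",
    "bragg_peaks",
    "SLD_D2O",
    "SLD_LIPID",
]

#: Scattering length density of D2O, held fixed during fitting (Å⁻²).
SLD_D2O = 6.36e-6
#: Scattering length density of the phospholipid, held fixed during fitting (Å⁻²).
SLD_LIPID = 1.0e-6


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ScatteringCurve:
    """A 1D scattering curve: q grid with intensities and optional 1σ errors."""

    q: np.ndarray
    intensity: np.ndarray
    sigma: np.ndarray | None = None

    def __post_init__(self) -> None:
        q = np.asarray(self.q, dtype=float)
        i = np.asarray(self.intensity, dtype=float)
        object.__setattr__(self, "q", q)
        object.__setattr__(self, "intensity", i)
        if q.ndim != 1 or i.shape != q.shape:
            raise ValueError("q and intensity must be 1D arrays of equal length")
        if q.size == 0:
            raise ValueError("empty curve")
        if np.any(q <= 0):
            raise ValueError("q must be positive")
        if np.any(np.diff(q) <= 0):
            raise ValueError("q must be strictly increasing")
        if self.sigma is not None:
            s = np.asarray(self.sigma, dtype=float)
            object.__setattr__(self, "sigma", s)
            if s.shape != q.shape:
                raise ValueError("sigma must match q in length")
            if np.any(s <= 0):
                raise ValueError("sigma must be positive where present")

    def __len__(self) -> int:
        return self.q.size


@dataclass(frozen=True)
class BCCParams:
    """BCC paracrystal of small vesicles.

    ``distortion_g`` is the Gaussian displacement of a lattice point divided
    by the nearest-neighbour distance d_nn = (√3/2)·a.
    """

    scale_bcc: float = 1.0
    sphere_radius: float = 125.0
    lattice_constant_a: float = 519.6
    distortion_g: float = 0.1
    sld_particle: float = SLD_LIPID
    sld_solvent: float = SLD_D2O

    def __post_init__(self) -> None:
        if self.sphere_radius <= 0 or self.lattice_constant_a <= 0:
            raise ValueError("lengths must be positive")
        if self.distortion_g < 0:
            raise ValueError("distortion_g must be >= 0")
        if self.scale_bcc < 0:
            raise ValueError("scale_bcc must be >= 0")

    @property
    def d_nn(self) -> float:
        """Nearest-neighbour distance of the BCC lattice (Å)."""
        return (np.sqrt(3.0) / 2.0) * self.lattice_constant_a


@dataclass(frozen=True)
class VesicleParams:
    """Large unilamellar vesicle (thin-shell core–shell sphere)."""

    scale_ves: float = 1.0
    volume_fraction_phi: float = 0.01
    r_core: float = 4960.0
    shell_thickness: float = 40.0
    sld_shell: float = SLD_LIPID
    sld_solvent: float = SLD_D2O

    def __post_init__(self) -> None:
        if self.r_core <= 0 or self.shell_thickness <= 0:
            raise ValueError("r_core and shell_thickness must be positive")
        if not 0.0 <= self.volume_fraction_phi <= 1.0:
            raise ValueError("volume_fraction_phi must lie in [0, 1]")

    @property
    def r_total(self) -> float:
        return self.r_core + self.shell_thickness


@dataclass(frozen=True)
class LamellarParams:
    """Paracrystalline stack of bilayers.

    ``n_layers_N`` may be non-integer: a value between ⌊N⌋ and ⌊N⌋+1 mixes
    stacks of the two integer sizes with weight x_N = 1 − frac(N) on ⌊N⌋.
    The 2πΔρ²Γ_m prefactor of the sheet intensity is absorbed into
    ``scale_lam``.
    """

    scale_lam: float = 1.0
    bilayer_thickness_t: float = 30.0
    n_layers_N: float = 4.0
    spacing_D: float = 250.0
    sigma_D: float = 25.0

    def __post_init__(self) -> None:
        if self.bilayer_thickness_t <= 0:
            raise ValueError("bilayer thickness must be positive")
        if self.spacing_D <= self.bilayer_thickness_t:
            raise ValueError("layer spacing must exceed bilayer thickness")
        if self.n_layers_N < 1:
            raise ValueError("mean stack size must be >= 1")
        if self.sigma_D < 0:
            raise ValueError("sigma_D must be >= 0")


@dataclass(frozen=True)
class CompositeParams:
    """All parameters of the three-population superposition."""

    bcc: BCCParams = field(default_factory=BCCParams)
    vesicle: VesicleParams = field(default_factory=VesicleParams)
    lamellar: LamellarParams = field(default_factory=LamellarParams)
    background_IB: float = 0.0

    def __post_init__(self) -> None:
        if self.background_IB < 0:
            raise ValueError("background must be >= 0")


@dataclass(frozen=True)
class FitResult:
    params: CompositeParams
    chi2_reduced: float
    param_uncertainties: Mapping[str, float]
    converged: bool
    n_iterations: int


# ---------------------------------------------------------------------------
# form and structure factors
# ---------------------------------------------------------------------------


def _sphere_amp(x: np.ndarray) -> np.ndarray:
    """3 j1(x)/x with j1(x) = (sin x − x cos x)/x², continuous limit 1 at x=0."""
    x = np.asarray(x, dtype=float)
    out = np.ones_like(x)
    nz = np.abs(x) > 0.02
    xs = x[nz]
    out[nz] = 3.0 * (np.sin(xs) - xs * np.cos(xs)) / xs**3
    # series avoids the sin/cos cancellation at small x (error ~ x^6/15120)
    sm = ~nz
    xs2 = x[sm] ** 2
    out[sm] = 1.0 - xs2 / 10.0 + xs2**2 / 280.0
    return out


def sphere_form_factor(q: np.ndarray | float, radius: float) -> np.ndarray:
    """Normalized sphere form factor P(q) = [3 j1(qR)/(qR)]², P(0) = 1."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    q = np.atleast_1d(np.asarray(q, dtype=float))
    return _sphere_amp(q * radius) ** 2


def _bcc_primitive_vectors(a: float) -> np.ndarray:
    """Primitive vectors of the BCC lattice, rows (3, 3)."""
    h = a / 2.0
    return np.array(
        [[-h, h, h], [h, -h, h], [h, h, -h]], dtype=float
    )


def _hemisphere_nodes(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Quadrature nodes over one orientation hemisphere.

    Gauss–Legendre in u = cosθ ∈ [0, 1] (n nodes) crossed with a uniform
    periodic grid in φ ∈ [0, 2π) (4n nodes). Returns unit vectors (M, 3)
    and normalized weights (M,). The hemisphere suffices because the
    triple-product lattice factor is inversion symmetric (cosine is even);
    it is NOT symmetric under single axis flips, so no smaller wedge is
    valid.
    """
    xu, wu = leggauss(n)
    u = 0.5 * (xu + 1.0)
    wu = 0.5 * wu
    m = 4 * n
    phi = np.arange(m) * (2.0 * np.pi / m)
    wp = np.full(m, 1.0 / m)
    st = np.sqrt(1.0 - u**2)
    qhat = np.stack(
        [
            np.outer(st, np.cos(phi)).ravel(),
            np.outer(st, np.sin(phi)).ravel(),
            np.repeat(u, phi.size),
        ],
        axis=1,
    )
    return qhat, np.outer(wu, wp).ravel()


def _z_orient_avg(
    q: np.ndarray, qhat: np.ndarray, wgt: np.ndarray, avec: np.ndarray, f: np.ndarray
) -> np.ndarray:
    """Weighted orientation average of the triple-product lattice factor."""
    f2 = f**2
    proj = qhat @ avec.T  # (M, 3)
    z = np.zeros_like(q)
    chunk = max(1, int(4e6 // max(q.size, 1)))
    for lo in range(0, proj.shape[0], chunk):
        p = proj[lo : lo + chunk]
        w = wgt[lo : lo + chunk]
        zk = np.ones((p.shape[0], q.size))
        for k in range(3):
            c = np.cos(p[:, k : k + 1] * q[None, :])
            zk *= (1.0 - f2[None, :]) / (1.0 - 2.0 * f[None, :] * c + f2[None, :])
        z += w @ zk
    return z


#: Hard ceiling on the per-q adaptive node count (cost grows quadratically).
MAX_ORIENT_NODES = 1200

# memo of recent lattice-factor evaluations (pure function of its arguments);
# repeated forward evaluations at identical shape parameters are common in
# fits and replicate studies
_Z_MEMO: dict = {}
_Z_MEMO_MAX = 64


def _z_memo_put(key, value):
    if len(_Z_MEMO) >= _Z_MEMO_MAX:
        _Z_MEMO.clear()
    _Z_MEMO[key] = value


def bcc_lattice_factor(
    q: np.ndarray | float,
    lattice_constant_a: float,
    distortion_g: float,
    n_orient: int = 150,
    adaptive: bool = True,
) -> np.ndarray:
    """Powder-averaged paracrystalline structure factor Z(q) for a BCC lattice.

    For a single orientation q̂ the lattice factor is a product over the
    three primitive directions::

        Z(q⃗) = ∏_k (1 − |F_k|²) / (1 − 2|F_k| cos(a⃗_k·q⃗) + |F_k|²)
        |F_k| = exp(−Δa² q² / 2),   Δa = g · d_nn,   d_nn = (√3/2) a

    The powder average is taken over one hemisphere of orientations
    (sufficient by inversion symmetry): Gauss–Legendre quadrature with
    ``n_orient`` nodes in cosθ crossed with a uniform periodic grid of
    4·``n_orient`` nodes in φ.

    At small q·Δa the orientation integrand develops near-singular ridges
    (the crystal is almost perfect), so with ``adaptive`` on, the node count
    for such q points is raised proportionally to the inverse ridge width,
    up to :data:`MAX_ORIENT_NODES` per axis. Below that floor the extreme
    low-q / low-g corner remains approximate.

    Parameters
    ----------
    n_orient:
        Base quadrature nodes in cosθ (4·n_orient² orientations in total).
        Must be at least 8.
    adaptive:
        Boost the node count where the ridge-width estimate demands it.
    """
    if distortion_g < 0:
        raise ValueError("distortion_g must be >= 0")
    if lattice_constant_a <= 0:
        raise ValueError("lattice constant must be positive")
    if n_orient < 8:
        raise ValueError("n_orient must be at least 8")

    q = np.atleast_1d(np.asarray(q, dtype=float))
    if np.any(q <= 0):
        raise ValueError("q must be positive")

    key = (q.tobytes(), lattice_constant_a, distortion_g, n_orient, adaptive)
    hit = _Z_MEMO.get(key)
    if hit is not None:
        return hit.copy()

    avec = _bcc_primitive_vectors(lattice_constant_a)
    d_nn = (np.sqrt(3.0) / 2.0) * lattice_constant_a
    delta_a = distortion_g * d_nn
    f = np.exp(-0.5 * delta_a**2 * q**2)

    if not adaptive:
        qhat, wgt = _octant_nodes(n_orient)
        z = _z_orient_avg(q, qhat, wgt, avec, f)
        _z_memo_put(key, z)
        return z.copy()

    # required nodes ~ ridge slope q|a_k| over ridge width (1 - f)
    a_len = np.linalg.norm(avec[0])
    with np.errstate(divide="ignore"):
        n_req = 2.5 * (np.pi / 2.0) * q * a_len / np.maximum(1.0 - f, 1e-300)
    n_req = np.clip(np.ceil(n_req), n_orient, MAX_ORIENT_NODES).astype(int)
    # bucket q points by node count rounded up to the next power of two
    buckets = np.minimum(
        2 ** np.ceil(np.log2(np.maximum(n_req, 1))).astype(int), MAX_ORIENT_NODES
    )
    buckets = np.maximum(buckets, n_orient)
    z = np.empty_like(q)
    for n in np.unique(buckets):
        sel = buckets == n
        qhat, wgt = _hemisphere_nodes(int(n))
        z[sel] = _z_orient_avg(q[sel], qhat, wgt, avec, f[sel])
    _z_memo_put(key, z)
    return z.copy()


def bcc_intensity(q: np.ndarray | float, p: BCCParams, n_orient: int = 150) -> np.ndarray:
    """Scattered intensity of the BCC paracrystal of small vesicles.

    ``scale_bcc`` absorbs the V_lattice/V_p amplitude of the crystal; the
    remaining factors are the particle volume, contrast, sphere form factor
    and the powder-averaged lattice factor.
    """
    q = np.atleast_1d(np.asarray(q, dtype=float))
    if p.scale_bcc == 0.0:
        return np.zeros_like(q)
    v_p = (4.0 / 3.0) * np.pi * p.sphere_radius**3
    contrast2 = (p.sld_particle - p.sld_solvent) ** 2
    pq = sphere_form_factor(q, p.sphere_radius)
    zq = bcc_lattice_factor(q, p.lattice_constant_a, p.distortion_g, n_orient=n_orient)
    return p.scale_bcc * contrast2 * v_p * pq * zq


def vesicle_intensity(q: np.ndarray | float, p: VesicleParams) -> np.ndarray:
    """Core–shell (thin solvent-filled shell) vesicle intensity.

    I(q) = scale · (ϕ / V_shell) · A(q)² with the two-term amplitude

        A(q) = V_core (ρ_solv − ρ_shell) · 3 j1(q R_core)/(q R_core)
             + V_total (ρ_shell − ρ_solv) · 3 j1(q R_total)/(q R_total)

    so that I(0) = scale · ϕ · V_shell · Δρ².
    """
    q = np.atleast_1d(np.asarray(q, dtype=float))
    r_core = p.r_core
    r_tot = p.r_total
    v_core = (4.0 / 3.0) * np.pi * r_core**3
    v_tot = (4.0 / 3.0) * np.pi * r_tot**3
    v_shell = v_tot - v_core
    drho = p.sld_shell - p.sld_solvent
    amp = (-drho) * v_core * _sphere_amp(q * r_core) + drho * v_tot * _sphere_amp(
        q * r_tot
    )
    return p.scale_ves * (p.volume_fraction_phi / v_shell) * amp**2


def bilayer_form(q: np.ndarray | float, thickness_t: float) -> np.ndarray:
    """Flat-sheet bilayer form factor (sin(qt)/(qt))², value 1 at q = 0."""
    if thickness_t <= 0:
        raise ValueError("thickness must be positive")
    q = np.atleast_1d(np.asarray(q, dtype=float))
    x = q * thickness_t
    return np.sinc(x / np.pi) ** 2


def _stack_zn_integer(q: np.ndarray, n: int, spacing_d: float, w: np.ndarray) -> np.ndarray:
    """Closed-form paracrystalline stack factor for an integer stack size."""
    qd = q * spacing_d
    cos_qd = np.cos(qd)
    denom = 1.0 + w**2 - 2.0 * w * cos_qd
    a_n = (
        4.0 * w**2
        - 2.0 * (w**3 + w) * cos_qd
        - 4.0 * w ** (n + 2) * np.cos(n * qd)
        + 2.0 * w ** (n + 3) * np.cos((n - 1) * qd)
        + 2.0 * w ** (n + 1) * np.cos((n + 1) * qd)
    )
    out = np.empty_like(q)
    ok = denom > 1e-12
    out[ok] = (1.0 - w[ok] ** 2) / denom[ok] + a_n[ok] / (n * denom[ok] ** 2)
    if not ok.all():
        # perfectly correlated layers at a Bragg point: evaluate the
        # underlying lattice sum directly
        bad = ~ok
        s = np.ones(bad.sum())
        for m in range(1, n):
            s += (2.0 * (n - m) / n) * w[bad] ** m * np.cos(m * q[bad] * spacing_d)
        out[bad] = s
    return out


def stack_interference(
    q: np.ndarray | float, N: float, spacing_D: float, sigma_D: float
) -> np.ndarray:
    """Interference function Z_N(q) of a paracrystalline bilayer stack.

    Layers sit at an average spacing D with Gaussian spread σ_D
    (w = exp(−σ_D² q² / 2)). Non-integer mean stack sizes mix the two
    neighbouring integer sizes with weight x_N = 1 − frac(N) on ⌊N⌋.
    """
    if N < 1:
        raise ValueError("stack size N must be >= 1")
    if spacing_D <= 0:
        raise ValueError("spacing must be positive")
    if sigma_D < 0:
        raise ValueError("sigma_D must be >= 0")
    q = np.atleast_1d(np.asarray(q, dtype=float))
    w = np.exp(-0.5 * sigma_D**2 * q**2)
    n_lo = int(np.floor(N))
    x_n = 1.0 - (N - n_lo)
    z = x_n * _stack_zn_integer(q, n_lo, spacing_D, w)
    if x_n < 1.0:
        z = z + (1.0 - x_n) * _stack_zn_integer(q, n_lo + 1, spacing_D, w)
    return z


def lamellar_intensity(q: np.ndarray | float, p: LamellarParams) -> np.ndarray:
    """Bilayer-stack intensity scale · P_bil(q) · Z_N(q) / q² (q > 0 only)."""
    q = np.atleast_1d(np.asarray(q, dtype=float))
    if np.any(q <= 0):
        raise ValueError("lamellar intensity diverges at q = 0; q must be positive")
    pq = bilayer_form(q, p.bilayer_thickness_t)
    zq = stack_interference(q, p.n_layers_N, p.spacing_D, p.sigma_D)
    return p.scale_lam * pq * zq / q**2


def composite_intensity(
    q: np.ndarray | float, p: CompositeParams, n_orient: int = 150
) -> np.ndarray:
    """Total model intensity: BCC + vesicle + lamellar terms plus background."""
    q = np.atleast_1d(np.asarray(q, dtype=float))
    return (
        bcc_intensity(q, p.bcc, n_orient=n_orient)
        + vesicle_intensity(q, p.vesicle)
        + lamellar_intensity(q, p.lamellar)
        + p.background_IB
    )


def smear_gaussian(
    q: np.ndarray, intensity: np.ndarray, dq_over_q: float = 0.10
) -> np.ndarray:
    """Optional Gaussian resolution smearing with relative width dq/q.

    Off by default everywhere; provided for instruments with a broad
    wavelength band. Each smeared point is a Gaussian-weighted average of
    the unsmeared curve with σ = dq_over_q · q.
    """
    q = np.asarray(q, dtype=float)
    intensity = np.asarray(intensity, dtype=float)
    if dq_over_q <= 0:
        return intensity.copy()
    out = np.empty_like(intensity)
    for i, (qi, s) in enumerate(zip(q, dq_over_q * q)):
        wgt = np.exp(-0.5 * ((q - qi) / s) ** 2)
        out[i] = np.sum(wgt * intensity) / np.sum(wgt)
    return out


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

#: Flat parameter names used by the fitter and the CLI config.
PARAM_NAMES: tuple[str, ...] = (
    "bcc_scale",
    "bcc_sphere_radius",
    "bcc_lattice_a",
    "bcc_distortion_g",
    "bcc_sld_particle",
    "bcc_sld_solvent",
    "ves_scale",
    "ves_phi",
    "ves_r_core",
    "ves_thickness",
    "ves_sld_shell",
    "ves_sld_solvent",
    "lam_scale",
    "lam_thickness",
    "lam_n_layers",
    "lam_spacing",
    "lam_sigma_d",
    "background",
)

#: SLDs are held fixed during fitting by default.
DEFAULT_FROZEN: frozenset[str] = frozenset(
    {"bcc_sld_particle", "bcc_sld_solvent", "ves_sld_shell", "ves_sld_solvent"}
)

_LENGTH_PARAMS = {
    "bcc_sphere_radius",
    "bcc_lattice_a",
    "ves_r_core",
    "ves_thickness",
    "lam_thickness",
    "lam_spacing",
    "lam_sigma_d",
}


def params_to_flat(p: CompositeParams) -> dict[str, float]:
    return {
        "bcc_scale": p.bcc.scale_bcc,
        "bcc_sphere_radius": p.bcc.sphere_radius,
        "bcc_lattice_a": p.bcc.lattice_constant_a,
        "bcc_distortion_g": p.bcc.distortion_g,
        "bcc_sld_particle": p.bcc.sld_particle,
        "bcc_sld_solvent": p.bcc.sld_solvent,
        "ves_scale": p.vesicle.scale_ves,
        "ves_phi": p.vesicle.volume_fraction_phi,
        "ves_r_core": p.vesicle.r_core,
        "ves_thickness": p.vesicle.shell_thickness,
        "ves_sld_shell": p.vesicle.sld_shell,
        "ves_sld_solvent": p.vesicle.sld_solvent,
        "lam_scale": p.lamellar.scale_lam,
        "lam_thickness": p.lamellar.bilayer_thickness_t,
        "lam_n_layers": p.lamellar.n_layers_N,
        "lam_spacing": p.lamellar.spacing_D,
        "lam_sigma_d": p.lamellar.sigma_D,
        "background": p.background_IB,
    }


def flat_to_params(v: Mapping[str, float]) -> CompositeParams:
    return CompositeParams(
        bcc=BCCParams(
            scale_bcc=v["bcc_scale"],
            sphere_radius=v["bcc_sphere_radius"],
            lattice_constant_a=v["bcc_lattice_a"],
            distortion_g=v["bcc_distortion_g"],
            sld_particle=v["bcc_sld_particle"],
            sld_solvent=v["bcc_sld_solvent"],
        ),
        vesicle=VesicleParams(
            scale_ves=v["ves_scale"],
            volume_fraction_phi=v["ves_phi"],
            r_core=v["ves_r_core"],
            shell_thickness=v["ves_thickness"],
            sld_shell=v["ves_sld_shell"],
            sld_solvent=v["ves_sld_solvent"],
        ),
        lamellar=LamellarParams(
            scale_lam=v["lam_scale"],
            bilayer_thickness_t=v["lam_thickness"],
            n_layers_N=v["lam_n_layers"],
            spacing_D=v["lam_spacing"],
            sigma_D=v["lam_sigma_d"],
        ),
        background_IB=v["background"],
    )


def table_start_params() -> CompositeParams:
    """Default starting point for fits and the synthetic generator.

    Geometry: bilayer 30 Å, BCC vesicle diameter 250 Å, nearest-neighbour
    distance 450 Å (a = 2·450/√3), large-vesicle radius 5000 Å, SLDs fixed
    at the D2O / phospholipid values. The amplitudes are set so each
    population dominates part of the measurement window, the way measured
    composite curves look: ``scale_lam`` absorbs the physical 2πΔρ²Γ_m
    prefactor (~5e-9 for lipid contrast in D2O with Γ_m ≈ 30 Å) and the
    large-vesicle amplitude produces the characteristic low-q shoulder.
    """
    return CompositeParams(
        bcc=BCCParams(
            scale_bcc=1.0,
            sphere_radius=125.0,
            lattice_constant_a=2.0 * 450.0 / np.sqrt(3.0),
            distortion_g=0.1,
        ),
        vesicle=VesicleParams(
            scale_ves=20.0,
            volume_fraction_phi=0.01,
            r_core=5000.0 - 40.0,
            shell_thickness=40.0,
        ),
        lamellar=LamellarParams(
            scale_lam=5e-9,
            bilayer_thickness_t=30.0,
            n_layers_N=4.0,
            spacing_D=250.0,
            sigma_D=25.0,
        ),
        background_IB=1e-6,
    )


class _ComponentCache:
    """Memoize the three component curves over the fit's fixed q grid.

    During a fit where a component's parameters are frozen the component
    curve never changes; recomputing the orientation-averaged BCC lattice
    factor on every residual call would dominate the cost.
    """

    def __init__(self, q: np.ndarray, n_orient: int) -> None:
        self.q = q
        self.n_orient = n_orient
        self._store: dict[tuple, np.ndarray] = {}

    def component(self, name: str, key: tuple, compute) -> np.ndarray:
        full_key = (name,) + key
        if full_key not in self._store:
            if len(self._store) > 256:
                self._store.clear()
            self._store[full_key] = compute()
        return self._store[full_key]


def _model_intensity(
    q: np.ndarray, v: Mapping[str, float], cache: _ComponentCache
) -> np.ndarray:
    p = flat_to_params(v)
    b = p.bcc
    bcc_shape = cache.component(
        "bcc",
        (b.sphere_radius, b.lattice_constant_a, b.distortion_g, b.sld_particle, b.sld_solvent),
        lambda: bcc_intensity(q, replace(b, scale_bcc=1.0), n_orient=cache.n_orient),
    )
    ves = p.vesicle
    ves_shape = cache.component(
        "ves",
        (ves.volume_fraction_phi, ves.r_core, ves.shell_thickness, ves.sld_shell, ves.sld_solvent),
        lambda: vesicle_intensity(q, replace(ves, scale_ves=1.0)),
    )
    lam = p.lamellar
    lam_shape = cache.component(
        "lam",
        (lam.bilayer_thickness_t, lam.n_layers_N, lam.spacing_D, lam.sigma_D),
        lambda: lamellar_intensity(q, replace(lam, scale_lam=1.0)),
    )
    return (
        b.scale_bcc * bcc_shape
        + ves.scale_ves * ves_shape
        + lam.scale_lam * lam_shape
        + p.background_IB
    )


def fit_composite(
    curve: ScatteringCurve,
    start: CompositeParams | None = None,
    frozen: Iterable[str] = DEFAULT_FROZEN,
    n_orient: int = 48,
    max_nfev: int = 2000,
) -> FitResult:
    """Weighted least-squares fit of the composite model to a curve.

    Parameters named in ``frozen`` (see :data:`PARAM_NAMES`) are held at
    their start values; SLDs are frozen by default. Lengths are bounded to
    [0.1×, 10×] of their start, amplitudes to [0, ∞). Weights are 1/σ where
    the curve carries uncertainties, else unit.

    Non-convergence is reported via ``FitResult.converged``, not raised.
    """
    import lmfit

    if len(curve) < 10:
        raise ValueError("curve must have at least 10 points")
    if np.all(curve.intensity == 0):
        raise ValueError("degenerate all-zero curve")
    frozen = set(frozen)
    unknown = frozen - set(PARAM_NAMES)
    if unknown:
        raise ValueError(f"unknown parameter names in frozen set: {sorted(unknown)}")

    start = start if start is not None else table_start_params()
    v0 = params_to_flat(start)

    pars = lmfit.Parameters()
    for name in PARAM_NAMES:
        val = v0[name]
        vary = name not in frozen
        lo, hi = 0.0, np.inf
        if name in _LENGTH_PARAMS and val > 0:
            lo, hi = 0.1 * val, 10.0 * val
        elif name == "bcc_distortion_g":
            lo, hi = 0.0, 1.0
        elif name == "ves_phi":
            lo, hi = 0.0, 1.0
        elif name == "lam_n_layers":
            lo, hi = 1.0, 100.0
        elif name.startswith(("bcc_sld", "ves_sld")):
            lo, hi = -np.inf, np.inf
        pars.add(name, value=val, vary=vary, min=lo, max=hi)

    q = curve.q
    weights = 1.0 / curve.sigma if curve.sigma is not None else np.ones_like(q)
    cache = _ComponentCache(q, n_orient)

    def residual(p: "lmfit.Parameters") -> np.ndarray:
        v = {n: p[n].value for n in PARAM_NAMES}
        return (_model_intensity(q, v, cache) - curve.intensity) * weights

    n_free = sum(1 for n in PARAM_NAMES if n not in frozen)
    if n_free == 0:
        r = residual(pars)
        chi2 = float(np.sum(r**2)) / max(len(curve) - 1, 1)
        return FitResult(start, chi2, {}, True, 0)

    minimizer = lmfit.Minimizer(residual, pars)
    out = minimizer.least_squares(max_nfev=max_nfev)
    vbest = {n: out.params[n].value for n in PARAM_NAMES}
    r = residual(out.params)
    dof = max(len(curve) - n_free, 1)
    chi2 = float(np.sum(r**2)) / dof
    unc = {
        n: float(out.params[n].stderr)
        for n in PARAM_NAMES
        if out.params[n].vary and out.params[n].stderr is not None
    }
    return FitResult(
        params=flat_to_params(vbest),
        chi2_reduced=chi2,
        param_uncertainties=unc,
        converged=bool(out.success),
        n_iterations=int(out.nfev),
    )


# ---------------------------------------------------------------------------
# Bragg reflections
# ---------------------------------------------------------------------------


def bragg_peaks(
    lattice_constant_a: float, q_max: float = 0.221
) -> list[tuple[tuple[int, int, int], float]]:
    """Allowed BCC Bragg reflections up to q_max.

    q_hkl = (2π/a)·√(h²+k²+l²) for h+k+l even (the BCC selection rule),
    deduplicated by multiplicity, sorted ascending in q. Each entry is
    ((h, k, l), q) with h ≥ k ≥ l ≥ 0 as the representative index.
    """
    if lattice_constant_a <= 0:
        raise ValueError("lattice constant must be positive")
    smax = int(np.ceil((q_max * lattice_constant_a / (2.0 * np.pi)) ** 2))
    seen: dict[int, tuple[int, int, int]] = {}
    hmax = int(np.ceil(np.sqrt(smax)))
    for h in range(hmax + 1):
        for k in range(h + 1):
            for l in range(k + 1):
                s = h * h + k * k + l * l
                if s == 0 or s > smax or (h + k + l) % 2 != 0:
                    continue
                if s not in seen:
                    seen[s] = (h, k, l)
    out = []
    for s in sorted(seen):
        qv = (2.0 * np.pi / lattice_constant_a) * np.sqrt(s)
        if qv <= q_max:
            out.append((seen[s], qv))
    return out
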