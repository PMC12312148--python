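"""Static 31P powder lineshapes for lipid phases and mixture decomposition.

The 31P chemical shift of a phospholipid headgroup in a fluid phase is
axially averaged; a powder of randomly oriented domains then shows the
classic uniaxial chemical-shift-anisotropy (CSA) pattern. With principal
values δ⊥ and δ∥ the resonance of a domain whose axis makes angle θ with
the field is

    δ(θ) = δ⊥ + (δ∥ − δ⊥) cos²θ,

and the isotropic orientation distribution maps to the singular (but
integrable) frequency density p(δ) ∝ 1 / (2√((δ − δ⊥)(δ∥ − δ⊥))) between
the two edges — peaked at δ⊥, with a shoulder running out to δ∥. Fast
isotropic tumbling (micelles, small vesicles, cubic phases) collapses the
pattern to a single line at the isotropic shift.

Phase signatures implemented, with defaults placed at the landmark
positions of fluid lipid systems:

* lamellar  — δ⊥ = −20 ppm, δ∥ = +45 ppm (peak at −20, shoulder toward +50);
* hexagonal — anisotropy of opposite sign and half magnitude
  (δ⊥ = +5 ppm, δ∥ = −27.5 ppm: peak near +5);
* isotropic — Gaussian at 0 ppm.

Each basis lineshape is area-normalized; a measured spectrum is decomposed
into nonnegative phase weights by nonnegative least squares.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import ndimage, optimize

__all__ = [
    "Spectrum31P",
    "PhaseBasis",
    "LAMELLAR_DEFAULT",
    "HEXAGONAL_DEFAULT",
    "ISOTROPIC_DEFAULT",
    "DEFAULT_BASES",
    "hexagonal_from_lamellar",
    "powder_lineshape",
    "mixture_spectrum",
    "decompose_spectrum",
    "default_grid",
]


@dataclass(frozen=True)
class Spectrum31P:
    """A 31P spectrum on a uniform ppm grid (stored ascending)."""

    ppm: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.ppm, dtype=float)
        i = np.asarray(self.intensity, dtype=float)
        if p.ndim != 1 or i.shape != p.shape:
            raise ValueError("ppm and intensity must be 1D of equal length")
        if p.size < 2:
            raise ValueError("need at least 2 grid points")
        d = np.diff(p)
        if np.all(d < 0):  # accept descending input, store ascending
            p, i = p[::-1], i[::-1]
            d = -d[::-1]
        if np.any(d <= 0):
            raise ValueError("ppm grid must be strictly monotone")
        if not np.allclose(d, d[0], rtol=1e-6):
            raise ValueError("ppm grid must be uniform")
        object.__setattr__(self, "ppm", p)
        object.__setattr__(self, "intensity", i)

    @property
    def dppm(self) -> float:
        return float(self.ppm[1] - self.ppm[0])

    def area(self) -> float:
        return float(np.trapezoid(self.intensity, self.ppm))


@dataclass(frozen=True)
class PhaseBasis:
    """One phase's lineshape parameters.

    For ``kind`` "isotropic", ``delta_perp`` is the line centre and
    ``delta_par`` is ignored. Anisotropic kinds require δ⊥ ≠ δ∥.
    """

    delta_perp: float
    delta_par: float
    broadening_sigma: float = 1.0
    kind: Literal["lamellar", "hexagonal", "isotropic"] = "lamellar"

    def __post_init__(self) -> None:
        if self.broadening_sigma <= 0:
            raise ValueError("broadening_sigma must be positive")
        if self.kind != "isotropic" and self.delta_perp == self.delta_par:
            raise ValueError("anisotropic lineshape needs delta_perp != delta_par")

    @property
    def delta_iso(self) -> float:
        if self.kind == "isotropic":
            return self.delta_perp
        return (2.0 * self.delta_perp + self.delta_par) / 3.0


LAMELLAR_DEFAULT = PhaseBasis(delta_perp=-20.0, delta_par=45.0, kind="lamellar")
HEXAGONAL_DEFAULT = PhaseBasis(delta_perp=5.0, delta_par=-27.5, kind="hexagonal")
ISOTROPIC_DEFAULT = PhaseBasis(delta_perp=0.0, delta_par=0.0, kind="isotropic")
DEFAULT_BASES: tuple[PhaseBasis, ...] = (
    LAMELLAR_DEFAULT,
    HEXAGONAL_DEFAULT,
    ISOTROPIC_DEFAULT,
)


def hexagonal_from_lamellar(lam: PhaseBasis) -> PhaseBasis:
    """Hexagonal-phase basis derived from a lamellar one.

    Fast lateral diffusion around the hexagonal-phase cylinders averages the
    CSA a second time, scaling the apparent anisotropy by −1/2 about the
    same isotropic shift.
    """
    iso = lam.delta_iso
    return PhaseBasis(
        delta_perp=iso - 0.5 * (lam.delta_perp - iso),
        delta_par=iso - 0.5 * (lam.delta_par - iso),
        broadening_sigma=lam.broadening_sigma,
        kind="hexagonal",
    )


def default_grid(ppm_min: float = -120.0, ppm_max: float = 120.0, n: int = 2048) -> np.ndarray:
    return np.linspace(ppm_min, ppm_max, n)


def _edge_cdf(delta: np.ndarray, d_perp: float, d_par: float) -> np.ndarray:
    """CDF of the uniaxial powder density between the two edges.

    With u = (δ − δ⊥)/(δ∥ − δ⊥) ∈ [0, 1] and cosθ uniform on [0, 1],
    P(δ' ≤ δ) = √u toward δ∥ — integrating out the inverse-square-root
    singularity at δ⊥ exactly.
    """
    u = (delta - d_perp) / (d_par - d_perp)
    return np.sqrt(np.clip(u, 0.0, 1.0))


def powder_lineshape(basis: PhaseBasis, grid: np.ndarray) -> Spectrum31P:
    """Unit-area powder lineshape of one phase on a uniform ppm grid.

    Anisotropic kinds integrate the exact orientation density over each
    grid cell (so the δ⊥ singularity is handled analytically) and then
    convolve with a Gaussian of width ``broadening_sigma``. The isotropic
    kind is a pure Gaussian at its centre. The output has unit area.
    """
    grid = np.asarray(grid, dtype=float)
    spec = Spectrum31P(grid, np.zeros_like(grid))
    ppm, dppm = spec.ppm, spec.dppm
    if basis.kind == "isotropic":
        y = np.exp(-0.5 * ((ppm - basis.delta_perp) / basis.broadening_sigma) ** 2)
    else:
        d_perp, d_par = basis.delta_perp, basis.delta_par
        edges = np.concatenate([ppm - dppm / 2.0, [ppm[-1] + dppm / 2.0]])
        cdf = _edge_cdf(edges, d_perp, d_par)
        # |ΔCDF| is the per-cell mass for either sign of the anisotropy
        mass = np.abs(np.diff(cdf))
        y = ndimage.gaussian_filter1d(
            mass / dppm, sigma=basis.broadening_sigma / dppm, mode="constant"
        )
    area = np.trapezoid(y, ppm)
    if area <= 0:
        raise ValueError("lineshape has no support on the supplied grid")
    return Spectrum31P(ppm, y / area)


def mixture_spectrum(
    bases: Sequence[PhaseBasis], weights: Sequence[float], grid: np.ndarray
) -> Spectrum31P:
    """Weighted sum of unit-area lineshapes; total area equals Σ weights."""
    weights = np.asarray(weights, dtype=float)
    if len(bases) != weights.size:
        raise ValueError("one weight per basis required")
    if np.any(weights < 0):
        raise ValueError("weights must be nonnegative")
    grid = np.asarray(grid, dtype=float)
    total = np.zeros_like(grid)
    for b, w in zip(bases, weights):
        if w > 0:
            total = total + w * powder_lineshape(b, grid).intensity
    return Spectrum31P(grid, total)


def decompose_spectrum(
    spec: Spectrum31P, bases: Sequence[PhaseBasis] = DEFAULT_BASES
) -> tuple[np.ndarray, float]:
    """Nonnegative least-squares phase weights of a spectrum.

    Returns ``(weights, relative_residual)`` where weights are on the
    area scale of the input spectrum and the residual is the L2 misfit
    divided by the L2 norm of the input.
    """
    mat = np.stack(
        [powder_lineshape(b, spec.ppm).intensity for b in bases], axis=1
    )
    if np.linalg.matrix_rank(mat) < mat.shape[1]:
        raise ValueError("basis lineshapes are linearly dependent on this grid")
    w, rnorm = optimize.nnls(mat, spec.intensity)
    denom = float(np.linalg.norm(spec.intensity))
    rel = rnorm / denom if denom > 0 else 0.0
    return w, float(rel)
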