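"""HU → density → transversely isotropic elasticity and strength mapping.

The mapping chain is the standard QCT-FE one for vertebral bone:

* apparent density   rho_app = 47 + 1.122 * HU          [mg/cm^3]
* ash density        rho_ash = 0.6 * rho_app            [g/cm^3 after /1000]
* axial modulus      Ez      = -349 + 5.82 * rho_app    [MPa]
* transverse moduli  Ex = Ey = 0.333 * Ez
* shear moduli       Gxy = 0.121 * Ez ; Gxz = Gyz = 0.157 * Ez
* max principal stress limit
      sigma_max = 137 * rho_ash^1.88   (rho_ash <  0.317)
      sigma_max = 114 * rho_ash^1.72   (rho_ash >= 0.317)
* min principal stress limit magnitude  sigma_min = 65.1 * rho_ash^1.93
* plastic strain parameter              eps_AB = -0.00315 + 0.0728 * rho_ash

Units: consistent mm–MPa–N system; rho_app in mg/cm^3 (the affine form only
yields physiological values there), rho_ash in g/cm^3 (the 0.317 branch
threshold and the power laws only make sense there).  The affine forms go
negative for marrow/fat HU, so densities, moduli and eps_AB are clamped
below at small positive floors — the solver needs positive stiffness.

Poisson ratios are not part of the mapping; defaults nu_xy = 0.381,
nu_xz = nu_yz = 0.104 (x→z sense) give a positive-definite tensor over the
whole physiological HU range.  The material z-axis is the global z
(superior–inferior) axis for every element.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "RHO_APP_FLOOR",
    "E_FLOOR",
    "ASH_BRANCH_THRESHOLD",
    "ElementMaterial",
    "MaterialTable",
    "hu_to_apparent_density",
    "apparent_to_ash",
    "density_to_moduli",
    "strength_limits",
    "unit_elasticity_tensor",
    "elasticity_tensor",
    "map_mesh",
    "material_table_frame",
]

RHO_APP_FLOOR = 1.0  # mg/cm^3
E_FLOOR = 0.01  # MPa
ASH_BRANCH_THRESHOLD = 0.317  # g/cm^3

RATIO_EX = 0.333
RATIO_GXY = 0.121
RATIO_GXZ = 0.157

DEFAULT_NU_XY = 0.381
DEFAULT_NU_XZ = 0.104


def hu_to_apparent_density(hu):
    """Apparent density in mg/cm^3, clamped below at ``RHO_APP_FLOOR``."""
    return np.maximum(47.0 + 1.122 * np.asarray(hu, dtype=np.float64), RHO_APP_FLOOR)


def apparent_to_ash(rho_app):
    """Ash density in g/cm^3 from apparent density in mg/cm^3."""
    return 0.6 * np.asarray(rho_app, dtype=np.float64) / 1000.0


def density_to_moduli(rho_app):
    """(Ez, Ex, Ey, Gxy, Gxz, Gyz) in MPa from apparent density in mg/cm^3."""
    ez = np.maximum(-349.0 + 5.82 * np.asarray(rho_app, dtype=np.float64), E_FLOOR)
    ex = RATIO_EX * ez
    return ez, ex, ex, RATIO_GXY * ez, RATIO_GXZ * ez, RATIO_GXZ * ez


def strength_limits(rho_ash):
    """(sigma_max, sigma_min, eps_AB) from ash density in g/cm^3.

    The branch boundary rho_ash == 0.317 belongs to the upper (1.72) branch;
    the two branches differ by < 2% there.
    """
    r = np.asarray(rho_ash, dtype=np.float64)
    if np.any(r < 0):
        raise ValueError("rho_ash must be >= 0")
    sigma_max = np.where(
        r < ASH_BRANCH_THRESHOLD, 137.0 * r**1.88, 114.0 * r**1.72
    )
    sigma_min = 65.1 * r**1.93
    eps_ab = np.maximum(-0.00315 + 0.0728 * r, 0.0)
    return sigma_max, sigma_min, eps_ab


def unit_elasticity_tensor(
    nu_xy: float = DEFAULT_NU_XY, nu_xz: float = DEFAULT_NU_XZ
) -> np.ndarray:
    """6x6 stiffness tensor (Voigt xx,yy,zz,yz,xz,xy; engineering shear) for Ez = 1 MPa.

    All moduli scale with Ez and the Poisson ratios are constant, so an
    element's tensor is ``Ez * unit_elasticity_tensor()``.  Falls back to
    isotropic nu = 0.3 if the requested ratios are not positive definite.
    """
    ex = RATIO_EX
    gxy, gxz = RATIO_GXY, RATIO_GXZ
    s = np.zeros((6, 6))
    s[0, 0] = s[1, 1] = 1.0 / ex
    s[2, 2] = 1.0
    s[0, 1] = s[1, 0] = -nu_xy / ex
    s[0, 2] = s[2, 0] = -nu_xz / ex
    s[1, 2] = s[2, 1] = -nu_xz / ex
    s[3, 3] = 1.0 / gxz  # yz
    s[4, 4] = 1.0 / gxz  # xz
    s[5, 5] = 1.0 / gxy  # xy
    c = np.linalg.inv(s)
    if np.linalg.eigvalsh(c).min() <= 0:
        import warnings

        warnings.warn(
            "transversely isotropic tensor not positive definite; "
            "falling back to isotropic nu = 0.3",
            stacklevel=2,
        )
        nu = 0.3
        lam = nu / ((1 + nu) * (1 - 2 * nu))
        mu = 1.0 / (2 * (1 + nu))
        c = np.zeros((6, 6))
        c[:3, :3] = lam
        c[np.arange(3), np.arange(3)] = lam + 2 * mu
        c[np.arange(3, 6), np.arange(3, 6)] = mu
    return c


def elasticity_tensor(ez: float, nu_xy=DEFAULT_NU_XY, nu_xz=DEFAULT_NU_XZ) -> np.ndarray:
    return float(ez) * unit_elasticity_tensor(nu_xy, nu_xz)


@dataclass
class ElementMaterial:
    """Material state of one tetrahedron."""

    hu: float
    rho_app: float  # mg/cm^3
    rho_ash: float  # g/cm^3
    Ez: float  # MPa
    Ex: float
    Ey: float
    Gxy: float
    Gxz: float
    Gyz: float
    nu_xy: float
    nu_xz: float
    sigma_max: float  # MPa, tension limit on sigma_1
    sigma_min: float  # MPa, magnitude of the compression limit on sigma_3
    eps_AB: float


class MaterialTable:
    """Per-element material arrays for a whole mesh (vectorized container).

    Indexing returns a scalar :class:`ElementMaterial`; the array attributes
    (``Ez``, ``sigma_max``, ...) are what the solver consumes.
    """

    def __init__(self, hu: np.ndarray, nu_xy=DEFAULT_NU_XY, nu_xz=DEFAULT_NU_XZ):
        self.hu = np.asarray(hu, dtype=np.float64)
        self.rho_app = hu_to_apparent_density(self.hu)
        self.rho_ash = apparent_to_ash(self.rho_app)
        self.Ez, self.Ex, self.Ey, self.Gxy, self.Gxz, self.Gyz = density_to_moduli(
            self.rho_app
        )
        self.sigma_max, self.sigma_min, self.eps_AB = strength_limits(self.rho_ash)
        self.nu_xy = float(nu_xy)
        self.nu_xz = float(nu_xz)
        self.unit_tensor = unit_elasticity_tensor(nu_xy, nu_xz)

    def __len__(self) -> int:
        return self.hu.size

    def __getitem__(self, i: int) -> ElementMaterial:
        return ElementMaterial(
            hu=float(self.hu[i]),
            rho_app=float(self.rho_app[i]),
            rho_ash=float(self.rho_ash[i]),
            Ez=float(self.Ez[i]),
            Ex=float(self.Ex[i]),
            Ey=float(self.Ey[i]),
            Gxy=float(self.Gxy[i]),
            Gxz=float(self.Gxz[i]),
            Gyz=float(self.Gyz[i]),
            nu_xy=self.nu_xy,
            nu_xz=self.nu_xz,
            sigma_max=float(self.sigma_max[i]),
            sigma_min=float(self.sigma_min[i]),
            eps_AB=float(self.eps_AB[i]),
        )

    def scaled_strength(self, k: float) -> "MaterialTable":
        """Copy with all stress limits multiplied by ``k`` (moduli unchanged)."""
        out = MaterialTable(self.hu, self.nu_xy, self.nu_xz)
        out.sigma_max = self.sigma_max * k
        out.sigma_min = self.sigma_min * k
        return out


def map_mesh(
    mesh, img, mask=None, nu_xy=DEFAULT_NU_XY, nu_xz=DEFAULT_NU_XZ
) -> MaterialTable:
    """One material per tetrahedron from its mean HU (material z = global z).

    When a label mask is given, background voxels are first replaced by the
    HU of their nearest labeled voxel, so element means are taken over bone
    only.  Stair-step boundary elements otherwise average in surrounding
    soft-tissue HU and acquire a spurious weak skin whose volume grows with
    the element size — the masked fill makes the material field, and hence
    the failure load, nearly independent of the mesh resolution.
    """
    from .image import ImageVolume, element_mean_hu

    if mask is not None:
        mask.check_grid(img)
        fg = mask.labels > 0
        if fg.any() and not fg.all():
            from scipy import ndimage

            idx = ndimage.distance_transform_edt(
                ~fg, sampling=img.spacing, return_distances=False, return_indices=True
            )
            img = ImageVolume(
                img.values[idx[0], idx[1], idx[2]], img.spacing, img.origin
            )

    hu = np.empty(len(mesh.tets), dtype=np.float64)
    for e, tet in enumerate(mesh.tets):
        hu[e] = element_mean_hu(img, mesh.nodes[tet])
    return MaterialTable(hu, nu_xy, nu_xz)


def material_table_frame(materials: MaterialTable) -> pd.DataFrame:
    """Material table export (element id, HU, densities, moduli, limits)."""
    return pd.DataFrame(
        {
            "element": np.arange(len(materials)),
            "hu": materials.hu,
            "rho_app_mg_cm3": materials.rho_app,
            "rho_ash_g_cm3": materials.rho_ash,
            "Ez_MPa": materials.Ez,
            "sigma_max_MPa": materials.sigma_max,
            "sigma_min_MPa": materials.sigma_min,
            "eps_AB": materials.eps_AB,
        }
    )
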