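"""Synthetic thoracic phantoms for lung-SBRT arc planning.

The generator stands in for a planning CT plus structure set: an elliptical
body, two lung ellipsoids of reduced density, and a tumor (the internal
target volume, ITV) of one of four analytic shapes placed inside a lung.
The planning target volume (PTV) is the isotropic 5 mm Euclidean expansion
of the ITV.  A cohort sampler reproduces the case mix of a typical
early-stage NSCLC SBRT series: ITV volumes spanning 0.56-69.39 cc with a
right-skewed (log-uniform) distribution, a mix of convex and concave target
shapes, both lateralities, and the standard 3x18 / 5x11 / 8x7.5 Gy
fractionation schemes.

All coordinates are world millimetres with axes (x: left-right,
y: posterior-anterior, z: inferior-superior); the grid is regular with the
world origin at the grid centre.  Masks are binary with a voxel-centre
inclusion rule (a voxel belongs to a structure iff its centre lies inside
the analytic shape); there is no partial-volume modelling.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
import yaml
from scipy import ndimage

__all__ = [
    "ImageGrid",
    "StructureSet",
    "PhantomSpec",
    "FractionationScheme",
    "PhantomError",
    "make_phantom",
    "sample_cohort",
    "reference_suite",
    "save_phantom",
    "load_grid",
    "load_mask",
    "FRACTIONATION_SCHEMES",
    "ITV_VOLUME_RANGE_CC",
    "PTV_MARGIN_MM",
]

# Isotropic ITV -> PTV setup margin (mm).
PTV_MARGIN_MM = 5.0

# Cohort ITV volume range (cc) spanned by the sampler.
ITV_VOLUME_RANGE_CC = (0.56, 69.39)

# Relative electron densities (water = 1.0); typical CT-derived values.
BODY_DENSITY = 1.0
LUNG_DENSITY = 0.26
TUMOR_DENSITY = 1.0


class PhantomError(ValueError):
    """Raised for invalid phantom specifications."""


# --------------------------------------------------------------------------
# Core containers
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ImageGrid:
    """Regular 3-D scalar grid (density or dose) with mm spacing.

    Parameters
    ----------
    values : ndarray, shape (nx, ny, nz)
        Scalar per voxel: relative electron density (unitless, water = 1)
        for anatomy grids, Gy for dose grids.
    spacing : tuple of float
        Voxel pitch (dx, dy, dz) in mm, all > 0.
    origin : tuple of float
        World-mm coordinate of the centre of voxel (0, 0, 0).
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))
        if values.ndim != 3 or min(values.shape) < 8:
            raise PhantomError(f"grid shape must be 3-D and >= (8,8,8), got {values.shape}")
        if any(s <= 0 for s in self.spacing):
            raise PhantomError(f"spacing must be positive, got {self.spacing}")
        if not np.all(np.isfinite(values)):
            raise PhantomError("grid values must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_volume_cc(self) -> float:
        dx, dy, dz = self.spacing
        return dx * dy * dz / 1000.0

    def axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """World-mm coordinates of voxel centres along each axis."""
        return tuple(
            self.origin[i] + self.spacing[i] * np.arange(self.shape[i])
            for i in range(3)
        )  # type: ignore[return-value]

    def meshgrid(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        ax = self.axes()
        return np.meshgrid(*ax, indexing="ij")  # type: ignore[return-value]

    def voxel_centers(self) -> np.ndarray:
        """(N, 3) array of all voxel-centre world coordinates (C order)."""
        gx, gy, gz = self.meshgrid()
        return np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])

    def with_values(self, values: np.ndarray) -> "ImageGrid":
        return ImageGrid(values, self.spacing, self.origin)

    def same_geometry(self, other: "ImageGrid") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
        )

    # -- IO ---------------------------------------------------------------

    def affine(self) -> np.ndarray:
        aff = np.diag(list(self.spacing) + [1.0])
        aff[:3, 3] = self.origin
        return aff

    def save(self, path: str | Path) -> None:
        import nibabel as nib

        nib.Nifti1Image(self.values.astype(np.float32), self.affine()).to_filename(str(path))


def mask_volume_cc(mask: np.ndarray, grid: ImageGrid) -> float:
    """Structure volume in cc: voxel count x voxel volume (shared routine)."""
    return float(np.count_nonzero(mask)) * grid.voxel_volume_cc


@dataclass
class StructureSet:
    """Named binary masks sharing one :class:`ImageGrid`."""

    grid: ImageGrid
    masks: dict[str, np.ndarray]

    REQUIRED = ("body", "lung_left", "lung_right", "itv", "ptv")

    def __post_init__(self) -> None:
        self.masks = {k: np.asarray(v, dtype=bool) for k, v in self.masks.items()}
        for name, m in self.masks.items():
            if m.shape != self.grid.shape:
                raise PhantomError(f"mask {name!r} shape {m.shape} != grid {self.grid.shape}")

    def __getitem__(self, name: str) -> np.ndarray:
        return self.masks[name]

    def __contains__(self, name: str) -> bool:
        return name in self.masks

    @property
    def lungs(self) -> np.ndarray:
        return self.masks["lung_left"] | self.masks["lung_right"]

    def volume_cc(self, name: str) -> float:
        return mask_volume_cc(self.masks[name], self.grid)

    def validate(self) -> None:
        missing = [n for n in self.REQUIRED if n not in self.masks]
        if missing:
            raise PhantomError(f"missing required structures: {missing}")
        itv, ptv, body = self.masks["itv"], self.masks["ptv"], self.masks["body"]
        if not itv.any():
            raise PhantomError("ITV is empty")
        if np.any(itv & ~ptv):
            raise PhantomError("ITV not contained in PTV")
        if np.any(ptv & ~body):
            raise PhantomError("PTV not contained in body")
        if np.any(self.lungs & ~body):
            raise PhantomError("lungs not contained in body")


@dataclass(frozen=True)
class FractionationScheme:
    """SBRT prescription: dose per fraction (Gy) and number of fractions."""

    dose_per_fraction_gy: float
    n_fractions: int

    @property
    def total_gy(self) -> float:
        return self.dose_per_fraction_gy * self.n_fractions

    def __post_init__(self) -> None:
        if self.total_gy <= 0:
            raise PhantomError("prescription total must be positive")

    @property
    def label(self) -> str:
        d = self.dose_per_fraction_gy
        return f"{self.n_fractions}x{d:g}"


#: The three supported schemes (54 / 55 / 60 Gy total).
FRACTIONATION_SCHEMES: dict[str, FractionationScheme] = {
    "3x18": FractionationScheme(18.0, 3),
    "5x11": FractionationScheme(11.0, 5),
    "8x7.5": FractionationScheme(7.5, 8),
}

#: Cohort mix of schemes (7 / 8 / 5 of 20 cases).
_SCHEME_WEIGHTS = {"3x18": 0.35, "5x11": 0.40, "8x7.5": 0.25}


# --------------------------------------------------------------------------
# Tumor shapes (analytic, in world mm relative to the tumor centre)
# --------------------------------------------------------------------------

def _inside_sphere(p: np.ndarray, r: float) -> np.ndarray:
    return np.einsum("...i,...i", p, p) <= r * r


def _inside_ellipsoid(p: np.ndarray, semiaxes: np.ndarray) -> np.ndarray:
    q = p / semiaxes
    return np.einsum("...i,...i", q, q) <= 1.0


def _inside_bilobed(p: np.ndarray, r1: float, r2: float, sep: float) -> np.ndarray:
    # Two overlapping spheres along z: a concave (peanut) target.
    off = np.array([0.0, 0.0, sep / 2.0])
    return _inside_sphere(p - off, r1) | _inside_sphere(p + off, r2)


def _inside_capsule(p: np.ndarray, r: float, half_len: float) -> np.ndarray:
    # Cylinder of radius r along z with hemispherical end caps.
    z = np.clip(p[..., 2], -half_len, half_len)
    d = p - np.stack([np.zeros_like(z), np.zeros_like(z), z], axis=-1)
    return np.einsum("...i,...i", d, d) <= r * r


def _sphere_volume(r: float) -> float:
    return 4.0 / 3.0 * np.pi * r**3


def _lens_volume(r1: float, r2: float, d: float) -> float:
    """Volume of the intersection of two spheres at centre distance d."""
    if d >= r1 + r2:
        return 0.0
    if d <= abs(r1 - r2):
        return _sphere_volume(min(r1, r2))
    return (
        np.pi
        * (r1 + r2 - d) ** 2
        * (d * d + 2 * d * r2 - 3 * r2 * r2 + 2 * d * r1 + 6 * r1 * r2 - 3 * r1 * r1)
        / (12.0 * d)
    )


def shape_volume_mm3(shape: str, params: dict[str, float]) -> float:
    """Analytic volume (mm^3) of a tumor shape."""
    if shape == "sphere":
        return _sphere_volume(params["r"])
    if shape == "ellipsoid":
        a, b, c = params["a"], params["b"], params["c"]
        return 4.0 / 3.0 * np.pi * a * b * c
    if shape == "bilobed":
        r1, r2, sep = params["r1"], params["r2"], params["sep"]
        return _sphere_volume(r1) + _sphere_volume(r2) - _lens_volume(r1, r2, sep)
    if shape == "capped_cylinder":
        r, h = params["r"], params["half_len"]
        return np.pi * r * r * (2 * h) + _sphere_volume(r)
    raise PhantomError(f"unknown tumor shape {shape!r}")


def _shape_inside_fn(shape: str, params: dict[str, float]) -> Callable[[np.ndarray], np.ndarray]:
    if shape == "sphere":
        return lambda p: _inside_sphere(p, params["r"])
    if shape == "ellipsoid":
        semi = np.array([params["a"], params["b"], params["c"]])
        return lambda p: _inside_ellipsoid(p, semi)
    if shape == "bilobed":
        return lambda p: _inside_bilobed(p, params["r1"], params["r2"], params["sep"])
    if shape == "capped_cylinder":
        return lambda p: _inside_capsule(p, params["r"], params["half_len"])
    raise PhantomError(f"unknown tumor shape {shape!r}")


def shape_half_extents(shape: str, params: dict[str, float]) -> np.ndarray:
    """Per-axis half-extents (mm) of the shape's bounding box."""
    if shape == "sphere":
        r = params["r"]
        return np.array([r, r, r])
    if shape == "ellipsoid":
        return np.array([params["a"], params["b"], params["c"]])
    if shape == "bilobed":
        r = max(params["r1"], params["r2"])
        return np.array([r, r, params["sep"] / 2.0 + r])
    if shape == "capped_cylinder":
        r, h = params["r"], params["half_len"]
        return np.array([r, r, h + r])
    raise PhantomError(f"unknown tumor shape {shape!r}")


def params_for_volume(shape: str, volume_cc: float, aspect: dict[str, float] | None = None) -> dict[str, float]:
    """Shape parameters realizing a requested analytic volume.

    ``aspect`` fixes the dimensionless shape ratios; the absolute scale is
    solved exactly (volume scales with the cube of the linear scale).
    """
    v_mm3 = volume_cc * 1000.0
    aspect = aspect or {}
    if shape == "sphere":
        return {"r": (v_mm3 / (4.0 / 3.0 * np.pi)) ** (1.0 / 3.0)}
    if shape == "ellipsoid":
        qa = aspect.get("qa", 1.0)
        qb = aspect.get("qb", 1.0)
        qc = aspect.get("qc", 3.0)
        s = (v_mm3 / (4.0 / 3.0 * np.pi * qa * qb * qc)) ** (1.0 / 3.0)
        return {"a": qa * s, "b": qb * s, "c": qc * s}
    if shape == "bilobed":
        f = aspect.get("lobe_ratio", 0.75)  # r2 / r1
        g = aspect.get("sep_ratio", 0.9)  # sep / (r1 + r2)
        base = {"r1": 1.0, "r2": f, "sep": g * (1.0 + f)}
        s = (v_mm3 / shape_volume_mm3("bilobed", base)) ** (1.0 / 3.0)
        return {k: v * s for k, v in base.items()}
    if shape == "capped_cylinder":
        ar = aspect.get("aspect", 2.0)  # half_len / r
        base = {"r": 1.0, "half_len": ar}
        s = (v_mm3 / shape_volume_mm3("capped_cylinder", base)) ** (1.0 / 3.0)
        return {"r": s, "half_len": ar * s}
    raise PhantomError(f"unknown tumor shape {shape!r}")


# --------------------------------------------------------------------------
# Phantom specification
# --------------------------------------------------------------------------

# Default thorax: 2 mm isotropic voxels on a 128^3 grid (256 mm cube).
_FINE = dict(spacing_mm=(2.0, 2.0, 2.0), grid_shape=(128, 128, 128),
             body_semiaxes_mm=(110.0, 85.0, 100.0))
# Coarse preset for fast tests: 3 mm / 64^3 (192 mm cube), thorax scaled to fit.
_COARSE = dict(spacing_mm=(3.0, 3.0, 3.0), grid_shape=(64, 64, 64),
               body_semiaxes_mm=(90.0, 70.0, 86.0))


def lung_geometry(body_semiaxes: tuple[float, float, float]) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Analytic lung ellipsoids (centre, semi-axes) derived from the body."""
    a, b, c = body_semiaxes
    semi = np.array([0.40 * a, 0.70 * b, 0.80 * c])
    return {
        "lung_left": (np.array([-0.47 * a, 0.03 * b, 0.0]), semi),
        "lung_right": (np.array([0.47 * a, 0.03 * b, 0.0]), semi),
    }


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of one synthetic case; the seed fixes everything."""

    tumor_shape: str = "sphere"
    tumor_params: dict = field(default_factory=lambda: {"r": 10.0})
    tumor_center_mm: tuple[float, float, float] = (-51.7, 2.6, 0.0)
    laterality: str = "left"
    fractionation: FractionationScheme = FRACTIONATION_SCHEMES["3x18"]
    body_semiaxes_mm: tuple[float, float, float] = (110.0, 85.0, 100.0)
    body_density: float = BODY_DENSITY
    lung_density: float = LUNG_DENSITY
    tumor_density: float = TUMOR_DENSITY
    spacing_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    grid_shape: tuple[int, int, int] = (128, 128, 128)
    seed: int = 0
    case_id: str = "case"

    def __post_init__(self) -> None:
        # Coerce numpy scalars so specs serialize and compare cleanly.
        for name in ("tumor_center_mm", "body_semiaxes_mm", "spacing_mm"):
            object.__setattr__(self, name, tuple(float(v) for v in getattr(self, name)))
        object.__setattr__(self, "grid_shape", tuple(int(v) for v in self.grid_shape))
        object.__setattr__(
            self, "tumor_params", {k: float(v) for k, v in self.tumor_params.items()}
        )
        for d in (self.body_density, self.lung_density, self.tumor_density):
            if not (0.0 < d <= 2.0):
                raise PhantomError(f"densities must lie in (0, 2], got {d}")

    @classmethod
    def preset(cls, which: str = "default", **overrides) -> "PhantomSpec":
        base = {"default": _FINE, "coarse": _COARSE}[which]
        kwargs = {**base, **overrides}
        # Default tumor centre: left lung centre of the chosen thorax.
        if "tumor_center_mm" not in overrides:
            lat = kwargs.get("laterality", "left")
            centre, _ = lung_geometry(kwargs["body_semiaxes_mm"])[f"lung_{lat}"]
            kwargs["tumor_center_mm"] = tuple(centre)
        return cls(**kwargs)

    def itv_volume_cc(self) -> float:
        return shape_volume_mm3(self.tumor_shape, self.tumor_params) / 1000.0


# --------------------------------------------------------------------------
# Phantom construction
# --------------------------------------------------------------------------

def make_phantom(spec: PhantomSpec) -> tuple[ImageGrid, StructureSet]:
    """Voxelize a :class:`PhantomSpec` into a density grid and structure set.

    The PTV is the 5 mm isotropic Euclidean expansion of the ITV (clipped to
    the body).  Raises :class:`PhantomError` if the tumor is not fully inside
    a lung or if the voxel spacing cannot resolve it (< 3 voxels across).
    """
    shape = np.asarray(spec.grid_shape, dtype=int)
    spacing = np.asarray(spec.spacing_mm, dtype=float)
    origin = -(shape - 1) / 2.0 * spacing  # grid centred on the world origin
    template = ImageGrid(np.zeros(tuple(shape)), tuple(spacing), tuple(origin))

    gx, gy, gz = template.meshgrid()
    pts = np.stack([gx, gy, gz], axis=-1)

    body_semi = np.asarray(spec.body_semiaxes_mm, dtype=float)
    body = _inside_ellipsoid(pts, body_semi)
    lungs = {}
    for name, (centre, semi) in lung_geometry(tuple(body_semi)).items():
        lungs[name] = _inside_ellipsoid(pts - centre, semi) & body

    half_ext = shape_half_extents(spec.tumor_shape, spec.tumor_params)
    if np.any(2.0 * half_ext / spacing < 3.0):
        raise PhantomError(
            f"spacing {tuple(spacing)} mm too coarse to resolve tumor of "
            f"half-extents {np.round(half_ext, 2)} mm (< 3 voxels across)"
        )

    centre = np.asarray(spec.tumor_center_mm, dtype=float)
    inside = _shape_inside_fn(spec.tumor_shape, spec.tumor_params)
    itv = inside(pts - centre)
    if not itv.any():
        raise PhantomError("ITV voxelized to an empty mask")
    lung_union = lungs["lung_left"] | lungs["lung_right"]
    n_outside = int(np.count_nonzero(itv & ~lung_union))
    if n_outside:
        raise PhantomError(
            f"tumor outside lung: {n_outside} ITV voxels fall outside the lungs "
            f"(centre {tuple(np.round(centre, 1))}, laterality {spec.laterality})"
        )

    # PTV: Euclidean distance-to-ITV <= 5 mm (anisotropic spacing honoured).
    dist = ndimage.distance_transform_edt(~itv, sampling=spacing)
    ptv = (dist <= PTV_MARGIN_MM) & body
    ptv |= itv

    density = np.zeros(tuple(shape))
    density[body] = spec.body_density
    density[lung_union] = spec.lung_density
    density[itv] = spec.tumor_density

    grid = template.with_values(density)
    structures = StructureSet(
        grid,
        {
            "body": body,
            "lung_left": lungs["lung_left"],
            "lung_right": lungs["lung_right"],
            "itv": itv,
            "ptv": ptv,
        },
    )
    structures.validate()
    return grid, structures


# --------------------------------------------------------------------------
# Cohort sampling
# --------------------------------------------------------------------------

_SHAPES = ("sphere", "ellipsoid", "bilobed", "capped_cylinder")


def _sample_aspect(shape: str, rng: np.random.Generator) -> dict[str, float]:
    if shape == "ellipsoid":
        # Mildly to strongly elongated, long axis cranio-caudal.
        q = rng.uniform(1.5, 3.0)
        return {"qa": 1.0, "qb": rng.uniform(0.8, 1.2), "qc": q}
    if shape == "bilobed":
        return {"lobe_ratio": rng.uniform(0.6, 0.9), "sep_ratio": rng.uniform(0.8, 1.05)}
    if shape == "capped_cylinder":
        return {"aspect": rng.uniform(1.2, 2.5)}
    return {}


def _place_tumor(
    shape: str,
    params: dict[str, float],
    laterality: str,
    body_semiaxes: tuple[float, float, float],
    rng: np.random.Generator,
) -> tuple[float, float, float]:
    """Sample a tumor centre such that the shape fits inside the lung.

    Uses a conservative criterion: the tumor's bounding box, corner-inflated
    into the lung ellipsoid equation, must evaluate <= 1.  Falls back to the
    lung centre if rejection sampling fails.
    """
    lc, semi = lung_geometry(body_semiaxes)[f"lung_{laterality}"]
    half = shape_half_extents(shape, params)
    slack = np.maximum(semi - half, 0.0)
    for _ in range(500):
        c = lc + rng.uniform(-slack, slack)
        if np.sum(((np.abs(c - lc) + half) / semi) ** 2) <= 1.0:
            return tuple(c)
    return tuple(lc)


def sample_cohort(
    n: int,
    seed: int,
    *,
    preset: str = "default",
    **grid_overrides,
) -> list[PhantomSpec]:
    """Draw ``n`` case specifications emulating the study's case mix.

    ITV volumes are log-uniform on [0.56, 69.39] cc (right-skewed, median
    well below the mean); each block of five cases contains at least one
    concave (bilobed) target; laterality, placement, and fractionation are
    randomized.  The same (n, seed) always yields the same list.
    """
    if n < 1:
        raise PhantomError("cohort size must be >= 1")
    rng = np.random.default_rng(seed)
    base = PhantomSpec.preset(preset, **grid_overrides)

    lo, hi = ITV_VOLUME_RANGE_CC
    volumes = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n))

    shapes = [str(rng.choice(_SHAPES)) for _ in range(n)]
    for start in range(0, n, 5):
        block = range(start, min(start + 5, n))
        if not any(shapes[i] == "bilobed" for i in block):
            shapes[int(rng.choice(list(block)))] = "bilobed"

    scheme_names = list(_SCHEME_WEIGHTS)
    scheme_p = np.array([_SCHEME_WEIGHTS[s] for s in scheme_names])

    specs = []
    for i in range(n):
        shape = shapes[i]
        # A tiny tumor must still span >= 3 voxels: bump the volume floor at
        # coarse spacing so every sampled case voxelizes.
        min_half = 1.6 * max(base.spacing_mm)
        vol = float(volumes[i])
        params = params_for_volume(shape, vol, _sample_aspect(shape, rng))
        if np.min(shape_half_extents(shape, params)) < min_half:
            scale = min_half / np.min(shape_half_extents(shape, params))
            params = {k: v * scale for k, v in params.items()}
        laterality = str(rng.choice(["left", "right"]))
        centre = _place_tumor(shape, params, laterality, base.body_semiaxes_mm, rng)
        scheme = FRACTIONATION_SCHEMES[str(rng.choice(scheme_names, p=scheme_p))]
        specs.append(
            dataclasses.replace(
                base,
                tumor_shape=shape,
                tumor_params=params,
                tumor_center_mm=centre,
                laterality=laterality,
                fractionation=scheme,
                seed=int(rng.integers(0, 2**31 - 1)),
                case_id=f"case{i:03d}",
            )
        )
    return specs


def reference_suite(seed: int, preset: str = "coarse", n_sampled: int = 2) -> list[PhantomSpec]:
    """Fixed benchmark suite of non-spherical targets.

    Three canonical cases -- a 3:1 cranio-caudally elongated ellipsoid, a
    concave bilobed target, and a capped cylinder, at mid-cohort volumes --
    plus ``n_sampled`` sampled non-spherical cases.  Used to demonstrate
    the conformity improvement of margin deformation on the shapes where a
    conformal arc struggles most.
    """
    base = PhantomSpec.preset(preset)
    canonical = [
        dataclasses.replace(
            base,
            tumor_shape="ellipsoid",
            tumor_params=params_for_volume("ellipsoid", 20.0, {"qa": 1, "qb": 1, "qc": 3}),
            case_id="ellipsoid_3to1",
        ),
        dataclasses.replace(
            base,
            tumor_shape="bilobed",
            tumor_params=params_for_volume("bilobed", 15.0),
            case_id="bilobed",
        ),
        dataclasses.replace(
            base,
            tumor_shape="capped_cylinder",
            tumor_params=params_for_volume("capped_cylinder", 25.0),
            case_id="capped_cylinder",
        ),
    ]
    sampled = [s for s in sample_cohort(4 * n_sampled + 4, seed, preset=preset)
               if s.tumor_shape != "sphere"][:n_sampled]
    sampled = [dataclasses.replace(s, case_id=f"sampled{i}") for i, s in enumerate(sampled)]
    return canonical + sampled


# --------------------------------------------------------------------------
# Persistence
# --------------------------------------------------------------------------

def spec_to_yaml(spec: PhantomSpec, path: str | Path) -> None:
    d = dataclasses.asdict(spec)
    d["fractionation"] = {
        "dose_per_fraction_gy": spec.fractionation.dose_per_fraction_gy,
        "n_fractions": spec.fractionation.n_fractions,
    }
    Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


def spec_from_yaml(path: str | Path) -> PhantomSpec:
    d = yaml.safe_load(Path(path).read_text())
    d["fractionation"] = FractionationScheme(**d["fractionation"])
    for key in ("tumor_center_mm", "body_semiaxes_mm", "spacing_mm"):
        d[key] = tuple(d[key])
    d["grid_shape"] = tuple(int(v) for v in d["grid_shape"])
    return PhantomSpec(**d)


def save_phantom(
    grid: ImageGrid, structures: StructureSet, outdir: str | Path, spec: PhantomSpec | None = None
) -> dict:
    """Write density + masks as NIfTI with a YAML spec and JSON manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files = {"density": "density.nii.gz"}
    grid.save(outdir / files["density"])
    for name, mask in structures.masks.items():
        fname = f"mask_{name}.nii.gz"
        grid.with_values(mask.astype(np.float64)).save(outdir / fname)
        files[name] = fname
    manifest = {
        "files": files,
        "volumes_cc": {n: structures.volume_cc(n) for n in structures.masks},
        "seed": None if spec is None else spec.seed,
    }
    if spec is not None:
        spec_to_yaml(spec, outdir / "spec.yaml")
        manifest["spec"] = "spec.yaml"
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def load_grid(path: str | Path) -> ImageGrid:
    import nibabel as nib

    img = nib.load(str(path))
    aff = img.affine
    spacing = tuple(float(aff[i, i]) for i in range(3))
    origin = tuple(float(aff[i, 3]) for i in range(3))
    return ImageGrid(np.asarray(img.dataobj, dtype=np.float64), spacing, origin)


def load_mask(path: str | Path) -> np.ndarray:
    return load_grid(path).values > 0.5
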