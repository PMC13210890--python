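"""Scattering phantoms: layered test objects for the forward model.

A phantom is a stack of non-overlapping layers along depth z (µm, increasing
into the sample).  Each layer carries an interface reflectivity map (the
specular/structured return at its top surface), an attenuation coefficient
``scattering_mu`` and a ``crosstalk_strength`` that controls how much of the
light removed from the ballistic channel reappears as delocalized crosstalk.
Scattering layers additionally contribute distributed volumetric backscatter
so that depth-resolved reconstructions show a Beer–Lambert decay rather than
isolated interface peaks.

Recipes emulate the classic bench objects of full-field OCT work: a
three-bar resolution target, a reflecting plane behind a diffusive slab, a
thick two-layer scattering slab with an embedded spherical defect, and an
isolated point reflector.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .config import OpticalConfig

RECIPES = (
    "bar_target",
    "plane_behind_diffuser",
    "two_layer_slab_with_defect",
    "point_target",
)


@dataclasses.dataclass(frozen=True)
class Layer:
    """One slab: top depth and thickness in µm, intensity reflectivity map
    in [0, 1] at the top interface, attenuation ``scattering_mu`` (1/µm) and
    dimensionless ``crosstalk_strength`` >= 0."""

    z_top: float
    thickness: float
    reflectivity_map: np.ndarray
    scattering_mu: float = 0.0
    crosstalk_strength: float = 0.0

    def __post_init__(self) -> None:
        r = np.asarray(self.reflectivity_map, dtype=float)
        if r.ndim != 2:
            raise ValueError("reflectivity_map must be 2-D")
        if np.any(r < 0) or np.any(r > 1):
            raise ValueError("reflectivity values must lie in [0, 1]")
        if self.scattering_mu < 0:
            raise ValueError("scattering_mu must be >= 0")
        if self.crosstalk_strength < 0:
            raise ValueError("crosstalk_strength must be >= 0")
        if self.thickness < 0:
            raise ValueError("thickness must be >= 0")

    @property
    def z_bottom(self) -> float:
        return self.z_top + self.thickness


@dataclasses.dataclass(frozen=True)
class Defect:
    """Spherical reflectivity perturbation: amplitudes inside the sphere are
    multiplied by (1 + contrast); contrast=-1 makes a void."""

    center: tuple[float, float, float]  # (x, y, z) µm
    radius: float
    contrast: float

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("defect radius must be positive")


@dataclasses.dataclass(frozen=True)
class AxialScatterer:
    """One discrete backscattering slice at depth z with a field-amplitude map."""

    z: float
    amplitude: np.ndarray


@dataclasses.dataclass(frozen=True)
class ScatteringPhantom:
    """An ordered, non-overlapping stack of layers plus optional defects.

    ``backscatter_fraction`` is the fraction of the intensity removed per
    unit depth by scattering that returns ballistically toward the detector
    (it sets the amplitude of the distributed volumetric signal);
    ``n_sub`` is the number of axial sub-slices used to discretise each
    scattering layer's volume.
    """

    layers: tuple[Layer, ...]
    defects: tuple[Defect, ...] = ()
    backscatter_fraction: float = 0.1
    n_sub: int = 32
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.layers:
            raise ValueError("phantom needs at least one layer")
        zs = [la.z_top for la in self.layers]
        if sorted(zs) != zs:
            raise ValueError("layers must be sorted by increasing z_top")
        for above, below in zip(self.layers, self.layers[1:]):
            if below.z_top < above.z_bottom - 1e-9:
                raise ValueError(
                    f"layers overlap: {above.z_top}+{above.thickness} vs {below.z_top}"
                )
        shapes = {la.reflectivity_map.shape for la in self.layers}
        if len(shapes) != 1:
            raise ValueError("all layers must share the lateral grid")

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.layers[0].reflectivity_map.shape

    @property
    def z_extent(self) -> float:
        return max(la.z_bottom for la in self.layers)

    # -- optical depth ----------------------------------------------------
    def optical_depth(self, z: float) -> float:
        """Single-pass attenuation integral Σ µ·(thickness above depth z)."""
        tau = 0.0
        for la in self.layers:
            if la.scattering_mu > 0:
                overlap = min(z, la.z_bottom) - la.z_top
                if overlap > 0:
                    tau += la.scattering_mu * overlap
        return tau

    def _apply_defects(self, amp: np.ndarray, z: float, config: OpticalConfig) -> np.ndarray:
        if not self.defects:
            return amp
        ny, nx = amp.shape
        pitch = config.pixel_pitch_obj
        x = (np.arange(nx) - nx / 2) * pitch
        y = (np.arange(ny) - ny / 2) * pitch
        xx, yy = np.meshgrid(x, y)
        out = amp.copy()
        for d in self.defects:
            dz = z - d.center[2]
            if abs(dz) >= d.radius:
                continue
            r_lat = np.sqrt(d.radius**2 - dz**2)
            inside = (xx - d.center[0]) ** 2 + (yy - d.center[1]) ** 2 <= r_lat**2
            out[inside] *= max(0.0, 1.0 + d.contrast)
        return out

    # -- discretisation ---------------------------------------------------
    def scatterers(self, config: OpticalConfig) -> list[AxialScatterer]:
        """Discretise into axial slices of field-amplitude maps.

        Each layer yields its interface slice (amplitude = √reflectivity)
        plus, when it scatters and ``backscatter_fraction`` > 0, ``n_sub``
        volumetric sub-slices of amplitude √(backscatter_fraction·µ·Δz).
        Attenuation above each slice is *not* applied here — the forward
        model applies it per the acquisition geometry.
        """
        if self.grid_shape != (config.ny, config.nx):
            raise ValueError("phantom grid does not match the detector grid")
        slices: list[AxialScatterer] = []
        for la in self.layers:
            amp = np.sqrt(la.reflectivity_map.astype(float))
            if np.any(amp > 0):
                slices.append(
                    AxialScatterer(la.z_top, self._apply_defects(amp, la.z_top, config))
                )
            if la.scattering_mu > 0 and self.backscatter_fraction > 0 and la.thickness > 0:
                dz = la.thickness / self.n_sub
                a0 = np.sqrt(self.backscatter_fraction * la.scattering_mu * dz)
                li = self.layers.index(la)
                for q in range(self.n_sub):
                    z = la.z_top + (q + 0.5) * dz
                    # tissue-like speckle texture, unit-mean Rayleigh, fixed by
                    # the phantom seed (it is the object, not noise)
                    rng = np.random.default_rng(
                        np.random.SeedSequence([0x7E97, abs(int(self.seed)), li, q])
                    )
                    texture = rng.rayleigh(scale=np.sqrt(2.0 / np.pi), size=self.grid_shape)
                    amp_q = a0 * texture
                    slices.append(AxialScatterer(z, self._apply_defects(amp_q, z, config)))
        slices.sort(key=lambda s: s.z)
        return slices


# ---------------------------------------------------------------------------
# recipes
# ---------------------------------------------------------------------------

def _three_bar_pattern(ny: int, nx: int, period: int, reflectivity: float = 1.0) -> np.ndarray:
    """Three-bar resolution group: 3 vertical bars of width period//2,
    separated by gaps of the same width, centred on the grid."""
    bar = period // 2
    pattern = np.zeros((ny, nx))
    group_w = 5 * bar  # bar gap bar gap bar
    x0 = (nx - group_w) // 2
    y0, y1 = ny // 4, 3 * ny // 4
    for b in range(3):
        xs = x0 + b * 2 * bar
        pattern[y0:y1, xs : xs + bar] = reflectivity
    return pattern


def make_phantom(recipe: str, config: OpticalConfig, seed: int = 0, **params) -> ScatteringPhantom:
    """Build a named phantom on the configured grid.

    Recipes
    -------
    bar_target : three-bar reflective resolution pattern at ``z0``
        (default 100 µm); ``period`` in pixels (default 8).
    plane_behind_diffuser : uniform reflecting plane at ``z_plane``
        (default 300 µm) under a diffusive slab of attenuation ``mu``
        (default 2e-3 /µm) and thickness ``thickness`` (default 200 µm);
        with ``mu=0`` the slab disappears and a single crosstalk-free
        layer remains.
    two_layer_slab_with_defect : two scattering layers (``mu1``, ``mu2``,
        defaults 2e-3 and 4e-3 /µm; thicknesses 300 µm each, first layer
        top at 50 µm) with a spherical defect of radius ``defect_radius``
        (default 90 µm) embedded in the second layer.
    point_target : single-pixel reflector at the grid centre, depth ``z0``.
    """
    ny, nx = config.ny, config.nx
    if recipe == "bar_target":
        period = int(params.pop("period", 8))
        z0 = float(params.pop("z0", 100.0))
        refl = float(params.pop("reflectivity", 1.0))
        layers = (Layer(z0, 0.0, _three_bar_pattern(ny, nx, period, refl)),)
        return ScatteringPhantom(layers=layers, seed=seed, **params)

    if recipe == "plane_behind_diffuser":
        mu = float(params.pop("mu", 2e-3))
        thickness = float(params.pop("thickness", 200.0))
        z_plane = float(params.pop("z_plane", 300.0))
        refl = float(params.pop("reflectivity", 0.5))
        ct = float(params.pop("crosstalk_strength", 0.5))
        plane = Layer(z_plane, 0.0, np.full((ny, nx), refl))
        if mu == 0:
            return ScatteringPhantom(layers=(plane,), seed=seed, **params)
        if mu < 0:
            raise ValueError("mu must be >= 0")
        diffuser = Layer(
            z_plane - thickness, thickness, np.zeros((ny, nx)),
            scattering_mu=mu, crosstalk_strength=ct,
        )
        return ScatteringPhantom(layers=(diffuser, plane), seed=seed, **params)

    if recipe == "two_layer_slab_with_defect":
        mu1 = float(params.pop("mu1", 2e-3))
        mu2 = float(params.pop("mu2", 4e-3))
        t1 = float(params.pop("t1", 300.0))
        t2 = float(params.pop("t2", 300.0))
        z_top = float(params.pop("z_top", 50.0))
        ct = float(params.pop("crosstalk_strength", 0.5))
        defect_radius = float(params.pop("defect_radius", 90.0))
        defect_contrast = float(params.pop("defect_contrast", 2.0))
        r1 = float(params.pop("r1", 0.05))
        r2 = float(params.pop("r2", 0.05))
        if mu1 < 0 or mu2 < 0:
            raise ValueError("mu must be >= 0")
        l1 = Layer(z_top, t1, np.full((ny, nx), r1), scattering_mu=mu1, crosstalk_strength=ct)
        l2 = Layer(z_top + t1, t2, np.full((ny, nx), r2), scattering_mu=mu2, crosstalk_strength=ct)
        defects = ()
        if defect_radius > 0:
            defects = (Defect((0.0, 0.0, z_top + t1 + t2 / 2), defect_radius, defect_contrast),)
        return ScatteringPhantom(layers=(l1, l2), defects=defects, seed=seed, **params)

    if recipe == "point_target":
        z0 = float(params.pop("z0", 100.0))
        refl = float(params.pop("reflectivity", 1.0))
        m = np.zeros((ny, nx))
        m[ny // 2, nx // 2] = refl
        return ScatteringPhantom(layers=(Layer(z0, 0.0, m),), seed=seed, **params)

    raise ValueError(f"unknown phantom recipe {recipe!r}; choose from {RECIPES}")
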