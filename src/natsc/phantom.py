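"""Synthetic pelvic sodium-MRI phantom with known ground truth.

The phantom stands in for a patient acquisition: a labelled compartment
map (prostate peripheral and transition zones, a focal lesion, femoral
blood vessels, a muscle body surrounded by air) with a true tissue
sodium concentration (TSC) per compartment, relaxation-weighted
steady-state signal, smooth complex receive-sensitivity fields for a
multichannel array, and radial k-space sampling with additive complex
Gaussian noise.

The default geometry emulates the cohort of the quantification study it
is designed to exercise: a ~59 cm^3 gland with a posterior-crescent
peripheral zone, a capsule-abutting 18 x 14 x 12 mm lesion carved out of
the PZ, a mirrored contralateral reference region, and bilateral
iliac-femoral vessels of 22 mm calibre carrying blood at 81 mM with small
cylindrical reference ROIs placed centrally inside the lumina.
Compartment TSC defaults are the cohort means reported for this kind of
patient collective (PZ 40.7, TZ 37.5, lesion 32.2 mM).  Truth maps are
piecewise constant: every voxel carries exactly the TSC of its label.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import (
    BLOOD_RELAXATION,
    MUSCLE_RELAXATION,
    PROSTATE_RELAXATION,
    RelaxationSet,
    ROIMask,
    SequenceParams,
    centered_origin,
    child_rng,
    voxel_centers,
)
from .gridding import nudft_forward, nufft_forward
from .quantify import mirror_contralateral, relaxation_factor
from .trajectory import Trajectory

__all__ = [
    "TissueCompartment",
    "PhantomVolume",
    "CoilProfile",
    "KSpaceData",
    "Ellipsoid",
    "Cylinder",
    "Region",
    "CompartmentSpec",
    "PhantomGeometry",
    "default_geometry",
    "build_phantom",
    "simulate_sensitivities",
    "steady_state_signal",
    "sample_kspace",
]


@dataclass(frozen=True)
class TissueCompartment:
    label: int
    name: str
    tsc_true: float  # mM
    relaxation: RelaxationSet

    def __post_init__(self) -> None:
        if self.label < 0:
            raise ValueError("labels must be non-negative")
        if self.tsc_true < 0:
            raise ValueError("tsc_true must be non-negative")


# ---------------------------------------------------------------------------
# geometry primitives


@dataclass(frozen=True)
class Ellipsoid:
    center: tuple  # mm
    radii: tuple  # mm

    def contains(self, x, y, z):
        cx, cy, cz = self.center
        rx, ry, rz = self.radii
        return ((x - cx) / rx) ** 2 + ((y - cy) / ry) ** 2 + ((z - cz) / rz) ** 2 <= 1.0


@dataclass(frozen=True)
class Cylinder:
    """Axis-aligned circular cylinder (axis = superior-inferior, z)."""

    center: tuple  # (x, y, z) mm of the mid-point
    radius: float  # mm
    half_length: float  # mm along z

    def contains(self, x, y, z):
        cx, cy, cz = self.center
        return ((x - cx) ** 2 + (y - cy) ** 2 <= self.radius**2) & (
            np.abs(z - cz) <= self.half_length
        )


@dataclass(frozen=True)
class HalfSpace:
    """Voxels with coordinate along ``axis`` below/above ``value``."""

    axis: int
    value: float
    side: str = "below"  # keep coords <= value ("below") or >= value ("above")

    def contains(self, x, y, z):
        coord = (x, y, z)[self.axis]
        keep = coord <= self.value if self.side == "below" else coord >= self.value
        return keep & np.ones(np.broadcast_shapes(x.shape, y.shape, z.shape), bool)


@dataclass(frozen=True)
class Region:
    """CSG-lite region: a base primitive intersected with ``within`` shapes
    and with ``minus`` shapes removed."""

    base: object
    within: tuple = ()
    minus: tuple = ()

    def mask(self, x, y, z) -> np.ndarray:
        m = self.base.contains(x, y, z)
        for w in self.within:
            m = m & w.contains(x, y, z)
        for s in self.minus:
            m = m & ~s.contains(x, y, z)
        return m

    def contains(self, x, y, z):
        """Regions compose: a Region can serve as a shape in another Region."""
        return self.mask(x, y, z)


@dataclass(frozen=True)
class CompartmentSpec:
    """One tissue compartment: geometry plus truth values.

    ``carve_from`` lists compartment names this shape may overwrite (e.g. a
    lesion carved out of the zone it sits in); any other overlap is an error.
    """

    name: str
    label: int
    tsc: float
    relaxation: RelaxationSet
    region: Region
    role: str | None = None  # ROI role emitted for this compartment
    carve_from: tuple = ()
    erosion_role: bool = True


@dataclass
class PhantomGeometry:
    compartments: list
    background_tsc: float = 20.0
    background_relaxation: RelaxationSet = field(default_factory=lambda: MUSCLE_RELAXATION)
    reference_rois: dict = field(default_factory=dict)  # role -> Region
    lesion_names: tuple = ()


def default_geometry(
    pz_tsc: float = 40.7,
    tz_tsc: float = 37.5,
    lesion_tsc: float = 32.2,
    blood_tsc: float = 81.0,
    body_tsc: float = 20.0,
    body_radius: float = 76.0,
) -> PhantomGeometry:
    """The default pelvic geometry (sizes in mm, see module docstring).

    The anatomy sits inside an elliptical muscle body surrounded by air
    (zero signal): the receive-field correction's thresholding step is
    built around finding that body/air boundary.
    """
    body = Cylinder((0.0, 0.0, 0.0), body_radius, 1e6)
    wp = Ellipsoid((0.0, 0.0, 0.0), (27.0, 25.0, 21.0))
    inner = Ellipsoid((0.0, 8.0, 2.0), (22.0, 21.0, 17.0))
    posterior = HalfSpace(axis=1, value=2.0, side="below")
    lesion = Ellipsoid((-10.0, -17.5, 0.0), (9.0, 7.0, 6.0))
    fbv_l = Cylinder((-42.0, -6.0, 0.0), 11.0, 30.0)
    fbv_r = Cylinder((42.0, -6.0, 0.0), 11.0, 30.0)

    # posterior crescent = gland below the coronal cut, outside the inner ellipsoid
    crescent = Region(wp, within=(posterior,), minus=(inner,))
    pz_region = Region(wp, within=(posterior,), minus=(inner, lesion))
    tz_region = Region(wp, minus=(crescent,))

    in_body = ("muscle_body",)
    comps = [
        CompartmentSpec("muscle_body", 6, body_tsc, MUSCLE_RELAXATION, Region(body)),
        CompartmentSpec("TZ", 1, tz_tsc, PROSTATE_RELAXATION, tz_region, role="TZ",
                        carve_from=in_body),
        CompartmentSpec("PZ", 2, pz_tsc, PROSTATE_RELAXATION, pz_region, role="PZ",
                        carve_from=in_body),
        CompartmentSpec(
            "lesion", 3, lesion_tsc, PROSTATE_RELAXATION,
            Region(lesion, within=(wp,)), role="lesion",
            carve_from=("PZ", "TZ") + in_body,
        ),
        CompartmentSpec("FBV_left_vessel", 4, blood_tsc, BLOOD_RELAXATION,
                        Region(fbv_l), carve_from=in_body),
        CompartmentSpec("FBV_right_vessel", 5, blood_tsc, BLOOD_RELAXATION,
                        Region(fbv_r), carve_from=in_body),
    ]
    refs = {
        "FBV_left": Region(Cylinder((-42.0, -6.0, 0.0), 4.0, 15.0)),
        "FBV_right": Region(Cylinder((42.0, -6.0, 0.0), 4.0, 15.0)),
    }
    return PhantomGeometry(
        compartments=comps,
        background_tsc=0.0,  # air outside the body
        reference_rois=refs,
        lesion_names=("lesion",),
    )


@dataclass
class PhantomVolume:
    labels: np.ndarray
    tsc_map: np.ndarray
    spacing: np.ndarray
    compartments: list
    origin: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.labels.shape != self.tsc_map.shape:
            raise ValueError("labels and tsc_map must have identical shapes")
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        if self.origin is None:
            self.origin = centered_origin(self.labels.shape, self.spacing)

    def compartment(self, name: str) -> TissueCompartment:
        for c in self.compartments:
            if c.name == name:
                return c
        raise KeyError(name)

    def rederive_tsc_map(self) -> np.ndarray:
        """TSC map recomputed purely from the label volume (invariant check)."""
        lut = np.zeros(max(c.label for c in self.compartments) + 1)
        for c in self.compartments:
            lut[c.label] = c.tsc_true
        return lut[self.labels]


def build_phantom(
    grid_shape=(64, 64, 64),
    spacing=(2.5, 2.5, 2.5),
    geometry: PhantomGeometry | None = None,
) -> tuple:
    """Rasterise a geometry onto a voxel grid.

    Returns ``(PhantomVolume, rois)`` where ``rois`` maps ROI roles (WP,
    PZ, TZ, lesion, contralateral, FBV_left, FBV_right) to ``ROIMask``.

    Raises ``ValueError`` if two compartments overlap without an explicit
    ``carve_from`` declaration, naming the offending pair.
    """
    grid_shape = tuple(int(g) for g in grid_shape)
    if any(g <= 0 for g in grid_shape):
        raise ValueError("grid_shape must be positive")
    spacing = np.asarray(spacing, dtype=float).reshape(3)
    if geometry is None:
        geometry = default_geometry()

    x, y, z = voxel_centers(grid_shape, spacing)
    labels = np.zeros(grid_shape, dtype=np.int16)
    name_of = {0: "background"}
    comp_masks: dict = {}

    for spec in geometry.compartments:
        m = spec.region.mask(x, y, z)
        clash = m & (labels != 0)
        if clash.any():
            hit = np.unique(labels[clash])
            for h in hit:
                if name_of[int(h)] not in spec.carve_from:
                    raise ValueError(
                        f"compartments {spec.name!r} and {name_of[int(h)]!r} overlap "
                        "without a carve_from declaration"
                    )
        labels[m] = spec.label
        name_of[spec.label] = spec.name

    # final masks come from the label volume so carved voxels are excluded
    for spec in geometry.compartments:
        comp_masks[spec.name] = labels == spec.label

    compartments = [
        TissueCompartment(0, "background", geometry.background_tsc, geometry.background_relaxation)
    ] + [
        TissueCompartment(s.label, s.name, s.tsc, s.relaxation) for s in geometry.compartments
    ]
    lut = np.zeros(max(c.label for c in compartments) + 1)
    for c in compartments:
        lut[c.label] = c.tsc_true
    tsc_map = lut[labels]

    phantom = PhantomVolume(labels=labels, tsc_map=tsc_map, spacing=spacing, compartments=compartments)

    rois: dict = {}
    origin = phantom.origin

    def add_roi(role, mask, name=None):
        rois[role if name is None else name] = ROIMask(
            mask=mask, role=role, spacing=spacing.copy(), origin=origin.copy(), name=name or role
        )

    prostate_roles = {"PZ", "TZ", "lesion"}
    wp_mask = np.zeros(grid_shape, bool)
    for spec in geometry.compartments:
        if spec.role in prostate_roles:
            wp_mask |= comp_masks[spec.name]
            add_roi(spec.role, comp_masks[spec.name], name=spec.role)
    if wp_mask.any():
        add_roi("WP", wp_mask)
    for name in geometry.lesion_names:
        lesion_roi = rois.get("lesion")
        if lesion_roi is not None and lesion_roi.n_voxels:
            mirrored = mirror_contralateral(lesion_roi, prostate_mask=wp_mask)
            mirrored.name = "contralateral"
            rois["contralateral"] = mirrored
    for role, region in geometry.reference_rois.items():
        add_roi(role, region.mask(x, y, z))

    return phantom, rois


# ---------------------------------------------------------------------------
# receive sensitivities


@dataclass
class CoilProfile:
    sensitivities: np.ndarray  # (n_channels, nx, ny, nz) complex

    def __post_init__(self) -> None:
        if self.sensitivities.ndim != 4:
            raise ValueError("sensitivities must be (n_channels, nx, ny, nz)")
        if self.n_channels < 1:
            raise ValueError("need at least one channel")
        flat = self.sensitivities.reshape(self.n_channels, -1)
        if not np.all(np.isfinite(flat)):
            raise ValueError("sensitivities must be finite")
        if np.any(np.abs(flat).max(axis=1) == 0):
            raise ValueError("a channel is identically zero")

    @property
    def n_channels(self) -> int:
        return self.sensitivities.shape[0]

    def rss(self) -> np.ndarray:
        return np.sqrt((np.abs(self.sensitivities) ** 2).sum(axis=0))


def simulate_sensitivities(
    grid_shape=(64, 64, 64),
    n_channels: int = 16,
    seed: int = 0,
    spacing=(2.5, 2.5, 2.5),
    constant: bool = False,
) -> CoilProfile:
    """Smooth complex receive fields for a cylindrical loop array.

    Loop elements are placed on two rings around the superior-inferior
    axis just outside the field of view; each element contributes a
    smooth magnitude falloff with distance and a slowly varying phase.
    Deterministic for a given seed (small seeded jitter of the element
    positions and phases); ``constant=True`` returns uniform unit fields.
    """
    if n_channels < 1:
        raise ValueError("n_channels must be >= 1")
    grid_shape = tuple(int(g) for g in grid_shape)
    spacing = np.asarray(spacing, dtype=float).reshape(3)
    if constant:
        sens = np.ones((n_channels,) + grid_shape, dtype=np.complex128)
        return CoilProfile(sens)

    rng = child_rng(seed, "coil-sensitivities")
    x, y, z = voxel_centers(grid_shape, spacing)
    fov = np.asarray(grid_shape) * spacing
    ring_radius = 0.75 * float(np.hypot(fov[0], fov[1])) / 2.0
    falloff = 0.9 * ring_radius

    n_rings = 1 if n_channels <= 8 else 2
    per_ring = int(np.ceil(n_channels / n_rings))
    sens = np.empty((n_channels,) + grid_shape, dtype=np.complex128)
    c = 0
    for ring in range(n_rings):
        z0 = (ring - (n_rings - 1) / 2.0) * 0.5 * fov[2]
        for j in range(per_ring):
            if c >= n_channels:
                break
            phi = 2 * np.pi * j / per_ring + ring * np.pi / per_ring
            phi += rng.normal(scale=0.03)
            cx = ring_radius * np.cos(phi)
            cy = ring_radius * np.sin(phi)
            cz = z0 + rng.normal(scale=0.02 * fov[2])
            d2 = (x - cx) ** 2 + (y - cy) ** 2 + (z - cz) ** 2
            mag = 1.0 / (1.0 + d2 / falloff**2)
            phase = (
                rng.uniform(0, 2 * np.pi)
                + (x * np.cos(phi) + y * np.sin(phi)) * (np.pi / (4 * ring_radius))
                + z * rng.normal(scale=np.pi / (8 * fov[2]))
            )
            sens[c] = mag * np.exp(1j * phase)
            c += 1
    return CoilProfile(sens)


# ---------------------------------------------------------------------------
# signal model and k-space sampling


def steady_state_signal(phantom: PhantomVolume, seq: SequenceParams) -> np.ndarray:
    """Relaxation-weighted signal: tsc * (1 - exp(-TR/T1)) * T2*-decay at TE.

    Uses :func:`natsc.quantify.relaxation_factor`, so the quantification
    stage inverts this model exactly.
    """
    lut = {}
    for comp in phantom.compartments:
        if comp.relaxation is None:
            raise ValueError(f"compartment {comp.name!r} has no relaxation parameters")
        lut[comp.label] = comp.tsc_true * relaxation_factor(comp.relaxation, seq)
    table = np.zeros(max(lut) + 1)
    for label, val in lut.items():
        table[label] = val
    return table[phantom.labels]


@dataclass
class KSpaceData:
    """Per-channel complex radial samples with their trajectory."""

    data: np.ndarray  # (n_channels, n_spokes, n_samples) complex
    trajectory: Trajectory
    noise_sigma: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.data.ndim != 3:
            raise ValueError("k-space data must be (n_channels, n_spokes, n_samples)")
        if self.data.shape[1:] != self.trajectory.coords.shape[:2]:
            raise ValueError("k-space data shape does not match the trajectory")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]


def sample_kspace(
    signal: np.ndarray,
    coils: CoilProfile,
    traj: Trajectory,
    spacing=(2.5, 2.5, 2.5),
    noise_sigma: float = 0.0,
    seed: int = 0,
    method: str = "auto",
) -> KSpaceData:
    """Synthesise multichannel radial k-space data from a signal volume.

    Per channel the coil-weighted image is Fourier-evaluated at the
    trajectory points; complex white Gaussian noise of standard deviation
    ``noise_sigma`` (per real/imaginary part, equal across channels) is
    added.  ``method`` is ``"exact"`` (direct non-uniform DFT),
    ``"gridded"`` (Kaiser-Bessel interpolated FFT) or ``"auto"``, which
    uses the exact evaluation when the product of sample count and
    support size is small enough and the gridded approximation otherwise.
    Deterministic given ``seed``.
    """
    signal = np.asarray(signal)
    if signal.shape != coils.sensitivities.shape[1:]:
        raise ValueError("signal grid does not match the coil profile grid")
    spacing = np.asarray(spacing, dtype=float).reshape(3)
    nyq = 1.0 / (2.0 * spacing)
    if np.any(np.abs(traj.coords.reshape(-1, 3)).max(axis=0) > nyq + 1e-12):
        raise ValueError("trajectory exceeds the Nyquist box of the signal grid")

    n_total = traj.n_spokes * traj.n_samples
    if method == "auto":
        n_support = int(np.count_nonzero(signal))
        method = "exact" if n_total * max(n_support, 1) <= 2e8 else "gridded"
    if method not in ("exact", "gridded"):
        raise ValueError(f"unknown method {method!r}")

    out = np.empty((coils.n_channels, traj.n_spokes, traj.n_samples), dtype=np.complex128)
    for c in range(coils.n_channels):
        weighted = coils.sensitivities[c] * signal
        if method == "exact":
            out[c] = nudft_forward(weighted, spacing, traj.coords)
        else:
            out[c] = nufft_forward(weighted, spacing, traj.coords)

    if noise_sigma > 0:
        rng = child_rng(seed, "kspace-noise")
        noise = rng.standard_normal(out.shape) + 1j * rng.standard_normal(out.shape)
        out = out + noise_sigma * noise

    return KSpaceData(data=out, trajectory=traj, noise_sigma=float(noise_sigma), seed=seed)
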