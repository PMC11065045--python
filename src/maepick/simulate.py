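"""Synthetic low-SNR micrographs with known particle ground truth.

The generator emulates the situation a few-shot particle picker faces: a
large grayscale field containing many copies of one particle motif at
random in-plane orientations, plus non-particle nuisances (elliptical
ice-like blobs, intensity ramps) and additive white Gaussian noise whose
variance is set from a requested signal-to-noise ratio.  It makes no
attempt at physical realism (no CTF, no structured ice): the point is to
give every downstream stage a testable input with exact ground truth.

SNR here is the ratio of particle-signal variance (measured inside
particle footprints) to noise variance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .io import Micrograph, write_coordinates, write_micrograph

MOTIF_KINDS = ("ring", "bar", "trefoil")


@dataclass
class SimParams:
    """Geometry and nuisance settings for one simulated micrograph.

    Defaults are a desk-scale version of typical cryo-EM screening data
    (micrographs of a few thousand pixels with particle diameters of
    ~150 px), shrunk ~4x so a CPU run stays interactive.
    """

    image_height: int = 1024
    image_width: int = 1024
    particle_diameter: int = 64
    n_particles: int = 40
    snr: float = 0.5
    n_contaminants: int = 4
    contaminant_scale_range: tuple = (24.0, 96.0)
    min_center_distance: float = 72.0
    rotation: bool = True
    motif_kind: str = "trefoil"
    seed: int = 0

    def __post_init__(self):
        if self.particle_diameter >= min(self.image_height, self.image_width):
            raise ValueError("particle_diameter must be smaller than the image")
        if self.snr <= 0:
            raise ValueError("snr must be positive")
        if self.motif_kind not in MOTIF_KINDS:
            raise ValueError(f"unknown motif_kind {self.motif_kind!r}; choose from {MOTIF_KINDS}")


@dataclass
class GroundTruth:
    """Known particle centers for one simulated micrograph."""

    micrograph_id: str
    centers: np.ndarray  # (N, 2) float, (x, y)
    diameter: float

    def __post_init__(self):
        self.centers = np.asarray(self.centers, dtype=float).reshape(-1, 2)


def render_particle_motif(diameter: int, orientation: float = 0.0,
                          motif_kind: str = "trefoil") -> np.ndarray:
    """Render one particle motif on a ``diameter x diameter`` patch.

    ``orientation`` is the in-plane rotation in degrees.  The motif is
    evaluated analytically on rotated coordinates, so no interpolation is
    involved.  ``ring`` is rotation-invariant, ``bar`` is 180deg-periodic
    and ``trefoil`` (three Gaussian lobes) is 120deg-periodic.
    Background pixels outside the motif support are zero.
    """
    if diameter < 8:
        raise ValueError("diameter must be >= 8 pixels")
    if motif_kind not in MOTIF_KINDS:
        raise ValueError(f"unknown motif_kind {motif_kind!r}; choose from {MOTIF_KINDS}")
    d = int(diameter)
    c = (d - 1) / 2.0
    yy, xx = np.mgrid[0:d, 0:d]
    x = (xx - c) / d  # normalized, center 0, half-width 0.5
    y = (yy - c) / d
    theta = np.deg2rad(orientation)
    # rotate coordinates into the motif frame
    u = np.cos(theta) * x + np.sin(theta) * y
    v = -np.sin(theta) * x + np.cos(theta) * y
    if motif_kind == "ring":
        r = np.hypot(x, y)
        patch = np.exp(-((r - 0.32) ** 2) / (2 * 0.06**2))
    elif motif_kind == "bar":
        patch = np.exp(-(u**2) / (2 * 0.28**2) - (v**2) / (2 * 0.07**2))
        patch *= (np.abs(u) < 0.45).astype(float)
    else:  # trefoil: three lobes 120 degrees apart
        patch = np.zeros((d, d))
        for ang in (0.0, 2 * np.pi / 3, 4 * np.pi / 3):
            cx_, cy_ = 0.24 * np.cos(ang), 0.24 * np.sin(ang)
            patch += np.exp(-((u - cx_) ** 2 + (v - cy_) ** 2) / (2 * 0.085**2))
    # apodize so nothing leaks outside the nominal footprint
    r = np.hypot(x, y)
    patch = patch * np.clip((0.5 - r) / 0.04, 0.0, 1.0)
    return patch.astype(np.float32)


def _sample_centers(rng: np.random.Generator, params: SimParams) -> np.ndarray:
    """Rejection-sample particle centers with a minimum pairwise distance."""
    margin = params.particle_diameter / 2.0
    lo_x, hi_x = margin, params.image_width - margin
    lo_y, hi_y = margin, params.image_height - margin
    if lo_x >= hi_x or lo_y >= hi_y:
        raise RuntimeError("image too small to inset particle centers by diameter/2")
    centers: list = []
    budget = 1000 * max(params.n_particles, 1)
    attempts = 0
    while len(centers) < params.n_particles:
        if attempts >= budget:
            raise RuntimeError(
                f"could not place {params.n_particles} centers with "
                f"min_center_distance={params.min_center_distance} in "
                f"{params.image_width}x{params.image_height} after {budget} attempts"
            )
        attempts += 1
        cand = np.array([rng.uniform(lo_x, hi_x), rng.uniform(lo_y, hi_y)])
        if centers:
            d = np.linalg.norm(np.asarray(centers) - cand, axis=1)
            if d.min() < params.min_center_distance:
                continue
        centers.append(cand)
    return np.asarray(centers, dtype=float).reshape(-1, 2)


def _add_contaminants(rng: np.random.Generator, image: np.ndarray,
                      params: SimParams, amplitude: float) -> None:
    """Elliptical Gaussian blobs and linear intensity ramps, in place."""
    h, w = image.shape
    yy, xx = np.mgrid[0:h, 0:w]
    lo, hi = params.contaminant_scale_range
    for _ in range(params.n_contaminants):
        if rng.uniform() < 0.75:  # blob
            cx, cy = rng.uniform(0, w), rng.uniform(0, h)
            sx, sy = rng.uniform(lo, hi, size=2)
            ang = rng.uniform(0, np.pi)
            u = np.cos(ang) * (xx - cx) + np.sin(ang) * (yy - cy)
            v = -np.sin(ang) * (xx - cx) + np.cos(ang) * (yy - cy)
            amp = amplitude * rng.uniform(0.5, 1.5) * rng.choice([-1.0, 1.0])
            image += amp * np.exp(-(u**2) / (2 * sx**2) - (v**2) / (2 * sy**2))
        else:  # linear ramp across the field
            gx, gy = rng.normal(size=2)
            ramp = (gx * (xx - w / 2) / w + gy * (yy - h / 2) / h)
            image += amplitude * 0.5 * ramp


def simulate_micrograph(params: SimParams, micrograph_id: str = "sim_000",
                        return_parts: bool = False):
    """Simulate one micrograph and its ground truth.

    The clean particle signal is scaled to unit footprint variance, noise
    sigma is then ``sqrt(1/snr)``, so the empirical footprint-signal to
    noise variance ratio matches ``params.snr`` up to sampling error.
    Identical ``params.seed`` gives bit-identical output.
    """
    rng = np.random.default_rng(params.seed)
    h, w = params.image_height, params.image_width
    d = params.particle_diameter
    signal = np.zeros((h, w), dtype=np.float64)
    centers = (_sample_centers(rng, params) if params.n_particles > 0
               else np.zeros((0, 2)))
    for cx, cy in centers:
        theta = rng.uniform(0.0, 360.0) if params.rotation else 0.0
        patch = render_particle_motif(d, theta, params.motif_kind)
        x0, y0 = int(round(cx - (d - 1) / 2)), int(round(cy - (d - 1) / 2))
        signal[y0 : y0 + d, x0 : x0 + d] += patch

    # scale signal so footprint variance is 1, then sigma = sqrt(1/snr)
    if len(centers):
        fp = _footprint_mask((h, w), centers, d)
        sig_var = signal[fp].var()
        if sig_var > 0:
            signal /= np.sqrt(sig_var)
        amplitude = signal[fp].max() if signal[fp].size else 1.0
    else:
        amplitude = 1.0
    sigma = float(np.sqrt(1.0 / params.snr))

    contaminants = np.zeros((h, w), dtype=np.float64)
    if params.n_contaminants > 0:
        _add_contaminants(rng, contaminants, params, 0.3 * amplitude)
    noise = rng.normal(0.0, sigma, size=(h, w))
    image = (signal + contaminants + noise).astype(np.float32)
    mic = Micrograph(image, micrograph_id=micrograph_id)
    gt = GroundTruth(micrograph_id, centers, float(d))
    if return_parts:
        return mic, gt, {"signal": signal.astype(np.float32),
                         "contaminants": contaminants.astype(np.float32),
                         "noise": noise.astype(np.float32), "sigma": sigma}
    return mic, gt


def _footprint_mask(shape: tuple, centers: np.ndarray, diameter: float) -> np.ndarray:
    """Boolean mask of pixels within diameter/2 of any particle center."""
    h, w = shape
    mask = np.zeros((h, w), dtype=bool)
    r = diameter / 2.0
    for cx, cy in np.atleast_2d(centers):
        x0, x1 = max(0, int(cx - r)), min(w, int(cx + r) + 1)
        y0, y1 = max(0, int(cy - r)), min(h, int(cy + r) + 1)
        yy, xx = np.mgrid[y0:y1, x0:x1]
        mask[y0:y1, x0:x1] |= (xx - cx) ** 2 + (yy - cy) ** 2 <= r**2
    return mask


def empirical_snr(image: np.ndarray, gt: GroundTruth) -> float:
    """Estimate footprint-signal variance over noise variance from one image.

    Noise variance is taken from background pixels (outside all particle
    footprints); the signal variance is the excess variance inside the
    footprints.  Only meaningful without contaminants.
    """
    fp = _footprint_mask(image.shape, gt.centers, gt.diameter)
    var_bg = float(image[~fp].var())
    var_fp = float(image[fp].var())
    return max(var_fp - var_bg, 0.0) / var_bg


@dataclass
class DatasetBundle:
    """One reference micrograph (with exemplar coordinates) plus queries."""

    reference: Micrograph
    reference_truth: GroundTruth
    exemplar_centers: np.ndarray  # (m, 2) subset of reference_truth.centers
    queries: list = field(default_factory=list)  # [(Micrograph, GroundTruth)]
    params: SimParams | None = None
    extra_references: list = field(default_factory=list)  # [(Micrograph, GroundTruth)]

    @property
    def micrographs(self) -> list:
        return [self.reference] + [m for m, _ in self.queries]

    def save(self, out_dir: str | Path) -> Path:
        """Write MRC micrographs + STAR ground truth / exemplar files."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        pairs = ([(self.reference, self.reference_truth)]
                 + list(self.extra_references) + list(self.queries))
        for mic, gt in pairs:
            write_micrograph(mic, out / f"{mic.micrograph_id}.mrc")
            write_coordinates(out / f"{mic.micrograph_id}_gt.star",
                              gt.centers, f"{mic.micrograph_id}.mrc")
        write_coordinates(out / "exemplars.star", self.exemplar_centers,
                          f"{self.reference.micrograph_id}.mrc")
        return out


def make_dataset(params: SimParams, n_reference: int = 1, n_query: int = 3,
                 n_exemplars: int = 15) -> DatasetBundle:
    """Simulate a reference micrograph plus query micrographs.

    All micrographs share the motif and ``SimParams`` except the seed
    (query i uses ``params.seed + 1 + i``).  ``n_exemplars`` ground-truth
    centers of the reference are designated as the labeled exemplars.
    """
    if n_reference < 1:
        raise ValueError("n_reference must be >= 1")
    ref_mic, ref_gt = simulate_micrograph(params, micrograph_id="reference_000")
    if n_exemplars > len(ref_gt.centers):
        warnings.warn(
            f"requested {n_exemplars} exemplars but only {len(ref_gt.centers)} "
            "particles exist; using all of them", stacklevel=2)
        n_exemplars = len(ref_gt.centers)
    rng = np.random.default_rng(params.seed + 7919)
    idx = rng.choice(len(ref_gt.centers), size=n_exemplars, replace=False)
    exemplars = ref_gt.centers[np.sort(idx)]
    extra = []
    for i in range(n_reference - 1):
        rp = replace(params, seed=params.seed + 10007 + i)
        extra.append(simulate_micrograph(rp, micrograph_id=f"reference_{i + 1:03d}"))
    queries = []
    for i in range(n_query):
        qp = replace(params, seed=params.seed + 1 + i)
        queries.append(simulate_micrograph(qp, micrograph_id=f"query_{i:03d}"))
    return DatasetBundle(ref_mic, ref_gt, exemplars, queries, params, extra)
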