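"""Synthetic microscopy fields with known ground truth.

The generator emulates the statistical structure the pipeline assumes:
non-dividing fibroblast nuclei rendered as smooth discs on the DAPI plane
(DNA content scaling with cell-cycle class), and two damage-marker channels
in which genuine repair foci appear as bright, compact Gaussian blobs
co-localized across channels at one sharp focal plane per cell, while
unspecific background speckles are dimmer, more diffuse and placed independently
per channel.  Per-channel additive Gaussian noise and a smooth background
gradient complete the picture; output is clipped to [0, 255] and quantized
to 8 bits.  It does not attempt photorealistic optics (no PSF model, no
camera-specific noise).

Default numbers reflect the acquisition regime the pipeline targets:
~120 px nucleus crops at 8 bits, a low spontaneous-to-low-dose foci count
(Poisson mean 2 per cell by default, configurable down to 0.3), and
background speckles outnumbering robust foci roughly 10-20 fold.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .core import FieldImage, N_PLANES


class PlacementError(RuntimeError):
    """Raised when nuclei cannot be placed without overlap."""


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic field.

    ``speckle_rate`` is the expected number of background signals per
    nucleus and per channel; with the default foci rate of 2 per cell the
    default of 30 keeps background signals 10-20x more numerous than foci.
    ``colocalization`` is the fraction of foci planted in both channels
    (the rest go to a single random channel); foci co-localize in G0/G1, so
    the default is 1.  ``zstack_defocus_sigmas`` give the extra Gaussian
    blur applied at increasing z-distance from a cell's focal plane.
    """

    field_size_px: tuple[int, int] = (520, 390)
    n_nuclei: int = 6
    nucleus_radius_px: tuple[float, float] = (28.0, 2.0)  # mean, sd
    foci_per_cell: float = 2.0
    focus_amplitude: float = 200.0
    focus_sigma_px: float = 1.5
    # background speckles emulate unspecific staining artefacts: dimmer and
    # more diffuse (less compact) than genuine repair foci; their amplitude
    # must stay low enough that overlapping speckles remain below half a
    # focus peak, or adjacent speckles fuse into detected foci objects
    speckle_rate: float = 30.0
    speckle_amplitude_frac: tuple[float, float] = (0.12, 0.22)
    speckle_sigma_frac: tuple[float, float] = (1.3, 1.7)
    # bright focus-like artifacts (dust, debris, unspecific binding) appear
    # in a single random channel; they are indistinguishable from foci for
    # any one-channel scorer and are only resolved by channel combination
    artifact_rate: float = 0.0
    artifact_amplitude_frac: tuple[float, float] = (0.7, 1.1)
    artifact_sigma_frac: tuple[float, float] = (0.9, 1.1)
    colocalization: float = 1.0
    channel_noise_sd: float = 1.5
    background_gradient: float = 6.0
    marker_background: float = 25.0
    dapi_level: float = 120.0
    frac_s_g2: float = 0.0
    frac_dying: float = 0.0
    zstack_defocus_sigmas: tuple[float, ...] = (0.0, 1.5, 3.0, 4.5, 6.0)
    rng_seed: int = 0

    def validate(self) -> None:
        if self.n_nuclei < 0 or self.foci_per_cell < 0 or self.speckle_rate < 0:
            raise ValueError("counts and rates must be >= 0")
        if self.focus_amplitude <= 0 or self.focus_sigma_px <= 0:
            raise ValueError("focus amplitude and sigma must be > 0")
        if not 0 <= self.colocalization <= 1:
            raise ValueError("colocalization must be in [0, 1]")
        if len(self.zstack_defocus_sigmas) != N_PLANES:
            raise ValueError(f"need {N_PLANES} defocus sigmas")
        area_needed = self.n_nuclei * np.pi * (2 * self.nucleus_radius_px[0]) ** 2
        if area_needed > self.field_size_px[0] * self.field_size_px[1]:
            raise ValueError("field too small for the requested nuclei")


@dataclass
class NucleusTruth:
    centre: tuple[float, float]
    radius: float
    cycle_class: str  # "G1" | "S-G2" | "dying"
    focal_plane: int
    foci: list = field(default_factory=list)  # (row, col, amplitude, channels)
    speckles_red: list = field(default_factory=list)  # (row, col, amplitude, sigma)
    speckles_green: list = field(default_factory=list)
    artifacts: list = field(default_factory=list)  # (row, col, amplitude, sigma, channel)


@dataclass
class GroundTruth:
    """Planted truth of one field: per-nucleus centres, masks (implicit via
    centre + radius), cycle classes and all planted signal positions."""

    field_size_px: tuple[int, int]
    nuclei: list[NucleusTruth] = field(default_factory=list)

    @property
    def n_foci_total(self) -> int:
        return sum(len(n.foci) for n in self.nuclei)

    def foci_per_cell(self, classes: tuple[str, ...] = ("G1",)) -> float:
        sel = [n for n in self.nuclei if n.cycle_class in classes]
        if not sel:
            return 0.0
        return sum(len(n.foci) for n in sel) / len(sel)


def _place_nuclei(spec: SyntheticSpec, rng: np.random.Generator) -> list[tuple[float, float, float]]:
    """Rejection-sample non-overlapping nucleus centres; margin keeps the
    crop window inside the field."""
    h, w = spec.field_size_px
    margin = 62.0  # half the default 120 px crop window plus slack
    placed: list[tuple[float, float, float]] = []
    for _ in range(spec.n_nuclei):
        radius = max(5.0, rng.normal(*spec.nucleus_radius_px))
        for _attempt in range(500):
            r = rng.uniform(margin, h - margin)
            c = rng.uniform(margin, w - margin)
            if all(np.hypot(r - pr, c - pc) > radius + prad + 6 for pr, pc, prad in placed):
                placed.append((r, c, radius))
                break
        else:
            raise PlacementError("could not place all nuclei without overlap")
    return placed


def _soft_disc(shape: tuple[int, int], centre: tuple[float, float], radius: float) -> np.ndarray:
    """Disc with a ~2 px soft edge, values in [0, 1]."""
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    dist = np.hypot(rr - centre[0], cc - centre[1])
    return np.clip((radius - dist) / 2.0 + 0.5, 0.0, 1.0)


def _add_blob(img: np.ndarray, centre: tuple[float, float], amplitude: float, sigma: float) -> None:
    r0, c0 = centre
    n = int(np.ceil(4 * sigma))
    rlo, rhi = max(0, int(r0) - n), min(img.shape[0], int(r0) + n + 1)
    clo, chi = max(0, int(c0) - n), min(img.shape[1], int(c0) + n + 1)
    rr, cc = np.mgrid[rlo:rhi, clo:chi]
    img[rlo:rhi, clo:chi] += amplitude * np.exp(
        -((rr - r0) ** 2 + (cc - c0) ** 2) / (2 * sigma**2)
    )


def generate_field(
    spec: SyntheticSpec, quantize: bool = True
) -> tuple[FieldImage, GroundTruth]:
    """Render one field and its ground truth.

    Foci and speckles are rendered before noise; with ``quantize=False``
    the float pathway (no clipping/quantization) is returned, which is the
    scale-invariant regime used by algebraic tests.  Identical spec + seed
    produce bit-identical output.
    """
    spec.validate()
    rng = np.random.default_rng(spec.rng_seed)
    h, w = spec.field_size_px
    truth = GroundTruth(field_size_px=(h, w))

    dapi = np.zeros((h, w), dtype=float)
    # per-nucleus signal patches (bounding-box windows) are blurred per
    # plane individually, so defocus stays local and cheap
    per_cell_layers: list[tuple[tuple[slice, slice], dict[str, np.ndarray]]] = []

    if spec.n_nuclei > 0:
        placements = _place_nuclei(spec, rng)
    else:
        placements = []

    for r0, c0, radius in placements:
        u = rng.uniform()
        if u < spec.frac_dying:
            cycle = "dying"
            disc = _soft_disc((h, w), (r0, c0), 0.5 * radius) * (2.5 * spec.dapi_level)
        elif u < spec.frac_dying + spec.frac_s_g2:
            cycle = "S-G2"
            disc = _soft_disc((h, w), (r0, c0), radius) * (2.0 * spec.dapi_level)
        else:
            cycle = "G1"
            disc = _soft_disc((h, w), (r0, c0), radius) * spec.dapi_level
        dapi += disc
        focal = int(rng.integers(0, N_PLANES))
        nucleus = NucleusTruth(
            centre=(r0, c0), radius=radius, cycle_class=cycle, focal_plane=focal
        )
        eff_radius = radius * (0.5 if cycle == "dying" else 1.0)

        # patch window: nucleus plus room for the deepest defocus blur
        pad = int(np.ceil(radius + 4 * max(spec.zstack_defocus_sigmas) + 8))
        rlo, rhi = max(0, int(r0) - pad), min(h, int(r0) + pad + 1)
        clo, chi = max(0, int(c0) - pad), min(w, int(c0) + pad + 1)
        win = (slice(rlo, rhi), slice(clo, chi))
        pshape = (rhi - rlo, chi - clo)
        pr0, pc0 = r0 - rlo, c0 - clo  # nucleus centre in patch coordinates

        layers = {"red": np.zeros(pshape), "green": np.zeros(pshape)}
        # marker baseline inside the nucleus (chromatin-bound background)
        base = _soft_disc(pshape, (pr0, pc0), eff_radius) * spec.marker_background
        layers["red"] += base
        layers["green"] += base
        if cycle == "dying":
            # pan-nuclear gammaH2AX signal of apoptotic cells
            layers["green"] += _soft_disc(pshape, (pr0, pc0), eff_radius) * 4 * spec.marker_background

        n_foci = int(rng.poisson(spec.foci_per_cell))
        for _ in range(n_foci):
            rho = eff_radius * 0.7 * np.sqrt(rng.uniform())
            ang = rng.uniform(0, 2 * np.pi)
            fr, fc = r0 + rho * np.cos(ang), c0 + rho * np.sin(ang)
            amp = spec.focus_amplitude * rng.uniform(0.8, 1.2)
            if rng.uniform() < spec.colocalization:
                channels = ("red", "green")
            else:
                channels = (("red",) if rng.uniform() < 0.5 else ("green",))
            for ch in channels:
                _add_blob(layers[ch], (fr - rlo, fc - clo), amp, spec.focus_sigma_px)
            nucleus.foci.append((fr, fc, amp, list(channels)))

        for ch, store in (("red", nucleus.speckles_red), ("green", nucleus.speckles_green)):
            n_spk = int(rng.poisson(spec.speckle_rate))
            for _ in range(n_spk):
                rho = eff_radius * 0.85 * np.sqrt(rng.uniform())
                ang = rng.uniform(0, 2 * np.pi)
                sr, sc = r0 + rho * np.cos(ang), c0 + rho * np.sin(ang)
                amp = spec.focus_amplitude * rng.uniform(*spec.speckle_amplitude_frac)
                sigma = spec.focus_sigma_px * rng.uniform(*spec.speckle_sigma_frac)
                _add_blob(layers[ch], (sr - rlo, sc - clo), amp, sigma)
                store.append((sr, sc, amp, sigma))

        n_art = int(rng.poisson(spec.artifact_rate))
        for _ in range(n_art):
            rho = eff_radius * 0.7 * np.sqrt(rng.uniform())
            ang = rng.uniform(0, 2 * np.pi)
            ar, ac = r0 + rho * np.cos(ang), c0 + rho * np.sin(ang)
            amp = spec.focus_amplitude * rng.uniform(*spec.artifact_amplitude_frac)
            sigma = spec.focus_sigma_px * rng.uniform(*spec.artifact_sigma_frac)
            ch = "red" if rng.uniform() < 0.5 else "green"
            _add_blob(layers[ch], (ar - rlo, ac - clo), amp, sigma)
            nucleus.artifacts.append((ar, ac, amp, sigma, ch))

        truth.nuclei.append(nucleus)
        per_cell_layers.append((win, layers))

    # assemble z-stacks: each cell's layer blurred according to the distance
    # of the plane from that cell's focal plane
    from scipy.ndimage import gaussian_filter

    stacks = {
        "red": np.zeros((N_PLANES, h, w), dtype=float),
        "green": np.zeros((N_PLANES, h, w), dtype=float),
    }
    for nucleus, (win, layers) in zip(truth.nuclei, per_cell_layers):
        for p in range(N_PLANES):
            sigma = spec.zstack_defocus_sigmas[min(abs(p - nucleus.focal_plane), N_PLANES - 1)]
            for ch in ("red", "green"):
                patch = layers[ch] if sigma == 0 else gaussian_filter(layers[ch], sigma)
                stacks[ch][(p,) + win] += patch

    # background gradient + noise, per channel
    grad = np.linspace(0.0, 1.0, w)[None, :] * np.ones((h, 1))
    for ch in ("red", "green"):
        stacks[ch] += spec.background_gradient * grad
        stacks[ch] += rng.normal(0.0, spec.channel_noise_sd, size=stacks[ch].shape)
    dapi += rng.normal(0.0, spec.channel_noise_sd, size=dapi.shape)

    if quantize:
        dapi = np.clip(np.rint(dapi), 0, 255).astype(np.uint8)
        for ch in ("red", "green"):
            stacks[ch] = np.clip(np.rint(stacks[ch]), 0, 255).astype(np.uint8)

    field_img = FieldImage(
        dapi=dapi,
        red_stack=stacks["red"],
        green_stack=stacks["green"],
        name=f"synthetic_{spec.rng_seed}",
    )
    return field_img, truth


def generate_oep_mixture(
    n_bg: int,
    n_foci: int,
    bg_logmean: float = -1.0,
    bg_logsd: float = 0.5,
    foci_logmean: float = 2.0,
    foci_logsd: float = 0.5,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Labelled log-normal OEP sample emulating the bimodal score
    distribution, for testing thresholding without images.

    Returns ``(values, labels)`` with label 1 = focus.  Log-means/-sds are
    base-10.
    """
    if n_bg < 0 or n_foci < 0:
        raise ValueError("counts must be >= 0")
    if bg_logsd <= 0 or foci_logsd <= 0:
        raise ValueError("log-sds must be > 0")
    rng = np.random.default_rng(seed)
    bg = 10.0 ** rng.normal(bg_logmean, bg_logsd, size=n_bg)
    fg = 10.0 ** rng.normal(foci_logmean, foci_logsd, size=n_foci)
    values = np.concatenate([bg, fg])
    labels = np.concatenate([np.zeros(n_bg, dtype=int), np.ones(n_foci, dtype=int)])
    return values, labels


def write_field(field_img: FieldImage, truth: GroundTruth, path: str | Path) -> None:
    """Write a field as a multi-page TIFF (page order: DAPI, red z1-z5,
    green z1-z5) with a ground-truth JSON sidecar."""
    import tifffile

    path = Path(path)
    pages = [field_img.dapi] + list(field_img.red_stack) + list(field_img.green_stack)
    tifffile.imwrite(path, np.stack(pages), photometric="minisblack")
    sidecar = path.with_suffix(".truth.json")
    sidecar.write_text(json.dumps(asdict(truth), indent=1))
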