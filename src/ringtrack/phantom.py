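"""Synthetic multi-channel microscopy phantoms with known ground truth.

The generator renders fields that emulate 20x widefield screening images
of adherent cells: elliptical nuclei (semi-axes 18-45 px, i.e. areas of
roughly 1000-6400 px^2) on a dim background, a DAPI channel for
segmentation and a gamma-H2AX channel carrying one of three patterns per
nucleus:

UNIFORM   flat nuclear signal at ``gh2ax_base``;
FOCI      flat base plus well-separated Gaussian puncta whose count
          scales with nucleus area so that the true foci density always
          exceeds the screening cutoff while spots stay resolvable;
RING      base signal scaled by ``ring_amplitude_ratio`` in the outer
          ``ring_band_fraction`` of the elliptical radial coordinate,
          which analytically satisfies the peripheral-quartile rule
          before any noise is added.

Noise is shot (Poisson) and/or read (Gaussian) noise, applied after
rendering and clipped to the bit-depth range.  Everything is driven by
one seed, so identical specs give bit-identical fields.

The phantom deliberately omits chromatin texture, optics (PSF), uneven
illumination and touching nuclei; it validates the measurement rules,
not the microscope.
"""

from __future__ import annotations

import math
import re as _re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import ChannelImage, ChannelRole, FieldOfView, Phenotype

__all__ = [
    "NoiseModel",
    "PhantomSpec",
    "analytic_ring_score",
    "apportion_phenotypes",
    "generate_field",
    "degrade",
    "match_nuclei_to_truth",
]


class PlacementError(Exception):
    """Raised when the requested nuclei cannot be placed without overlap."""


@dataclass(frozen=True)
class NoiseModel:
    """Shot/read noise description: Poisson resampling and/or additive
    zero-mean Gaussian of the given standard deviation."""

    poisson: bool = False
    gaussian_sd: float = 0.0

    @classmethod
    def parse(cls, text: str) -> "NoiseModel":
        """Parse ``none``, ``poisson``, ``gaussian(sd)`` or
        ``poisson+gaussian(sd)``."""
        text = text.strip().lower()
        if text == "none":
            return cls()
        poisson = False
        sd = 0.0
        for part in text.split("+"):
            part = part.strip()
            if part == "poisson":
                poisson = True
            else:
                m = _re.fullmatch(r"gaussian\(([0-9.eE+-]+)\)", part)
                if not m:
                    raise ValueError(f"unrecognised noise model component: {part!r}")
                sd = float(m.group(1))
        return cls(poisson=poisson, gaussian_sd=sd)

    @property
    def is_identity(self) -> bool:
        return not self.poisson and self.gaussian_sd == 0


def analytic_ring_score(band_fraction: float, amplitude_ratio: float) -> float:
    """Ring score of the ideal two-level radial profile.

    The profile is 1 for radial coordinate below ``1 - band_fraction``
    and ``amplitude_ratio`` in the outer band; quartile split at 0.75.
    The base intensity cancels, so the score is dimensionless.
    """
    s = 1.0 - band_fraction
    r = amplitude_ratio
    overall = s + (1.0 - s) * r
    if s >= 0.75:
        q123 = 1.0
        q4 = ((s - 0.75) * 1.0 + (1.0 - s) * r) / 0.25
    else:
        q123 = (s * 1.0 + (0.75 - s) * r) / 0.75
        q4 = r
    return (q4 - q123) / overall


def apportion_phenotypes(
    n_nuclei: int, phenotype_mix: dict[Phenotype, float]
) -> dict[Phenotype, int]:
    """Split ``n_nuclei`` across phenotypes by largest remainder, so a
    (1/3, 1/3, 1/3) mix of 30 nuclei yields exactly 10 of each."""
    order = [Phenotype.FOCI, Phenotype.RING, Phenotype.UNIFORM]
    props = {Phenotype(k): float(v) for k, v in phenotype_mix.items()}
    quotas = {p: n_nuclei * props.get(p, 0.0) for p in order}
    counts = {p: int(math.floor(q)) for p, q in quotas.items()}
    short = n_nuclei - sum(counts.values())
    by_remainder = sorted(order, key=lambda p: quotas[p] - counts[p], reverse=True)
    for p in by_remainder[:short]:
        counts[p] += 1
    return counts


@dataclass
class PhantomSpec:
    """Parameters of one synthetic field.

    Intensity defaults are on a 16-bit scale and chosen so that each
    decision rule has a clear margin under shot noise plus a read noise
    of a few percent of the nuclear DAPI level: nuclear signals sit well
    above background, foci at 4x the nuclear gamma-H2AX base, the ring
    band at 2x.  ``axis_ratio_max`` defaults to 1.6 so every rendered
    ellipse has eccentricity below the 0.8 segmentation filter
    (eccentricity sqrt(1 - 1/1.6^2) = 0.78); raise it to render
    deliberately elongated, filter-violating objects.
    """

    n_nuclei: int = 30
    phenotype_mix: dict = field(
        default_factory=lambda: {
            Phenotype.FOCI: 1 / 3,
            Phenotype.RING: 1 / 3,
            Phenotype.UNIFORM: 1 / 3,
        }
    )
    field_size_px: tuple[int, int] = (1024, 1024)
    axis_range_px: tuple[float, float] = (18.0, 45.0)
    axis_ratio_max: float = 1.6
    dapi_level: float = 2000.0
    dapi_background: float = 100.0
    gh2ax_base: float = 2000.0
    gh2ax_background: float = 1600.0
    focus_sigma_px: float = 2.0
    focus_amplitude: float = 8000.0
    foci_density_range: tuple[float, float] = (0.005, 0.0075)
    foci_per_nucleus_range: tuple[int, int] | None = None
    foci_density_cutoff: float = 0.0035
    ring_band_fraction: float = 0.25
    ring_amplitude_ratio: float = 2.0
    p53bp1_mode: str = "absent"
    noise_model: NoiseModel | str = "none"
    bit_depth: int = 16
    min_clearance_px: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.noise_model, str):
            self.noise_model = NoiseModel.parse(self.noise_model)
        self.phenotype_mix = {Phenotype(k): float(v) for k, v in self.phenotype_mix.items()}
        total = sum(self.phenotype_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"phenotype proportions sum to {total}, not 1")
        if self.p53bp1_mode not in ("absent", "copy_foci", "independent"):
            raise ValueError(f"unknown p53bp1_mode {self.p53bp1_mode!r}")
        lo, hi = self.axis_range_px
        if not 0 < lo <= hi:
            raise ValueError("axis_range_px must satisfy 0 < min <= max")
        # construction guarantees: every FOCI nucleus must clear the
        # density cutoff, and the ideal ring profile must clear the 10%
        # quartile rule
        if self.foci_per_nucleus_range is not None:
            max_area = math.pi * hi * hi
            if self.foci_per_nucleus_range[0] <= self.foci_density_cutoff * max_area:
                raise ValueError(
                    "foci_per_nucleus_range lower bound does not guarantee the "
                    f"density cutoff for the largest nucleus ({max_area:.0f} px^2)"
                )
        elif self.foci_density_range[0] <= self.foci_density_cutoff:
            raise ValueError(
                "foci_density_range lower bound must exceed the density cutoff"
            )
        if analytic_ring_score(self.ring_band_fraction, self.ring_amplitude_ratio) <= 0.10:
            raise ValueError("ring band/amplitude do not satisfy the peripheral quartile rule")


def _place_nuclei(spec: PhantomSpec, rng: np.random.Generator):
    """Rejection-sample non-overlapping ellipse geometries."""
    h, w = spec.field_size_px
    lo, hi = spec.axis_range_px
    placed: list[tuple[float, float, float, float, float]] = []  # (row, col, a, b, theta)
    failures = 0
    while len(placed) < spec.n_nuclei:
        if failures > 10 * spec.n_nuclei:
            raise PlacementError(
                f"could not place {spec.n_nuclei} nuclei in a {h}x{w} field "
                f"after {failures} failed attempts"
            )
        b = rng.uniform(lo, hi)
        a = min(b * rng.uniform(1.0, spec.axis_ratio_max), hi)
        theta = rng.uniform(0.0, math.pi)
        margin = a + 6.0
        if h - margin <= margin or w - margin <= margin:
            raise PlacementError("nuclei too large for the field")
        row = rng.uniform(margin, h - margin)
        col = rng.uniform(margin, w - margin)
        ok = all(
            math.hypot(row - r0, col - c0) > a + a0 + spec.min_clearance_px
            for r0, c0, a0, _, _ in placed
        )
        if ok:
            placed.append((row, col, a, b, theta))
        else:
            failures += 1
    return placed


def _elliptical_radius(rr, cc, row, col, a, b, theta):
    dr, dc = rr - row, cc - col
    u = dc * math.cos(theta) + dr * math.sin(theta)
    v = -dc * math.sin(theta) + dr * math.cos(theta)
    return np.sqrt((u / a) ** 2 + (v / b) ** 2)


def _draw_foci_count(spec: PhantomSpec, a: float, b: float, rng: np.random.Generator) -> int:
    """Number of foci for a nucleus with semi-axes ``a``, ``b``.

    By default the count scales with the analytic nucleus area via a
    density drawn from ``foci_density_range`` (above the cutoff by
    construction), which keeps spot spacing resolvable in nuclei of any
    permitted size; ``foci_per_nucleus_range`` overrides with a fixed
    count range."""
    if spec.foci_per_nucleus_range is not None:
        lo, hi = spec.foci_per_nucleus_range
        return int(rng.integers(lo, hi + 1))
    density = rng.uniform(*spec.foci_density_range)
    return max(1, int(round(math.pi * a * b * density)))


def _place_foci(
    n: int, row: float, col: float, a: float, b: float, theta: float, rng: np.random.Generator
) -> np.ndarray:
    """Focus centres inside the nucleus (radial coordinate < 0.8) with a
    minimum pairwise separation, relaxed stepwise if the nucleus is too
    crowded to honour the initial spacing."""
    for min_sep in (12.0, 10.0, 8.0, 7.0, 6.0, 5.0, 4.0, 3.0, 0.0):
        pts: list[tuple[float, float]] = []
        for _ in range(400 * n):
            t = rng.uniform(0.0, 2 * math.pi)
            rho = 0.8 * math.sqrt(rng.uniform(0.0, 1.0))
            u, v = rho * a * math.cos(t), rho * b * math.sin(t)
            pr = row + u * math.sin(theta) + v * math.cos(theta)
            pc = col + u * math.cos(theta) - v * math.sin(theta)
            if all(math.hypot(pr - q[0], pc - q[1]) >= min_sep for q in pts):
                pts.append((pr, pc))
                if len(pts) == n:
                    return np.asarray(pts)
    raise PlacementError(f"could not place {n} foci in nucleus at ({row:.0f},{col:.0f})")


def generate_field(
    spec: PhantomSpec, field_id: str = "phantom", condition: str = "phantom"
) -> tuple[FieldOfView, pd.DataFrame]:
    """Render one synthetic field and its per-nucleus ground truth.

    Returns the (optionally noisy) :class:`FieldOfView` and a table with
    one row per nucleus: id, centroid, semi-axes, orientation, true
    phenotype, true focus count and rendered pixel area.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.field_size_px
    dapi = np.full((h, w), float(spec.dapi_background))
    gh2ax = np.full((h, w), float(spec.gh2ax_background))
    p53 = np.full((h, w), float(spec.gh2ax_background)) if spec.p53bp1_mode != "absent" else None

    geometries = _place_nuclei(spec, rng)
    counts = apportion_phenotypes(spec.n_nuclei, spec.phenotype_mix)
    labels = [p for p in (Phenotype.FOCI, Phenotype.RING, Phenotype.UNIFORM) for _ in range(counts[p])]
    rng.shuffle(labels)

    rows = []
    for nucleus_id, ((row, col, a, b, theta), phenotype) in enumerate(
        zip(geometries, labels), start=1
    ):
        pad = int(math.ceil(a)) + 2
        r0, r1 = max(0, int(row) - pad), min(h, int(row) + pad + 1)
        c0, c1 = max(0, int(col) - pad), min(w, int(col) + pad + 1)
        rr, cc = np.mgrid[r0:r1, c0:c1]
        re_ = _elliptical_radius(rr, cc, row, col, a, b, theta)
        inside = re_ <= 1.0
        area = int(inside.sum())
        dapi[r0:r1, c0:c1][inside] = spec.dapi_level

        patch = np.full(inside.shape, float(spec.gh2ax_base))
        n_foci = 0
        foci_pts = np.empty((0, 2))
        if phenotype is Phenotype.RING:
            band = re_ >= 1.0 - spec.ring_band_fraction
            patch[band] = spec.gh2ax_base * spec.ring_amplitude_ratio
        elif phenotype is Phenotype.FOCI:
            n_foci = _draw_foci_count(spec, a, b, rng)
            foci_pts = _place_foci(n_foci, row, col, a, b, theta, rng)
            for pr, pc in foci_pts:
                patch += spec.focus_amplitude * np.exp(
                    -((rr - pr) ** 2 + (cc - pc) ** 2) / (2.0 * spec.focus_sigma_px**2)
                )
        gh2ax[r0:r1, c0:c1][inside] = patch[inside]

        if p53 is not None:
            if spec.p53bp1_mode == "copy_foci":
                p53[r0:r1, c0:c1][inside] = patch[inside]
            else:  # independent: own spots regardless of gamma-H2AX pattern
                n_own = _draw_foci_count(spec, a, b, rng)
                own = _place_foci(n_own, row, col, a, b, theta, rng)
                ppatch = np.full(inside.shape, float(spec.gh2ax_base))
                for pr, pc in own:
                    ppatch += spec.focus_amplitude * np.exp(
                        -((rr - pr) ** 2 + (cc - pc) ** 2) / (2.0 * spec.focus_sigma_px**2)
                    )
                p53[r0:r1, c0:c1][inside] = ppatch[inside]

        rows.append(
            {
                "nucleus_id": nucleus_id,
                "centroid_row": row,
                "centroid_col": col,
                "semi_axis_a": a,
                "semi_axis_b": b,
                "orientation_rad": theta,
                "true_phenotype": phenotype.value,
                "true_foci_count": n_foci,
                "area_px": area,
            }
        )

    limit = 2**spec.bit_depth - 1
    channels = {
        ChannelRole.DAPI: _quantize(dapi, limit, spec.bit_depth),
        ChannelRole.GH2AX: _quantize(gh2ax, limit, spec.bit_depth),
    }
    if p53 is not None:
        channels[ChannelRole.P53BP1] = _quantize(p53, limit, spec.bit_depth)
    fov = FieldOfView(channels=channels, field_id=field_id, condition=condition)
    if not spec.noise_model.is_identity:
        fov = degrade(fov, spec.noise_model, seed=int(rng.integers(0, 2**31 - 1)))
    return fov, pd.DataFrame(rows)


def _quantize(img: np.ndarray, limit: int, bit_depth: int) -> ChannelImage:
    arr = np.clip(np.rint(img), 0, limit).astype(np.uint16 if bit_depth == 16 else np.uint8)
    return ChannelImage(pixels=arr, channel_role=ChannelRole.OTHER, bit_depth=bit_depth)


def degrade(fov: FieldOfView, noise_model: NoiseModel | str, seed: int) -> FieldOfView:
    """Apply shot/read noise to every channel, clipping to the bit depth.

    Poisson noise resamples each pixel as Poisson with the clean value
    as mean (shot noise); Gaussian noise adds zero-mean read noise of
    the given standard deviation.  A fresh sub-seed per channel keeps
    channels independent; the identity model returns the field as is.
    """
    if isinstance(noise_model, str):
        noise_model = NoiseModel.parse(noise_model)
    if noise_model.is_identity:
        return fov
    rng = np.random.default_rng(seed)
    noisy = {}
    for role in sorted(fov.channels, key=lambda r: r.value):
        chan = fov.channels[role]
        img = chan.pixels.astype(np.float64)
        if noise_model.poisson:
            img = rng.poisson(img).astype(np.float64)
        if noise_model.gaussian_sd > 0:
            img = img + rng.normal(0.0, noise_model.gaussian_sd, size=img.shape)
        limit = 2**chan.bit_depth - 1
        noisy[role] = ChannelImage(
            pixels=np.clip(np.rint(img), 0, limit).astype(chan.pixels.dtype),
            channel_role=role,
            bit_depth=chan.bit_depth,
        )
    return FieldOfView(
        channels=noisy,
        field_id=fov.field_id,
        condition=fov.condition,
        pixel_size_um=fov.pixel_size_um,
        magnification=fov.magnification,
    )


def match_nuclei_to_truth(records, truth: pd.DataFrame) -> dict[int, int]:
    """Match segmented nuclei to ground-truth rows by nearest centroid.

    Returns ``{nucleus_id: truth nucleus_id}``; a segmented nucleus is
    matched only if its centroid lies within the matched ellipse's major
    semi-axis of the truth centroid.
    """
    out: dict[int, int] = {}
    tr = truth[["centroid_row", "centroid_col"]].to_numpy()
    for rec in records:
        d = np.hypot(tr[:, 0] - rec.centroid[0], tr[:, 1] - rec.centroid[1])
        k = int(np.argmin(d))
        if d[k] <= float(truth["semi_axis_a"].iloc[k]):
            out[rec.nucleus_id] = int(truth["nucleus_id"].iloc[k])
    return out
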