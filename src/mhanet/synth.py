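"""Deterministic synthetic image/mask pairs for three modalities.

The generator emulates the qualitative geometry of the three imaging
settings the network targets, without any download:

* ``vessel`` — dark curvilinear structures of varying thickness on a
  smooth textured background (retinal-fundus-like): random-walk curves
  with jittered curvature, rendered as chains of disks.
* ``stent`` — thin bright woven-lattice wires (fluoroscopy-like): two
  mirrored families of sinusoidal strands.
* ``polyp`` — one or two blob-like deformed ellipses with low contrast and
  blurred boundary: a radial Fourier perturbation of a circle.

Image = smooth low-frequency background texture +/- ``contrast`` on the
foreground, optional Gaussian blur, plus Gaussian pixel noise, clipped to
[0, 1]. Everything is a pure function of (spec, seed). A bounded retry
loop rescales structure count/size until the realized foreground fraction
falls inside the requested interval.
"""

from __future__ import annotations

import csv
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from PIL import Image
from scipy.ndimage import gaussian_filter
from skimage.draw import disk, polygon

STYLES = ("vessel", "stent", "polyp")
_MAX_RETRIES = 12


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for one synthetic sample."""

    size: tuple[int, int] = (96, 96)
    style: str = "vessel"
    foreground_fraction: tuple[float, float] = (0.03, 0.15)
    contrast: float = 0.5
    noise_sd: float = 0.03
    blur_sigma: float = 0.7

    def __post_init__(self):
        if self.style not in STYLES:
            raise ValueError(f"style must be one of {STYLES}, got {self.style!r}")
        lo, hi = self.foreground_fraction
        if not (0 < lo < hi < 1):
            raise ValueError(f"foreground_fraction interval {self.foreground_fraction} is empty")
        if not (0 < self.contrast <= 1):
            raise ValueError("contrast must lie in (0, 1]")
        if self.noise_sd < 0 or self.blur_sigma < 0:
            raise ValueError("noise_sd and blur_sigma must be >= 0")


@dataclass(frozen=True)
class SampleRecord:
    """One generated image/mask pair with its provenance."""

    image: np.ndarray  # (H, W, 3) float in [0, 1]
    mask: np.ndarray  # (H, W) uint8 in {0, 1}
    seed: int
    spec: SyntheticSpec


def default_spec(style: str, size: tuple[int, int] = (96, 96)) -> SyntheticSpec:
    """Per-style defaults with realistic foreground fractions."""
    presets = {
        "vessel": dict(foreground_fraction=(0.03, 0.15), contrast=0.45),
        "stent": dict(foreground_fraction=(0.01, 0.08), contrast=0.6),
        "polyp": dict(foreground_fraction=(0.05, 0.30), contrast=0.4),
    }
    return SyntheticSpec(size=size, style=style, **presets[style])


# -- mask rendering --------------------------------------------------------


def _draw_vessels(rng: np.random.Generator, hw, scale: float) -> np.ndarray:
    h, w = hw
    mask = np.zeros(hw, dtype=bool)
    n_curves = max(1, round(3 * scale * (h * w) / (96 * 96) + rng.integers(0, 2)))
    for _ in range(n_curves):
        edge = rng.integers(0, 4)
        if edge == 0:
            y, x, ang = 0.0, rng.uniform(0, w), rng.uniform(0.25, 0.75) * np.pi
        elif edge == 1:
            y, x, ang = h - 1.0, rng.uniform(0, w), -rng.uniform(0.25, 0.75) * np.pi
        elif edge == 2:
            y, x, ang = rng.uniform(0, h), 0.0, rng.uniform(-0.25, 0.25) * np.pi
        else:
            y, x, ang = rng.uniform(0, h), w - 1.0, np.pi + rng.uniform(-0.25, 0.25) * np.pi
        r = rng.uniform(1.0, 2.2)
        for _ in range(int(2.5 * max(h, w))):
            ang += rng.normal(0, 0.18)
            y += np.sin(ang)
            x += np.cos(ang)
            if not (0 <= y < h and 0 <= x < w):
                break
            r = np.clip(r + rng.normal(0, 0.05), 0.8, 3.0)
            rr, cc = disk((y, x), r, shape=hw)
            mask[rr, cc] = True
    return mask


def _draw_stent(rng: np.random.Generator, hw, scale: float) -> np.ndarray:
    h, w = hw
    mask = np.zeros(hw, dtype=bool)
    n_strands = max(1, round(1.5 * scale))
    xs = np.arange(w)
    amp = h * rng.uniform(0.06, 0.12)
    freq = rng.uniform(1.5, 3.0)
    for k in range(n_strands):
        off = (k + 0.5) * h / n_strands + rng.normal(0, 1.5)
        phase = rng.uniform(0, 2 * np.pi)
        for sign in (+1, -1):  # mirrored sinusoid pair -> woven lattice
            ys = np.round(off + sign * amp * np.sin(2 * np.pi * freq * xs / w + phase)).astype(int)
            for dy in (0, 1):  # wire width ~2 px
                yi = ys + dy
                ok = (yi >= 0) & (yi < h)
                mask[yi[ok], xs[ok]] = True
    return mask


def _draw_polyps(rng: np.random.Generator, hw, scale: float) -> np.ndarray:
    h, w = hw
    mask = np.zeros(hw, dtype=bool)
    n_blobs = 1 + (rng.random() < 0.3)
    lo_dim = min(h, w)
    for _ in range(n_blobs):
        r0 = scale * lo_dim * rng.uniform(0.12, 0.2) / np.sqrt(n_blobs)
        cy = rng.uniform(0.25 * h, 0.75 * h)
        cx = rng.uniform(0.25 * w, 0.75 * w)
        theta = np.linspace(0, 2 * np.pi, 200, endpoint=False)
        rr = np.full_like(theta, r0)
        for k in range(2, 6):
            rr += r0 * rng.normal(0, 0.08) * np.cos(k * theta + rng.uniform(0, 2 * np.pi))
        stretch = rng.uniform(0.7, 1.4)
        yy = cy + rr * np.sin(theta) * stretch
        xx = cx + rr * np.cos(theta)
        pr, pc = polygon(yy, xx, shape=hw)
        mask[pr, pc] = True
    return mask


_RENDERERS = {"vessel": _draw_vessels, "stent": _draw_stent, "polyp": _draw_polyps}


def _render_mask(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    lo, hi = spec.foreground_fraction
    target = 0.5 * (lo + hi)
    scale = 1.0
    for _ in range(_MAX_RETRIES):
        mask = _RENDERERS[spec.style](rng, spec.size, scale)
        frac = mask.mean()
        if lo <= frac <= hi:
            return mask.astype(np.uint8)
        if frac <= 0:
            scale = min(scale * 2.0, 32.0)
            continue
        adj = target / frac
        if spec.style == "polyp":  # blob area scales ~ radius^2
            adj = np.sqrt(adj)
        scale = float(np.clip(scale * adj, 1 / 32, 32.0))
    raise ValueError(
        f"could not realize foreground fraction in {spec.foreground_fraction} "
        f"for style {spec.style!r} after {_MAX_RETRIES} attempts"
    )


def generate_sample(spec: SyntheticSpec, seed: int) -> SampleRecord:
    """Render one image/mask pair, fully determined by (spec, seed)."""
    rng = np.random.default_rng(seed)
    h, w = spec.size
    mask = _render_mask(spec, rng)
    # smooth low-frequency background around mid-gray
    bg = gaussian_filter(rng.normal(size=(h, w)), sigma=max(h, w) / 8.0)
    span = max(bg.max() - bg.min(), 1e-9)
    bg = 0.45 + 0.2 * (bg - bg.min()) / span
    sign = -1.0 if spec.style == "vessel" else 1.0  # vessels are dark, wires/blobs bright
    field = bg + sign * spec.contrast * mask
    if spec.blur_sigma > 0:
        field = gaussian_filter(field, sigma=spec.blur_sigma)
    gains = 1.0 + 0.08 * rng.normal(size=3)
    image = field[:, :, None] * gains[None, None, :]
    if spec.noise_sd > 0:
        image = image + rng.normal(0, spec.noise_sd, size=image.shape)
    return SampleRecord(
        image=np.clip(image, 0.0, 1.0).astype(np.float32),
        mask=mask,
        seed=int(seed),
        spec=spec,
    )


def sample_seed(global_seed: int, index: int) -> int:
    """Counter-based per-sample seed: reproducible regardless of order."""
    return int(np.random.SeedSequence([int(global_seed), int(index)]).generate_state(1)[0] % 2**31)


def make_dataset(n: int, spec: SyntheticSpec, seed: int) -> list[SampleRecord]:
    """Generate ``n`` samples from one spec under a single global seed."""
    return [generate_sample(spec, sample_seed(seed, i)) for i in range(n)]


# -- disk round trip -------------------------------------------------------

MANIFEST_NAME = "manifest.csv"


def write_dataset(records: list[SampleRecord], directory: str | Path) -> Path:
    """Write images (8-bit RGB PNG), masks ({0,255} 8-bit PNG) and a CSV
    manifest; returns the manifest path."""
    directory = Path(directory)
    (directory / "images").mkdir(parents=True, exist_ok=True)
    (directory / "masks").mkdir(parents=True, exist_ok=True)
    manifest = directory / MANIFEST_NAME
    try:
        with open(manifest, "w", newline="") as f:
            writer = csv.writer(f)
            writer.writerow(["image_path", "mask_path", "seed", "style", "spec_json"])
            for i, rec in enumerate(records):
                img_rel = f"images/{i:05d}.png"
                msk_rel = f"masks/{i:05d}.png"
                img8 = np.round(rec.image * 255).astype(np.uint8)
                Image.fromarray(img8, mode="RGB").save(directory / img_rel)
                Image.fromarray(rec.mask * 255, mode="L").save(directory / msk_rel)
                writer.writerow([img_rel, msk_rel, rec.seed, rec.spec.style, json.dumps(asdict(rec.spec))])
    except OSError as e:
        raise OSError(f"failed writing dataset under {directory}: {e}") from e
    return manifest


def read_dataset(directory: str | Path) -> list[SampleRecord]:
    """Read a written dataset back; masks binarize at >127 exactly."""
    directory = Path(directory)
    manifest = directory / MANIFEST_NAME
    if not manifest.exists():
        raise FileNotFoundError(f"no {MANIFEST_NAME} under {directory}")
    out = []
    with open(manifest, newline="") as f:
        for row in csv.DictReader(f):
            img = np.asarray(Image.open(directory / row["image_path"]).convert("RGB"))
            msk = np.asarray(Image.open(directory / row["mask_path"]).convert("L"))
            spec_d = json.loads(row["spec_json"])
            spec_d["size"] = tuple(spec_d["size"])
            spec_d["foreground_fraction"] = tuple(spec_d["foreground_fraction"])
            out.append(
                SampleRecord(
                    image=(img / 255.0).astype(np.float32),
                    mask=(msk > 127).astype(np.uint8),
                    seed=int(row["seed"]),
                    spec=SyntheticSpec(**spec_d),
                )
            )
    return out
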