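"""Synthetic grain scenes and feature tables with known ground truth.

Real grain images of the reference study are proprietary, so every
downstream stage (segmentation, feature extraction, classification) is
exercised on rendered scenes instead.  Grains are drawn as boundary-wavy
ellipses — an ellipse whose radius is modulated by a low-order sinusoid —
filled with the class CIELab color converted to sRGB plus small per-pixel
Gaussian noise, placed in random non-touching poses on a uniform dark or
light background.  An optional touching mode places a fraction of grains in
contact to exercise watershed splitting.

A second, much cheaper path samples the nine morpho-colorimetric
descriptors directly from per-class Gaussian moments (``sample_feature_table``),
which is what the classifier tests use.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from skimage.color import lab2rgb

from .specs import FEATURE_NAMES, ClassSpec

YELLOWNESS_COEF = 142.86  # YI = 142.86 * b / L

BACKGROUND_GRAY = {"dark": 10, "light": 245}


class PlacementError(RuntimeError):
    """Raised when grains cannot be placed without touching."""

    def __init__(self, requested: int, achieved: int):
        self.requested = requested
        self.achieved = achieved
        super().__init__(
            f"could only place {achieved} of {requested} grains without "
            f"touching; use a larger image or fewer grains"
        )


@dataclass
class GrainTruth:
    """Analytic ground truth for one rendered grain."""

    class_id: int
    center: tuple[float, float]  # (row, col)
    semi_major: float
    semi_minor: float
    orientation: float  # radians, major axis vs. column axis
    waviness: float
    phase: float
    lab: tuple[float, float, float]

    @property
    def aspect_ratio(self) -> float:
        return self.semi_major / self.semi_minor


@dataclass
class GrainScene:
    """Rendered RGB image plus per-grain ground truth."""

    image: np.ndarray  # (H, W, 3) uint8
    truth: list[GrainTruth]
    truth_labels: np.ndarray  # (H, W) int32, 0 = background, k = grain k
    touching_pairs: list[tuple[int, int]]
    background_polarity: str

    @property
    def n_grains(self) -> int:
        return len(self.truth)


def _ellipse_radius(psi: np.ndarray, a: float, b: float) -> np.ndarray:
    """Polar radius of an axis-aligned ellipse at angle psi from its center."""
    return a * b / np.hypot(b * np.cos(psi), a * np.sin(psi))


def _rasterize_grain(
    shape: tuple[int, int], g: GrainTruth, k_wave: int = 4
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Return (rows, cols, inside) index arrays for one grain's pixels.

    A pixel belongs to the grain if its center lies inside the wavy-ellipse
    boundary r(psi) = r_ellipse(psi) * (1 + w * sin(k*psi + phase)).
    """
    r0, c0 = g.center
    reach = g.semi_major * (1.0 + g.waviness) + 1.5
    rlo = max(int(np.floor(r0 - reach)), 0)
    rhi = min(int(np.ceil(r0 + reach)) + 1, shape[0])
    clo = max(int(np.floor(c0 - reach)), 0)
    chi = min(int(np.ceil(c0 + reach)) + 1, shape[1])
    rr, cc = np.mgrid[rlo:rhi, clo:chi]
    dy = rr - r0
    dx = cc - c0
    ct, st = np.cos(g.orientation), np.sin(g.orientation)
    u = ct * dx + st * dy  # along major axis
    v = -st * dx + ct * dy
    psi = np.arctan2(v, u)
    radius = _ellipse_radius(psi, g.semi_major, g.semi_minor)
    boundary = radius * (1.0 + g.waviness * np.sin(k_wave * psi + g.phase))
    inside = np.hypot(u, v) <= boundary
    return rr[inside], cc[inside], inside


def _grain_reach(a: float, waviness: float, margin: float) -> float:
    return a * (1.0 + waviness) + margin


def _tangent_distance(g: "GrainTruth", h: "GrainTruth", phi: float) -> float:
    """Center distance at which two ellipses placed along ``phi`` touch.

    Uses support functions: ellipses A and B (B displaced by d along the
    unit vector of phi) first touch at d = min_n [h_A(n) + h_B(n)] /
    cos(n - phi) over contact normals n within 90 degrees of phi.  The sum
    of directional polar radii underestimates this whenever the contact
    normal is not aligned with phi, which would bury one tip inside the
    other grain.
    """
    n = phi + np.linspace(-np.pi / 2 + 0.05, np.pi / 2 - 0.05, 181)
    hA = np.hypot(g.semi_major * np.cos(n - g.orientation),
                  g.semi_minor * np.sin(n - g.orientation))
    hB = np.hypot(h.semi_major * np.cos(n - h.orientation),
                  h.semi_minor * np.sin(n - h.orientation))
    return float(np.min((hA + hB) / np.cos(n - phi)))


def render_grain_scene(
    specs: Sequence[ClassSpec],
    n_per_class: int,
    image_size: tuple[int, int] = (768, 768),
    touching_fraction: float = 0.0,
    seed: int | None = None,
    background: str | None = None,
    noise_sd: float = 2.0,
    margin: float = 3.0,
    max_tries: int = 2000,
) -> GrainScene:
    """Render a scene of grains in random poses with ground truth.

    Parameters
    ----------
    specs:
        Class specifications; ``n_per_class`` grains are rendered per spec.
    touching_fraction:
        Fraction of grains placed as touching pairs (near-tangent rigid-body
        contact) for watershed testing; the default 0 places all grains
        non-touching with a ``margin``-pixel clearance.
    background:
        'dark' or 'light'; default is the majority background polarity of
        the supplied specs.

    Deterministic for a fixed seed.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    if not specs:
        raise ValueError("specs must be non-empty")
    if not 0 <= touching_fraction <= 1:
        raise ValueError("touching_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    H, W = image_size

    if background is None:
        n_dark = sum(s.background_polarity == "dark" for s in specs)
        background = "dark" if n_dark * 2 >= len(specs) else "light"

    # Sample per-grain geometry and color first, then place.
    pending: list[GrainTruth] = []
    for spec in specs:
        for _ in range(n_per_class):
            a = max(rng.normal(spec.semi_major_mean, spec.semi_major_sd), 4.0)
            ar = max(rng.normal(spec.aspect_ratio_mean, spec.aspect_ratio_sd), 1.02)
            w = float(np.clip(rng.normal(spec.waviness_mean, spec.waviness_sd), 0.0, 0.2))
            lab = tuple(
                float(rng.normal(m, s)) for m, s in zip(spec.lab_mean, spec.lab_sd)
            )
            lab = (float(np.clip(lab[0], 0.0, 100.0)), lab[1], lab[2])
            pending.append(
                GrainTruth(
                    class_id=spec.class_id,
                    center=(np.nan, np.nan),
                    semi_major=float(a),
                    semi_minor=float(a / ar),
                    orientation=float(rng.uniform(0, np.pi)),
                    waviness=w,
                    phase=float(rng.uniform(0, 2 * np.pi)),
                    lab=lab,
                )
            )
    order = rng.permutation(len(pending))
    pending = [pending[i] for i in order]

    n_total = len(pending)
    n_touch = int(touching_fraction * n_total) // 2 * 2  # grains in pairs

    placed: list[GrainTruth] = []
    reaches: list[float] = []
    touching_pairs: list[tuple[int, int]] = []

    def fits(r0: float, c0: float, reach: float, partner: int | None = None) -> bool:
        if not (reach <= r0 <= H - 1 - reach and reach <= c0 <= W - 1 - reach):
            return False
        for j, (g, rj) in enumerate(zip(placed, reaches)):
            if partner is not None and j == partner:
                continue
            if np.hypot(r0 - g.center[0], c0 - g.center[1]) < reach + rj:
                return False
        return True

    idx = 0
    while idx < n_total:
        g = pending[idx]
        reach = _grain_reach(g.semi_major, g.waviness, margin)
        as_pair = idx + 1 < n_total and len(touching_pairs) * 2 < n_touch
        h = pending[idx + 1] if as_pair else None
        ok = False
        for _ in range(max_tries):
            r0 = rng.uniform(reach, H - 1 - reach)
            c0 = rng.uniform(reach, W - 1 - reach)
            if not fits(r0, c0, reach):
                continue
            if h is None:
                g.center = (float(r0), float(c0))
                placed.append(g)
                reaches.append(reach)
                ok = True
                break
            # partner in tip-to-flank contact: the contact direction stays
            # within 15 degrees of the first grain's major axis, so at least
            # one boundary is strongly curved at the contact point and the
            # pair leaves a watershed-detectable neck.  (Two grains lying
            # flank-to-flank in parallel merge into a near-convex blob that
            # no distance-transform method can split; that configuration is
            # deliberately not generated.)  Centers sit at 98% of the summed
            # directional radii: rigid-body contact with just enough overlap
            # to guarantee a pixel bridge after rasterization.
            reach2 = _grain_reach(h.semi_major, h.waviness, margin)
            for _ in range(50):
                phi = g.orientation + rng.uniform(-np.pi / 12, np.pi / 12)
                if rng.random() < 0.5:
                    phi += np.pi
                # tangency distance minus one pixel: rigid-body contact with
                # just enough overlap to guarantee a pixel bridge
                d = _tangent_distance(g, h, phi) - 1.0
                pr, pc = r0 + d * np.sin(phi), c0 + d * np.cos(phi)
                g.center = (float(r0), float(c0))
                placed.append(g)
                reaches.append(reach)
                if fits(pr, pc, reach2, partner=len(placed) - 1):
                    h.center = (float(pr), float(pc))
                    placed.append(h)
                    reaches.append(reach2)
                    touching_pairs.append((len(placed) - 2, len(placed) - 1))
                    ok = True
                    break
                placed.pop()
                reaches.pop()
            if ok:
                break
        if not ok:
            raise PlacementError(n_total, len(placed))
        idx += 2 if h is not None else 1

    # Rasterize.
    bg = BACKGROUND_GRAY[background]
    img = np.full((H, W, 3), float(bg))
    labels = np.zeros((H, W), dtype=np.int32)
    for k, g in enumerate(placed, start=1):
        rows, cols, _ = _rasterize_grain((H, W), g)
        rgb = lab2rgb(np.asarray(g.lab, dtype=float)[None, None, :])[0, 0]
        img[rows, cols] = np.clip(rgb, 0, 1) * 255.0
        labels[rows, cols] = k
    if noise_sd > 0:
        img += rng.normal(0.0, noise_sd, img.shape)
    image = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return GrainScene(
        image=image,
        truth=placed,
        truth_labels=labels,
        touching_pairs=touching_pairs,
        background_polarity=background,
    )


def sample_feature_table(
    specs: Sequence[ClassSpec], n_per_class: int, seed: int | None = None
) -> pd.DataFrame:
    """Sample per-grain feature vectors directly from class moments.

    Eight descriptors (FD, Cir, AR, Ext, APIdx, L, a, b) are independent
    Gaussian draws from each class's mean/SD; the yellowness index is then
    computed from the sampled L and b as YI = 142.86*b/L rather than sampled
    independently, preserving the exact algebraic tie between the three
    columns.  Values are clipped to descriptor domains (Cir > 0, AR >= 1,
    Ext in (0, 1], L in [0, 100]).
    """
    if n_per_class < 0:
        raise ValueError("n_per_class must be >= 0")
    rng = np.random.default_rng(seed)
    rows = []
    for spec in specs:
        if spec.feature_means is None or spec.feature_sds is None:
            raise ValueError(
                f"class {spec.abbreviation} lacks feature moments for sampling"
            )
        mu = spec.feature_means
        sd = spec.feature_sds
        for name in FEATURE_NAMES[:-1]:  # all but YI
            if name not in mu or name not in sd:
                raise ValueError(f"class {spec.abbreviation} missing moments for {name}")
        draws = {
            name: rng.normal(mu[name], sd[name], size=n_per_class)
            for name in FEATURE_NAMES[:-1]
        }
        draws["Cir"] = np.maximum(draws["Cir"], 1e-6)
        draws["AR"] = np.maximum(draws["AR"], 1.0)
        draws["Ext"] = np.clip(draws["Ext"], 1e-6, 1.0)
        draws["L"] = np.clip(draws["L"], 1e-6, 100.0)
        draws["YI"] = YELLOWNESS_COEF * draws["b"] / draws["L"]
        frame = pd.DataFrame(draws)
        frame["class_id"] = spec.class_id
        rows.append(frame)
    if not rows or n_per_class == 0:
        return pd.DataFrame(columns=list(FEATURE_NAMES) + ["class_id"])
    return pd.concat(rows, ignore_index=True)[list(FEATURE_NAMES) + ["class_id"]]


def separable_class_specs(n_classes: int = 15) -> list[ClassSpec]:
    """Feature-moment specs for a well-separated benchmark condition.

    Class means sit on a lightness x aspect-ratio lattice with steps of at
    least ten within-class standard deviations (L levels 15 apart with
    SD 1.5; AR levels 1.5 apart with SD 0.15), so every pair of classes is
    separated by >= 6 pooled SDs in at least one descriptor.  Used to check
    that the classifier recovers a signal that is unambiguous by
    construction; real rice classes overlap far more.
    """
    if not 1 <= n_classes <= 15:
        raise ValueError("n_classes must lie in 1..15")
    L_levels = [20.0, 35.0, 50.0, 65.0, 80.0]
    ar_levels = [1.5, 3.0, 4.5]
    specs = []
    for i in range(n_classes):
        L = L_levels[i % 5]
        ar = ar_levels[i // 5]
        means = {
            "FD": 1.7, "Cir": 0.8, "AR": ar, "Ext": 0.7, "APIdx": 0.5,
            "L": L, "a": 2.0, "b": 2.0, "YI": YELLOWNESS_COEF * 2.0 / L,
        }
        sds = {
            "FD": 0.05, "Cir": 0.03, "AR": 0.15, "Ext": 0.03, "APIdx": 0.05,
            "L": 1.5, "a": 0.3, "b": 0.4, "YI": 0.0,
        }
        specs.append(
            ClassSpec(
                class_id=i + 1,
                abbreviation=f"S{i + 1:02d}",
                semi_major_mean=float(np.sqrt(600.0 * ar / np.pi)),
                semi_major_sd=1.5,
                aspect_ratio_mean=ar,
                aspect_ratio_sd=0.15,
                lab_mean=(L, 2.0, 2.0),
                lab_sd=(1.5, 0.3, 0.4),
                background_polarity="dark" if L >= 40 else "light",
                feature_means=means,
                feature_sds=sds,
            )
        )
    return specs


def save_scene(scene: GrainScene, png_path: str | Path, truth_path: str | Path) -> None:
    """Write a scene as a PNG image plus a JSON ground-truth sidecar."""
    from PIL import Image

    Image.fromarray(scene.image).save(str(png_path))
    payload = {
        "background_polarity": scene.background_polarity,
        "touching_pairs": [list(p) for p in scene.touching_pairs],
        "grains": [asdict(g) for g in scene.truth],
    }
    Path(truth_path).write_text(json.dumps(payload, indent=1))


def load_truth(truth_path: str | Path) -> list[GrainTruth]:
    """Read the ground-truth sidecar written by :func:`save_scene`."""
    payload = json.loads(Path(truth_path).read_text())
    out = []
    for d in payload["grains"]:
        d["center"] = tuple(d["center"])
        d["lab"] = tuple(d["lab"])
        out.append(GrainTruth(**d))
    return out
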