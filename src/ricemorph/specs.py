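"""Class specifications for grain rendering and feature-space sampling.

A :class:`ClassSpec` bundles everything the synthetic module needs to know
about one rice type: an integer class id and abbreviation, the geometry of
its grains (semi-major axis, aspect ratio, boundary waviness), its CIELab
color, the background polarity it is imaged against, and optionally the
per-feature means/spreads of the nine morpho-colorimetric descriptors used
by the direct feature-space sampler.

The packaged default (``default_class_specs()``) covers the 15 commercial
rice types of the reference dataset, from short/bold grains (aspect ratio
about 1.6) to long/slender wild rice (aspect ratio 5.19), with class colors
spanning CIELab lightness 27.5 (black rice) to 59.5 (polished white rice).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np

FEATURE_NAMES = ("FD", "Cir", "AR", "Ext", "APIdx", "L", "a", "b", "YI")

#: Reference grain area (px^2) used to derive per-class semi-major axes from
#: the aspect-ratio mean: a = sqrt(area * AR / pi), b = a / AR.
REFERENCE_GRAIN_AREA = 600.0


@dataclass
class ClassSpec:
    """Rendering and sampling parameters for one grain class."""

    class_id: int
    abbreviation: str
    semi_major_mean: float
    semi_major_sd: float
    aspect_ratio_mean: float
    aspect_ratio_sd: float
    waviness_mean: float = 0.04
    waviness_sd: float = 0.01
    lab_mean: tuple[float, float, float] = (55.0, 2.0, 0.0)
    lab_sd: tuple[float, float, float] = (1.5, 0.3, 0.5)
    background_polarity: str = "dark"
    feature_means: dict[str, float] | None = None
    feature_sds: dict[str, float] | None = None

    def __post_init__(self) -> None:
        if self.aspect_ratio_mean < 1:
            raise ValueError(
                f"aspect-ratio mean must be >= 1, got {self.aspect_ratio_mean}"
            )
        L = self.lab_mean[0]
        if not 0 <= L <= 100:
            raise ValueError(f"CIELab L mean must lie in [0, 100], got {L}")
        for name, value in (
            ("semi_major_sd", self.semi_major_sd),
            ("aspect_ratio_sd", self.aspect_ratio_sd),
            ("waviness_sd", self.waviness_sd),
        ):
            if value < 0:
                raise ValueError(f"{name} must be non-negative, got {value}")
        if any(s < 0 for s in self.lab_sd):
            raise ValueError("lab_sd entries must be non-negative")
        if self.background_polarity not in ("dark", "light"):
            raise ValueError("background_polarity must be 'dark' or 'light'")
        if self.feature_sds is not None and any(
            v < 0 for v in self.feature_sds.values()
        ):
            raise ValueError("feature dispersions must be non-negative")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ClassSpec":
        d = dict(d)
        d["lab_mean"] = tuple(d["lab_mean"])
        d["lab_sd"] = tuple(d["lab_sd"])
        return cls(**d)


def load_reference_table() -> dict:
    """Return the packaged reference statistics for the 15 rice types."""
    with resources.files("ricemorph.data").joinpath("rice_reference.json").open() as fh:
        return json.load(fh)


def reference_class_counts() -> dict[str, int]:
    """Per-class grain counts of the reference dataset, keyed by abbreviation."""
    return {c["abbreviation"]: c["n"] for c in load_reference_table()["classes"]}


def default_class_specs() -> list[ClassSpec]:
    """Build the 15 default class specs from the packaged reference table.

    Geometry is derived from the class aspect-ratio mean at a common
    reference grain area so that slender classes render long and narrow and
    bold classes short and wide; colors are the class CIELab means.  Dark
    classes (L < 40: black and wild rice) get a light background, the rest a
    dark background, mirroring the contrast rule used at image capture.
    """
    specs = []
    for row in load_reference_table()["classes"]:
        mean, sd = row["mean"], row["sd"]
        ar = mean["AR"]
        a = float(np.sqrt(REFERENCE_GRAIN_AREA * ar / np.pi))
        specs.append(
            ClassSpec(
                class_id=row["class_id"],
                abbreviation=row["abbreviation"],
                semi_major_mean=a,
                semi_major_sd=0.06 * a,
                aspect_ratio_mean=ar,
                aspect_ratio_sd=sd["AR"],
                lab_mean=(mean["L"], mean["a"], mean["b"]),
                lab_sd=(sd["L"], sd["a"], sd["b"]),
                background_polarity="light" if mean["L"] < 40 else "dark",
                feature_means={k: mean[k] for k in FEATURE_NAMES},
                feature_sds={k: sd[k] for k in FEATURE_NAMES},
            )
        )
    return specs


def save_class_specs(specs: Sequence[ClassSpec], path: str | Path) -> None:
    """Write class specs to a JSON config file."""
    Path(path).write_text(
        json.dumps({"classes": [s.to_dict() for s in specs]}, indent=2)
    )


def load_class_specs(path: str | Path) -> list[ClassSpec]:
    """Read class specs from a JSON (or YAML) config file."""
    text = Path(path).read_text()
    if str(path).endswith((".yaml", ".yml")):
        import yaml

        payload = yaml.safe_load(text)
    else:
        payload = json.loads(text)
    return [ClassSpec.from_dict(d) for d in payload["classes"]]
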